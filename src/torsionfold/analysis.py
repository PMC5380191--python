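"""Trajectory observables: superposition RMSD, radius of gyration,
conformational clustering, reaction coordinates, Ramachandran populations,
and Karplus scalar couplings."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import constants as C
from .geometry import kabsch_rotation
from .peptide import PeptideStructure, Trajectory

__all__ = [
    "RamaClassifier",
    "KarplusParams",
    "NativeContactSpec",
    "kabsch_rmsd",
    "radius_of_gyration",
    "kmeans_cluster",
    "collective_hbond_distance",
    "stacking_distance",
    "classify_conformations",
    "karplus_j",
]

# indole ring heavy atoms used when no XIN pseudo-atom is present
_TRP_RING_ATOMS = ("CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2")

# approximate atomic masses (amu) for mass-weighted Rg
_MASSES = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}


def _select(structure: PeptideStructure, atom_selection) -> np.ndarray:
    """Resolve a selection (None = all atoms, atom-name iterable, or
    explicit 0-based index array) to index array."""
    if atom_selection is None:
        return np.arange(structure.n_atoms)
    sel = list(atom_selection)
    if sel and isinstance(sel[0], str):
        names = set(sel)
        return np.array([i for i, nm in enumerate(structure.atom_names)
                         if nm in names], dtype=int)
    return np.asarray(sel, dtype=int)


# ---------------------------------------------------------------------------
# Superposition and size
# ---------------------------------------------------------------------------

def kabsch_rmsd(
    mobile: PeptideStructure,
    reference: PeptideStructure,
    atom_selection=None,
) -> float:
    """Minimal RMSD (Å) over rigid rotations+translations between paired
    atom selections (proper rotation enforced)."""
    mi = _select(mobile, atom_selection)
    ri = _select(reference, atom_selection)
    if len(mi) != len(ri):
        raise ValueError(
            f"selection lengths differ: {len(mi)} vs {len(ri)}")
    if len(mi) < 3:
        raise ValueError("need at least 3 atoms for superposition")
    a = mobile.coordinates[mi]
    b = reference.coordinates[ri]
    rot, trans = kabsch_rotation(a, b)
    moved = a @ rot.T + trans
    return float(np.sqrt(np.mean(np.sum((moved - b) ** 2, axis=1))))


def radius_of_gyration(
    structure: PeptideStructure,
    atom_selection=None,
    mass_weighted: bool = False,
) -> float:
    """sqrt(Σ w_i |r_i − r_cm|² / Σ w_i) in Å."""
    idx = _select(structure, atom_selection)
    if len(idx) == 0:
        raise ValueError("empty atom selection")
    r = structure.coordinates[idx]
    if mass_weighted:
        w = np.array([_MASSES.get(structure.elements[i], 12.011)
                      for i in idx])
    else:
        w = np.ones(len(idx))
    cm = (w[:, None] * r).sum(axis=0) / w.sum()
    return float(np.sqrt((w * np.sum((r - cm) ** 2, axis=1)).sum() / w.sum()))


# ---------------------------------------------------------------------------
# Clustering
# ---------------------------------------------------------------------------

def _featurize(traj: Trajectory, atom_selection) -> np.ndarray:
    """Frames as flattened coordinates after superposition onto frame 0."""
    ref_idx = _select(traj.frames[0], atom_selection)
    ref = traj.frames[0].coordinates[ref_idx]
    ref = ref - ref.mean(axis=0)
    feats = np.empty((traj.n_frames, ref.size))
    for k, fr in enumerate(traj.frames):
        x = fr.coordinates[_select(fr, atom_selection)]
        rot, trans = kabsch_rotation(x, ref)
        feats[k] = (x @ rot.T + trans).ravel()
    return feats


def kmeans_cluster(
    trajectory: Trajectory,
    k: int,
    atom_selection=None,
    seed: int = 0,
    max_iter: int = 300,
):
    """Seeded Lloyd k-means over superposed frame coordinates.

    Returns ``(labels, centroid_frame_indices, populations)`` where the
    centroid frame of each cluster is its member closest to the cluster
    mean and populations sum to 1 exactly.
    """
    n = trajectory.n_frames
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > n:
        raise ValueError(f"k={k} exceeds the {n} available frames")
    x = _featurize(trajectory, atom_selection)
    rng = np.random.default_rng(seed)
    centers = x[rng.choice(n, size=k, replace=False)].copy()
    labels = np.full(n, -1)
    for _ in range(max_iter):
        d2 = ((x[:, None, :] - centers[None, :, :]) ** 2).sum(axis=2)
        new_labels = d2.argmin(axis=1)
        for c in range(k):
            if not np.any(new_labels == c):
                # re-seed an empty cluster with the farthest point
                far = int(d2.min(axis=1).argmax())
                new_labels[far] = c
        if np.array_equal(new_labels, labels):
            break
        labels = new_labels
        for c in range(k):
            centers[c] = x[labels == c].mean(axis=0)
    centroid_frames = []
    for c in range(k):
        members = np.flatnonzero(labels == c)
        d = ((x[members] - centers[c]) ** 2).sum(axis=1)
        centroid_frames.append(int(members[d.argmin()]))
    counts = np.bincount(labels, minlength=k)
    populations = counts / counts.sum()
    return labels, centroid_frames, populations


# ---------------------------------------------------------------------------
# Reaction coordinates
# ---------------------------------------------------------------------------

@dataclass
class NativeContactSpec:
    """Native inter-strand hydrogen bonds (donor residue, acceptor residue)
    and Trp stacking pairs (residue, residue), 1-based."""

    hbond_pairs: tuple[tuple[int, int], ...] = ()
    stacking_pairs: tuple[tuple[int, int], ...] = C.DEFAULT_STACKING_PAIRS


def collective_hbond_distance(
    frame: PeptideStructure,
    spec: NativeContactSpec,
    mode: str = "mean",
) -> float:
    """Aggregate N···O distance (Å) over the native hydrogen-bond pairs;
    ``mode`` is ``mean`` (default), ``max``, or ``rms``."""
    if not spec.hbond_pairs:
        raise ValueError("spec defines no native hydrogen-bond pairs")
    dists = []
    for donor, acceptor in spec.hbond_pairs:
        try:
            n = frame.position(donor, "N")
            o = frame.position(acceptor, "O")
        except KeyError as exc:
            raise KeyError(
                f"native pair ({donor}, {acceptor}): {exc}") from exc
        dists.append(float(np.linalg.norm(n - o)))
    dists = np.asarray(dists)
    if mode == "mean":
        return float(dists.mean())
    if mode == "max":
        return float(dists.max())
    if mode == "rms":
        return float(np.sqrt((dists ** 2).mean()))
    raise ValueError(f"unknown aggregation mode {mode!r}")


def _trp_centroid(frame: PeptideStructure, residue: int) -> np.ndarray:
    if frame.residue_name(residue) != "TRP":
        raise ValueError(f"residue {residue} is not TRP")
    if frame.has_atom(residue, "XIN"):
        return frame.position(residue, "XIN")
    ring = [frame.position(residue, nm) for nm in _TRP_RING_ATOMS
            if frame.has_atom(residue, nm)]
    if not ring:
        raise ValueError(
            f"TRP {residue} has neither an XIN pseudo-atom nor ring atoms")
    return np.mean(ring, axis=0)


def stacking_distance(frame: PeptideStructure, spec: NativeContactSpec) -> float:
    """Mean indole-centroid distance (Å) over the Trp stacking pairs."""
    if not spec.stacking_pairs:
        raise ValueError("spec defines no stacking pairs")
    dists = [float(np.linalg.norm(_trp_centroid(frame, a)
                                  - _trp_centroid(frame, b)))
             for a, b in spec.stacking_pairs]
    return float(np.mean(dists))


# ---------------------------------------------------------------------------
# Ramachandran classification and J couplings
# ---------------------------------------------------------------------------

@dataclass
class RamaClassifier:
    """Ordered (label, rectangles) regions on the Ramachandran plane;
    the first matching region wins and ``other`` is the fallback."""

    regions: tuple = C.DEFAULT_RAMA_REGIONS

    def __post_init__(self):
        for label, rects in self.regions:
            for pmin, pmax, qmin, qmax in rects:
                if not (-180 <= pmin <= pmax <= 180
                        and -180 <= qmin <= qmax <= 180):
                    raise ValueError(
                        f"region {label!r} rectangle outside [-180, 180]²")

    @property
    def labels(self) -> list[str]:
        return [lab for lab, _ in self.regions] + ["other"]

    def classify(self, phi: float, psi: float) -> str:
        for label, rects in self.regions:
            for pmin, pmax, qmin, qmax in rects:
                if pmin <= phi <= pmax and qmin <= psi <= qmax:
                    return label
        return "other"


def classify_conformations(phi_psi_list, classifier: RamaClassifier | None = None):
    """Population fraction per region label; fractions sum to 1 exactly."""
    classifier = classifier or RamaClassifier()
    counts = {lab: 0 for lab in classifier.labels}
    pts = list(phi_psi_list)
    for phi, psi in pts:
        counts[classifier.classify(float(phi), float(psi))] += 1
    n = max(len(pts), 1)
    return {lab: c / n for lab, c in counts.items()}


_KARPLUS = dict(C.DEFAULT_KARPLUS)


@dataclass
class KarplusParams:
    """J(θ) = A cos²θ + B cos θ + C with θ = φ − phase (Hz, degrees)."""

    A: float = _KARPLUS["A"]
    B: float = _KARPLUS["B"]
    C: float = _KARPLUS["C"]
    phase_deg: float = _KARPLUS["phase_deg"]

    def __post_init__(self):
        for v in (self.A, self.B, self.C, self.phase_deg):
            if not np.isfinite(v):
                raise ValueError("Karplus parameters must be finite")


def karplus_j(phi_deg, params: KarplusParams | None = None):
    """Three-bond scalar coupling (Hz) from the Karplus relation; accepts
    scalars or arrays (ensemble averages are plain means over frames)."""
    params = params or KarplusParams()
    theta = np.radians(np.asarray(phi_deg, dtype=float) - params.phase_deg)
    j = params.A * np.cos(theta) ** 2 + params.B * np.cos(theta) + params.C
    return float(j) if j.ndim == 0 else j
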