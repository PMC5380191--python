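"""Distance-dependent hydrogen-bond polarization charge model.

When a backbone hydrogen bond N–H···O=C forms, electron density
redistributes.  This module models the effect as a charge alteration that
decays exponentially with the donor–acceptor (N···O) distance d,

    Δq(d) = a · exp(−b · d),

applied as strictly paired transfers — N with its amide H, and C with its
carbonyl O — so total charge is conserved exactly by construction.  The
exponential was parameterized on hydrogen-bonded dipeptide pairs over
d ∈ [2.5, 6.5] Å; outside that range the model is clamped, not
extrapolated.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import curve_fit

from . import constants as C
from .errors import ConvergenceError
from .peptide import PeptideStructure

__all__ = [
    "HBond",
    "PolarizationParams",
    "ChargeSet",
    "detect_hbonds",
    "delta_q",
    "fit_exponential",
    "apply_polarization",
]


@dataclass(frozen=True)
class HBond:
    """One backbone hydrogen bond; ``d`` is the N···O distance in Å."""

    donor_n_index: int
    donor_h_index: int
    acceptor_o_index: int
    acceptor_c_index: int
    d: float

    def __post_init__(self):
        if self.d <= 0:
            raise ValueError("hydrogen-bond distance must be positive")

    @property
    def atom_indices(self) -> tuple[int, int, int, int]:
        return (self.donor_n_index, self.donor_h_index,
                self.acceptor_o_index, self.acceptor_c_index)


@dataclass
class PolarizationParams:
    """Exponential Δq(d) parameters: amplitude a (e) and decay b (1/Å) for
    the donor nitrogen and the acceptor oxygen, plus the validity range."""

    a_N: float = C.PLACEHOLDER_POLARIZATION["a_N"]
    b_N: float = C.PLACEHOLDER_POLARIZATION["b_N"]
    a_O: float = C.PLACEHOLDER_POLARIZATION["a_O"]
    b_O: float = C.PLACEHOLDER_POLARIZATION["b_O"]
    d_min: float = C.POLARIZATION_D_MIN_A
    d_max: float = C.POLARIZATION_D_MAX_A

    def __post_init__(self):
        if self.b_N <= 0 or self.b_O <= 0:
            raise ValueError("decay constants must be positive")
        if not self.d_min < self.d_max:
            raise ValueError("d_min must be below d_max")


@dataclass
class ChargeSet:
    """Base and polarized per-atom partial charges (e)."""

    base_charges: np.ndarray
    polarized_charges: np.ndarray
    provenance: str = ""

    def __post_init__(self):
        self.base_charges = np.asarray(self.base_charges, dtype=float)
        self.polarized_charges = np.asarray(self.polarized_charges, dtype=float)
        if self.base_charges.shape != self.polarized_charges.shape:
            raise ValueError("charge arrays must be aligned")
        if abs(self.base_charges.sum() - self.polarized_charges.sum()) > 1e-12:
            raise ValueError("polarization must conserve total charge")


def detect_hbonds(
    structure: PeptideStructure,
    d_cutoff: float = C.DEFAULT_HBOND_DISTANCE_A,
    angle_cutoff: float = C.DEFAULT_HBOND_ANGLE_DEG,
    min_seq_sep: int = C.DEFAULT_HBOND_MIN_SEQ_SEP,
) -> list[HBond]:
    """Backbone N–H···O=C hydrogen bonds.

    A donor/acceptor pair qualifies when the N···O distance is at most
    ``d_cutoff`` Å, the N–H···O angle at the hydrogen is at least
    ``angle_cutoff`` degrees, and the residues are at least ``min_seq_sep``
    apart in sequence.  Non-proline residues without an amide H are skipped
    with a warning.  Results are sorted by donor residue, then distance.
    """
    donors = []   # (residue, n_idx, h_idx)
    acceptors = []  # (residue, o_idx, c_idx)
    for r in structure.residue_ids:
        rname = structure.residue_name(r)
        if rname not in C.CAP_RESIDUES or rname == "NME":
            if structure.has_atom(r, "N"):
                if structure.has_atom(r, "H"):
                    donors.append((r, structure.atom_index(r, "N"),
                                   structure.atom_index(r, "H")))
                elif rname != "PRO":
                    warnings.warn(
                        f"residue {r} ({rname}) has no amide H; "
                        "skipped as donor", stacklevel=2)
        if structure.has_atom(r, "C") and structure.has_atom(r, "O"):
            acceptors.append((r, structure.atom_index(r, "O"),
                              structure.atom_index(r, "C")))

    coords = structure.coordinates
    found = []
    for dres, n_i, h_i in donors:
        for ares, o_i, c_i in acceptors:
            if abs(dres - ares) < min_seq_sep:
                continue
            d = float(np.linalg.norm(coords[n_i] - coords[o_i]))
            if d > d_cutoff or d_cutoff <= 0:
                continue
            hn = coords[n_i] - coords[h_i]
            ho = coords[o_i] - coords[h_i]
            cosang = np.dot(hn, ho) / (np.linalg.norm(hn) * np.linalg.norm(ho))
            angle = float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))
            if angle < angle_cutoff:
                continue
            found.append(HBond(n_i, h_i, o_i, c_i, d))
    res_of = {hb: structure.residue_indices[hb.donor_n_index] for hb in found}
    found.sort(key=lambda hb: (res_of[hb], hb.d))
    return found


def delta_q(params: PolarizationParams, d: float, atom_kind: str) -> float:
    """Charge alteration a·exp(−b·d) in e, with d clamped to the fitted
    range before evaluation."""
    if d <= 0:
        raise ValueError("distance must be positive")
    if atom_kind == "N":
        a, b = params.a_N, params.b_N
    elif atom_kind == "O":
        a, b = params.a_O, params.b_O
    else:
        raise ValueError(f"atom_kind must be 'N' or 'O', got {atom_kind!r}")
    d_eff = min(max(d, params.d_min), params.d_max)
    return a * np.exp(-b * d_eff)


def fit_exponential(samples) -> tuple[float, float]:
    """Fit (a, b) of Δq = a·exp(−b·d) to (d, Δq) samples.

    Nonlinear least squares seeded by the log-linear closed form.  All Δq
    must share one sign; the model cannot change sign.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim != 2 or samples.shape[1] != 2 or len(samples) < 3:
        raise ValueError("need >= 3 (d, delta_q) samples")
    d, dq = samples[:, 0], samples[:, 1]
    if len(np.unique(d)) != len(d):
        raise ValueError("d values must be distinct")
    if np.any(dq == 0) or (np.any(dq > 0) and np.any(dq < 0)):
        raise ValueError(
            "delta_q samples must be nonzero and share one sign")
    sign = 1.0 if dq[0] > 0 else -1.0
    # log-linear initialization: ln|dq| = ln|a| - b d
    slope, intercept = np.polyfit(d, np.log(np.abs(dq)), 1)
    p0 = (sign * np.exp(intercept), -slope)

    def model(x, a, b):
        return a * np.exp(-b * x)

    try:
        popt, _ = curve_fit(model, d, dq, p0=p0, maxfev=10000)
    except RuntimeError as exc:
        raise ConvergenceError(f"exponential fit did not converge: {exc}")
    return float(popt[0]), float(popt[1])


def apply_polarization(
    structure: PeptideStructure,
    base: ChargeSet,
    params: PolarizationParams,
    hbonds: list[HBond],
) -> ChargeSet:
    """Polarized charges after paired N↔H and C↔O transfers.

    Each hydrogen bond moves Δq_N(d) from H to N and Δq_O(d) from C to O.
    An atom engaged in several detected bonds receives charge only through
    its shortest-distance bond (the model was parameterized on a single
    hydrogen-bonded pair); bonds sharing any atom with an already-applied
    shorter bond are dropped entirely so the pairing stays consistent.
    """
    n = structure.n_atoms
    if base.base_charges.shape != (n,):
        raise ValueError("base charges not aligned with structure")
    q = base.base_charges.copy()
    used: set[int] = set()
    touched: dict[int, int] = {}
    for k, hb in enumerate(sorted(hbonds, key=lambda h: h.d)):
        atoms = hb.atom_indices
        if any(i >= n for i in atoms):
            raise ValueError("hydrogen bond references atoms outside structure")
        if any(i in used for i in atoms):
            continue
        dq_n = delta_q(params, hb.d, "N")
        dq_o = delta_q(params, hb.d, "O")
        for i in atoms:
            if i in touched:
                raise RuntimeError(
                    f"internal consistency error: atom {i} charged twice")
            touched[i] = k
        q[hb.donor_n_index] += dq_n
        q[hb.donor_h_index] -= dq_n
        q[hb.acceptor_o_index] += dq_o
        q[hb.acceptor_c_index] -= dq_o
        used.update(atoms)
    return ChargeSet(base_charges=base.base_charges, polarized_charges=q,
                     provenance="apply_polarization (shortest-partner rule)")
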