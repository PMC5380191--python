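"""Peptide structural model, PDB I/O, and deterministic ideal-geometry
fixture builders (helix, hairpin, extended chain).

The in-memory model is deliberately flat — parallel per-atom arrays — which
maps 1:1 onto PDB ATOM records and onto the force arrays used by the
mechanics module.  Atom indices are 0-based internally; residue numbering is
1-based, matching PDB output.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

from . import constants as C
from .errors import GeometryError, PDBFormatError
from .geometry import measure_dihedral, place_atom

__all__ = [
    "PeptideStructure",
    "Trajectory",
    "DihedralQuadruplet",
    "read_pdb",
    "write_pdb",
    "build_ideal_peptide",
    "enumerate_backbone_dihedrals",
]


@dataclass
class PeptideStructure:
    """Flat per-atom representation of one peptide conformation.

    All arrays are aligned: ``atom_names[i]`` labels the atom whose position
    is ``coordinates[i]`` (Å).  ``residue_indices`` are 1-based and
    non-decreasing.
    """

    atom_names: list[str]
    residue_names: list[str]
    residue_indices: np.ndarray
    elements: list[str]
    coordinates: np.ndarray

    def __post_init__(self):
        self.residue_indices = np.asarray(self.residue_indices, dtype=int)
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        self.validate()

    def validate(self) -> None:
        n = len(self.atom_names)
        if not (len(self.residue_names) == len(self.residue_indices)
                == len(self.elements) == n):
            raise ValueError("per-atom arrays have inconsistent lengths")
        if self.coordinates.shape != (n, 3):
            raise ValueError(
                f"coordinate array shape {self.coordinates.shape} != ({n}, 3)")
        if n and not np.all(np.isfinite(self.coordinates)):
            raise ValueError("non-finite coordinates")
        if n and np.any(np.diff(self.residue_indices) < 0):
            raise ValueError("residue_indices must be non-decreasing")

    @property
    def n_atoms(self) -> int:
        return len(self.atom_names)

    @property
    def residue_ids(self) -> list[int]:
        """Ordered unique residue indices."""
        seen: dict[int, None] = {}
        for r in self.residue_indices:
            seen[int(r)] = None
        return list(seen)

    def residue_name(self, residue_index: int) -> str:
        mask = self.residue_indices == residue_index
        if not mask.any():
            raise KeyError(f"no residue {residue_index}")
        return self.residue_names[int(np.flatnonzero(mask)[0])]

    def atom_index(self, residue_index: int, atom_name: str) -> int:
        """0-based index of *atom_name* in residue *residue_index*."""
        for i in np.flatnonzero(self.residue_indices == residue_index):
            if self.atom_names[int(i)] == atom_name:
                return int(i)
        raise KeyError(
            f"residue {residue_index} has no atom {atom_name!r}")

    def has_atom(self, residue_index: int, atom_name: str) -> bool:
        try:
            self.atom_index(residue_index, atom_name)
            return True
        except KeyError:
            return False

    def position(self, residue_index: int, atom_name: str) -> np.ndarray:
        return self.coordinates[self.atom_index(residue_index, atom_name)]

    def with_coordinates(self, coordinates: np.ndarray) -> "PeptideStructure":
        """Copy sharing topology but with new coordinates."""
        return PeptideStructure(
            atom_names=list(self.atom_names),
            residue_names=list(self.residue_names),
            residue_indices=self.residue_indices.copy(),
            elements=list(self.elements),
            coordinates=np.asarray(coordinates, dtype=float).copy(),
        )


@dataclass
class Trajectory:
    """Ordered frames sharing one topology, with optional per-frame
    temperature (K) and potential energy (kcal/mol) metadata."""

    frames: list[PeptideStructure]
    temperatures: np.ndarray | None = None
    energies: np.ndarray | None = None

    def __post_init__(self):
        if not self.frames:
            raise ValueError("trajectory must contain at least one frame")
        n0 = self.frames[0].n_atoms
        names0 = self.frames[0].atom_names
        for k, fr in enumerate(self.frames):
            if fr.n_atoms != n0 or fr.atom_names != names0:
                raise ValueError(
                    f"frame {k} does not share the topology of frame 0")
        for meta in ("temperatures", "energies"):
            arr = getattr(self, meta)
            if arr is not None:
                arr = np.asarray(arr, dtype=float)
                if arr.shape != (len(self.frames),):
                    raise ValueError(f"{meta} length != frame count")
                setattr(self, meta, arr)

    @property
    def n_frames(self) -> int:
        return len(self.frames)


@dataclass(frozen=True)
class DihedralQuadruplet:
    """Four 0-based atom indices defining a backbone φ or ψ torsion."""

    atom_indices: tuple[int, int, int, int]
    label: str              # "phi" | "psi"
    residue_index: int      # 1-based

    def __post_init__(self):
        if self.label not in ("phi", "psi"):
            raise ValueError(f"label must be phi or psi, got {self.label!r}")
        if len(set(self.atom_indices)) != 4:
            raise ValueError("atom indices must be four distinct atoms")


# ---------------------------------------------------------------------------
# PDB I/O (biotite-backed)
# ---------------------------------------------------------------------------

def _structure_to_atom_array(s: PeptideStructure) -> struc.AtomArray:
    arr = struc.AtomArray(s.n_atoms)
    arr.coord = s.coordinates.astype(np.float32)
    arr.atom_name = np.array(s.atom_names, dtype="U6")
    arr.res_name = np.array(s.residue_names, dtype="U5")
    arr.res_id = s.residue_indices
    arr.element = np.array(s.elements, dtype="U2")
    arr.chain_id = np.full(s.n_atoms, "A", dtype="U4")
    arr.hetero = np.full(s.n_atoms, False)
    return arr


def write_pdb(traj: "Trajectory | PeptideStructure", path) -> None:
    """Write a structure or trajectory as a (multi-model) PDB file."""
    if isinstance(traj, PeptideStructure):
        traj = Trajectory(frames=[traj])
    stack = struc.stack([_structure_to_atom_array(f) for f in traj.frames])
    pdb = PDBFile()
    pdb.set_structure(stack)
    pdb.write(str(path))


def _precheck_models(path) -> None:
    """Cheap text validation producing a model-index-naming error for
    multi-model files with inconsistent atom counts."""
    counts: list[int] = []
    current: int | None = None
    with open(path) as fh:
        for line in fh:
            rec = line[:6]
            if rec == "MODEL ":
                current = 0
            elif rec in ("ATOM  ", "HETATM"):
                if current is None:
                    current = 0
                current += 1
            elif rec.startswith("ENDMDL"):
                counts.append(current or 0)
                current = None
    if current is not None and current > 0:
        counts.append(current)
    if len(counts) > 1 and len(set(counts)) > 1:
        ref = counts[0]
        for k, c in enumerate(counts):
            if c != ref:
                raise PDBFormatError(
                    f"model {k + 1} has {c} atoms, expected {ref}")


def read_pdb(path) -> Trajectory:
    """Read a PDB file into a :class:`Trajectory` (one frame per MODEL)."""
    path = Path(path)
    if not path.exists():
        raise IOError(f"no such file: {path}")
    _precheck_models(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None)
    except PDBFormatError:
        raise
    except Exception as exc:  # biotite raises various parse errors
        raise PDBFormatError(f"cannot parse PDB file {path}: {exc}") from exc
    if isinstance(stack, struc.AtomArray):
        stack = struc.stack([stack])
    frames = []
    for model in stack:
        frames.append(PeptideStructure(
            atom_names=[str(x) for x in model.atom_name],
            residue_names=[str(x) for x in model.res_name],
            residue_indices=np.asarray(model.res_id, dtype=int),
            elements=[str(x) for x in model.element],
            coordinates=np.asarray(model.coord, dtype=float),
        ))
    return Trajectory(frames=frames)


# ---------------------------------------------------------------------------
# Ideal-geometry builder
# ---------------------------------------------------------------------------

class _Builder:
    """Accumulates atoms during an internal-coordinate build."""

    def __init__(self):
        self.names: list[str] = []
        self.resnames: list[str] = []
        self.resids: list[int] = []
        self.elements: list[str] = []
        self.coords: list[np.ndarray] = []

    def add(self, name, resname, resid, element, pos):
        self.names.append(name)
        self.resnames.append(resname)
        self.resids.append(resid)
        self.elements.append(element)
        self.coords.append(np.asarray(pos, dtype=float))

    def to_structure(self) -> PeptideStructure:
        order = np.argsort(np.asarray(self.resids, dtype=int), kind="stable")
        return PeptideStructure(
            atom_names=[self.names[i] for i in order],
            residue_names=[self.resnames[i] for i in order],
            residue_indices=np.asarray([self.resids[i] for i in order]),
            elements=[self.elements[i] for i in order],
            coordinates=np.asarray([self.coords[i] for i in order]),
        )


def build_ideal_peptide(
    sequence: str,
    dihedrals: Sequence[tuple[float, float]],
    capped: bool = False,
) -> PeptideStructure:
    """Build a peptide with the requested backbone (φ, ψ) per residue.

    Bond lengths/angles come from :mod:`torsionfold.constants`; ω is fixed
    trans (180°).  Measured backbone dihedrals of the result reproduce the
    requested values to well below 1e-6°.  For an uncapped chain, φ of the
    first residue and ψ of the last are not physically realizable (no
    flanking peptide group); with ``capped=True`` an ACE/NME pair is added
    and every requested torsion is realized.

    Hydrogens placed: amide H (not on PRO) and one HA per residue.  Side
    chains are a CB pseudo-atom (absent for GLY); TRP additionally carries
    an indole-centroid pseudo-atom ``XIN`` for stacking distances.
    """
    if len(sequence) == 0:
        raise ValueError("empty sequence")
    if len(dihedrals) != len(sequence):
        raise ValueError(
            f"{len(dihedrals)} dihedral pairs for {len(sequence)} residues")
    resnames = []
    for code in sequence:
        try:
            resnames.append(C.AA_1TO3[code.upper()])
        except KeyError:
            raise ValueError(f"unknown residue code {code!r}") from None
    for phi, psi in dihedrals:
        if not (-180.0 <= phi <= 180.0 and -180.0 <= psi <= 180.0):
            raise ValueError("dihedral angles must lie in [-180, 180]")

    n_res = len(sequence)
    first_resid = 2 if capped else 1
    b = _Builder()
    bl, ba = C.BOND_LENGTHS, C.BOND_ANGLES

    # backbone N/CA/C
    n_pos = [None] * n_res
    ca_pos = [None] * n_res
    c_pos = [None] * n_res
    n_pos[0] = np.zeros(3)
    ca_pos[0] = np.array([bl[("N", "CA")], 0.0, 0.0])
    ang = np.radians(180.0 - ba[("N", "CA", "C")])
    c_pos[0] = ca_pos[0] + bl[("CA", "C")] * np.array(
        [np.cos(ang), np.sin(ang), 0.0])
    for i in range(n_res - 1):
        psi_i = dihedrals[i][1]
        n_pos[i + 1] = place_atom(n_pos[i], ca_pos[i], c_pos[i],
                                  bl[("C", "N")], ba[("CA", "C", "N")], psi_i)
        ca_pos[i + 1] = place_atom(ca_pos[i], c_pos[i], n_pos[i + 1],
                                   bl[("N", "CA")], ba[("C", "N", "CA")],
                                   C.OMEGA_TRANS_DEG)
        c_pos[i + 1] = place_atom(c_pos[i], n_pos[i + 1], ca_pos[i + 1],
                                  bl[("CA", "C")], ba[("N", "CA", "C")],
                                  dihedrals[i + 1][0])

    for i in range(n_res):
        resid = first_resid + i
        rn = resnames[i]
        b.add("N", rn, resid, "N", n_pos[i])
        b.add("CA", rn, resid, "C", ca_pos[i])
        b.add("C", rn, resid, "C", c_pos[i])
        # carbonyl O anti to the next amide N (psi + 180)
        o = place_atom(n_pos[i], ca_pos[i], c_pos[i],
                       bl[("C", "O")], ba[("CA", "C", "O")],
                       dihedrals[i][1] + 180.0)
        b.add("O", rn, resid, "O", o)
        # amide H
        if rn != "PRO":
            if i > 0:
                h = place_atom(ca_pos[i - 1], c_pos[i - 1], n_pos[i],
                               bl[("N", "H")], ba[("C", "N", "H")], 0.0)
            else:
                h = place_atom(c_pos[0], ca_pos[0], n_pos[0],
                               bl[("N", "H")], ba[("CA", "N", "H")], 180.0)
            b.add("H", rn, resid, "H", h)
        # HA and CB about the N-CA axis, referenced to the carbonyl C
        ha = place_atom(c_pos[i], n_pos[i], ca_pos[i],
                        bl[("CA", "HA")], ba[("N", "CA", "HA")],
                        C.HA_IMPROPER_DEG)
        b.add("HA", rn, resid, "H", ha)
        if rn != "GLY":
            cb = place_atom(c_pos[i], n_pos[i], ca_pos[i],
                            bl[("CA", "CB")], ba[("N", "CA", "CB")],
                            C.CB_IMPROPER_DEG)
            b.add("CB", rn, resid, "C", cb)
            if rn == "TRP":
                xin = place_atom(n_pos[i], ca_pos[i], cb,
                                 bl[("CB", "XIN")], ba[("CA", "CB", "XIN")],
                                 C.XIN_TORSION_DEG)
                b.add("XIN", rn, resid, "C", xin)

    if capped:
        # ACE provides C(0) so that phi of residue 1 is realized
        c0 = place_atom(c_pos[0], ca_pos[0], n_pos[0],
                        bl[("C", "N")], ba[("C", "N", "CA")],
                        dihedrals[0][0])
        o0 = place_atom(ca_pos[0], n_pos[0], c0,
                        bl[("C", "O")], ba[("N", "C", "O")], 0.0)
        ch3_0 = place_atom(ca_pos[0], n_pos[0], c0,
                           bl[("C", "CH3")], ba[("N", "C", "CH3")],
                           C.OMEGA_TRANS_DEG)
        b.add("CH3", "ACE", 1, "C", ch3_0)
        b.add("C", "ACE", 1, "C", c0)
        b.add("O", "ACE", 1, "O", o0)
        # NME provides N(n+1) at psi of the last residue
        last = n_res - 1
        n_cap = place_atom(n_pos[last], ca_pos[last], c_pos[last],
                           bl[("C", "N")], ba[("CA", "C", "N")],
                           dihedrals[last][1])
        h_cap = place_atom(ca_pos[last], c_pos[last], n_cap,
                           bl[("N", "H")], ba[("C", "N", "H")], 0.0)
        ch3_cap = place_atom(ca_pos[last], c_pos[last], n_cap,
                             bl[("N", "CH3")], ba[("C", "N", "CH3")],
                             C.OMEGA_TRANS_DEG)
        cap_id = first_resid + n_res
        b.add("N", "NME", cap_id, "N", n_cap)
        b.add("H", "NME", cap_id, "H", h_cap)
        b.add("CH3", "NME", cap_id, "C", ch3_cap)

    return b.to_structure()


# ---------------------------------------------------------------------------
# Dihedral enumeration
# ---------------------------------------------------------------------------

def enumerate_backbone_dihedrals(
    structure: PeptideStructure,
) -> list[DihedralQuadruplet]:
    """All backbone φ (C⁻-N-CA-C) and ψ (N-CA-C-N⁺) quadruplets.

    For an n-residue uncapped chain this yields n−1 of each; ACE/NME caps
    contribute their C/N atoms so every amino residue of a capped chain has
    both torsions.

    Raises
    ------
    PDBFormatError
        If an amino residue is missing a backbone atom, naming the residue
        and the atom.
    """
    resids = structure.residue_ids
    amino = [r for r in resids
             if structure.residue_name(r) not in C.CAP_RESIDUES]
    has_caps = len(amino) < len(resids)
    if not amino or (len(amino) < 2 and not has_caps):
        raise ValueError("need at least 2 residues with full backbone "
                         "(or a capped chain)")

    for r in amino:
        for name in ("N", "CA", "C"):
            if not structure.has_atom(r, name):
                raise PDBFormatError(
                    f"residue {r} ({structure.residue_name(r)}) "
                    f"is missing backbone atom {name}")

    def prev_c(r: int) -> int | None:
        if r - 1 in resids and structure.has_atom(r - 1, "C"):
            return structure.atom_index(r - 1, "C")
        return None

    def next_n(r: int) -> int | None:
        if r + 1 in resids and structure.has_atom(r + 1, "N"):
            return structure.atom_index(r + 1, "N")
        return None

    quads: list[DihedralQuadruplet] = []
    for r in amino:
        i_n = structure.atom_index(r, "N")
        i_ca = structure.atom_index(r, "CA")
        i_c = structure.atom_index(r, "C")
        pc = prev_c(r)
        if pc is not None:
            quads.append(DihedralQuadruplet((pc, i_n, i_ca, i_c), "phi", r))
        nn = next_n(r)
        if nn is not None:
            quads.append(DihedralQuadruplet((i_n, i_ca, i_c, nn), "psi", r))
    return quads


def measure_backbone_dihedrals(
    structure: PeptideStructure,
) -> dict[int, dict[str, float]]:
    """Measured φ/ψ (degrees) keyed by residue index then label."""
    out: dict[int, dict[str, float]] = {}
    for q in enumerate_backbone_dihedrals(structure):
        pts = [structure.coordinates[i] for i in q.atom_indices]
        out.setdefault(q.residue_index, {})[q.label] = measure_dihedral(*pts)
    return out
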