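"""Cartesian forces from the 2D torsion surface.

For every residue carrying both a φ and a ψ quadruplet, the torsion energy
E(φ_r, ψ_r) contributes to atom k the force

    F_k = −( ∂E/∂φ · ∂φ/∂R_k + ∂E/∂ψ · ∂ψ/∂R_k )

with the dihedral gradients computed analytically.  Because each dihedral
gradient has zero net translation and zero net torque, the accumulated
force set is conservative: total force and total torque vanish to
numerical precision.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np

from .geometry import dihedral_gradient, measure_dihedral
from .peptide import DihedralQuadruplet, PeptideStructure
from .torsion2d import FourierCoefficients, evaluate_surface, surface_partials

logger = logging.getLogger(__name__)

__all__ = ["ForceSet", "torsion_forces"]


@dataclass
class ForceSet:
    """Per-atom 3-vectors in kcal/mol/Å, aligned with a structure's atoms."""

    forces: np.ndarray

    def __post_init__(self):
        self.forces = np.asarray(self.forces, dtype=float)
        if self.forces.ndim != 2 or self.forces.shape[1] != 3:
            raise ValueError("forces must have shape (n_atoms, 3)")
        if not np.all(np.isfinite(self.forces)):
            raise ValueError("non-finite forces")

    @property
    def net_force(self) -> np.ndarray:
        return self.forces.sum(axis=0)

    def net_torque(self, positions: np.ndarray) -> np.ndarray:
        return np.cross(np.asarray(positions, float), self.forces).sum(axis=0)


def torsion_forces(
    structure: PeptideStructure,
    quadruplets: list[DihedralQuadruplet],
    coeffs: FourierCoefficients,
) -> tuple[float, ForceSet]:
    """Total 2D-torsion energy (kcal/mol) and per-atom forces.

    Residues with only one of φ/ψ (chain termini) contribute nothing to the
    coupled 2D term and are skipped with a debug log entry.
    """
    by_residue: dict[int, dict[str, DihedralQuadruplet]] = {}
    for q in quadruplets:
        by_residue.setdefault(q.residue_index, {})[q.label] = q

    coords = structure.coordinates
    forces = np.zeros_like(coords)
    energy = 0.0
    for resid, quads in sorted(by_residue.items()):
        if "phi" not in quads or "psi" not in quads:
            logger.debug(
                "residue %d lacks a full (phi, psi) pair; skipped", resid)
            continue
        qphi, qpsi = quads["phi"], quads["psi"]
        p_phi = [coords[i] for i in qphi.atom_indices]
        p_psi = [coords[i] for i in qpsi.atom_indices]
        phi = measure_dihedral(*p_phi)
        psi = measure_dihedral(*p_psi)
        energy += evaluate_surface(coeffs, phi, psi)
        de_dphi, de_dpsi = surface_partials(coeffs, phi, psi)
        gphi = dihedral_gradient(*p_phi)
        gpsi = dihedral_gradient(*p_psi)
        for k, idx in enumerate(qphi.atom_indices):
            forces[idx] -= de_dphi * gphi[k]
        for k, idx in enumerate(qpsi.atom_indices):
            forces[idx] -= de_dpsi * gpsi[k]
    return float(energy), ForceSet(forces)
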