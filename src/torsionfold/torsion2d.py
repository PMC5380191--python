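"""Coupled two-dimensional backbone torsion surface.

A CMAP-style correction energy E(φ, ψ) is tabulated on a regular periodic
(φ, ψ) lattice — conventionally 24×24 nodes at 15° — obtained by
subtracting the non-torsion molecular-mechanics internal energy and the
solvation free energy from a quantum-chemical total:

    E_torsion = E_QM − E_other − G_solv

The tabulated surface is then expanded in a double Fourier series

    E(φ, ψ) = Σ_{m,n} [ c_cc cos mφ cos nψ + c_cs cos mφ sin nψ
                      + c_sc sin mφ cos nψ + c_ss sin mφ sin nψ ]

which is smooth, exactly periodic, and analytically differentiable — the
partial derivatives feed the Cartesian force evaluation in
:mod:`torsionfold.mechanics`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import CoefficientFormatError

__all__ = [
    "TorsionGrid",
    "FourierCoefficients",
    "decompose_grid",
    "fit_fourier",
    "evaluate_surface",
    "surface_partials",
    "write_coefficients",
    "read_coefficients",
    "write_grid_csv",
    "read_grid_csv",
]

_GRID_TOL = 1e-9


def _check_axis(values: np.ndarray, name: str) -> float:
    values = np.asarray(values, dtype=float)
    if values.ndim != 1 or len(values) < 2:
        raise ValueError(f"{name} must be a 1-D array of >= 2 angles")
    d = np.diff(values)
    if np.any(d <= 0):
        raise ValueError(f"{name} must be strictly increasing")
    spacing = d[0]
    if not np.allclose(d, spacing, atol=_GRID_TOL):
        raise ValueError(f"{name} must be uniformly spaced")
    if abs(360.0 / spacing - round(360.0 / spacing)) > 1e-8:
        raise ValueError(
            f"{name} spacing {spacing}° must divide 360° exactly")
    return float(spacing)


@dataclass
class TorsionGrid:
    """Tabulated torsion energy on a uniform periodic (φ, ψ) lattice.

    ``energy[i, j]`` is the energy (kcal/mol) at
    ``(phi_values[i], psi_values[j])``.  When component matrices are
    present, ``energy + offset == e_qm − e_other − g_solv`` elementwise
    (``offset`` records the min-shift applied by :func:`decompose_grid`).
    """

    phi_values: np.ndarray
    psi_values: np.ndarray
    energy: np.ndarray
    e_qm: np.ndarray | None = None
    e_other: np.ndarray | None = None
    g_solv: np.ndarray | None = None
    offset: float = 0.0

    def __post_init__(self):
        self.phi_values = np.asarray(self.phi_values, dtype=float)
        self.psi_values = np.asarray(self.psi_values, dtype=float)
        self.energy = np.asarray(self.energy, dtype=float)
        for name in ("e_qm", "e_other", "g_solv"):
            v = getattr(self, name)
            if v is not None:
                setattr(self, name, np.asarray(v, dtype=float))
        self.validate()

    def validate(self) -> None:
        _check_axis(self.phi_values, "phi_values")
        _check_axis(self.psi_values, "psi_values")
        shape = (len(self.phi_values), len(self.psi_values))
        if self.energy.shape != shape:
            raise ValueError(
                f"energy shape {self.energy.shape} != grid shape {shape}")
        if not np.all(np.isfinite(self.energy)):
            raise ValueError("non-finite grid energies")
        comps = (self.e_qm, self.e_other, self.g_solv)
        if all(c is not None for c in comps):
            recon = self.e_qm - self.e_other - self.g_solv
            if not np.allclose(self.energy + self.offset, recon, atol=1e-9):
                raise ValueError(
                    "energy + offset != e_qm - e_other - g_solv")

    @property
    def shape(self) -> tuple[int, int]:
        return self.energy.shape


@dataclass
class FourierCoefficients:
    """Coefficient matrices of the double Fourier expansion.

    Each matrix has shape (M+1, M+1) with ``[m, n]`` multiplying the basis
    function of order (m, n); rows m=0 of the sin-φ matrices and columns
    n=0 of the sin-ψ matrices are structurally zero.
    """

    c_cc: np.ndarray
    c_cs: np.ndarray
    c_sc: np.ndarray
    c_ss: np.ndarray
    offset: float = 0.0

    def __post_init__(self):
        mats = []
        for name in ("c_cc", "c_cs", "c_sc", "c_ss"):
            m = np.asarray(getattr(self, name), dtype=float)
            setattr(self, name, m)
            mats.append(m)
        shape = mats[0].shape
        if any(m.shape != shape for m in mats) or shape[0] != shape[1]:
            raise ValueError("coefficient matrices must share a square shape")
        if any(not np.all(np.isfinite(m)) for m in mats):
            raise ValueError("non-finite coefficients")
        if (np.any(self.c_sc[0, :] != 0.0) or np.any(self.c_ss[0, :] != 0.0)
                or np.any(self.c_cs[:, 0] != 0.0)
                or np.any(self.c_ss[:, 0] != 0.0)):
            raise ValueError(
                "structural zeros violated: sin terms of order 0 must vanish")

    @property
    def max_order(self) -> int:
        return self.c_cc.shape[0] - 1

    @classmethod
    def zeros(cls, max_order: int) -> "FourierCoefficients":
        z = np.zeros((max_order + 1, max_order + 1))
        return cls(z, z.copy(), z.copy(), z.copy())


def decompose_grid(e_qm, e_other, g_solv, phi_values, psi_values) -> TorsionGrid:
    """Extract the 2D torsion term E_QM − E_other − G_solv and shift its
    global minimum to zero (the shift is recorded in ``offset``)."""
    e_qm = np.asarray(e_qm, dtype=float)
    e_other = np.asarray(e_other, dtype=float)
    g_solv = np.asarray(g_solv, dtype=float)
    if not (e_qm.shape == e_other.shape == g_solv.shape):
        raise ValueError(
            f"component shapes differ: {e_qm.shape}, {e_other.shape}, "
            f"{g_solv.shape}")
    raw = e_qm - e_other - g_solv
    offset = float(raw.min())
    return TorsionGrid(
        phi_values=phi_values, psi_values=psi_values, energy=raw - offset,
        e_qm=e_qm, e_other=e_other, g_solv=g_solv, offset=offset,
    )


def _basis_columns(max_order: int):
    """(kind, m, n) for every structurally nonzero basis function."""
    cols = []
    for m in range(max_order + 1):
        for n in range(max_order + 1):
            cols.append(("cc", m, n))
            if n >= 1:
                cols.append(("cs", m, n))
            if m >= 1:
                cols.append(("sc", m, n))
            if m >= 1 and n >= 1:
                cols.append(("ss", m, n))
    return cols


def fit_fourier(grid: TorsionGrid, max_order: int) -> FourierCoefficients:
    """Least-squares fit of the double Fourier series to the grid energies.

    ``max_order`` must respect the aliasing (Nyquist) bound
    floor((n_nodes − 1) / 2) on each axis — 11 for a 24-point axis.
    """
    nphi, npsi = grid.shape
    bound = min((nphi - 1) // 2, (npsi - 1) // 2)
    if max_order < 0:
        raise ValueError("max_order must be >= 0")
    if max_order > bound:
        raise ValueError(
            f"max_order {max_order} exceeds the aliasing bound "
            f"floor((n_grid - 1)/2) = {bound} for a {nphi}x{npsi} grid")
    phi = np.radians(grid.phi_values)
    psi = np.radians(grid.psi_values)
    cols = _basis_columns(max_order)
    # tensor-product basis, rows ordered row-major in (phi, psi)
    a = np.empty((nphi * npsi, len(cols)))
    cphi = {m: np.cos(m * phi) for m in range(max_order + 1)}
    sphi = {m: np.sin(m * phi) for m in range(max_order + 1)}
    cpsi = {n: np.cos(n * psi) for n in range(max_order + 1)}
    spsi = {n: np.sin(n * psi) for n in range(max_order + 1)}
    for k, (kind, m, n) in enumerate(cols):
        fa = cphi[m] if kind[0] == "c" else sphi[m]
        fb = cpsi[n] if kind[1] == "c" else spsi[n]
        a[:, k] = np.outer(fa, fb).ravel()
    coef, *_ = np.linalg.lstsq(a, grid.energy.ravel(), rcond=None)
    out = FourierCoefficients.zeros(max_order)
    mats = {"cc": out.c_cc, "cs": out.c_cs, "sc": out.c_sc, "ss": out.c_ss}
    for (kind, m, n), c in zip(cols, coef):
        mats[kind][m, n] = c
    out.offset = grid.offset
    return out


def _trig(coeffs: FourierCoefficients, phi_deg, psi_deg):
    phi = np.deg2rad(np.asarray(phi_deg, dtype=float))
    psi = np.deg2rad(np.asarray(psi_deg, dtype=float))
    phi, psi = np.broadcast_arrays(phi, psi)
    orders = np.arange(coeffs.max_order + 1)
    pm = phi[..., None] * orders
    sn = psi[..., None] * orders
    return (np.cos(pm), np.sin(pm), np.cos(sn), np.sin(sn),
            orders, phi.shape)


def evaluate_surface(coeffs: FourierCoefficients, phi_deg, psi_deg):
    """Evaluate E(φ, ψ) in kcal/mol; accepts scalars or broadcastable
    arrays of angles in degrees.  Exactly periodic with period 360°."""
    cp, sp, cq, sq, _, shape = _trig(coeffs, phi_deg, psi_deg)
    e = (np.einsum("...m,mn,...n->...", cp, coeffs.c_cc, cq)
         + np.einsum("...m,mn,...n->...", cp, coeffs.c_cs, sq)
         + np.einsum("...m,mn,...n->...", sp, coeffs.c_sc, cq)
         + np.einsum("...m,mn,...n->...", sp, coeffs.c_ss, sq))
    return float(e) if shape == () else e


def surface_partials(coeffs: FourierCoefficients, phi_deg, psi_deg):
    """Analytic (∂E/∂φ, ∂E/∂ψ) in kcal/mol per *radian*."""
    cp, sp, cq, sq, orders, shape = _trig(coeffs, phi_deg, psi_deg)
    dcp = -sp * orders   # d/dφ cos(mφ)
    dsp = cp * orders    # d/dφ sin(mφ)
    dcq = -sq * orders
    dsq = cq * orders
    de_dphi = (np.einsum("...m,mn,...n->...", dcp, coeffs.c_cc, cq)
               + np.einsum("...m,mn,...n->...", dcp, coeffs.c_cs, sq)
               + np.einsum("...m,mn,...n->...", dsp, coeffs.c_sc, cq)
               + np.einsum("...m,mn,...n->...", dsp, coeffs.c_ss, sq))
    de_dpsi = (np.einsum("...m,mn,...n->...", cp, coeffs.c_cc, dcq)
               + np.einsum("...m,mn,...n->...", cp, coeffs.c_cs, dsq)
               + np.einsum("...m,mn,...n->...", sp, coeffs.c_sc, dcq)
               + np.einsum("...m,mn,...n->...", sp, coeffs.c_ss, dsq))
    if shape == ():
        return float(de_dphi), float(de_dpsi)
    return de_dphi, de_dpsi


# ---------------------------------------------------------------------------
# Text formats
# ---------------------------------------------------------------------------

def write_coefficients(coeffs: FourierCoefficients, path) -> None:
    """Write the coefficient file: a one-line header followed by one
    ``m n c_cc c_cs c_sc c_ss`` row per order pair, 17 significant digits."""
    m_ord = coeffs.max_order
    with open(path, "w") as fh:
        fh.write(f"TORSION2D v1 max_order={m_ord} units=kcal/mol\n")
        for m in range(m_ord + 1):
            for n in range(m_ord + 1):
                fh.write(
                    f"{m} {n} {coeffs.c_cc[m, n]:.17g} {coeffs.c_cs[m, n]:.17g} "
                    f"{coeffs.c_sc[m, n]:.17g} {coeffs.c_ss[m, n]:.17g}\n")


def read_coefficients(path) -> FourierCoefficients:
    with open(path) as fh:
        header = fh.readline().strip()
        parts = header.split()
        if (len(parts) != 4 or parts[0] != "TORSION2D" or parts[1] != "v1"
                or not parts[2].startswith("max_order=")):
            raise CoefficientFormatError(f"line 1: bad header {header!r}")
        try:
            m_ord = int(parts[2].split("=", 1)[1])
        except ValueError:
            raise CoefficientFormatError(
                f"line 1: bad max_order in {header!r}") from None
        out = FourierCoefficients.zeros(m_ord)
        seen = np.zeros((m_ord + 1, m_ord + 1), dtype=bool)
        for lineno, line in enumerate(fh, start=2):
            if not line.strip():
                continue
            fields = line.split()
            if len(fields) != 6:
                raise CoefficientFormatError(
                    f"line {lineno}: expected 6 columns, got {len(fields)}")
            try:
                m, n = int(fields[0]), int(fields[1])
                vals = [float(x) for x in fields[2:]]
            except ValueError:
                raise CoefficientFormatError(
                    f"line {lineno}: non-numeric entry") from None
            if not (0 <= m <= m_ord and 0 <= n <= m_ord):
                raise CoefficientFormatError(
                    f"line {lineno}: order ({m}, {n}) out of range")
            if (m == 0 and (vals[2] != 0 or vals[3] != 0)) or \
               (n == 0 and (vals[1] != 0 or vals[3] != 0)):
                raise CoefficientFormatError(
                    f"line {lineno}: nonzero structurally-zero coefficient")
            out.c_cc[m, n], out.c_cs[m, n] = vals[0], vals[1]
            out.c_sc[m, n], out.c_ss[m, n] = vals[2], vals[3]
            seen[m, n] = True
        if not seen.all():
            raise CoefficientFormatError(
                f"missing coefficient rows ({int((~seen).sum())} absent)")
    return out


def write_grid_csv(grid: TorsionGrid, path) -> None:
    """Grid CSV: ``phi_deg,psi_deg,energy`` (+ optional components), one row
    per node, row-major in φ then ψ."""
    pp, qq = np.meshgrid(grid.phi_values, grid.psi_values, indexing="ij")
    data = {"phi_deg": pp.ravel(), "psi_deg": qq.ravel(),
            "energy": grid.energy.ravel()}
    for name in ("e_qm", "e_other", "g_solv"):
        v = getattr(grid, name)
        if v is not None:
            data[name] = v.ravel()
    pd.DataFrame(data).to_csv(path, index=False)


def read_grid_csv(path) -> TorsionGrid:
    df = pd.read_csv(path)
    required = {"phi_deg", "psi_deg", "energy"}
    if not required.issubset(df.columns):
        raise ValueError(
            f"grid CSV must contain columns {sorted(required)}")
    phi = np.unique(df["phi_deg"].to_numpy())
    psi = np.unique(df["psi_deg"].to_numpy())
    shape = (len(phi), len(psi))
    if len(df) != shape[0] * shape[1]:
        raise ValueError("grid CSV does not cover a complete lattice")
    df = df.sort_values(["phi_deg", "psi_deg"], kind="stable")
    kwargs = {}
    for name in ("e_qm", "e_other", "g_solv"):
        if name in df.columns:
            kwargs[name] = df[name].to_numpy().reshape(shape)
    energy = df["energy"].to_numpy().reshape(shape)
    if len(kwargs) == 3:
        # recover the min-shift offset applied at decomposition time
        raw = kwargs["e_qm"] - kwargs["e_other"] - kwargs["g_solv"]
        kwargs["offset"] = float(np.mean(raw - energy))
    return TorsionGrid(phi_values=phi, psi_values=psi, energy=energy,
                       **kwargs)
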