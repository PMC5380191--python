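"""Multi-temperature WHAM, free-energy surfaces, and melting temperatures.

Replicas sampled at a ladder of temperatures are combined with the
weighted histogram analysis method: the self-consistent equations

    Ω(E_b) ∝ Σ_i n_i(E_b) / Σ_i N_i exp(f_i − β_i E_b)
    exp(−f_i) = Σ_b Ω(E_b) exp(−β_i E_b)

are iterated (in log space) until the per-replica shifts f_i are stable.
The recovered density of states Ω then reweights every sample to any
target temperature, which yields free-energy landscapes over arbitrary
recorded observables and the specific heat

    Cv(T) = (⟨E²⟩_T − ⟨E⟩_T²) / (k_B T²),

whose maximum over a temperature scan locates the heat-capacity peak.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .constants import KB_KCAL_MOL_K
from .errors import ConvergenceError
from .sampling import ReplicaEnsemble

__all__ = [
    "WhamState",
    "FreeEnergySurface",
    "ThermoCurve",
    "wham_solve",
    "free_energy_surface",
    "specific_heat_curve",
    "sample_weights",
]


@dataclass
class WhamState:
    """Converged WHAM solution over energy bins."""

    energy_edges: np.ndarray
    histograms: np.ndarray          # (n_replicas, n_bins) counts
    f: np.ndarray                   # per-replica dimensionless shifts, f[0]=0
    temperatures_K: np.ndarray
    sample_sizes: np.ndarray
    n_iterations: int
    final_max_delta: float
    converged: bool
    convergence_history: np.ndarray = field(default_factory=lambda: np.array([]))

    @property
    def bin_centers(self) -> np.ndarray:
        return 0.5 * (self.energy_edges[:-1] + self.energy_edges[1:])


@dataclass
class FreeEnergySurface:
    """Binned free energy (kcal/mol) over one or two observables,
    min-shifted to zero on occupied bins."""

    axis_names: tuple[str, ...]
    axis_edges: tuple[np.ndarray, ...]
    free_energy: np.ndarray
    occupied: np.ndarray
    temperature_K: float

    def __post_init__(self):
        occ = self.free_energy[self.occupied]
        if occ.size and (not np.all(np.isfinite(occ))
                         or abs(occ.min()) > 1e-9):
            raise ValueError("occupied free energies must be finite with min 0")


@dataclass
class ThermoCurve:
    """Specific heat over a temperature scan and its argmax."""

    temperatures: np.ndarray
    cv: np.ndarray
    tm: float
    out_of_range: bool = False

    def __post_init__(self):
        if np.any(self.cv < -1e-12):
            raise ValueError("specific heat must be non-negative")
        if not (self.temperatures.min() <= self.tm <= self.temperatures.max()):
            raise ValueError("tm outside the scan range")


def _pooled(ensemble: ReplicaEnsemble):
    energies = [df["energy"].to_numpy(dtype=float) for df in ensemble.samples]
    betas = 1.0 / (KB_KCAL_MOL_K * ensemble.temperatures_K)
    sizes = np.array([len(e) for e in energies])
    return energies, betas, sizes


def wham_solve(
    ensemble: ReplicaEnsemble,
    n_energy_bins: int = 200,
    tolerance: float = 1e-7,
    max_iter: int = 100000,
) -> WhamState:
    """Self-consistent temperature-WHAM over binned energies.

    Raises :class:`ConvergenceError` if max|Δf| has not dropped below
    ``tolerance`` after ``max_iter`` iterations; warns when adjacent
    replicas share no occupied energy bins (no histogram overlap).
    """
    energies, betas, sizes = _pooled(ensemble)
    pooled = np.concatenate(energies)
    lo, hi = pooled.min(), pooled.max()
    pad = 0.01 * max(hi - lo, 1e-12)
    edges = np.linspace(lo - pad, hi + pad, n_energy_bins + 1)
    hist = np.stack([np.histogram(e, bins=edges)[0] for e in energies])
    for i in range(len(energies) - 1):
        if not np.any((hist[i] > 0) & (hist[i + 1] > 0)):
            warnings.warn(
                f"replicas {i} and {i + 1} have no overlapping energy bins",
                stacklevel=2)
    centers = 0.5 * (edges[:-1] + edges[1:])
    total = hist.sum(axis=0)
    occupied = total > 0
    log_total = np.where(occupied, np.log(np.maximum(total, 1)), -np.inf)
    log_n = np.log(sizes)
    be = betas[:, None] * centers[None, :]   # (R, B)

    f = np.zeros(len(energies))
    history = []
    converged = False
    it = 0
    for it in range(1, max_iter + 1):
        # log denominator per bin: logsumexp_i [ln N_i + f_i − β_i E_b]
        log_denom = logsumexp(log_n[:, None] + f[:, None] - be, axis=0)
        log_omega = np.where(occupied, log_total - log_denom, -np.inf)
        new_f = -logsumexp(log_omega[None, :] - be, axis=1)
        new_f -= new_f[0]
        delta = float(np.max(np.abs(new_f - f)))
        history.append(delta)
        f = new_f
        if delta <= tolerance:
            converged = True
            break
    if not converged:
        raise ConvergenceError(
            f"WHAM did not converge in {max_iter} iterations "
            f"(last max|Δf| = {history[-1]:.3e})")
    return WhamState(
        energy_edges=edges, histograms=hist, f=f,
        temperatures_K=ensemble.temperatures_K.copy(),
        sample_sizes=sizes, n_iterations=it, final_max_delta=history[-1],
        converged=converged, convergence_history=np.asarray(history),
    )


def sample_weights(
    ensemble: ReplicaEnsemble,
    wham: WhamState,
    temperature_K: float,
) -> np.ndarray:
    """Normalized per-sample reweighting factors at the target temperature,
    aligned with the pooled sample order (replica 0 first)."""
    energies, betas, _ = _pooled(ensemble)
    pooled = np.concatenate(energies)
    beta = 1.0 / (KB_KCAL_MOL_K * temperature_K)
    log_n = np.log(wham.sample_sizes)
    log_denom = logsumexp(
        log_n[:, None] + wham.f[:, None] - betas[:, None] * pooled[None, :],
        axis=0)
    log_w = -beta * pooled - log_denom
    log_w -= logsumexp(log_w)
    return np.exp(log_w)


def _pooled_observable(ensemble: ReplicaEnsemble, name: str) -> np.ndarray:
    cols = []
    for k, df in enumerate(ensemble.samples):
        if name not in df.columns:
            raise ValueError(f"replica {k} has no observable {name!r}")
        cols.append(df[name].to_numpy(dtype=float))
    return np.concatenate(cols)


def free_energy_surface(
    ensemble: ReplicaEnsemble,
    wham: WhamState,
    obs_x: str,
    obs_y: str | None = None,
    bins: int | tuple[int, int] = 25,
    temperature_K: float = 300.0,
) -> FreeEnergySurface:
    """F = −k_B T ln P over one or two recorded observables, with P from
    WHAM-reweighted samples at ``temperature_K``; empty bins are masked and
    the occupied minimum is shifted to zero."""
    w = sample_weights(ensemble, wham, temperature_K)
    x = _pooled_observable(ensemble, obs_x)
    kt = KB_KCAL_MOL_K * temperature_K
    if obs_y is None:
        p, edges = np.histogram(x, bins=bins, weights=w)
        p = p[:, None]
        edges_t = (edges,)
        names = (obs_x,)
    else:
        y = _pooled_observable(ensemble, obs_y)
        p, ex, ey = np.histogram2d(x, y, bins=bins, weights=w)
        edges_t = (ex, ey)
        names = (obs_x, obs_y)
    occupied = p > 0
    with np.errstate(divide="ignore"):
        fe = np.where(occupied, -kt * np.log(np.where(occupied, p, 1.0)),
                      np.inf)
    fe = fe - fe[occupied].min()
    return FreeEnergySurface(
        axis_names=names, axis_edges=edges_t, free_energy=fe,
        occupied=occupied, temperature_K=temperature_K)


def specific_heat_curve(
    ensemble: ReplicaEnsemble,
    wham: WhamState,
    t_scan=None,
) -> ThermoCurve:
    """Cv(T) from WHAM-reweighted energy fluctuations over ``t_scan``
    (default: ladder span extended ±25% at 1 K resolution); the curve's
    argmax (ties broken toward lower T) is reported as ``tm``."""
    temps = ensemble.temperatures_K
    if t_scan is None:
        lo = 0.75 * temps.min()
        hi = 1.25 * temps.max()
        t_scan = np.arange(lo, hi + 0.5, 1.0)
    t_scan = np.asarray(t_scan, dtype=float)
    out_of_range = bool(t_scan.min() < temps.min() / 2.0
                        or t_scan.max() > temps.max() * 2.0)
    if out_of_range:
        warnings.warn("scan extends far beyond the sampled ladder; "
                      "reweighted moments may be unreliable", stacklevel=2)
    energies, betas, _ = _pooled(ensemble)
    pooled = np.concatenate(energies)
    log_n = np.log(wham.sample_sizes)
    log_denom = logsumexp(
        log_n[:, None] + wham.f[:, None] - betas[:, None] * pooled[None, :],
        axis=0)
    cv = np.empty_like(t_scan)
    for k, T in enumerate(t_scan):
        beta = 1.0 / (KB_KCAL_MOL_K * T)
        log_w = -beta * pooled - log_denom
        log_w -= logsumexp(log_w)
        w = np.exp(log_w)
        u1 = float(w @ pooled)
        u2 = float(w @ (pooled * pooled))
        cv[k] = max(u2 - u1 * u1, 0.0) / (KB_KCAL_MOL_K * T * T)
    tm = float(t_scan[int(np.argmax(cv))])
    return ThermoCurve(temperatures=t_scan, cv=cv, tm=tm,
                       out_of_range=out_of_range)
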