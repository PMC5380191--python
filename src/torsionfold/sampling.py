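"""Desk-scale samplers on the 2D torsion surface.

Metropolis Monte Carlo in (φ, ψ) space, a replica-exchange variant over a
temperature ladder, and an analytically solvable two-state ensemble
generator.  These stand in for molecular dynamics at the scale where every
expected distribution can be checked against quadrature or closed forms:
the samplers exercise the same potential surface and feed the same WHAM /
landscape analysis stack that full simulations would.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import minimize_scalar

from .constants import KB_KCAL_MOL_K, TEMPERATURE_LADDERS
from .geometry import wrap_angle
from .torsion2d import FourierCoefficients, evaluate_surface

__all__ = [
    "McConfig",
    "ReplicaEnsemble",
    "metropolis_mc",
    "replica_exchange_mc",
    "synth_two_state_ensemble",
    "two_state_tm",
    "two_state_cv_peak",
    "save_ensemble",
    "load_ensemble",
]


@dataclass
class McConfig:
    """Metropolis Monte Carlo settings.

    ``step_size_deg`` is the half-width of the uniform symmetric proposal
    applied to both angles; at 180° the proposal covers the whole torus and
    consecutive proposals are independent.
    """

    temperature_K: float
    n_steps: int
    step_size_deg: float = 30.0
    seed: int = 0
    report_stride: int = 1

    def __post_init__(self):
        if self.temperature_K <= 0:
            raise ValueError("temperature must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")
        if not 0.0 < self.step_size_deg <= 180.0:
            raise ValueError("step_size_deg must be in (0, 180]")
        if self.report_stride < 1:
            raise ValueError("report_stride must be >= 1")


@dataclass
class ReplicaEnsemble:
    """Per-temperature sample tables (energy + named observables) plus
    neighbor-swap statistics."""

    temperatures_K: np.ndarray
    samples: list[pd.DataFrame]
    exchange_stats: dict[tuple[int, int], tuple[int, int]] = field(
        default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperatures_K = np.asarray(self.temperatures_K, dtype=float)
        if len(self.samples) != len(self.temperatures_K):
            raise ValueError("one sample table per temperature required")
        if np.any(np.diff(self.temperatures_K) < 0):
            raise ValueError("temperatures must be increasing")
        for k, df in enumerate(self.samples):
            if len(df) == 0:
                raise ValueError(f"replica {k} has no samples")
            if "energy" not in df.columns:
                raise ValueError(f"replica {k} lacks an 'energy' column")
        for pair, (att, acc) in self.exchange_stats.items():
            if acc > att:
                raise ValueError(f"pair {pair}: accepted > attempted")

    @property
    def n_replicas(self) -> int:
        return len(self.temperatures_K)


def _scalar_evaluator(coeffs: FourierCoefficients):
    orders = np.arange(coeffs.max_order + 1)
    cc, cs, sc, ss = coeffs.c_cc, coeffs.c_cs, coeffs.c_sc, coeffs.c_ss

    def energy(phi_deg: float, psi_deg: float) -> float:
        fr = np.deg2rad(phi_deg) * orders
        pr = np.deg2rad(psi_deg) * orders
        cf, sf = np.cos(fr), np.sin(fr)
        cp, sp = np.cos(pr), np.sin(pr)
        return float(cf @ cc @ cp + cf @ cs @ sp + sf @ sc @ cp
                     + sf @ ss @ sp)

    return energy


def metropolis_mc(
    coeffs: FourierCoefficients,
    config: McConfig,
    start: tuple[float, float] = (0.0, 0.0),
) -> pd.DataFrame:
    """Metropolis chain on E(φ, ψ); returns step, phi, psi, energy and an
    overall acceptance rate in ``DataFrame.attrs['acceptance_rate']``.

    Proposals perturb both angles by independent uniform draws of width
    ``step_size_deg`` with periodic wrap-around; acceptance is
    min(1, exp(−ΔE / k_B T)).  Fixed seed → bit-reproducible chain.
    """
    rng = np.random.default_rng(config.seed)
    energy_of = _scalar_evaluator(coeffs)
    kt = KB_KCAL_MOL_K * config.temperature_K
    phi, psi = float(start[0]), float(start[1])
    e = energy_of(phi, psi)
    n = config.n_steps
    d_phi = rng.uniform(-config.step_size_deg, config.step_size_deg, size=n)
    d_psi = rng.uniform(-config.step_size_deg, config.step_size_deg, size=n)
    log_u = np.log(rng.random(size=n))
    rows_step, rows_phi, rows_psi, rows_e = [], [], [], []
    accepted = 0
    for t in range(n):
        new_phi = float(wrap_angle(phi + d_phi[t]))
        new_psi = float(wrap_angle(psi + d_psi[t]))
        new_e = energy_of(new_phi, new_psi)
        if (new_e <= e) or (log_u[t] < -(new_e - e) / kt):
            phi, psi, e = new_phi, new_psi, new_e
            accepted += 1
        if (t + 1) % config.report_stride == 0:
            rows_step.append(t + 1)
            rows_phi.append(phi)
            rows_psi.append(psi)
            rows_e.append(e)
    out = pd.DataFrame({"step": rows_step, "phi": rows_phi,
                        "psi": rows_psi, "energy": rows_e})
    out.attrs["acceptance_rate"] = accepted / n
    return out


def _vector_energy(coeffs: FourierCoefficients, phi_deg, psi_deg):
    return evaluate_surface(coeffs, phi_deg, psi_deg)


def replica_exchange_mc(
    coeffs: FourierCoefficients,
    temperatures_K,
    config: McConfig,
    swap_interval: int = 10,
    start: tuple[float, float] = (0.0, 0.0),
    allow_duplicate_temperatures: bool = False,
) -> ReplicaEnsemble:
    """Replica-exchange Metropolis MC over a temperature ladder.

    Every ``swap_interval`` steps, neighbor swaps are attempted with
    alternating even/odd pairing and acceptance
    min(1, exp[(β_i − β_j)(E_i − E_j)]).  ``allow_duplicate_temperatures``
    bypasses the duplicate check (validation mode: Δβ = 0 swaps must always
    be accepted).
    """
    temps = np.asarray(temperatures_K, dtype=float)
    if len(temps) < 2:
        raise ValueError("need at least 2 temperatures")
    if np.any(np.diff(temps) < 0):
        raise ValueError("temperatures must be sorted increasing")
    if not allow_duplicate_temperatures and len(np.unique(temps)) != len(temps):
        raise ValueError("duplicate temperatures in ladder")
    n_rep = len(temps)
    betas = 1.0 / (KB_KCAL_MOL_K * temps)
    rng = np.random.default_rng(config.seed)
    phi = np.full(n_rep, float(start[0]))
    psi = np.full(n_rep, float(start[1]))
    e = np.asarray(_vector_energy(coeffs, phi, psi), dtype=float)
    step_w = config.step_size_deg
    records: list[list[tuple[float, float, float]]] = [[] for _ in range(n_rep)]
    attempted = {(i, i + 1): 0 for i in range(n_rep - 1)}
    accepted = {(i, i + 1): 0 for i in range(n_rep - 1)}
    parity = 0
    for t in range(config.n_steps):
        prop_phi = wrap_angle(phi + rng.uniform(-step_w, step_w, n_rep))
        prop_psi = wrap_angle(psi + rng.uniform(-step_w, step_w, n_rep))
        prop_e = np.asarray(_vector_energy(coeffs, prop_phi, prop_psi))
        acc = rng.random(n_rep) < np.exp(np.minimum(0.0, -betas * (prop_e - e)))
        phi = np.where(acc, prop_phi, phi)
        psi = np.where(acc, prop_psi, psi)
        e = np.where(acc, prop_e, e)
        if (t + 1) % swap_interval == 0:
            for i in range(parity, n_rep - 1, 2):
                attempted[(i, i + 1)] += 1
                delta = (betas[i] - betas[i + 1]) * (e[i] - e[i + 1])
                if delta >= 0 or rng.random() < np.exp(delta):
                    accepted[(i, i + 1)] += 1
                    for arr in (phi, psi, e):
                        arr[i], arr[i + 1] = arr[i + 1], arr[i]
            parity = 1 - parity
        if (t + 1) % config.report_stride == 0:
            for r in range(n_rep):
                records[r].append((e[r], phi[r], psi[r]))
    samples = [pd.DataFrame(rec, columns=["energy", "phi", "psi"])
               for rec in records]
    stats = {pair: (attempted[pair], accepted[pair]) for pair in attempted}
    return ReplicaEnsemble(
        temperatures_K=temps, samples=samples, exchange_stats=stats,
        metadata={"swap_interval": swap_interval, "seed": config.seed,
                  "n_steps": config.n_steps,
                  "step_size_deg": config.step_size_deg},
    )


# ---------------------------------------------------------------------------
# Analytic two-state generator
# ---------------------------------------------------------------------------

def two_state_tm(delta_E: float, g_unfolded: int) -> float:
    """Half-occupancy (melting) temperature ΔE / (k_B ln g) in K."""
    return delta_E / (KB_KCAL_MOL_K * np.log(g_unfolded))


def _two_state_cv(T, delta_E, g):
    x = delta_E / (KB_KCAL_MOL_K * T)
    w = g * np.exp(-x)
    p_u = w / (1.0 + w)
    return delta_E**2 * p_u * (1.0 - p_u) / (KB_KCAL_MOL_K * T**2)


def two_state_cv_peak(delta_E: float, g_unfolded: int) -> float:
    """Closed-form argmax temperature (K) of the two-state specific heat
    (the Schottky-anomaly peak, below the half-occupancy temperature)."""
    tm = two_state_tm(delta_E, g_unfolded)
    res = minimize_scalar(
        lambda T: -_two_state_cv(T, delta_E, g_unfolded),
        bounds=(tm / 10.0, tm * 2.0), method="bounded",
        options={"xatol": 1e-6})
    return float(res.x)


def synth_two_state_ensemble(
    delta_E: float,
    g_unfolded: int,
    temperatures_K,
    n_per_T: int,
    seed: int = 0,
) -> ReplicaEnsemble:
    """I.i.d. samples from a folded/unfolded two-state system.

    The folded state has energy 0 and degeneracy 1, the unfolded state has
    energy ``delta_E`` (kcal/mol) and degeneracy ``g_unfolded``; at each
    ladder temperature a sample is folded with probability
    1 / (1 + g·exp(−ΔE/k_B T)).  A binary ``folded`` observable is
    included, and the metadata records the analytic melting temperature
    ΔE/(k_B ln g) and the closed-form Cv-peak temperature.
    """
    if delta_E <= 0:
        raise ValueError("delta_E must be positive")
    if g_unfolded < 2:
        raise ValueError("unfolded degeneracy must be >= 2")
    temps = np.asarray(temperatures_K, dtype=float)
    rng = np.random.default_rng(seed)
    samples = []
    for T in temps:
        w = g_unfolded * np.exp(-delta_E / (KB_KCAL_MOL_K * T))
        p_folded = 1.0 / (1.0 + w)
        folded = rng.random(n_per_T) < p_folded
        samples.append(pd.DataFrame({
            "energy": np.where(folded, 0.0, delta_E),
            "folded": folded.astype(float),
        }))
    return ReplicaEnsemble(
        temperatures_K=temps, samples=samples,
        metadata={
            "delta_E": delta_E, "g_unfolded": g_unfolded, "seed": seed,
            "tm_half_occupancy_K": two_state_tm(delta_E, g_unfolded),
            "tm_cv_peak_K": two_state_cv_peak(delta_E, g_unfolded),
        },
    )


# ---------------------------------------------------------------------------
# Ensemble directory format (text-only: manifest.json + per-replica CSV)
# ---------------------------------------------------------------------------

def save_ensemble(ensemble: ReplicaEnsemble, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    files = []
    for k, df in enumerate(ensemble.samples):
        name = f"replica_{k:02d}.csv"
        out = df.copy()
        out.insert(0, "step", np.arange(len(df)))
        out.to_csv(directory / name, index=False)
        files.append(name)
    manifest = {
        "temperatures_K": [float(t) for t in ensemble.temperatures_K],
        "replica_files": files,
        "exchange_stats": {f"{i}-{j}": list(v) for (i, j), v
                           in ensemble.exchange_stats.items()},
        "metadata": ensemble.metadata,
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1)


def load_ensemble(directory) -> ReplicaEnsemble:
    directory = Path(directory)
    with open(directory / "manifest.json") as fh:
        manifest = json.load(fh)
    samples = []
    for name in manifest["replica_files"]:
        df = pd.read_csv(directory / name)
        samples.append(df.drop(columns=["step"], errors="ignore"))
    stats = {}
    for key, val in manifest.get("exchange_stats", {}).items():
        i, j = key.split("-")
        stats[(int(i), int(j))] = tuple(val)
    return ReplicaEnsemble(
        temperatures_K=np.asarray(manifest["temperatures_K"]),
        samples=samples, exchange_stats=stats,
        metadata=manifest.get("metadata", {}),
    )
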