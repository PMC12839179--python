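"""Stiffness x actuation-timing parametric sweep.

Runs every exoskeleton setting of a stiffness/timing grid over a cohort
of foot contacts, computes the percent change in total muscle metabolic
energy relative to unassisted baseline walking (paired per contact, then
averaged), locates grid minima, and fits the quadratic stiffness-energy
relationship at a fixed timing slice.

Conditions per contact: baseline (no exoskeleton, no bracket mass),
no-actuation (brackets worn, spring never engaged) and each (k, tau)
grid cell (brackets worn, spring engaging at tau % of stance). Negative
percent change means the exoskeleton assists.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .energetics import trial_energy
from .exo import ExoGeometry, ExoSetting, resting_length_for_timing
from .gait import GaitTrial
from .muscles import MuscleParams
from .redundancy import DEFAULT_RESERVE_WEIGHT, TrialDynamics

__all__ = [
    "GRID_DEFAULTS", "SweepResult", "build_grid", "run_sweep",
    "find_minima", "quadratic_fit", "plot_heatmap",
]

log = logging.getLogger(__name__)

#: The study grid: 25 stiffnesses 5.5-17.5 kN/m (0.5 kN/m steps) x
#: 10 timings 15-60% of stance (5% steps) = 250 settings.
GRID_DEFAULTS = dict(k_min=5500.0, k_max=17500.0, k_step=500.0,
                     tau_min=15.0, tau_max=60.0, tau_step=5.0)


def build_grid(k_min: float = GRID_DEFAULTS["k_min"],
               k_max: float = GRID_DEFAULTS["k_max"],
               k_step: float = GRID_DEFAULTS["k_step"],
               tau_min: float = GRID_DEFAULTS["tau_min"],
               tau_max: float = GRID_DEFAULTS["tau_max"],
               tau_step: float = GRID_DEFAULTS["tau_step"],
               ) -> list[ExoSetting]:
    """Cartesian settings grid, stiffness-major, endpoints included.

    Values are built by integer index (min + i*step), never by float
    accumulation, so the endpoints are exactly representable; a step that
    does not divide the range within 1e-9 is an error.
    """
    settings = []
    axes = []
    for lo, hi, step, label in ((k_min, k_max, k_step, "stiffness"),
                                (tau_min, tau_max, tau_step, "timing")):
        if step <= 0:
            raise ValueError(f"{label} step must be positive")
        if lo > hi:
            raise ValueError(f"{label} min must not exceed max")
        n = (hi - lo) / step
        if abs(n - round(n)) > 1e-9:
            raise ValueError(f"{label} step {step} does not divide the range "
                             f"[{lo}, {hi}]")
        axes.append([lo + i * step for i in range(int(round(n)) + 1)])
    for k in axes[0]:
        for tau in axes[1]:
            settings.append(ExoSetting(stiffness_k=k, actuation_timing_tau=tau))
    return settings


@dataclass
class SweepResult:
    """Delta-energy grid and per-contact raw energies of one sweep."""

    stiffness: np.ndarray            # (nk,)
    timing: np.ndarray               # (ntau,)
    delta_grid: np.ndarray           # (nk, ntau) mean Delta% over contacts
    delta_sd: np.ndarray             # (nk, ntau) SD of Delta% over contacts
    per_contact: np.ndarray          # (nk, ntau, nc) J/kg
    baseline_per_contact: np.ndarray  # (nc,) J/kg
    no_actuation_per_contact: np.ndarray  # (nc,) J/kg
    failed: np.ndarray               # (nk, ntau) bool
    n_simulations: int
    global_minimum: tuple | None = None    # (k, tau, delta%)
    local_minima: list = field(default_factory=list)
    quadratic: dict | None = None

    @property
    def delta_per_contact(self) -> np.ndarray:
        """(nk, ntau, nc) percent change vs the same contact's baseline."""
        return 100.0 * (self.per_contact - self.baseline_per_contact) \
            / self.baseline_per_contact

    def cell_index(self, k: float, tau: float) -> tuple[int, int]:
        ik = int(np.argmin(np.abs(self.stiffness - k)))
        it = int(np.argmin(np.abs(self.timing - tau)))
        return ik, it

    def to_frame(self) -> pd.DataFrame:
        """Long-format grid table (stiffness ascending, then timing)."""
        rows = []
        nc = self.per_contact.shape[2]
        for i, k in enumerate(self.stiffness):
            for j, tau in enumerate(self.timing):
                rows.append({"stiffness_k": k, "actuation_timing_tau": tau,
                             "mean_delta_pct": self.delta_grid[i, j],
                             "sd_delta_pct": self.delta_sd[i, j],
                             "n_contacts": nc,
                             "failed": bool(self.failed[i, j])})
        return pd.DataFrame(rows)

    def summary(self) -> dict:
        return {
            "n_simulations": self.n_simulations,
            "baseline_J_per_kg": {
                "mean": float(np.mean(self.baseline_per_contact)),
                "sd": float(np.std(self.baseline_per_contact, ddof=1)),
            },
            "no_actuation_J_per_kg": {
                "mean": float(np.mean(self.no_actuation_per_contact)),
                "sd": float(np.std(self.no_actuation_per_contact, ddof=1)),
            },
            "global_minimum": self.global_minimum,
            "local_minima": self.local_minima,
            "quadratic_fit": self.quadratic,
        }


def run_sweep(cohort: list[GaitTrial], grid: list[ExoSetting],
              geometry: ExoGeometry, muscles: list[MuscleParams],
              reserve_weight: float = DEFAULT_RESERVE_WEIGHT) -> SweepResult:
    """Run baseline, no-actuation and every grid cell over the cohort.

    The spring resting length is re-derived from each contact's own
    kinematics, mirroring a per-trial device fit. A solver failure in a
    cell flags the cell and the sweep continues.
    """
    if not cohort:
        raise ValueError("cohort is empty")
    stiffness = np.array(sorted({s.stiffness_k for s in grid}))
    timing = np.array(sorted({s.actuation_timing_tau for s in grid}))
    nk, ntau, nc = stiffness.size, timing.size, len(cohort)

    per_contact = np.full((nk, ntau, nc), np.nan)
    baseline = np.zeros(nc)
    no_act = np.zeros(nc)
    failed = np.zeros((nk, ntau), bool)
    n_sim = 0

    for c, trial in enumerate(cohort):
        dyn = TrialDynamics(trial, muscles, reserve_weight)
        sol = dyn.solve(dyn.required_for(None, None))
        baseline[c] = trial_energy(trial, sol, muscles).total_energy_per_kg
        sol = dyn.solve(dyn.required_for(None, geometry))
        no_act[c] = trial_energy(trial, sol, muscles).total_energy_per_kg

        L0_by_tau = {tau: resting_length_for_timing(trial, geometry, tau)
                     for tau in timing}
        for setting in grid:
            ik = int(np.searchsorted(stiffness, setting.stiffness_k))
            it = int(np.searchsorted(timing, setting.actuation_timing_tau))
            fitted = setting.with_resting_length(
                L0_by_tau[setting.actuation_timing_tau])
            try:
                sol = dyn.solve(dyn.required_for(fitted, geometry))
                per_contact[ik, it, c] = trial_energy(
                    trial, sol, muscles).total_energy_per_kg
            except Exception:
                log.exception("solver failure at k=%s tau=%s contact=%s",
                              setting.stiffness_k,
                              setting.actuation_timing_tau, c)
                failed[ik, it] = True
            n_sim += 1

    log.info("sweep complete: %d grid simulations over %d contacts",
             n_sim, nc)
    delta = 100.0 * (per_contact - baseline) / baseline
    result = SweepResult(
        stiffness=stiffness, timing=timing,
        delta_grid=np.mean(delta, axis=2),
        delta_sd=np.std(delta, axis=2, ddof=1) if nc > 1
        else np.zeros((nk, ntau)),
        per_contact=per_contact,
        baseline_per_contact=baseline,
        no_actuation_per_contact=no_act,
        failed=failed,
        n_simulations=n_sim,
    )
    result.global_minimum, result.local_minima = find_minima(result)
    try:
        result.quadratic = quadratic_fit(result, float(timing[0]))
    except ValueError:       # fewer than 3 stiffness points in the grid
        result.quadratic = None
    return result


def find_minima(result: SweepResult) -> tuple[tuple, list]:
    """Global argmin (ties toward lower stiffness, then earlier timing)
    and cells strictly below all 4-neighbors; failed cells are excluded."""
    grid = np.where(result.failed, np.inf, result.delta_grid)
    if np.all(np.isinf(grid)):
        raise ValueError("all grid cells failed")
    if result.failed.any():
        log.warning("%d failed cells excluded from minima",
                    int(result.failed.sum()))
    # argmin scans stiffness-major, timing fastest: first hit wins ties
    # toward lower stiffness then earlier timing.
    flat = int(np.argmin(grid))
    ik, it = np.unravel_index(flat, grid.shape)
    global_min = (float(result.stiffness[ik]), float(result.timing[it]),
                  float(grid[ik, it]))

    local = []
    nk, ntau = grid.shape
    for i in range(nk):
        for j in range(ntau):
            if np.isinf(grid[i, j]):
                continue
            neigh = []
            if i > 0:
                neigh.append(grid[i - 1, j])
            if i < nk - 1:
                neigh.append(grid[i + 1, j])
            if j > 0:
                neigh.append(grid[i, j - 1])
            if j < ntau - 1:
                neigh.append(grid[i, j + 1])
            if all(grid[i, j] < n for n in neigh):
                local.append((float(result.stiffness[i]),
                              float(result.timing[j]),
                              float(grid[i, j])))
    return global_min, local


def quadratic_fit(result: SweepResult, tau: float) -> dict:
    """OLS fit of mean Delta% on (1, k, k^2) over one timing slice.

    Reports coefficients, R^2 and the vertex -c1/(2 c2) when the fit is
    convex (c2 > 0).
    """
    it = np.flatnonzero(np.isclose(result.timing, tau))
    if it.size != 1:
        raise ValueError(f"tau={tau} is not a grid timing")
    keep = ~result.failed[:, it[0]]
    k = result.stiffness[keep]
    y = result.delta_grid[keep, it[0]]
    if k.size < 3:
        raise ValueError("need at least 3 stiffness points")
    X = np.column_stack([np.ones_like(k), k, k * k])
    coef, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ coef
    ss_res = float(resid @ resid)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
    c0, c1, c2 = (float(v) for v in coef)
    convex = c2 > 0
    return {
        "tau": float(tau), "c0": c0, "c1": c1, "c2": c2,
        "r_squared": float(r2),
        "vertex_k": float(-c1 / (2 * c2)) if convex else None,
        "convex": bool(convex),
    }


def plot_heatmap(result: SweepResult, path: str | Path) -> None:
    """Optional heatmap export (stiffness rows ascending, timing columns
    ascending), mirroring the sweep's grid orientation."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(7, 5))
    im = ax.imshow(result.delta_grid, origin="lower", aspect="auto",
                   extent=(result.timing[0], result.timing[-1],
                           result.stiffness[0] / 1000,
                           result.stiffness[-1] / 1000),
                   cmap="RdBu_r")
    fig.colorbar(im, ax=ax, label="energy change vs baseline (%)")
    ax.set_xlabel("actuation timing (% of stance)")
    ax.set_ylabel("spring stiffness (kN/m)")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def write_outputs(result: SweepResult, outdir: str | Path) -> None:
    """Write sweep.csv and summary.json into ``outdir``."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    result.to_frame().to_csv(outdir / "sweep.csv", index=False,
                             float_format="%.12g")
    (outdir / "summary.json").write_text(
        json.dumps(result.summary(), indent=2, sort_keys=True) + "\n")
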