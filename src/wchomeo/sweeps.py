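"""Bifurcation maps over (rho, Iext), Hopf-boundary extraction, and the
integration-step and inhibitory-timescale sweeps.

The Hopf bifurcation between the stable-spiral and limit-cycle regimes is
located two ways.  The *analytic* boundary bisects the target rate at which
the Jacobian trace at the solved fixed point crosses zero (at onset the
mean rate equals the fixed point, so the boundary is the same on either
scale).  The *numerical* boundary bisects the target rate at which a pulse-
perturbed Euler simulation switches between damped ringing and a sustained
orbit, and therefore inherits the integration-step bias that the dt sweep
quantifies.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model_core import WCParams, SimConfig, Pulse, integrate
from .fixed_points import rI_nullcline, jacobian, find_fixed_points, classify
from .homeostasis import HomeostasisSpec, Mode, ADAPTED, solve, LOW_SIDE_CLAMPS
from .target_rate import solve_for_mean_rate
from .oscillations import peak_frequency_simulated, analytic_frequency

__all__ = [
    "BifurcationMap",
    "NumericalBoundary",
    "classify_grid",
    "solved_trace",
    "analytic_hopf_boundary",
    "spiral_onset_boundary",
    "numerical_hopf_boundary",
    "tauI_sweep",
    "excursion_map",
    "default_rho_grid",
    "default_Iext_grid",
]

#: peak-to-peak rE amplitude in the final second below which ringing counts
#: as damped, and above which the orbit counts as sustained
AMP_DAMPED = 1e-4
AMP_SUSTAINED = 1e-3


def default_rho_grid(step: float = 0.005, stop: float = 0.4) -> np.ndarray:
    """Target-rate axis: (0, ``stop``] in steps of ``step``."""
    return np.round(np.arange(step, stop + step / 2, step), 10)


def default_Iext_grid(step: float = 0.25, stop: float = 4.0) -> np.ndarray:
    return np.round(np.arange(0.0, stop + step / 2, step), 10)


@dataclass(frozen=True)
class BifurcationMap:
    """Grid of regime labels and solved parameters with boundary curves."""

    mode: Mode
    rho_values: np.ndarray
    Iext_values: np.ndarray
    class_grid: np.ndarray            # object array of labels ('' = blank)
    param_grids: dict                 # name -> 2D array (Iext x rho)
    boundary_hopf: dict               # Iext -> rho (trace zero crossing)
    boundary_spiral_fp: dict          # Iext -> rho (discriminant crossing)
    method: str

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for i, Iext in enumerate(self.Iext_values):
            for j, rho in enumerate(self.rho_values):
                row = {"mode": self.mode.value, "rho": float(rho),
                       "Iext": float(Iext),
                       "feasible": bool(self.class_grid[i, j] != ""),
                       "class": self.class_grid[i, j]}
                for name, grid in self.param_grids.items():
                    row[name] = grid[i, j]
                rows.append(row)
        return pd.DataFrame(rows)


def solved_trace(mode: Mode | str, target_rE: float, Iext: float,
                 spec: HomeostasisSpec | None = None) -> float:
    """Jacobian trace (1/ms) at the homeostatic fixed point; NaN if infeasible."""
    if spec is None:
        spec = HomeostasisSpec()
    sol = solve(mode, target_rE, Iext, spec)
    if not sol.feasible:
        return math.nan
    p = sol.params
    rI = float(rI_nullcline(target_rE, p))
    return float(np.trace(jacobian(target_rE, rI, p)))


def _solved_discriminant(mode, target_rE, Iext, spec) -> float:
    sol = solve(mode, target_rE, Iext, spec)
    if not sol.feasible:
        return math.nan
    p = sol.params
    rI = float(rI_nullcline(target_rE, p))
    J = jacobian(target_rE, rI, p)
    tr, det = float(np.trace(J)), float(np.linalg.det(J))
    return tr * tr - 4.0 * det


def _bisect_crossing(f, lo: float, hi: float, tol: float) -> float:
    flo = f(lo)
    for _ in range(200):
        if hi - lo < tol:
            break
        mid = 0.5 * (lo + hi)
        fm = f(mid)
        if math.isnan(fm):  # infeasible midpoints sit on the low-rho side
            lo = mid
            continue
        if (fm > 0) == (flo > 0):
            lo, flo = mid, fm
        else:
            hi = mid
    return 0.5 * (lo + hi)


def _scan_for_sign_change(f, grid) -> tuple[float, float] | None:
    prev_x = prev_v = None
    for x in grid:
        v = f(x)
        if math.isnan(v):
            prev_x = prev_v = None
            continue
        if prev_v is not None and (v > 0) != (prev_v > 0):
            return prev_x, x
        prev_x, prev_v = x, v
    return None


def analytic_hopf_boundary(
    mode: Mode | str,
    Iext: float,
    spec: HomeostasisSpec | None = None,
    rho_max: float = 0.4,
    tol: float = 1e-6,
) -> float | None:
    """Target rate at which the solved-fixed-point trace crosses zero.

    Returns None when no crossing exists below ``rho_max`` for this input.
    """
    if spec is None:
        spec = HomeostasisSpec()
    f = lambda r: solved_trace(mode, r, Iext, spec)
    bracket = _scan_for_sign_change(f, np.arange(0.005, rho_max + 1e-9, 0.005))
    if bracket is None:
        return None
    return _bisect_crossing(f, bracket[0], bracket[1], tol)


def spiral_onset_boundary(
    mode: Mode | str,
    Iext: float,
    spec: HomeostasisSpec | None = None,
    rho_max: float = 0.4,
    tol: float = 1e-6,
) -> float | None:
    """Target rate where the discriminant crosses zero (node -> spiral)."""
    if spec is None:
        spec = HomeostasisSpec()
    f = lambda r: _solved_discriminant(mode, r, Iext, spec)
    bracket = _scan_for_sign_change(f, np.arange(0.005, rho_max + 1e-9, 0.005))
    if bracket is None:
        return None
    return _bisect_crossing(f, bracket[0], bracket[1], tol)


@dataclass(frozen=True)
class NumericalBoundary:
    """Simulation-detected Hopf location, with the final bracket and a flag
    for cells whose amplitude fell between the damped/sustained thresholds."""

    rho: float
    bracket: tuple[float, float]
    ambiguous: bool
    dt: float


def _ring_amplitude(params: WCParams, dt: float) -> float:
    """Peak-to-peak rE amplitude over the final second of a pulse run."""
    sim = SimConfig(dt=dt, duration=5000.0,
                    pulses=(Pulse(onset=3000.0, amplitude=1.0, width=1.0),))
    traj = integrate(params, sim)
    tail = traj.rE[traj.times >= 4000.0]
    return float(tail.max() - tail.min())


def numerical_hopf_boundary(
    mode: Mode | str,
    Iext: float,
    dt: float = 0.1,
    spec: HomeostasisSpec | None = None,
    lo: float = 0.02,
    hi: float = 0.38,
    scan_step: float = 0.01,
    tol: float = 1e-4,
) -> NumericalBoundary | None:
    """Bisect the target rate separating damped from sustained oscillation.

    A coarse upward scan finds the first adjacent (damped, sustained) pair
    of feasible targets, and bisection refines inside it; this keeps the
    search local to the oscillation onset, away from the multistable region
    at high targets where the trajectory escapes to a saturated state.  The
    damped/sustained split is the geometric mean of the two amplitude
    thresholds; a final amplitude inside the ambiguous band is flagged (the
    bracket, not a sharp point, is then the honest answer).
    """
    if spec is None:
        spec = HomeostasisSpec()
    cut = math.sqrt(AMP_DAMPED * AMP_SUSTAINED)

    def sustained(r: float) -> bool | None:
        sol = solve(mode, r, Iext, spec)
        if not sol.feasible:
            return None
        return _ring_amplitude(sol.params, dt) > cut

    bracket = None
    prev_r = prev_s = None
    for r in np.arange(lo, hi + scan_step / 2, scan_step):
        s = sustained(float(r))
        if s is None:
            prev_r = prev_s = None
            continue
        if prev_s is False and s is True:
            bracket = (prev_r, float(r))
            break
        prev_r, prev_s = float(r), s
    if bracket is None:
        return None
    b_lo, b_hi = bracket
    while b_hi - b_lo > tol:
        mid = 0.5 * (b_lo + b_hi)
        s_mid = sustained(mid)
        if s_mid is True:
            b_hi = mid
        else:  # damped or infeasible midpoints stay on the low side
            b_lo = mid
    rho = 0.5 * (b_lo + b_hi)
    sol = solve(mode, rho, Iext, spec)
    amp = _ring_amplitude(sol.params, dt) if sol.feasible else math.nan
    ambiguous = bool(AMP_DAMPED < amp < AMP_SUSTAINED)
    return NumericalBoundary(rho=rho, bracket=(b_lo, b_hi), ambiguous=ambiguous,
                             dt=dt)


def classify_grid(
    mode: Mode | str,
    rho_values=None,
    Iext_values=None,
    spec: HomeostasisSpec | None = None,
    sim: SimConfig | None = None,
    use_mean_rate: bool = True,
) -> BifurcationMap:
    """Regime label and solved parameters per (rho, Iext) cell.

    With ``use_mean_rate`` the target is the mean rate (bisection through
    simulation); without it the target is taken as the fixed point directly,
    which is exact in the stable regimes and much faster for coarse maps.
    """
    mode = Mode(mode)
    if spec is None:
        spec = HomeostasisSpec()
    rho_values = default_rho_grid() if rho_values is None else np.asarray(rho_values, float)
    Iext_values = default_Iext_grid() if Iext_values is None else np.asarray(Iext_values, float)

    class_grid = np.full((len(Iext_values), len(rho_values)), "", dtype=object)
    param_grids = {name: np.full(class_grid.shape, np.nan)
                   for name in ADAPTED[mode]}
    for i, Iext in enumerate(Iext_values):
        for j, rho in enumerate(rho_values):
            if use_mean_rate:
                res = solve_for_mean_rate(rho, Iext, mode, spec, sim)
                sol, rE_fix = res.solution, res.rE_fixed
                ok = res.feasible
            else:
                sol = solve(mode, rho, Iext, spec)
                rE_fix, ok = rho, sol.feasible
            if not ok or sol is None:
                continue
            sc = classify(sol.params, target_rE=rE_fix)
            class_grid[i, j] = sc.label.value
            for name in param_grids:
                param_grids[name][i, j] = sol.solved.get(
                    name, getattr(sol.params, name))

    boundary_hopf = {float(I): analytic_hopf_boundary(mode, I, spec)
                     for I in Iext_values}
    boundary_spiral = {float(I): spiral_onset_boundary(mode, I, spec)
                       for I in Iext_values}
    return BifurcationMap(
        mode=mode, rho_values=rho_values, Iext_values=Iext_values,
        class_grid=class_grid, param_grids=param_grids,
        boundary_hopf=boundary_hopf, boundary_spiral_fp=boundary_spiral,
        method="mean_rate" if use_mean_rate else "fixed_point",
    )


def tauI_sweep(
    mode: Mode | str,
    tauI_values,
    Iext_values,
    spec: HomeostasisSpec | None = None,
) -> pd.DataFrame:
    """Analytic Hopf boundary for each (tauI, Iext); tauE stays at baseline."""
    if spec is None:
        spec = HomeostasisSpec()
    rows = []
    for tauI in tauI_values:
        sp = HomeostasisSpec(baseline=spec.baseline.replace(tauI=float(tauI)),
                             tau_homeo=spec.tau_homeo)
        for Iext in Iext_values:
            rho = analytic_hopf_boundary(mode, float(Iext), sp)
            rows.append({"mode": Mode(mode).value, "tauI": float(tauI),
                         "Iext": float(Iext), "rho_hopf": rho})
    return pd.DataFrame(rows)


def excursion_map(
    mode: Mode | str,
    rho_values=None,
    Iext_values=None,
    spec: HomeostasisSpec | None = None,
) -> pd.DataFrame:
    """log10 |solved / baseline| of each adapted parameter per cell.

    Zero means the solved value equals the default; infeasible cells are
    omitted.  Uses the fixed-point-target fast path (exact in the stable
    regimes, where parameter excursions are compared).
    """
    mode = Mode(mode)
    if spec is None:
        spec = HomeostasisSpec()
    rho_values = default_rho_grid() if rho_values is None else rho_values
    Iext_values = default_Iext_grid() if Iext_values is None else Iext_values
    rows = []
    for Iext in Iext_values:
        for rho in rho_values:
            sol = solve(mode, float(rho), float(Iext), spec)
            if not sol.feasible:
                continue
            row = {"mode": mode.value, "rho": float(rho), "Iext": float(Iext)}
            for name in ADAPTED[mode]:
                base = getattr(spec.baseline, name)
                val = sol.solved.get(name, getattr(sol.params, name))
                row[f"log10_{name}"] = math.log10(abs(val / base))
            rows.append(row)
    return pd.DataFrame(rows)
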