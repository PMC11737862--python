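"""Mapping a target *mean* firing rate to homeostatic parameters.

In the stable regimes the mean excitatory rate equals the fixed point, so
the closed-form solvers apply directly.  Inside a limit cycle the orbit is
asymmetric and the mean rate rises above the fixed point, and no analytic
expression for the cycle mean exists.  The set-point for a target mean rate
``rho`` is therefore found by simulation-in-the-loop bisection on the
candidate fixed point: at each midpoint the mode's closed-form solver fixes
the parameters, the node is simulated, and the achieved mean rate steers
the bracket.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_core import WCParams, SimConfig, integrate
from .homeostasis import (
    HomeostasisSpec,
    HomeostaticSolution,
    Mode,
    LOW_SIDE_CLAMPS,
    solve,
)

__all__ = ["TargetRateResult", "mean_rate", "solve_for_mean_rate"]

#: offset from the unit-interval endpoints avoiding the logit singularities
BRACKET_EPS = 1e-6
#: averaging window at the end of the run (ms)
MEAN_WINDOW = 2000.0


@dataclass(frozen=True)
class TargetRateResult:
    """Outcome of the mean-rate bisection."""

    rho: float
    Iext: float
    mode: Mode
    rE_fixed: float                  # located fixed-point coordinate
    solution: HomeostaticSolution | None
    mean_rate: float
    iterations: int
    converged: bool
    feasible: bool
    epsilon: float
    diagnostic: str = ""


def mean_rate(params: WCParams, sim: SimConfig | None = None,
              window: float = MEAN_WINDOW) -> float:
    """Mean excitatory rate over the final ``window`` ms of a simulation.

    The default 5 s run discards a 3 s transient implicitly; a shorter run
    than ``window`` + one step is refused.
    """
    if sim is None:
        sim = SimConfig()
    if sim.duration < window + sim.dt:
        raise ValueError("simulation shorter than the averaging window")
    traj = integrate(params, sim)
    sel = traj.times >= sim.duration - window
    return float(np.mean(traj.rE[sel]))


def solve_for_mean_rate(
    rho: float,
    Iext: float,
    mode: Mode | str,
    spec: HomeostasisSpec | None = None,
    sim: SimConfig | None = None,
    epsilon: float = 1e-10,
    max_iter: int = 80,
) -> TargetRateResult:
    """Bisection on the fixed point until the simulated mean rate hits rho.

    Bracket starts at (0, 1) (evaluated at small offsets from the endpoints
    to avoid the logit singularities).  A midpoint where the closed-form
    solver reports an infeasible solution moves the bracket according to
    which Dale constraint fired; if the bracket collapses without a feasible
    point the target is unattainable (a "blank" cell) and the result carries
    ``feasible=False`` instead of raising.  Monotonicity of the mean rate
    in the fixed point is assumed, as the bisection requires; the iteration
    cap only guards runtime (2^-80 is far below any useful epsilon).
    """
    if not (0.0 < rho < 1.0):
        raise ValueError("rho must lie strictly inside (0, 1)")
    mode = Mode(mode)
    if spec is None:
        spec = HomeostasisSpec()
    if sim is None:
        sim = SimConfig()

    lo, hi = BRACKET_EPS, 1.0 - BRACKET_EPS
    best: tuple[float, float, HomeostaticSolution] | None = None
    last_sol: HomeostaticSolution | None = None
    iterations = 0
    for iterations in range(1, max_iter + 1):
        mid = 0.5 * (lo + hi)
        sol = solve(mode, mid, Iext, spec)
        last_sol = sol
        if not sol.feasible:
            if any(c in LOW_SIDE_CLAMPS for c in sol.clamped):
                lo = mid
            else:
                hi = mid
            if hi - lo < 1e-13:
                return TargetRateResult(
                    rho=rho, Iext=Iext, mode=mode, rE_fixed=np.nan,
                    solution=sol, mean_rate=np.nan, iterations=iterations,
                    converged=False, feasible=False, epsilon=epsilon,
                    diagnostic="no feasible fixed point in the bracket",
                )
            continue
        mean = mean_rate(sol.params, sim)
        if best is None or abs(mean - rho) < abs(best[1] - rho):
            best = (mid, mean, sol)
        if abs(mean - rho) < epsilon:
            return TargetRateResult(
                rho=rho, Iext=Iext, mode=mode, rE_fixed=mid, solution=sol,
                mean_rate=mean, iterations=iterations, converged=True,
                feasible=True, epsilon=epsilon,
            )
        if mean > rho:
            hi = mid
        else:
            lo = mid
        if hi - lo < 1e-15:
            break

    if best is None:
        return TargetRateResult(
            rho=rho, Iext=Iext, mode=mode, rE_fixed=np.nan, solution=last_sol,
            mean_rate=np.nan, iterations=iterations, converged=False,
            feasible=False, epsilon=epsilon,
            diagnostic="no feasible fixed point encountered",
        )
    mid, mean, sol = best
    return TargetRateResult(
        rho=rho, Iext=Iext, mode=mode, rE_fixed=mid, solution=sol,
        mean_rate=mean, iterations=iterations, converged=False, feasible=True,
        epsilon=epsilon,
        diagnostic="bracket exhausted before reaching epsilon "
                   "(possible non-monotone mean-rate response)",
    )
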