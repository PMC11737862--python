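"""Closed-form homeostatic set-point solvers and slow homeostatic dynamics.

Firing-rate homeostasis adjusts circuit parameters so that a requested
excitatory rate ``rE*`` is a fixed point of the node under a given external
drive.  Each *mode* names the parameter(s) under homeostatic control:

========================  ====================================================
mode                      biological mechanism
========================  ====================================================
GE                        synaptic scaling of excitatory synapses (gain)
CEI                       scaling of inhibitory synapses onto pyramidal cells
MUE                       intrinsic excitability via the firing threshold
MUE_SIGMAE                threshold and slope co-adjusted with sigmaE = K*muE,
                          preserving the zero-input output F_E(0)
CIE                       scaling of excitatory synapses onto interneurons
GE_CEI                    joint scaling of excitation and inhibition
GE_CEI_MUE                the above plus threshold plasticity
GE_CEI_MUE_SIGMAE         all four, with sigmaE slaved to muE
========================  ====================================================

Single modes invert the fixed-point equation for the controlled parameter.
Combined modes assume every mechanism runs on the same slow timescale, so
each parameter's steady-state displacement from its baseline has equal
magnitude (opposite sign for parameters pushing the rate in opposite
directions); that linear constraint makes the joint inversion closed-form.

Dale's principle forbids sign changes of couplings: solutions requiring
GE < 0, cEI <= 0, sigmaE <= 0 or an unreachable inhibitory rate are flagged
infeasible rather than clamped.  All closed-form solvers require cII = 0 and
alpha = 0; other configurations need numeric root finding and are refused
explicitly.

:func:`simulate_homeostatic_odes` provides the dynamic counterpart: the
node is co-integrated with slow integral-control ODEs on the adapted
parameters (clamped online, since a running circuit cannot refuse), and
should converge to the closed-form solution whenever the target regime is a
stable fixed point.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model_core import WCParams, sigmoid
from .fixed_points import rE_nullcline, rI_nullcline

__all__ = [
    "Mode",
    "HomeostasisSpec",
    "HomeostaticSolution",
    "solve",
    "simulate_homeostatic_odes",
    "HomeostaticOdeResult",
]


class UnsupportedConfigurationError(ValueError):
    """Closed-form solvers require cII = 0 and alpha = 0."""


class Mode(str, enum.Enum):
    GE = "GE"
    CEI = "CEI"
    MUE = "MUE"
    MUE_SIGMAE = "MUE_SIGMAE"
    CIE = "CIE"
    GE_CEI = "GE_CEI"
    GE_CEI_MUE = "GE_CEI_MUE"
    GE_CEI_MUE_SIGMAE = "GE_CEI_MUE_SIGMAE"


#: parameters adapted by each mode (in baseline-attribute names)
ADAPTED: dict[Mode, tuple[str, ...]] = {
    Mode.GE: ("GE",),
    Mode.CEI: ("cEI",),
    Mode.MUE: ("muE",),
    Mode.MUE_SIGMAE: ("muE", "sigmaE"),
    Mode.CIE: ("cIE",),
    Mode.GE_CEI: ("GE", "cEI"),
    Mode.GE_CEI_MUE: ("GE", "cEI", "muE"),
    Mode.GE_CEI_MUE_SIGMAE: ("GE", "cEI", "muE", "sigmaE"),
}


@dataclass(frozen=True)
class HomeostasisSpec:
    """Baseline parameters and timescales shared by all solvers.

    ``K = sigmaE0 / muE0`` is the slope/threshold ratio preserved by
    coordinated intrinsic-excitability plasticity (0.25 at defaults).
    ``tau_homeo`` (ms) only matters for the dynamic simulation; it must be
    much larger than the membrane time constants.
    """

    baseline: WCParams = field(default_factory=WCParams)
    tau_homeo: float = 500.0

    def __post_init__(self) -> None:
        if self.tau_homeo <= 0:
            raise ValueError("tau_homeo must be positive")

    @property
    def K(self) -> float:
        return self.baseline.sigmaE / self.baseline.muE


@dataclass(frozen=True)
class HomeostaticSolution:
    """Outcome of a closed-form inversion for one (target rE, Iext) pair."""

    mode: Mode
    target_rE: float
    Iext: float
    params: WCParams
    solved: dict
    feasible: bool
    clamped: tuple[str, ...] = ()


def _check_closed_form_domain(target_rE: float, spec: HomeostasisSpec) -> None:
    if not (0.0 < target_rE < 1.0):
        raise ValueError("target rate must lie strictly inside (0, 1)")
    if spec.baseline.cII != 0 or spec.baseline.alpha != 0:
        raise UnsupportedConfigurationError(
            "closed-form homeostatic solvers require cII = 0 and alpha = 0; "
            "use numeric fixed-point analysis for generalized circuits"
        )


def _parts(target_rE: float, Iext: float, spec: HomeostasisSpec):
    """Common sub-expressions of the fixed-point equation at the target."""
    b = spec.baseline
    L = math.log((1.0 - target_rE) / target_rE)       # logit of the target
    FI = float(sigmoid(b.cIE * target_rE, b.muI, b.sigmaI))  # inhibitory rate
    S = b.cEE * target_rE + Iext                      # gain-scaled drive term
    return b, L, FI, S


def _finish(mode, target_rE, Iext, spec, solved: dict,
            clamped: tuple[str, ...], safe: dict | None = None) -> HomeostaticSolution:
    """Assemble a solution record.

    ``solved`` holds the raw inverted values (possibly Dale-violating);
    ``safe`` overrides them with constructible values for the params object
    when a clamp fired.
    """
    params = spec.baseline.replace(Iext=Iext, **(safe if safe is not None else solved))
    return HomeostaticSolution(
        mode=mode, target_rE=target_rE, Iext=Iext, params=params,
        solved=solved, feasible=not clamped, clamped=clamped,
    )


# --- single modes ----------------------------------------------------------

def solve_GE(target_rE: float, Iext: float, spec: HomeostasisSpec) -> HomeostaticSolution:
    """Excitatory gain maintaining the target rate; infeasible if GE < 0."""
    _check_closed_form_domain(target_rE, spec)
    b, L, FI, _ = _parts(target_rE, Iext, spec)
    denom = b.cEE * target_rE + Iext
    if denom <= 0:
        raise ValueError("cEE*rE + Iext must be positive for gain homeostasis")
    GE = (b.cEI * FI - b.sigmaE * L + b.muE) / denom
    clamped = ("GE",) if GE < 0 else ()
    safe = {"GE": 0.0} if clamped else None
    return _finish(Mode.GE, target_rE, Iext, spec, {"GE": GE}, clamped, safe)


def solve_cEI(target_rE: float, Iext: float, spec: HomeostasisSpec) -> HomeostaticSolution:
    """Inhibitory coupling maintaining the target rate; infeasible if cEI <= 0."""
    _check_closed_form_domain(target_rE, spec)
    b, L, FI, _ = _parts(target_rE, Iext, spec)
    cEI = (b.sigmaE * L + b.GE * b.cEE * target_rE + b.GE * Iext - b.muE) / FI
    clamped = ("cEI",) if cEI <= 0 else ()
    safe = {"cEI": max(cEI, 1e-12)} if clamped else None
    return _finish(Mode.CEI, target_rE, Iext, spec, {"cEI": cEI}, clamped, safe)


def solve_muE(target_rE: float, Iext: float, spec: HomeostasisSpec) -> HomeostaticSolution:
    """Firing threshold maintaining the target rate; always feasible."""
    _check_closed_form_domain(target_rE, spec)
    b, L, FI, _ = _parts(target_rE, Iext, spec)
    muE = b.sigmaE * L - b.cEI * FI + b.GE * b.cEE * target_rE + b.GE * Iext
    return _finish(Mode.MUE, target_rE, Iext, spec, {"muE": muE}, ())


def solve_muE_sigmaE(target_rE: float, Iext: float,
                     spec: HomeostasisSpec) -> HomeostaticSolution:
    """Coordinated threshold/slope plasticity with sigmaE = K * muE.

    Preserves the zero-input output F_E(0).  Infeasible if the solved slope
    is not positive; a denominator K*logit - 1 near zero is singular.
    """
    _check_closed_form_domain(target_rE, spec)
    b, L, FI, _ = _parts(target_rE, Iext, spec)
    K = spec.K
    denom = K * L - 1.0
    if abs(denom) < 1e-12:
        raise ValueError("singular slope/threshold inversion: K*logit(rE) = 1")
    muE = (b.cEI * FI - b.GE * b.cEE * target_rE - b.GE * Iext) / denom
    sigmaE = K * muE
    clamped = ("sigmaE",) if sigmaE <= 0 else ()
    solved = {"muE": muE, "sigmaE": sigmaE}
    safe = {"muE": muE, "sigmaE": b.sigmaE} if clamped else None
    return _finish(Mode.MUE_SIGMAE, target_rE, Iext, spec, solved, clamped, safe)


def solve_cIE(target_rE: float, Iext: float, spec: HomeostasisSpec) -> HomeostaticSolution:
    """Excitatory drive to interneurons maintaining the target rate.

    The excitatory nullcline fixes the inhibitory rate y required at the
    target; feasibility demands 0 < y < 1 (inhibitory activity saturates at
    high drive, which is why this mode breaks down for large Iext) and a
    non-negative coupling.
    """
    _check_closed_form_domain(target_rE, spec)
    b = spec.baseline
    y = float(rE_nullcline(target_rE, b.replace(Iext=Iext)))
    clamped: tuple[str, ...] = ()
    if y >= 1.0:
        clamped = ("rI_required_high",)
    elif y <= 0.0:
        clamped = ("rI_required_low",)
    if clamped:
        return HomeostaticSolution(Mode.CIE, target_rE, Iext,
                                   b.replace(Iext=Iext), {"cIE": math.nan},
                                   False, clamped)
    cIE = (b.muI - b.sigmaI * math.log(1.0 / y - 1.0)) / target_rE
    if cIE < 0:
        return HomeostaticSolution(Mode.CIE, target_rE, Iext,
                                   b.replace(Iext=Iext), {"cIE": cIE},
                                   False, ("cIE",))
    return _finish(Mode.CIE, target_rE, Iext, spec, {"cIE": cIE}, ())


# --- combined modes --------------------------------------------------------

def solve_GE_cEI(target_rE: float, Iext: float, spec: HomeostasisSpec,
                 timescale_ratio: float = 1.0) -> HomeostaticSolution:
    """Joint excitatory/inhibitory scaling under the equal-timescale
    constraint GE - GE0 = -(cEI - cEI0).

    ``timescale_ratio`` = tau_cEI / tau_GE generalizes the constraint to
    unequal homeostatic timescales: each parameter's steady-state
    displacement is inversely proportional to its timescale, giving
    GE - GE0 = -w*(cEI - cEI0) with w = tau_cEI / tau_GE.  Experimental;
    w = 1 recovers the standard equal-timescale inversion.
    """
    _check_closed_form_domain(target_rE, spec)
    if timescale_ratio <= 0:
        raise ValueError("timescale_ratio must be positive")
    w = timescale_ratio
    b, L, FI, S = _parts(target_rE, Iext, spec)
    cEI = (b.sigmaE * L + (b.GE + w * b.cEI) * S - b.muE) / (FI + w * S)
    GE = b.GE - w * (cEI - b.cEI)
    clamped = tuple(n for n, bad in (("GE", GE < 0), ("cEI", cEI <= 0)) if bad)
    solved = {"GE": GE, "cEI": cEI}
    safe = {"GE": max(GE, 0.0), "cEI": max(cEI, 1e-12)} if clamped else None
    return _finish(Mode.GE_CEI, target_rE, Iext, spec, solved, clamped, safe)


def _combined_mu(mode: Mode, target_rE: float, Iext: float,
                 spec: HomeostasisSpec, with_sigma: bool) -> HomeostaticSolution:
    b, L, FI, S = _parts(target_rE, Iext, spec)
    if with_sigma:
        denom = spec.K * L - 1.0 - FI - S
        if abs(denom) < 1e-12:
            raise ValueError("singular combined inversion")
        muE = ((b.cEI - b.muE) * FI - (b.GE + b.muE) * S) / denom
    else:
        muE = (b.sigmaE * L - (b.cEI - b.muE) * FI + (b.GE + b.muE) * S) \
            / (1.0 + FI + S)
    GE = b.GE - muE + b.muE
    cEI = b.cEI + muE - b.muE
    solved: dict = {"muE": muE, "GE": GE, "cEI": cEI}
    checks = [("GE", GE < 0), ("cEI", cEI <= 0)]
    if with_sigma:
        sigmaE = spec.K * muE
        solved["sigmaE"] = sigmaE
        checks.append(("sigmaE", sigmaE <= 0))
    clamped = tuple(n for n, bad in checks if bad)
    safe = None
    if clamped:
        safe = dict(solved)
        safe["GE"] = max(GE, 0.0)
        safe["cEI"] = max(cEI, 1e-12)
        if with_sigma:
            safe["sigmaE"] = solved["sigmaE"] if solved["sigmaE"] > 0 else b.sigmaE
    return _finish(mode, target_rE, Iext, spec, solved, clamped, safe)


def solve_GE_cEI_muE(target_rE: float, Iext: float,
                     spec: HomeostasisSpec) -> HomeostaticSolution:
    """Scaling of excitation and inhibition plus threshold plasticity.

    Equal timescales give GE = GE0 - (muE - muE0) and
    cEI = cEI0 + (muE - muE0), so GE + cEI + muE is conserved.
    """
    _check_closed_form_domain(target_rE, spec)
    return _combined_mu(Mode.GE_CEI_MUE, target_rE, Iext, spec, with_sigma=False)


def solve_GE_cEI_muE_sigmaE(target_rE: float, Iext: float,
                            spec: HomeostasisSpec) -> HomeostaticSolution:
    """All four mechanisms, with the slope slaved as sigmaE = K * muE."""
    _check_closed_form_domain(target_rE, spec)
    return _combined_mu(Mode.GE_CEI_MUE_SIGMAE, target_rE, Iext, spec,
                        with_sigma=True)


_SOLVERS = {
    Mode.GE: solve_GE,
    Mode.CEI: solve_cEI,
    Mode.MUE: solve_muE,
    Mode.MUE_SIGMAE: solve_muE_sigmaE,
    Mode.CIE: solve_cIE,
    Mode.GE_CEI: solve_GE_cEI,
    Mode.GE_CEI_MUE: solve_GE_cEI_muE,
    Mode.GE_CEI_MUE_SIGMAE: solve_GE_cEI_muE_sigmaE,
}


def solve(mode: Mode | str, target_rE: float, Iext: float,
          spec: HomeostasisSpec | None = None) -> HomeostaticSolution:
    """Dispatch to the closed-form solver for ``mode``."""
    if spec is None:
        spec = HomeostasisSpec()
    return _SOLVERS[Mode(mode)](target_rE, Iext, spec)


# Direction the bisection bracket must move when a clamp fires: clamps in
# this set occur at too-low target rates (tighten the lower bound).
LOW_SIDE_CLAMPS = frozenset({"GE", "cEI", "sigmaE", "rI_required_high"})


# --- dynamic homeostasis ---------------------------------------------------

#: sign of d(param)/dt relative to (rE - rho): parameters whose increase
#: raises the excitatory rate shrink when the rate is above target.
_ODE_SIGNS = {"GE": -1.0, "cEI": +1.0, "muE": +1.0, "cIE": +1.0}


@dataclass(frozen=True)
class HomeostaticOdeResult:
    """Parameter trajectories of the slow homeostatic dynamics."""

    mode: Mode
    times: np.ndarray                 # ms (subsampled)
    series: dict                      # param name -> array on `times`
    rE: np.ndarray                    # excitatory rate on `times`
    final_params: WCParams
    converged: bool

    def to_frame(self) -> pd.DataFrame:
        data = {"time_ms": self.times, "rE": self.rE}
        data.update(self.series)
        return pd.DataFrame(data)


def simulate_homeostatic_odes(
    mode: Mode | str,
    rho: float,
    Iext: float,
    spec: HomeostasisSpec | None = None,
    dt: float = 0.2,
    duration: float = 200_000.0,
    record_every: int = 250,
    rate_tol: float = 1e-4,
    timescales: dict | None = None,
) -> HomeostaticOdeResult:
    """Co-integrate the node with slow integral control on its parameters.

    Each adapted parameter follows tau_p * dp/dt = +/-(rE - rho), with the
    sign chosen so the feedback is negative; for coordinated intrinsic
    plasticity sigmaE is slaved to K * muE at every step.  ``timescales``
    maps parameter names to per-parameter tau_p (ms), defaulting to the
    spec's common ``tau_homeo``; unequal values displace each parameter
    inversely to its timescale.  Dale constraints are clamped online.
    Convergence is declared when the mean excitatory rate over the last 5%
    of the run is within ``rate_tol`` of ``rho``.
    """
    mode = Mode(mode)
    if spec is None:
        spec = HomeostasisSpec()
    b = spec.baseline
    if dt > min(b.tauE, b.tauI):
        raise ValueError("dt must not exceed min(tauE, tauI)")
    if spec.tau_homeo < 10.0 * max(b.tauE, b.tauI):
        raise ValueError("tau_homeo must be much slower than the node dynamics")

    adapted = [p for p in ADAPTED[mode] if p != "sigmaE"]
    slave_sigma = "sigmaE" in ADAPTED[mode]
    K = spec.K

    n_steps = int(round(duration / dt))
    p = {name: getattr(b, name) for name in
         ("cEE", "cIE", "cEI", "GE", "muE", "muI", "sigmaE", "sigmaI")}
    e, i = 0.0, 0.0
    aE, aI = dt / b.tauE, dt / b.tauI
    gains = {}
    for name in adapted:
        tau_p = spec.tau_homeo if not timescales else timescales.get(
            name, spec.tau_homeo)
        if tau_p < 10.0 * max(b.tauE, b.tauI):
            raise ValueError("homeostatic timescales must be much slower "
                             "than the node dynamics")
        gains[name] = dt / tau_p
    exp = math.exp

    n_rec = n_steps // record_every + 1
    times = np.empty(n_rec)
    rE_rec = np.empty(n_rec)
    rec = {name: np.empty(n_rec) for name in ADAPTED[mode]}
    j = 0
    for k in range(n_steps + 1):
        if k % record_every == 0 and j < n_rec:
            times[j] = k * dt
            rE_rec[j] = e
            for name in ADAPTED[mode]:
                rec[name][j] = p[name]
            j += 1
        if k == n_steps:
            break
        zE = -((p["GE"] * p["cEE"] * e - p["cEI"] * i + p["GE"] * Iext)
               - p["muE"]) / p["sigmaE"]
        zI = -((p["cIE"] * e) - p["muI"]) / p["sigmaI"]
        FE = 1.0 / (1.0 + exp(zE)) if zE < 700.0 else 0.0
        FI = 1.0 / (1.0 + exp(zI)) if zI < 700.0 else 0.0
        err = e - rho
        e = e + aE * (FE - e)
        i = i + aI * (FI - i)
        for name in adapted:
            p[name] += _ODE_SIGNS[name] * gains[name] * err
        # online Dale clamps: a running circuit cannot refuse a bound
        if p["GE"] < 0.0:
            p["GE"] = 0.0
        if p["cEI"] < 0.0:
            p["cEI"] = 0.0
        if p["cIE"] < 0.0:
            p["cIE"] = 0.0
        if slave_sigma:
            if p["muE"] < 1e-9:
                p["muE"] = 1e-9
            p["sigmaE"] = K * p["muE"]

    tail = max(1, n_rec // 20)
    converged = bool(abs(np.mean(rE_rec[-tail:]) - rho) < rate_tol)
    final = b.replace(Iext=Iext, **{name: p[name] for name in ADAPTED[mode]})
    return HomeostaticOdeResult(
        mode=mode, times=times[:j], rE=rE_rec[:j],
        series={name: rec[name][:j] for name in ADAPTED[mode]},
        final_params=final, converged=converged,
    )
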