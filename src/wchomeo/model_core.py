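"""Extended Wilson-Cowan neural-mass node and its deterministic integration.

The model describes the mean firing rates ``rE(t)`` and ``rI(t)`` of coupled
excitatory and inhibitory populations:

    tauE * drE/dt = -rE + F_E(GE*cEE*rE - cEI*rI + GE*Iext)
    tauI * drI/dt = -rI + F_I(cIE*rE - cII*rI + alpha*GE*Iext)

where ``F_E`` and ``F_I`` are logistic activation functions with separate
threshold (``mu``) and sensitivity (``sigma``) parameters.  The excitatory
gain ``GE`` multiplies every excitatory input onto the excitatory population
(recurrent and external), which is the handle used by synaptic-scaling
homeostasis.  Self-inhibition ``cII`` and the fraction ``alpha`` of external
drive reaching the inhibitory population default to zero, the configuration
in which the closed-form homeostatic solvers are valid.

Time is in milliseconds throughout; rates are dimensionless activities in
(0, 1).  Integration is explicit Euler; with ``dt <= min(tauE, tauI)`` each
update is a convex combination of the current rate and a sigmoid output, so
trajectories remain in [0, 1] by construction and are never clipped.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace, asdict
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

__all__ = [
    "WCParams",
    "Pulse",
    "SimConfig",
    "Trajectory",
    "sigmoid",
    "sigmoid_slope",
    "drift",
    "integrate",
]


class InvalidParameterError(ValueError):
    """A model parameter violates its domain constraint."""


@dataclass(frozen=True)
class WCParams:
    """Full parameter set of the extended Wilson-Cowan node.

    Defaults are the canonical gamma-resonant configuration: with these
    values the node crosses a Hopf bifurcation as external drive increases
    and oscillates near 40 Hz just above it.
    """

    cEE: float = 3.5    # recurrent excitatory coupling
    cIE: float = 3.75   # excitatory -> inhibitory coupling
    cEI: float = 2.5    # inhibitory -> excitatory coupling
    cII: float = 0.0    # inhibitory self-coupling
    GE: float = 1.0     # gain on all excitatory inputs to the E population
    muE: float = 1.0    # excitatory firing threshold
    muI: float = 1.0    # inhibitory firing threshold
    sigmaE: float = 0.25  # excitatory activation sensitivity
    sigmaI: float = 0.25  # inhibitory activation sensitivity
    tauE: float = 2.5   # excitatory time constant (ms)
    tauI: float = 5.0   # inhibitory time constant (ms)
    Iext: float = 0.0   # external excitatory drive
    alpha: float = 0.0  # fraction of Iext delivered to the I population

    def __post_init__(self) -> None:
        if self.tauE <= 0 or self.tauI <= 0:
            raise InvalidParameterError("time constants must be positive")
        if self.sigmaE <= 0 or self.sigmaI <= 0:
            raise InvalidParameterError("activation sensitivities must be positive")
        for name in ("cEE", "cIE", "cEI", "cII", "GE"):
            if getattr(self, name) < 0:
                raise InvalidParameterError(
                    f"{name} must be non-negative (Dale-consistent couplings)"
                )

    def replace(self, **changes) -> "WCParams":
        return replace(self, **changes)

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "WCParams":
        return cls(**d)


@dataclass(frozen=True)
class Pulse:
    """Additive square perturbation to the external drive.

    Active on ``[onset, onset + width)``; delivered to the excitatory
    population (it adds to ``Iext`` and is therefore multiplied by ``GE``).
    """

    onset: float            # ms
    amplitude: float = 1.0
    width: float = 1.0      # ms


@dataclass(frozen=True)
class SimConfig:
    """Deterministic Euler integration settings."""

    dt: float = 0.1               # ms
    duration: float = 5000.0      # ms
    r0: tuple[float, float] = (0.0, 0.0)
    pulses: tuple[Pulse, ...] = ()

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise InvalidParameterError("dt must be positive")
        if self.duration < self.dt:
            raise InvalidParameterError("duration must be at least one step")
        if not (0.0 <= self.r0[0] <= 1.0 and 0.0 <= self.r0[1] <= 1.0):
            raise InvalidParameterError("initial rates must lie in [0, 1]")
        for p in self.pulses:
            if p.width < self.dt:
                raise InvalidParameterError("pulse width must be at least dt")

    def replace(self, **changes) -> "SimConfig":
        return replace(self, **changes)


@dataclass(frozen=True)
class Trajectory:
    """Sampled firing-rate time series on a uniform grid (ms)."""

    times: np.ndarray
    rE: np.ndarray
    rI: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time_ms": self.times, "rE": self.rE, "rI": self.rI})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def sigmoid(x, mu: float, sigma: float):
    """Logistic activation F(x) = 1 / (1 + exp(-(x - mu) / sigma)).

    Strictly increasing, with F(mu) = 1/2 and range (0, 1).
    """
    if sigma <= 0:
        raise InvalidParameterError("sigma must be positive")
    return expit((np.asarray(x, dtype=float) - mu) / sigma)


def sigmoid_slope(x, mu: float, sigma: float):
    """Derivative of :func:`sigmoid`; equals F(1 - F) / sigma, maximal 1/(4*sigma) at x = mu."""
    f = sigmoid(x, mu, sigma)
    return f * (1.0 - f) / sigma


def drift(rE, rI, params: WCParams, Iext: float | None = None):
    """Instantaneous time derivatives (drE/dt, drI/dt) in 1/ms.

    ``Iext`` overrides ``params.Iext`` when given (used for pulses).
    """
    p = params
    I = p.Iext if Iext is None else Iext
    xE = p.GE * p.cEE * np.asarray(rE) - p.cEI * np.asarray(rI) + p.GE * I
    xI = p.cIE * np.asarray(rE) - p.cII * np.asarray(rI) + p.alpha * p.GE * I
    dE = (-np.asarray(rE) + sigmoid(xE, p.muE, p.sigmaE)) / p.tauE
    dI = (-np.asarray(rI) + sigmoid(xI, p.muI, p.sigmaI)) / p.tauI
    return dE, dI


# ---------------------------------------------------------------------------
# Euler kernel.  Compiled with numba when available; the pure-Python fallback
# computes the identical recurrence.

def _euler_py(rE0, rI0, n_steps, dt, cEE, cIE, cEI, cII, GE, muE, muI,
              sigmaE, sigmaI, tauE, tauI, alpha, iext):
    rE = np.empty(n_steps + 1)
    rI = np.empty(n_steps + 1)
    rE[0] = rE0
    rI[0] = rI0
    aE = dt / tauE
    aI = dt / tauI
    e, i = rE0, rI0
    exp = math.exp
    for k in range(n_steps):
        I = iext[k]
        zE = -((GE * cEE * e - cEI * i + GE * I) - muE) / sigmaE
        zI = -((cIE * e - cII * i + alpha * GE * I) - muI) / sigmaI
        FE = 1.0 / (1.0 + exp(zE)) if zE < 700.0 else 0.0
        FI = 1.0 / (1.0 + exp(zI)) if zI < 700.0 else 0.0
        e = e + aE * (FE - e)
        i = i + aI * (FI - i)
        rE[k + 1] = e
        rI[k + 1] = i
    return rE, rI


try:  # pragma: no cover - exercised implicitly everywhere
    from numba import njit

    _euler_kernel = njit(cache=True, fastmath=False)(_euler_py)
except ImportError:  # pragma: no cover
    _euler_kernel = _euler_py


def _drive_array(params: WCParams, sim: SimConfig, n_steps: int) -> np.ndarray:
    """Per-step external drive: baseline Iext plus any active pulses."""
    iext = np.full(n_steps, params.Iext, dtype=float)
    for p in sim.pulses:
        k0 = int(round(p.onset / sim.dt))
        k1 = int(round((p.onset + p.width) / sim.dt))
        iext[max(k0, 0):min(k1, n_steps)] += p.amplitude
    return iext


def integrate(params: WCParams, sim: SimConfig | None = None) -> Trajectory:
    """Explicit-Euler trajectory of the node; fully deterministic.

    Refuses ``dt > min(tauE, tauI)``: beyond that step size the update is no
    longer a convex combination and boundedness of the rates is lost.
    """
    if sim is None:
        sim = SimConfig()
    if sim.dt > min(params.tauE, params.tauI):
        raise InvalidParameterError(
            "dt must not exceed min(tauE, tauI); boundedness is not guaranteed"
        )
    n_steps = int(round(sim.duration / sim.dt))
    iext = _drive_array(params, sim, n_steps)
    rE, rI = _euler_kernel(
        float(sim.r0[0]), float(sim.r0[1]), n_steps, sim.dt,
        params.cEE, params.cIE, params.cEI, params.cII, params.GE,
        params.muE, params.muI, params.sigmaE, params.sigmaI,
        params.tauE, params.tauI, params.alpha, iext,
    )
    times = np.arange(n_steps + 1) * sim.dt
    return Trajectory(times=times, rE=rE, rI=rI)
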