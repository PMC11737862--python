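"""Nullclines, fixed-point detection, Jacobian and stability classification.

A fixed point is an intersection of the two nullclines.  Because the
excitatory nullcline involves a logit, fixed points are located by scanning
the signed difference of the two nullclines over ``rE`` in (0, 1) at a fine
resolution, bracketing every sign change and refining each bracket by root
finding.  Linear stability around each point follows from the 2x2 Jacobian:
the system regime is read off the trace, determinant and discriminant of
its eigenvalue pair.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .model_core import WCParams, sigmoid, sigmoid_slope

__all__ = [
    "FixedPoint",
    "PointLabel",
    "SystemLabel",
    "SystemClass",
    "rE_nullcline",
    "rI_nullcline",
    "residual",
    "find_fixed_points",
    "jacobian",
    "classify",
    "fixed_points_to_frame",
]

#: resolution of the residual scan over rE
SCAN_STEP = 1e-6
#: width to which each sign-change bracket is refined
REFINE_TOL = 1e-12
#: |trace| or |discriminant| below this is treated as degenerate
DEGENERATE_TOL = 1e-12
#: absolute tolerance for matching a fixed point to a requested target rE
TARGET_MATCH_TOL = 1e-6


class DomainError(ValueError):
    """Argument outside the open unit interval (or other domain violation)."""


class NoFixedPointError(RuntimeError):
    """The residual scan found no root; the sigmoidal system always has one,
    so this indicates corrupted parameters."""


class PointLabel(str, enum.Enum):
    STABLE_NODE = "stable node"
    STABLE_SPIRAL = "stable spiral"
    UNSTABLE_SPIRAL = "unstable spiral"
    UNSTABLE_NODE = "unstable node"
    SADDLE = "saddle"
    CENTER_DEGENERATE = "center/degenerate"


class SystemLabel(str, enum.Enum):
    STABLE_FIXED_POINT = "STABLE_FIXED_POINT"
    STABLE_SPIRAL = "STABLE_SPIRAL"
    LIMIT_CYCLE = "LIMIT_CYCLE"
    BISTABLE = "BISTABLE"
    UNSTABLE = "UNSTABLE"
    OTHER = "OTHER"


@dataclass(frozen=True)
class FixedPoint:
    """A root of the fixed-point equation with its linearization summary."""

    rE: float
    rI: float
    residual: float
    trace: float          # 1/ms
    det: float            # 1/ms^2
    eigenvalues: tuple[complex, complex]
    label: PointLabel

    @property
    def discriminant(self) -> float:
        return self.trace * self.trace - 4.0 * self.det


@dataclass(frozen=True)
class SystemClass:
    """Regime of the whole system given all its fixed points."""

    label: SystemLabel
    fixed_points: tuple[FixedPoint, ...]
    target_index: int | None = None


def rE_nullcline(rE, params: WCParams):
    """rI value at which drE/dt = 0 for the given rE (inverts F_E).

    Diverges to +inf as rE -> 0+ and to -inf as rE -> 1-.
    """
    p = params
    r = np.asarray(rE, dtype=float)
    if np.any(r <= 0) or np.any(r >= 1):
        raise DomainError("rE must lie strictly inside (0, 1)")
    if p.cEI == 0:
        raise DomainError("cEI = 0: the excitatory nullcline degenerates")
    return (
        p.sigmaE * np.log((1.0 - r) / r)
        + p.GE * p.cEE * r
        + p.GE * p.Iext
        - p.muE
    ) / p.cEI


def rI_nullcline(rE, params: WCParams):
    """rI value at which drI/dt = 0 for the given rE.

    Closed form for ``cII = 0``; with self-inhibition the relation
    rI = F_I(cIE*rE - cII*rI + alpha*GE*Iext) is implicit and is solved by
    bisection (the right-hand side decreases in rI, so the root is unique).
    """
    p = params
    base = p.cIE * np.asarray(rE, dtype=float) + p.alpha * p.GE * p.Iext
    if p.cII == 0:
        return sigmoid(base, p.muI, p.sigmaI)

    def solve_one(b: float) -> float:
        lo, hi = 0.0, 1.0
        # g(rI) = F_I(b - cII*rI) - rI is decreasing: bisect on its sign
        for _ in range(60):
            mid = 0.5 * (lo + hi)
            if sigmoid(b - p.cII * mid, p.muI, p.sigmaI) - mid > 0:
                lo = mid
            else:
                hi = mid
        return 0.5 * (lo + hi)

    if np.ndim(base) == 0:
        return solve_one(float(base))
    return np.array([solve_one(b) for b in np.ravel(base)]).reshape(np.shape(base))


def residual(rE, params: WCParams):
    """Signed fixed-point residual: rE_nullcline(rE) - rI_nullcline(rE).

    Zero exactly at fixed points; diverges to +inf as rE -> 0+.
    """
    return rE_nullcline(rE, params) - rI_nullcline(rE, params)


def jacobian(rE_star: float, rI_star: float, params: WCParams) -> np.ndarray:
    """Jacobian of the flow at a fixed point (entries in 1/ms).

    At a fixed point F(input) equals the rate itself, so the logistic slope
    simplifies to r*(1 - r*)/sigma; this avoids recomputing the inputs.
    """
    p = params
    dFE = rE_star * (1.0 - rE_star) / p.sigmaE
    dFI = rI_star * (1.0 - rI_star) / p.sigmaI
    a11 = (-1.0 + p.GE * p.cEE * dFE) / p.tauE
    a12 = (-p.cEI * dFE) / p.tauE
    a21 = (p.cIE * dFI) / p.tauI
    a22 = (-1.0 - p.cII * dFI) / p.tauI
    return np.array([[a11, a12], [a21, a22]])


def _eigenvalues(tr: float, det: float) -> tuple[complex, complex]:
    disc = tr * tr - 4.0 * det
    if disc >= 0:
        s = np.sqrt(disc)
        return ((tr + s) / 2.0 + 0j, (tr - s) / 2.0 + 0j)
    s = np.sqrt(-disc)
    return (complex(tr / 2.0, s / 2.0), complex(tr / 2.0, -s / 2.0))


def _point_label(tr: float, det: float) -> PointLabel:
    disc = tr * tr - 4.0 * det
    if abs(tr) < DEGENERATE_TOL or abs(disc) < DEGENERATE_TOL:
        return PointLabel.CENTER_DEGENERATE
    if det < 0:
        return PointLabel.SADDLE
    if tr < 0:
        return PointLabel.STABLE_SPIRAL if disc < 0 else PointLabel.STABLE_NODE
    return PointLabel.UNSTABLE_SPIRAL if disc < 0 else PointLabel.UNSTABLE_NODE


def _make_fixed_point(rE_star: float, params: WCParams) -> FixedPoint:
    rI_star = float(rI_nullcline(rE_star, params))
    res = float(residual(rE_star, params))
    J = jacobian(rE_star, rI_star, params)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    return FixedPoint(
        rE=rE_star,
        rI=rI_star,
        residual=res,
        trace=tr,
        det=det,
        eigenvalues=_eigenvalues(tr, det),
        label=_point_label(tr, det),
    )


def find_fixed_points(
    params: WCParams,
    scan_step: float = SCAN_STEP,
    refine_tol: float = REFINE_TOL,
) -> list[FixedPoint]:
    """Locate every fixed point by residual scanning plus bracket refinement.

    The residual is evaluated on a uniform rE grid over [scan_step,
    1 - scan_step]; each sign change is refined by Brent's method to a
    bracket below ``refine_tol`` in rE.  Points are returned ordered by rE.
    """
    grid = np.arange(scan_step, 1.0 - 0.5 * scan_step, scan_step)
    vals = residual(grid, params)
    sign = np.sign(vals)
    # exact zeros on the grid count as roots
    zero_idx = np.nonzero(sign == 0)[0]
    flips = np.nonzero(sign[:-1] * sign[1:] < 0)[0]
    roots: list[float] = [float(grid[i]) for i in zero_idx]
    f = lambda r: float(residual(r, params))
    for i in flips:
        roots.append(brentq(f, grid[i], grid[i + 1], xtol=refine_tol))
    if not roots:
        raise NoFixedPointError(
            "no root of the fixed-point residual found; parameters corrupt?"
        )
    roots.sort()
    return [_make_fixed_point(r, params) for r in roots]


_STABLE = (PointLabel.STABLE_NODE, PointLabel.STABLE_SPIRAL)


def classify(
    params: WCParams,
    target_rE: float | None = None,
    fixed_points: list[FixedPoint] | None = None,
) -> SystemClass:
    """Classify the system into one of the five dynamical regimes.

    Single fixed point: stable node -> STABLE_FIXED_POINT; stable spiral ->
    STABLE_SPIRAL; unstable spiral -> LIMIT_CYCLE (the flow points inward on
    the unit square, so by Poincare-Bendixson a periodic orbit exists).
    Multiple fixed points are judged relative to the point matching
    ``target_rE``: an unstable target gives UNSTABLE, a stable target among
    two stable equilibria gives BISTABLE.  Configurations the rules do not
    cover (e.g. a single unstable node, or no target supplied with several
    roots) are labelled OTHER rather than silently binned.
    """
    fps = fixed_points if fixed_points is not None else find_fixed_points(params)
    fps = tuple(fps)

    target_index: int | None = None
    if target_rE is not None:
        dists = [abs(fp.rE - target_rE) for fp in fps]
        j = int(np.argmin(dists))
        if dists[j] <= TARGET_MATCH_TOL:
            target_index = j

    if len(fps) == 1:
        fp = fps[0]
        mapping = {
            PointLabel.STABLE_NODE: SystemLabel.STABLE_FIXED_POINT,
            PointLabel.STABLE_SPIRAL: SystemLabel.STABLE_SPIRAL,
            PointLabel.UNSTABLE_SPIRAL: SystemLabel.LIMIT_CYCLE,
        }
        label = mapping.get(fp.label, SystemLabel.OTHER)
        return SystemClass(label=label, fixed_points=fps, target_index=target_index)

    if target_index is not None:
        target = fps[target_index]
        if target.label not in _STABLE:
            return SystemClass(SystemLabel.UNSTABLE, fps, target_index)
        n_stable = sum(fp.label in _STABLE for fp in fps)
        if n_stable == 2:
            return SystemClass(SystemLabel.BISTABLE, fps, target_index)
    return SystemClass(SystemLabel.OTHER, fps, target_index)


def fixed_points_to_frame(fps) -> pd.DataFrame:
    """Tabular report of fixed points (one row per point)."""
    return pd.DataFrame(
        {
            "rE": [fp.rE for fp in fps],
            "rI": [fp.rI for fp in fps],
            "residual": [fp.residual for fp in fps],
            "trace": [fp.trace for fp in fps],
            "det": [fp.det for fp in fps],
            "re_lambda": [fp.eigenvalues[0].real for fp in fps],
            "im_lambda": [abs(fp.eigenvalues[0].imag) for fp in fps],
            "label": [fp.label.value for fp in fps],
        }
    )
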