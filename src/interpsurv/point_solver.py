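"""Recover family parameters that interpolate specified survival coordinates.

Given coordinates (t_i, s_i) the survival function is rearranged and solved as
simultaneous equations: one point determines the exponential rate, two points
determine each two-parameter family. Weibull, log-logistic and log-normal
linearise exactly (their transformed survival is linear in ln t), so the
solution is closed form; Gompertz has no closed form and its shape is found by
bracketed root finding on a ratio equation that is strictly increasing in the
shape.

The solved model passes through the specified coordinates to within 1e−8
(plug-back residual), which is the definition of convergence here.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtri

from .distributions import FAMILIES, CureModel, ParametricModel, n_params
from .exceptions import (
    CureInfeasibleError,
    InfeasiblePointsError,
    NonConvergenceError,
    PointCountError,
    PointDomainError,
    PointMonotonicityError,
    PointsError,
    PointTieError,
)

__all__ = [
    "SurvivalPoint",
    "SolveResult",
    "validate_points",
    "solve",
    "solve_gompertz_shape",
    "solve_cure",
    "solve_all",
]

RESIDUAL_TOL = 1e-8


@dataclass(frozen=True)
class SurvivalPoint:
    """One (time, survival) coordinate the fitted curve must pass through."""

    time: float
    survival: float

    def __post_init__(self):
        object.__setattr__(self, "time", float(self.time))
        object.__setattr__(self, "survival", float(self.survival))


@dataclass(frozen=True)
class SolveResult:
    """Outcome of interpolating one family through a point set."""

    model: ParametricModel | CureModel
    residuals: np.ndarray
    converged: bool
    method: str  # "closed_form" | "root_find"

    @property
    def max_residual(self) -> float:
        return float(np.max(self.residuals))


def _coerce_point(p) -> SurvivalPoint:
    if isinstance(p, SurvivalPoint):
        return p
    t, s = p
    return SurvivalPoint(t, s)


def validate_points(points, required_count: int) -> list[SurvivalPoint]:
    """Sort points by time and enforce the interpolation preconditions.

    Exactly ``required_count`` points; strictly increasing times; strictly
    decreasing survival; every coordinate inside t > 0, 0 < s < 1.
    """
    pts = [_coerce_point(p) for p in points]
    if len(pts) != required_count:
        raise PointCountError(
            f"expected {required_count} point(s), got {len(pts)}"
        )
    for p in pts:
        if not np.isfinite(p.time) or p.time <= 0:
            raise PointDomainError(f"time must be > 0, got {p.time}")
        if not np.isfinite(p.survival) or not (0.0 < p.survival < 1.0):
            raise PointDomainError(
                f"survival must lie strictly in (0, 1), got {p.survival}"
            )
    pts.sort(key=lambda p: p.time)
    for a, b in zip(pts, pts[1:]):
        if a.time == b.time:
            raise PointTieError(f"duplicate time {a.time}")
        if b.survival >= a.survival:
            raise PointMonotonicityError(
                f"survival must strictly decrease with time: "
                f"S({a.time})={a.survival} vs S({b.time})={b.survival}"
            )
    return pts


def solve_gompertz_shape(t1: float, s1: float, t2: float, s2: float) -> float:
    """Shape b of the Gompertz model through two decreasing coordinates.

    b is the unique real root of (e^{b t2} − 1)/(e^{b t1} − 1) = ln s2 / ln s1,
    where the left side equals t2/t1 at b = 0 (removable singularity). The
    ratio is continuous and strictly increasing in b with range (1, ∞), so a
    sign-changing bracket found by doubling outward from [−1, 1] always exists
    for valid points; Brent's method then converges to machine precision.
    """
    target = np.log(s2) / np.log(s1)  # H(t2)/H(t1) > 1

    def ratio_minus_target(b: float) -> float:
        if b == 0.0:
            return t2 / t1 - target
        return np.expm1(b * t2) / np.expm1(b * t1) - target

    lo, hi = -1.0, 1.0
    cap = 500.0 / t2
    while ratio_minus_target(lo) > 0:
        lo *= 2.0
        if -lo > cap:
            raise NonConvergenceError("gompertz shape bracket expansion failed (low)")
    while ratio_minus_target(hi) < 0:
        hi *= 2.0
        if hi > cap:
            raise NonConvergenceError("gompertz shape bracket expansion failed (high)")
    b = brentq(ratio_minus_target, lo, hi, xtol=1e-15, rtol=8.9e-16, maxiter=200)
    if abs(ratio_minus_target(b)) > 1e-10:
        raise NonConvergenceError(
            f"gompertz ratio residual {ratio_minus_target(b):.3e} above 1e-10"
        )
    return float(b)


def _solve_params(family: str, pts: list[SurvivalPoint]) -> tuple[float, ...]:
    if family == "exponential":
        (p,) = pts
        return (-np.log(p.survival) / p.time,)

    (p1, p2) = pts
    t1, s1, t2, s2 = p1.time, p1.survival, p2.time, p2.survival
    dlogt = np.log(t2) - np.log(t1)

    if family == "weibull":
        y1, y2 = np.log(-np.log(s1)), np.log(-np.log(s2))
        k = (y2 - y1) / dlogt
        sigma = t1 * (-np.log(s1)) ** (-1.0 / k)
        return (k, sigma)
    if family == "loglogistic":
        y1, y2 = np.log(1.0 / s1 - 1.0), np.log(1.0 / s2 - 1.0)
        if y2 <= y1:  # cannot happen for strictly decreasing s, kept as a guard
            raise InfeasiblePointsError("log-logistic linearisation is degenerate")
        k = (y2 - y1) / dlogt
        sigma = t1 * (1.0 / s1 - 1.0) ** (-1.0 / k)
        return (k, sigma)
    if family == "lognormal":
        z1, z2 = ndtri(1.0 - s1), ndtri(1.0 - s2)
        if z2 <= z1:
            raise InfeasiblePointsError("log-normal linearisation is degenerate")
        sdlog = dlogt / (z2 - z1)
        meanlog = np.log(t1) - sdlog * z1
        return (meanlog, sdlog)
    if family == "gompertz":
        b = solve_gompertz_shape(t1, s1, t2, s2)
        if b == 0.0:
            a = -np.log(s1) / t1
        else:
            a = -np.log(s1) * b / np.expm1(b * t1)
        return (b, a)
    raise InfeasiblePointsError(f"unknown family {family!r}")


def solve(family: str, points, time_unit: str = "months") -> SolveResult:
    """Interpolate ``family`` exactly through ``points``.

    ``points`` must satisfy :func:`validate_points` for the family's required
    count (1 for exponential, 2 otherwise). Returns a :class:`SolveResult`
    whose model reproduces every coordinate to within 1e−8.
    """
    pts = validate_points(points, n_params(family))
    params = _solve_params(family, pts)
    model = ParametricModel(family, params, time_unit=time_unit)
    residuals = np.array(
        [abs(model.survival(p.time) - p.survival) for p in pts]
    )
    method = "root_find" if family == "gompertz" else "closed_form"
    return SolveResult(model, residuals, bool(residuals.max() < RESIDUAL_TOL), method)


def solve_cure(family: str, pi: float, points, time_unit: str = "months") -> SolveResult:
    """Interpolate a mixture cure model with fixed cure fraction ``pi``.

    Points are given on the overall survival scale; the base family is solved
    through the transformed coordinates s′ = (s − π)/(1 − π). Every point must
    satisfy s > π, else the cure plateau makes interpolation impossible.
    """
    if not (0.0 <= pi < 1.0):
        raise CureInfeasibleError("cure fraction must lie in [0, 1)")
    pts = validate_points(points, n_params(family))
    for p in pts:
        if p.survival <= pi:
            raise CureInfeasibleError(
                f"point survival {p.survival} is at or below the cure fraction {pi}"
            )
    base_pts = [
        SurvivalPoint(p.time, (p.survival - pi) / (1.0 - pi)) for p in pts
    ]
    base = solve(family, base_pts, time_unit=time_unit)
    model = CureModel(pi, base.model)
    residuals = np.array(
        [abs(model.survival(p.time) - p.survival) for p in pts]
    )
    return SolveResult(
        model, residuals, bool(residuals.max() < RESIDUAL_TOL), base.method
    )


def solve_all(points_one, points_two, time_unit: str = "months") -> dict:
    """Attempt every family: exponential through ``points_one`` (a single
    point), the two-parameter families through ``points_two``.

    Returns a mapping family name → :class:`SolveResult`, or the raised
    :class:`PointsError` / :class:`InfeasiblePointsError` for families that
    could not be solved — one entry per family, never a batch abort.
    """
    out: dict[str, SolveResult | Exception] = {}
    for family in FAMILIES:
        pts = points_one if family == "exponential" else points_two
        try:
            out[family] = solve(family, pts, time_unit=time_unit)
        except (PointsError, InfeasiblePointsError, NonConvergenceError) as err:
            out[family] = err
    return out
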