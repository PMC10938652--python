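"""Assembly of solved models into deliverable extrapolations.

Piecewise curves join a Kaplan-Meier prefix (or a bare anchor) at a time t0 to
a parametric tail solved on the conditional scale, so that the overall curve
still passes through user-specified unconditional coordinates. Background
mortality substitutes the general-population hazard wherever the model hazard
falls below it. Model averaging, hazard curves over a grid, and restricted
mean survival time (the area under S up to a horizon τ, convertible to
life-years) complete the health-economics toolkit.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .distributions import TIME_UNITS, CureModel, ParametricModel
from .exceptions import (
    LifeTableCoverageError,
    OutOfSupportError,
    ParameterError,
    PointMonotonicityError,
    PointOrderingError,
)
from .point_solver import SolveResult, SurvivalPoint, solve, solve_cure
from .survdata import KMCurve, LifeTable, km_survival_at

__all__ = [
    "PiecewiseModel",
    "MortalityAdjustedModel",
    "ModelAverage",
    "RMSTResult",
    "build_piecewise",
    "evaluate",
    "apply_background_mortality",
    "average_models",
    "rmst",
    "hazard_curve",
]


@dataclass(frozen=True)
class PiecewiseModel:
    """KM (or linear-anchor) prefix up to t0, conditional parametric tail after.

    For t ≥ t0, S(t) = anchor · S_tail(t − t0); the curve is continuous at t0
    by construction. With no Kaplan-Meier prefix the initial segment is the
    straight line from (0, 1) to (t0, anchor).
    """

    t0: float
    anchor: float
    tail: ParametricModel | CureModel
    prefix: KMCurve | None = None
    solve_result: SolveResult | None = None

    @property
    def time_unit(self) -> str:
        return self.tail.time_unit

    def survival(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        after = t_arr >= self.t0
        if after.any():
            out[after] = self.anchor * np.asarray(
                self.tail.survival(t_arr[after] - self.t0)
            )
        before = ~after
        if before.any():
            if self.prefix is not None:
                out[before] = [km_survival_at(self.prefix, ti) for ti in t_arr[before]]
            else:
                out[before] = 1.0 + (self.anchor - 1.0) * t_arr[before] / self.t0
        return float(out[0]) if np.ndim(t) == 0 else out

    def hazard(self, t):
        """Tail hazard beyond t0. Before t0 the linear-anchor prefix has
        h = −S′/S; a KM prefix is a step function, reported as hazard 0
        between events."""
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.empty_like(t_arr)
        after = t_arr >= self.t0
        if after.any():
            out[after] = np.asarray(self.tail.hazard(t_arr[after] - self.t0))
        before = ~after
        if before.any():
            if self.prefix is not None:
                out[before] = 0.0
            else:
                slope = (1.0 - self.anchor) / self.t0
                out[before] = slope / self.survival(t_arr[before])
        return float(out[0]) if np.ndim(t) == 0 else out

    def cumulative_hazard(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        H = -np.log(self.survival(t_arr))
        return float(H[0]) if np.ndim(t) == 0 else H


@dataclass(frozen=True)
class ModelAverage:
    """Arithmetic mean of member survival curves at every time point."""

    models: tuple

    def __post_init__(self):
        if len(self.models) == 0:
            raise ParameterError("model average requires at least one model")
        object.__setattr__(self, "models", tuple(self.models))

    def survival(self, t):
        vals = np.stack([np.atleast_1d(np.asarray(m.survival(t))) for m in self.models])
        out = vals.mean(axis=0)
        return float(out[0]) if np.ndim(t) == 0 else out

    def hazard(self, t):
        # −(d/dt) ln mean(S_i) = Σ h_i S_i / Σ S_i
        S = np.stack([np.atleast_1d(np.asarray(m.survival(t))) for m in self.models])
        h = np.stack([np.atleast_1d(np.asarray(m.hazard(t))) for m in self.models])
        out = (h * S).sum(axis=0) / S.sum(axis=0)
        return float(out[0]) if np.ndim(t) == 0 else out

    def cumulative_hazard(self, t):
        out = -np.log(np.atleast_1d(self.survival(t)))
        return float(out[0]) if np.ndim(t) == 0 else out


class MortalityAdjustedModel:
    """Inner model with a general-population hazard floor.

    The adjusted hazard is max(h_inner(t), h_pop(age0 + t/units_per_year)),
    with the population hazard piecewise-constant per whole year of age,
    −ln(1 − q_x) converted into the model's time unit. The survival is
    S_adj(t) = S_inner(t) · exp(−∫₀ᵗ max(0, h_pop − h_inner)), evaluated by
    trapezoidal quadrature on a fixed grid over the horizon; the excess
    integrand is bounded by the population hazard, so the quadrature is robust
    even where the inner hazard diverges at t = 0. The floor is applied after
    parameter estimation, so interpolated points may no longer be reproduced.
    """

    def __init__(
        self,
        inner,
        life_table: LifeTable,
        age0: float,
        sex: str,
        time_unit: str | None = None,
        horizon: float | None = None,
        n_grid: int = 20001,
    ):
        self.inner = inner
        self.life_table = life_table
        self.age0 = float(age0)
        self.sex = sex
        self.time_unit = time_unit or getattr(inner, "time_unit", "years")
        if self.time_unit not in TIME_UNITS:
            raise ParameterError(f"unknown time unit {self.time_unit!r}")
        self.units_per_year = TIME_UNITS[self.time_unit]
        lo, hi = life_table.age_range(sex)
        max_horizon = (hi + 1 - self.age0) * self.units_per_year
        if horizon is None:
            horizon = max_horizon
        if horizon > max_horizon + 1e-9:
            raise LifeTableCoverageError(
                f"life table for sex={sex} ends at age {hi}; horizon {horizon} "
                f"{self.time_unit} from age {self.age0} needs age "
                f"{self.age0 + horizon / self.units_per_year:.1f}"
            )
        if self.age0 < lo:
            raise LifeTableCoverageError(
                f"life table for sex={sex} starts at age {lo}, age0={self.age0}"
            )
        self.horizon = float(horizon)
        grid = np.linspace(0.0, self.horizon, n_grid)
        excess = np.maximum(0.0, self.population_hazard(grid) - self._inner_hazard(grid))
        dt = grid[1] - grid[0]
        cum = np.concatenate(
            [[0.0], np.cumsum((excess[1:] + excess[:-1]) * 0.5 * dt)]
        )
        self._grid = grid
        self._excess_cumhaz = cum

    def _inner_hazard(self, t):
        h = np.asarray(self.inner.hazard(t), dtype=float)
        return h

    def population_hazard(self, t):
        """Population hazard at model time t, in the model's time unit."""
        t = np.asarray(t, dtype=float)
        ages = self.age0 + t / self.units_per_year
        # clip the right edge of the horizon into the last covered age year
        lo, hi = self.life_table.age_range(self.sex)
        ages = np.minimum(ages, hi + 1 - 1e-9)
        return self.life_table.annual_hazard(ages, self.sex) / self.units_per_year

    def hazard(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        out = np.maximum(self._inner_hazard(t_arr), self.population_hazard(t_arr))
        return float(out[0]) if np.ndim(t) == 0 else out

    def survival(self, t):
        t_arr = np.atleast_1d(np.asarray(t, dtype=float))
        if np.any(t_arr > self.horizon + 1e-9):
            raise OutOfSupportError(
                f"evaluation beyond the mortality-adjustment horizon {self.horizon}"
            )
        excess = np.interp(t_arr, self._grid, self._excess_cumhaz)
        out = np.asarray(self.inner.survival(t_arr)) * np.exp(-excess)
        return float(out[0]) if np.ndim(t) == 0 else out

    def cumulative_hazard(self, t):
        out = -np.log(np.atleast_1d(self.survival(t)))
        return float(out[0]) if np.ndim(t) == 0 else out


@dataclass(frozen=True)
class RMSTResult:
    """Restricted mean survival time: area under S on [0, τ]."""

    tau: float
    value: float
    n_grid: int

    def to_years(self, time_unit: str) -> float:
        """Convert the RMST into life-years given the model's time unit."""
        return self.value / TIME_UNITS[time_unit]


def build_piecewise(
    anchor_source,
    family: str,
    overall_points,
    pi: float | None = None,
    t0: float | None = None,
    time_unit: str = "months",
) -> PiecewiseModel:
    """Join a KM prefix (or bare anchor) to a parametric tail.

    ``anchor_source`` is either a :class:`KMCurve` (then ``t0`` is required
    and the anchor is the KM step value at t0) or an explicit ``(t0, S0)``
    pair. ``overall_points`` are *unconditional* coordinates with time > t0
    and survival < anchor; they are converted to the conditional scale
    ((t − t0, s/anchor)) before solving, so the assembled curve passes through
    them exactly. With ``pi`` set, the tail is a mixture cure model and the
    plateau of the overall curve is anchor·π.
    """
    if isinstance(anchor_source, KMCurve):
        if t0 is None:
            raise ParameterError("t0 is required when anchoring on a KM curve")
        prefix = anchor_source
        anchor = km_survival_at(prefix, t0)
    else:
        t0_src, anchor = anchor_source
        if t0 is None:
            t0 = float(t0_src)
        prefix = None
    t0 = float(t0)
    anchor = float(anchor)
    if t0 < 0 or not (0.0 < anchor <= 1.0):
        raise ParameterError(f"invalid anchor ({t0}, {anchor})")

    pts = [p if isinstance(p, SurvivalPoint) else SurvivalPoint(*p) for p in overall_points]
    for p in pts:
        if p.time <= t0:
            raise PointOrderingError(
                f"point at t={p.time} does not lie beyond the join time t0={t0}"
            )
        if p.survival >= anchor:
            raise PointMonotonicityError(
                f"point survival {p.survival} is not below the anchor {anchor}"
            )
    conditional = [SurvivalPoint(p.time - t0, p.survival / anchor) for p in pts]
    if pi is None:
        res = solve(family, conditional, time_unit=time_unit)
    else:
        res = solve_cure(family, pi, conditional, time_unit=time_unit)
    return PiecewiseModel(
        t0=t0, anchor=anchor, tail=res.model, prefix=prefix, solve_result=res
    )


def evaluate(model, t):
    """Uniform evaluation: survival probability of any model object at t."""
    return model.survival(t)


def apply_background_mortality(
    inner,
    life_table: LifeTable,
    age0: float,
    sex: str,
    time_unit: str | None = None,
    horizon: float | None = None,
) -> MortalityAdjustedModel:
    """Floor the inner model's hazard at the general-population hazard."""
    return MortalityAdjustedModel(
        inner, life_table, age0, sex, time_unit=time_unit, horizon=horizon
    )


def average_models(models, t):
    """Mean survival of the given models at t (arithmetic average)."""
    return ModelAverage(tuple(models)).survival(t)


def rmst(model, tau: float, n_grid: int = 10001) -> RMSTResult:
    """Restricted mean survival time over [0, τ] by trapezoidal quadrature."""
    if tau <= 0:
        raise ParameterError("tau must be positive")
    grid = np.linspace(0.0, float(tau), n_grid)
    S = np.asarray(model.survival(grid), dtype=float)
    value = float(np.trapezoid(S, grid))
    return RMSTResult(tau=float(tau), value=value, n_grid=n_grid)


def hazard_curve(model, grid):
    """Hazard h(t) over a grid of positive times.

    Uses the model's own hazard where available, otherwise central finite
    differences of −ln S with relative step 1e−5·t.
    """
    grid = np.asarray(grid, dtype=float)
    if np.any(grid <= 0):
        raise ParameterError("hazard grid times must be positive")
    if hasattr(model, "hazard"):
        h = np.asarray(model.hazard(grid), dtype=float)
    else:
        eps = 1e-5 * grid
        with np.errstate(divide="ignore"):
            h = (
                np.log(np.asarray(model.survival(grid - eps)))
                - np.log(np.asarray(model.survival(grid + eps)))
            ) / (2.0 * eps)
    return np.column_stack([grid, h])
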