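"""statsmodels-style modelling surface.

:class:`SurvivalInterpolation` is the model object: it is constructed from
the user-specified (time, survival) coordinates plus optional structure (a
cure fraction, a piecewise join), and :meth:`fit` returns a
:class:`SurvivalInterpolationResults` carrying the solved parameters,
plug-back residuals, evaluators, RMST, a summary table, and PSA hanging off
the results.

Example
-------
>>> from interpsurv import SurvivalInterpolation
>>> res = SurvivalInterpolation([(1.46, 0.691), (4.73, 0.101)],
...                             family="weibull", time_unit="years").fit()
>>> round(res.params["shape"], 3), round(res.params["scale"], 3)
(1.552, 2.772)
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .distributions import CureModel, ParametricModel, n_params
from .exceptions import ParameterError
from .extrapolation import PiecewiseModel, build_piecewise, hazard_curve, rmst
from .point_solver import SolveResult, SurvivalPoint, solve, solve_cure
from .survdata import EventData, KMCurve


class SurvivalInterpolation:
    """Parametric survival model specified through interpolation coordinates.

    Parameters
    ----------
    points
        Sequence of (time, survival) coordinates on the *unconditional*
        survival scale — 1 for the exponential family, 2 otherwise.
    family
        One of ``exponential, weibull, loglogistic, lognormal, gompertz``.
    cure_fraction
        Optional mixture-cure plateau π in [0, 1).
    t0, anchor, km
        Optional piecewise join: either an explicit ``(t0, anchor)`` pair or
        a Kaplan-Meier curve (``km``) plus ``t0`` whose step value supplies
        the anchor. Points must then lie beyond t0 and below the anchor.
    time_unit
        days / weeks / months / years.
    """

    def __init__(
        self,
        points,
        family: str = "weibull",
        cure_fraction: float | None = None,
        t0: float | None = None,
        anchor: float | None = None,
        km: KMCurve | None = None,
        time_unit: str = "months",
    ):
        self.points = [
            p if isinstance(p, SurvivalPoint) else SurvivalPoint(*p) for p in points
        ]
        self.family = family
        self.cure_fraction = cure_fraction
        self.t0 = t0
        self.anchor = anchor
        self.km = km
        self.time_unit = time_unit
        if km is not None and t0 is None:
            raise ParameterError("a KM anchor requires t0")
        if anchor is not None and t0 is None:
            raise ParameterError("an explicit anchor requires t0")

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, time_col: str = "time",
                       survival_col: str = "survival", **kwargs):
        """Build from a DataFrame with time and survival columns."""
        pts = list(zip(df[time_col].astype(float), df[survival_col].astype(float)))
        return cls(pts, **kwargs)

    @property
    def piecewise(self) -> bool:
        return self.km is not None or self.t0 is not None

    def fit(self) -> "SurvivalInterpolationResults":
        """Solve the family exactly through the specified coordinates."""
        if self.piecewise:
            anchor_source = self.km if self.km is not None else (self.t0, self.anchor)
            model = build_piecewise(
                anchor_source,
                self.family,
                self.points,
                pi=self.cure_fraction,
                t0=self.t0,
                time_unit=self.time_unit,
            )
            result = model.solve_result
        elif self.cure_fraction is not None:
            result = solve_cure(self.family, self.cure_fraction, self.points,
                                time_unit=self.time_unit)
            model = result.model
        else:
            result = solve(self.family, self.points, time_unit=self.time_unit)
            model = result.model
        return SurvivalInterpolationResults(self, model, result)


class SurvivalInterpolationResults:
    """Solved interpolation: parameters, diagnostics and downstream tools."""

    def __init__(self, spec: SurvivalInterpolation, model, result: SolveResult):
        self.model_spec = spec
        self.model = model
        self.solve_result = result
        base = model
        if isinstance(base, PiecewiseModel):
            base = base.tail
        if isinstance(base, CureModel):
            base = base.base
        self._base = base
        self.params = pd.Series(base.params, index=base.param_names, name=base.family)
        self.residuals = np.asarray(result.residuals)
        self.converged = result.converged
        self.method = result.method

    # -- evaluation --------------------------------------------------------

    def survival(self, t):
        return self.model.survival(t)

    def hazard(self, t):
        return self.model.hazard(t)

    def cumulative_hazard(self, t):
        return self.model.cumulative_hazard(t)

    def hazard_curve(self, grid):
        return hazard_curve(self.model, grid)

    def rmst(self, tau: float, n_grid: int = 10001):
        """Restricted mean survival time over [0, τ]."""
        return rmst(self.model, tau, n_grid=n_grid)

    def psa(self, data: EventData, grid, n: int = 1000, seed=None):
        """Percentile bands from a data-derived variance-covariance.

        Fits this family to ``data`` by maximum likelihood, re-centres the
        covariance on the interpolated parameters, and samples.
        """
        from .psa import fit_mle, psa_bands

        inner = self.model
        if isinstance(inner, PiecewiseModel):
            raise ParameterError(
                "use interpsurv.psa.bootstrap_km_psa for piecewise models"
            )
        fit = fit_mle(self._base.family, data)
        return psa_bands(inner, fit, grid, n=n, seed=seed)

    def plot(self, tmax: float | None = None, ax=None, km: KMCurve | None = None):
        """Survival curve with optional KM overlay; returns the axes."""
        from .plotting import plot_survival

        if tmax is None:
            tmax = 2.0 * max(p.time for p in self.model_spec.points)
        label = self._base.family
        return plot_survival({label: self.model}, tmax, km=km, ax=ax,
                             points=self.model_spec.points)

    def summary(self) -> str:
        """Human-readable parameter and diagnostics table."""
        spec = self.model_spec
        lines = [
            "Survival interpolation results",
            "=" * 46,
            f"family:          {self._base.family}",
            f"time unit:       {spec.time_unit}",
            f"method:          {self.method}",
            f"converged:       {self.converged}",
            f"max residual:    {self.residuals.max():.3e}",
        ]
        if spec.cure_fraction is not None:
            lines.append(f"cure fraction:   {spec.cure_fraction}")
        if isinstance(self.model, PiecewiseModel):
            lines.append(
                f"piecewise join:  t0={self.model.t0}, anchor={self.model.anchor:.6g}"
            )
        lines.append("-" * 46)
        lines.append(f"{'parameter':<14}{'estimate':>16}")
        for name, value in self.params.items():
            lines.append(f"{name:<14}{value:>16.8g}")
        lines.append("-" * 46)
        lines.append("interpolated points (time, survival, residual):")
        for p, r in zip(sorted(spec.points, key=lambda q: q.time), self.residuals):
            lines.append(f"  ({p.time:g}, {p.survival:g})   {r:.2e}")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<SurvivalInterpolationResults {self._base.family} "
            f"params={dict(self.params.round(6))}>"
        )
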