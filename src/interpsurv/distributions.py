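"""Closed-form survival distributions.

Five parametric families are supported — exponential, Weibull, log-logistic,
log-normal and Gompertz — in the parameterisation conventional in survival
extrapolation work (the flexsurv convention):

=============  ==========================  =====================================
family         parameters                  survival function S(t)
=============  ==========================  =====================================
exponential    rate λ > 0                  exp(−λt)
weibull        shape k > 0, scale σ > 0    exp(−(t/σ)^k)
loglogistic    shape k > 0, scale σ > 0    1 / (1 + (t/σ)^k)
lognormal      meanlog μ ∈ ℝ, sdlog σ > 0  1 − Φ((ln t − μ)/σ)
gompertz       shape b ∈ ℝ, rate a > 0     exp(−(a/b)(e^{bt} − 1)); b=0 → e^{−at}
=============  ==========================  =====================================

The Gompertz shape may be negative, in which case the hazard decays
exponentially and the survival curve plateaus at exp(a/b) — an improper
distribution that is nonetheless a legitimate extrapolation shape (a de facto
cured fraction). Mixture cure models are provided separately via
:class:`CureModel`: S(t) = π + (1 − π)·S_base(t).

All evaluators are vectorised over time and return floats for scalar input.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.special import log_ndtr, ndtr, ndtri

from .exceptions import InfeasibleQuantileError, ParameterError

__all__ = [
    "FAMILIES",
    "TIME_UNITS",
    "ParametricModel",
    "CureModel",
    "n_params",
]

#: parameter names per family, in canonical order
FAMILIES: dict[str, tuple[str, ...]] = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "loglogistic": ("shape", "scale"),
    "lognormal": ("meanlog", "sdlog"),
    "gompertz": ("shape", "rate"),
}

#: time units per year, used when converting annual background mortality
TIME_UNITS: dict[str, float] = {
    "years": 1.0,
    "months": 12.0,
    "weeks": 52.18,
    "days": 365.25,
}


def n_params(family: str) -> int:
    """Number of free parameters of a family (1 for exponential, else 2)."""
    try:
        return len(FAMILIES[family])
    except KeyError:
        raise ParameterError(f"unknown family {family!r}; choose from {sorted(FAMILIES)}")


def _as_array(t):
    arr = np.asarray(t, dtype=float)
    return arr, arr.ndim == 0


def _ret(values, scalar):
    return float(values) if scalar else values


@dataclass(frozen=True)
class ParametricModel:
    """A named survival family with a concrete parameter vector.

    Parameters
    ----------
    family
        One of ``exponential, weibull, loglogistic, lognormal, gompertz``.
    params
        Parameter vector in the canonical order of :data:`FAMILIES`.
    time_unit
        Unit of the time axis; only consulted when the model is combined with
        an annual life table.
    """

    family: str
    params: tuple[float, ...]
    time_unit: str = "months"

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ParameterError(
                f"unknown family {self.family!r}; choose from {sorted(FAMILIES)}"
            )
        params = tuple(float(p) for p in np.atleast_1d(self.params))
        object.__setattr__(self, "params", params)
        if len(params) != len(FAMILIES[self.family]):
            raise ParameterError(
                f"{self.family} takes {len(FAMILIES[self.family])} parameters, "
                f"got {len(params)}"
            )
        if not all(np.isfinite(params)):
            raise ParameterError(f"non-finite parameters {params}")
        if self.time_unit not in TIME_UNITS:
            raise ParameterError(
                f"unknown time unit {self.time_unit!r}; choose from {sorted(TIME_UNITS)}"
            )
        f, p = self.family, params
        if f == "exponential" and p[0] <= 0:
            raise ParameterError("exponential rate must be > 0")
        if f in ("weibull", "loglogistic") and (p[0] <= 0 or p[1] <= 0):
            raise ParameterError(f"{f} shape and scale must be > 0")
        if f == "lognormal" and p[1] <= 0:
            raise ParameterError("lognormal sdlog must be > 0")
        if f == "gompertz" and p[1] <= 0:
            raise ParameterError("gompertz rate must be > 0")

    @property
    def param_names(self) -> tuple[str, ...]:
        return FAMILIES[self.family]

    @property
    def param_dict(self) -> dict[str, float]:
        return dict(zip(self.param_names, self.params))

    # -- core evaluators ---------------------------------------------------

    def cumulative_hazard(self, t):
        """H(t) = −ln S(t); H(0) = 0, non-decreasing."""
        t, scalar = _as_array(t)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        f, p = self.family, self.params
        if f == "exponential":
            H = p[0] * t
        elif f == "weibull":
            k, s = p
            with np.errstate(over="ignore"):
                H = (t / s) ** k
        elif f == "loglogistic":
            k, s = p
            with np.errstate(over="ignore"):
                H = np.log1p((t / s) ** k)
        elif f == "lognormal":
            mu, s = p
            with np.errstate(divide="ignore"):
                z = (np.log(t) - mu) / s
            H = -log_ndtr(-z)  # stable far into the right tail
        else:  # gompertz
            b, a = p
            H = a * t if b == 0 else (a / b) * np.expm1(b * t)
        return _ret(H, scalar)

    def survival(self, t):
        """S(t) = exp(−H(t))."""
        t, scalar = _as_array(t)
        return _ret(np.exp(-np.asarray(self.cumulative_hazard(t))), scalar)

    def hazard(self, t):
        """Instantaneous hazard h(t) = −d ln S / dt.

        At t = 0 the mathematical limit is returned where it exists; for
        Weibull/log-logistic with shape < 1 the hazard diverges and ``inf``
        is returned rather than raising.
        """
        t, scalar = _as_array(t)
        if np.any(t < 0):
            raise ValueError("time must be non-negative")
        f, p = self.family, self.params
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            if f == "exponential":
                h = np.full_like(t, p[0])
            elif f == "weibull":
                k, s = p
                h = (k / s) * (t / s) ** (k - 1.0)
            elif f == "loglogistic":
                k, s = p
                x = (t / s) ** k
                h = np.where(
                    np.isinf(x), 0.0, (k / s) * (t / s) ** (k - 1.0) / (1.0 + x)
                )
            elif f == "lognormal":
                mu, s = p
                z = (np.log(t) - mu) / s
                # h = pdf/S via logs: stable where S underflows
                logpdf = -0.5 * z * z - np.log(np.sqrt(2.0 * np.pi) * s * t)
                h = np.exp(logpdf - log_ndtr(-z))
            else:  # gompertz
                b, a = p
                h = a * np.exp(b * t)
        if f == "lognormal":
            h = np.where(t == 0, 0.0, h)
        elif f in ("weibull", "loglogistic"):
            k = p[0]
            if k == 1:
                h = np.where(t == 0, 1.0 / p[1] if f == "weibull" else p[0] / p[1], h)
            else:
                h = np.where(t == 0, 0.0 if k > 1 else np.inf, h)
        return _ret(h, scalar)

    def quantile(self, prob):
        """Invert the survival function: the time t with S(t) = prob.

        ``prob`` is a *survival* probability in (0, 1). A Gompertz model with
        negative shape plateaus at exp(a/b); probabilities at or below the
        plateau are unreachable and raise :class:`InfeasibleQuantileError`.
        """
        prob, scalar = _as_array(prob)
        if np.any((prob <= 0) | (prob >= 1)):
            raise ValueError("survival probability must lie strictly in (0, 1)")
        f, p = self.family, self.params
        H = -np.log(prob)
        if f == "exponential":
            t = H / p[0]
        elif f == "weibull":
            k, s = p
            t = s * H ** (1.0 / k)
        elif f == "loglogistic":
            k, s = p
            t = s * (1.0 / prob - 1.0) ** (1.0 / k)
        elif f == "lognormal":
            mu, s = p
            t = np.exp(mu + s * ndtri(1.0 - prob))
        else:  # gompertz
            b, a = p
            if b == 0:
                t = H / a
            else:
                x = (b / a) * H
                if np.any(x <= -1.0):
                    plateau = np.exp(a / b) if b < 0 else 0.0
                    raise InfeasibleQuantileError(
                        f"survival plateaus at {plateau:.6g}; "
                        f"probability below the plateau is unreachable"
                    )
                t = np.log1p(x) / b
        return _ret(t, scalar)

    @property
    def plateau(self) -> float:
        """Limiting survival as t → ∞ (0 for proper distributions)."""
        if self.family == "gompertz" and self.params[0] < 0:
            b, a = self.params
            return float(np.exp(a / b))
        return 0.0


@dataclass(frozen=True)
class CureModel:
    """Mixture cure model: a fraction ``pi`` is never at risk.

    S(t) = π + (1 − π)·S_base(t), so the curve plateaus at π — the shape seen
    when a subset of patients is effectively cured and the plateau cannot be
    captured by a standard parametric family.
    """

    pi: float
    base: ParametricModel

    def __post_init__(self):
        if not (0.0 <= self.pi < 1.0):
            raise ParameterError("cure fraction must lie in [0, 1)")

    @property
    def family(self) -> str:
        return self.base.family

    @property
    def time_unit(self) -> str:
        return self.base.time_unit

    def survival(self, t):
        t, scalar = _as_array(t)
        S = self.pi + (1.0 - self.pi) * np.asarray(self.base.survival(t))
        return _ret(S, scalar)

    def cumulative_hazard(self, t):
        t, scalar = _as_array(t)
        return _ret(-np.log(self.survival(t)), scalar)

    def hazard(self, t):
        # h = (1−π) f_base / S_cure, with f_base = h_base · S_base
        t, scalar = _as_array(t)
        Sb = np.asarray(self.base.survival(t))
        hb = np.asarray(self.base.hazard(t))
        S = self.pi + (1.0 - self.pi) * Sb
        with np.errstate(invalid="ignore"):
            h = (1.0 - self.pi) * hb * Sb / S
        h = np.where(np.isinf(hb) & (Sb > 0), np.inf, h)
        return _ret(h, scalar)

    def quantile(self, prob):
        prob, scalar = _as_array(prob)
        if np.any(prob <= self.pi):
            raise InfeasibleQuantileError(
                f"survival plateaus at the cure fraction {self.pi}; "
                f"probabilities at or below it are unreachable"
            )
        t = self.base.quantile((prob - self.pi) / (1.0 - self.pi))
        return _ret(np.asarray(t), scalar)

    @property
    def plateau(self) -> float:
        return self.pi + (1.0 - self.pi) * self.base.plateau
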