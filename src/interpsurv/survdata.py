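"""Right-censored event data, Kaplan-Meier curves and life tables.

Event data arrive as delimited text with a time column and an event/censor
status column (1 = event, 0 = censored by default; alternative codings are
mapped explicitly). The Kaplan-Meier product-limit estimate is computed with
lifelines; Greenwood's variance of ln Ŝ and the log(−log)-transformed 95%
pointwise confidence interval are assembled from its event table.

Life tables are long-format delimited text with columns ``age, sex, qx``
holding the annual probability of death q_x; the annual hazard is
−ln(1 − q_x).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from scipy.stats import norm

from .exceptions import (
    DegenerateCurveError,
    LifeTableContinuityError,
    LifeTableCoverageError,
    OutOfSupportError,
    ParameterError,
    SchemaError,
    StatusCodingError,
)

__all__ = [
    "EventData",
    "KMCurve",
    "LifeTable",
    "read_event_data",
    "kaplan_meier",
    "km_survival_at",
    "read_life_table",
]


@dataclass(frozen=True)
class EventData:
    """Right-censored observations: positive times, status 1=event 0=censored."""

    times: np.ndarray
    status: np.ndarray
    time_unit: str = "months"

    def __post_init__(self):
        times = np.asarray(self.times, dtype=float)
        status = np.asarray(self.status, dtype=int)
        if times.shape != status.shape or times.ndim != 1:
            raise ValueError("times and status must be matching 1-d arrays")
        if np.any(times <= 0) or not np.all(np.isfinite(times)):
            raise ValueError("all times must be positive and finite")
        if not np.isin(status, (0, 1)).all():
            raise StatusCodingError("status must be coded 0 (censored) / 1 (event)")
        object.__setattr__(self, "times", times)
        object.__setattr__(self, "status", status)

    def __len__(self) -> int:
        return self.times.size

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.times, "status": self.status})


def read_event_data(
    path,
    time_col: str = "time",
    status_col: str = "status",
    status_map: dict | None = None,
    sep: str = ",",
    time_unit: str = "months",
) -> EventData:
    """Read right-censored event data from delimited text.

    Rows with missing or non-positive times are dropped with a warning
    reporting the count. ``status_map`` translates non-numeric codings, e.g.
    ``{"event": 1, "censored": 0}``.
    """
    df = pd.read_csv(path, sep=sep)
    for col in (time_col, status_col):
        if col not in df.columns:
            raise SchemaError(f"missing column {col!r}; found {list(df.columns)}")
    times = pd.to_numeric(df[time_col], errors="coerce")
    status = df[status_col]
    if status_map is not None:
        status = status.map(status_map)
    status = pd.to_numeric(status, errors="coerce")
    bad = times.isna() | (times <= 0)
    if bad.any():
        warnings.warn(
            f"dropped {int(bad.sum())} row(s) with missing or non-positive time",
            stacklevel=2,
        )
        times, status = times[~bad], status[~bad]
    if status.isna().any() or not status.isin((0, 1)).all():
        raise StatusCodingError(
            "status column could not be coerced to {0, 1}; supply status_map"
        )
    return EventData(times.to_numpy(float), status.to_numpy(int), time_unit=time_unit)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate with Greenwood uncertainty.

    ``times``/``survival`` describe the right-continuous step function just
    after each event time; ``greenwood_var`` is the cumulative Greenwood sum
    Σ d_i / (n_i (n_i − d_i)), i.e. the variance of ln Ŝ.
    """

    times: np.ndarray          # event times (steps)
    survival: np.ndarray       # Ŝ just after each step
    at_risk: np.ndarray
    events: np.ndarray
    greenwood_var: np.ndarray
    ci_lower: np.ndarray
    ci_upper: np.ndarray
    last_follow_up: float
    n: int

    @property
    def median(self) -> float:
        """Smallest time at which Ŝ drops to 0.5 or below (nan if never)."""
        idx = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[idx[0]]) if idx.size else float("nan")


def kaplan_meier(data: EventData, alpha: float = 0.05) -> KMCurve:
    """Product-limit estimate Ŝ(t) = Π_{t_i ≤ t} (1 − d_i/n_i).

    The pointwise CI uses the log(−log Ŝ) transformation, which keeps the
    interval inside [0, 1]. Raises :class:`DegenerateCurveError` when the data
    contain no events at all.
    """
    if data.n_events == 0:
        raise DegenerateCurveError("Kaplan-Meier estimation requires at least one event")
    kmf = KaplanMeierFitter().fit(data.times, data.status)
    tab = kmf.event_table
    ev = tab[tab["observed"] > 0]
    times = ev.index.to_numpy(float)
    d = ev["observed"].to_numpy(float)
    n = ev["at_risk"].to_numpy(float)
    surv = kmf.survival_function_at_times(times).to_numpy(float)
    with np.errstate(divide="ignore", invalid="ignore"):
        terms = np.where(n > d, d / (n * (n - d)), np.inf)
    gw = np.cumsum(terms)
    z = norm.ppf(1.0 - alpha / 2.0)
    with np.errstate(divide="ignore", invalid="ignore"):
        logH = np.log(-np.log(surv))
        se_logH = np.sqrt(gw) / np.abs(np.log(surv))
        lower = surv ** np.exp(z * se_logH)
        upper = surv ** np.exp(-z * se_logH)
    lower = np.where(surv == 0.0, 0.0, lower)
    upper = np.where(surv == 0.0, 0.0, upper)
    return KMCurve(
        times=times,
        survival=surv,
        at_risk=n.astype(int),
        events=d.astype(int),
        greenwood_var=gw,
        ci_lower=lower,
        ci_upper=upper,
        last_follow_up=float(data.times.max()),
        n=len(data),
    )


def km_survival_at(curve: KMCurve, t: float) -> float:
    """Right-continuous step-function value Ŝ(t); 1 before the first event.

    Raises :class:`OutOfSupportError` beyond the last observed follow-up.
    """
    t = float(t)
    if t < 0:
        raise ValueError("time must be non-negative")
    if t > curve.last_follow_up:
        raise OutOfSupportError(
            f"t={t} exceeds the last observed follow-up {curve.last_follow_up}"
        )
    idx = np.searchsorted(curve.times, t, side="right")
    return 1.0 if idx == 0 else float(curve.survival[idx - 1])


@dataclass(frozen=True)
class LifeTable:
    """Age- and sex-specific annual mortality, q_x per whole year of age."""

    table: pd.DataFrame  # columns: age, sex, qx, hazard

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LifeTable":
        for col in ("age", "sex", "qx"):
            if col not in df.columns:
                raise SchemaError(f"life table missing column {col!r}")
        df = df[["age", "sex", "qx"]].copy()
        df["age"] = df["age"].astype(int)
        if np.any((df["qx"] < 0) | (df["qx"] >= 1)):
            raise ParameterError("q_x must lie in [0, 1)")
        bad_sex = set(df["sex"].unique()) - {"female", "male"}
        if bad_sex:
            raise SchemaError(f"unknown sex value(s) {sorted(bad_sex)}")
        for sex, grp in df.groupby("sex"):
            ages = np.sort(grp["age"].to_numpy())
            if np.any(np.diff(ages) != 1):
                gap = ages[np.nonzero(np.diff(ages) != 1)[0][0]] + 1
                raise LifeTableContinuityError(
                    f"life table for sex={sex} is missing age {gap}"
                )
        df["hazard"] = -np.log1p(-df["qx"])  # annual hazard
        return cls(df.sort_values(["sex", "age"]).reset_index(drop=True))

    def age_range(self, sex: str) -> tuple[int, int]:
        grp = self.table[self.table["sex"] == sex]
        if grp.empty:
            raise SchemaError(f"life table has no rows for sex={sex!r}")
        return int(grp["age"].min()), int(grp["age"].max())

    def annual_hazard(self, age, sex: str):
        """Annual hazard −ln(1 − q_x) at (possibly fractional) age, floor'd
        to whole years; vectorised over age."""
        age = np.asarray(age, dtype=float)
        lo, hi = self.age_range(sex)
        floored = np.floor(age).astype(int)
        if np.any(floored < lo) or np.any(floored > hi):
            raise LifeTableCoverageError(
                f"life table for sex={sex} covers ages {lo}-{hi}, "
                f"requested {floored.min()}-{floored.max()}"
            )
        grp = self.table[self.table["sex"] == sex].set_index("age")["hazard"]
        return grp.to_numpy()[floored - lo]


def read_life_table(path, sep: str = ",") -> LifeTable:
    """Read a long-format life table (columns ``age, sex, qx``) from text."""
    return LifeTable.from_frame(pd.read_csv(path, sep=sep))
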