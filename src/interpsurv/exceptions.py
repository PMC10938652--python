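"""Exception hierarchy.

Everything raised deliberately by this package derives from
:class:`InterpSurvError`, so callers (and the CLI) can separate usage and
feasibility problems from genuine bugs.
"""


class InterpSurvError(Exception):
    """Base class for all errors raised by interpsurv."""


class ParameterError(InterpSurvError, ValueError):
    """A distribution parameter vector violates its domain constraints."""


class InfeasibleQuantileError(InterpSurvError, ValueError):
    """Requested survival level lies below an achievable plateau."""


class PointsError(InterpSurvError, ValueError):
    """Base class for invalid interpolation-point sets."""


class PointCountError(PointsError):
    """Wrong number of interpolation points for the family."""


class PointTieError(PointsError):
    """Two interpolation points share the same time."""


class PointMonotonicityError(PointsError):
    """Survival probabilities are not strictly decreasing in time."""


class PointDomainError(PointsError):
    """A coordinate lies outside t > 0, 0 < s < 1."""


class PointOrderingError(PointsError):
    """A piecewise interpolation point does not lie beyond the join time."""


class InfeasiblePointsError(InterpSurvError, ValueError):
    """No parameter vector of the family passes through the given points."""


class CureInfeasibleError(InfeasiblePointsError):
    """An interpolation point lies at or below the cure fraction."""


class NonConvergenceError(InterpSurvError, RuntimeError):
    """A root search or optimiser failed to converge."""


class SchemaError(InterpSurvError, ValueError):
    """Delimited input is missing required columns."""


class StatusCodingError(InterpSurvError, ValueError):
    """Event/censor status values could not be mapped to {0, 1}."""


class DegenerateCurveError(InterpSurvError, ValueError):
    """Kaplan-Meier estimation attempted with zero events."""


class OutOfSupportError(InterpSurvError, ValueError):
    """Evaluation requested beyond the observed follow-up."""


class LifeTableContinuityError(InterpSurvError, ValueError):
    """Ages in a life table are not contiguous within sex."""


class LifeTableCoverageError(InterpSurvError, ValueError):
    """A life table does not cover the ages required by the horizon."""


class OptimizationError(NonConvergenceError):
    """Maximum-likelihood optimisation failed."""


class CovarianceError(InterpSurvError, RuntimeError):
    """Observed information matrix is singular or not finite."""
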