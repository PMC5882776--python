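"""Logistic reduction/accumulation kinetics.

Cumulative anaerobic reduction processes — Fe(II) accumulation, sulfate or
PCP decrement — are well described by the three-parameter logistic

    C(t) = a / (1 + b * exp(-k * t))

where ``a`` is the maximum capacity of the process (same unit as the
series), ``b`` a dimensionless regression coefficient locating the curve in
time, and ``k`` the first-order rate constant (d^-1).  Two derived
statistics summarise each fit: the maximum instantaneous rate

    Vmax = 0.25 * a * k        (unit of the series per day)

attained at the inflection point

    t_Vmax = ln(b) / k         (days),

where the curve passes through ``a / 2``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from pcpredox.errors import (
    DataConsistencyError,
    DegenerateInputError,
    InsufficientDataError,
    InvalidParameterError,
)

__all__ = [
    "TimeSeries",
    "LogisticParams",
    "LogisticFitResult",
    "logistic_value",
    "to_decrement",
    "fit_logistic",
    "vmax",
    "t_vmax",
    "r_squared",
]

#: analytes whose raw concentrations decrease and are fitted as decrement
DECREASING_ANALYTES = frozenset({"nitrate", "sulfate", "pcp"})


@dataclass(frozen=True)
class TimeSeries:
    """One analyte's concentration trajectory for one treatment/replicate.

    Parameters
    ----------
    treatment_id
        Label of the microcosm treatment (e.g. ``"control"``).
    analyte
        ``"nitrate"``, ``"sulfate"``, ``"fe2"``, ``"pcp"`` or a congener
        name such as ``"3,5-DCP"``.
    times
        Sampling times in days, strictly increasing, >= 0.
    values
        Concentrations, same length as ``times``; mM for nitrate/sulfate/
        Fe(II), µM for chlorophenols.
    replicate
        Replicate label, or ``"mean"`` for replicate-averaged series.
    unit
        Concentration unit string carried through I/O.
    """

    treatment_id: str
    analyte: str
    times: np.ndarray
    values: np.ndarray
    replicate: str = "mean"
    unit: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        v = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "times", t)
        object.__setattr__(self, "values", v)
        if t.ndim != 1 or v.ndim != 1 or len(t) != len(v):
            raise InvalidParameterError(
                "times and values must be 1-D and of equal length"
            )
        if len(t) and t[0] < 0:
            raise InvalidParameterError("times must be >= 0")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise InvalidParameterError("times must be strictly increasing")
        if not np.all(np.isfinite(v)) or np.any(v < 0):
            raise InvalidParameterError("values must be finite and >= 0")

    def __len__(self) -> int:
        return len(self.times)

    def with_values(self, values: np.ndarray) -> "TimeSeries":
        return TimeSeries(
            self.treatment_id, self.analyte, self.times, values,
            self.replicate, self.unit,
        )


@dataclass(frozen=True)
class LogisticParams:
    """Parameters (a, b, k) of the logistic ``a / (1 + b e^{-kt})``."""

    a: float
    b: float
    k: float

    def __post_init__(self) -> None:
        for name in ("a", "b", "k"):
            x = getattr(self, name)
            if not (math.isfinite(x) and x > 0):
                raise InvalidParameterError(
                    f"logistic parameter {name} must be finite and > 0, got {x!r}"
                )


@dataclass(frozen=True)
class LogisticFitResult:
    """A fitted logistic together with its derived rate statistics."""

    params: LogisticParams
    vmax: float
    t_vmax: float
    r2: float
    n_points: int
    converged: bool
    residuals: np.ndarray = field(repr=False, default=None)


def logistic_value(params: LogisticParams, t) -> float | np.ndarray:
    """Evaluate ``a / (1 + b * exp(-k t))`` at time(s) ``t`` (days).

    Strictly increasing in ``t`` and bounded in (0, a).
    """
    t = np.asarray(t, dtype=float)
    if not np.all(np.isfinite(t)):
        raise InvalidParameterError("t must be finite")
    out = params.a / (1.0 + params.b * np.exp(-params.k * t))
    return out if out.ndim else float(out)


def vmax(params: LogisticParams) -> float:
    """Maximum instantaneous rate of the logistic, ``0.25 * a * k``.

    This is the analytic maximum of dC/dt, attained at the inflection
    point ``t_vmax``.
    """
    return 0.25 * params.a * params.k


def t_vmax(params: LogisticParams) -> float:
    """Time of the maximum rate, ``ln(b) / k`` (days).

    At this time the curve passes through ``a / 2`` (the inflection).
    """
    return math.log(params.b) / params.k


def r_squared(observed, predicted) -> float:
    """Coefficient of determination ``1 - SS_res / SS_tot``."""
    obs = np.asarray(observed, dtype=float)
    pred = np.asarray(predicted, dtype=float)
    if obs.shape != pred.shape or obs.ndim != 1 or len(obs) < 2:
        raise InvalidParameterError(
            "observed and predicted must be equal-length 1-D arrays of >= 2"
        )
    ss_tot = float(np.sum((obs - obs.mean()) ** 2))
    if ss_tot == 0.0:
        raise DegenerateInputError("R^2 undefined for a constant observed series")
    ss_res = float(np.sum((obs - pred) ** 2))
    return 1.0 - ss_res / ss_tot


def to_decrement(
    series: TimeSeries,
    baseline: float | None = None,
    *,
    accumulation: bool = False,
    tolerance_frac: float = 0.02,
) -> TimeSeries:
    """Convert a decreasing concentration series to cumulative decrement.

    The logistic is fitted to *cumulative* quantities: accumulated Fe(II)
    passes through unchanged (``accumulation=True``) while decreasing
    analytes (sulfate, PCP, nitrate) are transformed to
    ``baseline - value``.

    Parameters
    ----------
    baseline
        Initial pool against which the decrement is measured.  Defaults
        to the value at the earliest time point.
    accumulation
        If True the series is already cumulative; it is returned as-is.
    tolerance_frac
        Values exceeding the baseline by up to this fraction of the
        baseline (measurement jitter) are clipped to zero decrement;
        larger excursions raise :class:`DataConsistencyError`.
    """
    if accumulation:
        return series
    if len(series) == 0:
        raise InsufficientDataError("empty series")
    base = float(series.values[0]) if baseline is None else float(baseline)
    if base < 0:
        raise InvalidParameterError("baseline must be >= 0")
    dec = base - series.values
    tol = tolerance_frac * base
    if np.any(dec < -tol):
        worst = float(dec.min())
        raise DataConsistencyError(
            f"value exceeds baseline {base:g} by {-worst:g} "
            f"(tolerance {tol:g}); check units or baseline"
        )
    return series.with_values(np.clip(dec, 0.0, None))


def _initial_guesses(t: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Deterministic starting points for the logistic fit.

    The primary guess sets a0 slightly above the observed maximum, k0
    from the slope of the log-linearised (logit) interior segment, and b0
    from the half-maximum crossing time t50 so that the candidate curve
    passes through a0/2 there (b0 = exp(k0 * t50)).  A few fallback
    starts guard against local minima on steep or lag-dominated curves.
    """
    ymax = float(y.max())
    a0 = ymax * 1.05
    span = max(float(t[-1] - t[0]), 1.0)
    # logit-slope estimate of k on the interior of the curve
    interior = (y > 0.05 * a0) & (y < 0.95 * a0)
    if interior.sum() >= 2:
        z = np.log(y[interior] / (a0 - y[interior]))
        k0 = float(np.polyfit(t[interior], z, 1)[0])
    else:
        k0 = 1.0 / span
    k0 = min(max(k0, 1e-3), 10.0)
    # half-maximum crossing time by linear interpolation
    above = np.nonzero(y >= 0.5 * a0)[0]
    if len(above) and above[0] > 0:
        i = above[0]
        frac = (0.5 * a0 - y[i - 1]) / max(y[i] - y[i - 1], 1e-30)
        t50 = float(t[i - 1] + frac * (t[i] - t[i - 1]))
    elif len(above):
        t50 = float(t[0])
    else:
        t50 = float(t[-1])
    guesses = [(a0, math.exp(min(k * t50, 500.0)), k) for k in (k0, 0.5 * k0, 2.0 * k0)]
    y0 = max(float(y[0]), 1e-6 * a0)
    guesses.append((a0, max(a0 / y0 - 1.0, 1e-6), k0))
    return guesses


def fit_logistic(
    series: TimeSeries,
    *,
    p0: tuple[float, float, float] | None = None,
    max_nfev: int = 10_000,
) -> LogisticFitResult:
    """Fit the 3-parameter logistic to a cumulative time series.

    Bounded trust-region nonlinear least squares with positivity
    constraints on all three parameters.  The series must already be
    cumulative (apply :func:`to_decrement` to decreasing analytes first).

    Raises
    ------
    InsufficientDataError
        Fewer than 4 distinct time points.
    DegenerateInputError
        Constant values (no signal to fit).
    """
    t = series.times
    y = series.values
    if len(np.unique(t)) < 4:
        raise InsufficientDataError(
            f"logistic fit needs >= 4 distinct time points, got {len(np.unique(t))}"
        )
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("cannot fit a logistic to a constant series")

    guesses = _initial_guesses(t, y) if p0 is None else [tuple(p0)]

    def resid(theta):
        a, b, k = theta
        return a / (1.0 + b * np.exp(-k * t)) - y

    sol = None
    for guess in guesses:
        cand = least_squares(
            resid,
            x0=np.asarray(guess, dtype=float),
            bounds=(np.full(3, 1e-12), np.full(3, np.inf)),
            method="trf",
            xtol=1e-10,
            ftol=1e-10,
            gtol=1e-10,
            max_nfev=max_nfev,
        )
        if sol is None or cand.cost < sol.cost:
            sol = cand
    a, b, k = map(float, sol.x)
    params = LogisticParams(a=a, b=b, k=k)
    pred = logistic_value(params, t)
    return LogisticFitResult(
        params=params,
        vmax=vmax(params),
        t_vmax=t_vmax(params),
        r2=r_squared(y, pred),
        n_points=len(t),
        converged=bool(sol.success),
        residuals=np.asarray(sol.fun),
    )
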