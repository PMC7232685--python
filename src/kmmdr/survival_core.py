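"""Nonparametric survival primitives.

Kaplan-Meier product-limit estimation, the KM median survival time, and the
two-sample log-rank statistic, in exactly the form consumed by the
high/low-risk classifiers and the interaction-search scores: the log-rank
statistic is the standardized form Z = Σ(d_1i − E_1i)/√(ΣV_i) whose square
is chi-square(1) under the null, and the KM median is the smallest event
time t with Ŝ(t) ≤ 0.5 (the boundary case Ŝ(t) = 0.5 defines the median at
that time).

Conventions (all standard): censored observations reduce the risk set
without a survival step; at tied times, events precede censoring; event
times where only one subject is at risk contribute zero log-rank variance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import _kernels
from .errors import DegenerateGroupError, InvalidInputError, UndefinedStatisticError

__all__ = [
    "NOT_ESTIMABLE",
    "SurvivalSample",
    "KMCurve",
    "LogRankResult",
    "is_estimable",
    "km_estimate",
    "km_median",
    "log_rank",
]

#: Sentinel for a median survival time that the KM curve never reaches
#: (heavy censoring / cure fraction).  Compare with :func:`is_estimable`.
NOT_ESTIMABLE: float = math.nan


def is_estimable(median: float) -> bool:
    """True when ``median`` is an actual time, not the NOT_ESTIMABLE sentinel."""
    return not math.isnan(median)


@dataclass(frozen=True)
class SurvivalSample:
    """Right-censored survival data for n subjects.

    Parameters
    ----------
    time : array of non-negative observed times (event or censoring).
    status : array of event indicators; 1 = event observed, 0 = censored.
    covariates : optional (n, m) array of adjusting covariates (z).
    """

    time: np.ndarray
    status: np.ndarray
    covariates: np.ndarray | None = None

    def __post_init__(self):
        time = np.asarray(self.time, dtype=np.float64)
        status = np.asarray(self.status)
        if time.ndim != 1 or status.ndim != 1 or time.shape != status.shape:
            raise InvalidInputError("time and status must be 1-d arrays of equal length")
        if time.shape[0] < 1:
            raise InvalidInputError("survival sample must contain at least one subject")
        if np.any(time < 0) or np.any(np.isnan(time)):
            raise InvalidInputError("every time must be a non-negative real number")
        if not np.isin(status, (0, 1)).all():
            raise InvalidInputError("every status must be 0 (censored) or 1 (event)")
        object.__setattr__(self, "time", time)
        object.__setattr__(self, "status", status.astype(np.int8))
        if self.covariates is not None:
            cov = np.atleast_2d(np.asarray(self.covariates, dtype=np.float64))
            if cov.shape[0] == 1 and time.shape[0] != 1:
                cov = cov.T
            if cov.shape[0] != time.shape[0]:
                raise InvalidInputError("covariate matrix must have one row per subject")
            object.__setattr__(self, "covariates", cov)

    @property
    def n(self) -> int:
        return self.time.shape[0]

    @property
    def n_events(self) -> int:
        return int(self.status.sum())

    def sorted_arrays(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(order, time, status) sorted by time, events first at ties."""
        order = _kernels.sort_order(self.time, self.status)
        return order, self.time[order], self.status[order]

    def subset(self, index: np.ndarray) -> "SurvivalSample":
        cov = None if self.covariates is None else self.covariates[index]
        return SurvivalSample(self.time[index], self.status[index], cov)


@dataclass(frozen=True)
class KMCurve:
    """Kaplan-Meier product-limit estimate over distinct event times."""

    event_times: np.ndarray  # strictly increasing distinct event times
    at_risk: np.ndarray      # n_i at each event time
    events: np.ndarray       # d_i at each event time
    survival: np.ndarray     # Ŝ(t_i) at each event time

    @property
    def d(self) -> int:
        """Number of distinct event times."""
        return self.event_times.shape[0]

    def survival_at(self, t: float) -> float:
        """Step-function value Ŝ(t); 1.0 before the first event."""
        i = np.searchsorted(self.event_times, t, side="right")
        return 1.0 if i == 0 else float(self.survival[i - 1])


@dataclass(frozen=True)
class LogRankResult:
    """Two-sample log-rank statistic and its per-event-time decomposition."""

    statistic: float               # Z
    score: float                   # Z², the search engine's model score
    observed_minus_expected: float  # Σ(d_1i − E_1i)
    variance: float                # ΣV_i
    per_time_terms: pd.DataFrame = field(repr=False)


def km_estimate(sample: SurvivalSample) -> KMCurve:
    """Kaplan-Meier product-limit estimate Ŝ(t) = Π_{i: t_i ≤ t} (1 − d_i/n_i).

    A sample with no events yields an empty curve (Ŝ ≡ 1 everywhere).
    """
    _, t, s = sample.sorted_arrays()
    et, nr, d, sv = _kernels.km_curve_sorted(t, s)
    return KMCurve(event_times=et, at_risk=nr, events=d, survival=sv)


def km_median(curve: KMCurve) -> float:
    """Smallest event time t with Ŝ(t) ≤ 0.5; NOT_ESTIMABLE if never reached."""
    hit = np.flatnonzero(curve.survival <= _kernels._HALF_TOL)
    if hit.size == 0:
        return NOT_ESTIMABLE
    return float(curve.event_times[hit[0]])


def log_rank(sample: SurvivalSample, group: np.ndarray) -> LogRankResult:
    """Two-sample log-rank test between ``group == 1`` and ``group == 0``.

    Z = Σ(d_1i − E_1i) / √(ΣV_i) over distinct event times, with
    E_1i = d_i n_1i / n_i and V_i = (n_i − d_i) d_i n_1i n_2i / ((n_i − 1) n_i²).

    Raises
    ------
    DegenerateGroupError
        If either group is empty.
    UndefinedStatisticError
        If there are no events or the variance sum is zero.
    """
    group = np.asarray(group).astype(bool)
    if group.shape[0] != sample.n:
        raise InvalidInputError("group labels must align with the sample")
    n1 = int(group.sum())
    if n1 == 0 or n1 == sample.n:
        raise DegenerateGroupError("both groups must be non-empty")
    order, t, s = sample.sorted_arrays()
    g = group[order]

    z, o_minus_e, var = _kernels.logrank_sorted(t, s, g)
    if not np.isfinite(var) or var <= 0.0:
        raise UndefinedStatisticError(
            "log-rank statistic undefined: zero variance (no informative event times)"
        )
    terms = _per_time_terms(t, s, g)
    return LogRankResult(
        statistic=float(z),
        score=float(z * z),
        observed_minus_expected=o_minus_e,
        variance=var,
        per_time_terms=terms,
    )


def _per_time_terms(t: np.ndarray, s: np.ndarray, g: np.ndarray) -> pd.DataFrame:
    """Per-event-time (t_i, d_1i, d_2i, n_1i, n_2i, E_1i, V_i) table."""
    n = t.shape[0]
    rows = []
    i = 0
    while i < n:
        j = i
        while j < n and t[j] == t[i]:
            j += 1
        d1 = int(np.sum(s[i:j] & g[i:j]))
        d2 = int(np.sum(s[i:j] & ~g[i:j]))
        d = d1 + d2
        if d > 0:
            nr = n - i
            n1 = int(np.sum(g[i:]))
            n2 = nr - n1
            e1 = d * n1 / nr
            v = 0.0 if nr <= 1 else (nr - d) * d * n1 * n2 / ((nr - 1) * nr * nr)
            rows.append((t[i], d1, d2, n1, n2, e1, v))
        i = j
    return pd.DataFrame(
        rows, columns=["time", "d1", "d2", "n1", "n2", "expected1", "variance"]
    )
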