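"""Low-level Kaplan-Meier / log-rank kernels on pre-sorted arrays.

The exhaustive interaction search evaluates tens of thousands of small
survival statistics per dataset, so these kernels avoid all object
construction.  Every function here assumes its inputs are already sorted by
time ascending with, at tied times, events (status 1) preceding censored
observations (status 0).  Under that ordering the at-risk count at
observation i is simply n - i, and a cumulative product over individual
events reproduces the tied product-limit factor (n_i - d_i)/n_i exactly.

Not-estimable medians and undefined log-rank statistics are signalled with
NaN rather than exceptions; the public wrappers in ``survival_core`` turn
them back into typed errors where the contract requires one.
"""

from __future__ import annotations

import numpy as np

# slack for "Ŝ(t) ≤ 0.5": the survival estimate is a product of rationals
# evaluated in floating point, and the median rule's boundary case (Ŝ hits
# one half exactly) must not be lost to rounding.
_HALF_TOL = 0.5 + 1e-12


def sort_order(time: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Indices sorting by time ascending, events before censored at ties."""
    return np.lexsort((-status, time))


def km_median_sorted(time: np.ndarray, status: np.ndarray) -> float:
    """Kaplan-Meier median of a sorted sample; NaN when not estimable.

    The median is the smallest event time t with Ŝ(t) ≤ 0.5, where
    Ŝ(t) = Π_{i: t_i ≤ t} (1 - d_i/n_i) over distinct event times.
    """
    n = time.shape[0]
    if n == 0:
        return np.nan
    ev = status != 0
    if not ev.any():
        return np.nan
    at_risk = n - np.arange(n, dtype=np.float64)
    factors = np.ones(n)
    factors[ev] = 1.0 - 1.0 / at_risk[ev]
    surv = np.cumprod(factors)
    hit = np.flatnonzero(ev & (surv <= _HALF_TOL))
    if hit.size == 0:
        return np.nan
    return float(time[hit[0]])


def km_curve_sorted(time: np.ndarray, status: np.ndarray):
    """(event_times, at_risk, events, survival) over distinct event times."""
    n = time.shape[0]
    ev = status != 0
    if not ev.any():
        z = np.empty(0)
        return z, z.astype(np.int64), z.astype(np.int64), z
    at_risk = n - np.arange(n, dtype=np.float64)
    factors = np.ones(n)
    factors[ev] = 1.0 - 1.0 / at_risk[ev]
    surv = np.cumprod(factors)

    ev_idx = np.flatnonzero(ev)
    ev_times = time[ev_idx]
    # last event index within each block of tied event times
    last = np.empty(ev_idx.size, dtype=bool)
    last[:-1] = ev_times[1:] != ev_times[:-1]
    last[-1] = True
    first = np.empty_like(last)
    first[0] = True
    first[1:] = last[:-1]

    t_out = ev_times[last]
    n_out = (n - ev_idx[first]).astype(np.int64)
    # events per distinct time: difference of cumulative event counts
    cum = np.cumsum(ev.astype(np.int64))
    d_out = cum[ev_idx[last]] - (cum[ev_idx[first]] - 1)
    s_out = surv[ev_idx[last]]
    return t_out, n_out, d_out, s_out


def logrank_sorted(
    time: np.ndarray, status: np.ndarray, group1: np.ndarray
) -> tuple[float, float, float]:
    """Two-sample log-rank on a sorted sample.

    ``group1`` is a boolean membership vector for the first group.  Returns
    (Z, sum(O - E), sum V); Z is NaN when the variance sum is zero or a
    group is empty.  Z = Σ(d_1i − E_1i)/√(ΣV_i) with the hypergeometric
    moments E_1i = d_i n_1i / n_i and
    V_i = (n_i − d_i) d_i n_1i n_2i / ((n_i − 1) n_i²); event times with
    n_i = 1 contribute zero variance.
    """
    n = time.shape[0]
    n1_total = int(group1.sum())
    if n1_total == 0 or n1_total == n:
        return np.nan, np.nan, np.nan

    new_block = np.empty(n, dtype=bool)
    new_block[0] = True
    np.not_equal(time[1:], time[:-1], out=new_block[1:])
    starts = np.flatnonzero(new_block)

    s64 = status.astype(np.int64, copy=False)
    g64 = group1.astype(np.int64, copy=False)
    cs = np.concatenate(([0], np.cumsum(s64)))
    cs1 = np.concatenate(([0], np.cumsum(s64 * g64)))
    cg = np.concatenate(([0], np.cumsum(g64)))

    ends = np.concatenate((starts[1:], [n]))
    d = (cs[ends] - cs[starts]).astype(np.float64)
    keep = d > 0
    if not keep.any():
        return np.nan, 0.0, 0.0
    d = d[keep]
    starts = starts[keep]
    ends = ends[keep]
    d1 = (cs1[ends] - cs1[starts]).astype(np.float64)
    nr = (n - starts).astype(np.float64)
    n1 = (n1_total - cg[starts]).astype(np.float64)
    n2 = nr - n1

    e1 = d * n1 / nr
    with np.errstate(divide="ignore", invalid="ignore"):
        v = (nr - d) * d * n1 * n2 / ((nr - 1.0) * nr * nr)
    v[nr <= 1.0] = 0.0

    o_minus_e = float(np.sum(d1 - e1))
    var = float(np.sum(v))
    if var <= 0.0:
        return np.nan, o_minus_e, var
    return o_minus_e / np.sqrt(var), o_minus_e, var


def logrank_score_sorted(
    time: np.ndarray, status: np.ndarray, group1: np.ndarray
) -> float:
    """Squared log-rank statistic Z²; 0.0 when Z is undefined.

    The search engine ranks candidate models by this score, where a
    degenerate high/low split (empty group, no variance) carries no
    evidence of association and scores zero.
    """
    z, _, _ = logrank_sorted(time, status, group1)
    if np.isnan(z):
        return 0.0
    return float(z * z)


def nelson_aalen_at_times_sorted(time: np.ndarray, status: np.ndarray) -> np.ndarray:
    """Nelson-Aalen cumulative hazard Λ̂ evaluated at each subject's own time.

    Sorted-input convention as above.  Returns Λ̂(t_i) per subject, where the
    estimate includes all events at times ≤ t_i (a subject censored at an
    event time is evaluated after the deaths at that time).
    """
    n = time.shape[0]
    ev = status != 0
    at_risk = n - np.arange(n, dtype=np.float64)
    increments = np.zeros(n)
    increments[ev] = 1.0 / at_risk[ev]
    cumhaz = np.cumsum(increments)
    # propagate the end-of-block value backwards across tied times so that
    # every subject at time t sees the full hazard mass at t
    last = np.empty(n, dtype=bool)
    last[:-1] = time[1:] != time[:-1]
    last[-1] = True
    last_idx = np.flatnonzero(last)
    return cumhaz[last_idx[np.searchsorted(last_idx, np.arange(n))]]
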