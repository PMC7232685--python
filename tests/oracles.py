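"""Independently coded brute-force survival statistics for cross-checking.

These deliberately avoid the package's sorted-array kernels: they loop over
the set of distinct event times and build every risk set from scratch, so
agreement with the package is a genuine dual-route check.
"""

import numpy as np


def brute_km_median(time, status):
    """Median by direct application of the product-limit step rule."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    surv = 1.0
    for t in sorted(set(time[status == 1])):
        at_risk = int(np.sum(time >= t))  # censored at t remain at risk
        deaths = int(np.sum((time == t) & (status == 1)))
        surv *= 1.0 - deaths / at_risk
        if surv <= 0.5 + 1e-12:
            return t
    return None


def brute_logrank(time, status, group1):
    """(Z, sum O−E, sum V) by per-event-time risk-set enumeration."""
    time = np.asarray(time, dtype=float)
    status = np.asarray(status, dtype=int)
    group1 = np.asarray(group1, dtype=bool)
    o_minus_e = 0.0
    var = 0.0
    for t in sorted(set(time[status == 1])):
        at_risk = time >= t
        n = int(at_risk.sum())
        n1 = int((at_risk & group1).sum())
        n2 = n - n1
        d = int(((time == t) & (status == 1)).sum())
        d1 = int(((time == t) & (status == 1) & group1).sum())
        o_minus_e += d1 - d * n1 / n
        if n > 1:
            var += (n - d) * d * n1 * n2 / ((n - 1) * n * n)
    if var <= 0:
        return np.nan, o_minus_e, var
    return o_minus_e / np.sqrt(var), o_minus_e, var
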