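"""Independent brute-force reference implementations used as test oracles.

Each function here is written from the textbook definition with plain
Python loops, deliberately sharing no code path with the package.
"""

from __future__ import annotations

import math

import numpy as np
from scipy import stats


def pearson_brute(x, y):
    """Definitional Pearson r and two-sided t-approximation p."""
    x = [float(v) for v in x]
    y = [float(v) for v in y]
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    sxy = sum((a - mx) * (b - my) for a, b in zip(x, y))
    sxx = sum((a - mx) ** 2 for a in x)
    syy = sum((b - my) ** 2 for b in y)
    r = sxy / math.sqrt(sxx * syy)
    r = max(-1.0, min(1.0, r))
    if abs(r) == 1.0:
        return r, 0.0
    t = r * math.sqrt((n - 2) / (1 - r * r))
    p = 2 * stats.t.sf(abs(t), df=n - 2)
    return r, float(p)


def bh_step_up_rejections(p, alpha):
    """Index set rejected by the BH step-up procedure at level alpha.

    Exact rational arithmetic so threshold comparisons carry no rounding.
    """
    from fractions import Fraction

    p = [Fraction(v) for v in p]
    alpha = Fraction(alpha)
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    k_max = 0
    for rank, idx in enumerate(order, start=1):
        if p[idx] <= Fraction(rank, m) * alpha:
            k_max = rank
    return {order[i] for i in range(k_max)}


def bh_adjust_brute(p):
    """Adjusted p_i = smallest alpha at which BH rejects hypothesis i.

    Tries every candidate alpha of the form p_j * m / rank_j (the only
    levels at which the rejection set can change), which is the step-up
    definition tested threshold by threshold.
    """
    from fractions import Fraction

    p = [Fraction(float(v)) for v in p]
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    candidates = sorted({p[idx] * m / rank for rank, idx in enumerate(order, 1)})
    out = [1.0] * m
    for i in range(m):
        for alpha in candidates:
            if i in bh_step_up_rejections(p, alpha):
                out[i] = min(1.0, float(alpha))
                break
    return out


def km_brute(time, event):
    """Product-limit estimate by explicit risk-set recount at each event time.

    Returns (event_times, survival, at_risk) as lists.
    """
    pairs = list(zip([float(t) for t in time], [int(e) for e in event]))
    event_times = sorted({t for t, e in pairs if e == 1})
    surv, at_risk, s = [], [], 1.0
    for t in event_times:
        n_risk = sum(1 for ti, _ in pairs if ti >= t)
        d = sum(1 for ti, ei in pairs if ti == t and ei == 1)
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
    return event_times, surv, at_risk


def logrank_brute(time_a, event_a, time_b, event_b):
    """Two-group log-rank chi-square from explicit O/E/V sums per event time."""
    a = list(zip(map(float, time_a), map(int, event_a)))
    b = list(zip(map(float, time_b), map(int, event_b)))
    event_times = sorted({t for t, e in a + b if e == 1})
    O = E = V = 0.0
    for t in event_times:
        n1 = sum(1 for ti, _ in a if ti >= t)
        n2 = sum(1 for ti, _ in b if ti >= t)
        n = n1 + n2
        d = sum(1 for ti, ei in a + b if ti == t and ei == 1)
        d1 = sum(1 for ti, ei in a if ti == t and ei == 1)
        O += d1
        E += d * n1 / n
        if n > 1:
            V += d * (n1 / n) * (n2 / n) * (n - d) / (n - 1)
    if V == 0:
        return 0.0, 1.0
    chi = (O - E) ** 2 / V
    return chi, float(stats.chi2.sf(chi, df=1))
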