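"""Independent brute-force oracles for the survival statistics.

These evaluate the defining formulas directly with explicit loops and plain
counting, sharing no code with the package implementation, so that
agreement on small instances is evidence of correctness rather than of
shared bugs.
"""

import numpy as np
from scipy.optimize import minimize_scalar


def km_brute(times, events):
    """Product-limit curve by explicit counting at each distinct event time."""
    times = list(map(float, times))
    events = list(map(int, events))
    ev_times = sorted({t for t, e in zip(times, events) if e == 1})
    s = 1.0
    out = []
    for t in ev_times:
        n = sum(1 for ti in times if ti >= t)
        d = sum(1 for ti, ei in zip(times, events) if ti == t and ei == 1)
        s *= 1.0 - d / n
        out.append((t, s))
    return out


def logrank_brute(group_a, group_b, weight="mantel_cox"):
    """Two-group weighted log-rank statistic by direct hypergeometric sums."""
    ta, ea = group_a
    tb, eb = group_b
    pooled = [(float(t), int(e), 0) for t, e in zip(ta, ea)]
    pooled += [(float(t), int(e), 1) for t, e in zip(tb, eb)]
    ev_times = sorted({t for t, e, _ in pooled if e == 1})
    num = 0.0
    den = 0.0
    for t in ev_times:
        n = sum(1 for ti, _, _ in pooled if ti >= t)
        n_a = sum(1 for ti, _, g in pooled if ti >= t and g == 0)
        d = sum(1 for ti, ei, _ in pooled if ti == t and ei == 1)
        d_a = sum(1 for ti, ei, g in pooled if ti == t and ei == 1 and g == 0)
        e_a = d * n_a / n
        if n > 1:
            v = d * (n_a / n) * (1 - n_a / n) * (n - d) / (n - 1)
        else:
            v = 0.0
        w = 1.0 if weight == "mantel_cox" else float(n)
        num += w * (d_a - e_a)
        den += w * w * v
    if den == 0.0:
        return None
    return num * num / den


def cox_efron_loglik(times, events, x, beta):
    """Efron-tie Cox partial log-likelihood evaluated directly."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for t in sorted(set(times[events == 1])):
        risk = times >= t
        dead = (times == t) & (events == 1)
        d = int(dead.sum())
        s_r = np.sum(np.exp(beta * x[risk]))
        s_d = np.sum(np.exp(beta * x[dead]))
        ll += beta * x[dead].sum()
        for ell in range(d):
            ll -= np.log(s_r - (ell / d) * s_d)
    return ll


def cox_mle_brute(times, events, x):
    """Maximize the partial likelihood by bounded scalar search (not Newton)."""
    res = minimize_scalar(
        lambda b: -cox_efron_loglik(times, events, x, b),
        bounds=(-10, 10),
        method="bounded",
        options={"xatol": 1e-10},
    )
    return float(res.x)
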