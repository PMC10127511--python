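"""From-scratch right-censored survival statistics.

Implements the product-limit (Kaplan-Meier) estimator, weighted log-rank
tests (Mantel-Cox with w_j = 1, Gehan-Breslow-Wilcoxon with w_j = n_j), the
log-rank test for trend over ordered groups, and two-group hazard-ratio
estimation by either the Mantel-Haenszel O/E ratio or a one-parameter Cox
partial likelihood with Efron tie handling.

Conventions: subjects censored exactly at an event time are counted at risk
for that event time (censoring happens after events at ties); p-values are
two-sided from the chi-square distribution with the stated df; confidence
intervals are 95% normal-approximation intervals on the log hazard ratio.

These routines are the package's own implementation; lifelines serves only
as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

__all__ = [
    "KaplanMeierEstimator",
    "km_estimate",
    "logrank_test",
    "logrank_trend",
    "LogRankResult",
    "HazardRatioEstimator",
    "hazard_ratio",
    "HazardRatioEstimate",
]


def _clean(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no survival records")
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if not np.all(np.isfinite(time)) or np.any(time < 0):
        raise ValueError("times must be finite and non-negative")
    if not np.all(np.isin(event, (0, 1))):
        raise ValueError("event indicator must be 0 or 1")
    return time, event


class KaplanMeierEstimator(BaseEstimator):
    """Product-limit survival curve S(t) = prod_{t_i <= t} (1 - d_i/n_i).

    Fitted attributes
    -----------------
    event_times_ : distinct event times, ascending
    survival_ : S(t) immediately after each event time
    n_at_risk_, n_events_ : risk-set size and event count at each event time
    censor_times_ : times of censored subjects (curve tick marks)
    """

    def fit(self, time, event):
        time, event = _clean(time, event)
        order = np.argsort(time, kind="stable")
        time, event = time[order], event[order]
        ev_times = np.unique(time[event == 1])
        n_at_risk = np.array([(time >= t).sum() for t in ev_times], dtype=int)
        n_events = np.array(
            [((time == t) & (event == 1)).sum() for t in ev_times], dtype=int
        )
        with np.errstate(divide="ignore", invalid="ignore"):
            factors = 1.0 - n_events / n_at_risk
        self.event_times_ = ev_times
        self.n_at_risk_ = n_at_risk
        self.n_events_ = n_events
        self.survival_ = np.cumprod(factors)
        self.censor_times_ = np.sort(time[event == 0])
        self.n_ = time.size
        return self

    def predict(self, times):
        """S(t) at arbitrary times (right-continuous step function)."""
        times = np.atleast_1d(np.asarray(times, dtype=float))
        idx = np.searchsorted(self.event_times_, times, side="right")
        surv = np.concatenate([[1.0], self.survival_])
        return surv[idx]

    @property
    def survival_function_(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.event_times_,
                "survival": self.survival_,
                "n_at_risk": self.n_at_risk_,
                "n_events": self.n_events_,
            }
        )

    def export_table(self) -> pd.DataFrame:
        """Curve table including censoring tick marks, for TSV export."""
        ev = self.survival_function_.assign(censor_flag=0)
        cz = pd.DataFrame(
            {
                "time": self.censor_times_,
                "survival": self.predict(self.censor_times_),
                "n_at_risk": [
                    int((np.r_[self.event_times_, np.inf] > t).sum()) for t in self.censor_times_
                ],
                "n_events": 0,
                "censor_flag": 1,
            }
        )
        out = pd.concat([ev, cz], ignore_index=True).sort_values(
            ["time", "censor_flag"], kind="stable"
        )
        return out.reset_index(drop=True)


def km_estimate(time, event) -> KaplanMeierEstimator:
    """Functional form of :class:`KaplanMeierEstimator`."""
    return KaplanMeierEstimator().fit(time, event)


@dataclass
class LogRankResult:
    statistic: float
    df: int
    p_value: float
    variant: str
    observed: np.ndarray | None = None
    expected: np.ndarray | None = None


def _risk_tables(times, events):
    """Pooled distinct event times with per-group at-risk/event counts."""
    pooled_t = np.concatenate(times)
    pooled_e = np.concatenate(events)
    ev_times = np.unique(pooled_t[pooled_e == 1])
    k = len(times)
    n_g = np.empty((len(ev_times), k))
    d_g = np.empty((len(ev_times), k))
    for g in range(k):
        t_sorted = np.sort(times[g])
        te_sorted = np.sort(times[g][events[g] == 1])
        n_g[:, g] = t_sorted.size - np.searchsorted(t_sorted, ev_times, side="left")
        d_g[:, g] = np.searchsorted(te_sorted, ev_times, side="right") - np.searchsorted(
            te_sorted, ev_times, side="left"
        )
    return ev_times, n_g, d_g


def logrank_test(*groups, variant: str = "mantel_cox") -> LogRankResult:
    """Weighted log-rank test between k >= 2 groups.

    Each group is a ``(time, event)`` pair.  At every pooled event time the
    observed per-group events are compared with their hypergeometric
    expectation; the chi-square statistic has k-1 degrees of freedom.  For
    two groups this reduces to (sum w_j (d_Aj - E_Aj))^2 / sum w_j^2 V_j.

    variant: ``mantel_cox`` (w_j = 1) or ``gehan_breslow_wilcoxon``
    (w_j = n_j, the pooled number at risk).
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if variant not in ("mantel_cox", "gehan_breslow_wilcoxon"):
        raise ValueError(f"unknown variant {variant!r}")
    times, events = zip(*(_clean(t, e) for t, e in groups))
    ev_times, n_g, d_g = _risk_tables(times, events)
    if len(ev_times) == 0:
        raise ValueError("no events in either group")
    n_j = n_g.sum(axis=1)
    d_j = d_g.sum(axis=1)
    w = np.ones_like(n_j) if variant == "mantel_cox" else n_j

    p = n_g / n_j[:, None]
    e_g = d_j[:, None] * p
    # multivariate hypergeometric covariance of the event-count vector
    mult = d_j * (n_j - d_j) / np.maximum(n_j - 1, 1.0)
    k = len(groups)
    u = (w[:, None] * (d_g - e_g)).sum(axis=0)[: k - 1]
    cov = np.zeros((k - 1, k - 1))
    for a in range(k - 1):
        for b in range(k - 1):
            vab = mult * (p[:, a] * ((a == b) - p[:, b]))
            cov[a, b] = (w**2 * vab).sum()
    if not np.any(np.diag(cov) > 0):
        raise ValueError("zero variance: no informative event times")
    try:
        stat = float(u @ np.linalg.solve(cov, u))
    except np.linalg.LinAlgError:
        stat = float(u @ np.linalg.pinv(cov) @ u)
    stat = max(stat, 0.0)
    df = k - 1
    return LogRankResult(
        statistic=stat,
        df=df,
        p_value=float(stats.chi2.sf(stat, df)),
        variant=variant,
        observed=d_g.sum(axis=0),
        expected=e_g.sum(axis=0),
    )


def logrank_trend(groups, scores=None) -> LogRankResult:
    """Log-rank test for trend across >= 3 ordered groups.

    ``groups`` is an ordered sequence of ``(time, event)`` pairs; ``scores``
    default to centered equally spaced values (-1, 0, +1 for three groups).
    The statistic is the squared score-weighted observed-minus-expected sum
    over its variance, chi-square with one degree of freedom.
    """
    if len(groups) < 3:
        raise ValueError(
            "trend test needs >=3 ordered groups; use logrank_test for two"
        )
    k = len(groups)
    if scores is None:
        scores = np.arange(k, dtype=float) - (k - 1) / 2.0
    scores = np.asarray(scores, dtype=float)
    if scores.size != k:
        raise ValueError("one score per group required")
    times, events = zip(*(_clean(t, e) for t, e in groups))
    ev_times, n_g, d_g = _risk_tables(times, events)
    if len(ev_times) == 0:
        raise ValueError("no events")
    n_j = n_g.sum(axis=1)
    d_j = d_g.sum(axis=1)
    p = n_g / n_j[:, None]
    e_g = d_j[:, None] * p
    u = float((scores[None, :] * (d_g - e_g)).sum())
    mult = d_j * (n_j - d_j) / np.maximum(n_j - 1, 1.0)
    sbar = (p * scores[None, :]).sum(axis=1)
    var_j = mult * ((p * scores[None, :] ** 2).sum(axis=1) - sbar**2)
    v = float(var_j.sum())
    if v <= 0:
        raise ValueError("zero variance: no informative event times")
    stat = u * u / v
    return LogRankResult(
        statistic=stat,
        df=1,
        p_value=float(stats.chi2.sf(stat, 1)),
        variant="trend",
        observed=d_g.sum(axis=0),
        expected=e_g.sum(axis=0),
    )


@dataclass
class HazardRatioEstimate:
    hr: float
    log_hr: float
    se_log_hr: float
    method: str
    ci95: tuple[float, float]
    n_iter: int = 0


def _cox_efron_binary(time, event, x, tol=1e-10, max_iter=60):
    """Newton-Raphson on the Efron partial likelihood, single covariate.

    Risk-set sums are computed as suffix sums over the time-sorted sample,
    so each Newton step is O(n); tied event times get the Efron correction
    (risk-set sums reduced by the fraction ell/d of the tied-death sums).
    """
    order = np.argsort(time, kind="stable")
    time, event, x = time[order], event[order], x[order]
    ev_times = np.unique(time[event == 1])
    # index of first subject with time >= t for each event time (ascending sort)
    risk_start = np.searchsorted(time, ev_times, side="left")
    # tied-death bookkeeping
    dead_groups = []
    for t in ev_times:
        dead_groups.append(np.flatnonzero((time == t) & (event == 1)))
    d_counts = np.array([len(g) for g in dead_groups])
    x_dead_sum = x[event == 1].sum()

    beta = 0.0
    n_iter = 0
    grad = hess = 0.0
    for n_iter in range(1, max_iter + 1):
        ex = np.exp(beta * x)
        ex1 = x * ex
        ex2 = x * ex1
        suf0 = np.concatenate([np.cumsum(ex[::-1])[::-1], [0.0]])
        suf1 = np.concatenate([np.cumsum(ex1[::-1])[::-1], [0.0]])
        suf2 = np.concatenate([np.cumsum(ex2[::-1])[::-1], [0.0]])
        s_r0 = suf0[risk_start]
        s_r1 = suf1[risk_start]
        s_r2 = suf2[risk_start]

        untied = d_counts == 1
        r0, r1, r2 = s_r0[untied], s_r1[untied], s_r2[untied]
        ratio1 = r1 / r0
        grad = x_dead_sum - ratio1.sum()
        hess = -(r2 / r0 - ratio1**2).sum()
        for j in np.flatnonzero(~untied):
            g = dead_groups[j]
            d = d_counts[j]
            s_d0, s_d1, s_d2 = ex[g].sum(), ex1[g].sum(), ex2[g].sum()
            f = np.arange(d) / d
            phi0 = s_r0[j] - f * s_d0
            phi1 = s_r1[j] - f * s_d1
            phi2 = s_r2[j] - f * s_d2
            grad -= (phi1 / phi0).sum()
            hess -= (phi2 / phi0 - (phi1 / phi0) ** 2).sum()
        if hess >= 0:  # degenerate; no curvature
            raise ValueError("Cox partial likelihood has no curvature (HR unidentifiable)")
        delta = grad / hess
        beta -= delta
        if abs(delta) < tol:
            break
    se = float(np.sqrt(-1.0 / hess))
    return float(beta), se, n_iter


class HazardRatioEstimator(BaseEstimator):
    """Two-group hazard ratio (group A vs group B).

    Parameters
    ----------
    method : "cox_efron" (default) or "mantel_haenszel"
        ``cox_efron`` maximizes the one-parameter Cox partial likelihood
        with Efron tie correction by Newton-Raphson (|step| < 1e-10);
        ``mantel_haenszel`` uses (O_A/E_A)/(O_B/E_B) with
        se(log HR) = sqrt(1/E_A + 1/E_B).
    alpha : confidence level complement for the CI (default 0.05 -> 95%).

    ``fit(time, event, group)`` takes a boolean/0-1 ``group`` vector, True
    for group A.  Fitted attributes: ``hazard_ratio_``, ``log_hr_``,
    ``se_log_hr_``, ``ci95_``, ``n_iter_``.
    """

    def __init__(self, method: str = "cox_efron", alpha: float = 0.05):
        self.method = method
        self.alpha = alpha

    def fit(self, time, event, group):
        time, event = _clean(time, event)
        group = np.asarray(group).astype(bool)
        if group.shape != time.shape:
            raise ValueError("group must align with time/event")
        for name, mask in (("A", group), ("B", ~group)):
            if not mask.any() or event[mask].sum() == 0:
                raise ValueError(f"group {name} has no events; HR unidentifiable")
        if self.method == "mantel_haenszel":
            ta, ea = time[group], event[group]
            tb, eb = time[~group], event[~group]
            _, n_g, d_g = _risk_tables((ta, tb), (ea, eb))
            n_j = n_g.sum(axis=1)
            d_j = d_g.sum(axis=1)
            e_g = d_j[:, None] * n_g / n_j[:, None]
            o_a, o_b = d_g.sum(axis=0)
            e_a, e_b = e_g.sum(axis=0)
            log_hr = float(np.log((o_a / e_a) / (o_b / e_b)))
            se = float(np.sqrt(1.0 / e_a + 1.0 / e_b))
            n_iter = 0
        elif self.method == "cox_efron":
            log_hr, se, n_iter = _cox_efron_binary(time, event, group.astype(float))
        else:
            raise ValueError(f"unknown method {self.method!r}")
        zcrit = stats.norm.ppf(1 - self.alpha / 2)
        self.log_hr_ = log_hr
        self.se_log_hr_ = se
        self.hazard_ratio_ = float(np.exp(log_hr))
        self.ci95_ = (float(np.exp(log_hr - zcrit * se)), float(np.exp(log_hr + zcrit * se)))
        self.n_iter_ = n_iter
        return self

    @property
    def estimate_(self) -> HazardRatioEstimate:
        return HazardRatioEstimate(
            hr=self.hazard_ratio_,
            log_hr=self.log_hr_,
            se_log_hr=self.se_log_hr_,
            method=self.method,
            ci95=self.ci95_,
            n_iter=self.n_iter_,
        )


def hazard_ratio(
    group_a: tuple, group_b: tuple, method: str = "cox_efron"
) -> HazardRatioEstimate:
    """HR of group A relative to group B from ``(time, event)`` pairs."""
    ta, ea = group_a
    tb, eb = group_b
    time = np.concatenate([np.asarray(ta, float), np.asarray(tb, float)])
    event = np.concatenate([np.asarray(ea, int), np.asarray(eb, int)])
    group = np.concatenate([np.ones(len(np.atleast_1d(ta)), bool), np.zeros(len(np.atleast_1d(tb)), bool)])
    return HazardRatioEstimator(method=method).fit(time, event, group).estimate_
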