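"""Survival statistics: Kaplan-Meier product-limit curves, the two-group
log-rank test, and a Friedman test for blocked rank comparisons.

These primitives back the per-gene prognostic scans, where the log-rank
statistic is evaluated many thousands of times per cohort, so they are
implemented directly on numpy arrays.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit survival curve.

    ``times`` are the distinct event times in increasing order and
    ``survival`` the curve value just after each; S(t) = 1 before the first
    event.  Censored observations shrink the risk set without a step.
    """

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    events: np.ndarray

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> KMEstimate:
    """Kaplan-Meier estimator of the survival function."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if t.size == 0:
        raise ValueError("empty survival input")
    if (t < 0).any() or not np.isfinite(t).all():
        raise ValueError("times must be finite and >= 0")
    order = np.argsort(t, kind="mergesort")
    t, e = t[order], e[order]
    event_times = np.unique(t[e])
    n = t.size
    surv, at_risk, d_out = [], [], []
    s = 1.0
    for et in event_times:
        n_risk = int(np.sum(t >= et))
        d = int(np.sum((t == et) & e))
        s *= 1.0 - d / n_risk
        surv.append(s)
        at_risk.append(n_risk)
        d_out.append(d)
    return KMEstimate(
        times=event_times,
        survival=np.asarray(surv, dtype=float),
        at_risk=np.asarray(at_risk, dtype=float),
        events=np.asarray(d_out, dtype=float),
    )


@dataclass(frozen=True)
class LogRankResult:
    chi2: float
    p: float
    observed_a: float
    expected_a: float

    @property
    def direction(self) -> int:
        """+1 when group A has more events than expected (worse survival)."""
        return 1 if self.observed_a > self.expected_a else -1


def logrank_test(times_a, events_a, times_b, events_b) -> LogRankResult:
    """One-degree-of-freedom log-rank test between two survival samples."""
    ta = np.asarray(times_a, dtype=float)
    ea = np.asarray(events_a, dtype=bool)
    tb = np.asarray(times_b, dtype=float)
    eb = np.asarray(events_b, dtype=bool)
    if ta.size == 0 or tb.size == 0:
        raise ValueError("both groups must be non-empty")
    if not (ea.any() or eb.any()):
        raise ValueError("no events in either group")
    event_times = np.unique(np.concatenate([ta[ea], tb[eb]]))
    o_a = e_a = var = 0.0
    for et in event_times:
        na = np.sum(ta >= et)
        nb = np.sum(tb >= et)
        n = na + nb
        da = np.sum((ta == et) & ea)
        db = np.sum((tb == et) & eb)
        d = da + db
        o_a += da
        e_a += d * na / n
        if n > 1:
            var += d * (na / n) * (nb / n) * (n - d) / (n - 1)
    if var == 0:
        return LogRankResult(chi2=0.0, p=1.0, observed_a=o_a, expected_a=e_a)
    chi2 = (o_a - e_a) ** 2 / var
    return LogRankResult(
        chi2=float(chi2),
        p=float(sps.chi2.sf(chi2, df=1)),
        observed_a=float(o_a),
        expected_a=float(e_a),
    )


def friedman_test(table) -> tuple[float, float]:
    """Friedman chi-square for a blocks x treatments table (tie-corrected).

    Blocks are e.g. cell lines, treatments the matched conditions compared
    within each block.  For three or more treatments this delegates to
    scipy; the two-treatment case (not supported there) uses the same
    rank-based statistic with one degree of freedom.
    """
    x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need a blocks x treatments table, >= 2 of each")
    n, k = x.shape
    if k >= 3:
        stat, p = sps.friedmanchisquare(*[x[:, j] for j in range(k)])
        return float(stat), float(p)
    ranks = np.vstack([sps.rankdata(row) for row in x])
    col_sums = ranks.sum(axis=0)
    stat = 12.0 / (n * k * (k + 1)) * np.sum(col_sums**2) - 3.0 * n * (k + 1)
    # tie correction within blocks
    tie_term = 0.0
    for row in x:
        _, counts = np.unique(row, return_counts=True)
        tie_term += np.sum(counts**3 - counts)
    c = 1.0 - tie_term / (n * k * (k**2 - 1))
    if c <= 0:  # every block fully tied
        return 0.0, 1.0
    stat /= c
    return float(stat), float(sps.chi2.sf(stat, df=k - 1))
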