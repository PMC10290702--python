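"""Group comparisons for pooled imaging replicates.

Three procedures cover the comparisons made on per-FOV statistics:
ROUT robust outlier removal at a stated false discovery rate Q,
the unpaired two-tailed Student's t test (pooled variance), and
one-way ANOVA with Tukey HSD pairwise comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "OutlierReport",
    "ComparisonResult",
    "rout_outliers",
    "t_test_two_sided",
    "anova_tukey",
]


@dataclass
class OutlierReport:
    """Per-value outlier flags from the ROUT procedure."""

    values: np.ndarray
    is_outlier: np.ndarray
    q: float
    center: float
    rsdr: float
    note: str = ""

    @property
    def cleaned(self) -> np.ndarray:
        return self.values[~self.is_outlier]


@dataclass
class ComparisonResult:
    """Outcome of a two-group or multi-group comparison."""

    test: str
    statistic: float
    df: float
    p_value: float
    tukey: pd.DataFrame | None = None
    degenerate: bool = False


def rout_outliers(values, q: float = 0.01) -> OutlierReport:
    """Flag outliers by the ROUT procedure at FDR level ``q``.

    For a one-sample scatter the "regression" model is the constant that a
    robust fit would return, the median.  Residuals are scaled by the RSDR
    (robust standard deviation of residuals): the 68.27th percentile of the
    absolute residuals times sqrt(n/(n-1)).  Scaled residuals are then
    tested outermost-inward against a t reference (df = n-1) with
    step-down FDR thresholds alpha_i = q*(n-i+1)/n; testing stops at the
    first non-significant residual and everything more extreme is flagged.

    This is a documented univariate variant validated by calibration; the
    commercial implementation's internal constants are not published.
    """
    x = np.asarray(values, dtype=float)
    n = len(x)
    if not (0 < q < 1):
        raise ValueError("q must lie in (0, 1)")
    if n < 3:
        msg = f"ROUT needs n >= 3 (got {n}); returning all values unflagged"
        warnings.warn(msg, stacklevel=2)
        return OutlierReport(x, np.zeros(n, bool), q, float(np.median(x)) if n else np.nan, 0.0, msg)
    center = float(np.median(x))
    resid = x - center
    rsdr = float(np.percentile(np.abs(resid), 68.27) * np.sqrt(n / (n - 1)))
    flags = np.zeros(n, dtype=bool)
    order = np.argsort(-np.abs(resid), kind="stable")  # outermost first
    for i, j in enumerate(order, start=1):
        if rsdr > 0:
            p = 2.0 * stats.t.sf(abs(resid[j]) / rsdr, df=n - 1)
        else:
            p = 0.0 if resid[j] != 0 else 1.0
        alpha = q * (n - i + 1) / n
        if p < alpha:
            flags[j] = True
        else:
            break
    return OutlierReport(x, flags, q, center, rsdr)


def t_test_two_sided(group_a, group_b) -> ComparisonResult:
    """Unpaired two-tailed Student's t test (pooled variance, not Welch)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each group needs n >= 2")
    df = len(a) + len(b) - 2
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0:
        # zero pooled variance: no sampling noise at all
        if a.mean() == b.mean():
            return ComparisonResult("student_t", 0.0, df, 1.0)
        sign = np.sign(a.mean() - b.mean())
        return ComparisonResult("student_t", float(sign * np.inf), df, 0.0, degenerate=True)
    t, p = stats.ttest_ind(a, b, equal_var=True)
    return ComparisonResult("student_t", float(t), df, float(p))


def anova_tukey(groups) -> ComparisonResult:
    """One-way ANOVA with Tukey HSD pairwise comparisons.

    ``groups`` is a mapping name -> values or a sequence of samples
    (auto-named).  Every group needs n >= 2.  The Tukey table reports the
    studentized-range adjusted two-sided p for every unordered pair.
    """
    if isinstance(groups, dict):
        names = list(groups)
        samples = [np.asarray(groups[k], dtype=float) for k in names]
    else:
        samples = [np.asarray(g, dtype=float) for g in groups]
        names = [f"group{i}" for i in range(len(samples))]
    if len(samples) < 2:
        raise ValueError("need at least 2 groups")
    for name, s in zip(names, samples):
        if len(s) < 2:
            raise ValueError(f"group {name!r} has n < 2")
    k = len(samples)
    n_total = sum(len(s) for s in samples)
    df = k - 1  # between-group degrees of freedom; residual df = n_total - k
    if all(s.var(ddof=1) == 0 for s in samples) and len({s.mean() for s in samples}) == 1:
        pairs = [
            {"group_a": names[i], "group_b": names[j], "diff": 0.0, "p_adj": 1.0}
            for i in range(k)
            for j in range(i + 1, k)
        ]
        return ComparisonResult("anova_tukey", 0.0, df, 1.0, pd.DataFrame(pairs))
    f, p = stats.f_oneway(*samples)
    hsd = stats.tukey_hsd(*samples)
    pairs = []
    for i in range(k):
        for j in range(i + 1, k):
            pairs.append(
                {
                    "group_a": names[i],
                    "group_b": names[j],
                    "diff": float(samples[i].mean() - samples[j].mean()),
                    "p_adj": float(hsd.pvalue[i, j]),
                }
            )
    return ComparisonResult("anova_tukey", float(f), df, float(p), pd.DataFrame(pairs))
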