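"""Group-comparison statistics: Tukey–Kramer pairwise tests, one-way ANOVA
reconstructed from printed summaries, Pearson chi-squared, and correlation
panels."""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd
from scipy import stats


def pairwise_tukey(scores, groups, alpha: float = 0.05) -> pd.DataFrame:
    """All pairwise mean contrasts with Tukey–Kramer adjusted p-values.

    Uses the studentized-range distribution with pooled within-group MSE
    and the unequal-n (Kramer) correction; the unadjusted two-tailed
    pooled-variance t-test p is reported alongside.  If every group is
    constant and equal the adjusted p is 1 by convention.
    """
    s = pd.Series(scores, dtype=float)
    g = pd.Series(groups)
    if len(s) != len(g):
        raise ValueError("scores and groups must have equal length")
    levels = list(pd.unique(g))
    k = len(levels)
    if k < 2:
        raise ValueError("need at least 2 groups")
    ns = {lv: int((g == lv).sum()) for lv in levels}
    for lv, n in ns.items():
        if n < 2:
            raise ValueError(f"group {lv!r} has fewer than 2 samples")
    means = {lv: s[g.values == lv].mean() for lv in levels}
    N = len(s)
    df = N - k
    ssw = sum(((s[g.values == lv] - means[lv]) ** 2).sum() for lv in levels)
    msw = ssw / df

    rows = []
    for a, b in itertools.combinations(levels, 2):
        diff = means[a] - means[b]
        if msw <= 0:
            p_adj = 1.0 if diff == 0 else 0.0
            p_unadj = p_adj
            tstat = 0.0 if diff == 0 else np.inf * np.sign(diff)
        else:
            se_t = np.sqrt(msw * (1.0 / ns[a] + 1.0 / ns[b]))
            tstat = diff / se_t
            p_unadj = 2.0 * stats.t.sf(abs(tstat), df)
            q = abs(diff) / np.sqrt(msw / 2.0 * (1.0 / ns[a] + 1.0 / ns[b]))
            p_adj = float(stats.studentized_range.sf(q, k, df))
        p_adj = float(min(1.0, max(p_adj, p_unadj)))
        rows.append(
            {
                "group_a": a,
                "group_b": b,
                "diff": diff,
                "t": tstat,
                "p_unadjusted": p_unadj,
                "p_tukey": p_adj,
                "significant": p_adj < alpha,
            }
        )
    return pd.DataFrame(rows)


def anova_from_summary(means, sds, ns) -> tuple[float, int, int, float]:
    """One-way fixed-effects ANOVA from per-group summary statistics.

    Between-group SS uses n-weighted deviations from the grand mean; the
    within-group mean square pools (n−1)·sd² across groups.  Returns
    (F, df_between, df_within, p).
    """
    means = np.asarray(means, dtype=float)
    sds = np.asarray(sds, dtype=float)
    ns = np.asarray(ns, dtype=int)
    if not (len(means) == len(sds) == len(ns)):
        raise ValueError("means, sds, ns must have equal length")
    k = len(means)
    if k < 2:
        raise ValueError("need at least 2 groups")
    if np.any(ns < 2) or np.any(sds < 0):
        raise ValueError("each group needs n >= 2 and sd >= 0")
    N = int(ns.sum())
    grand = float((ns * means).sum() / N)
    ssb = float((ns * (means - grand) ** 2).sum())
    ssw = float(((ns - 1) * sds**2).sum())
    df1, df2 = k - 1, N - k
    msb, msw = ssb / df1, ssw / df2
    if msw == 0:
        return (0.0, df1, df2, 1.0) if msb == 0 else (np.inf, df1, df2, 0.0)
    F = msb / msw
    return F, df1, df2, float(stats.f.sf(F, df1, df2))


def chi2_from_counts(table) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence (no continuity correction)."""
    T = np.asarray(table, dtype=float)
    if T.ndim != 2:
        raise ValueError("expected a 2-D contingency table")
    if np.any(T < 0):
        raise ValueError("counts must be non-negative")
    if np.any(T.sum(axis=0) == 0) or np.any(T.sum(axis=1) == 0):
        raise ValueError("empty row or column margin")
    res = stats.chi2_contingency(T, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def correlate_metrics(metrics: pd.DataFrame) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and two-tailed p over a samples-by-metrics table.

    Pairs are computed over complete observations; constant columns give
    NaN (undefined correlation).  Returns (r_matrix, p_matrix), both
    symmetric with unit/zero diagonals.
    """
    cols = list(metrics.columns)
    m = len(cols)
    R = pd.DataFrame(np.eye(m), index=cols, columns=cols)
    P = pd.DataFrame(np.zeros((m, m)), index=cols, columns=cols)
    for i, j in itertools.combinations(range(m), 2):
        pair = metrics.iloc[:, [i, j]].dropna()
        if len(pair) < 3 or pair.iloc[:, 0].nunique() == 1 or pair.iloc[:, 1].nunique() == 1:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(pair.iloc[:, 0], pair.iloc[:, 1])
        R.iloc[i, j] = R.iloc[j, i] = r
        P.iloc[i, j] = P.iloc[j, i] = p
    return R, P
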