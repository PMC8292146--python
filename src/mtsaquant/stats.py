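"""Group-comparison and correlation statistics over per-patient tables.

The cohort layer compares per-patient quantities (cell densities, CD34+
pixel percentages, population ratios, mean shortest distances) between two
outcome groups and reports correlations between population densities.
Densities and percentages are compared with the Mann-Whitney U test and
summarized as median (min-max); ratios are compared with an independent
t-test and summarized as mean (SD); paired comparisons use the Wilcoxon
signed-rank test; categorical 2x2 tables use Fisher's exact test; rank
correlations use Spearman's coefficient.

With small groups (the intended cohort sizes are around 9 and 13 patients),
the Mann-Whitney p-value is computed from the exact permutation distribution
of the rank sum — enumerated directly, so ties are handled exactly — and a
tie-corrected normal approximation is used for larger samples.  No
multiple-testing correction is applied by default; Benjamini-Hochberg can be
switched on.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats as sps

EXACT_MAX_COMBINED_N = 20


@dataclass(frozen=True)
class TestResult:
    statistic: float
    pvalue: float
    defined: bool = True
    note: str = ""


def _rankdata(values: np.ndarray) -> np.ndarray:
    return sps.rankdata(values, method="average")


def mann_whitney_u(group_a, group_b) -> TestResult:
    """Two-sided Mann-Whitney U test.

    For combined n <= 20 the p-value comes from exhaustive enumeration of all
    group assignments of the pooled (average-rank) ranks, so ties are exact:
    p = 2 * min(P(U <= u), P(U >= u)), capped at 1.  Larger samples use the
    tie-corrected normal approximation with continuity correction.
    """
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    n1, n2 = a.size, b.size
    ranks = _rankdata(np.concatenate([a, b]))
    u1 = ranks[:n1].sum() - n1 * (n1 + 1) / 2  # U for group A
    if n1 + n2 <= EXACT_MAX_COMBINED_N:
        combos = np.fromiter(
            (c for comb in combinations(range(n1 + n2), n1) for c in comb), dtype=np.intp
        ).reshape(-1, n1)
        u_all = ranks[combos].sum(axis=1) - n1 * (n1 + 1) / 2
        p_le = np.mean(u_all <= u1 + 1e-12)
        p_ge = np.mean(u_all >= u1 - 1e-12)
        p = min(1.0, 2 * min(p_le, p_ge))
    else:
        mu = n1 * n2 / 2
        n = n1 + n2
        _, tie_counts = np.unique(ranks, return_counts=True)
        tie_term = ((tie_counts**3 - tie_counts).sum()) / (n * (n - 1))
        sigma2 = n1 * n2 / 12 * (n + 1 - tie_term)
        if sigma2 <= 0:
            return TestResult(u1, 1.0, note="degenerate: all values tied")
        z = (u1 - mu - math.copysign(0.5, u1 - mu)) / math.sqrt(sigma2) if u1 != mu else 0.0
        p = min(1.0, 2 * sps.norm.sf(abs(z)))
    return TestResult(statistic=float(u1), pvalue=float(p))


def spearman_correlation(x, y) -> TestResult:
    """Spearman rank correlation with average ranks; p from the t-approximation."""
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size != y.size or x.size < 3:
        raise ValueError("need at least 3 paired observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return TestResult(math.nan, math.nan, defined=False, note="constant input")
    rho, p = sps.spearmanr(x, y)
    return TestResult(statistic=float(rho), pvalue=float(p))


def paired_wilcoxon(values_t1, values_t2) -> TestResult:
    """Wilcoxon signed-rank test between paired measurements; zero differences dropped."""
    t1 = np.asarray(values_t1, dtype=np.float64)
    t2 = np.asarray(values_t2, dtype=np.float64)
    if t1.size != t2.size:
        raise ValueError("paired samples must have equal length")
    diffs = t2 - t1
    if np.all(diffs == 0):
        return TestResult(math.nan, math.nan, defined=False, note="all differences zero")
    w, p = sps.wilcoxon(t1, t2, zero_method="wilcox")
    return TestResult(statistic=float(w), pvalue=float(p))


def independent_t(group_a, group_b) -> TestResult:
    """Two-sided independent-samples t-test (equal-variance)."""
    a = np.asarray(group_a, dtype=np.float64)
    b = np.asarray(group_b, dtype=np.float64)
    a = a[~np.isnan(a)]
    b = b[~np.isnan(b)]
    if a.size < 2 or b.size < 2:
        return TestResult(math.nan, math.nan, defined=False, note="group too small")
    t, p = sps.ttest_ind(a, b)
    return TestResult(statistic=float(t), pvalue=float(p))


def fishers_exact(table) -> TestResult:
    """Two-sided Fisher's exact test on a 2x2 table (odds ratio, p)."""
    table = np.asarray(table, dtype=np.int64)
    if table.shape != (2, 2) or np.any(table < 0):
        raise ValueError("need a non-negative 2x2 table")
    odds, p = sps.fisher_exact(table, alternative="two-sided")
    return TestResult(statistic=float(odds), pvalue=float(p))


def benjamini_hochberg(pvalues) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (optional, off by default upstream)."""
    p = np.asarray(pvalues, dtype=np.float64)
    n = p.size
    order = np.argsort(p)
    adj = np.empty(n)
    running = 1.0
    for rank_from_top, idx in enumerate(order[::-1]):
        k = n - rank_from_top
        running = min(running, p[idx] * n / k)
        adj[idx] = running
    return adj


def group_summaries(
    table: pd.DataFrame,
    group_col: str = "group",
    density_cols: tuple[str, ...] = (),
    ratio_cols: tuple[str, ...] = (),
) -> pd.DataFrame:
    """Per-group summaries: median (min-max) for densities and percentages,
    mean (SD) for ratios.

    Missing values are excluded per column with a recorded n; they are never
    silently dropped from the table itself.
    """
    rows = []
    for group, sub in table.groupby(group_col):
        for col in density_cols:
            vals = sub[col].dropna()
            rows.append({
                "group": group, "variable": col, "kind": "density",
                "n": len(vals), "n_missing": sub[col].isna().sum(),
                "median": vals.median() if len(vals) else math.nan,
                "min": vals.min() if len(vals) else math.nan,
                "max": vals.max() if len(vals) else math.nan,
            })
        for col in ratio_cols:
            vals = sub[col].dropna()
            rows.append({
                "group": group, "variable": col, "kind": "ratio",
                "n": len(vals), "n_missing": sub[col].isna().sum(),
                "mean": vals.mean() if len(vals) else math.nan,
                "sd": vals.std(ddof=1) if len(vals) > 1 else math.nan,
            })
    return pd.DataFrame(rows)
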