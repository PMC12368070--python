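"""Figure statistics: Wilcoxon tests, BH adjustment, boxplot summaries, MA values.

The Wilcoxon tests follow the R wilcox.test conventions: zero differences
dropped, exact permutation distribution for small samples (computed by
dynamic programming over the possible rank sums, so ties are handled
exactly), and a tie- and continuity-corrected normal approximation for
large samples.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

EXACT_LIMIT_SIGNED = 25
EXACT_LIMIT_RANKSUM = 30


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    method: str
    n: int


def _two_sided_p(cdf_le: float, cdf_ge: float) -> float:
    return float(min(1.0, 2.0 * min(cdf_le, cdf_ge)))


def wilcoxon_signed_rank(values, mu: float = 0.0) -> TestResult:
    """One-sample two-sided Wilcoxon signed-rank test against ``mu``.

    Exact permutation p for n <= 25 (DP over signed-rank sums using doubled
    midranks, so tied |d| are handled exactly); otherwise the normal
    approximation with tie correction and continuity correction.
    """
    d = np.asarray(values, dtype=float) - mu
    d = d[d != 0]
    n = len(d)
    if n == 0:
        raise ValueError("all values equal mu; signed-rank test undefined")
    ranks = sps.rankdata(np.abs(d))
    w_plus = float(ranks[d > 0].sum())
    if n <= EXACT_LIMIT_SIGNED:
        r2 = np.round(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        # counts[s] = number of sign assignments with doubled rank sum s
        counts = np.zeros(total + 1, dtype=float)
        counts[0] = 1.0
        for r in r2:
            counts[r:] += counts[:-r].copy() if r > 0 else counts.copy()
        counts /= counts.sum()
        w2 = int(round(2 * w_plus))
        cdf = np.cumsum(counts)
        p_le = float(cdf[w2])
        p_ge = float(counts[w2:].sum())
        return TestResult(w_plus, _two_sided_p(p_le, p_ge), "signed_rank_exact", n)
    mean = n * (n + 1) / 4.0
    _, tie_counts = np.unique(ranks, return_counts=True)
    var = n * (n + 1) * (2 * n + 1) / 24.0 - np.sum(tie_counts**3 - tie_counts) / 48.0
    z = w_plus - mean
    z -= 0.5 * np.sign(z)  # continuity correction
    z /= np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w_plus, p, "signed_rank_normal", n)


def wilcoxon_rank_sum(a, b) -> TestResult:
    """Two-sample two-sided Wilcoxon rank-sum (Mann-Whitney) test.

    Exact permutation p (DP over k-subset rank sums with doubled midranks)
    when n1 + n2 <= 30, else tie- and continuity-corrected normal
    approximation. The statistic reported is W = rank sum of ``a``.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    n1, n2 = len(a), len(b)
    if n1 == 0 or n2 == 0:
        raise ValueError("both samples must be non-empty")
    combined = np.concatenate([a, b])
    ranks = sps.rankdata(combined)
    w = float(ranks[:n1].sum())
    if n1 + n2 <= EXACT_LIMIT_RANKSUM:
        r2 = np.round(2 * ranks).astype(np.int64)
        total = int(r2.sum())
        # dp[k][s] = number of k-subsets of all ranks with doubled sum s
        dp = np.zeros((n1 + 1, total + 1), dtype=float)
        dp[0, 0] = 1.0
        for r in r2:
            dp[1:, r:] += dp[:-1, :-r].copy() if r > 0 else dp[:-1, :].copy()
        dist = dp[n1]
        dist /= dist.sum()
        w2 = int(round(2 * w))
        cdf = np.cumsum(dist)
        p_le = float(cdf[w2])
        p_ge = float(dist[w2:].sum())
        return TestResult(w, _two_sided_p(p_le, p_ge), "rank_sum_exact", n1 + n2)
    mean = n1 * (n1 + n2 + 1) / 2.0
    n = n1 + n2
    _, tie_counts = np.unique(ranks, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / ((n) * (n - 1))
    var = n1 * n2 / 12.0 * ((n + 1) - tie_term)
    z = w - mean
    z -= 0.5 * np.sign(z)
    z /= np.sqrt(var)
    p = float(min(1.0, 2.0 * sps.norm.sf(abs(z))))
    return TestResult(w, p, "rank_sum_normal", n1 + n2)


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg adjusted p-values (monotone, capped at 1)."""
    p = np.asarray(p_values, dtype=float)
    if len(p) == 0:
        return p
    return multipletests(p, method="fdr_bh")[1]


@dataclass(frozen=True)
class BoxplotSummary:
    """Tukey boxplot summary with notches.

    Hinges are type-7 (linear interpolation) quartiles; notches stretch to
    median -/+ 1.58 * IQR / sqrt(n), approximating a 95% CI of the median;
    whiskers extend to the most extreme data values within 1.5 * IQR of the
    hinges.
    """

    n: int
    median: float
    hinge_lo: float
    hinge_hi: float
    notch_lo: float
    notch_hi: float
    whisker_lo: float
    whisker_hi: float


def boxplot_summary(values) -> BoxplotSummary:
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if len(v) == 0:
        raise ValueError("no finite values")
    med = float(np.median(v))
    q1, q3 = (float(x) for x in np.quantile(v, [0.25, 0.75]))  # type-7
    iqr = q3 - q1
    half_notch = 1.58 * iqr / np.sqrt(len(v))
    lo_lim, hi_lim = q1 - 1.5 * iqr, q3 + 1.5 * iqr
    inside = v[(v >= lo_lim) & (v <= hi_lim)]
    return BoxplotSummary(
        n=len(v), median=med, hinge_lo=q1, hinge_hi=q3,
        notch_lo=med - half_notch, notch_hi=med + half_notch,
        whisker_lo=float(inside.min()), whisker_hi=float(inside.max()),
    )


def ma_table(counts: pd.DataFrame, size_factors: pd.Series,
             control_samples, treated_samples, pseudo: float = 1.0) -> pd.DataFrame:
    """Per-gene MA values from normalized counts.

    A (base_mean) is the mean normalized count over all samples; M
    (log2_fc) is log2((treated mean + pseudo) / (control mean + pseudo)).
    """
    sf = size_factors.reindex(counts.columns)
    if sf.isna().any() or (sf <= 0).any():
        raise ValueError("invalid size factors for MA table")
    norm = counts / sf
    mean_c = norm[list(control_samples)].mean(axis=1)
    mean_t = norm[list(treated_samples)].mean(axis=1)
    return pd.DataFrame(
        {
            "base_mean": norm.mean(axis=1),
            "mean_control": mean_c,
            "mean_treated": mean_t,
            "log2_fc": np.log2((mean_t + pseudo) / (mean_c + pseudo)),
        }
    )
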