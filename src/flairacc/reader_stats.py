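"""Paired ordinal statistics for the reader-study layer.

Implements the study's statistical toolkit: two-sided Wilcoxon signed-rank
tests (exact by enumeration for small samples, tie-corrected normal
approximation with continuity correction otherwise), Bonferroni adjustment,
and the two-way random-effects absolute-agreement single-measure intraclass
correlation ICC(2,1) with its F-based 95% confidence interval and the
conventional poor/moderate/good/excellent category labels.

The 4-point rating data this layer consumes are heavily tied; zero
differences are handled by the Pratt method by default (rank zeros with the
rest, then drop them from the statistic), which is the conservative choice
for such data.  The discard ("wilcox") policy is selectable.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

__all__ = [
    "RatingTable",
    "WilcoxonResult",
    "IccResult",
    "wilcoxon_signed_rank",
    "bonferroni_adjust",
    "icc_2_1",
    "classify_icc",
    "score_distribution",
]

RATING_SCALE = (1, 2, 3, 4)


@dataclass
class RatingTable:
    """Complete items x readers grid of ordinal scores on a 1-4 scale."""

    scores: pd.DataFrame  # index: item ids, columns: reader ids

    def __post_init__(self) -> None:
        vals = self.scores.to_numpy()
        if vals.size == 0:
            raise ValueError("rating table is empty")
        if np.any(pd.isna(vals)):
            raise ValueError("rating table has missing cells")
        if not np.isin(vals, RATING_SCALE).all():
            raise ValueError(f"all ratings must be in {RATING_SCALE}")

    @property
    def n_items(self) -> int:
        return self.scores.shape[0]

    @property
    def n_readers(self) -> int:
        return self.scores.shape[1]

    @classmethod
    def from_csv(cls, path) -> "RatingTable":
        return cls(pd.read_csv(path, index_col=0))

    def to_csv(self, path) -> None:
        self.scores.to_csv(path)


@dataclass
class WilcoxonResult:
    statistic: float  # W+: sum of ranks of positive differences
    p_value: float
    n: int
    n_nonzero: int
    mode: str
    degenerate: bool = False


@dataclass
class IccResult:
    estimate: float
    ci_low: float
    ci_high: float
    category: str | None
    n_items: int
    n_raters: int
    degenerate: bool = False


def _signed_ranks(diffs: np.ndarray, zero_policy: str):
    """Ranks of |d| (midranks for ties) and the W+ statistic.

    Pratt: zeros participate in the ranking, their ranks are then dropped.
    Wilcox: zeros are discarded before ranking.
    """
    if zero_policy not in ("pratt", "wilcox"):
        raise ValueError("zero_policy must be 'pratt' or 'wilcox'")
    if zero_policy == "wilcox":
        diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    nz = diffs != 0
    return ranks[nz], diffs[nz]


def _exact_wplus_pvalue(ranks: np.ndarray, w_plus: float) -> float:
    """Two-sided exact p by convolving the null distribution of W+ over all
    2^m sign assignments (midranks doubled to keep integer support)."""
    r2 = np.rint(2 * ranks).astype(np.int64)
    total = int(r2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in r2:
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt / 2.0  # each sign contributes probability 1/2
    w2 = int(np.rint(2 * w_plus))
    lower = dist[: w2 + 1].sum()
    upper = dist[w2:].sum()
    return float(min(1.0, 2.0 * min(lower, upper)))


def wilcoxon_signed_rank(
    a,
    b,
    zero_policy: str = "pratt",
    mode: str = "auto",
) -> WilcoxonResult:
    """Two-sided Wilcoxon signed-rank test for paired samples.

    ``mode``: ``"exact"`` enumerates the null distribution of the
    positive-rank sum (valid with ties and, under Pratt, zeros);
    ``"approx"`` uses the tie-corrected normal approximation with
    continuity correction; ``"auto"`` switches to exact for at most 12
    nonzero differences.  All-zero differences give a degenerate result
    with p = 1.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 1:
        raise ValueError("a and b must be equal-length 1D arrays")
    diffs = a - b
    n = diffs.size
    ranks, nz_diffs = _signed_ranks(diffs, zero_policy)
    m = ranks.size
    if m == 0:
        return WilcoxonResult(0.0, 1.0, n, 0, mode, degenerate=True)
    w_plus = float(ranks[nz_diffs > 0].sum())
    if mode == "auto":
        mode = "exact" if m <= 12 else "approx"
    if mode == "exact":
        p = _exact_wplus_pvalue(ranks, w_plus)
    elif mode == "approx":
        res = sps.wilcoxon(a, b, zero_method=zero_policy, correction=True,
                           alternative="two-sided", method="approx")
        p = float(res.pvalue)
    else:
        raise ValueError("mode must be 'exact', 'approx' or 'auto'")
    return WilcoxonResult(w_plus, p, n, m, mode)


def bonferroni_adjust(p_values, m: int | None = None) -> list[float]:
    """Bonferroni multiple-comparison adjustment: p -> min(1, m*p)."""
    p_values = list(p_values)
    if m is None:
        m = len(p_values)
    if m < len(p_values):
        raise ValueError("m must be at least the number of tests")
    for p in p_values:
        if not (0 <= p <= 1):
            raise ValueError(f"p value {p} outside [0, 1]")
    return [min(1.0, m * p) for p in p_values]


def icc_2_1(table: RatingTable | pd.DataFrame | np.ndarray,
            confidence: float = 0.95) -> IccResult:
    """ICC(2,1): two-way random effects, absolute agreement, single measure.

    From the two-way ANOVA mean squares (rows = items/targets, columns =
    raters)::

        ICC = (MSR - MSE) / (MSR + (k-1) MSE + (k/n) (MSC - MSE))

    with the F-based confidence interval of McGraw & Wong for this form.
    A table with zero variance everywhere is flagged degenerate.
    """
    if isinstance(table, RatingTable):
        x = table.scores.to_numpy(dtype=float)
    else:
        x = np.asarray(table, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need at least 2 items and 2 raters")
    n, k = x.shape
    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    sst = np.sum((x - grand) ** 2)
    if sst == 0:
        return IccResult(np.nan, np.nan, np.nan, None, n, k, degenerate=True)
    ssr = k * np.sum((row_mean - grand) ** 2)
    ssc = n * np.sum((col_mean - grand) ** 2)
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = max(sse / ((n - 1) * (k - 1)), 0.0)

    denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    icc = (msr - mse) / denom if denom != 0 else np.nan

    alpha = 1.0 - confidence
    if mse == 0 and msc == 0:
        lo = hi = 1.0  # exact agreement: the interval collapses
    else:
        a = (k * icc) / (n * (1.0 - icc)) if icc < 1 else np.inf
        bcoef = 1.0 + (k * icc * (n - 1)) / (n * (1.0 - icc)) if icc < 1 else np.inf
        if np.isfinite(a):
            v = (a * msc + bcoef * mse) ** 2 / (
                (a * msc) ** 2 / (k - 1)
                + (bcoef * mse) ** 2 / ((n - 1) * (k - 1)))
            f_lo = sps.f.ppf(1 - alpha / 2, n - 1, v)
            f_hi = sps.f.ppf(1 - alpha / 2, v, n - 1)
            common = (k * msc + (k * n - k - n) * mse)
            lo = n * (msr - f_lo * mse) / (f_lo * common + n * msr)
            hi = n * (f_hi * msr - mse) / (common + n * f_hi * msr)
        else:
            lo, hi = 1.0, 1.0
    lo, hi = float(min(lo, icc)), float(max(hi, icc))
    return IccResult(float(icc), lo, min(hi, 1.0), classify_icc(float(icc)), n, k)


def classify_icc(value: float) -> str:
    """Qualitative reliability label: < 0.50 poor; 0.50-0.75 moderate;
    (0.75, 0.90] good; > 0.90 excellent (boundaries assigned to the lower
    band's closed end)."""
    if value > 1:
        raise ValueError("ICC cannot exceed 1")
    if value < 0.50:
        return "poor"
    if value <= 0.75:
        return "moderate"
    if value <= 0.90:
        return "good"
    return "excellent"


def score_distribution(table: RatingTable, threshold: int = 3) -> float:
    """Percentage of (item, reader) scores at or above ``threshold``."""
    vals = table.scores.to_numpy()
    return float(100.0 * np.mean(vals >= threshold))
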