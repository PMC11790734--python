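"""Wilcoxon signed-rank, Bonferroni, ICC(2,1) and rating summaries."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats as sps

from flairacc.reader_stats import (IccResult, RatingTable, bonferroni_adjust,
                                   classify_icc, icc_2_1, score_distribution,
                                   wilcoxon_signed_rank)


# ---------------------------------------------------------------------------
# Wilcoxon
# ---------------------------------------------------------------------------

def brute_force_wilcoxon_p(diffs, zero_policy="pratt"):
    """Exact two-sided p by explicit enumeration of every sign assignment."""
    diffs = np.asarray(diffs, dtype=float)
    if zero_policy == "wilcox":
        diffs = diffs[diffs != 0]
    ranks = sps.rankdata(np.abs(diffs))
    nz = diffs != 0
    ranks_nz = ranks[nz]
    w_obs = ranks_nz[diffs[nz] > 0].sum()
    m = ranks_nz.size
    if m == 0:
        return 1.0
    ws = []
    for signs in itertools.product([0, 1], repeat=m):
        ws.append(sum(r for r, s in zip(ranks_nz, signs) if s))
    ws = np.asarray(ws)
    lower = np.mean(ws <= w_obs + 1e-9)
    upper = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lower, upper))


def test_wilcoxon_degenerate_all_zero():
    res = wilcoxon_signed_rank([2, 3, 4], [2, 3, 4])
    assert res.degenerate
    assert res.p_value == 1.0
    assert res.n_nonzero == 0


def test_wilcoxon_five_positive_differences_exact_tail():
    """n=5, all positive: one-sided tail 1/32, two-sided p = 1/16."""
    res = wilcoxon_signed_rank([2, 3, 4, 5, 6], [1, 2, 3, 4, 5], mode="exact")
    assert res.p_value == pytest.approx(0.0625)
    assert res.statistic == pytest.approx(15.0)


@settings(deadline=None, max_examples=40)
@given(
    n=st.integers(2, 10),
    seed=st.integers(0, 10_000),
    policy=st.sampled_from(["pratt", "wilcox"]),
)
def test_wilcoxon_exact_matches_enumeration(n, seed, policy):
    rng = np.random.default_rng(seed)
    a = rng.integers(1, 5, n).astype(float)
    b = rng.integers(1, 5, n).astype(float)
    if np.all(a == b):
        return
    res = wilcoxon_signed_rank(a, b, zero_policy=policy, mode="exact")
    assert res.p_value == pytest.approx(
        brute_force_wilcoxon_p(a - b, policy), abs=1e-12)


def test_wilcoxon_approx_mode_matches_scipy():
    rng = np.random.default_rng(3)
    a = rng.normal(0.2, 1.0, 40)
    b = rng.normal(0.0, 1.0, 40)
    res = wilcoxon_signed_rank(a, b, mode="approx")
    ref = sps.wilcoxon(a, b, zero_method="pratt", correction=True,
                       method="approx")
    assert res.p_value == pytest.approx(ref.pvalue)
    assert res.mode == "approx"


def test_wilcoxon_auto_switches_on_sample_size():
    small = wilcoxon_signed_rank([1, 2, 3], [3, 1, 2])
    assert small.mode == "exact"
    rng = np.random.default_rng(0)
    big = wilcoxon_signed_rank(rng.normal(size=30), rng.normal(size=30))
    assert big.mode == "approx"


def test_wilcoxon_input_validation():
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1, 2], [1, 2, 3])
    with pytest.raises(ValueError):
        wilcoxon_signed_rank([1], [2], zero_policy="drop-all")


# ---------------------------------------------------------------------------
# Bonferroni
# ---------------------------------------------------------------------------

def test_bonferroni_examples_and_cap():
    assert bonferroni_adjust([0.01], m=3) == [pytest.approx(0.03)]
    assert bonferroni_adjust([0.5], m=3) == [1.0]
    adj = bonferroni_adjust([0.01, 0.02, 0.04], m=3)
    assert adj == [pytest.approx(0.03), pytest.approx(0.06),
                   pytest.approx(0.12)]


@settings(deadline=None, max_examples=40)
@given(ps=st.lists(st.floats(0, 1), min_size=1, max_size=6))
def test_bonferroni_never_decreases_and_caps(ps):
    adj = bonferroni_adjust(ps)
    for p, a in zip(ps, adj):
        assert a >= p
        assert a <= 1.0


def test_bonferroni_validation():
    with pytest.raises(ValueError):
        bonferroni_adjust([1.2])
    with pytest.raises(ValueError):
        bonferroni_adjust([0.1, 0.2], m=1)


# ---------------------------------------------------------------------------
# ICC(2,1)
# ---------------------------------------------------------------------------

def oracle_icc_2_1(x):
    """Independent ANOVA mean-squares computation (explicit sums)."""
    x = np.asarray(x, dtype=float)
    n, k = x.shape
    grand = x.sum() / x.size
    msr = sum((x[i].sum() / k - grand) ** 2 for i in range(n)) * k / (n - 1)
    msc = sum((x[:, j].sum() / n - grand) ** 2 for j in range(k)) * n / (k - 1)
    sse = 0.0
    for i in range(n):
        for j in range(k):
            sse += (x[i, j] - x[i].sum() / k - x[:, j].sum() / n + grand) ** 2
    mse = sse / ((n - 1) * (k - 1))
    return (msr - mse) / (msr + (k - 1) * mse + k / n * (msc - mse))


def test_icc_perfect_agreement_is_one():
    x = np.tile(np.array([[1.0], [2.0], [3.0], [4.0]]), (1, 3))
    res = icc_2_1(x)
    assert res.estimate == pytest.approx(1.0)
    assert res.category == "excellent"


def test_icc_systematic_offset_penalized():
    items = np.arange(1, 11, dtype=float)
    x = np.column_stack([items, items + 1.0])
    res = icc_2_1(x)
    assert res.estimate < 1.0
    assert res.estimate == pytest.approx(oracle_icc_2_1(x), abs=1e-10)


def test_icc_random_table_matches_independent_oracle():
    rng = np.random.default_rng(7)
    x = rng.integers(1, 5, size=(100, 2)).astype(float)
    res = icc_2_1(x)
    assert res.estimate == pytest.approx(oracle_icc_2_1(x), abs=1e-10)
    assert res.ci_low <= res.estimate <= res.ci_high


def test_icc_matches_pingouin_reference_implementation():
    pingouin = pytest.importorskip("pingouin")
    rng = np.random.default_rng(11)
    latent = rng.normal(size=40)
    x = np.column_stack([latent + rng.normal(0, 0.5, 40) for _ in range(3)])
    df = pd.DataFrame(x, columns=list("abc")).reset_index().melt(
        id_vars="index", var_name="rater", value_name="score")
    ref = pingouin.intraclass_corr(data=df, targets="index", raters="rater",
                                   ratings="score").set_index("Type")
    row = ref.loc["ICC(A,1)"] if "ICC(A,1)" in ref.index else ref.loc["ICC2"]
    res = icc_2_1(x)
    assert res.estimate == pytest.approx(row["ICC"], abs=1e-8)
    ci_col = "CI95%" if "CI95%" in ref.columns else "CI95"
    lo, hi = row[ci_col]
    assert res.ci_low == pytest.approx(lo, abs=6e-3)  # pingouin rounds the CI
    assert res.ci_high == pytest.approx(hi, abs=6e-3)


def test_icc_invariant_under_relabeling():
    rng = np.random.default_rng(5)
    x = rng.integers(1, 5, size=(30, 3)).astype(float)
    base = icc_2_1(x).estimate
    perm_items = x[rng.permutation(30)]
    perm_raters = x[:, rng.permutation(3)]
    assert icc_2_1(perm_items).estimate == pytest.approx(base, abs=1e-12)
    assert icc_2_1(perm_raters).estimate == pytest.approx(base, abs=1e-12)


def test_icc_degenerate_zero_variance():
    res = icc_2_1(np.full((5, 3), 2.0))
    assert res.degenerate
    assert np.isnan(res.estimate)


def test_icc_validation():
    with pytest.raises(ValueError):
        icc_2_1(np.ones((1, 3)))


@pytest.mark.parametrize("value, label", [
    (0.798, "good"),      # reported reliability for the noise scores
    (0.462, "poor"),      # reported visibility reliability
    (0.50, "moderate"),
    (0.75, "moderate"),
    (0.90, "good"),
    (0.95, "excellent"),
    (-0.1, "poor"),
])
def test_icc_category_boundaries(value, label):
    assert classify_icc(value) == label


def test_icc_category_rejects_impossible_value():
    with pytest.raises(ValueError):
        classify_icc(1.2)


# ---------------------------------------------------------------------------
# rating tables
# ---------------------------------------------------------------------------

def _table(values):
    arr = np.asarray(values)
    return RatingTable(pd.DataFrame(
        arr, columns=[f"r{j}" for j in range(arr.shape[1])]))


def test_score_distribution_counting():
    assert score_distribution(_table(np.full((10, 3), 4))) == 100.0
    half = np.array([[2, 3]] * 10)
    assert score_distribution(_table(half)) == 50.0
    mostly = np.concatenate([np.full((97, 1), 3), np.full((3, 1), 2)])
    assert score_distribution(_table(mostly)) == pytest.approx(97.0)


def test_rating_table_validation():
    with pytest.raises(ValueError):
        _table(np.array([[0, 1], [2, 3]]))  # 0 outside the 1-4 scale
    with pytest.raises(ValueError):
        RatingTable(pd.DataFrame({"a": [1, np.nan]}))
    table = _table(np.array([[1, 2], [3, 4]]))
    assert table.n_items == 2 and table.n_readers == 2
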