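"""Hand-implemented tests vs independent oracles (scipy/statsmodels/enumeration)."""

import itertools
import math

import numpy as np
import pytest
import scipy.stats as sps
from hypothesis import given
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from melkquant import (
    ParameterError,
    cn_expression_report,
    holm_adjust,
    kendall_tau_b,
    kruskal_wallis,
    pearson_r,
    simulate_cn_expression,
    two_sample_t,
    wilcoxon_rank_sum,
)

RNG = np.random.default_rng(20240917)


# ---------------------------------------------------------------------------
# Pearson
# ---------------------------------------------------------------------------

def test_pearson_perfect_correlation():
    res = pearson_r([1, 2, 3, 4], [1, 2, 3, 4])
    assert res.statistic == 1.0
    assert res.p_value == 0.0


def test_pearson_matches_scipy_on_random_data():
    for _ in range(20):
        n = int(RNG.integers(5, 60))
        x = RNG.normal(size=n)
        y = 0.3 * x + RNG.normal(size=n)
        res = pearson_r(x, y)
        r_ref, p_ref = sps.pearsonr(x, y)
        assert res.statistic == pytest.approx(r_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)


def test_pearson_zero_variance_names_variable():
    with pytest.raises(ParameterError, match="x has zero variance"):
        pearson_r([1, 1, 1], [1, 2, 3])
    with pytest.raises(ParameterError, match="y has zero variance"):
        pearson_r([1, 2, 3], [2, 2, 2])


@given(st.floats(0.1, 10), st.floats(-5, 5))
def test_pearson_invariant_under_positive_affine_transforms(scale, shift):
    x = np.array([0.3, 1.2, -0.7, 2.4, 0.0, 1.1])
    y = np.array([0.1, 0.9, -1.1, 1.8, 0.4, 0.2])
    base = pearson_r(x, y).statistic
    assert pearson_r(scale * x + shift, y).statistic == pytest.approx(base, abs=1e-9)


# ---------------------------------------------------------------------------
# Kendall tau-b
# ---------------------------------------------------------------------------

def brute_force_tau_b(x, y):
    """O(n^2) pair counting straight from the definition."""
    n = len(x)
    concordant = discordant = ties_x = ties_y = 0
    for i, j in itertools.combinations(range(n), 2):
        dx, dy = x[i] - x[j], y[i] - y[j]
        if dx == 0 and dy == 0:
            ties_x += 1
            ties_y += 1
        elif dx == 0:
            ties_x += 1
        elif dy == 0:
            ties_y += 1
        elif dx * dy > 0:
            concordant += 1
        else:
            discordant += 1
    n0 = n * (n - 1) / 2
    return (concordant - discordant) / math.sqrt((n0 - ties_x) * (n0 - ties_y))


def test_tau_identical_order_and_reversal():
    x = [1, 2, 3, 4, 5]
    assert kendall_tau_b(x, [10, 20, 30, 40, 50]).statistic == pytest.approx(1.0)
    assert kendall_tau_b(x, [50, 40, 30, 20, 10]).statistic == pytest.approx(-1.0)


def test_tau_matches_brute_force_and_scipy_with_ties():
    for _ in range(30):
        n = int(RNG.integers(5, 31))
        x = RNG.integers(0, 5, size=n).astype(float)
        y = RNG.integers(0, 4, size=n).astype(float)
        if len(set(x)) < 2 or len(set(y)) < 2:
            continue
        res = kendall_tau_b(x, y)
        assert res.statistic == pytest.approx(brute_force_tau_b(x, y), abs=1e-12)
        tau_ref, p_ref = sps.kendalltau(x, y, method="asymptotic")
        assert res.statistic == pytest.approx(tau_ref, abs=1e-12)
        assert res.p_value == pytest.approx(p_ref, abs=1e-9)


def test_tau_antisymmetric_under_y_reversal():
    x = [1.0, 2.0, 2.0, 3.0, 5.0, 5.0]
    y = [2.0, 1.0, 4.0, 4.0, 3.0, 6.0]
    assert kendall_tau_b(x, [-v for v in y]).statistic == pytest.approx(
        -kendall_tau_b(x, y).statistic, abs=1e-12)


def test_tau_invariant_under_monotone_transform():
    x = [0.5, 1.5, 1.5, 3.0, 4.0]
    y = [1.0, 0.5, 2.5, 2.0, 5.0]
    base = kendall_tau_b(x, y).statistic
    assert kendall_tau_b([math.exp(v) for v in x], y).statistic == pytest.approx(base)


def test_tau_all_tied_rejected():
    with pytest.raises(ParameterError):
        kendall_tau_b([1, 1, 1], [1, 2, 3])


# ---------------------------------------------------------------------------
# Kruskal-Wallis
# ---------------------------------------------------------------------------

def test_kw_all_equal_convention():
    res = kruskal_wallis([[3.0, 3.0], [3.0, 3.0, 3.0]])
    assert res.statistic == 0.0 and res.p_value == 1.0


def test_kw_matches_scipy_with_ties():
    for _ in range(20):
        groups = [RNG.integers(0, 8, size=int(RNG.integers(3, 15))).astype(float)
                  for _ in range(int(RNG.integers(2, 5)))]
        if len(set(np.concatenate(groups))) < 2:
            continue
        res = kruskal_wallis(groups)
        h_ref, p_ref = sps.kruskal(*groups)
        assert res.statistic == pytest.approx(h_ref, rel=1e-12)
        assert res.p_value == pytest.approx(p_ref, rel=1e-9)


def test_kw_two_groups_consistent_with_rank_sum():
    a = RNG.normal(size=25).tolist()
    b = (RNG.normal(size=25) + 0.6).tolist()
    p_kw = kruskal_wallis([a, b]).p_value
    p_w = wilcoxon_rank_sum(a, b).p_value
    assert abs(p_kw - p_w) < 0.01


def test_kw_empty_group_rejected():
    with pytest.raises(ParameterError):
        kruskal_wallis([[1.0, 2.0], []])


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum
# ---------------------------------------------------------------------------

def exact_permutation_p(a, b):
    """Two-sided permutation p from full enumeration of rank assignments."""
    pooled = np.concatenate([a, b])
    ranks = sps.rankdata(pooled)
    n1 = len(a)
    mu = n1 * (len(pooled) + 1) / 2.0
    observed = abs(ranks[:n1].sum() - mu)
    count = total = 0
    for combo in itertools.combinations(range(len(pooled)), n1):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= observed - 1e-9:
            count += 1
    return count / total


def test_rank_sum_identical_samples():
    a = [1.0, 2.0, 3.0, 4.0]
    assert wilcoxon_rank_sum(a, list(a)).p_value > 0.95


def test_rank_sum_small_samples_use_exact_distribution():
    """Default small-sample p equals full enumeration; normal stays close."""
    for n1, n2 in [(4, 4), (5, 5), (6, 6), (5, 8), (8, 8)]:
        a = RNG.normal(size=n1)
        b = RNG.normal(size=n2) + 1.0
        reference = exact_permutation_p(a, b)
        assert wilcoxon_rank_sum(a, b).p_value == pytest.approx(reference, abs=1e-12)
        approx = wilcoxon_rank_sum(a, b, method="normal").p_value
        assert abs(approx - reference) < 0.05


def test_rank_sum_exact_method_agrees_with_enumeration():
    a = [1.0, 5.0, 2.0, 8.0]
    b = [3.0, 9.0, 11.0, 6.0, 7.0]
    res = wilcoxon_rank_sum(a, b, method="exact")
    assert res.p_value == pytest.approx(exact_permutation_p(a, b), abs=1e-12)


def test_rank_sum_p_decreases_with_shift_on_average():
    shifts = [0.0, 0.5, 1.0, 2.0]
    mean_ps = []
    for shift in shifts:
        ps = []
        for rep in range(40):
            rng = np.random.default_rng(1000 + rep)
            a = rng.normal(size=15)
            b = rng.normal(size=15) + shift
            ps.append(wilcoxon_rank_sum(a, b).p_value)
        mean_ps.append(np.mean(ps))
    assert mean_ps == sorted(mean_ps, reverse=True)


# ---------------------------------------------------------------------------
# Welch t
# ---------------------------------------------------------------------------

def test_t_identical_samples():
    a = [1.0, 2.0, 3.0]
    res = two_sample_t(a, list(a))
    assert res.statistic == 0.0 and res.p_value == pytest.approx(1.0)


def test_t_matches_hand_computation_and_scipy():
    a = [1.0, 2.0, 3.0]
    b = [2.0, 4.0, 6.0]
    res = two_sample_t(a, b)
    # hand: means 2 and 4, variances 1 and 4, se = sqrt(1/3 + 4/3)
    assert res.statistic == pytest.approx((2 - 4) / math.sqrt(5 / 3), rel=1e-12)
    t_ref, p_ref = sps.ttest_ind(a, b, equal_var=False)
    assert res.statistic == pytest.approx(t_ref, rel=1e-12)
    assert res.p_value == pytest.approx(p_ref, rel=1e-9)
    for _ in range(10):
        x = RNG.normal(size=int(RNG.integers(5, 30)))
        y = RNG.normal(size=int(RNG.integers(5, 30))) + 0.4
        mine = two_sample_t(x, y)
        t_ref, p_ref = sps.ttest_ind(x, y, equal_var=False)
        assert mine.statistic == pytest.approx(t_ref, rel=1e-10)
        assert mine.p_value == pytest.approx(p_ref, rel=1e-8)


def test_t_zero_variance_rejected():
    with pytest.raises(ParameterError):
        two_sample_t([2.0, 2.0], [5.0, 5.0])


# ---------------------------------------------------------------------------
# Holm
# ---------------------------------------------------------------------------

def test_holm_hand_example_and_degenerate_cases():
    assert holm_adjust([0.01, 0.04, 0.03]) == pytest.approx([0.03, 0.06, 0.06])
    assert holm_adjust([0.2]) == [0.2]
    assert holm_adjust([1.0, 1.0, 1.0]) == [1.0, 1.0, 1.0]
    assert holm_adjust([]) == []


def test_holm_matches_statsmodels_on_random_p():
    for _ in range(20):
        p = RNG.random(int(RNG.integers(1, 12))).tolist()
        expected = multipletests(p, method="holm")[1]
        assert holm_adjust(p) == pytest.approx(list(expected), abs=1e-12)


@given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=15))
def test_holm_dominates_input_and_preserves_order(p):
    adjusted = holm_adjust(p)
    assert all(0.0 <= q <= 1.0 for q in adjusted)
    assert all(q >= v for q, v in zip(adjusted, p))
    order = sorted(range(len(p)), key=lambda i: p[i])
    ranked = [adjusted[i] for i in order]
    assert ranked == sorted(ranked)


def test_holm_out_of_range_rejected():
    with pytest.raises(ParameterError):
        holm_adjust([0.5, 1.5])


# ---------------------------------------------------------------------------
# CN/expression driver
# ---------------------------------------------------------------------------

def test_report_flags_basal_shift_in_expression():
    df = simulate_cn_expression(
        n=400, target_r=0.3,
        subtype_effects={"basal": (0.0, 1.5), "luminal_A": (0.0, 0.0), "HER2": (0.0, 0.0)},
        proportions={"basal": 0.34, "luminal_A": 0.33, "HER2": 0.33},
        seed=5,
    )
    report = cn_expression_report(df)
    expr_ps = [row["p_holm"] for row in report["pairwise"]["log2_expr"]]
    cn_ps = [row["p_holm"] for row in report["pairwise"]["log2_cn"]]
    assert min(expr_ps) < 0.01
    assert min(expr_ps) < min(cn_ps)
    assert report["group_tests"]["log2_expr"]["p"] < 0.01


def test_report_null_p_roughly_uniform_under_label_permutation():
    rng = np.random.default_rng(3)
    ps = []
    for rep in range(100):
        df = simulate_cn_expression(
            n=60, target_r=0.3,
            subtype_effects={"basal": (0.0, 0.0), "luminal_A": (0.0, 0.0)},
            proportions={"basal": 0.5, "luminal_A": 0.5},
            seed=rep,
        )
        df["subtype"] = rng.permutation(df["subtype"].to_numpy())
        ps.append(cn_expression_report(df)["group_tests"]["log2_expr"]["p"])
    assert 0.25 < np.mean(ps) < 0.75
    assert (np.array(ps) < 0.05).mean() < 0.15


def test_report_requires_two_subtypes_and_reference():
    df = simulate_cn_expression(
        n=30, target_r=0.3,
        subtype_effects={"basal": (0.0, 0.0)}, proportions={"basal": 1.0}, seed=1)
    with pytest.raises(ParameterError):
        cn_expression_report(df)
    df2 = simulate_cn_expression(
        n=30, target_r=0.3,
        subtype_effects={"luminal_A": (0.0, 0.0), "HER2": (0.0, 0.0)},
        proportions={"luminal_A": 0.5, "HER2": 0.5}, seed=1)
    with pytest.raises(ParameterError):
        cn_expression_report(df2)
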