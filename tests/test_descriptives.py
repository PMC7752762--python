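"""Tests of the rank-based descriptive tests and table helpers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from wasatrial.descriptives import (
    dunn_bonferroni,
    fisher_exact_rxc,
    kruskal_wallis,
    proportion_endorsing,
)


def test_kruskal_wallis_hand_formula():
    """H = 12/(N(N+1)) * sum R_i^2/n_i - 3(N+1) on {1,2,3} vs {4,5,6}."""
    values = [1, 2, 3, 4, 5, 6]
    labels = ["a"] * 3 + ["b"] * 3
    H, df, p = kruskal_wallis(values, labels)
    assert H == pytest.approx(12 / (6 * 7) * (36 / 3 + 225 / 3) - 3 * 7, abs=1e-12)
    assert H == pytest.approx(3.857, abs=5e-4)
    assert df == 1


def test_kruskal_wallis_identical_values():
    H, df, p = kruskal_wallis([2.0] * 9, ["a"] * 3 + ["b"] * 3 + ["c"] * 3)
    assert H == 0.0 and p == 1.0


def test_kruskal_wallis_two_groups_equals_wilcoxon_chi_square():
    """For k = 2, H is the squared standardized rank-sum statistic."""
    rng = np.random.default_rng(3)
    x = rng.normal(size=12)
    y = rng.normal(1.0, 1.0, size=9)
    values = np.r_[x, y]
    labels = ["x"] * 12 + ["y"] * 9
    H, _, _ = kruskal_wallis(values, labels)
    ranks = stats.rankdata(values)
    n1, n2, N = 12, 9, 21
    R1 = ranks[:12].sum()
    z2 = (R1 - n1 * (N + 1) / 2) ** 2 / (n1 * n2 * (N + 1) / 12)
    assert H == pytest.approx(z2, rel=1e-10)


@given(st.lists(st.integers(-50, 50), min_size=6, max_size=24))
@settings(max_examples=40, deadline=None, derandomize=True)
def test_kruskal_wallis_monotone_invariance(values):
    labels = (["a", "b", "c"] * 8)[: len(values)]
    if len(set(values)) < 2:
        return
    H1, _, _ = kruskal_wallis(values, labels)
    H2, _, _ = kruskal_wallis(np.exp(np.asarray(values, dtype=float) / 10), labels)
    assert H1 == pytest.approx(H2, abs=1e-9)


def test_dunn_null_and_pair_count():
    values = [2.0] * 12
    labels = ["a", "b", "c", "d"] * 3
    res = dunn_bonferroni(values, labels)
    assert len(res.pairs) == 6  # 4 groups -> 6 pairs, Bonferroni factor 6
    assert (res.pairs["p_bonferroni"] == 1.0).all()
    assert all(v == "" for v in res.letters.values())


def test_dunn_flags_extreme_group_matching_permutation_oracle():
    """Only the pairs involving the shifted group are significant, and the
    same decisions come from a 10^4-draw permutation oracle."""
    rng = np.random.default_rng(11)
    groups = {"a": rng.normal(0, 1, 15), "b": rng.normal(0, 1, 15),
              "c": rng.normal(0, 1, 15), "d": rng.normal(8, 1, 15)}
    values = np.concatenate(list(groups.values()))
    labels = np.repeat(list(groups), [len(v) for v in groups.values()])
    res = dunn_bonferroni(values, labels)
    flagged = {
        tuple(sorted((r.group_a, r.group_b)))
        for r in res.pairs.itertuples()
        if r.significant
    }
    assert flagged == {("a", "d"), ("b", "d"), ("c", "d")}

    # permutation oracle, computed directly from mean-rank differences:
    # ranks are fixed, only the label assignment is shuffled; with equal
    # group sizes |z| is proportional to |mean-rank difference|, so the
    # permutation test on the difference decides the same hypotheses
    ranks = stats.rankdata(values)
    names = list(groups)
    sizes = np.array([len(groups[g]) for g in names])
    group_codes = np.repeat(np.arange(4), sizes)
    pair_idx = [(i, j) for i in range(4) for j in range(i + 1, 4)]
    sums_obs = np.bincount(group_codes, weights=ranks, minlength=4)
    means_obs = sums_obs / sizes
    obs_diff = {
        tuple(sorted((names[i], names[j]))): abs(means_obs[i] - means_obs[j])
        for i, j in pair_idx
    }
    n_perm = 10_000
    counts = {k: 0 for k in obs_diff}
    for _ in range(n_perm):
        perm_codes = rng.permutation(group_codes)
        means = np.bincount(perm_codes, weights=ranks, minlength=4) / sizes
        for i, j in pair_idx:
            key = tuple(sorted((names[i], names[j])))
            if abs(means[i] - means[j]) >= obs_diff[key] - 1e-12:
                counts[key] += 1
    for key, c in counts.items():
        p_perm = min(1.0, 6 * c / n_perm)
        assert (p_perm < 0.05) == (key in flagged)


def test_fisher_2x2_exact_value():
    """[[3,1],[1,3]]: full hypergeometric enumeration gives p = 34/70."""
    p, se = fisher_exact_rxc([[3, 1], [1, 3]])
    assert se is None
    assert p == pytest.approx(34 / 70, abs=1e-12)


@pytest.mark.parametrize(
    "table",
    [[[3, 1], [1, 3]], [[10, 2], [3, 9]], [[5, 5], [5, 5]], [[1, 9], [9, 1]], [[0, 5], [5, 3]]],
)
def test_fisher_2x2_agrees_with_classical_rule(table):
    p_mine, _ = fisher_exact_rxc(table)
    _, p_scipy = stats.fisher_exact(table, alternative="two-sided")
    assert p_mine == pytest.approx(p_scipy, abs=1e-12)


def test_fisher_zero_margin_invariance():
    p_with, _ = fisher_exact_rxc([[3, 1], [0, 0], [1, 3]])
    p_without, _ = fisher_exact_rxc([[3, 1], [1, 3]])
    assert p_with == pytest.approx(p_without, abs=1e-12)


def test_fisher_identical_rows_no_association():
    p, _ = fisher_exact_rxc([[4, 4], [4, 4]])
    assert p == pytest.approx(1.0)


def test_fisher_2x6_food_attitude_table():
    """A full-size 2x6 attitude table exceeds the enumeration budget and is
    estimated by margin-preserving Monte Carlo; the association is strong."""
    table = [[45, 157, 107, 32, 5, 0], [23, 79, 115, 43, 3, 0]]
    p, se = fisher_exact_rxc(table, rng=np.random.default_rng(9))
    assert se is not None and se < 1e-3
    assert p < 0.001  # women skew toward rating low-fat food as important

    # a down-scaled version of the same table enumerates exactly
    small = [[5, 16, 11, 3, 1], [2, 8, 12, 4, 1]]
    p_small, se_small = fisher_exact_rxc(small)
    assert se_small is None and 0 <= p_small <= 1


def test_fisher_monte_carlo_consistent_with_enumeration():
    table = [[8, 3, 5], [2, 7, 4]]
    p_exact, _ = fisher_exact_rxc(table)
    p_mc, se = fisher_exact_rxc(
        table, max_enumeration=1, rng=np.random.default_rng(4), n_monte_carlo=100_000
    )
    assert se is not None
    assert abs(p_mc - p_exact) < 5 * se + 1e-3


def test_fisher_rejects_bad_tables():
    with pytest.raises(ValueError):
        fisher_exact_rxc([[1.5, 2.0], [1.0, 2.0]])
    with pytest.raises(ValueError):
        fisher_exact_rxc([[-1, 2], [3, 4]])


def test_proportions_from_printed_counts():
    """Endorsement percentages recompute exactly from category counts with
    missing responses kept in the denominator."""
    women = {"very": 45, "moderately": 157, "little": 107, "not": 32, "missing": 5}
    men = {"very": 23, "moderately": 79, "little": 115, "not": 43, "missing": 3}
    pct_w, disp_w = proportion_endorsing(women, ["very", "moderately"])
    pct_m, disp_m = proportion_endorsing(men, ["very", "moderately"])
    assert sum(women.values()) == 346 and sum(men.values()) == 263
    assert disp_w == 58 and disp_m == 39
    assert pct_w == pytest.approx(100 * 202 / 346)
    pct_empty, disp_empty = proportion_endorsing(women, [])
    assert pct_empty == 0.0 and disp_empty == 0
    with pytest.raises(ValueError, match="unknown category"):
        proportion_endorsing(women, ["nonexistent"])
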