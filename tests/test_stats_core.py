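"""Unit and oracle tests for the shared statistical primitives.

Enumeration oracles are implemented here, independently of the package, and
frozen expected values were computed with them.
"""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from ladomics.stats_core import (
    ONE_SIDED_GREATER,
    bh_adjust,
    bootstrap_ci,
    fisher_exact,
    kruskal_wallis,
    spearman_corr,
    wilcoxon_rank_sum,
)


# ---------------------------------------------------------------------------
# oracles

def hypergeom_2x2_two_sided(table):
    """Two-sided Fisher p by explicit hypergeometric enumeration."""
    (a, b), (c, d) = table
    r1, c1, n = a + b, a + c, a + b + c + d

    def prob(x):
        return (
            math.comb(c1, x)
            * math.comb(n - c1, r1 - x)
            / math.comb(n, r1)
        )

    p_obs = prob(a)
    total = 0.0
    for x in range(max(0, r1 - (n - c1)), min(r1, c1) + 1):
        p = prob(x)
        if p <= p_obs * (1 + 1e-9):
            total += p
    return min(total, 1.0)


def fisher_2x3_oracle(table):
    """Two-sided exact p for a 2x3 table: full enumeration of the fiber."""
    table = np.asarray(table)
    r1 = table[0].sum()
    cols = table.sum(axis=0)
    n = table.sum()

    def prob(a, b, c):
        return (
            math.comb(cols[0], a) * math.comb(cols[1], b) * math.comb(cols[2], c)
            / math.comb(n, r1)
        )

    p_obs = prob(*table[0])
    total = 0.0
    for a in range(min(r1, cols[0]) + 1):
        for b in range(min(r1 - a, cols[1]) + 1):
            c = r1 - a - b
            if 0 <= c <= cols[2]:
                p = prob(a, b, c)
                if p <= p_obs * (1 + 1e-9):
                    total += p
    return min(total, 1.0)


def ranksum_exact_oracle(x, y, greater=True):
    """Exact one-sided rank-sum p by enumerating all rank assignments."""
    pooled = list(x) + list(y)
    nx = len(x)
    obs = sum(sorted(pooled).index(v) + 1 for v in x)  # no ties assumed
    count = 0
    total = 0
    for combo in itertools.combinations(range(1, len(pooled) + 1), nx):
        total += 1
        s = sum(combo)
        if (greater and s >= obs) or (not greater and s <= obs):
            count += 1
    return count / total


def bh_oracle(p):
    """BH q-values straight from the min-over-thresholds definition."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    running = np.inf
    for rank_from_top in range(m, 0, -1):
        idx = order[rank_from_top - 1]
        running = min(running, m * p[idx] / rank_from_top)
        q[idx] = min(running, 1.0)
    return q


# ---------------------------------------------------------------------------
# Fisher

def test_fisher_2x2_example():
    res = fisher_exact([[1, 9], [11, 3]])
    assert res.p_value == pytest.approx(0.00276, abs=2e-5)


def test_fisher_proportional_rows_p_one():
    assert fisher_exact([[2, 4], [3, 6]]).p_value == pytest.approx(1.0)
    assert fisher_exact([[1, 2, 3], [2, 4, 6]]).p_value == pytest.approx(1.0)


def test_fisher_2x3_matches_enumeration_oracle(rng):
    for _ in range(50):
        table = rng.integers(0, 8, size=(2, 3))
        if table.sum() == 0:
            continue
        assert fisher_exact(table).p_value == pytest.approx(
            fisher_2x3_oracle(table), rel=1e-8
        )


def test_fisher_2x3_fixed_example():
    # value computed with the enumeration oracle above
    table = [[2, 0, 0], [0, 2, 2]]
    assert fisher_2x3_oracle(table) == pytest.approx(0.2)
    assert fisher_exact(table).p_value == pytest.approx(0.2)


def test_fisher_2x2_exhaustive_small_margins():
    """2x2 test equals hypergeometric enumeration for all margins <= 15."""
    checked = 0
    for r1 in range(1, 16):
        for r2 in range(1, 16):
            for c1 in range(max(1, r1 + r2 - 15), min(15, r1 + r2) + 1):
                for a in range(max(0, c1 - r2), min(r1, c1) + 1):
                    table = [[a, r1 - a], [c1 - a, r2 - (c1 - a)]]
                    expected = hypergeom_2x2_two_sided(table)
                    got = fisher_exact(table).p_value
                    assert got == pytest.approx(expected, rel=1e-7, abs=1e-12)
                    checked += 1
    assert checked > 10_000


def test_fisher_one_sided_requires_2x2():
    with pytest.raises(ValueError):
        fisher_exact([[1, 2, 3], [4, 5, 6]], ONE_SIDED_GREATER)


def test_fisher_rejects_bad_cells():
    with pytest.raises(ValueError):
        fisher_exact([[1, -1], [2, 3]])
    with pytest.raises(ValueError):
        fisher_exact([[1.5, 1], [2, 3]])


# ---------------------------------------------------------------------------
# Kruskal-Wallis

def test_kruskal_wallis_hand_example():
    res = kruskal_wallis([[1, 2], [3, 4], [5, 6]])
    assert res.statistic == pytest.approx(32 / 7)


def test_kruskal_wallis_identical_values():
    res = kruskal_wallis([[2, 2], [2, 2]])
    assert res.statistic == 0.0
    assert res.p_value == 1.0


def test_kruskal_wallis_null_p_roughly_uniform(rng):
    pvals = []
    for _ in range(400):
        x = rng.normal(size=15)
        groups = [x[:5], x[5:10], x[10:]]
        pvals.append(kruskal_wallis(groups).p_value)
    frac = np.mean(np.asarray(pvals) < 0.05)
    assert 0.01 <= frac <= 0.10


# ---------------------------------------------------------------------------
# Wilcoxon rank-sum

def test_ranksum_exact_small_example():
    res = wilcoxon_rank_sum([3, 4], [1, 2], ONE_SIDED_GREATER)
    assert res.p_value == pytest.approx(1 / 6)
    assert res.p_value == pytest.approx(ranksum_exact_oracle([3, 4], [1, 2]))


def test_ranksum_equal_multisets_one_sided_at_least_half():
    res = wilcoxon_rank_sum([1.0, 2.5, 3.5], [3.5, 1.0, 2.5], ONE_SIDED_GREATER)
    assert res.p_value >= 0.5


def test_ranksum_swap_symmetry_exact_case(rng):
    """For exact no-tie samples, p(x>y) + p(y>x) = 1 + P(tie in rank sum)."""
    for _ in range(10):
        vals = rng.permutation(np.arange(1.0, 9.0))
        x, y = vals[:4], vals[4:]
        px = wilcoxon_rank_sum(x, y, ONE_SIDED_GREATER).p_value
        py = wilcoxon_rank_sum(y, x, ONE_SIDED_GREATER).p_value
        p_ge = ranksum_exact_oracle(x, y, greater=True)
        p_le = ranksum_exact_oracle(x, y, greater=False)
        tie_mass = p_ge + p_le - 1.0
        assert px + py == pytest.approx(1.0 + tie_mass, abs=1e-9)


# ---------------------------------------------------------------------------
# Benjamini-Hochberg

def test_bh_forced_example():
    assert bh_adjust([0.01, 0.02, 0.03]) == pytest.approx([0.03, 0.03, 0.03])


def test_bh_single_p():
    assert bh_adjust([0.2]) == pytest.approx([0.2])


def test_bh_matches_bruteforce_definition(rng):
    for _ in range(1000):
        p = rng.random(size=rng.integers(1, 25))
        assert bh_adjust(p) == pytest.approx(bh_oracle(p))


def test_bh_rejects_out_of_range():
    with pytest.raises(ValueError):
        bh_adjust([0.5, 1.2])


@settings(deadline=None, max_examples=50, derandomize=True)
@given(
    st.lists(st.floats(min_value=0.0, max_value=1.0), min_size=2, max_size=30)
)
def test_bh_monotone_and_bounded(pvals):
    q = bh_adjust(pvals)
    assert np.all((q >= 0) & (q <= 1))
    order = np.argsort(pvals)
    assert np.all(np.diff(np.asarray(q)[order]) >= -1e-12)


# ---------------------------------------------------------------------------
# Spearman

def test_spearman_extremes():
    assert spearman_corr([1, 2, 3, 4], [2, 4, 6, 8]).statistic == pytest.approx(1.0)
    assert spearman_corr([1, 2, 3, 4], [8, 6, 4, 2]).statistic == pytest.approx(-1.0)


def test_spearman_equals_pearson_of_ranks():
    x = [10.0, 3.0, 7.0, 1.0]
    y = [2.0, 9.0, 4.0, 8.0]
    rx = np.argsort(np.argsort(x)) + 1.0
    ry = np.argsort(np.argsort(y)) + 1.0
    expected = np.corrcoef(rx, ry)[0, 1]
    assert spearman_corr(x, y).statistic == pytest.approx(expected)


def test_spearman_zero_variance_flagged():
    res = spearman_corr([1, 1, 1], [1, 2, 3])
    assert np.isnan(res.statistic)
    assert res.flag


# ---------------------------------------------------------------------------
# bootstrap

def test_bootstrap_constant_vector():
    lo, hi = bootstrap_ci([5.0] * 20, "median", n_reps=200, seed=0)
    assert lo == hi == 5.0


def test_bootstrap_seeded_determinism(rng):
    v = rng.normal(size=50)
    assert bootstrap_ci(v, "mean", seed=42) == bootstrap_ci(v, "mean", seed=42)


def test_bootstrap_mean_ci_coverage(rng):
    covered = 0
    n_outer = 200
    for _ in range(n_outer):
        v = rng.normal(size=200)
        lo, hi = bootstrap_ci(v, "mean", n_reps=300, seed=rng)
        covered += lo <= 0.0 <= hi
    assert covered / n_outer == pytest.approx(0.95, abs=0.05)


def test_bootstrap_rejects_empty_and_few_reps():
    with pytest.raises(ValueError):
        bootstrap_ci([], "mean")
    with pytest.raises(ValueError):
        bootstrap_ci([1.0], "mean", n_reps=10)
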