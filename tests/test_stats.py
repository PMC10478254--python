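"""Exact tests against brute-force enumeration oracles and scipy cross-checks."""

import itertools
import math

import numpy as np
import pytest
from scipy import stats as sps

from stresstrata.stats import (
    ContingencyTable,
    bh_adjust,
    fisher_exact_2x2,
    fisher_exact_rxc,
    mann_whitney_u,
    student_t,
)


def mwu_enumeration_oracle(x, y):
    """Exact two-sided p by brute-force enumeration of rank splits."""
    pooled = sorted(list(x) + list(y))
    n, nx = len(pooled), len(x)
    assert len(set(pooled)) == n, "oracle valid only without ties"
    ranks_x = [pooled.index(v) + 1 for v in x]
    u_obs = sum(ranks_x) - nx * (nx + 1) / 2
    us = []
    for combo in itertools.combinations(range(1, n + 1), nx):
        us.append(sum(combo) - nx * (nx + 1) / 2)
    us = np.array(us)
    p_le = np.mean(us <= u_obs)
    p_ge = np.mean(us >= u_obs)
    return min(1.0, 2 * min(p_le, p_ge))


def fisher_2x2_oracle(a, b, c, d):
    """Minimum-likelihood two-sided p from factorial enumeration."""
    r1, r2, c1 = a + b, c + d, a + c
    n = r1 + r2

    def prob(k):
        return (
            math.comb(r1, k) * math.comb(r2, c1 - k) / math.comb(n, c1)
        )

    p_obs = prob(a)
    total = 0.0
    for k in range(max(0, c1 - r2), min(c1, r1) + 1):
        pk = prob(k)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(1.0, total)


def fisher_3x2_oracle(table):
    """Full enumeration of 3×2 tables by independent nested loops."""
    arr = np.asarray(table)
    rows = arr.sum(axis=1)
    cols = arr.sum(axis=0)
    n = arr.sum()

    def log_p(t):
        return (
            sum(math.lgamma(r + 1) for r in rows)
            + sum(math.lgamma(c + 1) for c in cols)
            - math.lgamma(n + 1)
            - sum(math.lgamma(v + 1) for v in np.ravel(t))
        )

    lp_obs = log_p(arr)
    total = 0.0
    for a in range(min(rows[0], cols[0]) + 1):
        b = rows[0] - a
        if b > cols[1]:
            continue
        for c in range(min(rows[1], cols[0] - a) + 1):
            d = rows[1] - c
            if d > cols[1] - b:
                continue
            e = cols[0] - a - c
            f = cols[1] - b - d
            if e < 0 or f < 0 or e + f != rows[2]:
                continue
            t = [[a, b], [c, d], [e, f]]
            lp = log_p(t)
            if lp <= lp_obs + 1e-9:
                total += math.exp(lp)
    return min(1.0, total)


class TestMannWhitney:
    def test_worked_example(self):
        res = mann_whitney_u([1, 2], [3, 4])
        assert res.statistic == 0.0
        assert res.p_two_sided == pytest.approx(1 / 3)
        assert "exact" in res.method

    def test_identical_samples_p_one(self):
        res = mann_whitney_u([1, 2, 3], [1, 2, 3])
        assert res.p_two_sided == pytest.approx(1.0)

    def test_exact_path_matches_enumeration_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(40):
            nx, ny = rng.integers(1, 7, size=2)
            x = rng.normal(size=nx)
            y = rng.normal(size=ny)
            res = mann_whitney_u(x, y)
            assert res.p_two_sided == pytest.approx(mwu_enumeration_oracle(x, y))

    def test_exact_path_matches_scipy_exact(self):
        rng = np.random.default_rng(1)
        for _ in range(20):
            x = rng.normal(size=5)
            y = rng.normal(size=6)
            res = mann_whitney_u(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_approximate_path_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=15)
        y = rng.normal(1.0, 1.0, size=14)
        res = mann_whitney_u(x, y)
        ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                               method="asymptotic", use_continuity=True)
        assert "approximation" in res.method
        assert res.p_two_sided == pytest.approx(ref.pvalue, rel=1e-9)

    def test_effect_size_definition(self):
        # perfect separation at n = 4 + 4: |Z| = (8 - 0.5)/sqrt(12)
        res = mann_whitney_u([1, 2, 3, 4], [5, 6, 7, 8])
        z = (8 - 0.5) / math.sqrt(4 * 4 * 9 / 12)
        assert res.effect_size_r == pytest.approx(z / math.sqrt(8))
        assert 0 <= res.effect_size_r <= 1

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError):
            mann_whitney_u([], [1.0])


class TestFisher2x2:
    def test_worked_examples(self):
        res = fisher_exact_2x2(ContingencyTable.from_array([[0, 3], [4, 0]]))
        assert res.p_two_sided == pytest.approx(1 / 35)
        res = fisher_exact_2x2(ContingencyTable.from_array([[1, 1], [1, 1]]))
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_enumeration_oracle_on_grid(self):
        for a in range(0, 6):
            for b in range(0, 6):
                for c in range(0, 6):
                    for d in range(0, 6):
                        if a + b + c + d == 0:
                            continue
                        res = fisher_exact_2x2(
                            ContingencyTable.from_array([[a, b], [c, d]])
                        )
                        assert res.p_two_sided == pytest.approx(
                            fisher_2x2_oracle(a, b, c, d), abs=1e-12
                        )

    def test_matches_scipy(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            t = rng.integers(0, 10, size=(2, 2))
            if t.sum() == 0:
                continue
            res = fisher_exact_2x2(ContingencyTable.from_array(t))
            assert res.p_two_sided == pytest.approx(
                sps.fisher_exact(t)[1], abs=1e-10
            )

    def test_permutation_invariance(self):
        t = [[2, 5], [7, 1]]
        base = fisher_exact_2x2(ContingencyTable.from_array(t)).p_two_sided
        for perm in ([[5, 2], [1, 7]], [[7, 1], [2, 5]]):
            assert fisher_exact_2x2(
                ContingencyTable.from_array(perm)
            ).p_two_sided == pytest.approx(base)

    def test_non_integer_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            ContingencyTable.from_array([[0.5, 1], [1, 1]])


class TestFisherRxC:
    def test_unique_completion_p_one(self):
        res = fisher_exact_rxc(ContingencyTable.from_array([[2, 0], [3, 0], [1, 0]]))
        assert res.p_two_sided == pytest.approx(1.0)

    def test_matches_2x2_path(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            t = rng.integers(0, 8, size=(2, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_rxc(
                ContingencyTable.from_array(t)
            ).p_two_sided == pytest.approx(
                fisher_exact_2x2(ContingencyTable.from_array(t)).p_two_sided,
                abs=1e-10,
            )

    def test_matches_3x2_brute_force(self):
        res = fisher_exact_rxc(ContingencyTable.from_array([[1, 0], [0, 1], [1, 1]]))
        assert res.p_two_sided == pytest.approx(
            fisher_3x2_oracle([[1, 0], [0, 1], [1, 1]])
        )
        rng = np.random.default_rng(5)
        for _ in range(15):
            t = rng.integers(0, 4, size=(3, 2))
            if t.sum() == 0:
                continue
            assert fisher_exact_rxc(
                ContingencyTable.from_array(t)
            ).p_two_sided == pytest.approx(fisher_3x2_oracle(t), abs=1e-10)

    def test_row_permutation_invariance(self):
        t = [[3, 1], [0, 2], [2, 2]]
        base = fisher_exact_rxc(ContingencyTable.from_array(t)).p_two_sided
        assert fisher_exact_rxc(
            ContingencyTable.from_array([[0, 2], [2, 2], [3, 1]])
        ).p_two_sided == pytest.approx(base)

    def test_total_bound_enforced(self):
        big = np.full((3, 2), 20)
        with pytest.raises(ValueError, match="Monte-Carlo"):
            fisher_exact_rxc(ContingencyTable.from_array(big))


class TestStudentT:
    def test_identical_samples(self):
        res = student_t([1, 2, 3], [1, 2, 3])
        assert res.statistic == 0.0
        assert res.p_two_sided == 1.0

    def test_antisymmetry(self):
        rng = np.random.default_rng(6)
        x, y = rng.normal(size=8), rng.normal(0.5, 1, size=9)
        a, b = student_t(x, y), student_t(y, x)
        assert a.statistic == pytest.approx(-b.statistic)
        assert a.p_two_sided == pytest.approx(b.p_two_sided)

    def test_matches_scipy_pooled(self):
        rng = np.random.default_rng(7)
        for _ in range(10):
            x = rng.normal(size=6)
            y = rng.normal(0.8, 1.3, size=9)
            res = student_t(x, y)
            ref = sps.ttest_ind(x, y, equal_var=True)
            assert res.statistic == pytest.approx(ref.statistic)
            assert res.p_two_sided == pytest.approx(ref.pvalue)

    def test_degenerate_variance_conventions(self):
        assert student_t([2, 2], [2, 2]).p_two_sided == 1.0
        with pytest.warns(UserWarning, match="zero pooled variance"):
            assert student_t([1, 1], [2, 2]).p_two_sided == 0.0


class TestBH:
    def test_worked_example(self):
        assert np.allclose(bh_adjust([0.01, 0.02, 0.03, 0.04]), [0.04] * 4)

    def test_single_p_unchanged(self):
        assert bh_adjust([0.37])[0] == pytest.approx(0.37)

    def test_matches_hand_cummin_oracle(self):
        rng = np.random.default_rng(8)
        p = rng.uniform(size=25)
        m = len(p)
        order = np.argsort(p)
        raw = p[order] * m / np.arange(1, m + 1)
        q_sorted = np.minimum.accumulate(raw[::-1])[::-1]
        oracle = np.empty(m)
        oracle[order] = np.minimum(q_sorted, 1.0)
        assert np.allclose(bh_adjust(p), oracle)

    def test_output_dominates_input(self):
        rng = np.random.default_rng(9)
        p = rng.uniform(size=50)
        q = bh_adjust(p)
        assert np.all(q >= p) and np.all(q <= 1.0)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust([0.5, 1.2])
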