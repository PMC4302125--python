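import math

import numpy as np
import pytest

from bipolarmeth.grouping import BipolarGroups
from bipolarmeth.permtest import (
    BipolarTestResult,
    db_inverse_statistic,
    fisher_dm_cpg,
    parametric_test,
    permutation_pvalue,
)

from _oracles import db_statistic, exact_permutation_pvalue, fisher_two_sided


def _groups(g1_idx, g2_idx, reads):
    g1_idx = np.asarray(g1_idx)
    g2_idx = np.asarray(g2_idx)
    m = len(g1_idx) + len(g2_idx)
    return BipolarGroups(
        g1_members=g1_idx,
        g2_members=g2_idx,
        g1_mean=reads[g1_idx].mean(0),
        g2_mean=reads[g2_idx].mean(0),
        h1=None,
        h2=None,
        provenance=np.full(m, "candidate", dtype=object),
        delta=None,
        method="delta",
    )


class TestDbInverseStatistic:
    def test_perfect_separation_is_huge_but_finite(self):
        g1 = np.ones((4, 4))
        g2 = np.zeros((4, 4))
        score = db_inverse_statistic(g1, g2, tau=0.0, eps=1e-8)
        assert score == pytest.approx(2.0 / 1e-8)
        assert math.isfinite(score)

    def test_identical_groups_score_zero(self):
        g = np.array([[1, 0, 1, 0], [0, 1, 0, 1]])
        assert db_inverse_statistic(g, g, tau=0.0) == 0.0

    def test_larger_tau_is_more_conservative(self, rng):
        g1 = rng.integers(0, 2, size=(6, 4))
        g2 = rng.integers(0, 2, size=(6, 4))
        assert db_inverse_statistic(g1, g2, tau=0.32) <= db_inverse_statistic(
            g1, g2, tau=0.0
        )

    def test_invariant_to_within_group_order_and_joint_column_permutation(self, rng):
        g1 = rng.integers(0, 2, size=(5, 4))
        g2 = rng.integers(0, 2, size=(7, 4))
        base = db_inverse_statistic(g1, g2, tau=0.1)
        assert db_inverse_statistic(g1[::-1], g2[::-1], tau=0.1) == pytest.approx(base)
        cols = rng.permutation(4)
        assert db_inverse_statistic(g1[:, cols], g2[:, cols], tau=0.1) == pytest.approx(
            base
        )

    def test_matches_independent_implementation(self, rng):
        for _ in range(10):
            g1 = rng.integers(0, 2, size=(int(rng.integers(1, 6)), 4))
            g2 = rng.integers(0, 2, size=(int(rng.integers(1, 6)), 4))
            tau = float(rng.uniform(0, 0.5))
            assert db_inverse_statistic(g1, g2, tau) == pytest.approx(
                db_statistic(g1, g2, tau)
            )

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            db_inverse_statistic(np.zeros((0, 4)), np.ones((2, 4)))


class TestPermutationPvalue:
    def test_strong_bipolar_sixteen_reads_hits_floor(self, pure_bipolar_reads):
        groups = _groups(np.arange(8), np.arange(8, 16), pure_bipolar_reads)
        res = permutation_pvalue(
            pure_bipolar_reads, groups, tau=0.32, n_permutations=999, rng=0
        )
        # C(16, 8) > 5000 -> Monte-Carlo with add-one estimator
        assert res.p_value == pytest.approx(1 / 1000)
        assert not res.exact and res.call

    def test_exact_enumeration_matches_bruteforce(self, rng):
        for trial in range(6):
            m = int(rng.integers(6, 11))
            n1 = int(rng.integers(2, m - 1))
            reads = rng.integers(0, 2, size=(m, 4))
            g1 = np.arange(n1)
            groups = _groups(g1, np.arange(n1, m), reads)
            for margin in (False, True):
                res = permutation_pvalue(
                    reads, groups, tau=0.2, rng=trial, require_margin=margin
                )
                assert res.exact
                assert res.p_value == pytest.approx(
                    exact_permutation_pvalue(reads, list(g1), 0.2, margin)
                )

    def test_identical_reads_give_p_one(self):
        reads = np.tile([1, 0, 1, 0], (8, 1))
        groups = _groups(np.arange(4), np.arange(4, 8), reads)
        res = permutation_pvalue(reads, groups, tau=0.0, rng=0)
        assert res.p_value == 1.0 and not res.call

    def test_null_pvalues_roughly_uniform(self):
        # random half/half grouping of exchangeable reads: p ~ uniform
        root = np.random.SeedSequence(11)
        ps = []
        for child in root.spawn(200):
            rng = np.random.default_rng(child)
            p = rng.beta(8, 8, size=4)
            reads = (rng.random((12, 4)) < p).astype(np.int8)
            groups = _groups(np.arange(6), np.arange(6, 12), reads)
            ps.append(
                permutation_pvalue(reads, groups, tau=0.0, rng=rng).p_value
            )
        assert 0.4 <= np.mean(ps) <= 0.6

    def test_margin_requirement_zeroes_weak_observations(self, rng):
        # homogeneous reads: no all-site margin above tau -> p = 1 outright
        reads = (rng.random((10, 4)) < 0.5).astype(np.int8)
        groups = _groups(np.arange(5), np.arange(5, 10), reads)
        res = permutation_pvalue(
            reads, groups, tau=0.9, rng=0, require_margin=True
        )
        assert res.p_value == 1.0 and res.statistic == 0.0

    def test_pvalue_floor_and_validation(self, pure_bipolar_reads):
        groups = _groups(np.arange(8), np.arange(8, 16), pure_bipolar_reads)
        res = permutation_pvalue(
            pure_bipolar_reads, groups, tau=0.0, n_permutations=99, rng=1
        )
        assert res.p_value >= 1 / 100
        with pytest.raises(ValueError):
            permutation_pvalue(pure_bipolar_reads, groups, n_permutations=0)

    def test_deterministic_given_rng_seed(self, rng):
        reads = rng.integers(0, 2, size=(20, 4))
        groups = _groups(np.arange(10), np.arange(10, 20), reads)
        r1 = permutation_pvalue(reads, groups, tau=0.1, rng=5)
        r2 = permutation_pvalue(reads, groups, tau=0.1, rng=5)
        assert r1.p_value == r2.p_value


class TestBipolarTestResult:
    def test_call_consistency_enforced(self):
        with pytest.raises(ValueError):
            BipolarTestResult(
                statistic=1.0, p_value=0.01, n_permutations=99, tau=0.0, call=False
            )
        with pytest.raises(ValueError):
            BipolarTestResult(
                statistic=1.0, p_value=0.0, n_permutations=99, tau=0.0, call=True
            )


class TestParametricStub:
    def test_not_implemented(self):
        with pytest.raises(NotImplementedError):
            parametric_test(np.ones((2, 4)), np.zeros((2, 4)))


class TestFisherDmCpg:
    def test_identical_tables_not_dm(self):
        counts = np.array([[5, 5]] * 4)
        res = fisher_dm_cpg(counts, counts)
        assert np.all(res.p_values == 1.0)
        assert not res.segment_dm_call

    def test_extreme_table_matches_hypergeometric_bruteforce(self):
        res = fisher_dm_cpg(np.array([[10, 0]]), np.array([[0, 10]]))
        expect = fisher_two_sided(10, 0, 0, 10)
        assert expect == pytest.approx(2 / math.comb(20, 10))
        assert res.p_values[0] == pytest.approx(expect)

    def test_random_tables_match_bruteforce(self, rng):
        for _ in range(10):
            a = rng.integers(0, 12, size=(1, 2))
            b = rng.integers(0, 12, size=(1, 2))
            if a.sum() == 0 or b.sum() == 0:
                continue
            res = fisher_dm_cpg(a, b)
            assert res.p_values[0] == pytest.approx(
                fisher_two_sided(a[0, 0], a[0, 1], b[0, 0], b[0, 1]), rel=1e-6
            )

    def test_all_sites_required_for_segment_call(self):
        a = np.array([[20, 0]] * 4)
        b = np.vstack([np.array([[0, 20]] * 3), np.array([[20, 0]])])
        res = fisher_dm_cpg(a, b)
        assert np.sum(res.q_values <= 0.05) == 3
        assert not res.segment_dm_call

    def test_consistent_direction_required(self):
        a = np.vstack([np.array([[20, 0]] * 2), np.array([[0, 20]] * 2)])
        b = np.vstack([np.array([[0, 20]] * 2), np.array([[20, 0]] * 2)])
        res = fisher_dm_cpg(a, b)
        assert np.all(res.q_values <= 0.05)
        assert not res.segment_dm_call

    def test_fully_separated_segment_is_dm(self):
        a = np.array([[20, 0]] * 4)
        b = np.array([[0, 20]] * 4)
        res = fisher_dm_cpg(a, b)
        assert res.segment_dm_call
        assert np.all(res.directions == 1)

    def test_zero_total_site_warns_and_p_one(self):
        a = np.array([[0, 0], [5, 5]])
        b = np.array([[3, 3], [5, 5]])
        with pytest.warns(UserWarning, match="zero total"):
            res = fisher_dm_cpg(a, b)
        assert res.p_values[0] == 1.0

    def test_qvalues_monotone_with_pvalues(self, rng):
        a = rng.integers(0, 15, size=(6, 2))
        b = rng.integers(0, 15, size=(6, 2))
        a += 1  # avoid zero-total warnings
        b += 1
        res = fisher_dm_cpg(a, b)
        order = np.argsort(res.p_values)
        assert np.all(np.diff(res.q_values[order]) >= -1e-12)
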