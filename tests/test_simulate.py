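import numpy as np
import pytest
import scipy.stats

from bipolarmeth.dpm import DpmConfig, dpm_map_search
from bipolarmeth.simulate import (
    SimDesign,
    average_pvalue_grid,
    bernoulli_mixture_cluster,
    beta_mean_sd,
    estimate_rates,
    kmeans_binary,
    misclassification_rate,
    simulate_labeled_segment,
    simulate_pattern_counts,
    simulate_segment,
)

from _oracles import best_bipartition_within_ss, misclassification_bruteforce


class TestBetaMoments:
    @pytest.mark.parametrize("a,b", [(8, 8), (5.96, 0.89), (0.72, 4.42), (2, 5)])
    def test_matches_scipy(self, a, b):
        mean, sd = beta_mean_sd(a, b)
        assert mean == pytest.approx(scipy.stats.beta.mean(a, b))
        assert sd == pytest.approx(scipy.stats.beta.std(a, b))


class TestSimulateSegment:
    def test_null_reads_share_one_probability_vector(self, rng):
        design = SimDesign(m=100000, n=4)
        seg = simulate_segment(design, "null", rng)
        col = seg.reads.mean(0)
        # all reads i.i.d. Bernoulli(p): column means concentrate near p,
        # which itself lies in (0, 1); 3 binomial SEs around the estimate
        se = np.sqrt(col * (1 - col) / design.m)
        assert seg.reads.shape == (design.m, 4)
        assert np.all(col > 3 * se.max()) and np.all(col < 1 - 3 * se.max())

    def test_alternative_origin_proportion(self, rng):
        design = SimDesign(m=20000, w=0.5)
        _, origins = simulate_labeled_segment(design, rng)
        assert abs((origins == 0).mean() - 0.5) < 0.02

    def test_alternative_separates_origin_levels(self, rng):
        design = SimDesign(m=5000, w=0.3)
        seg, origins = simulate_labeled_segment(design, rng)
        hyper_level = seg.reads[origins == 0].mean()
        hypo_level = seg.reads[origins == 1].mean()
        assert hyper_level > hypo_level

    def test_fresh_vectors_each_replicate(self):
        rng = np.random.default_rng(0)
        a = simulate_segment(SimDesign(m=2000), "null", rng).reads.mean(0)
        b = simulate_segment(SimDesign(m=2000), "null", rng).reads.mean(0)
        assert not np.allclose(a, b, atol=0.02)

    def test_bad_hypothesis_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_segment(SimDesign(), "h1", rng)

    def test_design_validation(self):
        with pytest.raises(ValueError):
            SimDesign(w=0.0)
        with pytest.raises(ValueError):
            SimDesign(hyper_beta=(0, 1))


class TestPatternCounts:
    def test_no_filler(self, rng):
        seg = simulate_pattern_counts(8, 8, rng=rng)
        assert seg.m == 16
        assert (seg.reads.sum(1) == 0).sum() == 8
        assert (seg.reads.sum(1) == 4).sum() == 8

    def test_all_filler_nonconstant(self, rng):
        seg = simulate_pattern_counts(0, 0, rng=rng)
        sums = seg.reads.sum(1)
        assert np.all((sums > 0) & (sums < 4))

    def test_single_filler(self, rng):
        seg = simulate_pattern_counts(1, 14, rng=rng)
        sums = seg.reads.sum(1)
        assert (sums == 0).sum() == 1 and (sums == 4).sum() == 14

    def test_overflow_rejected(self, rng):
        with pytest.raises(ValueError):
            simulate_pattern_counts(9, 8, rng=rng)


class TestEstimateRates:
    def test_degenerate_detectors(self):
        design = SimDesign(m=5, reps=50, seed=3)
        never = estimate_rates(design, "null", detector=lambda seg, rng: 1.0)
        always = estimate_rates(design, "null", detector=lambda seg, rng: 0.01)
        assert never.rate == 0.0 and always.rate == 1.0
        assert always.se == 0.0

    def test_reproducible_bit_for_bit(self):
        design = SimDesign(m=10, w=0.5, reps=30, permutations=49, seed=9)
        a = estimate_rates(design, "alternative")
        b = estimate_rates(design, "alternative")
        assert a.rate == b.rate


class TestKmeansBinary:
    def test_pure_blocks_recovered(self, pure_bipolar_reads):
        part = kmeans_binary(pure_bipolar_reads, seed=0)
        assert part.k == 2
        assert misclassification_rate(part.labels, [0] * 8 + [1] * 8) == 0.0

    def test_identical_reads_degenerate(self):
        part = kmeans_binary(np.tile([1, 0, 1, 0], (5, 1)), seed=0)
        assert part.k == 1 and np.all(part.labels == 0)

    def test_within_ss_matches_exhaustive_bipartition(self, rng):
        for trial in range(5):
            reads = rng.integers(0, 2, size=(8, 4)).astype(float)
            if np.allclose(reads, reads[0]):
                continue
            part = kmeans_binary(reads, seed=trial, restarts=20)
            if part.k < 2:
                continue
            ss = sum(
                float(((reads[part.labels == c] - part.cluster_means[c]) ** 2).sum())
                for c in range(2)
            )
            assert ss == pytest.approx(best_bipartition_within_ss(reads), abs=1e-9)

    def test_too_few_reads_rejected(self):
        with pytest.raises(ValueError):
            kmeans_binary(np.ones((1, 4)), k=2)


class TestBernoulliMixture:
    def test_pure_blocks_recovered(self, pure_bipolar_reads):
        part = bernoulli_mixture_cluster(pure_bipolar_reads, seed=0)
        assert misclassification_rate(part.labels, [0] * 8 + [1] * 8) == 0.0

    def test_label_switching_handled_across_seeds(self, pure_bipolar_reads):
        truth = [0] * 8 + [1] * 8
        for seed in range(4):
            part = bernoulli_mixture_cluster(pure_bipolar_reads, seed=seed)
            assert misclassification_rate(part.labels, truth) == 0.0

    def test_two_distinct_reads_split(self):
        reads = np.array([[1, 1, 1, 1], [0, 0, 0, 0]])
        part = bernoulli_mixture_cluster(reads, seed=1)
        assert part.k == 2

    def test_needs_two_reads(self):
        with pytest.raises(ValueError):
            bernoulli_mixture_cluster(np.ones((1, 4)))


class TestMisclassification:
    def test_perfect_and_inverted(self):
        truth = [0, 0, 1, 1]
        assert misclassification_rate([0, 0, 1, 1], truth) == 0.0
        assert misclassification_rate([1, 1, 0, 0], truth) == 0.0

    def test_matches_bruteforce_two_classes(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 12))
            labels = rng.integers(0, 2, size=m)
            truth = rng.integers(0, 2, size=m)
            assert misclassification_rate(labels, truth) == pytest.approx(
                misclassification_bruteforce(labels, truth)
            )

    def test_random_labels_approach_half(self, rng):
        truth = np.repeat([0, 1], 5000)
        labels = rng.integers(0, 2, size=10000)
        assert abs(misclassification_rate(labels, truth) - 0.5) < 0.03

    def test_extra_predicted_clusters_use_majority_mapping(self):
        # three predicted clusters over two true classes
        labels = [0, 0, 1, 1, 2, 2]
        truth = [0, 0, 1, 1, 1, 1]
        assert misclassification_rate(labels, truth) == 0.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            misclassification_rate([0, 1], [0, 1, 1])


class TestPvalueGrid:
    def test_tidy_output_and_range(self):
        df = average_pvalue_grid(
            [(8, 8), (1, 1)], deltas=(0.2, 0.35), reps=3, permutations=49, seed=0
        )
        assert set(df.columns) == {"i", "j", "delta", "mean_p", "reps"}
        assert len(df) == 4
        assert df.mean_p.between(0, 1).all()
        strong = df[(df.i == 8) & (df.j == 8)].mean_p
        weak = df[(df.i == 1) & (df.j == 1)].mean_p
        assert strong.max() < weak.min()


class TestTypeOneErrorControl:
    @pytest.mark.parametrize("m,w", [(10, 0.1), (20, 0.5)])
    def test_type_one_error_below_nominal_with_margin(self, m, w):
        """With tau = 0.32 the detector's false-positive rate on one-origin
        segments stays below the 0.05 level (within Monte-Carlo tolerance)."""
        reps = 120
        design = SimDesign(m=m, w=w, tau=0.32, reps=reps, permutations=99, seed=77)
        cell = estimate_rates(design, "null")
        assert cell.rate <= 0.05 + 3 * np.sqrt(0.05 * 0.95 / reps)


class TestDpmOnSimulatedData:
    def test_two_origin_segment_clusters_by_origin(self, rng):
        from bipolarmeth.io import OriginModel

        model = OriginModel(P=np.array([[0.9, 0.1]] * 4), q=np.array([0.5, 0.5]))
        reads, truth = model.sample(30, rng)
        part = dpm_map_search(reads, DpmConfig(seed=0))
        assert misclassification_rate(part.labels, truth) <= 0.1
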