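import itertools
import math

import numpy as np
import pytest

from ionclust import (IsotopeCriteria, cosine_similarity, evaluate_rir,
                      find_isotope_pairs, isotope_fraction, pearson_corr,
                      random_baseline_fraction, ranking_benchmark,
                      relative_isotope_ratio)
from ionclust.errors import ParameterError, UndefinedMetricError

from conftest import make_ion_image


def exact_permutation_mean(labels, pairs):
    """Exhaustive oracle: mean F over all label-vector permutations (n <= 8)."""
    labels = list(labels)
    fractions = []
    for perm in itertools.permutations(labels):
        grouped = sum(1 for i, j in pairs
                      if perm[i] == perm[j] and perm[i] != -1)
        fractions.append(grouped / len(pairs))
    return float(np.mean(fractions))


class TestPearson:
    def test_identical_images(self, rng):
        img = make_ion_image(rng.uniform(size=(5, 5)))
        assert pearson_corr(img, img) == pytest.approx(1.0)

    def test_anti_correlated(self, rng):
        x = rng.uniform(size=(5, 5))
        a = make_ion_image(x)
        b = make_ion_image(x.max() - x)  # offset keeps pixels non-negative
        assert pearson_corr(a, b) == pytest.approx(-1.0)

    def test_known_value(self):
        # covariance/variance oracle: r = 6.5 / sqrt(5 * 8.75) = 0.98270...
        r = pearson_corr(np.array([1.0, 2, 3, 4]), np.array([1.0, 2, 3, 5]))
        assert r == pytest.approx(6.5 / math.sqrt(5 * 8.75), abs=1e-12)
        assert r == pytest.approx(0.9827, abs=1e-4)

    def test_constant_input_nan(self):
        r = pearson_corr(np.ones(4), np.array([1.0, 2, 3, 4]))
        assert math.isnan(r)

    def test_shape_mismatch(self):
        with pytest.raises(ParameterError):
            pearson_corr(np.ones(3), np.ones(4))

    def test_masked_pixels_only(self):
        mask = np.array([[True, True, False]])
        a = make_ion_image(np.array([[1.0, 2.0, 0.0]]), mask=mask)
        b = make_ion_image(np.array([[2.0, 4.0, 0.0]]), mask=mask)
        assert pearson_corr(a, b) == pytest.approx(1.0)


class TestFindIsotopePairs:
    def imgs(self, n, rng):
        base = rng.uniform(size=(6, 6))
        return [make_ion_image(base.copy()) for _ in range(n)]

    def test_exact_shift_identical_images(self, rng):
        pairs = find_isotope_pairs([700.000, 701.003], self.imgs(2, rng),
                                   IsotopeCriteria(delta=0.01))
        assert len(pairs) == 1
        assert (pairs[0].i, pairs[0].j) == (0, 1)
        assert pairs[0].corr == pytest.approx(1.0)

    def test_shift_outside_tolerance(self, rng):
        pairs = find_isotope_pairs([700.000, 701.050], self.imgs(2, rng),
                                   IsotopeCriteria(delta=0.01))
        assert pairs == []

    def test_chain_excludes_double_shift(self, rng):
        mzs = [700.000, 701.003, 702.006]
        pairs = find_isotope_pairs(mzs, self.imgs(3, rng),
                                   IsotopeCriteria(delta=0.01))
        assert {(p.i, p.j) for p in pairs} == {(0, 1), (1, 2)}

    def test_low_correlation_rejected(self, rng):
        a = make_ion_image(rng.uniform(size=(6, 6)))
        b = make_ion_image(rng.uniform(size=(6, 6)))
        crit = IsotopeCriteria(delta=0.01, min_corr=0.99)
        assert find_isotope_pairs([700.0, 701.003], [a, b], crit) == []

    def test_unsorted_mzs_rejected(self, rng):
        with pytest.raises(ParameterError):
            find_isotope_pairs([701.0, 700.0], self.imgs(2, rng))

    def test_length_mismatch(self, rng):
        with pytest.raises(ParameterError):
            find_isotope_pairs([700.0, 701.0], self.imgs(3, rng))


class TestIsotopeFraction:
    def test_all_grouped(self):
        assert isotope_fraction([(0, 1), (2, 3)], [5, 5, 5, 5]) == 1.0

    def test_half_grouped(self):
        assert isotope_fraction([(0, 1), (2, 3)], [0, 0, 1, 2]) == 0.5

    def test_noise_member_not_grouped(self):
        assert isotope_fraction([(0, 1)], [-1, -1]) == 0.0

    def test_zero_pairs_undefined(self):
        with pytest.raises(UndefinedMetricError):
            isotope_fraction([], [0, 1])

    def test_label_permutation_invariance(self):
        pairs = [(0, 1), (1, 2), (3, 4)]
        labels = np.array([0, 0, 1, 1, 2])
        relabeled = np.array([7, 7, 3, 3, 0])
        assert (isotope_fraction(pairs, labels)
                == isotope_fraction(pairs, relabeled))


class TestRandomBaseline:
    def test_single_cluster_mean_one_sd_zero(self):
        mean, sd = random_baseline_fraction([0, 0, 0, 0], [(0, 1), (2, 3)],
                                            B=50, seed=0)
        assert mean == 1.0 and sd == 0.0

    def test_two_pairs_of_two_is_one_third(self):
        labels = [0, 0, 1, 1]
        pairs = [(0, 1)]
        exact = exact_permutation_mean(labels, pairs)
        assert exact == pytest.approx(1 / 3)
        mean, _ = random_baseline_fraction(labels, pairs, B=10000, seed=0)
        assert mean == pytest.approx(exact, abs=0.02)

    def test_bootstrap_matches_exhaustive_oracle_6_images(self):
        labels = [0, 0, 0, 1, 1, -1]
        pairs = [(0, 3), (1, 2), (4, 5)]
        exact = exact_permutation_mean(labels, pairs)
        mean, _ = random_baseline_fraction(labels, pairs, B=10000, seed=1)
        assert mean == pytest.approx(exact, abs=0.02)

    def test_b_zero_errors(self):
        with pytest.raises(ParameterError):
            random_baseline_fraction([0, 1], [(0, 1)], B=0)

    def test_zero_pairs_errors(self):
        with pytest.raises(UndefinedMetricError):
            random_baseline_fraction([0, 1], [], B=10)


class TestRelativeIsotopeRatio:
    def test_single_cluster_degenerate(self):
        assert relative_isotope_ratio(1.0, 1.0) == 1.0

    def test_sizes_22_instance_r_is_3(self):
        labels = [0, 0, 1, 1]
        pairs = [(0, 1)]
        F = isotope_fraction(pairs, labels)
        mean, _ = random_baseline_fraction(labels, pairs, B=10000, seed=0)
        assert relative_isotope_ratio(F, mean) == pytest.approx(3.0, abs=0.2)

    def test_f_zero(self):
        assert relative_isotope_ratio(0.0, 0.5) == 0.0

    def test_zero_baseline_infinite(self):
        with pytest.warns(UserWarning):
            assert relative_isotope_ratio(0.5, 0.0) == float("inf")

    def test_zero_over_zero_undefined(self):
        with pytest.raises(UndefinedMetricError):
            relative_isotope_ratio(0.0, 0.0)

    def test_null_self_consistency(self, rng):
        """E[R] over shuffled-label clusterings is 1 within 3 SE."""
        labels = np.array([0] * 5 + [1] * 5 + [2] * 4 + [-1] * 2)
        pairs = [(0, 5), (1, 6), (10, 11), (2, 14)]
        base_mean, base_sd = random_baseline_fraction(labels, pairs,
                                                      B=20000, seed=0)
        n_shuffles = 300
        fs = np.array([isotope_fraction(pairs, rng.permutation(labels))
                       for _ in range(n_shuffles)])
        r_mean = fs.mean() / base_mean
        se = math.sqrt(fs.var() / n_shuffles
                       + base_sd ** 2 / 20000) / base_mean
        assert abs(r_mean - 1.0) <= 3 * se


class TestCosineSimilarity:
    def test_identical(self):
        assert cosine_similarity([1.0, 2.0], [1.0, 2.0]) == pytest.approx(1.0)

    def test_orthogonal(self):
        assert cosine_similarity([1.0, 0.0], [0.0, 1.0]) == pytest.approx(0.0)

    def test_45_degrees(self):
        assert cosine_similarity([1.0, 0.0], [1.0, 1.0]) == pytest.approx(
            1 / math.sqrt(2), abs=1e-6)

    def test_zero_vector_errors(self):
        with pytest.raises(ParameterError):
            cosine_similarity([0.0, 0.0], [1.0, 0.0])


class TestRankingBenchmark:
    def test_perfect_proxy_recovers_everything(self, rng):
        sets = {}
        for s in range(4):
            scores = rng.uniform(0, 10, 12)
            sets[f"set{s}"] = (-scores, scores)  # similarity = -score
        segments = ranking_benchmark(sets, [0.5, 1.0, 2.0, 5.0])
        assert all(seg.fraction == 1.0 for seg in segments)
        assert all(seg.hits == seg.N for seg in segments)

    def test_hand_enumerated_case(self):
        scores = [0.5, 0.9, 1.5, 3.0, 4.0]
        sims = [0.1, 0.9, 0.2, 0.8, 0.0]  # ranks candidates {1, 3} on top
        segments = ranking_benchmark({"s": (sims, scores)}, [1.0])
        assert len(segments) == 1
        seg = segments[0]
        assert seg.N == 2 and seg.hits == 1 and seg.fraction == 0.5

    def test_cutoff_below_all_scores_skipped(self):
        segments = ranking_benchmark({"s": ([1.0, 2.0], [5.0, 6.0])}, [0.5])
        assert segments == []

    def test_monotone_transform_invariance(self, rng):
        scores = rng.uniform(0, 10, 15)
        sims = rng.normal(size=15)
        cutoffs = [1.0, 3.0, 7.0]
        base = ranking_benchmark({"s": (sims, scores)}, cutoffs)
        transformed = ranking_benchmark(
            {"s": (np.exp(sims) + 5.0, scores)}, cutoffs)
        assert [(s.N, s.hits) for s in base] == [(s.N, s.hits)
                                                 for s in transformed]

    def test_ties_broken_by_index(self):
        # all similarities equal: top-N = first N candidates by index
        segments = ranking_benchmark({"s": ([1.0, 1.0, 1.0],
                                            [9.0, 0.5, 0.5])}, [1.0])
        seg = segments[0]
        assert seg.N == 2 and seg.hits == 1

    def test_misaligned_lengths_error(self):
        with pytest.raises(ParameterError):
            ranking_benchmark({"s": ([1.0], [1.0, 2.0])}, [1.0])

    def test_pooling_across_sets(self):
        sets = {"a": ([-1.0, -2.0], [0.5, 5.0]),   # N=1, hit
                "b": ([0.1, 0.9, 0.5], [0.5, 9.0, 0.8])}  # N=2, 1 hit
        seg = ranking_benchmark(sets, [1.0])[0]
        assert seg.N == 3 and seg.hits == 2
        assert seg.fraction == pytest.approx(2 / 3)


class TestEvaluateRIR:
    def test_ground_truth_on_synthetic(self, synthetic, synthetic_images):
        dataset, truth = synthetic
        result = evaluate_rir(dataset.mz_axis, synthetic_images,
                              truth.pattern_label, B=500, seed=0)
        assert result.F_clust == 1.0
        assert result.n_pairs == len(truth.isotope_pairs)
        assert result.R > 1.0
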