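"""Tests for the hypergeometric bottleneck and multi-type inference."""

import itertools
import math

import numpy as np
import pytest
from scipy.stats import chisquare

from sirna_escape import (
    MultiInferenceConfig,
    PAPER_THETA,
    mh_sample_multi,
    mvhg_mode,
    mvhg_pmf,
    mvhg_sample,
    posterior_grid_multi,
    posterior_grid_single,
    InferenceConfig,
)


def enumerate_compositions(v0, s1):
    """All admissible escape compositions of total s1 (brute force)."""
    ranges = [range(0, min(c, s1) + 1) for c in v0]
    return [v for v in itertools.product(*ranges) if sum(v) == s1]


def exact_pmf(v1, v0):
    """Independent oracle for the bottleneck pmf via binomial coefficients."""
    num = math.prod(math.comb(n, k) for n, k in zip(v0, v1))
    return num / math.comb(sum(v0), sum(v1))


class TestMvhgPmf:
    @pytest.mark.parametrize(
        "v1,v0,expected",
        [
            ((1, 1), (2, 2), 2 / 3),
            ((2, 2), (2, 2), 1.0),
            ((3, 0), (2, 2), 0.0),  # component exceeds its population
        ],
    )
    def test_reference_values(self, v1, v0, expected):
        assert mvhg_pmf(v1, v0) == pytest.approx(expected)

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            mvhg_pmf([1], [2, 2])

    @pytest.mark.parametrize("v0", [(2, 2), (1, 4, 2), (3, 3, 3, 3)])
    def test_sums_to_one_over_all_compositions(self, v0):
        for s1 in range(0, sum(v0) + 1):
            comps = enumerate_compositions(v0, s1)
            total = sum(mvhg_pmf(v1, v0) for v1 in comps)
            assert total == pytest.approx(1.0, abs=1e-12)
            for v1 in comps:
                assert mvhg_pmf(v1, v0) == pytest.approx(exact_pmf(v1, v0))


class TestMvhgSample:
    def test_boundary_draws(self):
        v0 = [4, 3, 2]
        assert np.array_equal(mvhg_sample(9, v0, 1), v0)
        assert np.array_equal(mvhg_sample(0, v0, 1), [0, 0, 0])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            mvhg_sample(10, [4, 3, 2])

    def test_marginal_means(self, rng):
        draws = np.stack([mvhg_sample(70, [600] * 7, rng) for _ in range(10_000)])
        # hypergeometric marginal: mean 10, var n p (1-p) (N-n)/(N-1)
        var = 70 * (1 / 7) * (6 / 7) * (4200 - 70) / (4200 - 1)
        se = math.sqrt(var / 10_000)
        assert np.all(np.abs(draws.mean(axis=0) - 10) < 3 * se)

    def test_frequencies_match_pmf(self, rng):
        v0, s1, n = (3, 4, 5), 6, 10_000
        comps = enumerate_compositions(v0, s1)
        index = {v: i for i, v in enumerate(comps)}
        counts = np.zeros(len(comps))
        for _ in range(n):
            counts[index[tuple(mvhg_sample(s1, v0, rng))]] += 1
        expected = np.array([exact_pmf(v, v0) for v in comps]) * n
        assert chisquare(counts, expected).pvalue > 0.01


class TestMvhgMode:
    @pytest.mark.parametrize("v0", [(2, 2), (1, 4, 2), (3, 3, 3, 3), (6, 2, 4)])
    def test_achieves_enumerated_maximum(self, v0):
        for s1 in range(0, sum(v0) + 1):
            comps = enumerate_compositions(v0, s1)
            best = max(exact_pmf(v, v0) for v in comps)
            assert exact_pmf(tuple(mvhg_mode(s1, v0)), v0) == pytest.approx(best)

    def test_symmetric_allocations(self):
        assert np.array_equal(mvhg_mode(7, [600] * 7), [1] * 7)
        assert np.array_equal(mvhg_mode(140, [600] * 7), [20] * 7)
        assert np.array_equal(mvhg_mode(0, [600] * 7), [0] * 7)
        # symmetric tie: both (0,1) and (1,0) maximize; lex-smallest wins
        assert np.array_equal(mvhg_mode(1, [2, 2]), [0, 1])

    def test_reduced_symmetric_oracle(self):
        # scaled-down stand-ins for the seven-types-of-600 cases
        for s1, v0 in [(7, (6,) * 7), (14, (6,) * 7)]:
            comps = enumerate_compositions(list(v0), s1)
            best = max(exact_pmf(v, v0) for v in comps)
            mode = tuple(mvhg_mode(s1, v0))
            assert exact_pmf(mode, v0) == pytest.approx(best)
            # lexicographically smallest among the tied argmax compositions
            tied = sorted(v for v in comps if exact_pmf(v, v0) == pytest.approx(best))
            assert mode == tied[0]


class TestPosteriorGridMulti:
    def test_zero_time_single_type_matches_closed_form(self):
        # m=1: the only admissible composition is (s1,), so at dt=0 the
        # posterior reduces to the single-type zero-time law exactly
        cfg = MultiInferenceConfig(K=5, n_sims=50)
        grid = posterior_grid_multi([100], [10], 0.0, PAPER_THETA, cfg, rng=3)
        support = np.arange(1, 11)
        expected = 1.0 / np.maximum(np.abs(support - 10), 0.5)
        expected /= expected.sum()
        assert np.allclose(grid.probs, expected, atol=1e-12)

    def test_zero_time_agrees_with_single_type_grid(self):
        multi = posterior_grid_multi(
            [1000], [10], 0.0, PAPER_THETA, MultiInferenceConfig(K=3, n_sims=40), rng=1
        )
        single = posterior_grid_single(
            10, 0.0, PAPER_THETA, InferenceConfig(n_sims=40), rng=2
        )
        assert np.allclose(multi.probs, single.probs, atol=1e-12)

    def test_normalized_output(self):
        cfg = MultiInferenceConfig(K=10, n_sims=20)
        grid = posterior_grid_multi([50, 50], [12, 14], 12, PAPER_THETA, cfg, rng=8)
        assert grid.probs.sum() == pytest.approx(1.0, abs=1e-12)
        assert grid.support[-1] == 26  # smax defaults to sum(v2)


class TestChainSamplerMulti:
    def test_samples_stay_in_support_and_repeat_on_rejection(self):
        cfg = MultiInferenceConfig(N=1_000)
        chain = mh_sample_multi([20, 20], [10, 12], 12, PAPER_THETA, cfg, rng=4)
        assert chain.samples.min() >= 1 and chain.samples.max() <= 22
        rejected = np.flatnonzero(~chain.accepted[1:]) + 1
        assert np.array_equal(chain.samples[rejected], chain.samples[rejected - 1])

    def test_same_seed_bit_identical(self):
        cfg = MultiInferenceConfig(N=300)
        a = mh_sample_multi([20, 20], [10, 12], 12, PAPER_THETA, cfg, rng=6)
        b = mh_sample_multi([20, 20], [10, 12], 12, PAPER_THETA, cfg, rng=6)
        assert np.array_equal(a.samples, b.samples)
        assert np.array_equal(a.distances, b.distances)
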