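"""Synthetic-data generator tests: truncated power-law sampler, branching
raster, ECoG synthesis, jitter surrogate."""

import numpy as np
import pytest
from scipy.stats import norm

from neurocrit.avalanches import extract_avalanches
from neurocrit.point_process import binarize
from neurocrit.powerlaw import mle_exponent, truncated_pmf
from neurocrit.raster import EventRaster
from neurocrit.simulate import (
    BranchingParams,
    TruncatedPowerLawParams,
    jitter_null,
    sample_truncated_powerlaw,
    simulate_branching_raster,
    synthesize_ecog,
)


class TestTruncatedPowerLawSampler:
    def test_samples_respect_bounds_and_seed(self):
        p = TruncatedPowerLawParams(2.5, 4, 300, 5000, seed=1)
        s1 = sample_truncated_powerlaw(p)
        s2 = sample_truncated_powerlaw(p)
        assert s1.min() >= 4 and s1.max() <= 300
        assert np.array_equal(s1, s2)

    def test_degenerate_support_returns_constant(self):
        p = TruncatedPowerLawParams(3.0, 5, 5, 100, seed=2)
        assert np.all(sample_truncated_powerlaw(p) == 5)

    def test_invalid_bounds_rejected(self):
        with pytest.raises(ValueError):
            TruncatedPowerLawParams(2.0, 10, 5, 100)
        with pytest.raises(ValueError):
            TruncatedPowerLawParams(-1.0, 1, 5, 100)

    def test_frequencies_match_enumerated_pmf(self):
        """Empirical frequencies on a 10-point support agree with the exact
        normalized pmf within 3 Monte-Carlo standard errors."""
        n = 200_000
        s = sample_truncated_powerlaw(TruncatedPowerLawParams(2.0, 1, 10, n, seed=3))
        support, pmf = truncated_pmf(2.0, 1, 10)
        counts = np.bincount(s, minlength=11)[1:11]
        for k, (p_k, c) in enumerate(zip(pmf, counts)):
            se = np.sqrt(n * p_k * (1 - p_k))
            assert abs(c - n * p_k) < 3 * se, f"support point {k + 1}"

    def test_mle_round_trip_fig_range(self):
        """Refit on [16, 196] recovers a generating exponent of 2.7 +- 0.1."""
        s = sample_truncated_powerlaw(TruncatedPowerLawParams(2.7, 16, 196, 10_000, seed=4))
        assert abs(mle_exponent(s, 16, 196) - 2.7) < 0.1

    def test_ccdf_converges_with_sample_size(self):
        """Sup-distance between empirical and analytic truncated CCDF shrinks
        as n grows (10^3 vs 10^5)."""
        support, pmf = truncated_pmf(2.0, 1, 100)
        analytic_ccdf = 1 - np.cumsum(pmf)

        def sup_dist(n, seed):
            s = sample_truncated_powerlaw(TruncatedPowerLawParams(2.0, 1, 100, n, seed=seed))
            emp = 1 - np.searchsorted(np.sort(s), support, side="right") / n
            return np.max(np.abs(emp - analytic_ccdf))

        assert sup_dist(100_000, 5) < sup_dist(1_000, 5) < 0.1


class TestBranchingRaster:
    def test_zero_drive_gives_empty_raster(self):
        r = simulate_branching_raster(BranchingParams(8, 1000, 1.0, 0.0, seed=1))
        assert r.n_events == 0
        assert len(extract_avalanches(r)) == 0

    def test_zero_branching_gives_singleton_avalanches(self):
        r = simulate_branching_raster(
            BranchingParams(16, 50_000, 0.0, 0.002, seed=2)
        )
        cat = extract_avalanches(r)
        assert len(cat) > 0
        # isolated seeds cannot propagate; only coincident/adjacent seeds
        # (rare at this drive) produce S or T above 1
        assert np.mean(cat.sizes == 1) > 0.95
        singles = cat.sizes == 1
        assert np.all(cat.durations[singles] == 1)

    def test_mean_size_monotone_in_branching_ratio(self):
        means = []
        for br in [0.5, 0.625, 0.75, 0.875, 1.0]:
            r = simulate_branching_raster(
                BranchingParams(64, 50_000, br, 0.01, seed=7)
            )
            means.append(extract_avalanches(r).sizes.mean())
        assert all(a <= b for a, b in zip(means, means[1:]))

    def test_reproducible_and_validates(self):
        p = BranchingParams(8, 2000, 1.0, 0.05, seed=9)
        a, b = simulate_branching_raster(p), simulate_branching_raster(p)
        assert np.array_equal(a.channels, b.channels)
        assert np.array_equal(a.times, b.times)
        with pytest.raises(ValueError):
            BranchingParams(1, 100, 1.0, 0.1)


class TestSynthesizeEcog:
    def test_output_shape_matches_raster(self):
        r = EventRaster(np.array([0]), np.array([10]), 128, 6000)
        rec = synthesize_ecog(r, sampling_rate=1000.0, seed=1)
        assert rec.data.shape == (128, 6000)
        assert rec.sampling_rate == 1000.0

    def test_background_excursion_rate_matches_gaussian_tail(self):
        """With no planted events, re-detected events at sigma=4 match the
        N(0,1) tail count within 3 binomial SEs."""
        empty = EventRaster(np.array([], int), np.array([], int), 16, 100_000)
        rec = synthesize_ecog(empty, seed=36)
        detected = binarize(rec.normalized(), 4.0)
        n = 16 * 100_000
        p = 2 * norm.sf(4)
        se = np.sqrt(n * p * (1 - p))
        assert abs(detected.n_events - n * p) < 3 * se

    def test_planted_events_recovered(self):
        """>= 95% of amplitude-6 events are re-detected at sigma=4 within one
        pulse half-width of the planted bin."""
        rng = np.random.default_rng(37)
        times = np.sort(rng.choice(np.arange(10, 49_990, 10), 200, replace=False))
        planted = EventRaster(rng.integers(0, 16, 200), times, 16, 50_000)
        rec = synthesize_ecog(planted, event_amplitude=6.0, seed=38)
        dense = binarize(rec.normalized(), 4.0).to_dense()
        hits = sum(
            dense[c, max(0, t - 1): t + 2].any()
            for c, t in zip(planted.channels, planted.times)
        )
        assert hits / planted.n_events >= 0.95


class TestJitterNull:
    def test_zero_window_is_identity(self, toy_raster):
        j = jitter_null(toy_raster, 0, seed=1)
        assert np.array_equal(j.channels, toy_raster.channels)
        assert np.array_equal(j.times, toy_raster.times)

    def test_per_channel_counts_preserved(self, critical_raster):
        j = jitter_null(critical_raster, 30_000, seed=2)
        assert np.array_equal(
            j.counts_per_channel(), critical_raster.counts_per_channel()
        )

    def test_jitter_destroys_cascades(self, critical_raster):
        """A 30 s jitter breaks correlated cascades: the mean avalanche size
        drops relative to the original critical raster."""
        orig = extract_avalanches(critical_raster).sizes.mean()
        jit = extract_avalanches(jitter_null(critical_raster, 30_000, seed=3)).sizes.mean()
        assert jit < orig
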