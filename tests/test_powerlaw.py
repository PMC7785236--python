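"""Truncated power-law inference tests: MLE against brute-force likelihood
search, KS statistics against enumerated CDFs, surrogate p-values, range
scanning, CCDF conventions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from neurocrit.powerlaw import (
    InsufficientDataError,
    PowerLawFit,
    ccdf,
    fit_range,
    gof_pvalue,
    ks_statistic,
    mle_exponent,
    scan_range,
    truncated_cdf,
    truncated_pmf,
)
from neurocrit.simulate import TruncatedPowerLawParams, sample_truncated_powerlaw


def draw(exponent, x_min, x_max, n, seed):
    return sample_truncated_powerlaw(
        TruncatedPowerLawParams(exponent, x_min, x_max, n, seed=seed)
    )


class TestMle:
    def test_matches_brute_force_grid_search(self):
        """Numerical maximization agrees with an exhaustive likelihood grid
        at step 1e-4 to within one grid step."""
        s = draw(2.0, 1, 100, 500, seed=1)
        support = np.arange(1, 101, dtype=float)
        logs = np.log(s.astype(float))
        grid = np.arange(1.01, 8.0, 1e-4)
        # vectorized brute-force log-likelihood over the grid
        z = (support[None, :] ** (-grid[:, None])).sum(axis=1)
        ll = -grid * logs.sum() - len(s) * np.log(z)
        oracle = grid[np.argmax(ll)]
        assert abs(mle_exponent(s, 1, 100) - oracle) <= 1e-4

    @pytest.mark.parametrize("exponent", [1.5, 2.0, 2.7, 3.5])
    def test_recovery_bias_small(self, exponent):
        """|bias| < 0.05 at n = 10^4 across the exponent range."""
        s = draw(exponent, 5, 500, 10_000, seed=int(exponent * 10))
        assert abs(mle_exponent(s, 5, 500) - exponent) < 0.05

    def test_insufficient_samples_rejected(self):
        with pytest.raises(InsufficientDataError):
            mle_exponent([5, 6, 7], 5, 10)

    def test_degenerate_all_xmin_hits_bound(self):
        """All samples at x_min push the estimate to the search bound and the
        fit is flagged degenerate."""
        s = np.full(100, 2)
        e = mle_exponent(s, 2, 50)
        assert e > 7.9
        f = fit_range(s, 2, 50, n_surrogates=100, seed=1)
        assert f.degenerate


class TestKsStatistic:
    def test_near_perfect_fit_has_tiny_distance(self):
        """Samples laid out in exact proportion to the enumerated pmf."""
        support, pmf = truncated_pmf(2.0, 1, 20)
        counts = np.round(pmf * 10_000).astype(int)
        s = np.repeat(support.astype(int), counts)
        d = ks_statistic(s, PowerLawFit(2.0, 1, 20))
        assert d <= 1 / (2 * len(s)) + 1e-3

    def test_uniform_vs_powerlaw_matches_enumeration(self):
        """D for uniform samples against an exponent-3 fit equals the
        explicitly tabulated CDF difference."""
        s = np.repeat(np.arange(1, 51), 10)
        fit = PowerLawFit(3.0, 1, 50)
        support, model_cdf = truncated_cdf(3.0, 1, 50)
        emp_cdf = np.arange(1, 51) / 50.0
        oracle = np.max(np.abs(emp_cdf - model_cdf))
        assert ks_statistic(s, fit) == pytest.approx(oracle, abs=1e-12)

    def test_deterministic(self):
        s = draw(2.5, 1, 100, 1000, seed=3)
        fit = PowerLawFit(2.5, 1, 100)
        assert ks_statistic(s, fit) == ks_statistic(s, fit)


class TestGofPvalue:
    def test_misfit_rejected(self):
        """Geometric-tailed data fit as a power law over a wide range is
        rejected (p < 0.2)."""
        g = np.random.default_rng(13).geometric(0.2, 5000)
        e = mle_exponent(g, 1, int(g.max()))
        p = gof_pvalue(g, PowerLawFit(e, 1, int(g.max())), 200, seed=17)
        assert p < 0.2

    def test_well_specified_model_accepted(self):
        s = draw(2.0, 5, 200, 2000, seed=6)
        e = mle_exponent(s, 5, 200)
        p = gof_pvalue(s, PowerLawFit(e, 5, 200), 200, seed=7)
        assert p >= 0.2

    def test_surrogate_count_floor(self):
        s = draw(2.0, 1, 50, 500, seed=8)
        with pytest.raises(ValueError):
            gof_pvalue(s, PowerLawFit(2.0, 1, 50), n_surrogates=50)


class TestScanRange:
    def test_recovers_truncation_bounds(self):
        """Scanning samples from [16, 196] recovers x_min exactly and x_max
        within 20%."""
        s = draw(2.7, 16, 196, 10_000, seed=11)
        f = scan_range(s, 5, 200, seed=12)
        assert f.plausible
        assert abs(f.x_min - 16) <= 1
        assert abs(f.x_max - 196) <= 0.2 * 196

    def test_exponential_tail_narrows_range(self):
        """Geometric samples admit less than one decade of plausible power
        law — the qualitative anaesthetic signature."""
        g = np.random.default_rng(13).geometric(0.2, 5000)
        f = scan_range(g, 5, 200, seed=14)
        assert f.decades < 1.0

    def test_wide_powerlaw_spans_two_decades(self):
        s = draw(2.0, 1, 10_000, 20_000, seed=15)
        f = scan_range(s, 5, 200, seed=16)
        assert f.plausible
        assert f.decades >= 2.0

    def test_degenerate_sample_rejected(self):
        with pytest.raises(InsufficientDataError):
            scan_range(np.full(100, 7), 5, 200, seed=1)


class TestCcdf:
    def test_hand_enumeration(self):
        c = ccdf([1, 1, 2, 4])
        assert list(c.values) == [1, 2, 4]
        np.testing.assert_allclose(c.ccdf, [0.5, 0.25, 0.0])

    def test_single_repeated_value_drops_to_zero(self):
        c = ccdf([3, 3, 3])
        assert list(c.values) == [3]
        assert c.ccdf[0] == 0.0

    def test_truncated_tail_curves_downward(self):
        """log-CCDF of a doubly-truncated power law bends before x_max
        (negative second difference near the upper bound)."""
        s = draw(2.0, 10, 300, 100_000, seed=18)
        c = ccdf(s)
        keep = (c.ccdf > 0) & (c.values >= 100)
        logx, logy = np.log(c.values[keep]), np.log(c.ccdf[keep])
        second = np.diff(np.diff(logy) / np.diff(logx))
        assert second.mean() < 0

    @given(st.lists(st.integers(min_value=1, max_value=50), min_size=1, max_size=200))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_ccdf_is_valid_tail_function(self, xs):
        c = ccdf(xs)
        assert np.all(np.diff(c.ccdf) <= 1e-12)
        assert c.ccdf[-1] == 0.0
        assert c.ccdf[0] <= 1.0
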