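"""Scaling-battery tests: <S>(T) regression, exponent relation, shape
collapse, distribution distances, finite-size scaling, fold changes."""

import numpy as np
import pytest

from neurocrit.avalanches import Avalanche, AvalancheCatalog, extract_avalanches
from neurocrit.powerlaw import PowerLawFit
from neurocrit.raster import EventRaster
from neurocrit.scaling import (
    InsufficientScalingDataError,
    average_fold_change,
    distribution_distance,
    exponent_relation,
    finite_size_scaling,
    percentage_difference,
    shape_collapse,
    snz_from_regression,
)


def catalog_from_sizes(sizes, durations):
    avs = []
    start = 0
    for s, t in zip(sizes, durations):
        base, extra = divmod(int(s), int(t))
        profile = np.full(int(t), base)
        profile[:extra] += 1
        avs.append(Avalanche(start, int(t), int(s), profile))
        start += t + 2
    return AvalancheCatalog(avs, n_channels=1024, n_bins=start + 10)


class TestSnzRegression:
    def test_exact_log_linear_input(self):
        durations = np.repeat([1, 2, 4, 8, 16, 32], 3)
        sizes = np.round(2.0 * durations**1.3).astype(int)
        cat = catalog_from_sizes(sizes, durations)
        slope = snz_from_regression(cat, PowerLawFit(2.0, 1, 32))
        # the rounding to integer sizes perturbs the exact slope slightly
        assert slope == pytest.approx(1.3, abs=5e-3)

    def test_degenerate_single_duration_rejected(self):
        cat = catalog_from_sizes([3, 4, 5], [1, 1, 1])
        with pytest.raises(InsufficientScalingDataError):
            snz_from_regression(cat, PowerLawFit(2.0, 1, 10))


class TestExponentRelation:
    def test_printed_battery_values(self):
        assert exponent_relation(2.709, 4.422) == pytest.approx(2.00234055, abs=5e-9)
        assert exponent_relation(2.299, 2.446) == pytest.approx(1.1131639723, abs=5e-11)

    def test_equal_exponents_give_unity(self):
        assert exponent_relation(3.3, 3.3) == 1.0

    def test_domain_error(self):
        with pytest.raises(ValueError):
            exponent_relation(1.0, 2.0)


class TestPercentageDifference:
    def test_identity_and_closed_form(self):
        assert percentage_difference(2.5, 2.5) == 0.0
        assert percentage_difference(1.0, 3.0) == pytest.approx(100.0)

    def test_direct_arithmetic_oracle(self):
        assert percentage_difference(1.89, 1.33) == pytest.approx(34.78, abs=0.005)

    def test_rejects_non_positive(self):
        with pytest.raises(ValueError):
            percentage_difference(0.0, 1.0)


class TestShapeCollapse:
    @staticmethod
    def family(gamma_true=0.5, durations=(10, 20, 40), noise=0.0, seed=0):
        rng = np.random.default_rng(seed)
        out = {}
        for T in durations:
            u = np.linspace(0, 1, T)
            prof = T**gamma_true * 4 * u * (1 - u)
            if noise:
                prof = prof * (1 + noise * rng.standard_normal(T))
            out[T] = prof
        return out

    def test_exact_self_similar_family(self):
        gamma, err = shape_collapse(self.family(), gamma_grid=(0.0, 1.0, 0.01))
        assert gamma == pytest.approx(0.5, abs=0.011)
        assert err < 1e-4

    def test_noisy_family(self):
        gamma, _ = shape_collapse(self.family(noise=0.05, seed=1), gamma_grid=(0.0, 1.0, 0.01))
        assert abs(gamma - 0.5) < 0.1

    def test_random_profiles_collapse_poorly(self):
        rng = np.random.default_rng(2)
        rand = {T: rng.random(T) + 0.1 for T in (10, 20, 40)}
        _, err_self = shape_collapse(self.family(), gamma_grid=(0.0, 1.0, 0.01))
        _, err_rand = shape_collapse(rand, gamma_grid=(0.0, 1.0, 0.01))
        assert err_rand > 10 * err_self

    def test_too_few_durations_rejected(self):
        with pytest.raises(InsufficientScalingDataError):
            shape_collapse({10: np.ones(10), 20: np.ones(20)})


class TestDistributionDistance:
    @pytest.mark.parametrize("metric", ["ks", "wasserstein"])
    def test_identity_and_symmetry(self, metric):
        a = np.array([1, 2, 2, 5, 9])
        b = np.array([1, 3, 4, 4, 8])
        assert distribution_distance(a, a, metric) == 0.0
        assert distribution_distance(a, b, metric) == distribution_distance(b, a, metric)

    def test_small_fixture_matches_brute_force(self):
        a, b = [1, 2, 3], [2, 3, 4]
        # KS: empirical CDFs on {1,2,3,4} are [1/3,2/3,1,1] and [0,1/3,2/3,1]
        assert distribution_distance(a, b, "ks") == pytest.approx(1 / 3)
        # 1-Wasserstein of log-values: mean |sorted log difference|
        oracle = np.mean(np.abs(np.log([1, 2, 3]) - np.log([2, 3, 4])))
        assert distribution_distance(a, b, "wasserstein") == pytest.approx(oracle)

    def test_ks_bounded_by_one(self):
        assert distribution_distance([1] * 5, [1000] * 5, "ks") == 1.0

    def test_unknown_metric_rejected(self):
        with pytest.raises(ValueError):
            distribution_distance([1], [2], "cramer")


class TestFiniteSizeScaling:
    def test_rebin_factor_one_is_identity(self, toy_raster):
        r = toy_raster.rebin(1)
        assert np.array_equal(r.times, toy_raster.times)
        assert r.n_bins == toy_raster.n_bins

    def test_rebin_is_logical_or(self):
        r = EventRaster(np.array([0, 0, 1]), np.array([0, 1, 5]), 2, 8)
        c = r.rebin(2)
        # fine bins 0,1 merge into coarse bin 0: one event, not two
        assert c.n_events == 2
        assert set(zip(c.channels, c.times)) == {(0, 0), (1, 2)}

    def test_critical_raster_sizes_collapse(self, critical_raster):
        fss_size, _ = finite_size_scaling(critical_raster, n_draws=5, seed=32)
        assert fss_size.distance_raw > 0
        assert fss_size.fold_change < 0

    def test_tiny_fraction_rejected(self, toy_raster):
        with pytest.raises(ValueError):
            finite_size_scaling(toy_raster, fractions=(1.0, 0.125), n_draws=2, seed=1)


class TestAverageFoldChange:
    def test_printed_ketamine_size_columns(self):
        pairs = [(0.1653117455, 0.0508161703), (0.1445344283, 0.0550677446)]
        assert average_fold_change(pairs) == pytest.approx(-0.66, abs=0.005)

    def test_no_change_and_full_collapse(self):
        assert average_fold_change([(0.3, 0.3)]) == 0.0
        assert average_fold_change([(0.3, 0.0)]) == -1.0

    def test_zero_raw_rejected(self):
        with pytest.raises(ValueError):
            average_fold_change([(0.0, 0.1)])
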