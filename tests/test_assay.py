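import numpy as np
import pytest

from ubrec.assay import (BindingSeries, CorrelationResult, GrowthSeries,
                         LogisticGrowth, SingleSiteBinding, correlate,
                         growth_efficiency, integrate_rois, logistic,
                         oval_mask, single_site)
from ubrec.errors import FitError, UbrecError, UndefinedEfficiencyError
from ubrec.simulate import make_binding_series, make_growth_stack


def binding_fixture(kd=100.0, rmax=50.0, n=8):
    conc = np.geomspace(0.1 * kd, 3.0 * kd, n)
    return BindingSeries(tuple(conc), tuple(single_site(conc, kd, rmax)))


class TestBindingSeries:
    def test_validation(self):
        with pytest.raises(ValueError):
            BindingSeries((1.0, 2.0), (5.0,))
        with pytest.raises(ValueError):
            BindingSeries((2.0, 1.0, 3.0, 4.0), (1.0, 2.0, 3.0, 4.0))
        with pytest.raises(ValueError):
            BindingSeries((-1.0, 1.0, 2.0, 3.0), (1.0, 2.0, 3.0, 4.0))


class TestSingleSiteFit:
    def test_noiseless_recovery(self):
        fit = SingleSiteBinding(binding_fixture()).fit(bootstrap=0)
        assert fit.kd == pytest.approx(100.0, rel=1e-6)
        assert fit.rmax == pytest.approx(50.0, rel=1e-6)
        assert fit.converged

    def test_half_max_at_kd(self):
        assert single_site(100.0, 100.0, 50.0) == pytest.approx(25.0)

    def test_scale_equivariance(self):
        s = binding_fixture()
        scaled = BindingSeries(s.concentrations, tuple(np.array(s.responses) * 7.0))
        f1 = SingleSiteBinding(s).fit(bootstrap=0)
        f2 = SingleSiteBinding(scaled).fit(bootstrap=0)
        assert f2.kd == pytest.approx(f1.kd, rel=1e-6)
        assert f2.rmax == pytest.approx(7.0 * f1.rmax, rel=1e-6)

    def test_too_few_concentrations(self):
        conc = (1.0, 2.0, 3.0)
        with pytest.raises(FitError):
            SingleSiteBinding(BindingSeries(conc, (1.0, 2.0, 3.0)))

    def test_bootstrap_ci_brackets_truth(self):
        series, _ = make_binding_series(kd=200.0, rmax=60.0, noise_cv=0.03, seed=4)
        fit = SingleSiteBinding(series).fit(bootstrap=200, seed=1)
        lo, hi = fit.kd_ci
        assert lo < fit.kd < hi

    def test_bootstrap_seed_reproducible(self):
        series, _ = make_binding_series(seed=9)
        f1 = SingleSiteBinding(series).fit(bootstrap=50, seed=3)
        f2 = SingleSiteBinding(series).fit(bootstrap=50, seed=3)
        assert f1.kd_ci == f2.kd_ci

    def test_scaled_responses_convention(self):
        fit = SingleSiteBinding(binding_fixture(rmax=50.0)).fit(bootstrap=0)
        scaled = fit.scaled_responses(100.0)
        assert scaled.max() == pytest.approx(
            100.0 * np.max(fit.model.series.resp) / 50.0)

    def test_summary_mentions_estimates(self):
        fit = SingleSiteBinding(binding_fixture()).fit(bootstrap=0)
        text = fit.summary()
        assert "Kd" in text and "Rmax" in text and "binding" in text


class TestBindingClassification:
    def test_pure_noise_is_no_binding(self):
        rng = np.random.default_rng(0)
        conc = np.geomspace(1, 1000, 8)
        series = BindingSeries(tuple(conc), tuple(rng.normal(0, 1.0, 8)))
        assert SingleSiteBinding(series).fit(bootstrap=0).classification == "no-binding"

    def test_clean_within_range_is_binding(self):
        series = binding_fixture(kd=100.0)
        assert SingleSiteBinding(series).fit(bootstrap=0).classification == "binding"

    def test_kd_far_beyond_range_is_no_binding(self):
        # Kd at 50x the max tested concentration: the rule calls no-binding
        kd = 50.0 * 1000.0
        conc = np.geomspace(1.0, 1000.0, 8)
        series = BindingSeries(tuple(conc), tuple(single_site(conc, kd, 50.0)))
        assert SingleSiteBinding(series).fit(bootstrap=0).classification == "no-binding"


class TestLogisticFit:
    def test_exact_recovery(self):
        t = np.arange(0.0, 48.0, 1.0)
        series = GrowthSeries(tuple(t), tuple(logistic(t, 2.0, 0.5, 20.0)))
        fit = LogisticGrowth(series).fit()
        assert not fit.nsg
        assert fit.K == pytest.approx(2.0, rel=1e-4)
        assert fit.r == pytest.approx(0.5, rel=1e-4)
        assert fit.t50 == pytest.approx(20.0, rel=1e-4)

    def test_flat_series_is_nsg(self):
        t = tuple(np.arange(10.0))
        assert LogisticGrowth(GrowthSeries(t, tuple([5.0] * 10))).fit().nsg
        assert LogisticGrowth(GrowthSeries(t, tuple([0.0] * 10))).fit().nsg

    def test_time_shift_equivariance(self):
        t = np.arange(0.0, 48.0, 1.0)
        d = logistic(t, 2.0, 0.5, 20.0)
        f1 = LogisticGrowth(GrowthSeries(tuple(t), tuple(d))).fit()
        f2 = LogisticGrowth(GrowthSeries(tuple(t + 5.0), tuple(d))).fit()
        assert f2.K == pytest.approx(f1.K, rel=1e-4)
        assert f2.r == pytest.approx(f1.r, rel=1e-4)
        assert f2.t50 == pytest.approx(f1.t50 + 5.0, rel=1e-4)

    def test_too_few_points(self):
        with pytest.raises(FitError):
            LogisticGrowth(GrowthSeries((0.0, 1, 2, 3, 4), (0.0, 1, 2, 3, 4)))


class TestEfficiency:
    def test_closed_form_value(self):
        t = np.arange(0.0, 48.0, 1.0)
        fit = LogisticGrowth(GrowthSeries(tuple(t),
                                          tuple(logistic(t, 2.0, 0.5, 20.0)))).fit()
        assert growth_efficiency(fit) == pytest.approx((0.5 * 2.0 / 4.0) / 20.0,
                                                       rel=1e-4)

    def test_scaling_laws(self):
        t = np.arange(0.0, 60.0, 0.5)

        def eff(K, r, t50):
            return LogisticGrowth(GrowthSeries(
                tuple(t), tuple(logistic(t, K, r, t50)))).fit().efficiency

        base = eff(2.0, 0.5, 20.0)
        assert eff(4.0, 0.5, 20.0) == pytest.approx(2 * base, rel=1e-3)
        assert eff(2.0, 0.5, 40.0) == pytest.approx(base / 2, rel=1e-3)

    def test_slope_matches_finite_difference(self):
        K, r, t50 = 2.0, 0.5, 20.0
        h = 1e-6
        slope = (logistic(t50 + h, K, r, t50) - logistic(t50 - h, K, r, t50)) / (2 * h)
        assert slope == pytest.approx(r * K / 4.0, abs=1e-6)

    def test_nsg_efficiency_undefined(self):
        t = tuple(np.arange(10.0))
        fit = LogisticGrowth(GrowthSeries(t, tuple([1.0] * 10))).fit()
        with pytest.raises(UndefinedEfficiencyError):
            growth_efficiency(fit)

    def test_plateau_variant(self):
        t = np.arange(0.0, 48.0, 1.0)
        fit = LogisticGrowth(GrowthSeries(tuple(t),
                                          tuple(logistic(t, 2.0, 0.5, 20.0)))).fit()
        assert fit.efficiency_plateau == pytest.approx(2.0 / 20.0, rel=1e-4)


class TestIntegrateRois:
    def test_blank_stack_zero_series(self):
        stack = np.zeros((5, 60, 60))
        series = integrate_rois(stack, [(30, 30)])
        assert np.allclose(series[0].d, 0.0)

    def test_planted_integral_recovered(self):
        times = np.arange(0.0, 72.0, 0.5)
        spots = [{"center": (60, 50), "K": 2000.0, "r": 0.35, "t50": 24.0}]
        stack, truth = make_growth_stack(spots, times, noise_sd=0.0,
                                         background_level=7.0, seed=1)
        series = integrate_rois(stack, [(60, 50)], times=times)[0]
        planted = np.array(truth["integrals"][0])
        late = planted > 50  # compare where the spot has real signal
        np.testing.assert_allclose(np.array(series.d)[late], planted[late],
                                   rtol=0.02)

    def test_uniform_background_offset_invariance(self):
        times = np.arange(0.0, 36.0, 1.0)
        spots = [{"center": (40, 40), "K": 500.0, "r": 0.4, "t50": 15.0}]
        stack, _ = make_growth_stack(spots, times, image_shape=(80, 80),
                                     noise_sd=0.0, seed=2)
        s1 = integrate_rois(stack, [(40, 40)], times=times)[0]
        s2 = integrate_rois(stack + 123.4, [(40, 40)], times=times)[0]
        np.testing.assert_allclose(s2.d, s1.d, atol=1e-6)

    def test_clipped_roi_rejected(self):
        stack = np.zeros((3, 50, 50))
        with pytest.raises(UbrecError):
            integrate_rois(stack, [(5, 25)])

    def test_oval_mask_pixel_count(self):
        mask = oval_mask((60, 60), (30, 30), (20, 20))
        # pixels whose centers satisfy the ellipse inequality: close to pi*r^2
        assert abs(mask.sum() - np.pi * 100) < 20


class TestCorrelate:
    def test_perfect_positive(self):
        x = np.arange(6.0)
        res = correlate(x, 2 * x)
        assert res.r == pytest.approx(1.0)
        assert res.n == 6

    def test_perfect_negative(self):
        x = np.arange(1.0, 7.0)
        assert correlate(x, -x).r == pytest.approx(-1.0)

    def test_fixture_matches_covariance_oracle(self):
        x = np.array([1.0, 2.0, 4.0, 5.0, 7.0, 9.0])
        y = np.array([2.1, 2.9, 6.2, 8.8, 10.1, 15.5])
        xc, yc = x - x.mean(), y - y.mean()
        oracle = float((xc * yc).sum() / np.sqrt((xc ** 2).sum() * (yc ** 2).sum()))
        res = correlate(x, y)
        assert res.r == pytest.approx(oracle, abs=1e-12)
        assert 0 < res.p_value < 0.05

    def test_zero_variance_rejected(self):
        with pytest.raises(UbrecError):
            correlate([1.0, 1.0, 1.0, 1.0], [1.0, 2.0, 3.0, 4.0])

    def test_too_short(self):
        with pytest.raises(UbrecError):
            correlate([1.0, 2.0], [1.0, 2.0])

    def test_result_validation(self):
        with pytest.raises(ValueError):
            CorrelationResult(r=1.5, p_value=0.1, n=5)
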