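"""Spatio-temporal model: design, spatial kernel, and Gibbs sampler checks."""

import numpy as np
import pytest

import chltrend as ct
from chltrend.errors import InsufficientDataError, InvalidConfigurationError
from chltrend.priors import LOG_PER_MONTH, TrendPrior


class TestSpatialCorrelation:
    def test_zero_distance(self):
        assert ct.spatial_correlation(0.0, 500.0) == 1.0

    def test_negligibility_horizon(self):
        # three e-folding lengths: correlation ~ 0.05
        assert ct.spatial_correlation(1500.0, 500.0) == pytest.approx(np.exp(-3.0), rel=1e-12)

    def test_monotone_decreasing(self):
        d = np.linspace(0, 3000, 50)
        c = ct.spatial_correlation(d, 500.0)
        assert np.all(np.diff(c) < 0)
        assert np.all((c > 0) & (c <= 1))


class TestBuildDesign:
    def test_phase_alignment_at_start(self, one_region_field, one_region_mask):
        start_cal_month = one_region_field.start_month[1]
        d = ct.build_design(one_region_field, one_region_mask, 0, start_cal_month)
        seasonal = d.x_time[:, 2]
        assert seasonal[0] == pytest.approx(1.0)
        assert seasonal[12] == pytest.approx(1.0)
        assert seasonal[24] == pytest.approx(1.0)

    def test_time_column_centered(self, one_region_field, one_region_mask):
        d = ct.build_design(one_region_field, one_region_mask, 0, 6)
        assert d.x_time[:, 1].sum() == pytest.approx(0.0, abs=1e-9)
        assert d.x_time.shape == (one_region_field.n_months, 3)

    def test_seasonal_zero_mean_over_whole_years(self, one_region_field, one_region_mask):
        d = ct.build_design(one_region_field, one_region_mask, 0, 4)
        assert d.x_time[:120, 2].sum() == pytest.approx(0.0, abs=1e-9)

    def test_calendar_anchored_phase(self, one_region_truth, one_region_mask):
        # two records starting in different months agree on matching calendar months
        f_jan = ct.simulate_chl_field(one_region_truth, one_region_mask, 48, start_month=(2000, 1))
        f_jul = ct.simulate_chl_field(one_region_truth, one_region_mask, 48, start_month=(2000, 7))
        d_jan = ct.build_design(f_jan, one_region_mask, 0, 6)
        d_jul = ct.build_design(f_jul, one_region_mask, 0, 6)
        # July record's t=0 is calendar month 7 = Jan record's t=6
        np.testing.assert_allclose(d_jul.x_time[:12, 2], d_jan.x_time[6:18, 2], atol=1e-12)

    def test_unknown_region_raises(self, one_region_field, one_region_mask):
        with pytest.raises(KeyError):
            ct.build_design(one_region_field, one_region_mask, 5, 6)


def _conjugate_posterior(field, mask, design, sigma2, prior_prec, prior_mean):
    """Closed-form Bayesian linear regression posterior (process disabled)."""
    rows, cols = mask.cells_of(0)
    Z = field.values[rows, cols, :]
    X = design.x_time
    N = Z.shape[0]
    P = N * (X.T @ X) / sigma2 + prior_prec
    b = X.T @ Z.sum(axis=0) / sigma2 + prior_prec @ prior_mean
    cov = np.linalg.inv(P)
    return cov @ b, cov


@pytest.fixture(scope="module")
def noprocess_field():
    mask = ct.generate_region_layout(1, (6, 6), seed=3)
    truth = ct.SimulationTruth(
        region_trends={0: 1.0},
        intercepts={0: -1.0},
        seasonal_amplitudes={0: 0.2},
        seasonal_peak_months={0: 6},
        process_sd=0.0,
        nugget_sd=0.15,
        missing_fraction=0.0,
        seed=21,
    )
    return ct.simulate_chl_field(truth, mask, 96), mask


class TestConjugateLimit:
    def test_matches_closed_form_posterior(self, noprocess_field):
        field, mask = noprocess_field
        design = ct.build_design(field, mask, 0, 6)
        sigma2 = 0.15**2
        cfg = ct.STModelConfig(
            n_iterations=5000,
            n_burnin=200,
            seed=5,
            sample_process=False,
            fixed_nugget_variance=sigma2,
        )
        samples = ct.fit_st_model(field, mask, 0, design, cfg)
        prior_prec = np.diag([1e-4, 1.0 / ct.convert_prior_units(cfg.trend_prior, LOG_PER_MONTH).variance, 1e-4])
        mean, cov = _conjugate_posterior(field, mask, design, sigma2, prior_prec, np.zeros(3))
        n = samples.n_draws
        for j in range(3):  # every covariate, not just the trend
            se = np.sqrt(cov[j, j] / n)
            assert abs(samples.beta[:, j].mean() - mean[j]) < 3 * se
        sample_cov = np.cov(samples.beta.T)
        for j in range(3):
            for k in range(3):
                se = np.sqrt((cov[j, j] * cov[k, k] + cov[j, k] ** 2) / (n - 1))
                assert abs(sample_cov[j, k] - cov[j, k]) < 3 * se + 1e-15

    def test_degenerate_prior_pins_trend(self, noprocess_field):
        field, mask = noprocess_field
        design = ct.build_design(field, mask, 0, 6)
        mu0 = 5e-4
        cfg = ct.STModelConfig(
            trend_prior=TrendPrior(mu0, 1e-10, LOG_PER_MONTH, "ensemble", 2),
            n_iterations=1000,
            n_burnin=100,
            seed=6,
            sample_process=False,
            fixed_nugget_variance=0.15**2,
        )
        samples = ct.fit_st_model(field, mask, 0, design, cfg)
        assert abs(samples.trend_draws.mean() - mu0) < 1e-4


class TestGibbsSampler:
    def test_chain_reproducible(self, one_region_field, one_region_mask):
        design = ct.build_design(one_region_field, one_region_mask, 0, 6)
        cfg = ct.STModelConfig(n_iterations=1000, n_burnin=50, seed=9)
        a = ct.fit_st_model(one_region_field, one_region_mask, 0, design, cfg)
        b = ct.fit_st_model(one_region_field, one_region_mask, 0, design, cfg)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.rho, b.rho)
        np.testing.assert_array_equal(a.sigma2_nugget, b.sigma2_nugget)

    def test_draw_count_and_support(self, small_fit):
        assert small_fit.n_draws == 2000
        assert np.all(small_fit.sigma2_nugget > 0)
        assert np.all(small_fit.sigma2_process > 0)
        assert np.all((small_fit.rho > -1) & (small_fit.rho < 1))

    def test_recovers_known_trend(self, small_fit, one_region_truth):
        est = ct.estimate_from_draws(small_fit.trend_draws, 0, "vague")
        assert est.hdi_low_pct_yr < one_region_truth.region_trends[0] < est.hdi_high_pct_yr

    def test_recovers_variance_components(self, small_fit, one_region_truth):
        # nugget variance is well identified; process variance and rho are
        # weakly identified at this size, so only the nugget is pinned down
        assert small_fit.sigma2_nugget.mean() == pytest.approx(one_region_truth.nugget_sd**2, rel=0.25)
        # stationary marginal variance of w is the identified combination
        stat_var = (small_fit.sigma2_process / (1 - small_fit.rho**2)).mean()
        true_stat = one_region_truth.process_sd**2 / (1 - one_region_truth.ar1_rho**2)
        assert stat_var == pytest.approx(true_stat, rel=1.5)

    def test_handles_missing_months_by_imputation(self, one_region_truth, one_region_mask):
        import dataclasses

        truth = dataclasses.replace(one_region_truth, missing_fraction=0.35, seed=77)
        field = ct.simulate_chl_field(truth, one_region_mask, 96)
        design = ct.build_design(field, one_region_mask, 0, 6)
        cfg = ct.STModelConfig(n_iterations=1500, n_burnin=500, seed=10)
        samples = ct.fit_st_model(field, one_region_mask, 0, design, cfg)
        est = ct.estimate_from_draws(samples.trend_draws, 0, "vague")
        assert est.hdi_low_pct_yr - 0.5 < truth.region_trends[0] < est.hdi_high_pct_yr + 0.5

    def test_knot_approximation_close_to_full_rank(self, one_region_field, one_region_mask):
        design = ct.build_design(one_region_field, one_region_mask, 0, 6)
        full = ct.STModelConfig(n_iterations=1500, n_burnin=500, seed=12)
        red = ct.STModelConfig(n_iterations=1500, n_burnin=500, seed=12, knots=16)
        s_full = ct.fit_st_model(one_region_field, one_region_mask, 0, design, full)
        s_red = ct.fit_st_model(one_region_field, one_region_mask, 0, design, red)
        assert s_red.diagnostics["n_modes"] == 16
        e_full = ct.estimate_from_draws(s_full.trend_draws, 0, "vague")
        e_red = ct.estimate_from_draws(s_red.trend_draws, 0, "vague")
        assert abs(e_red.mode_pct_yr - e_full.mode_pct_yr) < e_full.hdi_width_pct_yr

    def test_all_missing_month_rejected(self, one_region_field, one_region_mask):
        broken = ct.ChlField(
            values=one_region_field.values.copy(),
            lat_centers=one_region_field.lat_centers,
            lon_centers=one_region_field.lon_centers,
            start_month=one_region_field.start_month,
        )
        broken.values[:, :, 30] = np.nan
        design = ct.build_design(broken, one_region_mask, 0, 6)
        cfg = ct.STModelConfig(n_iterations=1000, n_burnin=100, seed=1)
        with pytest.raises(InsufficientDataError):
            ct.fit_st_model(broken, one_region_mask, 0, design, cfg)

    def test_config_invariants_enforced(self):
        with pytest.raises(InvalidConfigurationError):
            ct.STModelConfig(n_iterations=500)
        with pytest.raises(InvalidConfigurationError):
            ct.STModelConfig(spatial_decay_km=-1.0)
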