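"""Generator checks: partitions, determinism, and moment recovery."""

import numpy as np
import pytest

import chltrend as ct
from chltrend.errors import InvalidConfigurationError
from chltrend.regions import NO_REGION, pairwise_distances_km


class TestRegionLayout:
    def test_single_region_covers_grid(self):
        mask = ct.generate_region_layout(1, (4, 4), seed=0)
        assert np.all(mask.region_of_cell == 0)

    def test_deterministic_given_seed(self):
        a = ct.generate_region_layout(4, (8, 8), seed=1)
        b = ct.generate_region_layout(4, (8, 8), seed=1)
        np.testing.assert_array_equal(a.region_of_cell, b.region_of_cell)

    @pytest.mark.parametrize("n_regions,shape,seed", [(4, (8, 8), 1), (3, (10, 6), 7), (6, (12, 12), 2)])
    def test_partition_disjoint_and_exhaustive(self, n_regions, shape, seed):
        mask = ct.generate_region_layout(n_regions, shape, seed=seed)
        assert mask.region_of_cell.shape == shape
        assert not np.any(mask.region_of_cell == NO_REGION)
        assert sorted(np.unique(mask.region_of_cell)) == list(range(n_regions))

    @pytest.mark.parametrize("n_regions,seed", [(4, 0), (4, 3), (5, 9)])
    def test_regions_contiguous(self, n_regions, seed):
        mask = ct.generate_region_layout(n_regions, (10, 10), seed=seed)
        grid = mask.region_of_cell
        for r in range(n_regions):
            cells = set(zip(*np.nonzero(grid == r)))
            start = next(iter(cells))
            seen = {start}
            stack = [start]
            while stack:
                i, j = stack.pop()
                for d in ((1, 0), (-1, 0), (0, 1), (0, -1)):
                    nb = (i + d[0], j + d[1])
                    if nb in cells and nb not in seen:
                        seen.add(nb)
                        stack.append(nb)
            assert seen == cells, f"region {r} is not contiguous"

    def test_too_many_regions_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            ct.generate_region_layout(17, (4, 4), seed=0)


class TestSimulateField:
    def test_noise_free_limit_is_exact_mean_surface(self):
        mask = ct.generate_region_layout(1, (4, 4), seed=0)
        truth = ct.SimulationTruth(
            region_trends={0: 1.0},
            intercepts={0: -1.0},
            seasonal_amplitudes={0: 0.2},
            seasonal_peak_months={0: 3},
            process_sd=0.0,
            nugget_sd=0.0,
            missing_fraction=0.0,
            seed=5,
        )
        field = ct.simulate_chl_field(truth, mask, 36)
        t = np.arange(36.0)
        months = field.calendar_months()
        beta = ct.from_percent_per_year(1.0)
        expected = -1.0 + beta * t + 0.2 * np.cos(2 * np.pi * (months - 3) / 12.0)
        np.testing.assert_allclose(field.values[0, 0, :], expected, rtol=0, atol=1e-12)
        # same deterministic surface in every cell of the region
        assert np.allclose(field.values, field.values[0, 0, :][None, None, :])

    def test_deterministic_given_truth_seed(self, one_region_truth, one_region_mask):
        a = ct.simulate_chl_field(one_region_truth, one_region_mask, 48)
        b = ct.simulate_chl_field(one_region_truth, one_region_mask, 48)
        np.testing.assert_array_equal(a.values, b.values)

    def test_ar1_moment_recovered(self):
        # pure process (no nugget/season/trend): pooled lag-1 autocorrelation ~ rho
        mask = ct.generate_region_layout(1, (8, 8), seed=1)
        truth = ct.SimulationTruth(
            region_trends={0: 0.0},
            intercepts={0: 0.0},
            seasonal_amplitudes={0: 0.0},
            seasonal_peak_months={0: 1},
            ar1_rho=0.6,
            process_sd=0.1,
            nugget_sd=0.0,
            missing_fraction=0.0,
            seed=8,
        )
        field = ct.simulate_chl_field(truth, mask, 120)  # 64 cells x 120 months > 5,000
        v = field.values.reshape(-1, 120)
        v = v - v.mean(axis=1, keepdims=True)
        rho_hat = np.sum(v[:, 1:] * v[:, :-1]) / np.sum(v[:, :-1] ** 2)
        assert abs(rho_hat - 0.6) < 0.1

    def test_spatial_correlation_decays_with_distance(self):
        mask = ct.generate_region_layout(1, (16, 16), seed=2)
        truth = ct.SimulationTruth(
            region_trends={0: 0.0},
            intercepts={0: 0.0},
            seasonal_amplitudes={0: 0.0},
            seasonal_peak_months={0: 1},
            spatial_decay_km=300.0,
            process_sd=0.1,
            nugget_sd=0.0,
            missing_fraction=0.0,
            seed=9,
        )
        field = ct.simulate_chl_field(truth, mask, 240)
        rows, cols = np.nonzero(mask.region_of_cell == 0)
        lats, lons = mask.lat_centers[rows], mask.lon_centers[cols]
        d = pairwise_distances_km(lats, lons)
        v = field.values.reshape(-1, 240)
        corr = np.corrcoef(v)
        near = (d > 0) & (d < 150.0)
        far = d >= 3 * 300.0
        assert corr[near].mean() > corr[far].mean()
        assert corr[far].mean() < 0.15

    def test_missingness_fraction_and_masking(self, one_region_mask):
        truth = ct.SimulationTruth(
            region_trends={0: 0.0},
            intercepts={0: 0.0},
            seasonal_amplitudes={0: 0.0},
            seasonal_peak_months={0: 1},
            missing_fraction=0.3,
            seed=4,
        )
        field = ct.simulate_chl_field(truth, one_region_mask, 60)
        frac = np.isnan(field.values).mean()
        assert abs(frac - 0.3) < 0.03


class TestClimateEnsemble:
    def _truth(self, **kw):
        base = dict(
            region_trends={0: 0.8},
            intercepts={0: -1.0},
            seasonal_amplitudes={0: 0.1},
            seasonal_peak_months={0: 4},
            seed=1,
        )
        base.update(kw)
        return ct.SimulationTruth(**base)

    def test_degenerate_ensemble_recovers_true_trend_exactly(self):
        truth = self._truth(process_sd=0.0)
        runs = ct.simulate_climate_ensemble(truth, 3, [1, 1, 1], 120, model_trend_sd=0.0, seed=0)
        for run in runs:
            slope, _ = ct.fit_gls_ar1_trend(run.series, start_month=run.start_month)
            assert abs(ct.to_percent_per_year(slope) - 0.8) < 1e-8

    def test_cmip5_table_layout_emits_24_runs(self):
        counts = list(ct.CMIP5_ENSEMBLE_COUNTS.values())
        assert len(counts) == 14 and sum(counts) == 24
        truth = self._truth()
        runs = ct.simulate_climate_ensemble(truth, 14, counts, 120, model_trend_sd=0.3, seed=5)
        assert len(runs) == 24
        assert len({r.model_id for r in runs}) == 14

    def test_deterministic_given_seed(self):
        truth = self._truth()
        a = ct.simulate_climate_ensemble(truth, 3, [1, 2, 1], 60, 0.5, seed=7)
        b = ct.simulate_climate_ensemble(truth, 3, [1, 2, 1], 60, 0.5, seed=7)
        for ra, rb in zip(a, b):
            np.testing.assert_array_equal(ra.series, rb.series)

    def test_fewer_than_two_models_rejected(self):
        with pytest.raises(InvalidConfigurationError):
            ct.simulate_climate_ensemble(self._truth(), 1, [1], 60, 0.5, seed=0)


class TestRoundTrips:
    def test_field_netcdf_roundtrip(self, one_region_field, tmp_path):
        p = tmp_path / "field.nc"
        one_region_field.to_netcdf(p)
        back = ct.ChlField.from_netcdf(p)
        np.testing.assert_allclose(back.values, one_region_field.values)
        assert back.start_month == one_region_field.start_month

    def test_mask_netcdf_roundtrip(self, one_region_mask, tmp_path):
        p = tmp_path / "mask.nc"
        one_region_mask.to_netcdf(p)
        back = ct.RegionMask.from_netcdf(p)
        np.testing.assert_array_equal(back.region_of_cell, one_region_mask.region_of_cell)
        np.testing.assert_allclose(back.cell_area_km2, one_region_mask.cell_area_km2)

    def test_truth_json_roundtrip(self, one_region_truth):
        back = ct.SimulationTruth.from_json(one_region_truth.to_json())
        assert back == one_region_truth

    def test_runs_csv_roundtrip(self, tmp_path):
        truth = ct.SimulationTruth(
            region_trends={0: 0.5, 1: -0.5},
            intercepts={0: -1.0, 1: -1.2},
            seasonal_amplitudes={0: 0.1, 1: 0.1},
            seasonal_peak_months={0: 2, 1: 9},
            seed=3,
        )
        runs = ct.simulate_climate_ensemble(truth, 2, [2, 1], 48, 0.4, seed=1)
        p = tmp_path / "runs.csv"
        from chltrend.synthetic import read_runs_csv, write_runs_csv

        write_runs_csv(runs, p)
        back = read_runs_csv(p)
        assert len(back) == len(runs)
        key = lambda r: (r.model_id, r.ensemble_id, r.region_id)
        for ra, rb in zip(sorted(runs, key=key), sorted(back, key=key)):
            assert key(ra) == key(rb)
            np.testing.assert_allclose(ra.series, rb.series)
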