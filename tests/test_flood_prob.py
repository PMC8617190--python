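"""Poisson-GPD flood frequency: fitting, the annual exceedance curve, the
Monte Carlo total-probability convolution, and rasterized surfaces."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from coastal_eae.config import RegionConfig, StationGPD
from coastal_eae.flood import (
    LOOKUP_ELEVATIONS, ExceedanceLookup, FloodFitError, GPDParams,
    annual_exceedance_probability, build_lookup_tables, expected_exceedances,
    fit_gpd, nearest_station_map, probability_surface, total_exceedance_curve,
)
from coastal_eae.synth import generate_stations_and_extremes

PARAMS = GPDParams(shape=0.1, scale=0.2, threshold=0.5, rate=3.0,
                   record_years=50)


class TestBaselineCurve:
    def test_closed_form_oracle(self):
        # N(1.0) = 3 * (1 + 0.1*0.5/0.2)^(-10) = 3 * 1.25^-10
        n = expected_exceedances(PARAMS, 1.0)
        assert n == pytest.approx(3 * 1.25 ** -10, rel=1e-12)
        assert float(n) == pytest.approx(0.3221, abs=1e-4)
        p = annual_exceedance_probability(PARAMS, 1.0)
        assert float(p) == pytest.approx(1 - np.exp(-3 * 1.25 ** -10),
                                         rel=1e-12)
        assert float(p) == pytest.approx(0.2754, abs=1e-4)

    def test_clamped_to_one_at_and_below_mhhw(self):
        assert float(annual_exceedance_probability(PARAMS, 0.0)) == 1.0
        assert float(annual_exceedance_probability(PARAMS, -2.0)) == 1.0

    def test_zero_beyond_negative_shape_upper_bound(self):
        p = GPDParams(shape=-0.2, scale=0.2, threshold=0.5, rate=3.0,
                      record_years=50)
        assert p.upper_bound == pytest.approx(1.5)
        assert float(annual_exceedance_probability(p, 1.6)) == 0.0
        assert float(annual_exceedance_probability(p, 1.4)) > 0.0

    def test_exponential_limit_matches_small_shape(self):
        near0 = GPDParams(shape=1e-12, scale=0.2, threshold=0.5, rate=3.0,
                          record_years=50)
        e = np.linspace(0.1, 5, 40)
        np.testing.assert_allclose(
            expected_exceedances(near0, e), 3.0 * np.exp(-(e - 0.5) / 0.2),
            rtol=1e-6)

    def test_curve_non_increasing_in_elevation(self):
        e = np.linspace(0, 10, 101)
        p = annual_exceedance_probability(PARAMS, e)
        assert (np.diff(p) <= 1e-15).all()


class TestFit:
    def test_rate_is_count_over_years(self):
        heights = 0.5 + stats.genpareto.rvs(0.1, scale=0.2, size=120,
                                            random_state=1)
        fit = fit_gpd(heights, 40, threshold=0.5)
        assert fit.rate == pytest.approx(3.0)
        assert fit.n_exceedances == 120

    def test_short_record_rejected(self):
        with pytest.raises(FloodFitError, match="30"):
            fit_gpd(np.linspace(0.6, 2, 50), 20, threshold=0.5)

    def test_too_few_exceedances_names_station(self):
        with pytest.raises(FloodFitError, match="gauge7"):
            fit_gpd(np.array([0.6] * 5 + [0.1] * 200), 50, threshold=0.5,
                    station="gauge7")

    def test_constant_excesses_flagged_degenerate(self):
        fit = fit_gpd(np.full(50, 0.6), 50, threshold=0.5)
        assert fit.degenerate
        assert fit.scale <= 1e-6

    def test_parameter_recovery_from_known_truth(self):
        """Median fit over 20 independent 50-year records recovers the
        generator's shape within +-0.15 and scale within +-20%."""
        truth = StationGPD(shape=0.1, scale=0.2, threshold=0.5, rate=3.0)
        shapes, scales = [], []
        for seed in range(20):
            cfg = RegionConfig(n_stations=1, station_gpd=(truth,),
                               record_years=50, seed=seed)
            _, extremes = generate_stations_and_extremes(cfg)
            fit = fit_gpd(extremes["height_m"].to_numpy(), 50,
                          threshold=truth.threshold)
            shapes.append(fit.shape)
            scales.append(fit.scale)
        assert abs(np.median(shapes) - truth.shape) < 0.15
        assert abs(np.median(scales) - truth.scale) / truth.scale < 0.20


class TestTotalProbability:
    def test_zero_slr_reproduces_baseline_exactly(self):
        col = total_exceedance_curve(PARAMS, np.zeros(10))
        np.testing.assert_array_equal(
            col, annual_exceedance_probability(PARAMS, LOOKUP_ELEVATIONS))

    def test_saturating_sample_averages_with_one(self):
        col = total_exceedance_curve(PARAMS, np.array([0.0, 20.0]))
        base = annual_exceedance_probability(PARAMS, LOOKUP_ELEVATIONS)
        np.testing.assert_allclose(col, (base + 1.0) / 2.0, rtol=1e-15)

    def test_matches_brute_force_sample_average(self):
        rng = np.random.default_rng(5)
        slr = np.maximum(rng.normal(0.5, 0.1, size=100), 0.0)
        col = total_exceedance_curve(PARAMS, slr, np.array([1.0]))
        # independent oracle: loop over samples, no vectorized shift
        acc = 0.0
        for s in slr:
            acc += float(annual_exceedance_probability(PARAMS, 1.0 - s))
        assert col[0] == pytest.approx(acc / len(slr), abs=1e-12)

    def test_duplicating_the_ensemble_changes_nothing(self):
        rng = np.random.default_rng(6)
        slr = rng.uniform(0, 1, size=50)
        a = total_exceedance_curve(PARAMS, slr)
        b = total_exceedance_curve(PARAMS, np.concatenate([slr, slr]))
        np.testing.assert_allclose(a, b, atol=1e-15)

    def test_columns_monotone_in_elevation_and_decade(self, default_region):
        slr = default_region.slr
        prev = None
        for decade in slr.decades:
            col = total_exceedance_curve(
                PARAMS, slr.samples_for(1, "4.5", decade))
            assert (np.diff(col) <= 1e-15).all()
            if prev is not None:
                assert (col >= prev - 1e-15).all()
            prev = col

    def test_mc_error_shrinks_with_ensemble_size(self):
        """Column standard error across seed replicates scales ~ 1/sqrt(M)."""
        def se(m):
            vals = []
            for seed in range(12):
                rng = np.random.default_rng(seed)
                slr = np.maximum(rng.normal(0.4, 0.2, size=m), 0)
                vals.append(total_exceedance_curve(PARAMS, slr,
                                                   np.array([1.0]))[0])
            return np.std(vals)
        ratio = se(64) / se(1024)
        assert 2.0 < ratio < 8.0  # ideal 4x, generous band


class TestSurface:
    def _lookup(self):
        return build_lookup_tables(
            {1: PARAMS,
             2: GPDParams(shape=0.0, scale=0.3, threshold=0.6, rate=2.0,
                          record_years=50)},
            lambda sid, scen, dec: np.array([0.0, 0.3]), ["4.5"], [2050])

    def test_value_at_grid_node_is_tabulated_value(self):
        lk = self._lookup()
        col = lk.column(1, "4.5", 2050)
        assert lk.interpolate(1, "4.5", 2050, 0.5) == col[5]

    def test_surface_monotone_and_special_pixels(self):
        lk = self._lookup()
        elev = np.array([[1.0, 2.0, 12.0, -0.5]])
        ocean = np.array([[False, False, False, True]])
        assign = np.ones_like(elev, dtype=int)
        surf = probability_surface(elev, ocean, assign, lk, "4.5", 2050)
        assert surf[0, 0] >= surf[0, 1]
        assert surf[0, 2] == 0.0  # above the 10 m lookup domain
        assert surf[0, 3] == 1.0  # ocean

    def test_surface_matches_direct_evaluation(self):
        """10x10 grid, 2 stations: the interpolated surface agrees with a
        per-pixel direct Monte Carlo evaluation (no lookup) to 1e-3."""
        rng = np.random.default_rng(9)
        elev = rng.uniform(0, 9.5, size=(10, 10))
        ocean = np.zeros((10, 10), dtype=bool)
        stations = pd.DataFrame({"station_id": [1, 2], "row": [0, 9],
                                 "col": [0, 0]})
        assign = nearest_station_map((10, 10), stations)
        slr = np.maximum(rng.normal(0.3, 0.1, size=200), 0)
        params = {1: PARAMS, 2: GPDParams(shape=-0.05, scale=0.25,
                                          threshold=0.4, rate=2.5,
                                          record_years=50)}
        lk = build_lookup_tables(params, lambda s, c, d: slr, ["4.5"], [2050])
        surf = probability_surface(elev, ocean, assign, lk, "4.5", 2050)
        for r in range(10):
            for c in range(10):
                direct = np.mean([
                    float(annual_exceedance_probability(
                        params[assign[r, c]], elev[r, c] - s)) for s in slr])
                assert surf[r, c] == pytest.approx(direct, abs=1e-3)

    def test_nearest_station_tie_breaks_to_lowest_id(self):
        stations = pd.DataFrame({"station_id": [2, 1], "row": [0, 2],
                                 "col": [0, 0]})
        assign = nearest_station_map((3, 1), stations)
        assert assign[1, 0] == 1  # equidistant -> lowest id

    def test_missing_lookup_is_hard_error(self):
        lk = self._lookup()
        with pytest.raises(KeyError, match="2100"):
            lk.column(1, "4.5", 2100)

    def test_lookup_roundtrip_through_frame(self):
        lk = self._lookup()
        back = ExceedanceLookup.from_frame(lk.to_frame())
        for key, col in lk.columns.items():
            np.testing.assert_allclose(back.columns[key], col)
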