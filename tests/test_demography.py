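"""Housing-unit method: proportional backcast to census controls, mixed
linear/power projection anchored at the launch year, P = H*PPHU + GQ, and
raking to SSP county totals."""

import numpy as np
import pandas as pd
import pytest

from coastal_eae.demography import (
    DemographyError, backcast_housing, compute_population, control_to_ssp,
    project_housing,
)


def _vintages(rows):
    return pd.DataFrame(rows, columns=["block_group_id", "county_id",
                                       "vintage_bin", "units"])


class TestBackcast:
    def test_proportional_allocation_worked_example(self):
        # county 1960 census 100; county pre-1960 stock 50; a block group
        # holding 10 of those units gets 100 * 10/50 = 20
        vint = _vintages([
            (1, 1, "pre1940", 10.0), (2, 1, "pre1940", 30.0),
            (2, 1, "1950s", 10.0),
        ])
        ctl = pd.DataFrame({"county_id": [1], "decade": [1960],
                            "units": [100.0]})
        hist = backcast_housing(vint, ctl)
        assert hist.loc[1, 1960] == pytest.approx(20.0)
        assert hist.loc[2, 1960] == pytest.approx(80.0)

    def test_single_blockgroup_county_gets_full_control(self):
        vint = _vintages([(7, 3, "pre1940", 12.0), (7, 3, "1960s", 5.0)])
        ctl = pd.DataFrame({"county_id": 3, "decade": [1940, 1980],
                            "units": [33.0, 55.0]})
        hist = backcast_housing(vint, ctl)
        assert hist.loc[7, 1940] == pytest.approx(33.0)
        assert hist.loc[7, 1980] == pytest.approx(55.0)

    def test_county_sums_conserve_controls(self, default_region):
        r = default_region
        hist = backcast_housing(r.vintages, r.controls)
        bg_cty = r.bg_county_map()
        sums = hist.groupby(bg_cty.reindex(hist.index)).sum()
        ctl = r.controls.pivot_table(index="county_id", columns="decade",
                                     values="units")
        np.testing.assert_allclose(sums[ctl.columns].to_numpy(),
                                   ctl.to_numpy(), rtol=1e-12)

    def test_scale_equivariance(self, default_region):
        r = default_region
        base = backcast_housing(r.vintages, r.controls)
        vint = r.vintages.assign(units=r.vintages["units"] * 3.0)
        ctl = r.controls.assign(units=r.controls["units"] * 3.0)
        np.testing.assert_allclose(backcast_housing(vint, ctl).to_numpy(),
                                   3.0 * base.to_numpy(), rtol=1e-12)

    def test_zero_denominator_with_positive_control_is_hard_error(self):
        vint = _vintages([(1, 1, "1990s", 10.0)])  # nothing built pre-1940
        ctl = pd.DataFrame({"county_id": [1], "decade": [1940],
                            "units": [10.0]})
        with pytest.raises(DemographyError, match="1940"):
            backcast_housing(vint, ctl)


def _hist(values):
    decades = list(range(1940, 2011, 10))
    return pd.DataFrame([values], index=pd.Index([1], name="block_group_id"),
                        columns=decades)


class TestProjection:
    def test_exactly_linear_series_continues_the_line(self):
        # H(tau) = 100 + 10*tau, tau = decades since 1930
        tau = np.arange(1, 9)
        hist = _hist(100.0 + 10.0 * tau)
        proj = project_housing(hist, horizon=(2020, 2050, 2100))
        for year in (2020, 2050, 2100):
            assert proj.loc[1, year] == pytest.approx(
                100 + 10 * (year - 1930) / 10, rel=1e-12)

    def test_constant_series_stays_constant(self):
        proj = project_housing(_hist(np.full(8, 50.0)),
                               horizon=(2020, 2100))
        assert proj.loc[1, 2020] == pytest.approx(50.0)
        assert proj.loc[1, 2100] == pytest.approx(50.0)

    def test_power_law_decline_recovered_against_loglog_oracle(self):
        tau = np.arange(1.0, 9.0)
        hist = _hist(200.0 * tau ** (-0.5))
        proj = project_housing(hist, horizon=(2100,))
        # independent oracle: plain least squares of log H on log tau
        b, a = np.polyfit(np.log(tau), np.log(200.0 * tau ** -0.5), 1)
        assert b == pytest.approx(-0.5, abs=0.05)
        tau_z, tau_t = 17.0, 8.0
        expected = (np.exp(a) * tau_z ** b
                    + (200.0 * 8 ** -0.5 - np.exp(a) * tau_t ** b))
        assert proj.loc[1, 2100] == pytest.approx(expected, rel=0.01)

    def test_launch_year_continuity_both_branches(self):
        grow = _hist(100.0 + 10.0 * np.arange(1, 9)
                     + np.array([0, 1, -2, 3, 0, -1, 2, 0.0]))
        decline = _hist(200.0 * np.arange(1.0, 9.0) ** -0.5)
        for hist in (grow, decline):
            proj = project_housing(hist, horizon=(2010, 2020))
            assert proj.loc[1, 2010] == pytest.approx(hist.loc[1, 2010],
                                                      rel=1e-9)

    def test_all_zero_series_projects_zero(self):
        proj = project_housing(_hist(np.zeros(8)), horizon=(2020, 2100))
        assert (proj.to_numpy() == 0).all()

    def test_projection_floor_is_zero(self):
        hist = _hist(np.array([80, 70, 60, 50, 40, 30, 20, 10.0]))
        proj = project_housing(hist, horizon=tuple(range(2020, 2101, 10)))
        assert (proj.to_numpy() >= 0).all()

    def test_too_short_history_is_an_error(self):
        hist = pd.DataFrame([[1.0, 2.0]], index=[1], columns=[2000, 2010])
        with pytest.raises(DemographyError):
            project_housing(hist)


class TestPopulation:
    def test_housing_unit_identity(self):
        housing = pd.DataFrame({2020: [10.0, 0.0]},
                               index=pd.Index([1, 2],
                                              name="block_group_id"))
        attrs = pd.DataFrame({"block_group_id": [1, 2], "pphu": [2.0, 3.0],
                              "gq": [5.0, 7.0]})
        pop = compute_population(housing, attrs)
        assert pop.loc[1, 2020] == 25.0
        assert pop.loc[2, 2020] == 7.0  # group quarters only

    def test_elementwise_against_direct_recomputation(self, default_region):
        r = default_region
        hist = backcast_housing(r.vintages, r.controls)
        pop = compute_population(hist, r.attributes)
        attrs = r.attributes.set_index("block_group_id")
        for bg in list(hist.index)[::5]:
            for d in (1940, 1980, 2010):
                assert pop.loc[bg, d] == pytest.approx(
                    hist.loc[bg, d] * attrs.loc[bg, "pphu"]
                    + attrs.loc[bg, "gq"], rel=1e-12)


class TestSSPControl:
    def _pop(self, values, decade=2020):
        return pd.DataFrame({decade: values},
                            index=pd.Index(range(1, len(values) + 1),
                                           name="block_group_id"))

    def test_uniform_scaling_to_control(self):
        pop = self._pop([30.0, 70.0])
        bg_cty = pd.Series([1, 1], index=[1, 2])
        ctl = pd.DataFrame({"county_id": [1], "ssp": ["SSP2"],
                            "decade": [2020], "population": [200.0]})
        out = control_to_ssp(pop, bg_cty, ctl).set_index("block_group_id")
        assert out.loc[1, "population"] == pytest.approx(60.0)
        assert out.loc[2, "population"] == pytest.approx(140.0)

    def test_control_equal_to_sum_is_identity(self):
        pop = self._pop([30.0, 70.0])
        bg_cty = pd.Series([1, 1], index=[1, 2])
        ctl = pd.DataFrame({"county_id": [1], "ssp": ["SSP2"],
                            "decade": [2020], "population": [100.0]})
        out = control_to_ssp(pop, bg_cty, ctl)
        np.testing.assert_allclose(out["population"], [30.0, 70.0])

    def test_zero_county_distributed_uniformly(self):
        pop = self._pop([0.0, 0.0])
        bg_cty = pd.Series([1, 1], index=[1, 2])
        ctl = pd.DataFrame({"county_id": [1], "ssp": ["SSP2"],
                            "decade": [2020], "population": [90.0]})
        out = control_to_ssp(pop, bg_cty, ctl)
        np.testing.assert_allclose(out["population"], [45.0, 45.0])

    def test_missing_county_control_is_hard_error(self):
        pop = self._pop([30.0, 70.0])
        bg_cty = pd.Series([1, 2], index=[1, 2])
        ctl = pd.DataFrame({"county_id": [1], "ssp": ["SSP2"],
                            "decade": [2020], "population": [200.0]})
        with pytest.raises(DemographyError, match="SSP2"):
            control_to_ssp(pop, bg_cty, ctl)

    def test_coarse_controls_are_interpolated(self):
        pop = pd.DataFrame({2020: [50.0], 2030: [50.0], 2040: [50.0]},
                           index=pd.Index([1], name="block_group_id"))
        bg_cty = pd.Series([1], index=[1])
        ctl = pd.DataFrame({"county_id": [1, 1], "ssp": ["SSP2", "SSP2"],
                            "decade": [2020, 2040],
                            "population": [100.0, 200.0]})
        out = control_to_ssp(pop, bg_cty, ctl).set_index("decade")
        assert out.loc[2030, "population"] == pytest.approx(150.0)

    def test_all_scenarios_conserve_county_totals(self, default_region):
        from coastal_eae.config import PipelineConfig
        from coastal_eae.pipeline import project_populations
        r = default_region
        pops = project_populations(r, PipelineConfig())
        sums = (pops.query("decade >= 2020")
                .groupby(["county_id", "ssp", "decade"])["population"].sum()
                .reset_index())
        merged = sums.merge(r.ssp_controls,
                            on=["county_id", "ssp", "decade"])
        np.testing.assert_allclose(merged["population_x"],
                                   merged["population_y"], rtol=1e-9)
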