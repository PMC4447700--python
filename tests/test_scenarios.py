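"""Forcing generator and scenario-transform behaviour."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

from baltfate.defaults import baltic_climatology, constant_climatology
from baltfate.scenarios import (
    DAYS_PER_YEAR,
    ClimatologyParams,
    ScenarioSpec,
    VariableClimate,
    apply_a1b_transform,
    build_emission_scenario,
    build_nutrient_loads,
    generate_rw_forcing,
)


def _noise_free(clim: ClimatologyParams) -> ClimatologyParams:
    basins = {
        b: {v: VariableClimate(mean=vc.mean, amplitude=vc.amplitude, sigma=0.0,
                               peak_doy=vc.peak_doy)
            for v, vc in vs.items()}
        for b, vs in clim.basins.items()
    }
    return ClimatologyParams(basins=basins, seed=clim.seed)


class TestRandomWeather:
    def test_same_seed_bit_identical(self):
        clim = baltic_climatology(seed=42)
        a = generate_rw_forcing(clim, 2000, 5)
        b = generate_rw_forcing(clim, 2000, 5)
        for var in a.data:
            np.testing.assert_array_equal(a.data[var], b.data[var])

    def test_different_seed_differs(self):
        a = generate_rw_forcing(baltic_climatology(seed=1), 2000, 5)
        b = generate_rw_forcing(baltic_climatology(seed=2), 2000, 5)
        assert not np.array_equal(a.data["air_temp"], b.data["air_temp"])

    def test_zero_noise_every_year_identical(self):
        clim = _noise_free(baltic_climatology(seed=0))
        f = generate_rw_forcing(clim, 2000, 4)
        for var in f.data:
            yearly = f.data[var].reshape(4, DAYS_PER_YEAR, -1)
            for y in range(1, 4):
                np.testing.assert_array_equal(yearly[y], yearly[0])

    def test_grand_mean_matches_climatology_within_3se(self):
        clim = baltic_climatology(seed=123)
        n_years = 100
        f = generate_rw_forcing(clim, 1950, n_years)
        for j, basin in enumerate(f.basins):
            vc = clim.basins[basin]["air_temp"]
            se = vc.sigma / np.sqrt(n_years)
            assert abs(f.air_temp[:, j].mean() - vc.mean) < 3 * se

    def test_long_run_stationary_no_trend(self):
        f = generate_rw_forcing(baltic_climatology(seed=7), 1950, 60)
        annual = f.air_temp[:, 0].reshape(60, DAYS_PER_YEAR).mean(axis=1)
        x = np.arange(60, dtype=float)
        slope, intercept = np.polyfit(x, annual, 1)
        resid = annual - (slope * x + intercept)
        se_slope = np.sqrt(resid.var(ddof=2) / ((x - x.mean()) ** 2).sum())
        assert abs(slope) < 3 * se_slope

    def test_nonpositive_years_rejected(self):
        with pytest.raises(ValueError):
            generate_rw_forcing(baltic_climatology(0), 2000, 0)

    def test_negative_amplitude_rejected(self):
        with pytest.raises(ValueError):
            VariableClimate(mean=1.0, amplitude=-0.1).validate("wind")

    def test_nonnegative_fields_clipped(self):
        f = generate_rw_forcing(baltic_climatology(seed=5), 2000, 30)
        for var in f.data:
            if var == "air_temp":
                continue
            assert (f.data[var] >= 0).all()


class TestA1b:
    @pytest.mark.parametrize("var,factor", [
        ("wind", 1.07), ("air_temp", 1.60), ("precip", 1.20)])
    def test_period_mean_ratios_exact(self, var, factor):
        base = generate_rw_forcing(baltic_climatology(seed=11), 2000, 30)
        tr = apply_a1b_transform(base, ScenarioSpec(climate="a1b"))
        ratio = tr.data[var].mean(axis=0) / base.data[var].mean(axis=0)
        np.testing.assert_allclose(ratio, factor, rtol=1e-12)

    def test_identity_when_factors_one(self):
        base = generate_rw_forcing(baltic_climatology(seed=3), 2000, 5)
        spec = ScenarioSpec(climate="a1b", a1b_wind_factor=1.0,
                            a1b_temp_factor=1.0, a1b_precip_factor=1.0)
        tr = apply_a1b_transform(base, spec)
        for var in base.data:
            np.testing.assert_array_equal(tr.data[var], base.data[var])

    def test_other_fields_untouched(self):
        base = generate_rw_forcing(baltic_climatology(seed=3), 2000, 5)
        tr = apply_a1b_transform(base, ScenarioSpec(climate="a1b"))
        for var in ("radiation", "discharge", "din_load", "dip_load",
                    "cont_load", "air_conc"):
            np.testing.assert_array_equal(tr.data[var], base.data[var])

    def test_delta_mode_warms_winter_days(self):
        # the additive-delta default must warm the coldest days, not cool them
        base = generate_rw_forcing(baltic_climatology(seed=3), 2000, 5)
        tr = apply_a1b_transform(base, ScenarioSpec(climate="a1b"))
        assert (tr.air_temp >= base.air_temp).all()
        assert tr.air_temp.min() > base.air_temp.min()

    def test_scale_mode_multiplies_each_value(self):
        base = generate_rw_forcing(baltic_climatology(seed=3), 2000, 5)
        spec = ScenarioSpec(climate="a1b", temperature_mode="scale")
        tr = apply_a1b_transform(base, spec)
        np.testing.assert_allclose(tr.air_temp, 1.60 * base.air_temp, rtol=1e-15)

    def test_invalid_factor_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(climate="a1b", a1b_wind_factor=0.0)


class TestNutrientScenarios:
    def test_constant_loads_identity(self):
        base = generate_rw_forcing(baltic_climatology(seed=9), 2000, 10)
        out = build_nutrient_loads(ScenarioSpec(nutrients="CL"), base)
        for var in base.data:
            np.testing.assert_array_equal(out.data[var], base.data[var])

    def test_bsap_endpoint_reaches_target_fraction(self):
        base = generate_rw_forcing(baltic_climatology(seed=9), 2000, 30)
        spec = ScenarioSpec(nutrients="BSAP", nutrient_target_factor=0.5,
                            nutrient_ramp_end_year=2020)
        out = build_nutrient_loads(spec, base)
        # from the end year onward the multiplier is the target exactly
        after = base.year >= 2021
        np.testing.assert_allclose(
            out.din_load[after], 0.5 * base.din_load[after], rtol=1e-12)

    def test_il_ramp_midpoint_interpolates_linearly(self):
        clim = _noise_free(constant_climatology())
        base = generate_rw_forcing(clim, 2000, 91)
        spec = ScenarioSpec(nutrients="IL", nutrient_target_factor=2.0)
        out = build_nutrient_loads(spec, base, horizon=90)
        # the day nearest the ramp midpoint carries a multiplier of 1.5
        mid = int(np.argmin(np.abs(base.frac_year - 2045.0)))
        assert out.din_load[mid, 0] / base.din_load[mid, 0] == pytest.approx(
            1.5, abs=1e-4)
        # and every day follows the linear interpolation formula exactly
        t = base.frac_year
        expected = 1.0 + np.clip((t - 2000.0) / 90.0, 0.0, 1.0) * 1.0
        np.testing.assert_allclose(
            out.din_load / base.din_load, expected[:, None], rtol=1e-12)

    def test_contaminant_and_weather_untouched(self):
        base = generate_rw_forcing(baltic_climatology(seed=9), 2000, 10)
        out = build_nutrient_loads(ScenarioSpec(nutrients="IL"), base)
        for var in ("air_temp", "wind", "precip", "radiation", "discharge",
                    "cont_load", "air_conc"):
            np.testing.assert_array_equal(out.data[var], base.data[var])

    def test_negative_target_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(nutrients="BSAP", nutrient_target_factor=-0.1)

    @given(target=st.floats(0.0, 3.0), end_offset=st.integers(1, 40))
    def test_multiplier_stays_between_one_and_target(self, target, end_offset):
        clim = _noise_free(constant_climatology())
        base = generate_rw_forcing(clim, 2000, 50)
        spec = ScenarioSpec(nutrients="IL", nutrient_target_factor=target,
                            nutrient_ramp_end_year=2000 + end_offset)
        out = build_nutrient_loads(spec, base)
        with np.errstate(invalid="ignore"):
            mult = np.where(base.din_load > 0, out.din_load / base.din_load, 1.0)
        lo, hi = min(1.0, target), max(1.0, target)
        assert (mult >= lo - 1e-9).all() and (mult <= hi + 1e-9).all()


class TestEmissionScenarios:
    def test_current_is_bit_identical(self):
        base = generate_rw_forcing(baltic_climatology(seed=2), 2000, 10)
        out = build_emission_scenario(ScenarioSpec(emissions="current"), base)
        for var in base.data:
            np.testing.assert_array_equal(out.data[var], base.data[var])

    def test_river_reduction_steps_at_reduction_year(self):
        base = generate_rw_forcing(baltic_climatology(seed=2), 2000, 15)
        spec = ScenarioSpec(emissions="red_river", reduction_year=2006,
                            reduction_fraction=0.9)
        out = build_emission_scenario(spec, base)
        in_2010 = base.year == 2010
        in_2005 = base.year == 2005
        np.testing.assert_allclose(out.cont_load[in_2010],
                                   0.10 * base.cont_load[in_2010], rtol=1e-15)
        np.testing.assert_array_equal(out.cont_load[in_2005],
                                      base.cont_load[in_2005])
        np.testing.assert_array_equal(out.air_conc, base.air_conc)

    def test_air_reduction_leaves_river_load_unchanged(self):
        base = generate_rw_forcing(baltic_climatology(seed=2), 2000, 15)
        spec = ScenarioSpec(emissions="red_air", reduction_year=2006,
                            reduction_fraction=0.9)
        out = build_emission_scenario(spec, base)
        after = base.year >= 2006
        np.testing.assert_allclose(out.air_conc[after],
                                   0.10 * base.air_conc[after], rtol=1e-15)
        np.testing.assert_array_equal(out.cont_load, base.cont_load)

    def test_reduction_year_outside_series_rejected(self):
        base = generate_rw_forcing(baltic_climatology(seed=2), 2000, 5)
        spec = ScenarioSpec(emissions="red_river", reduction_year=2050)
        with pytest.raises(ValueError):
            build_emission_scenario(spec, base)

    def test_emission_and_nutrient_transforms_commute(self):
        base = generate_rw_forcing(baltic_climatology(seed=2), 2000, 20)
        spec = ScenarioSpec(nutrients="BSAP", emissions="red_river",
                            reduction_year=2006)
        ab = build_emission_scenario(spec, build_nutrient_loads(spec, base))
        ba = build_nutrient_loads(spec, build_emission_scenario(spec, base))
        for var in base.data:
            np.testing.assert_array_equal(ab.data[var], ba.data[var])

    def test_invalid_scenario_labels_rejected(self):
        with pytest.raises(ValueError):
            ScenarioSpec(climate="rcp85")
        with pytest.raises(ValueError):
            ScenarioSpec(emissions="red_all")
        with pytest.raises(ValueError):
            ScenarioSpec(reduction_fraction=1.5)
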