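import math

import numpy as np
import pandas as pd
import pytest

from algaecast import (
    HarvestPolicy,
    HourlyMeteoSeries,
    LightAttenuation,
    StrainParams,
    apply_harvest,
    build_strain_surface,
    cold_archetype,
    depth_average_light,
    growth_rate,
    read_strain_csv,
    simulate_month,
    step_biomass,
    warm_archetype,
    write_strain_csv,
)
from algaecast.errors import DataError, DomainError
from algaecast.pond import WaterTempSeries
from conftest import make_hourly_frame


def small_strain(resp=0.1):
    temp = np.array([10.0, 20.0, 30.0])
    light = np.array([0.0, 500.0, 1000.0])
    surface = np.array([
        [-resp, 0.5, 0.8],
        [-resp, 1.0, 1.5],
        [-resp, 0.7, 1.1],
    ])
    return StrainParams("toy", temp, light, surface, dark_respiration_rate=resp)


class TestStrainParams:
    def test_dark_column_must_match_respiration(self):
        with pytest.raises(DataError, match="zero light"):
            StrainParams(
                "bad", [10.0, 20.0], [0.0, 500.0],
                [[0.0, 1.0], [0.0, 1.0]], dark_respiration_rate=0.1,
            )

    def test_grids_must_ascend(self):
        with pytest.raises(DataError, match="ascending"):
            StrainParams(
                "bad", [20.0, 10.0], [0.0, 500.0],
                [[-0.1, 1.0], [-0.1, 1.0]], dark_respiration_rate=0.1,
            )

    def test_csv_round_trip(self, tmp_path):
        strain = build_strain_surface(warm_archetype())
        path = tmp_path / "strain.csv"
        write_strain_csv(strain, path)
        back = read_strain_csv(path)
        assert back.name == strain.name
        assert back.dark_respiration_rate == strain.dark_respiration_rate
        assert back.valid_temp_range == strain.valid_temp_range
        np.testing.assert_array_equal(back.temp_grid, strain.temp_grid)
        np.testing.assert_array_equal(back.growth_rate_surface,
                                      strain.growth_rate_surface)


class TestGrowthRate:
    def test_grid_node_identity(self):
        s = small_strain()
        assert growth_rate(s, 500.0, 20.0) == 1.0
        assert growth_rate(s, 1000.0, 30.0) == 1.1

    def test_cell_center_is_mean_of_corners(self):
        s = small_strain()
        expected = (0.5 + 0.8 + 1.0 + 1.5) / 4.0
        assert growth_rate(s, 750.0, 15.0) == pytest.approx(expected)

    def test_zero_light_gives_dark_respiration_loss(self):
        s = small_strain(resp=0.17)
        for t in (10.0, 14.0, 25.0, 30.0):
            assert growth_rate(s, 0.0, t) == pytest.approx(-0.17)

    def test_light_clamps_to_grid_edge(self):
        s = small_strain()
        assert growth_rate(s, 5000.0, 20.0) == growth_rate(s, 1000.0, 20.0)

    def test_out_of_range_temperature_behaviors(self):
        s = small_strain()
        assert growth_rate(s, 500.0, 5.0) == growth_rate(s, 500.0, 10.0)
        s_die = small_strain()
        s_die.out_of_range_behavior = "dieoff"
        s_die.dieoff_rate = 0.4
        assert growth_rate(s_die, 500.0, 5.0) == -0.4

    def test_negative_light_rejected(self):
        with pytest.raises(DomainError):
            growth_rate(small_strain(), -1.0, 20.0)


class TestDepthAverageLight:
    def test_transparent_limit(self):
        atten = LightAttenuation(0.0, 0.0)
        assert depth_average_light(800.0, 0.3, 25.0, atten) == 800.0

    def test_closed_form_at_kd_ln2(self):
        # choose k_w so that k*d = ln 2 at zero biomass, d = 1 m
        atten = LightAttenuation(math.log(2.0), 0.0)
        got = depth_average_light(1000.0, 0.0, 100.0, atten)
        assert got == pytest.approx(1000.0 * 0.5 / math.log(2.0), rel=1e-12)
        # cross-check by numerical integration of I0*exp(-k z) over depth
        z = np.linspace(0.0, 1.0, 20001)
        numeric = np.trapezoid(1000.0 * np.exp(-math.log(2.0) * z), z)
        assert got == pytest.approx(numeric, rel=1e-6)

    def test_monotone_in_depth_and_concentration(self):
        atten = LightAttenuation()
        by_depth = [depth_average_light(1000.0, 0.2, d, atten)
                    for d in (10.0, 20.0, 30.0, 40.0)]
        assert np.all(np.diff(by_depth) < 0)
        by_conc = [depth_average_light(1000.0, c, 20.0, atten)
                   for c in (0.05, 0.2, 0.4, 0.8)]
        assert np.all(np.diff(by_conc) < 0)


class TestStepBiomassAndHarvest:
    def test_zero_rate_identity(self):
        assert step_biomass(0.3, 0.0, 5.0) == 0.3

    def test_doubling_at_ln2_per_day(self):
        assert step_biomass(0.2, math.log(2.0), 24.0) == pytest.approx(0.4)

    def test_exponential_steps_commute(self):
        c = step_biomass(step_biomass(0.25, 0.8, 12.0), -0.8, 12.0)
        assert c == pytest.approx(0.25, rel=1e-12)

    @pytest.mark.parametrize(
        "conc,depth,expected_harvest",
        [(0.5, 20.0, 80.0), (0.4, 20.0, 0.0), (0.5, 15.0, 60.0)],
    )
    def test_harvest_arithmetic(self, conc, depth, expected_harvest):
        new_conc, harvested = apply_harvest(conc, depth, HarvestPolicy())
        assert harvested == pytest.approx(expected_harvest)
        if expected_harvest > 0:
            assert new_conc == 0.1
        else:
            assert new_conc == conc


def month_met(**kw):
    return HourlyMeteoSeries(make_hourly_frame("2021-06-01", 30 * 24, **kw))


def water_series(met, temp):
    return WaterTempSeries(pd.Series(np.full(len(met), float(temp)),
                                     index=met.index))


def flat_strain(mu, resp=0.0):
    """Strain with growth rate ``mu`` at any positive light and temperature."""
    light = np.array([0.0, 1e-9, 3000.0])
    temp = np.array([-10.0, 50.0])
    surface = np.array([[-resp, mu, mu], [-resp, mu, mu]])
    return StrainParams("flat", temp, light, surface, dark_respiration_rate=resp)


class TestSimulateMonth:
    def test_inert_culture_production_is_inoculum(self):
        met = month_met(shortwave=100.0)
        prod = simulate_month(met, water_series(met, 20.0), flat_strain(0.0),
                              20.0, atten=LightAttenuation(0.0, 0.0))
        expected = 0.05 * 0.2 * 1000.0 / 30.0
        assert prod.areal_production == pytest.approx(expected)
        assert prod.harvest_events == []

    def test_constant_growth_matches_closed_form(self):
        # continuous light, mu = 0.1/day, trigger set high enough never to fire
        met = month_met(shortwave=100.0)
        policy = HarvestPolicy(trigger_conc=2.0, residual_conc=0.1,
                               initial_conc=0.05)
        prod = simulate_month(met, water_series(met, 20.0), flat_strain(0.1),
                              20.0, policy=policy,
                              atten=LightAttenuation(0.0, 0.0))
        expected = 0.05 * math.exp(0.1 * 30.0) * 0.2 * 1000.0 / 30.0
        assert prod.areal_production == pytest.approx(expected, rel=1e-9)

    def test_mass_ledger_closes(self, two_year_archive):
        from algaecast import simulate_pond, default_strain_registry

        met = two_year_archive.slice_month(2021, 7)
        water = simulate_pond(met, 20.0)
        strain = default_strain_registry()["warm_archetype"]
        prod = simulate_month(met, water, strain, 20.0)
        lhs = prod.initial_standing + prod.grown_mass
        rhs = prod.harvested_total + prod.final_standing
        assert lhs == pytest.approx(rhs, rel=1e-9)
        assert len(prod.harvest_events) > 0

    def test_concentration_bounded_by_trigger(self, two_year_archive):
        from algaecast import simulate_pond, default_strain_registry

        met = two_year_archive.slice_month(2021, 5)
        water = simulate_pond(met, 15.0)
        strain = default_strain_registry()["warm_archetype"]
        prod = simulate_month(met, water, strain, 15.0)
        conc = prod.concentration.to_numpy()
        assert np.all(conc >= 0.0)
        assert np.all(conc < HarvestPolicy().trigger_conc)

    def test_deterministic_across_reruns(self, two_year_archive):
        from algaecast import simulate_pond, default_strain_registry

        met = two_year_archive.slice_month(2021, 4)
        water = simulate_pond(met, 25.0)
        strain = default_strain_registry()["cold_archetype"]
        a = simulate_month(met, water, strain, 25.0)
        b = simulate_month(met, water, strain, 25.0)
        assert a.areal_production == b.areal_production

    def test_misaligned_series_rejected(self):
        met = month_met()
        other = HourlyMeteoSeries(make_hourly_frame("2021-07-01", 31 * 24))
        with pytest.raises(DataError):
            simulate_month(met, water_series(other, 20.0), flat_strain(0.0), 20.0)

    def test_partial_month_rejected(self):
        met = HourlyMeteoSeries(make_hourly_frame("2021-06-01", 20 * 24))
        with pytest.raises(DataError):
            simulate_month(met, water_series(met, 20.0), flat_strain(0.0), 20.0)


class TestSeasonalReversal:
    def test_warm_beats_cold_hot_and_loses_cold(self):
        warm = build_strain_surface(warm_archetype())
        cold = build_strain_surface(cold_archetype())
        # direct surface comparison at saturating light
        assert growth_rate(warm, 2000.0, 32.0) > growth_rate(cold, 2000.0, 32.0)
        assert growth_rate(warm, 2000.0, 12.0) < growth_rate(cold, 2000.0, 12.0)

    def test_production_reversal_at_sustained_temperatures(self):
        met = month_met(shortwave=np.tile(
            np.maximum(0.0, 700.0 * np.sin(2 * np.pi * (np.arange(24) - 6) / 24)), 30
        ))
        warm = build_strain_surface(warm_archetype())
        cold = build_strain_surface(cold_archetype())
        hot = water_series(met, 32.0)
        chilly = water_series(met, 12.0)
        p = {
            (s.name, t): simulate_month(met, w, s, 20.0).areal_production
            for s in (warm, cold)
            for t, w in (("hot", hot), ("cold", chilly))
        }
        assert p[("warm_archetype", "hot")] > p[("cold_archetype", "hot")]
        assert p[("cold_archetype", "cold")] > p[("warm_archetype", "cold")]
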