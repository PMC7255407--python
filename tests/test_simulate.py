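import dataclasses

import numpy as np
import pytest

import maizegxe as m
from maizegxe.cultivar import MATURITY_GROUPS, MATURITY_ORDER
from maizegxe.simulate import thermal_time_daily, photoperiod_delay

from conftest import make_constant_weather


def run(cv, wx, soil, species, ecotype, sowing="2016-03-05", irrigated=False):
    mgmt = m.Management(sowing_date=sowing,
                        irrigation_threshold=0.6 if irrigated else None)
    return m.simulate_season(cv, ecotype, species, wx, soil, mgmt)


class TestThermalTime:
    @pytest.mark.parametrize("tmax,tmin,expected", [
        (30.0, 20.0, 17.0),        # mean 25 minus base 8
        (10.0, 4.0, 0.0),          # mean 7 below base: clamped
        (28.0, 12.0, 12.0),
    ])
    def test_daily_growing_degree_days(self, tmax, tmin, expected):
        assert thermal_time_daily(tmax, tmin, 8.0) == pytest.approx(expected)

    def test_rejects_inverted_temperatures(self):
        with pytest.raises(ValueError):
            thermal_time_daily(15.0, 20.0, 8.0)

    def test_optional_cap_never_increases_value(self):
        for tmax in np.arange(20.0, 52.0, 2.0):
            for gap in (5.0, 10.0, 15.0):
                plain = thermal_time_daily(tmax, tmax - gap, 8.0, cap=False)
                capped = thermal_time_daily(tmax, tmax - gap, 8.0, cap=True)
                assert capped <= plain + 1e-12

    @pytest.mark.parametrize("daylength,p2,expected", [
        (12.0, 0.015, 0.0),        # below the 12.5 h threshold
        (13.5, 0.015, 0.015),      # one hour above
        (13.0, 0.0, 0.0),          # photoperiod-insensitive cultivar
    ])
    def test_photoperiod_delay(self, daylength, p2, expected):
        assert photoperiod_delay(daylength, p2) == pytest.approx(expected)


class TestSeasonSimulation:
    def test_zero_radiation_means_zero_biomass_and_yield(
            self, cultivars, species, ecotype, loamy_soil):
        wx = make_constant_weather(srad=0.0)
        res = run(cultivars[0], wx, loamy_soil, species, ecotype)
        assert res.biomass_anthesis == 0.0
        assert res.biomass_maturity == 0.0
        assert res.grain_yield == 0.0

    def test_doubling_p5_extends_maturity_and_fill(
            self, cultivars, species, ecotype, benign_weather, loamy_soil):
        base = cultivars[0]
        longer = dataclasses.replace(base, P5=2 * base.P5)
        r1 = run(base, benign_weather, loamy_soil, species, ecotype)
        r2 = run(longer, benign_weather, loamy_soil, species, ecotype)
        assert r2.dtm > r1.dtm
        assert r2.dta == r1.dta
        assert (r2.dtm - r2.dta) > (r1.dtm - r1.dta)

    def test_photoperiod_insensitive_cultivar_ignores_latitude(
            self, cultivars, species, ecotype, loamy_soil):
        cv = dataclasses.replace(cultivars[0], P2=0.0)
        r_eq = run(cv, make_constant_weather(latitude=0.0), loamy_soil,
                   species, ecotype)
        r_north = run(cv, make_constant_weather(latitude=14.0), loamy_soil,
                      species, ecotype)
        assert r_eq.dta == r_north.dta

    def test_yield_monotone_in_kernel_parameters(
            self, cultivars, species, ecotype, benign_weather, loamy_soil):
        base = cultivars[1]
        r0 = run(base, benign_weather, loamy_soil, species, ecotype)
        for attr in ("G2", "G3"):
            bigger = dataclasses.replace(base, **{attr: 1.3 * getattr(base, attr)})
            r1 = run(bigger, benign_weather, loamy_soil, species, ecotype)
            assert r1.grain_yield >= r0.grain_yield

    def test_anthesis_monotone_in_p1_and_phint(
            self, cultivars, species, ecotype, benign_weather, loamy_soil):
        base = cultivars[2]
        r0 = run(base, benign_weather, loamy_soil, species, ecotype)
        for attr in ("P1", "PHINT"):
            bigger = dataclasses.replace(base, **{attr: 1.15 * getattr(base, attr)})
            r1 = run(bigger, benign_weather, loamy_soil, species, ecotype)
            assert r1.dta >= r0.dta

    def test_energy_bound_biomass_below_rue_par_limit(
            self, cultivars, species, ecotype, benign_weather, loamy_soil):
        for cv in cultivars[:4]:
            res = run(cv, benign_weather, loamy_soil, species, ecotype)
            i0 = benign_weather.index_of(res.sowing_date)
            par_sum = 0.5 * benign_weather.srad[i0:i0 + res.dtm].sum()
            assert res.biomass_maturity / 0.01 <= ecotype.RUE * par_sum + 1e-9

    def test_water_mass_balance_closes(self, cultivars, species, ecotype,
                                       benign_weather, loamy_soil):
        res = run(cultivars[0], benign_weather, loamy_soil, species, ecotype)
        assert res.water_balance_error_mm < 0.1

    def test_bit_identical_reruns(self, cultivars, species, ecotype,
                                  benign_weather, loamy_soil):
        r1 = run(cultivars[5], benign_weather, loamy_soil, species, ecotype)
        r2 = run(cultivars[5], benign_weather, loamy_soil, species, ecotype)
        assert r1 == r2

    def test_incomplete_weather_raises(self, cultivars, species, ecotype,
                                       loamy_soil):
        wx = make_constant_weather(n_days=40)
        with pytest.raises(m.IncompleteSeasonError):
            run(cultivars[0], wx, loamy_soil, species, ecotype)

    def test_maturity_group_means_order_days_to_anthesis(
            self, cultivars, species, ecotype, benign_weather, loamy_soil):
        groups = {g: [] for g in MATURITY_ORDER}
        for cv in cultivars:
            res = run(cv, benign_weather, loamy_soil, species, ecotype)
            groups[MATURITY_GROUPS[cv.name]].append(res.dta)
        means = [np.mean(groups[g]) for g in MATURITY_ORDER]
        assert means == sorted(means)
        assert all(a < b for a, b in zip(means, means[1:]))


class TestAutoPlant:
    def test_heavy_rain_plants_on_first_window_day(self, loamy_soil):
        wx = make_constant_weather(rain_every=1, rain_mm=40.0)
        sow = m.auto_plant(wx, loamy_soil, wx.dates[0], window_days=30)
        assert sow == wx.dates[0]

    def test_no_rain_raises_no_planting(self, loamy_soil):
        wx = make_constant_weather(rain_mm=0.0)
        with pytest.raises(m.NoPlantingError):
            m.auto_plant(wx, loamy_soil, wx.dates[0], window_days=30)

    def test_zero_threshold_always_plants_immediately(self, loamy_soil):
        wx = make_constant_weather(rain_mm=0.0)
        sow = m.auto_plant(wx, loamy_soil, wx.dates[0], window_days=30,
                           threshold=0.0)
        assert sow == wx.dates[0]


class TestSeasonalAnalysis:
    def _two_identical_years(self):
        one = make_constant_weather(n_days=365, start="2017-01-01")
        dates = np.arange(np.datetime64("2017-01-01"),
                          np.datetime64("2017-01-01") + 730)
        tile = lambda a: np.concatenate([a, a])
        return m.WeatherSeries(dates, tile(one.tmax), tile(one.tmin),
                               tile(one.srad), tile(one.rain), one.latitude)

    def test_identical_years_have_zero_sd_and_collapsed_range(
            self, cultivars, species, ecotype, loamy_soil):
        wx = self._two_identical_years()
        summaries = m.seasonal_analysis(cultivars[:2], ecotype, species, wx,
                                        loamy_soil, season_start_doy=32,
                                        window_days=40)
        for s in summaries.values():
            assert s.sd_yield == 0.0
            assert s.max_yield == s.min_yield == s.mean_yield

    def test_single_year_rejected(self, cultivars, species, ecotype, loamy_soil):
        wx = make_constant_weather(n_days=300, start="2015-01-01")
        with pytest.raises(ValueError, match="at least 2 years"):
            m.seasonal_analysis(cultivars[:1], ecotype, species, wx,
                                loamy_soil, season_start_doy=32)

    def test_cdf_is_monotone_probability_grid(self, cultivars, species,
                                              ecotype, loamy_soil):
        wx = self._two_identical_years()
        summaries = m.seasonal_analysis(cultivars[:1], ecotype, species, wx,
                                        loamy_soil, season_start_doy=32,
                                        window_days=40)
        ys, prob = next(iter(summaries.values())).cdf
        assert np.all(np.diff(ys) >= 0)
        assert prob[-1] == pytest.approx(1.0)
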