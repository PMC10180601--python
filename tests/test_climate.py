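import warnings

import numpy as np
import pandas as pd
import pytest

from dendrostress import (
    aggregate_period,
    classify_drought,
    climate_index_table,
    detect_stress_years,
    heat_sum,
    month_window,
    previous_winter,
    saturation_vapour_pressure,
    spei,
    thornthwaite_pet,
    threshold_day_count,
    vegetation_period,
    vpd,
)

def make_daily(start, values: dict) -> pd.DataFrame:
    n = max(len(v) for v in values.values())
    idx = pd.date_range(start, periods=n, freq="D")
    return pd.DataFrame(values, index=idx)


class TestWindows:
    def test_previous_winter_span(self):
        w = previous_winter(1995)
        assert w.start == pd.Timestamp("1994-10-01")
        assert w.end == pd.Timestamp("1995-03-31")
        assert w.n_days == 182

    def test_vegetation_period_day_count(self):
        assert vegetation_period(1995).n_days == 183
        assert vegetation_period(1996).n_days == 183  # leap year: April-September unaffected

    def test_month_window(self):
        w = month_window(2000, 2)
        assert w.n_days == 29


class TestAggregation:
    def test_constant_mean(self):
        daily = make_daily("1995-01-01", {"tmean": np.full(365, 10.0)})
        assert aggregate_period(daily, vegetation_period(1995), "tmean") == pytest.approx(10.0)

    def test_precipitation_sum_over_vp(self):
        daily = make_daily("1995-01-01", {"ppt": np.ones(365)})
        assert aggregate_period(daily, vegetation_period(1995), "ppt", "sum") == pytest.approx(183.0)

    def test_missing_coverage_raises(self):
        daily = make_daily("1995-04-01", {"tmean": np.full(100, 10.0)})
        with pytest.raises(ValueError, match="missing"):
            aggregate_period(daily, vegetation_period(1995), "tmean")


class TestHeatAndCounts:
    def test_heat_sum_strict_threshold(self):
        daily = make_daily("1995-06-01", {"tmean": np.array([21.0, 25.0, 19.0, 20.0])})
        w = month_window(1995, 6)
        assert heat_sum(daily, w, tolerance=1.0) == pytest.approx(6.0)

    def test_hot_day_boundary_inclusive(self):
        daily = make_daily("1995-06-01", {"tmax": np.array([30.0, 29.9])})
        assert threshold_day_count(daily, month_window(1995, 6), "hot", tolerance=1.0) == 1

    def test_rain_day_boundary_exclusive(self):
        daily = make_daily("1995-06-01", {"ppt": np.array([1.0, 1.1])})
        assert threshold_day_count(daily, month_window(1995, 6), "rain", tolerance=1.0) == 1

    def test_ice_days_all_freezing(self):
        daily = make_daily("1995-01-01", {"tmax": np.full(31, -2.0)})
        assert threshold_day_count(daily, month_window(1995, 1), "ice") == 31


class TestVpd:
    def test_saturated_air_has_zero_deficit(self):
        assert vpd(17.3, 100.0) == pytest.approx(0.0)

    def test_dry_air_equals_saturation_pressure(self):
        assert vpd(25.0, 0.0) == pytest.approx(saturation_vapour_pressure(25.0))

    def test_magnus_reference_point(self):
        assert saturation_vapour_pressure(20.0) == pytest.approx(23.4, abs=0.1)
        assert vpd(20.0, 50.0) == pytest.approx(11.7, abs=0.1)

    def test_monotonicity(self):
        assert vpd(20.0, 40.0) > vpd(20.0, 60.0)   # drier air, larger deficit
        assert vpd(25.0, 50.0) > vpd(20.0, 50.0)   # warmer air, larger deficit

    def test_rh_out_of_range(self):
        with pytest.raises(ValueError, match="humidity"):
            vpd(20.0, 140.0)


class TestThornthwaite:
    def test_constant_ten_degrees_no_correction(self):
        idx = pd.period_range("2000-01", periods=12, freq="M")
        pet = thornthwaite_pet(pd.Series(10.0, index=idx), latitude=None)
        # I = 12 * 2^1.514 ~ 34.27, a ~ 1.043, PET ~ 48.9 mm/month
        assert np.allclose(pet.to_numpy(), 48.9, atol=0.5)

    def test_freezing_month_gives_zero(self):
        idx = pd.period_range("2000-01", periods=12, freq="M")
        t = pd.Series([-5.0] + [10.0] * 11, index=idx)
        pet = thornthwaite_pet(t, latitude=None)
        assert pet.iloc[0] == 0.0

    def test_warmer_month_evaporates_more(self):
        idx = pd.period_range("2000-01", periods=12, freq="M")
        t = pd.Series(np.linspace(2.0, 20.0, 12), index=idx)
        pet = thornthwaite_pet(t, latitude=None)
        assert (np.diff(pet.to_numpy()) > 0).all()

    def test_all_freezing_year_raises(self):
        idx = pd.period_range("2000-01", periods=12, freq="M")
        with pytest.raises(ValueError, match="<= 0"):
            thornthwaite_pet(pd.Series(-1.0, index=idx), latitude=None)


@pytest.fixture(scope="module")
def stationary_spei():
    rng = np.random.default_rng(42)
    idx = pd.period_range("1960-01", periods=60 * 12, freq="M")
    ppt = pd.Series(rng.gamma(3.0, 20.0, len(idx)), index=idx)
    pet = pd.Series(rng.gamma(4.0, 10.0, len(idx)), index=idx)
    return spei(ppt, pet, scale=3)


class TestSpei:
    def test_normalisation_per_calendar_month(self, stationary_spei):
        g = stationary_spei.data.groupby(stationary_spei.data.index.month)["spei"]
        assert (g.mean().abs() <= 0.1).all()
        assert g.std().between(0.85, 1.15).all()

    def test_monotone_in_water_balance(self, stationary_spei):
        df = stationary_spei.data
        for month in (1, 7):
            sub = df[df.index.month == month].sort_values("D")
            assert (np.diff(sub["spei"].to_numpy()) > 0).all()

    def test_median_maps_near_zero(self, stationary_spei):
        df = stationary_spei.data
        sub = df[df.index.month == 6]
        med_idx = (sub["D"] - sub["D"].median()).abs().idxmin()
        assert abs(sub.loc[med_idx, "spei"]) < 0.15

    def test_short_calibration_warns(self):
        idx = pd.period_range("2000-01", periods=10 * 12, freq="M")
        rng = np.random.default_rng(3)
        ppt = pd.Series(rng.gamma(3.0, 20.0, len(idx)), index=idx)
        pet = pd.Series(50.0 + rng.normal(0, 5, len(idx)), index=idx)
        with pytest.warns(UserWarning, match="calibration"):
            spei(ppt, pet)


class TestClassifyDrought:
    @pytest.mark.parametrize("value,expected", [
        (-0.99, "none"), (-1.0, "moderate"), (-1.2, "moderate"), (-1.49, "moderate"),
        (-1.5, "severe"), (-1.7, "severe"), (-1.99, "severe"),
        (-2.0, "extreme"), (-2.4, "extreme"), (0.7, "none"),
    ])
    def test_class_boundaries(self, value, expected):
        assert classify_drought(value) == expected

    def test_nonfinite_raises(self):
        with pytest.raises(ValueError):
            classify_drought(float("nan"))


class TestStressYears:
    def test_engineered_drought_flagged_on_both_criteria(self, study_index_table):
        reports = {r.year: r for r in detect_stress_years(study_index_table)}
        for year in (2003, 2018):  # severe engineered hot-dry years
            assert reports[year].primary_hot, year
            assert reports[year].primary_dry, year
            assert reports[year].is_stress

    def test_confirmation_flags_accompany_severe_years(self, study_index_table):
        reports = {r.year: r for r in detect_stress_years(study_index_table)}
        confirms = reports[2003].confirmations
        assert sum(confirms.values()) >= 2  # heat and water flags corroborate

    def test_all_years_identical_flags_everything(self):
        # inclusive >= / <= comparisons flag every tied year
        idx = pd.date_range("1994-01-01", "2005-12-31", freq="D")
        daily = pd.DataFrame(
            {"tmin": 5.0, "tmax": 15.0, "tmean": 10.0, "ppt": 1.0, "rh": 70.0},
            index=idx)
        years = np.arange(1995, 2006)  # first year lacks a previous winter
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")  # degenerate SPEI, short calibration
            table = climate_index_table(daily, years)
        reports = detect_stress_years(table, years)
        assert all(r.primary_hot and r.primary_dry for r in reports)

    def test_order_invariance(self, study_index_table):
        years = study_index_table.years
        a = detect_stress_years(study_index_table, years)
        b = detect_stress_years(study_index_table, years[::-1])
        flags_a = {r.year: (r.primary_hot, r.primary_dry) for r in a}
        flags_b = {r.year: (r.primary_hot, r.primary_dry) for r in b}
        assert flags_a == flags_b
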