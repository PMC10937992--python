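"""Compound-episode detection and accounting: exact-set categories,
partition identities, brute-force oracle equivalence."""

import numpy as np
import pandas as pd
import pytest

from airexposure.compound import (
    category_label,
    compound_composition,
    compound_exposure_by_category,
    compound_exposure_time,
    compound_mask,
    compound_share_of_unclean,
    population_with_any_compound,
    seasonal_profile,
)
from airexposure.grids import ConcentrationField, Grid, PopulationGrid, RegionSet
from airexposure.indicators import daily_exceedance


def _world(n_days=30, shape=(5, 5), seed=0, start="2015-01-01"):
    """Random multi-pollutant world with plenty of joint exceedances."""
    rng = np.random.default_rng(seed)
    grid = Grid.regular(*shape, resolution=0.1)
    dates = pd.date_range(start, periods=n_days, freq="D")
    limits = {"PM25": 15.0, "PM10": 45.0, "NO2": 25.0, "O3": 100.0}
    fields = {}
    for pol, lim in limits.items():
        vals = rng.gamma(shape=3.0, scale=lim / 2.5, size=(n_days,) + shape)
        fields[pol] = ConcentrationField(pol, grid, dates, vals)
    exceed = {p: daily_exceedance(fields[p], limits[p]) for p in limits}
    pop = PopulationGrid(grid, rng.integers(0, 1000, size=shape).astype(float))
    regions = RegionSet(
        region_ids=["W", "E"],
        labels=(np.arange(shape[1])[None, :] >= shape[1] // 2)
        .astype(int) * np.ones((shape[0], 1), dtype=int),
    )
    return fields, exceed, pop, regions, limits


class TestCompoundMask:
    def test_single_pollutant_exceedance_not_compound(self):
        _, exceed, *_ = _world()
        cf = compound_mask(exceed)
        one = cf.n_exceeding == 1
        assert not cf.is_compound[one].any()

    def test_exact_pair_category(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", periods=1, freq="D")
        mk = lambda pol, v: ConcentrationField(pol, g, dates, np.array([[[v]]]))
        exceed = {
            "PM25": daily_exceedance(mk("PM25", 20.0), 15.0),
            "PM10": daily_exceedance(mk("PM10", 10.0), 45.0),
            "NO2": daily_exceedance(mk("NO2", 30.0), 25.0),
            "O3": daily_exceedance(mk("O3", 50.0), 100.0),
        }
        cf = compound_mask(exceed)
        assert cf.is_compound[0, 0, 0]
        assert cf.categories_present() == [("NO2", "PM25")]

    def test_all_four_exceed_single_quadruple_category(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", periods=1, freq="D")
        mk = lambda pol, v: ConcentrationField(pol, g, dates, np.array([[[v]]]))
        exceed = {
            "PM25": daily_exceedance(mk("PM25", 99.0), 15.0),
            "PM10": daily_exceedance(mk("PM10", 99.0), 45.0),
            "NO2": daily_exceedance(mk("NO2", 99.0), 25.0),
            "O3": daily_exceedance(mk("O3", 999.0), 100.0),
        }
        cf = compound_mask(exceed)
        assert cf.categories_present() == [("NO2", "O3", "PM10", "PM25")]

    def test_triple_day_not_counted_in_pairs(self):
        _, exceed, pop, regions, _ = _world(seed=4)
        cf = compound_mask(exceed)
        triple = cf.category_bits(("PM25", "PM10", "NO2"))
        pair = cf.category_bits(("PM25", "PM10"))
        is_triple = cf.bits == triple
        is_pair = cf.bits == pair
        assert not (is_triple & is_pair).any()

    def test_mismatched_dates_rejected(self):
        _, exceed, *_ = _world(n_days=10)
        _, exceed2, *_ = _world(n_days=10, start="2016-01-01")
        bad = dict(exceed)
        bad["O3"] = exceed2["O3"]
        with pytest.raises(ValueError, match="share grid and dates"):
            compound_mask(bad)

    def test_missing_counts_as_non_exceeding_with_coverage(self):
        fields, _, *_ = _world(n_days=10)
        vals = fields["PM25"].values.copy()
        vals[0] = np.nan
        fields["PM25"] = ConcentrationField("PM25", fields["PM25"].grid,
                                            fields["PM25"].dates, vals)
        exceed = {p: daily_exceedance(fields[p], lim)
                  for p, lim in {"PM25": 15.0, "PM10": 45.0}.items()}
        cf = compound_mask(exceed)
        assert cf.coverage < 1.0
        assert not (cf.bits[0] & 1).any()  # PM25 bit never set on the NaN day


class TestExposureTimePartition:
    def test_per_category_sums_to_any_compound(self):
        _, exceed, pop, regions, _ = _world(seed=1)
        cf = compound_mask(exceed)
        table = compound_exposure_by_category(cf, pop, regions)
        any_e = compound_exposure_time(cf, pop, regions)
        assert np.allclose(table.sum(axis=1).to_numpy(), any_e.to_numpy())

    def test_single_cell_five_compound_days(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", periods=10, freq="D")
        pm = np.zeros((10, 1, 1))
        no2 = np.zeros((10, 1, 1))
        pm[:5] = 99.0
        no2[:5] = 99.0
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, no2), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.array([[123.0]]))
        regions = RegionSet(region_ids=["R"], labels=np.zeros((1, 1), dtype=int))
        assert compound_exposure_time(cf, pop, regions)["R"] == pytest.approx(5.0)

    def test_category_bounded_by_member_pollutant_exposure(self):
        from airexposure.indicators import unclean_exposure_time

        _, exceed, pop, regions, _ = _world(seed=2)
        cf = compound_mask(exceed)
        for cat in cf.categories_present():
            e_cat = compound_exposure_time(cf, pop, regions, category=cat)
            for pol in cat:
                e_pol = unclean_exposure_time(exceed[pol], pop, regions, year=2015)
                assert np.all(e_cat.to_numpy() <= e_pol.to_numpy() + 1e-9)

    def test_raising_a_limit_never_increases_compound_time(self):
        fields, _, pop, regions, limits = _world(seed=3)
        def any_days(pm25_limit):
            exceed = {p: daily_exceedance(fields[p],
                                          pm25_limit if p == "PM25" else limits[p])
                      for p in limits}
            cf = compound_mask(exceed)
            return compound_exposure_time(cf, pop, regions)
        lo = any_days(15.0)
        hi = any_days(25.0)
        assert np.all(hi.to_numpy() <= lo.to_numpy() + 1e-12)


class TestBruteForceOracle:
    def test_person_day_counts_match_triple_loop(self):
        # 5x5 grid, 30 days: direct enumeration over (day, lat, lon)
        _, exceed, pop, regions, _ = _world(n_days=30, shape=(5, 5), seed=7)
        cf = compound_mask(exceed)
        pols = cf.pollutants
        for rid in regions.region_ids:
            m = regions.mask(rid)
            person_days_any = 0.0
            person_days_cat: dict = {}
            for t in range(30):
                for i in range(5):
                    for j in range(5):
                        if not m[i, j]:
                            continue
                        members = tuple(sorted(
                            p for p in pols if exceed[p].exceeded[t, i, j]
                        ))
                        if len(members) >= 2:
                            person_days_any += pop.counts[i, j]
                            person_days_cat[members] = (
                                person_days_cat.get(members, 0.0) + pop.counts[i, j]
                            )
            pop_r = pop.counts[m].sum()
            e_any = compound_exposure_time(cf, pop, regions)[rid]
            assert e_any * pop_r == pytest.approx(person_days_any)
            for members, pd_count in person_days_cat.items():
                e_cat = compound_exposure_time(cf, pop, regions, category=members)[rid]
                assert e_cat * pop_r == pytest.approx(pd_count)

    def test_single_pollutant_exposure_matches_triple_loop(self):
        from airexposure.indicators import unclean_exposure_time

        _, exceed, pop, regions, _ = _world(n_days=30, shape=(5, 5), seed=8)
        for pol, ex in exceed.items():
            for rid in regions.region_ids:
                m = regions.mask(rid)
                brute = sum(
                    pop.counts[i, j]
                    for t in range(30)
                    for i in range(5)
                    for j in range(5)
                    if m[i, j] and ex.exceeded[t, i, j]
                )
                e = unclean_exposure_time(ex, pop, regions, year=2015)[rid]
                assert e * pop.counts[m].sum() == pytest.approx(brute)


class TestComposition:
    def test_single_category_is_everything(self):
        out = compound_composition(pd.Series({"NO2+PM25": 7.0}))
        assert out["NO2+PM25"] == pytest.approx(1.0)

    def test_three_to_one_split(self):
        out = compound_composition(pd.Series({"NO2+PM25": 3.0, "O3+PM25": 1.0}))
        assert out["NO2+PM25"] == pytest.approx(0.75)
        assert out["O3+PM25"] == pytest.approx(0.25)

    def test_fractions_sum_to_one(self):
        _, exceed, pop, regions, _ = _world(seed=9)
        cf = compound_mask(exceed)
        table = compound_exposure_by_category(cf, pop, regions)
        comp = compound_composition(table.sum(axis=0))
        assert comp.sum() == pytest.approx(1.0)

    def test_all_zero_undefined(self):
        with pytest.warns(UserWarning, match="undefined"):
            out = compound_composition(pd.Series({"NO2+PM25": 0.0}))
        assert out.isna().all()


class TestPopulationWithAnyCompound:
    def test_no_compound_days_zero_percent(self):
        g = Grid.regular(2, 2, 0.1)
        dates = pd.date_range("2015-01-01", periods=5, freq="D")
        zeros = np.zeros((5, 2, 2))
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, zeros), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, zeros), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.ones((2, 2)))
        regions = RegionSet(region_ids=["R"], labels=np.zeros((2, 2), dtype=int))
        assert population_with_any_compound(cf, pop, regions) == 0.0

    def test_everywhere_compound_hundred_percent(self):
        _, exceed, pop, regions, _ = _world(seed=10)
        # force joint exceedance everywhere on day 0
        for ex in exceed.values():
            ex.exceeded[0] = True
        cf = compound_mask(exceed)
        assert population_with_any_compound(cf, pop, regions) == pytest.approx(100.0)

    def test_two_region_hand_count(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0, 1.0]))
        dates = pd.date_range("2015-01-01", periods=3, freq="D")
        pm = np.zeros((3, 1, 2))
        no2 = np.zeros((3, 1, 2))
        pm[0, 0, 0] = 99.0  # only west cell ever has a compound day
        no2[0, 0, 0] = 99.0
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, no2), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.array([[100.0, 300.0]]))
        regions = RegionSet(region_ids=["W", "E"], labels=np.array([[0, 1]]))
        assert population_with_any_compound(cf, pop, regions) == pytest.approx(25.0)


class TestShareOfUnclean:
    def test_never_co_exceeding_pollutant_share_zero(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", periods=4, freq="D")
        pm = np.array([99.0, 99.0, 0.0, 0.0]).reshape(4, 1, 1)
        no2 = np.array([0.0, 0.0, 99.0, 0.0]).reshape(4, 1, 1)
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, no2), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.array([[10.0]]))
        share = compound_share_of_unclean(exceed, cf, pop)
        assert share["PM25"] == 0.0
        assert share["NO2"] == 0.0

    def test_always_co_exceeding_pollutant_share_one(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", periods=4, freq="D")
        pm = np.array([99.0, 99.0, 0.0, 0.0]).reshape(4, 1, 1)
        no2 = np.array([99.0, 99.0, 99.0, 0.0]).reshape(4, 1, 1)
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, no2), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.array([[10.0]]))
        share = compound_share_of_unclean(exceed, cf, pop)
        assert share["PM25"] == pytest.approx(1.0)
        assert share["NO2"] == pytest.approx(2.0 / 3.0)

    def test_toy_field_matches_enumeration(self):
        _, exceed, pop, regions, _ = _world(n_days=20, seed=11)
        cf = compound_mask(exceed)
        share = compound_share_of_unclean(exceed, cf, pop)
        for pol in cf.pollutants:
            num = den = 0.0
            for t in range(20):
                for i in range(5):
                    for j in range(5):
                        if exceed[pol].exceeded[t, i, j]:
                            den += pop.counts[i, j]
                            if cf.n_exceeding[t, i, j] >= 2:
                                num += pop.counts[i, j]
            assert share[pol] == pytest.approx(num / den)


class TestSeasonalProfile:
    def test_all_mass_in_january(self):
        g = Grid(lat=np.array([0.0]), lon=np.array([0.0]))
        dates = pd.date_range("2015-01-01", "2015-12-31", freq="D")
        pm = np.zeros((len(dates), 1, 1))
        no2 = np.zeros((len(dates), 1, 1))
        jan = dates.month == 1
        pm[jan] = 99.0
        no2[jan] = 99.0
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "NO2": daily_exceedance(ConcentrationField("NO2", g, dates, no2), 25.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.array([[50.0]]))
        regions = RegionSet(region_ids=["R"], labels=np.zeros((1, 1), dtype=int))
        prof = seasonal_profile(cf, pop, regions)
        assert prof.loc[1, "any"] == pytest.approx(31.0)
        assert prof.drop(index=1)["any"].sum() == 0.0

    def test_monthly_values_sum_to_annual_exposure(self):
        _, exceed, pop, regions, _ = _world(n_days=365, seed=12)
        cf = compound_mask(exceed)
        prof = seasonal_profile(cf, pop, regions)
        union = RegionSet(region_ids=["ALL"],
                          labels=np.zeros(pop.grid.shape, dtype=int))
        annual = compound_exposure_time(cf, pop, union)["ALL"]
        assert prof["any"].sum() == pytest.approx(annual)

    def test_warm_season_category_peaks_in_configured_months(self):
        # O3 exceeds only in summer; PM25 always: O3-involving compound
        # days must concentrate in the warm months
        g = Grid.regular(3, 3, 0.1)
        dates = pd.date_range("2015-01-01", "2015-12-31", freq="D")
        warm = np.isin(dates.month, [5, 6, 7, 8, 9])
        o3 = np.zeros((len(dates), 3, 3))
        o3[warm] = 150.0
        pm = np.full((len(dates), 3, 3), 30.0)
        exceed = {
            "PM25": daily_exceedance(ConcentrationField("PM25", g, dates, pm), 15.0),
            "O3": daily_exceedance(ConcentrationField("O3", g, dates, o3), 100.0),
        }
        cf = compound_mask(exceed)
        pop = PopulationGrid(g, np.ones((3, 3)))
        regions = RegionSet(region_ids=["R"], labels=np.zeros((3, 3), dtype=int))
        prof = seasonal_profile(cf, pop, regions)
        label = category_label(("O3", "PM25"))
        warm_sum = prof.loc[[5, 6, 7, 8, 9], label].sum()
        assert warm_sum == pytest.approx(prof[label].sum())
        assert warm_sum > 0
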