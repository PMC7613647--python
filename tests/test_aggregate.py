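import numpy as np
import pandas as pd
import pytest

from cosgpp import GPPSeries
from cosgpp.aggregate import (
    binned_response,
    common_mask,
    compare_methods,
    cumulative_gpp,
    daily_mean,
    diurnal_median,
    monthly_mean,
)
from cosgpp.datamodel import GAPFILLED, MEASURED, MISSING


def make_series(start, n_days, gpp=5.0, measured_per_day=48, method="A",
                gapfill_rest=True):
    """Constant-GPP series with a fixed number of measured slots per day."""
    idx = pd.date_range(start, periods=48 * n_days, freq="30min")
    vals = np.broadcast_to(np.asarray(gpp, dtype=float), (len(idx),)).copy()
    flag = np.empty(len(idx), dtype=object)
    for d in range(n_days):
        day = slice(48 * d, 48 * (d + 1))
        f = np.array([MEASURED] * measured_per_day
                     + [GAPFILLED if gapfill_rest else MISSING]
                     * (48 - measured_per_day), dtype=object)
        flag[day] = f
    vals[flag == MISSING] = np.nan
    return GPPSeries(method=method, gpp=pd.Series(vals, index=idx),
                     flag=pd.Series(flag, index=idx, dtype=object))


class TestDailyMean:
    def test_25_of_48_measured_included(self):
        s = make_series("2017-06-01", 1, measured_per_day=25, gapfill_rest=False)
        assert len(daily_mean(s)) == 1

    def test_24_of_48_excluded_strict_threshold(self):
        s = make_series("2017-06-01", 1, measured_per_day=24, gapfill_rest=False)
        assert len(daily_mean(s)) == 0

    def test_constant_day_mean_is_identity(self):
        s = make_series("2017-06-01", 1, gpp=5.0)
        assert daily_mean(s).iloc[0] == pytest.approx(5.0)

    def test_mean_uses_gapfilled_values_once_day_qualifies(self):
        idx = pd.date_range("2017-06-01", periods=48, freq="30min")
        vals = np.array([2.0] * 30 + [10.0] * 18)
        flag = pd.Series([MEASURED] * 30 + [GAPFILLED] * 18, index=idx,
                         dtype=object)
        s = GPPSeries(method="A", gpp=pd.Series(vals, index=idx), flag=flag)
        # the 50% rule counts measured slots, but the mean covers all available
        assert daily_mean(s).iloc[0] == pytest.approx(vals.mean())

    def test_scaling_commutes(self):
        s = make_series("2017-06-01", 4, gpp=3.0, measured_per_day=30)
        scaled = GPPSeries(method="A", gpp=2.0 * s.gpp, flag=s.flag)
        pd.testing.assert_series_equal(daily_mean(scaled), 2.0 * daily_mean(s))


class TestMonthlyMean:
    def test_constant_month(self):
        d = pd.Series(5.0, index=pd.date_range("2017-06-01", periods=30))
        assert monthly_mean(d).iloc[0] == pytest.approx(5.0)

    def test_two_day_mean(self):
        d = pd.Series([4.0, 6.0],
                      index=pd.DatetimeIndex(["2017-06-03", "2017-06-17"]))
        assert monthly_mean(d).iloc[0] == pytest.approx(5.0)

    def test_empty_month_missing(self):
        d = pd.Series(dtype=float, index=pd.DatetimeIndex([]))
        assert len(monthly_mean(d)) == 0


class TestDiurnalMedian:
    def test_low_coverage_month_excluded(self):
        # exactly 50% coverage: below the strict 55% bar
        s = make_series("2017-06-01", 30, measured_per_day=24,
                        gapfill_rest=False)
        assert diurnal_median([s]) == {}

    def test_noiseless_cycle_recovered(self):
        idx = pd.date_range("2017-06-01", periods=48 * 30, freq="30min")
        slot = idx.hour * 2 + idx.minute // 30
        cycle = np.sin(np.pi * slot / 48) * 10
        s = GPPSeries(method="A", gpp=pd.Series(cycle, index=idx),
                      flag=pd.Series(MEASURED, index=idx, dtype=object))
        out = diurnal_median([s])
        (month, frame), = out.items()
        np.testing.assert_allclose(frame["A"], np.sin(np.pi * np.arange(48) / 48) * 10)

    def test_disjoint_coverage_excludes_month(self):
        a = make_series("2017-06-01", 30, measured_per_day=24,
                        gapfill_rest=False, method="A")
        flipped_flag = a.flag.map(
            lambda f: MEASURED if f == MISSING else MISSING
        ).astype(object)
        gpp_b = pd.Series(np.where(flipped_flag == MEASURED, 5.0, np.nan),
                          index=a.index)
        b = GPPSeries(method="B", gpp=gpp_b, flag=flipped_flag)
        assert diurnal_median([a, b]) == {}


class TestCumulative:
    def test_constant_rate_closed_form(self):
        s = make_series("2017-05-01", 92, gpp=1.0)
        res = cumulative_gpp(s, "2017-05-01", "2017-07-31")
        assert res.total_gc_m2 == pytest.approx(92 * 86400 * 12.011e-6, rel=1e-12)
        assert res.n_halfhours == 92 * 48

    def test_zero_series(self):
        s = make_series("2017-05-01", 92, gpp=0.0)
        assert cumulative_gpp(s, "2017-05-01", "2017-07-31").total_gc_m2 == 0.0

    def test_incomplete_series_is_an_error(self):
        s = make_series("2017-05-01", 92, measured_per_day=24,
                        gapfill_rest=False)
        with pytest.raises(ValueError, match="complete gap-filled"):
            cumulative_gpp(s, "2017-05-01", "2017-07-31")

    def test_gapfilled_fraction_reported(self):
        s = make_series("2017-05-01", 92, measured_per_day=36)
        res = cumulative_gpp(s, "2017-05-01", "2017-07-31")
        assert res.gapfilled_fraction == pytest.approx(12 / 48)

    def test_linearity_over_series_sum(self):
        a = make_series("2017-05-01", 92, gpp=1.0)
        b = make_series("2017-05-01", 92, gpp=2.5)
        summed = GPPSeries(method="S", gpp=a.gpp + b.gpp, flag=a.flag)
        assert cumulative_gpp(summed, "2017-05-01", "2017-07-31").total_gc_m2 == (
            pytest.approx(
                cumulative_gpp(a, "2017-05-01", "2017-07-31").total_gc_m2
                + cumulative_gpp(b, "2017-05-01", "2017-07-31").total_gc_m2
            )
        )


class TestBinnedResponse:
    @staticmethod
    def _series_from(values, idx, method="A"):
        return GPPSeries(method=method, gpp=pd.Series(values, index=idx),
                         flag=pd.Series(MEASURED, index=idx, dtype=object))

    def test_equal_count_bins(self):
        idx = pd.date_range("2017-06-01", periods=1200, freq="30min")
        rng = np.random.default_rng(0)
        driver = pd.Series(rng.uniform(0, 2000, 1200), index=idx)
        s = self._series_from(rng.uniform(0, 20, 1200), idx)
        table = binned_response([s], driver, par=None)
        assert (table["n"] == 100).all()

    def test_remainder_rule_sizes_differ_by_at_most_one(self):
        idx = pd.date_range("2017-06-01", periods=1201, freq="30min")
        rng = np.random.default_rng(1)
        driver = pd.Series(rng.uniform(0, 2000, 1201), index=idx)
        s = self._series_from(rng.uniform(0, 20, 1201), idx)
        sizes = binned_response([s], driver, par=None)["n"]
        assert sizes.max() - sizes.min() <= 1
        assert sizes.sum() == 1201

    def test_noiseless_function_recovered_on_bins(self):
        idx = pd.date_range("2017-06-01", periods=1200, freq="30min")
        rng = np.random.default_rng(2)
        par = pd.Series(rng.uniform(1, 2000, 1200), index=idx)
        gpp = 20 * par / (par + 300)
        s = self._series_from(gpp, idx)
        table = binned_response([s], par, par=None)
        # oracle: sort raw PAR, split into 12 equal chunks, average f per chunk
        order = np.sort(par.to_numpy())
        oracle = [np.mean(20 * c / (c + 300)) for c in np.array_split(order, 12)]
        np.testing.assert_allclose(table["A"], oracle, rtol=1e-12)
        assert (np.diff(table["A"]) > 0).all()

    def test_par_floor_applies_to_other_drivers(self):
        idx = pd.date_range("2017-06-01", periods=1200, freq="30min")
        rng = np.random.default_rng(3)
        t_air = pd.Series(rng.uniform(5, 25, 1200), index=idx)
        par = pd.Series(rng.uniform(0, 2000, 1200), index=idx)
        s = self._series_from(rng.uniform(0, 20, 1200), idx)
        table = binned_response([s], t_air, par=par, par_floor=700.0)
        assert table["n"].sum() == (par > 700).sum()


class TestCompareMethods:
    def test_identical_series_zero_difference(self):
        a = make_series("2017-06-01", 20, gpp=5.0, method="A")
        b = make_series("2017-06-01", 20, gpp=5.0, method="B")
        rep = compare_methods([a, b], reference="A", timescale="30min")
        assert rep.pairs[0].median_relative_pct == pytest.approx(0.0)
        assert rep.anova_p == pytest.approx(1.0)

    def test_scale_factor_shows_as_percent(self):
        idx = pd.date_range("2017-06-01", periods=48 * 20, freq="30min")
        rng = np.random.default_rng(4)
        vals = rng.uniform(1, 10, len(idx))
        flag = pd.Series(MEASURED, index=idx, dtype=object)
        a = GPPSeries(method="A", gpp=pd.Series(vals, index=idx), flag=flag)
        b = GPPSeries(method="B", gpp=pd.Series(1.2 * vals, index=idx), flag=flag)
        rep = compare_methods([a, b], reference="A", timescale="daily")
        assert rep.pairs[0].median_relative_pct == pytest.approx(20.0, abs=1e-9)

    def test_anova_matches_textbook_formula(self):
        rng = np.random.default_rng(5)
        idx = pd.date_range("2017-06-01", periods=500, freq="30min")
        flag = pd.Series(MEASURED, index=idx, dtype=object)
        groups = [rng.normal(mu, 1.0, 500) for mu in (5.0, 5.5, 6.0)]
        series = [
            GPPSeries(method=f"M{i}", gpp=pd.Series(g, index=idx), flag=flag)
            for i, g in enumerate(groups)
        ]
        rep = compare_methods(series, reference="M0", timescale="30min")
        # brute-force one-way F statistic
        all_vals = np.concatenate(groups)
        grand = all_vals.mean()
        k, n = len(groups), len(all_vals)
        ss_between = sum(len(g) * (g.mean() - grand) ** 2 for g in groups)
        ss_within = sum(((g - g.mean()) ** 2).sum() for g in groups)
        f_oracle = (ss_between / (k - 1)) / (ss_within / (n - k))
        assert rep.anova_f == pytest.approx(f_oracle, rel=1e-9)

    def test_common_mask_shrinks_monotonically(self):
        a = make_series("2017-06-01", 10, measured_per_day=40, method="A",
                        gapfill_rest=False)
        b = make_series("2017-06-01", 10, measured_per_day=48, method="B")
        full = common_mask([a, b]).sum()
        b_less = make_series("2017-06-01", 10, measured_per_day=30, method="B",
                             gapfill_rest=False)
        assert common_mask([a, b_less]).sum() <= full
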