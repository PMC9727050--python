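"""Daily series I/O, hourly aggregation and stratified counting."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from tvdlnm import (DailySeries, aggregate_hourly, build_stratum_counts,
                    read_daily_series, write_daily_series)
from tvdlnm.synthetic import DEFAULT_STRATUM_SCHEME


def make_frame(n=4, **overrides):
    df = pd.DataFrame({
        "date": pd.date_range("2005-01-01", periods=n),
        "tmean": np.linspace(18, 22, n),
        "rh": np.full(n, 75.0),
        "pm10": np.full(n, 30.0),
        "holiday": [False] * n,
        "deaths_all": np.arange(1, n + 1),
    })
    for k, v in overrides.items():
        df[k] = v
    return df


class TestDailySeries:
    def test_toy_identity_read_back(self, tmp_path):
        path = tmp_path / "toy.csv"
        make_frame().to_csv(path, index=False)
        s = read_daily_series(path)
        assert s.n == 4
        np.testing.assert_array_equal(s.deaths("all"), [1, 2, 3, 4])
        assert sum(s.missing_report().values()) == 0
        assert list(s.frame["dow"][:2]) == [6, 7]  # 2005-01-01 was a Saturday

    def test_duplicate_date_error_names_date(self):
        df = make_frame()
        df.loc[2, "date"] = df.loc[1, "date"]
        with pytest.raises(ValueError, match="2005-01-02"):
            DailySeries(df)

    def test_gap_in_dates_rejected(self):
        df = make_frame()
        df.loc[3, "date"] = pd.Timestamp("2005-02-01")
        with pytest.raises(ValueError, match="consecutive"):
            DailySeries(df)

    def test_missing_tmean_loads_and_is_flagged(self, tmp_path):
        df = make_frame()
        df.loc[1, "tmean"] = np.nan
        path = tmp_path / "m.csv"
        df.to_csv(path, index=False)
        s = read_daily_series(path)
        assert s.n == 4 and s.missing_report()["tmean"] == 1

    def test_negative_count_rejected(self):
        with pytest.raises(ValueError, match="negative"):
            DailySeries(make_frame(deaths_all=[1, -2, 3, 4]))

    def test_out_of_range_rh_names_row(self):
        with pytest.raises(ValueError, match="row 1"):
            DailySeries(make_frame(rh=[50.0, 104.0, 60.0, 70.0]))

    def test_round_trip_lossless(self, tmp_path):
        df = make_frame(12)
        df.loc[5, "tmean"] = np.nan
        df.loc[7, "holiday"] = True
        s1 = DailySeries(df)
        path = tmp_path / "rt.csv"
        write_daily_series(s1, path)
        s2 = read_daily_series(path)
        pd.testing.assert_frame_equal(s1.frame, s2.frame)


class TestAggregateHourly:
    @staticmethod
    def hourly(station, day0, n_days, values):
        ts = pd.date_range(day0, periods=n_days * 24, freq="h")
        return pd.DataFrame({"station": station, "datetime": ts,
                             "value": values})

    def test_constant_station_returns_constant(self):
        h = self.hourly("s1", "2010-01-01", 2, 7.0)
        daily, kept = aggregate_hourly(h)
        assert kept == 1
        np.testing.assert_allclose(daily.to_numpy(), 7.0)

    def test_station_below_threshold_excluded(self):
        good = self.hourly("good", "2010-01-01", 2, 10.0)
        bad = self.hourly("bad", "2010-01-01", 2, 99.0)
        bad.loc[bad.index[: 24], "value"] = np.nan   # 50% valid < 75%
        daily, kept = aggregate_hourly(pd.concat([good, bad]),
                                       min_valid_fraction=0.75)
        assert kept == 1
        np.testing.assert_allclose(daily.to_numpy(), 10.0)

    def test_no_station_passes_is_error(self):
        h = self.hourly("s1", "2010-01-01", 2, 5.0)
        h.loc[h.index[:30], "value"] = np.nan
        with pytest.raises(ValueError, match="threshold"):
            aggregate_hourly(h, min_valid_fraction=0.95)

    def test_matches_two_stage_double_loop(self):
        rng = np.random.default_rng(8)
        frames = [self.hourly(s, "2010-01-01", 3,
                              rng.normal(20, 5, 72)) for s in "abc"]
        h = pd.concat(frames, ignore_index=True)
        h.loc[rng.choice(len(h), 20, replace=False), "value"] = np.nan
        daily, kept = aggregate_hourly(h, min_hours_per_day=18)
        # explicit two-stage oracle
        for di, day in enumerate(pd.date_range("2010-01-01", periods=3)):
            station_means = []
            for s in "abc":
                sub = h[(h["station"] == s) & (h["datetime"].dt.normalize()
                                               == day)]["value"].dropna()
                if len(sub) >= 18:
                    station_means.append(sub.mean())
            expected = np.mean(station_means) if station_means else np.nan
            np.testing.assert_allclose(daily.iloc[di], expected)

    @given(st.permutations(["a", "b", "c"]))
    def test_station_order_invariance(self, order):
        rng = np.random.default_rng(4)
        vals = {s: rng.normal(20, 3, 48) for s in "abc"}
        frames = [self.hourly(s, "2011-06-01", 2, vals[s]) for s in order]
        daily, _ = aggregate_hourly(pd.concat(frames, ignore_index=True))
        ref_frames = [self.hourly(s, "2011-06-01", 2, vals[s]) for s in "abc"]
        ref, _ = aggregate_hourly(pd.concat(ref_frames, ignore_index=True))
        np.testing.assert_allclose(daily.to_numpy(), ref.to_numpy())


class TestStratumCounts:
    dates = pd.date_range("2012-01-01", periods=3)

    def test_enumeration_of_two_records(self):
        rec = pd.DataFrame({
            "date": [self.dates[0]] * 2,
            "sex": ["M", "F"], "age": [70, 85],
            "ethnicity": ["white", "white"], "education": ["low", "mid"]})
        counts, tallies = build_stratum_counts(rec, DEFAULT_STRATUM_SCHEME,
                                               self.dates)
        day0 = counts.iloc[0]
        assert day0["deaths_male"] == 1 and day0["deaths_female"] == 1
        assert day0["deaths_age_65_79"] == 1 and day0["deaths_age_80_plus"] == 1
        assert day0["deaths_female_80_plus"] == 1
        assert day0["deaths_all"] == 2
        assert counts.iloc[1:].to_numpy().sum() == 0

    def test_missing_field_excluded_only_from_that_stratum(self):
        rec = pd.DataFrame({
            "date": [self.dates[1]], "sex": ["F"], "age": [70],
            "ethnicity": [None], "education": ["mid"]})
        counts, tallies = build_stratum_counts(rec, DEFAULT_STRATUM_SCHEME,
                                               self.dates)
        row = counts.iloc[1]
        assert row["deaths_all"] == 1 and row["deaths_female"] == 1
        assert row["deaths_age_65_79"] == 1
        assert row["deaths_white"] == 0 and row["deaths_nonwhite"] == 0
        assert tallies["white"] == 1 and tallies["all"] == 0

    def test_record_outside_range_rejected(self):
        rec = pd.DataFrame({"date": [pd.Timestamp("2011-12-31")],
                            "sex": ["F"], "age": [70],
                            "ethnicity": ["white"], "education": ["mid"]})
        with pytest.raises(ValueError, match="outside series range"):
            build_stratum_counts(rec, DEFAULT_STRATUM_SCHEME, self.dates)

    def test_column_sums_match_brute_force_filter(self):
        rng = np.random.default_rng(10)
        n = 1000
        rec = pd.DataFrame({
            "date": rng.choice(self.dates, n),
            "sex": rng.choice(["M", "F"], n),
            "age": rng.integers(65, 100, n).astype(float),
            "ethnicity": rng.choice(["white", "nonwhite", None], n,
                                    p=[0.6, 0.3, 0.1]),
            "education": rng.choice(["low", "mid", "high"], n)})
        counts, tallies = build_stratum_counts(rec, DEFAULT_STRATUM_SCHEME,
                                               self.dates)
        assert counts["deaths_all"].sum() == n
        assert counts["deaths_male"].sum() == (rec["sex"] == "M").sum()
        assert counts["deaths_age_80_plus"].sum() == (rec["age"] >= 80).sum()
        eth = rec["ethnicity"]
        assert counts["deaths_white"].sum() == (eth == "white").sum()
        assert tallies["white"] == eth.isna().sum()
        # partition property: males + females = all (sex never missing here)
        total = counts["deaths_male"] + counts["deaths_female"]
        np.testing.assert_array_equal(total.to_numpy(),
                                      counts["deaths_all"].to_numpy())
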