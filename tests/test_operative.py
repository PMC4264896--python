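"""Logger ingestion, daytime aggregation, patch ANOVA, warming projection and
exceedance accounting."""

from datetime import time

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from thermoperf.errors import ConfigError, ParseError
from thermoperf.operative import (
    TeSeries,
    daytime_filter,
    exceedance,
    interval_average,
    patch_anova,
    patch_summary,
    project_warming,
    read_logger_csv,
    write_logger_csv,
)


def make_series(temps, start="2013-10-15 07:00", freq="5min", *,
                exposure="sun", moisture="dry", model_id="m1", pond="pond1",
                mass_before=50.0, mass_after=43.5, hours=13.0):
    ts = pd.date_range(start, periods=len(temps), freq=freq)
    return TeSeries(
        model_id=model_id, pond=pond, exposure=exposure, moisture=moisture,
        samples=pd.DataFrame({"timestamp": ts, "temp_c": list(temps)}),
        mass_before_g=mass_before, mass_after_g=mass_after,
        deployment_hours=hours,
    )


class TestLoggerIO:
    def test_round_trip_lossless(self, te_table, tmp_path):
        path = tmp_path / "te.csv"
        te_table.to_csv(path, index=False)
        series = read_logger_csv(path)
        back = tmp_path / "back.csv"
        write_logger_csv(series, back)
        a = pd.read_csv(path)
        b = pd.read_csv(back)
        a_sorted = a.sort_values(["model_id", "timestamp"]).reset_index(drop=True)
        b_sorted = b.sort_values(["model_id", "timestamp"]).reset_index(drop=True)
        pd.testing.assert_frame_equal(a_sorted, b_sorted, check_like=True)

    def test_parses_full_deployment(self, te_series):
        assert len(te_series) == 8
        assert all(len(s.samples) == 288 for s in te_series)
        assert all(not s.gaps for s in te_series)

    def test_shuffled_rows_rejected_with_timestamp(self, te_table, tmp_path):
        shuffled = te_table.sample(frac=1.0, random_state=0)
        path = tmp_path / "shuffled.csv"
        shuffled.to_csv(path, index=False)
        with pytest.raises(ParseError, match=r"not strictly increasing at \d{4}"):
            read_logger_csv(path)

    def test_unknown_patch_label_rejected(self, te_table, tmp_path):
        bad = te_table.copy()
        bad.loc[bad["model_id"] == "model1", "exposure"] = "umbra"
        path = tmp_path / "bad.csv"
        bad.to_csv(path, index=False)
        with pytest.raises(ParseError, match="exposure"):
            read_logger_csv(path)

    def test_gap_flagged_not_interpolated(self, tmp_path):
        s = make_series(range(12))
        dropped = s.samples.drop(index=5)
        df = pd.DataFrame({
            "model_id": "m1", "pond": "pond1", "exposure": "sun",
            "moisture": "dry", "timestamp": dropped["timestamp"],
            "temp_c": dropped["temp_c"], "mass_before_g": 50.0,
            "mass_after_g": 43.5, "deployment_hours": 13.0,
        })
        path = tmp_path / "gap.csv"
        df.to_csv(path, index=False)
        (parsed,) = read_logger_csv(path)
        assert len(parsed.samples) == 11
        assert len(parsed.gaps) == 1


class TestDaytimeFilter:
    def test_full_day_window_is_identity(self):
        s = make_series(range(288), start="2013-10-15 00:00")
        out = daytime_filter(s, (time(0, 0), time(23, 59, 59)))
        assert len(out.samples) == 288

    def test_hand_counted_subset(self):
        # 06:00..08:55 at 5-min cadence = 36 samples; [07:00, 08:00) keeps 12
        s = make_series(range(36), start="2013-10-15 06:00")
        out = daytime_filter(s, (time(7, 0), time(8, 0)))
        assert len(out.samples) == 12
        assert out.samples["timestamp"].dt.time.min() == time(7, 0)
        assert out.samples["timestamp"].dt.time.max() == time(7, 55)

    def test_degenerate_window_rejected(self):
        s = make_series(range(12))
        with pytest.raises(ConfigError):
            daytime_filter(s, (time(7, 0), time(7, 0)))


class TestIntervalAverage:
    def test_constant_series(self):
        s = make_series([20.0] * 24)
        out = interval_average(s, 30)
        assert (out["mean_temp_c"] == 20.0).all()
        assert (out["sd_temp_c"] == 0.0).all()

    def test_two_replicates_average(self):
        a = make_series([10.0] * 12, model_id="m1")
        b = make_series([30.0] * 12, model_id="m2")
        out = interval_average([a, b], 30)
        assert (out["mean_temp_c"] == 20.0).all()

    def test_hand_computed_bin(self):
        s = make_series([1, 2, 3, 4, 5, 6])
        out = interval_average(s, 30)
        assert len(out) == 1
        assert out["mean_temp_c"].iloc[0] == pytest.approx(3.5)

    def test_width_must_match_cadence(self):
        s = make_series(range(12))
        with pytest.raises(ConfigError):
            interval_average(s, 7)

    def test_commutes_with_aligned_daytime_filter(self):
        s = make_series(np.sin(np.arange(288) / 10) * 10 + 20,
                        start="2013-10-15 00:00")
        window = (time(7, 0), time(20, 0))  # aligned to 30-min boundaries
        a = interval_average(daytime_filter(s, window), 30)
        filtered = daytime_filter(s, window)
        b_all = interval_average(s, 30)
        starts = filtered.samples["timestamp"].dt.floor("30min").unique()
        b = b_all[b_all["interval_start"].isin(starts)].reset_index(drop=True)
        pd.testing.assert_frame_equal(a, b)


class TestPatchSummary:
    def test_known_max_and_rate(self):
        s = make_series([18.0, 31.2, 25.0, 24.0, 22.0, 21.0])
        out = patch_summary(s)
        assert out.te_max == pytest.approx(31.2)
        assert out.mean_te == pytest.approx(np.mean([18.0, 31.2, 25, 24, 22, 21]))
        assert out.water_loss_rate == pytest.approx((50 - 43.5) / 13)  # 0.5 g/h

    def test_mass_gain_warns_negative_rate(self):
        s = make_series([20.0] * 6, mass_before=50.0, mass_after=51.0)
        with pytest.warns(UserWarning, match="negative"):
            out = patch_summary(s)
        assert out.water_loss_rate < 0

    def test_synthetic_sun_shade_gap(self, te_series):
        summaries = [patch_summary(s, window=(time(7), time(20)))
                     for s in te_series]
        sun = np.mean([s.mean_te for s in summaries if s.exposure == "sun"])
        shade = np.mean([s.mean_te for s in summaries if s.exposure == "shade"])
        assert abs((sun - shade) - 7.83) < 1.5


def anova_oracle(df, response):
    """Brute-force balanced two-way sums of squares (test oracle)."""
    y = df[response].to_numpy(float)
    grand = y.mean()
    sse = {}
    for factor in ("exposure", "moisture"):
        ss = sum(len(g) * (g[response].mean() - grand) ** 2
                 for _, g in df.groupby(factor))
        sse[factor] = ss
    ss_cells = sum(len(g) * (g[response].mean() - grand) ** 2
                   for _, g in df.groupby(["exposure", "moisture"]))
    ss_tot = float(((y - grand) ** 2).sum())
    ss_ab = ss_cells - sse["exposure"] - sse["moisture"]
    n = len(y)
    err_add = ss_tot - sse["exposure"] - sse["moisture"]
    err_full = ss_tot - ss_cells
    return {
        "exposure": (sse["exposure"] / (err_add / (n - 3)), n - 3),
        "moisture": (sse["moisture"] / (err_add / (n - 3)), n - 3),
        "exposure:moisture": (ss_ab / (err_full / (n - 4)), n - 4),
    }


def random_design(rng):
    rows = []
    i = 0
    for e in ("sun", "shade"):
        for m in ("wet", "dry"):
            for _ in range(2):
                i += 1
                rows.append({"model_id": f"m{i}", "exposure": e,
                             "moisture": m, "resp": rng.normal(20, 5)})
    return pd.DataFrame(rows)


class TestPatchAnova:
    def test_constant_response_all_null(self):
        df = random_design(np.random.default_rng(0))
        df["resp"] = 17.0
        table = patch_anova(df, "resp").set_index("factor")
        assert (table["F"] == 0.0).all()
        assert table.loc["exposure", "df2"] == 5
        assert table.loc["exposure:moisture", "df2"] == 4

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            df = random_design(rng)
            table = patch_anova(df, "resp").set_index("factor")
            oracle = anova_oracle(df, "resp")
            for factor, (f_expected, df_err) in oracle.items():
                assert table.loc[factor, "F"] == pytest.approx(f_expected, abs=1e-8)
                assert table.loc[factor, "df2"] == df_err

    def test_injected_exposure_effect(self):
        df = random_design(np.random.default_rng(3))
        df["resp"] = 20.0 + np.where(df["exposure"] == "sun", 8.0, 0.0)
        table = patch_anova(df, "resp").set_index("factor")
        assert table.loc["exposure", "p"] < 0.001
        assert table.loc["moisture", "F"] == pytest.approx(0.0, abs=1e-8)

    def test_unbalanced_rejected(self):
        df = random_design(np.random.default_rng(4)).iloc[:-1]
        with pytest.raises(ConfigError, match="unbalanced|cells"):
            patch_anova(df, "resp")


class TestProjectWarming:
    def test_zero_offset_is_identity(self):
        s = make_series([20.0] * 6)
        out = project_warming(s, 0.0)
        pd.testing.assert_frame_equal(out.samples, s.samples)

    def test_constant_shift(self):
        s = make_series([20.0] * 6)
        out = project_warming(s, 5.0)
        assert (out.samples["temp_c"] == 25.0).all()
        assert out.delta_t == 5.0

    def test_additivity(self):
        s = make_series(np.linspace(10, 30, 12))
        a = project_warming(project_warming(s, 3.0), 2.0)
        b = project_warming(s, 5.0)
        pd.testing.assert_frame_equal(a.samples, b.samples)
        assert a.delta_t == b.delta_t == 5.0


class TestExceedance:
    WINDOW = (time(7, 0), time(20, 0))

    def test_all_between_ctmin_and_topt(self):
        s = make_series([20.0] * 24)
        out = exceedance(s, (10.0, 25.0, 35.0), window=self.WINDOW)
        assert out.frac_ctmin_to_topt == 1.0
        assert out.frac_above_ctmax == 0.0

    def test_hand_counted_bands(self):
        # ten 30-min intervals: 3 above ct_max=30, 2 in (t_opt, ct_max],
        # 4 in [ct_min, t_opt], 1 below ct_min=10
        interval_means = [35, 33, 31, 28, 26, 20, 18, 15, 12, 5]
        temps = np.repeat(interval_means, 6)  # constant within interval
        s = make_series(temps, start="2013-10-15 08:00")
        out = exceedance(s, (10.0, 25.0, 30.0), window=self.WINDOW)
        assert out.n_intervals == 10
        assert out.frac_above_ctmax == pytest.approx(0.3)
        assert out.frac_topt_to_ctmax == pytest.approx(0.2)
        assert out.frac_ctmin_to_topt == pytest.approx(0.4)
        assert out.frac_below_ctmin == pytest.approx(0.1)

    def test_fractions_sum_to_one(self, te_series):
        for group in ([te_series[0]], te_series[:2]):
            if len({s.patch for s in group}) > 1:
                continue
            out = exceedance(group, (11.0, 26.0, 36.4), window=self.WINDOW,
                             delta_t=5.0)
            total = (out.frac_below_ctmin + out.frac_ctmin_to_topt
                     + out.frac_topt_to_ctmax + out.frac_above_ctmax)
            assert total == pytest.approx(1.0, abs=1e-12)

    @settings(deadline=None, derandomize=True, max_examples=20)
    @given(d1=st.floats(0, 8), d2=st.floats(0, 8))
    def test_warming_monotonicity(self, d1, d2):
        rng = np.random.default_rng(12)
        s = make_series(rng.uniform(15, 38, 60))
        lo, hi = sorted([d1, d2])
        a = exceedance(s, (10.0, 26.0, 36.0), window=self.WINDOW, delta_t=lo)
        b = exceedance(s, (10.0, 26.0, 36.0), window=self.WINDOW, delta_t=hi)
        assert b.frac_above_ctmax >= a.frac_above_ctmax

    def test_invalid_limits_rejected(self):
        s = make_series([20.0] * 6)
        with pytest.raises(ConfigError):
            exceedance(s, (30.0, 25.0, 20.0), window=self.WINDOW)

    def test_mixed_patches_rejected(self):
        a = make_series([20.0] * 6, exposure="sun")
        b = make_series([20.0] * 6, exposure="shade", model_id="m2")
        with pytest.raises(ConfigError, match="patch"):
            exceedance([a, b], (10.0, 25.0, 35.0), window=self.WINDOW)

    def test_raw_time_base_counts_samples(self):
        temps = [35.0] * 6 + [20.0] * 18
        s = make_series(temps)
        out = exceedance(s, (10.0, 25.0, 30.0), window=self.WINDOW,
                         time_base="raw")
        assert out.n_intervals == 24
        assert out.frac_above_ctmax == pytest.approx(6 / 24)
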