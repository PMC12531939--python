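import numpy as np
import pandas as pd
import pytest

from fedsense.preprocess import (
    OnlineChannelSeries,
    assemble_batch,
    cumulative_glucose_consumed,
    cumulative_trapezoid,
    daily_average,
    last_in_day,
    smooth_ph,
)


def series(times, values, name="ph"):
    return OnlineChannelSeries(name, np.asarray(times, float), np.asarray(values, float))


class TestSavitzkyGolay:
    def test_constant_series_unchanged(self):
        t = np.linspace(0, 3, 101)
        out = smooth_ph(series(t, np.full(101, 7.0)), window=11, polyorder=2)
        np.testing.assert_allclose(out.values, 7.0)

    def test_polynomials_up_to_polyorder_preserved(self):
        t = np.linspace(0, 3, 101)
        ramp = 6.8 + 0.1 * t
        out = smooth_ph(series(t, ramp), window=15, polyorder=1)
        np.testing.assert_allclose(out.values, ramp, atol=1e-10)

    def test_interior_points_match_per_window_polyfit_oracle(self):
        # each smoothed point is the independent least-squares polynomial
        # fit over its window, evaluated at the center
        rng = np.random.default_rng(3)
        t = np.arange(200) * 0.01
        v = np.sin(2 * np.pi * t) + 0.05 * rng.normal(size=200)
        window, poly = 21, 2
        out = smooth_ph(series(t, v), window=window, polyorder=poly)
        half = window // 2
        for i in (half, 60, 120, 199 - half):
            sl = slice(i - half, i + half + 1)
            coef = np.polynomial.polynomial.polyfit(t[sl] - t[i], v[sl], poly)
            assert out.values[i] == pytest.approx(coef[0], abs=1e-9)

    @pytest.mark.parametrize("window,err", [(10, "odd"), (501, "length")])
    def test_invalid_window_rejected(self, window, err):
        t = np.linspace(0, 1, 100)
        with pytest.raises(ValueError, match=err):
            smooth_ph(series(t, np.sin(t)), window=window)


class TestDailyAverage:
    def test_constant_and_two_point_mean(self):
        s = series([0.1, 0.4, 0.6, 0.9], [40.0, 40.0, 40.0, 40.0])
        vals, ok = daily_average(s, [0])
        assert ok.all() and vals[0] == 40.0
        s = series([0.25, 0.75], [6.9, 7.1])
        vals, _ = daily_average(s, [0])
        assert vals[0] == pytest.approx(7.0)

    def test_irregular_cadence_matches_groupby_oracle(self):
        rng = np.random.default_rng(8)
        t = np.sort(rng.uniform(0, 5, 400))
        t = t[np.diff(np.concatenate([[-1], t])) > 0]
        v = rng.normal(size=len(t))
        vals, ok = daily_average(series(t, v), np.arange(5))
        oracle = pd.Series(v).groupby(np.floor(t).astype(int)).mean()
        for d in range(5):
            if ok[d]:
                assert vals[d] == pytest.approx(oracle[d])

    def test_empty_series_is_error(self):
        with pytest.raises(ValueError, match="empty"):
            daily_average(series([], []), [0])

    def test_day_without_samples_flagged_missing(self):
        vals, ok = daily_average(series([0.5, 2.5], [1.0, 2.0]), [0, 1, 2])
        assert ok.tolist() == [True, False, True]
        assert np.isnan(vals[1])


class TestCumulativeTrapezoid:
    def test_constant_do_rectangle_integral(self):
        t = np.linspace(0, 2, 49)
        out = cumulative_trapezoid(series(t, np.full(49, 40.0)), [0, 1, 2])
        np.testing.assert_allclose(out, [0.0, 40.0, 80.0], atol=1e-9)

    def test_linear_signal_closed_form(self):
        t = np.linspace(0, 2, 81)
        out = cumulative_trapezoid(series(t, t), [2])
        assert out[0] == pytest.approx(2.0, abs=1e-9)

    def test_random_signal_matches_term_by_term_summation_oracle(self):
        rng = np.random.default_rng(1)
        t = np.sort(rng.uniform(0, 3, 50))
        v = rng.uniform(20, 60, 50)
        out = cumulative_trapezoid(series(t, v), [t[-1]])
        oracle = sum(
            (t[i + 1] - t[i]) * (v[i + 1] + v[i]) / 2 for i in range(49)
        )
        assert out[0] == pytest.approx(oracle, abs=1e-9)

    def test_additive_over_interval_concatenation(self):
        t = np.linspace(0, 4, 97)
        v = np.cos(t) + 2
        full = cumulative_trapezoid(series(t, v), [4])[0]
        first = cumulative_trapezoid(series(t[:49], v[:49]), [t[48]])[0]
        second = cumulative_trapezoid(series(t[48:], v[48:]), [4])[0]
        assert full == pytest.approx(first + second, abs=1e-9)

    def test_exact_for_piecewise_linear(self):
        t = np.array([0.0, 0.5, 2.0, 3.0])
        v = np.array([1.0, 2.0, 0.0, 4.0])
        out = cumulative_trapezoid(series(t, v), [3.0])
        exact = 0.5 * (1 + 2) / 2 + 1.5 * (2 + 0) / 2 + 1.0 * (0 + 4) / 2
        assert out[0] == pytest.approx(exact, abs=1e-12)

    def test_eval_outside_span_is_error(self):
        with pytest.raises(ValueError, match="span"):
            cumulative_trapezoid(series([0, 1], [1, 1]), [2])


class TestCumulativeGlucose:
    def test_single_interval_difference(self):
        cgc = cumulative_glucose_consumed([30.0, 20.0], [28.0, 20.0])
        assert cgc.tolist() == [0.0, 10.0]

    def test_residual_equals_postfeed_gives_zero(self):
        post = np.array([30.0, 30.0, 30.0])
        cgc = cumulative_glucose_consumed(post, post)
        np.testing.assert_allclose(cgc, 0.0)

    def test_five_interval_running_sum_oracle(self):
        post = np.array([30.0, 28.0, 33.0, 35.0, 30.0, 25.0])
        resid = np.array([30.0, 20.0, 18.0, 22.0, 19.0, 21.0])
        cgc = cumulative_glucose_consumed(post, resid)
        running, total = [0.0], 0.0
        for j in range(5):
            total += post[j] - resid[j + 1]
            running.append(total)
        np.testing.assert_allclose(cgc, running)

    def test_negative_consumption_warns_and_optionally_clamps(self):
        post = np.array([20.0, 30.0])
        resid = np.array([20.0, 25.0])  # apparent consumption -5
        with pytest.warns(UserWarning, match="negative"):
            kept = cumulative_glucose_consumed(post, resid)
        assert kept[1] == pytest.approx(-5.0)
        with pytest.warns(UserWarning):
            clamped = cumulative_glucose_consumed(post, resid, clamp_negative=True)
        assert clamped[1] == 0.0


class TestAssembleBatch:
    def test_round_trips_simulated_batch_through_files(self, tmp_path, delta_batch):
        from fedsense.io import read_batch, write_batch

        write_batch(delta_batch, tmp_path / "b")
        back = read_batch(tmp_path / "b")
        np.testing.assert_allclose(back.online, delta_batch.online, rtol=1e-12)
        np.testing.assert_array_equal(back.offline_mask, delta_batch.offline_mask)
        np.testing.assert_allclose(
            back.offline[back.offline_mask],
            delta_batch.offline[delta_batch.offline_mask], rtol=1e-12,
        )

    def test_paper_grid_mask_has_fifty_entries(self, delta_batch):
        assert delta_batch.n_days == 18
        assert len(delta_batch.sampling_days) == 10
        assert delta_batch.offline_mask.sum() == 50

    def test_empty_offline_log_gives_pure_online_batch(self, delta_batch):
        rec = assemble_batch(
            delta_batch.raw_online, pd.DataFrame(), delta_batch.day_grid,
            batch_id="online_only",
        )
        assert not rec.offline_mask.any()

    def test_missing_channel_listed_in_error(self, delta_batch):
        channels = dict(delta_batch.raw_online)
        channels.pop("o2_flow")
        with pytest.raises(ValueError, match="o2_flow"):
            assemble_batch(channels, pd.DataFrame(), delta_batch.day_grid)

    def test_daily_inputs_pass_through(self):
        # already-daily averages/running totals survive assembly unchanged
        days = np.arange(-3, 15)
        t = days.astype(float)
        channels = {
            "ph": series(t, np.full(18, 7.0)),
            "do_pct": series(t, np.full(18, 40.0)),
            "temp_c": series(t, np.where(days < 0, 37.0, 32.0)),
            "base_ml": series(t, np.linspace(0, 5, 18)),
            "o2_flow": series(t, np.zeros(18)),
            "co2_flow": series(t, np.zeros(18)),
        }
        rec = assemble_batch(channels, pd.DataFrame(), days, batch_id="daily")
        np.testing.assert_allclose(rec.online[:, 0], 7.0)
        np.testing.assert_allclose(rec.online[:, 1], 40.0)
        np.testing.assert_allclose(rec.online[:, 3], np.linspace(0, 5, 18))

    def test_last_in_day_for_running_totals(self):
        s = series([0.2, 0.8, 1.3, 1.9], [1.0, 2.0, 2.0, 5.0], "base_ml")
        vals, ok = last_in_day(s, [0, 1])
        assert vals.tolist() == [2.0, 5.0]
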