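"""Closed forms, detection rules, and invariances of feature extraction."""

import numpy as np
import pytest

from conftest import make_channel, make_ibi
from ppactiv.errors import ConfigurationError
from ppactiv.features import (
    FEATURE_NAMES,
    FeatureConfig,
    assemble_feature_series,
    bvp_features,
    detect_scr_events,
    eda_features,
    hrv_features,
    temp_slope,
)


class TestHrv:
    def test_constant_rr(self):
        ibi = make_ibi([1.0] * 400)
        mhr, mrri, sdnn, rmssd = hrv_features(ibi, 350.0, 300.0)
        assert mhr == pytest.approx(60.0)
        assert mrri == pytest.approx(1000.0)
        assert sdnn == pytest.approx(0.0)
        assert rmssd == pytest.approx(0.0)

    def test_alternating_rr_closed_form(self):
        # 150 beats of alternating 0.8/1.0 s inside the window
        ibi = make_ibi([0.8, 1.0] * 100)
        t = float(ibi.offsets[-1])
        mhr, mrri, sdnn, rmssd = hrv_features(ibi, t, 300.0)
        sel = (ibi.times > t - 300.0) & (ibi.times <= t)
        rr = ibi.rr[sel] * 1000
        assert mrri == pytest.approx(np.mean(rr))
        assert mrri == pytest.approx(900.0, abs=1.0)
        assert mhr == pytest.approx(60000.0 / mrri)
        assert rmssd == pytest.approx(200.0)
        assert sdnn == pytest.approx(np.std(rr, ddof=1))
        assert sdnn == pytest.approx(100.3, abs=0.3)

    def test_too_few_beats_masked(self):
        ibi = make_ibi([1.0, 1.0])
        assert np.isnan(hrv_features(ibi, 400.0, 300.0)).all()  # 0 beats
        # exactly two beats: first three defined, RMSSD not
        mhr, mrri, sdnn, rmssd = hrv_features(ibi, 2.5, 300.0)
        assert not np.isnan([mhr, mrri, sdnn]).any()
        assert np.isnan(rmssd)

    def test_time_shift_invariance(self):
        rng = np.random.default_rng(4)
        rr = rng.uniform(0.7, 1.1, 300)
        a = hrv_features(make_ibi(rr, start=0.0), 290.0, 200.0)
        b = hrv_features(make_ibi(rr, start=5000.0), 5290.0, 200.0)
        np.testing.assert_allclose(a, b)


class TestScrDetection:
    def test_constant_signal(self):
        assert detect_scr_events(make_channel([0.5] * 100)) == []

    def test_slow_ramp_counts_once(self):
        # 0.02 μS/s for 10 s then flat: a <5 s sub-segment rises 0.095
        ramp = 0.02 * np.arange(41) / 4.0
        sig = np.concatenate([ramp, np.full(40, ramp[-1])])
        events = detect_scr_events(make_channel(sig))
        assert len(events) == 1
        onset, peak, amp = events[0]
        assert onset == pytest.approx(0.0)
        assert peak == pytest.approx(10.0)
        assert amp == pytest.approx(0.2)

    def test_two_separated_ramps(self):
        ramp = np.linspace(0.0, 0.06, 13)  # 0.06 μS over 3 s at 4 Hz
        plateau = np.full(240, 0.06)  # 60 s flat
        sig = np.concatenate([ramp, plateau, 0.06 + ramp])
        assert len(detect_scr_events(make_channel(sig))) == 2

    def test_sub_threshold_rise_ignored(self):
        ramp = np.linspace(0.0, 0.04, 13)  # only 0.04 μS over 3 s
        sig = np.concatenate([ramp, np.full(40, 0.04)])
        assert detect_scr_events(make_channel(sig)) == []

    def test_only_rises_detected(self):
        ramp = np.linspace(0.0, 0.2, 21)
        sig = np.concatenate([ramp, np.full(40, 0.2)])
        assert len(detect_scr_events(make_channel(sig))) == 1
        assert detect_scr_events(make_channel(sig[::-1])) == []


class TestEda:
    def test_constant(self):
        ch = make_channel([0.5] * 1200)
        mamp, slope, events = eda_features(ch, 299.0, 300.0)
        assert mamp == pytest.approx(0.5)
        assert slope == pytest.approx(0.0)
        assert events == 0

    def test_linear_ramp_closed_form(self):
        n = 1200  # 300 s at 4 Hz
        ch = make_channel(np.linspace(0.1, 0.9, n))
        t = float(ch.times[-1])
        mamp, slope, _ = eda_features(ch, t, 300.0)
        assert mamp == pytest.approx(0.5)
        assert slope == pytest.approx(0.8 / ((n - 1) / 4.0))
        assert slope == pytest.approx(0.002667, abs=2e-5)

    def test_scaling_and_shift(self):
        rng = np.random.default_rng(1)
        x = np.cumsum(rng.normal(0, 0.01, 2000)) + 1.0
        ch = make_channel(x)
        t = 450.0
        mamp, slope, ev = eda_features(ch, t, 300.0)
        m2, s2, _ = eda_features(make_channel(3 * x), t, 300.0)
        assert m2 == pytest.approx(3 * mamp)
        assert s2 == pytest.approx(3 * slope)
        _, _, ev_shift = eda_features(make_channel(x + 5.0), t, 300.0)
        assert ev_shift == ev  # SCR count invariant to additive offsets


class TestBvpTemp:
    def test_constant_bvp(self):
        ch = make_channel([-2.0] * 100, name="BVP")
        assert bvp_features(ch, 20.0, 300.0) == (2.0, -2.0, -2.0)

    def test_sine_mean_abs(self):
        rate, A, periods = 64.0, 3.0, 200
        t = np.arange(int(rate * periods)) / rate  # 1 Hz sine, whole periods
        ch = make_channel(A * np.sin(2 * np.pi * t), rate_hz=rate, name="BVP")
        mean_abs, lo, hi = bvp_features(ch, float(periods), float(periods))
        assert mean_abs == pytest.approx(2 * A / np.pi, rel=0.01)
        assert lo == pytest.approx(-A, rel=1e-3)
        assert hi == pytest.approx(A, rel=1e-3)

    def test_min_le_max(self):
        rng = np.random.default_rng(2)
        ch = make_channel(rng.normal(size=3000), rate_hz=64.0, name="BVP")
        _, lo, hi = bvp_features(ch, 40.0, 30.0)
        assert lo <= hi

    def test_temp_constant_and_exact_line(self):
        const = make_channel([33.0] * 400, name="TEMP")
        assert temp_slope(const, 90.0, 60.0) == pytest.approx(0.0)
        t = np.arange(400) / 4.0
        line = make_channel(33.0 + 0.001 * t, name="TEMP")
        assert temp_slope(line, 90.0, 60.0) == pytest.approx(0.001)

    def test_temp_noisy_line_within_3se(self):
        rng = np.random.default_rng(3)
        n, rate, sigma, beta = 240, 4.0, 0.01, 0.002
        t = np.arange(n) / rate
        ch = make_channel(beta * t + rng.normal(0, sigma, n), name="TEMP")
        est = temp_slope(ch, float(t[-1]), 60.0)
        se = sigma / np.sqrt(np.sum((t - t.mean()) ** 2))
        assert abs(est - beta) < 3 * se


class TestAssemble:
    def test_shape_and_warmup(self, one_hour_recording):
        f = assemble_feature_series(one_hour_recording)
        assert f.n == 3600
        assert list(f.feature_names) == list(FEATURE_NAMES)
        assert not f.valid[:299].any()  # 5-minute warm-up masked
        assert f.valid[600:].mean() > 0.95
        # domain invariants on valid rows
        m = f.matrix[f.valid]
        assert (m[:, 2] >= 0).all() and (m[:, 3] >= 0).all()  # SDNN, RMSSD
        assert (m[:, 6] >= 0).all() and (m[:, 6] % 1 == 0).all()  # Events
        assert (m[:, 8] <= m[:, 9]).all()  # BVPmin <= BVPmax

    def test_rows_match_scalar_operations(self, one_hour_recording):
        rec = one_hour_recording
        f = assemble_feature_series(rec)
        cfg = FeatureConfig()
        rng = np.random.default_rng(0)
        for i in rng.choice(np.flatnonzero(f.valid), size=5, replace=False):
            t = float(f.timestamps[i])
            expected = (
                list(hrv_features(rec.ibi, t, cfg.hrv_window_s))
                + list(eda_features(rec.channels["EDA"], t, cfg.eda_window_s))
                + list(bvp_features(rec.channels["BVP"], t, cfg.bvp_window_s))
                + [temp_slope(rec.channels["TEMP"], t,
                              cfg.temp_slope_window_s)]
            )
            np.testing.assert_allclose(f.matrix[i], expected, atol=1e-8,
                                       rtol=1e-8)

    def test_causality_under_truncation(self, one_hour_recording):
        """Features at s <= t are unchanged when the input stops at t."""
        from ppactiv.io_formats import ChannelSeries, IBISeries, \
            PhysioRecording

        rec = one_hour_recording
        t_cut = rec.session_span[0] + 1800.0
        chans = {}
        for name, ch in rec.channels.items():
            keep = ch.times <= t_cut
            chans[name] = ChannelSeries(name, ch.start_time, ch.rate_hz,
                                        ch.values[keep])
        keep = rec.ibi.times <= t_cut
        trunc = PhysioRecording(
            rec.trader_id, rec.day, chans,
            IBISeries(rec.ibi.start_time, rec.ibi.offsets[keep],
                      rec.ibi.rr[keep]),
            (rec.session_span[0], t_cut),
        )
        full = assemble_feature_series(rec)
        part = assemble_feature_series(trunc)
        n = part.n
        np.testing.assert_array_equal(full.valid[:n], part.valid)
        # identical up to the numerical centring constant (~1e-13)
        np.testing.assert_allclose(full.matrix[:n][part.valid],
                                   part.matrix[part.valid],
                                   rtol=1e-9, atol=1e-9)

    def test_missing_channel_is_configuration_error(self, one_hour_recording):
        from ppactiv.io_formats import PhysioRecording

        rec = one_hour_recording
        chans = {k: v for k, v in rec.channels.items() if k != "EDA"}
        broken = PhysioRecording(rec.trader_id, rec.day, chans, rec.ibi,
                                 rec.session_span)
        with pytest.raises(ConfigurationError, match="EDA"):
            assemble_feature_series(broken)
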