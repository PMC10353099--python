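"""Per-modality detector behaviour against closed forms and brute-force oracles."""

import logging
import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import seizurekit as sk
from seizurekit.detectors import MagnitudeSeries
from conftest import make_recording, random_config, random_recording
from oracles import (
    oracle_baseline,
    oracle_desaturation,
    oracle_fall,
    oracle_jerk,
    oracle_tachycardia,
)


def series(m, rate=50.0):
    m = np.asarray(m, float)
    return MagnitudeSeries(t=np.arange(len(m)) / rate, m=m, rate=rate)


class TestMagnitude:
    @pytest.mark.parametrize("xyz, expected", [
        ((0.0, 0.0, 9.81), 9.81),   # gravity-only rest
        ((3.0, 4.0, 0.0), 5.0),     # 3-4-5 identity
    ])
    def test_known_norms(self, xyz, expected):
        ax, ay, az = xyz
        rec = make_recording(ax=[ax] * 3, ay=[ay] * 3, az=[az] * 3)
        assert sk.accel_magnitude(rec).m == pytest.approx([expected] * 3)

    def test_matches_per_sample_recomputation(self):
        rng = np.random.default_rng(11)
        rec = make_recording(ax=rng.normal(0, 5, 100), ay=rng.normal(0, 5, 100),
                             az=rng.normal(9.81, 5, 100))
        got = sk.accel_magnitude(rec).m
        expected = [math.sqrt(rec.ax[i] ** 2 + rec.ay[i] ** 2 + rec.az[i] ** 2)
                    for i in range(100)]
        assert got == pytest.approx(expected, abs=0)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rotation_invariance(self, seed):
        """The magnitude must not depend on the sensor's orientation."""
        rng = np.random.default_rng(seed)
        v = rng.normal(0, 5, (3, 20))
        q, _ = np.linalg.qr(rng.normal(size=(3, 3)))
        w = q @ v
        rec1 = make_recording(ax=v[0], ay=v[1], az=v[2])
        rec2 = make_recording(ax=w[0], ay=w[1], az=w[2])
        np.testing.assert_allclose(sk.accel_magnitude(rec1).m,
                                   sk.accel_magnitude(rec2).m, rtol=1e-9)


class TestSmooth:
    def test_constant_series_unchanged(self):
        s = sk.smooth(series([9.81] * 100), 0.5)
        assert s.m == pytest.approx([9.81] * 100)

    def test_spike_attenuation_closed_form(self):
        """A single spike in a 25-sample window is diluted 25-fold."""
        m = np.full(200, 9.81)
        m[100] = 50.0
        s = sk.smooth(series(m), 0.5)
        assert s.m[100] == pytest.approx(9.81 + (50 - 9.81) / 25)

    def test_degenerate_window_is_identity(self):
        m = np.random.default_rng(0).normal(9.81, 2, 50)
        s = sk.smooth(series(m), 0.001)
        assert np.array_equal(s.m, m)

    def test_edges_use_partial_windows(self):
        m = np.arange(10, dtype=float)
        s = sk.smooth(series(m, rate=10.0), 0.5)  # 5-sample window
        assert s.m[0] == pytest.approx(np.mean(m[:3]))
        assert s.m[-1] == pytest.approx(np.mean(m[-3:]))


class TestFall:
    def test_high_then_low_pattern(self, default_config):
        m = [9.81] * 50 + [30.0, 25.0, 8.0] + [9.81] * 50
        flags = sk.detect_fall(series(m), default_config)
        assert len(flags) == 1
        assert flags[0].evidence == 30.0
        assert flags[0].modality is sk.Modality.FALL

    def test_no_drop_no_flag(self, default_config):
        m = [9.81] * 50 + [30.0, 25.0, 24.0] + [12.0] * 200
        assert sk.detect_fall(series(m), default_config) == []

    def test_drop_outside_window_no_flag(self, default_config):
        # drop arrives 3 s after the impact: beyond fall_pattern_window (2 s)
        m = [9.81] * 10 + [30.0] + [15.0] * 150 + [8.0] + [9.81] * 10
        assert sk.detect_fall(series(m), default_config) == []

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_exhaustive_pair_scan(self, seed, default_config):
        rng = np.random.default_rng(seed)
        levels = np.array([9.81, 5.0, 15.0, 26.0, 32.0, 8.0])
        m = np.repeat(levels[rng.integers(0, 6, 120)], 4) + rng.normal(0, 0.5, 480)
        s = series(m)
        assert sk.detect_fall(s, default_config) == oracle_fall(
            s.m, s.t, default_config)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_monotone_in_a_high_for_impact_transients(self, seed):
        """Raising the impact threshold never creates new flags (for
        impact-like spikes, where each excursion fits the pattern window)."""
        rng = np.random.default_rng(seed)
        m = np.full(600, 9.81)
        for pos in rng.choice(np.arange(10, 580, 4), size=6, replace=False):
            m[pos] = rng.uniform(15, 45)
            m[pos + 1] = rng.uniform(4, 9)
        counts = [
            len(sk.detect_fall(series(m), sk.DetectorConfig(a_high=a)))
            for a in (15.1, 20.0, 25.0, 30.0, 40.0)
        ]
        assert counts == sorted(counts, reverse=True)


class TestBaseline:
    def test_fixed_mode_constant(self):
        rec = make_recording(hr=[70.0] * 100)
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=72.0)
        assert sk.hr_baseline(rec, cfg).tolist() == [72.0] * 100

    def test_fixed_mode_without_value_is_an_error(self):
        with pytest.raises(ValueError, match="baseline_fixed"):
            sk.DetectorConfig(baseline_mode="fixed")

    def test_rolling_constant_hr_after_warmup(self):
        rec = make_recording(hr=[70.0] * (50 * 30), rate=50.0)
        cfg = sk.DetectorConfig(baseline_window=10.0, baseline_gap=2.0)
        b = sk.hr_baseline(rec, cfg)
        assert np.all(np.isnan(b[:500]))
        assert np.all(b[500:] == 70.0)

    def test_gap_excludes_recent_step(self):
        """A step 20 s ago must not move a baseline whose gap is 30 s wide and
        whose window is dominated by pre-step history."""
        rate = 10.0
        n = int(620 * rate)
        hr = np.where(np.arange(n) / rate < 600.0, 70.0, 90.0)
        rec = make_recording(hr=hr, rate=rate)
        cfg = sk.DetectorConfig()
        b = sk.hr_baseline(rec, cfg)
        i = int(620 * rate) - 1
        assert b[i] == 70.0

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_brute_force_median(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_recording(rng, duration=20.0, rate=25.0)
        cfg = sk.DetectorConfig(baseline_window=6.0, baseline_gap=1.0,
                                baseline_update=0.5)
        got = sk.hr_baseline(rec, cfg)
        exp = oracle_baseline(rec, cfg)
        assert np.allclose(got, exp, equal_nan=True, atol=0)


class TestTachycardia:
    def test_sustained_rise_flags_with_excess_evidence(self):
        hr = np.concatenate([np.full(3000, 70.0), np.full(1000, 82.0)])
        rec = make_recording(hr=hr)
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=70.0)
        flags = sk.detect_tachycardia(rec, sk.hr_baseline(rec, cfg), cfg)
        assert len(flags) == 1
        assert flags[0].evidence == pytest.approx(12.0)

    def test_subthreshold_rise_ignored(self):
        hr = np.concatenate([np.full(3000, 70.0), np.full(1000, 79.0)])
        rec = make_recording(hr=hr)
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=70.0)
        assert sk.detect_tachycardia(rec, sk.hr_baseline(rec, cfg), cfg) == []

    def test_short_burst_debounced(self):
        hr = np.full(3000, 70.0)
        hr[1000:1100] = 85.0  # 2 s < min_tachycardia_duration (10 s)
        rec = make_recording(hr=hr)
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=70.0)
        assert sk.detect_tachycardia(rec, sk.hr_baseline(rec, cfg), cfg) == []

    def test_all_missing_hr_warns_and_idles(self, caplog):
        rec = make_recording(hr=np.full(100, np.nan))
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=70.0)
        with caplog.at_level(logging.WARNING):
            flags = sk.detect_tachycardia(rec, sk.hr_baseline(rec, cfg), cfg)
        assert flags == []
        assert "missing" in caplog.text

    def test_stale_hr_disables_detector(self):
        hr = np.full(3000, np.nan)
        hr[0] = 90.0  # single observation, then silence
        rec = make_recording(hr=hr)
        cfg = sk.DetectorConfig(baseline_mode="fixed", baseline_fixed=70.0,
                                min_tachycardia_duration=1.0)
        flags = sk.detect_tachycardia(rec, sk.hr_baseline(rec, cfg), cfg)
        # flag covers only the fresh 10 s, not the whole hour of stale fill
        assert len(flags) == 1
        assert flags[0].offset <= 10.0 + 0.03


class TestDesaturation:
    def test_dip_below_threshold_flags_min_spo2(self):
        spo2 = np.full(2000, 97.0)
        spo2[500:1250] = 86.0
        rec = make_recording(spo2=spo2)
        flags = sk.detect_desaturation(rec, sk.DetectorConfig())
        assert len(flags) == 1
        assert flags[0].evidence == 86.0

    def test_constant_normal_spo2_no_flags(self):
        rec = make_recording(spo2=np.full(1000, 97.0))
        assert sk.detect_desaturation(rec, sk.DetectorConfig()) == []

    def test_exact_threshold_is_not_a_desaturation(self):
        """The rule is strictly below 90 %."""
        spo2 = np.full(2000, 97.0)
        spo2[500:1250] = 90.0
        rec = make_recording(spo2=spo2)
        assert sk.detect_desaturation(rec, sk.DetectorConfig()) == []


class TestVibrationFrequency:
    def test_square_wave_rate_recovered(self, default_config):
        rec = make_recording(vib=(np.floor(2 * 10.0 * np.arange(500) / 50.0)
                                  % 2 == 0).astype(int))
        f = sk.vibration_frequency(rec, default_config, t=9.0)
        assert f == pytest.approx(10.0, abs=0.5)

    def test_silent_channel_inactive(self, default_config):
        rec = make_recording(vib=np.zeros(500, dtype=int))
        assert sk.vibration_frequency(rec, default_config, t=9.0) is None

    def test_sparse_edges_below_gate_inactive(self, default_config):
        vib = np.zeros(500, dtype=int)
        vib[[200, 240]] = 1  # 2 rising edges < vib_min_edges (4)
        rec = make_recording(vib=vib)
        assert sk.vibration_frequency(rec, default_config, t=6.0) is None

    def test_window_must_be_inside_recording(self, default_config):
        rec = make_recording(vib=np.zeros(500, dtype=int))
        with pytest.raises(ValueError, match="window"):
            sk.vibration_frequency(rec, default_config, t=1.0)


class TestJerk:
    @staticmethod
    def pulse_train(freq, duration=30.0, rate=50.0, start=5.0, stop=25.0):
        t = np.arange(int(duration * rate)) / rate
        vib = np.zeros(len(t), dtype=int)
        seg = (t >= start) & (t < stop)
        vib[seg] = (np.floor(2 * freq * (t[seg] - start)) % 2 == 0).astype(int)
        return make_recording(vib=vib)

    def test_out_of_band_train_flagged(self, default_config):
        flags = sk.detect_jerk(self.pulse_train(20.0), default_config)
        assert len(flags) == 1
        assert flags[0].evidence == pytest.approx(20.0, abs=0.5)

    def test_in_band_train_is_normal_movement(self, default_config):
        assert sk.detect_jerk(self.pulse_train(10.0), default_config) == []

    def test_inactive_channel_never_flagged(self, default_config):
        rec = make_recording(vib=np.zeros(1500, dtype=int))
        assert sk.detect_jerk(rec, default_config) == []

    def test_inside_semantics_flips_the_band(self):
        cfg = sk.DetectorConfig(band_semantics="inside")
        assert sk.detect_jerk(self.pulse_train(20.0), cfg) == []
        flags = sk.detect_jerk(self.pulse_train(10.0), cfg)
        assert len(flags) == 1
        assert flags[0].evidence == pytest.approx(10.0, abs=0.5)


class TestOracleEquivalence:
    """Flag sets equal a pointwise-predicate + interval-merge recomputation."""

    @pytest.mark.parametrize("seed", range(10))
    def test_all_detectors_match_brute_force(self, seed):
        rng = np.random.default_rng(seed)
        rec = random_recording(rng)
        cfg = random_config(rng)
        smoothed = sk.smooth(sk.accel_magnitude(rec), cfg.smooth_window)
        assert sk.detect_fall(smoothed, cfg) == oracle_fall(
            smoothed.m, smoothed.t, cfg)
        baseline = sk.hr_baseline(rec, cfg)
        assert sk.detect_tachycardia(rec, baseline, cfg) == oracle_tachycardia(rec, cfg)
        assert sk.detect_desaturation(rec, cfg) == oracle_desaturation(rec, cfg)
        assert sk.detect_jerk(rec, cfg) == oracle_jerk(rec, cfg)
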