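"""Feature extraction: window stats, spectral indices, IMNF, normalization.

Spectral expectations are checked against independent oracles: closed
forms for tones, and brute-force cumulative-power summation over the
periodogram for band-limited noise.
"""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import signal

from armfatigue.features import (EMG_FEATURES, OFS_FEATURES,
                                 assemble_features,
                                 canonical_feature_names,
                                 is_frequency_feature, imnf,
                                 normalize_features, spectral_stats,
                                 window_stats)

RATE = 1024.0


def band_noise(lo, hi, duration=8.0, rate=RATE, seed=0):
    rng = np.random.default_rng(seed)
    sos = signal.butter(4, [lo, hi], btype="bandpass", fs=rate, output="sos")
    return signal.sosfiltfilt(sos, rng.standard_normal(int(duration * rate)))


class TestWindowStats:
    @pytest.mark.parametrize("segment, expected", [
        ([1, 1, 1, 1], (1.0, 0.0, 1.0, 0.0)),
        ([0, 2], (1.0, np.sqrt(2), np.sqrt(2), 2.0)),
    ])
    def test_hand_computed(self, segment, expected):
        mean, std, rms, amp = window_stats(segment)
        exp_mean, exp_std, exp_rms, exp_amp = expected
        assert mean == pytest.approx(exp_mean)
        assert std == pytest.approx(exp_std)
        assert rms == pytest.approx(exp_rms)
        assert amp == pytest.approx(exp_amp)

    def test_sine_rms(self):
        t = np.arange(int(RATE)) / RATE  # whole periods of 8 Hz
        _, _, rms, _ = window_stats(np.sin(2 * np.pi * 8 * t))
        assert rms == pytest.approx(1 / np.sqrt(2), rel=1e-3)

    def test_too_short_rejected(self):
        with pytest.raises(ValueError):
            window_stats([1.0])

    @given(st.lists(st.floats(-1e3, 1e3), min_size=2, max_size=50))
    @settings(max_examples=100, deadline=None)
    def test_power_decomposition(self, xs):
        mean, std, rms, _ = window_stats(xs)
        assert rms ** 2 >= mean ** 2 - 1e-6 * max(1.0, mean ** 2)


class TestSpectralStats:
    def test_pure_tone(self):
        t = np.arange(int(8 * RATE)) / RATE
        mnf, mdf = spectral_stats(np.sin(2 * np.pi * 64 * t), RATE)
        assert mnf == pytest.approx(64.0, abs=1.0)
        assert mdf == pytest.approx(64.0, abs=1.0)

    def test_two_equal_tones_mean(self):
        t = np.arange(int(8 * RATE)) / RATE
        x = np.sin(2 * np.pi * 10 * t) + np.sin(2 * np.pi * 30 * t)
        mnf, _ = spectral_stats(x, RATE)
        assert mnf == pytest.approx(20.0, abs=1.0)

    def test_flat_band_midpoint_against_bruteforce(self):
        x = band_noise(100, 200, duration=30.0)
        mnf, mdf = spectral_stats(x, RATE)
        # independent brute-force cumulative-power oracle
        freqs, power = signal.periodogram(x, fs=RATE, window="hann",
                                          detrend="constant")
        freqs, power = freqs[1:], power[1:]
        oracle_mnf = np.sum(freqs * power) / np.sum(power)
        cum = 0.0
        for f, p in zip(freqs, power):
            cum += p
            if cum >= power.sum() / 2:
                oracle_mdf = f
                break
        assert mnf == pytest.approx(oracle_mnf, rel=1e-9)
        assert mdf == pytest.approx(oracle_mdf, rel=1e-9)
        assert mnf == pytest.approx(150.0, rel=0.05)
        assert mdf == pytest.approx(150.0, rel=0.05)

    def test_mdf_halves_cumulative_power(self):
        x = band_noise(50, 300, duration=10.0, seed=3)
        _, mdf = spectral_stats(x, RATE)
        freqs, power = signal.periodogram(x, fs=RATE, window="hann",
                                          detrend="constant")
        below = power[1:][freqs[1:] < mdf].sum() / power[1:].sum()
        grid_step = power[1:].max() / power[1:].sum()
        assert 0.5 - grid_step <= below <= 0.5

    def test_zero_segment_rejected(self):
        with pytest.raises(ValueError):
            spectral_stats(np.zeros(64), RATE)


class TestImnf:
    def test_stationary_tone(self):
        t = np.arange(int(4 * RATE)) / RATE
        est = imnf(np.sin(2 * np.pi * 100 * t), RATE, fmin=8.0)
        assert est == pytest.approx(100.0, rel=0.05)

    def test_chirp_time_average(self):
        t = np.arange(int(8 * RATE)) / RATE
        x = signal.chirp(t, f0=50, t1=t[-1], f1=150)
        est = imnf(x, RATE, fmin=8.0)
        assert est == pytest.approx(100.0, rel=0.10)

    def test_matches_mnf_for_stationary_noise(self):
        x = band_noise(60, 180, duration=8.0, seed=2)
        est = imnf(x, RATE, fmin=8.0)
        mnf, _ = spectral_stats(x, RATE)
        assert est == pytest.approx(mnf, rel=0.10)

    def test_short_or_silent_segment_rejected(self):
        with pytest.raises(ValueError):
            imnf(np.zeros(16), RATE)
        with pytest.raises(ValueError):
            imnf(np.zeros(64), RATE)


def _segments(rng, fs_imu=128.0, fs_ofs=100.0, duration=3.0):
    n_imu, n_ofs, n_emg = (int(duration * f) for f in (fs_imu, fs_ofs, RATE))
    channels = ("GyroX", "GyroY", "GyroZ", "AccX", "AccY", "AccZ")
    imu = lambda: pd.DataFrame(
        {ch: rng.normal(0, 1, n_imu) for ch in channels})
    t = np.arange(n_ofs) / fs_ofs
    return {
        "imu1": imu(), "imu2": imu(),
        "angle": 70 - 55 * np.cos(2 * np.pi * t / duration),
        "emg_bp": band_noise(60, 120, duration=duration, seed=1),
        "emg_env": np.abs(rng.normal(2, 0.5, n_emg)),
        "duration": duration,
    }


RATES = {"angle": 100.0, "emg": RATE, "imu1": 128.0, "imu2": 128.0}


class TestAssembleFeatures:
    rng = np.random.default_rng(7)

    @pytest.mark.parametrize("sensors, count", [
        (("imu1", "imu2", "ofs", "emg"), 63),
        (("emg",), 7),
        (("ofs",), 8),
        (("imu1",), 24),
        (("imu2",), 24),
        (("imu1", "imu2"), 48),
        (("imu1", "imu2", "ofs"), 56),
    ])
    def test_feature_counts(self, sensors, count):
        feats = assemble_features(_segments(self.rng), RATES, sensors)
        assert len(feats) == count
        assert list(feats) == canonical_feature_names(sensors)
        assert all(np.isfinite(v) for v in feats.values())

    def test_missing_sensor_rejected(self):
        segs = _segments(self.rng)
        del segs["emg_bp"]
        with pytest.raises(KeyError):
            assemble_features(segs, RATES, ("emg",))

    def test_ofs_rom_and_duration(self):
        segs = _segments(self.rng)
        feats = assemble_features(segs, RATES, ("ofs",))
        assert feats["FIB_ROM"] == pytest.approx(110.0, rel=0.01)
        assert feats["FIB_tnorm"] == 3.0


class TestNormalizeFeatures:
    def _table(self):
        names = canonical_feature_names()
        rng = np.random.default_rng(5)
        rows = []
        for sid in ("A", "B"):
            for cycle in range(4):
                feats = dict(zip(names, rng.uniform(0.5, 2.0, len(names))))
                rows.append({"subject_id": sid, "cycle": cycle,
                             "borg": float(cycle), "state": "LF", **feats})
        return pd.DataFrame(rows)

    def test_first_cycle_maps_to_one(self):
        out = normalize_features(self._table())
        firsts = out.groupby("subject_id").first()
        for col in canonical_feature_names():
            if not is_frequency_feature(col):
                assert np.allclose(firsts[col], 1.0)

    def test_frequency_features_unchanged(self):
        table = self._table()
        out = normalize_features(table)
        freq_cols = [c for c in canonical_feature_names()
                     if is_frequency_feature(c)]
        assert len(freq_cols) == 6  # FIB and EMG MNF/MDF/IMNF
        merged = out.sort_values(["subject_id", "cycle"]).reset_index()
        orig = table.sort_values(["subject_id", "cycle"]).reset_index()
        assert np.allclose(merged[freq_cols], orig[freq_cols])

    def test_simple_ratio(self):
        table = self._table()
        col = "EMG_mean"
        sub = table[table["subject_id"] == "A"].sort_values("cycle")
        expected = sub[col].iloc[2] / sub[col].iloc[0]
        out = normalize_features(table)
        got = out[(out["subject_id"] == "A")
                  & (out["cycle"] == 2)][col].iloc[0]
        assert got == pytest.approx(expected)

    def test_zero_first_cycle_named_in_error(self):
        table = self._table()
        table.loc[table.index[0], "EMG_std"] = 0.0
        with pytest.raises(ValueError, match="EMG_std"):
            normalize_features(table)
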