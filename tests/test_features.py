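import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import signal as sps

from pacpredict import PacSpec, generate_pac_signal
from pacpredict.features import (
    AmplitudeDistribution,
    FeatureConfig,
    PhaseAmpPair,
    amplitude_distribution,
    amplitude_envelope,
    band_pairs,
    build_feature_table,
    comodulogram,
    instantaneous_phase,
    mi_surrogate_null,
    modulation_index,
    spectral_features,
)
from pacpredict.preprocess import Band, canonical_bands
from pacpredict.segmentation import Window, WindowSet
from pacpredict.synthetic import Recording

FS = 512
N_BINS = 18


def brute_force_distribution(phase, amplitude, n_bins=N_BINS):
    """Per-sample loop oracle for the phase-binned amplitude distribution."""
    sums = [0.0] * n_bins
    counts = [0] * n_bins
    width = 360.0 / n_bins
    for ph, a in zip(phase.tolist(), amplitude.tolist()):
        j = int((ph + 180.0) // width)
        if j == n_bins:
            j = n_bins - 1
        sums[j] += a
        counts[j] += 1
    means = [s / c if c else 0.0 for s, c in zip(sums, counts)]
    total = sum(means)
    return [m / total for m in means]


def brute_force_mi(p):
    entropy = -sum(pi * math.log(pi) for pi in p if pi > 0)
    return (math.log(len(p)) - entropy) / math.log(len(p))


class TestPhase:
    def test_phase_slope_six_cycles_per_second(self):
        t = np.arange(0, 10, 1 / FS)
        phase = instantaneous_phase(np.sin(2 * np.pi * 6 * t))
        unwrapped = np.unwrap(np.radians(phase))
        sl = slice(FS, -FS)
        slope = np.polyfit(t[sl], unwrapped[sl], 1)[0] / (2 * np.pi)
        assert slope == pytest.approx(6.0, rel=0.01)

    def test_quadrature_offset(self):
        t = np.arange(0, 10, 1 / FS)
        pc = instantaneous_phase(np.cos(2 * np.pi * 6 * t))
        ps = instantaneous_phase(np.sin(2 * np.pi * 6 * t))
        diff = np.angle(np.exp(1j * np.radians(pc - ps)), deg=True)
        sl = slice(FS, -FS)
        assert np.allclose(diff[sl], 90.0, atol=1.0)

    def test_pure_tone_phase_histogram_uniform(self):
        t = np.arange(0, 30, 1 / FS)
        phase = instantaneous_phase(np.sin(2 * np.pi * 6 * t))
        idx = np.floor((phase + 180) / 20).astype(int)
        idx[idx == N_BINS] = N_BINS - 1
        frac = np.bincount(idx, minlength=N_BINS) / len(phase)
        assert np.abs(frac - 1 / N_BINS).max() < 0.02

    def test_zero_signal_rejected(self):
        with pytest.raises(ValueError):
            instantaneous_phase(np.zeros(100))


class TestEnvelope:
    def test_constant_tone_envelope(self):
        t = np.arange(0, 10, 1 / FS)
        env = amplitude_envelope(3.0 * np.sin(2 * np.pi * 60 * t))
        edge = int(0.05 * len(env))
        assert env[edge:-edge].mean() == pytest.approx(3.0, rel=0.01)

    def test_chirp_modulator_recovered(self):
        t = np.arange(0, 10, 1 / FS)
        modulator = 1 + 0.5 * np.sin(2 * np.pi * 6 * t)
        x = sps.chirp(t, 40, 10, 80) * modulator
        env = amplitude_envelope(x)
        sl = slice(FS // 2, -FS // 2)
        assert np.corrcoef(env[sl], modulator[sl])[0, 1] > 0.95

    def test_zero_signal_zero_envelope(self):
        np.testing.assert_array_equal(amplitude_envelope(np.zeros(64)), np.zeros(64))


class TestAmplitudeDistribution:
    def test_uniform(self):
        phase = np.linspace(-179.99, 179.99, N_BINS * 500)
        dist = amplitude_distribution(phase, np.ones_like(phase))
        np.testing.assert_allclose(dist.p, 1 / N_BINS, atol=1e-12)

    def test_concentrated_in_one_bin(self):
        phase = np.linspace(-179.0, 179.0, 3600)
        amp = np.where((phase >= -80) & (phase < -60), 1.0, 0.0)  # bin 5 (0-based)
        dist = amplitude_distribution(phase, amp)
        assert dist.p[5] == 1.0
        assert dist.p.sum() == pytest.approx(1.0, abs=1e-12)

    def test_matches_brute_force_oracle(self, rng):
        phase = rng.uniform(-180, 180, 1000)
        amp = rng.lognormal(0, 1, 1000)
        dist = amplitude_distribution(phase, amp)
        np.testing.assert_allclose(dist.p, brute_force_distribution(phase, amp), atol=1e-12)

    def test_plus_180_maps_to_last_bin(self):
        dist = amplitude_distribution(np.array([180.0, -180.0]), np.array([1.0, 1.0]))
        assert dist.p[-1] == 0.5 and dist.p[0] == 0.5

    def test_all_zero_amplitude_rejected(self):
        with pytest.raises(ValueError):
            amplitude_distribution(np.zeros(10), np.zeros(10))

    def test_validation(self):
        AmplitudeDistribution(p=np.full(17, 1 / 17), n_bins=17)  # custom bin count OK
        with pytest.raises(ValueError):
            AmplitudeDistribution(p=np.full(18, 1.0))  # does not sum to 1
        with pytest.raises(ValueError):
            AmplitudeDistribution(p=np.full(10, 0.1))  # wrong length for default bins


class TestModulationIndex:
    def test_uniform_is_exactly_zero(self):
        assert modulation_index(np.full(N_BINS, 1.0 / N_BINS)) == 0.0

    def test_one_hot_is_exactly_one(self):
        assert modulation_index(np.eye(N_BINS)[4]) == 1.0

    def test_half_half_closed_form(self):
        p = np.zeros(N_BINS)
        p[0] = p[1] = 0.5
        expected = 1 - math.log(2) / math.log(18)
        assert modulation_index(p) == pytest.approx(expected, abs=1e-12)

    def test_log_base_invariance(self):
        p = np.array([0.3, 0.2, 0.1] + [0.4 / 15] * 15)
        base10 = (math.log10(N_BINS) + sum(pi * math.log10(pi) for pi in p)) / math.log10(
            N_BINS
        )
        assert modulation_index(p) == pytest.approx(base10, abs=1e-12)

    @given(st.integers(0, 2**32 - 1))
    @settings(max_examples=50, deadline=None)
    def test_bounds_fuzz(self, seed):
        p = np.random.default_rng(seed).dirichlet(np.ones(N_BINS))
        assert 0.0 <= modulation_index(p) <= 1.0

    @given(st.floats(min_value=1e-6, max_value=1e6))
    @settings(max_examples=30, deadline=None)
    def test_amplitude_scale_invariance(self, scale):
        rng = np.random.default_rng(9)
        phase = rng.uniform(-180, 180, 2000)
        amp = rng.lognormal(0, 1, 2000)
        a = modulation_index(amplitude_distribution(phase, amp))
        b = modulation_index(amplitude_distribution(phase, scale * amp))
        assert a == pytest.approx(b, abs=1e-12)

    def test_oracle_equivalence_on_random_series(self, rng):
        for _ in range(10):
            phase = rng.uniform(-180, 180, 1920)
            amp = np.abs(rng.standard_normal(1920)) + 1e-3
            dist = amplitude_distribution(phase, amp)
            oracle_p = brute_force_distribution(phase, amp)
            np.testing.assert_allclose(dist.p, oracle_p, atol=1e-12)
            assert modulation_index(dist) == pytest.approx(
                brute_force_mi(oracle_p), abs=1e-12
            )


class TestComodulogram:
    def test_coupled_pair_is_argmax(self):
        x = generate_pac_signal(PacSpec(6, 60, 0.8), 30, 256, noise_sd=0.3, seed=1)
        cm = comodulogram(x, 256)
        assert max(cm, key=cm.get) == "theta_gamma"

    def test_chi_ordering(self):
        lo = generate_pac_signal(PacSpec(6, 60, 0.0), 30, 256, noise_sd=0.2, seed=2)
        hi = generate_pac_signal(PacSpec(6, 60, 0.8), 30, 256, noise_sd=0.2, seed=2)
        assert comodulogram(lo, 256)["theta_gamma"] < comodulogram(hi, 256)["theta_gamma"]

    def test_invalid_pair_rejected(self):
        with pytest.raises(ValueError, match="strictly above"):
            PhaseAmpPair(Band("gamma", 30, 80), Band("theta", 4, 8))

    def test_pair_enumeration(self):
        pairs = band_pairs(canonical_bands(512, exclude_delta=True))
        names = [p.name for p in pairs]
        assert names == [
            "theta_alpha",
            "theta_beta",
            "theta_gamma",
            "alpha_beta",
            "alpha_gamma",
            "beta_gamma",
        ]

    def test_white_noise_not_significant(self, rng):
        # per-trial: observed theta-gamma MI below the 95th percentile of its
        # own 200-shift surrogate null in >= 90% of trials
        fs, wins, n_trials = 128, 0, 20
        theta, gamma = Band("theta", 4, 8), Band("gamma", 30, 57.6)
        from pacpredict.preprocess import bandpass

        for s in range(n_trials):
            x = rng.standard_normal(30 * fs)
            phase = instantaneous_phase(bandpass(x, fs, theta))
            env = amplitude_envelope(bandpass(x, fs, gamma))
            mi = modulation_index(amplitude_distribution(phase, env))
            null = mi_surrogate_null(phase, env, n_perm=200, seed=s)
            wins += np.quantile(null, 0.95) > mi
        assert wins >= 0.9 * n_trials


class TestSpectralFeatures:
    def test_pure_tone_peak(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 10 * t)
        peak, _ = spectral_features(x, FS, Band("alpha", 8, 13))
        assert peak == pytest.approx(10.0, abs=0.5)

    def test_two_tone_median_between(self):
        t = np.arange(0, 30, 1 / FS)
        x = np.sin(2 * np.pi * 35 * t) + np.sin(2 * np.pi * 75 * t)
        _, median = spectral_features(x, FS, Band("gamma", 30, 80))
        assert 35.0 <= median <= 75.0

    def test_median_matches_periodogram_oracle(self, rng):
        from pacpredict.preprocess import bandpass

        band = Band("beta", 13, 30)
        x = rng.standard_normal(30 * FS)
        _, median = spectral_features(x, FS, band)
        y = bandpass(x, FS, band)
        f, p = sps.periodogram(y, FS)
        m = (f >= band.lo) & (f <= band.hi)
        cum = np.cumsum(p[m])
        oracle = f[m][np.searchsorted(cum, cum[-1] / 2)]
        assert abs(median - oracle) <= 1.0

    def test_frequencies_within_band(self, rng):
        band = Band("alpha", 8, 13)
        peak, median = spectral_features(rng.standard_normal(30 * FS), FS, band)
        assert band.lo <= peak <= band.hi
        assert band.lo <= median <= band.hi

    def test_window_too_short(self):
        with pytest.raises(ValueError, match="short"):
            spectral_features(np.random.default_rng(0).standard_normal(600), FS, Band("alpha", 8, 13))


class TestBuildFeatureTable:
    def _recording(self, n_channels=4, duration=400, fs=128, seed=0):
        rng = np.random.default_rng(seed)
        return Recording(
            signal=rng.standard_normal((n_channels, int(duration * fs))),
            fs=fs,
            channel_names=[f"CH{i + 1:02d}" for i in range(n_channels)],
        )

    def _windows(self, n=10):
        wins = [Window(50.0 + 15 * i, "interictal", 0) for i in range(n)]
        return WindowSet(windows=wins, window_s=30.0)

    def test_mi_only_shape(self):
        rec = self._recording()
        table = build_feature_table(
            rec, self._windows(), FeatureConfig(feature_set="pac", exclude_delta=True)
        )
        mi_cols = [c for c in table.columns if c.startswith("mi_")]
        assert len(table) == 40  # 10 windows x 4 channels
        assert len(mi_cols) == 6

    def test_spectral_only_columns(self):
        rec = self._recording(n_channels=1)
        table = build_feature_table(
            rec, self._windows(3), FeatureConfig(feature_set="spectral")
        )
        feat = [c for c in table.columns if c.startswith(("peak_", "median_"))]
        assert len(feat) == 10  # 2 per band x 5 bands

    def test_empty_window_set(self):
        rec = self._recording(n_channels=1)
        table = build_feature_table(rec, WindowSet(windows=[], window_s=30.0))
        assert table.empty

    def test_out_of_range_window_skipped(self):
        rec = self._recording(n_channels=1, duration=100)
        wins = WindowSet(
            windows=[Window(50.0, "interictal", 0), Window(90.0, "interictal", 0)],
            window_s=30.0,
        )
        table = build_feature_table(rec, wins, FeatureConfig(feature_set="pac"))
        assert list(table["window_start"]) == [50.0]

    def test_pair_subset(self):
        rec = self._recording(n_channels=1)
        table = build_feature_table(
            rec,
            self._windows(2),
            FeatureConfig(feature_set="pac", pairs=(("beta", "gamma"),)),
        )
        assert [c for c in table.columns if c.startswith("mi_")] == ["mi_beta_gamma"]

    def test_metadata_carried_through(self):
        rec = self._recording(n_channels=2)
        wins = WindowSet(windows=[Window(60.0, "preictal", 3)], window_s=30.0)
        table = build_feature_table(rec, wins, FeatureConfig(feature_set="pac"))
        assert set(table["label"]) == {"preictal"}
        assert set(table["seizure_id"]) == {3}
        assert sorted(table["channel"]) == ["CH01", "CH02"]
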