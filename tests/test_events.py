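"""LFP preprocessing and oscillation-event detection."""

import numpy as np
import pytest
from scipy import signal

from oscmem import synthetic as sd
from oscmem.events import (
    BandEventParams,
    EpochMap,
    LfpSignal,
    RippleParams,
    bandpass,
    concat_state_epochs,
    detect_band_events,
    detect_ripples,
    downsample_lfp,
    event_features,
    so_phase_at,
)
from oscmem.exceptions import ArgumentError, FeatureError
from oscmem.sleep import Hypnogram


def nrem_hypnogram(seconds):
    return Hypnogram(np.repeat("NREM", int(seconds)))


class TestDownsample:
    def test_decimation_ratio(self):
        raw = LfpSignal(np.zeros(30000), 30000, region="HPC")
        out = downsample_lfp(raw)
        assert out.n_samples == 1000 and out.rate_hz == 1000

    def test_passband_sinusoid_preserved(self):
        t = np.arange(0, 2.0, 1 / 30000)
        raw = LfpSignal(np.sin(2 * np.pi * 100 * t), 30000)
        out = downsample_lfp(raw)
        # amplitude from RMS (max-of-samples underestimates at 10/cycle)
        amp = np.sqrt(2) * np.std(out.samples[200:-200])
        assert amp == pytest.approx(1.0, rel=0.01)

    def test_800hz_component_attenuated(self):
        t = np.arange(0, 2.0, 1 / 30000)
        raw = LfpSignal(np.sin(2 * np.pi * 800 * t), 30000)
        out = downsample_lfp(raw)
        # > 20 dB attenuation: amplitude below 0.1
        assert np.abs(out.samples[500:-500]).max() < 0.1

    def test_wrong_rate_rejected(self):
        with pytest.raises(ArgumentError):
            downsample_lfp(LfpSignal(np.zeros(1000), 1000))


class TestConcat:
    def test_all_nrem_is_identity(self):
        rng = np.random.default_rng(0)
        lfp = LfpSignal(rng.standard_normal(5000), 1000)
        concat, emap = concat_state_epochs(lfp, nrem_hypnogram(5))
        assert np.array_equal(concat.samples, lfp.samples)
        assert emap.total_s == 5.0

    def test_roundtrip_bijection(self, rng):
        labels = np.array(["WAKE"] * 10 + ["NREM"] * 20 + ["REM"] * 5
                          + ["NREM"] * 15)
        hyp = Hypnogram(labels)
        lfp = LfpSignal(rng.standard_normal(50 * 1000), 1000)
        _, emap = concat_state_epochs(lfp, hyp)
        for _ in range(1000):
            seg = emap.segments[int(rng.integers(len(emap.segments)))]
            t = float(rng.uniform(seg[0], seg[1] - 1e-9))
            assert emap.to_original(emap.to_concat(t)) == pytest.approx(t)

    def test_concat_length_is_sum_of_epochs(self, rng):
        labels = np.array(["NREM", "WAKE", "NREM", "NREM", "REM", "NREM"])
        lfp = LfpSignal(rng.standard_normal(6000), 1000)
        concat, _ = concat_state_epochs(lfp, Hypnogram(labels))
        assert concat.n_samples == 4000

    def test_no_epochs_yields_empty(self):
        lfp = LfpSignal(np.zeros(3000), 1000)
        concat, emap = concat_state_epochs(lfp, Hypnogram(np.repeat("WAKE", 3)))
        assert concat.n_samples == 0 and emap.segments == []


def inject_burst(samples, fs, peak_s, freq, dur, amp):
    from scipy.signal.windows import hann

    n = int(round(dur * fs))
    t = np.arange(n) / fs
    i0 = int(round((peak_s - dur / 2) * fs))
    samples[i0 : i0 + n] += amp * hann(n) * np.sin(2 * np.pi * freq * t)


class TestRippleDetection:
    def test_zero_signal_zero_events(self):
        lfp = LfpSignal(np.zeros(60_000), 1000, region="HPC")
        assert detect_ripples(lfp, nrem_hypnogram(60)) == []

    def test_single_burst_recovered_with_timing(self):
        fs = 1000.0
        x = np.zeros(60_000)
        inject_burst(x, fs, 30.0, 150.0, 0.06, 80.0)
        lfp = LfpSignal(x, fs, region="HPC")
        # zero noise: threshold = 5*SD of the sparse burst + 5 uV
        events = detect_ripples(lfp, nrem_hypnogram(60))
        assert len(events) == 1
        ev = events[0]
        assert abs(ev.peak_s - 30.0) <= 0.010
        assert 100.0 <= ev.mean_freq_hz <= 300.0
        assert ev.start_s < 30.0 < ev.end_s
        # boundaries near analytic half-threshold crossings of the taper
        filt = bandpass(x, (100, 300), fs)
        thr = 5 * np.std(filt) + 5.0
        env = 80.0  # peak envelope
        # hann envelope = sin^2(pi t / d); solve for half-threshold crossing
        frac = (thr / 2) / env
        t_in = 0.06 * np.arcsin(np.sqrt(frac)) / np.pi
        assert ev.start_s == pytest.approx(30.0 - 0.03 + t_in, abs=0.005)
        assert ev.end_s == pytest.approx(30.0 + 0.03 - t_in, abs=0.005)

    def test_short_burst_fails_30ms_rule(self):
        fs = 1000.0
        x = np.zeros(60_000)
        inject_burst(x, fs, 30.0, 150.0, 0.020, 80.0)
        lfp = LfpSignal(x, fs, region="HPC")
        assert detect_ripples(lfp, nrem_hypnogram(60)) == []

    def test_translation_equivariance(self):
        fs = 1000.0
        rng = np.random.default_rng(5)
        x = rng.standard_normal(40_000) * 2
        inject_burst(x, fs, 20.0, 180.0, 0.08, 120.0)
        shift = 700  # samples
        lfp_a = LfpSignal(x[: -shift], fs, region="HPC")
        lfp_b = LfpSignal(np.concatenate([np.zeros(shift) + x[:shift] * 0, x[: -shift]]), fs, region="HPC")
        ev_a = detect_ripples(lfp_a, nrem_hypnogram(len(lfp_a.samples) / fs))
        ev_b = detect_ripples(lfp_b, nrem_hypnogram(len(lfp_b.samples) / fs))
        peaks_a = [e.peak_s for e in ev_a if abs(e.peak_s - 20.0) < 0.5]
        peaks_b = [e.peak_s for e in ev_b if abs(e.peak_s - 20.7) < 0.5]
        assert len(peaks_a) == len(peaks_b) == 1
        assert peaks_b[0] - peaks_a[0] == pytest.approx(shift / fs, abs=0.002)

    def test_events_lie_inside_nrem_and_are_ordered(self):
        hyp = sd.gen_hypnogram(
            900, {"WAKE": 100, "NREM": 200, "REM": 60, "INT": 10}, seed=3
        )
        spec = sd.EventSpec(
            rate_per_min={"ripple": 10, "spindle": 0, "delta": 0},
            amplitude_uv={"ripple": (120, 200), "spindle": (60, 120),
                          "delta": (80, 160)},
        )
        _, hpc, _ = sd.gen_lfp(hyp, spec, sd.NoiseSpec(), seed=3)
        events = detect_ripples(hpc, hyp)
        assert events, "expected detections on a strong-SNR fixture"
        for ev in events:
            assert ev.start_s < ev.peak_s < ev.end_s
            assert hyp.state_at(ev.peak_s) == "NREM"


class TestBandEvents:
    def test_infinite_threshold_zero_events(self):
        rng = np.random.default_rng(1)
        lfp = LfpSignal(rng.standard_normal(120_000), 1000)
        p = BandEventParams.for_kind("spindle", z_threshold=np.inf)
        assert detect_band_events(lfp, nrem_hypnogram(120), "spindle", p) == []

    def test_injected_spindle_recovered(self):
        fs = 1000.0
        rng = np.random.default_rng(2)
        x = rng.standard_normal(120_000) * 3
        inject_burst(x, fs, 60.0, 12.0, 0.8, 80.0)
        lfp = LfpSignal(x, fs, region="PFC")
        events = detect_band_events(lfp, nrem_hypnogram(120), "spindle")
        assert len(events) == 1
        assert abs(events[0].peak_s - 60.0) <= 0.025
        assert 9.0 <= events[0].mean_freq_hz <= 20.0

    def test_injected_delta_recovered_in_band(self):
        fs = 1000.0
        rng = np.random.default_rng(4)
        x = rng.standard_normal(120_000) * 3
        inject_burst(x, fs, 60.0, 2.0, 0.5, 150.0)
        lfp = LfpSignal(x, fs, region="PFC")
        events = detect_band_events(lfp, nrem_hypnogram(120), "delta")
        assert len(events) == 1
        assert 1.0 <= events[0].mean_freq_hz <= 6.0

    def test_unknown_kind_rejected(self):
        lfp = LfpSignal(np.zeros(5000), 1000)
        with pytest.raises(ArgumentError):
            detect_band_events(lfp, nrem_hypnogram(5), "gamma")


class TestEventFeatures:
    def test_pure_sinusoid(self):
        fs = 1000.0
        t = np.arange(0, 0.5, 1 / fs)
        amp, mf = event_features(40.0 * np.sin(2 * np.pi * 150 * t), fs)
        assert amp == pytest.approx(40.0, abs=1.0)
        assert mf == pytest.approx(150.0, abs=2.0)

    def test_amplitude_linearity_and_sign_invariance(self):
        fs = 1000.0
        t = np.arange(0, 0.3, 1 / fs)
        x = 10.0 * np.sin(2 * np.pi * 120 * t)
        a1, _ = event_features(x, fs)
        a2, _ = event_features(2 * x, fs)
        a3, _ = event_features(-x, fs)
        assert a2 == pytest.approx(2 * a1)
        assert a3 == pytest.approx(a1)

    def test_mean_freq_of_equal_power_mix(self):
        fs = 1000.0
        t = np.arange(0, 1.0, 1 / fs)
        x = np.sin(2 * np.pi * 120 * t) + np.sin(2 * np.pi * 180 * t)
        _, mf = event_features(x, fs)
        assert mf == pytest.approx(150.0, abs=3.0)

    def test_zero_segment_rejected(self):
        with pytest.raises(FeatureError):
            event_features(np.zeros(100), 1000.0)


class TestSoPhase:
    def test_peak_and_trough_convention(self):
        fs = 1000.0
        t = np.arange(0, 30.0, 1 / fs)
        lfp = LfpSignal(np.cos(2 * np.pi * 1.0 * t), fs, region="PFC")
        peaks = np.arange(5.0, 25.0, 1.0)  # cosine peaks at integer seconds
        troughs = peaks + 0.5
        ph_peak = so_phase_at(lfp, peaks)
        ph_trough = so_phase_at(lfp, troughs)
        assert np.all(np.minimum(ph_peak, 360 - ph_peak) <= 2.0)
        assert np.all(np.abs(ph_trough - 180.0) <= 2.0)

    def test_uniform_timestamps_give_uniform_phases(self):
        from scipy.stats import circmean

        fs = 250.0
        t = np.arange(0, 120.0, 1 / fs)
        lfp = LfpSignal(np.cos(2 * np.pi * 1.3 * t), fs, region="PFC")
        nonsig = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            ts = rng.uniform(5.0, 115.0, 400)
            ph = np.deg2rad(so_phase_at(lfp, ts))
            n = ph.size
            r = np.abs(np.mean(np.exp(1j * ph)))
            # Rayleigh test
            z = n * r**2
            p = np.exp(-z) * (
                1 + (2 * z - z**2) / (4 * n)
            )
            nonsig += p > 0.01
        assert nonsig >= 45

    def test_out_of_span_timestamp_rejected(self):
        lfp = LfpSignal(np.zeros(1000) + np.sin(np.arange(1000)), 1000)
        with pytest.raises(ArgumentError):
            so_phase_at(lfp, np.array([2.0]))
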