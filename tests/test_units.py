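"""Waveform features, cell typing, firing rates, ON/OFF, ripple responses."""

import numpy as np
import pytest

from conftest import brute_force_on_off
from oscmem import synthetic as sd
from oscmem.exceptions import ArgumentError, FeatureError
from oscmem.sleep import Hypnogram
from oscmem.units import (
    CellTypeClassifier,
    classify_cell_types,
    detect_on_off,
    matlab_smooth,
    quantile_groups,
    ripple_peth,
    ripple_response,
    state_firing_rate,
    waveform_features,
)


class TestWaveformFeatures:
    def test_sample_arithmetic_delay(self):
        w = np.zeros(82)
        w[40] = -100.0
        w[52] = 30.0
        f = waveform_features(w)
        assert f.trough_to_peak_ms == pytest.approx(12 / 30)

    def test_scale_invariance(self):
        w = sd.gen_waveform(0.6, 0.3)
        f1 = waveform_features(w)
        f2 = waveform_features(2 * w)
        assert f1.trough_to_peak_ms == f2.trough_to_peak_ms
        assert f1.spike_width_ms == pytest.approx(f2.spike_width_ms)

    def test_constructed_half_depth_width(self):
        # triangle trough: half-depth crossings exactly 4.5 samples either
        # side of the trough -> width 9 samples = 0.3 ms
        w = np.zeros(82)
        for k in range(10):
            w[40 - k] = w[40 + k] = -90.0 + 10.0 * k
        w[55] = 20.0
        f = waveform_features(w)
        assert f.spike_width_ms == pytest.approx(9 / 30, abs=1e-6)

    def test_flat_waveform_rejected(self):
        with pytest.raises(FeatureError):
            waveform_features(np.zeros(82))

    def test_wrong_length_rejected(self):
        with pytest.raises(ArgumentError):
            waveform_features(np.zeros(50))


def two_cluster_features(rng, n=100, sep=6.0):
    """Two Gaussian clusters separated by `sep` SDs on both axes."""
    sd_ = 0.03
    pyr = rng.normal([0.65, 0.40], sd_, size=(n, 2))
    inter = rng.normal([0.65 - sep * sd_, 0.40 - sep * sd_], sd_, size=(n, 2))
    X = np.vstack([pyr, inter])
    y = np.array(["pyramidal"] * n + ["interneuron"] * n)
    return X, y


class TestCellClassification:
    def test_well_separated_clusters_recovered(self, rng):
        X, y = two_cluster_features(rng)
        labels, _ = classify_cell_types(X, seed=0)
        mask = labels != "outlier"
        acc = np.mean(labels[mask] == y[mask])
        assert acc >= 0.95

    def test_point_3sd_from_centroid_is_outlier(self, rng):
        X, _ = two_cluster_features(rng)
        clf = CellTypeClassifier(random_state=0).fit(X)
        mu = clf.centroids_["pyramidal"]
        sd_ = clf.sds_["pyramidal"]
        probe = mu + np.array([3.0 * sd_[0], 0.0])
        assert clf.predict(probe[None, :])[0] == "outlier"

    def test_permutation_invariance(self, rng):
        X, _ = two_cluster_features(rng, n=50)
        labels, _ = classify_cell_types(X, seed=0)
        perm = rng.permutation(X.shape[0])
        labels_p, _ = classify_cell_types(X[perm], seed=0)
        assert np.array_equal(labels_p, labels[perm])

    def test_stable_under_duplication(self, rng):
        X, _ = two_cluster_features(rng, n=40)
        labels, _ = classify_cell_types(X, seed=0)
        labels_dup, _ = classify_cell_types(np.vstack([X, X]), seed=0)
        assert np.array_equal(labels_dup[: X.shape[0]], labels)
        assert np.array_equal(labels_dup[X.shape[0]:], labels)

    def test_too_few_neurons_rejected(self):
        with pytest.raises(ArgumentError):
            CellTypeClassifier().fit(np.array([[0.5, 0.3], [0.2, 0.1]]))


class TestFiringRates:
    def test_arithmetic(self):
        hyp = Hypnogram(np.array(["NREM"] * 50 + ["WAKE"] * 50))
        spikes = np.linspace(0.1, 49.9, 100)
        assert state_firing_rate(spikes, hyp, "NREM") == pytest.approx(2.0)

    def test_spikes_only_in_wake_gives_zero_nrem_rate(self):
        hyp = Hypnogram(np.array(["NREM"] * 50 + ["WAKE"] * 50))
        spikes = np.linspace(50.5, 99.5, 40)
        assert state_firing_rate(spikes, hyp, "NREM") == 0.0

    def test_zero_state_time_undefined(self):
        hyp = Hypnogram(np.repeat("WAKE", 100))
        assert state_firing_rate(np.array([1.0]), hyp, "REM") is None

    def test_pooled_equals_duration_weighted_epoch_rates(self, rng):
        labels = np.array(["NREM", "WAKE"])[rng.integers(0, 2, 400)]
        hyp = Hypnogram(labels)
        spikes = np.sort(rng.uniform(0, 400, 900))
        pooled = state_firing_rate(spikes, hyp, "NREM")
        # oracle: per-epoch counts / total duration
        total_t = 0.0
        total_n = 0
        for st, a, b in hyp.runs():
            if st == "NREM":
                total_t += b - a
                total_n += np.sum((spikes >= a) & (spikes < b))
        assert pooled == pytest.approx(total_n / total_t)


class TestQuantileGroups:
    def test_reference_splits_evenly(self):
        ref, _, bounds = quantile_groups(np.arange(1.0, 101.0))
        counts = np.bincount(ref, minlength=6)[1:]
        assert list(counts) == [20] * 5
        assert np.allclose(bounds, [20.8, 40.6, 60.4, 80.2])

    def test_target_above_reference_max_in_top_group(self):
        _, tgt, _ = quantile_groups(np.arange(1.0, 101.0), np.array([500.0]))
        assert tgt[0] == 5

    def test_near_equal_group_sizes_on_random_samples(self, rng):
        for _ in range(100):
            ref = rng.uniform(0, 10, 100)
            labels, _, _ = quantile_groups(ref)
            counts = np.bincount(labels, minlength=6)[1:]
            assert np.all(np.abs(counts - 20) <= 1)

    def test_k_too_small_rejected(self):
        with pytest.raises(ArgumentError):
            quantile_groups(np.arange(10.0), k=1)


class TestOnOff:
    def make_trains(self, rng, n_neurons=8, dur=20.0, rate=6.0):
        return [np.sort(rng.uniform(0, dur, rng.poisson(rate * dur)))
                for _ in range(n_neurons)]

    def test_gap_becomes_off_period(self):
        trains = [np.array([0.1, 0.11, 0.12, 0.13, 0.14, 0.15, 0.16, 0.17,
                            0.18, 0.19, 0.25, 0.26, 0.27, 0.28, 0.29, 0.30,
                            0.31, 0.32, 0.33, 0.34])] * 7
        res = detect_on_off(trains, [(0.0, 1.0)])
        assert res.off[0] == [(0.19, 0.25)]
        assert len(res.on[0]) == 2

    def test_min_spike_rule(self):
        # a 100 ms run with 9 spikes is discarded
        run = np.linspace(0.0, 0.1, 9)
        trains = [run] + [np.array([])] * 6
        res = detect_on_off(trains, [(0.0, 1.0)])
        assert res.on[0] == []

    def test_max_duration_rule(self):
        run = np.linspace(0.0, 5.0, 200)  # 5 s of dense firing
        trains = [run] + [np.array([])] * 6
        res = detect_on_off(trains, [(0.0, 6.0)])
        assert res.on[0] == []

    def test_min_neuron_precondition(self):
        with pytest.raises(ArgumentError):
            detect_on_off([np.array([0.1])] * 3, [(0.0, 1.0)])

    def test_matches_isi_scan_oracle_on_random_trains(self, rng):
        for _ in range(100):
            trains = self.make_trains(rng)
            bout = (0.0, 20.0)
            with np.errstate(all="ignore"):
                res = detect_on_off(trains, [bout])
            mua = np.sort(np.concatenate(trains))
            ons, offs = brute_force_on_off(list(mua))
            assert res.off.get(0, []) == pytest.approx(offs)
            assert res.on.get(0, []) == pytest.approx(ons)

    def test_intervals_never_overlap_and_off_durations_exceed_gap(self, rng):
        trains = self.make_trains(rng, rate=10.0)
        res = detect_on_off(trains, [(0.0, 20.0)])
        ivals = sorted(res.on[0] + res.off[0])
        for (a0, a1), (b0, b1) in zip(ivals, ivals[1:]):
            assert a1 <= b0 + 1e-12
        for s, e in res.off[0]:
            assert e - s > 0.050


class TestRipplePeth:
    def test_bin_count_and_z_normalization(self, rng):
        trains = [np.sort(rng.uniform(0, 200, 800)) for _ in range(5)]
        peaks = np.arange(5.0, 195.0, 2.0)
        peth = ripple_peth(trains, peaks)
        assert peth.bin_centers.size == 200
        assert np.allclose(peth.per_neuron_z.mean(axis=1), 0.0, atol=1e-9)
        assert np.allclose(peth.per_neuron_z.std(axis=1), 1.0, atol=1e-9)

    def test_neuron_firing_at_peaks_has_max_at_zero_lag(self):
        peaks = np.arange(5.0, 95.0, 1.0)
        trains = [np.sort(peaks + 0.001)]
        peth = ripple_peth(trains, peaks, smooth_passes=0)
        assert abs(peth.bin_centers[np.argmax(peth.mean_z)]) <= 0.01

    def test_independent_poisson_stays_within_null_band(self):
        ok = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            trains = [np.sort(rng.uniform(0, 400, 2000))]
            peaks = np.sort(rng.uniform(2, 398, 150))
            peth = ripple_peth(trains, peaks, smooth_passes=0)
            ok += np.max(np.abs(peth.per_neuron_z)) <= 4.0
        assert ok >= 18

    def test_smoothing_is_matlab_style(self):
        y = np.array([1.0, 2.0, 6.0, 2.0, 1.0, 1.0])
        out = matlab_smooth(y, 5)
        assert out[0] == 1.0
        assert out[1] == pytest.approx(3.0)
        assert out[2] == pytest.approx(12 / 5)


class TestRippleResponse:
    @staticmethod
    def modulated_train(rng, peaks, base_rate, gain, dur):
        """Poisson spikes with a rate x gain during [-40, +40] ms windows."""
        n = rng.poisson(base_rate * dur * max(gain, 1.0) * 1.2)
        cand = np.sort(rng.uniform(0, dur, n))
        near = np.zeros(cand.size, dtype=bool)
        for p in peaks:
            near |= np.abs(cand - p) <= 0.04
        lam = np.where(near, base_rate * gain, base_rate)
        keep = rng.uniform(0, base_rate * max(gain, 1.0) * 1.2, cand.size) < lam
        return cand[keep]

    def test_doubled_rate_during_ripple_is_active(self):
        rng = np.random.default_rng(0)
        peaks = np.sort(rng.uniform(5, 495, 500))
        spikes = self.modulated_train(rng, peaks, 5.0, 3.0, 500.0)
        r = ripple_response(spikes, peaks, seed=1)
        assert r.label == "active"
        assert r.rates_hz["during"] > r.rates_hz["baseline"]

    def test_silenced_during_ripple_is_suppressed(self):
        rng = np.random.default_rng(1)
        peaks = np.sort(rng.uniform(5, 495, 500))
        spikes = self.modulated_train(rng, peaks, 5.0, 0.0, 500.0)
        r = ripple_response(spikes, peaks, seed=1)
        assert r.label == "suppressed"

    def test_homogeneous_poisson_mostly_neutral(self):
        neutral = 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            peaks = np.sort(rng.uniform(5, 295, 300))
            spikes = np.sort(rng.uniform(0, 300, 1500))
            r = ripple_response(spikes, peaks, seed=seed)
            neutral += r.label == "neutral"
        assert neutral >= 45

    def test_no_ripples_rejected(self):
        with pytest.raises(ArgumentError):
            ripple_response(np.array([1.0]), np.array([]))


class TestEndToEndModulation:
    def test_generator_gains_recovered_as_labels(self):
        truth = sd.GroundTruth()
        rng = np.random.default_rng(9)
        for t in np.sort(rng.uniform(5, 595, 500)):
            truth.injected_events.append(
                sd.InjectedEvent("ripple", float(t), 60.0, 150.0, 0.08, "HPC")
            )
        peaks = truth.peaks("ripple")
        trains, _, truths = sd.gen_spike_trains(
            20, 600.0, lognormal_rate_params=(np.log(5.0), 0.0),
            ripple_gain_by_group={"up": 3.0, "down": 0.2},
            ground_truth=truth, seed=9,
        )
        correct = 0
        total = 0
        for train, tr in zip(trains, truths):
            r = ripple_response(train, peaks, seed=1)
            total += 1
            if tr.ripple_gain > 1 and r.label == "active":
                correct += 1
            elif tr.ripple_gain < 1 and r.label == "suppressed":
                correct += 1
        assert correct / total >= 0.9
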