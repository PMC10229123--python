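"""Single-unit analyses: waveform features and cell-type classification,
state-restricted firing rates and quantile groups, NREM ON/OFF period
detection from multiunit activity, and ripple-centered firing analyses.

Cell typing follows the standard extracellular convention: the
trough-to-peak delay and spike width (full width at half trough depth) of
the mean waveform separate putative pyramidal cells (long delay/width)
from interneurons (short); a two-component Gaussian mixture finds the
clusters and points beyond 2 per-cluster SDs of their centroid are flagged
as outliers.

Ripple-centered firing uses 10 ms bins spanning -1 to +1 s around each
ripple peak (200 bins); per-neuron count vectors are z-normalized across
bins before averaging, then smoothed twice with a 5-point moving average.
The ripple response compares the during-ripple epoch [-40, +40) ms against
a bootstrap of the baseline epoch [-200, -120) ms to label each neuron
suppressed, neutral, or active.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, ClusterMixin
from sklearn.mixture import GaussianMixture

from .exceptions import ArgumentError, DataError, FeatureError
from .sleep import Hypnogram

WAVEFORM_SAMPLES = 82
WAVEFORM_FS = 30000.0
PRE_TROUGH_SAMPLES = 40  # 40 samples precede the spike timestamp, 41 follow

RIPPLE_EPOCHS = {
    "baseline": (-0.200, -0.120),
    "pre": (-0.120, -0.040),
    "during": (-0.040, 0.040),
    "post": (0.040, 0.120),
}

__all__ = [
    "WaveformFeatures",
    "OnOffPeriods",
    "RipplePeth",
    "RippleResponse",
    "waveform_features",
    "CellTypeClassifier",
    "classify_cell_types",
    "state_firing_rate",
    "quantile_groups",
    "detect_on_off",
    "ripple_peth",
    "ripple_response",
    "matlab_smooth",
]


@dataclass
class WaveformFeatures:
    trough_to_peak_ms: float
    spike_width_ms: float

    def as_array(self) -> np.ndarray:
        return np.array([self.trough_to_peak_ms, self.spike_width_ms])


def waveform_features(waveform: np.ndarray) -> WaveformFeatures:
    """Trough-to-peak delay and spike width of an 82-sample mean waveform.

    The trough is the global minimum (must be negative); the delay runs
    from the trough to the subsequent maximum; the width is the full width
    of the trough at half its depth, with linearly interpolated crossings.
    Times are in ms at 30 kHz (1 sample = 1/30 ms).
    """
    w = np.asarray(waveform, dtype=float)
    if w.size != WAVEFORM_SAMPLES:
        raise ArgumentError(f"waveform must have {WAVEFORM_SAMPLES} samples")
    trough = int(np.argmin(w))
    depth = w[trough]
    if depth >= 0 or trough >= w.size - 1:
        raise FeatureError("waveform has no usable negative trough")
    after = w[trough + 1 :]
    peak = trough + 1 + int(np.argmax(after))
    delay_ms = (peak - trough) / WAVEFORM_FS * 1000.0

    half = depth / 2.0  # negative level
    left = trough
    while left > 0 and w[left - 1] < half:
        left -= 1
    if left == 0 and w[0] < half:
        raise FeatureError("half-depth crossing missing on the left")
    right = trough
    while right < w.size - 1 and w[right + 1] < half:
        right += 1
    if right == w.size - 1 and w[-1] < half:
        raise FeatureError("half-depth crossing missing on the right")
    # linear interpolation to sub-sample crossings
    tl = left - 1 + (w[left - 1] - half) / (w[left - 1] - w[left]) if left > 0 else 0.0
    tr = right + (w[right] - half) / (w[right] - w[right + 1]) if right < w.size - 1 else float(right)
    width_ms = (tr - tl) / WAVEFORM_FS * 1000.0
    return WaveformFeatures(delay_ms, width_ms)


class CellTypeClassifier(BaseEstimator, ClusterMixin):
    """Pyramidal/interneuron classification of waveform features.

    A two-component Gaussian mixture is fitted on (trough-to-peak delay,
    spike width); the component whose centroid is larger on both axes is
    labeled pyramidal.  Points beyond ``outlier_sd`` per-cluster standard
    deviations of their centroid on any axis become outliers.
    Deterministic given ``random_state`` (k-means++ init, best of
    ``n_init`` restarts).

    Attributes
    ----------
    labels_ : ndarray of str
        "pyramidal", "interneuron" or "outlier" per input row.
    centroids_ : dict
        Component means keyed by class name.
    """

    def __init__(self, outlier_sd: float = 2.0, n_init: int = 10,
                 random_state: int = 0) -> None:
        self.outlier_sd = outlier_sd
        self.n_init = n_init
        self.random_state = random_state

    def fit(self, X, y=None):
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != 2:
            raise ArgumentError("X must be (n_neurons, 2) feature rows")
        if X.shape[0] < 4:
            raise ArgumentError("need at least 4 neurons to fit two clusters")
        gmm = GaussianMixture(
            n_components=2,
            covariance_type="diag",
            n_init=self.n_init,
            init_params="k-means++",
            random_state=self.random_state,
        )
        try:
            comp = gmm.fit_predict(X)
        except Exception as exc:  # degenerate covariance
            raise DataError(f"mixture fit failed: {exc}") from exc
        means = gmm.means_
        sds = np.sqrt(gmm.covariances_)
        # pyramidal cluster: high delay AND high width; fall back to the
        # mean-sum ordering if the axes disagree.
        if np.all(means[0] >= means[1]):
            pyr = 0
        elif np.all(means[1] >= means[0]):
            pyr = 1
        else:
            pyr = int(np.argmax(means.sum(axis=1)))
        names = {pyr: "pyramidal", 1 - pyr: "interneuron"}
        labels = np.empty(X.shape[0], dtype=object)
        for i, (row, c) in enumerate(zip(X, comp)):
            z = np.abs(row - means[c]) / np.maximum(sds[c], 1e-12)
            labels[i] = "outlier" if np.any(z > self.outlier_sd) else names[c]
        self.gmm_ = gmm
        self.component_of_ = comp
        self.component_names_ = names
        self.labels_ = labels.astype("U11")
        self.centroids_ = {names[c]: means[c].copy() for c in (0, 1)}
        self.sds_ = {names[c]: sds[c].copy() for c in (0, 1)}
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=float)
        comp = self.gmm_.predict(X)
        means = self.gmm_.means_
        sds = np.sqrt(self.gmm_.covariances_)
        out = np.empty(X.shape[0], dtype=object)
        for i, (row, c) in enumerate(zip(X, comp)):
            z = np.abs(row - means[c]) / np.maximum(sds[c], 1e-12)
            out[i] = (
                "outlier" if np.any(z > self.outlier_sd)
                else self.component_names_[c]
            )
        return out.astype("U11")


def classify_cell_types(
    features: np.ndarray, seed: int = 0, outlier_sd: float = 2.0
) -> tuple[np.ndarray, dict[str, np.ndarray]]:
    """Functional wrapper: labels and centroids from waveform features."""
    clf = CellTypeClassifier(outlier_sd=outlier_sd, random_state=seed).fit(features)
    return clf.labels_, clf.centroids_


def state_firing_rate(
    spikes: np.ndarray, hypnogram: Hypnogram, state: str
) -> float | None:
    """Firing rate in a state: spikes in state epochs / seconds in state.

    Pools every epoch of the state across the recording.  Returns ``None``
    (undefined, not zero) when no time was spent in the state.
    """
    spikes = np.asarray(spikes, dtype=float)
    labels = hypnogram.labels
    seconds = float(np.count_nonzero(labels == state))
    if seconds == 0:
        return None
    if spikes.size:
        idx = np.floor(spikes - hypnogram.t0_s).astype(int)
        if idx.min() < 0 or idx.max() >= labels.size:
            raise ArgumentError("spike outside the hypnogram span")
        count = int(np.count_nonzero(labels[idx] == state))
    else:
        count = 0
    return count / seconds


def quantile_groups(
    reference_rates: np.ndarray,
    target_rates: np.ndarray | None = None,
    k: int = 5,
) -> tuple[np.ndarray, np.ndarray | None, np.ndarray]:
    """Quantile group labels (1..k) from reference-derived boundaries.

    Boundaries are the reference 20/40/60/80-percentiles (for k = 5); both
    sets are labeled with them, boundary values inclusive in the lower
    group (the reference upper limits act as thresholds).  Target values
    above the reference maximum fall in group k.

    Returns (reference_labels, target_labels, boundaries).
    """
    if k < 2:
        raise ArgumentError("k must be at least 2")
    ref = np.asarray(reference_rates, dtype=float)
    if ref.size == 0:
        raise ArgumentError("reference must be nonempty")
    bounds = np.quantile(ref, np.arange(1, k) / k)
    ref_labels = np.searchsorted(bounds, ref, side="left") + 1
    tgt_labels = None
    if target_rates is not None:
        tgt = np.asarray(target_rates, dtype=float)
        tgt_labels = np.searchsorted(bounds, tgt, side="left") + 1
    return ref_labels, tgt_labels, bounds


@dataclass
class OnOffPeriods:
    """Per-bout ON and OFF intervals, half-open, in seconds."""

    on: dict[int, list[tuple[float, float]]] = field(default_factory=dict)
    off: dict[int, list[tuple[float, float]]] = field(default_factory=dict)

    def durations_ms(self, kind: str) -> np.ndarray:
        store = self.on if kind == "on" else self.off
        return np.array(
            [1000.0 * (e - s) for ivals in store.values() for s, e in ivals]
        )


def detect_on_off(
    spike_trains: list[np.ndarray],
    nrem_bouts: list[tuple[float, float]],
    min_neurons: int = 7,
    min_spikes: int = 10,
    isi_gap_s: float = 0.050,
    on_min_s: float = 0.050,
    on_max_s: float = 4.0,
) -> OnOffPeriods:
    """NREM ON/OFF periods from pooled multiunit activity.

    Within each NREM bout the spike trains are merged into one MUA train.
    OFF periods are inter-spike gaps strictly longer than ``isi_gap_s``;
    the complementary spike runs are ON candidates, kept when their
    duration lies in [``on_min_s``, ``on_max_s``] and they contain at least
    ``min_spikes`` spikes.
    """
    if len(spike_trains) < min_neurons:
        raise ArgumentError(
            f"need at least {min_neurons} contributing neurons "
            f"(got {len(spike_trains)})"
        )
    result = OnOffPeriods()
    for bout_id, (b0, b1) in enumerate(nrem_bouts):
        if b1 <= b0:
            raise DataError("NREM bout with end <= start")
        mua = np.sort(
            np.concatenate(
                [t[(t >= b0) & (t < b1)] for t in spike_trains]
            )
        )
        if mua.size == 0:
            warnings.warn(f"bout {bout_id}: no MUA spikes, skipped", stacklevel=2)
            continue
        isi = np.diff(mua)
        gap_idx = np.flatnonzero(isi > isi_gap_s)
        result.off[bout_id] = [
            (float(mua[i]), float(mua[i + 1])) for i in gap_idx
        ]
        run_starts = np.concatenate(([0], gap_idx + 1))
        run_ends = np.concatenate((gap_idx, [mua.size - 1]))
        ons = []
        for a, b in zip(run_starts, run_ends):
            dur = float(mua[b] - mua[a])
            if on_min_s <= dur <= on_max_s and (b - a + 1) >= min_spikes:
                ons.append((float(mua[a]), float(mua[b])))
        result.on[bout_id] = ons
    return result


def matlab_smooth(y: np.ndarray, span: int = 5) -> np.ndarray:
    """Moving average with shrinking symmetric windows at the edges."""
    y = np.asarray(y, dtype=float)
    n = y.size
    half = span // 2
    out = np.empty(n)
    for i in range(n):
        k = min(i, n - 1 - i, half)
        out[i] = y[i - k : i + k + 1].mean()
    return out


@dataclass
class RipplePeth:
    """Ripple-centered population firing histogram."""

    bin_centers: np.ndarray
    per_neuron_z: np.ndarray  # (n_neurons, n_bins)
    mean_z: np.ndarray
    smoothed_z: np.ndarray
    neuron_ids: list[int]


def ripple_peth(
    spike_trains: list[np.ndarray],
    ripple_peaks: np.ndarray,
    half_window_s: float = 1.0,
    bin_s: float = 0.010,
    smooth_span: int = 5,
    smooth_passes: int = 2,
) -> RipplePeth:
    """Peri-ripple z-scored firing histogram averaged over neurons.

    Spike lags relative to each ripple peak are pooled per neuron, binned
    (200 bins of 10 ms for the defaults), and the count vector is
    z-normalized across bins; neurons with no spikes in any window (or a
    constant count vector) are excluded with a warning.  The neuron-average
    is smoothed ``smooth_passes`` times with a ``smooth_span``-point moving
    average.
    """
    peaks = np.sort(np.asarray(ripple_peaks, dtype=float))
    if peaks.size == 0:
        raise ArgumentError("need at least one ripple")
    edges = np.arange(-half_window_s, half_window_s + bin_s / 2, bin_s)
    centers = edges[:-1] + bin_s / 2
    rows = []
    kept = []
    for nid, train in enumerate(spike_trains):
        t = np.asarray(train, dtype=float)
        lags = []
        i0 = np.searchsorted(t, peaks - half_window_s)
        i1 = np.searchsorted(t, peaks + half_window_s)
        for p, a, b in zip(peaks, i0, i1):
            lags.append(t[a:b] - p)
        lags = np.concatenate(lags) if lags else np.empty(0)
        counts, _ = np.histogram(lags, bins=edges)
        sd = counts.std()
        if counts.sum() == 0 or sd == 0:
            warnings.warn(
                f"neuron {nid}: no ripple-window spikes or constant counts; "
                "excluded",
                stacklevel=2,
            )
            continue
        rows.append((counts - counts.mean()) / sd)
        kept.append(nid)
    if not rows:
        raise DataError("no neuron with usable ripple-window activity")
    per_neuron = np.stack(rows)
    mean_z = per_neuron.mean(axis=0)
    smoothed = mean_z
    for _ in range(smooth_passes):
        smoothed = matlab_smooth(smoothed, smooth_span)
    return RipplePeth(centers, per_neuron, mean_z, smoothed, kept)


@dataclass
class RippleResponse:
    rates_hz: dict[str, float]
    z_during: float
    label: str  # "suppressed" | "neutral" | "active"


def ripple_response(
    spikes: np.ndarray,
    ripple_peaks: np.ndarray,
    z_threshold: float = 2.0,
    n_boot: int = 1000,
    seed=None,
) -> RippleResponse:
    """Classify a neuron's ripple modulation from epoch firing rates.

    Counts spikes per ripple in the four epochs (baseline [-200, -120),
    pre [-120, -40), during [-40, +40), post [+40, +120) ms relative to the
    ripple peak, half-open).  The mean during - baseline rate difference is
    z-scored against its paired bootstrap distribution (``n_boot``
    resamples over ripples): z >= +threshold -> active, z <= -threshold ->
    suppressed, else neutral.
    """
    t = np.sort(np.asarray(spikes, dtype=float))
    peaks = np.asarray(ripple_peaks, dtype=float)
    if peaks.size == 0:
        raise ArgumentError("need at least one ripple")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    counts = {}
    for name, (lo, hi) in RIPPLE_EPOCHS.items():
        a = np.searchsorted(t, peaks + lo, side="left")
        b = np.searchsorted(t, peaks + hi, side="left")
        counts[name] = (b - a).astype(float)
    widths = {k: hi - lo for k, (lo, hi) in RIPPLE_EPOCHS.items()}
    rates = {k: float(counts[k].mean() / widths[k]) for k in RIPPLE_EPOCHS}

    # paired bootstrap of the during - baseline rate difference: resampling
    # ripples preserves the within-ripple pairing and yields a z that is
    # unit-normal under a homogeneous (unmodulated) neuron
    base = counts["baseline"] / widths["baseline"]
    during = counts["during"] / widths["during"]
    per_ripple_diff = during - base
    boot_idx = rng.integers(0, peaks.size, size=(n_boot, peaks.size))
    boot_diffs = per_ripple_diff[boot_idx].mean(axis=1)
    sd = float(boot_diffs.std())
    diff = float(per_ripple_diff.mean())
    if sd == 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / sd
    if z >= z_threshold:
        label = "active"
    elif z <= -z_threshold:
        label = "suppressed"
    else:
        label = "neutral"
    return RippleResponse(rates_hz=rates, z_during=float(z), label=label)
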