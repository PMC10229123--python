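"""Synthetic-data generation with known ground truth.

Every pipeline input — hypnogram, two-channel LFP, spike trains with
waveforms, and Object Space Task behavior — can be generated here with the
quantities the analyses are supposed to recover (event times and
amplitudes, coupling lags, firing rates, phase locking, ripple modulation,
true learning parameters) recorded in a :class:`GroundTruth` object.

Oscillation events are Hann-tapered sinusoid bursts: the simplest
morphology whose envelope, duration and mean frequency are analytically
known, so detector timing can be checked against closed-form values.  The
background is white noise plus a 1/f-shaped component obtained by spectral
shaping.  Ripples are injected on the hippocampal channel only and
spindles/delta waves on the cortical channel, and only inside NREM epochs,
matching where the detectors look.

All randomness flows through an explicit :class:`numpy.random.Generator`;
no global RNG state is touched, so a fixed seed reproduces every output
bitwise.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal.windows import hann
from scipy.special import i0

from .behavior import TaskSession, design_for_condition, simulate_session
from .coupling import SequenceWindows, count_sequences
from .events import LfpSignal
from .exceptions import ArgumentError, GenerationError
from .sleep import STATES, Hypnogram

__all__ = [
    "EventSpec",
    "NoiseSpec",
    "InjectedEvent",
    "GroundTruth",
    "NeuronTruth",
    "gen_hypnogram",
    "gen_lfp",
    "gen_spike_trains",
    "gen_waveform",
    "gen_behavior_session",
    "gen_event_trains",
]

_DEFAULT_BOUTS = {"WAKE": 120.0, "NREM": 300.0, "REM": 90.0, "INT": 20.0}


@dataclass
class InjectedEvent:
    kind: str
    peak_time_s: float
    amplitude_uv: float
    freq_hz: float
    duration_s: float
    channel: str  # "HPC" or "PFC"

    @property
    def start_s(self) -> float:
        return self.peak_time_s - self.duration_s / 2

    @property
    def end_s(self) -> float:
        return self.peak_time_s + self.duration_s / 2


@dataclass
class NeuronTruth:
    base_rate_hz: float
    so_phase_pref_deg: float
    so_kappa: float
    ripple_gain: float
    class_label: str  # "pyramidal" or "interneuron"


@dataclass
class GroundTruth:
    """Everything the generators injected, for downstream verification."""

    injected_events: list[InjectedEvent] = field(default_factory=list)
    coupling_links: list[tuple[int, int, float]] = field(default_factory=list)
    neuron_truth: list[NeuronTruth] = field(default_factory=list)
    behavior_truth: tuple[float, float] | None = None
    expected_counts: dict[str, int] | None = None

    def peaks(self, kind: str) -> np.ndarray:
        return np.array(
            sorted(e.peak_time_s for e in self.injected_events if e.kind == kind)
        )


@dataclass
class EventSpec:
    """Injection rates, amplitudes, in-band frequencies and coupling.

    Rates are events per minute of NREM.  Frequency ranges sit inside the
    detection band of each kind (ripple 100-300 Hz, spindle 9-20 Hz, delta
    1-6 Hz).  ``coupling`` maps a sequence type ("D-R", "R-D", "D-S") to a
    (probability, (lag_lo_s, lag_hi_s)) pair: each parent event spawns a
    child of the second kind at a uniform lag with that probability.
    """

    rate_per_min: dict[str, float] = field(
        default_factory=lambda: {"ripple": 10.0, "spindle": 3.0, "delta": 5.0}
    )
    amplitude_uv: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ripple": (40.0, 90.0),
            "spindle": (60.0, 120.0),
            "delta": (80.0, 160.0),
        }
    )
    freq_hz: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ripple": (120.0, 250.0),
            "spindle": (10.0, 16.0),
            "delta": (1.5, 4.0),
        }
    )
    duration_s: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "ripple": (0.06, 0.1),
            "spindle": (0.5, 1.5),
            "delta": (0.25, 0.6),
        }
    )
    coupling: dict[str, tuple[float, tuple[float, float]]] = field(
        default_factory=dict
    )

    def __post_init__(self) -> None:
        if any(r < 0 for r in self.rate_per_min.values()):
            raise ArgumentError("event rates must be nonnegative")
        detection = {"ripple": (100, 300), "spindle": (9, 20), "delta": (1, 6)}
        for kind, (lo, hi) in self.freq_hz.items():
            blo, bhi = detection[kind]
            if not (blo <= lo <= hi <= bhi):
                raise ArgumentError(
                    f"{kind} frequency range must lie inside {detection[kind]}"
                )


@dataclass
class NoiseSpec:
    """Background noise: white SD plus a 1/f^exponent shaped component."""

    white_sd_uv: float = 5.0
    pink_sd_uv: float = 15.0
    pink_exponent: float = 1.0

    def __post_init__(self) -> None:
        if self.white_sd_uv < 0 or self.pink_sd_uv < 0:
            raise ArgumentError("noise SDs must be nonnegative")


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def gen_hypnogram(
    duration_s: float,
    mean_bout_s: dict[str, float] | None = None,
    seed=None,
    start_state: str = "WAKE",
) -> Hypnogram:
    """Semi-Markov hypnogram: exponential bouts, uniform state switching.

    ``mean_bout_s`` gives the mean bout duration per state; a state with
    mean 0 is never entered.  Labels are 1 per second.
    """
    if duration_s < 1:
        raise ArgumentError("duration_s must be at least 1")
    rng = _rng(seed)
    means = dict(_DEFAULT_BOUTS)
    if mean_bout_s:
        means.update(mean_bout_s)
    if any(m < 0 for m in means.values()):
        raise ArgumentError("bout means must be nonnegative")
    active = [s for s in STATES if means[s] > 0]
    if not active:
        raise ArgumentError("at least one state must have a positive bout mean")
    state = start_state if start_state in active else active[0]
    n = int(duration_s)
    labels = np.empty(n, dtype="U4")
    t = 0
    while t < n:
        bout = max(1, int(round(rng.exponential(means[state]))))
        labels[t : t + bout] = state
        t += bout
        choices = [s for s in active if s != state]
        if choices:
            state = choices[int(rng.integers(len(choices)))]
    return Hypnogram(labels)


def _one_over_f(n: int, fs: float, sd: float, exponent: float,
                rng: np.random.Generator) -> np.ndarray:
    """1/f^exponent background via spectral shaping of white noise."""
    if sd == 0 or n < 4:
        return np.zeros(n)
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    shape = np.ones_like(freqs)
    nonzero = freqs > 0
    shape[nonzero] = freqs[nonzero] ** (-exponent / 2.0)
    shape[0] = 0.0
    x = np.fft.irfft(spec * shape, n=n)
    x *= sd / max(np.std(x), 1e-12)
    return x


def _burst(fs: float, freq: float, duration: float, amplitude: float,
           phase: float = 0.0) -> np.ndarray:
    n = max(int(round(duration * fs)), 3)
    t = np.arange(n) / fs
    return amplitude * hann(n) * np.sin(2 * np.pi * freq * t + phase)


def _nrem_intervals(hypnogram: Hypnogram) -> list[tuple[float, float]]:
    return [(s, e) for st, s, e in hypnogram.runs() if st == "NREM"]


def gen_lfp(
    hypnogram: Hypnogram,
    event_spec: EventSpec | None = None,
    noise_spec: NoiseSpec | None = None,
    rate_hz: float = 1000.0,
    seed=None,
) -> tuple[LfpSignal, LfpSignal, GroundTruth]:
    """Two-channel synthetic LFP (PFC, HPC) with injected NREM events.

    Ripples go on the HPC channel, spindles and delta waves on the PFC
    channel.  Event peaks fall only inside NREM epochs and whole events fit
    inside their epoch.  Couplings declared in ``event_spec.coupling`` add
    child events at the drawn lag and record the link in the ground truth.
    """
    if rate_hz not in (1000.0, 30000.0, 1000, 30000):
        raise ArgumentError("rate_hz must be 1000 or 30000")
    spec = event_spec or EventSpec()
    noise = noise_spec or NoiseSpec()
    rng = _rng(seed)
    fs = float(rate_hz)
    n = int(round(hypnogram.duration_s * fs))

    channels = {
        "PFC": _one_over_f(n, fs, noise.pink_sd_uv, noise.pink_exponent, rng)
        + noise.white_sd_uv * rng.standard_normal(n),
        "HPC": _one_over_f(n, fs, noise.pink_sd_uv, noise.pink_exponent, rng)
        + noise.white_sd_uv * rng.standard_normal(n),
    }
    channel_of = {"ripple": "HPC", "spindle": "PFC", "delta": "PFC"}

    nrem = _nrem_intervals(hypnogram)
    nrem_minutes = sum(e - s for s, e in nrem) / 60.0
    truth = GroundTruth()

    def draw(lo_hi: tuple[float, float]) -> float:
        lo, hi = lo_hi
        return float(rng.uniform(lo, hi))

    def place(kind: str, peak: float) -> int | None:
        dur = draw(spec.duration_s[kind])
        # keep the whole burst inside one NREM epoch
        for s, e in nrem:
            if s + dur / 2 <= peak <= e - dur / 2:
                break
        else:
            return None
        amp = draw(spec.amplitude_uv[kind])
        freq = draw(spec.freq_hz[kind])
        ev = InjectedEvent(kind, peak, amp, freq, dur, channel_of[kind])
        burst = _burst(fs, freq, dur, amp)
        i0 = int(round((peak - dur / 2) * fs))
        i1 = min(i0 + burst.size, n)
        if i0 < 0 or i1 <= i0:
            return None
        channels[ev.channel][i0:i1] += burst[: i1 - i0]
        truth.injected_events.append(ev)
        return len(truth.injected_events) - 1

    kind_of_letter = {"D": "delta", "R": "ripple", "S": "spindle"}
    min_gap = 0.25  # between same-kind event peaks, seconds

    for kind in ("delta", "spindle", "ripple"):
        rate = spec.rate_per_min.get(kind, 0.0)
        if rate <= 0 or nrem_minutes <= 0:
            continue
        n_events = rng.poisson(rate * nrem_minutes)
        placed: list[float] = []
        attempts = 0
        while len(placed) < n_events and attempts < 20 * n_events + 100:
            attempts += 1
            seg = nrem[int(rng.integers(len(nrem)))]
            peak = float(rng.uniform(seg[0] + 0.3, max(seg[0] + 0.3, seg[1] - 0.3)))
            others = truth.peaks(kind)
            if others.size and np.min(np.abs(others - peak)) < min_gap:
                continue
            idx = place(kind, peak)
            if idx is None:
                continue
            placed.append(peak)
            # couplings where this kind is the parent
            for seq, (prob, lag_range) in spec.coupling.items():
                parent_letter, child_letter = seq.split("-")
                if kind_of_letter[parent_letter] != kind:
                    continue
                if rng.uniform() < prob:
                    lag = draw(lag_range)
                    child_idx = place(kind_of_letter[child_letter], peak + lag)
                    if child_idx is not None:
                        truth.coupling_links.append((idx, child_idx, lag))

    pfc = LfpSignal(channels["PFC"], fs, region="PFC")
    hpc = LfpSignal(channels["HPC"], fs, region="HPC")
    return pfc, hpc, truth


def gen_waveform(
    trough_to_peak_ms: float,
    half_width_ms: float,
    amplitude_uv: float = 100.0,
    fs: float = 30000.0,
    n_samples: int = 82,
    trough_index: int = 40,
) -> np.ndarray:
    """Biphasic spike template: Gaussian trough plus delayed positive bump.

    ``half_width_ms`` sets the full width of the trough at half its depth;
    ``trough_to_peak_ms`` the delay from trough to the after-hyperpolarizing
    positive peak.
    """
    i = np.arange(n_samples, dtype=float)
    sigma = half_width_ms / 1000.0 * fs / (2.0 * np.sqrt(2.0 * np.log(2.0)))
    delay = trough_to_peak_ms / 1000.0 * fs
    trough = -amplitude_uv * np.exp(-0.5 * ((i - trough_index) / sigma) ** 2)
    bump = 0.45 * amplitude_uv * np.exp(
        -0.5 * ((i - trough_index - delay) / (1.6 * sigma)) ** 2
    )
    return trough + bump


def gen_spike_trains(
    n_neurons: int,
    duration_s: float,
    lognormal_rate_params: tuple[float, float] = (0.0, 1.0),
    so_locking: tuple[float, float] | None = None,
    ripple_gain_by_group: dict[str, float] | None = None,
    ground_truth: GroundTruth | None = None,
    seed=None,
    so_freq_hz: float = 1.0,
    ripple_halfwindow_s: float = 0.05,
    class_fraction_pyramidal: float = 0.8,
) -> tuple[list[np.ndarray], list[np.ndarray], list[NeuronTruth]]:
    """Inhomogeneous-Poisson spike trains with waveform templates.

    Base rates are log-normal (``exp(mu + sigma*z)`` Hz).  The rate is
    modulated by a von Mises gain on a slow-oscillation phase ramp
    (``so_locking = (kappa, pref_deg)``) normalized to unit mean, and by a
    multiplicative gain inside +/- ``ripple_halfwindow_s`` of every injected
    ripple peak in ``ground_truth``.  Waveforms follow the cell class:
    pyramidal templates have long trough-to-peak delay and width,
    interneurons short.

    Returns (spike_trains, waveforms, neuron_truth).
    """
    if n_neurons < 1:
        raise ArgumentError("n_neurons must be >= 1")
    rng = _rng(seed)
    gains = ripple_gain_by_group or {}
    if any(g < 0 for g in gains.values()):
        raise ArgumentError("ripple gains must be nonnegative")
    kappa, pref_deg = so_locking if so_locking else (0.0, 0.0)
    if kappa < 0:
        raise ArgumentError("so_locking kappa must be nonnegative")

    ripple_peaks = (
        ground_truth.peaks("ripple") if ground_truth is not None else np.array([])
    )
    mu, sigma = lognormal_rate_params
    group_names = sorted(gains) if gains else ["all"]

    trains: list[np.ndarray] = []
    waveforms: list[np.ndarray] = []
    truths: list[NeuronTruth] = []
    pref = np.deg2rad(pref_deg)
    for j in range(n_neurons):
        base = float(np.exp(mu + sigma * rng.standard_normal()))
        group = group_names[j % len(group_names)]
        rgain = gains.get(group, 1.0)
        is_pyr = rng.uniform() < class_fraction_pyramidal
        # thinning bound: von Mises peak gain times ripple gain
        vm_max = float(np.exp(kappa) / i0(kappa)) if kappa > 0 else 1.0
        lam_max = base * vm_max * max(rgain, 1.0)
        n_cand = rng.poisson(lam_max * duration_s)
        cand = np.sort(rng.uniform(0.0, duration_s, n_cand))
        phase = 2 * np.pi * so_freq_hz * cand
        gain = (
            np.exp(kappa * np.cos(phase - pref)) / i0(kappa) if kappa > 0 else 1.0
        )
        lam = base * gain * np.ones_like(cand)
        if ripple_peaks.size:
            near = np.min(
                np.abs(cand[:, None] - ripple_peaks[None, :]), axis=1
            ) <= ripple_halfwindow_s
            lam = np.where(near, lam * rgain, lam)
        keep = rng.uniform(0.0, lam_max, cand.size) < lam
        trains.append(cand[keep])
        if is_pyr:
            wf = gen_waveform(
                trough_to_peak_ms=float(rng.uniform(0.55, 0.85)),
                half_width_ms=float(rng.uniform(0.28, 0.42)),
            )
        else:
            wf = gen_waveform(
                trough_to_peak_ms=float(rng.uniform(0.12, 0.25)),
                half_width_ms=float(rng.uniform(0.1, 0.18)),
            )
        waveforms.append(wf)
        truths.append(
            NeuronTruth(
                base_rate_hz=base,
                so_phase_pref_deg=pref_deg,
                so_kappa=kappa,
                ripple_gain=rgain,
                class_label="pyramidal" if is_pyr else "interneuron",
            )
        )
    return trains, waveforms, truths


def gen_behavior_session(
    condition: str,
    alpha: float,
    beta: float,
    n_trials: int = 5,
    trial_minutes: float = 5.0,
    seed=None,
) -> tuple[TaskSession, GroundTruth]:
    """Simulate one Object Space Task session under the exploration model.

    Total exploration per trial is 8 s per trial-minute (40 s for the
    standard 5-minute trial), allocated between the two objects by the
    model.
    """
    rng = _rng(seed)
    design = design_for_condition(condition, n_trials, rng)
    total = round(8.0 * trial_minutes)
    session = simulate_session(alpha, beta, design, total, rng, condition=condition)
    truth = GroundTruth(behavior_truth=(alpha, beta))
    return session, truth


_CHAIN_RECIPES = {
    # sequence -> list of (letter, lag window from previous event)
    "D-S": [("D", None), ("S", (0.100, 1.300))],
    "D-R": [("D", None), ("R", (0.050, 0.400))],
    "R-D": [("R", None), ("D", (0.050, 0.250))],
    # R-D-S: in-chain R-D and D-S pairs are intrinsic to the triplet
    "R-D-S": [("R", None), ("D", (0.050, 0.250)), ("S", (0.100, 1.300))],
    # D-R-S: lags chosen so the induced D->S lag exceeds the 1.3 s D-S window
    "D-R-S": [("D", None), ("R", (0.360, 0.400)), ("S", (0.950, 1.000))],
    "D": [("D", None)],
    "R": [("R", None)],
    "S": [("S", None)],
}


def expected_sequence_counts(requests: dict[str, int]) -> dict[str, int]:
    """Oracle-side expected counts implied by a gen_event_trains request.

    A requested triplet necessarily contributes its in-chain pairs: R-D-S
    adds one R-D and one D-S; D-R-S adds one D-R (its D->S lag is pushed
    outside the D-S window by construction).
    """
    get = lambda k: int(requests.get(k, 0))
    return {
        "D-S": get("D-S") + get("R-D-S"),
        "D-R": get("D-R") + get("D-R-S"),
        "R-D": get("R-D") + get("R-D-S"),
        "R-D-S": get("R-D-S"),
        "D-R-S": get("D-R-S"),
    }


def gen_event_trains(
    counts_by_sequence_type: dict[str, int],
    windows: SequenceWindows | None = None,
    jitter_s: float = 1.0,
    seed=None,
    spacing_s: float = 6.0,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, GroundTruth]:
    """Construct delta/spindle/ripple peak trains with exact sequence counts.

    Each requested sequence instance (or isolated event, keys "D"/"R"/"S")
    occupies its own time slot, slots spaced ``spacing_s`` apart so no
    cross-slot lag can fall inside any sequence window; within-slot lags are
    drawn uniformly inside the corresponding window.  The output is checked
    against :func:`oscmem.coupling.count_sequences`; a mismatch (infeasible
    packing) raises :class:`GenerationError`.

    Returns (delta_peaks, spindle_peaks, ripple_peaks, ground_truth) with
    ``ground_truth.expected_counts`` holding the implied exact counts.
    """
    w = windows or SequenceWindows()
    if w != SequenceWindows():
        raise GenerationError(
            "gen_event_trains recipes are built for the default windows"
        )
    rng = _rng(seed)
    requests = {k: int(v) for k, v in counts_by_sequence_type.items()}
    unknown = set(requests) - set(_CHAIN_RECIPES)
    if unknown:
        raise ArgumentError(f"unknown sequence types: {sorted(unknown)}")
    if any(v < 0 for v in requests.values()):
        raise ArgumentError("requested counts must be nonnegative")
    max_span = 1.6  # longest chain (R-D-S: 0.25 + 1.3 s) plus margin
    if spacing_s <= max_span + 1.3:
        raise GenerationError(
            "spacing too small: cross-slot lags would enter sequence windows"
        )

    slots = [seq for seq, k in sorted(requests.items()) for _ in range(k)]
    rng.shuffle(slots)
    peaks: dict[str, list[float]] = {"D": [], "R": [], "S": []}
    for slot_idx, seq in enumerate(slots):
        base = slot_idx * spacing_s + float(rng.uniform(0.0, min(jitter_s, 1.0)))
        t = base
        for letter, lag_window in _CHAIN_RECIPES[seq]:
            if lag_window is not None:
                t += float(rng.uniform(*lag_window))
            peaks[letter].append(t)

    delta = np.sort(np.array(peaks["D"]))
    spindle = np.sort(np.array(peaks["S"]))
    ripple = np.sort(np.array(peaks["R"]))
    expected = expected_sequence_counts(requests)
    got = count_sequences(delta, spindle, ripple, w).as_dict()
    for key, val in expected.items():
        if got[key] != val:
            raise GenerationError(
                f"packing failed: {key} count {got[key]} != expected {val}"
            )
    truth = GroundTruth(expected_counts=expected)
    for kind, arr in (("delta", delta), ("spindle", spindle), ("ripple", ripple)):
        for t in arr:
            truth.injected_events.append(
                InjectedEvent(kind, float(t), 1.0, 0.0, 0.0, "PFC")
            )
    return delta, spindle, ripple, truth
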