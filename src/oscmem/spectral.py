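"""Spectral coherence, ripple-triggered spectrograms and nonparametric
spectral Granger causality between prelimbic cortex and hippocampus.

* **Theta coherence**: Welch magnitude-squared coherence on 1 s Hann
  windows with 80% overlap, averaged over 5-12 Hz.
* **Ripple-triggered spectrograms**: short-time Fourier magnitude in a
  +/- 1 s window around each ripple peak (100 ms Hann window, 10 ms steps),
  averaged over ripples, on a configurable frequency grid; a mains notch
  filter is applied first.
* **Pixel-based permutation test**: two-tailed max/min-statistic null over
  group-label permutations, controlling the family-wise error rate across
  time-frequency pixels.
* **Nonparametric spectral Granger causality**: the trial-averaged
  cross-spectral matrix is factorized with Wilson's algorithm into a
  minimum-phase transfer function and a noise covariance, from which the
  frequency-resolved directed influence follows (Geweke's measure) without
  fitting an autoregressive model.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

from .events import LfpSignal
from .exceptions import ArgumentError, EstimationError

__all__ = [
    "TFMatrix",
    "SignificanceMask",
    "GrangerResult",
    "theta_coherence",
    "median_amplitude_subset",
    "notch_filter",
    "ripple_triggered_spectrogram",
    "pixel_permutation_test",
    "wilson_factorize",
    "granger_from_trials",
    "granger_time_frequency",
    "spectral_granger",
    "granger_randomized_trials",
]


@dataclass
class TFMatrix:
    """A time-frequency matrix (times relative to the ripple peak)."""

    times: np.ndarray
    freqs: np.ndarray
    values: np.ndarray  # shape (n_freqs, n_times)

    def __post_init__(self) -> None:
        if self.values.shape != (self.freqs.size, self.times.size):
            raise ArgumentError("values must be (n_freqs, n_times)")


@dataclass
class SignificanceMask:
    mask: np.ndarray
    n_permutations: int
    alpha: float
    high_threshold: float
    low_threshold: float


@dataclass
class GrangerResult:
    times: np.ndarray | None
    freqs: np.ndarray
    x_to_y: np.ndarray
    y_to_x: np.ndarray


def _concat_segments(
    x: np.ndarray, segments: list[tuple[int, int]] | None
) -> np.ndarray:
    if segments is None:
        return x
    return np.concatenate([x[a:b] for a, b in segments]) if segments else x[:0]


def theta_coherence(
    pfc: np.ndarray | LfpSignal,
    hpc: np.ndarray | LfpSignal,
    fs: float | None = None,
    segments: list[tuple[int, int]] | None = None,
    window_s: float = 1.0,
    overlap: float = 0.8,
    band: tuple[float, float] = (5.0, 12.0),
) -> float:
    """Welch magnitude-squared coherence averaged over the theta band.

    ``segments`` (sample index pairs) restrict the estimate to a brain
    state, e.g. concatenated REM; at least two analysis windows must fit.
    """
    if isinstance(pfc, LfpSignal):
        fs = pfc.rate_hz
        pfc = pfc.samples
    if isinstance(hpc, LfpSignal):
        hpc = hpc.samples
    if fs is None:
        raise ArgumentError("fs required when passing bare arrays")
    x = _concat_segments(np.asarray(pfc, float), segments)
    y = _concat_segments(np.asarray(hpc, float), segments)
    if x.shape != y.shape:
        raise ArgumentError("paired signals must have equal length")
    nperseg = int(round(window_s * fs))
    noverlap = int(round(overlap * nperseg))
    n_windows = (x.size - noverlap) // (nperseg - noverlap) if x.size >= nperseg else 0
    if n_windows < 2:
        raise EstimationError("need at least 2 analysis windows for coherence")
    freqs, cxy = signal.coherence(
        x, y, fs=fs, window="hann", nperseg=nperseg, noverlap=noverlap,
        detrend="constant",
    )
    in_band = (freqs >= band[0]) & (freqs <= band[1])
    return float(np.mean(cxy[in_band]))


def median_amplitude_subset(amplitudes: np.ndarray, n: int = 2000) -> np.ndarray:
    """Indices of the ``n`` events closest in amplitude to the median.

    Stable: ties break by original order.  Fewer than ``n`` events returns
    all indices.
    """
    amp = np.asarray(amplitudes, dtype=float)
    if amp.size <= n:
        return np.arange(amp.size)
    med = float(np.median(amp))
    order = np.argsort(np.abs(amp - med), kind="stable")
    return np.sort(order[:n])


def notch_filter(x: np.ndarray, fs: float, freq: float = 50.0, q: float = 30.0) -> np.ndarray:
    """Zero-phase mains notch filter."""
    b, a = signal.iirnotch(freq, q, fs=fs)
    return signal.filtfilt(b, a, np.asarray(x, dtype=float))


def _extract_trials(
    samples: np.ndarray,
    fs: float,
    peaks: np.ndarray,
    half_span_s: float,
    t0_s: float = 0.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Stack fixed-length windows around peaks; drop peaks near the edges."""
    half = int(round(half_span_s * fs))
    centers = np.round((np.asarray(peaks, float) - t0_s) * fs).astype(int)
    ok = (centers - half >= 0) & (centers + half < samples.size)
    kept = centers[ok]
    trials = np.stack([samples[c - half : c + half + 1] for c in kept]) if kept.size else np.empty((0, 2 * half + 1))
    return trials, np.flatnonzero(ok)


def ripple_triggered_spectrogram(
    lfp: LfpSignal,
    ripple_peaks: np.ndarray,
    freq_range: tuple[float, float] = (100.0, 300.0),
    freq_step: float = 2.0,
    window_s: float = 0.1,
    step_s: float = 0.01,
    half_span_s: float = 1.0,
    notch_hz: float | None = 50.0,
    return_trials: bool = False,
) -> TFMatrix | tuple[TFMatrix, np.ndarray]:
    """STFT magnitude around ripple peaks, averaged over ripples.

    Each valid ripple (full +/- ``half_span_s`` coverage plus the window
    half-width) contributes one spectrogram; frequencies are evaluated
    exactly on the requested grid by direct DFT of the Hann-windowed
    frames.  ``return_trials`` also yields the per-ripple stack
    (n_ripples, n_freqs, n_times) for permutation statistics.
    """
    fs = lfp.rate_hz
    samples = lfp.samples
    if notch_hz is not None and notch_hz < fs / 2:
        samples = notch_filter(samples, fs, notch_hz)
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    times = np.arange(-half_span_s, half_span_s + step_s / 2, step_s)
    freqs = np.arange(freq_range[0], freq_range[1] + freq_step / 2, freq_step)
    margin_s = half_span_s + window_s / 2
    trials, _ = _extract_trials(samples, fs, ripple_peaks, margin_s, lfp.t0_s)
    if trials.shape[0] == 0:
        raise EstimationError("no ripple with full window coverage")

    taper = signal.windows.hann(wlen, sym=False)
    n_arr = np.arange(wlen)
    dft = np.exp(-2j * np.pi * freqs[:, None] * n_arr[None, :] / fs)  # (F, wlen)
    half_w = wlen // 2
    center0 = int(round(margin_s * fs))
    offsets = np.round(times * fs).astype(int) + center0

    stack = np.empty((trials.shape[0], freqs.size, times.size))
    for k, trial in enumerate(trials):
        frames = np.stack(
            [trial[c - half_w : c - half_w + wlen] for c in offsets]
        )  # (T, wlen)
        spec = np.abs(dft @ (frames * taper).T)  # (F, T)
        stack[k] = spec
    tf = TFMatrix(times=times, freqs=freqs, values=stack.mean(axis=0))
    return (tf, stack) if return_trials else tf


def pixel_permutation_test(
    trials_a: np.ndarray,
    trials_b: np.ndarray,
    n_perm: int = 500,
    alpha: float = 0.05,
    seed=None,
) -> SignificanceMask:
    """Two-tailed pixel-based permutation test on time-frequency trials.

    The statistic per pixel is the difference of group means; the null is
    the distribution of the maximum (and minimum) pixel statistic across
    random relabelings, which corrects for multiple comparisons over
    pixels.  Pixels above the 1 - alpha/2 quantile of the max-null or below
    the alpha/2 quantile of the min-null are flagged.
    """
    a = np.asarray(trials_a, dtype=float)
    b = np.asarray(trials_b, dtype=float)
    if a.ndim < 2 or b.ndim < 2 or a.shape[1:] != b.shape[1:]:
        raise ArgumentError("trial stacks must share the pixel grid")
    if a.shape[0] < 2 or b.shape[0] < 2:
        raise ArgumentError("need at least 2 trials per group")
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    na = a.shape[0]
    pooled = np.concatenate([a, b], axis=0)
    observed = a.mean(axis=0) - b.mean(axis=0)
    max_null = np.empty(n_perm)
    min_null = np.empty(n_perm)
    n_total = pooled.shape[0]
    for i in range(n_perm):
        perm = rng.permutation(n_total)
        diff = pooled[perm[:na]].mean(axis=0) - pooled[perm[na:]].mean(axis=0)
        max_null[i] = diff.max()
        min_null[i] = diff.min()
    hi = float(np.quantile(max_null, 1.0 - alpha / 2.0))
    lo = float(np.quantile(min_null, alpha / 2.0))
    mask = (observed > hi) | (observed < lo)
    return SignificanceMask(mask, n_perm, alpha, hi, lo)


def wilson_factorize(
    S: np.ndarray,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Wilson spectral-matrix factorization S(f) = H(f) Sigma H(f)*.

    Parameters
    ----------
    S
        One-sided cross-spectral density, shape (n_freqs, m, m), on a
        uniform grid from 0 to Nyquist inclusive.

    Returns
    -------
    H : ndarray (n_freqs, m, m)
        Minimum-phase transfer function.
    Sigma : ndarray (m, m)
        Innovation (noise) covariance.
    """
    S = np.asarray(S, dtype=complex)
    nf, m, _ = S.shape
    M = 2 * (nf - 1)
    Sfull = np.empty((M, m, m), dtype=complex)
    Sfull[:nf] = S
    # S(-f) = conj(S(f)) = S(f)^T for Hermitian S of a real process
    Sfull[nf:] = S[-2:0:-1].transpose(0, 2, 1)

    gamma = np.fft.ifft(Sfull, axis=0)
    gamma0 = np.real(gamma[0])
    # symmetrize and regularize before the Cholesky seed
    gamma0 = 0.5 * (gamma0 + gamma0.T)
    jitter = 1e-12 * np.trace(gamma0) / m if np.trace(gamma0) > 0 else 1e-12
    try:
        h0 = np.linalg.cholesky(gamma0 + jitter * np.eye(m)).T  # upper
    except np.linalg.LinAlgError as exc:
        raise EstimationError("spectral matrix is not positive definite") from exc
    psi = np.tile(h0.astype(complex), (M, 1, 1))
    identity = np.eye(m)

    converged = False
    for _ in range(max_iter):
        psi_inv = np.linalg.inv(psi)
        g = psi_inv @ Sfull @ np.conj(psi_inv.transpose(0, 2, 1)) + identity
        gam = np.fft.ifft(g, axis=0)
        beta0 = 0.5 * gam[0]
        gam[0] = np.triu(beta0)
        # causal part: lags 0 .. M/2-1 (the shared +/-M/2 lag of the even
        # grid is dropped, otherwise the iteration enters a limit cycle)
        gam[M // 2 :] = 0.0
        gplus = np.fft.fft(gam, axis=0)
        psi_new = psi @ gplus
        err = np.max(np.abs(psi_new - psi)) / max(np.max(np.abs(psi)), 1e-30)
        psi = psi_new
        if err < tol:
            converged = True
            break
    if not converged and err > 1e-4:
        raise EstimationError(
            f"Wilson factorization did not converge (residual {err:.2e})"
        )

    A0 = np.real(np.fft.ifft(psi, axis=0)[0])
    Sigma = A0 @ A0.T
    H = psi[:nf] @ np.linalg.inv(A0)
    return H, Sigma


def _granger_from_S(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Geweke directed influence for a bivariate spectral matrix.

    Channel order (x, y); returns (gc x->y, gc y->x) per frequency.
    """
    H, Sigma = wilson_factorize(S)
    Sxx = np.real(S[:, 0, 0])
    Syy = np.real(S[:, 1, 1])
    Hxy = np.abs(H[:, 0, 1]) ** 2
    Hyx = np.abs(H[:, 1, 0]) ** 2
    sxx, syy, sxy = Sigma[0, 0], Sigma[1, 1], Sigma[0, 1]
    eps = 1e-30
    # x -> y: part of Syy not explained by y's own innovations
    denom_y = Syy - (sxx - sxy**2 / max(syy, eps)) * Hyx
    gc_xy = np.log(np.maximum(Syy, eps) / np.maximum(denom_y, eps))
    denom_x = Sxx - (syy - sxy**2 / max(sxx, eps)) * Hxy
    gc_yx = np.log(np.maximum(Sxx, eps) / np.maximum(denom_x, eps))
    return np.maximum(gc_xy, 0.0), np.maximum(gc_yx, 0.0)


def _cross_spectra(
    x_trials: np.ndarray, y_trials: np.ndarray, taper: np.ndarray
) -> np.ndarray:
    """Trial-averaged one-sided cross-spectral matrix from tapered FFTs."""
    X = np.fft.rfft(x_trials * taper, axis=1)
    Y = np.fft.rfft(y_trials * taper, axis=1)
    nf = X.shape[1]
    S = np.empty((nf, 2, 2), dtype=complex)
    S[:, 0, 0] = np.mean(X * np.conj(X), axis=0)
    S[:, 1, 1] = np.mean(Y * np.conj(Y), axis=0)
    S[:, 0, 1] = np.mean(X * np.conj(Y), axis=0)
    S[:, 1, 0] = np.conj(S[:, 0, 1])
    return S


def granger_from_trials(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    fs: float,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GrangerResult:
    """Stationary nonparametric Granger causality from trial stacks.

    ``x_trials``/``y_trials`` are (n_trials, n_samples) simultaneous
    segments.  Tapers each trial with a Hann window, averages the
    cross-spectral matrix over trials, factorizes it, and returns the
    directed influence on the rFFT frequency grid.
    """
    x = np.atleast_2d(np.asarray(x_trials, dtype=float))
    y = np.atleast_2d(np.asarray(y_trials, dtype=float))
    if x.shape != y.shape:
        raise ArgumentError("trial stacks must have identical shape")
    if x.shape[0] < 1:
        raise EstimationError("need at least one trial")
    x = x - x.mean(axis=1, keepdims=True)
    y = y - y.mean(axis=1, keepdims=True)
    n = x.shape[1]
    taper = signal.windows.hann(n, sym=False)
    S = _cross_spectra(x, y, taper)
    freqs = np.fft.rfftfreq(n, d=1.0 / fs)
    gc_xy, gc_yx = _granger_from_S(S)
    return GrangerResult(times=None, freqs=freqs, x_to_y=gc_xy, y_to_x=gc_yx)


def granger_time_frequency(
    x_trials: np.ndarray,
    y_trials: np.ndarray,
    fs: float,
    window_s: float = 0.5,
    step_s: float = 0.01,
    center_s: float | None = None,
    tol: float = 1e-8,
    max_iter: int = 100,
) -> GrangerResult:
    """Time-frequency nonparametric Granger causality.

    Slides a Hann STFT window (``window_s``, ``step_s``) over the aligned
    trials; at each step the trial-averaged cross-spectral matrix of the
    windowed segments is factorized.  ``center_s`` places time 0 (defaults
    to the trial midpoint, i.e. the ripple peak for peak-centered trials).
    """
    x = np.atleast_2d(np.asarray(x_trials, dtype=float))
    y = np.atleast_2d(np.asarray(y_trials, dtype=float))
    if x.shape != y.shape:
        raise ArgumentError("trial stacks must have identical shape")
    n = x.shape[1]
    wlen = int(round(window_s * fs))
    step = int(round(step_s * fs))
    if wlen > n:
        raise ArgumentError("STFT window longer than the trials")
    starts = np.arange(0, n - wlen + 1, step)
    mid = (n - 1) / 2 if center_s is None else center_s * fs
    times = (starts + (wlen - 1) / 2 - mid) / fs
    taper = signal.windows.hann(wlen, sym=False)
    freqs = np.fft.rfftfreq(wlen, d=1.0 / fs)
    xy = np.empty((freqs.size, starts.size))
    yx = np.empty((freqs.size, starts.size))
    for k, s in enumerate(starts):
        xs = x[:, s : s + wlen]
        ys = y[:, s : s + wlen]
        xs = xs - xs.mean(axis=1, keepdims=True)
        ys = ys - ys.mean(axis=1, keepdims=True)
        S = _cross_spectra(xs, ys, taper)
        gc_xy, gc_yx = _granger_from_S(S)
        xy[:, k] = gc_xy
        yx[:, k] = gc_yx
    return GrangerResult(times=times, freqs=freqs, x_to_y=xy, y_to_x=yx)


def spectral_granger(
    pfc: LfpSignal,
    hpc: LfpSignal,
    ripple_peaks: np.ndarray,
    window_s: float = 2.2,
    stft_window_s: float = 0.5,
    stft_step_s: float = 0.01,
) -> tuple[GrangerResult, GrangerResult]:
    """Ripple-centered time-frequency Granger causality, both directions.

    Extracts a ``window_s`` window (default 2.2 s, long enough for one
    0.5 Hz cycle) around each ripple peak from both channels and runs
    :func:`granger_time_frequency`.  Returns the PFC->HPC direction first
    (as ``x_to_y`` of the first result; the second result swaps roles for
    symmetry of the return contract).
    """
    if pfc.rate_hz != hpc.rate_hz:
        raise ArgumentError("channels must share a sampling rate")
    fs = pfc.rate_hz
    half = window_s / 2
    x_trials, kept = _extract_trials(pfc.samples, fs, ripple_peaks, half, pfc.t0_s)
    y_trials, _ = _extract_trials(hpc.samples, fs, ripple_peaks, half, hpc.t0_s)
    if x_trials.shape[0] == 0:
        raise EstimationError("no ripple with full 2.2 s coverage")
    res = granger_time_frequency(
        x_trials, y_trials, fs, window_s=stft_window_s, step_s=stft_step_s
    )
    pfc_to_hpc = GrangerResult(res.times, res.freqs, res.x_to_y, res.y_to_x)
    hpc_to_pfc = GrangerResult(res.times, res.freqs, res.y_to_x, res.x_to_y)
    return pfc_to_hpc, hpc_to_pfc


def granger_randomized_trials(
    pfc: LfpSignal,
    hpc: LfpSignal,
    ripple_peaks: np.ndarray,
    n_ripples: int = 400,
    n_repeats: int = 30,
    seed=None,
    **granger_kwargs,
) -> list[tuple[GrangerResult, GrangerResult]]:
    """Randomized trial sets for between-group Granger statistics.

    Draws ``n_ripples`` random ripples (without replacement when possible),
    computes the time-frequency Granger causality, and repeats
    ``n_repeats`` times; the resulting list feeds the pixel permutation
    test.
    """
    rng = (
        seed
        if isinstance(seed, np.random.Generator)
        else np.random.default_rng(seed)
    )
    peaks = np.asarray(ripple_peaks, dtype=float)
    out = []
    for _ in range(n_repeats):
        if peaks.size > n_ripples:
            subset = np.sort(rng.choice(peaks, size=n_ripples, replace=False))
        else:
            subset = peaks
        out.append(spectral_granger(pfc, hpc, subset, **granger_kwargs))
    return out
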