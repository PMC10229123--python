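"""Cortico-hippocampal oscillation coupling during NREM sleep.

Counts temporal sequences between delta waves (D), sleep spindles (S) and
hippocampal ripples (R) from their peak times, plus ripple-spindle
co-occurrence from event intervals, and classifies each ripple as single or
coupled.  Sequence membership is decided on the peak-to-peak lag falling in
a fixed window, closed on both ends:

====== ==================  =================================
pair    window (s)          meaning
====== ==================  =================================
D-S     [0.100, 1.300]      delta followed by spindle
D-R     [0.050, 0.400]      delta followed by ripple
R-D     [0.050, 0.250]      ripple followed by delta
R-S     [0.002, 1.000]      ripple followed by spindle
====== ==================  =================================

Triplets: R-D-S counts delta waves preceded by a ripple (an R-D pair) and
followed by a spindle (a D-S pair); D-R-S counts ripples preceded by a
delta (D-R) and followed by a spindle (R-S).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .exceptions import ArgumentError, DataError

__all__ = [
    "SequenceWindows",
    "SequenceCounts",
    "RippleCouplingFractions",
    "match_pairs",
    "count_sequences",
    "ripple_spindle_cooccurrence",
    "ripple_coupling_fractions",
]


@dataclass(frozen=True)
class SequenceWindows:
    """Closed peak-to-peak lag windows (s) defining each sequence type."""

    ds: tuple[float, float] = (0.100, 1.300)
    dr: tuple[float, float] = (0.050, 0.400)
    rd: tuple[float, float] = (0.050, 0.250)
    rs: tuple[float, float] = (0.002, 1.000)

    def __post_init__(self) -> None:
        for name in ("ds", "dr", "rd", "rs"):
            lo, hi = getattr(self, name)
            if not (0 < lo < hi):
                raise ArgumentError(f"window {name} must satisfy 0 < lo < hi")


@dataclass
class SequenceCounts:
    """Counts per sequence type (``d_s_with_r`` requires event intervals)."""

    d_s: int
    d_r: int
    r_d: int
    r_d_s: int
    d_r_s: int
    d_s_with_r: int | None = None

    def as_dict(self) -> dict[str, int | None]:
        return {
            "D-S": self.d_s,
            "D-R": self.d_r,
            "R-D": self.r_d,
            "R-D-S": self.r_d_s,
            "D-R-S": self.d_r_s,
            "D-S-with-R": self.d_s_with_r,
        }


@dataclass
class RippleCouplingFractions:
    """Mutually exclusive ripple categories, normalized by total ripples.

    Precedence when a ripple qualifies for several: DR > RD > RS > single.
    """

    single: float
    dr: float
    rd: float
    rs: float
    n_ripples: int

    def as_dict(self) -> dict[str, float]:
        return {"single": self.single, "DR": self.dr, "RD": self.rd, "RS": self.rs}


def _check_sorted(peaks: np.ndarray, name: str) -> np.ndarray:
    peaks = np.asarray(peaks, dtype=float)
    if peaks.ndim != 1:
        raise ArgumentError(f"{name} must be a 1-D array of peak times")
    if peaks.size > 1 and np.any(np.diff(peaks) < 0):
        raise ArgumentError(f"{name} must be sorted ascending")
    return peaks


def match_pairs(
    a_peaks: np.ndarray,
    b_peaks: np.ndarray,
    window: tuple[float, float],
) -> list[tuple[int, int, float]]:
    """All ordered pairs (i, j) with lag ``b[j] - a[i]`` inside ``window``.

    The window is closed on both ends; an event may participate in several
    pairs.  Inputs must be sorted ascending.
    """
    a = _check_sorted(a_peaks, "a_peaks")
    b = _check_sorted(b_peaks, "b_peaks")
    lo, hi = window
    pairs: list[tuple[int, int, float]] = []
    j0 = np.searchsorted(b, a + lo, side="left")
    j1 = np.searchsorted(b, a + hi, side="right")
    for i in range(a.size):
        for j in range(int(j0[i]), int(j1[i])):
            pairs.append((i, j, float(b[j] - a[i])))
    return pairs


def count_sequences(
    delta_peaks: np.ndarray,
    spindle_peaks: np.ndarray,
    ripple_peaks: np.ndarray,
    windows: SequenceWindows | None = None,
    spindle_intervals: np.ndarray | None = None,
    ripple_intervals: np.ndarray | None = None,
) -> SequenceCounts:
    """Count D-S, D-R, R-D pairs and R-D-S, D-R-S triplets from peak times.

    ``d_s_with_r`` (a D-S pair whose spindle co-occurs with a ripple) needs
    event extents; pass ``spindle_intervals``/``ripple_intervals`` as
    ``(n, 2)`` start/end arrays aligned with the peak lists to enable it,
    otherwise it is reported as ``None``.
    """
    w = windows or SequenceWindows()
    ds_pairs = match_pairs(delta_peaks, spindle_peaks, w.ds)
    dr_pairs = match_pairs(delta_peaks, ripple_peaks, w.dr)
    rd_pairs = match_pairs(ripple_peaks, delta_peaks, w.rd)
    rs_pairs = match_pairs(ripple_peaks, spindle_peaks, w.rs)

    # Triplets are counted over the shared middle event.
    deltas_after_r = {j for _, j, _ in rd_pairs}
    deltas_before_s = {i for i, _, _ in ds_pairs}
    r_d_s = len(deltas_after_r & deltas_before_s)

    ripples_after_d = {j for _, j, _ in dr_pairs}
    ripples_before_s = {i for i, _, _ in rs_pairs}
    d_r_s = len(ripples_after_d & ripples_before_s)

    d_s_with_r: int | None = None
    if spindle_intervals is not None and ripple_intervals is not None:
        cooc_pairs, _, _ = ripple_spindle_cooccurrence(
            ripple_intervals, spindle_intervals
        )
        spindles_with_r = {j for _, j in cooc_pairs}
        d_s_with_r = sum(1 for _, j, _ in ds_pairs if j in spindles_with_r)

    return SequenceCounts(
        d_s=len(ds_pairs),
        d_r=len(dr_pairs),
        r_d=len(rd_pairs),
        r_d_s=r_d_s,
        d_r_s=d_r_s,
        d_s_with_r=d_s_with_r,
    )


def _as_intervals(events: np.ndarray, name: str) -> np.ndarray:
    arr = np.asarray(events, dtype=float)
    if arr.ndim != 2 or arr.shape[1] != 2:
        raise ArgumentError(f"{name} must be an (n, 2) array of [start, end]")
    if np.any(arr[:, 1] <= arr[:, 0]):
        raise DataError(f"{name} contains intervals with end <= start")
    return arr


def ripple_spindle_cooccurrence(
    ripples: np.ndarray,
    spindles: np.ndarray,
) -> tuple[list[tuple[int, int]], int, int]:
    """Ripple-spindle co-occurrence from event start/end intervals.

    A ripple and a spindle co-occur when the ripple lies entirely within the
    spindle, or when either event's start or end falls inside the other
    (boundaries inclusive).  For closed intervals this reduces to interval
    overlap.  A spindle is counted once however many ripples it hosts;
    ripples inside spindles are counted individually.

    Returns
    -------
    (pairs, n_spindles_with_ripple, n_ripples_in_spindles)
        ``pairs`` holds (ripple_index, spindle_index).
    """
    r = _as_intervals(ripples, "ripples")
    s = _as_intervals(spindles, "spindles")
    pairs: list[tuple[int, int]] = []
    if r.size and s.size:
        overlap = (r[:, None, 0] <= s[None, :, 1]) & (s[None, :, 0] <= r[:, None, 1])
        for i, j in zip(*np.nonzero(overlap)):
            pairs.append((int(i), int(j)))
    n_spindles = len({j for _, j in pairs})
    n_ripples = len({i for i, _ in pairs})
    return pairs, n_spindles, n_ripples


def ripple_coupling_fractions(
    ripple_peaks: np.ndarray,
    delta_peaks: np.ndarray,
    windows: SequenceWindows | None = None,
    ripple_intervals: np.ndarray | None = None,
    spindle_intervals: np.ndarray | None = None,
) -> RippleCouplingFractions:
    """Classify every ripple as DR, RD, ripple-with-spindle, or single.

    Categories are mutually exclusive with precedence DR > RD > RS > single,
    so the four fractions partition the ripple population and sum to 1.
    With zero ripples an all-zero result with ``n_ripples = 0`` is returned.
    """
    w = windows or SequenceWindows()
    r = _check_sorted(ripple_peaks, "ripple_peaks")
    n = r.size
    if n == 0:
        return RippleCouplingFractions(0.0, 0.0, 0.0, 0.0, 0)

    dr_ripples = {j for _, j, _ in match_pairs(delta_peaks, r, w.dr)}
    rd_ripples = {i for i, _, _ in match_pairs(r, delta_peaks, w.rd)}
    rs_ripples: set[int] = set()
    if ripple_intervals is not None and spindle_intervals is not None:
        pairs, _, _ = ripple_spindle_cooccurrence(ripple_intervals, spindle_intervals)
        rs_ripples = {i for i, _ in pairs}

    n_dr = n_rd = n_rs = n_single = 0
    for i in range(n):
        if i in dr_ripples:
            n_dr += 1
        elif i in rd_ripples:
            n_rd += 1
        elif i in rs_ripples:
            n_rs += 1
        else:
            n_single += 1
    return RippleCouplingFractions(
        single=n_single / n, dr=n_dr / n, rd=n_rd / n, rs=n_rs / n, n_ripples=n
    )
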