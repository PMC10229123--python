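"""Sleep-architecture segmentation from a 1 Hz hypnogram.

The hypnogram is a per-second vector of state labels (WAKE, NREM, REM, INT)
produced by manual scoring; it is the temporal backbone of every
state-restricted analysis in the package.  This module turns it into

* **bouts** — maximal same-state runs longer than a floor (default 4 s),
* **microarousals** — WAKE intrusions shorter than 15 s inside sleep,
* **sleep periods** — sleep separated by WAKE events longer than 300 s,
* **NREM episodes** — consecutive NREM bouts bridged across microarousals,
* **NREM periods** — episodes extended through trailing transitional (INT)
  bouts,
* **sleep cycles** — a NREM episode followed by zero or more INT bouts and
  then REM.

All intervals are half-open ``[start_s, end_s)`` in seconds from the start
of the recording; epochs are 1 s and 0-based.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .exceptions import ArgumentError, DataError

STATES = ("WAKE", "NREM", "REM", "INT")
SLEEP_STATES = frozenset({"NREM", "REM", "INT"})

__all__ = [
    "STATES",
    "SLEEP_STATES",
    "Hypnogram",
    "Bout",
    "Period",
    "ArchitectureSummary",
    "extract_bouts",
    "segment_sleep_periods",
    "architecture_summary",
]


@dataclass
class Hypnogram:
    """Per-second sleep-state labels.

    Parameters
    ----------
    labels
        Sequence of state names, one per second, each in :data:`STATES`.
    t0_s
        Recording-time offset of the first epoch.
    """

    labels: np.ndarray
    t0_s: float = 0.0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype="U4")
        if self.labels.size < 1:
            raise ArgumentError("hypnogram must contain at least one epoch")
        bad = set(np.unique(self.labels)) - set(STATES)
        if bad:
            raise DataError(f"unknown hypnogram labels: {sorted(bad)}")

    @property
    def duration_s(self) -> float:
        return float(self.labels.size)

    def runs(self) -> list[tuple[str, float, float]]:
        """Run-length encode into ``(state, start_s, end_s)`` triples."""
        labels = self.labels
        change = np.flatnonzero(labels[1:] != labels[:-1]) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [labels.size]))
        return [
            (str(labels[s]), self.t0_s + float(s), self.t0_s + float(e))
            for s, e in zip(starts, ends)
        ]

    def state_at(self, t_s: float) -> str:
        idx = int(np.floor(t_s - self.t0_s))
        if idx < 0 or idx >= self.labels.size:
            raise ArgumentError(f"time {t_s} s outside hypnogram span")
        return str(self.labels[idx])


@dataclass
class Bout:
    """A maximal same-state run; half-open interval in seconds."""

    state: str
    start_s: float
    end_s: float
    is_microarousal: bool = False
    is_sub_bout: bool = False

    def __post_init__(self) -> None:
        if self.end_s <= self.start_s:
            raise DataError("bout end must exceed start")

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


@dataclass
class Period:
    """A composite interval (sleep period, NREM episode/period, cycle)."""

    start_s: float
    end_s: float
    bout_indices: list[int] = field(default_factory=list)

    @property
    def duration_s(self) -> float:
        return self.end_s - self.start_s


def extract_bouts(
    hypnogram: Hypnogram,
    min_bout_s: float = 4.0,
    microarousal_max_s: float = 15.0,
    keep_sub_bouts: bool = False,
) -> list[Bout]:
    """Segment the hypnogram into state bouts.

    Runs with duration ``<= min_bout_s`` (strict "longer than" rule) are
    excluded from bout statistics; with ``keep_sub_bouts=True`` they are kept
    and flagged ``is_sub_bout`` so time accounting and bridging remain exact.
    WAKE runs shorter than ``microarousal_max_s`` flanked by sleep on both
    sides are flagged as microarousals regardless of the bout floor.
    """
    runs = hypnogram.runs()
    bouts: list[Bout] = []
    for i, (state, start, end) in enumerate(runs):
        dur = end - start
        micro = False
        if state == "WAKE" and dur < microarousal_max_s:
            prev_sleep = i > 0 and runs[i - 1][0] in SLEEP_STATES
            next_sleep = i < len(runs) - 1 and runs[i + 1][0] in SLEEP_STATES
            micro = prev_sleep and next_sleep
        sub = dur <= min_bout_s
        if sub and not keep_sub_bouts:
            continue
        bouts.append(
            Bout(state, start, end, is_microarousal=micro, is_sub_bout=sub)
        )
    return bouts


def _is_bridgeable(bout: Bout) -> bool:
    # A gap inside a NREM episode: a microarousal or any sub-bout run.
    return bout.is_microarousal or bout.is_sub_bout


def segment_sleep_periods(
    bouts: list[Bout],
    wake_split_s: float = 300.0,
) -> tuple[list[Period], list[Period], list[Period], list[Period]]:
    """Group bouts into sleep periods, NREM episodes/periods and sleep cycles.

    Parameters
    ----------
    bouts
        Contiguous run list from :func:`extract_bouts` with
        ``keep_sub_bouts=True`` (gap-free coverage is required so quiet-wake
        absorption and bridging are well defined).
    wake_split_s
        WAKE events strictly longer than this split sleep periods; shorter
        wake is absorbed as quiet wakefulness.

    Returns
    -------
    (sleep_periods, nrem_episodes, nrem_periods, sleep_cycles)
    """
    for a, b in zip(bouts, bouts[1:]):
        if not np.isclose(a.end_s, b.start_s):
            raise ArgumentError(
                "bout list must be contiguous; pass keep_sub_bouts=True"
            )

    # --- sleep periods: split at long WAKE, trim wake at the edges ----------
    sleep_periods: list[Period] = []
    current: list[int] = []
    for i, bout in enumerate(bouts):
        if bout.state == "WAKE" and bout.duration_s > wake_split_s:
            if current:
                sleep_periods.append(_trim_wake(bouts, current))
                current = []
        else:
            current.append(i)
    if current:
        sleep_periods.append(_trim_wake(bouts, current))
    sleep_periods = [p for p in sleep_periods if p is not None]

    # --- NREM episodes: NREM bouts bridged over microarousals/sub-bouts ----
    nrem_episodes: list[Period] = []
    i = 0
    n = len(bouts)
    while i < n:
        if bouts[i].state == "NREM" and not bouts[i].is_sub_bout:
            members = [i]
            j = i + 1
            while j < n:
                if bouts[j].state == "NREM" and not bouts[j].is_sub_bout:
                    members.append(j)
                    j += 1
                elif _is_bridgeable(bouts[j]) and j + 1 < n:
                    j += 1
                else:
                    break
            nrem_episodes.append(
                Period(bouts[members[0]].start_s, bouts[members[-1]].end_s, members)
            )
            i = members[-1] + 1
        else:
            i += 1

    # --- NREM periods: episode plus trailing transitional (INT) bouts ------
    nrem_periods: list[Period] = []
    for ep in nrem_episodes:
        j = ep.bout_indices[-1] + 1
        members = list(ep.bout_indices)
        end = ep.end_s
        while j < n and (bouts[j].state == "INT" or _is_bridgeable(bouts[j])):
            if bouts[j].state == "INT":
                members.append(j)
                end = bouts[j].end_s
            j += 1
        nrem_periods.append(Period(ep.start_s, end, members))

    # --- sleep cycles: NREM episode, optional INT, then REM ----------------
    sleep_cycles: list[Period] = []
    for ep in nrem_episodes:
        j = ep.bout_indices[-1] + 1
        members = list(ep.bout_indices)
        while j < n and (bouts[j].state == "INT" or _is_bridgeable(bouts[j])):
            if bouts[j].state == "INT":
                members.append(j)
            j += 1
        if j < n and bouts[j].state == "REM" and not bouts[j].is_sub_bout:
            members.append(j)
            sleep_cycles.append(Period(ep.start_s, bouts[j].end_s, members))

    return sleep_periods, nrem_episodes, nrem_periods, sleep_cycles


def _trim_wake(bouts: list[Bout], indices: list[int]) -> Period | None:
    """Drop leading/trailing WAKE from a candidate sleep period."""
    while indices and bouts[indices[0]].state == "WAKE":
        indices = indices[1:]
    while indices and bouts[indices[-1]].state == "WAKE":
        indices = indices[:-1]
    if not indices:
        return None
    return Period(bouts[indices[0]].start_s, bouts[indices[-1]].end_s, indices)


@dataclass
class ArchitectureSummary:
    """Macro/micro architecture statistics over an analysis window."""

    window: tuple[float, float]
    state_time_s: dict[str, float]
    tst_s: float
    pct_tst: dict[str, float] | None
    bout_count: dict[str, int]
    bout_mean_duration_s: dict[str, float]
    n_sleep_periods: int = 0
    n_nrem_episodes: int = 0
    n_sleep_cycles: int = 0
    mean_sleep_period_s: float = float("nan")


def architecture_summary(
    hypnogram: Hypnogram,
    bouts: list[Bout] | None = None,
    periods: tuple[list[Period], list[Period], list[Period], list[Period]] | None = None,
    window: tuple[float, float] | None = None,
) -> ArchitectureSummary:
    """Summarize totals, TST, %TST and bout statistics in ``window``.

    %TST is reported over the sleep states {NREM, REM, INT} and is ``None``
    when no sleep occurs in the window (undefined, never silently zero).
    """
    t0 = hypnogram.t0_s
    t1 = t0 + hypnogram.duration_s
    if window is None:
        window = (t0, t1)
    w0, w1 = window
    if not (t0 <= w0 < w1 <= t1):
        raise ArgumentError("window must be non-empty and inside the recording")

    i0 = int(np.floor(w0 - t0))
    i1 = int(np.ceil(w1 - t0))
    labels = hypnogram.labels[i0:i1]
    state_time = {s: float(np.count_nonzero(labels == s)) for s in STATES}
    tst = sum(state_time[s] for s in SLEEP_STATES)
    pct = (
        {s: 100.0 * state_time[s] / tst for s in SLEEP_STATES} if tst > 0 else None
    )

    if bouts is None:
        bouts = extract_bouts(hypnogram)
    in_win = [b for b in bouts if b.start_s < w1 and b.end_s > w0 and not b.is_sub_bout]
    bout_count = {s: sum(1 for b in in_win if b.state == s) for s in STATES}
    bout_mean = {
        s: (
            float(np.mean([b.duration_s for b in in_win if b.state == s]))
            if bout_count[s]
            else float("nan")
        )
        for s in STATES
    }

    summary = ArchitectureSummary(
        window=(w0, w1),
        state_time_s=state_time,
        tst_s=tst,
        pct_tst=pct,
        bout_count=bout_count,
        bout_mean_duration_s=bout_mean,
    )
    if periods is not None:
        sp, ep, _np_, cyc = periods
        summary.n_sleep_periods = len(sp)
        summary.n_nrem_episodes = len(ep)
        summary.n_sleep_cycles = len(cyc)
        if sp:
            summary.mean_sleep_period_s = float(np.mean([p.duration_s for p in sp]))
    return summary
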