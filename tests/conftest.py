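import numpy as np
import pytest

from oscmem.sleep import STATES, Hypnogram


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def random_hypnogram_factory():
    """Random label sequences (valid labels, arbitrary run structure)."""

    def make(rng, n_epochs):
        labels = np.array(STATES)[rng.integers(0, 4, size=n_epochs)]
        return Hypnogram(labels)

    return make


def brute_force_pairs(a, b, window):
    """Independent O(n^2) pair-matching oracle (plain loops)."""
    lo, hi = window
    out = []
    for i, ta in enumerate(a):
        for j, tb in enumerate(b):
            lag = tb - ta
            if lo <= lag <= hi:
                out.append((i, j, lag))
    return out


def brute_force_counts(deltas, spindles, ripples, windows):
    """Independent sequence-counting oracle built on exhaustive loops."""
    ds = brute_force_pairs(deltas, spindles, windows.ds)
    dr = brute_force_pairs(deltas, ripples, windows.dr)
    rd = brute_force_pairs(ripples, deltas, windows.rd)
    rs = brute_force_pairs(ripples, spindles, windows.rs)
    rds = len({d for _, d, _ in rd} & {d for d, _, _ in ds})
    drs = len({r for _, r, _ in dr} & {r for r, _, _ in rs})
    return {
        "D-S": len(ds),
        "D-R": len(dr),
        "R-D": len(rd),
        "R-D-S": rds,
        "D-R-S": drs,
    }


def numpy_oracle_counts(deltas, spindles, ripples, windows):
    """Broadcasting-based exhaustive oracle for large event trains."""

    def mask(a, b, win):
        lag = b[None, :] - a[:, None]
        return (lag >= win[0]) & (lag <= win[1])

    ds = mask(deltas, spindles, windows.ds)
    dr = mask(deltas, ripples, windows.dr)
    rd = mask(ripples, deltas, windows.rd)
    rs = mask(ripples, spindles, windows.rs)
    return {
        "D-S": int(ds.sum()),
        "D-R": int(dr.sum()),
        "R-D": int(rd.sum()),
        "R-D-S": int(np.sum(rd.any(axis=0) & ds.any(axis=1))),
        "D-R-S": int(np.sum(dr.any(axis=0) & rs.any(axis=1))),
    }


def brute_force_on_off(mua, gap_s=0.050, on_min_s=0.050, on_max_s=4.0,
                       min_spikes=10):
    """Independent ISI-scan ON/OFF oracle (plain python)."""
    mua = sorted(mua)
    offs, runs, current = [], [], [mua[0]] if mua else []
    for prev, cur in zip(mua, mua[1:]):
        if cur - prev > gap_s:
            offs.append((prev, cur))
            runs.append(current)
            current = [cur]
        else:
            current.append(cur)
    if current:
        runs.append(current)
    ons = [
        (r[0], r[-1])
        for r in runs
        if len(r) >= min_spikes and on_min_s <= r[-1] - r[0] <= on_max_s
    ]
    return ons, offs
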