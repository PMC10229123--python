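"""Plain-text/flat-binary readers and writers for the pipeline's artifacts.

LFP is stored as little-endian float32 flat binary with a JSON sidecar
(``rate_hz``, ``region``, ``n_samples``, ``units``); everything else is
CSV or JSON so files remain inspectable.
"""

from __future__ import annotations

import json
from dataclasses import asdict
from pathlib import Path

import numpy as np
import pandas as pd

from .behavior import TaskSession, TrialObservation
from .events import LfpSignal, OscEvent
from .sleep import Hypnogram
from .synthetic import GroundTruth, InjectedEvent, NeuronTruth

__all__ = [
    "write_lfp", "read_lfp",
    "write_hypnogram", "read_hypnogram",
    "write_spikes", "read_spikes",
    "write_waveforms", "read_waveforms",
    "write_events", "read_events",
    "write_behavior", "read_behavior",
    "write_ground_truth", "read_ground_truth",
]


def write_lfp(path: str | Path, lfp: LfpSignal) -> None:
    path = Path(path)
    lfp.samples.astype("<f4").tofile(path)
    sidecar = {
        "rate_hz": lfp.rate_hz,
        "region": lfp.region,
        "n_samples": int(lfp.n_samples),
        "t0_s": lfp.t0_s,
        "units": "uV",
    }
    path.with_suffix(path.suffix + ".json").write_text(json.dumps(sidecar))


def read_lfp(path: str | Path) -> LfpSignal:
    path = Path(path)
    meta = json.loads(path.with_suffix(path.suffix + ".json").read_text())
    samples = np.fromfile(path, dtype="<f4").astype(float)
    if samples.size != meta["n_samples"]:
        raise ValueError("LFP binary length disagrees with sidecar")
    return LfpSignal(samples, meta["rate_hz"], region=meta["region"],
                     t0_s=meta.get("t0_s", 0.0))


def write_hypnogram(path: str | Path, hyp: Hypnogram) -> None:
    df = pd.DataFrame({
        "epoch_start_s": hyp.t0_s + np.arange(hyp.labels.size, dtype=float),
        "label": hyp.labels,
    })
    df.to_csv(path, index=False)


def read_hypnogram(path: str | Path) -> Hypnogram:
    df = pd.read_csv(path)
    return Hypnogram(df["label"].to_numpy(dtype="U4"),
                     t0_s=float(df["epoch_start_s"].iloc[0]))


def write_spikes(path: str | Path, trains: list[np.ndarray]) -> None:
    rows = [(i, t) for i, train in enumerate(trains) for t in train]
    pd.DataFrame(rows, columns=["neuron_id", "t_s"]).to_csv(path, index=False)


def read_spikes(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    n = int(df["neuron_id"].max()) + 1 if len(df) else 0
    return [
        np.sort(df.loc[df["neuron_id"] == i, "t_s"].to_numpy(dtype=float))
        for i in range(n)
    ]


def write_waveforms(path: str | Path, waveforms: list[np.ndarray]) -> None:
    rows = [
        (i, j, v)
        for i, wf in enumerate(waveforms)
        for j, v in enumerate(wf)
    ]
    pd.DataFrame(rows, columns=["neuron_id", "sample_index", "value_uV"]).to_csv(
        path, index=False
    )


def read_waveforms(path: str | Path) -> list[np.ndarray]:
    df = pd.read_csv(path)
    n = int(df["neuron_id"].max()) + 1 if len(df) else 0
    return [
        df.loc[df["neuron_id"] == i].sort_values("sample_index")["value_uV"]
        .to_numpy(dtype=float)
        for i in range(n)
    ]


def write_events(path: str | Path, events: list[OscEvent]) -> None:
    pd.DataFrame(
        [
            {
                "kind": e.kind,
                "start_s": e.start_s,
                "peak_s": e.peak_s,
                "end_s": e.end_s,
                "amplitude_uV": e.amplitude_uv,
                "mean_freq_Hz": e.mean_freq_hz,
                "so_phase_deg": e.so_phase_deg,
                "period_id": e.period_id,
            }
            for e in events
        ],
        columns=["kind", "start_s", "peak_s", "end_s", "amplitude_uV",
                 "mean_freq_Hz", "so_phase_deg", "period_id"],
    ).to_csv(path, index=False)


def read_events(path: str | Path) -> list[OscEvent]:
    df = pd.read_csv(path)
    out = []
    for _, row in df.iterrows():
        phase = row.get("so_phase_deg")
        out.append(
            OscEvent(
                kind=row["kind"],
                start_s=float(row["start_s"]),
                peak_s=float(row["peak_s"]),
                end_s=float(row["end_s"]),
                amplitude_uv=float(row["amplitude_uV"]),
                mean_freq_hz=float(row["mean_freq_Hz"]),
                so_phase_deg=None if pd.isna(phase) else float(phase),
                period_id=int(row.get("period_id", 0)),
            )
        )
    return out


def write_behavior(path: str | Path, sessions: list[TaskSession]) -> None:
    rows = []
    for s_idx, sess in enumerate(sessions):
        for tr in sess.trials:
            rows.append({
                "session": s_idx,
                "subject": sess.subject or "",
                "condition": tr.condition,
                "trial": tr.trial_index,
                "loc_obj1": tr.locations[0],
                "loc_obj2": tr.locations[1],
                "explore_obj1_s": tr.explore_s[0],
                "explore_obj2_s": tr.explore_s[1],
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_behavior(path: str | Path) -> list[TaskSession]:
    df = pd.read_csv(path)
    sessions = []
    for s_idx, grp in df.groupby("session"):
        trials = [
            TrialObservation(
                condition=row["condition"],
                trial_index=int(row["trial"]),
                locations=(int(row["loc_obj1"]), int(row["loc_obj2"])),
                explore_s=(float(row["explore_obj1_s"]),
                           float(row["explore_obj2_s"])),
            )
            for _, row in grp.iterrows()
        ]
        subject = None
        if "subject" in grp:
            raw = grp["subject"].iloc[0]
            if not pd.isna(raw) and str(raw):
                subject = str(raw)
        sessions.append(TaskSession(condition=trials[0].condition,
                                    trials=trials, subject=subject))
    return sessions


def write_ground_truth(path: str | Path, truth: GroundTruth) -> None:
    payload = {
        "injected_events": [asdict(e) for e in truth.injected_events],
        "coupling_links": [list(link) for link in truth.coupling_links],
        "neuron_truth": [asdict(nt) for nt in truth.neuron_truth],
        "behavior_truth": truth.behavior_truth,
        "expected_counts": truth.expected_counts,
    }
    Path(path).write_text(json.dumps(payload, indent=1))


def read_ground_truth(path: str | Path) -> GroundTruth:
    payload = json.loads(Path(path).read_text())
    return GroundTruth(
        injected_events=[InjectedEvent(**e) for e in payload["injected_events"]],
        coupling_links=[tuple(link) for link in payload["coupling_links"]],
        neuron_truth=[NeuronTruth(**nt) for nt in payload["neuron_truth"]],
        behavior_truth=(
            tuple(payload["behavior_truth"]) if payload["behavior_truth"] else None
        ),
        expected_counts=payload["expected_counts"],
    )
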