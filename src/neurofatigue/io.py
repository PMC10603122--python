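"""Plain-text readers/writers for recordings, events and tables.

Recordings are stored as a CSV sample matrix (one column per channel)
plus a JSON sidecar carrying sampling rate, units and channel labels.
Events are tab-separated (onset_s, duration_s, label). Everything is
text so artifacts survive text-only archiving; EDF export is out of
scope in this build.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .types import EventStream, Recording, RrSeries


def _meta_path(path: Path) -> Path:
    return path.with_suffix(path.suffix + ".meta.json")


def save_recording(recording: Recording, path) -> None:
    path = Path(path)
    header = ",".join(recording.channels)
    np.savetxt(path, recording.data.T, delimiter=",", header=header, comments="", fmt="%.6g")
    meta = {
        "sfreq": recording.sfreq,
        "channels": list(recording.channels),
        "units": recording.units,
        "n_samples": recording.n_samples,
    }
    _meta_path(path).write_text(json.dumps(meta, indent=2))


def read_recording(path) -> Recording:
    path = Path(path)
    meta = json.loads(_meta_path(path).read_text())
    data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    if data.shape[0] != meta["n_samples"]:
        raise ValueError(
            f"{path}: expected {meta['n_samples']} samples, found {data.shape[0]}"
        )
    return Recording(data.T, meta["sfreq"], tuple(meta["channels"]), meta["units"])


def save_events(events: EventStream, path) -> None:
    pd.DataFrame(
        {
            "onset_s": events.onsets,
            "duration_s": events.durations,
            "label": events.labels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_events(path) -> EventStream:
    df = pd.read_csv(path, sep="\t")
    return EventStream(
        df["onset_s"].to_numpy(), df["label"].to_numpy(dtype=object), df["duration_s"].to_numpy()
    )


def save_rr(rr: RrSeries, path) -> None:
    pd.DataFrame({"beat_time_s": rr.beat_times}).to_csv(path, index=False)


def read_rr(path, provenance: str = "detected") -> RrSeries:
    df = pd.read_csv(path)
    return RrSeries(df["beat_time_s"].to_numpy(), provenance=provenance)


def _jsonable(obj):
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def save_json(obj, path) -> None:
    Path(path).write_text(json.dumps(_jsonable(obj), indent=2, sort_keys=True))


def read_json(path):
    return json.loads(Path(path).read_text())


__all__ = [
    "save_recording",
    "read_recording",
    "save_events",
    "read_events",
    "save_rr",
    "read_rr",
    "save_json",
    "read_json",
]
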