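"""CSV/JSON persistence for schedules, lick trains, and photometry."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Union

import numpy as np
import pandas as pd

from irilearn.behavior import LickTrain
from irilearn.schedule import EventSchedule, ProtocolSpec
from irilearn.synthetic import PhotometryTrace

PathLike = Union[str, Path]


def write_events(schedule: EventSchedule, path: PathLike) -> None:
    schedule.to_frame().to_csv(path, index=False)


def read_events(path: PathLike) -> EventSchedule:
    return EventSchedule.from_frame(pd.read_csv(path))


def write_licks(licks: LickTrain, path: PathLike) -> None:
    licks.to_frame().to_csv(path, index=False)


def read_licks(path: PathLike) -> LickTrain:
    return LickTrain.from_frame(pd.read_csv(path))


def write_photometry(trace: PhotometryTrace, path: PathLike) -> None:
    sess = (
        trace.session_index
        if trace.session_index is not None
        else np.ones(len(trace.time_s), dtype=int)
    )
    pd.DataFrame(
        {
            "session_index": sess,
            "time_s": trace.time_s,
            "f470": trace.f470,
            "f405": trace.f405,
        }
    ).to_csv(path, index=False)


def read_photometry(path: PathLike, sampling_rate: float = 120.0) -> PhotometryTrace:
    frame = pd.read_csv(path)
    t = frame["time_s"].to_numpy(float)
    if len(t) > 1:
        dt = np.median(np.diff(t))
        if dt > 0:
            sampling_rate = 1.0 / dt
    return PhotometryTrace(
        time_s=t,
        f470=frame["f470"].to_numpy(float),
        f405=frame["f405"].to_numpy(float),
        sampling_rate=float(sampling_rate),
        session_index=frame["session_index"].to_numpy(int),
    )


def write_protocol(spec: ProtocolSpec, path: PathLike) -> None:
    Path(path).write_text(spec.model_dump_json(indent=2))


def read_protocol(path: PathLike) -> ProtocolSpec:
    return ProtocolSpec.model_validate_json(Path(path).read_text())


def write_json(obj, path: PathLike) -> None:
    def default(o):
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        raise TypeError(f"cannot serialize {type(o)}")

    Path(path).write_text(json.dumps(obj, indent=2, default=default))
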