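"""Plain-text readers and writers for the pipeline's data products.

Sweeps travel as a CSV (time_s, current_pA) plus a JSON sidecar holding
the stimulus times, protocol and any attached ground truth; spike
sessions as spikes/trials/units CSVs; pupil traces as a four-column CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .epsc import EPSCSweep
from .pupil import PupilTrace
from .units import UnitSession

__all__ = [
    "write_sweep", "read_sweep",
    "write_spike_session", "read_spike_session",
    "write_pupil_trace", "read_pupil_trace",
]


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {"__type__": type(obj).__name__,
                **{k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}}
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    return obj


def write_sweep(sweep: EPSCSweep, csv_path: str | Path) -> None:
    csv_path = Path(csv_path)
    pd.DataFrame({"time_s": sweep.time_s,
                  "current_pA": sweep.current_pA}).to_csv(csv_path, index=False)
    sidecar = {"fs_hz": sweep.fs_hz,
               "stim_times_s": sweep.stim_times_s.tolist(),
               "meta": _jsonable(sweep.meta)}
    csv_path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1))


def read_sweep(csv_path: str | Path) -> EPSCSweep:
    csv_path = Path(csv_path)
    df = pd.read_csv(csv_path)
    side = json.loads(csv_path.with_suffix(".json").read_text())
    return EPSCSweep(time_s=df["time_s"].to_numpy(),
                     current_pA=df["current_pA"].to_numpy(),
                     fs_hz=float(side["fs_hz"]),
                     stim_times_s=np.asarray(side["stim_times_s"], float),
                     meta=side.get("meta", {}))


def write_spike_session(session: UnitSession, out_dir: str | Path) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    session.spikes.to_csv(out / "spikes.csv", index=False)
    session.trials.to_csv(out / "trials.csv", index=False)
    session.unit_meta.to_csv(out / "units.csv", index=False)
    (out / "ground_truth.json").write_text(
        json.dumps(_jsonable(session.ground_truth), indent=1))


def read_spike_session(in_dir: str | Path) -> UnitSession:
    p = Path(in_dir)
    gt_file = p / "ground_truth.json"
    gt = json.loads(gt_file.read_text()) if gt_file.exists() else {}
    return UnitSession(spikes=pd.read_csv(p / "spikes.csv"),
                       trials=pd.read_csv(p / "trials.csv"),
                       unit_meta=pd.read_csv(p / "units.csv"),
                       ground_truth=gt)


def write_pupil_trace(trace: PupilTrace, csv_path: str | Path) -> None:
    pd.DataFrame({"time_s": trace.time_s, "x_px": trace.x_px,
                  "y_px": trace.y_px,
                  "diameter_px": trace.diameter_px}).to_csv(csv_path, index=False)


def read_pupil_trace(csv_path: str | Path, fs_hz: float | None = None) -> PupilTrace:
    df = pd.read_csv(csv_path)
    t = df["time_s"].to_numpy()
    if fs_hz is None:
        fs_hz = 1.0 / float(np.median(np.diff(t)))
    return PupilTrace(time_s=t, x_px=df["x_px"].to_numpy(),
                      y_px=df["y_px"].to_numpy(),
                      diameter_px=df["diameter_px"].to_numpy(), fs_hz=fs_hz)
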