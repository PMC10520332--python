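"""Pupillometry: circle fitting, trace preprocessing and saccade detection.

The pipeline mirrors a standard video-oculography analysis: four pupil
landmark coordinates per frame are reduced to a circle (center + radius)
by algebraic least squares; center traces are median filtered and gated
on plausible pupil diameter; saccades are detected from the x-position
trace by joint inter-sample velocity (40 px/s) and acceleration
(340 px/s^2) thresholds, and summarised per trial and session with
trials containing fewer than two saccades excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.signal import medfilt

__all__ = [
    "PupilTrace",
    "SaccadeEvent",
    "fit_pupil_circle",
    "preprocess_pupil",
    "detect_saccades",
    "saccade_statistics",
]

V_THRESH_PX_S = 40.0
A_THRESH_PX_S2 = 340.0
DIAM_MIN_PX = 10.0
DIAM_MAX_PX = 50.0


@dataclass
class PupilTrace:
    """Pupil-center and diameter time series at uniform sampling."""

    time_s: np.ndarray
    x_px: np.ndarray
    y_px: np.ndarray
    diameter_px: np.ndarray
    fs_hz: float
    valid: np.ndarray | None = None   # per-sample gate after preprocessing
    usable: bool = True
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("time_s", "x_px", "y_px", "diameter_px"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        n = len(self.time_s)
        if any(len(getattr(self, k)) != n for k in ("x_px", "y_px", "diameter_px")):
            raise ValueError("all channels must share one length")
        if self.valid is not None:
            self.valid = np.asarray(self.valid, dtype=bool)


@dataclass
class SaccadeEvent:
    """One detected saccade on the x-position trace."""

    onset_s: float
    offset_s: float
    amplitude_px: float
    max_velocity_px_s: float

    def __post_init__(self) -> None:
        if self.offset_s <= self.onset_s:
            raise ValueError("offset must follow onset")
        if self.amplitude_px < 0:
            raise ValueError("amplitude is a magnitude")


def fit_pupil_circle(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares circle through >= 3 landmark points.

    Solves the linear (Kasa) system 2*a*x + 2*b*y + c = x^2 + y^2 for
    the center (a, b) and radius sqrt(c + a^2 + b^2).
    """
    pts = np.asarray(points, dtype=float)
    if pts.ndim != 2 or pts.shape[1] != 2 or pts.shape[0] < 3:
        raise ValueError("need >= 3 (x, y) points")
    A = np.column_stack([2 * pts[:, 0], 2 * pts[:, 1], np.ones(len(pts))])
    rhs = (pts ** 2).sum(axis=1)
    sol, res, rank, _ = np.linalg.lstsq(A, rhs, rcond=None)
    if rank < 3:
        raise ValueError("points are collinear; circle undefined")
    a, b, c = sol
    r2 = c + a * a + b * b
    if r2 <= 0:
        raise ValueError("degenerate circle fit")
    return np.array([a, b]), float(np.sqrt(r2))


def preprocess_pupil(trace: PupilTrace, median_window: int = 11,
                     diam_range_px: tuple[float, float] = (DIAM_MIN_PX, DIAM_MAX_PX),
                     ) -> PupilTrace:
    """Median-filter the channels, gate on diameter, center x.

    Samples with filtered diameter outside ``diam_range_px`` are marked
    invalid; x is re-centered by subtracting its mean over valid
    samples.  A trace with more than 50% invalid samples is flagged
    ``usable=False``.
    """
    if median_window % 2 == 0 or median_window < 1:
        raise ValueError("median_window must be a positive odd integer")
    x = medfilt(trace.x_px, median_window)
    y = medfilt(trace.y_px, median_window)
    d = medfilt(trace.diameter_px, median_window)
    valid = (d >= diam_range_px[0]) & (d <= diam_range_px[1])
    usable = bool(valid.mean() >= 0.5)
    if valid.any():
        x = x - x[valid].mean()
    return PupilTrace(time_s=trace.time_s.copy(), x_px=x, y_px=y,
                      diameter_px=d, fs_hz=trace.fs_hz, valid=valid,
                      usable=usable, meta=dict(trace.meta))


def _detect_in_segment(t: np.ndarray, x: np.ndarray, fs: float,
                       v_thresh: float, a_thresh: float,
                       require_neg_accel_offset: bool) -> list[SaccadeEvent]:
    n = len(x)
    if n < 3:
        return []
    v = np.abs(np.diff(x)) * fs                      # v[i]: speed into sample i+1
    acc_in = np.empty_like(v)                        # acceleration leading into v[i]
    acc_in[0] = 0.0
    acc_in[1:] = np.diff(v) * fs
    events: list[tuple[int, int]] = []
    i = 0
    m = len(v)
    while i < m:
        if v[i] > v_thresh and acc_in[i] > a_thresh:
            j = i + 1
            while j < m and v[j] >= v_thresh:
                if require_neg_accel_offset:
                    pass  # offset additionally needs deceleration; handled below
                j += 1
            if require_neg_accel_offset:
                while j < m and acc_in[j] > 0:
                    j += 1
            events.append((i, min(j, m)))
            i = j + 1
        else:
            i += 1
    # merge events separated by < 2 samples
    merged: list[tuple[int, int]] = []
    for on, off in events:
        if merged and on - merged[-1][1] < 2:
            merged[-1] = (merged[-1][0], off)
        else:
            merged.append((on, off))
    out = []
    for on, off in merged:
        off = min(off, n - 1)
        amp = abs(x[off] - x[on])
        vmax = float(np.max(v[on:off])) if off > on else float(v[on])
        out.append(SaccadeEvent(onset_s=float(t[on]), offset_s=float(t[off]),
                                amplitude_px=amp, max_velocity_px_s=vmax))
    return out


def detect_saccades(trace: PupilTrace, v_thresh: float = V_THRESH_PX_S,
                    a_thresh: float = A_THRESH_PX_S2,
                    require_neg_accel_offset: bool = False,
                    use_2d: bool = False) -> list[SaccadeEvent]:
    """Detect saccades by velocity + acceleration thresholds.

    A saccade onset is the first sample whose inter-sample velocity
    exceeds ``v_thresh`` while the acceleration leading into it exceeds
    ``a_thresh``; the offset is the next sample whose velocity drops
    below ``v_thresh``.  Events closer than 2 samples are merged.
    Invalid (diameter-gated) samples break the trace into segments and
    no event spans a gap.
    """
    if len(trace.time_s) < 3:
        raise ValueError("trace shorter than 3 samples")
    if use_2d:
        x = np.hypot(trace.x_px - trace.x_px[0], trace.y_px - trace.y_px[0])
    else:
        x = trace.x_px
    valid = trace.valid if trace.valid is not None else np.ones(len(x), bool)
    events: list[SaccadeEvent] = []
    # split into contiguous valid segments
    idx = np.flatnonzero(valid)
    if len(idx) == 0:
        return events
    breaks = np.flatnonzero(np.diff(idx) > 1)
    starts = np.concatenate([[0], breaks + 1])
    ends = np.concatenate([breaks, [len(idx) - 1]])
    for s, e in zip(starts, ends):
        seg = idx[s:e + 1]
        events.extend(_detect_in_segment(
            trace.time_s[seg], x[seg], trace.fs_hz,
            v_thresh, a_thresh, require_neg_accel_offset))
    return events


def saccade_statistics(events_by_trial: Mapping[object, Sequence[SaccadeEvent]],
                       epochs_by_trial: Mapping[object, str] | None = None,
                       min_saccades_per_trial: int = 2) -> dict:
    """Aggregate saccade events across trials of one session.

    Trials with fewer than ``min_saccades_per_trial`` detected saccades
    are excluded.  Returns the session total count, mean amplitude and
    mean maximum velocity over the surviving events, plus per-trial
    counts (by epoch label when provided).
    """
    kept = {tid: list(evs) for tid, evs in events_by_trial.items()
            if len(evs) >= min_saccades_per_trial}
    all_events = [e for evs in kept.values() for e in evs]
    per_trial = pd.DataFrame({
        "trial_id": list(kept.keys()),
        "n_saccades": [len(v) for v in kept.values()],
    })
    if epochs_by_trial is not None:
        per_trial["epoch"] = [epochs_by_trial.get(t) for t in kept]
        counts_by_epoch = (per_trial.groupby("epoch")["n_saccades"].mean()
                           .to_dict())
    else:
        counts_by_epoch = {}
    return {
        "n_trials_included": len(kept),
        "n_trials_excluded": len(events_by_trial) - len(kept),
        "total_saccades": len(all_events),
        "mean_amplitude_px": (float(np.mean([e.amplitude_px for e in all_events]))
                              if all_events else float("nan")),
        "mean_max_velocity_px_s": (float(np.mean([e.max_velocity_px_s
                                                  for e in all_events]))
                                   if all_events else float("nan")),
        "per_trial_counts": per_trial,
        "mean_count_by_epoch": counts_by_epoch,
    }
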