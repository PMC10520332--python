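"""Evoked-EPSC sweep preprocessing and short-term-plasticity ratios.

Sweeps are voltage-clamp current traces (pA, negative-going EPSCs)
recorded while stimulating afferents at annotated times.  The pipeline
smooths each sweep with a Savitzky-Golay filter, detrends it by
subtracting its upper envelope (the interpolant through pre-stimulus
baseline anchors), extracts per-pulse peak amplitudes, and forms the
paired-pulse ratio (PPR, 2nd/1st EPSC) and multiple-pulse ratios
(MPR, nth/1st EPSC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.signal import savgol_filter

__all__ = [
    "EPSCSweep",
    "PulseAmplitudes",
    "preprocess_sweep",
    "extract_pulse_amplitudes",
    "paired_pulse_ratio",
    "multiple_pulse_ratio",
    "average_amplitudes",
]

#: amplitudes below this magnitude (pA) are treated as undetectable when
#: used as a ratio denominator
DETECTION_FLOOR_PA = 1e-6


@dataclass
class EPSCSweep:
    """A single voltage-clamp sweep with stimulus annotations."""

    time_s: np.ndarray
    current_pA: np.ndarray
    fs_hz: float
    stim_times_s: np.ndarray
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.time_s = np.asarray(self.time_s, dtype=float)
        self.current_pA = np.asarray(self.current_pA, dtype=float)
        self.stim_times_s = np.asarray(self.stim_times_s, dtype=float)
        if self.time_s.shape != self.current_pA.shape:
            raise ValueError("time and current must have equal length")
        if self.fs_hz <= 0:
            raise ValueError("fs_hz must be positive")
        dt = np.diff(self.time_s)
        if len(dt) and not np.allclose(dt, 1.0 / self.fs_hz, rtol=1e-9, atol=1e-12):
            raise ValueError("sampling must be uniform at fs_hz")
        if np.any(np.diff(self.stim_times_s) <= 0):
            raise ValueError("stimulus times must be strictly increasing")
        if len(self.stim_times_s) and (
                self.stim_times_s[0] < self.time_s[0]
                or self.stim_times_s[-1] > self.time_s[-1]):
            raise ValueError("stimulus times must lie within the trace span")


@dataclass
class PulseAmplitudes:
    """Per-pulse EPSC peak magnitudes (positive, pA)."""

    amps_pA: np.ndarray
    peak_times_s: np.ndarray
    baseline_pA: np.ndarray

    def __post_init__(self) -> None:
        self.amps_pA = np.asarray(self.amps_pA, dtype=float)
        if np.any(self.amps_pA < 0):
            raise ValueError("amplitudes are magnitudes and must be >= 0")


def preprocess_sweep(sweep: EPSCSweep, savgol_window: int = 11,
                     savgol_order: int = 3, baseline_ms: float = 2.0,
                     detrend: bool = True) -> EPSCSweep:
    """Smooth a sweep and subtract its upper envelope.

    The upper envelope is the monotone-safe piecewise-cubic (PCHIP)
    interpolant through anchor points placed at the mean current over
    the ``baseline_ms`` immediately preceding each stimulus, plus the
    trace endpoints.  Subtracting it removes slow drift without eating
    the negative-going EPSC peaks; the output is ~0 at the anchors.
    """
    if savgol_window % 2 == 0:
        raise ValueError("savgol_window must be odd")
    if savgol_window <= savgol_order:
        raise ValueError("savgol_window must exceed savgol_order")
    if savgol_window >= len(sweep.current_pA):
        raise ValueError("savgol_window must be shorter than the trace")

    smoothed = savgol_filter(sweep.current_pA, savgol_window, savgol_order)
    if not detrend:
        return replace(sweep, current_pA=smoothed)

    n = len(smoothed)
    nb = max(1, int(round(baseline_ms * 1e-3 * sweep.fs_hz)))
    # anchor times are the centroids of their averaging windows so that a
    # linear drift is reproduced exactly
    anchor_t = [float(np.mean(sweep.time_s[:nb]))]
    anchor_v = [float(np.mean(smoothed[:nb]))]
    for t in sweep.stim_times_s:
        i = int(round((t - sweep.time_s[0]) * sweep.fs_hz))
        lo = max(0, i - nb)
        if i <= 0:
            continue
        ta = sweep.time_s[max(lo, 0):i].mean() if i > lo else sweep.time_s[i]
        if ta <= anchor_t[-1]:
            continue
        anchor_t.append(float(ta))
        anchor_v.append(float(np.mean(smoothed[lo:i])))
    t_last = float(np.mean(sweep.time_s[-nb:]))
    if t_last > anchor_t[-1]:
        anchor_t.append(t_last)
        anchor_v.append(float(np.mean(smoothed[-nb:])))

    if len(anchor_t) < 2:
        envelope = np.full(n, anchor_v[0])
    else:
        envelope = PchipInterpolator(anchor_t, anchor_v)(sweep.time_s)
    return replace(sweep, current_pA=smoothed - envelope)


def extract_pulse_amplitudes(sweep: EPSCSweep, search_ms: float | None = None,
                             baseline_ms: float = 2.0,
                             lag_min_ms: float = 0.5) -> PulseAmplitudes:
    """Measure the per-pulse peak EPSC magnitude.

    amplitude_k = (mean current over ``baseline_ms`` before stimulus k)
    minus (minimum current in (``lag_min_ms``, ``search_ms``] after
    stimulus k), reported as a positive magnitude.  The initial
    ``lag_min_ms`` skip avoids the stimulus artifact.
    """
    stim = sweep.stim_times_s
    if len(stim) == 0:
        raise ValueError("sweep has no stimulus annotations")
    ipi_ms = np.min(np.diff(stim)) * 1e3 if len(stim) > 1 else np.inf
    if search_ms is None:
        search_ms = min(ipi_ms, 25.0)
    if search_ms > ipi_ms:
        warnings.warn("search window collides with the next pulse; truncated")
        search_ms = ipi_ms

    fs = sweep.fs_hz
    nb = max(1, int(round(baseline_ms * 1e-3 * fs)))
    cur = sweep.current_pA
    amps = np.empty(len(stim))
    peak_t = np.empty(len(stim))
    base = np.empty(len(stim))
    for k, t in enumerate(stim):
        i = int(round((t - sweep.time_s[0]) * fs))
        j0 = i + max(1, int(np.ceil(lag_min_ms * 1e-3 * fs)))
        j1 = i + int(round(search_ms * 1e-3 * fs)) + 1
        j1 = min(j1, len(cur))
        if j0 >= j1:
            raise ValueError("empty peak-search window")
        blo = max(0, i - nb)
        if blo >= i:
            raise ValueError("no baseline samples before stimulus")
        b = float(np.mean(cur[blo:i]))
        jmin = j0 + int(np.argmin(cur[j0:j1]))
        amps[k] = max(0.0, b - float(cur[jmin]))
        peak_t[k] = sweep.time_s[jmin]
        base[k] = b
    return PulseAmplitudes(amps_pA=amps, peak_times_s=peak_t, baseline_pA=base)


def paired_pulse_ratio(amps: PulseAmplitudes) -> float:
    """PPR: second evoked EPSC / first evoked EPSC."""
    a = amps.amps_pA
    if len(a) != 2:
        raise ValueError("PPR requires exactly two pulses")
    if a[0] <= DETECTION_FLOOR_PA:
        raise ZeroDivisionError("first amplitude below detection floor")
    return float(a[1] / a[0])


def multiple_pulse_ratio(amps: PulseAmplitudes) -> np.ndarray:
    """MPR: nth evoked EPSC / first evoked EPSC; mpr[0] is exactly 1."""
    a = amps.amps_pA
    if len(a) < 2:
        raise ValueError("MPR requires at least two pulses")
    if a[0] <= DETECTION_FLOOR_PA:
        raise ZeroDivisionError("first amplitude below detection floor")
    mpr = a / a[0]
    mpr[0] = 1.0
    return mpr


def average_amplitudes(per_sweep: list[PulseAmplitudes]) -> PulseAmplitudes:
    """Average per-pulse amplitudes across trial repeats of one cell.

    Ratios downstream are computed from these averaged amplitudes, not
    averaged over per-sweep ratios.
    """
    if not per_sweep:
        raise ValueError("no sweeps to average")
    n = len(per_sweep[0].amps_pA)
    if any(len(p.amps_pA) != n for p in per_sweep):
        raise ValueError("sweeps have differing pulse counts")
    return PulseAmplitudes(
        amps_pA=np.mean([p.amps_pA for p in per_sweep], axis=0),
        peak_times_s=np.mean([p.peak_times_s for p in per_sweep], axis=0),
        baseline_pA=np.mean([p.baseline_pA for p in per_sweep], axis=0),
    )
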