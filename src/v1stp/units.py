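"""In-vivo unit and LFP quantification.

Implements the standard single-unit metrics for awake V1 recordings:
Gaussian-smoothed trial-averaged firing rates, baseline z-scoring,
good-unit filtering (> 0.5 Hz mean rate), orientation tuning (Gaussian
fit on the normalized-angle axis, R^2 > 0.95 gate) and orientation
selectivity index, oddball adaptation/mismatch peak windows,
familiarity-oscillation peak detection (>= 0.5 z amplitude, >= 100 ms
apart) with frequency, layer-4 LFP selection by evoked amplitude within
a cortical-depth window, and Morlet time-frequency power normalized to
a 400-ms pre-stimulus baseline in dB.

All time windows are half-open [start, end); stimulus onset is t = 0
within each trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.optimize import curve_fit
from scipy.signal import find_peaks

__all__ = [
    "UnitSession",
    "TuningResult",
    "OscillationResult",
    "gaussian_rate",
    "baseline_z",
    "select_good_units",
    "orientation_tuning",
    "oddball_metrics",
    "oscillation_peaks_frequency",
    "layer4_lfp_select",
    "morlet_power_db",
]

GOOD_UNIT_MIN_RATE_HZ = 0.5
R2_GOOD_FIT = 0.95
PEAK_MIN_SEPARATION_S = 0.100
PEAK_MIN_AMPLITUDE_Z = 0.5


@dataclass
class UnitSession:
    """Per-unit spike times with a trial/condition table.

    ``spikes`` is a DataFrame with columns (unit_id, trial_id, time_s)
    where time_s is relative to the trial's stimulus onset; ``trials``
    has (trial_id, condition, onset_s); ``unit_meta`` has
    (unit_id, mean_rate_hz).
    """

    spikes: pd.DataFrame
    trials: pd.DataFrame
    unit_meta: pd.DataFrame
    ground_truth: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for col in ("unit_id", "trial_id", "time_s"):
            if col not in self.spikes.columns:
                raise ValueError(f"spikes table missing column {col!r}")
        for col in ("trial_id", "condition", "onset_s"):
            if col not in self.trials.columns:
                raise ValueError(f"trials table missing column {col!r}")

    def unit_ids(self) -> np.ndarray:
        return np.asarray(self.unit_meta["unit_id"])


@dataclass
class TuningResult:
    """Orientation tuning of one unit."""

    preferred_deg: float
    osi: float | None
    gauss: tuple[float, float, float, float] | None  # (A, mu, sigma, b)
    r2: float
    good_fit: bool


@dataclass
class OscillationResult:
    """Detected firing-rate oscillation peaks and their mean frequency."""

    peak_times_s: np.ndarray
    frequency_hz: float | None
    n_peaks: int


def gaussian_rate(spike_times_s, n_trials: int, t_start_s: float,
                  t_end_s: float, sigma_ms: float = 50.0,
                  bin_ms: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Trial-averaged firing rate smoothed with a Gaussian kernel.

    The spike histogram over all trials is divided by (n_trials * bin
    width) and convolved with a unit-area Gaussian of SD ``sigma_ms``.

    Returns (time_s, rate_hz) with time at bin centers.
    """
    if sigma_ms <= 0 or bin_ms <= 0:
        raise ValueError("sigma_ms and bin_ms must be positive")
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    spikes = np.asarray(spike_times_s, dtype=float)
    edges = np.arange(t_start_s, t_end_s + bin_ms * 1e-3 / 2, bin_ms * 1e-3)
    counts, _ = np.histogram(spikes, bins=edges)
    rate = counts / (n_trials * bin_ms * 1e-3)
    smoothed = gaussian_filter1d(rate, sigma=sigma_ms / bin_ms, mode="constant")
    centers = (edges[:-1] + edges[1:]) / 2
    return centers, smoothed


def baseline_z(rate_hz: np.ndarray, time_s: np.ndarray, onset_s: float = 0.0,
               baseline_s: float = 0.2) -> np.ndarray:
    """Baseline-normalized response (FR - mean(FR0)) / std(FR0).

    FR0 is the firing rate within ``baseline_s`` before ``onset_s``
    (half-open window [onset - baseline_s, onset)).
    """
    time_s = np.asarray(time_s, float)
    rate_hz = np.asarray(rate_hz, float)
    sel = (time_s >= onset_s - baseline_s) & (time_s < onset_s)
    if not sel.any():
        raise ValueError("no samples in the pre-onset baseline window")
    mu = rate_hz[sel].mean()
    sd = rate_hz[sel].std()
    if sd == 0:
        raise ZeroDivisionError(
            "zero baseline SD; unit has no baseline variability and is "
            "excluded downstream")
    return (rate_hz - mu) / sd


def select_good_units(session: UnitSession,
                      min_rate_hz: float = GOOD_UNIT_MIN_RATE_HZ) -> UnitSession:
    """Keep units with mean firing rate strictly above ``min_rate_hz``."""
    keep = session.unit_meta["mean_rate_hz"] > min_rate_hz
    kept_ids = set(session.unit_meta.loc[keep, "unit_id"])
    return UnitSession(
        spikes=session.spikes[session.spikes["unit_id"].isin(kept_ids)].copy(),
        trials=session.trials.copy(),
        unit_meta=session.unit_meta[keep].reset_index(drop=True),
        ground_truth=session.ground_truth,
    )


def _gauss(x, A, mu, sigma, b):
    return A * np.exp(-((x - mu) ** 2) / (2 * sigma ** 2)) + b


def orientation_tuning(responses, angles_deg) -> TuningResult:
    """Orientation tuning from six stimulus-locked response values.

    The preferred orientation is the argmax response.  The orientation
    selectivity index is OSI = (R_pref - R_orth) / (R_pref + R_orth) on
    nonnegativity-clipped responses, with R_orth at preferred +/- 90
    degrees.  A Gaussian A*exp(-(x-mu)^2 / (2 sigma^2)) + b is fitted on
    the normalized-angle index axis (preferred orientation at index 0,
    indices -2..3); fits with R^2 > 0.95 are flagged good.
    """
    r = np.asarray(responses, dtype=float)
    angles = np.asarray(angles_deg, dtype=float)
    if len(r) != 6 or len(angles) != 6:
        raise ValueError("six responses at six angles required")
    if not np.all(np.isfinite(r)):
        raise ValueError("responses must be finite")
    pref_i = int(np.argmax(r))
    preferred = float(angles[pref_i])

    clipped = np.clip(r, 0, None)
    # orthogonal = angle 90 deg away on the 180-deg circle
    orth_angle = (preferred + 90.0) % 180.0
    diffs = np.abs((angles - orth_angle + 90.0) % 180.0 - 90.0)
    orth_i = int(np.argmin(diffs))
    denom = clipped[pref_i] + clipped[orth_i]
    osi = None if denom == 0 else float((clipped[pref_i] - clipped[orth_i]) / denom)

    # normalized-angle axis: shift responses so the preferred sits at 0,
    # covering indices -2..3 (one index = one 30-deg step)
    idx = np.arange(-2, 4)
    shifted = np.roll(r, 2 - pref_i)
    p0 = (float(r.max() - r.min()), 0.0, 1.0, float(r.min()))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, _ = curve_fit(_gauss, idx.astype(float), shifted, p0=p0,
                                maxfev=10000)
        pred = _gauss(idx.astype(float), *popt)
        ss_res = float(np.sum((shifted - pred) ** 2))
        ss_tot = float(np.sum((shifted - shifted.mean()) ** 2))
        r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 1.0
        gauss = tuple(float(v) for v in popt)
    except RuntimeError:
        gauss, r2 = None, 0.0
    return TuningResult(preferred_deg=preferred, osi=osi, gauss=gauss,
                        r2=r2, good_fit=r2 > R2_GOOD_FIT)


def oddball_metrics(rates_by_condition: dict, time_s: np.ndarray,
                    adaptation_window_s: tuple[float, float] = (0.0, 0.5),
                    mismatch_window_s: tuple[float, float] = (0.2, 0.5)) -> dict:
    """Peak-rate adaptation and mismatch measures from an oddball design.

    Adaptation compares the peak rate of the equal-probability control
    vs the redundant stimulus within [0, 0.5) s of onset; mismatch
    compares deviant vs redundant peaks within [0.2, 0.5) s.
    """
    for cond in ("control", "redundant", "deviant"):
        if cond not in rates_by_condition:
            raise ValueError(f"missing condition {cond!r}")
    time_s = np.asarray(time_s, float)

    def peak(cond: str, win: tuple[float, float]) -> float:
        sel = (time_s >= win[0]) & (time_s < win[1])
        if not sel.any():
            raise ValueError("empty window")
        return float(np.max(np.asarray(rates_by_condition[cond], float)[sel]))

    return {
        "adaptation_control_peak": peak("control", adaptation_window_s),
        "adaptation_redundant_peak": peak("redundant", adaptation_window_s),
        "mismatch_deviant_peak": peak("deviant", mismatch_window_s),
        "mismatch_redundant_peak": peak("redundant", mismatch_window_s),
    }


def oscillation_peaks_frequency(z_trace: np.ndarray, time_s: np.ndarray,
                                min_separation_s: float = PEAK_MIN_SEPARATION_S,
                                min_amplitude_z: float = PEAK_MIN_AMPLITUDE_Z,
                                ) -> OscillationResult:
    """Oscillation peaks >= 0.5 z, >= 100 ms apart, and their frequency.

    Local maxima are accepted greedily in order of descending amplitude
    (scipy's ``find_peaks`` distance rule).  The oscillation frequency
    is the mean over adjacent peak pairs of the inverse inter-peak
    interval; undefined with fewer than two peaks.
    """
    z = np.asarray(z_trace, float)
    t = np.asarray(time_s, float)
    if len(z) != len(t):
        raise ValueError("trace and time base must match")
    if len(z) < 3:
        return OscillationResult(np.array([]), None, 0)
    dt = float(np.median(np.diff(t)))
    dist = max(1, int(np.ceil(min_separation_s / dt)))
    peaks, _ = find_peaks(z, height=min_amplitude_z, distance=dist)
    peak_times = t[peaks]
    if len(peaks) >= 2:
        freq = float(np.mean(1.0 / np.diff(peak_times)))
    else:
        freq = None
    return OscillationResult(peak_times_s=peak_times, frequency_hz=freq,
                             n_peaks=len(peaks))


def layer4_lfp_select(lfp: np.ndarray, depths_um: np.ndarray,
                      time_s: np.ndarray,
                      depth_range_um: tuple[float, float] = (300.0, 500.0),
                      window_s: tuple[float, float] = (0.050, 0.150)) -> int:
    """Pick the layer-4 LFP channel.

    Among channels whose depth lies within ``depth_range_um`` below the
    brain surface, returns the index of the channel with the largest
    peak |LFP| within [50, 150) ms after stimulus onset (trial-averaged
    traces expected, one row per channel).
    """
    lfp = np.atleast_2d(np.asarray(lfp, float))
    depths = np.asarray(depths_um, float)
    t = np.asarray(time_s, float)
    if lfp.shape[0] != len(depths):
        raise ValueError("one depth per channel required")
    in_range = (depths >= depth_range_um[0]) & (depths <= depth_range_um[1])
    if not in_range.any():
        raise ValueError("no channel within the depth window")
    sel = (t >= window_s[0]) & (t < window_s[1])
    if not sel.any():
        raise ValueError("no samples in the post-onset window")
    amp = np.max(np.abs(lfp[:, sel]), axis=1)
    amp[~in_range] = -np.inf
    return int(np.argmax(amp))


def morlet_cycles(freqs_hz: np.ndarray, f_lo: float = 0.5, f_hi: float = 80.0,
                  c_lo: float = 2.0, c_hi: float = 22.0) -> np.ndarray:
    """Cycle count per frequency, linear from (0.5 Hz, 2) to (80 Hz, 22)."""
    f = np.asarray(freqs_hz, float)
    return c_lo + (c_hi - c_lo) * (f - f_lo) / (f_hi - f_lo)


def morlet_power_db(lfp_trials: np.ndarray, fs_hz: float, onset_s: float,
                    freqs_hz: np.ndarray | None = None,
                    baseline_s: float = 0.400) -> tuple[np.ndarray, np.ndarray]:
    """Morlet time-frequency power, baseline-normalized in dB.

    Per-trial power is computed by Morlet-wavelet convolution over
    0.5-80 Hz with cycle counts varying linearly from 2 to 22, divided
    per frequency by its mean power over the 400 ms preceding stimulus
    onset, trial-averaged, then converted to 10*log10 dB.

    Parameters
    ----------
    lfp_trials:
        Array (n_trials, n_samples); time base starts at t = 0 with
        stimulus onset at ``onset_s``.

    Returns
    -------
    freqs_hz, power_db:
        Frequency axis and (n_freqs, n_samples) dB matrix.
    """
    from mne.time_frequency import tfr_array_morlet

    x = np.atleast_2d(np.asarray(lfp_trials, float))
    if freqs_hz is None:
        freqs_hz = np.linspace(0.5, 80.0, 40)
    freqs_hz = np.asarray(freqs_hz, float)
    n0 = int(round(onset_s * fs_hz))
    nb = int(round(baseline_s * fs_hz))
    if n0 - nb < 0:
        raise ValueError("trace must cover a 400-ms pre-onset baseline")
    cycles = morlet_cycles(freqs_hz)
    power = tfr_array_morlet(x[:, np.newaxis, :], sfreq=fs_hz,
                             freqs=freqs_hz, n_cycles=cycles,
                             output="power", zero_mean=True, verbose="error")
    power = power[:, 0, :, :]  # (n_trials, n_freqs, n_samples)
    base = power[:, :, n0 - nb:n0].mean(axis=2, keepdims=True)
    normalized = (power / base).mean(axis=0)
    return freqs_hz, 10.0 * np.log10(normalized)
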