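"""Synthetic data generators with known ground truth.

Every pipeline input can be emulated here: evoked-EPSC sweeps generated
from Tsodyks-Markram dynamics plus recording noise and slow drift;
orientation-tuned / oddball / familiarity-oscillation Poisson spike
sessions; and pupil-position traces with injected saccades.  Each
generator attaches the ground truth it planted, is fully deterministic
for a given seed, and draws all randomness from one explicit
``numpy.random.default_rng(seed)`` (no global RNG state).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit

from .epsc import EPSCSweep
from .pupil import PupilTrace, SaccadeEvent
from .tm import TMParams, _event_amplitudes
from .units import UnitSession

__all__ = [
    "ProtocolSpec",
    "NoiseSpec",
    "SpikeSessionSpec",
    "PupilSpec",
    "generate_epsc_sweeps",
    "generate_spike_session",
    "generate_pupil_trace",
]

#: paired-pulse intervals used in the slice experiments (ms)
PAIRED_PULSE_IPIS_MS = (10.0, 25.0, 50.0, 100.0, 150.0, 200.0, 250.0, 500.0, 1000.0)
#: six grating orientations (deg), evenly spaced on the 180-deg circle
ORIENTATIONS_DEG = (15.0, 45.0, 75.0, 105.0, 135.0, 165.0)


@dataclass(frozen=True)
class ProtocolSpec:
    """A stimulation protocol: paired pulse or fixed-frequency train."""

    kind: str = "train"              # {"paired_pulse", "train"}
    ipi_ms: float = 50.0             # paired-pulse inter-pulse interval
    freq_hz: float = 20.0            # train frequency
    n_pulses: int = 10
    n_repeats: int = 1
    inter_train_s: float = 30.0
    pulse_width_ms: float = 0.2
    pre_ms: float = 50.0             # quiet lead-in before the first pulse
    post_ms: float = 100.0           # tail after the last pulse

    def __post_init__(self) -> None:
        if self.kind not in ("paired_pulse", "train"):
            raise ValueError("kind must be 'paired_pulse' or 'train'")
        if self.kind == "paired_pulse" and self.n_pulses != 2:
            raise ValueError("paired_pulse protocols have exactly 2 pulses")
        if self.ipi_ms <= 0 or self.freq_hz <= 0 or self.pulse_width_ms <= 0:
            raise ValueError("intervals and frequency must be positive")
        if self.n_pulses < 1 or self.n_repeats < 1:
            raise ValueError("counts must be positive")
        if self.inter_train_s < 0:
            raise ValueError("inter_train_s must be nonnegative")

    def stim_times_s(self) -> np.ndarray:
        """Stimulus times within one sweep, starting at pre_ms."""
        t0 = self.pre_ms * 1e-3
        if self.kind == "paired_pulse":
            return np.array([t0, t0 + self.ipi_ms * 1e-3])
        return t0 + np.arange(self.n_pulses) / self.freq_hz

    def sweep_duration_s(self) -> float:
        return float(self.stim_times_s()[-1] + self.post_ms * 1e-3)


@dataclass(frozen=True)
class NoiseSpec:
    """Recording-noise model: white noise, slow drift, trial gain."""

    white_sd_pA: float = 5.0
    drift_amp_pA: float = 10.0
    drift_period_s: float = 5.0
    drift_slope_pA_s: float = 5.0
    trial_gain_cv: float = 0.0

    def __post_init__(self) -> None:
        if min(self.white_sd_pA, self.drift_amp_pA, self.trial_gain_cv) < 0:
            raise ValueError("noise magnitudes must be nonnegative")
        if self.drift_period_s <= 0:
            raise ValueError("drift_period_s must be positive")


def _epsc_kernel(t_s: np.ndarray, rise_ms: float, decay_ms: float) -> np.ndarray:
    """Unit-peak difference-of-exponentials EPSC waveform (t in s, >= 0)."""
    tr, td = rise_ms * 1e-3, decay_ms * 1e-3
    t_peak = np.log(td / tr) * tr * td / (td - tr)
    peak = np.exp(-t_peak / td) - np.exp(-t_peak / tr)
    g = np.where(t_s >= 0, np.exp(-np.clip(t_s, 0, None) / td)
                 - np.exp(-np.clip(t_s, 0, None) / tr), 0.0)
    return g / peak


def generate_epsc_sweeps(protocol: ProtocolSpec, tm: TMParams,
                         noise: NoiseSpec, fs_hz: float = 20_000.0,
                         seed: int = 0, rise_ms: float = 0.5,
                         snr_warn: bool = True) -> list[EPSCSweep]:
    """Generate EPSC sweeps from TM dynamics plus noise and drift.

    Each of ``protocol.n_repeats`` sweeps superposes one negative-going
    EPSC waveform per stimulus — a difference-of-exponentials kernel
    (``rise_ms`` rise, ``tm.tau_in_ms`` decay) normalized to unit peak —
    whose amplitude is the exact Tsodyks-Markram event-model release for
    that pulse.  The sweep is then scaled by a log-normal trial gain and
    contaminated with white noise and a slow sinusoid + linear-ramp
    drift.  The true noiseless per-pulse amplitudes (including the trial
    gain) are attached under ``meta["true_amps_pA"]``;
    ``meta["base_amps_pA"]`` holds the gain-free TM oracle amplitudes.
    """
    if fs_hz <= 0:
        raise ValueError("fs_hz must be positive")
    if fs_hz < 10.0 / (tm.tau_in_ms * 1e-3):
        raise ValueError("fs_hz must resolve tau_in (fs >= 10/tau_in)")
    if not 0 < rise_ms < tm.tau_in_ms:
        raise ValueError("rise_ms must lie in (0, tau_in_ms)")
    rng = np.random.default_rng(seed)
    stim = protocol.stim_times_s()
    dur = protocol.sweep_duration_s()

    t = np.arange(0.0, dur, 1.0 / fs_hz)
    current = np.zeros_like(t)
    if tm.A_SE_pA > 0:
        y_post, _, _ = _event_amplitudes(tm, stim)
        base_amps = tm.A_SE_pA * y_post
        for t_k, a_k in zip(stim, base_amps):
            current -= a_k * _epsc_kernel(t - t_k, rise_ms, tm.tau_in_ms)
    else:
        base_amps = np.zeros(len(stim))

    if snr_warn and noise.white_sd_pA > 0 and base_amps[0] < noise.white_sd_pA:
        warnings.warn("first-pulse SNR < 1; amplitudes may be unrecoverable")

    sweeps = []
    for k in range(protocol.n_repeats):
        if noise.trial_gain_cv > 0:
            # log-normal with unit mean and CV = trial_gain_cv
            s2 = np.log(1.0 + noise.trial_gain_cv ** 2)
            gain = float(rng.lognormal(mean=-s2 / 2, sigma=np.sqrt(s2)))
        else:
            gain = 1.0
        phase = rng.uniform(0, 2 * np.pi)
        drift = (noise.drift_amp_pA * np.sin(2 * np.pi * t / noise.drift_period_s
                                             + phase)
                 + noise.drift_slope_pA_s * t)
        white = rng.normal(0.0, noise.white_sd_pA, size=len(t)) \
            if noise.white_sd_pA > 0 else 0.0
        trace = gain * current + drift + white
        sweeps.append(EPSCSweep(
            time_s=t.copy(), current_pA=trace, fs_hz=fs_hz,
            stim_times_s=stim.copy(),
            meta={"protocol": protocol, "repeat": k, "gain": gain,
                  "true_amps_pA": gain * base_amps,
                  "base_amps_pA": base_amps.copy(),
                  "tm_params": tm}))
    return sweeps


@dataclass(frozen=True)
class SpikeSessionSpec:
    """Design of a synthetic single-unit recording session."""

    mode: str = "tuning"             # {"tuning", "oddball", "familiarity"}
    n_units: int = 20
    orientations_deg: tuple = ORIENTATIONS_DEG
    trials_per_condition: int = 50
    baseline_hz: float = 5.0
    peak_gain: float = 2.0           # evoked rate = baseline * (1 + gain * ...)
    tuning_sd_deg: float = 30.0
    adaptation_factor: float = 0.6   # redundant-trial evoked scaling
    deviant_gain: float = 1.5        # deviant late-response scaling
    osc_freq_hz: float = 5.0
    osc_decay_s: float = 0.4
    stim_dur_s: float = 0.5
    trial_span_s: tuple = (-0.5, 1.5)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.mode not in ("tuning", "oddball", "familiarity"):
            raise ValueError("unknown mode")
        if len(self.orientations_deg) != 6:
            raise ValueError("six orientations required")
        if not 0.0 <= self.adaptation_factor <= 1.0:
            raise ValueError("adaptation_factor must lie in [0, 1]")
        if min(self.n_units, self.trials_per_condition) < 1:
            raise ValueError("counts must be positive")
        if self.baseline_hz <= 0 or self.peak_gain < 0 or self.deviant_gain < 0:
            raise ValueError("rates/gains out of range")
        if self.osc_freq_hz <= 0 or self.osc_decay_s <= 0 or self.tuning_sd_deg <= 0:
            raise ValueError("oscillation/tuning parameters must be positive")


def _circ_dist_deg(a: float, b: float) -> float:
    """Distance on the 180-degree orientation circle."""
    d = abs(a - b) % 180.0
    return min(d, 180.0 - d)


def expected_rate(spec: SpikeSessionSpec, t: np.ndarray, condition: str,
                  pref_deg: float | None = None) -> np.ndarray:
    """Planted expected firing rate (Hz) over trial time for one condition.

    For tuning mode ``condition`` is the orientation (as string of the
    angle); for oddball mode one of control/redundant/deviant; for
    familiarity mode it is ignored.  Negative modulated rates are
    clipped at zero.
    """
    base = spec.baseline_hz
    rate = np.full_like(t, base, dtype=float)
    in_stim = (t >= 0) & (t < spec.stim_dur_s)
    if spec.mode == "tuning":
        ori = float(condition)
        assert pref_deg is not None
        d = _circ_dist_deg(ori, pref_deg)
        bump = spec.peak_gain * np.exp(-d ** 2 / (2 * spec.tuning_sd_deg ** 2))
        rate[in_stim] += base * bump
    elif spec.mode == "oddball":
        early = (t >= 0) & (t < 0.2)
        late = (t >= 0.2) & (t < spec.stim_dur_s)
        evoked = base * spec.peak_gain
        if condition == "control":
            rate[in_stim] += evoked
        elif condition == "redundant":
            rate[in_stim] += evoked * spec.adaptation_factor
        elif condition == "deviant":
            rate[early] += evoked * spec.adaptation_factor
            rate[late] += evoked * spec.adaptation_factor * spec.deviant_gain
        else:
            raise ValueError(f"unknown oddball condition {condition!r}")
    else:  # familiarity: decaying post-stimulus rate oscillation
        stim_dur = 0.2
        rate[(t >= 0) & (t < stim_dur)] += base * spec.peak_gain
        post = t >= stim_dur
        tp = t[post] - stim_dur
        osc = (spec.peak_gain * np.exp(-tp / spec.osc_decay_s)
               * 0.5 * (1 + np.cos(2 * np.pi * spec.osc_freq_hz * tp)))
        rate[post] += base * osc
    if np.any(rate < 0):
        warnings.warn("negative modulated rate clipped at zero")
        rate = np.clip(rate, 0, None)
    return rate


def generate_spike_session(spec: SpikeSessionSpec) -> UnitSession:
    """Inhomogeneous-Poisson spike session with planted structure.

    Tuning mode plants a Gaussian orientation-rate bump per unit (known
    preferred orientation); oddball mode scales redundant-trial evoked
    rates by ``adaptation_factor`` and deviant late responses by
    ``deviant_gain`` with deviants in 10% of oddball-sequence trials;
    familiarity mode adds a decaying post-stimulus rate oscillation at
    ``osc_freq_hz``.
    """
    rng = np.random.default_rng(spec.seed)
    dt = 1e-3
    t = np.arange(spec.trial_span_s[0], spec.trial_span_s[1], dt) + dt / 2

    # build the trial table
    trial_rows = []
    if spec.mode == "tuning":
        conds = [str(o) for o in spec.orientations_deg
                 for _ in range(spec.trials_per_condition)]
    elif spec.mode == "oddball":
        n_odd = 10 * spec.trials_per_condition
        conds = (["control"] * spec.trials_per_condition
                 + ["redundant"] * (n_odd - n_odd // 10)
                 + ["deviant"] * (n_odd // 10))
    else:
        conds = ["familiar"] * spec.trials_per_condition
    rng.shuffle(conds)
    for i, c in enumerate(conds):
        trial_rows.append({"trial_id": i, "condition": c, "onset_s": 2.0 * i})
    trials = pd.DataFrame(trial_rows)

    prefs = rng.choice(spec.orientations_deg, size=spec.n_units)
    spike_rows = {"unit_id": [], "trial_id": [], "time_s": []}
    total_spikes = np.zeros(spec.n_units)
    span = spec.trial_span_s[1] - spec.trial_span_s[0]
    cond_trials = {c: trials.loc[trials["condition"] == c, "trial_id"].to_numpy()
                   for c in trials["condition"].unique()}
    for u in range(spec.n_units):
        for c, tids in cond_trials.items():
            lam = expected_rate(spec, t, c, pref_deg=prefs[u]) * dt
            counts = rng.poisson(lam, size=(len(tids), len(t)))
            rows, cols = np.nonzero(counts)
            reps = counts[rows, cols]
            rows = np.repeat(rows, reps)
            cols = np.repeat(cols, reps)
            if len(cols):
                times = t[cols] + rng.uniform(-dt / 2, dt / 2, size=len(cols))
                spike_rows["unit_id"].extend([u] * len(cols))
                spike_rows["trial_id"].extend(tids[rows])
                spike_rows["time_s"].extend(times)
                total_spikes[u] += len(cols)
    spikes = pd.DataFrame(spike_rows)
    mean_rate = total_spikes / (len(trials) * span)
    unit_meta = pd.DataFrame({"unit_id": np.arange(spec.n_units),
                              "mean_rate_hz": mean_rate})
    gt = {"spec": spec, "preferred_deg": prefs,
          "osc_freq_hz": spec.osc_freq_hz if spec.mode == "familiarity" else None}
    return UnitSession(spikes=spikes, trials=trials, unit_meta=unit_meta,
                       ground_truth=gt)


@dataclass(frozen=True)
class PupilSpec:
    """Design of a synthetic pupil trace with injected saccades."""

    fs_hz: float = 100.0
    duration_s: float = 10.0
    pursuit_freq_hz: float = 0.1
    pursuit_amp_px: float = 5.0
    saccade_times_s: tuple = ()
    saccade_amps_px: tuple = ()
    saccade_rise_ms: float = 10.0
    jitter_sd_px: float = 0.0
    diameter_px: float = 30.0
    outlier_diam_frac: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.fs_hz <= 0 or self.duration_s <= 0 or self.saccade_rise_ms <= 0:
            raise ValueError("fs, duration, rise time must be positive")
        if not 0.0 <= self.outlier_diam_frac <= 1.0:
            raise ValueError("outlier_diam_frac must lie in [0, 1]")
        if len(self.saccade_times_s) != len(self.saccade_amps_px):
            raise ValueError("one amplitude per saccade time")
        times = np.sort(np.asarray(self.saccade_times_s, float))
        if len(times) and (times[0] < 0 or times[-1] > self.duration_s):
            raise ValueError("saccade times must lie within the trace")
        if len(times) > 1 and np.min(np.diff(times)) <= 3 * self.saccade_rise_ms * 1e-3:
            raise ValueError("saccades overlap (separation <= 3x rise time)")


def generate_pupil_trace(spec: PupilSpec) -> PupilTrace:
    """Pupil x-trace = pursuit sinusoid + sigmoidal saccade steps + jitter.

    Ground-truth saccade events (onset, offset, amplitude) are attached
    under ``meta["true_saccades"]``; the diameter channel sits at
    ``diameter_px`` with ``outlier_diam_frac`` of samples pushed outside
    the (10, 50) px plausibility gate.
    """
    rng = np.random.default_rng(spec.seed)
    n = int(round(spec.duration_s * spec.fs_hz))
    t = np.arange(n) / spec.fs_hz
    x = spec.pursuit_amp_px * np.sin(2 * np.pi * spec.pursuit_freq_hz * t)

    rise_s = spec.saccade_rise_ms * 1e-3
    truth = []
    for t0, amp in zip(spec.saccade_times_s, spec.saccade_amps_px):
        # logistic step completing (5%..95%) within the rise time
        s = rise_s / 6.0
        x = x + amp * expit((t - t0) / s)
        truth.append(SaccadeEvent(onset_s=t0 - rise_s / 2,
                                  offset_s=t0 + rise_s / 2,
                                  amplitude_px=abs(amp),
                                  max_velocity_px_s=abs(amp) / rise_s))
    if spec.jitter_sd_px > 0:
        x = x + rng.normal(0.0, spec.jitter_sd_px, size=n)
    y = np.zeros(n)
    d = np.full(n, spec.diameter_px)
    if spec.outlier_diam_frac > 0:
        n_out = int(round(spec.outlier_diam_frac * n))
        out_idx = rng.choice(n, size=n_out, replace=False)
        d[out_idx] = 60.0
    return PupilTrace(time_s=t, x_px=x, y_px=y, diameter_px=d,
                      fs_hz=spec.fs_hz,
                      meta={"spec": spec, "true_saccades": truth})
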