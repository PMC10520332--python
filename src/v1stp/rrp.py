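"""Readily-releasable-pool estimation via the SMN cumulative-EPSC method.

The Schneggenburger-Meyer-Neher (SMN) estimator fits a straight line to
the steady-state tail of the cumulative per-pulse EPSC amplitudes of a
high-frequency train.  The back-extrapolated intercept at pulse index 0
is proportional to the size of the readily releasable pool (RRP) and
the slope to its replenishment rate.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import linregress

from .epsc import PulseAmplitudes
from .tm import TMFit, TMParams, _event_amplitudes

__all__ = ["RRPEstimate", "cumulative_peaks", "smn_linear_fit", "smn_on_model"]


@dataclass
class RRPEstimate:
    """Intercept/slope/R^2 of the steady-state cumulative-EPSC line."""

    intercept_pA: float
    slope_pA_per_pulse: float
    r2: float
    steady_pulses: list[int]


def cumulative_peaks(amps: PulseAmplitudes | np.ndarray) -> np.ndarray:
    """Cumulative sum of per-pulse amplitude magnitudes (nondecreasing)."""
    a = amps.amps_pA if isinstance(amps, PulseAmplitudes) else np.asarray(amps, float)
    if len(a) < 2:
        raise ValueError("need at least 2 pulses")
    if np.any(a < 0):
        raise ValueError("amplitudes must be nonnegative magnitudes")
    return np.cumsum(a)


def smn_linear_fit(cum: np.ndarray, n_steady: int = 5) -> RRPEstimate:
    """OLS of cumulative amplitude on 1-based pulse index over the tail.

    The last ``n_steady`` pulses are regressed and the line is
    back-extrapolated to index 0 for the intercept (the RRP-size proxy);
    the slope (pA/pulse) is the replenishment-rate proxy.
    """
    cum = np.asarray(cum, dtype=float)
    n = len(cum)
    if n_steady < 2:
        raise ValueError("n_steady must be >= 2 for a non-singular fit")
    if n_steady >= n:
        raise ValueError("n_steady must be smaller than the pulse count")
    idx = np.arange(n - n_steady + 1, n + 1)  # 1-based pulse indices
    y = cum[-n_steady:]
    res = linregress(idx, y)
    if np.ptp(y) == 0:
        r2 = 1.0  # a flat tail is fit exactly by a horizontal line
    else:
        r2 = float(res.rvalue ** 2)
    return RRPEstimate(intercept_pA=float(res.intercept),
                       slope_pA_per_pulse=float(res.slope),
                       r2=r2,
                       steady_pulses=[int(i) for i in idx])


def smn_on_model(fit: TMFit, stim_times_s: np.ndarray,
                 n_steady: int = 5) -> RRPEstimate:
    """Run the SMN estimator on a fitted TM model's simulated train.

    Cross-validates the data-side SMN estimate: the fitted model is
    driven by the same protocol, its per-pulse amplitudes cumulated and
    the steady-state line refit.
    """
    if not fit.converged:
        raise ValueError("refusing to cross-validate a non-converged fit")
    stim = np.asarray(stim_times_s, dtype=float)
    y_post, _, _ = _event_amplitudes(fit.params, stim)
    amps = fit.params.A_SE_pA * y_post
    return smn_linear_fit(np.cumsum(amps), n_steady=n_steady)
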