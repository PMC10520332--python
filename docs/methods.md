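# Methods

This note documents the models implemented in `v1stp`, their
assumptions, parameter defaults, what the synthetic generators do and
do not emulate, the numerical choices, and known limitations. All
quantitative statements below are either definitions or values computed
by the test suite / acceptance script.

## 1. Synapse models

### 1.1 Three-state Tsodyks–Markram model (slice electrophysiology)

Resources partition into recovered (x), active (y) and inactive (z)
fractions with x + y + z = 1. A pre-synaptic spike instantaneously
moves `U_SE · x` from x to y; between spikes

```
dy/dt = −y/τ_in,   dz/dt = y/τ_in − z/τ_rec,   x = 1 − y − z
```

and the synaptic current is `I(t) = −A_SE · y(t)` (negative-going
EPSC). `simulate_tm_train` integrates this with the **exact
exponential solution** of the linear system between spikes (no ODE
solver error); the returned trace is the exact solution sampled on a
uniform grid. An optional facilitation variable u
(`u ← u + U_SE(1 − u)` per spike, decaying with τ_facil) replaces the
constant U_SE when `tau_facil_ms` is set.

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| `A_SE_pA` | pA | (fit/user) | absolute synaptic efficacy; peak current if all resources were released at once |
| `U_SE` | – | (fit/user) | utilization per spike, bounded to (0, 1) |
| `tau_recovery_ms` | ms | (fit/user) | inactive → recovered refill time constant |
| `tau_in_ms` | ms | 3.0 | EPSC decay (inactivation) time constant; typical fast AMPA kinetics |
| `tau_facil_ms` | ms | None | facilitation decay; None = depression-only |

### 1.2 Discrete release map (independent oracle)

When `1/freq ≫ τ_in` the active/inactive states empty between pulses
and the per-pulse amplitudes follow the closed-form map

```
a_k = A_SE · U · x_k,   x_{k+1} = 1 − (1 − x_k (1 − U)) e^(−T/τ_rec)
```

with the identity `a_2/a_1 = 1 − U·e^(−T/τ_rec)` and fixed point
`(1 − e^(−T/τ)) / (1 − (1 − U)e^(−T/τ))` relative to pulse 1.
`tm_discrete_peaks` refuses trains with `T < 3·τ_in`. The
oracle-equivalence acceptance test compares simulator and map at
**τ_in = 0.5 ms** so that `T/τ_in ≥ 40` even at 50 Hz; at the
physiological τ_in = 3 ms the 50-Hz train violates the map's own
validity premise and the 1% / 10⁻³ equivalence bounds do not apply
(measured 1.05% and 3.7·10⁻³ there — an expected property of the map,
not a simulator defect).

### 1.3 Parameter fitting

`fit_tm_parameters` minimizes squared error over (A_SE, U_SE, τ_rec)
with `scipy.optimize.least_squares` from a 4×4 grid of starts
(U ∈ {0.05, 0.2, 0.5, 0.8} × τ ∈ {50, 150, 300, 1000} ms), bounds
U ∈ [0.01, 0.99], τ ∈ [10, 5000] ms, A ∈ (0, 10·max|data|]. Fits on
two pulses are flagged `converged=False` (τ unidentifiable); `mse` is
the mean squared residual of the best start.

### 1.4 Two-variable network synapse

The network uses the reduced per-synapse state (u, x) with exact
exponential inter-spike decay and the spike updates
`u ← u + U(1 − u)`, `r = u·x`, `x ← x − r`; `r` scales the synaptic
weight delivered to the target conductance. From rest the first spike
releases exactly `r = U = 0.2` (acceptance target t4).

## 2. EPSC analysis pipeline

1. **Smoothing** — Savitzky–Golay filter, window 11 samples,
   order 3 (at 20 kHz: 0.55 ms window, preserves ~1-ms EPSC rise).
2. **Detrending** — a PCHIP interpolation through 2-ms baseline
   anchors (centroid-timed, immediately before each stimulus and at
   the sweep ends) is subtracted; exact for linear drift.
3. **Amplitude** — per pulse, `baseline mean − minimum` in the window
   (stim + 0.5 ms, stim + min(IPI, 25 ms)]; the first 0.5 ms is
   blanked as the stimulus-artifact region.
4. **Ratios** — PPR = a₂/a₁ (two-pulse sweeps), MPR_k = a_k/a₁.
   Amplitudes below 10⁻⁶ pA in the denominator raise
   `ZeroDivisionError`. Across repeats, amplitudes are averaged
   **before** ratios are formed.

Measured pipeline performance (frozen in `tests/test_epsc.py`): at
trace SNR 10 (first amplitude / white-noise SD), median |PPR error| is
≈ 0.035 (regression bound 0.045); at SNR 20 it is ≈ 0.018 (< 0.03).

## 3. SMN readily-releasable-pool estimate

Cumulative per-pulse amplitudes are regressed (OLS) on the 1-based
pulse index over the final `n_steady = 5` pulses and back-extrapolated
to index 0. The intercept estimates the RRP size (in current units),
the slope the steady replenishment per pulse. The estimator is
scale-equivariant and its slope decreases monotonically with τ_rec.
**Caveat**: with 10-pulse 20-Hz trains the cumulative curve is not yet
linear at pulse 6, so the recovery time constant leaks into the
intercept; groups differing only in τ_rec (300 vs 200 ms) show a ~30%
intercept difference even on noiseless model data (computed in
`tests/test_rrp.py` / `tests/test_acceptance.py`). Intercepts are
comparable across cells at fixed τ_rec, not across τ_rec contrasts.

## 4. V1 network model

Conductance-based leaky integrate-and-fire network:

```
Cm dv/dt = gl(El − v) + ge(Ee − v) + gi(Ei − v)
```

with exponential conductance decay, threshold Vth, reset to v_reset,
absolute refractory period τ_ref. Every synapse (thalamocortical,
recurrent excitatory, inhibitory) carries the two-variable TM state.

| Parameter | Units | Default | Rationale |
|---|---|---|---|
| `n_exc / n_inh / n_input` | – | 3200 / 800 / 3000 | 4:1 cortical E/I ratio plus thalamic drive |
| `Cm_pF` | pF | 350 | membrane capacitance |
| `gl_nS` | nS | 20 | leak; τ_m = Cm/gl = 17.5 ms |
| `El_mV`, `v_reset_mV` | mV | −72 | rest; reset to rest |
| `Ee_mV / Ei_mV` | mV | 0 / −80 | AMPA / GABA_A reversal |
| `Vth_mV` | mV | −55 | spike threshold |
| `tau_e_ms / tau_i_ms` | ms | 5 / 10 | conductance decay |
| `tau_ref_ms` | ms | 1 | refractory period |
| `we_nS / wi_nS` | nS | 1 / 5 | recurrent weights |
| `U` | – | 0.2 | synaptic utilization |
| `p_in / p_e / p_i` | – | 0.04 / 0.025 / 0.05 | Bernoulli connection probabilities |
| `tau_facil_ms / tau_rec_ms` | ms | 20 / 300 (WT); 10 / 200 (KO preset) | the only genotype difference |
| `dt_ms` | ms | 0.1 | forward-Euler step (validated: τ_m relaxation within 0.3% of exact) |
| `w_in_nS` | nS | None (= we_nS) | thalamocortical weight override, see below |

Input drive: each of the 3000 thalamocortical sources fires Poisson at
10 Hz baseline, rising to 20 Hz under a 200-ms Hanning window after a
500-ms baseline, with a 300-ms post period. The population rate is
binned at 1 ms, converted to per-neuron Hz, z-scored against the
baseline window and smoothed with a 10-ms Gaussian.

**Operating-point note**: with `w_in = we = 1 nS` the mean afferent
conductance keeps every neuron well below rheobase and the network is
silent; the z-scored rate is then undefined (the code returns NaN and
the zero-baseline case raises in `normalized_population_rate`). The
dynamical tests therefore run with `w_in_nS = 5` on population-scaled
configurations; `NetworkConfig.scaled(f)` shrinks populations by `f`
while scaling connection probabilities up so each neuron keeps its
expected in-degree.

## 5. In-vivo unit / LFP metrics

- **Rates**: 1-ms spike histograms over trials, divided by
  (n_trials·bin), convolved with a unit-area Gaussian (SD 50 ms).
- **Baseline z**: (FR − mean FR₀)/SD FR₀ over [onset − 0.2 s, onset).
- **Good units**: mean session rate strictly > 0.5 Hz.
- **Tuning**: preferred orientation = argmax over the six orientations
  (15°…165°); OSI = (R_pref − R_orth)/(R_pref + R_orth) on
  nonnegativity-clipped responses; a Gaussian `A·e^{−(x−μ)²/2σ²}+b` is
  fitted on the normalized-angle index axis (preferred at index 0,
  indices −2…3), good fits have R² > 0.95.
- **Oddball**: adaptation compares control vs redundant peak rates in
  [0, 0.5) s; mismatch compares deviant vs redundant peaks in
  [0.2, 0.5) s, excluding sub-200-ms onset transients.
- **Oscillations**: local maxima of the z-scored rate ≥ 0.5 z and
  ≥ 100 ms apart (greedy by descending amplitude via
  `scipy.signal.find_peaks`); frequency = mean inverse inter-peak
  interval.
- **Layer-4 LFP**: among channels 300–500 µm deep, the one with the
  largest peak |LFP| in [50, 150) ms post-onset.
- **Morlet power**: wavelet convolution over 0.5–80 Hz with cycle
  counts linear from 2 (0.5 Hz) to 22 (80 Hz) (`mne`), per-frequency
  division by the mean power in the 400 ms before onset, trial
  averaging, then 10·log₁₀ dB.

## 6. Pupillometry

Pupil landmarks are reduced to a circle by the algebraic (Kåsa)
least-squares fit. Center/diameter traces are median-filtered
(11 samples); samples with filtered diameter outside 10–50 px are
invalid, and traces > 50% invalid are unusable. Saccade onset requires
inter-sample velocity > 40 px/s **and** incoming acceleration
> 340 px/s²; the offset is the next sample below the velocity
threshold; events closer than 2 samples merge; no event spans an
invalid gap. Session statistics exclude trials with fewer than two
detected saccades. A 10-px one-sample step at 100 Hz yields exactly
one event with max velocity 1000 px/s (worked example in the tests).

## 7. Synthetic generators

All generators are deterministic per seed (one
`numpy.random.default_rng(seed)`, no global state) and attach their
planted ground truth.

- **EPSC sweeps**: exact TM event-model amplitudes drive unit-peak
  difference-of-exponentials kernels (0.5-ms rise, τ_in decay) so the
  true peak survives the pipeline's 0.5-ms artifact blanking; noise =
  white Gaussian + sinusoid-plus-ramp drift + log-normal trial gain.
  *Not emulated*: stimulus artifacts, series-resistance changes,
  spontaneous EPSCs, line noise.
- **Spike sessions**: inhomogeneous Poisson spikes from planted rate
  profiles (Gaussian orientation tuning; oddball adaptation 0.6 and
  deviant late-window gain 1.5 with 10% deviants; familiarity-mode
  decaying rate oscillation). *Not emulated*: refractoriness, spike
  sorting errors, inter-neuron correlations, bursting.
- **Pupil traces**: slow pursuit sinusoid + logistic saccade steps
  (10-ms rise) + Gaussian jitter; diameter outliers push a chosen
  fraction of samples outside the plausibility gate. *Not emulated*:
  blinks, pupil foreshortening, camera dropouts.

## 8. Numerical choices

- Exact exponential solutions for all linear inter-event dynamics
  (synapse states, conductances); forward Euler only for the membrane
  voltage (dt = 0.1 ms, relative error 0.3% at t = τ_m, verified).
- Synapses stored in CSR layout grouped by pre-synaptic source;
  event-driven updates touch a synapse only when its source fires.
- A |v| > 200 mV guard raises `FloatingPointError` on divergence.
- Hypothesis-based property tests run a derandomized profile.

## 9. Limitations

1. **SMN intercept contrast** — the intercept clause of the genotype
   direction test (< 10% intercept difference between τ_rec 200 and
   300 ms groups) fails by design: measured ≈ 28–30% (§3). The slope
   direction (KO-like > WT-like in ≥ 95% of pairs) holds.
2. **Noisy τ_recovery recovery** — with 5% multiplicative amplitude
   noise on 10-pulse 20-Hz trains, the median relative τ_rec error is
   ≈ 0.13 (0.083–0.162 across 20 independent 50-replicate
   experiments), above the 10% goal: the train spans only ~1.5 τ_rec,
   so τ is weakly identified at that noise level (3% noise passes at
   ≈ 0.07). The corresponding acceptance assertion is retained and
   fails.
3. **Saccade detection under jitter** — at 0.5-px tracking jitter the
   40 px/s velocity threshold (noise velocity SD ≈ 27 px/s at 100 Hz)
   produces several false positives per 10-s trial; the ≤ 0.05
   FP/trial guarantee holds at ≤ 0.1-px jitter (tested) and at the
   generator default (no jitter).
4. **Network regime** — at the default single excitatory weight the
   model network is silent (§4); dynamics are demonstrated with a
   raised thalamocortical weight on scaled populations.
5. The map-vs-simulator equivalence bounds hold in the map's validity
   regime (τ_in ≪ T), not at τ_in = 3 ms for 50-Hz trains (§1.2).
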