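"""Conductance-based LIF network of V1 with short-term-plastic synapses.

The model is 3200 excitatory and 800 inhibitory leaky integrate-and-fire
neurons receiving Poisson drive from 3000 thalamocortical inputs whose
rate is shaped by a 200-ms Hanning bump between 10 and 20 Hz.  Each
synapse carries a simplified two-variable Tsodyks-Markram state: the
running release probability u (incremented by U*(1-u) per pre-synaptic
spike, decaying with tau_facil) and the available resource fraction x
(depleted by the release u*x, recovering with tau_rec).  On a
pre-synaptic spike the release fraction r = u*x increments the target's
excitatory or inhibitory conductance by r*w.

Membrane dynamics:  Cm dv/dt = gl (El - v) + ge (Ee - v) + gi (Ei - v),
with exponential conductance decay (tau_e, tau_i), threshold Vth, reset
to v_reset and a 1-ms refractory period.  Genotype presets differ only
in tau_facil (20 ms wild type, 10 ms auxilin knockout) and tau_rec
(300 ms vs 200 ms), modelling the knockout's reduced facilitation and
faster vesicle-pool recovery.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "NetworkConfig",
    "SynapseState",
    "Network",
    "SimResult",
    "build_network",
    "tm_synapse_step",
    "synapse_release_train",
    "run_simulation",
    "normalized_population_rate",
    "genotype_comparison",
]


@dataclass(frozen=True)
class NetworkConfig:
    """Model parameters; defaults are the wild-type configuration."""

    n_exc: int = 3200
    n_inh: int = 800
    n_input: int = 3000
    Cm_pF: float = 350.0
    El_mV: float = -72.0
    Ee_mV: float = 0.0
    Ei_mV: float = -80.0
    gl_nS: float = 20.0
    Vth_mV: float = -55.0
    v_reset_mV: float = -72.0   # reset to rest
    tau_e_ms: float = 5.0
    tau_i_ms: float = 10.0
    tau_ref_ms: float = 1.0
    we_nS: float = 1.0
    wi_nS: float = 5.0
    U: float = 0.2
    p_in: float = 0.04
    p_e: float = 0.025
    p_i: float = 0.05
    tau_facil_ms: float = 20.0
    tau_rec_ms: float = 300.0
    dt_ms: float = 0.1
    rate_lo_hz: float = 10.0
    rate_hi_hz: float = 20.0
    hanning_ms: float = 200.0
    baseline_ms: float = 500.0
    post_ms: float = 300.0
    n_seeds: int = 10
    plastic_inhibition: bool = True
    #: thalamocortical synaptic weight; None means equal to we_nS.  At
    #: the default single excitatory weight the mean afferent conductance
    #: stays well below rheobase; raising this puts the network in a
    #: fluctuation-driven spiking regime.
    w_in_nS: float | None = None

    def __post_init__(self) -> None:
        for p in (self.p_in, self.p_e, self.p_i):
            if not 0.0 <= p <= 1.0:
                raise ValueError("connection probabilities must lie in [0, 1]")
        if not 0.0 < self.U < 1.0:
            raise ValueError("U must lie in (0, 1)")
        if self.dt_ms <= 0:
            raise ValueError("dt_ms must be positive")
        if self.dt_ms > min(self.tau_e_ms, self.tau_i_ms, self.tau_facil_ms,
                            self.tau_rec_ms) / 10:
            raise ValueError("dt_ms must be <= min(tau)/10")

    @property
    def n_cortex(self) -> int:
        return self.n_exc + self.n_inh

    @classmethod
    def wildtype(cls, **overrides) -> "NetworkConfig":
        return cls(**overrides)

    @classmethod
    def auxko(cls, **overrides) -> "NetworkConfig":
        """Auxilin-knockout preset: faster facilitation decay and recovery."""
        overrides.setdefault("tau_facil_ms", 10.0)
        overrides.setdefault("tau_rec_ms", 200.0)
        return cls(**overrides)

    def scaled(self, factor: float) -> "NetworkConfig":
        """Shrink population sizes by ``factor`` for fast runs.

        Connection probabilities are scaled up (capped at 1) so each
        neuron keeps its expected in-degree and operating point.
        """
        return replace(self,
                       n_exc=max(1, int(self.n_exc / factor)),
                       n_inh=max(1, int(self.n_inh / factor)),
                       n_input=max(1, int(self.n_input / factor)),
                       p_in=min(1.0, self.p_in * factor),
                       p_e=min(1.0, self.p_e * factor),
                       p_i=min(1.0, self.p_i * factor))


@dataclass
class SynapseState:
    """Two-variable TM synapse state."""

    u: float = 0.0
    x: float = 1.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.u <= 1.0 and 0.0 <= self.x <= 1.0):
            raise ValueError("u and x must lie in [0, 1]")


def tm_synapse_step(state: SynapseState, dt_since_last_spike_ms: float,
                    spike: bool, config: NetworkConfig
                    ) -> tuple[SynapseState, float]:
    """Advance one synapse and return the released fraction.

    Between spikes u decays toward 0 with tau_facil and x recovers
    toward 1 with tau_rec (exact exponentials).  On a spike:
    u <- u + U (1 - u), then r = u * x, then x <- x - r.
    """
    if dt_since_last_spike_ms < 0:
        raise ValueError("dt must be nonnegative")
    u = state.u * np.exp(-dt_since_last_spike_ms / config.tau_facil_ms)
    x = 1.0 - (1.0 - state.x) * np.exp(-dt_since_last_spike_ms / config.tau_rec_ms)
    r = 0.0
    if spike:
        u = u + config.U * (1.0 - u)
        r = u * x
        x = x - r
    return SynapseState(u=float(u), x=float(x)), float(r)


def synapse_release_train(config: NetworkConfig, freq_hz: float,
                          n_pulses: int) -> np.ndarray:
    """Release fractions of one synapse probed at a fixed rate from rest."""
    state = SynapseState()
    T = 1e3 / freq_hz
    rel = np.empty(n_pulses)
    for k in range(n_pulses):
        state, rel[k] = tm_synapse_step(state, 0.0 if k == 0 else T, True, config)
    return rel


@dataclass
class Network:
    """Connectivity plus per-synapse plasticity state.

    Synapses are stored grouped by pre-synaptic neuron in CSR layout:
    for presynaptic source s (inputs first, then cortex), its targets
    are ``targets[offsets[s]:offsets[s+1]]`` with matching slices of the
    u and x state arrays.
    """

    config: NetworkConfig
    seed: int
    offsets: np.ndarray
    targets: np.ndarray
    u: np.ndarray
    x: np.ndarray

    @property
    def n_sources(self) -> int:
        return len(self.offsets) - 1

    def out_slice(self, source: int) -> slice:
        return slice(self.offsets[source], self.offsets[source + 1])


def build_network(config: NetworkConfig, seed: int) -> Network:
    """Draw Bernoulli connectivity and initialise synapses at rest.

    Sources are indexed inputs [0, n_input), then excitatory cortex,
    then inhibitory cortex.  Each ordered (source, target) pair carries
    at most one synapse; cortical self-connections are excluded.
    """
    rng = np.random.default_rng(seed)
    nc = config.n_cortex
    offsets = [0]
    target_chunks = []
    probs = ([config.p_in] * config.n_input
             + [config.p_e] * config.n_exc
             + [config.p_i] * config.n_inh)
    for s, p in enumerate(probs):
        mask = rng.random(nc) < p
        if s >= config.n_input:
            mask[s - config.n_input] = False  # no autapses
        tgt = np.flatnonzero(mask).astype(np.int32)
        target_chunks.append(tgt)
        offsets.append(offsets[-1] + len(tgt))
    targets = (np.concatenate(target_chunks) if target_chunks
               else np.empty(0, np.int32))
    n_syn = len(targets)
    return Network(config=config, seed=seed,
                   offsets=np.asarray(offsets, dtype=np.int64),
                   targets=targets,
                   u=np.zeros(n_syn), x=np.ones(n_syn))


@dataclass
class SimResult:
    """Raster plus normalized population rate of one simulation run."""

    spike_neurons: np.ndarray
    spike_times_ms: np.ndarray
    pop_rate_time_ms: np.ndarray
    pop_rate_norm: np.ndarray
    seed: int
    genotype: str = ""
    config: NetworkConfig = field(default_factory=NetworkConfig)
    v_final_mV: np.ndarray | None = None
    v_trace_mV: np.ndarray | None = None   # neuron 0, when recorded


def _input_rate_profile(config: NetworkConfig, n_steps: int) -> np.ndarray:
    """Common thalamocortical rate (Hz) per time step."""
    rate = np.full(n_steps, config.rate_lo_hz)
    i0 = int(round(config.baseline_ms / config.dt_ms))
    nh = int(round(config.hanning_ms / config.dt_ms))
    i1 = min(i0 + nh, n_steps)
    w = np.hanning(nh)
    rate[i0:i1] = config.rate_lo_hz + (config.rate_hi_hz - config.rate_lo_hz) * w[: i1 - i0]
    return rate


def run_simulation(network: Network, seed: int | None = None,
                   external_conductances: tuple[float, float] | None = None,
                   v_init_mV: float | np.ndarray | None = None,
                   record_v: bool = False) -> SimResult:
    """Integrate the network over baseline + Hanning stimulus + post.

    Forward-Euler membrane integration at dt = 0.1 ms; conductances and
    synapse variables decay with exact exponentials; synapse states are
    updated event-wise at pre-synaptic spikes only.

    ``external_conductances`` optionally clamps (ge, gi) in nS for all
    neurons, silencing synaptic input (diagnostic use);
    ``v_init_mV`` overrides the resting initial condition and
    ``record_v`` stores neuron 0's membrane trace on the result.
    """
    cfg = network.config
    rng = np.random.default_rng(network.seed if seed is None else seed)
    dt = cfg.dt_ms
    duration_ms = cfg.baseline_ms + cfg.hanning_ms + cfg.post_ms
    n_steps = int(round(duration_ms / dt))
    nc = cfg.n_cortex

    v = np.full(nc, cfg.El_mV)
    if v_init_mV is not None:
        v[:] = v_init_mV
    v_trace = np.empty(n_steps) if record_v else None
    ge = np.zeros(nc)
    gi = np.zeros(nc)
    if external_conductances is not None:
        ge[:] = external_conductances[0]
        gi[:] = external_conductances[1]
    refrac_until = np.full(nc, -np.inf)
    t_last = np.zeros(network.n_sources)  # last spike time per source

    w_in = cfg.w_in_nS if cfg.w_in_nS is not None else cfg.we_nS
    dec_e = np.exp(-dt / cfg.tau_e_ms)
    dec_i = np.exp(-dt / cfg.tau_i_ms)
    rate = _input_rate_profile(cfg, n_steps)

    spike_neurons: list[np.ndarray] = []
    spike_times: list[np.ndarray] = []
    counts = np.zeros(n_steps)

    # work on copies so a Network can be re-run reproducibly
    u, x = network.u.copy(), network.x.copy()
    offs, tgts = network.offsets, network.targets
    is_inh_source = np.zeros(network.n_sources, bool)
    is_inh_source[cfg.n_input + cfg.n_exc:] = True

    def deliver(sources: np.ndarray, t_now: float) -> None:
        for s in sources:
            sl = network.out_slice(int(s))
            if sl.start == sl.stop:
                t_last[s] = t_now
                continue
            d = t_now - t_last[s]
            inhibitory = is_inh_source[s]
            if cfg.plastic_inhibition or not inhibitory:
                u[sl] *= np.exp(-d / cfg.tau_facil_ms)
                x[sl] = 1.0 - (1.0 - x[sl]) * np.exp(-d / cfg.tau_rec_ms)
                u[sl] += cfg.U * (1.0 - u[sl])
                r = u[sl] * x[sl]
                x[sl] -= r
            else:
                r = np.ones(sl.stop - sl.start)
            t_last[s] = t_now
            if inhibitory:
                np.add.at(gi, tgts[sl], r * cfg.wi_nS)
            elif s < cfg.n_input:
                np.add.at(ge, tgts[sl], r * w_in)
            else:
                np.add.at(ge, tgts[sl], r * cfg.we_nS)

    for step in range(n_steps):
        t_now = step * dt
        if external_conductances is None:
            # thalamocortical Poisson drive
            p = rate[step] * dt * 1e-3
            in_spk = np.flatnonzero(rng.random(cfg.n_input) < p)
            deliver(in_spk, t_now)

        # membrane update (refractory neurons clamped)
        current = (cfg.gl_nS * (cfg.El_mV - v) + ge * (cfg.Ee_mV - v)
                   + gi * (cfg.Ei_mV - v))
        active = t_now >= refrac_until
        v[active] += dt / cfg.Cm_pF * current[active]
        if np.any(np.abs(v) > 200.0):
            raise FloatingPointError(
                f"membrane potential diverged at t={t_now:.1f} ms")

        fired = np.flatnonzero(active & (v >= cfg.Vth_mV))
        if len(fired):
            v[fired] = cfg.v_reset_mV
            refrac_until[fired] = t_now + cfg.tau_ref_ms
            spike_neurons.append(fired)
            spike_times.append(np.full(len(fired), t_now))
            counts[step] = len(fired)
            if external_conductances is None:
                deliver(fired + cfg.n_input, t_now)

        if external_conductances is None:
            ge *= dec_e
            gi *= dec_i
        if record_v:
            v_trace[step] = v[0]

    neurons = (np.concatenate(spike_neurons) if spike_neurons
               else np.empty(0, int))
    times = (np.concatenate(spike_times) if spike_times
             else np.empty(0, float))
    try:
        t_ms, z = normalized_population_rate(
            counts, cfg, baseline_window_ms=(0.0, cfg.baseline_ms))
    except ZeroDivisionError:
        # silent baseline (e.g. diagnostic clamp runs): z-score undefined
        t_ms = (np.arange(int(duration_ms)) + 0.5)
        z = np.full(len(t_ms), np.nan)
    return SimResult(spike_neurons=neurons, spike_times_ms=times,
                     pop_rate_time_ms=t_ms, pop_rate_norm=z,
                     seed=network.seed if seed is None else seed,
                     config=cfg, v_final_mV=v.copy(), v_trace_mV=v_trace)


def normalized_population_rate(step_counts: np.ndarray, config: NetworkConfig,
                               baseline_window_ms: tuple[float, float],
                               bin_ms: float = 1.0,
                               smooth_sigma_ms: float = 10.0
                               ) -> tuple[np.ndarray, np.ndarray]:
    """Z-score the population rate against its baseline and smooth it.

    The per-step population spike counts are binned to ``bin_ms``,
    converted to an average per-neuron rate, z-scored against the mean
    and SD within ``baseline_window_ms`` (which must precede the
    stimulus), then filtered with a 10-ms Gaussian kernel.
    """
    counts = np.asarray(step_counts, float)
    steps_per_bin = max(1, int(round(bin_ms / config.dt_ms)))
    n_bins = len(counts) // steps_per_bin
    binned = counts[: n_bins * steps_per_bin].reshape(n_bins, steps_per_bin).sum(axis=1)
    rate = binned / (config.n_cortex * bin_ms * 1e-3)
    t_ms = (np.arange(n_bins) + 0.5) * bin_ms
    sel = (t_ms >= baseline_window_ms[0]) & (t_ms < baseline_window_ms[1])
    if not sel.any():
        raise ValueError("empty baseline window")
    mu = rate[sel].mean()
    sd = rate[sel].std()
    if sd == 0:
        raise ZeroDivisionError(
            "zero baseline SD: lengthen the baseline window or raise drive")
    z = (rate - mu) / sd
    z = gaussian_filter1d(z, sigma=smooth_sigma_ms / bin_ms, mode="nearest")
    return t_ms, z


def genotype_comparison(config_wt: NetworkConfig, config_ko: NetworkConfig,
                        n_seeds: int = 10, seed0: int = 0) -> dict:
    """Run matched-seed simulations for both genotypes and summarise.

    Reports per-genotype mean and SD normalized-rate traces, the early
    transient peak (first 100 ms of the stimulus window) and the late
    steady-state level (mean over the final 100 ms of the stimulus).
    """
    out: dict = {}
    for name, cfg in (("WT", config_wt), ("AuxKO", config_ko)):
        traces = []
        for k in range(n_seeds):
            net = build_network(cfg, seed=seed0 + k)
            res = run_simulation(net)
            res.genotype = name
            traces.append(res.pop_rate_norm)
        traces = np.vstack(traces)
        t_ms = res.pop_rate_time_ms
        stim0, stim1 = cfg.baseline_ms, cfg.baseline_ms + cfg.hanning_ms
        early = (t_ms >= stim0) & (t_ms < stim0 + 100.0)
        late = (t_ms >= stim1 - 100.0) & (t_ms < stim1)
        out[name] = {
            "time_ms": t_ms,
            "mean_trace": traces.mean(axis=0),
            "sd_trace": traces.std(axis=0),
            "transient_peak": float(traces[:, early].max(axis=1).mean()),
            "steady_state": float(traces[:, late].mean(axis=1).mean()),
        }
    out["difference_trace"] = out["WT"]["mean_trace"] - out["AuxKO"]["mean_trace"]
    return out
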