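"""Deterministic time-stepped network simulation.

One step of the loop, at 1 ms resolution by default:

1. decay conductances and deposit the previous step's synaptic drive
   (1-step transmission delay),
2. RK4 membrane update,
3. spike detection and reset (plus externally forced spikes),
4. short-term plasticity relaxation and on-spike updates, producing the
   conductance deposits for the next step,
5. STDP pair updates (E-rule and I-rule),
6. recording.

All randomness (graph wiring, drive schedules, target choices) is consumed
up-front from named sub-seeds of the configured seed; the loop itself is
purely deterministic, so identical configurations yield bit-identical spike
rasters.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace, asdict

import numpy as np
from scipy import sparse

from . import _kernel
from .model_core import (Connectivity, KineticConstants, NeuronConstants,
                         init_connectivity)
from .plasticity import EStdpParams, IStdpParams, StpParams
from .raster import SpikeRaster

logger = logging.getLogger("critnet")

_SEED_ROLES = ("graph", "init_targets", "init_drive", "background",
               "pulse_targets", "pulse_drive", "param_noise", "init_v",
               "misc")


@dataclass(frozen=True)
class PulseTrainConfig:
    """Strong perturbation: trains of Poisson pulses into a fixed E subset.

    Each protocol at ``start_times_s`` delivers ``n_pulses`` windows of
    ``on_ms`` of Poisson spiking at ``rate_hz``, separated by ``off_ms`` of
    silence, into ``n_targets`` randomly chosen excitatory neurons (an
    independent draw from the initialization targets).
    """

    start_times_s: tuple = (300.0, 400.0, 500.0)
    n_pulses: int = 10
    on_ms: float = 500.0
    off_ms: float = 500.0
    rate_hz: float = 300.0
    n_targets: int = 20

    @property
    def span_ms(self) -> float:
        """Length of one protocol: n on-windows with n-1 gaps between."""
        if self.n_pulses == 0:
            return 0.0
        return self.n_pulses * self.on_ms + (self.n_pulses - 1) * self.off_ms


@dataclass
class SimulationConfig:
    """Full description of one deterministic run.

    The eight searched parameters (``A_plus`` … ``tau_D``) default to the
    candidate-network values; the remaining constants are fixed across all
    experiments.
    """

    n_neurons: int = 10_000
    frac_inhibitory: float = 0.2
    connection_prob: float = 0.01
    dt_ms: float = 1.0
    duration_s: float = 900.0
    seed: int = 0

    # searched parameter block
    A_plus: float = 0.0015
    beta: float = 1.21
    g_exc_max: float = 1.94     # nS, E->E and E->I
    g_inh_max: float = 4.74     # nS, I->E and I->I
    tau_AMPA: float = 19.0      # ms
    tau_GABA: float = 14.0      # ms
    tau_F: float = 41.0         # ms
    tau_D: float = 26.0         # ms

    # fixed constants
    neuron: NeuronConstants = field(default_factory=NeuronConstants)
    B_plus: float = 0.0015      # nS
    B_minus: float = 0.0003     # nS
    tau_I: float = 10.0         # ms
    tau_plus: float = 20.0      # ms
    tau_minus: float = 20.0     # ms
    U: float = 0.5
    refractory_ms: float = 2.0  # absolute refractory period (0 disables)
    w_init: float = 0.5         # initial normalised weight, all synapses
    # optional per-class overrides of the initial normalised weight
    w_init_exc: float | None = None
    w_init_inh: float | None = None
    # testing hook: explicit per-synapse initial weights (CSR data order)
    _w_init_override: object = None

    # initialization protocol
    init_v: str = "uniform"     # "uniform": V0 ~ U(V_rest, V_T); "rest": V0 = V_rest
    init_n_targets: int = 20
    init_rate_hz: float = 300.0
    init_duration_ms: float = 15.0

    # perturbations
    pulses: PulseTrainConfig | None = None
    extra_forced: tuple = ()     # ((step, neuron), ...) forced spikes

    # plasticity switches and optional disturbances
    estdp_on: bool = True
    # whether simultaneous (same-step) pre/post pairs trigger the E-rule's
    # dt = 0 depression branch; with the network's 1-step transmission
    # delay such pairs are outside each other's light-cone
    estdp_pair_dt0: bool = True
    # pair scheme: "nearest" pairs each spike with the partner's most
    # recent spike only; "all" pairs with every partner spike within
    # pair_cutoff_ms
    stdp_pairing: str = "nearest"
    pair_cutoff_ms: float = 100.0
    istdp_on: bool = True
    istdp_off_s: float | None = None
    background_rate_hz: float = 0.0   # whole-network Poisson drive, Hz/neuron
    param_noise_frac: float = 0.0     # one-off Gaussian jitter of the 8 params

    # recording
    record_raster: bool = True
    raster_window_s: tuple | None = None   # (t0, t1) seconds, None = full
    record_currents: bool = True
    snapshot_interval_s: float | None = None
    record_efficacy: bool = False
    chunk_steps: int = 5000

    def __post_init__(self) -> None:
        n_steps = self.duration_s * 1000.0 / self.dt_ms
        if abs(n_steps - round(n_steps)) > 1e-9:
            raise ValueError("duration must be an integer number of steps")
        for name in ("init_rate_hz", "background_rate_hz"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_steps(self) -> int:
        return int(round(self.duration_s * 1000.0 / self.dt_ms))

    def kinetics(self) -> KineticConstants:
        return KineticConstants(tau_AMPA=self.tau_AMPA, tau_GABA=self.tau_GABA)

    def estdp_params(self) -> EStdpParams:
        return EStdpParams(A_plus=self.A_plus, beta=self.beta,
                           tau_plus=self.tau_plus, tau_minus=self.tau_minus,
                           g_exc_max=self.g_exc_max)

    def istdp_params(self) -> IStdpParams:
        return IStdpParams(B_plus=self.B_plus, B_minus=self.B_minus,
                           tau_I=self.tau_I, g_inh_max=self.g_inh_max)

    def stp_params(self) -> StpParams:
        return StpParams(U=self.U, tau_F=self.tau_F, tau_D=self.tau_D)

    def seed_for(self, role: str) -> np.random.Generator:
        idx = _SEED_ROLES.index(role)
        ss = np.random.SeedSequence(entropy=self.seed, spawn_key=(idx,))
        return np.random.default_rng(ss)


@dataclass
class CurrentTally:
    """Summed synaptic currents per step (model units, nS * mV)."""

    exc: np.ndarray
    inh: np.ndarray

    @property
    def net(self) -> np.ndarray:
        return self.exc + self.inh


@dataclass
class RunResult:
    config: SimulationConfig
    connectivity: Connectivity
    raster: SpikeRaster | None
    spike_counts: np.ndarray            # per step, full duration
    currents: CurrentTally | None
    snapshot_times_ms: np.ndarray
    snapshots_w: list                   # float32 per-synapse normalised weights
    snapshots_eff: list                 # float32 per-synapse efficacy u*x
    syn_pre: np.ndarray                 # presynaptic neuron per synapse
    syn_post: np.ndarray
    w_final: np.ndarray
    resolved_params: dict

    def mean_rate_hz(self, t0_s: float = 1.0, t1_s: float | None = None) -> float:
        """Population rate: spikes per second per neuron in [t0, t1)."""
        dt = self.config.dt_ms
        i0 = int(round(t0_s * 1000.0 / dt))
        i1 = self.spike_counts.size if t1_s is None else int(round(t1_s * 1000.0 / dt))
        n_sec = (i1 - i0) * dt / 1000.0
        return float(self.spike_counts[i0:i1].sum()
                     / (self.config.n_neurons * n_sec))

    @property
    def syn_is_inhibitory(self) -> np.ndarray:
        return self.connectivity.is_inhibitory[self.syn_pre]


def poisson_drive(rate_hz: float, duration_ms: float, target_neurons,
                  seed, t0_ms: float = 0.0, dt_ms: float = 1.0):
    """Poisson external spike schedule.

    Each target receives an independent Poisson train at ``rate_hz`` over
    ``[t0_ms, t0_ms + duration_ms)``; events are returned as parallel
    ``(steps, neurons)`` arrays sorted by step (an event forces the target
    to spike at that step; multiple events in one step collapse to one
    spike at delivery).  ``seed`` may be an int or a Generator.
    """
    if rate_hz < 0:
        raise ValueError("rate must be >= 0")
    targets = np.asarray(target_neurons, dtype=np.int64)
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n_steps = int(round(duration_ms / dt_ms))
    if rate_hz == 0 or n_steps == 0 or targets.size == 0:
        if targets.size == 0 and rate_hz > 0 and n_steps > 0:
            logger.warning("poisson_drive: positive rate with no targets")
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    lam_total = rate_hz * dt_ms / 1000.0 * targets.size * n_steps
    n_events = rng.poisson(lam_total)
    steps = rng.integers(0, n_steps, size=n_events) + int(round(t0_ms / dt_ms))
    neurons = targets[rng.integers(0, targets.size, size=n_events)]
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order]


def pulse_protocol(pulses: PulseTrainConfig, targets, duration_s: float,
                   seed, dt_ms: float = 1.0):
    """Expand a pulse-train perturbation into a forced-spike schedule."""
    starts = np.asarray(pulses.start_times_s, dtype=float)
    span = pulses.span_ms
    ends = starts * 1000.0 + span
    if np.any(ends > duration_s * 1000.0):
        raise ValueError("pulse protocol extends past the run duration")
    order = np.argsort(starts)
    if np.any(starts[order][1:] * 1000.0 < ends[order][:-1]):
        raise ValueError("pulse protocols overlap")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    all_steps, all_neurons = [], []
    for s in starts:
        for p in range(pulses.n_pulses):
            t_on = s * 1000.0 + p * (pulses.on_ms + pulses.off_ms)
            st, ne = poisson_drive(pulses.rate_hz, pulses.on_ms, targets,
                                   rng, t0_ms=t_on, dt_ms=dt_ms)
            all_steps.append(st)
            all_neurons.append(ne)
    if not all_steps:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    steps = np.concatenate(all_steps)
    neurons = np.concatenate(all_neurons)
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order]


def _build_forced_schedule(config: SimulationConfig, conn: Connectivity):
    """Initialization drive + pulses + background + explicit extras."""
    exc_ids = np.flatnonzero(~conn.is_inhibitory)
    parts = []

    if config.init_n_targets > 0 and config.init_rate_hz > 0:
        rng_t = config.seed_for("init_targets")
        targets = rng_t.choice(exc_ids, size=config.init_n_targets,
                               replace=False)
        parts.append(poisson_drive(config.init_rate_hz,
                                   config.init_duration_ms, targets,
                                   config.seed_for("init_drive"),
                                   dt_ms=config.dt_ms))

    if config.pulses is not None and config.pulses.n_pulses > 0:
        rng_t = config.seed_for("pulse_targets")
        targets = rng_t.choice(exc_ids, size=config.pulses.n_targets,
                               replace=False)
        parts.append(pulse_protocol(config.pulses, targets,
                                    config.duration_s,
                                    config.seed_for("pulse_drive"),
                                    dt_ms=config.dt_ms))

    if config.background_rate_hz > 0:
        # generated in 1-s blocks with per-block seeds so that runs of
        # different durations share the schedule prefix (lets a short
        # perturbed run reproduce a long control run up to the event)
        role = _SEED_ROLES.index("background")
        all_targets = np.arange(config.n_neurons)
        for b in range(int(np.ceil(config.duration_s))):
            ss = np.random.SeedSequence(entropy=config.seed,
                                        spawn_key=(role, b))
            dur = min(1000.0, config.duration_s * 1000.0 - b * 1000.0)
            parts.append(poisson_drive(config.background_rate_hz, dur,
                                       all_targets,
                                       np.random.default_rng(ss),
                                       t0_ms=b * 1000.0,
                                       dt_ms=config.dt_ms))

    if config.extra_forced:
        ef = np.asarray(config.extra_forced, dtype=np.int64).reshape(-1, 2)
        parts.append((ef[:, 0], ef[:, 1]))

    if not parts:
        return np.empty(0, dtype=np.int64), np.empty(0, dtype=np.int64)
    steps = np.concatenate([p[0] for p in parts]).astype(np.int64)
    neurons = np.concatenate([p[1] for p in parts]).astype(np.int64)
    order = np.argsort(steps, kind="stable")
    return steps[order], neurons[order]


def _resolved_params(config: SimulationConfig) -> dict:
    names = ("A_plus", "beta", "g_exc_max", "g_inh_max",
             "tau_AMPA", "tau_GABA", "tau_F", "tau_D")
    vals = {k: getattr(config, k) for k in names}
    if config.param_noise_frac > 0:
        rng = config.seed_for("param_noise")
        for k in names:
            p = vals[k]
            vals[k] = float(p + rng.normal(0.0, config.param_noise_frac * p))
    return vals


def run(config: SimulationConfig) -> RunResult:
    """Execute one deterministic simulation."""
    conn = init_connectivity(config.n_neurons, config.frac_inhibitory,
                             config.connection_prob,
                             int(config.seed_for("graph").integers(2**31)))
    pars = _resolved_params(config)
    k = config.neuron

    A = conn.adjacency
    out_indptr = A.indptr.astype(np.int64)
    out_indices = A.indices.astype(np.int64)
    n_syn = A.nnz
    # CSC view with a map back into CSR synapse order
    B = sparse.csr_matrix(
        (np.arange(n_syn, dtype=np.int64), A.indices, A.indptr),
        shape=A.shape).tocsc()
    in_indptr = B.indptr.astype(np.int64)
    in_indices = B.indices.astype(np.int64)
    in_synidx = B.data.astype(np.int64)

    is_inh = conn.is_inhibitory
    syn_pre = np.repeat(np.arange(config.n_neurons),
                        np.diff(out_indptr)).astype(np.int64)
    syn_post = out_indices.copy()

    if config.init_v == "uniform":
        V = config.seed_for("init_v").uniform(k.V_rest, k.V_T,
                                              size=config.n_neurons)
    elif config.init_v == "rest":
        V = np.full(config.n_neurons, k.V_rest, dtype=np.float64)
    else:
        raise ValueError("init_v must be 'uniform' or 'rest'")
    gw = np.zeros(config.n_neurons)
    gz = np.zeros(config.n_neurons)
    dep_w = np.zeros(config.n_neurons)
    dep_z = np.zeros(config.n_neurons)
    w = np.full(n_syn, config.w_init, dtype=np.float64)
    if config.w_init_exc is not None:
        w[~is_inh[syn_pre]] = config.w_init_exc
    if config.w_init_inh is not None:
        w[is_inh[syn_pre]] = config.w_init_inh
    if config._w_init_override is not None:
        w[:] = np.asarray(config._w_init_override, dtype=np.float64)
    u = np.full(n_syn, config.U, dtype=np.float64)
    x = np.ones(n_syn, dtype=np.float64)
    last_pre = np.full(config.n_neurons, -1, dtype=np.int64)
    last_post = np.full(config.n_neurons, -1, dtype=np.int64)
    last_stp = np.full(config.n_neurons, -1, dtype=np.int64)
    ref_until = np.zeros(config.n_neurons, dtype=np.int64)
    ref_steps = int(round(config.refractory_ms / config.dt_ms))
    if config.stdp_pairing not in ("nearest", "all"):
        raise ValueError("stdp_pairing must be 'nearest' or 'all'")
    pairing_all = config.stdp_pairing == "all"
    pair_cutoff_steps = int(round(config.pair_cutoff_ms / config.dt_ms))
    # history capacity: refractoriness bounds spikes inside the cutoff
    K = max(4, pair_cutoff_steps // max(1, ref_steps + 1) + 2) if pairing_all else 4
    hist_steps = np.full((config.n_neurons, K), -10**9, dtype=np.int64)
    hist_len = np.zeros(config.n_neurons, dtype=np.int64)
    hist_head = np.zeros(config.n_neurons, dtype=np.int64)

    forced_steps, forced_neurons = _build_forced_schedule(config, conn)

    n_steps = config.n_steps
    spike_counts = np.zeros(n_steps, dtype=np.int64)
    iexc = np.zeros(n_steps)
    iinh = np.zeros(n_steps)

    if config.istdp_on:
        istdp_off_step = (n_steps + 1 if config.istdp_off_s is None
                          else int(round(config.istdp_off_s * 1000.0 / config.dt_ms)))
    else:
        istdp_off_step = 0

    if config.raster_window_s is not None:
        rw_lo = int(round(config.raster_window_s[0] * 1000.0 / config.dt_ms))
        rw_hi = int(round(config.raster_window_s[1] * 1000.0 / config.dt_ms))
    else:
        rw_lo, rw_hi = 0, n_steps

    snap_every = (None if config.snapshot_interval_s is None else
                  int(round(config.snapshot_interval_s * 1000.0 / config.dt_ms)))
    snap_times, snaps_w, snaps_eff = [], [], []
    stp = config.stp_params()

    def take_snapshot(step: int) -> None:
        snap_times.append(step * config.dt_ms)
        snaps_w.append(w.astype(np.float32))
        if config.record_efficacy:
            el = np.where(last_stp >= 0, (step - last_stp), 0)[syn_pre] * config.dt_ms
            u_rel = stp.U + (u - stp.U) * np.exp(-el / stp.tau_F)
            x_rel = 1.0 + (x - 1.0) * np.exp(-el / stp.tau_D)
            snaps_eff.append((u_rel * x_rel).astype(np.float32))

    if snap_every is not None:
        take_snapshot(0)

    ev_chunks_step, ev_chunks_neuron = [], []
    buf_cap = max(200_000, config.chunk_steps * max(64, config.n_neurons // 16))
    ev_steps = np.empty(buf_cap, dtype=np.int32)
    ev_neurons = np.empty(buf_cap, dtype=np.int32)
    fptr = 0
    step = 0
    while step < n_steps:
        chunk = min(config.chunk_steps, n_steps - step)
        if snap_every is not None:
            until_snap = snap_every - (step % snap_every)
            chunk = min(chunk, until_snap)
        done = 0
        while done < chunk:
            n_ev, d, fptr = _kernel.run_steps(
                step + done, chunk - done,
                V, gw, gz, dep_w, dep_z,
                out_indptr, out_indices,
                in_indptr, in_indices, in_synidx,
                is_inh,
                w, u, x,
                last_pre, last_post, last_stp, ref_until, ref_steps,
                hist_steps, hist_len, hist_head, pairing_all,
                pair_cutoff_steps,
                k.tau_m, k.V_T, k.V_rest, k.V_reset, k.E_ex, k.E_inh,
                pars["tau_AMPA"], pars["tau_GABA"], config.dt_ms,
                pars["A_plus"],
                pars["beta"] * pars["A_plus"] * config.tau_plus / config.tau_minus,
                config.tau_plus, config.tau_minus,
                pars["g_exc_max"], pars["g_inh_max"],
                config.B_plus, config.B_minus, config.tau_I,
                config.U, pars["tau_F"], pars["tau_D"],
                config.estdp_on, config.estdp_pair_dt0, istdp_off_step,
                forced_steps, forced_neurons, fptr,
                ev_steps, ev_neurons,
                spike_counts[step + done:step + chunk],
                iexc[step + done:step + chunk],
                iinh[step + done:step + chunk],
            )
            if d == 0 and n_ev == 0:
                raise RuntimeError("event buffer too small for a single step")
            if not np.all(np.isfinite(V)):
                bad = int(np.flatnonzero(~np.isfinite(V))[0])
                raise FloatingPointError(
                    f"non-finite membrane potential at step {step + done + d},"
                    f" neuron {bad}")
            if config.record_raster and n_ev:
                ev = ev_steps[:n_ev]
                keep = (ev >= rw_lo) & (ev < rw_hi)
                ev_chunks_step.append(ev[keep].copy())
                ev_chunks_neuron.append(ev_neurons[:n_ev][keep].copy())
            done += d
        step += chunk
        if snap_every is not None and step % snap_every == 0:
            take_snapshot(step)
        if step % 100_000 == 0 or step == n_steps:
            lo = max(0, step - config.chunk_steps)
            r = spike_counts[lo:step].sum() / (config.n_neurons
                                               * (step - lo) * config.dt_ms / 1000.0)
            logger.info("step %d/%d, recent rate %.1f Hz", step, n_steps, r)

    raster = None
    if config.record_raster:
        if ev_chunks_step:
            st = np.concatenate(ev_chunks_step)
            ne = np.concatenate(ev_chunks_neuron)
        else:
            st = np.empty(0, dtype=np.int32)
            ne = np.empty(0, dtype=np.int32)
        raster = SpikeRaster(st, ne, config.n_neurons, config.dt_ms)

    currents = CurrentTally(exc=iexc, inh=iinh) if config.record_currents else None
    return RunResult(
        config=config, connectivity=conn, raster=raster,
        spike_counts=spike_counts, currents=currents,
        snapshot_times_ms=np.asarray(snap_times),
        snapshots_w=snaps_w, snapshots_eff=snaps_eff,
        syn_pre=syn_pre, syn_post=syn_post, w_final=w.copy(),
        resolved_params=pars,
    )


def inject_single_spike(config: SimulationConfig, t_inject_s: float,
                        neuron: int | None = None):
    """Paired control/perturbed runs differing by one forced spike.

    The perturbation forces ``neuron`` (an excitatory neuron that did not
    spike at the injection step in the control run) to spike at
    ``t_inject_s``.  Returns ``(control, perturbed, neuron)``.
    """
    if not config.record_raster:
        raise ValueError("single-spike experiment requires raster recording")
    control = run(config)
    step = int(round(t_inject_s * 1000.0 / config.dt_ms))
    if not (0 <= step < config.n_steps):
        raise ValueError("injection time outside the run")
    rast = control.raster
    at_step = set(rast.neurons[rast.steps == step].tolist())
    exc_ids = np.flatnonzero(~control.connectivity.is_inhibitory)
    candidates = [int(i) for i in exc_ids if int(i) not in at_step]
    if neuron is None:
        rng = config.seed_for("misc")
        neuron = int(rng.choice(np.asarray(candidates)))
    elif neuron in at_step:
        raise ValueError(
            f"neuron {neuron} spikes naturally at t={t_inject_s}s; "
            f"candidates include {candidates[:10]}")
    pert_cfg = replace(config,
                       extra_forced=tuple(config.extra_forced)
                       + ((step, int(neuron)),))
    perturbed = run(pert_cfg)
    return control, perturbed, int(neuron)


def config_to_dict(config: SimulationConfig) -> dict:
    d = asdict(config)
    d["neuron"] = asdict(config.neuron)
    if config.pulses is not None:
        d["pulses"] = asdict(config.pulses)
    return d


def config_from_dict(d: dict) -> SimulationConfig:
    d = dict(d)
    if d.get("neuron") is not None:
        d["neuron"] = NeuronConstants(**d["neuron"])
    if d.get("pulses") is not None:
        p = dict(d["pulses"])
        if "start_times_s" in p:
            p["start_times_s"] = tuple(p["start_times_s"])
        d["pulses"] = PulseTrainConfig(**p)
    d["extra_forced"] = tuple(tuple(e) for e in d.get("extra_forced") or ())
    if d.get("raster_window_s") is not None:
        d["raster_window_s"] = tuple(d["raster_window_s"])
    return SimulationConfig(**d)
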