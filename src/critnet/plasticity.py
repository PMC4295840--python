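"""Synaptic plasticity rules: E-STDP, I-STDP and Tsodyks–Markram STP.

Three rules act continuously on every synapse:

* **E-STDP** (excitatory long-term plasticity, E→E and E→I synapses): the
  classical asymmetric pair rule.  With ``dt = t_pre - t_post``, causal
  pairs (dt < 0) potentiate by ``A+ exp(dt/tau+)`` and anti-causal pairs
  (dt >= 0) depress by ``A- exp(-dt/tau-)``, where the depression amplitude
  is fixed through the area ratio ``beta = |A- tau-| / |A+ tau+|``.
* **I-STDP** (inhibitory long-term plasticity, I→E and I→I synapses): a
  symmetric window that potentiates by ``B+ exp(-|dt|/tau)`` when
  ``|dt| <= tau`` and depresses by ``B- exp(-|dt|/tau)`` beyond it.
* **STP** (short-term plasticity): per-synapse utilisation ``u`` and
  resources ``x``.  Between presynaptic spikes, ``x`` relaxes to 1 with
  ``tau_D`` and ``u`` to the baseline ``U`` with ``tau_F``; at a spike
  ``u`` jumps by ``U (1 - u)`` first, the transmitted efficacy is
  ``u_new * x``, and ``x`` is depleted by that efficacy.

Weights are stored normalised to [0, 1].  On that scale the E-STDP
increment is ``F(dt)`` itself (equivalent to ``Δw = g_max F(dt)`` on the
conductance scale) and the I-STDP increment is ``Δz / g_inh_max``; all
updates are clamped to [0, 1].

The functions here are pure and operate on scalars or arrays; the simulator
kernel re-implements the same arithmetic in compiled form and is
cross-checked against these in the test-suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass(frozen=True)
class EStdpParams:
    A_plus: float = 0.0015     # max potentiation step (normalized weight)
    beta: float = 1.21         # depression/potentiation area ratio
    tau_plus: float = 20.0     # ms
    tau_minus: float = 20.0    # ms
    g_exc_max: float = 1.94    # nS

    def __post_init__(self) -> None:
        if self.A_plus <= 0 or self.beta <= 0:
            raise ValueError("A_plus and beta must be positive")
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")

    @property
    def A_minus(self) -> float:
        """Depression amplitude implied by the area ratio beta."""
        return self.beta * self.A_plus * self.tau_plus / self.tau_minus


@dataclass(frozen=True)
class IStdpParams:
    B_plus: float = 0.0015     # nS
    B_minus: float = 0.0003    # nS
    tau_I: float = 10.0        # ms, half-width of the potentiation window
    g_inh_max: float = 4.74    # nS

    def __post_init__(self) -> None:
        if self.B_plus <= 0 or self.B_minus <= 0 or self.tau_I <= 0:
            raise ValueError("I-STDP parameters must be positive")


@dataclass(frozen=True)
class StpParams:
    U: float = 0.5             # baseline utilisation fraction
    tau_F: float = 41.0        # facilitation, ms
    tau_D: float = 26.0        # depression, ms

    def __post_init__(self) -> None:
        if not (0 < self.U <= 1):
            raise ValueError("U must be in (0, 1]")
        if self.tau_F <= 0 or self.tau_D <= 0:
            raise ValueError("STP time constants must be positive")


@dataclass
class SynapticState:
    """Per-synapse plastic state plus per-neuron last-spike memory.

    Synapses are indexed by an external CSR layout (see the simulator);
    here the arrays are simply aligned with whatever synapse ordering the
    caller uses.  ``w_norm`` holds the normalised weight of every synapse
    ([0,1]; excitatory and inhibitory synapses live in the same array and
    are distinguished by the presynaptic neuron's class).
    """

    w_norm: np.ndarray
    u: np.ndarray
    x: np.ndarray
    last_pre_step: np.ndarray    # per presynaptic neuron, -1 if never
    last_post_step: np.ndarray   # per neuron, -1 if never

    @classmethod
    def initial(cls, n_synapses: int, n_neurons: int, w0: float = 0.5,
                U: float = 0.5) -> "SynapticState":
        return cls(
            w_norm=np.full(n_synapses, w0, dtype=np.float64),
            u=np.full(n_synapses, U, dtype=np.float64),
            x=np.ones(n_synapses, dtype=np.float64),
            last_pre_step=np.full(n_neurons, -1, dtype=np.int64),
            last_post_step=np.full(n_neurons, -1, dtype=np.int64),
        )


def estdp_delta(dt_pre_minus_post, params: EStdpParams):
    """Asymmetric E-STDP window F(dt) on the normalised-weight scale.

    dt < 0 (pre before post, causal) potentiates; dt >= 0 depresses.
    Accepts scalars or arrays.
    """
    dt = np.asarray(dt_pre_minus_post, dtype=np.float64)
    with np.errstate(over="ignore"):  # unused branch may overflow harmlessly
        out = np.where(
            dt < 0,
            params.A_plus * np.exp(np.minimum(dt, 0) / params.tau_plus),
            -params.A_minus * np.exp(-np.maximum(dt, 0) / params.tau_minus),
        )
    return out if out.ndim else float(out)


def istdp_delta(dt_pre_minus_post, params: IStdpParams):
    """Symmetric I-STDP window, in nS (conductance scale).

    Near-coincident pre/post spikes (|dt| <= tau_I) potentiate inhibition;
    more distant pairs weakly depress it.
    """
    dt = np.abs(np.asarray(dt_pre_minus_post, dtype=np.float64))
    env = np.exp(-dt / params.tau_I)
    out = np.where(dt <= params.tau_I, params.B_plus * env,
                   -params.B_minus * env)
    return out if out.ndim else float(out)


def apply_weight_update(w, delta, w_max: float = 1.0):
    """Clamped additive update: clamp(w + delta, 0, w_max)."""
    return np.clip(np.asarray(w, dtype=np.float64) + delta, 0.0, w_max)


def stp_relax(u, x, dt: float, params: StpParams):
    """Closed-form relaxation of (u, x) over dt ms with no spikes.

    x -> 1 with tau_D, u -> U with tau_F.
    """
    eF = np.exp(-dt / params.tau_F)
    eD = np.exp(-dt / params.tau_D)
    u_new = params.U + (np.asarray(u, dtype=np.float64) - params.U) * eF
    x_new = 1.0 + (np.asarray(x, dtype=np.float64) - 1.0) * eD
    return u_new, x_new


def stp_on_spike(u, x, params: StpParams):
    """Apply one presynaptic spike: facilitation first, then depletion.

    Returns (u_new, x_new, efficacy) with efficacy = u_new * x evaluated
    before depletion; the deposit onto the postsynaptic conductance is
    efficacy * weight * g_max.
    """
    u_new = np.asarray(u, dtype=np.float64) + params.U * (1.0 - np.asarray(u))
    efficacy = u_new * np.asarray(x, dtype=np.float64)
    x_new = np.asarray(x, dtype=np.float64) - efficacy
    return u_new, x_new, efficacy


def stdp_on_spike_events(
    state: SynapticState,
    spikes_this_step: np.ndarray,
    connectivity,
    e_params: EStdpParams,
    i_params: IStdpParams,
    step: int,
    dt_ms: float = 1.0,
    estdp_on: bool = True,
    istdp_on: bool = True,
) -> SynapticState:
    """Nearest-neighbour pair updates triggered by this step's spikes.

    For every spiking neuron, acting as *post*, each incoming synapse is
    paired once with its most recent presynaptic spike (causal branch,
    dt < 0); acting as *pre*, each outgoing synapse is paired once with the
    target's most recent postsynaptic spike (anti-causal branch, dt >= 0).
    A simultaneous pre/post pair is handled exactly once, through the
    dt = 0 anti-causal branch.  E-rule on synapses with excitatory
    presynaptic neuron, I-rule otherwise.  Mutates and returns ``state``.

    This is the reference (plain NumPy/Python) implementation of the event
    policy used by the compiled simulator kernel.
    """
    A = connectivity.adjacency
    A_csc = A.tocsc()
    is_inh = connectivity.is_inhibitory
    spiked_now = np.zeros(connectivity.n_neurons, dtype=bool)
    spiked_now[spikes_this_step] = True

    # synapse index lookup: CSR data order defines the synapse ordering
    indptr, indices = A.indptr, A.indices

    def syn_index(pre: int, post: int) -> int:
        row = indices[indptr[pre]:indptr[pre + 1]]
        return indptr[pre] + int(np.searchsorted(row, post))

    for nid in spikes_this_step:
        # post-side: incoming synapses, causal pairing with earlier pre spikes
        pres = A_csc.indices[A_csc.indptr[nid]:A_csc.indptr[nid + 1]]
        for pre in pres:
            if spiked_now[pre]:
                continue  # simultaneous pair handled on the pre side
            lp = state.last_pre_step[pre]
            if lp < 0:
                continue
            dt = (lp - step) * dt_ms  # < 0
            s = syn_index(pre, nid)
            if is_inh[pre]:
                if istdp_on:
                    dz = istdp_delta(dt, i_params) / i_params.g_inh_max
                    state.w_norm[s] = apply_weight_update(state.w_norm[s], dz)
            elif estdp_on:
                state.w_norm[s] = apply_weight_update(
                    state.w_norm[s], estdp_delta(dt, e_params))
        # pre-side: outgoing synapses, anti-causal pairing (dt >= 0)
        posts = indices[indptr[nid]:indptr[nid + 1]]
        for post in posts:
            lp = step if spiked_now[post] else state.last_post_step[post]
            if lp < 0:
                continue
            dt = (step - lp) * dt_ms  # >= 0
            s = syn_index(nid, post)
            if is_inh[nid]:
                if istdp_on:
                    dz = istdp_delta(dt, i_params) / i_params.g_inh_max
                    state.w_norm[s] = apply_weight_update(state.w_norm[s], dz)
            elif estdp_on:
                state.w_norm[s] = apply_weight_update(
                    state.w_norm[s], estdp_delta(dt, e_params))

    state.last_pre_step[spikes_this_step] = step
    state.last_post_step[spikes_this_step] = step
    return state
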