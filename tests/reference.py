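"""Slow reference simulator composed from the pure step functions.

Used to cross-check the compiled kernel on small networks: same step
order (deposit, membrane, detect, STP, STDP), no refractoriness,
nearest-neighbour pairing.
"""

from __future__ import annotations

import numpy as np

from critnet.model_core import (NeuronConstants, KineticConstants,
                                NeuronDynamicState, decay_and_deposit_conductances,
                                detect_spikes_and_reset, membrane_step)
from critnet.plasticity import (EStdpParams, IStdpParams, StpParams,
                                SynapticState, stdp_on_spike_events,
                                stp_on_spike, stp_relax)


def reference_run(conn, n_steps, constants=None, kinetics=None,
                  e_params=None, i_params=None, stp=None,
                  forced=None, v0=None, w0=0.5, dt=1.0):
    """Run ``n_steps`` and return (events, V, w_norm, currents)."""
    constants = constants or NeuronConstants()
    kinetics = kinetics or KineticConstants()
    e_params = e_params or EStdpParams()
    i_params = i_params or IStdpParams()
    stp = stp or StpParams()

    n = conn.n_neurons
    A = conn.adjacency
    n_syn = A.nnz
    syn_pre = np.repeat(np.arange(n), np.diff(A.indptr))
    syn_post = A.indices.copy()

    state = NeuronDynamicState.at_rest(n, constants)
    if v0 is not None:
        state.V = np.asarray(v0, dtype=np.float64).copy()
    syn = SynapticState.initial(n_syn, n, w0=w0, U=stp.U)
    dep_w = np.zeros(n)
    dep_z = np.zeros(n)
    forced = forced or {}
    events = []
    currents = []

    for step in range(n_steps):
        state = decay_and_deposit_conductances(state, kinetics, dep_w, dep_z, dt)
        dep_w = np.zeros(n)
        dep_z = np.zeros(n)
        currents.append((
            float(((constants.E_ex - state.V) * state.g_w).sum()),
            float(((constants.E_inh - state.V) * state.g_z).sum()),
        ))
        state = membrane_step(state, constants, kinetics, dt)
        state, spikes = detect_spikes_and_reset(state, constants)
        for nf in forced.get(step, ()):
            if nf not in spikes:
                state.V[nf] = constants.V_reset
                spikes = np.append(spikes, nf)
        spikes = np.sort(spikes)
        # STP relaxation for one step, then on-spike updates + deposits
        syn.u, syn.x = stp_relax(syn.u, syn.x, dt, stp)
        for j in spikes:
            sl = slice(A.indptr[j], A.indptr[j + 1])
            u_new, x_new, eff = stp_on_spike(syn.u[sl], syn.x[sl], stp)
            syn.u[sl] = u_new
            syn.x[sl] = x_new
            dep = eff * syn.w_norm[sl]
            if conn.is_inhibitory[j]:
                np.add.at(dep_z, syn_post[sl], dep * i_params.g_inh_max)
            else:
                np.add.at(dep_w, syn_post[sl], dep * e_params.g_exc_max)
        stdp_on_spike_events(syn, spikes, conn, e_params, i_params, step, dt)
        events.extend((step, int(s)) for s in spikes)

    return events, state.V, syn.w_norm, np.asarray(currents)
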