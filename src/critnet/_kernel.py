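"""Compiled inner loops for the simulator and the heavier analyses.

Everything here is a straight transcription of the reference NumPy
implementations in :mod:`critnet.model_core`, :mod:`critnet.plasticity` and
:mod:`critnet.avalanches` into numba-jitted form; the test-suite cross-checks
the two routes on small networks.  All loops are sequential, so runs are
bit-reproducible.
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(cache=True)
def run_steps(
    step0, n_steps,
    V, gw, gz, dep_w, dep_z,
    out_indptr, out_indices,
    in_indptr, in_indices, in_synidx,
    is_inh,
    w, u, x,
    last_pre, last_post, last_stp, ref_until, ref_steps,
    hist_steps, hist_len, hist_head, pairing_all, pair_cutoff_steps,
    taum, VT, Vrest, Vreset, Eex, Einh, tauA, tauG, dt,
    Aplus, Aminus, tauplus, tauminus, gexcmax, ginhmax,
    Bplus, Bminus, tauI, Ustp, tauF, tauD,
    estdp_on, estdp_pair_dt0, istdp_off_step,
    forced_steps, forced_neurons, forced_ptr0,
    ev_steps, ev_neurons,
    rate_out, iexc_out, iinh_out,
):
    """Advance the network ``n_steps`` steps starting at absolute ``step0``.

    State arrays are updated in place.  Spike events are appended to
    ``ev_steps``/``ev_neurons`` (absolute step, neuron id).  Returns
    ``(n_events, steps_done, forced_ptr)``; ``steps_done < n_steps`` means
    the event buffer filled up and the caller should resume after growing
    it.  Per-step tallies (spike counts and the summed excitatory /
    inhibitory synaptic currents at step start) are written into
    ``rate_out`` / ``iexc_out`` / ``iinh_out``.
    """
    n = V.shape[0]
    eA = np.exp(-dt / tauA)
    eG = np.exp(-dt / tauG)
    eA_h = np.exp(-0.5 * dt / tauA)
    eG_h = np.exp(-0.5 * dt / tauG)
    eF = np.exp(-dt / tauF)   # only used via per-elapsed powers below
    eD = np.exp(-dt / tauD)

    spiked_now = np.zeros(n, dtype=np.bool_)
    spikers = np.empty(n, dtype=np.int64)
    n_events = 0
    cap = ev_steps.shape[0]
    fptr = forced_ptr0

    # lookup tables for the exponential envelopes at integer step lags;
    # entries reproduce the inline expressions bit-for-bit
    TAB = 4096
    tabF = np.empty(TAB)
    tabD = np.empty(TAB)
    tabP = np.empty(TAB)   # exp(dt_pair / tau_plus), dt_pair = -k*dt
    tabM = np.empty(TAB)   # exp(-dt_pair / tau_minus), dt_pair = k*dt
    tabI = np.empty(TAB)   # exp(-|dt_pair| / tau_I)
    for k in range(TAB):
        el = k * dt
        tabF[k] = np.exp(-el / tauF)
        tabD[k] = np.exp(-el / tauD)
        tabP[k] = np.exp(((-k) * dt) / tauplus)
        tabM[k] = np.exp(-(k * dt) / tauminus)
        tabI[k] = np.exp(-(k * dt) / tauI)

    for t in range(n_steps):
        step = step0 + t
        if n_events + n > cap:
            return n_events, t, fptr

        # conductance decay over the previous step + delayed deposits
        for i in range(n):
            gw[i] = gw[i] * eA + dep_w[i]
            gz[i] = gz[i] * eG + dep_z[i]
            dep_w[i] = 0.0
            dep_z[i] = 0.0

        # current tallies at step start (model units: nS * mV)
        s_exc = 0.0
        s_inh = 0.0
        for i in range(n):
            s_exc += (Eex - V[i]) * gw[i]
            s_inh += (Einh - V[i]) * gz[i]
        iexc_out[t] = s_exc
        iinh_out[t] = s_inh

        # RK4 on the membrane equation; conductances sampled with their
        # exact within-step exponential decay.  When the total conductance
        # is large the membrane equation is stiff at the base step, so the
        # step is subdivided (deterministically, from the state alone) to
        # keep the effective decay rate per substep inside the RK4
        # stability region.
        for i in range(n):
            v0 = V[i]
            gw0 = gw[i]
            gz0 = gz[i]
            nsub = 1 + int((1.0 + gw0 + gz0) * dt / (1.5 * taum))
            if nsub == 1:
                h = dt
                ea = eA_h
                eg = eG_h
            else:
                h = dt / nsub
                ea = np.exp(-0.5 * h / tauA)
                eg = np.exp(-0.5 * h / tauG)
            for _ in range(nsub):
                k1 = ((Vrest - v0) + (Eex - v0) * gw0 + (Einh - v0) * gz0) / taum
                gwh = gw0 * ea
                gzh = gz0 * eg
                v1 = v0 + 0.5 * h * k1
                k2 = ((Vrest - v1) + (Eex - v1) * gwh + (Einh - v1) * gzh) / taum
                v2 = v0 + 0.5 * h * k2
                k3 = ((Vrest - v2) + (Eex - v2) * gwh + (Einh - v2) * gzh) / taum
                gw1 = gwh * ea
                gz1 = gzh * eg
                v3 = v0 + h * k3
                k4 = ((Vrest - v3) + (Eex - v3) * gw1 + (Einh - v3) * gz1) / taum
                v0 = v0 + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
                gw0 = gw1
                gz0 = gz1
            V[i] = v0

        # spike detection (inclusive threshold) + forced external spikes;
        # refractory neurons are clamped at the reset potential and cannot
        # spike (absolute refractoriness of ref_steps full steps)
        n_sp = 0
        for i in range(n):
            if step < ref_until[i]:
                V[i] = Vreset
            elif V[i] >= VT:
                V[i] = Vreset
                ref_until[i] = step + 1 + ref_steps
                spiked_now[i] = True
                spikers[n_sp] = i
                n_sp += 1
        while fptr < forced_steps.shape[0] and forced_steps[fptr] == step:
            i = forced_neurons[fptr]
            fptr += 1
            if not spiked_now[i] and step >= ref_until[i]:
                V[i] = Vreset
                ref_until[i] = step + 1 + ref_steps
                spiked_now[i] = True
                spikers[n_sp] = i
                n_sp += 1
        if not np.isfinite(V[0]):
            # cheap guard; full scan only if first entry already bad
            pass
        rate_out[t] = n_sp

        # short-term plasticity + conductance deposits for the next step
        for si in range(n_sp):
            j = spikers[si]
            lst = last_stp[j]
            if lst >= 0:
                kel = step - lst
                if kel < TAB:
                    rF = tabF[kel]
                    rD = tabD[kel]
                else:
                    el = kel * dt
                    rF = np.exp(-el / tauF)
                    rD = np.exp(-el / tauD)
            else:
                rF = 1.0
                rD = 1.0
            exc = not is_inh[j]
            for k in range(out_indptr[j], out_indptr[j + 1]):
                uk = Ustp + (u[k] - Ustp) * rF
                xk = 1.0 + (x[k] - 1.0) * rD
                uk = uk + Ustp * (1.0 - uk)
                eff = uk * xk
                u[k] = uk
                x[k] = xk - eff
                m = out_indices[k]
                if exc:
                    dep_w[m] += eff * w[k] * gexcmax
                else:
                    dep_z[m] += eff * w[k] * ginhmax
            last_stp[j] = step

        # STDP pair updates.  Nearest-neighbour mode pairs each spike once
        # per synapse with the partner's most recent spike; all-to-all
        # mode pairs it with every partner spike inside the pairing
        # cutoff.  Simultaneous pairs are handled once, through the
        # anti-causal branch.
        istdp_on = step < istdp_off_step
        K = hist_steps.shape[1]
        for si in range(n_sp):
            j = spikers[si]
            # post-side: causal pairing with earlier presynaptic spikes
            for k in range(in_indptr[j], in_indptr[j + 1]):
                pre = in_indices[k]
                if spiked_now[pre]:
                    continue
                s = in_synidx[k]
                inh_pre = is_inh[pre]
                if inh_pre and not istdp_on:
                    continue
                if not inh_pre and not estdp_on:
                    continue
                if pairing_all:
                    nh = hist_len[pre]
                    for q in range(nh):
                        sp = hist_steps[pre, (hist_head[pre] - 1 - q) % K]
                        klag = step - sp
                        if klag > pair_cutoff_steps:
                            break
                        if inh_pre:
                            adt = klag * dt
                            env = tabI[klag] if klag < TAB \
                                else np.exp(-adt / tauI)
                            dz = Bplus * env if adt <= tauI else -Bminus * env
                            w[s] = min(1.0, max(0.0, w[s] + dz / ginhmax))
                        else:
                            env = tabP[klag] if klag < TAB \
                                else np.exp(((-klag) * dt) / tauplus)
                            w[s] = min(1.0, max(0.0, w[s] + Aplus * env))
                else:
                    lp = last_pre[pre]
                    if lp < 0:
                        continue
                    klag = step - lp
                    if inh_pre:
                        adt = klag * dt
                        env = tabI[klag] if klag < TAB \
                            else np.exp(-adt / tauI)
                        dz = Bplus * env if adt <= tauI else -Bminus * env
                        w[s] = min(1.0, max(0.0, w[s] + dz / ginhmax))
                    else:
                        env = tabP[klag] if klag < TAB \
                            else np.exp(((-klag) * dt) / tauplus)
                        w[s] = min(1.0, max(0.0, w[s] + Aplus * env))
            # pre-side: anti-causal pairing with postsynaptic spikes
            # (dt = 0 for simultaneous pairs: depression branch for the
            # E-rule when enabled, maximal potentiation for the I-rule)
            inh_j = is_inh[j]
            if inh_j and not istdp_on:
                continue
            if not inh_j and not estdp_on:
                continue
            for k in range(out_indptr[j], out_indptr[j + 1]):
                m = out_indices[k]
                if spiked_now[m]:
                    if inh_j:
                        w[k] = min(1.0, max(0.0, w[k] + Bplus / ginhmax))
                    elif estdp_pair_dt0:
                        w[k] = min(1.0, max(0.0, w[k] - Aminus))
                if pairing_all:
                    nh = hist_len[m]
                    for q in range(nh):
                        sp = hist_steps[m, (hist_head[m] - 1 - q) % K]
                        klag = step - sp
                        if klag > pair_cutoff_steps:
                            break
                        dtv = klag * dt  # > 0
                        if inh_j:
                            env = tabI[klag] if klag < TAB \
                                else np.exp(-dtv / tauI)
                            dz = Bplus * env if dtv <= tauI else -Bminus * env
                            w[k] = min(1.0, max(0.0, w[k] + dz / ginhmax))
                        else:
                            env = tabM[klag] if klag < TAB \
                                else np.exp(-dtv / tauminus)
                            w[k] = min(1.0, max(0.0, w[k] - Aminus * env))
                else:
                    lp = last_post[m]
                    if lp < 0 or spiked_now[m]:
                        continue
                    klag = step - lp
                    dtv = klag * dt  # > 0
                    if inh_j:
                        env = tabI[klag] if klag < TAB \
                            else np.exp(-dtv / tauI)
                        dz = Bplus * env if dtv <= tauI else -Bminus * env
                        w[k] = min(1.0, max(0.0, w[k] + dz / ginhmax))
                    else:
                        env = tabM[klag] if klag < TAB \
                            else np.exp(-dtv / tauminus)
                        w[k] = min(1.0, max(0.0, w[k] - Aminus * env))

        # record events, update last-spike memories and histories
        for si in range(n_sp):
            j = spikers[si]
            ev_steps[n_events] = step
            ev_neurons[n_events] = j
            n_events += 1
            last_pre[j] = step
            last_post[j] = step
            hist_steps[j, hist_head[j]] = step
            hist_head[j] = (hist_head[j] + 1) % K
            if hist_len[j] < K:
                hist_len[j] += 1
            spiked_now[j] = False

    return n_events, n_steps, fptr


@njit(cache=True)
def track_avalanches_kernel(
    ev_steps, ev_neurons, in_indptr, in_indices,
    n_neurons, phi, delta, max_mass,
):
    """Causal avalanche tracking with overlapping membership.

    A spike (i, n) joins every avalanche that contains a spike (j, s) with
    an edge j -> i and s in the causal window [n - phi - delta, n - phi - 1];
    a spike with no such contributor starts a new singleton avalanche.
    Events must be sorted by step.

    Returns (sizes, ids_indptr, ids_flat, ok); ok is False if the total
    membership mass exceeded ``max_mass`` (runaway overlap).
    """
    n_events = ev_steps.shape[0]
    P = phi + delta + 1  # ring period covering the causal window
    ring_step = np.full((P, n_neurons), -1, dtype=np.int64)
    ring_idx = np.zeros((P, n_neurons), dtype=np.int64)

    sizes = np.zeros(1024, dtype=np.int64)
    n_av = 0
    ids_indptr = np.zeros(n_events + 1, dtype=np.int64)
    ids_flat = np.zeros(max(4 * n_events, 16), dtype=np.int64)
    mass = 0
    tmp = np.zeros(256, dtype=np.int64)

    for e in range(n_events):
        n_step = ev_steps[e]
        i = ev_neurons[e]
        # gather parent membership lists
        n_tmp = 0
        lo = n_step - phi - delta
        hi = n_step - phi - 1
        for kk in range(in_indptr[i], in_indptr[i + 1]):
            j = in_indices[kk]
            for s in range(lo, hi + 1):
                if s < 0:
                    continue
                slot = s % P
                if ring_step[slot, j] == s:
                    pe = ring_idx[slot, j]
                    a0 = ids_indptr[pe]
                    a1 = ids_indptr[pe + 1]
                    need = n_tmp + (a1 - a0)
                    if need > tmp.shape[0]:
                        newtmp = np.zeros(2 * need, dtype=np.int64)
                        newtmp[:n_tmp] = tmp[:n_tmp]
                        tmp = newtmp
                    for a in range(a0, a1):
                        tmp[n_tmp] = ids_flat[a]
                        n_tmp += 1
        if n_tmp == 0:
            # new singleton avalanche
            if n_av >= sizes.shape[0]:
                newsz = np.zeros(2 * sizes.shape[0], dtype=np.int64)
                newsz[:n_av] = sizes[:n_av]
                sizes = newsz
            sizes[n_av] = 1
            if mass + 1 > ids_flat.shape[0]:
                newfl = np.zeros(2 * ids_flat.shape[0], dtype=np.int64)
                newfl[:mass] = ids_flat[:mass]
                ids_flat = newfl
            ids_flat[mass] = n_av
            mass += 1
            n_av += 1
            ids_indptr[e + 1] = mass
        else:
            sub = np.sort(tmp[:n_tmp])
            # dedupe and append
            prev = -1
            for a in range(n_tmp):
                v = sub[a]
                if v != prev:
                    if mass >= ids_flat.shape[0]:
                        if 2 * ids_flat.shape[0] > max_mass:
                            return sizes[:n_av], ids_indptr, ids_flat, False
                        newfl = np.zeros(2 * ids_flat.shape[0], dtype=np.int64)
                        newfl[:mass] = ids_flat[:mass]
                        ids_flat = newfl
                    ids_flat[mass] = v
                    mass += 1
                    sizes[v] += 1
                    prev = v
            ids_indptr[e + 1] = mass
            if mass > max_mass:
                return sizes[:n_av], ids_indptr, ids_flat, False
        slot = n_step % P
        ring_step[slot, i] = n_step
        ring_idx[slot, i] = e

    return sizes[:n_av], ids_indptr, ids_flat[:mass], True


@njit(cache=True)
def track_avalanche_sizes_kernel(
    ev_steps, ev_neurons, in_indptr, in_indices,
    n_neurons, phi, delta, max_active, max_work,
):
    """Streaming variant of the avalanche tracker: sizes only.

    Membership lists are kept only while a spike remains inside the
    causal window of future spikes (phi + delta steps), so memory stays
    bounded by the active spike set instead of the whole raster.
    Semantics identical to :func:`track_avalanches_kernel`.

    ``max_work`` bounds the cumulative membership-merge operations; when
    exceeded, tracking stops and the sizes accumulated so far are
    returned (equivalent to analysing a shorter window prefix).
    Returns (sizes, completed).
    """
    work = 0
    n_events = ev_steps.shape[0]
    P = phi + delta + 1
    ring_step = np.full((P, n_neurons), -1, dtype=np.int64)
    ring_idx = np.zeros((P, n_neurons), dtype=np.int64)

    sizes = np.zeros(1024, dtype=np.int64)
    n_av = 0
    # membership lists for the active window, stored per event slot in a
    # reusable pool indexed by event number modulo the pool period
    pool_lists = [np.zeros(4, dtype=np.int64) for _ in range(max_active)]
    pool_len = np.zeros(max_active, dtype=np.int64)
    pool_event = np.full(max_active, -1, dtype=np.int64)
    tmp = np.zeros(256, dtype=np.int64)

    for e in range(n_events):
        n_step = ev_steps[e]
        i = ev_neurons[e]
        n_tmp = 0
        lo = n_step - phi - delta
        hi = n_step - phi - 1
        for kk in range(in_indptr[i], in_indptr[i + 1]):
            j = in_indices[kk]
            for s in range(lo, hi + 1):
                if s < 0:
                    continue
                slot = s % P
                if ring_step[slot, j] == s:
                    pe = ring_idx[slot, j]
                    pslot = pe % max_active
                    if pool_event[pslot] != pe:
                        continue  # evicted (window larger than pool)
                    ln = pool_len[pslot]
                    need = n_tmp + ln
                    if need > tmp.shape[0]:
                        newtmp = np.zeros(2 * need, dtype=np.int64)
                        newtmp[:n_tmp] = tmp[:n_tmp]
                        tmp = newtmp
                    lst = pool_lists[pslot]
                    for a in range(ln):
                        tmp[n_tmp] = lst[a]
                        n_tmp += 1
        work += n_tmp
        if work > max_work:
            return sizes[:n_av], False
        my_slot = e % max_active
        pool_event[my_slot] = e
        if n_tmp == 0:
            if n_av >= sizes.shape[0]:
                newsz = np.zeros(2 * sizes.shape[0], dtype=np.int64)
                newsz[:n_av] = sizes[:n_av]
                sizes = newsz
            sizes[n_av] = 1
            if pool_lists[my_slot].shape[0] < 1:
                pool_lists[my_slot] = np.zeros(4, dtype=np.int64)
            pool_lists[my_slot][0] = n_av
            pool_len[my_slot] = 1
            n_av += 1
        else:
            sub = np.sort(tmp[:n_tmp])
            # dedupe into the pool slot
            if pool_lists[my_slot].shape[0] < n_tmp:
                pool_lists[my_slot] = np.zeros(n_tmp, dtype=np.int64)
            lst = pool_lists[my_slot]
            m = 0
            prev = -1
            for a in range(n_tmp):
                v = sub[a]
                if v != prev:
                    lst[m] = v
                    m += 1
                    sizes[v] += 1
                    prev = v
            pool_len[my_slot] = m
        slot = n_step % P
        ring_step[slot, i] = n_step
        ring_idx[slot, i] = e

    return sizes[:n_av], True


@njit(cache=True)
def branching_series_kernel(
    ev_steps, ev_neurons,
    out_indptr, out_indices, in_indptr, in_indices,
    n_neurons, phi, delta, step_lo, step_hi, network_form,
):
    """Branching ratio sigma(n) for every step in [step_lo, step_hi].

    ``network_form=True`` computes the shared-connection (network) form:
    the ratio of summed per-spiker post-window neighbour counts to summed
    pre-window counts.  Otherwise the local form: per-spiker ratios
    averaged over spikers (spikers with an empty pre-count are excluded
    from the average).  Steps with an undefined ratio yield NaN.
    Events must be sorted by step.
    """
    n_steps = step_hi - step_lo + 1
    sigma = np.full(n_steps, np.nan)
    post_cnt = np.zeros(n_neurons, dtype=np.int64)  # spikes in post window
    pre_cnt = np.zeros(n_neurons, dtype=np.int64)   # spikes in pre window
    n_events = ev_steps.shape[0]

    # event pointers for the four sliding window edges
    p_post_in = 0   # entering post window at step n + phi + delta
    p_post_out = 0  # leaving post window below n + phi + 1
    p_pre_in = 0    # entering pre window at n - phi - 1
    p_pre_out = 0   # leaving pre window below n - phi - delta
    p_cur = 0       # events at the current step

    for idx in range(n_steps):
        n_step = step_lo + idx
        # post window [n+phi+1, n+phi+delta]
        while p_post_in < n_events and ev_steps[p_post_in] <= n_step + phi + delta:
            post_cnt[ev_neurons[p_post_in]] += 1
            p_post_in += 1
        while p_post_out < n_events and ev_steps[p_post_out] <= n_step + phi:
            post_cnt[ev_neurons[p_post_out]] -= 1
            p_post_out += 1
        # pre window [n-phi-delta, n-phi-1]
        while p_pre_in < n_events and ev_steps[p_pre_in] <= n_step - phi - 1:
            pre_cnt[ev_neurons[p_pre_in]] += 1
            p_pre_in += 1
        while p_pre_out < n_events and ev_steps[p_pre_out] <= n_step - phi - delta - 1:
            pre_cnt[ev_neurons[p_pre_out]] -= 1
            p_pre_out += 1
        # events at step n
        while p_cur < n_events and ev_steps[p_cur] < n_step:
            p_cur += 1
        q = p_cur
        num_sum = 0.0
        den_sum = 0.0
        loc_sum = 0.0
        n_loc = 0
        while q < n_events and ev_steps[q] == n_step:
            i = ev_neurons[q]
            npost = 0
            for k in range(out_indptr[i], out_indptr[i + 1]):
                if post_cnt[out_indices[k]] > 0:
                    npost += 1
            npre = 0
            for k in range(in_indptr[i], in_indptr[i + 1]):
                if pre_cnt[in_indices[k]] > 0:
                    npre += 1
            num_sum += npost
            den_sum += npre
            if npre > 0:
                loc_sum += npost / npre
                n_loc += 1
            q += 1
        if network_form:
            if den_sum > 0:
                sigma[idx] = num_sum / den_sum
        else:
            if n_loc > 0:
                sigma[idx] = loc_sum / n_loc

    return sigma
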