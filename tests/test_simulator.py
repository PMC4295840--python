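"""Simulation loop: determinism, causality, drive schedules, and the
compiled-kernel vs pure-function cross-check."""

import numpy as np
import pytest

from critnet.simulator import (PulseTrainConfig, SimulationConfig,
                               inject_single_spike, poisson_drive,
                               pulse_protocol, run)

from reference import reference_run


def _small_config(**kw):
    base = dict(n_neurons=80, frac_inhibitory=0.2, connection_prob=0.08,
                duration_s=1.0, seed=3, init_n_targets=5,
                chunk_steps=250, record_currents=True)
    base.update(kw)
    return SimulationConfig(**base)


class TestDeterminism:
    def test_identical_configs_give_identical_rasters(self):
        a = run(_small_config())
        b = run(_small_config())
        assert a.raster == b.raster
        np.testing.assert_array_equal(a.w_final, b.w_final)

    def test_different_seed_differs(self):
        a = run(_small_config(seed=3))
        b = run(_small_config(seed=4))
        assert not (a.raster == b.raster)

    def test_unconnected_undriven_network_is_silent(self):
        cfg = _small_config(connection_prob=1e-9, init_n_targets=0,
                            init_v="rest")
        res = run(cfg)
        assert res.raster.n_events == 0


class TestKernelMatchesPureFunctions:
    def test_dual_route_small_network(self):
        """Compiled loop == composition of the pure step functions.

        Run a small dense network for 300 steps with the initialization
        drive and compare spike events, final potentials and final
        weights (nearest pairing, no refractoriness, identical V0).
        """
        cfg = _small_config(duration_s=0.3, refractory_ms=0.0,
                            init_v="rest", init_n_targets=6,
                            init_rate_hz=400.0)
        res = run(cfg)
        conn = res.connectivity
        # reconstruct the forced schedule exactly as the simulator drew it
        from critnet.simulator import _build_forced_schedule
        fs, fn = _build_forced_schedule(cfg, conn)
        forced = {}
        for s, n in zip(fs.tolist(), fn.tolist()):
            forced.setdefault(s, []).append(n)
        events, V, w, currents = reference_run(
            conn, cfg.n_steps,
            e_params=cfg.estdp_params(), i_params=cfg.istdp_params(),
            stp=cfg.stp_params(), forced=forced, w0=cfg.w_init)
        got = list(zip(res.raster.steps.tolist(), res.raster.neurons.tolist()))
        assert got == events
        np.testing.assert_allclose(res.w_final, w, atol=1e-9)
        np.testing.assert_allclose(res.currents.exc, currents[:, 0],
                                   rtol=1e-9, atol=1e-6)

    def test_current_tally_invariant(self):
        res = run(_small_config())
        np.testing.assert_allclose(res.currents.net,
                                   res.currents.exc + res.currents.inh)
        assert np.all(res.currents.exc >= 0)
        assert np.all(res.currents.inh <= 0)


class TestCausality:
    def test_no_same_step_transmission(self):
        """A forced spike cannot trigger postsynaptic spikes in its own step."""
        conn_seed_cfg = _small_config(init_n_targets=0, init_v="rest",
                                      extra_forced=((10, 0),),
                                      duration_s=0.05)
        res = run(conn_seed_cfg)
        at10 = res.raster.neurons[res.raster.steps == 10]
        assert at10.tolist() == [0]


class TestPoissonDrive:
    def test_zero_rate_empty(self):
        steps, neurons = poisson_drive(0.0, 100.0, [1, 2], seed=0)
        assert steps.size == 0

    def test_expected_event_count(self):
        """20 targets x 300 Hz x 15 ms -> mean 90 events over many seeds."""
        totals = [poisson_drive(300.0, 15.0, np.arange(20), seed=s)[0].size
                  for s in range(1000)]
        se = np.std(totals, ddof=1) / np.sqrt(len(totals))
        assert abs(np.mean(totals) - 90.0) < 3 * se + 1e-9

    def test_same_seed_identical(self):
        a = poisson_drive(100.0, 50.0, [0, 1, 2], seed=7)
        b = poisson_drive(100.0, 50.0, [0, 1, 2], seed=7)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])


class TestPulseProtocol:
    def test_envelope_gating_and_span(self):
        """10 pulses of 500 ms separated by 500 ms span 9.5 s; no events in
        off-windows."""
        p = PulseTrainConfig(start_times_s=(1.0,), n_pulses=10)
        assert p.span_ms == pytest.approx(9500.0)
        steps, _ = pulse_protocol(p, np.arange(5), duration_s=20.0, seed=0)
        t = steps * 1.0
        rel = t - 1000.0
        assert rel.min() >= 0 and rel.max() < 9500.0
        phase = np.floor(rel / 500.0).astype(int)
        assert np.all(phase % 2 == 0)  # only on-windows

    def test_zero_pulses_empty(self):
        p = PulseTrainConfig(start_times_s=(1.0,), n_pulses=0)
        steps, _ = pulse_protocol(p, np.arange(5), duration_s=5.0, seed=0)
        assert steps.size == 0

    def test_overlapping_protocols_rejected(self):
        p = PulseTrainConfig(start_times_s=(1.0, 2.0), n_pulses=10)
        with pytest.raises(ValueError, match="overlap"):
            pulse_protocol(p, np.arange(5), duration_s=60.0, seed=0)

    def test_protocol_past_duration_rejected(self):
        p = PulseTrainConfig(start_times_s=(1.0,), n_pulses=10)
        with pytest.raises(ValueError, match="duration"):
            pulse_protocol(p, np.arange(5), duration_s=5.0, seed=0)


class TestSingleSpikeInjection:
    def test_unconnected_network_differs_by_exactly_one_event(self):
        cfg = _small_config(connection_prob=1e-9, init_n_targets=0,
                            init_v="uniform", duration_s=0.2,
                            estdp_on=False, istdp_on=False)
        control, perturbed, neuron = inject_single_spike(cfg, 0.05)
        extra = set(zip(perturbed.raster.steps.tolist(),
                        perturbed.raster.neurons.tolist())) \
            - set(zip(control.raster.steps.tolist(),
                      control.raster.neurons.tolist()))
        assert extra == {(50, neuron)}

    def test_control_equals_fresh_run(self):
        cfg = _small_config(duration_s=0.2)
        control, _, _ = inject_single_spike(cfg, 0.1)
        fresh = run(cfg)
        assert control.raster == fresh.raster

    def test_naturally_spiking_neuron_rejected(self):
        cfg = _small_config(duration_s=0.2, init_v="rest", init_n_targets=1,
                            init_rate_hz=2000.0, init_duration_ms=150.0)
        res = run(cfg)
        # probe at a step where some neuron spikes naturally
        assert res.raster.n_events > 0
        step = int(res.raster.steps[res.raster.n_events // 2])
        neuron = int(res.raster.neurons[res.raster.n_events // 2])
        with pytest.raises(ValueError, match="naturally"):
            inject_single_spike(cfg, step / 1000.0, neuron=neuron)


class TestSwitchesAndRecording:
    def test_istdp_freeze_after_switch_off(self):
        """Inhibitory weights stop changing after istdp_off_s."""
        cfg = _small_config(duration_s=0.6, istdp_off_s=0.3,
                            snapshot_interval_s=0.1)
        res = run(cfg)
        inh = res.syn_is_inhibitory
        # snapshots at 0.3..0.6 identical for inhibitory synapses
        w_at = {t: w for t, w in zip(res.snapshot_times_ms, res.snapshots_w)}
        np.testing.assert_array_equal(w_at[300.0][inh], w_at[600.0][inh])
        # excitatory weights still evolve (activity permitting)
        if res.raster.n_events > 50:
            assert not np.array_equal(w_at[300.0][~inh], w_at[600.0][~inh])

    def test_weight_snapshots_bounded_and_initial(self):
        cfg = _small_config(duration_s=0.2, snapshot_interval_s=0.1,
                            record_efficacy=True)
        res = run(cfg)
        assert res.snapshot_times_ms.tolist() == [0.0, 100.0, 200.0]
        for w in res.snapshots_w:
            assert np.all((w >= 0) & (w <= 1))
        assert np.all(res.snapshots_w[0] == 0.5)
        for e in res.snapshots_eff:
            assert np.all((e >= 0) & (e <= 1))

    def test_raster_window_restricts_events(self):
        cfg = _small_config(duration_s=0.4, raster_window_s=(0.1, 0.2))
        res = run(cfg)
        if res.raster.n_events:
            assert res.raster.steps.min() >= 100
            assert res.raster.steps.max() < 200
        # full-duration tallies are unaffected by the raster window
        assert res.spike_counts.size == cfg.n_steps

    def test_param_noise_perturbs_resolved_params(self):
        cfg = _small_config(param_noise_frac=0.01)
        res = run(cfg)
        assert res.resolved_params["tau_AMPA"] != 19.0
        assert abs(res.resolved_params["tau_AMPA"] - 19.0) < 19.0 * 0.06
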