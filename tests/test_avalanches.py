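"""Avalanche tracking, branching ratios, subsampling and exponent fits."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critnet.avalanches import (WindowSpec, branching_ratio_local,
                                branching_ratio_network,
                                branching_ratio_series, default_fit_range,
                                fit_size_exponent, sample_subgraph,
                                sliding_lambda, track_avalanches,
                                track_avalanches_bruteforce)
from critnet.fixtures import (exact_powerlaw_counts, make_toy_raster,
                              powerlaw_sizes)
from critnet.model_core import init_connectivity
from critnet.raster import SpikeRaster


class TestToyFixtures:
    @pytest.mark.parametrize("name", ["isolated", "chain-3", "tree-b2",
                                      "overlap-join"])
    def test_hand_computed_sizes(self, name):
        raster, conn, expected = make_toy_raster(name)
        av = track_avalanches(raster, conn)
        assert sorted(av.sizes.tolist()) == sorted(expected["sizes"])

    def test_overlapping_membership_shared_spike(self):
        """A spike bridging two avalanches belongs to both; no merging."""
        raster, conn, _ = make_toy_raster("overlap-join")
        av = track_avalanches(raster, conn)
        assert av.n_avalanches == 2
        # the last spike (index 2) belongs to both avalanches
        assert len(av.memberships(2)) == 2
        # conservation with overlap: size mass exceeds the spike count
        assert av.sizes.sum() == 4 > raster.n_events

    def test_degenerate_window_fragments_chain(self):
        """A grossly large offset skips causal links -> all singletons."""
        raster, conn, expected = make_toy_raster("fragmented-chain")
        av = track_avalanches(raster, conn, WindowSpec(delta=3, phi=3))
        assert sorted(av.sizes.tolist()) == expected["sizes_phi3"]

    def test_tree_branching_ratio_exact(self):
        """Feed-forward tree with b=2 children per spiker: sigma = 2."""
        raster, conn, expected = make_toy_raster("tree-b2")
        for step, sig in expected["sigma_at"].items():
            assert branching_ratio_network(
                raster, conn, WindowSpec(), step) == pytest.approx(sig)
            assert branching_ratio_local(
                raster, conn, WindowSpec(), step) == pytest.approx(sig)

    def test_empty_raster_has_no_defined_sigma(self):
        _, conn, _ = make_toy_raster("chain-3")
        empty = SpikeRaster([], [], conn.n_neurons)
        sig = branching_ratio_series(empty, conn, step_range=(0, 10))
        assert np.all(np.isnan(sig))


class TestBruteForceEquivalence:
    @given(st.integers(0, 10_000))
    @settings(max_examples=25, deadline=None)
    def test_tracker_matches_bruteforce_on_random_rasters(self, seed):
        """Compiled tracker == exhaustive set-semantics scan, spike by spike."""
        rng = np.random.default_rng(seed)
        n = int(rng.integers(5, 30))
        conn = init_connectivity(n, 0.2, float(rng.uniform(0.05, 0.4)),
                                 seed=seed)
        n_steps = int(rng.integers(10, 120))
        density = rng.uniform(0.005, 0.08)
        mask = rng.random((n_steps, n)) < density
        steps, neurons = np.nonzero(mask)
        raster = SpikeRaster(steps, neurons, n)
        window = WindowSpec(delta=int(rng.integers(1, 5)),
                            phi=int(rng.integers(0, 3)))
        fast = track_avalanches(raster, conn, window)
        slow = track_avalanches_bruteforce(raster, conn, window)
        assert sorted(fast.sizes.tolist()) == sorted(slow.sizes.tolist())
        np.testing.assert_array_equal(fast.ids_indptr, slow.ids_indptr)

    def test_streaming_mode_matches_full_tracker(self):
        """Sizes-only streaming path == full membership path."""
        rng = np.random.default_rng(11)
        conn = init_connectivity(150, 0.2, 0.06, seed=11)
        mask = rng.random((2000, 150)) < 0.012
        steps, neurons = np.nonzero(mask)
        raster = SpikeRaster(steps, neurons, 150)
        full = track_avalanches(raster, conn, keep_membership=True)
        stream = track_avalanches(raster, conn, keep_membership=False)
        assert not stream.has_membership
        assert sorted(full.sizes.tolist()) == sorted(stream.sizes.tolist())

    def test_membership_covers_every_spike(self):
        rng = np.random.default_rng(3)
        conn = init_connectivity(20, 0.2, 0.2, seed=3)
        mask = rng.random((80, 20)) < 0.05
        steps, neurons = np.nonzero(mask)
        raster = SpikeRaster(steps, neurons, 20)
        av = track_avalanches(raster, conn)
        for e in range(raster.n_events):
            assert len(av.memberships(e)) >= 1
        assert av.sizes.sum() >= raster.n_events
        assert np.all(av.sizes >= 1)


class TestSubgraph:
    def test_identity_at_p_one(self):
        conn = init_connectivity(50, 0.2, 0.2, seed=1)
        sub, ids = sample_subgraph(conn, 1.0, seed=0)
        assert sub.n_neurons == 50
        assert (sub.adjacency != conn.adjacency).nnz == 0

    def test_edges_survive_iff_both_endpoints_sampled(self):
        conn = init_connectivity(60, 0.2, 0.15, seed=2)
        sub, ids = sample_subgraph(conn, 0.4, seed=5)
        A = conn.adjacency.tocoo()
        expected = {(i, j) for i, j in zip(A.row, A.col)
                    if i in set(ids) and j in set(ids)}
        relabel = {int(v): k for k, v in enumerate(ids)}
        got = {(ids[i], ids[j]) for i, j in
               zip(*sub.adjacency.tocoo().coords)}
        assert got == expected

    def test_sampled_out_degree_scales_with_p(self):
        """Expected out-degree of sampled nodes ~ c * p * N."""
        degs = []
        for seed in range(30):
            conn = init_connectivity(400, 0.2, 0.1, seed=seed)
            sub, _ = sample_subgraph(conn, 0.5, seed=seed + 100)
            degs.append(sub.out_degrees().mean())
        assert np.mean(degs) == pytest.approx(0.1 * 0.5 * 400, rel=0.05)

    def test_invalid_probability(self):
        conn = init_connectivity(10, 0.2, 0.2, seed=0)
        with pytest.raises(ValueError):
            sample_subgraph(conn, 0.0, seed=0)


class TestExponentFit:
    def test_exact_power_law_recovered(self):
        """Counts exactly prop to s^-1.5 give slope -1.5 and R^2 = 1."""
        s, counts = exact_powerlaw_counts(-1.5, 50)
        sizes = np.repeat(s, np.round(counts).astype(int))
        fit = fit_size_exponent(sizes, fit_range=(1, 50))
        # exact up to integer rounding of the synthetic counts
        assert fit.slope == pytest.approx(-1.5, abs=1e-4)
        assert fit.r_squared == pytest.approx(1.0, abs=1e-7)

    def test_sampled_power_law_recovered(self):
        sizes = powerlaw_sizes(-1.5, 100, 100_000, seed=0)
        fit = fit_size_exponent(sizes, fit_range=(1, 30))
        assert fit.slope == pytest.approx(-1.5, abs=0.06)

    def test_single_support_point_rejected(self):
        with pytest.raises(ValueError):
            fit_size_exponent(np.full(100, 7))

    def test_default_fit_range_covers_initial_mass(self):
        sizes = powerlaw_sizes(-1.5, 200, 50_000, seed=1)
        lo, hi = default_fit_range(sizes)
        assert lo == 1 and 2 <= hi <= 200


class TestSlidingLambda:
    def test_stationary_raster_gives_stable_series(self):
        """On a stationary memoryless raster the lambda estimates are
        finite and constant within fit noise across windows."""
        from critnet.fixtures import poisson_raster

        conn = init_connectivity(150, 0.2, 0.04, seed=2)
        raster = poisson_raster(150, 20.0, 120.0, seed=2)
        starts, lams = sliding_lambda(raster, conn, window_s=40.0,
                                      stride_s=40.0, p=1.0, seed=0)
        assert starts.size == 3
        assert np.all(np.isfinite(lams))
        assert lams.std() < 0.3

    def test_short_raster_rejected(self):
        from critnet.fixtures import poisson_raster

        conn = init_connectivity(20, 0.2, 0.1, seed=0)
        raster = poisson_raster(20, 20.0, 5.0, seed=0)
        with pytest.raises(ValueError, match="shorter"):
            sliding_lambda(raster, conn, window_s=40.0)
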