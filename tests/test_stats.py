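"""Rates, ISI irregularity, correlations, divergence, drift reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from critnet.fixtures import poisson_raster
from critnet.raster import SpikeRaster, from_dense
from critnet.stats import (DivergenceResult, cov_isi, estimate_drift,
                           expected_random_distance, fit_divergence_exponent,
                           pairwise_correlations, population_rate,
                           spike_vector_distance)


class TestPopulationRate:
    def test_every_neuron_once_per_bin_is_100hz(self):
        """One spike per neuron per 10 ms bin -> 100 Hz population rate."""
        n, n_bins = 7, 12
        steps = np.concatenate([np.arange(n_bins) * 10 + 3] * n)
        neurons = np.repeat(np.arange(n), n_bins)
        raster = SpikeRaster(steps, neurons, n)
        rate = population_rate(raster, bin_ms=10.0, n_steps=n_bins * 10)
        np.testing.assert_allclose(rate.rate_hz, 100.0)

    def test_empty_raster_zero_series(self):
        raster = SpikeRaster([], [], 5)
        rate = population_rate(raster, bin_ms=10.0, n_steps=50)
        assert np.all(rate.rate_hz == 0.0)


class TestCovIsi:
    def test_periodic_train_has_zero_cov(self):
        raster = SpikeRaster(np.arange(50) * 20, np.zeros(50, int), 1)
        out = cov_isi(raster, [0], isi_min_ms=3, isi_max_ms=1000)
        assert out["cov"][0] == pytest.approx(0.0)

    def test_poisson_process_cov_near_one(self):
        """Exponential ISIs in a [10, 1000] ms window give CoV ~ 1 (slightly
        below from truncation)."""
        rng = np.random.default_rng(0)
        t = np.cumsum(rng.exponential(50.0, size=10_000))  # 20 Hz
        raster = SpikeRaster(np.round(t).astype(int), np.zeros(10_000, int), 1)
        out = cov_isi(raster, [0], isi_min_ms=10, isi_max_ms=1000)
        assert 0.80 < out["cov"][0] <= 1.02

    def test_relabeling_invariance(self):
        raster = poisson_raster(10, 30.0, 60.0, seed=4)
        a = cov_isi(raster, [2, 7])
        perm = np.argsort(np.argsort([7, 2]))
        b = cov_isi(raster, [7, 2])
        assert sorted(a["cov"].tolist()) == sorted(b["cov"].tolist())


class TestPairwiseCorrelations:
    def test_identical_copy_fully_correlated(self):
        rng = np.random.default_rng(1)
        steps = np.sort(rng.choice(5000, 400, replace=False))
        raster = SpikeRaster(np.concatenate([steps, steps]),
                             np.concatenate([np.zeros(400, int),
                                             np.ones(400, int)]), 2)
        corr = pairwise_correlations(raster, [0, 1], bin_ms=50.0)
        assert corr[0] == pytest.approx(1.0)

    def test_independent_trains_centered_at_zero(self):
        raster = poisson_raster(30, 25.0, 120.0, seed=9)
        corr = pairwise_correlations(raster, np.arange(30), bin_ms=50.0)
        assert abs(corr.mean()) < 0.02
        # SD shrinks with wider bins (fewer, larger samples -> here the
        # relevant effect: correlation noise ~ 1/sqrt(n_bins))
        corr_wide = pairwise_correlations(raster, np.arange(30), bin_ms=200.0)
        assert corr_wide.std() > corr.std() * 0.8  # both small, same order


class TestSpikeVectorDistance:
    def test_identical_rasters_zero(self):
        raster = poisson_raster(20, 30.0, 20.0, seed=0)
        d = spike_vector_distance(raster, raster)
        assert np.all(d.distance == 0.0)

    def test_single_differing_spike(self):
        a = SpikeRaster([5], [3], 10)
        b = SpikeRaster([], [], 10)
        d = spike_vector_distance(a, b)
        assert d.distance[5] == 1.0
        assert d.distance.sum() == 1.0

    def test_independent_rasters_match_bernoulli_expectation(self):
        """E[distance] ~ sqrt(2 N q (1-q)) for independent spike vectors."""
        n, q = 2000, 0.03
        a = poisson_raster(n, q * 1000, 2.0, seed=1)
        b = poisson_raster(n, q * 1000, 2.0, seed=2)
        d = spike_vector_distance(a, b)
        expected = expected_random_distance(n, q * 1000)
        assert np.mean(d.distance) == pytest.approx(expected, rel=0.05)

    @given(st.integers(0, 1000))
    @settings(max_examples=20, deadline=None)
    def test_metric_axioms_on_random_rasters(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.random((20, 15)) < 0.1
        Y = rng.random((20, 15)) < 0.1
        Z = rng.random((20, 15)) < 0.1
        a, b, c = (from_dense(M) for M in (X, Y, Z))
        dab = spike_vector_distance(a, b, n_steps=20).distance
        dba = spike_vector_distance(b, a, n_steps=20).distance
        dac = spike_vector_distance(a, c, n_steps=20).distance
        dcb = spike_vector_distance(c, b, n_steps=20).distance
        np.testing.assert_allclose(dab, dba)
        assert np.all(dab <= dac + dcb + 1e-12)
        assert np.all(spike_vector_distance(a, a).distance == 0)

    def test_hamming_mode(self):
        a = from_dense(np.eye(4, dtype=bool))
        b = from_dense(np.zeros((4, 4), dtype=bool))
        d = spike_vector_distance(a, b, metric="hamming")
        assert np.all(d.distance == 1.0)


class TestDivergenceFit:
    def test_exact_exponential_recovered(self):
        t = np.arange(100, dtype=float)
        d = DivergenceResult(distance=np.exp(0.1 * t), dt_ms=1.0)
        out = fit_divergence_exponent(d, (0, 100))
        assert out.xi == pytest.approx(0.1, abs=1e-12)

    def test_ci_covers_true_exponent(self):
        """95% CI covers the true growth rate in >= 90% of noisy draws."""
        rng = np.random.default_rng(0)
        t = np.arange(80, dtype=float)
        hits = 0
        for _ in range(100):
            d = np.exp(0.1 * t) * np.exp(rng.normal(0, 0.2, t.size))
            out = fit_divergence_exponent(
                DivergenceResult(distance=d, dt_ms=1.0), (0, 80))
            if out.xi_ci[0] <= 0.1 <= out.xi_ci[1]:
                hits += 1
        assert hits >= 90

    def test_flat_series_gives_zero(self):
        d = DivergenceResult(distance=np.full(50, 3.0), dt_ms=1.0)
        out = fit_divergence_exponent(d, (0, 50))
        assert out.xi == pytest.approx(0.0, abs=1e-12)

    def test_zeros_in_window_rejected(self):
        d = DivergenceResult(distance=np.array([0.0, 1, 2, 3.0]), dt_ms=1.0)
        with pytest.raises(ValueError):
            fit_divergence_exponent(d, (0, 4))


class TestDriftEstimation:
    def _ou(self, a, mu, sigma, n, seed):
        rng = np.random.default_rng(seed)
        y = np.empty(n)
        y[0] = mu
        for i in range(1, n):
            y[i] = y[i - 1] + a * (mu - y[i - 1]) + rng.normal(0, sigma)
        return y

    def test_ou_fixed_point_and_slope_recovered(self):
        """Discrete OU with a=0.1, mu=30: crossing at 30 +- 0.5, slope ~ -0.1."""
        y = self._ou(0.1, 30.0, 1.0, 100_000, seed=0)
        est = estimate_drift(y, n_bins=50, min_count=20)
        stable = [fp for fp, kind in est.fixed_points if kind == "stable"]
        assert len(stable) >= 1
        assert min(abs(s - 30.0) for s in stable) < 0.5
        slope = np.polyfit(est.bin_centers, est.drift, 1)[0]
        assert slope == pytest.approx(-0.1, rel=0.2)

    def test_constant_series_no_crossings(self):
        est = estimate_drift(np.full(1000, 5.0), n_bins=10, min_count=5)
        assert est.fixed_points == []
        assert np.all(est.drift == 0.0)

    def test_time_reversal_flips_transient_drift(self):
        """Reversing a relaxation transient flips the recovered drift sign.

        (A *stationary* OU series is time-reversible, so only the
        non-stationary approach to the fixed point carries an arrow of
        time.)
        """
        rng = np.random.default_rng(1)
        n, a, mu = 20_000, 0.002, 30.0
        y = np.empty(n)
        y[0] = 100.0
        for i in range(1, n):
            y[i] = y[i - 1] + a * (mu - y[i - 1]) + rng.normal(0, 0.2)
        fwd = estimate_drift(y, n_bins=40)
        rev = estimate_drift(y[::-1], n_bins=40)
        s_f = np.polyfit(fwd.bin_centers, fwd.drift, 1)[0]
        s_r = np.polyfit(rev.bin_centers, rev.drift, 1)[0]
        assert s_f < 0 < s_r
        assert s_r == pytest.approx(-s_f, rel=0.25)

    def test_short_series_rejected(self):
        with pytest.raises(ValueError):
            estimate_drift(np.arange(100.0), n_bins=50)
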