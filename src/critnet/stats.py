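"""Spike-train statistics: rates, ISI irregularity, correlations,
perturbation divergence, and Langevin drift reconstruction.

The drift estimator treats the population firing rate r(t) as a noisy
one-dimensional dynamical system  dr/dt = h(r) + noise  and recovers h by
binning the observed rate range and averaging the one-step increments
within each bin; zero crossings of h mark fixed points (stable where the
local slope is negative).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as sps

from .raster import SpikeRaster


@dataclass
class RateSeries:
    """Population rate in Hz per bin."""

    rate_hz: np.ndarray
    bin_ms: float

    @property
    def times_ms(self) -> np.ndarray:
        return np.arange(self.rate_hz.size) * self.bin_ms


@dataclass
class DriftEstimate:
    bin_centers: np.ndarray
    drift: np.ndarray            # mean one-step increment per bin
    counts: np.ndarray
    fixed_points: list           # (value, "stable"|"unstable")


@dataclass
class DivergenceResult:
    distance: np.ndarray         # per step
    dt_ms: float
    xi: float | None = None      # growth exponent per ms
    xi_ci: tuple | None = None
    fit_window_ms: tuple | None = None
    saturation: float | None = None


def population_rate(raster: SpikeRaster, bin_ms: float = 1.0,
                    n_steps: int | None = None) -> RateSeries:
    """Spikes per bin / (n_neurons * bin seconds)."""
    k = int(round(bin_ms / raster.dt_ms))
    if abs(k * raster.dt_ms - bin_ms) > 1e-9 or k < 1:
        raise ValueError("bin_ms must be a positive multiple of dt")
    counts = raster.counts_per_step(n_steps)
    n_bins = counts.size // k
    if counts.size % k:
        counts = np.concatenate([counts, np.zeros(k - counts.size % k,
                                                  dtype=counts.dtype)])
        n_bins += 1
    binned = counts.reshape(n_bins, k).sum(axis=1)
    rate = binned / (raster.n_neurons * bin_ms / 1000.0)
    return RateSeries(rate_hz=rate, bin_ms=bin_ms)


def rate_from_counts(spike_counts: np.ndarray, n_neurons: int,
                     bin_ms: float, dt_ms: float = 1.0) -> RateSeries:
    """Rate series straight from a per-step population spike count."""
    k = int(round(bin_ms / dt_ms))
    n_bins = spike_counts.size // k
    binned = spike_counts[: n_bins * k].reshape(n_bins, k).sum(axis=1)
    return RateSeries(binned / (n_neurons * bin_ms / 1000.0), bin_ms)


def cov_isi(raster: SpikeRaster, neurons=None, isi_min_ms: float = 3.0,
            isi_max_ms: float = 1000.0) -> dict:
    """Coefficient of variation (SD/mean) of retained ISIs per neuron.

    Only ISIs within [isi_min_ms, isi_max_ms] are kept; neurons with
    fewer than 2 retained ISIs are skipped.
    """
    if neurons is None:
        neurons = np.unique(raster.neurons)
    covs, kept = [], []
    n_skipped = 0
    for nid in np.asarray(neurons):
        isi = np.diff(raster.spike_times_of(int(nid)))
        isi = isi[(isi >= isi_min_ms) & (isi <= isi_max_ms)]
        if isi.size < 2:
            n_skipped += 1
            continue
        covs.append(isi.std(ddof=0) / isi.mean())
        kept.append(int(nid))
    return {"cov": np.asarray(covs), "neurons": np.asarray(kept),
            "n_skipped": n_skipped}


def pairwise_correlations(raster: SpikeRaster, neurons, bin_ms: float = 50.0,
                          t_start_ms: float = 0.0,
                          t_end_ms: float | None = None) -> np.ndarray:
    """Pearson correlations of binned spike counts, all unordered pairs.

    Pairs with a zero-variance member are skipped.
    """
    neurons = np.asarray(neurons)
    if neurons.size < 2:
        raise ValueError("need at least 2 neurons")
    if t_end_ms is None:
        t_end_ms = raster.duration_steps * raster.dt_ms
    edges = np.arange(t_start_ms, t_end_ms + 1e-9, bin_ms)
    X = np.empty((neurons.size, edges.size - 1))
    for a, nid in enumerate(neurons):
        t = raster.spike_times_of(int(nid))
        X[a] = np.histogram(t, bins=edges)[0]
    sd = X.std(axis=1)
    ok = sd > 0
    Xc = X[ok] - X[ok].mean(axis=1, keepdims=True)
    C = (Xc @ Xc.T) / ((edges.size - 1) * np.outer(sd[ok], sd[ok]))
    iu = np.triu_indices(C.shape[0], k=1)
    return C[iu]


def spike_vector_distance(raster_a: SpikeRaster, raster_b: SpikeRaster,
                          metric: str = "euclidean",
                          n_steps: int | None = None) -> DivergenceResult:
    """Per-step distance between the binary population spike vectors.

    ``euclidean`` (default) is the L2 distance, i.e. the square root of
    the Hamming distance between the two binary vectors; ``hamming``
    returns the raw differing-spike count.
    """
    if raster_a.n_neurons != raster_b.n_neurons:
        raise ValueError("rasters have different neuron counts")
    if raster_a.dt_ms != raster_b.dt_ms:
        raise ValueError("rasters have different step sizes")
    if n_steps is None:
        n_steps = max(raster_a.duration_steps, raster_b.duration_steps)
    n = raster_a.n_neurons
    key_a = raster_a.steps.astype(np.int64) * n + raster_a.neurons
    key_b = raster_b.steps.astype(np.int64) * n + raster_b.neurons
    only_a = np.setdiff1d(key_a, key_b, assume_unique=True)
    only_b = np.setdiff1d(key_b, key_a, assume_unique=True)
    diff_steps = np.concatenate([only_a // n, only_b // n]).astype(np.int64)
    ham = np.bincount(diff_steps, minlength=n_steps).astype(np.float64)
    d = np.sqrt(ham) if metric == "euclidean" else ham
    if metric not in ("euclidean", "hamming"):
        raise ValueError("metric must be 'euclidean' or 'hamming'")
    return DivergenceResult(distance=d, dt_ms=raster_a.dt_ms)


def fit_divergence_exponent(result: DivergenceResult, fit_window_ms: tuple,
                            ) -> DivergenceResult:
    """Exponential growth rate xi of the distance: log-linear least squares.

    Fits log d(t) = log d0 + xi * t over the (pre-saturation) window;
    the window must not contain zero distances.  Returns a copy of the
    result with xi, its 95% CI, and the saturation level (median of the
    post-window tail) filled in.
    """
    t0, t1 = fit_window_ms
    i0 = int(round(t0 / result.dt_ms))
    i1 = int(round(t1 / result.dt_ms))
    d = result.distance[i0:i1]
    if d.size < 3:
        raise ValueError("fit window too short")
    if np.any(d <= 0):
        raise ValueError("fit window contains zero distances")
    t = np.arange(i0, i1) * result.dt_ms
    res = sps.linregress(t, np.log(d))
    # 95% CI from the slope standard error
    tcrit = sps.t.ppf(0.975, d.size - 2)
    ci = (res.slope - tcrit * res.stderr, res.slope + tcrit * res.stderr)
    tail = result.distance[i1:]
    return DivergenceResult(
        distance=result.distance, dt_ms=result.dt_ms,
        xi=float(res.slope), xi_ci=(float(ci[0]), float(ci[1])),
        fit_window_ms=(t0, t1),
        saturation=float(np.median(tail)) if tail.size else None,
    )


def expected_random_distance(n_neurons: int, rate_hz: float,
                             dt_ms: float = 1.0) -> float:
    """Expected L2 distance between two independent random spike vectors.

    With per-step spike probability q = rate * dt, the expected squared
    Hamming distance is 2 N q (1 - q).
    """
    q = rate_hz * dt_ms / 1000.0
    return float(np.sqrt(2.0 * n_neurons * q * (1.0 - q)))


def smooth_rate(rate: RateSeries, window_ms: float = 10.0) -> RateSeries:
    """Moving-average smoothing of a rate series."""
    k = max(1, int(round(window_ms / rate.bin_ms)))
    kernel = np.ones(k) / k
    sm = np.convolve(rate.rate_hz, kernel, mode="valid")
    return RateSeries(rate_hz=sm, bin_ms=rate.bin_ms)


def estimate_drift(series: np.ndarray, n_bins: int = 50,
                   min_count: int = 20) -> DriftEstimate:
    """Binned mean one-step increments of a scalar time series.

    Approximates the deterministic component h(x) of a Langevin system
    from which ``series`` was sampled; only bins with at least
    ``min_count`` members are reported.
    """
    y = np.asarray(series, dtype=np.float64)
    if y.size < 10 * n_bins:
        raise ValueError("series too short for the requested binning")
    lo, hi = y.min(), y.max()
    if hi == lo:
        centers = np.array([lo])
        return DriftEstimate(bin_centers=centers, drift=np.zeros(1),
                             counts=np.array([y.size - 1]), fixed_points=[])
    edges = np.linspace(lo, hi, n_bins + 1)
    idx = np.clip(np.digitize(y[:-1], edges) - 1, 0, n_bins - 1)
    dy = np.diff(y)
    counts = np.bincount(idx, minlength=n_bins)
    sums = np.bincount(idx, weights=dy, minlength=n_bins)
    ok = counts >= min_count
    centers = 0.5 * (edges[:-1] + edges[1:])[ok]
    drift = sums[ok] / counts[ok]
    fixed_points = []
    for a in range(len(drift) - 1):
        if drift[a] == 0.0:
            continue
        if drift[a] * drift[a + 1] < 0:
            # linear interpolation of the crossing
            x0, x1 = centers[a], centers[a + 1]
            f0, f1 = drift[a], drift[a + 1]
            xc = x0 - f0 * (x1 - x0) / (f1 - f0)
            kind = "stable" if f0 > f1 else "unstable"
            fixed_points.append((float(xc), kind))
    return DriftEstimate(bin_centers=centers, drift=drift,
                         counts=counts[ok], fixed_points=fixed_points)
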