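"""Programmatic test inputs: toy rasters with known avalanche structure and
synthetic series with known scaling exponents.

These generators are first-class, seeded code: every fixture carries the
hand-computed quantities the analyses should recover from it.
"""

from __future__ import annotations

import numpy as np
from scipy import sparse

from .model_core import Connectivity
from .raster import SpikeRaster


def _conn_from_edges(n: int, edges, is_inh=None) -> Connectivity:
    A = sparse.csr_matrix(
        (np.ones(len(edges), dtype=bool),
         ([e[0] for e in edges], [e[1] for e in edges])), shape=(n, n))
    inh = np.zeros(n, dtype=bool) if is_inh is None else np.asarray(is_inh)
    return Connectivity(n_neurons=n, is_inhibitory=inh, adjacency=A,
                        connection_prob=0.0, seed=0)


def make_toy_raster(name: str):
    """Named micro-fixtures with hand-computed expected analysis results.

    Returns (raster, connectivity, expected) where ``expected`` holds
    avalanche sizes (phi=1, delta=3) and, where relevant, branching
    ratios.
    """
    if name == "isolated":
        # one spike, no presynaptic partners: a single size-1 avalanche
        conn = _conn_from_edges(3, [(0, 1)])
        raster = SpikeRaster([5], [2], 3)
        expected = {"sizes": [1]}
    elif name == "chain-3":
        # a -> b -> c firing at n, n+2, n+4: each link inside the causal
        # window [m-4, m-2], one avalanche of size 3
        conn = _conn_from_edges(3, [(0, 1), (1, 2)])
        raster = SpikeRaster([10, 12, 14], [0, 1, 2], 3)
        expected = {"sizes": [3]}
    elif name == "tree-b2":
        # feeder -> root -> two children -> four grandchildren; every
        # spiker from the root on triggers exactly 2 children one window
        # later, so the branching ratio at those steps is exactly 2
        edges = [(7, 0), (0, 1), (0, 2), (1, 3), (1, 4), (2, 5), (2, 6)]
        conn = _conn_from_edges(8, edges)
        steps = [7, 10, 12, 12, 14, 14, 14, 14]
        neurons = [7, 0, 1, 2, 3, 4, 5, 6]
        raster = SpikeRaster(steps, neurons, 8)
        expected = {"sizes": [8], "sigma_at": {10: 2.0, 12: 2.0}}
    elif name == "overlap-join":
        # two independent starts; a later spike has contributors in both
        # avalanches and is counted by each (overlapping membership)
        edges = [(0, 2), (1, 2)]
        conn = _conn_from_edges(3, edges)
        raster = SpikeRaster([10, 10, 12], [0, 1, 2], 3)
        expected = {"sizes": [2, 2]}
    elif name == "fragmented-chain":
        # same chain as chain-3 but analysed with too large an offset it
        # fragments; expectation stored for the degenerate window phi=3
        conn = _conn_from_edges(3, [(0, 1), (1, 2)])
        raster = SpikeRaster([10, 12, 14], [0, 1, 2], 3)
        expected = {"sizes_phi3": [1, 1, 1]}
    else:
        raise ValueError(f"unknown fixture {name!r}")
    return raster, conn, expected


def powerlaw_sizes(slope: float, s_max: int, n: int, seed=0) -> np.ndarray:
    """Integer sizes 1..s_max with counts proportional to s**slope.

    ``slope`` must be negative.  Sampling is exact multinomial from the
    normalized power-law mass.
    """
    if slope >= 0:
        raise ValueError("slope must be negative")
    rng = np.random.default_rng(seed)
    s = np.arange(1, s_max + 1, dtype=np.float64)
    p = s ** slope
    p /= p.sum()
    counts = rng.multinomial(n, p)
    return np.repeat(np.arange(1, s_max + 1), counts)


def exact_powerlaw_counts(slope: float, s_max: int, c0: float = 1e6):
    """Noise-free (size, count) table with count = c0 * s**slope."""
    s = np.arange(1, s_max + 1)
    return s, c0 * s.astype(float) ** slope


def white_isi(n: int, mean_ms: float = 25.0, sd_ms: float = 5.0,
              seed=0) -> np.ndarray:
    """I.i.d. (uncorrelated) positive intervals; DFA alpha = 0.5."""
    rng = np.random.default_rng(seed)
    y = rng.normal(mean_ms, sd_ms, size=n)
    return np.clip(y, 0.1, None)


def fgn(hurst: float, n: int, seed=0) -> np.ndarray:
    """Fractional Gaussian noise by circulant embedding (Davies–Harte).

    The increments have Hurst exponent ``hurst``; DFA of the series
    recovers alpha = hurst.
    """
    if not (0 < hurst < 1):
        raise ValueError("hurst must be in (0, 1)")
    rng = np.random.default_rng(seed)
    k = np.arange(n)
    # autocovariance of fGn
    gamma = 0.5 * (np.abs(k - 1) ** (2 * hurst) - 2 * k ** (2 * hurst)
                   + (k + 1) ** (2 * hurst))
    row = np.concatenate([gamma, gamma[-2:0:-1]])
    lam = np.fft.rfft(row).real
    lam = np.clip(lam, 0.0, None)  # guard tiny negatives from rounding
    m = row.size
    z = rng.normal(size=m // 2 + 1) + 1j * rng.normal(size=m // 2 + 1)
    z[0] = z[0].real * np.sqrt(2)
    if m % 2 == 0:
        z[-1] = z[-1].real * np.sqrt(2)
    w = np.fft.irfft(z * np.sqrt(lam * m / 2), n=m)
    return w[:n]


def hurst_isi(hurst: float, n: int, mean_ms: float = 25.0,
              sd_ms: float = 5.0, seed=0) -> np.ndarray:
    """Positive intervals with long-range correlations of exponent ``hurst``."""
    g = fgn(hurst, n, seed)
    g = (g - g.mean()) / g.std()
    return np.clip(mean_ms + sd_ms * g, 0.1, None)


def make_scaling_series(kind: str, n: int, seed=0, **params):
    """Synthetic series with known statistical structure.

    kind: 'white-isi', 'hurst-isi' (params: hurst), or 'powerlaw-sizes'
    (params: slope, s_max).  Returns (series, manifest) where the manifest
    records the true parameters.
    """
    if kind == "white-isi":
        return white_isi(n, seed=seed, **params), {"alpha": 0.5}
    if kind == "hurst-isi":
        h = params.pop("hurst", 0.8)
        return hurst_isi(h, n, seed=seed, **params), {"alpha": h}
    if kind == "powerlaw-sizes":
        slope = params.pop("slope", -1.5)
        s_max = params.pop("s_max", 100)
        return (powerlaw_sizes(slope, s_max, n, seed=seed),
                {"lambda": slope, "s_max": s_max})
    raise ValueError(f"unknown series kind {kind!r}")


def poisson_raster(n_neurons: int, rate_hz: float, duration_s: float,
                   seed=0, dt_ms: float = 1.0) -> SpikeRaster:
    """Independent Bernoulli-per-step spike trains (memoryless surrogate)."""
    rng = np.random.default_rng(seed)
    n_steps = int(round(duration_s * 1000.0 / dt_ms))
    p = rate_hz * dt_ms / 1000.0
    lam = p * n_neurons * n_steps
    n_ev = rng.poisson(lam)
    steps = rng.integers(0, n_steps, size=n_ev)
    neurons = rng.integers(0, n_neurons, size=n_ev)
    uniq = np.unique(steps.astype(np.int64) * n_neurons + neurons)
    return SpikeRaster(uniq // n_neurons, uniq % n_neurons, n_neurons, dt_ms)
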