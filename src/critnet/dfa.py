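"""Detrended fluctuation analysis of inter-spike-interval series.

The ISI series of a neuron is centered and integrated into a profile, the
profile is split into non-overlapping segments of length ``l``, each
segment is detrended by a least-squares linear fit, and the root mean
squared residual F(l) is collected over a range of scales.  For a process
with power-law correlations the fluctuation amplitude scales as
``F(l) ~ l^alpha``; alpha is the slope of log F vs log l.  alpha = 0.5 for
uncorrelated intervals, 0.5 < alpha < 1 for positive long-range
correlations.  (The exponent is fitted on the amplitude scale — F, not F².)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from .raster import SpikeRaster


@dataclass
class IsiSeries:
    """Ordered inter-spike intervals of one neuron, in ms."""

    intervals: np.ndarray

    def __post_init__(self) -> None:
        self.intervals = np.asarray(self.intervals, dtype=np.float64)
        if np.any(self.intervals <= 0):
            raise ValueError("intervals must be positive")

    @property
    def n(self) -> int:
        return int(self.intervals.size)


@dataclass
class DfaResult:
    scales: np.ndarray
    fluctuation: np.ndarray      # F(l), amplitude scale
    alpha: float                 # NaN when degenerate (zero fluctuation)
    fit_r_squared: float

    @property
    def degenerate(self) -> bool:
        return not np.isfinite(self.alpha)


def isi_from_raster(raster: SpikeRaster, neuron: int) -> IsiSeries:
    """Consecutive spike-time differences of one neuron, in ms."""
    t = raster.spike_times_of(neuron)
    if t.size < 2:
        raise ValueError(f"neuron {neuron} has fewer than 2 spikes")
    return IsiSeries(np.diff(t))


def default_scales(n: int, n_scales: int = 20, min_scale: int = 4
                   ) -> np.ndarray:
    """~20 log-spaced integer scales in [min_scale, n // 4]."""
    max_scale = n // 4
    if max_scale < min_scale:
        raise ValueError("series too short for DFA")
    s = np.unique(np.round(np.geomspace(min_scale, max_scale,
                                        n_scales)).astype(int))
    return s


def _fluctuation(profile: np.ndarray, l: int) -> float:
    """RMS linear-detrended residual over non-overlapping segments of length l."""
    n = profile.size
    m = n // l
    z = profile[: m * l].reshape(m, l)
    t = np.arange(l, dtype=np.float64)
    t_mean = t.mean()
    t_var = ((t - t_mean) ** 2).sum()
    z_mean = z.mean(axis=1, keepdims=True)
    slope = ((z - z_mean) * (t - t_mean)).sum(axis=1, keepdims=True) / t_var
    resid = z - z_mean - slope * (t - t_mean)
    return float(np.sqrt((resid ** 2).mean()))


def dfa_alpha(series: IsiSeries, scales: np.ndarray | None = None,
              detrend_order: int = 1) -> DfaResult:
    """DFA of an ISI series; alpha from the slope of log F(l) vs log l."""
    if detrend_order != 1:
        raise NotImplementedError("only first-order detrending is provided")
    y = series.intervals
    n = y.size
    if scales is None:
        scales = default_scales(n)
    scales = np.asarray(scales, dtype=int)
    if scales.min() < detrend_order + 2:
        raise ValueError("min scale must be >= detrend_order + 2")
    if scales.max() > n // 4:
        raise ValueError("max scale must be <= N/4")
    profile = np.cumsum(y - y.mean())
    F = np.array([_fluctuation(profile, int(l)) for l in scales])
    if np.any(F <= 0):
        return DfaResult(scales=scales, fluctuation=F, alpha=np.nan,
                         fit_r_squared=np.nan)
    res = stats.linregress(np.log(scales), np.log(F))
    return DfaResult(scales=scales, fluctuation=F,
                     alpha=float(res.slope),
                     fit_r_squared=float(res.rvalue ** 2))


def dfa_population(raster: SpikeRaster, neuron_sample_size: int = 1000,
                   seed=0, min_spikes: int = 64,
                   t0_ms: float = 0.0) -> dict:
    """DFA alpha for a random sample of neurons.

    Neurons with fewer than ``min_spikes`` spikes after ``t0_ms`` are
    skipped (count reported).  Returns a dict with per-neuron alphas,
    the sampled ids, mean/SD, and the skip count.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    size = min(neuron_sample_size, raster.n_neurons)
    sample = rng.choice(raster.n_neurons, size=size, replace=False)
    alphas, kept = [], []
    n_skipped = 0
    for nid in sample:
        t = raster.spike_times_of(int(nid))
        t = t[t >= t0_ms]
        if t.size < min_spikes:
            n_skipped += 1
            continue
        res = dfa_alpha(IsiSeries(np.diff(t)))
        if res.degenerate:
            n_skipped += 1
            continue
        alphas.append(res.alpha)
        kept.append(int(nid))
    alphas = np.asarray(alphas)
    return {
        "alpha": alphas,
        "neurons": np.asarray(kept),
        "mean": float(alphas.mean()) if alphas.size else np.nan,
        "sd": float(alphas.std(ddof=1)) if alphas.size > 1 else np.nan,
        "n_skipped": n_skipped,
    }
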