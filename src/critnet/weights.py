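"""Weight-evolution analyses: histograms, condition differences, flips,
thresholded in-degrees and STDP-vs-STP entropy.

All weights are on the normalised [0, 1] scale.  "Flips" are transitions
of a synapse between the low (< 0.1) and high (> 0.9) weight regime with
two-threshold hysteresis: after leaving one regime, a flip is recorded only
when the synapse fully enters the opposite regime.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class WeightSnapshotSeries:
    """Per-synapse snapshots over time, plus the synapse class labels."""

    times_ms: np.ndarray
    weights: list                   # arrays, one per snapshot
    syn_is_inhibitory: np.ndarray   # per synapse (presynaptic class)
    efficacy: list | None = None    # u*x snapshots, optional

    def __post_init__(self) -> None:
        self.times_ms = np.asarray(self.times_ms, dtype=np.float64)
        if np.any(np.diff(self.times_ms) <= 0):
            raise ValueError("snapshot times must be strictly increasing")
        if len(self.weights) != self.times_ms.size:
            raise ValueError("one weight array per snapshot time required")

    @classmethod
    def from_run(cls, result) -> "WeightSnapshotSeries":
        return cls(times_ms=result.snapshot_times_ms,
                   weights=result.snapshots_w,
                   syn_is_inhibitory=result.syn_is_inhibitory,
                   efficacy=result.snapshots_eff or None)


@dataclass
class EntropySeries:
    times_ms: np.ndarray
    H_g: np.ndarray       # entropy of excitatory weights, bits
    H_z: np.ndarray       # entropy of inhibitory weights, bits
    H_ux: np.ndarray      # entropy of synaptic efficacy, bits

    @property
    def dH_stdp_vs_stp(self) -> np.ndarray:
        """H_g - H_ux: positive when E-STDP dominates over STP."""
        return self.H_g - self.H_ux

    @property
    def dH_istdp_vs_stp(self) -> np.ndarray:
        return self.H_z - self.H_ux

    @property
    def dH_e_vs_i(self) -> np.ndarray:
        return self.H_g - self.H_z


def weight_mse(weights_a: np.ndarray, weights_b: np.ndarray) -> float:
    """Mean squared difference: ||w1 - w2||^2 / n_synapses."""
    a = np.asarray(weights_a, dtype=np.float64)
    b = np.asarray(weights_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("weight vectors must share the synapse indexing")
    d = a - b
    return float(d @ d / a.size)


def detect_flips(series: WeightSnapshotSeries, low: float = 0.1,
                 high: float = 0.9):
    """Flip events per synapse under two-threshold hysteresis.

    A synapse is armed when it sits in a regime (w < low or w > high); a
    flip is recorded at the first snapshot where it is found in the
    opposite regime.  Intermediate dwell does not count.  Returns
    (flip_times_ms, flip_synapse_indices) sorted by time, and the flip
    count per synapse, as a tuple.
    """
    if not (0 < low < high < 1):
        raise ValueError("require 0 < low < high < 1")
    W = np.asarray(series.weights)
    n_syn = W.shape[1]
    # regime per snapshot: -1 low, +1 high, 0 between
    reg = np.zeros(W.shape, dtype=np.int8)
    reg[W < low] = -1
    reg[W > high] = 1
    state = reg[0].copy()          # last fully-entered regime, 0 = never
    flip_t, flip_s = [], []
    counts = np.zeros(n_syn, dtype=np.int64)
    for t in range(1, W.shape[0]):
        r = reg[t]
        flipped = (r != 0) & (state != 0) & (r != state)
        idx = np.flatnonzero(flipped)
        if idx.size:
            flip_t.extend([series.times_ms[t]] * idx.size)
            flip_s.extend(idx.tolist())
            counts[idx] += 1
        entered = r != 0
        state[entered] = r[entered]
    return (np.asarray(flip_t), np.asarray(flip_s, dtype=np.int64), counts)


def in_degree_series(series: WeightSnapshotSeries, connectivity,
                     syn_post: np.ndarray, threshold: float = 0.1) -> dict:
    """Mean/SD in-degree over time, counting synapses with w >= threshold.

    Split by presynaptic class.  ``syn_post`` gives the postsynaptic
    neuron of each synapse, aligned with the snapshot weight arrays.
    """
    if not (0 < threshold < 1):
        raise ValueError("threshold must be in (0, 1)")
    n = connectivity.n_neurons
    inh = series.syn_is_inhibitory
    out = {"times_ms": series.times_ms,
           "exc_mean": [], "exc_sd": [], "inh_mean": [], "inh_sd": []}
    for W in series.weights:
        present = np.asarray(W) >= threshold
        for label, mask in (("exc", ~inh), ("inh", inh)):
            deg = np.bincount(syn_post[mask & present], minlength=n)
            out[f"{label}_mean"].append(deg.mean())
            out[f"{label}_sd"].append(deg.std(ddof=0))
    for k in ("exc_mean", "exc_sd", "inh_mean", "inh_sd"):
        out[k] = np.asarray(out[k])
    return out


def _entropy_bits(values: np.ndarray, k_bins: int) -> float:
    h, _ = np.histogram(np.asarray(values), bins=k_bins, range=(0.0, 1.0))
    p = h[h > 0] / h.sum()
    return float(-(p * np.log2(p)).sum())


def entropy_series(series: WeightSnapshotSeries, k_bins: int = 100
                   ) -> EntropySeries:
    """Shannon entropy (bits) of pooled per-synapse values per snapshot.

    Values are histogrammed into ``k_bins`` equal-width bins over [0, 1];
    H_g uses excitatory weights, H_z inhibitory weights, H_ux the
    synaptic efficacies (requires efficacy snapshots).
    """
    if k_bins < 2:
        raise ValueError("need at least 2 bins")
    if series.efficacy is None:
        raise ValueError("entropy of efficacy requires efficacy snapshots")
    inh = series.syn_is_inhibitory
    H_g = np.array([_entropy_bits(W[~inh], k_bins) for W in series.weights])
    H_z = np.array([_entropy_bits(W[inh], k_bins) for W in series.weights])
    H_ux = np.array([_entropy_bits(E, k_bins) for E in series.efficacy])
    return EntropySeries(times_ms=series.times_ms, H_g=H_g, H_z=H_z,
                         H_ux=H_ux)


def weight_histogram_series(series: WeightSnapshotSeries, k_bins: int = 50
                            ) -> dict:
    """Per-snapshot weight histograms, separately for E and I synapses."""
    if k_bins < 2:
        raise ValueError("need at least 2 bins")
    inh = series.syn_is_inhibitory
    edges = np.linspace(0.0, 1.0, k_bins + 1)
    exc = np.stack([np.histogram(W[~inh], bins=edges)[0]
                    for W in series.weights])
    inh_h = np.stack([np.histogram(W[inh], bins=edges)[0]
                      for W in series.weights])
    return {"edges": edges, "exc": exc, "inh": inh_h,
            "times_ms": series.times_ms}
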