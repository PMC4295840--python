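"""Spike raster container: an event list of (step, neuron) at fixed dt."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


@dataclass
class SpikeRaster:
    """Binary spike indicator per neuron per time step, stored as events.

    ``steps`` and ``neurons`` are parallel arrays sorted by step (then
    neuron); at most one event per (step, neuron).
    """

    steps: np.ndarray      # int64, time step indices
    neurons: np.ndarray    # int64, neuron ids
    n_neurons: int
    dt_ms: float = 1.0

    def __post_init__(self) -> None:
        self.steps = np.asarray(self.steps, dtype=np.int32)
        self.neurons = np.asarray(self.neurons, dtype=np.int32)
        if self.steps.shape != self.neurons.shape:
            raise ValueError("steps and neurons must have equal length")
        if self.steps.size and (self.neurons.min() < 0
                                or self.neurons.max() >= self.n_neurons):
            raise ValueError("neuron id out of range")
        if self.steps.size > 1:
            ds = np.diff(self.steps)
            dn = np.diff(self.neurons)
            if np.any(ds < 0) or np.any((ds == 0) & (dn <= 0)):
                order = np.lexsort((self.neurons, self.steps))
                self.steps = self.steps[order]
                self.neurons = self.neurons[order]

    @property
    def n_events(self) -> int:
        return int(self.steps.size)

    @property
    def times_ms(self) -> np.ndarray:
        return self.steps * self.dt_ms

    @property
    def duration_steps(self) -> int:
        return int(self.steps[-1]) + 1 if self.steps.size else 0

    def spike_times_of(self, neuron: int) -> np.ndarray:
        """Spike times of one neuron in ms, sorted."""
        return np.sort(self.steps[self.neurons == neuron]) * self.dt_ms

    def window(self, t0_ms: float, t1_ms: float) -> "SpikeRaster":
        """Events with t0_ms <= time < t1_ms, steps re-based to 0."""
        lo = int(np.ceil(t0_ms / self.dt_ms))
        hi = int(np.ceil(t1_ms / self.dt_ms))
        i0, i1 = np.searchsorted(self.steps, [lo, hi])
        return SpikeRaster(self.steps[i0:i1] - lo, self.neurons[i0:i1],
                           self.n_neurons, self.dt_ms)

    def subset(self, neuron_ids: np.ndarray, relabel: bool = True) -> "SpikeRaster":
        """Restrict to a neuron subset; optionally relabel ids to 0..k-1
        following the sorted order of ``neuron_ids``."""
        neuron_ids = np.unique(np.asarray(neuron_ids, dtype=np.int64))
        mask = np.isin(self.neurons, neuron_ids)
        neur = self.neurons[mask]
        if relabel:
            neur = np.searchsorted(neuron_ids, neur)
            n = len(neuron_ids)
        else:
            n = self.n_neurons
        return SpikeRaster(self.steps[mask], neur, n, self.dt_ms)

    def counts_per_step(self, n_steps: int | None = None) -> np.ndarray:
        """Population spike count at every step from 0 to n_steps-1."""
        if n_steps is None:
            n_steps = self.duration_steps
        return np.bincount(self.steps, minlength=n_steps).astype(np.int64)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, SpikeRaster):
            return NotImplemented
        return (self.n_neurons == other.n_neurons
                and self.dt_ms == other.dt_ms
                and np.array_equal(self.steps, other.steps)
                and np.array_equal(self.neurons, other.neurons))


def from_dense(X: np.ndarray, dt_ms: float = 1.0) -> SpikeRaster:
    """Build a raster from a dense (n_steps, n_neurons) binary matrix."""
    step, neuron = np.nonzero(np.asarray(X))
    return SpikeRaster(step, neuron, X.shape[1], dt_ms)
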