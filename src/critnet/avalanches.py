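"""Avalanche tracking, branching ratios and power-law exponent estimation.

An avalanche is a set of causally contiguous spikes.  A spike (i, n) is
attributed to *every* avalanche that already contains a presynaptic spike
(j, s) with an edge j -> i and s inside the causal window
``[n - phi - delta, n - phi - 1]``; a spike with no such contributor starts
a new singleton avalanche.  Avalanches may therefore overlap — a spike can
belong to several of them, and each of those counts it toward its size.

The branching ratio sigma(n) compares postsynaptic to presynaptic activity
around each step, in offset windows of width ``delta`` and offset ``phi``
(the network has a 1-step transmission delay, hence the default phi = 1;
delta = 3 covers conductance decay).  sigma = 1 is the critical balance
point.  The avalanche-size distribution of a critical network follows a
power law with slope lambda close to -3/2 on log-log axes.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

from . import _kernel
from .model_core import Connectivity
from .raster import SpikeRaster


@dataclass(frozen=True)
class WindowSpec:
    """Causal window: width ``delta`` steps at offset ``phi`` steps."""

    delta: int = 3
    phi: int = 1

    def __post_init__(self) -> None:
        if self.delta < 1 or self.phi < 0:
            raise ValueError("require delta >= 1 and phi >= 0")


@dataclass
class AvalancheSet:
    """Avalanche memberships of a raster; sizes are set cardinalities.

    For large rasters the tracker runs in streaming mode and retains only
    the sizes; ``memberships`` is then unavailable.
    """

    sizes: np.ndarray                    # int64, one entry per avalanche
    ids_indptr: np.ndarray | None = None  # per-spike membership offsets
    ids_flat: np.ndarray | None = None    # concatenated ids per spike
    truncated: bool = False              # streaming work budget exhausted

    @property
    def n_avalanches(self) -> int:
        return int(self.sizes.size)

    @property
    def has_membership(self) -> bool:
        return self.ids_indptr is not None

    def memberships(self, spike_index: int) -> np.ndarray:
        if not self.has_membership:
            raise ValueError("tracker ran in streaming (sizes-only) mode")
        return self.ids_flat[self.ids_indptr[spike_index]:
                             self.ids_indptr[spike_index + 1]]


@dataclass
class ExponentFit:
    slope: float            # lambda
    r_squared: float
    p_value: float
    fit_range: tuple        # (s_min, s_max) sizes included
    n_points: int


def _in_csr(connectivity: Connectivity):
    csc = connectivity.adjacency.tocsc()
    return csc.indptr.astype(np.int64), csc.indices.astype(np.int64)


def track_avalanches(raster: SpikeRaster, connectivity: Connectivity,
                     window: WindowSpec = WindowSpec(),
                     keep_membership: bool | None = None,
                     max_mass: int = 200_000_000,
                     max_work: int = 2_000_000_000) -> AvalancheSet:
    """Causal avalanche tracking with overlapping membership.

    The raster must be restricted to the neurons of ``connectivity``
    (ids matching matrix rows).  By default the full per-spike
    membership lists are kept for small rasters (< 200k spikes) while
    larger rasters run in streaming (sizes-only) mode with bounded
    memory; both paths implement identical set semantics.
    """
    if raster.n_neurons != connectivity.n_neurons:
        raise ValueError("raster and connectivity disagree on neuron count")
    in_indptr, in_indices = _in_csr(connectivity)
    ev_s = raster.steps.astype(np.int64)
    ev_n = raster.neurons.astype(np.int64)
    if keep_membership is None:
        keep_membership = raster.n_events < 200_000
    if keep_membership:
        sizes, indptr, flat, ok = _kernel.track_avalanches_kernel(
            ev_s, ev_n, in_indptr, in_indices, connectivity.n_neurons,
            window.phi, window.delta, max_mass)
        if not ok:
            raise RuntimeError(
                "avalanche membership mass exceeded max_mass; retry with "
                "keep_membership=False (streaming mode)")
        return AvalancheSet(sizes=sizes, ids_indptr=indptr, ids_flat=flat)
    # streaming: pool must hold every spike inside the causal horizon
    P = window.phi + window.delta + 1
    if raster.n_events:
        counts = np.bincount(ev_s - ev_s[0])
        win_max = np.convolve(counts, np.ones(P, dtype=np.int64),
                              mode="full").max()
    else:
        win_max = 1
    sizes, completed = _kernel.track_avalanche_sizes_kernel(
        ev_s, ev_n, in_indptr, in_indices, connectivity.n_neurons,
        window.phi, window.delta, int(win_max) + 8, max_work)
    return AvalancheSet(sizes=sizes, truncated=not completed)


def track_avalanches_bruteforce(raster: SpikeRaster,
                                connectivity: Connectivity,
                                window: WindowSpec = WindowSpec()
                                ) -> AvalancheSet:
    """Reference implementation: exhaustive per-spike window scan.

    Independent of the compiled tracker; quadratic-ish and meant for small
    rasters only.
    """
    A = connectivity.adjacency
    events = list(zip(raster.steps.tolist(), raster.neurons.tolist()))
    events.sort()
    memberships: list[set] = []
    sizes: list[int] = []
    for e, (n, i) in enumerate(events):
        ids: set = set()
        for p in range(e):
            s, j = events[p]
            if (n - window.phi - window.delta <= s <= n - window.phi - 1
                    and A[j, i]):
                ids |= memberships[p]
        if not ids:
            ids = {len(sizes)}
            sizes.append(0)
        for a in ids:
            sizes[a] += 1
        memberships.append(ids)
    indptr = np.zeros(len(events) + 1, dtype=np.int64)
    flat = []
    for e, ids in enumerate(memberships):
        flat.extend(sorted(ids))
        indptr[e + 1] = len(flat)
    return AvalancheSet(sizes=np.asarray(sizes, dtype=np.int64),
                        ids_indptr=indptr,
                        ids_flat=np.asarray(flat, dtype=np.int64))


def sample_subgraph(connectivity: Connectivity, p: float, seed
                    ) -> tuple[Connectivity, np.ndarray]:
    """Induced subgraph on a Bernoulli(p) node sample.

    Keeps an edge iff both endpoints were sampled; node ids are relabelled
    to 0..k-1 in sorted order.  Returns (sub_connectivity, sampled_ids).
    """
    if not (0 < p <= 1):
        raise ValueError("sampling probability must be in (0, 1]")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    keep = rng.random(connectivity.n_neurons) < p
    ids = np.flatnonzero(keep)
    if ids.size == 0:
        raise ValueError("empty node sample")
    sub = connectivity.adjacency[np.ix_(ids, ids)].tocsr()
    return Connectivity(
        n_neurons=ids.size,
        is_inhibitory=connectivity.is_inhibitory[ids],
        adjacency=sub,
        connection_prob=connectivity.connection_prob,
        seed=connectivity.seed,
    ), ids


def branching_ratio_series(raster: SpikeRaster, connectivity: Connectivity,
                           window: WindowSpec = WindowSpec(),
                           step_range: tuple | None = None,
                           network_form: bool = True) -> np.ndarray:
    """sigma(n) per step; NaN where undefined (no presynaptic activity)."""
    if raster.n_neurons != connectivity.n_neurons:
        raise ValueError("raster and connectivity disagree on neuron count")
    if step_range is None:
        lo, hi = 0, max(raster.duration_steps - 1, 0)
    else:
        lo, hi = step_range
    A = connectivity.adjacency
    in_indptr, in_indices = _in_csr(connectivity)
    return _kernel.branching_series_kernel(
        raster.steps.astype(np.int64), raster.neurons.astype(np.int64),
        A.indptr.astype(np.int64), A.indices.astype(np.int64),
        in_indptr, in_indices,
        connectivity.n_neurons, window.phi, window.delta, lo, hi,
        network_form)


def branching_ratio_network(raster: SpikeRaster, connectivity: Connectivity,
                            window: WindowSpec, step: int) -> float:
    """Shared-connection (network) branching ratio at one step; NaN if undefined."""
    return float(branching_ratio_series(raster, connectivity, window,
                                        (step, step), True)[0])


def branching_ratio_local(raster: SpikeRaster, connectivity: Connectivity,
                          window: WindowSpec, step: int) -> float:
    """Per-spiker branching ratios averaged over this step's spikers."""
    return float(branching_ratio_series(raster, connectivity, window,
                                        (step, step), False)[0])


def default_fit_range(sizes: np.ndarray, s_cap: int = 20) -> tuple:
    """Initial-segment fit range: sizes 1 .. min(s_cap, largest observed).

    Subsampled avalanche-size distributions are power-law over their
    initial segment and bend at larger sizes (finite-size and
    super-critical excess), so the default regression covers sizes up to
    ``s_cap``.  If that leaves fewer than 5 support points the range is
    widened to the largest observed size.
    """
    sizes = np.asarray(sizes)
    s_hi = int(min(s_cap, sizes.max()))
    if np.unique(sizes[sizes <= s_hi]).size < 5:
        s_hi = int(sizes.max())
    return (1, max(s_hi, 2))


def fit_size_exponent(sizes: np.ndarray, fit_range: tuple | None = None
                      ) -> ExponentFit:
    """OLS slope of log10(count) vs log10(size), unbinned.

    Only sizes with non-zero counts inside ``fit_range`` enter the
    regression; at least 5 distinct support points are required.
    """
    sizes = np.asarray(sizes, dtype=np.int64)
    if sizes.size == 0:
        raise ValueError("no avalanche sizes to fit")
    if fit_range is None:
        fit_range = default_fit_range(sizes)
    s_min, s_max = fit_range
    vals, counts = np.unique(sizes, return_counts=True)
    keep = (vals >= s_min) & (vals <= s_max)
    vals, counts = vals[keep], counts[keep]
    if vals.size < 5:
        raise ValueError(
            f"need >= 5 distinct sizes with support in {fit_range}, "
            f"got {vals.size}")
    res = stats.linregress(np.log10(vals), np.log10(counts))
    return ExponentFit(slope=float(res.slope),
                       r_squared=float(res.rvalue ** 2),
                       p_value=float(res.pvalue),
                       fit_range=(int(s_min), int(s_max)),
                       n_points=int(vals.size))


def subsampled_lambda(raster: SpikeRaster, connectivity: Connectivity,
                      p: float = 0.125, seed=0,
                      window: WindowSpec = WindowSpec(),
                      fit_range: tuple | None = None,
                      max_work: int = 2_000_000_000) -> ExponentFit:
    """Track avalanches on a p-subsampled graph and fit the size exponent."""
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    sub, ids = sample_subgraph(connectivity, p, rng)
    sub_raster = raster.subset(ids, relabel=True)
    av = track_avalanches(sub_raster, sub, window, max_work=max_work)
    return fit_size_exponent(av.sizes, fit_range)


def lambda_resampling(raster: SpikeRaster, connectivity: Connectivity,
                      n_resamples: int = 100, p: float = 0.125, seed=0,
                      window: WindowSpec = WindowSpec(),
                      max_work: int = 50_000_000) -> np.ndarray:
    """Distribution of lambda over repeated random subsamples.

    Per-draw tracking work is budgeted (see :func:`track_avalanches`);
    draws hitting the budget contribute the prefix they completed.
    """
    rng = np.random.default_rng(seed)
    out = np.empty(n_resamples)
    for r in range(n_resamples):
        out[r] = subsampled_lambda(raster, connectivity, p, rng,
                                   window, max_work=max_work).slope
    return out


def sliding_lambda(raster: SpikeRaster, connectivity: Connectivity,
                   window_s: float = 100.0, stride_s: float | None = None,
                   p: float = 0.125, seed=0,
                   avalanche_window: WindowSpec = WindowSpec()):
    """lambda estimate per sliding time window.

    One fixed p-subsample (drawn from ``seed``) is reused across windows.
    Returns (window_start_times_s, lambda_array); windows whose fit fails
    (too little support) yield NaN.
    """
    if stride_s is None:
        stride_s = window_s / 2.0
    dur_s = raster.duration_steps * raster.dt_ms / 1000.0
    if dur_s < window_s:
        raise ValueError("raster shorter than the sliding window")
    sub, ids = sample_subgraph(connectivity, p, seed) if p < 1 \
        else (connectivity, np.arange(connectivity.n_neurons))
    sub_raster = raster.subset(ids, relabel=True)
    starts = np.arange(0.0, dur_s - window_s + 1e-9, stride_s)
    lams = np.full(starts.size, np.nan)
    for i, t0 in enumerate(starts):
        rw = sub_raster.window(t0 * 1000.0, (t0 + window_s) * 1000.0)
        try:
            av = track_avalanches(rw, sub, avalanche_window)
            lams[i] = fit_size_exponent(av.sizes).slope
        except (ValueError, RuntimeError):
            pass
    return starts, lams
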