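"""Neuron model primitives: membrane dynamics, conductance kinetics, connectivity.

The network is built from conductance-based leaky integrate-and-fire neurons.
Each neuron's membrane potential obeys

    tau_m dV/dt = (V_rest - V) + (E_ex - V) g_w + (E_inh - V) g_z

where ``g_w`` and ``g_z`` are the aggregate excitatory and inhibitory
conductances (in nS, multiplying voltage differences directly; no capacitance
term is introduced).  Presynaptic spikes deposit instantaneous conductance
jumps that then decay exponentially with the AMPA / GABA time constants.
Deltas cannot be pushed through a Runge-Kutta step, so the convention here is
jump-at-step-boundary followed by integration of the smooth flow: the
membrane equation is advanced with classical RK4 while the conductances decay
with their exact closed-form exponential inside the step.

Connectivity is a directed Erdős–Rényi graph over labelled neurons, the first
block excitatory and the remainder inhibitory.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import sparse


@dataclass(frozen=True)
class NeuronConstants:
    """Fixed membrane constants, shared by every neuron in the network."""

    tau_m: float = 20.0       # membrane time constant, ms
    V_T: float = -54.0        # spike threshold, mV
    V_rest: float = -74.0     # resting potential, mV
    V_reset: float = -60.0    # post-spike potential, mV (14 mV above rest)
    E_ex: float = 0.0         # excitatory reversal potential, mV
    E_inh: float = -80.0      # inhibitory reversal potential, mV

    def __post_init__(self) -> None:
        if not (self.V_rest < self.V_reset < self.V_T):
            raise ValueError("require V_rest < V_reset < V_T")
        if not (self.E_inh < self.V_rest < self.E_ex):
            raise ValueError("require E_inh < V_rest < E_ex")
        if self.tau_m <= 0:
            raise ValueError("tau_m must be positive")


@dataclass(frozen=True)
class KineticConstants:
    """Receptor kinetics: exponential decay constants of the aggregate conductances."""

    tau_AMPA: float = 19.0    # ms
    tau_GABA: float = 14.0    # ms

    def __post_init__(self) -> None:
        if self.tau_AMPA <= 0 or self.tau_GABA <= 0:
            raise ValueError("kinetic time constants must be positive")


@dataclass
class Connectivity:
    """Directed random graph with per-neuron E/I labels.

    ``adjacency`` is a sparse boolean matrix in CSR form with entry (i, j)
    meaning a synapse from presynaptic neuron i onto postsynaptic neuron j.
    Neurons ``0 .. n_exc-1`` are excitatory, the rest inhibitory.
    """

    n_neurons: int
    is_inhibitory: np.ndarray          # bool per neuron
    adjacency: sparse.csr_matrix       # bool, pre -> post
    connection_prob: float
    seed: int

    @property
    def n_exc(self) -> int:
        return int(self.n_neurons - self.is_inhibitory.sum())

    @property
    def n_edges(self) -> int:
        return int(self.adjacency.nnz)

    def in_degrees(self, from_inhibitory: bool | None = None) -> np.ndarray:
        """In-degree per neuron, optionally restricted by presynaptic class."""
        A = self.adjacency
        if from_inhibitory is None:
            return np.asarray(A.sum(axis=0)).ravel()
        mask = self.is_inhibitory if from_inhibitory else ~self.is_inhibitory
        return np.asarray(A[mask].sum(axis=0)).ravel()

    def out_degrees(self) -> np.ndarray:
        return np.asarray(self.adjacency.sum(axis=1)).ravel()


@dataclass
class NeuronDynamicState:
    """Per-neuron dynamic variables carried across steps."""

    V: np.ndarray        # membrane potential, mV
    g_w: np.ndarray      # aggregate excitatory conductance, nS
    g_z: np.ndarray      # aggregate inhibitory conductance, nS
    spiked: np.ndarray = field(default=None)  # bool, last step's spikes

    def __post_init__(self) -> None:
        if self.spiked is None:
            self.spiked = np.zeros(self.V.shape, dtype=bool)

    @classmethod
    def at_rest(cls, n: int, constants: NeuronConstants) -> "NeuronDynamicState":
        return cls(
            V=np.full(n, constants.V_rest, dtype=np.float64),
            g_w=np.zeros(n, dtype=np.float64),
            g_z=np.zeros(n, dtype=np.float64),
        )


def init_connectivity(
    n: int, frac_inhibitory: float, c: float, seed: int
) -> Connectivity:
    """Directed Erdős–Rényi graph G(n, c) with a deterministic E/I partition.

    Each of the n(n-1) possible directed edges (self-loops excluded) is
    present independently with probability ``c``.  The first
    ``floor(n * (1 - frac_inhibitory))`` neurons are excitatory.  Edges are
    sampled with the geometric-gap method, so construction is O(edges) and
    fully reproducible from ``seed``.
    """
    if n < 2:
        raise ValueError("need at least 2 neurons")
    if not (0 <= c < 1):
        if c == 1.0:
            pass  # fully connected is allowed
        else:
            raise ValueError("connection probability must be in [0, 1]")
    if not (0 <= frac_inhibitory < 1):
        raise ValueError("inhibitory fraction must be in [0, 1)")

    n_exc = int(np.floor(n * (1.0 - frac_inhibitory)))
    is_inh = np.zeros(n, dtype=bool)
    is_inh[n_exc:] = True

    n_pairs = n * (n - 1)  # linearised ordered pairs, diagonal skipped
    rng = np.random.default_rng(seed)
    if c == 0:
        lin = np.empty(0, dtype=np.int64)
    elif c == 1.0:
        lin = np.arange(n_pairs, dtype=np.int64)
    else:
        # Batagelj–Brandes skipping: gaps between successive edges are
        # geometric(c); draw in slabs until the index space is exhausted.
        chunks = []
        pos = -1
        expect = int(n_pairs * c)
        while True:
            draw = max(1000, int(1.1 * (n_pairs - pos) * c))
            gaps = rng.geometric(c, size=draw).astype(np.int64)
            idx = pos + np.cumsum(gaps)
            pos = int(idx[-1])
            chunks.append(idx)
            if pos >= n_pairs:
                break
        lin = np.concatenate(chunks)
        lin = lin[lin < n_pairs]

    pre = lin // (n - 1)
    rem = lin % (n - 1)
    post = np.where(rem < pre, rem, rem + 1)  # skip the diagonal

    adj = sparse.csr_matrix(
        (np.ones(len(pre), dtype=bool), (pre, post)), shape=(n, n)
    )
    return Connectivity(
        n_neurons=n,
        is_inhibitory=is_inh,
        adjacency=adj,
        connection_prob=c,
        seed=seed,
    )


def _dVdt(
    V: np.ndarray, g_w: np.ndarray, g_z: np.ndarray, k: NeuronConstants
) -> np.ndarray:
    return (
        (k.V_rest - V) + (k.E_ex - V) * g_w + (k.E_inh - V) * g_z
    ) / k.tau_m


def membrane_step(
    state: NeuronDynamicState,
    constants: NeuronConstants,
    kinetics: KineticConstants,
    dt: float = 1.0,
) -> NeuronDynamicState:
    """Advance V by one RK4 step of the membrane equation.

    The conductances held in ``state`` are the values at the start of the
    step; the RK4 stages sample them at sub-step times through the exact
    exponential decay.  ``state.g_w``/``g_z`` themselves are not modified
    here (see :func:`decay_and_deposit_conductances`).  No spikes are
    emitted.
    """
    V, gw_s, gz_s = state.V, state.g_w, state.g_z
    if not (np.all(np.isfinite(V)) and np.all(np.isfinite(gw_s))
            and np.all(np.isfinite(gz_s))):
        raise FloatingPointError("non-finite neuron state entering membrane_step")

    # Large total conductance makes the base step stiff; subdivide it
    # (per neuron, deterministically) to stay in the RK4 stability region.
    nsub_all = 1 + ((1.0 + gw_s + gz_s) * dt / (1.5 * constants.tau_m)).astype(int)
    V_new = np.empty_like(V)
    for nsub in np.unique(nsub_all):
        sel = nsub_all == nsub
        h = dt / nsub
        dw_h = np.exp(-0.5 * h / kinetics.tau_AMPA)
        dz_h = np.exp(-0.5 * h / kinetics.tau_GABA)
        v = V[sel].copy()
        gw0, gz0 = gw_s[sel].copy(), gz_s[sel].copy()
        for _ in range(int(nsub)):
            k1 = _dVdt(v, gw0, gz0, constants)
            gw_h, gz_h = gw0 * dw_h, gz0 * dz_h
            k2 = _dVdt(v + 0.5 * h * k1, gw_h, gz_h, constants)
            k3 = _dVdt(v + 0.5 * h * k2, gw_h, gz_h, constants)
            gw_1, gz_1 = gw_h * dw_h, gz_h * dz_h
            k4 = _dVdt(v + h * k3, gw_1, gz_1, constants)
            v = v + (h / 6.0) * (k1 + 2 * k2 + 2 * k3 + k4)
            gw0, gz0 = gw_1, gz_1
        V_new[sel] = v
    return NeuronDynamicState(V=V_new, g_w=state.g_w.copy(), g_z=state.g_z.copy())


def decay_and_deposit_conductances(
    state: NeuronDynamicState,
    kinetics: KineticConstants,
    deposits_exc: np.ndarray | float = 0.0,
    deposits_inh: np.ndarray | float = 0.0,
    dt: float = 1.0,
) -> NeuronDynamicState:
    """Decay conductances by the exact exponential over dt, then add deposits.

    Deposits are the conductance jumps caused by the previous step's
    presynaptic spikes (1-step transmission delay), applied at the step
    boundary.
    """
    if np.any(np.asarray(deposits_exc) < 0) or np.any(np.asarray(deposits_inh) < 0):
        raise ValueError("conductance deposits must be non-negative")
    g_w = state.g_w * np.exp(-dt / kinetics.tau_AMPA) + deposits_exc
    g_z = state.g_z * np.exp(-dt / kinetics.tau_GABA) + deposits_inh
    return NeuronDynamicState(V=state.V.copy(), g_w=g_w, g_z=g_z,
                              spiked=state.spiked.copy())


def detect_spikes_and_reset(
    state: NeuronDynamicState, constants: NeuronConstants
) -> tuple[NeuronDynamicState, np.ndarray]:
    """Threshold crossing (inclusive, V >= V_T) with reset to V_reset.

    Returns the updated state and the integer ids of the spiking neurons.
    At most one spike per neuron per step by construction.
    """
    spiked = state.V >= constants.V_T
    V = np.where(spiked, constants.V_reset, state.V)
    new = NeuronDynamicState(V=V, g_w=state.g_w.copy(), g_z=state.g_z.copy(),
                             spiked=spiked)
    return new, np.flatnonzero(spiked)
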