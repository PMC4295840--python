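# Methods

## Model

The simulator implements a recurrent network of N conductance-based leaky
integrate-and-fire neurons (default N = 10,000; 80% excitatory, 20%
inhibitory) on a directed Erdős–Rényi graph with connection probability
c = 0.01 and no self-loops. The membrane potential of neuron *i* obeys

    τ_m dV_i/dt = (V_rest − V_i) + (E_ex − V_i) g_w,i + (E_inh − V_i) g_z,i

with τ_m = 20 ms, V_rest = −74 mV, V_T = −54 mV, V_reset = −60 mV,
E_ex = 0 mV, E_inh = −80 mV. The equation is taken literally: conductances
in nS multiply voltage differences directly and no capacitance term is
introduced. `g_w` and `g_z` are aggregate excitatory and inhibitory
conductances that decay exponentially with τ_AMPA = 19 ms and
τ_GABA = 14 ms and receive instantaneous jumps from presynaptic spikes with
a one-step (1 ms) transmission delay. Crossing V_T (inclusive) emits a
spike and resets V to V_reset, which is 14 mV above rest — this head start
is what produces the model's characteristic spike bursts.

Three plasticity mechanisms run continuously on every synapse:

* **E-STDP** (E→E, E→I): asymmetric window F(Δt) with Δt = t_pre − t_post;
  potentiation A⁺ e^(Δt/τ⁺) for Δt < 0, depression −A⁻ e^(−Δt/τ⁻) for
  Δt ≥ 0, with A⁺ = 0.0015, τ⁺ = τ⁻ = 20 ms and A⁻ fixed by the area
  ratio β = |A⁻τ⁻|/|A⁺τ⁺| = 1.21 (so A⁻ = 0.001815). Weights are stored
  normalised to [0, 1] of g_exc_max = 1.94 nS and clamped there.
* **I-STDP** (I→E, I→I): symmetric window; +B⁺ e^(−|Δt|/τ) for |Δt| ≤ τ,
  −B⁻ e^(−|Δt|/τ) beyond, with B⁺ = 0.0015 nS, B⁻ = 0.0003 nS, τ = 10 ms,
  normalised by g_inh_max = 4.74 nS. Because the depression branch carries
  the same decaying envelope, its magnitude is at most B⁻/e ≈ 1.1×10⁻⁴ nS:
  in practice this rule almost exclusively potentiates, so inhibition
  ratchets upward wherever pre/post spikes coincide within ~10 ms. That
  ratchet is the homeostatic brake of the model.
* **STP** (all synapses): Tsodyks–Markram utilisation/resource dynamics
  with U = 0.5, τ_F = 41 ms, τ_D = 26 ms (facilitating, τ_F > τ_D).
  On a presynaptic spike, u jumps by U(1−u) first, the transmitted efficacy
  is u_new·x, and x is depleted by that amount; between spikes both relax
  with their exact exponentials. Efficacy is evaluated at spike time and
  folded into the conductance deposit (deposit = u·x·w·g_max).

### Numerical scheme

The membrane equation is advanced with classical RK4 at dt = 1 ms;
conductances are sampled inside the step through their closed-form decay
and updated exactly at step boundaries (deltas cannot be integrated by
RK4, so jumps happen between steps). When the total conductance makes the
step stiff — (1 + g_w + g_z)·dt/τ_m outside the RK4 stability region,
which happens during the initialization burst — the step is subdivided
per neuron, deterministically from the state alone. Without this guard the
integrator overflows during the burst while the true solution merely
saturates.

Within one step the order is: deposit delayed conductances, RK4, spike
detection and reset (including externally forced spikes), STP relaxation
and on-spike updates (producing next-step deposits, using the weights
before this step's STDP), STDP pair updates, recording.

### Refractoriness

An absolute refractory period of 2 ms (configurable; V clamped at
V_reset) is part of the default neuron. It is calibrated by the model's
own reported saturation behaviour: without inhibitory plasticity the
network saturates at ≈320 Hz, which pins the minimum inter-spike interval
at three 1-ms steps (333 Hz); with no refractoriness the saturation rate
of the literal equations is 1000 Hz.

### STDP pairing

The pairing scheme is nearest-neighbour: each spike, acting as post,
pairs once per incoming synapse with that synapse's most recent
presynaptic spike (causal branch); acting as pre, once per outgoing
synapse with the target's most recent spike (anti-causal branch).
Simultaneous (same-step) pairs are handled exactly once, through the
Δt = 0 anti-causal branch: full-strength depression for the E-rule,
maximal potentiation for the I-rule. An all-to-all mode (every partner
spike within a 100 ms cutoff) is available behind
`SimulationConfig.stdp_pairing`.

### Initialization and drive

All weights start at 0.5 (normalised); STP starts at its rest point
(u = U, x = 1). Initial membrane potentials are drawn uniformly from
[V_rest, V_T) from a named sub-seed — with the all-at-rest initial
condition the (perfectly symmetric) network locks into synchronous
states. The run is seeded by Poisson forcing of 20 random excitatory
neurons at 300 Hz for 15 ms; an external event forces the target to spike
(membrane bypass). A constant whole-network Poisson background of
1 spike/s/neuron is available as a config switch and is used for the
steady-state analyses (see *Reproduction protocol*). Everything random is
drawn up-front from named sub-seeds of the run seed; the loop itself is
deterministic, and identical configurations reproduce rasters
bit-for-bit.

## Analyses

**Avalanches.** A spike (i, n) joins every avalanche containing a spike
(j, s) with an edge j→i and s ∈ [n−ϕ−Δ, n−ϕ−1]; otherwise it starts a
singleton. Avalanches overlap — a spike may belong to several, and each
counts it toward its size. Defaults ϕ = 1 (one-step delay), Δ = 3.
Analyses subsample 12.5% of neurons (induced subgraph) to emulate a
recorded patch. Two implementations share identical semantics: a full
tracker retaining per-spike membership lists (used below 2×10⁵ spikes and
cross-checked against a brute-force oracle), and a streaming tracker that
discards lists once spikes leave the causal horizon, with a work budget —
exhausting the budget is equivalent to analysing a shorter window prefix.

**Size exponent λ.** Ordinary least squares of log₁₀ count against
log₁₀ size, unbinned. The default fit range is the initial segment,
sizes 1–20: subsampled distributions in this model are power-law over
that segment and then bend (finite-size truncation below, a
super-critical excess of very large, strongly overlapping avalanches
above). The range is configurable and always reported.

**Branching ratio σ(n).** Ratio of the number of (spiker, postsynaptic
neighbour active in the offset post-window) pairs to the presynaptic
analogue, per step; neighbours count once per spiker regardless of how
often they fire in the window (shared connections count toward every
spiker). Steps with no presynaptic activity are undefined and excluded
from averages. A per-spiker ("local") variant averages individual ratios.

**DFA.** Per neuron, the ISI series is centred and integrated, split into
non-overlapping segments of length l, linearly detrended, and the RMS
residual F(l) collected over ~20 log-spaced scales in [4, N/4]. α is the
slope of log F vs log l (the amplitude convention, F ∝ l^α — the squared
convention would double every exponent and contradict the interpretation
that 0.5 < α < 1 marks positive long-range correlation). Population
analyses sample neurons at random and skip those with fewer than a
minimum number of spikes (default 512 for steady-state analyses); this
over-represents high-rate neurons when the analysed window is short.

**Drift reconstruction.** The population rate is treated as a Langevin
system; the deterministic component is the binned mean one-step increment
(50 bins, ≥20 samples per reported bin), with zero crossings classified
stable/unstable by the local slope. Time-reversal flips the recovered
transient drift; a *stationary* Ornstein–Uhlenbeck series is
time-reversible, so only non-stationary segments carry an arrow of time.

**Weights.** Condition differences use MSE = ‖w₁−w₂‖²/N. Flips use
two-threshold hysteresis (leave <0.1 / >0.9, record on entering the
opposite regime). Entropies pool per-synapse values into 100 equal bins
over [0, 1] per 1 s window (Shannon, bits), separately for E weights,
I weights and STP efficacies.

**Parameter search.** Greedy biased random walk on
R = √(r² + r_max²) (the square root is a monotone transform of the sum of
squares, so acceptance decisions are convention-independent); proposals
perturb each of the eight free parameters by Gaussian noise with SD equal
to 2% of its value, rejecting non-positive draws and ties. Every
evaluation is logged with PABA (no silent 1-s bin after initialization,
mean < 35 Hz, peak < 100 Hz on 1-s bins, strict inequalities) and
criticality flags (σ ∈ [0.9, 1.1], λ ∈ [−1.7, −1.3], mean α in (0.5, 1);
bands configurable and recorded).

## Reproduction protocol and measured behaviour

The candidate parameter set self-organizes through three phases: a
saturated initialization burst (~1 s, capped at ≈330 Hz by
refractoriness) during which bulk excitatory weights crash toward zero
and inhibitory weights ratchet up; a long reorganization in which a
minority of causally effective excitatory synapses potentiates toward the
ceiling (the backbone) while inhibition keeps creeping; and a steady
state at ~26–32 Hz with the branching ratio oscillating about 1.
Self-organized recovery depends on re-ignition: with no external input an
unlucky silent millisecond is absorbing. The steady-state analyses
therefore run the constant 1 Hz background variant, under which the
population rate settles into the reported band and the avalanche-size
exponent reaches ≈ −1.5 to −1.65 after 200–300 s. Parameter sets of this
kind are products of a search against a specific implementation;
conventions left open by the model description (pairing scheme,
refractory period, initial-state symmetry breaking) shift the viable
region, which is why the search module is part of the toolkit.

Problem sizes used by the test-suite and the acceptance script (chosen so
a full reproduction runs on a single desktop core): one 400 s full-scale
run at N = 10,000; λ fitted on the final 100 s with one 12.5% subsample;
the subsample-λ distribution over 100 draws on the final 10 s; DFA on
200–300 sampled neurons over the final 150–340 s; perturbation
experiments (pulse trains, single-spike divergence, I-STDP ablation) on
40–220 s runs sharing the steady-state configuration.

## Known limitations

* The synthetic background drive forces spikes rather than injecting
  current; forced spikes participate in plasticity like intrinsic ones.
* The steady state reached within the desk-scale horizon is slightly less
  mature than a 900 s run: the E/I current cancellation is partial
  (|net|/|E| ≈ 0.4–0.45 rather than ≪ 1), and population DFA exponents
  centre near 0.57–0.62. Both move in the expected direction as the run
  lengthens (inhibition continues to saturate and weights polarise).
* A single 100 s-window avalanche-exponent fit scatters between
  realizations and subsample draws (≈ −1.65 to −2.05): rare giant
  overlapping-avalanche clusters distort the small-size counts. The mean
  over ≥100 random subsamples is stable (≈ −1.60 to −1.65).
* The literal continuous-product STP mode (u·x multiplying the
  conductance at every instant) is not implemented; it requires
  per-synapse conductance traces, which is infeasible at N = 10,000 on
  one core. The deposit-time folding is the only mode.
* Under the background-drive protocol, disabling inhibitory STDP from the
  start still yields a stabilized rate (the drive floor plus E-STDP
  suffices); the role of inhibitory plasticity shows in the avalanche
  exponent, which fails to tune toward −3/2 when the rule is frozen
  mid-run, and in the intrinsic (undriven) network, which has no
  intermediate self-sustained regime without it.
* The avalanche definition is the causal-graph one only; the
  experimental-literature convention (LFP thresholding, time-bin
  concatenation) is out of scope.
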