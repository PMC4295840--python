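# critnet

Deterministic plastic spiking networks that self-tune to criticality, with
the full analysis toolkit used to diagnose the critical state.

Resting cortex shows two properties that look hard to reconcile: single
neurons fire irregularly and almost independently, while population
activity organizes into scale-invariant cascades — neuronal avalanches —
whose size distribution follows a power law with exponent ≈ −3/2.
`critnet` simulates a 10,000-neuron conductance-based leaky
integrate-and-fire network (80% excitatory / 20% inhibitory, 1% random
connectivity) in which the combination of short-term plasticity
(Tsodyks–Markram facilitation/depression), asymmetric excitatory STDP and
symmetric inhibitory STDP lets the network generate persistent
asynchronous background activity on its own and tune itself toward a
critical state — and back to it after strong perturbations. The dynamics
are fully deterministic given a seed, so the effect of a single added
spike can be followed exactly.

The critical state is diagnosed jointly by three measures:

* branching ratio σ(n) — postsynaptic vs presynaptic activity in offset
  windows through the actual synapses; σ = 1 is the critical balance,
* avalanche-size exponent λ — OLS slope of the unbinned log-log size
  distribution under causal avalanche tracking with overlapping
  membership; λ ≈ −3/2 at criticality,
* DFA exponent α of inter-spike-interval fluctuations; 0.5 < α < 1
  indicates long-range temporal correlations.

The package also provides E/I current tallies, spike-train statistics
(CoV of ISIs, pairwise correlations, spike-vector divergence between
paired runs), weight-dynamics analyses (histograms, flips, thresholded
in-degrees, STDP-vs-STP entropies), Langevin drift reconstruction of the
rate dynamics, and the biased random-walk parameter search used to find
viable parameter sets.

## Worked example

```python
import numpy as np
from critnet import SimulationConfig, run
from critnet.avalanches import (branching_ratio_series, lambda_resampling,
                                subsampled_lambda)
from critnet.dfa import dfa_population

cfg = SimulationConfig(duration_s=400.0, seed=1, background_rate_hz=1.0,
                       raster_window_s=(60.0, 400.0))
res = run(cfg)                              # ~9 minutes on one core
print(f"rate   {res.mean_rate_hz(t0_s=1.0):.2f} Hz")

sig = branching_ratio_series(res.raster, res.connectivity,
                             step_range=(200_000, 210_000))
print(f"sigma  {np.nanmean(sig):.4f}")

fit = subsampled_lambda(res.raster.window(300_000, 400_000),
                        res.connectivity, p=0.125, seed=3)
print(f"lambda {fit.slope:.3f}  (R2 {fit.r_squared:.3f})")

lams = lambda_resampling(res.raster.window(390_000, 400_000),
                         res.connectivity, n_resamples=100, seed=4)
print(f"lambda resampled {np.mean(lams):.3f} +- {np.std(lams, ddof=1):.3f}")

pop = dfa_population(res.raster, neuron_sample_size=200, seed=5,
                     min_spikes=512)
print(f"alpha  {pop['mean']:.3f} +- {pop['sd']:.3f}")
```

Output for this seed:

```
rate   34.95 Hz
sigma  1.0006
lambda -2.054  (R2 0.978)
lambda resampled -1.645 +- 0.250
alpha  0.621 +- 0.059
```

The rate is the self-sustained population firing rate after the
initialization transient; σ within a tenth of a percent of 1 means
spiking activity neither grows nor decays on average; λ near −3/2 on the
12.5% subsample is the avalanche signature of criticality (a single
100 s window fit scatters considerably between realizations because rare
giant avalanche clusters distort the small-size counts — the mean over
many random subsamples is the stable estimator); α above 0.5 indicates
long-range correlated ISI fluctuations.

A command-line interface wraps the same functionality:

```bash
critnet simulate --out run/ --seed 1 --duration-s 60
critnet analyze avalanches --raster run/raster.tsv --graph run/connectivity.mtx --out av/
critnet analyze dfa --raster run/raster.tsv --neurons 500 --out dfa/
critnet analyze weights --weights-a run/weights_final.mtx --graph run/connectivity.mtx --out w/
critnet perturb single-spike --config run/resolved_config.yaml --t-inject-s 30 --out div/
critnet search --iters 50 --seed 0 --out ledger.tsv
```

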