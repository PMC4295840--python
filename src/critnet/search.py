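"""Biased random-walk parameter search with activity and criticality filters.

The search perturbs the eight free network parameters by multiplicative
Gaussian noise (SD = 2% of each value) and greedily accepts a proposal
whenever it strictly lowers the rate performance index

    R = sqrt(r^2 + r_max^2)

built from the mean and peak population rates (the square root is a
strictly monotone transform of the sum of squares, so acceptance decisions
are unchanged by the convention).  Every evaluation is logged with its
PABA flag (persistent asynchronous background activity: no silent 1-s bin
after initialization, mean rate < 35 Hz, peak 1-s rate < 100 Hz) and its
criticality flags (branching ratio near 1, avalanche exponent near -3/2,
DFA alpha in (0.5, 1)).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np

from . import avalanches, dfa as dfa_mod
from .raster import SpikeRaster
from .stats import rate_from_counts


PARAM_NAMES = ("A_plus", "beta", "g_exc_max", "g_inh_max",
               "tau_AMPA", "tau_GABA", "tau_F", "tau_D")


@dataclass(frozen=True)
class ParamVector:
    """The eight searched parameters."""

    A_plus: float = 0.0015
    beta: float = 1.21
    g_exc_max: float = 1.94
    g_inh_max: float = 4.74
    tau_AMPA: float = 19.0
    tau_GABA: float = 14.0
    tau_F: float = 41.0
    tau_D: float = 26.0

    def __post_init__(self) -> None:
        for k in PARAM_NAMES:
            if getattr(self, k) <= 0:
                raise ValueError(f"{k} must be positive")

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, k) for k in PARAM_NAMES])

    @classmethod
    def from_array(cls, a) -> "ParamVector":
        return cls(**dict(zip(PARAM_NAMES, map(float, a))))


@dataclass
class SearchRecord:
    iteration: int
    params: ParamVector
    R: float
    mean_rate: float
    peak_rate: float
    paba: bool | None
    sigma_ok: bool | None
    lambda_ok: bool | None
    alpha_ok: bool | None
    accepted: bool
    seed: int

    def as_dict(self) -> dict:
        d = asdict(self)
        d.update(asdict(self.params))
        del d["params"]
        return d


def rate_performance(mean_rate: float, max_rate: float) -> float:
    """R = sqrt(r^2 + r_max^2); strictly increasing in both arguments."""
    if mean_rate < 0 or max_rate < 0:
        raise ValueError("rates must be >= 0")
    return float(np.hypot(mean_rate, max_rate))


def propose(params: ParamVector, seed, scale: float = 0.02) -> ParamVector:
    """Gaussian perturbation with SD = scale * value per parameter.

    Non-positive proposals are re-drawn.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    out = []
    for p in params.as_array():
        q = p + rng.normal(0.0, scale * p) if scale > 0 else p
        while q <= 0:
            q = p + rng.normal(0.0, scale * p)
        out.append(q)
    return ParamVector.from_array(out)


def paba_filter(spike_counts: np.ndarray, n_neurons: int,
                init_duration_ms: float = 15.0, dt_ms: float = 1.0,
                mean_limit_hz: float = 35.0,
                peak_limit_hz: float = 100.0) -> dict:
    """Persistent-activity filter on a per-step population spike count.

    PABA requires non-zero activity in every full 1-s bin after the
    initialization window; rate criteria (strict inequalities) are
    evaluated on 1-s bins.
    """
    start = int(round(init_duration_ms / dt_ms))
    rates = rate_from_counts(spike_counts[start:], n_neurons, 1000.0, dt_ms)
    r = rates.rate_hz
    persistent = bool(r.size > 0 and np.all(r > 0))
    mean_rate = float(r.mean()) if r.size else 0.0
    peak_rate = float(r.max()) if r.size else 0.0
    return {
        "paba": persistent and mean_rate < mean_limit_hz
        and peak_rate < peak_limit_hz,
        "persistent": persistent,
        "mean_rate": mean_rate,
        "peak_rate": peak_rate,
    }


def criticality_filter(raster: SpikeRaster, connectivity,
                       seed=0,
                       sigma_band: tuple = (0.9, 1.1),
                       lambda_band: tuple = (-1.7, -1.3),
                       alpha_band: tuple = (0.5, 1.0),
                       subsample_p: float = 0.125,
                       dfa_sample: int = 100,
                       t0_ms: float = 1000.0) -> dict:
    """Three criticality flags with the measured values.

    sigma: time-averaged network branching ratio after ``t0_ms``;
    lambda: avalanche-size exponent on a random subsample;
    alpha: mean DFA exponent over sampled neurons, strictly inside its band.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    out: dict = {"bands": {"sigma": sigma_band, "lambda": lambda_band,
                           "alpha": alpha_band}}
    t0_step = int(round(t0_ms / raster.dt_ms))
    sig = avalanches.branching_ratio_series(
        raster, connectivity,
        step_range=(t0_step, max(raster.duration_steps - 5, t0_step + 1)))
    sigma = float(np.nanmean(sig)) if np.any(np.isfinite(sig)) else np.nan
    out["sigma"] = sigma
    out["sigma_ok"] = bool(np.isfinite(sigma)
                           and sigma_band[0] <= sigma <= sigma_band[1])
    try:
        fit = avalanches.subsampled_lambda(raster, connectivity,
                                           p=subsample_p, seed=rng)
        out["lambda"] = fit.slope
        out["lambda_ok"] = bool(lambda_band[0] <= fit.slope <= lambda_band[1])
    except (ValueError, RuntimeError):
        out["lambda"] = np.nan
        out["lambda_ok"] = False
    pop = dfa_mod.dfa_population(raster, neuron_sample_size=dfa_sample,
                                 seed=rng, t0_ms=t0_ms)
    out["alpha"] = pop["mean"]
    out["alpha_ok"] = bool(np.isfinite(pop["mean"])
                           and alpha_band[0] < pop["mean"] < alpha_band[1])
    return out


def search(start: ParamVector, n_iter: int, backend, seed=0,
           scale: float = 0.02) -> list:
    """Greedy biased random walk on the rate performance index.

    ``backend(params, rng) -> dict`` must return at least ``mean_rate``
    and ``peak_rate`` and may add ``paba`` / ``sigma_ok`` / ``lambda_ok``
    / ``alpha_ok`` flags.  A proposal is accepted only on a strict
    improvement of R (ties rejected).  Backend failures are recorded and
    the iteration skipped.  Returns the full evaluation ledger.
    """
    rng = np.random.default_rng(seed)
    records: list[SearchRecord] = []
    current = start
    best_R = np.inf
    for it in range(n_iter):
        cand = current if it == 0 else propose(current, rng, scale)
        eval_seed = int(rng.integers(2**31))
        try:
            m = backend(cand, np.random.default_rng(eval_seed))
        except Exception:  # noqa: BLE001 - backend failures are data
            records.append(SearchRecord(
                iteration=it, params=cand, R=np.nan, mean_rate=np.nan,
                peak_rate=np.nan, paba=None, sigma_ok=None, lambda_ok=None,
                alpha_ok=None, accepted=False, seed=eval_seed))
            continue
        R = rate_performance(m["mean_rate"], m["peak_rate"])
        accepted = R < best_R
        if accepted:
            best_R = R
            current = cand
        records.append(SearchRecord(
            iteration=it, params=cand, R=R,
            mean_rate=float(m["mean_rate"]), peak_rate=float(m["peak_rate"]),
            paba=m.get("paba"), sigma_ok=m.get("sigma_ok"),
            lambda_ok=m.get("lambda_ok"), alpha_ok=m.get("alpha_ok"),
            accepted=accepted, seed=eval_seed))
    return records


def simulation_backend(n_neurons: int = 2000, duration_s: float = 60.0,
                       connection_prob: float = 0.05,
                       with_criticality: bool = False):
    """Backend factory running reduced-scale simulations.

    The default scale keeps the expected in-degree comparable to the full
    network by raising the connection probability.
    """
    from .simulator import SimulationConfig, run

    def backend(params: ParamVector, rng: np.random.Generator) -> dict:
        cfg = SimulationConfig(
            n_neurons=n_neurons, duration_s=duration_s,
            connection_prob=connection_prob,
            seed=int(rng.integers(2**31)),
            record_raster=with_criticality, record_currents=False,
            **{k: getattr(params, k) for k in PARAM_NAMES})
        res = run(cfg)
        out = paba_filter(res.spike_counts, n_neurons,
                          cfg.init_duration_ms, cfg.dt_ms)
        if with_criticality and res.raster is not None:
            out.update({k: v for k, v in criticality_filter(
                res.raster, res.connectivity, seed=rng).items()
                if k.endswith("_ok")})
        return out

    return backend
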