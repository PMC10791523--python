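"""ABC–SMC calibration of the unobservable model parameters.

The residence-time threshold t_rmax, the myotube–myotube fusion age gate
t_MTfuse and the force coefficients k_lat, k_nuc cannot be measured from
imaging, so they are inferred likelihood-free: candidate parameter
vectors are drawn from uniform priors, the agent-based model is run
forward, and candidates are kept when a weighted distance between
simulated and observed quality indicators (dM, D, D_var) falls below a
threshold ε that is tightened population by population (sequential
Monte Carlo with a Gaussian perturbation kernel and importance
reweighting).

The scheme is self-contained (numpy only) and bit-reproducible for a
fixed configuration seed, including under replicate parallelism, because
every forward-run seed is derived deterministically from (seed,
population, attempt, replicate).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import pandas as pd

from .engine import simulate
from .metrics import QualityIndicators, quality_from_sim
from .params import SimParams

__all__ = ["PriorSpec", "ABCConfig", "Posterior", "summary_distance",
           "abc_smc", "posterior_point_estimates", "weighted_quantile",
           "PARAM_NAMES"]

logger = logging.getLogger(__name__)

PARAM_NAMES = ("t_rmax", "t_mtfuse", "k_lat", "k_nuc")


@dataclass(frozen=True)
class PriorSpec:
    """Independent uniform priors over the inferred parameters.

    Defaults follow the calibration ranges: t_rmax 1–100 minutes,
    t_MTfuse 0.5–4.5 days, k_lat and k_nuc 0–1.
    """

    t_rmax: tuple[float, float] = (1.0, 100.0)
    t_mtfuse: tuple[float, float] = (0.5, 4.5)
    k_lat: tuple[float, float] = (0.0, 1.0)
    k_nuc: tuple[float, float] = (0.0, 1.0)

    def __post_init__(self) -> None:
        for name in PARAM_NAMES:
            lo, hi = getattr(self, name)
            if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
                raise ValueError(f"{name}: prior bounds must satisfy "
                                 f"lower < upper, got ({lo}, {hi})")

    @property
    def bounds(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in PARAM_NAMES])

    def sample(self, rng: np.random.Generator) -> np.ndarray:
        b = self.bounds
        return rng.uniform(b[:, 0], b[:, 1])

    def contains(self, theta: np.ndarray) -> bool:
        b = self.bounds
        return bool(np.all(theta >= b[:, 0]) and np.all(theta <= b[:, 1]))


@dataclass(frozen=True)
class ABCConfig:
    """SMC settings.

    The ε schedule is the weighted median of the previous population's
    accepted distances; the perturbation kernel is an independent
    Gaussian with per-parameter scale ``kernel_scale`` × the weighted
    particle SD, truncated to the prior box by rejection.  Per-particle
    distance is the mean over ``replicates_per_particle`` forward runs.
    """

    n_particles: int = 100
    n_populations: int = 6
    replicates_per_particle: int = 3
    kernel_scale: float = 1.5
    w_dm: float = 1.0
    w_d: float = 1.0
    w_dvar: float = 1.0
    rel_floor: float = 1e-6
    penalty: float = 10.0
    min_acceptance_rate: float = 0.02
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_particles < 2:
            raise ValueError("n_particles must be >= 2")
        if self.replicates_per_particle < 1:
            raise ValueError("replicates_per_particle must be >= 1")
        w = (self.w_dm, self.w_d, self.w_dvar)
        if any(x < 0 for x in w) or all(x == 0 for x in w):
            raise ValueError("distance weights must be >= 0 and not all zero")

    @property
    def weights(self) -> tuple[float, float, float]:
        return (self.w_dm, self.w_d, self.w_dvar)


@dataclass
class Posterior:
    """Weighted particle populations from an ABC–SMC run."""

    populations: list[pd.DataFrame]   # columns PARAM_NAMES+('weight','distance')
    epsilons: list[float]
    acceptance_rates: list[float]
    stopped_early: bool = False
    priors: PriorSpec = field(default_factory=PriorSpec)

    @property
    def final(self) -> pd.DataFrame:
        return self.populations[-1]

    def to_frame(self) -> pd.DataFrame:
        """Flat posterior CSV dialect: population, particle, weight,
        t_rmax, k_lat, k_nuc, t_mtfuse, distance."""
        frames = []
        for i, pop in enumerate(self.populations):
            f = pop.copy()
            f.insert(0, "population", i)
            f.insert(1, "particle", np.arange(len(pop)))
            frames.append(f)
        out = pd.concat(frames, ignore_index=True)
        return out[["population", "particle", "weight", "t_rmax", "k_lat",
                    "k_nuc", "t_mtfuse", "distance"]]


def summary_distance(sim: QualityIndicators, obs: QualityIndicators,
                     weights: tuple[float, float, float] = (1.0, 1.0, 1.0),
                     rel_floor: float = 1e-6,
                     penalty: float = 10.0) -> float:
    """Weighted relative discrepancy between simulated and observed Q.

    d = w_dM·|dM_s − dM_o| / max(|dM_o|, floor)
      + w_D·|D_s − D_o| / max(D_o, floor)
      + w_Dvar·|Dvar_s − Dvar_o| / max(Dvar_o, floor)

    A simulated component that is undefined (NaN — e.g. no tube formed,
    so D does not exist) contributes ``weight × penalty`` instead.
    """
    pairs = ((sim.dm, obs.dm), (sim.d, obs.d), (sim.d_var, obs.d_var))
    total = 0.0
    for w, (s, o) in zip(weights, pairs):
        if w == 0.0:
            continue
        if not math.isfinite(o):
            raise ValueError("observed quality indicators must be finite")
        if not math.isfinite(s):
            total += w * penalty
        else:
            total += w * abs(s - o) / max(abs(o), rel_floor)
    return total


def weighted_quantile(values: np.ndarray, weights: np.ndarray,
                      q: float | np.ndarray) -> float | np.ndarray:
    """Inverse-CDF weighted quantile: smallest x with F(x) >= q."""
    values = np.asarray(values, dtype=float)
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(values, kind="stable")
    v, w = values[order], weights[order]
    cum = np.cumsum(w) / w.sum()
    idx = np.searchsorted(cum, np.asarray(q), side="left")
    idx = np.clip(idx, 0, len(v) - 1)
    out = v[idx]
    return float(out) if np.isscalar(q) else out


def _replicate_seed(base_seed: int, population: int, attempt: int,
                    replicate: int) -> int:
    ss = np.random.SeedSequence(
        entropy=base_seed, spawn_key=(population, attempt, replicate))
    return int(ss.generate_state(1)[0] % (2**31))


def default_simulator(base_params: SimParams,
                      ) -> Callable[[np.ndarray, int], QualityIndicators]:
    """Forward model: run the ABM with the candidate parameters patched in."""
    def run(theta: np.ndarray, seed: int) -> QualityIndicators:
        p = base_params.with_inferred(
            t_rmax=theta[0], t_mtfuse=theta[1],
            k_lat=theta[2], k_nuc=theta[3], seed=seed)
        return quality_from_sim(simulate(p))
    return run


def abc_smc(observed: QualityIndicators, base_params: SimParams,
            priors: PriorSpec | None = None,
            cfg: ABCConfig | None = None,
            simulator: Callable[[np.ndarray, int], QualityIndicators] | None
            = None) -> Posterior:
    """Sequential ABC against observed quality indicators.

    Population 0 samples the prior with ε = ∞ (every particle
    accepted); each later population sets ε to the weighted median of
    the previous accepted distances, proposes from the weighted previous
    particles perturbed by the Gaussian kernel, and assigns standard SMC
    importance weights (uniform prior density over kernel mixture).  If
    a population's acceptance rate falls below the configured floor the
    run stops early and returns the populations completed so far with
    ``stopped_early`` set.
    """
    priors = priors or PriorSpec()
    cfg = cfg or ABCConfig()
    if simulator is None:
        simulator = default_simulator(base_params)
    rng = np.random.default_rng(cfg.seed)
    bounds = priors.bounds
    n_par = len(PARAM_NAMES)

    def _distance(theta: np.ndarray, pop: int, attempt: int) -> float:
        total = 0.0
        for rep in range(cfg.replicates_per_particle):
            seed = _replicate_seed(cfg.seed, pop, attempt, rep)
            q = simulator(theta, seed)
            total += summary_distance(q, observed, cfg.weights,
                                      cfg.rel_floor, cfg.penalty)
        return total / cfg.replicates_per_particle

    populations: list[pd.DataFrame] = []
    epsilons: list[float] = []
    acc_rates: list[float] = []
    stopped_early = False

    # population 0: plain prior sampling, no selection pressure
    thetas = np.empty((cfg.n_particles, n_par))
    dists = np.empty(cfg.n_particles)
    for i in range(cfg.n_particles):
        thetas[i] = priors.sample(rng)
        dists[i] = _distance(thetas[i], 0, i)
    weights = np.full(cfg.n_particles, 1.0 / cfg.n_particles)
    populations.append(_pop_frame(thetas, weights, dists))
    epsilons.append(math.inf)
    acc_rates.append(1.0)

    max_attempts = int(math.ceil(cfg.n_particles / cfg.min_acceptance_rate))
    for t in range(1, cfg.n_populations):
        prev_thetas = thetas
        prev_weights = weights
        eps = weighted_quantile(dists, prev_weights, 0.5)
        mean = np.average(prev_thetas, axis=0, weights=prev_weights)
        var = np.average((prev_thetas - mean) ** 2, axis=0,
                         weights=prev_weights)
        scale = cfg.kernel_scale * np.sqrt(var)
        scale = np.maximum(scale, 1e-6 * (bounds[:, 1] - bounds[:, 0]))

        new_thetas = np.empty_like(prev_thetas)
        new_dists = np.empty(cfg.n_particles)
        accepted = 0
        attempts = 0
        while accepted < cfg.n_particles and attempts < max_attempts:
            # propose inside the prior box (rejection sampling on the kernel)
            while True:
                ancestor = prev_thetas[
                    rng.choice(cfg.n_particles, p=prev_weights)]
                theta = ancestor + rng.normal(0.0, scale, size=n_par)
                if priors.contains(theta):
                    break
            d = _distance(theta, t, attempts)
            attempts += 1
            if d <= eps:
                new_thetas[accepted] = theta
                new_dists[accepted] = d
                accepted += 1
        if accepted < cfg.n_particles:
            logger.warning(
                "population %d: acceptance below floor (%d/%d after %d "
                "attempts); stopping early", t, accepted, cfg.n_particles,
                attempts)
            stopped_early = True
            break
        # importance weights: uniform prior / kernel mixture
        new_weights = np.empty(cfg.n_particles)
        inv2s2 = 1.0 / (2.0 * scale**2)
        norm = np.prod(1.0 / (math.sqrt(2 * math.pi) * scale))
        for i in range(cfg.n_particles):
            diff = new_thetas[i] - prev_thetas
            kern = norm * np.exp(-np.sum(diff**2 * inv2s2, axis=1))
            new_weights[i] = 1.0 / max(float(prev_weights @ kern), 1e-300)
        new_weights /= new_weights.sum()

        thetas, weights, dists = new_thetas, new_weights, new_dists
        populations.append(_pop_frame(thetas, weights, dists))
        epsilons.append(float(eps))
        acc_rates.append(accepted / attempts)

    return Posterior(populations=populations, epsilons=epsilons,
                     acceptance_rates=acc_rates, stopped_early=stopped_early,
                     priors=priors)


def _pop_frame(thetas: np.ndarray, weights: np.ndarray,
               dists: np.ndarray) -> pd.DataFrame:
    f = pd.DataFrame(thetas, columns=list(PARAM_NAMES))
    f["weight"] = weights
    f["distance"] = dists
    return f


def posterior_point_estimates(post: Posterior) -> pd.DataFrame:
    """Weighted point estimates and spread diagnostics per parameter.

    Returns a frame indexed by parameter with the weighted median and
    mean, the central 95% interval, and ``iqr_ratio`` — the final
    weighted interquartile range over the prior interquartile range
    (half the prior width); values well below 1 flag parameters the
    data actually constrain.
    """
    if not post.populations:
        raise ValueError("posterior holds no populations")
    final = post.final
    w = final["weight"].to_numpy()
    rows = {}
    for i, name in enumerate(PARAM_NAMES):
        v = final[name].to_numpy()
        q = weighted_quantile(v, w, np.array([0.025, 0.25, 0.5, 0.75, 0.975]))
        lo, hi = post.priors.bounds[i]
        prior_iqr = 0.5 * (hi - lo)
        rows[name] = {
            "median": q[2],
            "mean": float(np.average(v, weights=w)),
            "ci_lo": q[0],
            "ci_hi": q[4],
            "iqr_ratio": (q[3] - q[1]) / prior_iqr,
        }
    return pd.DataFrame(rows).T
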