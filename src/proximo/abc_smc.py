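"""Likelihood-free inference of (v_p, D) by ABC sequential Monte Carlo.

A population of particles is propagated through a sequence of shrinking
acceptance thresholds ε on the distance

    d(Y, f) = Σ_t Σ_i (y_i − f(x_i))² / σ² ,

summed over all fitted timepoints, where σ is the per-condition noise
scale.  Each generation resamples the previous population by weight,
perturbs with a component-wise Gaussian kernel (variance twice the
weighted population variance), and accepts proposals with distance below
the current ε, taken as the median of the previous generation's accepted
distances.  The run stops when ε falls below ``min_epsilon``, when
``max_populations`` is reached, or on acceptance-rate collapse.

Parameters are in the transformed frame (ṽ = v_p/L0, D̃ = D/L0², both
day⁻¹), matching the grid-inference axes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from ._kernel import batch_evolve
from .inference import DEFAULT_BOUNDS, profile_to_nodes
from .profiles import DensityProfile
from .rda import SimGrid

__all__ = ["ABCConfig", "ABCResult", "abc_smc"]


@dataclass(frozen=True)
class ABCConfig:
    """Settings of the ABC-SMC run (defaults follow the study)."""

    population_size: int = 100
    max_populations: int = 20
    min_epsilon: float = 0.1
    priors: dict = field(default_factory=lambda: {
        "vp": DEFAULT_BOUNDS["vp"], "D": DEFAULT_BOUNDS["D"]})
    sigma: float = 0.006  # per-condition noise scale entering the distance

    def __post_init__(self) -> None:
        if self.population_size < 10:
            raise ValueError("population_size must be >= 10")
        if self.min_epsilon <= 0:
            raise ValueError("min_epsilon must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        for p in ("vp", "D"):
            lo, hi = self.priors[p]
            if not lo < hi:
                raise ValueError(f"prior bounds for {p} must satisfy lo < hi")


@dataclass
class ABCResult:
    """Final weighted particle population over (ṽ, D̃)."""

    particles: np.ndarray        # (M, 2): columns vp, D (transformed)
    weights: np.ndarray          # (M,), sum to 1
    epsilons: list               # ε schedule actually used
    n_populations: int
    n_simulations: int
    converged: bool              # reached min_epsilon
    collapsed: bool = False      # stopped on acceptance-rate collapse

    def mean(self) -> dict:
        m = self.weights @ self.particles
        return {"vp": float(m[0]), "D": float(m[1])}

    def sd(self) -> dict:
        m = self.weights @ self.particles
        var = self.weights @ (self.particles - m) ** 2
        return {"vp": math.sqrt(var[0]), "D": math.sqrt(var[1])}


def _distance_fn(series: list[DensityProfile], r: float, a: float,
                 grid: SimGrid, sigma: float):
    """Build a batched distance evaluator from a profile series.

    The first profile is the IC; distances sum over later timepoints on
    the δ-grid nodes.
    """
    series = sorted(series, key=lambda p: p.timepoint)
    ic = series[0]
    L0 = float(ic.L)
    t0 = ic.timepoint
    ic_nodes = profile_to_nodes(ic, L0, grid)
    thetas = np.array([p.timepoint - t0 for p in series[1:]])
    data = np.stack([
        profile_to_nodes(p, L0 * math.exp(a * (p.timepoint - t0)), grid)
        for p in series[1:]])

    def dist(theta_batch: np.ndarray) -> np.ndarray:
        out, ok = batch_evolve(ic_nodes, theta_batch[:, 0], theta_batch[:, 1],
                               r, a, thetas)
        d = ((out - data[None]) ** 2).sum(axis=(1, 2)) / sigma**2
        d[~ok] = np.inf
        return d

    return dist


def abc_smc(series: list[DensityProfile], config: ABCConfig, r: float,
            a: float, grid: SimGrid | None = None, seed: int = 0,
            batch_factor: int = 4, max_batches_per_gen: int = 200) -> ABCResult:
    """ABC-SMC posterior over (ṽ, D̃) for one profile series.

    Parameters
    ----------
    series : profiles of one condition, first timepoint = IC.
    config : ABCConfig (priors in transformed units).
    r, a : upstream rate estimates (day⁻¹).
    seed : governs all sampling; recorded by callers in run metadata.
    batch_factor : proposals simulated per accepted-particle slot at a
        time (vectorized over the forward kernel).
    max_batches_per_gen : collapse guard; if a generation exhausts this
        many proposal batches without filling the population the run
        stops with ``collapsed=True`` and returns the last full
        population.
    """
    grid = grid or SimGrid()
    rng = np.random.default_rng(seed)
    dist = _distance_fn(series, r, a, grid, config.sigma)
    lo = np.array([config.priors["vp"][0], config.priors["D"][0]])
    hi = np.array([config.priors["vp"][1], config.priors["D"][1]])
    M = config.population_size
    n_sims = 0

    # generation 1: straight prior sample, all accepted
    particles = rng.uniform(lo, hi, size=(M, 2))
    dists = dist(particles)
    n_sims += M
    weights = np.full(M, 1.0 / M)
    epsilons: list[float] = []
    converged = False
    collapsed = False
    n_gen = 1

    while n_gen < config.max_populations:
        eps = float(np.median(dists))
        if eps <= config.min_epsilon:
            converged = True
            break
        epsilons.append(eps)
        var = np.average((particles - np.average(particles, axis=0,
                                                 weights=weights)) ** 2,
                         axis=0, weights=weights)
        ksd = np.sqrt(np.maximum(2.0 * var, 1e-30))
        new_p = np.empty((M, 2))
        new_d = np.empty(M)
        filled = 0
        batches = 0
        while filled < M:
            if batches >= max_batches_per_gen:
                collapsed = True
                break
            k = batch_factor * M
            parents = rng.choice(M, size=k, p=weights)
            prop = particles[parents] + rng.normal(0.0, 1.0, (k, 2)) * ksd
            inside = np.all((prop >= lo) & (prop <= hi), axis=1)
            prop = prop[inside]
            if len(prop) == 0:
                batches += 1
                continue
            d = dist(prop)
            n_sims += len(prop)
            acc = d <= eps
            take = min(int(acc.sum()), M - filled)
            new_p[filled:filled + take] = prop[acc][:take]
            new_d[filled:filled + take] = d[acc][:take]
            filled += take
            batches += 1
        if collapsed:
            break
        # importance weights: uniform prior / mixture of Gaussian kernels,
        # evaluated in log space (the flat prior cancels on normalization)
        diff = (new_p[:, None, :] - particles[None, :, :]) / ksd
        log_k = -0.5 * (diff**2).sum(axis=-1) - np.log(2 * np.pi * ksd[0] * ksd[1])
        rowmax = log_k.max(axis=1, keepdims=True)
        log_mix = rowmax[:, 0] + np.log(
            (weights[None, :] * np.exp(log_k - rowmax)).sum(axis=1))
        w = np.exp(-(log_mix - log_mix.min()))
        weights = w / w.sum()
        particles, dists = new_p, new_d
        n_gen += 1

    return ABCResult(particles=particles, weights=weights, epsilons=epsilons,
                     n_populations=n_gen, n_simulations=n_sims,
                     converged=converged, collapsed=collapsed)
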