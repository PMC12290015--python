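"""Variance-based (Sobol) sensitivity analysis of the RDA model.

The output analysed is the model-data distance Σ_c Σ_i (y_i − f_i)²/σ_c²
summed over the three experimental conditions, evaluated per timepoint,
with the four model parameters (D, v_p, r, a) varied over a box.  The
first-order index S1 measures each parameter's solo contribution to the
output variance; the total-order index ST includes all interactions.

Estimators: Saltelli sampling on a Sobol' sequence (A, B and the d
"AB_i" matrices, N(d + 2) model runs) with the Saltelli-2010 S1
estimator and the Jansen ST estimator; confidence intervals by bootstrap
over sample rows.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import qmc

from ._kernel import batch_evolve
from .rda import SimGrid
from .synthetic import GroundTruth, make_profile_series
from .rda import ModelParams

__all__ = ["SobolResult", "sobol_saltelli", "distance_sensitivity",
           "REFERENCE_CONDITIONS", "build_reference_series"]

# Published per-condition parameter estimates used to build synthetic
# reference series for the sensitivity analysis (rates in day⁻¹, v_p in
# μm/day, D in μm²/day, sigma in density units).
REFERENCE_CONDITIONS = {
    "control": {"a": 0.092, "r": 0.08, "vp": 1.2, "D": 977.0,
                "sigma": 0.006367},
    "tig1": {"a": 0.087, "r": 0.09, "vp": 22.5, "D": 1617.0,
             "sigma": 0.005426},
    "prod1": {"a": 0.084, "r": 0.05, "vp": 46.0, "D": 7022.0,
              "sigma": 0.005803},
}

PARAM_ORDER = ("D", "vp", "r", "a")


@dataclass
class SobolResult:
    """First- and total-order indices per parameter per timepoint.

    ``frame`` columns: param, timepoint, S1, S1_lo, S1_hi, ST, ST_lo,
    ST_hi (CI bounds from the bootstrap).  ``degenerate`` flags
    timepoints whose output variance was zero (indices undefined).
    """

    frame: pd.DataFrame
    base_samples: int
    n_boot: int
    degenerate: list

    def ranking(self, timepoint: float, order: str = "ST") -> list[str]:
        """Parameters sorted by decreasing index at one timepoint."""
        sub = self.frame[self.frame.timepoint == timepoint]
        return list(sub.sort_values(order, ascending=False).param)


def _indices(fA: np.ndarray, fB: np.ndarray, fAB: np.ndarray
             ) -> tuple[np.ndarray, np.ndarray]:
    """S1 (Saltelli 2010) and ST (Jansen) from sample evaluations.

    fA, fB: (N,); fAB: (d, N).  Returns (S1, ST) of shape (d,).
    """
    V = np.var(np.concatenate([fA, fB]))
    if V == 0:
        return np.full(fAB.shape[0], np.nan), np.full(fAB.shape[0], np.nan)
    S1 = np.mean(fB[None, :] * (fAB - fA[None, :]), axis=1) / V
    ST = 0.5 * np.mean((fA[None, :] - fAB) ** 2, axis=1) / V
    return S1, ST


def sobol_saltelli(func, ranges: dict, base_samples: int = 1024,
                   seed: int = 0, n_boot: int = 100,
                   timepoint_labels=None) -> SobolResult:
    """Sobol indices of ``func`` over a parameter box.

    Parameters
    ----------
    func : callable (M, d) -> (M,) or (M, T)
        Vector outputs are treated as independent outputs (one per
        timepoint label).
    ranges : mapping param -> (lo, hi); iteration order fixes the column
        order of the samples.
    base_samples : N, a power of two (Sobol' sequence balance).
    n_boot : bootstrap resamples for the confidence intervals.
    """
    names = list(ranges)
    d = len(names)
    if base_samples < 2 or base_samples & (base_samples - 1):
        raise ValueError("base_samples must be a power of 2")
    lo = np.array([ranges[p][0] for p in names])
    hi = np.array([ranges[p][1] for p in names])
    sampler = qmc.Sobol(d=2 * d, scramble=True, rng=np.random.default_rng(seed))
    base = sampler.random(base_samples)
    A = lo + base[:, :d] * (hi - lo)
    B = lo + base[:, d:] * (hi - lo)
    X = [A, B]
    for i in range(d):
        ABi = A.copy()
        ABi[:, i] = B[:, i]
        X.append(ABi)
    Y = np.asarray(func(np.vstack(X)), dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    T = Y.shape[1]
    labels = list(timepoint_labels) if timepoint_labels is not None \
        else list(range(T))
    N = base_samples
    fA = Y[:N]
    fB = Y[N:2 * N]
    fAB = Y[2 * N:].reshape(d, N, T)
    rng = np.random.default_rng(seed + 1)
    rows = []
    degenerate = []
    for t in range(T):
        S1, ST = _indices(fA[:, t], fB[:, t], fAB[:, :, t])
        if np.isnan(S1).all():
            degenerate.append(labels[t])
        boot_S1 = np.empty((n_boot, d))
        boot_ST = np.empty((n_boot, d))
        for b in range(n_boot):
            idx = rng.integers(0, N, N)
            boot_S1[b], boot_ST[b] = _indices(fA[idx, t], fB[idx, t],
                                              fAB[:, idx, t])
        s1_lo, s1_hi = np.nanpercentile(boot_S1, [2.5, 97.5], axis=0)
        st_lo, st_hi = np.nanpercentile(boot_ST, [2.5, 97.5], axis=0)
        for i, p in enumerate(names):
            rows.append({"param": p, "timepoint": labels[t],
                         "S1": S1[i], "S1_lo": s1_lo[i], "S1_hi": s1_hi[i],
                         "ST": ST[i], "ST_lo": st_lo[i], "ST_hi": st_hi[i]})
    return SobolResult(frame=pd.DataFrame(rows), base_samples=N,
                       n_boot=n_boot, degenerate=degenerate)


def build_reference_series(L0: float = 1000.0, grid: SimGrid | None = None,
                           timepoints=(1.0, 7.0, 12.0, 18.0, 24.0),
                           seed: int = 0, conditions: dict | None = None):
    """Synthetic per-condition reference series from the published
    parameter estimates, with each condition's own noise scale."""
    grid = grid or SimGrid()
    conditions = conditions or REFERENCE_CONDITIONS
    out = {}
    for i, (name, c) in enumerate(conditions.items()):
        params = ModelParams(r=c["r"], D=c["D"], a=c["a"], vp=c["vp"], L0=L0)
        gt = GroundTruth(params=params, noise_sigma=c["sigma"],
                         timepoints=tuple(float(t) for t in timepoints),
                         seed=seed + i, clip_noise=False)
        out[name] = make_profile_series(gt, grid, condition=name,
                                        noise_on_ic=False)
    return out


def distance_sensitivity(ranges: dict | None = None, L0: float = 1000.0,
                         grid: SimGrid | None = None,
                         timepoints=(7.0, 12.0, 18.0, 24.0),
                         base_samples: int = 1024, seed: int = 0,
                         n_boot: int = 100,
                         references: dict | None = None) -> SobolResult:
    """Sobol analysis of the model-data distance per timepoint.

    The reference data are synthetic series built from the published
    per-condition estimates (:data:`REFERENCE_CONDITIONS`); the output
    for a sampled (D, v_p, r, a) is Σ_c Σ_i (y_i − f_i)²/σ_c² at each
    timepoint, with all conditions sharing the sampled parameters and
    the common default initial condition.  Distances are evaluated on
    the normalized domain coordinate (δ-grid nodes).

    Default ranges span the spread of the published per-condition
    estimates.
    """
    grid = grid or SimGrid()
    if ranges is None:
        # default box: the spread of the published per-condition estimates
        ranges = {p: (min(c[p] for c in REFERENCE_CONDITIONS.values()),
                      max(c[p] for c in REFERENCE_CONDITIONS.values()))
                  for p in PARAM_ORDER}
    references = references or build_reference_series(
        L0, grid, timepoints=(1.0,) + tuple(timepoints), seed=seed)
    # data nodes per condition per fitted timepoint (δ frame)
    data = {}
    for name, series in references.items():
        later = sorted(series, key=lambda p: p.timepoint)[1:]
        data[name] = np.stack([p.rho for p in later])
    sigmas = {name: REFERENCE_CONDITIONS[name]["sigma"] for name in data}

    params0 = ModelParams(r=0.08, D=1000.0, a=0.09, vp=1.0, L0=L0)
    gt0 = GroundTruth(params=params0, noise_sigma=0.0)
    ic_nodes = gt0.ic_nodes(grid)
    t0 = 1.0
    thetas = np.asarray(timepoints, dtype=float) - t0

    def func(X: np.ndarray) -> np.ndarray:
        D, vp, r, a = (X[:, i] for i in range(4))
        out, ok = batch_evolve(ic_nodes, vp / L0, D / L0**2, r, a, thetas)
        dist = np.zeros((len(X), len(thetas)))
        for name, y in data.items():
            dist += ((out - y[None]) ** 2).sum(axis=-1) / sigmas[name] ** 2
        dist[~ok] = np.nan
        return dist

    return sobol_saltelli(func, ranges, base_samples=base_samples, seed=seed,
                          n_boot=n_boot, timepoint_labels=list(timepoints))
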