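"""Descriptive statistics of density-profile time series.

Gaussian moment fits of profiles, area-under-curve (AUC) growth,
arc-length growth, and exponential-rate estimation with Student-t
confidence intervals.  The expansion rate ``a`` is estimated from limb
lengths L(t) and the proliferation rate ``r`` from normalized AUCs; both
go through the same exponential fit c·exp(k·t), fitted per replicate and
pooled with a t-interval on the replicate rates.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import integrate, optimize, stats

from .profiles import DensityProfile

__all__ = [
    "MomentFit",
    "GrowthFit",
    "gaussian_moments",
    "auc",
    "normalize_auc",
    "fit_exponential",
    "estimate_a",
    "estimate_r",
    "doubling_time",
    "mean_shift",
]


@dataclass(frozen=True)
class MomentFit:
    """First two moments of a density profile treated as a weight function."""

    mean: float  # μm
    sd: float    # μm
    timepoint: float = 0.0


@dataclass(frozen=True)
class GrowthFit:
    """Pooled exponential growth rate with a Student-t confidence interval.

    ``rate`` is the mean of the per-replicate rates; ``ci95`` is
    rate ± t_{α/2, N−1} · std over the N replicate rates (α = 0.05).
    With a single replicate the CI is undefined (NaN bounds).
    """

    rate: float          # day⁻¹
    prefactor: float     # same units as y
    rate_sd: float       # day⁻¹, std of replicate rates
    ci95: tuple[float, float]
    n_replicates: int


def gaussian_moments(profile: DensityProfile) -> MomentFit:
    """Mean and standard deviation of a profile as a weight function.

    mean = Σ x·ρ / Σ ρ and sd = sqrt(Σ (x − mean)²·ρ / Σ ρ): the Gaussian
    fit of a profile by its first two moments.
    """
    w = profile.rho
    total = w.sum()
    if total <= 0:
        raise ValueError("cannot take moments of an all-zero profile")
    mean = float((profile.x * w).sum() / total)
    var = float((((profile.x - mean) ** 2) * w).sum() / total)
    return MomentFit(mean=mean, sd=math.sqrt(max(var, 0.0)),
                     timepoint=profile.timepoint)


def auc(profile: DensityProfile) -> float:
    """Area under the profile (Simpson rule; dimensionless·μm).

    Falls back to the trapezoid rule with a warning for fewer than three
    points.
    """
    if len(profile) < 3:
        warnings.warn("fewer than 3 points: falling back to trapezoid rule")
        return float(np.trapezoid(profile.rho, profile.x))
    return float(integrate.simpson(profile.rho, x=profile.x))


def normalize_auc(series: Sequence[DensityProfile]) -> pd.Series:
    """AUC(t) / AUC(t₁) for a time-ordered profile series.

    Index is the timepoint; the first entry is exactly 1.
    """
    if not series:
        raise ValueError("empty series")
    ordered = sorted(series, key=lambda p: p.timepoint)
    a0 = auc(ordered[0])
    if a0 <= 0:
        raise ValueError("initial AUC must be positive")
    return pd.Series({p.timepoint: auc(p) / a0 for p in ordered})


def _fit_single(t: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    """Nonlinear least squares for y = c·exp(k·t), log-linear init."""
    if np.any(y <= 0):
        raise ValueError("y must be strictly positive for an exponential fit")
    if len(t) < 3:
        raise ValueError("need at least 3 timepoints")
    slope, intercept = np.polyfit(t, np.log(y), 1)
    try:
        popt, _ = optimize.curve_fit(
            lambda tt, c, k: c * np.exp(k * tt), t, y,
            p0=[math.exp(intercept), slope], maxfev=10000)
    except RuntimeError as exc:  # pragma: no cover - singular fit
        raise RuntimeError(f"exponential fit failed to converge: {exc}") from exc
    c, k = float(popt[0]), float(popt[1])
    return c, k


def fit_exponential(t: np.ndarray,
                    y: np.ndarray | Sequence[np.ndarray],
                    alpha: float = 0.05) -> GrowthFit:
    """Fit y = c·exp(k·t) per replicate and pool the rates.

    Parameters
    ----------
    t : (T,) times in days, shared across replicates.
    y : (T,) single replicate, or (R, T) array / sequence of R replicate
        series (all strictly positive).
    alpha : significance level for the pooled CI (default 0.05 → 95%).

    The pooled rate is the mean of the per-replicate rates and the CI is
    rate ± t_{α/2, N−1}·std with N the number of replicates.
    """
    t = np.asarray(t, dtype=float)
    arr = np.asarray(y, dtype=float) if not isinstance(y, (list, tuple)) else y
    if isinstance(arr, np.ndarray) and arr.ndim == 1:
        reps = [arr]
    elif isinstance(arr, np.ndarray):
        reps = list(arr)
    else:
        reps = [np.asarray(r, dtype=float) for r in arr]
    fits = [_fit_single(t, r) for r in reps]
    rates = np.array([k for _, k in fits])
    prefs = np.array([c for c, _ in fits])
    n = len(rates)
    rate = float(rates.mean())
    if n >= 2:
        sd = float(rates.std(ddof=1))
        tcrit = float(stats.t.ppf(1 - alpha / 2, n - 1))
        ci = (rate - tcrit * sd, rate + tcrit * sd)
    else:
        sd = float("nan")
        ci = (float("nan"), float("nan"))
    return GrowthFit(rate=rate, prefactor=float(prefs.mean()), rate_sd=sd,
                     ci95=ci, n_replicates=n)


def estimate_a(t: np.ndarray, lengths: np.ndarray | Sequence[np.ndarray],
               alpha: float = 0.05) -> GrowthFit:
    """Expansion rate a from limb lengths L(t) = c·exp(a·t)."""
    return fit_exponential(t, lengths, alpha=alpha)


def estimate_r(t: np.ndarray, masses: np.ndarray | Sequence[np.ndarray],
               alpha: float = 0.05) -> GrowthFit:
    """Proliferation rate r from normalized AUCs Mass(t) = c·exp(r·t)."""
    return fit_exponential(t, masses, alpha=alpha)


def doubling_time(r: float) -> float:
    """Average net cell-cycle length T_c = ln 2 / r (days)."""
    if r <= 0:
        raise ValueError("r must be > 0")
    return math.log(2) / r


def mean_shift(series_by_condition: Mapping[str, Iterable[DensityProfile]],
               control: str = "control") -> pd.DataFrame:
    """Difference of Gaussian means vs the control condition per timepoint.

    For each condition and timepoint the per-replicate Gaussian-moment
    means are averaged; the returned frame holds
    mean(condition, t) − mean(control, t) (μm), proximal shifts negative
    under the distal-positive convention.  Timepoints missing in either
    condition are skipped with a warning.
    """
    if control not in series_by_condition:
        raise ValueError(f"control condition {control!r} not present")

    def per_tp(profiles: Iterable[DensityProfile]) -> dict[float, float]:
        acc: dict[float, list[float]] = {}
        for p in profiles:
            acc.setdefault(p.timepoint, []).append(gaussian_moments(p).mean)
        return {tp: float(np.mean(v)) for tp, v in acc.items()}

    ctrl = per_tp(series_by_condition[control])
    cols = {}
    for cond, profiles in series_by_condition.items():
        if cond == control:
            continue
        means = per_tp(profiles)
        shared = sorted(set(means) & set(ctrl))
        missing = (set(means) | set(ctrl)) - set(shared)
        if missing:
            warnings.warn(
                f"condition {cond!r}: timepoints {sorted(missing)} missing in "
                "one of the series; skipped")
        cols[cond] = pd.Series({tp: means[tp] - ctrl[tp] for tp in shared})
    return pd.DataFrame(cols)
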