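"""Model/Results front end for proximalisation inference.

:class:`ProximalisationModel` is built from a density-profile time
series for one condition (replicates allowed).  Construction estimates
the domain-expansion rate ``a`` from limb lengths and the proliferation
rate ``r`` from normalized profile areas (unless supplied); ``fit()``
runs the sequential Bayesian grid inference — or ABC-SMC with
``method="abc"`` — for the proximalisation velocity v_p, the diffusion
coefficient D and the noise scale σ, and returns a
:class:`ProximalisationResults` carrying posterior summaries in lab
units (μm/day, μm²/day) with a ``summary()`` table, simulation and
plotting helpers.

Example
-------
>>> from proximo import ProximalisationModel
>>> from proximo.rda import ModelParams
>>> from proximo.synthetic import GroundTruth, make_profile_series
>>> gt = GroundTruth(ModelParams(r=.08, D=1500, a=.092, vp=12, L0=1000),
...                  noise_sigma=.005, seed=1)
>>> series = make_profile_series(gt)
>>> res = ProximalisationModel(series, r=.08, a=.092, n_grid=40).fit()
>>> print(res.summary())        # doctest: +SKIP
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from . import growth, inference
from .abc_smc import ABCConfig, ABCResult, abc_smc
from .profiles import DensityProfile
from .rda import ModelParams, SimGrid, simulate

__all__ = ["ProximalisationModel", "ProximalisationResults"]


class ProximalisationModel:
    """RDA proximalisation model bound to a profile time series.

    Parameters
    ----------
    series : list of DensityProfile
        One condition; multiple replicates are averaged per timepoint on
        the normalized domain coordinate.  The earliest timepoint is the
        initial condition of the forward model.
    r, a : float, optional
        Proliferation and expansion rates (day⁻¹).  If omitted they are
        estimated from the series itself: ``a`` from an exponential fit
        to the profile domain lengths L(t), ``r`` from a fit to the
        normalized areas under the profiles, pooled over replicates.
    bounds : dict, optional
        Uniform prior bounds in transformed units (``vp``: v_p/L0,
        ``D``: D/L0², ``sigma``); default: the validation ranges.
    n_grid : int
        Posterior grid size per axis (N³ grid, N² simulations).
    sim_grid : SimGrid, optional
        Spatial discretization of the forward model.
    """

    def __init__(self, series: list[DensityProfile], r: float | None = None,
                 a: float | None = None, bounds: dict | None = None,
                 n_grid: int = 100, sim_grid: SimGrid | None = None):
        if len(series) < 2:
            raise ValueError("need profiles at two or more timepoints")
        self.sim_grid = sim_grid or SimGrid()
        self.bounds = dict(inference.DEFAULT_BOUNDS, **(bounds or {}))
        self.n_grid = n_grid
        self.condition = series[0].condition
        self._replicates = sorted({p.replicate for p in series})
        self.timepoints = np.array(sorted({p.timepoint for p in series}))
        self._by_rep = {
            rep: sorted((p for p in series if p.replicate == rep),
                        key=lambda p: p.timepoint)
            for rep in self._replicates}
        self.growth_fit_a: growth.GrowthFit | None = None
        self.growth_fit_r: growth.GrowthFit | None = None
        if a is None:
            self.growth_fit_a = growth.estimate_a(
                self.timepoints,
                [np.array([p.L for p in profs])
                 for profs in self._by_rep.values()])
            a = self.growth_fit_a.rate
        if r is None:
            self.growth_fit_r = growth.estimate_r(
                self.timepoints,
                [growth.normalize_auc(profs).to_numpy()
                 for profs in self._by_rep.values()])
            r = self.growth_fit_r.rate
        self.r = float(r)
        self.a = float(a)
        self.series = self._condition_mean_series(series)
        self.L0 = float(self.series[0].L)

    def _condition_mean_series(self, series) -> list[DensityProfile]:
        """Average replicates per timepoint on the δ coordinate."""
        out = []
        for tp in self.timepoints:
            profs = [p for p in series if p.timepoint == tp]
            L = float(np.mean([p.L for p in profs]))
            delta = self.sim_grid.delta
            vals = np.mean([p.interp(delta * p.L) for p in profs], axis=0)
            out.append(DensityProfile(x=delta * L, rho=vals, timepoint=tp,
                                      condition=self.condition,
                                      replicate="mean", L=L))
        return out

    def fit(self, method: str = "grid", seed: int = 0,
            abc_config: ABCConfig | None = None) -> "ProximalisationResults":
        """Posterior over (v_p, D[, σ]) by grid inference or ABC-SMC."""
        if method == "grid":
            post, summary, _ = inference.fit_grid_posterior(
                self.series, r=self.r, a=self.a, bounds=self.bounds,
                n=self.n_grid, grid=self.sim_grid)
            return ProximalisationResults(self, method, posterior=post,
                                          post_summary=summary)
        if method == "abc":
            cfg = abc_config or ABCConfig(priors={
                "vp": self.bounds["vp"], "D": self.bounds["D"]})
            res = abc_smc(self.series, cfg, r=self.r, a=self.a,
                          grid=self.sim_grid, seed=seed)
            return ProximalisationResults(self, method, abc_result=res)
        raise ValueError(f"unknown method {method!r}; use 'grid' or 'abc'")

    def simulate(self, vp: float, D: float, times) -> list[DensityProfile]:
        """Forward simulation from the series IC; vp, D in lab units."""
        params = ModelParams(r=self.r, D=D, a=self.a, vp=vp, L0=self.L0)
        return simulate(params, self.series[0], times, self.sim_grid)


class ProximalisationResults:
    """Fit results: posterior summaries in lab units plus diagnostics.

    Attributes
    ----------
    params : pd.Series
        Posterior means: ``v_p`` (μm/day), ``D`` (μm²/day) and, for the
        grid method, ``sigma`` (density units).
    bse : pd.Series
        Posterior standard deviations on the same scale.
    posterior : PosteriorGrid (grid method)
    abc_result : ABCResult (abc method)
    """

    def __init__(self, model: ProximalisationModel, method: str,
                 posterior=None, post_summary=None, abc_result: ABCResult | None = None):
        self.model = model
        self.method = method
        self.posterior = posterior
        self.post_summary = post_summary
        self.abc_result = abc_result
        L0 = model.L0
        scale = {"vp": L0, "D": L0**2, "sigma": 1.0}
        if method == "grid":
            mean = {p: post_summary.mean[p] * scale[p] for p in scale}
            sd = {p: post_summary.sd[p] * scale[p] for p in scale}
        else:
            m, s = abc_result.mean(), abc_result.sd()
            mean = {p: m[p] * scale[p] for p in ("vp", "D")}
            sd = {p: s[p] * scale[p] for p in ("vp", "D")}
        index = {"vp": "v_p", "D": "D", "sigma": "sigma"}
        self.params = pd.Series({index[p]: mean[p] for p in mean})
        self.bse = pd.Series({index[p]: sd[p] for p in sd})

    def conf_int(self) -> pd.DataFrame:
        """mean ± 2·sd intervals (the posterior summary convention)."""
        return pd.DataFrame({
            "lower": self.params - 2 * self.bse,
            "upper": self.params + 2 * self.bse})

    def simulate(self, times=None) -> list[DensityProfile]:
        """Forward simulation at the posterior-mean parameters."""
        times = self.model.timepoints if times is None else times
        return self.model.simulate(self.params["v_p"], self.params["D"], times)

    def summary(self) -> str:
        """Human-readable fit report."""
        m = self.model
        units = {"v_p": "μm/day", "D": "μm²/day", "sigma": "density"}
        lines = [
            "         Proximalisation model results",
            "=" * 58,
            f"Condition: {m.condition or '<unnamed>'}"
            f"        Method: {self.method}",
            f"Timepoints (dpe): {', '.join(f'{t:g}' for t in m.timepoints)}",
            f"L0 = {m.L0:.1f} μm    n_nodes = {m.sim_grid.n0}"
            + (f"    N_grid = {m.n_grid}" if self.method == "grid" else ""),
            f"a = {m.a:.4g} day⁻¹    r = {m.r:.4g} day⁻¹"
            + ("  (estimated)" if m.growth_fit_a or m.growth_fit_r
               else "  (supplied)"),
            "-" * 58,
            f"{'param':<8}{'mean':>12}{'sd':>12}{'[mean − 2sd':>14}"
            f"{'mean + 2sd]':>12}",
        ]
        ci = self.conf_int()
        for p in self.params.index:
            lines.append(
                f"{p:<8}{self.params[p]:>12.4g}{self.bse[p]:>12.3g}"
                f"{ci.loc[p, 'lower']:>14.4g}{ci.loc[p, 'upper']:>12.4g}"
                f"  {units.get(p, '')}")
        lines.append("-" * 58)
        if self.method == "abc":
            r = self.abc_result
            lines.append(
                f"ABC-SMC: {r.n_populations} populations, "
                f"{r.n_simulations} simulations, "
                f"converged={r.converged}, collapsed={r.collapsed}")
        return "\n".join(lines)

    def plot_fit(self, ax=None):
        """Data vs posterior-mean simulation at each timepoint."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        sims = self.simulate()
        cmap = plt.get_cmap("viridis")
        for i, (dat, sim) in enumerate(zip(self.model.series, sims)):
            c = cmap(i / max(len(sims) - 1, 1))
            ax.plot(dat.x, dat.rho, ".", ms=2, color=c, alpha=0.5)
            ax.plot(sim.x, sim.rho, "-", color=c,
                    label=f"{dat.timepoint:g} dpe")
        ax.set_xlabel("PD-axis position x (μm)")
        ax.set_ylabel("cell density ρ")
        ax.legend(fontsize=8)
        return ax

    def plot_posterior(self, axes=None):
        """Marginal posteriors (grid) or weighted particles (ABC)."""
        import matplotlib.pyplot as plt

        if self.method == "grid":
            names = ("vp", "D", "sigma")
            if axes is None:
                _, axes = plt.subplots(1, 3, figsize=(9, 2.5))
            s = self.post_summary
            scale = {"vp": self.model.L0, "D": self.model.L0**2, "sigma": 1.0}
            for ax, p in zip(axes, names):
                ax.plot(s.axes[p] * scale[p], s.marginals[p])
                ax.set_xlabel(p)
            return axes
        if axes is None:
            _, axes = plt.subplots()
        pts = self.abc_result.particles
        axes.scatter(pts[:, 0] * self.model.L0,
                     pts[:, 1] * self.model.L0**2,
                     s=5 + 200 * self.abc_result.weights, alpha=0.5)
        axes.set_xlabel("v_p (μm/day)")
        axes.set_ylabel("D (μm²/day)")
        return axes
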