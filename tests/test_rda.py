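"""RDA solver: literal upwind oracle, analytic limits, scenarios."""

import math

import numpy as np
import pytest

from proximo._kernel import batch_evolve
from proximo.rda import (ModelParams, SimGrid, default_timestep, evolve_nodes,
                         interpret_velocity, scenario_gaussian_ic,
                         scenario_reduced_rates, simulate)


def gaussian_nodes(grid, mu=0.5, sd=0.05):
    d = grid.delta
    return np.exp(-0.5 * ((d - mu) / sd) ** 2)


def upwind_oracle_step(rho, dd, h, Dt, vt, rma):
    """Literal hand-rolled implementation of the conservative upwind
    scheme: G = -D̃/ρ ∂ρ/∂δ - ṽ, interface flux upwinded on mean G,
    explicit reaction source."""
    n = len(rho)
    d = np.empty(n)
    for i in range(n):
        if i == 0:
            d[i] = (rho[1] - rho[0]) / dd
        elif i == n - 1:
            d[i] = (rho[-1] - rho[-2]) / dd
        else:
            d[i] = (rho[i + 1] - rho[i - 1]) / (2 * dd)
    floor = 1e-12 * max(rho)
    G = [-Dt * d[i] / max(rho[i], floor) - vt for i in range(n)]
    F = [0.0] * (n + 1)  # boundary fluxes stay zero
    for i in range(n - 1):
        gb = 0.5 * (G[i] + G[i + 1])
        F[i + 1] = (rho[i] if gb > 0 else rho[i + 1]) * gb
    out = np.empty(n)
    for i in range(n):
        out[i] = rho[i] - (h / dd) * (F[i + 1] - F[i]) + h * rma * rho[i]
    return out


class TestScheme:
    def test_one_step_matches_literal_oracle_on_20_nodes(self):
        grid = SimGrid(n0=20)
        rho = gaussian_nodes(grid, sd=0.15) + 0.05
        p = ModelParams(r=0.08, D=2000.0, a=0.09, vp=20.0, L0=1000.0)
        h = 1e-5  # far below every CFL bound: exactly one step is taken
        got = evolve_nodes(p, rho, np.array([h]), grid)[0]
        want = upwind_oracle_step(rho, grid.d_delta, h, p.D_tilde,
                                  p.vp_tilde, p.r - p.a)
        np.testing.assert_allclose(got, want, rtol=1e-12, atol=1e-15)

    def test_batch_kernel_matches_reference_path(self, small_grid):
        rho = gaussian_nodes(small_grid)
        p = ModelParams(r=0.08, D=1500.0, a=0.092, vp=12.0, L0=1000.0)
        thetas = np.array([5.0, 11.0, 23.0])
        ref = evolve_nodes(p, rho, thetas, small_grid)
        out, ok = batch_evolve(rho, np.array([p.vp_tilde]),
                               np.array([p.D_tilde]), p.r, p.a, thetas)
        assert ok.all()
        np.testing.assert_allclose(out[0], ref, rtol=1e-10, atol=1e-14)

    def test_reaction_term_close_to_operator_splitting(self, small_grid):
        # explicit same-step source vs Lie splitting (transport step then
        # exact exponential reaction): difference < 0.5% at default Δθ
        rho = gaussian_nodes(small_grid)
        p = ModelParams(r=0.08, D=1500.0, a=0.092, vp=10.0, L0=1000.0)
        got = evolve_nodes(p, rho, np.array([1.0]), small_grid)[0]
        dd = small_grid.d_delta
        dt = default_timestep(p, small_grid)
        split, theta = rho.copy(), 0.0
        while theta < 1.0 - 1e-12:
            h = min(dt, 1.0 - theta)
            Dt = p.D_tilde * math.exp(-2 * p.a * theta)
            vt = p.vp_tilde * math.exp(-p.a * theta)
            split = upwind_oracle_step(split, dd, h, Dt, vt, 0.0)
            split *= math.exp((p.r - p.a) * h)
            theta += h
        assert np.abs(got - split).sum() / split.sum() < 0.005

    def test_positivity_preserved_on_rough_ics(self, small_grid):
        rng = np.random.default_rng(0)
        p = ModelParams(r=0.05, D=3000.0, a=0.09, vp=30.0, L0=1000.0)
        for _ in range(5):
            rho = np.clip(gaussian_nodes(small_grid)
                          + rng.normal(0, 0.02, small_grid.n0), 0, None)
            out = evolve_nodes(p, rho, np.array([2.0, 10.0]), small_grid)
            assert np.all(out >= 0)
            assert np.all(np.isfinite(out))

    def test_grid_convergence_in_L1(self):
        # halving Δδ from the default 200 nodes changes the 24-day
        # profile by < 2% in L¹
        p = ModelParams(r=0.09, D=1617.0, a=0.087, vp=22.5, L0=1000.0)
        profs = {}
        for n0 in (200, 400):
            grid = SimGrid(n0=n0)
            out, ok = batch_evolve(gaussian_nodes(grid, mu=0.9, sd=0.05),
                                   np.array([p.vp_tilde]),
                                   np.array([p.D_tilde]), p.r, p.a,
                                   np.array([23.0]))
            assert ok.all()
            profs[n0] = np.interp(np.linspace(0, 1, 800), grid.delta, out[0, 0])
        l1 = np.abs(profs[200] - profs[400]).sum()
        assert l1 / profs[400].sum() < 0.02


class TestAnalyticLimits:
    def test_pure_diffusion_variance_growth(self):
        p = ModelParams(r=0, D=1000.0, a=0, vp=0, L0=3000.0)
        ic = scenario_gaussian_ic(mean=1500, sd=100, area=100, L0=3000,
                                  n_points=600)
        (prof,) = simulate(p, ic, [1.0], SimGrid(n0=200))
        w = prof.rho / np.trapezoid(prof.rho, prof.x)
        mu = np.trapezoid(prof.x * w, prof.x)
        var = np.trapezoid((prof.x - mu) ** 2 * w, prof.x)
        assert var == pytest.approx(100**2 + 2 * 1000.0 * 1.0, rel=0.05)

    def test_mass_conserved_without_reaction_or_drift(self):
        p = ModelParams(r=0, D=1000.0, a=0, vp=0, L0=3000.0)
        ic = scenario_gaussian_ic(mean=1500, sd=100, area=100, L0=3000,
                                  n_points=600)
        m0 = np.trapezoid(ic.rho, ic.x)
        (prof,) = simulate(p, ic, [24.0], SimGrid(n0=200))
        assert np.trapezoid(prof.rho, prof.x) == pytest.approx(m0, rel=1e-6)

    def test_pure_advection_translates_peak(self):
        p = ModelParams(r=0, D=10.0, a=0, vp=50.0, L0=3000.0)
        ic = scenario_gaussian_ic(mean=1500, sd=100, area=100, L0=3000,
                                  n_points=600)
        grid = SimGrid(n0=200)
        cell = 3000.0 / grid.n0
        for prof in simulate(p, ic, [1, 2, 3, 4, 5], grid):
            peak = prof.x[np.argmax(prof.rho)]
            assert abs(peak - (1500 - 50 * prof.timepoint)) <= cell

    def test_growth_law_auc(self):
        p = ModelParams(r=0.08, D=500.0, a=0.092, vp=0.0, L0=3000.0)
        ic = scenario_gaussian_ic(mean=1500, sd=150, area=100, L0=3000,
                                  n_points=600)
        (prof,) = simulate(p, ic, [24.0], SimGrid(n0=200))
        ratio = np.trapezoid(prof.rho, prof.x) / np.trapezoid(ic.rho, ic.x)
        assert ratio == pytest.approx(math.exp(0.08 * 24), rel=0.01)

    def test_exact_linearity_in_ic(self, small_grid):
        p = ModelParams(r=0.08, D=977.0, a=0.092, vp=22.0, L0=3000.0)
        rho = gaussian_nodes(small_grid, mu=0.5, sd=0.04)
        a1 = evolve_nodes(p, rho, np.array([10.0]), small_grid)
        a2 = evolve_nodes(p, 2 * rho, np.array([10.0]), small_grid)
        np.testing.assert_allclose(a2, 2 * a1, rtol=1e-12)


class TestTimestep:
    def test_plug_in_value(self):
        # D̃₀ = 0.005 day⁻¹ at n0 = 200: Δθ = (1/200)²/(3·0.005)
        p = ModelParams(r=0, D=0.005 * 1000.0**2, a=0, vp=0, L0=1000.0)
        dt = default_timestep(p, SimGrid(n0=200))
        assert dt == pytest.approx((1 / 200) ** 2 / (3 * 0.005))

    def test_doubling_nodes_quarters_step(self):
        p = ModelParams(r=0, D=2000.0, a=0, vp=0, L0=1000.0)
        assert default_timestep(p, SimGrid(n0=400)) == pytest.approx(
            default_timestep(p, SimGrid(n0=200)) / 4)

    def test_zero_D_uses_advective_bound(self):
        p = ModelParams(r=0, D=0.0, a=0, vp=20.0, L0=1000.0)
        dt = default_timestep(p, SimGrid(n0=200))
        assert dt == pytest.approx(0.9 * (1 / 200) / (2 * 0.02))

    def test_cfl_holds_across_validation_box(self, small_grid):
        # the chosen step never triggers instability over the prior box
        rho = gaussian_nodes(small_grid, mu=0.9, sd=0.05)
        vts = np.linspace(0.0005, 0.05, 6)
        Dts = np.linspace(0.00005, 0.005, 6)
        V, Dm = np.meshgrid(vts, Dts)
        out, ok = batch_evolve(rho, V.ravel(), Dm.ravel(), 0.08, 0.092,
                               np.array([23.0]))
        assert ok.all()
        assert np.all(out >= 0)


class TestScenarios:
    def test_doubling_ic_area_preserves_peak_positions(self, small_grid):
        p = ModelParams(r=0.09, D=1617.0, a=0.087, vp=22.5, L0=1000.0)
        times = [12.0, 24.0]
        ic1 = scenario_gaussian_ic(mean=900, sd=50, area=100, L0=1000)
        ic2 = scenario_gaussian_ic(mean=900, sd=50, area=200, L0=1000)
        s1 = simulate(p, ic1, times, small_grid)
        s2 = simulate(p, ic2, times, small_grid)
        for a, b in zip(s1, s2):
            assert np.argmax(a.rho) == np.argmax(b.rho)
            np.testing.assert_allclose(b.rho, 2 * a.rho, rtol=1e-12)

    def test_reduced_rates_shrink_domain_by_closed_form(self):
        p = ModelParams(r=0.09, D=1617.0, a=0.087, vp=22.5, L0=1000.0)
        q = scenario_reduced_rates(p, factor=0.5)
        assert q.r == pytest.approx(0.045)
        assert q.a == pytest.approx(0.0435)
        assert (q.D, q.vp) == (p.D, p.vp)
        L_full = p.L0 * math.exp(p.a * 24)
        L_red = q.L0 * math.exp(q.a * 24)
        assert L_red / L_full == pytest.approx(math.exp(-0.5 * p.a * 24))

    def test_identity_factor_is_noop(self):
        p = ModelParams(r=0.09, D=1617.0, a=0.087, vp=22.5, L0=1000.0)
        assert scenario_reduced_rates(p, factor=1.0) == p

    def test_invalid_factor_rejected(self):
        p = ModelParams(r=0.09, D=1617.0, a=0.087, vp=22.5, L0=1000.0)
        with pytest.raises(ValueError):
            scenario_reduced_rates(p, factor=0.0)


class TestInterpretation:
    def test_zero_velocity_flat_potential(self):
        pm = interpret_velocity(0.0, mobility=2.0)
        assert pm.force == 0.0
        np.testing.assert_allclose(pm.potential(np.linspace(0, 1000, 5)), 0.0)

    def test_definitional_arithmetic(self):
        pm = interpret_velocity(22.5, mobility=1.0)
        assert pm.potential_slope == pytest.approx(22.5)
        assert pm.attractant_gradient == pytest.approx(-22.5)

    def test_potential_difference_linear_in_length(self):
        pm = interpret_velocity(46.0, mobility=2.0)
        for L in (10.0, 1234.5):
            assert pm.potential(L) - pm.potential(0.0) == pytest.approx(
                46.0 * L / 2.0)

    def test_nonpositive_mobility_rejected(self):
        with pytest.raises(ValueError):
            interpret_velocity(1.0, mobility=0.0)


class TestValidation:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            ModelParams(r=0.1, D=-1.0, a=0.1, vp=0.0, L0=1000.0)
        with pytest.raises(ValueError):
            ModelParams(r=0.1, D=1.0, a=0.1, vp=0.0, L0=0.0)

    def test_times_before_ic_rejected(self):
        p = ModelParams(r=0, D=100.0, a=0, vp=0, L0=1000.0)
        ic = scenario_gaussian_ic(mean=500, sd=50, area=10, L0=1000,
                                  timepoint=5.0)
        with pytest.raises(ValueError):
            simulate(p, ic, [1.0])
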