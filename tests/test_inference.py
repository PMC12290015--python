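"""Sequential Bayesian grid inference: likelihood, updates, marginals."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from proximo.inference import (DEFAULT_BOUNDS, PosteriorGrid,
                               fit_grid_posterior, grid_forward_cache,
                               log_likelihood, marginals_and_summary,
                               sequential_update, validate_recovery)
from proximo.rda import ModelParams, SimGrid
from proximo.synthetic import GroundTruth, make_profile_series


class TestLogLikelihood:
    def test_zero_residuals(self):
        n, sigma = 17, 0.3
        y = np.linspace(0, 1, n)
        got = log_likelihood(y, y, sigma)
        assert got == pytest.approx(n * math.log(1 / (sigma * math.sqrt(2 * math.pi))))

    def test_one_sigma_residual_single_point(self):
        sigma = 0.25
        got = log_likelihood(np.array([1.0 + sigma]), np.array([1.0]), sigma)
        assert got == pytest.approx(-0.5 - math.log(sigma * math.sqrt(2 * math.pi)))

    def test_matches_naive_product_oracle(self):
        rng = np.random.default_rng(1)
        y = rng.normal(0.5, 0.1, 15)
        mu = rng.normal(0.5, 0.1, 15)
        sigma = 0.07
        dens = np.exp(-0.5 * ((y - mu) / sigma) ** 2) / (sigma * math.sqrt(2 * math.pi))
        assert math.exp(log_likelihood(y, mu, sigma)) == pytest.approx(
            float(np.prod(dens)), rel=1e-10)

    def test_invalid_sigma_and_shapes_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.ones(3), np.ones(3), 0.0)
        with pytest.raises(ValueError):
            log_likelihood(np.ones(3), np.ones(4), 0.1)


def tiny_prior(n=8):
    return PosteriorGrid.uniform(n=n)


class TestSequentialUpdate:
    def test_likelihood_flat_over_vp_D_leaves_their_posterior_uniform(self):
        # identical forward model at every (vp, D) node: the update can
        # only inform σ, so each σ-slice stays uniform over (vp, D) and
        # the vp/D marginals remain the prior's
        prior = tiny_prior()
        nv, nd = len(prior.vp_axis), len(prior.D_axis)
        rng = np.random.default_rng(0)
        data = rng.normal(0.5, 0.03, 30)
        model = np.broadcast_to(np.full(30, 0.5), (nv, nd, 30)).copy()
        post = sequential_update(prior, data, model)
        for s in range(len(prior.sigma_axis)):
            sl = post.log_prob[:, :, s]
            np.testing.assert_allclose(sl, sl[0, 0], atol=1e-9)
        from proximo.inference import marginals_and_summary
        summ = marginals_and_summary(post)
        np.testing.assert_allclose(summ.marginals["vp"], 1 / nv, atol=1e-9)
        np.testing.assert_allclose(summ.marginals["D"], 1 / nd, atol=1e-9)

    def test_batch_equals_sequential_in_log_space(self):
        rng = np.random.default_rng(2)
        prior = tiny_prior()
        nv, nd, ns = prior.log_prob.shape
        n = 25
        datasets = [rng.normal(0.5, 0.05, n) for _ in range(3)]
        models = [rng.uniform(0.3, 0.7, (nv, nd, n)) for _ in range(3)]
        seq = prior
        for y, m in zip(datasets, models):
            seq = sequential_update(seq, y, m)
        batch = PosteriorGrid(prior.vp_axis, prior.D_axis, prior.sigma_axis,
                              log_prob=prior.log_prob.copy())
        from proximo.inference import _loglik_cube
        for y, m in zip(datasets, models):
            batch.log_prob = batch.log_prob + _loglik_cube(y, m, prior.sigma_axis)
        batch.normalize()
        np.testing.assert_allclose(seq.log_prob, batch.log_prob, atol=1e-9)

    def test_noiseless_data_at_grid_node_recovers_node(self, small_grid):
        L0 = 1000.0
        prior = PosteriorGrid.uniform(n=12)
        j, k = 4, 7
        vp_t, D_t = prior.vp_axis[j], prior.D_axis[k]
        p = ModelParams(r=0.08, D=D_t * L0**2, a=0.092, vp=vp_t * L0, L0=L0)
        gt = GroundTruth(p, noise_sigma=0.0)
        series = make_profile_series(gt, small_grid)
        post, _, _ = fit_grid_posterior(series, r=0.08, a=0.092, n=12,
                                        grid=small_grid)
        mode = post.mode_indices()
        assert (mode[0], mode[1]) == (j, k)

    def test_all_minus_inf_posterior_rejected(self):
        prior = tiny_prior()
        bad = PosteriorGrid(prior.vp_axis, prior.D_axis, prior.sigma_axis,
                            log_prob=np.full(prior.log_prob.shape, -np.inf))
        with pytest.raises(ValueError, match="cannot explain"):
            bad.normalize()

    @settings(max_examples=20, derandomize=True, deadline=None)
    @given(scale=st.floats(min_value=1.0, max_value=1e5))
    def test_log_sum_exp_never_overflows(self, scale):
        # log-likelihoods down to −10⁵ normalize without overflow
        rng = np.random.default_rng(int(scale) % 2**31)
        prior = tiny_prior(6)
        lp = -scale * rng.uniform(0.1, 1.0, prior.log_prob.shape)
        grid = PosteriorGrid(prior.vp_axis, prior.D_axis, prior.sigma_axis,
                             log_prob=lp)
        grid.normalize()
        total = np.exp(grid.log_prob).sum()
        assert total == pytest.approx(1.0, abs=1e-9)


class TestMarginals:
    def test_product_of_independent_gaussians(self):
        n = 60
        axes = [np.linspace(0, 1, n) for _ in range(3)]
        mus, sds = (0.4, 0.6, 0.5), (0.05, 0.08, 0.1)
        logs = [(-0.5 * ((ax - m) / s) ** 2) for ax, m, s in zip(axes, mus, sds)]
        lp = logs[0][:, None, None] + logs[1][None, :, None] + logs[2][None, None, :]
        grid = PosteriorGrid(*axes, log_prob=lp).normalize()
        s = marginals_and_summary(grid)
        cell = axes[0][1] - axes[0][0]
        for p, m, sd in zip(("vp", "D", "sigma"), mus, sds):
            assert abs(s.mean[p] - m) < cell
            assert abs(s.sd[p] - sd) < 2 * cell

    def test_point_mass_degenerate_interval(self):
        n = 9
        lp = np.full((n, n, n), -np.inf)
        lp[3, 4, 5] = 0.0
        axes = [np.linspace(0, 1, n) for _ in range(3)]
        grid = PosteriorGrid(*axes, log_prob=lp).normalize()
        s = marginals_and_summary(grid)
        assert s.sd["vp"] == pytest.approx(0.0, abs=1e-12)
        assert s.interval["vp"][0] == pytest.approx(s.interval["vp"][1])

    def test_marginals_sum_to_one_for_random_grids(self):
        rng = np.random.default_rng(3)
        for _ in range(5):
            lp = rng.normal(0, 5, (7, 7, 7))
            axes = [np.linspace(0, 1, 7) for _ in range(3)]
            grid = PosteriorGrid(*axes, log_prob=lp).normalize()
            s = marginals_and_summary(grid)
            for p in ("vp", "D", "sigma"):
                assert s.marginals[p].sum() == pytest.approx(1.0, abs=1e-9)

    def test_unnormalized_grid_rejected(self):
        prior = tiny_prior()
        raw = PosteriorGrid(prior.vp_axis, prior.D_axis, prior.sigma_axis,
                            log_prob=prior.log_prob, normalized=False)
        with pytest.raises(ValueError):
            marginals_and_summary(raw)


class TestForwardCache:
    def test_cache_shape_and_consistency_with_single_runs(self, small_grid):
        from proximo.rda import evolve_nodes

        gt = GroundTruth(ModelParams(r=0.08, D=1000, a=0.09, vp=10, L0=1000.0),
                         noise_sigma=0.0)
        ic = gt.ic_nodes(small_grid)
        vp_ax = np.array([0.005, 0.02])
        D_ax = np.array([0.0005, 0.002, 0.004])
        thetas = np.array([5.0, 11.0])
        cache = grid_forward_cache(ic, vp_ax, D_ax, 0.08, 0.09, thetas)
        assert cache.shape == (2, 3, 2, small_grid.n0)
        p = ModelParams(r=0.08, D=0.002e6, a=0.09, vp=20.0, L0=1000.0)
        ref = evolve_nodes(p, ic, thetas, small_grid)
        np.testing.assert_allclose(cache[1, 1], ref, rtol=1e-10)


class TestRecovery:
    def test_zero_noise_modes_within_one_cell(self, small_grid):
        _, summary = validate_recovery(n_cases=6, seed=21, n=25,
                                       grid=small_grid, noise=False)
        assert summary["mode_within_one_cell_vp_D"] >= 5 / 6

    def test_noisy_coverage_on_validation_ranges(self, small_grid):
        report, summary = validate_recovery(n_cases=6, seed=22, n=25,
                                            grid=small_grid, noise=True)
        assert summary["coverage_vp"] >= 5 / 6
        assert summary["coverage_D"] >= 5 / 6
        # truths are drawn inside the prior box by construction
        for p in ("vp", "D", "sigma"):
            lo, hi = DEFAULT_BOUNDS[p]
            assert report[f"{p}_true"].between(lo, hi).all()
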