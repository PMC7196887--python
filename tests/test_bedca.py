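"""Bayesian distance correction: likelihood, conditionals, and recovery."""

import numpy as np
import pytest
from scipy import integrate, stats

from kinedelta import bedca
from kinedelta.bedca import (
    McmcConfig,
    NoiseModel,
    _draw_mu,
    _draw_orientations,
    _draw_tau2,
    _marginal_loglik,
    _marginal_loglik_numpy,
    delta1d,
    delta3d,
    fit_distance,
    likelihood_point,
    moment_init,
)
from kinedelta.spot_io import pair_displacements, chromatic_correct
from kinedelta.synthetic_data import SyntheticSpec, generate_pairs


def displacement_sample(mu, tau_xy, tau_z, n, seed):
    rng = np.random.default_rng(seed)
    u = rng.standard_normal((n, 3))
    u /= np.linalg.norm(u, axis=1, keepdims=True)
    eps = rng.standard_normal((n, 3)) * np.array([tau_xy, tau_xy, tau_z])
    return mu * u + eps


class TestDelta3d:
    def test_zero_and_pythagorean(self):
        assert delta3d([0, 0, 0]) == 0.0
        assert delta3d([3, 4, 0]) == pytest.approx(5.0)

    def test_matches_componentwise_formula(self, rng):
        v = rng.standard_normal((100, 3)) * 50
        np.testing.assert_allclose(delta3d(v), np.sqrt((v**2).sum(axis=1)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            delta3d([np.nan, 0, 0])


class TestLikelihoodPoint:
    def test_mu_zero_is_anisotropic_gaussian(self):
        noise = NoiseModel(30.0, 60.0)
        v = [10.0, 20.0, 30.0]
        expected = stats.multivariate_normal.pdf(v, cov=np.diag([900, 900, 3600]))
        assert likelihood_point(0.0, noise, v) == pytest.approx(expected, rel=1e-9)

    def test_isotropic_limit_matches_noncentral_chi(self):
        mu, tau = 50.0, 40.0
        noise = NoiseModel(tau, tau)
        r = np.linspace(0.5, mu + 6 * tau, 200)
        dens = likelihood_point(mu, noise, np.column_stack([r, 0 * r, 0 * r]))
        radial = 4 * np.pi * r**2 * dens
        closed = (
            r / (mu * tau * np.sqrt(2 * np.pi))
            * (np.exp(-((r - mu) ** 2) / (2 * tau**2))
               - np.exp(-((r + mu) ** 2) / (2 * tau**2)))
        )
        assert np.max(np.abs(radial - closed)) < 1e-6

    def test_integrates_to_one(self):
        mu, noise = 40.0, NoiseModel(25.0, 50.0)

        def radial_shell(rho, z):
            return 2 * np.pi * rho * likelihood_point(mu, noise, [rho, 0.0, z])

        total, _ = integrate.dblquad(
            radial_shell, -400, 400, 0, 400, epsabs=1e-6, epsrel=1e-6
        )
        assert total == pytest.approx(1.0, abs=1e-4)

    def test_rotation_invariance_about_optical_axis(self, rng):
        noise = NoiseModel(30.0, 60.0)
        v = np.array([25.0, -12.0, 40.0])
        base = likelihood_point(55.0, noise, v)
        for ang in (0.3, 1.2, 2.9):
            c, s = np.cos(ang), np.sin(ang)
            vr = np.array([c * v[0] - s * v[1], s * v[0] + c * v[1], v[2]])
            assert likelihood_point(55.0, noise, vr) == pytest.approx(base, rel=1e-10)

    def test_monte_carlo_histogram_agreement(self):
        # brute-force simulation vs quadrature density of the norm |v|;
        # the direction average cannot be skipped under anisotropic noise
        mu, noise = 60.0, NoiseModel(20.0, 45.0)
        v = displacement_sample(mu, noise.tau_xy, noise.tau_z, 200_000, seed=5)
        r = np.linalg.norm(v, axis=1)
        bins = np.linspace(0, 250, 26)
        hist, edges = np.histogram(r, bins=bins, density=True)
        centers = 0.5 * (edges[:-1] + edges[1:])
        theta = np.linspace(0, np.pi / 2, 41)[1:]  # z-symmetric: half sphere
        model = np.empty_like(centers)
        for i, rc in enumerate(centers):
            pts = np.column_stack(
                [rc * np.sin(theta), np.zeros_like(theta), rc * np.cos(theta)]
            )
            dens = likelihood_point(mu, noise, pts)
            model[i] = 4 * np.pi * rc**2 * np.trapezoid(
                dens * np.sin(theta), theta
            )
        mc_err = np.sqrt(np.maximum(hist, 1e-6) / (len(r) * np.diff(edges)))
        assert np.all(np.abs(hist - model) < 5 * mc_err + 2e-4)

    def test_sampler_quadrature_matches_reference(self, rng):
        # the fixed-order in-chain marginal agrees with the adaptive oracle
        v = rng.standard_normal((50, 3)) * 40
        rho, vz = np.hypot(v[:, 0], v[:, 1]), v[:, 2]
        nodes, weights = np.polynomial.legendre.leggauss(48)
        for mu in (0.0, 30.0, 90.0):
            fast = _marginal_loglik(mu, 900.0, 3600.0, rho, vz, nodes, weights)
            slow = _marginal_loglik_numpy(mu, 900.0, 3600.0, rho, vz, nodes, weights)
            oracle = np.sum(
                np.log(likelihood_point(mu, NoiseModel(30.0, 60.0), v))
            )
            assert fast == pytest.approx(slow, rel=1e-6)
            assert fast == pytest.approx(oracle, rel=1e-6)


class TestMomentInit:
    def test_noiseless_recovers_norm(self):
        v = displacement_sample(50.0, 1e-9, 1e-9, 100, seed=1)
        mu0, _, _ = moment_init(v, NoiseModel(1e-6, 1e-6))
        assert mu0 == pytest.approx(50.0, abs=1e-3)

    def test_calibration_recovers_noise_within_two_percent(self):
        v = displacement_sample(0.0, 30.0, 60.0, 10_000, seed=2)
        mu0, txy, tz = moment_init(v, calibration=True)
        assert mu0 == 0.0
        assert txy == pytest.approx(30.0, rel=0.02)
        assert tz == pytest.approx(60.0, rel=0.02)

    def test_below_noise_floor_clamps_to_zero(self):
        v = displacement_sample(0.0, 10.0, 10.0, 500, seed=3)
        mu0, _, _ = moment_init(v, NoiseModel(50.0, 50.0))
        assert mu0 == 0.0

    def test_insufficient_data(self):
        with pytest.raises(ValueError, match="at least 10"):
            moment_init(np.zeros((5, 3)), NoiseModel(1, 1))


class TestConditionals:
    def test_mu_conditional_is_truncated_normal(self):
        # with orientations fixed, repeated draws match the analytic form
        rng = np.random.default_rng(42)
        v = displacement_sample(50.0, 30.0, 60.0, 200, seed=7)
        u = v / np.linalg.norm(v, axis=1, keepdims=True)
        txy2, tz2, mu_max = 900.0, 3600.0, 500.0
        draws = np.array(
            [_draw_mu(u, v, txy2, tz2, mu_max, rng) for _ in range(10_000)]
        )
        inv = np.array([1 / txy2, 1 / txy2, 1 / tz2])
        a = np.sum(u**2 * inv)
        b = np.sum(u * inv * v)
        mean, sd = b / a, 1 / np.sqrt(a)
        lo, hi = (0 - mean) / sd, (mu_max - mean) / sd
        ks = stats.kstest(draws, stats.truncnorm(lo, hi, loc=mean, scale=sd).cdf)
        assert ks.pvalue > 0.01

    def test_tau_conditional_is_inverse_gamma(self):
        from kinedelta.bedca import PriorConfig

        rng = np.random.default_rng(1)
        priors = PriorConfig()
        ssq, nterms = 5.0e5, 600
        draws = np.array([_draw_tau2(ssq, nterms, priors, rng) for _ in range(10_000)])
        shape = priors.tau2_shape + nterms / 2
        scale = priors.tau2_scale + ssq / 2
        ks = stats.kstest(draws, stats.invgamma(shape, scale=scale).cdf)
        assert ks.pvalue > 0.01

    def test_orientation_conditional_moments(self):
        # against brute-force importance sampling on the sphere
        rng = np.random.default_rng(3)
        v = np.array([[40.0, 10.0, 60.0]])
        mu, txy2, tz2 = 50.0, 900.0, 3600.0
        draws = np.concatenate(
            [_draw_orientations(v, mu, txy2, tz2, rng) for _ in range(4000)]
        )
        m = 200_000
        cand = rng.standard_normal((m, 3))
        cand /= np.linalg.norm(cand, axis=1, keepdims=True)
        inv = np.array([1 / txy2, 1 / txy2, 1 / tz2])
        logw = mu * cand @ (inv * v[0]) - 0.5 * mu**2 * np.sum(cand**2 * inv, axis=1)
        w = np.exp(logw - logw.max())
        ref = (cand * w[:, None]).sum(axis=0) / w.sum()
        np.testing.assert_allclose(draws.mean(axis=0), ref, atol=0.02)


class TestFitDistance:
    def test_recovery_at_moderate_noise(self):
        spec = SyntheticSpec(
            mu=50.0, sigma_xy=30 / np.sqrt(2), sigma_z=60 / np.sqrt(2),
            n_cells=20, kts_per_cell=50, seed=1,
        )
        disp = pair_displacements(
            chromatic_correct(generate_pairs(spec), "568"), "568", "488"
        )
        post = fit_distance(disp, mcmc=McmcConfig(chains=2, iterations=4000, seed=1))
        assert post.mu_ci[0] <= 50.0 <= post.mu_ci[1]
        assert abs(post.mu_mean - 50.0) < 3 * post.mu_sd
        assert post.mu_mean < np.mean(disp.norms())  # bias is removed
        assert post.converged

    def test_same_epitope_calibration_behavior(self):
        # two labels on one epitope: true separation 0; inferred distance
        # must be far below the raw biased norm and hug the boundary
        spec = SyntheticSpec(
            mu=0.0, sigma_xy=30 / np.sqrt(2), sigma_z=60 / np.sqrt(2),
            n_cells=20, kts_per_cell=100, seed=2,
        )
        disp = pair_displacements(
            chromatic_correct(generate_pairs(spec), "568"), "568", "488"
        )
        post = fit_distance(disp, mcmc=McmcConfig(chains=2, iterations=2000, seed=2))
        d3d = float(np.mean(disp.norms()))
        assert post.mu_mean < d3d / 2
        assert post.mu_ci[0] == pytest.approx(0.0, abs=2.0)

    def test_noiseless_data_concentrates_at_truth(self):
        v = displacement_sample(48.7, 1e-12, 1e-12, 200, seed=4)
        post = fit_distance(
            v,
            noise=NoiseModel(0.5, 0.5, fixed=True),
            mcmc=McmcConfig(chains=2, iterations=1500, seed=3),
        )
        assert post.mu_mean == pytest.approx(48.7, abs=0.2)
        assert post.mu_sd < 0.2

    def test_reproducible_under_seed(self):
        v = displacement_sample(40.0, 20.0, 40.0, 200, seed=9)
        cfg = McmcConfig(chains=2, iterations=800, seed=11)
        a = fit_distance(v, mcmc=cfg)
        b = fit_distance(v, mcmc=cfg)
        assert a.mu_mean == b.mu_mean
        assert a.mu_ci == b.mu_ci

    def test_all_zero_vectors_rejected(self):
        with pytest.raises(ValueError, match="degenerate"):
            fit_distance(np.zeros((50, 3)))

    def test_few_vectors_warn(self):
        v = displacement_sample(40.0, 10.0, 20.0, 8, seed=5)
        with pytest.warns(UserWarning, match="posterior will be weak"):
            fit_distance(v, mcmc=McmcConfig(chains=2, iterations=400, seed=1))


class TestDelta1d:
    def test_parallel_and_orthogonal_projection(self):
        import pandas as pd
        from kinedelta.spot_io import DisplacementSet

        vec = pd.DataFrame(
            {
                "cell_id": ["c1", "c1"],
                "kinetochore_id": ["kt1", "kt2"],
                "dx": [50.0, 0.0],
                "dy": [0.0, 30.0],
                "dz": [0.0, 0.0],
            }
        )
        disp = DisplacementSet(vec, "488", "568", corrected=True)
        axes = {"kt1": (1.0, 0.0, 0.0), "kt2": (2.0, 0.0, 0.0)}
        out = delta1d(disp, axes)
        assert out.set_index("kinetochore_id").loc["kt1", "delta1d"] == pytest.approx(50.0)
        assert out.set_index("kinetochore_id").loc["kt2", "delta1d"] == pytest.approx(0.0)

    def test_missing_sister_excluded(self):
        import pandas as pd
        from kinedelta.spot_io import DisplacementSet

        vec = pd.DataFrame(
            {"cell_id": ["c1"], "kinetochore_id": ["kt1"], "dx": [1.0],
             "dy": [0.0], "dz": [0.0]}
        )
        out = delta1d(DisplacementSet(vec, "488", "568"), {})
        assert len(out) == 0

    def test_projection_underestimates_norm_on_average(self, rng):
        import pandas as pd
        from kinedelta.spot_io import DisplacementSet

        n = 2000
        v = displacement_sample(60.0, 15.0, 30.0, n, seed=6)
        axes_arr = rng.standard_normal((n, 3))
        axes_arr /= np.linalg.norm(axes_arr, axis=1, keepdims=True)
        vec = pd.DataFrame(
            {"cell_id": "c1", "kinetochore_id": [f"kt{i}" for i in range(n)],
             "dx": v[:, 0], "dy": v[:, 1], "dz": v[:, 2]}
        )
        axes = pd.DataFrame(
            {"kinetochore_id": [f"kt{i}" for i in range(n)],
             "ax": axes_arr[:, 0], "ay": axes_arr[:, 1], "az": axes_arr[:, 2]}
        )
        out = delta1d(DisplacementSet(vec, "488", "568"), axes)
        assert np.abs(out["delta1d"]).mean() < np.linalg.norm(v, axis=1).mean()
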