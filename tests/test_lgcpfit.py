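"""Laplace-on-a-grid LGCP inference: recovery, equivariance, MCMC oracle."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import normaltest

from lgcpmap import lgcpfit as lf
from lgcpmap import spdecore as sc
from lgcpmap import synthdata as sd


def intercept_design(K):
    return sd.CovariateSet(np.ones((K, 1)), ["intercept"],
                           {"intercept": {"type": "intercept"}})


@pytest.fixture(scope="module")
def flat_fit():
    """Counts equal to a large rounded offset: no spatial signal at all."""
    grid = sd.GridSpec(sd.square_window(20.0), cell_size=1.0)
    mesh = sc.build_mesh(grid, 5.0, 15.0)
    E = np.full(grid.n_cells, 200.0)
    data = lf.ModelData(counts=np.round(E), offset=E,
                        design=intercept_design(grid.n_cells),
                        projector=sc.make_projector(mesh, grid.centroids))
    return lf.fit_lgcp(data, mesh, settings=lf.FitSettings(grid_size=5))


class TestFlatData:
    def test_intercept_near_one_and_sigma_shrunk(self, flat_fit):
        s = lf.posterior_samples(flat_fit, 4000, seed=0)
        icpt = np.exp(np.median(s.beta[:, 0]))
        assert icpt == pytest.approx(1.0, abs=0.02)
        prior_median_s2 = sc.pc_prior_sigma(sc.PriorSpec()).median ** 2
        assert np.median(s.sigma**2) < prior_median_s2

    def test_grid_weights_normalised(self, flat_fit):
        w = flat_fit.hyper.weights
        assert np.all(w >= 0)
        assert w.sum() == pytest.approx(1.0)

    def test_conditional_modes_satisfy_score_equation(self, flat_fit):
        data = flat_fit.data
        X = data.design.design
        B = sp.hstack([data.projector, sp.csr_matrix(X)]).tocsr()
        g = int(np.argmax(flat_fit.hyper.weights))
        Q = sc.spde_precision(flat_fit.mesh, sc.MaternParams(
            sigma=flat_fit.hyper.sigma[g], rho=flat_fit.hyper.rho[g]))
        P = sp.block_diag([Q, sp.identity(X.shape[1]) / 10.0]).tocsr()
        u = flat_fit.modes[g]
        mu = data.offset * np.exp(B @ u)
        grad = B.T @ (data.counts - mu) - P @ u
        assert np.max(np.abs(grad)) < 1e-6


class TestOffsetEquivariance:
    def test_scaling_offset_shifts_intercept_only(self, model_data, mesh30):
        """Multiplying E by c moves beta_0 by -log c, all else unchanged.

        The identifiable linear predictor shifts uniformly by -log c at
        every hyperparameter point; the posterior mixture attributes the
        shift to the intercept (at near-improper corner points — huge
        sigma or range — the field's constant mode can absorb part of
        it, but those points carry negligible weight).
        """
        settings = lf.FitSettings(grid_size=3)
        fit1 = lf.fit_lgcp(model_data, mesh30, settings=settings)
        c = 4.0
        data2 = lf.ModelData(counts=model_data.counts,
                             offset=c * model_data.offset,
                             design=model_data.design,
                             projector=model_data.projector)
        fit2 = lf.fit_lgcp(data2, mesh30, settings=settings)
        np.testing.assert_allclose(fit1.hyper.weights, fit2.hyper.weights,
                                   atol=1e-4)
        X = model_data.design.design
        B = sp.hstack([model_data.projector, sp.csr_matrix(X)]).tocsr()
        for m1, m2 in zip(fit1.modes, fit2.modes):
            eta_shift = B @ (m1 - m2)
            np.testing.assert_allclose(eta_shift, np.log(c), atol=5e-3)
        icpt = model_data.design.columns.index("intercept")
        M = fit1.n_field
        w = fit1.hyper.weights
        b0_shift = sum(wi * (m1 - m2)[M + icpt]
                       for wi, m1, m2 in zip(w, fit1.modes, fit2.modes))
        assert b0_shift == pytest.approx(np.log(c), abs=0.02)
        rest_shift = sum(wi * np.abs(np.delete((m1 - m2)[M:], icpt)).max()
                         for wi, m1, m2 in zip(w, fit1.modes, fit2.modes))
        assert rest_shift < 5e-3


class TestRecovery:
    def test_known_effect_recovered(self, grid30, mesh30):
        """A simulated per-SD log-RR of log 1.17 lies inside its 95% CI.

        A single-covariate scenario with a weak residual field, so the
        effect is well identified from one realisation; frequentist
        coverage across replicates is exercised separately.
        """
        from lgcpmap import standardise
        cfg = sd.ScenarioConfig(seed=2, true_rho=15.0, true_sigma=0.1,
                                national_population=400_000,
                                target_total_cases=6000)
        scen = sd.simulate_scenario(grid30, cfg,
                                    covariate_names=["radiation"],
                                    mesh=mesh30)
        rates = standardise.national_rates(scen.cases, scen.panel)
        E = standardise.expected_cases(rates, scen.panel)
        data = lf.ModelData(
            counts=scen.cases.counts_per_cell(grid30), offset=E.E,
            design=scen.covariates,
            projector=sc.make_projector(mesh30, grid30.centroids))
        fit = lf.fit_lgcp(data, mesh30, settings=lf.FitSettings(grid_size=5))
        s = lf.posterior_samples(fit, 2000, seed=11)
        b = s.beta[:, s.columns.index("radiation")]
        lo, hi = np.percentile(b, [2.5, 97.5])
        assert lo <= cfg.true_beta["radiation"] <= hi

    def test_shrinkage_under_null_field(self):
        """Data generated with sigma = 0 shrink the posterior of sigma^2."""
        grid = sd.GridSpec(sd.square_window(20.0), cell_size=1.0)
        mesh = sc.build_mesh(grid, 5.0, 15.0)
        rng = np.random.default_rng(3)
        E = np.full(grid.n_cells, 10.0)
        y = rng.poisson(E)
        data = lf.ModelData(counts=y, offset=E,
                            design=intercept_design(grid.n_cells),
                            projector=sc.make_projector(mesh, grid.centroids))
        fit = lf.fit_lgcp(data, mesh, settings=lf.FitSettings(grid_size=5))
        s = lf.posterior_samples(fit, 4000, seed=1)
        assert np.median(s.sigma**2) < sc.pc_prior_sigma(sc.PriorSpec()).median ** 2


class TestPosteriorSampling:
    def test_seed_determinism(self, adjusted_fit):
        a = lf.posterior_samples(adjusted_fit, 500, seed=9)
        b = lf.posterior_samples(adjusted_fit, 500, seed=9)
        np.testing.assert_array_equal(a.beta, b.beta)
        np.testing.assert_array_equal(a.z_cells, b.z_cells)
        c = lf.posterior_samples(adjusted_fit, 500, seed=10)
        assert not np.array_equal(a.beta, c.beta)

    def test_sample_mean_matches_mixture_mean(self, adjusted_fit):
        s = lf.posterior_samples(adjusted_fit, 10_000, seed=2)
        M = adjusted_fit.n_field
        mix_mean = sum(w * m[M:] for w, m in zip(adjusted_fit.hyper.weights,
                                                 adjusted_fit.modes))
        se = s.beta.std(axis=0) / np.sqrt(len(s) / 4)  # conservative ESS
        assert np.all(np.abs(s.beta.mean(axis=0) - mix_mean) < 3 * se + 1e-4)

    def test_single_point_grid_draws_are_gaussian(self, model_data, mesh30):
        fit = lf.fit_lgcp(model_data, mesh30,
                          settings=lf.FitSettings(grid_size=1))
        s = lf.posterior_samples(fit, 10_000, seed=4)
        i = model_data.design.columns.index("radiation")
        assert normaltest(s.beta[:, i]).pvalue > 0.01

    def test_nonpositive_draw_count_rejected(self, adjusted_fit):
        with pytest.raises(ValueError):
            lf.posterior_samples(adjusted_fit, 0)

    def test_samples_export_columns(self, adjusted_samples, tmp_path):
        import pandas as pd
        adjusted_samples.to_csv(tmp_path / "draws.csv.gz")
        back = pd.read_csv(tmp_path / "draws.csv.gz")
        assert len(back) == len(adjusted_samples)
        assert "beta[radiation]" in back.columns
        assert "sigma" in back.columns


class TestMcmcOracle:
    def test_laplace_matches_metropolis_on_tiny_instance(self):
        """Posterior means of (Z, beta) vs a long random-walk chain.

        4 cells, 9-node mesh, hyperparameters fixed at a single grid
        point; the oracle evaluates the exact unnormalised posterior
        directly and mixes through a proposal scaled to the Laplace
        covariance.  Means must agree within 3 batch-means MC SEs.
        """
        grid = sd.GridSpec(sd.square_window(2.0), cell_size=1.0)
        mesh = sc.build_mesh(grid, 1.0, 0.0)
        assert mesh.n_nodes == 9
        rng = np.random.default_rng(42)
        E = np.full(4, 200.0)
        sigma, rho = 0.3, 2.0
        Q = sc.spde_precision(mesh, sc.MaternParams(sigma=sigma, rho=rho)
                              ).toarray()
        A = sc.make_projector(mesh, grid.centroids).toarray()
        z_true = np.linalg.solve(
            np.linalg.cholesky(Q).T, rng.standard_normal(9))
        y = rng.poisson(E * np.exp(0.1 + A @ z_true)).astype(float)

        data = lf.ModelData(counts=y, offset=E, design=intercept_design(4),
                            projector=sp.csr_matrix(A))
        # prior medians placed at (sigma, rho) so the 1-point grid sits there
        u_sig = sigma * (-np.log(0.01)) / np.log(2)
        priors = sc.PriorSpec(sigma_prior=(u_sig, 0.01),
                              range_prior=(rho, 0.5))
        fit = lf.fit_lgcp(data, mesh, priors, lf.FitSettings(grid_size=1))
        assert fit.hyper.sigma[0] == pytest.approx(sigma)
        assert fit.hyper.rho[0] == pytest.approx(rho)
        mode = fit.modes[0]
        cov_lap = fit.factors[0].inv()

        # independent oracle: direct log posterior + random-walk Metropolis
        P = np.zeros((10, 10))
        P[:9, :9] = Q
        P[9, 9] = 1.0 / 10.0
        B = np.hstack([A, np.ones((4, 1))])

        def logpost(u):
            eta = B @ u
            return y @ eta - E @ np.exp(eta) - 0.5 * u @ P @ u

        prop = np.linalg.cholesky(cov_lap * (2.38**2 / 10))
        n_iter, burn = 600_000, 50_000
        u = mode.copy()
        lp = logpost(u)
        chain = np.empty((n_iter, 10))
        steps = rng.standard_normal((n_iter, 10)) @ prop.T
        logu = np.log(rng.uniform(size=n_iter))
        for i in range(n_iter):
            cand = u + steps[i]
            lpc = logpost(cand)
            if lpc - lp > logu[i]:
                u, lp = cand, lpc
            chain[i] = u
        chain = chain[burn:]
        nb = 50
        bm = chain[: (len(chain) // nb) * nb].reshape(nb, -1, 10).mean(axis=1)
        se = bm.std(0, ddof=1) / np.sqrt(nb)
        assert np.all(np.abs(mode - chain.mean(0)) < 3 * se)
        # marginal SDs agree to a few percent as well
        np.testing.assert_allclose(np.sqrt(np.diag(cov_lap)),
                                   chain.std(0, ddof=1), rtol=0.05)


class TestModelDataValidation:
    def test_negative_counts_rejected(self, mesh30, grid30):
        A = sc.make_projector(mesh30, grid30.centroids)
        with pytest.raises(ValueError):
            lf.ModelData(counts=-np.ones(grid30.n_cells),
                         offset=np.ones(grid30.n_cells),
                         design=intercept_design(grid30.n_cells), projector=A)

    def test_cases_without_offset_flagged(self, mesh30, grid30):
        A = sc.make_projector(mesh30, grid30.centroids)
        counts = np.zeros(grid30.n_cells)
        counts[0] = 3
        with pytest.warns(RuntimeWarning, match="zero expected"):
            lf.ModelData(counts=counts, offset=np.zeros(grid30.n_cells),
                         design=intercept_design(grid30.n_cells), projector=A)

    def test_all_zero_data_rejected(self, mesh30, grid30):
        A = sc.make_projector(mesh30, grid30.centroids)
        data = lf.ModelData(counts=np.zeros(grid30.n_cells),
                            offset=np.zeros(grid30.n_cells),
                            design=intercept_design(grid30.n_cells),
                            projector=A)
        with pytest.raises(ValueError):
            lf.fit_lgcp(data, mesh30)
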