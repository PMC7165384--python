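"""Areal aggregation and the Besag–York–Mollié comparator."""

import numpy as np
import pytest
import scipy.sparse as sp
from scipy.stats import spearmanr

from lgcpmap import arealbym as ab
from lgcpmap import lgcpfit as lf
from lgcpmap import posterior as po
from lgcpmap import spdecore as sc
from lgcpmap import standardise as st
from lgcpmap import synthdata as sd


class TestPartition:
    def test_blocks_cover_all_cells(self, grid30, partition30):
        assert partition30.labels.size == grid30.n_cells
        assert partition30.n_areas == 36

    def test_adjacency_symmetric_no_self_loops(self, partition30):
        W = partition30.adjacency_matrix()
        assert abs(W - W.T).max() == 0
        assert W.diagonal().max() == 0

    def test_connected(self, partition30):
        assert partition30.is_connected()

    def test_icar_structure_rank_deficiency_one(self, partition30):
        W = partition30.adjacency_matrix()
        R = np.diag(np.asarray(W.sum(axis=1)).ravel()) - W.toarray()
        rank = np.linalg.matrix_rank(R)
        assert rank == partition30.n_areas - 1


class TestAggregate:
    def test_single_area_collapses_totals(self, grid30, scenario):
        K = grid30.n_cells
        part = ab.ArealPartition(np.zeros(K, int), [], 1)
        counts = scenario.cases.counts_per_cell(grid30)
        out = ab.aggregate(counts, scenario.expected,
                           scenario.covariates.intercept_only(), part)
        assert out.counts[0] == counts.sum()
        assert out.offset[0] == pytest.approx(scenario.expected.total)

    def test_expected_counts_conserved(self, grid30, scenario, partition30):
        counts = scenario.cases.counts_per_cell(grid30)
        out = ab.aggregate(counts, scenario.expected, scenario.covariates,
                           partition30)
        assert out.offset.sum() == pytest.approx(scenario.expected.total)
        assert out.counts.sum() == counts.sum()

    def test_population_weighted_mean(self):
        design = np.column_stack([np.ones(2), [0.0, 1.0]])
        cov = sd.CovariateSet(design, ["intercept", "x"],
                              {"intercept": {"type": "intercept"},
                               "x": {"type": "continuous"}})
        part = ab.ArealPartition(np.zeros(2, int), [], 1)
        out = ab.aggregate(np.zeros(2), sd.ExpectedSurface(np.ones(2)), cov,
                           part, weights=np.array([100.0, 300.0]))
        assert out.design.design[0, 1] == pytest.approx(0.75)

    def test_modal_categorical_assignment(self):
        design = np.column_stack([np.ones(3), [1.0, 1.0, 0.0]])
        cov = sd.CovariateSet(
            design, ["intercept", "lang:French"],
            {"intercept": {"type": "intercept"},
             "lang:French": {"type": "indicator", "reference": "German",
                             "covariate": "lang"}})
        part = ab.ArealPartition(np.zeros(3, int), [], 1)
        out = ab.aggregate(np.zeros(3), sd.ExpectedSurface(np.ones(3)), cov,
                           part)
        assert out.design.design[0, 1] == 1.0  # French in 2 of 3 cells

    def test_uncovered_cells_rejected(self, scenario, grid30):
        part = ab.ArealPartition(np.zeros(4, int), [], 1)
        with pytest.raises(ValueError, match="cover"):
            ab.aggregate(np.zeros(grid30.n_cells), scenario.expected,
                         scenario.covariates, part)


@pytest.fixture(scope="module")
def bym_fit(grid30, scenario, partition30):
    counts = scenario.cases.counts_per_cell(grid30)
    rates = st.national_rates(scenario.cases, scenario.panel)
    expected = st.expected_cases(rates, scenario.panel)
    pop = scenario.panel.counts.sum(axis=(0, 1))
    areal = ab.aggregate(counts, expected,
                         scenario.covariates.intercept_only(), partition30,
                         weights=pop)
    return ab.fit_bym(areal, settings=lf.FitSettings(grid_size=5))


class TestBymFit:
    def test_sum_to_zero_on_every_draw(self, bym_fit):
        _, u, v = ab.posterior_samples_bym(bym_fit, 500, seed=3, split=True)
        assert np.abs(u.sum(axis=1)).max() < 1e-8

    def test_flat_data_shrinks_both_scales(self):
        grid = sd.GridSpec(sd.square_window(20.0), cell_size=1.0)
        part = ab.block_partition(grid, 4)
        E = np.full(part.n_areas, 100.0)
        design = sd.CovariateSet(np.ones((part.n_areas, 1)), ["intercept"],
                                 {"intercept": {"type": "intercept"}})
        areal = ab.ArealData(counts=np.round(E), offset=E, design=design,
                             partition=part)
        fit = ab.fit_bym(areal, settings=lf.FitSettings(grid_size=5))
        s = ab.posterior_samples_bym(fit, 2000, seed=5)
        prior_med = sc.PCPriorSigma(1.0, 0.01).median
        assert np.median(s.sigma) < prior_med   # structured SD
        assert np.median(s.rho) < prior_med     # unstructured SD

    def test_disconnected_graph_rejected(self):
        part = ab.ArealPartition(np.array([0, 1]), [], 2)
        design = sd.CovariateSet(np.ones((2, 1)), ["intercept"],
                                 {"intercept": {"type": "intercept"}})
        areal = ab.ArealData(counts=np.ones(2), offset=np.ones(2),
                             design=design, partition=part)
        with pytest.raises(ValueError, match="disconnected"):
            ab.fit_bym(areal)

    def test_rank_agreement_with_lgcp(self, grid30, scenario, partition30,
                                      unadjusted_samples, bym_fit):
        """Area-level posterior RR ranks agree between BYM and the LGCP."""
        bs = ab.posterior_samples_bym(bym_fit, 2000, seed=7)
        by_area = np.median(bs.z_cells, axis=0)
        lg_area = np.array([
            np.median(unadjusted_samples.z_cells[:,
                                                 partition30.labels == a
                                                 ].mean(axis=1))
            for a in range(partition30.n_areas)])
        assert spearmanr(lg_area, by_area).statistic > 0.8

    def test_fixed_effect_direction_agrees_with_lgcp(
            self, grid30, scenario, partition30, adjusted_samples):
        """Adjusted BYM recovers the sign of the strong simulated effects."""
        counts = scenario.cases.counts_per_cell(grid30)
        rates = st.national_rates(scenario.cases, scenario.panel)
        expected = st.expected_cases(rates, scenario.panel)
        pop = scenario.panel.counts.sum(axis=(0, 1))
        areal = ab.aggregate(counts, expected, scenario.covariates,
                             partition30, weights=pop)
        fit = ab.fit_bym(areal, settings=lf.FitSettings(grid_size=3))
        bs = ab.posterior_samples_bym(fit, 2000, seed=8)
        bym_fe = po.fixed_effects_table(bs).set_index("covariate")
        lgcp_fe = po.fixed_effects_table(adjusted_samples).set_index(
            "covariate")
        # compare on effects simulated well away from the null and
        # precisely estimated by the LGCP (CI excluding 1)
        for name in ("radiation", "sep"):
            lg = lgcp_fe.loc[name]
            if lg["rr_lo"] > 1.0 or lg["rr_hi"] < 1.0:
                same_side = (bym_fe.loc[name, "rr_median"] - 1.0) * (
                    lg["rr_median"] - 1.0) > 0
                assert same_side


class TestBymMcmcOracle:
    def test_laplace_matches_metropolis_on_path_graph(self):
        """4 areas in a path; Laplace vs long random-walk chain, fixed scales."""
        part = ab.ArealPartition(np.arange(4), [(0, 1), (1, 2), (2, 3)], 4)
        rng = np.random.default_rng(11)
        E = np.full(4, 150.0)
        y = rng.poisson(E * np.exp([0.1, -0.1, 0.2, 0.0])).astype(float)
        design = sd.CovariateSet(np.ones((4, 1)), ["intercept"],
                                 {"intercept": {"type": "intercept"}})
        areal = ab.ArealData(counts=y, offset=E, design=design,
                             partition=part)
        sigma_u = sigma_v = 0.3
        u_cal = sigma_u * (-np.log(0.01)) / np.log(2)
        priors = ab.BymPriors(sigma_u_prior=(u_cal, 0.01),
                              sigma_v_prior=(u_cal, 0.01))
        fit = ab.fit_bym(areal, priors, lf.FitSettings(grid_size=1))
        assert fit.hyper.sigma[0] == pytest.approx(sigma_u)
        mode, cov_lap = fit.modes[0], fit.factors[0].inv()

        # oracle: direct posterior over (w, v, beta), dim 3 + 4 + 1
        S = fit.basis
        W = part.adjacency_matrix().toarray()
        R = np.diag(W.sum(axis=1)) - W
        Pw = S.T @ R @ S / sigma_u**2
        P = np.zeros((8, 8))
        P[:3, :3] = Pw
        P[3:7, 3:7] = np.eye(4) / sigma_v**2
        P[7, 7] = 1 / 10.0
        B = np.hstack([S, np.eye(4), np.ones((4, 1))])

        def logpost(q):
            eta = B @ q
            return y @ eta - E @ np.exp(eta) - 0.5 * q @ P @ q

        prop = np.linalg.cholesky(cov_lap * (2.38**2 / 8))
        n_iter, burn = 400_000, 40_000
        q = mode.copy()
        lp = logpost(q)
        chain = np.empty((n_iter, 8))
        steps = rng.standard_normal((n_iter, 8)) @ prop.T
        logu = np.log(rng.uniform(size=n_iter))
        for i in range(n_iter):
            cand = q + steps[i]
            lpc = logpost(cand)
            if lpc - lp > logu[i]:
                q, lp = cand, lpc
            chain[i] = q
        chain = chain[burn:]
        nb = 50
        bm = chain[: (len(chain) // nb) * nb].reshape(nb, -1, 8).mean(axis=1)
        se = bm.std(0, ddof=1) / np.sqrt(nb)
        assert np.all(np.abs(mode - chain.mean(0)) < 3 * se)
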