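"""Shared fixtures: a small synthetic study and fitted models, built once."""

import numpy as np
import pytest

from lgcpmap import arealbym, lgcpfit, spdecore, standardise, synthdata


@pytest.fixture(scope="session")
def grid30():
    return synthdata.GridSpec(synthdata.square_window(30.0), cell_size=1.0)


@pytest.fixture(scope="session")
def scenario_cfg():
    # moderate field so spatial structure is identifiable on a 30 km window
    return synthdata.ScenarioConfig(
        seed=5, true_rho=15.0, true_sigma=0.25,
        national_population=400_000, target_total_cases=6000,
    )


@pytest.fixture(scope="session")
def mesh30(grid30):
    return spdecore.build_mesh(grid30, node_spacing=5.0, buffer=20.0)


@pytest.fixture(scope="session")
def scenario(grid30, scenario_cfg, mesh30):
    return synthdata.simulate_scenario(grid30, scenario_cfg, mesh=mesh30)


@pytest.fixture(scope="session")
def model_data(scenario, grid30, mesh30):
    rates = standardise.national_rates(scenario.cases, scenario.panel)
    expected = standardise.expected_cases(rates, scenario.panel)
    counts = scenario.cases.counts_per_cell(grid30)
    A = spdecore.make_projector(mesh30, grid30.centroids)
    return lgcpfit.ModelData(
        counts=counts, offset=expected.E,
        design=scenario.covariates, projector=A,
    )


@pytest.fixture(scope="session")
def adjusted_fit(model_data, mesh30):
    return lgcpfit.fit_lgcp(model_data, mesh30,
                            settings=lgcpfit.FitSettings(grid_size=5))


@pytest.fixture(scope="session")
def adjusted_samples(adjusted_fit):
    return lgcpfit.posterior_samples(adjusted_fit, 2000, seed=11)


@pytest.fixture(scope="session")
def unadjusted_fit(model_data, mesh30):
    data = lgcpfit.ModelData(
        counts=model_data.counts, offset=model_data.offset,
        design=model_data.design.intercept_only(),
        projector=model_data.projector,
    )
    return lgcpfit.fit_lgcp(data, mesh30,
                            settings=lgcpfit.FitSettings(grid_size=5))


@pytest.fixture(scope="session")
def unadjusted_samples(unadjusted_fit):
    return lgcpfit.posterior_samples(unadjusted_fit, 2000, seed=12)


@pytest.fixture(scope="session")
def partition30(grid30):
    return arealbym.block_partition(grid30, 5)


@pytest.fixture()
def rng():
    # function-scoped so Monte-Carlo checks are independent of test order
    return np.random.default_rng(1234)
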