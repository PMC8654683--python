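import numpy as np
import pytest

from abxgeo import ddd, geostat, synthetic


@pytest.fixture(scope="session")
def small_world():
    cfg = synthetic.WorldConfig(n_countries=4, cells_per_country=16,
                                n_districts_per_country=4, years=(2000, 2007),
                                n_covariates=2, income_split=0.25, seed=7)
    return synthetic.generate_world(cfg)


@pytest.fixture(scope="session")
def gp_params():
    return geostat.GPHyperparams(spatial_range=3.0, marginal_sd=0.8, ar1_rho=0.7)


@pytest.fixture(scope="session")
def usage_surface(small_world, gp_params):
    return synthetic.simulate_latent_usage(small_world, [0.5, -0.3], gp_params, seed=11)


@pytest.fixture(scope="session")
def surveys(small_world, usage_surface):
    design = synthetic.SurveyDesign(n_point_surveys=30, n_polygon_surveys=8)
    return synthetic.simulate_surveys(small_world, usage_surface, design, seed=12)


@pytest.fixture(scope="session")
def registry():
    return ddd.ATCRegistry.load("2019")


@pytest.fixture(scope="session")
def truth(small_world, registry):
    return synthetic.default_ground_truth(small_world, seed=13, registry=registry)
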