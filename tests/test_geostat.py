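"""Space-time geostatistical model: covariance construction, the Laplace
machinery against the closed-form Gaussian oracle, posterior draws and
draw-level usage estimation."""

import numpy as np
import pandas as pd
import pytest

from abxgeo import geo, geostat, synthetic


@pytest.fixture(scope="module")
def tiny_world():
    cfg = synthetic.WorldConfig(n_countries=2, cells_per_country=9,
                                n_districts_per_country=3, years=(2000, 2003),
                                n_covariates=1, income_split=0.0, seed=3)
    return synthetic.generate_world(cfg)


def _point_records(world, usage, n=120, seed=0, N=80):
    rng = np.random.default_rng(seed)
    rows = []
    for i in range(n):
        c = int(rng.integers(world.n_cells))
        t = int(rng.integers(world.n_years))
        k = int(rng.binomial(N, usage[c, t]))
        rows.append({"survey_id": f"S{i % 12}", "year": int(world.years[t]),
                     "location_type": "cell", "location": int(world.cells.index[c]),
                     "N": N, "k": k, "weight": 1.0})
    return pd.DataFrame(rows)


def test_hyperparameter_validation():
    with pytest.raises(ValueError):
        geostat.GPHyperparams(-1.0, 1.0, 0.5)
    with pytest.raises(ValueError):
        geostat.GPHyperparams(1.0, -0.1, 0.5)
    with pytest.raises(ValueError):
        geostat.GPHyperparams(1.0, 1.0, 1.0)


def test_covariance_basic_structure(tiny_world):
    hyper = geostat.GPHyperparams(spatial_range=2.0, marginal_sd=0.7, ar1_rho=0.0)
    cov = geostat.build_space_time_covariance(tiny_world, hyper)
    dense = cov.dense()
    T = tiny_world.n_years
    # same cell, same year: the marginal variance (plus tiny jitter)
    assert dense[0, 0] == pytest.approx(0.7 ** 2, rel=1e-6)
    # rho = 0: cross-year covariance exactly zero
    assert dense[0, 1] == 0.0
    assert dense[0, T + 1] == 0.0  # different cell, different year
    # correlation at the range distance is 0.1 by the range convention
    assert geostat.matern_correlation(np.array([2.0]), 2.0, 1.0)[0] == pytest.approx(0.1, abs=1e-9)


def test_matern_large_nu_approaches_squared_exponential():
    d = np.linspace(0, 5.0, 200)
    rng_dist = 2.0
    m = geostat.matern_correlation(d, rng_dist, nu=50.0)
    se = np.exp(np.log(0.1) * (d / rng_dist) ** 2)  # SE with corr(range)=0.1
    assert np.max(np.abs(m - se)) < 0.01


def test_size_cap_enforced(small_world):
    big = geostat.GPHyperparams(1.0, 1.0, 0.5)
    cfg = synthetic.WorldConfig(n_countries=5, cells_per_country=81,
                                n_districts_per_country=3, years=(2000, 2001),
                                n_covariates=1, income_split=0.0, seed=0)
    world = synthetic.generate_world(cfg)
    with pytest.raises(ValueError, match="capped"):
        geostat.build_space_time_covariance(world, big)


def test_laplace_matches_gaussian_process_oracle(tiny_world):
    """Under a Gaussian likelihood the Laplace machinery is exact, so it must
    reproduce closed-form GP regression through an independent formula."""
    world = tiny_world
    hyper = geostat.GPHyperparams(spatial_range=2.5, marginal_sd=0.9, ar1_rho=0.6)
    rng = np.random.default_rng(1)
    n = 40
    cells = rng.integers(world.n_cells, size=n)
    tpos = rng.integers(world.n_years, size=n)
    y = rng.normal(0, 1, n)
    s2 = 0.3 ** 2
    recs = pd.DataFrame({"survey_id": "S0", "year": world.years[tpos],
                         "location_type": "cell",
                         "location": world.cells.index.to_numpy()[cells],
                         "N": 1, "k": 0, "weight": 1.0, "y": y})
    X_data = world.covariates[cells, tpos, :]
    X_grid = world.covariates.reshape(-1, 1)
    fit = geostat.fit(recs, X_data, X_grid, world, hyper_grid=[hyper],
                      family="gaussian", gauss_var=s2, refine_rounds=0)
    eta_fit = X_grid @ fit.beta_mean + fit.z_mean[fit.n_beta:]

    # oracle: joint Gaussian conditioning on eta = X beta + w
    cov = geostat.build_space_time_covariance(world, hyper)
    Sw = cov.dense()
    idx = cells * world.n_years + tpos
    B = geostat.BETA_PRIOR_SD ** 2
    C_dd = X_data @ (B * X_data.T) + Sw[np.ix_(idx, idx)]
    C_gd = X_grid @ (B * X_data.T) + Sw[:, idx]
    oracle = C_gd @ np.linalg.solve(C_dd + s2 * np.eye(n), y)
    assert np.max(np.abs(eta_fit - oracle)) < 1e-6


def test_fixed_effect_recovery_without_latent_field(tiny_world):
    # strong signal simulated with zero process variance: beta recovered
    # within 3 posterior sd and the flattest grid point selected
    world = tiny_world
    beta = np.array([1.2])
    flat = geostat.GPHyperparams(1.0, 0.0, 0.0)
    usage = synthetic.simulate_latent_usage(world, beta, flat, seed=5)
    recs = _point_records(world, usage, n=150, seed=6, N=150)
    X = world.covariates[world.cell_position(recs["location"].to_numpy()),
                         world.year_index(recs["year"].to_numpy()), :]
    grid = [geostat.GPHyperparams(2.0, sd, 0.3) for sd in (0.05, 0.3, 1.0)]
    fit = geostat.fit(recs, X, world.covariates.reshape(-1, 1), world,
                      hyper_grid=grid, refine_rounds=0)
    assert abs(fit.beta_mean[0] - 1.2) < 3 * fit.beta_sd[0]
    assert fit.hyper.marginal_sd == 0.05
    # the selected point is the exhaustive grid argmax
    t = fit.grid_table
    assert t.loc[t["log_marginal"].idxmax(), "marginal_sd"] == fit.hyper.marginal_sd


def test_more_data_shrinks_beta_posterior(tiny_world):
    world = tiny_world
    beta = np.array([0.8])
    flat = geostat.GPHyperparams(1.0, 0.0, 0.0)
    usage = synthetic.simulate_latent_usage(world, beta, flat, seed=7)
    hyper = [geostat.GPHyperparams(2.0, 0.3, 0.3)]
    X_grid = world.covariates.reshape(-1, 1)

    def posterior_sd(scale):
        recs = _point_records(world, usage, n=100, seed=8, N=50)
        recs["N"] *= scale
        recs["k"] *= scale
        X = world.covariates[world.cell_position(recs["location"].to_numpy()),
                             world.year_index(recs["year"].to_numpy()), :]
        return geostat.fit(recs, X, X_grid, world, hyper_grid=hyper,
                           refine_rounds=0).beta_sd[0]

    assert posterior_sd(2) < posterior_sd(1)


@pytest.fixture(scope="module")
def small_fit(tiny_world):
    world = tiny_world
    gp = geostat.GPHyperparams(2.0, 0.6, 0.5)
    usage = synthetic.simulate_latent_usage(world, [0.5], gp, seed=9)
    recs = _point_records(world, usage, n=100, seed=10)
    X = world.covariates[world.cell_position(recs["location"].to_numpy()),
                         world.year_index(recs["year"].to_numpy()), :]
    return geostat.fit(recs, X, world.covariates.reshape(-1, 1), world,
                       hyper_grid=[gp], refine_rounds=0)


def test_draws_deterministic_and_bounded(small_fit):
    d1 = geostat.draw_posterior(small_fit, n_draws=5, seed=3)
    d2 = geostat.draw_posterior(small_fit, n_draws=5, seed=3)
    assert np.array_equal(d1.draws, d2.draws)
    assert np.all((d1.draws > 0) & (d1.draws < 1))


def test_draw_mean_consistent_with_laplace_mean(small_fit):
    eta_draws = geostat.linear_predictor_draws(small_fit, n_draws=8000, seed=4)
    eta_mean = small_fit.X_grid @ small_fit.beta_mean + small_fit.z_mean[small_fit.n_beta:]
    mc_se = eta_draws.std(axis=0) / np.sqrt(len(eta_draws))
    assert np.all(np.abs(eta_draws.mean(axis=0) - eta_mean) < 3.5 * mc_se + 1e-9)


def test_estimate_usage_degenerate_and_convexity(tiny_world, small_fit):
    world = tiny_world
    # degenerate draws: identical surfaces give zero-width intervals
    flat = np.full((4, world.n_cells, world.n_years), 0.42)
    est, report = geostat.estimate_usage(geostat.PosteriorDraws(flat, seed=0), world)
    assert np.allclose(est["upper"] - est["lower"], 0.0)
    assert np.allclose(report["deviation_range"], 0.0)
    # national mean lies within the envelope of its districts in every draw
    draws = geostat.draw_posterior(small_fit, n_draws=30, seed=5)
    d_ids, d_agg = geo.aggregate_draws(draws.draws, world, "district")
    c_ids, c_agg = geo.aggregate_draws(draws.draws, world, "country")
    country_of = world.cells.groupby("district_id")["country"].first()
    for ci, c in enumerate(c_ids):
        members = [i for i, d in enumerate(d_ids) if country_of[d] == c]
        assert np.all(c_agg[:, ci, :] <= d_agg[:, members, :].max(axis=1) + 1e-12)
        assert np.all(c_agg[:, ci, :] >= d_agg[:, members, :].min(axis=1) - 1e-12)


def test_estimate_usage_region_fill(tiny_world, small_fit):
    draws = geostat.draw_posterior(small_fit, n_draws=20, seed=6)
    nodata = [tiny_world.countries.index[0]]
    est, _ = geostat.estimate_usage(draws, tiny_world, nodata_countries=nodata)
    filled = est[(est["level"] == "country") & (est["unit_id"] == nodata[0])]
    assert filled["imputed"].all()
    assert filled["mean"].notna().all()
    assert filled["lower"].isna().all()  # imputed national values carry no UI


def test_polygon_records_rejected_by_fit(tiny_world):
    recs = pd.DataFrame([{"survey_id": "S0", "year": 2000,
                          "location_type": "district",
                          "location": tiny_world.units("district")[0],
                          "N": 10, "k": 5, "weight": 1.0}])
    with pytest.raises(ValueError, match="resample"):
        geostat.fit(recs, np.zeros((1, 1)), np.zeros((tiny_world.n_cells
                                                      * tiny_world.n_years, 1)),
                    tiny_world, hyper_grid=[geostat.GPHyperparams(1.0, 0.5, 0.0)])
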