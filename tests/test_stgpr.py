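"""Consumption track: national feature assembly, stage-1 stacking,
GP smoothing limits and track combination."""

import numpy as np
import pandas as pd
import pytest

from abxgeo import ddd, geo, stgpr, synthetic


@pytest.fixture(scope="module")
def cons_world():
    cfg = synthetic.WorldConfig(n_countries=12, cells_per_country=4,
                                n_districts_per_country=2, years=(2000, 2009),
                                n_covariates=2, income_split=0.25,
                                countries_per_region=3, seed=21)
    return synthetic.generate_world(cfg)


@pytest.fixture(scope="module")
def features(cons_world):
    rng = np.random.default_rng(0)
    usage = np.clip(rng.uniform(0.2, 0.8, (cons_world.n_cells, cons_world.n_years)),
                    1e-3, 1 - 1e-3)
    ids, agg = geo.aggregate_draws(usage[None], cons_world, "country")
    usage_country = geo.summarise_draws(ids, agg, cons_world.years)
    return stgpr.build_national_features(cons_world, usage_country)


def test_feature_table_shape_and_join(cons_world, features):
    lmic = cons_world.lmic_countries()
    assert len(features) == len(lmic) * cons_world.n_years
    assert set(features["country"]) == set(lmic)
    # single-cell aggregation sanity: a country's national covariate equals
    # the population-weighted mean of its cells (exact for one cell)
    natcov = cons_world.national_covariates()
    merged = features.merge(natcov, on=["country", "year"], suffixes=("", "_direct"))
    for name in cons_world.covariate_names:
        assert np.allclose(merged[name], merged[f"{name}_direct"])


def test_missing_usage_raises(cons_world):
    empty = pd.DataFrame({"unit_id": [], "year": [], "mean": []})
    with pytest.raises(ValueError):
        stgpr.build_national_features(cons_world, empty)


def test_stage1_recovers_noiseless_log_linear_rates(features):
    rng = np.random.default_rng(1)
    cols = [c for c in features.columns if c not in ("country", "year")]
    X = features[cols].to_numpy(float)
    Xs = (X - X.mean(0)) / X.std(0)
    log_rate = np.log(12.0) + Xs @ np.array([0.4, -0.2, 0.3])[:Xs.shape[1]]
    obs = features[["country", "year"]].copy()
    obs["ddd_per_1000_per_day"] = np.exp(log_rate)
    table, result, weights = stgpr.stage1(features, obs, seed=0)
    r2 = 1 - np.sum((table["log_mean"] - log_rate) ** 2) / np.sum(
        (log_rate - log_rate.mean()) ** 2)
    assert r2 >= 0.95
    assert weights.sum() == pytest.approx(1.0, abs=1e-12)
    assert np.isfinite(np.exp(table["log_mean"])).all()
    assert (np.exp(table["log_mean"]) > 0).all()


def test_stage1_needs_two_countries(features):
    one = features[features["country"] == features["country"].iloc[0]]
    obs = one[["country", "year"]].assign(ddd_per_1000_per_day=10.0)
    with pytest.raises(ValueError):
        stgpr.stage1(features, obs)


def _stage1_table(features, log_mean):
    t = features[["country", "year"]].copy()
    t["log_mean"] = log_mean
    return t


def test_smooth_zero_amplitude_returns_prior(cons_world, features):
    s1 = _stage1_table(features, np.log(10.0))
    obs = features[["country", "year"]].iloc[:5].assign(ddd_per_1000_per_day=20.0)
    params = stgpr.STGPRParams(amplitude=0.0, n_draws=50, seed=0)
    out = stgpr.stgpr_smooth(s1, obs, cons_world, params)
    assert np.allclose(out.table["mean"], 10.0)
    assert np.allclose(out.table["upper"] - out.table["lower"], 0.0)


def test_smooth_interpolates_observations_as_nugget_vanishes(cons_world, features):
    rng = np.random.default_rng(3)
    s1 = _stage1_table(features, np.log(10.0))
    sel = features.sample(8, random_state=1)[["country", "year"]]
    obs = sel.assign(ddd_per_1000_per_day=np.exp(rng.normal(np.log(14), 0.2, len(sel))))
    params = stgpr.STGPRParams(amplitude=0.5, nugget_sd=1e-7, n_draws=10, seed=0)
    out = stgpr.stgpr_smooth(s1, obs, cons_world, params)
    merged = obs.merge(out.table, on=["country", "year"])
    # exact conditioning drives the posterior mean of the latent log rate to
    # the observation as the nugget vanishes
    assert np.allclose(merged["log_mean_post"],
                       np.log(merged["ddd_per_1000_per_day"]), atol=1e-6)


def test_smooth_unobserved_country_pooling(cons_world, features):
    # a country with no observations keeps its prior when lambda=0 and is
    # pulled toward its region's residual pattern when lambda>0
    s1 = _stage1_table(features, np.log(10.0))
    target = features["country"].iloc[0]
    region = cons_world.countries.loc[target, "region"]
    peers = [c for c in features["country"].unique()
             if c != target and cons_world.countries.loc[c, "region"] == region]
    obs = features[features["country"].isin(peers)][["country", "year"]]
    obs = obs.assign(ddd_per_1000_per_day=20.0)  # peers sit above the prior
    base = stgpr.STGPRParams(amplitude=0.4, region_pooling_weight=0.0,
                             n_draws=10, seed=0)
    out0 = stgpr.stgpr_smooth(s1, obs, cons_world, base)
    t0 = out0.table[out0.table["country"] == target]
    assert np.allclose(t0["log_mean_post"], np.log(10.0), atol=1e-8)
    pooled = stgpr.STGPRParams(amplitude=0.4, region_pooling_weight=0.5,
                               n_draws=10, seed=0)
    out1 = stgpr.stgpr_smooth(s1, obs, cons_world, pooled)
    t1 = out1.table[out1.table["country"] == target]
    assert (t1["log_mean_post"].to_numpy() > np.log(10.0) + 0.05).all()


def test_smooth_no_observations_warns(cons_world, features):
    s1 = _stage1_table(features, np.log(10.0))
    empty = features[["country", "year"]].iloc[:0].assign(ddd_per_1000_per_day=[])
    with pytest.warns(UserWarning):
        out = stgpr.stgpr_smooth(s1, empty, cons_world,
                                 stgpr.STGPRParams(n_draws=10, seed=0))
    assert np.allclose(out.table["mean"], 10.0)


def _constant_result(features, cons_world, rate, n_draws=20):
    lmic = sorted(features["country"].unique())
    index = features[["country", "year"]].reset_index(drop=True)
    draws = np.full((n_draws, len(index)), rate)
    table = index.copy()
    table["mean"] = rate
    table["lower"] = rate
    table["upper"] = rate
    return stgpr.STGPRResult(table=table, draws=draws, index=index, amplitude=0.0)


def test_combine_tracks_weighted_mean_and_volumes(cons_world, features):
    world = cons_world
    # equal populations everywhere for an analytic global rate
    world.population[:] = 100.0
    lmic_res = _constant_result(features, world, 10.0)
    hic = world.hic_countries()
    rows = [{"country": c, "year": int(y), "ddd_per_1000_per_day": 20.0}
            for c in hic for y in world.years]
    country_table, summary = stgpr.combine_tracks(lmic_res, pd.DataFrame(rows), world)
    n_l, n_h = len(world.lmic_countries()), len(hic)
    expect = (10.0 * n_l + 20.0 * n_h) / (n_l + n_h)
    glob = summary[summary["scope"] == "global"]
    assert np.allclose(glob["rate"], expect, atol=1e-9)
    # global volume is exactly the sum of country volumes
    for y in world.years:
        total = country_table.loc[country_table["year"] == y, "volume_ddd"].sum()
        assert glob.loc[glob["year"] == y, "volume_ddd"].iloc[0] == pytest.approx(
            total, rel=1e-12)
    # rate -> volume -> rate round trip
    r = country_table.iloc[0]
    assert ddd.rate(r["volume_ddd"], r["population"]) == pytest.approx(
        r["mean"], abs=1e-12)
    # HIC rows carry no uncertainty interval; LMIC rows are ordered
    hic_rows = country_table[country_table["track"] == "HIC"]
    assert hic_rows[["lower", "upper"]].isna().all().all()
    lmic_rows = country_table[country_table["track"] == "LMIC"]
    assert (lmic_rows["lower"] <= lmic_rows["mean"] + 1e-12).all()
    assert (lmic_rows["mean"] <= lmic_rows["upper"] + 1e-12).all()


def test_combine_tracks_rejects_bad_partition(cons_world, features):
    lmic_res = _constant_result(features, cons_world, 10.0)
    # overlap: a LMIC country also appears in the HIC table
    bad = pd.DataFrame([{"country": features["country"].iloc[0], "year": 2000,
                         "ddd_per_1000_per_day": 20.0}])
    with pytest.raises(ValueError):
        stgpr.combine_tracks(lmic_res, bad, cons_world)


def test_cross_validate_deterministic(cons_world, features):
    rng = np.random.default_rng(4)
    obs = features[["country", "year"]].copy()
    cols = [c for c in features.columns if c not in ("country", "year")]
    X = features[cols].to_numpy(float)
    obs["ddd_per_1000_per_day"] = np.exp(
        np.log(12) + 0.3 * (X[:, 0] - X[:, 0].mean()) + rng.normal(0, 0.15, len(X)))
    obs = obs[rng.random(len(obs)) < 0.7]
    params = stgpr.STGPRParams(n_draws=40)
    a = stgpr.cross_validate(features, obs, cons_world, params=params,
                             n_folds=4, seed=5)
    b = stgpr.cross_validate(features, obs, cons_world, params=params,
                             n_folds=4, seed=5)
    pd.testing.assert_frame_equal(a, b)
    assert (a["n_test"] > 0).all()
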