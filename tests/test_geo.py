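"""Survey preparation and aggregation: largest-remainder apportionment,
polygon resampling conservation, draw-level aggregation and deviation
statistics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abxgeo import geo, synthetic


def _record(loc_type, loc, N, k, year=2000):
    return pd.DataFrame([{"survey_id": "S0", "year": year, "location_type": loc_type,
                          "location": loc, "N": N, "k": k, "weight": 1.0}])


def test_largest_remainder_exact_example():
    assert geo.largest_remainder(40, np.array([0.25, 0.75])).tolist() == [10, 30]
    assert geo.largest_remainder(20, np.array([10.0, 30.0])).tolist() == [5, 15]


@given(total=st.integers(0, 10_000),
       shares=st.lists(st.floats(0.01, 100.0), min_size=1, max_size=8))
@settings(max_examples=200, deadline=None, derandomize=True)
def test_largest_remainder_sums_exactly(total, shares):
    out = geo.largest_remainder(total, np.array(shares))
    assert out.sum() == total
    assert (out >= 0).all()


def test_split_record_enforces_k_le_n():
    N_i, k_i = geo._split_record(10, 10, np.array([0.05, 0.95]))
    assert N_i.sum() == 10 and k_i.sum() == 10
    assert (k_i <= N_i).all()


def test_resample_single_cell_polygon_identity(small_world):
    # a polygon containing one populated cell resolves to that cell exactly
    one_cell = small_world.cells.index[0]
    district = small_world.cells.loc[one_cell, "district_id"]
    world = small_world
    rec = _record("district", district, 37, 12)
    # force a single point by a huge population quantum
    out = geo.resample_polygon_records(rec, world, quantum=1e12, seed=0)
    assert len(out) == 1
    assert out.iloc[0]["N"] == 37 and out.iloc[0]["k"] == 12
    assert out.iloc[0]["location_type"] == "cell"
    assert world.cells.loc[out.iloc[0]["location"], "district_id"] == district


def test_resample_two_cluster_arithmetic(small_world):
    # two far-apart populated cells, pops 100 and 300: N=40,k=20 splits 10/30, 5/15
    world = small_world
    district = world.units("district")[0]
    mask = (world.cells["district_id"] == district).to_numpy()
    pop = world.population.copy()
    pop[mask] = 0.0
    cells_in = np.flatnonzero(mask)
    pop[cells_in[0], :] = 100.0
    pop[cells_in[-1], :] = 300.0
    w2 = geo.GeoFrame(cells=world.cells, countries=world.countries, years=world.years,
                      population=pop, covariates=world.covariates,
                      covariate_names=world.covariate_names)
    out = geo.resample_polygon_records(_record("district", district, 40, 20), w2,
                                       quantum=200.0, seed=0)
    got = sorted(zip(out["N"], out["k"]))
    assert got == [(10, 5), (30, 15)]


def test_resample_conserves_counts(small_world, surveys):
    out = geo.resample_polygon_records(surveys, small_world, seed=1)
    assert out["N"].sum() == surveys["N"].sum()
    assert out["k"].sum() == surveys["k"].sum()
    assert (out["k"] <= out["N"]).all()
    # per-record conservation for each polygon record
    poly = surveys[surveys["location_type"] != "cell"]
    for _, rec in poly.iterrows():
        sub = out[out["survey_id"] == rec["survey_id"]]
        assert sub["N"].sum() == rec["N"]
        assert sub["k"].sum() == rec["k"]


def test_resample_points_stay_in_polygon_bbox(small_world, surveys):
    out = geo.resample_polygon_records(surveys, small_world, seed=1)
    poly = surveys[surveys["location_type"] == "district"]
    for _, rec in poly.iterrows():
        members = small_world.cells[small_world.cells["district_id"] == rec["location"]]
        placed = out[out["survey_id"] == rec["survey_id"]]["location"]
        coords = small_world.cells.loc[placed, ["x", "y"]]
        assert coords["x"].between(members["x"].min(), members["x"].max()).all()
        assert coords["y"].between(members["y"].min(), members["y"].max()).all()


def test_resample_zero_population_polygon_errors(small_world):
    district = small_world.units("district")[0]
    pop = small_world.population.copy()
    pop[(small_world.cells["district_id"] == district).to_numpy()] = 0.0
    w2 = geo.GeoFrame(cells=small_world.cells, countries=small_world.countries,
                      years=small_world.years, population=pop,
                      covariates=small_world.covariates)
    with pytest.raises(geo.UnplaceableRecordError) as err:
        geo.resample_polygon_records(_record("district", district, 10, 5), w2, seed=0)
    assert district in str(err.value)


def test_aggregate_weighted_mean_example(small_world):
    # two cells with pops 100/300 and values 0.2/0.6 aggregate to 0.5
    pop = np.zeros_like(small_world.population)
    country = small_world.countries.index[0]
    cells_in = np.flatnonzero((small_world.cells["country"] == country).to_numpy())
    pop[cells_in[0]] = 100.0
    pop[cells_in[1]] = 300.0
    w2 = geo.GeoFrame(cells=small_world.cells, countries=small_world.countries,
                      years=small_world.years, population=pop,
                      covariates=small_world.covariates)
    vals = np.zeros((1, small_world.n_cells, small_world.n_years))
    vals[0, cells_in[0]] = 0.2
    vals[0, cells_in[1]] = 0.6
    ids, agg = geo.aggregate_draws(vals, w2, "country")
    assert agg[0, ids.index(country), 0] == pytest.approx(0.5, abs=1e-12)
    # countries with zero population flagged NaN, never zero
    other = [i for i, u in enumerate(ids) if u != country]
    assert np.isnan(agg[0, other, :]).all()


def test_aggregate_constant_field_and_linearity(small_world):
    rng = np.random.default_rng(0)
    const = np.full((3, small_world.n_cells, small_world.n_years), 0.37)
    ids, agg = geo.aggregate_draws(const, small_world, "state")
    assert np.allclose(agg, 0.37)
    draws = rng.uniform(0, 1, (20, small_world.n_cells, small_world.n_years))
    ids, agg = geo.aggregate_draws(draws, small_world, "district")
    _, agg_mean = geo.aggregate_draws(draws.mean(axis=0, keepdims=True), small_world,
                                      "district")
    assert np.allclose(agg.mean(axis=0), agg_mean[0], atol=1e-12)


def test_aggregation_idempotent_across_levels(small_world):
    rng = np.random.default_rng(1)
    draws = rng.uniform(0, 1, (5, small_world.n_cells, small_world.n_years))
    c_ids, direct = geo.aggregate_draws(draws, small_world, "country")
    d_ids, by_district = geo.aggregate_draws(draws, small_world, "district")
    dpop = np.stack([small_world.population[
        (small_world.cells["district_id"] == d).to_numpy()].sum(axis=0) for d in d_ids])
    country_of = small_world.cells.groupby("district_id")["country"].first()
    for ci, c in enumerate(c_ids):
        members = [i for i, d in enumerate(d_ids) if country_of[d] == c]
        num = (by_district[:, members, :] * dpop[members][None]).sum(axis=1)
        redone = num / dpop[members].sum(axis=0)[None, :]
        assert np.allclose(redone, direct[:, ci, :], atol=1e-10)


def test_relative_deviation_examples():
    d, r = geo.relative_deviation([0.4, 0.6], 0.5)
    assert np.allclose(d, [-0.2, 0.2]) and r == pytest.approx(0.4)
    d, r = geo.relative_deviation([0.5, 0.5, 0.5], 0.5)
    assert np.allclose(d, 0) and r == 0
    with pytest.raises(ValueError):
        geo.relative_deviation([0.4], 0.0)


def test_relative_deviation_scale_invariance():
    ests = np.array([0.2, 0.45, 0.61])
    d1, r1 = geo.relative_deviation(ests, 0.4)
    d2, r2 = geo.relative_deviation(ests * 7.3, 0.4 * 7.3)
    assert np.allclose(d1, d2, atol=1e-12) and r1 == pytest.approx(r2, abs=1e-12)


def test_region_median_fill(small_world):
    countries = list(small_world.countries.index)
    est = pd.Series(np.nan, index=countries)
    region = small_world.countries["region"]
    # give every country but one an estimate; the odd/even median conventions
    target = countries[0]
    peers = [c for c in countries if region[c] == region[target] and c != target]
    est[peers] = 0.5
    others = [c for c in countries if region[c] != region[target]]
    est[others] = np.linspace(0.3, 0.7, len(others))
    filled, imputed = geo.region_median_fill(est, small_world)
    assert filled[target] == pytest.approx(pd.Series(0.5, index=peers).median())
    assert imputed[target] and not imputed[peers].any()
    # no missing countries: unchanged
    filled2, imputed2 = geo.region_median_fill(filled, small_world)
    pd.testing.assert_series_equal(filled2, filled)
    assert not imputed2.any()


def test_region_median_fill_even_count_convention(small_world):
    region = small_world.countries["region"]
    # all countries of one region missing -> error
    est = pd.Series(np.nan, index=small_world.countries.index)
    est[region == region.iloc[0]] = np.nan
    with pytest.raises(ValueError):
        geo.region_median_fill(est, small_world)


def test_geoframe_roundtrip(tmp_path, small_world):
    small_world.save(tmp_path / "w")
    back = geo.GeoFrame.load(tmp_path / "w")
    assert np.allclose(back.population, small_world.population)
    assert np.allclose(back.covariates, small_world.covariates)
    assert list(back.cells["district_id"]) == list(small_world.cells["district_id"])
    small_world.to_geojson(tmp_path / "w.geojson")
    import json
    gj = json.loads((tmp_path / "w.geojson").read_text())
    assert len(gj["features"]) == small_world.n_cells
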