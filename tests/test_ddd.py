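"""ATC/DDD conversion chain: unit arithmetic, registry versioning,
aggregation additivity and the brute-force oracle."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from abxgeo import ddd


@pytest.fixture(scope="module")
def pre2019():
    return ddd.ATCRegistry.load("pre-2019")


def _sales_frame(rows):
    return pd.DataFrame(rows, columns=ddd.SALES_COLUMNS)


def test_filter_j01():
    recs = _sales_frame([
        {"country": "A", "year": 2000, "atc": "J01CA04", "route": "oral",
         "sector": "retail", "unit": "kg", "quantity": 1.0, "mg_per_su": np.nan},
        {"country": "A", "year": 2000, "atc": "A07AA09", "route": "oral",
         "sector": "retail", "unit": "kg", "quantity": 1.0, "mg_per_su": np.nan},
        {"country": "A", "year": 2000, "atc": "J01MA02", "route": "oral",
         "sector": "retail", "unit": "kg", "quantity": 1.0, "mg_per_su": np.nan}])
    kept, dropped = ddd.filter_j01(recs)
    assert list(kept["atc"]) == ["J01CA04", "J01MA02"] and dropped == 1
    kept, dropped = ddd.filter_j01(recs.iloc[:0])
    assert kept.empty and dropped == 0
    all_j01 = recs[recs["atc"].str.startswith("J01")].reset_index(drop=True)
    kept, dropped = ddd.filter_j01(all_j01)
    pd.testing.assert_frame_equal(kept, all_j01)
    assert dropped == 0


def test_su_to_kg_arithmetic():
    assert ddd.su_to_kg(1000, 500) == pytest.approx(0.5)
    assert ddd.su_to_kg(0, 875) == 0.0
    assert ddd.su_to_kg(2_000_000, 875) == pytest.approx(1750.0)
    with pytest.raises(ddd.ConversionError):
        ddd.su_to_kg(10, np.nan)


def test_kg_to_ddd(registry):
    # amoxicillin oral DDD is 1.5 g in the 2019 index: 3 kg -> 2000 DDD
    assert ddd.kg_to_ddd(3.0, "J01CA04", "oral", registry) == pytest.approx(2000.0)
    assert ddd.kg_to_ddd(0.0, "J01CA04", "oral", registry) == 0.0
    with pytest.raises(ddd.RegistryError):
        ddd.kg_to_ddd(1.0, "J01ZZ99", "oral", registry)
    with pytest.raises(ddd.ConversionError):
        ddd.kg_to_ddd(1.0, "J01DB04", "oral", registry)  # cefazolin has no oral DDD


def test_registry_version_monotonicity(registry, pre2019):
    # the 2019 index raised amoxicillin's DDD: same mass, strictly fewer DDD
    kg = 12.34
    assert (ddd.kg_to_ddd(kg, "J01CA04", "oral", registry)
            < ddd.kg_to_ddd(kg, "J01CA04", "oral", pre2019))
    # and a raised DDD can never raise a country's total
    recs = _sales_frame([{"country": "A", "year": 2010, "atc": c, "route": "unknown",
                          "sector": "retail", "unit": "kg", "quantity": 5.0,
                          "mg_per_su": np.nan} for c in registry.codes])
    t_new = ddd.country_year_totals(recs, registry)["ddd_total"].iloc[0]
    t_old = ddd.country_year_totals(recs, pre2019)["ddd_total"].iloc[0]
    assert t_new <= t_old


def test_unknown_route_resolves_via_default(registry):
    e = registry["J01CA04"]
    assert e.ddd_grams("unknown") == e.ddd_grams(e.default_route)


def test_rate_and_volume():
    assert ddd.rate(7_300_000, 1_000_000) == pytest.approx(20.0)
    assert ddd.rate(0, 5) == 0.0
    assert ddd.rate(100.0, 2000.0) == pytest.approx(ddd.rate(100.0, 1000.0) / 2)
    with pytest.raises(ValueError):
        ddd.rate(1.0, 0)
    # rate <-> volume round trip
    for r in (0.3, 14.3, 45.9):
        pop = 1_234_567.0
        assert ddd.rate(ddd.volume(r, pop), pop) == pytest.approx(r, abs=1e-12)


def test_totals_additivity_and_sectors(registry):
    rows = [
        {"country": "A", "year": 2005, "atc": "J01CA04", "route": "oral",
         "sector": "retail", "unit": "DDD", "quantity": 100.0, "mg_per_su": np.nan},
        {"country": "A", "year": 2005, "atc": "J01MA02", "route": "oral",
         "sector": "hospital", "unit": "DDD", "quantity": 200.0, "mg_per_su": np.nan}]
    out = ddd.country_year_totals(_sales_frame(rows), registry)
    assert out["ddd_total"].iloc[0] == pytest.approx(300.0)
    assert out["sectors_present"].iloc[0] == frozenset({"hospital", "retail"})


@given(split=st.floats(0.01, 0.99), qty=st.floats(0.1, 1000.0))
@settings(max_examples=50, deadline=None, derandomize=True)
def test_totals_invariant_to_record_splitting(split, qty, registry):
    base = {"country": "A", "year": 2010, "atc": "J01FA10", "route": "oral",
            "sector": "retail", "unit": "kg", "mg_per_su": np.nan}
    whole = _sales_frame([{**base, "quantity": qty}])
    parts = _sales_frame([{**base, "quantity": qty * split},
                          {**base, "quantity": qty * (1 - split)}])
    t1 = ddd.country_year_totals(whole, registry)["ddd_total"].iloc[0]
    t2 = ddd.country_year_totals(parts, registry)["ddd_total"].iloc[0]
    assert t2 == pytest.approx(t1, rel=1e-9)


def test_country_year_totals_matches_bruteforce_oracle(registry):
    # independent record-by-record literal arithmetic on 1000 random records
    rng = np.random.default_rng(42)
    codes = registry.codes
    rows = []
    for _ in range(1000):
        code = codes[rng.integers(len(codes))]
        entry = registry[code]
        route = entry.default_route if rng.random() < 0.5 else "unknown"
        unit = ["SU", "kg", "DDD"][rng.integers(3)]
        rows.append({"country": f"C{rng.integers(5)}", "year": int(2000 + rng.integers(19)),
                     "atc": code, "route": route,
                     "sector": ["hospital", "retail"][rng.integers(2)], "unit": unit,
                     "quantity": float(rng.uniform(0, 1e6)),
                     "mg_per_su": float(rng.uniform(50, 1000)) if unit == "SU" else np.nan})
    recs = _sales_frame(rows)
    got = ddd.country_year_totals(recs, registry)

    oracle: dict = {}
    for r in rows:
        e = registry[r["atc"]]
        g = e.ddd_grams_oral if (r["route"] if r["route"] != "unknown"
                                 else e.default_route) == "oral" else e.ddd_grams_parenteral
        if r["unit"] == "DDD":
            val = r["quantity"]
        elif r["unit"] == "kg":
            val = r["quantity"] * 1000.0 / g
        else:
            val = (r["quantity"] * r["mg_per_su"] / 1e6) * 1000.0 / g
        oracle[(r["country"], r["year"])] = oracle.get((r["country"], r["year"]), 0.0) + val
    for _, row in got.iterrows():
        assert row["ddd_total"] == pytest.approx(oracle[(row["country"], row["year"])],
                                                 rel=1e-12)
    assert len(got) == len(oracle)


def test_totals_reject_unfiltered_records(registry):
    recs = _sales_frame([{"country": "A", "year": 2000, "atc": "A07AA09",
                          "route": "oral", "sector": "retail", "unit": "kg",
                          "quantity": 1.0, "mg_per_su": np.nan}])
    with pytest.raises(ddd.ConversionError):
        ddd.country_year_totals(recs, registry)


def test_registry_csv_roundtrip(tmp_path, registry):
    path = tmp_path / "reg.csv"
    rows = []
    for code in registry.codes:
        e = registry[code]
        rows.append({"atc_code": e.atc_code, "name": e.name,
                     "ddd_g_oral": e.ddd_grams_oral,
                     "ddd_g_parenteral": e.ddd_grams_parenteral, "atc3": e.atc3_class,
                     "atc4_select": e.select_atc4_class, "aware": e.aware_category,
                     "default_route": e.default_route})
    pd.DataFrame(rows).to_csv(path, index=False)
    back = ddd.ATCRegistry.from_csv(path)
    assert back.codes == registry.codes
    assert back["J01DD04"].class_label == "J01DD"
    assert back.aware_map()["J01DD"] == "Watch"
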