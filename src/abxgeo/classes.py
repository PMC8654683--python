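"""Allocation of total consumption to antibiotic classes and AWaRe groups.

Class proportions come from the cleaned (pre-imputation) sales records:
per country-year, each allocation class's share of the total DDD. For
country-years without input data, DDD-weighted GBD-region proportions are
substituted (sum the member countries' class DDD, then normalise — not a
mean of proportions). The proportions are applied to the *mean* total
consumption estimate only, so class-level tables carry no uncertainty
intervals; AWaRe (Access/Watch/Reserve) tables are the coarser partition
obtained through the registry's class-to-AWaRe map.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .ddd import ATCRegistry
from .geo import GeoFrame


def compute_proportions(totals: pd.DataFrame) -> pd.DataFrame:
    """Observed class proportions per country-year.

    ``totals`` is the output of :func:`abxgeo.ddd.country_year_totals`
    (pre-imputation) with its ``class_ddd`` dict column. Country-years
    with zero total yield no row (they fall back to the region).
    """
    rows = []
    for _, r in totals.iterrows():
        class_ddd = r["class_ddd"]
        if any(v < 0 for v in class_ddd.values()):
            raise ValueError(f"negative class subtotal for {r['country']} {r['year']}")
        tot = sum(class_ddd.values())
        if tot <= 0:
            continue
        for cls, v in sorted(class_ddd.items()):
            rows.append({"country": r["country"], "year": int(r["year"]), "class": cls,
                         "proportion": v / tot, "class_ddd": v, "basis": "country-observed"})
    return pd.DataFrame(rows, columns=["country", "year", "class", "proportion",
                                       "class_ddd", "basis"])


def region_fallback(proportions: pd.DataFrame, geo: GeoFrame,
                    countries: list | None = None,
                    years: list | None = None) -> pd.DataFrame:
    """Complete the proportions table for all requested country-years.

    Region proportions are DDD-weighted: the member countries' class DDD
    are summed and normalised. Year-specific region proportions are used
    when the region has data in that year, otherwise the region's
    all-years pool. Observed country-years pass through unchanged.
    """
    region_of = geo.countries["region"]
    countries = list(countries) if countries is not None else sorted(region_of.index)
    years = list(years) if years is not None else sorted(proportions["year"].unique())
    observed = {(c, y) for c, y in zip(proportions["country"], proportions["year"])}
    out = [proportions]
    for c in countries:
        region = region_of[c]
        members = set(region_of.index[region_of == region])
        reg_rows = proportions[proportions["country"].isin(members)]
        if reg_rows.empty:
            raise ValueError(f"region {region!r} has no observed country-year")
        for y in years:
            if (c, y) in observed:
                continue
            pool = reg_rows[reg_rows["year"] == y]
            if pool.empty:
                pool = reg_rows
            ddd = pool.groupby("class")["class_ddd"].sum()
            props = ddd / ddd.sum()
            out.append(pd.DataFrame({
                "country": c, "year": int(y), "class": props.index,
                "proportion": props.to_numpy(), "class_ddd": np.nan,
                "basis": "region-fallback"}))
    return pd.concat(out, ignore_index=True)


def allocate(estimates: pd.DataFrame, proportions: pd.DataFrame,
             registry: ATCRegistry):
    """Split mean total rates into class-level and AWaRe-level tables.

    ``estimates`` holds one row per country-year with a ``mean`` rate
    column (the combined-track table). Returns
    ``(class_table, aware_table)``; both partition the total mean rate.
    """
    aware_of = registry.aware_map()
    unmapped = set(proportions["class"]) - set(aware_of)
    if unmapped:
        raise KeyError(f"classes missing from the AWaRe map: {sorted(unmapped)}")
    est = estimates.rename(columns={"unit_id": "country"})
    merged = est[["country", "year", "mean"]].merge(
        proportions, on=["country", "year"], how="left")
    if merged["proportion"].isna().any():
        miss = merged.loc[merged["proportion"].isna(), ["country", "year"]].drop_duplicates()
        raise ValueError(f"no class proportions for country-years:\n{miss}")
    merged["rate"] = merged["mean"] * merged["proportion"]
    class_table = merged[["country", "year", "class", "rate", "basis"]].copy()
    aw = class_table.copy()
    aw["aware"] = aw["class"].map(aware_of)
    aware_table = (aw.groupby(["country", "year", "aware"], as_index=False)["rate"].sum())
    return class_table, aware_table
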