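"""ATC/DDD conversion engine.

Turns heterogeneous sales and surveillance records into country-year totals
of systemic-antibiotic (ATC J01) consumption, expressed in defined daily
doses (DDD) and as DDD per 1000 population per day, under a versioned
ATC/DDD registry.

The registry is user data, not code: two editable CSV snapshots
("pre-2019" and "2019") ship with the package covering common J01 codes
with route-specific DDD values, AWaRe categories and default routes. The
2019 index raised the DDD for several antibiotics (e.g. oral amoxicillin
1.0 g -> 1.5 g), so the same mass yields fewer DDD under it.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from importlib import resources

import numpy as np
import pandas as pd

#: Divisor for a DDD rate: DDD per 1000 per day uses a 365-day year by
#: convention; leap-year differences (<0.3%) are ignored.
DAYS_IN_YEAR = 365.0

ATC_PATTERN = re.compile(r"^[A-Z]\d\d[A-Z]{2}\d\d$")

SALES_COLUMNS = ["country", "year", "atc", "route", "sector", "unit", "quantity", "mg_per_su"]


class RegistryError(KeyError):
    pass


class ConversionError(ValueError):
    pass


@dataclass(frozen=True)
class ATCEntry:
    atc_code: str
    name: str
    ddd_grams_oral: float | None
    ddd_grams_parenteral: float | None
    atc3_class: str
    select_atc4_class: str | None
    aware_category: str
    default_route: str

    def __post_init__(self):
        if not ATC_PATTERN.match(self.atc_code):
            raise ValueError(f"malformed ATC code {self.atc_code!r}")
        if self.ddd_grams_oral is None and self.ddd_grams_parenteral is None:
            raise ValueError(f"{self.atc_code}: at least one route DDD required")
        for v in (self.ddd_grams_oral, self.ddd_grams_parenteral):
            if v is not None and v <= 0:
                raise ValueError(f"{self.atc_code}: DDD values must be positive")

    @property
    def class_label(self) -> str:
        """Allocation class: the selected ATC-4 class if configured, else ATC-3."""
        return self.select_atc4_class or self.atc3_class

    def ddd_grams(self, route: str) -> float:
        """Grams per DDD for a route; ``unknown`` resolves via default_route."""
        if route == "unknown":
            route = self.default_route
        g = {"oral": self.ddd_grams_oral, "parenteral": self.ddd_grams_parenteral}.get(route)
        if g is None:
            raise ConversionError(f"{self.atc_code}: no DDD value for route {route!r}")
        return g


class ATCRegistry:
    """Versioned lookup of J01 ATC entries and their DDD values."""

    def __init__(self, entries: dict[str, ATCEntry], version: str = "custom"):
        self.entries = dict(entries)
        self.version = version

    def __contains__(self, code):
        return code in self.entries

    def __getitem__(self, code) -> ATCEntry:
        try:
            return self.entries[code]
        except KeyError:
            raise RegistryError(f"ATC code {code!r} not in registry {self.version!r}")

    @property
    def codes(self) -> list[str]:
        return sorted(self.entries)

    def class_vocabulary(self) -> list[str]:
        return sorted({e.class_label for e in self.entries.values()})

    def aware_map(self) -> dict[str, str]:
        """class label -> AWaRe category (classes must map consistently)."""
        out: dict[str, str] = {}
        for e in self.entries.values():
            prev = out.setdefault(e.class_label, e.aware_category)
            if prev != e.aware_category:
                out[e.class_label] = "Mixed"
        return out

    @classmethod
    def from_frame(cls, df: pd.DataFrame, version: str = "custom") -> "ATCRegistry":
        entries = {}
        for _, r in df.iterrows():
            entries[r["atc_code"]] = ATCEntry(
                atc_code=r["atc_code"], name=r["name"],
                ddd_grams_oral=None if pd.isna(r["ddd_g_oral"]) else float(r["ddd_g_oral"]),
                ddd_grams_parenteral=None if pd.isna(r["ddd_g_parenteral"]) else float(r["ddd_g_parenteral"]),
                atc3_class=r["atc3"],
                select_atc4_class=None if pd.isna(r.get("atc4_select")) else r["atc4_select"] or None,
                aware_category=r["aware"], default_route=r["default_route"])
        return cls(entries, version)

    @classmethod
    def from_csv(cls, path, version: str = "custom") -> "ATCRegistry":
        return cls.from_frame(pd.read_csv(path), version)

    @classmethod
    def load(cls, version: str = "2019") -> "ATCRegistry":
        """Load a packaged registry snapshot, ``"pre-2019"`` or ``"2019"``."""
        fname = {"2019": "atc_registry_2019.csv", "pre-2019": "atc_registry_pre2019.csv"}
        if version not in fname:
            raise RegistryError(f"unknown registry version {version!r}")
        with resources.files("abxgeo.data").joinpath(fname[version]).open() as fh:
            return cls.from_frame(pd.read_csv(fh), version)


# ---------------------------------------------------------------------------
# Record-level conversions
# ---------------------------------------------------------------------------

def filter_j01(records: pd.DataFrame) -> tuple[pd.DataFrame, int]:
    """Keep systemic antibiotics (ATC codes starting with J01).

    Returns the filtered frame and the number of dropped records.
    """
    keep = records["atc"].astype(str).str.startswith("J01")
    return records[keep].reset_index(drop=True), int((~keep).sum())


def su_to_kg(quantity_su: float, mg_per_su: float) -> float:
    """Standard units (single doses) times strength to kilograms of substance."""
    if not np.isfinite(mg_per_su) or mg_per_su <= 0:
        raise ConversionError("SU record without positive mg_per_su strength")
    return quantity_su * mg_per_su / 1e6


def kg_to_ddd(kg: float, atc_code: str, route: str, registry: ATCRegistry) -> float:
    """Kilograms of active substance to defined daily doses."""
    return kg * 1000.0 / registry[atc_code].ddd_grams(route)


def record_ddd(rec, registry: ATCRegistry) -> float:
    """DDD content of one sales record, whatever its unit."""
    unit = rec["unit"]
    if unit == "DDD":
        return float(rec["quantity"])
    if unit == "SU":
        kg = su_to_kg(float(rec["quantity"]), float(rec["mg_per_su"]))
    elif unit == "kg":
        kg = float(rec["quantity"])
    else:
        raise ConversionError(f"unknown unit {unit!r} for record {rec.to_dict()}")
    return kg_to_ddd(kg, rec["atc"], rec["route"], registry)


# ---------------------------------------------------------------------------
# Country-year aggregation
# ---------------------------------------------------------------------------

def country_year_totals(records: pd.DataFrame, registry: ATCRegistry) -> pd.DataFrame:
    """Aggregate J01 sales records to one consumption value per country-year.

    Returns a frame with one row per (country, year):
    ``ddd_total``, ``ddd_hospital``, ``ddd_retail``, ``sectors_present``
    (frozenset), plus a ``class_ddd`` dict column of per-class subtotals
    (selected ATC-4 classes kept separate, everything else at ATC-3) for
    downstream class allocation.
    """
    recs = records.copy()
    if (~recs["atc"].astype(str).str.startswith("J01")).any():
        raise ConversionError("country_year_totals expects J01-filtered records")
    recs["ddd"] = [record_ddd(r, registry) for _, r in recs.iterrows()]
    recs["class_label"] = [registry[a].class_label for a in recs["atc"]]
    rows = []
    for (country, year), g in recs.groupby(["country", "year"], sort=True):
        by_sector = g.groupby("sector")["ddd"].sum()
        rows.append({
            "country": country, "year": int(year),
            "ddd_total": float(g["ddd"].sum()),
            "ddd_hospital": float(by_sector.get("hospital", 0.0)),
            "ddd_retail": float(by_sector.get("retail", 0.0)),
            "sectors_present": frozenset(g["sector"].unique()),
            "class_ddd": g.groupby("class_label")["ddd"].sum().to_dict(),
        })
    return pd.DataFrame(rows)


def rate(ddd_total: float, population: float) -> float:
    """DDD per 1000 population per day from an annual DDD total."""
    if population <= 0:
        raise ValueError("population must be positive")
    return ddd_total / population / DAYS_IN_YEAR * 1000.0


def volume(rate_per_1000_day: float, population: float) -> float:
    """Inverse of :func:`rate`: annual DDD volume from a rate."""
    return rate_per_1000_day * population * DAYS_IN_YEAR / 1000.0


def attach_rates(totals: pd.DataFrame, country_pop: pd.DataFrame) -> pd.DataFrame:
    """Add ``population`` and ``ddd_per_1000_per_day`` columns to totals."""
    out = totals.copy()
    out["population"] = [country_pop.loc[c, y] for c, y in zip(out["country"], out["year"])]
    out["ddd_per_1000_per_day"] = [rate(d, p) for d, p in zip(out["ddd_total"], out["population"])]
    return out
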