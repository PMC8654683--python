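"""Geographic data preparation.

Holds the admin-hierarchy container (:class:`GeoFrame`), polygon-to-point
resampling of survey records, population-weighted draw-level aggregation,
the within-country relative-deviation statistic, and region-median filling
of countries without estimates.

Survey records are kept as a plain :class:`pandas.DataFrame` with columns
``survey_id, year, location_type, location, N, k, weight`` where
``location_type`` is ``"cell"`` for point-referenced records and
``"district"`` / ``"state"`` for polygon-referenced ones.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.cluster import KMeans

SURVEY_COLUMNS = ["survey_id", "year", "location_type", "location", "N", "k", "weight"]

ADMIN_LEVELS = ("district", "state", "country")


class UnplaceableRecordError(ValueError):
    """Polygon survey records referencing areas with zero population."""

    def __init__(self, records):
        self.records = list(records)
        super().__init__(
            f"{len(self.records)} polygon record(s) reference areas with zero "
            f"population and cannot be resampled: {self.records}"
        )


@dataclass
class GeoFrame:
    """Grid cells with populations, covariates and a full admin hierarchy.

    Attributes
    ----------
    cells:
        One row per grid cell, indexed by integer ``cell_id``, with columns
        ``x, y`` (planar coordinates of the cell centre) and the membership
        columns ``district_id, state_id, country``.
    countries:
        One row per country, indexed by country code, with columns
        ``region, super_region, income_class`` (``income_class`` in
        ``{"HIC", "LMIC"}``).
    years:
        Sorted integer year vector of the study frame.
    population:
        ``(n_cells, n_years)`` non-negative array.
    covariates:
        ``(n_cells, n_years, n_covariates)`` array of covariate surfaces.
    """

    cells: pd.DataFrame
    countries: pd.DataFrame
    years: np.ndarray
    population: np.ndarray
    covariates: np.ndarray
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self):
        self.years = np.asarray(self.years, dtype=int)
        if self.years.size == 0:
            raise ValueError("year range must be non-empty")
        if np.any(self.population < 0):
            raise ValueError("populations must be non-negative")
        if self.population.shape != (self.n_cells, self.n_years):
            raise ValueError("population shape must be (n_cells, n_years)")
        missing = set(self.cells["country"]) - set(self.countries.index)
        if missing:
            raise ValueError(f"cells reference unknown countries: {sorted(missing)}")

    # -- basic accessors -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return len(self.cells)

    @property
    def n_years(self) -> int:
        return len(self.years)

    @property
    def n_covariates(self) -> int:
        return self.covariates.shape[2]

    @property
    def coords(self) -> np.ndarray:
        return self.cells[["x", "y"]].to_numpy(float)

    def year_index(self, year) -> np.ndarray:
        idx = np.searchsorted(self.years, year)
        if np.any(self.years[np.clip(idx, 0, self.n_years - 1)] != year):
            raise KeyError(f"year(s) outside study frame: {year}")
        return idx

    def cell_position(self, cell_id) -> np.ndarray:
        """Positional index of ``cell_id`` within the cell table."""
        return self.cells.index.get_indexer(np.atleast_1d(cell_id))

    def membership(self, level: str) -> pd.Series:
        """Cell -> admin-unit id at ``level`` in {district, state, country}."""
        col = {"district": "district_id", "state": "state_id", "country": "country"}[level]
        return self.cells[col]

    def units(self, level: str) -> list:
        return sorted(self.membership(level).unique())

    def hic_countries(self) -> list:
        return sorted(self.countries.index[self.countries["income_class"] == "HIC"])

    def lmic_countries(self) -> list:
        return sorted(self.countries.index[self.countries["income_class"] == "LMIC"])

    def country_population(self) -> pd.DataFrame:
        """Country x year population totals (countries as index)."""
        mem = self.cells["country"].to_numpy()
        out = {}
        for c in self.countries.index:
            out[c] = self.population[mem == c].sum(axis=0)
        return pd.DataFrame(out, index=self.years).T

    def national_covariates(self) -> pd.DataFrame:
        """Population-weighted national covariate means, one row per country-year."""
        mem = self.cells["country"].to_numpy()
        rows = []
        for c in self.countries.index:
            m = mem == c
            pop = self.population[m]  # (cells_c, years)
            cov = self.covariates[m]  # (cells_c, years, n_cov)
            tot = pop.sum(axis=0)
            w = np.where(tot > 0, tot, np.nan)
            means = np.einsum("ct,ctk->tk", pop, cov) / w[:, None]
            for j, year in enumerate(self.years):
                rows.append({"country": c, "year": int(year),
                             **{name: means[j, i] for i, name in enumerate(self.covariate_names)}})
        return pd.DataFrame(rows)

    # -- I/O --------------------------------------------------------------
    def save(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        self.cells.rename_axis("cell_id").to_csv(d / "world.csv")
        self.countries.rename_axis("country").to_csv(d / "countries.csv")
        pop = pd.DataFrame(self.population, index=self.cells.index, columns=self.years)
        pop.rename_axis("cell_id").to_csv(d / "population.csv")
        rows = []
        for i, name in enumerate(self.covariate_names):
            df = pd.DataFrame(self.covariates[:, :, i], index=self.cells.index, columns=self.years)
            long = df.rename_axis("cell_id").reset_index().melt("cell_id", var_name="year", value_name="value")
            long["covariate"] = name
            rows.append(long)
        pd.concat(rows).to_csv(d / "covariates.csv", index=False)

    @classmethod
    def load(cls, directory) -> "GeoFrame":
        d = Path(directory)
        cells = pd.read_csv(d / "world.csv", index_col="cell_id")
        countries = pd.read_csv(d / "countries.csv", index_col="country")
        pop = pd.read_csv(d / "population.csv", index_col="cell_id")
        years = np.array([int(y) for y in pop.columns])
        cov_long = pd.read_csv(d / "covariates.csv")
        names = sorted(cov_long["covariate"].unique())
        cov = np.zeros((len(cells), len(years), len(names)))
        for i, name in enumerate(names):
            sub = cov_long[cov_long["covariate"] == name].pivot(
                index="cell_id", columns="year", values="value")
            cov[:, :, i] = sub.loc[cells.index, years].to_numpy()
        return cls(cells=cells, countries=countries, years=years,
                   population=pop.to_numpy(float), covariates=cov, covariate_names=names)

    def to_geojson(self, path, cell_size: float = 1.0) -> None:
        """Write cells as unit-square polygon features (planar lattice)."""
        import json

        h = cell_size / 2.0
        feats = []
        for cid, row in self.cells.iterrows():
            x, y = row["x"], row["y"]
            ring = [[x - h, y - h], [x + h, y - h], [x + h, y + h], [x - h, y + h], [x - h, y - h]]
            feats.append({
                "type": "Feature",
                "properties": {"cell_id": int(cid), "district_id": row["district_id"],
                               "state_id": row["state_id"], "country": row["country"]},
                "geometry": {"type": "Polygon", "coordinates": [ring]},
            })
        Path(path).write_text(json.dumps({"type": "FeatureCollection", "features": feats}))


# ---------------------------------------------------------------------------
# Largest-remainder apportionment
# ---------------------------------------------------------------------------

def largest_remainder(total: int, shares: np.ndarray) -> np.ndarray:
    """Split integer ``total`` proportionally to ``shares``.

    Uses Hamilton's largest-remainder rule; ties in the fractional part are
    broken by lower index. The result sums to ``total`` exactly.
    """
    shares = np.asarray(shares, float)
    if shares.sum() <= 0:
        raise ValueError("shares must have positive sum")
    quota = total * shares / shares.sum()
    base = np.floor(quota).astype(int)
    short = int(total - base.sum())
    if short:
        frac = quota - base
        # argsort is stable: equal remainders resolve to the lower index
        order = np.argsort(-frac, kind="stable")
        base[order[:short]] += 1
    return base


def _split_record(N: int, k: int, pop_shares: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Apportion (N, k) over clusters; k_i <= N_i enforced by donating to the
    largest-N cluster."""
    N_i = largest_remainder(int(N), pop_shares)
    if N_i.sum() > 0:
        k_i = largest_remainder(int(k), N_i.astype(float))
    else:
        k_i = np.zeros_like(N_i)
    over = k_i - N_i
    while np.any(over > 0):
        j = int(np.argmax(over))
        surplus = int(over[j])
        k_i[j] -= surplus
        recipients = np.flatnonzero(N_i - k_i > 0)
        order = recipients[np.argsort(-N_i[recipients], kind="stable")]
        for r in order:
            room = int(N_i[r] - k_i[r])
            give = min(room, surplus)
            k_i[r] += give
            surplus -= give
            if surplus == 0:
                break
        over = k_i - N_i
    return N_i, k_i


def resample_polygon_records(records: pd.DataFrame, geo: GeoFrame, *,
                             quantum: float = 500.0, max_points: int = 10,
                             seed: int = 0) -> pd.DataFrame:
    """Resample polygon-referenced survey records to point (cell) locations.

    Polygon records are converted with population-weighted K-means on the
    member cells' centre coordinates; each centroid is snapped to the nearest
    member cell (ties to the lowest cell id), and the record's ``N`` and
    ``k`` are apportioned to the points proportionally to cluster population
    shares with largest-remainder rounding, conserving both sums exactly.

    The number of points is ``clamp(round(pop / quantum), 1, max_points)``
    (also bounded by the number of populated member cells).
    """
    rng = np.random.default_rng(seed)
    point_rows = []
    bad = []
    for idx, rec in records.iterrows():
        if rec["location_type"] == "cell":
            point_rows.append(rec.to_dict())
            continue
        level = rec["location_type"]
        mask = (geo.membership(level) == rec["location"]).to_numpy()
        if not mask.any():
            raise KeyError(f"unknown {level} code {rec['location']!r}")
        yi = int(geo.year_index(int(rec["year"])))
        pops = geo.population[mask, yi]
        if pops.sum() <= 0:
            bad.append((rec["survey_id"], rec["location"]))
            continue
        coords = geo.coords[mask]
        cell_ids = geo.cells.index.to_numpy()[mask]
        populated = pops > 0
        k_pts = int(np.clip(round(pops.sum() / quantum), 1, min(max_points, populated.sum())))
        if k_pts == 1 or populated.sum() == 1:
            labels = np.zeros(mask.sum(), dtype=int)
            centres = [np.average(coords, axis=0, weights=pops)]
        else:
            km = KMeans(n_clusters=k_pts, init="k-means++", n_init=10,
                        random_state=int(rng.integers(2**31)))
            labels = km.fit_predict(coords, sample_weight=pops)
            centres = km.cluster_centers_
        cluster_pop = np.array([pops[labels == c].sum() for c in range(len(centres))])
        keep = cluster_pop > 0
        centres = np.asarray(centres)[keep]
        cluster_pop = cluster_pop[keep]
        kept_clusters = np.flatnonzero(keep)
        N_i, k_i = _split_record(rec["N"], rec["k"], cluster_pop / cluster_pop.sum())
        for c, centre in enumerate(centres):
            members = labels == kept_clusters[c]
            d = np.linalg.norm(coords[members] - centre, axis=1)
            cand = cell_ids[members]
            # ties broken by lowest cell id (stable argsort on (d, id))
            best = cand[np.lexsort((cand, d))[0]]
            if N_i[c] == 0:
                continue
            point_rows.append({"survey_id": rec["survey_id"], "year": rec["year"],
                               "location_type": "cell", "location": int(best),
                               "N": int(N_i[c]), "k": int(k_i[c]),
                               "weight": rec.get("weight", 1.0)})
    if bad:
        raise UnplaceableRecordError(bad)
    return pd.DataFrame(point_rows, columns=SURVEY_COLUMNS)


# ---------------------------------------------------------------------------
# Draw-level aggregation
# ---------------------------------------------------------------------------

def aggregate_draws(cell_draws: np.ndarray, geo: GeoFrame, level: str):
    """Population-weighted aggregation of cell-level draws to admin units.

    Aggregation happens at the draw level: for every draw and year, the
    admin-unit value is the population-weighted mean over member cells.
    Summaries (means, intervals) are computed *after* aggregation so that
    uncertainty is preserved.

    Parameters
    ----------
    cell_draws:
        ``(n_draws, n_cells, n_years)`` array.
    level:
        One of ``district``, ``state``, ``country``.

    Returns
    -------
    (unit_ids, draws) where ``draws`` is ``(n_draws, n_units, n_years)``.
    Admin unit-years with zero population come back as NaN, never silently 0.
    """
    if level not in ADMIN_LEVELS:
        raise ValueError(f"level must be one of {ADMIN_LEVELS}")
    cell_draws = np.asarray(cell_draws, float)
    mem = geo.membership(level).to_numpy()
    unit_ids = sorted(pd.unique(mem))
    M = np.stack([(mem == u) for u in unit_ids]).astype(float)  # (units, cells)
    wpop = M[:, :, None] * geo.population[None, :, :]           # (units, cells, years)
    denom = wpop.sum(axis=1)                                    # (units, years)
    num = np.einsum("dct,uct->dut", cell_draws, wpop)
    with np.errstate(invalid="ignore", divide="ignore"):
        out = num / denom[None, :, :]
    out[:, denom == 0] = np.nan
    return unit_ids, out


def summarise_draws(unit_ids, draws: np.ndarray, years, level: str = "",
                    alpha: float = 0.05) -> pd.DataFrame:
    """Mean and percentile 95% UI per admin-unit-year from a draw array."""
    mean = draws.mean(axis=0)
    lower = np.quantile(draws, alpha / 2, axis=0)
    upper = np.quantile(draws, 1 - alpha / 2, axis=0)
    rows = []
    for i, u in enumerate(unit_ids):
        for j, y in enumerate(years):
            rows.append({"unit_id": u, "year": int(y), "mean": mean[i, j],
                         "lower": lower[i, j], "upper": upper[i, j]})
    df = pd.DataFrame(rows)
    if level:
        df["level"] = level
    return df


# ---------------------------------------------------------------------------
# Relative deviation and region-median fill
# ---------------------------------------------------------------------------

def relative_deviation(district_estimates, national_estimate: float):
    """Within-country deviation of each district from the national estimate.

    ``d_i = (district_i - national) / national``; the national summary is the
    range ``max(d) - min(d)``, a unit-free measure of subnational inequality.
    """
    if national_estimate <= 0:
        raise ValueError("national estimate must be positive")
    d = (np.asarray(district_estimates, float) - national_estimate) / national_estimate
    if isinstance(district_estimates, pd.Series):
        d = pd.Series(d, index=district_estimates.index)
    return d, float(np.max(d) - np.min(d))


def region_median_fill(national_estimates: pd.Series, geo: GeoFrame):
    """Fill countries without estimates with their region's median estimate.

    Returns the completed series plus a boolean flag series marking imputed
    entries. Raises if a country's region has no estimated member.
    """
    regions = geo.countries["region"]
    est = national_estimates.dropna()
    filled = national_estimates.reindex(geo.countries.index).copy()
    imputed = pd.Series(False, index=filled.index)
    for c in filled.index[filled.isna()]:
        peers = est.index.intersection(regions.index[regions == regions[c]])
        if len(peers) == 0:
            raise ValueError(f"no estimated country in region {regions[c]!r} to fill {c!r}")
        filled[c] = float(est.loc[peers].median())
        imputed[c] = True
    return filled, imputed
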