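"""Synthetic miniature world with known ground truth.

Generates a small planar lattice world — contiguous country blocks split
into states and districts, with smooth covariate surfaces and populations —
plus the three data streams the estimation pipeline consumes:

* household-survey records of children with lower-respiratory-tract
  infection symptoms and whether they received an antibiotic, point- or
  polygon-referenced, drawn Binomial(N, p) from a latent usage surface;
* national sales records (country-year-ATC-route-sector quantities) in
  mixed units — standard units with product strength for early years,
  kilograms later — that invert exactly through the DDD engine back to the
  ground-truth consumption rates before missingness is applied;
* the admin hierarchy itself with per-year populations and covariates.

The latent usage surface is simulated with the *same* Matérn x AR1
covariance constructor the geostatistical model fits with, so the
generative model and the inferential model agree by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import geo as geo_mod
from .ddd import ATCRegistry, volume
from .geostat import GPHyperparams, build_space_time_covariance


@dataclass
class WorldConfig:
    n_countries: int = 8
    cells_per_country: int = 16
    n_districts_per_country: int = 4
    n_states_per_country: int = 2
    years: tuple[int, int] = (2000, 2018)
    n_covariates: int = 3
    income_split: float = 0.25
    countries_per_region: int = 2
    regions_per_super_region: int = 2
    seed: int = 0

    def __post_init__(self):
        for name in ("n_countries", "cells_per_country", "n_districts_per_country",
                     "n_states_per_country", "n_covariates"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive count")
        if self.years[1] < self.years[0]:
            raise ValueError("year range must be non-empty")
        if not 0 <= self.income_split <= 1:
            raise ValueError("income_split must be a fraction")
        if self.n_districts_per_country > self.cells_per_country:
            raise ValueError("more districts than cells")

    @property
    def year_array(self) -> np.ndarray:
        return np.arange(self.years[0], self.years[1] + 1)


@dataclass
class SurveyDesign:
    n_point_surveys: int = 30
    n_polygon_surveys: int = 10
    N_range: tuple[int, int] = (20, 200)
    clusters_per_point_survey: int = 10
    clusters_per_polygon: int = 5  # polygon records aggregate >= 5 latent clusters


@dataclass
class MissingnessDesign:
    retail_only_frac: float = 0.0
    missing_year_frac: float = 0.0


@dataclass
class GroundTruth:
    """Everything the pipeline tries to estimate, held exactly."""

    beta: np.ndarray
    gp_params: GPHyperparams
    usage_surface: np.ndarray                 # (n_cells, n_years) in (0, 1)
    national_consumption: pd.DataFrame        # country x year, DDD/1000/day
    class_mix: pd.DataFrame                   # country x class, rows sum to 1
    sector_split: pd.Series                   # hospital fraction per country

    def __post_init__(self):
        if np.any(self.usage_surface <= 0) or np.any(self.usage_surface >= 1):
            raise ValueError("usage surface must lie strictly in (0, 1)")
        if not np.allclose(self.class_mix.sum(axis=1), 1.0, atol=1e-12):
            raise ValueError("class_mix rows must sum to 1")
        if ((self.sector_split < 0) | (self.sector_split > 1)).any():
            raise ValueError("sector_split must lie in [0, 1]")


# ---------------------------------------------------------------------------
# World generation
# ---------------------------------------------------------------------------

def _block_shape(cells: int) -> tuple[int, int]:
    h = int(np.sqrt(cells))
    while cells % h:
        h -= 1
    return h, cells // h


def _smooth_field(x, y, rng, n_waves: int = 4, freq_scale: float = 0.35):
    """Sum of low-frequency cosines: smooth noise on the lattice."""
    out = np.zeros_like(x)
    for _ in range(n_waves):
        kx, ky = rng.normal(0, freq_scale, 2)
        phase = rng.uniform(0, 2 * np.pi)
        out += rng.normal(0, 1) * np.cos(kx * x + ky * y + phase)
    return out / np.sqrt(n_waves)


def generate_world(config: WorldConfig) -> geo_mod.GeoFrame:
    """Build the admin hierarchy, populations and covariate surfaces.

    Countries are contiguous rectangular blocks of grid cells on a shared
    lattice, arranged in a near-square grid of blocks and split into
    contiguous states and districts. Covariates are fixed low-order
    spatial polynomials plus smooth cosine noise with a linear year trend,
    standardised over cell-years. The ``floor(income_split * n_countries)``
    countries with the highest mean simulated covariate value are labelled
    high-income (deterministic floor rule).
    """
    rng = np.random.default_rng(config.seed)
    H, W = _block_shape(config.cells_per_country)
    ncols = int(np.ceil(np.sqrt(config.n_countries)))
    rows = []
    for c in range(config.n_countries):
        bx, by = (c % ncols) * W, (c // ncols) * H
        name = f"C{c:02d}"
        for j in range(H):
            for i in range(W):
                rows.append({"x": bx + i + 0.5, "y": by + j + 0.5, "country": name})
    cells = pd.DataFrame(rows)
    cells.index.name = "cell_id"
    # contiguous districts and states within each country block
    district, state = [], []
    for c in range(config.n_countries):
        name = f"C{c:02d}"
        members = cells.index[cells["country"] == name]
        chunks = np.array_split(np.asarray(members), config.n_districts_per_country)
        d_of_state = np.array_split(np.arange(config.n_districts_per_country),
                                    min(config.n_states_per_country,
                                        config.n_districts_per_country))
        state_of_district = {}
        for s, ds in enumerate(d_of_state):
            for d in ds:
                state_of_district[d] = s
        for d, chunk in enumerate(chunks):
            for _ in chunk:
                district.append(f"{name}-D{d}")
                state.append(f"{name}-S{state_of_district[d]}")
    cells["district_id"] = district
    cells["state_id"] = state

    years = config.year_array
    T = len(years)
    x, y = cells["x"].to_numpy(), cells["y"].to_numpy()
    xs = (x - x.mean()) / max(x.std(), 1e-9)
    ys = (y - y.mean()) / max(y.std(), 1e-9)

    base_pop = 200.0 * np.exp(0.5 * _smooth_field(x, y, rng))
    growth = rng.uniform(0.005, 0.02)
    population = base_pop[:, None] * (1 + growth) ** np.arange(T)[None, :]

    tt = (np.arange(T) - (T - 1) / 2) / max(T - 1, 1)
    cov = np.zeros((len(cells), T, config.n_covariates))
    names = [f"cov{i}" for i in range(config.n_covariates)]
    for i in range(config.n_covariates):
        a = rng.normal(0, 1, 5)
        spatial = a[0] * xs + a[1] * ys + a[2] * xs ** 2 + a[3] * xs * ys \
            + _smooth_field(x, y, rng)
        slope = rng.normal(0, 0.5)
        surf = spatial[:, None] + slope * tt[None, :]
        cov[:, :, i] = (surf - surf.mean()) / max(surf.std(), 1e-9)

    countries = pd.DataFrame(index=sorted(cells["country"].unique()))
    countries.index.name = "country"
    n = config.n_countries
    region_of = {f"C{c:02d}": f"R{c // config.countries_per_region}" for c in range(n)}
    countries["region"] = [region_of[c] for c in countries.index]
    countries["super_region"] = [
        f"SR{int(r[1:]) // config.regions_per_super_region}" for r in countries["region"]]
    # income rule: floor(income_split * n) countries with highest covariate mean
    mean_cov = pd.Series(
        {c: cov[(cells["country"] == c).to_numpy()].mean() for c in countries.index})
    n_hic = int(np.floor(config.income_split * n))
    hic = set(mean_cov.sort_values(ascending=False).index[:n_hic])
    countries["income_class"] = ["HIC" if c in hic else "LMIC" for c in countries.index]

    return geo_mod.GeoFrame(cells=cells, countries=countries, years=years,
                            population=population, covariates=cov,
                            covariate_names=names)


# ---------------------------------------------------------------------------
# Latent usage surface and surveys
# ---------------------------------------------------------------------------

def simulate_latent_usage(world: geo_mod.GeoFrame, beta, gp_params: GPHyperparams,
                          seed: int = 0) -> np.ndarray:
    """One draw of the usage surface: logit(p) = X beta + w, w ~ GP.

    Uses the identical covariance constructor as the fitting code, so the
    simulated field has exactly the Matérn(space) x AR1(time) structure the
    model assumes.
    """
    beta = np.atleast_1d(np.asarray(beta, float))
    if len(beta) != world.n_covariates:
        raise ValueError(f"beta has {len(beta)} entries for {world.n_covariates} covariates")
    rng = np.random.default_rng(seed)
    eta = np.einsum("ctk,k->ct", world.covariates, beta)
    if gp_params.marginal_sd > 0:
        cov = build_space_time_covariance(world, gp_params)
        w = cov.sample(1, rng)[0].reshape(world.n_cells, world.n_years)
        eta = eta + w
    return 1.0 / (1.0 + np.exp(-eta))


def simulate_surveys(world: geo_mod.GeoFrame, usage_surface: np.ndarray,
                     design: SurveyDesign, seed: int = 0) -> pd.DataFrame:
    """Emulate DHS/MICS-style survey records from the latent surface.

    Point surveys yield one record per sampled cluster (cell), with
    k ~ Binomial(N, p) at the cell-year; polygon surveys report a single
    district-referenced record aggregating several latent clusters, so the
    exact within-polygon locations are lost, as in real admin-referenced
    survey rounds.
    """
    rng = np.random.default_rng(seed)
    lo, hi = design.N_range
    rows = []
    pop0 = world.population[:, 0]
    countries = list(world.countries.index)
    districts = world.units("district")
    sid = 0
    for _ in range(design.n_point_surveys):
        country = countries[rng.integers(len(countries))]
        t = int(rng.integers(world.n_years))
        mask = (world.cells["country"] == country).to_numpy()
        cands = np.flatnonzero(mask)
        w = pop0[cands] / pop0[cands].sum()
        for _ in range(design.clusters_per_point_survey):
            c = int(rng.choice(cands, p=w))
            N = int(rng.integers(lo, hi + 1))
            k = int(rng.binomial(N, usage_surface[c, t]))
            rows.append({"survey_id": f"S{sid:03d}", "year": int(world.years[t]),
                         "location_type": "cell",
                         "location": int(world.cells.index[c]),
                         "N": N, "k": k, "weight": 1.0})
        sid += 1
    for _ in range(design.n_polygon_surveys):
        d = districts[rng.integers(len(districts))]
        t = int(rng.integers(world.n_years))
        mask = (world.cells["district_id"] == d).to_numpy()
        cands = np.flatnonzero(mask)
        w = pop0[cands] / pop0[cands].sum()
        N_tot = k_tot = 0
        for _ in range(design.clusters_per_polygon):
            c = int(rng.choice(cands, p=w))
            N = int(rng.integers(lo, hi + 1))
            N_tot += N
            k_tot += int(rng.binomial(N, usage_surface[c, t]))
        rows.append({"survey_id": f"S{sid:03d}", "year": int(world.years[t]),
                     "location_type": "district", "location": d,
                     "N": N_tot, "k": k_tot, "weight": 1.0})
        sid += 1
    return pd.DataFrame(rows, columns=geo_mod.SURVEY_COLUMNS)


# ---------------------------------------------------------------------------
# Ground-truth consumption and sales records
# ---------------------------------------------------------------------------

def default_ground_truth(world: geo_mod.GeoFrame, *, seed: int = 0,
                         beta: np.ndarray | None = None,
                         gp_params: GPHyperparams | None = None,
                         registry: ATCRegistry | None = None,
                         usage_seed_offset: int = 101,
                         dirichlet_concentration: float = 5.0) -> GroundTruth:
    """Sample a coherent GroundTruth for a generated world.

    National consumption rates are log-linear in the national covariate
    means plus a mild upward time trend and country-level noise, spanning
    roughly 5-45 DDD per 1000 per day as observed across real countries;
    the class mix is a Dirichlet draw per country over the registry's
    allocation classes; the hospital share of sales is uniform on
    [0.1, 0.4].
    """
    rng = np.random.default_rng(seed)
    registry = registry or ATCRegistry.load("2019")
    if beta is None:
        beta = rng.normal(0, 0.5, world.n_covariates)
    beta = np.asarray(beta, float)
    if gp_params is None:
        extent = world.coords.max(axis=0) - world.coords.min(axis=0)
        gp_params = GPHyperparams(spatial_range=float(max(extent) / 4),
                                  marginal_sd=0.8, ar1_rho=0.7)
    usage = simulate_latent_usage(world, beta, gp_params, seed=seed + usage_seed_offset)

    natcov = world.national_covariates()
    tt = (natcov["year"] - world.years.mean()) / max(world.n_years - 1, 1)
    a = rng.normal(0, 0.15, world.n_covariates)
    # consumption levels cluster regionally (neighbouring countries share
    # markets and prescribing habits), with residual country offsets on top
    regions = world.countries["region"]
    region_eff = pd.Series(rng.normal(0, 0.25, regions.nunique()),
                           index=sorted(regions.unique()))
    country_eff = pd.Series(rng.normal(0, 0.25, len(world.countries)),
                            index=world.countries.index)
    log_rate = (np.log(14.0)
                + natcov[world.covariate_names].to_numpy() @ a
                + 0.4 * tt.to_numpy()
                + region_eff[regions[natcov["country"]]].to_numpy()
                + country_eff[natcov["country"]].to_numpy())
    rate = np.clip(np.exp(log_rate), 2.0, 50.0)
    national = natcov[["country", "year"]].copy()
    national["rate"] = rate
    national = national.pivot(index="country", columns="year", values="rate")

    classes = registry.class_vocabulary()
    mix = rng.dirichlet(np.full(len(classes), dirichlet_concentration),
                        size=len(world.countries))
    class_mix = pd.DataFrame(mix, index=world.countries.index, columns=classes)
    sector_split = pd.Series(rng.uniform(0.1, 0.4, len(world.countries)),
                             index=world.countries.index)
    return GroundTruth(beta=beta, gp_params=gp_params, usage_surface=usage,
                       national_consumption=national, class_mix=class_mix,
                       sector_split=sector_split)


def _class_code(registry: ATCRegistry, class_label: str) -> str:
    codes = [c for c in registry.codes if registry[c].class_label == class_label]
    if not codes:
        raise KeyError(f"class {class_label!r} absent from registry")
    return codes[0]


def simulate_sales(world: geo_mod.GeoFrame, truth: GroundTruth,
                   registry: ATCRegistry, missingness: MissingnessDesign | None = None,
                   seed: int = 0, kg_from_year: int = 2014) -> pd.DataFrame:
    """Emit sales records that invert exactly to the ground-truth rates.

    For each country-year the total DDD implied by the records equals
    ``rate x population x 365 / 1000`` before missingness; each allocation
    class is carried by one representative ATC code, split into hospital
    and retail sectors by the country's sector share. Years before
    ``kg_from_year`` are expressed in standard units with a product
    strength of half a DDD per dose; later years in kilograms (mirroring a
    sales-audit format change). Missingness then deletes all hospital
    records for a share of countries and whole high-income country-years.
    """
    missingness = missingness or MissingnessDesign()
    rng = np.random.default_rng(seed)
    pop = world.country_population()
    rows = []
    for country in truth.national_consumption.index:
        for year in truth.national_consumption.columns:
            total_ddd = volume(truth.national_consumption.loc[country, year],
                               pop.loc[country, year])
            for cls, frac in truth.class_mix.loc[country].items():
                if frac == 0:
                    continue
                code = _class_code(registry, cls)
                entry = registry[code]
                route = entry.default_route
                ddd_g = entry.ddd_grams(route)
                for sector, sfrac in (("hospital", truth.sector_split[country]),
                                      ("retail", 1 - truth.sector_split[country])):
                    ddd = total_ddd * frac * sfrac
                    kg = ddd * ddd_g / 1000.0
                    if year < kg_from_year:
                        mg_per_su = ddd_g * 1000.0 / 2.0
                        rows.append({"country": country, "year": int(year), "atc": code,
                                     "route": route, "sector": sector, "unit": "SU",
                                     "quantity": kg * 1e6 / mg_per_su,
                                     "mg_per_su": mg_per_su})
                    else:
                        rows.append({"country": country, "year": int(year), "atc": code,
                                     "route": route, "sector": sector, "unit": "kg",
                                     "quantity": kg, "mg_per_su": np.nan})
    sales = pd.DataFrame(rows, columns=["country", "year", "atc", "route", "sector",
                                        "unit", "quantity", "mg_per_su"])
    # sector missingness: a share of countries lose all hospital records
    countries = list(truth.national_consumption.index)
    n_retail_only = int(np.floor(missingness.retail_only_frac * len(countries)))
    retail_only = set(rng.choice(countries, size=n_retail_only, replace=False))
    if retail_only:
        sales = sales[~(sales["country"].isin(retail_only)
                        & (sales["sector"] == "hospital"))]
    # whole-year missingness among high-income country-years
    hic = [c for c in countries if world.countries.loc[c, "income_class"] == "HIC"]
    pairs = [(c, int(y)) for c in hic for y in truth.national_consumption.columns]
    n_drop = int(np.floor(missingness.missing_year_frac * len(pairs)))
    if n_drop:
        drop_idx = rng.choice(len(pairs), size=n_drop, replace=False)
        dropped = {pairs[i] for i in drop_idx}
        keep = [not ((c, y) in dropped) for c, y in zip(sales["country"], sales["year"])]
        sales = sales[keep]
    return sales.reset_index(drop=True)
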