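"""National antibiotic-consumption estimation for LMICs.

Two-stage framework on the log-rate scale:

1. **Stage 1**: a stacked ensemble (see :mod:`abxgeo.stacking`) regresses
   observed log consumption rates on national features — the aggregated
   antibiotic-usage estimate plus population-weighted covariate means —
   with country-grouped five-fold cross-validation, and the non-negative
   least-squares stack combination predicts a mean for *every*
   country-year, observed or not.
2. **ST-GPR smoothing**: the stage-1 series is used as the prior mean of a
   Gaussian process over country-years whose covariance is a Matérn-3/2
   kernel in time, shared within a country and (down-weighted by a pooling
   factor) across countries of the same GBD region. Exact Gaussian
   conditioning on the observed rates, with a nugget floor on the
   observation noise, yields the posterior; 1000 joint draws are
   exponentiated to give rates with percentile 95% uncertainty intervals.

The LMIC track is finally combined with the imputed high-income track
into a global table; high-income rows carry no uncertainty interval, and
regional/global rates are population-weighted means aggregated at the
draw level for LMICs and as point values for HICs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from . import stacking
from .ddd import volume
from .geo import GeoFrame


@dataclass
class STGPRParams:
    time_lengthscale: float = 5.0        # years
    amplitude: float | None = None       # None -> 1.4826 x MAD of stage-1 residuals
    nugget_sd: float = 0.05              # log-units observation noise floor
    region_pooling_weight: float = 0.3   # lambda: cross-country pooling within region
    n_draws: int = 1000
    seed: int = 0


def matern32(dt: np.ndarray, lengthscale: float) -> np.ndarray:
    a = np.sqrt(3.0) * np.abs(dt) / lengthscale
    return (1.0 + a) * np.exp(-a)


# ---------------------------------------------------------------------------
# Stage 1
# ---------------------------------------------------------------------------

def build_national_features(geo: GeoFrame, usage_country: pd.DataFrame) -> pd.DataFrame:
    """One feature row per LMIC country-year.

    ``usage_country`` is the country-level EstimateTable of the usage model
    (columns ``unit_id, year, mean``); features are the national usage mean
    plus the world's population-weighted national covariate means.
    """
    lmic = geo.lmic_countries()
    natcov = geo.national_covariates()
    usage = usage_country.rename(columns={"unit_id": "country", "mean": "usage"})
    feat = natcov.merge(usage[["country", "year", "usage"]], on=["country", "year"],
                        how="left")
    feat = feat[feat["country"].isin(lmic)].reset_index(drop=True)
    if feat["usage"].isna().any():
        missing = feat.loc[feat["usage"].isna(), ["country", "year"]]
        raise ValueError(f"usage estimate missing for country-years:\n{missing}")
    return feat


def stage1(features: pd.DataFrame, observations: pd.DataFrame, *,
           child_specs=None, n_folds: int = 5, seed: int = 0):
    """Stacked-ensemble prediction of log consumption for all country-years.

    ``observations`` holds ``country, year, ddd_per_1000_per_day`` for the
    observed subset. Returns ``(stage1_table, stack_result, weights)``
    where the table has a ``log_mean`` column for every feature row.
    """
    obs = observations[["country", "year", "ddd_per_1000_per_day"]].copy()
    obs = obs[obs["country"].isin(features["country"].unique())]
    if obs["country"].nunique() < 2:
        raise ValueError("need observations from at least 2 countries")
    merged = features.merge(obs, on=["country", "year"], how="inner")
    feat_cols = [c for c in features.columns if c not in ("country", "year")]
    X_obs = merged[feat_cols].to_numpy(float)
    y_obs = np.log(merged["ddd_per_1000_per_day"].to_numpy(float))
    n_folds = min(n_folds, merged["country"].nunique())
    folds = stacking.assign_folds(merged["country"].to_numpy(), n_folds=n_folds, seed=seed)
    specs = child_specs or stacking.default_children()
    result = stacking.fit_children_oos(X_obs, y_obs, None, specs, folds,
                                       outcome_family="gaussian", seed=seed)
    weights = stacking.fit_stack_weights(result.oos_predictions, y_obs, "gaussian")
    result.stack_weights = weights
    table = features[["country", "year"]].copy()
    table["log_mean"] = result.combined(features[feat_cols].to_numpy(float))
    # out-of-sample combined predictions at the observed rows: these carry
    # honest predictive error and drive the ST-GPR amplitude rule
    oos = merged[["country", "year"]].copy()
    oos["log_mean_oos"] = result.oos_predictions @ weights
    table = table.merge(oos, on=["country", "year"], how="left")
    return table, result, weights


# ---------------------------------------------------------------------------
# ST-GPR smoothing
# ---------------------------------------------------------------------------

@dataclass
class STGPRResult:
    table: pd.DataFrame                  # country, year, mean, lower, upper (rate scale)
    draws: np.ndarray                    # (n_draws, n_country_years), rate scale
    index: pd.DataFrame                  # country, year row order of draw columns
    amplitude: float
    params: STGPRParams = field(default_factory=STGPRParams)


def _st_kernel(index: pd.DataFrame, region_of: pd.Series, params: STGPRParams,
               amplitude: float) -> np.ndarray:
    years = index["year"].to_numpy(float)
    Kt = matern32(np.subtract.outer(years, years), params.time_lengthscale)
    country = index["country"].to_numpy()
    same_country = np.equal.outer(country, country)
    region = region_of[country].to_numpy()
    same_region = np.equal.outer(region, region)
    lam = params.region_pooling_weight
    struct = (1 - lam) * same_country + lam * same_region
    return amplitude ** 2 * Kt * struct


def stgpr_smooth(stage1_table: pd.DataFrame, observations: pd.DataFrame,
                 geo: GeoFrame, params: STGPRParams | None = None) -> STGPRResult:
    """Smooth stage-1 log-rate predictions toward the observed rates.

    GP prior mean = stage-1 series; covariance couples years within a
    country through a Matérn-3/2 kernel and, with weight
    ``region_pooling_weight``, country pairs of the same GBD region —
    so countries without any observation borrow the residual pattern of
    their region. The amplitude defaults to a robust scale (1.4826 x MAD)
    of the stage-1 residuals at observed points.
    """
    params = params or STGPRParams()
    index = stage1_table[["country", "year"]].reset_index(drop=True)
    # the prior mean uses out-of-sample stacked predictions wherever they
    # exist: in-sample predictions of flexible children interpolate the
    # observations, which would erase the residual field the GP smooths
    if "log_mean_oos" in stage1_table.columns:
        m = stage1_table["log_mean_oos"].fillna(
            stage1_table["log_mean"]).to_numpy(float)
    else:
        m = stage1_table["log_mean"].to_numpy(float)
    obs = observations[["country", "year", "ddd_per_1000_per_day"]].copy()
    obs = obs[obs["country"].isin(index["country"].unique())]
    key = index.assign(_row=np.arange(len(index)))
    obs = obs.merge(key, on=["country", "year"], how="inner")
    o = obs["_row"].to_numpy(int)
    y = np.log(obs["ddd_per_1000_per_day"].to_numpy(float))

    if len(o) == 0:
        warnings.warn("no consumption observations: returning the stage-1 prior")
        amplitude = params.amplitude or 0.0
    elif params.amplitude is not None:
        amplitude = params.amplitude
    else:
        resid = y - m[o]
        amplitude = float(1.4826 * np.median(np.abs(resid - np.median(resid))))
        amplitude = max(amplitude, 1e-6)

    rng = np.random.default_rng(params.seed)
    n = len(index)
    if amplitude == 0 or len(o) == 0:
        post_mean, post_cov = m.copy(), np.zeros((n, n))
    else:
        K = _st_kernel(index, geo.countries["region"], params, amplitude)
        Ko = K[np.ix_(o, o)] + params.nugget_sd ** 2 * np.eye(len(o))
        post_mean = m + K[:, o] @ np.linalg.solve(Ko, y - m[o])
        post_cov = K - K[:, o] @ np.linalg.solve(Ko, K[o, :])
    # draws on the log scale, exponentiated; negative eigenvalues from
    # numerical cancellation are clipped rather than jittered so that a
    # degenerate (zero-variance) posterior yields exactly constant draws
    evals, evecs = np.linalg.eigh(post_cov)
    root = evecs * np.sqrt(np.clip(evals, 0, None))
    eps = rng.standard_normal((n, params.n_draws))
    log_draws = post_mean[:, None] + root @ eps
    draws = np.exp(log_draws).T  # (n_draws, n)
    table = index.copy()
    table["mean"] = draws.mean(axis=0)
    table["lower"] = np.quantile(draws, 0.025, axis=0)
    table["upper"] = np.quantile(draws, 0.975, axis=0)
    table["log_mean_post"] = post_mean
    return STGPRResult(table=table, draws=draws, index=index,
                       amplitude=amplitude, params=params)


# ---------------------------------------------------------------------------
# Track combination and summaries
# ---------------------------------------------------------------------------

def combine_tracks(lmic: STGPRResult, hic_rates: pd.DataFrame, geo: GeoFrame):
    """Merge the LMIC draws with the imputed HIC point rates.

    Returns ``(country_table, summary_table)``. The country table has one
    row per country-year with mean/lower/upper rates (HIC rows carry NaN
    intervals), annual DDD volume and the track label. The summary gives
    population-weighted regional and global rates and volumes with
    draw-level UIs (the HIC contribution enters each draw as a constant).
    """
    lmic_countries = set(lmic.index["country"])
    hic_countries = set(hic_rates["country"])
    world_countries = set(geo.countries.index)
    if lmic_countries & hic_countries:
        raise ValueError(f"tracks overlap: {sorted(lmic_countries & hic_countries)}")
    if lmic_countries | hic_countries != world_countries:
        raise ValueError("tracks do not partition the country set")
    pop = geo.country_population()
    rows = []
    for _, r in lmic.table.iterrows():
        p = pop.loc[r["country"], int(r["year"])]
        rows.append({"country": r["country"], "year": int(r["year"]), "track": "LMIC",
                     "mean": r["mean"], "lower": r["lower"], "upper": r["upper"],
                     "population": p, "volume_ddd": volume(r["mean"], p)})
    for _, r in hic_rates.iterrows():
        p = pop.loc[r["country"], int(r["year"])]
        rows.append({"country": r["country"], "year": int(r["year"]), "track": "HIC",
                     "mean": r["ddd_per_1000_per_day"], "lower": np.nan, "upper": np.nan,
                     "population": p, "volume_ddd": volume(r["ddd_per_1000_per_day"], p)})
    country_table = pd.DataFrame(rows).sort_values(["country", "year"]).reset_index(drop=True)

    # draw-level regional/global aggregation
    years = sorted(country_table["year"].unique())
    n_draws = lmic.draws.shape[0]
    region_of = geo.countries["region"]
    summary_rows = []
    hic_tab = country_table[country_table["track"] == "HIC"]
    for scope, members in ([("global", world_countries)]
                           + [(r, set(region_of.index[region_of == r]))
                              for r in sorted(region_of.unique())]):
        for year in years:
            sel = (lmic.index["year"] == year) & lmic.index["country"].isin(members)
            cols = np.flatnonzero(sel.to_numpy())
            lmic_pop = np.array([pop.loc[c, year] for c in lmic.index.loc[sel, "country"]])
            hic_sel = hic_tab[(hic_tab["year"] == year) & hic_tab["country"].isin(members)]
            hic_vol = hic_sel["volume_ddd"].sum()
            hic_pop = hic_sel["population"].sum()
            vol_draws = (lmic.draws[:, cols] * lmic_pop * 365.0 / 1000.0).sum(axis=1) + hic_vol
            tot_pop = lmic_pop.sum() + hic_pop
            rate_draws = vol_draws / tot_pop / 365.0 * 1000.0
            summary_rows.append({
                "scope": scope, "year": year,
                "volume_ddd": float(vol_draws.mean()),
                "volume_lower": float(np.quantile(vol_draws, 0.025)),
                "volume_upper": float(np.quantile(vol_draws, 0.975)),
                "rate": float(rate_draws.mean()),
                "rate_lower": float(np.quantile(rate_draws, 0.025)),
                "rate_upper": float(np.quantile(rate_draws, 0.975)),
                "population": float(tot_pop)})
    summary = pd.DataFrame(summary_rows)
    glob = summary[summary["scope"] == "global"].set_index("year")["volume_ddd"]
    summary["pct_of_global"] = [100.0 * v / glob[y] for v, y
                                in zip(summary["volume_ddd"], summary["year"])]
    return country_table, summary


# ---------------------------------------------------------------------------
# Cross-validation
# ---------------------------------------------------------------------------

def cross_validate(features: pd.DataFrame, observations: pd.DataFrame, geo: GeoFrame, *,
                   params: STGPRParams | None = None, n_folds: int = 5,
                   seed: int = 0) -> pd.DataFrame:
    """Five-fold out-of-country validation of the full consumption pipeline.

    Observations are held out by country fold; the stage-1 ensemble and
    the GP smoother are refit without them and scored on the held-out log
    rates. Reported per fold: out-of-sample RMSE and bias (log scale) for
    stage 1 alone and for the smoothed pipeline, and the share of held-out
    observations covered by the 95% UI.
    """
    params = params or STGPRParams()
    obs = observations[["country", "year", "ddd_per_1000_per_day"]].copy()
    obs = obs[obs["country"].isin(features["country"].unique())].reset_index(drop=True)
    countries = obs["country"].unique()
    if len(countries) < n_folds:
        raise ValueError(f"need >= {n_folds} observed countries")
    folds = stacking.assign_folds(obs["country"].to_numpy(), n_folds=n_folds, seed=seed)
    rows = []
    for f in range(n_folds):
        train = obs[folds != f]
        test = obs[folds == f]
        s1, _, _ = stage1(features, train, n_folds=min(5, train["country"].nunique()),
                          seed=seed + f)
        smoothed = stgpr_smooth(s1, train, geo,
                                STGPRParams(**{**params.__dict__, "seed": seed + f}))
        key = ["country", "year"]
        s1_test = test.merge(s1, on=key)
        sm_test = test.merge(smoothed.table, on=key)
        y = np.log(s1_test["ddd_per_1000_per_day"].to_numpy())
        e1 = s1_test["log_mean"].to_numpy() - y
        y2 = np.log(sm_test["ddd_per_1000_per_day"].to_numpy())
        e2 = np.log(sm_test["mean"].to_numpy()) - y2
        # predictive interval for an *observation*: latent draws plus nugget
        pos = smoothed.index.assign(_r=np.arange(len(smoothed.index))).merge(
            test, on=key)["_r"].to_numpy(int)
        rng = np.random.default_rng(seed + 100 + f)
        pred = smoothed.draws[:, pos] * np.exp(
            rng.normal(0, params.nugget_sd, (smoothed.draws.shape[0], len(pos))))
        lo = np.quantile(pred, 0.025, axis=0)
        hi = np.quantile(pred, 0.975, axis=0)
        obs_vals = test.set_index(key).loc[
            list(zip(smoothed.index.loc[pos, "country"], smoothed.index.loc[pos, "year"])),
            "ddd_per_1000_per_day"].to_numpy()
        covered = (obs_vals >= lo) & (obs_vals <= hi)
        rows.append({"fold": f, "n_test": len(test),
                     "rmse_stage1": float(np.sqrt(np.mean(e1 ** 2))),
                     "rmse_pipeline": float(np.sqrt(np.mean(e2 ** 2))),
                     "bias_stage1": float(np.mean(e1)),
                     "bias_pipeline": float(np.mean(e2)),
                     "ui_coverage": float(covered.mean())})
    return pd.DataFrame(rows)
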