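"""CART multiple imputation for consumption tables.

Chained-equation multiple imputation where each target column is modelled
by a regression tree on the remaining columns and every missing entry is
filled by drawing one donor uniformly from the leaf the incomplete row
falls in. Donor draws guarantee imputed values always lie within the
observed range of their column and are used for (a) hospital-sector
consumption in countries reporting only retail sales and (b) missing
high-income country-year totals.

Observed entries are never modified; ``m`` independent chains give ``m``
completed tables, pooled by the cell-wise mean with between-imputation
variance reported alongside.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.tree import DecisionTreeRegressor


class UnimputableError(ValueError):
    pass


@dataclass
class ImputationTask:
    """A table with missing targets plus the controls of the imputation.

    ``table`` rows are country-years; ``targets`` name the columns to
    impute, every other numeric column serves as predictor. Categorical
    predictors must be one-hot encoded beforehand (see
    :func:`one_hot_regions`).
    """

    table: pd.DataFrame
    targets: list[str]
    m: int = 5
    n_iter: int = 10
    min_leaf: int = 5
    seed: int = 0
    predictors: list[str] = field(default_factory=list)

    def __post_init__(self):
        if self.m < 2:
            raise ValueError("need m >= 2 imputations")
        if not self.predictors:
            self.predictors = [c for c in self.table.columns
                               if c not in self.targets
                               and pd.api.types.is_numeric_dtype(self.table[c])]
        for t in self.targets:
            if self.table[t].notna().sum() == 0:
                raise UnimputableError(f"column {t!r} has no observed values")


def one_hot_regions(df: pd.DataFrame, column: str) -> pd.DataFrame:
    """One-hot encode a categorical column (e.g. GBD region) for tree fits."""
    dummies = pd.get_dummies(df[column], prefix=column, dtype=float)
    return pd.concat([df.drop(columns=[column]), dummies], axis=1)


def _impute_once(task: ImputationTask, rng: np.random.Generator) -> pd.DataFrame:
    tab = task.table.copy()
    miss = {t: tab[t].isna().to_numpy() for t in task.targets}
    # initialise missing entries with random draws from the observed values
    for t in task.targets:
        obs = tab.loc[~miss[t], t].to_numpy()
        tab.loc[miss[t], t] = rng.choice(obs, size=miss[t].sum(), replace=True)
    X_cols = task.predictors
    for _ in range(task.n_iter):
        for t in task.targets:
            if not miss[t].any():
                continue
            other = [c for c in task.targets if c != t and c in tab.columns]
            feats = tab[X_cols + other].to_numpy(float)
            tree = DecisionTreeRegressor(min_samples_leaf=task.min_leaf,
                                         random_state=int(rng.integers(2**31)))
            tree.fit(feats[~miss[t]], tab.loc[~miss[t], t].to_numpy(float))
            leaves = tree.apply(feats)
            obs_leaves = leaves[~miss[t]]
            obs_values = tab.loc[~miss[t], t].to_numpy()
            for i in np.flatnonzero(miss[t]):
                donors = obs_values[obs_leaves == leaves[i]]
                tab.iloc[i, tab.columns.get_loc(t)] = rng.choice(donors)
    return tab


def cart_mice(task: ImputationTask) -> list[pd.DataFrame]:
    """Run ``m`` independent CART chained-equation imputation chains."""
    rng = np.random.default_rng(task.seed)
    return [_impute_once(task, np.random.default_rng(int(rng.integers(2**31))))
            for _ in range(task.m)]


def pool(imputed_tables: list[pd.DataFrame], targets: list[str]):
    """Cell-wise mean across imputations plus between-imputation variance.

    Observed cells are identical in every table, so their pooled value is
    the observed value exactly.
    """
    shapes = {t.shape for t in imputed_tables}
    if len(shapes) != 1:
        raise ValueError("imputed tables differ in shape")
    pooled = imputed_tables[0].copy()
    between = pooled[targets].copy() * 0.0
    stack = {t: np.stack([tab[t].to_numpy(float) for tab in imputed_tables]) for t in targets}
    for t in targets:
        vals = stack[t].mean(axis=0)
        # cells identical across imputations (observed data, deterministic
        # donors) must come back bit-exact, not re-rounded through the mean
        same = np.all(stack[t] == stack[t][0], axis=0)
        vals[same] = stack[t][0][same]
        pooled[t] = vals
        between[t] = stack[t].var(axis=0, ddof=1)
    return pooled, between


def impute_hospital(obs: pd.DataFrame, covariates: pd.DataFrame | None = None, *,
                    m: int = 5, n_iter: int = 10, seed: int = 0) -> pd.DataFrame:
    """Impute hospital-sector DDD for retail-only country-years.

    ``obs`` needs columns ``country, year, ddd_retail, ddd_hospital,
    sectors_present, population``; hospital values are treated as missing
    wherever only the retail sector was observed. Predictors are retail
    DDD, population, year and any extra ``covariates`` (keyed by
    country/year). The returned frame has pooled hospital values, updated
    ``ddd_total`` and an ``imputed_hospital`` flag.
    """
    tab = obs.copy().reset_index(drop=True)
    retail_only = tab["sectors_present"].apply(lambda s: set(s) == {"retail"})
    if (~retail_only).sum() == 0:
        raise UnimputableError("no country with both sectors observed")
    tab.loc[retail_only, "ddd_hospital"] = np.nan
    work = tab[["country", "year", "ddd_retail", "ddd_hospital", "population"]].copy()
    if covariates is not None:
        work = work.merge(covariates, on=["country", "year"], how="left")
    task = ImputationTask(table=work.drop(columns=["country"]),
                          targets=["ddd_hospital"], m=m, n_iter=n_iter, seed=seed)
    pooled, _ = pool(cart_mice(task), ["ddd_hospital"])
    out = tab.copy()
    out["ddd_hospital"] = pooled["ddd_hospital"].to_numpy()
    out["imputed_hospital"] = retail_only.to_numpy()
    out["ddd_total"] = np.where(retail_only, out["ddd_retail"] + out["ddd_hospital"],
                                out["ddd_total"])
    return out


def impute_hic_missing(hic_rates: pd.DataFrame, covariates: pd.DataFrame | None = None, *,
                       region: pd.Series | None = None, m: int = 5, n_iter: int = 10,
                       seed: int = 0) -> pd.DataFrame:
    """Complete the high-income consumption-rate table by CART imputation.

    ``hic_rates`` has columns ``country, year, ddd_per_1000_per_day`` with
    NaN for missing country-years (whole countries or scattered years).
    Predictors: year, one-hot region (if given) and covariates. Imputed
    rows are flagged; consistent with the modelling strategy, no
    uncertainty interval accompanies these point values.
    """
    tab = hic_rates.copy().reset_index(drop=True)
    work = tab[["country", "year", "ddd_per_1000_per_day"]].copy()
    if covariates is not None:
        work = work.merge(covariates, on=["country", "year"], how="left")
    if region is not None:
        work["region"] = work["country"].map(region)
        work = one_hot_regions(work, "region")
    # country dummies let scattered missing years borrow from the same
    # country's observed series; wholly missing countries fall back to the
    # region and year splits
    work["_country"] = work["country"]
    work = one_hot_regions(work, "_country")
    task = ImputationTask(table=work.drop(columns=["country"]),
                          targets=["ddd_per_1000_per_day"], m=m, n_iter=n_iter, seed=seed)
    pooled, _ = pool(cart_mice(task), ["ddd_per_1000_per_day"])
    out = tab.copy()
    out["imputed"] = out["ddd_per_1000_per_day"].isna()
    out["ddd_per_1000_per_day"] = pooled["ddd_per_1000_per_day"].to_numpy()
    return out
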