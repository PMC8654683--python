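"""End-to-end orchestration of the estimation workflow.

``run`` executes the full chain on a synthetic world — world generation,
survey preparation, usage model, consumption observations, hospital and
HIC imputation, stage-1 ensemble, ST-GPR smoothing, track combination and
class allocation — writing every stage's CSV outputs plus a JSON run
manifest. All randomness derives from the single config seed, so rerunning
an identical config reproduces every output bit for bit.

``experiment_recovery`` is the replicate harness behind the calibration
and recovery experiments: it simulates worlds with known ground truth,
runs the pipeline and scores parameter recovery, interval coverage and
out-of-sample error.
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import classes as classes_mod
from . import ddd as ddd_mod
from . import geo as geo_mod
from . import geostat, stacking, stgpr
from . import impute as impute_mod
from . import synthetic

DEFAULT_INCOME_OVERRIDES = {"China": "HIC", "Russia": "HIC", "Lebanon": "HIC"}


@dataclass
class PipelineConfig:
    world: synthetic.WorldConfig = field(default_factory=lambda: synthetic.WorldConfig(
        n_countries=8, cells_per_country=9, n_districts_per_country=3,
        years=(2000, 2018), n_covariates=3, income_split=0.25))
    survey_design: synthetic.SurveyDesign = field(default_factory=synthetic.SurveyDesign)
    missingness: synthetic.MissingnessDesign = field(
        default_factory=lambda: synthetic.MissingnessDesign(retail_only_frac=0.25,
                                                            missing_year_frac=0.1))
    stgpr_params: stgpr.STGPRParams = field(default_factory=stgpr.STGPRParams)
    registry_version: str = "2019"
    n_draws: int = 1000
    hyper_grid_points: int = 5
    imputation_m: int = 5
    imputation_iter: int = 10
    obs_noise_sd: float = 0.0          # log-scale noise added to consumption obs
    obs_coverage: float = 1.0          # share of LMIC country-years observed
    income_overrides: dict = field(default_factory=lambda: dict(DEFAULT_INCOME_OVERRIDES))
    seed: int = 0

    def __post_init__(self):
        if self.n_draws < 2:
            raise ValueError("n_draws must be >= 2")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        kwargs = {}
        for key, sub in (("world", synthetic.WorldConfig),
                         ("survey_design", synthetic.SurveyDesign),
                         ("missingness", synthetic.MissingnessDesign),
                         ("stgpr_params", stgpr.STGPRParams)):
            if key in raw:
                block = raw.pop(key)
                if key == "world" and "years" in block:
                    block["years"] = tuple(block["years"])
                kwargs[key] = sub(**block)
        kwargs.update(raw)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return asdict(self)


class StageError(RuntimeError):
    def __init__(self, stage, cause):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")


def _apply_income_overrides(geo, overrides):
    for country, cls in overrides.items():
        if country in geo.countries.index:
            geo.countries.loc[country, "income_class"] = cls


def _usage_model(surveys, geo, n_draws, grid_points, seed):
    """Stacked children -> binomial space-time GP -> posterior draws."""
    points = geo_mod.resample_polygon_records(surveys, geo, seed=seed)
    idx = geo.cell_position(points["location"].to_numpy())
    t_idx = geo.year_index(points["year"].to_numpy())
    X_rows = geo.covariates[idx, t_idx, :]
    folds = stacking.assign_folds(points["survey_id"].to_numpy(),
                                  n_folds=min(5, points["survey_id"].nunique()),
                                  seed=seed)
    stack = stacking.fit_children_oos(
        X_rows, (points["k"].to_numpy(), points["N"].to_numpy()), None,
        stacking.default_children(), folds, outcome_family="binomial", seed=seed)
    X_data = stacking.logit(stack.oos_predictions)
    grid_cov = geo.covariates.reshape(-1, geo.n_covariates)
    X_grid = stacking.logit(stack.predict_full(grid_cov))
    grid = geostat.default_hyper_grid(points, geo, n_points=grid_points)
    fit = geostat.fit(points, X_data, X_grid, geo, hyper_grid=grid)
    draws = geostat.draw_posterior(fit, n_draws=n_draws, seed=seed + 7)
    return points, stack, fit, draws


def run(config: PipelineConfig, out_dir) -> dict:
    """Execute all stages in order; returns the run manifest."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {"config": config.to_dict(), "stages": {}, "outputs": []}
    rng = np.random.default_rng(config.seed)
    registry = ddd_mod.ATCRegistry.load(config.registry_version)

    def stage(name):
        class _Ctx:
            def __enter__(self_):
                self_.t0 = time.time()
                return self_

            def __exit__(self_, exc_type, exc, tb):
                if exc is not None:
                    raise StageError(name, exc) from exc
                manifest["stages"].setdefault(name, {})["seconds"] = round(
                    time.time() - self_.t0, 3)
        return _Ctx()

    def emit(name, df):
        path = out / name
        df.to_csv(path, index=False)
        manifest["outputs"].append(name)

    with stage("simulate"):
        world = synthetic.generate_world(config.world)
        _apply_income_overrides(world, config.income_overrides)
        truth = synthetic.default_ground_truth(world, seed=config.seed, registry=registry)
        surveys = synthetic.simulate_surveys(world, truth.usage_surface,
                                             config.survey_design, seed=config.seed + 1)
        sales = synthetic.simulate_sales(world, truth, registry,
                                         config.missingness, seed=config.seed + 2)
        world.save(out / "world")
        emit("surveys.csv", surveys)
        emit("sales.csv", sales)
        truth.national_consumption.reset_index().to_csv(out / "truth_consumption.csv",
                                                        index=False)
        manifest["outputs"].append("truth_consumption.csv")

    with stage("usage_model"):
        points, stack, fit, draws = _usage_model(
            surveys, world, config.n_draws, config.hyper_grid_points, config.seed + 3)
        emit("resampled_surveys.csv", points)
        oos = pd.DataFrame(stack.oos_predictions, columns=stack.child_names)
        oos.insert(0, "row", np.arange(len(oos)))
        oos["fold"] = stack.fold_assignment
        emit("stack_oos.csv", oos)
        cell_mean = draws.draws.mean(axis=0)
        cell_lo = np.quantile(draws.draws, 0.025, axis=0)
        cell_hi = np.quantile(draws.draws, 0.975, axis=0)
        cells_long = [{"cell_id": int(cid), "year": int(y),
                       "mean": cell_mean[i, j], "lower": cell_lo[i, j],
                       "upper": cell_hi[i, j]}
                      for i, cid in enumerate(world.cells.index)
                      for j, y in enumerate(world.years)]
        emit("usage_cells.csv", pd.DataFrame(cells_long))
        estimates, deviation = geostat.estimate_usage(draws, world)
        for level in geo_mod.ADMIN_LEVELS:
            emit(f"estimates_{level}.csv", estimates[estimates["level"] == level])
        emit("deviation_report.csv", deviation)
        (out / "fit_report.json").write_text(json.dumps({
            "selected": asdict(fit.hyper),
            "hyper_posterior_mean": asdict(fit.hyper_posterior_mean),
            "log_marginal_likelihood": fit.log_marginal_likelihood,
            "newton_iterations": fit.newton_iterations,
            "grid": fit.grid_table.to_dict(orient="records")}, indent=1))
        manifest["outputs"].append("fit_report.json")

    with stage("consumption_obs"):
        j01, n_dropped = ddd_mod.filter_j01(sales)
        totals = ddd_mod.country_year_totals(j01, registry)
        totals = ddd_mod.attach_rates(totals, world.country_population())
        proportions = classes_mod.compute_proportions(totals)  # pre-imputation
        manifest["stages"]["consumption_obs"] = {"dropped_non_j01": n_dropped}

    with stage("imputation"):
        completed = impute_mod.impute_hospital(totals, m=config.imputation_m,
                                               n_iter=config.imputation_iter,
                                               seed=config.seed + 4)
        completed["ddd_per_1000_per_day"] = [
            ddd_mod.rate(d, p) for d, p in zip(completed["ddd_total"],
                                               completed["population"])]
        emit("consumption_obs.csv",
             completed.drop(columns=["class_ddd", "sectors_present"]))
        hic = world.hic_countries()
        grid = pd.MultiIndex.from_product([hic, world.years],
                                          names=["country", "year"]).to_frame(index=False)
        hic_obs = grid.merge(
            completed.loc[completed["country"].isin(hic),
                          ["country", "year", "ddd_per_1000_per_day"]],
            on=["country", "year"], how="left")
        hic_rates = impute_mod.impute_hic_missing(
            hic_obs, region=world.countries["region"],
            m=config.imputation_m, n_iter=config.imputation_iter, seed=config.seed + 5)

    with stage("stage1"):
        usage_country = pd.read_csv(out / "estimates_country.csv")
        features = stgpr.build_national_features(world, usage_country)
        lmic_obs = completed[completed["country"].isin(world.lmic_countries())]
        lmic_obs = lmic_obs[["country", "year", "ddd_per_1000_per_day"]].copy()
        if config.obs_coverage < 1.0:
            keep = rng.random(len(lmic_obs)) < config.obs_coverage
            lmic_obs = lmic_obs[keep]
        if config.obs_noise_sd > 0:
            lmic_obs["ddd_per_1000_per_day"] *= np.exp(
                rng.normal(0, config.obs_noise_sd, len(lmic_obs)))
        s1, stack_result, weights = stgpr.stage1(features, lmic_obs, seed=config.seed + 6)
        (out / "stack_weights.json").write_text(json.dumps(
            {"weights": weights.tolist(), "children": stack_result.child_names}))
        manifest["outputs"].append("stack_weights.json")

    with stage("stgpr"):
        params = stgpr.STGPRParams(**{**config.stgpr_params.__dict__,
                                      "n_draws": config.n_draws,
                                      "seed": config.seed + 8})
        smoothed = stgpr.stgpr_smooth(s1, lmic_obs, world, params)

    with stage("combine"):
        country_table, summary = stgpr.combine_tracks(smoothed, hic_rates, world)
        country_table["n_draws"] = np.where(country_table["track"] == "LMIC",
                                            config.n_draws, 0)
        emit("consumption_country.csv", country_table)
        emit("consumption_summary.csv", summary)

    with stage("classes"):
        filled = classes_mod.region_fallback(proportions, world,
                                             years=list(world.years))
        class_table, aware_table = classes_mod.allocate(
            country_table.rename(columns={"country": "country"}), filled, registry)
        emit("class_consumption.csv", class_table)
        emit("aware_consumption.csv", aware_table)

    with stage("validate"):
        from .schemas import validate_outputs
        validate_outputs(out)

    manifest["seed"] = config.seed
    (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return manifest


# ---------------------------------------------------------------------------
# Replicate experiments
# ---------------------------------------------------------------------------

@dataclass
class RecoveryConfig:
    """Problem sizes of the replicate recovery/calibration experiments.

    The defaults are a miniature analogue of the study frame: 64-cell
    countries on an 8-year window keep the dense space-time covariance
    small enough for many replicates while leaving enough surveys
    (~60 records x ~10 clusters) to identify the covariance parameters.
    """

    n_replicates: int = 20
    world: synthetic.WorldConfig = field(default_factory=lambda: synthetic.WorldConfig(
        n_countries=4, cells_per_country=16, n_districts_per_country=4,
        years=(2000, 2011), n_covariates=2, income_split=0.25))
    survey_design: synthetic.SurveyDesign = field(
        default_factory=lambda: synthetic.SurveyDesign(n_point_surveys=50,
                                                       n_polygon_surveys=10))
    consumption_world: synthetic.WorldConfig = field(
        default_factory=lambda: synthetic.WorldConfig(
            n_countries=48, cells_per_country=4, n_districts_per_country=2,
            years=(2000, 2018), n_covariates=2, income_split=0.25,
            countries_per_region=4))
    beta: tuple = (0.5, -0.3)
    gp_params: geostat.GPHyperparams = field(default_factory=lambda: geostat.GPHyperparams(
        spatial_range=3.0, marginal_sd=0.8, ar1_rho=0.7))
    n_draws: int = 250
    hyper_grid_points: int = 5
    obs_noise_sd: float = 0.1
    obs_coverage: float = 0.6
    seed: int = 0


def recover_usage_once(rc: RecoveryConfig, seed: int) -> dict:
    """One usage-model replicate: simulate, fit, score recovery and coverage."""
    world_cfg = synthetic.WorldConfig(**{**rc.world.__dict__, "seed": seed})
    world = synthetic.generate_world(world_cfg)
    beta = np.asarray(rc.beta, float)
    usage = synthetic.simulate_latent_usage(world, beta, rc.gp_params, seed=seed + 11)
    surveys = synthetic.simulate_surveys(world, usage, rc.survey_design, seed=seed + 12)
    points = geo_mod.resample_polygon_records(surveys, world, seed=seed + 13)
    idx = world.cell_position(points["location"].to_numpy())
    t_idx = world.year_index(points["year"].to_numpy())
    # fit with the true covariates (recovery targets beta itself)
    X_data = world.covariates[idx, t_idx, :]
    X_grid = world.covariates.reshape(-1, world.n_covariates)
    grid = geostat.default_hyper_grid(points, world, n_points=rc.hyper_grid_points)
    fit = geostat.fit(points, X_data, X_grid, world, hyper_grid=grid)
    draws = geostat.draw_posterior(fit, n_draws=rc.n_draws, seed=seed + 14)
    # truth coverage at district level
    unit_ids, agg = geo_mod.aggregate_draws(draws.draws, world, "district")
    t_ids, t_agg = geo_mod.aggregate_draws(usage[None, :, :], world, "district")
    lo = np.quantile(agg, 0.025, axis=0)
    hi = np.quantile(agg, 0.975, axis=0)
    covered = (t_agg[0] >= lo) & (t_agg[0] <= hi)
    pm = fit.hyper_posterior_mean
    return {
        "beta_hat": fit.beta_mean.tolist(),
        "beta_sd": fit.beta_sd.tolist(),
        "beta_z": ((fit.beta_mean - beta) / fit.beta_sd).tolist(),
        "range_hat": pm.spatial_range, "sd_hat": pm.marginal_sd, "rho_hat": pm.ar1_rho,
        "range_true": rc.gp_params.spatial_range, "sd_true": rc.gp_params.marginal_sd,
        "rho_true": rc.gp_params.ar1_rho,
        "district_coverage": float(np.mean(covered)),
        "n_district_years": int(covered.size),
    }


def recover_consumption_once(rc: RecoveryConfig, seed: int) -> dict:
    """One consumption replicate: truth -> observations -> stage1+ST-GPR."""
    world_cfg = synthetic.WorldConfig(**{**rc.consumption_world.__dict__, "seed": seed})
    world = synthetic.generate_world(world_cfg)
    registry = ddd_mod.ATCRegistry.load("2019")
    truth = synthetic.default_ground_truth(world, seed=seed, registry=registry)
    rng = np.random.default_rng(seed + 21)
    # usage covariate: true surface aggregated nationally (isolates the
    # consumption track from usage-model error)
    c_ids, c_agg = geo_mod.aggregate_draws(truth.usage_surface[None], world, "country")
    usage_country = geo_mod.summarise_draws(c_ids, c_agg, world.years)
    features = stgpr.build_national_features(world, usage_country)
    true_rates = truth.national_consumption.loc[world.lmic_countries()]
    obs = true_rates.reset_index().melt("country", var_name="year",
                                        value_name="ddd_per_1000_per_day")
    obs["year"] = obs["year"].astype(int)
    keep = rng.random(len(obs)) < rc.obs_coverage
    obs = obs[keep].copy()
    obs["ddd_per_1000_per_day"] *= np.exp(rng.normal(0, rc.obs_noise_sd, len(obs)))
    s1, _, _ = stgpr.stage1(features, obs, seed=seed + 22)
    # the simulation's observation noise is known, so it serves as the nugget
    params = stgpr.STGPRParams(nugget_sd=rc.obs_noise_sd, n_draws=rc.n_draws,
                               seed=seed + 23)
    sm = stgpr.stgpr_smooth(s1, obs, world, params)
    merged = sm.table.merge(
        true_rates.reset_index().melt("country", var_name="year", value_name="truth")
        .astype({"year": int}), on=["country", "year"])
    log_err = np.log(merged["mean"]) - np.log(merged["truth"])
    s1m = s1.merge(merged[["country", "year", "truth"]], on=["country", "year"])
    log_err_s1 = s1m["log_mean"] - np.log(s1m["truth"])
    return {
        "rmse_pipeline": float(np.sqrt(np.mean(log_err ** 2))),
        "rmse_stage1": float(np.sqrt(np.mean(log_err_s1 ** 2))),
        "n_obs": int(len(obs)),
    }


def smoothing_benefit_once(rc: RecoveryConfig, seed: int) -> dict:
    """Cross-validated smoothing benefit under the model's own assumptions.

    The true log-rate surface is a learnable function of the features plus
    a residual field drawn from the ST-GPR kernel itself (Matérn-3/2 in
    time, region-pooled across countries); observations add log-normal
    noise at the known sd. Out-of-country cross-validation then compares
    the smoothed pipeline against stage 1 alone and scores 95%-UI coverage
    of the held-out observations.
    """
    world_cfg = synthetic.WorldConfig(**{**rc.consumption_world.__dict__, "seed": seed})
    world = synthetic.generate_world(world_cfg)
    rng = np.random.default_rng(seed + 31)
    registry = ddd_mod.ATCRegistry.load("2019")
    truth = synthetic.default_ground_truth(world, seed=seed, registry=registry)
    c_ids, c_agg = geo_mod.aggregate_draws(truth.usage_surface[None], world, "country")
    usage_country = geo_mod.summarise_draws(c_ids, c_agg, world.years)
    features = stgpr.build_national_features(world, usage_country)
    feat_cols = [c for c in features.columns if c not in ("country", "year")]
    Xf = features[feat_cols].to_numpy(float)
    Xs = (Xf - Xf.mean(0)) / np.maximum(Xf.std(0), 1e-9)
    mu = np.log(14.0) + Xs @ rng.normal(0, 0.25, Xs.shape[1])
    params = stgpr.STGPRParams(nugget_sd=rc.obs_noise_sd, n_draws=rc.n_draws,
                               seed=seed + 32)
    index = features[["country", "year"]].reset_index(drop=True)
    K = stgpr._st_kernel(index, world.countries["region"], params, amplitude=0.3)
    evals, evecs = np.linalg.eigh(K + 1e-10 * np.eye(len(K)))
    u = evecs @ (np.sqrt(np.clip(evals, 0, None)) * rng.standard_normal(len(K)))
    latent = np.exp(mu + u)
    obs = index.copy()
    obs["ddd_per_1000_per_day"] = latent * np.exp(
        rng.normal(0, rc.obs_noise_sd, len(latent)))
    obs = obs[rng.random(len(obs)) < rc.obs_coverage].copy()
    cv = stgpr.cross_validate(features, obs, world, params=params,
                              n_folds=min(5, obs["country"].nunique()), seed=seed + 33)
    return {
        "cv_rmse_pipeline": float(cv["rmse_pipeline"].mean()),
        "cv_rmse_stage1": float(cv["rmse_stage1"].mean()),
        "cv_coverage": float(np.average(cv["ui_coverage"], weights=cv["n_test"])),
        "n_obs": int(len(obs)),
    }


def experiment_recovery(rc: RecoveryConfig | None = None, out_path=None) -> dict:
    """Run the replicate experiments and aggregate their scores."""
    rc = rc or RecoveryConfig()
    usage_rows, cons_rows, bene_rows = [], [], []
    for r in range(rc.n_replicates):
        usage_rows.append(recover_usage_once(rc, seed=rc.seed + 1000 * r))
        cons_rows.append(recover_consumption_once(rc, seed=rc.seed + 1000 * r + 500))
        bene_rows.append(smoothing_benefit_once(rc, seed=rc.seed + 1000 * r + 750))
    usage = pd.DataFrame(usage_rows)
    cons = pd.DataFrame(cons_rows)
    bene = pd.DataFrame(bene_rows)
    beta_z = np.array([z for zs in usage["beta_z"] for z in zs])
    report = {
        "n_replicates": rc.n_replicates,
        "usage": {
            "beta_max_abs_z": float(np.max(np.abs(np.array(
                [np.mean([r[i] for r in usage["beta_z"]]) for i in range(len(rc.beta))])))),
            "beta_share_within_3sd": float(np.mean(np.abs(beta_z) < 3)),
            "range_rel_err": float(abs(np.exp(np.mean(np.log(usage["range_hat"])))
                                       - rc.gp_params.spatial_range)
                                   / rc.gp_params.spatial_range),
            "sd_rel_err": float(abs(np.exp(np.mean(np.log(usage["sd_hat"])))
                                    - rc.gp_params.marginal_sd)
                                / rc.gp_params.marginal_sd),
            "rho_err": float(abs(np.mean(usage["rho_hat"]) - rc.gp_params.ar1_rho)),
            "district_coverage": float(np.average(usage["district_coverage"],
                                                  weights=usage["n_district_years"])),
        },
        "consumption": {
            "rmse_pipeline_mean": float(cons["rmse_pipeline"].mean()),
            "rmse_stage1_mean": float(cons["rmse_stage1"].mean()),
            "share_pipeline_beats_stage1": float(
                np.mean(bene["cv_rmse_pipeline"] <= bene["cv_rmse_stage1"])),
            "cv_coverage": float(np.average(bene["cv_coverage"],
                                            weights=bene["n_obs"])),
        },
        "per_replicate": {"usage": usage_rows, "consumption": cons_rows,
                          "smoothing_benefit": bene_rows},
    }
    from .schemas import validate_report
    validate_report(report)
    if out_path:
        Path(out_path).write_text(json.dumps(report, indent=1))
    return report
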