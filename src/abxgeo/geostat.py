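"""Binomial spatio-temporal geostatistical model of antibiotic usage.

The model for survey record *j* at cell *s(j)* and year *t(j)*:

    k_j ~ Binomial(N_j, p_{s(j),t(j)}),
    logit(p_{s,t}) = x_{s,t}' beta + w(s, t),

where *w* is a zero-mean Gaussian process with separable covariance

    Cov[w(s,t), w(s',t')] = sd^2 * Matern_nu(|s - s'|; range) * rho^{|t-t'|},

i.e. a Kronecker product of a stationary Matérn spatial correlation and an
AR1 temporal correlation. The spatial range parameter is the distance at
which the Matérn correlation has decayed to 0.1.

Inference is a Gaussian (Laplace) approximation of the posterior of
(beta, w) computed by Newton optimisation, with the covariance
hyperparameters selected by maximising the Laplace-approximate marginal
likelihood over a coarse grid centred at moment-based initial values.
Uncertainty is propagated by joint draws from the Gaussian approximation;
all summaries (admin-level means, 95% uncertainty intervals, the
relative-deviation report) are computed at the draw level.

Covariance matrices are handled densely, which is exact but caps the
problem size at 400 cells x 19 years.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve, cholesky, solve_triangular
from scipy.optimize import brentq
from scipy.special import gammaln, kve

from . import geo as geo_mod

MAX_CELLS = 400
MAX_YEARS = 19
JITTER = 1e-8

BETA_PRIOR_SD = 5.0


class FitError(RuntimeError):
    pass


# ---------------------------------------------------------------------------
# Covariance construction (single code path shared with the simulator)
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GPHyperparams:
    """Covariance hyperparameters of the space-time Gaussian process.

    ``spatial_range`` is the distance at which the Matérn correlation
    equals 0.1 (a practical-range convention); ``marginal_sd`` the process
    standard deviation; ``ar1_rho`` the year-to-year autocorrelation;
    ``matern_nu`` the smoothness, fixed at 1 by default and not estimated.
    """

    spatial_range: float
    marginal_sd: float
    ar1_rho: float
    matern_nu: float = 1.0

    def __post_init__(self):
        if self.spatial_range <= 0:
            raise ValueError("spatial_range must be positive")
        if self.marginal_sd < 0:
            raise ValueError("marginal_sd must be non-negative")
        if not -1 < self.ar1_rho < 1:
            raise ValueError("ar1_rho must lie in (-1, 1)")


def _matern_shape(u: np.ndarray, nu: float) -> np.ndarray:
    """Matérn correlation as a function of scaled distance u = d / lengthscale.

    Evaluated in log space with the exponentially scaled Bessel function so
    that large smoothness values (the squared-exponential limit) stay finite.
    """
    u = np.asarray(u, float)
    out = np.ones_like(u)
    pos = u > 0
    a = np.sqrt(2 * nu) * u[pos]
    log_c = ((1 - nu) * np.log(2.0) - gammaln(nu) + nu * np.log(a)
             + np.log(kve(nu, a)) - a)
    out[pos] = np.exp(log_c)
    return out


def _lengthscale_for_range(spatial_range: float, nu: float) -> float:
    """Lengthscale such that the correlation at ``spatial_range`` is 0.1."""
    u_star = brentq(lambda u: _matern_shape(np.array([u]), nu)[0] - 0.1, 1e-8, 50.0)
    return spatial_range / u_star


def matern_correlation(dists: np.ndarray, spatial_range: float, nu: float = 1.0) -> np.ndarray:
    ell = _lengthscale_for_range(spatial_range, nu)
    return _matern_shape(dists / ell, nu)


def ar1_correlation(years: np.ndarray, rho: float) -> np.ndarray:
    lags = np.abs(np.subtract.outer(years, years))
    return np.power(float(rho), lags) if rho != 0 else (lags == 0).astype(float)


@dataclass
class SpaceTimeCovariance:
    """Kronecker-structured covariance sd^2 * (K_space ⊗ K_time).

    The latent field is vectorised cell-major: entry ``s * n_years + t``.
    """

    K_space: np.ndarray
    K_time: np.ndarray
    marginal_sd: float

    def dense(self) -> np.ndarray:
        return self.marginal_sd ** 2 * np.kron(self.K_space, self.K_time)

    def precision_and_logdet(self):
        """(dense precision, log|covariance|) via Kronecker identities."""
        S, T = len(self.K_space), len(self.K_time)
        cs = cholesky(self.K_space, lower=True)
        ct = cholesky(self.K_time, lower=True)
        logdet_s = 2 * np.log(np.diag(cs)).sum()
        logdet_t = 2 * np.log(np.diag(ct)).sum()
        eye_s, eye_t = np.eye(S), np.eye(T)
        Ks_inv = cho_solve((cs, True), eye_s)
        Kt_inv = cho_solve((ct, True), eye_t)
        Q = np.kron(Ks_inv, Kt_inv) / self.marginal_sd ** 2
        logdet = S * T * 2 * np.log(self.marginal_sd) + T * logdet_s + S * logdet_t
        return Q, logdet

    def sample(self, n_draws: int, rng: np.random.Generator) -> np.ndarray:
        """Draws of the latent field, shape (n_draws, S*T)."""
        cs = cholesky(self.K_space, lower=True)
        ct = cholesky(self.K_time, lower=True)
        S, T = len(self.K_space), len(self.K_time)
        eps = rng.standard_normal((n_draws, S, T))
        out = np.einsum("ij,djk,lk->dil", cs, eps, ct) * self.marginal_sd
        return out.reshape(n_draws, S * T)


def build_space_time_covariance(geo: geo_mod.GeoFrame, hyper: GPHyperparams) -> SpaceTimeCovariance:
    """Dense Matérn(space) x AR1(time) covariance on the cell-year grid.

    This constructor is the single code path used both to simulate latent
    surfaces and to fit them, guaranteeing generative/inferential symmetry.
    """
    if geo.n_cells > MAX_CELLS or geo.n_years > MAX_YEARS:
        raise ValueError(
            f"dense covariance capped at {MAX_CELLS} cells x {MAX_YEARS} years; "
            f"got {geo.n_cells} x {geo.n_years}")
    coords = geo.coords
    d = np.linalg.norm(coords[:, None, :] - coords[None, :, :], axis=2)
    Ks = matern_correlation(d, hyper.spatial_range, hyper.matern_nu)
    Kt = ar1_correlation(geo.years, hyper.ar1_rho)
    Ks[np.diag_indices_from(Ks)] += JITTER
    Kt[np.diag_indices_from(Kt)] += JITTER
    for name, K in (("spatial", Ks), ("temporal", Kt)):
        try:
            cholesky(K, lower=True)
        except np.linalg.LinAlgError as e:  # pragma: no cover - defensive
            raise FitError(f"{name} correlation not positive definite after jitter") from e
    return SpaceTimeCovariance(K_space=Ks, K_time=Kt, marginal_sd=hyper.marginal_sd)


# ---------------------------------------------------------------------------
# Laplace approximation at fixed hyperparameters
# ---------------------------------------------------------------------------

def _data_arrays(records: pd.DataFrame, geo: geo_mod.GeoFrame):
    if not (records["location_type"] == "cell").all():
        raise ValueError("fit expects point (cell-referenced) records; resample polygons first")
    cell_pos = geo.cell_position(records["location"].to_numpy())
    if np.any(cell_pos < 0):
        raise KeyError("record references unknown cell id")
    years = records["year"].to_numpy(int)
    clamped = np.clip(years, geo.years.min(), geo.years.max())
    if np.any(clamped != years):
        warnings.warn("record years outside the study frame were clamped")
    t_pos = geo.year_index(clamped)
    idx = cell_pos * geo.n_years + t_pos
    return idx, records["k"].to_numpy(float), records["N"].to_numpy(float)


def _newton_laplace(idx, k, N, X, Q, logdet_prior, family="binomial",
                    gauss_var=1.0, y_gauss=None, z0=None, max_iter=100, tol=1e-9):
    """Newton-optimised Laplace approximation of the (beta, w) posterior.

    Returns (z_hat, H, log_marginal, n_iter). ``Q`` is the joint prior
    precision over z = (beta, w); ``X`` the data-row design; ``idx`` the
    cell-year index of each data row.
    """
    p = X.shape[1]
    M = Q.shape[0] - p
    z = np.zeros(Q.shape[0]) if z0 is None else z0.copy()

    def eta_of(z):
        return X @ z[:p] + z[p:][idx]

    def loglik_terms(eta):
        if family == "binomial":
            with np.errstate(over="ignore"):
                ll = k * eta - N * np.logaddexp(0.0, eta)
            mu = 1.0 / (1.0 + np.exp(-eta))
            g = k - N * mu
            W = np.maximum(N * mu * (1 - mu), 1e-12)
        else:
            r = y_gauss - eta
            ll = -0.5 * r ** 2 / gauss_var
            g = r / gauss_var
            W = np.full_like(eta, 1.0 / gauss_var)
        return ll.sum(), g, W

    def objective(z):
        ll, _, _ = loglik_terms(eta_of(z))
        return -ll + 0.5 * z @ (Q @ z)

    f = objective(z)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        eta = eta_of(z)
        _, g, W = loglik_terms(eta)
        grad = Q @ z
        grad[:p] -= X.T @ g
        np.subtract.at(grad, p + idx, g)
        H = Q.copy()
        H[:p, :p] += X.T @ (W[:, None] * X)
        XW = X * W[:, None]
        for j in range(p):
            np.add.at(H[j, p:], idx, XW[:, j])
        H[p:, :p] = H[:p, p:].T
        diagW = np.zeros(M)
        np.add.at(diagW, idx, W)
        H[p + np.arange(M), p + np.arange(M)] += diagW
        try:
            c = cho_factor(H, lower=True)
        except np.linalg.LinAlgError as e:
            raise FitError("posterior Hessian not positive definite") from e
        step = cho_solve(c, -grad)
        # backtracking line search on the penalised deviance
        alpha, f_new = 1.0, np.inf
        for _ in range(30):
            f_new = objective(z + alpha * step)
            if f_new <= f - 1e-4 * alpha * (grad @ step) or f_new < f:
                break
            alpha *= 0.5
        z = z + alpha * step
        if abs(f - f_new) < tol * (1 + abs(f)):
            f = f_new
            break
        f = f_new
    else:
        raise FitError(f"Newton did not converge in {max_iter} iterations (obj={f:.6g})")
    # final Hessian at the mode
    eta = eta_of(z)
    ll, g, W = loglik_terms(eta)
    H = Q.copy()
    H[:p, :p] += X.T @ (W[:, None] * X)
    XW = X * W[:, None]
    for j in range(p):
        np.add.at(H[j, p:], idx, XW[:, j])
    H[p:, :p] = H[:p, p:].T
    diagW = np.zeros(M)
    np.add.at(diagW, idx, W)
    H[p + np.arange(M), p + np.arange(M)] += diagW
    cH = cholesky(H, lower=True)
    logdet_H = 2 * np.log(np.diag(cH)).sum()
    log_marginal = ll - 0.5 * z @ (Q @ z) - 0.5 * logdet_prior - 0.5 * logdet_H
    return z, H, float(log_marginal), n_iter


@dataclass
class LatentFit:
    """Gaussian approximation of the posterior at selected hyperparameters."""

    z_mean: np.ndarray                  # (p + S*T,): beta then vec(w)
    hessian: np.ndarray                 # posterior precision of z
    hyper: GPHyperparams
    X_grid: np.ndarray                  # (S*T, p) design on the full grid
    n_beta: int
    n_cells: int
    n_years: int
    log_marginal_likelihood: float
    grid_table: pd.DataFrame = field(default_factory=pd.DataFrame)
    hyper_posterior_mean: GPHyperparams | None = None
    newton_iterations: int = 0

    @property
    def beta_mean(self) -> np.ndarray:
        return self.z_mean[:self.n_beta]

    @property
    def beta_sd(self) -> np.ndarray:
        cov = np.linalg.inv(self.hessian)
        return np.sqrt(np.diag(cov)[:self.n_beta])

    @property
    def w_mean(self) -> np.ndarray:
        return self.z_mean[self.n_beta:].reshape(self.n_cells, self.n_years)


def default_hyper_grid(records: pd.DataFrame, geo: geo_mod.GeoFrame,
                       n_points: int = 5, half_width: float = 1.5) -> list[GPHyperparams]:
    """Coarse hyperparameter grid centred at moment-based initial values.

    Range: half the median pairwise distance between surveyed cells;
    marginal sd: excess spread of the empirical logits beyond binomial
    noise; rho: 0.5. The grid spans ``±half_width`` in log (range, sd) and
    atanh (rho) units.
    """
    pos = geo.cell_position(records["location"].to_numpy())
    coords = geo.coords[np.unique(pos[pos >= 0])]
    if len(coords) > 1:
        d = np.linalg.norm(coords[:, None] - coords[None, :], axis=2)
        range0 = np.median(d[np.triu_indices_from(d, 1)]) / 2
    else:
        range0 = 1.0
    range0 = max(range0, 1e-3)
    k = records["k"].to_numpy(float)
    N = records["N"].to_numpy(float)
    p_emp = np.clip(k / N, 0.02, 0.98)
    z = np.log(p_emp / (1 - p_emp))
    noise = np.mean(1.0 / (N * p_emp * (1 - p_emp)))
    sd0 = float(np.clip(np.sqrt(max(np.var(z) - noise, 0.09)), 0.3, 3.0))
    rho0 = 0.5
    grid = []
    offs = np.linspace(-half_width, half_width, n_points)
    for lr in np.log(range0) + offs:
        for ls in np.log(sd0) + offs:
            for ar in np.arctanh(rho0) + offs:
                grid.append(GPHyperparams(float(np.exp(lr)), float(np.exp(ls)),
                                          float(np.tanh(ar))))
    return grid


def _refined_grid(best: GPHyperparams, spacing: float, n: int = 3) -> list[GPHyperparams]:
    offs = np.linspace(-spacing, spacing, n)
    out = []
    for lr in np.log(best.spatial_range) + offs:
        for ls in np.log(best.marginal_sd) + offs:
            for ar in np.arctanh(best.ar1_rho) + offs:
                out.append(GPHyperparams(float(np.exp(lr)), float(np.exp(ls)),
                                         float(np.tanh(ar)), best.matern_nu))
    return out


def fit(records: pd.DataFrame, X_data: np.ndarray, X_grid: np.ndarray,
        geo: geo_mod.GeoFrame, hyper_grid: list[GPHyperparams] | None = None,
        family: str = "binomial", gauss_var: float = 1.0,
        refine_rounds: int = 1, refine_spacing: float = 0.375) -> LatentFit:
    """Fit the space-time binomial model by grid-searched Laplace inference.

    Parameters
    ----------
    records:
        Point survey records (``location_type == "cell"``) with counts N, k.
        For ``family="gaussian"`` a column ``y`` holds the response and
        ``gauss_var`` the known observation variance (used to validate the
        Laplace machinery against closed-form GP regression).
    X_data, X_grid:
        Covariate design at the data rows and on the full cell-year grid
        (``(S*T, p)``, cell-major); typically the logit-scale child
        predictions of the stacked ensemble. May have zero columns.
    """
    idx, k, N = (None, None, None)
    if family == "binomial":
        idx, k, N = _data_arrays(records, geo)
        y_gauss = None
    else:
        idx, _, _ = _data_arrays(records.assign(k=0, N=1), geo)
        k = N = None
        y_gauss = records["y"].to_numpy(float)
    X_data = np.asarray(X_data, float)
    if X_data.ndim == 1:
        X_data = X_data[:, None]
    p = X_data.shape[1]
    X_grid = np.asarray(X_grid, float).reshape(geo.n_cells * geo.n_years, p)
    if hyper_grid is None:
        if family != "binomial":
            raise ValueError("supply hyper_grid explicitly for the gaussian variant")
        hyper_grid = default_hyper_grid(records, geo)

    M = geo.n_cells * geo.n_years
    rows, fits = [], []
    z_warm = None

    def scan(grid_points):
        nonlocal z_warm
        for hyper in grid_points:
            cov = build_space_time_covariance(geo, hyper)
            Q_w, logdet_w = cov.precision_and_logdet()
            Q = np.zeros((p + M, p + M))
            Q[:p, :p] = np.eye(p) / BETA_PRIOR_SD ** 2
            Q[p:, p:] = Q_w
            logdet_prior = logdet_w + p * 2 * np.log(BETA_PRIOR_SD)
            z_hat, H, lml, iters = _newton_laplace(
                idx, k, N, X_data, Q, logdet_prior, family=family,
                gauss_var=gauss_var, y_gauss=y_gauss, z0=z_warm)
            z_warm = z_hat
            rows.append({"spatial_range": hyper.spatial_range,
                         "marginal_sd": hyper.marginal_sd,
                         "ar1_rho": hyper.ar1_rho, "log_marginal": lml,
                         "newton_iters": iters})
            fits.append((z_hat, H, hyper, lml, iters))

    scan(hyper_grid)
    # local refinement around the incumbent at half the initial spacing:
    # the coarse grid alone cannot resolve hyperparameters to better than
    # its spacing, which the refinement pass halves
    spacing = refine_spacing
    for _ in range(refine_rounds):
        best_now = fits[int(np.argmax([f[3] for f in fits]))][2]
        seen = {(r["spatial_range"], r["marginal_sd"], r["ar1_rho"]) for r in rows}
        extra = [h for h in _refined_grid(best_now, spacing)
                 if (h.spatial_range, h.marginal_sd, h.ar1_rho) not in seen]
        scan(extra)
        spacing /= 2
    table = pd.DataFrame(rows)
    best = int(table["log_marginal"].idxmax())
    z_hat, H, hyper, lml, iters = fits[best]
    # posterior mean of the hyperparameters over the grid (uniform prior)
    wts = np.exp(table["log_marginal"] - table["log_marginal"].max())
    wts = wts / wts.sum()
    hyper_pm = GPHyperparams(
        spatial_range=float(np.exp(np.sum(wts * np.log(table["spatial_range"])))),
        marginal_sd=float(np.exp(np.sum(wts * np.log(table["marginal_sd"])))),
        ar1_rho=float(np.tanh(np.sum(wts * np.arctanh(table["ar1_rho"])))),
    )
    return LatentFit(z_mean=z_hat, hessian=H, hyper=hyper, X_grid=X_grid, n_beta=p,
                     n_cells=geo.n_cells, n_years=geo.n_years,
                     log_marginal_likelihood=lml, grid_table=table,
                     hyper_posterior_mean=hyper_pm, newton_iterations=iters)


# ---------------------------------------------------------------------------
# Posterior draws and admin-level estimates
# ---------------------------------------------------------------------------

@dataclass
class PosteriorDraws:
    draws: np.ndarray   # (n_draws, n_cells, n_years) of p in (0, 1)
    seed: int

    @property
    def n_draws(self) -> int:
        return self.draws.shape[0]


def draw_posterior(fit_result: LatentFit, n_draws: int = 1000, seed: int = 0) -> PosteriorDraws:
    """Joint Gaussian draws of (beta, w), mapped to probability surfaces."""
    rng = np.random.default_rng(seed)
    L = cholesky(fit_result.hessian, lower=True)
    eps = rng.standard_normal((len(fit_result.z_mean), n_draws))
    z = fit_result.z_mean[:, None] + solve_triangular(L, eps, lower=True, trans="T")
    p = fit_result.n_beta
    eta = fit_result.X_grid @ z[:p] + z[p:]
    surf = 1.0 / (1.0 + np.exp(-eta))  # (S*T, n_draws)
    draws = surf.T.reshape(n_draws, fit_result.n_cells, fit_result.n_years)
    return PosteriorDraws(draws=draws, seed=seed)


def linear_predictor_draws(fit_result: LatentFit, n_draws: int, seed: int) -> np.ndarray:
    """Draws of eta = X beta + w on the grid (link scale), for diagnostics."""
    rng = np.random.default_rng(seed)
    L = cholesky(fit_result.hessian, lower=True)
    eps = rng.standard_normal((len(fit_result.z_mean), n_draws))
    z = fit_result.z_mean[:, None] + solve_triangular(L, eps, lower=True, trans="T")
    p = fit_result.n_beta
    return (fit_result.X_grid @ z[:p] + z[p:]).T


def estimate_usage(draws: PosteriorDraws, geo: geo_mod.GeoFrame,
                   nodata_countries: list | None = None):
    """Aggregate posterior usage draws to admin levels and summarise.

    Returns ``(estimates, deviation_report)``: one EstimateTable frame with
    district/state/country rows (mean, percentile 95% UI), countries in
    ``nodata_countries`` replaced by their region's median national mean
    (flagged ``imputed``), and a per-country-year report of the range of
    district relative deviations.
    """
    tables = []
    country_draws = None
    district_draws = None
    for level in geo_mod.ADMIN_LEVELS:
        unit_ids, agg = geo_mod.aggregate_draws(draws.draws, geo, level)
        tables.append((level, unit_ids, agg))
        if level == "country":
            country_draws = (unit_ids, agg)
        if level == "district":
            district_draws = (unit_ids, agg)
    frames = []
    for level, unit_ids, agg in tables:
        frames.append(geo_mod.summarise_draws(unit_ids, agg, geo.years, level=level))
    est = pd.concat(frames, ignore_index=True)
    est["imputed"] = False
    if nodata_countries:
        c_ids, c_agg = country_draws
        for year_j, year in enumerate(geo.years):
            means = pd.Series(c_agg.mean(axis=0)[:, year_j], index=c_ids)
            means[means.index.isin(nodata_countries)] = np.nan
            filled, imput = geo_mod.region_median_fill(means, geo)
            for c in filled.index[imput]:
                sel = (est["level"] == "country") & (est["unit_id"] == c) & (est["year"] == year)
                est.loc[sel, ["mean", "lower", "upper"]] = [filled[c], np.nan, np.nan]
                est.loc[sel, "imputed"] = True
    # relative-deviation report from posterior-mean surfaces
    d_ids, d_agg = district_draws
    c_ids, c_agg = country_draws
    d_mean = d_agg.mean(axis=0)
    c_mean = c_agg.mean(axis=0)
    district_country = geo.cells.groupby("district_id")["country"].first()
    report = []
    for ci, country in enumerate(c_ids):
        members = [i for i, d in enumerate(d_ids) if district_country[d] == country]
        for tj, year in enumerate(geo.years):
            nat = c_mean[ci, tj]
            if not np.isfinite(nat) or nat <= 0:
                continue
            devs, rng_dev = geo_mod.relative_deviation(d_mean[members, tj], nat)
            report.append({"country": country, "year": int(year),
                           "deviation_range": rng_dev,
                           "max_deviation": float(np.max(devs)),
                           "min_deviation": float(np.min(devs))})
    return est, pd.DataFrame(report)
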