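"""Stacked ensemble of covariate learners.

Three child learners — an additive spline smoother, gradient-boosted
regression trees and an elastic-net penalised regression — are fit with
grouped five-fold cross-validation to produce out-of-sample predictions
for every training row. The ensemble serves two roles downstream:

* the usage track passes the (logit-transformed) child out-of-sample
  columns as covariates into the binomial geostatistical model;
* the consumption track combines the children into a single stage-1 mean
  via non-negative least squares weights normalised to the simplex.

Fold grouping keeps all rows of one survey (usage) or one country
(consumption) together, so out-of-sample truly means out-of-survey /
out-of-country and spatial leakage is avoided.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import BSpline
from scipy.optimize import nnls
from sklearn.ensemble import GradientBoostingRegressor
from sklearn.linear_model import ElasticNetCV
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler

PROB_CLAMP = 1e-6

CHILD_KINDS = ("additive-smoother", "boosted-trees", "elastic-net")


def logit(p):
    return np.log(p / (1.0 - p))


def expit(z):
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class ChildSpec:
    kind: str
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        if self.kind not in CHILD_KINDS:
            raise ValueError(f"unknown child kind {self.kind!r}")


def default_children() -> list[ChildSpec]:
    return [
        ChildSpec("additive-smoother", {"basis_size": 8, "penalty": 1.0}),
        ChildSpec("boosted-trees", {"n_estimators": 500, "max_depth": 3,
                                    "learning_rate": 0.05}),
        ChildSpec("elastic-net", {"l1_ratio": 0.5}),
    ]


# ---------------------------------------------------------------------------
# Child learners (all fit a weighted regression on a continuous response)
# ---------------------------------------------------------------------------

class AdditiveSmoother:
    """Additive model of univariate cubic B-spline smoothers.

    Fit by penalised weighted least squares with a second-difference
    penalty on each covariate's coefficient block — the same function
    class as a generalised additive model, realised with dense linear
    algebra only.
    """

    def __init__(self, basis_size: int = 8, penalty: float = 1.0):
        self.basis_size = int(basis_size)
        self.penalty = float(penalty)

    def _basis(self, x: np.ndarray, j: int) -> np.ndarray:
        lo, hi, knots = self._knots[j]
        xc = np.clip(x, lo, hi)
        return BSpline.design_matrix(xc, knots, 3).toarray()

    def fit(self, X, y, sample_weight=None):
        X = np.asarray(X, float)
        y = np.asarray(y, float)
        w = np.ones(len(y)) if sample_weight is None else np.asarray(sample_weight, float)
        self._knots = []
        blocks = [np.ones((len(y), 1))]
        pens = [np.zeros((1, 1))]
        for j in range(X.shape[1]):
            lo, hi = X[:, j].min(), X[:, j].max()
            if hi <= lo:  # constant covariate: no basis
                self._knots.append((lo, hi, None))
                continue
            n_int = max(self.basis_size - 3, 1)
            inner = np.quantile(X[:, j], np.linspace(0, 1, n_int + 1)[1:-1])
            knots = np.concatenate([[lo] * 4, np.unique(inner), [hi + 1e-9 * (hi - lo + 1)] * 4])
            self._knots.append((lo, hi, knots))
            B = self._basis(X[:, j], j)
            k = B.shape[1]
            D = np.diff(np.eye(k), 2, axis=0)
            blocks.append(B)
            pens.append(self.penalty * D.T @ D + 1e-8 * np.eye(k))
        D_full = np.hstack(blocks)
        P = np.zeros((D_full.shape[1], D_full.shape[1]))
        ofs = 0
        for p in pens:
            k = p.shape[0]
            P[ofs:ofs + k, ofs:ofs + k] = p
            ofs += k
        A = D_full.T @ (D_full * w[:, None]) + P
        b = D_full.T @ (w * y)
        self.coef_ = np.linalg.solve(A + 1e-10 * np.eye(len(A)), b)
        return self

    def predict(self, X):
        X = np.asarray(X, float)
        out = np.full(len(X), self.coef_[0])
        ofs = 1
        for j in range(X.shape[1]):
            lo, hi, knots = self._knots[j]
            if knots is None:
                continue
            B = self._basis(X[:, j], j)
            out += B @ self.coef_[ofs:ofs + B.shape[1]]
            ofs += B.shape[1]
        return out


def _make_child(spec: ChildSpec, seed: int):
    p = dict(spec.params)
    if spec.kind == "additive-smoother":
        return AdditiveSmoother(**p)
    if spec.kind == "boosted-trees":
        return GradientBoostingRegressor(
            n_estimators=p.get("n_estimators", 500),
            max_depth=p.get("max_depth", 3),
            learning_rate=p.get("learning_rate", 0.05),
            validation_fraction=0.2, n_iter_no_change=10,
            random_state=seed)
    if spec.kind == "elastic-net":
        return make_pipeline(StandardScaler(), ElasticNetCV(
            l1_ratio=p.get("l1_ratio", 0.5), cv=5, max_iter=20000, random_state=seed))
    raise ValueError(spec.kind)


def _fit_child(model, X, y, w):
    if w is None:
        model.fit(X, y)
        return model
    try:
        model.fit(X, y, sample_weight=w)
    except (TypeError, ValueError):
        # pipeline: route the weight to the final estimator
        model.fit(X, y, **{f"{model.steps[-1][0]}__sample_weight": w})
    return model


# ---------------------------------------------------------------------------
# Folds
# ---------------------------------------------------------------------------

def assign_folds(groups, n_folds: int = 5, seed: int = 0) -> np.ndarray:
    """Group-respecting fold assignment, balanced to within one group.

    All rows sharing a group label (one survey, one country) land in the
    same fold; shuffled groups are dealt round-robin over the folds.
    """
    groups = np.asarray(groups)
    uniq = np.unique(groups)
    if n_folds < 2:
        raise ValueError("need n_folds >= 2")
    if len(uniq) < n_folds:
        raise ValueError(f"only {len(uniq)} groups for {n_folds} folds")
    rng = np.random.default_rng(seed)
    order = rng.permutation(uniq)
    fold_of = {g: i % n_folds for i, g in enumerate(order)}
    return np.array([fold_of[g] for g in groups], dtype=int)


# ---------------------------------------------------------------------------
# Out-of-sample child fits and stacking weights
# ---------------------------------------------------------------------------

@dataclass
class StackResult:
    oos_predictions: np.ndarray          # (n_rows, n_children), response scale
    full_fit_predictors: list            # refit on all rows
    fold_assignment: np.ndarray
    child_names: list[str]
    outcome_family: str
    stack_weights: np.ndarray | None = None

    def predict_full(self, X) -> np.ndarray:
        """(n_rows, n_children) predictions from the all-data refits."""
        cols = [_predict_response(m, X, self.outcome_family)
                for m in self.full_fit_predictors]
        return np.column_stack(cols)

    def combined(self, X) -> np.ndarray:
        if self.stack_weights is None:
            raise ValueError("stack weights not fitted")
        return self.predict_full(X) @ self.stack_weights


def _prepare_response(y, weights, family):
    if family == "binomial":
        k = np.asarray(y[0], float)
        N = np.asarray(y[1], float)
        p = np.clip(k / N, PROB_CLAMP, 1 - PROB_CLAMP)
        z = logit(p)
        w = N if weights is None else N * np.asarray(weights, float)
        if np.all(k == 0) or np.all(k == N):
            import warnings
            warnings.warn("degenerate binomial response (all 0 or all N)")
        return z, w
    z = np.asarray(y, float)
    w = None if weights is None else np.asarray(weights, float)
    return z, w


def _predict_response(model, X, family):
    z = model.predict(np.asarray(X, float))
    if family == "binomial":
        return np.clip(expit(z), PROB_CLAMP, 1 - PROB_CLAMP)
    return z


def fit_children_oos(X, y, weights, specs: list[ChildSpec], fold_assignment,
                     outcome_family: str = "gaussian", seed: int = 0) -> StackResult:
    """Fit each child per fold and predict the held-out rows.

    ``y`` is a ``(k, N)`` pair of count arrays for the binomial family
    (children are then fit on empirical proportions on the logit scale,
    with N as weights) or a plain response vector for the gaussian family.
    ``full_fit_predictors`` are refit on all rows for grid prediction.
    """
    X = np.asarray(X, float)
    folds = np.asarray(fold_assignment, int)
    z, w = _prepare_response(y, weights, outcome_family)
    n = len(z)
    oos = np.full((n, len(specs)), np.nan)
    for f in np.unique(folds):
        tr, te = folds != f, folds == f
        for c, spec in enumerate(specs):
            model = _fit_child(_make_child(spec, seed + 1000 * c + f), X[tr], z[tr],
                               None if w is None else w[tr])
            oos[te, c] = _predict_response(model, X[te], outcome_family)
    full = [_fit_child(_make_child(spec, seed + 1000 * c), X, z, w)
            for c, spec in enumerate(specs)]
    return StackResult(oos_predictions=oos, full_fit_predictors=full,
                       fold_assignment=folds, child_names=[s.kind for s in specs],
                       outcome_family=outcome_family)


def fit_stack_weights(oos_predictions: np.ndarray, y, outcome_family: str = "gaussian",
                      weights=None) -> np.ndarray:
    """Simplex stacking weights by non-negative least squares.

    Weights solve ``min ||y - P w||`` over ``w >= 0`` and are then
    normalised to sum to one. For the binomial family the target is the
    empirical proportion and rows are weighted by N.
    """
    P = np.asarray(oos_predictions, float)
    if P.ndim != 2 or P.shape[1] < 1:
        raise ValueError("need at least one child column")
    if np.any(np.all(P == 0, axis=0)):
        raise ValueError("all-zero child column")
    if outcome_family == "binomial":
        k, N = np.asarray(y[0], float), np.asarray(y[1], float)
        target = k / N
        w_row = N
    else:
        target = np.asarray(y, float)
        w_row = np.ones(len(target)) if weights is None else np.asarray(weights, float)
    sw = np.sqrt(w_row)
    coef, _ = nnls(P * sw[:, None], target * sw)
    if coef.sum() <= 0:
        coef = np.ones(P.shape[1])
    return coef / coef.sum()
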