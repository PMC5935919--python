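"""L1-penalized logistic regression with per-feature penalty weights.

The fitting surface used by the two-stage iterated LASSO pipeline:

* :func:`standardize` — column centering/scaling (population SD) with the
  parameters retained for prediction and coefficient back-transformation;
* :func:`fit_penalized` — weighted-L1 logistic fit at one ``lambda``;
* :func:`lambda_grid` / :func:`cv_select_lambda` — descending log-spaced
  penalty path and stratified cross-validated selection by out-of-fold
  log-likelihood;
* :func:`adaptive_weights` — inverse-magnitude penalty weights for the
  adaptive stage.

The penalty multiplies the summed (not averaged) log-likelihood, matching the
parametrization of the classical ``penalized``-style software family; lambda
values are comparable only under this convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.model_selection import StratifiedKFold

from ._solver import _logistic_irls, kkt_residual, neg_loglik, penalized_objective
from .errors import FitError, ValidationError

__all__ = [
    "Standardization",
    "standardize",
    "PenalizedFit",
    "fit_penalized",
    "lambda_grid",
    "CvResult",
    "cv_select_lambda",
    "adaptive_weights",
]

_DIVERGENCE_BOUND = 1e4  # |coef| beyond this on any scale means separation


@dataclass(frozen=True)
class Standardization:
    """Per-column center/scale and the convention used to compute them."""

    columns: tuple[str, ...]
    center: np.ndarray
    scale: np.ndarray
    ddof: int = 0  # population-SD convention

    def transform(self, X: np.ndarray) -> np.ndarray:
        return (X - self.center) / self.scale

    def subset(self, columns) -> "Standardization":
        idx = [self.columns.index(c) for c in columns]
        return Standardization(
            tuple(columns), self.center[idx], self.scale[idx], self.ddof
        )

    def beta_to_raw(self, intercept: float, beta: np.ndarray) -> tuple[float, np.ndarray]:
        """Map standardized-scale coefficients to the original (ppb) scale."""
        raw = beta / self.scale
        return intercept - float(np.sum(raw * self.center)), raw

    def beta_to_std(self, intercept: float, beta: np.ndarray) -> tuple[float, np.ndarray]:
        std = beta * self.scale
        return intercept + float(np.sum(beta * self.center)), std


def standardize(
    X: np.ndarray, columns, *, ddof: int = 0
) -> tuple[np.ndarray, Standardization]:
    """Center and scale columns to mean 0, SD 1 (population SD by default)."""
    X = np.asarray(X, dtype=float)
    center = X.mean(axis=0)
    scale = X.std(axis=0, ddof=ddof)
    zero = np.flatnonzero(scale == 0)
    if zero.size:
        names = [columns[j] for j in zero]
        raise ValidationError(f"zero-variance feature(s): {names}")
    params = Standardization(tuple(columns), center, scale, ddof)
    return params.transform(X), params


@dataclass(frozen=True)
class PenalizedFit:
    """A fitted weighted-L1 logistic model at a single lambda."""

    columns: tuple[str, ...]
    intercept: float
    beta: np.ndarray
    lam: float
    weights: np.ndarray  # per-feature penalty weights; inf = forced out
    converged: bool
    n_iter: int
    kkt: float  # independent subgradient residual at the solution
    objective_value: float
    standardization: Standardization | None = None

    @property
    def active(self) -> tuple[str, ...]:
        return tuple(c for c, b in zip(self.columns, self.beta) if b != 0.0)

    def linear_predictor(self, X: np.ndarray) -> np.ndarray:
        return self.intercept + X @ self.beta

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        return 1.0 / (1.0 + np.exp(-self.linear_predictor(X)))


def _validate_xy(X, y):
    X = np.ascontiguousarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.ndim != 2 or y.shape != (X.shape[0],):
        raise ValidationError("X must be (n, p) and y of length n")
    if not np.all(np.isin(y, (0.0, 1.0))):
        raise ValidationError("y must be binary 0/1")
    return X, y


def fit_penalized(
    X: np.ndarray,
    y: np.ndarray,
    lam: float,
    weights: np.ndarray | None = None,
    *,
    columns=None,
    tol: float = 1e-8,
    max_iter: int = 200,
    cd_sweeps: int = 100_000,
    warm_start: tuple[float, np.ndarray] | None = None,
    standardization: Standardization | None = None,
) -> PenalizedFit:
    """Minimize -loglik + lam * sum_j weights_j |beta_j| (intercept unpenalized).

    Convergence is declared on the subgradient (KKT) residual of the logistic
    objective, checked at ``max(tol, 1e-7)`` absolute; non-convergence is
    flagged on the returned fit, and unpenalized divergence (perfect
    separation) raises :class:`FitError`.
    """
    X, y = _validate_xy(X, y)
    n, p = X.shape
    if lam < 0:
        raise ValidationError("lambda must be >= 0")
    w = np.ones(p) if weights is None else np.asarray(weights, dtype=float).copy()
    if w.shape != (p,) or np.any(w < 0):
        raise ValidationError("weights must be a non-negative length-p vector")
    if columns is None:
        columns = tuple(f"x{j}" for j in range(p))

    if warm_start is not None:
        b0, beta = float(warm_start[0]), np.array(warm_start[1], dtype=float)
    else:
        ybar = y.mean()
        b0 = float(np.log(ybar / (1 - ybar))) if 0 < ybar < 1 else 0.0
        beta = np.zeros(p)
    beta[~np.isfinite(w)] = 0.0

    kkt_tol = max(tol, 1e-7)
    beta, b0, n_it, _ = _logistic_irls(
        X, y, float(lam), w, beta, b0, kkt_tol, max_iter, tol, cd_sweeps
    )
    if not np.all(np.isfinite(beta)) or not np.isfinite(b0):
        raise FitError("solver produced non-finite coefficients")
    if max(np.max(np.abs(beta), initial=0.0), abs(b0)) > _DIVERGENCE_BOUND:
        raise FitError(
            "coefficients diverged (perfect separation with an insufficient penalty)"
        )
    kkt = kkt_residual(X, y, beta, b0, float(lam), w)
    # with no effective penalty a separable dataset has no MLE: the deviance
    # drains to zero while the score never vanishes
    finite_w = w[np.isfinite(w)]
    if (lam == 0.0 or finite_w.sum() == 0.0) and kkt > kkt_tol:
        if neg_loglik(X, y, beta, b0) < 0.05 * max(1.0, n / 100):
            raise FitError("perfect separation: unpenalized likelihood diverges")
    return PenalizedFit(
        columns=tuple(columns),
        intercept=b0,
        beta=beta,
        lam=float(lam),
        weights=w,
        converged=bool(kkt <= kkt_tol * 10),
        n_iter=int(n_it),
        kkt=float(kkt),
        objective_value=penalized_objective(X, y, beta, b0, float(lam), w),
        standardization=standardization,
    )


def lambda_max(X: np.ndarray, y: np.ndarray, weights: np.ndarray | None = None) -> float:
    """Smallest lambda at which every penalized coefficient is zero."""
    X, y = _validate_xy(X, y)
    w = np.ones(X.shape[1]) if weights is None else np.asarray(weights, dtype=float)
    score = np.abs(X.T @ (y - y.mean()))
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = np.where(w > 0, score / w, np.inf)
    ratio = ratio[np.isfinite(w) & (w > 0)]
    if ratio.size == 0:
        raise ValidationError("no penalized feature with finite positive weight")
    return float(ratio.max())


def lambda_grid(
    X: np.ndarray,
    y: np.ndarray,
    weights: np.ndarray | None = None,
    *,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> np.ndarray:
    """Descending log-spaced grid from lambda_max down to lambda_max*min_ratio."""
    lmax = lambda_max(X, y, weights)
    return np.geomspace(lmax, lmax * min_ratio, n_lambda)


@dataclass(frozen=True)
class CvResult:
    """Cross-validated lambda selection record."""

    lambda_grid: np.ndarray  # descending
    cv_score: np.ndarray  # summed out-of-fold log-likelihood per lambda
    lambda_chosen: float
    fold_assignments: np.ndarray  # fold index per observation
    n_folds: int
    seed: int
    chosen_index: int = field(default=-1)

    def __post_init__(self):
        if self.chosen_index < 0:
            object.__setattr__(
                self, "chosen_index", int(np.flatnonzero(self.lambda_grid == self.lambda_chosen)[0])
            )


def _path_fits(X, y, grid, weights, tol=1e-8, max_iter=200):
    """Warm-started fits along a descending lambda grid; yields (b0, beta)."""
    warm = None
    out = []
    for lam in grid:
        fit = fit_penalized(
            X, y, lam, weights, tol=tol, max_iter=max_iter, warm_start=warm
        )
        warm = (fit.intercept, fit.beta.copy())
        out.append(fit)
    return out


#: Fold fits along the CV path only rank lambdas, so they run at a looser
#: subgradient tolerance than returned fits (which keep the tight default).
CV_PATH_TOL = 1e-4


def cv_select_lambda(
    X: np.ndarray,
    y: np.ndarray,
    *,
    n_folds: int = 50,
    grid: np.ndarray | None = None,
    weights: np.ndarray | None = None,
    seed: int = 0,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
    tol: float | None = None,
) -> CvResult:
    """Choose lambda by stratified k-fold out-of-fold log-likelihood.

    Folds are stratified by outcome and drawn reproducibly from ``seed``;
    the score is the held-out log-likelihood summed over folds; ties on the
    score go to the larger lambda (parsimony).
    """
    X, y = _validate_xy(X, y)
    n = X.shape[0]
    n_pos, n_neg = int(y.sum()), int(n - y.sum())
    if n_folds > n:
        raise ValidationError(f"n_folds={n_folds} exceeds n={n}")
    if n_folds > min(n_pos, n_neg):
        raise ValidationError(
            f"n_folds={n_folds} exceeds the smaller class count "
            f"({min(n_pos, n_neg)}); folds would lose a class"
        )
    if grid is None:
        grid = lambda_grid(X, y, weights, n_lambda=n_lambda, min_ratio=min_ratio)
    grid = np.asarray(grid, dtype=float)
    if np.any(np.diff(grid) > 0):
        raise ValidationError("lambda grid must be descending")

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    assignments = np.empty(n, dtype=int)
    scores = np.zeros(grid.size)
    for k, (tr, te) in enumerate(skf.split(X, y)):
        assignments[te] = k
        if len(np.unique(y[tr])) < 2:
            raise ValidationError(f"fold {k}: training part has a single class")
        fits = _path_fits(
            X[tr], y[tr], grid, weights,
            tol=CV_PATH_TOL if tol is None else tol, max_iter=50,
        )
        for g, fit in enumerate(fits):
            scores[g] -= neg_loglik(X[te], y[te], fit.beta, fit.intercept)
    best = np.flatnonzero(scores == scores.max())
    chosen = int(best[0])  # grid is descending: first maximizer = largest lambda
    return CvResult(
        lambda_grid=grid,
        cv_score=scores,
        lambda_chosen=float(grid[chosen]),
        fold_assignments=assignments,
        n_folds=n_folds,
        seed=seed,
        chosen_index=chosen,
    )


def adaptive_weights(beta: np.ndarray) -> np.ndarray:
    """Inverse-magnitude penalty weights: w_j = 1/|beta_j|, 0 -> inf.

    A coefficient shrunk to zero in the first stage gets infinite weight and
    is thereby eliminated from the adaptive fit.
    """
    beta = np.asarray(beta, dtype=float)
    with np.errstate(divide="ignore"):
        return np.where(beta == 0.0, np.inf, 1.0 / np.abs(beta))
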