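"""The two-stage iterated LASSO / adaptive-LASSO diagnostic pipeline.

Stage 1 (screen): one LASSO over age, sex and every retained VOC at a
cross-validated penalty; terms with zero coefficient are eliminated, the
surviving coefficients themselves are discarded (only membership matters).

Stage 2 (iterated fit on the survivors, age always offered):
a LASSO at a cross-validated penalty produces pilot coefficients, whose
inverse magnitudes become per-term penalty weights for an adaptive LASSO —
again with cross-validated penalty — whose nonzero terms form the final
diagnostic model.  Confidence intervals come from a subject-level stratified
bootstrap of the adaptive fit with selection, penalty and weights frozen.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from . import __version__ as _pkg_version
from .cohort import CohortTable
from .errors import FitError, ValidationError
from .lasso import (
    CvResult,
    PenalizedFit,
    Standardization,
    adaptive_weights,
    cv_select_lambda,
    fit_penalized,
    standardize,
)

__all__ = ["ScreenResult", "DiagnosticModel", "screen_stage", "iterated_fit", "bootstrap_ci"]

log = logging.getLogger(__name__)


def _stage_seeds(seed: int, n: int = 4) -> list[int]:
    """Independent sub-seeds (< 2**31) for each stochastic stage."""
    return [int(s) for s in np.random.SeedSequence(seed).generate_state(n) % (2**31)]


@dataclass(frozen=True)
class ScreenResult:
    """Stage-1 output: surviving terms and the (discarded) screen coefficients."""

    retained: tuple[str, ...]  # nonzero terms (covariates and/or VOCs)
    fit: PenalizedFit
    cv: CvResult

    @property
    def retained_features(self) -> tuple[str, ...]:
        return tuple(t for t in self.retained if t not in CohortTable.COVARIATES)


@dataclass(frozen=True)
class DiagnosticModel:
    """The deployable diagnostic model.

    Coefficients are stored on both the standardized scale (the fitting
    scale) and the original scale (ppb for VOCs, years for age); the two are
    algebraically equivalent predictors.  ``cutoff`` is the probability
    threshold chosen at the training operating point; ``ci`` holds bootstrap
    percentile intervals per term and scale once attached.
    """

    terms: tuple[str, ...]  # selected terms, nonzero coefficients
    intercept_std: float
    beta_std: np.ndarray  # over terms, standardized scale
    intercept_raw: float
    beta_raw: np.ndarray  # over terms, original scale
    standardization: Standardization  # over adaptive_terms (training data)
    adaptive_terms: tuple[str, ...]  # stage-2 candidate set (selection frozen)
    adaptive_penalty_weights: np.ndarray  # over adaptive_terms
    lambdas: dict  # {"screen": .., "lasso": .., "adaptive": ..}
    seed: int
    cutoff: float | None = None
    ci: dict | None = None  # {"standardized": {term: [lo, hi]}, "raw": {...}}
    n_training: int = 0
    version: str = _pkg_version

    def __post_init__(self):
        if self.cutoff is not None and not (0.0 < self.cutoff < 1.0):
            raise ValidationError("cutoff must lie strictly inside (0, 1)")
        if any(b == 0 for b in self.beta_std):
            raise ValidationError("selected terms must have nonzero coefficients")

    @property
    def is_null(self) -> bool:
        return len(self.terms) == 0

    @property
    def selected_vocs(self) -> tuple[str, ...]:
        return tuple(t for t in self.terms if t not in CohortTable.COVARIATES)

    def coefficient(self, term: str, scale: str = "raw") -> float:
        beta = self.beta_raw if scale == "raw" else self.beta_std
        return float(beta[self.terms.index(term)])

    def predict_proba(self, table: CohortTable) -> np.ndarray:
        """Score subjects with the frozen model (training-time scaling)."""
        for t in self.terms:
            if t not in table.frame.columns:
                raise ValidationError(f"cohort lacks model term {t!r}")
        if self.is_null:
            eta = np.full(table.n, self.intercept_raw)
        else:
            X = table.frame[list(self.terms)].to_numpy(dtype=float)
            eta = self.intercept_raw + X @ self.beta_raw
        return 1.0 / (1.0 + np.exp(-eta))

    def with_cutoff(self, cutoff: float) -> "DiagnosticModel":
        return dataclasses.replace(self, cutoff=float(cutoff))

    def with_ci(self, ci: dict) -> "DiagnosticModel":
        return dataclasses.replace(self, ci=ci)

    # -- serialization (bit-exact float round-trip via JSON repr) ----------

    def to_dict(self) -> dict:
        return {
            "format": "breathvoc-diagnostic-model",
            "version": self.version,
            "seed": self.seed,
            "n_training": self.n_training,
            "terms": list(self.terms),
            "intercept_std": self.intercept_std,
            "beta_std": [float(b) for b in self.beta_std],
            "intercept_raw": self.intercept_raw,
            "beta_raw": [float(b) for b in self.beta_raw],
            "standardization": {
                "columns": list(self.standardization.columns),
                "center": [float(c) for c in self.standardization.center],
                "scale": [float(s) for s in self.standardization.scale],
                "ddof": self.standardization.ddof,
            },
            "adaptive_terms": list(self.adaptive_terms),
            "adaptive_penalty_weights": [
                None if not np.isfinite(w) else float(w)
                for w in self.adaptive_penalty_weights
            ],
            "lambdas": {k: float(v) for k, v in self.lambdas.items()},
            "cutoff": self.cutoff,
            "ci": self.ci,
        }

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, d: dict) -> "DiagnosticModel":
        if d.get("format") != "breathvoc-diagnostic-model":
            raise ValidationError("not a diagnostic-model document")
        std = Standardization(
            tuple(d["standardization"]["columns"]),
            np.array(d["standardization"]["center"], dtype=float),
            np.array(d["standardization"]["scale"], dtype=float),
            int(d["standardization"]["ddof"]),
        )
        return cls(
            terms=tuple(d["terms"]),
            intercept_std=float(d["intercept_std"]),
            beta_std=np.array(d["beta_std"], dtype=float),
            intercept_raw=float(d["intercept_raw"]),
            beta_raw=np.array(d["beta_raw"], dtype=float),
            standardization=std,
            adaptive_terms=tuple(d["adaptive_terms"]),
            adaptive_penalty_weights=np.array(
                [np.inf if w is None else w for w in d["adaptive_penalty_weights"]],
                dtype=float,
            ),
            lambdas={k: float(v) for k, v in d["lambdas"].items()},
            seed=int(d["seed"]),
            cutoff=None if d.get("cutoff") is None else float(d["cutoff"]),
            ci=d.get("ci"),
            n_training=int(d.get("n_training", 0)),
            version=d.get("version", _pkg_version),
        )

    @classmethod
    def from_json(cls, source: str | Path) -> "DiagnosticModel":
        p = Path(source)
        text = p.read_text() if p.exists() else str(source)
        try:
            return cls.from_dict(json.loads(text))
        except (json.JSONDecodeError, KeyError) as e:
            raise ValidationError(f"corrupt model document: {e}") from e


def _design_std(table: CohortTable, columns=None):
    X, cols = table.design(columns)
    Xs, std = standardize(X, cols)
    return Xs, table.outcome.astype(float), cols, std


def screen_stage(
    table: CohortTable,
    seed: int = 0,
    *,
    n_folds: int = 50,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> ScreenResult:
    """Stage-1 LASSO screen over age, sex and all panel features."""
    Xs, y, cols, std = _design_std(table)
    cv = cv_select_lambda(
        Xs, y, n_folds=n_folds, seed=seed, n_lambda=n_lambda, min_ratio=min_ratio
    )
    fit = fit_penalized(Xs, y, cv.lambda_chosen, columns=cols, standardization=std)
    retained = fit.active
    if not retained:
        log.warning("screen stage retained no terms: null model")
    return ScreenResult(retained=retained, fit=fit, cv=cv)


def iterated_fit(
    table: CohortTable,
    seed: int = 0,
    *,
    n_folds: int = 50,
    n_lambda: int = 100,
    min_ratio: float = 1e-4,
) -> DiagnosticModel:
    """Run screen -> LASSO -> adaptive LASSO and return the final model.

    Every stage's penalty is chosen by ``n_folds``-fold stratified
    cross-validation with a stage-specific sub-seed derived from ``seed``.
    Age is always offered to stage 2 even if the screen dropped it.
    """
    s_screen, s_lasso, s_adapt, _ = _stage_seeds(seed)
    screen = screen_stage(
        table, s_screen, n_folds=n_folds, n_lambda=n_lambda, min_ratio=min_ratio
    )
    retained = set(screen.retained) | {"age"}
    _, all_cols = table.design()
    terms2 = [c for c in all_cols if c in retained]

    Xs, y, cols, std = _design_std(table, terms2)
    cv_lasso = cv_select_lambda(
        Xs, y, n_folds=n_folds, seed=s_lasso, n_lambda=n_lambda, min_ratio=min_ratio
    )
    pilot = fit_penalized(Xs, y, cv_lasso.lambda_chosen, columns=cols)

    weights = adaptive_weights(pilot.beta)
    lambdas = {"screen": screen.cv.lambda_chosen, "lasso": cv_lasso.lambda_chosen}
    if not np.any(np.isfinite(weights)):
        log.warning("pilot LASSO shrank every term to zero: null model")
        return _null_model(table, std, tuple(cols), weights, lambdas, seed)

    cv_adapt = cv_select_lambda(
        Xs, y, n_folds=n_folds, weights=weights, seed=s_adapt,
        n_lambda=n_lambda, min_ratio=min_ratio,
    )
    final = fit_penalized(Xs, y, cv_adapt.lambda_chosen, weights, columns=cols)
    lambdas["adaptive"] = cv_adapt.lambda_chosen
    if not final.converged:
        raise FitError("adaptive stage did not converge")

    sel = [j for j, b in enumerate(final.beta) if b != 0.0]
    if not sel:
        log.warning("adaptive stage shrank every term to zero: null model")
        return _null_model(table, std, tuple(cols), weights, lambdas, seed)
    sel_terms = tuple(cols[j] for j in sel)
    beta_std = final.beta[sel]
    sub = std.subset(sel_terms)
    intercept_raw, beta_raw = sub.beta_to_raw(final.intercept, beta_std)
    return DiagnosticModel(
        terms=sel_terms,
        intercept_std=final.intercept,
        beta_std=beta_std,
        intercept_raw=intercept_raw,
        beta_raw=beta_raw,
        standardization=std,
        adaptive_terms=tuple(cols),
        adaptive_penalty_weights=weights,
        lambdas=lambdas,
        seed=seed,
        n_training=table.n,
    )


def _null_model(table, std, cols, weights, lambdas, seed) -> DiagnosticModel:
    ybar = table.outcome.mean()
    b0 = float(np.log(ybar / (1 - ybar))) if 0 < ybar < 1 else 0.0
    lambdas = dict(lambdas)
    lambdas.setdefault("adaptive", float("nan"))
    return DiagnosticModel(
        terms=(),
        intercept_std=b0,
        beta_std=np.empty(0),
        intercept_raw=b0,
        beta_raw=np.empty(0),
        standardization=std,
        adaptive_terms=cols,
        adaptive_penalty_weights=weights,
        lambdas=lambdas,
        seed=seed,
        n_training=table.n,
    )


def bootstrap_ci(
    table: CohortTable,
    model: DiagnosticModel,
    *,
    n_boot: int = 200,
    seed: int = 0,
    level: float = 0.95,
    resample: bool = True,
) -> DiagnosticModel:
    """Percentile bootstrap CIs for the final model's coefficients.

    Subjects are resampled with replacement, stratified by outcome (class
    counts preserved), and the adaptive-LASSO stage is refit on each resample
    with the selected candidate set, penalty and weights frozen at their
    training values; the training standardization is reused so coefficients
    are comparable across resamples.  ``resample=False`` is a degenerate mode
    (every draw is the original data) useful to verify the machinery.
    """
    if n_boot < 2:
        raise ValidationError("n_boot must be >= 2")
    if model.is_null:
        raise ValidationError("cannot bootstrap a null model")
    rng = np.random.default_rng(seed)
    cols = list(model.adaptive_terms)
    X_raw = table.frame[cols].to_numpy(dtype=float)
    Xs = model.standardization.transform(X_raw)
    y = table.outcome.astype(float)
    idx_case = np.flatnonzero(y == 1)
    idx_ctrl = np.flatnonzero(y == 0)
    lam = model.lambdas["adaptive"]
    w = model.adaptive_penalty_weights

    draws_std = np.empty((n_boot, len(cols) + 1))  # intercept first
    for b in range(n_boot):
        for attempt in range(10):
            if resample:
                idx = np.concatenate([
                    rng.choice(idx_case, idx_case.size, replace=True),
                    rng.choice(idx_ctrl, idx_ctrl.size, replace=True),
                ])
            else:
                idx = np.arange(y.size)
            if len(np.unique(y[idx])) == 2:
                break
            log.warning("bootstrap resample %d attempt %d single-class; redrawing", b, attempt)
        else:
            raise FitError(f"bootstrap resample {b}: single class after 10 redraws")
        fit = fit_penalized(Xs[idx], y[idx], lam, w, columns=cols)
        draws_std[b, 0] = fit.intercept
        draws_std[b, 1:] = fit.beta

    # per-draw raw-scale coefficients (componentwise back-transform)
    scale = model.standardization.scale
    center = model.standardization.center
    draws_raw = np.empty_like(draws_std)
    draws_raw[:, 1:] = draws_std[:, 1:] / scale
    draws_raw[:, 0] = draws_std[:, 0] - draws_raw[:, 1:] @ center

    lo_q, hi_q = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    ci = {"level": level, "n_boot": n_boot, "standardized": {}, "raw": {}}
    for scale_name, draws in (("standardized", draws_std), ("raw", draws_raw)):
        out = ci[scale_name]
        out["intercept"] = [
            float(np.percentile(draws[:, 0], lo_q)),
            float(np.percentile(draws[:, 0], hi_q)),
        ]
        for t in model.terms:
            j = 1 + cols.index(t)
            out[t] = [
                float(np.percentile(draws[:, j], lo_q)),
                float(np.percentile(draws[:, j], hi_q)),
            ]
    return model.with_ci(ci)
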