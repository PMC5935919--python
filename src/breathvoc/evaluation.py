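"""ROC analysis, operating-point selection and frozen-model validation.

Classification rule: predicted probability >= cutoff calls a case.  The
default operating-point policy maximizes specificity subject to 100%
training sensitivity (no false negatives), mirroring a rule-out screening
use; an alternative policy hits a target sensitivity instead.  Displayed
percentages are rounded half-up to one decimal; the integer confusion counts
are always the primary state.
"""

from __future__ import annotations

import decimal
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd
from sklearn import metrics as _skm

from .errors import ValidationError

__all__ = [
    "RocResult",
    "ConfusionReport",
    "roc_curve",
    "choose_cutoff",
    "confusion_at",
    "validate_cohort",
    "round_percent",
]


def round_percent(x: float, digits: int = 1) -> float:
    """Half-up rounding for display percentages (84.25 -> 84.3)."""
    q = decimal.Decimal(10) ** -digits
    return float(decimal.Decimal(repr(x)).quantize(q, rounding=decimal.ROUND_HALF_UP))


@dataclass(frozen=True)
class RocResult:
    """Threshold-indexed sensitivity/specificity curves and the AUC."""

    thresholds: np.ndarray  # descending; +inf first
    sensitivity: np.ndarray  # per threshold, fraction in [0, 1]
    specificity: np.ndarray
    auc: float
    n_cases: int
    n_controls: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "sensitivity": self.sensitivity,
                "specificity": self.specificity,
            }
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


@dataclass(frozen=True)
class ConfusionReport:
    """Integer confusion counts at one cutoff, with derived percentages."""

    cutoff: float
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n_cases(self) -> int:
        return self.tp + self.fn

    @property
    def n_controls(self) -> int:
        return self.tn + self.fp

    @property
    def sensitivity(self) -> float:
        return 100.0 * self.tp / self.n_cases

    @property
    def specificity(self) -> float:
        return 100.0 * self.tn / self.n_controls

    def to_dict(self) -> dict:
        d = asdict(self)
        d["sensitivity_pct"] = round_percent(self.sensitivity)
        d["specificity_pct"] = round_percent(self.specificity)
        return d


def _check_scores(scores, outcome):
    scores = np.asarray(scores, dtype=float)
    outcome = np.asarray(outcome, dtype=int)
    if scores.shape != outcome.shape or scores.ndim != 1:
        raise ValidationError("scores and outcome must be 1-d of equal length")
    if not (np.any(outcome == 1) and np.any(outcome == 0)):
        raise ValidationError("both classes must be present")
    return scores, outcome


def roc_curve(scores, outcome) -> RocResult:
    """ROC over the observed score values (plus a +inf endpoint).

    The AUC is the trapezoidal area, identical to the tie-corrected
    Mann-Whitney concordance probability of the scores.
    """
    scores, outcome = _check_scores(scores, outcome)
    fpr, tpr, thr = _skm.roc_curve(outcome, scores)
    auc = float(_skm.auc(fpr, tpr))
    return RocResult(
        thresholds=thr.astype(float),
        sensitivity=tpr,
        specificity=1.0 - fpr,
        auc=auc,
        n_cases=int((outcome == 1).sum()),
        n_controls=int((outcome == 0).sum()),
    )


def choose_cutoff(
    scores,
    outcome,
    policy: str = "max_specificity_at_full_sensitivity",
    *,
    target_sensitivity: float | None = None,
) -> float:
    """Pick the probability cutoff for the case/control call (score >= cutoff).

    ``max_specificity_at_full_sensitivity`` returns the largest cutoff with
    zero false negatives on these scores — i.e. the smallest case score.
    ``target_sensitivity`` (percent) returns the largest cutoff with
    sensitivity >= target; an unreachable target is an error.
    """
    scores, outcome = _check_scores(scores, outcome)
    case_scores = np.sort(scores[outcome == 1])
    if policy == "max_specificity_at_full_sensitivity":
        return float(case_scores[0])
    if policy == "target_sensitivity":
        if target_sensitivity is None:
            raise ValidationError("target_sensitivity policy needs a target")
        if target_sensitivity > 100.0 or target_sensitivity <= 0.0:
            raise ValidationError("target sensitivity must be in (0, 100]")
        n = case_scores.size
        # largest cutoff keeping at least ceil(target/100 * n) cases called
        need = int(np.ceil(target_sensitivity / 100.0 * n))
        return float(case_scores[n - need])
    raise ValidationError(f"unknown cutoff policy {policy!r}")


def confusion_at(scores, outcome, cutoff: float) -> ConfusionReport:
    """Exact integer confusion counts at ``cutoff`` (score >= cutoff -> case)."""
    scores, outcome = _check_scores(scores, outcome)
    call = scores >= cutoff
    return ConfusionReport(
        cutoff=float(cutoff),
        tp=int(np.sum(call & (outcome == 1))),
        fp=int(np.sum(call & (outcome == 0))),
        tn=int(np.sum(~call & (outcome == 0))),
        fn=int(np.sum(~call & (outcome == 1))),
    )


def validate_cohort(model, new_table) -> ConfusionReport:
    """Score an independent cohort with a frozen model and its stored cutoff.

    No refitting and no re-standardization: the model's training-time scaling
    and probability cutoff are applied as-is.
    """
    if model.cutoff is None:
        raise ValidationError("model has no stored cutoff; choose one on training data")
    scores = model.predict_proba(new_table)
    return confusion_at(scores, new_table.outcome, model.cutoff)


def plot_roc(roc: RocResult, path, title: str = "ROC") -> None:
    """Two-panel figure: sensitivity/specificity vs threshold, and the ROC."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax1, ax2) = plt.subplots(1, 2, figsize=(9, 4))
    finite = np.isfinite(roc.thresholds)
    ax1.plot(roc.thresholds[finite], roc.sensitivity[finite], label="sensitivity")
    ax1.plot(roc.thresholds[finite], roc.specificity[finite], label="specificity")
    ax1.set_xlabel("probability cutoff")
    ax1.set_ylabel("fraction")
    ax1.legend()
    ax2.plot(1.0 - roc.specificity, roc.sensitivity)
    ax2.plot([0, 1], [0, 1], ls=":", c="grey")
    ax2.set_xlabel("1 - specificity")
    ax2.set_ylabel("sensitivity")
    ax2.set_title(f"AUC = {roc.auc:.4f}")
    fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
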