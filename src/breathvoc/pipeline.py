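"""End-to-end orchestration: QC -> age restriction -> gradient filter ->
iterated fit -> bootstrap CIs -> operating point -> (optional) validation.

This is the programmatic surface behind both the command line and the
analysis scripts; every number in a report is recomputed from the inputs.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .cohort import ALVEOLAR, ENVIRONMENTAL, BreathSample, CohortTable, build_cohort_table
from .evaluation import ConfusionReport, RocResult, choose_cutoff, confusion_at, roc_curve, round_percent
from .filters import AGE_WINDOW, CO2_QC_THRESHOLD, GradientFilterResult, age_restrict, gradient_filter, qc_co2_filter
from .model import DiagnosticModel, bootstrap_ci, iterated_fit
from .errors import ValidationError

__all__ = ["FitReport", "run_fit", "run_validate"]


@dataclass(frozen=True)
class FitReport:
    """Everything the training pipeline produced, with stage-by-stage counts."""

    n_input: int
    n_alveolar: int
    n_qc_rejected: int
    n_age_excluded: int
    n_modelled: int
    n_cases: int
    n_controls: int
    panel_size_full: int
    panel_size_retained: int
    gradient: GradientFilterResult
    n_screen_retained: int
    model: DiagnosticModel
    roc: RocResult
    confusion: ConfusionReport
    scores: pd.DataFrame  # per-subject: outcome, score, call

    def summary(self) -> dict:
        m = self.model
        return {
            "n_input_samples": self.n_input,
            "n_alveolar": self.n_alveolar,
            "n_qc_rejected": self.n_qc_rejected,
            "n_age_excluded": self.n_age_excluded,
            "n_modelled": self.n_modelled,
            "n_cases": self.n_cases,
            "n_controls": self.n_controls,
            "panel_full": self.panel_size_full,
            "panel_retained": self.panel_size_retained,
            "n_screen_retained_vocs": self.n_screen_retained,
            "n_final_vocs": len(m.selected_vocs),
            "final_terms": list(m.terms),
            "null_model": m.is_null,
            "auc": self.roc.auc,
            "cutoff": m.cutoff,
            "training_confusion": self.confusion.to_dict(),
            "lambdas": {k: float(v) for k, v in m.lambdas.items()},
            "seed": m.seed,
        }

    def text_report(self) -> str:
        s = self.summary()
        m = self.model
        lines = [
            "Breath-VOC diagnostic model — training report",
            "=" * 46,
            f"samples in: {s['n_input_samples']} "
            f"(alveolar {s['n_alveolar']}, QC-rejected {s['n_qc_rejected']}, "
            f"age-excluded {s['n_age_excluded']})",
            f"modelled subjects: {s['n_modelled']} "
            f"({s['n_controls']} controls / {s['n_cases']} cases)",
            f"VOC panel: {s['panel_full']} -> {s['panel_retained']} after gradient filter",
            f"screen stage retained {s['n_screen_retained_vocs']} VOCs; "
            f"final model: {s['n_final_vocs']} VOCs"
            + (" plus age" if "age" in m.terms else ""),
            "",
        ]
        if m.is_null:
            lines.append("NULL MODEL: no term survived the adaptive stage.")
        else:
            lines.append(f"{'term':<16}{'coef (std)':>12}{'coef (raw)':>14}  95% CI (std)")
            for t in m.terms:
                ci = ""
                if m.ci:
                    lo, hi = m.ci["standardized"][t]
                    ci = f"[{lo:+.3f}, {hi:+.3f}]"
                lines.append(
                    f"{t:<16}{m.coefficient(t, 'standardized'):>+12.4f}"
                    f"{m.coefficient(t, 'raw'):>+14.6f}  {ci}"
                )
            lines.append(f"intercept (raw scale): {m.intercept_raw:+.4f}")
        lines += [
            "",
            f"AUC = {self.roc.auc:.4f}",
            f"cutoff = {m.cutoff:.6f} (score >= cutoff calls a case)"
            if m.cutoff is not None else "no cutoff chosen",
            f"training sensitivity = {round_percent(self.confusion.sensitivity)}% "
            f"({self.confusion.fn}/{self.confusion.n_cases} false negatives)",
            f"training specificity = {round_percent(self.confusion.specificity)}% "
            f"({self.confusion.fp}/{self.confusion.n_controls} false positives)",
        ]
        return "\n".join(lines)


def run_fit(
    samples: Sequence[BreathSample],
    seed: int,
    *,
    qc_threshold: float = CO2_QC_THRESHOLD,
    age_window: tuple[float, float] = AGE_WINDOW,
    gradient_mode: str = "test",
    gradient_alpha: float = 0.05,
    explicit_list: Sequence[str] | None = None,
    n_folds: int = 50,
    n_lambda: int = 100,
    n_boot: int = 200,
    cutoff_policy: str = "max_specificity_at_full_sensitivity",
    target_sensitivity: float | None = None,
) -> FitReport:
    """Run the full training pipeline on raw breath samples."""
    kept, rejected = qc_co2_filter(samples, qc_threshold)
    alveolar = [s for s in kept if s.sample_type == ALVEOLAR]
    environmental = [s for s in kept if s.sample_type == ENVIRONMENTAL]
    in_window, age_excluded = age_restrict(alveolar, *age_window)
    if not in_window:
        raise ValidationError("no alveolar samples survive QC and age restriction")

    grad = gradient_filter(
        in_window,
        environmental,
        mode=gradient_mode,
        alpha=gradient_alpha,
        explicit_list=explicit_list,
    )
    table = build_cohort_table(in_window, grad.retained)
    model = iterated_fit(table, seed, n_folds=n_folds, n_lambda=n_lambda)
    if not model.is_null and n_boot >= 2:
        model = bootstrap_ci(table, model, n_boot=n_boot, seed=seed)

    scores = model.predict_proba(table)
    y = table.outcome
    roc = roc_curve(scores, y)
    cutoff = choose_cutoff(
        scores, y, cutoff_policy, target_sensitivity=target_sensitivity
    )
    model = model.with_cutoff(cutoff)
    confusion = confusion_at(scores, y, cutoff)
    score_frame = pd.DataFrame(
        {
            "subject_id": table.frame.index,
            "outcome": y,
            "score": scores,
            "call": (scores >= cutoff).astype(int),
        }
    )
    n_screen = len(
        [t for t in model.adaptive_terms if t not in CohortTable.COVARIATES]
    )
    return FitReport(
        n_input=len(samples),
        n_alveolar=len(alveolar) + sum(1 for s, _ in rejected if s.sample_type == ALVEOLAR),
        n_qc_rejected=len(rejected),
        n_age_excluded=len(age_excluded),
        n_modelled=table.n,
        n_cases=int(y.sum()),
        n_controls=int((1 - y).sum()),
        panel_size_full=samples[0].panel.count if samples else 0,
        panel_size_retained=grad.retained.count,
        gradient=grad,
        n_screen_retained=n_screen,
        model=model,
        roc=roc,
        confusion=confusion,
        scores=score_frame,
    )


def run_validate(
    model: DiagnosticModel,
    samples: Sequence[BreathSample],
    *,
    qc_threshold: float = CO2_QC_THRESHOLD,
    age_window: tuple[float, float] = AGE_WINDOW,
) -> tuple[ConfusionReport, pd.DataFrame]:
    """Score an independent cohort with a frozen model (no refitting)."""
    kept, _ = qc_co2_filter(samples, qc_threshold)
    alveolar = [s for s in kept if s.sample_type == ALVEOLAR]
    in_window, _ = age_restrict(alveolar, *age_window)
    panel = in_window[0].panel if in_window else None
    if panel is None:
        raise ValidationError("no validation samples survive QC and age restriction")
    table = build_cohort_table(in_window, panel)
    scores = model.predict_proba(table)
    report = confusion_at(scores, table.outcome, model.cutoff)
    frame = pd.DataFrame(
        {
            "subject_id": table.frame.index,
            "outcome": table.outcome,
            "score": scores,
            "call": (scores >= model.cutoff).astype(int),
        }
    )
    return report, frame


def write_report_bundle(report: FitReport, out_dir: str | Path, seed: int) -> dict[str, Path]:
    """Write the model, report, scores and ROC curve under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "model": out / "model.json",
        "report": out / "report.txt",
        "summary": out / "summary.json",
        "scores": out / "training_scores.csv",
        "roc": out / "roc_curve.csv",
    }
    report.model.to_json(paths["model"])
    paths["report"].write_text(report.text_report() + "\n")
    paths["summary"].write_text(json.dumps(report.summary(), indent=2))
    report.scores.to_csv(paths["scores"], index=False)
    report.roc.to_csv(paths["roc"])
    return paths
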