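"""Breath-sample records, cohort tables, and delimited-file I/O.

The on-disk dialect is comma-separated UTF-8 with a fixed mandatory-column
prefix (sample_id, subject_id, sample_type, group, sex, age, co2_pct, o2_pct)
followed by one column per VOC channel, values in ppb.  Environmental (room
air) samples carry an empty ``group`` field: room air has no case/control
status.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ParseError, SchemaError, ValidationError
from .panel import VOCPanel

__all__ = [
    "BreathSample",
    "CohortTable",
    "MANDATORY_COLUMNS",
    "read_cohort",
    "write_cohort",
    "build_cohort_table",
]

MANDATORY_COLUMNS = (
    "sample_id",
    "subject_id",
    "sample_type",
    "group",
    "sex",
    "age",
    "co2_pct",
    "o2_pct",
)

ALVEOLAR = "alveolar"
ENVIRONMENTAL = "environmental"


@dataclass(frozen=True)
class BreathSample:
    """One measured air sample with QC fields and a ppb concentration vector."""

    sample_id: str
    subject_id: str
    sample_type: str  # "alveolar" | "environmental"
    group: str | None  # "case" | "control"; None for environmental samples
    sex: str | None  # "M" | "F"
    age: float | None  # years
    co2: float | None  # volume percent
    o2: float | None  # volume percent
    panel: VOCPanel
    concentrations: np.ndarray  # ppb, aligned with panel

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        object.__setattr__(self, "concentrations", conc)
        if conc.shape != (self.panel.count,):
            raise ValidationError(
                f"sample {self.sample_id}: {conc.shape[0]} concentrations for a "
                f"{self.panel.count}-feature panel"
            )
        if not np.all(np.isfinite(conc)) or np.any(conc < 0):
            raise ValidationError(
                f"sample {self.sample_id}: concentrations must be finite and >= 0"
            )
        if self.sample_type not in (ALVEOLAR, ENVIRONMENTAL):
            raise ValidationError(
                f"sample {self.sample_id}: unknown sample_type {self.sample_type!r}"
            )
        if self.sample_type == ENVIRONMENTAL and self.group is not None:
            raise ValidationError(
                f"sample {self.sample_id}: environmental samples carry no outcome label"
            )
        if self.group not in (None, "case", "control"):
            raise ValidationError(
                f"sample {self.sample_id}: unknown group {self.group!r}"
            )
        if self.age is not None and self.age < 0:
            raise ValidationError(f"sample {self.sample_id}: negative age")
        if self.co2 is not None and self.co2 < 0:
            raise ValidationError(f"sample {self.sample_id}: negative CO2")

    def value(self, label: str) -> float:
        return float(self.concentrations[self.panel.index(label)])

    def with_panel(self, panel: VOCPanel) -> "BreathSample":
        idx = [self.panel.index(n) for n in panel.names]
        return replace(self, panel=panel, concentrations=self.concentrations[idx])


@dataclass(frozen=True)
class CohortTable:
    """Subject-level modelling table: outcome, covariates and VOC features.

    ``frame`` holds one row per subject, indexed by subject_id, with columns
    ``outcome`` (case=1/control=0), ``age``, ``sex`` (M=1/F=0) and one column
    per panel feature (ppb).
    """

    frame: pd.DataFrame
    panel: VOCPanel

    COVARIATES = ("age", "sex")

    def __post_init__(self) -> None:
        f = self.frame
        missing = [c for c in ("outcome", "age", "sex") if c not in f.columns]
        if missing:
            raise SchemaError(f"cohort table missing columns {missing}")
        for name in self.panel.names:
            if name not in f.columns:
                raise SchemaError(f"cohort table missing feature column {name!r}")
        if f.index.has_duplicates:
            raise ValidationError("duplicate subject_id in cohort table")
        if f[list(self.panel.names)].isna().any().any():
            raise ValidationError("missing feature values in cohort table")

    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def outcome(self) -> np.ndarray:
        return self.frame["outcome"].to_numpy(dtype=int)

    @property
    def feature_names(self) -> tuple[str, ...]:
        return self.panel.names

    def design(self, columns: Sequence[str] | None = None) -> tuple[np.ndarray, list[str]]:
        """Raw (unstandardized) design matrix for the given columns.

        Defaults to covariates followed by every panel feature.
        """
        cols = list(columns) if columns is not None else (
            list(self.COVARIATES) + list(self.panel.names)
        )
        return self.frame[cols].to_numpy(dtype=float), cols

    def restrict_features(self, labels: Iterable[str]) -> "CohortTable":
        sub = self.panel.subset(labels)
        keep = ["outcome", "age", "sex", *sub.names]
        return CohortTable(self.frame[keep].copy(), sub)


def _sample_to_row(s: BreathSample) -> dict:
    row = {
        "sample_id": s.sample_id,
        "subject_id": s.subject_id,
        "sample_type": s.sample_type,
        "group": s.group if s.group is not None else "",
        "sex": s.sex if s.sex is not None else "",
        "age": s.age if s.age is not None else "",
        "co2_pct": s.co2 if s.co2 is not None else "",
        "o2_pct": s.o2 if s.o2 is not None else "",
    }
    row.update(zip(s.panel.names, s.concentrations))
    return row


def write_cohort(samples: Sequence[BreathSample], path: str | Path) -> Path:
    """Write samples to the CSV dialect; deterministic column order."""
    samples = list(samples)
    if samples:
        panel = samples[0].panel
        for s in samples[1:]:
            if s.panel.names != panel.names:
                raise SchemaError(
                    f"sample {s.sample_id} uses a different panel than {samples[0].sample_id}"
                )
        columns = list(MANDATORY_COLUMNS) + list(panel.names)
        frame = pd.DataFrame([_sample_to_row(s) for s in samples], columns=columns)
    else:
        frame = pd.DataFrame(columns=list(MANDATORY_COLUMNS))
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


def read_cohort(path: str | Path, panel_spec: VOCPanel | None = None) -> list[BreathSample]:
    """Parse a cohort CSV into BreathSample records.

    VOC columns are every column after the mandatory prefix; their file order
    becomes the panel order.  ``panel_spec``, when given, must match the file's
    VOC columns as a set and fixes the panel object used.
    """
    path = Path(path)
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    for col in MANDATORY_COLUMNS:
        if col not in frame.columns:
            raise SchemaError(f"{path.name}: missing mandatory column {col!r}")
    voc_cols = [c for c in frame.columns if c not in MANDATORY_COLUMNS]
    panel = VOCPanel(tuple(voc_cols))
    if panel_spec is not None:
        if set(panel_spec.names) != set(voc_cols):
            raise SchemaError(
                f"{path.name}: VOC columns do not match the supplied panel"
            )
        panel = panel_spec
        frame = frame[list(MANDATORY_COLUMNS) + list(panel.names)]

    samples: list[BreathSample] = []
    for i, rec in enumerate(frame.to_dict("records")):
        conc = np.empty(panel.count)
        for j, name in enumerate(panel.names):
            raw = rec[name]
            try:
                conc[j] = float(raw)
            except (TypeError, ValueError):
                raise ParseError(
                    f"{path.name}: non-numeric concentration {raw!r} "
                    f"at row {i + 2}, column {name!r}"
                ) from None
        def _opt_float(key: str) -> float | None:
            v = rec[key]
            if v == "":
                return None
            try:
                return float(v)
            except ValueError:
                raise ParseError(
                    f"{path.name}: non-numeric {key} {v!r} at row {i + 2}"
                ) from None

        samples.append(
            BreathSample(
                sample_id=rec["sample_id"],
                subject_id=rec["subject_id"],
                sample_type=rec["sample_type"],
                group=rec["group"] or None,
                sex=rec["sex"] or None,
                age=_opt_float("age"),
                co2=_opt_float("co2_pct"),
                o2=_opt_float("o2_pct"),
                panel=panel,
                concentrations=conc,
            )
        )
    return samples


def build_cohort_table(kept_alveolar: Sequence[BreathSample], panel: VOCPanel) -> CohortTable:
    """Assemble the subject-level modelling table from QC-passed alveolar samples.

    One alveolar sample per subject; outcome encoded case=1/control=0, sex M=1/F=0;
    features restricted to ``panel`` (typically the gradient-filtered sub-panel).
    """
    rows = {}
    for s in kept_alveolar:
        if s.sample_type != ALVEOLAR:
            raise ValidationError(f"sample {s.sample_id} is not alveolar")
        if s.group is None:
            raise ValidationError(f"sample {s.sample_id} has no case/control label")
        if s.sex not in ("M", "F"):
            raise ValidationError(f"sample {s.sample_id}: sex must be M or F")
        if s.age is None or math.isnan(s.age):
            raise ValidationError(f"sample {s.sample_id}: missing age")
        if s.subject_id in rows:
            raise ValidationError(f"duplicate subject_id {s.subject_id!r}")
        sub = s.with_panel(panel) if s.panel.names != panel.names else s
        row = {
            "outcome": 1 if s.group == "case" else 0,
            "age": float(s.age),
            "sex": 1.0 if s.sex == "M" else 0.0,
        }
        row.update(zip(panel.names, sub.concentrations))
        rows[s.subject_id] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "subject_id"
    if frame.empty:
        frame = pd.DataFrame(columns=["outcome", "age", "sex", *panel.names])
    return CohortTable(frame, panel)
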