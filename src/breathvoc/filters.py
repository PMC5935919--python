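"""Sample QC and the alveolar-gradient molecule filter.

Three data-reduction rules precede modelling:

1. CO2 quality control — an alveolar sample with end-tidal CO2 below 2 vol%
   was not a proper end-tidal collection and is discarded.
2. Age restriction — cases and controls are kept only within a common age
   window (default 40-75 inclusive) so age cannot proxy for recruitment source.
3. Alveolar-gradient filter — a molecule significantly more concentrated in
   room air than in alveolar air is of exogenous origin (absorbed, partially
   retained, re-exhaled) and is removed from the candidate-marker panel.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .cohort import ALVEOLAR, ENVIRONMENTAL, BreathSample
from .errors import ValidationError
from .panel import VOCPanel, normalize_label

__all__ = [
    "qc_co2_filter",
    "age_restrict",
    "gradient_filter",
    "GradientFilterResult",
    "CO2_QC_THRESHOLD",
    "AGE_WINDOW",
]

CO2_QC_THRESHOLD = 2.0  # vol%; strictly-below is rejected
AGE_WINDOW = (40.0, 75.0)  # inclusive bounds


def qc_co2_filter(
    samples: Sequence[BreathSample], threshold: float = CO2_QC_THRESHOLD
) -> tuple[list[BreathSample], list[tuple[BreathSample, str]]]:
    """Split samples into (kept, rejected) by the end-tidal CO2 criterion.

    Alveolar samples with CO2 strictly below ``threshold`` are rejected with a
    reason; environmental samples are always kept (the criterion measures
    exhalation quality, not room air). A missing CO2 value on an alveolar
    sample is an error rather than a silent keep.
    """
    kept: list[BreathSample] = []
    rejected: list[tuple[BreathSample, str]] = []
    for s in samples:
        if s.sample_type == ENVIRONMENTAL:
            kept.append(s)
            continue
        if s.co2 is None or np.isnan(s.co2):
            raise ValidationError(f"alveolar sample {s.sample_id} has no CO2 value")
        if s.co2 < threshold:
            rejected.append((s, f"CO2 {s.co2:g}% < {threshold:g}%"))
        else:
            kept.append(s)
    return kept, rejected


def age_restrict(
    samples: Sequence[BreathSample],
    low: float = AGE_WINDOW[0],
    high: float = AGE_WINDOW[1],
) -> tuple[list[BreathSample], list[BreathSample]]:
    """Keep samples whose subject age satisfies low <= age <= high (inclusive)."""
    kept: list[BreathSample] = []
    excluded: list[BreathSample] = []
    for s in samples:
        if s.age is None or np.isnan(s.age):
            raise ValidationError(f"sample {s.sample_id} has no age")
        if s.age < 0:
            raise ValidationError(f"sample {s.sample_id} has negative age")
        (kept if low <= s.age <= high else excluded).append(s)
    return kept, excluded


@dataclass(frozen=True)
class GradientFilterResult:
    """Outcome of the alveolar-gradient molecule filter."""

    retained: VOCPanel
    excluded: tuple[str, ...]
    mode: str  # "test" | "explicit_list"
    statistics: pd.DataFrame | None = None  # per molecule: statistic, p_value (test mode)

    def __post_init__(self) -> None:
        if set(self.excluded) & set(self.retained.names):
            raise ValidationError("retained and excluded labels overlap")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"label": n, "status": "retained"} for n in self.retained.names]
        rows += [{"label": n, "status": "excluded"} for n in self.excluded]
        out = pd.DataFrame(rows)
        if self.statistics is not None:
            out = out.merge(self.statistics, on="label", how="left")
        return out


def gradient_filter(
    alveolar: Sequence[BreathSample],
    environmental: Sequence[BreathSample] | None = None,
    *,
    mode: str = "test",
    alpha: float = 0.05,
    explicit_list: Sequence[str] | None = None,
) -> GradientFilterResult:
    """Drop molecules significantly more present in room air than in breath.

    ``test`` mode pairs each alveolar sample with the same subject's room-air
    sample and applies a one-sided paired Wilcoxon signed-rank test
    (environmental > alveolar) per molecule at level ``alpha``.
    ``explicit_list`` mode excludes exactly the listed labels, reproducing a
    published exclusion without re-deriving it.
    """
    if not alveolar:
        raise ValidationError("gradient_filter needs at least one alveolar sample")
    panel = alveolar[0].panel

    if mode == "explicit_list":
        if explicit_list is None:
            raise ValidationError("explicit_list mode requires a label list")
        labels = tuple(normalize_label(l, set(panel.names)) for l in explicit_list)
        return GradientFilterResult(
            retained=panel.drop(labels), excluded=labels, mode=mode
        )
    if mode != "test":
        raise ValidationError(f"unknown gradient-filter mode {mode!r}")

    if not environmental:
        raise ValidationError("test mode requires paired environmental samples")
    env_by_subject = {s.subject_id: s for s in environmental if s.sample_type == ENVIRONMENTAL}
    pairs = [
        (a, env_by_subject[a.subject_id])
        for a in alveolar
        if a.sample_type == ALVEOLAR and a.subject_id in env_by_subject
    ]
    if not pairs:
        raise ValidationError(
            "test mode found no alveolar/environmental pairs sharing a subject_id"
        )

    alv = np.array([a.concentrations for a, _ in pairs])
    env = np.array([e.concentrations for _, e in pairs])
    excluded: list[str] = []
    rows = []
    for j, label in enumerate(panel.names):
        diff = env[:, j] - alv[:, j]
        if np.allclose(diff, 0):
            stat, p = 0.0, 1.0  # identical paired values: no environmental excess
        else:
            res = stats.wilcoxon(diff, alternative="greater")
            stat, p = float(res.statistic), float(res.pvalue)
        rows.append({"label": label, "statistic": stat, "p_value": p})
        if p < alpha:
            excluded.append(label)
    return GradientFilterResult(
        retained=panel.drop(excluded),
        excluded=tuple(excluded),
        mode="test",
        statistics=pd.DataFrame(rows),
    )
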