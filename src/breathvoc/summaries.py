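"""Descriptive statistics for VOC concentrations, by case/control group.

For each feature and group the eight statistics customary in breathomics
reports are computed: median, geometric mean, minimum, maximum, arithmetic
mean, standard deviation and the 5th/95th percentiles, all in ppb.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.stats import gmean

from .cohort import CohortTable
from .errors import ValidationError

__all__ = ["SummaryStats", "summarize"]

STATISTICS = (
    "median",
    "geometric_mean",
    "min",
    "max",
    "mean",
    "sd",
    "p5",
    "p95",
)


@dataclass(frozen=True)
class SummaryStats:
    """Per-feature, per-group summary table (rows: (group, feature))."""

    frame: pd.DataFrame  # MultiIndex (group, feature) x STATISTICS

    def get(self, group: str, feature: str, statistic: str) -> float:
        return float(self.frame.loc[(group, feature), statistic])

    def to_csv(self, path) -> None:
        self.frame.to_csv(path)


def _geometric_mean(values: np.ndarray, label: str) -> float:
    """Geometric mean with zeros floored at half the smallest positive value."""
    if np.any(values == 0):
        positive = values[values > 0]
        if positive.size == 0:
            return 0.0
        eps = positive.min() / 2.0
        warnings.warn(
            f"{label}: zero concentrations floored at {eps:g} ppb for the "
            "geometric mean",
            stacklevel=3,
        )
        values = np.where(values == 0, eps, values)
    return float(gmean(values))


def summarize(
    table: CohortTable,
    features: Sequence[str] | None = None,
    group_names: tuple[str, str] = ("control", "case"),
) -> SummaryStats:
    """Summary statistics per feature, split by outcome group.

    SD uses the sample convention (ddof=1); percentiles use linear
    interpolation.  Each outcome group must be non-empty.
    """
    names = tuple(features) if features is not None else table.panel.names
    out_rows = {}
    for outcome, gname in ((0, group_names[0]), (1, group_names[1])):
        sub = table.frame[table.frame["outcome"] == outcome]
        if sub.empty:
            raise ValidationError(f"empty group {gname!r}")
        for name in names:
            v = sub[name].to_numpy(dtype=float)
            out_rows[(gname, name)] = {
                "median": float(np.median(v)),
                "geometric_mean": _geometric_mean(v, name),
                "min": float(v.min()),
                "max": float(v.max()),
                "mean": float(v.mean()),
                "sd": float(v.std(ddof=1)) if v.size > 1 else 0.0,
                "p5": float(np.percentile(v, 5)),
                "p95": float(np.percentile(v, 95)),
            }
    frame = pd.DataFrame.from_dict(out_rows, orient="index", columns=list(STATISTICS))
    frame.index = pd.MultiIndex.from_tuples(frame.index, names=["group", "feature"])
    return SummaryStats(frame)
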