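"""The published diagnostic-model coefficients.

The study's final ductal-adenocarcinoma model is a logistic score over age
and ten VOCs.  Both stages are recorded: the first-stage screening LASSO
(22 nonzero terms) and the second-stage adaptive LASSO (the deployable model,
with bootstrap confidence intervals).  The scale of the printed coefficients
is ambiguous — the methods standardized the predictors, yet the magnitudes
are plausible on raw ppb — so evaluation takes an explicit ``scale`` argument
and neither convention is claimed correct.
"""

from __future__ import annotations

from typing import Mapping

import numpy as np

from .errors import ValidationError
from .lasso import Standardization

__all__ = [
    "FIRST_STAGE_COEFFICIENTS",
    "FINAL_MODEL_COEFFICIENTS",
    "FINAL_MODEL_CI",
    "apply_published_model",
]

#: First screening LASSO: 21 VOCs plus age (sex and 49 VOCs shrank to zero).
FIRST_STAGE_COEFFICIENTS: dict[str, float] = {
    "intercept": -5.3255467964,
    "age": +0.1493804071,
    "ammonia": +0.0036286701,
    "M34": -0.1699431526,
    "M37": +0.0006675672,
    "M42": +0.0009076002,
    "M43": +0.0007153015,
    "M44": +0.0047526254,
    "M46": -0.0007407600,
    "M60": -0.0003390278,
    "n-propanol": +0.0054942415,
    "M62": -0.2138505207,
    "sulfur dioxide": -0.2595054348,
    "M66": -0.1459224298,
    "M71": +0.0062530914,
    "M74": -0.0120892660,
    "M75": -0.0008072235,
    "M88": -0.0142597155,
    "M89": +0.2297944263,
    "M91": -0.0286331109,
    "M106": -0.0135291587,
    "M111": +0.0926572905,
    "M112": +0.0054448431,
}

#: Final adaptive-LASSO model: age plus ten VOCs.
FINAL_MODEL_COEFFICIENTS: dict[str, float] = {
    "intercept": -4.832765,
    "age": +0.119876,
    "ammonia": +0.001723,
    "M34": -0.102787,
    "M43": +0.002183,
    "M44": +0.001295,
    "M62": -0.335321,
    "sulfur dioxide": -0.384319,
    "M71": +0.012486,
    "M74": -0.021012,
    "M89": +0.426043,
    "M112": +0.023171,
}

#: 95% bootstrap confidence intervals for the final model's coefficients.
FINAL_MODEL_CI: dict[str, tuple[float, float]] = {
    "intercept": (-19.837, +4.153),
    "age": (+0.032, +0.403),
    "ammonia": (+0.000, +0.023),
    "M34": (-0.402, +0.000),
    "M43": (-0.006, +0.005),
    "M44": (+0.001, +0.051),
    "M62": (-1.007, -0.077),
    "sulfur dioxide": (-1.116, -0.132),
    "M71": (+0.000, +0.040),
    "M74": (-0.159, +0.000),
    "M89": (+0.536, +2.368),
    "M112": (+0.000, +0.230),
}


def apply_published_model(
    features: Mapping[str, float],
    age: float,
    *,
    scale: str = "raw",
    standardization: Standardization | None = None,
) -> float:
    """Probability of disease under the published final model.

    ``features`` maps the ten VOC labels to ppb values.  ``scale="raw"``
    applies the printed coefficients directly to ppb and years;
    ``scale="standardized"`` treats them as standardized-scale coefficients
    and requires a :class:`~breathvoc.lasso.Standardization` covering every
    model term.
    """
    terms = [k for k in FINAL_MODEL_COEFFICIENTS if k != "intercept"]
    values = {}
    for t in terms:
        if t == "age":
            values[t] = float(age)
            continue
        if t not in features:
            raise ValidationError(f"missing feature {t!r} for the published model")
        values[t] = float(features[t])
    if scale == "standardized":
        if standardization is None:
            raise ValidationError("standardized scale requires standardization params")
        for t in terms:
            if t not in standardization.columns:
                raise ValidationError(f"standardization lacks term {t!r}")
            j = standardization.columns.index(t)
            values[t] = (values[t] - standardization.center[j]) / standardization.scale[j]
    elif scale != "raw":
        raise ValidationError(f"unknown scale {scale!r}")
    eta = FINAL_MODEL_COEFFICIENTS["intercept"] + sum(
        FINAL_MODEL_COEFFICIENTS[t] * values[t] for t in terms
    )
    return float(1.0 / (1.0 + np.exp(-eta)))
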