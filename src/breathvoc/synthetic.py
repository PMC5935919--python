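"""Seeded generator of synthetic breath cohorts.

Real breath-VOC tables from the study population are not publicly
depositable, so the pipeline is exercised on synthetic cohorts with the same
statistical structure: per-VOC log-normal positive concentrations, a
designated informative subset whose case/control geometric means are
calibrated to the study's printed per-group summary statistics, paired
room-air (environmental) samples with a configurable set of exogenous
molecules in environmental excess, truncated-normal ages per group, and
end-tidal CO2 values straddling the 2% QC threshold.

The outcome mechanism is "two-population": the case/control label shifts the
log-location of the informative features; the implied logistic coefficients
on log-concentrations (the truth for recovery tests) are derived from those
shifts.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import ALVEOLAR, ENVIRONMENTAL, BreathSample
from .errors import ValidationError
from .panel import CALIBRATED_COMPOUNDS, ENV_EXCESS_MASSES, STUDY_PANEL, VOCPanel

__all__ = [
    "FeatureParams",
    "GeneratorConfig",
    "SyntheticTruth",
    "generate_cohort",
    "generate_published_like_run",
]


def _sigma_from_cv(mean: float, sd: float) -> float:
    """Log-scale SD of a log-normal from its arithmetic mean and SD."""
    return math.sqrt(math.log(1.0 + (sd / mean) ** 2))


def _sigma_from_span(p5: float, p95: float) -> float:
    """Log-scale SD from a 5th-95th percentile span (log-normal quantiles)."""
    return math.log(p95 / p5) / (2 * 1.6448536269514722)


@dataclass(frozen=True)
class FeatureParams:
    """Log-normal parameters of one VOC channel, per group, plus room air."""

    gm_control: float  # geometric mean (ppb) in controls = log-normal median
    gm_case: float
    sigma_control: float  # log-scale SD
    sigma_case: float
    env_gm: float
    env_sigma: float

    @property
    def informative(self) -> bool:
        return self.gm_case != self.gm_control

    @property
    def log_ratio(self) -> float:
        return math.log(self.gm_case / self.gm_control)


def _shared(gm, sigma, env_gm=None, env_sigma=None) -> FeatureParams:
    return FeatureParams(
        gm, gm, sigma, sigma,
        env_gm if env_gm is not None else 0.25 * gm,
        env_sigma if env_sigma is not None else sigma,
    )


# Calibration of the ten informative VOCs from the study's printed per-group
# summary table: location = geometric mean; spread back-solved from the
# arithmetic mean/SD (exact for a log-normal).  Room-air levels for ammonia
# and sulfur dioxide come from the printed environmental summaries; unnamed
# masses default to a small fraction of the alveolar level (positive alveolar
# gradient: these molecules survive the gradient filter).
_T4 = {
    # label: (gm_ctrl, mean_ctrl, sd_ctrl, gm_case, mean_case, sd_case)
    "ammonia": (88.8, 106.5, 72.9, 118.2, 136.7, 102.8),
    "M34": (18.7, 19.2, 4.0, 12.8, 13.3, 4.4),
    "M43": (1023.9, 1087.5, 397.8, 1337.8, 1874.4, 2109.5),
    "M44": (6576.8, 6918.8, 2115.9, 6141.6, 6371.2, 1749.0),
    "M62": (7.5, 8.7, 5.7, 6.3, 7.7, 6.0),
    "sulfur dioxide": (10.4, 10.6, 2.0, 6.9, 7.7, 3.6),
    "M71": (36.1, 44.5, 36.1, 41.2, 49.4, 34.5),
    "M74": (9.4, 17.4, 41.7, 9.6, 16.2, 22.5),
    "M89": (1.5, 2.2, 2.5, 3.4, 5.7, 6.9),
    "M112": (9.6, 12.0, 15.4, 14.5, 16.7, 10.9),
}

# Room-air (environmental) medians and 5-95th spans for the directly
# calibrated compounds, from the printed environmental summary table.
_ENV = {
    "methanol": (633.0, 323.0, 1166.0),
    "acetonitrile": (129.0, 48.0, 802.0),
    "ethanol": (525.0, 121.0, 3187.0),
    "MEK": (45.0, 14.0, 147.0),
    "acetone": (181.0, 67.0, 392.0),
    "isoprene": (18.0, 8.9, 34.4),
    "n-propanol": (47.0, 20.0, 1729.0),
    "benzene": (5.6, 0.7, 13.0),
    "toluene": (4.8, 1.1, 11.7),
    "n-heptane": (14.3, 6.7, 34.1),
    "ammonia": (70.0, 24.0, 116.0),
    "sulfur dioxide": (10.4, 5.9, 14.6),
}

# Alveolar medians and 5-95th spans for the calibrated compounds that are not
# part of the informative set (shared across groups).
_ALV_CAL = {
    "methanol": (492.0, 294.0, 841.0),
    "acetonitrile": (176.0, 66.0, 1164.0),
    "ethanol": (349.0, 88.0, 1361.0),
    "MEK": (78.0, 36.0, 281.0),
    "acetone": (534.0, 244.0, 1676.0),
    "isoprene": (149.0, 63.0, 292.0),
    "n-propanol": (80.0, 45.0, 194.0),
    "benzene": (9.4, 2.2, 35.9),
    "toluene": (4.8, 1.6, 14.5),
    "n-heptane": (15.6, 6.0, 31.5),
}

#: Generic trace-channel level for unnamed masses with no printed calibration.
_DEFAULT_MASS_GM = 20.0
_DEFAULT_MASS_SIGMA = 0.9
#: Environmental multiple for molecules of exogenous origin (env >> alveolar).
_ENV_EXCESS_FACTOR = 4.0


def default_feature_params(
    panel: VOCPanel = STUDY_PANEL,
    env_excess_set: tuple[str, ...] = ENV_EXCESS_MASSES,
) -> dict[str, FeatureParams]:
    """The study-calibrated per-channel parameters for a panel."""
    out: dict[str, FeatureParams] = {}
    excess = set(env_excess_set)
    for label in panel.names:
        if label in _T4:
            gc, mc, sc, gk, mk, sk = _T4[label]
            env = _ENV.get(label)
            out[label] = FeatureParams(
                gm_control=gc,
                gm_case=gk,
                sigma_control=_sigma_from_cv(mc, sc),
                sigma_case=_sigma_from_cv(mk, sk),
                env_gm=env[0] if env else 0.25 * gc,
                env_sigma=_sigma_from_span(env[1], env[2]) if env
                else _sigma_from_cv(mc, sc),
            )
        elif label in _ALV_CAL:
            med, p5, p95 = _ALV_CAL[label]
            env = _ENV[label]
            out[label] = _shared(
                med, _sigma_from_span(p5, p95), env[0], _sigma_from_span(env[1], env[2])
            )
        else:
            gm, sigma = _DEFAULT_MASS_GM, _DEFAULT_MASS_SIGMA
            if label in excess:
                out[label] = _shared(gm, sigma, _ENV_EXCESS_FACTOR * gm, sigma)
            else:
                out[label] = _shared(gm, sigma)
    return out


@dataclass(frozen=True)
class GeneratorConfig:
    """Everything that determines a synthetic cohort draw."""

    n_cases: int = 65
    n_controls: int = 102
    panel: VOCPanel = STUDY_PANEL
    features: dict[str, FeatureParams] = field(default_factory=default_feature_params)
    env_excess_set: tuple[str, ...] = ENV_EXCESS_MASSES
    age_control: tuple[float, float] = (53.0, 9.0)  # mean, SD (years)
    age_case: tuple[float, float] = (61.0, 8.0)
    age_range: tuple[float, float] = (21.0, 83.0)
    age_window_only: bool = False  # restrict ages to [40, 75]
    co2_mean: float = 4.5  # vol%
    co2_sd: float = 0.7
    co2_low_fraction: float = 0.05  # fraction of alveolar samples failing QC
    o2_mean: float = 16.0
    o2_sd: float = 1.2
    p_male: float = 0.5
    rho: float = 0.0  # equicorrelation of log-concentrations
    noise_sigma: float = 0.0  # extra multiplicative measurement noise
    seed: int = 0

    def __post_init__(self):
        missing = [n for n in self.panel.names if n not in self.features]
        if missing:
            raise ValidationError(f"no feature parameters for {missing}")
        for label, p in self.features.items():
            if min(p.gm_control, p.gm_case, p.env_gm) <= 0 or min(
                p.sigma_control, p.sigma_case, p.env_sigma
            ) <= 0:
                raise ValidationError(f"{label}: location/spread must be positive")
        if not 0.0 <= self.rho < 1.0:
            raise ValidationError("rho must be in [0, 1)")
        inf_set = {l for l, p in self.features.items() if p.informative}
        if inf_set & set(self.env_excess_set):
            raise ValidationError(
                "informative features cannot also be environmental-excess"
            )

    @property
    def informative_set(self) -> tuple[str, ...]:
        return tuple(l for l in self.panel.names if self.features[l].informative)


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth of a generated cohort, for recovery tests."""

    informative: tuple[str, ...]
    log_ratio: dict[str, float]  # case-vs-control shift of log-concentration
    implied_coefficients: dict[str, float]  # on log-concentration scale
    bayes_auc: float  # realized AUC of the true discriminant on this cohort


def _truncnorm(rng: np.random.Generator, mean, sd, lo, hi, size) -> np.ndarray:
    out = np.empty(size)
    filled = 0
    while filled < size:
        draw = rng.normal(mean, sd, size=2 * (size - filled) + 8)
        draw = draw[(draw >= lo) & (draw <= hi)]
        take = min(draw.size, size - filled)
        out[filled : filled + take] = draw[:take]
        filled += take
    return out


def _draw_block(rng, config: GeneratorConfig, group: str, ages: np.ndarray, start: int):
    """Alveolar + paired environmental samples for one subject block."""
    n = ages.size
    panel = config.panel
    p = panel.count
    mu = np.empty(p)
    sig = np.empty(p)
    env_mu = np.empty(p)
    env_sig = np.empty(p)
    for j, label in enumerate(panel.names):
        fp = config.features[label]
        mu[j] = math.log(fp.gm_case if group == "case" else fp.gm_control)
        sig[j] = fp.sigma_case if group == "case" else fp.sigma_control
        env_mu[j] = math.log(fp.env_gm)
        env_sig[j] = fp.env_sigma

    z = rng.standard_normal((n, p))
    if config.rho > 0:
        shared = rng.standard_normal((n, 1))
        z = math.sqrt(config.rho) * shared + math.sqrt(1 - config.rho) * z
    log_alv = mu + sig * z
    if config.noise_sigma > 0:
        log_alv = log_alv + rng.normal(0.0, config.noise_sigma, size=(n, p))
    alv = np.exp(log_alv)
    env = np.exp(env_mu + env_sig * rng.standard_normal((n, p)))

    sexes = np.where(rng.random(n) < config.p_male, "M", "F")
    low = rng.random(n) < config.co2_low_fraction
    co2 = np.where(
        low,
        rng.uniform(1.2, 1.95, size=n),
        _truncnorm(rng, config.co2_mean, config.co2_sd, 2.0, np.inf, n),
    )
    o2 = rng.normal(config.o2_mean, config.o2_sd, size=n)

    samples = []
    for i in range(n):
        sid = f"S{start + i:04d}"
        samples.append(
            BreathSample(
                sample_id=f"A-{sid}", subject_id=sid, sample_type=ALVEOLAR,
                group=group, sex=str(sexes[i]), age=float(round(ages[i])),
                co2=float(co2[i]), o2=float(o2[i]),
                panel=panel, concentrations=alv[i],
            )
        )
        samples.append(
            BreathSample(
                sample_id=f"E-{sid}", subject_id=sid, sample_type=ENVIRONMENTAL,
                group=None, sex=None, age=None,
                co2=float(rng.uniform(0.03, 0.15)), o2=float(rng.normal(20.9, 0.2)),
                panel=panel, concentrations=env[i],
            )
        )
    return samples, log_alv


def _truth(config: GeneratorConfig, log_alv: np.ndarray, y: np.ndarray) -> SyntheticTruth:
    panel = config.panel
    informative = config.informative_set
    log_ratio = {l: config.features[l].log_ratio for l in informative}
    coef = {}
    for l in informative:
        fp = config.features[l]
        pooled_var = 0.5 * (fp.sigma_control**2 + fp.sigma_case**2)
        coef[l] = fp.log_ratio / pooled_var  # LDA weight on log-concentration
    if informative and 0 < y.sum() < y.size:
        idx = [panel.index(l) for l in informative]
        w = np.array([coef[l] for l in informative])
        score = log_alv[:, idx] @ w
        pos, neg = score[y == 1], score[y == 0]
        auc = (
            (pos[:, None] > neg[None, :]).mean()
            + 0.5 * (pos[:, None] == neg[None, :]).mean()
        )
    else:
        auc = 0.5
    return SyntheticTruth(
        informative=informative,
        log_ratio=log_ratio,
        implied_coefficients=coef,
        bayes_auc=float(auc),
    )


def generate_cohort(config: GeneratorConfig) -> tuple[list[BreathSample], SyntheticTruth]:
    """One synthetic cohort: paired alveolar/environmental samples plus truth.

    Controls come first, then cases; the draw is fully determined by
    ``config`` (including its seed).
    """
    rng = np.random.default_rng(config.seed)
    lo, hi = config.age_range
    if config.age_window_only:
        lo, hi = max(lo, 40.0), min(hi, 75.0)
    ages_ctrl = _truncnorm(rng, *config.age_control, lo, hi, config.n_controls)
    ages_case = _truncnorm(rng, *config.age_case, lo, hi, config.n_cases)
    ctrl, log_ctrl = _draw_block(rng, config, "control", ages_ctrl, 0)
    case, log_case = _draw_block(rng, config, "case", ages_case, config.n_controls)
    y = np.r_[np.zeros(config.n_controls), np.ones(config.n_cases)]
    truth = _truth(config, np.vstack([log_ctrl, log_case]), y)
    return ctrl + case, truth


def generate_published_like_run(
    seed: int, config: GeneratorConfig | None = None
) -> tuple[list[BreathSample], list[BreathSample]]:
    """A 219-subject training cohort and a 50-subject validation cohort.

    The training cohort reproduces the study's age-exclusion structure
    exactly: 102 controls and 65 cases inside the 40-75 window, plus 41
    controls under 40, one 78-year-old control, one 23-year-old case and 9
    cases over 75 — so the age restriction keeps exactly 167 subjects.  The
    validation cohort holds 26 controls and 24 cases aged 40-75.  All CO2
    values pass QC (the printed cohort flow involves no CO2 exclusions).
    """
    base = config if config is not None else GeneratorConfig()
    base = replace(base, co2_low_fraction=0.0, seed=seed)
    rng = np.random.default_rng(np.random.SeedSequence(seed).generate_state(1)[0])

    blocks: list[tuple[str, np.ndarray]] = [
        ("control", _truncnorm(rng, *base.age_control, 40, 75, 102)),
        ("control", np.floor(rng.uniform(21, 40, size=41))),
        ("control", np.array([78.0])),
        ("case", _truncnorm(rng, *base.age_case, 40, 75, 65)),
        ("case", np.array([23.0])),
        ("case", np.floor(rng.uniform(76, 84, size=9))),
    ]
    training: list[BreathSample] = []
    start = 0
    for group, ages in blocks:
        samples, _ = _draw_block(rng, base, group, ages, start)
        training.extend(samples)
        start += ages.size

    validation: list[BreathSample] = []
    for group, n in (("control", 26), ("case", 24)):
        mean_sd = base.age_control if group == "control" else base.age_case
        ages = _truncnorm(rng, *mean_sd, 40, 75, n)
        samples, _ = _draw_block(rng, base, group, ages, start)
        validation.extend(samples)
        start += n
    return training, validation
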