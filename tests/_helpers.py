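"""Shared data builders for the test suite."""

import numpy as np

from breathvoc import ENV_EXCESS_MASSES, STUDY_PANEL, build_cohort_table, generate_cohort
from breathvoc.synthetic import FeatureParams, GeneratorConfig, _shared

RETAINED_PANEL = STUDY_PANEL.drop(ENV_EXCESS_MASSES)
PLANTED = ("M37", "M60", "M75", "M91", "M106")


def logistic_data(seed=0, n=120, p=5, beta=None, intercept=0.3):
    """Bernoulli draws from a known logistic law over Gaussian features."""
    rng = np.random.default_rng(seed)
    X = rng.normal(size=(n, p))
    if beta is None:
        beta = np.zeros(p)
        beta[: min(3, p)] = [1.2, -1.5, 0.8][: min(3, p)]
    eta = intercept + X @ beta
    y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
    return X, y


def planted_config(seed, planted, delta=0.6, sigma=0.6, n=300, panel=RETAINED_PANEL):
    """Null breath cohort with a known informative subset planted.

    The per-feature standardized log-shift is delta/sigma (= 1 at the
    defaults, the regime where penalized selection is well-posed without the
    near-separation degeneracy of much larger shifts).
    """
    feats = {l: _shared(20.0, 0.7) for l in panel.names}
    for i, l in enumerate(planted):
        ratio = np.exp(delta) if i % 2 == 0 else np.exp(-delta)
        feats[l] = FeatureParams(20.0, 20.0 * ratio, sigma, sigma, 5.0, sigma)
    return GeneratorConfig(
        n_cases=n, n_controls=n, panel=panel, features=feats,
        env_excess_set=(), seed=seed,
    )


def planted_table(seed, planted, **kw):
    cfg = planted_config(seed, planted, **kw)
    samples, _ = generate_cohort(cfg)
    alv = [s for s in samples if s.sample_type == "alveolar"]
    return build_cohort_table(alv, cfg.panel)
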