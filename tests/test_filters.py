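"""CO2 QC, age restriction and the alveolar-gradient filter."""

import math

import numpy as np
import pytest
from scipy import stats

from breathvoc import (
    ENV_EXCESS_MASSES,
    STUDY_PANEL,
    age_restrict,
    gradient_filter,
    qc_co2_filter,
)
from breathvoc.errors import ValidationError


class TestCo2QC:
    @pytest.mark.parametrize(
        "co2,kept", [(1.9, False), (2.0, True), (2.1, True), (0.0, False)]
    )
    def test_strictly_below_threshold_rejected(self, make_sample, co2, kept):
        k, r = qc_co2_filter([make_sample("S1", co2=co2)])
        assert (len(k) == 1) == kept
        if not kept:
            assert "CO2" in r[0][1]

    def test_counts_partition_and_idempotence(self, make_sample):
        samples = [make_sample(f"S{i}", co2=c) for i, c in
                   enumerate([1.0, 1.5, 1.99, 2.0, 3.0, 4.0, 5.0, 2.5, 6.0, 2.2])]
        kept, rejected = qc_co2_filter(samples)
        assert len(kept) == 7 and len(rejected) == 3
        assert len(kept) + len(rejected) == len(samples)
        kept2, rejected2 = qc_co2_filter(kept)
        assert kept2 == kept and rejected2 == []

    def test_environmental_samples_always_kept(self, make_sample):
        env = make_sample("S1", stype="environmental", co2=0.04)
        kept, _ = qc_co2_filter([env])
        assert kept == [env]

    def test_missing_co2_is_error(self, make_sample):
        with pytest.raises(ValidationError, match="CO2"):
            qc_co2_filter([make_sample("S1", co2=None)])


class TestAgeRestriction:
    @pytest.mark.parametrize("age,kept", [(39.9, False), (40, True), (75, True), (75.1, False)])
    def test_inclusive_window(self, make_sample, age, kept):
        k, _ = age_restrict([make_sample("S1", age=age)])
        assert (len(k) == 1) == kept

    def test_unbounded_window_is_identity_and_narrowing_monotone(self, make_sample):
        samples = [make_sample(f"S{i}", age=a) for i, a in enumerate([21, 40, 55, 75, 83])]
        k_all, _ = age_restrict(samples, -math.inf, math.inf)
        assert k_all == samples
        prev = len(samples)
        for lo, hi in [(30, 80), (40, 75), (50, 70), (60, 60)]:
            k, _ = age_restrict(samples, lo, hi)
            assert len(k) <= prev
            prev = len(k)

    def test_empty_input(self):
        assert age_restrict([]) == ([], [])

    def test_negative_age_is_error(self, make_sample):
        with pytest.raises(ValidationError):
            age_restrict([make_sample("S1", age=-1.0)])

    def test_published_exclusion_structure_gives_167(self, published_pair):
        training, _ = published_pair
        alveolar = [s for s in training if s.sample_type == "alveolar"]
        assert len(alveolar) == 219
        kept, excluded = age_restrict(alveolar)
        assert len(kept) == 167
        assert sum(s.group == "control" for s in kept) == 102
        assert sum(s.group == "case" for s in kept) == 65
        assert len(excluded) == 52


class TestGradientFilter:
    def test_explicit_list_removes_published_masses(self, published_pair):
        training, _ = published_pair
        alv = [s for s in training if s.sample_type == "alveolar"]
        res = gradient_filter(alv, mode="explicit_list", explicit_list=ENV_EXCESS_MASSES)
        assert res.retained.count == 70
        assert set(res.excluded) == set(ENV_EXCESS_MASSES)
        assert set(res.retained.names) | set(res.excluded) == set(STUDY_PANEL.names)

    def test_explicit_list_count_identity(self, tiny_cohort):
        alv = [s for s in tiny_cohort if s.sample_type == "alveolar"]
        res = gradient_filter(alv, mode="explicit_list", explicit_list=["M34"])
        assert res.retained.count == alv[0].panel.count - 1

    def test_identical_env_and_alv_retained(self, make_sample):
        alv = [make_sample(f"S{i}", conc=(50.0, 10.0, 1.0)) for i in range(12)]
        env = [
            make_sample(f"S{i}", stype="environmental", conc=(50.0, 10.0, 1.0))
            for i in range(12)
        ]
        res = gradient_filter(alv, env, mode="test")
        assert res.excluded == ()

    def test_tenfold_environmental_excess_excluded(self, make_sample):
        # env = 10 x alv on every one of 30 pairs: the one-sided signed-rank
        # p-value is 2^-30, far below alpha
        rng = np.random.default_rng(1)
        alv, env = [], []
        for i in range(30):
            base = rng.lognormal(3.0, 0.4, size=3)
            alv.append(make_sample(f"S{i}", conc=tuple(base)))
            env.append(
                make_sample(
                    f"S{i}", stype="environmental",
                    conc=(base[0], 10 * base[1], base[2]),
                )
            )
        res = gradient_filter(alv, env, mode="test")
        assert "M34" in res.excluded
        p = res.statistics.set_index("label").loc["M34", "p_value"]
        assert p == pytest.approx(2.0**-30, rel=1e-9)

    def test_signed_rank_pvalue_matches_enumeration(self):
        # independent oracle: enumerate all sign assignments at small n
        rng = np.random.default_rng(3)
        diff = rng.normal(0.4, 1.0, size=9)
        ranks = stats.rankdata(np.abs(diff))
        w_obs = ranks[diff > 0].sum()
        count = 0
        n = len(diff)
        for mask in range(2**n):
            signs = [(mask >> i) & 1 for i in range(n)]
            w = sum(r for r, s in zip(ranks, signs) if s)
            count += w >= w_obs
        p_enum = count / 2**n
        p_scipy = stats.wilcoxon(diff, alternative="greater").pvalue
        assert p_scipy == pytest.approx(p_enum, abs=1e-12)

    def test_no_pairing_information_is_error(self, make_sample):
        alv = [make_sample("S1")]
        env = [make_sample("S2", stype="environmental")]
        with pytest.raises(ValidationError):
            gradient_filter(alv, env, mode="test")
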