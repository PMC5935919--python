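"""Two-stage pipeline: screening, iterated fit, bootstrap CIs, serialization,
and the published coefficient table."""

import dataclasses

import numpy as np
import pytest

from breathvoc import (
    STUDY_PANEL,
    ENV_EXCESS_MASSES,
    DiagnosticModel,
    apply_published_model,
    bootstrap_ci,
    build_cohort_table,
    generate_cohort,
    iterated_fit,
    screen_stage,
)
from breathvoc.errors import ValidationError
from breathvoc.published import FINAL_MODEL_CI, FINAL_MODEL_COEFFICIENTS
from _helpers import PLANTED, planted_table


class TestScreenStage:
    def test_planted_signal_survives_screen(self):
        # the screen must keep every informative feature (it may keep noise
        # on top: its job is only to discard, never to finalize)
        hits = 0
        reps = 8
        for seed in range(reps):
            table = planted_table(seed, PLANTED, n=250)
            res = screen_stage(table, seed, n_folds=8, n_lambda=40)
            hits += set(PLANTED) <= set(res.retained_features)
        assert hits >= int(0.9 * reps)

    def test_pure_noise_with_strong_penalty_gives_small_or_empty_set(self):
        table = planted_table(0, (), n=60)
        res = screen_stage(table, 0, n_folds=5, n_lambda=8, min_ratio=0.5)
        assert len(res.retained_features) <= 5


class TestIteratedFit:
    def test_final_model_nests_in_screen_and_keeps_planted(self):
        table = planted_table(3, PLANTED)
        model = iterated_fit(table, 3, n_folds=10, n_lambda=50)
        assert set(model.terms) <= set(model.adaptive_terms)
        assert set(PLANTED) <= set(model.selected_vocs)
        assert all(model.coefficient(t, "standardized") != 0 for t in model.terms)

    def test_seeded_determinism(self):
        table = planted_table(4, PLANTED, n=120)
        m1 = iterated_fit(table, 11, n_folds=8, n_lambda=30)
        m2 = iterated_fit(table, 11, n_folds=8, n_lambda=30)
        assert m1.terms == m2.terms
        np.testing.assert_array_equal(m1.beta_std, m2.beta_std)
        assert m1.lambdas == m2.lambdas

    def test_raw_and_standardized_scales_agree_on_predictions(self):
        table = planted_table(5, PLANTED, n=150)
        model = iterated_fit(table, 5, n_folds=8, n_lambda=30)
        X = table.frame[list(model.terms)].to_numpy(dtype=float)
        sub = model.standardization.subset(model.terms)
        eta_std = model.intercept_std + sub.transform(X) @ model.beta_std
        eta_raw = model.intercept_raw + X @ model.beta_raw
        np.testing.assert_allclose(eta_std, eta_raw, atol=1e-8)


@pytest.fixture(scope="module")
def fitted():
    table = planted_table(6, PLANTED, n=200)
    model = iterated_fit(table, 6, n_folds=8, n_lambda=30)
    return table, model


class TestBootstrapCI:
    def test_degenerate_resampling_gives_zero_width(self, fitted):
        table, model = fitted
        m = bootstrap_ci(table, model, n_boot=5, seed=0, resample=False)
        for t in model.terms:
            lo, hi = m.ci["standardized"][t]
            assert lo == pytest.approx(hi, abs=1e-9)
            assert lo == pytest.approx(model.coefficient(t, "standardized"), abs=1e-6)

    def test_intervals_ordered_and_cover_estimates(self, fitted):
        table, model = fitted
        m = bootstrap_ci(table, model, n_boot=40, seed=1)
        inside = 0
        for t in m.terms:
            lo, hi = m.ci["standardized"][t]
            assert lo <= hi
            inside += lo <= m.coefficient(t, "standardized") <= hi
        assert inside >= int(0.9 * len(m.terms))

    def test_strong_planted_terms_keep_sign(self, fitted):
        table, model = fitted
        m = bootstrap_ci(table, model, n_boot=40, seed=2)
        for t in set(PLANTED) & set(m.terms):
            lo, hi = m.ci["standardized"][t]
            point = m.coefficient(t, "standardized")
            assert np.sign(lo) == np.sign(hi) == np.sign(point)

    def test_too_few_resamples_rejected(self, fitted):
        table, model = fitted
        with pytest.raises(ValidationError):
            bootstrap_ci(table, model, n_boot=1, seed=0)


class TestSerialization:
    def test_json_round_trip_is_bit_exact(self, tmp_path):
        table = planted_table(7, PLANTED, n=150)
        model = iterated_fit(table, 7, n_folds=8, n_lambda=30)
        model = bootstrap_ci(table, model, n_boot=10, seed=3).with_cutoff(0.42)
        path = tmp_path / "model.json"
        model.to_json(path)
        back = DiagnosticModel.from_json(path)
        assert back.terms == model.terms
        np.testing.assert_array_equal(back.beta_std, model.beta_std)
        np.testing.assert_array_equal(back.beta_raw, model.beta_raw)
        assert back.intercept_raw == model.intercept_raw
        assert back.cutoff == model.cutoff
        assert back.ci == model.ci
        np.testing.assert_array_equal(
            back.adaptive_penalty_weights, model.adaptive_penalty_weights
        )
        scores_a = model.predict_proba(table)
        scores_b = back.predict_proba(table)
        np.testing.assert_array_equal(scores_a, scores_b)

    def test_corrupt_document_rejected(self, tmp_path):
        p = tmp_path / "bad.json"
        p.write_text('{"format": "something-else"}')
        with pytest.raises(ValidationError):
            DiagnosticModel.from_json(p)

    def test_invalid_cutoff_rejected(self):
        table = planted_table(8, PLANTED, n=120)
        model = iterated_fit(table, 8, n_folds=8, n_lambda=20)
        with pytest.raises(ValidationError):
            model.with_cutoff(1.5)


class TestPublishedModel:
    def test_intercept_only_evaluation(self):
        features = {v: 0.0 for v in FINAL_MODEL_COEFFICIENTS if v not in ("intercept", "age")}
        p = apply_published_model(features, age=0.0)
        assert p == pytest.approx(1 / (1 + np.exp(4.832765)), abs=1e-12)

    def test_m89_coefficient_is_positive_monotone(self):
        base = {v: 10.0 for v in FINAL_MODEL_COEFFICIENTS if v not in ("intercept", "age")}
        lo = apply_published_model(base, age=60.0)
        base["M89"] = 20.0
        hi = apply_published_model(base, age=60.0)
        assert hi > lo

    def test_case_median_profile_scores_above_control_median_profile(self):
        control = {
            "ammonia": 91.0, "M34": 19.4, "M43": 1025.7, "M44": 7220.3,
            "M62": 7.3, "sulfur dioxide": 11.0, "M71": 31.9, "M74": 7.9,
            "M89": 1.3, "M112": 8.9,
        }
        case = {
            "ammonia": 106.7, "M34": 12.4, "M43": 1195.7, "M44": 6106.7,
            "M62": 5.7, "sulfur dioxide": 6.0, "M71": 42.2, "M74": 8.4,
            "M89": 3.5, "M112": 14.0,
        }
        assert apply_published_model(case, 61.0) > apply_published_model(control, 53.0)

    def test_missing_feature_is_error(self):
        with pytest.raises(ValidationError, match="missing feature"):
            apply_published_model({"ammonia": 100.0}, age=60.0)

    def test_published_ci_bounds_are_ordered_and_match_terms(self):
        assert set(FINAL_MODEL_CI) == set(FINAL_MODEL_COEFFICIENTS)
        for term, (lo, hi) in FINAL_MODEL_CI.items():
            assert lo <= hi
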