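"""The activity algorithm: coding, gate, two-stage fit, combination, score."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.special import logit

from acrodat.errors import (
    CoherenceWarning,
    DegenerateModelError,
    GateViolationError,
    NotFittedError,
    ValidationError,
)
from acrodat.model import (
    FIVE_PARAM_CODING,
    THREE_PARAM_CODING,
    ActivityProbabilities,
    CovariateCoding,
    GiniCartClassifier,
    TwoStageActivityClassifier,
    acrodat_score,
    classify,
    code_covariates,
    combine_probabilities,
    fit_cart,
    fit_two_stage,
    is_gated,
    score_all_scenarios,
)
from acrodat.scenario import decode_scenario, enumerate_scenarios
from acrodat.simulate import SimConfig, simulate_ratings


def ratings_as_pairs(rt):
    return [
        (tuple(decode_scenario(s)), r)
        for s, r in zip(rt.df["scenario_id"], rt.df["rating"])
    ]


@pytest.fixture(scope="module")
def fitted_model():
    rt, _ = simulate_ratings(SimConfig(n_raters=40, per_rater=60, seed=9))
    return fit_two_stage(ratings_as_pairs(rt), coding="three_param")


class TestCovariateCoding:
    def test_full_coding_has_ten_columns(self):
        assert FIVE_PARAM_CODING.n_columns == 10
        assert code_covariates((1, 1, 1, 1, 1), FIVE_PARAM_CODING).tolist() == [0.0] * 10

    def test_default_coding_indicator_pattern(self):
        row = code_covariates((2, 2, 3, 2, 1), THREE_PARAM_CODING)
        # columns: comorb_2, comorb_3, symp_2, symp_3, qol_2, qol_3
        assert row.tolist() == [0, 1, 1, 0, 0, 0]

    def test_unknown_parameter_rejected(self):
        with pytest.raises(ValidationError):
            CovariateCoding(("igf", "bogus"))


class TestScore:
    @pytest.mark.parametrize(
        "p,expected",
        [((1, 0, 0), 0.0), ((0, 1, 0), 0.5), ((0, 0, 1), 1.0), ((0.25, 0.5, 0.25), 0.5)],
    )
    def test_vertices_and_midpoint(self, p, expected):
        assert acrodat_score(p) == pytest.approx(expected)

    def test_non_normalized_input_rejected(self):
        with pytest.raises(ValidationError):
            acrodat_score((0.5, 0.5, 0.5))

    @given(st.tuples(st.floats(0.001, 1), st.floats(0.001, 1), st.floats(0.001, 1)))
    @settings(max_examples=200)
    def test_linear_on_simplex_with_unit_range(self, raw):
        p = np.array(raw) / sum(raw)
        s = acrodat_score(p)
        assert 0.0 <= s <= 1.0
        # linearity: score equals the probability-weighted vertex scores
        assert s == pytest.approx(p[1] * 0.5 + p[2] * 1.0)


class TestGate:
    def test_gate_predicate(self):
        assert is_gated((3, 1, 1, 1, 1))
        assert is_gated((1, 3, 2, 2, 2))
        assert not is_gated((2, 2, 3, 3, 3))

    def test_all_135_gated_vectors_classify_sda(self, fitted_model, level_grid):
        gated = [v for v in level_grid if v[0] == 3 or v[1] == 3]
        assert len(gated) == 135  # 81 + 81 - 27 by inclusion-exclusion
        preds = fitted_model.predict(np.array(gated))
        assert (preds == "S-DA").all()
        assert fitted_model.acrodat_scores(np.array(gated)).tolist() == [1.0] * 135

    def test_gate_rows_excluded_from_fit(self):
        data = [((3, 1, 1, 1, 1), "S")] * 50 + [
            ((1, 1, 1, 1, 1), "S"),
            ((1, 1, 2, 2, 2), "M-DA"),
            ((1, 1, 3, 3, 3), "S-DA"),
        ] * 30
        est = fit_two_stage(data)
        assert est.n_gated_ == 50
        assert est.n_retained_ == 90

    def test_combination_refused_for_gated_vector(self, fitted_model):
        with pytest.raises(GateViolationError):
            combine_probabilities(fitted_model, (3, 1, 1, 1, 1))

    def test_classify_gated_returns_marker_and_unit_score(self, fitted_model):
        label, probs, score = classify(fitted_model, (1, 3, 1, 1, 1))
        assert (label, probs, score) == ("S-DA", "gate", 1.0)


class TestCombination:
    def _manual_model(self, p1, p2, mode):
        """A fitted shell whose two stages predict constants p1, p2."""
        est = TwoStageActivityClassifier(coding="three_param", mode=mode)
        d = {
            "coding": list(THREE_PARAM_CODING.included_params),
            "mode": mode,
            "ridge": 0.0,
            "model1": {"intercept": float(logit(p1)), "coefficients": [0.0] * 6,
                       "converged": True},
            "model2": {"intercept": float(logit(p2)), "coefficients": [0.0] * 6,
                       "converged": True},
        }
        return TwoStageActivityClassifier.from_dict(d)

    def test_literal_arithmetic(self):
        est = self._manual_model(0.5, 0.2, "literal")
        p = combine_probabilities(est, (1, 1, 1, 1, 1))
        assert p == pytest.approx((0.5, 0.3, 0.2))

    def test_literal_clamps_and_warns_on_incoherence(self):
        est = self._manual_model(0.9, 0.4, "literal")
        with pytest.warns(CoherenceWarning):
            p = combine_probabilities(est, (1, 1, 1, 1, 1))
        assert p.p_mda == 0.0
        assert p.p_s + p.p_sda == pytest.approx(1.0)
        assert p.p_s / p.p_sda == pytest.approx(0.9 / 0.4)
        assert est.n_clamped_ == 1

    def test_conditional_arithmetic(self):
        est = self._manual_model(0.5, 0.2, "conditional")
        p = combine_probabilities(est, (1, 1, 1, 1, 1))
        assert p == pytest.approx((0.5, 0.4, 0.1))

    @given(st.floats(0.01, 0.99), st.floats(0.01, 0.99),
           st.sampled_from(["literal", "conditional"]))
    @settings(max_examples=100)
    def test_combination_always_normalized(self, p1, p2, mode):
        est = self._manual_model(p1, p2, mode)
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", CoherenceWarning)
            p = combine_probabilities(est, (2, 2, 2, 2, 2))
        assert sum(p) == pytest.approx(1.0)
        assert min(p) >= 0.0


class TestTwoStageFit:
    def test_intercept_only_reproduces_empirical_proportions(self):
        # covariates held at the reference level: the ML intercept is the
        # exact logit of the empirical proportion (closed-form oracle)
        rng = np.random.default_rng(0)
        n = 3000
        X = np.ones((n, 5), dtype=int)
        X[:, :2] = rng.integers(1, 3, size=(n, 2))  # vary only gate-free igf/tumor
        y = rng.choice(["S", "M-DA", "S-DA"], size=n, p=(0.5, 0.3, 0.2))
        est = TwoStageActivityClassifier(coding="three_param", mode="conditional").fit(X, y)
        p_s_hat = (y == "S").mean()
        p2_hat = (y[y != "S"] == "S-DA").mean()
        assert est.model1_.intercept == pytest.approx(logit(p_s_hat), abs=1e-4)
        assert np.abs(est.model1_.coefficients).max() < 1e-4
        assert est.model2_.intercept == pytest.approx(logit(p2_hat), abs=1e-4)
        # and the score equation holds on random covariates too
        X2 = rng.integers(1, 3, size=(n, 5))
        est2 = TwoStageActivityClassifier(coding="three_param", mode="conditional").fit(X2, y)
        assert est2.model1_.predict(X2).mean() == pytest.approx(p_s_hat, abs=1e-4)

    def test_coefficient_recovery_within_three_standard_errors(self, recovery_config):
        # sequential-family truth IS a two-stage logistic with known
        # coefficients: level-2 indicator -w/s, level-3 indicator -2w/s
        cfg = SimConfig(**{**recovery_config.__dict__, "n_raters": 50, "seed": 13})
        rt, _ = simulate_ratings(cfg)  # ~5,400 ratings
        est = fit_two_stage(ratings_as_pairs(rt), coding="three_param", mode="conditional")
        s = cfg.noise_sd
        truth1 = np.array([[-w / s, -2 * w / s] for w in cfg.weights[2:]]).ravel()
        Z = THREE_PARAM_CODING.design_matrix(
            np.array([tuple(decode_scenario(i)) for i in cfg.common_ids])
        )
        # observed-information standard errors at the fit
        reps = np.repeat(Z, cfg.n_raters, axis=0)
        eta = est.model1_.intercept + reps @ est.model1_.coefficients
        w_fisher = np.exp(eta) / (1 + np.exp(eta)) ** 2
        Zd = np.column_stack([np.ones(len(reps)), reps])
        cov = np.linalg.inv(Zd.T @ (Zd * w_fisher[:, None]))
        se = np.sqrt(np.diag(cov))[1:]
        assert np.all(np.abs(est.model1_.coefficients - truth1) < 3 * se)

    def test_empty_second_stage_is_degenerate(self):
        data = [((1, 1, 1, 1, 1), "S")] * 50
        with pytest.raises(DegenerateModelError):
            fit_two_stage(data)

    def test_unfitted_model_refuses_to_predict(self):
        with pytest.raises(NotFittedError):
            TwoStageActivityClassifier().predict(np.ones((1, 5), int))

    def test_sklearn_params_round_trip(self):
        est = TwoStageActivityClassifier(ridge=0.5, mode="conditional")
        params = est.get_params()
        assert params["ridge"] == 0.5
        clone = TwoStageActivityClassifier(**params)
        assert clone.get_params() == params


class TestClassify:
    def test_stable_profile_classified_stable(self, fitted_model):
        # all-level-1 profile: simulator truth strongly favors S, matching
        # the unanimous stable rating of the mildest common scenario
        label, probs, score = classify(fitted_model, (1, 1, 1, 1, 1))
        assert label == "S"
        assert probs.p_s > 0.6
        assert score < 0.35

    def test_severe_compensatory_profile_not_stable(self, fitted_model):
        label, _, score = classify(fitted_model, (2, 2, 3, 3, 3))
        assert label == "M-DA"
        assert score > 0.4

    def test_score_all_scenarios_report(self, fitted_model):
        report = score_all_scenarios(fitted_model)
        assert len(report) == 243
        assert int(report["gated"].sum()) == 135
        assert (report.loc[report["gated"], "activity_class"] == "S-DA").all()
        assert report.loc[report["scenario_id"] == 243, "activity_class"].item() == "S-DA"
        non_gate = report[~report["gated"]]
        assert non_gate["score"].between(0, 1).all()
        sums = non_gate[["p_s", "p_mda", "p_sda"]].sum(axis=1)
        assert np.allclose(sums, 1.0)

    def test_serialization_round_trip(self, fitted_model):
        clone = TwoStageActivityClassifier.from_dict(fitted_model.to_dict())
        grid = np.array([tuple(v) for _, v in enumerate_scenarios()])
        assert np.allclose(clone.predict_proba(grid), fitted_model.predict_proba(grid))


class TestCart:
    def test_gate_rule_yields_gate_splits_with_pure_leaves(self):
        # deterministic rule: S-DA iff igf=3 or tumor=3, else S
        data = []
        for _, v in enumerate_scenarios():
            label = "S-DA" if (v.igf == 3 or v.tumor == 3) else "S"
            data.extend([(tuple(v), label)] * 2)
        root = fit_cart(data, min_leaf=5)
        assert root.param in ("igf", "tumor")
        assert root.levels_left == frozenset({1, 2})
        assert root.right.is_leaf and root.right.prediction == "S-DA"
        assert root.right.class_distribution[2] == pytest.approx(1.0)
        child = root.left
        assert child.param in ("igf", "tumor") and child.param != root.param
        assert child.right.prediction == "S-DA"
        assert child.left.is_leaf and child.left.prediction == "S"

    def test_single_class_data_gives_single_leaf(self):
        data = [((1, 1, 1, 1, 1), "S"), ((2, 2, 2, 2, 2), "S")] * 10
        root = fit_cart(data, min_leaf=1)
        assert root.is_leaf
        assert root.prediction == "S"

    def test_empty_data_rejected(self):
        with pytest.raises(ValidationError):
            fit_cart([], min_leaf=1)

    def test_accuracy_near_bayes_rate_on_simulated_data(self):
        cfg = SimConfig(n_raters=120, per_rater=80, gate_in_truth=True, seed=21)
        rt, truth = simulate_ratings(cfg)
        est = GiniCartClassifier(min_leaf=40).fit(
            np.array([tuple(decode_scenario(s)) for s in rt.df["scenario_id"]]),
            rt.df["rating"].to_numpy(dtype=object),
        )
        # held-out draw from the same generator
        rt2, _ = simulate_ratings(SimConfig(**{**cfg.__dict__, "seed": 22}))
        X2 = np.array([tuple(decode_scenario(s)) for s in rt2.df["scenario_id"]])
        y2 = rt2.df["rating"].to_numpy(dtype=object)
        acc = (est.predict(X2) == y2).mean()
        # Bayes rate: mean of the per-scenario max class probability
        T = truth.as_array()
        ids = rt2.df["scenario_id"].to_numpy() - 1
        bayes = T[ids].max(axis=1).mean()
        assert acc >= bayes - 0.05
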