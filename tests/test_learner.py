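"""Learner mechanics: splitting, resampling, reduction, CV, simplification."""

import datetime as dt

import numpy as np
import pytest

from phenoforge.features import build_feature_matrix, labels_to_bool
from phenoforge.learner import (
    Combination,
    LearnerConfig,
    Order,
    Reducer,
    Sampling,
    TrainedTree,
    combinations,
    nested_cv,
    reduce_features,
    resample,
    select_best_combination,
    simplify_definition,
    split_train_validation,
    stratified_folds,
    train_final_tree,
    validate_final,
)
from phenoforge.pipeline import audit_no_leakage
from phenoforge.rules import evaluate_definition
from phenoforge.synthetic import CohortConfig, generate_cohort
from phenoforge.types import Label

from conftest import make_chart, make_record


def dummy_charts(n):
    return [
        make_chart([make_record(pid=f"P{i}", code="401")], pid=f"P{i}", label=Label.NON_CASE)
        for i in range(n)
    ]


class TestSplit:
    def test_reference_sizes(self):
        train, valid = split_train_validation(dummy_charts(2775), seed=0)
        assert {len(train), len(valid)} == {1388, 1387}

    def test_deterministic(self):
        charts = dummy_charts(101)
        a = split_train_validation(charts, seed=4)
        b = split_train_validation(charts, seed=4)
        assert [c.patient_id for c in a[0]] == [c.patient_id for c in b[0]]

    def test_two_charts(self):
        train, valid = split_train_validation(dummy_charts(2), seed=0)
        assert len(train) == 1 and len(valid) == 1

    def test_disjoint_and_exhaustive(self):
        charts = dummy_charts(51)
        train, valid = split_train_validation(charts, seed=1)
        ids = {c.patient_id for c in train} | {c.patient_id for c in valid}
        assert len(ids) == 51
        audit_no_leakage(
            [c.patient_id for c in train], [c.patient_id for c in valid]
        )


class TestStratifiedFolds:
    def test_exact_divisibility(self):
        y = np.array([True] * 100 + [False] * 400)
        assign = stratified_folds(y, 10, seed=0)
        for f in range(10):
            assert int(np.sum(y[assign == f])) == 10
            assert int(np.sum(~y[assign == f])) == 40

    def test_plus_minus_one(self):
        y = np.array([True] * 101 + [False] * 400)
        assign = stratified_folds(y, 10, seed=0)
        case_counts = [int(np.sum(y[assign == f])) for f in range(10)]
        assert set(case_counts) <= {10, 11}

    def test_k_one_rejected(self):
        with pytest.raises(ValueError):
            stratified_folds(np.array([True, False] * 5), 1, seed=0)

    def test_class_smaller_than_k_rejected(self):
        y = np.array([True] * 3 + [False] * 50)
        with pytest.raises(ValueError):
            stratified_folds(y, 10, seed=0)


class TestResample:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(0)
        X = rng.integers(0, 2, size=(500, 4)).astype(np.uint8)
        y = np.array([True] * 100 + [False] * 400)
        return X, y

    def test_under(self, data):
        X, y = data
        Xr, yr = resample(X, y, Sampling.UNDER, seed=1)
        assert int(yr.sum()) == 100 and int((~yr).sum()) == 100

    def test_over(self, data):
        X, y = data
        Xr, yr = resample(X, y, Sampling.OVER, seed=1)
        assert int(yr.sum()) == 400 and int((~yr).sum()) == 400

    def test_combined_geometric_mean(self, data):
        X, y = data
        Xr, yr = resample(X, y, Sampling.COMBINED, seed=1)
        assert int(yr.sum()) == 200 and int((~yr).sum()) == 200

    def test_none_identity(self, data):
        X, y = data
        Xr, yr = resample(X, y, Sampling.NONE, seed=1)
        assert Xr is X and yr is y

    def test_original_untouched(self, data):
        X, y = data
        X0 = X.copy()
        resample(X, y, Sampling.COMBINED, seed=1)
        assert np.array_equal(X, X0)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            resample(np.zeros((3, 1)), np.array([True] * 3), Sampling.UNDER, 0)


class TestReduceFeatures:
    @pytest.fixture
    def data(self):
        rng = np.random.default_rng(2)
        y = np.array([True] * 30 + [False] * 70)
        X = rng.integers(0, 2, size=(100, 12)).astype(np.float32)
        X[:, 3] = y  # perfectly informative column
        X[:, 7] = 0  # constant all-zero column
        return X, y

    @pytest.mark.parametrize("reducer", [Reducer.RFE, Reducer.KBF])
    def test_identity_when_target_is_all(self, data, reducer):
        X, y = data
        assert reduce_features(X, y, reducer, X.shape[1]) == list(range(X.shape[1]))

    @pytest.mark.parametrize("reducer", [Reducer.RFE, Reducer.KBF])
    def test_label_copy_survives(self, data, reducer):
        X, y = data
        kept = reduce_features(X, y, reducer, 3, seed=0)
        assert 3 in kept

    def test_zero_column_eliminated_first_by_kbf(self, data):
        X, y = data
        kept = reduce_features(X, y, Reducer.KBF, X.shape[1] - 1, seed=0)
        assert 7 not in kept


class TestCombinations:
    def test_fourteen_rows(self):
        assert len(combinations(LearnerConfig())) == 14

    def test_labels_reflect_application_order(self):
        c = Combination(Sampling.OVER, Reducer.RFE, Order.REDUCE_THEN_SAMPLE)
        assert c.label == "RFE;random over-sampling"
        c = Combination(Sampling.OVER, Reducer.RFE, Order.SAMPLE_THEN_REDUCE)
        assert c.label == "random over-sampling;RFE"

    def test_none_collapsed(self):
        labels = [c.label for c in combinations(LearnerConfig())]
        assert labels.count("RFE;None") == 1
        assert labels.count("kBF;None") == 1
        assert not any(l == "None;RFE" for l in labels)


class TestSelectBest:
    def _result(self, f1, sn, ppv):
        import pandas as pd

        from phenoforge.learner import CombinationResult

        df = pd.DataFrame(
            {"sensitivity": [sn], "specificity": [0.9], "ppv": [ppv], "npv": [0.9], "f1": [f1]}
        )
        return CombinationResult(Combination(Sampling.NONE, Reducer.RFE, Order.REDUCE_THEN_SAMPLE), df)

    def test_single(self):
        r = self._result(0.5, 0.5, 0.5)
        assert select_best_combination([r]) is r

    def test_higher_f1_wins(self):
        a, b = self._result(0.799, 0.812, 0.786), self._result(0.720, 0.903, 0.598)
        assert select_best_combination([b, a]) is a

    def test_tie_broken_by_sensitivity(self):
        a, b = self._result(0.7, 0.9, 0.6), self._result(0.7, 0.8, 0.7)
        assert select_best_combination([b, a]) is a


@pytest.fixture(scope="module")
def tiny_training():
    """Zero-noise separable cohort, featurized, with desk-scale config."""
    cfg = CohortConfig(n_patients=240, seed=13, text_noise_rate=0.0,
                       reviewer_error_rate=0.0, unclassifiable_rate=0.0)
    cohort = generate_cohort(cfg)
    charts = cohort.labelled_charts
    matrix = build_feature_matrix(charts, min_support=5)
    labels = [c.label for c in charts]
    config = LearnerConfig(
        hyperparameter_grid={"criterion": ["gini"], "max_depth": [4], "class_weight": [None]},
        outer_folds=4,
        inner_folds=3,
        reduced_feature_count=15,
        seed=3,
    )
    return cohort, charts, matrix, labels, config


class TestNestedCV:
    def test_emits_fourteen_rows_and_perfect_combination(self, tiny_training):
        _, _, matrix, labels, config = tiny_training
        results = nested_cv(matrix, labels, config)
        assert len(results) == 14
        assert max(r.mean_f1 for r in results) == pytest.approx(1.0)
        for r in results:
            assert len(r.per_fold) == config.outer_folds

    def test_permuted_labels_near_baseline(self, tiny_training):
        _, _, matrix, labels, config = tiny_training
        rng = np.random.default_rng(1)
        permuted = list(rng.permutation(np.array([l.value for l in labels])))
        permuted = [Label(v) for v in permuted]
        results = nested_cv(matrix, permuted, config)
        best = select_best_combination(results)
        assert best.mean_f1 < 0.5  # signal destroyed


class TestFinalTreeAndSimplification:
    def test_perfect_feature_dominates(self, tiny_training):
        _, _, matrix, labels, config = tiny_training
        best = Combination(Sampling.NONE, Reducer.RFE, Order.REDUCE_THEN_SAMPLE)
        tree = train_final_tree(matrix, labels, best, config)
        assert sum(tree.importances.values()) == pytest.approx(1.0, abs=1e-9)
        top = max(tree.importances.items(), key=lambda kv: kv[1])
        assert top[0].startswith("code_prefix:")

    def test_constant_labels_single_leaf(self, tiny_training):
        _, _, matrix, _, config = tiny_training
        labels = [Label.NON_CASE] * len(matrix.patient_ids)
        best = Combination(Sampling.NONE, Reducer.RFE, Order.REDUCE_THEN_SAMPLE)
        tree = train_final_tree(matrix, labels, best, config)
        assert tree.importances == {}
        assert len(tree.rules) == 1 and tree.rules[0].verdict is False

    def test_candidate_count_and_recovery(self, tiny_training):
        cohort, charts, matrix, labels, config = tiny_training
        best = Combination(Sampling.NONE, Reducer.RFE, Order.REDUCE_THEN_SAMPLE)
        tree = train_final_tree(matrix, labels, best, config)
        s = min(9, len(tree.importances))
        result = simplify_definition(tree, matrix, labels, s=9)
        assert len(result.candidates) == s + s * (s - 1) // 2

    def test_singleton_preferred_on_tie(self):
        """A perfectly separating singleton beats any equal-scoring pair."""
        from phenoforge.features import FeatureMatrix, FeatureSpec, Variant
        from phenoforge.rules import MatchKind
        from phenoforge.types import DIAGNOSIS_SOURCES

        scope = frozenset(DIAGNOSIS_SOURCES)
        specs = [
            FeatureSpec(MatchKind.CODE_PREFIX, "627", scope, Variant.GE1_WHOLE),
            FeatureSpec(MatchKind.CODE_PREFIX, "6272", scope, Variant.GE1_WHOLE),
        ]
        y = np.array([True] * 6 + [False] * 6)
        a = y.astype(np.uint8)  # perfect feature
        b = a.copy()
        b[0] = 0  # strict subset: misses one case
        matrix = FeatureMatrix([f"P{i}" for i in range(12)], specs,
                               np.stack([a, b], axis=1), 8)
        fake = TrainedTree(specs=specs, importances={specs[0].name: 0.5, specs[1].name: 0.5},
                           rules=[], params={}, classifier=None)
        labels = [Label.CASE if v else Label.NON_CASE for v in y]
        result = simplify_definition(fake, matrix, labels, s=2)
        # pair (a OR b) == a exactly ties singleton {a}; simplicity wins
        assert result.chosen.feature_names == (specs[0].name,)
        assert len(result.candidates) == 3

    def test_equivalence_engine_vs_matrix(self, tiny_training):
        """Chosen definition: rule-engine verdicts == feature-column OR."""
        _, charts, matrix, labels, config = tiny_training
        best = Combination(Sampling.NONE, Reducer.RFE, Order.REDUCE_THEN_SAMPLE)
        tree = train_final_tree(matrix, labels, best, config)
        result = simplify_definition(tree, matrix, labels, s=9)
        cols = {s.name: j for j, s in enumerate(matrix.specs)}
        expected = np.zeros(len(charts), dtype=bool)
        for name in result.chosen.feature_names:
            expected |= matrix.values[:, cols[name]].astype(bool)
        engine = np.array(
            [evaluate_definition(c, result.chosen.definition) for c in charts]
        )
        assert np.array_equal(engine, expected)

    def test_validate_final_perfect_on_zero_noise(self, tiny_training):
        cohort, charts, matrix, labels, config = tiny_training
        report = validate_final(cohort.config.planted_definition, charts)
        assert report.sensitivity.value == 1.0
        assert report.specificity.value == 1.0

    def test_definition_matching_nothing(self, tiny_training):
        from phenoforge.rules import CaseDefinition, Clause, MatchKind

        _, charts, _, _, _ = tiny_training
        defn = CaseDefinition((Clause(MatchKind.CODE_PREFIX, "999"),))
        report = validate_final(defn, charts)
        assert report.sensitivity.value == 0.0
        assert report.specificity.value == 1.0


def test_audit_no_leakage_detects_overlap():
    with pytest.raises(RuntimeError, match="leakage"):
        audit_no_leakage(["a", "b"], ["b", "c"])
    digest = audit_no_leakage(["a"], ["b", "c"])
    assert len(digest) == 64
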