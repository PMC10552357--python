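"""Feature engineering: temporal variants, support filter, prescreen."""

import datetime as dt

import numpy as np
import pytest

from phenoforge.features import (
    adhoc_importance,
    adhoc_importance_scores,
    build_feature_matrix,
    labels_to_bool,
    prescreen_top_k,
)
from phenoforge.rules import evaluate_clause
from phenoforge.types import Label

from conftest import make_chart, make_record


def charts_with_code(n, code="627", dates=(dt.date(2018, 1, 1),), start=0):
    return [
        make_chart(
            [make_record(pid=f"P{start + i}", code=code, date=d) for d in dates],
            pid=f"P{start + i}",
        )
        for i in range(n)
    ]


class TestMinSupport:
    def test_boundary_nine_dropped_ten_kept(self):
        # "627" in 10 charts, "4019" in 9; filler keeps charts non-empty
        charts = charts_with_code(10, "627") + charts_with_code(9, "401.9", start=10)
        m10 = build_feature_matrix(charts, min_support=10)
        names = set(m10.names)
        assert "code_prefix:627|ge1" in names
        assert all("4019" not in n and "401" not in n for n in names)

    def test_generated_count_counts_all_variants(self):
        charts = charts_with_code(10, "627")
        m = build_feature_matrix(charts, min_support=1)
        # one base ("627"), four variants generated
        assert m.n_generated == 4


class TestTemporalVariants:
    def test_single_occurrence_only_ge1(self):
        charts = charts_with_code(10, "627")
        m = build_feature_matrix(charts, min_support=1)
        row = dict(zip(m.names, m.values[0]))
        assert row["code_prefix:627|ge1"] == 1
        assert row.get("code_prefix:627|ge2_12mo", 0) == 0
        assert row.get("code_prefix:627|ge2_24mo", 0) == 0
        assert row.get("code_prefix:627|ge2_whole", 0) == 0

    def test_pair_thirteen_months_apart(self):
        dates = (dt.date(2018, 1, 1), dt.date(2019, 2, 1))  # 396 days
        charts = charts_with_code(10, "627", dates=dates)
        m = build_feature_matrix(charts, min_support=1)
        row = dict(zip(m.names, m.values[0]))
        assert row["code_prefix:627|ge2_24mo"] == 1
        # the 12-month variant is 0 for everyone, so its column is
        # support-filtered away entirely
        assert row.get("code_prefix:627|ge2_12mo", 0) == 0
        assert row["code_prefix:627|ge2_whole"] == 1


def test_matrix_columns_reproducible_from_rule_engine(small_cohort):
    """Every column equals clause-engine re-evaluation of its spec."""
    charts = small_cohort.labelled_charts[:120]
    m = build_feature_matrix(charts, min_support=10)
    assert m.values.shape[1] > 20
    for j, spec in enumerate(m.specs):
        clause = spec.to_clause()
        recomputed = np.array([evaluate_clause(c, clause) for c in charts], dtype=np.uint8)
        assert np.array_equal(recomputed, m.values[:, j]), spec.name


def test_feature_scale_at_study_size(full_cohort):
    """Pre-support feature count lands in the expected 1e4-1e5 range."""
    m = build_feature_matrix(full_cohort.labelled_charts, min_support=10)
    assert 10_000 <= m.n_generated <= 250_000
    assert m.values.shape[1] >= 300  # enough survivors to prescreen


class TestAdhocImportance:
    def test_formula(self):
        y = np.array([True] * 100 + [False] * 100)
        col = np.zeros(200, dtype=np.uint8)
        col[:10] = 1  # TP=10
        col[100:102] = 1  # FP=2
        assert adhoc_importance(col, y) == pytest.approx(0.08)

    def test_tp_equals_fp_scores_zero(self):
        y = np.array([True] * 10 + [False] * 10)
        col = np.zeros(20, dtype=np.uint8)
        col[0] = col[10] = 1
        assert adhoc_importance(col, y) == 0.0

    def test_maximum_score(self):
        y = np.array([True] * 10 + [False] * 10)
        col = y.astype(np.uint8)
        assert adhoc_importance(col, y) == 1.0

    def test_no_cases_rejected(self):
        with pytest.raises(ValueError):
            adhoc_importance(np.ones(5, dtype=np.uint8), np.zeros(5, dtype=bool))

    def test_invariant_to_cohort_duplication(self):
        rng = np.random.default_rng(5)
        y = rng.random(50) < 0.3
        y[0] = True
        col = (rng.random(50) < 0.4).astype(np.uint8)
        doubled = adhoc_importance(np.tile(col, 2), np.tile(y, 2))
        assert adhoc_importance(col, y) == pytest.approx(doubled)


class TestPrescreen:
    def _matrix(self, charts):
        return build_feature_matrix(charts, min_support=1)

    def test_fewer_columns_than_k_keeps_all(self, small_cohort):
        charts = small_cohort.labelled_charts[:50]
        m = build_feature_matrix(charts, min_support=10)
        labels = [c.label for c in charts]
        out = prescreen_top_k(m, labels, k=10_000)
        assert out.values.shape[1] == m.values.shape[1]

    def test_planted_column_always_retained(self, small_cohort):
        charts = small_cohort.labelled_charts
        m = build_feature_matrix(charts, min_support=10)
        labels = labels_to_bool([c.label for c in charts])
        scores = adhoc_importance_scores(m.values, labels)
        top = prescreen_top_k(m, labels, k=1)
        best = float(scores.max())
        kept_score = adhoc_importance(top.values[:, 0], labels)
        assert kept_score == pytest.approx(best)

    def test_never_removes_strictly_better_column(self, small_cohort):
        charts = small_cohort.labelled_charts
        m = build_feature_matrix(charts, min_support=10)
        labels = labels_to_bool([c.label for c in charts])
        scores = adhoc_importance_scores(m.values, labels)
        k = 20
        kept = set(prescreen_top_k(m, labels, k=k).names)
        cutoff = np.sort(scores)[::-1][k - 1]
        for name, score in zip(m.names, scores):
            if score > cutoff:
                assert name in kept

    def test_tie_broken_lexicographically(self):
        # two identical columns tie; the lexicographically smaller name wins
        charts = []
        for i in range(12):
            recs = [make_record(pid=f"P{i}", code="627", date=dt.date(2018, 1, 1))]
            if i < 6:
                recs.append(
                    make_record(pid=f"P{i}", code="401.1", date=dt.date(2018, 2, 1))
                )
                recs.append(
                    make_record(pid=f"P{i}", code="585.9", date=dt.date(2018, 3, 1))
                )
            charts.append(make_chart(recs, pid=f"P{i}", label=Label.CASE if i < 6 else Label.NON_CASE))
        m = build_feature_matrix(charts, min_support=1)
        labels = [c.label for c in charts]
        # columns for 401*/585* are identical (present in the 6 cases only)
        out = prescreen_top_k(m, labels, k=1)
        assert out.names[0] == "code_prefix:4011|ge1"


def test_feature_matrix_csv_round_trip(tmp_path, small_cohort):
    charts = small_cohort.labelled_charts[:60]
    m = build_feature_matrix(charts, min_support=5)
    m.to_csv(tmp_path)
    m2 = type(m).from_csv(tmp_path)
    assert m2.names == m.names
    assert m2.patient_ids == m.patient_ids
    assert np.array_equal(m2.values, m.values)
    assert m2.n_generated == m.n_generated
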