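"""Chart -> binary feature matrix construction.

Every code (at several prefix depths, realising "or any sub-codes") and
every free-text word / adjacent word pair becomes a candidate feature
base; each base is expanded into four temporal variants:

* one or more occurrences anywhere in the chart,
* two or more within 12 consecutive months,
* two or more within 24 consecutive months,
* two or more anywhere in the chart.

All features are binary.  Bases seen in fewer than ``min_support``
patients are dropped (support counts patients, not records), and an ad
hoc importance score — (TP - FP) / number-of-cases — prescreens the
surviving columns down to the top *k* for the learner.
"""

from __future__ import annotations

import enum
from collections import Counter
from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rules import Clause, MatchKind, Window
from .text import NegationLexicon, default_lexicon, filter_negated, tokenize
from .types import (
    DIAGNOSIS_SOURCES,
    TEXT_SOURCES,
    CodeSystem,
    Label,
    PatientChart,
    Source,
    normalize_code,
)

#: ATC codes are hierarchical at character boundaries 1, 3, 4, 5, 7;
#: prefixes shorter than 3 characters are too coarse to be useful rules.
ATC_PREFIX_LENGTHS: tuple[int, ...] = (3, 4, 5, 7)
ICD9_MIN_PREFIX = 3


class Variant(str, enum.Enum):
    GE1_WHOLE = "ge1"
    GE2_12MO = "ge2_12mo"
    GE2_24MO = "ge2_24mo"
    GE2_WHOLE = "ge2_whole"


_VARIANT_CLAUSE = {
    Variant.GE1_WHOLE: (1, Window.WHOLE_CHART),
    Variant.GE2_12MO: (2, Window.MONTHS_12),
    Variant.GE2_24MO: (2, Window.MONTHS_24),
    Variant.GE2_WHOLE: (2, Window.WHOLE_CHART),
}


@dataclass(frozen=True)
class FeatureSpec:
    """One engineered feature: a (kind, pattern, scope) base plus variant."""

    match_kind: MatchKind
    pattern: str
    scope: frozenset[Source]
    variant: Variant

    @property
    def name(self) -> str:
        return f"{self.match_kind.value}:{self.pattern}|{self.variant.value}"

    def to_clause(self) -> Clause:
        min_count, window = _VARIANT_CLAUSE[self.variant]
        return Clause(
            match_kind=self.match_kind,
            pattern=self.pattern,
            min_count=min_count,
            window=window,
            scope=self.scope,
        )


@dataclass
class FeatureMatrix:
    """Binary patients x features matrix with feature provenance."""

    patient_ids: list[str]
    specs: list[FeatureSpec]
    values: np.ndarray  # uint8, shape (n_patients, n_specs)
    n_generated: int  # feature count before minimum-support filtering

    def __post_init__(self) -> None:
        if self.values.shape != (len(self.patient_ids), len(self.specs)):
            raise ValueError("matrix shape does not match ids/specs")

    @property
    def names(self) -> list[str]:
        return [s.name for s in self.specs]

    def select(self, cols: Sequence[int]) -> "FeatureMatrix":
        cols = list(cols)
        return FeatureMatrix(
            patient_ids=self.patient_ids,
            specs=[self.specs[c] for c in cols],
            values=self.values[:, cols],
            n_generated=self.n_generated,
        )

    def rows(self, idx: Sequence[int]) -> np.ndarray:
        return self.values[np.asarray(idx, dtype=int)]

    def to_csv(self, directory) -> None:
        """Persist as sparse triplets plus a feature dictionary."""
        import pandas as pd
        from pathlib import Path

        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        rows_idx, cols_idx = np.nonzero(self.values)
        pd.DataFrame(
            {
                "patient_id": [self.patient_ids[i] for i in rows_idx],
                "feature_name": [self.specs[j].name for j in cols_idx],
                "value": 1,
            }
        ).to_csv(directory / "features.csv", index=False)
        pd.DataFrame(
            [
                {
                    "name": s.name,
                    "match_kind": s.match_kind.value,
                    "pattern": s.pattern,
                    "variant": s.variant.value,
                    "scope": "|".join(sorted(src.value for src in s.scope)),
                }
                for s in self.specs
            ]
        ).to_csv(directory / "feature_dict.csv", index=False)
        pd.DataFrame({"patient_id": self.patient_ids}).to_csv(
            directory / "matrix_patients.csv", index=False
        )
        (directory / "matrix_meta.yaml").write_text(
            f"n_generated: {self.n_generated}\n"
        )

    @classmethod
    def from_csv(cls, directory) -> "FeatureMatrix":
        import pandas as pd
        import yaml
        from pathlib import Path

        directory = Path(directory)
        dict_df = pd.read_csv(directory / "feature_dict.csv", dtype=str)
        specs = [
            FeatureSpec(
                MatchKind(r.match_kind),
                r.pattern,
                frozenset(Source(s) for s in r.scope.split("|")),
                Variant(r.variant),
            )
            for r in dict_df.itertuples(index=False)
        ]
        patient_ids = pd.read_csv(directory / "matrix_patients.csv", dtype=str)[
            "patient_id"
        ].tolist()
        meta = yaml.safe_load((directory / "matrix_meta.yaml").read_text())
        values = np.zeros((len(patient_ids), len(specs)), dtype=np.uint8)
        row_of = {p: i for i, p in enumerate(patient_ids)}
        col_of = {s.name: j for j, s in enumerate(specs)}
        trip = pd.read_csv(directory / "features.csv", dtype=str)
        for r in trip.itertuples(index=False):
            values[row_of[r.patient_id], col_of[r.feature_name]] = 1
        return cls(patient_ids, specs, values, int(meta["n_generated"]))


# ---------------------------------------------------------------------------
# Base extraction


def _code_bases(record) -> list[tuple[MatchKind, str]]:
    norm = normalize_code(record.code)
    if record.code_system is CodeSystem.ICD9CM:
        if record.source not in DIAGNOSIS_SOURCES:
            return []
        lengths = range(ICD9_MIN_PREFIX, len(norm) + 1) if len(norm) > ICD9_MIN_PREFIX else [len(norm)]
    elif record.code_system is CodeSystem.ATC:
        if record.source is not Source.MEDICATION:
            return []
        lengths = [l for l in ATC_PREFIX_LENGTHS if l <= len(norm)] or [len(norm)]
    else:
        return []
    return [(MatchKind.CODE_PREFIX, norm[:l]) for l in lengths]


def _text_bases(record, lexicon: NegationLexicon) -> list[tuple[MatchKind, str]]:
    if record.source not in TEXT_SOURCES or not record.free_text:
        return []
    tokens = tokenize(filter_negated(record.free_text, lexicon))
    bases = [(MatchKind.TEXT_UNIGRAM, t) for t in set(tokens)]
    bases += [(MatchKind.TEXT_BIGRAM, f"{a} {b}") for a, b in set(zip(tokens, tokens[1:]))]
    return bases


def _base_scope(kind: MatchKind, pattern: str) -> frozenset[Source]:
    if kind is MatchKind.CODE_PREFIX:
        # ATC codes start with a letter, ICD-9-CM codes with a digit (V/E
        # codes are not used here); the scope follows the code system.
        return frozenset({Source.MEDICATION}) if pattern[0].isalpha() else frozenset(DIAGNOSIS_SOURCES)
    return frozenset(TEXT_SOURCES)


def _variant_flags(ordinals: list[int]) -> tuple[bool, bool, bool, bool]:
    """(ge1, ge2_12mo, ge2_24mo, ge2_whole) from sorted date ordinals."""
    if len(ordinals) < 2:
        return True, False, False, False
    gaps = [b - a for a, b in zip(ordinals, ordinals[1:])]
    mg = min(gaps)
    return True, mg <= 365, mg <= 730, True


def chart_base_dates(
    chart: PatientChart, lexicon: NegationLexicon
) -> dict[tuple[MatchKind, str], list[int]]:
    """Map each feature base present in the chart to its sorted date ordinals."""
    out: dict[tuple[MatchKind, str], list[int]] = {}
    for rec in chart.records:
        ordinal = rec.date.toordinal()
        bases = []
        if rec.code:
            bases.extend(_code_bases(rec))
        if rec.free_text:
            bases.extend(_text_bases(rec, lexicon))
        for base in bases:
            out.setdefault(base, []).append(ordinal)
    for dates in out.values():
        dates.sort()
    return out


def build_feature_matrix(
    charts: Sequence[PatientChart],
    min_support: int = 10,
    lexicon: NegationLexicon | None = None,
) -> FeatureMatrix:
    """Construct the binary feature matrix for a set of charts.

    Column semantics are exactly those of the clause engine: every
    column is reproducible by evaluating ``spec.to_clause()`` against
    the raw chart.  Columns supported by fewer than ``min_support``
    patients are dropped; ``n_generated`` records the feature count
    before that filter.
    """
    if not charts:
        raise ValueError("need at least one chart")
    if lexicon is None:
        lexicon = default_lexicon()

    per_patient = [chart_base_dates(c, lexicon) for c in charts]
    support: Counter = Counter()
    for bd in per_patient:
        support.update(bd.keys())
    n_generated = 4 * len(support)

    kept = sorted(
        (b for b, c in support.items() if c >= min_support),
        key=lambda b: (b[0].value, b[1]),
    )
    n = len(charts)
    base_index = {b: j for j, b in enumerate(kept)}
    # one uint8 block per variant, bases as columns
    variants = list(Variant)
    blocks = [np.zeros((n, len(kept)), dtype=np.uint8) for _ in variants]
    for i, bd in enumerate(per_patient):
        for base, dates in bd.items():
            j = base_index.get(base)
            if j is None:
                continue
            flags = _variant_flags(dates)
            for v, flag in enumerate(flags):
                if flag:
                    blocks[v][i, j] = 1

    specs: list[FeatureSpec] = []
    cols: list[np.ndarray] = []
    for v, variant in enumerate(variants):
        sums = blocks[v].sum(axis=0)
        for j, base in enumerate(kept):
            if sums[j] >= min_support:
                kind, pattern = base
                specs.append(FeatureSpec(kind, pattern, _base_scope(kind, pattern), variant))
                cols.append(blocks[v][:, j])
    order = np.argsort([s.name for s in specs], kind="stable")
    specs = [specs[o] for o in order]
    values = (
        np.stack([cols[o] for o in order], axis=1) if specs else np.zeros((n, 0), dtype=np.uint8)
    )
    return FeatureMatrix(
        patient_ids=[c.patient_id for c in charts],
        specs=specs,
        values=values,
        n_generated=n_generated,
    )


# ---------------------------------------------------------------------------
# Ad hoc importance prescreen


def labels_to_bool(labels: Sequence[Label]) -> np.ndarray:
    out = np.empty(len(labels), dtype=bool)
    for i, lab in enumerate(labels):
        if lab is Label.CASE:
            out[i] = True
        elif lab is Label.NON_CASE:
            out[i] = False
        else:
            raise ValueError("only case/non_case labels enter the learner")
    return out


def adhoc_importance(column: np.ndarray, labels: Sequence[Label] | np.ndarray) -> float:
    """(TP - FP) / P: cases with the feature minus non-cases with it,
    over the number of cases."""
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    col = np.asarray(column).astype(bool)
    p = int(y.sum())
    if p == 0:
        raise ValueError("no cases present; importance undefined")
    tp = int(np.sum(col & y))
    fp = int(np.sum(col & ~y))
    return (tp - fp) / p


def adhoc_importance_scores(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    p = int(y.sum())
    if p == 0:
        raise ValueError("no cases present; importance undefined")
    Xf = X.astype(np.float64)
    return (Xf[y].sum(axis=0) - Xf[~y].sum(axis=0)) / p


def prescreen_columns(X: np.ndarray, names: Sequence[str], y: np.ndarray, k: int = 300) -> list[int]:
    """Indices of the k highest ad hoc importance columns.

    Ties at the cutoff break lexicographically by feature name, so the
    selection is stable and reproducible.
    """
    scores = adhoc_importance_scores(X, y)
    order = sorted(range(len(names)), key=lambda j: (-scores[j], names[j]))
    return sorted(order[:k])


def prescreen_top_k(
    matrix: FeatureMatrix, labels: Sequence[Label] | np.ndarray, k: int = 300
) -> FeatureMatrix:
    """The feature matrix reduced to the top-k ad hoc importance columns."""
    if matrix.values.shape[1] == 0:
        raise ValueError("matrix has no columns")
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    return matrix.select(prescreen_columns(matrix.values, matrix.names, y, k))
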