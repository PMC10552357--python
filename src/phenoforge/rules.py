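"""Case-definition rule objects and the chart evaluation engine.

A :class:`CaseDefinition` is an OR-combination of clauses of the form
"at least *k* matches of a code prefix / text term, within a rolling
window of *w* months, among records from source tables *S*".  This is
the machine-evaluable artefact the whole pipeline exists to produce;
e.g. the rule "two ICD-9 627* within 24 months OR one ATC G03CA*
anywhere in the chart" is expressible as two clauses.

"Within 12/24 consecutive months" is implemented as a rolling window of
365/730 days between the earliest and latest of the qualifying records:
calendar-month arithmetic is ambiguous, while the rolling form is
monotone and independent of record order.  "Sub-codes" are realised as
string-prefix matches on dot-stripped, upper-cased codes.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field
from typing import Iterable

import yaml

from .text import NegationLexicon, default_lexicon, extract_ngrams, filter_negated, tokenize
from .types import PatientChart, Source, normalize_code


class MatchKind(str, enum.Enum):
    CODE_PREFIX = "code_prefix"
    TEXT_UNIGRAM = "text_unigram"
    TEXT_BIGRAM = "text_bigram"


class Window(enum.Enum):
    """Rolling-window length for repeated-occurrence clauses."""

    MONTHS_12 = 12
    MONTHS_24 = 24
    WHOLE_CHART = "whole_chart"

    @property
    def days(self) -> int | None:
        if self is Window.MONTHS_12:
            return 365
        if self is Window.MONTHS_24:
            return 730
        return None


@dataclass(frozen=True)
class Clause:
    """One disjunct: >= min_count matches of a pattern within a window."""

    match_kind: MatchKind
    pattern: str
    min_count: int = 1
    window: Window = Window.WHOLE_CHART
    scope: frozenset[Source] = frozenset(Source)

    def __post_init__(self) -> None:
        if not self.pattern:
            raise ValueError("clause pattern must be non-empty")
        if self.min_count < 1:
            raise ValueError("min_count must be >= 1")
        if self.min_count == 1 and self.window is not Window.WHOLE_CHART:
            raise ValueError("min_count=1 requires a whole-chart window")
        if not self.scope:
            raise ValueError("clause scope must be non-empty")
        object.__setattr__(self, "scope", frozenset(self.scope))

    def describe(self) -> str:
        win = {Window.MONTHS_12: " within 12 months", Window.MONTHS_24: " within 24 months"}.get(
            self.window, ""
        )
        return f">={self.min_count} x {self.match_kind.value} '{self.pattern}'{win}"


@dataclass(frozen=True)
class CaseDefinition:
    """Disjunction (OR) of clauses; monotone in chart content."""

    clauses: tuple[Clause, ...]

    def __post_init__(self) -> None:
        if not self.clauses:
            raise ValueError("case definition needs at least one clause")
        object.__setattr__(self, "clauses", tuple(self.clauses))

    def describe(self) -> str:
        return " OR ".join(c.describe() for c in self.clauses)


def dates_satisfy_window(dates: list[_dt.date], min_count: int, window: Window) -> bool:
    """True iff some ``min_count`` of the dates span <= the window length.

    For sorted dates the optimal subset of size k is always k consecutive
    dates, so a linear scan over consecutive runs is exact.
    """
    if len(dates) < min_count:
        return False
    limit = window.days
    if limit is None:
        return True
    ds = sorted(dates)
    k = min_count
    return any((ds[i + k - 1] - ds[i]).days <= limit for i in range(len(ds) - k + 1))


def clause_match_dates(
    chart: PatientChart, clause: Clause, lexicon: NegationLexicon | None = None
) -> list[_dt.date]:
    """Dates of records matching the clause's pattern within its scope.

    Text matching tokenises each record's free text after negation
    filtering; a record contributes (once) if the clause's unigram or
    bigram occurs among its n-grams.
    """
    out: list[_dt.date] = []
    if clause.match_kind is MatchKind.CODE_PREFIX:
        pat = normalize_code(clause.pattern)
        for rec in chart.records:
            if rec.source in clause.scope and rec.code and normalize_code(rec.code).startswith(pat):
                out.append(rec.date)
        return out
    if lexicon is None:
        lexicon = default_lexicon()
    pat = clause.pattern.lower()
    for rec in chart.records:
        if rec.source in clause.scope and rec.free_text:
            grams = extract_ngrams(tokenize(filter_negated(rec.free_text, lexicon)))
            if pat in grams:
                out.append(rec.date)
    return out


def evaluate_clause(
    chart: PatientChart, clause: Clause, lexicon: NegationLexicon | None = None
) -> bool:
    """Whether the chart satisfies one clause (empty chart -> False)."""
    dates = clause_match_dates(chart, clause, lexicon)
    return dates_satisfy_window(dates, clause.min_count, clause.window)


def evaluate_definition(
    chart: PatientChart, definition: CaseDefinition, lexicon: NegationLexicon | None = None
) -> bool:
    """OR over the definition's clauses."""
    return any(evaluate_clause(chart, c, lexicon) for c in definition.clauses)


# ---------------------------------------------------------------------------
# Serialisation: definitions are portable YAML artefacts.

def clause_to_dict(clause: Clause) -> dict:
    return {
        "match_kind": clause.match_kind.value,
        "pattern": clause.pattern,
        "min_count": clause.min_count,
        "window_months": clause.window.value if clause.window is not Window.WHOLE_CHART else "whole_chart",
        "scope": sorted(s.value for s in clause.scope),
    }


def clause_from_dict(d: dict) -> Clause:
    win = d.get("window_months", "whole_chart")
    window = Window.WHOLE_CHART if win == "whole_chart" else Window(int(win))
    return Clause(
        match_kind=MatchKind(d["match_kind"]),
        pattern=d["pattern"],
        min_count=int(d.get("min_count", 1)),
        window=window,
        scope=frozenset(Source(s) for s in d["scope"]),
    )


def definition_to_yaml(definition: CaseDefinition) -> str:
    doc = {"combination": "OR", "clauses": [clause_to_dict(c) for c in definition.clauses]}
    return yaml.safe_dump(doc, sort_keys=False)


def definition_from_yaml(text: str) -> CaseDefinition:
    doc = yaml.safe_load(text)
    return CaseDefinition(tuple(clause_from_dict(d) for d in doc["clauses"]))


def make_definition(clauses: Iterable[Clause]) -> CaseDefinition:
    return CaseDefinition(tuple(clauses))
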