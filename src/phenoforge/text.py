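"""Clinical free-text handling: tokenisation, n-grams and negation filtering.

Short diagnostic free-text (billing/encounter/problem-list/referral
fields, <255 chars) is represented as a bag of words and adjacent word
pairs.  Before n-gram extraction, mentions of the target condition terms
that occur inside a negated or uncertain construction ("not menopause",
"menopause?", "rule out menopause", ...) are removed so that ruled-out
or queried diagnoses never fire a text rule.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

_TOKEN_RE = re.compile(r"[a-z0-9]+\??")

#: Default condition-term patterns; a trailing ``*`` matches any suffix.
DEFAULT_TARGET_TERMS: tuple[str, ...] = ("menopaus*", "climacteric")

# Negated / uncertain constructions around a condition term.  "{term}"
# marks the slot.  The first three are the canonical examples; the rest
# cover common chart shorthand for negation (no/denies/without/ruled
# out/negative for ...) and uncertainty (?/query/possible/suspected ...).
DEFAULT_NEGATION_TEMPLATES: tuple[str, ...] = (
    "not {term}",
    "{term}?",
    "rule out {term}",
    "ruled out {term}",
    "rules out {term}",
    "r/o {term}",
    "ro {term}",
    "no {term}",
    "without {term}",
    "w/o {term}",
    "denies {term}",
    "denied {term}",
    "denying {term}",
    "negative for {term}",
    "neg for {term}",
    "no evidence of {term}",
    "no sign of {term}",
    "no signs of {term}",
    "no symptoms of {term}",
    "no history of {term}",
    "no hx of {term}",
    "not yet {term}",
    "never {term}",
    "unlikely {term}",
    "doubt {term}",
    "doubtful {term}",
    "doubted {term}",
    "query {term}",
    "queried {term}",
    "possible {term}",
    "possibly {term}",
    "probable {term}",
    "suspected {term}",
    "suspect {term}",
    "suspicion of {term}",
    "concern for {term}",
    "concerned about {term}",
    "screen for {term}",
    "screening for {term}",
    "to exclude {term}",
    "exclude {term}",
    "excluding {term}",
    "evaluate for {term}",
    "eval for {term}",
    "assess for {term}",
    "workup for {term}",
    "{term} unlikely",
    "{term} ruled out",
    "{term} excluded",
    "{term} not confirmed",
)


def tokenize(text: str) -> list[str]:
    """Lower-case and split on whitespace/punctuation.

    A ``?`` directly following a word stays attached to it
    ("menopause?" -> ["menopause?"]) because trailing question marks
    signal diagnostic uncertainty in chart shorthand.
    """
    return _TOKEN_RE.findall(text.lower())


def extract_ngrams(tokens: list[str]) -> set[str]:
    """All unigrams plus adjacent ordered bigrams (joined by one space)."""
    grams = set(tokens)
    grams.update(f"{a} {b}" for a, b in zip(tokens, tokens[1:]))
    return grams


@dataclass(frozen=True)
class _CompiledTemplate:
    pre: tuple[str, ...]
    post: tuple[str, ...]
    qmark: bool  # "{term}?" form: the term token itself ends with '?'


def _compile(template: str) -> _CompiledTemplate:
    if "{term}" not in template:
        raise ValueError(f"template {template!r} lacks a {{term}} slot")
    before, after = template.split("{term}", 1)
    qmark = after.startswith("?")
    if qmark:
        after = after[1:]
    return _CompiledTemplate(tuple(tokenize(before)), tuple(tokenize(after)), qmark)


@dataclass
class NegationLexicon:
    """Templates describing negated/uncertain mentions of a target term."""

    templates: tuple[str, ...] = DEFAULT_NEGATION_TEMPLATES
    _compiled: list[_CompiledTemplate] = field(init=False, repr=False)

    def __post_init__(self) -> None:
        if not self.templates:
            raise ValueError("negation lexicon must be non-empty")
        self._compiled = [_compile(t) for t in self.templates]

    def __len__(self) -> int:
        return len(self.templates)

    def is_negated(self, tokens: list[str], i: int) -> bool:
        """Whether the target-term token at position ``i`` sits in a template."""
        tok = tokens[i]
        for tpl in self._compiled:
            if tpl.qmark:
                if tok.endswith("?") and not tpl.pre and not tpl.post:
                    return True
                continue
            if tpl.pre:
                n = len(tpl.pre)
                if i >= n and tuple(tokens[i - n : i]) == tpl.pre:
                    return True
            elif tpl.post:
                n = len(tpl.post)
                if tuple(tokens[i + 1 : i + 1 + n]) == tpl.post:
                    return True
        return False


def _matches_target(token: str, target_terms: tuple[str, ...]) -> bool:
    word = token.rstrip("?")
    for term in target_terms:
        if term.endswith("*"):
            if word.startswith(term[:-1]):
                return True
        elif word == term:
            return True
    return False


def filter_negated(
    text: str,
    lexicon: NegationLexicon | None = None,
    target_terms: tuple[str, ...] = DEFAULT_TARGET_TERMS,
) -> str:
    """Drop target-term mentions that match a negation/uncertainty template.

    Operates mention by mention: an affirmative mention elsewhere in the
    same text survives.  Returns the surviving tokens joined by spaces
    (tokenisation is idempotent, so downstream n-gram extraction sees
    exactly the surviving tokens).
    """
    if lexicon is None:
        lexicon = default_lexicon()
    tokens = tokenize(text)
    kept = [
        tok
        for i, tok in enumerate(tokens)
        if not (_matches_target(tok, target_terms) and lexicon.is_negated(tokens, i))
    ]
    return " ".join(kept)


_DEFAULT_LEXICON: NegationLexicon | None = None


def default_lexicon() -> NegationLexicon:
    """The shipped 50-template lexicon (compiled once)."""
    global _DEFAULT_LEXICON
    if _DEFAULT_LEXICON is None:
        _DEFAULT_LEXICON = NegationLexicon()
    return _DEFAULT_LEXICON
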