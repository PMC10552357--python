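"""Synthetic CPCSSN-shaped cohort generation.

Produces labelled five-table primary-care cohorts with a *planted*
ground-truth phenotype rule, so every downstream stage (feature
engineering, the nested-CV learner, rule simplification, validation)
can be exercised and calibrated without access to real EMR data.

The default emulates the study conditions of the problematic-menopause
phenotype: women aged 45-60, ~19% case prevalence, ICD-9 627* diagnosis
codes and ATC G03CA* estrogen prescriptions as the true signal,
affirmative and negated/uncertain "menopaus*" free text, chronic-
condition distractor codes, and five simulated chart reviewers whose
majority vote forms the reference-standard label.

True cases satisfy the planted definition by construction; non-cases
carry distractors plus *sub-threshold* signal — a single 627 code, or a
627 pair spaced more than 24 months apart, or negated menopause text —
so that single mentions are genuinely insufficient evidence and the
temporal window of the planted rule is the discriminating detail.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field

import numpy as np

from .rules import CaseDefinition, Clause, MatchKind, Window
from .text import DEFAULT_NEGATION_TEMPLATES
from .types import (
    DIAGNOSIS_SOURCES,
    ClinicalRecord,
    CodeSystem,
    Label,
    PatientChart,
    Source,
)

# ---------------------------------------------------------------------------
# Static pools


def default_planted_definition() -> CaseDefinition:
    """Two ICD-9 627* within 24 months OR one ATC G03CA* anywhere."""
    return CaseDefinition(
        (
            Clause(
                MatchKind.CODE_PREFIX,
                "627",
                min_count=2,
                window=Window.MONTHS_24,
                scope=frozenset(DIAGNOSIS_SOURCES),
            ),
            Clause(
                MatchKind.CODE_PREFIX,
                "G03CA",
                min_count=1,
                window=Window.WHOLE_CHART,
                scope=frozenset({Source.MEDICATION}),
            ),
        )
    )


#: Eleven chronic-condition ICD-9 families used as diagnosis distractors
#: (kidney disease, COPD, dementia, depression, diabetes, dyslipidemia,
#: epilepsy, herpes zoster, hypertension, osteoarthritis, parkinsonism).
CHRONIC_FAMILIES: dict[str, tuple[str, ...]] = {
    "585": ("585", "585.9"),
    "496": ("496",),
    "290": ("290.0", "290.4"),
    "311": ("311",),
    "250": ("250.0", "250.00", "250.1"),
    "272": ("272.0", "272.4"),
    "345": ("345.9",),
    "053": ("053.9",),
    "401": ("401.1", "401.9"),
    "715": ("715.9", "715.90"),
    "332": ("332.0",),
}

#: Acute/episodic complaint codes for background visits of patients
#: without (or outside) their chronic conditions.
ACUTE_CODES: tuple[str, ...] = (
    "780.79", "784.0", "724.2", "465.9", "788.1",
    "729.5", "719.46", "477.9", "564.00", "786.2",
)

ATC_DISTRACTORS: tuple[str, ...] = (
    "C09AA02", "A10BA02", "N06AB06", "C10AA01", "N02BE01",
    "R03AC02", "C07AB02", "A02BC01", "M01AE01", "N05BA06",
)

#: Rare non-case G03 prescriptions (contraceptives and a synthetic
#: estrogen) sharing G03/G03C prefixes with the planted estrogen signal
#: but never G03CA itself, so every coarser code prefix is impure and
#: the planted code depth is the discriminating one.
NONCASE_G03: tuple[str, ...] = ("G03AC03", "G03AA07", "G03CB01")

CASE_627_CODES: tuple[str, ...] = ("627", "627.2", "627.4", "627.9")
CASE_G03CA_CODES: tuple[str, ...] = ("G03CA03", "G03CA04", "G03CA57")
CASE_EXTRA_G03: tuple[str, ...] = ("G03DA04", "G03DB01")

AFFIRMATIVE_TEXTS: tuple[str, ...] = (
    "menopausal symptoms",
    "postmenopausal",
    "menopause management",
    "climacteric symptoms",
    "perimenopausal hot flashes",
    "menopausal hot flashes",
    "menopause followup",
)

NEGATED_TERMS: tuple[str, ...] = ("menopause", "menopausal")

_CLINICAL_WORDS = (
    "hypertension diabetes followup refill cough fever fatigue insomnia anxiety "
    "depression headache migraine back pain knee shoulder rash dizziness nausea "
    "screening bloodwork injection counselling renewal review chronic acute visit "
    "assessment results discussed stable improved worsening referral consult imaging "
    "xray ultrasound vaccination flu shot wellness annual physical exam"
).split()


def _pseudo_vocab() -> list[str]:
    pre = ["car", "neo", "sta", "lum", "ver", "dol", "mak", "rin",
           "tos", "pel", "gam", "fen", "bor", "sul", "tre", "qui"]
    suf = ["dine", "mab", "pril", "zole", "itis", "emia", "osis",
           "algia", "pathy", "gram", "scopy", "ectomy"]
    return [p + s for p in pre for s in suf]


#: Fixed free-text vocabulary for background records (clinical words
#: plus pronounceable pseudo-terms); zipf-weighted draws give a realistic
#: long tail of rare words and word pairs.
VOCAB: tuple[str, ...] = tuple(_CLINICAL_WORDS + _pseudo_vocab())
_VOCAB_W = 1.0 / np.arange(1, len(VOCAB) + 1) ** 0.8
_VOCAB_P = _VOCAB_W / _VOCAB_W.sum()

REFERRAL_SPECIALTIES: tuple[str, ...] = (
    "gynecology", "cardiology", "dermatology", "orthopedics", "physiotherapy",
)


# ---------------------------------------------------------------------------
# Configuration


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for one synthetic cohort.

    Defaults mirror the reference study sample: ~19% prevalence among
    women aged 45-60 over a ten-year extract, five reviewers, and one
    unclassifiable chart expected per 2,776.
    """

    n_patients: int = 2776
    prevalence: float = 0.19
    seed: int = 0
    date_start: _dt.date = _dt.date(2011, 1, 1)
    date_end: _dt.date = _dt.date(2020, 12, 31)
    planted_definition: CaseDefinition = field(default_factory=default_planted_definition)
    text_noise_rate: float = 0.10
    negation_rate: float = 0.15
    subthreshold_rate: float = 0.10
    spaced_pair_rate: float = 0.05
    reviewer_error_rate: float = 0.04
    n_reviewers: int = 5
    unclassifiable_rate: float = 1.0 / 2776.0
    records_mean: float = 15.0
    records_dispersion: float = 1.5

    def __post_init__(self) -> None:
        if self.n_patients < 1:
            raise ValueError("n_patients must be >= 1")
        if not 0 < self.prevalence < 1:
            raise ValueError("prevalence must lie strictly in (0, 1)")
        for name in ("text_noise_rate", "negation_rate", "subthreshold_rate",
                     "spaced_pair_rate", "unclassifiable_rate"):
            v = getattr(self, name)
            if not 0 <= v <= 1:
                raise ValueError(f"{name} must lie in [0, 1]")
        if not 0 <= self.reviewer_error_rate < 0.5:
            raise ValueError("reviewer_error_rate must lie in [0, 0.5)")
        if self.n_reviewers < 1 or self.n_reviewers % 2 == 0:
            raise ValueError("n_reviewers must be a positive odd number")
        span = (self.date_end - self.date_start).days
        if span < 0:
            raise ValueError("date_end precedes date_start")
        # satisfiability: every clause needs min_count distinct days in span
        for clause in self.planted_definition.clauses:
            if span + 1 < clause.min_count:
                raise ValueError(
                    f"planted clause {clause.describe()!r} unsatisfiable in date span"
                )

    @property
    def span_days(self) -> int:
        return (self.date_end - self.date_start).days


@dataclass
class SyntheticCohort:
    charts: list[PatientChart]
    truth: dict[str, Label]
    reviewer_ratings: np.ndarray  # subjects x 2 (case votes, non-case votes)
    config: CohortConfig

    @property
    def labelled_charts(self) -> list[PatientChart]:
        """Charts with a usable consensus label (unclassifiable excluded)."""
        return [c for c in self.charts if c.label in (Label.CASE, Label.NON_CASE)]


# ---------------------------------------------------------------------------
# Generation


def _rand_date(rng: np.random.Generator, config: CohortConfig) -> _dt.date:
    return config.date_start + _dt.timedelta(days=int(rng.integers(0, config.span_days + 1)))


def _filler_words(rng: np.random.Generator, n_lo: int = 1, n_hi: int = 4) -> str:
    k = int(rng.integers(n_lo, n_hi + 1))
    idx = rng.choice(len(VOCAB), size=k, p=_VOCAB_P)
    return " ".join(VOCAB[i] for i in idx)


def _background_record(pid: str, rng: np.random.Generator, config: CohortConfig,
                       chronic: list[str]) -> ClinicalRecord:
    date = _rand_date(rng, config)
    u = rng.random()
    if u < 0.28:
        source = Source.BILLING
    elif u < 0.56:
        source = Source.ENCOUNTER_DIAGNOSIS
    elif u < 0.70:
        source = Source.HEALTH_CONDITION
    elif u < 0.92:
        source = Source.MEDICATION
    else:
        source = Source.REFERRAL
    if source is Source.MEDICATION:
        code = ATC_DISTRACTORS[int(rng.integers(len(ATC_DISTRACTORS)))]
        return ClinicalRecord(pid, source, date, CodeSystem.ATC, code, "")
    if source is Source.REFERRAL:
        text = f"{REFERRAL_SPECIALTIES[int(rng.integers(len(REFERRAL_SPECIALTIES)))]} {_filler_words(rng, 1, 2)}"
        return ClinicalRecord(pid, source, date, CodeSystem.NONE, "", text)
    if chronic and rng.random() < 0.6:
        fam = chronic[int(rng.integers(len(chronic)))]
        codes = CHRONIC_FAMILIES[fam]
        code = codes[int(rng.integers(len(codes)))]
    else:
        code = ACUTE_CODES[int(rng.integers(len(ACUTE_CODES)))]
    text = _filler_words(rng, 2, 4) if rng.random() < 0.8 else ""
    return ClinicalRecord(pid, source, date, CodeSystem.ICD9CM, code, text)


def _diag_source(rng: np.random.Generator) -> Source:
    return (Source.BILLING, Source.ENCOUNTER_DIAGNOSIS, Source.HEALTH_CONDITION)[
        int(rng.integers(3))
    ]


def _case_text(rng: np.random.Generator, config: CohortConfig) -> str:
    """Affirmative menopause text, degraded to filler at the text-noise rate."""
    if rng.random() < config.text_noise_rate:
        return _filler_words(rng, 2, 4)
    return AFFIRMATIVE_TEXTS[int(rng.integers(len(AFFIRMATIVE_TEXTS)))]


def _plant_case(pid: str, rng: np.random.Generator, config: CohortConfig) -> list[ClinicalRecord]:
    """Records guaranteeing the planted definition on this chart."""
    records: list[ClinicalRecord] = []
    u = rng.random()
    has_icd, has_atc = (True, False) if u < 0.30 else (False, True) if u < 0.55 else (True, True)
    if has_icd:
        # pair (sometimes triple) of 627* codes spanning 30-700 days,
        # so the 12-month variant misses some true cases while the
        # 24-month window captures them all
        span = int(rng.integers(30, 701))
        start_limit = max(config.span_days - span, 0)
        first = int(rng.integers(0, start_limit + 1))
        offsets = [first, first + min(span, config.span_days)]
        if rng.random() < 0.4:
            offsets.append(first + int(rng.integers(0, min(span, config.span_days) + 1)))
        for off in offsets:
            date = config.date_start + _dt.timedelta(days=off)
            code = CASE_627_CODES[int(rng.integers(len(CASE_627_CODES)))]
            text = _case_text(rng, config) if rng.random() < 0.7 else ""
            records.append(
                ClinicalRecord(pid, _diag_source(rng), date, CodeSystem.ICD9CM, code, text)
            )
    if has_atc:
        for _ in range(1 + int(rng.random() < 0.4)):
            code = CASE_G03CA_CODES[int(rng.integers(len(CASE_G03CA_CODES)))]
            records.append(
                ClinicalRecord(pid, Source.MEDICATION, _rand_date(rng, config),
                               CodeSystem.ATC, code, "")
            )
    if rng.random() < 0.3:
        code = CASE_EXTRA_G03[int(rng.integers(len(CASE_EXTRA_G03)))]
        records.append(
            ClinicalRecord(pid, Source.MEDICATION, _rand_date(rng, config),
                           CodeSystem.ATC, code, "")
        )
    if rng.random() < 0.6:
        records.append(
            ClinicalRecord(pid, _diag_source(rng), _rand_date(rng, config),
                           CodeSystem.NONE, "", _case_text(rng, config))
        )
    return records


def _plant_noncase(pid: str, rng: np.random.Generator, config: CohortConfig) -> list[ClinicalRecord]:
    """Sub-threshold and negated signal that must NOT satisfy the rule."""
    records: list[ClinicalRecord] = []
    if rng.random() < config.negation_rate:
        for _ in range(1 + int(rng.random() < 0.3)):
            template = DEFAULT_NEGATION_TEMPLATES[
                int(rng.integers(len(DEFAULT_NEGATION_TEMPLATES)))
            ]
            term = NEGATED_TERMS[int(rng.integers(len(NEGATED_TERMS)))]
            text = template.replace("{term}", term)
            records.append(
                ClinicalRecord(pid, _diag_source(rng), _rand_date(rng, config),
                               CodeSystem.NONE, "", text)
            )
    u = rng.random()
    if u < config.subthreshold_rate:
        code = CASE_627_CODES[int(rng.integers(len(CASE_627_CODES)))]
        records.append(
            ClinicalRecord(pid, _diag_source(rng), _rand_date(rng, config),
                           CodeSystem.ICD9CM, code, "")
        )
    elif u < config.subthreshold_rate + config.spaced_pair_rate and config.span_days > 760:
        # 627 pair spaced beyond the 24-month window: a "history" pattern
        gap = int(rng.integers(761, min(1500, config.span_days) + 1))
        first = int(rng.integers(0, config.span_days - gap + 1))
        for off in (first, first + gap):
            code = CASE_627_CODES[int(rng.integers(len(CASE_627_CODES)))]
            records.append(
                ClinicalRecord(pid, _diag_source(rng),
                               config.date_start + _dt.timedelta(days=off),
                               CodeSystem.ICD9CM, code, "")
            )
    if rng.random() < 0.03:
        code = NONCASE_G03[int(rng.integers(len(NONCASE_G03)))]
        records.append(
            ClinicalRecord(pid, Source.MEDICATION, _rand_date(rng, config),
                           CodeSystem.ATC, code, "")
        )
    return records


def simulate_reviewers(
    truth: list[Label], config: CohortConfig, rng: np.random.Generator
) -> tuple[list[Label], np.ndarray]:
    """Independent reviewers, majority consensus, rare unclassifiables.

    Each reviewer flips each chart's true label with probability
    ``reviewer_error_rate``; the consensus is the majority vote.  A
    small fraction of charts is marked unclassifiable regardless of
    votes.  Returns (consensus labels, subjects x 2 vote-count table)
    with columns (case votes, non-case votes).
    """
    n = len(truth)
    labels: list[Label] = []
    ratings = np.zeros((n, 2), dtype=int)
    for i, t in enumerate(truth):
        true_case = t is Label.CASE
        flips = rng.random(config.n_reviewers) < config.reviewer_error_rate
        case_votes = int(np.sum(flips != true_case))
        ratings[i, 0] = case_votes
        ratings[i, 1] = config.n_reviewers - case_votes
        if rng.random() < config.unclassifiable_rate:
            labels.append(Label.UNCLASSIFIABLE)
        else:
            labels.append(Label.CASE if case_votes * 2 > config.n_reviewers else Label.NON_CASE)
    return labels, ratings


def generate_cohort(config: CohortConfig) -> SyntheticCohort:
    """Deterministically generate one labelled cohort from the config seed."""
    ss = np.random.SeedSequence(config.seed)
    rng_struct, rng_review = (np.random.default_rng(s) for s in ss.spawn(2))

    n = config.n_patients
    is_case = rng_struct.random(n) < config.prevalence
    ages = rng_struct.integers(45, 61, size=n)
    n_background = np.maximum(
        rng_struct.negative_binomial(
            config.records_dispersion,
            config.records_dispersion / (config.records_dispersion + config.records_mean),
            size=n,
        ),
        1,
    )

    charts: list[PatientChart] = []
    truth: dict[str, Label] = {}
    width = len(str(n))
    for i in range(n):
        pid = f"P{i:0{width}d}"
        chronic = [f for f in CHRONIC_FAMILIES if rng_struct.random() < 0.095]
        records = [
            _background_record(pid, rng_struct, config, chronic)
            for _ in range(int(n_background[i]))
        ]
        if is_case[i]:
            records += _plant_case(pid, rng_struct, config)
            truth[pid] = Label.CASE
        else:
            records += _plant_noncase(pid, rng_struct, config)
            truth[pid] = Label.NON_CASE
        charts.append(PatientChart(pid, int(ages[i]), "F", records))

    consensus, ratings = simulate_reviewers([truth[c.patient_id] for c in charts],
                                            config, rng_review)
    for chart, label in zip(charts, consensus):
        chart.label = label
    return SyntheticCohort(charts=charts, truth=truth, reviewer_ratings=ratings, config=config)
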