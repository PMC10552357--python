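"""Domain types for primary-care EMR charts.

A patient chart is an ordered collection of dated records drawn from the
five source tables of a CPCSSN-style extract: billing claims, encounter
diagnoses, the health-condition (problem list) table, prescribed
medications and referrals.  Each record carries a diagnosis or drug code
(ICD-9-CM or ATC) and/or a short free-text fragment (under 255
characters).  Charts may additionally carry a reference-standard label
assigned by chart reviewers.
"""

from __future__ import annotations

import datetime as _dt
import enum
from dataclasses import dataclass, field


class Source(str, enum.Enum):
    """The five chart source tables."""

    BILLING = "billing"
    ENCOUNTER_DIAGNOSIS = "encounter_diagnosis"
    HEALTH_CONDITION = "health_condition"
    MEDICATION = "medication"
    REFERRAL = "referral"


#: Sources whose records carry ICD-9 diagnosis codes.
DIAGNOSIS_SOURCES = frozenset(
    {Source.BILLING, Source.ENCOUNTER_DIAGNOSIS, Source.HEALTH_CONDITION}
)

#: Sources whose records may carry free text.
TEXT_SOURCES = frozenset(
    {Source.BILLING, Source.ENCOUNTER_DIAGNOSIS, Source.HEALTH_CONDITION, Source.REFERRAL}
)


class CodeSystem(str, enum.Enum):
    ICD9CM = "ICD9CM"
    ATC = "ATC"
    NONE = "none"


class Label(str, enum.Enum):
    CASE = "case"
    NON_CASE = "non_case"
    UNCLASSIFIABLE = "unclassifiable"
    UNLABELLED = "unlabelled"


MAX_FREE_TEXT = 255


def normalize_code(code: str) -> str:
    """Canonical code form: upper-case, dots and whitespace stripped.

    ICD-9 "627.2" and "6272" normalise to the same string, so sub-code
    matching reduces to a string-prefix test.
    """
    return "".join(code.split()).replace(".", "").upper()


@dataclass(frozen=True)
class ClinicalRecord:
    """One dated coded/text entry from one source table of a patient chart."""

    patient_id: str
    source: Source
    date: _dt.date
    code_system: CodeSystem = CodeSystem.NONE
    code: str = ""
    free_text: str = ""

    def __post_init__(self) -> None:
        if not isinstance(self.date, _dt.date) or isinstance(self.date, _dt.datetime):
            raise TypeError("date must be a datetime.date")
        if not self.code and not self.free_text:
            raise ValueError("record needs at least one of code/free_text")
        if len(self.free_text) > MAX_FREE_TEXT:
            raise ValueError(f"free_text exceeds {MAX_FREE_TEXT} characters")
        if self.code and self.code_system is CodeSystem.NONE:
            raise ValueError("coded record needs a code_system")
        if self.code_system is CodeSystem.ATC and self.source is not Source.MEDICATION:
            raise ValueError("ATC codes occur only in the medication table")
        if self.source is Source.REFERRAL and self.code:
            raise ValueError("referral records carry free text only")


def _record_sort_key(rec: "ClinicalRecord"):
    # date first; the remaining fields make the order total, so charts
    # serialise and round-trip byte-identically
    return (rec.date, rec.source.value, rec.code_system.value, rec.code, rec.free_text)


@dataclass
class PatientChart:
    """All records of one patient plus demographics and an optional label.

    Records are kept sorted by date ascending; the study filter admits
    women aged 45-60 with at least one record.
    """

    patient_id: str
    age_years: int
    sex: str = "F"
    records: list[ClinicalRecord] = field(default_factory=list)
    label: Label = Label.UNLABELLED

    def __post_init__(self) -> None:
        for rec in self.records:
            if rec.patient_id != self.patient_id:
                raise ValueError(
                    f"record patient_id {rec.patient_id!r} != chart {self.patient_id!r}"
                )
        self.records = sorted(self.records, key=_record_sort_key)

    def add(self, record: ClinicalRecord) -> None:
        if record.patient_id != self.patient_id:
            raise ValueError("record belongs to a different patient")
        self.records.append(record)
        self.records.sort(key=_record_sort_key)

    def in_study_sample(self) -> bool:
        """Age 45-60 inclusive with at least one clinical record."""
        return 45 <= self.age_years <= 60 and len(self.records) > 0

    def __len__(self) -> int:
        return len(self.records)
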