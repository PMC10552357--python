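"""Delimited-text I/O for cohorts.

One UTF-8 CSV per source table (``billing.csv`` ... ``referral.csv``)
with columns ``patient_id, date, code_system, code, free_text``; a
demographics table (``patients.csv``: patient_id, birth_year, sex); a
label table (``labels.csv``); plus, for synthetic cohorts, the ground
truth, the reviewer vote table, and a YAML manifest recording the seed
and full generator configuration so a written cohort round-trips
exactly.
"""

from __future__ import annotations

import datetime as _dt
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .rules import CaseDefinition, clause_from_dict, clause_to_dict
from .synthetic import CohortConfig, SyntheticCohort
from .types import ClinicalRecord, CodeSystem, Label, PatientChart, Source

RECORD_COLUMNS = ["patient_id", "date", "code_system", "code", "free_text"]
SOURCE_FILES = {s: f"{s.value}.csv" for s in Source}


class SchemaError(ValueError):
    """A cohort file violates the expected CSV schema."""


def config_to_dict(config: CohortConfig) -> dict:
    d = {
        "n_patients": config.n_patients,
        "prevalence": config.prevalence,
        "seed": config.seed,
        "date_start": config.date_start.isoformat(),
        "date_end": config.date_end.isoformat(),
        "planted_definition": [clause_to_dict(c) for c in config.planted_definition.clauses],
        "text_noise_rate": config.text_noise_rate,
        "negation_rate": config.negation_rate,
        "subthreshold_rate": config.subthreshold_rate,
        "spaced_pair_rate": config.spaced_pair_rate,
        "reviewer_error_rate": config.reviewer_error_rate,
        "n_reviewers": config.n_reviewers,
        "unclassifiable_rate": config.unclassifiable_rate,
        "records_mean": config.records_mean,
        "records_dispersion": config.records_dispersion,
    }
    return d


def config_from_dict(d: dict) -> CohortConfig:
    d = dict(d)
    d["date_start"] = _dt.date.fromisoformat(d["date_start"])
    d["date_end"] = _dt.date.fromisoformat(d["date_end"])
    d["planted_definition"] = CaseDefinition(
        tuple(clause_from_dict(c) for c in d["planted_definition"])
    )
    return CohortConfig(**d)


def write_cohort(cohort: SyntheticCohort, directory: str | Path) -> None:
    """Write a cohort as the standard CSV tables plus manifest."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    rows: dict[Source, list[dict]] = {s: [] for s in Source}
    for chart in cohort.charts:
        for rec in chart.records:
            rows[rec.source].append(
                {
                    "patient_id": rec.patient_id,
                    "date": rec.date.isoformat(),
                    "code_system": rec.code_system.value,
                    "code": rec.code,
                    "free_text": rec.free_text,
                }
            )
    for source, fname in SOURCE_FILES.items():
        pd.DataFrame(rows[source], columns=RECORD_COLUMNS).to_csv(
            directory / fname, index=False
        )

    ref_year = cohort.config.date_end.year
    pd.DataFrame(
        [
            {
                "patient_id": c.patient_id,
                "birth_year": ref_year - c.age_years,
                "sex": c.sex,
            }
            for c in cohort.charts
        ],
        columns=["patient_id", "birth_year", "sex"],
    ).to_csv(directory / "patients.csv", index=False)
    pd.DataFrame(
        [{"patient_id": c.patient_id, "label": c.label.value} for c in cohort.charts],
        columns=["patient_id", "label"],
    ).to_csv(directory / "labels.csv", index=False)
    pd.DataFrame(
        [{"patient_id": pid, "truth": lab.value} for pid, lab in cohort.truth.items()],
        columns=["patient_id", "truth"],
    ).to_csv(directory / "truth.csv", index=False)
    pd.DataFrame(
        cohort.reviewer_ratings, columns=["case_votes", "non_case_votes"]
    ).assign(patient_id=[c.patient_id for c in cohort.charts][: len(cohort.reviewer_ratings)])[
        ["patient_id", "case_votes", "non_case_votes"]
    ].to_csv(directory / "ratings.csv", index=False)
    manifest = {
        "seed": cohort.config.seed,
        "reference_year": ref_year,
        "config": config_to_dict(cohort.config),
    }
    (directory / "manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


def _read_table(path: Path, required: list[str]) -> pd.DataFrame:
    if not path.exists():
        raise SchemaError(f"missing cohort file {path.name}")
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing column(s) {', '.join(missing)}")
    return df


def _parse_record(row: pd.Series, source: Source, fname: str, line: int) -> ClinicalRecord:
    try:
        return ClinicalRecord(
            patient_id=row["patient_id"],
            source=source,
            date=_dt.date.fromisoformat(row["date"]),
            code_system=CodeSystem(row["code_system"]) if row["code_system"] else CodeSystem.NONE,
            code=row["code"],
            free_text=row["free_text"],
        )
    except (ValueError, TypeError) as exc:
        raise SchemaError(f"{fname} row {line}: {exc}") from exc


def read_charts(directory: str | Path, reference_year: int | None = None) -> list[PatientChart]:
    """Read the CSV tables into charts (label table applied if present)."""
    directory = Path(directory)
    if reference_year is None:
        manifest_path = directory / "manifest.yaml"
        if manifest_path.exists():
            reference_year = yaml.safe_load(manifest_path.read_text())["reference_year"]
        else:
            raise SchemaError("no manifest.yaml; pass reference_year explicitly")

    records: dict[str, list[ClinicalRecord]] = {}
    for source, fname in SOURCE_FILES.items():
        df = _read_table(directory / fname, RECORD_COLUMNS)
        for i, row in enumerate(df.itertuples(index=False), start=2):
            rec = _parse_record(row._asdict(), source, fname, i)
            records.setdefault(rec.patient_id, []).append(rec)

    patients = _read_table(directory / "patients.csv", ["patient_id", "birth_year", "sex"])
    labels_path = directory / "labels.csv"
    label_map: dict[str, Label] = {}
    if labels_path.exists():
        ldf = _read_table(labels_path, ["patient_id", "label"])
        for i, row in enumerate(ldf.itertuples(index=False), start=2):
            try:
                label_map[row.patient_id] = Label(row.label)
            except ValueError as exc:
                raise SchemaError(f"labels.csv row {i}: {exc}") from exc

    charts = []
    for i, row in enumerate(patients.itertuples(index=False), start=2):
        try:
            age = reference_year - int(row.birth_year)
        except ValueError as exc:
            raise SchemaError(f"patients.csv row {i}: {exc}") from exc
        charts.append(
            PatientChart(
                patient_id=row.patient_id,
                age_years=age,
                sex=row.sex,
                records=records.get(row.patient_id, []),
                label=label_map.get(row.patient_id, Label.UNLABELLED),
            )
        )
    return charts


def read_cohort(directory: str | Path) -> SyntheticCohort:
    """Inverse of :func:`write_cohort` (requires the manifest)."""
    directory = Path(directory)
    manifest = yaml.safe_load((directory / "manifest.yaml").read_text())
    config = config_from_dict(manifest["config"])
    charts = read_charts(directory, reference_year=manifest["reference_year"])
    truth_df = _read_table(directory / "truth.csv", ["patient_id", "truth"])
    truth = {row.patient_id: Label(row.truth) for row in truth_df.itertuples(index=False)}
    ratings_df = _read_table(directory / "ratings.csv", ["patient_id", "case_votes", "non_case_votes"])
    ratings = ratings_df[["case_votes", "non_case_votes"]].to_numpy(dtype=int)
    return SyntheticCohort(charts=charts, truth=truth, reviewer_ratings=ratings, config=config)
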