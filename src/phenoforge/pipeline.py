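"""End-to-end pipeline orchestration.

``run_all`` ties the stages together: generate (or load) a cohort,
split into train/test and validation halves, featurize the train/test
half, run the nested-CV combination comparison, train the final tree,
simplify to a one- or two-clause case definition, and measure it once
on the validation half.  A manifest records seed, configuration hash,
stage timings and artefact digests so a run can be reproduced and
checked byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import __version__
from .cohort_io import config_from_dict, config_to_dict, write_cohort
from .features import FeatureMatrix, build_feature_matrix
from .learner import (
    CombinationResult,
    LearnerConfig,
    SimplificationResult,
    TrainedTree,
    nested_cv,
    select_best_combination,
    simplify_definition,
    split_train_validation,
    train_final_tree,
    validate_final,
)
from .rules import definition_to_yaml
from .stats import KappaResult, ValidationReport, fleiss_kappa
from .synthetic import CHRONIC_FAMILIES, CohortConfig, SyntheticCohort, generate_cohort
from .types import CodeSystem, Label, PatientChart, normalize_code

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Layered configuration for one reproducible run.

    The study-condition defaults live on :class:`CohortConfig`
    (prevalence 0.19, five reviewers, ...) and :class:`LearnerConfig`
    (10 outer / 10 inner folds, 300-feature prescreen); here sit the
    cross-stage knobs: minimum feature support (10 patients), the
    number of top features fed to simplification (9), and the run seed
    that every stochastic stage derives its substreams from.
    """

    seed: int = 0
    cohort: CohortConfig = field(default_factory=CohortConfig)
    learner: LearnerConfig = field(default_factory=LearnerConfig)
    min_support: int = 10
    simplify_s: int = 9
    kappa_subset: int = 120

    def __post_init__(self) -> None:
        # the run seed flows into both stage configs unless they were
        # explicitly constructed with their own
        if self.cohort.seed == 0 and self.seed != 0:
            self.cohort = dataclasses.replace(self.cohort, seed=self.seed)
        if self.learner.seed == 0 and self.seed != 0:
            self.learner = dataclasses.replace(self.learner, seed=self.seed + 1)

    def to_dict(self) -> dict:
        return {
            "seed": self.seed,
            "min_support": self.min_support,
            "simplify_s": self.simplify_s,
            "kappa_subset": self.kappa_subset,
            "cohort": config_to_dict(self.cohort),
            "learner": {
                "hyperparameter_grid": {
                    k: [_cw_out(v) for v in vals]
                    for k, vals in self.learner.hyperparameter_grid.items()
                },
                "outer_folds": self.learner.outer_folds,
                "inner_folds": self.learner.inner_folds,
                "prescreen_k": self.learner.prescreen_k,
                "reduced_feature_count": self.learner.reduced_feature_count,
                "rfe_step": self.learner.rfe_step,
                "seed": self.learner.seed,
            },
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        learner_d = dict(d.get("learner", {}))
        if "hyperparameter_grid" in learner_d:
            learner_d["hyperparameter_grid"] = {
                k: [_cw_in(v) for v in vals]
                for k, vals in learner_d["hyperparameter_grid"].items()
            }
        return cls(
            seed=d.get("seed", 0),
            min_support=d.get("min_support", 10),
            simplify_s=d.get("simplify_s", 9),
            kappa_subset=d.get("kappa_subset", 120),
            cohort=config_from_dict(d["cohort"]) if "cohort" in d else CohortConfig(),
            learner=LearnerConfig(**learner_d) if learner_d else LearnerConfig(),
        )


def _cw_out(v):
    # class_weight dicts have int keys, which YAML handles fine
    return v


def _cw_in(v):
    if isinstance(v, dict):
        return {int(k): w for k, w in v.items()}
    return v


def config_hash(config: PipelineConfig) -> str:
    doc = yaml.safe_dump(config.to_dict(), sort_keys=True)
    return hashlib.sha256(doc.encode()).hexdigest()


def audit_no_leakage(train_ids: list[str], validation_ids: list[str]) -> str:
    """Assert train/validation disjointness; return the validation-set digest."""
    overlap = set(train_ids) & set(validation_ids)
    if overlap:
        raise RuntimeError(f"validation leakage: {len(overlap)} patient ids shared")
    digest = hashlib.sha256("\n".join(sorted(validation_ids)).encode()).hexdigest()
    return digest


@dataclass
class RunManifest:
    seed: int
    config_hash: str
    validation_digest: str
    stage_seconds: dict[str, float]
    version: str = __version__

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class RunResult:
    config: PipelineConfig
    cohort: SyntheticCohort
    train_charts: list[PatientChart]
    validation_charts: list[PatientChart]
    matrix: FeatureMatrix
    cv_results: list[CombinationResult]
    best: CombinationResult
    tree: TrainedTree
    simplification: SimplificationResult
    validation_report: ValidationReport
    kappa: KappaResult
    manifest: RunManifest

    def combination_table(self) -> pd.DataFrame:
        return pd.DataFrame([r.summary_row() for r in self.cv_results])

    def importance_table(self) -> pd.DataFrame:
        rows = sorted(self.tree.importances.items(), key=lambda kv: (-kv[1], kv[0]))
        return pd.DataFrame(rows, columns=["feature", "importance"])


def run_all(config: PipelineConfig, out_dir: str | Path | None = None) -> RunResult:
    """Execute every stage; optionally write all artefacts to ``out_dir``."""
    timings: dict[str, float] = {}

    def stage(name: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, *exc):
                timings[name] = round(time.perf_counter() - self.t0, 3)
                logger.info("stage %s: %.1fs", name, timings[name])

        return _T()

    with stage("simulate"):
        cohort = generate_cohort(config.cohort)
        labelled = cohort.labelled_charts
        subset = cohort.reviewer_ratings[: config.kappa_subset]
        kappa = fleiss_kappa(subset)

    with stage("split"):
        train_charts, valid_charts = split_train_validation(labelled, config.seed)
        validation_digest = audit_no_leakage(
            [c.patient_id for c in train_charts], [c.patient_id for c in valid_charts]
        )

    with stage("featurize"):
        matrix = build_feature_matrix(train_charts, min_support=config.min_support)
        y = [c.label for c in train_charts]

    with stage("nested_cv"):
        cv_results = nested_cv(matrix, y, config.learner)
        best = select_best_combination(cv_results)

    with stage("final_tree"):
        tree = train_final_tree(matrix, y, best.combination, config.learner)

    with stage("simplify"):
        simplification = simplify_definition(tree, matrix, y, s=config.simplify_s)

    with stage("validate"):
        report = validate_final(simplification.chosen.definition, valid_charts)

    manifest = RunManifest(
        seed=config.seed,
        config_hash=config_hash(config),
        validation_digest=validation_digest,
        stage_seconds=timings,
    )
    result = RunResult(
        config=config,
        cohort=cohort,
        train_charts=train_charts,
        validation_charts=valid_charts,
        matrix=matrix,
        cv_results=cv_results,
        best=best,
        tree=tree,
        simplification=simplification,
        validation_report=report,
        kappa=kappa,
        manifest=manifest,
    )
    if out_dir is not None:
        write_run_artifacts(result, Path(out_dir))
    return result


def _report_text(result: RunResult) -> str:
    rep = result.validation_report
    lines = [
        f"phenoforge run (seed {result.config.seed})",
        f"cohort: {len(result.cohort.charts)} charts, "
        f"{sum(1 for l in result.cohort.truth.values() if l is Label.CASE)} true cases",
        f"reviewer agreement (Fleiss kappa, first {result.kappa.n_subjects} charts): "
        f"{result.kappa.kappa:.2f}",
        f"best combination: {result.best.label} (mean F1 {result.best.mean_f1:.3f})",
        f"chosen case definition: {result.simplification.chosen.definition.describe()}",
        "validation-half metrics:",
        f"  sensitivity {rep.sensitivity}",
        f"  specificity {rep.specificity}",
        f"  PPV         {rep.ppv}",
        f"  NPV         {rep.npv}",
        f"  F1          {rep.f1:.3f}" if rep.f1 is not None else "  F1          undefined",
    ]
    return "\n".join(lines) + "\n"


def write_run_artifacts(result: RunResult, out_dir: Path) -> None:
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    write_cohort(result.cohort, out_dir / "cohort")
    result.matrix.to_csv(out_dir / "features")
    result.combination_table().to_csv(out_dir / "combination_table.csv", index=False)
    result.importance_table().to_csv(out_dir / "importance_table.csv", index=False)
    (out_dir / "case_definition.yaml").write_text(
        definition_to_yaml(result.simplification.chosen.definition)
    )
    pd.DataFrame([result.validation_report.to_dict()]).to_csv(
        out_dir / "validation_report.csv", index=False
    )
    cohort_summary(result.cohort.charts).to_csv(out_dir / "cohort_summary.csv")
    (out_dir / "report.txt").write_text(_report_text(result))
    manifest = result.manifest.to_dict()
    manifest["config"] = result.config.to_dict()
    (out_dir / "run_manifest.yaml").write_text(yaml.safe_dump(manifest, sort_keys=False))


# ---------------------------------------------------------------------------
# Cohort summary (descriptive plumbing)

AGE_BANDS = ((45, 49), (50, 54), (55, 60))
CONDITION_BANDS = ("0", "1", "2", "3+")


def _chronic_condition_count(chart: PatientChart) -> int:
    fams = set()
    for rec in chart.records:
        if rec.code_system is CodeSystem.ICD9CM:
            norm = normalize_code(rec.code)
            for fam in CHRONIC_FAMILIES:
                if norm.startswith(fam):
                    fams.add(fam)
    return len(fams)


def cohort_summary(charts: list[PatientChart]) -> pd.DataFrame:
    """Counts by age band and by number of chronic conditions."""
    age_counts = {f"{lo}-{hi}": 0 for lo, hi in AGE_BANDS}
    for c in charts:
        for lo, hi in AGE_BANDS:
            if lo <= c.age_years <= hi:
                age_counts[f"{lo}-{hi}"] += 1
                break
    cond_counts = dict.fromkeys(CONDITION_BANDS, 0)
    for c in charts:
        n = _chronic_condition_count(c)
        cond_counts[str(n) if n < 3 else "3+"] += 1
    rows = [("age", band, cnt) for band, cnt in age_counts.items()]
    rows += [("chronic_conditions", band, cnt) for band, cnt in cond_counts.items()]
    return pd.DataFrame(rows, columns=["characteristic", "band", "count"]).set_index(
        ["characteristic", "band"]
    )
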