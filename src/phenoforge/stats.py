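"""Validity statistics for case-definition evaluation.

Covers the confusion matrix, sensitivity/specificity/PPV/NPV with
binomial confidence intervals, the F1 score (harmonic mean of
sensitivity and PPV) used as the training optimisation metric, the Wald
sample-size formula for validating a case definition at a target
sensitivity precision, and Fleiss's kappa for multi-reviewer agreement.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from statsmodels.stats.proportion import proportion_confint

from .types import Label


class CIMethod(str, enum.Enum):
    WALD = "wald"
    WILSON = "wilson"
    CLOPPER_PEARSON = "clopper_pearson"


_SM_METHOD = {
    CIMethod.WALD: "normal",
    CIMethod.WILSON: "wilson",
    CIMethod.CLOPPER_PEARSON: "beta",
}


@dataclass(frozen=True)
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def transpose(self) -> "ConfusionMatrix":
        """Swap the roles of the two classes (tp<->tn, fp<->fn)."""
        return ConfusionMatrix(tp=self.tn, fp=self.fn, fn=self.fp, tn=self.tp)


@dataclass(frozen=True)
class Metric:
    """A proportion with its confidence interval; None when undefined."""

    value: float | None
    lower: float | None = None
    upper: float | None = None

    def __str__(self) -> str:
        if self.value is None:
            return "undefined"
        return f"{100 * self.value:.1f}% ({100 * self.lower:.1f}-{100 * self.upper:.1f}%)"


@dataclass(frozen=True)
class ValidationReport:
    sensitivity: Metric
    specificity: Metric
    ppv: Metric
    npv: Metric
    f1: float | None
    n: int

    def to_dict(self) -> dict:
        out: dict = {"n": self.n, "f1": self.f1}
        for name in ("sensitivity", "specificity", "ppv", "npv"):
            m: Metric = getattr(self, name)
            out[name] = m.value
            out[f"{name}_ci"] = (m.lower, m.upper)
        return out


def confusion(labels: Sequence[Label], predictions: Sequence[bool]) -> ConfusionMatrix:
    """Tally predictions against case/non-case labels."""
    if len(labels) != len(predictions):
        raise ValueError("labels and predictions differ in length")
    tp = fp = fn = tn = 0
    for lab, pred in zip(labels, predictions):
        if lab is Label.CASE:
            if pred:
                tp += 1
            else:
                fn += 1
        elif lab is Label.NON_CASE:
            if pred:
                fp += 1
            else:
                tn += 1
        else:
            raise ValueError(f"unexpected label {lab}; exclude unclassifiable charts upstream")
    return ConfusionMatrix(tp=tp, fp=fp, fn=fn, tn=tn)


def _proportion(num: int, den: int, ci_method: CIMethod, alpha: float) -> Metric:
    if den == 0:
        return Metric(None)
    p = num / den
    lo, hi = proportion_confint(num, den, alpha=alpha, method=_SM_METHOD[ci_method])
    return Metric(p, float(np.clip(lo, 0.0, 1.0)), float(np.clip(hi, 0.0, 1.0)))


def f1_score(sn: float, ppv: float) -> float:
    """Harmonic mean of sensitivity and PPV; 0 when either is 0."""
    if not (0 <= sn <= 1 and 0 <= ppv <= 1):
        raise ValueError("sensitivity and PPV must lie in [0, 1]")
    if sn == 0 or ppv == 0:
        return 0.0
    return 2.0 / (1.0 / sn + 1.0 / ppv)


def validity_metrics(
    cm: ConfusionMatrix,
    ci_method: CIMethod = CIMethod.WALD,
    alpha: float = 0.05,
) -> ValidationReport:
    """Sensitivity, specificity, PPV, NPV (each with a CI) and F1.

    A zero denominator yields an undefined metric (value None), never a
    silent 0.  F1 is undefined when sensitivity or PPV is.
    """
    sn = _proportion(cm.tp, cm.tp + cm.fn, ci_method, alpha)
    sp = _proportion(cm.tn, cm.tn + cm.fp, ci_method, alpha)
    ppv = _proportion(cm.tp, cm.tp + cm.fp, ci_method, alpha)
    npv = _proportion(cm.tn, cm.tn + cm.fn, ci_method, alpha)
    f1 = None
    if sn.value is not None and ppv.value is not None:
        f1 = f1_score(sn.value, ppv.value)
    return ValidationReport(sn, sp, ppv, npv, f1, cm.n)


@dataclass(frozen=True)
class SampleSizeParams:
    """Inputs to the Wald validation-set size formula."""

    expected_sensitivity: float
    ci_full_width: float
    expected_prevalence: float

    def __post_init__(self) -> None:
        if not 0 < self.expected_sensitivity < 1:
            raise ValueError("expected sensitivity must lie strictly in (0, 1)")
        if not 0 < self.ci_full_width <= 1:
            raise ValueError("CI full width must lie in (0, 1]")
        if not 0 < self.expected_prevalence <= 1:
            raise ValueError("expected prevalence must lie in (0, 1]")


def sample_size(params: SampleSizeParams, z: float = 1.96) -> int:
    """N = ceil( z^2 * Sn(1-Sn) / ((c/2)^2 * p) ).

    The number of charts needed so that the 95% Wald CI of the estimated
    sensitivity has full width at most ``c`` when prevalence is ``p``.
    """
    sn = params.expected_sensitivity
    c = params.ci_full_width
    p = params.expected_prevalence
    return math.ceil(z * z * sn * (1 - sn) / ((c / 2) ** 2 * p))


@dataclass(frozen=True)
class KappaResult:
    kappa: float
    n_subjects: int
    n_raters: int


def fleiss_kappa(ratings: np.ndarray | Sequence[Sequence[int]]) -> KappaResult:
    """Fleiss's kappa from a subjects x categories count table.

    Every subject must be rated by the same number of raters (>= 2).
    kappa = (Pbar - PbarE) / (1 - PbarE); when the chance agreement
    PbarE is 1 (all ratings in one category, hence perfect agreement)
    kappa is 1 by the all-agree limit.
    """
    table = np.asarray(ratings, dtype=float)
    if table.ndim != 2 or table.shape[0] < 1 or table.shape[1] < 2:
        raise ValueError("ratings must be a subjects x categories table")
    row_sums = table.sum(axis=1)
    r = row_sums[0]
    if r < 2 or not np.all(row_sums == r):
        raise ValueError("every subject must be rated by the same number (>=2) of raters")
    n_subjects = table.shape[0]
    p_cat = table.sum(axis=0) / (n_subjects * r)
    p_i = (np.sum(table * table, axis=1) - r) / (r * (r - 1))
    p_bar = float(p_i.mean())
    p_e = float(np.sum(p_cat**2))
    kappa = 1.0 if math.isclose(p_e, 1.0) else (p_bar - p_e) / (1 - p_e)
    return KappaResult(kappa=float(kappa), n_subjects=n_subjects, n_raters=int(r))
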