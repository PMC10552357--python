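"""Decision-tree phenotype learning with nested cross-validation.

The training algorithm, end to end:

1. split the labelled charts into a train/test half and an untouched
   validation half;
2. inside nested 10-fold cross-validation, compare 14 combinations of
   class-rebalancing method (none / random over / random under /
   combined) x feature reducer (RFE / k-best) x order of application,
   with inner-loop hyperparameter optimisation of a CART decision tree
   maximising the F1 score;
3. retrain the best combination on the whole train/test half;
4. rank the final tree's features by impurity importance, build every
   singleton and pair (OR) case definition from the top features,
   and keep the one with the best train/test validity metrics;
5. measure the chosen definition once on the held-out validation half.

Class rebalancing, the 300-feature prescreen and feature reduction are
fitted on training data only; test folds and the validation half are
never resampled or used for any fitting decision.
"""

from __future__ import annotations

import enum
import itertools
import logging
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats as _sstats
from sklearn.feature_selection import RFE, chi2
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .features import FeatureMatrix, FeatureSpec, labels_to_bool, prescreen_columns
from .rules import CaseDefinition, evaluate_definition
from .stats import ConfusionMatrix, ValidationReport, confusion, validity_metrics
from .text import NegationLexicon
from .types import Label, PatientChart

logger = logging.getLogger(__name__)


class Sampling(str, enum.Enum):
    NONE = "None"
    OVER = "random over-sampling"
    UNDER = "random under-sampling"
    COMBINED = "random over- & under-sampling"


class Reducer(str, enum.Enum):
    RFE = "RFE"
    KBF = "kBF"


class Order(str, enum.Enum):
    REDUCE_THEN_SAMPLE = "reduce_then_sample"
    SAMPLE_THEN_REDUCE = "sample_then_reduce"


def default_grid() -> dict:
    """Full CART hyperparameter grid (editable config)."""
    return {
        "criterion": ["gini", "entropy"],
        "splitter": ["best", "random"],
        "max_depth": [2, 3, 4, 5, 8, None],
        "min_samples_leaf": [2, 5, 10, 20],
        "class_weight": [None, "balanced", {0: 1, 1: 2}, {0: 1, 1: 4}],
    }


def fast_grid() -> dict:
    """Desk-scale grid exercising each hyperparameter family cheaply."""
    return {
        "criterion": ["gini", "entropy"],
        "splitter": ["best"],
        "max_depth": [4, None],
        "min_samples_leaf": [2],
        "class_weight": [None, "balanced"],
    }


@dataclass
class LearnerConfig:
    hyperparameter_grid: dict = field(default_factory=fast_grid)
    sampling_methods: tuple[Sampling, ...] = (
        Sampling.COMBINED, Sampling.OVER, Sampling.UNDER, Sampling.NONE,
    )
    reducers: tuple[Reducer, ...] = (Reducer.RFE, Reducer.KBF)
    orders: tuple[Order, ...] = (Order.SAMPLE_THEN_REDUCE, Order.REDUCE_THEN_SAMPLE)
    outer_folds: int = 10
    inner_folds: int = 10
    prescreen_k: int = 300
    reduced_feature_count: int = 25
    rfe_step: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.hyperparameter_grid or any(
            not v for v in self.hyperparameter_grid.values()
        ):
            raise ValueError("hyperparameter grid must be non-empty")
        if not (self.sampling_methods and self.reducers and self.orders):
            raise ValueError("sampling/reducer/order grids must be non-empty")
        if self.outer_folds < 2 or self.inner_folds < 2:
            raise ValueError("folds must be >= 2")


@dataclass(frozen=True)
class Combination:
    sampling: Sampling
    reducer: Reducer
    order: Order

    @property
    def label(self) -> str:
        """Table-style name, first method = first applied."""
        if self.order is Order.SAMPLE_THEN_REDUCE:
            return f"{self.sampling.value};{self.reducer.value}"
        return f"{self.reducer.value};{self.sampling.value}"


def combinations(config: LearnerConfig) -> list[Combination]:
    """Sampling x reducer x order grid, collapsing the order-duplicate
    rows of sampling method "none" (14 rows on the default grid)."""
    out = []
    for samp, red, order in itertools.product(
        config.sampling_methods, config.reducers, config.orders
    ):
        if samp is Sampling.NONE and order is Order.SAMPLE_THEN_REDUCE:
            continue  # "none" makes the two orders identical
        out.append(Combination(samp, red, order))
    return out


# ---------------------------------------------------------------------------
# Splitting


def split_train_validation(
    charts: Sequence[PatientChart], seed: int
) -> tuple[list[PatientChart], list[PatientChart]]:
    """Random disjoint halves (sizes differing by at most one).

    The second half is the validation set: it must stay untouched until
    the final assessment of the chosen case definition.
    """
    if len(charts) < 2:
        raise ValueError("need at least two charts to split")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(charts))
    cut = (len(charts) + 1) // 2
    train = [charts[i] for i in sorted(order[:cut])]
    valid = [charts[i] for i in sorted(order[cut:])]
    return train, valid


def stratified_folds(labels: Sequence[Label] | np.ndarray, k: int, seed: int) -> np.ndarray:
    """Fold assignment with per-fold class counts differing by <= 1."""
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    if k < 2:
        raise ValueError("need at least 2 folds")
    counts = np.bincount(y.astype(int), minlength=2)
    if counts.min() < k:
        raise ValueError(f"smallest class ({counts.min()}) is smaller than k={k}")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed % 2**31)
    assign = np.empty(len(y), dtype=int)
    for f, (_, test_idx) in enumerate(skf.split(np.zeros(len(y)), y)):
        assign[test_idx] = f
    return assign


# ---------------------------------------------------------------------------
# Resampling (random over-/under-sampling and their combination)


def resample(
    X: np.ndarray, y: np.ndarray, method: Sampling, seed: int | np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Rebalance classes by random duplication/removal of rows.

    under: non-cases randomly dropped to the case count;
    over: cases randomly duplicated to the non-case count;
    combined: both classes meet at the (rounded) geometric mean of the
    class sizes.  Never applied to test data.
    """
    if method is Sampling.NONE:
        return X, y
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    case_idx = np.where(y)[0]
    non_idx = np.where(~y)[0]
    if len(case_idx) == 0 or len(non_idx) == 0:
        raise ValueError("both classes must be present to resample")
    if method is Sampling.UNDER:
        keep_non = rng.choice(non_idx, size=len(case_idx), replace=False)
        idx = np.concatenate([case_idx, keep_non])
    elif method is Sampling.OVER:
        extra = rng.choice(case_idx, size=len(non_idx) - len(case_idx), replace=True)
        idx = np.concatenate([np.arange(len(y)), extra])
    else:  # COMBINED
        g = int(round(np.sqrt(len(case_idx) * len(non_idx))))
        idx = np.concatenate([_resize(case_idx, g, rng), _resize(non_idx, g, rng)])
    return X[idx], y[idx]


def _resize(idx: np.ndarray, target: int, rng: np.random.Generator) -> np.ndarray:
    if target <= len(idx):
        return rng.choice(idx, size=target, replace=False)
    extra = rng.choice(idx, size=target - len(idx), replace=True)
    return np.concatenate([idx, extra])


# ---------------------------------------------------------------------------
# Feature reduction


def reduce_features(
    X: np.ndarray,
    y: np.ndarray,
    reducer: Reducer,
    target_count: int,
    seed: int = 0,
    rfe_step: float = 0.3,
) -> list[int]:
    """Column subset chosen by RFE (iterated tree refits, dropping the
    lowest-importance block each round) or k-best chi-squared scores."""
    n_cols = X.shape[1]
    if target_count >= n_cols:
        return list(range(n_cols))
    if reducer is Reducer.RFE:
        est = DecisionTreeClassifier(random_state=seed % 2**31)
        sel = RFE(est, n_features_to_select=target_count, step=rfe_step)
        sel.fit(X, y)
        return list(np.where(sel.support_)[0])
    scores, _ = chi2(X, y)
    scores = np.nan_to_num(scores, nan=0.0)
    order = np.argsort(-scores, kind="stable")
    return sorted(order[:target_count].tolist())


# ---------------------------------------------------------------------------
# Nested cross-validation


@dataclass
class CombinationResult:
    combination: Combination
    per_fold: pd.DataFrame  # columns: sensitivity, specificity, ppv, npv, f1

    @property
    def label(self) -> str:
        return self.combination.label

    def mean(self, metric: str) -> float:
        return float(np.nanmean(self.per_fold[metric].to_numpy()))

    def ci(self, metric: str, alpha: float = 0.05) -> tuple[float, float]:
        """t-based CI of the fold mean, clipped to [0, 1]."""
        vals = self.per_fold[metric].to_numpy()
        vals = vals[~np.isnan(vals)]
        m = float(vals.mean())
        if len(vals) < 2:
            return m, m
        half = _sstats.t.ppf(1 - alpha / 2, len(vals) - 1) * vals.std(ddof=1) / np.sqrt(len(vals))
        return max(0.0, m - half), min(1.0, m + half)

    @property
    def mean_f1(self) -> float:
        return self.mean("f1")

    @property
    def f1_of_means(self) -> float:
        """F1 recomputed from the mean sensitivity and mean PPV (the
        harmonic-mean identity holds exactly only for a single fold)."""
        sn, ppv = self.mean("sensitivity"), self.mean("ppv")
        if sn == 0 or ppv == 0:
            return 0.0
        return 2.0 / (1.0 / sn + 1.0 / ppv)

    def summary_row(self) -> dict:
        row: dict = {"combination": self.label}
        for metric in ("sensitivity", "specificity", "ppv", "npv"):
            lo, hi = self.ci(metric)
            row[metric] = self.mean(metric)
            row[f"{metric}_ci_low"], row[f"{metric}_ci_high"] = lo, hi
        row["f1"] = self.mean_f1
        return row


def _fold_metrics(y_true: np.ndarray, pred: np.ndarray) -> dict:
    tp = int(np.sum(pred & y_true))
    fp = int(np.sum(pred & ~y_true))
    fn = int(np.sum(~pred & y_true))
    tn = int(np.sum(~pred & ~y_true))
    def frac(a: int, b: int) -> float:
        return a / b if b else np.nan
    sn = frac(tp, tp + fn)
    ppv = frac(tp, tp + fp)
    f1 = 2 * tp / (2 * tp + fp + fn) if (2 * tp + fp + fn) else np.nan
    return {
        "sensitivity": sn,
        "specificity": frac(tn, tn + fp),
        "ppv": ppv,
        "npv": frac(tn, tn + fn),
        "f1": f1,
    }


def _tree_seed(config: LearnerConfig, *key: int) -> int:
    return int(np.random.SeedSequence((config.seed, *key)).generate_state(1)[0] % 2**31)


def _select_hyperparams(
    X: np.ndarray,
    y: np.ndarray,
    sampling: Sampling,
    param_list: list[dict],
    config: LearnerConfig,
    key: tuple[int, ...],
) -> dict:
    """Inner k-fold grid search maximising mean F1.

    Resampling is applied to each inner training split only; inner test
    splits stay untouched.
    """
    assign = stratified_folds(y, config.inner_folds, _tree_seed(config, *key, 1))
    sums = np.zeros(len(param_list))
    counts = np.zeros(len(param_list))
    for g in range(config.inner_folds):
        tr = assign != g
        te = ~tr
        if y[tr].all() or not y[tr].any():
            logger.warning("inner fold %d has a single class; skipped", g)
            continue
        Xi, yi = resample(X[tr], y[tr], sampling, _tree_seed(config, *key, 2, g))
        Xt, yt = X[te], y[te]
        for p, params in enumerate(param_list):
            clf = DecisionTreeClassifier(random_state=_tree_seed(config, *key, 3, g), **params)
            clf.fit(Xi, yi)
            pred = clf.predict(Xt).astype(bool)
            f1 = _fold_metrics(yt, pred)["f1"]
            if not np.isnan(f1):
                sums[p] += f1
                counts[p] += 1
    means = np.where(counts > 0, sums / np.maximum(counts, 1), -1.0)
    return param_list[int(np.argmax(means))]


def _prepare_fold(
    Xtr: np.ndarray,
    ytr: np.ndarray,
    combo: Combination,
    config: LearnerConfig,
    key: tuple[int, ...],
) -> list[int]:
    """Feature reduction for one training set, honouring the combo order."""
    if combo.order is Order.REDUCE_THEN_SAMPLE:
        return reduce_features(
            Xtr, ytr, combo.reducer, config.reduced_feature_count,
            _tree_seed(config, *key, 4), config.rfe_step,
        )
    Xs, ys = resample(Xtr, ytr, combo.sampling, _tree_seed(config, *key, 5))
    return reduce_features(
        Xs, ys, combo.reducer, config.reduced_feature_count,
        _tree_seed(config, *key, 4), config.rfe_step,
    )


def nested_cv(
    matrix: FeatureMatrix, labels: Sequence[Label] | np.ndarray, config: LearnerConfig
) -> list[CombinationResult]:
    """Outer-loop performance estimates for every combination.

    Within each outer fold: prescreen to the top-k ad hoc importance
    features on the training folds, reduce/resample in the combination's
    order, pick hyperparameters by inner k-fold F1, train on the (re-
    sampled) training folds and measure on the untouched test fold.
    """
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    X_all = matrix.values.astype(np.float32)
    outer = stratified_folds(y, config.outer_folds, _tree_seed(config, 0))
    param_list = list(ParameterGrid(config.hyperparameter_grid))
    results: list[CombinationResult] = []
    # prescreen depends only on the fold, not the combination
    names = matrix.names
    fold_cols: dict[int, list[int]] = {}
    for f in range(config.outer_folds):
        tr = np.where(outer != f)[0]
        fold_cols[f] = prescreen_columns(matrix.values[tr], names, y[tr], config.prescreen_k)
    for c, combo in enumerate(combinations(config)):
        rows = []
        for f in range(config.outer_folds):
            tr = outer != f
            te = ~tr
            cols = fold_cols[f]
            Xtr = X_all[np.where(tr)[0]][:, cols]
            ytr = y[tr]
            red = _prepare_fold(Xtr, ytr, combo, config, (c, f))
            Xr = Xtr[:, red]
            params = _select_hyperparams(Xr, ytr, combo.sampling, param_list, config, (c, f))
            Xo, yo = resample(Xr, ytr, combo.sampling, _tree_seed(config, c, f, 6))
            clf = DecisionTreeClassifier(random_state=_tree_seed(config, c, f, 7), **params)
            clf.fit(Xo, yo)
            Xte = X_all[np.where(te)[0]][:, cols][:, red]
            pred = clf.predict(Xte).astype(bool)
            rows.append(_fold_metrics(y[te], pred))
        results.append(CombinationResult(combo, pd.DataFrame(rows)))
    return results


def select_best_combination(results: Sequence[CombinationResult]) -> CombinationResult:
    """Highest mean F1; ties broken by mean sensitivity, then mean PPV."""
    if not results:
        raise ValueError("no combination results")
    return max(
        results,
        key=lambda r: (r.mean_f1, r.mean("sensitivity"), r.mean("ppv")),
    )


# ---------------------------------------------------------------------------
# Final tree, rule extraction, simplification


@dataclass
class TreeRule:
    conditions: list[tuple[str, bool]]  # (feature name, must be present?)
    verdict: bool
    n_samples: int


@dataclass
class TrainedTree:
    specs: list[FeatureSpec]  # the reduced feature set, in column order
    importances: dict[str, float]  # nonzero importances, summing to 1
    rules: list[TreeRule]
    params: dict
    classifier: DecisionTreeClassifier

    @property
    def feature_names(self) -> list[str]:
        return [s.name for s in self.specs]

    def spec_by_name(self, name: str) -> FeatureSpec:
        for s in self.specs:
            if s.name == name:
                return s
        raise KeyError(name)


def _extract_rules(clf: DecisionTreeClassifier, names: list[str]) -> list[TreeRule]:
    tree = clf.tree_
    rules: list[TreeRule] = []

    def walk(node: int, conds: list[tuple[str, bool]]) -> None:
        if tree.children_left[node] == -1:  # leaf
            counts = tree.value[node][0]
            verdict = bool(np.argmax(counts) == 1) if len(counts) > 1 else False
            rules.append(TreeRule(list(conds), verdict, int(tree.n_node_samples[node])))
            return
        name = names[tree.feature[node]]
        walk(tree.children_left[node], conds + [(name, False)])  # feature absent
        walk(tree.children_right[node], conds + [(name, True)])  # feature present

    walk(0, [])
    return rules


def train_final_tree(
    matrix: FeatureMatrix,
    labels: Sequence[Label] | np.ndarray,
    best: Combination,
    config: LearnerConfig,
) -> TrainedTree:
    """Retrain the winning combination on the whole train/test matrix."""
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    if y.all() or not y.any():
        # degenerate constant labels: a single-leaf tree with no rules
        clf = DecisionTreeClassifier(random_state=_tree_seed(config, 99, 0, 7))
        clf.fit(matrix.values.astype(np.float32), y)
        verdict = bool(y.any())
        return TrainedTree(
            specs=list(matrix.specs),
            importances={},
            rules=[TreeRule([], verdict, len(y))],
            params={},
            classifier=clf,
        )
    cols = prescreen_columns(matrix.values, matrix.names, y, config.prescreen_k)
    X = matrix.values.astype(np.float32)[:, cols]
    red = _prepare_fold(X, y, best, config, (99, 0))
    Xr = X[:, red]
    specs = [matrix.specs[cols[j]] for j in red]
    param_list = list(ParameterGrid(config.hyperparameter_grid))
    params = _select_hyperparams(Xr, y, best.sampling, param_list, config, (99, 0))
    Xo, yo = resample(Xr, y, best.sampling, _tree_seed(config, 99, 0, 6))
    clf = DecisionTreeClassifier(random_state=_tree_seed(config, 99, 0, 7), **params)
    clf.fit(Xo, yo)
    names = [s.name for s in specs]
    raw = clf.feature_importances_
    total = raw.sum()
    importances = (
        {names[j]: float(raw[j]) / total for j in range(len(names)) if raw[j] > 0}
        if total > 0
        else {}
    )
    return TrainedTree(
        specs=specs,
        importances=importances,
        rules=_extract_rules(clf, names),
        params=params,
        classifier=clf,
    )


@dataclass
class Candidate:
    definition: CaseDefinition
    feature_names: tuple[str, ...]
    report: ValidationReport


@dataclass
class SimplificationResult:
    candidates: list[Candidate]
    chosen: Candidate


def simplify_definition(
    tree: TrainedTree,
    matrix: FeatureMatrix,
    labels: Sequence[Label] | np.ndarray,
    s: int = 9,
) -> SimplificationResult:
    """Importance-ranked simplification of the provisional definition.

    Take the top-s features by importance; form every singleton and
    every OR-pair case definition (s + C(s,2) candidates); score each on
    the full train/test set through the feature columns (identical to
    rule-engine evaluation by construction); keep the best by F1 with
    sensitivity, PPV, then simplicity tie-breaks.
    """
    if not tree.importances:
        raise ValueError("tree has no nonzero-importance features")
    y = labels if isinstance(labels, np.ndarray) and labels.dtype == bool else labels_to_bool(labels)
    ranked = sorted(tree.importances.items(), key=lambda kv: (-kv[1], kv[0]))[:s]
    names = [n for n, _ in ranked]
    col_of = {spec.name: j for j, spec in enumerate(matrix.specs)}
    y_labels = [Label.CASE if v else Label.NON_CASE for v in y]

    def make(feats: tuple[str, ...]) -> Candidate:
        clauses = tuple(tree.spec_by_name(n).to_clause() for n in feats)
        verdict = np.zeros(len(y), dtype=bool)
        for n in feats:
            verdict |= matrix.values[:, col_of[n]].astype(bool)
        report = validity_metrics(confusion(y_labels, verdict.tolist()))
        return Candidate(CaseDefinition(clauses), feats, report)

    candidates = [make((n,)) for n in names]
    candidates += [make(pair) for pair in itertools.combinations(names, 2)]

    def score(c: Candidate):
        rep = c.report
        f1 = rep.f1 if rep.f1 is not None else -1.0
        sn = rep.sensitivity.value if rep.sensitivity.value is not None else -1.0
        ppv = rep.ppv.value if rep.ppv.value is not None else -1.0
        return (f1, sn, ppv, -len(c.definition.clauses), tuple(sorted(c.feature_names)))

    chosen = max(candidates, key=score)
    return SimplificationResult(candidates=candidates, chosen=chosen)


def validate_final(
    definition: CaseDefinition,
    charts: Sequence[PatientChart],
    lexicon: NegationLexicon | None = None,
) -> ValidationReport:
    """Apply the rule engine to independent labelled charts."""
    usable = [c for c in charts if c.label in (Label.CASE, Label.NON_CASE)]
    preds = [evaluate_definition(c, definition, lexicon) for c in usable]
    return validity_metrics(confusion([c.label for c in usable], preds))
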