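"""Classifier roster, CV/independent-test protocol, and evaluation metrics.

The eight metrics are ACC, MCC, Sn (recall), Sp (specificity), NPV,
P (precision), auROC and auPRC.  The threshold metrics come straight from
the 2x2 confusion counts; auROC is the Mann–Whitney statistic computed with
midranks, and auPRC is the average-precision step sum.  Any metric whose
denominator is zero on a given fold is reported as 0 and flagged degenerate
rather than aborting the run.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
from scipy.stats import rankdata
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .exceptions import ConfigError, InputError, UndefinedMetricError
from .io import EmbeddingSet

__all__ = [
    "ConfusionCounts",
    "MetricsReport",
    "ClassifierSpec",
    "CVResult",
    "FAMILIES",
    "confusion",
    "scalar_metrics",
    "roc_auc",
    "pr_auc",
    "evaluate",
    "fit_predict",
    "cross_validate",
    "compare_classifiers",
]

METRIC_NAMES = ("ACC", "MCC", "Sn", "Sp", "NPV", "P", "auROC", "auPRC")

FAMILIES = (
    "margin-kernel",
    "boosted-trees-hist",
    "boosted-trees-exact",
    "logistic",
    "k-nearest-neighbor",
)


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    @property
    def total(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass(frozen=True)
class MetricsReport:
    ACC: float
    MCC: float
    Sn: float
    Sp: float
    NPV: float
    P: float
    auROC: float
    auPRC: float
    counts: Optional[ConfusionCounts] = None
    degenerate: frozenset[str] = frozenset()

    def as_dict(self) -> dict[str, float]:
        return {name: getattr(self, name) for name in METRIC_NAMES}


@dataclass(frozen=True)
class ClassifierSpec:
    """One roster entry: a model family plus hyperparameter overrides.

    Defaults (recorded in every run report): margin-kernel = RBF SVM with
    C = 1 and kernel width 1/(d * feature variance); logistic = L2, C = 1;
    k-nearest-neighbor k = 5; both boosted-tree families 100 trees, depth 6,
    learning rate 0.1.
    """

    family: str
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ConfigError(
                f"unknown family '{self.family}'; choose from {FAMILIES}"
            )

    def build(self):
        hp = dict(self.hyperparameters)
        if self.family == "margin-kernel":
            return SVC(
                kernel=hp.pop("kernel", "rbf"),
                C=hp.pop("C", 1.0),
                gamma=hp.pop("gamma", "scale"),
                random_state=self.seed,
                **hp,
            )
        if self.family == "logistic":
            # sklearn's default penalty is already L2
            return LogisticRegression(
                C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 1000), **hp
            )
        if self.family == "k-nearest-neighbor":
            return KNeighborsClassifier(n_neighbors=hp.pop("k", 5), **hp)
        if self.family == "boosted-trees-hist":
            from lightgbm import LGBMClassifier

            return LGBMClassifier(
                n_estimators=hp.pop("n_estimators", 100),
                max_depth=hp.pop("max_depth", 6),
                learning_rate=hp.pop("learning_rate", 0.1),
                random_state=self.seed,
                verbose=-1,
                **hp,
            )
        if self.family == "boosted-trees-exact":
            from xgboost import XGBClassifier

            return XGBClassifier(
                n_estimators=hp.pop("n_estimators", 100),
                max_depth=hp.pop("max_depth", 6),
                learning_rate=hp.pop("learning_rate", 0.1),
                tree_method=hp.pop("tree_method", "exact"),
                random_state=self.seed,
                **hp,
            )
        raise ConfigError(self.family)


@dataclass(frozen=True)
class CVResult:
    spec: ClassifierSpec
    fold_metrics: tuple[MetricsReport, ...]
    mean_metrics: MetricsReport
    test_metrics: Optional[MetricsReport] = None


def confusion(labels: Sequence[int], predicted: Sequence[int]) -> ConfusionCounts:
    """2x2 counts with 1 = positive."""
    y = np.asarray(labels, dtype=int)
    p = np.asarray(predicted, dtype=int)
    if y.shape != p.shape or y.size == 0:
        raise InputError("labels and predictions must be equal-length, non-empty")
    return ConfusionCounts(
        TP=int(np.sum((y == 1) & (p == 1))),
        TN=int(np.sum((y == 0) & (p == 0))),
        FP=int(np.sum((y == 0) & (p == 1))),
        FN=int(np.sum((y == 1) & (p == 0))),
    )


def _safe_div(num: float, den: float, flag: str, flags: set[str]) -> float:
    if den == 0:
        flags.add(flag)
        return 0.0
    return num / den


def scalar_metrics(c: ConfusionCounts) -> tuple[dict[str, float], frozenset[str]]:
    """The six threshold metrics from confusion counts.

    Returns the metric dict plus the set of metrics whose denominator was
    zero (reported as 0).
    """
    if c.total == 0:
        raise InputError("empty confusion table")
    flags: set[str] = set()
    tp, tn, fp, fn = float(c.TP), float(c.TN), float(c.FP), float(c.FN)
    acc = (tp + tn) / (tp + tn + fp + fn)
    mcc_den = np.sqrt((tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe_div(tp * tn - fp * fn, mcc_den, "MCC", flags)
    sn = _safe_div(tp, tp + fn, "Sn", flags)
    sp = _safe_div(tn, tn + fp, "Sp", flags)
    npv = _safe_div(tn, tn + fn, "NPV", flags)
    prec = _safe_div(tp, tp + fp, "P", flags)
    return (
        {"ACC": acc, "MCC": mcc, "Sn": sn, "Sp": sp, "NPV": npv, "P": prec},
        frozenset(flags),
    )


def roc_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the ROC curve via midranks (Mann–Whitney form).

    Equals P(score_pos > score_neg) + 0.5 * P(tie) over random
    positive/negative pairs.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InputError("labels and scores must be equal length")
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("auROC needs both classes present")
    ranks = rankdata(s)  # midranks for ties
    rank_sum_pos = float(np.sum(ranks[y == 1]))
    u = rank_sum_pos - n_pos * (n_pos + 1) / 2.0
    return u / (n_pos * n_neg)


def pr_auc(labels: Sequence[int], scores: Sequence[float]) -> float:
    """Area under the precision-recall curve (average-precision step sum).

    AP = sum_i (R_i - R_{i-1}) * P_i over descending score thresholds, with
    tied scores entering together.
    """
    y = np.asarray(labels, dtype=int)
    s = np.asarray(scores, dtype=float)
    if y.shape != s.shape:
        raise InputError("labels and scores must be equal length")
    n_pos = int(np.sum(y == 1))
    if n_pos == 0:
        raise UndefinedMetricError("auPRC needs at least one positive")
    order = np.argsort(-s, kind="stable")
    y_sorted = y[order]
    s_sorted = s[order]
    tp_cum = np.cumsum(y_sorted)
    pred_cum = np.arange(1, y.size + 1)
    # only evaluate at the last index of each tied-score block
    block_end = np.r_[s_sorted[1:] != s_sorted[:-1], True]
    tp = tp_cum[block_end].astype(float)
    npred = pred_cum[block_end].astype(float)
    precision = tp / npred
    recall = tp / n_pos
    prev_recall = np.r_[0.0, recall[:-1]]
    return float(np.sum((recall - prev_recall) * precision))


def evaluate(
    labels: Sequence[int], predicted: Sequence[int], scores: Sequence[float]
) -> MetricsReport:
    """Full eight-metric report for one evaluation split."""
    counts = confusion(labels, predicted)
    scalars, flags = scalar_metrics(counts)
    return MetricsReport(
        **scalars,
        auROC=roc_auc(labels, scores),
        auPRC=pr_auc(labels, scores),
        counts=counts,
        degenerate=flags,
    )


def fit_predict(
    spec: ClassifierSpec, train: EmbeddingSet, eval_set: EmbeddingSet
) -> tuple[np.ndarray, np.ndarray]:
    """Fit on ``train``, score and hard-classify ``eval_set``.

    Scores are continuous with higher = more positive: the signed margin
    for the kernel family (ranking metrics need no calibration), the
    positive-class probability elsewhere.  Hard labels come from each
    family's native decision rule.
    """
    if len(np.unique(train.labels)) < 2:
        raise InputError("training set must contain both classes")
    if train.d != eval_set.d:
        raise InputError(f"dimension mismatch: train d={train.d}, eval d={eval_set.d}")
    model = spec.build()
    model.fit(train.features, train.labels)
    if spec.family == "margin-kernel":
        scores = model.decision_function(eval_set.features)
    else:
        scores = model.predict_proba(eval_set.features)[:, 1]
    predicted = model.predict(eval_set.features).astype(int)
    return np.asarray(scores, dtype=float), predicted


def _mean_report(folds: Sequence[MetricsReport]) -> MetricsReport:
    means = {
        name: float(np.mean([getattr(f, name) for f in folds]))
        for name in METRIC_NAMES
    }
    flags = frozenset().union(*(f.degenerate for f in folds))
    return MetricsReport(**means, counts=None, degenerate=flags)


def cross_validate(
    spec: ClassifierSpec,
    train: EmbeddingSet,
    folds: int = 5,
    seed: int = 0,
    test: Optional[EmbeddingSet] = None,
) -> CVResult:
    """Label-stratified k-fold CV, optionally plus an independent test.

    The independent-test metrics come from a model refit on the full
    training set.  Fold assignment depends only on ``seed`` so roster
    comparisons can share folds.
    """
    counts = np.bincount(train.labels, minlength=2)
    if counts.min() < folds:
        raise InputError(
            f"smallest class has {counts.min()} samples; need >= {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    fold_metrics = []
    for tr_idx, va_idx in skf.split(train.features, train.labels):
        tr, va = train.subset(tr_idx), train.subset(va_idx)
        scores, predicted = fit_predict(spec, tr, va)
        fold_metrics.append(evaluate(va.labels, predicted, scores))
    test_metrics = None
    if test is not None:
        scores, predicted = fit_predict(spec, train, test)
        test_metrics = evaluate(test.labels, predicted, scores)
    return CVResult(
        spec=spec,
        fold_metrics=tuple(fold_metrics),
        mean_metrics=_mean_report(fold_metrics),
        test_metrics=test_metrics,
    )


def compare_classifiers(
    specs: Sequence[ClassifierSpec],
    train: EmbeddingSet,
    test: Optional[EmbeddingSet] = None,
    folds: int = 5,
    seed: int = 0,
) -> list[CVResult]:
    """Run the roster under shared fold assignments (paired comparison)."""
    return [cross_validate(s, train, folds=folds, seed=seed, test=test) for s in specs]


def default_roster(seed: int = 0) -> list[ClassifierSpec]:
    """The five-family roster with default hyperparameters."""
    return [ClassifierSpec(family=f, seed=seed) for f in FAMILIES]
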