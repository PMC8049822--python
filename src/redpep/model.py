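"""RBF-SVM training, cross-validation and evaluation metrics.

The classifier is a support vector machine with RBF kernel; C and gamma
are tuned by grid search on an exponent lattice strictly inside
2^-5 < C < 2^15 and 2^-15 < gamma < 2^3. Evaluation pools out-of-fold
predictions from stratified k-fold cross-validation into one confusion
matrix (Sn, Sp, Acc) and one ROC curve whose area is computed by the
trapezoidal rule.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import joblib
import numpy as np
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .encoding import FeatureMatrix
from .errors import (
    ConfigurationError,
    EncodingMismatchError,
    StratificationError,
    UndefinedMetricError,
)

DEFAULT_SEED = 1


@dataclass(frozen=True, order=True)
class SVMConfig:
    """RBF-kernel hyperparameters. Ordering (C, then gamma) encodes the
    grid-search tie rule: smaller C wins, then smaller gamma."""

    C: float
    gamma: float

    def __post_init__(self) -> None:
        if self.C <= 0 or self.gamma <= 0:
            raise ConfigurationError("C and gamma must be positive")


def default_grid(step: int = 2) -> list[SVMConfig]:
    """Exponent lattice strictly inside the open intervals
    (2^-5, 2^15) for C and (2^-15, 2^3) for gamma.

    With the default step 2 this is C in {2^-4, 2^-2, ..., 2^14} and
    gamma in {2^-14, 2^-12, ..., 2^2}: 10 x 9 = 90 candidates.
    """
    cs = [2.0**e for e in range(-4, 15, step)]
    gammas = [2.0**e for e in range(-14, 3, step)]
    return [SVMConfig(c, g) for c in cs for g in gammas]


@dataclass(frozen=True)
class ConfusionCounts:
    TP: int
    TN: int
    FP: int
    FN: int

    def __post_init__(self) -> None:
        if min(self.TP, self.TN, self.FP, self.FN) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def n(self) -> int:
        return self.TP + self.TN + self.FP + self.FN


@dataclass
class EvaluationReport:
    """Pooled cross-validation (or hold-out) evaluation result."""

    confusion: ConfusionCounts
    sn: float
    sp: float
    acc: float
    roc_points: list[tuple[float, float]]
    auc: float | None
    per_fold: list[dict] = field(default_factory=list)
    config: SVMConfig | None = None
    seed: int | None = None

    def to_text(self) -> str:
        """Structured key-value report plus ROC point table."""
        c = self.confusion
        lines = [
            f"TP\t{c.TP}",
            f"TN\t{c.TN}",
            f"FP\t{c.FP}",
            f"FN\t{c.FN}",
            f"Sn\t{self.sn:.6f}",
            f"Sp\t{self.sp:.6f}",
            f"Acc\t{self.acc:.6f}",
            f"AUC\t{'NA' if self.auc is None else format(self.auc, '.6f')}",
        ]
        if self.config is not None:
            lines.append(f"C\t{self.config.C:.10g}")
            lines.append(f"gamma\t{self.config.gamma:.10g}")
        if self.seed is not None:
            lines.append(f"seed\t{self.seed}")
        for fold in self.per_fold:
            lines.append(
                "fold\t{index}\tacc\t{acc:.6f}".format(**fold)
            )
        lines.append("roc\tFPR\tTPR")
        for fpr, tpr in self.roc_points:
            lines.append(f"roc\t{fpr:.6f}\t{tpr:.6f}")
        return "\n".join(lines) + "\n"


def compute_metrics(confusion: ConfusionCounts) -> tuple[float, float, float]:
    """Sensitivity TP/(TP+FN), specificity TN/(TN+FP), accuracy (TP+TN)/n.

    Raises :class:`~redpep.errors.UndefinedMetricError` when a class is
    absent rather than silently returning 0.
    """
    pos = confusion.TP + confusion.FN
    neg = confusion.TN + confusion.FP
    if pos == 0:
        raise UndefinedMetricError("no positive samples: Sn undefined")
    if neg == 0:
        raise UndefinedMetricError("no negative samples: Sp undefined")
    sn = confusion.TP / pos
    sp = confusion.TN / neg
    acc = (confusion.TP + confusion.TN) / (pos + neg)
    return sn, sp, acc


def roc_auc(
    scores: np.ndarray, labels: np.ndarray
) -> tuple[list[tuple[float, float]], float]:
    """ROC points and trapezoidal AUC from decision scores.

    Thresholds sweep the distinct score values from high to low; the curve
    is anchored at (0, 0) and (1, 1) and the area is the trapezoidal sum
    sum_i [ (1-beta_i) dalpha + 1/2 d(1-beta) dalpha ], which equals the
    Mann-Whitney statistic P(score+ > score-) + 1/2 P(tie).
    """
    scores = np.asarray(scores, dtype=np.float64)
    labels = np.asarray(labels)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise UndefinedMetricError("ROC/AUC needs both classes present")
    order = np.argsort(-scores, kind="stable")
    s, y = scores[order], labels[order]
    points: list[tuple[float, float]] = [(0.0, 0.0)]
    tp = fp = 0
    for i in range(len(s)):
        if y[i] == 1:
            tp += 1
        else:
            fp += 1
        # emit a point only after the last of a run of tied scores
        if i + 1 == len(s) or s[i + 1] != s[i]:
            points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    auc = 0.0
    for (a0, b0), (a1, b1) in zip(points, points[1:]):
        auc += (a1 - a0) * (b0 + 0.5 * (b1 - b0))
    return points, auc


def _confusion_from(pred: np.ndarray, labels: np.ndarray) -> ConfusionCounts:
    return ConfusionCounts(
        TP=int(np.sum((pred == 1) & (labels == 1))),
        TN=int(np.sum((pred == 0) & (labels == 0))),
        FP=int(np.sum((pred == 1) & (labels == 0))),
        FN=int(np.sum((pred == 0) & (labels == 1))),
    )


def _make_svc(config: SVMConfig) -> SVC:
    return SVC(kernel="rbf", C=config.C, gamma=config.gamma)


def _stratified_folds(
    labels: np.ndarray, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    counts = np.bincount(labels, minlength=2)
    if counts.min() < folds:
        raise StratificationError(
            f"smallest class has {counts.min()} sample(s), "
            f"fewer than {folds} folds"
        )
    skf = StratifiedKFold(n_splits=folds, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros(len(labels)), labels))


def cross_validate(
    matrix: FeatureMatrix,
    config: SVMConfig,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> EvaluationReport:
    """Stratified k-fold CV with pooled out-of-fold predictions.

    One confusion matrix, one Sn/Sp/Acc triple and one ROC/AUC are
    computed from the pooled predictions and decision scores; per-fold
    accuracies are retained for diagnostics. Deterministic for a fixed
    seed.
    """
    X, y = matrix.values, matrix.labels
    pred = np.empty(len(y), dtype=np.int64)
    score = np.empty(len(y), dtype=np.float64)
    per_fold = []
    for idx, (train, test) in enumerate(_stratified_folds(y, folds, seed)):
        clf = _make_svc(config).fit(X[train], y[train])
        p = clf.predict(X[test])
        pred[test] = p
        score[test] = clf.decision_function(X[test])
        per_fold.append(
            {"index": idx, "acc": float(np.mean(p == y[test]))}
        )
    confusion = _confusion_from(pred, y)
    sn, sp, acc = compute_metrics(confusion)
    points, auc = roc_auc(score, y)
    return EvaluationReport(
        confusion=confusion,
        sn=sn,
        sp=sp,
        acc=acc,
        roc_points=points,
        auc=auc,
        per_fold=per_fold,
        config=config,
        seed=seed,
    )


def cv_accuracy(
    matrix: FeatureMatrix,
    config: SVMConfig,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> float:
    """Mean of per-fold accuracies (the grid-search objective)."""
    X, y = matrix.values, matrix.labels
    accs = []
    for train, test in _stratified_folds(y, folds, seed):
        clf = _make_svc(config).fit(X[train], y[train])
        accs.append(float(np.mean(clf.predict(X[test]) == y[test])))
    return float(np.mean(accs))


def grid_search(
    matrix: FeatureMatrix,
    grid: list[SVMConfig],
    folds: int = 5,
    seed: int = DEFAULT_SEED,
) -> tuple[SVMConfig, float]:
    """Best config by mean CV accuracy; ties go to smaller C, then gamma."""
    if not grid:
        raise ConfigurationError("empty hyperparameter grid")
    best: tuple[float, SVMConfig] | None = None
    for config in sorted(grid):
        acc = cv_accuracy(matrix, config, folds=folds, seed=seed)
        if best is None or acc > best[0]:
            best = (acc, config)
    return best[1], best[0]


@dataclass
class FittedModel:
    """A trained SVM plus the provenance needed to encode new data."""

    svc: SVC
    config: SVMConfig
    scheme_notation: str
    scheme_type_id: int
    scheme_size: int
    n: int
    feature_names: list[str]
    seed: int = DEFAULT_SEED

    def _check(self, matrix: FeatureMatrix) -> None:
        if (
            matrix.scheme.notation != self.scheme_notation
            or matrix.n != self.n
        ):
            raise EncodingMismatchError(
                f"model expects scheme {self.scheme_notation!r} N={self.n}, "
                f"got {matrix.scheme.notation!r} N={matrix.n}"
            )

    def save(self, path: str | Path) -> None:
        payload = {
            "svc": self.svc,
            "meta": {
                "C": self.config.C,
                "gamma": self.config.gamma,
                "scheme_notation": self.scheme_notation,
                "scheme_type_id": self.scheme_type_id,
                "scheme_size": self.scheme_size,
                "n": self.n,
                "feature_names": self.feature_names,
                "seed": self.seed,
            },
        }
        joblib.dump(payload, path)

    @classmethod
    def load(cls, path: str | Path) -> "FittedModel":
        payload = joblib.load(path)
        meta = payload["meta"]
        return cls(
            svc=payload["svc"],
            config=SVMConfig(meta["C"], meta["gamma"]),
            scheme_notation=meta["scheme_notation"],
            scheme_type_id=meta["scheme_type_id"],
            scheme_size=meta["scheme_size"],
            n=meta["n"],
            feature_names=meta["feature_names"],
            seed=meta["seed"],
        )

    def meta_json(self) -> str:
        return json.dumps(
            {
                "C": self.config.C,
                "gamma": self.config.gamma,
                "scheme_notation": self.scheme_notation,
                "n": self.n,
                "n_features": len(self.feature_names),
                "seed": self.seed,
            },
            sort_keys=True,
        )


def train_final(
    matrix: FeatureMatrix, config: SVMConfig, seed: int = DEFAULT_SEED
) -> FittedModel:
    """Fit the SVM on the full matrix and package it with provenance."""
    svc = _make_svc(config).fit(matrix.values, matrix.labels)
    return FittedModel(
        svc=svc,
        config=config,
        scheme_notation=matrix.scheme.notation,
        scheme_type_id=matrix.scheme.type_id,
        scheme_size=matrix.scheme.size,
        n=matrix.n,
        feature_names=list(matrix.feature_names),
        seed=seed,
    )


def predict(
    model: FittedModel, matrix: FeatureMatrix
) -> tuple[np.ndarray, np.ndarray]:
    """Per-sample (predicted class, decision score) for an encoded matrix.

    The matrix must share the model's (scheme, N); its columns are
    restricted to the model's selected feature set, failing loudly on a
    mismatched encoding.
    """
    model._check(matrix)
    sub = (
        matrix
        if matrix.feature_names == model.feature_names
        else matrix.select_columns(model.feature_names)
    )
    return model.svc.predict(sub.values), model.svc.decision_function(sub.values)
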