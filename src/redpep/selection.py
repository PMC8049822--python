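"""Feature ranking by two-group one-way ANOVA and incremental selection.

Each feature is scored by the ratio of between-group to within-group mean
squares (F). Features are then evaluated as growing prefixes of the ranked
list (incremental feature selection, step 1 by default); the optimal prefix
length is the arg-max of cross-validated accuracy, smallest length on ties.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .encoding import FeatureMatrix
from .errors import DegenerateGroupsError, EncodingError
from .model import DEFAULT_SEED, SVMConfig, cv_accuracy, grid_search


@dataclass
class RankedFeatures:
    """Features in descending F order; ties keep original column order."""

    entries: list[tuple[str, float]]
    n_pos: int
    n_neg: int

    @property
    def names(self) -> list[str]:
        return [name for name, _ in self.entries]


@dataclass
class IFSCurve:
    """(k, cv accuracy) points for prefix lengths k = 1, 1+step, ..."""

    points: list[tuple[int, float]]
    optimal_k: int
    optimal_accuracy: float

    def write_tsv(self, path: str | Path) -> None:
        with Path(path).open("w") as fh:
            fh.write("k\taccuracy\n")
            for k, acc in self.points:
                fh.write(f"{k}\t{acc:.6f}\n")


def anova_f_scores(matrix: FeatureMatrix) -> RankedFeatures:
    """Two-group one-way ANOVA F per feature.

    F = MSB / MSW with degrees of freedom (1, n_pos + n_neg - 2).
    A feature with zero within-group variance but distinct group means
    scores +inf (a perfect separator, ranked first); a feature constant
    across all samples scores 0. Both classes must have at least two
    samples.
    """
    y = matrix.labels
    n_pos = int(np.sum(y == 1))
    n_neg = int(np.sum(y == 0))
    if n_pos < 2 or n_neg < 2:
        raise DegenerateGroupsError(
            f"need >=2 samples per class, got {n_pos} positive / "
            f"{n_neg} negative"
        )
    Xp = matrix.values[y == 1]
    Xn = matrix.values[y == 0]
    mp = Xp.mean(axis=0)
    mn = Xn.mean(axis=0)
    grand = matrix.values.mean(axis=0)
    ssb = n_pos * (mp - grand) ** 2 + n_neg * (mn - grand) ** 2
    ssw = ((Xp - mp) ** 2).sum(axis=0) + ((Xn - mn) ** 2).sum(axis=0)
    df_within = n_pos + n_neg - 2
    with np.errstate(divide="ignore", invalid="ignore"):
        f = (ssb / 1.0) / (ssw / df_within)
    f = np.where(ssw == 0, np.where(ssb == 0, 0.0, np.inf), f)
    order = np.argsort(-f, kind="stable")
    entries = [(matrix.feature_names[j], float(f[j])) for j in order]
    return RankedFeatures(entries=entries, n_pos=n_pos, n_neg=n_neg)


def incremental_feature_selection(
    matrix: FeatureMatrix,
    ranking: RankedFeatures,
    grid: list[SVMConfig] | None = None,
    fixed_config: SVMConfig | None = None,
    folds: int = 5,
    seed: int = DEFAULT_SEED,
    step: int = 1,
    max_k: int | None = None,
) -> IFSCurve:
    """Accuracy curve over ranked-feature prefixes.

    For each prefix length k the SVM is evaluated by stratified CV; with
    ``grid`` given, C and gamma are re-tuned per k, otherwise the supplied
    ``fixed_config`` is reused (much faster; the tuning-per-prefix question
    is left to the caller). Returns the full curve and the smallest
    arg-max k.
    """
    if (grid is None) == (fixed_config is None):
        raise ValueError("pass exactly one of grid / fixed_config")
    total = len(matrix.feature_names)
    if len(ranking.entries) != total:
        raise EncodingError(
            f"ranking covers {len(ranking.entries)} features, matrix has {total}"
        )
    if max_k is None:
        max_k = total
    names = ranking.names
    points: list[tuple[int, float]] = []
    ks = list(range(1, max_k + 1, step))
    if ks[-1] != max_k:
        ks.append(max_k)
    for k in ks:
        sub = matrix.select_columns(names[:k])
        if grid is not None:
            _, acc = grid_search(sub, grid, folds=folds, seed=seed)
        else:
            acc = cv_accuracy(sub, fixed_config, folds=folds, seed=seed)
        points.append((k, acc))
    best_k, best_acc = max(points, key=lambda p: (p[1], -p[0]))
    return IFSCurve(points=points, optimal_k=best_k, optimal_accuracy=best_acc)
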