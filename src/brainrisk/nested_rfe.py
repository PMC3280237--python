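"""Nested leave-one-matched-pair-out cross-validation with RFE.

The estimator of generalization accuracy is a 3-way nested scheme.  The outer
loop holds out one matched at-risk/control pair as the test set.  The inner
loop holds out, in turn, each remaining pair as a validation set and runs
recursive feature elimination (RFE) on the rest: at each voxel-count level a
GP classifier is fitted, voxels are ranked by the absolute value of its linear
weight vector, and the ``step`` lowest-ranked voxels are removed.  Validation
accuracy is averaged per level across inner folds; the level with maximal mean
validation accuracy (ties broken toward the larger level) is then used for the
outer fold: RFE is recomputed on all non-test pairs down to that level and the
resulting classifier predicts the held-out pair.  The test pair never enters
training, ranking or level selection.

Everything is deterministic — folds are enumerated in lexicographic pair-id
order and |weight| ties are broken by voxel index.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_io import FeatureDataset
from .gpc import GPConfig, classify, fit_gpc, predict_proba, weight_vector

__all__ = [
    "RFEConfig",
    "RFEPath",
    "FoldResult",
    "CVResult",
    "rfe_levels",
    "rfe_path",
    "rfe_to_target",
    "select_level",
    "run_nested_cv",
    "compute_metrics",
]


@dataclass(frozen=True)
class RFEConfig:
    step: int = 5000          # voxels removed per iteration
    ranking: str = "absolute_weight"
    level_floor: int = 1      # smallest evaluated voxel count

    def __post_init__(self) -> None:
        if self.step < 1:
            raise ValueError("step must be >= 1")
        if self.level_floor < 1:
            raise ValueError("level_floor must be >= 1")
        if self.ranking != "absolute_weight":
            raise ValueError(f"unsupported ranking: {self.ranking!r}")


@dataclass
class RFEPath:
    levels: list                   # strictly decreasing voxel counts
    surviving_voxel_sets: list     # per level, sorted column indices (np arrays)
    weights_per_level: list        # per level, the fitted weight vector


@dataclass
class FoldResult:
    test_pair_id: str
    selected_voxel_count: int
    test_probabilities: np.ndarray   # one per test subject
    predicted_labels: np.ndarray
    true_labels: np.ndarray
    test_subject_ids: np.ndarray = None


@dataclass
class CVResult:
    folds: list
    accuracy: float        # percent
    sensitivity: float     # percent, over at-risk subjects
    specificity: float     # percent, over controls
    mean_selected_voxels: float

    def to_dict(self) -> dict:
        return {
            "accuracy": self.accuracy,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "mean_selected_voxels": self.mean_selected_voxels,
            "folds": [
                {
                    "test_pair_id": str(f.test_pair_id),
                    "selected_voxel_count": int(f.selected_voxel_count),
                    "test_subject_ids": [str(s) for s in f.test_subject_ids],
                    "test_probabilities": [float(p) for p in f.test_probabilities],
                    "predicted_labels": [int(l) for l in f.predicted_labels],
                    "true_labels": [int(l) for l in f.true_labels],
                }
                for f in self.folds
            ],
        }


def rfe_levels(n_voxels: int, config: RFEConfig) -> list:
    """Voxel-count grid: full size, minus multiples of step, then the floor."""
    if n_voxels < 1:
        raise ValueError("need at least one voxel")
    levels = [n_voxels]
    while levels[-1] - config.step > config.level_floor:
        levels.append(levels[-1] - config.step)
    if levels[-1] > config.level_floor:
        levels.append(config.level_floor)
    return levels


def _rank_columns(weights: np.ndarray, columns: np.ndarray) -> np.ndarray:
    """Columns ordered from least to most important (|weight|, then index)."""
    order = np.lexsort((columns, np.abs(weights)))
    return columns[order]


def _iter_rfe(X, y, levels, gp_config):
    """Yield (level, surviving columns, fitted model, weights) along the path."""
    surviving = np.arange(X.shape[1])
    for pos, level in enumerate(levels):
        try:
            model = fit_gpc(X[:, surviving], y, gp_config)
        except Exception as exc:
            raise type(exc)(f"RFE level {level}: {exc}") from exc
        w = weight_vector(model)
        yield level, surviving, model, w
        if pos + 1 < len(levels):
            n_remove = level - levels[pos + 1]
            ranked = _rank_columns(w, surviving)
            surviving = np.sort(ranked[n_remove:])


def rfe_path(X_train, y_train, rfe_config: RFEConfig | None = None,
             gp_config: GPConfig | None = None) -> RFEPath:
    """Run RFE from the full voxel set down to the level floor."""
    rfe_config = rfe_config or RFEConfig()
    gp_config = gp_config or GPConfig()
    X_train = np.asarray(X_train, dtype=float)
    levels = rfe_levels(X_train.shape[1], rfe_config)
    surv, weights = [], []
    for _level, s, _model, w in _iter_rfe(X_train, y_train, levels, gp_config):
        surv.append(s)
        weights.append(w)
    return RFEPath(levels=levels, surviving_voxel_sets=surv, weights_per_level=weights)


def rfe_to_target(X_train, y_train, target: int,
                  rfe_config: RFEConfig | None = None,
                  gp_config: GPConfig | None = None):
    """RFE down to exactly ``target`` voxels (final partial removal allowed).

    Returns (surviving columns, fitted model at the target level).
    """
    rfe_config = rfe_config or RFEConfig()
    gp_config = gp_config or GPConfig()
    X_train = np.asarray(X_train, dtype=float)
    n = X_train.shape[1]
    if not 1 <= target <= n:
        raise ValueError(f"target voxel count {target} outside [1, {n}]")
    levels = [lv for lv in rfe_levels(n, rfe_config) if lv > target]
    levels.append(target)
    last = None
    for level, s, model, w in _iter_rfe(X_train, y_train, levels, gp_config):
        last = (s, model)
    return last


def select_level(validation_accuracy_per_level: dict) -> int:
    """Level with maximal mean validation accuracy; ties go to the largest."""
    if not validation_accuracy_per_level:
        raise ValueError("no levels to select from")
    return max(validation_accuracy_per_level,
               key=lambda lv: (validation_accuracy_per_level[lv], lv))


def compute_metrics(folds) -> tuple:
    """Accuracy, sensitivity and specificity (percent) over all test subjects."""
    if not folds:
        raise ValueError("no folds")
    true = np.concatenate([np.asarray(f.true_labels) for f in folds])
    pred = np.concatenate([np.asarray(f.predicted_labels) for f in folds])
    correct = pred == true
    accuracy = 100.0 * float(np.sum(correct)) / len(true)
    pos = true == 1
    sensitivity = 100.0 * float(np.sum(correct & pos)) / max(int(np.sum(pos)), 1)
    specificity = 100.0 * float(np.sum(correct & ~pos)) / max(int(np.sum(~pos)), 1)
    return accuracy, sensitivity, specificity


def run_nested_cv(dataset: FeatureDataset,
                  rfe_config: RFEConfig | None = None,
                  gp_config: GPConfig | None = None) -> CVResult:
    """Leave-one-pair-out nested cross-validation with per-fold RFE."""
    rfe_config = rfe_config or RFEConfig()
    gp_config = gp_config or GPConfig()
    X, y, pairs = dataset.X, dataset.y.astype(float), dataset.pairs
    pair_ids = dataset.pair_ids  # lexicographic order
    if len(pair_ids) < 3:
        raise ValueError("nested cross-validation needs at least 3 pairs")
    levels = rfe_levels(X.shape[1], rfe_config)
    row_idx = {pid: np.flatnonzero(pairs == pid) for pid in pair_ids}

    folds = []
    for test_pid in pair_ids:
        test_rows = row_idx[test_pid]
        rest_pids = [p for p in pair_ids if p != test_pid]
        rest_rows = np.concatenate([row_idx[p] for p in rest_pids])

        # inner loop: validation accuracy per level, pooled over inner folds
        correct = dict.fromkeys(levels, 0)
        total = dict.fromkeys(levels, 0)
        for val_pid in rest_pids:
            val_rows = row_idx[val_pid]
            train_rows = np.concatenate(
                [row_idx[p] for p in rest_pids if p != val_pid])
            X_tr, y_tr = X[train_rows], y[train_rows]
            X_val, y_val = X[val_rows], y[val_rows]
            try:
                for level, surv, model, _w in _iter_rfe(X_tr, y_tr, levels, gp_config):
                    p = predict_proba(model, X_val[:, surv])
                    correct[level] += int(np.sum(classify(p) == y_val))
                    total[level] += len(y_val)
            except Exception as exc:
                raise type(exc)(
                    f"outer fold {test_pid!r}, inner fold {val_pid!r}: {exc}"
                ) from exc
        mean_acc = {lv: 100.0 * correct[lv] / total[lv] for lv in levels}
        selected = select_level(mean_acc)

        # outer fold: recompute RFE on all non-test pairs down to the
        # selected level, then predict the held-out pair
        X_rest, y_rest = X[rest_rows], y[rest_rows]
        try:
            for level, surv, model, _w in _iter_rfe(X_rest, y_rest, levels, gp_config):
                if level == selected:
                    break
            p_test = predict_proba(model, X[test_rows][:, surv])
        except Exception as exc:
            raise type(exc)(f"outer fold {test_pid!r}: {exc}") from exc
        folds.append(FoldResult(
            test_pair_id=test_pid,
            selected_voxel_count=int(selected),
            test_probabilities=p_test,
            predicted_labels=classify(p_test),
            true_labels=dataset.y[test_rows],
            test_subject_ids=dataset.subject_ids[test_rows],
        ))

    accuracy, sensitivity, specificity = compute_metrics(folds)
    return CVResult(
        folds=folds,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        mean_selected_voxels=float(
            np.mean([f.selected_voxel_count for f in folds])),
    )
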