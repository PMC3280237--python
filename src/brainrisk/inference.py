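"""Significance testing and clinical-outcome scoring.

Three pieces of statistical machinery sit on top of the classifier:

* permutation tests of cross-validated accuracy (the whole nested RFE
  cross-validation is rerun under every relabelling) and of AUC;
* a pooled-variance one-tailed two-sample t-test comparing the predictive
  probabilities of at-risk subjects who later developed a disorder with those
  who stayed healthy;
* an ROC curve over predictive-probability risk scores with trapezoidal AUC
  (equal to the tie-corrected Mann-Whitney pairwise probability).

Permutation randomness is counter-based: permutation ``b`` of a run seeded
with ``seed`` draws from ``numpy.random.default_rng([seed, b])``, so results
are reproducible and independent of evaluation order.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .data_io import FeatureDataset

__all__ = [
    "PermutationConfig",
    "PermutationResult",
    "OutcomeTestResult",
    "ROCResult",
    "permutation_pvalue",
    "permute_labels",
    "ttest_outcome",
    "roc_curve",
    "auc_permutation_pvalue",
]


@dataclass(frozen=True)
class PermutationConfig:
    n_permutations: int = 1000
    seed: int = 0
    scheme: str = "within_pair_flip"       # or "free_relabel"
    comparison: str = "strictly_greater"   # or "greater_or_equal"

    def __post_init__(self) -> None:
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.scheme not in ("within_pair_flip", "free_relabel"):
            raise ValueError(f"unknown scheme: {self.scheme!r}")
        if self.comparison not in ("strictly_greater", "greater_or_equal", "mid_p"):
            raise ValueError(f"unknown comparison: {self.comparison!r}")


@dataclass
class PermutationResult:
    observed_statistic: float
    permuted_statistics: np.ndarray
    p_value: float

    def to_dict(self) -> dict:
        return {
            "observed_statistic": self.observed_statistic,
            "p_value": self.p_value,
            "n_permutations": len(self.permuted_statistics),
            "permuted_statistics": [float(v) for v in self.permuted_statistics],
        }


@dataclass
class OutcomeTestResult:
    t_statistic: float
    degrees_of_freedom: int
    p_value_one_tailed: float
    group_means: tuple  # (developers, non-developers)

    def to_dict(self) -> dict:
        return {
            "t_statistic": self.t_statistic,
            "degrees_of_freedom": self.degrees_of_freedom,
            "p_value_one_tailed": self.p_value_one_tailed,
            "mean_developers": self.group_means[0],
            "mean_non_developers": self.group_means[1],
        }


@dataclass
class ROCResult:
    scores: np.ndarray
    labels: np.ndarray          # 1 = positive (developer), 0 = negative
    points: np.ndarray          # (k, 2) array of (FP rate, TP rate)
    auc: float
    permutation_p_value: float = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "points": [[float(a), float(b)] for a, b in self.points],
            "scores": [float(s) for s in self.scores],
            "labels": [int(l) for l in self.labels],
        }
        if self.permutation_p_value is not None:
            d["permutation_p_value"] = self.permutation_p_value
        return d


def _pvalue(observed: float, permuted: np.ndarray, comparison: str) -> float:
    """The permutation p-value under the configured comparison rule.

    ``strictly_greater`` counts permuted statistics strictly above the
    observed one and divides by the number of permutations; the
    ``greater_or_equal`` alternative counts ties as beating and uses the
    (count + 1) / (N + 1) estimator, which is never anticonservative.
    ``mid_p`` counts ties as half — with a heavily tied (discrete) statistic
    such as accuracy on few subjects, the strict rule is anticonservative and
    the >= rule very conservative, while the mid-p rule keeps the rejection
    rate close to the nominal level.
    """
    permuted = np.asarray(permuted, dtype=float)
    if comparison == "strictly_greater":
        return float(np.sum(permuted > observed)) / len(permuted)
    if comparison == "mid_p":
        gt = float(np.sum(permuted > observed))
        eq = float(np.sum(permuted == observed))
        return (gt + 0.5 * eq) / len(permuted)
    return (float(np.sum(permuted >= observed)) + 1.0) / (len(permuted) + 1.0)


def permute_labels(y: np.ndarray, pairs: np.ndarray, scheme: str,
                   rng: np.random.Generator) -> np.ndarray:
    """One random relabelling of the group labels.

    ``within_pair_flip`` swaps (or not, with probability 1/2) the two labels
    inside each matched pair, respecting the paired exchangeability structure;
    ``free_relabel`` randomly permutes the whole label vector.
    """
    y = np.asarray(y)
    if scheme == "free_relabel":
        return y[rng.permutation(len(y))]
    y_new = y.copy()
    for pid in np.unique(pairs):
        if rng.random() < 0.5:
            rows = np.flatnonzero(pairs == pid)
            y_new[rows] = y_new[rows][::-1]
    return y_new


def permutation_pvalue(dataset: FeatureDataset, pipeline,
                       config: PermutationConfig) -> PermutationResult:
    """Permutation test of a pipeline statistic (e.g. nested-CV accuracy).

    ``pipeline`` maps a FeatureDataset to a scalar statistic and is rerun in
    full for every permuted label vector.
    """
    observed = float(pipeline(dataset))
    permuted = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        rng = np.random.default_rng([config.seed, b])
        y_b = permute_labels(dataset.y, dataset.pairs, config.scheme, rng)
        ds_b = dataclasses.replace(dataset, X=dataset.X, y=y_b)
        try:
            permuted[b] = float(pipeline(ds_b))
        except Exception as exc:
            raise type(exc)(f"permutation {b}: {exc}") from exc
    return PermutationResult(
        observed_statistic=observed,
        permuted_statistics=permuted,
        p_value=_pvalue(observed, permuted, config.comparison),
    )


def ttest_outcome(probs_developers, probs_nondevelopers) -> OutcomeTestResult:
    """Pooled-variance two-sample t-test, one-tailed for "developers higher".

    Degrees of freedom are n1 + n2 - 2.
    """
    a = np.asarray(probs_developers, dtype=float)
    b = np.asarray(probs_nondevelopers, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each outcome group needs at least 2 values")
    n1, n2 = len(a), len(b)
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(a, ddof=1) + (n2 - 1) * np.var(b, ddof=1)) / df
    if sp2 <= 0:
        raise ValueError("zero pooled variance: t statistic is undefined")
    t = (a.mean() - b.mean()) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    p = float(stats.t.sf(t, df))
    return OutcomeTestResult(
        t_statistic=float(t),
        degrees_of_freedom=int(df),
        p_value_one_tailed=p,
        group_means=(float(a.mean()), float(b.mean())),
    )


def roc_curve(scores, labels) -> ROCResult:
    """ROC curve and trapezoidal AUC, sweeping thresholds over unique scores.

    Labels are binary with 1 = positive (developer).  Tied scores contribute
    half, so the AUC equals the Mann-Whitney pairwise probability.
    """
    scores = np.asarray(scores, dtype=float).ravel()
    labels = np.asarray(labels).ravel().astype(int)
    if len(scores) != len(labels):
        raise ValueError("scores and labels must have equal length")
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both outcome classes must be present")

    points = [(0.0, 0.0)]
    for thr in np.unique(scores)[::-1]:  # descending thresholds
        pred_pos = scores >= thr
        tp = int(np.sum(pred_pos & (labels == 1)))
        fp = int(np.sum(pred_pos & (labels == 0)))
        points.append((fp / n_neg, tp / n_pos))
    if points[-1] != (1.0, 1.0):
        points.append((1.0, 1.0))
    pts = np.array(points)
    auc = float(np.trapezoid(pts[:, 1], pts[:, 0]))
    return ROCResult(scores=scores, labels=labels, points=pts, auc=auc)


def auc_permutation_pvalue(scores, labels,
                           config: PermutationConfig) -> PermutationResult:
    """Permutation test of the AUC under free relabelling of outcomes."""
    observed = roc_curve(scores, labels).auc
    labels = np.asarray(labels).ravel().astype(int)
    permuted = np.empty(config.n_permutations)
    for b in range(config.n_permutations):
        rng = np.random.default_rng([config.seed, b])
        permuted[b] = roc_curve(scores, labels[rng.permutation(len(labels))]).auc
    return PermutationResult(
        observed_statistic=float(observed),
        permuted_statistics=permuted,
        p_value=_pvalue(observed, permuted, config.comparison),
    )
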