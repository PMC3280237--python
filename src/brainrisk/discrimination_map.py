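"""Whole-group discrimination weight map.

After cross-validation, a single map is produced by training the classifier on
ALL subjects and eliminating voxels until the rounded mean of the per-fold
selected voxel counts remains.  The map holds the raw linear-kernel weights of
that final model — positive where a voxel pushes the decision toward the
at-risk class, negative toward controls, exactly zero on eliminated voxels.
It is a representation of the decision boundary, not a statistical map, and is
deliberately left unthresholded.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .data_io import FeatureDataset, write_weight_map
from .gpc import GPConfig, weight_vector
from .nested_rfe import CVResult, RFEConfig, rfe_to_target

__all__ = ["MapSpec", "mean_selected_voxels", "build_map"]


@dataclass(frozen=True)
class MapSpec:
    target_voxel_count: int
    rfe_config: RFEConfig = RFEConfig()
    gp_config: GPConfig = GPConfig()

    def __post_init__(self) -> None:
        if self.target_voxel_count < 1:
            raise ValueError("target_voxel_count must be >= 1")


def mean_selected_voxels(cv_result: CVResult) -> int:
    """Rounded (half-up) mean of the per-fold selected voxel counts."""
    if not cv_result.folds:
        raise ValueError("cross-validation result has no folds")
    m = float(np.mean([f.selected_voxel_count for f in cv_result.folds]))
    return int(math.floor(m + 0.5))


def build_map(dataset: FeatureDataset, spec: MapSpec, out_path=None) -> np.ndarray:
    """Weight map from a whole-group fit at ``spec.target_voxel_count`` voxels.

    Returns the full-length per-voxel weight vector (zeros on eliminated
    voxels); if ``out_path`` is given the map is also written as NIfTI.
    """
    n_voxels = dataset.X.shape[1]
    if spec.target_voxel_count > n_voxels:
        raise ValueError(
            f"target voxel count {spec.target_voxel_count} exceeds the mask "
            f"size {n_voxels}"
        )
    surviving, model = rfe_to_target(
        dataset.X, dataset.y.astype(float), spec.target_voxel_count,
        spec.rfe_config, spec.gp_config,
    )
    weights = np.zeros(n_voxels)
    weights[surviving] = weight_vector(model)
    if out_path is not None:
        write_weight_map(weights, dataset.mask, out_path)
    return weights
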