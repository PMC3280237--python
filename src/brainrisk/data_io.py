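"""Reading beta images, masks and subject metadata; writing weight maps.

Conventions fixed here and relied on everywhere else:

* voxel ordering is row-major (C order) over the 3-D grid — the column order
  of every feature matrix is a pure function of the mask;
* labels are +1 for the at-risk group and -1 for controls;
* voxel indices are 0-based; world coordinates live only in the affine;
* images are never resampled — grids must match exactly and affines must
  agree elementwise within ``AFFINE_TOL``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "AFFINE_TOL",
    "GROUP_AT_RISK",
    "GROUP_CONTROL",
    "OUTCOMES",
    "SubjectRecord",
    "BrainMask",
    "FeatureDataset",
    "read_metadata",
    "load_features",
    "write_weight_map",
]

AFFINE_TOL = 1e-4
GROUP_AT_RISK = "at_risk"
GROUP_CONTROL = "control"
GROUPS = (GROUP_AT_RISK, GROUP_CONTROL)
OUTCOMES = ("developer", "non_developer", "unknown")
PATH_COLUMN_PREFIX = "path_"


@dataclass(frozen=True)
class SubjectRecord:
    subject_id: str
    pair_id: str
    group: str
    outcome: str = "unknown"
    image_paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown group {self.group!r} "
                f"(expected one of {GROUPS})"
            )
        if self.outcome not in OUTCOMES:
            raise ValueError(
                f"subject {self.subject_id!r}: unknown outcome {self.outcome!r}"
            )
        if self.group == GROUP_CONTROL and self.outcome != "unknown":
            raise ValueError(
                f"subject {self.subject_id!r} is a control but has outcome "
                f"{self.outcome!r}; follow-up outcomes apply to at-risk subjects only"
            )


@dataclass(frozen=True)
class BrainMask:
    """A binary mask on a fixed grid.

    ``voxel_indices`` is a (V, 3) integer array in row-major grid order; it
    defines the column order of every feature matrix built with this mask.
    """

    grid_shape: tuple
    affine: np.ndarray
    voxel_indices: np.ndarray

    @classmethod
    def from_array(cls, mask_array: np.ndarray, affine: np.ndarray) -> "BrainMask":
        mask_array = np.asarray(mask_array)
        if mask_array.ndim != 3:
            raise ValueError(f"mask must be 3-D, got shape {mask_array.shape}")
        idx = np.argwhere(mask_array != 0)  # argwhere is row-major ordered
        if len(idx) == 0:
            raise ValueError("empty mask: no nonzero voxels")
        return cls(
            grid_shape=tuple(int(s) for s in mask_array.shape),
            affine=np.asarray(affine, dtype=float),
            voxel_indices=np.ascontiguousarray(idx),
        )

    @classmethod
    def from_image(cls, path) -> "BrainMask":
        img = nib.load(str(path))
        return cls.from_array(np.asanyarray(img.dataobj), img.affine)

    @property
    def n_voxels(self) -> int:
        return self.voxel_indices.shape[0]

    def index_tuple(self):
        """Tuple of index arrays suitable for fancy indexing into the grid."""
        return tuple(self.voxel_indices.T)


@dataclass
class FeatureDataset:
    """Subject-by-voxel matrix with group labels and matched-pair structure."""

    X: np.ndarray           # (n_subjects, n_voxels) float64
    y: np.ndarray           # (n_subjects,) in {+1 (at_risk), -1 (control)}
    pairs: np.ndarray       # (n_subjects,) pair ids, aligned with rows
    mask: BrainMask
    condition: str
    subject_ids: np.ndarray = None

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=np.float64)
        self.y = np.asarray(self.y, dtype=int)
        self.pairs = np.asarray(self.pairs)
        if self.subject_ids is None:
            self.subject_ids = np.array([f"s{i}" for i in range(len(self.y))])
        else:
            self.subject_ids = np.asarray(self.subject_ids)
        n, v = self.X.shape
        if len(self.y) != n or len(self.pairs) != n or len(self.subject_ids) != n:
            raise ValueError("rows of X, y, pairs and subject_ids must align")
        if v != self.mask.n_voxels:
            raise ValueError(
                f"X has {v} columns but the mask has {self.mask.n_voxels} voxels"
            )
        if not np.all(np.isfinite(self.X)):
            raise ValueError("feature matrix contains non-finite values")
        if not np.all(np.isin(self.y, (-1, 1))):
            raise ValueError("labels must be +1 or -1")
        if int(np.sum(self.y == 1)) != int(np.sum(self.y == -1)):
            raise ValueError("groups must be balanced (equal +1 and -1 counts)")

    @property
    def n_subjects(self) -> int:
        return self.X.shape[0]

    @property
    def pair_ids(self) -> np.ndarray:
        """Distinct pair ids in deterministic (lexicographic) order."""
        return np.unique(self.pairs)


def read_metadata(path) -> list:
    """Read the subject metadata CSV into validated SubjectRecords.

    Expected header: ``subject_id, pair_id, group[, outcome]`` plus one
    ``path_<condition>`` column per condition.  Row order is preserved.
    Relative image paths are resolved against the CSV's directory.
    """
    base = Path(path).parent
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = ("subject_id", "pair_id", "group")
    for col in required:
        if col not in df.columns:
            raise ValueError(f"metadata is missing required column {col!r}")
    path_cols = [c for c in df.columns if c.startswith(PATH_COLUMN_PREFIX)]

    records = []
    for i, row in df.iterrows():
        outcome = row.get("outcome", "") or "unknown"
        try:
            rec = SubjectRecord(
                subject_id=row["subject_id"],
                pair_id=row["pair_id"],
                group=row["group"],
                outcome=outcome,
                image_paths={
                    c[len(PATH_COLUMN_PREFIX):]:
                        row[c] if Path(row[c]).is_absolute() else str(base / row[c])
                    for c in path_cols
                },
            )
        except ValueError as exc:
            raise ValueError(f"metadata row {i}: {exc}") from exc
        records.append(rec)

    ids = [r.subject_id for r in records]
    dup = {s for s in ids if ids.count(s) > 1}
    if dup:
        raise ValueError(f"duplicate subject ids: {sorted(dup)}")
    by_pair = {}
    for r in records:
        by_pair.setdefault(r.pair_id, []).append(r)
    for pid, members in sorted(by_pair.items()):
        if len(members) != 2:
            raise ValueError(
                f"pair {pid!r} has {len(members)} subjects; each pair id must "
                f"occur exactly twice"
            )
        groups = sorted(m.group for m in members)
        if groups != sorted(GROUPS):
            raise ValueError(
                f"pair {pid!r} does not contain one at-risk subject and one "
                f"control (got groups {groups})"
            )
    return records


def load_features(records, mask, condition: str) -> FeatureDataset:
    """Assemble the subject-by-voxel matrix for one condition.

    ``mask`` may be a BrainMask or a path to a mask image.  All images must
    share the mask's grid and affine.
    """
    if not isinstance(mask, BrainMask):
        mask = BrainMask.from_image(mask)
    idx = mask.index_tuple()
    rows = []
    for rec in records:
        if condition not in rec.image_paths:
            raise ValueError(
                f"subject {rec.subject_id!r} has no image for condition {condition!r}"
            )
        fpath = rec.image_paths[condition]
        if not Path(fpath).exists():
            raise FileNotFoundError(
                f"subject {rec.subject_id!r}: image file not found: {fpath}"
            )
        img = nib.load(str(fpath))
        if tuple(img.shape) != mask.grid_shape:
            raise ValueError(
                f"subject {rec.subject_id!r}: image grid {tuple(img.shape)} does "
                f"not match mask grid {mask.grid_shape} ({fpath})"
            )
        if not np.allclose(img.affine, mask.affine, atol=AFFINE_TOL, rtol=0):
            raise ValueError(
                f"subject {rec.subject_id!r}: image affine differs from the mask "
                f"affine by more than {AFFINE_TOL} ({fpath})"
            )
        data = np.asarray(img.get_fdata(dtype=np.float64))
        vals = data[idx]
        if not np.all(np.isfinite(vals)):
            raise ValueError(
                f"subject {rec.subject_id!r}: non-finite beta values inside the "
                f"mask ({fpath})"
            )
        rows.append(vals)
    X = np.vstack(rows)
    y = np.array([1 if r.group == GROUP_AT_RISK else -1 for r in records])
    return FeatureDataset(
        X=X,
        y=y,
        pairs=np.array([r.pair_id for r in records]),
        mask=mask,
        condition=condition,
        subject_ids=np.array([r.subject_id for r in records]),
    )


def write_weight_map(weights, mask: BrainMask, out_path) -> Path:
    """Write a per-voxel weight vector as a NIfTI image on the mask grid.

    Out-of-mask voxels are exactly zero.  Data are stored as float64 so that
    a round trip reproduces the weights to full precision.
    """
    weights = np.asarray(weights, dtype=np.float64).ravel()
    if len(weights) != mask.n_voxels:
        raise ValueError(
            f"weight vector has length {len(weights)} but the mask has "
            f"{mask.n_voxels} voxels"
        )
    vol = np.zeros(mask.grid_shape, dtype=np.float64)
    vol[mask.index_tuple()] = weights
    img = nib.Nifti1Image(vol, mask.affine)
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    nib.save(img, str(out_path))
    return out_path
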