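"""Synthetic paired-group beta-image datasets.

The generator emulates the statistical structure the analysis pipeline
assumes: matched at-risk/control pairs, per-subject beta images with a shared
baseline offset, spatially correlated Gaussian noise (white noise smoothed
with a Gaussian kernel and rescaled to a target standard deviation), and a
spatially clustered multivariate group difference planted in one condition
only.  Each at-risk subject carries the group effect scaled by a private
positive amplitude (lognormal, sigma = 0.25), so risk scores vary within the
at-risk group; follow-up "developer" labels are drawn with probability
logistic in the standardized log-amplitude, with the intercept calibrated so
the expected developer fraction among followed subjects equals
``outcome_fraction``.

With ``effect_size = 0`` group labels are exchangeable by construction, which
is the property permutation-test calibration rests on.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass
from pathlib import Path

import nibabel as nib
import numpy as np
from numpy.polynomial.hermite_e import hermegauss
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq
from scipy.special import expit

from .data_io import (
    GROUP_AT_RISK,
    GROUP_CONTROL,
    BrainMask,
    FeatureDataset,
    SubjectRecord,
)

__all__ = ["SyntheticSpec", "SyntheticDataset", "simulate", "generate_dataset", "presets"]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))
_LOG_AMP_SIGMA = 0.25


@dataclass(frozen=True)
class SyntheticSpec:
    """Full parameterization of one synthetic paired-group dataset."""

    n_pairs: int = 16
    grid_shape: tuple = (12, 12, 12)
    conditions: tuple = ("neutral", "mild", "intense")
    signal_condition: str = "neutral"
    cluster_center: tuple = (6, 6, 6)
    cluster_radius: float = 2.3
    effect_size: float = 1.5        # group mean shift on signal voxels, in noise SDs
    noise_sd: float = 1.0
    smoothing_fwhm: float = 2.0     # voxels; 0 disables spatial correlation
    subject_offset_sd: float = 0.5  # shared per-subject baseline
    outcome_fraction: float = 6.0 / 13.0  # expected developer fraction (followed)
    followup_fraction: float = 1.0  # fraction of at-risk subjects with follow-up
    outcome_coupling: float = 0.0   # logistic slope on standardized log-amplitude
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_pairs < 1:
            raise ValueError("n_pairs must be >= 1")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        if not 0.0 <= self.outcome_fraction <= 1.0:
            raise ValueError("outcome_fraction must lie in [0, 1]")
        if not 0.0 <= self.followup_fraction <= 1.0:
            raise ValueError("followup_fraction must lie in [0, 1]")
        if self.outcome_coupling < 0:
            raise ValueError("outcome_coupling must be >= 0")
        if self.signal_condition not in self.conditions:
            raise ValueError(
                f"signal_condition {self.signal_condition!r} not in conditions")
        for c, s in zip(self.cluster_center, self.grid_shape):
            if not 0 <= c < s:
                raise ValueError(
                    f"cluster center {self.cluster_center} outside grid "
                    f"{self.grid_shape}")

    def cluster_voxel_indices(self) -> np.ndarray:
        """(k, 3) indices of the planted cluster (row-major order)."""
        grids = np.indices(self.grid_shape)
        d2 = sum((g - c) ** 2 for g, c in zip(grids, self.cluster_center))
        return np.argwhere(d2 <= self.cluster_radius ** 2)


@dataclass
class SyntheticDataset:
    spec: SyntheticSpec
    records: list                 # SubjectRecord per row
    mask: BrainMask
    datasets: dict                # condition -> FeatureDataset
    amplitudes: dict              # at-risk subject id -> signal amplitude
    cluster_columns: np.ndarray   # mask-column indices of planted voxels


def _smoothing_norm(grid_shape, sigma) -> float:
    """L2 norm of the smoothing kernel, so filtered white noise has unit SD."""
    norm2 = 1.0
    for _ in grid_shape:
        n = max(int(np.ceil(8 * sigma)) * 2 + 17, 33)
        delta = np.zeros(n)
        delta[n // 2] = 1.0
        g = gaussian_filter(delta, sigma, mode="constant")
        norm2 *= float(np.sum(g * g))
    return float(np.sqrt(norm2))


def _calibrate_intercept(coupling: float, target: float) -> float:
    """Intercept a with E[expit(a + coupling * Z)] = target, Z ~ N(0, 1)."""
    if target <= 0.0:
        return -np.inf
    if target >= 1.0:
        return np.inf
    nodes, weights = hermegauss(61)
    weights = weights / weights.sum()

    def mean_prob(a):
        return float(weights @ expit(a + coupling * nodes)) - target

    return brentq(mean_prob, -60.0, 60.0, xtol=1e-12)


def simulate(spec: SyntheticSpec) -> SyntheticDataset:
    """Generate one dataset in memory, fully reproducible from ``spec.seed``."""
    rng = np.random.default_rng(spec.seed)
    n = spec.n_pairs
    mask_arr = np.ones(spec.grid_shape, dtype=np.uint8)
    affine = np.diag([3.0, 3.0, 3.0, 1.0])  # 3 mm isotropic desk-scale grid
    mask = BrainMask.from_array(mask_arr, affine)

    cluster_idx = spec.cluster_voxel_indices()
    flat_cluster = np.ravel_multi_index(tuple(cluster_idx.T), spec.grid_shape)
    flat_mask = np.ravel_multi_index(tuple(mask.voxel_indices.T), spec.grid_shape)
    cluster_cols = np.flatnonzero(np.isin(flat_mask, flat_cluster))

    # deterministic draw order: offsets, amplitudes, followup, developer, noise
    offsets = rng.normal(0.0, spec.subject_offset_sd, size=2 * n)
    amplitudes = np.exp(rng.normal(0.0, _LOG_AMP_SIGMA, size=n))

    n_follow = int(round(spec.followup_fraction * n))
    followed = np.sort(rng.choice(n, size=n_follow, replace=False))
    intercept = _calibrate_intercept(spec.outcome_coupling, spec.outcome_fraction)
    z_amp = np.log(amplitudes) / _LOG_AMP_SIGMA
    p_dev = expit(intercept + spec.outcome_coupling * z_amp)
    dev_draw = rng.random(n) < p_dev

    sigma = spec.smoothing_fwhm * _FWHM_TO_SIGMA
    norm = _smoothing_norm(spec.grid_shape, sigma) if sigma > 0 else 1.0
    cond_baseline = {c: 0.25 * k for k, c in enumerate(spec.conditions)}

    records = []
    volumes = {c: [] for c in spec.conditions}
    for i in range(n):
        for j, group in enumerate((GROUP_AT_RISK, GROUP_CONTROL)):
            subj = 2 * i + j
            sid = f"s{i:02d}{'r' if group == GROUP_AT_RISK else 'c'}"
            if group == GROUP_AT_RISK:
                outcome = "unknown"
                if i in followed:
                    outcome = "developer" if dev_draw[i] else "non_developer"
            else:
                outcome = "unknown"
            records.append(SubjectRecord(
                subject_id=sid, pair_id=f"p{i:02d}", group=group, outcome=outcome))
            for cond in spec.conditions:
                white = rng.standard_normal(spec.grid_shape)
                if sigma > 0:
                    noise = gaussian_filter(white, sigma, mode="constant") / norm
                else:
                    noise = white
                vol = offsets[subj] + cond_baseline[cond] + spec.noise_sd * noise
                if group == GROUP_AT_RISK and cond == spec.signal_condition:
                    vol.flat[flat_cluster] += (
                        spec.effect_size * spec.noise_sd * amplitudes[i])
                volumes[cond].append(vol)

    idx = mask.index_tuple()
    y = np.array([1 if r.group == GROUP_AT_RISK else -1 for r in records])
    pairs = np.array([r.pair_id for r in records])
    sids = np.array([r.subject_id for r in records])
    datasets = {
        cond: FeatureDataset(
            X=np.vstack([v[idx] for v in volumes[cond]]),
            y=y, pairs=pairs, mask=mask, condition=cond, subject_ids=sids)
        for cond in spec.conditions
    }
    amp_by_sid = {f"s{i:02d}r": float(amplitudes[i]) for i in range(n)}
    return SyntheticDataset(
        spec=spec, records=records, mask=mask, datasets=datasets,
        amplitudes=amp_by_sid, cluster_columns=cluster_cols,
    )


def generate_dataset(spec: SyntheticSpec, out_dir) -> SyntheticDataset:
    """Generate a dataset and write it to disk as NIfTI + CSV.

    Writes ``mask.nii.gz``, one ``beta_<subject>_<condition>.nii.gz`` per
    subject and condition, ``metadata.csv`` and a ``manifest.json`` recording
    the spec.  Returns the in-memory dataset with records pointing at the
    written files.  Identical specs produce byte-identical files.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    data = simulate(spec)

    mask_img = nib.Nifti1Image(
        np.ones(spec.grid_shape, dtype=np.uint8), data.mask.affine)
    nib.save(mask_img, str(out_dir / "mask.nii.gz"))

    idx = data.mask.index_tuple()
    new_records = []
    rows = []
    for row, rec in enumerate(data.records):
        abs_paths, rel_paths = {}, {}
        for cond in spec.conditions:
            vol = np.zeros(spec.grid_shape)
            vol[idx] = data.datasets[cond].X[row]
            fname = f"beta_{rec.subject_id}_{cond}.nii.gz"
            nib.save(nib.Nifti1Image(vol, data.mask.affine), str(out_dir / fname))
            abs_paths[cond] = str(out_dir / fname)
            rel_paths[cond] = fname  # CSV holds paths relative to itself
        new_records.append(dataclasses.replace(rec, image_paths=abs_paths))
        rows.append({
            "subject_id": rec.subject_id, "pair_id": rec.pair_id,
            "group": rec.group, "outcome": rec.outcome,
            **{f"path_{c}": p for c, p in rel_paths.items()},
        })

    import pandas as pd
    pd.DataFrame(rows).to_csv(out_dir / "metadata.csv", index=False)
    manifest = {"spec": {**dataclasses.asdict(spec)}, "format_version": 1}
    # tuples -> lists for JSON stability
    (out_dir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=list, sort_keys=True))
    data.records = new_records
    return data


def presets() -> dict:
    """Named generator settings with fixed seeds.

    * ``null`` — no group effect anywhere: exchangeable labels for
      calibration studies (8 pairs, 500 voxels).
    * ``easy`` — a strong, weakly-noisy planted cluster (~57 voxels among
      2000) for signal-recovery checks, with outcome strongly coupled to the
      signal amplitude.
    * ``paperlike`` — study-scale geometry: 16 matched pairs, three task
      conditions with the group difference in the neutral condition only, and
      follow-up outcomes for 13 of 16 at-risk subjects with an expected
      6/13 developer fraction.
    """
    return {
        "null": SyntheticSpec(
            n_pairs=8, grid_shape=(10, 10, 5), conditions=("neutral",),
            signal_condition="neutral", cluster_center=(5, 5, 2),
            cluster_radius=1.5, effect_size=0.0, noise_sd=1.0,
            smoothing_fwhm=1.5, subject_offset_sd=0.5,
            outcome_fraction=0.5, followup_fraction=1.0,
            outcome_coupling=0.0, seed=101,
        ),
        "easy": SyntheticSpec(
            n_pairs=8, grid_shape=(20, 10, 10), conditions=("neutral",),
            signal_condition="neutral", cluster_center=(10, 5, 5),
            cluster_radius=2.3, effect_size=3.0, noise_sd=1.0,
            smoothing_fwhm=1.5, subject_offset_sd=0.5,
            outcome_fraction=0.5, followup_fraction=1.0,
            outcome_coupling=3.0, seed=7,
        ),
        "paperlike": SyntheticSpec(
            n_pairs=16, grid_shape=(12, 12, 12),
            conditions=("neutral", "mild", "intense"),
            signal_condition="neutral", cluster_center=(6, 6, 6),
            cluster_radius=2.3, effect_size=1.5, noise_sd=1.0,
            smoothing_fwhm=2.0, subject_offset_sd=0.5,
            outcome_fraction=6.0 / 13.0, followup_fraction=13.0 / 16.0,
            outcome_coupling=2.0, seed=11,
        ),
    }
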