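"""Lesion feature extraction: overlap patient masks with template regions.

Produces the binary V x N (voxels x patients) matrix decoded per region, and
applies the lesion-coverage inclusion rule: a region is analyzed only if at
least ``min_patients`` patients each have strictly more than ``min_voxels``
lesioned voxels inside it.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import LesionCohort, Region, VoxelTemplate, check_grids_match

__all__ = [
    "ConnectionFeatureMatrix",
    "CoverageResult",
    "extract_features",
    "coverage_filter",
    "intersect_mask",
    "subset_cohort",
]


@dataclass(frozen=True)
class ConnectionFeatureMatrix:
    """Binary voxels x patients lesion matrix for one region (1 = lesioned)."""

    region: str
    voxel_indices: np.ndarray  # (V,) flat indices, template order
    patient_ids: list[str]     # (N,) cohort order
    values: np.ndarray         # (V, N) uint8

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.shape != (len(self.voxel_indices), len(self.patient_ids)):
            raise ValueError("feature matrix shape mismatch")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("feature matrix must be binary")
        object.__setattr__(self, "values", vals.astype(np.uint8))

    @property
    def n_voxels(self) -> int:
        return len(self.voxel_indices)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def lesioned_voxels_per_patient(self) -> np.ndarray:
        return self.values.sum(axis=0).astype(int)


def extract_features(template: VoxelTemplate, cohort: LesionCohort,
                     region: str) -> ConnectionFeatureMatrix:
    """Restrict every patient's mask to one region's voxels (template voxel
    order, cohort patient order)."""
    check_grids_match(template.grid, cohort.grid)
    if region not in template.regions:
        raise KeyError(f"unknown region {region!r}")
    vox = template.regions[region].voxels
    values = np.zeros((len(vox), cohort.n_patients), dtype=np.uint8)
    for p, pid in enumerate(cohort.patient_ids):
        values[:, p] = np.isin(vox, cohort.masks[pid], assume_unique=True)
    return ConnectionFeatureMatrix(region, vox, cohort.patient_ids, values)


@dataclass(frozen=True)
class CoverageResult:
    kept: list[str]
    dropped: list[str]
    qualifying_patients: dict[str, int]

    def report(self) -> pd.DataFrame:
        rows = [{"region": r, "qualifying_patients": self.qualifying_patients[r],
                 "kept": r in self.kept}
                for r in list(self.kept) + list(self.dropped)]
        return pd.DataFrame(rows).sort_values("region").reset_index(drop=True)


def coverage_filter(features: list[ConnectionFeatureMatrix],
                    min_patients: int = 5, min_voxels: int = 20) -> CoverageResult:
    """Keep regions with >= ``min_patients`` patients each having strictly more
    than ``min_voxels`` lesioned voxels in the region."""
    kept, dropped, counts = [], [], {}
    for f in features:
        qualifying = int((f.lesioned_voxels_per_patient() > min_voxels).sum())
        counts[f.region] = qualifying
        (kept if qualifying >= min_patients else dropped).append(f.region)
    return CoverageResult(kept=kept, dropped=dropped, qualifying_patients=counts)


def intersect_mask(template: VoxelTemplate, region: str,
                   mask: np.ndarray) -> VoxelTemplate:
    """Restrict a region's voxel set to a binary volume mask (e.g. a
    segmentation-derived white-matter mask). An empty result is allowed but
    flagged with a warning."""
    if region not in template.regions:
        raise KeyError(f"unknown region {region!r}")
    mask = np.asarray(mask)
    if mask.shape != template.grid.shape:
        raise ValueError(
            f"mask shape {mask.shape} does not match grid {template.grid.shape}")
    mask_idx = template.grid.indices_from_volume(mask != 0)
    old = template.regions[region]
    new_vox = np.intersect1d(old.voxels, mask_idx, assume_unique=True)
    if new_vox.size == 0:
        warnings.warn(f"region {region!r} is empty after mask intersection",
                      stacklevel=2)
    return template.with_region(region, Region(kind=old.kind, voxels=new_vox))


def subset_cohort(cohort: LesionCohort, predicate) -> LesionCohort:
    """Keep patients for which ``predicate(metadata row)`` is true, preserving order."""
    keep = [bool(predicate(row)) for _, row in cohort.patients.iterrows()]
    if not any(keep):
        raise ValueError("subset predicate excluded every patient")
    patients = cohort.patients[keep].reset_index(drop=True)
    masks = {pid: cohort.masks[pid] for pid in patients["patient_id"]}
    return LesionCohort(grid=cohort.grid, patients=patients, masks=masks)
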