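"""Spatial containers: the voxel grid, the labeled template, lesion cohorts,
and the patients x items naming matrix.

Voxel sets are stored as 0-based flat indices in x-fastest (Fortran) order on
the template grid; this convention is recorded in every sidecar so that masks
written to NIfTI and masks held in memory agree voxel for voxel.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GridSpec",
    "Region",
    "VoxelTemplate",
    "LesionCohort",
    "NamingMatrix",
    "grids_match",
    "check_grids_match",
]

#: flat-index memory order used everywhere (x varies fastest)
INDEX_ORDER = "F"


@dataclass(frozen=True)
class GridSpec:
    """A fixed 3-D voxel grid with a voxel-to-mm affine."""

    shape: tuple[int, int, int]
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self):
        shape = tuple(int(s) for s in self.shape)
        if len(shape) != 3 or any(s < 1 for s in shape):
            raise ValueError(f"grid shape must be 3 positive extents, got {self.shape}")
        affine = np.asarray(self.affine, dtype=float)
        if affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        if abs(np.linalg.det(affine)) < 1e-12:
            raise ValueError("affine must be invertible")
        object.__setattr__(self, "shape", shape)
        object.__setattr__(self, "affine", affine)

    @property
    def n_voxels(self) -> int:
        return int(np.prod(self.shape))

    def ravel(self, ijk: np.ndarray) -> np.ndarray:
        """(n,3) voxel coordinates -> flat indices (x-fastest)."""
        ijk = np.asarray(ijk)
        return np.ravel_multi_index((ijk[..., 0], ijk[..., 1], ijk[..., 2]),
                                    self.shape, order=INDEX_ORDER)

    def unravel(self, flat: np.ndarray) -> np.ndarray:
        """flat indices -> (n,3) voxel coordinates."""
        i, j, k = np.unravel_index(np.asarray(flat), self.shape, order=INDEX_ORDER)
        return np.stack([i, j, k], axis=-1)

    def volume_from_indices(self, flat: np.ndarray, dtype=np.uint8) -> np.ndarray:
        vol = np.zeros(self.n_voxels, dtype=dtype)
        vol[np.asarray(flat, dtype=np.int64)] = 1
        return vol.reshape(self.shape, order=INDEX_ORDER)

    def indices_from_volume(self, vol: np.ndarray) -> np.ndarray:
        if vol.shape != self.shape:
            raise ValueError(f"volume shape {vol.shape} != grid shape {self.shape}")
        flat = vol.reshape(-1, order=INDEX_ORDER)
        return np.flatnonzero(flat)


def grids_match(a: GridSpec, b: GridSpec, atol: float = 1e-6) -> bool:
    return a.shape == b.shape and np.allclose(a.affine, b.affine, atol=atol)


def check_grids_match(a: GridSpec, b: GridSpec, atol: float = 1e-6) -> None:
    if not grids_match(a, b, atol=atol):
        raise ValueError(
            "grid mismatch: shapes "
            f"{a.shape} vs {b.shape}; affines\n{a.affine}\nvs\n{b.affine}"
        )


@dataclass(frozen=True)
class Region:
    """A named voxel set (white-matter connection or gray-matter node)."""

    kind: str  # "connection" | "gm_node"
    voxels: np.ndarray  # sorted unique flat indices

    def __post_init__(self):
        vox = np.unique(np.asarray(self.voxels, dtype=np.int64))
        if len(vox) != len(self.voxels):
            raise ValueError("region voxel indices must be unique")
        object.__setattr__(self, "voxels", vox)

    @property
    def n_voxels(self) -> int:
        return len(self.voxels)


@dataclass(frozen=True)
class VoxelTemplate:
    """Named voxel sets on a fixed grid; the spatial reference for all overlaps."""

    grid: GridSpec
    regions: dict[str, Region]

    def __post_init__(self):
        n = self.grid.n_voxels
        for name, reg in self.regions.items():
            if reg.n_voxels and (reg.voxels.min() < 0 or reg.voxels.max() >= n):
                raise ValueError(f"region {name!r} has voxel indices outside the grid")

    @property
    def names(self) -> list[str]:
        return list(self.regions)

    def __getitem__(self, name: str) -> Region:
        return self.regions[name]

    def with_region(self, name: str, region: Region) -> "VoxelTemplate":
        regions = dict(self.regions)
        regions[name] = region
        return dataclasses.replace(self, regions=regions)

    def label_volume(self) -> tuple[np.ndarray, pd.DataFrame]:
        """Integer label volume plus the (name, label, kind) region table."""
        vol = np.zeros(self.grid.n_voxels, dtype=np.int32)
        rows = []
        for label, (name, reg) in enumerate(self.regions.items(), start=1):
            vol[reg.voxels] = label
            rows.append({"name": name, "label": label, "kind": reg.kind})
        return (vol.reshape(self.grid.shape, order=INDEX_ORDER),
                pd.DataFrame(rows, columns=["name", "label", "kind"]))


@dataclass(frozen=True)
class LesionCohort:
    """Per-patient binary lesion masks on the template grid plus metadata."""

    grid: GridSpec
    patients: pd.DataFrame  # columns: patient_id, etiology, hemisphere
    masks: dict[str, np.ndarray]  # patient_id -> sorted flat lesioned-voxel indices

    def __post_init__(self):
        ids = list(self.patients["patient_id"])
        if set(ids) != set(self.masks):
            raise ValueError("cohort manifest and masks disagree on patient ids")
        n = self.grid.n_voxels
        masks = {}
        for pid in ids:
            m = np.unique(np.asarray(self.masks[pid], dtype=np.int64))
            if m.size and (m.min() < 0 or m.max() >= n):
                raise ValueError(f"mask of patient {pid!r} falls outside the grid")
            masks[pid] = m
        object.__setattr__(self, "masks", masks)
        object.__setattr__(self, "patients", self.patients.reset_index(drop=True))

    @property
    def patient_ids(self) -> list[str]:
        return list(self.patients["patient_id"])

    @property
    def n_patients(self) -> int:
        return len(self.patients)

    def mask_volume(self, patient_id: str) -> np.ndarray:
        return self.grid.volume_from_indices(self.masks[patient_id])


@dataclass(frozen=True)
class NamingMatrix:
    """Binary patients x items response table (1 correct, 0 wrong); no missing cells."""

    patient_ids: list[str]
    item_ids: list[str]
    values: np.ndarray  # (P, I) uint8

    def __post_init__(self):
        vals = np.asarray(self.values)
        if vals.shape != (len(self.patient_ids), len(self.item_ids)):
            raise ValueError("naming matrix shape does not match patient/item lists")
        if not np.isin(vals, (0, 1)).all():
            raise ValueError("naming matrix must be binary")
        object.__setattr__(self, "values", vals.astype(np.uint8))
        object.__setattr__(self, "patient_ids", list(self.patient_ids))
        object.__setattr__(self, "item_ids", list(self.item_ids))

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    @property
    def n_items(self) -> int:
        return len(self.item_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.patient_ids, columns=self.item_ids)

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "NamingMatrix":
        return cls(list(df.index), list(df.columns), df.to_numpy())
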