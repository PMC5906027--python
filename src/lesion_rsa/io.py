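"""Reading and writing the on-disk formats (NIfTI volumes, TSV/CSV tables)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .core import GridSpec, LesionCohort, NamingMatrix, Region, VoxelTemplate
from .features import ConnectionFeatureMatrix

__all__ = [
    "save_template", "load_template",
    "save_cohort", "load_cohort",
    "save_naming", "load_naming",
    "features_to_triplets",
]


def _save_nifti(vol: np.ndarray, affine: np.ndarray, path: Path) -> None:
    nib.save(nib.Nifti1Image(np.asarray(vol), affine), str(path))


def save_template(template: VoxelTemplate, out_dir: str | Path) -> None:
    """Integer label volume (labels.nii.gz) + region table (regions.tsv)."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    vol, table = template.label_volume()
    _save_nifti(vol, template.grid.affine, out_dir / "labels.nii.gz")
    table.to_csv(out_dir / "regions.tsv", sep="\t", index=False)


def load_template(in_dir: str | Path) -> VoxelTemplate:
    in_dir = Path(in_dir)
    img = nib.load(str(in_dir / "labels.nii.gz"))
    vol = np.asarray(img.dataobj).astype(np.int32)
    grid = GridSpec(shape=vol.shape, affine=np.asarray(img.affine))
    table = pd.read_csv(in_dir / "regions.tsv", sep="\t")
    regions = {}
    for _, row in table.iterrows():
        idx = grid.indices_from_volume(vol == int(row["label"]))
        regions[str(row["name"])] = Region(kind=str(row["kind"]), voxels=idx)
    return VoxelTemplate(grid=grid, regions=regions)


def save_cohort(cohort: LesionCohort, out_dir: str | Path) -> None:
    """One binary NIfTI per patient plus a cohort manifest TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest = cohort.patients.copy()
    files = []
    for pid in cohort.patient_ids:
        fn = f"{pid}_lesion.nii.gz"
        _save_nifti(cohort.mask_volume(pid), cohort.grid.affine, out_dir / fn)
        files.append(fn)
    manifest["file"] = files
    manifest.to_csv(out_dir / "cohort.tsv", sep="\t", index=False)


def load_cohort(in_dir: str | Path) -> LesionCohort:
    in_dir = Path(in_dir)
    manifest = pd.read_csv(in_dir / "cohort.tsv", sep="\t")
    grid = None
    masks = {}
    for _, row in manifest.iterrows():
        img = nib.load(str(in_dir / row["file"]))
        vol = np.asarray(img.dataobj)
        if grid is None:
            grid = GridSpec(shape=vol.shape, affine=np.asarray(img.affine))
        masks[str(row["patient_id"])] = grid.indices_from_volume(vol != 0)
    patients = manifest[["patient_id", "etiology", "hemisphere"]].astype(str)
    return LesionCohort(grid=grid, patients=patients, masks=masks)


def save_naming(naming: NamingMatrix, path: str | Path) -> None:
    naming.to_frame().to_csv(path)


def load_naming(path: str | Path) -> NamingMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = df.index.astype(str)
    df.columns = df.columns.astype(str)
    return NamingMatrix.from_frame(df)


def features_to_triplets(features: list[ConnectionFeatureMatrix]) -> pd.DataFrame:
    """Sparse triplet encoding (region, voxel_index, patient_id) of lesioned cells."""
    rows = []
    for f in features:
        v_idx, p_idx = np.nonzero(f.values)
        for v, p in zip(v_idx, p_idx):
            rows.append((f.region, int(f.voxel_indices[v]), f.patient_ids[p]))
    return pd.DataFrame(rows, columns=["region", "voxel_index", "patient_id"])
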