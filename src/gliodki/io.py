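"""NIfTI-1 and table I/O.

All NIfTI outputs carry the input grid's affine unchanged; the default
affine for phantom data is a diagonal voxel-size matrix.  Diffusivities in
the maps are µm²/ms; b-values in .bval files are s/mm² (FSL dialect).
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .phantom import PhantomCase
from .scheme import write_bval_bvec

ROI_TABLE_COLUMNS = ["case_id", "roi", "MD", "FA", "MK", "AK", "RK", "KA",
                     "AWF", "AxEAD", "AxIAD", "RadEAD", "RadIAD", "TORT",
                     "CBF"]


def default_affine(voxel_mm: float) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0] = aff[1, 1] = aff[2, 2] = voxel_mm
    return aff


def save_nifti(path, data: np.ndarray, affine: np.ndarray) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine)
    nib.save(img, str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), np.asarray(img.affine)


def voxel_size_mm(affine: np.ndarray) -> np.ndarray:
    return np.sqrt((np.asarray(affine)[:3, :3] ** 2).sum(axis=0))


def write_phantom_case(case: PhantomCase, out_dir, prefix: str = "phantom") -> dict:
    """Write one phantom case: DWI, bval/bvec, CBF, labels, ROIs, truth maps."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = default_affine(case.spec.voxel_mm)
    paths = {
        "dwi": out / f"{prefix}_dwi.nii.gz",
        "bval": out / f"{prefix}.bval",
        "bvec": out / f"{prefix}.bvec",
        "cbf": out / f"{prefix}_cbf.nii.gz",
        "labels": out / f"{prefix}_labels.nii.gz",
        "rois": out / f"{prefix}_rois.nii.gz",
    }
    save_nifti(paths["dwi"], case.dwi, aff)
    write_bval_bvec(case.scheme, paths["bval"], paths["bvec"])
    save_nifti(paths["cbf"], case.cbf, aff)
    save_nifti(paths["labels"], case.labels.astype(np.float32), aff)
    save_nifti(paths["rois"], case.rois.astype(np.float32), aff)
    for name, arr in case.truth.items():
        p = out / f"{prefix}_truth_{name}.nii.gz"
        save_nifti(p, arr, aff)
        paths[f"truth_{name}"] = p
    return {k: str(v) for k, v in paths.items()}


def write_tensor_field(field, out_dir, affine, prefix: str = "tensors") -> dict:
    """Tensor field as multi-volume NIfTI.

    Component order: ``d`` = [Dxx, Dyy, Dzz, Dxy, Dxz, Dyz]; ``w`` = the 15
    unique W components in sorted-index order (see gliodki.tensors).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {
        "d": out / f"{prefix}_d.nii.gz",
        "w": out / f"{prefix}_w.nii.gz",
        "s0": out / f"{prefix}_s0.nii.gz",
        "valid": out / f"{prefix}_valid.nii.gz",
    }
    save_nifti(paths["d"], field.d, affine)
    save_nifti(paths["w"], field.w, affine)
    save_nifti(paths["s0"], field.s0, affine)
    save_nifti(paths["valid"], field.valid.astype(np.float32), affine)
    return {k: str(v) for k, v in paths.items()}


def write_maps(maps, out_dir, affine, prefix: str = "") -> dict:
    """Each scalar/WMTI map (and its validity mask) as NIfTI-1."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    paths = {}
    for name, arr in maps.as_dict().items():
        p = out / f"{prefix}{name}.nii.gz"
        save_nifti(p, arr, affine)
        paths[name] = str(p)
        m = out / f"{prefix}{name}_valid.nii.gz"
        save_nifti(m, maps.mask_for(name).astype(np.float32), affine)
        paths[f"{name}_valid"] = str(m)
    return paths


def write_roi_table(table: pd.DataFrame, path) -> None:
    cols = [c for c in ROI_TABLE_COLUMNS if c in table.columns]
    cols += [c for c in table.columns if c not in cols]
    table[cols].to_csv(path, index=False)


def read_roi_table(path) -> pd.DataFrame:
    table = pd.read_csv(path)
    for col in ("case_id", "roi"):
        if col not in table.columns:
            raise ValueError(f"ROI table missing required column {col!r}")
    bad = set(table["roi"].unique()) - {1, 2, 3, 4}
    if bad:
        raise ValueError(f"ROI labels restricted to 1-4; found {sorted(bad)}")
    return table
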