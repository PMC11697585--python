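"""Reading and writing of study inputs/outputs (NIfTI, FSL text, LUT, manifest)."""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import yaml

__all__ = [
    "load_volume",
    "save_volume",
    "load_bvals_bvecs",
    "load_lut",
    "load_manifest",
]


def load_volume(path) -> np.ndarray:
    return np.asarray(nib.load(str(path)).get_fdata())


def save_volume(path, data: np.ndarray, voxel_size: float = 1.0) -> None:
    affine = np.diag([voxel_size, voxel_size, voxel_size, 1.0])
    nib.Nifti1Image(np.asarray(data, dtype=np.float32), affine).to_filename(str(path))


def load_bvals_bvecs(bvals_path, bvecs_path) -> tuple[np.ndarray, np.ndarray]:
    """FSL convention: bvals one row; bvecs three rows (x, y, z)."""
    bvals = np.loadtxt(bvals_path).ravel()
    bvecs = np.loadtxt(bvecs_path)
    if bvecs.shape[0] == 3 and bvecs.shape[1] != 3:
        bvecs = bvecs.T
    elif bvecs.shape == (3, 3):
        bvecs = bvecs.T  # ambiguous; FSL stores directions in columns
    return bvals, np.asarray(bvecs, dtype=float)


def load_lut(path) -> dict[int, tuple[str, str]]:
    """Tab-separated lookup table: id, name, hemisphere (with header)."""
    lut: dict[int, tuple[str, str]] = {}
    with open(path) as fh:
        header = fh.readline()
        if not header.lower().startswith("id"):
            fh.seek(0)
        for line in fh:
            line = line.strip()
            if not line:
                continue
            lid, name, hemi = line.split("\t")
            lut[int(lid)] = (name, hemi)
    return lut


def load_manifest(study_dir) -> dict:
    with open(Path(study_dir) / "manifest.yaml") as fh:
        return yaml.safe_load(fh)
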