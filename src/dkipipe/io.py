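"""File formats: NIfTI volumes, FSL gradient tables, delimited tables.

Tensor maps are stored as multi-volume NIfTI with the package's
canonical component ordering, documented in a plain-text sidecar so the
files remain self-describing.  All cohort volumes must share one grid
(shape and affine); grids are checked, never resampled.
"""

from __future__ import annotations

import json
import hashlib
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .model import D_COMPONENT_INDICES, W_COMPONENT_INDICES, GradientScheme

__all__ = [
    "save_nifti",
    "load_nifti",
    "save_tensor_maps",
    "load_tensor_maps",
    "save_labels",
    "load_labels",
    "check_same_grid",
    "write_manifest",
]

_D_NAMES = ["D" + "".join(str(i + 1) for i in idx) for idx in D_COMPONENT_INDICES]
_W_NAMES = ["W" + "".join(str(i + 1) for i in idx) for idx in W_COMPONENT_INDICES]


def save_nifti(data: np.ndarray, path, affine: np.ndarray | None = None) -> None:
    affine = np.eye(4) if affine is None else affine
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


def load_nifti(path) -> tuple[np.ndarray, np.ndarray]:
    img = nib.load(str(path))
    return np.asarray(img.get_fdata()), img.affine


def check_same_grid(*images: tuple[np.ndarray, np.ndarray]) -> None:
    """Require identical 3-D shape and affine across (data, affine) pairs."""
    shape0, aff0 = images[0][0].shape[:3], images[0][1]
    for data, aff in images[1:]:
        if data.shape[:3] != shape0 or not np.allclose(aff, aff0, atol=1e-6):
            raise ValueError("volumes are not on a shared grid (shape/affine mismatch)")


def save_tensor_maps(maps: dict[str, np.ndarray], out_dir, affine=None) -> None:
    """Write D/W/S0/flag maps plus a sidecar naming the component order."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    save_nifti(maps["D"], out / "dt.nii.gz", affine)
    save_nifti(maps["W"], out / "kt.nii.gz", affine)
    save_nifti(maps["s0"], out / "s0.nii.gz", affine)
    save_nifti(maps["flags"].astype(float), out / "flags.nii.gz", affine)
    sidecar = out / "tensor_components.txt"
    sidecar.write_text(
        "dt.nii.gz volumes: " + " ".join(_D_NAMES) + "\n"
        "kt.nii.gz volumes: " + " ".join(_W_NAMES) + "\n"
        "flags: bit1=clipped-signal bit2=degenerate-mean-diffusivity bit4=kurtosis-range\n"
    )


def load_tensor_maps(in_dir) -> dict[str, np.ndarray]:
    d = Path(in_dir)
    maps = {
        "D": load_nifti(d / "dt.nii.gz")[0],
        "W": load_nifti(d / "kt.nii.gz")[0],
        "s0": load_nifti(d / "s0.nii.gz")[0],
    }
    flags = d / "flags.nii.gz"
    if flags.exists():
        maps["flags"] = load_nifti(flags)[0].astype(np.int32)
    return maps


def save_labels(labels: pd.DataFrame, path) -> None:
    labels.to_csv(path, sep="\t", index=False)


def load_labels(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_scheme(scheme: GradientScheme, out_dir) -> None:
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    scheme.to_bval_bvec(out / "dwi.bval", out / "dwi.bvec")


def load_scheme(in_dir) -> GradientScheme:
    d = Path(in_dir)
    return GradientScheme.from_bval_bvec(d / "dwi.bval", d / "dwi.bvec")


def write_manifest(out_dir, inputs: dict[str, Path], meta: dict) -> None:
    """Record input-file hashes and run metadata for reproducibility."""
    entries = {}
    for name, p in inputs.items():
        p = Path(p)
        entries[name] = {
            "path": str(p),
            "sha256": hashlib.sha256(p.read_bytes()).hexdigest() if p.is_file() else None,
        }
    manifest = {"inputs": entries, **meta}
    Path(out_dir, "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
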