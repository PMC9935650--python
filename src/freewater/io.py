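"""File formats: NIfTI volumes, FSL-dialect bval/bvec, delimited tables.

MD values are stored in mm^2/s internally; cohort tables written to disk
carry an additional ``mean_md_1e6`` column in the conventional
x 10^-6 mm^2/s reporting units.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .fitting import DWIVolume
from .gradients import GradientScheme


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def write_nifti(path, data, voxel_size=(2.0, 2.0, 2.0)):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    img = nib.Nifti1Image(np.asarray(data).astype(np.float32), _affine(voxel_size))
    nib.save(img, str(path))
    return path


def read_nifti(path):
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=float)
    voxel_size = tuple(float(z) for z in img.header.get_zooms()[:3])
    return data, voxel_size


def write_gradients(bval_path, bvec_path, scheme: GradientScheme):
    """FSL dialect: one row of b-values; three rows of direction components."""
    Path(bval_path).parent.mkdir(parents=True, exist_ok=True)
    with open(bval_path, "w") as fh:
        fh.write(" ".join(f"{b:g}" for b in scheme.bvals) + "\n")
    with open(bvec_path, "w") as fh:
        for row in scheme.bvecs.T:
            fh.write(" ".join(f"{v:.8f}" for v in row) + "\n")


def read_gradients(bval_path, bvec_path) -> GradientScheme:
    """Read FSL bval/bvec; re-normalise bvecs within 1e-3 of unit norm."""
    try:
        bvals = np.loadtxt(bval_path, ndmin=1)
        bvecs = np.loadtxt(bvec_path, ndmin=2)
    except ValueError as err:
        raise ValueError(f"malformed gradient table: {err}") from err
    if bvecs.shape[0] == 3:
        bvecs = bvecs.T
    if bvecs.shape != (bvals.size, 3):
        raise ValueError("bvec table shape does not match bval count")
    dw = bvals > 0
    norms = np.linalg.norm(bvecs[dw], axis=1)
    if np.any(np.abs(norms - 1.0) > 1e-3):
        raise ValueError("diffusion direction vectors deviate from unit norm beyond 1e-3")
    bvecs = bvecs.copy()
    bvecs[dw] /= norms[:, None]
    return GradientScheme(bvals, bvecs)


def write_dwi(prefix, dwi: DWIVolume):
    """Write <prefix>_dwi.nii.gz, _mask.nii.gz, .bval, .bvec."""
    prefix = Path(prefix)
    write_nifti(prefix.with_name(prefix.name + "_dwi.nii.gz"), dwi.signal, dwi.voxel_size)
    write_nifti(prefix.with_name(prefix.name + "_mask.nii.gz"), dwi.mask.astype(np.float32), dwi.voxel_size)
    write_gradients(prefix.with_name(prefix.name + ".bval"), prefix.with_name(prefix.name + ".bvec"), dwi.scheme)
    return prefix


def read_dwi(nifti_path, bval_path, bvec_path, mask_path=None) -> DWIVolume:
    """Load a DWI volume with its gradient table (and optional mask)."""
    signal, voxel_size = read_nifti(nifti_path)
    scheme = read_gradients(bval_path, bvec_path)
    if signal.ndim != 4:
        raise ValueError("DWI NIfTI must be 4D")
    if signal.shape[-1] != len(scheme):
        raise ValueError(
            f"volume count ({signal.shape[-1]}) does not match gradient table length ({len(scheme)})"
        )
    if mask_path is not None:
        mask, _ = read_nifti(mask_path)
        mask = mask > 0.5
    else:
        mask = signal[..., scheme.b0_mask].mean(axis=-1) > 0
    return DWIVolume(signal=signal, scheme=scheme, mask=mask, voxel_size=voxel_size)


def write_metrics_table(path, table: pd.DataFrame):
    """Cohort table as tab-separated text; MD also in x1e-6 reporting units."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    out = table.copy()
    if "mean_md" in out.columns:
        out["mean_md_1e6"] = out["mean_md"] * 1e6
    out.to_csv(path, sep="\t", index=False)
    return path


def read_metrics_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def config_hash(obj) -> str:
    payload = json.dumps(obj, sort_keys=True, default=str).encode()
    return hashlib.sha256(payload).hexdigest()[:16]


def write_manifest(path, manifest: dict):
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    path.write_text(json.dumps(manifest, indent=2, default=str))


def read_manifest(path) -> dict:
    return json.loads(Path(path).read_text())
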