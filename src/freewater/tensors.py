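"""Diffusion-tensor algebra: packing, eigenvalues, MD/FA, construction.

Tensors are stored in lower-triangular order ``(Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)``
with diffusivities in mm^2/s. Arrays may carry any number of leading axes;
the last axis of length 6 is the packed tensor.
"""

from __future__ import annotations

import numpy as np

# index maps between packed 6-vectors and symmetric 3x3 matrices
_ROW = np.array([0, 0, 1, 0, 1, 2])
_COL = np.array([0, 1, 1, 2, 2, 2])


def tensor_to_matrix(tensor: np.ndarray) -> np.ndarray:
    """Expand packed tensors (..., 6) to symmetric matrices (..., 3, 3)."""
    tensor = np.asarray(tensor, dtype=float)
    out = np.zeros(tensor.shape[:-1] + (3, 3), dtype=float)
    out[..., _ROW, _COL] = tensor
    out[..., _COL, _ROW] = tensor
    return out


def matrix_to_tensor(matrix: np.ndarray) -> np.ndarray:
    """Pack symmetric matrices (..., 3, 3) into 6-vectors (..., 6)."""
    matrix = np.asarray(matrix, dtype=float)
    return matrix[..., _ROW, _COL]


def tensor_eigenvalues(tensor: np.ndarray) -> np.ndarray:
    """Eigenvalues of packed tensors, sorted descending (lam1 >= lam2 >= lam3)."""
    vals = np.linalg.eigvalsh(tensor_to_matrix(tensor))
    return vals[..., ::-1]


def md_of_tensor(tensor: np.ndarray) -> np.ndarray:
    """Mean diffusivity: trace/3 = (lam1 + lam2 + lam3)/3 (mm^2/s).

    Accepts packed 6-vectors or full 3x3 matrices; rotation invariant.
    """
    tensor = np.asarray(tensor, dtype=float)
    if tensor.shape[-1] == 6 and (tensor.ndim == 1 or tensor.shape[-2:] != (3, 3)):
        return (tensor[..., 0] + tensor[..., 2] + tensor[..., 5]) / 3.0
    return np.trace(tensor, axis1=-2, axis2=-1) / 3.0


def fa_of_tensor(tensor: np.ndarray) -> np.ndarray:
    """Fractional anisotropy in [0, 1].

    FA = sqrt(3/2) * ||lam - MD|| / ||lam||; the all-zero tensor maps to 0.
    """
    tensor = np.asarray(tensor, dtype=float)
    if not (tensor.shape[-1] == 6 and (tensor.ndim == 1 or tensor.shape[-2:] != (3, 3))):
        tensor = matrix_to_tensor(tensor)
    lam = tensor_eigenvalues(tensor)
    md = lam.mean(axis=-1, keepdims=True)
    num = np.sqrt((3.0 / 2.0) * ((lam - md) ** 2).sum(axis=-1))
    den = np.sqrt((lam**2).sum(axis=-1))
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.clip(fa, 0.0, 1.0)


_FROB_W = np.array([1.0, 2.0, 1.0, 2.0, 2.0, 1.0])  # Frobenius weights, packed order
_MD_VEC = np.array([1.0, 0.0, 1.0, 0.0, 0.0, 1.0]) / 3.0


def fa_of_tensor_debiased(tensor: np.ndarray, cov: np.ndarray) -> np.ndarray:
    """FA with the tensor's estimation variance removed (moment form).

    Per-voxel FA computed from a noisy tensor estimate is inflated:
    eigenvalue dispersion picks up estimation noise on top of true
    anisotropy. In the moment form

        FA^2 = (3/2) * ||D - MD*I||_F^2 / ||D||_F^2,

    estimation noise adds its (Frobenius-weighted) covariance trace to each
    squared norm in expectation, so subtracting plug-in estimates of those
    traces yields an approximately unbiased FA. ``cov`` is the per-voxel
    6x6 covariance of the packed tensor estimate; with zero covariance this
    reproduces :func:`fa_of_tensor` exactly. Overcorrected voxels clip to 0.
    """
    t = np.asarray(tensor, dtype=float)
    c = np.asarray(cov, dtype=float)
    normsq = (_FROB_W * t**2).sum(axis=-1)
    md = t @ _MD_VEC
    tr_w = (_FROB_W * np.diagonal(c, axis1=-2, axis2=-1)).sum(axis=-1)
    var_md = np.einsum("...ij,i,j->...", c, _MD_VEC, _MD_VEC)
    num = normsq - 3.0 * md**2 - (tr_w - 3.0 * var_md)
    den = normsq - tr_w
    with np.errstate(invalid="ignore", divide="ignore", over="ignore"):
        ratio = np.where(den > 0, num / np.maximum(den, 1e-300), 0.0)
    return np.sqrt(1.5 * np.clip(ratio, 0.0, 2.0 / 3.0))


def axial_delta_for_fa(fa) -> np.ndarray:
    """Anisotropy parameter of an axisymmetric (prolate) tensor with given FA.

    For eigenvalues MD*(1+2*delta), MD*(1-delta), MD*(1-delta):
    FA = 3*delta / sqrt(3 + 6*delta^2), inverted here.
    """
    fa = np.asarray(fa, dtype=float)
    if np.any(fa < 0) or np.any(fa >= np.sqrt(1.5)):
        raise ValueError("axisymmetric prolate FA must lie in [0, sqrt(3/2))")
    return fa * np.sqrt(3.0 / (9.0 - 6.0 * fa**2))


def tensor_from_md_fa_axis(md, fa, axis) -> np.ndarray:
    """Axisymmetric tensor with given MD, FA and principal axis, packed (..., 6).

    Eigenvalues are MD*(1+2*delta) along ``axis`` and MD*(1-delta) across it.
    """
    md = np.asarray(md, dtype=float)
    fa = np.asarray(fa, dtype=float)
    axis = np.asarray(axis, dtype=float)
    norm = np.linalg.norm(axis, axis=-1, keepdims=True)
    if np.any(norm == 0):
        raise ValueError("principal axis must be non-zero")
    n = axis / norm
    delta = axial_delta_for_fa(fa)
    lam_perp = md * (1.0 - delta)
    lam_par = md * (1.0 + 2.0 * delta)
    outer = n[..., :, None] * n[..., None, :]
    eye = np.eye(3)
    mat = lam_perp[..., None, None] * eye + (lam_par - lam_perp)[..., None, None] * outer
    return matrix_to_tensor(mat)


def clip_tensor_eigenvalues(tensor: np.ndarray, low: float, high: float) -> np.ndarray:
    """Project packed tensors onto the box low <= eigenvalue <= high."""
    mat = tensor_to_matrix(tensor)
    vals, vecs = np.linalg.eigh(mat)
    vals = np.clip(vals, low, high)
    mat = np.einsum("...ij,...j,...kj->...ik", vecs, vals, vecs)
    return matrix_to_tensor(mat)
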