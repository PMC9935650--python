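"""Per-voxel diffusion model fits: single tensor and free-water bi-tensor.

The single-tensor fit is two-pass weighted linear least squares on the
log signal. The free-water fit minimises, per voxel,

    sum_i (S_i/s0 - [(1-f) exp(-b_i g_i^T D g_i) + f exp(-b_i d_w)])^2
        + lambda_reg * sum_edges (f_u - f_v)^2

over the free-water fraction f in [0, 1] and the tissue tensor D,
parameterised by its Cholesky factor (guaranteeing positive
semi-definiteness), with a Levenberg-Marquardt scheme vectorised over all
in-mask voxels.

Identifiability. At a single shell, (f, MD_tissue) is exactly
non-identifiable in an isotropic voxel: the attenuation
(1-f) exp(-b MD) + f exp(-b d_w) depends on the pair only through one
scalar, and anisotropy restores identifiability far too weakly to matter
at realistic SNR. The estimator therefore behaves as a MAP fit: the f
field carries a Gaussian prior centred at its initial value (whose weight
is scaled by the estimated noise level, so it vanishes on noise-free
data) together with a quadratic spatial smoothness penalty, and accuracy
in near-isotropic tissue is inherited from the initialisation. The init
interpolates each voxel's decay between a tissue reference MD and the
free-water decay; by default that reference is estimated per subject from
high-FA voxels, where the free-water fraction is physiologically small.
d_w is the fixed free-water diffusivity (3.0e-3 mm^2/s).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator

from .gradients import GradientScheme
from .tensors import (
    clip_tensor_eigenvalues,
    fa_of_tensor,
    fa_of_tensor_debiased,
    matrix_to_tensor,
    md_of_tensor,
    tensor_to_matrix,
)

D_WATER = 3.0e-3  # mm^2/s
EIG_BOX = (0.1e-3, 2.5e-3)  # mm^2/s, tissue-tensor eigenvalue constraints
MD_TISSUE_INIT = 0.6e-3  # mm^2/s, generic tissue MD anchoring the f init
WM_FA_THRESHOLD = 0.35  # single-tensor FA above which a voxel anchors the reference
WM_FW_PRIOR = 0.05  # assumed free-water fraction in high-FA reference voxels
GM_WM_MD_RATIO = 1.07  # grey-matter over white-matter tissue diffusivity


@dataclass
class DWIVolume:
    """A 4D diffusion acquisition: signal, gradient scheme, brain mask."""

    signal: np.ndarray  # (X, Y, Z, n_volumes), arbitrary units, non-negative
    scheme: GradientScheme
    mask: np.ndarray  # (X, Y, Z) bool
    voxel_size: tuple = (2.0, 2.0, 2.0)

    def __post_init__(self):
        self.signal = np.asarray(self.signal, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.signal.ndim != 4:
            raise ValueError("signal must be 4D (x, y, z, volume)")
        if self.signal.shape[-1] != len(self.scheme):
            raise ValueError("volume count does not match gradient scheme length")
        if self.signal.shape[:3] != self.mask.shape:
            raise ValueError("mask grid does not match signal grid")

    @property
    def grid_shape(self):
        return self.signal.shape[:3]

    def b0_mean(self) -> np.ndarray:
        """Mean of the b=0 volumes (the fixed s0 estimate)."""
        return self.signal[..., self.scheme.b0_mask].mean(axis=-1)


@dataclass
class TensorField:
    """Per-voxel symmetric tensors, packed (Dxx, Dxy, Dyy, Dxz, Dyz, Dzz)."""

    tensor: np.ndarray  # (X, Y, Z, 6), mm^2/s
    s0_map: np.ndarray  # (X, Y, Z)
    mask: np.ndarray  # (X, Y, Z) bool
    invalid: np.ndarray | None = None  # voxels with too many non-positive signals
    fa_debiased: np.ndarray | None = None  # noise-debiased FA map, if computed

    def eigenvalues(self) -> np.ndarray:
        """(X, Y, Z, 3), sorted descending; zeros outside the mask."""
        vals = np.linalg.eigvalsh(tensor_to_matrix(self.tensor))[..., ::-1]
        return vals

    def md(self) -> np.ndarray:
        return md_of_tensor(self.tensor)


@dataclass
class FreeWaterFit:
    """Result of the bi-tensor fit: tissue tensor + free-water fraction."""

    tissue_tensor: TensorField
    fw_fraction: np.ndarray  # (X, Y, Z) in [0, 1]
    converged: np.ndarray  # (X, Y, Z) bool
    residual: np.ndarray  # (X, Y, Z) RMS residual in normalised (S/s0) units
    f_at_bound: np.ndarray | None = None
    fa_debiased: np.ndarray | None = None  # noise-debiased tissue FA map
    n_iter: int = 0


def _mask_neighbours(mask: np.ndarray):
    """Index pairs of 6-connected in-mask neighbours, plus per-voxel degree."""
    flat_index = -np.ones(mask.shape, dtype=np.int64)
    flat_index[mask] = np.arange(mask.sum())
    pairs_a, pairs_b = [], []
    for axis in range(3):
        sl_a = [slice(None)] * 3
        sl_b = [slice(None)] * 3
        sl_a[axis] = slice(None, -1)
        sl_b[axis] = slice(1, None)
        both = mask[tuple(sl_a)] & mask[tuple(sl_b)]
        pairs_a.append(flat_index[tuple(sl_a)][both])
        pairs_b.append(flat_index[tuple(sl_b)][both])
    a = np.concatenate(pairs_a)
    b = np.concatenate(pairs_b)
    deg = np.zeros(int(mask.sum()))
    np.add.at(deg, a, 1.0)
    np.add.at(deg, b, 1.0)
    return a, b, deg


def _neighbour_sum(f, a, b, w=None):
    out = np.zeros_like(f)
    if w is None:
        np.add.at(out, a, f[b])
        np.add.at(out, b, f[a])
    else:
        np.add.at(out, a, w * f[b])
        np.add.at(out, b, w * f[a])
    return out


def _safe_inv(G: np.ndarray, rel_ridge: float = 1e-10) -> np.ndarray:
    """Scaled, ridged inverse of a stack of (near-)SPD Gram matrices.

    Used for covariance estimates only: pathological voxels (e.g. pure CSF
    after free-water subtraction) yield Gram matrices that are numerically
    singular; a trace-scaled ridge keeps the inverse finite there, leaving
    well-conditioned voxels essentially untouched.
    """
    k = G.shape[-1]
    d = np.trace(G, axis1=-2, axis2=-1) / k
    d = np.maximum(d, 1e-300)
    Gn = G / d[..., None, None] + rel_ridge * np.eye(k)
    with np.errstate(over="ignore"):
        inv = np.linalg.inv(Gn) / d[..., None, None]
    # voxels with a vanishing trace saturate to a huge but finite covariance
    return np.nan_to_num(inv, nan=0.0, posinf=1e300, neginf=-1e300)


def _edge_weights(a_idx, b_idx, f0, md_st, f_scale=0.1, md_scale=1.5e-4):
    """Edge-preserving similarity weights from the initialisation.

    Smoothness penalties must not bleed across tissue boundaries (CSF rim
    vs parenchyma, lesion vs normal tissue), so each 6-neighbour edge is
    weighted by the similarity of the two voxels' initial free-water
    fraction and apparent MD. Within homogeneous regions the weight is ~1;
    across boundaries it decays to ~0.
    """
    df = (f0[a_idx] - f0[b_idx]) / f_scale
    dmd = (md_st[a_idx] - md_st[b_idx]) / md_scale
    return np.exp(-(df**2) - dmd**2)


class SingleTensorFitter(BaseEstimator):
    """Conventional DTI: weighted linear least squares on the log signal.

    Two passes: ordinary least squares, then weights equal to the squared
    predicted signal. Non-positive signals are excluded per voxel (zero
    weight); voxels where more than ``max_nonpositive_frac`` of the signals
    are non-positive are flagged invalid and get a zero tensor. Output
    eigenvalues are clamped at zero.
    """

    def __init__(self, n_passes: int = 2, max_nonpositive_frac: float = 0.25):
        self.n_passes = n_passes
        self.max_nonpositive_frac = max_nonpositive_frac

    def fit(self, dwi: DWIVolume, y=None):
        mask = dwi.mask
        S = dwi.signal[mask]  # (N, M)
        B = dwi.scheme.design_matrix()  # (M, 7)
        positive = S > 0
        invalid = positive.mean(axis=1) < (1.0 - self.max_nonpositive_frac)
        logS = np.log(np.where(positive, S, 1.0))
        w = positive.astype(float)
        beta = None
        for _ in range(max(self.n_passes, 1)):
            A = np.einsum("mi,nm,mj->nij", B, w, B)
            A += 1e-12 * np.eye(7)
            rhs = np.einsum("mi,nm->ni", B, w * logS)
            beta = np.linalg.solve(A, rhs[..., None])[..., 0]
            pred = np.exp(np.clip(beta @ B.T, -50.0, 50.0))
            w = positive * pred**2
        tensor = np.zeros(mask.shape + (6,))
        s0_map = np.zeros(mask.shape)
        packed = beta[:, 1:]  # design columns already ordered as packed tensor
        packed[invalid] = 0.0
        # clamp eigenvalues at zero
        mat = tensor_to_matrix(packed)
        vals, vecs = np.linalg.eigh(mat)
        vals = np.maximum(vals, 0.0)
        packed = matrix_to_tensor(np.einsum("...ij,...j,...kj->...ik", vecs, vals, vecs))
        tensor[mask] = packed
        s0_map[mask] = np.where(invalid, 0.0, np.exp(np.clip(beta[:, 0], -50, 50)))
        invalid_map = np.zeros(mask.shape, dtype=bool)
        invalid_map[mask] = invalid

        # debiased FA from the WLS covariance of the tensor estimate
        resid = np.where(positive, logS - beta @ B.T, 0.0)
        dof = np.maximum(positive.sum(axis=1) - 7, 1)
        sigma2 = (w * resid**2).sum(axis=1) / dof
        G = np.einsum("mi,nm,mj->nij", B, w, B)
        cov = sigma2[:, None, None] * _safe_inv(G)[:, 1:, 1:]
        fa_deb = np.zeros(mask.shape)
        fa_deb[mask] = np.where(invalid, 0.0, fa_of_tensor_debiased(packed, cov))

        self.tensor_ = tensor
        self.s0_map_ = s0_map
        self.invalid_ = invalid_map
        self.fa_debiased_ = fa_deb
        self.mask_ = mask.copy()
        return self

    def result(self) -> TensorField:
        return TensorField(
            self.tensor_, self.s0_map_, self.mask_, self.invalid_, self.fa_debiased_
        )


def fit_single_tensor(dwi: DWIVolume, **kwargs) -> TensorField:
    """Functional wrapper around :class:`SingleTensorFitter`."""
    return SingleTensorFitter(**kwargs).fit(dwi).result()


def estimate_tissue_anchor(
    single: TensorField,
    mask: np.ndarray,
    b_shell: float,
    d_water: float = D_WATER,
    fa_threshold: float = WM_FA_THRESHOLD,
    wm_fw_prior: float = WM_FW_PRIOR,
    gm_wm_ratio: float = GM_WM_MD_RATIO,
    min_reference_voxels: int = 50,
) -> np.ndarray:
    """Per-voxel tissue-MD reference for the free-water initialisation.

    Single-shell data cannot separate f from the tissue MD in isotropic
    voxels, so the f init needs an external tissue-MD reference — and a
    fixed constant cannot track the large between-subject MD differences
    this pipeline is meant to detect. This estimates the reference from
    the subject's own data using two physiological priors: (i) voxels with
    high *measured* FA carry little free water (free water suppresses FA),
    so their apparent MD, corrected for a small nominal fraction
    ``wm_fw_prior``, estimates the white-matter tissue MD; (ii) grey-matter
    tissue diffusivity sits a fixed factor ``gm_wm_ratio`` above white
    matter. High-FA voxels get the white-matter reference, the rest the
    grey-matter one. Falls back to the median over all plausible-MD voxels
    (then to ``MD_TISSUE_INIT``) when too few high-FA voxels exist.
    """
    md_st = single.md()
    fa_st = fa_of_tensor(single.tensor)
    valid = mask & (md_st > 0.2e-3) & (md_st < 1.5e-3)
    if single.invalid is not None:
        valid &= ~single.invalid
    high_fa = valid & (fa_st >= fa_threshold)
    reference = high_fa if int(high_fa.sum()) >= min_reference_voxels else valid
    if int(reference.sum()) == 0:
        anchor_wm = MD_TISSUE_INIT
    else:
        md_ref = float(np.median(md_st[reference]))
        e_w = np.exp(-b_shell * d_water)
        e_app = np.exp(-b_shell * md_ref)
        e_tis = (e_app - wm_fw_prior * e_w) / (1.0 - wm_fw_prior)
        anchor_wm = -np.log(np.clip(e_tis, 1e-12, None)) / b_shell
        anchor_wm = float(np.clip(anchor_wm, 0.3e-3, 1.2e-3))
    return np.where(fa_st >= fa_threshold, anchor_wm, anchor_wm * gm_wm_ratio)


def init_free_water(
    dwi: DWIVolume,
    single: TensorField | None = None,
    d_water: float = D_WATER,
    md_tissue="auto",
    f_clip=(0.05, 0.95),
    eig_box=EIG_BOX,
):
    """Initial (f map, tissue tensor) for the bi-tensor fit.

    f is initialised by placing each voxel's single-tensor signal decay
    between a tissue reference decay and the free-water decay at the shell
    b-value:

        f0 = (exp(-b MD_st) - exp(-b md_tissue)) / (exp(-b d_water) - exp(-b md_tissue))

    clipped to ``f_clip``. ``md_tissue`` may be a scalar (e.g. the generic
    0.6e-3), a per-voxel array, or ``"auto"`` (default), which estimates a
    subject-specific reference via :func:`estimate_tissue_anchor`. The
    tissue tensor is then re-fit (single-tensor WLS) on the signal with the
    estimated free-water component removed, and projected into the
    eigenvalue box.
    """
    if single is None:
        single = fit_single_tensor(dwi)
    b_shell = float(dwi.scheme.bvals.max())
    if isinstance(md_tissue, str):
        if md_tissue != "auto":
            raise ValueError("md_tissue must be 'auto', a scalar, or an array")
        md_tissue = estimate_tissue_anchor(single, dwi.mask, b_shell, d_water)
    md_st = single.md()
    e_st = np.exp(-b_shell * md_st)
    e_tis = np.exp(-b_shell * np.asarray(md_tissue, dtype=float))
    e_w = np.exp(-b_shell * d_water)
    f0 = np.clip((e_st - e_tis) / (e_w - e_tis), f_clip[0], f_clip[1])
    f0[~dwi.mask] = 0.0

    s0 = dwi.b0_mean()
    b = dwi.scheme.bvals
    fw_signal = (f0[..., None] * s0[..., None]) * np.exp(-b * d_water)
    corrected = (dwi.signal - fw_signal) / np.maximum(1.0 - f0[..., None], 0.05)
    corrected = np.maximum(corrected, 1e-6 * np.maximum(s0[..., None], 1.0))
    tissue_dwi = DWIVolume(corrected, dwi.scheme, dwi.mask, dwi.voxel_size)
    tissue = fit_single_tensor(tissue_dwi)
    packed = tissue.tensor.copy()
    packed[dwi.mask] = clip_tensor_eigenvalues(packed[dwi.mask], *eig_box)
    return f0, TensorField(packed, s0, dwi.mask, tissue.invalid)


class FreeWaterFitter(BaseEstimator):
    """Two-compartment (tissue + free water) fit on single-shell DWI.

    Levenberg-Marquardt on (f, Cholesky(D)) per voxel, vectorised over the
    mask, with Jacobi-coupled quadratic smoothness penalties on the f field
    (``lambda_reg``) and optionally on the tensor Cholesky entries
    (``lambda_tensor``, off by default: it trades FA variance for MD bias),
    plus a Gaussian prior on f centred at its initial value (see the module
    docstring: single-shell data leave f unidentified in isotropic voxels,
    so without the prior the optimiser wanders along the f/MD ridge under
    noise). The prior weight is the estimated per-observation noise
    variance divided by ``f_prior_sd**2``, so it vanishes on noise-free
    data and the fit reduces to maximum likelihood there. Smoothness
    penalties are edge-preserving: each neighbour edge is weighted by the
    similarity of the two voxels' initialisation (so CSF/parenchyma and
    lesion/tissue boundaries are not blurred). ``"auto"`` penalty weights
    are set to about 1% of the data term at initialisation. s0 is the mean
    b=0 signal, held fixed.

    Fitted attributes: ``tensor_`` (packed tissue tensors, eigenvalues
    projected into ``eig_box``), ``fw_fraction_``, ``converged_``,
    ``residual_`` (RMS, S/s0 units), ``f_at_bound_``, ``n_iter_``.
    """

    def __init__(
        self,
        d_water: float = D_WATER,
        lambda_reg="auto",
        lambda_tensor=0.0,
        eig_box=EIG_BOX,
        max_iter: int = 200,
        tol: float = 1e-8,
        md_tissue_init="auto",
        f_prior_sd: float | None = 0.1,
        project_every: int = 10,
    ):
        self.d_water = d_water
        self.lambda_reg = lambda_reg
        self.lambda_tensor = lambda_tensor
        self.eig_box = eig_box
        self.max_iter = max_iter
        self.tol = tol
        self.md_tissue_init = md_tissue_init
        self.f_prior_sd = f_prior_sd
        self.project_every = project_every

    # -- internal vectorised model ------------------------------------------------

    @staticmethod
    def _forward(f, R, g, b, e_w):
        """Attenuation model and tensor quadratic form for all voxels."""
        V = np.einsum("mi,nij->nmj", g, R)  # (N, M, 3) = R^T g per voxel
        q = (V**2).sum(axis=-1)
        E_t = np.exp(-b * q)
        m = (1.0 - f[:, None]) * E_t + f[:, None] * e_w
        return m, E_t, V

    def fit(self, dwi: DWIVolume, init=None, y=None):
        mask = dwi.mask
        N = int(mask.sum())
        s0 = dwi.b0_mean()
        dw_rows = ~dwi.scheme.b0_mask
        b = dwi.scheme.bvals[dw_rows]
        g = dwi.scheme.bvecs[dw_rows]
        M = int(dw_rows.sum())
        y_obs = dwi.signal[mask][:, dw_rows] / np.maximum(s0[mask][:, None], 1e-12)
        e_w = np.exp(-b * self.d_water)

        single = fit_single_tensor(dwi)
        if init is None:
            f, tissue0 = init_free_water(
                dwi, single, self.d_water, self.md_tissue_init, eig_box=self.eig_box
            )
            f = f[mask].copy()
            D0 = tissue0.tensor[mask]
        else:
            f_map, tensor_map = init
            f = np.asarray(f_map, dtype=float)[mask].copy()
            D0 = np.asarray(tensor_map, dtype=float)[mask]
        D0 = clip_tensor_eigenvalues(D0, *self.eig_box)
        R = np.linalg.cholesky(tensor_to_matrix(D0))
        f_init = f.copy()

        a_idx, b_idx, _ = _mask_neighbours(mask)
        w_edge = _edge_weights(a_idx, b_idx, f_init, single.md()[mask])
        deg = np.zeros(N)
        np.add.at(deg, a_idx, w_edge)
        np.add.at(deg, b_idx, w_edge)

        # lower-triangular parameter slots of R: (row, col)
        tri = [(0, 0), (1, 0), (1, 1), (2, 0), (2, 1), (2, 2)]
        tri_r = [i for i, _ in tri]
        tri_c = [j for _, j in tri]

        m, E_t, V = self._forward(f, R, g, b, e_w)
        r = y_obs - m
        data_cost = (r**2).sum(axis=1)
        Rp = R[:, tri_r, tri_c]
        if self.lambda_reg == "auto":
            edge_pen = w_edge * (f[a_idx] - f[b_idx]) ** 2
            mean_edge = edge_pen.mean() if edge_pen.size else 0.0
            lam_reg = 0.01 * data_cost.mean() / max(mean_edge, 1e-4)
        else:
            lam_reg = float(self.lambda_reg)
        if self.lambda_tensor == "auto":
            ten_pen = (w_edge[:, None] * (Rp[a_idx] - Rp[b_idx]) ** 2).sum(axis=1)
            mean_ten = ten_pen.mean() if ten_pen.size else 0.0
            lam_ten = 0.01 * data_cost.mean() / max(mean_ten, 1e-7)
        else:
            lam_ten = float(self.lambda_tensor)
        # Gaussian prior on f, weighted by the estimated noise variance so
        # noise-free data are fit unconstrained (pure maximum likelihood).
        if self.f_prior_sd:
            sigma2_hat = float(np.median(data_cost)) / max(M, 1)
            w_prior = sigma2_hat / float(self.f_prior_sd) ** 2
        else:
            w_prior = 0.0

        mu = np.full(N, 1e-3)
        converged = np.zeros(N, dtype=bool)
        eye7 = np.eye(7)

        def _nb_all(f_, Rp_):
            nb_f = _neighbour_sum(f_, a_idx, b_idx, w_edge)
            nb_R = np.stack(
                [_neighbour_sum(Rp_[:, k], a_idx, b_idx, w_edge) for k in range(6)],
                axis=1,
            )
            return nb_f, nb_R

        def _pen_cost(f_, Rp_, nb_f, nb_R):
            return (
                lam_reg * (deg * f_**2 - 2.0 * f_ * nb_f)
                + w_prior * (f_ - f_init) ** 2
                + lam_ten * (deg[:, None] * Rp_**2 - 2.0 * Rp_ * nb_R).sum(axis=1)
            )

        nb_f, nb_R = _nb_all(f, Rp)
        cost = data_cost + _pen_cost(f, Rp, nb_f, nb_R)
        n_iter = 0
        for stage in range(2):
            if stage == 1:
                # The initial prior weight uses the residuals at the init,
                # which include init misfit and therefore over-estimate the
                # noise level (on noise-free data the prior must vanish).
                # Re-estimate sigma^2 at the stage-1 solution and re-run.
                if not self.f_prior_sd:
                    break
                sigma2_hat = float(np.median(data_cost)) / max(M, 1)
                w_prior_new = sigma2_hat / float(self.f_prior_sd) ** 2
                if w_prior_new >= 0.9 * w_prior:
                    break  # noise-dominated residuals: weight is already right
                w_prior = w_prior_new
                mu = np.full(N, 1e-3)
                converged = np.zeros(N, dtype=bool)
                cost = data_cost + _pen_cost(f, Rp, nb_f, nb_R)
            for it in range(self.max_iter):
                n_iter += 1
                # Jacobian of the model wrt (f, R lower-triangular entries)
                J = np.empty((N, M, 7))
                J[:, :, 0] = e_w - E_t
                coef = -(1.0 - f[:, None]) * b * E_t  # (N, M)
                for k, (i, j) in enumerate(tri):
                    J[:, :, k + 1] = coef * 2.0 * g[:, i] * V[:, :, j]
                A = np.einsum("nmi,nmj->nij", J, J)
                rhs = np.einsum("nmi,nm->ni", J, r)
                # Jacobi-coupled smoothness penalties and the init-centred f prior
                A[:, 0, 0] += lam_reg * deg + w_prior
                rhs[:, 0] -= lam_reg * (deg * f - nb_f) + w_prior * (f - f_init)
                for k in range(6):
                    A[:, k + 1, k + 1] += lam_ten * deg
                    rhs[:, k + 1] -= lam_ten * (deg * Rp[:, k] - nb_R[:, k])
                damp = A + mu[:, None, None] * (A * eye7) + 1e-14 * eye7
                try:
                    delta = np.linalg.solve(damp, rhs[..., None])[..., 0]
                except np.linalg.LinAlgError:  # pragma: no cover
                    delta = np.linalg.solve(damp + 1e-10 * eye7, rhs[..., None])[..., 0]

                f_new = np.clip(f + delta[:, 0], 0.0, 1.0)
                R_new = R.copy()
                for k, (i, j) in enumerate(tri):
                    R_new[:, i, j] += delta[:, k + 1]
                Rp_new = R_new[:, tri_r, tri_c]
                m_new, E_t_new, V_new = self._forward(f_new, R_new, g, b, e_w)
                r_new = y_obs - m_new
                data_new = (r_new**2).sum(axis=1)
                cost_new = data_new + _pen_cost(f_new, Rp_new, nb_f, nb_R)

                accept = cost_new < cost
                improve = np.where(accept, cost - cost_new, 0.0)
                f = np.where(accept, f_new, f)
                R = np.where(accept[:, None, None], R_new, R)
                m = np.where(accept[:, None], m_new, m)
                E_t = np.where(accept[:, None], E_t_new, E_t)
                V = np.where(accept[:, None, None], V_new, V)
                r = np.where(accept[:, None], r_new, r)
                data_cost = np.where(accept, data_new, data_cost)
                mu = np.where(accept, np.maximum(mu * 0.4, 1e-12), np.minimum(mu * 4.0, 1e8))
                small = self.tol * np.maximum(cost, 1e-30)
                converged |= (accept & (improve <= small)) | (mu >= 1e6)
                converged &= ~(accept & (improve > small))
                # negligible parameter motion also counts as converged (Jacobi
                # neighbour exchange can keep cost improvements above tol*cost
                # long after the estimates have stopped moving meaningfully)
                step_small = (np.abs(delta[:, 0]) < 1e-6) & (
                    np.abs(delta[:, 1:]).max(axis=1) < 1e-8
                )
                converged |= accept & step_small
                Rp = R[:, tri_r, tri_c]
                nb_f, nb_R = _nb_all(f, Rp)
                cost = data_cost + _pen_cost(f, Rp, nb_f, nb_R)

                if (it + 1) % self.project_every == 0:
                    D = matrix_to_tensor(R @ np.swapaxes(R, 1, 2))
                    D = clip_tensor_eigenvalues(D, *self.eig_box)
                    R = np.linalg.cholesky(tensor_to_matrix(D))
                    m, E_t, V = self._forward(f, R, g, b, e_w)
                    r = y_obs - m
                    data_cost = (r**2).sum(axis=1)
                    Rp = R[:, tri_r, tri_c]
                    nb_f, nb_R = _nb_all(f, Rp)
                    cost = data_cost + _pen_cost(f, Rp, nb_f, nb_R)
                if converged.all():
                    break

        D = matrix_to_tensor(R @ np.swapaxes(R, 1, 2))
        D = clip_tensor_eigenvalues(D, *self.eig_box)
        m, E_t, V = self._forward(
            f, np.linalg.cholesky(tensor_to_matrix(D)), g, b, e_w
        )
        rms = np.sqrt(((y_obs - m) ** 2).mean(axis=1))

        # debiased FA: tensor-estimate covariance from the Gauss-Newton
        # approximation in the packed-tensor parameterisation
        qd = np.stack(
            [
                g[:, 0] ** 2,
                2.0 * g[:, 0] * g[:, 1],
                g[:, 1] ** 2,
                2.0 * g[:, 0] * g[:, 2],
                2.0 * g[:, 1] * g[:, 2],
                g[:, 2] ** 2,
            ],
            axis=1,
        )  # (M, 6)
        JD = ((1.0 - f[:, None]) * b * E_t)[:, :, None] * qd[None, :, :]
        G = np.einsum("nmi,nmj->nij", JD, JD)
        sigma2_vox = rms**2 * M / max(M - 7, 1)
        covD = sigma2_vox[:, None, None] * _safe_inv(G)
        fa_deb_vec = fa_of_tensor_debiased(D, covD)

        shape = mask.shape
        tensor_map = np.zeros(shape + (6,))
        tensor_map[mask] = D
        f_map = np.zeros(shape)
        f_map[mask] = f
        conv_map = np.zeros(shape, dtype=bool)
        conv_map[mask] = converged
        res_map = np.zeros(shape)
        res_map[mask] = rms
        bound_map = np.zeros(shape, dtype=bool)
        bound_map[mask] = (f <= 1e-6) | (f >= 1.0 - 1e-6)
        fa_deb_map = np.zeros(shape)
        fa_deb_map[mask] = fa_deb_vec

        self.tensor_ = tensor_map
        self.fw_fraction_ = f_map
        self.converged_ = conv_map
        self.residual_ = res_map
        self.f_at_bound_ = bound_map
        self.s0_map_ = s0
        self.mask_ = mask.copy()
        self.invalid_ = single.invalid
        self.fa_debiased_ = fa_deb_map
        self.lambda_reg_ = lam_reg
        self.lambda_tensor_ = lam_ten
        self.f_prior_weight_ = w_prior
        self.f_init_ = f_init
        self.n_iter_ = n_iter
        return self

    def result(self) -> FreeWaterFit:
        return FreeWaterFit(
            tissue_tensor=TensorField(self.tensor_, self.s0_map_, self.mask_, self.invalid_),
            fw_fraction=self.fw_fraction_,
            converged=self.converged_,
            residual=self.residual_,
            f_at_bound=self.f_at_bound_,
            fa_debiased=self.fa_debiased_,
            n_iter=self.n_iter_,
        )


def fit_free_water(dwi: DWIVolume, init=None, **kwargs) -> FreeWaterFit:
    """Functional wrapper around :class:`FreeWaterFitter`."""
    return FreeWaterFitter(**kwargs).fit(dwi, init=init).result()
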