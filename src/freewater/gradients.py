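"""Gradient schemes (b-values and unit directions) for single-shell DWI.

The acquisitions emulated here use one b=0 volume plus 30 or 32 directions
at b = 1000 s/mm^2. Directions are laid out quasi-uniformly on a hemisphere
with a golden-angle spiral, which for n >= 6 yields a full-rank log-linear
tensor design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

DEFAULT_B = 1000.0  # s/mm^2, the single diffusion shell


@dataclass(frozen=True)
class GradientScheme:
    """b-values (s/mm^2) and unit gradient directions, one row per volume.

    b=0 volumes carry a zero direction vector. At least one b=0 volume and
    six distinct directions are required for the tensor to be identifiable.
    """

    bvals: np.ndarray
    bvecs: np.ndarray

    def __post_init__(self):
        bvals = np.asarray(self.bvals, dtype=float).ravel()
        bvecs = np.asarray(self.bvecs, dtype=float).reshape(-1, 3)
        if bvals.shape[0] != bvecs.shape[0]:
            raise ValueError("bvals and bvecs lengths differ")
        if bvals.shape[0] < 7:
            raise ValueError("at least 7 volumes (1 b0 + 6 directions) required")
        if np.any(bvals < 0):
            raise ValueError("negative b-value")
        dw = bvals > 0
        if dw.sum() < 6 or (~dw).sum() < 1:
            raise ValueError("scheme needs >= 1 b0 volume and >= 6 diffusion directions")
        norms = np.linalg.norm(bvecs[dw], axis=1)
        if np.any(np.abs(norms - 1.0) > 1e-6):
            raise ValueError("diffusion-weighted bvecs must have unit norm (tol 1e-6)")
        object.__setattr__(self, "bvals", bvals)
        object.__setattr__(self, "bvecs", bvecs)

    def __len__(self) -> int:
        return self.bvals.shape[0]

    @property
    def b0_mask(self) -> np.ndarray:
        return self.bvals == 0

    @property
    def n_b0(self) -> int:
        return int(self.b0_mask.sum())

    @property
    def n_directions(self) -> int:
        return int((~self.b0_mask).sum())

    def design_matrix(self) -> np.ndarray:
        """Log-linear tensor design, columns [ln S0, Dxx, Dxy, Dyy, Dxz, Dyz, Dzz].

        ln S = ln S0 - b g^T D g, so the tensor columns carry -b times the
        quadratic-form coefficients (off-diagonals doubled).
        """
        b = self.bvals
        gx, gy, gz = self.bvecs.T
        return np.column_stack(
            [
                np.ones_like(b),
                -b * gx * gx,
                -2 * b * gx * gy,
                -b * gy * gy,
                -2 * b * gx * gz,
                -2 * b * gy * gz,
                -b * gz * gz,
            ]
        )


def hemisphere_directions(n: int) -> np.ndarray:
    """n quasi-uniform unit vectors on the upper hemisphere (golden-angle spiral)."""
    if n < 1:
        raise ValueError("need at least one direction")
    i = np.arange(n)
    # z spans (0, 1]: one hemisphere; golden angle decorrelates azimuths
    z = (i + 0.5) / n
    phi = i * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z**2, 0.0, 1.0))
    return np.column_stack([r * np.cos(phi), r * np.sin(phi), z])


def make_gradient_scheme(n_dirs: int, b: float = DEFAULT_B, n_b0: int = 1) -> GradientScheme:
    """Build a single-shell scheme with ``n_b0`` b=0 volumes then ``n_dirs`` directions.

    Raises ``ValueError`` when the scheme would leave the tensor unidentifiable
    (fewer than six directions) or carry no b=0 reference.
    """
    if n_dirs < 6:
        raise ValueError("tensor is not identifiable with fewer than 6 directions")
    if n_b0 < 1:
        raise ValueError("at least one b=0 volume required")
    if b <= 0:
        raise ValueError("shell b-value must be positive")
    dirs = hemisphere_directions(n_dirs)
    bvals = np.concatenate([np.zeros(n_b0), np.full(n_dirs, float(b))])
    bvecs = np.vstack([np.zeros((n_b0, 3)), dirs])
    scheme = GradientScheme(bvals, bvecs)
    if np.linalg.matrix_rank(scheme.design_matrix()) < 7:
        raise ValueError("gradient design is rank deficient")  # pragma: no cover
    return scheme
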