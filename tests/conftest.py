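"""Shared fixtures and phantom helpers for the test suite."""

import numpy as np
import pytest

from freewater import GroundTruthPhantom, make_gradient_scheme
from freewater.simulate import LABEL_WM, simulate_dwi
from freewater.tensors import tensor_from_md_fa_axis


@pytest.fixture(scope="session")
def scheme30():
    """The study's default acquisition: 1 b=0 + 30 directions at b=1000."""
    return make_gradient_scheme(30)


def uniform_phantom(md, fa, f, grid=(10, 10, 10), axis=(1.0, 0.0, 0.0), s0=500.0):
    """A spatially uniform phantom: one tissue tensor, one free-water fraction."""
    grid = tuple(grid)
    mask = np.ones(grid, dtype=bool)
    n = int(mask.sum())
    tensor = np.zeros(grid + (6,))
    tensor[mask] = tensor_from_md_fa_axis(
        np.full(n, float(md)), np.full(n, float(fa)), np.tile(np.asarray(axis, float), (n, 1))
    )
    return GroundTruthPhantom(
        tissue_tensor=tensor,
        fw_fraction=np.full(grid, float(f)),
        mask=mask,
        tissue_label=np.full(grid, LABEL_WM, dtype=np.int8),
        s0=s0,
    )


def uniform_dwi(md, fa, f, grid=(10, 10, 10), scheme=None, snr_b0=np.inf, seed=0, **kwargs):
    """Simulate a DWI acquisition of a uniform phantom (noise-free by default)."""
    if scheme is None:
        scheme = make_gradient_scheme(30)
    phantom = uniform_phantom(md, fa, f, grid=grid, **kwargs)
    return simulate_dwi(phantom, scheme, snr_b0=snr_b0, seed=seed), phantom
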