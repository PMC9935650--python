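import numpy as np
import pytest

from freewater import DWIVolume, make_gradient_scheme
from freewater.fitting import (
    FreeWaterFitter,
    estimate_tissue_anchor,
    fit_free_water,
    fit_single_tensor,
    init_free_water,
)
from freewater.tensors import fa_of_tensor, matrix_to_tensor, md_of_tensor

from conftest import uniform_dwi


# ---------------------------------------------------------------- single tensor
def test_single_tensor_noise_free_oracle(scheme30):
    dwi, phantom = uniform_dwi(0.7e-3, 0.8704, 0.0, grid=(6, 6, 6), scheme=scheme30)
    st = fit_single_tensor(dwi)
    err = np.abs(st.tensor[dwi.mask] - phantom.tissue_tensor[dwi.mask])
    assert err.max() < 1e-9  # mm^2/s elementwise


def test_single_tensor_isotropy_forced(scheme30):
    a = 0.9e-3
    s0 = 400.0
    signal = np.full((5, 5, 5, 31), s0) * np.exp(-scheme30.bvals * a)
    dwi = DWIVolume(signal, scheme30, np.ones((5, 5, 5), bool))
    st = fit_single_tensor(dwi)
    expect = matrix_to_tensor(a * np.eye(3))
    assert np.allclose(st.tensor[dwi.mask], expect, atol=1e-12)
    assert np.allclose(st.s0_map[dwi.mask], s0)


def test_single_tensor_equals_tissue_at_f_zero(scheme30):
    dwi, phantom = uniform_dwi(0.8e-3, 0.4, 0.0, grid=(6, 6, 6), scheme=scheme30)
    st = fit_single_tensor(dwi)
    assert np.allclose(st.tensor[dwi.mask], phantom.tissue_tensor[dwi.mask], atol=1e-9)


def test_single_tensor_invalid_flagging(scheme30):
    dwi, _ = uniform_dwi(0.7e-3, 0.3, 0.0, grid=(5, 5, 5), scheme=scheme30)
    dwi.signal[2, 2, 2, 1:16] = 0.0  # half the volumes non-positive
    st = fit_single_tensor(dwi)
    assert st.invalid is not None
    assert st.invalid[2, 2, 2]
    assert np.all(st.tensor[2, 2, 2] == 0.0)
    assert not st.invalid[0, 0, 0]


def test_single_tensor_debiased_fa_below_raw_under_noise(scheme30):
    dwi, phantom = uniform_dwi(0.7e-3, 0.2, 0.0, grid=(12, 12, 12), scheme=scheme30,
                               snr_b0=30, seed=2)
    st = fit_single_tensor(dwi)
    raw = fa_of_tensor(st.tensor[dwi.mask]).mean()
    deb = st.fa_debiased[dwi.mask].mean()
    assert deb < raw  # debiasing removes noise inflation
    assert abs(deb - 0.2) < abs(raw - 0.2)


# ---------------------------------------------------------------- initialisation
def test_init_clips_at_lower_endpoint(scheme30):
    # single-tensor MD equal to the tissue reference -> f at the lower clip
    dwi, _ = uniform_dwi(0.6e-3, 0.0, 0.0, grid=(5, 5, 5), scheme=scheme30)
    f0, _ = init_free_water(dwi, md_tissue=0.6e-3)
    assert np.allclose(f0[dwi.mask], 0.05)


def test_init_clips_at_upper_endpoint(scheme30):
    # pure free-water signal -> single-tensor MD ~ d_w -> f at the upper clip
    dwi, _ = uniform_dwi(0.7e-3, 0.0, 1.0, grid=(5, 5, 5), scheme=scheme30)
    f0, _ = init_free_water(dwi, md_tissue=0.6e-3)
    assert np.allclose(f0[dwi.mask], 0.95)


def test_init_interpolation_formula(scheme30):
    # single-tensor MD 1.2e-3, b=1000, tissue 0.6e-3, d_w 3e-3:
    # f0 = (e^-1.2 - e^-0.6) / (e^-3 - e^-0.6) = 0.49622...
    dwi, _ = uniform_dwi(1.2e-3, 0.0, 0.0, grid=(5, 5, 5), scheme=scheme30)
    f0, _ = init_free_water(dwi, md_tissue=0.6e-3)
    expect = (np.exp(-1.2) - np.exp(-0.6)) / (np.exp(-3.0) - np.exp(-0.6))
    assert np.allclose(f0[dwi.mask], expect, atol=1e-6)
    assert expect == pytest.approx(0.4962, abs=1e-4)


def test_estimate_tissue_anchor_tracks_subject_md(scheme30):
    # high-FA phantom with true tissue MD 0.75e-3 and fw 0.05 (the prior's
    # nominal value): the anchor should land on the true tissue MD
    dwi, _ = uniform_dwi(0.75e-3, 0.5, 0.05, grid=(8, 8, 8), scheme=scheme30)
    st = fit_single_tensor(dwi)
    anchor = estimate_tissue_anchor(st, dwi.mask, 1000.0)
    assert np.allclose(anchor[dwi.mask], 0.75e-3, rtol=0.02)


def test_estimate_tissue_anchor_gm_ratio(scheme30):
    # low-FA voxels get the white-matter anchor scaled by the GM/WM ratio
    dwi, _ = uniform_dwi(0.75e-3, 0.1, 0.05, grid=(8, 8, 8), scheme=scheme30)
    st = fit_single_tensor(dwi)
    anchor = estimate_tissue_anchor(st, dwi.mask, 1000.0)
    fa = fa_of_tensor(st.tensor)
    assert (fa[dwi.mask] < 0.35).all()
    wm_anchor = estimate_tissue_anchor(st, dwi.mask, 1000.0, gm_wm_ratio=1.0)
    assert np.allclose(anchor[dwi.mask], 1.07 * wm_anchor[dwi.mask])


def test_init_rejects_unknown_md_tissue(scheme30):
    dwi, _ = uniform_dwi(0.7e-3, 0.3, 0.1, grid=(5, 5, 5), scheme=scheme30)
    with pytest.raises(ValueError):
        init_free_water(dwi, md_tissue="median")


# ---------------------------------------------------------------- free water fit
def test_free_water_noise_free_oracle_from_truth(scheme30):
    """Noise-free, initialised at truth, lambda_reg = 0: recovered f within
    0.01 and tissue MD within 1% of the generating values."""
    dwi, phantom = uniform_dwi(0.7e-3, 0.4, 0.3, grid=(6, 6, 6), scheme=scheme30)
    init = (phantom.fw_fraction, phantom.tissue_tensor)
    fit = fit_free_water(dwi, init=init, lambda_reg=0.0, f_prior_sd=None)
    assert np.abs(fit.fw_fraction[dwi.mask] - 0.3).max() < 0.01
    md = md_of_tensor(fit.tissue_tensor.tensor[dwi.mask])
    assert np.abs(md - 0.7e-3).max() < 0.01 * 0.7e-3


def test_free_water_noise_free_default_init(scheme30):
    """Anisotropy identifies f on noise-free data even from the default init."""
    dwi, _ = uniform_dwi(0.7e-3, 0.4, 0.3, grid=(6, 6, 6), scheme=scheme30)
    fit = fit_free_water(dwi)
    assert np.abs(fit.fw_fraction[dwi.mask] - 0.3).max() < 0.01
    md = md_of_tensor(fit.tissue_tensor.tensor[dwi.mask])
    assert np.abs(md - 0.7e-3).max() < 0.01 * 0.7e-3


def test_free_water_degenerate_single_compartment(scheme30):
    dwi, _ = uniform_dwi(0.8e-3, 0.4, 0.0, grid=(6, 6, 6), scheme=scheme30)
    fit = fit_free_water(dwi)
    st = fit_single_tensor(dwi)
    assert np.abs(fit.fw_fraction[dwi.mask]).max() < 0.02
    md_fw = md_of_tensor(fit.tissue_tensor.tensor[dwi.mask])
    md_st = md_of_tensor(st.tensor[dwi.mask])
    assert np.allclose(md_fw, md_st, rtol=0.01)


def test_free_water_snr30_known_reference(scheme30):
    """At snr_b0 = 30 with a correctly specified tissue reference, the
    in-mask median absolute f error stays below 0.05."""
    dwi, _ = uniform_dwi(0.7e-3, 0.4, 0.3, grid=(10, 10, 10), scheme=scheme30,
                         snr_b0=30, seed=1)
    fit = fit_free_water(dwi, md_tissue_init=0.7e-3)
    err = np.abs(fit.fw_fraction[dwi.mask] - 0.3)
    assert np.median(err) < 0.05


def test_free_water_snr30_cohort_phantom():
    """At snr_b0 = 30 on a calibrated cohort phantom (where the data-driven
    tissue reference is applicable), the in-mask median absolute f error
    stays below 0.05."""
    from freewater.simulate import CohortConfig, sample_cohort

    sub = sample_cohort(CohortConfig(n_good=2, n_poor=2), seed=2)[0]  # study grid 24^3
    fit = fit_free_water(sub.dwi)
    err = np.abs(fit.fw_fraction - sub.phantom.fw_fraction)[sub.dwi.mask]
    assert np.median(err) < 0.05


def test_free_water_estimator_is_sklearn_like(scheme30):
    dwi, _ = uniform_dwi(0.7e-3, 0.4, 0.2, grid=(5, 5, 5), scheme=scheme30)
    est = FreeWaterFitter(max_iter=20)
    params = est.get_params()
    assert params["d_water"] == 3.0e-3
    assert est.set_params(max_iter=30) is est
    fitted = est.fit(dwi)
    assert fitted is est
    res = est.result()
    assert res.fw_fraction.shape == dwi.grid_shape
    assert res.fa_debiased.shape == dwi.grid_shape
    assert res.converged.dtype == bool


def test_dwi_volume_validation(scheme30):
    with pytest.raises(ValueError):
        DWIVolume(np.ones((4, 4, 4)), scheme30, np.ones((4, 4, 4), bool))  # 3D signal
    with pytest.raises(ValueError):
        DWIVolume(np.ones((4, 4, 4, 30)), scheme30, np.ones((4, 4, 4), bool))  # bad count
    with pytest.raises(ValueError):
        DWIVolume(np.ones((4, 4, 4, 31)), scheme30, np.ones((5, 4, 4), bool))  # bad mask
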