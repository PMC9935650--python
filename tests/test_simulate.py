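import numpy as np
import pytest

from freewater.simulate import (
    CohortConfig,
    GOOD_CALIBRATION,
    LABEL_CSF_BORDER,
    LABEL_LESION,
    SubjectSpec,
    forward_signal,
    make_phantom,
    sample_cohort,
    sample_cohort_metrics,
    simulate_dwi,
    tissue_mask_ratio,
    wm_fa_for_whole_brain_fa,
    wm_weight,
)
from freewater.tensors import fa_of_tensor

from conftest import uniform_dwi, uniform_phantom


def _spec(**kw):
    base = dict(outcome="good", target_tissue_md=726e-6, target_wm_fa=0.45, seed=7)
    base.update(kw)
    return SubjectSpec(**base)


def test_phantom_hits_md_target():
    p = make_phantom(_spec())
    md = p.md_map()[p.tissue_mask]
    assert abs(md.mean() - 726e-6) <= 0.02 * 726e-6


def test_phantom_no_lesions_by_default():
    p = make_phantom(_spec())
    assert not (p.md_map()[p.tissue_mask] < 450e-6).any()
    assert (p.tissue_label == LABEL_LESION).sum() == 0


def test_phantom_lesion_fraction_count():
    p = make_phantom(_spec(outcome="poor", target_tissue_md=700e-6, lesion_fraction=0.18))
    n_mask = int(p.mask.sum())
    n_lesion = int((p.tissue_label == LABEL_LESION).sum())
    assert abs(n_lesion - 0.18 * n_mask) <= 1.0


def test_phantom_rim_is_free_water():
    p = make_phantom(_spec())
    rim = p.tissue_label == LABEL_CSF_BORDER
    assert rim.any()
    assert np.all(p.fw_fraction[rim] == 1.0)


def test_phantom_rejects_bad_spec():
    with pytest.raises(ValueError):
        SubjectSpec(outcome="good", target_tissue_md=-1.0, target_wm_fa=0.4)
    with pytest.raises(ValueError):
        SubjectSpec(outcome="poor", target_tissue_md=700e-6, target_wm_fa=0.4, lesion_fraction=1.5)
    with pytest.raises(ValueError):
        make_phantom(_spec(), grid_shape=(6, 6, 6))  # too small


def test_forward_signal_pure_free_water(scheme30):
    dwi, _ = uniform_dwi(0.7e-3, 0.3, 1.0, grid=(8, 8, 8), scheme=scheme30)
    dw = ~scheme30.b0_mask
    att = dwi.signal[4, 4, 4, dw] / dwi.signal[4, 4, 4, scheme30.b0_mask].mean()
    assert np.allclose(att, np.exp(-3.0), atol=5e-4)  # exp(-1000 * 3e-3) ~ 0.0498


def test_forward_signal_two_compartment_value(scheme30):
    # f=0.3, isotropic D=0.7e-3, b=1000 -> 0.7 e^-0.7 + 0.3 e^-3 ~ 0.3625
    dwi, _ = uniform_dwi(0.7e-3, 0.0, 0.3, grid=(8, 8, 8), scheme=scheme30)
    dw = ~scheme30.b0_mask
    att = dwi.signal[4, 4, 4, dw] / dwi.signal[4, 4, 4, scheme30.b0_mask].mean()
    expect = 0.7 * np.exp(-0.7) + 0.3 * np.exp(-3.0)
    assert np.allclose(att, expect, atol=5e-4)
    assert expect == pytest.approx(0.3625, abs=5e-4)


def test_simulate_dwi_noise_free_is_exact(scheme30):
    p = uniform_phantom(0.7e-3, 0.3, 0.1, grid=(8, 8, 8))
    exact = forward_signal(p, scheme30)
    dwi = simulate_dwi(p, scheme30, snr_b0=np.inf)
    assert np.array_equal(dwi.signal, exact)


def test_simulate_dwi_seed_reproducible(scheme30):
    p = uniform_phantom(0.7e-3, 0.3, 0.1, grid=(8, 8, 8))
    a = simulate_dwi(p, scheme30, snr_b0=30, seed=5)
    b = simulate_dwi(p, scheme30, snr_b0=30, seed=5)
    c = simulate_dwi(p, scheme30, snr_b0=30, seed=6)
    assert np.array_equal(a.signal, b.signal)
    assert not np.array_equal(a.signal, c.signal)


def test_rician_b0_mean_within_one_percent(scheme30):
    """Rician property: at snr_b0 >= 20, b0 mean over >= 1e4 voxels within 1% of s0."""
    p = uniform_phantom(0.7e-3, 0.3, 0.05, grid=(24, 24, 24))  # 13824 voxels
    dwi = simulate_dwi(p, scheme30, snr_b0=20, seed=0)
    b0 = dwi.signal[..., scheme30.b0_mask][p.mask]
    assert abs(b0.mean() - p.s0) <= 0.01 * p.s0


def test_simulate_dwi_rejects_bad_args(scheme30):
    p = uniform_phantom(0.7e-3, 0.3, 0.1, grid=(8, 8, 8))
    with pytest.raises(ValueError):
        simulate_dwi(p, scheme30, snr_b0=0.0)
    with pytest.raises(ValueError):
        simulate_dwi(p, scheme30, noise="poisson")


def test_sample_cohort_composition():
    subs = sample_cohort(CohortConfig(n_good=3, n_poor=2, grid_shape=(10, 10, 10), n_dirs=6), seed=0)
    assert len(subs) == 5
    outcomes = [s.clinical.outcome for s in subs]
    assert outcomes.count("good") == 3 and outcomes.count("poor") == 2
    assert len({s.subject_id for s in subs}) == 5


def test_sample_cohort_seed_reproducible():
    cfg = CohortConfig(n_good=2, n_poor=2, grid_shape=(10, 10, 10), n_dirs=6)
    a = sample_cohort(cfg, seed=3)
    b = sample_cohort(cfg, seed=3)
    for s, t in zip(a, b):
        assert np.array_equal(s.dwi.signal, t.dwi.signal)
        assert s.clinical == t.clinical


def test_sample_cohort_minimum_group_size():
    with pytest.raises(ValueError):
        sample_cohort(CohortConfig(n_good=1, n_poor=2), seed=0)


def test_cohort_metrics_median_tracks_calibration():
    """500 good-outcome draws: empirical median tissue MD within 1% of the
    calibrated median (Table 2 middle quartile atom)."""
    cfg = CohortConfig(n_good=500, n_poor=2)
    t = sample_cohort_metrics(cfg, seed=0)
    good = t[t.outcome == "good"]
    med = GOOD_CALIBRATION.md_quartiles[1]
    assert abs(np.median(good.mean_md) - med) <= 0.01 * med


def test_wm_fa_calibration_accounts_for_lesions():
    w = wm_weight((24, 24, 24))
    # with no lesions the tissue mixture mean hits the target exactly
    fa_wm = wm_fa_for_whole_brain_fa(0.30, w)
    assert w * fa_wm + (1 - w) * 0.15 == pytest.approx(0.30)
    # with a lesion share, the lesioned whole-brain mean hits the target
    fa_wm_l = wm_fa_for_whole_brain_fa(0.28, w, lesion_share=0.2)
    mixed = 0.2 * 0.15 + 0.8 * (w * fa_wm_l + (1 - w) * 0.15)
    assert mixed == pytest.approx(0.28)


def test_poor_phantom_ground_truth_fa_on_target():
    """Group-level ground-truth whole-brain FA matches the calibration target."""
    subs = sample_cohort(CohortConfig(n_good=2, n_poor=12, grid_shape=(16, 16, 16)), seed=4)
    fas = [
        fa_of_tensor(s.phantom.tissue_tensor[s.phantom.tissue_mask]).mean()
        for s in subs
        if s.clinical.outcome == "poor"
    ]
    # target 0.28, subject draws N(0.28, 0.03): mean of 12 within ~3 sd of the target
    assert abs(np.mean(fas) - 0.28) < 3 * 0.03 / np.sqrt(12)


def test_tissue_mask_ratio_bounds():
    r = tissue_mask_ratio((24, 24, 24))
    assert 0.5 < r < 1.0
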