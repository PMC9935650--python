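import numpy as np
import pandas as pd
import pytest

from freewater.groupstats import (
    cohens_d,
    cohens_d_from_samples,
    compare_groups,
    tfce_transform,
    voxelwise_permutation_test,
)


# ------------------------------------------------------------------ Cohen's d
def test_cohens_d_table2_fa_row():
    eff = cohens_d(0.30, 0.03, 30, 0.28, 0.03, 20)
    assert eff.d == pytest.approx(0.667, abs=5e-4)
    assert eff.ci_low == pytest.approx(0.085, abs=5e-3)
    assert eff.ci_high == pytest.approx(1.248, abs=5e-3)


def test_cohens_d_null_and_unit():
    assert cohens_d(5.0, 1.0, 10, 5.0, 1.0, 10).d == 0.0
    assert cohens_d(1.0, 1.0, 10, 0.0, 1.0, 10).d == pytest.approx(1.0)


def test_cohens_d_antisymmetry():
    a = cohens_d(0.30, 0.03, 30, 0.28, 0.03, 20)
    b = cohens_d(0.28, 0.03, 20, 0.30, 0.03, 30)
    assert a.d == pytest.approx(-b.d)


def test_cohens_d_validation():
    with pytest.raises(ValueError):
        cohens_d(1.0, 1.0, 1, 0.0, 1.0, 10)
    with pytest.raises(ValueError):
        cohens_d(1.0, 0.0, 10, 0.0, 1.0, 10)


def test_cohens_d_from_samples_matches_summaries():
    rng = np.random.default_rng(0)
    x = rng.normal(1.0, 1.0, 40)
    y = rng.normal(0.0, 1.0, 30)
    a = cohens_d_from_samples(x, y)
    b = cohens_d(x.mean(), x.std(ddof=1), 40, y.mean(), y.std(ddof=1), 30)
    assert a.d == pytest.approx(b.d)


# ------------------------------------------------------------- compare_groups
def _table(**cols):
    return pd.DataFrame(cols)


def test_compare_groups_shockable_rhythm_chi2():
    # Table 1: shockable first rhythm 30/30 (good) vs 15/20 (poor)
    outcome = ["good"] * 30 + ["poor"] * 20
    shock = [True] * 30 + [True] * 15 + [False] * 5
    out = compare_groups(_table(outcome=outcome, shockable_rhythm=shock))
    row = out.loc["shockable_rhythm"]
    assert row["test"] == "chi-squared"
    assert row["statistic"] == pytest.approx(8.33, abs=0.01)
    assert row["p"] < 0.01


def test_compare_groups_identical_samples_null():
    outcome = ["good"] * 5 + ["poor"] * 5
    vals = [1.0, 2.0, 3.0, 4.0, 5.0] * 2
    out = compare_groups(_table(outcome=outcome, x=vals))
    row = out.loc["x"]
    assert row["statistic"] == 0.0
    assert row["p"] == pytest.approx(1.0)


def test_compare_groups_nonnormal_uses_mann_whitney():
    rng = np.random.default_rng(0)
    outcome = ["good"] * 25 + ["poor"] * 25
    vals = np.concatenate([rng.lognormal(0, 1.5, 25), rng.lognormal(1.0, 1.5, 25)])
    out = compare_groups(_table(outcome=outcome, x=vals))
    assert out.loc["x", "test"] == "mann-whitney"


def test_compare_groups_continuous_carries_effect_size():
    rng = np.random.default_rng(1)
    outcome = ["good"] * 20 + ["poor"] * 20
    vals = np.concatenate([rng.normal(1.0, 1.0, 20), rng.normal(0.0, 1.0, 20)])
    out = compare_groups(_table(outcome=outcome, x=vals))
    row = out.loc["x"]
    assert np.isfinite(row["d"])
    assert row["d_ci_low"] <= row["d"] <= row["d_ci_high"]


def test_compare_groups_requires_two_groups():
    with pytest.raises(ValueError):
        compare_groups(_table(outcome=["good"] * 4, x=[1.0, 2.0, 3.0, 4.0]))


# ------------------------------------------------------------------ TFCE
def test_tfce_zero_and_negative_maps():
    assert np.all(tfce_transform(np.zeros((4, 4, 4))) == 0.0)
    assert np.all(tfce_transform(-np.ones((4, 4, 4))) == 0.0)


def test_tfce_monotone_under_scaling():
    rng = np.random.default_rng(0)
    stat = np.maximum(rng.normal(0.5, 1.0, (6, 6, 6)), 0.0)
    base = tfce_transform(stat)
    scaled = tfce_transform(1.5 * stat)
    assert np.all(scaled >= base - 1e-12)


def test_tfce_larger_cluster_scores_higher():
    a = np.zeros((8, 8, 8))
    a[1, 1, 1] = 2.0  # isolated voxel
    b = np.zeros((8, 8, 8))
    b[4:7, 4:7, 4:7] = 2.0  # 27-voxel cluster at the same height
    assert tfce_transform(b)[5, 5, 5] > tfce_transform(a)[1, 1, 1]


# --------------------------------------------------- voxelwise permutation test
def test_voxelwise_degenerate_null_no_significance():
    maps = np.ones((12, 5, 5, 5))  # identical constant maps
    labels = np.array(["good"] * 6 + ["poor"] * 6)
    res = voxelwise_permutation_test(maps, labels, n_perm=100, alpha=0.05)
    assert res.sig_mask.sum() == 0
    assert np.all(res.stat_map == 0.0)


def test_voxelwise_power_detects_implanted_effect():
    rng = np.random.default_rng(0)
    grid = (8, 8, 8)
    maps = rng.normal(0.0, 1.0, (30 + 20,) + grid)
    region = np.s_[2:5, 2:5, 2:5]
    maps[(slice(30, 50),) + region] += 3.0  # +3 SD offset in the poor group
    labels = np.array(["good"] * 30 + ["poor"] * 20)
    res = voxelwise_permutation_test(maps, labels, n_perm=500, alpha=0.01, seed=1)
    sig_region = res.sig_mask[region]
    assert sig_region.mean() > 0.9  # region flagged
    outside = res.sig_mask.copy()
    outside[region] = False
    assert outside.sum() <= 2  # essentially nothing else


def test_voxelwise_exact_enumeration_small_n():
    rng = np.random.default_rng(2)
    maps = rng.normal(0.0, 1.0, (8, 4, 4, 4))
    labels = np.array(["good"] * 4 + ["poor"] * 4)  # comb(8,4)=70 < n_perm
    with pytest.warns(UserWarning, match="enumerating exactly"):
        res = voxelwise_permutation_test(maps, labels, n_perm=1000, alpha=0.05)
    assert res.exact
    assert res.n_perm == 70


def test_voxelwise_tfce_method_runs():
    rng = np.random.default_rng(3)
    maps = rng.normal(0.0, 1.0, (12, 5, 5, 5))
    maps[6:, 1:3, 1:3, 1:3] += 4.0
    labels = np.array(["good"] * 6 + ["poor"] * 6)
    res = voxelwise_permutation_test(maps, labels, n_perm=100, alpha=0.05, method="tfce", seed=0)
    assert res.method == "tfce"
    assert res.p_fwe_map.min() >= 0.0 and res.p_fwe_map.max() <= 1.0


def test_voxelwise_validation():
    maps = np.zeros((10, 4, 4, 4))
    labels = np.array(["good"] * 5 + ["poor"] * 5)
    with pytest.raises(ValueError):
        voxelwise_permutation_test(maps, labels, n_perm=50)  # too few permutations
    with pytest.raises(ValueError):
        voxelwise_permutation_test(maps[..., 0], labels)  # not 4D
    with pytest.raises(ValueError):
        voxelwise_permutation_test(maps, np.array(["good"] * 10))  # one group
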