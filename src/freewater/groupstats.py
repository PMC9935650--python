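"""Group comparisons: descriptive tests, Cohen's d, voxelwise permutation.

The voxelwise layer re-implements max-statistic permutation inference with
family-wise error control on spatially aligned scalar maps (two-sample
pooled-variance t statistic, sign convention positive = good > poor), with
an optional threshold-free cluster enhancement (TFCE) variant using the
conventional E = 0.5, H = 2, dh = 0.1 constants and 26-neighbourhood
connectivity.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass
from math import comb

import numpy as np
import pandas as pd
from scipy import ndimage, stats

_CONN26 = np.ones((3, 3, 3), dtype=int)


@dataclass(frozen=True)
class EffectSize:
    """Cohen's d with a normal-approximation 95% confidence interval."""

    d: float
    ci_low: float
    ci_high: float

    def __post_init__(self):
        if not (self.ci_low <= self.d <= self.ci_high):
            raise ValueError("confidence interval must bracket d")


@dataclass
class VoxelwiseResult:
    stat_map: np.ndarray  # signed two-sample t, positive = good > poor
    p_fwe_map: np.ndarray
    sig_mask: np.ndarray
    n_perm: int
    method: str
    exact: bool = False


def cohens_d(mean1, sd1, n1, mean2, sd2, n2, ci_level: float = 0.95) -> EffectSize:
    """Cohen's d from group summaries, with pooled SD.

    d = (mean1 - mean2) / s_pooled,
    s_pooled = sqrt(((n1-1) sd1^2 + (n2-1) sd2^2) / (n1+n2-2)),
    SE(d) = sqrt((n1+n2)/(n1 n2) + d^2/(2(n1+n2-2))) (normal approximation).
    """
    if n1 < 2 or n2 < 2:
        raise ValueError("each group needs n >= 2")
    if sd1 <= 0 or sd2 <= 0:
        raise ValueError("degenerate (non-positive) standard deviation")
    dof = n1 + n2 - 2
    sp = np.sqrt(((n1 - 1) * sd1**2 + (n2 - 1) * sd2**2) / dof)
    d = (mean1 - mean2) / sp
    se = np.sqrt((n1 + n2) / (n1 * n2) + d**2 / (2 * dof))
    z = stats.norm.ppf(0.5 + ci_level / 2)
    return EffectSize(float(d), float(d - z * se), float(d + z * se))


def cohens_d_from_samples(x, y, **kwargs) -> EffectSize:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    return cohens_d(x.mean(), x.std(ddof=1), len(x), y.mean(), y.std(ddof=1), len(y), **kwargs)


def _is_categorical(series: pd.Series) -> bool:
    return (
        series.dtype == bool
        or series.dtype == object
        or isinstance(series.dtype, pd.CategoricalDtype)
        or series.nunique() <= 2
    )


def _summary_continuous(x, normal: bool) -> str:
    x = np.asarray(x, dtype=float)
    if normal:
        return f"{x.mean():.3g} ± {x.std(ddof=1):.3g}"
    q25, q50, q75 = np.percentile(x, [25, 50, 75])
    return f"{q50:.3g} [{q25:.3g}–{q75:.3g}]"


def compare_groups(
    table: pd.DataFrame,
    group_col: str = "outcome",
    variables=None,
    normality_alpha: float = 0.05,
) -> pd.DataFrame:
    """Per-variable two-group tests with publication-style summaries.

    Continuous variables are screened for normality (Shapiro-Wilk at
    ``normality_alpha`` in both groups): near-normal ones get a Student
    t-test and mean ± SD summaries, the rest Mann-Whitney U and
    median [IQR]. Categorical variables get a chi-squared test (no
    continuity correction) and n (%) summaries. Continuous rows also carry
    Cohen's d with its 95% CI.
    """
    groups = list(pd.unique(table[group_col]))
    if len(groups) != 2:
        raise ValueError("exactly two outcome groups required")
    if "good" in groups:  # keep the conventional good-vs-poor ordering
        groups = ["good"] + [g for g in groups if g != "good"]
    g1 = table[table[group_col] == groups[0]]
    g2 = table[table[group_col] == groups[1]]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("each group needs n >= 2")
    if variables is None:
        variables = [c for c in table.columns if c != group_col]

    rows = []
    for var in variables:
        x1, x2 = g1[var], g2[var]
        if _is_categorical(table[var]):
            ct = pd.crosstab(table[group_col], table[var])
            chi2, p, _, _ = stats.chi2_contingency(ct.values, correction=False)
            top = table[var].mode().iloc[0]
            s1 = f"{(x1 == top).sum()} ({100 * (x1 == top).mean():.0f}%)"
            s2 = f"{(x2 == top).sum()} ({100 * (x2 == top).mean():.0f}%)"
            rows.append(
                dict(variable=var, kind="categorical", test="chi-squared",
                     statistic=float(chi2), p=float(p),
                     summary_1=s1, summary_2=s2, d=np.nan, d_ci_low=np.nan, d_ci_high=np.nan)
            )
        else:
            a1 = np.asarray(x1, dtype=float)
            a2 = np.asarray(x2, dtype=float)
            normal = (
                stats.shapiro(a1).pvalue > normality_alpha
                and stats.shapiro(a2).pvalue > normality_alpha
            )
            if np.var(a1) == 0 and np.var(a2) == 0 and a1.mean() == a2.mean():
                test, stat, p = "t-test", 0.0, 1.0
                normal = True
            elif normal:
                res = stats.ttest_ind(a1, a2, equal_var=True)
                test, stat, p = "t-test", float(res.statistic), float(res.pvalue)
            else:
                res = stats.mannwhitneyu(a1, a2, alternative="two-sided")
                test, stat, p = "mann-whitney", float(res.statistic), float(res.pvalue)
            try:
                eff = cohens_d_from_samples(a1, a2)
                d, lo, hi = eff.d, eff.ci_low, eff.ci_high
            except ValueError:
                d = lo = hi = np.nan
            rows.append(
                dict(variable=var, kind="continuous", test=test, statistic=stat, p=p,
                     summary_1=_summary_continuous(a1, normal),
                     summary_2=_summary_continuous(a2, normal),
                     d=d, d_ci_low=lo, d_ci_high=hi)
            )
    out = pd.DataFrame(rows).set_index("variable")
    out.attrs["groups"] = tuple(groups)
    return out


# --------------------------------------------------------------------------
# voxelwise permutation inference
# --------------------------------------------------------------------------

def _t_maps(X: np.ndarray, member: np.ndarray) -> np.ndarray:
    """Two-sample pooled-variance t maps for many group assignments at once.

    X: (n_subjects, n_voxels); member: (n_assignments, n_subjects) boolean
    group-1 membership (each row has the same group sizes). Returns
    (n_assignments, n_voxels); 0/0 degeneracies map to 0.
    """
    member = member.astype(float)
    n = X.shape[0]
    n1 = member[0].sum()
    n2 = n - n1
    tot = X.sum(axis=0)
    totsq = (X**2).sum(axis=0)
    s1 = member @ X
    ss1 = member @ (X**2)
    s2 = tot - s1
    ss2 = totsq - ss1
    m1 = s1 / n1
    m2 = s2 / n2
    v1 = np.maximum(ss1 - n1 * m1**2, 0.0) / (n1 - 1)
    v2 = np.maximum(ss2 - n2 * m2**2, 0.0) / (n2 - 1)
    sp2 = ((n1 - 1) * v1 + (n2 - 1) * v2) / (n1 + n2 - 2)
    denom = np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2))
    diff = m1 - m2
    with np.errstate(invalid="ignore", divide="ignore"):
        t = np.where(denom > 0, diff / np.where(denom > 0, denom, 1.0), 0.0)
    return t


def tfce_transform(stat_map: np.ndarray, mask=None, e: float = 0.5, h: float = 2.0, dh: float = 0.1) -> np.ndarray:
    """Threshold-free cluster enhancement of a non-negative statistic map.

    score(v) = sum over thresholds th (steps of dh) of
               extent(component of v at th)^e * th^h * dh,
    with 26-neighbourhood components. Negative input values score 0.
    """
    stat = np.asarray(stat_map, dtype=float)
    if mask is not None:
        stat = np.where(mask, stat, 0.0)
    out = np.zeros_like(stat)
    top = float(stat.max())
    if top <= 0:
        return out
    for th in np.arange(dh, top + dh, dh):
        sup = stat >= th
        if not sup.any():
            break
        labels, n_lab = ndimage.label(sup, structure=_CONN26)
        sizes = np.bincount(labels.ravel())
        out[sup] += sizes[labels[sup]] ** e * th**h * dh
    return out


def _signed_tfce(t_map_3d, mask, **kw):
    """Two-sided TFCE magnitude: max of positive- and negative-part scores."""
    pos = tfce_transform(t_map_3d, mask, **kw)
    neg = tfce_transform(-t_map_3d, mask, **kw)
    return np.maximum(pos, neg)


def voxelwise_permutation_test(
    maps,
    labels,
    n_perm: int = 1000,
    alpha: float = 0.01,
    method: str = "maxstat",
    mask=None,
    seed: int = 0,
    tfce_params=None,
) -> VoxelwiseResult:
    """FWE-corrected two-group voxelwise comparison on aligned maps.

    ``maps`` is (n_subjects, X, Y, Z); ``labels`` holds two outcome values
    ('good' is group 1 when present, so positive stats mean good > poor).
    FWE control is by the permutation distribution of the maximum |t|
    across voxels (``method="maxstat"``) or of the maximum two-sided TFCE
    score (``method="tfce"``). p_fwe = (1 + #{perm max >= observed}) /
    (1 + n_perm); when fewer distinct label permutations exist than
    ``n_perm``, they are enumerated exactly (with a warning).
    """
    maps = np.asarray(maps, dtype=float)
    labels = np.asarray(labels)
    if maps.ndim != 4 or maps.shape[0] != labels.shape[0]:
        raise ValueError("maps must be (n_subjects, X, Y, Z) matching labels")
    if n_perm < 100:
        raise ValueError("n_perm must be >= 100")
    if method not in ("maxstat", "tfce"):
        raise ValueError("method must be 'maxstat' or 'tfce'")
    uniq = list(pd.unique(labels))
    if len(uniq) != 2:
        raise ValueError("labels must contain exactly two groups")
    group1 = "good" if "good" in uniq else uniq[0]
    g1 = labels == group1
    n = len(labels)
    n1 = int(g1.sum())
    grid = maps.shape[1:]
    if mask is None:
        mask = np.ones(grid, dtype=bool)
    mask = np.asarray(mask, dtype=bool)
    X = maps[:, mask]

    n_distinct = comb(n, n1)
    exact = n_distinct <= n_perm
    if exact:
        warnings.warn(
            f"only {n_distinct} distinct permutations; enumerating exactly",
            UserWarning,
        )
        members = np.zeros((n_distinct, n), dtype=bool)
        for i, c in enumerate(itertools.combinations(range(n), n1)):
            members[i, list(c)] = True
    else:
        rng = np.random.default_rng(seed)
        members = np.zeros((n_perm, n), dtype=bool)
        for i in range(n_perm):
            members[i, rng.choice(n, n1, replace=False)] = True

    t_obs = _t_maps(X, g1[None, :])[0]
    t_perm = _t_maps(X, members)

    if method == "maxstat":
        obs_score = np.abs(t_obs)
        max_null = np.abs(t_perm).max(axis=1) if X.shape[1] else np.zeros(len(members))
    else:
        kw = dict(tfce_params or {})
        obs3 = np.zeros(grid)
        obs3[mask] = t_obs
        score3 = _signed_tfce(obs3, mask, **kw)
        obs_score = score3[mask]
        max_null = np.empty(len(members))
        buf = np.zeros(grid)
        for i in range(len(members)):
            buf[mask] = t_perm[i]
            max_null[i] = _signed_tfce(buf, mask, **kw).max()

    if exact:
        p_in = (max_null[None, :] >= obs_score[:, None]).mean(axis=1)
    else:
        p_in = (1.0 + (max_null[None, :] >= obs_score[:, None]).sum(axis=1)) / (1.0 + len(members))

    stat_map = np.zeros(grid)
    stat_map[mask] = t_obs
    p_map = np.ones(grid)
    p_map[mask] = p_in
    return VoxelwiseResult(
        stat_map=stat_map,
        p_fwe_map=p_map,
        sig_mask=p_map < alpha,
        n_perm=len(members),
        method=method,
        exact=exact,
    )
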