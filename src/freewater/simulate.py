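"""Synthetic phantoms, noisy DWI, and calibrated two-group cohorts.

The generator emulates a post-cardiac-arrest DTI cohort: layered spherical
phantoms (anisotropic white-matter core, quasi-isotropic grey-matter shell
with elevated free-water fraction, a one-voxel CSF-border rim with f = 1),
optional cytotoxic-injury lesions (contiguous low-MD blobs) and a scattered
low-MD tail, imaged with a single-shell scheme under Rician noise.

Cohort-level calibration targets the published group structure: good-outcome
whole-brain tissue MD centred on 726e-6 mm^2/s vs poor-outcome 663e-6,
whole-brain FA 0.30 vs 0.28, and %MD450 medians 3.4% vs 18%. Subject-level
MD and %MD450 are drawn from three-point empirical distributions at the
printed quartiles, coupled through a single severity draw per subject.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gradients import GradientScheme, make_gradient_scheme
from .tensors import axial_delta_for_fa, md_of_tensor, tensor_from_md_fa_axis

D_WATER = 3.0e-3  # mm^2/s, free-water diffusivity at body temperature

LABEL_WM = 1
LABEL_GM = 2
LABEL_LESION = 3
LABEL_CSF_BORDER = 4
LABEL_NAMES = {LABEL_WM: "WM", LABEL_GM: "GM", LABEL_LESION: "lesion", LABEL_CSF_BORDER: "CSF-border"}

# phantom eigenvalue admissibility box (mm^2/s)
EIG_LOW = 0.05e-3
EIG_HIGH = 3.0e-3

FA_GM = 0.15
FA_LESION = 0.15  # mean FA of implanted cytotoxic-oedema lesions
MD_WM_BASE = 750e-6
MD_GM_BASE = 800e-6
LESION_MD_RANGE = (300e-6, 430e-6)
# cytotoxic oedema shrinks the extracellular space, so lesion free water is low
LESION_FW_RANGE = (0.02, 0.08)


@dataclass(frozen=True)
class ClinicalRecord:
    """Per-subject clinical covariates and the dichotomised CPC outcome."""

    age: float
    sex: str  # {"M", "F"}
    duration_resus: float  # minutes
    shockable_rhythm: bool
    first_lactate: float  # mmol/L
    eeg_category: str  # {"I", "II", "III"}
    outcome: str  # {"good": CPC 1-2, "poor": CPC 3-5}

    def __post_init__(self):
        if self.age <= 0:
            raise ValueError("age must be positive")
        if self.duration_resus <= 0:
            raise ValueError("duration_resus must be positive")
        if self.sex not in ("M", "F"):
            raise ValueError("sex must be 'M' or 'F'")
        if self.eeg_category not in ("I", "II", "III"):
            raise ValueError("eeg_category must be one of I, II, III")
        if self.outcome not in ("good", "poor"):
            raise ValueError("outcome must be 'good' or 'poor'")


@dataclass(frozen=True)
class SubjectSpec:
    """Ground-truth parameters for one synthetic subject."""

    outcome: str
    target_tissue_md: float  # mm^2/s, subject mean tissue MD
    target_wm_fa: float
    lesion_fraction: float = 0.0  # contiguous lesion voxels / mask voxels
    low_md_tail_fraction: float = 0.0  # scattered sub-450 voxels / mask voxels
    clinical: ClinicalRecord | None = None
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.lesion_fraction <= 1.0:
            raise ValueError("lesion_fraction must lie in [0, 1]")
        if not 0.0 <= self.low_md_tail_fraction <= 1.0:
            raise ValueError("low_md_tail_fraction must lie in [0, 1]")
        if self.target_tissue_md <= 0:
            raise ValueError("target_tissue_md must be positive")


@dataclass
class GroundTruthPhantom:
    """Voxelwise ground truth: tissue tensor, free-water fraction, labels."""

    tissue_tensor: np.ndarray  # (X, Y, Z, 6) packed, mm^2/s
    fw_fraction: np.ndarray  # (X, Y, Z) in [0, 1]
    mask: np.ndarray  # (X, Y, Z) bool
    tissue_label: np.ndarray  # (X, Y, Z) int codes, 0 outside mask
    s0: float = 500.0
    voxel_size: tuple = (2.0, 2.0, 2.0)

    @property
    def tissue_mask(self) -> np.ndarray:
        """In-mask voxels excluding the CSF-border rim."""
        return self.mask & (self.tissue_label != LABEL_CSF_BORDER)

    def md_map(self) -> np.ndarray:
        return md_of_tensor(self.tissue_tensor)


def _geometry(grid_shape, wm_volume_fraction=0.5):
    """Radial layer labels for a spherical phantom on the given grid."""
    grid_shape = tuple(int(s) for s in grid_shape)
    if len(grid_shape) != 3 or min(grid_shape) < 8:
        raise ValueError("grid_shape must be 3 dimensions, each >= 8")
    center = (np.array(grid_shape) - 1) / 2.0
    idx = np.indices(grid_shape).astype(float)
    r = np.sqrt(((idx - center[:, None, None, None]) ** 2).sum(axis=0))
    r_outer = min(grid_shape) / 2.0 - 1.0
    r_tissue = r_outer - 1.0  # one-voxel CSF-border rim
    r_wm = r_tissue * wm_volume_fraction ** (1.0 / 3.0)
    label = np.zeros(grid_shape, dtype=np.int8)
    label[r <= r_outer] = LABEL_CSF_BORDER
    label[r <= r_tissue] = LABEL_GM
    label[r <= r_wm] = LABEL_WM
    return label, r, center


def tissue_mask_ratio(grid_shape, wm_volume_fraction=0.5) -> float:
    """Tissue (WM+GM) voxel count over full mask count for the phantom geometry."""
    label, _, _ = _geometry(grid_shape, wm_volume_fraction)
    mask = label > 0
    tissue = (label == LABEL_WM) | (label == LABEL_GM)
    return float(tissue.sum()) / float(mask.sum())


def wm_weight(grid_shape, wm_volume_fraction=0.5) -> float:
    """WM voxel count over tissue voxel count for the phantom geometry."""
    label, _, _ = _geometry(grid_shape, wm_volume_fraction)
    wm = (label == LABEL_WM).sum()
    gm = (label == LABEL_GM).sum()
    return float(wm) / float(wm + gm)


def wm_fa_for_whole_brain_fa(fa_target, w_wm, fa_gm=FA_GM, lesion_share=0.0, fa_lesion=FA_LESION):
    """WM FA needed so the tissue-volume mean FA hits ``fa_target``.

    ``lesion_share`` is the fraction of tissue voxels replaced by implanted
    lesions (mean FA ``fa_lesion``); the rest is a WM/GM mixture with WM
    weight ``w_wm``. Ignoring the lesion share would make heavily lesioned
    (poor-outcome) subjects undershoot their whole-brain FA target.
    """
    normal = (fa_target - lesion_share * fa_lesion) / max(1.0 - lesion_share, 1e-6)
    return np.clip((normal - (1.0 - w_wm) * fa_gm) / w_wm, 0.05, 0.75)


def _smooth_axis_field(grid_shape, center):
    """A smoothly varying unit principal-axis field (tangential fibre layout)."""
    idx = np.indices(grid_shape).astype(float)
    rel = idx - center[:, None, None, None]
    # tangent to circles around the z axis, tilted out of plane
    ax = np.stack([-rel[1], rel[0], 0.35 * np.ones(grid_shape)], axis=-1)
    norm = np.linalg.norm(ax, axis=-1, keepdims=True)
    fallback = np.array([1.0, 0.0, 0.0])
    ax = np.where(norm > 1e-6, ax / np.maximum(norm, 1e-6), fallback)
    return ax


def _grow_lesions(rng, label, r, r_tissue, n_target):
    """Grow spherical blobs in GM / superficial WM until exactly n_target voxels.

    Returns a boolean lesion map with exactly ``n_target`` voxels; the final
    blob is trimmed voxel-by-voxel (farthest from its centre first).
    """
    tissue = (label == LABEL_WM) | (label == LABEL_GM)
    superficial = tissue & (r >= 0.55 * r_tissue)
    candidates = np.argwhere(superficial)
    if n_target > tissue.sum():
        raise ValueError("lesion_fraction exceeds achievable tissue volume")
    lesion = np.zeros(label.shape, dtype=bool)
    idx = np.indices(label.shape).astype(float)
    guard = 0
    while lesion.sum() < n_target:
        guard += 1
        if guard > 10000:  # pragma: no cover
            raise RuntimeError("lesion growth failed to reach target volume")
        c = candidates[rng.integers(len(candidates))]
        radius = rng.uniform(1.5, 3.5)
        d2 = ((idx - c[:, None, None, None]) ** 2).sum(axis=0)
        blob = (d2 <= radius**2) & tissue & ~lesion
        deficit = n_target - lesion.sum()
        if blob.sum() > deficit:
            # trim: keep the voxels closest to the blob centre
            coords = np.argwhere(blob)
            dist = d2[tuple(coords.T)]
            keep = coords[np.argsort(dist, kind="stable")[:deficit]]
            blob = np.zeros_like(blob)
            blob[tuple(keep.T)] = True
        lesion |= blob
    return lesion


def make_phantom(spec: SubjectSpec, grid_shape=(24, 24, 24), wm_volume_fraction=0.5) -> GroundTruthPhantom:
    """Build the layered ground-truth phantom for one subject.

    The whole-mask mean tissue MD is matched to ``spec.target_tissue_md``
    (within 2%) by scaling the non-lesion tissue MD after implanting lesions
    and the low-MD tail; the CSF-border rim's (physically irrelevant) tissue
    tensor is set isotropic at the tissue-mean MD so that whole-mask and
    tissue-only means coincide.
    """
    rng = np.random.default_rng(spec.seed)
    label, r, center = _geometry(grid_shape, wm_volume_fraction)
    mask = label > 0
    n_mask = int(mask.sum())
    r_outer = min(grid_shape) / 2.0 - 1.0
    r_tissue = r_outer - 1.0

    # base fields with mild voxelwise heterogeneity
    md = np.zeros(grid_shape)
    fa = np.zeros(grid_shape)
    fw = np.zeros(grid_shape)
    wm = label == LABEL_WM
    gm = label == LABEL_GM
    rim = label == LABEL_CSF_BORDER
    md[wm] = MD_WM_BASE * rng.lognormal(0.0, 0.02, wm.sum())
    md[gm] = MD_GM_BASE * rng.lognormal(0.0, 0.02, gm.sum())
    fa[wm] = np.clip(spec.target_wm_fa + rng.normal(0.0, 0.02, wm.sum()), 0.02, 0.85)
    fa[gm] = np.clip(FA_GM + rng.normal(0.0, 0.02, gm.sum()), 0.02, 0.5)
    fw[wm] = rng.uniform(0.02, 0.10, wm.sum())
    fw[gm] = rng.uniform(0.20, 0.40, gm.sum())
    fw[rim] = 1.0

    # contiguous lesion blobs (poor outcome): cytotoxic injury, MD in [300, 430]e-6
    n_lesion = int(round(spec.lesion_fraction * n_mask))
    if n_lesion > 0:
        lesion = _grow_lesions(rng, label, r, r_tissue, n_lesion)
        label[lesion] = LABEL_LESION
        md[lesion] = rng.uniform(*LESION_MD_RANGE, lesion.sum())
        fa[lesion] = np.clip(rng.normal(FA_LESION, 0.03, lesion.sum()), 0.02, 0.4)
        fw[lesion] = rng.uniform(*LESION_FW_RANGE, lesion.sum())
    else:
        lesion = np.zeros(grid_shape, dtype=bool)

    # scattered low-MD tail (single voxels, host tissue label retained)
    n_tail = int(round(spec.low_md_tail_fraction * n_mask))
    tail = np.zeros(grid_shape, dtype=bool)
    if n_tail > 0:
        pool = np.argwhere(gm & ~lesion)
        if n_tail > len(pool):  # fall back to WM if GM is exhausted
            pool = np.argwhere((gm | wm) & ~lesion)
        if n_tail > len(pool):
            raise ValueError("low_md_tail_fraction exceeds achievable tissue volume")
        pick = pool[rng.choice(len(pool), n_tail, replace=False)]
        tail[tuple(pick.T)] = True
        md[tail] = rng.uniform(*LESION_MD_RANGE, n_tail)
        fw[tail] = rng.uniform(*LESION_FW_RANGE, n_tail)

    # scale adjustable tissue MD so the tissue mean hits the target
    tissue = mask & ~rim
    fixed = lesion | tail
    adjustable = tissue & ~fixed
    n_t = tissue.sum()
    target_sum = spec.target_tissue_md * n_t
    scale = (target_sum - md[fixed & tissue].sum()) / md[adjustable].sum()
    if scale <= 0:
        raise ValueError("target_tissue_md unreachable with the implanted lesion load")
    md[adjustable] *= scale
    # keep axisymmetric eigenvalues inside the phantom admissibility box
    delta = np.zeros(grid_shape)
    delta[tissue] = axial_delta_for_fa(fa[tissue])
    with np.errstate(divide="ignore", invalid="ignore"):
        md_hi = EIG_HIGH / (1.0 + 2.0 * delta)
        md_lo = EIG_LOW / np.maximum(1.0 - delta, 1e-6)
    md[tissue] = np.clip(md[tissue], md_lo[tissue], md_hi[tissue])
    mean_md = md[tissue].mean()
    if abs(mean_md - spec.target_tissue_md) > 0.02 * spec.target_tissue_md:
        raise ValueError("phantom mean tissue MD missed its target by more than 2%")

    md[rim] = mean_md  # rim tissue tensor is masked by f = 1 in the signal
    fa[rim] = 0.0

    axis = _smooth_axis_field(grid_shape, center)
    tensor = np.zeros(grid_shape + (6,))
    tensor[mask] = tensor_from_md_fa_axis(md[mask], fa[mask], axis[mask])
    return GroundTruthPhantom(
        tissue_tensor=tensor,
        fw_fraction=fw,
        mask=mask,
        tissue_label=label,
    )


def forward_signal(phantom: GroundTruthPhantom, scheme: GradientScheme, d_water: float = D_WATER) -> np.ndarray:
    """Noise-free two-compartment signal, zero outside the mask.

    Per voxel and volume: s0 * [(1-f) exp(-b g^T D g) + f exp(-b d_water)].
    """
    mask = phantom.mask
    f = phantom.fw_fraction[mask]
    D = phantom.tissue_tensor[mask]  # (N, 6) packed
    b = scheme.bvals
    g = scheme.bvecs
    # q[n, m] = g_m^T D_n g_m via packed quadratic form
    gx, gy, gz = g.T
    q = (
        D[:, 0:1] * gx**2
        + D[:, 2:3] * gy**2
        + D[:, 5:6] * gz**2
        + 2 * D[:, 1:2] * gx * gy
        + 2 * D[:, 3:4] * gx * gz
        + 2 * D[:, 4:5] * gy * gz
    )
    att = (1.0 - f[:, None]) * np.exp(-b * q) + f[:, None] * np.exp(-b * d_water)
    out = np.zeros(mask.shape + (len(scheme),))
    out[mask] = phantom.s0 * att
    return out


def simulate_dwi(
    phantom: GroundTruthPhantom,
    scheme: GradientScheme,
    snr_b0: float = 30.0,
    seed: int = 0,
    noise: str = "rician",
    d_water: float = D_WATER,
):
    """Simulate a noisy DWI acquisition of the phantom.

    ``snr_b0`` is the b=0 signal-to-noise ratio (sigma = s0 / snr_b0);
    ``np.inf`` returns the exact forward model. Noise is Rician (magnitude
    MR) by default; ``noise="gaussian"`` is available for debugging.
    """
    from .fitting import DWIVolume

    if not snr_b0 > 0:
        raise ValueError("snr_b0 must be positive (np.inf for noise-free)")
    signal = forward_signal(phantom, scheme, d_water)
    if np.isfinite(snr_b0):
        rng = np.random.default_rng(seed)
        sigma = phantom.s0 / snr_b0
        m = phantom.mask
        shape = (int(m.sum()), len(scheme))
        if noise == "rician":
            n1 = rng.normal(0.0, sigma, shape)
            n2 = rng.normal(0.0, sigma, shape)
            signal[m] = np.sqrt((signal[m] + n1) ** 2 + n2**2)
        elif noise == "gaussian":
            signal[m] = np.maximum(signal[m] + rng.normal(0.0, sigma, shape), 0.0)
        else:
            raise ValueError("noise must be 'rician' or 'gaussian'")
    return DWIVolume(
        signal=signal,
        scheme=scheme,
        mask=phantom.mask.copy(),
        voxel_size=phantom.voxel_size,
    )


# --------------------------------------------------------------------------
# cohort-level calibration (published Tables 1-2 group structure)
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class GroupCalibration:
    """Per-group calibration: quartile atoms for MD / %MD450, FA, clinical."""

    md_quartiles: tuple  # mm^2/s, (q25, median, q75)
    fa_mean: float
    fa_sd: float
    pct450_quartiles: tuple  # percent, (q25, median, q75)
    age_mean: float
    age_sd: float
    male_frac: float
    shockable_prob: float
    duration_median: float  # minutes
    duration_iqr: tuple
    lactate_median: float  # mmol/L
    lactate_iqr: tuple
    eeg_probs: tuple  # P(category I, II, III)


GOOD_CALIBRATION = GroupCalibration(
    md_quartiles=(702e-6, 726e-6, 740e-6),
    fa_mean=0.30,
    fa_sd=0.03,
    pct450_quartiles=(1.8, 3.4, 6.4),
    age_mean=56.0,
    age_sd=11.0,
    male_frac=0.83,
    shockable_prob=1.0,
    duration_median=12.0,
    duration_iqr=(10.0, 15.0),
    lactate_median=3.6,
    lactate_iqr=(2.7, 6.7),
    eeg_probs=(0.0, 0.50, 0.50),
)

POOR_CALIBRATION = GroupCalibration(
    md_quartiles=(575e-6, 663e-6, 736e-6),
    fa_mean=0.28,
    fa_sd=0.03,
    pct450_quartiles=(5.8, 18.0, 32.8),
    age_mean=67.0,
    age_sd=11.0,
    male_frac=0.70,
    shockable_prob=0.75,
    duration_median=23.0,
    duration_iqr=(19.0, 31.0),
    lactate_median=4.1,
    lactate_iqr=(3.1, 5.4),
    eeg_probs=(0.15, 0.05, 0.80),
)


@dataclass(frozen=True)
class CohortConfig:
    """Study conditions for a synthetic cohort run."""

    n_good: int = 30
    n_poor: int = 20
    grid_shape: tuple = (24, 24, 24)
    n_dirs: int = 30
    b: float = 1000.0
    n_b0: int = 1
    snr_b0: float = 30.0
    wm_volume_fraction: float = 0.5
    good: GroupCalibration = GOOD_CALIBRATION
    poor: GroupCalibration = POOR_CALIBRATION


@dataclass
class CohortSubject:
    subject_id: str
    spec: SubjectSpec
    phantom: GroundTruthPhantom
    dwi: object  # DWIVolume
    clinical: ClinicalRecord


def _lognormal_sigma(median, iqr):
    """Sigma of a log-normal matched to the printed median and IQR bounds."""
    q25, q75 = iqr
    return float(np.log(q75 / q25) / 1.349)


def _draw_severity(rng):
    """Severity index in {0, 1, 2} with probabilities (0.25, 0.5, 0.25)."""
    return int(rng.choice(3, p=(0.25, 0.5, 0.25)))


def draw_clinical(rng, cal: GroupCalibration, outcome: str) -> ClinicalRecord:
    """One clinical covariate record per the Table-1 group distributions."""
    return ClinicalRecord(
        age=float(np.clip(rng.normal(cal.age_mean, cal.age_sd), 18.0, 95.0)),
        sex="M" if rng.random() < cal.male_frac else "F",
        duration_resus=float(
            max(rng.lognormal(np.log(cal.duration_median), _lognormal_sigma(cal.duration_median, cal.duration_iqr)), 1.0)
        ),
        shockable_rhythm=bool(rng.random() < cal.shockable_prob),
        first_lactate=float(
            max(rng.lognormal(np.log(cal.lactate_median), _lognormal_sigma(cal.lactate_median, cal.lactate_iqr)), 0.3)
        ),
        eeg_category=("I", "II", "III")[int(rng.choice(3, p=cal.eeg_probs))],
        outcome=outcome,
    )


def draw_subject_spec(rng, cal: GroupCalibration, outcome: str, config: CohortConfig) -> SubjectSpec:
    """Draw one subject's ground-truth targets from the group calibration.

    MD and %MD450 atoms are coupled through a single severity draw (severe
    injury = lower tissue MD and larger sub-450 volume). Good-outcome
    subjects get a scattered low-MD tail instead of contiguous lesions.
    """
    s = _draw_severity(rng)
    target_md = cal.md_quartiles[2 - s]
    pct450 = cal.pct450_quartiles[s]
    ratio = tissue_mask_ratio(config.grid_shape, config.wm_volume_fraction)
    implant_fraction = (pct450 / 100.0) * ratio
    fa_target = float(np.clip(rng.normal(cal.fa_mean, cal.fa_sd), 0.18, 0.42))
    w = wm_weight(config.grid_shape, config.wm_volume_fraction)
    lesion_share = pct450 / 100.0 if outcome == "poor" else 0.0
    wm_fa = float(wm_fa_for_whole_brain_fa(fa_target, w, lesion_share=lesion_share))
    clinical = draw_clinical(rng, cal, outcome)
    lesion_fraction = implant_fraction if outcome == "poor" else 0.0
    tail_fraction = implant_fraction if outcome == "good" else 0.0
    return SubjectSpec(
        outcome=outcome,
        target_tissue_md=float(target_md),
        target_wm_fa=wm_fa,
        lesion_fraction=float(lesion_fraction),
        low_md_tail_fraction=float(tail_fraction),
        clinical=clinical,
        seed=int(rng.integers(0, 2**31 - 1)),
    )


def sample_cohort(config: CohortConfig = CohortConfig(), seed: int = 0) -> list:
    """Generate the full imaging cohort: specs, phantoms, noisy DWI, covariates."""
    if config.n_good < 2 or config.n_poor < 2:
        raise ValueError("need at least 2 subjects per outcome group")
    rng = np.random.default_rng(seed)
    scheme = make_gradient_scheme(config.n_dirs, config.b, config.n_b0)
    subjects = []
    plan = [("good", config.good)] * config.n_good + [("poor", config.poor)] * config.n_poor
    for i, (outcome, cal) in enumerate(plan):
        spec = draw_subject_spec(rng, cal, outcome, config)
        phantom = make_phantom(spec, config.grid_shape, config.wm_volume_fraction)
        dwi = simulate_dwi(phantom, scheme, config.snr_b0, seed=spec.seed + 1)
        subjects.append(
            CohortSubject(
                subject_id=f"sub-{i+1:03d}",
                spec=spec,
                phantom=phantom,
                dwi=dwi,
                clinical=spec.clinical,
            )
        )
    return subjects


def sample_cohort_metrics(config: CohortConfig = CohortConfig(), seed: int = 0) -> pd.DataFrame:
    """Draw a cohort metrics table directly from the calibrated distributions.

    Bypasses image simulation and fitting: subject-level mean MD, mean FA and
    %MD450 are drawn from the same group calibration the phantom sampler
    uses, with small continuous jitter standing in for measurement noise.
    Intended for prediction-layer simulations where only the table matters.
    """
    rng = np.random.default_rng(seed)
    rows = []
    plan = [("good", config.good)] * config.n_good + [("poor", config.poor)] * config.n_poor
    for i, (outcome, cal) in enumerate(plan):
        s = _draw_severity(rng)
        mean_md = cal.md_quartiles[2 - s] * rng.lognormal(0.0, 0.015)
        pct450 = max(cal.pct450_quartiles[s] * rng.lognormal(0.0, 0.08), 0.0)
        mean_fa = float(np.clip(rng.normal(cal.fa_mean, cal.fa_sd), 0.15, 0.45))
        c = draw_clinical(rng, cal, outcome)
        rows.append(
            {
                "subject_id": f"sub-{i+1:03d}",
                "outcome": outcome,
                "mean_md": float(mean_md),
                "mean_fa": mean_fa,
                "pct_md450": float(pct450),
                "age": c.age,
                "sex": c.sex,
                "duration_resus": c.duration_resus,
                "shockable_rhythm": c.shockable_rhythm,
                "first_lactate": c.first_lactate,
                "eeg_category": c.eeg_category,
            }
        )
    return pd.DataFrame(rows)
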