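"""Scalar maps (MD, FA) and per-subject whole-brain summary metrics.

The study's per-subject read-outs are the whole-brain mean MD, mean FA and
%MD450 (percentage of in-mask voxels with MD strictly below 450e-6 mm^2/s).
On uncorrected MD maps an artifact/CSF filter removes voxels with
ADC < 200e-6 or > 2000e-6 mm^2/s before summarising; corrected maps
exclude voxels where the tissue compartment is unidentifiable (fitted
free-water fraction >= 0.9), voxels the fit flagged invalid, and — when an
apparent (uncorrected) MD map is supplied — voxels outside the same ADC
window evaluated on the apparent MD. The latter mirrors the uncorrected
pipeline's CSF exclusion: in free-water-dominated voxels the corrected MD
no longer reflects CSF, so the exclusion must be decided on the apparent
diffusivity.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .fitting import FreeWaterFit, TensorField
from .simulate import ClinicalRecord
from .tensors import fa_of_tensor, md_of_tensor

ADC_LOW = 200e-6
ADC_HIGH = 2000e-6
MD450 = 450e-6
F_MAX_TISSUE = 0.9  # above this fitted f, the tissue tensor is not trusted


@dataclass
class ScalarMap:
    """A per-voxel scalar field with its analysis mask."""

    values: np.ndarray
    mask: np.ndarray
    kind: str  # {"MD", "FA"}

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.mask.shape:
            raise ValueError("values and mask grids differ")
        if self.kind not in ("MD", "FA"):
            raise ValueError("kind must be 'MD' or 'FA'")

    def in_mask(self) -> np.ndarray:
        return self.values[self.mask]


@dataclass
class SubjectMetrics:
    """The row of the cohort table: whole-brain metrics plus covariates."""

    mean_md: float  # mm^2/s
    mean_fa: float
    pct_md450: float  # percent
    corrected: bool
    clinical: ClinicalRecord | None = None
    subject_id: str = ""

    def __post_init__(self):
        if not 0.0 <= self.pct_md450 <= 100.0:
            raise ValueError("pct_md450 must lie in [0, 100]")
        if not 0.0 <= self.mean_fa <= 1.0:
            raise ValueError("mean_fa must lie in [0, 1]")


def apply_adc_filter(md_map: ScalarMap, low: float = ADC_LOW, high: float = ADC_HIGH) -> ScalarMap:
    """Shrink the mask to voxels with low <= MD <= high (values untouched).

    Applied to uncorrected MD maps to remove artifacts and CSF; bounds are
    inclusive (only strictly out-of-range voxels are removed). Idempotent.
    """
    if low >= high:
        raise ValueError("ADC filter requires low < high")
    keep = md_map.mask & (md_map.values >= low) & (md_map.values <= high)
    return ScalarMap(md_map.values, keep, md_map.kind)


def pct_md_below(md_map: ScalarMap, threshold: float = MD450) -> float:
    """Percentage of in-mask voxels with MD strictly below ``threshold``."""
    n = int(md_map.mask.sum())
    if n == 0:
        raise ValueError("empty mask")
    return 100.0 * float((md_map.values[md_map.mask] < threshold).sum()) / n


def whole_brain_summary(
    md_map: ScalarMap,
    fa_map: ScalarMap,
    clinical: ClinicalRecord | None = None,
    corrected: bool = True,
    md450_threshold: float = MD450,
    subject_id: str = "",
) -> SubjectMetrics:
    """Arithmetic-mean whole-brain reduction of MD and FA maps plus %MD450.

    The two maps must share a mask. %MD450 is evaluated on the supplied MD
    map (by default the free-water-corrected one).
    """
    if not np.array_equal(md_map.mask, fa_map.mask):
        raise ValueError("MD and FA maps must share a mask")
    if not md_map.mask.any():
        raise ValueError("empty mask")
    return SubjectMetrics(
        mean_md=float(md_map.in_mask().mean()),
        mean_fa=float(np.clip(fa_map.in_mask().mean(), 0.0, 1.0)),
        pct_md450=pct_md_below(md_map, md450_threshold),
        corrected=corrected,
        clinical=clinical,
        subject_id=subject_id,
    )


def subject_maps(
    fit,
    mask: np.ndarray,
    corrected: bool = True,
    f_max: float = F_MAX_TISSUE,
    apparent_md: np.ndarray | None = None,
):
    """MD and FA ScalarMaps from a fit result, with the analysis mask applied.

    ``fit`` is a :class:`FreeWaterFit` (corrected) or :class:`TensorField`
    (uncorrected). Corrected maps exclude free-water-dominated voxels
    (fitted f >= ``f_max``), invalid voxels, and (when ``apparent_md`` from
    the uncorrected fit is given) voxels whose apparent MD falls outside
    the physiological ADC window; uncorrected MD maps get the 200/2000e-6
    ADC filter downstream via :func:`apply_adc_filter`.
    """
    if isinstance(fit, FreeWaterFit):
        tensor = fit.tissue_tensor.tensor
        fa_deb = fit.fa_debiased
        keep = mask & (fit.fw_fraction < f_max)
        if fit.tissue_tensor.invalid is not None:
            keep &= ~fit.tissue_tensor.invalid
        if apparent_md is not None:
            keep &= (apparent_md >= ADC_LOW) & (apparent_md <= ADC_HIGH)
    elif isinstance(fit, TensorField):
        tensor = fit.tensor
        fa_deb = fit.fa_debiased
        keep = mask.copy()
        if fit.invalid is not None:
            keep &= ~fit.invalid
    else:
        raise TypeError("fit must be a FreeWaterFit or TensorField")
    md = md_of_tensor(tensor)
    fa = fa_deb if fa_deb is not None else fa_of_tensor(tensor)
    return ScalarMap(md, keep, "MD"), ScalarMap(fa, keep, "FA")


def summarise_subject(
    fit, dwi, clinical=None, corrected=True, subject_id="", apparent_md=None, **kwargs
) -> SubjectMetrics:
    """One-call reduction: fit result -> SubjectMetrics.

    For uncorrected fits the ADC artifact filter is applied to the MD mask
    (and the FA map inherits the filtered mask, so both metrics share it).
    For corrected fits, pass ``apparent_md`` (the uncorrected MD map) to
    apply the ADC-window CSF exclusion; if omitted it is computed from a
    single-tensor fit of ``dwi``.
    """
    if corrected and apparent_md is None and isinstance(fit, FreeWaterFit):
        from .fitting import fit_single_tensor

        apparent_md = fit_single_tensor(dwi).md()
    md_map, fa_map = subject_maps(
        fit, dwi.mask, corrected=corrected, apparent_md=apparent_md
    )
    if not corrected:
        md_map = apply_adc_filter(md_map)
        fa_map = ScalarMap(fa_map.values, md_map.mask, "FA")
    return whole_brain_summary(
        md_map, fa_map, clinical=clinical, corrected=corrected, subject_id=subject_id, **kwargs
    )


def metrics_to_frame(metrics: list) -> "pd.DataFrame":
    """Stack SubjectMetrics into the cohort table (MD in mm^2/s)."""
    import pandas as pd

    rows = []
    for m in metrics:
        row = {
            "subject_id": m.subject_id,
            "corrected": m.corrected,
            "mean_md": m.mean_md,
            "mean_fa": m.mean_fa,
            "pct_md450": m.pct_md450,
        }
        if m.clinical is not None:
            c = m.clinical
            row.update(
                outcome=c.outcome,
                age=c.age,
                sex=c.sex,
                duration_resus=c.duration_resus,
                shockable_rhythm=c.shockable_rhythm,
                first_lactate=c.first_lactate,
                eeg_category=c.eeg_category,
            )
        rows.append(row)
    return pd.DataFrame(rows)
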