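"""Pipeline driver: simulate -> fit -> metrics -> stats -> predict.

Each stage persists its artifacts under the output directory and records
completion in a JSON run manifest keyed by a configuration hash, so a run
can be resumed (``resume=True``) with only missing stages recomputed.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as fio
from .fitting import FreeWaterFitter, fit_single_tensor
from .groupstats import compare_groups, voxelwise_permutation_test
from .maps import subject_maps, summarise_subject
from .prediction import run_model_suite
from .simulate import CohortConfig, sample_cohort

log = logging.getLogger("freewater")


@dataclass
class PipelineConfig:
    """All tunables of a full synthetic-cohort run.

    Defaults reproduce the study constants: 30/20 good/poor subjects, one
    b=0 plus 30 directions at b = 1000 s/mm^2, free-water diffusivity
    3.0e-3 mm^2/s, ADC artifact window [200, 2000]e-6, %MD450 threshold
    450e-6, voxelwise alpha 0.01, 10-fold cross-validation.
    """

    out_dir: str = "freewater_run"
    n_good: int = 30
    n_poor: int = 20
    grid: int = 24
    n_dirs: int = 30
    b: float = 1000.0
    n_b0: int = 1
    snr_b0: float = 30.0
    d_water: float = 3.0e-3
    lambda_reg: object = "auto"
    eig_low: float = 0.1e-3
    eig_high: float = 2.5e-3
    max_iter: int = 200
    tol: float = 1e-8
    adc_low: float = 200e-6
    adc_high: float = 2000e-6
    md450_threshold: float = 450e-6
    n_perm: int = 1000
    alpha: float = 0.01
    stats_method: str = "maxstat"
    k_folds: int = 10
    n_boot: int = 2000
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.adc_low < self.adc_high):
            raise ValueError("ADC thresholds must be positive and ordered")
        if self.md450_threshold <= 0:
            raise ValueError("md450_threshold must be positive")

    def cohort_config(self) -> CohortConfig:
        return CohortConfig(
            n_good=self.n_good,
            n_poor=self.n_poor,
            grid_shape=(self.grid,) * 3,
            n_dirs=self.n_dirs,
            b=self.b,
            n_b0=self.n_b0,
            snr_b0=self.snr_b0,
        )

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def to_yaml(self, path):
        Path(path).write_text(yaml.safe_dump(asdict(self)))


def _subject_dir(out: Path, sid: str) -> Path:
    return out / "subjects" / sid


def stage_simulate(config: PipelineConfig, out: Path):
    subjects = sample_cohort(config.cohort_config(), seed=config.seed)
    rows = []
    for s in subjects:
        sdir = _subject_dir(out, s.subject_id)
        fio.write_dwi(sdir / s.subject_id, s.dwi)
        fio.write_nifti(sdir / f"{s.subject_id}_gt_f.nii.gz", s.phantom.fw_fraction)
        fio.write_nifti(sdir / f"{s.subject_id}_gt_md.nii.gz", s.phantom.md_map())
        fio.write_nifti(sdir / f"{s.subject_id}_gt_label.nii.gz", s.phantom.tissue_label)
        c = s.clinical
        rows.append(
            dict(
                subject_id=s.subject_id, outcome=c.outcome, age=c.age, sex=c.sex,
                duration_resus=c.duration_resus, shockable_rhythm=c.shockable_rhythm,
                first_lactate=c.first_lactate, eeg_category=c.eeg_category,
            )
        )
    fio.write_metrics_table(out / "covariates.tsv", pd.DataFrame(rows))
    log.info("simulated %d subjects", len(subjects))
    return subjects


def _subject_ids(out: Path):
    cov = fio.read_metrics_table(out / "covariates.tsv")
    return list(cov["subject_id"]), cov


def stage_fit(config: PipelineConfig, out: Path):
    ids, _ = _subject_ids(out)
    fitter_kw = dict(
        d_water=config.d_water,
        lambda_reg=config.lambda_reg,
        eig_box=(config.eig_low, config.eig_high),
        max_iter=config.max_iter,
        tol=config.tol,
    )
    for sid in ids:
        sdir = _subject_dir(out, sid)
        dwi = fio.read_dwi(
            sdir / f"{sid}_dwi.nii.gz", sdir / f"{sid}.bval", sdir / f"{sid}.bvec",
            mask_path=sdir / f"{sid}_mask.nii.gz",
        )
        single = fit_single_tensor(dwi)
        fw = FreeWaterFitter(**fitter_kw).fit(dwi).result()
        fio.write_nifti(sdir / f"{sid}_st_tensor.nii.gz", single.tensor, dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_st_fa.nii.gz", single.fa_debiased, dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_fw_tensor.nii.gz", fw.tissue_tensor.tensor, dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_fw_fa.nii.gz", fw.fa_debiased, dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_fw_f.nii.gz", fw.fw_fraction, dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_fw_converged.nii.gz", fw.converged.astype(float), dwi.voxel_size)
        fio.write_nifti(sdir / f"{sid}_fw_residual.nii.gz", fw.residual, dwi.voxel_size)
        log.info("fit %s (lambda_reg=%.4g)", sid, getattr(fw, "lambda_reg_", np.nan) if hasattr(fw, "lambda_reg_") else np.nan)


def _load_fit(sdir: Path, sid: str):
    from .fitting import FreeWaterFit, TensorField

    dwi = fio.read_dwi(
        sdir / f"{sid}_dwi.nii.gz", sdir / f"{sid}.bval", sdir / f"{sid}.bvec",
        mask_path=sdir / f"{sid}_mask.nii.gz",
    )
    fw_tensor, _ = fio.read_nifti(sdir / f"{sid}_fw_tensor.nii.gz")
    f_map, _ = fio.read_nifti(sdir / f"{sid}_fw_f.nii.gz")
    conv, _ = fio.read_nifti(sdir / f"{sid}_fw_converged.nii.gz")
    res, _ = fio.read_nifti(sdir / f"{sid}_fw_residual.nii.gz")
    st_tensor, _ = fio.read_nifti(sdir / f"{sid}_st_tensor.nii.gz")
    fw_fa, _ = fio.read_nifti(sdir / f"{sid}_fw_fa.nii.gz")
    st_fa, _ = fio.read_nifti(sdir / f"{sid}_st_fa.nii.gz")
    fw = FreeWaterFit(
        tissue_tensor=TensorField(fw_tensor, dwi.b0_mean(), dwi.mask),
        fw_fraction=f_map, converged=conv > 0.5, residual=res, fa_debiased=fw_fa,
    )
    st = TensorField(st_tensor, dwi.b0_mean(), dwi.mask, fa_debiased=st_fa)
    return dwi, st, fw


def stage_metrics(config: PipelineConfig, out: Path):
    ids, cov = _subject_ids(out)
    from .simulate import ClinicalRecord

    rows = []
    for sid in ids:
        sdir = _subject_dir(out, sid)
        dwi, st, fw = _load_fit(sdir, sid)
        crow = cov[cov.subject_id == sid].iloc[0]
        clin = ClinicalRecord(
            age=float(crow.age), sex=str(crow.sex), duration_resus=float(crow.duration_resus),
            shockable_rhythm=bool(crow.shockable_rhythm), first_lactate=float(crow.first_lactate),
            eeg_category=str(crow.eeg_category), outcome=str(crow.outcome),
        )
        for corrected, fit in ((True, fw), (False, st)):
            m = summarise_subject(
                fit, dwi, clinical=clin, corrected=corrected, subject_id=sid,
                md450_threshold=config.md450_threshold,
                apparent_md=st.md() if corrected else None,
            )
            rows.append(
                dict(subject_id=sid, corrected=corrected, outcome=clin.outcome,
                     mean_md=m.mean_md, mean_fa=m.mean_fa, pct_md450=m.pct_md450,
                     age=clin.age, sex=clin.sex, duration_resus=clin.duration_resus,
                     shockable_rhythm=clin.shockable_rhythm,
                     first_lactate=clin.first_lactate, eeg_category=clin.eeg_category)
            )
    fio.write_metrics_table(out / "metrics.tsv", pd.DataFrame(rows))


def stage_stats(config: PipelineConfig, out: Path):
    if config.n_perm < 100:
        log.warning("n_perm < 100: voxelwise stats stage skipped")
        return
    ids, cov = _subject_ids(out)
    md_maps, fa_maps, masks, labels = [], [], [], []
    from .tensors import fa_of_tensor, md_of_tensor

    for sid in ids:
        sdir = _subject_dir(out, sid)
        dwi, st, fw = _load_fit(sdir, sid)
        md_map, fa_map = subject_maps(fw, dwi.mask, corrected=True, apparent_md=st.md())
        md_maps.append(md_map.values)
        fa_maps.append(fa_map.values)
        masks.append(md_map.mask)
        labels.append(cov[cov.subject_id == sid].iloc[0].outcome)
    shared = np.logical_and.reduce(masks)
    labels = np.array(labels)
    report = {}
    for kind, stack in (("md", md_maps), ("fa", fa_maps)):
        res = voxelwise_permutation_test(
            np.stack(stack), labels, n_perm=config.n_perm, alpha=config.alpha,
            method=config.stats_method, mask=shared, seed=config.seed,
        )
        fio.write_nifti(out / f"voxelwise_{kind}_tstat.nii.gz", res.stat_map)
        fio.write_nifti(out / f"voxelwise_{kind}_pfwe.nii.gz", res.p_fwe_map)
        fio.write_nifti(out / f"voxelwise_{kind}_sig.nii.gz", res.sig_mask.astype(float))
        report[kind] = int(res.sig_mask.sum())
    metrics = fio.read_metrics_table(out / "metrics.tsv")
    corrected = metrics[metrics.corrected]
    comparison = compare_groups(
        corrected, variables=["mean_md", "mean_fa", "pct_md450", "age", "sex",
                              "duration_resus", "shockable_rhythm", "first_lactate",
                              "eeg_category"],
    )
    comparison.to_csv(out / "group_comparison.tsv", sep="\t")
    fio.write_manifest(out / "voxelwise_summary.json", report)


def stage_predict(config: PipelineConfig, out: Path):
    metrics = fio.read_metrics_table(out / "metrics.tsv")
    table = metrics[metrics.corrected].reset_index(drop=True)
    results, summary = run_model_suite(table, seed=config.seed, k=config.k_folds, n_boot=config.n_boot)
    summary.to_csv(out / "prediction_summary.tsv", sep="\t")
    for name, r in results.items():
        np.savetxt(out / f"roc_{name}.tsv", r.roc_points, delimiter="\t", header="fpr\ttpr", comments="")
    return summary


STAGES = ("simulate", "fit", "metrics", "stats", "predict")


def run_pipeline(config: PipelineConfig, resume: bool = False):
    """Execute all stages; returns the output directory path.

    With ``resume=True``, stages already marked complete in the manifest
    (with a matching configuration hash) are skipped.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    chash = fio.config_hash(asdict(config))
    manifest_path = out / "manifest.json"
    manifest = {"config_hash": chash, "seed": config.seed, "stages": {}}
    if resume and manifest_path.exists():
        old = fio.read_manifest(manifest_path)
        if old.get("config_hash") == chash:
            manifest = old
    config.to_yaml(out / "config.yaml")
    funcs = {
        "simulate": stage_simulate,
        "fit": stage_fit,
        "metrics": stage_metrics,
        "stats": stage_stats,
        "predict": stage_predict,
    }
    for stage in STAGES:
        if resume and manifest["stages"].get(stage) == "done":
            log.info("stage %s: resumed (skipped)", stage)
            continue
        log.info("stage %s: running", stage)
        try:
            funcs[stage](config, out)
        except Exception as err:
            manifest["stages"][stage] = f"failed: {err}"
            fio.write_manifest(manifest_path, manifest)
            raise RuntimeError(f"pipeline stage '{stage}' failed: {err}") from err
        manifest["stages"][stage] = "done"
        fio.write_manifest(manifest_path, manifest)
    return out
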