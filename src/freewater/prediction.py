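"""Cross-validated logistic prediction of neurological outcome.

Four model specifications are compared on the same stratified 10-fold
splits: a clinical model (age, sex, duration of resuscitation, shockable
first rhythm, first lactate, EEG category), a DTI-only model (whole-brain
mean free-water-corrected FA and MD), and the clinical model augmented with
either (FA, MD) or (FA, %MD450). Out-of-fold predicted probabilities of
poor outcome are pooled across folds; reported operating points follow the
prognostication guideline convention: maximal sensitivity for poor outcome
at 100% specificity, and sensitivity for good outcome at >= 90% specificity.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.compose import ColumnTransformer
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

CLINICAL_COVARIATES = [
    "age",
    "sex",
    "duration_resus",
    "shockable_rhythm",
    "first_lactate",
    "eeg_category",
]
DTI_COVARIATES = ["mean_fa", "mean_md"]

# ridge strength on standardised covariates; keeps quasi-separated fits defined
RIDGE_ALPHA = 1e-2


@dataclass(frozen=True)
class ModelSpec:
    """One logistic model: a name and an ordered covariate list."""

    name: str
    covariates: tuple
    positive_class: str = "poor"


MODEL_SPECS = {
    "clinical": ModelSpec("clinical", tuple(CLINICAL_COVARIATES)),
    "dti_only": ModelSpec("dti_only", tuple(DTI_COVARIATES)),
    "clinical_plus_dti": ModelSpec(
        "clinical_plus_dti", tuple(CLINICAL_COVARIATES + DTI_COVARIATES)
    ),
    "clinical_plus_fa_md450": ModelSpec(
        "clinical_plus_fa_md450", tuple(CLINICAL_COVARIATES + ["mean_fa", "pct_md450"])
    ),
}


@dataclass
class OperatingPoint:
    sensitivity: float  # percent
    ci_low: float
    ci_high: float
    spec_floor: float  # percent
    attained: bool = True


@dataclass
class ModelResult:
    """Pooled cross-validated predictions and derived operating points."""

    name: str
    oof_probability: np.ndarray  # P(poor) per subject, one out-of-fold value each
    labels: np.ndarray  # outcome per subject
    auc: float
    sens_poor_at_spec100: OperatingPoint
    sens_good_at_spec90: OperatingPoint
    roc_points: np.ndarray  # (n_points, 2) of (fpr, tpr) for poor detection


def _design(table: pd.DataFrame, covariates) -> pd.DataFrame:
    """Numeric design frame: dummy-coded categoricals, floats elsewhere.

    EEG category is coded as two indicators against reference category III;
    sex as an indicator for male; booleans as 0/1.
    """
    cols = {}
    for cov in covariates:
        s = table[cov]
        if cov == "eeg_category":
            cols["eeg_I"] = (s == "I").astype(float)
            cols["eeg_II"] = (s == "II").astype(float)
        elif cov == "sex":
            cols["sex_M"] = (s == "M").astype(float)
        elif s.dtype == bool:
            cols[cov] = s.astype(float)
        else:
            cols[cov] = s.astype(float)
    X = pd.DataFrame(cols, index=table.index)
    constant = [c for c in X.columns if X[c].nunique() <= 1]
    if constant:
        warnings.warn(f"dropping zero-variance covariates: {constant}", UserWarning)
        X = X.drop(columns=constant)
    return X


def _pipeline(X: pd.DataFrame) -> Pipeline:
    continuous = [c for c in X.columns if X[c].nunique() > 2]
    binary = [c for c in X.columns if c not in continuous]
    pre = ColumnTransformer(
        [("num", StandardScaler(), continuous), ("bin", "passthrough", binary)]
    )
    # ridge (l2) penalty is the sklearn default; strength = RIDGE_ALPHA
    clf = LogisticRegression(C=1.0 / RIDGE_ALPHA, solver="lbfgs", max_iter=2000)
    return Pipeline([("pre", pre), ("clf", clf)])


def roc_auc(probabilities, labels, positive_class="poor"):
    """AUC via the rank-sum (Mann-Whitney) estimator, plus ROC points.

    AUC is the probability that a random positive scores above a random
    negative, with ties counted half. ROC points come from a threshold sweep.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels) == positive_class
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(p)  # midranks handle ties
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    fpr, tpr, _ = roc_curve(y.astype(int), p)
    return float(auc), np.column_stack([fpr, tpr])


def sensitivity_at_specificity(
    probabilities,
    labels,
    spec_floor: float = 100.0,
    positive_class: str = "poor",
    n_boot: int = 2000,
    seed: int = 0,
    ci_level: float = 0.95,
) -> OperatingPoint:
    """Maximal sensitivity among thresholds whose specificity >= spec_floor.

    Scores are probabilities of ``positive_class``; a subject is called
    positive when its score >= threshold. The 95% CI is a stratified
    bootstrap (positives and negatives resampled separately) of the same
    statistic. If no threshold attains the floor (impossible for floors
    <= 100, since calling no one positive gives specificity 100%), the
    sensitivity is 0 and ``attained`` is False.
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels) == positive_class
    pos = p[y]
    neg = p[~y]
    if len(pos) == 0 or len(neg) == 0:
        raise ValueError("both classes must be present")

    def _sens(pos_s, neg_s):
        thresholds = np.concatenate([np.unique(np.concatenate([pos_s, neg_s])), [np.inf]])
        best = None
        for th in thresholds:
            spec = 100.0 * (neg_s < th).mean()
            if spec >= spec_floor:
                sens = 100.0 * (pos_s >= th).mean()
                best = sens if best is None else max(best, sens)
        return best

    point = _sens(pos, neg)
    attained = point is not None
    if not attained:
        point = 0.0
    rng = np.random.default_rng(seed)
    boots = np.empty(n_boot)
    for i in range(n_boot):
        bp = pos[rng.integers(0, len(pos), len(pos))]
        bn = neg[rng.integers(0, len(neg), len(neg))]
        v = _sens(bp, bn)
        boots[i] = 0.0 if v is None else v
    lo, hi = np.percentile(boots, [100 * (0.5 - ci_level / 2), 100 * (0.5 + ci_level / 2)])
    return OperatingPoint(float(point), float(lo), float(hi), spec_floor, attained)


def fit_logistic_cv(
    table: pd.DataFrame,
    spec: ModelSpec,
    k: int = 10,
    seed: int = 0,
    n_boot: int = 2000,
) -> ModelResult:
    """Stratified k-fold cross-validated logistic regression for one spec.

    Continuous covariates are standardised on each training fold;
    categorical covariates are dummy-coded; a small ridge penalty keeps the
    fit defined under quasi-separation. Predictions are pooled out-of-fold:
    each subject receives exactly one predicted probability of poor outcome.
    """
    missing = [c for c in spec.covariates if c not in table.columns]
    if missing:
        raise ValueError(f"table lacks covariates: {missing}")
    y = (table["outcome"].to_numpy() == spec.positive_class).astype(int)
    if y.sum() == 0 or y.sum() == len(y):
        raise ValueError("both outcome classes must be present")
    X = _design(table, spec.covariates)

    oof = np.full(len(table), np.nan)
    for attempt in range(10):
        splitter = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
        folds = list(splitter.split(X, y))
        if all(len(np.unique(y[tr])) == 2 for tr, _ in folds):
            break
    else:  # pragma: no cover
        raise ValueError("could not draw stratified folds with both classes in training")
    for tr, te in folds:
        pipe = _pipeline(X)
        pipe.fit(X.iloc[tr], y[tr])
        oof[te] = pipe.predict_proba(X.iloc[te])[:, 1]
    assert not np.isnan(oof).any()

    labels = table["outcome"].to_numpy()
    auc, roc_points = roc_auc(oof, labels, positive_class="poor")
    sens_poor = sensitivity_at_specificity(
        oof, labels, spec_floor=100.0, positive_class="poor", n_boot=n_boot, seed=seed
    )
    sens_good = sensitivity_at_specificity(
        1.0 - oof, labels, spec_floor=90.0, positive_class="good", n_boot=n_boot, seed=seed
    )
    return ModelResult(
        name=spec.name,
        oof_probability=oof,
        labels=labels,
        auc=auc,
        sens_poor_at_spec100=sens_poor,
        sens_good_at_spec90=sens_good,
        roc_points=roc_points,
    )


def run_model_suite(table: pd.DataFrame, seed: int = 0, k: int = 10, n_boot: int = 2000):
    """Run the four model specifications on shared folds.

    Returns (dict of ModelResult by name, side-by-side summary DataFrame).
    """
    results = {}
    for name, spec in MODEL_SPECS.items():
        results[name] = fit_logistic_cv(table, spec, k=k, seed=seed, n_boot=n_boot)
    rows = [
        {
            "model": r.name,
            "auc": r.auc,
            "sens_poor_at_spec100": r.sens_poor_at_spec100.sensitivity,
            "sens_poor_ci": (r.sens_poor_at_spec100.ci_low, r.sens_poor_at_spec100.ci_high),
            "sens_good_at_spec90": r.sens_good_at_spec90.sensitivity,
            "sens_good_ci": (r.sens_good_at_spec90.ci_low, r.sens_good_at_spec90.ci_high),
        }
        for r in results.values()
    ]
    return results, pd.DataFrame(rows).set_index("model")
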