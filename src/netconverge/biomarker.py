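"""qPCR biomarker evaluation: relative quantification and diagnostic accuracy.

Implements the ddCt (delta-delta Ct) workflow for a single target transcript
against a reference gene, case-control testing on the log (Ct) scale,
covariate screening and adjustment, and ROC analysis with the
Hanley-McNeil confidence interval for the AUC.

Conventions: lower Ct means more transcript, so dCt = Ct(target) -
Ct(reference) is inversely related to expression and the per-sample
expression score used for ROC is -dCt.  Fold change is 2**(-ddCt) relative
to the calibrator group's mean dCt.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from sklearn.metrics import roc_auc_score, roc_curve

logger = logging.getLogger(__name__)

REQUIRED_COLUMNS = ("sample", "group", "target_ct", "reference_ct")


def load_qpcr_table(path: str | Path) -> pd.DataFrame:
    """Read a Ct table TSV (sample, group, target_ct, reference_ct, covariates...).

    Samples missing either Ct are dropped with a warning; non-positive or
    non-finite Ct values are rejected.
    """
    df = pd.read_csv(path, sep="\t", float_precision="round_trip")
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing column(s) {missing}")
    return validate_qpcr(df, source=str(path))


def validate_qpcr(df: pd.DataFrame, source: str = "qPCR table") -> pd.DataFrame:
    df = df.copy()
    incomplete = df["target_ct"].isna() | df["reference_ct"].isna()
    if incomplete.any():
        logger.warning("%s: dropped %d sample(s) missing a Ct value", source,
                       int(incomplete.sum()))
        df = df[~incomplete]
    for col in ("target_ct", "reference_ct"):
        vals = df[col].to_numpy(float)
        if not np.all(np.isfinite(vals)) or (vals <= 0).any():
            raise ValueError(f"{source}: {col} must be positive and finite")
    return df.reset_index(drop=True)


@dataclass
class DdctResult:
    """Per-sample relative quantification plus the group summary.

    ``per_sample`` columns: sample, group, delta_ct, delta_delta_ct,
    fold_change.  ``group_summary`` reports, per group, the arithmetic
    mean +/- SEM of the per-sample fold changes (presentation style) and
    ``fold_change_group`` = 2**(-mean ddCt), the group-level estimator that
    is unbiased on the log scale.
    """

    per_sample: pd.DataFrame
    group_summary: pd.DataFrame
    calibrator_group: str


def delta_delta_ct(data: pd.DataFrame, calibrator_group: str) -> DdctResult:
    """Relative quantification of the target transcript by the ddCt method.

    Per sample: dCt = target_ct - reference_ct; ddCt = dCt minus the mean
    dCt of the calibrator group; fold change = 2**(-ddCt).  The calibrator
    group's mean log2 fold change is 0 by construction (its group-level
    fold change is exactly 1).
    """
    data = validate_qpcr(data)
    cal = data[data["group"] == calibrator_group]
    if not len(cal):
        raise ValueError(f"calibrator group {calibrator_group!r} is empty or absent")

    dct = data["target_ct"].to_numpy(float) - data["reference_ct"].to_numpy(float)
    cal_mean = dct[(data["group"] == calibrator_group).to_numpy()].mean()
    ddct = dct - cal_mean
    fold = 2.0 ** (-ddct)

    per_sample = pd.DataFrame({
        "sample": data["sample"],
        "group": data["group"],
        "delta_ct": dct,
        "delta_delta_ct": ddct,
        "fold_change": fold,
    })
    rows = []
    for group, sub in per_sample.groupby("group", sort=True):
        f = sub["fold_change"].to_numpy()
        rows.append({
            "group": group,
            "n": len(sub),
            "mean_fold_change": f.mean(),
            "sem_fold_change": f.std(ddof=1) / np.sqrt(len(f)) if len(f) > 1 else np.nan,
            "mean_delta_ct": sub["delta_ct"].mean(),
            "fold_change_group": 2.0 ** (-sub["delta_delta_ct"].mean()),
        })
    return DdctResult(per_sample=per_sample,
                      group_summary=pd.DataFrame(rows),
                      calibrator_group=calibrator_group)


def group_difference(data: pd.DataFrame, case_group: str, control_group: str,
                     welch: bool = False) -> tuple[float, float]:
    """Pooled-variance two-tailed t-test on per-sample dCt values.

    Testing on the Ct (log) scale rather than on fold changes keeps the
    errors symmetric on the tested scale.  Returns (t, p).
    """
    data = validate_qpcr(data)
    dct = data["target_ct"] - data["reference_ct"]
    case = dct[data["group"] == case_group]
    ctrl = dct[data["group"] == control_group]
    for name, vals in ((case_group, case), (control_group, ctrl)):
        if len(vals) < 2:
            raise ValueError(f"group {name!r} has < 2 samples")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(case, ctrl, equal_var=not welch)
    if not np.isfinite(t):
        diff = case.mean() - ctrl.mean()
        # zero pooled variance: no evidence if means agree, infinite if not
        t, p = (0.0, 1.0) if np.isclose(diff, 0.0) else (np.sign(diff) * np.inf, 0.0)
        logger.info("group_difference: zero-variance groups handled (t=%s)", t)
    return float(t), float(p)


def covariate_screen(values: Sequence[float] | pd.Series,
                     covariates: pd.DataFrame) -> pd.DataFrame:
    """Pearson correlation of a per-sample measure with each covariate.

    Binary/categorical covariates with two levels are coded 0/1
    (point-biserial).  Pairs with missing values are dropped per covariate;
    a covariate that is constant (or leaves < 3 pairs) is reported with
    R undefined.  Columns: covariate, r, p, n, note.
    """
    y = pd.Series(np.asarray(values, dtype=float),
                  index=covariates.index if hasattr(covariates, "index") else None)
    rows = []
    for name in covariates.columns:
        x = covariates[name]
        if not pd.api.types.is_numeric_dtype(x):
            levels = sorted(x.dropna().unique())
            if len(levels) == 2:
                x = x.map({levels[0]: 0.0, levels[1]: 1.0})
            else:
                rows.append({"covariate": name, "r": np.nan, "p": np.nan,
                             "n": 0, "note": f"non-numeric with {len(levels)} levels"})
                continue
        mask = x.notna() & y.notna()
        xv, yv = x[mask].to_numpy(float), y[mask].to_numpy(float)
        if len(xv) < 3:
            rows.append({"covariate": name, "r": np.nan, "p": np.nan,
                         "n": int(len(xv)), "note": "fewer than 3 paired observations"})
            continue
        if np.ptp(xv) == 0 or np.ptp(yv) == 0:
            rows.append({"covariate": name, "r": np.nan, "p": np.nan,
                         "n": int(len(xv)), "note": "constant covariate or values"})
            continue
        r, p = stats.pearsonr(xv, yv)
        rows.append({"covariate": name, "r": float(r), "p": float(p),
                     "n": int(len(xv)), "note": ""})
    return pd.DataFrame(rows, columns=["covariate", "r", "p", "n", "note"])


@dataclass
class AdjustedEffect:
    coefficient: float
    std_error: float
    p_value: float
    n: int
    covariates: list[str]


def adjust_covariates(values: Sequence[float] | pd.Series,
                      groups: Sequence[str] | pd.Series,
                      covariates: pd.DataFrame | None = None,
                      case_group: str | None = None) -> AdjustedEffect:
    """OLS of the per-sample measure on group plus covariates.

    The group term is coded 1 for the case group (by default the
    lexicographically later label of the two present); the reported
    coefficient is the covariate-adjusted case-control difference, with its
    standard error and two-tailed p.  With no covariates it equals the raw
    difference of group means.  A rank-deficient design raises an error
    naming the collinear columns.
    """
    y = np.asarray(values, dtype=float)
    groups = pd.Series(np.asarray(groups, dtype=object))
    labels = sorted(groups.unique())
    if len(labels) != 2:
        raise ValueError(f"need exactly 2 group labels, found {labels}")
    case_group = case_group or labels[1]
    X = pd.DataFrame({"group": (groups == case_group).astype(float).to_numpy()})
    if covariates is not None and len(covariates.columns):
        cov = covariates.reset_index(drop=True).copy()
        for name in cov.columns:
            if not pd.api.types.is_numeric_dtype(cov[name]):
                levels = sorted(cov[name].dropna().unique())
                if len(levels) != 2:
                    raise ValueError(f"covariate {name!r} is non-numeric with "
                                     f"{len(levels)} levels; code it numerically")
                cov[name] = cov[name].map({levels[0]: 0.0, levels[1]: 1.0})
        X = pd.concat([X, cov.astype(float)], axis=1)
    X = sm.add_constant(X, has_constant="add")
    design = X.to_numpy(float)
    if np.isnan(design).any() or np.isnan(y).any():
        raise ValueError("missing values in response or design")
    rank = np.linalg.matrix_rank(design)
    if rank < design.shape[1]:
        culprits = [c for c in X.columns if c != "const" and
                    np.linalg.matrix_rank(X.drop(columns=[c]).to_numpy(float)) == rank]
        raise ValueError(f"design matrix is rank deficient; collinear column(s): "
                         f"{culprits or list(X.columns)}")
    fit = sm.OLS(y, X).fit()
    return AdjustedEffect(coefficient=float(fit.params["group"]),
                          std_error=float(fit.bse["group"]),
                          p_value=float(fit.pvalues["group"]),
                          n=int(fit.nobs),
                          covariates=[c for c in X.columns
                                      if c not in ("const", "group")])


@dataclass
class RocResult:
    """Empirical ROC curve with AUC, Hanley-McNeil 95% CI and p vs 0.5."""

    points: pd.DataFrame       # columns: threshold, fpr, tpr
    auc: float
    ci_low: float
    ci_high: float
    p_value: float
    n_case: int
    n_control: int
    flipped: bool              # True if the score was negated for orientation


def hanley_mcneil_se(auc: float, n_case: int, n_control: int) -> float:
    """Standard error of the empirical AUC (Hanley & McNeil 1982)."""
    q1 = auc / (2 - auc)
    q2 = 2 * auc ** 2 / (1 + auc)
    var = (auc * (1 - auc) + (n_case - 1) * (q1 - auc ** 2)
           + (n_control - 1) * (q2 - auc ** 2)) / (n_case * n_control)
    return float(np.sqrt(max(var, 0.0)))


def roc_analysis(scores: Sequence[float] | pd.Series,
                 labels: Sequence[str] | pd.Series,
                 case_label: str | None = None) -> RocResult:
    """Empirical ROC over all thresholds of a per-sample score.

    AUC is the Mann-Whitney probability that a random case outscores a
    random control, ties counted 0.5.  If cases score lower than controls
    on average the score is negated (recorded in ``flipped``) so the
    reported AUC is >= 0.5.  The 95% CI uses the Hanley-McNeil standard
    error with normal quantiles, truncated to [0, 1]; the p-value is the
    two-sided normal test of AUC against 0.5.
    """
    scores = np.asarray(scores, dtype=float)
    labels = pd.Series(np.asarray(labels, dtype=object))
    present = sorted(labels.unique())
    if case_label is None:
        if len(present) != 2:
            raise ValueError(f"need exactly 2 class labels, found {present}")
        case_label = present[1]
    y = (labels == case_label).to_numpy()
    n_case, n_control = int(y.sum()), int((~y).sum())
    if n_case == 0 or n_control == 0:
        raise ValueError("both classes must be non-empty")

    flipped = False
    if scores[y].mean() < scores[~y].mean():
        scores = -scores
        flipped = True
    auc = float(roc_auc_score(y, scores))
    fpr, tpr, thresholds = roc_curve(y, scores)
    points = pd.DataFrame({"threshold": thresholds, "fpr": fpr, "tpr": tpr})

    se = hanley_mcneil_se(auc, n_case, n_control)
    z = stats.norm.ppf(0.975)
    ci_low = max(0.0, auc - z * se)
    ci_high = min(1.0, auc + z * se)
    if se > 0:
        p = float(2 * stats.norm.sf(abs(auc - 0.5) / se))
    else:
        p = 1.0 if auc == 0.5 else 0.0
    return RocResult(points=points, auc=auc, ci_low=ci_low, ci_high=ci_high,
                     p_value=p, n_case=n_case, n_control=n_control, flipped=flipped)


def roc_bootstrap_ci(scores, labels, case_label: str | None = None,
                     n_boot: int = 2000, seed: int = 0) -> tuple[float, float]:
    """Stratified bootstrap percentile 95% CI for the AUC (alternative to
    Hanley-McNeil)."""
    scores = np.asarray(scores, dtype=float)
    labels = pd.Series(np.asarray(labels, dtype=object))
    present = sorted(labels.unique())
    case_label = case_label or present[1]
    y = (labels == case_label).to_numpy()
    case_scores, ctrl_scores = scores[y], scores[~y]
    rng = np.random.default_rng(seed)
    aucs = np.empty(n_boot)
    for b in range(n_boot):
        cs = rng.choice(case_scores, size=len(case_scores), replace=True)
        ks = rng.choice(ctrl_scores, size=len(ctrl_scores), replace=True)
        yy = np.r_[np.ones(len(cs), bool), np.zeros(len(ks), bool)]
        aucs[b] = roc_auc_score(yy, np.r_[cs, ks])
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return float(lo), float(hi)
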