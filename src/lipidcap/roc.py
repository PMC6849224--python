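"""Cross-validated ROC analysis and the three-criterion biomarker call.

Each feature is evaluated univariately: a logistic-regression scorer on the
standardized feature is trained per fold of a stratified k-fold
cross-validation (k = 5) repeated 25 times; the out-of-fold ROC areas give
the mean AUC and a percentile 95% confidence interval over the 125 fold
AUCs.  Standardization is fitted on training folds only.  A feature is
called a biomarker when mean AUC >= 0.80 ("excellent classification"),
the asymptotic Mann-Whitney p is < 0.05, and the 95% CI does not cross the
chance line AUC = 0.50.

Also provided: random oversampling of the minority class (with
replacement, to the majority size) for sample-size sensitivity analyses,
and a corticosteroid-adjusted logistic-regression check of the feature
effect.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .core import Dataset
from .differential import Contrast, mwu_test, select_samples

__all__ = [
    "CvAucResult",
    "AdjustedTestResult",
    "cv_auc",
    "roc_table",
    "classify_biomarkers",
    "oversample_minority",
    "covariate_adjusted_test",
    "AUC_MIN",
    "ALPHA",
]

AUC_MIN = 0.80
ALPHA = 0.05
#: effectively unregularized logistic scorer; the penalty only guards
#: against separation blowing up the optimizer.
LOGREG_C = 1e6


@dataclass(frozen=True)
class CvAucResult:
    mean_auc: float
    ci_low: float
    ci_high: float
    direction: int          # +1: higher values indicate the case class
    fold_aucs: np.ndarray

    def __iter__(self):
        return iter((self.mean_auc, self.ci_low, self.ci_high))


def cv_auc(values, labels, k: int = 5, repeats: int = 25,
           seed: int = 0) -> CvAucResult:
    """Repeated stratified k-fold cross-validated ROC area of one feature.

    ``labels`` is binary with 1 = case.  The orientation is fixed so the
    mean AUC is >= 0.5; the direction flag records whether the feature had
    to be negated (direction -1: lower values indicate the case).
    """
    x = np.asarray(values, float).reshape(-1, 1)
    y = np.asarray(labels, int)
    if set(np.unique(y)) != {0, 1}:
        raise ValueError("labels must contain both classes (0/1)")
    n_min = min((y == 0).sum(), (y == 1).sum())
    if n_min < k:
        raise ValueError(
            f"smallest class has {n_min} samples < k={k}; use a smaller k")
    rng = np.random.default_rng(seed)
    aucs = []
    for _ in range(repeats):
        skf = StratifiedKFold(n_splits=k, shuffle=True,
                              random_state=int(rng.integers(2**31 - 1)))
        for train, test in skf.split(x, y):
            mu, sd = x[train].mean(), x[train].std()
            sd = sd if sd > 0 else 1.0
            clf = LogisticRegression(C=LOGREG_C, solver="liblinear")
            clf.fit((x[train] - mu) / sd, y[train])
            score = clf.decision_function((x[test] - mu) / sd)
            aucs.append(roc_auc_score(y[test], score))
    aucs = np.asarray(aucs)
    # the trained scorer orients itself, so the direction of the raw
    # feature is recorded from its full-data ROC area
    direction = 1 if roc_auc_score(y, x.ravel()) >= 0.5 else -1
    if aucs.mean() < 0.5:
        aucs = 1.0 - aucs
    lo, hi = np.percentile(aucs, [2.5, 97.5])
    return CvAucResult(float(aucs.mean()), float(lo), float(hi), direction,
                       aucs)


def full_data_auc(values, labels) -> float:
    """Empirical ROC area on the full data (no cross-validation)."""
    return float(roc_auc_score(np.asarray(labels, int),
                               np.asarray(values, float)))


def roc_table(features: pd.DataFrame, meta: pd.DataFrame, contrast: Contrast,
              k: int = 5, repeats: int = 25, seed: int = 0,
              auc_min: float = AUC_MIN, alpha: float = ALPHA,
              family: str = "analytes") -> pd.DataFrame:
    """Cross-validated ROC summary and biomarker call per feature."""
    case_ids = select_samples(meta, *contrast.case)
    ctrl_ids = select_samples(meta, *contrast.control)
    ids = case_ids.append(ctrl_ids)
    y = np.concatenate([np.ones(len(case_ids), int),
                        np.zeros(len(ctrl_ids), int)])
    rows = []
    rng = np.random.default_rng(seed)
    for name in features.columns:
        x = features.loc[ids, name].to_numpy(float)
        ok = np.isfinite(x)
        res = cv_auc(x[ok], y[ok], k=k, repeats=repeats,
                     seed=int(rng.integers(2**31 - 1)))
        _, p = mwu_test(x[ok][y[ok] == 1], x[ok][y[ok] == 0])
        rows.append({
            "feature": name, "mean_auc": res.mean_auc, "ci_low": res.ci_low,
            "ci_high": res.ci_high, "p_asymptotic": p,
            "direction": res.direction,
            "n_case": int((y[ok] == 1).sum()),
            "n_control": int((y[ok] == 0).sum()),
            "is_biomarker": bool(res.mean_auc >= auc_min and p < alpha
                                 and res.ci_low > 0.5),
        })
    table = pd.DataFrame(rows).set_index("feature")
    table["contrast"] = contrast.name
    table["family"] = family
    return table.sort_values("mean_auc", ascending=False)


def classify_biomarkers(roc_results: pd.DataFrame,
                        diff_results: pd.DataFrame | None = None,
                        auc_min: float = AUC_MIN, alpha: float = ALPHA
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Apply the three biomarker criteria and summarise counts.

    When ``diff_results`` is given, its Mann-Whitney p replaces the one in
    ``roc_results`` (they coincide when computed on the same samples).
    Returns ``(table, summary)`` where summary counts biomarkers per
    contrast and family.
    """
    table = roc_results.copy()
    if diff_results is not None:
        missing = set(table.index) - set(diff_results.index)
        if missing:
            raise ValueError(f"features without test results: {sorted(missing)}")
        table["p_asymptotic"] = diff_results["p_mwu"].reindex(table.index)
    table["is_biomarker"] = ((table["mean_auc"] >= auc_min)
                             & (table["p_asymptotic"] < alpha)
                             & (table["ci_low"] > 0.5))
    group_cols = [c for c in ("contrast", "family") if c in table.columns]
    if group_cols:
        summary = (table.groupby(group_cols, observed=True)["is_biomarker"]
                   .agg(n_biomarkers="sum", n_features="count").reset_index())
        summary["proportion"] = (summary["n_biomarkers"]
                                 / summary["n_features"])
    else:
        summary = pd.DataFrame({
            "n_biomarkers": [int(table["is_biomarker"].sum())],
            "n_features": [len(table)]})
    return table, summary


def oversample_minority(ds: Dataset, contrast: Contrast, seed: int = 0
                        ) -> Dataset:
    """Oversample the smaller contrast group to the larger one's size.

    Original samples are all preserved; the deficit is filled by sampling
    minority samples at random with replacement.  Duplicates get suffixed
    sample ids and are tagged in an ``oversampled`` metadata column.
    """
    case_ids = select_samples(ds.meta, *contrast.case)
    ctrl_ids = select_samples(ds.meta, *contrast.control)
    keep = case_ids.append(ctrl_ids)
    out = ds.subset_samples(keep)
    meta = out.meta.copy()
    meta["oversampled"] = False
    if len(case_ids) == len(ctrl_ids):
        warnings.warn("groups have equal size; oversampling is a no-op",
                      stacklevel=2)
        return Dataset(out.panel, meta, out.values, out.mask)
    minority = case_ids if len(case_ids) < len(ctrl_ids) else ctrl_ids
    deficit = abs(len(case_ids) - len(ctrl_ids))
    rng = np.random.default_rng(seed)
    picks = minority[rng.integers(0, len(minority), size=deficit)]
    counts: dict[str, int] = {}
    new_ids = []
    for pid in picks:
        counts[pid] = counts.get(pid, 0) + 1
        new_ids.append(f"{pid}_ovs{counts[pid]}")
    dup_meta = meta.loc[picks].copy()
    dup_meta.index = new_ids
    dup_meta["oversampled"] = True
    dup_values = out.values.loc[picks].copy()
    dup_values.index = new_ids
    dup_mask = out.mask.loc[picks].copy()
    dup_mask.index = new_ids
    return Dataset(out.panel, pd.concat([meta, dup_meta]),
                   pd.concat([out.values, dup_values]),
                   pd.concat([out.mask, dup_mask]))


@dataclass(frozen=True)
class AdjustedTestResult:
    p: float
    coef: float
    flagged: bool
    note: str


def covariate_adjusted_test(values, labels, covariate) -> AdjustedTestResult:
    """Wald p for the feature in a logistic model adjusting for a binary
    covariate (e.g. corticosteroid treatment).

    The feature is standardized.  Perfect feature/covariate aliasing and
    complete separation are detected and flagged instead of producing a
    spurious p-value.
    """
    x = np.asarray(values, float)
    y = np.asarray(labels, int)
    c = np.asarray(covariate, float)
    z = (x - x.mean()) / (x.std() if x.std() > 0 else 1.0)
    if np.ptp(c) > 0:
        r = np.corrcoef(z, c)[0, 1]
        if abs(r) > 1 - 1e-10:
            return AdjustedTestResult(
                float("nan"), float("nan"), True,
                "feature aliases the covariate; feature term not identifiable")
    X = sm.add_constant(np.column_stack([z, c]))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            fit = sm.Logit(y, X).fit(disp=0, maxiter=200)
        bse = fit.bse[1]
        if not np.isfinite(bse) or bse > 1e3:
            raise np.linalg.LinAlgError("unstable standard error")
        return AdjustedTestResult(float(fit.pvalues[1]),
                                  float(fit.params[1]), False, "ok")
    except Exception:
        return AdjustedTestResult(
            float("nan"), float("nan"), True,
            "separation or non-convergence; consider a penalized fit")
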