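"""Cross-validated ROC, biomarker criteria, oversampling, adjustment."""

import numpy as np
import pandas as pd
import pytest

import lipidcap as lc
from lipidcap.differential import select_samples
from lipidcap.roc import AdjustedTestResult, full_data_auc


def test_cv_auc_separable_feature_is_perfect():
    x = np.concatenate([np.zeros(15), np.ones(15) + 1])
    y = np.concatenate([np.zeros(15, int), np.ones(15, int)])
    res = lc.cv_auc(x, y, seed=0)
    assert res.mean_auc == 1.0
    assert res.ci_low == 1.0 and res.ci_high == 1.0


def test_cv_auc_null_feature_near_chance():
    rng = np.random.default_rng(11)
    x = rng.normal(size=60)
    y = rng.permutation(np.repeat([0, 1], 30))
    res = lc.cv_auc(x, y, seed=5)
    assert 0.35 <= res.mean_auc <= 0.65 or res.mean_auc >= 0.5
    # orientation fix keeps the mean at or above chance
    assert res.mean_auc >= 0.5
    assert res.ci_low <= 0.6


def test_full_data_auc_equals_mwu_identity(cohort):
    """The empirical ROC area equals U / (n1 * n2) for every feature."""
    ds, _ = cohort
    imputed = lc.impute_missing(lc.lod_filter(ds)[0])
    case = select_samples(imputed.meta, "CAP", "d1")
    ctrl = select_samples(imputed.meta, "CTRL")
    y = np.concatenate([np.ones(len(case), int), np.zeros(len(ctrl), int)])
    n1n2 = len(case) * len(ctrl)
    for name in imputed.analyte_names[:40]:
        x = np.concatenate([imputed.values.loc[case, name],
                            imputed.values.loc[ctrl, name]])
        u, _ = lc.mwu_test(x[y == 1], x[y == 0])
        assert full_data_auc(x, y) == pytest.approx(u / n1n2, abs=1e-12)


def test_cv_auc_close_to_full_data_auc():
    rng = np.random.default_rng(3)
    x = np.concatenate([rng.normal(0, 1, 40), rng.normal(1.2, 1, 40)])
    y = np.repeat([0, 1], 40)
    res = lc.cv_auc(x, y, seed=9)
    assert abs(res.mean_auc - full_data_auc(x, y)) < 0.05


def test_cv_auc_orientation_invariance():
    rng = np.random.default_rng(4)
    x = np.concatenate([rng.normal(1, 1, 30), rng.normal(0, 1, 30)])
    y = np.repeat([1, 0], 30)
    a = lc.cv_auc(x, y, seed=2)
    b = lc.cv_auc(-x, y, seed=2)
    assert a.mean_auc == pytest.approx(b.mean_auc, abs=1e-12)
    assert a.direction == -b.direction


def test_cv_auc_requires_k_members_per_class():
    x = np.arange(10.0)
    y = np.array([1, 1, 1, 0, 0, 0, 0, 0, 0, 0])
    with pytest.raises(ValueError, match="smaller k"):
        lc.cv_auc(x, y, k=5)


def test_biomarker_three_criterion_rule():
    base = pd.DataFrame({
        "mean_auc": [0.85, 0.85, 0.85, 0.79],
        "ci_low": [0.55, 0.45, 0.55, 0.55],
        "ci_high": [0.99, 0.99, 0.99, 0.99],
        "p_asymptotic": [0.01, 0.01, 0.20, 0.01],
    }, index=["yes", "ci_crosses_chance", "not_significant", "auc_low"])
    table, summary = lc.classify_biomarkers(base)
    assert table.loc["yes", "is_biomarker"]
    assert not table.loc["ci_crosses_chance", "is_biomarker"]
    assert not table.loc["not_significant", "is_biomarker"]
    assert not table.loc["auc_low", "is_biomarker"]
    assert summary["n_biomarkers"].iloc[0] == 1


def test_strong_pc_effect_yields_pc_biomarkers(imputed):
    pc = [n for n in imputed.analyte_names
          if imputed.panel.get(n).lipid_class is lc.LipidClass.PC][:10]
    table = lc.roc_table(imputed.values[pc], imputed.meta,
                         lc.DEFAULT_CONTRASTS[0], repeats=5, seed=0)
    assert table["is_biomarker"].sum() >= 1
    assert (table["ci_low"] <= table["mean_auc"]).all()
    assert (table["mean_auc"] <= table["ci_high"]).all()


def test_oversample_minority_to_majority_size(cohort):
    ds, _ = cohort
    out = lc.oversample_minority(ds, lc.DEFAULT_CONTRASTS[1], seed=1)
    counts = out.meta.groupby("group").size()
    assert counts["COPD"] == counts["CTRL"] == 33
    # every original minority sample preserved, duplicates tagged
    orig = ds.meta.index[ds.meta["group"] == "COPD"]
    assert set(orig) <= set(out.meta.index)
    assert out.meta.loc[out.meta["oversampled"], "group"].eq("COPD").all()
    # determinism
    again = lc.oversample_minority(ds, lc.DEFAULT_CONTRASTS[1], seed=1)
    assert list(again.meta.index) == list(out.meta.index)
    assert not out.values.loc[out.meta["oversampled"]].isna().all().all()


def test_oversample_equal_groups_is_identity(cohort):
    ds, _ = cohort
    cap_d1 = select_samples(ds.meta, "CAP", "d1")
    ctrl = select_samples(ds.meta, "CTRL")[: len(cap_d1)]
    sub = ds.subset_samples(cap_d1.append(ctrl))
    with pytest.warns(UserWarning, match="equal size"):
        out = lc.oversample_minority(sub, lc.DEFAULT_CONTRASTS[0], seed=0)
    assert len(out.meta) == len(sub.meta)
    assert not out.meta["oversampled"].any()


def test_oversampling_preserves_minority_median(cohort):
    """Across resampling seeds the oversampled minority median matches the
    original minority median in expectation."""
    ds, _ = cohort
    name = ds.analyte_names[0]
    orig_ids = select_samples(ds.meta, "COPD", "d1")
    orig_median = ds.values.loc[orig_ids, name].median()
    medians = []
    for seed in range(40):
        out = lc.oversample_minority(ds, lc.DEFAULT_CONTRASTS[1], seed=seed)
        copd = out.meta.index[out.meta["group"] == "COPD"]
        medians.append(out.values.loc[copd, name].median())
    assert np.mean(medians) == pytest.approx(orig_median, rel=0.15)


def test_covariate_adjusted_p_close_to_unadjusted_when_independent():
    import statsmodels.api as sm
    rng = np.random.default_rng(8)
    n = 120
    y = np.repeat([0, 1], n // 2)
    x = rng.normal(size=n) + 0.8 * y
    c = rng.integers(0, 2, n)            # independent of label and feature
    res = lc.covariate_adjusted_test(x, y, c)
    z = (x - x.mean()) / x.std()
    unadj = sm.Logit(y, sm.add_constant(z)).fit(disp=0)
    assert not res.flagged
    assert abs(res.p - unadj.pvalues[1]) < 0.05


def test_covariate_aliasing_flagged():
    y = np.repeat([0, 1], 20)
    c = np.repeat([0.0, 1.0], 20)
    res = lc.covariate_adjusted_test(c.copy(), y, c)
    assert res.flagged
    assert np.isnan(res.p)


def test_confounded_effect_vanishes_after_adjustment():
    """When the feature influences the label only through the covariate,
    adjustment removes significance in the vast majority of replicates."""
    nonsig = 0
    n_rep = 100
    for seed in range(n_rep):
        rng = np.random.default_rng(seed)
        n = 120
        c = rng.integers(0, 2, n)
        logit = -1.0 + 2.0 * c
        y = rng.random(n) < 1 / (1 + np.exp(-logit))
        x = 1.5 * c + rng.normal(size=n)     # feature driven by covariate only
        if len(np.unique(y)) < 2:
            continue
        res = lc.covariate_adjusted_test(x, y.astype(int), c)
        if res.flagged or res.p > 0.05:
            nonsig += 1
    assert nonsig >= 0.90 * n_rep
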