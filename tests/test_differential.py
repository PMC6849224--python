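"""Fold changes, rank tests and Benjamini-Hochberg correction."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipidcap as lc
from lipidcap.differential import Contrast, select_samples

from conftest import toy_dataset


# -------------------------------------------------------------- fold change
def test_fold_change_examples():
    assert lc.fold_change([2, 4, 6], [1, 2, 3]) == pytest.approx(2.0)
    assert lc.fold_change([1, 2, 3], [1, 2, 3]) == pytest.approx(1.0)
    assert np.isnan(lc.fold_change([1, 2], [0, 0, 0]))
    with pytest.raises(ValueError):
        lc.fold_change([], [1])


def test_fold_change_recovers_generator_truth(cohort):
    """Estimated CAP d1 / control fold of PC analytes matches the
    per-analyte generator truth within 20%."""
    ds, truth = cohort
    imputed = lc.impute_missing(lc.lod_filter(ds)[0])
    d1 = select_samples(imputed.meta, "CAP", "d1")
    ctrl = select_samples(imputed.meta, "CTRL")
    pc = [n for n in imputed.analyte_names
          if imputed.panel.get(n).lipid_class is lc.LipidClass.PC]
    est = (imputed.values.loc[d1, pc].median()
           / imputed.values.loc[ctrl, pc].median())
    true = truth.effects.loc[("CAP", "d1"), pc]
    rel = (est / true).to_numpy()
    assert np.median(np.abs(rel - 1)) < 0.20


# ------------------------------------------------------------------- MWU
def test_mwu_hand_counted_u():
    u, p = lc.mwu_test([1, 2, 3], [4, 5, 6])     # zero pairwise wins for x
    assert u == 0.0
    assert p < 0.1


def test_mwu_identical_samples():
    u, p = lc.mwu_test([1, 2, 3, 4], [1, 2, 3, 4])
    assert p > 0.9
    u, p = lc.mwu_test([5, 5, 5], [5, 5, 5])     # fully tied: degenerate
    assert p == 1.0


def test_mwu_asymptotic_close_to_exact_permutation():
    """On tiny samples the asymptotic p agrees with full enumeration of the
    permutation null within 0.05."""
    rng = np.random.default_rng(0)
    for _ in range(10):
        pooled = rng.normal(size=10)
        x, y = pooled[:5], pooled[5:]
        u_obs, p_asym = lc.mwu_test(x, y)

        def u_stat(a, b):
            return sum((ai > bi) + 0.5 * (ai == bi)
                       for ai in a for bi in b)

        n = len(pooled)
        u_center = len(x) * len(y) / 2
        count = 0
        total = 0
        for idx in itertools.combinations(range(n), 5):
            a = pooled[list(idx)]
            b = pooled[[i for i in range(n) if i not in idx]]
            if abs(u_stat(a, b) - u_center) >= abs(u_obs - u_center) - 1e-12:
                count += 1
            total += 1
        p_exact = count / total
        assert abs(p_asym - p_exact) <= 0.05


# ------------------------------------------------------------------- KW
def test_kw_identical_groups_h_zero():
    h, p = lc.kw_test([[1, 2, 3], [1, 2, 3], [1, 2, 3]])
    assert h == pytest.approx(0.0, abs=1e-12)
    assert p == 1.0


def test_kw_two_groups_matches_mwu():
    rng = np.random.default_rng(1)
    for _ in range(20):
        x = rng.normal(size=12)
        y = rng.normal(0.5, size=15)
        _, p_mwu = lc.mwu_test(x, y)
        _, p_kw = lc.kw_test([x, y])
        assert abs(p_mwu - p_kw) < 0.02


def test_kw_matches_rank_formula_by_hand():
    """H from the textbook rank formula on three tiny tie-free groups."""
    groups = [[1.0, 3.0, 5.0], [2.0, 4.0, 9.0], [6.0, 7.0, 8.0]]
    pooled = np.concatenate(groups)
    ranks = pd.Series(pooled).rank().to_numpy()
    n = len(pooled)
    start = 0
    h = 0.0
    for g in groups:
        r = ranks[start:start + len(g)]
        h += r.sum() ** 2 / len(g)
        start += len(g)
    h = 12 / (n * (n + 1)) * h - 3 * (n + 1)
    h_got, _ = lc.kw_test(groups)
    assert h_got == pytest.approx(h, abs=1e-10)


# ------------------------------------------------------------------- BH
def _bh_bruteforce(pvals, fdr=0.05):
    """Literal step-up rule: find the largest k with p_(k) <= k*fdr/m; the
    q-value is the minimum of p_(j)*m/j over j >= rank."""
    p = np.asarray(pvals, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for rank_pos, idx in enumerate(order, start=1):
        candidates = [p[order[j - 1]] * m / j for j in range(rank_pos, m + 1)]
        q[idx] = min(1.0, min(candidates))
    return q, q <= fdr


def test_bh_worked_example():
    q, reject = lc.bh_adjust([0.01, 0.02, 0.03, 0.04])
    assert np.allclose(q, [0.04, 0.04, 0.04, 0.04])
    assert reject.all()


def test_bh_trivial_cases():
    q, reject = lc.bh_adjust([0.2])
    assert q[0] == pytest.approx(0.2) and not reject[0]
    q, reject = lc.bh_adjust([1.0, 1.0, 1.0])
    assert not reject.any()
    with pytest.raises(ValueError):
        lc.bh_adjust([0.5, 1.5])


def test_bh_matches_bruteforce_and_statsmodels():
    from statsmodels.stats.multitest import multipletests
    rng = np.random.default_rng(2024)
    for _ in range(1000):
        m = int(rng.integers(1, 40))
        p = rng.random(m)
        q, reject = lc.bh_adjust(p)
        q_bf, reject_bf = _bh_bruteforce(p)
        assert np.allclose(q, q_bf, atol=1e-12)
        assert (reject == reject_bf).all()
        sm_reject, sm_q, *_ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(q, sm_q, atol=1e-12)
        assert (reject == sm_reject).all()


# ------------------------------------------------------- differential table
def test_differential_table_sorted_and_consistent(imputed):
    table = lc.differential_table(imputed.values, imputed.meta,
                                  lc.DEFAULT_CONTRASTS[0])
    fc = table["fold_change"].to_numpy()
    assert (np.diff(fc[~np.isnan(fc)]) <= 1e-12).all()
    # q >= p always; tiers consistent with thresholds
    assert (table["q_bh"] >= table["p_mwu"] - 1e-12).all()
    sig = table[table["sig_tier"] == "p001"]
    assert (sig["p_mwu"] < 0.001).all()


def test_differential_mostly_downregulated_in_cap(imputed):
    """With effect directions mirroring the disease, >90% of significantly
    changed analytes at admission are downregulated."""
    table = lc.differential_table(imputed.values, imputed.meta,
                                  lc.DEFAULT_CONTRASTS[0])
    sig = table[table["p_mwu"] < 0.05]
    assert len(sig) > 30
    assert (sig["fold_change"] < 1).mean() > 0.9


def test_differential_null_split_half_calibrated():
    """Splitting the control group against itself: the BH rejection rate
    stays near the nominal FDR."""
    cfg = lc.default_config(seed=123, n_ctrl=66, lod_quantile=0.0)
    ds, _ = lc.generate_cohort(cfg)
    ctrl = ds.meta.index[ds.meta["group"] == "CTRL"]
    meta = ds.meta.loc[ctrl].copy()            # controls only
    half = ctrl[: len(ctrl) // 2]
    meta.loc[half, "group"] = "CAP"            # relabel half as pseudo-cases
    meta.loc[half, "timepoint"] = "d1"
    table = lc.differential_table(ds.values.loc[ctrl], meta,
                                  lc.DEFAULT_CONTRASTS[0])
    assert table["reject_fdr"].mean() <= 0.075


def test_contrast_validation():
    with pytest.raises(ValueError):
        Contrast(("CAP", "d1"), ("CAP", "d1"), "self")
    ds = toy_dataset([[1.0, 1.0]] * 4, ["CAP", "CAP", "CTRL", "CTRL"])
    with pytest.raises(ValueError, match="3 samples"):
        lc.differential_table(ds.values, ds.meta, lc.DEFAULT_CONTRASTS[0])


def test_kw_timecourse_detects_recovery(imputed):
    lysopc = [n for n in imputed.analyte_names
              if imputed.panel.get(n).lipid_class is lc.LipidClass.LYSOPC]
    p = lc.kw_timecourse(imputed.values[lysopc], imputed.meta)
    assert (p < 0.05).mean() > 0.8
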