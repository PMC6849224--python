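"""Fold changes, nonparametric tests and Benjamini-Hochberg correction.

Fold change is the ratio of case to control medians.  Group differences
are assessed with the Mann-Whitney U test (two-sided asymptotic p, average
ranks with tie and continuity corrections) and the Kruskal-Wallis H test
for the CAP time course.  Multiple testing is controlled per feature
family (analytes and indicators separately) with the Benjamini-Hochberg
step-up procedure at FDR 0.05.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .core import Dataset

__all__ = [
    "Contrast",
    "DEFAULT_CONTRASTS",
    "fold_change",
    "mwu_test",
    "kw_test",
    "bh_adjust",
    "differential_table",
    "kw_timecourse",
    "select_samples",
]


@dataclass(frozen=True)
class Contrast:
    """A case-vs-control comparison between (group, timepoint) selections.

    ``timepoint=None`` selects all samples of the group; single-draw groups
    match any requested timepoint.
    """

    case: tuple[str, str | None]
    control: tuple[str, str | None]
    name: str

    def __post_init__(self) -> None:
        if self.case == self.control:
            raise ValueError(f"{self.name}: case equals control")


DEFAULT_CONTRASTS = (
    Contrast(("CAP", "d1"), ("CTRL", None), "CAP_d1_vs_CTRL"),
    Contrast(("COPD", "d1"), ("CTRL", None), "COPD_vs_CTRL"),
    Contrast(("CAP", "d1"), ("COPD", "d1"), "CAP_d1_vs_COPD"),
)


def select_samples(meta: pd.DataFrame, group: str,
                   timepoint: str | None = None) -> pd.Index:
    keep = meta["group"] == group
    if timepoint is not None:
        keep &= (meta["timepoint"] == timepoint) | (
            meta["timepoint"] == "single")
    return meta.index[keep]


def fold_change(case_values, control_values) -> float:
    """Ratio of medians, ``median(case) / median(control)``.

    Returns NaN (undefined) when the control median is zero.
    """
    case = np.asarray(case_values, float)
    control = np.asarray(control_values, float)
    if case.size == 0 or control.size == 0:
        raise ValueError("fold_change needs nonempty case and control")
    m_ctrl = np.median(control)
    if m_ctrl == 0:
        return float("nan")
    return float(np.median(case) / m_ctrl)


def mwu_test(x, y) -> tuple[float, float]:
    """Mann-Whitney U (two-sided asymptotic p with tie correction).

    Returns ``(U, p)`` with U counted for ``x`` ("number of pairwise wins"),
    so that ``U / (n1 * n2)`` is the empirical ROC area of ``x`` vs ``y``.
    Completely tied data yield the degenerate ``p = 1``.
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.size < 3 or y.size < 3:
        raise ValueError("mwu_test needs at least 3 values per group")
    if np.ptp(np.concatenate([x, y])) == 0:
        return x.size * y.size / 2.0, 1.0
    res = stats.mannwhitneyu(x, y, alternative="two-sided",
                             method="asymptotic", use_continuity=True)
    return float(res.statistic), float(res.pvalue)


def kw_test(groups) -> tuple[float, float]:
    """Kruskal-Wallis H with tie correction and chi-square asymptotic p."""
    groups = [np.asarray(g, float) for g in groups]
    if len(groups) < 2:
        raise ValueError("kw_test needs at least 2 groups")
    if any(g.size < 3 for g in groups):
        raise ValueError("kw_test needs at least 3 values per group")
    if np.ptp(np.concatenate(groups)) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def bh_adjust(pvals, fdr: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini-Hochberg step-up adjusted q-values and rejection flags.

    q_(i) = min over j >= i of p_(j) * m / j (monotonicity enforced),
    reject iff q <= fdr.
    """
    p = np.asarray(pvals, float)
    if p.size == 0:
        return np.array([]), np.array([], dtype=bool)
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q_sorted = np.minimum(q_sorted, 1.0)
    q = np.empty_like(q_sorted)
    q[order] = q_sorted
    return q, q <= fdr


def _sig_tier(p: float) -> str:
    if p < 0.001:
        return "p001"
    if p < 0.01:
        return "p01"
    if p < 0.05:
        return "p05"
    return "ns"


def differential_table(features: pd.DataFrame, meta: pd.DataFrame,
                       contrast: Contrast, fdr: float = 0.05,
                       family: str = "analytes") -> pd.DataFrame:
    """Per-feature fold change, Mann-Whitney p, BH q and significance tiers
    for one contrast, sorted by descending fold change.

    ``features`` is samples x features (analyte concentrations or metabolic
    indicators; NaN cells — e.g. undefined ratios — are dropped per
    feature).  BH correction is applied across the features of this table
    only, i.e. within the feature family.
    """
    case_ids = select_samples(meta, *contrast.case)
    ctrl_ids = select_samples(meta, *contrast.control)
    if len(case_ids) < 3 or len(ctrl_ids) < 3:
        raise ValueError(
            f"{contrast.name}: needs >= 3 samples per side, got "
            f"{len(case_ids)}/{len(ctrl_ids)}")
    rows = []
    for name in features.columns:
        case = features.loc[case_ids, name].dropna().to_numpy()
        ctrl = features.loc[ctrl_ids, name].dropna().to_numpy()
        fc = fold_change(case, ctrl) if case.size and ctrl.size else np.nan
        u, p = mwu_test(case, ctrl)
        rows.append({"feature": name, "fold_change": fc, "U": u, "p_mwu": p,
                     "n_case": case.size, "n_control": ctrl.size})
    table = pd.DataFrame(rows).set_index("feature")
    q, reject = bh_adjust(table["p_mwu"].to_numpy(), fdr=fdr)
    table["q_bh"] = q
    table["reject_fdr"] = reject
    table["sig_tier"] = table["p_mwu"].map(_sig_tier)
    table["fdr_tier"] = table["q_bh"].map(_sig_tier)
    table["contrast"] = contrast.name
    table["family"] = family
    return table.sort_values("fold_change", ascending=False,
                             na_position="last")


def kw_timecourse(features: pd.DataFrame, meta: pd.DataFrame,
                  group: str = "CAP") -> pd.Series:
    """Kruskal-Wallis p per feature across the group's time course."""
    tps = sorted(set(meta.loc[meta["group"] == group, "timepoint"]))
    out = {}
    for name in features.columns:
        groups = [features.loc[select_samples(meta, group, tp), name]
                  .dropna().to_numpy() for tp in tps]
        out[name] = kw_test(groups)[1]
    return pd.Series(out, name="p_kw")
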