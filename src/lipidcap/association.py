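"""Ordination and marker-correlation analyses.

PCA on standardized features summarises global lipid "reprogramming":
group/timepoint centroids trace the normalization of the CAP profile
toward controls.  The between-group reprogramming distance is computed in
the full standardized feature space (not the 2-D projection) and divided
by the square root of the feature count so subsets of different sizes
(whole panel, single classes, indicators) are comparable.  Pearson
correlations of features with CRP and PCT are computed over the pooled CAP
time course.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

from .differential import select_samples

__all__ = [
    "CentroidMap",
    "standardize_matrix",
    "pca_centroids",
    "centroid_distance",
    "pearson_vs_marker",
    "correlation_summary",
]


def standardize_matrix(values: pd.DataFrame) -> pd.DataFrame:
    """Center to mean 0 and scale to unit (population) variance per column.

    Zero-variance columns cannot be scaled and are dropped with a warning.
    """
    mat = values.astype(float)
    sd = mat.std(axis=0, ddof=0)
    constant = sd[sd == 0].index.tolist()
    if constant:
        warnings.warn(f"dropping zero-variance columns: {constant}",
                      stacklevel=2)
        mat = mat.drop(columns=constant)
        sd = sd.drop(constant)
    return (mat - mat.mean(axis=0)) / sd


@dataclass
class CentroidMap:
    """PCA scores, per-(group, timepoint) centroids and loadings."""

    scores: pd.DataFrame                 # samples x components
    centroids: pd.DataFrame              # (group, timepoint) x components
    feature_centroids: pd.DataFrame      # (group, timepoint) x features (z)
    explained_variance_ratio: np.ndarray
    loadings: pd.DataFrame               # features x components


def _group_keys(meta: pd.DataFrame) -> list[tuple[str, str]]:
    keys = meta[["group", "timepoint"]].drop_duplicates()
    return [tuple(r) for r in keys.to_numpy()]


def pca_centroids(features: pd.DataFrame, meta: pd.DataFrame,
                  n_components: int = 2) -> CentroidMap:
    """PCA of the standardized feature matrix with group/timepoint centroids.

    Each centroid is the mean score vector of all samples in that
    (group, timepoint) cell; a single-sample cell's centroid is that
    sample's scores.  Loadings are the component weights per feature.
    """
    z = standardize_matrix(features)
    if z.shape[0] < 2 or z.shape[1] < 2:
        raise ValueError("PCA needs at least 2 samples and 2 features")
    n_components = min(n_components, z.shape[0], z.shape[1])
    pca = PCA(n_components=n_components, svd_solver="full")
    scores = pd.DataFrame(pca.fit_transform(z.to_numpy()), index=z.index,
                          columns=[f"PC{i+1}" for i in range(n_components)])
    meta_aligned = meta.loc[z.index]
    cent_rows, feat_rows, index = [], [], []
    for g, tp in _group_keys(meta_aligned):
        ids = meta_aligned.index[(meta_aligned["group"] == g)
                                 & (meta_aligned["timepoint"] == tp)]
        cent_rows.append(scores.loc[ids].mean(axis=0))
        feat_rows.append(z.loc[ids].mean(axis=0))
        index.append((g, tp))
    midx = pd.MultiIndex.from_tuples(index, names=["group", "timepoint"])
    loadings = pd.DataFrame(pca.components_.T, index=z.columns,
                            columns=scores.columns)
    return CentroidMap(
        scores=scores,
        centroids=pd.DataFrame(cent_rows, index=midx),
        feature_centroids=pd.DataFrame(feat_rows, index=midx),
        explained_variance_ratio=pca.explained_variance_ratio_,
        loadings=loadings,
    )


def centroid_distance(features: pd.DataFrame, meta: pd.DataFrame,
                      group_a: str, group_b: str,
                      timepoint: str | None = "d1"
                      ) -> tuple[float, float]:
    """Euclidean distance between two group-mean vectors in standardized
    feature space.

    Returns ``(raw, normalized)`` where ``normalized = raw / sqrt(p)``
    (p = number of features), making subsets of different sizes
    comparable.  ``timepoint`` applies only to groups with a time course.
    """
    if features.shape[1] == 0:
        raise ValueError("empty feature subset")
    z = standardize_matrix(features)
    ids_a = select_samples(meta, group_a, timepoint)
    ids_b = select_samples(meta, group_b, timepoint)
    if len(ids_a) == 0 or len(ids_b) == 0:
        raise ValueError(f"empty selection for {group_a!r} or {group_b!r}")
    diff = z.loc[ids_a].mean(axis=0) - z.loc[ids_b].mean(axis=0)
    raw = float(np.linalg.norm(diff))
    return raw, raw / np.sqrt(z.shape[1])


def pearson_vs_marker(features: pd.DataFrame, meta: pd.DataFrame,
                      marker: str, group: str = "CAP") -> pd.DataFrame:
    """Pearson r and two-sided p of each feature against a clinical marker,
    over all samples of ``group`` (CAP pooled across its time course).

    Zero-variance features (or marker) yield an undefined flag.
    """
    ids = select_samples(meta, group)
    m = meta.loc[ids, marker].astype(float)
    rows = []
    for name in features.columns:
        x = features.loc[ids, name].astype(float)
        ok = x.notna() & m.notna()
        undefined = (ok.sum() < 3 or np.ptp(x[ok].to_numpy()) == 0
                     or np.ptp(m[ok].to_numpy()) == 0)
        if undefined:
            r, p = np.nan, np.nan
        else:
            r, p = stats.pearsonr(x[ok], m[ok])
        rows.append({"feature": name, "marker": marker, "r": float(r),
                     "p": float(p), "n": int(ok.sum()),
                     "undefined": bool(undefined)})
    return pd.DataFrame(rows).set_index("feature")


def correlation_summary(corr: pd.DataFrame, alpha: float = 0.05
                        ) -> dict[str, int]:
    """Counts of significant negative/positive correlations."""
    sig = corr[(~corr["undefined"]) & (corr["p"] < alpha)]
    return {
        "n_features": int(len(corr)),
        "n_significant": int(len(sig)),
        "n_significant_negative": int((sig["r"] < 0).sum()),
        "n_significant_positive": int((sig["r"] > 0).sum()),
    }
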