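"""Standardization, PCA centroids, reprogramming distances, correlations."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import lipidcap as lc

from conftest import toy_dataset


def test_standardize_hand_example():
    df = pd.DataFrame({"a": [1.0, 2.0, 3.0]})
    z = lc.standardize_matrix(df)
    sigma = np.sqrt(2.0 / 3.0)                       # population scaling
    assert np.allclose(z["a"], [-1 / sigma, 0.0, 1 / sigma])
    assert np.allclose(z["a"], [-1.22474487, 0, 1.22474487], atol=1e-6)


def test_standardize_idempotent_and_drops_constant():
    rng = np.random.default_rng(0)
    df = pd.DataFrame(rng.normal(size=(30, 3)), columns=list("abc"))
    z1 = lc.standardize_matrix(df)
    z2 = lc.standardize_matrix(z1)
    assert np.allclose(z1.to_numpy(), z2.to_numpy(), atol=1e-9)
    df["const"] = 5.0
    with pytest.warns(UserWarning, match="const"):
        z3 = lc.standardize_matrix(df)
    assert "const" not in z3.columns


def test_pca_single_sample_group_centroid_is_its_scores():
    rng = np.random.default_rng(1)
    vals = np.abs(rng.normal(5, 1, size=(7, 2))) + 0.1
    groups = ["CAP"] * 3 + ["COPD"] + ["CTRL"] * 3
    tps = ["d1"] * 3 + ["d1"] + ["single"] * 3
    ds = toy_dataset(vals, groups, timepoints=tps)
    cmap = lc.pca_centroids(ds.values, ds.meta)
    sid = ds.meta.index[ds.meta["group"] == "COPD"][0]
    assert np.allclose(cmap.centroids.loc[("COPD", "d1")],
                       cmap.scores.loc[sid])
    evr = cmap.explained_variance_ratio
    assert ((evr >= -1e-12) & (evr <= 1 + 1e-12)).all()
    assert (np.diff(evr) <= 1e-12).all()


def test_pca_symmetric_data_centroids_at_origin():
    vals = np.array([[1.0, 2.0], [3.0, 4.0], [3.0, 2.0], [1.0, 4.0]])
    ds = toy_dataset(vals, ["CAP"] * 4, timepoints=["d1"] * 4)
    cmap = lc.pca_centroids(ds.values, ds.meta)
    assert np.allclose(cmap.centroids.loc[("CAP", "d1")], 0.0, atol=1e-12)


def test_pca_full_reconstruction(imputed):
    from sklearn.decomposition import PCA
    z = lc.standardize_matrix(imputed.values.iloc[:, :30])
    pca = PCA(svd_solver="full")
    scores = pca.fit_transform(z.to_numpy())
    recon = scores @ pca.components_ + pca.mean_
    assert np.abs(recon - z.to_numpy()).max() < 1e-8


def test_cap_centroid_approaches_control_over_time(imputed):
    cmap = lc.pca_centroids(imputed.values, imputed.meta)
    ctrl = cmap.centroids.loc[("CTRL", "single")].to_numpy()
    dists = [np.linalg.norm(cmap.centroids.loc[("CAP", tp)].to_numpy() - ctrl)
             for tp in ("d1", "d2", "d4", "f1", "f2")]
    assert all(b < a for a, b in zip(dists, dists[1:]))


def test_centroid_distance_matches_manual_euclid():
    """Oracle: standardize by hand, subtract group means, take the norm;
    the normalized variant divides by sqrt(number of features)."""
    rng = np.random.default_rng(7)
    vals = np.abs(rng.normal(8, 2, size=(10, 2))) + 0.1
    groups = ["CAP"] * 5 + ["CTRL"] * 5
    ds = toy_dataset(vals, groups)
    z = (vals - vals.mean(axis=0)) / vals.std(axis=0, ddof=0)
    diff = z[:5].mean(axis=0) - z[5:].mean(axis=0)
    expected_raw = float(np.sqrt((diff ** 2).sum()))     # Pythagoras
    raw, norm = lc.centroid_distance(ds.values, ds.meta, "CAP", "CTRL")
    assert raw == pytest.approx(expected_raw, abs=1e-12)
    assert norm == pytest.approx(expected_raw / np.sqrt(2), abs=1e-12)


def test_centroid_distance_identical_groups_zero_and_scale_invariant():
    rng = np.random.default_rng(2)
    vals = np.abs(rng.normal(10, 2, size=(12, 2))) + 0.1
    groups = ["CAP"] * 6 + ["CTRL"] * 6
    ds = toy_dataset(vals, groups)
    # identical groups: duplicate control block
    vals2 = np.vstack([vals[6:], vals[6:]])
    ds_same = toy_dataset(vals2, groups)
    raw, norm = lc.centroid_distance(ds_same.values, ds_same.meta,
                                     "CAP", "CTRL", "d1")
    assert raw == pytest.approx(0.0, abs=1e-12)
    # rescaling features before standardization changes nothing
    raw1, norm1 = lc.centroid_distance(ds.values, ds.meta, "CAP", "CTRL")
    scaled = ds.values * np.array([10.0, 0.01])
    raw2, norm2 = lc.centroid_distance(scaled, ds.meta, "CAP", "CTRL")
    assert raw1 == pytest.approx(raw2, rel=1e-9)
    assert norm1 == pytest.approx(raw1 / np.sqrt(2), rel=1e-12)


def test_centroid_distance_empty_subset_rejected(imputed):
    with pytest.raises(ValueError, match="empty"):
        lc.centroid_distance(imputed.values.iloc[:, :0], imputed.meta,
                             "CAP", "CTRL")


def test_class_distance_ordering_single_cohort(imputed):
    norms = {}
    for cls, classes in (("PC", ("PC",)), ("lysoPC", ("lysoPC",)),
                         ("SM", ("SM", "SM(OH)")), ("AC", ("AC",))):
        names = [n for n in imputed.analyte_names
                 if imputed.panel.get(n).lipid_class.value in classes]
        _, norms[cls] = lc.centroid_distance(imputed.values[names],
                                             imputed.meta, "CAP", "CTRL")
    assert norms["PC"] > norms["lysoPC"] >= norms["SM"] > norms["AC"]


def test_pearson_exact_relationships(imputed):
    meta = imputed.meta
    cap_ids = meta.index[meta["group"] == "CAP"]
    feats = pd.DataFrame({
        "prop": 2.0 * meta["crp"],
        "anti": -meta["crp"] + 7.0,
    })
    rows = lc.pearson_vs_marker(feats, meta, "crp")
    assert rows.loc["prop", "r"] == pytest.approx(1.0)
    assert rows.loc["anti", "r"] == pytest.approx(-1.0)


def test_pearson_matches_covariance_formula():
    x = np.array([1.0, 2.0, 4.0, 5.0])
    y = np.array([1.0, 3.0, 3.0, 5.0])
    r_manual = (((x - x.mean()) * (y - y.mean())).sum()
                / np.sqrt(((x - x.mean()) ** 2).sum()
                          * ((y - y.mean()) ** 2).sum()))
    meta = pd.DataFrame({
        "subject_id": list("abcd"), "group": ["CAP"] * 4,
        "timepoint": ["d1", "d2", "d4", "f1"], "age": [50] * 4,
        "sex": ["M"] * 4, "crp": y,
    }, index=pd.Index(list("abcd"), name="sample_id"))
    feats = pd.DataFrame({"f": x}, index=meta.index)
    rows = lc.pearson_vs_marker(feats, meta, "crp")
    assert rows.loc["f", "r"] == pytest.approx(r_manual, abs=1e-12)


@settings(max_examples=25, deadline=None)
@given(st.floats(0.1, 10.0), st.floats(-5.0, 5.0))
def test_pearson_affine_invariance(a, b):
    rng = np.random.default_rng(5)
    x = rng.normal(size=20)
    y = x + rng.normal(scale=0.5, size=20)
    meta = pd.DataFrame({
        "subject_id": [f"s{i}" for i in range(20)], "group": ["CAP"] * 20,
        "timepoint": ["d1"] * 20, "age": [50] * 20, "sex": ["M"] * 20,
        "crp": y,
    }, index=pd.Index([f"s{i}" for i in range(20)], name="sample_id"))
    feats = pd.DataFrame({"f": x, "g": a * x + b}, index=meta.index)
    rows = lc.pearson_vs_marker(feats, meta, "crp")
    assert rows.loc["f", "r"] == pytest.approx(rows.loc["g", "r"], abs=1e-9)


def test_zero_variance_feature_flagged_undefined():
    meta = pd.DataFrame({
        "subject_id": list("abcd"), "group": ["CAP"] * 4,
        "timepoint": ["d1"] * 4, "age": [50] * 4, "sex": ["M"] * 4,
        "crp": [1.0, 2.0, 3.0, 4.0],
    }, index=pd.Index(list("abcd"), name="sample_id"))
    feats = pd.DataFrame({"f": [5.0] * 4}, index=meta.index)
    rows = lc.pearson_vs_marker(feats, meta, "crp")
    assert bool(rows.loc["f", "undefined"])


def test_lipid_correlations_with_crp_mostly_negative(imputed):
    rows = lc.pearson_vs_marker(imputed.values, imputed.meta, "crp")
    summary = lc.correlation_summary(rows)
    assert summary["n_significant_negative"] > summary[
        "n_significant_positive"]
    assert summary["n_significant_negative"] >= 0.5 * summary["n_features"]
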