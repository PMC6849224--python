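"""Global lipid reprogramming: PCA centroids, class distances, CRP links.

The CAP centroid drifts back toward the control centroid over the time
course; the per-class reprogramming distance at admission is largest for
phosphatidylcholines and smallest for acylcarnitines; and most lipids
correlate negatively with CRP across the CAP time course.
"""

import numpy as np

import lipidcap as lc

ds, _ = lc.generate_cohort(lc.default_config(seed=7))
imputed = lc.impute_missing(lc.lod_filter(ds)[0])
meta = imputed.meta

cmap = lc.pca_centroids(imputed.values, meta)
print("explained variance:",
      np.round(cmap.explained_variance_ratio, 2).tolist())
ctrl = cmap.centroids.loc[("CTRL", "single")].to_numpy()
for tp in ("d1", "d2", "d4", "f1", "f2"):
    d = np.linalg.norm(cmap.centroids.loc[("CAP", tp)].to_numpy() - ctrl)
    print(f"  CAP {tp} centroid distance to controls: {d:.2f}")

print("\nper-class reprogramming distance (CAP d1 vs CTRL, per feature):")
for cls, classes in (("PC", ("PC",)), ("lysoPC", ("lysoPC",)),
                     ("SM", ("SM", "SM(OH)")), ("AC", ("AC",))):
    names = [n for n in imputed.analyte_names
             if imputed.panel.get(n).lipid_class.value in classes]
    _, norm = lc.centroid_distance(imputed.values[names], meta,
                                   "CAP", "CTRL", "d1")
    print(f"  {cls:<7s} {norm:.2f}")

corr = lc.pearson_vs_marker(imputed.values, meta, "crp")
s = lc.correlation_summary(corr)
print(f"\nCRP correlations: {s['n_significant_negative']} negative / "
      f"{s['n_significant_positive']} positive significant "
      f"of {s['n_features']} analytes")
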