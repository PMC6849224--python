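"""End-to-end pipeline: simulate -> qc -> impute -> indicators -> diff ->
roc -> lfs -> ordination -> correlate, with a machine-readable manifest.

Every stage writes plain CSV artifacts into the output directory; the
manifest records per-stage output hashes and the child seed, so identical
configuration + seed give byte-identical manifests.  A single master seed
fans out deterministically to per-stage child seeds via
``numpy.random.SeedSequence.spawn``, making stages independently
reproducible.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import association, differential, indicators as ind_mod, preprocess, \
    resolution, roc as roc_mod, simulate
from .core import (
    Dataset,
    LipidClass,
    default_panel,
    read_dataset,
    write_dataset,
)
from .differential import DEFAULT_CONTRASTS, Contrast

__all__ = ["RunConfig", "run_all", "report", "STAGES"]

log = logging.getLogger("lipidcap")

STAGES = ("simulate", "qc", "impute", "indicators", "diff", "roc", "lfs",
          "ordination", "correlate")


@dataclass
class RunConfig:
    out_dir: str | Path = "lipidcap_run"
    seed: int = 0
    generator: simulate.GeneratorConfig | None = None
    conc_path: str | Path | None = None     # alternative to the generator
    meta_path: str | Path | None = None
    min_detect_frac: float = 0.75
    fdr: float = 0.05
    auc_min: float = 0.80
    alpha: float = 0.05
    k: int = 5
    repeats: int = 25
    contrasts: tuple[Contrast, ...] = DEFAULT_CONTRASTS
    roc_contrasts: tuple[str, ...] = ("CAP_d1_vs_CTRL", "COPD_vs_CTRL",
                                      "CAP_d1_vs_COPD")
    clinical_features: tuple[str, ...] = ("asm_activity",)
    markers: tuple[str, ...] = ("crp", "pct")

    def validate(self) -> None:
        for name, v, lo, hi in [("min_detect_frac", self.min_detect_frac, 0, 1),
                                ("fdr", self.fdr, 0, 1),
                                ("alpha", self.alpha, 0, 1),
                                ("auc_min", self.auc_min, 0.5, 1)]:
            if not lo < v <= hi:
                raise ValueError(f"{name} must lie in ({lo}, {hi}]: got {v}")
        if self.k < 2 or self.repeats < 1:
            raise ValueError("need k >= 2 and repeats >= 1")
        if (self.conc_path is None) != (self.meta_path is None):
            raise ValueError("conc_path and meta_path must be given together")


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def _child_seeds(seed: int, n: int) -> list[int]:
    # SeedSequence gives independent child streams; keep them below 2**31
    return [int(s.generate_state(1)[0] % (2**31 - 1))
            for s in np.random.SeedSequence(seed).spawn(n)]


def _write_csv(df: pd.DataFrame, path: Path, **kw) -> Path:
    df.to_csv(path, float_format="%.12g", **kw)
    return path


def run_all(config: RunConfig) -> dict:
    """Execute all stages in order and write ``manifest.json``.

    Returns the manifest dict.  A stage failure is recorded in the manifest
    before the exception propagates.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seeds = dict(zip(STAGES, _child_seeds(config.seed, len(STAGES))))
    manifest: dict = {"seed": config.seed, "stages": []}
    t_all = time.time()

    def record(stage: str, paths: dict[str, Path]) -> None:
        manifest["stages"].append({
            "stage": stage, "seed": seeds[stage],
            "outputs": {k: {"path": str(p.relative_to(out)),
                            "sha256": _sha256(p)}
                        for k, p in sorted(paths.items())},
        })
        log.info("stage %-10s done (%.1fs)", stage, time.time() - t_all)

    try:
        # ---- simulate / load ---------------------------------------------
        if config.conc_path is not None:
            panel = default_panel()
            ds = read_dataset(config.conc_path, config.meta_path, panel)
            paths = write_dataset(ds, out)
        else:
            gen = config.generator or simulate.default_config()
            gen = dataclasses.replace(gen, seed=seeds["simulate"])
            ds, truth = simulate.generate_cohort(gen)
            paths = write_dataset(ds, out)
            paths["truth"] = truth.write(out)
            paths["truth_clinical"] = out / "truth_clinical.csv"
        record("simulate", paths)

        # ---- qc -----------------------------------------------------------
        filtered, qc_report = preprocess.lod_filter(ds, config.min_detect_frac)
        qc_path = out / "qc_report.csv"
        qc_report.write(qc_path)
        record("qc", {"qc_report": qc_path})

        # ---- impute -------------------------------------------------------
        imputed = preprocess.impute_missing(filtered)
        imp_paths = {"imputed": _write_csv(
            imputed.values, out / "imputed_concentrations.csv",
            index_label="sample_id")}
        record("impute", imp_paths)

        # ---- indicators ---------------------------------------------------
        defs = ind_mod.default_indicator_defs()
        ind = ind_mod.compute_indicators(imputed, defs)
        ind_path = _write_csv(ind.values, out / "indicators.csv",
                              index_label="sample_id")
        record("indicators", {"indicators": ind_path})

        meta = imputed.meta
        analyte_features = imputed.values
        indicator_features = ind.values
        clinical_features = meta[list(config.clinical_features)].astype(float)

        # ---- differential -------------------------------------------------
        diff_tables = []
        for contrast in config.contrasts:
            for family, feats in (("analytes", analyte_features),
                                  ("indicators", indicator_features),
                                  ("clinical", clinical_features)):
                diff_tables.append(differential.differential_table(
                    feats, meta, contrast, fdr=config.fdr, family=family))
        diff_all = pd.concat(diff_tables)
        diff_path = _write_csv(diff_all, out / "differential.csv",
                               index_label="feature")
        record("diff", {"differential": diff_path})

        # ---- roc ----------------------------------------------------------
        roc_tables = []
        roc_rng = np.random.default_rng(seeds["roc"])
        for contrast in config.contrasts:
            if contrast.name not in config.roc_contrasts:
                continue
            for family, feats in (("analytes", analyte_features),
                                  ("indicators", indicator_features),
                                  ("clinical", clinical_features)):
                roc_tables.append(roc_mod.roc_table(
                    feats, meta, contrast, k=config.k,
                    repeats=config.repeats,
                    seed=int(roc_rng.integers(2**31 - 1)),
                    auc_min=config.auc_min, alpha=config.alpha,
                    family=family))
        roc_all = pd.concat(roc_tables)
        roc_path = _write_csv(roc_all, out / "roc.csv",
                              index_label="feature")
        record("roc", {"roc": roc_path})

        # ---- lfs ----------------------------------------------------------
        lfs_results = []
        fam_of = {}
        for family, feats in (("analytes", analyte_features),
                              ("indicators", indicator_features)):
            for name in feats.columns:
                series = resolution.median_ratio_series(feats, meta, name)
                lfs_results.append(resolution.lfs_ndf(series))
                fam_of[name] = family
        lfs_table = resolution.rank_resolution_markers(lfs_results)
        lfs_table["family"] = lfs_table.index.map(fam_of)
        lfs_path = _write_csv(lfs_table, out / "lfs.csv",
                              index_label="feature")
        record("lfs", {"lfs": lfs_path})

        # ---- ordination ----------------------------------------------------
        cmap = association.pca_centroids(analyte_features, meta)
        cent_path = _write_csv(cmap.centroids, out / "centroids.csv")
        load_path = _write_csv(cmap.loadings, out / "loadings.csv",
                               index_label="feature")
        dist_rows = []
        subsets: dict[str, pd.DataFrame] = {"all_analytes": analyte_features}
        for cls in ("PC", "lysoPC", "SM", "AC"):
            members = [n for n in analyte_features.columns
                       if imputed.panel.get(n).lipid_class in (
                           (LipidClass.SM, LipidClass.SM_OH)
                           if cls == "SM" else (LipidClass(cls),))]
            if members:
                subsets[cls] = analyte_features[members]
        subsets["indicators"] = indicator_features
        for subset_name, feats in subsets.items():
            for grp in ("CAP", "COPD"):
                raw, norm = association.centroid_distance(
                    feats, meta, grp, "CTRL", "d1")
                dist_rows.append({"subset": subset_name, "group": grp,
                                  "raw": raw, "normalized": norm})
        dist_path = _write_csv(pd.DataFrame(dist_rows),
                               out / "distances.csv", index=False)
        record("ordination", {"centroids": cent_path, "loadings": load_path,
                              "distances": dist_path})

        # ---- correlate -----------------------------------------------------
        corr_tables = []
        for marker in config.markers:
            for family, feats in (("analytes", analyte_features),
                                  ("indicators", indicator_features),
                                  ("clinical", clinical_features)):
                tab = association.pearson_vs_marker(feats, meta, marker)
                tab["family"] = family
                corr_tables.append(tab)
        corr_all = pd.concat(corr_tables)
        corr_path = _write_csv(corr_all, out / "correlations.csv",
                               index_label="feature")
        record("correlate", {"correlations": corr_path})
    except Exception as exc:
        manifest["failed_at"] = (STAGES[len(manifest["stages"])]
                                 if len(manifest["stages"]) < len(STAGES)
                                 else "unknown")
        manifest["error"] = str(exc)
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest


def report(out_dir: str | Path) -> dict:
    """Summarise a completed run from its stage artifacts.

    Emits per-contrast biomarker counts, the fold-change/AUC/p table of
    called biomarkers, the top resolution markers (LFS, 1-NDF), and the
    correlation summary; written to ``report.json``.
    """
    out = Path(out_dir)
    manifest_path = out / "manifest.json"
    if not manifest_path.exists():
        raise FileNotFoundError(f"no manifest in {out}; run the pipeline first")
    manifest = json.loads(manifest_path.read_text())
    done = {s["stage"] for s in manifest["stages"]}
    missing = set(STAGES) - done
    if missing:
        raise ValueError(f"incomplete run; missing stages: {sorted(missing)}")

    roc_all = pd.read_csv(out / "roc.csv", index_col="feature")
    diff_all = pd.read_csv(out / "differential.csv", index_col="feature")
    lfs_table = pd.read_csv(out / "lfs.csv", index_col="feature")
    corr_all = pd.read_csv(out / "correlations.csv", index_col="feature")

    counts = (roc_all.groupby(["contrast", "family"], observed=True)
              ["is_biomarker"].sum().astype(int).reset_index()
              .rename(columns={"is_biomarker": "n_biomarkers"}))
    biomarkers = roc_all[roc_all["is_biomarker"]].copy()
    key = ["contrast", "family"]
    fc = diff_all.reset_index().set_index(key + ["feature"])["fold_change"]
    biomarkers = biomarkers.reset_index().set_index(key + ["feature"])
    biomarkers["fold_change"] = fc.reindex(biomarkers.index)
    biomarkers = biomarkers.reset_index()

    corr_summary = {}
    for (marker, family), tab in corr_all.groupby(["marker", "family"],
                                                  observed=True):
        corr_summary[f"{marker}/{family}"] = association.correlation_summary(
            tab)

    rep = {
        "biomarker_counts": counts.to_dict(orient="records"),
        "biomarkers": biomarkers[key + ["feature", "fold_change", "mean_auc",
                                        "ci_low", "ci_high", "p_asymptotic"]]
        .to_dict(orient="records"),
        "top_resolution_markers": (
            lfs_table.sort_values("rank_score", ascending=False).head(10)
            [["lfs", "ndf", "one_minus_ndf", "rank_score", "family"]]
            .reset_index().to_dict(orient="records")),
        "correlation_summary": corr_summary,
    }
    (out / "report.json").write_text(json.dumps(rep, indent=2))
    return rep
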