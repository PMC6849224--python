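"""Analyte QC by detection fraction, and covariate-regression imputation.

Analytes are kept only when a measured value above the limit of detection
is available in at least 75% of all samples (pooled over groups and
timepoints).  Remaining missing cells are then replaced by predictions of
per-analyte ordinary-least-squares models on age, sex, disease group and
sample-collection timepoint, floored at half the analyte LOD so imputed
concentrations stay positive.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import Dataset, LipidClass

__all__ = ["QcReport", "lod_filter", "impute_missing", "ImputationError"]

DEFAULT_MIN_DETECT_FRAC = 0.75


class ImputationError(ValueError):
    """Raised when an analyte has too few observed values to fit the model."""


@dataclass
class QcReport:
    """Per-analyte detection fractions and keep/drop decisions."""

    table: pd.DataFrame          # analyte, lipid_class, detected_fraction, kept
    min_detect_frac: float

    @property
    def kept(self) -> list[str]:
        return self.table.index[self.table["kept"]].tolist()

    @property
    def dropped(self) -> list[str]:
        return self.table.index[~self.table["kept"]].tolist()

    @property
    def class_summary(self) -> pd.DataFrame:
        return (self.table.groupby("lipid_class", observed=True)["kept"]
                .agg(kept="sum", total="count")
                .assign(dropped=lambda t: t["total"] - t["kept"]))

    def write(self, path) -> None:
        self.table.to_csv(path, index_label="analyte", float_format="%.6g")


def lod_filter(ds: Dataset,
               min_detect_frac: float = DEFAULT_MIN_DETECT_FRAC
               ) -> tuple[Dataset, QcReport]:
    """Drop analytes detected above LOD in less than ``min_detect_frac``
    of all samples ("at least 75%" keeps an analyte at exactly 75%)."""
    if not 0 < min_detect_frac <= 1:
        raise ValueError("min_detect_frac must lie in (0, 1]")
    if ds.n_samples == 0:
        raise ValueError("cannot QC-filter an empty dataset")
    detected = ds.detected_fraction
    kept_flags = detected >= min_detect_frac
    table = pd.DataFrame({
        "lipid_class": [ds.panel.get(n).lipid_class.value
                        for n in ds.analyte_names],
        "detected_fraction": detected,
        "kept": kept_flags,
    })
    table.index.name = "analyte"
    report = QcReport(table=table, min_detect_frac=min_detect_frac)
    return ds.subset_analytes(report.kept), report


def _design_matrix(meta: pd.DataFrame) -> pd.DataFrame:
    """Covariate design: intercept, age, sex, group and timepoint indicators.

    Control/COPD samples (and CAP day 1) sit at the reference timepoint
    level, so timepoint effects are estimated from the CAP time course only.
    """
    X = pd.DataFrame(index=meta.index)
    X["intercept"] = 1.0
    X["age"] = meta["age"].astype(float)
    X["sex_M"] = (meta["sex"] == "M").astype(float)
    for g in ("CAP", "COPD"):
        X[f"group_{g}"] = (meta["group"] == g).astype(float)
    for tp in ("d2", "d4", "f1", "f2"):
        X[f"tp_{tp}"] = (meta["timepoint"] == tp).astype(float)
    return X


def impute_missing(ds: Dataset) -> Dataset:
    """Replace missing cells by per-analyte OLS predictions.

    Each analyte is regressed (observed cells only, all groups pooled) on
    age, sex, group and timepoint indicators; predictions for the missing
    cells are floored at half the analyte LOD.  Observed cells are never
    altered.  The result carries an empty missingness mask.
    """
    if not ds.mask.to_numpy().any():
        return ds.copy()
    X = _design_matrix(ds.meta).to_numpy()
    n_coef = X.shape[1]
    values = ds.values.to_numpy(copy=True)
    mask = ds.mask.to_numpy()
    lods = ds.panel.lods.reindex(ds.analyte_names).to_numpy()
    for j, name in enumerate(ds.analyte_names):
        miss = mask[:, j]
        if not miss.any():
            continue
        obs = ~miss & np.isfinite(values[:, j])
        if obs.sum() < n_coef + 2:
            raise ImputationError(
                f"analyte {name!r}: only {int(obs.sum())} observed values, "
                f"need at least {n_coef + 2} to fit the imputation model")
        Xo = X[obs]
        rank = np.linalg.matrix_rank(Xo)
        if rank < n_coef:
            warnings.warn(
                f"analyte {name!r}: rank-deficient design "
                f"(rank {rank} < {n_coef}); aliased columns resolved by "
                "minimum-norm least squares", stacklevel=2)
        beta, *_ = np.linalg.lstsq(Xo, values[obs, j], rcond=None)
        pred = X[miss] @ beta
        floor = lods[j] / 2.0 if np.isfinite(lods[j]) else 0.0
        values[miss, j] = np.maximum(pred, floor)
    out_values = pd.DataFrame(values, index=ds.values.index,
                              columns=ds.values.columns)
    empty_mask = pd.DataFrame(False, index=ds.mask.index,
                              columns=ds.mask.columns)
    return Dataset(ds.panel, ds.meta.copy(), out_values, empty_mask)
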