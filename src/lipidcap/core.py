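"""Panel registry, analyte nomenclature, dataset container and CSV I/O.

The analysis operates on a targeted lipidomics panel of 145 analytes
(76 phosphatidylcholines, 14 lysophosphatidylcholines, 15 sphingomyelins
including hydroxysphingomyelins, and 40 acylcarnitines), optionally
extended by 4 ceramides measured with a dedicated assay but analyzed
identically downstream.

Analyte names follow the common targeted-lipidomics nomenclature: ``Cx:y``
where ``x`` is the total number of side-chain carbon atoms and ``y`` the
total number of double bonds; ``aa`` marks two ester-linked fatty acids,
``ae`` one ether-linked fatty alcohol.  Acylcarnitines are written ``Cn``,
``Cn:m`` with optional ``-OH`` (hydroxyl), ``-DC`` (dicarboxyl) or
``-M-DC`` (methyl-dicarboxyl) moieties.

Concentrations are in micromolar (uM).  A cell is *missing* when it was
not measured (empty / ``NA``) or when the measured value lies below the
analyte's limit of detection (LOD); below-LOD raw values are retained in
files but masked for analysis and later replaced by imputation.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field, replace
from enum import Enum
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "LipidClass",
    "BondType",
    "AnalyteDef",
    "AnalyteNameError",
    "DatasetFormatError",
    "PanelRegistry",
    "Dataset",
    "parse_analyte_name",
    "default_panel",
    "load_panel",
    "save_panel",
    "read_dataset",
    "write_dataset",
    "GROUPS",
    "CAP_TIMEPOINTS",
    "TIMEPOINTS",
]

GROUPS = ("CAP", "COPD", "CTRL")
#: ordinal time course for the pneumonia group: admission day 1, days 2 and 4,
#: and two follow-up visits after completion of antibiotic treatment.
CAP_TIMEPOINTS = ("d1", "d2", "d4", "f1", "f2")
TIMEPOINTS = CAP_TIMEPOINTS + ("single",)

META_REQUIRED = ("subject_id", "group", "timepoint", "age", "sex")
META_OPTIONAL = ("crp", "pct", "asm_activity", "corticosteroid")


class LipidClass(str, Enum):
    PC = "PC"
    LYSOPC = "lysoPC"
    SM = "SM"
    SM_OH = "SM(OH)"
    AC = "AC"
    CER = "CER"


class BondType(str, Enum):
    AA = "aa"   # two ester-linked fatty acids
    AE = "ae"   # one ether-linked fatty alcohol
    A = "a"     # single ester-linked fatty acid (lysoPC)
    NONE = "none"


class AnalyteNameError(ValueError):
    """Raised when an analyte name does not follow the panel nomenclature."""


class DatasetFormatError(ValueError):
    """Raised when a concentration/metadata file pair fails validation."""


@dataclass(frozen=True)
class AnalyteDef:
    """One panel analyte.

    ``moiety`` carries the acylcarnitine suffix (``OH``, ``DC``, ``M-DC``)
    when present, since e.g. dicarboxyl-acylcarnitines enter dedicated
    metabolic indicators.
    """

    name: str
    lipid_class: LipidClass
    bond_type: BondType
    n_carbons: int
    n_double_bonds: int
    lod: float | None = None
    moiety: str | None = None

    def __post_init__(self) -> None:
        if self.n_carbons < 0 or self.n_double_bonds < 0:
            raise ValueError(f"{self.name}: negative carbon/double-bond count")
        if self.n_carbons > 0 and self.n_double_bonds > self.n_carbons:
            raise ValueError(
                f"{self.name}: {self.n_double_bonds} double bonds exceed "
                f"{self.n_carbons} carbons"
            )
        if self.lod is not None and not self.lod > 0:
            raise ValueError(f"{self.name}: LOD must be positive, got {self.lod}")


_PC_RE = re.compile(r"^PC (aa|ae) C(\d+):(\d+)$")
_LPC_RE = re.compile(r"^lysoPC a C(\d+):(\d+)$")
_SMOH_RE = re.compile(r"^SM \(OH\) C(\d+):(\d+)$")
_SM_RE = re.compile(r"^SM C(\d+):(\d+)$")
_CER_RE = re.compile(r"^Cer C(\d+):(\d+)$")
_AC_RE = re.compile(r"^C(\d+)(?::(\d+))?(?:-(M-DC|OH|DC))?$")

# trivial-name synonyms for short-chain acylcarnitines
_AC_SYNONYMS = {
    "carnitine": "C0",
    "acetylcarnitine": "C2",
    "propionylcarnitine": "C3",
    "butyrylcarnitine": "C4",
    "valerylcarnitine": "C5",
}


def parse_analyte_name(name: str) -> AnalyteDef:
    """Parse a panel analyte name into its class, bond type and ``Cx:y``.

    Returns an :class:`AnalyteDef` without a LOD.  Raises
    :class:`AnalyteNameError` naming the offending token otherwise.
    """
    if not name or not name.strip():
        raise AnalyteNameError("empty analyte name")
    name = name.strip()
    canonical = _AC_SYNONYMS.get(name.lower(), name)

    m = _PC_RE.match(canonical)
    if m:
        bond, c, d = m.group(1), int(m.group(2)), int(m.group(3))
        return AnalyteDef(name, LipidClass.PC, BondType(bond), c, d)
    m = _LPC_RE.match(canonical)
    if m:
        return AnalyteDef(name, LipidClass.LYSOPC, BondType.A,
                          int(m.group(1)), int(m.group(2)))
    m = _SMOH_RE.match(canonical)
    if m:
        return AnalyteDef(name, LipidClass.SM_OH, BondType.NONE,
                          int(m.group(1)), int(m.group(2)))
    m = _SM_RE.match(canonical)
    if m:
        return AnalyteDef(name, LipidClass.SM, BondType.NONE,
                          int(m.group(1)), int(m.group(2)))
    m = _CER_RE.match(canonical)
    if m:
        return AnalyteDef(name, LipidClass.CER, BondType.NONE,
                          int(m.group(1)), int(m.group(2)))
    m = _AC_RE.match(canonical)
    if m:
        carbons = int(m.group(1))
        dbonds = int(m.group(2)) if m.group(2) else 0
        return AnalyteDef(name, LipidClass.AC, BondType.NONE, carbons, dbonds,
                          moiety=m.group(3))
    raise AnalyteNameError(f"unparseable analyte name: {name!r}")


# --------------------------------------------------------------------------
# default panel
# --------------------------------------------------------------------------

_PC_AA = [
    "C24:0", "C26:0", "C28:1", "C30:0", "C30:2", "C32:0", "C32:1", "C32:2",
    "C32:3", "C34:1", "C34:2", "C34:3", "C34:4", "C36:0", "C36:1", "C36:2",
    "C36:3", "C36:4", "C36:5", "C36:6", "C38:0", "C38:1", "C38:3", "C38:4",
    "C38:5", "C38:6", "C40:1", "C40:2", "C40:3", "C40:4", "C40:5", "C40:6",
    "C42:0", "C42:1", "C42:2", "C42:4", "C42:5", "C42:6",
]
_PC_AE = [
    "C30:0", "C30:1", "C30:2", "C32:1", "C32:2", "C34:0", "C34:1", "C34:2",
    "C34:3", "C36:0", "C36:1", "C36:2", "C36:3", "C36:4", "C36:5", "C38:0",
    "C38:1", "C38:2", "C38:3", "C38:4", "C38:5", "C38:6", "C40:1", "C40:2",
    "C40:3", "C40:4", "C40:5", "C40:6", "C42:0", "C42:1", "C42:2", "C42:3",
    "C42:4", "C42:5", "C44:3", "C44:4", "C44:5", "C44:6",
]
_LYSOPC = [
    "C14:0", "C16:0", "C16:1", "C17:0", "C18:0", "C18:1", "C18:2", "C20:3",
    "C20:4", "C24:0", "C26:0", "C26:1", "C28:0", "C28:1",
]
_SM = [
    "C16:0", "C16:1", "C18:0", "C18:1", "C20:2", "C22:3", "C24:0", "C24:1",
    "C26:0", "C26:1",
]
_SM_OH = ["C14:1", "C16:1", "C22:1", "C22:2", "C24:1"]
_AC = [
    "C0", "C2", "C3", "C3:1", "C3-OH", "C3-DC", "C4", "C4:1", "C5", "C5:1",
    "C5-OH", "C5-DC", "C5:1-DC", "C5-M-DC", "C6", "C6:1", "C7-DC", "C8",
    "C9", "C10", "C10:1", "C10:2", "C12", "C12:1", "C12-DC", "C14", "C14:1",
    "C14:2", "C14:1-OH", "C14:2-OH", "C16", "C16:1", "C16:2", "C16-OH",
    "C16:1-OH", "C16:2-OH", "C18", "C18:1", "C18:2", "C18:1-OH",
]
_CERAMIDES = ["C16:0", "C18:0", "C24:0", "C24:1"]

DEFAULT_PANEL_NAMES: tuple[str, ...] = tuple(
    [f"PC aa {s}" for s in _PC_AA]
    + [f"PC ae {s}" for s in _PC_AE]
    + [f"lysoPC a {s}" for s in _LYSOPC]
    + [f"SM {s}" for s in _SM]
    + [f"SM (OH) {s}" for s in _SM_OH]
    + _AC
)
CERAMIDE_NAMES: tuple[str, ...] = tuple(f"Cer {s}" for s in _CERAMIDES)

#: order-of-magnitude plausible class geometric-mean plasma concentration (uM),
#: keyed by class (and bond type for PC); used for default LODs and as
#: generator baselines.
CLASS_BASELINE_UM: dict[str, float] = {
    "PC aa": 30.0,
    "PC ae": 4.0,
    "lysoPC": 12.0,
    "SM": 10.0,
    "SM(OH)": 1.5,
    "AC": 0.12,
    "CER": 0.6,
}

#: acylcarnitines that are reliably quantified in plasma; the remaining 30
#: (plus a handful of rare long-chain phospholipids) typically fall below the
#: kit LOD in most samples and are removed by the detection-fraction filter.
WELL_DETECTED_AC = frozenset(
    {"C0", "C2", "C3", "C4", "C5", "C5-DC", "C16", "C18", "C18:1", "C18:2"}
)
LOW_DETECTION_ANALYTES: frozenset[str] = frozenset(
    {a for a in _AC if a not in WELL_DETECTED_AC}
    | {"PC aa C26:0", "PC ae C44:6", "lysoPC a C26:1", "SM (OH) C14:1"}
)


def baseline_key(a: AnalyteDef) -> str:
    """Map an analyte to its baseline-concentration class key."""
    if a.lipid_class is LipidClass.PC:
        return f"PC {a.bond_type.value}"
    if a.lipid_class is LipidClass.SM_OH:
        return "SM(OH)"
    return a.lipid_class.value


@dataclass
class PanelRegistry:
    """Ordered collection of panel analytes with unique names."""

    analytes: list[AnalyteDef]

    def __post_init__(self) -> None:
        names = [a.name for a in self.analytes]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate analyte names in panel: {dupes}")
        self._by_name = {a.name: a for a in self.analytes}

    def __len__(self) -> int:
        return len(self.analytes)

    def __contains__(self, name: str) -> bool:
        return name in self._by_name

    @property
    def names(self) -> list[str]:
        return [a.name for a in self.analytes]

    def get(self, name: str) -> AnalyteDef:
        try:
            return self._by_name[name]
        except KeyError:
            raise KeyError(f"analyte not in panel: {name!r}") from None

    @property
    def lods(self) -> pd.Series:
        return pd.Series({a.name: (np.nan if a.lod is None else a.lod)
                          for a in self.analytes}, dtype=float)

    @property
    def class_counts(self) -> dict[str, int]:
        """Analyte counts per class; hydroxysphingomyelins count as SM."""
        counts: dict[str, int] = {}
        for a in self.analytes:
            key = ("SM" if a.lipid_class in (LipidClass.SM, LipidClass.SM_OH)
                   else a.lipid_class.value)
            counts[key] = counts.get(key, 0) + 1
        return counts

    def members(self, lipid_class: LipidClass | str,
                bond_type: BondType | str | None = None) -> list[str]:
        lc = LipidClass(lipid_class)
        out = [a for a in self.analytes if a.lipid_class is lc]
        if bond_type is not None:
            bt = BondType(bond_type)
            out = [a for a in out if a.bond_type is bt]
        return [a.name for a in out]

    def subset(self, names: list[str]) -> "PanelRegistry":
        missing = [n for n in names if n not in self._by_name]
        if missing:
            raise KeyError(f"analytes not in panel: {missing}")
        return PanelRegistry([self._by_name[n] for n in names])

    def with_lods(self, lods: pd.Series) -> "PanelRegistry":
        """Return a copy with LODs replaced where ``lods`` provides a value."""
        out = []
        for a in self.analytes:
            if a.name in lods.index and np.isfinite(lods[a.name]):
                out.append(replace(a, lod=float(lods[a.name])))
            else:
                out.append(a)
        return PanelRegistry(out)


def _default_lod(a: AnalyteDef) -> float:
    base = CLASS_BASELINE_UM[baseline_key(a)]
    factor = 1.3 if a.name in LOW_DETECTION_ANALYTES else 0.05
    return base * factor


def default_panel(include_ceramides: bool = False) -> PanelRegistry:
    """The default 145-analyte panel (76 PC, 14 lysoPC, 15 SM, 40 AC).

    With ``include_ceramides=True`` the panel is extended by the four
    ceramides (C16:0, C18:0, C24:0, C24:1) quantified with a dedicated
    LC-MS assay.  Default LODs are configuration values — set to a small
    fraction of the class-typical concentration for well-detected analytes
    and above it for the analytes known to quantify poorly in plasma.
    """
    names = DEFAULT_PANEL_NAMES + (CERAMIDE_NAMES if include_ceramides else ())
    analytes = []
    for n in names:
        a = parse_analyte_name(n)
        analytes.append(replace(a, lod=_default_lod(a)))
    return PanelRegistry(analytes)


def load_panel(path: str | Path) -> PanelRegistry:
    """Load a panel from YAML: a list of ``{name, lod}`` mappings.

    Lipid class and Cx:y are inferred from the name by the parser.
    """
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not isinstance(entries, list):
        raise DatasetFormatError(f"panel file {path}: expected a list")
    analytes = []
    for e in entries:
        a = parse_analyte_name(str(e["name"]))
        lod = e.get("lod")
        analytes.append(replace(a, lod=None if lod is None else float(lod)))
    return PanelRegistry(analytes)


def save_panel(panel: PanelRegistry, path: str | Path) -> Path:
    path = Path(path)
    entries = [{"name": a.name, "lod": a.lod} for a in panel.analytes]
    with open(path, "w") as fh:
        yaml.safe_dump(entries, fh, sort_keys=False)
    return path


# --------------------------------------------------------------------------
# dataset container
# --------------------------------------------------------------------------

@dataclass
class Dataset:
    """Concentration matrix plus missingness mask and sample metadata.

    ``values`` is samples x analytes (uM, raw as measured, may contain
    below-LOD values), ``mask`` the boolean missingness matrix (True =
    not measured or below LOD), ``meta`` the per-sample metadata indexed
    by ``sample_id``.
    """

    panel: PanelRegistry
    meta: pd.DataFrame
    values: pd.DataFrame
    mask: pd.DataFrame

    def __post_init__(self) -> None:
        self.validate()

    # -- structure ---------------------------------------------------------
    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_analytes(self) -> int:
        return self.values.shape[1]

    @property
    def analyte_names(self) -> list[str]:
        return list(self.values.columns)

    def validate(self) -> None:
        if list(self.values.columns) != self.panel.names:
            raise DatasetFormatError(
                "value columns do not match panel order: "
                f"{set(self.values.columns) ^ set(self.panel.names) or 'order mismatch'}"
            )
        if not self.values.index.equals(self.meta.index):
            raise DatasetFormatError("sample ids of values and metadata differ")
        if self.values.index.has_duplicates:
            dupes = self.values.index[self.values.index.duplicated()].tolist()
            raise DatasetFormatError(f"duplicate sample ids: {dupes}")
        if self.mask.shape != self.values.shape:
            raise DatasetFormatError("mask shape differs from values shape")
        missing_cols = [c for c in META_REQUIRED if c not in self.meta.columns]
        if missing_cols:
            raise DatasetFormatError(f"metadata lacks columns: {missing_cols}")
        bad_groups = set(self.meta["group"]) - set(GROUPS)
        if bad_groups:
            raise DatasetFormatError(f"unknown groups: {sorted(bad_groups)}")
        bad_tp = set(self.meta["timepoint"]) - set(TIMEPOINTS)
        if bad_tp:
            raise DatasetFormatError(f"unknown timepoints: {sorted(bad_tp)}")
        observed = self.values.to_numpy()[~self.mask.to_numpy(dtype=bool)]
        if observed.size and (np.isnan(observed).any() or (observed < 0).any()):
            raise DatasetFormatError("non-missing values must be finite and >= 0")

    # -- selection ---------------------------------------------------------
    def sample_index(self, group: str | None = None,
                     timepoint: str | None = None) -> pd.Index:
        """Sample ids matching a (group, timepoint) selection.

        ``timepoint`` is only applied to groups that carry a time course;
        single-draw groups (timepoint ``single``) match any requested
        timepoint.
        """
        keep = pd.Series(True, index=self.meta.index)
        if group is not None:
            keep &= self.meta["group"] == group
        if timepoint is not None:
            keep &= (self.meta["timepoint"] == timepoint) | (
                self.meta["timepoint"] == "single"
            )
        return self.meta.index[keep]

    def subset_samples(self, sample_ids: pd.Index | list[str]) -> "Dataset":
        return Dataset(self.panel, self.meta.loc[sample_ids].copy(),
                       self.values.loc[sample_ids].copy(),
                       self.mask.loc[sample_ids].copy())

    def subset_analytes(self, names: list[str]) -> "Dataset":
        return Dataset(self.panel.subset(names), self.meta.copy(),
                       self.values[names].copy(), self.mask[names].copy())

    def copy(self) -> "Dataset":
        return Dataset(self.panel, self.meta.copy(), self.values.copy(),
                       self.mask.copy())

    @property
    def detected_fraction(self) -> pd.Series:
        """Per analyte, fraction of samples with a measured value above LOD."""
        return 1.0 - self.mask.mean(axis=0)


def _compute_mask(values: pd.DataFrame, panel: PanelRegistry) -> pd.DataFrame:
    lods = panel.lods.reindex(values.columns)
    below = values.lt(lods, axis=1).fillna(False)
    return values.isna() | below


def make_dataset(panel: PanelRegistry, meta: pd.DataFrame,
                 values: pd.DataFrame) -> Dataset:
    """Assemble a dataset, deriving the missingness mask from the LOD rule."""
    values = values[panel.names]
    return Dataset(panel, meta, values, _compute_mask(values, panel))


def read_dataset(conc_path: str | Path, meta_path: str | Path,
                 panel: PanelRegistry) -> Dataset:
    """Read concentration and metadata CSVs into a validated dataset.

    Cells are flagged missing when empty, ``NA`` or below the analyte LOD.
    Column order in memory follows the panel, not the file.
    """
    conc = pd.read_csv(conc_path, index_col="sample_id")
    meta = pd.read_csv(meta_path, index_col="sample_id")
    unknown = [c for c in conc.columns if c not in panel]
    if unknown:
        raise DatasetFormatError(
            f"unknown analyte columns in {conc_path}: {unknown}")
    absent = [n for n in panel.names if n not in conc.columns]
    if absent:
        raise DatasetFormatError(
            f"panel analytes absent from {conc_path}: {absent}")
    if set(conc.index) != set(meta.index):
        diff = sorted(set(conc.index) ^ set(meta.index))
        raise DatasetFormatError(
            f"sample ids differ between concentration and metadata files: {diff}")
    meta = meta.loc[conc.index]
    if "corticosteroid" in meta.columns:
        meta["corticosteroid"] = meta["corticosteroid"].astype(bool)
    return make_dataset(panel, meta, conc.astype(float))


def write_dataset(ds: Dataset, out_dir: str | Path) -> dict[str, Path]:
    """Write ``concentrations.csv`` and ``samples.csv`` (plus ``panel.yaml``).

    Columns follow panel order; missing cells are written as ``NA``, except
    that measured below-LOD values are retained (the mask is reconstructed
    from the LOD rule on read, so a write/read round trip is exact).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    lods = ds.panel.lods.reindex(ds.values.columns)
    vals = ds.values.copy()
    # cells masked for a reason other than the LOD rule must be blanked
    reconstructible = vals.notna() & vals.lt(lods, axis=1).fillna(False)
    blank = ds.mask & ~reconstructible
    vals[blank] = np.nan
    conc_path = out_dir / "concentrations.csv"
    meta_path = out_dir / "samples.csv"
    vals.to_csv(conc_path, index_label="sample_id", na_rep="NA",
                float_format="%.12g")
    ds.meta.to_csv(meta_path, index_label="sample_id", na_rep="NA",
                   float_format="%.12g")
    panel_path = save_panel(ds.panel, out_dir / "panel.yaml")
    return {"concentrations": conc_path, "samples": meta_path,
            "panel": panel_path}
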