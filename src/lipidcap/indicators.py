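"""Metabolic indicators: class sums, class ratios, and lipid-pair ratios.

The 47 default indicators summarise biochemically related lipids — 11 class
sums, 11 ratios involving one or two classes, and 25 ratios of specific
lipid pairs.  Sums act as concentration pools (uM); ratios are
dimensionless proxies for enzyme or pathway activity, e.g.
``lysoPC a C16:0 / lysoPC a C16:1`` for phospholipase-mediated turnover of
the parent phosphatidylcholines, or dicarboxyl-acylcarnitines over total
acylcarnitines for omega-oxidation.

Definitions live in an editable YAML file so the set can be replaced
wholesale.  Members can be given as explicit analyte-name lists or as
selectors over the panel (class, bond type, acyl moiety, double-bond
constraints); selectors resolve against the analytes actually present, so
sums adapt gracefully after the detection-fraction filter.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .core import BondType, Dataset, LipidClass, PanelRegistry

__all__ = [
    "IndicatorDef",
    "IndicatorMatrix",
    "IndicatorError",
    "load_indicator_defs",
    "default_indicator_defs",
    "compute_indicators",
    "resolve_selector",
]

KINDS = ("class_sum", "class_ratio", "pair_ratio")


class IndicatorError(ValueError):
    """Raised for unresolvable or malformed indicator definitions."""


@dataclass(frozen=True)
class IndicatorDef:
    """One metabolic indicator.

    ``numerator``/``denominator`` are either lists of analyte names or
    selector mappings (keys: ``classes``, ``bond``, ``moiety``,
    ``double_bonds``, ``min_double_bonds``, ``max_double_bonds``).
    Class sums have no denominator; ratios must have one.
    """

    name: str
    kind: str
    numerator: tuple | dict
    denominator: tuple | dict | None = None

    def __post_init__(self) -> None:
        if self.kind not in KINDS:
            raise IndicatorError(f"{self.name}: unknown kind {self.kind!r}")
        if self.kind == "class_sum" and self.denominator is not None:
            raise IndicatorError(f"{self.name}: class_sum takes no denominator")
        if self.kind != "class_sum" and not self.denominator:
            raise IndicatorError(f"{self.name}: ratio needs a denominator")


@dataclass
class IndicatorMatrix:
    """Samples x indicators values with an undefined-cell flag matrix.

    A ratio is undefined for a sample when its denominator is zero; such
    cells hold NaN in ``values`` and True in ``undefined``, and the sample
    is meant to be excluded from that indicator's downstream tests.
    """

    values: pd.DataFrame
    undefined: pd.DataFrame

    @property
    def names(self) -> list[str]:
        return list(self.values.columns)


def resolve_selector(sel, panel: PanelRegistry) -> list[str]:
    """Resolve a member specification to panel analyte names.

    Explicit name lists must resolve completely; selector mappings resolve
    to whichever matching analytes the panel currently contains.
    """
    if isinstance(sel, (list, tuple)):
        missing = [n for n in sel if n not in panel]
        if missing:
            raise IndicatorError(f"unresolvable analyte reference: {missing}")
        return list(sel)
    if not isinstance(sel, dict):
        raise IndicatorError(f"bad member specification: {sel!r}")
    if "classes" in sel:
        classes = sel["classes"]
    elif "class" in sel:
        classes = [sel["class"]]
    else:
        raise IndicatorError(f"selector needs a class: {sel!r}")
    try:
        wanted = {LipidClass(c) for c in classes}
    except ValueError as exc:
        raise IndicatorError(str(exc)) from None
    out = []
    for a in panel.analytes:
        if a.lipid_class not in wanted:
            continue
        if "bond" in sel and a.bond_type is not BondType(sel["bond"]):
            continue
        if "moiety" in sel and a.moiety != sel["moiety"]:
            continue
        if "double_bonds" in sel and a.n_double_bonds != sel["double_bonds"]:
            continue
        if ("min_double_bonds" in sel
                and a.n_double_bonds < sel["min_double_bonds"]):
            continue
        if ("max_double_bonds" in sel
                and a.n_double_bonds > sel["max_double_bonds"]):
            continue
        out.append(a.name)
    return out


def _parse_defs(entries, panel: PanelRegistry | None) -> list[IndicatorDef]:
    defs = []
    seen = set()
    for e in entries:
        name = str(e["name"])
        if name in seen:
            raise IndicatorError(f"duplicate indicator name: {name!r}")
        seen.add(name)
        num = e["numerator"]
        den = e.get("denominator")
        d = IndicatorDef(
            name=name, kind=str(e["kind"]),
            numerator=tuple(num) if isinstance(num, list) else num,
            denominator=(tuple(den) if isinstance(den, list) else den),
        )
        if panel is not None:   # validate references against the panel
            resolve_selector(d.numerator, panel)
            if d.denominator is not None:
                resolve_selector(d.denominator, panel)
        defs.append(d)
    return defs


def load_indicator_defs(path: str | Path,
                        panel: PanelRegistry | None = None
                        ) -> list[IndicatorDef]:
    """Load indicator definitions from YAML, optionally validating all
    analyte references against ``panel``."""
    with open(path) as fh:
        entries = yaml.safe_load(fh)
    if not entries:
        warnings.warn(f"indicator file {path} defines no indicators",
                      stacklevel=2)
        return []
    return _parse_defs(entries, panel)


def default_indicator_defs(panel: PanelRegistry | None = None
                           ) -> list[IndicatorDef]:
    """The shipped default set: 11 class sums + 11 class ratios + 25 pair
    ratios = 47 indicators."""
    ref = resources.files("lipidcap").joinpath("data/indicators.yaml")
    entries = yaml.safe_load(ref.read_text())
    return _parse_defs(entries, panel)


def compute_indicators(ds: Dataset, defs: list[IndicatorDef]
                       ) -> IndicatorMatrix:
    """Evaluate indicator definitions per sample on an imputed dataset.

    An indicator whose members are all absent from the dataset (e.g. after
    the detection-fraction filter removed an entire acyl-moiety group) is
    skipped with a warning rather than reported as a column of undefined
    cells.
    """
    if ds.mask.to_numpy().any():
        raise ValueError(
            "dataset contains missing values; run imputation before "
            "computing indicators")
    avail = ds.panel
    values = {}
    undefined = {}
    for d in defs:
        try:
            num_members = resolve_selector(d.numerator, avail)
            den_members = (resolve_selector(d.denominator, avail)
                           if d.kind != "class_sum" else None)
        except IndicatorError as exc:
            warnings.warn(f"skipping indicator {d.name!r}: {exc}",
                          stacklevel=2)
            continue
        if not num_members or (d.kind != "class_sum" and not den_members):
            warnings.warn(
                f"skipping indicator {d.name!r}: no member analytes left "
                "in the dataset", stacklevel=2)
            continue
        num = ds.values[num_members].sum(axis=1)
        if d.kind == "class_sum":
            values[d.name] = num
            undefined[d.name] = pd.Series(False, index=ds.values.index)
            continue
        den = ds.values[den_members].sum(axis=1)
        undef = den == 0
        ratio = num / den.where(~undef, np.nan)
        values[d.name] = ratio
        undefined[d.name] = undef
    return IndicatorMatrix(values=pd.DataFrame(values),
                           undefined=pd.DataFrame(undefined))
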