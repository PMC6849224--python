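"""Shared fixtures: a default synthetic cohort and its processed stages."""

import numpy as np
import pandas as pd
import pytest

import lipidcap as lc


@pytest.fixture(scope="session")
def panel():
    return lc.default_panel()


@pytest.fixture(scope="session")
def cohort():
    """Default synthetic cohort (seed 7) with its truth sidecar."""
    return lc.generate_cohort(lc.default_config(seed=7))


@pytest.fixture(scope="session")
def filtered(cohort):
    ds, _ = cohort
    out, report = lc.lod_filter(ds)
    return out, report


@pytest.fixture(scope="session")
def imputed(filtered):
    return lc.impute_missing(filtered[0])


@pytest.fixture(scope="session")
def indicator_matrix(imputed):
    import warnings
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        return lc.compute_indicators(imputed, lc.default_indicator_defs())


def toy_dataset(values: np.ndarray, groups, timepoints=None, ages=None,
                analyte_names=("PC aa C34:4", "lysoPC a C16:0"),
                lods=None, sexes=None):
    """Small hand-built dataset for unit tests."""
    values = np.asarray(values, float)
    n, p = values.shape
    names = list(analyte_names)[:p]
    analytes = []
    for j, name in enumerate(names):
        a = lc.parse_analyte_name(name)
        from dataclasses import replace
        analytes.append(replace(a, lod=(lods[j] if lods else 1e-6)))
    panel = lc.PanelRegistry(analytes)
    ids = [f"S{i}" for i in range(n)]
    meta = pd.DataFrame({
        "subject_id": ids,
        "group": list(groups),
        "timepoint": list(timepoints) if timepoints is not None
        else ["d1" if g != "CTRL" else "single" for g in groups],
        "age": list(ages) if ages is not None else [50] * n,
        "sex": list(sexes) if sexes is not None else ["M"] * n,
    }, index=pd.Index(ids, name="sample_id"))
    vals = pd.DataFrame(values, index=meta.index, columns=names)
    return lc.make_dataset(panel, meta, vals)
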