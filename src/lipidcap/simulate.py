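"""Seeded synthetic cohort generator.

Emulates the statistical structure of a hospital-based lipidomics study of
community-acquired pneumonia (CAP, 29 subjects sampled at admission and 4
later time points, one subject lost to follow-up after day 4), infection-
associated COPD exacerbation (13 subjects, single admission draw) and
age/sex-matched controls (33 subjects, single draw).

Model
-----
Concentrations are log-normal.  For analyte *a* in sample *i* (subject *s*,
group *g*, timepoint *t*)::

    log c = log b_a + u_{s,a} + s_s * r_class(t) * (1 + j_a) * log m_{a,g}
            + eps_{i,a}

with per-analyte baseline ``b_a`` drawn around a class-typical level,
subject-by-analyte random intercepts ``u`` (repeated-measures correlation),
a latent per-subject inflammation scalar ``s_s`` (log-normal, median 1)
shared between the lipid effects and the clinical markers (CRP, PCT, acid
sphingomyelinase activity) — this is what produces the predominantly
negative lipid-vs-CRP correlations without hard-coding correlation
targets — a class-specific recovery schedule ``r_class`` (fraction of the
admission effect remaining at each timepoint), per-analyte effect jitter
``j_a`` and measurement noise ``eps``.

Per-analyte LODs are set at a configurable quantile of a log-normal fit
to the simulated control marginal (by default far below the control range,
as kit LODs are for abundant phospholipids); a fixed set of poorly detected
analytes (most acylcarnitines and a few rare phospholipids) gets a much
higher quantile so that the downstream detection-fraction filter removes
them, mirroring the typical behaviour of the assay in plasma.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy import stats

from .core import (
    CAP_TIMEPOINTS,
    CLASS_BASELINE_UM,
    LOW_DETECTION_ANALYTES,
    Dataset,
    PanelRegistry,
    baseline_key,
    default_panel,
)

__all__ = [
    "EffectProfile",
    "ClinicalMarkerParams",
    "GeneratorConfig",
    "TruthSidecar",
    "default_config",
    "generate_cohort",
    "generate_clinical_markers",
    "save_config",
    "load_config",
]


class ConfigError(ValueError):
    """Raised when a generator configuration is invalid."""


@dataclass(frozen=True)
class EffectProfile:
    """Class-level disease effect on concentrations.

    ``cap_d1_multiplier`` is the median fold change CAP-at-admission vs.
    controls encoded as generator truth; ``recovery_fractions`` map the five
    CAP timepoints (d1, d2, d4, f1, f2) to the fraction of the admission
    log-effect still present (d1 = 1.0, non-increasing).
    """

    cap_d1_multiplier: float
    copd_multiplier: float
    recovery_fractions: tuple[float, ...] = (1.0, 1.0, 1.0, 1.0, 1.0)

    def __post_init__(self) -> None:
        if self.cap_d1_multiplier <= 0 or self.copd_multiplier <= 0:
            raise ConfigError("effect multipliers must be > 0")
        r = self.recovery_fractions
        if len(r) != len(CAP_TIMEPOINTS):
            raise ConfigError("recovery_fractions must have 5 entries")
        if abs(r[0] - 1.0) > 1e-12:
            raise ConfigError("recovery_fractions must start at 1.0")
        if any(b > a + 1e-12 for a, b in zip(r, r[1:])):
            raise ConfigError("recovery_fractions must be non-increasing")
        if any(not 0 <= x <= 1 for x in r):
            raise ConfigError("recovery_fractions must lie in [0, 1]")


@dataclass(frozen=True)
class ClinicalMarkerParams:
    """Log-normal parameters of one clinical marker.

    ``medians`` holds the admission-day group medians; ``floor`` models the
    assay's lower reporting limit (draws are clipped there, which reproduces
    the piling-up of control values at the limit).
    """

    medians: dict[str, float]
    log_sd: float
    floor: float | None = None

    def __post_init__(self) -> None:
        for g in ("CAP", "COPD", "CTRL"):
            if g not in self.medians:
                raise ConfigError(f"clinical marker lacks a median for {g}")
            if self.medians[g] <= 0:
                raise ConfigError("clinical marker medians must be > 0")
        if self.log_sd < 0:
            raise ConfigError("log_sd must be >= 0")


# Effect directions and magnitudes mirror the qualitative structure of the
# study: phosphatidylcholines depressed most at admission, then lysoPC, then
# SM; acylcarnitines essentially flat except one short-chain species;
# selected SM and the dicarboxyl-acylcarnitine route up in COPD; ceramides
# C16:0/C18:0 (and mildly C24:1) up in CAP.  LysoPC recovers fastest.
DEFAULT_EFFECT_PROFILES: dict[str, EffectProfile] = {
    "PC": EffectProfile(0.45, 0.75, (1.0, 0.90, 0.75, 0.55, 0.35)),
    "lysoPC": EffectProfile(0.55, 0.80, (1.0, 0.80, 0.55, 0.30, 0.05)),
    "SM": EffectProfile(0.70, 1.00, (1.0, 0.85, 0.70, 0.50, 0.30)),
    "SM(OH)": EffectProfile(0.70, 1.00, (1.0, 0.85, 0.70, 0.50, 0.30)),
    "AC": EffectProfile(1.0, 1.0, (1.0, 1.0, 1.0, 1.0, 1.0)),
    "CER": EffectProfile(1.0, 1.0, (1.0, 0.85, 0.65, 0.40, 0.15)),
}

DEFAULT_ANALYTE_OVERRIDES: dict[str, dict[str, float]] = {
    "C5": {"cap": 1.6, "copd": 1.15},
    "PC ae C36:0": {"cap": 1.3},
    "SM C16:0": {"copd": 1.4},
    "SM C18:0": {"copd": 1.4},
    "SM C24:0": {"copd": 1.35},
    "C5-DC": {"copd": 1.3},
    "Cer C16:0": {"cap": 1.8},
    "Cer C18:0": {"cap": 1.7},
    "Cer C24:1": {"cap": 1.3},
}

# Admission-day medians follow the study population's laboratory table
# (CRP in mg/l, PCT in ng/l); acid sphingomyelinase activity is in arbitrary
# units with control median 100, CAP 2.8-fold and COPD 1.75-fold higher.
DEFAULT_CLINICAL: dict[str, ClinicalMarkerParams] = {
    "crp": ClinicalMarkerParams({"CAP": 102.0, "COPD": 14.0, "CTRL": 3.1},
                                log_sd=0.9, floor=3.1),
    "pct": ClinicalMarkerParams({"CAP": 0.23, "COPD": 0.09, "CTRL": 0.02},
                                log_sd=1.2, floor=0.02),
    "asm_activity": ClinicalMarkerParams(
        {"CAP": 280.0, "COPD": 175.0, "CTRL": 100.0}, log_sd=0.45),
}

#: fraction of the admission inflammation remaining, applied to the clinical
#: markers over the CAP time course (d1..f2).
DEFAULT_CLINICAL_RECOVERY = (1.0, 0.75, 0.55, 0.25, 0.05)


@dataclass
class GeneratorConfig:
    n_cap: int = 29
    n_copd: int = 13
    n_ctrl: int = 33
    timepoints: tuple[str, ...] = CAP_TIMEPOINTS
    baseline_log_mean: dict[str, float] = field(
        default_factory=lambda: {k: float(np.log(v))
                                 for k, v in CLASS_BASELINE_UM.items()})
    baseline_log_sd: float = 1.0
    effect_profiles: dict[str, EffectProfile] = field(
        default_factory=lambda: dict(DEFAULT_EFFECT_PROFILES))
    analyte_overrides: dict[str, dict[str, float]] = field(
        default_factory=lambda: {k: dict(v)
                                 for k, v in DEFAULT_ANALYTE_OVERRIDES.items()})
    effect_jitter_sd: float = 0.15
    subject_log_sd: float = 0.35
    noise_log_sd: float = 0.15
    inflammation_sd: float = 0.25
    lod_quantile: float = 1e-4
    low_detection_quantile: float = 0.85
    low_detection_analytes: frozenset[str] = LOW_DETECTION_ANALYTES
    clinical_marker_params: dict[str, ClinicalMarkerParams] = field(
        default_factory=lambda: dict(DEFAULT_CLINICAL))
    clinical_recovery: tuple[float, ...] = DEFAULT_CLINICAL_RECOVERY
    dropout_subjects: int = 1          # CAP subjects lost to follow-up after d4
    dropout_timepoints: tuple[str, ...] = ("f1", "f2")
    p_female: float = 0.40
    p_corticosteroid: dict[str, float] = field(
        default_factory=lambda: {"CAP": 0.22, "COPD": 0.62, "CTRL": 0.033})
    age_mean: float = 60.0
    age_sd: float = 14.0
    age_range: tuple[float, float] = (24.0, 90.0)
    include_ceramides: bool = False
    seed: int = 0

    def validate(self) -> None:
        if min(self.n_cap, self.n_copd, self.n_ctrl) <= 0:
            raise ConfigError("group sizes must be > 0")
        for q in (self.lod_quantile, self.low_detection_quantile):
            if not 0 <= q < 1:
                raise ConfigError("LOD quantiles must lie in [0, 1)")
        for name, v in [("baseline_log_sd", self.baseline_log_sd),
                        ("effect_jitter_sd", self.effect_jitter_sd),
                        ("subject_log_sd", self.subject_log_sd),
                        ("noise_log_sd", self.noise_log_sd),
                        ("inflammation_sd", self.inflammation_sd)]:
            if v < 0:
                raise ConfigError(f"{name} must be >= 0")
        if not 0 <= self.p_female <= 1:
            raise ConfigError("p_female must lie in [0, 1]")
        if self.dropout_subjects < 0 or self.dropout_subjects > self.n_cap:
            raise ConfigError("dropout_subjects out of range")
        for cls in set(self.effect_profiles) - set(DEFAULT_EFFECT_PROFILES):
            raise ConfigError(f"unknown lipid class in effect_profiles: {cls}")


def default_config(**overrides) -> GeneratorConfig:
    cfg = GeneratorConfig(**overrides)
    cfg.validate()
    return cfg


@dataclass
class TruthSidecar:
    """Ground truth used by the generator, for parameter-recovery tests.

    ``effects``: expected multiplicative concentration effect (at unit
    inflammation) per (group, timepoint) x analyte.  ``clinical``: expected
    per-sample clinical-marker medians.  ``baselines``: per-analyte baseline
    concentration (uM).  ``inflammation``: latent per-subject scalar.
    """

    effects: pd.DataFrame
    clinical: pd.DataFrame
    baselines: pd.Series
    inflammation: pd.Series

    def write(self, out_dir: str | Path) -> Path:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        path = out_dir / "truth.csv"
        self.effects.to_csv(path, float_format="%.12g")
        self.clinical.to_csv(out_dir / "truth_clinical.csv",
                             float_format="%.12g")
        return path


def _effect_log_multipliers(cfg: GeneratorConfig, panel: PanelRegistry
                            ) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Per-analyte log fold (CAP d1, COPD) and recovery rows (5 x analytes)."""
    log_cap = np.empty(len(panel))
    log_copd = np.empty(len(panel))
    recovery = np.empty((len(CAP_TIMEPOINTS), len(panel)))
    for j, a in enumerate(panel.analytes):
        cls = ("SM(OH)" if a.lipid_class.value == "SM(OH)"
               else a.lipid_class.value)
        prof = cfg.effect_profiles[cls]
        cap_m, copd_m = prof.cap_d1_multiplier, prof.copd_multiplier
        override = cfg.analyte_overrides.get(a.name)
        if override:
            cap_m = override.get("cap", cap_m)
            copd_m = override.get("copd", copd_m)
        log_cap[j] = np.log(cap_m)
        log_copd[j] = np.log(copd_m)
        recovery[:, j] = prof.recovery_fractions
    return log_cap, log_copd, recovery


def generate_clinical_markers(cfg: GeneratorConfig, group: str, n: int,
                              rng: np.random.Generator,
                              timepoint: str = "d1",
                              inflammation: np.ndarray | None = None
                              ) -> pd.DataFrame:
    """Draw CRP, PCT and ASM activity for ``n`` samples of one group.

    The group median at admission equals the configured median; over the CAP
    time course the log-effect decays by the clinical recovery schedule, so
    medians approach the control median by the last follow-up.  The optional
    ``inflammation`` scalars couple the markers to the latent severity that
    also drives the lipid effects.
    """
    if group not in ("CAP", "COPD", "CTRL"):
        raise ConfigError(f"unknown group: {group}")
    s = np.ones(n) if inflammation is None else np.asarray(inflammation, float)
    if s.shape != (n,):
        raise ConfigError("inflammation must have length n")
    if group == "CAP":
        r = cfg.clinical_recovery[CAP_TIMEPOINTS.index(timepoint)]
    elif group == "COPD":
        r = 1.0
    else:
        r = 0.0
    out = {}
    for name, par in cfg.clinical_marker_params.items():
        base = np.log(par.medians["CTRL"])
        effect = np.log(par.medians[group] / par.medians["CTRL"]) if r else 0.0
        draws = np.exp(base + s * r * effect
                       + rng.normal(0.0, par.log_sd, size=n))
        if par.floor is not None:
            draws = np.maximum(draws, par.floor)
        out[name] = draws
    return pd.DataFrame(out)


def _subject_table(cfg: GeneratorConfig, rng: np.random.Generator
                   ) -> pd.DataFrame:
    rows = []
    for group, n in (("CAP", cfg.n_cap), ("COPD", cfg.n_copd),
                     ("CTRL", cfg.n_ctrl)):
        for i in range(n):
            rows.append({"subject_id": f"{group}{i + 1:02d}", "group": group})
    subj = pd.DataFrame(rows).set_index("subject_id")
    n = len(subj)
    ages = np.clip(rng.normal(cfg.age_mean, cfg.age_sd, size=n),
                   *cfg.age_range)
    subj["age"] = np.round(ages).astype(int)
    subj["sex"] = np.where(rng.random(n) < cfg.p_female, "F", "M")
    p_cort = subj["group"].map(cfg.p_corticosteroid).to_numpy(float)
    subj["corticosteroid"] = rng.random(n) < p_cort
    subj["inflammation"] = np.where(
        subj["group"] == "CTRL", 1.0,
        np.exp(rng.normal(0.0, cfg.inflammation_sd, size=n)))
    return subj


def generate_cohort(cfg: GeneratorConfig | None = None,
                    panel: PanelRegistry | None = None
                    ) -> tuple[Dataset, TruthSidecar]:
    """Generate a seeded synthetic cohort with its ground-truth sidecar.

    The same configuration and seed give bit-identical output.
    """
    cfg = cfg or default_config()
    cfg.validate()
    panel = panel or default_panel(include_ceramides=cfg.include_ceramides)
    rng = np.random.default_rng(cfg.seed)
    n_analytes = len(panel)

    # 1. per-analyte baselines and effect jitter (fixed draw order)
    class_log_mean = np.array(
        [cfg.baseline_log_mean[baseline_key(a)] for a in panel.analytes])
    log_base = class_log_mean + rng.normal(0.0, cfg.baseline_log_sd,
                                           size=n_analytes)
    jitter = rng.normal(0.0, cfg.effect_jitter_sd, size=n_analytes)
    log_cap, log_copd, recovery = _effect_log_multipliers(cfg, panel)

    # 2. subjects
    subjects = _subject_table(cfg, rng)
    subj_intercepts = {
        sid: rng.normal(0.0, cfg.subject_log_sd, size=n_analytes)
        for sid in subjects.index
    }

    # 3. sample skeleton; the last CAP subjects are the ones lost to follow-up
    dropped = set(subjects.index[subjects["group"] == "CAP"]
                  [cfg.n_cap - cfg.dropout_subjects:])
    samples: list[dict] = []
    for sid, row in subjects.iterrows():
        if row["group"] == "CAP":
            for tp in cfg.timepoints:
                if sid in dropped and tp in cfg.dropout_timepoints:
                    continue
                samples.append({"sample_id": f"{sid}_{tp}",
                                "subject_id": sid, "timepoint": tp})
        elif row["group"] == "COPD":
            samples.append({"sample_id": f"{sid}_d1", "subject_id": sid,
                            "timepoint": "d1"})
        else:
            samples.append({"sample_id": sid, "subject_id": sid,
                            "timepoint": "single"})
    meta = pd.DataFrame(samples).set_index("sample_id")
    meta = meta.join(subjects.drop(columns=["inflammation"]), on="subject_id")
    meta = meta[["subject_id", "group", "timepoint", "age", "sex",
                 "corticosteroid"]]

    # 4. concentrations
    n_samples = len(meta)
    values = np.empty((n_samples, n_analytes))
    truth_clin_rows = []
    clin_cols = list(cfg.clinical_marker_params)
    clinical = pd.DataFrame(index=meta.index, columns=clin_cols, dtype=float)
    for i, (sample_id, row) in enumerate(meta.iterrows()):
        group, tp = row["group"], row["timepoint"]
        s = subjects.loc[row["subject_id"], "inflammation"]
        if group == "CAP":
            t_ix = CAP_TIMEPOINTS.index(tp)
            effect = s * recovery[t_ix] * (1.0 + jitter) * log_cap
        elif group == "COPD":
            effect = s * (1.0 + jitter) * log_copd
        else:
            effect = np.zeros(n_analytes)
        noise = rng.normal(0.0, cfg.noise_log_sd, size=n_analytes)
        values[i] = np.exp(log_base + subj_intercepts[row["subject_id"]]
                           + effect + noise)
        clin = generate_clinical_markers(
            cfg, group, 1, rng, timepoint=tp if group == "CAP" else "d1",
            inflammation=np.array([s]))
        clinical.loc[sample_id] = clin.iloc[0]
        truth_clin_rows.append(_expected_clinical(cfg, group, tp, s))
    values_df = pd.DataFrame(values, index=meta.index, columns=panel.names)
    meta = meta.join(clinical)
    meta = meta[["subject_id", "group", "timepoint", "age", "sex",
                 "crp", "pct", "asm_activity", "corticosteroid"]]

    # 5. LODs from the control marginal; the mask follows the LOD rule
    ctrl_ids = meta.index[meta["group"] == "CTRL"]
    q = np.array([cfg.low_detection_quantile
                  if a.name in cfg.low_detection_analytes else cfg.lod_quantile
                  for a in panel.analytes])
    log_ctrl = np.log(values_df.loc[ctrl_ids].to_numpy())
    mu, sd = log_ctrl.mean(axis=0), log_ctrl.std(axis=0, ddof=0)
    with np.errstate(divide="ignore"):
        lods = np.where(q > 0, np.exp(mu + sd * stats.norm.ppf(q)), 1e-300)
    panel_with_lods = panel.with_lods(pd.Series(lods, index=panel.names))
    mask = values_df.lt(pd.Series(lods, index=panel.names), axis=1)
    ds = Dataset(panel_with_lods, meta, values_df, mask)

    # 6. truth sidecar
    effect_rows = {}
    for tp_ix, tp in enumerate(CAP_TIMEPOINTS):
        effect_rows[("CAP", tp)] = np.exp(
            recovery[tp_ix] * (1.0 + jitter) * log_cap)
    effect_rows[("COPD", "d1")] = np.exp((1.0 + jitter) * log_copd)
    effect_rows[("CTRL", "single")] = np.ones(n_analytes)
    effects = pd.DataFrame(effect_rows, index=panel.names).T
    effects.index = pd.MultiIndex.from_tuples(effects.index,
                                              names=["group", "timepoint"])
    truth = TruthSidecar(
        effects=effects,
        clinical=pd.DataFrame(truth_clin_rows, index=meta.index),
        baselines=pd.Series(np.exp(log_base), index=panel.names),
        inflammation=subjects["inflammation"].copy(),
    )
    return ds, truth


def _expected_clinical(cfg: GeneratorConfig, group: str, tp: str,
                       s: float) -> dict[str, float]:
    if group == "CAP":
        r = cfg.clinical_recovery[CAP_TIMEPOINTS.index(tp)]
    elif group == "COPD":
        r = 1.0
    else:
        r = 0.0
    out = {}
    for name, par in cfg.clinical_marker_params.items():
        med = par.medians["CTRL"] * (par.medians[group]
                                     / par.medians["CTRL"]) ** (s * r)
        if par.floor is not None:
            med = max(med, par.floor)
        out[name] = med
    return out


# --------------------------------------------------------------------------
# configuration serialization
# --------------------------------------------------------------------------

def save_config(cfg: GeneratorConfig, path: str | Path) -> Path:
    path = Path(path)
    d = dataclasses.asdict(cfg)
    d["effect_profiles"] = {
        k: {"cap_d1_multiplier": p.cap_d1_multiplier,
            "copd_multiplier": p.copd_multiplier,
            "recovery_fractions": list(p.recovery_fractions)}
        for k, p in cfg.effect_profiles.items()}
    d["clinical_marker_params"] = {
        k: {"medians": dict(p.medians), "log_sd": p.log_sd, "floor": p.floor}
        for k, p in cfg.clinical_marker_params.items()}
    d["low_detection_analytes"] = sorted(cfg.low_detection_analytes)
    d["timepoints"] = list(cfg.timepoints)
    d["clinical_recovery"] = list(cfg.clinical_recovery)
    d["dropout_timepoints"] = list(cfg.dropout_timepoints)
    d["age_range"] = list(cfg.age_range)
    with open(path, "w") as fh:
        yaml.safe_dump(d, fh, sort_keys=False)
    return path


def load_config(path: str | Path) -> GeneratorConfig:
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["effect_profiles"] = {
        k: EffectProfile(p["cap_d1_multiplier"], p["copd_multiplier"],
                         tuple(p["recovery_fractions"]))
        for k, p in d.get("effect_profiles", {}).items()}
    d["clinical_marker_params"] = {
        k: ClinicalMarkerParams(p["medians"], p["log_sd"], p.get("floor"))
        for k, p in d.get("clinical_marker_params", {}).items()}
    d["low_detection_analytes"] = frozenset(d.get("low_detection_analytes", ()))
    for key in ("timepoints", "clinical_recovery", "dropout_timepoints",
                "age_range"):
        if key in d:
            d[key] = tuple(d[key])
    cfg = GeneratorConfig(**d)
    cfg.validate()
    return cfg
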