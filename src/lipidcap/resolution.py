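"""Resolution-marker statistics: linear fitting slope (LFS) and normalized
distance to fitting (NDF).

For each feature, the five ratios of CAP timepoint medians to the control
median (d1, d2, d4, f1, f2) are fitted by ordinary least squares against
ordinal time.  The slope (LFS) measures how fast the feature normalizes;
the NDF — the sum of absolute vertical residuals divided by the range of
the ratios, normalized by the number of observations (5) — measures how
linear the trajectory is (0 = perfectly linear).  Features are then ranked
by ``|LFS| * (1 - min(NDF, 1))``, i.e. steep *and* linear normalization;
the scatter coordinates (LFS, 1 - NDF) are exported so users can apply
their own cut.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .core import CAP_TIMEPOINTS
from .differential import select_samples

__all__ = [
    "MedianRatioSeries",
    "LfsResult",
    "median_ratio_series",
    "lfs_ndf",
    "rank_resolution_markers",
]

#: ordinal positions of the five CAP timepoints; follow-up visits happen at
#: variable per-patient times, so calendar days are not used.
DEFAULT_X = (1.0, 2.0, 3.0, 4.0, 5.0)


@dataclass(frozen=True)
class MedianRatioSeries:
    """Per-timepoint ratios of CAP medians to the control median."""

    feature: str
    ratios: tuple[float, ...]
    x: tuple[float, ...] = DEFAULT_X

    def __post_init__(self) -> None:
        if len(self.ratios) != len(self.x):
            raise ValueError("ratios and x must have equal length")
        if any(b <= a for a, b in zip(self.x, self.x[1:])):
            raise ValueError("x must be strictly increasing")


@dataclass(frozen=True)
class LfsResult:
    feature: str
    lfs: float              # OLS slope, ratio units per timepoint step
    intercept: float
    ndf: float              # 0 = perfectly linear trajectory
    ratios: tuple[float, ...]

    @property
    def rank_score(self) -> float:
        return abs(self.lfs) * (1.0 - min(self.ndf, 1.0))

    @property
    def normalizing(self) -> bool:
        """True when the slope points from the admission ratio toward 1."""
        d1 = self.ratios[0]
        if d1 == 1.0:
            return True
        return (d1 < 1.0) == (self.lfs > 0)


def median_ratio_series(features: pd.DataFrame, meta: pd.DataFrame,
                        feature: str, group: str = "CAP",
                        control: str = "CTRL") -> MedianRatioSeries:
    """Ratio of the CAP median at each timepoint to the control median."""
    ctrl_ids = select_samples(meta, control)
    if len(ctrl_ids) == 0:
        raise ValueError("control group is empty")
    ctrl_median = float(features.loc[ctrl_ids, feature].dropna().median())
    if ctrl_median == 0:
        raise ZeroDivisionError(
            f"{feature}: control median is zero; ratio undefined")
    ratios = []
    missing_tp = []
    for tp in CAP_TIMEPOINTS:
        vals = features.loc[select_samples(meta, group, tp), feature].dropna()
        if len(vals) < 3:
            missing_tp.append(tp)
            continue
        ratios.append(float(vals.median()) / ctrl_median)
    if missing_tp:
        raise ValueError(
            f"{feature}: timepoints with < 3 samples: {missing_tp}")
    return MedianRatioSeries(feature, tuple(ratios))


def lfs_ndf(series: MedianRatioSeries) -> LfsResult:
    """OLS fit of the ratio series against ordinal time.

    LFS is the slope; NDF is the sum of absolute vertical residuals divided
    by (max ratio - min ratio), normalized by the number of observations.
    A constant series (zero range) fits its own line perfectly: LFS = 0,
    NDF = 0.
    """
    y = np.asarray(series.ratios, float)
    x = np.asarray(series.x, float)
    rng = y.max() - y.min()
    if rng == 0:
        return LfsResult(series.feature, 0.0, float(y[0]), 0.0, series.ratios)
    slope, intercept = np.polyfit(x, y, 1)
    resid = np.abs(y - (slope * x + intercept))
    ndf = (resid.sum() / rng) / y.size
    return LfsResult(series.feature, float(slope), float(intercept),
                     float(ndf), series.ratios)


def rank_resolution_markers(results: list[LfsResult]) -> pd.DataFrame:
    """Rank features by steep, linear normalization.

    ``rank_score = |LFS| * (1 - min(NDF, 1))``.  Features whose admission
    ratio is on the wrong side of 1 relative to the slope direction (i.e.
    the trajectory moves *away* from control levels) are flagged and sorted
    below normalizing ones.
    """
    if not results:
        raise ValueError("no results to rank")
    rows = []
    for r in results:
        row = {"feature": r.feature, "lfs": r.lfs, "intercept": r.intercept,
               "ndf": r.ndf, "one_minus_ndf": 1.0 - min(r.ndf, 1.0),
               "rank_score": r.rank_score, "normalizing": r.normalizing}
        for tp, ratio in zip(CAP_TIMEPOINTS, r.ratios):
            row[f"ratio_{tp}"] = ratio
        rows.append(row)
    table = pd.DataFrame(rows).set_index("feature")
    return table.sort_values(["normalizing", "rank_score"],
                             ascending=[False, False])
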