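"""Hemispheric selectivity scalars from statistic maps.

Selectivity S_{C,H} summarizes one category contrast's map within one
hemisphere, inside the intersection of an anatomical mask and a
stimulus-responsive mask.  Three metrics: summed positive statistics, peak
statistic (floored at 0 so the laterality index stays in [-1, 1]), and the
count of voxels exceeding a one-sided significance threshold.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .glm import StatMap

__all__ = [
    "ROIMask",
    "SelectivityResult",
    "responsive_mask",
    "summed_selectivity",
    "peak_selectivity",
    "count_selectivity",
    "selectivity",
    "METRICS",
]

METRICS = ("summed", "peak", "count")


@dataclass
class ROIMask:
    """Anatomical + responsive voxel masks with hemisphere labels."""

    anatomical: np.ndarray  # bool per voxel
    hemispheres: np.ndarray  # "L"/"R" per voxel
    responsive: np.ndarray | None = None  # bool per voxel; None = all responsive

    def __post_init__(self) -> None:
        self.anatomical = np.asarray(self.anatomical, dtype=bool)
        self.hemispheres = np.asarray(self.hemispheres)
        if self.responsive is not None:
            self.responsive = np.asarray(self.responsive, dtype=bool)
            if self.responsive.shape != self.anatomical.shape:
                raise ValueError("responsive mask shape mismatch")
        if self.hemispheres.shape != self.anatomical.shape:
            raise ValueError("hemisphere labels shape mismatch")
        for h in ("L", "R"):
            if not (self.anatomical & (self.hemispheres == h)).any():
                raise ValueError(f"anatomical mask empty in hemisphere {h}")

    def voxels(self, hemisphere: str) -> np.ndarray:
        m = self.anatomical & (self.hemispheres == hemisphere)
        if self.responsive is not None:
            m = m & self.responsive
        return m


@dataclass
class SelectivityResult:
    s_left: float
    s_right: float
    metric: str
    n_left: int
    n_right: int
    category: str = ""
    baseline: str = ""
    run_split: str = ""


def responsive_mask(omnibus: StatMap, alpha: float = 0.001) -> np.ndarray:
    """Voxels responding more during stimulation than rest.

    For t maps: one-sided p < alpha under Student-t with the map's df.
    For effect maps (degenerate-noise simulations): effect > 0.
    """
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    if omnibus.kind == "effect":
        return omnibus.data > 0
    if omnibus.df is None or omnibus.df <= 0:
        raise ValueError("responsive mask requires a t map with positive df")
    threshold = sps.t.ppf(1.0 - alpha, omnibus.df)
    return omnibus.data > threshold


def _masked(values: np.ndarray, tmap_hemis: np.ndarray | None,
            roi: ROIMask, hemisphere: str) -> np.ndarray:
    mask = roi.voxels(hemisphere)
    if values.shape != mask.shape:
        raise ValueError("stat map and mask cover different voxel sets")
    return values[mask]


def summed_selectivity(tmap: StatMap, roi: ROIMask, hemisphere: str) -> float:
    """Sum of positive statistics over the hemisphere's masked voxels."""
    v = _masked(tmap.data, tmap.hemispheres, roi, hemisphere)
    return float(np.clip(v, 0.0, None).sum())


def peak_selectivity(tmap: StatMap, roi: ROIMask, hemisphere: str) -> float:
    """Maximum statistic over the masked voxels, floored at 0."""
    v = _masked(tmap.data, tmap.hemispheres, roi, hemisphere)
    return float(max(v.max(), 0.0)) if v.size else 0.0


def count_selectivity(
    tmap: StatMap, roi: ROIMask, hemisphere: str, alpha: float = 0.001
) -> float:
    """Number of masked voxels with one-sided p < alpha (t maps) or
    statistic > 0 (effect maps)."""
    v = _masked(tmap.data, tmap.hemispheres, roi, hemisphere)
    if tmap.kind == "effect":
        return float((v > 0).sum())
    threshold = sps.t.ppf(1.0 - alpha, tmap.df)
    return float((v > threshold).sum())


def selectivity(
    tmap: StatMap,
    roi: ROIMask,
    hemisphere: str,
    metric: str = "summed",
    alpha: float = 0.001,
) -> float:
    if metric == "summed":
        return summed_selectivity(tmap, roi, hemisphere)
    if metric == "peak":
        return peak_selectivity(tmap, roi, hemisphere)
    if metric == "count":
        return count_selectivity(tmap, roi, hemisphere, alpha=alpha)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def selectivity_pair(
    tmap: StatMap, roi: ROIMask, metric: str = "summed", alpha: float = 0.001, **meta
) -> SelectivityResult:
    return SelectivityResult(
        s_left=selectivity(tmap, roi, "L", metric, alpha),
        s_right=selectivity(tmap, roi, "R", metric, alpha),
        metric=metric,
        n_left=int(roi.voxels("L").sum()),
        n_right=int(roi.voxels("R").sum()),
        **meta,
    )
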