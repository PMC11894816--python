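"""Homotopic parcel atlases, parcel-level LI, and coupling analyses.

A homotopic atlas pairs every left-hemisphere parcel with a mirror partner
on the right, so a laterality index can be computed per parcel pair.
Coupling is the cross-subject correlation between a parcel's LI and a
target region's LI (computed on disjoint run splits), with
Benjamini-Hochberg FDR across parcels.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from statsmodels.stats.multitest import multipletests

from .glm import StatMap
from .laterality import laterality_index

__all__ = [
    "ParcelAtlas",
    "synthetic_homotopic_atlas",
    "parcel_selectivity",
    "parcel_li_table",
    "CouplingResult",
    "parcel_coupling",
    "mean_li_vs_coupling",
]


@dataclass
class ParcelAtlas:
    """voxel -> parcel assignment with an L/R homotopic bijection.

    parcel_ids: integer parcel id per voxel (-1 = unassigned);
    hemispheres: "L"/"R" per voxel.  A parcel id must appear in exactly one
    hemisphere; ``homotopic`` maps each left parcel id to its right partner.
    """

    parcel_ids: np.ndarray
    hemispheres: np.ndarray
    homotopic: dict[int, int]

    def __post_init__(self) -> None:
        self.parcel_ids = np.asarray(self.parcel_ids, dtype=int)
        self.hemispheres = np.asarray(self.hemispheres)
        if self.parcel_ids.shape != self.hemispheres.shape:
            raise ValueError("parcel ids and hemisphere labels shape mismatch")
        left = set(np.unique(self.parcel_ids[(self.hemispheres == "L") & (self.parcel_ids >= 0)]))
        right = set(np.unique(self.parcel_ids[(self.hemispheres == "R") & (self.parcel_ids >= 0)]))
        if left & right:
            raise ValueError(f"parcels present in both hemispheres: {sorted(left & right)}")
        if set(self.homotopic) != left or set(self.homotopic.values()) != right:
            raise ValueError("homotopic map is not a bijection between L and R parcels")
        if len(set(self.homotopic.values())) != len(self.homotopic):
            raise ValueError("homotopic map is not injective")

    @property
    def n_pairs(self) -> int:
        return len(self.homotopic)

    @property
    def n_unassigned(self) -> int:
        return int((self.parcel_ids < 0).sum())

    def pair_labels(self) -> list[int]:
        return sorted(self.homotopic)


def synthetic_homotopic_atlas(n_voxels_per_hemisphere: int, n_parcels: int) -> ParcelAtlas:
    """Symmetric atlas fixture: contiguous equal-size parcels, voxel i on the
    left homotopic to voxel i on the right.  Left parcels are 0..P-1, right
    parcels P..2P-1, paired in order."""
    if n_parcels < 1 or n_parcels > n_voxels_per_hemisphere:
        raise ValueError("need 1 <= n_parcels <= n_voxels_per_hemisphere")
    per_hemi = np.minimum(
        np.arange(n_voxels_per_hemisphere) * n_parcels // n_voxels_per_hemisphere,
        n_parcels - 1,
    )
    parcel_ids = np.concatenate([per_hemi, per_hemi + n_parcels])
    hemis = np.array(["L"] * n_voxels_per_hemisphere + ["R"] * n_voxels_per_hemisphere)
    homotopic = {int(p): int(p + n_parcels) for p in range(n_parcels)}
    return ParcelAtlas(parcel_ids=parcel_ids, hemispheres=hemis, homotopic=homotopic)


def parcel_selectivity(tmap: StatMap, atlas: ParcelAtlas, metric: str = "summed",
                       alpha: float = 0.001) -> dict[int, float]:
    """Selectivity per parcel (summed positive statistic / peak / count)."""
    if tmap.data.shape != atlas.parcel_ids.shape:
        raise ValueError("stat map and atlas cover different voxel sets")
    out: dict[int, float] = {}
    if metric == "count" and tmap.kind == "t":
        thr = sps.t.ppf(1.0 - alpha, tmap.df)
    else:
        thr = 0.0
    for p in np.unique(atlas.parcel_ids):
        if p < 0:
            continue
        v = tmap.data[atlas.parcel_ids == p]
        if metric == "summed":
            out[int(p)] = float(np.clip(v, 0.0, None).sum())
        elif metric == "peak":
            out[int(p)] = float(max(v.max(), 0.0)) if v.size else 0.0
        elif metric == "count":
            out[int(p)] = float((v > thr).sum())
        else:
            raise ValueError(f"unknown metric {metric!r}")
    return out


def parcel_li_table(
    tmaps: dict[str, StatMap], atlas: ParcelAtlas, metric: str = "summed"
) -> pd.DataFrame:
    """Per-subject, per-homotopic-pair LI from a dict subject_id -> StatMap.

    Returns a tidy frame (subject_id, parcel, s_left, s_right, li); rows
    with zero bilateral selectivity carry NaN LI.  Unassigned voxels are
    reported via the frame's ``attrs["n_unassigned"]``.
    """
    rows = []
    for sid, tmap in tmaps.items():
        sel = parcel_selectivity(tmap, atlas, metric=metric)
        for left_p in atlas.pair_labels():
            s_l = sel[left_p]
            s_r = sel[atlas.homotopic[left_p]]
            rows.append(
                {"subject_id": sid, "parcel": left_p, "s_left": s_l, "s_right": s_r,
                 "li": laterality_index(s_l, s_r)}
            )
    out = pd.DataFrame(rows)
    out.attrs["n_unassigned"] = atlas.n_unassigned
    return out


@dataclass
class CouplingResult:
    """Per-parcel coupling with a target region's LI."""

    table: pd.DataFrame  # parcel, r, p, q, n, significant
    target_label: str
    method: str
    fdr_alpha: float

    @property
    def n_significant(self) -> int:
        return int(self.table["significant"].sum())


def _rank_corr_columns(target: np.ndarray, parcels: np.ndarray, method: str):
    """Correlate a target vector with each column of a matrix (NaN-aware),
    returning r and two-sided p per column via the t approximation."""
    n_parcels = parcels.shape[1]
    r = np.full(n_parcels, np.nan)
    p = np.full(n_parcels, np.nan)
    n = np.zeros(n_parcels, dtype=int)
    for j in range(n_parcels):
        y = parcels[:, j]
        ok = np.isfinite(target) & np.isfinite(y)
        n[j] = int(ok.sum())
        if n[j] < 3:
            continue
        x, yy = target[ok], y[ok]
        if np.std(x) == 0 or np.std(yy) == 0:
            continue
        if method == "spearman":
            rr, pp = sps.spearmanr(x, yy)
        else:
            rr, pp = sps.pearsonr(x, yy)
        r[j], p[j] = rr, pp
    return r, p, n


def parcel_coupling(
    parcel_table: pd.DataFrame,
    target_li: pd.Series,
    method: str = "spearman",
    fdr_alpha: float = 0.05,
    target_label: str = "target",
    exclude_parcels=(),
) -> CouplingResult:
    """Cross-subject correlation of each parcel's LI with the target LI.

    parcel_table comes from :func:`parcel_li_table` computed on one run
    split; target_li is indexed by subject_id and must come from the
    complementary split (the caller owns that convention).  BH FDR is
    applied across parcels.
    """
    wide = parcel_table.pivot(index="subject_id", columns="parcel", values="li")
    wide = wide.drop(columns=[p for p in exclude_parcels if p in wide.columns])
    subjects = wide.index.intersection(target_li.index)
    if len(subjects) < 3:
        raise ValueError("need at least 3 subjects with both parcel and target LIs")
    target = target_li.loc[subjects].to_numpy(dtype=float)
    mat = wide.loc[subjects].to_numpy(dtype=float)
    r, p, n = _rank_corr_columns(target, mat, method)

    q = np.full_like(p, np.nan)
    ok = np.isfinite(p)
    if ok.sum():
        _, q_ok, _, _ = multipletests(p[ok], alpha=fdr_alpha, method="fdr_bh")
        q[ok] = q_ok
    table = pd.DataFrame(
        {"parcel": wide.columns.to_numpy(), "r": r, "p": p, "q": q, "n": n,
         "significant": np.where(np.isfinite(q), q < fdr_alpha, False)}
    )
    return CouplingResult(table=table, target_label=target_label,
                          method=method, fdr_alpha=fdr_alpha)


def mean_li_vs_coupling(
    coupling: CouplingResult, mean_li: pd.Series, top_k: int = 50
) -> dict:
    """Rank correlation across parcels between mean LI and coupling r, plus
    a summary of the ``top_k`` most (leftward-) lateralized parcels."""
    tab = coupling.table.set_index("parcel")
    parcels = tab.index.intersection(mean_li.index)
    if len(parcels) < 3:
        raise ValueError("need at least 3 matched parcels")
    m = mean_li.loc[parcels].to_numpy(dtype=float)
    r = tab.loc[parcels, "r"].to_numpy(dtype=float)
    ok = np.isfinite(m) & np.isfinite(r)
    rho, p = sps.spearmanr(m[ok], r[ok])
    order = np.argsort(-m)  # most leftward first
    k = min(top_k, int(ok.sum()))
    top_idx = [i for i in order if ok[i]][:k]
    top = pd.DataFrame(
        {"parcel": np.asarray(parcels)[top_idx], "mean_li": m[top_idx],
         "coupling_r": r[top_idx]}
    )
    return {
        "rho": float(rho),
        "p": float(p),
        "n_parcels": int(ok.sum()),
        "top_parcels": top,
        "top_fraction_positive": float((top["coupling_r"] > 0).mean()) if k else np.nan,
    }
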