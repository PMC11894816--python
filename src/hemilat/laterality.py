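"""Laterality indices and cross-participant analyses.

The laterality index of a category C is

    LI_C = (S_{C,L} - S_{C,R}) / (S_{C,L} + S_{C,R}),

positive for leftward lateralization.  Cross-participant analyses always
correlate LIs computed from disjoint run splits (odd runs {1,3,5} for the
first category, even runs {2,4} for the second) so estimation noise is
statistically independent between the two sides.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

from .glm import StatMap

__all__ = [
    "laterality_index",
    "CorrelationResult",
    "correlate",
    "pairwise_li_correlation",
    "residualize_li",
    "residualized_correlation",
    "split_half_reliability",
    "dice_overlap",
    "selective_mask",
    "handedness_sweep",
    "independent_task_contrast",
    "flag_rightward_text",
]


def laterality_index(s_left, s_right):
    """(S_L - S_R) / (S_L + S_R); NaN where both selectivities are zero.

    Accepts scalars or arrays; inputs must be nonnegative.
    """
    s_l = np.asarray(s_left, dtype=float)
    s_r = np.asarray(s_right, dtype=float)
    if (s_l < 0).any() or (s_r < 0).any():
        raise ValueError("selectivities must be nonnegative")
    total = s_l + s_r
    with np.errstate(invalid="ignore", divide="ignore"):
        li = np.where(total > 0, (s_l - s_r) / np.where(total > 0, total, 1.0), np.nan)
    if li.ndim == 0:
        return float(li)
    return li


@dataclass
class CorrelationResult:
    r: float
    p: float
    n: int
    method: str
    n_excluded: int = 0  # subjects dropped for undefined LI


def correlate(x, y, method: str = "pearson") -> CorrelationResult:
    """Correlation across subjects, pairwise-complete over defined LIs."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("LI vectors must be the same length")
    ok = np.isfinite(x) & np.isfinite(y)
    n_excluded = int((~ok).sum())
    x, y = x[ok], y[ok]
    if x.size < 3:
        raise ValueError(f"need at least 3 complete subjects, got {x.size}")
    if method == "pearson":
        r, p = sps.pearsonr(x, y)
    elif method == "spearman":
        r, p = sps.spearmanr(x, y)
    else:
        raise ValueError(f"unknown correlation method {method!r}")
    return CorrelationResult(r=float(r), p=float(p), n=int(x.size),
                             method=method, n_excluded=n_excluded)


def _select_li(table: pd.DataFrame, category: str, baseline: str,
               run_split: str, metric: str, heldout: str | None = None) -> pd.Series:
    sel = table[
        (table["category"] == category)
        & (table["baseline"] == baseline)
        & (table["run_split"] == run_split)
        & (table["metric"] == metric)
    ]
    if baseline == "heldout" and heldout is not None and "heldout" in table.columns:
        sel = sel[sel["heldout"] == heldout]
    if sel.empty:
        raise ValueError(
            f"no LI rows for category={category}, baseline={baseline}, "
            f"run_split={run_split}, metric={metric}"
        )
    if sel["subject_id"].duplicated().any():
        raise ValueError(
            f"ambiguous LI selection for category={category}, baseline={baseline}: "
            "multiple rows per subject (specify the held-out category)"
        )
    return sel.set_index("subject_id")["li"]


def pairwise_li_correlation(
    table: pd.DataFrame,
    cat_a: str,
    cat_b: str,
    baseline: str = "full",
    heldout: str | None = None,
    metric: str = "summed",
    method: str = "pearson",
    residualize_on: str | None = None,
) -> CorrelationResult:
    """Correlate cat_a's odd-split LI with cat_b's even-split LI across subjects.

    ``residualize_on`` names a third category whose fixation-baseline LI is
    regressed out of both sides (covariate taken from the same split as the
    LI it is removed from) before correlating.
    """
    if cat_a == cat_b:
        raise ValueError("categories in a pairwise comparison must differ")
    if baseline == "heldout" and heldout is None:
        from .pipeline import heldout_for_pair

        heldout = heldout_for_pair(cat_a, cat_b)
    li_a = _select_li(table, cat_a, baseline, "odd", metric, heldout=heldout)
    li_b = _select_li(table, cat_b, baseline, "even", metric, heldout=heldout)
    subjects = li_a.index.intersection(li_b.index)
    a = li_a.loc[subjects].to_numpy()
    b = li_b.loc[subjects].to_numpy()
    if residualize_on is not None:
        cov_a = _select_li(table, residualize_on, "fixation", "odd", metric)
        cov_b = _select_li(table, residualize_on, "fixation", "even", metric)
        a = residualize_li(a, cov_a.loc[subjects].to_numpy())
        b = residualize_li(b, cov_b.loc[subjects].to_numpy())
    return correlate(a, b, method=method)


def residualize_li(li_target, li_covariate) -> np.ndarray:
    """Residuals of a simple linear regression of target LI on covariate LI.

    NaNs in either vector propagate to the residuals; the fit uses complete
    pairs only.
    """
    y = np.asarray(li_target, dtype=float)
    x = np.asarray(li_covariate, dtype=float)
    if y.shape != x.shape:
        raise ValueError("target and covariate must be matched per subject")
    ok = np.isfinite(x) & np.isfinite(y)
    xc = x[ok]
    if xc.size < 3 or np.var(xc) == 0:
        raise ValueError("covariate has zero variance or too few complete pairs")
    slope, intercept = np.polyfit(xc, y[ok], 1)
    resid = np.full_like(y, np.nan)
    resid[ok] = y[ok] - (slope * x[ok] + intercept)
    return resid


def residualized_correlation(a, b, cov_a, cov_b, method: str = "pearson") -> CorrelationResult:
    """Correlation of two LI vectors after regressing a covariate LI out of each."""
    return correlate(residualize_li(a, cov_a), residualize_li(b, cov_b), method=method)


def split_half_reliability(
    table: pd.DataFrame,
    category: str,
    baseline: str = "full",
    metric: str = "summed",
    method: str = "spearman",
) -> CorrelationResult:
    """Rank correlation of odd-run vs even-run LI across subjects."""
    li_odd = _select_li(table, category, baseline, "odd", metric)
    li_even = _select_li(table, category, baseline, "even", metric)
    subjects = li_odd.index.intersection(li_even.index)
    return correlate(li_odd.loc[subjects], li_even.loc[subjects], method=method)


def selective_mask(tmap: StatMap, alpha: float = 0.001) -> np.ndarray:
    """Binarize a selectivity map: 1 where positive selectivity exceeds the
    one-sided p < alpha threshold (effect maps: statistic > 0)."""
    if tmap.kind == "effect":
        return tmap.data > 0
    return tmap.data > sps.t.ppf(1.0 - alpha, tmap.df)


def dice_overlap(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Dice coefficient 2|A∩B| / (|A| + |B|); 0 when both masks are empty."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must cover the same voxel set")
    denom = a.sum() + b.sum()
    if denom == 0:
        return 0.0
    return float(2.0 * (a & b).sum() / denom)


def handedness_sweep(
    li_a,
    li_b,
    handedness,
    thresholds=None,
    method: str = "pearson",
    partial_handedness: bool = False,
) -> pd.DataFrame:
    """Correlation of two LI vectors over subjects with handedness > threshold.

    Default thresholds span -100..90 in steps of 10 (Edinburgh scale;
    -100 includes everyone, 40 is the conventional right-handed cutoff).
    Thresholds leaving fewer than 3 subjects yield NaN rows rather than
    errors.  ``partial_handedness`` additionally residualizes both LIs on
    the handedness score within the retained subjects.
    """
    li_a = np.asarray(li_a, dtype=float)
    li_b = np.asarray(li_b, dtype=float)
    handedness = np.asarray(handedness, dtype=float)
    if thresholds is None:
        thresholds = np.arange(-100, 100, 10)
    rows = []
    for h in thresholds:
        keep = handedness > h
        row = {"threshold": float(h), "n": int(keep.sum()), "r": np.nan, "p": np.nan}
        a, b = li_a[keep], li_b[keep]
        ok = np.isfinite(a) & np.isfinite(b)
        if ok.sum() >= 3:
            try:
                if partial_handedness:
                    hh = handedness[keep]
                    if np.var(hh[ok]) > 0:
                        a = residualize_li(a, hh)
                        b = residualize_li(b, hh)
                res = correlate(a, b, method=method)
                row["r"], row["p"], row["n"] = res.r, res.p, res.n
            except ValueError:
                pass
        rows.append(row)
    return pd.DataFrame(rows)


def independent_task_contrast(map_cat_vs_fix: StatMap, map_base_vs_fix: StatMap) -> StatMap:
    """Re-baseline a category-vs-fixation map by subtracting a baseline
    category's vs-fixation map (e.g. bodies-vs-fixation minus
    places-vs-fixation), voxelwise."""
    if map_cat_vs_fix.data.shape != map_base_vs_fix.data.shape:
        raise ValueError("maps cover different voxel sets")
    if map_cat_vs_fix.kind != map_base_vs_fix.kind:
        raise ValueError("cannot mix t and effect maps")
    return StatMap(
        data=map_cat_vs_fix.data - map_base_vs_fix.data,
        df=map_cat_vs_fix.df,
        kind=map_cat_vs_fix.kind,
        name=f"{map_cat_vs_fix.name}-minus-{map_base_vs_fix.name}",
        hemispheres=map_cat_vs_fix.hemispheres,
    )


def flag_rightward_text(table: pd.DataFrame, threshold: float = -0.4,
                        metric: str = "summed") -> pd.Series:
    """Subject screen: flag strongly rightward text laterality (LI < threshold),
    computed from the all-runs full-baseline text LI.  Optional filter,
    default unused by the pipeline."""
    li = _select_li(table, "text", "full", "all", metric)
    return li < threshold
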