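"""Cohort-level pipeline: simulate -> fit -> selectivity -> laterality table.

All subjects in a cohort share one counterbalanced design (and hence one
design matrix), so the GLM projector is computed once; per-subject work is
a pair of small matrix products.  Statistic maps are t maps when noise is
present and contrast-effect maps when the simulation is noiseless (where
residual variance is numerically zero and t is undefined).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .contrasts import DOMAINS, build_domain_contrast, split_runs
from .design import AcquisitionSpec, StimulusDesign, build_block_design
from .glm import DesignMatrix, StatMap, build_design_matrix, canonical_hrf
from .population import Cohort, PopulationSpec, sample_population
from .selectivity import METRICS, ROIMask, responsive_mask
from .timeseries import ar1_noise, neural_regressors

__all__ = [
    "CohortFit",
    "fit_cohort",
    "domain_stat_maps",
    "cohort_li_table",
    "simulate_li_table",
    "heldout_for_pair",
]

RUN_SPLITS = ("odd", "even", "all")


def heldout_for_pair(cat_a: str, cat_b: str) -> str:
    """The third domain, used as the held-out baseline for a pairwise comparison."""
    rest = [d for d in DOMAINS if d not in (cat_a, cat_b)]
    if len(rest) != 1:
        raise ValueError(f"({cat_a}, {cat_b}) is not a valid domain pair")
    return rest[0]


@dataclass
class CohortFit:
    """Stacked GLM results for a cohort sharing one design matrix."""

    cohort: Cohort
    design: StimulusDesign
    acq: AcquisitionSpec
    design_matrix: DesignMatrix
    betas: np.ndarray  # (n_subjects, n_regressors, n_voxels)
    sigma2: np.ndarray  # (n_subjects, n_voxels)
    df: int
    xtx_inv: np.ndarray
    stat_kind: str  # "t" when noise present, "effect" otherwise

    @property
    def n_subjects(self) -> int:
        return self.betas.shape[0]

    def contrast_weight_vector(self, weights) -> np.ndarray:
        c = np.zeros(self.betas.shape[1])
        items = weights.weights.items() if hasattr(weights, "weights") else weights.items()
        for key, w in items:
            if key not in self.design_matrix.task_index:
                raise KeyError(f"contrast references absent column {key}")
            c[self.design_matrix.task_index[key]] = w
        return c

    def contrast_maps(self, weights, kind: str | None = None) -> np.ndarray:
        """(n_subjects, n_voxels) statistic maps for one contrast."""
        kind = kind or self.stat_kind
        c = self.contrast_weight_vector(weights)
        effect = np.einsum("p,spv->sv", c, self.betas)
        if kind == "effect":
            return effect
        var_factor = float(c @ self.xtx_inv @ c)
        denom = np.sqrt(self.sigma2 * var_factor)
        with np.errstate(divide="ignore", invalid="ignore"):
            return np.where(denom > 0, effect / denom, 0.0)

    def subject_stat_map(self, i: int, weights, name: str = "") -> StatMap:
        data = self.contrast_maps(weights)[i]
        return StatMap(data=data, df=self.df, kind=self.stat_kind, name=name,
                       hemispheres=self.cohort.hemispheres)

    def omnibus_weights(self, runs: list[int] | None = None) -> dict:
        runs = runs or list(range(1, self.acq.n_runs + 1))
        cats = list(self.cohort.spec.categories)
        w = 1.0 / (len(cats) * len(runs))
        return {(c, r): w for c in cats for r in runs}

    def responsive_masks(self, alpha: float = 0.001,
                         runs: list[int] | None = None) -> np.ndarray:
        """(n_subjects, n_voxels) responsive masks from the stimulus-vs-rest
        omnibus map over the given runs (default: all runs)."""
        maps = self.contrast_maps(self.omnibus_weights(runs))
        if self.stat_kind == "effect":
            return maps > 0
        from scipy import stats as sps

        return maps > sps.t.ppf(1.0 - alpha, self.df)


def fit_cohort(
    cohort: Cohort,
    acq: AcquisitionSpec | None = None,
    seed: int | np.random.Generator = 0,
    design: StimulusDesign | None = None,
    nuisance: np.ndarray | None = None,
) -> CohortFit:
    """Simulate every subject's series and fit the shared-design GLM.

    Noise SD and AR coefficient come from the cohort's PopulationSpec.
    """
    acq = acq or AcquisitionSpec()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    spec = cohort.spec
    conditions = list(spec.categories)
    if design is None:
        design = build_block_design(acq, conditions, rng)
    hrf = canonical_hrf(0.1)
    dm = build_design_matrix(design, acq, conditions, hrf=hrf, nuisance=nuisance)
    regs = neural_regressors(design, acq, conditions, hrf=hrf)
    signal_basis = np.vstack(regs)  # (total_timepoints, n_conditions)

    X = dm.X
    xtx_inv = np.linalg.inv(X.T @ X)
    projector = xtx_inv @ X.T
    df = X.shape[0] - np.linalg.matrix_rank(X)

    n_subj = cohort.n_subjects
    n_vox = cohort.amplitudes.shape[2]
    betas = np.empty((n_subj, X.shape[1], n_vox))
    sigma2 = np.empty((n_subj, n_vox))
    noisy = spec.noise_sd > 0
    for i in range(n_subj):
        amp = cohort.amplitudes[i] + cohort.shared_maps[i][None, :]
        y = signal_basis @ amp
        if noisy:
            y = y + ar1_noise(rng, y.shape, spec.noise_sd, spec.ar_coefficient)
        b = projector @ y
        resid = y - X @ b
        betas[i] = b
        sigma2[i] = np.einsum("tv,tv->v", resid, resid) / df

    return CohortFit(
        cohort=cohort, design=design, acq=acq, design_matrix=dm,
        betas=betas, sigma2=sigma2, df=df, xtx_inv=xtx_inv,
        stat_kind="t" if noisy else "effect",
    )


def _domain_contrasts(fit: CohortFit, baselines, n_runs: int):
    """All (category, baseline, heldout, split) contrast vectors needed for
    the laterality table."""
    specs = []
    for cat in DOMAINS:
        for baseline in baselines:
            if baseline == "heldout":
                helds = [d for d in DOMAINS if d != cat]
            else:
                helds = [None]
            for heldout in helds:
                for split in RUN_SPLITS:
                    specs.append((cat, baseline, heldout, split))
    return specs


def domain_stat_maps(fit: CohortFit, baselines=("full", "heldout", "fixation")):
    """dict (category, baseline, heldout, split) -> (n_subjects, n_voxels) maps."""
    out = {}
    for cat, baseline, heldout, split in _domain_contrasts(fit, baselines, fit.acq.n_runs):
        cv = build_domain_contrast(
            cat, baseline, run_split=split, heldout_category=heldout,
            n_runs=fit.acq.n_runs,
        )
        out[(cat, baseline, heldout, split)] = fit.contrast_maps(cv)
    return out


def _hemisphere_selectivity(maps: np.ndarray, resp: np.ndarray,
                            hemi_mask: np.ndarray, metric: str,
                            stat_kind: str, df: int, alpha: float):
    """Vectorized selectivity over subjects for one hemisphere."""
    use = resp & hemi_mask[None, :]
    vals = np.where(use, maps, np.nan)
    if metric == "summed":
        return np.nansum(np.clip(vals, 0.0, None), axis=1)
    if metric == "peak":
        with np.errstate(all="ignore"):
            peak = np.nanmax(np.where(use, maps, -np.inf), axis=1)
        return np.clip(np.where(np.isfinite(peak), peak, 0.0), 0.0, None)
    if metric == "count":
        if stat_kind == "t":
            from scipy import stats as sps

            thr = sps.t.ppf(1.0 - alpha, df)
        else:
            thr = 0.0
        return np.nansum(np.where(use, maps > thr, False), axis=1).astype(float)
    raise ValueError(f"unknown metric {metric!r}")


def cohort_li_table(
    fit: CohortFit,
    baselines=("full", "heldout", "fixation"),
    metrics=("summed",),
    alpha: float = 0.001,
    anatomical: np.ndarray | None = None,
    mask_policy: str = "all-runs",
) -> pd.DataFrame:
    """Tidy laterality table: one row per subject x category x baseline x
    (heldout) x metric x run split, with handedness attached.

    mask_policy selects the stimulus-responsive mask: "all-runs" (one mask
    per subject from the omnibus over every run, standard localizer
    practice) or "per-split" (a mask per run split, keeping the two sides
    of a cross-split comparison fully independent — a shared mask's
    hemispheric sampling noise otherwise couples all of a subject's LIs).
    """
    from .laterality import laterality_index

    if mask_policy not in ("all-runs", "per-split"):
        raise ValueError(f"unknown mask_policy {mask_policy!r}")
    n_vox = fit.betas.shape[2]
    hemis = fit.cohort.hemispheres
    if anatomical is None:
        anatomical = np.ones(n_vox, dtype=bool)
    if mask_policy == "all-runs":
        shared_mask = fit.responsive_masks(alpha=alpha) & anatomical[None, :]
        resp_by_split = {s: shared_mask for s in RUN_SPLITS}
    else:
        resp_by_split = {
            s: fit.responsive_masks(alpha=alpha, runs=list(split_runs(s, fit.acq.n_runs)))
            & anatomical[None, :]
            for s in RUN_SPLITS
        }
    left = hemis == "L"
    right = hemis == "R"

    maps = domain_stat_maps(fit, baselines=baselines)
    rows = []
    ids = fit.cohort.subject_ids
    hand = fit.cohort.handedness
    for (cat, baseline, heldout, split), m in maps.items():
        resp = resp_by_split[split]
        for metric in metrics:
            s_l = _hemisphere_selectivity(m, resp, left, metric, fit.stat_kind, fit.df, alpha)
            s_r = _hemisphere_selectivity(m, resp, right, metric, fit.stat_kind, fit.df, alpha)
            li = laterality_index(s_l, s_r)
            for i, sid in enumerate(ids):
                rows.append(
                    {
                        "subject_id": sid, "category": cat, "baseline": baseline,
                        "heldout": heldout if heldout is not None else "",
                        "metric": metric, "run_split": split,
                        "s_left": s_l[i], "s_right": s_r[i], "li": li[i],
                        "handedness": hand[i],
                    }
                )
    table = pd.DataFrame(rows)
    table.attrs["n_undefined"] = int(table["li"].isna().sum())
    table.attrs["stat_kind"] = fit.stat_kind
    return table


def simulate_li_table(
    spec: PopulationSpec,
    acq: AcquisitionSpec | None = None,
    seed: int = 0,
    baselines=("full", "heldout", "fixation"),
    metrics=("summed",),
    alpha: float = 0.001,
    mask_policy: str = "all-runs",
) -> tuple[pd.DataFrame, Cohort]:
    """End-to-end convenience: sample a cohort, simulate, fit, and tabulate LIs."""
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    cohort = sample_population(spec, rng)
    fit = fit_cohort(cohort, acq=acq, seed=rng)
    table = cohort_li_table(fit, baselines=baselines, metrics=metrics,
                            alpha=alpha, mask_policy=mask_policy)
    return table, cohort
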