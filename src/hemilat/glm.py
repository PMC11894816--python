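"""Voxelwise general linear model for block-design BOLD data.

Each mini-block is modeled as a single boxcar event of its stated duration,
convolved with a canonical double-gamma hemodynamic response function.  The
design matrix holds one task column per condition per run, per-run mean
columns, and any user-supplied nuisance columns appended verbatim.  Fitting
is ordinary least squares per voxel, with an optional one-pass
Cochrane-Orcutt AR(1) prewhitening using a single coefficient pooled over
voxels.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats

__all__ = [
    "HRFParams",
    "canonical_hrf",
    "DesignMatrix",
    "build_design_matrix",
    "BetaEstimates",
    "fit_glm",
    "StatMap",
    "contrast_stat_map",
    "contrast_tmap",
    "omnibus_contrast",
]

_OVERSAMPLE_DT = 0.1  # s; grid for boxcar construction before convolution


@dataclass(frozen=True)
class HRFParams:
    """Double-gamma HRF: response gamma minus scaled undershoot gamma.

    Shape parameters are the conventional ones (peak delay 6 s, undershoot
    delay 16 s, unit dispersions, undershoot ratio 1/6, 32 s support).
    """

    peak_delay: float = 6.0
    undershoot_delay: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    undershoot_ratio: float = 1.0 / 6.0
    duration: float = 32.0


def canonical_hrf(dt: float, params: HRFParams | None = None) -> np.ndarray:
    """Sample the canonical double-gamma HRF at spacing ``dt`` seconds.

    Returned kernel spans [0, params.duration) and is normalized to unit
    peak, so a sustained response plateaus near the per-voxel amplitude.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    p = params or HRFParams()
    t = np.arange(0.0, p.duration, dt)
    peak = stats.gamma.pdf(t, p.peak_delay / p.peak_dispersion, scale=p.peak_dispersion)
    under = stats.gamma.pdf(
        t, p.undershoot_delay / p.undershoot_dispersion, scale=p.undershoot_dispersion
    )
    h = peak - p.undershoot_ratio * under
    return h / h.max()


def condition_regressors(
    run_blocks,
    conditions: list[str],
    n_timepoints: int,
    tr: float,
    hrf: np.ndarray | None = None,
    hrf_dt: float = _OVERSAMPLE_DT,
) -> np.ndarray:
    """HRF-convolved boxcar regressors for one run, sampled on the TR grid.

    Returns an (n_timepoints, len(conditions)) array.  Conditions absent
    from the run yield all-zero columns.  Rest blocks are simply not listed
    in ``conditions`` (implicit baseline).
    """
    if hrf is None:
        hrf = canonical_hrf(hrf_dt)
    n_fine = int(np.ceil(n_timepoints * tr / hrf_dt)) + len(hrf)
    out = np.zeros((n_timepoints, len(conditions)))
    sample_idx = np.round(np.arange(n_timepoints) * tr / hrf_dt).astype(int)

    # reject overlapping blocks
    ordered = sorted(run_blocks, key=lambda b: b.onset_seconds)
    for a, b in zip(ordered[:-1], ordered[1:]):
        if b.onset_seconds < a.onset_seconds + a.duration_seconds - 1e-9:
            raise ValueError(
                f"overlapping blocks at {a.onset_seconds} s and {b.onset_seconds} s"
            )

    for j, cond in enumerate(conditions):
        box = np.zeros(n_fine)
        for blk in run_blocks:
            if blk.condition != cond:
                continue
            i0 = int(np.round(blk.onset_seconds / hrf_dt))
            i1 = int(np.round((blk.onset_seconds + blk.duration_seconds) / hrf_dt))
            box[i0:i1] = 1.0
        if not box.any():
            continue
        # Riemann approximation of the continuous convolution integral; a
        # sustained block then plateaus near amplitude x HRF area
        conv = np.convolve(box, hrf)[:n_fine] * hrf_dt
        out[:, j] = conv[sample_idx]
    return out


@dataclass
class DesignMatrix:
    """Timepoint x regressor matrix with labeled columns.

    Task columns are named ``"<condition>_run<r>"`` (1-based run index),
    run means ``"mean_run<r>"``, nuisance columns ``"nuisance_<i>"``.
    """

    X: np.ndarray
    labels: list[str]
    task_index: dict[tuple[str, int], int]  # (condition, run) -> column
    run_slices: list[slice]  # timepoint range of each run
    tr: float

    @property
    def n_timepoints(self) -> int:
        return self.X.shape[0]

    @property
    def n_regressors(self) -> int:
        return self.X.shape[1]

    def column(self, label: str) -> int:
        return self.labels.index(label)


def build_design_matrix(
    design,
    acq,
    conditions: list[str],
    hrf: np.ndarray | None = None,
    nuisance: np.ndarray | None = None,
    drift_cosines: int = 0,
) -> DesignMatrix:
    """Assemble the GLM design matrix for a multi-run stimulus design.

    Parameters
    ----------
    design : StimulusDesign
    acq : AcquisitionSpec
    conditions : stimulus conditions to model (rest excluded -> implicit
        fixation baseline).
    hrf : optional kernel sampled at 0.1 s; default canonical double-gamma.
    nuisance : optional (total_timepoints, q) matrix appended verbatim
        (mean-centered per run to preserve the run-mean interpretation).
    drift_cosines : number of per-run discrete cosine drift columns to add.
    """
    from .design import REST

    conditions = [c for c in conditions if c != REST]
    n_runs = design.n_runs
    tp_per_run = [acq.n_timepoints(len(run)) for run in design.runs]
    total_tp = int(np.sum(tp_per_run))

    run_slices = []
    start = 0
    for tp in tp_per_run:
        run_slices.append(slice(start, start + tp))
        start += tp

    blocks_cols: list[np.ndarray] = []
    labels: list[str] = []
    task_index: dict[tuple[str, int], int] = {}

    # condition x run task columns
    for r, run in enumerate(design.runs, start=1):
        reg = condition_regressors(run, conditions, tp_per_run[r - 1], acq.tr_seconds, hrf=hrf)
        for j, cond in enumerate(conditions):
            col = np.zeros(total_tp)
            col[run_slices[r - 1]] = reg[:, j]
            task_index[(cond, r)] = len(labels)
            labels.append(f"{cond}_run{r}")
            blocks_cols.append(col)

    # per-run mean columns
    for r in range(1, n_runs + 1):
        col = np.zeros(total_tp)
        col[run_slices[r - 1]] = 1.0
        labels.append(f"mean_run{r}")
        blocks_cols.append(col)

    # optional per-run cosine drift columns
    for r in range(1, n_runs + 1):
        tp = tp_per_run[r - 1]
        for j in range(1, drift_cosines + 1):
            col = np.zeros(total_tp)
            t = np.arange(tp)
            col[run_slices[r - 1]] = np.cos(np.pi * j * (2 * t + 1) / (2 * tp))
            labels.append(f"drift_run{r}_{j}")
            blocks_cols.append(col)

    X = np.column_stack(blocks_cols)

    if nuisance is not None:
        nuisance = np.asarray(nuisance, dtype=float)
        if nuisance.ndim == 1:
            nuisance = nuisance[:, None]
        if nuisance.shape[0] != total_tp:
            raise ValueError(
                f"nuisance has {nuisance.shape[0]} timepoints, design has {total_tp}"
            )
        centered = nuisance.copy()
        for sl in run_slices:
            centered[sl] -= centered[sl].mean(axis=0)
        for i in range(centered.shape[1]):
            labels.append(f"nuisance_{i}")
        X = np.column_stack([X, centered])

    return DesignMatrix(X=X, labels=labels, task_index=task_index,
                        run_slices=run_slices, tr=acq.tr_seconds)


@dataclass
class BetaEstimates:
    """Per-voxel OLS estimates: (n_regressors, n_voxels) betas plus noise terms."""

    betas: np.ndarray
    sigma2: np.ndarray  # residual variance per voxel (RSS / df)
    df: int
    xtx_inv: np.ndarray
    labels: list[str]
    task_index: dict[tuple[str, int], int]
    ar_coefficient: float | None = None

    @property
    def n_voxels(self) -> int:
        return self.betas.shape[1]

    def beta(self, condition: str, run: int) -> np.ndarray:
        return self.betas[self.task_index[(condition, run)]]


def _check_rank(X: np.ndarray, labels: list[str]) -> None:
    # name near-collinear columns via the R factor's diagonal
    _, R = np.linalg.qr(X)
    diag = np.abs(np.diag(R))
    scale = diag.max() if diag.size else 0.0
    bad = [labels[i] for i in np.nonzero(diag < 1e-10 * max(scale, 1e-300))[0]]
    if bad:
        raise ValueError(f"design matrix is rank deficient; collinear columns: {bad}")


def _ols(Y: np.ndarray, X: np.ndarray) -> tuple[np.ndarray, np.ndarray, int, np.ndarray]:
    xtx = X.T @ X
    xtx_inv = np.linalg.inv(xtx)
    betas = xtx_inv @ (X.T @ Y)
    resid = Y - X @ betas
    df = X.shape[0] - np.linalg.matrix_rank(X)
    if df <= 0:
        raise ValueError("no residual degrees of freedom")
    sigma2 = np.einsum("tv,tv->v", resid, resid) / df
    return betas, sigma2, df, xtx_inv


def fit_glm(series: np.ndarray, design: DesignMatrix, whitening: str = "none") -> BetaEstimates:
    """Fit the GLM to a (timepoints, voxels) series.

    whitening="ar1" runs one Cochrane-Orcutt pass: estimate a single AR(1)
    coefficient from residuals pooled over voxels, quasi-difference data and
    design within each run, and refit.
    """
    Y = np.asarray(series, dtype=float)
    if Y.ndim == 1:
        Y = Y[:, None]
    if Y.shape[0] != design.n_timepoints:
        raise ValueError(
            f"series has {Y.shape[0]} timepoints, design has {design.n_timepoints}"
        )
    if np.isnan(Y).any():
        raise ValueError("series contains NaN values")
    if whitening not in ("none", "ar1"):
        raise ValueError(f"unknown whitening {whitening!r}")

    _check_rank(design.X, design.labels)
    betas, sigma2, df, xtx_inv = _ols(Y, design.X)
    rho = None
    if whitening == "ar1":
        resid = Y - design.X @ betas
        num = 0.0
        den = 0.0
        for sl in design.run_slices:
            r = resid[sl]
            num += np.sum(r[1:] * r[:-1])
            den += np.sum(r[:-1] ** 2)
        rho = float(num / den) if den > 0 else 0.0
        rho = float(np.clip(rho, -0.99, 0.99))
        Yw = Y.copy()
        Xw = design.X.copy()
        for sl in design.run_slices:
            Yw[sl][1:] = Y[sl][1:] - rho * Y[sl][:-1]
            Xw[sl][1:] = design.X[sl][1:] - rho * design.X[sl][:-1]
        betas, sigma2, df, xtx_inv = _ols(Yw, Xw)

    return BetaEstimates(
        betas=betas, sigma2=sigma2, df=df, xtx_inv=xtx_inv,
        labels=design.labels, task_index=design.task_index, ar_coefficient=rho,
    )


@dataclass
class StatMap:
    """Per-voxel statistic map for one contrast.

    kind is "t" (t-statistic) or "effect" (the contrast estimate c'beta,
    used when residual variance is degenerate, e.g. noiseless simulations).
    """

    data: np.ndarray
    df: int
    kind: str = "t"
    name: str = ""
    hemispheres: np.ndarray | None = None  # per-voxel "L"/"R"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.kind not in ("t", "effect"):
            raise ValueError(f"unknown StatMap kind {self.kind!r}")


def _contrast_vector_to_weights(betas: BetaEstimates, weights) -> np.ndarray:
    """Accept a dense array, a {(condition, run): w} dict, or a ContrastVector."""
    if hasattr(weights, "weights"):  # ContrastVector
        weights = weights.weights
    if isinstance(weights, dict):
        c = np.zeros(betas.betas.shape[0])
        for key, w in weights.items():
            if key not in betas.task_index:
                raise KeyError(f"contrast references absent column {key}")
            c[betas.task_index[key]] = w
        return c
    c = np.asarray(weights, dtype=float)
    if c.shape[0] != betas.betas.shape[0]:
        raise ValueError("dense contrast length does not match regressor count")
    return c


def contrast_stat_map(
    betas: BetaEstimates, weights, kind: str = "t", name: str = ""
) -> StatMap:
    """t = c'beta / sqrt(sigma2 * c'(X'X)^-1 c), or the effect c'beta."""
    c = _contrast_vector_to_weights(betas, weights)
    effect = c @ betas.betas
    if kind == "effect":
        return StatMap(data=effect, df=betas.df, kind="effect", name=name)
    var_factor = float(c @ betas.xtx_inv @ c)
    denom = np.sqrt(betas.sigma2 * var_factor)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(denom > 0, effect / denom, 0.0)
    return StatMap(data=t, df=betas.df, kind="t", name=name)


def contrast_tmap(betas: BetaEstimates, weights, name: str = "") -> StatMap:
    return contrast_stat_map(betas, weights, kind="t", name=name)


def omnibus_contrast(betas: BetaEstimates, conditions: list[str], runs: list[int]) -> dict:
    """Mean of all stimulus conditions over the given runs vs. the implicit
    rest baseline, balanced over conditions (the stimulus-vs-rest map that
    defines the responsive mask)."""
    w = 1.0 / (len(conditions) * len(runs))
    return {(c, r): w for c in conditions for r in runs}
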