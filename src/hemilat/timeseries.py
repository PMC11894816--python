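"""Forward simulation of block-design BOLD time series.

Signal model per voxel: block boxcars weighted by the voxel's per-condition
amplitude (category amplitude plus the category-unspecific shared
component on every stimulus condition; rest blocks carry zero signal),
convolved with the HRF and sampled on the TR grid, plus additive Gaussian
noise (optionally AR(1)).
"""

from __future__ import annotations

import numpy as np

from .design import REST, AcquisitionSpec, StimulusDesign
from .glm import canonical_hrf, condition_regressors
from .population import SubjectGroundTruth

__all__ = ["neural_regressors", "simulate_timeseries"]


def neural_regressors(
    design: StimulusDesign,
    acq: AcquisitionSpec,
    conditions: list[str],
    hrf: np.ndarray | None = None,
) -> list[np.ndarray]:
    """Per-run HRF-convolved condition regressors used as the signal basis.

    Identical construction to the GLM's task columns, which is what makes
    noiseless recovery exact.
    """
    if hrf is None:
        hrf = canonical_hrf(0.1)
    conditions = [c for c in conditions if c != REST]
    out = []
    for run in design.runs:
        tp = acq.n_timepoints(len(run))
        out.append(condition_regressors(run, conditions, tp, acq.tr_seconds, hrf=hrf))
    return out


def ar1_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, rho: float
) -> np.ndarray:
    """Stationary AR(1) noise with marginal SD ``sd``; rho=0 gives white noise."""
    white = rng.standard_normal(shape)
    if rho == 0.0:
        return sd * white
    innov_sd = np.sqrt(1.0 - rho**2)
    out = np.empty(shape)
    out[0] = white[0]
    for t in range(1, shape[0]):
        out[t] = rho * out[t - 1] + innov_sd * white[t]
    return sd * out


def simulate_timeseries(
    subject: SubjectGroundTruth,
    design: StimulusDesign,
    acq: AcquisitionSpec,
    hrf: np.ndarray | None = None,
    noise_sd: float = 0.0,
    ar_coefficient: float = 0.0,
    seed: int | np.random.Generator = 0,
) -> list[np.ndarray]:
    """Simulate per-run (timepoints, voxels) series for one subject."""
    if np.isnan(subject.amplitudes).any() or np.isnan(subject.shared_map).any():
        raise ValueError("subject amplitude maps contain NaN")
    if design.n_runs != acq.n_runs:
        raise ValueError(
            f"design has {design.n_runs} runs but acquisition expects {acq.n_runs}"
        )
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    conditions = [c for c in subject.categories]
    regs = neural_regressors(design, acq, conditions, hrf=hrf)
    # every stimulus condition drives the voxel's category amplitude plus
    # the shared arousal component
    amp = subject.amplitudes + subject.shared_map[None, :]
    runs = []
    for reg in regs:
        signal = reg @ amp  # (timepoints, voxels)
        if noise_sd > 0:
            signal = signal + ar1_noise(rng, signal.shape, noise_sd, ar_coefficient)
        runs.append(signal)
    return runs
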