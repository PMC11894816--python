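"""Synthetic cohorts of ground-truth subjects.

Each subject carries per-voxel response-amplitude maps for six stimulus
categories in two hemispheres, a category-unspecific shared ("arousal")
activation map loading on every stimulus condition, a true laterality index
(LI) per category, and an Edinburgh handedness score.

Generative scheme
-----------------
* True LIs across categories follow a Gaussian copula: a latent standard
  normal vector with correlation ``li_correlation`` is scaled by
  ``true_li_sd`` and shifted by ``true_li_means``, then clipped to (-1, 1).
  The linear map preserves the target correlation exactly in population.
* Voxel tuning: for every voxel, a latent normal vector across categories
  with correlation ``overlap`` is mapped through a lognormal transform
  (mean-one), so overlap 1 yields identical maps and overlap 0 independent
  ones.
* The right-hemisphere tuning pattern is a homotopic mirror copy of the
  left (optionally perturbed by ``pattern_asymmetry``); lateralization is
  realized by hemisphere-specific gains chosen so the LI of summed
  amplitudes equals the drawn true LI exactly.  With an exact mirror the
  per-voxel amplitude ratio is constant, so summed, peak, and
  count-oriented laterality all agree with the stored true LI.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "DEFAULT_CATEGORIES",
    "TEXT_CONDITIONS",
    "PopulationSpec",
    "SubjectGroundTruth",
    "Cohort",
    "sample_population",
]

DEFAULT_CATEGORIES: tuple[str, ...] = (
    "faces",
    "words",
    "inverted_words",
    "letter_strings",
    "objects",
    "scrambled",
)
TEXT_CONDITIONS: tuple[str, ...] = ("words", "inverted_words", "letter_strings")

# group-level laterality: faces rightward, text leftward, objects near zero
_DEFAULT_LI_MEANS = {
    "faces": -0.25,
    "words": 0.3,
    "inverted_words": 0.3,
    "letter_strings": 0.3,
    "objects": -0.05,
    "scrambled": 0.0,
}


def _default_li_means(categories: tuple[str, ...]) -> np.ndarray:
    return np.array([_DEFAULT_LI_MEANS.get(c, 0.0) for c in categories])


@dataclass
class PopulationSpec:
    """Parameters of the simulated population.

    true_li_means / true_li_sd are per-category arrays aligned with
    ``categories``.  ``li_correlation`` is the target cross-subject
    correlation matrix of true LIs (symmetric PSD, unit diagonal);
    ``overlap`` in [0, 1] controls shared voxel tuning between category
    maps.  ``shared_activation_amplitude`` scales an arousal component
    common to all stimulus conditions, whose own laterality varies across
    subjects with SD ``shared_li_sd``.  Handedness is Edinburgh-scale,
    clipped to [-100, 100].
    """

    n_subjects: int = 51
    categories: tuple[str, ...] = DEFAULT_CATEGORIES
    n_voxels_per_hemisphere: int = 50
    true_li_means: np.ndarray | None = None
    true_li_sd: np.ndarray | float = 0.2
    li_correlation: np.ndarray | None = None
    overlap: np.ndarray | float = 0.2
    shared_activation_amplitude: float = 0.5
    shared_li_sd: float = 0.2
    amplitude_mean: float = 1.0
    tuning_log_sd: float = 0.5
    pattern_asymmetry: float = 0.0
    noise_sd: float = 4.0
    ar_coefficient: float = 0.0
    handedness_mean: float = 86.9
    handedness_sd: float = 16.5

    def __post_init__(self) -> None:
        k = len(self.categories)
        if self.true_li_means is None:
            self.true_li_means = _default_li_means(self.categories)
        self.true_li_means = np.asarray(self.true_li_means, dtype=float)
        if np.isscalar(self.true_li_sd):
            self.true_li_sd = np.full(k, float(self.true_li_sd))
        self.true_li_sd = np.asarray(self.true_li_sd, dtype=float)
        if self.li_correlation is None:
            self.li_correlation = np.eye(k)
        self.li_correlation = np.asarray(self.li_correlation, dtype=float)
        if np.isscalar(self.overlap):
            off = float(self.overlap)
            self.overlap = np.full((k, k), off)
            np.fill_diagonal(self.overlap, 1.0)
        self.overlap = np.asarray(self.overlap, dtype=float)
        self.validate()

    def validate(self) -> None:
        k = len(self.categories)
        if self.n_subjects < 2:
            raise ValueError("n_subjects must be >= 2")
        for name, m in (("li_correlation", self.li_correlation), ("overlap", self.overlap)):
            if m.shape != (k, k):
                raise ValueError(f"{name} must be {k}x{k}")
            if not np.allclose(m, m.T, atol=1e-10):
                raise ValueError(f"{name} must be symmetric")
        if not np.allclose(np.diag(self.li_correlation), 1.0):
            raise ValueError("li_correlation must have unit diagonal")
        eigvals = np.linalg.eigvalsh(self.li_correlation)
        if eigvals.min() < -1e-8:
            raise ValueError(
                f"li_correlation is not positive semi-definite "
                f"(smallest eigenvalue {eigvals.min():.3g})"
            )
        if (self.overlap < -1e-12).any() or (self.overlap > 1 + 1e-12).any():
            raise ValueError("overlap entries must lie in [0, 1]")
        if np.abs(self.true_li_means).max() >= 1:
            raise ValueError("true_li_means must lie in (-1, 1)")
        if self.shared_activation_amplitude < 0:
            raise ValueError("shared_activation_amplitude must be nonnegative")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")

    def with_updates(self, **kwargs) -> "PopulationSpec":
        return replace(self, **kwargs)


@dataclass
class SubjectGroundTruth:
    """One simulated subject.

    amplitudes: (n_categories, n_voxels) with the left hemisphere occupying
    the first ``n_voxels_per_hemisphere`` columns and the right hemisphere,
    in homotopic voxel order, the rest.  shared_map is the arousal
    component added to every stimulus condition's response.
    """

    subject_id: str
    categories: tuple[str, ...]
    amplitudes: np.ndarray
    shared_map: np.ndarray
    true_li: np.ndarray
    handedness: float
    n_voxels_per_hemisphere: int

    @property
    def hemispheres(self) -> np.ndarray:
        v = self.n_voxels_per_hemisphere
        return np.array(["L"] * v + ["R"] * v)

    def amplitude_li(self) -> np.ndarray:
        """LI of summed positive amplitudes per category (sanity check)."""
        v = self.n_voxels_per_hemisphere
        pos = np.clip(self.amplitudes, 0.0, None)
        s_l = pos[:, :v].sum(axis=1)
        s_r = pos[:, v:].sum(axis=1)
        with np.errstate(invalid="ignore"):
            return (s_l - s_r) / (s_l + s_r)


@dataclass
class Cohort:
    """Stacked cohort arrays plus per-subject views."""

    spec: PopulationSpec
    amplitudes: np.ndarray  # (n_subjects, n_categories, n_voxels)
    shared_maps: np.ndarray  # (n_subjects, n_voxels)
    true_li: np.ndarray  # (n_subjects, n_categories)
    shared_li: np.ndarray  # (n_subjects,)
    handedness: np.ndarray  # (n_subjects,)
    subject_ids: list[str] = field(default_factory=list)

    @property
    def n_subjects(self) -> int:
        return self.amplitudes.shape[0]

    @property
    def hemispheres(self) -> np.ndarray:
        v = self.spec.n_voxels_per_hemisphere
        return np.array(["L"] * v + ["R"] * v)

    @property
    def subjects(self) -> list[SubjectGroundTruth]:
        return [self.subject(i) for i in range(self.n_subjects)]

    def subject(self, i: int) -> SubjectGroundTruth:
        return SubjectGroundTruth(
            subject_id=self.subject_ids[i],
            categories=self.spec.categories,
            amplitudes=self.amplitudes[i],
            shared_map=self.shared_maps[i],
            true_li=self.true_li[i],
            handedness=float(self.handedness[i]),
            n_voxels_per_hemisphere=self.spec.n_voxels_per_hemisphere,
        )

    def true_li_frame(self):
        import pandas as pd

        rows = []
        for i, sid in enumerate(self.subject_ids):
            for j, cat in enumerate(self.spec.categories):
                rows.append(
                    {"subject_id": sid, "category": cat,
                     "true_li": self.true_li[i, j],
                     "handedness": self.handedness[i]}
                )
        return pd.DataFrame(rows)


def _psd_factor(corr: np.ndarray) -> np.ndarray:
    """Matrix square root tolerant of PSD-degenerate correlation matrices."""
    vals, vecs = np.linalg.eigh(corr)
    vals = np.clip(vals, 0.0, None)
    return vecs * np.sqrt(vals)


def _lognormal_from_latent(z: np.ndarray, mean: float, log_sd: float) -> np.ndarray:
    """Mean-``mean`` lognormal transform of standard-normal latents."""
    return mean * np.exp(log_sd * z - 0.5 * log_sd**2)


def _hemisphere_gains(base_left: np.ndarray, base_right: np.ndarray,
                      li: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Gains g_L, g_R so (g_L*A_L - g_R*A_R) / (g_L*A_L + g_R*A_R) = li,
    keeping the bilateral amplitude total fixed."""
    a_l = base_left.sum(axis=-1)
    a_r = base_right.sum(axis=-1)
    total = a_l + a_r
    g_l = (1.0 + li) * total / (2.0 * a_l)
    g_r = (1.0 - li) * total / (2.0 * a_r)
    return g_l, g_r


def sample_population(spec: PopulationSpec, seed: int | np.random.Generator) -> Cohort:
    """Draw a cohort of ground-truth subjects; deterministic under a fixed seed."""
    spec.validate()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    n, k, v = spec.n_subjects, len(spec.categories), spec.n_voxels_per_hemisphere

    # true LIs via Gaussian copula
    li_factor = _psd_factor(spec.li_correlation)
    z = rng.standard_normal((n, k)) @ li_factor.T
    true_li = np.clip(spec.true_li_means + spec.true_li_sd * z, -0.999, 0.999)

    # shared-component laterality and handedness
    shared_li = np.clip(rng.standard_normal(n) * spec.shared_li_sd, -0.999, 0.999)
    handedness = np.clip(
        rng.normal(spec.handedness_mean, spec.handedness_sd, size=n), -100.0, 100.0
    )

    # voxel tuning: latent normals correlated across categories per overlap
    ov_factor = _psd_factor(spec.overlap)
    latent = rng.standard_normal((n, v, k)) @ ov_factor.T  # (n, v, k)
    base_left = _lognormal_from_latent(
        np.transpose(latent, (0, 2, 1)), spec.amplitude_mean, spec.tuning_log_sd
    )  # (n, k, v)
    base_right = base_left.copy()
    shared_base_left = _lognormal_from_latent(
        rng.standard_normal((n, v)), 1.0, spec.tuning_log_sd
    )
    shared_base_right = shared_base_left.copy()
    if spec.pattern_asymmetry > 0:
        s = spec.pattern_asymmetry
        base_right = base_right * np.exp(
            s * rng.standard_normal(base_right.shape) - 0.5 * s**2
        )
        shared_base_right = shared_base_right * np.exp(
            s * rng.standard_normal(shared_base_right.shape) - 0.5 * s**2
        )

    g_l, g_r = _hemisphere_gains(base_left, base_right, true_li)
    amplitudes = np.concatenate(
        [base_left * g_l[..., None], base_right * g_r[..., None]], axis=-1
    )

    sg_l, sg_r = _hemisphere_gains(shared_base_left, shared_base_right, shared_li)
    shared_maps = spec.shared_activation_amplitude * np.concatenate(
        [shared_base_left * sg_l[:, None], shared_base_right * sg_r[:, None]], axis=-1
    )

    ids = [f"sub-{i + 1:03d}" for i in range(n)]
    return Cohort(
        spec=spec, amplitudes=amplitudes, shared_maps=shared_maps,
        true_li=true_li, shared_li=shared_li, handedness=handedness, subject_ids=ids,
    )
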