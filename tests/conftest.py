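"""Shared fixtures: small cohorts fitted once per session."""

import numpy as np
import pytest

from hemilat.design import AcquisitionSpec
from hemilat.pipeline import fit_cohort, simulate_li_table
from hemilat.population import PopulationSpec, sample_population


@pytest.fixture(scope="session")
def zero_noise_20():
    """20-subject noiseless cohort (arousal off) with its LI table."""
    spec = PopulationSpec(
        n_subjects=20, noise_sd=0.0, shared_activation_amplitude=0.0
    )
    table, cohort = simulate_li_table(
        spec, seed=11, baselines=("fixation",), metrics=("summed", "peak")
    )
    return table, cohort


@pytest.fixture(scope="session")
def small_fit():
    """Small noisy cohort fitted once (8 subjects, 16 voxels/hemisphere)."""
    spec = PopulationSpec(n_subjects=8, n_voxels_per_hemisphere=16)
    rng = np.random.default_rng(3)
    cohort = sample_population(spec, rng)
    return fit_cohort(cohort, seed=rng)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
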