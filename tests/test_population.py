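import numpy as np
import pytest

from hemilat.population import (
    DEFAULT_CATEGORIES,
    PopulationSpec,
    sample_population,
)


def test_copula_identity_correlation():
    spec = PopulationSpec(n_subjects=2000, n_voxels_per_hemisphere=4)
    cohort = sample_population(spec, 0)
    corr = np.corrcoef(cohort.true_li.T)
    off = corr[~np.eye(corr.shape[0], dtype=bool)]
    assert np.abs(off).max() < 0.07  # identity target, SE ~ 1/sqrt(2000)


def test_copula_hits_target_correlation():
    k = len(DEFAULT_CATEGORIES)
    target = np.eye(k)
    target[0, 1] = target[1, 0] = 0.7
    spec = PopulationSpec(
        n_subjects=2000, n_voxels_per_hemisphere=4, li_correlation=target
    )
    cohort = sample_population(spec, 1)
    r = np.corrcoef(cohort.true_li[:, 0], cohort.true_li[:, 1])[0, 1]
    assert r == pytest.approx(0.7, abs=0.1)


def test_degenerate_sd_gives_exact_means():
    spec = PopulationSpec(n_subjects=5, n_voxels_per_hemisphere=4, true_li_sd=0.0)
    cohort = sample_population(spec, 2)
    assert np.allclose(cohort.true_li, spec.true_li_means[None, :])


def test_amplitude_li_matches_drawn_truth_exactly():
    spec = PopulationSpec(n_subjects=10, n_voxels_per_hemisphere=12)
    cohort = sample_population(spec, 3)
    for subj in cohort.subjects:
        assert np.allclose(subj.amplitude_li(), subj.true_li, atol=1e-10)


def test_shared_map_laterality_matches_shared_li():
    spec = PopulationSpec(n_subjects=10, n_voxels_per_hemisphere=12)
    cohort = sample_population(spec, 4)
    v = spec.n_voxels_per_hemisphere
    s_l = cohort.shared_maps[:, :v].sum(axis=1)
    s_r = cohort.shared_maps[:, v:].sum(axis=1)
    li = (s_l - s_r) / (s_l + s_r)
    assert np.allclose(li, cohort.shared_li, atol=1e-10)


def test_overlap_one_ties_tuning_patterns():
    spec = PopulationSpec(n_subjects=3, n_voxels_per_hemisphere=20, overlap=1.0)
    cohort = sample_population(spec, 5)
    v = spec.n_voxels_per_hemisphere
    for i in range(cohort.n_subjects):
        left = cohort.amplitudes[i, :, :v]
        # with overlap 1 every category map is a positive multiple of a
        # single shared pattern: pairwise voxel ratios are constant
        for c in range(1, left.shape[0]):
            ratio = left[c] / left[0]
            assert np.allclose(ratio, ratio[0], atol=1e-8)


def test_overlap_raises_map_correlation():
    def mean_pair_corr(overlap, seed):
        spec = PopulationSpec(
            n_subjects=2, n_voxels_per_hemisphere=400, overlap=overlap
        )
        cohort = sample_population(spec, seed)
        v = spec.n_voxels_per_hemisphere
        left = cohort.amplitudes[0, :, :v]
        c = np.corrcoef(left)
        return c[~np.eye(c.shape[0], dtype=bool)].mean()

    assert mean_pair_corr(0.0, 6) < 0.2 < mean_pair_corr(0.8, 6)


def test_mirror_hemispheres_homotopic():
    spec = PopulationSpec(n_subjects=2, n_voxels_per_hemisphere=10)
    cohort = sample_population(spec, 7)
    v = spec.n_voxels_per_hemisphere
    left = cohort.amplitudes[:, :, :v]
    right = cohort.amplitudes[:, :, v:]
    # right is a scaled mirror copy: per-voxel ratio constant per category
    ratio = right / left
    assert np.allclose(ratio, ratio[..., :1], atol=1e-10)


def test_psd_rejection_names_eigenvalue():
    k = len(DEFAULT_CATEGORIES)
    bad = np.full((k, k), 0.9)
    np.fill_diagonal(bad, 1.0)
    bad[0, 1] = bad[1, 0] = -0.9  # not PSD
    with pytest.raises(ValueError, match="eigenvalue"):
        PopulationSpec(li_correlation=bad)


def test_validation_errors():
    with pytest.raises(ValueError):
        PopulationSpec(n_subjects=1)
    with pytest.raises(ValueError, match="symmetric"):
        k = len(DEFAULT_CATEGORIES)
        m = np.eye(k)
        m[0, 1] = 0.5
        PopulationSpec(li_correlation=m)
    with pytest.raises(ValueError, match="diagonal"):
        k = len(DEFAULT_CATEGORIES)
        PopulationSpec(li_correlation=0.5 * np.eye(k))
    with pytest.raises(ValueError, match="overlap"):
        PopulationSpec(overlap=1.5)
    with pytest.raises(ValueError, match="li_means"):
        PopulationSpec(true_li_means=np.array([1.0, 0, 0, 0, 0, 0]))
    with pytest.raises(ValueError, match="noise_sd"):
        PopulationSpec(noise_sd=-1.0)
    with pytest.raises(ValueError, match="shared_activation"):
        PopulationSpec(shared_activation_amplitude=-0.1)


def test_handedness_clipped_and_shaped():
    spec = PopulationSpec(n_subjects=500, n_voxels_per_hemisphere=4)
    cohort = sample_population(spec, 8)
    assert cohort.handedness.min() >= -100.0
    assert cohort.handedness.max() <= 100.0
    assert cohort.handedness.shape == (500,)


def test_sampling_deterministic():
    spec = PopulationSpec(n_subjects=4, n_voxels_per_hemisphere=6)
    c1 = sample_population(spec, 9)
    c2 = sample_population(spec, 9)
    assert np.array_equal(c1.amplitudes, c2.amplitudes)
    assert np.array_equal(c1.true_li, c2.true_li)
    assert c1.subject_ids == c2.subject_ids


def test_true_li_frame_shape():
    spec = PopulationSpec(n_subjects=3, n_voxels_per_hemisphere=4)
    cohort = sample_population(spec, 10)
    frame = cohort.true_li_frame()
    assert len(frame) == 3 * len(DEFAULT_CATEGORIES)
    assert set(frame.columns) >= {"subject_id", "category", "true_li", "handedness"}
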