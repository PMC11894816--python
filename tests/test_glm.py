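import numpy as np
import pytest

from hemilat.design import AcquisitionSpec, Block, StimulusDesign, build_block_design
from hemilat.glm import (
    DesignMatrix,
    HRFParams,
    StatMap,
    build_design_matrix,
    canonical_hrf,
    condition_regressors,
    contrast_stat_map,
    fit_glm,
    omnibus_contrast,
)


def _manual_design(X):
    X = np.asarray(X, dtype=float)
    return DesignMatrix(
        X=X,
        labels=[f"col{i}" for i in range(X.shape[1])],
        task_index={},
        run_slices=[slice(0, X.shape[0])],
        tr=2.0,
    )


# ------------------------------------------------------------------ HRF

def test_hrf_unit_peak_and_timing():
    dt = 0.1
    h = canonical_hrf(dt)
    assert h.max() == pytest.approx(1.0)
    peak_time = np.argmax(h) * dt
    assert 4.5 <= peak_time <= 6.5
    assert len(h) == int(HRFParams().duration / dt)
    # undershoot: a negative lobe after the peak
    assert h.min() < 0


def test_hrf_rejects_bad_dt():
    with pytest.raises(ValueError):
        canonical_hrf(0.0)


def test_condition_regressor_plateau_and_absent_condition():
    blocks = [Block("a", 10.0, 30.0)]
    tr = 2.0
    reg = condition_regressors(blocks, ["a", "b"], 40, tr)
    assert np.allclose(reg[:, 1], 0.0)  # absent condition -> zero column
    # a long block's response tops out at the maximum cumulative HRF
    # integral (the undershoot has not yet subtracted at that point)
    h = canonical_hrf(0.1)
    peak_area = (np.cumsum(h) * 0.1).max()
    assert reg[:, 0].max() == pytest.approx(peak_area, rel=0.05)


def test_condition_regressors_reject_overlap():
    blocks = [Block("a", 10.0, 6.0), Block("a", 12.0, 6.0)]
    with pytest.raises(ValueError, match="overlap"):
        condition_regressors(blocks, ["a"], 30, 2.0)


# ------------------------------------------------------- design matrix

def test_design_matrix_columns_and_nuisance():
    acq = AcquisitionSpec(n_runs=2)
    conds = ["a", "b", "c"]
    design = build_block_design(acq, conds, seed=0)
    total_tp = sum(acq.n_timepoints(len(run)) for run in design.runs)
    nuisance = np.random.default_rng(1).standard_normal((total_tp, 13))
    dm = build_design_matrix(design, acq, conds, nuisance=nuisance)
    # 3 conditions x 2 runs task + 2 run means + 13 nuisance
    assert dm.n_regressors == 3 * 2 + 2 + 13
    assert sum(lab.startswith("nuisance_") for lab in dm.labels) == 13
    # nuisance mean-centered within each run
    for sl in dm.run_slices:
        assert np.allclose(dm.X[sl, -13:].mean(axis=0), 0.0, atol=1e-12)
    # run-mean columns are disjoint indicators
    mean_cols = [dm.column(f"mean_run{r}") for r in (1, 2)]
    assert np.allclose(dm.X[:, mean_cols].sum(axis=1), 1.0)


def test_design_matrix_rejects_nuisance_length():
    acq = AcquisitionSpec(n_runs=1)
    design = build_block_design(acq, ["a", "b"], seed=0)
    with pytest.raises(ValueError, match="timepoints"):
        build_design_matrix(design, acq, ["a", "b"], nuisance=np.zeros((5, 2)))


def test_design_matrix_excludes_rest_column():
    acq = AcquisitionSpec(n_runs=1)
    design = build_block_design(acq, ["a", "b"], seed=0)
    dm = build_design_matrix(design, acq, ["a", "b", "rest"])
    assert not any("rest" in lab for lab in dm.labels)


# ---------------------------------------------------------------- OLS

def test_noiseless_recovery():
    acq = AcquisitionSpec(n_runs=2)
    conds = ["a", "b"]
    design = build_block_design(acq, conds, seed=2)
    dm = build_design_matrix(design, acq, conds)
    true = np.zeros((dm.n_regressors, 3))
    for (cond, run), idx in dm.task_index.items():
        true[idx] = [1.0, 2.5, -0.5]
    y = dm.X @ true
    est = fit_glm(y, dm)
    assert np.allclose(est.betas, true, atol=1e-6)
    assert np.all(est.sigma2 < 1e-12)


def test_linearity_in_data():
    X = np.random.default_rng(5).standard_normal((30, 4))
    dm = _manual_design(X)
    y1 = np.random.default_rng(6).standard_normal((30, 2))
    y2 = np.random.default_rng(7).standard_normal((30, 2))
    b1 = fit_glm(y1, dm).betas
    b2 = fit_glm(y2, dm).betas
    b = fit_glm(2.0 * y1 + 3.0 * y2, dm).betas
    assert np.allclose(b, 2.0 * b1 + 3.0 * b2, atol=1e-10)


def test_hand_computed_t():
    # intercept-only model: y = [1..5], beta = 3, sigma2 = 2.5,
    # t = 3 / sqrt(2.5 / 5) = 4.2426...
    dm = _manual_design(np.ones((5, 1)))
    est = fit_glm(np.array([1.0, 2.0, 3.0, 4.0, 5.0]), dm)
    assert est.betas[0, 0] == pytest.approx(3.0)
    assert est.sigma2[0] == pytest.approx(2.5)
    assert est.df == 4
    t = contrast_stat_map(est, np.array([1.0])).data[0]
    assert t == pytest.approx(3.0 / np.sqrt(2.5 / 5.0), abs=1e-12)


def test_rank_deficient_names_columns():
    X = np.ones((10, 2))  # duplicate columns
    dm = _manual_design(X)
    with pytest.raises(ValueError, match="col"):
        fit_glm(np.zeros(10), dm)


def test_nan_series_rejected():
    dm = _manual_design(np.ones((5, 1)))
    y = np.array([1.0, np.nan, 3.0, 4.0, 5.0])
    with pytest.raises(ValueError, match="NaN"):
        fit_glm(y, dm)


def test_unknown_whitening_rejected():
    dm = _manual_design(np.ones((5, 1)))
    with pytest.raises(ValueError, match="whitening"):
        fit_glm(np.zeros(5), dm, whitening="arma")


def test_ar1_null_coefficient_near_zero(rng):
    # white-noise data -> AR(1) coefficient estimate within +-0.05 of 0
    X = np.column_stack([np.ones(500), rng.standard_normal(500)])
    dm = _manual_design(X)
    est = fit_glm(rng.standard_normal((500, 20)), dm, whitening="ar1")
    assert abs(est.ar_coefficient) < 0.05


def test_ar1_recovers_positive_coefficient(rng):
    from hemilat.timeseries import ar1_noise

    X = np.ones((800, 1))
    dm = _manual_design(X)
    noise = ar1_noise(rng, (800, 30), sd=1.0, rho=0.4)
    est = fit_glm(noise, dm, whitening="ar1")
    assert est.ar_coefficient == pytest.approx(0.4, abs=0.08)


# ----------------------------------------------------------- contrasts

def test_contrast_dict_and_errors():
    acq = AcquisitionSpec(n_runs=1)
    design = build_block_design(acq, ["a", "b"], seed=0)
    dm = build_design_matrix(design, acq, ["a", "b"])
    est = fit_glm(np.random.default_rng(0).standard_normal((dm.n_timepoints, 2)), dm)
    smap = contrast_stat_map(est, {("a", 1): 1.0, ("b", 1): -1.0})
    assert smap.kind == "t" and smap.data.shape == (2,)
    with pytest.raises(KeyError):
        contrast_stat_map(est, {("missing", 1): 1.0})
    with pytest.raises(ValueError, match="length"):
        contrast_stat_map(est, np.ones(dm.n_regressors + 1))


def test_omnibus_contrast_balanced():
    d = omnibus_contrast(None, ["a", "b"], [1, 2])
    assert sum(d.values()) == pytest.approx(1.0)
    assert all(v == pytest.approx(0.25) for v in d.values())


def test_statmap_kind_validation():
    with pytest.raises(ValueError, match="kind"):
        StatMap(data=np.zeros(3), df=10, kind="z")
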