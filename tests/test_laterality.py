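import numpy as np
import pandas as pd
import pytest

from hemilat.glm import StatMap
from hemilat.laterality import (
    correlate,
    dice_overlap,
    flag_rightward_text,
    handedness_sweep,
    independent_task_contrast,
    laterality_index,
    pairwise_li_correlation,
    residualize_li,
    residualized_correlation,
    selective_mask,
    split_half_reliability,
)


def _table(rows):
    base = {"metric": "summed", "heldout": ""}
    return pd.DataFrame([{**base, **r} for r in rows])


def _li_rows(category, baseline, run_split, lis, **extra):
    return [
        {"subject_id": f"s{i}", "category": category, "baseline": baseline,
         "run_split": run_split, "li": li, **extra}
        for i, li in enumerate(lis)
    ]


# -------------------------------------------------------------- algebra

def test_li_values_and_nan():
    assert laterality_index(3.0, 1.0) == pytest.approx(0.5)
    assert laterality_index(2.0, 2.0) == pytest.approx(0.0)
    assert laterality_index(0.0, 4.0) == pytest.approx(-1.0)
    assert np.isnan(laterality_index(0.0, 0.0))
    arr = laterality_index([3.0, 0.0], [1.0, 0.0])
    assert arr[0] == pytest.approx(0.5) and np.isnan(arr[1])


def test_li_rejects_negative():
    with pytest.raises(ValueError, match="nonnegative"):
        laterality_index(-1.0, 2.0)


# ------------------------------------------------------------ correlate

def test_correlate_excludes_nan_pairs(rng):
    x = rng.standard_normal(50)
    y = x + 0.1 * rng.standard_normal(50)
    x[0] = np.nan
    res = correlate(x, y)
    assert res.n == 49 and res.n_excluded == 1
    assert res.r > 0.9


def test_correlate_errors(rng):
    with pytest.raises(ValueError, match="length"):
        correlate(np.zeros(3), np.zeros(4))
    with pytest.raises(ValueError, match="3 complete"):
        correlate(np.array([1.0, np.nan, 2.0]), np.array([1.0, 2.0, 3.0]))
    with pytest.raises(ValueError, match="method"):
        correlate(rng.standard_normal(5), rng.standard_normal(5), method="kendall")


# --------------------------------------------------------- residualize

def test_residualize_orthogonal(rng):
    cov = rng.standard_normal(100)
    target = 0.7 * cov + rng.standard_normal(100)
    resid = residualize_li(target, cov)
    assert abs(np.corrcoef(resid, cov)[0, 1]) < 1e-10
    assert resid.mean() == pytest.approx(0.0, abs=1e-10)


def test_residualize_errors():
    with pytest.raises(ValueError, match="matched"):
        residualize_li(np.zeros(4), np.zeros(5))
    with pytest.raises(ValueError, match="variance"):
        residualize_li(np.arange(5.0), np.ones(5))


def test_residualized_correlation_removes_shared_factor(rng):
    shared = rng.standard_normal(300)
    a = shared + 0.3 * rng.standard_normal(300)
    b = shared + 0.3 * rng.standard_normal(300)
    raw = correlate(a, b).r
    resid = residualized_correlation(a, b, shared, shared).r
    assert raw > 0.8
    assert abs(resid) < 0.15


# ----------------------------------------------------- table selection

def test_pairwise_li_correlation_on_constructed_table(rng):
    li = rng.uniform(-0.5, 0.5, 30)
    rows = _li_rows("faces", "full", "odd", li) + _li_rows(
        "text", "full", "even", li + 0.05 * rng.standard_normal(30)
    )
    res = pairwise_li_correlation(_table(rows), "faces", "text", baseline="full")
    assert res.r > 0.9 and res.n == 30


def test_pairwise_heldout_inferred_and_filtered(rng):
    li = rng.uniform(-0.5, 0.5, 20)
    rows = (
        _li_rows("faces", "heldout", "odd", li, heldout="objects")
        + _li_rows("faces", "heldout", "odd", -li, heldout="text")
        + _li_rows("text", "heldout", "even", li, heldout="objects")
        + _li_rows("text", "heldout", "even", -li, heldout="faces")
    )
    # faces vs text -> held-out category is objects on both sides
    res = pairwise_li_correlation(_table(rows), "faces", "text", baseline="heldout")
    assert res.r > 0.99


def test_pairwise_same_category_rejected():
    with pytest.raises(ValueError, match="differ"):
        pairwise_li_correlation(_table([]), "faces", "faces")


def test_select_li_missing_and_ambiguous(rng):
    rows = _li_rows("faces", "full", "odd", rng.uniform(-1, 1, 5))
    with pytest.raises(ValueError, match="no LI rows"):
        pairwise_li_correlation(_table(rows), "faces", "text", baseline="full")
    dup = rows + rows  # two rows per subject, same labels
    tab = _table(dup + _li_rows("text", "full", "even", rng.uniform(-1, 1, 5)))
    with pytest.raises(ValueError, match="ambiguous"):
        pairwise_li_correlation(tab, "faces", "text", baseline="full")


def test_split_half_reliability_perfect():
    li = np.linspace(-0.5, 0.5, 10)
    rows = _li_rows("faces", "full", "odd", li) + _li_rows("faces", "full", "even", li)
    res = split_half_reliability(_table(rows), "faces")
    assert res.method == "spearman"
    assert res.r == pytest.approx(1.0)


# ----------------------------------------------------------------- dice

def test_dice_cases():
    a = np.array([True, True, False, False])
    assert dice_overlap(a, a) == pytest.approx(1.0)
    assert dice_overlap(a, ~a) == pytest.approx(0.0)
    b = np.array([True, False, False, False])
    assert dice_overlap(a, b) == pytest.approx(2 * 1 / (2 + 1))
    half = np.array([True, True, True, True])
    quarter = np.array([True, False, True, False])
    assert dice_overlap(half, quarter) == pytest.approx(2 * 2 / (4 + 2))
    assert dice_overlap(np.zeros(4, bool), np.zeros(4, bool)) == 0.0
    with pytest.raises(ValueError, match="voxel"):
        dice_overlap(np.zeros(4, bool), np.zeros(5, bool))


def test_selective_mask_kinds():
    from scipy import stats as sps

    df = 30
    thr = sps.t.ppf(0.999, df)
    tmap = StatMap(data=np.array([thr + 0.1, thr - 0.1]), df=df)
    assert selective_mask(tmap).tolist() == [True, False]
    emap = StatMap(data=np.array([0.2, -0.2]), df=0, kind="effect")
    assert selective_mask(emap).tolist() == [True, False]


# ----------------------------------------------------------- handedness

def test_handedness_sweep_nested_and_small_n(rng):
    n = 60
    li_a = rng.standard_normal(n)
    li_b = rng.standard_normal(n)
    hand = rng.uniform(-100, 100, n)
    sweep = handedness_sweep(li_a, li_b, hand)
    assert sweep["threshold"].iloc[0] == -100.0
    # retained sample sizes are nonincreasing in the threshold
    assert (np.diff(sweep["n"].to_numpy()) <= 0).all()
    assert sweep["n"].iloc[0] == n
    # thresholds retaining < 3 subjects yield NaN rather than an error
    tight = handedness_sweep(li_a[:3], li_b[:3], np.array([0.0, 0.0, 0.0]),
                             thresholds=[50.0])
    assert np.isnan(tight["r"].iloc[0])


def test_handedness_sweep_partial(rng):
    n = 80
    hand = rng.uniform(-100, 100, n)
    li_a = 0.01 * hand + 0.1 * rng.standard_normal(n)
    li_b = 0.01 * hand + 0.1 * rng.standard_normal(n)
    raw = handedness_sweep(li_a, li_b, hand, thresholds=[-100.0])
    partial = handedness_sweep(li_a, li_b, hand, thresholds=[-100.0],
                               partial_handedness=True)
    assert partial["r"].iloc[0] < raw["r"].iloc[0]


# --------------------------------------------------- independent tasks

def test_independent_task_contrast_algebra():
    a = StatMap(data=np.array([3.0, 1.0]), df=10, name="bodies")
    b = StatMap(data=np.array([1.0, 2.0]), df=10, name="places")
    diff = independent_task_contrast(a, b)
    assert np.allclose(diff.data, [2.0, -1.0])
    anti = independent_task_contrast(b, a)
    assert np.allclose(diff.data, -anti.data)
    with pytest.raises(ValueError, match="voxel"):
        independent_task_contrast(a, StatMap(data=np.zeros(3), df=10))
    with pytest.raises(ValueError, match="mix"):
        independent_task_contrast(a, StatMap(data=np.zeros(2), df=0, kind="effect"))


def test_flag_rightward_text():
    rows = _li_rows("text", "full", "all", [-0.6, -0.2, 0.3])
    flags = flag_rightward_text(_table(rows))
    assert flags.tolist() == [True, False, False]
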