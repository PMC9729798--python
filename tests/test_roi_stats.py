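import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dietmri import (
    ParamMap,
    build_roi_table,
    filter_map_values,
    iqr_fences,
    make_roi_masks,
    remove_outliers_iqr,
    roi_mean,
)
from dietmri.roi_stats import ROITemplate


# --- template masks -------------------------------------------------------


def test_template_voxel_counts(roi_masks):
    counts = {r: int(m.sum()) for r, m in roi_masks.items()}
    assert counts == {"hypothalamus": 70, "hippocampus": 60, "NAc": 80, "ILA": 20}


def test_masks_pairwise_disjoint(roi_masks):
    stack = np.stack(list(roi_masks.values()))
    assert stack.sum(axis=0).max() == 1


def test_masks_deterministic(roi_masks):
    again = make_roi_masks()
    for r in roi_masks:
        assert np.array_equal(roi_masks[r], again[r])


def test_geometry_too_small():
    with pytest.raises(ValueError):
        make_roi_masks(ROITemplate(), matrix=16)


# --- retention filters ----------------------------------------------------


def test_t2_filter_strict_bounds():
    assert filter_map_values(np.array([25.0, 45.0, 85.0]), "T2").tolist() == [45.0]
    # boundary values are excluded (strict inequalities)
    assert filter_map_values(np.array([30.0, 80.0]), "T2").size == 0


def test_adc_filter_strict_bounds():
    out = filter_map_values(np.array([-50.0, 600.0, 1300.0]), "ADC")
    assert out.tolist() == [600.0]
    assert filter_map_values(np.array([0.0, 1200.0]), "ADC").size == 0


def test_mtr_filter_positive_only():
    out = filter_map_values(np.array([-10.0, 0.0, 5.0]), "MTR")
    assert out.tolist() == [5.0]


def test_filter_empty_input():
    assert filter_map_values(np.array([]), "T2").size == 0


def test_filter_unknown_parameter():
    with pytest.raises(ValueError):
        filter_map_values(np.array([1.0]), "FA")


@settings(deadline=None, max_examples=50)
@given(st.lists(st.floats(allow_nan=False, allow_infinity=False, width=32), max_size=30))
def test_filter_idempotent(values):
    arr = np.array(values, dtype=float)
    once = filter_map_values(arr, "T2")
    twice = filter_map_values(once, "T2")
    assert np.array_equal(once, twice)


# --- IQR outlier rule -----------------------------------------------------


def test_iqr_worked_example():
    vals = np.array([10.0, 11.0, 12.0, 13.0, 100.0])
    lo, hi = iqr_fences(vals)
    assert (lo, hi) == (8.0, 16.0)  # Q1=11, Q3=13 under linear interpolation
    df = pd.DataFrame(dict(diet="SD", day=0, region="ILA", value=vals))
    out = remove_outliers_iqr(df)
    assert sorted(out["value"]) == [10.0, 11.0, 12.0, 13.0]


def test_iqr_all_equal_removes_nothing():
    df = pd.DataFrame(dict(diet="SD", day=0, region="ILA", value=[5.0] * 6))
    assert len(remove_outliers_iqr(df)) == 6


def test_iqr_small_group_skipped():
    df = pd.DataFrame(dict(diet="SD", day=0, region="ILA", value=[1.0, 2.0, 100.0]))
    assert len(remove_outliers_iqr(df)) == 3


def test_iqr_idempotent_on_own_output(rng):
    vals = np.concatenate([rng.normal(50, 2, 20), [500.0]])
    df = pd.DataFrame(dict(diet="SD", day=0, region="ILA", value=vals))
    once = remove_outliers_iqr(df)
    twice = remove_outliers_iqr(once)
    assert once["value"].tolist() == twice["value"].tolist()


def test_iqr_grouping_is_respected():
    # the aberrant value sits in its own group and must survive there
    df = pd.DataFrame(
        dict(
            diet=["SD"] * 5 + ["HFD"],
            day=0,
            region="ILA",
            value=[10.0, 11.0, 12.0, 13.0, 100.0, 100.0],
        )
    )
    out = remove_outliers_iqr(df)
    assert out.loc[out.diet == "HFD", "value"].tolist() == [100.0]
    assert 100.0 not in out.loc[out.diet == "SD", "value"].tolist()


# --- roi_mean -------------------------------------------------------------


def _uniform_map(value, shape=(16, 16), name="T2", valid=True):
    vals = np.full(shape, float(value))
    return ParamMap(name, vals, np.full(shape, valid), "ms")


def test_roi_mean_constant_field():
    mask = np.zeros((16, 16), bool)
    mask[2:9, 2:12] = True  # 70 voxels
    rm = roi_mean(_uniform_map(45.0), mask)
    assert rm.value == 45.0
    assert rm.n_voxels_used == 70


def test_roi_mean_excludes_csf_voxels():
    vals = np.full((16, 16), 45.0)
    vals[0:2] = 150.0  # CSF-like T2, outside the 30-80 ms window
    pmap = ParamMap("T2", vals, np.ones((16, 16), bool), "ms")
    mask = np.zeros((16, 16), bool)
    mask[0:4] = True
    rm = roi_mean(pmap, mask)
    assert rm.value == pytest.approx(45.0)
    assert rm.n_voxels_used == 32


def test_roi_mean_all_invalid_gives_missing():
    rm = roi_mean(_uniform_map(45.0, valid=False), np.ones((16, 16), bool))
    assert rm.value is None
    assert rm.reason == "no_valid_voxels"


def test_roi_mean_permutation_invariant(rng):
    vals = rng.uniform(40, 70, (16, 16))
    pmap = ParamMap("T2", vals, np.ones((16, 16), bool), "ms")
    mask = rng.random((16, 16)) < 0.4
    base = roi_mean(pmap, mask)
    perm = rng.permutation(16)
    pmap2 = ParamMap("T2", vals[perm], np.ones((16, 16), bool), "ms")
    assert roi_mean(pmap2, mask[perm]).value == pytest.approx(base.value)


# --- build_roi_table ------------------------------------------------------


def _entry(animal, day, value, masks, diet="SD"):
    shape = next(iter(masks.values())).shape
    return dict(
        animal_id=animal,
        sex="male",
        diet=diet,
        day=day,
        maps={"T2": _uniform_map(value, shape)},
    )


def test_build_roi_table_counting(roi_masks):
    entries = [
        _entry("a1", 0, 45.0, roi_masks),
        _entry("a1", 7, 46.0, roi_masks),
        _entry("a2", 0, 45.5, roi_masks),
        _entry("a2", 7, 46.5, roi_masks),
    ]
    table = build_roi_table(entries, roi_masks, apply_outlier_rule=False)
    assert len(table) == 2 * 2 * 4  # animals x days x regions, 1 parameter


def test_build_roi_table_drops_aberrant_animal(roi_masks):
    values = [45.0, 45.5, 46.0, 46.5, 200.0]
    entries = [_entry(f"a{i}", 0, v, roi_masks) for i, v in enumerate(values)]
    table = build_roi_table(entries, roi_masks)
    assert "a4" not in table["animal_id"].tolist()
    assert len(table) == 4 * 4


def test_build_roi_table_duplicate_key_raises(roi_masks):
    entries = [_entry("a1", 0, 45.0, roi_masks), _entry("a1", 0, 45.0, roi_masks)]
    with pytest.raises(ValueError):
        build_roi_table(entries, roi_masks)


def test_roi_table_csv_roundtrip(tmp_path, roi_masks):
    entries = [_entry("a1", 0, 45.0, roi_masks), _entry("a2", 0, 46.0, roi_masks)]
    table = build_roi_table(entries, roi_masks, apply_outlier_rule=False)
    path = tmp_path / "roi.csv"
    table.to_csv(path, index=False)
    back = pd.read_csv(path)
    pd.testing.assert_frame_equal(table, back, check_dtype=False)
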