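"""Integrated gradients, heatmap normalization, stripe region, selection."""
import math

import numpy as np
import pandas as pd
import pytest

from slidescape.attribution import (AttributionMap, SelectionConfig,
                                    aggregate_patient_score, form_groups,
                                    integrated_gradients,
                                    select_explanatory_patches,
                                    slide_normalize, tumor_stripe_region)
from slidescape.core_io import Patch, RegionMask, SlideGeometry, tile_slide

# ---------------------------------------------------------------------------
# integrated gradients


def test_ig_linear_scorer_closed_form(rng):
    w = rng.normal(size=6)
    x = rng.normal(size=6)
    res = integrated_gradients(lambda v: float(w @ v) + 3.0, x, steps=8)
    np.testing.assert_allclose(res.attributions, w * x, rtol=1e-9, atol=1e-9)
    assert res.completeness_gap < 1e-9


def test_ig_zero_at_baseline(rng):
    x = rng.normal(size=4)
    res = integrated_gradients(lambda v: float((v**2).sum()), x, baseline=x)
    np.testing.assert_array_equal(res.attributions, np.zeros(4))


def test_ig_quadratic_completeness(rng):
    A = rng.normal(size=(5, 5))
    A = A + A.T
    b = rng.normal(size=5)
    x = rng.normal(size=5)

    def f(v):
        return float(0.5 * v @ A @ v + b @ v)

    res = integrated_gradients(f, x, steps=512)
    rel = res.completeness_gap / abs(res.score_input - res.score_baseline)
    assert rel < 1e-3


def test_ig_error_decreases_as_steps_double(rng):
    """Midpoint-rule error is O(1/m²) for smooth non-polynomial scorers."""
    x = np.array([1.3, -0.7, 0.4])

    def f(v):
        return float(np.exp(v).sum())

    gaps = [integrated_gradients(f, x, steps=m).completeness_gap
            for m in (8, 16, 32, 64)]
    assert all(g2 < g1 for g1, g2 in zip(gaps, gaps[1:]))


def test_ig_supports_analytic_gradient(rng):
    w = rng.normal(size=4)
    x = rng.normal(size=4)
    res = integrated_gradients(lambda v: float(w @ v), x,
                               grad=lambda v: w, steps=16)
    np.testing.assert_allclose(res.attributions, w * x, rtol=1e-12)


def test_ig_rejects_few_steps():
    with pytest.raises(ValueError):
        integrated_gradients(lambda v: 0.0, np.ones(2), steps=4)


# ---------------------------------------------------------------------------
# normalization


def test_slide_normalize_examples():
    amap = AttributionMap("s", {(0, 0): -2.0, (0, 1): 0.0, (0, 2): 2.0})
    out = slide_normalize(amap)
    assert out.scores == {(0, 0): 0.0, (0, 1): 0.5, (0, 2): 1.0}
    assert out.normalization == "slide_minmax"


def test_slide_normalize_constant_convention():
    out = slide_normalize(AttributionMap("s", {(0, 0): 3.0, (0, 1): 3.0}))
    assert set(out.scores.values()) == {0.5}


def test_slide_normalize_idempotent(rng):
    amap = AttributionMap("s", {(0, i): float(v)
                                for i, v in enumerate(rng.normal(size=9))})
    once = slide_normalize(amap)
    twice = slide_normalize(once)
    assert once.scores == pytest.approx(twice.scores)


def test_attribution_map_csv_roundtrip(tmp_path, rng):
    amap = AttributionMap("s1", {(r, c): float(rng.normal())
                                 for r in range(3) for c in range(4)})
    amap.write_csv(tmp_path / "a.csv")
    back = AttributionMap.read_csv(tmp_path / "a.csv")
    assert back.slide_id == "s1"
    assert back.scores == pytest.approx(amap.scores)


# ---------------------------------------------------------------------------
# tumor stripe region


def test_stripe_zero_width_is_identity(rng):
    grid = rng.random((20, 20)) < 0.3
    mask = RegionMask(grid, 8, "tumor")
    out = tumor_stripe_region(mask, 0.0, mpp=0.5)
    np.testing.assert_array_equal(out.grid, grid)


def test_stripe_single_cell_disk():
    """radius-2 dilation of one cell = the 13-cell Euclidean disk."""
    grid = np.zeros((9, 9), bool)
    grid[4, 4] = True
    mask = RegionMask(grid, 8, "tumor")
    out = tumor_stripe_region(mask, stripe_width_um=8.0, mpp=0.5)  # r = 2
    assert out.grid.sum() == 13
    ii, jj = np.nonzero(out.grid)
    assert all((i - 4) ** 2 + (j - 4) ** 2 <= 4 for i, j in zip(ii, jj))


def test_stripe_monotone_in_width(rng):
    grid = np.zeros((30, 30), bool)
    grid[12:18, 12:18] = True
    mask = RegionMask(grid, 8, "tumor")
    r400 = tumor_stripe_region(mask, 400.0, mpp=0.5)
    r800 = tumor_stripe_region(mask, 800.0, mpp=0.5)
    assert (r800.grid | r400.grid).sum() == r800.grid.sum()


def test_stripe_empty_mask_warns():
    mask = RegionMask(np.zeros((5, 5), bool), 8, "tumor")
    with pytest.warns(UserWarning, match="empty"):
        out = tumor_stripe_region(mask, 800.0, mpp=0.5)
    assert not out.grid.any()


# ---------------------------------------------------------------------------
# selection


def _full_region(n_rows, n_cols, patch=256):
    return RegionMask(np.ones((n_rows, n_cols), bool), patch, "tumor")


def _distinct_map(n_rows, n_cols, rng):
    scores = rng.permutation(n_rows * n_cols) + 1.0  # positive, distinct
    return AttributionMap("s", {(r, c): float(scores[r * n_cols + c])
                                for r in range(n_rows) for c in range(n_cols)})


def test_selection_cap_at_200(rng):
    geom = SlideGeometry("s", 60 * 256, 50 * 256)
    patches = tile_slide(geom)
    assert len(patches) == 3000
    amap = _distinct_map(50, 60, rng)
    sel = select_explanatory_patches(amap, patches, _full_region(50, 60))
    assert len(sel) == 200  # ceil(0.1·3000)=300, capped at 200
    assert sel["score"].min() > sorted(amap.scores.values())[-201]


def test_selection_top_fraction_below_cap(rng):
    geom = SlideGeometry("s", 10 * 256, 5 * 256)
    patches = tile_slide(geom)
    amap = _distinct_map(5, 10, rng)
    sel = select_explanatory_patches(amap, patches, _full_region(5, 10))
    assert len(sel) == 5  # ceil(0.1·50)


def test_selection_sign_rule_empty(rng):
    geom = SlideGeometry("s", 512, 512)
    patches = tile_slide(geom)
    amap = AttributionMap("s", {(p.row, p.col): -1.0 for p in patches})
    with pytest.warns(UserWarning, match="no candidate"):
        sel = select_explanatory_patches(amap, patches, _full_region(2, 2))
    assert sel.empty


def test_selection_tie_break_lexicographic():
    geom = SlideGeometry("s", 5 * 256, 4 * 256)
    patches = tile_slide(geom)
    amap = AttributionMap("s", {(p.row, p.col): 1.0 for p in patches})
    sel = select_explanatory_patches(amap, patches, _full_region(4, 5))
    assert len(sel) == 2  # ceil(0.1·20)
    assert list(map(tuple, sel[["row", "col"]].to_numpy())) == [(0, 0), (0, 1)]


def test_selection_cap_formula_property(rng):
    geom = SlideGeometry("s", 8 * 256, 8 * 256)
    patches = tile_slide(geom)
    for cap, frac in [(3, 0.25), (200, 0.5), (1, 1.0)]:
        amap = AttributionMap("s", {(p.row, p.col): float(rng.normal())
                                    for p in patches})
        cfg = SelectionConfig(top_fraction=frac, per_slide_cap=cap)
        n_cand = sum(1 for v in amap.scores.values() if v > 0)
        sel = select_explanatory_patches(amap, patches, _full_region(8, 8), cfg)
        assert len(sel) == min(cap, math.ceil(frac * n_cand))


def test_selection_region_restriction(rng):
    geom = SlideGeometry("s", 4 * 256, 4 * 256)
    patches = tile_slide(geom)
    amap = AttributionMap("s", {(p.row, p.col): 1.0 + p.col for p in patches})
    grid = np.zeros((4, 4), bool)
    grid[:, 0] = True  # only column 0 in region
    sel = select_explanatory_patches(
        amap, patches, RegionMask(grid, 256, "tumor"),
        SelectionConfig(top_fraction=1.0))
    assert set(sel["col"]) == {0}


def test_selection_unchanged_by_normalization_when_positive(rng):
    """Min-max normalization is monotone, so for all-positive raw maps the
    selected set is identical."""
    geom = SlideGeometry("s", 6 * 256, 6 * 256)
    patches = tile_slide(geom)
    amap = _distinct_map(6, 6, rng)
    raw = select_explanatory_patches(amap, patches, _full_region(6, 6))
    norm_map = slide_normalize(amap)
    # drop the (single) zero-normalized minimum, which the sign rule excludes
    norm = select_explanatory_patches(norm_map, patches, _full_region(6, 6))
    assert set(map(tuple, raw[["row", "col"]].to_numpy())) == \
        set(map(tuple, norm[["row", "col"]].to_numpy()))


# ---------------------------------------------------------------------------
# groups and patient aggregation


def _toy_tables():
    manifest = pd.DataFrame({
        "patient_id": ["P1", "P2"], "slide_id": ["s1", "s2"],
        "label": ["progress", "non_progress"]})
    selections = pd.DataFrame({
        "slide_id": ["s1", "s1", "s2"], "row": [0, 0, 1],
        "col": [0, 1, 1], "score": [2.0, 1.0, 3.0]})
    features = pd.DataFrame({
        "slide_id": ["s1", "s1", "s2", "s2"], "row": [0, 0, 1, 0],
        "col": [0, 1, 1, 0], "f1": [1.0, 2.0, 3.0, 4.0]})
    return manifest, selections, features


def test_form_groups_assigns_by_slide_label():
    manifest, selections, features = _toy_tables()
    out = form_groups(manifest, selections, features)
    assert len(out) == 3
    assert set(out.loc[out["group"] == "positive", "slide_id"]) == {"s1"}
    assert set(out.loc[out["group"] == "negative", "slide_id"]) == {"s2"}


def test_form_groups_missing_feature_row_raises():
    manifest, selections, features = _toy_tables()
    with pytest.raises(ValueError, match="without feature rows"):
        form_groups(manifest, selections, features.iloc[:1])


def test_form_groups_single_label_warns():
    manifest, selections, features = _toy_tables()
    sel = selections[selections["slide_id"] == "s1"]
    with pytest.warns(UserWarning, match="negative group is empty"):
        out = form_groups(manifest, sel, features)
    assert (out["group"] == "positive").all()


def test_aggregate_patient_score():
    assert aggregate_patient_score([0.7]) == 0.7
    assert aggregate_patient_score([0.2, 0.9, 0.4]) == 0.9
    assert aggregate_patient_score([0.9, 0.4, 0.2]) == 0.9
    with pytest.raises(ValueError):
        aggregate_patient_score([])


def test_form_groups_can_exclude_misclassified():
    manifest, selections, features = _toy_tables()
    predictions = pd.DataFrame({
        "slide_id": ["s1", "s2"],
        "predicted_label": ["progress", "progress"]})  # s2 misclassified
    with pytest.warns(UserWarning, match="misclassified"):
        out = form_groups(manifest, selections, features,
                          predictions=predictions)
    assert set(out["slide_id"]) == {"s1"}
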