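"""Size-filter cleanup, colony labelling and area/confluency metrics."""

import numpy as np
import pytest

from colonyscan.postprocess import ColonyLabelMap, cleanup, colony_table, metrics
from helpers_oracles import flood_fill_cleanup


def _rect_mask(shape, r0, r1, c0, c1):
    m = np.zeros(shape, dtype=np.uint8)
    m[r0:r1, c0:c1] = 1
    return m


def test_object_at_size_threshold_survives_one_below_does_not():
    below = _rect_mask((80, 1400), 10, 13, 10, 1343)  # 3 x 1333 = 3999 px
    assert below.sum() == 3999
    out = cleanup(below)
    assert out.n_colonies == 0 and out.mask.sum() == 0
    at = _rect_mask((80, 1400), 10, 14, 10, 1010)  # 4 x 1000 = 4000 px
    assert at.sum() == 4000
    out = cleanup(at)
    assert out.n_colonies == 1 and out.mask.sum() == 4000


def test_small_hole_filled_and_counted_in_colony_area():
    m = _rect_mask((80, 120), 10, 60, 10, 112)  # 50 x 102 = 5100 px
    m[30:40, 50:60] = 0  # 100-px hole -> object 5000 px
    assert m.sum() == 5000
    out = cleanup(m)
    assert out.n_colonies == 1
    assert out.mask.sum() == 5100
    np.testing.assert_array_equal(out.areas_px, [5100])


def test_hole_at_threshold_not_filled():
    m = _rect_mask((200, 200), 5, 195, 5, 195)
    m[50:125, 50:130] = 0  # 75 x 80 = 6000-px hole: strict < 6000 keeps it
    out = cleanup(m, min_object=4000, min_hole_fill=6000)
    assert out.mask[60, 60] == 0
    out2 = cleanup(m, min_object=4000, min_hole_fill=6001)
    assert out2.mask[60, 60] == 1


def test_empty_mask_stays_empty():
    out = cleanup(np.zeros((50, 50), dtype=np.uint8))
    assert out.n_colonies == 0
    assert out.mask.sum() == 0


def test_border_touching_background_is_not_a_hole():
    m = np.ones((100, 100), dtype=np.uint8)
    m[:50, 40:60] = 0  # background channel reaching the border
    out = cleanup(m)
    assert out.mask[10, 50] == 0


def test_non_binary_input_rejected():
    with pytest.raises(ValueError, match="binary"):
        cleanup(np.full((10, 10), 3))


def _random_blob_mask(seed, shape=(120, 120)):
    rng = np.random.default_rng(seed)
    from scipy import ndimage as ndi

    noise = ndi.gaussian_filter(rng.normal(size=shape), 6)
    return (noise > 0.2).astype(np.uint8)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_cleanup_matches_flood_fill_oracle(seed):
    raw = _random_blob_mask(seed)
    ours = cleanup(raw, min_object=60, min_hole_fill=40).mask.astype(bool)
    oracle = flood_fill_cleanup(raw, min_object=60, min_hole_fill=40)
    np.testing.assert_array_equal(ours, oracle)


@pytest.mark.parametrize("seed", [3, 4])
def test_cleanup_is_idempotent(seed):
    raw = _random_blob_mask(seed)
    once = cleanup(raw, min_object=60, min_hole_fill=40)
    twice = cleanup(once.mask, min_object=60, min_hole_fill=40)
    np.testing.assert_array_equal(once.mask, twice.mask)


def test_cleanup_only_removes_small_objects_and_fills_holes():
    raw = _random_blob_mask(7)
    out = cleanup(raw, min_object=60, min_hole_fill=40)
    added = out.mask.astype(bool) & ~raw.astype(bool)
    removed = raw.astype(bool) & ~out.mask.astype(bool)
    # added pixels are exactly filled holes: none touches the border
    assert not added[0, :].any() and not added[-1, :].any()
    assert not added[:, 0].any() and not added[:, -1].any()
    # removed pixels all belonged to components below the size threshold
    from skimage import measure

    lbl = measure.label(raw, connectivity=2)
    for comp_id in np.unique(lbl[removed]):
        assert (lbl == comp_id).sum() < 60


def test_area_sum_matches_positive_pixels():
    raw = _random_blob_mask(9)
    out = cleanup(raw, min_object=60, min_hole_fill=40)
    assert out.areas_px.sum() == out.mask.sum()
    assert out.labels.max() == out.n_colonies


# --- metrics -------------------------------------------------------------


def _single_colony_map(n_px, shape=(100, 100), calibration=2.86):
    mask = np.zeros(shape, dtype=np.uint8)
    mask.ravel()[:n_px] = 0  # placeholder, replaced below
    # contiguous block of n_px pixels in the first rows
    full_rows, rem = divmod(n_px, shape[1])
    mask[:full_rows, :] = 1
    if rem:
        mask[full_rows, :rem] = 1
    labels = mask.astype(np.int32)
    return ColonyLabelMap(
        mask=mask,
        labels=labels,
        areas_px=np.array([n_px]),
        area_per_pixel_um2=calibration,
    )


def test_area_calibration_at_published_pixel_size():
    m = metrics(_single_colony_map(1000))
    assert m.total_area_mm2 == pytest.approx(2860e-6)  # 2860 um^2
    assert m.confluency == pytest.approx(0.1)


def test_mean_area_is_total_over_count():
    clm = cleanup(
        _rect_mask((300, 300), 10, 110, 10, 110)
        | _rect_mask((300, 300), 150, 250, 150, 250),
        min_object=4000,
    )
    m = metrics(clm)
    assert m.n_colonies == 2
    assert m.mean_area_mm2 == pytest.approx(m.total_area_mm2 / 2)


def test_zero_mask_metrics_flagged():
    clm = cleanup(np.zeros((50, 50), dtype=np.uint8))
    m = metrics(clm)
    assert m.n_colonies == 0
    assert m.total_area_mm2 == 0.0
    assert m.mean_area_mm2 == 0.0
    assert not m.mean_area_defined
    assert m.confluency == 0.0


def test_confluency_conservation(rng):
    raw = _random_blob_mask(11)
    clm = cleanup(raw, min_object=60, min_hole_fill=40)
    m = metrics(clm)
    assert m.confluency * raw.size == pytest.approx(clm.areas_px.sum())


def test_colony_table_lists_each_component():
    clm = cleanup(
        _rect_mask((300, 300), 10, 110, 10, 110)
        | _rect_mask((300, 300), 150, 250, 150, 250),
        min_object=4000,
    )
    table = colony_table(clm)
    assert list(table["colony_id"]) == [1, 2]
    assert table["area_px"].sum() == clm.mask.sum()
    assert table["area_mm2"].sum() == pytest.approx(metrics(clm).total_area_mm2)
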