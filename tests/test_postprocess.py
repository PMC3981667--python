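import numpy as np
import pytest

from forestchange import PipelineConfig, compose_final, plurality_label, segment
from forestchange.masking import combine_mask_planes
from forestchange.postprocess import SegmentMap, morphological_clean
from forestchange.raster_io import CLASS_CODES, default_grid
from forestchange.training import DISTURBED, NO_CHANGE, REGROWTH
from tests.conftest import make_pair, make_scene

import datetime as dt


def _masks_all_valid(shape):
    empty = np.zeros(shape, dtype=bool)
    full = np.ones(shape, dtype=bool)
    return combine_mask_planes(empty, empty, empty, empty, empty, empty,
                               full, full, empty)


# ---------------------------------------------------------------------------
# morphological cleaning
# ---------------------------------------------------------------------------

def test_empty_disturbed_layer_unchanged():
    labels = np.full((10, 10), NO_CHANGE)
    np.testing.assert_array_equal(morphological_clean(labels, PipelineConfig()), labels)


def test_isolated_disturbed_pixel_removed():
    labels = np.full((10, 10), NO_CHANGE)
    labels[5, 5] = DISTURBED
    cleaned = morphological_clean(labels, PipelineConfig())
    assert cleaned[5, 5] == NO_CHANGE
    assert (cleaned == NO_CHANGE).all()


def test_solid_block_preserved_exactly():
    labels = np.full((20, 20), NO_CHANGE)
    labels[5:15, 5:15] = DISTURBED
    cleaned = morphological_clean(labels, PipelineConfig())
    np.testing.assert_array_equal(cleaned, labels)


def test_regrowth_layer_untouched_by_cleaning():
    labels = np.full((10, 10), NO_CHANGE)
    labels[3, 3] = REGROWTH
    cleaned = morphological_clean(labels, PipelineConfig())
    assert cleaned[3, 3] == REGROWTH


# ---------------------------------------------------------------------------
# segmentation
# ---------------------------------------------------------------------------

def _pair_from_stacks(early_bands, late_bands):
    early = make_scene(early_bands, date=dt.date(2000, 7, 1))
    late = make_scene(late_bands, date=dt.date(2005, 7, 1))
    return make_pair(early, late)


def test_homogeneous_image_is_one_segment():
    shape = (24, 24)
    pair = _pair_from_stacks({"red": np.full(shape, 0.1)}, {"red": np.full(shape, 0.1)})
    seg = segment(pair, _masks_all_valid(shape), PipelineConfig())
    assert seg.n_segments == 1
    assert seg.sizes[1] == 24 * 24


def test_two_halves_with_large_gap_are_two_segments():
    shape = (24, 24)
    red = np.full(shape, 0.05)
    red[:, 12:] = 0.45  # spectral gap far above the merge threshold
    pair = _pair_from_stacks({"red": red}, {"red": red})
    seg = segment(pair, _masks_all_valid(shape), PipelineConfig())
    assert seg.n_segments == 2
    left = np.unique(seg.ids[:, :12])
    right = np.unique(seg.ids[:, 12:])
    assert len(left) == 1 and len(right) == 1 and left[0] != right[0]


def test_random_image_respects_mmu():
    rng = np.random.default_rng(45)
    shape = (32, 32)
    roles = ("red", "nir", "swir1")
    early = {r: rng.uniform(0, 1, shape) for r in roles}
    late = {r: rng.uniform(0, 1, shape) for r in roles}
    pair = _pair_from_stacks(early, late)
    cfg = PipelineConfig()
    seg = segment(pair, _masks_all_valid(shape), cfg)
    assert seg.sizes[1:].min() >= cfg.mmu


def test_segment_ids_partition_valid_region():
    rng = np.random.default_rng(46)
    shape = (32, 32)
    pair = _pair_from_stacks({"red": rng.uniform(0, 1, shape)},
                             {"red": rng.uniform(0, 1, shape)})
    valid = np.ones(shape, dtype=bool)
    valid[:4, :] = False
    empty = np.zeros(shape, dtype=bool)
    masks = combine_mask_planes(empty, empty, empty, empty, empty, empty,
                                valid, valid, empty)
    seg = segment(pair, masks, PipelineConfig())
    assert (seg.ids[valid] > 0).all()
    assert (seg.ids[~valid] == 0).all()
    # sizes consistent with the id plane
    for sid in range(1, seg.n_segments + 1):
        assert (seg.ids == sid).sum() == seg.sizes[sid]


def test_no_valid_pixels_gives_empty_map():
    shape = (8, 8)
    pair = _pair_from_stacks({"red": np.zeros(shape)}, {"red": np.zeros(shape)})
    empty = np.zeros(shape, dtype=bool)
    masks = combine_mask_planes(empty, empty, empty, empty, empty, empty,
                                empty, empty, empty)
    seg = segment(pair, masks, PipelineConfig())
    assert seg.n_segments == 0


def test_segmentation_is_deterministic():
    rng = np.random.default_rng(47)
    shape = (32, 32)
    early = {r: rng.uniform(0, 0.3, shape) for r in ("red", "nir", "swir1")}
    late = {r: rng.uniform(0, 0.3, shape) for r in ("red", "nir", "swir1")}
    pair = _pair_from_stacks(early, late)
    s1 = segment(pair, _masks_all_valid(shape), PipelineConfig())
    s2 = segment(pair, _masks_all_valid(shape), PipelineConfig())
    np.testing.assert_array_equal(s1.ids, s2.ids)


# ---------------------------------------------------------------------------
# plurality labelling
# ---------------------------------------------------------------------------

def _toy_segmap(ids):
    ids = np.asarray(ids)
    n = ids.max()
    sizes = np.bincount(ids.ravel(), minlength=n + 1)
    return SegmentMap(ids=ids, sizes=sizes, means=np.zeros((n + 1, 6)))


def test_uniform_segment_keeps_its_label():
    seg = _toy_segmap([[1, 1], [1, 1]])
    labels = np.full((2, 2), DISTURBED)
    assert plurality_label(seg, labels)[1] == DISTURBED


def test_plurality_counting():
    seg = _toy_segmap([[1, 1, 1], [1, 1, 1]])
    labels = np.array([[DISTURBED, DISTURBED, DISTURBED],
                       [DISTURBED, NO_CHANGE, NO_CHANGE]])
    assert plurality_label(seg, labels)[1] == DISTURBED


def test_tie_goes_to_no_change():
    seg = _toy_segmap([[1, 1, 1], [1, 1, 1]])
    labels = np.array([[DISTURBED] * 3, [REGROWTH] * 3])
    assert plurality_label(seg, labels)[1] == NO_CHANGE
    labels2 = np.array([[DISTURBED] * 3, [NO_CHANGE] * 3])
    assert plurality_label(seg, labels2)[1] == NO_CHANGE


# ---------------------------------------------------------------------------
# final composition
# ---------------------------------------------------------------------------

def test_cloud_precedence_beats_classification():
    shape = (8, 8)
    ids = np.ones(shape, dtype=np.int64)
    seg = _toy_segmap(ids)
    seg_labels = np.array([NO_CHANGE, DISTURBED])
    empty = np.zeros(shape, dtype=bool)
    cloud2 = np.zeros(shape, dtype=bool)
    cloud2[0, 0] = True
    masks = combine_mask_planes(empty, cloud2, empty, empty, empty, empty,
                                np.ones(shape, bool), np.ones(shape, bool), empty)
    cmap = compose_final(seg, seg_labels, masks, empty, default_grid(shape))
    assert cmap.class_raster[0, 0] == CLASS_CODES["cloud"]
    assert cmap.class_raster[1, 1] == CLASS_CODES["disturbed"]


def test_every_pixel_has_exactly_one_code():
    rng = np.random.default_rng(48)
    shape = (16, 16)
    ids = np.zeros(shape, dtype=np.int64)
    valid = rng.random(shape) < 0.6
    ids[valid] = 1 + (np.cumsum(valid.ravel()).reshape(shape)[valid] % 3)
    seg = _toy_segmap(ids)
    seg_labels = np.array([NO_CHANGE, DISTURBED, NO_CHANGE, REGROWTH])
    planes = [rng.random(shape) < 0.1 for _ in range(7)]
    masks = combine_mask_planes(planes[0], planes[1], planes[2], planes[3],
                                planes[4], planes[5], valid, valid, planes[6])
    nodata = planes[6]
    cmap = compose_final(seg, seg_labels, masks, nodata, default_grid(shape))
    assert set(np.unique(cmap.class_raster)) <= set(range(7))
    assert (cmap.class_raster[nodata] == 0).all()
    assert (cmap.class_raster[~nodata] > 0).all()


def test_toy_composite_matches_hand_built_expectation():
    shape = (16, 16)
    empty = np.zeros(shape, dtype=bool)
    forest = np.zeros(shape, dtype=bool)
    forest[:, :8] = True  # left half forest, right half never-forest
    ids = np.zeros(shape, dtype=np.int64)
    ids[:, :8] = 1
    ids[:8, :8] = 2  # top-left quadrant disturbed segment
    seg = _toy_segmap(ids)
    seg_labels = np.array([NO_CHANGE, NO_CHANGE, DISTURBED])
    water = np.zeros(shape, dtype=bool)
    water[15, :] = True
    masks = combine_mask_planes(empty, empty, empty, empty, water, empty,
                                forest, forest, empty)
    cmap = compose_final(seg, seg_labels, masks, empty, default_grid(shape))
    expected = np.full(shape, CLASS_CODES["stable_nonforest"], dtype=np.uint8)
    expected[:, :8] = CLASS_CODES["stable_forest"]
    expected[:8, :8] = CLASS_CODES["disturbed"]
    expected[15, :] = CLASS_CODES["water"]
    np.testing.assert_array_equal(cmap.class_raster, expected)
    # polygon layer tiles the classified area
    assert sum(p.pixel_count for p in cmap.polygons) == shape[0] * shape[1]
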