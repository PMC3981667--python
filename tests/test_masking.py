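"""Mask rules checked against exhaustive per-pixel oracles and constructions."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from forestchange import PipelineConfig, cloud_shadow_mask, forest_mask, water_mask
from forestchange.masking import combine_mask_planes, _forest_peak_threshold
from tests.conftest import make_scene


# ---------------------------------------------------------------------------
# water
# ---------------------------------------------------------------------------

def water_oracle(scene, cfg):
    """Brute-force per-pixel application of the printed water rule."""
    h, w = scene.shape
    out = np.zeros((h, w), dtype=bool)
    for r in range(h):
        for c in range(w):
            if scene.nodata_mask[r, c]:
                continue
            red = scene.bands["red"][r, c]
            nir = scene.bands["nir"][r, c]
            swir = scene.bands["swir1"][r, c]
            if swir >= cfg.water_swir_max:
                continue
            decreasing = red > nir > swir
            ndvi_ok = (nir + red) > 0 and (nir - red) / (nir + red) < cfg.water_ndvi_max
            out[r, c] = decreasing or ndvi_ok
    return out


def test_water_rule_examples():
    cfg = PipelineConfig()
    # dark pixel with negative NDVI and decreasing trend -> water
    s = make_scene({"red": [[0.06]], "nir": [[0.04]], "swir1": [[0.02]]})
    assert water_mask(s, cfg)[0, 0]
    # SWIR at 30 % can never be water
    s = make_scene({"red": [[0.06]], "nir": [[0.04]], "swir1": [[0.30]]})
    assert not water_mask(s, cfg)[0, 0]
    # NDVI exactly at the cutoff with a non-decreasing trend: not water
    # (strict inequalities on both clauses)
    red, nir = 0.07, 0.13  # ndvi = 0.3 exactly
    s = make_scene({"red": [[red]], "nir": [[nir]], "swir1": [[0.10]]})
    assert not water_mask(s, cfg)[0, 0]


def test_water_mask_matches_bruteforce_oracle():
    rng = np.random.default_rng(11)
    cfg = PipelineConfig()
    for _ in range(3):
        bands = {r: rng.uniform(0, 0.5, (64, 64))
                 for r in ("blue", "green", "red", "nir", "swir1", "swir2")}
        scene = make_scene(bands)
        np.testing.assert_array_equal(water_mask(scene, cfg), water_oracle(scene, cfg))


@settings(derandomize=True, max_examples=200)
@given(
    red=st.floats(0.0, 0.6),
    nir=st.floats(1e-4, 0.6),
    swir=st.floats(0.0, 0.6),
)
def test_water_rule_single_pixel_property(red, nir, swir):
    """Vectorized rule equals its scalar reading for arbitrary reflectances."""
    cfg = PipelineConfig()
    s = make_scene({"red": [[red]], "nir": [[nir]], "swir1": [[swir]]})
    expect = swir < cfg.water_swir_max and (
        (red > nir > swir)
        or ((nir + red) > 0 and (nir - red) / (nir + red) < cfg.water_ndvi_max)
    )
    assert bool(water_mask(s, cfg)[0, 0]) == expect


def test_water_mask_excludes_nodata_and_is_idempotent():
    nodata = np.zeros((8, 8), dtype=bool)
    nodata[0] = True
    s = make_scene({"red": np.full((8, 8), 0.06), "nir": np.full((8, 8), 0.04),
                    "swir1": np.full((8, 8), 0.02)}, nodata=nodata)
    cfg = PipelineConfig()
    m1 = water_mask(s, cfg)
    assert not m1[0].any() and m1[1:].all()
    np.testing.assert_array_equal(m1, water_mask(s, cfg))


def test_water_recall_precision_on_noiseless_synthetic():
    from forestchange import SceneSpec, generate_scene_pair

    spec = SceneSpec(width=128, height=128, noise_sd=0.0, patch_jitter_sd=0.0, psf_sigma=0.0, seed=12, frac_cloud=0.0)
    pair, truth = generate_scene_pair(spec)
    est = water_mask(pair.early, PipelineConfig())
    tp = (est & truth.water).sum()
    assert tp / truth.water.sum() >= 0.99
    assert tp / est.sum() >= 0.99


# ---------------------------------------------------------------------------
# forest
# ---------------------------------------------------------------------------

def test_two_level_window_thresholds_between_modes():
    rng = np.random.default_rng(13)
    red = np.where(rng.random((64, 64)) < 0.6, 0.03, 0.15)
    cfg = PipelineConfig(window_size=64)
    scene = make_scene({"red": red})
    mask = forest_mask(scene, cfg)
    np.testing.assert_array_equal(mask, red == 0.03)


def test_unimodal_bright_window_has_no_forest():
    scene = make_scene({"red": np.full((64, 64), 0.20)})
    assert not forest_mask(scene, PipelineConfig(window_size=64)).any()


def test_noisy_bimodal_window_recovers_truth():
    rng = np.random.default_rng(14)
    truth = rng.random((64, 64)) < 0.5
    red = np.where(truth, 0.03, 0.12) + rng.normal(0, 0.01, (64, 64))
    scene = make_scene({"red": np.clip(red, 0, 1)})
    mask = forest_mask(scene, PipelineConfig(window_size=64))
    agreement = (mask == truth).mean()
    assert agreement >= 0.99


def test_forest_peak_threshold_brute_force_equivalence():
    """Windowed mask equals direct per-window application of the rule."""
    rng = np.random.default_rng(15)
    cfg = PipelineConfig(window_size=32)
    red = np.clip(
        np.where(rng.random((64, 64)) < 0.5, 0.04, 0.18)
        + rng.normal(0, 0.01, (64, 64)),
        0, 1,
    )
    scene = make_scene({"red": red})
    got = forest_mask(scene, cfg)
    expected = np.zeros((64, 64), dtype=bool)
    for r0 in range(0, 64, 32):
        for c0 in range(0, 64, 32):
            win = red[r0 : r0 + 32, c0 : c0 + 32]
            thr = _forest_peak_threshold(win.ravel(), cfg)
            if thr is not None:
                expected[r0 : r0 + 32, c0 : c0 + 32] = win <= thr
    np.testing.assert_array_equal(got, expected)


# ---------------------------------------------------------------------------
# cloud and shadow
# ---------------------------------------------------------------------------

def test_no_bright_pixels_no_cloud_no_shadow():
    scene = make_scene(shape=(32, 32), fill=0.05)
    cloud, shadow = cloud_shadow_mask(scene, PipelineConfig())
    assert not cloud.any() and not shadow.any()


def test_bright_cold_block_detected_with_bounded_spill():
    cfg = PipelineConfig()
    shape = (64, 64)
    bands = {r: np.full(shape, 0.05) for r in ("blue", "green", "red", "nir", "swir1", "swir2")}
    for r in bands:
        bands[r][10:20, 10:20] = 0.6
    thermal = np.full(shape, 295.0)
    thermal[10:20, 10:20] = 260.0
    scene = make_scene(bands, thermal=thermal)
    cloud, _ = cloud_shadow_mask(scene, cfg)
    block = np.zeros(shape, dtype=bool)
    block[10:20, 10:20] = True
    assert (cloud & block).sum() >= (block.sum() - 4 * 10 * cfg.morph_radius)
    assert not (cloud & ~block).any()


def test_shadow_centroid_matches_projection_geometry():
    """A square cloud at known height casts a shadow at h*tan(zenith)."""
    cfg = PipelineConfig()
    shape = (96, 96)
    zenith, azimuth, height, px = 30.0, 135.0, 1000.0, 30.0
    bands = {r: np.full(shape, 0.25) for r in ("blue", "green", "red", "nir", "swir1", "swir2")}
    thermal = np.full(shape, 295.0)
    # cloud block
    bands_cloud = slice(40, 50)
    for r in bands:
        bands[r][bands_cloud, bands_cloud] = 0.6
    thermal[bands_cloud, bands_cloud] = 260.0
    # dark ground patch exactly at the geometric shadow position
    dist = height * np.tan(np.deg2rad(zenith)) / px
    az = np.deg2rad(azimuth + 180.0)
    dr = int(round(-dist * np.cos(az)))
    dc = int(round(dist * np.sin(az)))
    dark = slice(40 + dr, 50 + dr), slice(40 + dc, 50 + dc)
    bands["nir"][dark] = 0.05
    scene = make_scene(bands, thermal=thermal, sun_zenith=zenith, sun_azimuth=azimuth)
    _, shadow = cloud_shadow_mask(scene, cfg)
    assert shadow.any()
    sr, sc = np.nonzero(shadow)
    assert abs(sr.mean() - (44.5 + dr)) <= 1.5
    assert abs(sc.mean() - (44.5 + dc)) <= 1.5


def test_missing_thermal_degrades_to_spectral_only():
    shape = (32, 32)
    bands = {r: np.full(shape, 0.05) for r in ("blue", "green", "red", "nir", "swir1", "swir2")}
    for r in bands:
        bands[r][5:15, 5:15] = 0.6
    scene = make_scene(bands, thermal=None)
    cloud, _ = cloud_shadow_mask(scene, PipelineConfig())
    assert cloud[6:14, 6:14].all()


# ---------------------------------------------------------------------------
# combination
# ---------------------------------------------------------------------------

def test_combine_all_clear_all_forest_is_fully_valid():
    shape = (8, 8)
    empty = np.zeros(shape, dtype=bool)
    full = np.ones(shape, dtype=bool)
    ms = combine_mask_planes(empty, empty, empty, empty, empty, empty, full, full, empty)
    assert ms.valid.all()


def test_combine_union_semantics_and_early_forest_gate():
    rng = np.random.default_rng(16)
    shape = (8, 8)
    planes = [rng.random(shape) < 0.2 for _ in range(7)]  # c1 c2 s1 s2 w1 w2 nodata
    f1 = rng.random(shape) < 0.7
    f2 = rng.random(shape) < 0.7
    ms = combine_mask_planes(planes[0], planes[1], planes[2], planes[3],
                             planes[4], planes[5], f1, f2, planes[6])
    # brute-force set arithmetic per pixel
    for r in range(shape[0]):
        for c in range(shape[1]):
            excluded = any(p[r, c] for p in planes)
            assert ms.valid[r, c] == ((not excluded) and f1[r, c])
    # cloudy at date 2 only -> invalid even where forest
    cloudy2 = planes[1] & f1 & ~np.logical_or.reduce(
        [planes[0], planes[2], planes[3], planes[4], planes[5], planes[6]]
    )
    assert not ms.valid[cloudy2].any()
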