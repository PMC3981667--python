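"""Cloud, cloud-shadow, water and forest masks, and the combined valid mask.

Three spectral screens run per date:

* **water** — a pixel is water iff its SWIR reflectance is below 25 % and it
  shows either a strictly decreasing visible-to-infrared trend
  (red > nir > swir1) or NDVI below 0.3, or both.
* **forest** — per local window, the red-band histogram is smoothed and its
  lowest-reflectance prominent mode (the "forest peak") located; pixels at or
  below the peak plus a margin are forest.  Bright unimodal windows have no
  dark peak and contribute no forest.
* **cloud / shadow** — a simplified spectral-thermal screen: bright (blue and
  SWIR), spectrally flat in the visible, and colder than the scene median
  brightness temperature; each cloud object's shadow is found by projecting
  the object along the anti-solar azimuth over a sweep of candidate cloud
  heights and keeping the projection that best overlaps dark-NIR ground.

The combined valid-analysis plane excludes cloud, shadow and water at either
date plus nodata, and gates on the EARLY date's forest mask so that pixels
cleared between the dates stay inside the analysis region.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .config import PipelineConfig
from .raster_io import Scene, ScenePair


@dataclass
class MaskSet:
    """Per-date boolean planes plus the combined valid-analysis plane."""

    cloud_early: np.ndarray
    cloud_late: np.ndarray
    shadow_early: np.ndarray
    shadow_late: np.ndarray
    water_early: np.ndarray
    water_late: np.ndarray
    forest_early: np.ndarray
    forest_late: np.ndarray
    valid: np.ndarray


def ndvi(scene: Scene) -> np.ma.MaskedArray:
    """(nir - red) / (nir + red), masked where the denominator is <= 0."""
    nir = scene.bands["nir"]
    red = scene.bands["red"]
    denom = nir + red
    bad = (denom <= 0) | scene.nodata_mask
    with np.errstate(divide="ignore", invalid="ignore"):
        vals = np.where(bad, 0.0, (nir - red) / np.where(bad, 1.0, denom))
    return np.ma.MaskedArray(vals, mask=bad)


def water_mask(scene: Scene, cfg: PipelineConfig) -> np.ndarray:
    """Spectral water rule; nodata pixels are never water."""
    red = scene.bands["red"]
    nir = scene.bands["nir"]
    swir = scene.bands["swir1"]
    nd = ndvi(scene)
    decreasing = (red > nir) & (nir > swir)
    low_ndvi = (~nd.mask) & (nd.data < cfg.water_ndvi_max)
    mask = (swir < cfg.water_swir_max) & (decreasing | low_ndvi)
    mask &= ~scene.nodata_mask
    return mask


def _iter_windows(shape: tuple[int, int], size: int, stride: int):
    h, w = shape
    for r0 in range(0, h, stride):
        for c0 in range(0, w, stride):
            yield r0, c0, min(r0 + size, h), min(c0 + size, w)


def _forest_peak_threshold(red_values: np.ndarray, cfg: PipelineConfig) -> float | None:
    """Red-reflectance threshold from the window's dark histogram peak.

    The histogram (fixed bin width) is smoothed with a short moving average;
    a mode is prominent when its smoothed count reaches the configured
    fraction of the window's valid pixels, and only peaks darker than
    ``forest_peak_max_red`` qualify.  The threshold is the peak centre plus
    ``max(half-prominence width, margin_bins * bin width)`` — a bare peak
    location would cut the forest mode in half.  Returns None when the
    window has no dark peak.
    """
    n = red_values.size
    if n == 0:
        return None
    bw = cfg.forest_hist_bin_width
    nbins = int(np.ceil(1.0 / bw))
    counts, edges = np.histogram(red_values, bins=nbins, range=(0.0, 1.0))
    k = cfg.forest_hist_smooth_bins
    kernel = np.ones(k) / k
    smooth = np.convolve(counts, kernel, mode="same")
    min_count = cfg.forest_peak_prominence_frac * n
    # local maxima of the smoothed histogram (plateaus count once, at the left edge)
    for i in range(len(smooth)):
        left = smooth[i - 1] if i > 0 else -np.inf
        right = smooth[i + 1] if i < len(smooth) - 1 else -np.inf
        if smooth[i] < min_count or smooth[i] < left or smooth[i] <= right:
            continue
        centre = (edges[i] + edges[i + 1]) / 2.0
        if centre >= cfg.forest_peak_max_red:
            return None  # darkest prominent mode is not dark: no forest peak
        # full width of the peak at half prominence
        j = i
        while j < len(smooth) - 1 and smooth[j] > smooth[i] / 2.0:
            j += 1
        i2 = i
        while i2 > 0 and smooth[i2] > smooth[i] / 2.0:
            i2 -= 1
        half_prom_width = (j - i2) * bw
        margin = max(half_prom_width, cfg.forest_peak_margin_bins * bw)
        return centre + margin
    return None


def forest_mask(scene: Scene, cfg: PipelineConfig) -> np.ndarray:
    """Dark-peak forest mask over local windows of the red band."""
    red = scene.bands["red"]
    ok = ~scene.nodata_mask
    out = np.zeros(scene.shape, dtype=bool)
    for r0, c0, r1, c1 in _iter_windows(scene.shape, cfg.window_size, cfg.effective_stride):
        wok = ok[r0:r1, c0:c1]
        values = red[r0:r1, c0:c1][wok]
        thr = _forest_peak_threshold(values, cfg)
        if thr is None:
            continue
        out[r0:r1, c0:c1] |= wok & (red[r0:r1, c0:c1] <= thr)
    return out


def _anti_solar_shift(zenith: float, azimuth: float, height: float, pixel_size: float):
    """(row, col) displacement of a shadow cast by a cloud at ``height`` m."""
    dist = height * np.tan(np.deg2rad(zenith))
    az = np.deg2rad((azimuth + 180.0) % 360.0)
    east = dist * np.sin(az)
    north = dist * np.cos(az)
    return int(round(-north / pixel_size)), int(round(east / pixel_size))


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs, cs = np.nonzero(mask)
    rs, cs = rs + dr, cs + dc
    keep = (rs >= 0) & (rs < h) & (cs >= 0) & (cs < w)
    out[rs[keep], cs[keep]] = True
    return out


def cloud_shadow_mask(
    scene: Scene, cfg: PipelineConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Simplified spectral-thermal cloud screen + geometric shadow matching."""
    blue = scene.bands["blue"]
    green = scene.bands["green"]
    red = scene.bands["red"]
    nir = scene.bands["nir"]
    swir = scene.bands["swir1"]
    ok = ~scene.nodata_mask

    bright = (blue > cfg.cloud_blue_min) & (swir > cfg.cloud_swir_min)
    vis_mean = (blue + green + red) / 3.0
    with np.errstate(divide="ignore", invalid="ignore"):
        spread = np.maximum.reduce(
            [np.abs(blue - vis_mean), np.abs(green - vis_mean), np.abs(red - vis_mean)]
        ) / np.where(vis_mean > 0, vis_mean, 1.0)
    white = spread < cfg.cloud_whiteness_max
    cloud = bright & white & ok
    if scene.thermal is not None:
        bt = scene.thermal
        median_bt = np.median(bt[ok]) if ok.any() else 0.0
        cloud &= bt < (median_bt - cfg.cloud_bt_margin)
    # else: spectral-only screen (caller may warn)

    if cfg.morph_radius > 0 and cloud.any():
        foot = np.ones((2 * cfg.morph_radius + 1,) * 2, dtype=bool)
        cloud = ndimage.binary_opening(cloud, structure=foot)

    shadow = np.zeros_like(cloud)
    if cloud.any():
        dark = (nir < cfg.shadow_nir_max) & ok & ~cloud
        labeled, nobj = ndimage.label(cloud, structure=np.ones((3, 3), dtype=int))
        heights = np.arange(
            cfg.cloud_height_min,
            cfg.cloud_height_max + cfg.cloud_height_step / 2,
            cfg.cloud_height_step,
        )
        px = scene.grid.pixel_size
        for obj in range(1, nobj + 1):
            omask = labeled == obj
            best, best_overlap = None, 0
            for h in heights:
                dr, dc = _anti_solar_shift(scene.sun_zenith, scene.sun_azimuth, h, px)
                proj = _shift_mask(omask, dr, dc) & ~cloud
                overlap = int((proj & dark).sum())
                if overlap > best_overlap:
                    best, best_overlap = proj, overlap
            if best is not None:
                shadow |= best
    return cloud, shadow


def combine_masks(pair: ScenePair, cfg: PipelineConfig) -> MaskSet:
    """Run all screens on both dates and combine into the valid plane."""
    ce, se = cloud_shadow_mask(pair.early, cfg)
    cl, sl = cloud_shadow_mask(pair.late, cfg)
    we = water_mask(pair.early, cfg)
    wl = water_mask(pair.late, cfg)
    fe = forest_mask(pair.early, cfg)
    fl = forest_mask(pair.late, cfg)
    return combine_mask_planes(ce, cl, se, sl, we, wl, fe, fl, pair.nodata_mask)


def combine_mask_planes(
    cloud_early, cloud_late, shadow_early, shadow_late,
    water_early, water_late, forest_early, forest_late, nodata,
) -> MaskSet:
    """valid = NOT(any cloud/shadow/water/nodata) AND forest at the early date."""
    excluded = (
        cloud_early | cloud_late | shadow_early | shadow_late
        | water_early | water_late | nodata
    )
    valid = ~excluded & forest_early
    return MaskSet(
        cloud_early=cloud_early,
        cloud_late=cloud_late,
        shadow_early=shadow_early,
        shadow_late=shadow_late,
        water_early=water_early,
        water_late=water_late,
        forest_early=forest_early,
        forest_late=forest_late,
        valid=valid,
    )
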