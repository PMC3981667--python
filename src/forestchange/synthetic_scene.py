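"""Synthetic bi-temporal scene pairs with per-pixel truth.

The generator emulates the kind of Landsat TM/ETM+ scene pair the pipeline
expects: TOA reflectance fractions in [0, 1] for six reflective bands, a
thermal brightness-temperature plane in Kelvin, and known solar geometry.
The landscape is painted as patches (axis-aligned rectangles and dilated
random-walk blobs) of seven surface conditions over a stable non-forest
background, each with a spectral archetype per date plus i.i.d. Gaussian
band noise.  Clouds are bright, spectrally flat and cold; their shadows are
displaced along the anti-solar azimuth at a known cloud height, so geometric
shadow matching is exercised with a known answer.

Archetype reflectances are documented package constants chosen to satisfy
the qualitative orderings the method relies on (mature forest dark in red
and SWIR, cleared land bright in SWIR, water dark and decreasing from
visible to infrared, agriculture flipping brightness between dates as a
confuser); they are synthetic stand-ins, not measurements from any sensor.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .raster_io import BAND_ORDER, Scene, ScenePair, default_grid

# surface condition ids used internally by the generator
FOREST, DISTURBED, REGROWTH, AGRICULTURE, WATER, NONFOREST = range(6)

#: change labels in TruthMaps
CHANGE_NONE, CHANGE_DISTURBED, CHANGE_REGROWTH = 0, 1, 2

# per-condition archetype reflectance (blue, green, red, nir, swir1, swir2)
# at each date; synthetic stand-in values (see module docstring).
_ARCHETYPES: dict[int, tuple[tuple[float, ...], tuple[float, ...]]] = {
    # mature forest: dark red, high NIR, low SWIR, both dates
    FOREST: ((0.02, 0.04, 0.03, 0.30, 0.10, 0.05),) * 2,
    # disturbance: forest at date 1, freshly cleared (bright SWIR) at date 2
    DISTURBED: (
        (0.02, 0.04, 0.03, 0.30, 0.10, 0.05),
        (0.08, 0.10, 0.12, 0.22, 0.28, 0.22),
    ),
    # regrowth: young regrowing stand at date 1 (dark red, still-elevated
    # SWIR), closed canopy at date 2
    REGROWTH: (
        (0.03, 0.05, 0.045, 0.26, 0.20, 0.13),
        (0.02, 0.04, 0.03, 0.30, 0.10, 0.05),
    ),
    # shifting agriculture: green crop then bare field (brightness flip)
    AGRICULTURE: (
        (0.05, 0.07, 0.08, 0.42, 0.16, 0.10),
        (0.10, 0.13, 0.16, 0.24, 0.32, 0.26),
    ),
    # water: dark, strictly decreasing visible -> infrared
    WATER: ((0.06, 0.05, 0.04, 0.02, 0.012, 0.008),) * 2,
    # stable non-forest background: bright soil / senescent grass
    NONFOREST: ((0.10, 0.12, 0.15, 0.25, 0.30, 0.25),) * 2,
}

_CLOUD_REFLECTANCE = 0.60
_SHADOW_FACTOR = 0.35  # multiplicative darkening under cloud shadow
_SURFACE_BT = {FOREST: 290.0, DISTURBED: 294.0, REGROWTH: 291.0,
               AGRICULTURE: 293.0, WATER: 288.0, NONFOREST: 296.0}
_CLOUD_BT = 262.0


class SceneSpecError(ValueError):
    pass


@dataclass
class SceneSpec:
    """Parameters of one synthetic scene pair."""

    width: int = 256
    height: int = 256
    #: target area fractions; the remainder is stable non-forest background
    frac_forest: float = 0.55
    frac_disturbance: float = 0.10
    frac_regrowth: float = 0.05
    frac_agriculture: float = 0.10
    frac_water: float = 0.05
    frac_cloud: float = 0.02
    #: patch edge lengths are drawn log-uniformly from [min, max]
    patch_min: int = 6
    patch_max: int = 48
    #: i.i.d. per-band reflectance noise SD
    noise_sd: float = 0.01
    #: per-patch spectral offset SD (stand-to-stand / field-to-field
    #: variability; drawn once per patch, band and date)
    patch_jitter_sd: float = 0.008
    #: Gaussian point-spread sigma in pixels: mixes spectra across patch
    #: boundaries the way a real sensor footprint does
    psf_sigma: float = 0.7
    #: thermal noise SD in Kelvin
    thermal_noise_sd: float = 1.0
    sun_zenith: float = 30.0
    sun_azimuth: float = 135.0
    #: cloud height used to displace shadows (metres)
    cloud_height: float = 1000.0
    pixel_size: float = 30.0
    date_early: _dt.date = _dt.date(2000, 7, 1)
    date_late: _dt.date = _dt.date(2005, 7, 1)
    seed: int = 0

    def __post_init__(self) -> None:
        fracs = self.class_fractions()
        if any(f < 0 or f > 1 for f in fracs.values()):
            raise SceneSpecError("class fractions must lie in [0, 1]")
        if sum(fracs.values()) > 1:
            raise SceneSpecError("class fractions must sum to <= 1")
        if self.noise_sd < 0 or self.thermal_noise_sd < 0 or self.patch_jitter_sd < 0:
            raise SceneSpecError("noise SDs must be >= 0")
        if self.patch_min < 1 or self.patch_max < self.patch_min:
            raise SceneSpecError("patch size range is invalid")

    def class_fractions(self) -> dict[int, float]:
        return {
            FOREST: self.frac_forest,
            DISTURBED: self.frac_disturbance,
            REGROWTH: self.frac_regrowth,
            AGRICULTURE: self.frac_agriculture,
            WATER: self.frac_water,
        }


@dataclass
class TruthMaps:
    """Per-pixel ground truth for a generated pair."""

    condition: np.ndarray  # (H, W) surface condition id (cloud-free)
    change: np.ndarray  # (H, W) CHANGE_* labels
    forest_early: np.ndarray  # bool: truly forest at date 1
    forest_late: np.ndarray
    water: np.ndarray  # bool, date-independent here
    cloud_early: np.ndarray
    cloud_late: np.ndarray
    shadow_early: np.ndarray
    shadow_late: np.ndarray


def _paint_patches(
    cls: np.ndarray,
    patch_id: np.ndarray,
    next_id: int,
    cond: int,
    target_px: int,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> int:
    """Paint rectangles / blobs of ``cond`` until its area reaches target.

    Each painted patch gets a distinct id in ``patch_id`` (used for
    per-patch spectral jitter); returns the next free id.
    """
    h, w = cls.shape
    # enough attempts to hit the target even when later patches mostly land
    # on already-painted ground; residual quantization slack is acceptable
    mean_area = float(np.exp(np.log(spec.patch_min) + np.log(spec.patch_max)))
    budget = max(200, int(8 * target_px / max(mean_area, 1.0)))
    painted = int((cls == cond).sum())
    lo, hi = np.log(spec.patch_min), np.log(spec.patch_max + 1)
    for _ in range(budget):
        if painted >= target_px:
            break
        if rng.random() < 0.5:  # axis-aligned rectangle
            ph = int(np.exp(rng.uniform(lo, hi)))
            pw = int(np.exp(rng.uniform(lo, hi)))
            r0 = int(rng.integers(0, max(1, h - ph)))
            c0 = int(rng.integers(0, max(1, w - pw)))
            patch = np.zeros_like(cls, dtype=bool)
            patch[r0 : r0 + ph, c0 : c0 + pw] = True
        else:  # dilated random walk blob
            steps = int(np.exp(rng.uniform(lo, hi))) ** 2 // 2 + 4
            r, c = int(rng.integers(0, h)), int(rng.integers(0, w))
            patch = np.zeros_like(cls, dtype=bool)
            for _ in range(steps):
                patch[r, c] = True
                dr, dc = rng.integers(-1, 2, size=2)
                r = int(np.clip(r + dr, 0, h - 1))
                c = int(np.clip(c + dc, 0, w - 1))
            patch = ndimage.binary_dilation(patch, iterations=1)
        fresh = patch & (cls == NONFOREST)
        if fresh.any():
            cls[fresh] = cond
            patch_id[fresh] = next_id
            next_id += 1
        painted += int(fresh.sum())
    return next_id


def _render_date(
    cls: np.ndarray,
    patch_id: np.ndarray,
    n_patches: int,
    date_idx: int,
    spec: SceneSpec,
    rng: np.random.Generator,
) -> tuple[dict[str, np.ndarray], np.ndarray]:
    h, w = cls.shape
    refl = np.empty((h, w, 6))
    bt = np.empty((h, w))
    for cond, (arch0, arch1) in _ARCHETYPES.items():
        arch = (arch0, arch1)[date_idx]
        sel = cls == cond
        refl[sel] = arch
        bt[sel] = _SURFACE_BT[cond]
    # stand-to-stand variability: one offset per patch, band and date
    jitter = rng.normal(0.0, spec.patch_jitter_sd, size=(n_patches + 1, 6))
    refl = refl + jitter[patch_id]
    # sensor footprint: boundary pixels mix the spectra of adjacent patches
    if spec.psf_sigma > 0:
        for i in range(6):
            refl[..., i] = ndimage.gaussian_filter(refl[..., i], spec.psf_sigma)
        bt = ndimage.gaussian_filter(bt, spec.psf_sigma)
    refl = refl + rng.normal(0.0, spec.noise_sd, size=refl.shape)
    bt = bt + rng.normal(0.0, spec.thermal_noise_sd, size=bt.shape)
    bands = {role: np.clip(refl[..., i], 0.0, 1.0) for i, role in enumerate(BAND_ORDER)}
    return bands, bt


def _shadow_offset(spec: SceneSpec) -> tuple[int, int]:
    """(row, col) pixel displacement of a shadow from its cloud."""
    dist = spec.cloud_height * np.tan(np.deg2rad(spec.sun_zenith))
    az = np.deg2rad((spec.sun_azimuth + 180.0) % 360.0)  # anti-solar azimuth
    east = dist * np.sin(az)
    north = dist * np.cos(az)
    return int(round(-north / spec.pixel_size)), int(round(east / spec.pixel_size))


def _shift_mask(mask: np.ndarray, dr: int, dc: int) -> np.ndarray:
    out = np.zeros_like(mask)
    h, w = mask.shape
    rs, cs = np.nonzero(mask)
    rs, cs = rs + dr, cs + dc
    keep = (rs >= 0) & (rs < h) & (cs >= 0) & (cs < w)
    out[rs[keep], cs[keep]] = True
    return out


def generate_scene_pair(spec: SceneSpec) -> tuple[ScenePair, TruthMaps]:
    """Deterministically generate a pair and its truth from a spec."""
    rng = np.random.default_rng(spec.seed)
    h, w = spec.height, spec.width
    cls = np.full((h, w), NONFOREST, dtype=np.int32)
    patch_id = np.zeros((h, w), dtype=np.int64)  # 0 = background
    next_id = 1
    # paint in a fixed order so large classes don't swallow small ones
    total = h * w
    for cond in (WATER, FOREST, AGRICULTURE, DISTURBED, REGROWTH):
        next_id = _paint_patches(
            cls, patch_id, next_id, cond, int(spec.class_fractions()[cond] * total),
            spec, rng,
        )

    bands_e, bt_e = _render_date(cls, patch_id, next_id - 1, 0, spec, rng)
    bands_l, bt_l = _render_date(cls, patch_id, next_id - 1, 1, spec, rng)

    # clouds per date: square-ish patches, each with a displaced shadow
    dr, dc = _shadow_offset(spec)
    clouds, shadows = [], []
    target_cloud = int(spec.frac_cloud * total)
    for _ in range(2):
        cmask = np.zeros((h, w), dtype=bool)
        while cmask.sum() < target_cloud:
            edge = int(rng.integers(spec.patch_min, spec.patch_max + 1))
            r0 = int(rng.integers(0, max(1, h - edge)))
            c0 = int(rng.integers(0, max(1, w - edge)))
            cmask[r0 : r0 + edge, c0 : c0 + edge] = True
            if target_cloud == 0:
                break
        if target_cloud == 0:
            clouds.append(cmask)
            shadows.append(np.zeros_like(cmask))
            continue
        smask = _shift_mask(cmask, dr, dc) & ~cmask
        clouds.append(cmask)
        shadows.append(smask)

    for bands, bt, cmask, smask in (
        (bands_e, bt_e, clouds[0], shadows[0]),
        (bands_l, bt_l, clouds[1], shadows[1]),
    ):
        for role in BAND_ORDER:
            plane = bands[role]
            plane[smask] = plane[smask] * _SHADOW_FACTOR
            plane[cmask] = np.clip(
                _CLOUD_REFLECTANCE + rng.normal(0, spec.noise_sd, int(cmask.sum())),
                0.0,
                1.0,
            )
        bt[cmask] = _CLOUD_BT + rng.normal(0, spec.thermal_noise_sd, int(cmask.sum()))

    grid = default_grid((h, w), spec.pixel_size)
    nodata = np.zeros((h, w), dtype=bool)
    early = Scene(
        date=spec.date_early,
        bands=bands_e,
        thermal=bt_e,
        nodata_mask=nodata.copy(),
        sun_zenith=spec.sun_zenith,
        sun_azimuth=spec.sun_azimuth,
        grid=grid,
    )
    late = Scene(
        date=spec.date_late,
        bands=bands_l,
        thermal=bt_l,
        nodata_mask=nodata.copy(),
        sun_zenith=spec.sun_zenith,
        sun_azimuth=spec.sun_azimuth,
        grid=grid,
    )
    pair = ScenePair(early=early, late=late)

    change = np.full((h, w), CHANGE_NONE, dtype=np.int32)
    change[cls == DISTURBED] = CHANGE_DISTURBED
    change[cls == REGROWTH] = CHANGE_REGROWTH
    truth = TruthMaps(
        condition=cls,
        change=change,
        forest_early=(cls == FOREST) | (cls == DISTURBED),
        forest_late=(cls == FOREST) | (cls == REGROWTH),
        water=cls == WATER,
        cloud_early=clouds[0],
        cloud_late=clouds[1],
        shadow_early=shadows[0],
        shadow_late=shadows[1],
    )
    return pair, truth
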