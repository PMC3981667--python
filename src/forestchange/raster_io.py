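"""Scene and map containers plus TIFF / GeoJSON / YAML-sidecar I/O.

A :class:`Scene` is one acquisition date: six reflective bands as top-of-
atmosphere reflectance fractions in [0, 1], an optional thermal brightness-
temperature plane in Kelvin, a nodata mask, solar geometry and a grid
(geotransform + CRS).  A :class:`ScenePair` is two co-registered scenes in
chronological order.  Rasters are stored as plain multi-band TIFF with the
georeferencing, acquisition date, solar geometry and band order in a YAML
sidecar next to the raster; class maps additionally carry a GeoJSON polygon
layer.  All algorithms in this package work in 0-based, row-major pixel
coordinates; the geotransform is applied only at I/O boundaries.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Mapping

import numpy as np
import tifffile
import yaml
from shapely import affinity
from shapely.geometry import mapping as shapely_mapping
from shapely.ops import unary_union
from shapely.geometry import box as shapely_box
from skimage.measure import label as cc_label

BAND_ORDER = ("blue", "green", "red", "nir", "swir1", "swir2")

#: final map code table
CLASS_CODES = {
    "nodata": 0,
    "disturbed": 1,
    "stable_forest": 2,
    "stable_nonforest": 3,
    "water": 4,
    "cloud": 5,
    "cloud_shadow": 6,
}
CODE_NAMES = {v: k for k, v in CLASS_CODES.items()}


class RegistrationError(ValueError):
    """Raised when rasters that must share a grid do not."""


@dataclass(frozen=True)
class Grid:
    """Geotransform (GDAL-style 6-tuple), CRS string and raster shape."""

    transform: tuple[float, float, float, float, float, float]
    crs: str
    shape: tuple[int, int]  # (rows, cols)

    @property
    def pixel_size(self) -> float:
        return abs(self.transform[1])

    def matches(self, other: "Grid") -> bool:
        return (
            self.shape == other.shape
            and self.crs == other.crs
            and np.allclose(self.transform, other.transform)
        )


def default_grid(shape: tuple[int, int], pixel_size: float = 30.0) -> Grid:
    """A simple north-up grid: origin (0, 0), square pixels."""
    return Grid(
        transform=(0.0, pixel_size, 0.0, 0.0, 0.0, -pixel_size),
        crs="EPSG:32615",
        shape=shape,
    )


@dataclass
class Scene:
    date: _dt.date
    bands: dict[str, np.ndarray]  # role -> (H, W) float reflectance
    thermal: np.ndarray | None  # (H, W) Kelvin, or None
    nodata_mask: np.ndarray  # (H, W) bool, True where invalid
    sun_zenith: float  # degrees
    sun_azimuth: float  # degrees clockwise from north
    grid: Grid

    def __post_init__(self) -> None:
        shp = self.grid.shape
        for role in BAND_ORDER:
            if role not in self.bands:
                raise ValueError(f"missing band {role!r}")
            if self.bands[role].shape != shp:
                raise RegistrationError(f"band {role!r} shape != grid shape")
        if self.thermal is not None and self.thermal.shape != shp:
            raise RegistrationError("thermal shape != grid shape")
        if self.nodata_mask.shape != shp:
            raise RegistrationError("nodata_mask shape != grid shape")
        if not 0 <= self.sun_zenith < 90:
            raise ValueError("sun_zenith must lie in [0, 90)")
        if not 0 <= self.sun_azimuth < 360:
            raise ValueError("sun_azimuth must lie in [0, 360)")
        ok = ~self.nodata_mask
        for role in BAND_ORDER:
            vals = self.bands[role][ok]
            if vals.size and (vals.min() < -1e-6 or vals.max() > 1 + 1e-6):
                raise ValueError(
                    f"band {role!r} has reflectance outside [0, 1] on valid pixels"
                )

    @property
    def shape(self) -> tuple[int, int]:
        return self.grid.shape

    def band_stack(self) -> np.ndarray:
        """(H, W, 6) reflectance stack in canonical band order."""
        return np.stack([self.bands[r] for r in BAND_ORDER], axis=-1)


@dataclass
class ScenePair:
    early: Scene
    late: Scene

    def __post_init__(self) -> None:
        if not self.early.grid.matches(self.late.grid):
            raise RegistrationError("scene grids do not match")
        if self.early.date >= self.late.date:
            raise ValueError("early.date must precede late.date")

    @property
    def grid(self) -> Grid:
        return self.early.grid

    @property
    def nodata_mask(self) -> np.ndarray:
        return self.early.nodata_mask | self.late.nodata_mask

    def swapped(self) -> "ScenePair":
        """The same pair with the date roles exchanged (for symmetry tests)."""
        pair = ScenePair.__new__(ScenePair)
        pair.early = self.late
        pair.late = self.early
        return pair


def pair_scenes(a: Scene, b: Scene) -> ScenePair:
    """Build a chronologically ordered pair regardless of argument order."""
    if not a.grid.matches(b.grid):
        raise RegistrationError("scene grids do not match")
    if a.date == b.date:
        raise ValueError("scenes must have distinct dates")
    early, late = (a, b) if a.date < b.date else (b, a)
    return ScenePair(early=early, late=late)


@dataclass
class MapPolygon:
    polygon_id: int
    class_code: int
    pixel_count: int
    geometry: Any  # shapely geometry in map coordinates

    @property
    def class_name(self) -> str:
        return CODE_NAMES[self.class_code]


@dataclass
class ChangeMap:
    """Final categorical raster plus its polygon layer."""

    class_raster: np.ndarray  # (H, W) uint8 codes 0..6
    grid: Grid
    polygons: list[MapPolygon] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_raster.shape != self.grid.shape:
            raise RegistrationError("class raster shape != grid shape")
        codes = np.unique(self.class_raster)
        if not np.isin(codes, list(CODE_NAMES)).all():
            raise ValueError("class raster contains codes outside 0..6")


# ---------------------------------------------------------------------------
# scene I/O
# ---------------------------------------------------------------------------

def write_scene(scene: Scene, raster_path: str | Path) -> None:
    """Write a scene as a multi-band float32 TIFF plus a YAML sidecar."""
    raster_path = Path(raster_path)
    planes = [scene.bands[r].astype(np.float32) for r in BAND_ORDER]
    band_names = list(BAND_ORDER)
    if scene.thermal is not None:
        planes.append(scene.thermal.astype(np.float32))
        band_names.append("thermal")
    planes.append(scene.nodata_mask.astype(np.float32))
    band_names.append("nodata")
    tifffile.imwrite(raster_path, np.stack(planes, axis=0))
    meta = {
        "date": scene.date.isoformat(),
        "sun_zenith": float(scene.sun_zenith),
        "sun_azimuth": float(scene.sun_azimuth),
        "bands": band_names,
        "geotransform": [float(v) for v in scene.grid.transform],
        "crs": scene.grid.crs,
        "reflectance_scale": 1.0,
    }
    _sidecar(raster_path).write_text(yaml.safe_dump(meta, sort_keys=True))


def _sidecar(raster_path: Path) -> Path:
    return raster_path.with_suffix(raster_path.suffix + ".yaml")


def read_scene(
    band_paths: str | Path | Mapping[str, str | Path],
    metadata: str | Path | Mapping[str, Any] | None = None,
) -> Scene:
    """Read a scene from one stacked TIFF or a mapping of per-band TIFFs.

    ``metadata`` may be a YAML sidecar path or an already-parsed mapping; when
    ``band_paths`` is a single stacked raster written by :func:`write_scene`
    the sidecar is found automatically.  Reflectance is divided by the
    sidecar's ``reflectance_scale`` so stored integers scale to fractions.
    Nodata holes from any band propagate to the scene mask.
    """
    if isinstance(band_paths, (str, Path)):
        raster_path = Path(band_paths)
        meta = _load_meta(metadata, default=_sidecar(raster_path))
        stack = tifffile.imread(raster_path)
        if stack.ndim == 2:
            stack = stack[None]
        names = meta["bands"]
        if len(names) != stack.shape[0]:
            raise RegistrationError("band list in sidecar does not match raster")
        planes = {n: stack[i].astype(np.float64) for i, n in enumerate(names)}
    else:
        meta = _load_meta(metadata, default=None)
        planes = {}
        shape = None
        for role, p in band_paths.items():
            arr = tifffile.imread(Path(p)).astype(np.float64)
            if shape is None:
                shape = arr.shape
            elif arr.shape != shape:
                raise RegistrationError(f"band {role!r} grid differs from the others")
            planes[role] = arr

    scale = float(meta.get("reflectance_scale", 1.0))
    shape = next(iter(planes.values())).shape
    nodata = planes.pop("nodata", np.zeros(shape)) > 0.5
    thermal = planes.pop("thermal", None)
    bands = {}
    for role in BAND_ORDER:
        if role not in planes:
            raise ValueError(f"missing band {role!r}")
        plane = planes[role] / scale
        nodata |= ~np.isfinite(plane)
        bands[role] = np.where(np.isfinite(plane), plane, 0.0)
    for role in BAND_ORDER:
        bands[role] = np.where(nodata, 0.0, np.clip(bands[role], 0.0, 1.0))
    grid = Grid(
        transform=tuple(float(v) for v in meta["geotransform"]),
        crs=str(meta["crs"]),
        shape=shape,
    )
    return Scene(
        date=_dt.date.fromisoformat(str(meta["date"])),
        bands=bands,
        thermal=thermal,
        nodata_mask=nodata,
        sun_zenith=float(meta["sun_zenith"]),
        sun_azimuth=float(meta["sun_azimuth"]),
        grid=grid,
    )


def _load_meta(metadata, default: Path | None) -> Mapping[str, Any]:
    if metadata is None:
        if default is None or not default.exists():
            raise ValueError("scene metadata is required")
        metadata = default
    if isinstance(metadata, (str, Path)):
        return yaml.safe_load(Path(metadata).read_text())
    return metadata


# ---------------------------------------------------------------------------
# polygon layer
# ---------------------------------------------------------------------------

def _region_geometry(mask: np.ndarray) -> Any:
    """Union of per-row pixel-run rectangles, in pixel coordinates.

    Row runs keep the box count proportional to the region's row extent
    rather than its area, so vectorizing large stable regions stays cheap.
    Pixel (r, c) covers the unit square [c, c+1] x [r, r+1].
    """
    boxes = []
    rows, cols = np.nonzero(mask)
    for r in np.unique(rows):
        cc = np.sort(cols[rows == r])
        breaks = np.nonzero(np.diff(cc) > 1)[0]
        starts = np.concatenate(([0], breaks + 1))
        ends = np.concatenate((breaks, [len(cc) - 1]))
        for s, e in zip(starts, ends):
            boxes.append(shapely_box(float(cc[s]), float(r), float(cc[e]) + 1.0, float(r) + 1.0))
    return unary_union(boxes)


def _pixel_to_map(geom: Any, grid: Grid) -> Any:
    gt = grid.transform
    # x = gt0 + col*gt1 + row*gt2 ; y = gt3 + col*gt4 + row*gt5
    return affinity.affine_transform(geom, [gt[1], gt[2], gt[4], gt[5], gt[0], gt[3]])


def vectorize(class_raster: np.ndarray, grid: Grid) -> list[MapPolygon]:
    """8-connected regions of equal class code, as map-coordinate polygons.

    Nodata (code 0) is not vectorized; the polygon layer tiles the
    classified area exactly (areas in pixel units sum to the classified
    pixel count).
    """
    polygons: list[MapPolygon] = []
    pid = 0
    for code in sorted(np.unique(class_raster)):
        if code == CLASS_CODES["nodata"]:
            continue
        labeled = cc_label(class_raster == code, connectivity=2)
        for region in range(1, labeled.max() + 1):
            mask = labeled == region
            geom = _pixel_to_map(_region_geometry(mask), grid)
            pid += 1
            polygons.append(
                MapPolygon(
                    polygon_id=pid,
                    class_code=int(code),
                    pixel_count=int(mask.sum()),
                    geometry=geom,
                )
            )
    return polygons


def write_change_map(
    cmap: ChangeMap, raster_path: str | Path, vector_path: str | Path | None = None
) -> None:
    """Write the class raster (TIFF + sidecar with the code table) and polygons."""
    raster_path = Path(raster_path)
    tifffile.imwrite(raster_path, cmap.class_raster.astype(np.uint8))
    meta = {
        "geotransform": [float(v) for v in cmap.grid.transform],
        "crs": cmap.grid.crs,
        "class_codes": dict(CLASS_CODES),
    }
    _sidecar(raster_path).write_text(yaml.safe_dump(meta, sort_keys=True))
    if vector_path is not None:
        features = [
            {
                "type": "Feature",
                "properties": {
                    "polygon_id": p.polygon_id,
                    "class_code": p.class_code,
                    "class_name": p.class_name,
                    "pixel_count": p.pixel_count,
                },
                "geometry": shapely_mapping(p.geometry),
            }
            for p in cmap.polygons
        ]
        Path(vector_path).write_text(
            json.dumps({"type": "FeatureCollection", "features": features})
        )


def read_change_map(raster_path: str | Path) -> ChangeMap:
    raster_path = Path(raster_path)
    raster = tifffile.imread(raster_path).astype(np.uint8)
    meta = yaml.safe_load(_sidecar(raster_path).read_text())
    grid = Grid(
        transform=tuple(float(v) for v in meta["geotransform"]),
        crs=str(meta["crs"]),
        shape=raster.shape,
    )
    cmap = ChangeMap(class_raster=raster, grid=grid)
    cmap.polygons = vectorize(raster, grid)
    return cmap
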