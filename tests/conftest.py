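import datetime as dt

import numpy as np
import pytest

from forestchange import (
    PipelineConfig,
    Scene,
    ScenePair,
    SceneSpec,
    generate_scene_pair,
)
from forestchange.raster_io import BAND_ORDER, default_grid


def make_scene(
    bands: dict[str, np.ndarray] | None = None,
    shape: tuple[int, int] = (8, 8),
    date: dt.date = dt.date(2000, 7, 1),
    fill: float = 0.1,
    thermal: float | np.ndarray | None = 290.0,
    sun_zenith: float = 30.0,
    sun_azimuth: float = 135.0,
    nodata: np.ndarray | None = None,
    pixel_size: float = 30.0,
) -> Scene:
    """Constant-fill scene with selected bands overridden."""
    if bands:
        bands = {k: np.asarray(v, dtype=float) for k, v in bands.items()}
        shape = next(iter(bands.values())).shape
    full = {role: np.full(shape, fill) for role in BAND_ORDER}
    if bands:
        full.update(bands)
    if isinstance(thermal, (int, float)):
        thermal = np.full(shape, float(thermal))
    return Scene(
        date=date,
        bands=full,
        thermal=thermal,
        nodata_mask=nodata if nodata is not None else np.zeros(shape, dtype=bool),
        sun_zenith=sun_zenith,
        sun_azimuth=sun_azimuth,
        grid=default_grid(shape, pixel_size),
    )


def make_pair(early: Scene, late: Scene) -> ScenePair:
    return ScenePair(early=early, late=late)


@pytest.fixture(scope="session")
def small_cfg() -> PipelineConfig:
    """Config adapted to small test rasters (windows sized to the scene)."""
    return PipelineConfig(
        window_size=80,
        rng_seed=7,
        svm_c_exp=(-1, 7, 2),
        svm_gamma_exp=(-5, 1, 2),
        grid_search_max_samples=600,
    )


@pytest.fixture(scope="session")
def small_scene_pair():
    """A 160x160 synthetic pair with truth, shared across tests."""
    spec = SceneSpec(width=160, height=160, seed=7)
    return generate_scene_pair(spec)


@pytest.fixture(scope="session")
def small_pipeline_result(small_scene_pair, small_cfg):
    from forestchange import run_pipeline

    pair, _ = small_scene_pair
    return run_pipeline(pair, small_cfg, sensor="TM")
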