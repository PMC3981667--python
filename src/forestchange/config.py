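"""Central pipeline configuration.

Every tunable constant used anywhere in the pipeline lives here, so a run is
fully described by one :class:`PipelineConfig` plus the input scene pair.
Defaults follow the published method where it states a value (threshold
multiplier 1.5, 400-pixel local windows, 25 % SWIR / 0.3 NDVI water cutoffs,
six-pixel minimum mapping unit, 10-fold cross-validation, 70 % filter
training fraction) and documented package choices where it does not.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Any

import yaml

logger = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Raised when a configuration file cannot be parsed or validated."""


@dataclass
class PipelineConfig:
    # --- training extraction (local-window thresholding) ---
    #: tail threshold in sigma-multiples; fixed across all windows and images
    threshold_multiplier: float = 1.5
    #: local window edge length in pixels
    window_size: int = 400
    #: window stride in pixels; None means stride = window_size (tiling)
    window_stride: int | None = None
    #: half-width of the no-change band in sigma-multiples
    no_change_band: float = 0.5
    #: minimum samples in each tail for a window to contribute training data
    min_tail_count: int = 25
    #: minimum fraction of a window that must be valid (unmasked) pixels
    window_min_valid_frac: float = 0.25
    #: cap on the total extracted training set (stratified subsample, seeded);
    #: keeps the filter and classifier tractable on large scenes
    max_training_samples: int = 6000

    # --- water rule ---
    #: SWIR reflectance ceiling for water (fraction)
    water_swir_max: float = 0.25
    #: NDVI ceiling for water
    water_ndvi_max: float = 0.3

    # --- forest dark-peak rule ---
    #: red-band histogram bin width (reflectance fraction)
    forest_hist_bin_width: float = 0.005
    #: moving-average smoothing span, in bins
    forest_hist_smooth_bins: int = 3
    #: a histogram mode is prominent if its count >= this fraction of the window
    forest_peak_prominence_frac: float = 0.05
    #: threshold margin floor, in bins, added to the dark-peak location
    forest_peak_margin_bins: int = 2
    #: a peak darker than this red reflectance can qualify as the forest peak
    forest_peak_max_red: float = 0.10

    # --- cloud / cloud-shadow screen ---
    cloud_blue_min: float = 0.25
    cloud_swir_min: float = 0.15
    #: max relative spread of visible bands around their mean (whiteness test)
    cloud_whiteness_max: float = 0.35
    #: clouds must be at least this many Kelvin below the scene median BT
    cloud_bt_margin: float = 4.0
    #: NIR ceiling identifying dark (shadow-candidate) pixels
    shadow_nir_max: float = 0.12
    #: candidate cloud heights for geometric shadow projection (metres)
    cloud_height_min: float = 200.0
    cloud_height_max: float = 3000.0
    cloud_height_step: float = 200.0

    # --- consensus label-noise filter ---
    n_folds: int = 10
    filter_train_frac: float = 0.70
    #: "consensus" removes a sample only when every filter classifier missed it;
    #: "majority" (off by default) removes on a majority of misses
    filter_mode: str = "consensus"
    filter_enabled: bool = True
    #: fixed filter-classifier hyperparameters (the choice is deliberately plain;
    #: only the consensus matters)
    filter_tree_max_depth: int = 10
    filter_knn_k: int = 5
    filter_mlp_hidden: int = 16
    filter_mlp_max_iter: int = 300

    # --- final SVM ---
    #: log2 grid for the penalty C: exponents -5..15 step 2
    svm_c_exp: tuple[int, int, int] = (-5, 15, 2)
    #: log2 grid for the RBF width gamma: exponents -15..3 step 2
    svm_gamma_exp: tuple[int, int, int] = (-15, 3, 2)
    grid_cv_folds: int = 5
    #: stratified subsample cap used during grid search (speed; the winning
    #: parameters are refit on the full training set)
    grid_search_max_samples: int = 2000

    # --- post-processing ---
    morph_radius: int = 1
    #: region-merge stopping distance on 6-band mean vectors (reflectance units)
    merge_threshold: float = 0.05
    mmu: int = 6

    # --- validation ---
    n_samples_per_stratum: int = 100

    # --- misc ---
    #: which SWIR band drives the difference image
    swir_band: str = "swir1"
    #: one global seed governs every stochastic stage
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.validate()

    # -- validation -------------------------------------------------------
    def validate(self) -> None:
        if not self.threshold_multiplier > 0:
            raise ConfigError("threshold_multiplier must be > 0")
        if not 0 < self.filter_train_frac < 1:
            raise ConfigError("filter_train_frac must lie in (0, 1)")
        if self.mmu < 1:
            raise ConfigError("mmu must be >= 1")
        if self.n_folds < 2:
            raise ConfigError("n_folds must be >= 2")
        if self.window_size < 16:
            raise ConfigError("window_size must be >= 16")
        if self.window_stride is not None and self.window_stride < 1:
            raise ConfigError("window_stride must be >= 1")
        if self.no_change_band <= 0:
            raise ConfigError("no_change_band must be > 0")
        if self.min_tail_count < 1:
            raise ConfigError("min_tail_count must be >= 1")
        if not 0 <= self.window_min_valid_frac <= 1:
            raise ConfigError("window_min_valid_frac must lie in [0, 1]")
        if self.filter_mode not in ("consensus", "majority"):
            raise ConfigError("filter_mode must be 'consensus' or 'majority'")
        if self.swir_band not in ("swir1", "swir2"):
            raise ConfigError("swir_band must be 'swir1' or 'swir2'")
        if self.forest_hist_bin_width <= 0:
            raise ConfigError("forest_hist_bin_width must be > 0")
        if self.merge_threshold <= 0:
            raise ConfigError("merge_threshold must be > 0")
        for name in ("svm_c_exp", "svm_gamma_exp"):
            rng = getattr(self, name)
            if len(rng) != 3 or rng[2] <= 0 or rng[1] < rng[0]:
                raise ConfigError(f"{name} must be (lo, hi, step) with step > 0, hi >= lo")

    # -- derived ----------------------------------------------------------
    @property
    def effective_stride(self) -> int:
        return self.window_stride if self.window_stride is not None else self.window_size

    def c_grid(self) -> list[float]:
        lo, hi, step = self.svm_c_exp
        return [2.0**e for e in range(lo, hi + 1, step)]

    def gamma_grid(self) -> list[float]:
        lo, hi, step = self.svm_gamma_exp
        return [2.0**e for e in range(lo, hi + 1, step)]

    # -- (de)serialization -------------------------------------------------
    def to_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["svm_c_exp"] = list(self.svm_c_exp)
        d["svm_gamma_exp"] = list(self.svm_gamma_exp)
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        known = {f.name: f for f in dataclasses.fields(cls)}
        kwargs: dict[str, Any] = {}
        for key, value in data.items():
            if key not in known:
                raise ConfigError(f"unknown configuration key: {key!r}")
            if key in ("svm_c_exp", "svm_gamma_exp"):
                value = tuple(int(v) for v in value)
            kwargs[key] = value
        try:
            return cls(**kwargs)
        except TypeError as exc:  # wrong type for a field
            raise ConfigError(str(exc)) from exc


def load_config(path: str | Path | None = None) -> PipelineConfig:
    """Load a YAML config file; unspecified fields take documented defaults.

    An empty or absent file yields the all-default configuration.  The full
    effective configuration (defaults plus overrides) is logged.
    """
    if path is None:
        cfg = PipelineConfig()
    else:
        text = Path(path).read_text()
        try:
            data = yaml.safe_load(text)
        except yaml.YAMLError as exc:
            raise ConfigError(f"cannot parse config file {path}: {exc}") from exc
        if data is None:
            cfg = PipelineConfig()
        elif not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
        else:
            cfg = PipelineConfig.from_dict(data)
    logger.info("effective configuration: %s", cfg.to_dict())
    return cfg
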