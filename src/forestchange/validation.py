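"""Stratified polygon sampling and map-accuracy metrics.

Accuracy is assessed on two strata of the final map — forest disturbance
and stable forest — by drawing up to ``n_samples_per_stratum`` polygons
uniformly without replacement from each stratum, attaching a reference
label to each (for synthetic data, the plurality of per-pixel truth), and
tabulating a map-by-reference confusion matrix.  Each polygon counts as one
unit (per-site assessment); area weighting is available as an option.
Reported metrics: overall accuracy, per-class user's and producer's
accuracy, and the ROC point (TPR, FPR) of the disturbance class.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .config import PipelineConfig
from .raster_io import CLASS_CODES, ChangeMap, MapPolygon
from .synthetic_scene import CHANGE_DISTURBED, TruthMaps

logger = logging.getLogger(__name__)

#: strata under assessment (map codes)
STRATA = ("disturbed", "stable_forest")


@dataclass
class AccuracyReport:
    """Confusion matrix and derived accuracies, rows = map, cols = reference."""

    confusion: np.ndarray  # (2, 2) counts, order = STRATA
    class_names: tuple[str, ...] = STRATA

    @property
    def total(self) -> int:
        return int(self.confusion.sum())

    @property
    def overall_accuracy(self) -> float:
        return float(np.trace(self.confusion)) / self.total if self.total else float("nan")

    def users_accuracy(self, cls: str) -> float:
        i = self.class_names.index(cls)
        row = self.confusion[i].sum()
        return float(self.confusion[i, i]) / row if row else float("nan")

    def producers_accuracy(self, cls: str) -> float:
        i = self.class_names.index(cls)
        col = self.confusion[:, i].sum()
        return float(self.confusion[i, i]) / col if col else float("nan")

    @property
    def tpr(self) -> float:
        """Fraction of truly disturbed sites mapped as disturbed."""
        return self.producers_accuracy("disturbed")

    @property
    def fpr(self) -> float:
        """Fraction of truly stable sites mapped as disturbed."""
        i = self.class_names.index("disturbed")
        j = self.class_names.index("stable_forest")
        col = self.confusion[:, j].sum()
        return float(self.confusion[i, j]) / col if col else float("nan")

    def to_dict(self) -> dict:
        return {
            "confusion": self.confusion.tolist(),
            "class_order": list(self.class_names),
            "overall_accuracy": self.overall_accuracy,
            "users_accuracy": {c: self.users_accuracy(c) for c in self.class_names},
            "producers_accuracy": {c: self.producers_accuracy(c) for c in self.class_names},
            "tpr": self.tpr,
            "fpr": self.fpr,
            "n_sites": self.total,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    def to_text(self) -> str:
        lines = ["confusion matrix (rows = map, cols = reference):"]
        header = "".join(f"{c:>16}" for c in self.class_names)
        lines.append(" " * 16 + header)
        for i, c in enumerate(self.class_names):
            lines.append(f"{c:>16}" + "".join(f"{v:>16d}" for v in self.confusion[i]))
        lines.append(f"overall accuracy: {self.overall_accuracy:.3f}")
        for c in self.class_names:
            lines.append(
                f"{c}: user's {self.users_accuracy(c):.3f}, "
                f"producer's {self.producers_accuracy(c):.3f}"
            )
        lines.append(f"disturbance TPR {self.tpr:.3f}, FPR {self.fpr:.3f}")
        return "\n".join(lines)


def stratified_sample(
    cmap: ChangeMap, cfg: PipelineConfig
) -> list[MapPolygon]:
    """Up to n_samples_per_stratum polygons per stratum, without replacement."""
    rng = np.random.default_rng(cfg.rng_seed + 3)
    sample: list[MapPolygon] = []
    for stratum in STRATA:
        code = CLASS_CODES[stratum]
        pool = [p for p in cmap.polygons if p.class_code == code]
        if not pool:
            warnings.warn(f"stratum {stratum!r} has no polygons; zero samples drawn")
            continue
        k = min(cfg.n_samples_per_stratum, len(pool))
        if k < cfg.n_samples_per_stratum:
            warnings.warn(
                f"stratum {stratum!r} has only {len(pool)} polygons; all returned"
            )
        picked = rng.choice(len(pool), size=k, replace=False)
        sample.extend(pool[i] for i in sorted(picked))
    return sample


def _polygon_pixels(poly: MapPolygon, cmap: ChangeMap) -> tuple[np.ndarray, np.ndarray]:
    """Pixel coordinates of one map polygon, recovered from the class raster."""
    from skimage.measure import label as cc_label

    labeled = cc_label(cmap.class_raster == poly.class_code, connectivity=2)
    # locate the component containing the polygon's representative point
    rep = poly.geometry.representative_point()
    gt = cmap.grid.transform
    det = gt[1] * gt[5] - gt[2] * gt[4]
    col = ((rep.x - gt[0]) * gt[5] - (rep.y - gt[3]) * gt[2]) / det
    row = ((rep.y - gt[3]) * gt[1] - (rep.x - gt[0]) * gt[4]) / det
    r, c = int(row), int(col)
    region = labeled[r, c]
    if region == 0:
        raise ValueError("polygon representative point falls outside its class")
    return np.nonzero(labeled == region)


def reference_label(
    poly: MapPolygon, cmap: ChangeMap, truth: TruthMaps
) -> str:
    """Plurality of per-pixel truth within the polygon: disturbed vs stable."""
    rows, cols = _polygon_pixels(poly, cmap)
    n_dist = int((truth.change[rows, cols] == CHANGE_DISTURBED).sum())
    return "disturbed" if n_dist * 2 > len(rows) else "stable_forest"


def assess(
    sample: list[MapPolygon],
    cmap: ChangeMap,
    truth: TruthMaps | dict[int, str],
    area_weighted: bool = False,
) -> AccuracyReport:
    """Confusion matrix over the sampled polygons.

    ``truth`` is either the generator's TruthMaps (reference = plurality of
    truth pixels) or a mapping polygon_id -> reference label.
    """
    confusion = np.zeros((2, 2), dtype=np.int64)
    for poly in sample:
        map_label = poly.class_name
        if map_label not in STRATA:
            raise ValueError(f"sampled polygon has non-assessed class {map_label!r}")
        if isinstance(truth, TruthMaps):
            ref = reference_label(poly, cmap, truth)
        else:
            ref = truth[poly.polygon_id]
        if ref not in STRATA:
            raise ValueError(f"reference label {ref!r} outside assessed vocabulary")
        weight = poly.pixel_count if area_weighted else 1
        confusion[STRATA.index(map_label), STRATA.index(ref)] += weight
    return AccuracyReport(confusion=confusion)
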