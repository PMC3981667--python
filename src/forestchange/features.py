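"""Tasseled-cap (Kauth–Thomas) features and the SWIR difference image.

The final classifier consumes a six-plane stack: the early date's
brightness, greenness and wetness, plus the multi-temporal change indices
ΔB, ΔG, ΔW (late minus early).  Anchoring on the early-date indices pins
the pre-disturbance condition of the forest; the change indices carry the
disturbance signal and a falling wetness (ΔW < 0) marks clearing.

Training extraction instead uses the plain SWIR difference d = early − late,
oriented so that disturbance (forest → cleared, SWIR rising) sits in the
negative tail and regrowth in the positive tail.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .raster_io import BAND_ORDER, Scene, ScenePair

FEATURE_NAMES = ("brightness_1", "greenness_1", "wetness_1",
                 "delta_brightness", "delta_greenness", "delta_wetness")


@dataclass(frozen=True)
class KTCoefficients:
    """A 3x6 matrix mapping the six reflective bands to (B, G, W)."""

    sensor: str
    matrix: np.ndarray  # (3, 6), rows = brightness, greenness, wetness
    citation: str

    def __post_init__(self) -> None:
        object.__setattr__(self, "matrix", np.asarray(self.matrix, dtype=float))
        if self.matrix.shape != (3, 6):
            raise ValueError("KT coefficient matrix must be 3x6")


# Reflectance-based tasseled-cap coefficients from the standard literature.
_COEFFICIENTS = {
    "TM": KTCoefficients(
        sensor="TM",
        matrix=np.array(
            [
                [0.2043, 0.4158, 0.5524, 0.5741, 0.3124, 0.2303],
                [-0.1603, -0.2819, -0.4934, 0.7940, -0.0002, -0.1446],
                [0.0315, 0.2021, 0.3102, 0.1594, -0.6806, -0.6109],
            ]
        ),
        citation="Crist (1985), Remote Sens. Environ. 17:301-306 (TM reflectance factors)",
    ),
    "ETM+": KTCoefficients(
        sensor="ETM+",
        matrix=np.array(
            [
                [0.3561, 0.3972, 0.3904, 0.6966, 0.2286, 0.1596],
                [-0.3344, -0.3544, -0.4556, 0.6966, -0.0242, -0.2630],
                [0.2626, 0.2141, 0.0926, 0.0656, -0.7629, -0.5388],
            ]
        ),
        citation="Huang et al. (2002), Int. J. Remote Sens. 23:1741-1748 (ETM+ at-satellite reflectance)",
    ),
    # Documented identity-like stand-in so unit tests and synthetic runs do
    # not depend on literature constants: brightness = band mean, greenness
    # contrasts NIR with red, wetness is (negated) SWIR content.
    "SYNTHETIC": KTCoefficients(
        sensor="SYNTHETIC",
        matrix=np.array(
            [
                [1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6, 1 / 6],
                [0.0, 0.0, -np.sqrt(0.5), np.sqrt(0.5), 0.0, 0.0],
                [0.0, 0.0, 0.0, 0.0, -np.sqrt(0.5), -np.sqrt(0.5)],
            ]
        ),
        citation="synthetic stand-in matrix (package-defined, not from the literature)",
    ),
}


def kt_coefficients(sensor: str) -> KTCoefficients:
    try:
        return _COEFFICIENTS[sensor]
    except KeyError:
        raise KeyError(
            f"no packaged tasseled-cap coefficients for sensor {sensor!r}; "
            f"available: {sorted(_COEFFICIENTS)}"
        ) from None


def kt_transform(
    scene: Scene, coeffs: KTCoefficients
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Brightness, greenness, wetness planes: a pure linear map, no offset."""
    stack = scene.band_stack()  # (H, W, 6)
    out = stack @ coeffs.matrix.T  # (H, W, 3)
    return out[..., 0], out[..., 1], out[..., 2]


@dataclass
class FeatureStack:
    """Planes [B1, G1, W1, dB, dG, dW] on the pair grid."""

    planes: np.ndarray  # (H, W, 6)
    sensor: str

    def __post_init__(self) -> None:
        if self.planes.ndim != 3 or self.planes.shape[-1] != 6:
            raise ValueError("FeatureStack requires exactly six planes")

    @property
    def shape(self) -> tuple[int, int]:
        return self.planes.shape[:2]

    def vectors(self, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
        """6-feature vectors at the given pixel coordinates, (n, 6)."""
        return self.planes[rows, cols, :]


def mkt_stack(pair: ScenePair, coeffs: KTCoefficients) -> FeatureStack:
    """Six-plane multi-temporal tasseled-cap stack; Δ = late − early."""
    b1, g1, w1 = kt_transform(pair.early, coeffs)
    b2, g2, w2 = kt_transform(pair.late, coeffs)
    planes = np.stack([b1, g1, w1, b2 - b1, g2 - g1, w2 - w1], axis=-1)
    return FeatureStack(planes=planes, sensor=coeffs.sensor)


@dataclass
class DiffImage:
    """SWIR difference d = early − late: disturbance in the negative tail."""

    data: np.ndarray  # (H, W)
    band: str


def swir_difference(pair: ScenePair, band: str = "swir1") -> DiffImage:
    if band not in BAND_ORDER:
        raise ValueError(f"unknown band {band!r}")
    return DiffImage(data=pair.early.bands[band] - pair.late.bands[band], band=band)
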