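"""Anatomical factors from annotations: landmark distances, caliber, normalization.

The detection of the optic disc, fovea and artery/vein labels happens
upstream; this module consumes their coordinates and turns them into the
normalized [0, 1] factors the weighted metric combines. Distances are
measured from the vessel's *center point*, defined as the point at half arc
length along the centerline (robust to nonuniform sampling), to the
landmark center. Distance factors are inverted and bounded so that vessels
closer to the optic disc or the fovea receive larger factors; calibers are
normalized per image by default so resolution does not leak into the factor.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .config import MetricConfig
from .errors import AnnotationError, ConfigError, ContractViolationError
from .geometry import Centerline
from .metrics import ARTERY, VEIN, AnatomicalProfile

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class LandmarkSet:
    """Optic-disc circle, fovea center, and the image frame they live in."""

    od_center: tuple[float, float]
    od_radius: float
    fovea_center: tuple[float, float]
    image_width: int
    image_height: int

    def __post_init__(self) -> None:
        if self.od_radius <= 0:
            raise ContractViolationError("od_radius must be positive")
        if self.image_width <= 0 or self.image_height <= 0:
            raise ContractViolationError("image dimensions must be positive")
        for name in ("od_center", "fovea_center"):
            x, y = getattr(self, name)
            if not (0 <= x <= self.image_width and 0 <= y <= self.image_height):
                raise ContractViolationError(f"{name} lies outside the image bounds")
        if tuple(self.od_center) == tuple(self.fovea_center):
            raise ContractViolationError("fovea_center must differ from od_center")
        # The fovea conventionally sits about two disc diameters from the
        # disc center; a layout far from that is suspicious but not fatal.
        d = math.dist(self.od_center, self.fovea_center)
        dd = 2.0 * self.od_radius
        if not (1.0 * dd <= d <= 3.5 * dd):
            logger.warning(
                "fovea-disc distance %.1f px is %.2f disc diameters from the disc "
                "center; ~2 is the usual anatomy", d, d / dd,
            )

    @property
    def half_diagonal(self) -> float:
        return 0.5 * math.hypot(self.image_width, self.image_height)


def center_point(c: Centerline) -> np.ndarray:
    """The point at half arc length along the centerline (interpolated)."""
    pts = c.points
    steps = np.linalg.norm(np.diff(pts, axis=0), axis=1)
    cum = np.concatenate([[0.0], np.cumsum(steps)])
    half = 0.5 * cum[-1]
    k = int(np.searchsorted(cum, half, side="right") - 1)
    k = min(k, len(steps) - 1)
    frac = (half - cum[k]) / steps[k]
    return pts[k] + frac * (pts[k + 1] - pts[k])


def distance_to_od(c: Centerline, landmarks: LandmarkSet) -> float:
    """Euclidean distance from the vessel center point to the optic-disc center."""
    return float(np.linalg.norm(center_point(c) - np.asarray(landmarks.od_center)))


def distance_to_fovea(c: Centerline, landmarks: LandmarkSet) -> float:
    """Euclidean distance from the vessel center point to the fovea center."""
    return float(np.linalg.norm(center_point(c) - np.asarray(landmarks.fovea_center)))


def aggregate_caliber(per_point_calibers) -> float:
    """Mean vessel caliber over the sampled width measurements (pixels)."""
    vals = np.asarray(per_point_calibers, dtype=float)
    if vals.size == 0:
        raise AnnotationError("caliber annotation is empty")
    if np.any(~np.isfinite(vals)) or np.any(vals <= 0):
        raise AnnotationError("caliber samples must be positive and finite")
    return float(vals.mean())


def _distance_scale(landmarks: LandmarkSet, config: MetricConfig) -> float:
    if config.distance_norm == "half-diagonal":
        return landmarks.half_diagonal
    if config.distance_norm == "absolute":
        return config.distance_scale_px
    if config.distance_norm == "disc-diameters":
        return config.distance_scale_dd * 2.0 * landmarks.od_radius
    raise ConfigError(f"unknown distance_norm {config.distance_norm!r}")


def normalize_distance(dist_px: float, landmarks: LandmarkSet,
                       config: MetricConfig | None = None) -> float:
    """Map a raw landmark distance to the bounded proximity factor in [0, 1].

    c_d = max(0, 1 - d / D_norm): zero distance gives the maximum factor 1,
    distances at or beyond the normalizing scale give 0, and the mapping is
    nonincreasing in the raw distance.
    """
    cfg = config or MetricConfig()
    scale = _distance_scale(landmarks, cfg)
    if scale <= 0:
        raise ConfigError("distance normalization scale is zero")
    return max(0.0, 1.0 - dist_px / scale)


def normalize_caliber(caliber_px: float, max_caliber_px: float,
                      config: MetricConfig | None = None) -> float:
    """Map a mean caliber to [0, 1] (per-image maximum by default)."""
    cfg = config or MetricConfig()
    denom = max_caliber_px if cfg.caliber_norm == "per-image" else cfg.caliber_scale_px
    if denom <= 0:
        raise ConfigError("caliber normalization denominator is zero")
    return float(np.clip(caliber_px / denom, 0.0, 1.0))


def normalize_profile(
    av_class: str,
    caliber_px: float,
    dist_od_px: float,
    dist_fovea_px: float,
    landmarks: LandmarkSet,
    max_caliber_px: float,
    config: MetricConfig | None = None,
) -> AnatomicalProfile:
    """Assemble the normalized :class:`AnatomicalProfile` of one vessel.

    The artery/vein indicator encodes artery = 0, vein = 1. A vessel whose
    center point lies inside the optic-disc circle saturates the disc
    proximity factor at 1 (the distance itself is still reported raw).
    """
    cfg = config or MetricConfig()
    if av_class not in (ARTERY, VEIN):
        raise AnnotationError(f"av_class must be artery/vein, got {av_class!r}")
    eff_dist_od = 0.0 if dist_od_px <= landmarks.od_radius else dist_od_px
    return AnatomicalProfile(
        av_class=av_class,
        caliber_px=caliber_px,
        dist_od_px=dist_od_px,
        dist_fovea_px=dist_fovea_px,
        c_av=0.0 if av_class == ARTERY else 1.0,
        c_caliber=normalize_caliber(caliber_px, max_caliber_px, cfg),
        c_dod=normalize_distance(eff_dist_od, landmarks, cfg),
        c_dfov=normalize_distance(dist_fovea_px, landmarks, cfg),
    )
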