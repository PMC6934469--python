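"""The tortuosity metric core.

Per vessel, the mathematical tortuosity is the constant-sign-curvature
(Grisan-style) measure

    tau_g = (n - 1) / L_c * sum_i (L_csi / L_xsi - 1)

where the centerline is decomposed into n subsegments of constant-sign
curvature, L_c is the vessel arc length and L_csi / L_xsi the arc and chord
length of subsegment i. Higher counts of convexity changes and higher
arc-to-chord excess both increase tau_g; a straight vessel or a single
constant-sign arc scores 0.

The anatomically weighted factor for a vessel is

    f_c = [ (w_AV*(1 - c_AV) + (1 - w_AV)*c_AV)
            + w_caliber*c_caliber + w_dOD*c_dOD + w_dFov*c_dFov ] * L_c

with normalized factors c in [0, 1]: the artery/vein indicator c_AV
(artery = 0, vein = 1, so w_AV is the weight granted to arteries and
1 - w_AV to veins), the per-image-normalized caliber, and bounded inverted
distances to the optic disc and to the fovea (closer => larger). The local
weighted tortuosity is tau_c = tau_g * f_c, and retina scores compose the
per-vessel values with f as the composition weight.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np

from .config import MetricConfig
from .errors import ContractViolationError, UndefinedScoreError
from .geometry import Centerline, arc_length, decompose_constant_sign

logger = logging.getLogger(__name__)

ARTERY = "artery"
VEIN = "vein"


@dataclass(frozen=True)
class AnatomicalProfile:
    """Raw and normalized anatomical factors of one vessel.

    c_av is the binary class indicator (artery = 0, vein = 1); the other
    normalized values lie in [0, 1] with "closer to the landmark" and
    "thicker relative to the image" mapping to larger values.
    """

    av_class: str
    caliber_px: float
    dist_od_px: float
    dist_fovea_px: float
    c_av: float
    c_caliber: float
    c_dod: float
    c_dfov: float

    def __post_init__(self) -> None:
        if self.av_class not in (ARTERY, VEIN):
            raise ContractViolationError(f"av_class must be artery/vein, got {self.av_class!r}")
        if self.c_av not in (0.0, 1.0):
            raise ContractViolationError(f"c_av must be exactly 0 or 1, got {self.c_av}")
        for name in ("c_caliber", "c_dod", "c_dfov"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractViolationError(f"{name}={v} outside [0, 1]")
        if self.caliber_px <= 0:
            raise ContractViolationError("caliber_px must be positive")
        if self.dist_od_px < 0 or self.dist_fovea_px < 0:
            raise ContractViolationError("distances must be nonnegative")

    @property
    def c_vector(self) -> np.ndarray:
        """(c_av, c_caliber, c_dod, c_dfov) as a float array."""
        return np.array([self.c_av, self.c_caliber, self.c_dod, self.c_dfov])


@dataclass(frozen=True)
class WeightConfig:
    """The decision vector of the weight fit: four factor weights + threshold.

    Weights lie in [0, 1] (no simplex constraint); ``threshold`` is the
    decision cut t_h on the composed retina score: predicted relevant iff
    score >= t_h.
    """

    w_av: float = 0.0
    w_caliber: float = 0.0
    w_dod: float = 0.0
    w_dfov: float = 0.0
    threshold: float = 0.0

    def __post_init__(self) -> None:
        for name in ("w_av", "w_caliber", "w_dod", "w_dfov"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ContractViolationError(f"{name}={v} outside [0, 1]")
        if not np.isfinite(self.threshold):
            raise ContractViolationError("threshold must be finite")

    @property
    def weights(self) -> np.ndarray:
        return np.array([self.w_av, self.w_caliber, self.w_dod, self.w_dfov])

    @classmethod
    def from_vector(cls, x) -> "WeightConfig":
        x = np.asarray(x, dtype=float)
        return cls(w_av=float(x[0]), w_caliber=float(x[1]), w_dod=float(x[2]),
                   w_dfov=float(x[3]), threshold=float(x[4]))

    def as_vector(self) -> np.ndarray:
        return np.array([self.w_av, self.w_caliber, self.w_dod, self.w_dfov, self.threshold])


@dataclass(frozen=True)
class VesselScore:
    """Per-vessel outputs: mathematical tau_g, weighted factor f_c, tau_c."""

    vessel_id: str
    tau_g: float
    f_c: float
    tau_c: float


def grisan_tortuosity(c: Centerline, config: MetricConfig | None = None) -> float:
    """Constant-sign-curvature tortuosity of one centerline.

    Decomposes the vessel into constant-sign-curvature subsegments and
    evaluates (n-1)/L_c * sum(L_csi/L_xsi - 1) (or the (n-1)/n variant when
    ``config.prefactor == "original"``). Returns 0 for n = 1. Degenerate
    subsegments with coincident endpoints contribute no ratio term.
    """
    cfg = config or MetricConfig()
    segs = decompose_constant_sign(c, min_run=cfg.min_run)
    n = len(segs)
    if n == 1:
        return 0.0
    total = 0.0
    for s in segs:
        if s.chord_length == 0.0:
            logger.warning("skipping degenerate subsegment ratio for vessel %r", c.vessel_id)
            continue
        total += s.arc_length / s.chord_length - 1.0
    L_c = arc_length(c)
    pref = (n - 1) / L_c
    if cfg.prefactor == "original":
        pref /= n
    return pref * total


def weighted_factor(profile: AnatomicalProfile, w: WeightConfig, L_c: float) -> float:
    """Anatomically weighted factor f_c of one vessel (pixel-scaled)."""
    if L_c <= 0:
        raise ContractViolationError(f"L_c must be positive, got {L_c}")
    av_term = w.w_av * (1.0 - profile.c_av) + (1.0 - w.w_av) * profile.c_av
    bracket = (av_term + w.w_caliber * profile.c_caliber
               + w.w_dod * profile.c_dod + w.w_dfov * profile.c_dfov)
    return bracket * L_c


def local_tortuosity(tau_g: float, f_c: float) -> float:
    """Local weighted tortuosity tau_c = tau_g * f_c."""
    if tau_g < 0 or f_c < 0:
        raise ContractViolationError("tau_g and f_c must be nonnegative")
    return tau_g * f_c


def compose_global(tau_g, f, mode: str = "weighted-mean") -> float:
    """Compose per-vessel tortuosity values into one retina score.

    ``"weighted-mean"`` (default) returns sum(tau_g*f)/sum(f): the factor f
    weights each vessel's mathematical tortuosity in the composition, and
    the result lies within [min tau_g, max tau_g]. ``"literal"`` returns
    sum((tau_g*f)*f)/sum(f), applying f both inside the local score and as
    the composition weight.
    """
    tau_g = np.asarray(tau_g, dtype=float)
    f = np.asarray(f, dtype=float)
    if tau_g.size == 0:
        raise UndefinedScoreError("cannot compose an empty vessel list")
    if tau_g.shape != f.shape:
        raise ContractViolationError("tau_g and f must have the same length")
    total = float(np.sum(f))
    if total <= 0.0:
        raise UndefinedScoreError("total composition weight is zero")
    if mode == "weighted-mean":
        return float(np.sum(tau_g * f) / total)
    if mode == "literal":
        return float(np.sum(tau_g * f * f) / total)
    raise ContractViolationError(f"unknown composition mode {mode!r}")
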