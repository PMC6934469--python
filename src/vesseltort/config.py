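"""Metric configuration: every choice the tortuosity pipeline leaves open.

The curvature-based metric and the anatomical weighting are fully specified
only up to a handful of discrete choices (smoothing window, curvature noise
guard, metric prefactor, composition rule, distance/caliber normalization).
They are collected here so a run can be reproduced from its config hash.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass

import yaml

from .errors import ConfigError

_PREFACTORS = ("printed", "original")
_COMPOSITIONS = ("weighted-mean", "literal")
_DISTANCE_NORMS = ("half-diagonal", "absolute", "disc-diameters")
_CALIBER_NORMS = ("per-image", "absolute")


@dataclass(frozen=True)
class MetricConfig:
    """Tunable choices of the tortuosity metric pipeline.

    Parameters
    ----------
    smoothing_window : int
        Odd window (in points) of the centered moving average applied to raw
        integer-pixel centerlines; 1 disables smoothing. Default 5.
    min_run : int
        Minimum number of interior points a constant-sign curvature run must
        span; shorter runs are merged into their longer neighbour. Suppresses
        single-point sign flips from pixel jitter. Default 3.
    prefactor : str
        ``"printed"`` uses the (n-1)/L_c prefactor of the metric as used here;
        ``"original"`` uses (n-1)/n * 1/L_c from the original formulation of
        the constant-sign-curvature metric.
    composition : str
        ``"weighted-mean"`` composes retina scores as sum(tau_g*f)/sum(f);
        ``"literal"`` composes sum((tau_g*f)*f)/sum(f), i.e. the anatomical
        factor applied both inside the local score and as composition weight.
    distance_norm : str
        How raw landmark distances map to [0, 1] proximity factors:
        ``"half-diagonal"`` divides by half the image diagonal,
        ``"absolute"`` by ``distance_scale_px``, ``"disc-diameters"`` by
        ``distance_scale_dd`` optic-disc diameters.
    distance_scale_px : float
        Normalizing distance in pixels for ``distance_norm="absolute"``.
    distance_scale_dd : float
        Normalizing distance in disc diameters for ``"disc-diameters"``.
    caliber_norm : str
        ``"per-image"`` divides each vessel caliber by the maximum mean
        caliber within the same retina; ``"absolute"`` divides by
        ``caliber_scale_px``. Values are clipped to [0, 1].
    caliber_scale_px : float
        Normalizing caliber for ``caliber_norm="absolute"``.
    """

    smoothing_window: int = 5
    min_run: int = 3
    prefactor: str = "printed"
    composition: str = "weighted-mean"
    distance_norm: str = "half-diagonal"
    distance_scale_px: float = 500.0
    distance_scale_dd: float = 5.0
    caliber_norm: str = "per-image"
    caliber_scale_px: float = 20.0

    def __post_init__(self) -> None:
        if self.smoothing_window < 1 or self.smoothing_window % 2 == 0:
            raise ConfigError(
                f"smoothing_window must be odd and >= 1, got {self.smoothing_window}"
            )
        if self.min_run < 1:
            raise ConfigError(f"min_run must be >= 1, got {self.min_run}")
        for field, allowed in (
            ("prefactor", _PREFACTORS),
            ("composition", _COMPOSITIONS),
            ("distance_norm", _DISTANCE_NORMS),
            ("caliber_norm", _CALIBER_NORMS),
        ):
            value = getattr(self, field)
            if value not in allowed:
                raise ConfigError(f"{field} must be one of {allowed}, got {value!r}")
        if self.distance_scale_px <= 0 or self.distance_scale_dd <= 0:
            raise ConfigError("distance scales must be positive")
        if self.caliber_scale_px <= 0:
            raise ConfigError("caliber_scale_px must be positive")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "MetricConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**d)

    def config_hash(self) -> str:
        """Short stable hash identifying this configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha1(blob).hexdigest()[:12]


def load_config(path) -> MetricConfig:
    """Read a :class:`MetricConfig` from a YAML file (missing keys -> defaults)."""
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    if not isinstance(data, dict):
        raise ConfigError(f"config file {path} must contain a mapping")
    return MetricConfig.from_dict(data)


def save_config(cfg: MetricConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(cfg.to_dict(), fh, sort_keys=True)
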