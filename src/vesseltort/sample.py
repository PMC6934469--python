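"""In-memory containers for annotated retinas.

A :class:`RetinaSample` bundles everything the metric needs for one retina:
the landmark set, and each vessel's centerline points, artery/vein label and
per-point caliber samples. Samples arrive from the vessel-graph JSON reader
or from the synthetic cohort generator.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .anatomy import LandmarkSet
from .errors import AnnotationError, VesselGraphError
from .geometry import Centerline
from .metrics import ARTERY, VEIN


@dataclass(frozen=True)
class Vessel:
    """One annotated vessel: centerline, artery/vein label, caliber samples."""

    vessel_id: str
    points: np.ndarray
    av_class: str
    calibers: np.ndarray

    def __post_init__(self) -> None:
        # Centerline construction validates the geometry invariants.
        cl = Centerline(self.points, vessel_id=self.vessel_id)
        object.__setattr__(self, "points", cl.points)
        if self.av_class not in (ARTERY, VEIN):
            raise AnnotationError(
                f"vessel {self.vessel_id!r}: av_class must be artery/vein, got {self.av_class!r}"
            )
        cal = np.asarray(self.calibers, dtype=float)
        if cal.size == 0 or np.any(~np.isfinite(cal)) or np.any(cal <= 0):
            raise AnnotationError(
                f"vessel {self.vessel_id!r}: calibers must be a nonempty positive sequence"
            )
        object.__setattr__(self, "calibers", cal)

    @property
    def centerline(self) -> Centerline:
        return Centerline(self.points, vessel_id=self.vessel_id)


@dataclass(frozen=True)
class RetinaSample:
    """One retina: unique-id vessels plus the anatomical landmark set."""

    retina_id: str
    landmarks: LandmarkSet
    vessels: tuple[Vessel, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "vessels", tuple(self.vessels))
        if len(self.vessels) == 0:
            raise VesselGraphError(f"retina {self.retina_id!r} has no vessels")
        ids = [v.vessel_id for v in self.vessels]
        if len(set(ids)) != len(ids):
            dupes = sorted({i for i in ids if ids.count(i) > 1})
            raise VesselGraphError(f"retina {self.retina_id!r}: duplicate vessel ids {dupes}")

    def __len__(self) -> int:
        return len(self.vessels)
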