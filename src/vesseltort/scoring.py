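"""Scoring retinas: per-vessel profiles, retina scores, and fast cohort features.

Two scoring modes exist. ``baseline`` composes the per-vessel mathematical
tortuosity tau_g using arc length alone as the composition weight (the pure
mathematical retina score tau_G). ``proposed`` weights each vessel with the
anatomical factor f_c built from the artery/vein class, caliber, and the
distances to the optic disc and fovea (the anatomically weighted score
tau_C).

Because tau_g, arc length and the normalized anatomical factors of a vessel
do not depend on the weight vector, they are precomputed once per cohort
into :class:`CohortFeatures`; evaluating a population of candidate weight
vectors is then a couple of matrix products, which is what makes the
evolutionary weight search cheap.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .anatomy import (aggregate_caliber, center_point, distance_to_fovea,
                      distance_to_od, normalize_profile)
from .config import MetricConfig
from .errors import ContractViolationError, UndefinedScoreError
from .metrics import (AnatomicalProfile, VesselScore, WeightConfig,
                      compose_global, grisan_tortuosity, local_tortuosity,
                      weighted_factor)
from .geometry import arc_length
from .sample import RetinaSample, Vessel


def smooth_cohort(samples, config: MetricConfig | None = None):
    """Apply centerline smoothing to every vessel of every retina.

    Intended for raster-derived integer-pixel traces; the synthetic
    generator emits continuous coordinates, so the pipeline never smooths
    implicitly. Returns new samples; the window comes from
    ``config.smoothing_window``.
    """
    from .geometry import smooth_centerline

    cfg = config or MetricConfig()
    out = []
    for s in samples:
        vessels = [
            Vessel(vessel_id=v.vessel_id,
                   points=smooth_centerline(v.points, cfg.smoothing_window).points,
                   av_class=v.av_class, calibers=v.calibers)
            for v in s.vessels
        ]
        out.append(RetinaSample(retina_id=s.retina_id, landmarks=s.landmarks,
                                vessels=tuple(vessels)))
    return out


def build_profiles(sample: RetinaSample, config: MetricConfig | None = None
                   ) -> dict[str, AnatomicalProfile]:
    """Normalized anatomical profiles for every vessel of one retina.

    Caliber normalization is per-image by default: each vessel's mean
    caliber is divided by the largest mean caliber in the same retina.
    """
    cfg = config or MetricConfig()
    mean_calibers = {v.vessel_id: aggregate_caliber(v.calibers) for v in sample.vessels}
    max_caliber = max(mean_calibers.values())
    profiles = {}
    for v in sample.vessels:
        cl = v.centerline
        profiles[v.vessel_id] = normalize_profile(
            av_class=v.av_class,
            caliber_px=mean_calibers[v.vessel_id],
            dist_od_px=distance_to_od(cl, sample.landmarks),
            dist_fovea_px=distance_to_fovea(cl, sample.landmarks),
            landmarks=sample.landmarks,
            max_caliber_px=max_caliber,
            config=cfg,
        )
    return profiles


def score_retina(
    sample: RetinaSample,
    weights: WeightConfig | None = None,
    mode: str = "proposed",
    config: MetricConfig | None = None,
) -> tuple[float, list[VesselScore]]:
    """Global tortuosity score of one retina plus its per-vessel breakdown.

    ``mode="baseline"`` ignores the anatomical factors and composes tau_g
    with arc length as weight (tau_G); ``mode="proposed"`` uses the full
    anatomical factor f_c (tau_C) and requires ``weights``.
    """
    cfg = config or MetricConfig()
    if mode not in ("baseline", "proposed"):
        raise ContractViolationError(f"mode must be baseline/proposed, got {mode!r}")
    if mode == "proposed" and weights is None:
        raise ContractViolationError("proposed mode requires a WeightConfig")

    profiles = build_profiles(sample, cfg) if mode == "proposed" else None
    scores: list[VesselScore] = []
    for v in sample.vessels:
        cl = v.centerline
        tau_g = grisan_tortuosity(cl, cfg)
        L_c = arc_length(cl)
        f_c = L_c if mode == "baseline" else weighted_factor(profiles[v.vessel_id], weights, L_c)
        scores.append(VesselScore(vessel_id=v.vessel_id, tau_g=tau_g, f_c=f_c,
                                  tau_c=local_tortuosity(tau_g, f_c)))
    tau = compose_global([s.tau_g for s in scores], [s.f_c for s in scores],
                         mode=cfg.composition)
    return tau, scores


@dataclass(frozen=True)
class CohortFeatures:
    """Weight-independent per-vessel quantities of a cohort, ready for batch scoring.

    Arrays are concatenated over all vessels of all retinas; ``group`` is the
    dense (n_vessels, n_retinas) membership matrix used to aggregate
    per-vessel terms into retina scores. Retinas that end up with no vessels
    (possible after artery/vein restriction) score 0.
    """

    retina_ids: tuple[str, ...]
    tau_g: np.ndarray          # (V,)
    length: np.ndarray         # (V,)
    c: np.ndarray              # (V, 4): c_av, c_caliber, c_dod, c_dfov
    group: np.ndarray          # (V, R)
    composition: str = "weighted-mean"

    @classmethod
    def from_cohort(
        cls,
        samples,
        config: MetricConfig | None = None,
        vessel_class: str | None = None,
    ) -> "CohortFeatures":
        """Precompute features; ``vessel_class`` restricts to arteries or veins."""
        cfg = config or MetricConfig()
        retina_ids, tau_g, length, c_rows, owner = [], [], [], [], []
        for r_idx, sample in enumerate(samples):
            retina_ids.append(sample.retina_id)
            profiles = build_profiles(sample, cfg)
            for v in sample.vessels:
                if vessel_class is not None and v.av_class != vessel_class:
                    continue
                cl = v.centerline
                tau_g.append(grisan_tortuosity(cl, cfg))
                length.append(arc_length(cl))
                c_rows.append(profiles[v.vessel_id].c_vector)
                owner.append(r_idx)
        n_r = len(retina_ids)
        n_v = len(tau_g)
        group = np.zeros((n_v, n_r))
        if n_v:
            group[np.arange(n_v), owner] = 1.0
        return cls(
            retina_ids=tuple(retina_ids),
            tau_g=np.asarray(tau_g, dtype=float),
            length=np.asarray(length, dtype=float),
            c=np.asarray(c_rows, dtype=float).reshape(n_v, 4),
            group=group,
            composition=cfg.composition,
        )

    @property
    def n_retinas(self) -> int:
        return len(self.retina_ids)

    def subset(self, retina_indices) -> "CohortFeatures":
        """Features restricted to a subset of retinas (e.g. one CV split)."""
        idx = np.asarray(retina_indices, dtype=int)
        sub_group = self.group[:, idx]
        keep = sub_group.sum(axis=1) > 0
        return CohortFeatures(
            retina_ids=tuple(self.retina_ids[i] for i in idx),
            tau_g=self.tau_g[keep],
            length=self.length[keep],
            c=self.c[keep],
            group=sub_group[keep],
            composition=self.composition,
        )

    def factor_matrix(self, W: np.ndarray) -> np.ndarray:
        """Anatomical factors f for a batch of weight rows: (P, V)."""
        W = np.atleast_2d(np.asarray(W, dtype=float))
        c_av, c_cal, c_dod, c_dfov = self.c.T
        av_term = np.outer(W[:, 0], 1.0 - c_av) + np.outer(1.0 - W[:, 0], c_av)
        bracket = (av_term + np.outer(W[:, 1], c_cal)
                   + np.outer(W[:, 2], c_dod) + np.outer(W[:, 3], c_dfov))
        return bracket * self.length[None, :]

    def scores(self, W: np.ndarray) -> np.ndarray:
        """Anatomically weighted retina scores for weight rows W: (P, R).

        W has columns (w_av, w_caliber, w_dod, w_dfov); a trailing threshold
        column, if present, is ignored here.
        """
        W = np.atleast_2d(np.asarray(W, dtype=float))
        F = self.factor_matrix(W[:, :4])
        tau_term = self.tau_g[None, :] * F
        if self.composition == "literal":
            tau_term = tau_term * F
        num = tau_term @ self.group
        den = F @ self.group
        out = np.zeros_like(num)
        np.divide(num, den, out=out, where=den > 0)
        return out

    def baseline_scores(self) -> np.ndarray:
        """Pure mathematical retina scores tau_G (arc-length composition): (R,)."""
        F = self.length[None, :]
        tau_term = self.tau_g[None, :] * F
        if self.composition == "literal":
            tau_term = tau_term * F
        num = (tau_term @ self.group)[0]
        den = (F @ self.group)[0]
        out = np.zeros_like(num)
        np.divide(num, den, out=out, where=den > 0)
        return out

    def score_config(self, w: WeightConfig) -> np.ndarray:
        """Retina scores for a single :class:`WeightConfig`: (R,)."""
        return self.scores(w.weights[None, :])[0]
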