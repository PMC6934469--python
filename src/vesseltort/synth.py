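"""Synthetic retinal cohorts with planted ground truth.

The generator emulates the annotated output of an upstream fundus-analysis
pipeline at the level this package consumes: per-retina vessel centerlines
with artery/vein labels and caliber samples, an optic-disc circle and a
fovea center in a plausible layout (fovea about two disc diameters from the
disc center), and expert-style ratings.

Vessels are sinusoids along a straight baseline radiating from the disc:
the number of half-periods controls the count of convexity changes (the
constant-sign-curvature decomposition of such a vessel has exactly that
many subsegments) and the amplitude controls the arc-to-chord excess, so
the two drivers of the tortuosity metric are analytically controllable.
Each retina carries a latent severity in [0, 1] raising the fraction of
tortuous vessels, while most tortuosity variation remains at the vessel
level — which vessels are tortuous (artery or vein, near or far from the
fovea) is what separates the anatomically weighted score from the purely
mathematical one.

Labels are planted: a retina is "relevant" iff its anatomically weighted
score under the planted weights w* reaches a threshold t* (chosen by
default as the score quantile reproducing a 141:59 non-relevant:relevant
split), then flipped independently at the label-noise rate. Rater matrices
flip the true label per rater at per-rater error rates.
"""

from __future__ import annotations

import dataclasses
import math
from dataclasses import dataclass

import numpy as np

from .anatomy import LandmarkSet
from .config import MetricConfig
from .errors import ConfigError
from .evaluate import N_RATERS, RatingSet
from .metrics import ARTERY, VEIN, WeightConfig
from .sample import RetinaSample, Vessel
from .scoring import CohortFeatures

import logging

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class GeneratorConfig:
    """Study conditions of the synthetic cohort (all units in pixels).

    Defaults mirror the scale of the study cohort the harness emulates:
    200 retinas, five raters, and a ~141:59 non-relevant:relevant consensus
    split. Tortuosity is sparse and heavy-tailed — about one vessel in five
    is tortuous, with wide amplitude/half-period spread — so a retina's
    relevance hinges on *which* vessels are tortuous, not merely how many.
    The planted weights put all the anatomical signal on the artery/vein
    distinction and fovea proximity, the two factors clinically reported as
    most informative; caliber and disc distance carry none individually.
    ``label_config``, when set, is the metric configuration of the
    label-planting mechanism (the synthetic "specialist perception"), which
    may differ from the configuration the analysis pipeline uses — e.g. a
    proximity factor that saturates outside the macular region.
    """

    n_retinas: int = 200
    vessels_per_retina: tuple[int, int] = (6, 10)
    image_size: tuple[int, int] = (768, 768)
    od_radius: float = 42.0
    fovea_disc_diameters: float = 2.0
    artery_fraction: float = 0.4
    main_vessel_fraction: float = 0.35
    caliber_main: tuple[float, float] = (10.0, 16.0)
    caliber_secondary: tuple[float, float] = (3.0, 8.0)
    caliber_jitter: float = 0.4
    vessel_length: tuple[float, float] = (180.0, 280.0)
    amplitude_tortuous: tuple[float, float] = (4.0, 14.0)
    amplitude_mild: tuple[float, float] = (0.0, 2.5)
    half_periods_tortuous: tuple[int, int] = (3, 10)
    half_periods_mild: tuple[int, int] = (1, 3)
    tortuous_rate_base: float = 0.2
    tortuous_rate_slope: float = 0.0
    points_per_half_period: int = 60
    planted_weights: tuple[float, float, float, float] = (1.0, 0.0, 0.0, 0.4)
    relevant_fraction: float = 59.0 / 200.0
    label_noise: float = 0.0
    rater_error_rates: tuple[float, ...] = (0.12, 0.10, 0.08, 0.06, 0.05)
    label_config: MetricConfig | None = None

    def __post_init__(self) -> None:
        if self.n_retinas < 1:
            raise ConfigError("n_retinas must be positive")
        for name in ("vessels_per_retina", "caliber_main", "caliber_secondary",
                     "vessel_length", "amplitude_tortuous", "amplitude_mild",
                     "half_periods_tortuous", "half_periods_mild"):
            lo, hi = getattr(self, name)
            if lo > hi or hi <= 0:
                raise ConfigError(f"{name} must be a nonempty positive range")
        if not (0.0 <= self.label_noise < 0.5):
            raise ConfigError("label_noise must lie in [0, 0.5)")
        if len(self.rater_error_rates) != N_RATERS or any(
            not (0.0 <= e < 0.5) for e in self.rater_error_rates
        ):
            raise ConfigError(f"need {N_RATERS} rater error rates in [0, 0.5)")
        if not (0.0 < self.relevant_fraction < 1.0):
            raise ConfigError("relevant_fraction must lie in (0, 1)")

    def planted_config(self, threshold: float = 0.0) -> WeightConfig:
        w = self.planted_weights
        return WeightConfig(w_av=w[0], w_caliber=w[1], w_dod=w[2], w_dfov=w[3],
                            threshold=threshold)


def generate_vessel(
    length: float,
    amplitude: float,
    half_periods: int,
    anchor=(0.0, 0.0),
    orientation: float = 0.0,
    points_per_half_period: int = 60,
) -> np.ndarray:
    """Sample a sinusoid-on-a-baseline centerline as an (N, 2) point array.

    The baseline runs from ``anchor`` in direction ``orientation`` (radians)
    for ``length`` pixels; the transverse offset is a sine with
    ``half_periods`` half-waves of the given amplitude. Zero amplitude (or
    zero half-periods) yields a straight vessel.
    """
    if length <= 0:
        raise ConfigError("vessel length must be positive")
    n = max(2, points_per_half_period * max(half_periods, 1) + 1)
    t = np.linspace(0.0, length, n)
    if amplitude == 0.0 or half_periods == 0:
        offset = np.zeros_like(t)
    else:
        offset = amplitude * np.sin(math.pi * half_periods * t / length)
    cos_o, sin_o = math.cos(orientation), math.sin(orientation)
    x = anchor[0] + t * cos_o - offset * sin_o
    y = anchor[1] + t * sin_o + offset * cos_o
    return np.column_stack([x, y])


def _make_landmarks(cfg: GeneratorConfig, rng: np.random.Generator) -> LandmarkSet:
    w, h = cfg.image_size
    od = np.array([0.25 * w, 0.5 * h]) + rng.uniform(-0.02, 0.02, 2) * np.array([w, h])
    dist = cfg.fovea_disc_diameters * 2.0 * cfg.od_radius * rng.uniform(0.95, 1.05)
    angle = rng.uniform(-0.1, 0.1)
    fovea = od + dist * np.array([math.cos(angle), math.sin(angle)])
    return LandmarkSet(od_center=tuple(od), od_radius=cfg.od_radius,
                       fovea_center=tuple(fovea), image_width=w, image_height=h)


def generate_retina(
    cfg: GeneratorConfig,
    rng: np.random.Generator,
    retina_id: str = "r000",
    severity: float | None = None,
) -> RetinaSample:
    """One synthetic retina: vessels radiating from the disc, with annotations."""
    landmarks = _make_landmarks(cfg, rng)
    od = np.asarray(landmarks.od_center)
    if severity is None:
        severity = float(rng.uniform())
    n_vessels = int(rng.integers(cfg.vessels_per_retina[0], cfg.vessels_per_retina[1] + 1))
    p_tortuous = cfg.tortuous_rate_base + cfg.tortuous_rate_slope * severity
    # fixed-count selection: the severity sets how many vessels are tortuous,
    # the draw decides which ones (their class and location carry the
    # anatomical signal that distinguishes the weighted from the plain score)
    n_tortuous = int(round(n_vessels * p_tortuous))
    tortuous_set = set(rng.choice(n_vessels, size=n_tortuous, replace=False).tolist())

    vessels = []
    for k in range(n_vessels):
        theta = rng.uniform(-0.55 * math.pi, 0.55 * math.pi)
        anchor = od + cfg.od_radius * np.array([math.cos(theta), math.sin(theta)])
        orientation = theta + rng.uniform(-0.25, 0.25)
        length = rng.uniform(*cfg.vessel_length)
        if k in tortuous_set:
            amplitude = rng.uniform(*cfg.amplitude_tortuous)
            lo, hi = cfg.half_periods_tortuous
        else:
            amplitude = rng.uniform(*cfg.amplitude_mild)
            lo, hi = cfg.half_periods_mild
        half_periods = int(rng.integers(lo, hi + 1))
        amplitude *= rng.choice([-1.0, 1.0])
        points = generate_vessel(length, amplitude, half_periods, anchor, orientation,
                                 cfg.points_per_half_period)
        is_main = rng.uniform() < cfg.main_vessel_fraction
        cal_range = cfg.caliber_main if is_main else cfg.caliber_secondary
        base = rng.uniform(*cal_range)
        calibers = np.clip(base + rng.normal(0.0, cfg.caliber_jitter, points.shape[0]), 0.5, None)
        av_class = ARTERY if rng.uniform() < cfg.artery_fraction else VEIN
        vessels.append(Vessel(vessel_id=f"{retina_id}-v{k:02d}", points=points,
                              av_class=av_class, calibers=calibers))
    return RetinaSample(retina_id=retina_id, landmarks=landmarks, vessels=tuple(vessels))


def generate_cohort(cfg: GeneratorConfig | None = None, seed: int = 0) -> list[RetinaSample]:
    """A cohort of ``cfg.n_retinas`` synthetic retinas, deterministic in the seed."""
    cfg = cfg or GeneratorConfig()
    rng = np.random.default_rng(seed)
    return [
        generate_retina(cfg, rng, retina_id=f"r{i:03d}")
        for i in range(cfg.n_retinas)
    ]


def generate_labels(
    samples,
    cfg: GeneratorConfig | None = None,
    threshold: float | None = None,
    rng: np.random.Generator | None = None,
    metric_config: MetricConfig | None = None,
    features: CohortFeatures | None = None,
) -> tuple[np.ndarray, float]:
    """Planted relevance labels: score with w*, threshold, flip with noise.

    Scoring uses ``cfg.label_config`` when set (the planting mechanism may
    differ from the analysis configuration), else ``metric_config``. If
    ``threshold`` is None it is set to the score quantile that makes
    ``cfg.relevant_fraction`` of the cohort relevant. Returns the (possibly
    noisy) labels and the threshold t* actually used.
    """
    cfg = cfg or GeneratorConfig()
    rng = rng if rng is not None else np.random.default_rng(0)
    if features is None:
        features = CohortFeatures.from_cohort(samples, cfg.label_config or metric_config)
    scores = features.scores(np.asarray(cfg.planted_weights)[None, :])[0]
    if threshold is None:
        threshold = float(np.quantile(scores, 1.0 - cfg.relevant_fraction))
    labels = (scores >= threshold).astype(int)
    if labels.min() == labels.max():
        logger.warning(
            "planted threshold %.4g yields a single class; regenerate with another "
            "threshold or cohort seed", threshold,
        )
    if cfg.label_noise > 0:
        flips = rng.uniform(size=labels.size) < cfg.label_noise
        labels = np.where(flips, 1 - labels, labels)
    return labels.astype(int), float(threshold)


def generate_ratings(
    labels,
    retina_ids,
    rater_error_rates=None,
    rng: np.random.Generator | None = None,
) -> RatingSet:
    """Five-rater matrix: each rater flips each true label at their error rate."""
    rates = tuple(rater_error_rates if rater_error_rates is not None
                  else GeneratorConfig().rater_error_rates)
    if len(rates) != N_RATERS or any(not (0.0 <= e < 0.5) for e in rates):
        raise ConfigError(f"need {N_RATERS} rater error rates in [0, 0.5)")
    rng = rng if rng is not None else np.random.default_rng(0)
    lab = np.asarray(labels, dtype=int)
    ratings = np.empty((lab.size, N_RATERS), dtype=int)
    for j, rate in enumerate(rates):
        flips = rng.uniform(size=lab.size) < rate
        ratings[:, j] = np.where(flips, 1 - lab, lab)
    return RatingSet(retina_ids=tuple(retina_ids), ratings=ratings)


def generate_study(
    cfg: GeneratorConfig | None = None,
    seed: int = 0,
    metric_config: MetricConfig | None = None,
):
    """Cohort + labels + ratings in one call (one seed drives everything).

    Returns ``(samples, labels, ratings, threshold)``.
    """
    cfg = cfg or GeneratorConfig()
    ss = np.random.SeedSequence(seed)
    s_cohort, s_labels, s_ratings = ss.spawn(3)
    samples = generate_cohort(cfg, seed=int(s_cohort.generate_state(1)[0] % (2**31)))
    labels, threshold = generate_labels(
        samples, cfg, rng=np.random.default_rng(s_labels), metric_config=metric_config
    )
    ratings = generate_ratings(
        labels, [s.retina_id for s in samples], cfg.rater_error_rates,
        rng=np.random.default_rng(s_ratings),
    )
    return samples, labels, ratings, threshold


def headline_conditions() -> GeneratorConfig:
    """Study conditions for the anatomical-dependence comparison.

    A 300-retina cohort whose relevance labels come from a "specialist
    perception" mechanism that weights arteries fully, weights fovea
    proximity with a factor saturating 2.5 disc diameters from the fovea
    (roughly the macular region), ignores caliber and disc distance, and is
    corrupted by 10% label noise. The analysis pipeline still runs with its
    default configuration, so the mechanism is approximable but not exactly
    representable — as with real expert perception.
    """
    return dataclasses.replace(
        GeneratorConfig(),
        n_retinas=300,
        label_noise=0.1,
        label_config=MetricConfig(distance_norm="disc-diameters",
                                  distance_scale_dd=2.5),
    )


def av_only_conditions() -> GeneratorConfig:
    """Study conditions where only the artery/vein factor drives the labels."""
    return dataclasses.replace(
        GeneratorConfig(),
        planted_weights=(1.0, 0.0, 0.0, 0.0),
        label_noise=0.05,
    )
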