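"""Model/Results front-end for the weight fit.

`TortuosityModel` holds a cohort (retina samples plus binary consensus
labels) and a metric configuration; `fit()` runs the multi-objective
NSGA-II search for the anatomical weights and decision threshold, and
returns a `TortuosityResults` carrying the Pareto front, the selected
operating point, and prediction/summary utilities — the statsmodels-style
endog/exog -> fit -> results workflow, adapted to a two-objective fit whose
"estimate" is a front of sensitivity/specificity trade-offs rather than a
single coefficient vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .config import MetricConfig
from .errors import ContractViolationError
from .evaluate import _VARIANT_CLASS, _VARIANT_FIXED, VARIANTS
from .metrics import WeightConfig
from .optimize import (CandidateSolution, NSGAParams, ParetoFront,
                       evaluate_solutions, nsga_optimize)
from .roc import ROCCurve
from .scoring import CohortFeatures


class TortuosityModel:
    """Anatomically weighted tortuosity classifier for a labelled cohort.

    Parameters
    ----------
    samples : sequence of RetinaSample
        The annotated cohort.
    labels : array-like of {0, 1}
        Consensus relevance labels, one per retina, aligned with ``samples``.
    variant : str
        One of ``proposed`` (all four anatomical weights free), the
        single-factor variants (``av_only``, ``dod_only``, ``dfov_only``,
        ``caliber_only``) or the class-restricted ``arteries_only`` /
        ``veins_only``. The threshold-only ``baseline`` metric has nothing
        to fit; use :func:`vesseltort.evaluate.experiment_run` for it.
    config : MetricConfig, optional
        Metric configuration (smoothing, composition rule, normalizations).
    """

    def __init__(self, samples, labels, variant: str = "proposed",
                 config: MetricConfig | None = None):
        if variant not in VARIANTS or variant == "baseline":
            raise ContractViolationError(
                f"variant must be a fittable member of {VARIANTS[1:]}, got {variant!r}"
            )
        self.samples = list(samples)
        self.labels = np.asarray(labels, dtype=int)
        if self.labels.size != len(self.samples):
            raise ContractViolationError("labels length must match the cohort")
        self.variant = variant
        self.config = config or MetricConfig()
        self.features = CohortFeatures.from_cohort(
            self.samples, self.config, vessel_class=_VARIANT_CLASS.get(variant)
        )

    @classmethod
    def from_files(cls, graph_path, ratings_path, variant: str = "proposed",
                   config: MetricConfig | None = None) -> "TortuosityModel":
        """Build a model from a vessel-graph JSON and a ratings CSV.

        Labels are the majority-vote consensus of the five raters; the
        ratings rows are aligned to the cohort by retina_id.
        """
        from .io import read_ratings, read_vessel_graph

        samples = read_vessel_graph(graph_path)
        ratings = read_ratings(ratings_path)
        by_id = dict(zip(ratings.retina_ids, ratings.consensus))
        missing = [s.retina_id for s in samples if s.retina_id not in by_id]
        if missing:
            raise ContractViolationError(f"no ratings for retinas {missing[:5]}")
        labels = np.array([by_id[s.retina_id] for s in samples])
        return cls(samples, labels, variant=variant, config=config)

    def fit(self, seed: int = 0, pop_size: int = 100, generations: int = 200,
            params: NSGAParams | None = None) -> "TortuosityResults":
        """Run the NSGA-II weight/threshold search and wrap the result."""
        p = params or NSGAParams(pop_size=pop_size, generations=generations, seed=seed)
        front = nsga_optimize(self.features, self.labels, p,
                              fixed_weights=_VARIANT_FIXED.get(self.variant))
        return TortuosityResults(model=self, front=front)


@dataclass(frozen=True)
class TortuosityResults:
    """Fit results: the Pareto front plus the max-Youden operating point."""

    model: TortuosityModel
    front: ParetoFront

    @property
    def best(self) -> CandidateSolution:
        return self.front.best()

    @property
    def weights(self) -> WeightConfig:
        """Weights and threshold of the selected (max-Youden) solution."""
        return self.best.config

    @property
    def sensitivity(self) -> float:
        return self.best.sensitivity

    @property
    def specificity(self) -> float:
        return self.best.specificity

    @property
    def youden(self) -> float:
        return self.best.youden

    def roc(self) -> ROCCurve:
        """Training ROC: convex hull of the front's operating points."""
        return self.front.roc()

    def predict(self, samples=None, weights: WeightConfig | None = None) -> np.ndarray:
        """Binary relevance predictions for a cohort (default: training cohort)."""
        w = weights or self.weights
        if samples is None:
            features = self.model.features
        else:
            features = CohortFeatures.from_cohort(
                samples, self.model.config, vessel_class=_VARIANT_CLASS.get(self.model.variant)
            )
        scores = features.score_config(w)
        return (scores >= w.threshold).astype(int)

    def evaluate(self, samples, labels) -> tuple[list[CandidateSolution], ROCCurve]:
        """Apply the whole front to a held-out cohort; returns points and hull ROC."""
        features = CohortFeatures.from_cohort(
            samples, self.model.config, vessel_class=_VARIANT_CLASS.get(self.model.variant)
        )
        sols = evaluate_solutions(self.front, features, np.asarray(labels, dtype=int))
        from .optimize import roc_from_solutions

        return sols, roc_from_solutions(sols)

    def front_frame(self) -> pd.DataFrame:
        """The Pareto front as a tidy DataFrame."""
        rows = [
            {
                "w_av": s.config.w_av, "w_caliber": s.config.w_caliber,
                "w_dod": s.config.w_dod, "w_dfov": s.config.w_dfov,
                "threshold": s.config.threshold,
                "sensitivity": s.sensitivity, "specificity": s.specificity,
                "youden": s.youden,
            }
            for s in self.front.solutions
        ]
        return pd.DataFrame(rows)

    def summary(self) -> str:
        b = self.best
        meta = self.front.metadata
        lines = [
            "Anatomically weighted tortuosity fit",
            "=" * 52,
            f"variant:            {self.model.variant}",
            f"retinas:            {self.model.features.n_retinas}"
            f"  (relevant: {int(self.model.labels.sum())})",
            f"composition:        {self.model.config.composition}",
            f"NSGA-II:            pop {meta.get('pop_size')}, "
            f"{meta.get('generations')} generations, seed {meta.get('seed')}",
            f"evaluated:          {meta.get('n_evaluated')} candidates",
            f"Pareto front size:  {len(self.front)}",
            f"train ROC hull AUC: {self.roc().auc:.3f}",
            "-" * 52,
            "selected operating point (max Youden):",
            f"  w_av={b.config.w_av:.3f}  w_caliber={b.config.w_caliber:.3f}  "
            f"w_dod={b.config.w_dod:.3f}  w_dfov={b.config.w_dfov:.3f}",
            f"  threshold t_h={b.config.threshold:.4g}",
            f"  sensitivity={b.sensitivity:.3f}  specificity={b.specificity:.3f}  "
            f"Youden={b.youden:.3f}",
        ]
        return "\n".join(lines)
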