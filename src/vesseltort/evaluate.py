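"""Study-level evaluation: inter-rater agreement, MCCV, and the variant harness.

Expert annotations are a retinas x 5 binary matrix (0 non-relevant, 1
relevant); the consensus label of a retina is the majority vote of its five
raters (odd panel, so never tied). Agreement is summarized by the
proportions of full consensus / at-least-4 / 3-vs-2 rows and by Cohen's
kappa between rater pairs and between each rater and the consensus.

Generalization is assessed by stratified Monte Carlo cross-validation:
repeated random splits preserving the class proportions, the weight search
run on each training half, the resulting Pareto-front configurations
applied to the held-out half, and the per-split ROC curves vertically
averaged into one mean train and one mean test curve per variant.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.model_selection import StratifiedShuffleSplit

from .config import MetricConfig
from .errors import (ContractViolationError, RatingsFormatError,
                     UndefinedStatisticError)
from .metrics import ARTERY, VEIN
from .optimize import (NSGAParams, evaluate_solutions, nsga_optimize,
                       roc_from_solutions)
from .roc import ROCCurve, interpolate_rocs, roc_staircase
from .scoring import CohortFeatures

N_RATERS = 5

VARIANTS = ("baseline", "proposed", "av_only", "dod_only", "dfov_only",
            "caliber_only", "arteries_only", "veins_only")

# single-factor variants pin the other three weights at 0 (decision-vector
# indices: 0 av, 1 caliber, 2 dod, 3 dfov)
_VARIANT_FIXED = {
    "av_only": {1: 0.0, 2: 0.0, 3: 0.0},
    "dod_only": {0: 0.0, 1: 0.0, 3: 0.0},
    "dfov_only": {0: 0.0, 1: 0.0, 2: 0.0},
    "caliber_only": {0: 0.0, 2: 0.0, 3: 0.0},
}
_VARIANT_CLASS = {"arteries_only": ARTERY, "veins_only": VEIN}


@dataclass(frozen=True)
class RatingSet:
    """Binary ratings of one cohort by a five-specialist panel."""

    retina_ids: tuple[str, ...]
    ratings: np.ndarray  # (n_retinas, 5), values in {0, 1}

    def __post_init__(self) -> None:
        r = np.asarray(self.ratings)
        if r.ndim != 2 or r.shape[1] != N_RATERS:
            raise RatingsFormatError(f"ratings must be (n, {N_RATERS}), got {r.shape}")
        if not np.isin(r, (0, 1)).all():
            raise RatingsFormatError("ratings must be binary 0/1")
        if len(self.retina_ids) != r.shape[0]:
            raise RatingsFormatError("retina_ids and ratings disagree in length")
        if len(set(self.retina_ids)) != len(self.retina_ids):
            raise RatingsFormatError("duplicate retina_id in ratings")
        object.__setattr__(self, "ratings", r.astype(int))
        object.__setattr__(self, "retina_ids", tuple(self.retina_ids))

    @property
    def consensus(self) -> np.ndarray:
        """Majority-vote consensus label per retina."""
        return (self.ratings.sum(axis=1) * 2 > N_RATERS).astype(int)


def consensus_label(votes) -> int:
    """Majority label of one five-vote row."""
    v = np.asarray(votes)
    if v.shape != (N_RATERS,) or not np.isin(v, (0, 1)).all():
        raise RatingsFormatError(f"expected {N_RATERS} binary votes, got {votes!r}")
    return int(v.sum() * 2 > N_RATERS)


def agreement_summary(ratings) -> dict[str, float]:
    """Proportions of rows with full consensus, >= 4 agreeing, and 3-vs-2 splits.

    The buckets are exclusive (a unanimous row counts only as full
    consensus) and the three proportions sum to 1.
    """
    r = np.asarray(ratings)
    if r.ndim != 2 or r.shape[1] != N_RATERS or not np.isin(r, (0, 1)).all():
        raise RatingsFormatError("ratings must be an (n, 5) binary matrix")
    majority_size = np.maximum(r.sum(axis=1), N_RATERS - r.sum(axis=1))
    n = r.shape[0]
    return {
        "full_consensus": float(np.mean(majority_size == 5)),
        "four_agree": float(np.mean(majority_size == 4)),
        "three_vs_two": float(np.mean(majority_size == 3)),
    }


def cohen_kappa(labels_a, labels_b) -> float:
    """Chance-corrected agreement between two binary raters.

    kappa = (p_o - p_e) / (1 - p_e) with observed agreement p_o and chance
    agreement p_e from the marginal label frequencies. Perfect agreement
    returns 1 even when both raters are a degenerate constant (p_e = 1).
    """
    a = np.asarray(labels_a, dtype=int)
    b = np.asarray(labels_b, dtype=int)
    if a.shape != b.shape or a.ndim != 1 or a.size == 0:
        raise ContractViolationError("kappa needs two equal-length nonempty vectors")
    if not (np.isin(a, (0, 1)).all() and np.isin(b, (0, 1)).all()):
        raise ContractViolationError("kappa is implemented for binary labels")
    p_o = float(np.mean(a == b))
    if p_o == 1.0:
        return 1.0
    pa1, pb1 = a.mean(), b.mean()
    p_e = pa1 * pb1 + (1 - pa1) * (1 - pb1)
    return float((p_o - p_e) / (1 - p_e))


def kappa_table(ratings: RatingSet) -> pd.DataFrame:
    """Pairwise rater kappas plus each rater against the consensus."""
    r = ratings.ratings
    cols = [f"E{i + 1}" for i in range(N_RATERS)]
    consensus = ratings.consensus
    table = pd.DataFrame(index=cols, columns=cols + ["Rc"], dtype=float)
    for i in range(N_RATERS):
        for j in range(i + 1, N_RATERS):
            table.iloc[i, j] = cohen_kappa(r[:, i], r[:, j])
        table.loc[cols[i], "Rc"] = cohen_kappa(r[:, i], consensus)
    return table


def mccv_split(labels, n_splits: int = 10, train_fraction: float = 0.5,
               seed: int = 0) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified Monte Carlo CV splits: disjoint, covering, class-balanced.

    Each split partitions the cohort into train/test with the cohort's class
    proportions preserved to within one sample in each part; reproducible
    given the seed.
    """
    lab = np.asarray(labels, dtype=int)
    if not (0.0 < train_fraction < 1.0):
        raise ContractViolationError("train_fraction must lie in (0, 1)")
    classes, counts = np.unique(lab, return_counts=True)
    if classes.size < 2:
        raise UndefinedStatisticError("stratified splitting needs both classes present")
    if counts.min() < 2:
        raise UndefinedStatisticError(
            f"class with {counts.min()} member(s) is too small to stratify"
        )
    test_fraction = 1.0 - train_fraction
    splitter = StratifiedShuffleSplit(
        n_splits=n_splits, train_size=train_fraction, test_size=test_fraction,
        random_state=seed,
    )
    return [(np.sort(tr), np.sort(te)) for tr, te in splitter.split(lab[:, None], lab)]


@dataclass(frozen=True)
class ExperimentResult:
    """Mean train/test ROC of one variant across the MCCV splits."""

    variant: str
    train_aucs: tuple[float, ...]
    test_aucs: tuple[float, ...]
    mean_train_curve: ROCCurve
    mean_test_curve: ROCCurve
    metadata: dict = field(default_factory=dict)

    @property
    def mean_train_auc(self) -> float:
        return self.mean_train_curve.auc

    @property
    def mean_test_auc(self) -> float:
        return self.mean_test_curve.auc

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for split, (tr, te) in enumerate(zip(self.train_aucs, self.test_aucs)):
            rows.append({"variant": self.variant, "split": split, "stage": "train", "auc": tr})
            rows.append({"variant": self.variant, "split": split, "stage": "test", "auc": te})
        return pd.DataFrame(rows)


def experiment_run(
    samples,
    labels,
    variant: str = "proposed",
    config: MetricConfig | None = None,
    n_splits: int = 10,
    train_fraction: float = 0.5,
    seed: int = 0,
    nsga_params: NSGAParams | None = None,
    features: CohortFeatures | None = None,
) -> ExperimentResult:
    """Run one metric variant through the full MCCV protocol.

    ``baseline`` sweeps the threshold over the pure mathematical score
    (no optimization); the other variants run the evolutionary weight search
    on each training split and apply the front to the test split, building
    train and test ROC curves from the convex hull of the candidate
    operating points. Returns per-split AUCs and the vertically averaged
    mean curves.
    """
    if variant not in VARIANTS:
        raise ContractViolationError(f"unknown variant {variant!r}; choose from {VARIANTS}")
    cfg = config or MetricConfig()
    lab = np.asarray(labels, dtype=int)
    if features is None:
        features = CohortFeatures.from_cohort(
            samples, cfg, vessel_class=_VARIANT_CLASS.get(variant)
        )
    base_params = nsga_params or NSGAParams()
    splits = mccv_split(lab, n_splits=n_splits, train_fraction=train_fraction, seed=seed)
    split_seeds = [
        int(s.generate_state(1)[0] % (2**31))
        for s in np.random.SeedSequence(seed).spawn(n_splits)
    ]

    train_curves, test_curves = [], []
    for (tr, te), split_seed in zip(splits, split_seeds):
        f_tr, f_te = features.subset(tr), features.subset(te)
        if variant == "baseline":
            train_curves.append(roc_staircase(f_tr.baseline_scores(), lab[tr]))
            test_curves.append(roc_staircase(f_te.baseline_scores(), lab[te]))
        else:
            params = NSGAParams(
                pop_size=base_params.pop_size,
                generations=base_params.generations,
                crossover_prob=base_params.crossover_prob,
                eta_crossover=base_params.eta_crossover,
                eta_mutation=base_params.eta_mutation,
                mutation_prob=base_params.mutation_prob,
                seed=split_seed,
            )
            front = nsga_optimize(f_tr, lab[tr], params,
                                  fixed_weights=_VARIANT_FIXED.get(variant))
            train_curves.append(front.roc())
            test_curves.append(roc_from_solutions(evaluate_solutions(front, f_te, lab[te])))

    return ExperimentResult(
        variant=variant,
        train_aucs=tuple(c.auc for c in train_curves),
        test_aucs=tuple(c.auc for c in test_curves),
        mean_train_curve=interpolate_rocs(train_curves),
        mean_test_curve=interpolate_rocs(test_curves),
        metadata={
            "n_splits": n_splits,
            "train_fraction": train_fraction,
            "seed": seed,
            "pop_size": base_params.pop_size,
            "generations": base_params.generations,
        },
    )
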