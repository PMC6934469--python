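"""Multi-objective weight search: NSGA-II over (weights, threshold).

The decision vector is (w_av, w_caliber, w_dod, w_dfov, t_h): four factor
weights in [0, 1] and a decision threshold over the composed retina score.
Each candidate classifies every retina of the training cohort (relevant iff
score >= t_h) and is evaluated by the two objectives sensitivity and
specificity against the expert consensus labels; both are maximized jointly
so the evolutionary search traces the attainable sensitivity/specificity
trade-off rather than a single operating point.

The implementation is the canonical NSGA-II loop — fast nondominated
sorting, crowding distance, binary tournament selection, simulated binary
crossover and polynomial mutation — vectorized over the population, with an
archive of every evaluated individual. The returned Pareto front is the
nondominated subset of the full archive, which is a superset-safe version of
the final population's first front.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ContractViolationError, UndefinedStatisticError
from .metrics import WeightConfig
from .roc import ROCCurve, roc_from_points
from .scoring import CohortFeatures

N_VARS = 5  # four weights + threshold


def classify_cohort(scores, threshold: float) -> np.ndarray:
    """Binary relevance predictions: score >= threshold."""
    return (np.asarray(scores, dtype=float) >= threshold).astype(int)


def confusion_stats(predictions, labels) -> tuple[float, float]:
    """(sensitivity, specificity) of binary predictions against labels."""
    pred = np.asarray(predictions, dtype=int)
    lab = np.asarray(labels, dtype=int)
    if pred.shape != lab.shape:
        raise ContractViolationError("predictions and labels must have equal length")
    pos = lab == 1
    neg = lab == 0
    if not pos.any() or not neg.any():
        raise UndefinedStatisticError("both classes must be present in labels")
    sens = float(np.sum(pred[pos] == 1) / pos.sum())
    spec = float(np.sum(pred[neg] == 0) / neg.sum())
    return sens, spec


@dataclass(frozen=True)
class CandidateSolution:
    """One evaluated decision vector with its training operating point."""

    config: WeightConfig
    sensitivity: float
    specificity: float

    @property
    def youden(self) -> float:
        return self.sensitivity + self.specificity - 1.0


@dataclass(frozen=True)
class ParetoFront:
    """Nondominated candidate solutions plus the run metadata that produced them."""

    solutions: tuple[CandidateSolution, ...]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        object.__setattr__(self, "solutions", tuple(self.solutions))

    def __len__(self) -> int:
        return len(self.solutions)

    def operating_points(self) -> np.ndarray:
        """(FPR, TPR) rows for the front solutions."""
        return np.array([[1.0 - s.specificity, s.sensitivity] for s in self.solutions])

    def roc(self) -> ROCCurve:
        return roc_from_points(self.operating_points())

    def best(self) -> CandidateSolution:
        """Front solution with the highest Youden index (ties: first found)."""
        return max(self.solutions, key=lambda s: s.youden)


@dataclass(frozen=True)
class NSGAParams:
    """Evolution hyper-parameters (engineering defaults, all exposed)."""

    pop_size: int = 100
    generations: int = 200
    crossover_prob: float = 0.9
    eta_crossover: float = 15.0
    eta_mutation: float = 20.0
    mutation_prob: float = 1.0 / N_VARS
    seed: int = 0


def _dominates_matrix(obj: np.ndarray) -> np.ndarray:
    """d[i, j] True iff i dominates j (maximization, both objectives)."""
    ge = (obj[:, None, :] >= obj[None, :, :]).all(axis=2)
    gt = (obj[:, None, :] > obj[None, :, :]).any(axis=2)
    return ge & gt


def fast_nondominated_sort(obj: np.ndarray) -> np.ndarray:
    """Rank of each individual (0 = first front), maximization in all columns."""
    n = obj.shape[0]
    dom = _dominates_matrix(obj)
    n_dominators = dom.sum(axis=0)
    ranks = np.full(n, -1, dtype=int)
    current = np.nonzero(n_dominators == 0)[0]
    r = 0
    remaining = n_dominators.astype(int).copy()
    while current.size:
        ranks[current] = r
        remaining[current] = -1
        freed = dom[current].sum(axis=0)
        remaining = remaining - freed
        current = np.nonzero(remaining == 0)[0]
        r += 1
    return ranks


def crowding_distance(obj: np.ndarray, ranks: np.ndarray) -> np.ndarray:
    """Per-front crowding distance (boundary individuals get infinity)."""
    n = obj.shape[0]
    crowd = np.zeros(n)
    for r in np.unique(ranks):
        idx = np.nonzero(ranks == r)[0]
        if idx.size <= 2:
            crowd[idx] = np.inf
            continue
        for m in range(obj.shape[1]):
            order = idx[np.argsort(obj[idx, m], kind="stable")]
            span = obj[order[-1], m] - obj[order[0], m]
            crowd[order[0]] = crowd[order[-1]] = np.inf
            if span > 0:
                gaps = (obj[order[2:], m] - obj[order[:-2], m]) / span
                crowd[order[1:-1]] += gaps
    return crowd


def _sbx_crossover(parents: np.ndarray, lo, hi, prob, eta, rng) -> np.ndarray:
    """Simulated binary crossover on consecutive parent pairs."""
    children = parents.copy()
    n_pairs = parents.shape[0] // 2
    for k in range(n_pairs):
        p1, p2 = children[2 * k], children[2 * k + 1]
        if rng.random() > prob:
            continue
        for j in range(parents.shape[1]):
            if rng.random() > 0.5 or abs(p1[j] - p2[j]) < 1e-14 or lo[j] == hi[j]:
                continue
            x1, x2 = min(p1[j], p2[j]), max(p1[j], p2[j])
            u = rng.random()
            beta = (2 * u) ** (1 / (eta + 1)) if u <= 0.5 else (1 / (2 * (1 - u))) ** (1 / (eta + 1))
            c1 = 0.5 * ((x1 + x2) - beta * (x2 - x1))
            c2 = 0.5 * ((x1 + x2) + beta * (x2 - x1))
            p1[j] = min(max(c1, lo[j]), hi[j])
            p2[j] = min(max(c2, lo[j]), hi[j])
    return children


def _polynomial_mutation(X: np.ndarray, lo, hi, prob, eta, rng) -> np.ndarray:
    out = X.copy()
    for i in range(out.shape[0]):
        for j in range(out.shape[1]):
            if lo[j] == hi[j] or rng.random() > prob:
                continue
            x = out[i, j]
            span = hi[j] - lo[j]
            u = rng.random()
            if u < 0.5:
                delta = (2 * u + (1 - 2 * u) * (1 - (x - lo[j]) / span) ** (eta + 1)) ** (1 / (eta + 1)) - 1
            else:
                delta = 1 - (2 * (1 - u) + 2 * (u - 0.5) * (1 - (hi[j] - x) / span) ** (eta + 1)) ** (1 / (eta + 1))
            out[i, j] = min(max(x + delta * span, lo[j]), hi[j])
    return out


def _evaluate(X: np.ndarray, features: CohortFeatures, labels: np.ndarray) -> np.ndarray:
    """Objectives (sensitivity, specificity) for a batch of decision vectors."""
    scores = features.scores(X[:, :4])
    pred = scores >= X[:, 4:5]
    pos = labels == 1
    neg = labels == 0
    sens = pred[:, pos].sum(axis=1) / pos.sum()
    spec = (~pred[:, neg]).sum(axis=1) / neg.sum()
    return np.column_stack([sens, spec])


def nondominated_filter(obj: np.ndarray) -> np.ndarray:
    """Indices of the nondominated, deduplicated points (2 objectives, maximize).

    O(n log n) skyline sweep; among identical objective pairs the earliest
    index is kept, so the result is deterministic.
    """
    _, first = np.unique(obj.round(15), axis=0, return_index=True)
    idx = np.sort(first)
    pts = obj[idx]
    order = np.lexsort((-pts[:, 1], -pts[:, 0]))
    keep = []
    best_second = -np.inf
    for k in order:
        if pts[k, 1] > best_second:
            keep.append(idx[k])
            best_second = pts[k, 1]
    return np.asarray(sorted(keep), dtype=int)


def default_threshold_bounds(features: CohortFeatures, seed: int = 0,
                             n_probe: int = 128) -> tuple[float, float]:
    """Threshold search range [0, q99] from probe scores under the weight bounds."""
    rng = np.random.default_rng(seed)
    probes = rng.random((n_probe, 4))
    probes[0] = 0.0
    probes[1] = 1.0
    scores = features.scores(probes)
    hi = float(np.quantile(scores, 0.99))
    return 0.0, max(hi, 1e-12)


def nsga_optimize(
    features: CohortFeatures,
    labels,
    params: NSGAParams | None = None,
    fixed_weights: dict[int, float] | None = None,
) -> ParetoFront:
    """Run NSGA-II and return the nondominated set over all evaluated individuals.

    ``fixed_weights`` pins decision variables (by index 0-3) to a constant,
    which is how single-factor variants freeze the other three weights at 0.
    Reproducible bit-for-bit given identical inputs, params and seed.
    """
    p = params or NSGAParams()
    labels = np.asarray(labels, dtype=int)
    if labels.size != features.n_retinas:
        raise ContractViolationError("labels length must match the cohort")
    if np.unique(labels).size < 2:
        raise UndefinedStatisticError(
            "optimization refused: training labels contain a single class"
        )

    lo = np.zeros(N_VARS)
    hi = np.ones(N_VARS)
    lo[4], hi[4] = default_threshold_bounds(features, seed=p.seed)
    for j, v in (fixed_weights or {}).items():
        lo[j] = hi[j] = v

    rng = np.random.default_rng(p.seed)
    X = lo + (hi - lo) * rng.random((p.pop_size, N_VARS))
    obj = _evaluate(X, features, labels)
    archive_X = [X.copy()]
    archive_obj = [obj.copy()]

    for _ in range(p.generations):
        ranks = fast_nondominated_sort(obj)
        crowd = crowding_distance(obj, ranks)
        # binary tournament on (rank, -crowding)
        cand = rng.integers(0, p.pop_size, size=(p.pop_size, 2))
        a, b = cand[:, 0], cand[:, 1]
        a_wins = (ranks[a] < ranks[b]) | ((ranks[a] == ranks[b]) & (crowd[a] >= crowd[b]))
        parents = X[np.where(a_wins, a, b)]
        children = _sbx_crossover(parents, lo, hi, p.crossover_prob, p.eta_crossover, rng)
        children = _polynomial_mutation(children, lo, hi, p.mutation_prob, p.eta_mutation, rng)
        child_obj = _evaluate(children, features, labels)
        archive_X.append(children.copy())
        archive_obj.append(child_obj.copy())

        # environmental selection over parents + children
        pool_X = np.vstack([X, children])
        pool_obj = np.vstack([obj, child_obj])
        pool_ranks = fast_nondominated_sort(pool_obj)
        pool_crowd = crowding_distance(pool_obj, pool_ranks)
        order = np.lexsort((np.arange(pool_X.shape[0]), -pool_crowd, pool_ranks))
        survivors = order[: p.pop_size]
        X, obj = pool_X[survivors], pool_obj[survivors]

    all_X = np.vstack(archive_X)
    all_obj = np.vstack(archive_obj)
    front_idx = nondominated_filter(all_obj)
    solutions = [
        CandidateSolution(
            config=WeightConfig.from_vector(all_X[i]),
            sensitivity=float(all_obj[i, 0]),
            specificity=float(all_obj[i, 1]),
        )
        for i in front_idx
    ]
    solutions.sort(key=lambda s: (s.sensitivity, -s.specificity))
    meta = {
        "pop_size": p.pop_size,
        "generations": p.generations,
        "seed": p.seed,
        "n_evaluated": int(all_X.shape[0]),
        "threshold_bounds": [float(lo[4]), float(hi[4])],
    }
    return ParetoFront(solutions=tuple(solutions), metadata=meta)


def evaluate_solutions(front: ParetoFront, features: CohortFeatures, labels
                       ) -> list[CandidateSolution]:
    """Re-evaluate front configurations on another cohort (e.g. the test split)."""
    labels = np.asarray(labels, dtype=int)
    X = np.array([s.config.as_vector() for s in front.solutions])
    obj = _evaluate(X, features, labels)
    return [
        CandidateSolution(config=s.config, sensitivity=float(o[0]), specificity=float(o[1]))
        for s, o in zip(front.solutions, obj)
    ]


def roc_from_solutions(solutions) -> ROCCurve:
    """Upper-left convex-hull ROC through candidate-solution operating points."""
    pts = [[1.0 - s.specificity, s.sensitivity] for s in solutions]
    return roc_from_points(pts)
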