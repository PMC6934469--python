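# Methods

This note documents the models, algorithms, numerical choices and synthetic
study design behind `vesseltort`, and what the shipped experiments do and
do not demonstrate.

## Vessel geometry and the tortuosity metric

Centerlines are ordered planar polylines in pixel units (raster convention:
origin top-left, y downward, coordinates continuous). Raster-derived
integer traces should first pass through `smooth_centerline`, a centered
moving average (default window 5 points, endpoints fixed, window shrinking
symmetrically near the ends); the pipeline never smooths implicitly because
the synthetic generator emits continuous coordinates.

The discrete curvature sign at an interior point is the sign of the z
component of the cross product of the two difference vectors meeting there.
This estimator is parameter-free and orientation-consistent; exact zeros
(collinear triples, detected with a 1e-12 relative tolerance on the cross
product) are reported as sign 0. The constant-sign decomposition takes
maximal runs of equal nonzero sign, places the boundary between adjacent
runs midway through any intervening collinear stretch, and anchors the
first and last subsegment at the vessel endpoints, so subsegments partition
the polyline and share boundary points (their arc lengths sum to the vessel
arc length to machine precision). Two guards handle digitization noise:
zero-sign points never form segments of their own, and any run spanning
fewer than `min_run` interior points (default 3) is merged into its longer
neighbour — single-point sign flips from sub-pixel jitter would otherwise
masquerade as convexity changes. An entirely straight vessel is one
subsegment.

The per-vessel metric is `tau_g = (n-1)/L_c * sum(L_csi/L_xsi - 1)`. The
prefactor follows this form by default; the variant that additionally
divides by `n` (found in older formulations of the same metric) is
available as `MetricConfig(prefactor="original")`. A subsegment whose chord
degenerates to zero (a closed loop, impossible in a valid vessel tree but
tolerated) contributes no ratio term and logs a warning. `tau_g` scales as
1/s under uniform coordinate scaling by s — the arc/chord ratios are
scale-free, the 1/L_c prefactor is not — so scores should be compared at a
common image resolution, which the per-image factor normalization below
also assumes.

## Anatomical factors and normalization

Each vessel's "center point" is the point at half arc length (interpolated
along the polyline, robust to nonuniform sampling). Distances to the
optic-disc center and fovea center are Euclidean distances from that point.
Raw quantities map to normalized factors in [0, 1]:

- `c_AV`: artery 0, vein 1. Consequently `w_AV` is the weight granted to
  arteries and `1 - w_AV` to veins; at `w_AV = 0.5` the class is ignored.
- `c_caliber`: the vessel's mean caliber divided by the largest mean
  caliber in the same retina (clipped to [0, 1]). Per-image normalization
  removes resolution dependence; an absolute pixel scale is available.
- `c_dOD`, `c_dFov`: `max(0, 1 - d / D_norm)`, so proximity to the
  landmark increases the factor and the mapping is bounded and
  nonincreasing. `D_norm` defaults to half the image diagonal; absolute
  pixel scales and multiples of the optic-disc diameter are configurable. A
  vessel whose center point falls inside the optic-disc circle saturates
  `c_dOD` at 1 (the raw distance to the disc center is kept for reporting).

Landmark layouts are validated: the fovea must differ from the disc center,
both must lie inside the image, and a fovea further than ~1–3.5 disc
diameters from the disc center triggers a warning (the usual anatomy is
about 2), not an error.

## Composition

The retina score composes per-vessel values with the anatomical factor as
composition weight. Substituting the local score `tau_c = tau_g * f` into a
ratio composition `sum(tau_c f)/sum(f)` would apply `f` twice; the default
`"weighted-mean"` mode therefore computes `sum(tau_g f)/sum(f)`, treating
`f` purely as the weight each vessel carries in the composition. This keeps
the retina score inside `[min tau_g, max tau_g]` and makes it invariant to
vessel order and, when all factors are equal across vessels, equal to the
plain mean. The double-application reading is kept as
`MetricConfig(composition="literal")` for comparison; every output records
which mode produced it. The baseline score `tau_G` uses `f = L_c`
(arc-length weighting only). A cohort restricted to one vessel class
(artery-only / vein-only analyses) can leave a retina with no vessels; such
retinas score 0 rather than erroring, since "no vessels of the class" is
evidence of absent class-specific tortuosity.

## Weight fitting

The decision vector is `(w_AV, w_caliber, w_dOD, w_dFov, t_h)`: weights
bounded in [0, 1] with no simplex constraint, and the threshold bounded by
[0, q99], the 99th percentile of probe scores over random weight vectors on
the training cohort (an unbounded threshold only wastes search budget).
The two objectives — sensitivity and specificity against the consensus
labels — are maximized jointly by NSGA-II: fast nondominated sorting,
crowding distance, binary tournament selection, simulated binary crossover
(eta 15, rate 0.9) and polynomial mutation (eta 20, rate 1/5 per
variable). Population 100 and 200 generations by default; the
cross-validated experiments use population 60 and 80 generations, which
pilot convergence checks showed is past the point of diminishing returns at
these cohort sizes. All operator parameters are exposed in `NSGAParams`.
Runs are bit-reproducible given the seed. Evaluation is vectorized: the
per-vessel quantities that do not depend on the weights (`tau_g`, arc
length, normalized factors) are precomputed once per cohort, so evaluating
a population is two matrix products.

The returned Pareto front is the nondominated, deduplicated set over *all*
evaluated individuals (an archive), not just the final population; ties in
objective space keep the earliest-evaluated representative, which makes the
front deterministic. Single-factor variants (`av_only` etc.) pin the other
three weights at 0; class-restricted variants (`arteries_only`,
`veins_only`) drop vessels of the other class before scoring.

## Evaluation harness

Candidate solutions map to ROC points `(1 - specificity, sensitivity)`.
The ROC curve of a solution set is the upper-left convex hull of those
points anchored at (0,0) and (1,1) — any hull point is achievable by
randomizing between two configurations — computed by a monotone-chain upper
hull after collapsing duplicate FPRs to their maximum TPR. The baseline
metric has nothing to fit, so its curve is the ordinary empirical staircase
over all thresholds (whose trapezoid AUC equals the Mann-Whitney statistic,
ties counted half). Cross-validation is stratified Monte Carlo: repeated
random 50/50 train/test splits (fraction configurable) preserving class
proportions to within one sample, splitting at the retina level (the
synthetic cohort has one retina per patient). Per-split curves are combined
by vertical averaging — TPR linearly interpolated on a fixed 101-point FPR
grid and averaged pointwise — and the mean curve's trapezoid AUC is
reported. Threshold averaging would be a defensible alternative; vertical
averaging was chosen as the more common convention.

Inter-rater agreement uses the majority vote of the five-rater panel (odd
panel, no ties) as consensus, the exclusive full-consensus / 4-agree /
3-vs-2 row proportions, and binary Cohen's kappa
`(p_o - p_e)/(1 - p_e)`; perfect agreement returns kappa 1 even for
degenerate constant raters (where `p_e = 1` makes the formula 0/0).

## Synthetic study design

The generator emulates the *output* of an upstream fundus pipeline, not
images. Landmarks: a 768x768 px frame, optic-disc radius 42 px, fovea
placed 2 disc diameters from the disc center (±5% distance, ±0.1 rad
angle). Vessels radiate from the disc rim over a ±99° fan toward the fovea
side, 6–10 per retina, lengths 180–280 px; 35% are "main" vessels with
calibers 10–16 px, the rest 3–8 px, with 0.4 px Gaussian per-point caliber
jitter; 40% are arteries. Each vessel is a sinusoid along its baseline
(≥ 60 samples per half-wave), whose half-period count equals its number of
constant-sign subsegments and whose amplitude controls arc/chord excess —
the two drivers of the metric are therefore analytically controllable, and
the generator is cross-checked against the decomposer in tests. Other
curve families (spirals, branch points, vessel crossings) are not
modelled.

Tortuosity is sparse and heavy-tailed: one vessel in five is tortuous
(amplitude 4–14 px, 3–10 half-periods), the rest nearly straight
(amplitude ≤ 2.5 px, 1–3 half-periods). The tortuous count per retina is
set by a severity rate (optionally severity-graded per retina; flat by
default) and the *identity* of the tortuous vessels is random. This is the
deliberate core of the design: with dense, severity-driven tortuosity the
mathematical score and any anatomically weighted score rank retinas almost
identically (pilot rank-AUC ~0.97) and no weighting scheme could
demonstrably help; with sparse tortuosity, a retina's relevance hinges on
*which* vessels are tortuous, which is exactly the information the
anatomical factors carry.

Labels are planted: a retina is relevant iff its anatomically weighted
score under planted weights `w* = (1.0, 0.0, 0.0, 0.4)` reaches a
threshold `t*`, set by default at the score quantile producing a 141:59
non-relevant:relevant split (the consensus distribution the panel design
mirrors), then flipped independently at the label-noise rate. The planted
weights put the signal on the artery/vein distinction with a secondary
fovea-proximity term and none on caliber or disc distance individually —
the factor ranking clinical raters are reported to exhibit. Raters flip
the true label at per-rater error rates (0.12, 0.10, 0.08, 0.06, 0.05),
yielding pairwise kappas in the 0.5–0.9 range and a consensus that
denoises.

Two named study conditions build on the defaults. `headline_conditions()`
(300 retinas, 10% label noise) plants labels with a *mechanism config*
whose fovea factor saturates 2.5 disc diameters from the fovea — roughly
the macular region — while the analysis pipeline keeps its default
half-diagonal normalization. The mechanism is therefore approximable but
not exactly representable by the fitted model, as with real expert
perception. `av_only_conditions()` plants labels through the artery/vein
factor alone with 5% noise, for the single-factor relevance experiment.

## What the experiments show — and what they do not

The shipped experiments demonstrate, on cohorts with planted ground truth:
that the metric implementation matches independent analytic and
combinatorial oracles; that the evolutionary fit recovers planted weight
structure (test-set Youden ≥ 0.9 across optimization seeds at zero noise);
that when relevance genuinely depends on anatomy, the anatomically
weighted metric generalizes measurably better than the purely mathematical
baseline under 10% label noise; and that the single-factor harness
correctly attributes relevance to the factor that generated the labels.
They do not validate the metric clinically: synthetic vessels are
single-segment sinusoids without branching, crossings, segmentation errors
or image-quality effects, rater errors are independent Bernoulli flips
rather than structured disagreement, and the planted-label mechanism is
known. Results on this generator bound what the pipeline can do when its
assumptions hold; they say nothing about how often those assumptions hold
in clinical images.

## Numerical and engineering notes

- Problem sizes: the recovery experiment uses 200-retina train and test
  cohorts and 10 optimization seeds; the cross-validated comparisons use
  10 splits. These sizes give stable statistics at desk scale.
- Degenerate inputs: empty vessel lists and zero total composition weight
  raise `UndefinedScoreError`; single-class label vectors refuse
  optimization, splitting and ROC construction with
  `UndefinedStatisticError` rather than returning NaN.
- Ties: predictions use `score >= t_h`; AUC handles score ties with the
  half-credit convention; nondominated sorting breaks ties by crowding
  distance and then by index, keeping runs deterministic.
- Seeds: every randomized entry point takes one integer seed;
  sub-processes (per-split optimizer seeds, cohort/label/rater streams)
  derive from it via `numpy` SeedSequence spawning, all below 2^31.
- File formats: vessel graphs are versioned JSON (schema "1.0", documented
  in `vesseltort/io.py`), ratings and scores are CSV with a `#` metadata
  header carrying the config hash and seed of the producing run.
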