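# vesseltort

Anatomically weighted quantification of retinal vascular tortuosity.

Tortuosity — the abnormal twisting of retinal blood vessels — is a candidate
biomarker for diabetic retinopathy and several systemic vascular diseases,
but purely geometric tortuosity indices do not capture how clinicians
actually weigh what they see: a tortuous artery near the fovea matters more
than an equally tortuous peripheral vein. `vesseltort` is a toolkit for
researchers studying this gap. It computes the constant-sign-curvature
(Grisan-style) tortuosity of each vessel, weights each vessel by anatomical
factors — artery/vein class, caliber, distance to the optic disc, distance
to the fovea — fits the factor weights and a decision threshold to binary
expert relevance labels with a multi-objective evolutionary search
(NSGA-II), and evaluates metric variants with stratified Monte Carlo
cross-validation and convex-hull ROC analysis. A synthetic-cohort generator
with planted ground truth makes the whole pipeline testable without any
clinical data.

## The metric

A vessel centerline is split into the *n* maximal subsegments over which
the discrete curvature does not change sign. Its mathematical tortuosity is

    tau_g = (n - 1) / L_c * sum_{i=1..n} (L_csi / L_xsi - 1)

with `L_c` the vessel arc length and `L_csi`, `L_xsi` the arc and chord
length of subsegment *i*: more convexity changes and more arc-over-chord
excess both mean more tortuosity, and a straight vessel or single arc
scores 0. Each vessel also receives an anatomical weight

    f_c = [ (w_AV (1 - c_AV) + (1 - w_AV) c_AV)
            + w_caliber c_caliber + w_dOD c_dOD + w_dFov c_dFov ] * L_c

where the normalized factors `c` lie in [0, 1] (`c_AV`: artery 0 / vein 1;
caliber normalized per image; landmark distances inverted and bounded so
closer means larger). The retina-level score composes the per-vessel values
as the f-weighted mean `tau_C = sum(tau_g f) / sum(f)`; the purely
mathematical baseline `tau_G` is the same composition with `f = L_c`. The
four weights plus the decision threshold `t_h` (relevant iff score >= t_h)
are fitted by NSGA-II maximizing sensitivity and specificity jointly
against the majority-vote consensus of a five-rater panel.

## Worked example

Generate a 60-retina synthetic cohort with planted relevance labels and a
five-rater panel, score it, and fit the weights:

```sh
$ vesseltort synth --n 60 --seed 4 --out cohort.json --ratings-out ratings.csv
wrote 60 retinas (18 relevant) to cohort.json

$ vesseltort score --input cohort.json --mode baseline --out tauG.csv
$ head -4 tauG.csv
# config_hash=44c773d53837 mode=baseline weights=
retina_id,tau,mode,composition
r000,0.00803946993414,baseline,weighted-mean
r001,0.000192024974752,baseline,weighted-mean

$ vesseltort optimize --input cohort.json --ratings ratings.csv \
      --seed 0 --pop 60 --gens 60 --out front.json
Anatomically weighted tortuosity fit
====================================================
variant:            proposed
retinas:            60  (relevant: 18)
composition:        weighted-mean
NSGA-II:            pop 60, 60 generations, seed 0
evaluated:          3660 candidates
Pareto front size:  1
train ROC hull AUC: 1.000
----------------------------------------------------
selected operating point (max Youden):
  w_av=0.881  w_caliber=0.008  w_dod=0.000  w_dfov=0.086
  threshold t_h=0.008895
  sensitivity=1.000  specificity=1.000  Youden=1.000
```

The per-retina `tau` column is the composed tortuosity score (dimensionless
for the baseline; pixel-scaled under anatomical weighting). The fit
recovers an operating point dominated by the artery/vein weight — the
cohort's labels were planted with exactly that structure — and classifies
every training retina correctly, so the Pareto front collapses to the
single ideal point. `vesseltort agreement --ratings ratings.csv` prints the
consensus proportions and the pairwise Cohen-kappa table of the synthetic
panel, and `vesseltort evaluate` runs the cross-validated
baseline-vs-weighted comparison.

The same workflow is available as a library:

```python
import vesseltort as vt

samples, labels, ratings, t_star = vt.generate_study(vt.GeneratorConfig(), seed=4)
model = vt.TortuosityModel(samples, labels)        # variant="proposed"
res = model.fit(seed=0)                            # NSGA-II weight search
print(res.summary()); print(res.weights)           # Pareto front + max-Youden point
```

## Scope

The toolkit consumes *annotated* vessel graphs (centerline coordinates,
artery/vein labels, caliber samples, optic-disc circle, fovea center) in a
versioned JSON schema documented in `vesseltort/io.py`. Image processing —
vessel segmentation, centerline extraction, landmark detection, artery/vein
classification — is upstream and out of scope.
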