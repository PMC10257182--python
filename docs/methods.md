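# Methods

## Problem setting

Senolytics — compounds that selectively kill senescent cells — are rare, and
the published evidence for them is small and heterogeneous: a few dozen
positives mined from papers and patents, set against thousands of library
compounds assumed inactive. `senoscreen` implements a virtual-screening
pipeline built for exactly this regime: physicochemical featurisation of
SMILES, diversity quality control of the positive set, precision-first
training of imbalanced binary classifiers, library screening with extreme-
outlier hit calling, and dose-response quantification of validation plates.

## Featurisation

Compounds are represented by the full continuous physicochemical descriptor
set of RDKit (~200 descriptors: molecular weight, partial charges, valence
electrons, Chi connectivity, E-state and Kappa shape indices, ...).  The
descriptor provider is an interface: a "precomputed" provider reads
descriptor CSVs so every downstream stage runs without a chemistry toolkit.
Isomeric SMILES are preferred where available; unparseable SMILES are
excluded and logged rather than silently dropped.

Non-finite descriptor values (some descriptors are undefined for some
molecules) are handled by policy; the default `drop_feature` removes the
offending columns, keeping the compound set intact.  How such values were
handled in the original data assembly is not documented anywhere we know
of, so the default is our own choice, stated here rather than asserted as
anyone else's.

Z-scoring uses the sample SD (ddof = 1) per feature, fitted on the training
table and *applied* to screening libraries — normalising a screening library
with its own statistics would leak distributional information between
libraries.  Constant columns are flagged and mapped to 0.  The prediction-
score z-scores in the screening module use the same sample-SD convention for
consistency; at library sizes in the thousands the sample/population
distinction is far below every decision threshold in the pipeline.

## Diversity quality control

Three complementary views of how clustered the positive set is:

1. **k-means / silhouette curve** under the cosine distance between
   z-scored descriptor vectors.  Rows are normalised to unit length so
   Euclidean k-means performs spherical updates (on the unit sphere,
   ‖u−v‖² = 2·cosine distance).  The score is the within-cluster sum of
   point-to-centroid cosine distances; the silhouette uses the same metric.
   Both are averaged over repeats with different initial seeds (default
   100).  A near-linear score decrease and low silhouettes indicate a
   diverse, poorly clustered positive set.

2. **Continuous Tanimoto graph.**  The continuous Tanimoto distance
   1 − u·v/(‖u‖² + ‖v‖² − u·v) is computed on per-feature min-max rescaled
   descriptors, because the Tanimoto form misbehaves on negative
   coordinates; a clamp to [0, 1] guards floating-point excursions, and two
   all-zero vectors are at distance 0 by convention.  The complete distance
   graph is sparsified to **MST ∪ symmetrised 7-NN**.  A literal
   intersection of MST with a kNN graph can never exceed n − 1 edges, which
   contradicts the edge counts such graphs are reported to have (hundreds of
   edges on ~58 nodes); the union is the only construction consistent with
   those counts, and a `combine="intersection"` switch is provided for
   sensitivity checks.  kNN rank ties break by compound id so the graph is
   deterministic.

3. **Louvain resolution sweep.**  Community detection runs on similarity
   weights (1 − distance) across a γ grid (default 0.1–3.0, step 0.05,
   100 runs per γ).  Plateaus — maximal γ intervals on which the rounded
   mean community count is constant and at least `min_width` wide — flag
   candidate natural cluster numbers.  The adjusted Rand index against the
   literature-source labels measures whether communities merely recover
   provenance; values indistinguishable from 0 mean they do not.

## Feature selection and PCA profile

Descriptors are ranked by mean decrease in Gini impurity over a random
forest (default 500 trees; deterministic given a seed; ties in importance
break by feature name).  The selection policy is configurable (`top_k`,
`above_mean`, `above_threshold`); reproduction-mode configs use
`top_k(165)` as a stated reproduction parameter — no published cutoff rule
exists to derive it from.  Selection deliberately runs on the full table
before any split, mirroring the original workflow, which makes downstream
hold-out metrics over-optimistic; that caveat is inherent to the design
being reproduced, and a strict per-fold mode is the obvious extension for
honest evaluation.

The PCA explained-variance profile documents the intrinsic dimensionality
of descriptor data; on the synthetic generator's default covariance,
~198 of 200 components are needed for 99% variance, and on real descriptor
matrices more than half the features are typically required — which is why
feature selection removes relatively little.

## Imbalanced model harness

Five algorithm families: RBF-kernel SVM, random forest, gradient-boosted
trees (XGBoost), logistic regression, Gaussian naive Bayes.  Scoring uses
precision = TP/(TP+FP), recall = TP/(TP+FN), F1 = TP/(TP+(FP+FN)/2); at
~2% prevalence accuracy is uninformative and is not reported.  Undefined
metrics (zero denominators) propagate as flagged NaNs and are excluded from
fold means with the exclusion count reported — coercing them to 0 would
silently punish abstaining classifiers.

Cross-validation is stratified (per-fold positive counts differ by ≤1).
SMOTE (synthetic minority points as convex combinations of minority
kNN pairs; implemented in-package) is applied **inside training folds
only**.  Grid search maximises mean CV precision with ties broken toward
the smaller hyperparameter value.  The 70/30 stratified split at study
scale (2523 rows, 58 positives) holds out exactly 17 positives and 740
negatives.

Probability scores: tree and linear models expose their native calibrated
probabilities.  The SVM's probabilities come from a Platt sigmoid fitted on
cross-validated decision values of the training data, with the same class
weighting as the SVM itself — so a class-weight-balanced SVM produces
probabilities of the *balanced* problem, consistent with how
`class_weight="balanced"` behaves in the other estimators.  (A sigmoid
calibrated to raw label frequencies would pin every probability below 0.5
at 2% prevalence, making the 0.5-threshold confusion matrix degenerate for
any non-separable data.)  Confusion matrices use a strict score > 0.5
threshold by default; screening uses its own cutoffs.

**Null calibration.**  The harness's no-leakage check uses balanced specs
with shallow trees (`balanced_specs()`): with balanced weights and limited
depth, leaf probabilities track the weighted class split instead of
collapsing to pure majority leaves, so every algorithm emits positive
predictions even on label-independent features.  Pooled over folds, the
precision of those predictions must sit within 3 binomial SDs of
prevalence; pooling (rather than averaging per-fold ratios) gives the band
a well-defined denominator.

## Screening

The trained model scores the library; scores are standardised over the
library alone (not training + screening pooled), and hits are compounds
exceeding **all** set cutoffs with strict inequality (score > p_min,
z > z_min).  The default probability cutoff is 0.44 with the implied
z-score of the lowest-scoring hit reported, so a hit set can be described
either way.  Rank ties break by compound id.  Hits are related back to the
training positives by continuous Tanimoto distances (min/median per hit,
plus the fraction of training compounds at distance ≥ 0.99), and a 2-D
t-SNE (perplexity 50, learning rate 200, 1200 iterations, fixed seed)
embeds training and screening sets together for overlap inspection.

## Assay analysis

Nuclei counts are normalised to the vehicle-well mean (×100).  Dose-response
data are fitted by ordinary least squares to the log-inhibitor vs
normalised-response variable-slope curve

    response = bottom + (top − bottom) / (1 + 10^((log10 IC50 − log10 d)·hill)),

with the top plateau fixed at 100%, bottom free but bounded to [0, top]
(the original fitting software constrains the top only; bottom handling is
unstated, and an unbounded bottom can drift negative on noisy plates).
Fitting is multi-start over both slope signs and five IC50 positions across
the tested range; a fit whose plateaus are within 10 percentage points of
each other carries no IC50 information and is flagged non-converged rather
than raised.  IC50s outside the tested dose range carry an extrapolation
flag.  Replicates are fitted as individual points (fitting to means is the
other defensible choice; individual points weight the fit by replicate
count).  The senolytic index is SI = IC50(control)/IC50(senescent), defined
only for two converged fits in the same dose units.

## Synthetic-data generator

The generator emulates the statistical structure of the real screen, not
its chemistry: descriptors are simulated directly in feature space.

* **Negatives:** zero-mean Gaussian, unit marginal variance, equicorrelated
  blocks of 10 features at `feature_correlation` (default 0.3).  Gaussian
  blocks keep the intrinsic dimensionality high, qualitatively matching
  descriptor matrices where PCA needs most components.  No public
  distributional description of LOPAC/Prestwick descriptor space exists;
  this family is a stand-in, and conclusions from passing tests are about
  the pipeline's statistical machinery, not about real chemical matter.
* **Positives:** same covariance, mean shifted by `effect_size` (in
  marginal-SD units, random ± signs) on `n_informative` of the features
  (default 40 of 200), plus a per-source offset with SD `source_separation`
  on the same features, drawn once per source.  Positives are split across
  15 sources with geometrically decaying counts, mirroring few-large /
  many-small literature sources.
* **Defaults are the study conditions:** 2465 negatives + 58 positives
  (2.3% prevalence), 200 features, 15 sources, 4340-compound screen.
  `effect_size` defaults to 1.0 (moderate signal); recovery analyses use
  2.5 (strong, comfortably above the ≥2 regime in which full recovery is
  expected).  `screen_active_frac` defaults to 0.005 (~22 planted actives
  in 4340 — the order of the hit set a selective screen returns).
* **Label noise** flips a fraction of negative labels to positive,
  modelling background compounds that are in truth unreported senolytics;
  default 0.
* **Ground truth** (informative indices, source means, plant flags) travels
  in a separate field, is serialised only to a sidecar JSON, and is never
  written into descriptor CSVs — no training path can touch it by
  construction.  Screening rows come from an independent random substream,
  so no screening row duplicates a training row.

## Determinism and problem sizes

All randomness descends from one master seed through named substreams
(table generation, fold assignment, model init, SMOTE, k-means repeats,
Louvain runs), recorded in the run manifest; identical configs produce
byte-identical outputs.  The test suite exercises most components on
scaled-down tables (hundreds of rows, tens of features) and runs the
end-to-end recovery, null-calibration and counting checks at the full
default scale; the acceptance script reruns those full-scale analyses (10
recovery seeds, 100 Louvain runs, all five algorithms) in a few minutes on
one CPU.

## Known limitations

* The Gaussian-block generator has no heavy tails, no discrete descriptors
  and no duplicated chemotypes; real descriptor matrices have all three.
* Null-calibration guarantees are statements about pooled precision under
  balanced specs; they do not certify calibration of any individual model's
  probabilities.
* The dose-response fitter assumes a monotone single-site curve; biphasic
  responses will fit poorly and surface only through the residual sum of
  squares.
* The deep-learning benchmark sometimes run alongside such pipelines, SAR
  interpretation, and all wet-lab statistics are out of scope.
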