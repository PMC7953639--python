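# Methods

This note documents the models, the synthetic-data design, the numerical
conventions and the open design choices made in `stillstack`, in that
order. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## 1. The synthetic registry generator

The generator (`stillstack.synth`) emulates the statistical skeleton of a
national perinatal registry in which stillbirth prevalence is 0.396%,
per-feature missingness lies in [0%, 4.63%], about 19.74% of rows carry at
least one missing value, and the stillbirth timing variable splits 4557
before delivery / 144 during delivery / 801 unknown out of 5502
stillbirths. Two of the published accountings of these totals disagree
(5502 vs 5602 stillbirths; 801 vs 901 unknown); the generator defaults to
the internally consistent 5502 accounting and exposes every count as a
parameter rather than resolving the discrepancy.

Design:

- **Label accounting is exact, not sampled.** The stillbirth count is
  `round(n_total * stillbirth_rate)` with random row placement, and the
  before/during/unknown split is likewise fixed by rounding. This keeps
  tests on tiny n deterministic. With `n_total = 20000` and
  `stillbirth_rate = 0.2751` a table carries exactly 5502 stillbirths and
  reproduces the 4557/144/801 split.
- **Class-conditional forms.** Numeric features are Gaussian location
  shifts: base N(loc, scale) for livebirths, shifted by `effect` scale
  units for stillbirths and additionally by `effect_timing` for
  during-delivery cases. The gestational-age analogue uses a two-component
  Gaussian mixture for the stillbirth class instead, reflecting the
  non-linear, fluctuating shape of the empirical stillbirth distribution
  over gestational weeks. Binary features get an additive logit shift;
  nominal/ordinal features an exponential probability tilt across level
  scores spread over [-1, 1]. Non-informative features are identically
  distributed in all classes. The default schema's numeric moments follow
  the published class-conditional statistics (gestational age 38.53±1.57
  vs 34.95±3.99; fetal weight 3122.9±485.7 vs 2198.2±939.8; maternal age
  27.98±6.27 vs 29.73±6.73; pregnancy count 2.61±1.67 vs 3.05±1.92).
- **Unknown-time rows** are drawn from a latent before/during mixture at
  the known-time odds, then relabelled `unknown`: the timing exists but
  was not recorded. At inference, `unknown` is therefore treated as
  missing ground truth, never as a predictable class.
- **Missingness is MCAR.** The mechanism is unstated in the source
  material; MCAR keeps imputation behaviour analysable. Per-feature rates
  follow a deterministic heavy-tailed pattern capped at 4.63%, with a
  common scale factor solved by bisection so the expected any-missing row
  fraction is 19.74%; a couple of features sit exactly at the cap, many at
  zero, matching the published range.
- **Determinism.** Every stream derives from `(seed, stream index)` via
  `numpy` `default_rng`, so identical configurations are bit-identical,
  including mask positions.

What the generator does **not** model: covariance among features
(province–hospital nesting, parity–age correlation), geographic realism,
informative missingness, temporal drift. Passing tests therefore show the
*method* behaves as specified on data with this skeleton; they say nothing
about clinical performance on real registry data.

Two schemas are provided: `default_schema()` (50 features mirroring the
published feature list, codes f1–f53) and `compact_schema()` (a 14-feature
subset covering all four dtypes and the strongly informative perinatal
features) used where the full stack must be refitted many times.

## 2. Preprocessing

- Features with missing fraction **strictly greater** than 5% are removed
  (the rule is "more than 5%", so an exactly-5% feature survives).
- Imputation is median (numeric) / mode (categorical), with ties broken
  toward the lowest level code. Model-based imputation was deliberately
  excluded: the procedure must be deterministic and auditable, and an
  imputed-cell mask is retained.
- Encoding: binary → {0,1}; ordinal → integer codes (order preserved);
  nominal → one-hot over training levels plus an explicit `__other__`
  column that absorbs unseen levels at transform time (logged as a
  warning, never an exception); numeric → min-max to [0,1] using
  *training-split* statistics only. Constant columns map to 0 (the min-max
  formula is undefined at zero range, and 0 avoids NaN propagation).
  Fitted parameters round-trip through JSON so test rows are always
  encoded with training statistics (no leakage).
- Class balancing is seeded majority undersampling on training splits
  only (default ratio 1:1). At 0.4% prevalence several of the base
  classifiers cannot learn anything from the raw class ratio;
  undersampling is the cheapest reproducible remedy. Whether the original
  study up- or down-sampled, and in which order relative to
  normalization, is unstated; both orderings are reachable through the
  configuration, with undersampling-after-encoding as the documented
  default.

## 3. Consensus feature ranking

Three importance measures over five classifiers populate the meta feature
table (MFT), rows = features, columns = (classifier, measure) pairs:
{DT, GBC, RF} × {GI, MDA} and {LR, SVM-linear} × {MC, MDA}. A fourth
measure ("CN") is mentioned once in the source methodology but never
defined anywhere; it is not implemented.

- **MDA** permutes all encoded columns of a feature *jointly* (the one-hot
  block of a nominal feature moves as a unit) and averages the drop from
  baseline accuracy over `n_repeats = 10` seeded permutations (5 in the
  desk-scale drivers), computed on held-out rows rather than training
  rows. Scores may be negative. The held-out choice and the repeat count
  are this package's decisions; the source does not state either.
- **GI** is total impurity decrease aggregated over trees and one-hot
  blocks, normalized to sum to 1.
- **MC** is the absolute hyperplane coefficient, one-hot blocks aggregated
  by maximum absolute value; inputs are normalized so magnitudes are
  comparable. Defined only for linear models (LR, linear-kernel SVM).

MFT columns are min-max normalized (constant columns → 0) so no
(classifier, measure) pair dominates. Rows are clustered by Lloyd's
K-means (Euclidean distance, random data-point initialization, 10 seeded
restarts keeping the lowest within-cluster sum of squares, 300-iteration
cap). K is swept from 2 to 10 and the mean silhouette
s(i) = (b−a)/max(a,b) selects the top candidate values of K; singleton
clusters contribute silhouette 0 by convention (the definition is silent
there), and the all-singletons partition scores 0.

Clusters are ranked by the **unweighted mean of their centroid
coordinates**, descending. The source says only "centroid feature
scores"; the unweighted mean treats all normalized columns equally, which
is the same rationale the normalization step is built on. Ties break by
cluster size (larger first), then cluster id. Feature sets are unions of
the top-ranked clusters across the two tasks; the default keep-rule drops
only the lowest-ranked cluster per task. Per-task ranking (step-1 MFT for
the step-1 task, step-2 MFT for the step-2 task) is used throughout.

## 4. The stacked ensemble

Two consecutive layers of the same five base classifiers in normal
stacking mode; the meta features are **hard predicted labels** (the
specified contract), with probability stacking available behind
`SEConfig(use_proba=True)` but off by default. Layer 2 and the aggregator
see exactly five columns; raw features never re-enter the stack.

**Out-of-fold stacking.** Training each next stage on in-sample
predictions of the previous stage leaks training fit into the meta
features. The source describes the direct wiring only, so both modes are
implemented; the default is out-of-fold (5-fold cross-validated
predictions), a deliberate deviation documented here. `stacking="direct"`
restores the literal wiring.

**Vote-boosting aggregation.** The source cites an agreement-based
instance-weighting idea without equations; the concretization here is:

1. agreement a_i = (plurality vote count)/5 ∈ {0.6, 0.8, 1.0};
2. initial instance weights ∝ Beta(α, α) density at a_i (clipped to
   [0.01, 0.99]); α = 1 (default) gives uniform weights, α > 1 emphasizes
   disputed instances, α < 1 emphasizes unanimous ones;
3. boosted decision stumps over the five meta-columns: each round picks
   the column whose direct vote minimizes weighted error, with the usual
   log-odds round weight, and rounds with error ≥ 0.5 are rejected.

Restricting stumps to *direct column predictors with non-negative round
weights* makes the unanimity invariant provable: when all five votes
agree on an instance, every admissible stump casts that same vote, so the
aggregate equals it regardless of the learned weights. If no column beats
chance in the first round, the aggregator degrades to an unweighted
majority vote. The aggregator's score is the weighted vote mean in [0,1];
ties at exactly 0.5 resolve to the positive class (stillbirth / during),
privileging sensitivity.

Default hyperparameters (DT depth 8; GBC 60 trees, depth 3; LR C=1; RF
100 trees; SVM linear C=1) and the small grids used for 9:1 grid search
are this package's choices; the source gives none. Layers are tuned
per-layer, not jointly. All stage seeds derive from a master seed via
`SeedSequence`, so fit and predict are reproducible bit-for-bit.

## 5. The two-step hierarchy

Step 1: stillbirth (positive) vs livebirth, trained on all rows. Step 2:
during (positive) vs before delivery, trained only on known-time
stillbirths; unknown-time rows are counted in an exclusion log. Routing
at inference: step-1 negatives are final (`livebirth`); positives receive
step 2's label. Every instance gets exactly one of three labels, and
unknown-time rows do get step-2 predictions when step 1 flags them.

Per-step feature sets may differ; the default uses the same top-cluster
union for both steps. Step-2 metrics are computed on ground-truth
known-time stillbirths by default (isolating step-2 quality);
`step2_on_routed=True` restricts to rows step 1 actually routed, since
the source does not say which convention its reported numbers use.

## 6. Evaluation

- Confusion metrics use the convention *undefined ratio → 0 with a
  warning* (e.g. precision with no positive predictions).
- ROC/PR curves come from a full threshold sweep; the PR curve is kept as
  the raw zigzag, uninterpolated. Trapezoidal ROC-AUC equals the
  normalized Mann–Whitney concordance exactly (tested to 1e−12).
- Cross-validation is stratified on the four-way label (livebirth /
  before / during / unknown) so every fold can train both steps; the
  whole pipeline, including imputation, encoding and balancing, is
  refitted per fold. The reported "average" block is the arithmetic mean
  of the step-1 and step-2 metrics. Leave-one-out is intentionally
  unsupported: it contradicts stratification, which the two-step design
  requires.
- Calibration is isotonic regression (pool-adjacent-violators); the
  "calibration score" is the Brier score of the calibrated
  probabilities, chosen because the source's score of similar magnitude
  is most plausibly a Brier value; log-loss can be substituted by the
  caller.
- The permutation-null test refits the model on randomly permuted
  training labels (the standard exchangeable null — the source's "random
  different training datasets" is read as this) and records held-out AUC;
  p = (1 + #{null ≥ observed})/(1 + N) is never zero. The API takes a
  `fit_score` callable, so the null can be built for the full stacked
  ensemble or for a cheap surrogate when thousands of refits are needed.

## 7. Desk-scale study conditions

The reference study analyzed ~1.4M births with 10,000 permutation
repeats. This package's drivers and tests run on one CPU in minutes, so
the experiment defaults are scaled down, chosen once as follows:

- **Registry-statistics checks** use prevalence-true tables
  (rate 0.00396) at n = 50,000–100,000, where the 0.396% / 19.74% / 4.63%
  statistics are measurable.
- **Model-development tables** are case-control style (enriched
  stillbirth rate 0.25–0.2751 at n = 4,000–20,000). At true prevalence
  and desk n, a table holds ~2 during-delivery rows, making step 2
  degenerate; enrichment is the standard epidemiological answer. The
  0.2751 rate makes a 20,000-row table carry exactly 5502 stillbirths —
  the size of the second-step cohort in the source registry.
- Ranking recovery uses 50 seeded registries (n = 1200, three planted
  features at effect 1 SD among 7 noise features); ensemble ordering uses
  20 seeded datasets (n = 4000) in the test suite and 10 in the
  acceptance script; the permutation-uniformity check runs 100 runs at 99
  repeats with a logistic-regression surrogate in the significance API
  (the uniformity property is classifier-agnostic; refitting the full
  stack 10⁴ times is not informative enough to justify its cost).
- The experiment driver records a manifest (config hash, seed, version)
  sufficient to reproduce every artifact byte-identically.

## 8. Known limitations

- The generator's independence assumption means consensus ranking is
  never confronted with correlated predictors, where permutation
  importance is known to split credit; real-registry rankings would need
  the pairwise-dependence hooks this package does not provide.
- Step-2 performance at desk scale is limited by the tiny during-delivery
  class (~60–150 rows); cross-validated step-2 metrics are accordingly
  noisy and well below step-1 metrics.
- The vote-boosting concretization is one member of the family the source
  sketches; other emphasis functions satisfy the same contract.
- No DeLong confidence intervals for AUC; dispersion is reported across
  CV folds only.
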