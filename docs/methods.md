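# Methods

This note documents the models, the synthetic-data generator, the numerical
choices and the known limitations of `fairsite`. It states no empirical
result that the test suite or `scripts/acceptance.py` does not itself
compute.

## Problem setting

One row per patient presentation: a feature vector x (19 routinely
collected clinical measurements — vital signs, full blood count, liver
function, electrolytes), a binary outcome y (infection status confirmed by
a reference test), and a site label z (one of five hospitals). The task is
binary classification with a calibrated operating point; the fairness
question is whether the thresholded classifier's error rates are equal
across sites (equalized odds: Ŷ ⫫ Z | Y).

## Synthetic cohort generator

Real multi-hospital screening datasets are access-controlled, so the
generator emulates the statistical structure the analysis depends on,
without claiming physiological realism.

**Model.** For each site independently: y ~ Bernoulli(prevalence); each
feature is drawn from a class-conditional Gaussian with negative-class mean
0, positive-class mean equal to the feature's class effect (in SD units)
and unit SD, then transformed by the site's affine shift
x ↦ scale·x + loc. Outlier rows (probability `outlier_rate`, default 0.01)
have one randomly chosen blood-count analogue multiplied by 10, emulating
rare extreme haematology values. Missingness is applied last, completely at
random per feature. Each site owns a random stream keyed by (global seed,
CRC32 of the site id), so adding or reordering sites leaves other sites'
draws untouched, and identical configurations are byte-identical.

**Default scenario.** Four majority sites of 2000 rows at prevalences
0.050 / 0.043 / 0.053 / 0.122, and one minority site of 215 rows
(~2.6% of the cohort) at prevalence 0.747 — the size and case-mix imbalance
typical of a small specialised infectious-disease ICU joining a consortium
of large emergency departments. The minority site's respiratory rate and
temperature are location-shifted by +2.4 and +1.9 SD. These sizes place the
two-sample KS statistic against any majority site near 2Φ(d/2) − 1
(≈ 0.77 and 0.66), inside the 0.6–0.8 band observed for strongly drifted
vitals in real cross-country comparisons, while all other features stay
well below 0.5. Class effects (respiratory rate 1.2, temperature 0.9,
plus weaker haematology effects including negative lymphocyte/eosinophil
effects) deliberately overlap the shifted features: the drifted vitals are
also the most informative predictors, which is exactly the regime where
"drop the shifted features" is costly and algorithm-level debiasing is
interesting.

**What the generator does not model** — and therefore what passing tests do
not establish about real data: correlations between analytes, temporal or
seasonal dynamics, site-specific measurement protocols beyond an affine
shift, label noise from imperfect reference tests, and informative
missingness. Results here validate the machinery and the direction of the
effects, not effect sizes on any real cohort.

An optional `age` column (Normal(55, 18) clipped to [18, 100]) supports
case–control matching only and is never a predictor, since the feature
schema is fixed to the 19 clinical measurements.

## Cohort preparation

- **Matching**: each case receives exactly `ratio` (default 20) distinct
  controls within `age_window` years, greedily nearest-age without
  replacement, cases processed in a seeded random order. Output prevalence
  is exactly 1/(ratio+1). The matcher errors on the first case whose
  eligible pool is too small rather than silently relaxing the window.
- **Splits**: label-stratified 60/20/20 with largest-remainder rounding per
  class, ties broken in split order (train, continuous validation, test);
  deterministic given the plan seed. In the pipeline each site is split
  independently, mirroring per-extract splitting.
- **Missingness filter**: a feature is dropped iff its missing fraction
  exceeds 0.30 *strictly*, measured on training rows when split tags exist
  (a `pooled` scope covers single-extract use).
- **Standardisation and imputation**: per-feature training mean, population
  SD (divide by n) and raw-scale median. Missing entries are imputed with
  the raw median first, then all values standardised; this order makes
  imputation and standardisation commute for observed values and maps every
  imputed entry to (median − mean)/SD. Imputation alone is idempotent.
  Zero-variance features are rejected by name. State is fit on training
  rows only and applied unchanged to validation and test.

## Covariate-shift screening

Per feature, a two-sample KS test between every reference site and the
target site, plus all reference-site pairs; missing values are dropped
pairwise. The Bonferroni factor counts every test performed
(features × pairs). A feature is *selected* as drifted when its minimum KS
statistic across all reference–target pairs exceeds 0.5 and its corrected
p-value is below 1e-4 in each of those pairs — requiring significance in
every pair, not any pair, so a single anomalous reference cannot nominate a
feature. The 0.5 cut-off is a parameter; KS is invariant to monotone
transforms, so running the scan before or after standardisation is
equivalent. A Kruskal–Wallis scan per feature across all sites is provided
as a purely descriptive companion.

## Models

All four families satisfy one contract: `score(rows)` returns P(y=1) per
row, deterministically for a trained model.

**Gradient boosting** (XGBoost, 200 trees, depth 4, learning rate 0.1,
single-threaded, seeded) is the reference model; its internal gain-based
importance ranking is normalised to sum 1.

**Feedforward network.** Hidden layers (32, 16) with ReLU, linear→sigmoid
output, binary cross-entropy, Adam at 1e-3, batch 256, 50 epochs, seeded
shuffling; He initialisation. The numerical core is a small dense-network
implementation with manual backpropagation whose backward pass also returns
the gradient with respect to the network *input* — the hook the adversarial
coupling needs. Determinism is to within accumulation order (tested at
1e-6). Published hyperparameter sets for this screening task are not
available, so these defaults are explicit configuration, not constants.

**Adversarial debiasing.** A site adversary (hidden (16,), softmax over the
5 sites) reads the classifier's sigmoid score concatenated with the true
label; conditioning on the label makes the adversary's target the
within-class score distributions, i.e. equalized odds rather than
demographic parity. Training is a joint single pass with gradient reversal:
the classifier descends BCE − λ·(adversary cross-entropy), the adversary
term flowing back through the score; an alternating-updates mode is
available behind a flag. Three design choices matter at this class
imbalance and are deliberate:

- the adversary's cross-entropy is class-weighted by inverse site
  frequency — with a ~2.6% minority site an unweighted adversary collapses
  to the majority sites and provides almost no debiasing gradient for the
  site that needs it;
- the adversary runs at a higher learning rate (5e-3) with 3 updates per
  classifier update, so it tracks the non-stationary classifier instead of
  lagging into irrelevance;
- λ defaults to 2.0 and the default epoch budget is 150: the adversarial
  dynamic converges more slowly than plain supervised training, and at this
  imbalance λ=1 under-corrects. A `sweep_lambda` utility tabulates the
  adversary's residual (balanced) site accuracy across λ values; it should
  fall toward chance (1/5) as λ grows.

Diagnostics report per-epoch losses and the final adversary accuracy, raw
and balanced over sites.

**RL debiasing.** Classification as a one-step contextual bandit: the
policy network (same backbone, 2-action softmax head) samples an action per
row, receives +1 for a correct call and −1 otherwise, and is updated by
REINFORCE with a moving-average baseline (momentum 0.9) — gradients flow
only through the action actually taken, which is the selective-feedback
property that distinguishes the paradigm from supervised learning. An
episode is one pass over the training set; the default budget is 200
episodes. Fairness shaping multiplies each sample's reward by
w_g = N/(G·n_g) for its (site × label) group — proportional to 1/n_g and
averaging exactly 1 over the training set — so the total learning signal is
equalised across groups. With shaping off and separable data, the learned
decision boundary agrees with the supervised network's (tested at ≥95%
row agreement). Exploration comes from the stochastic policy itself;
the sampling temperature is fixed at 1.

## Evaluation

- **Threshold calibration**: candidates are 0, 1 and all midpoints between
  adjacent sorted unique validation scores (the complete set of achievable
  operating points under score ≥ t → positive). Among candidates within
  ±0.05 of the 0.9 sensitivity target, the one maximising specificity is
  chosen (ties to the larger threshold); if none is feasible the closest
  candidate is returned flagged infeasible. Because the feasible set is
  defined by the tolerance, the achieved validation sensitivity is in-band
  by construction whenever feasibility holds.
- **Metrics**: AUROC (rank statistic; ties 1/2), AUPRC (step-wise
  precision-recall integral, not interpolated), and thresholded
  sensitivity/specificity/PPV/NPV. PPV and NPV use the evaluated set's own
  prevalence. A metric with an empty denominator (e.g. specificity at a
  site with no negatives) is reported as an explicit absent value, never 0.
- **Uncertainty**: 95% percentile intervals over 1000 whole-set bootstrap
  resamples, unstratified by default (a stratified option guards degenerate
  small sets); all six metrics share the same resamples. Model comparison
  is the one-sided paired bootstrap — the same resample indices applied to
  both models; p is the fraction of iterations where A does not beat B,
  exact ties counting one half, so a model against itself yields exactly
  0.5.
- **Fairness**: SD_TP and SD_FP are population SDs (the site set is the
  population of interest, not a sample; a `ddof` option gives the sample
  SD). The false-positive rate uses the standard FP/(FP+TN) denominator; an
  `as_printed` audit variant with denominator TP+FN is retained because
  both conventions appear in the applied literature. Sites contribute
  equally regardless of size.

## Experiment protocol and problem sizes

The pipeline evaluates one model roster per seed: generate → split →
filter → standardise → drift scan → train → calibrate on validation →
evaluate on test (overall, equalized odds, and per site). Stochastic
study-level properties (debiasing direction, feature-removal trade-off,
null behaviours) are judged by the median over five independent replicates,
each redrawing the cohort and reinitialising the models with the replicate
seed — a single synthetic draw proves little, and medians are robust to an
occasional unlucky replicate. The default scenario (8215 rows, 19 features)
keeps a full five-replicate comparison under a couple of minutes on one
CPU; the minority site's test split has only ~43 rows, so per-site rate
estimates there are intrinsically noisy, which is the realistic regime for
a small collaborating site.

## Known limitations

- SD_TP at desk scale is dominated by sampling noise (20–50 test positives
  per majority site); improvements smaller than ~0.02 are not resolvable
  from a single replicate.
- The adversarial and RL formulations implement one declared design each
  (label-conditioned score adversary; inverse-group-frequency reward
  shaping). Other published variants (feature-level adversaries, value-based
  agents, alternative shaping) are out of scope.
- Probability calibration is not performed; only the operating threshold is
  selected downstream.
- The generator's independence of features given class and site is a
  simplification; fairness conclusions transfer to real cohorts only
  directionally.
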