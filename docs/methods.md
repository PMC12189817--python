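# Methods

This note records the modeling choices, defaults and their rationale, what
the synthetic data does and does not emulate, and the numerical details a
maintainer would want.

## Data model and preprocessing

A cohort is a set of patients, each an ordered T × N_r visit matrix with
an observed mask; `visit_index` is an integer rank, not a timestamp — the
model consumes ordered visits only and no inter-visit interval feature is
used.  Preprocessing is strictly causal:

1. **Forward fill** carries each feature's most recent observed value to
   later unobserved visits.  There is no backward fill: entries before a
   feature's first observation stay undefined, because filling them would
   leak future measurements into the past.
2. **Standardization** z-scores each feature with mean and *population*
   (divide-by-n) standard deviation computed over the defined (observed or
   forward-filled) entries of training-split patients only.  Statistics
   are computed *after* forward filling, so they describe the values the
   model will actually see.  Features constant on the train split get
   sd := 1, which maps them to 0, consistent with the imputation rule.
3. **All-missing imputation** sets entries still undefined to the
   standardized train mean, i.e. 0.  "Dataset-level averages" are
   interpreted as train-split means to preserve test integrity.

The long-format interchange CSV cannot represent a trailing visit with no
observed feature (T is inferred from the largest visit index); the
generator therefore guarantees at least one observed feature per visit,
which also matches clinical reality — a recorded visit implies at least
one recorded measurement.

Padding in mini-batches is 0 after imputation, but correctness never
relies on the padding value: lengths select the final embedding and mask
every loss.

## Synthetic cohort generator

The generator's defaults define the reference study conditions: 2000
patients, 20 features (12 informative), latent dimension 3, 4–10 visits,
AR(1) coefficient 0.8, emission noise sd 0.5, 30% missingness, 13%
prevalence.  Mechanism:

* a latent severity indicator c ~ Bernoulli(prevalence) adds a constant
  per-visit drift (scale 0.5) along the risk direction to the patient's
  latent AR(1) state z_t = 0.8·z_{t−1} + drift·1[c] + ε_t;
* informative features are noisy linear emissions of z_t through
  unit-norm loadings with cosine 0.6 to the risk direction (alternating
  sign), so each informative feature carries a genuine marginal
  association with the outcome; remaining features are pure N(0,1) noise,
  exercising the filtering gate;
* the label is drawn from a logistic link on the terminal latent state
  (link scale 2), with the intercept calibrated by bisection (50
  iterations on [−30, 30]) so the mean risk matches the target
  prevalence within ±0.03 empirically;
* missingness is Bernoulli at `missing_rate`, optionally increased for
  high-risk visit states (`mnar_strength`); splits are 70/10/20,
  stratified by label.

Because latent dynamics and emissions are linear-Gaussian, a closed-form
one-step predictor exists (`one_step_oracle_mse`) and the auxiliary
next-visit task is learnable by construction; the retained true risk is
the Bayes-optimal score and upper-bounds any model's expected ranking
performance.

What the generator does **not** emulate: timestamped irregular intervals,
categorical codes and their hierarchies, feature-specific measurement
processes, nonstationary policies, and label noise correlated with
missingness beyond the single MNAR knob.  Passing tests therefore show
the pipeline behaves correctly under the stated statistical assumptions,
not that the model reaches any particular performance on real clinical
data.

## Network and objective

* Recurrent cells are standard GRUs (reset/update/candidate gates, hidden
  state initialized to zero), one for each branch with disjoint
  parameters.  Weights initialize uniform(−1/√N_h, 1/√N_h) from
  `init_seed`; biases start at zero.
* Prediction uses the **final** visit's embeddings and the final record
  for the gate: the outcome is sequence-level, and the gate is defined on
  the patient's latest record.
* The next-visit head and the target head are single affine layers (the
  target head adds a logistic squashing so ŷ ∈ (0,1); binary
  cross-entropy needs a probability).  W_f, W_t and W_gate carry no bias
  (pure matrix products); the heads do.
* The decorrelation penalty is computed per batch on the final-visit
  projection vectors — the batch index runs over patients, not visits —
  separately for g_future and g_task and summed.  A
  `joint_decorrelation` switch penalizes the concatenation instead.  For
  `context_minus` the penalty applies to g_task alone.  Covariance uses
  divisor B exactly.
* The future loss averages squared error over features, sums over the
  T−1 supervised steps and divides by T (not T−1); single-visit patients
  are excluded from it.

Default dimensions N_h = N_g = 64 and α = 0.1 are pragmatic choices —
large enough to learn the reference cohorts, small enough to train in
seconds on a CPU; both are config-exposed, and the α = {0, 0.1, 1} sweep
in the test suite confirms the expected regularization path (final
decorrelation term non-increasing in α).

## Training protocol

Two-stage by default: the future branch pretrains on L_future alone
(checkpoint selected on validation L_future, which is the natural
stage-1 criterion since no target labels are involved), then freezes
while the task encoder, projections, gate and head train on
L_task + α·L_decorrelation with checkpoint selection and early stopping
(patience 10) on validation AUPRC.  Freezing follows the two-stage
pretrain-then-consume reading of the design; `stage="joint"` adds
L_future with unit weight and trains everything at once for comparison.

Optimizer: Adam with decoupled weight decay (0.01) and global-norm
gradient clipping at 5.0 — both conventional guards for small recurrent
nets, config-exposed.  Learning rate 0.001 with linear warmup over the
first 5 epochs then half-cosine decay to 0 at `max_epochs`; the schedule
is evaluated per epoch at index epoch+1, so the first epoch trains at
lr/warmup rather than 0.  Batch size 256; per-epoch reshuffling derives
deterministically from the config seed, so identical configs give
byte-identical logs.  ŷ is clamped to [1e−7, 1−1e−7] inside the
cross-entropy, with a logged warning when clamping fires.

Everything runs on an in-package reverse-mode autodiff engine over
float64 numpy arrays (tape of closures, unbroadcast-aware); gradients are
verified against central finite differences in the test suite to ~1e−6
relative error.

## Evaluation

AUPRC uses the average-precision estimator; AUROC the normalized
Mann–Whitney statistic (ties half-credit); min(+P, Se) is the maximum
over unique-score thresholds of the pointwise minimum of precision and
sensitivity — the standard operationalization in the EHR benchmark
lineage, since the pointwise quantity alone has no canonical threshold.
All three are cross-checked against exhaustive threshold-enumeration
oracles on small instances.  Bootstrap CIs resample patients with
replacement (default 1000 replicates); single-class resamples are
redrawn.  The gate diagnostic reduces each patient's gate_future vector
to its mean — a uniform gate gives (N_g+1)/(2N_g) ≈ 0.508 — and reports
group means by outcome; on reference cohorts the adverse-outcome group
shows the higher mean, i.e. the model leans more on future-predictive
features for high-risk patients.  This is reported as a diagnostic
direction, not asserted as a fixed magnitude.

## Problem sizes in tests and the acceptance script

The test suite trains on cohorts of 200–2000 patients with 16–64 hidden
units and ≤ 40 epochs, and the ablation-direction check uses five
1500-patient cohorts; these sizes give stable directions while keeping
the whole suite to a few minutes on one CPU.  The acceptance script uses
the reference 2000-patient conditions with `max_epochs=40` and 200
bootstrap replicates.  Stochastic checks (learnability margins, ablation
ordering) are run under fixed seeds; the ordering full ≥ context− holds
in the 5-seed mean, while single seeds can invert it — expected sampling
noise at these cohort sizes.

## Known limitations

* No timestamp handling: visit rank is the only temporal structure.
* The interchange format cannot express a fully-unobserved trailing
  visit.
* The autodiff engine implements exactly the operations the model needs;
  it is not a general-purpose framework, and training is CPU-only.
* `min(+P, Se)` scans unique scores only; with heavy score ties the
  attainable operating points are coarse.
* Bootstrap CIs treat patients as exchangeable; clustered admissions are
  out of scope.
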