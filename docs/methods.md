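# Methods

This note documents the models implemented in difekit, the assumptions and
numerical choices behind them, what the synthetic cohorts do and do not
emulate, and the design decisions taken where the problem was genuinely
open. Everything quantitative stated here is computed by the test suite or
the pipeline itself.

## The scoring equation

The score of a patient at haemodialysis initiation is

    Y = p15 + p1·W·( p2·Scr^p3·(ln age)^p4·Alb^p5·Hb^p6·(ln BUN)^p7·P^p8
                     + p9·e^HF + p10·e^DM + p11·e^female + p16 )
    W = 1 / (1 + exp(t1 + t2·Scr + t3·Alb + t4·Hb + t5·ln BUN + t6·P))

a Takagi–Sugeno-type construction: a sigmoid gate `W ∈ (0,1)` over the six
numerical indicators multiplies a consequent that combines a log-power
product of the same indicators with additive exponential terms for the
binary covariates. All logarithms are natural. Units are fixed: Scr and BUN
in mg/dL, Alb and Hb in g/dL, phosphate in mmol/L; `difekit.cohort.convert_units`
handles SI conversions (×88.4 creatinine, ×0.357 BUN, ×10 for g/dL → g/L —
note the g/dL→g/L factor is a multiplication by 10; a division would be
dimensionally inverted). The 13 consequent parameters are indexed
p1–p11, p15, p16 (p12–p14 do not occur in the closed form) plus six gate
parameters t1–t6; parameter JSON files must contain exactly these 19 keys.

Interpretation conventions, fixed by the worked examples: lower Y = more
urgent initiation; `score < threshold` ⇒ *start now* / predicted poor
(<36-month) survival; the boundary `score == threshold` belongs to the
good side. The threshold is conventionally 30 with candidate grid
{29, 30, 31, 32, 33}.

The published fitted parameter values live in a supplementary appendix that
is not distributed with the toolkit; `difekit.dife.example_parameters()`
is therefore an explicitly **synthetic** demonstration set, chosen only so
that typical at-initiation covariates produce scores near the conventional
threshold with a clinically sensible orientation (higher albumin and
haemoglobin raise Y; heart failure and diabetes lower it). It is used for
demos and as the generating truth in simulation studies, and must not be
used clinically.

## eGFR comparators

- Chinese-modified MDRD equation 7:
  `170·Scr^-0.999·age^-0.176·BUN^-0.170·Alb^0.318`, ×0.762 if female,
  ×1.202 if of Chinese descent. The ethnicity factor defaults **on** (the
  target population); it is a flag.
- CKD-EPI 2009 creatinine equation: `141·min(Scr/κ,1)^α·max(Scr/κ,1)^-1.209·
  0.993^age` with sex-specific κ/α, ×1.018 female. The optional 1.159 race
  coefficient defaults **off**; this is a documented package choice, not a
  claim about how any particular study computed it.

Both calculators return raw floats; display rounding (nearest integer) is
the caller's concern, keeping computation and presentation separate. Both
are strictly decreasing in creatinine and in age at fixed labs.

## Synthetic cohorts

`generate_cohort` emulates the marginal structure of an incident
haemodialysis population: continuous covariates are truncated normals at
physiologic bounds (e.g. Scr ∈ [1, 30] mg/dL, Alb ∈ [1, 6] g/dL) coupled by
a Gaussian copula, and binary signs/symptoms are Bernoulli draws. Defaults:
age 54.0 ± 13.8 y, Hb 8.5 ± 2.1 g/dL, Alb 3.5 ± 0.7 g/dL, BUN 85.7 ± 5.7
mg/dL, Scr 10.1 ± 4.5 mg/dL, P 2.0 ± 0.7 mmol/L, K 4.8 ± 0.9 mmol/L;
female 40.1%, heart failure 29.1%, vomiting 26.5%, oedema ≥II° 45.0%,
uraemic encephalopathy 2.6%, diabetes 22.4%; 36-month baseline death
probability 12.2%. The truncated-normal location is calibrated (Brent root
find) so the *truncated* mean equals the configured target. The only
default copula correlation is Scr–BUN = 0.5 (both track azotaemia); no
published covariance structure exists for the other pairs, so they default
to independence. BMI is not generated: its reported moments are not usable
as a normal distribution and it is not a model covariate.

The ground-truth risk process is logistic:
`P(death ≤ 36 m) = expit(logit(0.122) + β'z)` with `z` standardised
covariates. The default β (age 0.50, Scr 0.15, BUN 0.05, Alb −0.40,
Hb −0.35, P 0.20, female −0.10, HF 0.50, DM 0.35 per SD / per presence) is
deliberately **multi-covariate** — nutrition, anaemia and comorbidity carry
risk that creatinine alone does not — which is exactly the regime in which
a multi-covariate score should out-discriminate an eGFR-only assessment.
Conditional on death, event times are uniform on (0, 36] months (no
published hazard shape); survivors are censored at 36.

What the generator does **not** emulate: longitudinal lab trajectories,
informative censoring, centre effects, missingness mechanisms (patients
with missing albumin/phosphate are excluded, not imputed), and any real
joint distribution beyond the single configured copula correlation. Tests
passing on these cohorts therefore demonstrate correctness and internal
operating characteristics of the machinery, not clinical performance on
real patients.

`difekit.simulation.simulate_equation_cohort` layers a second, fully known
outcome process on top: the good-survival indicator is Bernoulli with
probability `expit((Y_true − c)/s)` where `Y_true` comes from a known
parameter set. The default link scale `s = 5` score units (~0.8 of the
score SD under the default covariates) puts the true-score AUC in the
low-to-mid 0.7s, the discrimination regime typical of incident-dialysis
risk scores. This is the testbed for parameter recovery.

## Variable selection (KLNN-RBM)

The selection outcome is three-class survival after initiation: <12 months,
12 to <36 months, >36 months. Boundary conventions: exactly 12 months →
middle class; a death recorded at exactly 36 months → middle class;
censored alive at 36 → long survivor.

The classifier is an explicit small network:

1. **Kernel feature map.** RBF features against up to 50 training
   landmarks with a median-heuristic bandwidth (median pairwise distance of
   the z-scored covariates), or the identity map for a linear kernel. The
   explicit map keeps the model O(n·landmarks) and lets the same hidden
   layer apply to any kernel.
2. **Hidden layer pretraining.** The kernel features are z-scored and a
   Gaussian-visible / Bernoulli-hidden RBM is trained on them by one-step
   contrastive divergence (CD-1, mean-field Gaussian reconstruction);
   pretraining on the *feature* matrix is what makes the RBM weight shape
   (n_features × hidden) consistent with the layer it initialises.
   Gaussian visibles are the standard RBM variant for continuous inputs.
3. **Supervised head.** A sigmoid hidden layer (RBM-initialised) and a
   softmax output, trained end-to-end by minibatch SGD on the multinomial
   log-likelihood. Defaults: 10 hidden units, 100 CD epochs, 100 SGD
   epochs, base learning rate 0.01 with harmonic decay `lr/(1 + epoch/10)`
   (a plain `lr/epoch` schedule freezes the network long before 100 epochs;
   the tempered decay reaches high training accuracy on separable data
   while remaining a decaying schedule), batch size 32. All of these are
   configuration, not doctrine — none is externally prescribed.

`cv_accuracy` runs `n_simulations` (default 20) independent repetitions of
stratified 10-fold cross-validation; each simulation reshuffles the folds
*and* reinitialises the network, and a simulation's accuracy is the
fraction of records classified correctly in their unique test fold. The
subset search keeps the five MDRD-equation variables (age, sex, Scr, BUN,
Alb) in every subset and enumerates the 2^8 combinations of the eight
further clinical factors by default; a full exhaustive search (≥2
variables) and greedy forward selection are available. Ties rank the
smaller subset first, then lexicographic order.

A caution that the harness itself makes visible: maximising CV accuracy
over 256 subsets is a selection procedure, and the winner's accuracy is
optimistically biased under the null. The ranking should be read as a
screening device, not as an unbiased accuracy estimate.

## Equation fitting (PSO)

The printed closed form is fitted directly — no attempt is made to
reconstruct an unspecified multi-rule fuzzy architecture behind it. A
particle is the 19 equation parameters plus two link parameters (c, log s);
the swarm minimises the cross-entropy between `expit((Y − c)/s)` and the
binary 36-month outcome (1 = survived ≥ 36 months; a death at exactly 36
months counts as poor survival). A squared-error loss is available via
`loss="mse"`.

PSO defaults: swarm 60, inertia 0.72, cognitive = social = 1.49, 500
iterations, velocity clamped to 20% of each parameter's range, positions
clipped to bounds. Bounds: [−50, 50] for coefficients and gates, [−5, 5]
for the six exponents (keeps the power product finite), c ∈ [−200, 200],
log s ∈ [−3, 5]. Three initialisation devices matter in practice:

- random particles start in a tight sub-box (|θ| ≤ 3): most of the full
  box saturates the power terms and gives the swarm nothing to follow;
- one particle sits at the constant-score baseline (Y ≡ 0, link matched to
  the outcome base rate), which guarantees the fitted training loss never
  exceeds the intercept-only loss;
- one particle is warm-started from a logistic regression on the
  log-transformed numerical indicators. The product term is exp-linear in
  (ln Scr, ln ln age, ln Alb, ln Hb, ln ln BUN, ln P), so with exponents
  ε·β and weight 1/ε it linearises to const + β'u: a maximum-likelihood
  logistic solution maps onto a nearby point of the equation's parameter
  space (ε = 0.5), and its link is calibrated by a one-dimensional
  logistic fit of the outcome on the warm score. Without this particle the
  swarm reliably finds *a* local optimum but often misses weak covariate
  signal; with it, fitted discrimination tracks the oracle.

Ten-fold cross-validation acts as early stopping: one PSO run per training
fold tracks the held-out loss of the running global best per iteration, the
iteration budget minimising the mean held-out loss is selected, and the
final swarm refits on all data with that budget (`cv_early_stop=False`
skips this and uses the full budget — the configuration used in the fixed-
budget simulation studies).

**Score anchoring.** The link leaves the score scale unidentified: any
affine map of Y is absorbed exactly by p15 → a·p15 + b, p1 → a·p1. Fitted
scores are therefore reported on the conventional scale where the link
midpoint is 30 and one link unit is 5 score points, which makes the
candidate-threshold grid 29–33 meaningful for a fresh fit. `anchor=None`
disables this.

Outlier removal before fitting drops records with any continuous covariate
beyond |z| > 4 (or an IQR rule), logging the removed ids; threshold
selection then maximises diagnostic accuracy over the candidate grid
subject to sensitivity ≥ 0.40 (ties → smaller threshold). The floor
reflects the judgement that a screening threshold missing most poor
survivors is clinically useless even when it is the most accurate; it is
configurable, and if no candidate meets it the unconstrained maximiser is
returned flagged.

## Evaluation

- **AUC** uses the rank (Mann–Whitney) formulation with half-credit ties.
  Orientation is explicit: higher score = higher predicted event risk, and
  nothing is auto-flipped; eGFR-based comparators enter as −eGFR.
- **Bootstrap.** CIs are stratified case-resampling percentile intervals
  (cases and controls resampled separately, so every replicate retains both
  classes — the redraw-on-degenerate-resample rule is thereby vacuous by
  construction); the AUC-difference test resamples patients once per
  replicate (paired across models, stratified by outcome) and reads a
  two-sided p-value off the bootstrap distribution of ΔAUC against zero,
  with add-one smoothing (p ≥ 2/(B+1)). Default 2000 replicates, fully
  seeded and bit-reproducible.
- **Survival.** Kaplan–Meier estimation and the two-group log-rank test
  are delegated to lifelines; mortality is reported as deaths per 100
  patient-years with follow-up capped at 36 months. A no-event comparison
  returns χ² = 0 with a flag instead of raising.
- **Logistic comparator.** Maximum-likelihood logistic regression
  (statsmodels) of 36-month poor survival on the nine score covariates.
  Exponentiated coefficients are reported as **odds ratios** with Wald 95%
  CIs — a logistic model has no hazard ratios, whatever a results table may
  call them. Calibration is the Hosmer–Lemeshow statistic over 10 risk
  deciles (df = groups − 2, empty/degenerate deciles merged by the
  quantile cut). Constant covariates are dropped with a flag; suspected
  separation (extreme coefficients or standard errors) is flagged, not
  raised.

## Pipeline and reproducibility

`run_develop` executes (optional) variable selection → outlier removal →
PSO fit → threshold selection and writes `params.json`,
`threshold_report.csv` and a manifest recording the seed, a SHA-256 hash of
the effective configuration, the package version, record counts and
per-stage timings. `run_validate` scores the validation cohort at the
working threshold and writes `metrics.json` (confusion metrics, four AUCs
with CIs, three paired comparisons, per-group mortality, log-rank),
`roc_comparison.csv` and `km_groups.csv`. Identical configuration and seed
reproduce artifacts byte-for-byte. Variable selection is off by default in
the pipeline: it is the expensive stage, and the default workflow fits the
fixed nine-variable equation.

Problem sizes in the shipped studies are chosen at desk scale: parameter
recovery uses 1500-patient development / 500-patient validation cohorts
with a fixed 200-iteration swarm budget over 10 replicates; bootstrap
coverage uses 200 replicates of n = 500 binormal scores (true AUC 0.75)
with 2000 resamples each; the discrimination comparison uses ten
1281 + 504 replicates. The default full pipeline (1281 + 504, CV early
stopping, 2000 bootstraps) completes in well under a minute on one CPU.

## Known limitations

- The outcome model for fitting is a calibrated logistic link on a single
  score; no time-to-event likelihood, competing risks or time-dependent
  ROC.
- PSO is stochastic and the loss surface is multimodal; different seeds can
  land on different parameter vectors with similar discrimination. Only
  the score's ordering (and its anchored scale) is reproducible in a
  meaningful sense, not individual parameter values.
- The KLNN-RBM's "modified maximum-likelihood" training is realised as
  standard multinomial likelihood with SGD; the modification point is the
  `_SoftmaxNet` class, deliberately small and replaceable.
- Synthetic validation shows machinery correctness, not clinical validity;
  real-cohort statistics are out of reach without patient data.
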