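# Methods

## The model

A tumor's targeted-therapy response is assumed to be governed by a latent
binary **pathway activation** A. Activation can be caused by a *functional*
(pathogenic) driver-gene mutation or by pathway amplification; a functional
lesion activates the pathway with probability `penetrance`. Passenger
(non-pathogenic) mutations never activate. Activation shifts the expression
of a block of pathway "signal" genes and increases sensitivity to drugs that
target the pathway. A **phenocopy** is a sample with A = 1 but no driver
mutation — in this model, always CNV-routed.

The phenocopy signature is a gradient-boosted tree classifier of *mutation
status* from pathway-restricted expression. It is deliberately not trained
on drug response: association with response arises only through the
signature's ability to recognize the activated expression state, which is
the scientific claim the pipeline is built to test.

## Pipeline stages and key choices

**Mutation annotation.** Protein-altering classes retained: missense,
nonsense, nonstop, frameshift, in-frame indels, start-lost. Excluded:
silent, splicing, intronic, upstream, downstream, UTRs; unknown classes are
excluded with a warning rather than an error. Pathogenicity is an OR over
evidence: SIFT {D, deleterious}; PolyPhen-2 HDIV/HVAR {D, P,
probably_damaging, possibly_damaging}; FATHMM {D, deleterious}; ClinVar
{pathogenic, likely_pathogenic}. Matching is case-insensitive and
space/underscore tolerant; missing fields carry no evidence. Both PolyPhen
categories (probably and possibly damaging) are accepted by default; the
vocabulary tables are arguments and can be overridden. CNV is never used for
labels — copy-number thresholds are not comparable across datasets — and
enters only the cohort-comparison stage.

**Normalization.** Default dialect is the per-sample fractional rank over
the shared gene universe (average ranks for ties, scaled to (0, 1]). It is
idempotent and invariant to any strictly monotone per-sample transform,
which is what allows one locked signature to score RNA-seq, array and
cell-line profiles on a common scale. Constant samples map to a uniform
profile with a warning. A per-gene z-score dialect and a pass-through are
selectable; the dialect used at training is recorded inside the signature
and enforced at prediction, so a result always declares how its inputs were
scaled.

**Training filter.** Cancer types with `any_mutation` rate strictly below 5%
are dropped from training; a type at exactly 5% is retained. The rate uses
all protein-altering mutations, not only pathogenic ones, matching the
training-label definition.

**Signature training.** Objective `binary:hinge`, learning rate 0.3 (the
backend default), CPU histogram tree construction, single-threaded for
determinism. The grid is depth {2, 3, 4, 6} x trees {50, 100, 200, 400} by
default and fully configurable; the tests and the acceptance script use the
{2, 3} x {50, 100} corner, which is where the tuner lands on the synthetic
cohorts anyway. Folds are stratified (keeps folds valid at low alteration
rates) with a fixed seed. Model selection uses ROC AUC on **pooled**
out-of-fold margins (pooling is recorded in the signature metadata); ties
prefer fewer trees, then shallower trees. Per fold, one ensemble is trained
to the largest tree count and scored at smaller counts via its leading
trees, which is exact for boosting. The final model is refit on all training
data and locked: any attribute assignment raises, and serialization
(native JSON model dump + metadata sidecar) is byte-stable, so a file hash
taken before validation certifies the signature afterwards. At prediction,
calls are hinge margins thresholded at 0; missing feature genes are imputed
at mid-rank 0.5 (neutral under the rank dialect) up to a 50% missingness
ceiling, beyond which prediction refuses.

**Nested models.** Responses are first oriented so lower = more sensitive
(ActArea negated; IC50 z-scores and AUC unchanged; an `oriented` flag makes
the operation idempotent). Complete cases only, with a default minimum of
20; no imputation. The LR statistic is the Gaussian-ML deviance
n·ln(RSS0/RSS1) with df = rank difference (1), referred to the chi-square
upper tail — the standard LR for nested OLS. An exactly collinear or
constant phenocopy column makes the test undefined; such results are flagged
degenerate and excluded from the FDR family rather than given a p-value of
1. The BH family defaults to all drug/pathway/dataset tests pooled in a run
(per-dataset family by flag). In the three-predictor variant the pathogenic
indicator must imply the mutation indicator, the reduced model is
intercept + mutation + pathogenic, and a cohort with no pathogenic mutations
drops the column and flags the result.

**Biomarker metrics.** Responders are the most-sensitive quartile of each
drug's oriented values over *all* assayed lines (stratification never moves
the cutoff): cutoff = the ceil(n/4)-th smallest value, with boundary ties
included. Metrics with zero denominators are reported as missing, never as
zero. The three phenocopy strata (mutation-negative, pathogenic,
non-pathogenic) partition the cohort by construction.

**Cohort comparisons.** Rate shifts use the two-proportion Pearson
chi-square without continuity correction (a pooled rate of exactly 0 or 1
returns statistic 0, p 1); small clinical 2x2 tables use Fisher's exact
test. Arms are treated as unpaired aggregates. A sample "has pathway CNV"
if any pathway gene (driver or feature) is non-neutral; amplification-only
mode by flag.

## The synthetic generator

Draw order per cohort is fixed (mutation, pathogenicity, amplification,
penetrance, expression noise, passengers, annotation flips, drug noise), so
a config hashes to a bit-identical bundle. Defaults: 4 cancer types x 250
samples with alteration rates (0.10, 0.20, 0.30, 0.04) — one type sits below
the 5% filter so the filter is always exercised; pathogenic_fraction 0.7;
cnv_rate 0.10; penetrance 0.9; 100 pathway genes of which 30 carry a
signal shift of 1.0 z-unit against expression noise sd 1.0; 10 drugs, half
on-target with effect 1.0 response-unit against noise sd 1.0;
annotation_error_rate 0.05; passenger mutations at Poisson rate 0.5 per
sample spanning both retained and excluded variant classes. Effect sizes
are calibration choices of this package (no external values exist for
them): unit effects against unit noise make single-gene evidence weak but
pathway-aggregate evidence strong, which is the regime the method is
designed for. Annotation strings use the tools' own categorical
vocabularies; a record's consensus is flipped with `annotation_error_rate`,
and pathogenic records always carry at least one damaging call so the
zero-error regime reproduces truth exactly. Paired cohorts draw two
independent arms and eliminate each activated post-arm tumor with
probability `treatment_selection_strength`, giving a post-arm activation
rate of (1−s)p/(1−sp). A continuous-activation variant (activation level
uniform on [0.5, 1], scaling both expression and response effects) is
available behind a config flag and off by default.

What the generator does **not** emulate: gene–gene covariance, batch
effects, tumor purity, subclonality, dose–response curve shape, and
non-CNV phenocopy mechanisms. Passing tests therefore certify the
statistical machinery and the causal logic, not performance on real tumors.

## Measurement regimes

The tests and `scripts/acceptance.py` measure each property in a regime
chosen once for identifiability:

* **Recovery regime** (signature training checks): pathogenic_fraction = 1,
  penetrance = 1, cnv_rate = 0, annotation_error_rate = 0, four types x 500
  samples. Mutation labels then coincide with the latent activation, so
  cross-validated AUC (≥ 0.99 observed) and held-out balanced accuracy
  (≈ 0.97) measure classifier recovery, not label noise. Permuted-label
  controls concentrate at AUC 0.5.
* **Null regime** (type-I error): activation ≡ mutation drives all 1000
  drugs; the phenocopy vector is mutation with independent 30% flips, hence
  conditionally uninformative. Empirical rejection at p < 0.05 and a KS
  uniformity check calibrate the LR p-values at n = 300.
* **Mechanism regime** (power): one type x 500 lines, alteration rate 0.2,
  cnv_rate 0.15, penetrance 0.9, drug_effect 1, noise 1, 200 on-target and
  200 off-target drugs, signature from the recovery regime. On-target
  rejection at q < 0.05 and the off-target share of rejections measure power
  and FDR control of the full pipeline.
* **Strong-signal regime** (condition-1 specificity/NPV): drug_effect 3 with
  activation rate 0.22, so activated lines nearly fill the responder
  quartile. Note an intrinsic ceiling: with a *global* top-quartile
  responder definition, if the activation rate is p < 0.25 then about
  (0.25 − p)/(1 − p) of mutation-negative lines respond by chance alone, and
  no classifier can push condition-1 NPV above 1 minus that; the regime's
  activation rate is chosen so the bound sits above 0.9.
* **Clinical regime** (pre/post direction): one type x 100 patients per arm,
  activation rate 0.3, selection strength 0.5 vs 0, 200 replicate seeds,
  latent activation as the phenocopy truth.

Problem sizes throughout are the package's own defaults for a desk-scale
run; all scale linearly via the config.

## Known limitations

Headline numbers at real-data scale (fractions of actual drugs improved,
per-pathway percentages, clinical response rates) require the
TCGA/GDSC/CCLE/DepMap/GEO datasets and are out of scope; this package
reproduces the *method* and verifies it against planted ground truth. The normalization used by the original
cross-platform analysis is not fully specified anywhere public; fractional
rank is this package's explicit, recorded choice. The LR chi-square is
asymptotic; at n below ~50 its p-values run slightly liberal relative to the
exact F test (an F-test variant of the comparison is a natural extension).
Degenerate-case policy (collinear predictors, empty strata, one-armed
comparisons) is to flag and exclude rather than fabricate a value.
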