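# Methods

This note records the statistical procedures `pedigrs` implements, the
design of the synthetic-data generator, the numerical conventions, and the
choices made where the underlying study designs leave the method open.

## Genotype quality control

QC is per-SNP only: a SNP is dropped when its call rate (fraction of
non-missing calls) is below `callrate_min` (default 0.95) or when the
exact Hardy–Weinberg test rejects at `hwe_alpha` (default 10⁻³, recorded
in every QC report header).  Call rate is checked first, so a SNP failing
both criteria is reported under the call-rate reason.  Per-individual call
rates are never used to drop anyone.

The HWE test is the exact conditional test, not the asymptotic chi-square:
conditional on the observed allele totals, every attainable heterozygote
count has a known probability, and the p-value sums the probabilities of
all configurations no more probable than the observed one.  "No more
probable" is decided with a 10⁻¹² relative tolerance so floating-point ties
behave like exact ties.  The exact form matters because QC targets exactly
the small genotype classes where the chi-square approximation is worst;
for large balanced samples the two agree (tested).  A monomorphic SNP has
a single attainable configuration and p = 1.

Dosage coding counts risk alleles per call (0/1/2); the risk/other
orientation comes solely from the weights file.  No strand flipping or
A/T–C/G ambiguity resolution is attempted — an allele outside the declared
pair is a hard error naming the SNP and individual, because silent strand
fixes are the classic way scores get corrupted.  Missing calls remaining
after QC are imputed as 2·p̂ with p̂ the SNP's observed risk-allele
frequency (the HWE expectation), which preserves each column mean exactly;
whether the original analyses imputed or dropped such individuals is not
documented, and imputation keeps every genotyped child scoreable.

## The score

The score is the raw weighted sum of dosages — it is deliberately *not*
divided by the number of SNPs or the weight total, so its scale matches
GWAS-weight conventions (a 44-SNP panel at these weights yields means
around 0.5–1.2 in BMI Z·allele units).  Quantile strata use sample
quantiles with linear interpolation of order statistics; values tied with
a cut point go to the lower stratum.  Normality is summarised by the
Lilliefors statistic (KS distance after estimating mean and SD); because
its null distribution depends on n, the p-value is Monte-Carlo (default
2000 seeded standard-normal replicates of the same n, configurable).

## Association models

Linear models are OLS with covariates dummy-encoded against a first-level
reference; the exposure's contribution is the partial R² (R² of the full
model minus R² without the exposure).  CIs are t-based.  Logistic models
are MLE logit with Wald CIs on the link scale, exponentiated for ORs.
Both the deviance ratio D² = 1 − dev_full/dev_null and the Nagelkerke
pseudo-R² are reported for logistic fits: reports in this literature label
a logistic variance-explained quantity "h²" without defining it, so both
candidates are emitted and the ambiguity is explicit in the API.  The OR
per 0.1 score unit is exp(0.1·β) — note that dividing a per-unit OR by 10,
as narrative summaries sometimes do, is not a valid rescaling; only the
exponent scales.

Perfect or quasi-separation (|coef| > 30 or non-convergence) raises a
dedicated error for inference, but the prediction path tolerates it:
a separated training fit still ranks subjects correctly, so AUC evaluation
fits with BFGS and ignores the divergence.

Stepwise selection is greedy bidirectional AIC minimisation with
covariates always retained and ties broken by input order, making it
deterministic.  Under the null, AIC's penalty of 2 admits each candidate
with probability P(χ²₁ > 2) ≈ 0.157 — sparse, but not empty for large
candidate sets; the tests assert exactly this calibration.

Benjamini–Hochberg adjustment (step-up, q_i = min_{j≥i} p_j·m/j, capped at
1) is applied once per analysis family — one scan, one table — never
pooled across modules and never split into subfamilies.

## Prediction

Cohorts entering AUC evaluation must already exclude the overweight class:
the case/control framing is normal weight vs obesity, and the module
refuses the middle class rather than silently binning it.  Splits are
75/25, stratified by outcome (plain random assignment destabilises small
test sets; the stratification is recorded).  Complete cases are taken per
factor set, mirroring designs where each questionnaire block has its own
missingness; the combined model (union of covariates from all sets with
AUC ≥ 0.60) is fitted on the complete-case intersection with a fresh
seeded split.  AUC uses the Mann–Whitney rank formulation with half-credit
ties; the CI is DeLong's, from placement-value variances (degenerate at
separation, where the variance estimate is zero).

## Gene×environment scan

Each lifestyle factor E enters one moderated regression
`BMI Z = β₀ + β₁·pGRS + β₂·E + β₃·(pGRS×E) + β₄·Origin + β₅·Tanner + ε`,
fitted literally (no centering by default; a `center` flag exists for
ill-conditioned factors and leaves β₃ and its SE unchanged — verified to
10⁻⁸).  Only quantitative or ordinal factors are admitted, ordinal ones as
numeric codes, i.e. modelled linearly.  β₃ is tested by the marginal
two-sided t-test, asymptotically the 1-df likelihood-ratio test (the
agreement at n = 5000 is itself a test).  FDR covers the whole scan as one
family; per-factor complete cases, with n recorded per row.  The
plot-support stratification cuts the score at mean ± 1 SD and reports the
outcome-vs-factor slope per band.

## Longitudinal trajectories

Insulin resistance is HOMA-IR against inclusive cut-offs: ≥ 2.5 at Tanner
I; ≥ 3.38 (boys) / ≥ 3.90 (girls) at Tanner II–V.  Weight status uses an
age- and sex-specific BMI cut-off table supplied as configuration (the
bundled `make_weight_status_table` is a smooth synthetic stand-in for a
national reference, for simulation and testing only); the obesity boundary
is inclusive (BMI at the cut-off classifies as obesity) and this
convention is explicit in the classifier.

Scheme 1 maps the (weight, IR) pair at both timepoints onto five groups,
pooling overweight with obesity as the group definitions do: stable
normal-weight non-IR (reference), stable OW/OB non-IR, OW/OB with IR
resolving, OW/OB developing IR, and OW/OB persistently IR.  The five
groups do not cover every conceivable transition (a normal-weight child
presenting IR, weight-class crossings); uncovered combinations raise an
explicit unclassifiable error rather than being silently binned — how such
children were handled in the source designs is not documented, and the
mapping table is exported so the choice is auditable.  Scheme 2 labels
weight-only transitions and keeps overweight distinct; all nine
transitions are defined.  Trajectory odds ratios dichotomise the score at
the top tertile (chosen over quartiles for small cohorts) and fit one
logistic model per comparison group against the reference, BH-adjusted
across groups.

Delta direction conventions differ by analysis and are therefore carried
in the output metadata: longitudinal cardio-metabolic deltas are T1 − T0,
while the RCT response is T0 − T1 (positive = BMI Z reduction).

## RCT interaction

Two parameterisations of the same estimand: (1) OLS of the per-child BMI Z
reduction on score, arm, score×arm; (2) a random-intercept linear mixed
model (REML) on the long data with fixed effects score, time, arm, all
two-way products, the three-way score×time×arm product and optional
covariates, Wald z-test on the three-way term.  With balanced complete
two-timepoint data the three-way fixed effect equals minus the
change-score interaction exactly (the sign flips because the delta is
T0 − T1 while the mixed model measures growth toward T1); this algebraic
identity, verified to 10⁻⁶, is the module's central correctness check.
Time-invariant covariates enter the mixed model as level effects only and
cannot move the time-interacted terms.  The mixed-model solver is
statsmodels' MixedLM; the contract fixed here is the model structure, the
tested term and the balanced-data equivalence, not the optimizer.

## Synthetic-data generator

The generator's defaults encode the study conditions the package targets.

**Panel** (56 SNPs): risk-allele frequencies uniform on (0.10, 0.50);
per-allele weights half-normal with scale 0.03 BMI Z/allele — the adult-BMI
GWAS weight scale, giving a 44-SNP score an SD near 0.13.  Risk alleles
are BMI-increasing by construction, so weights are positive, as in
published scoring files.

**Genotypes** (600 children): independent SNPs drawn from exact HWE
proportions (p², 2pq, q²) — no linkage disequilibrium, matching the
additive-independent treatment of the score.  Eight designated SNPs
receive exactly ⌈0.12·n⌉ missing calls (call rate 0.88 < 0.95); four are
drawn with an inbreeding-coefficient distortion (genotype probabilities
p²+Fpq, 2pq(1−F), q²+Fpq) whose magnitude is solved from the classical
approximation that the HWE chi-square statistic is n·F̂² with
F̂ ≈ N(F, 1/n), inflated 30% for the exact test's conservatism, so the
exact test rejects with probability ≥ 0.99 at the configured α.  Below the
n where that F would exceed 0.95 the generator refuses and names the
minimum n.  Each SNP's engineered property (clean SNPs pass, designated
failures fail) is then verified by actually running the exact test and the
SNP redrawn on the rare fluke, so the downstream QC outcome — 56 in,
44 out — is deterministic by construction for every seed.  All other SNPs
get exactly ⌊missing_rate·n⌋ missing calls (default 1%).

**Phenotype**: BMI Z = √h²·z(score) + covariate component + noise, with
the standardized score signal scaled so the score's variance share equals
`h2_target` (default 0.05, the mid-single-digit percent range such scores
explain in children) and sex/Tanner/origin effects carrying 10%.  The
ground truth records the implied coefficient on the raw score and the
realized variance fraction.  Weight status derives from BMI Z cut-offs
(1.04, 1.64) — the Z-scale analogues of the 85th/95th-percentile
overweight/obesity boundaries.

**Environment** (47 factors, the size of a typical lifestyle
questionnaire): ordinal codes 0–4 by default (questionnaire items are
small ordinal scales; a continuous generator is available since the
original item distributions are not documented).  Factors with configured
interaction coefficients add β₃·pGRS·E to BMI Z — exactly the scan's
product term — others are pure noise.

**Trajectories** (group sizes 20/20/20/20/16 = 96): per child, BMI Z and
HOMA-IR drawn uniformly on the correct side of the weight and IR cut-offs
for the assigned group at each timepoint, Tanner I at baseline and II–V at
follow-up.  Score enrichment in a group is parameterised as a top-tertile
odds multiplier m (membership probability m/(m+2), reducing to 1/3 at
m = 1), with scores drawn from the matching tertile band of N(1.18, 0.13).

**RCT** (59 placebo / 65 treated): baseline BMI Z ~ N(2.5, 0.6) (an
obesity cohort), reduction = 0.05 + 0.15·treated + γ·pGRS·treated + noise
(SD 0.3), with γ the configurable interaction (default 0, the null
finding such trials report).

One RNG stream per sub-simulation, derived from the master seed by fixed
offsets, so enlarging the panel does not perturb phenotype draws;
identical configurations give byte-identical outputs.

What the generator does *not* emulate — and what passing tests therefore
do not establish about real data: LD between SNPs, genotyping batch or
plate effects, the covariance of real biomarker panels, informative
missingness, population stratification beyond a three-level origin label,
and real questionnaire item distributions.  Recovery and calibration
results show the estimators are correct under the stated model, not that
the model captures any particular cohort.

## Problem sizes in the test suite

Monte-Carlo checks use sizes chosen to bound their variance: CI coverage
over 200 seeds (binomial SD ≈ 1.5% at 95%), type-I calibration over 2000
replicates at n = 150 (SD ≈ 0.5% at 5%), FDR-scan family false-positive
rate over 200 scans of 47 factors at n = 300, variance-explained recovery
over 50 seeds at n = 5000, and mixed-model calibration over 400 trials of
120 children.  Exact oracles run exhaustively where enumeration is cheap
(all genotype tables with ≤ 30 subjects; all case-control pairs at
n ≤ 50).

## Known limitations

* No LD pruning, reference-panel imputation, multi-allelic variants or
  strand-ambiguity resolution; the weights file is the single source of
  orientation truth.
* The unweighted allele-count score variant is intentionally absent.
* BMI Z itself is consumed, not derived from raw anthropometry against a
  national reference; likewise QUICKI is consumed as a column.  HOMA-IR is
  computed as glucose·insulin/405 only when absent, and flagged derived.
* The gene×environment scan models ordinal items linearly; categorical ×
  score contrasts and multi-factor joint interaction models are out of
  scope.
* Split-sample AUC only — no cross-validation, calibration curves or
  reclassification indices.
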