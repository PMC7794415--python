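# Methods

`dermrisk` implements a survey-based composite risk-score analysis for
the three major skin cancers (basal cell carcinoma, squamous cell
carcinoma, melanoma): a synthetic cohort generator, a per-variant
association scan with clumping-and-thresholding PRS, staged risk-factor
selection into per-cancer binomial GLMs, grouped composite scores (DRS
and the age-free DRSA), tail-enrichment evaluation, and lifetime-risk /
incidence / age-of-onset trajectories with prospective validation.

## The synthetic cohort generator

The generator is first-class code, not a fixture: it defines the study
conditions under which every downstream claim is tested.

**Disease mechanism.** Case status is not a single cross-sectional
logistic draw.  Each participant carries a linear predictor
`eta = sum_j beta_j x_j + sum_k w_k g_k` over survey factors and
genotype dosages, and is exposed, for every year `a` from 30 up to their
current age, to a yearly diagnosis hazard

    h(a) = h0(a) * exp(eta - mean(eta)),     clipped to [0, 1],

where `h0(a)` is a per-cancer baseline schedule (default: exponential in
age, calibrated once so cohort prevalences land near survey reality —
about 13% BCC, 6% SCC, 3% melanoma at the cohort's age structure).  The
first success sets case status and the age at diagnosis.  Centering
`eta` makes `h0` the hazard of an average-risk participant; it shifts
only the implicit intercept, never an odds ratio.  This mechanism gives
ground truth for cumulative incidence (closed form `1 - prod(1 - h)`),
incident cases, and onset ages, while cross-sectional case status still
approximately follows the logistic model the GLMs fit — exactly so in
the rare-disease limit (see "Known limitations").

**Factor catalog.** ~25 mixed factors named after the skin-cancer
risk-factor literature, in the groups used for the grouped scores: Mole
(4: dysplastic moles, large moles, arm mole count, early actinic
keratosis), Susceptibility (8: pigmentation and sun-reaction items),
Exposure (8: sunbathing, tanning beds, latitude/elevation, weekly sun,
outdoor job, physical activity), Miscellaneous (7: weight, BMI, smoking,
alcohol, allergies, morning person, clean desk), plus sex.  Effect
directions follow the literature; magnitudes are generator truth, chosen
once to be realistic (the dysplastic-mole melanoma log-OR is planted at
ln 6.7; actinic keratosis at ln 3.2–3.5 for the keratinocyte cancers;
sex at ln 1.6; weight positive and BMI negative with a 0.8 Gaussian-
copula correlation so the collinearity diagnostics have something real
to find).  Ordinal factors are drawn by discretizing a latent normal;
`age_slope` shifts the (latent) mean per year of age, so zero slopes
make a factor exactly age-independent.  Survey encodings (level counts
and frequencies) are plausible choices documented in
`default_factor_catalog`; the real survey's encodings are not public.

**Family history** is drawn per relative (father, mother, ≥1 sibling,
≥1 child) with probability `logistic(intercept_rel + 0.5 z)`, where `z`
is the proband's standardized mean linear predictor — a shared-risk
proxy that makes the family-history score informative without
simulating pedigrees.

**Follow-up.** Each of `followup_years` waves is answered by a
`response_rate` fraction (default 0.55, a typical response
proportion for yearly health follow-up surveys).  Baseline controls convert with their
yearly hazard at `current_age + k`; the wave-k answer covers *that year
only* — a wave-1 convert answering wave 2 reports no new diagnosis, as
a "diagnosed in the last 12 months" question would.  Baseline cases
report treatment with a recurrence probability (default 0.3).

**Missingness** is MCAR on factor columns only (default 5%, inside the 2–15%
per-question range typical of long health surveys).  **Genotypes** are Hardy–Weinberg
`Binomial(2, maf)` dosages on a synthetic map (22 chromosomes, 100 kb
spacing); variants are independent unless an explicit `ld_blocks`
correlation is configured (used by the clumping tests).  All randomness
flows from one seed through named substreams; identical configs are
byte-identical.

What the generator does *not* emulate: realistic LD, pedigrees,
informative missingness, calendar effects, misreporting.  Passing tests
therefore certify the machinery under these idealized conditions, not
performance on real survey data.

## Genetics

The per-variant scan is a maximum-likelihood logistic regression of
case status on dosage plus covariates (own IRLS; Wald p-values;
separation flags the variant as non-converged and excludes it from
selection; empirical MAF below 0.01 is skipped to avoid separation
artifacts).  Genomic control is the median 1-df chi-square over
0.4549364.  PRS selection is greedy clumping and thresholding: take the
smallest p ≤ 1e-6 (ties by chromosome, position), discard unselected
variants within 250 kb on the same chromosome with dosage r² > 0.1,
repeat.  The window and r² cap are standard clumping practice and
configurable.
Scores are weighted dosage sums with missing dosages imputed at
2·MAF.

**Analytic power.** For MAF `p`, per-allele OR, and case/control counts,
the case-enriched allele frequency is `pbar = OR p / (1 - p + OR p)`,
the log-OR variance is
`1/(2 n_case pbar (1-pbar)) + 1/(2 n_ctrl p (1-p))`, and power is the
two-sided normal tail beyond `z_{1-alpha/2}` at the resulting
non-centrality.  A vectorized Monte-Carlo oracle (logistic Wald tests
on simulated case-control genotype counts) cross-checks the formula in
the tests to 0.02.  Reference power values reported for this study design are
reproduced to a documented ±0.05 at best: the three reference values
are mutually inconsistent with any single two-group analytic family at
the stated counts (no choice of allele vs trend statistic, one- vs
two-sided, or prevalence adjustment passes through all three).  The
SCC-scale value is the one this formula cannot reach (0.977 analytic
vs 0.86 reference); the corresponding acceptance assertion is left
failing rather than fitted.

## Model building

Continuous factors enter through orthogonal polynomial bases (Forsythe
three-term recurrence, orthonormal on the training sample; the stored
recurrence re-applies the training basis to validation data, and makes
deviance explained invariant to affine recodings).  The polynomial
degree is chosen by sequential single-factor likelihood-ratio tests
from degree 2 up to 4 at p < 0.01.  Categorical factors are
reference-coded with the most frequent level as reference.  Ordinal
survey factors enter as single numeric columns.

Missing phenotypes are completed by predictive mean matching: each
incomplete numeric column is regressed (OLS) on the complete columns
and every missing cell takes the observed value of the nearest-
prediction donor; categorical columns take the modal class; columns
≥50% missing are dropped.  Non-missing cells are never modified.

Stage-1 selection fits the all-factor GLM per cancer and keeps a factor
if *any* of its design columns has Wald p < 0.05 (factor-level
selection keeps categorical factors interpretable; the union over the
three cancers is retained, and demographic covariates are never
dropped).  The extra-phenotype scan refits the base model plus one
candidate at a time and keeps candidates at p < 1e-8 in any cancer,
skipping candidates aliased with the base design (R² > 0.999).
Correlated candidates are grouped by mixed-variable hierarchical
clustering: cluster homogeneity is the first eigenvalue of the PCAmix
of its members (squared correlation for quantitative members,
correlation ratio for qualitative ones, against the cluster's first
principal component); merging minimizes the homogeneity decrease, and
each cluster is represented by its lowest-p, lowest-missingness member.
No Python implementation of this clustering exists in the environment,
so it is implemented here directly from its definition.

The final model is an ordinary binomial GLM (statsmodels, logit link).
Deviance explained is `1 - deviance/null deviance`.  The deviance
decomposition ranks factors by single-factor deviance explained and
refits cumulatively in that order (marginal contributions telescope to
the full-model value exactly).  VIF is `1/(1-R²)` per design column,
with exact collinearity reported as infinite.  Interaction tests are
likelihood-ratio tests of all cross products of two factors' column
blocks, so interactions with a polynomial block are tested against the
whole block.  Factors are kept unless VIF > 10, the conventional cutoff
(weight and BMI sit around 7–8 by design and stay in).

## Risk scores

Every score is `sum_j x_ij beta_j` over a factor subset, with the
per-cancer fitted coefficients as weights and no intercept (scores are
used only through ranks, bins, and z-scales, so location is
irrelevant).  DRS uses all factors; DRSA removes only the age
polynomial block and reuses the remaining weights unchanged, keeping
sex and ancestry.  The six grouped scores follow the factor→group map;
with the age block they partition the DRS exactly.  The family-history
score is the simple sum of the four relative indicators with raw values
3 and 4 collapsed (few participants report both parents, a sibling and
a child affected).  Standardization is against the training-set mean
and SD, which are recorded; OR-per-SD therefore refers to the training
scale.

## Evaluation

AUC is computed by the rank (Mann–Whitney) statistic, with ties counted
half; percentile bins are rank-based with stable tie-breaking by input
order and sizes differing by at most one, making bin summaries
invariant under monotone score transforms.  Fold enrichment compares a
bin's prevalence with the pooled prevalence of the middle band, bins
48–53 by default (configurable).  Per-bin
mean age at diagnosis carries a normal-approximation 95% CI over cases;
any reported cell that would derive from fewer than five participants
is masked.  Cancer-stage summaries are computed over cases only.

## Trajectories

Lifetime risk `P_a` per DRSA stratum is estimated retrospectively:
`P̂_a` = (cases in the stratum with diagnosis age ≤ a and current age
≥ a) / (stratum members with current age ≥ a), then smoothed by
weighted isotonic regression in `a` (the estimator is a package design
decision).  The
m-year incidence is `I_a = (P_a - P_{a-m}) / (1 - P_{a-m})`, exact per
age point; negative raw incidences (impossible after smoothing) clamp
to zero with a warning.  The expected age of diagnosis is
`m = sum(S_a I_a a)/sum(S_a I_a)` over ages 30–90, with the matching
weighted SD; `S_a` is a user-supplied survival table, with a bundled
*synthetic* Gompertz schedule (yearly mortality 5e-4·exp(0.09(a-30)))
standing in for an official life table so nothing needs downloading.

Prospective statuses follow the standard definitions: *incident* =
baseline control reporting a diagnosis in any answered wave;
*cancer-free* = baseline case reporting no treatment; contradictory
reports (a case reporting a first diagnosis) count as persistent cases;
participants answering no wave are excluded from rates.  The
expected-vs-observed check compares the stratum's curve-derived
window incidence, evaluated at each participant's attained age, with
the observed conversion fraction among baseline controls who answered
*every* wave of the window (partial responders carry censored exposure
and would deflate a multi-year rate), with Wilson 95% CIs.

## Numerical choices and problem sizes

Tolerances: exact identities at 1e-12; GLM oracle agreement at 1e-6;
calibration bands at the binomial sampling width of the replicate
counts.  Test problem sizes are chosen so the full suite runs in
minutes on one CPU: parameter recovery and DRSA age-independence run at
n = 50,000 (20 seeds for interval coverage), calibration at 1,000
null replicates, the prospective concordance check at n = 20,000 over
20 seeds — at that size the observed-side binomial noise dominates the
expected side's own Monte-Carlo error, which the CI-based check treats
as zero.  The end-to-end pipeline demo uses n = 2,500–5,000 with 120–200
variants and a handful of strongly associated variants planted so the
PRS stage selects a non-empty model at the 1e-6 threshold.

## Known limitations

- **Hazard-scale vs cross-sectional coefficients.**  The GLM estimates
  the cross-sectional conditional log-odds, which differs from the
  generator's hazard-scale log-OR once cumulative incidence is
  non-negligible (odds saturation; ~12.5% for BCC) and is further
  attenuated by the unmodelled genotype burden (non-collapsibility).
  At n = 50,000 the discrepancy reaches 1–2 SE for the largest effects,
  so 95% Wald intervals cover the hazard-scale truth at ~88% rather
  than 95%.  Point recovery within 3 SE is unaffected.
- The retrospective lifetime-risk estimator assumes no cohort effects
  and no differential mortality by risk stratum; both hold in the
  generator and neither holds in real data.
- The bundled survival schedule is synthetic; substantive onset
  expectations require a real life table.
- Principal components are computed on the full genotype matrix
  (training + validation), as is conventional for ancestry axes; all
  other fitted quantities are training-only.
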