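# Methods

`prosteo` implements a longitudinal proteome-to-osteoporosis analysis pipeline
for a three-visit cohort with repeated serum-proteome and DXA bone mineral
density (BMD) measurements at two sites (lumbar spine, LS; femoral neck, FN),
together with a synthetic-data generator that supplies ground truth for every
stage. This note records the models, the defaults and their rationale, the
numerical choices, and the known limitations.

## Synthetic cohort generator

The generator emulates a middle-aged, two-batch cohort. Defaults mirror the
scale of such a study: 3415 participants (72% female, age 57.5 ± 5.1 y), 413
proteins at 3 visits spaced 3.3 years apart, batches split 1785:1630. The
desk-scale pipeline configuration used by the tests and the acceptance script
is 800 participants, 60 proteins, 8 BMD proteins and 12 age proteins, which
runs end to end in a few minutes on one CPU.

**BMD model.** Per participant and site, a latent T-score follows a linear
growth curve: level + slope·t + visit noise. The level combines baseline age
(−0.05 T/y), sex (−0.25 T for women), a weak BMI confounder, the causal
proteins (each `bmd_effect_sd_per_sd` = 0.3 BMD-SD per protein-SD, half
positive and half negative), and a person-specific random intercept whose
variance is set so the latent level has unit variance — this keeps generated
effects directly recoverable on the standardized scale. The slope combines a
population decline (−0.06 T/y, SD 0.03) with an age-acceleration term (below).
BMD in g/cm² is `ref_mean + ref_sd · T` with Hologic-style young-adult
references (LS 1.047 ± 0.110, FN 0.858 ± 0.120 g/cm²). Osteoporosis is *not*
an independent event process: events derive from T-scores of the simulated
BMD, keeping ground truth coherent between the association, risk-score,
survival and biological-age stages.

**Biological age.** True biological age is `BA_true = CA + Δ`,
`Δ ~ N(0, 5²)` years. Age-coupled proteins follow `x_j = q_j + k_j·BA_true +
N(0, s_j²)` with `s_j` set so each protein correlates 0.4 with `BA_true`
(a moderate clock panel; with 12 such proteins the aggregated estimate is
informative enough for the recovery tests while remaining far from a perfect
clock). Δ also steepens the BMD slope (−0.02 T/y per year of Δ), so
accelerated agers reach osteoporosis sooner — this is the coupling the
survival-of-acceleration tests detect.

**Abundance scale, missingness and batches.** Abundances live on a positive
intensity-like scale (lognormal around a per-protein baseline with log-scale
CV 0.2–0.4, plus visit-level measurement noise). This matters: half-minimum
imputation is only sensible on an intensity scale, where half the smallest
observed value sits just below the data. (On a symmetric log scale the imputed
constant lands many SDs below the distribution and a point mass there inflates
each batch's SD by a randomly different amount, which manifests as spurious
between-cohort heterogeneity of association estimates.) Missingness is
left-censored: each measurement batch has its own detection limit, so the
lowest `missing_rate` (default 10%) of each protein is removed per batch. The
validation batch additionally carries a per-protein multiplicative intensity
bias (log-SD 0.1), the residual of imperfect cross-run normalization.

**Covariates** (BMI, waist-hip ratio, blood pressure, lipids, glucose, urate,
lifestyle and diet variables, supplements) are weakly correlated Gaussians and
binaries; BMI confounds both BMD and a handful of non-causal proteins so that
covariate adjustment is actually exercised. Protein-protein correlation beyond
these mechanisms defaults to independence.

**GWAS summary statistics.** Per SNP, a true instrument effect
`γ_i ~ U(0.06, 0.25)` (oriented positive, the usual reporting convention for
published pQTL instruments) with observed `b_X = γ + N(0, se_X²)` and
`b_Y = θ·γ + α_i + N(0, se_Y²)`. Pleiotropy `α_i` can be applied to a fraction
of SNPs with a directional mean. In the 50%-invalid robustness scenario the
pleiotropy is assigned to the *weakest* half of the instruments: the valid
SNPs then hold ≈77% of the inverse-variance weight, the regime in which the
weighted median is consistent while IVW is not. (With pleiotropy assigned
uniformly at random, 50% invalid instruments put the weighted median exactly
at its breakdown point — a boundary case, not a useful test of robustness.)

## Preprocessing

Missing abundances are imputed with half the per-protein minimum observed over
all analyzed samples pooled across visits. Standardization (mean 0, SD 1 with
the n−1 denominator) is fit on the baseline rows of each batch separately and
applied to that batch's follow-up rows, preventing leakage across the
discovery/validation split. T-scores are `(BMD − ref_mean)/ref_sd`; the status
partition is total with half-open boundaries — osteoporosis T < −2.5,
osteopenia −2.5 ≤ T < −1, normal T ≥ −1 — plus a treated-flag override. Fold
change is `(mean_case − mean_control)/mean_control` on imputed, unstandardized
abundances with a two-sided Welch t test (Wilcoxon available) and
Benjamini-Hochberg adjustment; the BH step-up is implemented in-repo and
property-tested against the brute-force definition. The PCA batch check
reports variance explained and the absolute batch-mean gap on PC1 in SD units;
no batch correction is applied.

## Protein selection

Labels are ever-osteoporosis at the given site during follow-up, one row per
participant with baseline protein z-scores. The discovery cohort is split
70/30 (`round(n·train_frac)`), deterministic given the seed. The
gradient-boosting selector fits LightGBM (200 trees, 15 leaves, learning rate
0.05 — defaults logged in the result object) and retains features with mean
absolute TreeSHAP attribution above zero, applied with tolerance 1e-12
because a strict > 0 is numerically fragile. The LASSO selector is an
L1-penalized logistic regression with the penalty chosen by 10-fold
cross-validated deviance. Validation-cohort performance re-scores the trained
model; selection is not re-run there. The AUC is the Mann-Whitney formulation
with ties counted 1/2, implemented in-repo and cross-checked against brute
force and scikit-learn.

## Association and meta-analysis

Per cohort, BMD at all visits (standardized within cohort) is regressed on the
baseline protein z-score with a per-participant random intercept, adjusting
for baseline covariates, fitted by REML (statsmodels MixedLM, L-BFGS).
Missing covariates are handled complete-case per model. Two degenerate cases
reduce exactly and are dispatched accordingly: one observation per participant
(random intercept unidentified → OLS) and noise-free outcomes (REML variance
components collapse → OLS SE with a floor). Cohorts are pooled with
DerSimonian-Laird random effects; Cochran's Q, τ² and I² are reported, with
two-sided normal p-values. A protein-site pair is flagged when the pooled
p < 0.05 and I² < 30% (both strict); BH-adjusted q-values are attached per
site family for reporting but do not enter the flag. In the recovery tests a
planted protein counts as recovered when flagged at either BMD site: with two
cohorts, I² ≥ 30 occurs with probability ≈0.23 under exact homogeneity
(P(χ²₁ > 1.43)), capping per-site sensitivity near 0.77 regardless of effect
size, while the either-site union is what the joint protein list reflects.

## Risk score, trajectories, survival

The protein risk score is the meta-β-weighted sum of standardized abundances
over flagged proteins, with weights sign-flipped to a risk scale (positive =
BMD-lowering) so hazard ratios above 1 are expected; scores are z-standardized
over the scoring set and also handled as quartiles (stable-rank tie-break).

The trajectory model is a K-class mixture of linear growth curves with a
shared residual SD, fitted by EM (responsibilities initialized from k-means on
per-person OLS intercept/slope, random restarts, convergence at Δlog-lik
< 1e-8; the log-likelihood is checked non-decreasing). Classes are labelled in
ascending-intercept order. Model order over K = 1..5 is chosen by BIC
(−2ℓ + p·log N) among fits whose every class has average posterior probability
of assignment ≥ 0.7; equal BICs break toward fewer classes. Trajectories are
linear because three visits support no higher order.

Survival records take the visit date of the first osteoporotic classification
as the event time (interval-observed at visits; interval-censoring methods are
out of scope), censor at the last attended visit, and exclude prevalent
baseline cases with logging. Cox models use Efron tie handling (visit times
create heavy ties) via lifelines, with Wald CIs. Dose-response uses a
restricted cubic spline basis (Harrell's knot quantiles; 4 knots at
0.05/0.35/0.65/0.95), implemented in-repo and oracle-tested against the
truncated-power formula. The quartile trend test enters the quartile rank as a
single ordinal covariate.

## Klemera-Doubal biological age

Each selected protein is regressed on chronological age (q_j, k_j, residual SD
s_j floored at 1e-6, correlation r_j). The uncorrected estimate aggregates by
information content:

    BA_E = Σ_j (x_j − q_j) k_j / s_j²  /  Σ_j k_j² / s_j²

and the CA-corrected estimate (the proteomic age) adds CA as a pseudo-marker
with weight 1/s_BA²:

    s_BA² = Var(BA_E − CA) − (1 − r_char²)/r_char² · (CA_max − CA_min)²/(12 m).

The characteristic correlation r_char is the (k²/s²)-weighted mean of |r_j| —
one of several variants in the literature; it is config-overridable. When the
correction makes s_BA² non-positive (weakly age-correlated panels), s_BA²
falls back to Var(BA_E − CA) so the corrected estimate stays defined. Age
acceleration is the OLS residual of BA_EC on CA over the scoring set (sample
mean 0 by construction), reported in years and in SD units. Candidate proteins
are screened by |corr(x, CA)| ≥ 0.1 with BH q < 0.05 and greedily pruned at
pairwise |r| > 0.7, keeping the stronger CA-correlate; the age panel is
selected independently of the osteoporosis-protein selection.

## Mendelian randomization

Instruments require exposure p ≤ 5×10⁻⁸ (inclusive). Harmonization aligns
outcome effects to the exposure effect allele (sign-flip on swapped or
complementary-strand alleles), drops palindromic SNPs with effect-allele
frequency in (0.42, 0.58) or unknown, and drops allele-incompatible SNPs; it
is idempotent. Estimators: per-SNP Wald ratio (first-order SE), IVW as
weighted origin regression (fixed-effect SE, multiplicatively inflated when
Q/(k−1) > 1, flag recorded), MR-Egger with exposure effects oriented positive
and overdispersion-scaled SEs floored at 1 (t-based p on k−2 df), weighted
median (inverse-ratio-variance weights, linear interpolation at cumulative
weight 0.5, seeded parametric-bootstrap SE, 1000 reps), and simple/weighted
mode (Gaussian-kernel density argmax with a modified-Silverman bandwidth,
bootstrap SE). LD clumping, Steiger filtering and MR-PRESSO are out of scope;
instruments are assumed independent.

## What the tests do and do not show

The generator produces linear effects, Gaussian noise, independent proteins
(up to the designed confounding) and missingness exactly at a detection
limit. Passing tests therefore demonstrate that the estimators recover what
they claim under their own model assumptions and remain calibrated under
permutation and homogeneity nulls — not that real serum proteomes satisfy
those assumptions. In particular, real batch effects are not purely
multiplicative, real protein panels are strongly inter-correlated, real BMD
trajectories need not be linear, and real instruments can violate InSIDE in
ways no simulation switch covers. Problem sizes in the test suite (n =
300–2000 participants, 50–200 replicates) are the package's chosen desk-scale
defaults; all stochastic tests are seeded.
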