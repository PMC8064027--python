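# Methods

This note documents the statistical procedures implemented in `caseseries`,
the defaults and their rationale, what the synthetic cohort generator does
and does not emulate, and the numerical choices that matter.

## Data model

A cohort is a wide table: one row per participant (group ∈ {control, left,
right, bilateral}, age, education, and for patients lesion volume and time
since stroke) and one column per `test__measure` pair of a declared
battery. The packaged default battery has 22 tests across four domains
(3 low/intermediate vision, 8 word, 6 object, 5 face); a 12-test subset
(4 per composite domain) is flagged `in_composite`. Missingness is an
explicit boolean mask; empty CSV cells are missing, and imputation never
overwrites an observed value. Group labels are normalized
case-insensitively; anything else is an error, as are duplicate IDs,
non-numeric score cells (reported with row/column coordinates), controls
carrying lesion fields, and missing age for any participant entering a
covariate-adjusted test (age is never imputed).

## Preprocessing

**Direction alignment.** Lower-is-better measures (RTs) are negated after
which all columns read higher-is-better; the rewritten schema makes the
operation idempotent. Plain negation (not log-RT) is the simplest monotone
map and downstream steps standardize anyway.

**Measure collapsing.** Each multi-measure test is reduced to one score:
its measures are z-scored, the first unrotated principal component of
their correlation matrix is taken, and the component score is rescaled to
unit variance. The sign is fixed so the accuracy measure loads positively
(falling back to the alphabetically first measure), which makes the result
exactly invariant to measure column order. A `fit_mask` argument selects
the rows that estimate the standardization and weights — patients for the
group PCA (controls are then mapped through patient-derived weights for
projection), all subjects for the composites. Collapsing requires a
complete matrix, hence runs after imputation.

**Reference standardization.** Columns are z-scored against a chosen
reference subgroup (mean, SD with ddof = 1, both recorded). The group PCA
standardizes to the patients, so the origin of the factor space is the
patient-group mean.

## PPCA imputation

Model: `x = W z + mu + eps`, `z ~ N(0, I_k)`, isotropic noise. Fitting is
EM over the observed entries only (MAR assumption): the E-step computes
each row's latent posterior given its observed coordinates (batched via
the Woodbury identity); the M-step jointly re-estimates `(mu_j, w_j)` per
variable from the rows observing it, then the noise variance. The
observed-data log-likelihood is tracked per iteration and is monotone
non-decreasing (checked in tests with 1e-8 relative slack). Defaults:
relative log-likelihood tolerance 1e-6, max 1000 iterations, noise floored
at 1e-12, random orthonormal initialization seeded for determinism.
Missing cells are imputed by the posterior mean `mu_m + W_m E[z|x_obs]`.

The component count is chosen by repeated element-wise k-fold
cross-validation: observed cells are partitioned into folds (re-drawn until
every row and column stays observed when any one fold is masked; an error
suggests fewer folds when impossible), each fold is held out in turn, the
model refit at each candidate k, and held-out RMSE averaged; the argmin
wins with ties to the smaller k. Cell-wise holdout is used rather than
row-wise because a fully removed row has no observed anchor to reconstruct
from. Default 5 folds; repetitions default to 10 in the pipeline
(configurable upward; CV on strong low-rank signal is insensitive to the
repetition count, which mainly smooths the RMSE curve). Patients and
controls are imputed under separately fitted models so patient pathology
never shapes control imputations.

## Group PCA

Sampling adequacy is the Kaiser–Meyer–Olkin measure,
`KMO = Σ r² / (Σ r² + Σ q²)` over off-diagonal elements, with anti-image
partial correlations `q_ij = −r^{ij}/√(r^{ii} r^{jj})` from the inverse
correlation matrix. Degenerate inputs: a diagonal R is 0/0 and raises; a
singular R raises with advice rather than being silently ridged (the
singularity guard is the smallest eigenvalue, not the determinant, because
a healthy battery with strong shared variance has a legitimately tiny
determinant). Any 2-variable matrix gives exactly 0.5.

Extraction eigendecomposes the patient correlation matrix and retains
components with eigenvalue strictly > 1, falling back to one component so
degenerate inputs never yield an empty solution; loadings are eigenvectors
scaled by √λ. Varimax rotation maximizes the summed per-factor variance of
squared loadings via the standard SVD fixed-point iteration, with Kaiser
row-normalization on by default, tolerance 1e-12 on the relative change of
the singular-value sum (tight enough that the criterion sits within 1e-6
of a 0.01°-grid brute-force optimum) and a 2000-iteration cap. Columns are
sign-fixed (largest-|loading| entry positive) and ordered by post-rotation
variance explained. Communalities and total variance explained are
conserved by the rotation (orthogonal invariants, tested at 1e-8).

Factor scores use the regression method, `Ws = R⁻¹Λ` (pseudo-inverse on a
singular R), the common default of mainstream factor-analysis software;
fitting rows therefore have mean-zero scores. Controls are z-scored with
the patient statistics and multiplied by the same coefficients. The
deficit cutoff per factor is `control_mean − 2·control_sd` over the
individual projected control scores (`score_sd` mode). Because "project a
cut-off score" also admits projecting a single pseudo-subject at
test-level mean − 2 SD — identical for the mean by linearity but not for
the SD — that reading is preserved as `cutoff_mode="projected_pseudosubject"`;
neither is asserted to be the original procedure.

## Single-case statistics

**Modified t.** `t = (y* − m)/(s√((n+1)/n))` on `n − 1` df: the case is
treated as an extra draw from the control distribution, not compared to a
known population.

**Bayesian deficit test with covariates** (`btd_cov`). Controls' scores
are regressed on `[1, X]`. Per draw: `σ² = SSE/g`, `g ~ χ²(n−c−1)`;
`β ~ N(b, σ²(DᵀD)⁻¹)`; the case is standardized against the drawn
conditional distribution at its own covariates and the standard-normal
lower tail recorded. The mean over draws is the one-tailed p and the
point estimate of the abnormality percentile; the 2.5th/97.5th percentiles
of the per-draw tails give the 95% credible interval. With zero covariates
this reproduces the modified-t p (verified to 0.005 at 100k draws), and
under the null with one covariate its one-tailed rejection rate at
α = .05 is calibrated (tested within [0.042, 0.058] over 5000 cases at
n = 46).

**Bayesian standardized difference test with covariates** (`bsdt_cov`).
Bivariate regression of the two task scores on `[1, X]`; per draw
`Σ ~ InvWishart(S, n−c−1)` (Bartlett construction), `B ~ matrix-normal
(B̂, (DᵀD)⁻¹, Σ)`; the case's two conditional z-scores and the drawn
correlation give `d = (z_x − z_y)/√(2 − 2ρ)`, referred to the standard
normal; the tail-adjusted mean over draws is `p_diff`. Only this
standard-theory prior is implemented — the enum rejects `calibrated`
explicitly, since its exact construction is not pinned down — and its
two-tailed null rejection rate is verified within [0.03, 0.07] (mild
prior sensitivity is expected and documented rather than corrected).

Defaults: deficit tests one-tailed (lower), difference tests two-tailed,
α = .05, no multiple-testing correction (matching standard practice in
this design; callers can Bonferroni-adjust α), 100k draws for reported
analyses and 10k in the pipeline default, mandatory seeds.

## Composites and classification

Composites are built per domain from the `in_composite` tests over
controls *and* patients: first unrotated PC of the standardized tests,
sign-fixed so the mean loading is positive, unit variance over the fitting
sample. The `rank_sum` variant averages per-test ranks (mean rank on
ties); both methods yield the same deficit flags for ≥80% of patients on
the default cohort (tested). Age is the default covariate; education is
excluded by default (in the motivating data it did not correlate with the
composites).

Flags (p < α per domain) map to the 8 deficit patterns. Dissociation
testing is gated on ≥1 deficit. For each domain pair the more impaired
task (smaller deficit p) plays X; criteria are (1) X flagged, (2) Y's
deficit p ≥ α — "within the control range" operationalized with the same
inferential machinery as criterion 1 rather than a ±2 SD band — and
(3) `bsdt_cov` p < α. Classical = 1∧2∧3; differential = both tasks flagged
with 3; the label logic makes a classical label structurally impossible
when criterion 2 fails. `pooled_t_from_summary` provides the
pooled-variance two-sample t for demographic comparisons given as
mean (SD, n) per subgroup.

## Synthetic cohort generator

The generator's defaults define the validation conditions: 46 controls,
32 left / 23 right / 9 bilateral patients, 22 tests, 3% MCAR missingness.
Each subject draws latent abilities `(a1, a2)` from a bivariate normal
(correlation 0.3); test scores are `Λ*·a + γ·z(age) + noise` with
generating loadings word (0.8, 0.1), object (0.5, 0.5), face (0.1, 0.8),
low-level (0.3, 0.3) and `γ = −0.25` (performance declines with age on
every test). Lesion effects depress factor 1 for left lesions, factor 2
for right, both for bilateral (1.2 SD each) scaled by `(volume/37 cm³)^0.5`
with lognormal volumes (medians 32/35/61 cm³; bilateral largest). Tests
with accuracy + RT pairs derive both from the test score with a
within-test correlation of 0.7. Per-domain noise SDs (word .25,
object .40, face .55, low-level .50) were fixed analytically so the
control group shows the tightest distribution on word tests and the
loosest on face tests, and so the patient correlation matrix carries two
dominant factors explaining roughly three quarters of the variance with
KMO near .9 — the regime this kind of battery exhibits in practice.

Planted category-selective cases (default: 4 word cases at Δ = 3 control
SD) *replace* the lesion effect of the selected patients with a pure shift
of −Δ·SD on their domain's tests only: a category-selective deficit is
modelled as bypassing the shared factors, which is what makes it selective
and what the classification should recover as a word-only pattern.

What the generator does **not** emulate: realistic RT distributions
(scores are Gaussian; real RTs are skewed), MNAR missingness (real missing
data partly track severity; the mask here is MCAR by design), lesion
geometry, ceiling/floor effects, and test-specific age slopes. Passing
recovery tests therefore show the pipeline recovers structure *of the
assumed form*; they do not certify behaviour under MNAR missingness or
heavy-tailed measures.

Recovery metrics (`recovery_report`): planted-case sensitivity per domain
(fraction recovered as exactly that domain's selective pattern), a
planted-vs-recovered label matrix, the false-positive rate among patients
with neither shift nor plant, minimum Tucker congruence between recovered
and generating loadings (greedy column matching, sign-free), and
imputation RMSE against a column-mean baseline.

## Pipeline and reproducibility

`run_full_analysis` executes validation → orientation → per-group PPCA
imputation → collapsing → group PCA with control projection → composites →
deficit tests → patterns → dissociations → overlay. Every stochastic stage
receives a seed derived from the master seed through fixed spawn keys, so
adding a stage never perturbs earlier streams; outputs are pure functions
of (inputs, config, seed) and bundle writes are byte-identical across
reruns (floats serialized with shortest exact round-trip representation,
hash manifest included). Problem sizes in the test suite and acceptance
script (e.g. 100 CV seeds, 40 retention seeds, 25 planted-recovery seeds,
5000 calibration cases at 2000 draws) were chosen as the smallest runs
whose Monte-Carlo error is comfortably below the property margins being
checked.

## Known limitations

* The Bayesian tests are Monte-Carlo only; no closed-form shortcut is
  provided, so p-values carry O(1/√n_mc) jitter (credible intervals
  quantify it).
* The `calibrated` prior variant of the standardized difference test is
  not implemented.
* Oblique rotations, parallel analysis, hierarchical clustering and
  lesion-behaviour inference are out of scope.
* With very small control samples (n < c + 4) the difference test is
  undefined and raises rather than approximating.
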