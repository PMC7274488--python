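# Methods

`thyromr` implements a complete causal-inference chain from registry-style
records and genotype dosages to observational, one-sample Mendelian
randomization (MR), and two-sample MR estimates of the effect of adiposity
traits and type 2 diabetes (T2DM) liability on benign nodular thyroid disease
and differentiated thyroid cancer. The individual-level data such analyses
are normally run on (a national biobank with cancer-registry and hospital
linkage) are access-restricted, so the package ships a synthetic-cohort
generator that encodes the statistical structure the estimators assume and
lets every stage be exercised and calibrated end to end.

## Phenotyping rules

Diagnoses live in a long table (participant, ICD-10 code, date, histology
class, toxic flag). The rule engine defines:

* **Thyroid cancer cases** — at least one `C73` record with papillary or
  follicular histology. Medullary and anaplastic carcinoma, lymphoma, and
  unspecified subtypes have distinct aetiology and exclude the participant
  (reason `histology`) when no eligible record exists. The earliest eligible
  date is the index date, collapsing recurrences and duplicates.
* **Benign nodular disease cases** — at least one non-toxic `D34` record;
  toxic-only carriers are excluded (reason `toxic`) and are not eligible
  controls either.
* **Dual-diagnosis window** — participants whose cancer and benign index
  dates lie strictly within 12 months of each other are removed from both
  analyses (`diagnostic_uncertainty`): a nodule worked up and found
  malignant is one clinical episode, not two diseases. The window is
  computed on day-resolution dates as `< 365.25 * months/12` days; a pair
  exactly at the boundary is retained. A zero window excludes nobody.
* **T2DM status** — self-reported doctor-diagnosed diabetes, excluding
  diagnosis under age 35, insulin within the first year, and diagnosis less
  than a year before enrollment (screens out probable type 1 diabetes).
  Recency is computed from `age_at_recruitment - age_at_diagnosis`, the
  resolution the questionnaire provides. Missing subfields fail the
  criterion rather than being imputed — conservative, and consistent with an
  exclusion-based definition.
* **Controls** — separate groups per outcome: cancer controls have no
  C-prefixed diagnosis of any site; benign controls no `D34` of any kind.
  For each outcome every participant is exactly one of case / control /
  excluded, and every exclusion carries a reason, so the filter cascade is
  auditable.
* **Sensitivity switch** — removing carriers of thyroid-dysfunction codes
  (default prefixes `E03`, `E05`) from cases and controls, for re-running
  the one-sample MR without hypo-/hyperthyroidism.

Open point resolved as a default: a cancer case with a benign-nodule history
more than 12 months earlier keeps its benign-case status in the benign
analysis (such genuine antecedents exist and are informative); the window
parameter makes the alternative easy to test.

## Genetic risk scores

`raw = sum_j beta_j * dosage_j` with weights from the source GWAS, oriented
to the trait-increasing allele (negative weights are flipped together with
`dosage -> 2 - dosage` at load time). The rescaled score multiplies by
`n_variants / sum_j beta_j`, expressing the score in average trait-increasing
allele counts (range 0 to `2 * n_variants`); this is the standard rescaling
convention and makes the score invariant to a common rescaling of the
weights. Instrument strength is the squared t statistic of the score in a
linear regression of the exposure on score plus covariates — the
single-parameter first-stage F compared against the conventional threshold
of 10. Liability quartiles use the empirical 25/50/75 percentiles of the
whole scored population (cases and controls together, matching the published
near-25% control distribution across quartiles); boundary ties go to the
lower quartile.

## Observational models

Covariate-adjusted logistic regression, with continuous predictors scaled
per SD of the analysis population (the SD is reported alongside, e.g.
4.8 kg/m² for BMI) and skewed measures rank-inverse-normal transformed
(`Phi^-1((rank - 0.5)/n)`, average ranks for ties). The default adjustment
set is age, sex, smoking status, alcohol, Townsend deprivation index, BMI,
and T2DM (the exposure itself is dropped from the set); demographic
comparisons use an age+sex preset. Wald CIs on the exponentiated coefficient
match the OR (CI) reporting convention. Complete-case analysis with logged
exclusion counts; fits refuse to report below 10 cases; non-convergence
(separation) raises rather than returning garbage.

## One-sample MR

Two-stage predictor substitution: stage 1 regresses the exposure on the GRS
plus covariates (age, sex, assessment centre, genotyping platform, five
principal components); stage 2 regresses case status on the stage-1 fitted
values plus the same covariates with a logistic link. The published wording
of the second stage is ambiguous between predictor substitution and a
control-function form; predictor substitution is the standard two-stage
approach for binary outcomes and is the default, with the control-function
variant (`control_function=True`, fitted values replaced by exposure +
first-stage residuals) available for comparison. Standard errors are HC1
sandwich estimates, absorbing first-stage noise under a strong instrument;
F < 10 attaches an explicit weak-instrument note. A single-binary-instrument,
covariate-free fit reproduces the Wald ratio of the reduced-form to
first-stage coefficients exactly (an affine-reparametrization identity used
as a test oracle).

One-sample MR of a binary exposure (T2DM itself) is deliberately not
provided — ratio estimates for binary exposures are hard to interpret — and
the genetic-liability quartile contrast stands in: logistic regression of
the outcome on quartile indicators (lowest quartile reference) plus
covariates, alongside crude cross-product ORs from the 2x2 counts with
Woolf CIs.

## Two-sample MR

On harmonized rows (exposure-increasing orientation; palindromic A/T / C/G
variants kept or dropped by policy; allele-mismatched variants rejected by
name):

* **Wald ratio** `b_out/b_exp`, first-order SE `se_out/|b_exp|` (optional
  second-order form).
* **IVW** fixed-effect closed form
  `sum(w b_x b_y) / sum(w b_x^2)`, `w = 1/se_out^2`, SE
  `1/sqrt(sum(w b_x^2))`; equal to the inverse-variance meta-analysis of the
  Wald ratios, and to the single ratio when k = 1. Cochran's Q is attached;
  a multiplicative random-effects flag scales the SE by
  `max(1, sqrt(Q/(k-1)))`. Fixed-effect is the default because single
  un-inflated estimates are the convention in the result tables this package
  mirrors.
* **MR-Egger** — weighted regression with free intercept, k >= 3 required.
  SEs use the multiplicative-error convention: fixed-effect SEs inflated by
  `max(1, sqrt(RSS_w/(k-2)))`, p-values on t(k-2). The intercept estimates
  average directional pleiotropy; its p-value is the pleiotropy test.
* **Weighted median** — ratios sorted, inverse-variance ratio weights, the
  estimate linearly interpolated where the standardized cumulative weight
  `(cum_j - w_j/2)/W` crosses 0.5. Consistent while valid instruments carry
  more than half the weight. SE by parametric bootstrap (default 1000
  resamples of both betas from their normal sampling distributions; the seed
  is mandatory).
* **Penalized weighted median** — each variant's heterogeneity contribution
  `Q_j = w_j (r_j - beta_WM)^2` becomes a one-df chi-square p-value and the
  weight is multiplied by `min(1, 20 p_j)` (penalty constant 20,
  configurable); the median is recomputed. Only clear outliers are
  down-weighted, so homogeneous data reproduce the plain weighted median.

## Synthetic generator

One integer seed drives a single `numpy.random.Generator`; sub-draws occur
in a fixed order, so equal seeds give byte-identical cohorts.

* **Genotypes**: independent biallelic variants, dosage ~ binomial(2, eaf)
  under Hardy-Weinberg equilibrium; unrelated individuals. Default panels:
  73 variants for BMI and 14 for favourable adiposity (the sizes of the
  published instrument sets for those traits); 38-70 for the other traits —
  plausible GWAS-era panel sizes fixed once as defaults. Frequencies are
  uniform(0.05, 0.95) and weights |N(0, 0.03)| + 0.005 SD/allele, since the
  source study does not print its instrument tables.
* **Exposure**: `sqrt(r2) * z + c_x * U + sigma * eps`, standardized; `z` is
  the standardized weighted allele score, `U` a latent standard-normal
  confounder entering both equations (the simplest structure matching a
  single confounding arrow), and `sigma` chosen so the score explains
  exactly `r2` of the exposure variance (default 1.5%, a typical polygenic
  yield for an anthropometric trait; it puts the default first-stage F in
  the hundreds at n = 50 000).
* **Outcome**: Bernoulli from `logit p = b0 + beta_causal * x + c_y * U`,
  with `b0` calibrated by Brent root-finding on the marginal mean of the
  logistic link so the realized prevalence matches the target (defaults
  0.5% for benign disease and 0.1% for cancer, the prevalences of the real
  cohorts). An empty case set raises with advice to enlarge `n`.
* **Records**: cases receive the outcome's ICD-10 code (papillary/follicular
  histology for cancer) at a date within the linkage window around
  enrollment; background codes (breast cancer 2%, hypothyroidism 1%,
  hyperthyroidism 0.3%) exercise the control-history and sensitivity rules.
  Covariates (age 40-69, sex, smoking, alcohol, Townsend, lipids, centres,
  platform, five PCs) are independent draws; the studied trait column is the
  standardized exposure mapped into natural units.
* **Summary statistics**: `beta_exp ~ N(b_j, se)` with
  `se = 1/sqrt(2 p (1-p) n)`, `beta_out ~ N(causal * b_j + alpha_j, se')`;
  `alpha_j` is zero, balanced (mean-zero normal) or directional
  (nonzero-mean normal) pleiotropy.

What the generator does **not** emulate: linkage disequilibrium,
relatedness, population stratification, genotyping error, coding noise in
the registries, missing-data mechanisms, or detection bias in control
selection. Passing calibration here therefore demonstrates correctness of
the estimators under their stated assumptions, not robustness to those
real-data complications.

## Calibration studies (`thyromr.studies`)

Monte-Carlo experiments, fully seed-determined, shared by the test suite and
`scripts/acceptance.py`:

* estimator recovery: 50 datasets x 50 valid instruments, true effect 0.2
  (exposure GWAS n = 300 000, outcome n = 400 000); each estimator's mean
  should sit within Monte-Carlo error of the truth.
* Egger intercept type-I error: 400 balanced-pleiotropy datasets. The study
  panel draws frequencies from (0.3, 0.7) and sets the pleiotropy SD to the
  median outcome SE so the null is near-homoskedastic on the weighted scale
  the test operates on; with strongly unequal SEs the intercept test is
  known to drift off nominal.
* weighted-median robustness: 40% of 50 instruments receive a directional
  offset of 0.02 on the outcome scale (an order of magnitude above the
  outcome SEs), displacing IVW far outside its own CI while the weighted
  median stays within bootstrap error of the truth. Because the median's
  consistency condition is on weight share rather than variant count, the
  invalid set is drawn subject to carrying less than half of the
  inverse-variance ratio weight.
* two-stage coverage: simulated registry cohorts of n = 50 000 at the 0.5%
  benign-prevalence default with causal log-OR 0.3, each run end to end
  through the phenotyping rules, GRS and two-stage estimator; the 95% CI
  should cover the truth at close to nominal rate. The test suite uses 100
  replicates; the acceptance script reports a 50-replicate version of the
  same study.

## Numerical choices and limitations

* Intercept calibration: `brentq` on [-40, 15], tolerance 1e-12.
* Quartile ties: boundary values to the lower quartile; degenerate
  (constant) score distributions raise.
* Logistic fits: Newton, 200 iterations; non-convergence or non-finite SEs
  raise `SeparationError`.
* Bootstrap SEs for the median estimators assume approximate normality of
  the estimator; with very few instruments the bootstrap distribution can be
  skewed.
* The weighted median carries a small finite-sample bias toward zero from
  noise in the ratio denominators; it is visible (but within Monte-Carlo
  tolerance) in the recovery study.
* Two-stage predictor substitution targets the conditional causal log-OR;
  with a rare outcome the noncollapsibility gap to the marginal log-OR is
  negligible, which is why coverage is nominal at the default prevalences.
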