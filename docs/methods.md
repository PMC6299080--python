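# Methods

`mirsig` implements a signature-discovery chain for survival biomarkers of
the kind used in miRNA prognostic studies: a paired differential-expression
screen, a univariate Cox screen, bootstrap-stability LASSO-Cox selection
summarized by the resample model inclusion proportion (RMIP), an
unpenalized refit of the top-ranked features into a risk score
dichotomized at the training-set median, and survival / contingency /
time-dependent-ROC evaluation of the resulting low/high risk groups.
This note records the models, the numerical choices, and what the
synthetic test bed does and does not establish.

## Stage 1 — paired differential expression

For feature *g* with tumour-minus-normal log2 differences
d_g1 … d_gn over n tissue pairs, the classical paired t statistic is
t_g = d̄_g / (s_g/√n) with n−1 degrees of freedom.  The moderated variant
shrinks the per-feature variance toward a common prior under the
hierarchical model

    s_g² | σ_g² ~ σ_g² χ²_{d_g}/d_g,      1/σ_g² ~ χ²_{d0}/(d0 s0²),

giving the posterior variance s̃_g² = (d0 s0² + d_g s_g²)/(d0 + d_g) and a
moderated t with d0 + d_g degrees of freedom.  (d0, s0²) are estimated by
matching the first two moments of log s_g², whose mean and variance have
closed forms in the digamma/trigamma functions; the trigamma inverse is a
Newton iteration.  When the observed spread of log-variances does not
exceed the chi-square sampling noise, d0 = ∞ (fully pooled variance).
The implementation agrees with Bioconductor limma's empirical-Bayes
moderated t to machine precision on shared inputs (tested by running
limma through Rscript on the same difference matrix).

Zero-variance features are reported with p = 1 and flagged, and are
excluded from (d0, s0²) estimation — shrinking an exactly-zero variance
would manufacture an infinite statistic out of a degenerate feature.
Multiplicity is controlled by Benjamini–Hochberg step-up q-values; the
screen's default call is q < 0.05, with a configuration switch to raw
p < 0.05.  Only the paired two-group design is supported; there is no
general design-matrix machinery.

## Stage 2 — scale normalization and univariate Cox screen

Relative qRT-PCR expression (2^−ΔCt, normalized to a reference small RNA)
is mapped to a readable log scale by x′ = log2(10000·x) = log2(10⁴) − ΔCt.
Each candidate feature is then fit in its own single-covariate Cox model
against progression-free survival; features with Wald p below the screen
threshold (default 0.1) form the candidate panel.

## Stage 3 — LASSO-Cox path, cross-validation, bagging

The selection objective is

    minimize_β  −(1/n)·ℓ_Breslow(β) + λ‖β‖₁

with features standardized to unit variance internally and coefficients
reported on the original scale (soft-thresholding is scale-sensitive and
qRT-PCR features live on heterogeneous scales).  The λ grid is log-spaced
with K = 100 points from λmax = max_j |(1/n)·U_j(0)| down to
λmax/100, where U is the partial-likelihood score; at λmax the all-zero
solution satisfies the stationarity conditions exactly.

The solver is proximal Newton with warm starts along the path: at each
outer iteration the exact gradient and Hessian of the Breslow partial
likelihood are computed on a working set (screened by the sequential
strong rule), the ℓ1-penalized quadratic model is minimized by cyclic
coordinate descent with soft-thresholding, and the step is safeguarded by
halving on the penalized objective.  Convergence is declared only when
the exact KKT stationarity residual over *all* features falls below
tolerance (10⁻⁷ by default; violators outside the working set are
admitted and the solve repeats).  On clean fixtures the path agrees with
an independent penalized-Cox implementation (scikit-survival's coxnet, a
port of glmnet) to better than 10⁻⁴ at matched λ, and the smallest-λ
solution agrees with the unpenalized Newton fit to 10⁻³.

Three standard path-termination devices are implemented.  A saturated
fit (relative likelihood gain below 10⁻⁵ of the deviance explained, or
dev-ratio above 0.99) ends the path early; a model denser than one
coefficient per three events (disabled when the panel is already smaller)
ends it; and at small λ the penalized optimum can be genuinely unbounded
under monotone likelihood — frequent on bootstrap resamples, where
duplicated subjects make quasi-separation easy — in which case the path
is truncated at the last solvable grid point inside CV/bagging, and a
direct path call raises, naming the λ index.

Cross-validation uses the Verweij–Van Houwelingen cross-validated
partial likelihood: for held-out fold k,
dev_k = −2·(ℓ_full(β̂₋ₖ) − ℓ₋ₖ(β̂₋ₖ)).  Fold deviances are divided by the
fold's event count and averaged with event-count weights — the
convention of cv.glmnet for Cox families.  This matters: with unweighted
fold SEs the between-fold variation in event totals dominates the
standard error and the 1-SE rule collapses to the empty model even for
very strong predictors.  λ_1SE is the largest λ whose mean deviance is
within one standard error of the minimum.  Each bootstrap resample draws
n subjects with replacement (duplicates entering the partial likelihood
as separate rows), gets a fresh seeded 10-fold deal, and contributes the
nonzero set of the full-resample path at its own λ_1SE.  RMIP_j is the
fraction of B resamples (default 1000) selecting feature j.  Resamples
whose CV degenerates (a training fold without events, or a collapsed
path) are redrawn and counted; more than 10% redraws aborts with a
diagnostic.  Top-k selection (default k = 2) breaks RMIP ties
lexicographically and can also report the largest consecutive RMIP drop
as an elbow suggestion.

## Stage 4 — signature, cutoff, evaluation

The selected features are refit jointly in an unpenalized Cox model; the
risk score is the linear predictor Σ β_j x_j and the cutoff is the exact
median of the training-cohort scores.  A score strictly above the cutoff
is high risk; a score equal to the cutoff (the median-attaining patient
in odd cohorts) is low risk.  Validation cohorts are always dichotomized
at the *training* cutoff.

Survival machinery is implemented directly: Newton–Raphson on the
Breslow (default) or Efron partial likelihood with step-halving,
convergence at max |score| < 10⁻⁸ or likelihood gain < 10⁻¹⁰, Wald CIs at
the fixed 1.96 quantile; rank-deficient covariate sets are rejected
naming the collinear columns, and monotone likelihood is detected by
coefficient escape (|β| > 20, hazard ratios beyond e²⁰ being
epidemiologically meaningless).  Kaplan–Meier curves carry Greenwood
variances; the median CI inverts the pointwise log(−log) interval
(a Brookmeyer–Crowley-type construction).  The log-rank test is the
unweighted G-group statistic with df = G−1.  The response-by-risk
contingency analysis uses Pearson chi-square without continuity
correction, switching to Fisher's exact test for 2×2 tables with any
expected cell below 5; the progressive rate is the PD share of each risk
group, displayed to two decimals with the exact fraction retained.
Interaction models code both factors 0/1 and add the product term; an
empty cell in the 2×2 factor table is rejected naming the product term.

Time-dependent discrimination is the cumulative/dynamic AUC(t) with
inverse-probability-of-censoring weights: cases (events by t) are
weighted by 1/Ĝ(T−), Ĝ being the Kaplan–Meier estimate of the censoring
distribution; the constant control weight cancels.  With no censoring
this reduces exactly to the naive case/control AUC.  CIs are a
200-resample percentile bootstrap over patients.  Post hoc power uses
the Schoenfeld approximation Φ(|ln HR|·√(d·p(1−p)) − z_{1−α/2}) with d
the observed events — the formula is an assumption, since power formulas
are rarely reported alongside such analyses.

## Synthetic test bed

The generator emulates the two-arm layout of the study it mirrors:
21 tumour/normal tissue pairs profiled over 200 features (about 15%
shifted by ±1.5 log2 units, a per-pair random effect inducing within-pair
correlation), and training/internal/external cohorts of 67/40/44 patients
measuring the DE panel on the log2(10⁴·2^−ΔCt) scale with one shared set
of assay-level feature means — sharing is essential, otherwise the
training median cutoff would not transfer across cohorts.  PFS follows a
Weibull proportional-hazards model (shape 1 by default, i.e. exponential,
for closed-form sanity checks) with a 10-month baseline median; censoring
is an independent exponential/administrative mix whose rate is solved by
bisection against the target censoring fraction (default 0.25,
administrative cap at 60 months).  Best response is an ordinal logit on
the true linear predictor with cutpoints at a 4/30/46/20 CR/PR/SD/PD
marginal mix, so higher risk means more progressive disease.

The default planted coefficients (−0.26 and +0.09 per log2 unit on two
DE features) echo the published signature's refit coefficients.  At
n = 67 these are far too weak for reliable selection — the weaker one has
a standardized effect of ~0.07 — so recovery experiments use
`scaled_effects(8.0)`, fixed once by pilot runs, which makes the pair
detectable (standardized effects ≈ −1.7 and +0.6) while preserving sign
and ratio.  Recovery results therefore demonstrate that the machinery
ranks a detectable planted pair first; they say nothing about power at
the true underlying effect sizes, which are not identifiable from the
published summary tables.
The generator also does not attempt microarray probe-level noise, batch
effects, or stromal contamination; passing tests show algorithmic
correctness and calibration, not robustness to those artifacts.
Log-normal expression is a stand-in — no distributional description of
the emulated qRT-PCR values is available.

Ground truth (planted DE sets, coefficients, per-patient linear
predictors) is written beside the fixtures and never read by any pipeline
stage; the test suite deletes the ground-truth file before an end-to-end
CLI run to enforce this at the artifact level.

## Determinism and problem sizes

One global seed expands into per-stage children through
`numpy.random.SeedSequence` spawn keys indexed by a fixed stage list, so
any stage can be re-run in isolation and reproduce the full-run result;
two runs with identical config, inputs and seed produce byte-identical
stage artifacts (asserted via SHA-256 digests in the run manifest).
The test suite and the acceptance script run the bagging experiments at
B = 200 resamples with 20 meta-replicates and the calibration suites at
50 replicates — sizes chosen so the full evidence chain (null
calibration, oracle equivalence, scaled-down recovery) completes in a few
minutes on one core; production runs default to the published B = 1000.

## Known limitations

* Breslow ties only in the penalized path (Efron is available in the
  unpenalized fitter); with qRT-PCR-scale continuous inputs ties arise
  mainly from bootstrap duplication, where Breslow is the convention.
* The published patient-level quantities (median PFS values, Table HRs,
  the 0.022 cutoff, the −0.259/0.092 coefficients, ROC AUCs, the
  88.3%/98.4% power values) are not reproducible without the undeposited
  cohort data and are not claimed; the recomputable targets are the six
  progressive rates implied by the published response-by-risk counts.
  The pooled progressive-rate denominators printed alongside them (12/82
  and 22/69) disagree by one patient with the sums of the per-cohort
  counts (82 vs 83, 69 vs 68); the per-cohort numbers are used and the
  discrepancy is left as documented.
* No multiple-testing correction is applied across the evaluation tables,
  matching the emulated analysis; interpret the per-cohort p-values
  accordingly.
* The time-dependent ROC estimator and evaluation time are choices
  (IPCW, t = 12 months by default); a naive ignore-censoring variant is
  available behind a flag for sensitivity analysis.
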