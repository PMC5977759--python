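# Methods

## The model and the estimation problem

The package predicts survival times directly through the accelerated
failure time (AFT) model `log(y) = Xβ + ε`, with standardised covariates
and i.i.d. errors whose distribution is left unspecified. Two obstacles
shape everything else: p ≫ n (so ordinary least squares overfits) and
right censoring (so `log(y)` is only a lower bound where δ = 0).
Dimension reduction handles the first; a nonparametric residual-imputation
loop handles the second, after which any complete-data fitter applies.

Point predictions are `ŷ = exp(x'β̂ + intercept)` — the conditional
*median* under any error symmetric on the log scale. No residual-mean
("smearing") correction is added: the measures used downstream either
depend only on ranks (c-index, LPS labels) or are reported alongside a
bootstrap interval that absorbs calibration error, and the minimal choice
keeps the prediction a pure function of the linear predictor.

## Fitters

* **PLS / SPLS.** PLS1 latent factors are computed by NIPALS from both X
  and log y; the model is then OLS on the factors, reported back on the
  covariate scale (for orthogonal scores these coincide with the standard
  PLS1 regression coefficients; the test suite cross-checks against
  scikit-learn's PLSRegression). SPLS soft-thresholds the direction
  `z = X'r` at η·max|z| per component, accumulates the active set, and
  refits PLS on the active columns — the structure of the reference SPLS
  algorithm — so η = 0 runs the identical code path as PLS and reproduces
  it exactly. When the response residual becomes numerically orthogonal to
  X the factor count is reduced with a warning rather than failing.
* **Lasso / elastic net.** The objective
  `½‖y − Xb‖² + λ[(1−α)/2‖b‖² + α‖b‖₁]` is solved by scikit-learn
  coordinate descent (its `alpha` parameter equals λ/n for this objective;
  the mapping is exact, and an independent convex-solver oracle verifies it
  in the tests). Non-convergence raises with diagnostics instead of
  returning a silently unconverged fit.
* **Clinical-only null model.** Unpenalised least squares on sex, age
  (standardised, continuous — the dichotomised under-18-months variant is
  not used) and MYCN status, run through the same imputation wrapper.

Tuning is 10-fold cross-validation on mean squared error of log time, with
the fold assignment seeded and shared across the grid so grid points are
compared on identical splits. Exact CV ties break toward the simpler
model (smaller v, larger η, larger λ). The λ grid holds 100 log-spaced
values from λ_max (the smallest λ with an all-zero solution) down four
orders of magnitude, mirroring the shape of the usual path-solver default.

## Censoring imputation

The loop (defaults n_K = 5 outer iterations × n_D = 5 imputed datasets)
estimates the residual distribution by Kaplan-Meier using the original
censoring indicators, then replaces each censored `log(yᵢ)` with
`xᵢ'β̂ + e*`, `e*` drawn from the KM masses restricted to values strictly
above the censoring residual — hence imputed times strictly exceed
observed censored times. Numerical choices:

* **Tail repair.** If the largest residual is censored, the KM leaves
  probability mass beyond its support; that mass is assigned to the
  largest residual as if it were an event, so conditional sampling above
  any floor is always possible.
* **Tie-break at the maximum.** If the censored residual *is* the sample
  maximum, the conditional support above it is empty even after repair;
  the sampler then returns the floor itself and the imputed time is bumped
  by one ULP, keeping the imputed-exceeds-observed guarantee strict.
* **Averaging.** The n_D refit coefficient vectors are averaged
  componentwise on the original covariate scale (PLS/SPLS factors are not
  comparable across refits; covariate-scale coefficients are).
* **Re-tuning.** Hyperparameters may be re-tuned inside every refit
  (`retune="always"`), frozen after the first tuned fit (`"first"`, the
  study default — a cost control that changed results negligibly in
  development), or fixed (`"never"`).

## Performance measures

IPCW-RMSE weights each uncensored squared error by the inverse of the
censoring-distribution KM evaluated as a left limit at the observed time
(the censoring KM swaps δ for 1−δ); weights are capped at 10⁸ with a
warning where that left limit underflows, keeping the estimator finite and
the event visible. Harrell's c-index uses strict inequalities — tied
predictions score zero, not half. The logrank statistic uses the
hypergeometric variance with single-subject risk sets contributing zero,
referred to χ²(1); no tie correction beyond that variance and no
stratified or weighted variants. Confidence intervals are percentile
bootstrap over patients resampled jointly (B = 1000, 2.5th/97.5th
percentiles); resamples on which a measure is undefined are redrawn and an
error is raised if more than half fail.

The percentile bootstrap undercovers for heavy-tailed error
distributions: with log-normal survival times and strong covariate
effects, nominal 95% intervals for the IPCW-RMSE can cover far less. The
coverage test therefore uses a bounded-error world where the percentile
method is adequate; intervals on long-tailed real data should be read as
approximate.

## Ensemble

Bagging (B = 20) with out-of-bag evaluation of K = 3 measures — IPCW-RMSE
(lower better) and the LPS2/LPS5 logrank statistics (higher better:
stronger separation). The published description cites a weighted
rank-aggregation procedure without printing it; mean-rank (Borda)
aggregation with deterministic tie-breaks (first-listed measure, then
candidate order) is used instead, validated against an exhaustive
footrule-minimising oracle at small M, and the aggregator is a pluggable
function. A candidate that fails on a bag, or a measure undefined on an
OOB sample (e.g. a degenerate LPS split), receives the worst rank for that
iteration; an empty OOB set triggers a logged redraw. Because fitting
needs complete data, censored training times are imputed once before
bagging with the predictions of the best individual model (lowest CV
error by default; a config handle). OOB logrank measures are computed on
the clinically high-risk members of the OOB sample when flags exist.

## Synthetic cohorts

The generator states the world the tests live in: 249/249 train/test
(n = 498), p = 2000 standardised covariates in three equal annotation
blocks ("gene", "transcript", "intron") with the 20-coefficient true
support spread round-robin across blocks so every feature-set choice
carries signal; errors normal with sd 1 by default (normal gives a
log-normal AFT with closed forms for oracle checks; logistic and
minimum-extreme-value alternatives are provided); baseline median survival
exp(1.6) ≈ 5 years; 36% of patients flagged clinically high-risk (the
fraction implied by the published cohort's test-set table). Censoring
times are exponential with the rate solved by bisection so the expected
censored fraction — `mean(1 − exp(−rate·Tᵢ))` given the realised true
times — hits the target; the cohort's real censoring rate is not
published, so it is an explicit parameter defaulting to 0.40. The
high-risk flag marks the patients with the smallest expected survival and
then flips 10% of labels, emulating a clinical stratum enriched for (but
not identical to) short survivors. Clinical covariates (sex, age, MYCN)
are independent noise: the null model's test c-index should be ~0.5, and
the tests assert exactly that.

What the generator does *not* emulate: correlated read-count noise,
annotation structure shared between transcripts and their introns,
library-size artefacts, or any real clinical signal. A green end-to-end
test establishes that the machinery is correct and leakage-free under the
stated model — not that the biological conclusions transfer.

The raw-count generator exists purely so the zero-count filter and intron
normalisation have integer inputs to act on (Poisson counts with
Dirichlet rates and controllable structural zeros).

## Degenerate inputs and other conventions

Empty survival data, single-group logrank, all-censored IPCW input and
c-index without comparable pairs raise informative errors; a covariate
with no variation gets Cox coefficient 0 and p-value 1. The univariate
Cox Newton solver caps |β| at 15: a perfectly concordant covariate has a
monotone partial likelihood with no finite maximiser, and the capped Wald
p-value matches where reference implementations plateau. Features whose
fit does not converge are recorded with p-value 1 and a flag, never an
abort. Zero-variance features are dropped before standardisation with a
warning. The >80%-zero filter is strict ("over"): exactly 80% zeros is
retained. The LPS boundary is inclusive (ŷ = t is LPS). All times are
converted to years at ingestion; cutoffs (2, 5) are in years.

Every stochastic stage derives its seed from the master seed through a
documented counter scheme (`pipeline.derive_seed`), making full study runs
byte-reproducible; the test suite asserts byte-identical report bundles
across repeated runs.

## Known limitations

* Semiparametric AFT estimation (Buckley-James, rank-based) and boosting
  are out of scope by design.
* The TI feature set concatenates the independently ranked top-2000
  transcript and intron sets rather than re-ranking jointly.
* Rubin's-rules variance combination is deliberately absent: the
  imputation loop averages point estimates only, so between-imputation
  variability is not propagated into standard errors.
* Gene/transcript normalisation is accepted as upstream input (only the
  intron formula is computed in-package, being the one printed in closed
  form).
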