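# Methods

This note documents the statistical models, algorithms, default settings
and design choices behind `otashort`, in the order the pipeline applies
them.

## Measurement model

Responses are ordered categories `1..m` (internally `0..m-1`). The
generalized partial credit model (GPCM) gives item *j* with discrimination
`a_j` and step difficulties `b_j1 < ... < b_j,m-1` the category
probabilities

    P(X_j = c | theta) = exp( sum_{v<=c} a_j (theta - b_jv) )
                         / sum_k exp( sum_{v<=k} a_j (theta - b_jv) ),

with the cumulative term for category 0 defined as zero. `b_jv` is the
trait level at which categories `v-1` and `v` are equally likely; `a_j`
controls how sharply the response distribution moves with the trait.
Identification fixes the latent trait to N(0, 1) in the reference
population, so each item carries one discrimination plus `m-1`
difficulties.

**Estimation.** Marginal maximum likelihood by EM. The E-step places
posterior weight on a fixed quadrature grid — 61 equally spaced nodes on
(-6, 6) with normalized normal-density weights — chosen over adaptive
schemes for exact reproducibility. The M-step maximizes each item's
expected complete-data log-likelihood with L-BFGS-B using the analytic
gradient (a generalized EM step, so the marginal log-likelihood is
monotone; the iteration history is retained and asserted in tests).
Convergence: largest absolute parameter change below 1e-4, at most 500
iterations; non-convergence is flagged, not raised. Starting values:
`a = 1`, difficulties from normal quantiles of the cumulative category
proportions. Discriminations are bounded below at 1e-3; an estimate
collapsing toward zero triggers a warning. Missing responses are skipped
person-wise in the likelihood (ignorable missingness); summed scores use
complete cases only.

**Scoring.** Factor scores are expected a posteriori (EAP): the posterior
mean of the trait on the same grid. Persons with no observed responses
get NaN.

**Information.** Item information is the Fisher information
`a^2 Var(C | theta)` with `C` the 0-based category score; test information
is the exact sum over items. Integrated information uses Simpson's rule on
2001 points. "The entire ability range" is operationalized as (-10, 10):
with that convention per-item integrals are additive against full-range
test totals (on the published 21-item calibration the per-item column sums
to 59.34 against a printed full-scale total of 59.36, i.e. within
two-decimal rounding).

## Unidimensionality screen

Polychoric correlations are estimated pairwise by the two-step method:
thresholds from marginal normal quantiles, then a 1-D maximum-likelihood
search for the correlation of the underlying bivariate normal. The
bivariate normal CDF is evaluated through Owen's T function and
cross-checked in tests against an independent implementation. Empty
categories collapse automatically; a pair left with a constant variable is
reported by name.

Minimum-residual (ULS) factoring minimizes the sum of squared off-diagonal
residuals of `R - LL'` over the uniquenesses; Heywood cases are clamped at
communality 1 with a warning, and each factor's sign is fixed so its
loading sum is non-negative. The unidimensionality gate passes when the
first-to-second eigenvalue ratio of the raw polychoric matrix exceeds 3
and the first factor explains at least 20% of total variance (the
denominator is the item count, i.e. unit variances; both thresholds are
configurable — the 20-40% band in the methodological literature is
operationalized as a single minimum). Items with negative first-factor
loadings run against the intended orientation and are removed before any
IRT calibration, mirroring standard practice for miskeyed items. KMO and
Bartlett's sphericity test are reported for sampling adequacy. Whether
raw or reduced (communality-adjusted) eigenvalues should feed the ratio is
genuinely open in the literature; the raw convention was chosen as the
most common.

## DIF screen (iterative Wald)

Gender DIF uses a two-group joint GPCM: constrained items share parameters
across groups, free items are group-specific, the reference prior is fixed
N(0, 1), and the focal group's mean and variance are estimated (freeing
both is the default so that true impact is absorbed by the prior rather
than misread as item DIF). Parameter covariance is the inverse observed
information, obtained by central finite differences (step 1e-4) of the
analytic marginal-likelihood gradient. The Wald statistic for item *j* is
`d' V^-1 d` with `d` the focal-minus-reference parameter vector and `V`
its covariance block; df equals the item's parameter count (`m` for an
m-category item).

Stage 1 (Wald-2) literally fits one constrained model per studied item
with all other items as anchors and provisionally flags items at
`p < 0.05`. The anchors are then the five non-flagged items with the
largest discriminations from the fully constrained fit (MaxA5; count
configurable, ties to the lower index). Stage 2 (Wald-1) fixes the
anchors, frees all other items in a single joint fit, and removes items at
`p < 0.05`. One pass of the two stages is the default (an optional
loop-until-stable flag exists); no multiplicity correction is applied by
default (a Benjamini-Hochberg option exists but defaults off, matching the
raw-alpha convention of the screening literature). Calibration on null
simulations (8 four-category items, 500 per group) gives a rejection rate
of about 0.03-0.06 at nominal 0.05 and approximately uniform p-values (a
mild finite-sample conservatism, mean null p around 0.52-0.55, is visible
at this group size); power against a 0.75 threshold shift at that size is
essentially 1.

## Optimal test assembly

For a fixed length L the objective is the summed item information at the
anchor trait points (-3, -1, 0, 1, 3) — evaluated exactly at the points,
not integrated between them. The 0/1 selection problem is solved by
branch-and-bound integer programming (HiGHS via `scipy.optimize.milp`);
because a cardinality-constrained modular objective is also solved exactly
by taking the top-L items, that closed form is computed on every solve and
the two must agree, which doubles as a continuous correctness check. Ties
resolve to the lexicographically smallest index set.

The optimal short form is the smallest L (searched ascending over
4..J-1 by default) whose information-optimal subset keeps at least 95% of
the DIF-free scale's Cronbach's alpha, and correlates at least 0.9 with
the DIF-free scale's summed score and EAP score, all on the training
sample. During the search the subset EAP uses the full model restricted to
the subset (no refit) for speed and determinism; the final reported short
form is refitted. The whole per-length audit trail (selected set,
objective, constraint values, pass flags) is returned and logged.

## Evaluation

* Cronbach's alpha on complete cases with the Feldt F-based 95% interval
  (via `pingouin`); a population version from a covariance matrix is also
  exposed and equals the Spearman-Brown form on parallel items.
* Pearson correlations with Fisher-z intervals
  (`scipy.stats.pearsonr.confidence_interval`).
* Convergent validity: plain Pearson correlations of the short-form summed
  score with each covariate, no attenuation correction.
* One-factor CFA treats the Likert items as continuous and fits by maximum
  likelihood to the Pearson covariance matrix (an ordinal WLSMV estimator
  would be a defensible alternative and is out of scope). Fit indices:
  `chi2 = (n-1) F_ML`; RMSEA with 90% interval from noncentral chi-square
  inversion; SRMR as the root mean square of standardized residuals
  including the diagonal (the dialect is stated so results are auditable);
  CFI against the independence baseline, clamped so RMSEA = 0 and CFI = 1
  whenever `chi2 <= df`. Adequacy cutoffs: RMSEA and SRMR at most 0.08,
  CFI at least 0.90.
* Information retention: 100 x subset / full integrated information,
  reported to one decimal, over the entire range and over (-3, 3). The
  subset's information comes from a GPCM refitted on the subset
  (final-report convention) while the additivity checks use the restricted
  full model; both paths are exposed because published subset totals are
  consistent with a refit rather than with row sums of the full-model
  table.

## Synthetic data generator

The generator emulates community questionnaire samples: by default 569
persons (training) and 500 (test), 21 six-category items, standard-normal
trait, discriminations uniform on (0.12, 1.7) — the span of the published
full-scale calibration — and covariates jointly normal with the trait at
+0.27 and -0.11, rescaled to NEO-like integer sums (mean 36, SD 7, range
12-60). Step difficulties are sorted normal draws (SD 0.7, a value typical
of well-behaved Likert items whose categories are all used) around an
item location drawn N(0, 1), which guarantees ordered categories. Group
membership is Bernoulli with focal fraction 0.37 (the approximate male
share of the emulated samples); DIF is injected as additive shifts on the
focal group's parameters only, with ordering violations rejected.
Reversed items are recorded as `m + 1 - x` and flagged (recoded at
ingest); *miskeyed* items are recorded reversed but left unflagged, which
is how a negative-loading item survives reverse-coding and must be caught
by the EFA screen. True trait values and generating parameters are kept
as clearly marked simulation truth (sidecar JSON on disk).

What the generator does not emulate: survey-mode effects, nonresponse,
demographic structure, local dependence between items, or multidimensional
traits. Passing tests therefore demonstrate correct recovery of the
stated generating process, not robustness to those real-data features.

## Problem sizes used in checks

Stochastic checks are sized for a desk-class single core: parameter
recovery uses n = 1000 with the full 21-item design; Wald calibration uses
8 four-category items at 500 per group with 200 null replicates x 3
studied items (the acceptance script runs a further reduced 60 x 3) and 40
power replicates at a 0.75 threshold shift; recovery-consistency uses 8
items over n in {250, 500, 1000, 4000} with 10 replicates; the planted
end-to-end scenario uses the default 569 + 500 two-sample design. Seeds
are fixed in the test suite and derived from a single `--seed` in the
acceptance script.

## Known limitations

* Threshold estimates of very weakly discriminating items (a near 0.1)
  are intrinsically noisy at n = 1000; their RMSE is dominated by sampling
  variance (it halves with each quadrupling of n) and can exceed 0.25
  for unlucky realizations. Step difficulties located where the trait
  density is negligible (|b| > 3, i.e. quasi-empty categories) are barely
  identified and can drift far from truth, as maximum likelihood does
  without category collapsing; global RMSE(b) summaries are dominated by
  such parameters when the generator draws an extreme item location.
* The Wald tests rely on asymptotic chi-square calibration; at a few
  hundred persons per group small finite-sample deviations (observed as
  mild conservatism) remain.
* The polychoric step assumes an underlying bivariate normal; gross
  violations (e.g. strong skew plus floor effects) bias the screen.
* Single-factor CFA on Pearson covariances understates fit sensitivity
  for strongly categorical data relative to ordinal estimators.
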