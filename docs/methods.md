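# Methods

## Estimand and model

For participant *i* at annual wave *t*, let `A_it` be the alcohol category
(abstainer, occasional, moderate, above-guideline), `Y_i,t+1` the indicator
of probable depression (CES-D-10 >= 8) one wave later, `L_it` the
time-varying confounder, `V_i` baseline covariates, and `C_it` the
indicator of remaining under follow-up. The target is the population-average
(marginal) odds ratio of depression under sustained exposure to each
category versus sustained moderate consumption.

The marginal structural model is a logistic model in current category only,

    logit P(Y_{t+1}(a) = 1) = b0 + b_abst 1[a=abstainer]
                                 + b_occ 1[a=occasional] + b_above 1[a=above],

fitted on observed (exposure wave, outcome wave) pairs with a one-wave lag
by weighted estimating equations: binomial family, logit link, participant
clusters, independence working correlation, observation weights
`w_it = IPTW_it x IPCW_it`, and a robust sandwich covariance (statsmodels
GEE). With unit weights, one wave and independence correlation the fit is
exactly ordinary logistic regression (verified to 1e-6 in the tests).
Wald tests and 95% CIs are formed on the log-OR scale; a joint 3-df Wald
test across categories summarises each analysis block.

Identification assumes exchangeability given (L̄, V, Ā-history), positivity
and consistency, plus censoring-at-random given the modeled retention
covariates. E-values quantify robustness to violations of the first
assumption.

### Weights

- **Treatment (IPTW).** A multinomial-logit propensity model of `A_t` on
  (L_t, V, previous category), fitted separately for the baseline wave
  (which has no previous category) and pooled over follow-up waves. The
  per-row denominator is the probability of the category actually reported.
  A one-vs-rest mode (four binary logistic fits, renormalized, with the
  pre-normalization sum logged) exists for comparison with analyses that
  describe binary logistic propensity models; the multinomial default
  guarantees proper probability vectors.
- **Stabilization.** The per-protocol default multiplies by the empirical
  transition numerator P̂(A_t | A_{t-1}, wave) and cumulates the ratio over
  waves (Robins-style stabilized weights for treatment regimes). The
  transition numerator cancels the persistence part of the denominator, so
  the cumulated products stay short-tailed. A marginal per-wave numerator
  and fully unstabilized weights are available; unstabilized cumulative
  products over six highly persistent waves reach ~4x10^5 and are unusable,
  which is why they are not the analysis default.
- **Censoring (IPCW).** Pooled logistic retention model over waves >= 1
  (wave indicators included) on covariates measured at the last observed
  wave plus indicators of the last observed category, reciprocal,
  cumulated. Dropout in this setting genuinely depends on current health
  and on exposure (occasional drinkers retain worst), so the default uses
  time-updated covariates; a baseline-covariates-only mode is provided for
  comparability with descriptions that specify baseline predictors.
- **Trimming.** `combine_and_trim` supports percentile exclusion (the
  conventional 2nd/98th rule; nearest-rank cuts computed once on the
  analysis rows) and winsorization ("cap"). The analysis entry points
  default to *no* trimming: replicated calibration (200 cohorts, n = 2000,
  4 waves) shows that with transition-stabilized weights the untrimmed
  estimator is unbiased (per-category mean log-OR error < 0.01, CI coverage
  0.96-0.97), whereas excluding or capping even the top 0.5% of weights
  biases the above-guideline contrast by -0.03 to -0.12 log-OR. The
  mechanism is that the upper weight tail is concentrated on female
  above-guideline drinkers — exactly the observations that carry the
  sex-confounding correction for that category — so tail trimming
  selectively removes the correction. Trimming remains available for
  fidelity comparisons and is exercised by the tests.

### Framings and scenarios

- **Per-protocol** (primary): annually re-classified exposure, cumulative
  IPTW x IPCW.
- **Intention-to-treat**: the baseline category is carried forward; the
  treatment weight is the baseline propensity weight (a point-treatment
  weight), censoring weights as above. With category switching over
  follow-up, ITT attenuates toward the null relative to PP.
- **Sensitivity scenarios** re-estimate all weights on their own subset:
  (1) excluding former drinkers, (2) excluding participants with baseline
  CES-D-10 >= 8, (3) outcome cutoff 10. (4) E-values accompany every
  estimate: E = R + sqrt(R(R-1)) with R the OR (inverted if < 1), treating
  the OR as a risk ratio because per-wave outcome prevalence is ~9%; a
  sqrt(OR) common-outcome conversion is available. Published robustness
  tables regenerate from their printed 2-dp odds ratios in 23 of 24 cells
  to within 0.01; the one genuine outlier (adjusted above-guideline OR 1.15
  printed next to E 1.51, formula 1.57) is reported at the formula value
  and flagged, not forced.

## Synthetic cohort

The generator emulates the structural features the estimator relies on, for
a cohort of ~16,500 community-dwelling adults aged 70+ observed over six
annual waves (scaled-down sizes are used where noted):

- **Baseline covariates**: age ~ N(75.1, 4.6^2); 53.9% female; a standard
  normal health burden L_0.
- **Exposure**: multinomial logit in (L, sex) whose intercepts are
  calibrated by Gauss-Hermite quadrature and root solving so the marginal
  baseline shares equal 26.9/21.2/32.6/19.3%; wave-to-wave persistence
  enters as a utility bonus for repeating the previous category, sized from
  the target repeat probabilities (0.90 abstainer, 0.50 occasional — the
  two reported adherence anchors — and 0.75/0.65 for moderate/above, chosen
  once as realistic). Sicker participants abstain more (utility +0.6 per SD
  of L) and exceed guidelines less (-0.4); women are less likely to drink
  above guidelines (-0.6).
- **Confounder dynamics**: L_t = 0.7 L_{t-1} + g[A_{t-1}] + N(0, 0.5^2).
  The treatment -> confounder feedback g is implemented and configurable
  but defaults to zero: with nonzero feedback the sustained-exposure oracle
  contrast and the current-category marginal summary differ by a small
  amount (~0.016 log-OR at g = 0.02), i.e. the single-coefficient MSM is no
  longer exactly saturated in the features that matter. Defaulting g to
  zero makes the estimand of the fitted model coincide exactly with the
  oracle, which keeps validation interpretable; tests that need feedback
  switch it on explicitly.
- **Outcome**: CES-D-10 totals are drawn from a latent logistic
  proportional-odds scale with threshold spacing 0.45 around the 8 cutoff,
  so that *every* cutoff is exactly a logistic model in the same linear
  predictor: intercept (first-order calibrated to ~9% per-wave prevalence),
  conditional category log-ORs (log 1.20, log 1.13, 0, log 1.18 — a
  J-shape), 0.5 per SD of L, 0.15 per SD of age, 0.25 for women, and an
  optional female x category interaction used by the power calculator.
  Partially missing item sets are never imputed; a missing scale at an
  observed wave is a censored outcome wave.
- **Censoring**: monotone dropout, logistic in the last observed (L, A)
  with base rate 6%/wave and category shifts (+0.5 occasional, +0.3 above,
  +0.2 abstainer), giving 68-92% retention over six waves, informative in
  both health and exposure.
- **Former drinkers**: 25% of baseline abstainers are flagged, enabling the
  sick-quitter sensitivity scenario.

Because the odds ratio is noncollapsible, the true *marginal* ORs implied
by the conditional coefficients are computed by counterfactual Monte Carlo
(`true_marginal_effects`): one arm per category with every participant held
at that category at every wave and censoring switched off, common random
numbers across arms, risks pooled over post-baseline waves, Monte-Carlo
standard errors from participant-level variation (conservative under the
coupling). At the default settings the truth is OR 1.19-1.20 (abstainer),
1.13 (occasional), 1.17-1.18 (above-guideline) versus moderate; the
default n_mc = 200,000 yields MC SE < 0.01 per log-OR, and quadrupling
n_mc halves the SE.

What the generator does **not** emulate: the real covariate joint
distribution (comorbidities, polypharmacy, education and the rest enter
real analyses as generic covariates; the simulator carries one scalar
health confounder plus age and sex), non-monotone wave skipping (an
intermittent-administration mask is out of scope; dropout is monotone),
item-level CES-D responses, and any treatment-effect heterogeneity beyond
the configurable sex interaction. Passing tests therefore demonstrate that
the estimator recovers known truths under the assumed data-generating
structure — not that the published estimates are correct for the real
cohort, whose data are access-controlled.

## Numerical choices and edge cases

- Category classification is a total partition; records with drinks but no
  drinking days (or heavy episodes with zero consumption) are rejected as
  inconsistent rather than guessed. A weekly total exactly at the
  sex-specific limit counts as moderate, keeping moderate-as-reference.
- CES-D-10 reversal positions default to items 5 and 8 of the standard
  short form and are configurable.
- Exclusion rules apply in order against the then-current participant set;
  per-rule counts are order-dependent, the final set is not (the rules are
  set-intersective).
- Percentile cuts use nearest-rank order statistics; a degenerate all-equal
  weight distribution excludes nothing; trimming at (0, 100) is the
  identity.
- SMDs pool variances as sqrt((v1+v2)/2), use p(1-p) for binary covariates,
  define 0/0 as 0 when group means agree, and error otherwise.
- Constant covariate columns are dropped from propensity designs (absorbed
  by the intercept); separation or non-convergence raises with the
  offending covariates named.
- Multinomial fits use Newton iterations (statsmodels MNLogit); censoring
  and one-vs-rest fits use IRLS GLMs. Reported probabilities are validated
  to lie in (0, 1] and to sum to one within 1e-10 per row.
- Problem sizes in the test suite: the replicated calibration uses 200
  cohorts of n = 2000 over 4 waves against an oracle with n_mc = 400,000;
  balance is checked at n = 10,000; structural fidelity at the full
  n = 16,563 over 6 waves. The suite runs in a few minutes on one CPU.

## Known limitations

- The per-protocol weighted estimator targets the sustained-exposure
  contrast exactly only when outcome risk depends on exposure history
  through the current category (true in the default generator; with strong
  treatment-confounder feedback a history-saturated MSM would be needed).
- IPCW assumes censoring at random given the modeled covariates; the
  baseline-only censoring mode is knowingly misspecified when dropout
  depends on time-varying health, and is provided for fidelity comparisons.
- No doubly-robust or machine-learning estimators, no continuous-dose
  response, no E-values for scales other than the (rare-outcome) odds
  ratio.
- The power calculator is a generic simulation tool; it makes no claim to
  reproduce any published post hoc power statement, whose assumptions
  (alpha, correlation structure, variance) are not stated.
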