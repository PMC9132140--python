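# Methods

## The measurement model

Speech intelligibility is measured as the proportion of a child's words that
naive adult listeners recover by orthographic transcription against known
targets. Tokens are lowercased, stripped of punctuation, and credited by
multiset intersection with the target (order-free; a word said twice is
credited at most twice). A child's score at an utterance length is the
summed words-correct over summed target words per listener, averaged over
the two listeners. No homophone or spelling normalization is applied by
default; `score_utterance` accepts a pluggable normalizer for studies that
credit homophones.

Listener agreement uses the one-way random-effects, average-measures ICC:
each child is heard by a different listener pair, so rater is nested in
child and the one-way ANOVA decomposition is the only identifiable one.
ICC = (MSB − MSW)/MSB with the exact F interval on (n−1, n(k−1)) degrees of
freedom. `pingouin`'s ICC(1,k) is used in the test suite as an independent
cross-check, never as the implementation.

## Imputation-weighting of the multiword composite

The sentence-elicitation protocol stops at the first length a child cannot
complete, so missingness at long lengths is structural, not informative
about the missing score beyond what shorter lengths and the ceiling say.
For each target length L ∈ {3..7} an OLS regression predicts the length-L
score from the scores at all shorter lengths plus the ceiling
(`longest_length`), trained only on children who produced length L. Missing
lengths are filled ascending, each imputed value carried forward as a
predictor for the next. Regressions run on the logit scale so
back-transformed predictions stay in (0, 1); only boundary scores are
nudged inward (ε = 0.005) — interior scores are transformed exactly, which
keeps deterministic logit-linear relations exactly extendable (a test
oracle). Children whose ceiling is below two words have no multiword anchor
and are flagged rather than imputed. Single imputation only; no
between-imputation variance is propagated (a known limitation).

The composite is the weighted mean of lengths 2–7 with weights proportional
to the probability of producing each length at the child's age, renormalized
to sum to one. The default weight model is one logistic regression of
{longest ≥ L} on age per length, nested across lengths by isotonization;
`method="empirical"` (6-month band proportions) and `method="ordinal"`
(proportional odds) are alternatives. Model-smoothed weights were chosen
over empirical proportions because they are defined at every age and stable
in sparse bands.

## Beta location-scale growth model

Scores are modelled as Beta(a(t), b(t)) with a = μ(1−σ²)/σ²,
b = (1−μ)(1−σ²)/σ², so E[y] = μ and Var[y] = σ²μ(1−μ). This is the
location/scale convention in which σ ∈ (0, 1) (σ² is the variance as a
fraction of the Bernoulli maximum μ(1−μ)); it is not the 1/(1+φ) precision
convention, and the two coincide only for constant scale (used as a
cross-check against `statsmodels`' beta regression). Both logit(μ) and
logit(σ) are natural cubic spline functions of age — 3 df for the location
and 2 df for the scale by default — with boundary knots at the observed age
extremes and interior knots at equally spaced age quantiles. The natural
(linear-beyond-boundary) constraint keeps percentile curves tame at the
edges of the 30–119-month window.

Fitting maximizes the likelihood with an analytic gradient (BFGS warm-started
at the logits of the sample mean and moment-based σ, followed by damped
Newton polishing; one deterministic restart from a perturbed start on
failure). `converged_` is true only when the mean-log-likelihood gradient
norm is below 1e−6. Both the inverse observed information (`vcov_model_`)
and the observation-level sandwich A⁻¹BA⁻¹ (`vcov_robust_`) are reported;
the sandwich is the covariance the bootstrap samples from. Exact 0/1 scores
are inadmissible under the beta support and must be squeezed once at
pipeline entry with y′ = (y(n−1) + 0.5)/n.

Diagnostics: quantile residuals Φ⁻¹(F_beta(yᵢ; μᵢ, σᵢ)), standard normal
under correct specification.

## Percentile curves and their summaries

Percentile curves are q_p(t) = F⁻¹(p; μ(t), σ(t)) via the regularized
incomplete beta inverse. Threshold ages are first up-crossings on a 1-month
grid refined by linear interpolation; a curve already above the threshold
at 30 months is censored "≤ 30", one never reaching it by 120 is "≥ 120".
Steepest growth uses central differences on a 0.1-month grid (grids coarser
than 0.5 months are rejected), reports percentage points per month, breaks
flat ties toward the earliest age, and flags peaks pinned to a grid end as
truncated — the peak for the median curve genuinely can precede the
youngest sampled age.

Confidence intervals are parametric-bootstrap: draw coefficient vectors from
MVN(θ̂, vcov_robust) (eigendecomposition square root; eigenvalues in
(−1e−10, 0) are treated as rounding and clipped, anything lower aborts),
recompute the functional per draw, and take empirical .025/.975 quantiles
under numpy's linear-interpolation order-statistic rule (recorded in output
metadata). Threshold-age draws censored at a grid bound contribute the
bound value; a CI endpoint equal to a bound is rendered "≤ 30"/"≥ 120".
The production default is 10,000 draws; the test suite and the acceptance
script use 200–2,000, which changes CI endpoints by well under a month.
The same draws are reused across functionals for a given fit.

## What the synthetic cohort emulates

No child-level data are distributed with the package, so a seeded generator
reproduces the statistical structure the analysis assumes:

- **Median growth**: a four-parameter logistic in age on the proportion
  scale — floor 0.25, ceiling 0.99, midpoint 40 months, rate 0.09/month for
  multiword speech. Single words carry a −0.35-logit offset from 48 months
  on, the constant few-point multiword advantage of older children.
- **Funnel**: between-child heterogeneity is Gaussian on the logit scale
  with SD declining logistically from 0.85 to 0.50 logits (midpoint 60
  months, rate 0.08/month), scaled by `ability_sd` (default 1). The
  observed-SD funnel this produces (≈18 points at 30–35 months, ≈1 point at
  96–119) matches the regime reported for real cohorts of this design.
- **Ceiling / selection**: per-length completion probabilities are logistic
  in age and latent ability (intercepts 3.3, 2.2, 1.1, 0.0, −1.3, −2.6 at
  36 months for lengths 2–7; slopes 0.13/month and 1.0/SD), applied
  sequentially with stop-at-first-failure. Ability in the completion model
  induces the selection effect: young children who reach long utterances
  are the more intelligible ones. The intercept ladder was calibrated so
  the youngest band's ceiling distribution peaks at three words and
  model-smoothed weights for lengths 6–7 are practically zero at 30 months.
- **Listener noise**: binomial over the words at each length (38 single
  words, 10·L sentence words), independent across the two listeners — the
  simplest mechanism consistent with ICCs in the .95–.98 range. No
  per-utterance correlation, no listener covariates.

`true_quantile_curve` is the generator's ground-truth oracle: the score
given ability is an averaged-binomial proportion treated as normal with the
matching mean and variance, mixed over the Gaussian ability by Gauss–Hermite
quadrature (61 nodes) and inverted by Brent's method. Its accuracy is
verified against the empirical quantiles of 10⁶ simulated children (within
0.005).

What the generator does **not** emulate: phoneme-level errors, utterance-level
listener correlation, longitudinal trajectories (the design is
cross-sectional), covariate effects other than age, and real-world listening
conditions. Passing recovery tests therefore shows the estimator chain is
correct under the stated generative assumptions, not that any particular
real cohort satisfies them.

## Experiment sizes

Parameter-recovery runs use 20 cohorts of 538 children with the ceiling
disabled (the multiword law is smooth there; the single-word offset is a
deliberate step and not a spline-recovery target). The coverage experiment
uses 100 replicates of 300 children with 500 draws each. These sizes give
Monte-Carlo error comfortably inside the asserted bands while keeping the
default test run fast on one core.

## Known limitations

- The σ-convention beta model cannot represent bimodal score distributions;
  zero/one-inflation is handled by squeezing, not by a mixture.
- Single imputation understates composite uncertainty for children far from
  their ceiling.
- The robust covariance is observation-level; any clustering (e.g. shared
  listeners) would require a clustered sandwich.
- Weights are renormalized probabilities; with all completion probabilities
  tiny (out-of-range ages) the weights are undefined and an error is raised.
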