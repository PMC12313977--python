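# Methods

`ddmediate` implements an analysis chain that links an emotion-regulation
strategy score to temporal impulsivity: (1) per-subject estimation of a
hyperbolic delay-discounting rate from binary intertemporal choices,
(2) questionnaire scoring with internal-consistency reliability,
(3) covariate-adjusted rank correlation, and (4) covariate-adjusted linear
mediation through a scalar brain-volume mediator with case-bootstrap
inference. Because raw participant data of this kind are private, the
package ships a seeded synthetic-cohort generator with the same statistical
structure, so every stage is testable end to end and parameter recovery can
be quantified against ground truth.

## Choice model and estimation

Each trial offers a fixed immediate reward (₩10,000) against a larger
delayed reward (₩11,000–48,000 at 2–180 days). The subjective value of a
delayed amount *A* at delay *D* days is the hyperbolic discount

    SV = A / (1 + kD),

with *k* (per day) the subject's discount rate. Choices are stochastic in
the subjective-value difference through a logistic rule

    P(delayed) = 1 / (1 + exp(−β(SV_delayed − SV_immediate))),

where β is an inverse temperature; because SV differences are on a KRW
scale (hundreds to tens of thousands), plausible β values are small
(≈10⁻⁴–10⁻³). (k, β) are estimated jointly per subject by maximising the
Bernoulli likelihood of the 120 binary choices.

Numerical choices:

* Optimisation is over (log₁₀k, log₁₀β) with bounds log₁₀k ∈ [−5, 0],
  log₁₀β ∈ [−6, 0]; positivity holds by construction and the surface is
  better conditioned in log space.
* A deterministic 7×7 log-spaced grid of starting points is scored; the
  best 3 are refined with bounded L-BFGS-B. No randomness enters fitting,
  so refits are bit-identical.
* Choice probabilities are floored at ε = 10⁻¹² inside logarithms
  (configurable), so degenerate responders have finite likelihood.
* Degenerate choosers make the likelihood flat on a plateau touching one
  or more bounds (an all-immediate chooser is consistent with any
  sufficiently large k; a fully model-consistent responder with any
  sufficiently large β). After optimisation, each coordinate is pushed to
  its bound when that costs no likelihood, and a `boundary_flag`
  (`k_low`/`k_high`/`beta_low`/`beta_high`) records the degeneracy.
* Analyses downstream use log₁₀k, which normalises the right-skewed k
  distribution.

**Identifiability exclusion.** The 120-trial menu can only discriminate
discount rates within a range set by its amount/delay grid (roughly
log₁₀k ∈ [−3.2, −0.04] for the default grid endpoints). Subjects whose
fitted k is pinned at a k search bound carry no information about their
rate, and a handful of such fits (pinned at log₁₀k = −5) would dominate
cohort SDs and regression slopes as gross outliers. The pipeline therefore
excludes `k_low`/`k_high`-flagged subjects from descriptives, correlation,
and mediation (typically 2–5% of a default cohort); the full fit table,
including flags, is always written. A `beta_high` flag alone does not
exclude a subject — a perfectly consistent responder has a well-identified
k.

## Trial menu

The exact 120 amount×delay pairs of the task are treated as data: the
default menu is a factorial grid of 12 evenly spaced amounts over
₩11,000–48,000 by 10 approximately log-spaced integer delays over 2–180
days (log spacing constrains the hyperbola more evenly than linear
spacing). Rounding collisions at short delays are replaced by the smallest
unused integer days so the count is preserved. Any menu satisfying the
task bounds can be supplied as CSV; all downstream code treats the menu as
data, so the estimation machinery is independent of the grid choice.

## Questionnaire scoring and reliability

The ERQ's ten 7-point items split 6/4 into cognitive-reappraisal and
expressive-suppression subscales (standard assignment: items 1, 3, 5, 7,
8, 10 vs 2, 4, 6, 9; configurable). Subscales are scored as item sums
(ranges 6–42 and 4–28); no items are reverse-keyed. Reliability is
Cronbach's alpha with n−1 variances throughout, which makes the
duplicated-items case exactly α = 1.

## Covariate-adjusted rank correlation

"Spearman correlation controlling for covariates" is operationalised as
rank-transform-then-residualise: x and y are converted to average ranks,
each is residualised on [intercept, age, sex, handedness, education] by
least squares, and the Pearson correlation of residuals is returned with a
t-approximation p on n − 2 − q degrees of freedom. The alternative order
(residualise raw values, then Spearman) is available behind a flag for
sensitivity analysis, as is a seeded permutation p. Sex and handedness are
coded 0/1 and the coding is recorded in outputs so signs are
interpretable. A related published figure caption lists IQ in place of
handedness among the adjustment variables; no IQ measure exists in the
data description, so the handedness set is implemented and the discrepancy
is noted here rather than resolved.

## Mediation

Three OLS fits sharing one covariate set C = {age, sex, handedness,
education, TIV} decompose the effect of X (reappraisal) on Y (log₁₀k)
through M (left ventral-striatum gray-matter volume):

    M ~ 1 + X + C        → a
    Y ~ 1 + X + M + C    → c′, b
    Y ~ 1 + X + C        → c,   indirect effect ab = a·b

With identical covariates the identity c = c′ + a·b is exact and is
asserted after every fit. Point estimates and analytic SEs come from OLS;
inference on ab uses a nonparametric case bootstrap: subjects are resampled
with replacement (default 10,000 draws), all paths recomputed per
resample by batched normal equations (RMS-equilibrated columns; resamples
whose Gram matrix is numerically singular — e.g. no left-hander drawn —
are redrawn and counted, with a warning above 1%). The percentile interval
is the default (a bias-corrected variant is available behind a flag), and
two-sided p-values use the sign convention 2·min(F(0), 1−F(0)) with the
(r+1)/(B+1) small-sample adjustment. Everything is reproducible
byte-for-byte given the seed.

The mediation *pattern* is labelled at level α: "full-pattern" when the
indirect effect is significant, the direct effect is not, and the total
effect is; "partial" when indirect and direct are both significant; else
"none". The label always carries a non-causal framing suffix: with
cross-sectional data this is a statistical decomposition, not evidence of
mechanism.

Raw-scale (unstandardised) fitting is the default; whether to standardise
first was an open choice and raw scales keep coefficients in interpretable
units (log₁₀k per ERQ point, etc.).

## Synthetic cohorts

The generator emulates a cohort of 155 young adults:

| quantity | default | source of scale |
|---|---|---|
| log₁₀k | N(−2.002, 0.456²) | cohort descriptive |
| choice noise | log₁₀β ~ N(−3.2, 0.3²) | calibrated: ~90% model-consistent choices |
| reappraisal score | 27.632 ± 6.676 (6 items) | cohort descriptive |
| suppression score | 14.077 ± 4.624 (4 items) | cohort descriptive |
| item loadings | back-solved from α targets 0.843 / 0.718 | reliability |
| age / education | N(22.56, 2.76²) / N(15.11, 1.39²) years | cohort descriptive |
| sex / handedness | Bernoulli(78/155) / Bernoulli(150/155) | cohort counts |
| TIV | N(1.5×10⁶, (1.5×10⁵)²) mm³ | field-typical values |
| mediator (VS GMV) | 0.45 ± 0.05 modulated-GM units | chosen so planted b is scale-consistent |
| planted paths | a = −0.002, b = 2.047, c′ = −0.009 | reported path coefficients |

Residual SDs of the mediator and outcome equations are back-solved so the
*marginal* SDs of M and log₁₀k hit their targets given the planted paths.
Questionnaire items are expanded from the score latent by a discretised
one-factor model; a frozen moment-matching correction (scale inflation
≈1.07, small mean offset, solved once numerically) compensates the
variance lost to rounding/clipping so observed integer sum scores
reproduce the target mean and SD at large n. Discretisation still
attenuates inter-item correlations slightly, so realised alphas run
≈0.83/0.70 against the 0.843/0.718 loadings targets; item-level realism
beyond this is out of scope. The β distribution is unanchored by any
reported estimate and is flagged as a calibration choice.

What the generator does **not** emulate: trial-order effects, shared
method variance between questionnaire and task, non-Gaussian covariate
distributions, spatial structure of the mediator (it is generated directly
as a scalar), and any selection process in recruitment. Passing tests
therefore demonstrate correctness of the estimation and inference
machinery under the assumed data-generating process, not robustness to
real-data pathologies.

The exposure entering the planted structural equations is the continuous
score latent; the cohort table carries the observed integer item sum,
whose correlation with the latent is ≈0.92 at the default reliability, so
recovered path a is mildly attenuated relative to its planted value.

## Pipeline and reproducibility

`run-all` executes simulate → fit → score → describe → correlate →
mediate. Mediation runs only for subscales whose adjusted correlation with
log₁₀k passes a configurable significance gate (α = 0.05 by default,
1.0 disables), mirroring a conditional analysis design; the gate is
configurable because frozen gates make null-simulation calibration
impossible. The run manifest records the package version, seed, full
configuration, and SHA-256 of every output file, and contains no
timestamps, so identical configurations yield byte-identical manifests.

Problem sizes used by the test suite and the reproduction script: cohorts
of 155 subjects × 120 trials; 10,000 bootstrap draws for single analyses;
null-calibration studies use 500 Monte-Carlo replicates × 2,000 draws
(bootstrap) and 2,000 replicates (rank correlation), chosen to keep
Monte-Carlo error around the thresholds being checked.

## Known limitations

* The ROI module computes a mask mean on a pre-aligned grid only — no
  resampling, registration, or voxelwise statistics; it is a stand-in for
  a full morphometry pipeline, which is out of scope.
* The bootstrap test of ab at a planted null (a = 0, b ≠ 0) is mildly
  conservative at n = 155 — a well-documented property of percentile
  bootstrap tests of product terms, whose null distribution is a
  spiky product-normal; measured type-I error sits near 0.03 at nominal
  0.05 (see the acceptance suite).
* Analytic SEs for ab use the first-order delta method (Sobel) and are
  reported for reference only; bootstrap inference is authoritative.
* Hierarchical/Bayesian discounting estimation, alternative discounting
  functionals, and moderated mediation are out of scope.
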