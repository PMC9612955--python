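# Methods

This note documents the statistical models implemented by `hypoalgesia`, the
assumptions behind them, the synthetic cohort used to exercise them, and the
numerical choices that matter when reproducing results.

## The experiment being modelled

The package targets a within-subjects motivated-distraction design: on each
of 64 trials a participant performs either an easy left–right arrow task or a
demanding 2-back working-memory task, for either $0.00 or an
individually calibrated monetary amount, while a warm (non-painful) or hot
(painful) stimulus is applied; the trial ends with a 0–100 rating of the
stimulus. The 2×2×2 factorial (task × reward × temperature) is balanced with
8 trials per cell, ordered pseudo-randomly with at most 3 consecutive trials
at the same temperature.

Three calibrations individualize the stimuli before the main task:

1. **Thermal.** 7 temperatures (40, 44–49 °C) × 4 forearm sites are rated on
   warmth (non-painful) or pain-intensity (painful) scales. A line is fitted
   to each branch and inverted: the *low* temperature is where fitted warmth
   reaches 80/100, the *high* temperature where fitted pain reaches 60/100,
   both clipped to the stimulated 40–49 °C range. If a branch's slope is not
   positive, an isotonic fit is inverted instead; a flat curve is an error,
   not a guess.
2. **ISI staircase.** 15 trials of the 2-back task with the interstimulus
   interval (ISI) adjusted after each trial to bring the nonparametric
   sensitivity A into the 0.75–0.85 band: A above the band shortens the ISI,
   below lengthens it. Steps are multiplicative (×/÷1.5), with the step
   factor's excess over 1 halved at every direction reversal; the calibrated
   ISI is the geometric mean of the last (up to four) reversal points, a
   standard variance-reducing staircase estimate. ISIs are clamped to the
   displayable 19–2583 ms.
3. **Monetary.** 26 pain-for-money offers ($0.00–$3.00) are accepted or
   rejected; a maximum-likelihood logistic regression of acceptance on offer
   is inverted at 95%: `amount_95 = (logit(0.95) − intercept)/slope`, clamped
   to [$0.50, $3.00]. Completely separated choices (including all-accept /
   all-reject) have no finite MLE and fall back to the midpoint between the
   highest rejected and lowest accepted offers; a non-positive slope clamps
   to $3.00. Both fallbacks warn.

## Performance scoring: the A statistic

Task performance per trial is the nonparametric sensitivity A computed from
hit rate H and false-alarm rate F (2-back: "same" on a 2-back match is a
hit; LR control: "left" on a left arrow, an arbitrary convention that A's
symmetry makes immaterial). The three-case rectified-area form is used:

- F ≤ 0.5 ≤ H: A = 3/4 + (H−F)/4 − F(1−H)
- F ≤ H < 0.5: A = 3/4 + (H−F)/4 − F/(4H)
- 0.5 < F ≤ H: A = 3/4 + (H−F)/4 − (1−H)/(4(1−F))

with A(H,F) = 1 − A(F,H) for F > H. Two edge conventions: exact chance
H = F returns 0.5 — including the corners (0,0) and (1,1) — which preserves
both the chance anchor and the complement identity A(H,F) + A(F,H) = 1 on
the whole unit square; and F/(4H) is taken as 0 when F = 0 < H. Omitted
responses are scored conservatively: a target omission is a miss, a
non-target omission earns no false alarm.

## Trial filtering

Ratings answered faster than 150 ms are removed (the 150 ms boundary itself
is kept: the rule is strictly "faster than"). High-temperature trials
classified "not painful" have their pain rating set to 0. Ratings are
rescaled to 0–1 for the mediation model. Pain analyses use only
high-temperature trials; performance analyses only 2-back trials (the arrow
task is at ceiling). Removal fractions are reported against both the
all-trials and high-temperature-only denominators, since either can be the
base of a quoted percentage.

## Repeated-measures ANOVA and contrasts

Condition-cell means per participant feed a two-factor within-subjects
ANOVA (statsmodels `AnovaRM`). In a 2×2 design every effect has 1 numerator
df and n−1 denominator df, and each F equals the square of the paired t on
the corresponding difference score — an identity the test suite enforces to
1e-8 against an independent paired-t oracle. Partial η² is recovered as
F/(F + df_den). Effects whose difference score is identically zero are 0/0
degenerate and reported as F = 0 with a note. Planned contrasts are the four
simple effects, tested as paired t's using each contrast's own
paired-difference variance (robust to sphericity concerns), with
Holm–Bonferroni step-down adjustment over the 4-member family. Condition
error bars use the Cousineau–O'Brien within-subject method: center each
participant's cells on their own mean, re-center on the grand mean, and
inflate the per-cell SD by √(C/(C−1)) before dividing by √n.

## Multilevel moderated mediation

The core engine estimates a 1-1-1 mediation — task demands X → performance
M → pain Y, all varying at trial level within participants — using the
stacked (selector-variable) formulation: each trial contributes a mediator
row and an outcome row, with indicator variables switching the relevant
predictors on, so a single mixed model estimates both equations jointly:

    M = int_M + (a + a_rew·W)·X + rew_M·W + γ₁t + γ₂log t + ε_M
    Y = int_Y + (b + b_rew·W)·M + (c′ + c′_rew·W)·X + rew_Y·W + γ₁t + γ₂log t + ε_Y

W is the reward indicator; trial number and its log absorb drift and early
sensitization. Any subset of {int_M, int_Y, a, b, c′} can carry
participant-level random effects with an unstructured covariance Ψ;
residuals are independent with separate variances for mediator and outcome
rows. The default random set adds the two random intercepts to the random
a/b/c′ paths; a `paper` preset uses {a, b, c′} only.

Because a_j and b_j may covary across participants, the population-average
indirect effect is covariance-inclusive:

    ab = a·b + cov(a_j, b_j),
    IE(w) = (a + a_rew·w)(b + b_rew·w) + cov(a_j, b_j),  w ∈ {0, 1},

with the moderation difference IE(1) − IE(0). With Ψ forced diagonal the
estimate reduces exactly to the product of fixed effects. The total effect c
and its moderation c_rew come from a separate mixed model of Y on X, W,
X·W and the time covariates (random intercept and task slope), with no
performance predictor.

### Estimation

Restricted maximum likelihood, with the fixed effects profiled out by GLS.
Ψ is parameterized by its Cholesky factor with log diagonal (so any
unconstrained parameter vector yields a valid covariance, and boundary
cases Ψ → 0 are reachable); residual variances are log-parameterized.
All data enter through per-participant, per-row-type cross-products, so one
objective evaluation is a handful of batched q×q operations via the
Woodbury identity regardless of trial count — and a participant-level
bootstrap replicate is just an index into the stored cross-products. The
analytic REML gradient (verified against finite differences in the test
suite) drives L-BFGS-B with up to 3 jittered restarts; design columns are
equilibrated to unit RMS internally (the raw trial-number covariate
otherwise degrades the conditioning of the GLS normal matrix) and estimates
mapped back on report. Convergence requires a gradient sup-norm below 1e-4
(the optimizer targets 1e-6); failures are flagged, never silently replaced.
The objective is monotone over accepted iterates, which the tests assert.

Reported coefficient df is (stacked rows − fixed effects) — deliberately
approximate, with inference intended to rest on the bootstrap intervals
rather than these large-sample t's.

### Bootstrap

Interval estimates resample participants with replacement (each sampled
participant's full trial set enters once per draw), refit the stacked model
warm-started at the full-data variance parameters, and take 2.5/97.5
percentiles of every fixed effect and indirect quantity. Replicates whose
optimizer fails the gradient criterion are dropped and counted; more than
10% drops is an error. The default pipeline B is 200; the `paper` preset
uses 10,000.

## Synthetic cohort

No raw data ship with the package, so the generator runs the mediation
model forward with participant-level random effects drawn from a
configurable Ψ — exactly the structure the estimators assume, which is what
parameter-recovery and coverage validation require. Default fixed effects
and cohort size are the study-reported estimates (57 participants,
mediator intercept 0.96, a = −0.13, a_rew = 0.04, b = −0.16, c′ = −0.04,
rew_Y = −0.13, b_rew = 0.09, c′_rew = −0.04, log-trial drifts 0.01/0.03,
cov(a_j, b_j) = 0.005). Random-effect SDs and residual SDs
(σ_M = 0.06, σ_Y = 0.18) are not reported quantities; they were chosen once
as plausible for A-scores near ceiling and mid-scale ratings, giving the
a_j–b_j correlation a moderate 0.7. Realism features, each configurable:
ratings and A-scores clipped to their bounded scales, ~90% of
high-temperature trials classified painful (the realized proportion is not
a reported quantity, so it is an explicit free parameter), ~1.1% fast-guess
reaction times that the 150 ms filter removes, and per-participant
calibration parameters scattered around the reported cohort means (low
45.3 °C, high 48.4 °C, ISI ≈ 881 ms, amount ≈ $2.02).

Clipping censors the linear model near its bounds — with the near-ceiling
mediator intercept this biases the task effect on the order of 0.01 — so
**estimator-validation simulations disable clipping, set the painful
probability to 1, and the fast-guess rate to 0**: recovery and coverage
checks validate the estimator under the model it assumes; the censoring
switches exist to make end-to-end pipeline output realistic, not to test
consistency under censoring. Passing recovery tests therefore demonstrate
correctness of the estimation machinery, not robustness to bounded-scale
censoring, informative classification, or non-Gaussian residuals in real
data.

Simulated observers: 2-back sensitivity follows a saturating curve
d′(ISI) = d_max·ISI/(ISI + τ) (d_max ≈ 3, τ ≈ 1000 ms, per-participant
scatter), responses from an equal-variance Gaussian detector; money
choices are Bernoulli with logistic value functions; heat ratings are
linear in temperature per branch with Gaussian noise.

## Validation problem sizes

The deep checks run at sizes chosen for desk hardware: parameter recovery
averages 50 cohorts at the full study scale (J=60 × 64 trials); the
covariance-inclusive indirect effect check uses 25 cohorts at J=57; the
bootstrap coverage study uses 200 cohorts at J=30 × 16 trials with B=300
(scaled down from B=10,000), checking that the nominal 95% interval covers
the generating indirect effect 93–97% of the time. Percentile cluster
bootstraps at 30 clusters are known to undercover slightly, and this check
sits at — in the shipped run, marginally below — that band's lower edge;
the check is kept at its nominal band rather than widened to fit.

## Known limitations

- The thermal calibration fits plain per-branch lines; it does not model
  central/peripheral adaptation across stimulation sites.
- Residuals of the mediator and outcome rows of the same trial are assumed
  independent given the random effects (no within-trial M–Y residual
  covariance), matching the canonical stacked formulation.
- Reported df for coefficient t's is approximate (see above).
- The LR-task scoring convention (left = signal) is a documented choice; A
  is invariant to swapping it.
- Conditional indirect effects are evaluated only at W = 0 and W = 1, the
  two reward conditions of the design.
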