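# Methods

## Task and data model

A dyad plays 30 rounds of a competitive reaction time game. Each round has
exactly one winner, who chooses an integer blast level in 1–8 delivered to
the loser; blast level is the behavioural measure of reactive aggression.
The win rule is minimally rigged: when the two reaction times fall within
100 ms of each other the winner is drawn uniformly at random, otherwise the
faster press wins. With exchangeable reaction-time distributions this pins
each player's win rate at 1/2 regardless of skill difference inside the tie
window.

Trial data are tidy CSV, one row per round (dyad, round index, winner,
loser, genders, blast, condition, reaction times). Two conditions are
modelled: `immediate` (the winner selects a blast straight away) and
`forced_break` (a 5–15 s delay is imposed first, blocking impulsive
selection). A third label, `forced_response` (a 3 s shot clock whose
timeouts draw a random blast in 4–8), is accepted on input and collapsed
into `immediate` at read time, since its winners also respond without a
break.

## Kinematic features

Only winners emit blasts, so each player's aggression trace is the
subsequence of rounds they won. On that win series we define level (most
recent blast), velocity (difference of the two most recent blasts) and
acceleration (difference of the two most recent velocities). The modelling
table pairs each won round (the outcome) with both players' kinematics
computed strictly before that round; a row therefore requires three prior
wins from *each* player, so the earliest possible row is round 7 and the
construction can never leak future information.

Two readings of "most recent rounds" are possible when a player did not win
the immediately preceding round: kinematics over the player's own win
series (used here), or over calendar rounds with zero-filling for losses.
We use the win-series reading because only winners make choices; zero
filling would conflate "did not win" with "did not change". Rows with
incomplete lag history are dropped (complete case), not imputed. The
generator, which needs a value for every round it simulates, substitutes
zeros for unavailable lags; those early rounds can never become modelling
rows, so the substitution never reaches the fitted model.

## Generative model

The simulator draws each round as follows: log-normal reaction times per
player (median 350 ms, log-sd 0.2 — only the ordering and the 100 ms tie
window matter downstream), the win rule above, then a blast for the winner:

```
eta  = 2.00 + 0.44·L_tgt + 1.03·V_agg − 0.36·A_agg − 0.35·V_tgt + 0.11·A_tgt
       + context terms
blast = clamp(round(eta + Normal(0, noise_sd)), 1, 8)
```

The coefficient defaults are the fitted general model of the original
study; the aggressor's own level carries no weight. `noise_sd` defaults to
1.0, a calibration choice (the residual noise of the real process is not
published) that places the simulated conditional R² in the observed ~0.6–0.75
range. Rounding is half-away-from-zero; clamping enforces the 1–8 scale.

Three context effects sit on the linear predictor:

* **Woman-woman offset** (−0.72): the difference between the woman-woman
  reference intercept (1.28) and the general intercept (2.00), so all-women
  pairs play at a lower baseline.
* **Initiation impulse**: in each of the first 5 rounds, a winning man adds
  +5 blast units with probability 0.95. These are calibration knobs, not
  estimates; they are set so that in mixed pairs men initiate heightened
  aggression roughly an order of magnitude more often than women (odds
  ratio ≈ 9–10.5 in 400-dyad calibration runs). Confining the impulse to
  rounds 1–5 also guarantees it never enters a modelling row (rows start at
  round 7).
* **Forced-break reduction** (0.5 blast units), applied only when the
  condition is `forced_break` and the pair contains at least one man —
  reproducing the observed pattern that breaks reduce aggression in
  man-containing pairs and leave woman-woman pairs unaffected.

All randomness flows from a master seed; each dyad consumes an independent
substream keyed by (seed, dyad index), so per-dyad data are reproducible
regardless of generation order.

### What the generator does and does not emulate

It reproduces the statistical skeleton the analysis assumes: one winner per
round at 50% rates, integer blasts 1–8, coupled-oscillator dynamics with
the published coefficients, lower woman-woman baselines, male-dominated
initiation, and a man-specific forced-break effect. It does not emulate
individual differences in trait aggression (random-effect variances arise
only through the dynamics), emotional or verbal behaviour, learning or
fatigue across rounds, or the transient of real play — the simulated grand
mean rises from the intercept toward its fixed point (≈3.6) rather than
oscillating around a stationary level from round 1. Passing tests therefore
validate the pipeline's correctness and calibration on data of known
structure; they are not evidence about real behaviour.

## Oscillator model estimation

`fit_general` fits the six-predictor linear mixed model with random
intercepts for dyad and for individual-within-dyad (statsmodels `MixedLM`,
REML, L-BFGS with a Powell fallback, convergence tolerance at machine
defaults tighter than 1e-8 on the profiled objective). The original report
calls the estimator "linear least squares" but quotes marginal/conditional
R², which presuppose random effects; the mixed model is therefore the
default, with `method="pooled"` (OLS, dyad-clustered robust SEs) as a
sensitivity variant. Random slopes are not modelled. P-values are
large-sample Wald tests. Standardised betas use whole-table standard
deviations. Marginal R² is fixed-effect variance over (fixed + dyad +
individual + residual); conditional R² adds the random-intercept variances
to the numerator, so conditional ≥ marginal always, with equality iff both
random variances are zero.

The moderated model keeps only woman-aggressor rows, with a man-target
indicator interacted with every term; the woman-woman pair is the reference
and predictions for woman-man pairs are reference plus difference, term by
term, exactly.

## Parameter recovery and the discretisation bias

The recovery protocol (also used by `scripts/acceptance.py`) simulates 200
dyads × 30 rounds per replicate from the homogeneous process — the default
coefficients with the three context effects switched off, so the generating
model lies inside the fitted family — rebuilds the lagged table, refits,
and averages coefficients over 50 replicates. Problem sizes (200 dyads, 50
replicates) were chosen to put Monte-Carlo error well below the 0.1-unit
scale of interest.

Because emitted blasts are rounded and clamped to 1–8, the observed outcome
is a censored version of the linear predictor, and the refit is slightly
attenuated: slope coefficients recover within |0.06| of their generating
values (aggressor velocity ≈ 0.98 vs 1.03), but the intercept recovers
high by ≈ +0.13 — its generating value (2.00) sits near the blast floor,
where censoring lifts the conditional mean. This is a deterministic
property of the discretised emission, not Monte-Carlo error; the acceptance
suite keeps the intercept check at the same ±0.1 band as the slopes so the
bias stays measured rather than hidden, and that one check is expected to
fail by ~0.03.

## Escalation statistic

The initiation of heightened aggression is the earliest round whose blast
is at or above the dyad's overall mean blast (all 30 rounds enter the mean);
its winner is the initiator. Such a round always exists. "At or above" is
`>=` by default with a strict `>` flag; constant-blast dyads initiate at
round 1 by convention and are flagged as degenerate for optional exclusion.
The gender summary over mixed dyads reports proportions, the odds ratio,
and an intercept-only logistic regression of initiator-is-man, whose
exponentiated intercept equals the odds ratio exactly; complete separation
(all initiators one gender) yields an unbounded odds ratio with a warning
rather than an error.

## Grand-mean sinusoid

The grand mean of the winner's blast at each round index is fit with
`y(t) = a·sin(b·t + c) + d` by nonlinear least squares on the 1-based round
index. Initialisation is multi-start: `d₀` = series mean, `a₀` = √2 ×
series sd, `b₀` = dominant discrete-Fourier frequency of the demeaned
series, and eight phase starts; the best start by residual norm wins.
Frequency is constrained to [π/n, π] radians/round — at least half a cycle
over the window (slower sines are indistinguishable from a trend and
otherwise produce huge-amplitude degenerate fits) and at most the Nyquist
rate. Fits are reported canonically (a ≥ 0, c ∈ [0, 2π)); per-parameter
p-values are Wald tests with n − 4 degrees of freedom; if no sinusoid beats
the constant model the fallback d = mean is returned with a warning.

## Inferential layer

Rank tests are implemented from the definitions: mid-ranks, tie-corrected
variance, 0.5 continuity correction toward the null, normal approximation —
switched automatically to exact enumeration (all C(N, n1) group assignments,
or all 2ⁿ sign patterns, two-sided by the doubling rule) when the combined
sample size is at most 12. Zero differences in the signed-rank test are
dropped before ranking (classical rule; a keep variant exists behind a
flag). Effect size is r = |z|/√N with N the observations entering the test.

JZS Bayes factors use a Cauchy prior (default scale √2/2, exposed as a
parameter) on the standardised effect via its inverse-gamma mixing
representation, and the corresponding Zellner–Siow mixture-of-g prior for
linear models; the one-dimensional integral over the mixing parameter is
evaluated by adaptive quadrature on the log scale after an exponential
substitution with max-shifting, so evidence ratios of order 10^±100 neither
overflow nor underflow. Reported integration error is relative and in
practice < 1e-10. Nested-model comparisons return the with/without evidence
ratio for a predictor block.

The forced-break contrast stratifies dyads into woman-woman (WW) versus
man-containing (M+): trial-level rank-sum tests within each stratum across
conditions, a between-strata test on dyad-mean blasts of forced-break dyads
centred on their stratum's immediate-condition mean, one-sided signed-rank
floor tests of WW blasts against the scale minimum, and an optional
bootstrap "simulated subtraction" distribution (dyads resampled with
replacement within stratum × condition) for visualisation only. Trial-level
tests ignore dyad clustering — at null effects their size is near nominal
in our simulations (≈0.03–0.08 at α=0.05) but grows slowly with cluster
count; the dyad-level between test is the clustering-robust summary.

## Known limitations

* The simulator's transient start (grand mean rising toward the fixed
  point) differs from real play, which oscillates around a stationary level;
  sinusoid fits on simulated data therefore mostly capture the transient.
* Unit of analysis for the inferential layer is the trial unless stated;
  clustering within dyads is only partially addressed (see above).
* The mixed model assumes independent Gaussian residuals; no autoregressive
  residual structure is modelled.
* The intercept of the refit oscillator model inherits a ≈ +0.13
  discretisation bias from the 1–8 emission scale (quantified above).
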