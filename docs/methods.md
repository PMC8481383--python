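# Methods

This note documents the models, generator assumptions, numerical choices
and known limitations of `turntimes`.

## Winner-takes-the-turn simulation

**Procedure.** From a trial-level response-time table (participant ×
condition × trial), form all unordered k-subsets of participants
(lexicographic order; above a configurable cap, default 10,000, subsets are
sampled uniformly under the run seed). For each subset, condition and
simulated trial, one response time is drawn per member from that member's
condition pool and the minimum is recorded as the winning time. The gain
per condition is the difference between the central tendency (mean or
median) of all kept responses and of the winning times.

**Sampling policy.** The default draws each member's
`trials_per_condition` samples *without replacement* when the pool is
large enough and falls back to with-replacement otherwise; the policy is
configurable (`with_replacement`, `exhaustive`) because resampling schemes
differ across analysis traditions and the choice is not substantive for
the gain. `exhaustive` enumerates every cross-member combination of pool
entries and exists for small oracle datasets where the simulation can be
checked against direct enumeration.

**Filtering.** Incorrect trials are removed by flag; then, per condition,
responses deviating by more than `sd_factor` (default 2.5) sample standard
deviations (n−1 denominator) from the condition mean are removed, with
strict inequalities. The rule is applied uniformly; bounds are reported so
any borderline value can be audited.

**Monotonicity and plateau.** The sweep over k supports *coupled*
sampling: each replicate fixes a participant ordering and one draw per
participant × condition × trial, and the k-set winner is the cumulative
minimum over the first k members. Supersets therefore reuse subset draws
and the per-k mean is non-increasing *exactly*, not just in expectation.
With bounded-support pools the per-k mean flattens once the fast edge of
the pool is exhausted; the package's acceptance check operationalizes
"plateau" as the last decrement (k = 9→10) falling below 25% of the first
(k = 2→3), an order-of-magnitude flattening that holds with wide margin
for uniform pools (theoretical ratio ≈ 0.11).

**Ties** in the minimum do not affect the winning value; winner identity
(metadata only) goes to the lexicographically smallest participant id.

## Transition measurement

A transition is measured from the offset of vocalization of one turn to
the onset of the next turn by a different speaker: for each turn, the next
turn is the earliest-onset turn starting after it whose speaker differs
(onset ties broken by speaker id). Negative values are overlaps; zero is
counted as non-overlap (a perfect no-gap-no-overlap latch). A transition
is typed QR iff the prior turn carries the `question` label and the next
turn the `response` label — strict conjunction and adjacency; a question
answered by a counter-question is non-QR.

Exclusion categories are applied with a fixed precedence (backchannel →
interrupted prior → extended silence → unclear overlap → laughter start),
first match wins. The order is a determinism device; the categories rarely
co-occur in practice. The `unclear_overlap` label excludes a transition if
it sits on *either* flanking turn, so one labelled turn can exclude two
transitions.

Outliers are removed within each group-size stratum (QR and non-QR
pooled) beyond quartile ± 1.5 × IQR, strict inequalities. Quartiles use
linear interpolation between order statistics (R type-7, the default of
the common analysis environments); the convention matters for the bounds
and is recorded in the filter report. Strata with fewer than 4 values are
kept unfiltered with a warning.

## Mixed models

**Transition-time LMM.** Response: signed transition time (ms). Fixed
effects: intercept; overlap dummy; and group-size (dyad = +0.5, triad =
−0.5), transition-type (QR = +0.5) and their interaction, each estimated
*within* the two overlap levels (dummy-by-contrast expansion). With this
coding the `gap:group_size` coefficient is directly the dyad − triad
difference in mean gap duration. Random effects: by-responder intercept +
overlap + transition-type slopes with correlations, no slope interactions.
Fitted by maximum likelihood (not REML — the fit feeds likelihood-ratio
tests) through statsmodels' `MixedLM`. The reduced design
(`include_overlap=False`) drops the overlap dummy, its nested expansion
and its random slope: the full-vs-reduced comparison adds 4 fixed effects
and 3 random (co)variances, hence a 7-df likelihood-ratio test.

**Overlap GLMM.** Response: overlap indicator; binomial family, logit
link; fixed effects group_size × type (sum contrasts); random by-responder
intercept + type slope with correlation. statsmodels has no frequentist
binomial GLMM, so the fit is implemented here: the random-effect
covariance is parameterised by its Cholesky factor (so zero-variance
boundary fits are representable and flagged as singular), each group's
random-effect mode is found by vectorized Newton iterations, and the
Laplace-approximate marginal likelihood is maximised by L-BFGS-B.
Fixed-effect standard errors come from the numerically differentiated
observed information at the optimum with the covariance parameters held at
their estimates, as is conventional. On a seed-fixed synthetic corpus the
fit agrees with lme4::glmer (Laplace) to ~1e-6 in coefficients, standard
errors and log-likelihood; that comparison is frozen as a test oracle.

**Inference.** Coefficients are reported with normal-approximation z
statistics and two-sided p-values. Satterthwaite denominator degrees of
freedom are not implemented: the package's validation surface is
coefficient signs, magnitudes and calibration on synthetic data, where the
normal approximation is adequate at the sample sizes involved; this is a
deliberate scope decision, recorded here.

**Marginal contrasts.** The group-size effect within transition type t is
`β_gs ± 0.5 β_int` (+ for QR, − for non-QR), with delta-method standard
errors from the fixed-effect covariance. The decomposition is verified in
tests against a refit with re-leveled (dummy) type coding, which is a pure
reparameterization.

**Degenerate inputs.** Single-level grouping factors raise; non-converged
or boundary (singular) fits are returned with flags and notes, never
silently and never suppressed.

## Descriptives

`describe` reports n, mean, sample sd, median (midpoint convention),
unscaled median absolute deviation and KDE modes. Modes are local maxima
of a Gaussian kernel density (Silverman's rule by default, configurable)
evaluated on a 512-point grid spanning the data range ± 3 bandwidths; a
secondary mode must reach ≥ 10% of the primary mode's density, a guard
against KDE ripple. At most two modes are reported, matching the
unimodal/bimodal structure of the distributions this package deals with.

## Synthetic data: what it emulates, and what it does not

**Response times.** Unimodal right-skewed conditions are ex-Gaussian
(mean μ + τ, variance σ² + τ²); bimodal conditions are two-Gaussian
mixtures whose early component may precede the question offset (negative
latencies). The packaged four-condition default emulates a
picture-question answering task with cell means/sds of roughly 417 (177),
344 (172), 200 (249) and 234 (241) ms, including a 40 ms-sd per-participant
additive shift (random intercept), drawn once per participant. Incorrect
trials (3% by default) keep a latency from the same distribution — only
the flag differs, since exclusion acts on the flag.

**Corpora.** Turns are chained on one timeline per conversation: each next
turn is by a different speaker and starts at the prior turn's offset plus
a signed draw — from a ≥ 0-truncated Gaussian gap distribution, or, with
probability `overlap_prob[(group_size, type)]`, from a negative-truncated
overlap distribution. The responder's random intercept (sd 75 ms by
default) shifts the location of either draw, so the sign of a transition
is decided purely by the overlap Bernoulli draw. Defaults (12 dyads + 12
triads, 5 minutes; overlap probabilities 0.32/0.24 dyad and 0.35/0.38
triad for QR/non-QR; gap means 390 vs 335 ms; overlap mean −270 ms; QR
rate 0.30; exclusion rates summing to 0.22) were chosen once to mirror
the magnitudes a dyad/triad corpus analysis reports — overall overlap
probability near 0.32, a ~55 ms dyad − triad gap difference, an overlap
excess for triads confined to non-QR transitions — and are not estimates
of any particular corpus. Overlap draws are bounded at −600 ms and turn
durations at ≥ 1300 ms so per-speaker interval tiers stay disjoint
(deep overlap never reaches back past the same speaker's previous turn).

Because gap draws are truncated at zero, the realized expected gap
difference is slightly below the nominal location difference; the
generator's `GroundTruth.expected_gap_diff` integrates the truncated-normal
mean over the intercept distribution (Gauss–Hermite quadrature) so
recovery tests can target the exact injected value rather than the nominal
one. The ground truth also carries a per-transition ledger (stratum, sign,
injected exclusion category, effective exclusion reason), making
count-conservation checks exact by construction.

**What passing tests do and do not show.** The generator has no lexical
content, no acoustics, no gaze or gesture, no pragmatics (dispreferred
responses, repair), no within-speaker turn sequences, and speakers do not
adapt their behavior to competition. Recovery results therefore show the
*pipeline and models* are correct and calibrated under the assumed
data-generating process — not that real corpora satisfy that process.

## Parameter-recovery harness

100 synthetic corpora at reduced size (6 dyads + 6 triads, 4 minutes each;
roughly 550 kept transitions and 30 responders per corpus — sizes chosen
as the smallest at which both models are comfortably identified) with an
injected +55 ms dyad − triad non-overlap gap difference and a triad
overlap excess confined to non-QR (0.55 vs 0.30; QR equal at 0.30).
Recovery criteria: the 95% CI of the LMM's `gap:group_size` coefficient
covers the exact injected value in ≥ 85/100 runs with |mean bias| below
half the mean standard error, and the GLMM marginal contrasts yield a
significant negative group-size effect within non-QR together with a null
within QR in ≥ 90/100 runs. Observed rates (seed-dependent): coverage
91–95%, joint contrast rate 95–96%.

## Known limitations

* The LMM relies on statsmodels' `MixedLM` optimizer; near-singular
  random-effect structures (which the full model often has on synthetic
  data, where type and overlap slopes are truly zero) can yield slightly
  lower log-likelihoods than lme4 on the same data (observed ≤ 0.1).
* The GLMM uses a Laplace approximation; with very small clusters or rare
  outcomes adaptive quadrature would be more accurate.
* TextGrid support covers interval tiers in the long text format, one tier
  per speaker, with annotation labels in a sidecar CSV — not point tiers
  or short-format files.
* The measurement rule emits one transition per turn into the earliest
  later-onset turn by a different speaker; corpora with consecutive
  same-speaker turns (which the generator never produces) will map both
  turns onto the same next turn rather than merging them into one turn.
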