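# Methods

This note documents the models implemented in `painloop`, the synthetic
data they are exercised on, the defaults and why they were chosen, and the
limits of what the test suite can establish.

## Study design being emulated

A two-day closed-loop design: on day 1 a subject receives a pseudo-random
sequence of high/low electrical pain stimuli (6 sessions × 30 trials) while
multivoxel responses are recorded, and a sparse decoder of stimulus
intensity is trained.  On day 2 the decoder runs in real time and its
output P(pain) — the probability that the last stimulus was high-intensity
— is the sole feedback to a controller that decides which stimulator fires
next.  Intermittent 0–10 ratings (40% of trials in the original design)
support the frequency-learning analysis.  A separate two-group pre/post
experiment probes endogenous modulation with a thermal
temporal-contrast-enhancement test.  Cohort sizes follow the design: 19
subjects for the closed loop, 28 per group for the contrast test, 14
calibration trials for the psychometric intensity setting.

## Synthetic data

All inputs are generated with known ground truth; nothing is downloaded.

- **Trial sequences** are i.i.d. Bernoulli(p_high = 0.5) labels per trial,
  with explicit yoking (a target subject copies a named source verbatim).
  Yoking is an explicit mapping rather than an implicit rotation because
  the original pairing order is not recoverable.
- **Voxel patterns**: baseline blocks (5 TRs/session) and trial blocks
  (5 TRs) of N(0, σ) noise; within TRs 3–5, a chosen informative subset of
  voxels is shifted ±`class_shift`/2 by label.  No hemodynamic convolution
  or autocorrelated noise is modelled — features are trial-level
  stand-ins, so decoder tests speak to the estimator, not to fMRI noise
  structure.
- **Decoder emissions** are hierarchical: per subject, per-class mean
  P(pain) is drawn once from a normal truncated to (0, 1) with population
  means 0.6025 (high) and 0.4670 (low) — the midpoints of the reported
  across-subject 95% CIs — and between-subject SDs back-solved from those
  CIs assuming normality (SD = halfwidth·√19/1.96 ≈ 0.128 each).
  Trial-level emissions are Beta-distributed around the subject mean with
  `within_subject_sd = 0.15`.  The Beta family and the trial-level
  dispersion are modelling choices (the summaries constrain only subject
  means); both are exposed configuration.  If the requested SD is
  infeasible for a Beta at that mean, the variance is clamped to
  0.95·m(1−m) with a warning.  `sham` mode gives both classes one shared
  mean (feedback carries no information); `perfect` mode emits exactly
  1/0.
- **Ratings** are the generative twin of the analysis regression:
  β₀ + stimulus_effect·identity + session_drift·session +
  β₁·surprisal(ω) + N(0, σ), clipped to [0, 10].  Defaults β₀ = 5,
  β₁ = 0.8, ω = 10, σ = 0.5, stimulus_effect = 1.5 put ratings mid-scale
  with a clearly detectable but not dominant uncertainty coupling.
- **Contrast traces**: a plateau profile on a 1 s grid over 21 s (4.0 in
  T1/T3, 5.5 in T2) plus a triangular overshoot peaking 1 s into T2 and an
  undershoot 1 s into T3 (amplitude 1.2 each), scaled by a group ×
  condition gain; experimental post-gain 1.6 vs 1.0 elsewhere.  Each
  subject × condition adds N(0, 0.4) jitter to its gain: endogenous
  modulation varies strongly between people, and without this the
  synthetic group effect size was several times larger than anything
  plausible for an attentional manipulation.  With the default the
  pipeline produces d ≈ 0.9–1.0 and between-subject change SDs of the
  order seen in pre/post offset-analgesia testing.  Sample noise is i.i.d.
  N(0, 0.3) per 1 s sample; ratings are clipped to [0, 10].
- **Intensity calibration** fits both a scaled logistic
  10/(1+exp(−(c−c50)/s)) and a scaled Weibull CDF to (current, rating)
  pairs and inverts the lower-SSE fit at VAS 1 and 8.

## Decoder

Features: per session and voxel, baseline mean m and SD s (ddof = 1) from
the baseline block; trial TR values map to (v−m)/s and are averaged over
TRs 3–5 (the first two post-stimulus TRs are discarded as
hemodynamically premature).  A zero baseline SD is an error naming the
voxel and session.

Training is variational-Bayes logistic regression with ARD.  The logistic
likelihood is handled with the Jaakkola–Jordan local bound (λ(ξ) =
tanh(ξ/2)/(4ξ)), giving a Gaussian posterior N(m, S) with
S⁻¹ = diag(α) + 2ΦᵀΛΦ, m = SΦᵀ(y−½).  Precisions follow the MacKay
fixed point α_j = γ_j/m_j², γ_j = 1 − α_j S_jj; a feature is pruned
(weight exactly 0) once α_j exceeds 1e8.  The intercept keeps a fixed,
nearly flat prior (precision 1e-6) and is never pruned.  Convergence:
relative change of the variational free energy below 1e-6, cap 500
iterations (non-convergence returns the best iterate with a warning).
With `ard=False` all feature precisions stay at `prior_precision`, and the
fit matches a ridge-penalized maximum-likelihood logistic regression to
within 0.02 in predicted probability (tested against scikit-learn).

Two numerical notes.  EM-style precision updates (α = 1/(m²+S_jj)) were
rejected: their approach to the pruning threshold is so slow that no
feature is ever pruned in hundreds of iterations.  And the retained-set
size on pure-noise data grows with the trials-per-voxel ratio (≈8/100
voxels at 40 trials, ≈29/100 at 180, ≈31/500 at 180) — a known
overfitting mode of sparse Bayesian learning; at the realistic ROI scale
(180 trials, 500 voxels) null retention is ≈6%.

Cross-validation uses stratified shuffled folds (scikit-learn) with a
fixed seed; sensitivity/specificity take high pain as positive, and
`n_features` is the mean retained count across folds.

## Controller

P(pain) is scaled to 2p−1; the chosen action's value moves toward
−p_scaled with step α = 0.5; the unchosen action is untouched; both
values reset to 0 at session starts.  Q stays in [−1, 1] for all time
(each update is a convex combination of Q and a target in [−1, 1]).
Under ε-greedy selection exploration draws uniformly over both actions,
so the non-greedy action has probability ε/2 = 0.2; ties (both values
equal, e.g. at session start) break uniformly at random.

The selection rule admits two readings: the prose one (explore with
probability ε = 0.4) and a literal one in which the printed inequality
(random action when the uniform draw exceeds ε) explores 60% of the time.
The package defaults to the prose reading — it is stated twice and gives
the textbook asymptote (a perfect decoder drives delivery to ε/2 = 0.20,
which the tests verify) — with `explore_semantics="literal"` as a
configuration switch.

**Known discrepancy.**  Under the prose reading with the calibrated
emission model, the simulated mean high-pain percentage is ≈37.4% (100
cohort replicates of 19 subjects), noticeably below the ≈43.5% observed
in the original closed-loop experiment; the literal reading lands at
≈41.6%.  The calibrated generative model is evidently a cleaner feedback
channel than the real-time system it emulates (its trial-level dispersion
knob is not constrained by any published summary), so the simulated
controller controls pain better than the real one did.  We report the
number the stated conditions actually produce rather than adjusting the
dispersion post hoc to match.  The qualitative results are robust to this:
Q(low) > Q(high) in essentially every replicate, delivery is significantly
below 50%, sham feedback leaves it at 50%, and the perfect-decoder
asymptote is exact.

Value summaries default to trial-means of the post-update values within
subject (`session_final` is available); the group comparison is a paired
t test.

## Frequency model

Counts update recursively as N ← (N+u)·e^(−1/ω) (the most recent past
trial carries lag 1; the current trial never enters its own predictor),
with plain counts when ω is absent.  The posterior mean is
(N_h+1)/(N_h+N_l+2); the uncertainty predictor is the surprisal
−log₂ p of the realized stimulus under the pre-update mean — the formula
as used, not the Shannon entropy of the posterior.  Surprisal uses log₂
(bits); BIC uses natural log.

Rating residuals come from per-subject OLS on [intercept, identity (±1),
session number].  In the grid fit (ω ∈ {1..29, none}) the surprisal
predictor is, by default, residualized on that same nuisance design
before the regression: by Frisch–Waugh–Lovell the slope then equals the
one from jointly regressing raw ratings on nuisance + surprisal.  Without
this partialling, surprisal's correlation with identity (≈0.11 on matched
sequences) attenuates β₁ by a few percent and noiseless recovery is no
longer exact; `partial_nuisance=False` restores the literal two-stage
reading.  κ = 2 without leak, 3 with; a numerically zero error variance
maps to BIC = −∞ with a warning.  Group-level ω minimizes the mean BIC
across subjects.  Fisher-z group statistics exclude subjects with
zero-variance series or |r| ≥ 1−1e-12 (atanh diverges), with warnings.

## Contrast enhancement

T1 samples before 6 s are discarded (they never enter the magnitude and
only inflate the normalization variance); remaining samples are z-scored
within subject + condition (pre and post are normalized separately; a
pooled option is a one-line change at the call site since normalization
operates per group of rows), linearly interpolated to a 1 s grid, and
averaged across trials.  Magnitude = max over T2 − min over T3.  The
group statistic is pooled-SD Cohen's d on signed post − pre changes (the
printed ± values behave as SDs: only that reading reproduces the
reported d), with a percentile bootstrap (default 10,000 resamples,
subject resampling within groups).  Percentile coverage at n = 28/group
measures ≈94% in Monte-Carlo — the usual mild undercoverage of percentile
bootstraps at this scale; BCa was not implemented.

## Determinism and problem sizes

Every stochastic stage accepts an integer seed or Generator; pipeline
stages derive independent streams from (seed, stage name, replicate) so
any stage can be re-run in isolation and full reports are regenerable
bit-exactly.  Simulation sizes used by the tests and the acceptance
script — 100 cohort replicates for the closed loop, 100 seeds for
parameter recovery, 300 Monte-Carlo replicates for bootstrap coverage —
were chosen so that Monte-Carlo error is comfortably below the assertion
tolerances while the whole suite runs in a few minutes.

## Limitations

- No hemodynamic response modelling, fMRI noise spectra, or EEG synthesis;
  decoder results characterize the estimator on idealized features.
- The emission model's trial-level dispersion is a free parameter; see the
  known discrepancy above.
- No hierarchical (shared-ω) estimation or marginal-likelihood model
  comparison beyond BIC; no repeated-measures ANOVA machinery beyond the
  summary statistics (delegated to standard libraries where needed).
- Statistical guard tests (binomial bands, t intervals) are calibrated
  checks with designed false-alarm rates; where cross-validation
  correlations inflate variance beyond the binomial model, tests average
  over independent datasets rather than widening bands.
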