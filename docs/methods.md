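# Methods

This note documents the models and procedures implemented in `dyadcoord`,
the assumptions behind them, the synthetic-data generator used to test
them, and the numerical and design choices that were genuinely open.

## The measurement problem

Two people in conversation coordinate: their pupil dynamics, gaze targets,
head movements, prosody, turn-taking and word choice covary in time. The
package quantifies this *interpersonal coordination* (IC) for one dyad in
one round of a collaborative bargaining game as a vector of 27 features,
then asks two statistical questions:

1. **Validation** — does a feature reflect the interaction itself rather
   than the shared context? Each feature is compared against *pseudo
   pairs*: artificial dyads assembled from two participants who played the
   same round, in the same condition and (here) the same gender stratum,
   but never with each other. A one-tailed permutation t-test per feature,
   Holm-corrected across the family, decides which features survive.
2. **Modeling** — do the surviving features predict objective outcomes
   (wealth gain, goal-completion times) and subjective outcomes (13
   Likert items aggregated per pair)? A LASSO at the median-of-11 repeated
   5-fold-CV one-standard-error penalty restricts the predictor set; a
   linear mixed model with pair-level random intercepts is refit on the
   selected set, reporting Wald p-values and local effect sizes
   f² = (R²_full − R²_reduced)/(1 − R²_full) on the marginal
   (fixed-effects) R². A random forest (500 trees, 10-fold CV, `mtry`
   tuned over {2, ⌊√p⌋, ⌊p/3⌋}) probes how well the IC features separate
   experimental conditions or rounds.

## The 27 features

* **Pupil-size coordination.** Pupil series are cleaned by a
  confidence gate (≥ 0.6), an absolute diameter gate (1.5–9 mm), a
  rolling-SD gate (3 SD in a 1 s window), single-sample spike removal
  (> 0.1 mm per sample on both flanks), removal of valid clusters shorter
  than 1/12 s, linear interpolation, and a zero-phase 4 Hz Butterworth
  low-pass (order 3). These thresholds are pupillometry-literature
  conventions, all config-exposed. Screen brightness is regressed out by
  per-session, per-participant OLS. Coordination is the mean, over 6 s
  windows advanced by 3 s, of the unconstrained DTW alignment cost with
  absolute local distance |aᵢ − bⱼ| (lower = more coordinated). No
  per-window z-normalisation is applied and no warping band is imposed.
* **Gaze coordination.** Six screen areas of interest (AOIs); the
  feature is the total duration of same-AOI co-fixation episodes divided
  by round duration, in percent. Episodes are exact interval
  intersections of valid fixations, not grid approximations.
* **Motion coordination.** Head motion energy = squared velocity
  integrated over a trailing 6 s window advanced by 1 sample; the feature
  is the Pearson correlation of the two partners' energy series.
* **Prosodic coordination.** Time-aligned moving averages (TAMA):
  duration-weighted window means (25 s window, 12.5 s step) of segment
  pitch and intensity per speaker, correlated across partners over
  jointly non-missing windows (≥ 5 required, config). Level asymmetries
  are absolute differences of duration-weighted means and SDs.
* **Conversation structure.** Segments shorter than 1 s that sit inside
  the partner's speech, or in a partner gap after which the partner speaks
  next, are backchannels and never claim the floor. Runs of same-speaker
  segments not broken by a partner turn merge into turns; internal
  silences ≥ 0.2 s are pauses; turn length is speech time only. A turn
  overlapping the partner's turn end by ≥ 0.5 s is an interruption, its
  response time is minus the overlap, and the interrupted turn is
  truncated at the interrupter's onset (syllables prorated). Features are
  pair-level absolute differences of per-speaker aggregates plus lag-1
  adaptation correlations (value on a turn vs the partner's value on the
  immediately following turn; ≥ 4 pairs per direction required).
  A turn-initial overlap below 0.5 s is not an interruption; its response
  time is clipped at 0 so negative response times occur only with
  interruptions.
* **Language style matching.** Per 2-minute segment and function-word
  category, 1 − |X₁−X₂|/(X₁+X₂+0.0001), averaged over the 8 categories
  and then over segments. A category unused by both speakers counts as a
  perfect match (the formula's 0.0001 guard).

Missingness is data, not error: every absent feature carries a reason
(low-quality pupil trace, too few joint windows, too few turn pairs, a
silent speaker), and observations with missing predictors are dropped per
model only.

Ambiguities resolved as package decisions (all config-switchable where
meaningful): `Pause_per_Speech` is pause-time over speech-time (not a
count ratio); speaking time is turn speech time (backchannels excluded)
relative to round duration; per-window speech amount counts a
speaker-silent window as 0 syllables, because silent windows are exactly
what makes speech amount anti-correlated across partners in a turn-taking
conversation; overall speech rate is total syllables over total speaking
time.

## Transforms and the validation test

Absolute-difference and time-like predictors are natural-log transformed
(columns containing zeros use log(x + ε) with ε half the smallest positive
observed value); Pearson-type predictors (including the adaptation means)
are Fisher-Z transformed; the DTW distance, the gaze percentage and LSM
stay on their native scales. The real-vs-pseudo test runs on the
transformed scale by default, with the log shift chosen on the combined
real + pseudo values so both groups share one transform.

The permutation test uses the Welch t statistic (config-switchable to
pooled t), re-randomises group labels, enumerates all label assignments
exhaustively when C(n₁+n₂, n₁) ≤ 10⁵ and otherwise draws Monte-Carlo
permutations, and reports the add-one estimator p = (#extreme + 1)/(N + 1)
so p is never 0. One-tailed directions encode the orientation
"coordination ⇒": correlations, the gaze ratio and LSM are expected
higher in real pairs; distances and differences lower. Speech-amount
correlation is expected *lower* (more negative) in real pairs — one
partner is silent precisely while the other talks. The pseudo-pair count
per stratum defaults to the number of real pairs (balanced groups).

### What is, and is not, null at zero coupling

Pseudo-pair features are computed on the artificial dyad exactly as for
real pairs: traces truncated to the shorter session, segment tables merged
as if the two speakers had been conversing. This has a consequence worth
stating plainly: **turn alternation is itself interaction.** A merged pair
of two independent conversations has no common floor — turn rates need
not match, "response times" are gaps between unrelated streams, pauses
are broken by the other stream's speech, and speech amount loses its
alternation-driven anticorrelation. The 17 conversation-structure
features therefore differ between real and merged-pseudo dyads even when
every generator coupling knob is zero; this is real structure, not a
miscalibrated test. The type-I calibration experiments accordingly
measure the false-rejection rate on the 10 features whose computation
involves no cross-speaker turn interleaving (pupil DTW, gaze, motion, the
pitch/intensity TAMA correlations and level differences, LSM), and treat
the speech-amount correlation as a positive control that must reject in
its configured direction. Pseudo pairs are additionally restricted to the
same gender stratum: the study design pairs same-gender interlocutors, so
a cross-gender pseudo pair would differ from every real pair in pitch
baseline for reasons unrelated to interaction.

## The synthetic-dyad generator

The generator emulates the derived recordings the pipeline consumes, with
one cross-partner coupling knob per modality; all knobs at zero give
partners that are statistically independent apart from the shared game
context. It is the package's test bed, not a model of human physiology.

* **Pupil:** two Ornstein–Uhlenbeck states (θ = 1 s⁻¹, σ = 0.35) mutually
  pulled together at rate `pupil_coupling`, on a ~4.5 mm baseline, minus
  0.02 mm per unit of a shared slow luminance driver (OU, θ = 0.15 s⁻¹)
  that the brightness regression should remove, at 120 Hz, with Poisson
  blink artifacts (rate 0.12 s⁻¹) that collapse tracker confidence.
* **Gaze:** per-partner semi-Markov AOI walks, log-normal dwell times
  (median 0.9 s, σ = 0.6, clipped 0.2–5 s), 30 ms saccade gaps; at each
  switch the switcher copies the partner's current AOI with probability
  `gaze_follow_prob`. At probability 1 the two streams lock onto the same
  AOI from the first switch on.
* **Head velocity:** |own OU + `motion_coupling` · shared OU| + 0.05.
* **Turn engine:** alternating renewal. Turn speech time is log-normal
  with σ = 0.55 and mean calibrated to 3.24 s; response gaps log-normal
  with mean 0.45 s. `turn_adaptation` injects a lag-1 autoregression of a
  speaker's log turn length and log response time on the partner's
  previous realized value (variance-preserving, so the mean calibration
  holds at any adaptation level). Interruptions occur with probability
  0.04 (overlap 0.5–1.2 s into the partner's final chunk); sub-1 s
  backchannels are inserted inside the partner's turn with probability
  0.25, placed clear of regions where turns may overlap. Pauses ≥ 0.2 s
  split turns into chunks of ≥ 1.05 s so chunks are never mistaken for
  backchannels.
* **Prosody:** per-speaker pitch/intensity baselines (female 205 Hz /
  male 120 Hz, 60 dB) drift turn-by-turn and are pulled toward the
  partner's last realized value with weight 1 − e^(−`prosody_coupling`);
  per-segment noise (4 Hz / 1.5 dB) is independent.
* **Function words:** each speaker's 8-category profile is a mixture
  `lsm_overlap`·(dyad Dirichlet profile) + (1−`lsm_overlap`)·(individual
  profile); counts are multinomial (~60 words per 2-minute segment).
* **Game log and questionnaire:** wealth gains ~N(0.35, 0.12²) per
  player on an initial 100; goal times uniform in (0.45, 0.95)·duration,
  unreached with probability 0.12; Likert responses are a pair-level
  quality latent plus noise, clipped to 1–7.

Cohort outcomes are drawn as Σ β·T(feature) + pair intercept + noise,
where the features are computed from the simulated signals by the regular
pipeline and T is the standard transform above — so a mixed model fitted
on the transformed matrix estimates the β that generated the data.

**What the generator does not emulate:** real pupil foreshortening and
gaze-position-dependent artifacts, semantic gaze behaviour, interpersonal
timing beyond lag-1, prosodic convergence over content, or any
cross-modal coupling. Passing tests show the *pipeline* measures what it
claims on data with known structure; they are not evidence about human
behaviour.

## Experiment sizes

The statistical experiments run on one CPU; sizes were chosen to keep a
full test run and the acceptance script each within tens of minutes while
leaving the assertions at their stated thresholds:

* type-I calibration: 60 cohorts (tests) / 40 (script) of 12 pairs,
  120 s sessions, 800 permutations per test. At these counts a single
  feature's rejection-rate estimate carries binomial noise of ~0.02–0.03,
  so the band check applies to the pooled rate over the 10 null features
  exactly, and to each single feature with its own 99% binomial envelope.
* power: 10 cohorts of 40 pairs (the study-scale cohort size) at the
  documented strong coupling setting; survival asserted at ≥ 80%.
* monotonicity: 3 levels per knob × 30 seeds (tests) / 20 (script).
* recovery: 25 (tests) / 20 (script) replicates of 18 pairs × 2 rounds
  across three gaze-coupling conditions, true β = 0.1 per gaze percentage
  point (signal-to-noise ≈ 2, the regime the selection-consistency
  property is stated for).
* random forest: informative-feature check at n = 120; chance
  calibration over 50 (tests) / 30 (script) shuffled-label datasets at
  fixed mtry = 2 (tuning adds nothing to a chance check), importance
  computation skipped there.

## Numerical choices and degenerate inputs

* DTW uses a full dynamic program (numba-compiled); windows with any
  missing sample in either partner are skipped; fewer than one full joint
  window makes the feature missing.
* Brightness regression with constant luminance degenerates to mean
  centering (logged).
* Pupil cleaning is idempotent up to the low-pass filter's residual
  passband attenuation (re-cleaning re-invalidates nothing; values move
  by < 0.05 mm on typical traces).
* Zero-variance groups with equal means give permutation p = 1;
  zero-variance series make Pearson-type features missing rather than 0.
* The LASSO lambda grid is glmnet-style (100 log-spaced points from the
  data-driven maximum down to 10⁻³ of it); predictors are z-scored on
  training folds only; the final refit standardizes on the full data.
* MixedLM fits use REML; a random-intercept variance below 10⁻⁸ of the
  residual variance is flagged singular but still reported. With one
  observation per pair the intercept variance is confounded with the
  residual; estimates reduce to OLS and the singular flag fires.
* CSV round trips are exact: floats are written with 17 significant
  digits and parsed with round-trip precision.

## Known limitations

* The pseudo-pair scheme is the only surrogate implemented; no phase
  randomization or segment shuffling.
* The merged-pseudo computation makes the conversation-structure
  features unfalsifiable as *null* features (see above); their real-vs-
  pseudo differences conflate genuine adaptation with alternation
  structure. Interpretation of those features should lean on the
  adaptation correlations, whose generative counterpart is explicit.
* LASSO cross-validation folds are drawn over sessions, not pairs;
  with multiple rounds per pair this slightly favours optimistic CV error.
* f² uses marginal (fixed-effects) R²; conditional-R² variants would
  give smaller values for the same fit.
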