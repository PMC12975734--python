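# dyadcoord

Multimodal interpersonal-coordination analysis for dyadic conversation.

When two people talk, their behaviour and physiology covary: pupils
dilate together, gaze lands on the same objects, heads move in sympathy,
prosody converges, turn-taking becomes mutually adapted, and word choice
aligns. `dyadcoord` quantifies this coordination for pairs playing a
collaborative bargaining game, validates each measure against a
constrained pseudo-pair null, and models communication outcomes from the
validated measures. It is aimed at researchers in social signal
processing and dyadic interaction who work with *derived* recordings
(pupil and motion traces, fixation and speech-segment tables) rather than
raw audio/video.

## What it computes

For each pair × round the package derives 27 coordination features:

* **Pupil-size coordination** — mean windowed dynamic-time-warping
  distance `DTW(p_A, p_B)` of cleaned, brightness-regressed pupil series
  (6 s windows, 3 s step; lower = more coordinated);
* **Gaze coordination** — % of the round both partners fixate the same
  screen area of interest;
* **Motion coordination** — Pearson r of head motion energy
  `∫ v² dt` over sliding 6 s windows;
* **Prosodic coordination** — Pearson r of time-aligned moving averages
  (25 s / 12.5 s) of pitch and intensity, plus pair-level |Δ| of means
  and SDs;
* **Conversation structure** — turn lengths, response times, pauses,
  backchannels (< 1 s, no floor claim), interruptions (≥ 0.5 s overlap),
  speaking times, speech rate/amount: pair differences and lag-1
  turn-by-turn adaptation correlations;
* **Language style matching** —
  `LSM_X = 1 − |X₁−X₂| / (X₁+X₂+0.0001)` per function-word category,
  averaged over 8 categories and 2-minute segments.

Each feature is then tested against **pseudo pairs** (participants who
played the same round in the same condition, but with someone else) by
one-tailed permutation t-tests with Holm correction; surviving features
enter (1) LASSO selection at the median-of-11 one-standard-error λ
followed by a linear mixed model with pair random intercepts and f²
effect sizes, and (2) random-forest classification of condition/round
with variable importance.

A fully seeded synthetic-dyad generator with one coupling knob per
modality (`pupil_coupling`, `gaze_follow_prob`, `motion_coupling`,
`prosody_coupling`, `turn_adaptation`, `lsm_overlap`) makes the whole
chain testable without human data. See `docs/methods.md` for the models,
assumptions and design decisions.

## Worked example

Simulate a strongly coupled 12-pair cohort, compute features, and
validate them against pseudo pairs:

```python
import pandas as pd
from dyadcoord import (CouplingConfig, GroundTruth, simulate_cohort,
                       feature_table, make_pseudo_pairs,
                       pseudo_feature_table, validate_features, results_table)

coupling = CouplingConfig(pupil_coupling=6, gaze_follow_prob=0.8,
                          motion_coupling=3, prosody_coupling=3,
                          turn_adaptation=0.6, lsm_overlap=1.0)
sessions, _, _ = simulate_cohort(12, duration=150.0, seed=7,
                                 truth=GroundTruth(coupling=coupling))
real, _ = feature_table(sessions)
pseudo = pseudo_feature_table(sessions, make_pseudo_pairs(sessions, seed=7))
results, survivors = validate_features(real, pseudo, n_perm=5000, seed=7)
print(results_table(results).loc[[0, 1, 2, 6, 22, 26],
      ["feature", "cohens_d", "p_holm", "significance"]].to_string(index=False))
print("survivors:", survivors)
```

prints

```
                feature  cohens_d   p_holm significance
Pupil_Size_Coordination   -19.488 0.005399           **
      Gaze_Coordination    14.524 0.005399           **
    Motion_Coordination     6.915 0.005399           **
      Pitch_Correlation     1.352 0.005399           **
 Turn_Length_Adaptation     1.739 0.005399           **
                    LSM     1.023 0.149970
survivors: ['Pupil_Size_Coordination', 'Gaze_Coordination', 'Motion_Coordination',
 'Intensity_Correlation', 'Intensity_Difference', 'Pitch_Correlation',
 'Pitch_Difference', 'Speech_Amount_Correlation', 'Pause_per_Speech_Difference',
 'Response_Time_Adaptation', 'Response_Time_Difference', 'Turn_Length_Adaptation']
```

Reading the rows: the pseudo-pair null isolates interaction-driven
coordination. The DTW distance is *smaller* in real pairs (negative d —
coordinated pupils are closer); the gaze ratio, the motion and prosody
correlations and the turn-length adaptation are larger, and they survive
Holm correction (`p_holm < 0.05`). LSM's effect (d ≈ 1) falls just short
of the Holm bar at 12 pairs; it survives reliably at study-scale cohorts
of 40 pairs. On a zero-coupling cohort the continuous-modality features
(pupil, gaze, motion, prosody) and LSM drop out of the survivor list;
conversation-structure features can still differ because turn alternation
itself distinguishes a real conversation from two merged independent ones
(see `docs/methods.md`).

The same chain runs from the shell on a directory of session bundles
(CSV + JSON, one directory per pair × round):

```bash
dyadcoord simulate --n-pairs 12 --duration 300 --gaze-follow-prob 0.8 --seed 1 cohort/
dyadcoord all --seed 1 cohort/ results/
```

producing `features.csv`, `validation.csv`, per-outcome model JSONs and
classification JSONs, each stamped with the config hash and seed.

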