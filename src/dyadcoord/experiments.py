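"""Cohort-level validation experiments.

These runners measure the statistical behaviour of the pipeline on
synthetic cohorts: type-I calibration of the real-vs-pseudo permutation
test at zero coupling, survival power and monotonicity of each coupling
knob, parameter recovery of the LASSO -> mixed-model chain, random-forest
sanity, and the self-pair limiting case.  They are used by both the test
suite and the acceptance script; problem sizes are arguments so callers can
trade precision for runtime.

A note on the null: turn alternation is itself interaction.  Features
derived from the interleaved turn structure (turn rates, response times,
pauses, speech-amount correlation, ...) differ between real dyads and
merged pseudo dyads even when every coupling knob is zero, because a merged
pair of independent conversations has no common floor.  Calibration of the
permutation test is therefore measured on the features whose computation
does not involve cross-speaker turn interleaving; for those the zero-knob
cohort is a genuine null.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureConfig, compute_feature_vector
from .models import lasso_select, model_outcome, rf_classify, transform_predictors
from .synth import simulate_cohort, simulate_session
from .types import (
    FUNCTION_WORD_CATEGORIES,
    CouplingConfig,
    DyadSession,
    GroundTruth,
    SessionMetadata,
    SignalTrace,
)
from .validation import make_pseudo_pairs, pseudo_feature_table, validate_features

#: Features whose real-vs-pseudo comparison is genuinely null at zero
#: coupling (no cross-speaker turn interleaving enters their computation).
NULL_CALIBRATION_FEATURES: tuple[str, ...] = (
    "Pupil_Size_Coordination",
    "Gaze_Coordination",
    "Motion_Coordination",
    "Intensity_Correlation",
    "Intensity_Difference",
    "Intensity_SD_Difference",
    "Pitch_Correlation",
    "Pitch_Difference",
    "Pitch_SD_Difference",
    "LSM",
)

#: A documented "strong" setting for every coupling knob, and the feature
#: each knob targets (per the feature-orientation table).
STRONG_COUPLING = CouplingConfig(
    pupil_coupling=6.0,
    gaze_follow_prob=0.8,
    motion_coupling=3.0,
    prosody_coupling=3.0,
    turn_adaptation=0.6,
    lsm_overlap=1.0,
)

KNOB_TARGETS: dict[str, tuple[str, str]] = {
    # knob -> (target feature, direction in which coordination moves it)
    "pupil_coupling": ("Pupil_Size_Coordination", "decreasing"),
    "gaze_follow_prob": ("Gaze_Coordination", "increasing"),
    "motion_coupling": ("Motion_Coordination", "increasing"),
    "prosody_coupling": ("Pitch_Correlation", "increasing"),
    "turn_adaptation": ("Turn_Length_Adaptation", "increasing"),
    "lsm_overlap": ("LSM", "increasing"),
}

KNOB_LEVELS: dict[str, tuple[float, float, float]] = {
    "pupil_coupling": (0.0, 2.0, 6.0),
    "gaze_follow_prob": (0.0, 0.4, 0.8),
    "motion_coupling": (0.0, 1.0, 3.0),
    "prosody_coupling": (0.0, 1.0, 3.0),
    "turn_adaptation": (0.0, 0.3, 0.6),
    "lsm_overlap": (0.0, 0.5, 1.0),
}

POWER_TARGET_FEATURES: tuple[str, ...] = (
    "Pupil_Size_Coordination",
    "Gaze_Coordination",
    "Motion_Coordination",
    "Pitch_Correlation",
    "Intensity_Correlation",
    "Turn_Length_Adaptation",
    "Response_Time_Adaptation",
    "LSM",
)


def _cohort_tables(
    n_pairs: int,
    coupling: CouplingConfig,
    duration: float,
    seed: int,
    config: FeatureConfig | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Real and pseudo feature tables for one simulated cohort."""
    sessions, _, _ = simulate_cohort(
        n_pairs,
        conditions=["Baseline"],
        rounds_per_pair=1,
        truth=GroundTruth(coupling=coupling, outcome_betas={}),
        duration=duration,
        seed=seed,
    )
    rows = []
    for s in sessions:
        fv = compute_feature_vector(s, config)
        rows.append({"pair_id": s.metadata.pair_id, "bg_round": s.metadata.bg_round, **fv.values})
    real = pd.DataFrame(rows)
    pairs = make_pseudo_pairs(sessions, seed=seed + 1)
    pseudo = pseudo_feature_table(sessions, pairs, config)
    return real, pseudo


# ==========================================================================
# Null calibration (type I error of the permutation validation)
# ==========================================================================


@dataclass
class CalibrationResult:
    rejection_rate: dict[str, float]  # raw p < alpha, per feature
    pooled_null_rate: float  # over NULL_CALIBRATION_FEATURES
    fwer_holm: float  # any Holm-significant null feature, per cohort
    speech_amount_reject_rate: float  # positive control (real_smaller)
    n_cohorts: int


def null_calibration(
    n_cohorts: int = 60,
    n_pairs: int = 12,
    duration: float = 120.0,
    n_perm: int = 800,
    alpha: float = 0.05,
    seed: int = 0,
) -> CalibrationResult:
    """Rejection rates of the real-vs-pseudo test on zero-coupling cohorts."""
    rng = np.random.default_rng(seed)
    reject_counts: dict[str, int] = {}
    tested_counts: dict[str, int] = {}
    fwer_hits = 0
    sa_hits = 0
    for _ in range(n_cohorts):
        cseed = int(rng.integers(0, 2**31 - 1))
        real, pseudo = _cohort_tables(n_pairs, CouplingConfig(), duration, cseed)
        results, _ = validate_features(
            real, pseudo, alpha=alpha, n_perm=n_perm, seed=cseed + 7
        )
        any_null_holm = False
        for t in results:
            tested_counts[t.feature] = tested_counts.get(t.feature, 0) + 1
            if t.p_raw < alpha:
                reject_counts[t.feature] = reject_counts.get(t.feature, 0) + 1
            if t.feature in NULL_CALIBRATION_FEATURES and t.significant:
                any_null_holm = True
            if t.feature == "Speech_Amount_Correlation" and t.p_raw < alpha:
                sa_hits += 1
        fwer_hits += any_null_holm
    rates = {
        f: reject_counts.get(f, 0) / tested_counts[f] for f in sorted(tested_counts)
    }
    null_hits = sum(reject_counts.get(f, 0) for f in NULL_CALIBRATION_FEATURES)
    null_n = sum(tested_counts.get(f, 0) for f in NULL_CALIBRATION_FEATURES)
    return CalibrationResult(
        rejection_rate=rates,
        pooled_null_rate=null_hits / null_n if null_n else float("nan"),
        fwer_holm=fwer_hits / n_cohorts,
        speech_amount_reject_rate=sa_hits / n_cohorts,
        n_cohorts=n_cohorts,
    )


# ==========================================================================
# Power and monotonicity of the coupling knobs
# ==========================================================================


def power_survival(
    n_cohorts: int = 12,
    n_pairs: int = 40,
    duration: float = 120.0,
    n_perm: int = 800,
    alpha: float = 0.05,
    seed: int = 0,
    targets: tuple[str, ...] = POWER_TARGET_FEATURES,
) -> dict[str, float]:
    """Fraction of strongly-coupled cohorts in which each targeted feature
    survives the Holm-corrected validation."""
    rng = np.random.default_rng(seed)
    hits = {f: 0 for f in targets}
    for _ in range(n_cohorts):
        cseed = int(rng.integers(0, 2**31 - 1))
        real, pseudo = _cohort_tables(n_pairs, STRONG_COUPLING, duration, cseed)
        _, survivors = validate_features(real, pseudo, alpha=alpha, n_perm=n_perm, seed=cseed + 7)
        for f in targets:
            hits[f] += f in survivors
    return {f: hits[f] / n_cohorts for f in targets}


def monotonicity(
    n_seeds: int = 30, duration: float = 150.0, seed: int = 0
) -> dict[str, dict]:
    """Mean targeted-feature value at three levels of each knob.

    Coordination features should move monotonically with their knob (the
    DTW distance decreases; everything else increases).
    """
    out: dict[str, dict] = {}
    for knob, (feature, trend) in KNOB_TARGETS.items():
        means = []
        for li, level in enumerate(KNOB_LEVELS[knob]):
            vals = []
            for k in range(n_seeds):
                md = SessionMetadata(
                    pair_id=f"M{k}", condition="Baseline", bg_round=1, time_before_bg_round=0.0
                )
                s = simulate_session(
                    md,
                    CouplingConfig(**{knob: level}),
                    duration,
                    seed=seed + 100_000 * li + k,
                )
                vals.append(compute_feature_vector(s).values[feature])
            means.append(float(np.nanmean(vals)))
        if trend == "increasing":
            ok = means[0] < means[1] < means[2]
        else:
            ok = means[0] > means[1] > means[2]
        out[knob] = {"feature": feature, "trend": trend, "means": means, "monotone": bool(ok)}
    return out


# ==========================================================================
# Parameter recovery of the LASSO -> LMM chain
# ==========================================================================


@dataclass
class RecoveryResult:
    selection_rate: float  # LASSO picks the true predictor
    coverage_rate: float  # LMM 95% CI covers the true beta
    significant_rate: float
    n_replicates: int
    beta_true: float
    beta_estimates: list[float]


def recovery(
    n_replicates: int = 25,
    n_pairs: int = 18,
    rounds: int = 2,
    duration: float = 100.0,
    beta: float = 0.1,
    true_feature: str = "Gaze_Coordination",
    seed: int = 0,
) -> RecoveryResult:
    """Simulate cohorts with a known outcome model and score recovery.

    The true model puts a single nonzero coefficient on the gaze
    coordination ratio; gaze coupling varies across conditions so the
    predictor has real between-pair variance.  Features are computed from
    the simulated signals, outcomes are generated from the transformed
    features, and the two-step analysis must (a) select the true predictor
    and (b) cover the true coefficient with its 95% confidence interval.
    """
    rng = np.random.default_rng(seed)
    sel = cov = sig = 0
    betas = []
    coupling_by_condition = {
        "Baseline": CouplingConfig(gaze_follow_prob=0.0),
        "Unfamiliar": CouplingConfig(gaze_follow_prob=0.3),
        "Unimodal": CouplingConfig(gaze_follow_prob=0.6),
    }
    truth = GroundTruth(
        outcome_betas={true_feature: beta}, random_intercept_sd=0.5, residual_sd=1.0
    )
    for _ in range(n_replicates):
        cseed = int(rng.integers(0, 2**31 - 1))
        sessions, outcomes, _ = simulate_cohort(
            n_pairs,
            conditions=list(coupling_by_condition),
            rounds_per_pair=rounds,
            coupling_by_condition=coupling_by_condition,
            truth=truth,
            duration=duration,
            seed=cseed,
        )
        feats = outcomes.attrs["feature_table"].drop(columns=["pair_id", "bg_round"])
        transformed, _ = transform_predictors(feats)
        transformed = transformed.dropna(axis=1, how="any")
        res = model_outcome(
            transformed,
            outcomes["outcome"],
            outcomes["pair_id"],
            outcome="synthetic",
            seed=cseed % 10_000,
        )
        if true_feature in res.selected_predictors:
            sel += 1
            est, p = res.coefficients[true_feature]
            lo, hi = res.conf_int[true_feature]
            betas.append(est)
            cov += lo <= beta <= hi
            sig += p < 0.05
    return RecoveryResult(
        selection_rate=sel / n_replicates,
        coverage_rate=cov / max(sel, 1),
        significant_rate=sig / max(sel, 1),
        n_replicates=n_replicates,
        beta_true=beta,
        beta_estimates=betas,
    )


# ==========================================================================
# Random-forest sanity
# ==========================================================================


def classifier_informative(n_obs: int = 120, n_noise: int = 26, seed: int = 0):
    """One feature equals the class label plus tiny noise: the classifier
    must be near-perfect and rank that feature on top."""
    rng = np.random.default_rng(seed)
    labels = rng.integers(0, 2, n_obs)
    X = pd.DataFrame(rng.normal(0, 1, (n_obs, n_noise)), columns=[f"noise_{i}" for i in range(n_noise)])
    X.insert(0, "informative", labels + rng.normal(0, 0.05, n_obs))
    return rf_classify(X, labels.astype(str), contrast="informative", seed=seed)


def classifier_chance(
    n_seeds: int = 50, n_obs: int = 40, n_feat: int = 27, seed: int = 0
) -> dict[str, float]:
    """Kappa on shuffled labels should be centred on 0 and accuracy near
    the majority-class rate."""
    rng = np.random.default_rng(seed)
    kappas, accs = [], []
    for _ in range(n_seeds):
        s = int(rng.integers(0, 2**31 - 1))
        r = np.random.default_rng(s)
        X = pd.DataFrame(r.normal(0, 1, (n_obs, n_feat)))
        X.columns = [f"f{i}" for i in range(n_feat)]
        labels = r.permutation(np.repeat(["x", "y"], n_obs // 2))
        res = rf_classify(
            X, labels, contrast="chance", seed=s, mtry_grid=(2,), importance=False
        )
        kappas.append(res.kappa)
        accs.append(res.accuracy)
    return {
        "mean_kappa": float(np.mean(kappas)),
        "mean_accuracy": float(np.mean(accs)),
        "n_seeds": n_seeds,
    }


# ==========================================================================
# Self-pair limiting case
# ==========================================================================


def make_self_paired_session(duration: float = 300.0) -> DyadSession:
    """A session whose partner B is an exact copy of A with shifted turn
    roles: B's k-th turn copies A's k-th turn 4 s later with identical
    length, response time, prosody and syllables, and B's continuous
    signals equal A's.

    In this limit every correlation feature is 1, every difference feature
    0, the DTW distance 0 and LSM 1 — a fixed point the pipeline must hit.
    """
    rate = 120.0
    n = int(duration * rate)
    t = np.arange(n) / rate
    diam = 4.5 + 0.4 * np.sin(2 * np.pi * 0.11 * t) + 0.2 * np.sin(2 * np.pi * 0.37 * t)
    conf = np.full(n, 0.99)
    lum = np.full(n, 50.0)
    vel = np.abs(np.sin(2 * np.pi * 0.21 * t)) + 0.2
    pupil = SignalTrace(t, diam, rate)
    confidence = SignalTrace(t, conf, rate)
    luminance = SignalTrace(t, lum, rate)
    velocity = SignalTrace(t, vel, rate)

    aois = ["partner_face", "tokens_left", "buy_area"]
    fix_rows = []
    pos = 0.0
    k = 0
    while pos < duration:
        end = min(pos + 1.0, duration)
        fix_rows.append({"onset": pos, "offset": end, "aoi": aois[k % 3], "valid": True})
        pos = end
        k += 1
    fixations = pd.DataFrame(fix_rows)

    # period 8 s: A's turn k at 8k, B's copy at 8k + 4.  Turn length and
    # response time are constant (their adaptation correlations are then
    # undefined-by-zero-variance, which the limit permits); prosody and
    # syllable counts vary linearly so every defined correlation is exactly 1
    n_turns = int((duration - 8) // 8)
    seg_rows = []
    for k in range(n_turns):
        length = 3.0
        pitch = 180.0 + 1.0 * k
        inten = 60.0 + 0.5 * k
        syll = 15 + k
        for spk, onset in (("A", 8.0 * k), ("B", 8.0 * k + 4.0)):
            seg_rows.append(
                {
                    "speaker": spk,
                    "onset": onset,
                    "offset": onset + length,
                    "mean_pitch": pitch,
                    "mean_intensity": inten,
                    "n_syllables": syll,
                }
            )
    segments = pd.DataFrame(seg_rows)

    counts = dict(zip(FUNCTION_WORD_CATEGORIES, (12, 8, 9, 11, 7, 9, 4, 5)))
    fw_rows = []
    for p in ("A", "B"):
        for si in range(int(duration // 120)):
            fw_rows.append({"speaker": p, "segment_index": si, **counts})
    funcwords = pd.DataFrame(fw_rows)

    md = SessionMetadata(
        pair_id="SELF", condition="Baseline", bg_round=1, time_before_bg_round=0.0
    )
    gamelog = {
        "total_time": duration,
        "players": {
            p: {"initial_wealth": 100.0, "final_wealth": 140.0, "goal_time": 200.0}
            for p in ("A", "B")
        },
    }
    return DyadSession(
        metadata=md,
        duration=duration,
        pupil={"A": pupil, "B": pupil.copy()},
        confidence={"A": confidence, "B": confidence.copy()},
        luminance={"A": luminance, "B": luminance.copy()},
        fixations={"A": fixations, "B": fixations.copy()},
        velocity={"A": velocity, "B": velocity.copy()},
        segments=segments,
        funcwords=funcwords,
        gamelog=gamelog,
        questionnaire=pd.DataFrame(),
    )


def self_pair_features(duration: float = 300.0):
    """Feature vector of the self-paired session, using a TAMA grid whose
    windows hold whole turn pairs (24 s window, 8 s step) so windowed means
    match exactly between the two copies."""
    config = FeatureConfig(tama_window=24.0, tama_step=8.0)
    return compute_feature_vector(make_self_paired_session(duration), config)
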