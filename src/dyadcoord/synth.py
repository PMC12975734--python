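"""Synthetic dyad generator.

Simulates the derived recordings of one pair playing one round of the
bargaining game — pupil/luminance series at 120 Hz, AOI-labelled fixations,
head-velocity series, alternating speech segments with prosody, per-2-minute
function-word counts, a game log and questionnaire responses — from a
generative model with one cross-partner coupling knob per modality:

* ``pupil_coupling`` — mutual pull between the two partners' pupil
  Ornstein-Uhlenbeck states (on top of a shared luminance driver that the
  brightness regression is expected to remove);
* ``gaze_follow_prob`` — probability that a partner, when switching
  fixation, lands on the other's current AOI;
* ``motion_coupling`` — weight of a shared latent component in both
  partners' head-velocity processes;
* ``prosody_coupling`` — pull of each speaker's pitch/intensity baseline
  toward the partner's last realized values;
* ``turn_adaptation`` — lag-1 autoregression of a speaker's (log) turn
  length and response time on the partner's previous realized value;
* ``lsm_overlap`` — mixing weight of a shared dyad-level function-word
  profile into each speaker's individual profile.

All knobs at zero yield partners that are statistically independent apart
from the shared game context.  Turn lengths are log-normal and calibrated
to a mean of 3.24 s.
"""

from __future__ import annotations

import math
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    AOIS,
    CONDITIONS,
    FUNCTION_WORD_CATEGORIES,
    CouplingConfig,
    DyadSession,
    GroundTruth,
    SessionMetadata,
    SignalTrace,
)

RATE = 120.0  # Hz, eye and motion trackers

#: Log-normal turn-length parameters calibrated so E[turn length] = 3.24 s.
TURN_LENGTH_MEAN = 3.24
TURN_LENGTH_SIGMA = 0.55
TURN_LENGTH_MU = math.log(TURN_LENGTH_MEAN) - TURN_LENGTH_SIGMA**2 / 2

RESPONSE_TIME_MEAN = 0.45
RESPONSE_TIME_SIGMA = 0.6
RESPONSE_TIME_MU = math.log(RESPONSE_TIME_MEAN) - RESPONSE_TIME_SIGMA**2 / 2

INTERRUPTION_PROB = 0.04
BACKCHANNEL_PROB = 0.25  # per partner turn

#: Typical relative use of the eight function-word categories.
FUNCWORD_BASE = np.array([0.18, 0.12, 0.14, 0.16, 0.12, 0.14, 0.06, 0.08])

_PITCH_BASE = {"female": 205.0, "male": 120.0}


def _ou(rng: np.random.Generator, n: int, dt: float, theta: float, sigma: float) -> np.ndarray:
    """Zero-mean Ornstein-Uhlenbeck path by Euler-Maruyama."""
    x = np.empty(n)
    x[0] = rng.normal(0.0, sigma / math.sqrt(2 * theta))
    noise = rng.normal(0.0, sigma * math.sqrt(dt), n - 1)
    for i in range(1, n):
        x[i] = x[i - 1] - theta * x[i - 1] * dt + noise[i - 1]
    return x


def _coupled_ou_pair(
    rng: np.random.Generator, n: int, dt: float, theta: float, sigma: float, gain: float
) -> tuple[np.ndarray, np.ndarray]:
    """Two OU processes mutually pulled together with rate ``gain`` (1/s)."""
    xa = np.empty(n)
    xb = np.empty(n)
    s0 = sigma / math.sqrt(2 * theta)
    xa[0], xb[0] = rng.normal(0.0, s0, 2)
    na = rng.normal(0.0, sigma * math.sqrt(dt), n - 1)
    nb = rng.normal(0.0, sigma * math.sqrt(dt), n - 1)
    for i in range(1, n):
        pull = gain * (xb[i - 1] - xa[i - 1]) * dt
        xa[i] = xa[i - 1] - theta * xa[i - 1] * dt + pull + na[i - 1]
        xb[i] = xb[i - 1] - theta * xb[i - 1] * dt - pull + nb[i - 1]
    return xa, xb


# --------------------------------------------------------------------------
# Modality generators
# --------------------------------------------------------------------------


def _gen_pupil(rng, n, dt, coupling: CouplingConfig):
    lum_shared = 50.0 + _ou(rng, n, dt, theta=0.15, sigma=1.2)
    xa, xb = _coupled_ou_pair(rng, n, dt, theta=1.0, sigma=0.35, gain=coupling.pupil_coupling)
    t = np.arange(n) * dt
    out = {}
    for p, x in (("A", xa), ("B", xb)):
        base = 4.5 + rng.normal(0.0, 0.25)
        lum = lum_shared + rng.normal(0.0, 0.05, n)
        diam = base + x - 0.02 * (lum - 50.0) + rng.normal(0.0, 0.01, n)
        conf = np.minimum(0.98 + rng.normal(0.0, 0.01, n), 1.0)
        # blinks: brief confidence collapses with diameter artifacts
        n_blinks = rng.poisson(0.12 * n * dt)
        for _ in range(n_blinks):
            c = rng.integers(0, n)
            half = int(rng.uniform(0.05, 0.15) / dt)
            sl = slice(max(0, c - half), min(n, c + half + 1))
            conf[sl] = rng.uniform(0.0, 0.3)
            diam[sl] = diam[sl] * rng.uniform(0.2, 0.6)
        out[p] = (
            SignalTrace(t.copy(), diam, RATE),
            SignalTrace(t.copy(), conf, RATE),
            SignalTrace(t.copy(), lum, RATE),
        )
    return out


def _gen_fixations(rng, duration: float, coupling: CouplingConfig):
    """Event-driven two-partner semi-Markov AOI process.

    Dwell times are log-normal; at each switch the switcher copies the
    partner's current AOI with probability ``gaze_follow_prob``, otherwise
    it picks a different AOI uniformly.  A 30 ms saccade gap separates
    consecutive fixations.
    """
    gap = 0.03

    def dwell() -> float:
        return float(np.clip(rng.lognormal(math.log(0.9), 0.6), 0.2, 5.0))

    current = {p: rng.choice(AOIS) for p in ("A", "B")}
    next_switch = {p: dwell() for p in ("A", "B")}
    fix_start = {p: 0.0 for p in ("A", "B")}
    rows = {p: [] for p in ("A", "B")}
    while min(next_switch.values()) < duration:
        p = "A" if next_switch["A"] <= next_switch["B"] else "B"
        t_sw = next_switch[p]
        rows[p].append(
            {
                "onset": fix_start[p],
                "offset": t_sw,
                "aoi": current[p],
                "valid": rng.random() > 0.02,
            }
        )
        other = "B" if p == "A" else "A"
        if rng.random() < coupling.gaze_follow_prob:
            current[p] = current[other]
        else:
            choices = [a for a in AOIS if a != current[p]]
            current[p] = choices[rng.integers(0, len(choices))]
        fix_start[p] = t_sw + gap
        next_switch[p] = fix_start[p] + dwell()
    for p in ("A", "B"):
        if fix_start[p] < duration:
            rows[p].append(
                {"onset": fix_start[p], "offset": duration, "aoi": current[p], "valid": True}
            )
    return {p: pd.DataFrame(rows[p]) for p in ("A", "B")}


def _gen_velocity(rng, n, dt, coupling: CouplingConfig):
    shared = _ou(rng, n, dt, theta=0.8, sigma=1.0)
    t = np.arange(n) * dt
    out = {}
    for p in ("A", "B"):
        own = _ou(rng, n, dt, theta=0.8, sigma=1.0)
        v = np.abs(own + coupling.motion_coupling * shared) + 0.05
        out[p] = SignalTrace(t.copy(), v, RATE)
    return out


def _gen_conversation(rng, duration: float, coupling: CouplingConfig, gender: str):
    """Alternating-renewal turn engine with lag-1 adaptation, pauses,
    interruptions and backchannels."""
    a = coupling.turn_adaptation
    prosody_w = 1.0 - math.exp(-coupling.prosody_coupling)

    pitch_state = {p: _PITCH_BASE[gender] + rng.normal(0.0, 12.0) for p in ("A", "B")}
    inten_state = {p: 60.0 + rng.normal(0.0, 2.5) for p in ("A", "B")}
    syll_rate = {p: rng.normal(5.0, 0.35) for p in ("A", "B")}
    last_log_tl = {p: TURN_LENGTH_MU for p in ("A", "B")}
    last_log_rt = {p: RESPONSE_TIME_MU for p in ("A", "B")}
    last_pitch_obs = dict(pitch_state)
    last_inten_obs = dict(inten_state)

    segs: list[dict] = []
    t = 0.3
    speaker = "A"
    prev_last_chunk = None  # (onset, offset) of previous turn's final chunk
    own_end = {"A": 0.0, "B": 0.0}  # end of each speaker's latest own segment
    while True:
        partner = "B" if speaker == "A" else "A"
        # response time: log-normal with lag-1 pull toward partner's previous
        z = rng.normal()
        log_rt = (
            RESPONSE_TIME_MU
            + a * (last_log_rt[partner] - RESPONSE_TIME_MU)
            + math.sqrt(max(1 - a**2, 0.05)) * RESPONSE_TIME_SIGMA * z
        )
        rt = math.exp(log_rt)
        onset = t + rt
        if prev_last_chunk is not None and rng.random() < INTERRUPTION_PROB:
            max_overlap = prev_last_chunk[1] - prev_last_chunk[0] - 0.1
            overlap = min(0.5 + rng.exponential(0.3), max_overlap, 1.2)
            if overlap >= 0.5:
                onset = t - overlap
                log_rt = math.log(RESPONSE_TIME_MEAN)  # do not propagate negatives
        # a speaker's new turn can never overlap their own previous speech
        onset = max(onset, own_end[speaker] + 0.05)
        last_log_rt[speaker] = log_rt

        z = rng.normal()
        log_tl = (
            TURN_LENGTH_MU
            + a * (last_log_tl[partner] - TURN_LENGTH_MU)
            + math.sqrt(max(1 - a**2, 0.05)) * TURN_LENGTH_SIGMA * z
        )
        speech = float(np.clip(math.exp(log_tl), 1.05, 25.0))
        last_log_tl[speaker] = log_tl
        if onset + speech > duration - 0.5:
            break

        # prosody states drift and pull toward the partner's last realization
        for state, obs, drift in (
            (pitch_state, last_pitch_obs, 2.0),
            (inten_state, last_inten_obs, 0.8),
        ):
            state[speaker] += prosody_w * 0.6 * (obs[partner] - state[speaker]) + rng.normal(
                0.0, drift
            )

        # split speech into chunks separated by >= 0.2 s pauses
        n_pauses = min(rng.poisson(speech / 10.0), max(int(speech / 1.15) - 1, 0))
        props = rng.dirichlet(np.ones(n_pauses + 1) * 3.0)
        chunks = 1.05 + props * max(speech - 1.05 * (n_pauses + 1), 0.0)
        pauses = 0.25 + rng.exponential(0.12, n_pauses).clip(max=0.55)
        pos = onset
        chunk_spans = []
        for i, c in enumerate(chunks):
            seg_pitch = pitch_state[speaker] + rng.normal(0.0, 4.0)
            seg_inten = inten_state[speaker] + rng.normal(0.0, 1.5)
            segs.append(
                {
                    "speaker": speaker,
                    "onset": pos,
                    "offset": pos + c,
                    "mean_pitch": seg_pitch,
                    "mean_intensity": seg_inten,
                    "n_syllables": max(1, int(round(syll_rate[speaker] * c + rng.normal(0, 0.7)))),
                }
            )
            chunk_spans.append((pos, pos + c))
            pos += c
            if i < n_pauses:
                pos += pauses[i]
        last_pitch_obs[speaker] = pitch_state[speaker]
        last_inten_obs[speaker] = inten_state[speaker]

        # partner backchannel inside one chunk of this turn
        if rng.random() < BACKCHANNEL_PROB:
            # keep clear of the turn-final region (a later interruption by
            # the partner reaches <= 1.2 s into the last chunk) and of the
            # turn-initial region (when this turn interrupted, the partner
            # is still speaking until t): the partner's backchannel must
            # never overlap the partner's own speech
            spans = [
                (
                    max(s[0], t + 0.05) if s is chunk_spans[0] else s[0],
                    s[1] - (1.3 if s is chunk_spans[-1] else 0.0),
                )
                for s in chunk_spans
            ]
            spans = [s for s in spans if s[1] - s[0] > 1.0]
            if spans:
                lo, hi = spans[rng.integers(0, len(spans))]
                bdur = rng.uniform(0.3, 0.8)
                bstart = rng.uniform(lo + 0.05, hi - bdur - 0.05) if hi - bdur - 0.1 > lo else None
                if bstart is not None:
                    own_end[partner] = max(own_end[partner], bstart + bdur)
                    segs.append(
                        {
                            "speaker": partner,
                            "onset": bstart,
                            "offset": bstart + bdur,
                            "mean_pitch": pitch_state[partner] + rng.normal(0.0, 4.0),
                            "mean_intensity": inten_state[partner] + rng.normal(0.0, 1.5),
                            "n_syllables": 1,
                        }
                    )
        prev_last_chunk = chunk_spans[-1]
        own_end[speaker] = chunk_spans[-1][1]
        t = pos  # end of this turn's speech (pauses included)
        speaker = partner
    df = pd.DataFrame(segs).sort_values(["onset", "offset"], kind="stable").reset_index(drop=True)
    return df


def _gen_funcwords(rng, duration: float, coupling: CouplingConfig) -> pd.DataFrame:
    n_seg = int(duration // 120)
    lam = coupling.lsm_overlap
    dyad = rng.dirichlet(FUNCWORD_BASE * 40.0)
    rows = []
    for p in ("A", "B"):
        indiv = rng.dirichlet(FUNCWORD_BASE * 40.0)
        profile = lam * dyad + (1 - lam) * indiv
        for s in range(n_seg):
            n_words = rng.poisson(60)
            counts = rng.multinomial(n_words, profile)
            rows.append(
                {"speaker": p, "segment_index": s, **dict(zip(FUNCTION_WORD_CATEGORIES, counts))}
            )
    cols = ["speaker", "segment_index", *FUNCTION_WORD_CATEGORIES]
    return pd.DataFrame(rows, columns=cols)


def _gen_gamelog(rng, duration: float) -> dict:
    log: dict = {"total_time": duration, "players": {}}
    for p in ("A", "B"):
        initial = 100.0
        gain = max(float(rng.normal(0.35, 0.12)), -0.3)
        reached = rng.random() < 0.88
        goal_time = float(rng.uniform(0.45, 0.95) * duration) if reached else None
        # coarse wealth trajectory (drifting random walk ending at final wealth)
        k = max(int(duration // 10), 2)
        steps = rng.normal(gain * initial / k, 2.0, k)
        traj = initial + np.cumsum(steps)
        traj[-1] = initial * (1.0 + gain)
        log["players"][p] = {
            "initial_wealth": initial,
            "final_wealth": initial * (1.0 + gain),
            "goal_time": goal_time,
            "wealth_trajectory": [round(float(w), 3) for w in traj],
        }
    return log


def _gen_questionnaire(rng) -> pd.DataFrame:
    from .models import SUBJECTIVE_ITEMS

    quality = rng.normal(5.3, 0.6)
    rows = []
    for p in ("A", "B"):
        for item in SUBJECTIVE_ITEMS:
            v = int(np.clip(round(quality + rng.normal(0.0, 0.8)), 1, 7))
            rows.append({"participant": p, "item": item, "response": v})
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Public API
# --------------------------------------------------------------------------


def simulate_session(
    metadata: SessionMetadata,
    coupling: CouplingConfig,
    duration: float,
    seed: Optional[int] = None,
) -> DyadSession:
    """Simulate one dyad session of ``duration`` seconds (60-900 s).

    The same (metadata, coupling, duration, seed) always produces an
    identical session; ``seed`` defaults to ``coupling.seed``.
    """
    if not 60.0 <= duration <= 900.0:
        raise ValueError(f"duration must be in [60, 900] s, got {duration}")
    rng = np.random.default_rng(coupling.seed if seed is None else seed)
    dt = 1.0 / RATE
    n = int(round(duration * RATE))

    pupil_data = _gen_pupil(rng, n, dt, coupling)
    fixations = _gen_fixations(rng, duration, coupling)
    velocity = _gen_velocity(rng, n, dt, coupling)
    segments = _gen_conversation(rng, duration, coupling, metadata.gender)
    funcwords = _gen_funcwords(rng, duration, coupling)
    gamelog = _gen_gamelog(rng, duration)
    questionnaire = _gen_questionnaire(rng)

    return DyadSession(
        metadata=metadata,
        duration=duration,
        pupil={p: pupil_data[p][0] for p in ("A", "B")},
        confidence={p: pupil_data[p][1] for p in ("A", "B")},
        luminance={p: pupil_data[p][2] for p in ("A", "B")},
        fixations=fixations,
        velocity=velocity,
        segments=segments,
        funcwords=funcwords,
        gamelog=gamelog,
        questionnaire=questionnaire,
    )


def simulate_cohort(
    n_pairs: int,
    conditions: list[str] | None = None,
    rounds_per_pair: int = 1,
    coupling_by_condition: dict[str, CouplingConfig] | None = None,
    truth: GroundTruth | None = None,
    duration: float = 300.0,
    seed: int = 0,
    feature_table: Optional[pd.DataFrame] = None,
) -> tuple[list[DyadSession], pd.DataFrame, GroundTruth]:
    """Simulate a cohort of pairs with outcomes from a known linear model.

    ``n_pairs`` pairs are split as evenly as possible over ``conditions``
    (each condition needs at least 2 pairs so that pseudo-pairing remains
    possible).  Outcomes are drawn as

        outcome = sum_f beta_f * T(feature_f) + pair_intercept + noise

    where the features are *computed from the simulated signals* by the
    regular feature pipeline and T is the standard predictor transform
    (log / Fisher Z by semantic class).  The ground truth is returned
    alongside and is never consumed by analysis stages.
    """
    from .features import compute_feature_vector
    from .models import transform_predictors

    conditions = list(conditions or CONDITIONS[:1])
    truth = truth or GroundTruth()
    coupling_by_condition = coupling_by_condition or {
        c: truth.coupling for c in conditions
    }
    n_cond = len(conditions)
    per = [n_pairs // n_cond + (1 if i < n_pairs % n_cond else 0) for i in range(n_cond)]
    if min(per) < 2:
        raise ValueError("need at least 2 pairs per condition for pseudo-pairing")

    ss = np.random.SeedSequence(seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    sessions: list[DyadSession] = []
    pair_idx = 0
    for cond, n_c in zip(conditions, per):
        for _ in range(n_c):
            pair_idx += 1
            pair_id = f"P{pair_idx:03d}"
            gender = "female" if rng.random() < 0.72 else "male"
            ages = rng.normal(21.4, 2.7, 2).clip(18, 38)
            hand = rng.choice(["right", "left", "mixed"], p=[0.9, 0.08, 0.02])
            elapsed = 0.0
            for r in range(1, rounds_per_pair + 1):
                md = SessionMetadata(
                    pair_id=pair_id,
                    condition=cond,
                    bg_round=r,
                    time_before_bg_round=elapsed if r > 1 else 0.0,
                    mean_age=float(ages.mean()),
                    age_difference=float(abs(ages[0] - ages[1])),
                    gender=gender,
                    handedness=hand,
                )
                sess_seed = int(ss.spawn(1)[0].generate_state(1)[0] % (2**31))
                sessions.append(
                    simulate_session(md, coupling_by_condition[cond], duration, seed=sess_seed)
                )
                elapsed += duration + float(rng.uniform(30, 120))

    # features -> transformed model matrix -> outcomes
    if feature_table is None:
        rows = []
        for s in sessions:
            fv = compute_feature_vector(s)
            rows.append(
                {"pair_id": s.metadata.pair_id, "bg_round": s.metadata.bg_round, **fv.values}
            )
        feature_table = pd.DataFrame(rows)
    transformed, _ = transform_predictors(
        feature_table.drop(columns=["pair_id", "bg_round"], errors="ignore")
    )
    lin = np.zeros(len(feature_table))
    for name, beta in truth.outcome_betas.items():
        col = transformed[name].to_numpy(float)
        col = np.where(np.isfinite(col), col, np.nanmean(col))
        lin = lin + beta * col
    pair_ids = feature_table["pair_id"].to_numpy()
    intercepts = {
        pid: rng.normal(0.0, truth.random_intercept_sd) for pid in pd.unique(pair_ids)
    }
    y = (
        lin
        + np.array([intercepts[p] for p in pair_ids])
        + rng.normal(0.0, truth.residual_sd, len(feature_table))
    )
    outcomes = feature_table[["pair_id", "bg_round"]].copy()
    outcomes["condition"] = [s.metadata.condition for s in sessions]
    outcomes["outcome"] = y
    # the computed feature table rides along so callers need not recompute it
    outcomes.attrs["feature_table"] = feature_table
    return sessions, outcomes, truth
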