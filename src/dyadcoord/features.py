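"""The 27 dyad-level interpersonal-coordination (IC) features.

One feature vector summarizes how much two interlocutors' behaviour and
physiology covaried during one game round:

* pupil-size coordination — mean windowed dynamic-time-warping distance of
  the cleaned, brightness-regressed pupil series (lower = more coordinated);
* gaze coordination — percentage of the round both partners fixated the
  same screen area;
* head-motion coordination — Pearson r of windowed motion energy;
* prosodic coordination — correlations of time-aligned moving averages
  (TAMA) of pitch/intensity plus pair-level differences;
* conversation-structure coordination — turn-taking statistics (turn
  length, response time, pauses, backchannels, interruptions) as pair
  differences and lag-1 turn-by-turn adaptation correlations;
* language style matching (LSM) over eight function-word categories.

Missing features are data, not errors: every absent value carries a reason.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field
from typing import Optional

import numpy as np
import pandas as pd
from numba import njit

from .prep import CleanResult, PupilCleanConfig, clean_pupil, motion_energy, regress_out_brightness
from .types import (
    FEATURE_NAMES,
    FUNCTION_WORD_CATEGORIES,
    PARTICIPANTS,
    DyadSession,
    ICFeatureVector,
    SignalTrace,
    validate_fixations,
    validate_segments,
)

log = logging.getLogger(__name__)

_EPS = 1e-9


@dataclass
class FeatureConfig:
    """Window sizes and thresholds of the IC measures (seconds unless noted)."""

    dtw_window: float = 6.0
    dtw_step: float = 3.0
    motion_window: float = 6.0
    motion_step: int = 1  # samples
    tama_window: float = 25.0
    tama_step: float = 12.5
    lsm_segment: float = 120.0
    backchannel_max: float = 1.0
    interruption_min_overlap: float = 0.5
    pause_min: float = 0.2
    min_joint_windows: int = 5
    min_turn_pairs: int = 4
    #: count a speaker-silent TAMA window as 0 syllables for Speech_Amount
    #: (silent windows are informative for speech amount: one partner is
    #: silent precisely while the other talks).
    speech_amount_zero_fill: bool = True
    pupil_clean: PupilCleanConfig = dc_field(default_factory=PupilCleanConfig)


# ==========================================================================
# Dynamic time warping
# ==========================================================================


@njit(cache=True)
def _dtw_kernel(a: np.ndarray, b: np.ndarray) -> float:  # pragma: no cover - numba
    n, m = a.shape[0], b.shape[0]
    prev = np.empty(m)
    curr = np.empty(m)
    acc = 0.0
    for j in range(m):
        acc += abs(a[0] - b[j])
        prev[j] = acc
    for i in range(1, n):
        curr[0] = prev[0] + abs(a[i] - b[0])
        for j in range(1, m):
            best = prev[j]
            if prev[j - 1] < best:
                best = prev[j - 1]
            if curr[j - 1] < best:
                best = curr[j - 1]
            curr[j] = abs(a[i] - b[j]) + best
        prev, curr = curr, prev
    return prev[m - 1]


def dtw_distance(a: np.ndarray, b: np.ndarray) -> float:
    """Unconstrained DTW alignment cost with absolute (1-D Euclidean) local
    distance: the minimum over monotone warping paths of the summed
    |a_i - b_j| along the path."""
    a = np.ascontiguousarray(a, dtype=np.float64)
    b = np.ascontiguousarray(b, dtype=np.float64)
    if a.size == 0 or b.size == 0:
        raise ValueError("DTW inputs must be non-empty")
    return float(_dtw_kernel(a, b))


def pupil_coordination(
    pupil_a: SignalTrace,
    pupil_b: SignalTrace,
    window: float = 6.0,
    step: float = 3.0,
) -> tuple[float, int]:
    """Mean windowed DTW distance between two preprocessed pupil series.

    Both traces must be uniformly sampled at the same rate (cleaned and
    brightness-regressed).  The distance is computed per window and averaged
    over windows; lower values mean more coordinated pupil dynamics.
    Returns ``(mean_distance, n_windows)``; NaN with 0 windows when less
    than one full joint window is available.
    """
    if abs(pupil_a.rate_hint - pupil_b.rate_hint) > 1e-6:
        raise ValueError("pupil traces must share a sampling rate")
    rate = pupil_a.rate_hint
    n = min(len(pupil_a), len(pupil_b))
    w = int(round(window * rate))
    s = max(1, int(round(step * rate)))
    if n < w:
        return float("nan"), 0
    va, vb = pupil_a.values[:n], pupil_b.values[:n]
    ok = pupil_a.valid[:n] & pupil_b.valid[:n]
    dists = []
    for start in range(0, n - w + 1, s):
        sl = slice(start, start + w)
        if not ok[sl].all():
            continue
        dists.append(dtw_distance(va[sl], vb[sl]))
    if not dists:
        return float("nan"), 0
    return float(np.mean(dists)), len(dists)


# ==========================================================================
# Gaze coordination
# ==========================================================================


def gaze_coordination(
    fix_a: pd.DataFrame, fix_b: pd.DataFrame, round_duration: float
) -> float:
    """Percentage of the round both partners fixate the same AOI.

    Sums the durations of all interval intersections in which both valid
    fixations carry the same AOI label, divides by the round duration and
    scales to percent.
    """
    if round_duration <= 0:
        raise ValueError("round_duration must be positive")
    fix_a = validate_fixations(fix_a)
    fix_b = validate_fixations(fix_b)
    total = 0.0
    a = fix_a[fix_a["valid"].astype(bool)].reset_index(drop=True)
    b = fix_b[fix_b["valid"].astype(bool)].reset_index(drop=True)
    if len(a) == 0 or len(b) == 0:
        log.warning("empty fixation track: gaze coordination 0")
        return 0.0
    i = j = 0
    a_on, a_off, a_aoi = a["onset"].to_numpy(), a["offset"].to_numpy(), a["aoi"].to_numpy()
    b_on, b_off, b_aoi = b["onset"].to_numpy(), b["offset"].to_numpy(), b["aoi"].to_numpy()
    while i < len(a) and j < len(b):
        lo = max(a_on[i], b_on[j], 0.0)
        hi = min(a_off[i], b_off[j], round_duration)
        if hi > lo and a_aoi[i] == b_aoi[j]:
            total += hi - lo
        if a_off[i] <= b_off[j]:
            i += 1
        else:
            j += 1
    return 100.0 * total / round_duration


# ==========================================================================
# Motion coordination
# ==========================================================================


def motion_coordination(energy_a: SignalTrace, energy_b: SignalTrace) -> float:
    """Pearson correlation of the two partners' motion-energy series."""
    n = min(len(energy_a), len(energy_b))
    if n < 3:
        return float("nan")
    return _pearson(energy_a.values[:n], energy_b.values[:n])


def _pearson(x: np.ndarray, y: np.ndarray) -> float:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.std() == 0 or y.std() == 0:
        return float("nan")
    return float(np.corrcoef(x, y)[0, 1])


# ==========================================================================
# TAMA: time-aligned moving averages of prosody
# ==========================================================================


def tama_series(
    segments: pd.DataFrame,
    speaker: str,
    field: str,
    window: float = 25.0,
    step: float = 12.5,
    duration: Optional[float] = None,
) -> np.ndarray:
    """Windowed prosodic series for one speaker on a fixed window grid.

    For ``pitch``/``intensity``/``speech_rate`` each window holds the
    duration-weighted mean of the per-segment value over the speaker's
    speech portions inside the window (for speech rate this equals summed
    syllables over summed speech time).  ``speech_amount`` is the summed
    (duration-prorated) syllable count per window.  Windows without speech
    from the speaker are NaN.
    """
    segments = validate_segments(segments)
    if duration is None:
        duration = float(segments["offset"].max()) if len(segments) else 0.0
    if duration < window:
        raise ValueError(f"session shorter than one {window} s window")
    sub = segments[segments["speaker"] == speaker]
    on = sub["onset"].to_numpy(float)
    off = sub["offset"].to_numpy(float)
    if field == "pitch":
        val = sub["mean_pitch"].to_numpy(float)
    elif field == "intensity":
        val = sub["mean_intensity"].to_numpy(float)
    elif field == "speech_rate":
        val = sub["n_syllables"].to_numpy(float) / np.maximum(off - on, _EPS)
    elif field == "speech_amount":
        val = sub["n_syllables"].to_numpy(float)
    else:
        raise ValueError(f"unknown TAMA field: {field}")
    n_win = int(np.floor((duration - window) / step + 1e-9)) + 1
    out = np.full(n_win, np.nan)
    for k in range(n_win):
        lo, hi = k * step, k * step + window
        portion = np.clip(np.minimum(off, hi) - np.maximum(on, lo), 0.0, None)
        m = portion > 0
        if not m.any():
            continue
        if field == "speech_amount":
            out[k] = float(np.sum(val[m] * portion[m] / (off[m] - on[m])))
        else:
            out[k] = float(np.sum(val[m] * portion[m]) / np.sum(portion[m]))
    return out


def windowed_correlation(
    series_a: np.ndarray, series_b: np.ndarray, min_joint: int = 5
) -> tuple[float, int]:
    """Pearson r over windows where both series are present.

    Returns ``(r, n_joint_windows)``; NaN when fewer than ``min_joint``
    windows contribute or either side is constant.
    """
    a = np.asarray(series_a, dtype=float)
    b = np.asarray(series_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("series must share the window grid")
    m = np.isfinite(a) & np.isfinite(b)
    n = int(m.sum())
    if n < min_joint:
        return float("nan"), n
    return _pearson(a[m], b[m]), n


# ==========================================================================
# Turn detection
# ==========================================================================

TURN_COLUMNS = (
    "speaker",
    "turn_onset",
    "turn_offset",
    "turn_length",
    "response_time",
    "n_pauses",
    "pause_time",
    "n_syllables",
    "interrupted_partner",
)


@dataclass
class TurnDetectionResult:
    turns: pd.DataFrame
    backchannels: pd.DataFrame  # speaker, onset, offset
    interruptions: pd.DataFrame  # speaker (interrupter), time, overlap


def _other(speaker: str) -> str:
    return "B" if speaker == "A" else "A"


def detect_turns(
    segments: pd.DataFrame,
    backchannel_max: float = 1.0,
    interruption_min_overlap: float = 0.5,
    pause_min: float = 0.2,
) -> TurnDetectionResult:
    """Classify speech segments into turns, backchannels and interruptions.

    Rules:

    * a segment shorter than ``backchannel_max`` that lies inside the
      partner's speech, or in a gap between partner segments after which
      the partner (not the producer) speaks next, is a backchannel — it
      never claims the floor and is excluded from turns;
    * maximal runs of consecutive same-speaker segments not broken by a
      partner turn merge into one turn; internal silences of at least
      ``pause_min`` count as pauses, and turn length is speech time only;
    * a turn whose onset overlaps the partner's ongoing turn by at least
      ``interruption_min_overlap`` is an interruption: its response time is
      minus the overlap and the partner's turn is truncated at the
      interrupter's onset;
    * response time is otherwise the silence between the partner's turn
      offset and the own turn onset (first turn: undefined).
    """
    segments = validate_segments(segments)
    segs = segments.reset_index(drop=True)

    # ---- backchannel pass -------------------------------------------------
    is_bc = np.zeros(len(segs), dtype=bool)
    on = segs["onset"].to_numpy(float)
    off = segs["offset"].to_numpy(float)
    spk = segs["speaker"].to_numpy()
    for i in range(len(segs)):
        if off[i] - on[i] >= backchannel_max:
            continue
        partner = _other(spk[i])
        pm = spk == partner
        # fully inside one partner segment
        inside = pm & (on <= on[i] + _EPS) & (off >= off[i] - _EPS)
        if inside.any():
            is_bc[i] = True
            continue
        # in a partner gap: partner spoke last before it and speaks next after it
        before = np.flatnonzero((on < on[i] - _EPS) & (np.arange(len(segs)) != i))
        after = np.flatnonzero(on > on[i] + _EPS)
        prev_ok = before.size > 0 and spk[before[np.argmax(on[before])]] == partner
        next_ok = after.size > 0 and spk[after[np.argmin(on[after])]] == partner
        if prev_ok and next_ok:
            is_bc[i] = True

    backchannels = segs[is_bc][["speaker", "onset", "offset"]].reset_index(drop=True)
    core = segs[~is_bc].reset_index(drop=True)

    # ---- merge same-speaker runs into turns -------------------------------
    raw_turns: list[dict] = []
    for i in range(len(core)):
        row = core.iloc[i]
        if raw_turns and raw_turns[-1]["speaker"] == row["speaker"]:
            t = raw_turns[-1]
            gap = row["onset"] - t["segs"][-1][1]
            if gap >= pause_min:
                t["n_pauses"] += 1
                t["pause_time"] += gap
            t["segs"].append((row["onset"], row["offset"]))
            t["n_syllables"] += float(row["n_syllables"])
        else:
            raw_turns.append(
                {
                    "speaker": row["speaker"],
                    "segs": [(row["onset"], row["offset"])],
                    "n_pauses": 0,
                    "pause_time": 0.0,
                    "n_syllables": float(row["n_syllables"]),
                }
            )

    # ---- response times, interruptions, truncation ------------------------
    rows: list[dict] = []
    inter_rows: list[dict] = []
    for k, t in enumerate(raw_turns):
        onset = t["segs"][0][0]
        offset = t["segs"][-1][1]
        speech = sum(o2 - o1 for o1, o2 in t["segs"])
        rt = np.nan
        interrupted = False
        if k > 0:
            prev = rows[-1]
            overlap = prev["turn_offset"] - onset
            if overlap >= interruption_min_overlap:
                interrupted = True
                rt = -overlap
                inter_rows.append({"speaker": t["speaker"], "time": onset, "overlap": overlap})
                # the interrupted partner loses the floor at the overlap start
                clipped = [(o1, min(o2, onset)) for o1, o2 in prev["_segs"] if o1 < onset]
                new_speech = sum(o2 - o1 for o1, o2 in clipped)
                if prev["turn_length"] > 0:
                    prev["n_syllables"] *= new_speech / prev["turn_length"]
                prev["turn_length"] = new_speech
                prev["turn_offset"] = min(prev["turn_offset"], onset)
            else:
                # sub-threshold overlaps are not interruptions; clip at zero
                rt = max(onset - prev["turn_offset"], 0.0)
        rows.append(
            {
                "speaker": t["speaker"],
                "turn_onset": onset,
                "turn_offset": offset,
                "turn_length": speech,
                "response_time": rt,
                "n_pauses": t["n_pauses"],
                "pause_time": t["pause_time"],
                "n_syllables": t["n_syllables"],
                "interrupted_partner": interrupted,
                "_segs": t["segs"],
            }
        )
    turns = pd.DataFrame(rows, columns=list(TURN_COLUMNS) + ["_segs"]).drop(columns="_segs")
    interruptions = pd.DataFrame(inter_rows, columns=["speaker", "time", "overlap"])
    return TurnDetectionResult(turns, backchannels, interruptions)


# ==========================================================================
# Lag-1 adaptation
# ==========================================================================


def adaptation_crosscorr(
    turns: pd.DataFrame, value_column: str, min_pairs: int = 4
) -> tuple[float, float, float, float, int]:
    """Lag-1 adaptation correlations for a per-turn quantity.

    r(A→B) is the Pearson correlation between A's value on a turn and B's
    value on the immediately following B turn; r(B→A) analogously.  Returns
    ``(mean_r, abs_diff_r, r_ab, r_ba, n_pairs_min)``; NaNs when either
    direction has fewer than ``min_pairs`` usable turn pairs.
    """
    vals = turns[value_column].to_numpy(float)
    spk = turns["speaker"].to_numpy()
    pairs = {"A": ([], []), "B": ([], [])}
    for k in range(len(turns) - 1):
        if spk[k + 1] == spk[k]:
            continue
        x, y = vals[k], vals[k + 1]
        if np.isfinite(x) and np.isfinite(y):
            px, py = pairs[spk[k]]
            px.append(x)
            py.append(y)
    r = {}
    n_min = min(len(pairs["A"][0]), len(pairs["B"][0]))
    for d in ("A", "B"):
        px, py = pairs[d]
        r[d] = _pearson(np.array(px), np.array(py)) if len(px) >= min_pairs else float("nan")
    if not (np.isfinite(r["A"]) and np.isfinite(r["B"])):
        return float("nan"), float("nan"), r["A"], r["B"], n_min
    return (
        float((r["A"] + r["B"]) / 2.0),
        float(abs(r["A"] - r["B"])),
        r["A"],
        r["B"],
        n_min,
    )


# ==========================================================================
# Language style matching
# ==========================================================================


def lsm(counts_a: pd.DataFrame, counts_b: pd.DataFrame) -> float:
    """Composite language style matching between two speakers.

    Inputs are per-2-minute-segment function-word counts (one row per
    segment, one column per category).  Per segment and category,
    ``1 - |x1 - x2| / (x1 + x2 + 0.0001)``; category values are averaged
    into a segment LSM, segment values into the session LSM.
    """
    common = counts_a.index.intersection(counts_b.index)
    if len(common) == 0:
        return float("nan")
    seg_vals = []
    for idx in common:
        x1 = counts_a.loc[idx, list(FUNCTION_WORD_CATEGORIES)].to_numpy(float)
        x2 = counts_b.loc[idx, list(FUNCTION_WORD_CATEGORIES)].to_numpy(float)
        cat = 1.0 - np.abs(x1 - x2) / (x1 + x2 + 0.0001)
        seg_vals.append(float(cat.mean()))
    return float(np.mean(seg_vals))


# ==========================================================================
# Structural features
# ==========================================================================


def structural_features(
    result: TurnDetectionResult,
    segments: pd.DataFrame,
    session_duration: float,
    config: FeatureConfig | None = None,
) -> tuple[dict[str, float], dict[str, str], dict[str, object]]:
    """The 17 conversation-structure entries of the feature vector.

    Per-speaker aggregates (means, SDs, per-minute rates, per-turn ratios)
    become pair-level absolute differences; lag-1 adaptation features come
    from :func:`adaptation_crosscorr`; the speech-rate and speech-amount
    correlations use the TAMA window grid.
    """
    config = config or FeatureConfig()
    turns, bc = result.turns, result.backchannels
    minutes = session_duration / 60.0
    values: dict[str, float] = {}
    missing: dict[str, str] = {}
    prov: dict[str, object] = {}

    stats: dict[str, dict[str, float]] = {}
    for spk in PARTICIPANTS:
        tt = turns[turns["speaker"] == spk]
        if len(tt) == 0:
            stats[spk] = {}
            continue
        tl = tt["turn_length"].to_numpy(float)
        rt = tt["response_time"].to_numpy(float)
        rt = rt[np.isfinite(rt)]
        speech_time = float(tl.sum())
        stats[spk] = {
            "turn_length_mean": float(tl.mean()),
            "turn_length_sd": float(tl.std(ddof=1)) if len(tl) > 1 else 0.0,
            "turn_rate": len(tt) / minutes,
            "response_time_mean": float(rt.mean()) if rt.size else np.nan,
            "speaking_time_rel": speech_time / session_duration,
            "speech_rate": float(tt["n_syllables"].sum()) / max(speech_time, _EPS),
            "pause_per_min": float(tt["n_pauses"].sum()) / minutes,
            "pause_per_speech": float(tt["pause_time"].sum()) / max(speech_time, _EPS),
            "pause_per_turn": float(tt["n_pauses"].sum()) / len(tt),
            "backchannel_rate": float((bc["speaker"] == spk).sum()) / minutes,
            "interrupt_rate": float((result.interruptions["speaker"] == spk).sum()) / minutes,
        }
    prov["n_turns"] = {s: int((turns["speaker"] == s).sum()) for s in PARTICIPANTS}

    diffs = {
        "Speech_Rate_Difference": "speech_rate",
        "Speaking_Time_Difference": "speaking_time_rel",
        "Backchannel_Rate_Difference": "backchannel_rate",
        "Interrupt_Rate_Difference": "interrupt_rate",
        "Pause_per_Minute_Difference": "pause_per_min",
        "Pause_per_Speech_Difference": "pause_per_speech",
        "Pause_per_Turn_Difference": "pause_per_turn",
        "Response_Time_Difference": "response_time_mean",
        "Turn_Length_Difference": "turn_length_mean",
        "Turn_Length_SD_Difference": "turn_length_sd",
        "Turn_Rate_Difference": "turn_rate",
    }
    for feat, key in diffs.items():
        a, b = stats["A"].get(key, np.nan), stats["B"].get(key, np.nan)
        if np.isfinite(a) and np.isfinite(b):
            values[feat] = abs(a - b)
        else:
            values[feat] = np.nan
            missing[feat] = "a speaker has no usable turns"

    for feat_base, col in (("Response_Time", "response_time"), ("Turn_Length", "turn_length")):
        mean_r, diff_r, r_ab, r_ba, n_pairs = adaptation_crosscorr(
            turns, col, min_pairs=config.min_turn_pairs
        )
        values[f"{feat_base}_Adaptation"] = mean_r
        values[f"{feat_base}_Adaptation_Difference"] = diff_r
        prov[f"{feat_base.lower()}_adaptation_pairs"] = n_pairs
        if not np.isfinite(mean_r):
            reason = f"fewer than {config.min_turn_pairs} lag-1 turn pairs (or constant values)"
            missing[f"{feat_base}_Adaptation"] = reason
            missing[f"{feat_base}_Adaptation_Difference"] = reason

    # TAMA-based structural correlations
    for feat, field in (
        ("Speech_Rate_Correlation", "speech_rate"),
        ("Speech_Amount_Correlation", "speech_amount"),
    ):
        try:
            sa = tama_series(segments, "A", field, config.tama_window, config.tama_step, session_duration)
            sb = tama_series(segments, "B", field, config.tama_window, config.tama_step, session_duration)
        except ValueError as exc:
            values[feat] = np.nan
            missing[feat] = str(exc)
            continue
        if field == "speech_amount" and config.speech_amount_zero_fill:
            sa = np.nan_to_num(sa, nan=0.0)
            sb = np.nan_to_num(sb, nan=0.0)
        r, n = windowed_correlation(sa, sb, config.min_joint_windows)
        values[feat] = r
        prov[f"{feat}_windows"] = n
        if not np.isfinite(r):
            missing[feat] = f"fewer than {config.min_joint_windows} joint windows or constant series"
    return values, missing, prov


# ==========================================================================
# Full feature vector
# ==========================================================================


def _weighted_prosody_stats(segments: pd.DataFrame, speaker: str) -> dict[str, float]:
    """Duration-weighted mean and SD of pitch/intensity over a speaker's
    segments."""
    sub = segments[segments["speaker"] == speaker]
    if len(sub) == 0:
        return {}
    w = (sub["offset"] - sub["onset"]).to_numpy(float)
    out = {}
    for field, col in (("pitch", "mean_pitch"), ("intensity", "mean_intensity")):
        x = sub[col].to_numpy(float)
        mu = float(np.average(x, weights=w))
        var = float(np.average((x - mu) ** 2, weights=w))
        out[f"{field}_mean"] = mu
        out[f"{field}_sd"] = float(np.sqrt(var))
    return out


def compute_feature_vector(
    session: DyadSession, config: FeatureConfig | None = None
) -> ICFeatureVector:
    """Compute all 27 IC features for one session.

    Every feature is either a finite value or NaN with a recorded reason;
    provenance (window counts, turn counts, pupil quality) is attached.
    """
    config = config or FeatureConfig()
    values: dict[str, float] = {n: np.nan for n in FEATURE_NAMES}
    missing: dict[str, str] = {}
    prov: dict[str, object] = {}
    duration = session.duration

    # ---- pupil ------------------------------------------------------------
    residuals: dict[str, SignalTrace] = {}
    low_quality = False
    for p in PARTICIPANTS:
        try:
            cleaned: CleanResult = clean_pupil(
                session.pupil[p], session.confidence[p], config.pupil_clean
            )
        except ValueError as exc:
            missing["Pupil_Size_Coordination"] = f"pupil {p}: {exc}"
            low_quality = True
            continue
        prov[f"pupil_invalid_fraction_{p}"] = cleaned.invalid_fraction
        if cleaned.low_quality:
            low_quality = True
            missing["Pupil_Size_Coordination"] = f"pupil {p} low-quality"
            continue
        lum = session.luminance[p]
        n = min(len(cleaned.trace), len(lum))
        residuals[p] = regress_out_brightness(
            SignalTrace(cleaned.trace.t[:n], cleaned.trace.values[:n], cleaned.trace.rate_hint),
            SignalTrace(lum.t[:n], lum.values[:n], lum.rate_hint),
        )
    if not low_quality and len(residuals) == 2:
        d, nw = pupil_coordination(
            residuals["A"], residuals["B"], config.dtw_window, config.dtw_step
        )
        values["Pupil_Size_Coordination"] = d
        prov["dtw_windows"] = nw
        if not np.isfinite(d):
            missing["Pupil_Size_Coordination"] = "less than one full joint DTW window"

    # ---- gaze -------------------------------------------------------------
    try:
        values["Gaze_Coordination"] = gaze_coordination(
            session.fixations["A"], session.fixations["B"], duration
        )
    except ValueError as exc:
        missing["Gaze_Coordination"] = str(exc)

    # ---- motion -----------------------------------------------------------
    try:
        ea = motion_energy(session.velocity["A"], config.motion_window, config.motion_step)
        eb = motion_energy(session.velocity["B"], config.motion_window, config.motion_step)
        r = motion_coordination(ea, eb)
        values["Motion_Coordination"] = r
        if not np.isfinite(r):
            missing["Motion_Coordination"] = "zero variance in a motion-energy series"
    except ValueError as exc:
        missing["Motion_Coordination"] = str(exc)

    # ---- prosody: TAMA correlations and level differences -----------------
    segments = validate_segments(session.segments)
    for feat, field in (("Intensity_Correlation", "intensity"), ("Pitch_Correlation", "pitch")):
        try:
            sa = tama_series(segments, "A", field, config.tama_window, config.tama_step, duration)
            sb = tama_series(segments, "B", field, config.tama_window, config.tama_step, duration)
            r, n = windowed_correlation(sa, sb, config.min_joint_windows)
            values[feat] = r
            prov[f"{feat}_windows"] = n
            if not np.isfinite(r):
                missing[feat] = (
                    f"fewer than {config.min_joint_windows} joint windows or constant series"
                )
        except ValueError as exc:
            values[feat] = np.nan
            missing[feat] = str(exc)

    pstats = {p: _weighted_prosody_stats(segments, p) for p in PARTICIPANTS}
    for feat, key in (
        ("Intensity_Difference", "intensity_mean"),
        ("Intensity_SD_Difference", "intensity_sd"),
        ("Pitch_Difference", "pitch_mean"),
        ("Pitch_SD_Difference", "pitch_sd"),
    ):
        a, b = pstats["A"].get(key), pstats["B"].get(key)
        if a is not None and b is not None:
            values[feat] = abs(a - b)
        else:
            missing[feat] = "a speaker has no speech segments"

    # ---- conversation structure -------------------------------------------
    turn_result = detect_turns(
        segments,
        config.backchannel_max,
        config.interruption_min_overlap,
        config.pause_min,
    )
    svals, smiss, sprov = structural_features(turn_result, segments, duration, config)
    values.update(svals)
    missing.update(smiss)
    prov.update(sprov)

    # ---- LSM --------------------------------------------------------------
    fw = session.funcwords
    if len(fw):
        ca = fw[fw["speaker"] == "A"].set_index("segment_index")
        cb = fw[fw["speaker"] == "B"].set_index("segment_index")
        v = lsm(ca, cb)
        values["LSM"] = v
        prov["lsm_segments"] = int(len(ca.index.intersection(cb.index)))
        if not np.isfinite(v):
            missing["LSM"] = "no joint 2-minute segments"
    else:
        missing["LSM"] = "no function-word counts"

    return ICFeatureVector(values=values, missing=missing, provenance=prov)
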