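"""Core containers for dyadic-session data and coordination features.

A *session* is one pair of interlocutors playing one round of the bargaining
game.  Everything downstream (preprocessing, the 27 interpersonal-coordination
features, pseudo-pair validation, outcome models) operates on these
containers.  Continuous signals are :class:`SignalTrace` objects; interval
data (fixations, speech segments) are plain :class:`pandas.DataFrame` tables
with schema-check helpers so they stay diff-friendly on disk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal, Optional

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field, model_validator

# --------------------------------------------------------------------------
# Fixed vocabularies
# --------------------------------------------------------------------------

#: The six screen areas a fixation can land in during the bargaining game.
AOIS: tuple[str, ...] = (
    "tokens_left",
    "tokens_right",
    "sell_area",
    "buy_area",
    "bargain_button",
    "partner_face",
)

CONDITIONS: tuple[str, ...] = ("Baseline", "Unfamiliar", "Unimodal")

PARTICIPANTS: tuple[str, str] = ("A", "B")

#: Function-word categories entering language style matching.
FUNCTION_WORD_CATEGORIES: tuple[str, ...] = (
    "personal_pronouns",
    "impersonal_pronouns",
    "conjunctions",
    "adverbs",
    "articles",
    "auxiliary_words",
    "negations",
    "quantifiers",
)

#: The 27 dyad-level interpersonal-coordination features, in canonical order.
FEATURE_NAMES: tuple[str, ...] = (
    "Pupil_Size_Coordination",
    "Gaze_Coordination",
    "Motion_Coordination",
    "Intensity_Correlation",
    "Intensity_Difference",
    "Intensity_SD_Difference",
    "Pitch_Correlation",
    "Pitch_Difference",
    "Pitch_SD_Difference",
    "Speech_Rate_Correlation",
    "Speech_Rate_Difference",
    "Speech_Amount_Correlation",
    "Speaking_Time_Difference",
    "Backchannel_Rate_Difference",
    "Interrupt_Rate_Difference",
    "Pause_per_Minute_Difference",
    "Pause_per_Speech_Difference",
    "Pause_per_Turn_Difference",
    "Response_Time_Adaptation_Difference",
    "Response_Time_Adaptation",
    "Response_Time_Difference",
    "Turn_Length_Adaptation_Difference",
    "Turn_Length_Adaptation",
    "Turn_Length_Difference",
    "Turn_Length_SD_Difference",
    "Turn_Rate_Difference",
    "LSM",
)

#: Pearson-type features: Fisher Z-transformed before statistics.
CORRELATION_FEATURES: frozenset[str] = frozenset(
    {
        "Motion_Coordination",
        "Intensity_Correlation",
        "Pitch_Correlation",
        "Speech_Rate_Correlation",
        "Speech_Amount_Correlation",
        "Response_Time_Adaptation",
        "Turn_Length_Adaptation",
    }
)

#: Absolute-difference (and time-like) features: log-transformed.
DIFFERENCE_FEATURES: frozenset[str] = frozenset(
    n for n in FEATURE_NAMES if n.endswith("_Difference")
)

#: Default one-tailed direction for the real-vs-pseudo permutation test:
#: coordination pushes correlations, the gaze ratio and LSM up, and pushes
#: distances/differences down.  Speech_Amount_Correlation is pushed *down*
#: in real pairs by the turn-taking structure (one talks while the other is
#: silent), hence real_smaller.
DEFAULT_DIRECTIONS: dict[str, str] = {
    **{n: "real_smaller" for n in DIFFERENCE_FEATURES},
    "Pupil_Size_Coordination": "real_smaller",
    "Speech_Amount_Correlation": "real_smaller",
    "Gaze_Coordination": "real_greater",
    "Motion_Coordination": "real_greater",
    "Intensity_Correlation": "real_greater",
    "Pitch_Correlation": "real_greater",
    "Speech_Rate_Correlation": "real_greater",
    "Response_Time_Adaptation": "real_greater",
    "Turn_Length_Adaptation": "real_greater",
    "LSM": "real_greater",
}


# --------------------------------------------------------------------------
# Continuous signals
# --------------------------------------------------------------------------


@dataclass
class SignalTrace:
    """A timestamped 1-D measurement series with per-sample validity.

    Parameters
    ----------
    t : array of float
        Timestamps in seconds from round start, strictly increasing.
    values : array of float
        Measurement values (mm for pupil diameter, a.u. for luminance,
        units/s for head velocity).  Must be finite wherever ``valid``.
    rate_hint : float
        Nominal sampling rate in Hz.
    valid : bool array, optional
        Per-sample validity mask; defaults to all-valid.
    """

    t: np.ndarray
    values: np.ndarray
    rate_hint: float
    valid: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.t = np.asarray(self.t, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.t.shape, dtype=bool)
        self.valid = np.asarray(self.valid, dtype=bool)
        if self.t.ndim != 1 or self.t.shape != self.values.shape:
            raise ValueError("t and values must be 1-D arrays of equal length")
        if self.t.size and np.any(np.diff(self.t) <= 0):
            raise ValueError("timestamps must be strictly increasing")
        if self.valid.shape != self.t.shape:
            raise ValueError("valid mask must match t")
        if np.any(~np.isfinite(self.values[self.valid])):
            raise ValueError("values must be finite where valid")

    def __len__(self) -> int:
        return self.t.size

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if self.t.size else 0.0

    def copy(self) -> "SignalTrace":
        return SignalTrace(self.t.copy(), self.values.copy(), self.rate_hint, self.valid.copy())

    def resample_uniform(self, rate: Optional[float] = None) -> "SignalTrace":
        """Linear-interpolate onto a uniform grid at ``rate`` Hz.

        Windowed operations assume uniform sampling; irregular traces are
        regridded first.  Invalid samples do not contribute to the
        interpolation; grid points with no valid neighbour on one side take
        the nearest valid value.
        """
        rate = rate or self.rate_hint
        if self.t.size < 2:
            return self.copy()
        n = int(np.floor((self.t[-1] - self.t[0]) * rate)) + 1
        grid = self.t[0] + np.arange(n) / rate
        if not self.valid.any():
            return SignalTrace(grid, np.zeros(n), rate, np.zeros(n, dtype=bool))
        vals = np.interp(grid, self.t[self.valid], self.values[self.valid])
        # a grid point is valid if its nearest original sample is valid
        idx = np.searchsorted(self.t, grid)
        idx = np.clip(idx, 0, self.t.size - 1)
        left = np.clip(idx - 1, 0, self.t.size - 1)
        nearest = np.where(
            np.abs(self.t[idx] - grid) <= np.abs(grid - self.t[left]), idx, left
        )
        return SignalTrace(grid, vals, rate, self.valid[nearest])


# --------------------------------------------------------------------------
# Interval tables
# --------------------------------------------------------------------------

FIXATION_COLUMNS = ("onset", "offset", "aoi", "valid")
SEGMENT_COLUMNS = ("speaker", "onset", "offset", "mean_pitch", "mean_intensity", "n_syllables")


def validate_fixations(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a fixation track: sorted, non-overlapping, known AOIs."""
    missing = set(FIXATION_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"fixation table missing columns: {sorted(missing)}")
    if len(df) == 0:
        return df.reset_index(drop=True)
    if (df["offset"] <= df["onset"]).any():
        bad = int(np.argmax((df["offset"] <= df["onset"]).to_numpy()))
        raise ValueError(f"fixation row {bad}: offset <= onset")
    unknown = set(df["aoi"]) - set(AOIS)
    if unknown:
        raise ValueError(f"unknown AOI labels: {sorted(unknown)}")
    df = df.sort_values("onset", kind="stable").reset_index(drop=True)
    if (df["onset"].to_numpy()[1:] < df["offset"].to_numpy()[:-1] - 1e-9).any():
        raise ValueError("fixation intervals overlap")
    return df


def validate_segments(df: pd.DataFrame) -> pd.DataFrame:
    """Schema check for a speech-segment table.

    Same-speaker segments must not overlap; cross-speaker overlap is real
    conversational behaviour (interruptions, backchannels) and is allowed.
    """
    missing = set(SEGMENT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"segment table missing columns: {sorted(missing)}")
    if len(df) == 0:
        return df.reset_index(drop=True)
    unknown = set(df["speaker"]) - set(PARTICIPANTS)
    if unknown:
        raise ValueError(f"unknown speakers: {sorted(unknown)}")
    if (df["offset"] <= df["onset"]).any():
        bad = int(np.argmax((df["offset"] <= df["onset"]).to_numpy()))
        raise ValueError(f"segment row {bad}: offset <= onset")
    df = df.sort_values(["onset", "offset"], kind="stable").reset_index(drop=True)
    for spk in PARTICIPANTS:
        sub = df[df["speaker"] == spk]
        on = sub["onset"].to_numpy()
        off = sub["offset"].to_numpy()
        if on.size > 1 and (on[1:] < off[:-1] - 1e-9).any():
            raise ValueError(f"same-speaker segments overlap for speaker {spk}")
    return df


# --------------------------------------------------------------------------
# Metadata, coupling and ground truth (simulation inputs)
# --------------------------------------------------------------------------


class SessionMetadata(BaseModel):
    pair_id: str
    condition: Literal["Baseline", "Unfamiliar", "Unimodal"]
    bg_round: int = Field(ge=1, le=4)
    time_before_bg_round: float = Field(ge=0.0)
    mean_age: float = 21.4
    age_difference: float = Field(default=2.0, ge=0.0)
    gender: Literal["female", "male"] = "female"
    handedness: Literal["left", "right", "mixed"] = "right"

    @model_validator(mode="after")
    def _first_round_starts_at_zero(self) -> "SessionMetadata":
        if self.bg_round == 1 and self.time_before_bg_round != 0.0:
            raise ValueError("time_before_bg_round must be 0 when bg_round is 1")
        return self


class CouplingConfig(BaseModel):
    """Cross-partner coupling knobs of the synthetic-dyad generator.

    Each knob targets the coordination feature(s) built to detect it; all
    zero yields statistically independent partners (apart from the shared
    task context such as screen luminance).
    """

    pupil_coupling: float = Field(default=0.0, ge=0.0)
    gaze_follow_prob: float = Field(default=0.0, ge=0.0, le=1.0)
    motion_coupling: float = Field(default=0.0, ge=0.0)
    prosody_coupling: float = Field(default=0.0, ge=0.0)
    turn_adaptation: float = Field(default=0.0, gt=-1.0, lt=1.0)
    lsm_overlap: float = Field(default=0.0, ge=0.0, le=1.0)
    seed: int = 0


class GroundTruth(BaseModel):
    """Generative truth stored with every simulated cohort, never consumed
    by the analysis stages (it exists so parameter recovery can be scored)."""

    outcome_betas: dict[str, float] = Field(default_factory=dict)
    random_intercept_sd: float = Field(default=0.5, ge=0.0)
    residual_sd: float = Field(default=1.0, ge=0.0)
    coupling: CouplingConfig = Field(default_factory=CouplingConfig)


# --------------------------------------------------------------------------
# The session bundle
# --------------------------------------------------------------------------


@dataclass
class DyadSession:
    """All derived signals for one pair in one bargaining-game round."""

    metadata: SessionMetadata
    duration: float
    pupil: dict[str, SignalTrace]
    confidence: dict[str, SignalTrace]
    luminance: dict[str, SignalTrace]
    fixations: dict[str, pd.DataFrame]
    velocity: dict[str, SignalTrace]
    segments: pd.DataFrame
    funcwords: pd.DataFrame
    gamelog: dict
    questionnaire: pd.DataFrame = field(default_factory=pd.DataFrame)


@dataclass
class ICFeatureVector:
    """The 27 coordination features for one session.

    ``values`` holds a float (or NaN) per feature name; a NaN value carries
    a reason string in ``missing``.  ``provenance`` records the window and
    turn counts behind each estimate.
    """

    values: dict[str, float]
    missing: dict[str, str] = field(default_factory=dict)
    provenance: dict[str, object] = field(default_factory=dict)

    def __getitem__(self, name: str) -> float:
        return self.values[name]

    def as_series(self) -> pd.Series:
        return pd.Series({n: self.values.get(n, np.nan) for n in FEATURE_NAMES})
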