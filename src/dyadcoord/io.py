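"""Session-bundle schema, readers/writers, run configuration and the
pipeline that chains the stages.

A session bundle is a directory of plain CSV/JSON files (UTF-8, "." decimal,
seconds from round start, empty fields for missing values)::

    metadata.json                  # SessionMetadata + duration
    A_pupil.csv      B_pupil.csv   # t, diameter, confidence
    A_luminance.csv  B_luminance.csv
    A_fixations.csv  B_fixations.csv   # onset, offset, aoi, valid
    A_velocity.csv   B_velocity.csv    # t, v
    segments.csv                   # speaker, onset, offset, pitch, intensity, syllables
    funcwords.csv                  # speaker, segment_index, 8 category columns
    gamelog.json
    questionnaire.csv              # participant, item, response

Every pipeline output embeds the config hash and seed that produced it.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd
from pydantic import BaseModel, Field

from . import models as om
from . import validation as pv
from .features import FeatureConfig, compute_feature_vector
from .prep import PupilCleanConfig
from .types import (
    AOIS,
    FEATURE_NAMES,
    FUNCTION_WORD_CATEGORIES,
    DyadSession,
    SessionMetadata,
    SignalTrace,
)

log = logging.getLogger(__name__)

RATE_DEFAULT = 120.0


class BundleError(ValueError):
    """Raised when a session bundle violates its schema; carries a list of
    located violations (file, row, field, message)."""

    def __init__(self, violations: list[str]):
        self.violations = violations
        super().__init__("; ".join(violations))


class RunConfig(BaseModel):
    """All analysis parameters, serialized with every output."""

    # windows (seconds)
    dtw_window: float = 6.0
    dtw_step: float = 3.0
    motion_window: float = 6.0
    motion_step: int = 1  # samples
    tama_window: float = 25.0
    tama_step: float = 12.5
    lsm_segment: float = 120.0
    # conversation thresholds (seconds)
    backchannel_max: float = 1.0
    interruption_min_overlap: float = 0.5
    pause_min: float = 0.2
    # minimum-data rules
    min_joint_windows: int = 5
    min_turn_pairs: int = 4
    # statistics
    alpha: float = 0.05
    n_perm: int = 100_000
    lasso_folds: int = 5
    lasso_repeats: int = 11
    rf_trees: int = 500
    rf_folds: int = 10
    direction_overrides: dict[str, str] = Field(default_factory=dict)
    seed: int = 0

    def feature_config(self) -> FeatureConfig:
        return FeatureConfig(
            dtw_window=self.dtw_window,
            dtw_step=self.dtw_step,
            motion_window=self.motion_window,
            motion_step=self.motion_step,
            tama_window=self.tama_window,
            tama_step=self.tama_step,
            lsm_segment=self.lsm_segment,
            backchannel_max=self.backchannel_max,
            interruption_min_overlap=self.interruption_min_overlap,
            pause_min=self.pause_min,
            min_joint_windows=self.min_joint_windows,
            min_turn_pairs=self.min_turn_pairs,
            pupil_clean=PupilCleanConfig(),
        )

    def config_hash(self) -> str:
        return hashlib.sha256(self.model_dump_json().encode()).hexdigest()[:16]


# ==========================================================================
# Writing
# ==========================================================================


def write_bundle(session: DyadSession, path: str | Path) -> Path:
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    meta = {**session.metadata.model_dump(), "duration": session.duration}
    (path / "metadata.json").write_text(json.dumps(meta, indent=1, sort_keys=True))
    for p in ("A", "B"):
        pd.DataFrame(
            {
                "t": session.pupil[p].t,
                "diameter": session.pupil[p].values,
                "confidence": session.confidence[p].values,
            }
        ).to_csv(path / f"{p}_pupil.csv", index=False, float_format="%.17g")
        pd.DataFrame({"t": session.luminance[p].t, "value": session.luminance[p].values}).to_csv(
            path / f"{p}_luminance.csv", index=False, float_format="%.17g"
        )
        session.fixations[p].to_csv(path / f"{p}_fixations.csv", index=False, float_format="%.17g")
        pd.DataFrame({"t": session.velocity[p].t, "v": session.velocity[p].values}).to_csv(
            path / f"{p}_velocity.csv", index=False, float_format="%.17g"
        )
    seg = session.segments.rename(
        columns={"mean_pitch": "pitch", "mean_intensity": "intensity", "n_syllables": "syllables"}
    )
    seg.to_csv(path / "segments.csv", index=False, float_format="%.17g")
    session.funcwords.to_csv(path / "funcwords.csv", index=False)
    (path / "gamelog.json").write_text(json.dumps(session.gamelog, indent=1, sort_keys=True))
    session.questionnaire.to_csv(path / "questionnaire.csv", index=False)
    return path


def write_cohort(sessions: list[DyadSession], root: str | Path, truth=None) -> Path:
    root = Path(root)
    for s in sessions:
        write_bundle(s, root / f"{s.metadata.pair_id}_r{s.metadata.bg_round}")
    if truth is not None:
        (root / "ground_truth.json").write_text(truth.model_dump_json(indent=1))
    return root


# ==========================================================================
# Reading
# ==========================================================================


def _read_csv(path: Path, required: tuple[str, ...], errors: list[str]) -> pd.DataFrame | None:
    if not path.exists():
        errors.append(f"{path.name}: file missing")
        return None
    df = pd.read_csv(path, float_precision="round_trip")
    missing = set(required) - set(df.columns)
    if missing:
        errors.append(f"{path.name}: missing columns {sorted(missing)}")
        return None
    return df


def _check_intervals(df: pd.DataFrame, name: str, errors: list[str]) -> None:
    bad = np.flatnonzero((df["offset"].to_numpy() <= df["onset"].to_numpy()))
    for row in bad[:5]:
        errors.append(f"{name}: row {row}: field offset: offset <= onset")


def read_bundle(path: str | Path, rate: float = RATE_DEFAULT) -> DyadSession:
    """Read and validate a session bundle; raises :class:`BundleError`
    listing every schema violation found (file, row, field)."""
    path = Path(path)
    errors: list[str] = []
    meta_file = path / "metadata.json"
    if not meta_file.exists():
        raise BundleError([f"{meta_file.name}: file missing"])
    try:
        meta = json.loads(meta_file.read_text())
        duration = float(meta.pop("duration"))
        metadata = SessionMetadata(**meta)
    except Exception as exc:
        raise BundleError([f"metadata.json: {exc}"]) from exc

    pupil, conf, lum, vel, fix = {}, {}, {}, {}, {}
    for p in ("A", "B"):
        df = _read_csv(path / f"{p}_pupil.csv", ("t", "diameter", "confidence"), errors)
        if df is not None:
            pupil[p] = SignalTrace(df["t"], df["diameter"], rate)
            conf[p] = SignalTrace(df["t"], df["confidence"], rate)
        df = _read_csv(path / f"{p}_luminance.csv", ("t", "value"), errors)
        if df is not None:
            lum[p] = SignalTrace(df["t"], df["value"], rate)
        df = _read_csv(path / f"{p}_fixations.csv", ("onset", "offset", "aoi", "valid"), errors)
        if df is not None:
            _check_intervals(df, f"{p}_fixations.csv", errors)
            unknown = set(df["aoi"]) - set(AOIS)
            if unknown:
                errors.append(f"{p}_fixations.csv: field aoi: unknown labels {sorted(unknown)}")
            fix[p] = df
        df = _read_csv(path / f"{p}_velocity.csv", ("t", "v"), errors)
        if df is not None:
            vel[p] = SignalTrace(df["t"], df["v"], rate)
    seg = _read_csv(
        path / "segments.csv", ("speaker", "onset", "offset", "pitch", "intensity", "syllables"), errors
    )
    if seg is not None:
        _check_intervals(seg, "segments.csv", errors)
        unknown = set(seg["speaker"]) - {"A", "B"}
        if unknown:
            errors.append(f"segments.csv: field speaker: unknown {sorted(unknown)}")
        seg = seg.rename(
            columns={"pitch": "mean_pitch", "intensity": "mean_intensity", "syllables": "n_syllables"}
        )
    fw = _read_csv(path / "funcwords.csv", ("speaker", "segment_index", *FUNCTION_WORD_CATEGORIES), errors)
    game_file = path / "gamelog.json"
    gamelog = None
    if game_file.exists():
        try:
            gamelog = json.loads(game_file.read_text())
        except Exception as exc:
            errors.append(f"gamelog.json: {exc}")
    else:
        errors.append("gamelog.json: file missing")
    quest = _read_csv(path / "questionnaire.csv", ("participant", "item", "response"), errors)
    if errors:
        raise BundleError(errors)
    return DyadSession(
        metadata=metadata,
        duration=duration,
        pupil=pupil,
        confidence=conf,
        luminance=lum,
        fixations=fix,
        velocity=vel,
        segments=seg,
        funcwords=fw,
        gamelog=gamelog,
        questionnaire=quest,
    )


def read_cohort(root: str | Path) -> tuple[list[DyadSession], dict[str, list[str]]]:
    """Read all bundles under ``root``; corrupt bundles are reported, not
    fatal."""
    root = Path(root)
    sessions, problems = [], {}
    for d in sorted(p for p in root.iterdir() if p.is_dir()):
        try:
            sessions.append(read_bundle(d))
        except BundleError as exc:
            problems[d.name] = exc.violations
            log.error("bundle %s rejected: %s", d.name, exc.violations[:3])
    return sessions, problems


# ==========================================================================
# Pipeline
# ==========================================================================


def _stamp(config: RunConfig) -> str:
    return f"# config_hash={config.config_hash()} seed={config.seed}\n"


def _write_csv(df: pd.DataFrame, path: Path, config: RunConfig) -> None:
    with open(path, "w") as fh:
        fh.write(_stamp(config))
        df.to_csv(fh, index=False)


def feature_table(
    sessions: list[DyadSession], config: FeatureConfig | None = None
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Features (one row per pair x round) plus the missingness sidecar."""
    rows, miss = [], []
    for s in sessions:
        fv = compute_feature_vector(s, config)
        rows.append({"pair_id": s.metadata.pair_id, "bg_round": s.metadata.bg_round, **fv.values})
        for feat, reason in fv.missing.items():
            miss.append(
                {
                    "pair_id": s.metadata.pair_id,
                    "bg_round": s.metadata.bg_round,
                    "feature": feat,
                    "reason": reason,
                }
            )
    return pd.DataFrame(rows), pd.DataFrame(miss, columns=["pair_id", "bg_round", "feature", "reason"])


def run_pipeline(cohort_dir: str | Path, out_dir: str | Path, config: RunConfig | None = None) -> dict:
    """Run the full analysis on a directory of session bundles.

    Produces ``features.csv`` (+ missingness log), ``validation.csv``
    (real-vs-pseudo tests), per-outcome model JSONs under ``models/`` and
    classification JSONs under ``classification/``.  Deterministic given
    the config seed.
    """
    config = config or RunConfig()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings = {}
    sessions, problems = read_cohort(cohort_dir)
    if problems:
        (out / "bundle_problems.json").write_text(json.dumps(problems, indent=1))
    if not sessions:
        raise RuntimeError("no readable session bundles")
    timings["read"] = time.time() - t0

    fc = config.feature_config()
    feats, missing = feature_table(sessions, fc)
    _write_csv(feats, out / "features.csv", config)
    _write_csv(missing, out / "missingness.csv", config)
    timings["features"] = time.time() - t0

    pairs = pv.make_pseudo_pairs(sessions, seed=config.seed)
    pseudo = pv.pseudo_feature_table(sessions, pairs, fc)
    results, survivors = pv.validate_features(
        feats,
        pseudo,
        direction_map=config.direction_overrides,
        alpha=config.alpha,
        n_perm=config.n_perm,
        seed=config.seed,
    )
    _write_csv(pv.results_table(results), out / "validation.csv", config)
    timings["validation"] = time.time() - t0

    # outcomes and two-step models
    meta_rows = []
    for s in sessions:
        md = s.metadata
        meta_rows.append(
            {
                "pair_id": md.pair_id,
                "bg_round": md.bg_round,
                "BG_Round": md.bg_round,
                "Condition": md.condition,
                "Time_before_BG_Round": md.time_before_bg_round,
                "Mean_Age": md.mean_age,
                "Age_Difference": md.age_difference,
                "Gender": md.gender,
                "Handedness": md.handedness,
                **om.compute_objective_outcomes(s.gamelog),
                **om.aggregate_subjective(s.questionnaire),
            }
        )
    meta = pd.DataFrame(meta_rows)
    table = feats.merge(meta, on=["pair_id", "bg_round"])
    predictors = table[survivors + ["BG_Round", "Time_before_BG_Round", "Mean_Age", "Age_Difference"]]
    predictors, _ = om.transform_predictors(predictors)
    # categorical manipulations/demographics as dummies
    for col in ("Condition", "Gender", "Handedness"):
        d = pd.get_dummies(table[col], prefix=col, drop_first=True, dtype=float)
        predictors = pd.concat([predictors, d], axis=1)

    (out / "models").mkdir(exist_ok=True)
    edges = []
    outcome_names = [
        "Mean_Wealth_Increase",
        "Difference_in_Wealth_Increase",
        "Mean_Goal_Time",
        "Difference_in_Goal_Time",
        "Total_Time",
        *om.SUBJECTIVE_ITEMS,
    ]
    for name in outcome_names:
        y = table[name]
        if y.notna().sum() < 3 * config.lasso_folds:
            continue
        res = om.model_outcome(
            predictors,
            y,
            table["pair_id"],
            outcome=name,
            folds=config.lasso_folds,
            repeats=config.lasso_repeats,
            seed=config.seed,
        )
        payload = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            **dataclasses.asdict(res),
        }
        (out / "models" / f"{name}.json").write_text(json.dumps(payload, indent=1, default=float))
        for pred in res.selected_predictors:
            est, p = res.coefficients.get(pred, (np.nan, np.nan))
            if p < config.alpha:
                edges.append(
                    {
                        "predictor": pred,
                        "outcome": name,
                        "sign": "+" if est > 0 else "-",
                        "f2": res.f2.get(pred, np.nan),
                    }
                )
    _write_csv(pd.DataFrame(edges, columns=["predictor", "outcome", "sign", "f2"]),
               out / "network_edges.csv", config)
    timings["models"] = time.time() - t0

    # condition / difficulty classification on the full IC set
    (out / "classification").mkdir(exist_ok=True)
    ic = feats[[c for c in FEATURE_NAMES if c in feats.columns]]
    ic_t, _ = om.transform_predictors(ic)
    ic_t = ic_t.fillna(ic_t.mean(numeric_only=True))
    cond = table["Condition"].to_numpy()
    contrasts = []
    for other in ("Unfamiliar", "Unimodal"):
        mask = np.isin(cond, ["Baseline", other])
        if len(np.unique(cond[mask])) == 2:
            contrasts.append((f"Baseline_vs_{other}", mask, cond))
    rounds = table["BG_Round"].to_numpy()
    if len(np.unique(rounds)) > 1:
        contrasts.append(("BG_Round", np.ones(len(table), dtype=bool), rounds.astype(str)))
    for cname, mask, labels in contrasts:
        res = om.rf_classify(
            ic_t[mask],
            labels[mask],
            contrast=cname,
            seed=config.seed,
            n_trees=config.rf_trees,
            folds=config.rf_folds,
        )
        payload = {
            "config_hash": config.config_hash(),
            "seed": config.seed,
            **dataclasses.asdict(res),
        }
        (out / "classification" / f"{cname}.json").write_text(
            json.dumps(payload, indent=1, default=float)
        )
    timings["classification"] = time.time() - t0
    (out / "run_info.json").write_text(
        json.dumps(
            {
                "config_hash": config.config_hash(),
                "seed": config.seed,
                "config": config.model_dump(),
                "n_sessions": len(sessions),
                "survivors": survivors,
                "timings_s": {k: round(v, 2) for k, v in timings.items()},
            },
            indent=1,
        )
    )
    return {"survivors": survivors, "n_sessions": len(sessions), "problems": problems}
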