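"""Pseudo-pair construction and permutation validation of the IC features.

A coordination measure is only trusted if real pairs differ from *pseudo
pairs* — artificial dyads assembled from two participants who never
interacted but played the same game round in the same condition.  Pseudo
pairs share all contextual commonalities (task, round, condition) with real
pairs, so a real-vs-pseudo difference isolates coordination caused by the
actual interaction.  Each feature is compared with a one-tailed permutation
t-test in its hypothesized direction; Holm's step-down correction controls
the family-wise error rate, and only surviving features enter the outcome
models.
"""

from __future__ import annotations

import itertools
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .features import FeatureConfig, compute_feature_vector
from .models import transform_predictors
from .types import (
    DEFAULT_DIRECTIONS,
    FEATURE_NAMES,
    DyadSession,
    SessionMetadata,
    SignalTrace,
)

log = logging.getLogger(__name__)


# ==========================================================================
# Pseudo-pair construction
# ==========================================================================


@dataclass
class PseudoPairSet:
    """Admissible cross-pair matchings per (condition, round) stratum."""

    pairs: pd.DataFrame  # pair_id_1, role_1, pair_id_2, role_2, condition, bg_round
    seed: int

    def __len__(self) -> int:
        return len(self.pairs)


def _session_key(s: DyadSession) -> tuple[str, int]:
    return (s.metadata.condition, s.metadata.bg_round)


def make_pseudo_pairs(
    sessions: list[DyadSession],
    n_per_stratum: int | None = None,
    seed: int = 0,
) -> PseudoPairSet:
    """Draw random admissible pseudo pairings, stratified by condition and
    round.

    Within each stratum a random perfect matching over the participants is
    drawn, rejecting matchings that pair two members of the same real pair;
    each participant is used at most once per draw.  The default number of
    pseudo pairs per stratum equals the number of real pairs in it
    (balanced real/pseudo groups).  Strata with fewer than two real pairs
    are skipped with a warning.
    """
    rng = np.random.default_rng(seed)
    strata: dict[tuple[str, int, str], list[tuple[str, str]]] = {}
    for s in sessions:
        # gender joins the stratum key: the study design pairs same-gender
        # interlocutors, so an admissible pseudo pair must be same-gender too
        # (a cross-gender pseudo pair would differ from real pairs in pitch
        # for reasons unrelated to interaction)
        key = (*_session_key(s), s.metadata.gender)
        strata.setdefault(key, [])
        for role in ("A", "B"):
            strata[key].append((s.metadata.pair_id, role))
    rows = []
    for (cond, rnd, _gender), members in sorted(strata.items()):
        n_real = len(members) // 2
        if n_real < 2:
            log.warning("stratum (%s, round %d): fewer than 2 real pairs, skipped", cond, rnd)
            continue
        want = n_per_stratum if n_per_stratum is not None else n_real
        matching = None
        for _ in range(200):
            perm = rng.permutation(len(members))
            cand = [(members[perm[2 * i]], members[perm[2 * i + 1]]) for i in range(n_real)]
            if all(m1[0] != m2[0] for m1, m2 in cand):
                matching = cand
                break
        if matching is None:  # degenerate stratum; greedy fallback
            pool = [members[i] for i in rng.permutation(len(members))]
            matching = []
            while len(pool) > 1:
                first = pool.pop(0)
                j = next((k for k, m in enumerate(pool) if m[0] != first[0]), None)
                if j is None:
                    break
                matching.append((first, pool.pop(j)))
        for m1, m2 in matching[:want]:
            rows.append(
                {
                    "pair_id_1": m1[0],
                    "role_1": m1[1],
                    "pair_id_2": m2[0],
                    "role_2": m2[1],
                    "condition": cond,
                    "bg_round": rnd,
                }
            )
    df = pd.DataFrame(
        rows, columns=["pair_id_1", "role_1", "pair_id_2", "role_2", "condition", "bg_round"]
    )
    return PseudoPairSet(df, seed)


def _truncate_trace(trace: SignalTrace, duration: float) -> SignalTrace:
    n = int(np.searchsorted(trace.t, duration, side="right"))
    return SignalTrace(trace.t[:n].copy(), trace.values[:n].copy(), trace.rate_hint, trace.valid[:n].copy())


def _clip_intervals(df: pd.DataFrame, duration: float) -> pd.DataFrame:
    out = df[df["onset"] < duration].copy()
    out["offset"] = out["offset"].clip(upper=duration)
    return out.reset_index(drop=True)


def assemble_pseudo_session(
    s1: DyadSession, role1: str, s2: DyadSession, role2: str
) -> DyadSession:
    """Build the artificial dyad of two single-sided recordings.

    Member 1 becomes participant A and member 2 participant B; all signals
    are truncated to the shorter session, and the two speakers' segment
    tables are merged as if they had been conversing.
    """
    duration = min(s1.duration, s2.duration)
    members = {"A": (s1, role1), "B": (s2, role2)}
    pupil, conf, lum, vel, fix = {}, {}, {}, {}, {}
    seg_parts, fw_parts = [], []
    n_lsm_seg = int(duration // 120)
    for new_role, (sess, old_role) in members.items():
        pupil[new_role] = _truncate_trace(sess.pupil[old_role], duration)
        conf[new_role] = _truncate_trace(sess.confidence[old_role], duration)
        lum[new_role] = _truncate_trace(sess.luminance[old_role], duration)
        vel[new_role] = _truncate_trace(sess.velocity[old_role], duration)
        fix[new_role] = _clip_intervals(sess.fixations[old_role], duration)
        seg = sess.segments[sess.segments["speaker"] == old_role]
        seg = _clip_intervals(seg, duration)
        seg = seg.assign(speaker=new_role)
        seg_parts.append(seg)
        fw = sess.funcwords
        fw = fw[(fw["speaker"] == old_role) & (fw["segment_index"] < n_lsm_seg)]
        fw_parts.append(fw.assign(speaker=new_role))
    segments = (
        pd.concat(seg_parts, ignore_index=True)
        .sort_values(["onset", "offset"], kind="stable")
        .reset_index(drop=True)
    )
    meta = SessionMetadata(
        pair_id=f"PSEUDO_{s1.metadata.pair_id}{role1}_{s2.metadata.pair_id}{role2}",
        condition=s1.metadata.condition,
        bg_round=s1.metadata.bg_round,
        time_before_bg_round=s1.metadata.time_before_bg_round if s1.metadata.bg_round > 1 else 0.0,
        mean_age=(s1.metadata.mean_age + s2.metadata.mean_age) / 2,
        age_difference=abs(s1.metadata.mean_age - s2.metadata.mean_age),
        gender=s1.metadata.gender,
        handedness=s1.metadata.handedness,
    )
    return DyadSession(
        metadata=meta,
        duration=duration,
        pupil=pupil,
        confidence=conf,
        luminance=lum,
        fixations=fix,
        velocity=vel,
        segments=segments,
        funcwords=pd.concat(fw_parts, ignore_index=True),
        gamelog=s1.gamelog,
        questionnaire=s1.questionnaire,
    )


def pseudo_feature(
    pairing: pd.Series,
    sessions_by_key: dict[tuple[str, int, str], DyadSession],
    config: FeatureConfig | None = None,
):
    """Feature vector of one pseudo pairing, computed exactly as for real
    pairs."""
    key1 = (pairing["condition"], pairing["bg_round"], pairing["pair_id_1"])
    key2 = (pairing["condition"], pairing["bg_round"], pairing["pair_id_2"])
    pseudo = assemble_pseudo_session(
        sessions_by_key[key1], pairing["role_1"], sessions_by_key[key2], pairing["role_2"]
    )
    return compute_feature_vector(pseudo, config)


def pseudo_feature_table(
    sessions: list[DyadSession],
    pairs: PseudoPairSet,
    config: FeatureConfig | None = None,
) -> pd.DataFrame:
    lookup = {
        (s.metadata.condition, s.metadata.bg_round, s.metadata.pair_id): s for s in sessions
    }
    rows = []
    for _, row in pairs.pairs.iterrows():
        fv = pseudo_feature(row, lookup, config)
        rows.append(
            {
                "pair_id_1": row["pair_id_1"],
                "pair_id_2": row["pair_id_2"],
                "bg_round": row["bg_round"],
                **fv.values,
            }
        )
    return pd.DataFrame(rows)


# ==========================================================================
# Permutation t-tests with Holm correction
# ==========================================================================


@dataclass
class PermutationTestResult:
    feature: str
    t_observed: float
    p_raw: float
    p_holm: float
    cohens_d: float
    direction: str
    n_real: int
    n_pseudo: int
    n_permutations: int
    exhaustive: bool
    significant: bool
    mean_real: float = float("nan")
    sd_real: float = float("nan")
    mean_pseudo: float = float("nan")
    sd_pseudo: float = float("nan")


def _welch_t(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    v1 = x1.var(ddof=1) if n1 > 1 else 0.0
    v2 = x2.var(ddof=1) if n2 > 1 else 0.0
    denom = math.sqrt(v1 / n1 + v2 / n2)
    num = x1.mean() - x2.mean()
    if denom == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / denom


def _pooled_t(x1: np.ndarray, x2: np.ndarray) -> float:
    n1, n2 = len(x1), len(x2)
    sp2 = ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / (n1 + n2 - 2)
    denom = math.sqrt(sp2 * (1 / n1 + 1 / n2))
    num = x1.mean() - x2.mean()
    if denom == 0:
        return 0.0 if num == 0 else math.copysign(math.inf, num)
    return num / denom


def permutation_t_test(
    real: np.ndarray,
    pseudo: np.ndarray,
    direction: str = "real_greater",
    n_perm: int = 100_000,
    seed: int = 0,
    statistic: str = "welch",
    feature: str = "",
    enumerate_mode: str = "auto",
) -> PermutationTestResult:
    """One-tailed two-sample permutation t-test of real vs pseudo values.

    The observed Welch t (real minus pseudo) is compared against the null
    built by re-randomizing group labels.  When the number of label
    assignments C(n1+n2, n1) is at most 10^5, all assignments are
    enumerated; otherwise ``n_perm`` Monte-Carlo draws are used.  The
    add-one estimator p = (#extreme + 1) / (N + 1) avoids p = 0.  Cohen's d
    uses the pooled standard deviation.
    """
    x1 = np.asarray(real, dtype=float)
    x2 = np.asarray(pseudo, dtype=float)
    x1, x2 = x1[np.isfinite(x1)], x2[np.isfinite(x2)]
    n1, n2 = len(x1), len(x2)
    if n1 < 3 or n2 < 3:
        raise ValueError("need at least 3 values per group")
    if direction not in ("real_greater", "real_smaller"):
        raise ValueError(f"unknown direction: {direction}")
    tfun = _welch_t if statistic == "welch" else _pooled_t
    t_obs = tfun(x1, x2)

    pooled = np.concatenate([x1, x2])
    sp = math.sqrt(
        ((n1 - 1) * x1.var(ddof=1) + (n2 - 1) * x2.var(ddof=1)) / max(n1 + n2 - 2, 1)
    )
    d = (x1.mean() - x2.mean()) / sp if sp > 0 else 0.0

    if x1.var() == 0 and x2.var() == 0 and x1.mean() == x2.mean():
        p_raw, n_used, exhaustive = 1.0, 0, False
    else:
        n_total = n1 + n2
        if enumerate_mode == "auto":
            exhaustive = math.comb(n_total, n1) <= 100_000
        else:
            exhaustive = enumerate_mode == "exhaustive"
        if exhaustive:
            idx_all = np.fromiter(
                itertools.chain.from_iterable(itertools.combinations(range(n_total), n1)),
                dtype=np.intp,
            ).reshape(-1, n1)
            g1 = pooled[idx_all]
            mask = np.ones((idx_all.shape[0], n_total), dtype=bool)
            np.put_along_axis(mask, idx_all, False, axis=1)
            g2 = np.broadcast_to(pooled, (idx_all.shape[0], n_total))[mask].reshape(-1, n2)
            n_used = idx_all.shape[0]
        else:
            rng = np.random.default_rng(seed)
            order = rng.permuted(
                np.broadcast_to(np.arange(n_total), (n_perm, n_total)).copy(), axis=1
            )
            shuffled = pooled[order]
            g1, g2 = shuffled[:, :n1], shuffled[:, n1:]
            n_used = n_perm
        m1, m2 = g1.mean(axis=1), g2.mean(axis=1)
        if statistic == "welch":
            v1 = g1.var(axis=1, ddof=1)
            v2 = g2.var(axis=1, ddof=1)
            denom = np.sqrt(v1 / n1 + v2 / n2)
        else:
            sp2 = ((n1 - 1) * g1.var(axis=1, ddof=1) + (n2 - 1) * g2.var(axis=1, ddof=1)) / (
                n1 + n2 - 2
            )
            denom = np.sqrt(sp2 * (1 / n1 + 1 / n2))
        with np.errstate(divide="ignore", invalid="ignore"):
            t_null = np.where(
                denom > 0,
                np.divide(m1 - m2, denom, out=np.zeros_like(denom), where=denom > 0),
                np.where(m1 == m2, 0.0, np.copysign(np.inf, m1 - m2)),
            )
        if direction == "real_greater":
            extreme = int(np.sum(t_null >= t_obs - 1e-12))
        else:
            extreme = int(np.sum(t_null <= t_obs + 1e-12))
        p_raw = (extreme + 1) / (n_used + 1)
    return PermutationTestResult(
        feature=feature,
        t_observed=float(t_obs),
        p_raw=float(min(p_raw, 1.0)),
        p_holm=float("nan"),
        cohens_d=float(d),
        direction=direction,
        n_real=n1,
        n_pseudo=n2,
        n_permutations=n_used,
        exhaustive=exhaustive,
        significant=False,
        mean_real=float(x1.mean()),
        sd_real=float(x1.std(ddof=1)),
        mean_pseudo=float(x2.mean()),
        sd_pseudo=float(x2.std(ddof=1)),
    )


def holm_correct(p_values: list[float] | np.ndarray) -> np.ndarray:
    """Holm step-down adjustment of a family of p-values, clipped at 1."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p <= 0) | (p > 1)):
        raise ValueError("p-values must be in (0, 1]")
    return multipletests(p, method="holm")[1]


def validate_features(
    real_features: pd.DataFrame,
    pseudo_features: pd.DataFrame,
    direction_map: dict[str, str] | None = None,
    alpha: float = 0.05,
    n_perm: int = 100_000,
    seed: int = 0,
    use_transformed: bool = True,
    statistic: str = "welch",
    max_missing: float = 0.5,
) -> tuple[list[PermutationTestResult], list[str]]:
    """Run the real-vs-pseudo permutation test for every feature.

    Features missing in more than ``max_missing`` of the sessions of either
    group are excluded with a warning.  Tests run on the transformed scale
    (log / Fisher Z, with the shift chosen on the combined real+pseudo
    values) by default.  Returns the per-feature results (Holm-adjusted,
    in feature order) and the surviving feature names.
    """
    direction_map = {**DEFAULT_DIRECTIONS, **(direction_map or {})}
    feats = [f for f in FEATURE_NAMES if f in real_features.columns and f in pseudo_features.columns]
    real = real_features[feats].apply(pd.to_numeric)
    pseudo = pseudo_features[feats].apply(pd.to_numeric)
    if use_transformed:
        combined = pd.concat([real, pseudo], ignore_index=True)
        transformed, _ = transform_predictors(combined)
        real = transformed.iloc[: len(real)].reset_index(drop=True)
        pseudo = transformed.iloc[len(real) :].reset_index(drop=True)
    results: list[PermutationTestResult] = []
    rng = np.random.default_rng(seed)
    for f in feats:
        r, q = real[f].dropna(), pseudo[f].dropna()
        if len(r) < max_missing * len(real) or len(q) < max_missing * len(pseudo):
            log.warning("feature %s missing in more than half the sessions: excluded", f)
            continue
        results.append(
            permutation_t_test(
                r.to_numpy(),
                q.to_numpy(),
                direction=direction_map[f],
                n_perm=n_perm,
                seed=int(rng.integers(0, 2**31 - 1)),
                statistic=statistic,
                feature=f,
            )
        )
    adjusted = holm_correct([t.p_raw for t in results])
    survivors = []
    for t, ph in zip(results, adjusted):
        t.p_holm = float(ph)
        t.significant = bool(ph < alpha)
        if t.significant:
            survivors.append(t.feature)
    return results, survivors


def results_table(results: list[PermutationTestResult]) -> pd.DataFrame:
    """Summary table of the validation: feature, Cohen's d, group means
    (SD), direction and significance stars."""

    def stars(p: float) -> str:
        return "***" if p < 0.001 else "**" if p < 0.01 else "*" if p < 0.05 else ""

    rows = [
        {
            "feature": t.feature,
            "cohens_d": round(t.cohens_d, 3),
            "mean_sd_real": f"{t.mean_real:.3f} ({t.sd_real:.3f})",
            "mean_sd_pseudo": f"{t.mean_pseudo:.3f} ({t.sd_pseudo:.3f})",
            "direction": "P < R" if t.t_observed > 0 else "P > R",
            "p_raw": t.p_raw,
            "p_holm": t.p_holm,
            "significance": stars(t.p_holm),
        }
        for t in results
    ]
    return pd.DataFrame(rows)
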