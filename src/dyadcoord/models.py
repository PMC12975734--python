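"""Outcome computation and the two-step predictor-selection analysis.

Objective outcomes come from the game log (wealth gain and goal-time
efficacy); subjective outcomes aggregate the two partners' 7-point Likert
responses per item (MEAN or absolute DIFFERENCE).  Predictors are
transformed by semantic class (log for absolute differences and time-like
variables, Fisher Z for correlations), then each outcome is modeled in two
steps: LASSO with the 1-standard-error lambda (median over 11 repeated
5-fold cross-validations) restricts the predictor set, and a linear mixed
model with pair-level random intercepts is refit on the selected set, with
per-predictor local effect sizes f2.  A random-forest classifier probes how
well the coordination features separate experimental conditions or rounds.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.linear_model import Lasso, lasso_path
from sklearn.metrics import cohen_kappa_score
from sklearn.model_selection import KFold, StratifiedKFold, cross_val_predict, cross_val_score
import statsmodels.api as sm

from .types import CORRELATION_FEATURES, DIFFERENCE_FEATURES

log = logging.getLogger(__name__)

#: Table of subjective items and their pair-level aggregation rule.
SUBJECTIVE_RULES: dict[str, str] = {
    "Perceived_Difficulty": "MEAN",
    "Naturalness_of_Conversation": "MEAN",
    "Rapport": "MEAN",
    "Liking": "MEAN",
    "Disagreement": "MEAN",
    "Perceived_Synchrony": "MEAN",
    "Difference_in_Leading": "DIFFERENCE",
    "Pleasantness_of_the_Task": "MEAN",
    "Surprisal_of_Behavior": "MEAN",
    "Truthfulness": "MEAN",
    "Individual_Task_Performance": "DIFFERENCE",
    "Efficiency_in_Trading": "MEAN",
    "Predictability_of_the_Partner": "MEAN",
}
SUBJECTIVE_ITEMS: tuple[str, ...] = tuple(SUBJECTIVE_RULES)

#: Predictor columns that are log-transformed besides the difference features.
LOG_EXTRA: frozenset[str] = frozenset({"Time_before_BG_Round", "Age_Difference"})


# ==========================================================================
# Outcomes
# ==========================================================================


def compute_objective_outcomes(gamelog: dict) -> dict[str, float]:
    """Objective communication gain/efficacy measures from a game log.

    Difference_in_Goal_Time is defined only when both players collected all
    must-have tokens; Mean_Goal_Time averages over the players who did
    (missing if neither).
    """
    players = gamelog["players"]
    inc = {}
    for p, d in players.items():
        if d["initial_wealth"] <= 0:
            raise ValueError(f"player {p}: initial wealth must be positive")
        inc[p] = (d["final_wealth"] - d["initial_wealth"]) / d["initial_wealth"]
    goals = {p: d.get("goal_time") for p, d in players.items()}
    reached = [g for g in goals.values() if g is not None]
    out = {
        "Mean_Wealth_Increase": float(np.mean(list(inc.values()))),
        "Difference_in_Wealth_Increase": float(abs(inc["A"] - inc["B"])),
        "Mean_Goal_Time": float(np.mean(reached)) if reached else np.nan,
        "Difference_in_Goal_Time": (
            float(abs(goals["A"] - goals["B"])) if len(reached) == 2 else np.nan
        ),
        "Total_Time": float(gamelog["total_time"]),
    }
    return out


def aggregate_subjective(
    responses: pd.DataFrame, rule_map: dict[str, str] | None = None
) -> dict[str, float]:
    """Aggregate per-participant Likert responses to pair-level outcomes.

    MEAN items average the two responses; DIFFERENCE items take the
    absolute difference.  A missing response makes that outcome missing.
    """
    rule_map = rule_map or SUBJECTIVE_RULES
    out: dict[str, float] = {}
    for item, rule in rule_map.items():
        vals = responses.loc[responses["item"] == item, "response"].to_numpy(float)
        if vals.size != 2 or not np.isfinite(vals).all():
            out[item] = np.nan
            continue
        if np.any((vals < 1) | (vals > 7)):
            raise ValueError(f"{item}: Likert responses must be in [1, 7]")
        out[item] = float(vals.mean()) if rule == "MEAN" else float(abs(vals[0] - vals[1]))
    return out


# ==========================================================================
# Predictor transforms
# ==========================================================================


def transform_predictors(
    df: pd.DataFrame, outlier_z: float = 3.0
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Transform predictors to approximate normality by semantic class.

    Absolute-difference and time-like variables are natural-log transformed
    (columns containing zeros use log(x + eps) with eps equal to half the
    smallest positive observed value); Pearson-type variables are Fisher
    Z-transformed (arctanh).  Returns the transformed frame and a boolean
    frame flagging |z| > ``outlier_z`` values for manual review.
    """
    out = df.copy()
    for col in df.columns:
        x = pd.to_numeric(df[col], errors="coerce") if df[col].dtype != object else None
        if x is None:
            continue
        xv = x.to_numpy(float)
        if col in CORRELATION_FEATURES:
            out[col] = np.arctanh(np.clip(xv, -1 + 1e-12, 1 - 1e-12))
        elif col in DIFFERENCE_FEATURES or col in LOG_EXTRA:
            pos = xv[np.isfinite(xv) & (xv > 0)]
            if np.any(np.isfinite(xv) & (xv <= 0)):
                eps = pos.min() / 2.0 if pos.size else 1e-4
                log.info("column %s: zero values, using log(x + %.3g)", col, eps)
                out[col] = np.log(xv + eps)
            else:
                out[col] = np.log(xv)
    flags = pd.DataFrame(False, index=df.index, columns=df.columns)
    for col in out.columns:
        if out[col].dtype == object:
            continue
        xv = out[col].to_numpy(float)
        if not np.isfinite(xv).any():
            continue
        mu, sd = np.nanmean(xv), np.nanstd(xv)
        if np.isfinite(sd) and sd > 0:
            flags[col] = np.abs(xv - mu) > outlier_z * sd
    return out, flags


# ==========================================================================
# LASSO selection with the median-of-11 one-standard-error lambda
# ==========================================================================


@dataclass
class LassoSelection:
    lambda_1se_median: float
    selected: list[str]
    coefficients: dict[str, float]
    lambdas: list[float] = field(default_factory=list)


def _alpha_grid(Xs: np.ndarray, yc: np.ndarray, n_alphas: int = 100) -> np.ndarray:
    alpha_max = np.abs(Xs.T @ yc).max() / len(yc)
    alpha_max = max(alpha_max, 1e-8)
    return np.logspace(np.log10(alpha_max), np.log10(alpha_max * 1e-3), n_alphas)


def lasso_select(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    folds: int = 5,
    repeats: int = 11,
    seed: int = 0,
) -> LassoSelection:
    """Select predictors by LASSO at the median 1-SE lambda.

    For each of ``repeats`` random fold splits, 5-fold cross-validation
    evaluates a shared lambda grid (predictors z-scored on the training
    folds only); the 1-SE lambda is the largest one whose mean CV error is
    within one standard error of the minimum.  The median of the repeated
    1-SE lambdas is used to refit on the full (standardized) data; nonzero
    coefficients form the selected set.
    """
    cols = list(X.columns)
    Xm = X.to_numpy(float)
    yv = np.asarray(y, dtype=float)
    n = len(yv)
    if n < folds:
        raise ValueError("need at least as many observations as folds")
    mu, sd = Xm.mean(axis=0), Xm.std(axis=0)
    sd = np.where(sd > 0, sd, 1.0)
    Xs_full = (Xm - mu) / sd
    grid = _alpha_grid(Xs_full, yv - yv.mean())

    lambdas = []
    import warnings

    for rep in range(repeats):
        kf = KFold(n_splits=folds, shuffle=True, random_state=seed + rep)
        mse = np.zeros((folds, grid.size))
        for f, (tr, va) in enumerate(kf.split(Xm)):
            m, s = Xm[tr].mean(axis=0), Xm[tr].std(axis=0)
            s = np.where(s > 0, s, 1.0)
            Xtr, Xva = (Xm[tr] - m) / s, (Xm[va] - m) / s
            ybar = yv[tr].mean()
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                _, coefs, _ = lasso_path(Xtr, yv[tr] - ybar, alphas=grid, max_iter=5000)
            pred = Xva @ coefs + ybar
            mse[f] = ((pred - yv[va][:, None]) ** 2).mean(axis=0)
        mean_mse = mse.mean(axis=0)
        se = mse.std(axis=0, ddof=1) / np.sqrt(folds)
        i_min = int(np.argmin(mean_mse))
        thresh = mean_mse[i_min] + se[i_min]
        # grid is descending: the 1-SE lambda is the largest alpha under the
        # threshold
        ok = np.flatnonzero(mean_mse <= thresh)
        lambdas.append(float(grid[ok[0]]))
    lam = float(np.median(lambdas))
    fit = Lasso(alpha=lam, fit_intercept=True, max_iter=50_000)
    fit.fit(Xs_full, yv)
    coefs = dict(zip(cols, fit.coef_))
    selected = [c for c in cols if abs(coefs[c]) > 1e-10]
    if not selected:
        log.info("LASSO: no predictors selected (empty model)")
    return LassoSelection(lam, selected, coefs, lambdas)


# ==========================================================================
# Linear mixed model with pair random intercepts
# ==========================================================================


@dataclass
class OutcomeModelResult:
    outcome: str
    lasso_lambda: float
    selected_predictors: list[str]
    coefficients: dict[str, tuple[float, float]]  # name -> (estimate, p)
    conf_int: dict[str, tuple[float, float]]
    f2: dict[str, float]
    n_obs: int
    n_pairs: int
    converged: bool
    singular: bool
    r2_marginal: float


def _marginal_r2(fit, X: np.ndarray) -> float:
    """Fixed-effects (marginal) R2: variance of the fixed-effect predictions
    over the total of fixed, random-intercept and residual variance."""
    beta = np.asarray(fit.fe_params)
    fixed = X @ beta
    var_f = float(np.var(fixed))
    var_re = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    var_e = float(fit.scale)
    return var_f / (var_f + var_re + var_e)


def fit_lmm(
    X: pd.DataFrame,
    y: np.ndarray | pd.Series,
    pair_ids: np.ndarray | pd.Series,
    outcome: str = "outcome",
    lasso_lambda: float = float("nan"),
) -> OutcomeModelResult:
    """Fit ``y ~ X + (1 | pair)`` by REML and report per-predictor f2.

    f2 for a predictor compares the marginal R2 of the full model with a
    reduced model refit without that predictor.
    """
    yv = np.asarray(y, dtype=float)
    groups = np.asarray(pair_ids)
    exog = sm.add_constant(X.to_numpy(float), has_constant="add")
    names = ["Intercept", *X.columns]
    model = sm.MixedLM(yv, exog, groups=groups)
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        fit = model.fit(reml=True)
    var_re = float(np.asarray(fit.cov_re).ravel()[0]) if fit.cov_re.size else 0.0
    singular = var_re < 1e-8 * max(float(fit.scale), 1e-12)
    if singular:
        log.warning("random-intercept variance ~ 0 (singular fit); model still reported")
    r2_full = _marginal_r2(fit, exog)
    coeffs = {
        nm: (float(fit.fe_params[i]), float(fit.pvalues[i])) for i, nm in enumerate(names)
    }
    ci = np.asarray(fit.conf_int())
    conf = {nm: (float(ci[i, 0]), float(ci[i, 1])) for i, nm in enumerate(names)}
    f2: dict[str, float] = {}
    for col in X.columns:
        reduced_X = X.drop(columns=[col])
        r_exog = sm.add_constant(reduced_X.to_numpy(float), has_constant="add")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            r_fit = sm.MixedLM(yv, r_exog, groups=groups).fit(reml=True)
        f2[col] = f2_effect_size(r2_full, _marginal_r2(r_fit, r_exog))
    return OutcomeModelResult(
        outcome=outcome,
        lasso_lambda=lasso_lambda,
        selected_predictors=list(X.columns),
        coefficients=coeffs,
        conf_int=conf,
        f2=f2,
        n_obs=len(yv),
        n_pairs=len(np.unique(groups)),
        converged=bool(fit.converged),
        singular=singular,
        r2_marginal=r2_full,
    )


def f2_effect_size(r2_full: float, r2_reduced: float) -> float:
    """Cohen's local effect size f2 = (R2_full - R2_reduced) / (1 - R2_full)."""
    if r2_full >= 1.0:
        raise ValueError("R2_full must be < 1")
    return (r2_full - r2_reduced) / (1.0 - r2_full)


def model_outcome(
    predictors: pd.DataFrame,
    y: pd.Series | np.ndarray,
    pair_ids: np.ndarray | pd.Series,
    outcome: str = "outcome",
    folds: int = 5,
    repeats: int = 11,
    seed: int = 0,
) -> OutcomeModelResult:
    """The full two-step analysis for one outcome: LASSO selection followed
    by a pair-random-intercept LMM on the selected predictors.

    Rows with a missing predictor or outcome are dropped for this outcome
    only.
    """
    yv = pd.Series(np.asarray(y, dtype=float)).reset_index(drop=True)
    Xd = predictors.reset_index(drop=True)
    groups = pd.Series(np.asarray(pair_ids)).reset_index(drop=True)
    keep = Xd.notna().all(axis=1) & yv.notna()
    Xd, yv, groups = Xd[keep], yv[keep], groups[keep]
    sel = lasso_select(Xd, yv, folds=folds, repeats=repeats, seed=seed)
    if not sel.selected:
        return OutcomeModelResult(
            outcome=outcome,
            lasso_lambda=sel.lambda_1se_median,
            selected_predictors=[],
            coefficients={},
            conf_int={},
            f2={},
            n_obs=int(keep.sum()),
            n_pairs=int(groups.nunique()),
            converged=True,
            singular=False,
            r2_marginal=0.0,
        )
    res = fit_lmm(
        Xd[sel.selected], yv, groups.to_numpy(), outcome=outcome, lasso_lambda=sel.lambda_1se_median
    )
    return res


# ==========================================================================
# Random-forest condition / difficulty classification
# ==========================================================================


@dataclass
class ClassificationResult:
    contrast: str
    accuracy: float  # percent
    kappa: float
    mtry: int
    n_trees: int
    folds: int
    importance: dict[str, float]  # relative 0-100, top = 100


def rf_classify(
    X: pd.DataFrame,
    labels: np.ndarray | pd.Series,
    contrast: str = "",
    seed: int = 0,
    n_trees: int = 500,
    folds: int = 10,
    mtry_grid: tuple[int, ...] | None = None,
    importance: bool = True,
) -> ClassificationResult:
    """Cross-validated random-forest classification with tuned mtry.

    mtry (features per split) is tuned over {2, floor(sqrt p), floor(p/3)}
    by stratified CV accuracy; Cohen's kappa comes from out-of-fold
    predictions at the best mtry, and permutation-style variable importance
    is rescaled so the top variable scores 100.
    """
    yv = np.asarray(labels)
    classes, counts = np.unique(yv, return_counts=True)
    if classes.size < 2:
        raise ValueError("need at least 2 classes")
    eff_folds = int(min(folds, counts.min()))
    if eff_folds < folds:
        log.info("smallest class has %d members: folds reduced to %d", counts.min(), eff_folds)
    p = X.shape[1]
    grid = sorted(set(mtry_grid) if mtry_grid else {2, max(int(np.sqrt(p)), 1), max(p // 3, 1)})
    Xv = X.to_numpy(float)
    cv = StratifiedKFold(n_splits=eff_folds, shuffle=True, random_state=seed)
    best_mtry, best_acc = grid[0], -1.0
    if len(grid) > 1:
        for mtry in grid:
            clf = RandomForestClassifier(
                n_estimators=n_trees, max_features=min(mtry, p), random_state=seed, n_jobs=1
            )
            acc = float(np.mean(cross_val_score(clf, Xv, yv, cv=cv, scoring="accuracy")))
            if acc > best_acc:
                best_mtry, best_acc = mtry, acc
    clf = RandomForestClassifier(
        n_estimators=n_trees, max_features=min(best_mtry, p), random_state=seed, n_jobs=1
    )
    pred = cross_val_predict(clf, Xv, yv, cv=cv)
    kappa = float(cohen_kappa_score(yv, pred))
    if len(grid) == 1:
        best_acc = float(np.mean(pred == yv))
    if importance:
        clf.fit(Xv, yv)
        imp = permutation_importance(clf, Xv, yv, n_repeats=5, random_state=seed, n_jobs=1)
        raw = np.clip(imp.importances_mean, 0.0, None)
        top = raw.max()
        scaled = raw / top * 100.0 if top > 0 else np.zeros_like(raw)
        importance_map = dict(sorted(zip(X.columns, scaled), key=lambda kv: -kv[1]))
    else:
        importance_map = {}
    return ClassificationResult(
        contrast=contrast,
        accuracy=100.0 * best_acc,
        kappa=kappa,
        mtry=best_mtry,
        n_trees=n_trees,
        folds=eff_folds,
        importance=importance_map,
    )
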