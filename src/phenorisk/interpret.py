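"""Feature-outcome associations and model attribution reports.

Three views of what drives predictions:

* Spearman rank correlations between user-level feature medians and the
  continuous outcome scale scores, with Benjamini-Hochberg control across
  features within each outcome;
* Welch two-sample t-tests comparing user-level features between high- and
  low-risk groups, again BH-adjusted;
* per-prediction additive attributions from a model-agnostic permutation
  sampling Shapley estimator, optionally aggregated by sensor category
  (passive features summed per category, active items kept individual).

The Shapley estimator averages telescoping marginal contributions along
random feature permutations against sampled background rows, so the
per-row attributions sum exactly to model(x) minus the mean background
output regardless of the number of permutations.
"""

from __future__ import annotations

import logging
from collections.abc import Callable

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .features import SENTINEL, FeatureMatrix
from .registry import FeatureSpec
from .scales import OUTCOME_SCORE_COLUMN

logger = logging.getLogger(__name__)


def user_level_medians(matrix: FeatureMatrix) -> pd.DataFrame:
    """Per-user medians of each feature across days (sentinels excluded).

    Users with no observation of a feature get NaN for it.
    """
    cols = matrix.feature_columns
    df = matrix.df[["user_id", *cols]].copy()
    df[cols] = df[cols].where(df[cols] != SENTINEL, np.nan)
    return df.groupby("user_id", sort=False).median().reset_index()


# ---------------------------------------------------------------------------
# Associations
# ---------------------------------------------------------------------------

def spearman_table(
    user_features: pd.DataFrame,
    scores: pd.DataFrame,
    outcomes: list[str] | None = None,
    min_n: int = 4,
) -> pd.DataFrame:
    """Spearman correlation of every feature with every outcome score.

    ``user_features`` is one row per user (e.g. from
    :func:`user_level_medians`); NaN cells are excluded pairwise. Midrank
    ties, two-sided p, BH adjustment across features within each outcome.
    Features with fewer than ``min_n`` observations or zero variance are
    emitted with NaN rho and a reason.
    """
    outcomes = outcomes or list(OUTCOME_SCORE_COLUMN)
    feat_cols = [c for c in user_features.columns if c != "user_id"]
    merged = user_features.merge(scores, on="user_id", how="inner")
    rows = []
    for outcome in outcomes:
        score_col = OUTCOME_SCORE_COLUMN[outcome]
        y = merged[score_col].to_numpy(dtype=float)
        recs = []
        for feat in feat_cols:
            x = merged[feat].to_numpy(dtype=float)
            ok = np.isfinite(x) & np.isfinite(y)
            n = int(ok.sum())
            if n < min_n:
                recs.append((feat, np.nan, np.nan, n, "too few observations"))
                continue
            if np.all(x[ok] == x[ok][0]) or np.all(y[ok] == y[ok][0]):
                recs.append((feat, np.nan, np.nan, n, "constant values"))
                continue
            rho, p = stats.spearmanr(x[ok], y[ok])
            recs.append((feat, float(rho), float(p), n, ""))
        pvals = np.array([r[2] for r in recs], dtype=float)
        finite = np.isfinite(pvals)
        adj = np.full(len(recs), np.nan)
        if finite.any():
            adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
        for (feat, rho, p, n, reason), pa in zip(recs, adj):
            rows.append({
                "feature": feat, "outcome": outcome, "rho": rho,
                "p": p, "p_adj": pa, "n": n, "note": reason,
            })
    return pd.DataFrame(rows)


def group_difference_tests(
    user_features: pd.DataFrame, labels: np.ndarray | pd.Series
) -> pd.DataFrame:
    """Welch t-tests of user-level features between high/low-risk groups.

    Group means/SEs are reported on standardized values (z-scored over the
    pooled non-missing users) so effect directions are comparable across
    features; BH adjustment is across features.
    """
    y = np.asarray(labels, dtype=bool)
    feat_cols = [c for c in user_features.columns if c != "user_id"]
    if y.sum() < 2 or (~y).sum() < 2:
        raise ValueError("need at least 2 users per risk group")
    recs = []
    for feat in feat_cols:
        x = user_features[feat].to_numpy(dtype=float)
        ok = np.isfinite(x)
        if ok.sum() < 4 or y[ok].sum() < 2 or (~y[ok]).sum() < 2:
            recs.append({"feature": feat, "t": np.nan, "p": np.nan,
                         "mean_high": np.nan, "mean_low": np.nan,
                         "se_high": np.nan, "se_low": np.nan,
                         "direction": 0, "note": "too few observations"})
            continue
        xs = x[ok]
        sd = xs.std()
        z = (xs - xs.mean()) / (sd if sd > 0 else 1.0)
        hi, lo = z[y[ok]], z[~y[ok]]
        if np.allclose(hi.std(), 0) and np.allclose(lo.std(), 0) and np.isclose(hi.mean(), lo.mean()):
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_ind(hi, lo, equal_var=False)
        recs.append({
            "feature": feat, "t": float(t), "p": float(p),
            "mean_high": float(hi.mean()), "mean_low": float(lo.mean()),
            "se_high": float(hi.std(ddof=1) / np.sqrt(len(hi))) if len(hi) > 1 else np.nan,
            "se_low": float(lo.std(ddof=1) / np.sqrt(len(lo))) if len(lo) > 1 else np.nan,
            "direction": int(np.sign(hi.mean() - lo.mean())), "note": "",
        })
    out = pd.DataFrame(recs)
    pvals = out["p"].to_numpy(dtype=float)
    finite = np.isfinite(pvals)
    adj = np.full(len(out), np.nan)
    if finite.any():
        adj[finite] = multipletests(pvals[finite], method="fdr_bh")[1]
    out["p_adj"] = adj
    return out


# ---------------------------------------------------------------------------
# Sampling Shapley attributions
# ---------------------------------------------------------------------------

def shap_attributions(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    background: np.ndarray,
    rows: np.ndarray,
    n_permutations: int = 16,
    background_size: int = 100,
    rng: np.random.Generator | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Permutation-sampling Shapley attributions on the model output scale.

    For each evaluated row, features are inserted one by one along random
    permutations into a sampled background row, and the marginal output
    changes are averaged. Because each permutation's marginals telescope,
    the attributions of each row sum *exactly* to ``predict_fn(row)`` minus
    that row's returned base value (the mean model output over the
    background rows it was paired with, an unbiased estimate of the
    expected background output).

    Returns (attributions of shape (n_rows, n_features), per-row base
    values of shape (n_rows,)).
    """
    rng = rng or np.random.default_rng(0)
    background = np.atleast_2d(np.asarray(background, dtype=float))
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background sample is empty")
    if background.shape[0] > background_size:
        sel = rng.choice(background.shape[0], size=background_size, replace=False)
        background = background[sel]
    d = rows.shape[1]
    attributions = np.zeros((rows.shape[0], d))
    base = np.zeros(rows.shape[0])

    for _ in range(n_permutations):
        perm = rng.permutation(d)
        bg = background[rng.integers(background.shape[0], size=rows.shape[0])]
        # stacked inputs: step k has features perm[:k] from the row, rest background
        prev = bg.copy()
        prev_out = np.asarray(predict_fn(prev), dtype=float)
        base += prev_out
        for j in perm:
            cur = prev.copy()
            cur[:, j] = rows[:, j]
            cur_out = np.asarray(predict_fn(cur), dtype=float)
            attributions[:, j] += cur_out - prev_out
            prev, prev_out = cur, cur_out
    attributions /= n_permutations
    base /= n_permutations
    return attributions, base


def exact_shapley(
    predict_fn: Callable[[np.ndarray], np.ndarray],
    background_row: np.ndarray,
    row: np.ndarray,
) -> np.ndarray:
    """Exhaustive Shapley values against a single background row.

    Enumerates all 2^d coalitions; intended for small d only (testing and
    validation of the sampling estimator).
    """
    from itertools import combinations
    from math import factorial

    row = np.asarray(row, dtype=float).ravel()
    bg = np.asarray(background_row, dtype=float).ravel()
    d = len(row)
    if d > 16:
        raise ValueError("exact enumeration limited to d <= 16")

    def value(subset: tuple[int, ...]) -> float:
        x = bg.copy()
        x[list(subset)] = row[list(subset)]
        return float(predict_fn(x[None, :])[0])

    cache: dict[tuple[int, ...], float] = {}

    def v(subset: tuple[int, ...]) -> float:
        if subset not in cache:
            cache[subset] = value(subset)
        return cache[subset]

    phi = np.zeros(d)
    idx = list(range(d))
    for j in idx:
        others = [i for i in idx if i != j]
        for k in range(d):
            weight = factorial(k) * factorial(d - k - 1) / factorial(d)
            for subset in combinations(others, k):
                phi[j] += weight * (v(tuple(sorted((*subset, j)))) - v(subset))
    return phi


def aggregate_importance_by_sensor(
    attributions: np.ndarray,
    columns: list[str],
    registry: list[FeatureSpec],
    active_columns: list[str],
) -> pd.DataFrame:
    """Mean |attribution| per feature, passive features summed by sensor.

    Active items are reported individually; the output is sorted by
    importance, descending. Raises if a column is neither a registered
    passive feature nor a known active item.
    """
    attributions = np.atleast_2d(np.asarray(attributions, dtype=float))
    by_name = {s.name: s for s in registry}
    active = set(active_columns)
    importance = np.abs(attributions).mean(axis=0)
    per_feature = dict(zip(columns, importance))
    agg: dict[str, float] = {}
    members: dict[str, list[str]] = {}
    for col, imp in per_feature.items():
        if col in active:
            key, group = col, "active"
        elif col in by_name:
            key, group = by_name[col].category, "passive"
        else:
            raise ValueError(f"column {col!r} not in registry or active items")
        agg[key] = agg.get(key, 0.0) + float(imp)
        members.setdefault(key, []).append(col)
    rows = [
        {"name": k, "importance": v,
         "group": "active" if k in active else "passive",
         "n_members": len(members[k])}
        for k, v in agg.items()
    ]
    out = pd.DataFrame(rows).sort_values("importance", ascending=False, kind="stable")
    return out.reset_index(drop=True)
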