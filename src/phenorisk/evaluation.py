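"""Leave-one-subject-out evaluation, metrics, comparisons, stratification.

The harness mirrors a strict subject-level protocol: for every fold one
user is held out; feature normalization statistics, triplet sampling,
class weights and all model fitting use only the remaining users' rows;
the held-out user's day-level probabilities are averaged into one
user-level prediction. Repetitions re-seed model initialization, batching
and triplet sampling, and metrics are reported as mean (SD) across
repetitions.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import average_precision_score, roc_auc_score

from .features import SENTINEL, FeatureMatrix, fit_apply_normalizer
from .model import (
    ClassifierState,
    FinetuneConfig,
    PretrainConfig,
    finetune_classifier,
    init_encoder,
    pretrain_encoder,
    predict_user,
    train_supervised,
)
from .scales import LABEL_COLUMNS

logger = logging.getLogger(__name__)

METRIC_NAMES = (
    "balanced_accuracy", "auc", "auc_pr", "f1", "f1_macro",
    "sensitivity", "specificity", "precision", "recall",
)


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


@dataclass
class ExperimentResult:
    outcome: str
    modality: str
    pretraining: bool
    predictions: list[pd.DataFrame]  # one frame per repetition
    seeds: list[int]
    fold_audits: list[dict] = field(default_factory=list)
    skipped_folds: int = 0

    def per_repetition_metric(self, name: str = "balanced_accuracy") -> np.ndarray:
        vals = []
        for frame in self.predictions:
            _, m = confusion_and_metrics(frame["label"].to_numpy(), frame["prob"].to_numpy())
            vals.append(m[name])
        return np.asarray(vals)


def loso_folds(user_ids) -> list[tuple[list, object]]:
    """One (train users, test user) fold per user."""
    users = list(dict.fromkeys(user_ids))
    if len(users) < 3:
        raise ValueError("leave-one-subject-out needs at least 3 users")
    return [([u for u in users if u != test], test) for test in users]


def confusion_and_metrics(
    labels: np.ndarray, probs: np.ndarray, threshold: float = 0.5
) -> tuple[ConfusionMatrix, dict[str, float]]:
    """User-level confusion matrix and the full metric suite.

    Balanced accuracy = (sensitivity + specificity) / 2; AUC uses the rank
    (Mann-Whitney) formulation; AUC-PR integrates the precision-recall
    curve. Requires both classes in the truth vector.
    """
    y = np.asarray(labels).astype(bool)
    p = np.asarray(probs, dtype=float)
    if y.all() or not y.any():
        raise ValueError("both classes must be present to compute threshold metrics/AUC")
    pred = p >= threshold
    cm = ConfusionMatrix(
        tp=int((pred & y).sum()), fp=int((pred & ~y).sum()),
        tn=int((~pred & ~y).sum()), fn=int((~pred & y).sum()),
    )
    return cm, metrics_from_confusion(cm, y, p)


def metrics_from_confusion(
    cm: ConfusionMatrix, labels: np.ndarray | None = None, probs: np.ndarray | None = None
) -> dict[str, float]:
    """Threshold metrics from counts; rank metrics when probabilities given."""
    sens = cm.tp / (cm.tp + cm.fn) if (cm.tp + cm.fn) else np.nan
    spec = cm.tn / (cm.tn + cm.fp) if (cm.tn + cm.fp) else np.nan
    prec = cm.tp / (cm.tp + cm.fp) if (cm.tp + cm.fp) else 0.0
    f1 = 2 * cm.tp / (2 * cm.tp + cm.fp + cm.fn) if (2 * cm.tp + cm.fp + cm.fn) else 0.0
    f1_neg = 2 * cm.tn / (2 * cm.tn + cm.fn + cm.fp) if (2 * cm.tn + cm.fn + cm.fp) else 0.0
    out = {
        "balanced_accuracy": (sens + spec) / 2.0,
        "f1": f1,
        "f1_macro": (f1 + f1_neg) / 2.0,
        "sensitivity": sens,
        "specificity": spec,
        "precision": prec,
        "recall": sens,
    }
    if labels is not None and probs is not None:
        out["auc"] = float(roc_auc_score(np.asarray(labels).astype(int), probs))
        out["auc_pr"] = float(average_precision_score(np.asarray(labels).astype(int), probs))
    else:
        out["auc"] = np.nan
        out["auc_pr"] = np.nan
    return out


def summarize_repetitions(result: ExperimentResult) -> pd.DataFrame:
    """Table-style report: mean (SD) of each metric across repetitions.

    The SD over a single repetition is reported as 0, never dropped."""
    rows = {name: [] for name in METRIC_NAMES}
    for frame in result.predictions:
        _, m = confusion_and_metrics(frame["label"].to_numpy(), frame["prob"].to_numpy())
        for name in METRIC_NAMES:
            rows[name].append(m[name])
    report = pd.DataFrame({
        "metric": list(METRIC_NAMES),
        "mean": [float(np.mean(rows[n])) for n in METRIC_NAMES],
        "sd": [float(np.std(rows[n])) for n in METRIC_NAMES],
    })
    return report


# ---------------------------------------------------------------------------
# LOSO experiment
# ---------------------------------------------------------------------------

def users_with_both_modalities(matrix: FeatureMatrix) -> list:
    """Users contributing at least one observed active and one observed
    passive value (the fair-comparison subset)."""
    df = matrix.df
    act = df[matrix.active_columns].to_numpy(dtype=float)
    pas = df[matrix.passive_columns].to_numpy(dtype=float)
    has_act = pd.Series((act != SENTINEL).any(axis=1), index=df.index)
    has_pas = pd.Series((pas != SENTINEL).any(axis=1), index=df.index)
    by_user = pd.DataFrame({"u": df["user_id"], "a": has_act, "p": has_pas}).groupby("u", sort=False)
    flags = by_user.agg({"a": "any", "p": "any"})
    return [u for u, row in flags.iterrows() if row["a"] and row["p"]]


def _informative_rows(df: pd.DataFrame, cols: list[str]) -> np.ndarray:
    vals = df[cols].to_numpy(dtype=float)
    return (vals != SENTINEL).any(axis=1)


def _spawn_seeds(seed: int, n: int) -> list[int]:
    ss = np.random.SeedSequence(seed)
    return [int(s.generate_state(1)[0] % (2 ** 31)) for s in ss.spawn(n)]


def run_loso_experiment(
    matrix: FeatureMatrix,
    labels: pd.DataFrame,
    outcome: str,
    modality: str = "combined",
    pretraining: bool = True,
    repetitions: int = 1,
    seed: int = 0,
    pre_cfg: PretrainConfig | None = None,
    ft_cfg: FinetuneConfig | None = None,
    restrict_both_modalities: bool = True,
    audit: bool = False,
) -> ExperimentResult:
    """Repeated leave-one-subject-out evaluation of one model variant.

    ``matrix`` should already be cumulative-median aggregated; per-fold
    z-normalization is fitted inside each fold on training rows only.
    Degenerate folds (single-class training labels) are skipped with a
    warning and counted in ``skipped_folds``.
    """
    pre_cfg = pre_cfg or PretrainConfig()
    ft_cfg = ft_cfg or FinetuneConfig()
    label_col = LABEL_COLUMNS[outcome]
    cols = matrix.columns_for_modality(modality)

    users = users_with_both_modalities(matrix) if restrict_both_modalities \
        else list(dict.fromkeys(matrix.df["user_id"]))
    label_map = dict(zip(labels["user_id"], labels[label_col].astype(bool)))
    users = [u for u in users if u in label_map]

    sub = matrix.df[matrix.df["user_id"].isin(users)].reset_index(drop=True)
    keep = _informative_rows(sub, cols)
    sub = sub.loc[keep].reset_index(drop=True)
    users = [u for u in users if u in set(sub["user_id"])]
    folds = loso_folds(users)

    sub_matrix = FeatureMatrix(sub, matrix.registry, matrix.active_items)
    global_mean = None
    if audit:
        _, gstate = fit_apply_normalizer(sub_matrix, np.ones(len(sub), dtype=bool))
        global_mean = gstate.mean

    rep_seeds = _spawn_seeds(seed, repetitions)
    predictions: list[pd.DataFrame] = []
    audits: list[dict] = []
    skipped = 0

    user_rows = {u: np.flatnonzero((sub["user_id"] == u).to_numpy()) for u in users}
    row_users = sub["user_id"].to_numpy()

    for rep_seed in rep_seeds:
        rng = np.random.default_rng(rep_seed)
        recs = []
        for train_users, test_user in folds:
            fold_seed = int(rng.integers(2 ** 31))
            train_mask = np.isin(row_users, train_users)
            y_train_users = np.array([label_map[u] for u in row_users[train_mask]])
            if y_train_users.all() or not y_train_users.any():
                logger.warning("fold %s skipped: single-class training labels", test_user)
                skipped += 1
                continue

            normed, state = fit_apply_normalizer(sub_matrix, train_mask)
            xall = normed.df[cols].to_numpy(dtype=float)
            x_train = xall[train_mask]
            train_uid = row_users[train_mask]

            if pretraining:
                p_cfg = PretrainConfig(**{**pre_cfg.__dict__, "seed": fold_seed})
                encoder = pretrain_encoder(x_train, train_uid, p_cfg)
                f_cfg = FinetuneConfig(**{**ft_cfg.__dict__, "seed": fold_seed})
                clf = finetune_classifier(encoder, x_train, y_train_users.astype(float),
                                          f_cfg, outcome)
            else:
                f_cfg = FinetuneConfig(**{**ft_cfg.__dict__, "seed": fold_seed})
                clf = train_supervised(x_train, y_train_users.astype(float),
                                       pre_cfg, f_cfg, outcome)

            test_rows = xall[user_rows[test_user]]
            prob, pred = predict_user(clf, test_rows)
            recs.append({"user_id": test_user, "prob": prob,
                         "pred": pred, "label": bool(label_map[test_user])})

            if audit:
                test_in_train = bool(np.isin(sub.index[user_rows[test_user]],
                                             sub.index[train_mask]).any())
                audits.append({
                    "repetition_seed": rep_seed,
                    "test_user": test_user,
                    "test_rows_in_training": test_in_train,
                    "n_train_rows": int(train_mask.sum()),
                    "class_weight_labels_from_train_only": len(y_train_users) == int(train_mask.sum()),
                    "normalizer_differs_from_global":
                        bool(not np.allclose(state.mean, global_mean, equal_nan=True)),
                })
        predictions.append(pd.DataFrame(recs))
    return ExperimentResult(outcome=outcome, modality=modality, pretraining=pretraining,
                            predictions=predictions, seeds=rep_seeds,
                            fold_audits=audits, skipped_folds=skipped)


# ---------------------------------------------------------------------------
# Comparisons
# ---------------------------------------------------------------------------

def compare_runs(
    metric_a: np.ndarray, metric_b: np.ndarray, test: str = "wilcoxon",
    alternative: str = "two-sided",
) -> tuple[float, float]:
    """Paired test on per-repetition metric vectors; returns (stat, p)."""
    a = np.asarray(metric_a, dtype=float)
    b = np.asarray(metric_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired metric vectors must have equal length")
    if test == "wilcoxon":
        if np.allclose(a, b):
            return np.nan, 1.0  # degenerate: no difference
        res = stats.wilcoxon(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    if test == "paired_t":
        res = stats.ttest_rel(a, b, alternative=alternative)
        return float(res.statistic), float(res.pvalue)
    raise ValueError(f"unknown test {test!r}")


# ---------------------------------------------------------------------------
# External validation
# ---------------------------------------------------------------------------

def external_validation(
    train_matrix: FeatureMatrix,
    train_labels: pd.DataFrame,
    holdout_matrix: FeatureMatrix,
    holdout_labels: pd.DataFrame,
    outcome: str,
    modality: str = "combined",
    pretraining: bool = True,
    seed: int = 0,
    pre_cfg: PretrainConfig | None = None,
    ft_cfg: FinetuneConfig | None = None,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Fit the whole pipeline on one cohort, evaluate user-level on another.

    The holdout cohort contributes nothing upstream: normalization
    statistics, triplets and class weights come from the training cohort
    only. Returns (per-user predictions, metric dict).
    """
    pre_cfg = pre_cfg or PretrainConfig()
    ft_cfg = ft_cfg or FinetuneConfig()
    train_users = set(train_matrix.df["user_id"])
    hold_users = set(holdout_matrix.df["user_id"])
    if train_users & hold_users:
        raise ValueError(f"user overlap between cohorts: {sorted(train_users & hold_users)[:5]}")
    if [s.name for s in train_matrix.registry] != [s.name for s in holdout_matrix.registry]:
        raise ValueError("feature registries differ between cohorts")

    label_col = LABEL_COLUMNS[outcome]
    cols = train_matrix.columns_for_modality(modality)
    tr = train_matrix.df.loc[_informative_rows(train_matrix.df, cols)].reset_index(drop=True)
    tr_matrix = FeatureMatrix(tr, train_matrix.registry, train_matrix.active_items)
    normed, state = fit_apply_normalizer(tr_matrix, np.ones(len(tr), dtype=bool))
    from .features import apply_normalizer

    ho = holdout_matrix.df.loc[_informative_rows(holdout_matrix.df, cols)].reset_index(drop=True)
    ho_norm = apply_normalizer(FeatureMatrix(ho, holdout_matrix.registry, holdout_matrix.active_items), state)

    x_train = normed.df[cols].to_numpy(dtype=float)
    train_uid = normed.df["user_id"].to_numpy()
    lmap = dict(zip(train_labels["user_id"], train_labels[label_col].astype(bool)))
    y_train = np.array([lmap[u] for u in train_uid], dtype=float)

    seeds = _spawn_seeds(seed, 1)
    if pretraining:
        p_cfg = PretrainConfig(**{**pre_cfg.__dict__, "seed": seeds[0]})
        encoder = pretrain_encoder(x_train, train_uid, p_cfg)
        f_cfg = FinetuneConfig(**{**ft_cfg.__dict__, "seed": seeds[0]})
        clf = finetune_classifier(encoder, x_train, y_train, f_cfg, outcome)
    else:
        f_cfg = FinetuneConfig(**{**ft_cfg.__dict__, "seed": seeds[0]})
        clf = train_supervised(x_train, y_train, pre_cfg, f_cfg, outcome)

    hmap = dict(zip(holdout_labels["user_id"], holdout_labels[label_col].astype(bool)))
    xh = ho_norm.df[cols].to_numpy(dtype=float)
    hid = ho_norm.df["user_id"].to_numpy()
    recs = []
    for u in dict.fromkeys(hid):
        rows = xh[hid == u]
        prob, pred = predict_user(clf, rows)
        recs.append({"user_id": u, "prob": prob, "pred": pred, "label": bool(hmap[u])})
    preds = pd.DataFrame(recs)
    _, m = confusion_and_metrics(preds["label"].to_numpy(), preds["prob"].to_numpy())
    return preds, m


# ---------------------------------------------------------------------------
# Stratified reports
# ---------------------------------------------------------------------------

DEFAULT_SCORE_BINS = {
    "sdq": [(1, 8), (9, 16), (17, 24), (25, 40)],
    "insomnia": [(0, 8), (9, 16), (17, 24), (25, 32)],
    "si": [(0, 0), (1, 1), (2, 2), (3, 4)],
    "ed": [(0.0, 1.5), (1.5, 2.69), (2.69, 4.0), (4.0, 6.0)],
}


def stratified_report(
    predictions: pd.DataFrame, grouping: pd.Series, kind: str = "subgroup"
) -> pd.DataFrame:
    """Per-group accuracy table.

    ``predictions`` must carry user_id/prob/pred/label; ``grouping`` maps
    user_id -> group label (score bin, sex, site, or sensor-count split).
    Score-bin reports (`kind="bins"`) use plain accuracy; subgroup reports
    use balanced accuracy (NaN when the group has a single class). Empty
    groups are omitted with a warning.
    """
    df = predictions.copy()
    df["group"] = df["user_id"].map(grouping)
    rows = []
    for group, g in df.groupby("group", sort=True, dropna=False):
        if len(g) == 0:
            logger.warning("group %r is empty; omitted", group)
            continue
        correct = (g["pred"].to_numpy(dtype=bool) == g["label"].to_numpy(dtype=bool))
        rec = {"group": group, "n": len(g), "accuracy": float(correct.mean())}
        y = g["label"].to_numpy(dtype=bool)
        if kind != "bins" and y.any() and not y.all():
            _, m = confusion_and_metrics(y, g["prob"].to_numpy())
            rec["balanced_accuracy"] = m["balanced_accuracy"]
        else:
            rec["balanced_accuracy"] = np.nan
        rows.append(rec)
    return pd.DataFrame(rows)


def sensor_count_split(profiles: pd.DataFrame, threshold: int = 3) -> pd.Series:
    """Fairness grouping: users with <= threshold sensors vs more."""
    counts = profiles["enabled_sensors"].fillna("").map(
        lambda s: len([c for c in s.split(";") if c])
    )
    labels = np.where(counts <= threshold, f"<={threshold} sensors", f">{threshold} sensors")
    return pd.Series(labels, index=profiles["user_id"].to_numpy())


def score_bins(scores: pd.DataFrame, outcome: str,
               bins: list[tuple[float, float]] | None = None) -> pd.Series:
    """Map each user's outcome score to a labelled score bin."""
    from .scales import OUTCOME_SCORE_COLUMN

    bins = bins or DEFAULT_SCORE_BINS[outcome]
    col = OUTCOME_SCORE_COLUMN[outcome]
    vals = scores[col].to_numpy(dtype=float)
    labels = np.full(len(vals), "", dtype=object)
    for lo, hi in bins:
        sel = (vals >= lo) & (vals <= hi) & (labels == "")
        labels[sel] = f"{lo}-{hi}"
    return pd.Series(labels, index=scores["user_id"].to_numpy())
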