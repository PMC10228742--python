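"""Interictal-vs-preictal classification with a random forest.

Max-min normalization to (-1, 1) fitted on training rows only, grouped
k-fold cross-validation (all windows of one seizure — including its paired
interictal sample — stay in one fold), per-fold grid search over the forest
hyperparameters, and the four confusion-matrix metrics with preictal as the
positive class.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import GridSearchCV

from .features import META_COLUMNS

__all__ = [
    "NormalizationParams",
    "ClassifierConfig",
    "ConfusionCounts",
    "EvaluationReport",
    "minmax_normalize",
    "make_folds",
    "compute_metrics",
    "train_eval",
]

POSITIVE_LABEL = "preictal"
NEGATIVE_LABEL = "interictal"


@dataclass
class NormalizationParams:
    """Per-feature training min/max and the target mapping range."""

    data_min: pd.Series
    data_max: pd.Series
    feature_range: tuple[float, float] = (-1.0, 1.0)


def _feature_columns(table: pd.DataFrame, feature_cols: Optional[Sequence[str]]) -> list[str]:
    if feature_cols is not None:
        return list(feature_cols)
    return [c for c in table.columns if c not in META_COLUMNS]


def minmax_normalize(
    table: pd.DataFrame,
    params: Optional[NormalizationParams] = None,
    feature_cols: Optional[Sequence[str]] = None,
    feature_range: tuple[float, float] = (-1.0, 1.0),
) -> tuple[pd.DataFrame, NormalizationParams]:
    """Scale feature columns so the fitted min/max map to *feature_range*.

    With ``params=None`` the min/max are fitted on *table* itself (the
    training rows); pass the returned params to transform held-out rows,
    which may then land outside the range.  A constant feature maps to the
    range midpoint (0 for (-1, 1)) with a warning.
    """
    cols = _feature_columns(table, feature_cols)
    if params is None:
        params = NormalizationParams(
            data_min=table[cols].min(), data_max=table[cols].max(), feature_range=feature_range
        )
    lo, hi = params.feature_range
    out = table.copy()
    span = params.data_max - params.data_min
    constant = span[span == 0].index.tolist()
    if constant:
        warnings.warn(f"constant feature(s) mapped to range midpoint: {constant}")
    for c in cols:
        if span[c] == 0:
            out[c] = (lo + hi) / 2.0
        else:
            out[c] = (table[c] - params.data_min[c]) / span[c] * (hi - lo) + lo
    return out, params


def make_folds(table: pd.DataFrame, k: int = 10, seed: int = 0) -> tuple[pd.Series, int]:
    """Assign each row to one of *k* folds, grouped by seizure id.

    Groups are shuffled (seeded) and dealt round-robin so fold sizes differ
    by at most one group.  If there are fewer groups than folds, k falls
    back to the group count (leave-one-seizure-out) with a warning.
    """
    if k < 2:
        raise ValueError("k must be at least 2")
    if table["seizure_id"].isna().any():
        raise ValueError("every row needs a seizure_id for grouped folds")
    groups = np.sort(table["seizure_id"].unique())
    if len(groups) < 2:
        raise ValueError("need at least 2 seizure groups for cross-validation")
    if len(groups) < k:
        warnings.warn(
            f"only {len(groups)} seizure groups for k={k}; "
            "falling back to leave-one-seizure-out"
        )
        k = len(groups)
    order = np.random.default_rng(seed).permutation(len(groups))
    fold_of_group = {groups[g]: i % k for i, g in enumerate(order)}
    return table["seizure_id"].map(fold_of_group), k


@dataclass(frozen=True)
class ConfusionCounts:
    """Window counts with preictal as the positive class."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


def compute_metrics(counts: ConfusionCounts) -> dict[str, float]:
    """Accuracy, precision, recall and F1 from confusion counts.

    Zero-denominator precision/recall (and the F1 they imply) are reported
    as 0 with a warning.
    """
    if counts.total == 0:
        raise ValueError("empty confusion table")
    accuracy = (counts.tp + counts.tn) / counts.total
    if counts.tp + counts.fp == 0:
        warnings.warn("no predicted positives; precision set to 0")
        precision = 0.0
    else:
        precision = counts.tp / (counts.tp + counts.fp)
    if counts.tp + counts.fn == 0:
        warnings.warn("no actual positives; recall set to 0")
        recall = 0.0
    else:
        recall = counts.tp / (counts.tp + counts.fn)
    if precision + recall == 0:
        f1 = 0.0
    else:
        f1 = 2.0 * precision * recall / (precision + recall)
    return {"accuracy": accuracy, "precision": precision, "recall": recall, "f1": f1}


@dataclass(frozen=True)
class ClassifierConfig:
    """Grid, fold count and seed for the random-forest evaluation."""

    n_estimators: Sequence[int] = (50, 100, 200)
    min_samples_split: Sequence[int] = (2, 5, 10)
    max_depth: Sequence[Optional[int]] = (5, 10, None)
    k: int = 10
    seed: int = 0
    inner_cv: int = 3
    per_channel: bool = True

    @property
    def grid(self) -> dict[str, list]:
        return {
            "n_estimators": list(self.n_estimators),
            "min_samples_split": list(self.min_samples_split),
            "max_depth": list(self.max_depth),
        }

    @property
    def n_grid_points(self) -> int:
        return len(self.n_estimators) * len(self.min_samples_split) * len(self.max_depth)


@dataclass
class EvaluationReport:
    """Per-(channel, fold) metrics plus fold-then-channel averaged aggregates."""

    per_fold: pd.DataFrame
    aggregate: dict[str, float]
    k: int
    seed: int

    def to_dict(self) -> dict:
        return {
            "aggregate": self.aggregate,
            "k": self.k,
            "seed": self.seed,
            "per_fold": self.per_fold.to_dict(orient="records"),
        }


def _rf_seed(seed: int, fold: int, channel_index: int) -> int:
    return int(np.random.SeedSequence([seed, fold, channel_index]).generate_state(1)[0] % (2**31))


def train_eval(table: pd.DataFrame, config: ClassifierConfig = ClassifierConfig()) -> EvaluationReport:
    """Grouped k-fold evaluation of a random forest on a feature table.

    Per fold and channel: normalization is fitted on the training rows, the
    hyperparameter triple is chosen by grid search with inner CV on the
    training rows only, and the refit forest is scored on the held-out
    fold.  Metrics are averaged over folds within each channel, then over
    channels.  Deterministic given the config seed.
    """
    table = table.dropna(subset=_feature_columns(table, None)).reset_index(drop=True)
    if table.empty:
        raise ValueError("empty feature table")
    folds, k = make_folds(table, k=config.k, seed=config.seed)
    feature_cols = _feature_columns(table, None)
    channels = sorted(table["channel"].unique()) if config.per_channel else ["__pooled__"]

    records = []
    for ci, ch in enumerate(channels):
        ch_mask = np.ones(len(table), dtype=bool) if ch == "__pooled__" else (
            table["channel"] == ch
        ).to_numpy()
        for fold in range(k):
            tr = table[ch_mask & (folds != fold).to_numpy()]
            te = table[ch_mask & (folds == fold).to_numpy()]
            if te.empty or tr["label"].nunique() < 2:
                warnings.warn(f"fold {fold} channel {ch}: skipped (degenerate split)")
                continue
            tr_scaled, params = minmax_normalize(tr, feature_cols=feature_cols)
            te_scaled, _ = minmax_normalize(te, params=params, feature_cols=feature_cols)
            x_tr = tr_scaled[feature_cols].to_numpy()
            y_tr = (tr["label"] == POSITIVE_LABEL).to_numpy()
            x_te = te_scaled[feature_cols].to_numpy()
            y_te = (te["label"] == POSITIVE_LABEL).to_numpy()

            rf_seed = _rf_seed(config.seed, fold, ci)
            if config.n_grid_points == 1:
                best = {k_: v[0] for k_, v in config.grid.items()}
                model = RandomForestClassifier(random_state=rf_seed, **best).fit(x_tr, y_tr)
            else:
                search = GridSearchCV(
                    RandomForestClassifier(random_state=rf_seed),
                    config.grid,
                    cv=config.inner_cv,
                    scoring="accuracy",
                    n_jobs=1,
                )
                search.fit(x_tr, y_tr)
                best = search.best_params_
                model = search.best_estimator_
            pred = model.predict(x_te)
            counts = ConfusionCounts(
                tp=int(np.sum(pred & y_te)),
                tn=int(np.sum(~pred & ~y_te)),
                fp=int(np.sum(pred & ~y_te)),
                fn=int(np.sum(~pred & y_te)),
            )
            metrics = compute_metrics(counts)
            records.append(
                {
                    "channel": ch,
                    "fold": fold,
                    "tp": counts.tp,
                    "tn": counts.tn,
                    "fp": counts.fp,
                    "fn": counts.fn,
                    **metrics,
                    "params": best,
                }
            )
    if not records:
        raise ValueError("no evaluable folds")
    per_fold = pd.DataFrame(records)
    metric_names = ("accuracy", "precision", "recall", "f1")
    per_channel = per_fold.groupby("channel")[list(metric_names)].mean()
    aggregate = {m: float(per_channel[m].mean()) for m in metric_names}
    return EvaluationReport(per_fold=per_fold, aggregate=aggregate, k=k, seed=config.seed)
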