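"""Trait classification workflow.

Per trait: map the continuous 1-5 score to five categories, select one of
three feature sets (all 62, 61 without the triangular index, 34 clinically
relevant), split subjects 75/25 stratified by category, tune a random forest
(number of trees and variables per split) by 10-fold cross-validation on the
training part, then report the held-out accuracy with an exact binomial
(Clopper-Pearson) 95% confidence interval and impurity-based feature
importances rescaled so the maximum is 100.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import beta
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import KFold, StratifiedKFold

from .exceptions import (
    DegenerateLabelsError,
    NotFittedError,
    ParameterError,
    StructuralError,
)
from .features import feature_set_columns, validate_feature_names

logger = logging.getLogger("cardiotrait")

_BIN_EDGES = (1.50, 2.50, 3.50, 4.50)

DEFAULT_NTREE_GRID = (250, 500, 1000)


def default_mtry_grid(n_features: int) -> tuple[int, ...]:
    """mtry candidates around the square-root heuristic: sqrt(p)/2, sqrt(p), 2*sqrt(p)."""
    root = math.sqrt(n_features)
    values = {max(1, int(root / 2)), max(1, int(root)), min(n_features, int(2 * root))}
    return tuple(sorted(values))


def bin_scores(score):
    """Map a 1-5 score to its five-level category.

    Half-open bins with strict lower bounds at the .50 boundaries:
    1 for [1.00, 1.50], 2 for (1.50, 2.50], 3 for (2.50, 3.50],
    4 for (3.50, 4.50], 5 for (4.50, 5.00].
    """
    arr = np.asarray(score, dtype=float)
    if np.isnan(arr).any() or (arr < 1.0).any() or (arr > 5.0).any():
        raise ParameterError(f"scores must lie in [1, 5], got {score!r}")
    cats = np.digitize(arr, _BIN_EDGES, right=True) + 1
    if np.isscalar(score) or arr.ndim == 0:
        return int(cats)
    return cats.astype(int)


def select_features(table: pd.DataFrame, mode: str) -> pd.DataFrame:
    """Reduce a 62-column feature table to one of the three study sets."""
    validate_feature_names(table.columns)
    return table[list(feature_set_columns(mode))]


def stratified_split(features: pd.DataFrame, categories: pd.Series,
                     train_frac: float = 0.75, seed: int = 0):
    """Per-category random split; singleton categories go to train."""
    if len(features) < 2:
        raise ParameterError("need at least 2 subjects to split")
    if not features.index.equals(categories.index):
        raise ParameterError("features and categories must share an index")
    rng = np.random.default_rng(seed)
    cats = sorted(categories.unique())
    quotas = {c: train_frac * (categories == c).sum() for c in cats}
    n_train_by_cat = {c: int(math.floor(q)) for c, q in quotas.items()}
    # largest-remainder allocation keeps the overall train share at train_frac
    target = int(round(train_frac * len(categories)))
    leftover = target - sum(n_train_by_cat.values())
    for c in sorted(cats, key=lambda c: quotas[c] - math.floor(quotas[c]),
                    reverse=True)[:max(leftover, 0)]:
        n_train_by_cat[c] += 1

    train_idx: list = []
    test_idx: list = []
    for cat in cats:
        members = categories.index[categories == cat].to_numpy()
        rng.shuffle(members)
        n_c = len(members)
        if n_c == 1:
            logger.warning("category %s has a single member; assigned to train", cat)
            train_idx.extend(members)
            continue
        n_train = min(max(n_train_by_cat[cat], 1), n_c)
        train_idx.extend(members[:n_train])
        test_idx.extend(members[n_train:])
    train_idx = pd.Index(train_idx)
    test_idx = pd.Index(test_idx)
    return (features.loc[train_idx], categories.loc[train_idx],
            features.loc[test_idx], categories.loc[test_idx])


def train_rf(
    train_X: pd.DataFrame,
    train_y: pd.Series,
    cv_folds: int = 10,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    mtry_grid: tuple[int, ...] | None = None,
    seed: int = 0,
) -> tuple[RandomForestClassifier, float, int, int]:
    """Grid-tune (ntree, mtry) by CV accuracy; refit the winner on all of train.

    Returns (model, cv_mean_accuracy_percent, best_ntree, best_mtry).
    Deterministic given the seed; ties resolve to the first grid entry.
    """
    y = np.asarray(train_y)
    X = np.asarray(train_X, dtype=float)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise DegenerateLabelsError("training set contains a single class")
    if mtry_grid is None:
        mtry_grid = default_mtry_grid(X.shape[1])

    min_class = int(counts.min())
    n_folds = min(cv_folds, len(y))
    if min_class >= 2:
        n_folds = min(n_folds, max(min_class, 2))
        if n_folds < cv_folds:
            logger.warning("reducing CV folds to %d (smallest class has %d members)",
                           n_folds, min_class)
        splitter = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    else:
        logger.warning("a class has a single training member; plain %d-fold CV", n_folds)
        splitter = KFold(n_splits=min(n_folds, cv_folds), shuffle=True, random_state=seed)

    folds = list(splitter.split(X, y))
    best: tuple[float, int, int] | None = None
    for ntree in ntree_grid:
        for mtry in mtry_grid:
            accs = []
            for tr, va in folds:
                if np.unique(y[tr]).size < 2:
                    continue
                model = RandomForestClassifier(
                    n_estimators=ntree, max_features=min(mtry, X.shape[1]),
                    random_state=seed)
                model.fit(X[tr], y[tr])
                accs.append(float(np.mean(model.predict(X[va]) == y[va])))
            mean_acc = float(np.mean(accs)) if accs else 0.0
            if best is None or mean_acc > best[0]:
                best = (mean_acc, ntree, mtry)
    cv_acc, ntree, mtry = best
    model = RandomForestClassifier(n_estimators=ntree,
                                   max_features=min(mtry, X.shape[1]),
                                   random_state=seed)
    model.fit(X, y)
    return model, 100.0 * cv_acc, ntree, mtry


def clopper_pearson(k: int, n: int, conf: float = 0.95) -> tuple[float, float]:
    """Exact two-sided binomial confidence interval on a proportion."""
    if not 0 <= k <= n or n <= 0:
        raise ParameterError(f"need 0 <= k <= n with n > 0, got k={k}, n={n}")
    alpha = 1.0 - conf
    lo = 0.0 if k == 0 else float(beta.ppf(alpha / 2.0, k, n - k + 1))
    hi = 1.0 if k == n else float(beta.ppf(1.0 - alpha / 2.0, k + 1, n - k))
    return lo, hi


def _round1(x: float) -> float:
    """Round half away from zero to one decimal (presentation convention)."""
    return math.floor(abs(x) * 10.0 + 0.5) / 10.0 * (1 if x >= 0 else -1)


def evaluate(model, test_X, test_y) -> tuple[float, tuple[float, float]]:
    """Held-out accuracy (%) with its exact binomial 95% CI, to one decimal."""
    X = np.asarray(test_X, dtype=float)
    y = np.asarray(test_y)
    if len(y) == 0:
        raise ParameterError("test set is empty")
    k = int(np.sum(model.predict(X) == y))
    n = len(y)
    lo, hi = clopper_pearson(k, n)
    return _round1(100.0 * k / n), (_round1(100.0 * lo), _round1(100.0 * hi))


def feature_importance(model, feature_names) -> list[tuple[str, float]]:
    """Impurity importances rescaled so the maximum is 100, descending."""
    if not hasattr(model, "feature_importances_"):
        raise NotFittedError("model has no feature_importances_; train it first")
    imp = np.asarray(model.feature_importances_, dtype=float)
    names = list(feature_names)
    if len(names) != imp.size:
        raise StructuralError(
            f"{len(names)} names for {imp.size} importances")
    top = imp.max()
    if top > 0:
        imp = 100.0 * imp / top
    order = np.argsort(-imp, kind="stable")
    return [(names[i], float(imp[i])) for i in order]


@dataclass
class ClassificationReport:
    trait: str
    feature_set: str
    cv_mean_accuracy: float        # %
    test_accuracy: float           # %
    ci95: tuple[float, float]      # %
    n_test: int
    n_train: int
    ntree: int
    mtry: int
    seed: int
    importances: list = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=2))


def run_trait_classification(
    features: pd.DataFrame,
    traits: pd.DataFrame,
    trait: str,
    feature_set: str = "clinical34",
    seed: int = 0,
    cv_folds: int = 10,
    ntree_grid: tuple[int, ...] = DEFAULT_NTREE_GRID,
    mtry_grid: tuple[int, ...] | None = None,
) -> ClassificationReport:
    """End-to-end classification of one trait from a feature table.

    Subjects missing the trait score are excluded before the split.
    """
    if trait not in traits.columns:
        raise ParameterError(f"trait {trait!r} not in trait table")
    scores = traits[trait].dropna()
    common = features.index.intersection(scores.index)
    if len(common) < 4:
        raise ParameterError(f"only {len(common)} subjects with both ECG and {trait}")
    X = select_features(features.loc[common], feature_set)
    y = pd.Series(bin_scores(scores.loc[common].to_numpy()), index=common)

    train_X, train_y, test_X, test_y = stratified_split(X, y, seed=seed)
    model, cv_acc, ntree, mtry = train_rf(
        train_X, train_y, cv_folds=cv_folds, ntree_grid=ntree_grid,
        mtry_grid=mtry_grid, seed=seed)
    test_acc, ci = evaluate(model, test_X, test_y)
    ranked = feature_importance(model, X.columns)
    logger.info("%s/%s: cv=%.1f%% test=%.1f%% CI=(%.1f, %.1f) n_test=%d",
                trait, feature_set, cv_acc, test_acc, ci[0], ci[1], len(test_y))
    return ClassificationReport(
        trait=trait, feature_set=feature_set, cv_mean_accuracy=cv_acc,
        test_accuracy=test_acc, ci95=ci, n_test=int(len(test_y)),
        n_train=int(len(train_y)), ntree=ntree, mtry=mtry, seed=seed,
        importances=ranked)
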