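"""ANOVA F-value feature ranking and incremental feature selection (IFS).

Each feature is scored by the one-way ANOVA F statistic across label groups
(F = MS_between / MS_within, with the 0/0 -> 0 convention for features that
are constant everywhere). IFS then grows the feature set along the ranking
and picks the smallest subset maximising stratified cross-validated
accuracy.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, clone
from sklearn.feature_selection import SelectorMixin
from sklearn.model_selection import StratifiedKFold
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC


class SelectionError(ValueError):
    pass


def anova_f(X: np.ndarray, y) -> np.ndarray:
    """One-way ANOVA F statistic of each column of ``X`` across groups ``y``.

    F = (SSB/(k-1)) / (SSW/(n-k)). A feature with zero within- and
    between-group variance gets F = 0; zero within-group variance with
    non-zero between-group variance gives +inf.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, inv = np.unique(y, return_inverse=True)
    k = classes.size
    n = X.shape[0]
    if k < 2:
        raise SelectionError("ANOVA requires at least 2 classes")
    counts = np.bincount(inv).astype(float)
    if counts.min() < 2:
        raise SelectionError("every class needs at least 2 samples")

    grand = X.mean(axis=0)
    ssb = np.zeros(X.shape[1])
    ssw = np.zeros(X.shape[1])
    for g in range(k):
        Xg = X[inv == g]
        mg = Xg.mean(axis=0)
        ssb += counts[g] * (mg - grand) ** 2
        ssw += ((Xg - mg) ** 2).sum(axis=0)

    msb = ssb / (k - 1)
    msw = ssw / (n - k)
    with np.errstate(divide="ignore", invalid="ignore"):
        f = msb / msw
    f[np.isnan(f)] = 0.0  # 0/0: constant feature
    return f


@dataclass
class RankedFeatures:
    """Feature names in descending-F order with their F values."""

    feature_names: list[str]
    f_values: np.ndarray

    def __post_init__(self) -> None:
        self.f_values = np.asarray(self.f_values, dtype=float)
        if len(self.feature_names) != self.f_values.size:
            raise SelectionError("names and F values differ in length")
        finite = self.f_values[np.isfinite(self.f_values)]
        if finite.size and np.any(np.diff(self.f_values) > 0):
            raise SelectionError("F values must be non-increasing")

    def top(self, n: int) -> list[str]:
        return self.feature_names[:n]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"feature": self.feature_names, "F": self.f_values})


def anova_rank(X: pd.DataFrame, y) -> RankedFeatures:
    """Rank the columns of a feature matrix by descending ANOVA F.

    Ties (and equal infinities) keep original column order.
    """
    f = anova_f(X.to_numpy(), y)
    order = np.argsort(-f, kind="stable")
    return RankedFeatures([X.columns[i] for i in order], f[order])


class AnovaTopK(SelectorMixin, BaseEstimator):
    """Transformer keeping the ``n_features`` columns with highest ANOVA F.

    ``n_features=None`` keeps everything (still computes the ranking, exposed
    as ``scores_`` and ``ranking_``).
    """

    def __init__(self, n_features: int | None = None):
        self.n_features = n_features

    def fit(self, X, y=None):
        if y is None:
            raise SelectionError("AnovaTopK requires labels")
        X = np.asarray(X, dtype=float)
        self.n_features_in_ = X.shape[1]
        self.scores_ = anova_f(X, y)
        self.ranking_ = np.argsort(-self.scores_, kind="stable")
        return self

    def _get_support_mask(self):
        mask = np.zeros(self.n_features_in_, dtype=bool)
        k = self.n_features_in_ if self.n_features is None else min(
            self.n_features, self.n_features_in_)
        mask[self.ranking_[:k]] = True
        return mask

    def __sklearn_tags__(self):
        tags = super().__sklearn_tags__()
        tags.target_tags.required = True
        return tags


def default_ifs_trainer() -> BaseEstimator:
    # fixed hyperparameters: no per-subset grid search inside IFS
    return make_pipeline(StandardScaler(), SVC(C=8.0, kernel="rbf", gamma="scale"))


@dataclass
class IFSResult:
    """Accuracy-vs-subset-size curve and the chosen optimum."""

    curve: list[tuple[int, float]]
    optimal_size: int
    optimal_features: list[str]
    optimal_accuracy: float
    provenance: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "curve": [[int(n), float(a)] for n, a in self.curve],
            "optimal_size": int(self.optimal_size),
            "optimal_features": list(self.optimal_features),
            "optimal_accuracy": float(self.optimal_accuracy),
            "provenance": self.provenance,
        }


def incremental_feature_selection(
    ranked: RankedFeatures,
    X: pd.DataFrame,
    y,
    cv_folds: int = 5,
    trainer: BaseEstimator | None = None,
    stride: int = 1,
    max_features: int | None = None,
    seed: int = 0,
    refit_ranking: bool = True,
) -> IFSResult:
    """Sweep subset sizes along the ranking and pick the best.

    For n = 1, 1+stride, ... the top-n features are cross-validated with
    ``trainer`` (cloned per fold; default: standardise + RBF-SVM with fixed
    hyperparameters) and the full accuracy curve is returned together with
    the smallest n attaining the maximum.

    With ``refit_ranking`` (the default) each cross-validation fold
    re-ranks the features on its training split only and uses its own
    top-n, so the curve is free of selection leakage — with thousands of
    candidate features, ranking once on all samples lets the test folds
    influence which features are scored and inflates the curve on pure
    noise. The reported ``optimal_features`` are always the top-n of the
    supplied full-data ranking (the subset a final model would use).
    ``refit_ranking=False`` reproduces the classic fixed-ranking sweep.
    """
    missing = [f for f in ranked.feature_names if f not in X.columns]
    if missing:
        raise SelectionError(f"ranking refers to unknown features: {missing[:3]}")
    if cv_folds < 2:
        raise SelectionError("cv_folds must be >= 2")
    if trainer is None:
        trainer = default_ifs_trainer()

    y = np.asarray(y)
    p_all = len(ranked.feature_names)
    p = p_all if max_features is None else min(p_all, max_features)
    sizes = list(range(1, p + 1, max(stride, 1)))
    if sizes[-1] != p:
        sizes.append(p)

    Xo = X[ranked.feature_names].to_numpy()  # global rank order as base
    skf = StratifiedKFold(n_splits=cv_folds, shuffle=True, random_state=seed)
    splits = list(skf.split(Xo, y))
    if refit_ranking:
        fold_orders = [np.argsort(-anova_f(Xo[train], y[train]), kind="stable")
                       for train, _ in splits]
    else:
        fold_orders = [np.arange(p_all)] * len(splits)

    curve: list[tuple[int, float]] = []
    best_n, best_acc = sizes[0], -1.0
    for n in sizes:
        correct = 0
        try:
            for (train, test), order in zip(splits, fold_orders):
                cols = order[:n]
                model = clone(trainer)
                model.fit(Xo[np.ix_(train, cols)], y[train])
                correct += int(np.sum(model.predict(Xo[np.ix_(test, cols)]) == y[test]))
        except Exception as exc:
            raise SelectionError(f"trainer failed at subset size {n}: {exc}") from exc
        acc = correct / len(y)
        curve.append((n, acc))
        if acc > best_acc:
            best_n, best_acc = n, acc

    return IFSResult(
        curve=curve,
        optimal_size=best_n,
        optimal_features=ranked.top(best_n),
        optimal_accuracy=best_acc,
        provenance={"cv_folds": cv_folds, "seed": seed, "stride": stride,
                    "refit_ranking": refit_ranking},
    )
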