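"""Relatedness regression: ensemble of bagged trees, a random-subspace
instance-based regressor, and regression by discretisation.

The ensemble averages three meta-regressors and clips predictions to the
1-5 relatedness scale:

* bagging over variance-reduction regression trees (a functional analogue
  of reduced-error-pruned trees),
* a random-subspace ensemble over a distance-weighted k-nearest-neighbour
  regressor (the instance-based member),
* regression by discretisation: the score range [1, 5] is split into 10
  equal-width bins, a 150-tree random forest classifies the bin, and the
  prediction is the probability-weighted mean score of each bin.

All sub-models are seeded from ``random_state``, so a fixed seed gives
bit-identical training and prediction across runs.
"""

from __future__ import annotations

import logging

import numpy as np
from scipy import stats
from sklearn.base import BaseEstimator, RegressorMixin, clone
from sklearn.ensemble import BaggingRegressor, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsRegressor
from sklearn.tree import DecisionTreeRegressor
from sklearn.utils.validation import check_is_fitted, validate_data

from .registry import FEATURE_GROUPS, FEATURE_NAMES, N_FEATURES, group_columns
from .features.syntactic import bag_overlap

logger = logging.getLogger(__name__)

SCORE_RANGE = (1.0, 5.0)


def _check_scores(y: np.ndarray) -> None:
    if np.min(y) < SCORE_RANGE[0] or np.max(y) > SCORE_RANGE[1]:
        raise ValueError("relatedness scores must lie in [1, 5]")
    if np.ptp(y) == 0:
        raise ValueError("constant target: cannot fit a relatedness model")


class DiscretizedRegressor(RegressorMixin, BaseEstimator):
    """Regression by discretisation.

    The continuous target over ``value_range`` is cut into ``n_bins``
    equal-width intervals, a probabilistic classifier is fitted on the bin
    labels, and the prediction is the expected value of the per-bin mean
    target under the predicted bin probabilities.
    """

    def __init__(
        self,
        classifier=None,
        n_bins: int = 10,
        value_range: tuple[float, float] = SCORE_RANGE,
        random_state: int | None = None,
    ):
        self.classifier = classifier
        self.n_bins = n_bins
        self.value_range = value_range
        self.random_state = random_state

    def fit(self, X, y) -> "DiscretizedRegressor":
        X, y = validate_data(self, X, y, y_numeric=True)
        lo, hi = self.value_range
        edges = np.linspace(lo, hi, self.n_bins + 1)
        labels = np.clip(np.digitize(y, edges[1:-1]), 0, self.n_bins - 1)
        clf = self.classifier
        if clf is None:
            clf = RandomForestClassifier(n_estimators=150)
        clf = clone(clf)
        if "random_state" in clf.get_params():
            clf.set_params(random_state=self.random_state)
        self.classifier_ = clf.fit(X, labels)
        midpoints = 0.5 * (edges[:-1] + edges[1:])
        self.bin_means_ = np.array(
            [
                y[labels == b].mean() if np.any(labels == b) else midpoints[b]
                for b in range(self.n_bins)
            ]
        )
        self.bin_edges_ = edges
        return self

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "classifier_")
        X = validate_data(self, X, reset=False)
        proba = self.classifier_.predict_proba(X)
        means = self.bin_means_[self.classifier_.classes_]
        return proba @ means


class RelatednessRegressor(RegressorMixin, BaseEstimator):
    """Ensemble relatedness model over the 34-feature pair encoding.

    Averages the three sub-model predictions and clips to [1, 5].

    Parameters map onto the sub-models: ``n_bagging`` trees in the bagged
    ensemble (``min_samples_leaf`` per tree), ``n_subspace`` members with
    ``subspace_features`` feature fraction over a ``knn_k``-neighbour
    distance-weighted regressor, and a ``n_forest``-tree forest over
    ``n_bins`` score bins for the discretised member.
    """

    _required_n_samples = 10

    def __init__(
        self,
        n_bagging: int = 10,
        min_samples_leaf: int = 2,
        n_subspace: int = 10,
        subspace_features: float = 0.5,
        knn_k: int = 10,
        n_forest: int = 150,
        n_bins: int = 10,
        random_state: int | None = None,
    ):
        self.n_bagging = n_bagging
        self.min_samples_leaf = min_samples_leaf
        self.n_subspace = n_subspace
        self.subspace_features = subspace_features
        self.knn_k = knn_k
        self.n_forest = n_forest
        self.n_bins = n_bins
        self.random_state = random_state

    def fit(self, X, y) -> "RelatednessRegressor":
        X, y = validate_data(self, X, y, y_numeric=True)
        if X.shape[0] < self._required_n_samples:
            raise ValueError(
                f"need at least {self._required_n_samples} training pairs, got {X.shape[0]}"
            )
        _check_scores(y)
        rng = np.random.RandomState(self.random_state)
        seeds = rng.randint(0, 2**31 - 1, size=3)

        self.bagging_ = BaggingRegressor(
            estimator=DecisionTreeRegressor(min_samples_leaf=self.min_samples_leaf),
            n_estimators=self.n_bagging,
            random_state=seeds[0],
        ).fit(X, y)

        k = min(self.knn_k, X.shape[0])
        self.subspace_ = BaggingRegressor(
            estimator=KNeighborsRegressor(n_neighbors=k, weights="distance"),
            n_estimators=self.n_subspace,
            bootstrap=False,
            max_features=self.subspace_features,
            random_state=seeds[1],
        ).fit(X, y)

        self.discretized_ = DiscretizedRegressor(
            classifier=RandomForestClassifier(n_estimators=self.n_forest),
            n_bins=self.n_bins,
            random_state=int(seeds[2]),
        ).fit(X, y)
        return self

    def _submodel_predictions(self, X) -> np.ndarray:
        return np.vstack(
            [
                self.bagging_.predict(X),
                self.subspace_.predict(X),
                self.discretized_.predict(X),
            ]
        )

    def predict(self, X) -> np.ndarray:
        check_is_fitted(self, "bagging_")
        X = validate_data(self, X, reset=False)
        preds = self._submodel_predictions(X).mean(axis=0)
        return np.clip(preds, *SCORE_RANGE)


def baseline_score(sent_a, sent_b) -> float:
    """Naive word-overlap baseline mapped onto the 1-5 scale: 1 + 4*nu
    where nu is the bag-of-words overlap of the two processed sentences."""
    return 1.0 + 4.0 * bag_overlap(sent_a.tokens, sent_b.tokens)


def _cv_pearson(X, y, model, n_folds: int, seed: int | None) -> float:
    """Pooled out-of-fold Pearson correlation, folds stratified by score bin."""
    edges = np.linspace(*SCORE_RANGE, 11)
    bins = np.clip(np.digitize(y, edges[1:-1]), 0, 9)
    # merge bins too small to stratify on
    counts = np.bincount(bins, minlength=10)
    if np.any((counts > 0) & (counts < n_folds)):
        bins = np.clip(bins // 2, 0, 4)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    preds = np.empty_like(y, dtype=float)
    for train_idx, test_idx in skf.split(X, bins):
        m = clone(model).fit(X[train_idx], y[train_idx])
        preds[test_idx] = m.predict(X[test_idx])
    return float(stats.pearsonr(preds, y)[0])


def ablation(
    X,
    y,
    model: RelatednessRegressor | None = None,
    groups: dict[str, list[int]] | None = None,
    n_folds: int = 10,
    random_state: int | None = None,
) -> dict[str, tuple[float, float]]:
    """Leave-one-group-out and group-only cross-validated Pearson.

    ``groups`` maps group names to column indices and must partition the 34
    features exactly once (default: the registry's 8 groups).  Returns
    {group: (pearson_without_group, pearson_group_only)}.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float)
    if X.shape[1] != N_FEATURES:
        raise ValueError(f"expected {N_FEATURES} feature columns, got {X.shape[1]}")
    if groups is None:
        groups = {g: group_columns(g) for g in FEATURE_GROUPS}
    covered = sorted(i for cols in groups.values() for i in cols)
    if covered != list(range(N_FEATURES)):
        raise ValueError("feature groups must partition all 34 features exactly once")
    if model is None:
        model = RelatednessRegressor(random_state=random_state)
    results: dict[str, tuple[float, float]] = {}
    for group, cols in groups.items():
        rest = [i for i in range(N_FEATURES) if i not in cols]
        loo = _cv_pearson(X[:, rest], y, model, n_folds, random_state)
        only = _cv_pearson(X[:, cols], y, model, n_folds, random_state)
        results[group] = (loo, only)
        logger.info("ablation %s: leave-out %.4f, only %.4f", group, loo, only)
    return results
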