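"""Optimal fusion-feature extraction by tree-frequency ranking.

The fitted forest's best trees point at the most recognizable features: the
top 100 trees by held-out accuracy are retained, every feature is scored by
how many retained trees drew it into their subset, the 400 highest-frequency
features are kept, and nested prefix subsets (sizes 70, 75, ..., 400 — 67
subsets) are each re-evaluated with a freshly trained forest. The smallest
subset attaining the maximum accuracy is the optimal fusion feature subset.

All ties are broken deterministically: retained trees by tree index,
frequency ties by canonical feature order (region-major column index).
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
from sklearn.base import BaseEstimator, TransformerMixin

from ._random import derive_seed
from .forest import (
    MultimodalRandomForestClassifier,
    SplitSpec,
    accuracy,
    default_feature_count,
    split_train_test,
)

logger = logging.getLogger(__name__)


@dataclass
class FeatureFrequencyTable:
    """Features ranked by occurrence count among the retained trees."""

    feature_indices: np.ndarray  # column indices, descending count order
    counts: np.ndarray
    n_retained_trees: int

    def __post_init__(self) -> None:
        self.feature_indices = np.asarray(self.feature_indices, dtype=int)
        self.counts = np.asarray(self.counts, dtype=int)
        if (self.counts < 1).any():
            raise ValueError("listed features must have count >= 1")

    def __len__(self) -> int:
        return len(self.feature_indices)


@dataclass
class SubsetScanResult:
    sizes: np.ndarray
    accuracies: np.ndarray
    optimal_size: int | None = None
    optimal_features: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.sizes = np.asarray(self.sizes, dtype=int)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if not (np.diff(self.sizes) > 0).all():
            raise ValueError("subset sizes must be strictly increasing")


@dataclass
class SelectionResult:
    """Full output of the feature-selection stage."""

    tree_accuracies: np.ndarray
    retained_tree_indices: np.ndarray
    frequency_table: FeatureFrequencyTable
    scan: SubsetScanResult
    optimal_features: np.ndarray = field(default_factory=lambda: np.array([], int))


def rank_trees(
    forest: MultimodalRandomForestClassifier,
    X_eval,
    y_eval,
    top_k: int = 100,
) -> tuple[np.ndarray, np.ndarray]:
    """Indices of the ``top_k`` trees by held-out accuracy (ties at the
    cutoff broken by tree index, lower first). Returns (indices, accuracies
    of all trees)."""
    trees = forest.trees_
    if top_k > len(trees):
        raise ValueError(f"top_k={top_k} exceeds forest size {len(trees)}")
    y_eval = np.asarray(y_eval)
    accs = np.array([accuracy(t.predict(np.asarray(X_eval)), y_eval) for t in trees])
    order = np.lexsort((np.arange(len(trees)), -accs))
    return order[:top_k], accs


def feature_frequencies(
    forest: MultimodalRandomForestClassifier,
    retained_tree_indices,
    top_b: int = 400,
) -> FeatureFrequencyTable:
    """Occurrence count of every feature among the retained trees' subsets,
    sorted descending (frequency ties by canonical feature order), truncated
    to the first ``top_b``."""
    retained = list(retained_tree_indices)
    if not retained:
        raise ValueError("no retained trees")
    counter: Counter[int] = Counter()
    for t in retained:
        counter.update(int(f) for f in forest.trees_[t].feature_subset)
    items = sorted(counter.items(), key=lambda kv: (-kv[1], kv[0]))
    if top_b > len(items):
        logger.warning(
            "only %d distinct features among retained trees (< top_b=%d); keeping all",
            len(items),
            top_b,
        )
    items = items[:top_b]
    return FeatureFrequencyTable(
        feature_indices=np.array([f for f, _ in items]),
        counts=np.array([c for _, c in items]),
        n_retained_trees=len(retained),
    )


def nested_subsets(
    table: FeatureFrequencyTable,
    size_min: int = 70,
    size_max: int = 400,
    step: int = 5,
) -> list[np.ndarray]:
    """Prefixes of the frequency ranking with sizes size_min, size_min+step,
    ..., size_max; each subset contains all smaller ones."""
    if size_min > size_max:
        raise ValueError("size_min exceeds size_max")
    if size_max > len(table):
        raise ValueError(
            f"size_max={size_max} exceeds the frequency table length {len(table)}"
        )
    sizes = range(size_min, size_max + 1, step)
    return [table.feature_indices[:s].copy() for s in sizes]


def evaluate_subsets(
    subsets: list[np.ndarray],
    X_train,
    y_train,
    X_test,
    y_test,
    n_estimators: int = 350,
    seed: int = 0,
    **forest_params,
) -> SubsetScanResult:
    """Retrain an MRF restricted to each subset's columns and record its
    held-out accuracy. m is recomputed per subset (sqrt rule, capped at the
    subset size); per-subset seeds derive deterministically from ``seed``."""
    if not subsets:
        raise ValueError("no subsets to evaluate")
    X_train = np.asarray(X_train, dtype=float)
    X_test = np.asarray(X_test, dtype=float)
    sizes, accs = [], []
    for cols in subsets:
        cols = np.asarray(cols, dtype=int)
        size = len(cols)
        model = MultimodalRandomForestClassifier(
            n_estimators=n_estimators,
            max_features=min(size, default_feature_count(size)),
            random_state=derive_seed(seed, "subset", size),
            **forest_params,
        ).fit(X_train[:, cols], np.asarray(y_train))
        sizes.append(size)
        accs.append(model.score(X_test[:, cols], np.asarray(y_test)))
    result = SubsetScanResult(sizes=np.array(sizes), accuracies=np.array(accs))
    best = select_optimal_size(result)
    result.optimal_size = best
    result.optimal_features = subsets[int(np.flatnonzero(result.sizes == best)[0])]
    return result


def select_optimal_size(scan: SubsetScanResult) -> int:
    """Smallest subset size attaining the maximum accuracy (parsimony)."""
    if scan.sizes.size == 0:
        raise ValueError("empty scan")
    best = np.flatnonzero(scan.accuracies == scan.accuracies.max())[0]
    return int(scan.sizes[best])


class TreeFrequencyFeatureSelector(BaseEstimator, TransformerMixin):
    """End-to-end feature selector: split, train an MRF, rank its trees,
    count feature frequencies and pick the optimal prefix subset.

    ``transform`` restricts a fusion matrix to the optimal features.

    Attributes
    ----------
    forest_ : the fitted full-matrix MRF
    selection_result_ : SelectionResult
    selected_features_ : np.ndarray — optimal feature column indices
    support_ : boolean mask over input columns
    """

    def __init__(
        self,
        n_estimators: int = 350,
        top_trees: int = 100,
        top_features: int = 400,
        subset_min: int = 70,
        subset_max: int = 400,
        subset_step: int = 5,
        split_ratio: tuple[int, int] = (6, 4),
        random_state: int | None = None,
        **forest_params,
    ):
        self.n_estimators = n_estimators
        self.top_trees = top_trees
        self.top_features = top_features
        self.subset_min = subset_min
        self.subset_max = subset_max
        self.subset_step = subset_step
        self.split_ratio = split_ratio
        self.random_state = random_state
        self.forest_params = forest_params

    def fit(self, X, y) -> "TreeFrequencyFeatureSelector":
        X = np.asarray(X, dtype=float)
        y = np.asarray(y, dtype=int)
        seed = 0 if self.random_state is None else int(self.random_state)
        train, test = split_train_test(
            y, SplitSpec(ratio=self.split_ratio, seed=derive_seed(seed, "split"))
        )
        forest = MultimodalRandomForestClassifier(
            n_estimators=self.n_estimators,
            random_state=derive_seed(seed, "forest"),
            **self.forest_params,
        ).fit(X[train], y[train])
        self.forest_ = forest
        self.selection_result_ = select_features(
            forest,
            X[train],
            y[train],
            X[test],
            y[test],
            top_trees=self.top_trees,
            top_features=self.top_features,
            subset_min=self.subset_min,
            subset_max=self.subset_max,
            subset_step=self.subset_step,
            seed=seed,
        )
        self.selected_features_ = self.selection_result_.optimal_features
        self.support_ = np.zeros(X.shape[1], dtype=bool)
        self.support_[self.selected_features_] = True
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> np.ndarray:
        return np.asarray(X, dtype=float)[:, self.selected_features_]

    def get_support(self) -> np.ndarray:
        return self.support_


def select_features(
    forest: MultimodalRandomForestClassifier,
    X_train,
    y_train,
    X_test,
    y_test,
    top_trees: int = 100,
    top_features: int = 400,
    subset_min: int = 70,
    subset_max: int = 400,
    subset_step: int = 5,
    seed: int = 0,
    subset_n_estimators: int | None = None,
) -> SelectionResult:
    """The full selection stage on an already fitted forest."""
    retained, tree_accs = rank_trees(forest, X_test, y_test, top_k=top_trees)
    table = feature_frequencies(forest, retained, top_b=top_features)
    subset_max_eff = min(subset_max, len(table))
    if subset_max_eff < subset_max:
        logger.warning(
            "frequency table shorter than subset_max; scanning up to %d", subset_max_eff
        )
    subsets = nested_subsets(table, subset_min, subset_max_eff, subset_step)
    scan = evaluate_subsets(
        subsets,
        X_train,
        y_train,
        X_test,
        y_test,
        n_estimators=subset_n_estimators or forest.n_estimators,
        seed=derive_seed(seed, "subset-scan"),
    )
    return SelectionResult(
        tree_accuracies=tree_accs,
        retained_tree_indices=retained,
        frequency_table=table,
        scan=scan,
        optimal_features=scan.optimal_features,
    )
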