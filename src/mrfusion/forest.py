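"""The multimodal random forest (MRF).

A random-subspace ensemble of CART trees over fusion features: each tree is
grown on a bootstrap resample of the training subjects and on its own random
subset of m fusion features, drawn once per tree (not per node, unlike the
canonical per-node-mtry random forest). Prediction is by majority vote over
trees, with exact ties resolved to -1 (the AD class). The default m is the
nearest integer to sqrt(M) — 57 features for the full M = 3240 fusion matrix.

Also provides the 6:4 stratified train/test split, the accuracy measure
C = sum(s_i) / T, the tree-count grid search over [10, 600] and the plateau
rule that picks the smallest stable ensemble size.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin

from . import _cart
from ._random import derive_seed

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# splitting and scoring
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SplitSpec:
    """Train/test partition specification (default 6:4, stratified)."""

    ratio: tuple[int, int] = (6, 4)
    stratified: bool = True
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.ratio) <= 0:
            raise ValueError("ratio components must be positive")

    @property
    def train_fraction(self) -> float:
        return self.ratio[0] / sum(self.ratio)


def split_train_test(
    labels: np.ndarray, spec: SplitSpec
) -> tuple[np.ndarray, np.ndarray]:
    """Disjoint, exhaustive train/test indices; round(frac*n) per stratum."""
    labels = np.asarray(labels)
    rng = np.random.default_rng(spec.seed)
    frac = spec.train_fraction
    train: list[np.ndarray] = []
    test: list[np.ndarray] = []
    if spec.stratified:
        for cls in np.unique(labels):
            idx = np.flatnonzero(labels == cls)
            if len(idx) < 2:
                raise ValueError(f"class {cls} has fewer than 2 subjects")
            perm = rng.permutation(idx)
            k = round(frac * len(idx))
            if k == 0 or k == len(idx):
                raise ValueError(f"class {cls} absent from one side of the split")
            train.append(perm[:k])
            test.append(perm[k:])
    else:
        perm = rng.permutation(len(labels))
        k = round(frac * len(labels))
        train.append(perm[:k])
        test.append(perm[k:])
    return np.sort(np.concatenate(train)), np.sort(np.concatenate(test))


def accuracy(predictions, truth) -> float:
    """Classification accuracy C = (1/T) * sum_i s_i over the test set."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if predictions.shape != truth.shape:
        raise ValueError("predictions and truth differ in length")
    if predictions.size == 0:
        raise ValueError("empty test set")
    return float((predictions == truth).mean())


def default_feature_count(n_features: int) -> int:
    """Per-tree feature count m: the nearest integer to sqrt(M), >= 1."""
    if n_features < 1:
        raise ValueError("n_features must be >= 1")
    return max(1, round(float(np.sqrt(n_features))))


# ---------------------------------------------------------------------------
# trees and the forest estimator
# ---------------------------------------------------------------------------

@dataclass
class TreeSpec:
    """One fitted CART tree and the random draws that produced it."""

    feature_subset: np.ndarray  # column indices into the full matrix
    sample_indices: np.ndarray  # training-row indices (with repeats)
    feature: np.ndarray
    threshold: np.ndarray
    left: np.ndarray
    right: np.ndarray
    value: np.ndarray

    def predict(self, X: np.ndarray) -> np.ndarray:
        sub = np.ascontiguousarray(X[:, self.feature_subset], dtype=np.float64)
        return _cart.predict_tree(
            self.feature, self.threshold, self.left, self.right, self.value, sub
        ).astype(int)

    @property
    def n_nodes(self) -> int:
        return len(self.feature)

    def to_dict(self) -> dict:
        return {
            "feature_subset": self.feature_subset.tolist(),
            "sample_indices": self.sample_indices.tolist(),
            "feature": self.feature.tolist(),
            "threshold": self.threshold.tolist(),
            "left": self.left.tolist(),
            "right": self.right.tolist(),
            "value": self.value.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "TreeSpec":
        return cls(
            feature_subset=np.asarray(d["feature_subset"], dtype=np.int64),
            sample_indices=np.asarray(d["sample_indices"], dtype=np.int64),
            feature=np.asarray(d["feature"], dtype=np.int32),
            threshold=np.asarray(d["threshold"], dtype=np.float64),
            left=np.asarray(d["left"], dtype=np.int32),
            right=np.asarray(d["right"], dtype=np.int32),
            value=np.asarray(d["value"], dtype=np.int8),
        )


def fit_cart(
    X: np.ndarray,
    y: np.ndarray,
    feature_subset: np.ndarray | None = None,
    sample_indices: np.ndarray | None = None,
    max_depth: int | None = None,
    min_samples_leaf: int = 1,
) -> TreeSpec:
    """Fit one CART tree on ``X[sample_indices][:, feature_subset]``."""
    X = np.asarray(X, dtype=np.float64)
    y = np.asarray(y, dtype=np.int8)
    if X.shape[0] == 0:
        raise ValueError("empty sample set")
    if feature_subset is None:
        feature_subset = np.arange(X.shape[1])
    if sample_indices is None:
        sample_indices = np.arange(X.shape[0])
    sub = np.ascontiguousarray(X[np.ix_(sample_indices, feature_subset)])
    nodes = _cart.build_tree(
        sub,
        y[sample_indices],
        -1 if max_depth is None else int(max_depth),
        int(min_samples_leaf),
    )
    return TreeSpec(
        feature_subset=np.asarray(feature_subset, dtype=np.int64),
        sample_indices=np.asarray(sample_indices, dtype=np.int64),
        feature=nodes[0],
        threshold=nodes[1],
        left=nodes[2],
        right=nodes[3],
        value=nodes[4],
    )


def draw_tree_inputs(
    n_samples: int,
    n_features: int,
    m: int,
    rng: np.random.Generator,
    bootstrap: bool = True,
    sample_fraction: float = 1.0,
) -> tuple[np.ndarray, np.ndarray]:
    """Random draws for one tree: a resample of training rows and m distinct
    features (sorted for a deterministic record)."""
    if m > n_features:
        raise ValueError(f"m={m} exceeds the number of features {n_features}")
    if bootstrap:
        sample = rng.integers(0, n_samples, size=n_samples)
    else:
        k = max(1, round(sample_fraction * n_samples))
        sample = rng.permutation(n_samples)[:k]
    features = np.sort(rng.choice(n_features, size=m, replace=False))
    return sample, features


class MultimodalRandomForestClassifier(BaseEstimator, ClassifierMixin):
    """Random-subspace CART ensemble with majority voting.

    Parameters
    ----------
    n_estimators : int
        Number of trees (the ensemble size a). Default 350, the stable count
        found by the tree-count grid search on the reference analysis.
    max_features : "sqrt" | int
        Per-tree feature-subset size m. "sqrt" uses round(sqrt(M)).
    bootstrap : bool
        If True, each tree resamples the full training size with replacement;
        if False, it subsamples ``sample_fraction`` of rows without
        replacement.
    max_depth : int | None
        Depth cap for the trees; None grows to pure leaves.
    random_state : int | None
        Seed of the per-tree draw streams.

    Attributes
    ----------
    trees_ : list[TreeSpec]
    m_ : int — the per-tree feature count actually used.
    n_tie_votes_ : int — exact vote ties (resolved to -1) in the last predict.
    """

    def __init__(
        self,
        n_estimators: int = 350,
        max_features: str | int = "sqrt",
        bootstrap: bool = True,
        sample_fraction: float = 1.0,
        max_depth: int | None = None,
        min_samples_leaf: int = 1,
        random_state: int | None = None,
    ):
        self.n_estimators = n_estimators
        self.max_features = max_features
        self.bootstrap = bootstrap
        self.sample_fraction = sample_fraction
        self.max_depth = max_depth
        self.min_samples_leaf = min_samples_leaf
        self.random_state = random_state

    def _resolve_m(self, n_features: int) -> int:
        if self.max_features == "sqrt":
            return min(n_features, default_feature_count(n_features))
        m = int(self.max_features)
        if not 1 <= m <= n_features:
            raise ValueError(f"max_features={m} outside [1, {n_features}]")
        return m

    def fit(self, X, y) -> "MultimodalRandomForestClassifier":
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y, dtype=int)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be 2-D with one label per row")
        if X.shape[0] == 0:
            raise ValueError("empty training set")
        if not np.isin(y, (-1, 1)).all():
            raise ValueError("labels must be -1 (AD) or +1 (NC)")
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")

        n, M = X.shape
        self.n_features_in_ = M
        self.classes_ = np.array([-1, 1])
        self.m_ = self._resolve_m(M)

        seeds = np.random.SeedSequence(self.random_state).spawn(self.n_estimators)
        self.trees_ = []
        for t in range(self.n_estimators):
            rng = np.random.default_rng(seeds[t])
            sample, features = draw_tree_inputs(
                n, M, self.m_, rng, self.bootstrap, self.sample_fraction
            )
            self.trees_.append(
                fit_cart(
                    X,
                    y,
                    feature_subset=features,
                    sample_indices=sample,
                    max_depth=self.max_depth,
                    min_samples_leaf=self.min_samples_leaf,
                )
            )
        return self

    def vote_sum(self, X) -> np.ndarray:
        """Sum of tree votes per sample (in [-a, a])."""
        if not hasattr(self, "trees_"):
            raise ValueError("forest is not fitted")
        X = np.asarray(X, dtype=np.float64)
        votes = np.zeros(X.shape[0], dtype=np.int64)
        for tree in self.trees_:
            votes += tree.predict(X)
        return votes

    def predict(self, X) -> np.ndarray:
        votes = self.vote_sum(X)
        ties = int((votes == 0).sum())
        self.n_tie_votes_ = ties
        if ties:
            logger.info("%d tied majority votes resolved to -1 (AD)", ties)
        return np.where(votes > 0, 1, -1)

    def score(self, X, y, sample_weight=None) -> float:
        return accuracy(self.predict(X), np.asarray(y))


# ---------------------------------------------------------------------------
# tree-count grid search
# ---------------------------------------------------------------------------

@dataclass
class AccuracyCurve:
    """Test accuracy as a function of the ensemble size."""

    tree_counts: np.ndarray
    accuracies: np.ndarray
    chosen: int | None = None

    def __post_init__(self) -> None:
        self.tree_counts = np.asarray(self.tree_counts, dtype=int)
        self.accuracies = np.asarray(self.accuracies, dtype=float)
        if not (np.diff(self.tree_counts) > 0).all():
            raise ValueError("tree counts must be strictly increasing")
        if ((self.accuracies < 0) | (self.accuracies > 1)).any():
            raise ValueError("accuracies outside [0, 1]")


def scan_tree_counts(
    X_train,
    y_train,
    X_test,
    y_test,
    grid_start: int = 10,
    grid_end: int = 600,
    step: int = 10,
    seed: int = 0,
    **forest_params,
) -> AccuracyCurve:
    """Train and evaluate one forest per grid point of the ensemble size.

    The search range honours the interval [0, 600] in steps of 10 but starts
    at ``grid_start`` = 10 because a 0-tree forest is undefined. Per-point
    seeds are derived deterministically from ``seed``.
    """
    if step < 1 or grid_start < step or grid_end < grid_start:
        raise ValueError("degenerate tree-count grid")
    counts = np.arange(grid_start, grid_end + 1, step)
    accs = []
    for a in counts:
        model = MultimodalRandomForestClassifier(
            n_estimators=int(a),
            random_state=derive_seed(seed, "scan", int(a)),
            **forest_params,
        ).fit(X_train, y_train)
        accs.append(model.score(X_test, y_test))
    return AccuracyCurve(tree_counts=counts, accuracies=np.array(accs))


def select_stable_count(
    curve: AccuracyCurve, window: int = 5, epsilon: float = 0.02
) -> int:
    """Smallest grid point from which the accuracy curve stays on its final
    plateau: every rolling-window mean from there on deviates from the final
    window's mean by less than ``epsilon``. Transient spikes shorter than the
    window are absorbed by the averaging."""
    acc = curve.accuracies
    if len(acc) < window:
        raise ValueError(f"curve shorter than the stability window ({window})")
    kernel = np.ones(window) / window
    rolling = np.convolve(acc, kernel, mode="valid")  # rolling[j] = mean acc[j:j+w]
    plateau = rolling[-1]
    stable_from = len(rolling) - 1
    for j in range(len(rolling) - 1, -1, -1):
        if abs(rolling[j] - plateau) < epsilon:
            stable_from = j
        else:
            break
    if stable_from == len(rolling) - 1 and len(rolling) > 1:
        logger.warning(
            "no stable region before the end of the grid; returning the grid maximum"
        )
        return int(curve.tree_counts[-1])
    return int(curve.tree_counts[stable_from])
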