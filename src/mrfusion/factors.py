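"""Pathogenic factor extraction and comparison statistics.

Every optimal fusion feature is a (brain region, gene) pair; counting how
often each region and each gene occurs inside the optimal subset ranks the
factors by their association with the disease. Also provides the
hypergeometric upper-tail overlap test used to compare feature sets between
methods, and a Welch t-test per-feature filter as the unimodal baseline
selector.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .fusion import FeatureID


@dataclass
class FactorRanking:
    """Region and gene frequency counts inside the optimal feature subset,
    each sorted descending with name tie-break. Both count vectors sum to the
    subset size (every feature contributes one region and one gene)."""

    region_counts: pd.Series
    gene_counts: pd.Series


def extract_factors(features: list[FeatureID]) -> FactorRanking:
    if not features:
        raise ValueError("empty feature subset")
    regions = pd.Series([f.region_name for f in features], dtype=str)
    genes = pd.Series([f.gene_id for f in features], dtype=str)

    def ranked(s: pd.Series) -> pd.Series:
        counts = s.value_counts()
        df = pd.DataFrame({"name": counts.index.to_numpy(), "count": counts.to_numpy()})
        df = df.sort_values(["count", "name"], ascending=[False, True], kind="mergesort")
        return pd.Series(df["count"].to_numpy(), index=df["name"].to_numpy())

    return FactorRanking(region_counts=ranked(regions), gene_counts=ranked(genes))


@dataclass(frozen=True)
class OverlapTestResult:
    universe: int
    size_a: int
    size_b: int
    overlap: int
    p_value: float


def hypergeometric_overlap(
    universe: int, size_a: int, size_b: int, overlap: int
) -> OverlapTestResult:
    """Upper-tail hypergeometric probability P(X >= overlap) for the overlap
    of two fixed-size sets drawn from a common universe.

    The universe size must be supplied explicitly: overlap p-values are only
    meaningful relative to a stated universe.
    """
    if not (0 <= overlap <= min(size_a, size_b) <= universe):
        raise ValueError(
            f"inconsistent counts: universe={universe}, sizes=({size_a},{size_b}), overlap={overlap}"
        )
    if max(size_a, size_b) > universe:
        raise ValueError("set larger than the universe")
    # survival function of Hypergeometric(universe, size_a, size_b)
    p = float(stats.hypergeom.sf(overlap - 1, universe, size_a, size_b))
    return OverlapTestResult(universe, size_a, size_b, overlap, min(1.0, max(p, 0.0)))


def ttest_feature_filter(
    X,
    y,
    top_k: int | None = None,
    alpha: float | None = None,
    bonferroni: bool = False,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Welch two-sample t statistic per feature column; select either the
    ``top_k`` largest |t| or all features with p < alpha (optionally
    Bonferroni-corrected). Exactly one of ``top_k`` / ``alpha`` is required.

    Zero-variance guard: when both class variances vanish the statistic is 0
    for equal means (p = 1) and infinite for different means (the feature
    ranks first). Ties in |t| are broken by column index.

    Returns (selected column indices, t statistics, p-values).
    """
    if (top_k is None) == (alpha is None):
        raise ValueError("specify exactly one of top_k or alpha")
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    g1, g2 = X[y == -1], X[y == 1]
    if len(g1) < 2 or len(g2) < 2:
        raise ValueError("need at least 2 subjects per class")
    with np.errstate(divide="ignore", invalid="ignore"):
        t, p = stats.ttest_ind(g1, g2, axis=0, equal_var=False)
    t = np.asarray(t, dtype=float)
    p = np.asarray(p, dtype=float)
    degenerate = ~np.isfinite(t)
    if degenerate.any():
        diff = g1.mean(axis=0) - g2.mean(axis=0)
        signed_inf = np.copysign(np.inf, diff[degenerate])
        t[degenerate] = np.where(diff[degenerate] == 0, 0.0, signed_inf)
        p[degenerate] = np.where(diff[degenerate] == 0, 1.0, 0.0)

    if top_k is not None:
        if not 1 <= top_k <= X.shape[1]:
            raise ValueError("top_k outside [1, n_features]")
        order = np.lexsort((np.arange(X.shape[1]), -np.abs(t)))
        selected = np.sort(order[:top_k])
    else:
        level = alpha / X.shape[1] if bonferroni else alpha
        selected = np.flatnonzero(p < level)
    return selected, t, p
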