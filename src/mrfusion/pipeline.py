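"""In-memory orchestration of the analysis chain.

``fuse_dataset`` runs QC -> gene grouping -> segmentation/encoding -> fusion
on a dataset; ``analyze_fusion_matrix`` runs split -> tree-count scan ->
final forest -> feature selection -> factor extraction on a fusion matrix.
``run_all`` in :mod:`mrfusion.io` wraps these with file reading/writing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import qc
from ._random import derive_seed
from .factors import FactorRanking, extract_factors
from .forest import (
    AccuracyCurve,
    MultimodalRandomForestClassifier,
    SplitSpec,
    scan_tree_counts,
    select_stable_count,
    split_train_test,
)
from .fusion import FeatureID, FusionFeatureMatrix, build_fusion_matrix, truncate_series
from .selection import SelectionResult, select_features
from .simulate import SyntheticDataset


@dataclass
class FusionArtifacts:
    """QC-side intermediates leading to the fusion matrix."""

    matrix: FusionFeatureMatrix
    qc_report: qc.QCReport
    groups: list[qc.GeneGroup]
    segment_length: int
    n_unmapped: int
    n_imputed: int


def fuse_dataset(dataset: SyntheticDataset, config) -> FusionArtifacts:
    """QC, group, segment, encode and fuse one (in-memory) dataset.

    ``config`` is a :class:`mrfusion.io.PipelineConfig`.
    """
    table, report = qc.apply_qc(dataset.genotypes, config.qc_thresholds())
    if table.n_snps == 0 or table.n_subjects == 0:
        raise RuntimeError("stage qc: empty table after filtering")
    groups, n_unmapped = qc.group_by_gene(table, config.min_snps_per_gene)
    if not groups:
        raise RuntimeError("stage qc: no gene group above the SNP-count threshold")
    sequences, L, n_imputed = qc.segment_to_length(
        table, groups, policy=config.allele_policy,
        seed=derive_seed(config.seed, "allele-policy"),
    )
    encoded = qc.encode_gene_matrices(sequences)

    keep = [dataset.roi.subject_ids.index(s) for s in table.subject_ids]
    roi = truncate_series(
        type(dataset.roi)(
            subject_ids=[dataset.roi.subject_ids[i] for i in keep],
            region_names=dataset.roi.region_names,
            series=dataset.roi.series[keep],
        ),
        L,
    )
    label_map = {
        s: int(l) for s, l in zip(dataset.genotypes.subject_ids, dataset.labels)
    }
    label_map = {s: label_map[s] for s in table.subject_ids}
    matrix = build_fusion_matrix(roi, encoded, label_map)
    return FusionArtifacts(
        matrix=matrix,
        qc_report=report,
        groups=groups,
        segment_length=L,
        n_unmapped=n_unmapped,
        n_imputed=n_imputed,
    )


@dataclass
class AnalysisResult:
    """Everything the classification/selection/extraction stages produce."""

    train_idx: np.ndarray
    test_idx: np.ndarray
    curve: AccuracyCurve
    selected_tree_count: int
    forest: MultimodalRandomForestClassifier
    full_forest_accuracy: float
    selection: SelectionResult
    optimal_feature_ids: list[FeatureID] = field(default_factory=list)
    ranking: FactorRanking | None = None
    optimal_accuracy: float = 0.0


def analyze_fusion_matrix(matrix: FusionFeatureMatrix, config) -> AnalysisResult:
    """Split, scan the tree-count grid, train the stable-size forest, select
    the optimal feature subset and rank factors. Fully seeded by
    ``config.seed``."""
    seed = config.seed
    X, y = matrix.values, matrix.labels
    train, test = split_train_test(
        y, SplitSpec(ratio=config.split_ratio, seed=derive_seed(seed, "split"))
    )

    curve = scan_tree_counts(
        X[train], y[train], X[test], y[test],
        grid_start=config.tree_grid_start,
        grid_end=config.tree_grid_end,
        step=config.tree_grid_step,
        seed=derive_seed(seed, "tree-scan"),
    )
    a_star = select_stable_count(
        curve, window=config.stability_window, epsilon=config.stability_epsilon
    )
    curve.chosen = a_star

    forest = MultimodalRandomForestClassifier(
        n_estimators=a_star, random_state=derive_seed(seed, "forest")
    ).fit(X[train], y[train])
    full_accuracy = forest.score(X[test], y[test])

    result = select_features(
        forest,
        X[train], y[train], X[test], y[test],
        top_trees=min(config.top_trees, a_star),
        top_features=config.top_features,
        subset_min=config.subset_min,
        subset_max=config.subset_max,
        subset_step=config.subset_step,
        seed=derive_seed(seed, "selection"),
    )
    optimal_ids = [matrix.column_ids[i] for i in result.optimal_features]
    ranking = extract_factors(optimal_ids)
    optimal_accuracy = float(
        result.scan.accuracies[
            np.flatnonzero(result.scan.sizes == result.scan.optimal_size)[0]
        ]
    )
    return AnalysisResult(
        train_idx=train,
        test_idx=test,
        curve=curve,
        selected_tree_count=a_star,
        forest=forest,
        full_forest_accuracy=full_accuracy,
        selection=result,
        optimal_feature_ids=optimal_ids,
        ranking=ranking,
        optimal_accuracy=optimal_accuracy,
    )
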