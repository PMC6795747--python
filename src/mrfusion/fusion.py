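"""Region-gene fusion features.

A fusion feature is the Pearson correlation between one brain region's
truncated time series (first L timepoints) and one gene's digitally encoded
SNP sequence (length L), computed per subject. With R regions and G genes the
fusion matrix has one row per subject and M = R*G columns in region-major
order (all genes of region 1, then region 2, ...).

Degenerate correlations (a constant series or a constant code vector) are set
to 0 and counted, keeping M fixed for the downstream forest bookkeeping.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

from .qc import EncodedGeneMatrix

logger = logging.getLogger(__name__)

FEATURE_SEP = "×"  # the multiplication sign in "REGION×GENE"


@dataclass(frozen=True, order=True)
class FeatureID:
    """Identity of one fusion feature: a (region, gene) pair."""

    region_index: int
    gene_index: int
    region_name: str = field(compare=False)
    gene_id: str = field(compare=False)

    def __str__(self) -> str:
        return f"{self.region_name}{FEATURE_SEP}{self.gene_id}"

    @staticmethod
    def parse(text: str, region_names: list[str], gene_ids: list[str]) -> "FeatureID":
        region_name, gene_id = text.split(FEATURE_SEP)
        return FeatureID(
            region_index=region_names.index(region_name),
            gene_index=gene_ids.index(gene_id),
            region_name=region_name,
            gene_id=gene_id,
        )


@dataclass
class ROISeriesSet:
    """Per-subject ROI time series: subjects x regions x timepoints."""

    subject_ids: list[str]
    region_names: list[str]
    series: np.ndarray

    def __post_init__(self) -> None:
        self.series = np.asarray(self.series, dtype=float)
        if self.series.shape[:2] != (len(self.subject_ids), len(self.region_names)):
            raise ValueError(
                f"series shape {self.series.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.region_names)} regions"
            )
        if len(set(self.region_names)) != len(self.region_names):
            raise ValueError("region names are not unique")

    @property
    def n_timepoints(self) -> int:
        return self.series.shape[2]


@dataclass
class FusionFeatureMatrix:
    """Subjects x (regions*genes) Pearson fusion features with labels."""

    subject_ids: list[str]
    labels: np.ndarray  # (n,) in {-1, +1}
    column_ids: list[FeatureID]  # region-major order
    values: np.ndarray  # (n, R*G)
    region_names: list[str] = field(default_factory=list)
    gene_ids: list[str] = field(default_factory=list)
    n_degenerate: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        self.values = np.asarray(self.values, dtype=float)
        if not np.isin(self.labels, (-1, 1)).all():
            raise ValueError("labels must be -1 (AD) or +1 (NC)")
        if self.values.shape != (len(self.subject_ids), len(self.column_ids)):
            raise ValueError("values shape does not match subjects x columns")

    @property
    def n_features(self) -> int:
        return len(self.column_ids)


def truncate_series(series_set: ROISeriesSet, length: int) -> ROISeriesSet:
    """Keep the first ``length`` timepoints of every region series."""
    if series_set.n_timepoints < length:
        short = series_set.subject_ids[0] if series_set.subject_ids else "?"
        raise ValueError(
            f"time series of length {series_set.n_timepoints} shorter than the "
            f"gene segment length {length} (subject {short})"
        )
    return ROISeriesSet(
        subject_ids=series_set.subject_ids,
        region_names=series_set.region_names,
        series=series_set.series[:, :, :length],
    )


def pearson(x, y) -> float:
    """Sample Pearson correlation coefficient of two equal-length vectors.

    Raises on zero variance in either argument; the matrix builder maps that
    degenerate case to 0 instead.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("pearson expects two equal-length 1-D vectors")
    if x.size < 3:
        raise ValueError("pearson requires length >= 3")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        raise ValueError("zero variance in pearson input")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


def _standardize_rows(mat: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rows z-scored to unit norm; constant rows flagged and zeroed."""
    centered = mat - mat.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms == 0
    norms[degenerate] = 1.0
    return centered / norms[:, None], degenerate


def build_fusion_matrix(
    truncated_series: ROISeriesSet,
    encoded_genes: list[EncodedGeneMatrix],
    labels: dict[str, int] | np.ndarray,
) -> FusionFeatureMatrix:
    """Correlate every region's truncated series with every gene's codes.

    The subject order of the series set defines the row order; ``labels`` may
    be a subject_id -> label mapping or an array aligned with that order.
    """
    subject_ids = truncated_series.subject_ids
    if isinstance(labels, dict):
        missing = sorted(set(subject_ids) - set(labels))
        extra = sorted(set(labels) - set(subject_ids))
        if missing or extra:
            raise ValueError(
                f"subject mismatch between modalities: series-only={missing}, labels-only={extra}"
            )
        labels = np.array([labels[s] for s in subject_ids])

    n, n_regions, L = truncated_series.series.shape
    if not encoded_genes:
        raise ValueError("no encoded genes")
    for g in encoded_genes:
        if g.codes.shape != (n, L):
            raise ValueError(
                f"gene {g.gene_id} codes shape {g.codes.shape} does not match "
                f"{n} subjects x L={L}"
            )

    gene_ids = [g.gene_id for g in encoded_genes]
    codes = np.stack([g.codes for g in encoded_genes], axis=1).astype(float)  # (n, G, L)

    values = np.empty((n, n_regions * len(gene_ids)))
    n_degenerate = 0
    for s in range(n):
        zr, deg_r = _standardize_rows(truncated_series.series[s])
        zg, deg_g = _standardize_rows(codes[s])
        corr = zr @ zg.T  # (R, G)
        deg = deg_r[:, None] | deg_g[None, :]
        if deg.any():
            corr[deg] = 0.0
            n_degenerate += int(deg.sum())
        values[s] = np.clip(corr, -1.0, 1.0).ravel()  # region-major

    if n_degenerate:
        logger.warning(
            "%d degenerate (zero-variance) correlations set to 0", n_degenerate
        )

    column_ids = [
        FeatureID(r, g, truncated_series.region_names[r], gene_ids[g])
        for r in range(n_regions)
        for g in range(len(gene_ids))
    ]
    return FusionFeatureMatrix(
        subject_ids=list(subject_ids),
        labels=labels,
        column_ids=column_ids,
        values=values,
        region_names=list(truncated_series.region_names),
        gene_ids=gene_ids,
        n_degenerate=n_degenerate,
    )
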