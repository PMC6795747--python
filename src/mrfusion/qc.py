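"""Genotype quality control, gene grouping, segmentation and digital encoding.

The QC stage mirrors standard chip-genotyping practice: subjects are dropped
by sample call rate, then SNPs by genotyping (call) rate, minor allele
frequency and an exact Hardy-Weinberg equilibrium test, in that fixed order.
Surviving SNPs are grouped into genes, genes with more than ``min_snps`` SNPs
are kept, every gene is truncated to the common length L (the smallest
retained group), and each subject's per-gene nucleotide sequence is encoded
digitally as A=1, T=2, C=3, G=4.

Diploid calls carry two alleles per SNP while the encoded sequence holds one
letter per position; the reduction is governed by an explicit allele policy
(``major_allele`` by default: the subject contributes the cohort-major allele
unless homozygous for the minor one). Missing calls that survive QC are
imputed to the cohort-major allele and counted.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

MISSING = "0"
VALID_ALLELES = frozenset("ACGT")

#: Digital encoding of nucleotides.
ENCODING = {"A": 1, "T": 2, "C": 3, "G": 4}
DECODING = {v: k for k, v in ENCODING.items()}

ALLELE_POLICIES = ("major_allele", "first_allele", "seeded_random")


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------

@dataclass
class GenotypeTable:
    """Subjects x SNPs diploid nucleotide calls with SNP metadata.

    Parameters
    ----------
    subject_ids
        Ordered subject identifiers (unique).
    snps
        One row per SNP with columns ``snp_id``, ``chromosome``, ``position``,
        ``gene_id`` (may be missing), ``allele_a``, ``allele_b``.
    calls
        ``(n_subjects, n_snps, 2)`` array of single-character allele symbols;
        both symbols are ``"0"`` for a missing call.
    """

    subject_ids: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.calls = np.asarray(self.calls, dtype="U1")
        if self.calls.shape != (len(self.subject_ids), len(self.snps), 2):
            raise ValueError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.subject_ids)} subjects x {len(self.snps)} SNPs"
            )
        if len(set(self.subject_ids)) != len(self.subject_ids):
            raise ValueError("duplicate subject ids")
        bad = ~(
            np.isin(self.calls, sorted(VALID_ALLELES)) | (self.calls == MISSING)
        )
        if bad.any():
            sym = sorted(set(self.calls[bad].tolist()))
            raise ValueError(f"invalid allele symbols in calls: {sym}")

    @property
    def n_subjects(self) -> int:
        return len(self.subject_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean (subjects, snps) mask of missing calls."""
        return self.calls[:, :, 0] == MISSING

    def subset(self, subject_idx=None, snp_idx=None) -> "GenotypeTable":
        subject_idx = (
            np.arange(self.n_subjects) if subject_idx is None else np.asarray(subject_idx)
        )
        snp_idx = np.arange(self.n_snps) if snp_idx is None else np.asarray(snp_idx)
        return GenotypeTable(
            subject_ids=[self.subject_ids[i] for i in subject_idx],
            snps=self.snps.iloc[snp_idx].reset_index(drop=True),
            calls=self.calls[np.ix_(subject_idx, snp_idx)],
        )

    def equals(self, other: "GenotypeTable") -> bool:
        return (
            self.subject_ids == other.subject_ids
            and self.snps.equals(other.snps)
            and np.array_equal(self.calls, other.calls)
        )


@dataclass(frozen=True)
class QCThresholds:
    """QC cutoffs; defaults are 95% / 99.9% / 4% / 1e-4."""

    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.999
    maf_min: float = 0.04
    hwe_p_min: float = 1e-4

    def __post_init__(self) -> None:
        for name in (
            "sample_call_rate_min",
            "snp_call_rate_min",
            "maf_min",
            "hwe_p_min",
        ):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise ValueError(f"{name}={v} outside [0, 1]")


@dataclass
class QCReport:
    thresholds: QCThresholds
    n_subjects_in: int = 0
    n_snps_in: int = 0
    subjects_removed_call_rate: int = 0
    snps_removed_call_rate: int = 0
    snps_removed_maf: int = 0
    snps_removed_hwe: int = 0
    n_subjects_out: int = 0
    n_snps_out: int = 0
    warnings: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = {k: v for k, v in self.__dict__.items() if k != "thresholds"}
        d["thresholds"] = dict(self.thresholds.__dict__)
        return d


@dataclass(frozen=True)
class GeneGroup:
    """SNPs of one gene surviving QC, in genomic-position order."""

    gene_id: str
    snp_ids: tuple[str, ...]
    snp_indices: tuple[int, ...]

    @property
    def group_size(self) -> int:
        return len(self.snp_ids)


@dataclass
class EncodedGeneMatrix:
    """Per-gene digital codes: subjects x L integers in {1, 2, 3, 4}."""

    gene_id: str
    codes: np.ndarray  # (n_subjects, L) int8

    def __post_init__(self) -> None:
        self.codes = np.asarray(self.codes, dtype=np.int8)
        if self.codes.size and not np.isin(self.codes, (1, 2, 3, 4)).all():
            raise ValueError(f"codes for {self.gene_id} outside {{1,2,3,4}}")

    @property
    def segment_length(self) -> int:
        return self.codes.shape[1]


# ---------------------------------------------------------------------------
# per-filter statistics
# ---------------------------------------------------------------------------

def sample_call_rate(table: GenotypeTable) -> np.ndarray:
    """Fraction of non-missing calls per subject."""
    if table.n_snps == 0:
        raise ValueError("table has zero SNPs")
    return 1.0 - table.missing_mask.mean(axis=1)


def snp_call_rate(table: GenotypeTable) -> np.ndarray:
    """Fraction of non-missing calls per SNP (the genotyping rate)."""
    if table.n_subjects == 0:
        raise ValueError("table has zero subjects")
    return 1.0 - table.missing_mask.mean(axis=0)


def allele_counts(table: GenotypeTable) -> tuple[np.ndarray, np.ndarray]:
    """Per-SNP counts of allele_a and allele_b among non-missing calls."""
    a = table.snps["allele_a"].to_numpy(dtype="U1")[None, :, None]
    b = table.snps["allele_b"].to_numpy(dtype="U1")[None, :, None]
    count_a = (table.calls == a).sum(axis=(0, 2))
    count_b = (table.calls == b).sum(axis=(0, 2))
    return count_a, count_b


def minor_allele_frequency(table: GenotypeTable) -> np.ndarray:
    """Per-SNP minor allele frequency among non-missing calls, in [0, 0.5]."""
    count_a, count_b = allele_counts(table)
    total = count_a + count_b
    if (total == 0).any():
        bad = table.snps["snp_id"][total == 0].tolist()
        raise ValueError(f"all-missing SNP columns: {bad}")
    return np.minimum(count_a, count_b) / total


def genotype_counts(table: GenotypeTable) -> np.ndarray:
    """Per-SNP (hom allele_a, het, hom allele_b) counts. Shape (n_snps, 3)."""
    a = table.snps["allele_a"].to_numpy(dtype="U1")[None, :]
    is_a0 = table.calls[:, :, 0] == a
    is_a1 = table.calls[:, :, 1] == a
    non_missing = ~table.missing_mask
    hom_a = (is_a0 & is_a1 & non_missing).sum(axis=0)
    het = ((is_a0 ^ is_a1) & non_missing).sum(axis=0)
    hom_b = (~is_a0 & ~is_a1 & non_missing).sum(axis=0)
    return np.stack([hom_a, het, hom_b], axis=1)


def hwe_exact_test(n_hom_a: int, n_het: int, n_hom_b: int) -> float:
    """Exact conditional Hardy-Weinberg equilibrium test p-value.

    Conditions on the observed allele counts and sums the probabilities of all
    heterozygote counts whose conditional probability does not exceed that of
    the observed count (the standard exact genotype test used in chip QC).
    """
    if min(n_hom_a, n_het, n_hom_b) < 0:
        raise ValueError("negative genotype count")
    n = n_hom_a + n_het + n_hom_b
    if n == 0:
        raise ValueError("no genotyped subjects")
    n_rare = 2 * min(n_hom_a, n_hom_b) + n_het  # minor allele count
    # attainable heterozygote counts share the parity of the rare-allele count
    hets = np.arange(n_rare % 2, min(n_rare, 2 * n - n_rare) + 1, 2)
    log_probs = _hwe_log_probs(n, n_rare, hets)
    probs = np.exp(log_probs - log_probs.max())
    probs /= probs.sum()
    p_obs = probs[np.flatnonzero(hets == n_het)[0]]
    return float(min(1.0, probs[probs <= p_obs * (1 + 1e-12)].sum()))


def _hwe_log_probs(n: int, n_rare: int, hets: np.ndarray) -> np.ndarray:
    # P(het | n, n_rare) up to a constant: n! / (n_aa! n_ab! n_bb!) * 2^het
    from scipy.special import gammaln

    hom_rare = (n_rare - hets) // 2
    hom_common = n - hets - hom_rare
    return (
        hets * math.log(2.0)
        - gammaln(hom_rare + 1)
        - gammaln(hets + 1)
        - gammaln(hom_common + 1)
    )


def hwe_pvalues(table: GenotypeTable) -> np.ndarray:
    counts = genotype_counts(table)
    return np.array([hwe_exact_test(*row) for row in counts])


# ---------------------------------------------------------------------------
# the QC pipeline
# ---------------------------------------------------------------------------

def apply_qc(
    table: GenotypeTable, thresholds: QCThresholds | None = None
) -> tuple[GenotypeTable, QCReport]:
    """Apply the four filters in fixed order: sample call rate, SNP call
    rate, MAF, HWE. Returns the filtered table and a removal report."""
    thresholds = thresholds or QCThresholds()
    report = QCReport(
        thresholds=thresholds,
        n_subjects_in=table.n_subjects,
        n_snps_in=table.n_snps,
    )

    keep_subj = sample_call_rate(table) >= thresholds.sample_call_rate_min
    report.subjects_removed_call_rate = int((~keep_subj).sum())
    table = table.subset(subject_idx=np.flatnonzero(keep_subj))
    if table.n_subjects == 0:
        report.warnings.append("all subjects removed by sample call rate")
        report.n_subjects_out = report.n_snps_out = 0
        return table, report

    keep = snp_call_rate(table) >= thresholds.snp_call_rate_min
    report.snps_removed_call_rate = int((~keep).sum())
    table = table.subset(snp_idx=np.flatnonzero(keep))

    if table.n_snps:
        keep = minor_allele_frequency(table) >= thresholds.maf_min
        report.snps_removed_maf = int((~keep).sum())
        table = table.subset(snp_idx=np.flatnonzero(keep))

    if table.n_snps:
        keep = hwe_pvalues(table) >= thresholds.hwe_p_min
        report.snps_removed_hwe = int((~keep).sum())
        table = table.subset(snp_idx=np.flatnonzero(keep))

    if table.n_snps == 0:
        report.warnings.append("no SNPs survived QC")
    report.n_subjects_out = table.n_subjects
    report.n_snps_out = table.n_snps
    return table, report


def attach_gene_map(table: GenotypeTable, gene_map: dict[str, str]) -> GenotypeTable:
    """Return a copy of ``table`` with ``gene_id`` set from a SNP->gene map."""
    snps = table.snps.copy()
    snps["gene_id"] = snps["snp_id"].map(gene_map)
    return GenotypeTable(table.subject_ids, snps, table.calls)


def group_by_gene(
    table: GenotypeTable, min_snps: int = 30
) -> tuple[list[GeneGroup], int]:
    """Group surviving SNPs into genes, keeping genes with strictly more than
    ``min_snps`` SNPs. Returns (groups, n_unmapped_snps_dropped)."""
    snps = table.snps
    if "gene_id" not in snps.columns or snps["gene_id"].isna().all():
        raise ValueError("no gene assignments; attach a gene map first")
    mapped = snps[snps["gene_id"].notna()]
    n_unmapped = len(snps) - len(mapped)
    if n_unmapped:
        logger.info("dropping %d SNPs without a gene assignment", n_unmapped)
    groups = []
    for gene_id, sub in mapped.groupby("gene_id", sort=True):
        if len(sub) <= min_snps:
            continue
        sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
        groups.append(
            GeneGroup(
                gene_id=str(gene_id),
                snp_ids=tuple(sub["snp_id"]),
                snp_indices=tuple(int(i) for i in sub.index),
            )
        )
    return groups, n_unmapped


def cohort_major_alleles(table: GenotypeTable) -> np.ndarray:
    """Per-SNP cohort-major allele (ties resolved to the alphabetically
    smaller allele, deterministically)."""
    count_a, count_b = allele_counts(table)
    a = table.snps["allele_a"].to_numpy(dtype="U1")
    b = table.snps["allele_b"].to_numpy(dtype="U1")
    tie_choice = np.where(a < b, a, b)
    major = np.where(count_a > count_b, a, np.where(count_b > count_a, b, tie_choice))
    return major.astype("U1")


def segment_to_length(
    table: GenotypeTable,
    groups: list[GeneGroup],
    policy: str = "major_allele",
    seed: int | None = None,
) -> tuple[dict[str, np.ndarray], int, int]:
    """Truncate every gene to the common length L (smallest group) and reduce
    each subject's diploid calls to one nucleotide per SNP.

    Returns ``(sequences, L, n_imputed)`` where ``sequences[gene_id]`` is a
    ``(n_subjects, L)`` array of nucleotide letters.
    """
    if not groups:
        raise ValueError("no retained gene groups")
    if policy not in ALLELE_POLICIES:
        raise ValueError(f"unknown allele policy {policy!r}; one of {ALLELE_POLICIES}")
    L = min(g.group_size for g in groups)
    if L == 0:
        raise ValueError("empty gene group")

    major = cohort_major_alleles(table)
    missing = table.missing_mask
    n_imputed = 0
    rng = np.random.default_rng(seed)

    sequences: dict[str, np.ndarray] = {}
    for g in groups:
        idx = np.asarray(g.snp_indices[:L])
        calls = table.calls[:, idx, :]  # (n, L, 2)
        miss = missing[:, idx]
        if policy == "first_allele":
            seq = calls[:, :, 0].copy()
        elif policy == "seeded_random":
            pick = rng.integers(0, 2, size=miss.shape)
            seq = np.take_along_axis(calls, pick[:, :, None], axis=2)[:, :, 0]
        else:  # major_allele: cohort-major unless homozygous for the other
            maj = major[idx][None, :]
            hom_other = (calls[:, :, 0] == calls[:, :, 1]) & (calls[:, :, 0] != maj)
            seq = np.where(hom_other, calls[:, :, 0], maj)
        imputed = miss.sum()
        if imputed:
            seq = np.where(miss, major[idx][None, :], seq)
            n_imputed += int(imputed)
        sequences[g.gene_id] = seq.astype("U1")
    if n_imputed:
        logger.info("imputed %d missing calls to the cohort-major allele", n_imputed)
    return sequences, L, n_imputed


def encode_sequence(sequence) -> np.ndarray:
    """Digitally encode a nucleotide sequence: A=1, T=2, C=3, G=4.

    Accepts a string or array of single letters; any other symbol (including
    unresolved missing calls) is a hard error.
    """
    arr = np.asarray(list(sequence) if isinstance(sequence, str) else sequence, dtype="U1")
    out = np.zeros(arr.shape, dtype=np.int8)
    for sym, code in ENCODING.items():
        out[arr == sym] = code
    if arr.size and (out == 0).any():
        bad = sorted(set(arr[out == 0].tolist()))
        raise ValueError(f"cannot encode symbols {bad}; expected one of A,T,C,G")
    return out


def decode_sequence(codes) -> str:
    codes = np.asarray(codes)
    try:
        return "".join(DECODING[int(c)] for c in codes.ravel())
    except KeyError as e:
        raise ValueError(f"cannot decode symbol {e}") from None


def encode_gene_matrices(sequences: dict[str, np.ndarray]) -> list[EncodedGeneMatrix]:
    """Encode per-gene nucleotide matrices; genes ordered by gene_id."""
    return [
        EncodedGeneMatrix(gene_id=g, codes=encode_sequence(sequences[g]).reshape(sequences[g].shape))
        for g in sorted(sequences)
    ]
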