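"""Synthetic paired genotype + ROI-time-series datasets with planted truth.

The generator emulates the structure of a two-group (AD vs NC) imaging
genetics cohort: nucleotide-allele SNP calls grouped into genes with
configurable minor allele frequencies, missingness and Hardy-Weinberg
violations, per-subject ROI time series on a 90-region parcellation, and a
set of planted region-gene couplings that exist only in the AD group.

For a planted coupling (r, g, e) the first L_g points of every AD subject's
region-r series are replaced by

    e * standardize(encoded gene-g sequence of that subject) + (1 - e) * noise

so at effect e = 1 the fusion feature for (r, g) equals exactly 1 for AD
subjects while NC subjects carry pure noise. The encoded sequence uses the
same cohort-major allele policy as the QC stage, so the planted signal
survives encoding downstream.

Everything is driven by named substreams of one seed; identical configs give
byte-identical fixtures.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import qc
from ._random import derive_rng
from .aal import AAL90_REGION_NAMES
from .fusion import ROISeriesSet

AD_LABEL = -1
NC_LABEL = +1

#: Default planted couplings: concentrated on one region and one gene
#: ((r*, g*), (r*, g2), (r3, g*)) at effects 0.9 / 0.85 / 0.8.
DEFAULT_COUPLINGS = ((41, 7, 0.9), (41, 19, 0.85), (63, 7, 0.8))


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions of one synthetic cohort.

    The defaults mirror the reference cohort scale: 37 AD + 35 NC subjects,
    90 regions, 36 genes of 40-50 SNPs each (so all genes clear the strict
    >30 group-size rule after QC), MAF in [0.1, 0.5] (clear of the 4%
    filter), and three AD-only couplings at effects 0.8-0.9. Missingness
    defaults to zero so planted couplings stay aligned with the post-QC
    segmented sequences; raise it to exercise the call-rate filters.
    """

    n_ad: int = 37
    n_nc: int = 35
    n_regions: int = 90
    n_genes: int = 36
    snps_per_gene: tuple[int, int] = (40, 50)
    n_timepoints: int = 130
    planted_couplings: tuple[tuple[int, int, float], ...] = DEFAULT_COUPLINGS
    maf_range: tuple[float, float] = (0.1, 0.5)
    missing_rate: float = 0.0
    hwe_violation_genes: tuple[int, ...] = ()
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_ad < 2 or self.n_nc < 2:
            raise ValueError("need at least 2 subjects per group")
        if self.snps_per_gene[0] < 1 or self.snps_per_gene[0] > self.snps_per_gene[1]:
            raise ValueError("snps_per_gene must satisfy 1 <= min <= max")
        if not (0 < self.maf_range[0] <= self.maf_range[1] <= 0.5):
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate outside [0, 1)")
        if self.noise_sd <= 0:
            raise ValueError("noise_sd must be positive")
        for r, g, e in self.planted_couplings:
            if not (0 <= r < self.n_regions and 0 <= g < self.n_genes):
                raise ValueError(f"planted coupling ({r},{g}) out of bounds")
            if not 0 <= e <= 1:
                raise ValueError(f"effect size {e} outside [0, 1]")
        for g in self.hwe_violation_genes:
            if not 0 <= g < self.n_genes:
                raise ValueError(f"hwe_violation gene {g} out of bounds")

    @property
    def n_subjects(self) -> int:
        return self.n_ad + self.n_nc

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        d = dict(d)
        for key in ("snps_per_gene", "maf_range", "hwe_violation_genes"):
            if key in d:
                d[key] = tuple(d[key])
        if "planted_couplings" in d:
            d["planted_couplings"] = tuple(
                (int(r), int(g), float(e)) for r, g, e in d["planted_couplings"]
            )
        return cls(**d)


@dataclass
class SyntheticTruth:
    """Ground truth of one generated dataset."""

    config: SimulationConfig
    true_maf: np.ndarray  # per SNP
    planted_couplings: tuple[tuple[int, int, float], ...]
    labels: np.ndarray  # per subject, -1 AD / +1 NC

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if not np.isin(self.labels, (AD_LABEL, NC_LABEL)).all():
            raise ValueError("labels must be -1 or +1")
        if len(self.labels) != self.config.n_subjects:
            raise ValueError("one label per generated subject required")


@dataclass
class SyntheticDataset:
    genotypes: qc.GenotypeTable
    roi: ROISeriesSet
    truth: SyntheticTruth

    @property
    def labels(self) -> np.ndarray:
        return self.truth.labels


# inbreeding coefficient used for planted HWE violations (excess homozygosity)
HWE_VIOLATION_F = 0.5

_ALLELES = np.array(list("ACGT"))


def generate_genotypes(
    config: SimulationConfig,
) -> tuple[qc.GenotypeTable, SyntheticTruth]:
    """Draw the genotype table: genes of configured SNP counts, genotypes
    under Hardy-Weinberg proportions (or inbreeding-distorted ones for genes
    listed in ``hwe_violation_genes``), missing calls at ``missing_rate``."""
    rng = derive_rng(config.seed, "genotypes")
    n = config.n_subjects

    snp_rows = []
    gene_sizes = rng.integers(
        config.snps_per_gene[0], config.snps_per_gene[1] + 1, size=config.n_genes
    )
    if (gene_sizes == 0).any():
        raise ValueError("every gene needs at least one SNP")

    calls_cols = []
    true_mafs = []
    snp_counter = 0
    for g in range(config.n_genes):
        gene_id = f"GENE{g:04d}"
        chrom = (g % 22) + 1
        base_pos = 1_000_000 * (g // 22 + 1)
        violating = g in config.hwe_violation_genes
        for k in range(int(gene_sizes[g])):
            a_idx = rng.choice(4, size=2, replace=False)
            major, minor = _ALLELES[a_idx[0]], _ALLELES[a_idx[1]]
            maf = float(rng.uniform(*config.maf_range))
            true_mafs.append(maf)
            q, p = maf, 1.0 - maf
            if violating:
                f = HWE_VIOLATION_F
                probs = (p * p + f * p * q, 2 * p * q * (1 - f), q * q + f * p * q)
            else:
                probs = (p * p, 2 * p * q, q * q)
            geno = rng.choice(3, size=n, p=probs)  # 0 hom-major, 1 het, 2 hom-minor
            col = np.empty((n, 2), dtype="U1")
            col[geno == 0] = (major, major)
            col[geno == 1] = (major, minor)
            col[geno == 2] = (minor, minor)
            calls_cols.append(col)
            snp_rows.append(
                {
                    "snp_id": f"SNP{snp_counter:06d}",
                    "chromosome": chrom,
                    "position": base_pos + 10_000 * k,
                    "gene_id": gene_id,
                    "allele_a": str(major),
                    "allele_b": str(minor),
                }
            )
            snp_counter += 1

    calls = np.stack(calls_cols, axis=1)  # (n, n_snps, 2)
    if config.missing_rate > 0:
        miss = rng.random((n, calls.shape[1])) < config.missing_rate
        calls[miss] = qc.MISSING

    subject_ids = [f"AD{i:03d}" for i in range(config.n_ad)] + [
        f"NC{i:03d}" for i in range(config.n_nc)
    ]
    labels = np.array([AD_LABEL] * config.n_ad + [NC_LABEL] * config.n_nc)
    table = qc.GenotypeTable(
        subject_ids=subject_ids,
        snps=pd.DataFrame(snp_rows),
        calls=calls,
    )
    truth = SyntheticTruth(
        config=config,
        true_maf=np.array(true_mafs),
        planted_couplings=tuple(config.planted_couplings),
        labels=labels,
    )
    return table, truth


def _encoded_gene_zscores(table: qc.GenotypeTable, gene_id: str) -> np.ndarray:
    """Standardized encoded sequence of one full gene, per subject (n, L_g).

    Uses the same cohort-major allele policy and missing-call imputation as
    the QC stage so the planted series segment matches what the downstream
    encoder produces.
    """
    sub = table.snps[table.snps["gene_id"] == gene_id]
    sub = sub.sort_values(["chromosome", "position"], kind="mergesort")
    group = qc.GeneGroup(
        gene_id=gene_id,
        snp_ids=tuple(sub["snp_id"]),
        snp_indices=tuple(int(i) for i in sub.index),
    )
    sequences, _, _ = qc.segment_to_length(table, [group], policy="major_allele")
    codes = qc.encode_sequence(sequences[gene_id]).astype(float)
    centered = codes - codes.mean(axis=1, keepdims=True)
    sd = centered.std(axis=1)
    sd[sd == 0] = 1.0
    return centered / sd[:, None]


def generate_roi_series(
    config: SimulationConfig,
    table: qc.GenotypeTable,
    truth: SyntheticTruth,
) -> ROISeriesSet:
    """Draw ROI series: i.i.d. Gaussian noise everywhere, except that for
    each planted coupling (r, g, e) the AD subjects' region-r series opens
    with the standardized encoded gene-g sequence mixed at weight e."""
    rng = derive_rng(config.seed, "roi")
    n = config.n_subjects
    series = rng.normal(0.0, config.noise_sd, size=(n, config.n_regions, config.n_timepoints))

    gene_ids = sorted(table.snps["gene_id"].dropna().unique())
    max_len = int(table.snps.groupby("gene_id").size().max())
    if config.n_timepoints < max_len:
        raise ValueError(
            f"n_timepoints={config.n_timepoints} shorter than the longest gene ({max_len} SNPs)"
        )

    # couplings sharing a region are planted as an additive mixture; for a
    # single coupling this reduces to e*z + (1-e)*noise exactly
    by_region: dict[int, list[tuple[int, float]]] = {}
    for r, g, e in truth.planted_couplings:
        by_region.setdefault(r, []).append((g, e))

    ad = np.flatnonzero(truth.labels == AD_LABEL)
    for r, planted in by_region.items():
        max_len = 0
        signal = np.zeros((len(ad), config.n_timepoints))
        for g, e in planted:
            z = _encoded_gene_zscores(table, gene_ids[g])  # (n, L_g)
            L = z.shape[1]
            signal[:, :L] += e * z[ad]
            max_len = max(max_len, L)
        noise_weight = 1.0 - max(e for _, e in planted)
        series[ad, r, :max_len] = (
            signal[:, :max_len] + noise_weight * series[ad, r, :max_len]
        )

    region_names = list(AAL90_REGION_NAMES[: config.n_regions])
    if config.n_regions > 90:
        region_names += [f"Region_{i:03d}" for i in range(90, config.n_regions)]
    return ROISeriesSet(
        subject_ids=list(table.subject_ids),
        region_names=region_names,
        series=series,
    )


def generate_dataset(config: SimulationConfig) -> SyntheticDataset:
    table, truth = generate_genotypes(config)
    roi = generate_roi_series(config, table, truth)
    return SyntheticDataset(genotypes=table, roi=roi, truth=truth)


# ---------------------------------------------------------------------------
# fixture writing (one directory, all plain text)
# ---------------------------------------------------------------------------

FLOAT_FMT = "%.9g"


def write_fixture(dataset: SyntheticDataset, out_dir: str | Path) -> dict[str, Path]:
    """Write the dataset as a plain-text fixture directory.

    Emits genotypes.ped / genotypes.map (PLINK text, missing allele "0"),
    gene_map.tsv, roi/<subject>.tsv (rows = regions, columns = timepoints),
    labels.tsv and truth.json. All files round-trip losslessly through the
    pipeline readers.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    table, roi, truth = dataset.genotypes, dataset.roi, dataset.truth

    ped_path = out / "genotypes.ped"
    with ped_path.open("w", newline="\n") as fh:
        for i, subj in enumerate(table.subject_ids):
            pheno = "2" if truth.labels[i] == AD_LABEL else "1"
            fields = [subj, subj, "0", "0", "0", pheno]
            fields.extend(table.calls[i].ravel())
            fh.write("\t".join(fields) + "\n")

    map_path = out / "genotypes.map"
    with map_path.open("w", newline="\n") as fh:
        for _, row in table.snps.iterrows():
            fh.write(f"{row.chromosome}\t{row.snp_id}\t0\t{row.position}\n")

    gene_map_path = out / "gene_map.tsv"
    with gene_map_path.open("w", newline="\n") as fh:
        fh.write("snp_id\tgene_id\n")
        for _, row in table.snps.iterrows():
            fh.write(f"{row.snp_id}\t{row.gene_id}\n")

    roi_dir = out / "roi"
    roi_dir.mkdir(exist_ok=True)
    header = "region\t" + "\t".join(str(t) for t in range(roi.n_timepoints))
    for i, subj in enumerate(roi.subject_ids):
        with (roi_dir / f"{subj}.tsv").open("w", newline="\n") as fh:
            fh.write(header + "\n")
            for r, name in enumerate(roi.region_names):
                vals = "\t".join(FLOAT_FMT % v for v in roi.series[i, r])
                fh.write(f"{name}\t{vals}\n")

    labels_path = out / "labels.tsv"
    with labels_path.open("w", newline="\n") as fh:
        fh.write("subject_id\tlabel\n")
        for subj, lab in zip(table.subject_ids, truth.labels):
            fh.write(f"{subj}\t{int(lab)}\n")

    truth_path = out / "truth.json"
    payload = {
        "config": truth.config.to_dict(),
        "true_maf": [float(FLOAT_FMT % m) for m in truth.true_maf],
        "planted_couplings": [
            {"region_index": r, "gene_index": g, "effect_size": e}
            for r, g, e in truth.planted_couplings
        ],
        "labels": {s: int(l) for s, l in zip(table.subject_ids, truth.labels)},
    }
    truth_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")

    return {
        "ped": ped_path,
        "map": map_path,
        "gene_map": gene_map_path,
        "roi_dir": roi_dir,
        "labels": labels_path,
        "truth": truth_path,
    }
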