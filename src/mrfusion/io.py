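"""Readers/writers for the on-disk formats, run configuration and the
end-to-end orchestrated analysis.

Formats are plain text throughout: PLINK-style .ped/.map genotypes (missing
allele "0"), TSV tables (UTF-8, Unix newlines, 9-significant-digit floats)
and JSON reports. ``run_all`` executes the whole chain
simulate -> QC -> encode -> fuse -> split -> tree-count scan -> train ->
feature selection -> factor extraction, and emits a manifest whose bytes are
reproducible from the master seed alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import qc
from ._random import derive_seed
from .forest import MultimodalRandomForestClassifier
from .fusion import (
    FeatureID,
    FusionFeatureMatrix,
    ROISeriesSet,
    build_fusion_matrix,
    truncate_series,
)
from .pipeline import analyze_fusion_matrix
from .simulate import FLOAT_FMT, SimulationConfig, generate_dataset, write_fixture

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# readers
# ---------------------------------------------------------------------------

def read_ped_map(ped_path: str | Path, map_path: str | Path) -> qc.GenotypeTable:
    """Read PLINK-style text pedigree + map files into a GenotypeTable."""
    map_rows = []
    with Path(map_path).open() as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 4:
                raise ValueError(f"{map_path}:{ln}: expected 4 columns, got {len(parts)}")
            chrom, snp_id, _dist, pos = parts
            map_rows.append(
                {
                    "snp_id": snp_id,
                    "chromosome": int(chrom),
                    "position": int(pos),
                    "gene_id": None,
                    "allele_a": "",
                    "allele_b": "",
                }
            )
    if not map_rows:
        raise ValueError(f"empty map file {map_path}")
    n_snps = len(map_rows)

    subject_ids: list[str] = []
    labels: list[int] = []
    call_rows = []
    valid = qc.VALID_ALLELES | {qc.MISSING}
    with Path(ped_path).open() as fh:
        for ln, line in enumerate(fh, 1):
            parts = line.rstrip("\n").split("\t")
            if len(parts) != 6 + 2 * n_snps:
                raise ValueError(
                    f"{ped_path}:{ln}: expected {6 + 2 * n_snps} columns, got {len(parts)}"
                )
            iid = parts[1]
            if iid in subject_ids:
                raise ValueError(f"{ped_path}:{ln}: duplicate subject id {iid}")
            subject_ids.append(iid)
            labels.append(-1 if parts[5] == "2" else +1)
            alleles = parts[6:]
            for col, sym in enumerate(alleles):
                if sym not in valid:
                    raise ValueError(
                        f"{ped_path}:{ln}: non-nucleotide allele {sym!r} at allele column {col + 1}"
                    )
            call_rows.append(np.array(alleles, dtype="U1").reshape(n_snps, 2))
    if not call_rows:
        raise ValueError(f"empty ped file {ped_path}")
    calls = np.stack(call_rows, axis=0)
    # half-missing calls are treated as fully missing
    half = (calls == qc.MISSING).any(axis=2) & ~(calls == qc.MISSING).all(axis=2)
    if half.any():
        logger.warning("%d half-missing calls set to missing", int(half.sum()))
        calls[half] = qc.MISSING

    snps = pd.DataFrame(map_rows)
    # infer the two alleles per SNP from the observed calls
    allele_a = np.empty(n_snps, dtype="U1")
    allele_b = np.empty(n_snps, dtype="U1")
    for j in range(n_snps):
        seen = sorted(set(calls[:, j, :].ravel()) - {qc.MISSING})
        if len(seen) > 2:
            raise ValueError(f"SNP {snps.snp_id[j]} has more than two alleles: {seen}")
        seen = (seen + seen + ["A", "A"])[:2]  # pad monomorphic/all-missing columns
        allele_a[j], allele_b[j] = seen[0], seen[1]
    snps["allele_a"] = allele_a
    snps["allele_b"] = allele_b
    return qc.GenotypeTable(subject_ids=subject_ids, snps=snps, calls=calls)


def read_gene_map(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"snp_id", "gene_id"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns snp_id, gene_id")
    if df.empty:
        raise ValueError(f"empty gene map {path}")
    return dict(zip(df["snp_id"], df["gene_id"]))


def read_labels(path: str | Path) -> tuple[list[str], np.ndarray]:
    df = pd.read_csv(path, sep="\t", dtype={"subject_id": str, "label": int})
    if not {"subject_id", "label"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns subject_id, label")
    labels = df["label"].to_numpy()
    if not np.isin(labels, (-1, 1)).all():
        raise ValueError(f"{path}: labels must be -1 or +1")
    return df["subject_id"].tolist(), labels


def read_roi_dir(roi_dir: str | Path, subject_ids: list[str]) -> ROISeriesSet:
    """Read one TSV per subject (rows = regions, first column = region
    name, remaining columns = timepoints) in the given subject order."""
    roi_dir = Path(roi_dir)
    series = []
    region_names: list[str] | None = None
    for subj in subject_ids:
        path = roi_dir / f"{subj}.tsv"
        if not path.exists():
            raise FileNotFoundError(f"missing ROI table for subject {subj}: {path}")
        df = pd.read_csv(path, sep="\t", index_col=0)
        if region_names is None:
            region_names = df.index.tolist()
        elif df.index.tolist() != region_names:
            raise ValueError(f"{path}: region names differ from previous subjects")
        series.append(df.to_numpy(dtype=float))
    return ROISeriesSet(
        subject_ids=list(subject_ids),
        region_names=list(region_names or []),
        series=np.stack(series, axis=0),
    )


# ---------------------------------------------------------------------------
# writers
# ---------------------------------------------------------------------------

def _write_tsv(path: Path, header: list[str], rows) -> None:
    with path.open("w", newline="\n") as fh:
        fh.write("\t".join(header) + "\n")
        for row in rows:
            fh.write(
                "\t".join(
                    FLOAT_FMT % v if isinstance(v, float) else str(v) for v in row
                )
                + "\n"
            )


def write_fusion_matrix(matrix: FusionFeatureMatrix, path: str | Path) -> None:
    path = Path(path)
    header = ["subject_id", "label"] + [str(c) for c in matrix.column_ids]
    rows = (
        [matrix.subject_ids[i], int(matrix.labels[i])] + [float(v) for v in matrix.values[i]]
        for i in range(len(matrix.subject_ids))
    )
    _write_tsv(path, header, rows)
    sidecar = {
        "n_regions": len(matrix.region_names),
        "n_genes": len(matrix.gene_ids),
        "region_names": matrix.region_names,
        "gene_ids": matrix.gene_ids,
        "subject_ids": matrix.subject_ids,
        "labels": [int(v) for v in matrix.labels],
        "n_degenerate": matrix.n_degenerate,
    }
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=1, sort_keys=True) + "\n")


def read_fusion_matrix(path: str | Path) -> FusionFeatureMatrix:
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    df = pd.read_csv(path, sep="\t")
    region_names = sidecar["region_names"]
    gene_ids = sidecar["gene_ids"]
    column_ids = [
        FeatureID.parse(c, region_names, gene_ids) for c in df.columns[2:]
    ]
    return FusionFeatureMatrix(
        subject_ids=df["subject_id"].astype(str).tolist(),
        labels=df["label"].to_numpy(),
        column_ids=column_ids,
        values=df.iloc[:, 2:].to_numpy(dtype=float),
        region_names=region_names,
        gene_ids=gene_ids,
        n_degenerate=sidecar.get("n_degenerate", 0),
    )


def write_forest(model: MultimodalRandomForestClassifier, path: str | Path) -> None:
    payload = {
        "params": model.get_params(),
        "m": model.m_,
        "n_features_in": model.n_features_in_,
        "trees": [t.to_dict() for t in model.trees_],
    }
    Path(path).write_text(json.dumps(payload, sort_keys=True) + "\n")


def read_forest(path: str | Path) -> MultimodalRandomForestClassifier:
    from .forest import TreeSpec

    payload = json.loads(Path(path).read_text())
    model = MultimodalRandomForestClassifier(**payload["params"])
    model.m_ = payload["m"]
    model.n_features_in_ = payload["n_features_in"]
    model.classes_ = np.array([-1, 1])
    model.trees_ = [TreeSpec.from_dict(d) for d in payload["trees"]]
    return model


# ---------------------------------------------------------------------------
# pipeline configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PipelineConfig:
    """All stage parameters with the reference analysis values as defaults."""

    # QC
    sample_call_rate_min: float = 0.95
    snp_call_rate_min: float = 0.999
    maf_min: float = 0.04
    hwe_p_min: float = 1e-4
    min_snps_per_gene: int = 30
    allele_policy: str = "major_allele"
    # split
    split_ratio: tuple[int, int] = (6, 4)
    # tree-count scan
    tree_grid_start: int = 10
    tree_grid_end: int = 600
    tree_grid_step: int = 10
    stability_window: int = 5
    stability_epsilon: float = 0.02
    # selection
    top_trees: int = 100
    top_features: int = 400
    subset_min: int = 70
    subset_max: int = 400
    subset_step: int = 5
    # seeds and simulation
    seed: int = 0
    simulation: SimulationConfig = field(default_factory=SimulationConfig)

    def __post_init__(self) -> None:
        if self.allele_policy not in qc.ALLELE_POLICIES:
            raise ValueError(f"unknown allele policy {self.allele_policy!r}")
        if self.min_snps_per_gene < 0:
            raise ValueError("min_snps_per_gene must be >= 0")
        if self.subset_min > self.subset_max:
            raise ValueError("subset_min exceeds subset_max")

    def qc_thresholds(self) -> qc.QCThresholds:
        return qc.QCThresholds(
            sample_call_rate_min=self.sample_call_rate_min,
            snp_call_rate_min=self.snp_call_rate_min,
            maf_min=self.maf_min,
            hwe_p_min=self.hwe_p_min,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        if "split_ratio" in d:
            d["split_ratio"] = tuple(d["split_ratio"])
        if "simulation" in d and isinstance(d["simulation"], dict):
            d["simulation"] = SimulationConfig.from_dict(d["simulation"])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with Path(path).open() as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


# ---------------------------------------------------------------------------
# orchestration
# ---------------------------------------------------------------------------

@dataclass
class RunManifest:
    config_hash: str
    master_seed: int
    stage_seeds: dict[str, int] = field(default_factory=dict)
    input_digests: dict[str, str] = field(default_factory=dict)
    outputs: dict[str, str] = field(default_factory=dict)
    summary: dict = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=1, sort_keys=True) + "\n"


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_all(
    config: PipelineConfig,
    out_dir: str | Path,
    simulate: bool = True,
    input_dir: str | Path | None = None,
) -> RunManifest:
    """Execute the full analysis chain and write every artifact to ``out_dir``.

    With ``simulate=True`` a synthetic fixture is generated first (into
    ``out_dir/data``) and then consumed through the same on-disk readers as
    real inputs, so the simulated path exercises the identical code path.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = config.seed
    manifest = RunManifest(
        config_hash=hashlib.sha256(
            json.dumps(config.to_dict(), sort_keys=True).encode()
        ).hexdigest(),
        master_seed=seed,
    )
    (out / "config.yaml").write_text(config.to_yaml())
    manifest.outputs["config.yaml"] = _digest(out / "config.yaml")

    # --- inputs -----------------------------------------------------------
    if simulate:
        sim_config = dataclasses.replace(
            config.simulation, seed=derive_seed(seed, "simulate")
        )
        manifest.stage_seeds["simulate"] = sim_config.seed
        dataset = generate_dataset(sim_config)
        paths = write_fixture(dataset, out / "data")
        data_dir = out / "data"
    elif input_dir is not None:
        data_dir = Path(input_dir)
        paths = {
            "ped": data_dir / "genotypes.ped",
            "map": data_dir / "genotypes.map",
            "gene_map": data_dir / "gene_map.tsv",
            "roi_dir": data_dir / "roi",
            "labels": data_dir / "labels.tsv",
        }
    else:
        raise ValueError("either simulate=True or input_dir is required")
    for key in ("ped", "map", "gene_map", "labels"):
        if not Path(paths[key]).exists():
            raise FileNotFoundError(f"stage inputs: missing {key} file {paths[key]}")
        manifest.input_digests[key] = _digest(Path(paths[key]))

    # --- genotype QC ------------------------------------------------------
    table = read_ped_map(paths["ped"], paths["map"])
    table = qc.attach_gene_map(table, read_gene_map(paths["gene_map"]))
    table, report = qc.apply_qc(table, config.qc_thresholds())
    manifest.warnings.extend(report.warnings)
    (out / "qc_report.json").write_text(
        json.dumps(report.to_dict(), indent=1, sort_keys=True) + "\n"
    )
    if table.n_snps == 0 or table.n_subjects == 0:
        raise RuntimeError("stage qc: empty table after filtering")

    groups, n_unmapped = qc.group_by_gene(table, config.min_snps_per_gene)
    if not groups:
        raise RuntimeError("stage qc: no gene group above the SNP-count threshold")
    sequences, L, n_imputed = qc.segment_to_length(
        table,
        groups,
        policy=config.allele_policy,
        seed=derive_seed(seed, "allele-policy"),
    )
    encoded = qc.encode_gene_matrices(sequences)
    _write_tsv(
        out / "encoded_genes.tsv",
        ["gene_id", "subject_id"] + [f"pos{j}" for j in range(L)],
        (
            [g.gene_id, table.subject_ids[i]] + [int(v) for v in g.codes[i]]
            for g in encoded
            for i in range(table.n_subjects)
        ),
    )

    # --- fusion -----------------------------------------------------------
    subj_ids, labels = read_labels(paths["labels"])
    label_map = dict(zip(subj_ids, (int(v) for v in labels)))
    missing_labels = set(table.subject_ids) - set(label_map)
    if missing_labels:
        raise RuntimeError(f"stage fuse: subjects without labels: {sorted(missing_labels)}")
    roi = read_roi_dir(paths["roi_dir"], table.subject_ids)
    roi = truncate_series(roi, L)
    matrix = build_fusion_matrix(roi, encoded, label_map)
    write_fusion_matrix(matrix, out / "fusion_matrix.tsv")

    # --- split, tree-count scan, forest, selection, factors ----------------
    for stage in ("split", "tree-scan", "forest", "selection"):
        manifest.stage_seeds[stage] = derive_seed(seed, stage)
    analysis = analyze_fusion_matrix(matrix, config)
    curve = analysis.curve
    a_star = analysis.selected_tree_count
    _write_tsv(
        out / "tree_count_curve.tsv",
        ["n_trees", "accuracy"],
        zip(curve.tree_counts.tolist(), (float(a) for a in curve.accuracies)),
    )
    write_forest(analysis.forest, out / "forest.json")

    result = analysis.selection
    table_ids = [matrix.column_ids[i] for i in result.frequency_table.feature_indices]
    _write_tsv(
        out / "feature_frequencies.tsv",
        ["rank", "feature_id", "count"],
        (
            (rank + 1, str(fid), int(cnt))
            for rank, (fid, cnt) in enumerate(zip(table_ids, result.frequency_table.counts))
        ),
    )
    _write_tsv(
        out / "subset_scan.tsv",
        ["size", "accuracy"],
        zip(result.scan.sizes.tolist(), (float(a) for a in result.scan.accuracies)),
    )
    optimal_ids = analysis.optimal_feature_ids
    _write_tsv(
        out / "optimal_features.tsv",
        ["rank", "feature_id"],
        ((i + 1, str(fid)) for i, fid in enumerate(optimal_ids)),
    )

    # --- factor extraction -------------------------------------------------
    ranking = analysis.ranking
    _write_tsv(
        out / "region_ranking.tsv",
        ["region", "count"],
        ((name, int(c)) for name, c in ranking.region_counts.items()),
    )
    _write_tsv(
        out / "gene_ranking.tsv",
        ["gene", "count"],
        ((name, int(c)) for name, c in ranking.gene_counts.items()),
    )

    optimal_size = int(result.scan.optimal_size)
    optimal_accuracy = analysis.optimal_accuracy
    manifest.summary = {
        "n_subjects": table.n_subjects,
        "n_snps_post_qc": table.n_snps,
        "n_unmapped_snps": n_unmapped,
        "n_imputed_calls": n_imputed,
        "n_genes_retained": len(groups),
        "segment_length": L,
        "n_fusion_features": matrix.n_features,
        "n_degenerate_features": matrix.n_degenerate,
        "per_tree_feature_count": analysis.forest.m_,
        "selected_tree_count": a_star,
        "full_forest_test_accuracy": analysis.full_forest_accuracy,
        "optimal_subset_size": optimal_size,
        "optimal_subset_test_accuracy": optimal_accuracy,
        "top_region": str(ranking.region_counts.index[0]),
        "top_gene": str(ranking.gene_counts.index[0]),
    }
    for name in (
        "qc_report.json", "encoded_genes.tsv", "fusion_matrix.tsv",
        "tree_count_curve.tsv", "forest.json", "feature_frequencies.tsv",
        "subset_scan.tsv", "optimal_features.tsv", "region_ranking.tsv",
        "gene_ranking.tsv",
    ):
        manifest.outputs[name] = _digest(out / name)
    (out / "manifest.json").write_text(manifest.to_json())
    return manifest
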