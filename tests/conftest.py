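import numpy as np
import pandas as pd
import pytest

from mrfusion import GenotypeTable, SimulationConfig, generate_dataset
from mrfusion.io import PipelineConfig


def make_table(calls, allele_a=None, allele_b=None, gene_ids=None):
    """Build a small GenotypeTable from a (subjects, snps, 2) call array."""
    calls = np.asarray(calls, dtype="U1")
    n, p, _ = calls.shape
    if allele_a is None or allele_b is None:
        allele_a, allele_b = [], []
        for j in range(p):
            seen = sorted(set(calls[:, j, :].ravel()) - {"0"})
            seen = (seen + ["A", "C"])[:2]
            allele_a.append(seen[0])
            allele_b.append(seen[1])
    snps = pd.DataFrame(
        {
            "snp_id": [f"snp{j}" for j in range(p)],
            "chromosome": [1] * p,
            "position": list(range(100, 100 + p)),
            "gene_id": gene_ids if gene_ids is not None else [None] * p,
            "allele_a": allele_a,
            "allele_b": allele_b,
        }
    )
    return GenotypeTable(
        subject_ids=[f"S{i}" for i in range(n)], snps=snps, calls=calls
    )


@pytest.fixture(scope="session")
def small_sim_config():
    """A reduced cohort that still exercises every pipeline stage."""
    return SimulationConfig(
        n_ad=10,
        n_nc=10,
        n_regions=6,
        n_genes=4,
        snps_per_gene=(31, 34),
        n_timepoints=40,
        planted_couplings=((1, 2, 1.0),),
        maf_range=(0.25, 0.5),
        seed=42,
    )


@pytest.fixture(scope="session")
def small_dataset(small_sim_config):
    return generate_dataset(small_sim_config)


@pytest.fixture(scope="session")
def small_pipeline_config(small_sim_config):
    return PipelineConfig(
        seed=42,
        simulation=small_sim_config,
        min_snps_per_gene=30,
        tree_grid_start=10,
        tree_grid_end=60,
        tree_grid_step=10,
        top_trees=20,
        top_features=24,
        subset_min=4,
        subset_max=20,
        subset_step=4,
    )
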