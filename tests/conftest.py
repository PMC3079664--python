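import numpy as np
import pytest

from rsnpset import (
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
    SimulationConfig,
    simulate_null_dataset,
)
from rsnpset.snp_sets import build_snp_sets, map_snps_to_genes

#: Session-wide base seed; all test randomness derives from it.
BASE_SEED = 20260921 % (2**31)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(BASE_SEED)


@pytest.fixture
def tiny_genotypes():
    """4 SNPs x 6 samples, one missing entry."""
    dosages = np.array(
        [
            [0, 1, 2, 1, 0, 2],
            [-1, 0, 0, 1, 1, 2],
            [2, 2, 1, 0, 0, 0],
            [0, 0, 0, 1, 2, 2],
        ],
        dtype=np.int8,
    )
    return GenotypeMatrix(
        [f"rs{i}" for i in range(1, 5)], [f"S{j}" for j in range(1, 7)], dosages
    )


@pytest.fixture
def tiny_labels():
    status = [False, False, False, True, True, True]
    cohort = ["A", "B", "A", None, None, None]
    return PhenotypeLabels([f"S{j}" for j in range(1, 7)], status, cohort)


@pytest.fixture
def tiny_collection():
    return GeneSetCollection(
        [
            GeneSet("PATH_A", "first", ("G1", "G2")),
            GeneSet("PATH_B", "second", ("G2", "G3", "NOPE")),
        ]
    )


@pytest.fixture(scope="session")
def null_dataset_small():
    """Small null dataset reused across tests (200 SNPs, 60+60 samples)."""
    cfg = SimulationConfig(
        n_snps=200, n_genes=20, genes_per_set=2, n_sets=10,
        n_cases=60, n_controls=60, seed=BASE_SEED,
    )
    return simulate_null_dataset(cfg)


@pytest.fixture(scope="session")
def null_sets_small(null_dataset_small):
    mapping = map_snps_to_genes(
        null_dataset_small.snp_annotation, null_dataset_small.gene_annotation
    )
    return build_snp_sets(mapping, null_dataset_small.gene_sets)
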