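"""Synthetic case/control GWAS fixtures with known ground truth.

Genotypes are biallelic dosages drawn per SNP from Hardy-Weinberg proportions
at a minor-allele frequency sampled uniformly from a configurable range.
Genes are tiled along synthetic chromosomes with their SNPs placed inside the
gene body, and gene sets partition consecutive genes, so the positional
SNP-to-gene mapping is unambiguous at the default window.

Planted association follows the additive model the trend test targets: for an
associated SNP, case genotypes are drawn with probability proportional to
HWE(k) * RR^k (k = dosage, RR = per-allele genotypic relative risk), controls
from plain HWE.  With RR = 1 the generator reduces exactly to the null
generator under the same seed: each randomness source (MAF spectrum, genotype
draws, missingness, planted-SNP choice) uses its own child stream of the
seed, so the genotype stream does not depend on the planting draws.

SNPs are independent by default.  An optional LD mode (``ld_block_size`` > 1)
copies each block's root genotypes to the other block members, alternating
the allele coding — maximal within-block dependence, to exercise the claim
that label permutation remains valid under LD.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .io_formats import (
    GeneSet,
    GeneSetCollection,
    GenotypeMatrix,
    PhenotypeLabels,
)

log = logging.getLogger(__name__)

_N_CHROMOSOMES = 22
_INTERGENIC_GAP = 60_000  # > 2x the default 5 kb window: unambiguous mapping
_SNP_SPACING = 1_000


@dataclass(frozen=True)
class SimulationConfig:
    """Study-design parameters for the generator.

    Defaults are the desk-scale analogue of a case/control GWAS: 2,000 SNPs
    in 200 genes grouped into 40 disjoint 5-gene sets, 250 cases and 250
    controls, MAF uniform on (0.05, 0.5), no missingness, no LD.
    """

    n_snps: int = 2000
    n_cases: int = 250
    n_controls: int = 250
    maf_range: tuple[float, float] = (0.05, 0.5)
    n_genes: int = 200
    genes_per_set: int = 5
    n_sets: int = 40
    planted_set_ids: tuple[int, ...] = ()
    fraction_associated_in_planted: float = 0.3
    genotype_relative_risk: float = 1.5
    missing_rate: float = 0.0
    ld_block_size: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_snps, self.n_cases, self.n_controls, self.n_genes,
               self.genes_per_set, self.n_sets, self.ld_block_size) < 1:
            raise ValueError("counts must be >= 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError("maf_range must satisfy 0 < lo <= hi < 1")
        if not 0.0 < self.fraction_associated_in_planted < 1.0:
            raise ValueError("fraction_associated_in_planted must be in (0, 1)")
        if self.genotype_relative_risk < 1.0:
            raise ValueError("genotype_relative_risk must be >= 1")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must be in [0, 1)")
        if self.n_sets * self.genes_per_set > self.n_genes:
            raise ValueError("n_sets * genes_per_set exceeds n_genes")
        if any(t < 0 or t >= self.n_sets for t in self.planted_set_ids):
            raise ValueError("planted_set_ids out of range")
        if self.n_genes > self.n_snps:
            raise ValueError("need at least one SNP per gene")


@dataclass
class SimulatedDataset:
    genotypes: GenotypeMatrix
    labels: PhenotypeLabels
    snp_annotation: pd.DataFrame
    gene_annotation: pd.DataFrame
    gene_sets: GeneSetCollection
    truth: pd.DataFrame | None = None  # (snp_id, set) rows for planted SNPs


def _layout(config: SimulationConfig) -> tuple[pd.DataFrame, pd.DataFrame, np.ndarray]:
    """Deterministic gene/SNP placement; returns (snp_ann, gene_ann, snp_gene)."""
    base, extra = divmod(config.n_snps, config.n_genes)
    snps_per_gene = np.full(config.n_genes, base, dtype=int)
    snps_per_gene[:extra] += 1

    chrom_slot = np.zeros(_N_CHROMOSOMES, dtype=np.int64)  # next free position
    gene_rows, snp_rows = [], []
    snp_gene = np.empty(config.n_snps, dtype=np.int64)
    snp_i = 0
    for g in range(config.n_genes):
        c = g % _N_CHROMOSOMES
        k = snps_per_gene[g]
        start = chrom_slot[c] + _INTERGENIC_GAP
        end = start + _SNP_SPACING * (k + 1)
        chrom_slot[c] = end
        gene_rows.append((f"GENE{g + 1:04d}", str(c + 1), start, end))
        for j in range(k):
            snp_rows.append((f"rs{snp_i + 1:06d}", str(c + 1), start + _SNP_SPACING * (j + 1)))
            snp_gene[snp_i] = g
            snp_i += 1
    gene_ann = pd.DataFrame(gene_rows, columns=["gene_id", "chrom", "start", "end"])
    snp_ann = pd.DataFrame(snp_rows, columns=["snp_id", "chrom", "pos"])
    return snp_ann, gene_ann, snp_gene


def _gene_sets(config: SimulationConfig) -> GeneSetCollection:
    sets = []
    for t in range(config.n_sets):
        genes = tuple(
            f"GENE{g + 1:04d}"
            for g in range(t * config.genes_per_set, (t + 1) * config.genes_per_set)
        )
        sets.append(GeneSet(f"SET{t + 1:03d}", f"synthetic pathway {t + 1}", genes))
    return GeneSetCollection(sets)


def _simulate(config: SimulationConfig) -> SimulatedDataset:
    snp_ann, gene_ann, snp_gene = _layout(config)
    collection = _gene_sets(config)
    n, l1, l2 = config.n_snps, config.n_controls, config.n_cases
    l = l1 + l2

    # independent child streams: the genotype stream must not depend on
    # whether (or which) SNPs are planted, so RR = 1 reduces to the null
    rng_maf = np.random.default_rng([config.seed, 0])
    rng_geno = np.random.default_rng([config.seed, 1])
    rng_missing = np.random.default_rng([config.seed, 2])
    rng_truth = np.random.default_rng([config.seed, 3])

    maf = rng_maf.uniform(*config.maf_range, size=n)
    hwe = np.stack([(1 - maf) ** 2, 2 * maf * (1 - maf), maf**2], axis=1)  # (n, 3)

    truth_rows: list[tuple[str, str]] = []
    associated = np.zeros(n, dtype=bool)
    rr_power = np.array([1.0, config.genotype_relative_risk,
                         config.genotype_relative_risk ** 2])
    for t in sorted(config.planted_set_ids):
        gene_lo = t * config.genes_per_set
        gene_hi = (t + 1) * config.genes_per_set
        set_snps = np.flatnonzero((snp_gene >= gene_lo) & (snp_gene < gene_hi))
        k = max(1, int(round(config.fraction_associated_in_planted * set_snps.size)))
        chosen = rng_truth.choice(set_snps, size=k, replace=False)
        associated[chosen] = True
        name = collection.sets[t].name
        truth_rows.extend((snp_ann["snp_id"].iloc[i], name) for i in sorted(chosen))

    case_probs = hwe * rr_power[None, :]
    case_probs /= case_probs.sum(axis=1, keepdims=True)
    case_probs = np.where(associated[:, None], case_probs, hwe)

    # inverse-CDF draw from one uniform per (SNP, sample)
    u = rng_geno.random((n, l))
    cum_ctrl = np.cumsum(hwe, axis=1)
    cum_case = np.cumsum(case_probs, axis=1)
    dosages = np.zeros((n, l), dtype=np.int8)
    for cum, cols in ((cum_ctrl, slice(0, l1)), (cum_case, slice(l1, l))):
        block = u[:, cols]
        dosages[:, cols] = (block > cum[:, [0]]).astype(np.int8) + (
            block > cum[:, [1]]
        ).astype(np.int8)

    if config.ld_block_size > 1:
        # copy-with-flip: block members replicate the root SNP's genotypes,
        # alternating the allele coding (dosage -> 2 - dosage)
        for start in range(0, n, config.ld_block_size):
            stop = min(start + config.ld_block_size, n)
            for i in range(start + 1, stop):
                dosages[i] = dosages[start] if (i - start) % 2 == 0 else 2 - dosages[start]

    if config.missing_rate > 0:
        miss = rng_missing.random((n, l)) < config.missing_rate
        dosages[miss] = -1

    sample_ids = [f"C{j + 1:05d}" for j in range(l1)] + [f"P{j + 1:05d}" for j in range(l2)]
    status = np.zeros(l, dtype=bool)
    status[l1:] = True
    # two control cohorts, mirroring a two-source control design
    cohort = np.array(
        [("COHORT_A" if j % 2 == 0 else "COHORT_B") if j < l1 else None for j in range(l)],
        dtype=object,
    )
    genotypes = GenotypeMatrix(list(snp_ann["snp_id"]), sample_ids, dosages)
    labels = PhenotypeLabels(sample_ids, status, cohort)
    truth = (
        pd.DataFrame(truth_rows, columns=["snp_id", "set"])
        if config.planted_set_ids
        else None
    )
    return SimulatedDataset(genotypes, labels, snp_ann, gene_ann, collection, truth)


def simulate_null_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Genotypes independent of phenotype (no planted sets allowed)."""
    if config.planted_set_ids:
        raise ValueError("null dataset must not have planted sets")
    return _simulate(config)


def simulate_planted_dataset(config: SimulationConfig) -> SimulatedDataset:
    """Dataset with per-allele relative risk planted in chosen sets.

    Returns the same tuple as the null generator plus a truth table listing
    every associated SNP and its host set.  With RR = 1 the genotypes are
    identical to the null generator's under the same seed.
    """
    if not config.planted_set_ids:
        raise ValueError("planted dataset needs planted_set_ids")
    return _simulate(config)
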