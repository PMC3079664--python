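"""Resolve gene sets (pathways) to SNP sets by positional mapping.

A SNP is assigned to a gene when it lies on the same chromosome within
``window_kb`` kilobases of the gene body (boundary inclusive); a SNP inside
the shared span of two overlapping genes is assigned to both.  An optional
closest-gene mode instead assigns every SNP to its nearest gene(s) at any
distance.  A gene set's SNP set is the union of SNPs mapped to any of its
member genes.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io_formats import GeneSetCollection

log = logging.getLogger(__name__)

#: Default gene-to-SNP assignment window in kilobases.
DEFAULT_WINDOW_KB = 5.0


@dataclass
class SnpGeneMap:
    """Per-SNP gene assignments over an ordered SNP universe.

    ``genes[i]`` is the (possibly empty) frozenset of gene_ids mapped to
    ``snp_ids[i]``.  The mapping is a pure function of the two annotations
    and the window.
    """

    snp_ids: list[str]
    genes: list[frozenset]

    def __post_init__(self) -> None:
        if len(self.snp_ids) != len(self.genes):
            raise ValueError("snp_ids/genes length mismatch")

    def to_frame(self) -> pd.DataFrame:
        """Long-form (snp_id, gene_id) pairs, for TSV export."""
        rows = [
            (s, g) for s, gs in zip(self.snp_ids, self.genes) for g in sorted(gs)
        ]
        return pd.DataFrame(rows, columns=["snp_id", "gene_id"])

    def mapped_mask(self) -> np.ndarray:
        """Boolean mask of SNPs mapped to at least one gene."""
        return np.array([len(g) > 0 for g in self.genes])


@dataclass
class SnpSet:
    """A named SNP set: indices into the SNP universe plus mapping provenance."""

    name: str
    snp_indices: np.ndarray
    genes_matched: int
    genes_unmatched: int

    def __post_init__(self) -> None:
        self.snp_indices = np.unique(np.asarray(self.snp_indices, dtype=np.int64))

    @property
    def m(self) -> int:
        return int(self.snp_indices.size)


def map_snps_to_genes(
    snps: pd.DataFrame,
    genes: pd.DataFrame,
    window_kb: float = DEFAULT_WINDOW_KB,
    closest_gene: bool = False,
) -> SnpGeneMap:
    """Assign SNPs to genes by position.

    ``snps``/``genes`` are the annotation tables from
    :mod:`rsnpset.io_formats` (1-based coordinates, normalized chromosome
    labels).  Window mode (default): SNP maps to gene G iff it lies in
    [start - window, end + window] on the same chromosome.  Closest-gene
    mode: each SNP maps to the nearest gene(s) on its chromosome regardless
    of distance (ties map to all nearest genes); SNPs on gene-less
    chromosomes stay unmapped.
    """
    window = int(round(window_kb * 1000))
    assigned: list[set] = [set() for _ in range(len(snps))]
    snp_rows = snps.reset_index(drop=True)

    for chrom, snp_idx in snp_rows.groupby("chrom").groups.items():
        g = genes[genes["chrom"] == chrom]
        if g.empty:
            continue
        idx = np.asarray(snp_idx)
        pos = snp_rows.loc[idx, "pos"].to_numpy()
        order = np.argsort(pos, kind="mergesort")
        pos_sorted = pos[order]
        idx_sorted = idx[order]
        if not closest_gene:
            starts = g["start"].to_numpy() - window
            ends = g["end"].to_numpy() + window
            for gene_id, lo, hi in zip(g["gene_id"], starts, ends):
                a = np.searchsorted(pos_sorted, lo, side="left")
                b = np.searchsorted(pos_sorted, hi, side="right")
                for i in idx_sorted[a:b]:
                    assigned[i].add(gene_id)
        else:
            gstart = g["start"].to_numpy()
            gend = g["end"].to_numpy()
            gids = g["gene_id"].to_numpy()
            for i, p in zip(idx_sorted, pos_sorted):
                dist = np.maximum(gstart - p, 0) + np.maximum(p - gend, 0)
                dmin = dist.min()
                for gid in gids[dist == dmin]:
                    assigned[i].add(gid)

    return SnpGeneMap(list(snp_rows["snp_id"]), [frozenset(a) for a in assigned])


def build_snp_sets(
    snp_gene_map: SnpGeneMap,
    collection: GeneSetCollection,
    min_snps: int = 2,
    max_snps: int | None = None,
) -> list[SnpSet]:
    """Resolve each gene set to the union of SNPs mapped to its member genes.

    Sets with fewer than ``min_snps`` or more than ``max_snps`` member SNPs
    are excluded with a logged reason; genes absent from the gene-SNP map are
    counted per set as ``genes_unmatched``.  Raises if nothing survives.
    """
    gene_to_snps: dict[str, list[int]] = {}
    for i, gs in enumerate(snp_gene_map.genes):
        for g in gs:
            gene_to_snps.setdefault(g, []).append(i)

    out: list[SnpSet] = []
    for gene_set in collection:
        idx: set[int] = set()
        matched = 0
        for g in gene_set.genes:
            snps = gene_to_snps.get(g)
            if snps is not None:
                matched += 1
                idx.update(snps)
        unmatched = len(gene_set.genes) - matched
        s = SnpSet(gene_set.name, np.fromiter(idx, dtype=np.int64, count=len(idx)),
                   matched, unmatched)
        if s.m < min_snps:
            log.info("excluding set %s: m=%d < min_snps=%d", s.name, s.m, min_snps)
            continue
        if max_snps is not None and s.m > max_snps:
            log.info("excluding set %s: m=%d > max_snps=%d", s.name, s.m, max_snps)
            continue
        out.append(s)
    if not out:
        raise ValueError("no gene set survived the size filter")
    return out


def set_summary(sets: list[SnpSet]) -> pd.DataFrame:
    """Per-set summary table (set, m, genes_matched, genes_unmatched)."""
    return pd.DataFrame(
        {
            "set": [s.name for s in sets],
            "m": [s.m for s in sets],
            "genes_matched": [s.genes_matched for s in sets],
            "genes_unmatched": [s.genes_unmatched for s in sets],
        }
    )
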