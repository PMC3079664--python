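"""Random-set enrichment of SNP sets: scores, permutation null, p/FDR/FWER.

For a SNP set S of size m in a universe of n post-QC SNPs, with d SNPs
genome-wide significant at level alpha and y of them inside S, the
enrichment score standardizes y against the analytic randomization null —
random m-SNP sets — under which y ~ Hyp(m, d, n):

    mu = m d / n,   sigma^2 = m (d/n) (1 - d/n) (n - m) / (n - 1),
    z = (y - mu) / sigma            (z = 0 when sigma^2 = 0).

The phenotype-label permutation null is layered on top: labels are permuted
Pi times (genotype columns untouched, preserving LD), all n single-SNP
p-values are recomputed, and z_pi is re-standardized with that permutation's
own d_pi.  The set's p-value is the fraction of permutations with
z_pi >= z_obs; FDR and FWER over the T sets are estimated from the same
permutation score matrix.  Only over-representation (large z) is tested.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .association import MODELS, AssociationKernel
from .io_formats import GenotypeMatrix, PhenotypeLabels
from .snp_sets import SnpSet

log = logging.getLogger(__name__)

DEFAULT_ALPHA = 0.01
DEFAULT_PERMUTATIONS = 1000


def count_significant(pvalues, alpha: float) -> int:
    """d = number of SNPs with p-value P <= alpha (inclusive)."""
    p = np.asarray(pvalues, dtype=float)
    if (p < 0).any() or (p > 1).any():
        raise ValueError("p-values must lie in [0, 1]")
    return int((p <= alpha).sum())


def count_in_set(pvalues, snp_set: SnpSet, alpha: float) -> int:
    """y = number of set-member SNPs with p-value P <= alpha."""
    p = np.asarray(pvalues, dtype=float)
    if snp_set.snp_indices.size and snp_set.snp_indices.max() >= p.size:
        raise ValueError(f"set {snp_set.name} indexes beyond the SNP universe")
    return int((p[snp_set.snp_indices] <= alpha).sum())


def hypergeom_moments(m: int, d: int, n: int) -> tuple[float, float]:
    """Mean and variance of y ~ Hyp(m, d, n).

    mu = m d / n;  sigma^2 = m (d/n) (1 - d/n) (n - m) / (n - 1), with
    sigma^2 = 0 when n = 1.
    """
    if not (0 <= m <= n and 0 <= d <= n and n >= 1):
        raise ValueError(f"need 0 <= m, d <= n and n >= 1; got m={m}, d={d}, n={n}")
    frac = d / n
    mu = m * frac
    sigma2 = 0.0 if n == 1 else m * frac * (1.0 - frac) * (n - m) / (n - 1.0)
    return float(mu), float(sigma2)


def standardized_score(y: int, m: int, d: int, n: int) -> float:
    """Restandardized enrichment score z = (y - mu) / sigma; 0 when sigma = 0."""
    mu, sigma2 = hypergeom_moments(m, d, n)
    if sigma2 == 0.0:
        return 0.0
    return float((y - mu) / np.sqrt(sigma2))


def _scores_from_pvalues(
    pvalues: np.ndarray, member: np.ndarray, m: np.ndarray, alpha: float
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """(y, z, d) for one or many p-value vectors.

    ``pvalues``: (n,) or (n, B); ``member``: (T, n) 0/1 membership matrix.
    Vectorized restandardization shared by the observed and permuted paths.
    """
    p = np.atleast_2d(np.asarray(pvalues, dtype=float).T).T  # (n, B)
    n = p.shape[0]
    sig = (p <= alpha).astype(np.float64)  # (n, B)
    d = sig.sum(axis=0)  # (B,)
    y = member @ sig  # (T, B)
    frac = d / n
    mu = m[:, None] * frac[None, :]
    sigma2 = m[:, None] * (frac * (1.0 - frac))[None, :] * (n - m[:, None]) / max(n - 1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sigma2 > 0, (y - mu) / np.sqrt(np.where(sigma2 > 0, sigma2, 1.0)), 0.0)
    return y, z, d


@dataclass
class PermutationScores:
    """Standardized scores from label permutations: a Pi x T matrix.

    Carries per-permutation genome-wide significant counts ``d`` and run
    identity (seed, block id, alpha, model, universe size) so independent
    blocks can be validated and pooled.
    """

    set_names: list[str]
    m: np.ndarray  # (T,) set sizes
    z: np.ndarray  # (Pi, T)
    d: np.ndarray  # (Pi,)
    n: int
    alpha: float
    model: str
    seed: int | None = None
    block_id: int = 0

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        self.d = np.asarray(self.d)
        self.m = np.asarray(self.m, dtype=np.int64)
        if self.z.shape != (self.d.size, len(self.set_names)):
            raise ValueError("score matrix shape inconsistent with Pi and T")
        if self.m.shape != (len(self.set_names),):
            raise ValueError("set-size vector inconsistent with set list")

    @property
    def n_permutations(self) -> int:
        return int(self.d.size)

    def save(self, path) -> None:
        np.savez(
            path,
            set_names=np.array(self.set_names),
            m=self.m,
            z=self.z,
            d=self.d,
            n=self.n,
            alpha=self.alpha,
            model=self.model,
            seed=-1 if self.seed is None else self.seed,
            block_id=self.block_id,
        )

    @classmethod
    def load(cls, path) -> "PermutationScores":
        with np.load(path, allow_pickle=False) as f:
            seed = int(f["seed"])
            return cls(
                set_names=[str(s) for s in f["set_names"]],
                m=f["m"],
                z=f["z"],
                d=f["d"],
                n=int(f["n"]),
                alpha=float(f["alpha"]),
                model=str(f["model"]),
                seed=None if seed < 0 else seed,
                block_id=int(f["block_id"]),
            )


def _membership(sets: list[SnpSet], n: int) -> tuple[np.ndarray, np.ndarray]:
    member = np.zeros((len(sets), n), dtype=np.float64)
    for t, s in enumerate(sets):
        if s.snp_indices.size and s.snp_indices.max() >= n:
            raise ValueError(f"set {s.name} indexes beyond the SNP universe")
        member[t, s.snp_indices] = 1.0
    return member, np.array([s.m for s in sets], dtype=np.int64)


def observed_scores(
    genotypes: GenotypeMatrix,
    labels: PhenotypeLabels,
    sets: list[SnpSet],
    model: str = "additive",
    alpha: float = DEFAULT_ALPHA,
) -> pd.DataFrame:
    """Observed per-set (m, y, z) plus genome-wide d under the true labels."""
    kernel = AssociationKernel(genotypes.dosages)
    pvals = kernel.pvalues(labels.status.astype(np.float64), model)[1]
    member, m = _membership(sets, genotypes.n_snps)
    y, z, d = _scores_from_pvalues(pvals, member, m, alpha)
    return pd.DataFrame(
        {
            "name": [s.name for s in sets],
            "m_snps": m,
            "y": y[:, 0].astype(int),
            "d": int(d[0]),
            "z": z[:, 0],
        }
    )


def permutation_scores(
    genotypes: GenotypeMatrix,
    labels: PhenotypeLabels,
    sets: list[SnpSet],
    model: str = "additive",
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = 0,
    block_id: int = 0,
    permutation_indices: np.ndarray | None = None,
    batch_size: int = 256,
) -> PermutationScores:
    """Standardized scores over phenotype-label permutations.

    Each permutation shuffles the case/control labels uniformly (preserving
    the l1/l2 split; genotype columns untouched), recomputes all n single-SNP
    p-values under ``model``, then d_pi, per-set y_pi, and the score z_pi
    standardized by Hyp(m, d_pi, n) moments.  Reproducible from ``seed``.

    ``permutation_indices`` (Pi x l integer array) overrides random label
    shuffling — a hook for identity-permutation checks.  Permutations are
    processed in batches of ``batch_size`` so memory stays bounded at
    n x batch_size doubles.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}")
    if genotypes.sample_ids != labels.sample_ids:
        raise ValueError("genotype/phenotype sample order mismatch; align first")
    if n_permutations < 1:
        raise ValueError("need at least one permutation")

    status = labels.status.astype(np.float64)
    l = status.size
    if permutation_indices is not None:
        permutation_indices = np.asarray(permutation_indices)
        if permutation_indices.shape[1] != l:
            raise ValueError("permutation indices must have one column per sample")
        n_permutations = permutation_indices.shape[0]

    kernel = AssociationKernel(genotypes.dosages)
    member, m = _membership(sets, genotypes.n_snps)
    rng = np.random.default_rng(seed)

    z_rows, d_rows = [], []
    for start in range(0, n_permutations, batch_size):
        b = min(batch_size, n_permutations - start)
        cases = np.empty((l, b))
        for j in range(b):
            if permutation_indices is not None:
                cases[:, j] = status[permutation_indices[start + j]]
            else:
                cases[:, j] = rng.permutation(status)
        pvals = kernel.pvalues_batch(cases, model)  # (n, b)
        _, z, d = _scores_from_pvalues(pvals, member, m, alpha)
        z_rows.append(z.T)
        d_rows.append(d)

    return PermutationScores(
        set_names=[s.name for s in sets],
        m=m,
        z=np.concatenate(z_rows, axis=0),
        d=np.concatenate(d_rows).astype(np.int64),
        n=genotypes.n_snps,
        alpha=alpha,
        model=model,
        seed=seed,
        block_id=block_id,
    )


def enrichment_pvalue(z_obs: float, z_perm_column, smooth: bool = False) -> float:
    """Permutation p-value P = (1/Pi) sum_pi I(z_pi >= z_obs).

    With ``smooth=True`` the add-one form (1 + sum I) / (1 + Pi) is used,
    which never returns exactly zero.
    """
    zp = np.asarray(z_perm_column, dtype=float)
    if zp.size < 1:
        raise ValueError("need at least one permutation score")
    hits = int((zp >= z_obs).sum())
    if smooth:
        return (1.0 + hits) / (1.0 + zp.size)
    return hits / zp.size


def compute_fdr(z_obs_all, z_perm) -> np.ndarray:
    """Permutation FDR per set (GSEA-style construction).

    FDR(S) = mean_pi[ #{S': z_pi(S') >= z(S)} / T ] / [ #{S': z_obs(S') >=
    z(S)} / T ], clamped to [0, 1].  The denominator counts S itself, so it
    is at least 1/T.
    """
    z_obs = np.asarray(z_obs_all, dtype=float)
    zp = np.asarray(z_perm, dtype=float)
    T = z_obs.size
    if T < 1:
        raise ValueError("need at least one set")
    # mean over permutations of the null exceedance count at each threshold
    num = (zp[:, :, None] >= z_obs[None, None, :]).sum(axis=1).mean(axis=0) / T
    den = (z_obs[:, None] >= z_obs[None, :]).sum(axis=0) / T
    return np.clip(num / den, 0.0, 1.0)


def compute_fwer(z_obs_all, z_perm) -> np.ndarray:
    """FWER(S) = fraction of permutations whose maximum score over all sets
    reaches z(S)."""
    z_obs = np.asarray(z_obs_all, dtype=float)
    zp = np.asarray(z_perm, dtype=float)
    zmax = zp.max(axis=1)
    return (zmax[:, None] >= z_obs[None, :]).mean(axis=0)


def combine_blocks(blocks: list[PermutationScores]) -> PermutationScores:
    """Pool permutation blocks by row concatenation.

    Blocks must share the set list, universe size n, alpha and model
    (distinct seeds are expected); downstream p/FDR/FWER on the pooled matrix
    equal a single run over the concatenated permutation stream.
    """
    if not blocks:
        raise ValueError("no blocks to combine")
    first = blocks[0]
    for b in blocks[1:]:
        if b.set_names != first.set_names or not np.array_equal(b.m, first.m):
            raise ValueError("blocks have mismatched set lists")
        if b.n != first.n or b.alpha != first.alpha or b.model != first.model:
            raise ValueError("blocks have mismatched n, alpha or model")
    if len(blocks) == 1:
        return first
    return PermutationScores(
        set_names=first.set_names,
        m=first.m,
        z=np.concatenate([b.z for b in blocks], axis=0),
        d=np.concatenate([b.d for b in blocks]),
        n=first.n,
        alpha=first.alpha,
        model=first.model,
        seed=first.seed,
        block_id=first.block_id,
    )


@dataclass
class EnrichmentReport:
    """Final per-set results plus the run's global quantities."""

    table: pd.DataFrame  # name, m_snps, y, d, z, p_value, FDR, FWER
    n: int
    d: int
    alpha: float
    n_permutations: int
    model: str
    seed: int | None

    def to_frame(self) -> pd.DataFrame:
        return self.table.copy()


def report_from_scores(
    observed: pd.DataFrame, scores: PermutationScores, smooth_p: bool = False
) -> EnrichmentReport:
    """Assemble p/FDR/FWER from observed scores and a (pooled) score matrix."""
    if list(observed["name"]) != scores.set_names:
        raise ValueError("observed/permuted set lists differ")
    z_obs = observed["z"].to_numpy()
    p = np.array([enrichment_pvalue(z, scores.z[:, t], smooth_p) for t, z in enumerate(z_obs)])
    fdr = compute_fdr(z_obs, scores.z)
    fwer = compute_fwer(z_obs, scores.z)
    table = observed.copy()
    table["p_value"] = p
    table["FDR"] = fdr
    table["FWER"] = fwer
    return EnrichmentReport(
        table=table,
        n=scores.n,
        d=int(observed["d"].iloc[0]),
        alpha=scores.alpha,
        n_permutations=scores.n_permutations,
        model=scores.model,
        seed=scores.seed,
    )


def run_rs_snp(
    genotypes: GenotypeMatrix,
    labels: PhenotypeLabels,
    sets: list[SnpSet],
    model: str = "additive",
    alpha: float = DEFAULT_ALPHA,
    n_permutations: int = DEFAULT_PERMUTATIONS,
    seed: int | None = 0,
    smooth_p: bool = False,
) -> EnrichmentReport:
    """Full enrichment analysis on QC'd inputs; deterministic given ``seed``."""
    obs = observed_scores(genotypes, labels, sets, model, alpha)
    log.info(
        "enrichment run: n=%d SNPs, d=%d significant at alpha=%g, T=%d sets, Pi=%d",
        genotypes.n_snps, int(obs["d"].iloc[0]), alpha, len(sets), n_permutations,
    )
    scores = permutation_scores(
        genotypes, labels, sets, model, alpha, n_permutations, seed
    )
    return report_from_scores(obs, scores, smooth_p)
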