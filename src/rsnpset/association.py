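"""Single-SNP case/control association tests under five genetic models.

For each SNP a statistic ``D`` and p-value ``P`` are computed from the 2x3
(case/control x dosage) contingency table:

- ``general``        — 2-df Pearson chi-square on the genotype table;
- ``dominant``       — 1-df chi-square on {0} vs {1,2} dosage collapse;
- ``recessive``      — 1-df chi-square on {0,1} vs {2};
- ``multiplicative`` — 1-df chi-square on the 2x2 allelic table;
- ``additive``       — 1-df Cochran-Armitage trend test with weights (0,1,2).

The 2x2 models switch from chi-square to Fisher's exact test when any
expected cell count is below 5.  All statistics are vectorized across SNPs:
this module is the inner kernel re-run for every phenotype-label permutation,
so the batched paths (whole label matrices at once) matter.

Missing genotypes are handled per SNP by complete-case tables.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io_formats import GenotypeMatrix, PhenotypeLabels

log = logging.getLogger(__name__)

MODELS = ("general", "dominant", "recessive", "multiplicative", "additive")

#: Expected-count threshold below which 2x2 models use Fisher's exact test.
FISHER_EXPECTED_MIN = 5.0


@dataclass(frozen=True)
class AssociationResult:
    """Per-SNP association outcome: statistic ``D`` and p-value ``P``."""

    snp_id: str | None
    model: str
    D: float
    P: float


def genotype_table(snp_row, status) -> np.ndarray:
    """2x3 contingency table (controls, cases) x (dosage 0, 1, 2).

    Missing entries (``-1``) are excluded from their class count.  Raises if
    a phenotype class has no non-missing genotype.
    """
    row = np.asarray(snp_row)
    status = np.asarray(status, dtype=bool)
    table = np.empty((2, 3), dtype=np.int64)
    for cls, mask in enumerate((~status, status)):
        vals = row[mask]
        vals = vals[vals >= 0]
        if vals.size == 0:
            raise ValueError("a phenotype class has no non-missing genotypes")
        table[cls] = np.bincount(vals, minlength=3)[:3]
    return table


# ---------------------------------------------------------------------------
# vectorized statistic kernels (tables given as count arrays)
# ---------------------------------------------------------------------------

def _chi2_general(r: np.ndarray, s: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Pearson chi-square over stacked 2x3 tables.

    ``r``/``s`` are case/control count arrays of shape (..., 3).  All-zero
    genotype columns are dropped (df reduced); one remaining column, or an
    empty row, yields D = 0, P = 1.
    """
    r = np.asarray(r, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    col = r + s
    R = r.sum(axis=-1)
    S = s.sum(axis=-1)
    N = R + S
    active = col > 0
    k = active.sum(axis=-1)  # non-empty genotype columns
    with np.errstate(divide="ignore", invalid="ignore"):
        e_r = R[..., None] * col / N[..., None]
        e_s = S[..., None] * col / N[..., None]
        cells = np.where(active & (e_r > 0), (r - e_r) ** 2 / e_r, 0.0) + np.where(
            active & (e_s > 0), (s - e_s) ** 2 / e_s, 0.0
        )
    stat = cells.sum(axis=-1)
    df = np.maximum(k - 1, 0)
    degenerate = (df == 0) | (R == 0) | (S == 0)
    stat = np.where(degenerate, 0.0, stat)
    pval = np.where(degenerate, 1.0, stats.chi2.sf(stat, np.maximum(df, 1)))
    return stat, pval


def _chi2_2x2(a, b, c, d) -> tuple[np.ndarray, np.ndarray]:
    """1-df Pearson chi-square (no continuity correction) on 2x2 tables
    [[a, b], [c, d]]; any zero margin yields D = 0, P = 1."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    r1, r2 = a + b, c + d
    c1, c2 = a + c, b + d
    denom = r1 * r2 * c1 * c2
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, n * (a * d - b * c) ** 2 / denom, 0.0)
    pval = np.where(denom > 0, stats.chi2.sf(stat, 1), 1.0)
    return stat, np.asarray(pval)


def fisher_exact_two_sided(a, b, c, d) -> np.ndarray:
    """Two-sided Fisher's exact test p-values for stacked 2x2 tables.

    Conditions on the margins (first-cell count k ~ hypergeometric) and sums
    the probabilities of all k whose pmf does not exceed the observed
    table's.  Vectorized over tables: the support of every table is
    enumerated in one broadcast pmf evaluation.  Ties are detected with a
    1e-11 relative tolerance (hypergeometric pmfs of small tables that are
    truly distinct differ by far more).
    """
    a, b, c, d = np.broadcast_arrays(
        *(np.asarray(x, dtype=np.int64) for x in (a, b, c, d))
    )
    shape = a.shape
    a, b, c, d = (x.reshape(-1) for x in (a, b, c, d))
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    lo = np.maximum(0, r1 + c1 - n)
    hi = np.minimum(r1, c1)
    width = int((hi - lo).max()) + 1 if a.size else 1
    k = lo[:, None] + np.arange(width)[None, :]
    valid = k <= hi[:, None]
    pmf = stats.hypergeom.pmf(np.where(valid, k, lo[:, None]), n[:, None],
                              c1[:, None], r1[:, None])
    p_obs = stats.hypergeom.pmf(a, n, c1, r1)
    include = valid & (pmf <= p_obs[:, None] * (1.0 + 1e-11))
    out = np.minimum((pmf * include).sum(axis=1), 1.0)
    return out.reshape(shape)


def _fisher_fixup(a, b, c, d, pval) -> np.ndarray:
    """Replace chi-square p-values by Fisher's exact (two-sided) wherever any
    expected 2x2 cell count is below :data:`FISHER_EXPECTED_MIN`."""
    a, b, c, d = (np.asarray(x, dtype=np.float64) for x in (a, b, c, d))
    n = a + b + c + d
    with np.errstate(divide="ignore", invalid="ignore"):
        e_min = np.where(
            n > 0,
            np.minimum.reduce(
                [
                    (a + b) * (a + c),
                    (a + b) * (b + d),
                    (c + d) * (a + c),
                    (c + d) * (b + d),
                ]
            )
            / n,
            0.0,
        )
    nonzero_margins = ((a + b) > 0) & ((c + d) > 0) & ((a + c) > 0) & ((b + d) > 0)
    use_fisher = np.atleast_1d((e_min < FISHER_EXPECTED_MIN) & nonzero_margins)
    pval = np.array(np.atleast_1d(pval), dtype=np.float64, copy=True)
    if use_fisher.any():
        idx = np.flatnonzero(use_fisher.reshape(-1))
        flat = [np.atleast_1d(x).reshape(-1)[idx] for x in (a, b, c, d)]
        pval.reshape(-1)[idx] = fisher_exact_two_sided(*flat)
    return pval


def _collapse_2x2(r, s, model: str):
    """Collapse 2x3 genotype counts into the model's 2x2 table.

    Rows are (controls, cases); returns (a, b, c, d) = control/exposed layout
    ``[[s_ref, s_alt], [r_ref, r_alt]]`` cell counts.
    """
    r = np.asarray(r, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    if model == "dominant":  # {0} vs {1,2}
        return s[..., 0], s[..., 1] + s[..., 2], r[..., 0], r[..., 1] + r[..., 2]
    if model == "recessive":  # {0,1} vs {2}
        return s[..., 0] + s[..., 1], s[..., 2], r[..., 0] + r[..., 1], r[..., 2]
    if model == "multiplicative":  # allelic counts
        return (
            2 * s[..., 0] + s[..., 1],
            s[..., 1] + 2 * s[..., 2],
            2 * r[..., 0] + r[..., 1],
            r[..., 1] + 2 * r[..., 2],
        )
    raise ValueError(f"no 2x2 collapse for model {model!r}")


def _trend(r, s, weights=(0.0, 1.0, 2.0)) -> tuple[np.ndarray, np.ndarray]:
    """Cochran-Armitage trend chi-square (1 df) over stacked 2x3 tables.

    Score-test form: with category weights t_k, case counts r_k, totals
    n_k = r_k + s_k, N = sum n_k, R = sum r_k,

        D = N * (N * sum(t r) - R * sum(t n))^2
            / (R * (N - R) * (N * sum(t^2 n) - (sum(t n))^2))

    Zero trend variance (monomorphic SNP) or an empty phenotype class yields
    D = 0, P = 1.
    """
    r = np.asarray(r, dtype=np.float64)
    s = np.asarray(s, dtype=np.float64)
    t = np.asarray(weights, dtype=np.float64)
    n_k = r + s
    N = n_k.sum(axis=-1)
    R = r.sum(axis=-1)
    st_r = (t * r).sum(axis=-1)
    st_n = (t * n_k).sum(axis=-1)
    st2_n = (t**2 * n_k).sum(axis=-1)
    denom = R * (N - R) * (N * st2_n - st_n**2)
    with np.errstate(divide="ignore", invalid="ignore"):
        stat = np.where(denom > 0, N * (N * st_r - R * st_n) ** 2 / denom, 0.0)
    pval = np.where(denom > 0, stats.chi2.sf(stat, 1), 1.0)
    return stat, np.asarray(pval)


# ---------------------------------------------------------------------------
# scalar table API
# ---------------------------------------------------------------------------

def _split_table(table) -> tuple[np.ndarray, np.ndarray]:
    table = np.asarray(table, dtype=np.float64)
    if table.shape != (2, 3):
        raise ValueError("expected a 2x3 (controls, cases) x (0,1,2) table")
    if (table < 0).any():
        raise ValueError("negative counts")
    return table[1], table[0]  # cases, controls


def _result(model, stat, pval, snp_id=None) -> AssociationResult:
    return AssociationResult(snp_id, model, float(np.squeeze(stat)), float(np.squeeze(pval)))


def test_general(table, snp_id=None) -> AssociationResult:
    """2-df chi-square on the full 2x3 genotype table (general model)."""
    r, s = _split_table(table)
    stat, pval = _chi2_general(r[None, :], s[None, :])
    return _result("general", stat, pval, snp_id)


def _test_2x2(table, model, snp_id=None) -> AssociationResult:
    r, s = _split_table(table)
    a, b, c, d = _collapse_2x2(r[None, :], s[None, :], model)
    stat, pval = _chi2_2x2(a, b, c, d)
    pval = _fisher_fixup(a, b, c, d, pval)
    return _result(model, stat, pval, snp_id)


def test_dominant(table, snp_id=None) -> AssociationResult:
    """1-df test on dosage {1,2} vs {0} (dominant model)."""
    return _test_2x2(table, "dominant", snp_id)


def test_recessive(table, snp_id=None) -> AssociationResult:
    """1-df test on dosage {2} vs {0,1} (recessive model)."""
    return _test_2x2(table, "recessive", snp_id)


def test_multiplicative(table, snp_id=None) -> AssociationResult:
    """1-df test on the 2x2 allele-count table (multiplicative model)."""
    return _test_2x2(table, "multiplicative", snp_id)


def cochran_armitage_trend(table, weights=(0, 1, 2), snp_id=None) -> AssociationResult:
    """Cochran-Armitage trend test with linear dosage weights (additive model)."""
    r, s = _split_table(table)
    stat, pval = _trend(r[None, :], s[None, :], weights)
    return _result("additive", stat, pval, snp_id)


# statistical tests, not pytest tests: keep them out of test collection
for _fn in (test_general, test_dominant, test_recessive, test_multiplicative):
    _fn.__test__ = False
del _fn

_TABLE_TESTS = {
    "general": test_general,
    "dominant": test_dominant,
    "recessive": test_recessive,
    "multiplicative": test_multiplicative,
    "additive": cochran_armitage_trend,
}


def test_table(table, model: str, snp_id=None) -> AssociationResult:
    """Dispatch a single 2x3 table to the named genetic model's test."""
    if model not in _TABLE_TESTS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    return _TABLE_TESTS[model](table, snp_id=snp_id)


# ---------------------------------------------------------------------------
# whole-matrix kernel
# ---------------------------------------------------------------------------

class AssociationKernel:
    """Precomputed one-hot dosage indicators for fast repeated scans.

    Holds ``(dosage == k)`` indicator matrices so that per-class genotype
    counts for any label assignment reduce to matrix products — the repeated
    operation of the permutation procedure.
    """

    def __init__(self, dosages: np.ndarray):
        dosages = np.asarray(dosages)
        self.n_snps, self.n_samples = dosages.shape
        self.onehot = [(dosages == k).astype(np.float64) for k in (0, 1, 2)]
        self.nonmissing = (dosages >= 0).astype(np.float64)

    def counts(self, case: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        """Case and control count arrays of shape (n_snps, 3[, n_labelings]).

        ``case`` may be a single boolean/0-1 vector (length l) or a matrix
        (l x B) of B labelings; counts use non-missing entries only.
        """
        case = np.asarray(case, dtype=np.float64)
        r = np.stack([h @ case for h in self.onehot], axis=1)
        tot = np.stack([h.sum(axis=1) for h in self.onehot], axis=1)
        s = tot[..., None] - r if case.ndim == 2 else tot - r
        return r, s

    def pvalues(self, case: np.ndarray, model: str) -> tuple[np.ndarray, np.ndarray]:
        """(D, P) arrays over all SNPs for one label assignment."""
        r, s = self.counts(case)
        return _model_stats(r, s, model)

    def trend_pvalues_batch(self, case_matrix: np.ndarray) -> np.ndarray:
        """P-value matrix (n_snps x B) for B labelings under the trend test.

        Single BLAS-sized batch for the additive model — the pipeline default
        and the hot path of the permutation loop.
        """
        case = np.asarray(case_matrix, dtype=np.float64)
        r1 = self.onehot[1] @ case
        r2 = self.onehot[2] @ case
        R = self.nonmissing @ case
        n1 = self.onehot[1].sum(axis=1)[:, None]
        n2 = self.onehot[2].sum(axis=1)[:, None]
        N = self.nonmissing.sum(axis=1)[:, None]
        st_r = r1 + 2.0 * r2
        st_n = n1 + 2.0 * n2
        st2_n = n1 + 4.0 * n2
        denom = R * (N - R) * (N * st2_n - st_n**2)
        with np.errstate(divide="ignore", invalid="ignore"):
            stat = np.where(denom > 0, N * (N * st_r - R * st_n) ** 2 / denom, 0.0)
        return np.where(denom > 0, stats.chi2.sf(stat, 1), 1.0)

    def pvalues_batch(self, case_matrix: np.ndarray, model: str) -> np.ndarray:
        """P-value matrix (n_snps x B) for B labelings under any model."""
        if model == "additive":
            return self.trend_pvalues_batch(case_matrix)
        case = np.asarray(case_matrix, dtype=np.float64)
        out = np.empty((self.n_snps, case.shape[1]))
        for b in range(case.shape[1]):
            out[:, b] = self.pvalues(case[:, b], model)[1]
        return out


def _model_stats(r, s, model: str) -> tuple[np.ndarray, np.ndarray]:
    if model == "general":
        return _chi2_general(r, s)
    if model == "additive":
        return _trend(r, s)
    if model in ("dominant", "recessive", "multiplicative"):
        a, b, c, d = _collapse_2x2(r, s, model)
        stat, pval = _chi2_2x2(a, b, c, d)
        return stat, _fisher_fixup(a, b, c, d, pval)
    raise ValueError(f"unknown model {model!r}; choose from {MODELS}")


def associate_all(
    genotypes: GenotypeMatrix, labels: PhenotypeLabels, model: str = "additive"
) -> pd.DataFrame:
    """Genome scan: one (snp_id, D, P) row per SNP, in input order.

    A SNP whose table is unusable (a phenotype class entirely missing) gets
    P = 1 with a logged warning instead of aborting the scan.
    """
    if model not in MODELS:
        raise ValueError(f"unknown model {model!r}; choose from {MODELS}")
    if genotypes.sample_ids != labels.sample_ids:
        raise ValueError("genotype/phenotype sample order mismatch; align first")
    kernel = AssociationKernel(genotypes.dosages)
    stat, pval = kernel.pvalues(labels.status.astype(np.float64), model)

    r, s = kernel.counts(labels.status.astype(np.float64))
    empty_class = (r.sum(axis=1) == 0) | (s.sum(axis=1) == 0)
    if empty_class.any():
        log.warning(
            "%d SNPs had an entirely missing phenotype class; P set to 1",
            int(empty_class.sum()),
        )
        stat = np.where(empty_class, 0.0, stat)
        pval = np.where(empty_class, 1.0, pval)
    return pd.DataFrame({"snp_id": genotypes.snp_ids, "D": stat, "P": pval})
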