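"""Marker-level quality control for case/control genotype matrices.

Three filter rules, applied per SNP in this order (the first failing rule is
recorded as the removal reason):

1. Hardy-Weinberg exact test in the pooled controls, remove if p < threshold;
2. association between the two control cohorts (1-df trend and/or 2-df
   chi-square), remove if p < threshold — skipped when the phenotype file
   carries no two control cohorts;
3. minor allele frequency over all samples, remove if MAF < threshold.

Thresholds are strict: a marker exactly at a threshold is kept.  Missing
genotypes are excluded per marker before counting (complete-case).  Default
thresholds: HWE 5.7e-7, control-association 5.7e-7, MAF 0.01.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .association import _chi2_general, _trend
from .io_formats import GenotypeMatrix, PhenotypeLabels

log = logging.getLogger(__name__)

#: Default filter thresholds.
DEFAULT_HWE_P = 5.7e-7
DEFAULT_CTRL_P = 5.7e-7
DEFAULT_MAF = 0.01


class SingleCohortError(ValueError):
    """Control-vs-control association is inapplicable: fewer than two cohorts."""


@dataclass(frozen=True)
class QcThresholds:
    """Removal thresholds (strict ``<`` removes; at-threshold markers kept)."""

    hwe_p_min: float = DEFAULT_HWE_P
    control_assoc_p_min: float = DEFAULT_CTRL_P
    maf_min: float = DEFAULT_MAF

    def __post_init__(self) -> None:
        for name in ("hwe_p_min", "control_assoc_p_min", "maf_min"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")


def hwe_exact_pvalue(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Exact conditional Hardy-Weinberg test p-value.

    Conditions on the observed allele totals and sums the probabilities of
    all heterozygote counts whose conditional probability does not exceed the
    observed count's.  Probabilities follow the standard recurrence over
    heterozygote counts of matching parity (numerically stable, no
    factorials).  Monomorphic markers give p = 1.
    """
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype counts")
    n = sum(counts)
    if n < 1:
        raise ValueError("all-zero genotype counts")
    n_AA, n_Aa, n_aa = counts
    # rare-allele copy count; support of het counts shares its parity
    rare = min(2 * n_AA + n_Aa, 2 * n_aa + n_Aa)
    if rare == 0:
        return 1.0
    hets = list(range(rare % 2, rare + 1, 2))
    probs = np.zeros(len(hets))
    # start from the largest het count (mode neighborhood not needed: we
    # normalize at the end, so any anchor works; descend via the recurrence)
    probs[-1] = 1.0
    for idx in range(len(hets) - 1, 0, -1):
        h = hets[idx]
        hom_r = (rare - h) // 2
        hom_c = n - h - hom_r
        # P(h-2) / P(h) = h*(h-1) / (4*(hom_r+1)*(hom_c+1))
        probs[idx - 1] = probs[idx] * h * (h - 1) / (4.0 * (hom_r + 1) * (hom_c + 1))
    probs /= probs.sum()
    p_obs = probs[hets.index(n_Aa)]
    return float(min(1.0, probs[probs <= p_obs * (1.0 + 1e-9)].sum()))


def minor_allele_frequency(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """MAF = min(p, 1-p) with p = (2*n_AA + n_Aa) / (2*total)."""
    counts = (int(n_AA), int(n_Aa), int(n_aa))
    if any(c < 0 for c in counts):
        raise ValueError("negative genotype counts")
    total = sum(counts)
    if total < 1:
        raise ValueError("no genotypes")
    p = (2 * counts[0] + counts[1]) / (2.0 * total)
    return float(min(p, 1.0 - p))


def _cohort_table(dosages_row, cohort_labels) -> np.ndarray:
    """2x3 genotype table between the two control cohorts (complete-case)."""
    row = np.asarray(dosages_row)
    cohorts = sorted({c for c in cohort_labels if c is not None})
    if len(cohorts) != 2:
        raise SingleCohortError(
            f"control-vs-control test needs exactly 2 cohorts, found {len(cohorts)}"
        )
    table = np.zeros((2, 3), dtype=np.int64)
    for ci, c in enumerate(cohorts):
        mask = np.array([lab == c for lab in cohort_labels])
        vals = row[mask]
        vals = vals[vals >= 0]
        table[ci] = np.bincount(vals, minlength=3)[:3]
    return table


def control_group_association_pvalue(dosages_row, cohort_labels, df: int | str = "min") -> float:
    """P-value for genotype-distribution differences between two control cohorts.

    ``df=2``: 2-df chi-square on the 2x3 cohort table; ``df=1``:
    Cochran-Armitage trend test between cohorts; ``df='min'``: the smaller of
    the two (both tests applied).  Raises :class:`SingleCohortError` when the
    cohort structure does not provide two groups.
    """
    table = _cohort_table(dosages_row, cohort_labels)
    r, s = table[1][None, :].astype(float), table[0][None, :].astype(float)
    ps = []
    if df in (2, "2", "min"):
        ps.append(float(_chi2_general(r, s)[1][0]))
    if df in (1, "1", "min"):
        ps.append(float(_trend(r, s)[1][0]))
    if not ps:
        raise ValueError(f"df must be 1, 2 or 'min', got {df!r}")
    return min(ps)


def _genotype_counts(dosages: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """(n_snps, 3) genotype counts over the masked samples, missing excluded."""
    sub = dosages[:, mask]
    return np.stack([(sub == k).sum(axis=1) for k in (0, 1, 2)], axis=1)


def apply_marker_qc(
    genotypes: GenotypeMatrix,
    labels: PhenotypeLabels,
    thresholds: QcThresholds | None = None,
    ctrl_df: int | str = "min",
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Apply the three marker filters; returns (filtered matrix, QC report).

    The report has one row per input SNP: (snp_id, maf, hwe_p,
    control_assoc_p, kept, reason).  HWE is computed on pooled controls; MAF
    on all samples.  The control-association rule is applied only when the
    labels carry two control cohorts.  Surviving SNP order is preserved, and
    the operation is idempotent.
    """
    if thresholds is None:
        thresholds = QcThresholds()
    if genotypes.sample_ids != labels.sample_ids:
        raise ValueError("genotype/phenotype sample order mismatch; align first")

    dos = genotypes.dosages
    ctrl_counts = _genotype_counts(dos, ~labels.status)
    all_counts = _genotype_counts(dos, np.ones(genotypes.n_samples, dtype=bool))

    n = genotypes.n_snps
    maf = np.array(
        [
            minor_allele_frequency(*all_counts[i]) if all_counts[i].sum() else 0.0
            for i in range(n)
        ]
    )
    hwe_p = np.array(
        [
            hwe_exact_pvalue(*ctrl_counts[i]) if ctrl_counts[i].sum() else 1.0
            for i in range(n)
        ]
    )

    cohorts = labels.control_cohorts()
    ctrl_p = np.full(n, np.nan)
    if len(cohorts) == 2:
        ctrl_only = ~labels.status
        cohort_labs = [labels.cohort[j] for j in np.flatnonzero(ctrl_only)]
        sub = dos[:, ctrl_only]
        for i in range(n):
            ctrl_p[i] = control_group_association_pvalue(sub[i], cohort_labs, ctrl_df)
    elif len(cohorts) > 2:
        raise ValueError(f"more than two control cohorts: {cohorts}")

    fail_hwe = hwe_p < thresholds.hwe_p_min
    fail_ctrl = np.where(np.isnan(ctrl_p), False, ctrl_p < thresholds.control_assoc_p_min)
    fail_maf = maf < thresholds.maf_min

    reason = np.full(n, "", dtype=object)
    reason[fail_maf] = "maf"
    reason[fail_ctrl] = "control_assoc"
    reason[fail_hwe] = "hwe"  # first rule in order wins
    kept = reason == ""

    report = pd.DataFrame(
        {
            "snp_id": genotypes.snp_ids,
            "maf": maf,
            "hwe_p": hwe_p,
            "control_assoc_p": ctrl_p,
            "kept": kept,
            "reason": reason,
        }
    )
    removed = pd.Series(reason[~kept]).value_counts().to_dict()
    log.info("marker QC: kept %d / %d SNPs; removals by rule: %s", kept.sum(), n, removed)
    return genotypes.select_snps(kept), report


def write_qc_report(report: pd.DataFrame, path) -> None:
    report.to_csv(path, sep="\t", index=False, float_format="%.10g")
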