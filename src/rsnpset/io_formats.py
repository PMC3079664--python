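"""File formats and canonical in-memory containers.

Genotypes are held as an ``n`` SNPs x ``l`` samples matrix of minor-allele
dosages (0/1/2, ``-1`` for missing).  Supported external formats: a simple
genotype TSV dialect, classic PLINK ``.ped``/``.map`` pairs, phenotype and
annotation TSVs, and MSigDB-style GMT gene-set files.  Coordinates are
1-based inclusive throughout; chromosome labels are normalized by stripping
a leading ``chr`` prefix.
"""
from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Sentinel for a missing dosage in :class:`GenotypeMatrix.dosages`.
MISSING = -1

_VALID_CODES = frozenset({-1, 0, 1, 2})


class FormatError(ValueError):
    """Raised when an input file violates its declared dialect."""


def _check_unique(ids, what: str) -> None:
    dup = [k for k, c in Counter(ids).items() if c > 1]
    if dup:
        raise FormatError(f"duplicate {what}: {dup[:5]}")


@dataclass
class GenotypeMatrix:
    """Minor-allele dosage matrix for ``n`` SNPs x ``l`` samples.

    ``dosages[i, j]`` counts copies of the minor/alternate allele carried by
    sample ``j`` at SNP ``i``; ``-1`` marks a missing genotype.
    """

    snp_ids: list[str]
    sample_ids: list[str]
    dosages: np.ndarray

    def __post_init__(self) -> None:
        self.snp_ids = list(self.snp_ids)
        self.sample_ids = list(self.sample_ids)
        self.dosages = np.asarray(self.dosages, dtype=np.int8)
        n, l = self.dosages.shape
        if n < 1 or l < 2:
            raise ValueError(f"need n >= 1 SNPs and l >= 2 samples, got {n} x {l}")
        if len(self.snp_ids) != n or len(self.sample_ids) != l:
            raise ValueError("id lengths do not match dosage matrix shape")
        _check_unique(self.snp_ids, "snp_id")
        _check_unique(self.sample_ids, "sample_id")
        bad = set(np.unique(self.dosages)) - _VALID_CODES
        if bad:
            raise ValueError(f"invalid dosage codes {sorted(bad)}; allowed 0/1/2/-1")

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[1]

    def select_snps(self, index) -> "GenotypeMatrix":
        """Subset SNPs by boolean mask or integer index, preserving order."""
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            [self.snp_ids[i] for i in idx], self.sample_ids, self.dosages[idx]
        )

    def select_samples(self, index) -> "GenotypeMatrix":
        idx = np.asarray(index)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return GenotypeMatrix(
            self.snp_ids, [self.sample_ids[j] for j in idx], self.dosages[:, idx]
        )

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.snp_ids == other.snp_ids
            and self.sample_ids == other.sample_ids
            and np.array_equal(self.dosages, other.dosages)
        )


@dataclass
class PhenotypeLabels:
    """Binary case/control status per sample, optional control cohort label."""

    sample_ids: list[str]
    status: np.ndarray  # bool, True = case
    cohort: np.ndarray | None = None  # object array, non-None on controls only

    def __post_init__(self) -> None:
        self.sample_ids = list(self.sample_ids)
        self.status = np.asarray(self.status, dtype=bool)
        _check_unique(self.sample_ids, "sample_id")
        if self.status.shape != (len(self.sample_ids),):
            raise ValueError("status length mismatch")
        if self.n_cases < 1 or self.n_controls < 1:
            raise ValueError("need at least one case and one control")
        if self.cohort is not None:
            self.cohort = np.asarray(self.cohort, dtype=object)
            if self.cohort.shape != self.status.shape:
                raise ValueError("cohort length mismatch")
            if any(c is not None for c in self.cohort[self.status]):
                raise ValueError("cohort labels are defined on controls only")

    @property
    def n_cases(self) -> int:
        return int(self.status.sum())

    @property
    def n_controls(self) -> int:
        return int((~self.status).sum())

    def control_cohorts(self) -> list:
        """Distinct cohort labels among controls (empty if no cohort info)."""
        if self.cohort is None:
            return []
        labs = {c for c in self.cohort[~self.status] if c is not None}
        return sorted(labs)

    def reorder(self, sample_ids: list[str]) -> "PhenotypeLabels":
        pos = {s: j for j, s in enumerate(self.sample_ids)}
        idx = [pos[s] for s in sample_ids]
        return PhenotypeLabels(
            sample_ids,
            self.status[idx],
            None if self.cohort is None else self.cohort[idx],
        )


@dataclass(frozen=True)
class GeneSet:
    name: str
    description: str
    genes: tuple[str, ...]

    def __post_init__(self) -> None:
        if not self.genes:
            raise ValueError(f"gene set {self.name!r} is empty")


@dataclass
class GeneSetCollection:
    """Ordered collection of named gene sets (a pathway collection)."""

    sets: list[GeneSet]

    def __post_init__(self) -> None:
        if not self.sets:
            raise ValueError("empty gene-set collection")
        _check_unique([s.name for s in self.sets], "set name")

    def __len__(self) -> int:
        return len(self.sets)

    def __iter__(self):
        return iter(self.sets)


def normalize_chromosome(label: str) -> str:
    """Normalize chromosome labels: '1' and 'chr1' both become '1'."""
    label = str(label).strip()
    if label.lower().startswith("chr"):
        label = label[3:]
    return label


# ---------------------------------------------------------------------------
# genotype TSV dialect
# ---------------------------------------------------------------------------

def read_genotypes(path, format: str = "tsv") -> GenotypeMatrix:
    """Read a genotype matrix.

    ``format='tsv'``: header row ``snp_id<TAB>sample...``, one row per SNP,
    codes 0/1/2/NA.  ``format='plink_ped'``: classic ``.ped``/``.map`` pair
    (``path`` may be the prefix or either file); the dosage counts the minor
    allele, determined per SNP by overall frequency with lexicographic
    tie-break.
    """
    if format == "tsv":
        return _read_genotypes_tsv(path)
    if format == "plink_ped":
        return _read_plink(path)[0]
    raise ValueError(f"unknown genotype format {format!r}")


def _read_genotypes_tsv(path) -> GenotypeMatrix:
    code = {"0": 0, "1": 1, "2": 2, "NA": MISSING}
    with open(path) as fh:
        header = fh.readline().rstrip("\n")
        if not header:
            raise FormatError(f"{path}: empty file")
        cols = header.split("\t")
        if cols[0] != "snp_id":
            raise FormatError(f"{path}: first header field must be 'snp_id'")
        sample_ids = cols[1:]
        snp_ids, rows = [], []
        for lineno, line in enumerate(fh, start=2):
            fields = line.rstrip("\n").split("\t")
            if len(fields) != len(cols):
                raise FormatError(
                    f"{path}:{lineno}: expected {len(cols)} fields, got {len(fields)}"
                )
            snp_ids.append(fields[0])
            try:
                rows.append([code[f] for f in fields[1:]])
            except KeyError as exc:
                raise FormatError(
                    f"{path}:{lineno}: invalid genotype code {exc.args[0]!r}"
                ) from None
    if not rows:
        raise FormatError(f"{path}: no genotype rows")
    return GenotypeMatrix(snp_ids, sample_ids, np.array(rows, dtype=np.int8))


def write_genotypes(genotypes: GenotypeMatrix, path) -> None:
    """Write the genotype TSV dialect (round-trips with :func:`read_genotypes`)."""
    code = {MISSING: "NA", 0: "0", 1: "1", 2: "2"}
    with open(path, "w") as fh:
        fh.write("snp_id\t" + "\t".join(genotypes.sample_ids) + "\n")
        for sid, row in zip(genotypes.snp_ids, genotypes.dosages):
            fh.write(sid + "\t" + "\t".join(code[int(v)] for v in row) + "\n")


# ---------------------------------------------------------------------------
# PLINK classic text format
# ---------------------------------------------------------------------------

def _plink_paths(path) -> tuple[Path, Path]:
    p = Path(path)
    if p.suffix in {".ped", ".map"}:
        p = p.with_suffix("")
    ped, mp = p.with_suffix(".ped"), p.with_suffix(".map")
    if not ped.exists() or not mp.exists():
        raise FileNotFoundError(f"need both {ped} and {mp}")
    return ped, mp


def _read_plink(path) -> tuple[GenotypeMatrix, PhenotypeLabels | None]:
    """Read a classic .ped/.map pair; returns genotypes and, when the .ped
    phenotype column codes 1/2, case/control labels."""
    ped, mp = _plink_paths(path)
    map_rows = []
    with open(mp) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            if len(f) < 4:
                raise FormatError(f"{mp}:{lineno}: expected 4 fields")
            map_rows.append((normalize_chromosome(f[0]), f[1], int(f[3])))
    n = len(map_rows)
    snp_ids = [r[1] for r in map_rows]
    _check_unique(snp_ids, "snp_id")

    sample_ids: list[str] = []
    phenos: list[str] = []
    alleles: list[list[tuple[str, str]]] = []  # per sample: per SNP allele pair
    with open(ped) as fh:
        for lineno, line in enumerate(fh, start=1):
            f = line.split()
            if not f:
                continue
            if len(f) != 6 + 2 * n:
                raise FormatError(
                    f"{ped}:{lineno}: expected {6 + 2 * n} fields, got {len(f)}"
                )
            sample_ids.append(f[1])
            phenos.append(f[5])
            alleles.append(list(zip(f[6::2], f[7::2])))
    _check_unique(sample_ids, "sample_id")

    l = len(sample_ids)
    dosages = np.full((n, l), MISSING, dtype=np.int8)
    for i, sid in enumerate(snp_ids):
        counts: Counter = Counter()
        for j in range(l):
            a, b = alleles[j][i]
            for al in (a, b):
                if al != "0":
                    counts[al] += 1
        obs = sorted(counts)
        if len(obs) > 2:
            raise FormatError(f"{ped}: SNP {sid} is not biallelic: alleles {obs}")
        if not obs:
            continue  # all missing
        if len(obs) == 1:
            # monomorphic: the unobserved alternate is the minor allele
            for j in range(l):
                if alleles[j][i][0] != "0":
                    dosages[i, j] = 0
            continue
        # minor = least frequent allele; on a 50/50 tie the lexicographically
        # first allele is taken as major (reference)
        a1, a2 = obs
        minor = a2 if counts[a1] >= counts[a2] else a1
        for j in range(l):
            a, b = alleles[j][i]
            if a == "0" or b == "0":
                continue
            dosages[i, j] = (a == minor) + (b == minor)

    labels = None
    if set(phenos) <= {"1", "2"} and "1" in phenos and "2" in phenos:
        labels = PhenotypeLabels(sample_ids, [p == "2" for p in phenos])
    return GenotypeMatrix(snp_ids, sample_ids, dosages), labels


def read_plink(path) -> tuple[GenotypeMatrix, PhenotypeLabels | None]:
    """Public wrapper over the classic .ped/.map reader."""
    return _read_plink(path)


# ---------------------------------------------------------------------------
# phenotypes
# ---------------------------------------------------------------------------

_STATUS = {"0": False, "1": True, "control": False, "case": True}


def read_phenotypes(path) -> PhenotypeLabels:
    """Read a phenotype TSV: columns ``sample_id``, ``status`` (0/1 or
    control/case), optional ``cohort`` (control subgroup)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("sample_id", "status"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    try:
        status = [_STATUS[s.lower()] for s in df["status"]]
    except KeyError as exc:
        raise FormatError(f"{path}: invalid status {exc.args[0]!r}") from None
    cohort = None
    if "cohort" in df.columns:
        cohort = np.array(
            [None if (pd.isna(c) or c == "") else c for c in df["cohort"]],
            dtype=object,
        )
    return PhenotypeLabels(list(df["sample_id"]), status, cohort)


def write_phenotypes(labels: PhenotypeLabels, path) -> None:
    with open(path, "w") as fh:
        has_cohort = labels.cohort is not None
        fh.write("sample_id\tstatus" + ("\tcohort" if has_cohort else "") + "\n")
        for j, sid in enumerate(labels.sample_ids):
            row = f"{sid}\t{'case' if labels.status[j] else 'control'}"
            if has_cohort:
                c = labels.cohort[j]
                row += "\t" + ("" if c is None else str(c))
            fh.write(row + "\n")


def align_samples(
    genotypes: GenotypeMatrix, labels: PhenotypeLabels
) -> tuple[GenotypeMatrix, PhenotypeLabels]:
    """Match samples between genotypes and phenotypes.

    Genotyped samples absent from the phenotype file are dropped with a
    warning (cohort-exclusion workflow); phenotype samples absent from the
    genotypes are ignored.  Labels are returned in genotype column order.
    """
    known = set(labels.sample_ids)
    keep = [j for j, s in enumerate(genotypes.sample_ids) if s in known]
    dropped = genotypes.n_samples - len(keep)
    if dropped:
        log.warning("dropping %d genotyped samples absent from phenotype file", dropped)
        genotypes = genotypes.select_samples(keep)
    return genotypes, labels.reorder(genotypes.sample_ids)


# ---------------------------------------------------------------------------
# annotations
# ---------------------------------------------------------------------------

def read_snp_annotation(path) -> pd.DataFrame:
    """Read SNP positions: TSV columns (snp_id, chrom, pos), 1-based.

    Rows with unparseable coordinates are rejected with a reported count.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("snp_id", "chrom", "pos"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    pos = pd.to_numeric(df["pos"], errors="coerce")
    ok = pos.notna() & (pos >= 1)
    if (~ok).sum():
        log.warning("%s: rejected %d rows with unparseable positions", path, (~ok).sum())
    out = pd.DataFrame(
        {
            "snp_id": df.loc[ok, "snp_id"],
            "chrom": df.loc[ok, "chrom"].map(normalize_chromosome),
            "pos": pos[ok].astype(np.int64),
        }
    ).reset_index(drop=True)
    _check_unique(out["snp_id"], "snp_id")
    return out


def read_gene_annotation(path) -> pd.DataFrame:
    """Read gene coordinates: TSV columns (gene_id, chrom, start, end),
    1-based inclusive.  Rows with unparseable or inverted coordinates are
    rejected with a reported count."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in ("gene_id", "chrom", "start", "end"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing column {col!r}")
    start = pd.to_numeric(df["start"], errors="coerce")
    end = pd.to_numeric(df["end"], errors="coerce")
    ok = start.notna() & end.notna() & (start >= 1) & (start <= end)
    if (~ok).sum():
        log.warning("%s: rejected %d rows with invalid coordinates", path, (~ok).sum())
    out = pd.DataFrame(
        {
            "gene_id": df.loc[ok, "gene_id"],
            "chrom": df.loc[ok, "chrom"].map(normalize_chromosome),
            "start": start[ok].astype(np.int64),
            "end": end[ok].astype(np.int64),
        }
    ).reset_index(drop=True)
    _check_unique(out["gene_id"], "gene_id")
    return out


def write_snp_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


def write_gene_annotation(df: pd.DataFrame, path) -> None:
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# GMT
# ---------------------------------------------------------------------------

def read_gmt(path) -> GeneSetCollection:
    """Read an MSigDB-style GMT file: name<TAB>description<TAB>gene...

    File order is preserved; duplicate genes within a set are de-duplicated
    (first occurrence wins)."""
    sets = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(f"{path}:{lineno}: GMT line needs >= 3 fields")
            genes = tuple(dict.fromkeys(g for g in fields[2:] if g))
            sets.append(GeneSet(fields[0], fields[1], genes))
    if not sets:
        raise FormatError(f"{path}: empty GMT file")
    return GeneSetCollection(sets)


def write_gmt(collection: GeneSetCollection, path) -> None:
    with open(path, "w") as fh:
        for s in collection:
            fh.write("\t".join([s.name, s.description, *s.genes]) + "\n")


# ---------------------------------------------------------------------------
# enrichment report
# ---------------------------------------------------------------------------

REPORT_COLUMNS = ["name", "m_snps", "y", "d", "z", "p_value", "FDR", "FWER"]


def write_enrichment_report(report, path) -> None:
    """Write a per-set enrichment report TSV.

    Rows are sorted by p-value ascending, then z descending, then name; the
    byte output is deterministic for a fixed report.
    """
    df = report.to_frame() if hasattr(report, "to_frame") else pd.DataFrame(report)
    missing = [c for c in REPORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"report missing columns {missing}")
    df = df[REPORT_COLUMNS].sort_values(
        ["p_value", "z", "name"], ascending=[True, False, True], kind="mergesort"
    )
    df.to_csv(path, sep="\t", index=False, float_format="%.10g")
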