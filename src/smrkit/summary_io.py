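"""Readers, writers and allele bookkeeping for GWAS / cis-eQTL summary statistics.

Summary-level association files are the raw material of summary-data Mendelian
randomization: per-SNP regression coefficients, standard errors and p-values
from a trait GWAS and from a cis-eQTL study, plus an LD reference panel of
genotype dosages used to estimate correlations between instruments.

Three concerns live here:

* parsing tab-delimited summary files with configurable column dialects,
  validating each row's internal consistency and reporting (not silently
  dropping) rows that fail;
* allele harmonization — putting the GWAS and eQTL effect for one SNP on the
  same effect allele, flipping signs where the files disagree on allele order;
* LD — reading a reference genotype panel (plain dosage matrix or VCF) and
  computing signed Pearson correlations between dosage columns.

Coordinates are 1-based throughout and the cis window is closed
(``|bp - gene_bp| <= window_bp``).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

logger = logging.getLogger("smrkit")

__all__ = [
    "GwasRecord",
    "EqtlRecord",
    "LdMatrix",
    "HarmonizedPair",
    "DialectError",
    "DuplicateRecordError",
    "read_gwas",
    "write_gwas",
    "read_eqtl",
    "write_eqtl",
    "read_genotypes",
    "compute_ld",
    "harmonize",
    "cis_window",
]

#: |z| above which a two-sided normal p-value underflows double precision;
#: files that print p = 0 are accepted only when the z-score clears this.
_Z_UNDERFLOW = 37.0

#: Default relative tolerance on |b/se| vs the z implied by the stored p.
#: Printed summary statistics round b and se (often to 2 significant figures),
#: so the implied z can differ by several percent; 25% covers that without
#: passing genuinely inconsistent rows.
_Z_RTOL = 0.25

GWAS_DIALECT: Mapping[str, str] = {
    "snp": "SNP", "a1": "A1", "a2": "A2", "freq": "freq",
    "b": "b", "se": "se", "p": "p", "n": "N",
    "chrom": "Chr", "bp": "BP",
}

EQTL_DIALECT: Mapping[str, str] = {
    "gene": "Gene", "gene_chrom": "GeneChr", "gene_bp": "GeneBP",
    "snp": "SNP", "chrom": "Chr", "bp": "BP", "a1": "A1", "a2": "A2",
    "b": "b", "se": "se", "p": "p",
}


class DialectError(ValueError):
    """A mandatory column is missing from a summary-statistics file."""


class DuplicateRecordError(ValueError):
    """Duplicate (gene, SNP) rows in an eQTL summary file."""


@dataclass(frozen=True)
class GwasRecord:
    """One SNP's association with the trait, on the a1 (effect) allele."""

    snp_id: str
    a1: str
    a2: str
    b_gwas: float
    se_gwas: float
    p_gwas: float
    freq: float | None = None
    n: float | None = None
    chrom: str | None = None
    bp: int | None = None

    @property
    def z(self) -> float:
        return self.b_gwas / self.se_gwas


@dataclass(frozen=True)
class EqtlRecord:
    """One SNP-gene cis association, on the a1 (effect) allele."""

    gene: str
    snp_id: str
    a1: str
    a2: str
    b_eqtl: float
    se_eqtl: float
    p_eqtl: float
    gene_chrom: str | None = None
    gene_bp: int | None = None
    chrom: str | None = None
    bp: int | None = None

    @property
    def z(self) -> float:
        return self.b_eqtl / self.se_eqtl


@dataclass(frozen=True)
class HarmonizedPair:
    """A GWAS and an eQTL record for one SNP with aligned effect alleles.

    After harmonization both records report effects for the GWAS record's a1.
    ``flag`` is ``"aligned"``, ``"flipped"`` or ``"dropped"``; when dropped,
    ``reason`` explains why and the records retain their input orientation.
    """

    gwas: GwasRecord
    eqtl: EqtlRecord
    flag: str
    reason: str | None = None

    @property
    def ok(self) -> bool:
        return self.flag in ("aligned", "flipped")


class LdMatrix:
    """Signed pairwise Pearson correlations among SNP dosage columns.

    Entries are oriented to the allele whose dosage was correlated; callers
    harmonizing effects to a different allele must flip the corresponding
    rows/columns (see :func:`compute_ld`'s ``flip`` argument).
    """

    def __init__(self, snp_ids: Sequence[str], r: np.ndarray):
        r = np.asarray(r, dtype=float)
        if r.shape != (len(snp_ids), len(snp_ids)):
            raise ValueError("LD matrix shape does not match SNP list")
        self.snp_ids = list(snp_ids)
        self.r = r
        self._index = {s: i for i, s in enumerate(self.snp_ids)}

    def validate(self, tol: float = 1e-8) -> None:
        r = self.r
        if not np.allclose(r, r.T, atol=tol):
            raise ValueError("LD matrix is not symmetric")
        if not np.allclose(np.diag(r), 1.0, atol=tol):
            raise ValueError("LD matrix diagonal is not 1")
        if np.any(np.abs(r) > 1 + tol):
            raise ValueError("LD correlations outside [-1, 1]")
        w = np.linalg.eigvalsh((r + r.T) / 2)
        if w.min() < -1e-6 * max(1.0, w.max()):
            raise ValueError("LD matrix is not positive semi-definite")

    def r_between(self, snp_a: str, snp_b: str) -> float:
        return float(self.r[self._index[snp_a], self._index[snp_b]])

    def submatrix(self, snp_ids: Sequence[str]) -> "LdMatrix":
        idx = [self._index[s] for s in snp_ids]
        return LdMatrix(list(snp_ids), self.r[np.ix_(idx, idx)])

    def __len__(self) -> int:
        return len(self.snp_ids)


def _p_consistent(b: float, se: float, p: float, rtol: float = _Z_RTOL) -> bool:
    """Check p against the two-sided normal tail of b/se, tolerating rounding."""
    z = abs(b / se)
    if p == 0.0:
        return z > _Z_UNDERFLOW
    z_from_p = float(stats.norm.isf(p / 2.0))
    return abs(z_from_p - z) <= max(rtol * z, 0.5)


def _check_gwas(rec: GwasRecord) -> str | None:
    if rec.se_gwas <= 0:
        return f"se = {rec.se_gwas} is not > 0"
    if not rec.a1 or not rec.a2 or rec.a1 == rec.a2:
        return f"alleles invalid (a1={rec.a1!r}, a2={rec.a2!r})"
    if not (0.0 <= rec.p_gwas <= 1.0):
        return f"p = {rec.p_gwas} outside [0, 1]"
    if rec.freq is not None and not (0.0 <= rec.freq <= 1.0):
        return f"freq = {rec.freq} outside [0, 1]"
    if not _p_consistent(rec.b_gwas, rec.se_gwas, rec.p_gwas):
        return f"p = {rec.p_gwas} inconsistent with |b/se| = {abs(rec.z):.3g}"
    return None


def _check_eqtl(rec: EqtlRecord) -> str | None:
    if rec.se_eqtl <= 0:
        return f"se = {rec.se_eqtl} is not > 0"
    if not rec.a1 or not rec.a2 or rec.a1 == rec.a2:
        return f"alleles invalid (a1={rec.a1!r}, a2={rec.a2!r})"
    if not (0.0 <= rec.p_eqtl <= 1.0):
        return f"p = {rec.p_eqtl} outside [0, 1]"
    if not _p_consistent(rec.b_eqtl, rec.se_eqtl, rec.p_eqtl):
        return f"p = {rec.p_eqtl} inconsistent with |b/se| = {abs(rec.z):.3g}"
    return None


def _read_table(path, dialect: Mapping[str, str], required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [dialect[k] for k in required if dialect[k] not in df.columns]
    if missing:
        raise DialectError(
            f"{path}: missing mandatory column(s) {missing}; present: {list(df.columns)}"
        )
    return df


def _float(row, col: str):
    v = row.get(col)
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    return float(v)


def read_gwas(path, dialect: Mapping[str, str] | None = None) -> list[GwasRecord]:
    """Read a tab-delimited GWAS summary file into :class:`GwasRecord` rows.

    The default dialect matches the common ``.ma`` layout
    (``SNP A1 A2 freq b se p N``); supply ``dialect`` to remap column names.
    Rows violating record invariants are logged with their line number and
    skipped. A missing mandatory column raises :class:`DialectError`.
    """
    d = dict(GWAS_DIALECT, **(dialect or {}))
    df = _read_table(path, d, ["snp", "a1", "a2", "b", "se", "p"])
    records: list[GwasRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2  # header is line 1
        try:
            rec = GwasRecord(
                snp_id=str(row[d["snp"]]),
                a1=str(row[d["a1"]]).upper(),
                a2=str(row[d["a2"]]).upper(),
                b_gwas=float(row[d["b"]]),
                se_gwas=float(row[d["se"]]),
                p_gwas=float(row[d["p"]]),
                freq=_float(row, d["freq"]),
                n=_float(row, d["n"]),
                chrom=str(row[d["chrom"]]) if d["chrom"] in row and pd.notna(row[d["chrom"]]) else None,
                bp=int(float(row[d["bp"]])) if d["bp"] in row and pd.notna(row[d["bp"]]) else None,
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d: unparsable row skipped (%s)", path, line, exc)
            continue
        problem = _check_gwas(rec)
        if problem is not None:
            logger.warning("%s line %d (%s): %s; row skipped", path, line, rec.snp_id, problem)
            continue
        records.append(rec)
    return records


def write_gwas(records: Iterable[GwasRecord], path, dialect: Mapping[str, str] | None = None) -> None:
    """Write GWAS records back to TSV, preserving numeric fields exactly."""
    d = dict(GWAS_DIALECT, **(dialect or {}))
    rows = [
        {
            d["snp"]: r.snp_id, d["a1"]: r.a1, d["a2"]: r.a2,
            d["freq"]: r.freq, d["b"]: r.b_gwas, d["se"]: r.se_gwas,
            d["p"]: r.p_gwas, d["n"]: r.n, d["chrom"]: r.chrom, d["bp"]: r.bp,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_eqtl(path, dialect: Mapping[str, str] | None = None) -> list[EqtlRecord]:
    """Read a tab-delimited cis-eQTL summary file into :class:`EqtlRecord` rows.

    Duplicate (gene, SNP) rows raise :class:`DuplicateRecordError` naming the
    duplicates; per-row invariant failures are logged and skipped as in
    :func:`read_gwas`.
    """
    d = dict(EQTL_DIALECT, **(dialect or {}))
    df = _read_table(path, d, ["gene", "snp", "a1", "a2", "b", "se", "p"])
    keys = list(zip(df[d["gene"]], df[d["snp"]]))
    seen: set = set()
    dups = sorted({k for k in keys if k in seen or seen.add(k)})
    if dups:
        raise DuplicateRecordError(f"{path}: duplicate (gene, SNP) rows: {dups}")
    records: list[EqtlRecord] = []
    for i, row in enumerate(df.to_dict("records")):
        line = i + 2
        try:
            rec = EqtlRecord(
                gene=str(row[d["gene"]]),
                snp_id=str(row[d["snp"]]),
                a1=str(row[d["a1"]]).upper(),
                a2=str(row[d["a2"]]).upper(),
                b_eqtl=float(row[d["b"]]),
                se_eqtl=float(row[d["se"]]),
                p_eqtl=float(row[d["p"]]),
                gene_chrom=str(row[d["gene_chrom"]]) if d["gene_chrom"] in row and pd.notna(row[d["gene_chrom"]]) else None,
                gene_bp=int(float(row[d["gene_bp"]])) if d["gene_bp"] in row and pd.notna(row[d["gene_bp"]]) else None,
                chrom=str(row[d["chrom"]]) if d["chrom"] in row and pd.notna(row[d["chrom"]]) else None,
                bp=int(float(row[d["bp"]])) if d["bp"] in row and pd.notna(row[d["bp"]]) else None,
            )
        except (TypeError, ValueError) as exc:
            logger.warning("%s line %d: unparsable row skipped (%s)", path, line, exc)
            continue
        problem = _check_eqtl(rec)
        if problem is not None:
            logger.warning("%s line %d (%s/%s): %s; row skipped",
                           path, line, rec.gene, rec.snp_id, problem)
            continue
        records.append(rec)
    return records


def write_eqtl(records: Iterable[EqtlRecord], path, dialect: Mapping[str, str] | None = None) -> None:
    d = dict(EQTL_DIALECT, **(dialect or {}))
    rows = [
        {
            d["gene"]: r.gene, d["gene_chrom"]: r.gene_chrom, d["gene_bp"]: r.gene_bp,
            d["snp"]: r.snp_id, d["chrom"]: r.chrom, d["bp"]: r.bp,
            d["a1"]: r.a1, d["a2"]: r.a2,
            d["b"]: r.b_eqtl, d["se"]: r.se_eqtl, d["p"]: r.p_eqtl,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _read_genotypes_vcf(path) -> pd.DataFrame:
    try:
        from cyvcf2 import VCF
    except ImportError as exc:  # pragma: no cover
        raise ImportError("reading VCF reference panels requires cyvcf2") from exc
    ids, cols, alleles = [], [], {}
    vcf = VCF(str(path))
    for var in vcf:
        if len(var.ALT) != 1:
            logger.warning("%s: multi-allelic site %s skipped", path, var.ID or var.POS)
            continue
        snp = var.ID or f"{var.CHROM}:{var.POS}"
        # per-sample allele indices; -1 marks a missing call
        g = np.array([s.count(1) if -1 not in s else np.nan
                      for s in (gt[:2] for gt in var.genotypes)], dtype=float)
        ids.append(snp)
        cols.append(g)
        alleles[snp] = (var.REF, var.ALT[0])
    df = pd.DataFrame(np.column_stack(cols) if cols else np.empty((0, 0)), columns=ids)
    df.attrs["alleles"] = alleles
    return df


def read_genotypes(path) -> pd.DataFrame:
    """Read an LD reference panel into an individuals x SNPs dosage DataFrame.

    Accepts either a VCF of biallelic sites (dosage = ALT-allele count; the
    REF/ALT pair per SNP is stored in ``df.attrs["alleles"]``) or a plain
    whitespace-delimited matrix whose header row gives SNP IDs. Missing
    dosages are imputed to the per-SNP mean; SNPs with all dosages missing
    are dropped with a warning.
    """
    path = str(path)
    if path.endswith((".vcf", ".vcf.gz")):
        df = _read_genotypes_vcf(path)
    else:
        df = pd.read_csv(path, sep=r"\s+", engine="python")
        df = df.apply(pd.to_numeric, errors="coerce")
    all_missing = [c for c in df.columns if df[c].isna().all()]
    if all_missing:
        logger.warning("%s: SNP(s) %s have no called genotypes; dropped", path, all_missing)
        df = df.drop(columns=all_missing)
    df = df.fillna(df.mean())
    return df


def compute_ld(genotypes: pd.DataFrame, snp_subset: Sequence[str] | None = None,
               flip: Iterable[str] = ()) -> LdMatrix:
    """Signed Pearson LD among dosage columns of a reference panel.

    ``flip`` lists SNPs whose dosage should be counted on the opposite allele
    (``g -> 2 - g``), which negates that SNP's correlations; use it to orient
    the panel to harmonized effect alleles. Zero-variance SNPs are excluded
    with a warning rather than producing NaN rows.
    """
    if len(genotypes) < 2:
        raise ValueError("LD needs at least 2 individuals")
    cols = list(snp_subset) if snp_subset is not None else list(genotypes.columns)
    missing = [c for c in cols if c not in genotypes.columns]
    if missing:
        raise KeyError(f"SNPs absent from genotype panel: {missing}")
    G = genotypes[cols].to_numpy(dtype=float).copy()
    flip = set(flip)
    for j, c in enumerate(cols):
        if c in flip:
            G[:, j] = -G[:, j]
    sd = G.std(axis=0)
    keep = sd > 0
    dropped = [c for c, k in zip(cols, keep) if not k]
    if dropped:
        logger.warning("zero-variance SNP(s) excluded from LD: %s", dropped)
    kept_cols = [c for c, k in zip(cols, keep) if k]
    r = np.corrcoef(G[:, keep], rowvar=False)
    r = np.atleast_2d(r)
    np.fill_diagonal(r, 1.0)
    return LdMatrix(kept_cols, np.clip(r, -1.0, 1.0))


_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


def is_palindromic(a1: str, a2: str) -> bool:
    """A/T and C/G SNPs: strand-ambiguous in files that carry no strand info."""
    return _COMPLEMENT.get(a1.upper()) == a2.upper()


def harmonize(gwas: GwasRecord, eqtl: EqtlRecord,
              palindrome_policy: str = "drop") -> HarmonizedPair:
    """Align one GWAS and one eQTL record to the GWAS effect allele.

    If the eQTL file lists the same alleles in swapped order, its effect sign
    is negated and the pair flagged ``flipped``. Disjoint allele sets yield
    ``dropped`` with reason ``mismatch``. Palindromic SNPs (A/T, C/G) are
    dropped by default (``palindrome_policy="drop"``) because strand cannot
    be resolved from summary data alone; pass ``"keep"`` to retain them.
    """
    if gwas.snp_id != eqtl.snp_id:
        raise ValueError(f"SNP IDs differ: {gwas.snp_id} vs {eqtl.snp_id}")
    if palindrome_policy not in ("drop", "keep"):
        raise ValueError(f"unknown palindrome_policy {palindrome_policy!r}")
    if palindrome_policy == "drop" and (
        is_palindromic(gwas.a1, gwas.a2) or is_palindromic(eqtl.a1, eqtl.a2)
    ):
        return HarmonizedPair(gwas, eqtl, "dropped", "palindromic")
    if {gwas.a1, gwas.a2} != {eqtl.a1, eqtl.a2}:
        return HarmonizedPair(gwas, eqtl, "dropped", "mismatch")
    if (eqtl.a1, eqtl.a2) == (gwas.a1, gwas.a2):
        return HarmonizedPair(gwas, eqtl, "aligned")
    flipped = replace(eqtl, a1=gwas.a1, a2=gwas.a2, b_eqtl=-eqtl.b_eqtl)
    return HarmonizedPair(gwas, flipped, "flipped")


def cis_window(eqtl_records: Iterable[EqtlRecord], gene: str,
               window_bp: int = 1_000_000) -> list[EqtlRecord]:
    """Keep a gene's SNPs within ``window_bp`` of its anchor position.

    The window is closed: a SNP exactly ``window_bp`` away is kept. SNPs on a
    different chromosome than the gene are excluded regardless of position.
    """
    out = []
    for rec in eqtl_records:
        if rec.gene != gene:
            continue
        if rec.gene_bp is None or rec.bp is None:
            raise ValueError(f"record {rec.gene}/{rec.snp_id} lacks positions for cis filtering")
        if rec.gene_chrom is not None and rec.chrom is not None and rec.chrom != rec.gene_chrom:
            continue
        if abs(rec.bp - rec.gene_bp) <= window_bp:
            out.append(rec)
    return out
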