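"""Replication of discovery SNPs and eQTL effects in independent datasets.

Second stage of the workflow: each discovery risk SNP is looked up in an
independent trait GWAS (direction of effect, nominal significance, and
Bonferroni significance over the SNPs carried forward), and each SNP-gene
eQTL effect is looked up in an independent expression dataset (sign
concordance plus a genome-wide significance requirement, default
p < 5e-8). All comparisons are made after harmonizing the replication
records to the discovery effect alleles; a zero replication effect counts
as discordant.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Sequence

from .summary_io import EqtlRecord, GwasRecord, harmonize

logger = logging.getLogger("smrkit")

__all__ = ["ReplicationRecord", "replicate_gwas", "replicate_eqtl"]


@dataclass
class ReplicationRecord:
    """Replication flags for one discovery SNP (or SNP-gene pair)."""

    snp_id: str
    gene: str | None
    b_discovery: float
    b_replication: float | None = None
    se_replication: float | None = None
    p_replication: float | None = None
    sign_concordant: bool | None = None
    nominal: bool | None = None
    bonferroni: bool | None = None
    eqtl_replicated: bool | None = None
    status: str = "ok"           # "ok" | "missing"


def _summary(records: Sequence[ReplicationRecord]) -> dict:
    found = [r for r in records if r.status == "ok"]
    return {
        "n_snps": len(records),
        "n_found": len(found),
        "n_concordant_nominal": sum(1 for r in found if r.sign_concordant and r.nominal),
        "n_bonferroni": sum(1 for r in found if r.sign_concordant and r.bonferroni),
    }


def replicate_gwas(discovery: Sequence[GwasRecord],
                   replication: Sequence[GwasRecord],
                   alpha: float = 0.05,
                   missing_in_denominator: bool = True,
                   gene_of: dict[str, str] | None = None
                   ) -> tuple[list[ReplicationRecord], dict]:
    """Look up discovery SNPs in an independent GWAS.

    The Bonferroni denominator is the number of SNPs carried to replication;
    by default SNPs absent from the replication file stay in it (conservative).
    Returns per-SNP records and a summary count dict.
    """
    rep_index = {r.snp_id: r for r in replication}
    n_tests = len(discovery) if missing_in_denominator else \
        sum(1 for d in discovery if d.snp_id in rep_index)
    n_tests = max(n_tests, 1)
    cut = alpha / n_tests

    out: list[ReplicationRecord] = []
    for disc in discovery:
        gene = (gene_of or {}).get(disc.snp_id)
        rep = rep_index.get(disc.snp_id)
        if rep is None:
            out.append(ReplicationRecord(disc.snp_id, gene, disc.b_gwas, status="missing"))
            continue
        # reuse allele harmonization by treating the replication row as the
        # record to orient onto the discovery effect allele
        pair = harmonize(disc, EqtlRecord(gene or "", rep.snp_id, rep.a1, rep.a2,
                                          rep.b_gwas, rep.se_gwas, rep.p_gwas),
                         palindrome_policy="keep")
        if not pair.ok:
            out.append(ReplicationRecord(disc.snp_id, gene, disc.b_gwas,
                                         status="missing"))
            logger.warning("replication alleles for %s do not match discovery (%s)",
                           disc.snp_id, pair.reason)
            continue
        b_rep, se_rep, p_rep = pair.eqtl.b_eqtl, pair.eqtl.se_eqtl, pair.eqtl.p_eqtl
        out.append(ReplicationRecord(
            snp_id=disc.snp_id, gene=gene, b_discovery=disc.b_gwas,
            b_replication=b_rep, se_replication=se_rep, p_replication=p_rep,
            sign_concordant=disc.b_gwas * b_rep > 0,
            nominal=p_rep < alpha,
            bonferroni=p_rep < cut,
        ))
    summary = _summary(out)
    summary["bonferroni_threshold"] = cut
    summary["n_tests"] = n_tests
    return out, summary


def replicate_eqtl(discovery: Sequence[EqtlRecord],
                   replication: Sequence[EqtlRecord],
                   genome_wide_p: float = 5e-8
                   ) -> tuple[list[ReplicationRecord], dict]:
    """Look up discovery SNP-gene eQTL effects in an independent eQTL set.

    An effect replicates when the replication p is genome-wide significant
    (default < 5e-8) and the sign agrees with discovery after allele
    harmonization.
    """
    rep_index = {(r.gene, r.snp_id): r for r in replication}
    out: list[ReplicationRecord] = []
    for disc in discovery:
        rep = rep_index.get((disc.gene, disc.snp_id))
        if rep is None:
            out.append(ReplicationRecord(disc.snp_id, disc.gene, disc.b_eqtl,
                                         status="missing"))
            continue
        pair = harmonize(
            GwasRecord(disc.snp_id, disc.a1, disc.a2, disc.b_eqtl,
                       disc.se_eqtl, disc.p_eqtl),
            rep, palindrome_policy="keep")
        if not pair.ok:
            out.append(ReplicationRecord(disc.snp_id, disc.gene, disc.b_eqtl,
                                         status="missing"))
            continue
        b_rep, se_rep, p_rep = pair.eqtl.b_eqtl, pair.eqtl.se_eqtl, pair.eqtl.p_eqtl
        concordant = disc.b_eqtl * b_rep > 0
        out.append(ReplicationRecord(
            snp_id=disc.snp_id, gene=disc.gene, b_discovery=disc.b_eqtl,
            b_replication=b_rep, se_replication=se_rep, p_replication=p_rep,
            sign_concordant=concordant,
            nominal=p_rep < 0.05,
            bonferroni=None,
            eqtl_replicated=concordant and p_rep < genome_wide_p,
        ))
    summary = {
        "n_pairs": len(out),
        "n_found": sum(1 for r in out if r.status == "ok"),
        "n_replicated": sum(1 for r in out if r.eqtl_replicated),
        "genome_wide_p": genome_wide_p,
    }
    return out, summary
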