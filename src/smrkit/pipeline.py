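"""Orchestration of the four-stage gene-prioritization workflow.

Stage 1 (discovery): per tissue, run the SMR test for every gene with a
qualifying instrument, then HEIDI for genes passing the pooled SMR
Bonferroni cut. The SMR test count is pooled across tissues; the HEIDI
Bonferroni family is the number of HEIDI tests actually performed.

Stage 2 (replication): look up surviving SNPs in an independent GWAS and the
surviving SNP-gene eQTL effects in independent expression panels.

Stage 3 (differential expression): compare candidate-gene expression between
cases and controls per region with BH correction.

Stage 4 (convergence): a gene is called convergent when it survives
SMR+HEIDI *and* its SNP replicates in the GWAS (sign-concordant and
Bonferroni-significant) *and* its eQTL effect replicates *and* it is
differentially expressed (FDR < alpha in at least one region). Each flag can
be relaxed independently since the stages are logically separate filters.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .diff_expression import DeResult, ExpressionMatrix, de_table
from .heidi import HeidiConfig, heidi_test, select_heidi_snps
from .multiple_testing import ThresholdConfig, apply_smr_heidi_filter
from .replication import ReplicationRecord, replicate_eqtl, replicate_gwas
from .smr import SmrConfig, SmrResult, harmonized_cis_pairs, run_smr
from .summary_io import EqtlRecord, GwasRecord, compute_ld

logger = logging.getLogger("smrkit")

__all__ = ["TissueData", "DiscoveryResult", "FullResult",
           "run_discovery", "run_full"]


@dataclass
class TissueData:
    """One tissue's eQTL summary set plus its LD reference panel."""

    name: str
    eqtl: list[EqtlRecord]
    genotypes: pd.DataFrame


@dataclass
class DiscoveryResult:
    results: list[SmrResult]
    survivors: list[SmrResult]
    skipped: dict[str, dict[str, str]]        # tissue -> gene -> reason
    thresholds: ThresholdConfig
    manifest: dict


@dataclass
class FullResult:
    discovery: DiscoveryResult
    gwas_replication: list[ReplicationRecord] | None
    eqtl_replication: list[ReplicationRecord] | None
    de_results: list[DeResult] | None
    convergent_genes: list[str] | None        # None = not evaluated
    gene_flags: dict[str, dict]
    manifest: dict


def _panel_flips(pairs, genotypes: pd.DataFrame) -> set[str]:
    """SNPs whose panel dosage counts the opposite of the harmonized a1.

    Plain dosage matrices are assumed to count the harmonized effect allele
    (true for the synthetic generator); VCF panels carry REF/ALT in
    ``attrs["alleles"]`` and dosages count ALT, so a pair whose harmonized
    a1 is the panel REF needs its LD signs flipped.
    """
    alleles = genotypes.attrs.get("alleles")
    if not alleles:
        return set()
    flips = set()
    for p in pairs:
        al = alleles.get(p.gwas.snp_id)
        if al is not None and p.gwas.a1 == al[0]:
            flips.add(p.gwas.snp_id)
    return flips


def _run_heidi_for(result: SmrResult, tissue: TissueData, gwas_index,
                   smr_config: SmrConfig, heidi_config: HeidiConfig,
                   rng: np.random.Generator) -> None:
    pairs = harmonized_cis_pairs(gwas_index, tissue.eqtl, result.gene, smr_config)
    pairs = [p for p in pairs if p.gwas.snp_id in tissue.genotypes.columns]
    top = next((p for p in pairs if p.gwas.snp_id == result.top_snp), None)
    if top is None:
        logger.warning("%s/%s: top SNP %s absent from reference panel; HEIDI skipped",
                       tissue.name, result.gene, result.top_snp)
        return
    ld = compute_ld(tissue.genotypes, [p.gwas.snp_id for p in pairs],
                    flip=_panel_flips(pairs, tissue.genotypes))
    candidates, status = select_heidi_snps(pairs, top, ld, heidi_config)
    if status != "ok":
        result.nsnp_heidi = len(candidates)
        return
    hres = heidi_test(top, candidates, ld, heidi_config, rng=rng)
    result.p_heidi = hres.p_heidi
    result.nsnp_heidi = hres.m_used


def run_discovery(gwas: Sequence[GwasRecord], tissues: Sequence[TissueData],
                  smr_config: SmrConfig = SmrConfig(),
                  heidi_config: HeidiConfig = HeidiConfig(),
                  alpha: float = 0.05, seed: int = 0) -> DiscoveryResult:
    """Stage 1: SMR per tissue, pooled Bonferroni, HEIDI on significant genes."""
    if not tissues:
        raise ValueError("at least one tissue must be configured")
    rng = np.random.default_rng(seed)
    gwas_index = {g.snp_id: g for g in gwas}

    all_results: list[SmrResult] = []
    skipped: dict[str, dict[str, str]] = {}
    for tissue in tissues:
        if not tissue.eqtl:
            logger.warning("tissue %s has no eQTL records; skipped", tissue.name)
            skipped[tissue.name] = {}
            continue
        results, skip = run_smr(gwas, tissue.eqtl, smr_config)
        for r in results:
            r.tissue = tissue.name
        all_results.extend(results)
        skipped[tissue.name] = skip

    n_smr = max(len(all_results), 1)
    smr_cut = alpha / n_smr
    significant = [r for r in all_results if r.p_smr < smr_cut]
    tissue_by_name = {t.name: t for t in tissues}
    for r in significant:
        _run_heidi_for(r, tissue_by_name[r.tissue], gwas_index,
                       smr_config, heidi_config, rng)
    n_heidi = max(sum(1 for r in significant if r.p_heidi is not None), 1)

    thresholds = ThresholdConfig(alpha=alpha, n_smr_tests=n_smr,
                                 n_heidi_tests=n_heidi)
    survivors, report = apply_smr_heidi_filter(all_results, thresholds)
    manifest = {
        "n_smr_tests": len(all_results),
        "n_heidi_tests": n_heidi,
        "alpha": alpha,
        "smr_threshold": thresholds.smr_threshold,
        "heidi_threshold": thresholds.heidi_threshold,
        "n_significant_smr": len(significant),
        "survivor_counts": report["survivors_per_tissue"],
        "skipped_genes": {t: len(s) for t, s in skipped.items()},
    }
    return DiscoveryResult(all_results, survivors, skipped, thresholds, manifest)


def run_full(gwas: Sequence[GwasRecord], tissues: Sequence[TissueData],
             replication_gwas: Sequence[GwasRecord] | None = None,
             replication_eqtl: Sequence[EqtlRecord] | None = None,
             expression: ExpressionMatrix | None = None,
             smr_config: SmrConfig = SmrConfig(),
             heidi_config: HeidiConfig = HeidiConfig(),
             alpha: float = 0.05, de_alpha: float = 0.05,
             seed: int = 0) -> FullResult:
    """Run discovery, replication and DE, then the convergence summary.

    Stages whose inputs are missing are skipped; the convergence list is then
    marked not-evaluated (``None``) rather than silently empty.
    """
    disc = run_discovery(gwas, tissues, smr_config, heidi_config, alpha, seed)
    gwas_index = {g.snp_id: g for g in gwas}
    survivor_genes = sorted({r.gene for r in disc.survivors})
    gene_flags: dict[str, dict] = {g: {"smr_heidi": True} for g in survivor_genes}

    gwas_rep = None
    if replication_gwas is not None and disc.survivors:
        snps = sorted({r.top_snp for r in disc.survivors})
        disc_records = [gwas_index[s] for s in snps if s in gwas_index]
        gene_of = {r.top_snp: r.gene for r in disc.survivors}
        gwas_rep, _ = replicate_gwas(disc_records, list(replication_gwas),
                                     alpha=alpha, gene_of=gene_of)
        by_snp = {r.snp_id: r for r in gwas_rep}
        for r in disc.survivors:
            rec = by_snp.get(r.top_snp)
            gene_flags[r.gene]["gwas_replicated"] = bool(
                rec and rec.status == "ok" and rec.sign_concordant and rec.bonferroni)

    eqtl_rep = None
    if replication_eqtl is not None and disc.survivors:
        disc_eqtl = []
        for r in disc.survivors:
            match = next((e for t in tissues for e in t.eqtl
                          if e.gene == r.gene and e.snp_id == r.top_snp), None)
            if match is not None:
                disc_eqtl.append(match)
        eqtl_rep, _ = replicate_eqtl(disc_eqtl, list(replication_eqtl))
        by_pair = {(r.gene, r.snp_id): r for r in eqtl_rep}
        for r in disc.survivors:
            rec = by_pair.get((r.gene, r.top_snp))
            gene_flags[r.gene]["eqtl_replicated"] = bool(rec and rec.eqtl_replicated)

    de_results = None
    if expression is not None and survivor_genes:
        regions = sorted(expression.metadata["region"].unique())
        de_results = de_table(expression, survivor_genes, regions)
        for g in survivor_genes:
            hits = [r for r in de_results
                    if r.gene == g and r.status == "ok" and r.fdr is not None]
            gene_flags[g]["de_significant"] = any(r.fdr < de_alpha for r in hits)

    required = ["smr_heidi"]
    evaluated = replication_gwas is not None and replication_eqtl is not None \
        and expression is not None
    if evaluated:
        required += ["gwas_replicated", "eqtl_replicated", "de_significant"]
        convergent = [g for g in survivor_genes
                      if all(gene_flags[g].get(k, False) for k in required)]
    else:
        convergent = None

    manifest = dict(disc.manifest)
    manifest["convergence_evaluated"] = evaluated
    manifest["convergent_genes"] = convergent
    return FullResult(disc, gwas_rep, eqtl_rep, de_results, convergent,
                      gene_flags, manifest)


def content_hash(paths: Sequence[Path]) -> str:
    """SHA-256 over the concatenated bytes of output files, for run manifests."""
    h = hashlib.sha256()
    for p in sorted(map(Path, paths)):
        h.update(p.name.encode())
        h.update(p.read_bytes())
    return h.hexdigest()


def write_manifest(manifest: dict, path) -> None:
    Path(path).write_text(json.dumps(manifest, indent=2, default=str) + "\n")
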