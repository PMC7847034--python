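"""The SMR test: a Wald-ratio link between gene expression and a trait.

For a gene with a strong cis-eQTL, the top associated SNP serves as an
instrumental variable. With harmonized per-allele effects b_eQTL (SNP on
expression) and b_GWAS (SNP on trait), the SMR effect of expression on the
trait is the Wald ratio

    b_SMR = b_GWAS / b_eQTL,

and its chi-square statistic (1 df) combines the two z-scores

    T_SMR = z_GWAS^2 * z_eQTL^2 / (z_GWAS^2 + z_eQTL^2),   z = b / se,

equivalently 1/T_SMR = 1/z_GWAS^2 + 1/z_eQTL^2. The standard error follows as
se_SMR = |b_SMR| / sqrt(T_SMR). A positive b_SMR means higher expression of
the gene is associated with higher trait risk on the GWAS effect scale.

T_SMR is bounded by the weaker of the two z-scores, so the test can never be
more significant than either constituent association.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .summary_io import EqtlRecord, GwasRecord, HarmonizedPair, cis_window, harmonize

logger = logging.getLogger("smrkit")

__all__ = ["SmrConfig", "SmrResult", "select_top_snp", "smr_test", "run_smr",
           "harmonized_cis_pairs", "results_to_frame"]

LN10 = math.log(10.0)


@dataclass(frozen=True)
class SmrConfig:
    """Knobs for instrument selection and harmonization."""

    p_instrument: float = 5e-8      # top cis-eQTL must beat this to instrument a gene
    cis_window_bp: int = 1_000_000
    palindrome_policy: str = "drop"


@dataclass
class SmrResult:
    """Per-gene SMR output row (HEIDI fields filled by the heidi module)."""

    gene: str
    top_snp: str
    b_gwas: float
    se_gwas: float
    p_gwas: float
    b_eqtl: float
    se_eqtl: float
    p_eqtl: float
    b_smr: float
    se_smr: float
    t_smr: float
    p_smr: float
    log10_p_smr: float
    p_heidi: float | None = None
    nsnp_heidi: int | None = None
    tissue: str | None = None


def select_top_snp(cis_records: Sequence[EqtlRecord],
                   p_top_threshold: float = 5e-8) -> EqtlRecord | None:
    """Pick the instrument: the smallest-p cis-eQTL below the threshold.

    Ties on p are broken by larger |z| (relevant when p underflows to 0),
    then lexicographic SNP ID, so selection is deterministic.
    """
    eligible = [r for r in cis_records if r.p_eqtl < p_top_threshold]
    if not eligible:
        return None
    return min(eligible, key=lambda r: (r.p_eqtl, -abs(r.z), r.snp_id))


def smr_test(pair: HarmonizedPair) -> SmrResult:
    """Compute the Wald ratio and its chi-square test for one harmonized pair.

    Raises ``ValueError`` for a zero eQTL effect (undefined ratio) or
    non-positive standard errors. A zero GWAS effect is legitimate and gives
    b_SMR = 0, T_SMR = 0, p_SMR = 1.
    """
    g, e = pair.gwas, pair.eqtl
    if not pair.ok:
        raise ValueError(f"pair for {g.snp_id} was dropped ({pair.reason}); cannot test")
    if e.b_eqtl == 0:
        raise ValueError(f"{g.snp_id}: b_eqtl = 0 gives an undefined Wald ratio")
    if g.se_gwas <= 0 or e.se_eqtl <= 0:
        raise ValueError(f"{g.snp_id}: standard errors must be > 0")

    z_g, z_e = g.b_gwas / g.se_gwas, e.b_eqtl / e.se_eqtl
    b_smr = g.b_gwas / e.b_eqtl
    denom = z_g * z_g + z_e * z_e
    t_smr = 0.0 if denom == 0 else (z_g * z_g) * (z_e * z_e) / denom
    # delta-method SE; equals |b_smr| * sqrt(1/z_g^2 + 1/z_e^2) when b_gwas != 0
    se_smr = abs(b_smr) * math.sqrt(1.0 / (z_g * z_g) + 1.0 / (z_e * z_e)) if z_g != 0 \
        else g.se_gwas / abs(e.b_eqtl)
    p_smr = float(stats.chi2.sf(t_smr, df=1))
    log10_p = float(stats.chi2.logsf(t_smr, df=1)) / LN10
    return SmrResult(
        gene=e.gene, top_snp=g.snp_id,
        b_gwas=g.b_gwas, se_gwas=g.se_gwas, p_gwas=g.p_gwas,
        b_eqtl=e.b_eqtl, se_eqtl=e.se_eqtl, p_eqtl=e.p_eqtl,
        b_smr=b_smr, se_smr=se_smr, t_smr=t_smr, p_smr=p_smr,
        log10_p_smr=log10_p,
    )


def harmonized_cis_pairs(gwas_index: Mapping[str, GwasRecord],
                         eqtl_records: Sequence[EqtlRecord], gene: str,
                         config: SmrConfig) -> list[HarmonizedPair]:
    """All harmonizable GWAS/eQTL pairs in a gene's cis window."""
    pairs = []
    for rec in cis_window(eqtl_records, gene, config.cis_window_bp):
        g = gwas_index.get(rec.snp_id)
        if g is None:
            continue
        pair = harmonize(g, rec, config.palindrome_policy)
        if pair.ok:
            pairs.append(pair)
    return pairs


def run_smr(gwas: Sequence[GwasRecord], eqtl: Sequence[EqtlRecord],
            config: SmrConfig = SmrConfig()) -> tuple[list[SmrResult], dict[str, str]]:
    """SMR across all genes in an eQTL summary set.

    Returns one :class:`SmrResult` per gene with a qualifying instrument, and
    a skip report mapping each unanalyzed gene to a reason
    (``no_overlap``, ``no_instrument``, ``zero_eqtl_effect``).
    """
    gwas_index: dict[str, GwasRecord] = {}
    for g in gwas:
        if g.snp_id in gwas_index:
            logger.warning("duplicate GWAS SNP %s; keeping first occurrence", g.snp_id)
            continue
        gwas_index[g.snp_id] = g

    genes = sorted({r.gene for r in eqtl})
    results: list[SmrResult] = []
    skipped: dict[str, str] = {}
    for gene in genes:
        pairs = harmonized_cis_pairs(gwas_index, eqtl, gene, config)
        if not pairs:
            skipped[gene] = "no_overlap"
            continue
        top_rec = select_top_snp([p.eqtl for p in pairs], config.p_instrument)
        if top_rec is None:
            skipped[gene] = "no_instrument"
            continue
        top_pair = next(p for p in pairs if p.eqtl.snp_id == top_rec.snp_id)
        try:
            results.append(smr_test(top_pair))
        except ValueError:
            skipped[gene] = "zero_eqtl_effect"
    if not results and not skipped:
        logger.warning("no genes found in eQTL input")
    if not results and skipped and all(v == "no_overlap" for v in skipped.values()):
        logger.warning("no SNP overlap between GWAS and eQTL inputs")
    return results, skipped


def results_to_frame(results: Iterable[SmrResult]) -> pd.DataFrame:
    """SMR results as a DataFrame mirroring the standard output column set."""
    cols = ["gene", "top_snp", "b_gwas", "se_gwas", "p_gwas",
            "b_eqtl", "se_eqtl", "p_eqtl", "b_smr", "se_smr",
            "t_smr", "p_smr", "log10_p_smr", "p_heidi", "nsnp_heidi", "tissue"]
    return pd.DataFrame([{c: getattr(r, c) for c in cols} for r in results], columns=cols)
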