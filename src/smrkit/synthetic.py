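"""Synthetic twin-cohort simulator with LD and known causal architecture.

Generates the inputs the SMR/HEIDI workflow consumes — per-SNP linear
regression summary statistics from two *independent* cohorts (an eQTL cohort
measuring gene expression and a GWAS cohort measuring a continuous trait)
plus an LD reference panel — for one cis locus under a known scenario:

* ``pleiotropy``: a single causal SNP c affects expression
  (x = b_zx * g_c + e) and the trait only through expression
  (y = b_xy * b_zx * g_c + e), so the true Wald ratio at every SNP is b_xy;
* ``linkage``: the expression-causal SNP c and a *different* trait-causal
  SNP c2 in LD with it (y = b_zy_direct * g_c2 + e), so Wald ratios vary
  across the locus;
* ``null``: expression is heritable but the trait is pure noise.

Genotypes follow a dichotomized-Gaussian haplotype model: two latent AR(1)
Gaussian vectors (correlation ld_rho^|i-j|) are thresholded at each SNP's
MAF quantile and summed to a 0/1/2 dosage. Realized dosage LD is attenuated
relative to the latent rho; the generator therefore measures the realized
correlation between causal SNPs and records it in the truth object instead
of assuming the latent value.

Everything is driven by one integer seed; identical configs give
byte-identical output files.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .smr import SmrResult
from .summary_io import EqtlRecord, GwasRecord, write_eqtl, write_gwas

__all__ = ["SimConfig", "SimTruth", "SimulatedLocus", "simulate_genotypes",
           "simulate_cohorts", "write_cohorts", "table1_fixture",
           "table1_smr_results"]

_GENE_BP = 50_000_000
_SNP_SPACING = 10_000


@dataclass(frozen=True)
class SimConfig:
    """Generative parameters for one simulated cis locus.

    Cohort sizes default to a well-powered eQTL study (n_eqtl = 5,000), a
    large GWAS (n_gwas = 20,000) and a reference panel of 500 — enough for
    the top cis-eQTL to clear the genome-wide instrument threshold with
    b_zx = 0.7 and for LD estimates accurate to a few percent. Effect sizes
    are on the scale of phenotypes with unit residual variance.
    """

    scenario: str = "pleiotropy"        # "pleiotropy" | "linkage" | "null"
    m_snps: int = 50
    maf_range: tuple[float, float] = (0.1, 0.5)
    ld_rho: float = 0.8
    b_zx: float = 0.7                   # causal SNP -> expression
    b_xy: float = 0.2                   # expression -> trait (pleiotropy)
    b_zy_direct: float = 0.1            # SNP -> trait (linkage)
    causal_index: int | None = None     # default m_snps // 2
    causal_index2: int | None = None    # default causal_index + 1 (realized r^2 ~ 0.25)
    n_eqtl: int = 5_000
    n_gwas: int = 20_000
    n_ref: int = 500
    seed: int = 0
    gene: str = "GENE1"
    chrom: str = "1"
    snp_prefix: str = "snp"             # distinct per locus when combining loci

    def __post_init__(self):
        if self.scenario not in ("pleiotropy", "linkage", "null"):
            raise ValueError(f"unknown scenario {self.scenario!r}")
        if not (-1.0 < self.ld_rho < 1.0):
            raise ValueError(f"ld_rho = {self.ld_rho} must satisfy |rho| < 1")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 1.0):
            raise ValueError(f"invalid maf_range {self.maf_range}")
        c = self.c1
        if not (0 <= c < self.m_snps):
            raise ValueError("causal_index out of range")
        if self.scenario == "linkage":
            c2 = self.c2
            if not (0 <= c2 < self.m_snps) or c2 == c:
                raise ValueError("causal_index2 must differ from causal_index and be in range")

    @property
    def c1(self) -> int:
        return self.m_snps // 2 if self.causal_index is None else self.causal_index

    @property
    def c2(self) -> int:
        return self.c1 + 1 if self.causal_index2 is None else self.causal_index2

    @property
    def snp_ids(self) -> list[str]:
        return [f"{self.snp_prefix}{j + 1:03d}" for j in range(self.m_snps)]

    @property
    def positions(self) -> list[int]:
        start = _GENE_BP - (self.m_snps // 2) * _SNP_SPACING
        return [start + j * _SNP_SPACING for j in range(self.m_snps)]


@dataclass
class SimTruth:
    """What the generator actually did, written alongside every dataset."""

    scenario: str
    causal_snps: list[str]
    b_zx: float
    b_xy: float | None
    b_zy_direct: float | None
    realized_ld_causal: float | None   # dosage r between the two causal SNPs
    mafs: list[float]
    seed: int

    def to_json(self) -> str:
        return json.dumps(dataclasses.asdict(self), indent=2)


@dataclass
class SimulatedLocus:
    config: SimConfig
    gwas: list[GwasRecord]
    eqtl: list[EqtlRecord]
    ref_genotypes: pd.DataFrame       # individuals x SNPs, dosages of a1
    truth: SimTruth


def _haplotype_block(rng: np.random.Generator, n: int, m: int, rho: float) -> np.ndarray:
    """Latent AR(1) Gaussians: z_j = rho z_{j-1} + sqrt(1-rho^2) e_j."""
    e = rng.standard_normal((n, m))
    if rho == 0.0 or m == 1:
        return e
    z = np.empty_like(e)
    z[:, 0] = e[:, 0]
    w = np.sqrt(1.0 - rho * rho)
    for j in range(1, m):
        z[:, j] = rho * z[:, j - 1] + w * e[:, j]
    return z


def _genotypes(rng: np.random.Generator, n: int, mafs: np.ndarray, rho: float) -> np.ndarray:
    thresh = stats.norm.ppf(mafs)
    h1 = _haplotype_block(rng, n, mafs.size, rho) < thresh
    h2 = _haplotype_block(rng, n, mafs.size, rho) < thresh
    return (h1.astype(np.int8) + h2.astype(np.int8)).astype(float)


def simulate_genotypes(config: SimConfig, n: int) -> pd.DataFrame:
    """Standalone genotype draw (individuals x SNPs dosage DataFrame)."""
    if n < 2:
        raise ValueError("need at least 2 individuals")
    rng = np.random.default_rng(config.seed)
    mafs = rng.uniform(*config.maf_range, size=config.m_snps)
    return pd.DataFrame(_genotypes(rng, n, mafs, config.ld_rho),
                        columns=config.snp_ids)


def _marginal_regressions(G: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, ...]:
    """Per-SNP simple linear regression of y on each dosage column (with intercept)."""
    n = y.size
    gc = G - G.mean(axis=0)
    yc = y - y.mean()
    sxx = np.einsum("ij,ij->j", gc, gc)
    sxx_safe = np.where(sxx > 0, sxx, np.nan)
    b = gc.T @ yc / sxx_safe
    rss = np.maximum(yc @ yc - b * b * sxx_safe, 0.0)
    se = np.sqrt(rss / (n - 2) / sxx_safe)
    with np.errstate(invalid="ignore", divide="ignore"):
        tstat = b / se
    p = 2.0 * stats.t.sf(np.abs(tstat), df=n - 2)
    bad = ~np.isfinite(b)
    b[bad], se[bad], p[bad] = 0.0, np.inf, 1.0
    return b, se, np.clip(p, np.finfo(float).tiny, 1.0)


def simulate_cohorts(config: SimConfig) -> SimulatedLocus:
    """Draw the eQTL cohort, the GWAS cohort and the reference panel.

    The three samples are disjoint by construction (independent draws from
    the same genotype law). Every summary record reports the effect of the
    a1 allele, whose dosage is what the genotype matrices count, so no
    harmonization flips are needed within a purely simulated analysis.
    """
    rng = np.random.default_rng(config.seed)
    m = config.m_snps
    mafs = rng.uniform(*config.maf_range, size=m)
    c1, c2 = config.c1, config.c2

    # eQTL cohort: expression = b_zx * g_c + N(0,1)
    G_e = _genotypes(rng, config.n_eqtl, mafs, config.ld_rho)
    x = config.b_zx * G_e[:, c1] + rng.standard_normal(config.n_eqtl)
    b_e, se_e, p_e = _marginal_regressions(G_e, x)

    # GWAS cohort (independent individuals)
    G_g = _genotypes(rng, config.n_gwas, mafs, config.ld_rho)
    noise = rng.standard_normal(config.n_gwas)
    if config.scenario == "pleiotropy":
        y = config.b_xy * config.b_zx * G_g[:, c1] + noise
    elif config.scenario == "linkage":
        y = config.b_zy_direct * G_g[:, c2] + noise
    else:
        y = noise
    b_g, se_g, p_g = _marginal_regressions(G_g, y)

    # reference panel, same LD law
    G_r = _genotypes(rng, config.n_ref, mafs, config.ld_rho)
    ref = pd.DataFrame(G_r, columns=config.snp_ids)

    freqs = G_g.mean(axis=0) / 2.0
    ids, bps = config.snp_ids, config.positions
    gwas = [
        GwasRecord(ids[j], "A", "G", float(b_g[j]), float(se_g[j]), float(p_g[j]),
                   freq=float(freqs[j]), n=config.n_gwas,
                   chrom=config.chrom, bp=bps[j])
        for j in range(m)
    ]
    eqtl = [
        EqtlRecord(config.gene, ids[j], "A", "G", float(b_e[j]), float(se_e[j]),
                   float(p_e[j]), gene_chrom=config.chrom, gene_bp=_GENE_BP,
                   chrom=config.chrom, bp=bps[j])
        for j in range(m)
    ]

    realized_ld = None
    causal = [ids[c1]]
    if config.scenario == "linkage":
        realized_ld = float(np.corrcoef(G_r[:, c1], G_r[:, c2])[0, 1])
        causal.append(ids[c2])
    truth = SimTruth(
        scenario=config.scenario, causal_snps=causal, b_zx=config.b_zx,
        b_xy=config.b_xy if config.scenario == "pleiotropy" else None,
        b_zy_direct=config.b_zy_direct if config.scenario == "linkage" else None,
        realized_ld_causal=realized_ld, mafs=[float(f) for f in mafs],
        seed=config.seed,
    )
    return SimulatedLocus(config, gwas, eqtl, ref, truth)


def write_cohorts(locus: SimulatedLocus, outdir) -> dict[str, Path]:
    """Emit the locus as the package's TSV dialects plus a truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "gwas": outdir / "gwas.tsv",
        "eqtl": outdir / "eqtl.tsv",
        "ref": outdir / "ref_genotypes.tsv",
        "truth": outdir / "truth.json",
    }
    write_gwas(locus.gwas, paths["gwas"])
    write_eqtl(locus.eqtl, paths["eqtl"])
    locus.ref_genotypes.to_csv(paths["ref"], sep="\t", index=False)
    paths["truth"].write_text(locus.truth.to_json())
    return paths


# ---------------------------------------------------------------------------
# Packaged discovery-table fixture

def table1_fixture() -> pd.DataFrame:
    """The published 17-row discovery table (15 blood + 2 brain rows).

    Columns: tissue, chrom, bp, snp, a1, a2, gene, and the printed
    b/se/p triples for GWAS, eQTL and SMR plus p_heidi. p-values printed as
    0.00E+00 denote double-precision underflow of the eQTL association.
    """
    ref = importlib.resources.files("smrkit").joinpath("data/table1.tsv")
    with importlib.resources.as_file(ref) as path:
        df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    return df


def table1_smr_results() -> list[SmrResult]:
    """Fixture rows as :class:`SmrResult` objects with printed values.

    t_smr is back-filled from the printed (b_smr, se_smr) pair and
    log10_p_smr from the printed p, so downstream filters behave exactly as
    they would on freshly computed results.
    """
    out = []
    for row in table1_fixture().to_dict("records"):
        t = (row["b_smr"] / row["se_smr"]) ** 2 if row["se_smr"] else float("nan")
        log10_p = float(np.log10(row["p_smr"])) if row["p_smr"] > 0 else float("-inf")
        out.append(SmrResult(
            gene=row["gene"], top_snp=row["snp"],
            b_gwas=row["b_gwas"], se_gwas=row["se_gwas"], p_gwas=row["p_gwas"],
            b_eqtl=row["b_eqtl"], se_eqtl=row["se_eqtl"], p_eqtl=row["p_eqtl"],
            b_smr=row["b_smr"], se_smr=row["se_smr"], t_smr=t,
            p_smr=row["p_smr"], log10_p_smr=log10_p,
            p_heidi=row["p_heidi"], tissue=row["tissue"],
        ))
    return out
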