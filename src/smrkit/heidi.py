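"""The HEIDI test: heterogeneity in dependent instruments.

A significant SMR association can arise two ways: one causal variant affects
both expression and trait (pleiotropy/causality), or two distinct variants in
LD each affect one of them (linkage). Under the single-variant model every
cis-SNP in LD with the causal site estimates the *same* Wald ratio
b_xy = b_GWAS/b_eQTL, so heterogeneity among those ratios is evidence for
linkage.

For candidate SNPs i = 1..m (the top instrument excluded) the test forms
deviations d_i = b_xy(i) - b_xy(top). First-order error propagation with the
signed LD correlation r_ij between SNPs (independent GWAS and eQTL cohorts)
gives

    cov(b_xy(i), b_xy(j)) = r_ij se_G(i) se_G(j) / (b_E(i) b_E(j))
                          + r_ij b_G(i) b_G(j) se_E(i) se_E(j) / (b_E(i)^2 b_E(j)^2)

and V = cov(d) follows by including the top-SNP terms. The statistic is
T_HEIDI = sum_i (d_i / sqrt(V_ii))^2, distributed under the null as a weighted
sum of 1-df chi-squares with weights equal to the eigenvalues of the
correlation matrix of d. The tail probability is evaluated analytically by
Imhof's numerical inversion of the characteristic function (exact up to
quadrature error); a skewness/kurtosis-matched noncentral chi-square
approximation and a Monte-Carlo estimate serve as fallbacks when the
quadrature's validity check fails.

A small HEIDI p-value favors linkage; SMR hits are usually *retained* only
when p_HEIDI exceeds a threshold.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy import integrate, stats

from .summary_io import HarmonizedPair, LdMatrix

logger = logging.getLogger("smrkit")

__all__ = ["HeidiConfig", "HeidiResult", "select_heidi_snps", "heidi_test",
           "imhof_sf", "liu_sf", "mc_sf", "quadform_sf"]


@dataclass(frozen=True)
class HeidiConfig:
    """Eligibility and evaluation settings for the HEIDI test.

    The defaults follow common SMR practice: candidates must themselves show
    an eQTL signal (p_eqtl below ``p_include``, i.e. |z| > ~3.16), be in
    informative but not redundant LD with the top SNP (r^2 within
    ``[r2_min, r2_max]``), at most ``max_snps`` strongest candidates are
    used, and fewer than ``min_snps`` leaves the test undefined.
    """

    p_include: float = 1.57e-3
    r2_min: float = 0.05
    r2_max: float = 0.9
    max_snps: int = 20
    min_snps: int = 3
    mc_draws: int = 100_000


@dataclass
class HeidiResult:
    p_heidi: float | None
    t_heidi: float | None
    m_used: int
    status: str                  # "ok" | "insufficient_snps"
    method: str | None = None    # "moment_match" | "monte_carlo"


def select_heidi_snps(cis_pairs: Sequence[HarmonizedPair], top_pair: HarmonizedPair,
                      ld: LdMatrix, config: HeidiConfig = HeidiConfig()
                      ) -> tuple[list[HarmonizedPair], str]:
    """Filter cis pairs to HEIDI-eligible candidates.

    Returns the kept pairs (smallest eQTL p first, capped at ``max_snps``)
    and a status: ``"ok"`` or ``"insufficient_snps"`` when fewer than
    ``min_snps`` survive.
    """
    top_snp = top_pair.gwas.snp_id
    eligible = []
    for pair in cis_pairs:
        snp = pair.gwas.snp_id
        if snp == top_snp or not pair.ok:
            continue
        if snp not in ld.snp_ids:
            continue
        if pair.eqtl.p_eqtl >= config.p_include or pair.eqtl.b_eqtl == 0:
            continue
        r2 = ld.r_between(snp, top_snp) ** 2
        if not (config.r2_min <= r2 <= config.r2_max):
            continue
        eligible.append(pair)
    eligible.sort(key=lambda p: (p.eqtl.p_eqtl, -abs(p.eqtl.z), p.eqtl.snp_id))
    kept = eligible[: config.max_snps]
    status = "ok" if len(kept) >= config.min_snps else "insufficient_snps"
    return kept, status


def _ratio_cov(pairs_i: Sequence[HarmonizedPair], pairs_j: Sequence[HarmonizedPair],
               r_block: np.ndarray) -> np.ndarray:
    """Delta-method covariance of Wald ratios between two SNP sets."""
    bg_i = np.array([p.gwas.b_gwas for p in pairs_i])
    sg_i = np.array([p.gwas.se_gwas for p in pairs_i])
    be_i = np.array([p.eqtl.b_eqtl for p in pairs_i])
    se_i = np.array([p.eqtl.se_eqtl for p in pairs_i])
    bg_j = np.array([p.gwas.b_gwas for p in pairs_j])
    sg_j = np.array([p.gwas.se_gwas for p in pairs_j])
    be_j = np.array([p.eqtl.b_eqtl for p in pairs_j])
    se_j = np.array([p.eqtl.se_eqtl for p in pairs_j])
    gwas_term = np.outer(sg_i, sg_j) / np.outer(be_i, be_j)
    eqtl_term = (np.outer(bg_i, bg_j) * np.outer(se_i, se_j)
                 / np.outer(be_i ** 2, be_j ** 2))
    return r_block * (gwas_term + eqtl_term)


def heidi_test(top_pair: HarmonizedPair, candidates: Sequence[HarmonizedPair],
               ld: LdMatrix, config: HeidiConfig = HeidiConfig(),
               rng: np.random.Generator | None = None) -> HeidiResult:
    """Run HEIDI for one gene given the top instrument and eligible candidates.

    ``ld`` must cover the top SNP and every candidate, oriented to the
    harmonized effect alleles. If the propagated covariance of the deviations
    is not positive semi-definite (numerical noise from an estimated LD
    matrix), it is projected to the nearest PSD matrix by flooring negative
    eigenvalues at zero.
    """
    m = len(candidates)
    if m < config.min_snps:
        return HeidiResult(None, None, m, "insufficient_snps")

    order = [top_pair.gwas.snp_id] + [p.gwas.snp_id for p in candidates]
    r = ld.submatrix(order).r
    r_cand = r[1:, 1:]
    r_top = r[1:, 0]

    beta_top = top_pair.gwas.b_gwas / top_pair.eqtl.b_eqtl
    beta = np.array([p.gwas.b_gwas / p.eqtl.b_eqtl for p in candidates])
    d = beta - beta_top

    cov_cc = _ratio_cov(candidates, candidates, r_cand)
    cov_ct = _ratio_cov(candidates, [top_pair], r_top.reshape(-1, 1))[:, 0]
    var_t = _ratio_cov([top_pair], [top_pair], np.ones((1, 1)))[0, 0]
    V = cov_cc - cov_ct[:, None] - cov_ct[None, :] + var_t

    w, U = np.linalg.eigh((V + V.T) / 2)
    if w.min() < -1e-10 * max(1.0, w.max()):
        logger.warning("HEIDI covariance not PSD (min eigenvalue %.3g); projecting", w.min())
    V = (U * np.clip(w, 0.0, None)) @ U.T

    sd = np.sqrt(np.diag(V))
    if np.any(sd == 0):
        # degenerate candidate (d fully determined by top); drop its contribution
        keep = sd > 0
        d, V, sd = d[keep], V[np.ix_(keep, keep)], sd[keep]
        if d.size == 0:
            return HeidiResult(1.0, 0.0, m, "ok", "moment_match")
    z = d / sd
    t_heidi = float(z @ z)
    corr = V / np.outer(sd, sd)
    lam = np.clip(np.linalg.eigvalsh((corr + corr.T) / 2), 0.0, None)

    p, method = quadform_sf(t_heidi, lam, mc_draws=config.mc_draws, rng=rng)
    return HeidiResult(min(max(p, np.finfo(float).tiny), 1.0), t_heidi, m, "ok", method)


# ---------------------------------------------------------------------------
# Tail probabilities for Q = sum_k lam_k * chi^2_1

def imhof_sf(t: float, lam: Sequence[float]) -> tuple[float, float]:
    """Exact tail probability by Imhof's inversion of the characteristic function.

    P(Q > t) = 1/2 + (1/pi) * int_0^inf sin(theta(u)) / (u * rho(u)) du with
    theta(u) = (1/2) sum_k atan(lam_k u) - t u / 2 and
    rho(u) = prod_k (1 + lam_k^2 u^2)^(1/4), evaluated by adaptive
    quadrature over the half-line. Returns (probability, quadrature error
    estimate); callers should treat a large error estimate as failure.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0, 0.0

    def integrand(u):
        theta = 0.5 * np.sum(np.arctan(lam * u)) - 0.5 * t * u
        rho = np.exp(0.25 * np.sum(np.log1p((lam * u) ** 2)))
        return np.sin(theta) / (u * rho)

    out = integrate.quad(integrand, 0.0, np.inf, limit=500, full_output=1)
    val, abserr = out[0], out[1]
    return 0.5 + val / math.pi, abserr


def liu_sf(t: float, lam: Sequence[float]) -> float:
    """Moment-matching tail probability for a weighted sum of 1-df chi-squares.

    Matches mean, variance and skewness (or kurtosis when skewness^2 exceeds
    kurtosis) to a noncentral chi-square, following the modified
    moment-matching scheme commonly used for variance-component score tests.
    """
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    c1, c2, c3, c4 = (np.sum(lam ** k) for k in (1, 2, 3, 4))
    s1 = c3 / c2 ** 1.5
    s2 = c4 / c2 ** 2
    if s1 ** 2 > s2:
        a = 1.0 / (s1 - math.sqrt(s1 ** 2 - s2))
        delta = s1 * a ** 3 - a ** 2
        df = a ** 2 - 2 * delta
    else:
        delta = 0.0
        df = 1.0 / s2
        a = math.sqrt(df)
    mu_q, sigma_q = c1, math.sqrt(2 * c2)
    mu_x, sigma_x = df + delta, math.sqrt(2 * (df + 2 * delta))
    x = (t - mu_q) / sigma_q * sigma_x + mu_x
    if delta > 0:
        return float(stats.ncx2.sf(x, df, delta))
    return float(stats.chi2.sf(x, df))


def mc_sf(t: float, lam: Sequence[float], draws: int = 100_000,
          rng: np.random.Generator | None = None) -> float:
    """Monte-Carlo tail probability for Q = sum lam_k chi^2_1."""
    rng = np.random.default_rng(0) if rng is None else rng
    lam = np.asarray(lam, dtype=float)
    lam = lam[lam > 0]
    if lam.size == 0:
        return 1.0
    q = rng.standard_normal((draws, lam.size)) ** 2 @ lam
    return float((np.count_nonzero(q >= t) + 1) / (draws + 1))


def quadform_sf(t: float, lam: Sequence[float], mc_draws: int = 100_000,
                rng: np.random.Generator | None = None) -> tuple[float, str]:
    """Tail probability with validity checking.

    Imhof's inversion is primary. Its absolute quadrature error floor makes
    deep-tail values unreliable, so the result is accepted only when it is
    well above the error estimate and inside [0, 1]; otherwise the
    moment-matching approximation (accurate in the right tail) is tried,
    and failing that the Monte-Carlo estimate at ``mc_draws`` draws is used.
    """
    lam = np.asarray(lam, dtype=float)
    if t <= 0:
        return 1.0, "imhof"
    if lam[lam > 0].size == 1:
        return float(stats.chi2.sf(t / lam[lam > 0][0], df=1)), "imhof"
    p, abserr = imhof_sf(t, lam)
    if abserr < 1e-6 and max(10.0 * abserr, 1e-8) < p <= 1 + 1e-8:
        return float(min(p, 1.0)), "imhof"
    p = liu_sf(t, lam)
    if np.isfinite(p) and 0.0 <= p <= 1.0:
        return p, "moment_match"
    logger.warning("moment-matching p invalid (%.3g); falling back to Monte Carlo", p)
    return mc_sf(t, lam, mc_draws, rng), "monte_carlo"
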