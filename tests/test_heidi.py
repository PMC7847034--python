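"""HEIDI candidate selection, the quadratic-form statistic, and its p-value."""

import numpy as np
import pytest
from scipy import stats

from smrkit.heidi import (HeidiConfig, heidi_test, imhof_sf, liu_sf, mc_sf,
                          quadform_sf, select_heidi_snps)
from smrkit.summary_io import EqtlRecord, GwasRecord, HarmonizedPair, LdMatrix


def pair(snp, b_g, se_g, b_e, se_e, p_e=1e-10):
    return HarmonizedPair(
        GwasRecord(snp, "A", "G", b_g, se_g, 1e-4),
        EqtlRecord("G1", snp, "A", "G", b_e, se_e, p_e),
        "aligned",
    )


def ar1_ld(snp_ids, rho=0.6):
    m = len(snp_ids)
    r = rho ** np.abs(np.subtract.outer(np.arange(m), np.arange(m)))
    return LdMatrix(snp_ids, r)


class TestSelectHeidiSnps:
    def _setup(self, m=5, rho=0.6):
        top = pair("top", 0.05, 0.01, 0.7, 0.02)
        cands = [pair(f"s{i}", 0.04, 0.01, 0.5, 0.02) for i in range(m)]
        ld = ar1_ld(["top"] + [p.gwas.snp_id for p in cands], rho)
        return top, cands, ld

    def test_high_ld_candidate_removed(self):
        top, cands, _ = self._setup(5)
        r = np.full((6, 6), 0.5)
        np.fill_diagonal(r, 1.0)
        r[0, 1] = r[1, 0] = np.sqrt(0.95)  # r^2 = 0.95 with top
        ld = LdMatrix(["top"] + [p.gwas.snp_id for p in cands], r)
        kept, status = select_heidi_snps(cands, top, ld)
        assert status == "ok" and len(kept) == 4
        assert "s0" not in [p.gwas.snp_id for p in kept]

    def test_too_few_candidates(self):
        top, cands, ld = self._setup(2)
        kept, status = select_heidi_snps(cands, top, ld)
        assert status == "insufficient_snps" and len(kept) == 2

    def test_cap_keeps_smallest_p(self):
        top = pair("top", 0.05, 0.01, 0.7, 0.02)
        cands = [pair(f"s{i:02d}", 0.04, 0.01, 0.5, 0.02, p_e=1e-10 * (i + 1))
                 for i in range(30)]
        r = np.full((31, 31), 0.5)
        np.fill_diagonal(r, 1.0)
        ld = LdMatrix(["top"] + [p.gwas.snp_id for p in cands], r)
        kept, status = select_heidi_snps(cands, top, ld)
        assert status == "ok" and len(kept) == 20
        cutoff = sorted(p.eqtl.p_eqtl for p in cands)[20]
        assert all(p.eqtl.p_eqtl <= cutoff for p in kept)

    def test_weak_eqtl_candidates_excluded(self):
        top, cands, ld = self._setup(5)
        weak = pair("weak", 0.04, 0.01, 0.5, 0.02, p_e=0.01)
        kept, _ = select_heidi_snps(cands + [weak], top, ld)
        assert "weak" not in [p.gwas.snp_id for p in kept]


class TestHeidiTest:
    def test_equal_ratios_give_p_one(self):
        """If every SNP's Wald ratio is identical, T = 0 and p = 1."""
        top = pair("top", 0.2 * 0.7, 0.01, 0.7, 0.02)
        cands = [pair(f"s{i}", 0.2 * be, 0.01, be, 0.02)
                 for i, be in enumerate([0.6, 0.5, 0.4])]
        ld = ar1_ld(["top", "s0", "s1", "s2"])
        res = heidi_test(top, cands, ld)
        assert res.t_heidi == pytest.approx(0.0, abs=1e-20)
        assert res.p_heidi == pytest.approx(1.0, abs=1e-9)

    def test_single_candidate_matches_normal_tail(self):
        """With one independent candidate, p is the chi-square(1) tail of z_d^2."""
        top = pair("top", 0.10, 0.01, 0.8, 0.02)
        cand = pair("s0", 0.02, 0.01, 0.5, 0.02)
        ld = LdMatrix(["top", "s0"], np.eye(2))
        res = heidi_test(top, [cand], ld, HeidiConfig(min_snps=1))
        d = 0.02 / 0.5 - 0.10 / 0.8
        var = (0.01 / 0.5) ** 2 + (0.02 * 0.02 / 0.5 ** 2) ** 2 \
            + (0.01 / 0.8) ** 2 + (0.10 * 0.02 / 0.8 ** 2) ** 2
        expected = stats.chi2.sf(d * d / var, df=1)
        assert res.p_heidi == pytest.approx(expected, rel=1e-10)

    def test_reorder_invariance(self):
        rng = np.random.default_rng(5)
        top = pair("top", 0.06, 0.01, 0.7, 0.02)
        cands = [pair(f"s{i}", rng.normal(0.04, 0.01), 0.01,
                      rng.normal(0.5, 0.05), 0.02) for i in range(5)]
        ld = ar1_ld(["top"] + [p.gwas.snp_id for p in cands])
        p_fwd = heidi_test(top, cands, ld).p_heidi
        perm = [cands[i] for i in (3, 0, 4, 1, 2)]
        p_perm = heidi_test(top, perm, ld).p_heidi
        assert p_fwd == pytest.approx(p_perm, rel=1e-9)

    def test_insufficient_snps_status(self):
        top = pair("top", 0.05, 0.01, 0.7, 0.02)
        res = heidi_test(top, [pair("s0", 0.04, 0.01, 0.5, 0.02)],
                         ar1_ld(["top", "s0"]))
        assert res.status == "insufficient_snps" and res.p_heidi is None

    def test_ar1_toy_matches_monte_carlo_null(self):
        """Analytic p within 3 MC SEs of the empirical quadratic-form tail."""
        rng = np.random.default_rng(17)
        top = pair("top", 0.06, 0.008, 0.75, 0.015)
        b_g = [0.055, 0.048, 0.060, 0.035, 0.050]
        b_e = [0.70, 0.62, 0.71, 0.55, 0.64]
        cands = [pair(f"s{i}", b_g[i], 0.008, b_e[i], 0.015) for i in range(5)]
        ld = ar1_ld(["top"] + [p.gwas.snp_id for p in cands])
        res = heidi_test(top, cands, ld)
        # rebuild the deviation covariance independently and sample the null
        from smrkit.heidi import _ratio_cov
        r = ld.r
        cov_cc = _ratio_cov(cands, cands, r[1:, 1:])
        cov_ct = _ratio_cov(cands, [top], r[1:, 0].reshape(-1, 1))[:, 0]
        var_t = _ratio_cov([top], [top], np.ones((1, 1)))[0, 0]
        V = cov_cc - cov_ct[:, None] - cov_ct[None, :] + var_t
        L = np.linalg.cholesky(V + 1e-14 * np.eye(5))
        draws = rng.standard_normal((100_000, 5)) @ L.T
        z2 = (draws / np.sqrt(np.diag(V))) ** 2
        t_null = z2.sum(axis=1)
        p_emp = float(np.mean(t_null >= res.t_heidi))
        se = np.sqrt(p_emp * (1 - p_emp) / 100_000)
        assert res.p_heidi == pytest.approx(p_emp, abs=3 * se)


class TestQuadformTail:
    def test_equal_weights_reduce_to_chi2(self):
        for t in (0.5, 3.0, 9.0):
            p, err = imhof_sf(t, [1.0, 1.0, 1.0])
            assert p == pytest.approx(stats.chi2.sf(t, 3), abs=1e-5)

    def test_single_weight_exact(self):
        p, method = quadform_sf(4.0, [2.0])
        assert p == pytest.approx(stats.chi2.sf(2.0, 1), rel=1e-12)

    def test_zero_statistic(self):
        assert quadform_sf(0.0, [1.0, 2.0])[0] == 1.0

    def test_liu_accurate_in_right_tail(self):
        lam = [1.8, 1.0, 0.4]
        t = 25.0
        p_imhof, _ = imhof_sf(t, lam)
        assert liu_sf(t, lam) == pytest.approx(p_imhof, rel=0.1)

    def test_analytic_vs_monte_carlo_random_instances(self):
        rng = np.random.default_rng(99)
        for i in range(10):
            A = rng.standard_normal((4, 6))
            C = A @ A.T
            d = np.sqrt(np.diag(C))
            lam = np.clip(np.linalg.eigvalsh(C / np.outer(d, d)), 0, None)
            t = float(rng.standard_normal(4) ** 2 @ lam)
            p, method = quadform_sf(t, lam)
            p_mc = mc_sf(t, lam, 100_000, np.random.default_rng(500 + i))
            se = max(np.sqrt(p_mc * (1 - p_mc) / 100_000), 1e-6)
            assert abs(p - p_mc) <= 3 * se
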