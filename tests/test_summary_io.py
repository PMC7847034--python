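"""Parsing, validation, harmonization, LD and cis-window behaviour."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from smrkit.summary_io import (DialectError, DuplicateRecordError, EqtlRecord,
                               GwasRecord, cis_window, compute_ld, harmonize,
                               read_eqtl, read_genotypes, read_gwas,
                               write_eqtl, write_gwas)
from smrkit.synthetic import table1_fixture

GWAS_HEADER = ["SNP", "A1", "A2", "freq", "b", "se", "p", "N"]


def gwas_rows():
    return [
        ["rs1", "A", "G", 0.3, 0.05, 0.01, 5.7e-7, 1000],
        ["rs2", "C", "A", 0.2, -0.02, 0.02, 0.317, 1000],
        ["rs3", "G", "C", 0.4, 0.00, 0.015, 1.0, 1000],
    ]


class TestReadGwas:
    def test_well_formed_file(self, write_tsv):
        path = write_tsv("g.tsv", GWAS_HEADER, gwas_rows())
        records = read_gwas(path)
        assert len(records) == 3
        assert records[0].snp_id == "rs1" and records[0].b_gwas == 0.05

    def test_zero_se_row_rejected_with_warning(self, write_tsv, caplog):
        rows = gwas_rows()
        rows[1][5] = 0.0
        path = write_tsv("g.tsv", GWAS_HEADER, rows)
        with caplog.at_level("WARNING", logger="smrkit"):
            records = read_gwas(path)
        assert len(records) == 2
        assert sum("rs2" in r.message for r in caplog.records) == 1

    def test_missing_column_names_it(self, write_tsv):
        path = write_tsv("g.tsv", ["SNP", "A1", "A2", "b", "p"], [])
        with pytest.raises(DialectError, match="se"):
            read_gwas(path)

    def test_unparsable_numeric_reports_line(self, write_tsv, caplog):
        rows = gwas_rows()
        rows[2][4] = "not_a_number"
        path = write_tsv("g.tsv", GWAS_HEADER, rows)
        with caplog.at_level("WARNING", logger="smrkit"):
            records = read_gwas(path)
        assert len(records) == 2
        assert any("line 4" in r.message for r in caplog.records)

    def test_inconsistent_p_rejected(self, write_tsv, caplog):
        rows = gwas_rows()
        rows[0][6] = 0.9  # |z| = 5 cannot have p = 0.9
        path = write_tsv("g.tsv", GWAS_HEADER, rows)
        with caplog.at_level("WARNING", logger="smrkit"):
            records = read_gwas(path)
        assert len(records) == 2

    def test_roundtrip_preserves_numeric_fields(self, write_tsv, tmp_path):
        path = write_tsv("g.tsv", GWAS_HEADER, gwas_rows())
        records = read_gwas(path)
        out = tmp_path / "copy.tsv"
        write_gwas(records, out)
        again = read_gwas(out)
        for a, b in zip(records, again):
            assert a == b

    def test_table1_gwas_columns(self, write_tsv):
        df = table1_fixture()
        rows = [[r.snp, r.a1, r.a2, 0.5, r.b_gwas, r.se_gwas, r.p_gwas, 100]
                for r in df.itertuples()]
        path = write_tsv("t1.tsv", GWAS_HEADER, rows)
        records = read_gwas(path)
        assert len(records) == 17
        bin1 = [r for r in records if r.snp_id == "rs11682128"]
        assert bin1[0].b_gwas == 0.031


EQTL_HEADER = ["Gene", "GeneChr", "GeneBP", "SNP", "Chr", "BP", "A1", "A2", "b", "se", "p"]


def eqtl_rows():
    rows = []
    for gi, gene in enumerate(["G1", "G2"]):
        for si in range(5):
            rows.append([gene, "1", 1_000_000 + gi, f"rs{si}", "1",
                         1_000_000 + si * 100, "A", "G", 0.5, 0.05, 1e-22])
    return rows


class TestReadEqtl:
    def test_two_gene_toy(self, write_tsv):
        path = write_tsv("e.tsv", EQTL_HEADER, eqtl_rows())
        records = read_eqtl(path)
        assert len(records) == 10
        assert len({r.gene for r in records}) == 2

    def test_duplicate_gene_snp_raises(self, write_tsv):
        rows = eqtl_rows() + [eqtl_rows()[0]]
        path = write_tsv("e.tsv", EQTL_HEADER, rows)
        with pytest.raises(DuplicateRecordError, match="rs0"):
            read_eqtl(path)

    def test_table1_eqtl_columns_bin1(self, write_tsv):
        df = table1_fixture()
        blood = df[df.tissue == "blood"]
        rows = [[r.gene, r.chrom, r.bp, r.snp, r.chrom, r.bp, r.a1, r.a2,
                 r.b_eqtl, r.se_eqtl, r.p_eqtl] for r in blood.itertuples()]
        path = write_tsv("t1e.tsv", EQTL_HEADER, rows)
        records = read_eqtl(path)
        assert len(records) == 15
        bin1 = next(r for r in records if r.gene == "BIN1")
        assert bin1.b_eqtl == 0.742 and bin1.se_eqtl == 0.009

    def test_roundtrip(self, write_tsv, tmp_path):
        path = write_tsv("e.tsv", EQTL_HEADER, eqtl_rows())
        records = read_eqtl(path)
        out = tmp_path / "copy.tsv"
        write_eqtl(records, out)
        assert read_eqtl(out) == records


class TestReadGenotypes:
    def test_plain_matrix(self, write_tsv):
        path = write_tsv("geno.tsv", ["rs1", "rs2", "rs3"],
                         [[0, 1, 2], [1, 1, 0], [2, 0, 1], [0, 2, 2]])
        df = read_genotypes(path)
        assert df.shape == (4, 3)
        assert list(df.columns) == ["rs1", "rs2", "rs3"]

    def test_missing_value_mean_imputed(self, write_tsv):
        path = write_tsv("geno.tsv", ["rs1", "rs2"],
                         [[0, 1], [2, 1], ["NA", 0], [2, 2]])
        df = read_genotypes(path)
        # remaining dosages 0, 2, 2 have mean 4/3
        assert df.loc[2, "rs1"] == pytest.approx(4.0 / 3.0)

    def test_vcf_multiallelic_skipped(self, tmp_path, caplog):
        vcf = tmp_path / "panel.vcf"
        header = (
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tS1\tS2\tS3\n"
        )
        lines = []
        for i in range(5):
            alt = "T,G" if i == 2 else "T"
            lines.append(f"1\t{100 + i}\trs{i}\tA\t{alt}\t.\t.\t.\tGT\t0/1\t1/1\t0/0")
        vcf.write_text(header + "\n".join(lines) + "\n")
        with caplog.at_level("WARNING", logger="smrkit"):
            df = read_genotypes(vcf)
        assert df.shape == (3, 4)
        assert "rs2" not in df.columns
        assert list(df["rs0"]) == [1.0, 2.0, 0.0]
        assert df.attrs["alleles"]["rs0"] == ("A", "T")


class TestComputeLd:
    def test_duplicated_column_r_one(self):
        g = pd.DataFrame({"a": [0, 1, 2, 1, 0], "b": [0, 1, 2, 1, 0]})
        ld = compute_ld(g)
        assert ld.r_between("a", "b") == pytest.approx(1.0)

    def test_complement_column_r_minus_one(self):
        g = pd.DataFrame({"a": [0.0, 1, 2, 1, 0]})
        g["b"] = 2.0 - g["a"]
        assert compute_ld(g).r_between("a", "b") == pytest.approx(-1.0)

    def test_matches_hand_computed_pearson(self):
        rng = np.random.default_rng(7)
        G = rng.integers(0, 3, size=(10, 4)).astype(float)
        df = pd.DataFrame(G, columns=list("abcd"))
        ld = compute_ld(df)
        for i in range(4):
            for j in range(4):
                x, y = G[:, i], G[:, j]
                expected = (np.mean(x * y) - x.mean() * y.mean()) / (
                    x.std() * y.std())
                assert ld.r[i, j] == pytest.approx(expected, abs=1e-12)

    def test_zero_variance_snp_excluded(self, caplog):
        g = pd.DataFrame({"a": [0, 1, 2, 0], "b": [1, 1, 1, 1]})
        with caplog.at_level("WARNING", logger="smrkit"):
            ld = compute_ld(g)
        assert ld.snp_ids == ["a"]

    def test_flip_negates_correlations(self):
        rng = np.random.default_rng(3)
        df = pd.DataFrame(rng.integers(0, 3, size=(30, 2)).astype(float),
                          columns=["a", "b"])
        plain = compute_ld(df).r_between("a", "b")
        flipped = compute_ld(df, flip=["b"]).r_between("a", "b")
        assert flipped == pytest.approx(-plain)

    @given(st.integers(0, 2 ** 31 - 1))
    def test_equals_brute_force_on_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        G = rng.integers(0, 3, size=(20, 6)).astype(float)
        G[:, 0] = np.arange(20) % 3  # guarantee at least one polymorphic SNP
        df = pd.DataFrame(G, columns=[f"s{i}" for i in range(6)])
        keep = [c for c in df.columns if df[c].std() > 0]
        ld = compute_ld(df)
        assert ld.snp_ids == keep
        expected = np.corrcoef(df[keep].to_numpy(), rowvar=False)
        np.testing.assert_allclose(ld.r, expected, atol=1e-12)


def _gwas(snp="rs1", a1="A", a2="G", b=0.5):
    return GwasRecord(snp, a1, a2, b, 0.1, 5.7e-7)


def _eqtl(snp="rs1", a1="A", a2="G", b=0.3):
    return EqtlRecord("GENE", snp, a1, a2, b, 0.1, 2.7e-3)


class TestHarmonize:
    def test_matching_order_aligned(self):
        pair = harmonize(_gwas(), _eqtl())
        assert pair.flag == "aligned"
        assert pair.eqtl.b_eqtl == 0.3

    def test_swapped_alleles_flip_sign(self):
        pair = harmonize(_gwas(), _eqtl(a1="G", a2="A"))
        assert pair.flag == "flipped"
        assert pair.eqtl.b_eqtl == -0.3
        assert pair.eqtl.a1 == "A"

    def test_disjoint_alleles_dropped(self):
        pair = harmonize(_gwas(), _eqtl(a1="C", a2="T"))
        assert pair.flag == "dropped" and pair.reason == "mismatch"

    def test_palindromic_dropped_by_default_kept_by_policy(self):
        g, e = _gwas(a1="A", a2="T"), _eqtl(a1="A", a2="T")
        assert harmonize(g, e).flag == "dropped"
        assert harmonize(g, e, palindrome_policy="keep").flag == "aligned"

    def test_relabeling_invariance(self):
        """Swapping a1/a2 and negating b in the input leaves effects identical."""
        direct = harmonize(_gwas(), _eqtl())
        relabeled = harmonize(_gwas(), _eqtl(a1="G", a2="A", b=-0.3))
        assert direct.eqtl.b_eqtl == relabeled.eqtl.b_eqtl
        assert direct.eqtl.a1 == relabeled.eqtl.a1


class TestCisWindow:
    GENE_BP = 127_839_474

    def _rec(self, bp, chrom="2", gene_chrom="2"):
        return EqtlRecord("BIN1", f"rs_{bp}", "A", "G", 0.5, 0.1, 5.7e-7,
                          gene_chrom=gene_chrom, gene_bp=self.GENE_BP,
                          chrom=chrom, bp=bp)

    def test_boundary_snp_kept(self):
        recs = [self._rec(self.GENE_BP + 1_000_000)]
        assert len(cis_window(recs, "BIN1")) == 1

    def test_just_outside_excluded(self):
        recs = [self._rec(self.GENE_BP + 1_000_001)]
        assert cis_window(recs, "BIN1") == []

    def test_other_chromosome_excluded(self):
        recs = [self._rec(self.GENE_BP, chrom="3")]
        assert cis_window(recs, "BIN1") == []

    @given(st.integers(0, 2_000_000), st.integers(0, 2_000_000))
    def test_monotone_in_window(self, w1, w2):
        lo, hi = sorted([w1, w2])
        recs = [self._rec(self.GENE_BP + off) for off in
                (-1_500_000, -999_999, 0, 500_000, 1_000_000, 1_200_000)]
        small = {r.snp_id for r in cis_window(recs, "BIN1", lo)}
        large = {r.snp_id for r in cis_window(recs, "BIN1", hi)}
        assert small <= large
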