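"""Standard-form encoding, cleaning rules and genotype file readers."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import akernel as ak
from akernel.standard_form import (CONTROL, DISEASE, MISSING, LocusMeta,
                                   SnpDef, decode_standard_form,
                                   read_genotypes, read_phenotypes,
                                   read_standard_tsv, write_phenotype_tsv,
                                   write_standard_tsv)


def _snp(i, a, b):
    return SnpDef.from_alleles(f"rs{i}", "1", 100 * i, a, b)


class TestSnpDef:
    def test_orders_alleles_by_fixed_rank(self):
        s = _snp(1, "A", "T")
        assert (s.allele_hi, s.allele_lo) == ("T", "A")
        assert SnpDef.from_alleles("x", "1", 1, "G", "C").allele_hi == "G"

    @pytest.mark.parametrize("a,b", [("A", "A"), ("A", "N")])
    def test_rejects_bad_alleles(self, a, b):
        with pytest.raises(ValueError):
            SnpDef("rs1", "1", 1, a, b)


class TestEncode:
    @pytest.mark.parametrize(
        "alleles,geno,expected",
        [
            (("A", "T"), "AT", (2, 1)),   # heterozygote -> 2 1
            (("C", "G"), "CC", (1, 1)),   # lo homozygote
            (("C", "T"), "TT", (2, 2)),   # hi homozygote
            (("A", "G"), "GA", (2, 1)),
        ],
    )
    def test_worked_rows(self, alleles, geno, expected):
        snp = _snp(1, *alleles)
        m = ak.encode_standard_form([[geno]], [snp])
        assert tuple(m.symbols[0]) == expected

    def test_missing_genotype_encodes_missing_pair(self):
        m = ak.encode_standard_form([[None], ["AT"]], [_snp(1, "A", "T")])
        assert tuple(m.symbols[0]) == (MISSING, MISSING)
        assert tuple(m.symbols[1]) == (2, 1)

    def test_foreign_allele_rejected_with_locus_identity(self):
        with pytest.raises(ValueError, match="rs1"):
            ak.encode_standard_form([["AC"]], [_snp(1, "A", "T")])

    def test_homozygous_column_has_identical_compartments(self):
        m = ak.encode_standard_form([["TT"]] * 6, [_snp(1, "A", "T")])
        assert (m.symbols[:, 0] == m.symbols[:, 1]).all()

    def test_odd_even_pairing_metadata(self):
        snps = [_snp(1, "A", "T"), _snp(2, "C", "G")]
        m = ak.encode_standard_form([["AT", "CC"]], snps)
        assert [lm.compartment for lm in m.loci] == ["odd", "even"] * 2
        assert [lm.snp_index for lm in m.loci] == [1, 1, 2, 2]
        assert m.locus_ids == ["rs1.o", "rs1.e", "rs2.o", "rs2.e"]

    @settings(deadline=None, max_examples=30)
    @given(st.lists(st.tuples(st.integers(0, 2)), min_size=1, max_size=8),
           st.sampled_from([("A", "T"), ("C", "G"), ("A", "C"), ("G", "T")]))
    def test_round_trip_up_to_pair_order(self, rows, alleles):
        """Encoding then decoding reproduces genotypes as unordered pairs."""
        snp = _snp(1, *alleles)
        hi, lo = snp.allele_hi, snp.allele_lo
        geno = [[{0: lo + lo, 1: hi + lo, 2: hi + hi}[r[0]]] for r in rows]
        m = ak.encode_standard_form(geno, [snp])
        dec = decode_standard_form(m)
        for g_in, g_out in zip(geno, dec[:, 0]):
            assert sorted(g_in[0]) == sorted(g_out)

    def test_encoding_constraint_odd_dominates_even(self, planted):
        """P(odd=2) >= P(even=2) at every SNP of encoder-produced data."""
        m, _ = planted
        p = (m.symbols == 2).mean(axis=0)
        assert (p[0::2] >= p[1::2]).all()


class TestCleaning:
    def _with_missing(self, n_missing_snp0):
        snps = [_snp(i, "A", "T") for i in range(1, 11)]
        geno = np.full((6, 10), "AT", dtype=object)
        for i in range((n_missing_snp0 + 1) // 2):
            geno[i, 0] = None
        return ak.encode_standard_form(geno, snps)

    def test_snp_with_three_missing_symbols_removed(self):
        # 2 missing genotypes = 4 missing symbols > 2
        m = self._with_missing(4)
        out, rep = ak.filter_missing_loci(m, max_missing=2)
        assert out.n_snps == 9 and list(rep.snp_id) == ["rs1"]
        assert rep.n_missing.iloc[0] == 4

    def test_clean_matrix_unchanged_and_idempotent(self, planted):
        m, _ = planted
        out, rep = ak.filter_missing_loci(m)
        assert len(rep) == 0
        assert np.array_equal(out.symbols, m.symbols)
        out2, rep2 = ak.filter_missing_loci(out)
        assert len(rep2) == 0 and np.array_equal(out2.symbols, out.symbols)

    def test_exactly_one_of_ten_snps_dropped(self):
        m = self._with_missing(5)  # 3 genotypes missing -> 6 symbols
        out, rep = ak.filter_missing_loci(m)
        assert out.n_snps == 9
        assert [lm.snp_index for lm in out.loci] == [k // 2 + 1 for k in range(18)]

    def test_impute_modal_unanimous_and_majority(self):
        snps = [_snp(1, "A", "T")]
        geno = [["TT"], ["TT"], ["TT"], [None]]
        m = ak.impute_modal(ak.encode_standard_form(geno, snps))
        assert (m.symbols == 2).all()
        geno = [["AA"], ["AA"], ["TT"], [None]]
        m = ak.impute_modal(ak.encode_standard_form(geno, snps))
        assert tuple(m.symbols[3]) == (1, 1)

    def test_impute_tie_breaks_to_symbol_two(self):
        geno = [["AA"], ["TT"], [None]]
        m = ak.impute_modal(ak.encode_standard_form(geno, [_snp(1, "A", "T")]))
        assert tuple(m.symbols[2]) == (2, 2)

    def test_impute_preserves_observed_counts(self):
        geno = [["AA"], ["AT"], ["TT"], [None], [None]]
        m0 = ak.encode_standard_form(geno, [_snp(1, "A", "T")])
        m1 = ak.impute_modal(m0)
        obs = m0.symbols != MISSING
        assert np.array_equal(m0.symbols[obs], m1.symbols[obs])
        assert (m1.symbols != MISSING).all()

    def test_impute_all_missing_column_rejected(self):
        m = ak.encode_standard_form([[None], [None]], [_snp(1, "A", "T")])
        with pytest.raises(ValueError, match="all-missing"):
            ak.impute_modal(m)


VCF_TEXT = """\
##fileformat=VCFv4.2
##contig=<ID=1>
#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tsampA\tsampB\tsampC
1\t100\trs1\tA\tT\t.\tPASS\t.\tGT\t0/1\t1/1\t./.
1\t200\trs2\tC\tG\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1
1\t300\trs3\tA\tAT\t.\tPASS\t.\tGT\t0/0\t0/0\t0/0
"""


class TestReaders:
    @pytest.fixture()
    def pheno_file(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("sampA\tdisease\nsampB\tdisease\nsampC\tcontrol\n")
        return p

    def test_vcf_hand_decode(self, tmp_path, pheno_file):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(VCF_TEXT)
        m = read_genotypes(vcf, "vcf", pheno_file)
        assert m.n_snps == 2  # the indel record is skipped
        # rs1: A/T -> hi=T; sampA 0/1=AT het (2,1); sampB TT (2,2); sampC missing
        assert tuple(m.symbols[0, :2]) == (2, 1)
        assert tuple(m.symbols[1, :2]) == (2, 2)
        assert tuple(m.symbols[2, :2]) == (MISSING, MISSING)
        # rs2: C/G hi=G; CC=(1,1), CG=(2,1), GG=(2,2)
        assert [tuple(r) for r in m.symbols[:, 2:]] == [(1, 1), (2, 1), (2, 2)]
        assert list(m.labels) == [DISEASE, DISEASE, CONTROL]

    def test_ped_map_matches_vcf_decode(self, tmp_path, pheno_file):
        (tmp_path / "toy.map").write_text("1 rs1 0 100\n1 rs2 0 200\n")
        (tmp_path / "toy.ped").write_text(
            "f sampA 0 0 1 2 A T C C\n"
            "f sampB 0 0 1 2 T T C G\n"
            "f sampC 0 0 1 1 0 0 G G\n"
        )
        m = read_genotypes(tmp_path / "toy.ped", "ped", pheno_file)
        assert [tuple(r) for r in m.symbols] == [
            (2, 1, 1, 1), (2, 2, 2, 1), (MISSING, MISSING, 2, 2)]

    def test_standard_tsv_round_trip(self, tmp_path, planted):
        m, _ = planted
        std = tmp_path / "std.tsv"
        ph = tmp_path / "ph.tsv"
        write_standard_tsv(m, std)
        write_phenotype_tsv(m, ph)
        back = read_standard_tsv(std, ph)
        assert np.array_equal(back.symbols, m.symbols)
        assert back.locus_ids == m.locus_ids
        assert list(back.labels) == list(m.labels)

    def test_unknown_sample_in_phenotype_rejected(self, tmp_path):
        vcf = tmp_path / "toy.vcf"
        vcf.write_text(VCF_TEXT)
        ph = tmp_path / "ph.tsv"
        ph.write_text("sampA\tdisease\n")
        with pytest.raises(ValueError, match="absent"):
            read_genotypes(vcf, "vcf", ph)
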