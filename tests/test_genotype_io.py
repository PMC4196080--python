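"""Weight/dosage/phenotype IO and allele harmonization."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import telogrs as tg
from telogrs.errors import FormatError, HarmonizationError
from telogrs.genotype_io import write_dosage_tsv

from conftest import make_dosage_matrix

WEIGHT_HEADER = "rsid\tchrom\tpos\teffect_allele\tother_allele\tmaf\tweight\n"


class TestReadWeights:
    def test_bundled_instrument_set(self, weights):
        assert len(weights) == 7
        terc = next(w for w in weights if w.rsid == "rs10936599")
        assert terc.weight == pytest.approx(-0.097)
        assert terc.maf == pytest.approx(0.252)
        assert terc.chrom == "3" and terc.pos == 169492101
        assert {w.rsid for w in weights} == {
            "rs10936599", "rs2736100", "rs7675998", "rs9420907",
            "rs8105767", "rs755017", "rs11125529",
        }

    def test_empty_file_with_header(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(WEIGHT_HEADER)
        assert tg.read_weights(p) == []

    def test_duplicate_rsid_rejected(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text(
            WEIGHT_HEADER
            + "rs1\t1\t100\tA\tG\t0.2\t0.1\n"
            + "rs1\t1\t101\tA\tG\t0.2\t0.1\n"
        )
        with pytest.raises(FormatError, match="rs1"):
            tg.read_weights(p)

    def test_missing_column_named(self, tmp_path):
        p = tmp_path / "w.tsv"
        p.write_text("rsid\tchrom\tpos\tmaf\tweight\nrs1\t1\t5\t0.1\t0.2\n")
        with pytest.raises(FormatError, match="effect_allele"):
            tg.read_weights(p)

    def test_roundtrip(self, weights, tmp_path):
        p = tmp_path / "w.tsv"
        tg.write_weights(weights, p)
        back = tg.read_weights(p)
        assert [w.rsid for w in back] == [w.rsid for w in weights]
        assert [w.weight for w in back] == [w.weight for w in weights]

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(maf=0.6), "MAF"),
            (dict(maf=0.0), "MAF"),
            (dict(weight=0.0), "weight"),
            (dict(other_allele="A"), "identical"),
        ],
    )
    def test_invalid_snp_weight(self, kwargs, msg):
        base = dict(rsid="rs1", chrom="1", pos=1, effect_allele="A",
                    other_allele="G", maf=0.2, weight=0.1)
        base.update(kwargs)
        with pytest.raises(FormatError, match=msg):
            tg.SnpWeight(**base)


class TestReadDosages:
    def test_tsv_basic(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("sample_id\trs1\nA\t0\nB\t1\nC\t2\n")
        dm = tg.read_dosages(p, format="tsv")
        assert dm.values[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert dm.coded_freq()[0] == pytest.approx(0.5)

    def test_tsv_missing_masked(self, tmp_path):
        p = tmp_path / "d.tsv"
        p.write_text("sample_id\trs1\nA\t1.5\nB\t\n")
        dm = tg.read_dosages(p, format="tsv")
        assert dm.mask[1, 0] and not dm.mask[0, 0]

    def test_vcf_hard_genotypes(self, tmp_path):
        p = tmp_path / "d.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\tC\n"
            "1\t100\trs1\tG\tA\t.\tPASS\t.\tGT\t0/0\t0/1\t1/1\n"
        )
        dm = tg.read_dosages(p, format="vcf")
        assert dm.values[:, 0].tolist() == [0.0, 1.0, 2.0]
        assert dm.coded_allele[0] == "A" and dm.other_allele[0] == "G"

    def test_vcf_dosage_field_unrounded(self, tmp_path):
        p = tmp_path / "d.vcf"
        p.write_text(
            "##fileformat=VCFv4.2\n"
            '##FORMAT=<ID=DS,Number=1,Type=Float,Description="Dosage">\n'
            "##contig=<ID=1>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\tA\tB\n"
            "1\t100\trs1\tG\tA\t.\tPASS\t.\tDS\t1.37\t0.02\n"
        )
        dm = tg.read_dosages(p, format="vcf")
        assert dm.values[0, 0] == pytest.approx(1.37, abs=1e-6)

    def test_vcf_roundtrip(self, small_cohort, tmp_path):
        _, dosages, _, _ = small_cohort
        sub = make_dosage_matrix(
            dosages.values[:50], dosages.rsids, dosages.coded_allele,
            dosages.other_allele, chrom=dosages.chrom, pos=dosages.pos,
        )
        sub.sample_ids = dosages.sample_ids[:50]
        p = tmp_path / "sim.vcf"
        tg.write_dosage_vcf(sub, p)
        back = tg.read_dosages(p, format="vcf")
        order = [list(back.rsids).index(r) for r in sub.rsids]
        np.testing.assert_allclose(back.values[:, order], sub.values, atol=1e-5)

    def test_tsv_roundtrip_preserves_mask(self, tmp_path):
        dm = make_dosage_matrix([[1.0, 0.5], [2.0, 1.5]], ["rs1", "rs2"],
                                ["A", "C"], ["G", "T"],
                                mask=[[False, True], [False, False]])
        p = tmp_path / "d.tsv"
        write_dosage_tsv(dm, p)
        back = tg.read_dosages(p, format="tsv")
        assert back.mask[0, 1] and not back.mask[1, 1]


class TestPhenotypes:
    def test_roundtrip_with_covariates(self, small_cohort, tmp_path):
        _, _, cohort, _ = small_cohort
        p = tmp_path / "pheno.tsv"
        tg.write_phenotypes(cohort, p)
        back = tg.read_phenotypes(p)
        np.testing.assert_array_equal(back.status, cohort.status)
        np.testing.assert_array_equal(back.stratum, cohort.stratum)
        np.testing.assert_allclose(back.measured_telomere, cohort.measured_telomere, atol=1e-4)

    def test_bad_status_rejected(self, tmp_path):
        p = tmp_path / "pheno.tsv"
        p.write_text("sample_id\tstatus\tstratum\nA\t2\tr1\n")
        with pytest.raises(FormatError):
            tg.read_phenotypes(p)


class TestHarmonize:
    def w(self, ea="T", oa="C", maf=0.5, weight=-0.1, rsid="rs1"):
        return tg.SnpWeight(rsid=rsid, chrom="1", pos=100, effect_allele=ea,
                            other_allele=oa, maf=maf, weight=weight)

    def test_allele_flip(self):
        # weight alleles T/C; source coded C with other T -> d -> 2-d
        dm = make_dosage_matrix([[0.0], [1.0], [2.0]], ["rs1"], ["C"], ["T"])
        harm, rep = tg.harmonize([self.w()], dm)
        assert rep.action("rs1") == "allele_flip"
        assert harm.values[:, 0].tolist() == [2.0, 1.0, 0.0]
        assert harm.coded_allele[0] == "T"

    def test_strand_flip_keeps_dosage(self):
        # weight A/G; source T/C coded T is the same variant on the other strand
        dm = make_dosage_matrix([[0.0], [1.0], [2.0]], ["rs1"], ["T"], ["C"])
        harm, rep = tg.harmonize([self.w(ea="A", oa="G", weight=0.1)], dm)
        assert rep.action("rs1") == "strand_flip"
        assert harm.values[:, 0].tolist() == [0.0, 1.0, 2.0]

    def test_strand_and_allele_flip(self):
        # weight A/G; source coded G' = C on the other strand
        dm = make_dosage_matrix([[0.0], [1.0], [2.0]], ["rs1"], ["C"], ["T"])
        harm, rep = tg.harmonize([self.w(ea="A", oa="G", weight=0.1)], dm)
        assert rep.action("rs1") == "strand_flip_and_allele_flip"
        assert harm.values[:, 0].tolist() == [2.0, 1.0, 0.0]

    def test_palindromic_high_maf_dropped(self):
        dm = make_dosage_matrix([[1.0]] * 4, ["rs1"], ["A"], ["T"])
        w = self.w(ea="A", oa="T", maf=0.48, weight=0.1)
        harm, rep = tg.harmonize([w], dm, palindromic_maf_limit=0.4)
        assert rep.action("rs1") == "dropped_palindromic"
        assert harm.n_snps == 0

    def test_palindromic_low_maf_resolved_by_frequency(self):
        # observed coded freq 0.1 matches weight maf 0.1 -> keep as match
        vals = [[0.0]] * 8 + [[1.0]] * 2
        dm = make_dosage_matrix(vals, ["rs1"], ["A"], ["T"])
        w = self.w(ea="A", oa="T", maf=0.1, weight=0.1)
        harm, rep = tg.harmonize([w], dm)
        assert rep.action("rs1") == "match"
        # observed coded freq 0.9 is concordant with the flipped orientation
        vals = [[2.0]] * 8 + [[1.0]] * 2
        dm = make_dosage_matrix(vals, ["rs1"], ["A"], ["T"])
        harm, rep = tg.harmonize([w], dm)
        assert rep.action("rs1") == "allele_flip"

    def test_unmatched_dropped_and_accounted(self):
        dm = make_dosage_matrix([[1.0]], ["rsX"], ["A"], ["G"])
        harm, rep = tg.harmonize([self.w()], dm)
        assert rep.action("rs1") == "dropped_unmatched"
        assert len(rep.records) == 1  # every weight SNP exactly once

    def test_match_by_position_fallback(self):
        dm = make_dosage_matrix([[2.0], [0.0]], ["chr1:100"], ["T"], ["C"],
                                chrom=["1"], pos=[100])
        harm, rep = tg.harmonize([self.w()], dm)
        assert rep.action("rs1") == "match"
        assert harm.rsids[0] == "rs1"

    def test_ambiguous_double_match_raises(self):
        dm = make_dosage_matrix([[1.0, 1.0]], ["rs1", "rs1"], ["T", "T"], ["C", "C"])
        with pytest.raises(HarmonizationError, match="rs1"):
            tg.harmonize([self.w()], dm)

    def test_tsv_source_without_alleles_trusted(self):
        dm = make_dosage_matrix([[0.0], [2.0]], ["rs1"], [None], [None])
        harm, rep = tg.harmonize([self.w()], dm)
        assert rep.action("rs1") == "match"
        assert harm.coded_allele[0] == "T"  # weight effect allele recorded

    def test_frequency_mismatch_warns(self):
        dm = make_dosage_matrix([[2.0]] * 9 + [[1.0]], ["rs1"], ["T"], ["C"])
        with pytest.warns(UserWarning, match="frequency"):
            tg.harmonize([self.w(maf=0.05)], dm)

    def test_involution(self, weights, small_cohort):
        """Harmonizing an already-harmonized matrix is the identity."""
        _, dosages, _, _ = small_cohort
        once, rep1 = tg.harmonize(weights, dosages)
        twice, rep2 = tg.harmonize(weights, once)
        assert (rep2.records["action"] == "match").all()
        np.testing.assert_array_equal(once.values, twice.values)

    @given(st.integers(0, 3))
    def test_involution_on_flipped_sources(self, which):
        """Any resolvable source orientation harmonizes to the same matrix."""
        w = self.w(ea="A", oa="G", weight=0.1)
        base = np.array([[0.0], [1.0], [2.0], [1.0]])
        comp = {"A": "T", "G": "C"}
        orientations = [
            ("A", "G", base),          # match
            ("G", "A", 2 - base),      # allele flip
            ("T", "C", base),          # strand flip
            ("C", "T", 2 - base),      # strand + allele flip
        ]
        ca, oa, vals = orientations[which]
        dm = make_dosage_matrix(vals, ["rs1"], [ca], [oa])
        harm, _ = tg.harmonize([w], dm)
        np.testing.assert_allclose(harm.values, base, atol=1e-12)
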