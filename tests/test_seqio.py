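import logging

import pytest
from hypothesis import given, settings, strategies as st

from mirsnp import seqio
from mirsnp.errors import AlphabetError, ParseError
from mirsnp.predict import MirSNPCall
from mirsnp.seqio import (MatureMiRNA, SNPRecord, UTRRecord, normalize_rna,
                          read_fasta, read_ped, read_snp_table, write_fasta,
                          write_mirsnp_report, write_ped)


class TestFasta:
    def test_reads_mirbase_style_record(self, tmp_path):
        p = tmp_path / "m.fa"
        p.write_text(">hsa-miR-616\nauaa\n")
        recs = read_fasta(p, alphabet="rna")
        assert len(recs) == 1
        assert recs[0].mirna_id == "hsa-miR-616"
        assert recs[0].sequence == "AUAA"

    def test_empty_file_gives_empty_list(self, tmp_path):
        p = tmp_path / "e.fa"
        p.write_text("")
        assert read_fasta(p, alphabet="rna") == []

    def test_duplicate_ids_kept_with_warning(self, tmp_path, caplog):
        p = tmp_path / "d.fa"
        p.write_text(">x\nACGU\n>x\nGGGG\n")
        with caplog.at_level(logging.WARNING):
            recs = read_fasta(p, alphabet="rna")
        assert [r.sequence for r in recs] == ["ACGU", "GGGG"]
        assert any("duplicate" in r.message for r in caplog.records)

    def test_sequence_before_header_names_line(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text("ACGT\n>x\nACGT\n")
        with pytest.raises(ParseError, match="line 1"):
            read_fasta(p, alphabet="dna")

    def test_illegal_character_names_record(self, tmp_path):
        p = tmp_path / "bad.fa"
        p.write_text(">ok\nACGU\n>weird\nACGX\n")
        with pytest.raises(AlphabetError, match="weird"):
            read_fasta(p, alphabet="rna")

    def test_round_trip_preserves_ids_and_sequences(self, tmp_path):
        recs = [MatureMiRNA("a", "ACGU"), MatureMiRNA("b", "UUUUGGG")]
        p = tmp_path / "rt.fa"
        write_fasta(recs, p)
        back = read_fasta(p, alphabet="rna")
        assert [(r.mirna_id, r.sequence) for r in back] == [
            (r.mirna_id, r.sequence) for r in recs
        ]


class TestNormalizeRna:
    def test_transliterates_dna(self):
        assert normalize_rna("acgt") == "ACGU"

    def test_rejects_other_characters(self):
        with pytest.raises(AlphabetError):
            normalize_rna("ACGX")

    @settings(derandomize=True, max_examples=50)
    @given(st.text(alphabet="ACGTUacgtu", min_size=1, max_size=50))
    def test_idempotent_and_length_preserving(self, seq):
        once = normalize_rna(seq)
        assert normalize_rna(once) == once
        assert len(once) == len(seq)
        assert set(once) <= set("ACGU")


class TestSnpTable:
    def _write(self, tmp_path, rows):
        p = tmp_path / "snps.tsv"
        p.write_text("".join("\t".join(map(str, r)) + "\n" for r in rows))
        return p

    def test_maf_filter_is_inclusive_at_threshold(self, tmp_path):
        p = self._write(tmp_path, [
            ("rs1060120", "tx1", 10, "A", "G", 0.30),
            ("rs_low", "tx1", 11, "A", "C", 0.029),
            ("rs_edge", "tx1", 12, "C", "T", 0.03),
        ])
        kept = read_snp_table(p, maf_min=0.03)
        assert [s.rsid for s in kept] == ["rs1060120", "rs_edge"]

    def test_offset_outside_utr_skipped_with_warning(self, tmp_path, caplog):
        utrs = {"tx1": UTRRecord("tx1", "ACGTACGT")}
        p = self._write(tmp_path, [("rs_far", "tx1", 99, "A", "G", 0.2)])
        with caplog.at_level(logging.WARNING):
            kept = read_snp_table(p, maf_min=0.03, utrs=utrs)
        assert kept == []
        assert any("outside" in r.message for r in caplog.records)

    def test_non_biallelic_skipped(self, tmp_path):
        p = self._write(tmp_path, [("rs_bad", "tx1", 1, "AT", "G", 0.2)])
        assert read_snp_table(p, maf_min=0.03) == []

    def test_maf_partition_property(self, tmp_path, rng):
        rows = [(f"rs{i}", "tx1", i, "A", "G", round(float(m), 4))
                for i, m in enumerate(rng.uniform(0, 0.5, 50))]
        p = self._write(tmp_path, rows)
        kept = read_snp_table(p, maf_min=0.1)
        kept_ids = {s.rsid for s in kept}
        for rsid, _, _, _, _, maf in rows:
            assert (rsid in kept_ids) == (maf >= 0.1)

    def test_vcf_input(self, tmp_path):
        vcf = tmp_path / "s.vcf"
        vcf.write_text(
            "##fileformat=VCFv4.2\n"
            '##INFO=<ID=MAF,Number=1,Type=Float,Description="maf">\n'
            "##contig=<ID=tx1,length=1000>\n"
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n"
            "tx1\t11\trs1\tA\tG\t.\t.\tMAF=0.25\n"
            "tx1\t12\trs2\tA\tG\t.\t.\tMAF=0.01\n"
        )
        kept = read_snp_table(vcf, format="vcf", maf_min=0.03)
        assert len(kept) == 1
        assert kept[0].rsid == "rs1"
        assert kept[0].utr_offset == 10  # 1-based VCF POS -> 0-based offset


class TestReport:
    def _call(self, rsid, verdict, best=None, mirnas=()):
        return MirSNPCall(rsid, "GENE", ("A", "G"),
                          {"A": best, "G": best}, tuple(mirnas), verdict, 0.0)

    def test_equal_verdict_row(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_mirsnp_report([self._call("rs1060120", "equal",
                                        mirnas=("hsa-miR-616",))], p)
        lines = p.read_text().splitlines()
        assert len(lines) == 2
        assert lines[0].split("\t") == list(seqio.REPORT_COLUMNS)
        assert lines[1].split("\t")[-1] == "equal"

    def test_empty_calls_header_only(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_mirsnp_report([], p)
        assert p.read_text().splitlines() == ["\t".join(seqio.REPORT_COLUMNS)]

    def test_no_alignment_row_has_empty_mirna_column(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_mirsnp_report([self._call("rs1663196", "island_no_alignment")], p)
        row = p.read_text().splitlines()[1].split("\t")
        assert row[3] == ""
        assert row[-1] == "island_no_alignment"

    def test_rows_sorted_by_rsid(self, tmp_path):
        p = tmp_path / "r.tsv"
        write_mirsnp_report(
            [self._call("rs_b", "equal"), self._call("rs_a", "equal")], p)
        rows = [l.split("\t")[0] for l in p.read_text().splitlines()[1:]]
        assert rows == ["rs_a", "rs_b"]


class TestPed:
    def test_round_trip(self, tmp_path):
        p = tmp_path / "f.ped"
        p.write_text(
            "fam1 dad 0 0 1 A A A B\n"
            "fam1 mom 0 0 2 A B 0 0\n"
            "fam1 kid dad mom 1 A B B B\n"
        )
        ped = read_ped(p, ["snp1", "snp2"])
        assert ped.genotypes[("dad", "snp1")] == ("A", "A")
        assert ped.genotypes[("mom", "snp2")] is None
        out = tmp_path / "o.ped"
        write_ped(ped, out)
        assert out.read_text() == p.read_text()

    def test_unresolvable_parent_raises(self, tmp_path):
        p = tmp_path / "f.ped"
        p.write_text("fam1 kid ghost 0 1 A A\n")
        with pytest.raises(Exception, match="ghost"):
            read_ped(p, ["snp1"])

    def test_wrong_column_count_names_line(self, tmp_path):
        p = tmp_path / "f.ped"
        p.write_text("fam1 kid 0 0 1 A\n")
        with pytest.raises(ParseError, match="expected 7"):
            read_ped(p, ["snp1"])


def test_snprecord_rejects_identical_alleles():
    with pytest.raises(Exception):
        SNPRecord("rs1", "tx", 5, ("A", "A"), 0.2)
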