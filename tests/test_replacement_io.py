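import io

import pytest

from dirsel.replacement_io import (
    DEFAULT_BLAST_FIELDS,
    FilterReport,
    Replacement,
    ReplacementList,
    diff_aligned,
    fetch_or_load_fasta,
    parse_blast_pairs,
    read_replacement_table,
    translate_cds,
    write_replacement_table,
)


class TestReplacement:
    def test_valid(self):
        r = Replacement(82, "C", "R")
        assert (r.site, r.from_res, r.to_res) == (82, "C", "R")

    def test_identical_residues_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            Replacement(1, "A", "A")

    @pytest.mark.parametrize("res", ["X", "B", "Z", "-"])
    def test_non_standard_rejected(self, res):
        with pytest.raises(ValueError, match="non-standard"):
            Replacement(1, res, "A")

    def test_site_must_be_positive(self):
        with pytest.raises(ValueError, match="site"):
            Replacement(0, "A", "C")


class TestReplacementList:
    def test_sites_strictly_increasing(self):
        reps = (Replacement(5, "A", "C"), Replacement(3, "C", "A"))
        with pytest.raises(ValueError, match="strictly increasing"):
            ReplacementList(reps, 10)

    def test_site_within_length(self):
        with pytest.raises(ValueError, match="exceeds"):
            ReplacementList((Replacement(11, "A", "C"),), 10)


class TestTranslateCds:
    def test_atg_standard(self):
        assert translate_cds("ATG") == "M"

    def test_645nt_gives_215_residues(self):
        cds = "ATG" + "GCT" * 214  # M + 214 x Ala
        assert len(cds) == 645
        assert translate_cds(cds, 5) == "M" + "A" * 214

    def test_trailing_bases_dropped_with_warning(self):
        cds = "ATG" + "GCT" * 214 + "G"
        with pytest.warns(UserWarning, match="trailing"):
            protein = translate_cds(cds, 5)
        assert len(protein) == 215

    def test_invertebrate_mito_code_differs(self):
        # AGA: Arg under the standard code, Ser under table 5
        assert translate_cds("AGA", 1) == "R"
        assert translate_cds("AGA", 5) == "S"

    def test_non_iupac_rejected(self):
        with pytest.raises(ValueError, match="non-IUPAC"):
            translate_cds("AT!")

    def test_ambiguous_codon_yields_x_with_warning(self):
        with pytest.warns(UserWarning, match="ambiguous"):
            assert translate_cds("ATGNNN") == "MX"

    def test_internal_stop_flagged(self):
        with pytest.warns(UserWarning, match="stop"):
            protein = translate_cds("ATGTAAATG", 1)
        assert protein == "M*M"

    def test_unknown_table(self):
        with pytest.raises(ValueError, match="genetic code"):
            translate_cds("ATG", 99)


class TestDiffAligned:
    def test_sage1_synthetic_pair(self, sage1_pair, sage1):
        a, b = sage1_pair
        rl = diff_aligned(a, b)
        assert len(rl) == 15
        assert rl.replacements[0] == Replacement(82, "C", "R")
        assert rl.replacements == sage1.replacements

    def test_identical_sequences(self):
        rl = diff_aligned("MKVC", "MKVC")
        assert len(rl) == 0
        assert rl.filter_report == FilterReport(matches=4)

    def test_gap_excluded_and_counted(self):
        rl = diff_aligned("MK-C", "MKVC")
        assert len(rl) == 0
        assert rl.filter_report.gaps == 1

    def test_nonstandard_excluded_and_counted(self):
        rl = diff_aligned("MKXC", "MKVA")
        assert rl.filter_report.nonstandard == 1
        assert len(rl) == 1  # only the C->A difference at site 4

    def test_length_mismatch(self):
        with pytest.raises(ValueError, match="length"):
            diff_aligned("MK", "MKV")

    def test_swap_symmetry(self, sage1_pair):
        a, b = sage1_pair
        fwd = diff_aligned(a, b)
        rev = diff_aligned(b, a)
        assert [r.site for r in fwd] == [r.site for r in rev]
        for rf, rr in zip(fwd, rev):
            assert (rf.from_res, rf.to_res) == (rr.to_res, rr.from_res)

    def test_filter_report_partitions_alignment(self, sage1_pair):
        a, b = sage1_pair
        fr = diff_aligned(a, b).filter_report
        assert fr.matches + fr.mismatches + fr.filtered == len(a)


BLAST_ROW = (
    "q1\ts1\t98.0\t10\t1\t0\t1\t10\t1\t10\t1e-5\t50.1\tMKVACDEFGH\tMKVACDEFGY"
)


class TestParseBlastPairs:
    def test_single_hsp(self):
        pairs = parse_blast_pairs(io.StringIO(BLAST_ROW + "\n"))
        assert len(pairs) == 1
        assert pairs[0].labels == ("q1", "s1")
        assert len(pairs[0].qseq) == len(pairs[0].sseq)

    def test_empty_file(self):
        assert parse_blast_pairs(io.StringIO("")) == []

    def test_gapped_hsp_retained(self):
        row = BLAST_ROW.replace("MKVACDEFGH", "MKVA-DEFGH")
        pairs = parse_blast_pairs(io.StringIO(row + "\n"))
        rl = diff_aligned(pairs[0].qseq, pairs[0].sseq)
        assert rl.filter_report.gaps == 1

    def test_missing_sequence_columns_named(self):
        with pytest.raises(ValueError, match="qseq.*sseq|'qseq' and 'sseq'"):
            parse_blast_pairs(io.StringIO("q1\ts1\n"), fields=("qseqid", "sseqid"))

    def test_fields_comment_overrides_layout(self):
        text = (
            "# BLASTP 2.16.0+\n"
            "# Fields: query id, subject id, query seq, subject seq\n"
            "q1\ts1\tMKV\tMKC\n"
        )
        pairs = parse_blast_pairs(io.StringIO(text))
        assert pairs[0].qseq == "MKV"

    def test_short_row_rejected(self):
        with pytest.raises(ValueError, match="columns"):
            parse_blast_pairs(io.StringIO("q1\ts1\tMKV\n"))

    def test_default_fields_cover_std_plus_seqs(self):
        assert DEFAULT_BLAST_FIELDS[-2:] == ("qseq", "sseq")


class TestReplacementTable:
    def test_sage1_table(self, sage1_table_text, sage1):
        rl = read_replacement_table(io.StringIO(sage1_table_text))
        assert len(rl) == 15
        assert rl.replacements == sage1.replacements

    def test_three_letter_codes_accepted(self):
        rl = read_replacement_table(io.StringIO("site\tfrom\tto\n82\tCys\tArg\n"))
        assert rl.replacements[0] == Replacement(82, "C", "R")

    def test_header_only(self):
        rl = read_replacement_table(io.StringIO("site\tfrom\tto\n"))
        assert len(rl) == 0

    def test_duplicate_site_rejected(self):
        text = "site\tfrom\tto\n82\tC\tR\n82\tV\tA\n"
        with pytest.raises(ValueError, match="duplicate.*82"):
            read_replacement_table(io.StringIO(text))

    def test_from_equals_to_rejected(self):
        with pytest.raises(ValueError, match="identical"):
            read_replacement_table(io.StringIO("site\tfrom\tto\n5\tA\tA\n"))

    def test_missing_header(self):
        with pytest.raises(ValueError, match="header"):
            read_replacement_table(io.StringIO("82\tC\tR\n"))

    def test_roundtrip_byte_identical(self, sage1_table_text):
        rl = read_replacement_table(io.StringIO(sage1_table_text))
        buf = io.StringIO()
        write_replacement_table(rl, buf)
        assert buf.getvalue() == sage1_table_text


class TestFetchOrLoadFasta:
    def test_local_single_record(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">seq1 demo\nMKV\n")
        rec = fetch_or_load_fasta(str(p))
        assert rec.id == "seq1"
        assert str(rec.seq) == "MKV"

    def test_multi_record_needs_selector(self, tmp_path):
        p = tmp_path / "x.fasta"
        p.write_text(">a\nMK\n>b\nMV\n")
        with pytest.raises(ValueError, match="record_id"):
            fetch_or_load_fasta(str(p))
        rec = fetch_or_load_fasta(str(p), record_id="b")
        assert str(rec.seq) == "MV"

    def test_cached_accession_loaded_without_network(self, tmp_path):
        (tmp_path / "FJ000001.fasta").write_text(">FJ000001\nATG\n")
        rec = fetch_or_load_fasta("FJ000001", cache_dir=tmp_path)
        assert str(rec.seq) == "ATG"

    def test_fetch_disabled_error_is_actionable(self, tmp_path):
        with pytest.raises(FileNotFoundError, match="allow_network"):
            fetch_or_load_fasta("FJ000001", cache_dir=tmp_path)
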