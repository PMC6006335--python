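"""Format readers/writers: coordinate conventions, filters, round trips."""

import warnings

import pytest

from oointegrity import genomic_io as gio
from oointegrity.genomic_io import ParseError, cigar_blocks

from conftest import SAM_HEADER, sam_line, write_sam

GTF_LINE = ('chr1\tsrc\texon\t{start}\t{end}\t.\t+\t.\t'
            'gene_id "g1"; transcript_id "g1.t1";')


class TestGtf:
    def test_one_based_inclusive_converted_to_half_open(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_LINE.format(start=11, end=20) + "\n")
        ann = gio.read_gtf(p)
        exon = ann.genes["g1"].transcripts["g1.t1"][0]
        assert (exon.start, exon.end) == (10, 20)

    def test_empty_file_yields_zero_genes(self, tmp_path):
        p = tmp_path / "empty.gtf"
        p.write_text("")
        assert len(gio.read_gtf(p)) == 0

    def test_out_of_order_exons_stored_sorted(self, tmp_path):
        p = tmp_path / "a.gtf"
        p.write_text(GTF_LINE.format(start=501, end=600) + "\n"
                     + GTF_LINE.format(start=101, end=200) + "\n")
        exons = gio.read_gtf(p).genes["g1"].transcripts["g1.t1"]
        assert [e.start for e in exons] == [100, 500]

    @pytest.mark.parametrize("bad, lineno", [
        ("chr1\tsrc\texon\t10\t20\t.\t+\t.", 1),          # 8 columns
        (GTF_LINE.format(start=30, end=20), 1),           # end < start
    ])
    def test_malformed_line_names_line_number(self, tmp_path, bad, lineno):
        p = tmp_path / "bad.gtf"
        p.write_text(bad + "\n")
        with pytest.raises(ParseError, match=f":{lineno}:"):
            gio.read_gtf(p)

    def test_round_trip_preserves_records(self, tmp_path, toy_annotation):
        p = tmp_path / "rt.gtf"
        gio.write_gtf(p, toy_annotation)
        back = gio.read_gtf(p)
        assert set(back.genes) == set(toy_annotation.genes)
        for gid, g in toy_annotation.genes.items():
            assert back.genes[gid].transcripts == g.transcripts
            assert back.genes[gid].strand == g.strand


RMSK_HEADER = "genoName\tgenoStart\tgenoEnd\tstrand\trepName\trepClass\trepFamily\n"


class TestRepeatTable:
    def test_rmsk_row(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(RMSK_HEADER + "chr1\t100\t290\t+\tB2_Mm2\tSINE\tB2\n")
        (el,) = gio.read_repeat_table(p, "rmsk")
        assert (el.interval.start, el.interval.end) == (100, 290)
        assert el.class_ == "SINE" and el.name == "B2_Mm2"

    def test_duplicate_rows_collapsed_with_warning(self, tmp_path):
        p = tmp_path / "r.tsv"
        row = "chr1\t100\t290\t+\tB2_Mm2\tSINE\tB2\n"
        p.write_text(RMSK_HEADER + row + row)
        with pytest.warns(UserWarning, match="1 duplicate"):
            els = gio.read_repeat_table(p, "rmsk")
        assert len(els) == 1

    def test_bed_empty_interval_rejected(self, tmp_path):
        p = tmp_path / "r.bed"
        p.write_text("chr1\t100\t100\tB2_Mm2\t0\t+\tSINE\tB2\n")
        with pytest.raises(ParseError, match="empty interval"):
            gio.read_repeat_table(p, "bed")

    def test_negative_coordinate_rejected(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(RMSK_HEADER + "chr1\t-5\t100\t+\tB2\tSINE\tB2\n")
        with pytest.raises(ParseError, match="negative"):
            gio.read_repeat_table(p, "rmsk")

    def test_unknown_dialect(self, tmp_path):
        p = tmp_path / "r.tsv"
        p.write_text(RMSK_HEADER)
        with pytest.raises(ValueError, match="dialect"):
            gio.read_repeat_table(p, "gff")

    @pytest.mark.parametrize("dialect", ["rmsk", "bed"])
    def test_round_trip(self, tmp_path, dialect):
        els = [gio.RepeatElement.make(
            gio.GenomicInterval("chr1", 100 * i, 100 * i + 80, "+"),
            f"B2like_{i}", "B2", "SINE") for i in range(1, 4)]
        p = tmp_path / "rt.tsv"
        gio.write_repeat_table(p, els, dialect)
        with warnings.catch_warnings():
            warnings.simplefilter("error")
            back = gio.read_repeat_table(p, dialect)
        assert sorted(e.id for e in back) == sorted(e.id for e in els)


class TestCigarBlocks:
    @pytest.mark.parametrize("pos, cigar, expected", [
        (100, [(0, 50)], ((100, 150),)),                       # 50M
        (0, [(0, 20), (3, 100), (0, 30)], ((0, 20), (120, 150))),
        (10, [(0, 10), (2, 5), (0, 10)], ((10, 35),)),         # D inside block
        (10, [(4, 5), (0, 10), (1, 3), (0, 10)], ((10, 30),)),  # S/I no ref
    ])
    def test_block_decomposition(self, pos, cigar, expected):
        assert cigar_blocks(pos, cigar) == expected

    def test_block_length_conservation(self):
        # sum of block lengths equals reference-consuming CIGAR length
        cigar = [(4, 3), (0, 12), (2, 4), (3, 50), (8, 7), (1, 2), (0, 9)]
        ref_len = sum(ln for op, ln in cigar if op in (0, 2, 7, 8))
        blocks = cigar_blocks(5, cigar)
        assert sum(e - s for s, e in blocks) == ref_len

    @pytest.mark.parametrize("cigar", [
        [(3, 10), (0, 20)],            # N first
        [(0, 20), (3, 10)],            # N last
        [(0, 10), (9, 5), (0, 10)],    # back-skip op unsupported
    ])
    def test_rejected_cigars(self, cigar):
        with pytest.raises(ValueError):
            cigar_blocks(0, cigar)


class TestReadAlignments:
    def test_blocks_from_sam(self, tmp_path):
        p = tmp_path / "c.sam"
        write_sam(p, [sam_line("r1", 101, "50M"),
                      sam_line("r2", 1, "20M100N30M")])
        recs, counts = gio.read_alignments(p)
        assert recs[0].blocks == ((100, 150),)
        assert recs[1].blocks == ((0, 20), (120, 150))
        assert counts.kept == 2 and counts.total == 2

    def test_multimapper_dropped_when_unique_only(self, tmp_path):
        p = tmp_path / "c.sam"
        write_sam(p, [sam_line("r1", 101, "50M", nh=2),
                      sam_line("r2", 201, "50M", nh=1)])
        recs, counts = gio.read_alignments(p, unique_only=True)
        assert [r.read_id for r in recs] == ["r2"]
        assert counts.dropped_multimapper == 1

    def test_secondary_dropped_when_primary_only(self, tmp_path):
        p = tmp_path / "c.sam"
        write_sam(p, [sam_line("r1", 101, "50M", flag=256),
                      sam_line("r2", 201, "50M")])
        recs, counts = gio.read_alignments(p, primary_only=True)
        assert [r.read_id for r in recs] == ["r2"]
        assert counts.dropped_nonprimary == 1

    def test_unique_filter_is_monotone(self, tmp_path):
        p = tmp_path / "c.sam"
        write_sam(p, [sam_line(f"r{i}", 1 + 10 * i, "30M", nh=1 + i % 3)
                      for i in range(9)])
        all_recs, _ = gio.read_alignments(p, unique_only=False)
        uniq_recs, _ = gio.read_alignments(p, unique_only=True)
        assert {r.read_id for r in uniq_recs} <= {r.read_id for r in all_recs}

    def test_cell_id_from_filename_and_rg(self, tmp_path):
        p = tmp_path / "oocyte7.sam"
        write_sam(p, [sam_line("r1", 101, "50M")])
        recs, _ = gio.read_alignments(p)
        assert recs[0].cell_id == "oocyte7"
        header = SAM_HEADER + "@RG\tID:cellX\n"
        write_sam(p, [sam_line("r1", 101, "50M") + "\tRG:Z:cellX"], header)
        recs, _ = gio.read_alignments(p)
        assert recs[0].cell_id == "cellX"
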