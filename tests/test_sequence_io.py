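import pytest

from symbgc import sequence_io as sio


# ---------------------------------------------------------------------------
# FASTA
# ---------------------------------------------------------------------------


class TestReadFasta:
    def test_single_record_uppercased(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">c1\nacgt\n")
        contigs = sio.read_fasta(path)
        assert len(contigs) == 1
        assert contigs[0].id == "c1"
        assert contigs[0].seq == "ACGT"
        assert contigs[0].length == 4

    def test_wrapped_lines_and_description(self, tmp_path):
        path = tmp_path / "a.fasta"
        path.write_text(">c1 some description\nAC\nGT\n")
        (contig,) = sio.read_fasta(path)
        assert contig.id == "c1"
        assert contig.seq == "ACGT"

    def test_empty_file_warns(self, tmp_path, caplog):
        path = tmp_path / "empty.fasta"
        path.write_text("")
        with caplog.at_level("WARNING", logger="symbgc.sequence_io"):
            assert sio.read_fasta(path) == []
        assert any("no records" in r.message for r in caplog.records)

    def test_sequence_before_header_names_line(self, tmp_path):
        path = tmp_path / "bad.fasta"
        path.write_text("ACGT\n>c1\nACGT\n")
        with pytest.raises(sio.InputError, match="line 1"):
            sio.read_fasta(path)

    def test_duplicate_id_rejected(self, tmp_path):
        path = tmp_path / "dup.fasta"
        path.write_text(">c1\nAC\n>c1\nGT\n")
        with pytest.raises(sio.InputError, match="duplicate"):
            sio.read_fasta(path)

    def test_round_trip(self, tmp_path):
        contigs = [
            sio.Contig("c1", "ACGTACGTNN"),
            sio.Contig("c2", "TTTT"),
        ]
        path = tmp_path / "rt.fasta"
        sio.write_fasta(path, contigs, width=4)
        back = sio.read_fasta(path)
        assert [(c.id, c.seq) for c in back] == [(c.id, c.seq) for c in contigs]


# ---------------------------------------------------------------------------
# GFF + categories
# ---------------------------------------------------------------------------


def _write_gene_inputs(tmp_path, contig_seq, start, end, strand, category="annotated"):
    gff = tmp_path / "genes.gff"
    gff.write_text(
        "##gff-version 3\n"
        f"c1\tsrc\tCDS\t{start}\t{end}\t.\t{strand}\t0\tID=g1\n"
    )
    cat = tmp_path / "cats.tsv"
    cat.write_text(f"g1\t{category}\n")
    return gff, cat, [sio.Contig("c1", contig_seq)]


class TestReadGffGenes:
    def test_forward_strand_cds(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(tmp_path, "ATGAAATTTGGG", 1, 6, "+")
        (gene,) = sio.read_gff_genes(gff, cat, contigs)
        assert gene.cds_seq == "ATGAAA"

    def test_reverse_strand_cds(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(tmp_path, "ATGAAA", 1, 6, "-")
        (gene,) = sio.read_gff_genes(gff, cat, contigs)
        assert gene.cds_seq == "TTTCAT"

    def test_category_applied(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(
            tmp_path, "ATGAAATTT", 1, 9, "+", category="ribosomal"
        )
        (gene,) = sio.read_gff_genes(gff, cat, contigs)
        assert gene.category == "ribosomal"

    def test_missing_category_defaults_hypothetical(self, tmp_path, caplog):
        gff = tmp_path / "genes.gff"
        gff.write_text("c1\tsrc\tCDS\t1\t6\t.\t+\t0\tID=gX\n")
        cat = tmp_path / "cats.tsv"
        cat.write_text("")
        with caplog.at_level("WARNING", logger="symbgc.sequence_io"):
            (gene,) = sio.read_gff_genes(gff, cat, [sio.Contig("c1", "ATGAAA")])
        assert gene.category == "hypothetical"
        assert any("defaulted" in r.message for r in caplog.records)

    def test_coordinates_outside_contig_error(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(tmp_path, "ATGAAA", 1, 60, "+")
        with pytest.raises(sio.InputError, match="outside"):
            sio.read_gff_genes(gff, cat, contigs)

    def test_unknown_category_lists_allowed(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(tmp_path, "ATGAAA", 1, 6, "+")
        cat.write_text("g1\tplasmid\n")
        with pytest.raises(sio.InputError, match="annotated"):
            sio.read_gff_genes(gff, cat, contigs)

    def test_round_trip_preserves_coordinates_and_strand(self, tmp_path):
        genes = [
            sio.GeneRecord("g1", "c1", 3, 8, "+", "annotated", "ATGAAA"),
            sio.GeneRecord("g2", "c1", 10, 15, "-", "bgc", "TTTCAT"),
        ]
        gff = tmp_path / "rt.gff"
        sio.write_gff_genes(gff, genes)
        cat = tmp_path / "cats.tsv"
        sio.write_category_table(cat, genes)
        contig = sio.Contig("c1", "GCATGAAACATGAAAC")
        back = sio.read_gff_genes(gff, cat, [contig])
        assert [(g.gene_id, g.start, g.end, g.strand, g.category) for g in back] == [
            (g.gene_id, g.start, g.end, g.strand, g.category) for g in genes
        ]

    def test_cds_extraction_deterministic(self, tmp_path):
        gff, cat, contigs = _write_gene_inputs(tmp_path, "ATGAAATTT", 1, 9, "+")
        first = sio.read_gff_genes(gff, cat, contigs)
        second = sio.read_gff_genes(gff, cat, contigs)
        assert first[0].cds_seq == second[0].cds_seq


# ---------------------------------------------------------------------------
# SAM
# ---------------------------------------------------------------------------

_SAM_HEADER = "@HD\tVN:1.6\n@SQ\tSN:c1\tLN:1000\n@SQ\tSN:c2\tLN:1000\n"


class TestSam:
    def test_round_trip_of_simulator_output(self, small_bundle_dir):
        bundle = small_bundle_dir
        reads = sio.read_sam(bundle.paths["sam"])
        assert len(reads) == len(bundle.alignments)
        by_key = {(r.read_id, r.is_read1): r for r in reads}
        for orig in bundle.alignments[:200]:
            got = by_key[(orig.read_id, orig.is_read1)]
            assert got.contig_id == orig.contig_id
            assert got.pos == orig.pos
            assert got.seq == orig.seq

    def test_secondary_alignments_ignored(self, tmp_path):
        path = tmp_path / "sec.sam"
        path.write_text(
            _SAM_HEADER
            + "r1\t65\tc1\t1\t60\t4M\t=\t10\t13\tACGT\tIIII\n"
            + "r1\t321\tc1\t50\t60\t4M\t=\t10\t0\tACGT\tIIII\n"  # secondary
            + "r1\t129\tc1\t10\t60\t4M\t=\t1\t-13\tACGT\tIIII\n"
        )
        reads = sio.read_sam(path)
        assert len(reads) == 2
        pairs = sio.pair_reads(reads)
        assert len(pairs) == 1
        assert pairs[0].proper_pair

    def test_truncated_file_errors(self, tmp_path):
        path = tmp_path / "trunc.sam"
        path.write_text(_SAM_HEADER + "r1\t0\tc1\n")
        with pytest.raises(sio.InputError):
            sio.read_sam_pairs(path)

    def test_unknown_reference_errors(self, tmp_path):
        path = tmp_path / "badref.sam"
        path.write_text(_SAM_HEADER + "r1\t0\tcX\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
        with pytest.raises(sio.InputError, match="absent from header"):
            sio.read_sam(path)

    def test_unpaired_reads_dropped(self, tmp_path, caplog):
        path = tmp_path / "unpaired.sam"
        path.write_text(_SAM_HEADER + "r1\t64\tc1\t1\t60\t4M\t*\t0\t0\tACGT\tIIII\n")
        with caplog.at_level("INFO", logger="symbgc.sequence_io"):
            pairs = sio.read_sam_pairs(path)
        assert pairs == []


# ---------------------------------------------------------------------------
# GFA
# ---------------------------------------------------------------------------


class TestGfa:
    def _write(self, tmp_path, lines):
        path = tmp_path / "g.gfa"
        path.write_text("H\tVN:Z:1.0\nS\ta\tACGT\nS\tb\tACGT\n" + lines)
        return path

    def test_plus_plus_link(self, tmp_path):
        graph = sio.read_gfa(self._write(tmp_path, "L\ta\t+\tb\t+\t0M\n"))
        assert graph.has_edge("a", "3p", "b", "5p")
        assert graph.has_edge("b", "5p", "a", "3p")  # symmetric

    def test_minus_plus_link(self, tmp_path):
        graph = sio.read_gfa(self._write(tmp_path, "L\ta\t-\tb\t+\t0M\n"))
        assert graph.has_edge("a", "5p", "b", "5p")

    def test_duplicate_links_deduplicated(self, tmp_path):
        graph = sio.read_gfa(
            self._write(tmp_path, "L\ta\t+\tb\t+\t0M\nL\ta\t+\tb\t+\t0M\n")
        )
        assert len(graph.edges) == 1

    def test_unknown_segment_errors(self, tmp_path):
        with pytest.raises(sio.InputError, match="unknown segment"):
            sio.read_gfa(self._write(tmp_path, "L\ta\t+\tzz\t+\t0M\n"))


# ---------------------------------------------------------------------------
# variant & homolog tables
# ---------------------------------------------------------------------------


def test_variant_table_round_trip(tmp_path):
    rows = [
        sio.VariantRow("bgc", 100, "ins1", ".", "+ACGTGA", (5, 12)),
        sio.VariantRow("bgc", 250, "snp1", "C", "T", (30, 14)),
    ]
    path = tmp_path / "v.tsv"
    sio.write_variant_table(path, rows)
    back = sio.read_variant_table(path)
    assert back == rows
    assert back[0].is_insertion and back[0].inserted_seq == "ACGTGA"
    assert not back[1].is_insertion


def test_homolog_table_round_trip(tmp_path):
    rows = [("g1", 100, 200), ("g2", 300, None)]
    path = tmp_path / "h.tsv"
    sio.write_homolog_table(path, rows)
    assert sio.read_homolog_table(path) == rows
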