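"""Genome parsing, operon grouping, and upstream-window extraction."""

import pytest

from bifidoreg import genome_io as gio
from bifidoreg.genome_io import (EmptyRegionError, Gene, Genome,
                                 GenomeFormatError, extract_upstream,
                                 group_operons, load_genome,
                                 reverse_complement)

GENBANK_2CDS = """\
LOCUS       ctg1                     300 bp    DNA     linear   BCT 01-JAN-2020
DEFINITION  toy record.
ACCESSION   ctg1
VERSION     ctg1
FEATURES             Location/Qualifiers
     source          1..300
     CDS             10..108
                     /locus_tag="gA"
                     /translation="MKLVNTGHAELSDFAQRWIVPETSGYKNMLHDRCEFQTAYWGIKV"
     CDS             complement(151..249)
                     /locus_tag="gB"
                     /translation="MTDYRKQLGAHWISEPVNFMCLDGSTAYQERIKVHNWPFGELSD"
ORIGIN
        1 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
       61 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      121 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      181 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
      241 acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt acgtacgtac gtacgtacgt
//
"""


@pytest.fixture
def gbk_path(tmp_path):
    p = tmp_path / "toy.gbk"
    p.write_text(GENBANK_2CDS)
    return p


@pytest.fixture
def fasta_gff_paths(tmp_path):
    seq = "ACGT" * 75
    fasta = tmp_path / "toy.fna"
    fasta.write_text(f">ctg1\n{seq}\n")
    gff = tmp_path / "toy.gff3"
    gff.write_text(
        "##gff-version 3\n"
        "ctg1\tsrc\tCDS\t10\t108\t.\t+\t0\tID=gA;locus_tag=gA\n"
        "ctg1\tsrc\tCDS\t151\t249\t.\t-\t0\tID=gB;locus_tag=gB\n")
    return fasta, gff


class TestLoadGenome:
    def test_genbank_two_cds_opposite_strands(self, gbk_path):
        genome = load_genome(gbk_path, "genbank", genome_id="toy")
        assert [g.gene_id for g in genome.genes] == ["gA", "gB"]
        assert [(g.start, g.end, g.strand) for g in genome.genes] == \
            [(9, 108, "+"), (150, 249, "-")]
        assert genome.genes[0].protein_seq.startswith("MKLV")

    def test_fasta_gff3_equals_genbank(self, gbk_path, fasta_gff_paths):
        fromgbk = load_genome(gbk_path, "genbank", genome_id="toy")
        fasta, gff = fasta_gff_paths
        fromgff = load_genome(gff, "fasta+gff3", fasta=fasta,
                              genome_id="toy")
        assert [(g.gene_id, g.start, g.end, g.strand)
                for g in fromgbk.genes] == \
               [(g.gene_id, g.start, g.end, g.strand)
                for g in fromgff.genes]

    def test_gff3_unknown_contig_is_named_in_error(self, tmp_path):
        fasta = tmp_path / "a.fna"
        fasta.write_text(">ctg1\nACGTACGTACGT\n")
        gff = tmp_path / "a.gff3"
        gff.write_text("ctgX\tsrc\tCDS\t1\t9\t.\t+\t0\tID=g1\n")
        with pytest.raises(GenomeFormatError, match="ctgX"):
            load_genome(gff, "fasta+gff3", fasta=fasta)

    def test_unparseable_genbank_raises(self, tmp_path):
        bad = tmp_path / "bad.gbk"
        bad.write_text("this is not genbank\n")
        with pytest.raises(GenomeFormatError):
            load_genome(bad, "genbank")


def _genome_with(genes, length=5000):
    return Genome("g", {"c1": "ACGT" * (length // 4)}, genes)


class TestGroupOperons:
    def test_gaps_under_threshold_merge(self):
        genes = [Gene("a", "c1", 100, 400, "+"),
                 Gene("b", "c1", 440, 700, "+"),
                 Gene("c", "c1", 760, 1000, "+")]
        ops = group_operons(_genome_with(genes), max_gap_bp=150)
        assert len(ops) == 1
        assert ops[0].leader.gene_id == "a"

    def test_gap_over_threshold_splits(self):
        genes = [Gene("a", "c1", 100, 400, "+"),
                 Gene("b", "c1", 900, 1200, "+")]
        ops = group_operons(_genome_with(genes), max_gap_bp=150)
        assert [len(o) for o in ops] == [1, 1]

    def test_divergent_pair_two_operons_facing_shared_region(self):
        # the araU/araFGH arrangement: (-) gene, shared intergenic, (+) gene
        genes = [Gene("u", "c1", 100, 400, "-"),
                 Gene("f", "c1", 500, 800, "+")]
        ops = group_operons(_genome_with(genes), max_gap_bp=150)
        assert len(ops) == 2
        leaders = {o.leader.gene_id for o in ops}
        assert leaders == {"u", "f"}

    def test_minus_strand_leader_is_rightmost(self):
        genes = [Gene("a", "c1", 100, 400, "-"),
                 Gene("b", "c1", 450, 700, "-")]
        ops = group_operons(_genome_with(genes), max_gap_bp=150)
        assert len(ops) == 1
        assert ops[0].leader.gene_id == "b"

    def test_idempotent_and_order_independent(self):
        genes = [Gene("a", "c1", 100, 400, "+"),
                 Gene("b", "c1", 440, 700, "+"),
                 Gene("c", "c1", 1000, 1300, "-")]
        g1 = _genome_with(genes)
        g2 = _genome_with(list(reversed(genes)))
        sig = lambda ops: [[g.gene_id for g in o] for o in ops]
        assert sig(group_operons(g1)) == sig(group_operons(g2))


class TestExtractUpstream:
    def test_plus_strand_window(self):
        g = Gene("a", "c1", 1000, 1300, "+")
        genome = _genome_with([g])
        r = extract_upstream(genome, g)
        assert (r.abs_start, r.abs_end) == (650, 1050)
        assert len(r) == 400
        assert r.offset_of_start_codon == 350

    def test_minus_strand_is_revcomp_of_forward_slice(self):
        g = Gene("a", "c1", 100, 300, "-")
        genome = _genome_with([g])
        r = extract_upstream(genome, g)
        contig = genome.contigs["c1"]
        # independent one-liner oracle
        assert r.seq == reverse_complement(contig[250:650])
        assert (r.abs_start, r.abs_end) == (250, 650)

    def test_clipping_at_contig_start(self):
        g = Gene("a", "c1", 100, 400, "+")
        genome = _genome_with([g])
        r = extract_upstream(genome, g)
        assert (r.abs_start, r.abs_end) == (0, 150)
        assert len(r) == 150
        assert r.offset_of_start_codon == 100

    def test_window_off_contig_raises(self):
        g = Gene("a", "c1", 4990, 4999, "-")
        genome = _genome_with([g])
        with pytest.raises(EmptyRegionError):
            extract_upstream(genome, g, window=(-350, -300))

    def test_strand_symmetry(self):
        """Reverse-complementing the genome and flipping strands yields
        the identical region sequence."""
        contig = ("ACGTTGCA" * 700)[:5000]
        g_fwd = Gene("a", "c1", 1000, 1300, "+")
        genome_fwd = Genome("g", {"c1": contig}, [g_fwd])
        n = len(contig)
        g_rev = Gene("a", "c1", n - 1300, n - 1000, "-")
        genome_rev = Genome("g", {"c1": reverse_complement(contig)}, [g_rev])
        r1 = extract_upstream(genome_fwd, g_fwd)
        r2 = extract_upstream(genome_rev, g_rev)
        assert r1.seq == r2.seq

    def test_coordinates_map_back_injectively(self):
        g = Gene("a", "c1", 1000, 1300, "-")
        genome = _genome_with([g])
        r = extract_upstream(genome, g)
        coords = [r.to_genome_coords(i) for i in range(len(r))]
        assert len(set(coords)) == len(coords)
        contig = genome.contigs["c1"]
        for i in (0, 17, 399):
            assert reverse_complement(contig[coords[i]]) == r.seq[i]


class TestOperonTable:
    def test_tsv_has_documented_columns_and_rows(self, tmp_path):
        genes = [Gene("a", "c1", 100, 400, "+", role="araB"),
                 Gene("b", "c1", 440, 700, "+")]
        genome = _genome_with(genes)
        ops = group_operons(genome)
        out = tmp_path / "operons.tsv"
        gio.write_operon_table(genome, ops, out)
        lines = out.read_text().splitlines()
        assert lines[0].split("\t") == [
            "genome_id", "operon_id", "gene_id", "contig", "start", "end",
            "strand", "role"]
        assert len(lines) == 3
        assert lines[1].split("\t")[2] == "a"
        assert lines[1].split("\t")[7] == "araB"
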