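"""Annotated-genome input, operon grouping, and upstream-region extraction.

Coordinates are 0-based half-open on the forward strand throughout.  The
upstream window used for binding-site search is -350..+50 relative to the
annotated start codon (position 0 of the window scale is the first base of
the start codon), reverse-complemented for minus-strand genes so the returned
sequence always reads 5'->3' relative to the gene.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

DEFAULT_WINDOW = (-350, 50)
#: conventional prokaryotic intergenic-gap threshold for operon grouping (bp)
DEFAULT_OPERON_GAP = 150

_COMPLEMENT = str.maketrans("ACGTRYKMBDHVNacgtrykmbdhvn",
                            "TGCAYRMKVHDBNtgcayrmkvhdbn")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (IUPAC codes preserved)."""
    return seq.translate(_COMPLEMENT)[::-1]


class GenomeFormatError(ValueError):
    """Raised when an input file does not parse as the named standard."""


class EmptyRegionError(ValueError):
    """Raised when a requested upstream window lies entirely off-contig."""


@dataclass(frozen=True)
class Gene:
    """A protein-coding gene anchored to a contig.

    ``start``/``end`` are 0-based half-open forward-strand coordinates;
    ``strand`` is ``+`` or ``-``.  ``role`` is an optional functional-role
    label from the arabinose/AOS subsystem vocabulary.
    """

    gene_id: str
    contig_id: str
    start: int
    end: int
    strand: str
    protein_seq: str = ""
    role: str | None = None

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise ValueError(f"{self.gene_id}: start must be < end "
                             f"({self.start} >= {self.end})")
        if self.strand not in {"+", "-"}:
            raise ValueError(f"{self.gene_id}: strand must be '+' or '-', "
                             f"got {self.strand!r}")

    @property
    def start_codon_pos(self) -> int:
        """Forward-strand coordinate of the first base of the start codon."""
        return self.start if self.strand == "+" else self.end - 1


@dataclass
class Genome:
    """Contigs plus strand-aware gene annotations for one genome."""

    genome_id: str
    contigs: dict[str, str]
    genes: list[Gene] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen: set[str] = set()
        for g in self.genes:
            if g.gene_id in seen:
                raise ValueError(f"duplicate gene id {g.gene_id!r} "
                                 f"in genome {self.genome_id}")
            seen.add(g.gene_id)
            if g.contig_id not in self.contigs:
                raise ValueError(f"gene {g.gene_id} references unknown "
                                 f"contig {g.contig_id!r}")
            if g.end > len(self.contigs[g.contig_id]):
                raise ValueError(f"gene {g.gene_id} extends past end of "
                                 f"contig {g.contig_id}")

    def gene(self, gene_id: str) -> Gene:
        for g in self.genes:
            if g.gene_id == gene_id:
                return g
        raise KeyError(gene_id)

    @property
    def proteome(self) -> dict[str, str]:
        return {g.gene_id: g.protein_seq for g in self.genes if g.protein_seq}


@dataclass(frozen=True)
class UpstreamRegion:
    """The -350..+50 window around a gene's start codon.

    ``seq`` reads 5'->3' relative to the gene.  ``abs_start``/``abs_end`` are
    forward-strand genome coordinates of the window.
    ``offset_of_start_codon`` is the index in ``seq`` of the start codon's
    first base (``len(seq) - 50`` when no clipping occurred).
    """

    gene_id: str
    contig_id: str
    abs_start: int
    abs_end: int
    seq: str
    offset_of_start_codon: int
    strand: str = "+"

    def __len__(self) -> int:
        return len(self.seq)

    def to_genome_coords(self, i: int) -> int:
        """Forward-strand genome coordinate of ``seq[i]``."""
        if self.strand == "+":
            return self.abs_start + i
        return self.abs_end - 1 - i


@dataclass
class Operon:
    """A run of co-transcribed same-strand genes; the leader is the first
    gene in transcription order and owns the regulatory upstream region."""

    operon_id: str
    genes: list[Gene]

    @property
    def leader(self) -> Gene:
        return self.genes[0]

    @property
    def strand(self) -> str:
        return self.genes[0].strand

    def __iter__(self):
        return iter(self.genes)

    def __len__(self) -> int:
        return len(self.genes)


# ---------------------------------------------------------------------------
# loading


def load_genome(path: str | Path, fmt: str = "genbank",
                fasta: str | Path | None = None,
                genome_id: str | None = None) -> Genome:
    """Read an annotated genome from GenBank or FASTA+GFF3.

    Parameters
    ----------
    path
        GenBank flat file, or the GFF3 file when ``fmt == "fasta+gff3"``.
    fmt
        ``"genbank"`` or ``"fasta+gff3"``.
    fasta
        Nucleotide FASTA accompanying the GFF3 (required for that format).
    genome_id
        Identifier for the genome; defaults to the file stem.

    One :class:`Gene` is produced per CDS feature.  Protein sequences come
    from the annotation (``translation`` qualifier) or are translated with
    the bacterial code (table 11) when absent.  CDS features without usable
    coordinates are skipped with a logged warning.
    """
    path = Path(path)
    gid = genome_id or path.stem
    if fmt == "genbank":
        return _load_genbank(path, gid)
    if fmt == "fasta+gff3":
        if fasta is None:
            raise ValueError("fasta path required for fasta+gff3 format")
        return _load_fasta_gff3(Path(fasta), path, gid)
    raise ValueError(f"unknown format {fmt!r}")


def _load_genbank(path: Path, genome_id: str) -> Genome:
    try:
        records = list(SeqIO.parse(str(path), "genbank"))
    except Exception as exc:  # Bio raises assorted parse errors
        raise GenomeFormatError(f"{path}: not a parseable GenBank file: {exc}")
    if not records:
        raise GenomeFormatError(f"{path}: no GenBank records found")
    contigs: dict[str, str] = {}
    genes: list[Gene] = []
    for rec in records:
        contigs[rec.id] = str(rec.seq).upper()
        for feat in rec.features:
            if feat.type != "CDS":
                continue
            if feat.location is None:
                logger.warning("CDS without coordinates skipped in %s", rec.id)
                continue
            quals = feat.qualifiers
            gene_id = (quals.get("locus_tag") or quals.get("gene")
                       or [f"{rec.id}_{int(feat.location.start)}"])[0]
            start = int(feat.location.start)
            end = int(feat.location.end)
            strand = "-" if feat.location.strand == -1 else "+"
            if "translation" in quals:
                prot = quals["translation"][0]
            else:
                prot = _translate_cds(contigs[rec.id][start:end], strand)
            role = quals.get("function", [None])[0]
            genes.append(Gene(gene_id, rec.id, start, end, strand,
                              protein_seq=prot, role=role))
    return Genome(genome_id, contigs, genes)


def _translate_cds(dna: str, strand: str) -> str:
    if strand == "-":
        dna = reverse_complement(dna)
    prot = str(Seq(dna).translate(table=11))
    return prot.rstrip("*")


def _load_fasta_gff3(fasta: Path, gff3: Path, genome_id: str) -> Genome:
    contigs = {rec.id: str(rec.seq).upper()
               for rec in SeqIO.parse(str(fasta), "fasta")}
    if not contigs:
        raise GenomeFormatError(f"{fasta}: no FASTA records found")
    genes: list[Gene] = []
    with open(gff3) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise GenomeFormatError(
                    f"{gff3}:{lineno}: expected 9 tab-separated columns")
            seqid, _src, ftype, start, end, _score, strand, _phase, attrs = fields
            if ftype != "CDS":
                continue
            if seqid not in contigs:
                raise GenomeFormatError(
                    f"{gff3}:{lineno}: contig {seqid!r} absent from {fasta}")
            attr = _parse_gff3_attrs(attrs)
            gene_id = (attr.get("locus_tag") or attr.get("ID")
                       or f"{seqid}_{start}")
            # GFF3 is 1-based inclusive; convert to 0-based half-open
            s, e = int(start) - 1, int(end)
            prot = attr.get("translation") or _translate_cds(
                contigs[seqid][s:e], strand)
            genes.append(Gene(gene_id, seqid, s, e, strand,
                              protein_seq=prot, role=attr.get("role")))
    return Genome(genome_id, contigs, genes)


def _parse_gff3_attrs(attrs: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attrs.split(";"):
        part = part.strip()
        if "=" in part:
            k, v = part.split("=", 1)
            out[k] = v
    return out


# ---------------------------------------------------------------------------
# operons


def group_operons(genome: Genome,
                  max_gap_bp: int = DEFAULT_OPERON_GAP) -> list[Operon]:
    """Group consecutive same-strand genes into operons.

    Genes are sorted by contig and coordinate; adjacent same-strand genes
    whose intergenic gap is at most ``max_gap_bp`` are merged.  Each operon's
    genes are ordered in transcription order, so for a minus-strand operon
    the rightmost gene is the leader.  Divergently transcribed pairs always
    fall into separate operons.
    """
    ordered = sorted(genome.genes, key=lambda g: (g.contig_id, g.start, g.end))
    operons: list[Operon] = []
    run: list[Gene] = []

    def _flush() -> None:
        if not run:
            return
        tx = list(run) if run[0].strand == "+" else list(reversed(run))
        operons.append(Operon(f"{genome.genome_id}_op{len(operons):04d}", tx))
        run.clear()

    for gene in ordered:
        if run and (gene.contig_id != run[-1].contig_id
                    or gene.strand != run[-1].strand
                    or gene.start - run[-1].end > max_gap_bp):
            _flush()
        run.append(gene)
    _flush()
    return operons


# ---------------------------------------------------------------------------
# upstream windows


def extract_upstream(genome: Genome, gene: Gene,
                     window: tuple[int, int] = DEFAULT_WINDOW
                     ) -> UpstreamRegion:
    """Extract the window around a gene's start codon (default -350..+50).

    For a plus-strand gene with start codon at ``s`` the forward-strand
    interval is ``[s + window[0], s + window[1])``; for a minus-strand gene
    with start codon at ``e - 1`` it is ``[e - window[1], e - window[0])``
    and the sequence is reverse-complemented.  Windows are clipped at contig
    ends; the window is NOT truncated at a preceding gene's boundary (the
    scan uses a fixed window), so overlap with upstream coding sequence can
    occur and is the caller's concern to flag.
    """
    contig = genome.contigs[gene.contig_id]
    lo, hi = window
    if gene.strand == "+":
        a, b = gene.start + lo, gene.start + hi
    else:
        a, b = gene.end - hi, gene.end - lo
    a_clip, b_clip = max(a, 0), min(b, len(contig))
    if a_clip >= b_clip:
        raise EmptyRegionError(
            f"window for {gene.gene_id} lies entirely off contig "
            f"{gene.contig_id}")
    raw = contig[a_clip:b_clip]
    if gene.strand == "+":
        seq = raw
        offset = gene.start - a_clip
    else:
        seq = reverse_complement(raw)
        offset = b_clip - gene.end
    return UpstreamRegion(gene.gene_id, gene.contig_id, a_clip, b_clip,
                          seq, offset, strand=gene.strand)


def upstream_regions_for_leaders(genome: Genome, operons: Sequence[Operon],
                                 window: tuple[int, int] = DEFAULT_WINDOW
                                 ) -> dict[str, UpstreamRegion]:
    """Upstream window for every operon leader, keyed by leader gene id."""
    out: dict[str, UpstreamRegion] = {}
    for op in operons:
        try:
            out[op.leader.gene_id] = extract_upstream(genome, op.leader, window)
        except EmptyRegionError:
            logger.warning("no upstream window for %s", op.leader.gene_id)
    return out


# ---------------------------------------------------------------------------
# tabular output


def write_operon_table(genome: Genome, operons: Iterable[Operon],
                       path: str | Path) -> None:
    """TSV of genes grouped by operon (one row per gene)."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "operon_id", "gene_id", "contig",
                    "start", "end", "strand", "role"])
        for op in operons:
            for g in op:
                w.writerow([genome.genome_id, op.operon_id, g.gene_id,
                            g.contig_id, g.start, g.end, g.strand,
                            g.role or ""])
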