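"""Scan upstream regions and whole genomes for TF-binding sites.

Hits are reported in the -350..+50 window of operon leaders.  Because the
motif model is exactly palindromic, a site and its reverse complement score
identically; forward/reverse reports of the same interval are therefore
collapsed to a single hit with strand ".".  A site in the shared intergenic
region of a divergently transcribed gene pair is attributed to both leaders
(two hits, one genomic interval), since such a site can regulate both
operons.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np

from bifidoreg.genome_io import Genome, Operon, UpstreamRegion, \
    upstream_regions_for_leaders
from bifidoreg.motif_core import MotifModel, encode


@dataclass(frozen=True)
class SiteHit:
    """A scored candidate binding site anchored to a target gene."""

    motif_name: str
    genome_id: str
    target_gene_id: str
    contig: str
    abs_start: int          # forward-strand genome coordinate
    strand: str             # "+", "-", or "." for an exact palindrome
    sequence: str
    score: float
    site_class: str         # "strong" | "weak"
    pos_vs_start_codon: int  # signed offset of site start vs start codon
    shared: bool = False    # attributed to two divergent leaders

    @property
    def abs_end(self) -> int:
        return self.abs_start + len(self.sequence)

    @property
    def interval(self) -> tuple[str, int, int]:
        return (self.contig, self.abs_start, self.abs_end)


def score_site(model: MotifModel, seq: str) -> float:
    """Sum of positional weights; NaN sentinel on ambiguous bases."""
    return model.score(seq)


def scan_region(model: MotifModel, region: UpstreamRegion,
                genome_id: str = "") -> list[SiteHit]:
    """All windows of ``region`` scoring at or above the weak threshold.

    One strand is scanned (palindromic symmetry covers the other); each hit
    carries strand "." and its position relative to the start codon.  Hits
    are sorted by score descending, ties by position.
    """
    if math.isnan(model.weak_threshold):
        raise ValueError(f"motif {model.name}: thresholds not calibrated")
    codes = encode(region.seq)
    scores = model.score_windows(codes)
    hits: list[SiteHit] = []
    L = model.length
    for i in np.nonzero(scores >= model.weak_threshold)[0]:
        i = int(i)
        score = float(scores[i])
        cls = "strong" if score >= model.strong_threshold else "weak"
        if region.strand == "+":
            abs_start = region.abs_start + i
        else:
            abs_start = region.abs_end - i - L
        hits.append(SiteHit(
            motif_name=model.name,
            genome_id=genome_id,
            target_gene_id=region.gene_id,
            contig=region.contig_id,
            abs_start=abs_start,
            strand=".",
            sequence=region.seq[i:i + L],
            score=score,
            site_class=cls,
            pos_vs_start_codon=i - region.offset_of_start_codon,
        ))
    hits.sort(key=lambda h: (-h.score, h.abs_start))
    return hits


def scan_genome(model: MotifModel, genome: Genome,
                operons: Sequence[Operon],
                window: tuple[int, int] = (-350, 50),
                all_genes: bool = False) -> list[SiteHit]:
    """Scan the upstream window of every operon leader in a genome.

    With ``all_genes=True`` every gene's upstream window is scanned instead
    of leaders only.  A hit whose genomic interval appears in the windows of
    two divergently transcribed leaders is reported once per leader with
    ``shared=True``.
    """
    if all_genes:
        regions = {}
        from bifidoreg.genome_io import EmptyRegionError, extract_upstream
        for g in genome.genes:
            try:
                regions[g.gene_id] = extract_upstream(genome, g, window)
            except EmptyRegionError:
                continue
    else:
        regions = upstream_regions_for_leaders(genome, operons, window)

    hits: list[SiteHit] = []
    for region in regions.values():
        hits.extend(scan_region(model, region, genome_id=genome.genome_id))

    # mark sites falling in the shared window of two divergent leaders
    by_interval: dict[tuple[str, int, int], list[int]] = {}
    for idx, h in enumerate(hits):
        by_interval.setdefault(h.interval, []).append(idx)
    for idxs in by_interval.values():
        targets = {hits[i].target_gene_id for i in idxs}
        if len(targets) > 1:
            for i in idxs:
                hits[i] = SiteHit(**{**hits[i].__dict__, "shared": True})
    hits.sort(key=lambda h: (h.contig, h.abs_start, h.target_gene_id))
    return hits


# ---------------------------------------------------------------------------
# output

TSV_COLUMNS = ["motif", "genome_id", "target_gene", "contig", "start", "end",
               "strand", "sequence", "score", "class",
               "pos_vs_start_codon", "shared"]


def write_hits_tsv(hits: Iterable[SiteHit], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(TSV_COLUMNS)
        for h in hits:
            w.writerow([h.motif_name, h.genome_id, h.target_gene_id,
                        h.contig, h.abs_start, h.abs_end, h.strand,
                        h.sequence, f"{h.score:.4f}", h.site_class,
                        h.pos_vs_start_codon, int(h.shared)])


def write_hits_gff3(hits: Iterable[SiteHit], path) -> None:
    """GFF3 (1-based inclusive) with type TF_binding_site."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for i, h in enumerate(hits):
            attrs = (f"ID=site{i:05d};motif={h.motif_name};"
                     f"class={h.site_class};target_gene={h.target_gene_id};"
                     f"shared={int(h.shared)}")
            fh.write("\t".join([
                h.contig, "bifidoreg", "TF_binding_site",
                str(h.abs_start + 1), str(h.abs_end), f"{h.score:.4f}",
                h.strand, ".", attrs]) + "\n")
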