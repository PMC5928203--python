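"""Ortholog detection across genomes by reciprocal best protein hits.

Pairwise protein similarity is computed with a Smith-Waterman local
alignment under BLOSUM62 with affine gaps (open 11, extend 1), which yields
BLAST-comparable identity/coverage figures without an external search
binary.  One-to-one pairs come from reciprocal best hits; single-linkage
clustering over all genome pairs produces ortholog groups, and gene
neighborhoods (synteny) resolve genomes that contribute more than one
candidate to a group.  A precomputed ortholog table can be supplied instead
to bypass the module.
"""

from __future__ import annotations

import csv
import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from Bio import Align
from Bio.Align import substitution_matrices

from bifidoreg.genome_io import Genome

DEFAULT_MIN_IDENTITY = 30.0   # percent
DEFAULT_MIN_COVERAGE = 70.0   # percent of BOTH sequences
DEFAULT_SYNTENY_WINDOW = 5    # genes on either side


@dataclass(frozen=True)
class SimilarityHit:
    """One query->subject local-alignment hit."""

    query: str
    subject: str
    score: float
    pct_identity: float
    coverage_query: float
    coverage_subject: float
    aln_length: int


@dataclass
class OrthologGroup:
    """A cross-genome family with at most one member per genome."""

    group_id: str
    members: dict[str, str] = field(default_factory=dict)  # genome -> gene
    reference_member: str | None = None

    def __len__(self) -> int:
        return len(self.members)


def _make_aligner() -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "local"
    aligner.substitution_matrix = substitution_matrices.load("BLOSUM62")
    aligner.open_gap_score = -11.0
    aligner.extend_gap_score = -1.0
    return aligner


def _alignment_stats(aln) -> tuple[int, int]:
    """(identical positions, alignment columns with both residues)."""
    ident = 0
    cols = 0
    qa, sa = aln[0], aln[1]
    for x, y in zip(qa, sa):
        if x == "-" or y == "-":
            cols += 1
            continue
        cols += 1
        if x == y:
            ident += 1
    return ident, cols


def all_vs_all_similarity(proteome_a: Mapping[str, str],
                          proteome_b: Mapping[str, str],
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          min_coverage: float = DEFAULT_MIN_COVERAGE
                          ) -> list[SimilarityHit]:
    """Score every protein of A against every protein of B.

    Hits below the identity or (bidirectional) coverage thresholds are
    dropped.  Output is sorted by query, then score descending, then longer
    alignment, then subject id — a total order that makes downstream
    best-hit selection deterministic.
    """
    if not proteome_a or not proteome_b:
        raise ValueError("empty proteome")
    aligner = _make_aligner()
    hits: list[SimilarityHit] = []
    for qid, qseq in proteome_a.items():
        for sid, sseq in proteome_b.items():
            if not qseq or not sseq:
                continue
            alns = aligner.align(qseq, sseq)
            if len(alns) == 0:
                continue
            aln = alns[0]
            ident, cols = _alignment_stats(aln)
            if cols == 0:
                continue
            pid = 100.0 * ident / cols
            # coverage = aligned (non-gap) span of each sequence
            q_aligned = sum(e - s for s, e in aln.aligned[0])
            s_aligned = sum(e - s for s, e in aln.aligned[1])
            cov_q = 100.0 * q_aligned / len(qseq)
            cov_s = 100.0 * s_aligned / len(sseq)
            if pid >= min_identity and cov_q >= min_coverage \
                    and cov_s >= min_coverage:
                hits.append(SimilarityHit(qid, sid, float(aln.score), pid,
                                          cov_q, cov_s, cols))
    hits.sort(key=lambda h: (h.query, -h.score, -h.aln_length, h.subject))
    return hits


def _best_hits(hits: Sequence[SimilarityHit]) -> dict[str, SimilarityHit]:
    best: dict[str, SimilarityHit] = {}
    for h in hits:  # hits are pre-sorted; first per query wins
        if h.query not in best:
            best[h.query] = h
    return best


def reciprocal_best_hits(pairs_ab: Sequence[SimilarityHit],
                         pairs_ba: Sequence[SimilarityHit],
                         min_identity: float = DEFAULT_MIN_IDENTITY,
                         min_coverage: float = DEFAULT_MIN_COVERAGE
                         ) -> list[tuple[str, str, float]]:
    """(a, b, score) pairs where b is a's best hit and vice versa.

    Ties between equally scoring hits break by longer alignment, then
    lexicographic gene id (already encoded in the hit ordering), so the
    result does not depend on input order.
    """
    best_ab = _best_hits(pairs_ab)
    best_ba = _best_hits(pairs_ba)
    out = []
    for a, hit in sorted(best_ab.items()):
        if hit.pct_identity < min_identity or \
                min(hit.coverage_query, hit.coverage_subject) < min_coverage:
            continue
        back = best_ba.get(hit.subject)
        if back is not None and back.subject == a:
            out.append((a, hit.subject, hit.score))
    return out


class _UnionFind:
    def __init__(self) -> None:
        self.parent: dict = {}

    def find(self, x):
        self.parent.setdefault(x, x)
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            # deterministic root: smaller key wins
            if rb < ra:
                ra, rb = rb, ra
            self.parent[rb] = ra


def _gene_positions(genome: Genome) -> dict[str, tuple[str, int]]:
    """gene_id -> (contig, ordinal position along the contig)."""
    out: dict[str, tuple[str, int]] = {}
    ordered = sorted(genome.genes, key=lambda g: (g.contig_id, g.start))
    counters: dict[str, int] = {}
    for g in ordered:
        i = counters.get(g.contig_id, 0)
        out[g.gene_id] = (g.contig_id, i)
        counters[g.contig_id] = i + 1
    return out


def build_groups(rbh_pairs: Mapping[tuple[str, str],
                                    Sequence[tuple[str, str, float]]],
                 genomes: Sequence[Genome],
                 synteny_window: int = DEFAULT_SYNTENY_WINDOW,
                 reference_genome: str | None = None
                 ) -> list[OrthologGroup]:
    """Cluster reciprocal-best-hit pairs into ortholog groups.

    ``rbh_pairs`` maps an ordered genome-id pair (ga, gb) to the RBH list of
    that pair.  Single-linkage clustering joins genes across all pairs; when
    a genome contributes more than one gene to a cluster, the gene sharing
    at least one orthologous neighbor within ``synteny_window`` genes of
    another member is kept, otherwise the best-scoring one; displaced genes
    become singleton groups.
    """
    uf = _UnionFind()
    pair_score: dict[frozenset, float] = {}
    for (ga, gb), pairs in sorted(rbh_pairs.items()):
        for a, b, score in pairs:
            ka, kb = (ga, a), (gb, b)
            uf.union(ka, kb)
            pair_score[frozenset((ka, kb))] = score

    clusters: dict = {}
    for key in sorted(uf.parent):
        clusters.setdefault(uf.find(key), []).append(key)

    positions = {g.genome_id: _gene_positions(g) for g in genomes}
    gene_cluster = {key: root for root, keys in clusters.items()
                    for key in keys}

    def neighbor_clusters(genome_id: str, gene_id: str) -> set:
        pos = positions[genome_id]
        contig, i = pos[gene_id]
        out = set()
        for other, (c2, j) in pos.items():
            if other == gene_id or c2 != contig:
                continue
            if abs(j - i) <= synteny_window:
                root = gene_cluster.get((genome_id, other))
                if root is not None:
                    out.add(root)
        return out

    def member_score(key) -> float:
        return max((s for fs, s in pair_score.items() if key in fs),
                   default=0.0)

    groups: list[OrthologGroup] = []
    singletons: list[tuple[str, str]] = []
    for root in sorted(clusters):
        keys = sorted(clusters[root])
        by_genome: dict[str, list[tuple[str, str]]] = {}
        for gid, gene in keys:
            by_genome.setdefault(gid, []).append((gid, gene))
        chosen: dict[str, str] = {}
        for gid, cands in sorted(by_genome.items()):
            if len(cands) == 1:
                chosen[gid] = cands[0][1]
                continue
            other_neighbors: set = set()
            for og, ocands in by_genome.items():
                if og == gid:
                    continue
                for _, gene in ocands:
                    other_neighbors |= neighbor_clusters(og, gene)
            syntenic = [c for c in cands
                        if neighbor_clusters(gid, c[1]) & other_neighbors]
            pool = syntenic or cands
            pool.sort(key=lambda k: (-member_score(k), k[1]))
            chosen[gid] = pool[0][1]
            singletons.extend(c for c in cands if c[1] != chosen[gid])
        groups.append(OrthologGroup("", dict(sorted(chosen.items()))))

    for gid, gene in sorted(singletons):
        groups.append(OrthologGroup("", {gid: gene}))

    # genes that never entered a reciprocal pair (e.g., the losing copy of
    # a recent duplication) become singleton groups too
    placed = {(gid, gene) for g in groups for gid, gene in g.members.items()}
    for genome in sorted(genomes, key=lambda g: g.genome_id):
        for gene in sorted(genome.genes, key=lambda g: g.gene_id):
            if gene.protein_seq and \
                    (genome.genome_id, gene.gene_id) not in placed:
                groups.append(OrthologGroup(
                    "", {genome.genome_id: gene.gene_id}))

    # stable ids: order by (size desc, first member)
    groups.sort(key=lambda g: (-len(g), sorted(g.members.items())))
    for i, g in enumerate(groups):
        g.group_id = f"OG{i:04d}"
        if reference_genome and reference_genome in g.members:
            g.reference_member = g.members[reference_genome]
    return groups


def infer_ortholog_groups(genomes: Sequence[Genome],
                          min_identity: float = DEFAULT_MIN_IDENTITY,
                          min_coverage: float = DEFAULT_MIN_COVERAGE,
                          synteny_window: int = DEFAULT_SYNTENY_WINDOW,
                          reference_genome: str | None = None
                          ) -> list[OrthologGroup]:
    """End-to-end ortholog inference over a set of genomes."""
    rbh: dict[tuple[str, str], list[tuple[str, str, float]]] = {}
    for ga, gb in itertools.combinations(
            sorted(genomes, key=lambda g: g.genome_id), 2):
        ab = all_vs_all_similarity(ga.proteome, gb.proteome,
                                   min_identity, min_coverage)
        ba = all_vs_all_similarity(gb.proteome, ga.proteome,
                                   min_identity, min_coverage)
        rbh[(ga.genome_id, gb.genome_id)] = reciprocal_best_hits(
            ab, ba, min_identity, min_coverage)
    return build_groups(rbh, genomes, synteny_window, reference_genome)


# ---------------------------------------------------------------------------
# table round trip


def write_ortholog_table(groups: Iterable[OrthologGroup], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["group_id", "genome_id", "gene_id"])
        for g in groups:
            for genome_id, gene_id in sorted(g.members.items()):
                w.writerow([g.group_id, genome_id, gene_id])


def read_ortholog_table(path) -> list[OrthologGroup]:
    by_id: dict[str, OrthologGroup] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            grp = by_id.setdefault(row["group_id"],
                                   OrthologGroup(row["group_id"]))
            grp.members[row["genome_id"]] = row["gene_id"]
    return [by_id[k] for k in sorted(by_id)]
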