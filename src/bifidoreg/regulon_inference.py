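"""Cross-genome regulon propagation, consistency filtering, and core calls.

A candidate regulon member is an ortholog group (or a genome-specific
operon) whose leader carries a binding-site hit.  The consistency check
accepts a member only when strong sites recur in enough genomes carrying
the gene; weak sites count only with orthologous strong support elsewhere
(phylogenetic footprinting).  Core members are those whose sites are
conserved in at least ``core_min`` genomes.
"""

from __future__ import annotations

import csv
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from bifidoreg.genome_io import Genome, Operon
from bifidoreg.motif_core import MotifModel
from bifidoreg.orthology import OrthologGroup
from bifidoreg.site_scan import SiteHit, scan_genome
from bifidoreg.subsystem_phenotype import ROLES, TF_ROLES

DEFAULT_MIN_GENOMES = 3
DEFAULT_CORE_MIN = 20
GENOME_SPECIFIC_PREFIX = "specific"


@dataclass
class RegulonMember:
    """One accepted member with its per-genome site evidence."""

    member_id: str                      # ortholog group id or specific key
    genome_hits: dict[str, list[SiteHit]] = field(default_factory=dict)
    conservation_count: int = 0
    genome_specific: bool = False
    conservation_class: str = ""        # core | group-specific | genome-specific
    mode: str = "ND"

    def genomes(self) -> list[str]:
        return sorted(self.genome_hits)


@dataclass
class Regulon:
    """A TF ortholog group mapped to its accepted members."""

    tf_name: str
    tf_group: OrthologGroup | None
    members: list[RegulonMember] = field(default_factory=list)


def propagate(tf_group: OrthologGroup, motif: MotifModel,
              genomes: Sequence[Genome],
              operons_by_genome: Mapping[str, Sequence[Operon]],
              ortholog_groups: Sequence[OrthologGroup],
              window: tuple[int, int] = (-350, 50)
              ) -> dict[str, dict[str, list[SiteHit]]]:
    """Scan every TF-carrying genome and key hits by target ortholog group.

    Only genomes with a member in ``tf_group`` are scanned.  Each hit's
    target operon leader is mapped to its ortholog group; leaders without a
    group elsewhere become genome-specific candidates keyed
    ``specific:<genome>:<gene>``.
    """
    carriers = [g for g in genomes if g.genome_id in tf_group.members]
    if not carriers:
        raise ValueError(f"TF group {tf_group.group_id} absent from all "
                         "supplied genomes")
    gene_to_group: dict[tuple[str, str], str] = {}
    for grp in ortholog_groups:
        for genome_id, gene_id in grp.members.items():
            gene_to_group[(genome_id, gene_id)] = grp.group_id

    candidates: dict[str, dict[str, list[SiteHit]]] = {}
    for genome in carriers:
        hits = scan_genome(motif, genome, operons_by_genome[genome.genome_id],
                           window=window)
        for hit in hits:
            key = gene_to_group.get((genome.genome_id, hit.target_gene_id))
            if key is None:
                key = (f"{GENOME_SPECIFIC_PREFIX}:{genome.genome_id}:"
                       f"{hit.target_gene_id}")
            candidates.setdefault(key, {}).setdefault(
                genome.genome_id, []).append(hit)
    return candidates


def _carrier_count(member_id: str, tf_genomes: set[str],
                   ortholog_groups_by_id: Mapping[str, OrthologGroup]) -> int:
    grp = ortholog_groups_by_id.get(member_id)
    if grp is None:
        return 1
    return len(set(grp.members) & tf_genomes)


def consistency_filter(candidates: Mapping[str, Mapping[str, list[SiteHit]]],
                       tf_genomes: Iterable[str],
                       ortholog_groups: Sequence[OrthologGroup] = (),
                       min_genomes: int = DEFAULT_MIN_GENOMES,
                       weak_needs_support: bool = True
                       ) -> list[RegulonMember]:
    """Accept candidates whose sites recur across genomes.

    A member passes when strong hits occur in at least
    ``min(min_genomes, ceil(0.5 * carriers))`` genomes, where *carriers* is
    the number of TF-carrying genomes that carry the gene at all — so a
    rarely distributed gene needs sites in only half its carriers, and the
    requirement is monotone non-decreasing in ``min_genomes``.  Weak hits
    are kept only when the same group has a strong hit in another genome
    (orthologous footprinting support), unless ``weak_needs_support`` is
    off.  Genome-specific candidates (no ortholog elsewhere, including
    singleton groups) need a strong hit and are flagged.
    """
    tf_set = set(tf_genomes)
    groups_by_id = {g.group_id: g for g in ortholog_groups}
    accepted: list[RegulonMember] = []
    for member_id in sorted(candidates):
        per_genome = candidates[member_id]
        strong = {g for g, hits in per_genome.items()
                  if any(h.site_class == "strong" for h in hits)}
        weak_only = set(per_genome) - strong
        grp = groups_by_id.get(member_id)
        specific = member_id.startswith(GENOME_SPECIFIC_PREFIX + ":") \
            or (grp is not None and len(grp.members) <= 1)

        if specific:
            if not strong:
                continue
            kept = {g: [h for h in per_genome[g]] for g in strong}
            member = RegulonMember(member_id, kept, len(kept),
                                   genome_specific=True)
            accepted.append(member)
            continue

        carriers = _carrier_count(member_id, tf_set, groups_by_id)
        required = min(min_genomes, max(1, math.ceil(0.5 * carriers)))
        if len(strong) < required:
            continue

        kept_genomes = set(strong)
        for g in weak_only:
            if not weak_needs_support or strong - {g}:
                kept_genomes.add(g)
        kept = {g: list(per_genome[g]) for g in sorted(kept_genomes)}
        accepted.append(RegulonMember(member_id, kept, len(kept)))
    return accepted


def call_core(members: Sequence[RegulonMember],
              core_min: int = DEFAULT_CORE_MIN) -> dict[str, list[str]]:
    """Partition members into core / group-specific / genome-specific.

    Core = site conserved in at least ``core_min`` genomes.  The labels are
    written onto the members and the partition returned by class.
    """
    partition: dict[str, list[str]] = {
        "core": [], "group-specific": [], "genome-specific": []}
    for m in members:
        if m.genome_specific:
            m.conservation_class = "genome-specific"
        elif m.conservation_count >= core_min:
            m.conservation_class = "core"
        else:
            m.conservation_class = "group-specific"
        partition[m.conservation_class].append(m.member_id)
    return partition


# ---------------------------------------------------------------------------
# local-regulator discovery by chromosomal co-localization


@dataclass(frozen=True)
class LocalTFCandidate:
    genome_id: str
    gene_id: str
    tf_family: str
    role: str
    operon_id: str
    nearby_pathway_genes: tuple[str, ...]


def local_tf_discovery(genomes: Sequence[Genome],
                       operons_by_genome: Mapping[str, Sequence[Operon]],
                       max_operon_distance: int = 2
                       ) -> list[LocalTFCandidate]:
    """Find TF-family genes co-localized with arabinose/AOS pathway genes.

    Local regulators of sugar catabolism usually sit next to the genes they
    control; a gene with a TF-family role within ``max_operon_distance``
    operons of any pathway-role gene (on the same contig) is reported.
    """
    pathway_roles = ROLES - set(TF_ROLES)
    out: list[LocalTFCandidate] = []
    for genome in genomes:
        operons = list(operons_by_genome[genome.genome_id])
        by_contig: dict[str, list[Operon]] = {}
        for op in operons:
            by_contig.setdefault(op.leader.contig_id, []).append(op)
        for contig_ops in by_contig.values():
            contig_ops.sort(key=lambda op: min(g.start for g in op))
            pathway_idx = [i for i, op in enumerate(contig_ops)
                           if any(g.role in pathway_roles for g in op)]
            for i, op in enumerate(contig_ops):
                for gene in op:
                    fam = TF_ROLES.get(gene.role or "")
                    if fam is None:
                        continue
                    near = [j for j in pathway_idx
                            if abs(j - i) <= max_operon_distance]
                    if not near:
                        continue
                    nearby = tuple(
                        g.gene_id for j in near for g in contig_ops[j]
                        if g.role in pathway_roles)
                    out.append(LocalTFCandidate(
                        genome.genome_id, gene.gene_id, fam, gene.role,
                        op.operon_id, nearby))
    out.sort(key=lambda c: (c.genome_id, c.gene_id))
    return out


# ---------------------------------------------------------------------------
# report


def write_regulon_tsv(regulon: Regulon, path) -> None:
    """Regulon inventory: one row per member, with conservation and mode."""
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["tf_name", "member", "n_genomes_with_site",
                    "class", "mode", "genomes"])
        for m in regulon.members:
            w.writerow([regulon.tf_name, m.member_id, m.conservation_count,
                        m.conservation_class or "", m.mode,
                        ",".join(m.genomes())])
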