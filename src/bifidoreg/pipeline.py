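"""End-to-end orchestration: load -> orthologs -> motif -> scan -> infer ->
mode -> phenotype, with reproducible, manifest-stamped outputs.

Two entry paths mirror the two regulon-reconstruction situations: a
*known-TF* run starts from a training set of binding sites and builds the
weight matrix directly; a *novel-TF* run first finds candidate local
regulators by chromosomal co-localization with pathway genes, then
discovers a palindromic motif de novo in the upstream regions of their
neighborhoods.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

from bifidoreg import genome_io, motif_core, orthology, promoter_mode, \
    regulon_inference, site_scan, subsystem_phenotype

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """All tunables of a run; round-trips losslessly through JSON."""

    window: tuple[int, int] = (-350, 50)
    operon_max_gap: int = 150
    min_identity: float = 30.0
    min_coverage: float = 70.0
    synteny_window: int = 5
    motif_length: int = 16
    scan_lengths: tuple[int, ...] = ()   # non-empty: pick best IC/column
    n_restarts: int = 20
    strong_fraction: float = 1.0
    weak_ratio: float = 0.95
    min_genomes: int = 3
    core_min: int = 20
    max_operon_distance: int = 2
    tf_role: str = "araQ"
    seed: int = 0

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        d = json.loads(text)
        d["window"] = tuple(d["window"])
        d["scan_lengths"] = tuple(d["scan_lengths"])
        return cls(**d)

    @property
    def config_hash(self) -> str:
        return hashlib.sha256(self.to_json().encode()).hexdigest()[:12]


@dataclass
class RunResult:
    config: PipelineConfig
    ortholog_groups: list[orthology.OrthologGroup]
    motif: motif_core.MotifModel
    hits: dict[str, list[site_scan.SiteHit]]
    members: list[regulon_inference.RegulonMember]
    partition: dict[str, list[str]]
    phenotypes: list[subsystem_phenotype.PhenotypeCall]

    def regulon_matrix(self) -> dict[str, set[str]]:
        """member id -> genomes with an accepted site."""
        return {m.member_id: set(m.genome_hits) for m in self.members}

    def write(self, outdir: str | Path) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        stamp = self.config.config_hash
        orthology.write_ortholog_table(
            self.ortholog_groups, outdir / f"orthologs.{stamp}.tsv")
        motif_core.write_transfac(self.motif,
                                  outdir / f"motif.{stamp}.txt")
        all_hits = [h for hits in self.hits.values() for h in hits]
        site_scan.write_hits_tsv(all_hits, outdir / f"sites.{stamp}.tsv")
        site_scan.write_hits_gff3(all_hits, outdir / f"sites.{stamp}.gff3")
        regulon = regulon_inference.Regulon(self.motif.name, None,
                                            self.members)
        regulon_inference.write_regulon_tsv(
            regulon, outdir / f"regulon.{stamp}.tsv")
        subsystem_phenotype.write_phenotype_tsv(
            self.phenotypes, outdir / f"phenotypes.{stamp}.tsv")
        manifest = {
            "config": json.loads(self.config.to_json()),
            "config_hash": stamp,
            "seed": self.config.seed,
            "n_genomes": len(self.hits),
            "motif_consensus": self.motif.consensus,
        }
        with open(outdir / f"manifest.{stamp}.json", "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")


class StageError(RuntimeError):
    """A pipeline stage failed; the stage name is in the message."""


def _stage(name: str):
    def deco(fn):
        def wrapper(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:
                raise StageError(f"stage {name!r} failed: {exc}") from exc
            logger.info("stage %s done in %.2fs", name,
                        time.perf_counter() - t0)
            return out
        return wrapper
    return deco


def find_tf_group(groups: Sequence[orthology.OrthologGroup],
                  genomes: Sequence[genome_io.Genome],
                  tf_role: str) -> orthology.OrthologGroup:
    """The ortholog group whose members carry the TF role annotation."""
    tf_genes = {(g.genome_id, gene.gene_id)
                for g in genomes for gene in g.genes
                if gene.role == tf_role}
    best = None
    for grp in groups:
        overlap = sum((gid, gene) in tf_genes
                      for gid, gene in grp.members.items())
        if overlap and (best is None or overlap > best[0]):
            best = (overlap, grp)
    if best is None:
        raise StageError(f"no ortholog group carries TF role {tf_role!r}")
    return best[1]


def candidate_regions_from_neighborhoods(
        genomes: Sequence[genome_io.Genome],
        operons_by_genome: Mapping[str, Sequence[genome_io.Operon]],
        config: PipelineConfig) -> list[genome_io.UpstreamRegion]:
    """Upstream regions feeding novel-TF motif discovery: the windows of
    every operon leader within ``max_operon_distance`` operons of a
    candidate local regulator carrying the configured TF role."""
    cands = [c for c in regulon_inference.local_tf_discovery(
        genomes, operons_by_genome, config.max_operon_distance)
        if c.role == config.tf_role]
    regions: list[genome_io.UpstreamRegion] = []
    seen: set[tuple[str, str]] = set()
    by_genome: dict[str, list[regulon_inference.LocalTFCandidate]] = {}
    for c in cands:
        by_genome.setdefault(c.genome_id, []).append(c)
    for genome in genomes:
        ops = list(operons_by_genome[genome.genome_id])
        tf_op_ids = {c.operon_id for c in by_genome.get(genome.genome_id, [])}
        if not tf_op_ids:
            continue
        idx_of = {op.operon_id: i for i, op in enumerate(ops)}
        for op_id in tf_op_ids:
            i = idx_of[op_id]
            lo = max(0, i - config.max_operon_distance)
            hi = min(len(ops), i + config.max_operon_distance + 1)
            for op in ops[lo:hi]:
                key = (genome.genome_id, op.leader.gene_id)
                if key in seen:
                    continue
                seen.add(key)
                try:
                    regions.append(genome_io.extract_upstream(
                        genome, op.leader, config.window))
                except genome_io.EmptyRegionError:
                    continue
    return regions


def run_all(genomes: Sequence[genome_io.Genome],
            config: PipelineConfig,
            training_sites: motif_core.SiteAlignment | None = None,
            ortholog_groups: Sequence[orthology.OrthologGroup] | None = None,
            motif_name: str = "TF") -> RunResult:
    """Execute the full reconstruction over a set of genomes.

    With ``training_sites`` the known-TF path builds the matrix from them;
    otherwise the novel-TF path discovers the motif in co-localized
    neighborhoods.  ``ortholog_groups`` may be precomputed (e.g., from a
    table) to skip the similarity stage.
    """
    operons_by_genome = {
        g.genome_id: genome_io.group_operons(g, config.operon_max_gap)
        for g in genomes}

    if ortholog_groups is None:
        ortholog_groups = _stage("orthology")(
            orthology.infer_ortholog_groups)(
                genomes, config.min_identity, config.min_coverage,
                config.synteny_window)

    tf_group = find_tf_group(ortholog_groups, genomes, config.tf_role)

    if training_sites is not None:
        motif = motif_core.from_sites(motif_name, training_sites)
        motif_core.calibrate_thresholds(motif, config.strong_fraction,
                                        config.weak_ratio)
    else:
        regions = candidate_regions_from_neighborhoods(
            genomes, operons_by_genome, config)
        discover = _stage("motif-discovery")(
            motif_core.discover_palindromic_motif
            if not config.scan_lengths else motif_core.discover_best_length)
        if config.scan_lengths:
            motif = discover(regions, config.scan_lengths,
                             n_restarts=config.n_restarts,
                             seed=config.seed, name=motif_name)
        else:
            motif = discover(regions, config.motif_length,
                             n_restarts=config.n_restarts,
                             seed=config.seed, name=motif_name)
        motif_core.calibrate_thresholds(motif, config.strong_fraction,
                                        config.weak_ratio)

    candidates = _stage("propagate")(regulon_inference.propagate)(
        tf_group, motif, genomes, operons_by_genome, ortholog_groups,
        config.window)
    members = _stage("consistency-filter")(
        regulon_inference.consistency_filter)(
            candidates, set(tf_group.members), ortholog_groups,
            config.min_genomes)
    partition = regulon_inference.call_core(members, config.core_min)

    _classify_member_modes(members, genomes, operons_by_genome, config)

    hits = {g.genome_id: [] for g in genomes}
    for m in members:
        for gid, hlist in m.genome_hits.items():
            hits[gid].extend(hlist)

    table = subsystem_phenotype.populate_subsystem(genomes)
    phenotypes = subsystem_phenotype.assign_all(table)

    return RunResult(config, list(ortholog_groups), motif, hits, members,
                     partition, phenotypes)


def _classify_member_modes(members, genomes, operons_by_genome,
                           config) -> None:
    """Majority-vote regulatory mode per member across its genomes."""
    genome_by_id = {g.genome_id: g for g in genomes}
    for m in members:
        votes: list[str] = []
        for gid, hlist in m.genome_hits.items():
            genome = genome_by_id[gid]
            for h in hlist:
                try:
                    region = genome_io.extract_upstream(
                        genome, genome.gene(h.target_gene_id), config.window)
                except (KeyError, genome_io.EmptyRegionError):
                    continue
                promoter = promoter_mode.find_promoter(region)
                votes.append(promoter_mode.classify_mode(h, promoter, region))
        informative = [v for v in votes if v != promoter_mode.UNDETERMINED]
        if not informative:
            m.mode = promoter_mode.UNDETERMINED
        else:
            m.mode = max(sorted(set(informative)), key=informative.count)
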