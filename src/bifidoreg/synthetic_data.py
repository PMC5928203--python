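"""Ground-truthed synthetic clades for end-to-end pipeline testing.

The generator emulates the statistical structure the regulon analysis
assumes: a clade of genomes sharing protein families (star topology, a
configurable substitution rate per branch), GC-biased intergenic background
(default 60%, the typical bifidobacterial genome composition), palindromic
TF-binding sites implanted in the -350..+50 upstream windows of designated
target families, optional exact-consensus -35/-10 promoter elements laid
out to make a site's regulatory mode unambiguous, and per-genome
arabinose/AOS role complements realizing requested utilization phenotypes.

Every implanted feature is recorded in a :class:`GroundTruth` so consuming
tests measure recovery against construction rather than against the
pipeline itself.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from bifidoreg.genome_io import Gene, Genome, reverse_complement
from bifidoreg.promoter_mode import (MINUS10_CONSENSUS, MINUS35_CONSENSUS)
from bifidoreg.subsystem_phenotype import ROLES

# one codon per amino acid (bacterial table 11 compatible)
_CODON = {
    "A": "GCT", "C": "TGC", "D": "GAC", "E": "GAA", "F": "TTC", "G": "GGC",
    "H": "CAC", "I": "ATC", "K": "AAA", "L": "CTG", "M": "ATG", "N": "AAC",
    "P": "CCG", "Q": "CAG", "R": "CGC", "S": "TCT", "T": "ACC", "V": "GTG",
    "W": "TGG", "Y": "TAC",
}
_AA = "".join(sorted(_CODON))
_STOP = "TAA"

DEFAULT_CONSENSUS = "ATGTTAGCGCTAACAT"   # 16-bp exact palindrome

# fixed promoter geometry used by the activator/repressor layouts,
# offsets relative to the start codon (element start)
MINUS10_OFFSET = -45
MINUS35_OFFSET = -68          # 17-bp spacer between the hexamers
# the repressor-layout site sits entirely downstream of the -10 element
# (one of the geometries the mode rule calls repression); placing it there
# keeps both the site and the promoter hexamers intact in the sequence
REPRESSOR_SITE_OFFSET = -30
ACTIVATOR_SITE_OFFSET = -120  # ends upstream of the -35 element for L <= 52

PHENOTYPE_WITNESS_ROLES: dict[str, frozenset[str]] = {
    "U1": frozenset({"araB", "araD", "araA", "araE"}),
    "U2": frozenset({"araB", "araD", "araA", "aauA", "aauB", "aauC",
                     "abfII_1"}),
    "U3": frozenset({"araB", "araD", "araA", "bauT", "hypBA1"}),
    "U123": frozenset({"araB", "araD", "araA", "araE", "aauA", "aauB",
                       "aauC", "abfII_1", "bauT", "hypBA1"}),
    "0": frozenset(),
    "unique": frozenset({"araB", "araD", "araA"}),
}


def assign_truth_phenotypes(label: str) -> frozenset[str]:
    """Minimal role complement realizing a requested phenotype label.

    The witness sets invert the phenotype rules: running the phenotype
    caller on the returned roles reproduces exactly ``label``.
    """
    try:
        return PHENOTYPE_WITNESS_ROLES[label]
    except KeyError:
        raise ValueError(f"unknown phenotype label {label!r}; expected one "
                         f"of {sorted(PHENOTYPE_WITNESS_ROLES)}")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic clade; defaults give the standard
    benchmark clade (8 genomes, one TF, 4 universally targeted families)."""

    n_genomes: int = 8
    n_families: int = 8               # protein families besides the TF
    n_target_families: int = 4        # families carrying implanted sites
    protein_length: int = 120         # amino acids, incl. leading Met
    divergence: float = 0.05          # substitutions/site per star branch
    gc: float = 0.60                  # intergenic background G+C
    intergenic_len: int = 450         # >= window span upstream of each gene
    consensus: str = DEFAULT_CONSENSUS
    mismatch_prob: float = 0.0        # per-position site noise
    asymmetric_noise: bool = False    # skip re-palindromization of sites
    site_offset: int = ACTIVATOR_SITE_OFFSET  # site start vs start codon
    site_offset_jitter: int = 0       # uniform jitter, promoterless only
    design: np.ndarray | None = None  # target-family x genome presence
    layouts: dict[int, str] = field(default_factory=dict)  # fam -> layout
    tf_present: list[bool] | None = None
    tf_role: str | None = "araQ"
    phenotypes: list[str] | None = None
    divergent_pair: bool = False      # add an araU/araFGH-style pair
    seed: int = 0

    def __post_init__(self) -> None:
        L = len(self.consensus)
        if L % 2 != 0 or self.consensus != reverse_complement(self.consensus):
            raise ValueError("consensus must be an even-length palindrome")
        if not 0.0 <= self.mismatch_prob < 0.5:
            raise ValueError("mismatch_prob must be in [0, 0.5)")
        if self.design is not None:
            self.design = np.asarray(self.design, dtype=bool)
            if self.design.shape != (self.n_target_families, self.n_genomes):
                raise ValueError(
                    f"design matrix shape {self.design.shape} != "
                    f"({self.n_target_families}, {self.n_genomes})")
        for fam, layout in self.layouts.items():
            if layout not in {"activator", "repressor", "none"}:
                raise ValueError(f"unknown layout {layout!r}")
            if fam >= self.n_target_families:
                raise ValueError(f"layout for non-target family {fam}")
        if self.site_offset < -350 or self.site_offset + L > 50:
            raise ValueError("site does not fit the -350..+50 window")
        if self.intergenic_len < 350 + 30:
            raise ValueError("intergenic_len too short for the upstream "
                             "window plus margins")
        if self.phenotypes is not None:
            if len(self.phenotypes) != self.n_genomes:
                raise ValueError("one phenotype label per genome required")
            for lab in self.phenotypes:
                assign_truth_phenotypes(lab)
        if self.tf_present is not None \
                and len(self.tf_present) != self.n_genomes:
            raise ValueError("tf_present must have one flag per genome")

    def effective_design(self) -> np.ndarray:
        if self.design is not None:
            return self.design
        return np.ones((self.n_target_families, self.n_genomes), dtype=bool)

    def layout_of(self, fam: int) -> str:
        return self.layouts.get(fam, "none")


@dataclass(frozen=True)
class TruthSite:
    genome_id: str
    gene_id: str                 # target gene (operon leader)
    contig_id: str
    abs_start: int               # forward-strand genome coordinate
    offset_vs_start_codon: int
    sequence: str
    family: str


@dataclass(frozen=True)
class TruthPromoter:
    genome_id: str
    gene_id: str
    minus35_offset: int          # vs start codon
    minus10_offset: int
    layout: str                  # activator | repressor
    true_mode: str               # activator | repressor


@dataclass
class GroundTruth:
    consensus: str
    sites: list[TruthSite] = field(default_factory=list)
    promoters: list[TruthPromoter] = field(default_factory=list)
    families: dict[tuple[str, str], str] = field(default_factory=dict)
    modes: dict[str, str] = field(default_factory=dict)   # family -> mode
    phenotypes: dict[str, str] = field(default_factory=dict)
    design: dict[tuple[str, str], bool] = field(default_factory=dict)

    def regulon_matrix(self) -> dict[str, set[str]]:
        """family -> set of genomes with an implanted site."""
        out: dict[str, set[str]] = {}
        for s in self.sites:
            out.setdefault(s.family, set()).add(s.genome_id)
        return out


@dataclass
class Clade:
    config: SimulationConfig
    genomes: list[Genome]
    truth: GroundTruth

    def write(self, outdir: str | Path) -> None:
        write_clade(self, outdir)


# ---------------------------------------------------------------------------
# sequence-level helpers


def random_background(length: int, gc: float,
                      rng: np.random.Generator) -> str:
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(rng.choice(list("ACGT"), size=length, p=p))


def mutate_site(consensus: str, mismatch_prob: float,
                rng: np.random.Generator,
                asymmetric: bool = False) -> str:
    """Draw a site: per position the consensus base w.p. 1-p, else a
    uniform other base; then mirror the first half onto the second so the
    emitted site stays self-complementary (skipped when ``asymmetric``)."""
    bases = "ACGT"
    site = []
    for b in consensus:
        if rng.random() < mismatch_prob:
            site.append(rng.choice([x for x in bases if x != b]))
        else:
            site.append(b)
    if not asymmetric:
        L = len(site)
        comp = {"A": "T", "C": "G", "G": "C", "T": "A"}
        for j in range(L // 2):
            site[L - 1 - j] = comp[site[j]]
    return "".join(site)


def implant_site(region: str, consensus: str, mismatch_prob: float,
                 position: int, rng: np.random.Generator,
                 asymmetric: bool = False) -> tuple[str, str]:
    """Place a (noisy) copy of ``consensus`` at ``position`` in ``region``.

    Returns (mutated region, the implanted site sequence).  ``position`` is
    an index into the region and must keep the site inside it.
    """
    L = len(consensus)
    if position < 0 or position + L > len(region):
        raise ValueError(f"site position {position} outside region of "
                         f"length {len(region)}")
    site = mutate_site(consensus, mismatch_prob, rng, asymmetric)
    return region[:position] + site + region[position + L:], site


def mutate_protein(ancestor: str, divergence: float,
                   rng: np.random.Generator) -> str:
    """Substitute each position (except the initiator Met) w.p.
    ``divergence`` with a uniformly chosen different residue."""
    out = [ancestor[0]]
    for aa in ancestor[1:]:
        if rng.random() < divergence:
            out.append(rng.choice([x for x in _AA if x != aa]))
        else:
            out.append(aa)
    return "".join(out)


def reverse_translate(protein: str) -> str:
    return "".join(_CODON[aa] for aa in protein) + _STOP


# ---------------------------------------------------------------------------
# clade generation


def _random_protein(length: int, rng: np.random.Generator) -> str:
    return "M" + "".join(rng.choice(list(_AA), size=length - 1))


def generate_clade(config: SimulationConfig) -> Clade:
    """Build the clade described by ``config``; deterministic given seed."""
    rng = np.random.default_rng(config.seed)
    L = len(config.consensus)
    design = config.effective_design()
    tf_present = config.tf_present or [True] * config.n_genomes

    fam_ancestors = [_random_protein(config.protein_length, rng)
                     for _ in range(config.n_families)]
    tf_ancestor = _random_protein(config.protein_length, rng)
    role_ancestors = {role: _random_protein(80, rng)
                      for role in sorted(ROLES)}
    div_ancestors = (_random_protein(80, rng), _random_protein(80, rng))
    pheno_labels = config.phenotypes or ["U1"] * config.n_genomes

    truth = GroundTruth(consensus=config.consensus)
    genomes: list[Genome] = []
    for gi in range(config.n_genomes):
        genome_id = f"G{gi:02d}"
        contig_id = f"{genome_id}_c1"
        parts: list[str] = []
        genes: list[Gene] = []
        pos = 0

        def _emit_gene(gene_id: str, protein: str, role: str | None,
                       family: str, target_fam: int | None = None,
                       layout: str = "none") -> None:
            nonlocal pos
            ig = random_background(config.intergenic_len, config.gc, rng)
            site_rec = None
            if target_fam is not None:
                offset = {"activator": ACTIVATOR_SITE_OFFSET,
                          "repressor": REPRESSOR_SITE_OFFSET,
                          "none": config.site_offset}[layout]
                if layout == "none" and config.site_offset_jitter:
                    j = int(rng.integers(-config.site_offset_jitter,
                                         config.site_offset_jitter + 1))
                    offset = int(np.clip(offset + j, -350, 50 - L))
                idx = len(ig) + offset
                ig, site = implant_site(ig, config.consensus,
                                        config.mismatch_prob, idx, rng,
                                        config.asymmetric_noise)
                site_rec = (idx, offset, site)
                if layout in {"activator", "repressor"}:
                    m35 = len(ig) + MINUS35_OFFSET
                    m10 = len(ig) + MINUS10_OFFSET
                    ig = (ig[:m35] + MINUS35_CONSENSUS + ig[m35 + 6:m10]
                          + MINUS10_CONSENSUS + ig[m10 + 6:])
                    truth.promoters.append(TruthPromoter(
                        genome_id, gene_id, MINUS35_OFFSET, MINUS10_OFFSET,
                        layout, layout))
            parts.append(ig)
            pos += len(ig)
            if site_rec is not None:
                idx, offset, site = site_rec
                truth.sites.append(TruthSite(
                    genome_id, gene_id, contig_id,
                    pos - len(ig) + idx, offset, site, family))
            dna = reverse_translate(protein)
            genes.append(Gene(gene_id, contig_id, pos, pos + len(dna), "+",
                              protein_seq=protein, role=role))
            parts.append(dna)
            pos += len(dna)
            truth.families[(genome_id, gene_id)] = family

        # phenotype witness genes
        label = pheno_labels[gi]
        truth.phenotypes[genome_id] = label
        for role in sorted(assign_truth_phenotypes(label)):
            _emit_gene(f"{genome_id}_{role}",
                       mutate_protein(role_ancestors[role],
                                      config.divergence, rng),
                       role, f"role:{role}")

        # the TF gene
        if tf_present[gi]:
            _emit_gene(f"{genome_id}_tf",
                       mutate_protein(tf_ancestor, config.divergence, rng),
                       config.tf_role, "tf")

        # target and filler families
        for fam in range(config.n_families):
            fam_name = f"fam{fam}"
            is_target = fam < config.n_target_families
            targeted = bool(is_target and tf_present[gi]
                            and design[fam, gi])
            layout = config.layout_of(fam) if is_target else "none"
            _emit_gene(f"{genome_id}_f{fam}",
                       mutate_protein(fam_ancestors[fam],
                                      config.divergence, rng),
                       None, fam_name,
                       target_fam=fam if targeted else None,
                       layout=layout)
            if is_target:
                truth.design[(fam_name, genome_id)] = targeted
                truth.modes[fam_name] = {"activator": "activator",
                                         "repressor": "repressor",
                                         "none": "ND"}[layout]

        if config.divergent_pair and tf_present[gi]:
            _emit_divergent_pair(config, rng, genome_id, contig_id,
                                 parts, genes, truth, div_ancestors,
                                 pos_ref=[pos])
            pos = genes[-1].end

        parts.append(random_background(120, config.gc, rng))
        genomes.append(Genome(genome_id, {contig_id: "".join(parts)}, genes))

    return Clade(config, genomes, truth)


def _emit_divergent_pair(config: SimulationConfig, rng: np.random.Generator,
                         genome_id: str, contig_id: str, parts: list[str],
                         genes: list[Gene], truth: GroundTruth,
                         ancestors: tuple[str, str],
                         pos_ref: list[int]) -> None:
    """Append a head-to-head gene pair sharing one intergenic region with a
    single site in the middle of the shared window (the araU/araFGH
    arrangement: a divergently transcribed regulator/transporter pair whose
    common upstream region carries the operator)."""
    pos = pos_ref[0]
    L = len(config.consensus)
    prot_a = mutate_protein(ancestors[0], config.divergence, rng)
    prot_b = mutate_protein(ancestors[1], config.divergence, rng)
    dna_a = reverse_complement(reverse_translate(prot_a))  # minus strand
    gene_a = Gene(f"{genome_id}_divA", contig_id, pos, pos + len(dna_a),
                  "-", protein_seq=prot_a, role="araU")
    parts.append(dna_a)
    pos += len(dna_a)

    ig = random_background(config.intergenic_len, config.gc, rng)
    mid = len(ig) // 2
    ig, site = implant_site(ig, config.consensus, config.mismatch_prob,
                            mid, rng, config.asymmetric_noise)
    parts.append(ig)
    site_abs = pos + mid
    pos += len(ig)

    dna_b = reverse_translate(prot_b)
    gene_b = Gene(f"{genome_id}_divB", contig_id, pos, pos + len(dna_b),
                  "+", protein_seq=prot_b, role="araF")
    parts.append(dna_b)
    pos += len(dna_b)

    genes.extend([gene_a, gene_b])
    truth.families[(genome_id, gene_a.gene_id)] = "divA"
    truth.families[(genome_id, gene_b.gene_id)] = "divB"
    truth.sites.append(TruthSite(
        genome_id, gene_a.gene_id, contig_id, site_abs,
        gene_a.end - site_abs - L, site, "divA"))
    truth.sites.append(TruthSite(
        genome_id, gene_b.gene_id, contig_id, site_abs,
        site_abs - gene_b.start, site, "divB"))
    pos_ref[0] = pos


# ---------------------------------------------------------------------------
# file emission


def write_clade(clade: Clade, outdir: str | Path) -> None:
    """Emit FASTA+GFF3 per genome, truth TSVs, and a config manifest."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for genome in clade.genomes:
        with open(outdir / f"{genome.genome_id}.fna", "w") as fh:
            for cid, seq in genome.contigs.items():
                fh.write(f">{cid}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i:i + 60] + "\n")
        with open(outdir / f"{genome.genome_id}.gff3", "w") as fh:
            fh.write("##gff-version 3\n")
            for g in genome.genes:
                attrs = f"ID={g.gene_id};locus_tag={g.gene_id}"
                if g.role:
                    attrs += f";role={g.role}"
                fh.write("\t".join([
                    g.contig_id, "bifidoreg_sim", "CDS",
                    str(g.start + 1), str(g.end), ".", g.strand, "0",
                    attrs]) + "\n")

    t = clade.truth
    with open(outdir / "truth_sites.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tcontig\tabs_start\t"
                 "offset_vs_start_codon\tsequence\tfamily\n")
        for s in t.sites:
            fh.write(f"{s.genome_id}\t{s.gene_id}\t{s.contig_id}\t"
                     f"{s.abs_start}\t{s.offset_vs_start_codon}\t"
                     f"{s.sequence}\t{s.family}\n")
    with open(outdir / "truth_families.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tfamily\n")
        for (gid, gene), fam in sorted(t.families.items()):
            fh.write(f"{gid}\t{gene}\t{fam}\n")
    with open(outdir / "truth_regulon.tsv", "w") as fh:
        fh.write("family\tgenome_id\tsite_present\n")
        for (fam, gid), present in sorted(t.design.items()):
            fh.write(f"{fam}\t{gid}\t{int(present)}\n")
    with open(outdir / "truth_promoters.tsv", "w") as fh:
        fh.write("genome_id\tgene_id\tminus35_offset\tminus10_offset\t"
                 "layout\ttrue_mode\n")
        for p in t.promoters:
            fh.write(f"{p.genome_id}\t{p.gene_id}\t{p.minus35_offset}\t"
                     f"{p.minus10_offset}\t{p.layout}\t{p.true_mode}\n")
    with open(outdir / "truth_phenotypes.tsv", "w") as fh:
        fh.write("genome_id\tphenotype\n")
        for gid, lab in sorted(t.phenotypes.items()):
            fh.write(f"{gid}\t{lab}\n")

    cfg = dataclasses.asdict(clade.config)
    if cfg["design"] is not None:
        cfg["design"] = np.asarray(cfg["design"]).astype(int).tolist()
    with open(outdir / "manifest.json", "w") as fh:
        json.dump({"config": cfg, "seed": clade.config.seed}, fh, indent=2,
                  sort_keys=True)
        fh.write("\n")
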