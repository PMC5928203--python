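"""The arabinose/AOS functional-role subsystem and phenotype assignment.

Utilization capability labels per genome:

U1  — arabinose monosaccharide: the araBDA catabolic operon (ribulokinase,
      L-ribulose-5-P 4-epimerase, L-arabinose isomerase) plus an arabinose
      transporter (araE permease, or the complete araFGH ABC system).
U2  — alpha-arabino-oligosaccharides: araBDA plus an alpha-AOS uptake system
      (complete AraNtPtQt or AauABC ABC systems, or the AbfT1/AbfT2/XsaT
      permeases) plus at least one intracellular alpha-L-arabinofuranosidase.
U3  — beta-arabino-oligosaccharides: araBDA plus beta-AOS uptake (complete
      BauABC or the BauT permease) plus the beta-L-arabinofuranosidase
      HypBA1.
0   — none of the above and araBDA absent.
unique — araBDA present but no known arabinose/AOS transporter at all
      (arabinose may still arrive through an unrecognized route).

An advisory flag "AXOS-route" marks genomes where araBDA plus the XosABC
transporter plus AbfA/XynB suggest arabinose salvage from
arabinoxylo-oligosaccharides; it is a hypothesis, not a U-label.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from bifidoreg.genome_io import Genome

ROLES: frozenset[str] = frozenset({
    # catabolic core and regulators
    "araA", "araB", "araD", "araE", "araF", "araG", "araH", "araQ", "araU",
    "abfR", "aauR", "aauU1", "aauU2", "bauR1", "bauR2", "xsaR",
    # arabinofuranosidases / arabinanases
    "abfB2", "afuB-H1", "abfII_1", "abfII_2", "abnA1", "abnA2", "abfC",
    "abfBad", "abfA", "axh-d3", "abfA2", "axh-m23", "abfE1", "abfE2",
    "abfB", "xsa", "hypBA1", "hypBA2",
    # transporters
    "araNt", "araPt", "araQt", "aauA", "aauB", "aauC", "abfT1", "abfT2",
    "xsaT", "bauA", "bauB", "bauC", "bauT", "xosABC",
    # xylosidase of the AXOS route
    "xynB",
})

TF_ROLES: dict[str, str] = {
    "araQ": "LacI", "araU": "ROK", "abfR": "LacI", "aauR": "LacI",
    "aauU1": "LacI", "aauU2": "LacI", "bauR1": "LacI", "bauR2": "LacI",
    "xsaR": "TetR",
}

#: multi-subunit transporters: all subunits required for a working system
TRANSPORTER_COMPLEXES: dict[str, frozenset[str]] = {
    "araFGH": frozenset({"araF", "araG", "araH"}),
    "araNtPtQt": frozenset({"araNt", "araPt", "araQt"}),
    "aauABC": frozenset({"aauA", "aauB", "aauC"}),
    "bauABC": frozenset({"bauA", "bauB", "bauC"}),
}

#: intracellular alpha-L-arabinofuranosidases that can digest imported
#: alpha-AOS (localization per the input annotation)
INTRACELLULAR_ALPHA_ABF: frozenset[str] = frozenset({
    "abfB2", "afuB-H1", "abfII_1", "abfII_2", "abfC", "abfBad", "abfB",
    "xsa",
})

ALL_TRANSPORTER_ROLES: frozenset[str] = frozenset({
    "araE", "araF", "araG", "araH", "araNt", "araPt", "araQt",
    "aauA", "aauB", "aauC", "abfT1", "abfT2", "xsaT",
    "bauA", "bauB", "bauC", "bauT", "xosABC",
})


class UnknownRoleError(ValueError):
    """A role label outside the subsystem vocabulary."""


class ConflictingRoleError(ValueError):
    """One gene mapped to more than one role."""


@dataclass
class SubsystemTable:
    """Genome x role presence matrix with the supporting gene per cell."""

    cells: dict[str, dict[str, list[str]]] = field(default_factory=dict)

    def add(self, genome_id: str, role: str, gene_id: str) -> None:
        if role not in ROLES:
            raise UnknownRoleError(f"unknown role {role!r} "
                                   f"(gene {gene_id}, genome {genome_id})")
        self.cells.setdefault(genome_id, {}).setdefault(role, [])
        if gene_id not in self.cells[genome_id][role]:
            self.cells[genome_id][role].append(gene_id)

    def roles_of(self, genome_id: str) -> frozenset[str]:
        return frozenset(self.cells.get(genome_id, {}))

    def genomes(self) -> list[str]:
        return sorted(self.cells)

    def complete(self, genome_id: str, complex_name: str,
                 completeness: float = 1.0) -> bool:
        """Is a multi-subunit transporter usable?  By default every subunit
        is required; ``completeness`` relaxes that to a fraction."""
        subunits = TRANSPORTER_COMPLEXES[complex_name]
        present = len(subunits & self.roles_of(genome_id))
        return present >= completeness * len(subunits)


@dataclass(frozen=True)
class PhenotypeCall:
    """Per-genome utilization phenotype with the evidence behind it."""

    genome_id: str
    labels: frozenset[str]           # subset of {"U1","U2","U3"}
    composite: str                   # "U1".."U123", "0" or "unique"
    evidence: Mapping[str, frozenset[str]] = field(default_factory=dict)
    flags: frozenset[str] = frozenset()


def populate_subsystem(genomes: Sequence[Genome],
                       annotations: Mapping[tuple[str, str], str] | None
                       = None) -> SubsystemTable:
    """Build the presence matrix from gene role labels.

    ``annotations`` maps (genome_id, gene_id) to a role and overrides the
    in-genome labels; a gene carrying two different roles is a conflict and
    raises, listing the offenders.
    """
    table = SubsystemTable()
    conflicts: list[str] = []
    for genome in genomes:
        for gene in genome.genes:
            role = gene.role
            override = None
            if annotations:
                override = annotations.get((genome.genome_id, gene.gene_id))
            if role and override and role != override:
                conflicts.append(f"{genome.genome_id}:{gene.gene_id} "
                                 f"({role!r} vs {override!r})")
                continue
            final = override or role
            if final:
                table.add(genome.genome_id, final, gene.gene_id)
    if conflicts:
        raise ConflictingRoleError(
            "conflicting role assignments: " + "; ".join(conflicts))
    return table


def assign_phenotype(table: SubsystemTable, genome_id: str,
                     completeness: float = 1.0) -> PhenotypeCall:
    """Phenotype from one genome's role complement (a pure function)."""
    roles = table.roles_of(genome_id)
    ara_bda = {"araA", "araB", "araD"} <= roles
    labels: set[str] = set()
    evidence: dict[str, frozenset[str]] = {}

    if ara_bda:
        if "araE" in roles or table.complete(genome_id, "araFGH",
                                             completeness):
            labels.add("U1")
            evidence["U1"] = frozenset({"araA", "araB", "araD"} | (
                {"araE"} if "araE" in roles
                else TRANSPORTER_COMPLEXES["araFGH"]))
        alpha_uptake = (
            table.complete(genome_id, "araNtPtQt", completeness)
            or table.complete(genome_id, "aauABC", completeness)
            or bool({"abfT1", "abfT2", "xsaT"} & roles))
        alpha_gh = INTRACELLULAR_ALPHA_ABF & roles
        if alpha_uptake and alpha_gh:
            labels.add("U2")
            evidence["U2"] = frozenset({"araA", "araB", "araD"} | alpha_gh)
        beta_uptake = (table.complete(genome_id, "bauABC", completeness)
                       or "bauT" in roles)
        if beta_uptake and "hypBA1" in roles:
            labels.add("U3")
            evidence["U3"] = frozenset({"araA", "araB", "araD", "hypBA1"})

    flags: set[str] = set()
    if ara_bda and "xosABC" in roles and {"abfA", "xynB"} & roles:
        flags.add("AXOS-route")

    if labels:
        composite = "U" + "".join(sorted(lab[1] for lab in labels))
    elif ara_bda and not (ALL_TRANSPORTER_ROLES & roles):
        composite = "unique"
    else:
        composite = "0"
    return PhenotypeCall(genome_id, frozenset(labels), composite,
                         evidence, frozenset(flags))


def assign_all(table: SubsystemTable,
               completeness: float = 1.0) -> list[PhenotypeCall]:
    return [assign_phenotype(table, g, completeness)
            for g in table.genomes()]


def concordance(calls: Iterable[PhenotypeCall],
                fermentation: Mapping[str, str]
                ) -> tuple[int, int, float]:
    """Agreement between predicted arabinose utilization (U1) and
    fermentation data ('+'/'-' per genome).

    Returns (n_match, n_total, fraction).  A genome matches when U1 was
    predicted and fermentation is '+', or U1 was not predicted and
    fermentation is '-'.
    """
    n_match = n_total = 0
    for call in calls:
        label = fermentation.get(call.genome_id)
        if label is None:
            continue
        if label not in {"+", "-"}:
            raise ValueError(f"fermentation label must be '+' or '-', "
                             f"got {label!r}")
        n_total += 1
        if ("U1" in call.labels) == (label == "+"):
            n_match += 1
    if n_total == 0:
        raise ValueError("no genomes shared between calls and "
                         "fermentation table")
    return n_match, n_total, n_match / n_total


# ---------------------------------------------------------------------------
# round-trippable tables


def write_subsystem_tsv(table: SubsystemTable, path) -> None:
    roles = sorted(ROLES)
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id"] + roles)
        for g in table.genomes():
            row = [g]
            for r in roles:
                genes = table.cells[g].get(r, [])
                row.append(",".join(genes) if genes else "0")
            w.writerow(row)


def read_subsystem_tsv(path) -> SubsystemTable:
    table = SubsystemTable()
    with open(path, newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader)
        roles = header[1:]
        for row in reader:
            g = row[0]
            table.cells.setdefault(g, {})
            for role, cell in zip(roles, row[1:]):
                if cell and cell != "0":
                    for gene in cell.split(","):
                        table.add(g, role, gene)
    return table


def write_phenotype_tsv(calls: Iterable[PhenotypeCall], path) -> None:
    with open(path, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "U1", "U2", "U3", "composite", "flags"])
        for c in calls:
            w.writerow([c.genome_id,
                        int("U1" in c.labels), int("U2" in c.labels),
                        int("U3" in c.labels), c.composite,
                        ",".join(sorted(c.flags))])
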