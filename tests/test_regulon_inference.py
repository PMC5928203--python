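"""Consistency filtering, core-regulon calls, and local-TF discovery."""

import pytest

from bifidoreg import genome_io as gio
from bifidoreg import regulon_inference as ri
from bifidoreg.genome_io import Gene, Genome
from bifidoreg.orthology import OrthologGroup
from bifidoreg.site_scan import SiteHit


def _hit(genome, gene, cls="strong", score=20.0):
    return SiteHit("TF", genome, gene, "c1", 100, ".", "ACGT" * 4, score,
                   cls, -120)


def _candidates(spec):
    """spec: {member: {genome: class}} -> propagate-style candidate table."""
    out = {}
    for member, per_genome in spec.items():
        out[member] = {g: [_hit(g, f"{g}_x", cls)]
                       for g, cls in per_genome.items()}
    return out


SIX = [f"G{i}" for i in range(6)]


def _groups(member_genomes):
    return [OrthologGroup(mid, {g: f"{g}_x" for g in gens})
            for mid, gens in member_genomes.items()]


class TestConsistencyFilter:
    def test_strong_in_all_six_accepted(self):
        cands = _candidates({"OG1": {g: "strong" for g in SIX}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}))
        assert len(members) == 1
        assert members[0].conservation_count == 6

    def test_single_weak_without_support_rejected(self):
        cands = _candidates({"OG1": {"G0": "weak"}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}))
        assert members == []

    def test_weak_with_two_strong_supporters_accepted(self):
        # hand-built truth table: weak in G0 + strong in G1, G2 (and G3)
        cands = _candidates({"OG1": {"G0": "weak", "G1": "strong",
                                     "G2": "strong", "G3": "strong"}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}))
        assert len(members) == 1
        assert members[0].conservation_count == 4
        assert "G0" in members[0].genome_hits

    def test_weak_support_disabled_counts_strong_only(self):
        cands = _candidates({"OG1": {"G0": "weak", "G1": "strong",
                                     "G2": "strong", "G3": "strong"}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}),
                                        weak_needs_support=False)
        assert members[0].conservation_count == 4

    def test_two_strong_below_min_genomes_rejected(self):
        cands = _candidates({"OG1": {"G0": "strong", "G1": "strong"}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}),
                                        min_genomes=3)
        assert members == []

    def test_rare_gene_fallback_half_of_carriers(self):
        # only 2 TF-carrying genomes have the gene; 1 strong = 50% passes
        groups = _groups({"OG1": ["G0", "G1"]})
        cands = _candidates({"OG1": {"G0": "strong"}})
        members = ri.consistency_filter(cands, SIX, groups, min_genomes=3)
        assert len(members) == 1

    def test_genome_specific_needs_strong(self):
        weak = _candidates({"specific:G0:G0_x": {"G0": "weak"}})
        strong = _candidates({"specific:G0:G0_x": {"G0": "strong"}})
        assert ri.consistency_filter(weak, SIX) == []
        members = ri.consistency_filter(strong, SIX)
        assert len(members) == 1
        assert members[0].genome_specific

    def test_monotone_in_min_genomes(self):
        cands = _candidates({
            "OG1": {g: "strong" for g in SIX},
            "OG2": {"G0": "strong", "G1": "strong", "G2": "strong"},
            "OG3": {"G0": "strong", "G1": "strong", "G2": "strong",
                    "G3": "strong"},
        })
        groups = _groups({k: SIX for k in ("OG1", "OG2", "OG3")})
        prev = None
        for k in (3, 4, 5, 6, 7):
            ids = {m.member_id
                   for m in ri.consistency_filter(cands, SIX, groups,
                                                  min_genomes=k)}
            if prev is not None:
                assert ids <= prev
            prev = ids

    def test_conservation_equals_acceptance_matrix_column_sum(self):
        cands = _candidates({"OG1": {"G0": "strong", "G1": "strong",
                                     "G2": "weak", "G3": "strong"}})
        members = ri.consistency_filter(cands, SIX, _groups({"OG1": SIX}))
        m = members[0]
        assert m.conservation_count == len(m.genome_hits)


class TestCallCore:
    def _member(self, n, specific=False):
        return ri.RegulonMember(f"m{n}", {f"G{i}": [] for i in range(n)},
                                n, genome_specific=specific)

    def test_conserved_24_is_core_at_20(self):
        m = self._member(24)
        part = ri.call_core([m], core_min=20)
        assert part["core"] == ["m24"]
        assert m.conservation_class == "core"

    def test_conserved_8_not_core(self):
        m = self._member(8)
        part = ri.call_core([m], core_min=20)
        assert part["core"] == []
        assert m.conservation_class == "group-specific"

    def test_empty_regulon_empty_partition(self):
        part = ri.call_core([], core_min=20)
        assert all(v == [] for v in part.values())

    def test_genome_specific_label(self):
        m = self._member(1, specific=True)
        part = ri.call_core([m])
        assert part["genome-specific"] == ["m1"]


def _genome_with_roles(gid, roles_at):
    """roles_at: list of (name, role); genes spaced into separate operons."""
    genes = []
    pos = 500
    for name, role in roles_at:
        genes.append(Gene(f"{gid}_{name}", "c1", pos, pos + 300, "+",
                          protein_seq="M" + "A" * 50, role=role))
        pos += 800
    return Genome(gid, {"c1": "A" * (pos + 500)}, genes)


class TestLocalTFDiscovery:
    def test_rok_gene_near_transporter_reported(self):
        genome = _genome_with_roles("g", [("tf", "araU"), ("t1", "araF"),
                                          ("t2", "araG")])
        operons = {"g": gio.group_operons(genome)}
        cands = ri.local_tf_discovery([genome], operons)
        assert [c.gene_id for c in cands] == ["g_tf"]
        assert cands[0].tf_family == "ROK"
        assert "g_t1" in cands[0].nearby_pathway_genes

    def test_distant_tf_not_reported(self):
        entries = [("tf", "araU")] + [(f"x{i}", None) for i in range(20)] \
            + [("t1", "araF")]
        genome = _genome_with_roles("g", entries)
        operons = {"g": gio.group_operons(genome)}
        assert ri.local_tf_discovery([genome], operons) == []

    def test_no_tf_annotations_empty(self):
        genome = _genome_with_roles("g", [("t1", "araF"), ("t2", "araG")])
        operons = {"g": gio.group_operons(genome)}
        assert ri.local_tf_discovery([genome], operons) == []


class TestPropagate:
    def test_tf_absent_everywhere_raises(self, bench_clade, bench_operons,
                                         bench_model):
        empty_group = OrthologGroup("OGX", {})
        with pytest.raises(ValueError):
            ri.propagate(empty_group, bench_model, bench_clade.genomes,
                         bench_operons, [])

    def test_non_carrier_genome_excluded(self, bench_model):
        from bifidoreg import synthetic_data as sd
        cfg = sd.SimulationConfig(n_genomes=4, seed=55,
                                  tf_present=[True, True, True, False])
        clade = sd.generate_clade(cfg)
        ops = {g.genome_id: gio.group_operons(g) for g in clade.genomes}
        tf_group = OrthologGroup("OGTF", {
            g.genome_id: f"{g.genome_id}_tf" for g in clade.genomes
            if any(gene.gene_id.endswith("_tf") for gene in g.genes)})
        import bifidoreg.motif_core as mc
        sites = [mc.Site(s.genome_id, s.gene_id, s.sequence)
                 for s in clade.truth.sites]
        model = mc.from_sites("TF", mc.SiteAlignment(sites, 16))
        mc.calibrate_thresholds(model)
        cands = ri.propagate(tf_group, model, clade.genomes, ops, [])
        scanned = {g for per in cands.values() for g in per}
        assert "G03" not in scanned
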