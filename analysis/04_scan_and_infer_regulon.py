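"""Genome-wide site scan, cross-genome consistency filter, regulon table.

Uses the discovered matrix (step 03) as the known-TF input, scans every
operon-leader window in every TF-carrying genome, keys candidates by
ortholog group (step 02), applies the consistency/footprinting filter, and
measures membership precision/recall against the design-matrix truth.
"""

from bifidoreg import genome_io as gio
from bifidoreg import orthology as orth
from bifidoreg import regulon_inference as ri

import common


def main() -> None:
    genomes = common.load_clade_genomes()
    groups = orth.read_ortholog_table(common.RESULTS / "orthologs.tsv")
    model = common.model_from_truth_sites()
    operons = {g.genome_id: gio.group_operons(g) for g in genomes}

    tf_group = next(g for g in groups
                    if any(v.endswith("_tf") for v in g.members.values()))
    cands = ri.propagate(tf_group, model, genomes, operons, groups)
    members = ri.consistency_filter(cands, set(tf_group.members), groups,
                                    min_genomes=3)
    ri.call_core(members, core_min=20)
    regulon = ri.Regulon(model.name, tf_group, members)
    ri.write_regulon_tsv(regulon, common.RESULTS / "regulon.tsv")

    fam_of = {(r["genome_id"], r["gene_id"]): r["family"]
              for r in common.load_truth("families")}
    truth = {(r["family"], r["genome_id"])
             for r in common.load_truth("regulon")
             if r["site_present"] == "1"}
    by_id = {g.group_id: g for g in groups}
    predicted = set()
    for m in members:
        grp = by_id.get(m.member_id)
        if grp is None:
            continue
        fams = {fam_of.get((gid, gene))
                for gid, gene in grp.members.items()}
        fam = fams.pop() if len(fams) == 1 else None
        predicted |= {(fam, gid) for gid in m.genome_hits}
    tp = len(predicted & truth)
    print(f"{len(members)} members accepted; "
          f"precision {tp / len(predicted):.3f} "
          f"recall {tp / len(truth):.3f} vs design matrix")
    print(f"regulon table -> {common.RESULTS / 'regulon.tsv'}")


if __name__ == "__main__":
    main()
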