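"""Build ortholog groups across the clade and check them against truth.

Reciprocal-best-hit orthology with synteny resolution, run from the
FASTA+GFF3 files on disk; purity is measured against the generator's
family labels.
"""

from bifidoreg import orthology as orth

import common


def main() -> None:
    genomes = common.load_clade_genomes()
    groups = orth.infer_ortholog_groups(genomes)
    orth.write_ortholog_table(groups, common.RESULTS / "orthologs.tsv")

    fam_of = {(r["genome_id"], r["gene_id"]): r["family"]
              for r in common.load_truth("families")}
    multi = [g for g in groups if len(g) > 1]
    pure = sum(len({fam_of[(gid, gene)]
                    for gid, gene in g.members.items()}) == 1
               for g in multi)
    print(f"{len(groups)} groups ({len(multi)} with >=2 members); "
          f"purity {pure}/{len(multi)}")
    print(f"table -> {common.RESULTS / 'orthologs.tsv'}")


if __name__ == "__main__":
    main()
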