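"""De-novo palindromic motif discovery in target upstream regions.

Collects the -350..+50 windows of the site-carrying operon leaders (as the
truth table names them), searches them for a shared palindrome, and
compares the recovered consensus with the implanted one.  Also verifies
the discovered motif is significant against a shuffled-region null.
"""

from bifidoreg import genome_io as gio
from bifidoreg import motif_core as mc

import common


def main() -> None:
    genomes = common.load_clade_genomes()
    truth_sites = common.load_truth("sites")
    regions = []
    for genome in genomes:
        operons = gio.group_operons(genome)
        ups = gio.upstream_regions_for_leaders(genome, operons)
        regions.extend(ups[r["gene_id"]] for r in truth_sites
                       if r["genome_id"] == genome.genome_id
                       and r["gene_id"] in ups)

    model = mc.discover_palindromic_motif(regions, 16, seed=11,
                                          name="AraQ-like")
    mc.write_transfac(model, common.RESULTS / "motif.txt")
    mc.write_sites_fasta(model, common.RESULTS / "motif_sites.fna")

    print(f"{len(regions)} regions scanned")
    print(f"recovered consensus: {model.consensus} "
          f"(IC {model.ic_bits:.1f} bits, "
          f"thresholds strong {model.strong_threshold:.2f} / "
          f"weak {model.weak_threshold:.2f})")
    sig = mc.is_significant(model, regions, n_shuffles=15, seed=12)
    print(f"significant vs shuffled null: {sig}")
    print(f"matrix -> {common.RESULTS / 'motif.txt'}")


if __name__ == "__main__":
    main()
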