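"""Promoter element location and repression/activation calls per site.

For every implanted site, find the best -35/spacer/-10 arrangement in the
same upstream window and classify the site's regulatory mode from its
position relative to the promoter; compare with the generator's layout
labels (activator / repressor / promoterless -> ND).
"""

import csv

from bifidoreg import genome_io as gio
from bifidoreg import promoter_mode as pm
from bifidoreg import site_scan as ss

import common


def main() -> None:
    genomes = common.load_clade_genomes()
    model = common.model_from_truth_sites()
    truth_sites = common.load_truth("sites")
    fam_of = {(r["genome_id"], r["gene_id"]): r["family"]
              for r in common.load_truth("families")}
    # the generator's mode truth is per family: promoter rows name layouts
    layout_mode = {"activator": "activator", "repressor": "repressor"}
    fam_mode = {}
    for r in common.load_truth("promoters"):
        fam_mode[fam_of[(r["genome_id"], r["gene_id"])]] = \
            layout_mode[r["layout"]]

    rows = []
    correct = total = 0
    for genome in genomes:
        operons = gio.group_operons(genome)
        ups = gio.upstream_regions_for_leaders(genome, operons)
        for r in truth_sites:
            if r["genome_id"] != genome.genome_id:
                continue
            region = ups[r["gene_id"]]
            hit = next(h for h in ss.scan_region(model, region)
                       if h.abs_start == int(r["abs_start"]))
            ann = pm.find_promoter(region)
            mode = pm.classify_mode(hit, ann, region)
            fam = fam_of[(r["genome_id"], r["gene_id"])]
            expected = fam_mode.get(fam, "ND")
            total += 1
            correct += (mode == expected)
            rows.append([r["genome_id"], r["gene_id"],
                         ann.minus35_offset if ann.confident else "",
                         ann.minus10_offset if ann.confident else "",
                         ann.spacer_len if ann.confident else "",
                         mode, expected])

    out = common.RESULTS / "modes.tsv"
    with open(out, "w", newline="") as fh:
        w = csv.writer(fh, delimiter="\t", lineterminator="\n")
        w.writerow(["genome_id", "gene_id", "minus35_offset",
                    "minus10_offset", "spacer", "mode", "true_mode"])
        w.writerows(rows)
    print(f"mode recovery {correct}/{total}")
    print(f"table -> {out}")


if __name__ == "__main__":
    main()
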