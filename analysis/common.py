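"""Shared paths and loaders for the numbered analysis scripts.

The scripts form a pipeline over ``results/``: 01 writes the benchmark
clade (genomes + ground truth), later steps read those files back through
the package's own parsers and write their tables next to them.
"""

from __future__ import annotations

import csv
from pathlib import Path

from bifidoreg import genome_io as gio

ROOT = Path(__file__).resolve().parent.parent
RESULTS = ROOT / "results"
CLADE_DIR = RESULTS / "clade"

#: the benchmark clade every analysis step works on
CLADE_SEED = 20180424 % 2**16
N_GENOMES = 8
MISMATCH_PROB = 0.05
LAYOUTS = {0: "activator", 1: "repressor", 2: "none", 3: "none"}
PHENOTYPES = ["U1", "U2", "U3", "U123", "0", "unique", "U1", "U2"]


def load_clade_genomes() -> list[gio.Genome]:
    genomes = []
    for fna in sorted(CLADE_DIR.glob("*.fna")):
        genomes.append(gio.load_genome(fna.with_suffix(".gff3"),
                                       "fasta+gff3", fasta=fna,
                                       genome_id=fna.stem))
    if not genomes:
        raise SystemExit("no clade found under results/clade — "
                         "run analysis/01_simulate_clade.py first")
    return genomes


def load_truth(name: str) -> list[dict[str, str]]:
    with open(CLADE_DIR / f"truth_{name}.tsv", newline="") as fh:
        return list(csv.DictReader(fh, delimiter="\t"))


def model_from_truth_sites():
    """Known-TF weight matrix rebuilt from the truth site table."""
    from bifidoreg import motif_core as mc
    sites = [mc.Site(r["genome_id"], r["gene_id"], r["sequence"])
             for r in load_truth("sites")]
    model = mc.from_sites("AraQ-like", mc.SiteAlignment(sites, 16))
    mc.calibrate_thresholds(model)
    return model
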