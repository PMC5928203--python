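"""Generate the benchmark clade all later analysis steps consume.

Eight genomes sharing a TF and four site-carrying target families; light
site noise (5% per position before re-palindromization); two target
families get exact-consensus promoters laid out so the implanted operator
is unambiguously activating or repressing; phenotype witness genes cover
every utilization label.
"""

from bifidoreg import synthetic_data as sd

import common


def main() -> None:
    cfg = sd.SimulationConfig(
        n_genomes=common.N_GENOMES,
        mismatch_prob=common.MISMATCH_PROB,
        layouts=common.LAYOUTS,
        phenotypes=common.PHENOTYPES,
        seed=common.CLADE_SEED,
    )
    clade = sd.generate_clade(cfg)
    clade.write(common.CLADE_DIR)
    n_sites = len(clade.truth.sites)
    print(f"wrote {cfg.n_genomes} genomes to {common.CLADE_DIR}")
    print(f"implanted {n_sites} sites of consensus {cfg.consensus}")
    print(f"phenotype labels: {sorted(set(clade.truth.phenotypes.values()))}")


if __name__ == "__main__":
    main()
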