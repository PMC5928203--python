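import numpy as np
import pytest

from bifidoreg import genome_io as gio
from bifidoreg import motif_core as mc
from bifidoreg import synthetic_data as sd


@pytest.fixture(scope="session")
def bench_clade():
    """8-genome clade, 4 universally targeted families, light site noise."""
    cfg = sd.SimulationConfig(n_genomes=8, mismatch_prob=0.05, seed=101)
    return sd.generate_clade(cfg)


@pytest.fixture(scope="session")
def bench_operons(bench_clade):
    return {g.genome_id: gio.group_operons(g) for g in bench_clade.genomes}


@pytest.fixture(scope="session")
def bench_model(bench_clade):
    """Known-TF model: matrix built from the generator's truth sites."""
    sites = [mc.Site(s.genome_id, s.gene_id, s.sequence)
             for s in bench_clade.truth.sites]
    model = mc.from_sites("TF", mc.SiteAlignment(
        sites, len(bench_clade.config.consensus)))
    mc.calibrate_thresholds(model)
    return model


def hamming_to_palindrome(a: str, b: str) -> int:
    """Hamming distance modulo strand (a palindrome equals its revcomp)."""
    return min(sum(x != y for x, y in zip(a, b)),
               sum(x != y for x, y in zip(a, gio.reverse_complement(b))))


@pytest.fixture
def toy_pwm():
    """Small L=4 palindromic model with calibrated thresholds."""
    rng = np.random.default_rng(4)
    counts = mc.symmetrize_counts(rng.integers(0, 10, size=(4, 4)))
    model = mc.MotifModel("toy", counts)
    model.strong_threshold = 0.0
    model.weak_threshold = -1.0
    return model
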