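"""Reproducible benchmark computations over the synthetic clade generator.

Each function runs one stage of the pipeline against generator ground truth
and returns the measured quantity.  They are used both by the acceptance
test suite and by ``scripts/acceptance.py``; all randomness is controlled
through the single ``seed`` argument.
"""

from __future__ import annotations

import itertools

import numpy as np

from bifidoreg import genome_io as gio
from bifidoreg import motif_core as mc
from bifidoreg import orthology as orth
from bifidoreg import promoter_mode as pm
from bifidoreg import regulon_inference as ri
from bifidoreg import site_scan as ss
from bifidoreg import subsystem_phenotype as sp
from bifidoreg import synthetic_data as sd

PHENOTYPE_LABELS = ("U1", "U2", "U3", "U123", "0", "unique")


def _target_regions(clade, operons=None):
    operons = operons or {g.genome_id: gio.group_operons(g)
                          for g in clade.genomes}
    regions = []
    for genome in clade.genomes:
        ups = gio.upstream_regions_for_leaders(genome,
                                               operons[genome.genome_id])
        regions.extend(ups[s.gene_id] for s in clade.truth.sites
                       if s.genome_id == genome.genome_id
                       and s.gene_id in ups)
    return regions


def model_from_truth(clade, name: str = "TF") -> mc.MotifModel:
    """Known-TF model: weight matrix built from the generator's sites."""
    sites = [mc.Site(s.genome_id, s.gene_id, s.sequence)
             for s in clade.truth.sites]
    model = mc.from_sites(name, mc.SiteAlignment(
        sites, len(clade.truth.consensus)))
    mc.calibrate_thresholds(model)
    return model


# ---------------------------------------------------------------------------
# motif discovery recovery


def motif_recovery(n_runs: int = 100, seed: int = 0,
                   n_genomes: int = 8, mismatch_prob: float = 0.1
                   ) -> tuple[int, int]:
    """De-novo discovery on fresh clades: how often is the recovered
    consensus within Hamming distance 1 of the implanted palindrome?

    Returns (n_recovered, n_runs).
    """
    rng = np.random.default_rng(seed)
    recovered = 0
    for _ in range(n_runs):
        cfg = sd.SimulationConfig(n_genomes=n_genomes,
                                  mismatch_prob=mismatch_prob,
                                  seed=int(rng.integers(2**31)))
        clade = sd.generate_clade(cfg)
        regions = _target_regions(clade)
        model = mc.discover_palindromic_motif(
            regions, len(cfg.consensus), seed=int(rng.integers(2**31)))
        d = min(sum(a != b for a, b in zip(model.consensus, cfg.consensus)),
                sum(a != b for a, b in
                    zip(model.consensus,
                        gio.reverse_complement(cfg.consensus))))
        recovered += (d <= 1)
    return recovered, n_runs


# ---------------------------------------------------------------------------
# scan scoring vs brute force


def scan_oracle_agreement(seed: int = 0) -> tuple[int, int]:
    """Exhaustive L=4 check of PWM scoring against an independent
    brute-force enumerator; returns (n_equal, 256)."""
    rng = np.random.default_rng(seed)
    counts = mc.symmetrize_counts(rng.integers(0, 10, size=(4, 4)))
    model = mc.MotifModel("toy", counts)
    weights = model.weights.tolist()
    idx = {"A": 0, "C": 1, "G": 2, "T": 3}
    n_equal = 0
    for tup in itertools.product("ACGT", repeat=4):
        seq = "".join(tup)
        brute = sum(weights[j][idx[b]] for j, b in enumerate(seq))
        n_equal += (abs(model.score(seq) - brute) < 1e-12)
    return n_equal, 256


def pwm_algebra_max_deviation(seed: int = 0) -> float:
    """Largest violation across the PWM identities: zero-sum weight
    columns, palindromic score symmetry (exhaustive at L=6), and
    idempotent symmetrization."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(5):
        raw = rng.integers(0, 15, size=(6, 4)).astype(float)
        sym = mc.symmetrize_counts(raw)
        worst = max(worst, float(np.abs(
            mc.symmetrize_counts(sym) - sym).max()))
        w = mc.build_weights(sym)
        worst = max(worst, float(np.abs(w.sum(axis=1)).max()))
    counts = mc.symmetrize_counts(rng.integers(0, 12, size=(6, 4)))
    model = mc.MotifModel("p", counts)
    for i in range(4 ** 6):
        codes = np.array([(i // 4 ** j) % 4 for j in range(6)])
        fwd = model.score_codes(codes)
        rev = model.score_codes(mc.revcomp_codes(codes))
        worst = max(worst, abs(fwd - rev))
    return worst


# ---------------------------------------------------------------------------
# regulon membership recovery


def regulon_recovery(seed: int = 0, n_genomes: int = 8,
                     min_genomes: int = 3,
                     mismatch_prob: float = 0.05,
                     use_inferred_orthologs: bool = True
                     ) -> tuple[float, float, int]:
    """Precision/recall of accepted regulon members against the design
    matrix of a synthetic clade; returns (precision, recall, n_truth)."""
    rng = np.random.default_rng(seed)
    design = rng.random((4, n_genomes)) < 0.7
    design[:, :min_genomes] = True  # every family has enough carriers
    cfg = sd.SimulationConfig(n_genomes=n_genomes,
                              mismatch_prob=mismatch_prob,
                              design=design,
                              seed=int(rng.integers(2**31)))
    clade = sd.generate_clade(cfg)
    model = model_from_truth(clade)
    operons = {g.genome_id: gio.group_operons(g) for g in clade.genomes}

    if use_inferred_orthologs:
        groups = orth.infer_ortholog_groups(clade.genomes)
    else:
        groups = _truth_groups(clade)
    tf_group = _tf_group(groups, clade)
    cands = ri.propagate(tf_group, model, clade.genomes, operons, groups)
    members = ri.consistency_filter(cands, set(tf_group.members), groups,
                                    min_genomes=min_genomes)

    gene2fam = clade.truth.families
    by_id = {g.group_id: g for g in groups}
    predicted = set()
    for m in members:
        grp = by_id.get(m.member_id)
        if grp is None:
            continue
        fams = {gene2fam.get((gid, gene))
                for gid, gene in grp.members.items()}
        fam = fams.pop() if len(fams) == 1 else None
        for gid in m.genome_hits:
            predicted.add((fam, gid))
    truth = {(f"fam{f}", f"G{g:02d}")
             for f in range(4) for g in range(n_genomes) if design[f, g]}
    tp = len(predicted & truth)
    precision = tp / len(predicted) if predicted else 0.0
    recall = tp / len(truth)
    return precision, recall, len(truth)


def _truth_groups(clade):
    by_fam: dict[str, dict[str, str]] = {}
    for (gid, gene), fam in clade.truth.families.items():
        by_fam.setdefault(fam, {})[gid] = gene
    return [orth.OrthologGroup(fam, members)
            for fam, members in sorted(by_fam.items())]


def _tf_group(groups, clade):
    for grp in groups:
        if any(gene.endswith("_tf") for gene in grp.members.values()):
            return grp
    raise RuntimeError("TF group not found")


def filter_monotone_in_min_genomes(seed: int = 0) -> bool:
    """Accepted member sets must shrink (weakly) as min_genomes rises."""
    rng = np.random.default_rng(seed)
    design = rng.random((4, 8)) < 0.6
    design[:, :2] = True
    cfg = sd.SimulationConfig(n_genomes=8, mismatch_prob=0.1,
                              design=design,
                              seed=int(rng.integers(2**31)))
    clade = sd.generate_clade(cfg)
    model = model_from_truth(clade)
    operons = {g.genome_id: gio.group_operons(g) for g in clade.genomes}
    groups = _truth_groups(clade)
    tf_group = _tf_group(groups, clade)
    cands = ri.propagate(tf_group, model, clade.genomes, operons, groups)
    prev = None
    for k in range(2, 9):
        ids = {m.member_id for m in ri.consistency_filter(
            cands, set(tf_group.members), groups, min_genomes=k)}
        if prev is not None and not ids <= prev:
            return False
        prev = ids
    return True


# ---------------------------------------------------------------------------
# regulatory-mode recovery


def mode_recovery(seed: int = 0, n_genomes: int = 6) -> tuple[int, int]:
    """Mode labels recovered on generator-labeled promoter layouts with
    exact-consensus promoters and sites; returns (n_correct, n_total)."""
    cfg = sd.SimulationConfig(
        n_genomes=n_genomes, mismatch_prob=0.0, seed=seed,
        layouts={0: "activator", 1: "repressor", 2: "none", 3: "none"})
    clade = sd.generate_clade(cfg)
    model = model_from_truth(clade)
    correct = total = 0
    for genome in clade.genomes:
        operons = gio.group_operons(genome)
        ups = gio.upstream_regions_for_leaders(genome, operons)
        for s in clade.truth.sites:
            if s.genome_id != genome.genome_id:
                continue
            region = ups[s.gene_id]
            hit = next(h for h in ss.scan_region(model, region)
                       if h.abs_start == s.abs_start)
            mode = pm.classify_mode(hit, pm.find_promoter(region), region)
            fam = clade.truth.families[(genome.genome_id, s.gene_id)]
            total += 1
            correct += (mode == clade.truth.modes[fam])
    return correct, total


def mode_transition_monotone() -> bool:
    """Sliding a site downstream through a fixed promoter switches
    activator -> repressor exactly once, never back."""
    ann = pm.PromoterAnnotation(282, pm.MINUS35_CONSENSUS, 9.0,
                                305, pm.MINUS10_CONSENSUS, 9.0,
                                17, 18.0, "confident")
    labels = [pm.classify_mode_offsets(s, s + 16, ann) for s in range(380)]
    switches = sum(1 for a, b in zip(labels, labels[1:]) if a != b)
    return switches == 1 and labels[0] == pm.ACTIVATOR \
        and labels[-1] == pm.REPRESSOR


# ---------------------------------------------------------------------------
# phenotypes


def phenotype_roundtrip() -> tuple[int, int]:
    """Each phenotype label's witness role set must reproduce exactly that
    label through the phenotype rules; returns (n_correct, n_labels)."""
    cfg = sd.SimulationConfig(n_genomes=len(PHENOTYPE_LABELS),
                              phenotypes=list(PHENOTYPE_LABELS),
                              n_target_families=0, seed=1)
    clade = sd.generate_clade(cfg)
    table = sp.populate_subsystem(clade.genomes)
    correct = 0
    for genome in clade.genomes:
        call = sp.assign_phenotype(table, genome.genome_id)
        correct += (call.composite == clade.truth.phenotypes[genome.genome_id])
    return correct, len(PHENOTYPE_LABELS)


def arabinose_concordance(seed: int = 0) -> tuple[int, int, float]:
    """Predicted arabinose utilization vs a fermentation panel of 22
    strains with two genuinely discrepant cases (strains lacking any known
    arabinose transporter that nevertheless ferment arabinose).

    Returns (n_match, n_total, fraction).
    """
    rng = np.random.default_rng(seed)
    labels = [str(rng.choice(["U1", "U123", "0", "U2"])) for _ in range(20)]
    labels += ["unique", "unique"]  # araBDA without any known transporter
    cfg = sd.SimulationConfig(n_genomes=22, phenotypes=list(labels),
                              n_target_families=0,
                              seed=int(rng.integers(2**31)))
    clade = sd.generate_clade(cfg)
    table = sp.populate_subsystem(clade.genomes)
    calls = sp.assign_all(table)
    fermentation = {}
    for call in calls:
        if call.composite == "unique":
            # ferments arabinose despite no recognizable transporter gene
            fermentation[call.genome_id] = "+"
        else:
            fermentation[call.genome_id] = \
                "+" if "U1" in call.labels else "-"
    return sp.concordance(calls, fermentation)
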