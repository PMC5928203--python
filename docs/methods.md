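# Methods

## The reconstruction model

A TF's operator is modeled as an even-length palindrome bound by a
homodimer.  The binding model is an L×4 count matrix over training sites,
symmetrized against its reverse-complement mirror,

    N′(b, j) = (N(b, j) + N(complement(b), L+1−j)) / 2,

with positional weights

    w(b, j) = ln(N′(b, j) + 0.5) − ¼ Σ_b′ ln(N′(b′, j) + 0.5).

Each weight column sums to zero, and because the count matrix equals its
own mirror, score(s) = score(revcomp(s)) for every sequence — one strand
of a region needs scanning.  A site's score is the sum of its positional
weights; information content is Σ f·log2(f/0.25) over pseudocounted
column frequencies, bounded by 2 bits per column.

Candidate sites are searched in a fixed −350..+50 window around annotated
start codons of operon leaders (operons: same-strand runs with intergenic
gaps ≤ `operon_max_gap`, default 150 bp).  The window is deliberately not
truncated at upstream gene boundaries; overlap with coding sequence is
possible and left to downstream interpretation.

### Thresholds

Score thresholds are calibrated from the training sites rather than fixed
on an absolute scale: `strong = strong_fraction × min(training scores)`
(default fraction 1.0) and `weak = weak_ratio × strong` (default 0.95,
mirroring a 4.75:5 strong:weak convention).  A laxer preset
(`GLOBAL_REGULON_PRESET`: strong_fraction 0.95, weak_ratio 4.5/4.75) suits
large diffuse regulons where the default would be too conservative.
Absolute thresholds can be injected for users with an external score
scale.

### De-novo discovery

Discovery is a seeded greedy iteration: a restart seeds the matrix from
one L-mer plus its reverse complement, then alternates (score all windows
of every region on one strand) ↔ (rebuild the symmetrized counts from each
region's best window) until stable or 50 iterations.  Two choices matter:

- **Seeding.**  Restarts are seeded preferentially from near-perfect
  palindromic windows (≥ L/2 − 1 self-complementary pairs), falling back
  to random L-mers.  Palindromic operators are self-complementary, so
  these seeds are the highest-prior starting points; without this, most
  random seeds converge to diffuse background motifs.
- **Zero-or-one site per region.**  A region contributes its best window
  to the next count matrix only if it scores ≥ 60% of the current
  consensus score (at least 4 regions are always kept).  This keeps
  mixed region sets — where only a subset of candidate genes is actually
  regulated — from diluting the matrix; in GC-rich (~60%) intergenic
  background the undamped iteration reliably converges to GC-rich
  pseudo-palindromes instead of the true motif.

The winning restart maximizes IC × (fraction of regions whose best window
scores ≥ 75% of the consensus score).  Significance is judged against an
empirical null: IC of motifs discovered in per-region shuffles; a motif at
or below the null's 95th percentile is reported as not significant.
Motif length defaults to a scan over {14, 16, 18, 20, 22} with the best
IC-per-column winning, since operator lengths differ between TF families.

### Orthology

Reciprocal best hits under local Smith–Waterman alignment (BLOSUM62, gap
open 11 / extend 1), thresholds 30% identity and 70% coverage of both
sequences — conventional cutoffs, configurable.  Single-linkage clustering
merges pairs across genomes; when one genome contributes several genes to
a cluster, the copy sharing an orthologous neighbor within ±5 genes is
kept and displaced copies become singleton groups.  Ties anywhere break by
score, then alignment length, then lexicographic gene id, so results are
independent of input order.  A precomputed ortholog table can replace the
whole stage.

### Consistency filter and footprinting

Candidates are keyed by the ortholog group of the target operon leader.  A
member is accepted when strong sites recur in at least
`min(min_genomes, ⌈carriers/2⌉)` genomes, where *carriers* counts
TF-carrying genomes possessing the gene.  The cap makes the requirement
monotone non-decreasing in `min_genomes` (a plain "50% fallback only when
carriers < min_genomes" rule paradoxically *relaxes* the filter as
`min_genomes` grows past the carrier count) while preserving the intent
that rarely distributed genes are not held to an unreachable bar.  Weak
sites count only when the same group has a strong site in another genome —
conservation of a site upstream of orthologs is the footprinting evidence
that a marginal score is real.  Genes with no ortholog elsewhere
(including paralogs displaced during synteny resolution) need a strong
site and are flagged genome-specific.  Members conserved in ≥ `core_min`
genomes (default 20) are labeled core.

### Promoter location and regulatory mode

σ70 promoters are modeled as consensus-biased matrices for TTGACA (−35)
and TATAAT (−10) with a 15–19 bp spacer (no penalty inside the range,
disallowed outside), searched on the coding strand; ties prefer the
arrangement closest to the start codon.  A call is **confident** only when
the joint score (a) exceeds the 95th percentile of best joint scores over
composition-preserving shuffles of the same region, and (b) lies within
1.0 of the maximum achievable joint score — i.e., essentially a consensus
−35/−10 pair.  The floor is deliberate: an empirical cutoff alone passes
~5% of promoterless regions by construction, and a mode call hung on a
spurious promoter is worse than ND.  The cost is sensitivity — weak but
real promoters are reported ND — which matches how conservatively mode
should be assigned from sequence alone.

Mode follows promoter geometry: a site ending before the −35 element
leaves the polymerase footprint free (activator); any site at or
downstream of the −35 start — overlapping either element, filling the
spacer, or sitting downstream of the −10 — occludes initiation
(repressor); without a confident promoter the mode is ND.  The rule is
total and ordered: sliding a site downstream through a promoter switches
activator → repressor exactly once.

### Phenotype rules

Phenotypes are pure functions of a genome's role set:

- U1: araB ∧ araD ∧ araA ∧ (araE ∨ araFGH complete)
- U2: araBDA ∧ (araNtPtQt ∨ aauABC complete ∨ abfT1 ∨ abfT2 ∨ xsaT)
  ∧ ≥1 intracellular α-L-arabinofuranosidase
- U3: araBDA ∧ (bauABC complete ∨ bauT) ∧ hypBA1
- "unique": araBDA present but no known transporter role at all
- 0: otherwise

Multi-subunit transporters require every subunit by default
(`completeness` relaxes the fraction).  The xosABC/abfA–xynB route is
reported as an advisory "AXOS-route" flag, not a U-label, because it is a
plausible-but-unconfirmed salvage pathway.  The rule set is monotone:
adding roles never removes a label.

## The synthetic clade generator

The generator emulates what the analysis assumes about real data: genomes
share single-copy protein families diverged from common ancestors along a
star topology (default 0.05 substitutions/site per branch, no indels);
intergenic background is i.i.d. with 60% G+C (the typical bifidobacterial
composition); each target family's upstream window carries one implanted
operator (per-position mismatch probability p, then one half mirrored so
the site stays exactly self-complementary — an `asymmetric_noise` flag
disables the mirroring to stress the symmetrization); promoter layouts
place exact TTGACA–17bp–TATAAT elements so that the site is unambiguously
upstream of the −35 (activator layout, site at −120) or downstream of the
−10 (repressor layout, site at −30); phenotype witness genes realize any
requested label.  A `divergent_pair` option adds a head-to-head
regulator/transporter pair sharing one operator in the common intergenic
region.

What it does **not** emulate: operon structure variation, regulator
pseudogenization, horizontal transfer, codon usage, overlapping genes,
promoter strength variation, or site turnover along a real phylogeny.
Passing the round-trip benchmarks therefore demonstrates internal
correctness of the chain (discovery inverts implantation, the filter
inverts the design matrix, the rules invert the witness sets), not
performance on real genomes, where annotation errors and diverged sites
dominate.

## Benchmark problem sizes

The shipped benchmarks run on 8-genome clades with 4 target families
(32 implanted sites), 100 discovery runs for the recovery rate, exhaustive
enumeration at L=4/L=6 for the scoring oracles, and a 22-strain panel for
fermentation concordance — sizes chosen so the full suite and the
acceptance script each complete in about half a minute on one CPU while
every stage still runs end to end from files.

## Numerical and degenerate-input choices

- Pseudocount 0.5 everywhere (weights and frequencies); natural log for
  weights, log2 for information content.
- Coordinates 0-based half-open on the forward strand; window position 0
  is the first base of the start codon; GFF3 output converts to 1-based
  inclusive.
- Sites overlapping any non-ACGT base score NaN/−∞ and are discarded at
  scan time.
- A single training site collapses both thresholds to its score and logs
  a warning.
- Fewer than 4 usable regions is an error for discovery.
- Palindromic self-overlap: forward/reverse reports of one interval are
  deduplicated to one hit with strand ".".
- All randomness flows through seeded `numpy` generators; the promoter
  null uses a fixed internal seed so calibration is reproducible across
  processes.

## Known limitations

- The consistency filter's 50%-cap and the weak-site support rule are
  interpretations of a qualitative procedure; both are configurable.
- Promoter calls are conservative by design (see above) and limited to
  σ70-style promoters on the coding strand.
- Orthology is pairwise-similarity based; deep paralogy or gene fusions
  need a precomputed table from a dedicated tool.
- Intracellular vs extracellular hydrolase classification relies entirely
  on the input annotation.
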