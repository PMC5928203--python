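# bifidoreg

Comparative-genomics reconstruction of transcription-factor (TF) regulons
for arabinose and arabino-oligosaccharide (AOS) utilization in
*Bifidobacteriaceae*-like genome sets.

Bifidobacteria ferment plant-derived arabinose and AOS, and the genes for
uptake (permeases, ABC systems) and catabolism (α-/β-L-arabinofuranosidases,
the araBDA operon) are controlled by a small set of LacI-, TetR- and
ROK-family regulators that bind palindromic operators in promoter regions.
Reconstructing who regulates what — across dozens of genomes, from sequence
alone — is a classic comparative-genomics exercise: find the operator motif,
scan genomes for sites, and keep only sites conserved across orthologs.
This package implements that whole chain as a reusable library for people
who want to run or stress-test such reconstructions without manual curation:

1. **genome_io** — GenBank / FASTA+GFF3 input, operon grouping
   (same-strand gap ≤ 150 bp), strand-aware extraction of the −350..+50
   window around each start codon.
2. **orthology** — reciprocal-best-hit ortholog groups (Smith–Waterman,
   BLOSUM62, affine gaps 11/1; ≥30% identity, ≥70% bidirectional coverage)
   with gene-neighborhood (synteny) resolution of paralogs.
3. **motif_core** — palindromic position weight matrices and de-novo motif
   discovery.  Counts are symmetrized,
   N′(b,j) = (N(b,j) + N(b̄, L+1−j))/2, and weights are zero-sum
   log-counts, w(b,j) = ln(N(b,j)+0.5) − ¼·Σ_b′ ln(N(b′,j)+0.5), so
   score(s) = score(revcomp(s)) exactly.
4. **site_scan** — genome-wide scanning of operon-leader windows with
   strong/weak score classes (weak = 0.95 × strong by default, a laxer
   global-regulon preset is provided); shared sites in divergent
   intergenic regions are attributed to both leaders.
5. **regulon_inference** — cross-genome propagation over ortholog groups,
   a consistency filter (strong sites must recur in ≥ min(min_genomes,
   ⌈carriers/2⌉) genomes; weak sites need orthologous strong support —
   phylogenetic footprinting), core-regulon calls (conserved in ≥ 20
   genomes by default), and local-TF discovery by chromosomal
   co-localization.
6. **promoter_mode** — σ70 −35/spacer/−10 promoter location and a binary
   mode rule: a site entirely upstream of the −35 element is an activator
   site; one overlapping the elements or downstream of the −10 is a
   repressor site; no confident promoter ⇒ ND.
7. **subsystem_phenotype** — a controlled vocabulary of arabinose/AOS
   functional roles and per-genome utilization phenotypes:
   U1 (arabinose) = araBDA + (araE or complete araFGH);
   U2 (α-AOS) = araBDA + an α-AOS transporter + an intracellular
   α-L-arabinofuranosidase; U3 (β-AOS) = araBDA + (bauABC or bauT) +
   hypBA1; "unique" = araBDA with no known transporter; 0 = none.
8. **synthetic_data** — a ground-truthed clade generator (ortholog
   families, GC-biased intergenic background, implanted palindromic sites,
   promoter layouts, phenotype witness genes) so the entire chain is
   testable offline.

`analysis/01…06` are numbered narrative drivers that run these stages over
a benchmark clade and write their tables under `results/`;
`bifidoreg.pipeline.run_all` (and the `bifidoreg` CLI) orchestrate the same
stages end to end.

## Worked example

```sh
cd analysis
python 01_simulate_clade.py
python 02_infer_orthologs.py
python 03_discover_motif.py
python 04_scan_and_infer_regulon.py
python 05_classify_modes.py
python 06_assign_phenotypes.py
```

prints (abridged):

```
wrote 8 genomes to results/clade
implanted 32 sites of consensus ATGTTAGCGCTAACAT
19 groups (19 with >=2 members); purity 19/19
recovered consensus: ATGTTAGCGCTAACAT (IC 24.4 bits,
    thresholds strong 34.59 / weak 32.86)
4 members accepted; precision 1.000 recall 1.000 vs design matrix
mode recovery 32/32
phenotype recovery 8/8
fermentation concordance 20/22 = 90.9%
```

Reading this: the de-novo search recovered the implanted 16-bp palindrome
exactly (24.4 bits of information content; the score thresholds are
calibrated from the training sites).  All four target families were
accepted as regulon members in exactly the genomes where the design matrix
placed sites.  Every implanted site was classified correctly as
activating, repressing or ND from its position against the −35/−10
elements, and the gene-content rules reproduced every intended phenotype.
The fermentation panel contains two strains that ferment arabinose despite
lacking any recognized transporter gene, so concordance is 20/22 ≈ 91% —
the kind of honest discrepancy such reconstructions surface.

## Scope notes

Gene calling, GH-family/transporter-family assignment, and protein
localization are *inputs* (annotations), not predictions made here.
Running against real GenBank genomes requires only FASTA+GFF3 or GenBank
files plus role annotations using the subsystem vocabulary.
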