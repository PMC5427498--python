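# Methods

This note documents the models, conventions and numerical choices behind
`annodiff`, and what its synthetic-data tests do and do not demonstrate
about real data.

## Sequence model and gene models

Genomes are scaffold FASTA plus GFF3 gene models, 1-based inclusive
coordinates throughout; any half-open arithmetic is confined to I/O
adapters. Ambiguity codes other than N are normalized to N on input (with
a logged count), because downstream codon counting treats any ambiguity as
unusable. For multi-transcript genes the transcript with the longest
summed CDS is canonical for every downstream analysis. Gap totals count
maximal runs of N of length ≥ 1 (no minimum run length; configurable in
principle, the choice only affects the gap-total summary). N50 is defined
as the length of the scaffold at which the cumulative length in descending
order first reaches half the assembly, with `n50_count` the number of
scaffolds up to and including it; the convention is documented rather than
asserted against any external assembly's printed value.

## Alignment

Ortholog pairs are aligned with global Needleman–Wunsch over BLOSUM62 with
affine gaps (defaults: open 11, extend 1, in the convention where a
length-L gap costs `open + (L−1)·extend`), because Ka/Ks needs full-length
in-frame pairing. Identity is the fraction of matching columns among
columns gapped in neither row. Candidate pairs for all-vs-all scans come
from a shared k-mer prefilter (k = 5, ≥ 2 shared k-mers).

Homology *detection* — the stand-in for a database search with an e-value
cutoff — uses Smith–Waterman local scores normalized by the smaller
self-score of the pair, with threshold 0.2. Local scoring is essential for
gene fragments: a half-length gene model aligned globally against its
full-length counterpart pays an end-gap penalty that can push the score
below zero. The 0.2 threshold was calibrated so that shuffled unrelated
proteins qualify far less than 1% of the time (a test enforces this);
equivalence with any particular e-value is not claimed.

Codon back-translation maps each protein-alignment column to one codon
column (CDS supplied without the terminal stop, so 3×protein length is
enforced). The low-quality mask slides a 15-bp window one codon at a time
and, in any window whose nucleotide identity falls below 0.4, masks the
*mismatching* codon columns. Masking only the mismatching columns (rather
than the whole window) keeps an isolated fully-mismatched block masked
exactly, without eating one identical codon on each side; the choice is
conservative for site counts and idempotent.

## Ka/Ks (NG86 + Jukes–Cantor)

The normative estimator is Nei–Gojobori (1986) counting:

* per codon, the synonymous site count is
  `s = Σ_pos (synonymous viable neighbours / viable neighbours)`, where a
  neighbour is viable if the single-base change does not create a stop
  codon; `n = 3 − s`;
* pairwise differences are decomposed over all orderings of the differing
  positions with equal weights; any path through a stop codon is
  discarded, and a codon pair whose every path hits a stop is excluded and
  counted;
* `pS = Ns/S`, `pN = Na/N` with S, N averaged over the two sequences, and
  `d = −(3/4)·ln(1 − (4/3)p)`, undefined (never 0 or ∞) at `p ≥ 3/4` —
  saturation propagates as an explicit flag.

ω = Ka/Ks is defined only when Ks > 0. Equal path weighting is known to
be slightly biased when ω differs from 1 (real histories favour
synonymous-step routes); at the divergences used here the effect on mean
Ks is under ~2% and a mild (≲1 SE at n = 200 genes) downward tendency is
visible in the relative-rate contrast at the outgroup distance. A
transition/transversion-aware estimator would reduce this but is out of
scope; NG86 is fully specified and oracle-checkable by enumeration, which
is why it is the tested contract.

Population-genetic conversions are closed forms: net divergence
`Ks − π_ancestral/2` (floored at 0 with a warning), divergence time
`Ks/(2u)` generations (u defaults to nothing; the worked example uses
5.7 × 10⁻⁹/site/generation and five generations per year), and Ne ratios
as π ratios under equal mutation rates. With the worked-example inputs the
time formula gives 4.49 × 10⁶ generations; the source analysis quotes
≈ 4.8 × 10⁶ for the same inputs — the formula is implemented as stated and
the computed value is reported, the discrepancy being in the source's
arithmetic, not a tunable here. Likewise `0.0512 − 0.0183/2 = 0.04205`,
printed as 0.0421 at four decimals.

Standard errors of means are sample SD/√n throughout.

## Orthology, orphans, splits, paralog ages

RBH pairs require each gene to be the other's best significant hit, ties
broken by score, then normalized score, then lexicographic id. Clusters
are single-linkage over RBH edges plus within-genome edges that satisfy
either (a) the in-paralog rule — within-genome score at least the anchored
gene's weakest between-genome RBH score — or (b) co-ortholog convergence:
both genes' best cross-genome hit is the same gene. Rule (b) captures
duplicates older than the species split that still share one ortholog, as
Markov-cluster methods do in practice; equivalence with OrthoMCL is not
claimed — recovery on simulated truth is the contract.

Orphan classification applies the precedence reference-proteome homolog >
cross-genome homolog (species-specific) > lineage-specific orphan, over
genes not already placed in clusters. Split/merge events are emitted when
≥ 2 genes of one genome share a best hit in the other and their local
alignment footprints on the shared protein overlap by at most 20% of the
shorter footprint (threshold configurable; the source is silent). A
premature stop is a `*` strictly before the final annotated codon.

Paralog ages are per-gene means of masked-alignment Ks against same-genome
cluster mates, binned at width 0.1 — coarse enough that desk-scale paralog
counts yield a stable mode — with the mean 1:1 ortholog Ks of the same run
drawn as the young/old benchmark.

## Intron gain/loss polarization

Intron positions are protein-coordinate (codon index, phase) values,
computed from CDS segments in translation order. Sites from both ingroup
genes and the outgroup gene are projected into the ingroup-A residue frame
through the pairwise protein alignments; a site is scorable only when both
20-aa flanks align at ≥ 60% identity in both alignments with at least 5 aa
of flank available — otherwise it is dropped and counted, never guessed.
Projection is exact: the same codon index and phase after projection, with
zero slippage tolerated (strictness favours precision; the no-injection
control shows zero false events). Presence triples are polarized by the
Dollo truth table; the test suite checks it against exhaustive
minimal-event enumeration on the 3-taxon tree. Event summaries report
per-genome gain/loss counts, medians and GC of the gained/lost introns
(the lost intron's length is read from the genome retaining it), a
percent-excess statistic, and N/A medians for empty classes.

## Contamination triage

Breadth of coverage is the fraction of positions with depth ≥ 1 (minimum
depth configurable). Decision rule per scaffold: a bacterial best hit with
e-value < 10⁻⁵ and identity > 95% → drop; else keep iff PE breadth > 0.80
and sperm breadth > 0.30, annotating the (0.30, 0.80] sperm band for
review (kept by default, mirroring a manual-check-then-keep protocol);
else drop for low support. Taxonomy is consumed as a precomputed best-hit
table — no database search is run. Decisions are monotone in the breadths
and the filter is idempotent.

## Synthetic genome pairs and the truth ledger

The generator builds a common ancestor (default 200 genes on 5 scaffolds):
exons per gene 1 + Poisson(5.9) targeting a mean of 6.9, exon lengths
30 + Exponential(207) bp targeting a 237-bp mean, intron lengths lognormal
with median 70 bp (σ = 0.35, min 30), GT..AG ends, coding GC 0.45,
noncoding 0.35, genes on both strands with exponential intergenic spacers.
Every ancestral gene has a canonical start, stop and no internal stops.

Evolution applies, per site, the JC69 transition kernel for the configured
branch length (so divergence composes additively across branches), with
codon awareness in CDS: proposals are drawn uniformly among *viable*
(non-stop) neighbour bases, synonymous proposals always accepted,
nonsynonymous accepted with probability ω (default 0.25). Drawing
proposals among viable neighbours (rather than all three bases with
stop-rejection) makes the generator's site exposure match NG86's
viable-neighbour site accounting; with uniform-3 proposals the realized
silent divergence undershoots its target by several percent because
stop-adjacent synonymous sites (e.g. Tyr/Cys third positions) are counted
as full synonymous sites but rarely exposed. Start and terminal codons are
fixed; introns and intergenic DNA evolve neutrally with GT/AG pinned.
Ingroup branches default to 0.025 each (pairwise Ks ≈ 0.05) and may be set
asymmetrically; the outgroup branch is 4× the ingroup branch — comfortably
outside the ingroup divergence, well below JC saturation.

Injected artifacts (each one ledger row, one structural event per gene,
re-drawn on collision): false genes in genome B (single-exon, 150–450 bp,
GC 0.30, half with a premature stop, never expression-supported, random
sequence so they have no homolog anywhere); split models in B (one gene's
CDS re-annotated as two fragment models at an intron boundary, phases
recomputed, sequence untouched); in-paralog duplications in B (gene region
copied, CDS evolved to pairwise Ks 0.15, appended to the same scaffold);
intron gains (new GT..AG intron inserted at a uniform exonic position ≥ 6
bp from exon ends, all downstream coordinates shifted) and losses (an
ancestral intron — hence present in the outgroup — excised) on either
lineage; and geneless contaminant scaffolds (GC 0.60) added to genome A,
flagged bacterial in the emitted taxonomy table and given zero sperm
depth. Emission writes FASTA/GFF3 for all three genomes, samtools-style
depth TSVs, the taxonomy table, per-gene expression flags and the ledger,
byte-identically at a fixed seed (one seeded generator threads every
draw).

What the generator does *not* emulate: indels inside coding sequence
(frame-preserving or otherwise), rate variation among genes and sites,
transition/transversion bias, codon-usage bias, recombination,
heterozygosity within a lineage, assembly gaps, and fragmented or
misassembled scaffolds. Passing recovery tests therefore demonstrates
correctness of the detectors under clean, well-posed conditions — the
audit's discriminative power on real drafts (where alignment error and
annotation noise correlate) is expected to be lower, which is why every
threshold above is exposed as a parameter.

## Problem sizes and determinism

The test suite and the acceptance script run the estimator battery at 200
genes per condition (~450 codons per gene) and the classifier battery on
the default configuration (200 genes plus 117 injected events), sizes at
which the recovery targets (mean Ks within 10%, ω within ±0.05, counts
within ±1, recall/precision ≥ 0.95) are comfortably inside the estimators'
sampling error. All randomness flows from a single seed; fixed-seed runs
are byte-reproducible end to end, and the suite uses seed 1 throughout by
convention.

## Known limitations

* NG86's equal path weighting slightly biases Ks/Ka at higher divergence
  (see above); no ts/tv-aware or maximum-likelihood estimator is provided.
* The e-value surrogate is a normalized local score; absolute thresholds
  are not transferable to BLAST statistics.
* Orphan classification depends on the supplied reference proteomes; with
  none, "unassigned" absorbs unclustered genes with outgroup homology
  only.
* Intron mapping requires an annotated outgroup gene model (FASTA +
  GFF3); outgroups supplied as bare CDS/protein FASTA cannot be queried
  for intron presence and the intron stage is skipped.
* The evidence-consensus stage consumes labelled candidate gene sets; it
  does not model evidence quality beyond presence/absence.
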