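# Methods

## Scope and data model

The pipeline operates on annotation-level and hit-table-level data only: it
consumes genome annotations (GFF3/TSV), protein-family homology hit tables,
domain hit tables in protein coordinates, aligned FASTA, and newick trees.
It does not run BLAST, ClustalW or tree inference itself; hit tables, trees
and alignments are inputs (real or simulated). All genomic and protein
coordinates are 1-based inclusive (the GFF3 convention); gene-order ranks
within a replicon are 0-based and assigned by sorting on start coordinate,
so results are independent of feature order in the input file. Protein ids
are namespaced `genome|protein` as soon as genomes are pooled.

## Co-occurrence screen

A family is *present* in a genome iff at least one retained hit (e-value ≤
`evalue_max`, default 1e-5; best hit per protein/family) maps to a protein
annotated on any replicon of that genome. "SufBC present" requires both
sufB and sufC, because the scaffold functions as a unit. The scaffold-free
count asks for sufT with none of sufB, iscU, nifU — the configuration seen
in lactobacilli, whose sufT instead sits in an operon with an FeS-requiring
enzyme. Percentages are reported to one decimal place with round-half-even,
matching how such screens conventionally print fractions. Genome totals are
parameters throughout, never constants: published snapshots of "all
complete genomes" are version-dependent, so no count is hard-coded.

## Operon association rule

A sufT homolog is *suf-operon associated* iff

1. its rank offset to the nearest sufB/sufC gene on the same replicon is
   ≤ `max_orf_distance` (default 4; adjacent = 1; 0 only when sufT lies
   inside the block's rank span, as in some actinobacterial operons), and
2. the rank-contiguous chain of genes linking it to (and through) the block
   is plausibly one transcription unit: a single shared strand and every
   intergenic gap ≤ `gap_max_bp` (default 150 bp).

Condition 2 is a declared stand-in for "transcribed from a common
promoter": a standard distance-and-strand operon-prediction heuristic. The
150 bp default is the usual prokaryotic operon gap threshold and is
configurable precisely because it is a heuristic choice, not a measured
property. Chains are in rank order (= start-coordinate order), so
colinearity with the shared strand's transcription direction holds by
construction. sufB/sufC genes are grouped into blocks (rank gap ≤ 2); when
two blocks are equidistant the one with the smaller start coordinate is
used, for determinism. Homologs on a replicon without any block are
non-associated with distance "unlinked". Each homolog of a multi-copy
genome is assessed independently, and the partition counts homologs, not
genomes. The verdict is invariant under reversing the replicon's coordinate
system and under coordinate translation, and is monotone in both
thresholds (loosening never un-associates a homolog); all three properties
are tested.

## Modular architectures

Classification uses exactly one DUF59 hit per protein (anything else is a
hard error naming the protein) plus motif hits at e-value ≤ 0.01, the
conventional CDD screening threshold. Motif side is the motif midpoint
relative to the DUF59 span; midpoints inside the span are ambiguous and
ignored. Qualifying motifs map to their class (S3–S9 and explicit
`unknown_N` → S2); a protein with no annotated flank motif is S1 when both
flanks are shorter than `min_flank_aa` (default 30 aa) and S2 when the
N-flank is at least that long (an unannotated N-terminal extension is
exactly what defines S2). The 30 aa default is our choice of the smallest
flank that could plausibly hold an independent motif; no published length
rule exists for this class boundary. Two deliberate escape labels keep the
partition honest rather than silently binning: `composite` (qualifying
motifs on both flanks — the nine structures are single-flank) and
`unclassified` (long bare C-flank, or a qualifying motif on the side
opposite its canonical class). Classification is invariant to hit order and
to adding sub-threshold hits.

Core-region truncation maps ungapped reference positions (default 1–99, the
minimal DUF59 core in the Ta0200-style reference numbering; both reference
and range are configuration) to the smallest alignment-column window
containing them, by walking the gapped reference. Conservation scans count
only non-gap characters in the denominator, so a column that is cysteine in
every sequence that has a residue there is "strictly conserved" even if
some sequences are gapped.

## Parsimony and clustering

`fitch_score` is the classical union/intersection down-pass over a rooted
binary tree (bitmask state sets; k-state categorical traits work
unchanged). Unrooted inputs are rooted arbitrarily — the score is
rooting-invariant, which the tests verify over random rerootings — and
polytomies are binarized deterministically (children ordered by smallest
descendant tip label, combined left-to-right) with the result flagged,
since the score is then an upper bound for the original multifurcating
tree.

`count_events` decomposes a most-parsimonious binary reconstruction into
gains (0→1 edges) and losses (1→0). Rather than the classical Fitch
up-pass, it runs unit-cost dynamic programming (Sankoff) to get, for every
node and state, the exact minimum subtree cost, then traces back top-down
choosing a cost-minimizing child state at each edge. Ties are broken by
convention: DELTRAN keeps the parent's state (delays changes tipward),
ACCTRAN flips it (accelerates changes rootward). Because every traceback
choice is cost-minimizing, the labeling is exactly most-parsimonious and
`n_gains + n_losses = score` always (asserted at run time). A requested
root state outside the most-parsimonious set is an error, not a silent
override. This operationalizes "how often was the trait recruited and
lost" — a quantity screens of this kind usually read off a colored tree by
eye — as a reproducible statistic; it is our interpretation, and the
ACCTRAN/DELTRAN pair brackets the placement ambiguity.

The clustering test uses the parsimony score as statistic and uniform
shuffles of the tip-state vector (fixed state multiset) as the null, with
the +1-corrected p-value `p = (1 + #{null ≤ obs}) / (1 + n_perm)`. This is
the standard assumption-light test of phylogenetic signal for discrete
traits; because Fitch scores are small integers the null is discrete and
the test is conservative (p-values super-uniform), which the calibration
test quantifies. The RNG seed is a required argument; there is no hidden
global state.

## Synthetic data

The generator defines the study conditions under which the pipeline is
validated:

* **Cohorts.** Default 200 genomes of 50 ORFs each (gene lengths 300–1500
  nt, intergenic gaps uniform on 5–120 bp), with sufBC in 65.4% of genomes,
  sufT in 69.7% of sufBC genomes and 11.8% of the rest, and 49.15% of
  sufT-with-sufBC homologs operon-associated — the frequencies of the
  genome screen this pipeline is built around. Non-associated homologs are
  planted with an explicit mode — `far` (>4 ranks), `opposite_strand`,
  `big_gap` (400 bp), `other_replicon` — so every failure branch of the
  classifier is exercised and recorded in the ground truth. A configurable
  handful of lactobacilli-style genomes (sufT plus an FeS-enzyme operon
  partner, no scaffolds) and sub-threshold decoy hits (e-value above the
  family filter) are planted too. An exact-count planner
  (`plan_partition_cohort`) builds one-homolog-per-genome cohorts for exact
  partition-recovery checks.
* **Architectures.** Per planted class, a DUF59 hit plus flank motif hits
  with coordinates respecting the classifier's side/flank rules; default
  class proportions are the S1–S9 frequencies of the screen
  (563/88/75/20/5/4/3/2/1 over 761).
* **Trees and traits.** Yule trees (unit root-to-tip depth, ultrametric by
  default) via dendropy's birth–death sampler; binary traits evolve along
  branches under a two-state continuous-time Markov chain with gain/loss
  rates per unit branch length (defaults 0.5/0.5 on 100-tip trees), every
  change event recorded with branch and position. With equal rates the
  event count is Poisson with mean rate × total tree length, which the
  tests check against the analytic expectation; the recorded event count
  also upper-bounds the parsimony score in every replicate.
* **Alignments.** Uniform random amino acids with planted invariant
  columns; gaps sprinkled outside conserved columns (and outside the
  reference when a gapless reference is requested).

Everything is driven by `random.Random(seed)` — integer-state, platform
independent — and every emitted file parses with the package's own readers.

What the simulator does **not** emulate: realistic sequence evolution (no
substitution models behind the hit tables or alignments), paralog
complexity beyond one near-block homolog per genome, overlapping or nested
genes beyond what rank logic sees, and correlated gene content across the
cohort. Passing the recovery tests therefore shows the pipeline's rules are
implemented exactly as stated and are internally consistent — not that the
rules themselves are robust to annotation noise or unusual genome
architectures in real data.

## Problem sizes and numerical choices

The validation suite runs exhaustive Fitch-vs-enumeration checks on all
rooted binary topologies with 4–6 tips (all 2^n binary tip assignments)
and random samples at 7–8 tips; parsimony lower-bound checks over 500
trait simulations on 50-tip trees; permutation-test calibration over 1000
null-true replicates of 200 permutations on a 32-tip tree; and exact
ground-truth recovery on a 200-genome cohort plus a 761-genome
partition-planted cohort. These sizes give stable Monte-Carlo verdicts
(binomial standard error ≈ 0.7 percentage points for the calibration rate)
while keeping the whole suite fast.

Degenerate inputs are defined, not accidental: a single-gene chain is
trivially co-transcribed; an empty cohort yields a zero report; a constant
trait is an error for the clustering test (the statistic is undefined);
e-value ties in best-hit selection break by score then row order;
architecture count maps omit zero-count labels.

## Known limitations

* The co-promoter heuristic cannot see promoters; internal promoters or
  long leaders will misclassify borderline operons in real data.
* Gain/loss decompositions are convention-dependent wherever the
  most-parsimonious reconstruction is ambiguous; only the score itself is
  convention-free.
* Polytomy binarization makes parsimony scores upper bounds on
  multifurcating trees (flagged in results).
* The architecture classifier trusts its domain-hit input; split or
  truncated DUF59 hits must be resolved upstream.
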