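# Methods

## Coordinate and strand conventions

All internal coordinates are 0-based half-open on the forward genomic
axis; GFF3 (1-based inclusive) is converted at the I/O boundary and
nowhere else. Plastomes are circular by default: upstream windows,
gene-extension searches and distance arithmetic wrap through the origin.
On the minus strand a transcript's 5' end is the interval's larger
coordinate, and every "upstream"/"downstream" computation is
strand-aware. Inverted-repeat gene copies share an id; both records are
kept and flagged as duplicates rather than merged or renamed.

## The dRNA-seq count model

The generator emulates the observable signature of TEX treatment rather
than simulating reads. A planted primary TSS of strength `s` yields
TEX− 5'-end counts ~ Poisson(`s`·depth/1e6) and TEX+ counts ~
Poisson(`α·s`·depth/1e6); a processed 5' end yields TEX− ~ Poisson(`s`)
and TEX+ ~ Poisson(`surv·s`). Defaults: `α = 2.5` (the fold enrichment
measured at the psbA primary 5' end after TEX treatment), survival
`surv = 0.2`, Poisson background 0.05 counts/base, depth 1e6 mapped
reads per library, gene-body coverage decaying geometrically at
0.999/nt for 600 nt downstream of each 5' end (both libraries for
primary ends, survival-scaled in TEX+ for processed ends). Total mapped
reads are recorded as the nominal depth, so expectations scale linearly
with depth and normalized values are depth-invariant.

Processed 5' ends are placed uniformly inside gene bodies at one per
300 nt with strengths U(20, 80). The strength floor is a calibration
choice: at default survival the TEX+ expectation of the weakest
processed site is then 4 per million — clearly above the tier-3 floor
(0.5) and clearly below its own TEX− signal (20+), so processed sites
are robustly non-enriched and tier separation does not ride on Poisson
tails. Planted primary TSSs (default 40, strengths U(10, 100), 20–150 nt
upstream of gene starts) clear the 2-per-million tier-1 floor by
construction.

What the generator does **not** model: read-level artifacts (mapping
bias, soft-clipping), RNA secondary structure, partial TEX digestion
heterogeneity, transcript 3' ends, and realistic plastome gene content
(genes are random intervals with real ATG start codons, one forced
two-gene operon, and a 75/25 CDS/tRNA mix). Passing tests therefore
demonstrate correctness of the calling rules under the stated count
model, not robustness to library-preparation artifacts.

## Tier rules — operational choices

The printed rule fixes only the 2-per-million floors, the identical-
nucleotide requirement and the >1 enrichment. Everything else is an
operational decision, configurable in `ClassifierConfig`:

- "at least >2 per million" is read as strictly greater than 2.0.
- Candidates are strand-specific local maxima of the TEX+ 5'-end track
  within ±3 nt; candidates within 5 nt merge to the highest value
  (leftmost on ties). `same_start` requires a TEX− local maximum at the
  identical nucleotide.
- "Extended into an annotated gene" = containment in a same-strand gene,
  OR a same-strand gene start ≤ 500 nt downstream with TEX− body
  coverage ≥ 1 per million over ≥ 90% of the intervening bases. The
  enrichment ratio is computed on 5'-end tracks (TSS evidence is a
  5'-end property); body coverage is used only for this continuity test.
- Tier 3 additionally requires TEX+ 5'-end coverage > 0.5 per million,
  preventing background positions with chance −10 matches from being
  called.
- No pseudocount in the enrichment ratio: TEX− = 0 makes the ratio
  undefined (reported as such), and such positions can only enter via
  tier 3.
- Classification precedence (iTSS/aTSS before gTSS) is forced by the
  operon case in which a TSS inside an upstream gene, 141 nt before the
  next gene's start, is internal. The gTSS window W = 300 nt is
  conservative against observed gTSS distances up to ~144 nt. Ties break
  by nearer start codon, then lower gene coordinate. CDS, tRNA and rRNA
  features are all eligible.

## Promoter scanning

Consensus patterns carry case semantics (uppercase weight 2, lowercase
weight 1); a window subsequence scores the sum of weights at matching
positions, compared case-insensitively with IUPAC degeneracy. The
default threshold is max−1: all strongly conserved positions must match
and at most one weakly conserved position may miss. Spacing is counted
between the element's 3' end and the TSS; the legal −10 range is 3–9 nt
and ties go to the smaller spacing. The −35 scan runs 15–19 nt 5' of
the −10 element (a standard sigma-70 spacer convention) with a
user-supplied pattern, and absence is a valid result. The weight scheme
and threshold are package conventions, not measured energies; both are
configurable.

## Conservation and footprints

Column similarity is the count of the most frequent A/C/G/T residue
divided by the number of rows. Gaps count in the denominator by default
(a gapped species is evidence against conservation; `ignore_gap_rows`
flips this), N is never counted toward the majority, and an all-gap
column scores 0. Display bins are half-open downward: black = 1.0
exactly, dark gray [0.8, 1.0), light gray [0.6, 0.8), white below 0.6.
ATG-relative offsets count ungapped reference-row (first sequence)
positions: the A of ATG is +1, the base before it −1, no position 0;
a reference-gap column inherits the offset of the nearest reference
base toward the anchor. Footprints are maximal runs of ≥ 6 columns with
similarity ≥ 0.8 inside the search window (−100..−1 by default),
never bridged across a sub-threshold column — parameters chosen to
match the scale of experimentally mapped angiosperm PPR footprints, all
configurable.

The alignment generator guarantees the planted conservation level by
construction: in each footprint column exactly ⌈level·n⌉ rows carry the
consensus base (Bernoulli sampling could dip below the stated level).
Background columns are i.i.d. uniform over ACGT with 2% gap probability
in non-reference rows; for 30 species the background majority fraction
sits near 0.33, far from the 0.8 calling threshold.

## Parts and Type IIS syntax

Only the 5'UTR–CDS junction of the common syntax is modeled: the
standard AATG overhang inserts one adenosine, the custom ATGg overhang
requires a G as the fourth CDS base and inserts nothing. Full L0→L2
assembly simulation is out of scope. The transversion map A↔C/G↔T was
chosen because it has no fixed points (every targeted base changes) and
is an involution, which the tests exploit; shuffling uses a seeded
permutation. Mutated parts are re-screened for accidentally introduced
BsaI/SapI sites, which raise a warning. Parts are always reported 5'→3'
on the transcript strand.

## Imaging pipeline

Segmentation uses only the chlorophyll channel: Gaussian smooth (σ = 2
px) → Phansalkar threshold (radius 15, p = 2, q = 10, k = 0.25,
r = 0.5) → removal of objects < 10 px → distance-transform watershed
with seeds at local maxima of the (σ = 1 smoothed) distance map,
minimum separation 5 px. The local window is a (2·radius+1) square with
reflected edges; the smoothed distance map avoids spurious seed pairs
on elongated plastids. A minimum-intensity floor (10% of dynamic range)
is intersected with the threshold mask: where both local mean and SD
approach zero the Phansalkar threshold degenerates toward ~2.75·μ → 0
and would otherwise mark near-zero background as foreground. All
parameters are conventional defaults and configurable.

Ratios are per-ROI mean CFP / mean chlorophyll; since depth attenuation
multiplies both channels identically, the ratio is exactly invariant to
it. ROIs with zero chlorophyll mean are dropped (logged). Aggregation is
strictly hierarchical — ROI → image (mean of ROI ratios) → line (mean of
image means with standard error) — never pooling ROIs across images.
Z-stacks are handled per-slice with per-image pooling. The image
generator places elliptical plastids on a 32 px grid (non-overlapping by
construction; optional tangent pairs for watershed tests), base
chlorophyll intensity 0.6 of dynamic range, per-plastid attenuation
e^(−z/τ) with z ~ U(0, τ), i.e. down to e^−1. It does not model
spectral bleed-through, 3-D point-spread, or structured backgrounds.

## Problem sizes and tolerances in the tests

The tier-rule fidelity check uses 1000 candidates drawn from a value
grid straddling every threshold (0, 0.4, 0.5, 0.51, 1.0, 1.9, 2.0,
2.01, 2.5, 3.0, 8.0 per million) and demands exact agreement with a
hand-coded evaluator. TSS recovery runs ten independent 120 kb
simulations (40 planted TSSs each) and requires tier-1 recall and
precision ≥ 0.9 with zero processed-site leakage. The classifier is
compared exactly against an exhaustive-scan oracle on 1000 random
genome/TSS pairs. Footprint recovery uses 30-species, 120-column
alignments across 20 seeds (mean Jaccard ≥ 0.8); ratiometric recovery
uses 16 plastids × 5 seeds with noise SD 0.02 against signal 0.6·e^(−z)
(mean relative error ≤ 5%). These sizes keep the full suite under a few
seconds while leaving the statistical margins wide.

## Known limitations

- TPM is computed from given per-transcript counts; multi-mapping
  resolution and quantification from reads are upstream concerns.
- Motif discovery is out of scope: the scanner verifies and locates
  user-supplied consensus elements only.
- Alignments are consumed pre-computed; no aligner is invoked and no
  phylogenetic weighting is applied.
- The enrichment-state EQUAL label uses exact float equality of
  normalized values and exists for display parity; the tier rules use
  strict inequalities throughout.
- The tier rules are evaluated on 5'-end count tracks, treating TSS
  evidence as a 5'-end property; full-body coverage enters only through
  the tier-2 continuity test. Both thresholds and the continuity
  definition are configurable for users who prefer windowed coverage.
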