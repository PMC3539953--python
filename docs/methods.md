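# Methods

This note documents the models and procedures estforge implements, the
parameter defaults and why they were chosen, the numerical conventions, and
what the synthetic-data validation does and does not establish.

## Trimming

Poly-A (3') and poly-T (5') tails are defined as terminal runs of at least
`min_tail_length = 4` matching bases allowing at most
`tail_mismatches_allowed = 1` non-matching base strictly inside the run (the
innermost base of a run must match, so the trimmer never eats past the tail
into the read body). Because removing one admissible run can expose another
one within a fresh mismatch budget, a single pass is not idempotent; the
trimmer therefore iterates to a fixed point.

Terminal-N trimming advances inward from each end while any window anchored
at the terminus exceeds the N-fraction threshold; windows shorter than
`window = 30` (near sequence ends) use their actual length as denominator,
which in particular forces removal of every terminal N. The constants
(window 30, threshold 20%) are the classical `trimseq`-style defaults for
EST cleanup. Tail and N trimming are interleaved to a joint fixed point —
library artifacts place terminal Ns outside the poly-A tail, so each pass
can expose work for the other — making the combined operation idempotent,
which the property suite checks on random sequences.

`min_length_after_trim = 100` is this package's floor (single-pass reads
below ~100 nt carry little mapping information); it is exposed in the
config and reported, not hard-wired.

## Assembly

The assembler is a deterministic greedy best-overlap-first agglomeration.
Overlaps are ungapped placements (suffix–prefix or containment, both
orientations): for a candidate offset, identity = matching columns /
overlap columns. Candidate offsets are enumerated exhaustively for small
pairs and seeded by shared k-mers (k = 14) for large ones. An overlap is
admissible when it spans ≥ `min_overlap_length = 40` columns at identity ≥
`overlap_identity = 0.80` (the classical EST-assembly identity cutoff; the
same threshold governs containment). The best admissible overlap —
highest identity, then longest, then lexicographically smallest id pair —
is merged; the merged consensus is re-called by per-column majority vote
over the member ESTs (ties resolved by the earliest-added member covering
the column) and the process repeats. Ungapped overlaps are a deliberate
v1 simplification: single-pass EST disagreements are dominated by
substitutions, and the trimming stage removes the indel-rich termini.

Published contig/singleton counts from other assemblers are tool-specific
and not a contract of this module; the contract is conservation (every EST
placed exactly once), determinism under the stated tie rules, and exact
reconstruction of low-similarity transcripts from error-free tiled reads,
which the acceptance suite verifies for 50 transcripts.

## Mapping and best-hit filtering

`align_local` is a Smith–Waterman local alignment under the NUC44 scoring
matrix with a linear gap penalty of 8 per gap base; both EST orientations
are tried. The NUC44 table is generated, not transcribed: the score of two
IUPAC codes is the mean of the canonical +5/−4 match/mismatch scores over
all base pairs the codes denote (so A·N = −1.75, kept as floats). Hits are
ranked by raw alignment score; an explicit E-value model is intentionally
absent (score ranking preserves per-species best-hit semantics without a
database-size model). "Support of 80%" is interpreted as EST coverage —
the aligned EST span divided by EST length — matching the phrase's
reference to the EST sequence; the best hit per EST per species is the
highest-scoring hit with coverage ≥ 0.80, ties broken by identity then
transcript id.

For throughput, candidate transcripts are pre-screened by a packed k-mer
index (k = 12): votes are binned by (transcript, strand, diagonal bucket),
candidates far below the best-voted one are discarded, and the alignment
runs in a diagonal band (half-width 50) around the voted diagonal. The
screen is a heuristic: an EST sharing no k-mer with a transcript cannot be
found. `AlignmentParams(prescreen=False, band=None)` restores exhaustive
full-matrix search, and the test suite verifies that the screened path
reproduces the exhaustive scores on overlapping-read fixtures.

Region transfer walks the alignment column map: each aligned EST position
inherits the region (5'UTR / CDS / 3'UTR, from the reference's 1-based
inclusive CDS interval) of its paired transcript position. An EST counts
as "annotated with" a region from one aligned base; per-region aligned
lengths and EST-coordinate intervals are reported so stricter filters can
be applied downstream. Transcript coverage is the spanned fraction of the
transcript (interval span / length); quasi-complete means coverage > 0.90.
Transcripts without CDS annotation are excluded from region analyses and
counted.

## Over-representation

The right-tailed Fisher exact test is the hypergeometric upper tail
P(X ≥ gen_a) with X ~ Hypergeom(universe_size, gen_b, universe_hits),
evaluated through `scipy.stats.hypergeom.sf`; Benjamini–Hochberg
adjustment uses `statsmodels` (`fdr_bh`). Both are checked against
exact-integer enumeration oracles. The gene universe is not dictated by
the method; the default — all genes of the supplied GMT collection plus
the mapped genes — is overridable, and gene sets are intersected with the
universe before testing. The reported `minus_log10_q` column is base 10.

## Distances and trees

For a species subset, the common EST set contains the ESTs with a
qualifying best hit in every species. Per EST and species the aligned
transcript subsequence (alignment interval ∩ region interval) is
extracted; the focal species is represented by the EST's own bases aligned
to a designated annotation species within the region. Each pair of
per-species sequences is globally aligned (Needleman–Wunsch, NUC44,
g = 8, deterministic diagonal > up > left traceback); the p-distance
counts differing sites among gap-free columns where both bases are
canonical (A/C/G/T); the Jukes–Cantor ML transform gives
d = −(3/4)·ln(1 − (4/3)·p), with p ≥ 0.75 raising a saturation signal
that drops the pair from averaging. The matrix entry is the arithmetic
mean of d over ESTs with a finite distance. Distances, not scores, are
what gets averaged for tree building — the named method estimates a
distance; `average_score_matrix` separately reports mean alignment
scores (rescaled by 1e-4) for presentation parity with score-matrix
conventions, but scores are similarities and feed no tree. Cells with no
finite pair are missing and refuse UPGMA.

UPGMA merges the closest pair (ties: lexicographically smallest
representative-label pair), places the new node at half the merge
distance, and updates distances by the size-weighted group average. On an
exactly ultrametric input the algorithm is an exact inverse — the tree's
induced path distances reproduce the matrix — which the acceptance suite
checks to 1e-9 on random ultrametric matrices. Robinson–Foulds
comparisons use dendropy as an independent implementation.

In the recovery harness the pairwise global alignments run with a
diagonal band (half-width 64, auto-widened past any length difference):
the generator introduces no indels, so the optimal path is near-diagonal
and the band is exact there. Exact full-matrix alignment remains the
default of the public `nw_align`/`pairwise_distance` API.

## Synthetic data

The generator's defaults are the study conditions the pipeline targets:
a 5-taxon ultrametric tree
`(((hsap:0.01,ptro:0.01):0.01,(csab:0.015,mmul:0.015):0.005):0.01,cjac:0.03);`
with branch lengths in substitutions/site at rate multiplier 1, focal
species `csab`; 200 transcripts (5'UTR 60–300 nt, CDS 300–900 nt, 3'UTR
90–450 nt, uniform); region rate multipliers 5'UTR 2.0 > 3'UTR 1.5 > CDS
1.0, encoding the weaker conservation of untranslated regions; 1,000 ESTs
with truncated-Normal(563, 167) lengths on [100, 1200] (the empirical PBMC
EST length distribution), uniform start positions, 50% strand flips, 0.5%
per-base substitution errors, poly-A tails (p = 0.4, 8–20 nt) and terminal
Ns (p = 0.15 per end, 1–8 nt), with a rank-power-law (α = 1) abundance
skew mimicking the heavy head of real expression rankings. Evolution is
exact JC69: per branch each site substitutes with probability
(3/4)(1 − e^(−(4/3)·d)) to a uniformly chosen other base, so the expected
p between two species is the closed form at their (region-scaled,
boost-adjusted) path length and the JC estimator is unbiased for it —
generator and estimator are mutual oracles. Per-lineage rate boosts apply
to a leaf's terminal branch only; the default tree's heights (sister
split 0.015, family join 0.020) were chosen so that a 3× 5'UTR boost on
the focal terminal branch moves the boosted 5'UTR sister distance
(0.015·3·m + 0.015·m) past the sister-to-other-clade distance (0.040·m),
flipping the focal leaf out of its sister pair in the UPGMA tree — the
qualitative region-effect phenomenon the region-restricted trees exist to
detect — while leaving the CDS topology intact.

What the generator does **not** emulate: indels (region coordinates stay
exact across species, as the region-transfer logic assumes), isoforms and
splicing, within-species polymorphism, chimeric reads, vector
contamination, and quality scores. Passing recovery tests therefore show
correctness of the statistical machinery under the stated model, not
robustness to structural variation in real libraries.

## Problem sizes and determinism

The acceptance suites run the recovery analysis at 200 transcripts and
1,000 ESTs over 20 simulation seeds (10 in the standalone acceptance
script), sizes at which the binomial sampling error of the mean distances
is far below the 10% relative-error contract while a full run stays in the
minutes range on one CPU. All randomness flows through
`numpy.random.default_rng` seeded from the config; reruns with the same
seed are bit-identical (manifest checksums included), and hit/annotation
tables carry a provenance header with tool version, config hash and seed.

## Degenerate inputs and edge conventions

Empty libraries warn and return empty results; empty sequences are dropped
before alignment; an all-N read trims to the empty string; a distance
matrix cell with no finite pair is a missing-value marker that UPGMA
refuses; alignments with zero comparable columns raise an
undefined-distance signal rather than returning 0. Coordinates are
0-based half-open internally and 1-based inclusive in every TSV output.

## Known limitations

Ungapped assembly overlaps; linear (not affine) gap penalties; no
model beyond JC69 (no K2P/GTR) and no bootstrap support; pairwise (not
multiple) alignment throughout; the k-mer prescreen can miss extremely
diverged orthologs (use exhaustive mode for small reference sets); no
spliced/genomic alignment. These mirror the scope of the classical EST
workflow the package implements.
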