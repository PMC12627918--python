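# Methods

This note documents the models, conventions and numerical choices behind
`metaresolve`, and what the synthetic benchmarks do and do not demonstrate.

## Error model

The unit of analysis is the unordered sequence pair. With BINs as the
species-proxy truth, a threshold S_T classifies each pair as "same taxon"
(S_XY >= S_T) or "different taxa" (S_XY < S_T):

- **over-splitting rate** at S_T: the fraction of intra-BIN pairs with
  S_XY < S_T (same species called different);
- **over-merging rate** at S_T: the fraction of inter-BIN pairs with
  S_XY >= S_T (different species called the same);
- **global error** GE(S_T) is their sum; **S_OPT** is the grid threshold
  minimizing GE, with ties broken toward the lower threshold.

Over-splitting is non-decreasing and over-merging non-increasing in S_T by
construction, so GE is well-behaved on the grid. Denominators are always
*all* pairs of the relevant class in the dataset: pairs dropped by the k-mer
prescreen (below 90% estimated similarity) count as non-errors for
over-merging and as errors for over-splitting, which is exact for any
S_T at or above the prescreen threshold. The same pair-level definitions
score OTU partitions: an intra-BIN pair split across OTUs is an
over-split; an inter-BIN pair sharing an OTU is an over-merge.

## Pairwise similarity

S_XY is the ratio of matching columns to alignment length, terminal gaps
excluded. The alignment is a free-end-gap (overlap) alignment under unit
scoring (match +1, mismatch -1, gap -1); among score-optimal alignments the
one with the most matching columns is used, then the fewest columns.
A pure edit-cost minimization with free ends is degenerate — the empty
overlap costs nothing — so the match reward is required; with it, the
aligner reproduces the global-identity behaviour of standard similarity
tools at default scoring. Internal gap columns count toward the alignment
length (as non-matches); "N" and any two different IUPAC codes are
non-matching columns.

Similarities are stored as exact integer pairs (matches, columns) and
compared with thresholds as rationals, so a pair at exactly S_XY = S_T is
classified identically on every platform. The dynamic programme packs the
lexicographic objective into a single 64-bit key and is compiled with
numba; an independent memoised exhaustive search (itself validated against
literal path enumeration) serves as the test oracle.

The k-mer prescreen is deliberately permissive: on indel-free data a pair
at similarity >= t over length L has at least (L - k + 1) - k*floor(L(1-t))
shared k-mers, so true candidates are never lost; extra candidates merely
cost compute.

## Metabarcode extraction

Primer sites are located with at most five primer-template mismatches and
at most one insertion or deletion, counted separately. A degenerate primer
position matches at zero cost any template base within its IUPAC expansion;
a template base outside the expansion (including ambiguity codes not
covered) is a mismatch. Both strands are searched. For each sequence the
forward/reverse site pair whose implied insert length is closest to the
documented mean is retained, ties broken by fewest total primer errors,
then leftmost position. Consensus start/end columns are the modes over all
sequences (ties toward the smaller column), and the extracted metabarcode
is the *insert* — primer-binding regions excluded — which matches published
per-metabarcode lengths (e.g., 63 bp for the shortest 12S marker).
Reverse-orientation primer sets are located by swapping the primer roles on
the sense strand; the extracted insert is reverse-complemented into
metabarcode orientation so each metabarcode set shares one strand
convention. Indels inside a primer match shift the insert boundary to the
template position adjacent to the primer's terminal aligned base.

QC rejects extractions shorter than half the first quartile of lengths,
longer than twice the third quartile (quartiles by linear interpolation;
skipped with a warning below four sequences), or with more than 10%
missing nucleotides. Long, highly degenerate primer sets that cannot be
matched reliably produce a clean per-sequence "no amplicon" outcome, not a
failure.

## Metabarcode gaps

For the ladder BIN > genus > family > order, each level's distribution
collects, per taxon, the similarities of sequence pairs from *different
sub-taxa* of that taxon (sub-taxa: sequences, BINs, genera, families
respectively); only taxa with at least two sequences from two different
sub-taxa contribute, each at equal weight. The gap between adjacent levels
is (Q1 of the upper-level distribution + Q3 of the lower-level
distribution) / 2, with quartiles by linear interpolation between order
statistics. The default summarises each taxon by its mean before taking
quartiles; the all-pairs variant pools raw pair similarities instead
(weighting taxa by their pair counts) and is a first-class option.

## De novo clustering

- **Hierarchical linkage** (single = nearest neighbour, complete = furthest
  neighbour, UPGMA) operates on distance 1 - S_XY via
  `scipy.cluster.hierarchy`; the dendrogram is cut at 1 - C_T/100
  *inclusively* (merges at exactly the cut height are applied, mirroring
  the S_XY >= S_T convention; a 1e-9 tolerance absorbs binary-float
  representation differences, negligible against the data's similarity
  granularity). Missing (prescreened-out) pairs are treated as maximally
  distant.
- **SWARM-style**: sequences within d edit differences (computed with
  edlib) are linked; OTUs are connected components. d =
  floor(L_max * (1 - C_T/100)) — the threshold's complement, since C_T is a
  similarity; the literal product with C_T (which would collapse everything
  into one OTU) is selectable for audit only.
- **Greedy centroid**: scan by decreasing length (ties by identifier; all
  reference sequences have abundance 1), joining the first centroid at or
  above C_T, else opening a new centroid.

OTU counts are non-decreasing in C_T for the dendrogram cuts and for the
d-difference components by construction. For the greedy scan this is an
empirical regularity on hierarchical data, not a theorem: on star-shaped
similarity structures the centroid set itself changes with the threshold
and small count inversions can occur.

## Synthetic data

The generator simulates one root sequence per gene and evolves it down the
hierarchy with independent per-branch substitutions (uniform among the
three alternative bases, no indels). Branch rates are chosen so the
*expected pairwise divergence* between two sequences whose deepest shared
rank is BIN/genus/family/order equals d_bin/d_genus/d_family/d_order
(defaults 1%, 8%, 15%, 22% — magnitudes typical of fish mitochondrial
genes at those ranks). Realized Hamming divergence is slightly below the
nominal value because two lineages can hit the same site:
E[divergence] = d - (4/3)(d/2)^2, which the calibration tests use. Default
gene lengths (12S 950, 16S 1700, COI 1550, CytB 1140 bp) keep the rRNA
length filters meaningful.

Primer planting writes 5'-site + insert + reverse-complemented 3'-site at
fixed in-gene offsets (stacking multiple sets per gene left to right), with
degenerate positions resolved uniformly and *exactly* the requested number
of mismatches per primer copy. Planted mismatch bases are chosen outside
the IUPAC expansion of their own and both neighbouring primer positions,
at internal positions only: otherwise a single-indel shift in the site
search can realign a mutated base with a neighbouring primer base and
silently absorb one planted mismatch, blurring the budget boundary the
tests rely on.

Because evolution is substitution-only, the true alignment is the identity:
unaligned per-gene FASTA doubles as the alignment consumed by extraction,
and similarity expectations have closed forms. What passing tests therefore
do *not* show: robustness to real indel variation, alignment-construction
error, rate heterogeneity among sites, codon structure, chimeras or
sequencing noise. Indel handling is exercised separately with hand-built
fixtures at the primer-matching and alignment level.

## Mock communities

A community is drawn by sampling `n_bins` BINs uniformly without
replacement, then `seqs_per_bin` sequences per BIN (exhaustively, with a
record, when a BIN is smaller). Sampling is fully determined by
(seed, replicate index). Each community is clustered (UPGMA by default —
the tree-cut semantics of Neighbour-Joining are not defined here, and the
deviation is carried in every result row's method field) and scored against
the BIN truth. Vacuous error classes (one BIN sampled: no inter pairs;
redundancy one: no intra pairs) are flagged, encoded zero, and excluded
from trend statistics. The richness trend statistic is the Spearman
correlation between richness and the over-merging rate at a fixed C_T over
all replicates with a defined rate; the fixed threshold is taken just
below the genus-level similarity plateau (93% at the default divergences),
where merging across BINs of one genus is possible and the
over-splitting-to-over-merging transition is visible.

## Problem sizes and determinism

The test suite and `scripts/acceptance.py` run entirely on generated data:
oracle comparisons use up to 200-sequence datasets and 50x50 matrices;
threshold-recovery uses 50 seeds of a 16-sequence hierarchy scored on
1,200 bp sequences; extraction recovery uses 1,000 mitogenomes; the mock
sweep uses a 40-BIN reference with 5 richness levels x 20 replicates.
These sizes give stable statistics (binomial standard errors well inside
the asserted margins) while keeping the full suite in the low minutes on
one CPU. All randomness flows from explicit seeds; reruns are
byte-identical.

## Known limitations

- Real GenBank taxonomy lines are parsed heuristically (suffix-based rank
  inference); the TSV taxonomy input is authoritative.
- The aligner is exact but quadratic; all-vs-all on tens of thousands of
  long sequences would need the prescreen plus banded heuristics that are
  intentionally out of scope.
- BIN labels are consumed as input; nothing here re-derives BINs, queries
  remote databases, builds multiple sequence alignments, or fits the
  mixed-effects models used for downstream statistical summaries.
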