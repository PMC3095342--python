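# Methods

This note records the models, algorithmic choices and knobs behind
plastidmark, and what the simulation-based tests do and do not
demonstrate about real data.

## Quadripartite structure detection

The detector finds the longest pair of disjoint, *exactly*
reverse-complementary segments of length ≥ `min_len` (default 1,000 bp)
by seed-and-extend: k-mers of the sequence are matched against an index
of the reverse complement at a sparse anchor stride chosen so that any
repeat of the minimum length must contain an anchor, and anchor hits
are extended to maximal matches. On circular genomes the scan runs over
the doubled sequence and coordinates are normalized modulo the genome
length, which makes detection rotation-invariant. Ties between equally
long candidate pairs are broken by smaller SSC, then lower start
coordinate. Exactness is a deliberate restriction: inverted repeats
with internal mismatches are out of scope, and the trade is that every
detection result is verifiable (`IRa == revcomp(IRb)` is asserted).

Partition convention: intervals are 0-based half-open; one region may
wrap the circular origin (its `end` exceeds the genome length). The
single-copy gap following IRb is the SSC (the smaller gap), the other
gap the LSC.

Genome statistics: GC excludes N from numerator and denominator; the
coding fraction is the union of exon intervals over the genome length,
with the protein (CDS) component measured first and RNA defined as
coding − protein so the decomposition is exact even where features
overlap. A gene is IR-duplicated when annotated once inside each IR
(geometrically, or via an explicit `IR_duplicate` flag); distinct and
total gene counts are reported side by side without further
reconciliation.

## PCR walking and assembly

The tiling planner emits amplicons of `target_len` (default 2,500 bp,
i.e. the middle of a 2–3 kb walking design) stepping by
`target_len − overlap` (default overlap 200 bp); the amplicon count is
`ceil((L − overlap) / (target_len − overlap))` and the final amplicon
is truncated to the interval end. The assembler greedily merges the
fragment pair with the longest suffix/prefix overlap (both orientations
considered) subject to `min_overlap` 30, `min_identity` 0.95 and a
minimum alignment score of 40 under match +1 / mismatch −1 — the score
is this package's concrete interpretation of an otherwise unpublished
vendor scoring scheme. Ties break by overlap length then fragment id,
so assembly is deterministic.

## Gene functionality classification

Each query region (spliced gene sequence plus flanking context) is
compared against a functional reference CDS by **local** affine-gap
alignment (match +2, mismatch −3, gap open 15, gap extension 6.66 — the
alignment penalties of the classic MEGA configuration). Local rather
than global alignment keeps flanking intergenic sequence out of the
comparison and lets terminal truncations be read directly off the
unaligned reference ends.

Heavy affine penalties refuse to bridge deletions much longer than the
flanking arms, which would misread a large internal deletion as a
truncation. A *tail rescue* pass therefore re-aligns unaligned
reference/query terminal tails (≥ 20 bp on both sides, accepted at
≥ 0.8 identity) and merges the blocks, so the intervening span
surfaces as an ordinary deletion event. Multi-exon genes are compared
as spliced CDS; intron presence is not a lesion.

Premature stops are counted by translating the query's aligned
subsequence (gaps stripped) with the plastid/bacterial genetic code, in
the frame anchored at the reference start codon. This is the query's
de-facto reading frame, so stops created downstream of a frameshift are
visible; stop indices are codon positions in that frame, bounded by the
reference codon count, and the terminal stop is excluded.

Categories are assigned with a fixed precedence:

1. **absent** — coverage ≤ `absent_max_coverage` (default 0.10) or
   unalignable (identity below 0.5);
2. **truncated** — terminal truncation alone removes ≥ 10% of the
   reference (`truncated_max_coverage` default 0.90);
3. **frame shift** (`frame_disrupted`) — any indel event, explicitly
   including in-frame deletions;
4. **internal stop** — length unchanged and ≥ 1 premature stop;
5. **functional** otherwise.

The absent/truncated coverage cutoffs quantify qualitative field
definitions ("no sequence exists", "only partial coding sequences") and
are config-exposed; a terminal loss below 10% of the CDS classifies as
functional under these defaults, which is the documented behavior of
the knob rather than a claim about biology. Indels take precedence
over stops because a deletion that also creates a stop is conventionally
drawn as a frameshift in gene-structure surveys.

## In-silico PCR

Primer sites require an exact 3'-terminal base match and at most
`max_mismatch` (default 2) mismatches elsewhere; IUPAC-degenerate
primer bases match their expansion sets, and ambiguity codes in the
template count as mismatches. Scanning covers both strands and is
circular-aware (sites and products may span the origin). A region
amplifies only if exactly one compatible forward/reverse pair yields a
product, optionally within ±50% of the expected size; zero products is
the "no amplification" signal and multiple products (e.g. from an
IR-duplicated site) is an explicit ambiguity error. Wet-lab PCR is
more forgiving; this stringency is an artifact decision and every knob
is exposed.

## Progressive alignment

`align_region` is a deliberately simple, fully deterministic
progressive aligner: 6-mer profile distances feed an NJ guide tree;
sub-alignments are merged bottom-up by aligning their column-majority
consensus sequences globally with affine gaps (open 15, extension 6.66)
and propagating the induced gap columns into both profiles.
Consensus-based profile merging is a simplification of full
profile-profile scoring, adequate for the high-identity, small-indel
regions this package targets; anything harder should be aligned
externally and supplied pre-aligned (equal-length FASTA is accepted
everywhere an alignment is).

## Tree inference

- Distances: p or JC69 (`d = −(3/4) ln(1 − 4p/3)`), with complete or
  pairwise gap deletion (complete is the default, matching the usual
  "gaps excluded from the analysis" treatment). p ≥ 0.75 raises a
  saturation error naming the pair.
- NJ follows the standard Q-criterion with lowest-index tie-breaking;
  negative branch lengths are clamped to zero with the deficit moved to
  the sister branch. UPGMA returns the rooted ultrametric tree.
- Fitch scoring treats gaps and ambiguity codes as missing data and is
  vectorized over columns; multifurcations are resolved
  deterministically before scoring.
- The MP search runs `n_random_addition` replicates (default 100; the
  tests use 5–10, which saturates at ≤ 15 taxa) of stepwise addition
  from a random taxon order followed by NNI hill climbing to a local
  optimum, collecting all distinct best topologies. NNI rather than
  SPR/TBR is a documented simplification adequate at this scale. CI is
  computed over parsimony-informative characters, RI over all.
- Bootstrap resamples supermatrix columns with replacement (not
  stratified by partition, matching single-matrix practice), rebuilds
  each replicate with the chosen method, and takes a majority-rule
  consensus: a bipartition is retained when its support is ≥ the
  collapse threshold (default 50%, so support exactly at 50 survives a
  strict "< 50% collapses" rule) and compatible with every
  better-supported retained split. Supports are integer percentages on
  internal-node labels.

All stochastic steps consume a single explicit seed; fixed seed and
input order give byte-identical output.

## Pedigree congruence

Because plastomes are maternally inherited, the female-parent chain of
every variety terminates at a maternal founder, and taxa sharing a
founder must be a clade in a correct plastid tree. A group of ≥ 2 taxa
is *recovered* iff some edge bipartitions exactly that group; members
of recovered groups are correct, of unrecovered groups incorrect.
Singleton-lineage taxa are correct unless they attach inside the
minimal spanning subtree of another group (an intruder breaking it);
when no group of size ≥ 2 exists they are unevaluable. The score uses
bipartitions only, hence is rooting-invariant. This formalization is
one defensible reading of informal "correct placement by inspection";
per-taxon detail is reported precisely because real surveys show
individual anomalous varieties worth examining.

Subset evaluation builds a reference tree from all regions, then scores
each candidate subset's tree (same builder and seed protocol) by
placement correctness, Robinson–Foulds distance to the reference, and
total length, ranked in that order. The default scan enumerates
subsets of size ≤ 3 plus the full set with a single NJ tree per subset;
per-subset bootstrap is optional because 2⁸ subsets × 1,000 replicates
is not a desk-scale default.

## Synthetic data: what it emulates and what it does not

`simulate_plastome` plants the quadripartite structure exactly
(default 82,324 / 25,755 / 12,650 bp, total 146,484 bp) with uniform
random single-copy sequence at a target GC of 0.3732 and panel genes as
valid ORFs (start codon, sense codons, terminal stop, table-11 code).
The four IR junctions are made non-extendable so the maximal exact
inverted repeat is exactly the planted one; detection results on
simulated genomes are therefore deterministic in length.

Lesion injection applies at most one lesion per gene (composites are
rejected), records the expected category using the same precedence
rules as the classifier, remaps all downstream annotation coordinates,
and keeps the deletion junction of removed genes so a region around it
can still be "amplified" (and classifies as absent). The default
cohort spec mirrors a published-survey shape: ndhK lost and ndhJ
truncated everywhere, the 17 bp ndhC frameshift, three ndhG internal
stops (with a ~250 bp ndhG deletion in one genus group), assorted ndhD
truncations and ndhE lesions.

`simulate_maternal_pedigree` evolves eight marker regions (lengths
summing to 7,042 bp; the two spacer regions total 1,846 bp) along a
15-variety pedigree shaped like a commercial orchid panel: maternal
groups of 4, 6 and 3 plus two singletons. Founders drift independently
(star-like) from one ancestral region set at 0.05 subs/site — chosen
once as a realistic intergeneric chloroplast divergence and kept
analytically transparent; a non-star founder phylogeny can be supplied
via a custom pedigree. Each hybrid's regions are a mutated copy of its
female parent's at 0.02 subs/site per generation; the male parent
contributes nothing. Per-region rates scale with multipliers that
reproduce the usual variability ranking (spacers ≫ matK > coding
genes ≫ rbcL). Indels are off by default in the pedigree simulation so
distance models stay exact; lesion injection is the only indel source.

Passing tests on these simulations show that the pipeline's inference
is correct *under the generating model*: site-independent substitutions,
no rate heterogeneity (no GTR+Γ), no recombination or heteroplasmy, no
alignment error beyond what the simple aligner introduces, and clean
maternal inheritance. They do not certify performance on real
sequence with RNA editing, microsatellite slippage, or IR
expansion/contraction boundary effects.

## Numerical and degenerate-input conventions

- All coordinates 0-based half-open internally; GFF3 converted at the
  boundary. One partition interval may wrap the circular origin.
- Alignment co-optima: the first optimum reported by the (C-coded)
  pairwise aligner is used everywhere, so gap placement within repeats
  is deterministic but may sit anywhere inside the repeat.
- Distance ties in NJ/UPGMA and equal-score trees in MP break by lowest
  index / first enumeration; consensus ties break by support, split
  size, then lexicographic taxon sets.
- Seeds: every generator and search accepts one integer seed;
  pipeline stages derive per-stage seeds deterministically from the
  global seed, all below 2³¹.
- Problem sizes in the test suite are chosen for the desk: full-scale
  (146 kb) structure detection, 15-taxon trees, 100–200 bootstrap
  replicates, 10-seed recovery panels; the algorithms accept larger
  inputs with the expected polynomial cost growth.
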