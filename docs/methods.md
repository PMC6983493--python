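# Methods

## Coordinate and length conventions

All coordinates are 1-based inclusive (the VCF/GFF convention);
conversion happens only at parser boundaries.  DEL/DUP/INV carry
`length = end − start + 1`; INS carries the inserted-sequence length
with `end = start`, so every variant has exactly one unambiguous length
and clusters as the point *(start, end)* (INS degenerates to
*(start, start)*).  Consensus coordinates are arithmetic means over
cluster members rounded half-up, because integer genome coordinates are
required downstream; the rounded consensus length may therefore differ
from the consensus span by one.

One VCF subtlety: for interval types the writer emits END but not SVLEN.
htslib derives a symbolic record's end from SVLEN, when present, under
the REF-anchor convention (`end = pos + |SVLEN|`), which is off by one
against the span convention above; END alone round-trips exactly.

## Pair-distance deletion caller

The inner gap between FR-oriented mates is
`right.start − left.end − 1`, clamped to zero for overlapping mates.
Gaps strictly greater than `min_gap` (default 700 bp) witness a
deletion of interval `[left.end + 1, right.start − 1]` — the unique
convention making event length equal the observed excess gap.  The gap
is compared directly to the threshold, not to the threshold plus the
expected inner gap, because with a 260-bp insert and 151-bp reads the
expected inner gap is negative and the 700-bp margin already absorbs
the library spread.

Single-pair events are clustered on *(start, end)* with Euclidean
distances and Ward linkage; the tree is cut by the inconsistency
criterion (depth 2, coefficient threshold 1.15 — a widely used default
for that criterion; both exposed as parameters since no value is
canonical).  Flat clusters are then split so that neither the start nor
the end range exceeds `max_spread` (7 bp), and finally groups are
greedily re-merged (tightest pairs first) while both ranges stay within
the window.  The re-merge step exists because a tree cut can leave one
genuine event split across flat clusters; the 7-bp window, not the cut,
is the defining constraint of an event, and with it the output equals a
brute-force spread-bounded agglomeration whenever events are separated.

PCR-duplicate collapsing before support counting is available but off
by default: in an overlapping-mate library, genuinely distinct fragments
spanning the same junction routinely produce identical inner
coordinates, so collapsing on coordinates systematically undercounts
support.

## Meta-clustering

`cluster_at` is scipy's Ward linkage on raw Euclidean distances over
*(start, end)*, with flat clusters formed by cutting the dendrogram at
height *t* (cophenetic criterion, boundary inclusive).  Length and type
are deliberately not distance features; type homogeneity is enforced by
the filter stage, which also requires independent support — both
technologies in `cross_technology` mode, ≥ 2 callers in
`min_two_callers` mode.

The grid crosses 14 distance thresholds (5…1000 bp) with 22 minimum
read-support thresholds (4…1500).  The base clustering round at the
3-read entry cutoff is included as a 23rd support level: the stricter
grid levels are repetitions of that base round, and omitting it would
make calls supported by exactly three reads unreachable at any grid
point.  Deduplication across grid points uses exact equality of the
rounded consensus `(type, start, end, length)`; coordinate-distinct
near-duplicates are intentionally kept (the method's counts include
coordinate variants of one biological SV), with the representative at
each identity taken from the grid point with the largest total support
and the provenance of all emitting grid points merged.

Circularity is never handled by coordinate wrapping.  SVs longer than
half the genome are removed unless supported by ≥ 20 long reads and
≥ 3 callers, which targets the linearization-point artifact of mapping
a circular genome onto a linear reference; endpoints within one read
length of the reference ends can additionally be flagged.

For short-read-only datasets, `select_robust_subset` restricts analysis
to the `ceil(fraction × n)` most robust SVs (default fraction 4.98%, an
empirical calibration from a dataset sequenced with both technologies;
configuration, not a constant of nature): all two-caller SVs, truncated
or topped up by descending frequency, ties broken by higher support
then lower start.

## Frequencies and the Poisson burden

Reference coverage "at the SV position" is the mean per-base depth at
the two breakpoints (the single insertion point for INS) — breakpoint
depth is the quantity directly comparable to breakpoint-supporting
reads.  For a consensus cluster, the support entering the frequency is
the *mean* of member supports, not the sum: members are redundant
measurements of the same molecules by different callers, and summing
would multiply-count them.  Zero support yields frequency 0, flagged
as undefined when coverage is also zero.

Genome burden assumes the per-genome SV count is Poisson with rate
`λ = Σ f_i`; the burdened fraction is `1 − exp(−λ)`, and per-type
fractions combine multiplicatively (`1 − ∏(1 − f_type)`), which is
algebraically identical and verified to 1e-12 in the tests.  A
frequency of exactly 1 makes the per-variant rate `−ln(1 − f)`
undefined, hence the open interval requirement.

Gene impact: a deletion overlapping a gene truncates it; any other SV
is inactivating when at least one breakpoint falls strictly inside the
gene body and non-inactivating only when it spans the gene completely.
The "at least one" reading (rather than "exactly one") makes the
classification total — a duplication or inversion with both breakpoints
inside a gene still disrupts that copy's coding capacity.  A deletion
fully containing a gene counts as inactivating (the copy loses the
gene).

## TE junction scanning

Short-read junction rules: virus-exclusive segment ≥ 16 bp,
host-exclusive segment ≥ 16 bp, combined aligned length ≥ 130 bp of a
151-bp read, and signed read-interval overlap within [−5, 20]
(positive = shared bases, negative = unaligned micro-gap, so −5 permits
a ≤ 5-bp gap).  One junction per read — the largest aligned span, ties
broken by score then coordinates — making output independent of
alignment order.  PCR duplicates share the virus-side genome breakpoint,
the host element breakpoint and the orientation.

Long-read hits are resolved greedily by descending score (ties: lower
read start, then lexicographic target id), keeping a hit only when
disjoint from everything already kept; the result is pairwise
non-overlapping and every dropped hit overlaps a kept hit of equal or
higher score.  Completeness is the covered fraction of the TE
consensus, full-length at ≥ 0.95 (boundary inclusive, configurable —
no numeric criterion for "full-length" is canonical); an unknown
consensus length withholds classification.

"At a read end" means the TE interval includes read position 1 or the
final position, with no slack window — the strictest literal reading of
a segment that begins or terminates its read.  The enrichment test is
the exact upper-tail binomial probability `P(X ≥ k)` with
`p0 = total TE bp / total read bp` over all reads in the analysed set.
The per-superfamily insertion frequency
`unique reads / (unique reads + mean depth)` is an explicit stand-in
(the published tables of this kind do not state their formula) and is
exposed for replacement; the table-totalling logic does not depend on
it.

## Synthetic data: what it emulates, and what it does not

The generator targets desk scale: a 50-kb circular genome at 2,000×
depth with 100 planted SVs replaces the hundreds-of-kilobase genomes at
> 195,000× of real surveys, because detection counts scale with depth
and the tests target behaviour, not absolute counts.  Frequencies are
log-uniform on [1e-4, 0.05], reproducing a regime where most variants
sit below 1%; interval lengths are log-uniform on [50 bp, half the
genome].

Caller profiles: four short-read callers (breakpoint jitter σ = 2 bp)
and two long-read callers (σ = 15 bp — error-prone long reads map
approximately), each detecting a supported-type SV with probability
0.95 provided its binomially sampled support (`Binomial(depth, f)`) is
at least 1.  At the very deep coverage emulated, callers miss variants
mainly through support sampling, so the residual per-call dropout is
small.  False calls arrive at 0.002 × depth per caller with low
support.  The coverage track is flat at the nominal depth, binomially
reduced inside planted deletions.

Read pairs: background fragments are Normal(260, 30) bp with 151-bp
mates; deletion-spanning pairs are drawn `Binomial(depth, f)` per
planted deletion, with fragment length conditioned on exceeding two
read lengths (only such fragments can place the junction between the
mates) and the junction placed uniformly within the inner gap.

Chimera artifacts join two uniformly drawn breakpoints (≥ 50 bp apart),
are confined to one technology, and may appear in several callers of
that technology, mirroring a library-construction chimera shared by all
callers that consumed the library.

The generator does **not** emulate sequencing error, base quality,
alignment ambiguity in repeats, coverage waves, or read-level chimera
formation (artifacts are modelled at the call level, since the pipeline
consumes calls).  Passing recovery tests therefore demonstrate the
correctness of the clustering, filtering and estimation machinery under
the stated noise model — not caller performance on real reads.

## Numerical choices

- Rounding of consensus quantities: half-up (`floor(x + 0.5)`).
- Dendrogram cuts: scipy `fcluster` with the distance criterion,
  boundary inclusive (a merge at exactly height *t* is applied).
- Inconsistency criterion: depth 2, threshold 1.15, both configurable.
- Greedy matchings (shared SVs, hit resolution) order candidates by
  distance or score with coordinate/lexicographic tie-breaks, so all
  outputs are deterministic and order-independent.
- Binomial tail probabilities use scipy's survival function; the
  calibration test runs 1,000 replicates at n = 500 segments and
  p0 = 0.1, where the exact size of the level-0.05 test is 0.046.
- Degenerate inputs: empty call sets propagate to empty outputs; a
  single call forms a singleton cluster; clusters with no members
  report zero support.

## Known limitations

- Dedupe identity is exact, so one biological SV emitted with slightly
  different consensus coordinates at different grid points appears as
  several rows; burden estimates consequently over-count λ in
  proportion to that redundancy, as the underlying counting method
  does.
- Breakends/translocations are out of scope; unsupported VCF record
  types are skipped and reported.
- The caller-dialect map (which INFO key holds read support) ships
  with defaults for six callers and must be extended for others.
- Coordinates are never wrapped around the circular origin; variants
  genuinely spanning the origin are only handled by the
  half-genome-length artifact filter.
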