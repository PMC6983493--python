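# svmeta

Structural-variant (SV) meta-calling, population-frequency estimation and
host transposable-element (TE) scanning for deep-sequenced populations of
large double-stranded DNA viruses.

## The problem

A virus population purified from infected hosts contains not one genome
but a cloud of variants: deletions, duplications, insertions and
inversions, many of them defective genomes segregating at frequencies far
below one percent.  At sequencing depths of thousands to hundreds of
thousands of reads per base these variants are detectable in individual
reads — but every SV caller has its own biases and both short-read and
long-read libraries produce artificial chimeric fragments that masquerade
as SVs.  `svmeta` is for virologists and population geneticists who want
a conservative, auditable consensus SV set from such data, together with
per-variant population frequencies and a genome-burden estimate.

## The method

1. **Pair-distance deletion calling** (`svmeta.pairdist`).  Read pairs
   whose mates map more than 700 bp apart (far beyond a ~260-bp-insert
   library's spread) witness a deletion spanning the inner interval.
   Single-pair events are merged by Ward-linkage hierarchical clustering
   on the breakpoint pair *(start, end)* with an inconsistency-criterion
   cut, constrained so that start and end ranges within a merged event
   stay within 7 bp.

2. **Meta-clustering** (`svmeta.metacluster`).  Calls from multiple
   callers (four short-read, two long-read) with read support ≥ 3 and
   length ≥ 50 bp are clustered as points *(start, end)* under Euclidean
   distance and Ward linkage.  Because no single dendrogram cut is right
   — tight cuts split one variant across callers, loose cuts lump
   distinct variants — clustering is repeated over a grid of 14 distance
   thresholds (5–1000 bp) × 22 minimum-read-support thresholds (4–1500).
   At every grid point, clusters are kept only if all members share one
   SV type and the variant is supported either by both sequencing
   technologies (library chimeras do not reproduce across technologies)
   or, for short-read-only data, by at least two callers.  The union over
   all grid points is deduplicated by exact consensus identity, and SVs
   longer than half the circular genome are removed unless heavily
   supported (linearization-point artifacts).

3. **Frequencies and burden** (`svmeta.popstats`).  Each SV's frequency
   is `support / (support + reference coverage)` at its breakpoints,
   using a per-base coverage track.  With per-SV frequencies `f_i`,
   the number of SVs per genome is modelled as Poisson with rate
   `λ = Σ f_i`, so the fraction of genomes carrying ≥ 1 SV is
   `1 − exp(−λ)`; per-type fractions combine to the total burden as
   `1 − ∏(1 − f_type)`, the same quantity algebraically.

4. **TE junction scanning** (`svmeta.tejunctions`).  Short reads
   aligning ≥ 16 bp exclusively to the virus and ≥ 16 bp exclusively to
   a host TE, over ≥ 130 of 151 bp, with segment overlap in [−5, 20] bp,
   are virus–host junctions; PCR duplicates collapse on their junction
   coordinates.  In long reads, overlapping database hits resolve to the
   best score, the covered consensus fraction classifies each TE copy as
   full-length or truncated, and an exact binomial test asks whether
   truncated copies sit at read ends more often than sequence content
   predicts.

5. **Synthetic data with known truth** (`svmeta.synth`).  A generator
   produces circular genomes, planted SVs with log-uniform frequencies,
   emulated caller outputs with caller-specific jitter and sensitivity,
   read pairs, injected single-technology chimera artifacts and planted
   TE reads — so every stage is testable without downloads.

## Worked example

```bash
svmeta run --outdir demo --seed 42
```

simulates a 50-kb circular genome at 2,000× depth with 100 planted SVs,
emulates six callers, and runs the full pipeline.  It prints the
per-stage record counts and ends with:

```
159 SVs (8 robust) -> demo/results
```

`demo/results/summary.tsv` is the per-type burden table:

```
sv_type  n_svs  frequency_pct  min_length_bp  mean_length_bp  max_length_bp
DEL      77     52.48          55             4531            17530
DUP      29     37.27          121            1963            5411
INS      12     14.71          72             1138            1710
INV      41     37.34          53             1841            22500
Total    159    84.07          53             3113            22500
```

`n_svs` counts deduplicated consensus variants (coordinate-distinct
emissions of one biological SV at different grid points are separate
rows, as in the underlying method); `frequency_pct` is the Poisson
estimate of the percentage of genomes carrying ≥ 1 SV of that type.
`demo/results/frequencies.tsv` lists each SV with its breakpoints,
support, reference coverage, frequency, and supporting callers and
technologies, e.g.

```
sv_id            sv_type  start  end    length  support  ref_coverage  frequency   callers                                  technologies
DEL_1790_10990   DEL      1790   10990  9200    10       1992.5        0.00499376  fermikit,lumpy,pairdist,pbhoney,pindel   long,short
```

a deletion recovered by five callers across both technologies at an
estimated frequency of 0.5%.

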