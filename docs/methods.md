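# Methods

## The analysis model

`nemabar` analyses specimen-level amplicon barcoding data: every sample is
one hand-picked nematode, PCR-amplified in four regions of the 18S SSU
gene and deep-sequenced, so that each (sample, region) cell of the data is
a small table of denoised sequence variants (SVs) with read counts. The
core modelling assumptions are:

1. **One specimen, one dominant SV per region.** The most abundant
   nematode-derived SV in a retained sample is the specimen's sequence.
2. **rDNA repeats are polymorphic.** A specimen may carry a second repeat
   haplotype; it appears as a minor SV of the same order, a few edits from
   the major SV, recurring across samples of the same species. Recurrence
   is recorded as supporting evidence but not required — genuine alleles
   can occur in a single retained sample.
3. **Minor SVs of a different order are a second animal** (prey or
   contamination), not an allele; such samples are kept, with the major SV
   used downstream.
4. **Same-order minor variation that cannot be one allele family is
   unresolvable** at this locus, and the sample is excluded.

Two isolates are the same taxon when their major SVs are identical in
every region where both have data (exact identity, not a percent
threshold; the locus is slow enough that within-species variation shows up
as the explicit allele calls instead). Agreement in one region combined
with disagreement in another is a conflict and blocks the merge even via
intermediate isolates; the clustering is a constrained agglomeration over
the compatibility graph.

## Parameters that matter

| parameter | default | meaning |
|---|---|---|
| `min_reads` | 1000 | minimum nematode-derived reads per retained sample (strict >) |
| `min_nem_frac` | 0.65 | minimum nematode relative abundance (strict >) |
| `minor_floor` | 0.07 | relative-abundance floor for a minor SV to be considered |
| `max_allele_edits` | 5 | Levenshtein cap for a same-order minor to count as an allele |
| `phylum_min_frac` | 0.01 | phyla strictly below this are dropped after aggregation |
| `distance_model` | `jc` | Jukes–Cantor with pairwise deletion (`p` available) |
| `bootstrap` | 1000 | column-resampling replicates |

The 65% criterion counts the major nematode SV unconditionally and minor
nematode SVs only when each individually exceeds the 7% floor relative to
total sample reads; inside SV resolution the same floor is applied within
the sample's nematode fraction (the quantity the allele fractions are
defined on). `max_allele_edits = 5` covers the worst observed allele
patterns (four scattered substitutions; a substitution plus a two-base
insertion) while staying far below between-species distances at this
locus.

## Numerical choices

- **Distances.** Pairwise deletion of columns holding `-` or `N` in either
  sequence; Jukes–Cantor `d = −(3/4)·ln(1 − (4/3)p)`, with saturated pairs
  (p ≥ 3/4) assigned a configurable cap (default 5.0). A pair with zero
  comparable columns is an error naming the pair.
- **Neighbor joining.** Classic Saitou–Nei with the Studier–Keppler
  Q-criterion. Ties in Q are broken on the lowest (i, j) index pair;
  negative branch lengths are clamped to zero with the deficit moved to
  the sibling edge (preserving the joined pair's path length). Both rules
  exist purely for determinism; on additive matrices the generating
  topology and branch lengths are recovered exactly (tested against an
  exhaustive-topology least-squares oracle up to six taxa).
- **Bootstrap.** One column-index resample per replicate, shared by all
  pairs, drawn from a seeded generator after sorting labels — supports are
  therefore invariant to leaf input order. Supports are counts out of B,
  stored on internal nodes and written as internal newick labels.
- **Rooting.** The root is placed at the midpoint of the outgroup's
  pendant edge; ingroup topology is untouched.
- **Cluster counting** is done on the outgroup-rooted tree. A maximal
  clade is pure for order X when every leaf is X-labeled; rOTU query
  leaves and the outgroup break purity; a pure clade containing the root
  counts as one cluster. Orders with a single reference species are
  reported but flagged `omitted` (their count is 1 by construction).
- **Order assignment** walks from the rOTU leaf to progressively larger
  ancestral clades: the first clade containing reference leaves assigns
  its unanimous order, or its majority order, with ties deferred upward; a
  root-level tie is broken alphabetically (deterministic; in practice ties
  vanish long before the root). Feeding codes transfer from the reference
  leaf at minimum patristic distance, ties to the lexicographically
  smaller label; an rOTU lacking a region is assigned on the largest
  region-set tree that contains it.
- **Percentages** are rounded half-away-from-zero to one decimal, computed
  on exact integer ratios via `decimal` so that printed compositions are
  reproducible.

## What the synthetic generator emulates

`SimulationConfig` defaults describe a 96-specimen survey: ~25% failed
amplifications (<1,000 reads), ~28% of the remainder contaminated by
non-nematode DNA (nematode fraction drawn in [0.10, 0.50], below the QC
threshold), ~7% carrying a second nematode of a different order (fraction
[0.10, 0.30] of nematode reads), and roughly a third of species carrying a
polymorphic allele pair (minor fraction [0.10, 0.45] of nematode reads,
clearing the 7% floor with margin; the pair differs by exactly
`allele_edit_count` edits, verified at generation time). Read counts are
multinomial draws at a log-normal depth around 20,000 reads. References
are 6 orders × 5 species (~1,600 nt) with all eight primer sites planted —
the region-3/region-4 inserts overlap on a 63 bp block as on the real
gene — and substitution-only evolution in the variable blocks
(within-order 1.5%, between-order 12%, outgroup 30%). Specimens are drawn
from a 12-species community subset carrying a small extra divergence
(0.8%) from their reference sequences, so query leaves sit near, but not
on, reference leaves, as in a real survey.

Deliberately **not** emulated: read-level errors and chimeras (the input
contract starts at denoised SV tables), PCR efficiency bias, indel
variation between species (indels occur only inside designated allele
pairs, which keeps all regional inserts equal-length and alignment-free),
and rate variation across regions. Passing tests therefore demonstrate the
pipeline's logic — thresholds, classification, clustering, tree building
and evaluation — under clean alignments, not robustness to alignment error
or denoiser artifacts in real data.

## Problem sizes

The test suite and the default synthetic pipeline run at survey scale: 96
samples, ~31 reference taxa, four ~300 nt regions (concatenations up to
~1,300 nt), 100 bootstrap replicates over eight region sets — a couple of
minutes end to end on one core. The bootstrap default for analyses is
1,000 replicates; the brute-force cluster-count oracle is exercised on
1,000 random labeled trees of up to 30 leaves.

## Known limitations

- Exact-identity clustering treats any un-called sequencing artifact as a
  new taxon; the QC floor and allele calling are the only guards.
- The order-cluster metric depends on the rooting and on which query
  leaves are present; counts with and without rOTU leaves are therefore
  reported separately.
- ClustalX-era distance corrections used in older analyses are not
  reproduced bit-for-bit; Jukes–Cantor is the package's stated model and
  p-distance the alternative.
- Feeding-type transfer assumes trophic ecology is conserved at the
  nearest-reference level; codes are reported with their uncertainty
  markers rather than resolved.
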