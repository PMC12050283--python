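# Methods

## The detection problem

Random rolling-circle amplification (phi29) of a circular DNA template
produces a linear concatemer: some rotation of the circle's monomer
sequence repeated `n` full times plus a partial pass. A read is therefore
evidence for a circle when (a) it self-repeats with a well-defined period
and (b) that repeat structure does *not* already exist head-to-tail in the
linear genome. Reads from genomic tandem arrays satisfy (a) but not (b)
and must be excluded; plain linear reads satisfy neither.

## Concatemer decomposition

`decompose_concatemer` finds the dominant self-repeat period as the mode
of distances between consecutive occurrences of repeated k-mers
(k = 15 by default). The mode search uses a distance-proportional
smoothing window (±max(3, d/50)) so that indel jitter at nanopore-like
error rates does not fragment the peak; the refined period is the median
of supporting distances. A decomposition is reported only when the
supporting k-mer pairs cover ≥ 2k bases of the read.

The *repeat span* — the read interval covered by supporting k-mer pairs —
bounds all downstream unit statistics. This matters for reads that are
only partly concatemeric (e.g. a repeat followed by unrelated sequence):
slicing the whole read into period-length units would compare unrelated
windows and poison the divergence estimate. Within the span:

- `n_units` = span length / period (fractional; a 3.4-pass read reports 3.4);
- `unit_divergence` = mean edlib edit distance between adjacent
  period-length units, divided by the period;
- the consensus is built by aligning every unit to the medoid unit (the
  unit with minimal summed edit distance to the others) and taking the
  per-column majority in medoid coordinates. A fixed-column majority over
  stacked slices would mis-vote as soon as indels shift the columns; the
  medoid frame keeps the vote aligned while still erasing isolated errors.

Unit filters follow the published identification criteria and are applied
independently: unit length ≥ 200 bp, units ≥ 2, divergence ≤ 25% (the
bound is inclusive — "exceeding" 25% rejects). The 200 bp unit floor is
what gives every emitted locus its minimum size.

## Mapping

The built-in mapper is deliberately minimal: exact k-mer seeds grouped
into diagonal bands per (chromosome, strand), greedily chained, extended
with a gapless X-drop (match +1, mismatch −3, drop 12) and scored with
edlib identity. It is adequate up to roughly 5% divergence, which is all
the synthetic pipeline requires; real-data users can import PAF records
from any long-read aligner — every downstream stage consumes
`AlignmentSegment`, not the mapper.

Three mapper-derived quantities drive the caller:

- **Genomic-tandem exclusion**: a read is linear-genome-explainable when a
  single diagonal band (one collinear alignment) covers ≥ 80% of the read.
  An RCA read of a circle can never achieve this once it has ≥ 2 passes
  (each pass maps in its own band), so the rule only removes background.
- **Locus interval**: the consensus is one rotation of the circular
  monomer, so it maps as up to two adjacent wrap-around pieces; the locus
  is the hull of those pieces.
- **Aligned fraction**: the union of read intervals over all bands that
  align to the locus, divided by read length — the per-read "80% of read
  length aligns to the region of origin" criterion.

Loci are single-linkage clusters of per-read candidate intervals at
reciprocal overlap ≥ 0.8; the emitted interval takes member-lower-median
endpoints (deterministic, robust to outlier reads), and clusters with
fewer than 3 supporting reads are dropped.

## Multi-fragment circles

Reads of circles joining several non-contiguous genomic fragments align
as a repeating cycle of segments. After sorting by read coordinate,
trimming read-overlaps at the midpoint, and re-joining split alignments
(consecutive segments whose reference gap tracks the read gap — indels
can split one fragment's alignment into two diagonal bands), the segment
identity sequence is searched for its smallest period. Two segments are
identical when chromosome and strand agree and either both reference
endpoints fall within 20 bp or the intervals overlap reciprocally ≥ 0.9;
a clipped first/last segment (read starting or ending mid-fragment) is
dropped before the search. A period is accepted when at least 75% of its
index comparisons agree — error-free reads still require full agreement
in practice, while nanopore-level jitter no longer doubles the period.
`Nfragment` is the period, `Nfullpass` the number of complete cycles
(the trailing partial cycle never counts). Reads pass at Nfullpass ≥ 1
and Nfragment ≥ 1 and are single-fragment at Nfragment = 1, multi at ≥ 2,
matching the convention that ~99% single-fragment reads are retained as
such rather than filtered.

Multi-fragment reads are grouped by (core gene, Nfragment); the core gene
maximizes summed fragment overlap, ties to the smaller (chrom, start).
Groups carry an `ltr_flanked` flag — true when every gap between
genomically adjacent same-chromosome fragments contains LTR-superfamily
elements of a single subfamily — the configuration an LTR-mediated
homologous-recombination origin would produce. The flag is descriptive
only; no mechanistic inference is made.

## ID unification

"Same ID" is an equivalence relation, so assigning one ID to every pair of
loci overlapping by strictly more than 200 bp forces transitive closure:
unified IDs are connected components of the overlap graph, computed by a
sorted sweep with union-find and verified in tests against an O(n²)
brute-force oracle. Chaining across long regions is an accepted
consequence and is visible in the `n_members` column. Member locus
coordinates are never altered; the unified region is the coordinate hull.
Strand is ignored (loci are unstranded intervals) and the rule applies
uniformly within and across samples.

## Annotation

Location classes partition the catalog by construction: priority
gene > up2kb > down2kb > intergenic, ties within a level to the largest
overlap then the smaller (chrom, start). Upstream/downstream windows are
2 kb and strand-aware (upstream = before the TSS in gene orientation);
an unstranded mode is available. Track overlaps (TE, ncRNA, NUMT, NUPT)
are non-exclusive labels with a 1 bp minimum on half-open intervals — a
zero-length touch is never a hit — and a full-length ecRepeatUnit requires
inclusive containment of the repeat unit's interval. Genes without
annotated UTR/CDS parts are treated as CDS over the whole body.

## GMPR + EMD differential analysis

eccDNA count matrices are zero-inflated, which breaks total-count and
median-of-ratios normalization. GMPR size factors use only mutually
non-zero features: r_ij is the median of c_ki/c_kj over features non-zero
in both samples, and s_i is the geometric mean of r_ij over all
qualifying columns *including* the self-column (r_ii = 1), rescaled to
geometric mean 1. Including the self-ratio is what the reference
implementation does, and it is what makes the factor of an
equal-composition sample exactly proportional to its depth: with it an
entry-wise doubling doubles the factor ratio exactly, and a 4-fold depth
confound across four samples normalizes away (verified to < 1% in tests);
without it the factors overcorrect by the power n/(n−1).

Each feature's group difference is the exact 1-D earth mover's distance
between normalized counts, EMD = ∫|F_A − F_B| dx (for equal group sizes,
the mean absolute difference of sorted values). No histogram binning is
used; the binned variant converges to this as bins shrink, and exactness
makes closed-form test values possible.

Significance uses a permutation null pooled across features. With two
replicates per group only three unordered label splits exist; the null
pools the two non-identity splits over all features, p = (1 + #null ≥
observed)/(1 + #null), and q-values are Benjamini–Hochberg. Excluding the
identity split keeps planted effects out of their own null; with it a
strong feature's observed score would sit in the pool and no feature
could ever clear BH in a 2v2 design. True effects then share the minimal
pooled p and pass BH through ties — the resolution a pooled null buys is
exactly what a 3-permutation per-feature null cannot provide.

Classification is gated on q < 0.05 first. *Exclusive* is decided on raw
counts (presence/absence is depth-robust): positive in every replicate of
one group, zero in every replicate of the other. Everything else
significant is *differential* toward the group with the higher mean
normalized count.

## The synthetic-data generator

The generator emulates the study conditions the pipeline targets:

- **Genome**: random sequence (GC 0.44, rice-like), default 2 × 100 kb;
  non-overlapping gene models whose 5'UTR/CDS/3'UTR tile the gene span;
  TE/repeat-unit/ncRNA/NUMT/NUPT interval labels with a
  class1/superfamily/subfamily hierarchy (Stowaway, Kiddo, Gypsy, Copia,
  ...); and genomic tandem arrays written literally into the sequence
  (150–800 bp monomer × 3–10 copies) as the caller's negative controls.
- **Circles**: single-fragment sizes from a log-normal law (median 500 bp,
  σ = 0.8) truncated to [200 bp, 37 kb] — the printed size range and
  central tendency of plant eccDNA; multi-fragment templates join 2–10
  fragments, cross-chromosomal when possible; `ltr_flanked_pair` templates
  flank an annotated LTR element. Templates avoid the planted tandem
  arrays (a repeat-borne template would multi-map and not define a unique
  locus) and single templates avoid each other, so "one circle, one
  locus" is well-posed ground truth.
- **Reads**: pass count 1 + Poisson(mean − 1) (default mean 5) plus a
  uniform partial pass — guaranteeing ≥ 1 full pass so decomposition is
  well-posed; per-base substitution/insertion/deletion errors at
  configurable rates (≤ 20%); strand flipped with probability 0.5.
  Quality strings are constant; homopolymer bias and chimeras are not
  modeled, so passing tests bound algorithmic correctness, not real
  nanopore robustness.
- **Counts**: 2 groups × 2 replicates, 2000 features,
  Bernoulli(0.7)·Poisson(10) background; 40 exclusive features per group
  (present with λ ×5 and a count floor of 1, structurally absent in the
  other group) and 40 differential features (λ ×5 in the up group).
  The count floor makes the exclusivity predicate hold by construction.

Everything is deterministic given the seed; identical spec + seed gives
byte-identical FASTA/GFF3/BED/FASTQ output.

## Problem sizes and numerical choices

Tests and the acceptance script run on 2 × 100 kb genomes, 6–60 circles,
a few hundred reads per scenario and 2000-feature count matrices — sizes
at which every stage completes in seconds while all thresholds and
recovery properties are exercised at their boundaries (199/200 bp units,
200/201 bp overlaps, 79/80% aligned fraction, 24/26% divergence,
±1 bp containment). Tie-breaks are deterministic throughout (lower
median, smaller coordinate, sorted iteration), and k-mer size 15 keeps
random 200 kb genomes collision-free (4^15 ≫ genome size).

## Known limitations

- The internal mapper is not a general aligner; above ~5% divergence or on
  repeat-dense real genomes, import external PAF alignments instead.
- Unified IDs chain transitively; two distant loci can share an ID through
  intermediates. This mirrors the equivalence-relation semantics of the
  ID rule rather than a reciprocal-overlap merge.
- The 2v2 permutation design has only three label splits; all resolution
  comes from pooling the null across features, so q-values assume features
  are largely exchangeable under the null.
- Circles smaller than 200 bp are out of scope by design (the unit-length
  floor), as is base-quality-aware consensus polishing.
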