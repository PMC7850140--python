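# Methods

This note records the modelling assumptions, parameter choices and numerical
decisions behind clipcall, and what the synthetic benchmarks do and do not
demonstrate.

## Signal model

The caller assumes a coordinate-sorted, indexed BAM of paired-end short
reads with duplicate flags set and SA tags present on split reads (the
output of a standard bwa-mem + duplicate-marking workflow). All internal
coordinates are 0-based half-open; conversion to the 1-based SAM/VCF
conventions happens only at the I/O boundary, so a deletion written with
POS p and END e removes reference bases [p, e−1] in 1-based terms.

Library statistics are estimated per 1 Mb chunk: insert-size mean and
*population* standard deviation over |TLEN| of primary, non-duplicate,
mapq-60 reads, counting each pair once through its leftmost mate
(TLEN > 0). The population sd makes small fixtures exactly checkable and
differs negligibly from the sample sd at chunk scale. A chunk without
qualifying pairs inherits the previous chunk's statistics (or global
defaults of 500 ± 50 bp, 150 bp reads). Reads are processed in the chunk
containing their start, so no read is double-counted at chunk edges;
boundary-duplicate calls are collapsed at the merge (same type within
10 bp, sizes within 20 %).

Thresholds, with defaults (all in `CallerConfig`):

| parameter | default | meaning |
| --- | --- | --- |
| `min_clip` | 5 bp | clips must be strictly longer to count as signal |
| `support_frac` | 0.10 | X = max(2, ⌈0.10·coverage⌉); the floor of 2 stops single reads nominating candidates below 10× |
| `discordant_pad` | 300 bp | insert-size test |TLEN| > min(μ+σ, μ+300) |
| `bin_width` | 1000 bp | SM↔MS partner search radius for extension |
| `min_overlap_n` | 30 bp | extension overlap must be strictly longer |
| `boundary_shift` | 3 bp | mismatches excused at overlap termini (clip-boundary sequencing errors) |
| `assembly_window` | 1200 bp | read-collection window around a candidate |
| `kmers` | 41, 61, 81 | assembly k-mer sizes; contigs pooled without deduplication |
| `complex_mapq`, `complex_hq_ratio` | 50, 0.8 | rescue-node clip confidence |
| `tra_mapq` | 20 | both split segments of a translocation must exceed this |
| `min_sv` | 50 bp | SV/indel boundary |
| `exclusion_radius` | 200 bp | "near the breakpoint" everywhere it is needed |

## Read extension

The overlap test compares the last n bases of the MS read with the first n
of the SM read, n from read_length − 30 downward, accepting the first
(largest) n > 30 whose interior matches exactly; up to 3 bases at each end
of the compared substrings may mismatch. The interior is exact by design —
a mismatch budget there would break the property that, with error-free
reads, the join is an exact substring of the donor haplotype. Where the
boundary tolerance hides a disagreement, the MS read's bases win (an
arbitrary but fixed choice).

One join is emitted per SM read: the partner with the largest n, ties to
the leftmost partner breakpoint. This keeps downstream support counting
honest — emitting all feasible pairs would double-count the same physical
reads.

**Periodicity guard.** A join whose overlap is (nearly) tandem-periodic
with period ≤ 25 is rejected. With a periodic overlap the join offset is
pinned only modulo the period, and a wrong offset silently removes or adds
repeat copies, mis-sizing the insertion while keeping its position — the
worst kind of error, because the mis-sized call then blocks the assembly
node that could have handled the site. The periodicity test is a shifted
self-comparison tolerating a 10 % mismatch fraction, so isolated sequencing
errors cannot mask a genuine repeat (a non-periodic sequence mismatches its
own shift at ~75 % of positions, leaving a wide margin). Tandem-array
insertions consequently flow to local assembly and are typically reported
as partially assembled (breakpoint exact, size unknown), which is the
honest statement of what short reads can resolve there.

## Builtin spliced aligner

Queries originate from clipped reads, so their true locus is known to
within the clip breakpoint; the builtin backend therefore searches only
±50 kb around each query's anchor. It seeds exact 15-mers (skipping seeds
with > 8 window hits), merges co-diagonal seeds into anchors, chains
anchors colinearly by dynamic programming with a mild gap penalty, and
emits M runs between chained anchors, I for surplus query, D for surplus
reference. Equal-length query/reference gaps become M (substitution runs),
which is what tolerates scattered sequencing errors between seeds. Mapping
quality is a coarse uniqueness proxy (60 unique, 20 ambiguous). Queries at
one candidate site share a single k-mer index of the window.

The ±50 kb window bounds the deletion span discoverable from one anchored
query; genome-wide discovery of larger events should use the minimap2
backend. Junctions may shift by ±1 bp when an SV boundary base coincides
with the reference — ordinary indel placement ambiguity, far inside the
200 bp evaluation window.

## Local assembly

The de Bruijn assembler indexes k-mers of reads and their reverse
complements, prunes k-mers seen fewer than twice, clips dangling unitigs
shorter than 2k (up to four rounds), pops simple bubbles keeping the
higher-coverage arm, and reports maximal non-branching paths. These are
conventional small-assembler defaults; the assembler is calibrated only by
the planted-insertion recovery property (≥ 90 % of 100–400 bp insertions
with unique flanks recovered at exact size on seeded fixtures). Because
both strands are indexed, contigs appear in both orientations; downstream
clustering absorbs the redundancy. Coverage-2 pruning means sequence ends
covered once are not reconstructed — irrelevant here, since the contig's
informative part is the junction interior.

## Decision tree

Nodes run strictly in order (CIGAR → spliced → assembly → complex) and the
first success terminates the candidate, which the tests verify with
execution counters. Node 1 requires X-fold read support for both outcomes
(insertion call and small-indel termination), symmetrical with every other
node. The DEL/INV/TRA exclusion stated for the rescue node is also applied
to *imprecise* (partially assembled) insertions from node 3: a clipped
contig at a known deletion or inversion breakpoint is that event's clip
signal, not an insertion. Fully assembled insertions, having an explicit
junction-spanning alignment, are exempt.

## Inversions and translocations

Split-read junctions are exact and cluster at 20 bp tolerance; pair-derived
breakpoints are inferred from insert sizes and scatter by up to an insert
length, so they are folded into an overlapping split cluster as additional
support rather than clustered independently — pair-only clusters (events
too large or too clip-poor for splits) use insert-size slack and are
marked `PAIR`. A single same-orientation pair constrains only the *sum* of
the two inversion breakpoints, which is why snapping to clipped-read
breakpoints within 200 bp takes precedence over the insert-size formula.

Translocation evidence is keyed by junction orientation (which side of
each breakpoint is joined): a reciprocal exchange creates two junctions at
the same coordinate pair, distinguishable only by orientation, and both
are called and written as reciprocal BND pairs.

## Simulator

The simulator is the package's fixture factory and encodes the study
conditions: uniform genotypes over 1|1, 0|1, 1|0 (hom:het = 1:2); 200
random inversions of 50 bp–10 kb; reciprocal translocations as alternating
segment exchanges between 10 random chromosome pairs per haplotype, three
per pair (60 breakpoints per haplotype), always heterozygous; events kept
≥ 1 kb apart; reads at 15× per haplotype (30× pooled) with
Normal(500, 50) inserts and 0.002 per-base substitution errors. About 30 %
of generated insertions are tandem arrays of a random 20-mer, mimicking
the repeat enrichment of real SVs and exercising the hard case for
extension and assembly.

What the simulator does *not* model: indel sequencing errors, quality-score
correlation along reads, GC/coverage bias, real repeat families (SINE/LINE,
segmental duplications), heterozygous SNP background, and chromosome-scale
genome structure. Passing benchmarks on these genomes therefore
demonstrates the machinery is correct, not that real-genome accuracy will
match: random toy sequence is nearly repeat-free, so mapping ambiguity —
the dominant error source on real data — is largely absent, and the
near-perfect toy-genome metrics should be read in that light.

## Evaluation

Matching follows the standard windows (±200 bp; size difference < 50 % of
the *truth* size where both sizes are known; window-only for size-less
insertion calls and translocations, either breakend). The one-to-one
assignment is solved optimally (maximum cardinality, then minimum total
breakpoint distance, via the Hungarian algorithm) rather than greedily:
greedy nearest-first is provably suboptimal on instances where a size-less
call sits nearer a truth event than the only precise call compatible with
it, and optimal assignment makes the brute-force-oracle equivalence hold by
construction. Extra calls on one truth event count as false positives; no
deduplication is applied before precision.

Problem sizes in the shipped benchmarks — 2 Mb genomes, ≤ 90 events, one
CPU — are chosen so the full suite runs in a few minutes while every code
path (all four tree nodes, both inversion evidence classes, cross-chromosome
translocations) is exercised; sensitivity/precision thresholds in the
regression test (0.85/0.70/0.90) are regression floors for this
configuration, not claims about real data.

## Known limitations

- No genotyping of calls; tandem duplications are reported as insertions.
- No CRAM input; duplicate flags are trusted, not recomputed.
- The builtin aligner is for candidate-anchored queries; it is not a
  general-purpose whole-genome spliced aligner.
- Read-depth (coverage) evidence is not used.
- Pair-only inversion breakpoints are coarse when no clipped reads exist
  within the snap radius.
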