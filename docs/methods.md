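# Methods

This note documents the model, the algorithmic and numerical choices, and
the simulation designs behind `ontcorrect`, at the level of detail a
maintainer or reviewer needs to reason about its behaviour.

## Problem setting and assumptions

Input reads are assumed to be oriented, full-length cDNA reads grouped into
gene-family clusters; orientation detection, primer trimming and clustering
are upstream concerns. Within a cluster, reads from different isoforms share
exons, and the method's premise is that a shared exon accumulates coverage
across all isoforms containing it, so that even a transcript sequenced once
can be corrected over its shared regions. Errors are assumed to be dense
(several percent per base) but locally independent; systematic basecaller
artifacts are not modelled beyond the homopolymer safeguards described
below.

## Correction pipeline

### Anchors

Positional minimizers (lexicographically smallest k-mer per window of `w`
k-mer start positions, leftmost on ties, duplicates collapsed) act as
alignment-free anchors. Defaults: `k = 9`; `w = k + ⌊|C|/500⌋` grows with
cluster size `|C|` to bound the anchor count on large clusters, so for
clusters under 500 reads every k-mer is an anchor candidate. Anchor pairs on
one read must be separated by `x_min = 2k` to `x_max = 80` nt; pairs whose
two anchors are both `A^k` are masked because polyA tails otherwise flood
the pair index. Minimizer comparison is plain byte-lexicographic; `N` is an
ordinary symbol sorting between `G` and `T`, so it never displaces an ACGT
k-mer.

### Support and the similarity rule

The support of a candidate interval counts the reads whose occurrence of
the same anchor pair spans a *similar* segment, where segments `s, s′`
(anchor windows included) are similar iff

    ed(s, s′) < |s| (ε_s + ε_s′),

with `ε` the mean per-base error probability of the segment inferred from
quality values — the expected number of differences between two
independently erroneous copies of the same sequence. The inequality is
strict; a `1e-9` guard keeps it exact at representable boundaries (e.g.
`ed = 14` against `|s| = 100, ε = 0.07 + 0.07`). If a read carries the pair
several times, only its closest occurrence counts, and each read counts at
most once; the target read always supports itself, so support ≥ 1 and every
candidate has positive weight.

**Batch computation.** Evaluating `ed(s, s′)` per (candidate × occurrence)
with a separate alignment call is the dominant cost of the whole method and
scales as tens of millions of calls per cluster. Instead, one whole-read
global alignment per read pair is computed (and cached), and the segment
edit cost is read off the induced sub-alignment between the anchor
coordinates, using prefix arrays over the alignment path. Because the two
anchors are exact-match k-mers present in both reads, the optimal global
path almost always aligns them position by position, and the induced cost
then equals the optimal segment edit distance; where the paths diverge the
induced cost is an upper bound, i.e. the batch rule is conservative. On
random 7%-error fixtures the batch support equals the direct per-segment
computation for ~98% of candidates and is at most one lower otherwise (the
direct implementation, `partitioning.compute_support`, is kept as the
reference and tested against the batch path). Partner error rates use the
partner span induced by the same alignment path.

### Partitioning

Candidates are weighted `support × span` (`a(q − p − k)`) and a maximum-
weight set of non-overlapping intervals is found by the standard
predecessor dynamic program after sorting by interval end (`O(n log n)`).
Intervals are half-open `[p + k, q)`; anchors are excluded, so adjacent
selected intervals may share an anchor k-mer. On ties the DP includes the
later-sorted interval, making the solution deterministic. Regions not
covered by any selected interval — read ends and unsupported junctions —
are passed through unmodified, as are the anchor k-mers themselves.

### Consensus

Supporting segments (target first, then cluster order; capped at
`max_seq_to_spoa = 200`) are condensed into a consensus by star alignment:
each segment is globally aligned to a center segment of median length, the
pairwise alignments are merged into columns (insertions relative to the
center open shared, left-justified gap columns), and each column takes its
majority symbol (ties prefer the center's symbol, then the
lexicographically smallest). This construction has the two properties the
downstream correction relies on — identical segments reproduce themselves
exactly, and an isolated minority variant is voted out — and fills the role
a partial-order-alignment heaviest-bundle consensus would fill; it was
chosen because it reduces to cached pairwise alignments and stays fast in
pure Python/numpy.

### Trusted variants and row correction

All supporting segments are aligned back to the consensus into a matrix
`A` (insertion columns are all-gap in the consensus row). For each column
`j`, row windows spanning `2⌊k/2⌋ + 1` columns centred on `j` (truncated at
matrix edges) are counted by exact string equality, gaps included. A
non-consensus window `b` is trusted iff it occurs in at least 3 rows and at
least

    max(3, m·T / min(ed(c′, b), ed(HC(c′), HC(b))))

times, where `m` is the number of rows, `T = 0.1`, `c′` is the consensus
window, `HC` is homopolymer compression, and edit distances are computed on
gap-stripped strings. The threshold is real-valued (no rounding). If
`HC(c′) = HC(b)` the variation is a pure homopolymer-length change and is
never trusted, reflecting the elevated homopolymer error rate of the
platform. The consensus window is always trusted. For the corrected row,
every column's symbol is replaced by the variant of the trusted context
nearest its own window (ties: higher count, then the consensus context);
decisions are made against the original row, so column order cannot
cascade. Only columns whose row position falls inside the anchor-free core
are corrected, and the corrected cores are spliced back between the
unchanged anchors.

An isolated SNP consequently survives correction exactly when it is carried
by at least `max(3, mT)` matrix rows — at least three reads and at least a
10% frequency at default `T` — which the test suite verifies analytically
over `m = 10…100`.

### Exact and approximate modes

Clusters of at most `exact_instance_limit = 50` reads are corrected
exactly: every read builds, schedules and corrects its own intervals.
Larger clusters use the approximate mode: whenever an interval is
corrected, all sibling rows of its matrix are corrected too and cached per
read (span, corrected substring, support; on colliding spans the
higher-support entry wins). A later read whose candidate interval exactly
matches a cached span reuses the stored support and — if the interval is
selected — the stored substring, skipping consensus construction. Cached
spans that merely overlap a candidate are ignored: substituting their
support was tried and corrupted the scheduling weights badly enough to
multiply the post-correction error rate several-fold, whereas with
exact-match reuse the two modes agree closely (on a 65-read three-isoform
cluster, median post-correction error 0.42–0.51% in both modes). Reads are
processed in batches of `max_seq = 1000`; the pair index and cache are per
batch, and correction contains no randomness, so reruns are byte-identical.

Output qualities are a constant Phred 30 placeholder: the method does not
model post-correction base quality, and corrected segment lengths can
change, so original qualities cannot be carried through meaningfully.

## Simulator

`make_gene` draws exons uniformly over ACGT (default 4–7 exons of 60–140 nt
in the depth experiment); isoform 1 contains every exon and each further
isoform drops a random non-empty subset of up to half the exons, distinct
from previous isoforms and always sharing at least one exon pairwise. The
multi-exon drops reflect that real splice variants typically differ by more
than a single small cassette exon; variable transcription start/end sites
and intron retention are not modelled.

`simulate_reads` applies an i.i.d. per-base process: with probability
`error_rate` an event occurs, split 0.35/0.30/0.35 among substitution (to a
uniformly chosen different base), single-base insertion after the position,
and deletion — the normalization of a measured ONT cDNA profile of roughly
2.5%/2.2%/3.0% per-base substitution/insertion/deletion rates. Quality
strings encode the nominal error rate, and true event counts are logged per
read (truth error rate = events / (transcript length + insertions)). This
model omits several features of real ONT data — bursty and
homopolymer-correlated errors, per-base quality variation, length-dependent
error placement, polyA tails and adapters — so passing simulation tests
demonstrates the algorithm's behaviour under calibrated, locally
independent noise, not performance on real flowcell data. One consequence
worth knowing: with exactly calibrated qualities the similarity threshold
sits at the expected distance between two 7%-error segments, so measured
support is roughly half the sharing reads, and SNP retention needs somewhat
more depth than with real, variable qualities.

All randomness flows from a single seed through `numpy` `SeedSequence`
spawning; replicates are independent substreams and every experiment is
reproducible.

## Evaluator

Error rates are mismatch rates: insertions + deletions + substitutions of a
unit-cost global alignment divided by the alignment length (matches +
events). A read is *miscorrected* if it has more mismatches to its true
transcript after correction than before, and *overcorrected* if its
corrected sequence is strictly closer (edit distance) to another transcript
than to its true one; the overcorrection distance is `ed(true) −
ed(closest)` (≥ 1 whenever flagged). Read-to-isoform assignment in the
exon-deletion experiment uses strictly smaller edit distance; ties are
excluded from both numerator and denominator.

## Experiment designs and problem sizes

- **SNP retention** (`snp_experiment`): two copies of a random 208-nt
  transcript, a SNP planted uniformly in [50, 150]; `round(n·f)` mutant
  reads of `n` total at 7% error; 10 replicates per condition; a replicate
  is retained if any corrected read carries the SNP base at the SNP
  position, located by alignment to the mutant allele. The acceptance
  script scans `n = 10…100` in steps of 10 for `f = 0.2` and `f = 0.1` and
  reports the smallest `n` retaining in ≥ 8/10 replicates.
- **Exon retention** (`exon_experiment`): same two-copy design with a 5, 10
  or 20 nt substring deleted from one copy; reports the minor-isoform read
  fraction before and after correction.
- **Depth curve** (`depth_experiment`): 20 genes per replicate, 1–4
  isoforms each, per-transcript depths cycling (1, 2, 3, 5, 10, 1, 2, 3,
  20, 50); reads at 7% error; each gene cluster corrected and evaluated
  against its own transcripts. The acceptance script pools three replicate
  simulations (~1500 reads) so the low-depth medians rest on a few dozen
  reads each; the test suite pools two. These sizes are the package's
  desk-scale stand-in for chromosome-scale simulations; the depth-1 median
  in particular is a mixture over how much of each transcript is shared
  with well-covered siblings and remains the noisiest reported number.
- **Uncorrected error rate**: 5000 reads of ~600 nt at the default 7%
  model; the alignment-measured median sits slightly below the nominal
  event rate (~6.6–6.8% vs 7%) because adjacent events can be explained by
  fewer alignment operations.

## Known limitations

- Correction quality at junction-adjacent regions of rare isoforms is
  limited by design: intervals crossing an exon boundary unique to a
  low-depth isoform have support ~1 and are left nearly untouched.
- Very small exons (~5 nt) in a minor isoform can be overcorrected toward
  the major isoform, as the exon-deletion experiment shows; 20-nt exons are
  safe.
- The engine encodes anchor pairs in one 64-bit integer and therefore
  requires `k ≤ 13`.
- Threads: clusters are independent units of work and the CLI accepts a
  thread count for pipeline compatibility, but execution is serial; any
  parallel schedule must reproduce the serial output byte for byte.
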