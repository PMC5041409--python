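# Methods

## Scope and conventions

`pirnakit` implements a complete small-RNA → piRNA profiling chain for
multi-library developmental designs. Internally all coordinates are
0-based half-open; GFF3 (1-based closed) and BED are converted at the
I/O boundary only. All sequences are upper-case DNA (U → T on input), so
"1U" is measured as T at position 1. The 5′ end of a minus-strand
placement is its rightmost base (`end − 1`).

## Cleaning

The chain is: 3′-adapter trim → drop reads containing `N` → drop reads
shorter than 18 nt → keep 24–30 nt → drop reads containing a homopolymer
run of ≥ 8 identical bases → collapse to unique tags with per-library
counts. The trimmer removes the full adapter (and anything after it)
when it occurs in the read, otherwise the longest read suffix equal to
an adapter prefix of ≥ 6 nt; quality-based cleaning is limited to the
`N` rule, since base-quality handling is a sequencing-facility concern
rather than part of this analysis. Every read is accounted to exactly
one bucket (kept or one drop reason) and the accounting is asserted at
run time.

Tags overlapping structural ncRNA annotation (rRNA, tRNA, snRNA,
snoRNA, miRNA) at **any** genomic placement are excluded after mapping.
Exon-overlapping tags are deliberately **kept**: they constitute the
gene-derived piRNA class that the downstream composition, strand-bias
and signature analyses describe, whereas structural ncRNA fragments are
degradation contamination. This is a substantive design choice — a
cleaning rule that discarded all exonic reads would contradict the
existence of the gene-derived analyses.

## Mapping

Tags are placed by exact matching (0 mismatches) on both strands, all
occurrences reported, no multi-hit cap. Exactness is the normative
choice because cluster calling is defined over perfect matches and
because it makes the mapper verifiable against a naive full scan (a
test does exactly that). The index is seed-and-verify: 12-mers of the
plus strand are hashed; a query anchors on its first 12 bases and is
verified by direct comparison; minus-strand hits come from querying the
reverse complement. Uniquely mapped tags feed composition and ping-pong
statistics; multi-mapping tags are retained for cluster calling, where
every placement contributes (an optional 1/n-hits fractional weighting
exists for sensitivity checks). SAM ingest accepts only ungapped
full-length matches with NM = 0, so a third-party mapper can be swapped
in under the same contract.

## Annotation

Category precedence is repeat > gene > intergenic: a repeat inside an
intron counts as repeat, because TE silencing is the pathway's primary
function and the three categories must partition the tags. Within
genes, CDS > UTR > intron; remaining ties break deterministically by
longest overlap, then leftmost feature. Orientation is sense when tag
and feature strands agree. Compositions are reported both read-weighted
and tag-weighted, since either convention is defensible and they differ
whenever abundance correlates with category.

## Signatures

Base-composition matrices are position × {A,C,G,T} frequencies over the
first 30 positions, weighted per read (counts) or per tag; each
populated row sums to 1. `frac_1U` is row 1's T frequency, `frac_10A`
row 10's A frequency.

Ping-pong: for a plus 5′ end at *p* and minus 5′ end at *q* on one
contig, the overlap is *d = q − p + 1* (both boundary bases counted), so
the canonical signature is *d* = 10 — stated explicitly because
off-by-one variants of this statistic abound. Pairs with 1 ≤ *d* ≤ 30
accumulate the product of the two read counts (default) or 1
(distinct-pair weighting). Only uniquely mapped tags participate. The
summary `z10` is (w₁₀ − mean w_{d≠10}) / sd w_{d≠10} (sample sd); the
per-distance 5′-base table supports logo-style rendering. Matrices and
histograms are exported as TSV; graphical rendering is out of scope.

## Cluster calling

Windows of 5 kb holding ≥ 10 **distinct** piRNA sequences are marked
("sequences" is read as distinct tags; read support is a separate
criterion), marked windows < 20 kb apart (edge to edge) merge, and each
merged locus is trimmed to the outermost placement overlapping its
span. Calling uses tags with ≥ 200 supporting reads across libraries (a
per-tag prefilter against isolated high-frequency tags), and a called
cluster must itself hold ≥ 200 reads. Cluster TPM per library is member
read count × 10⁶ / library total. Strandness is `plus_only`,
`minus_only`, `divergent_non_overlapping` (both strands present but
their spans disjoint), or the residual `mixed_overlapping` state, which
is reported rather than forced into a class.

The scan is event-driven and **exactly** equivalent to evaluating every
possible window start position: the distinct-sequence count of the
window starting at *s* is piecewise constant with breakpoints only at
placement-derived positions, so sweeping the breakpoints reproduces the
per-bp enumeration. A stepped scan (e.g. every 1 kb) was considered and
rejected: it saves nothing at these data sizes and admits boundary
jitter that an exact sweep does not; the test suite holds the caller to
per-bp enumeration exactly. Merge distance is measured
footprint-edge-to-footprint-edge.

## Differential expression

The "Poisson test" on tag counts is concretised as the exact
conditional binomial (Audic–Claverie-equivalent) test: conditional on
*x + y* total reads, *x* ~ Binomial(*x + y*, *N_a*/(*N_a* + *N_b*))
under the null of equal relative abundance; the two-sided *p* doubles
the smaller tail, capped at 1. It is symmetric in the two libraries,
scale-invariant in the totals, and verifiable against an exact rational
tail sum (a test does so to 1e−10). Raw and Benjamini–Hochberg adjusted
*p* are both emitted; a call requires adjusted *p* ≤ 0.05 **and**
|log₂ ratio| ≥ 1, where the ratio compares totals-normalised counts
with a pseudocount of 1 added to both raw counts when either is zero.
Significant tags whose lower count is exactly 0 carry a
library-specific flag. Expression profiles cluster by average linkage
on 1 − Pearson distance of log₂(TPM + 1); pairs involving a
zero-variance row fall back to rescaled Euclidean distance (logged).
Top-*N*-per-stage unions break ties by row total, then label.

## Pool size

The sequence pool is estimated by capture–recapture over library pairs.
The bias-corrected Chapman estimator is the default because it is
finite at zero overlap and less biased than Lincoln–Petersen at small
overlap (Lincoln–Petersen is selectable; the two agree within 1% at
large overlap, which a regression test checks). The multi-library point
estimate is the **median** of all pairwise estimates, and the pairwise
extremes are reported as minimum and maximum — matching the
min/point/max reporting shape of the estimate. The estimator assumes
equal catchability; on real libraries, abundance heterogeneity biases
it downward, which is one reason the pairwise spread is always
reported.

## Synthetic data: what it emulates, and what it does not

`build_genome` plants, on random contigs (default 6 × 80 kb), repeats of
all six classes (one family, LTR/Gypsy, is pasted as identical copies
so its reads genuinely multi-map), three-exon genes with strand-aware
UTR/CDS structure, and structural ncRNAs. `simulate_libraries` draws
reads from a pool of piRNA-producing loci:

* **Length mixture** — miRNA-like component: truncated discrete
  Gaussian, mean 21.5, sd 1, on 18–23 nt; piRNA-like component: mean
  27, sd 1, on 24–30 nt. The per-library piRNA weight makes embryo and
  sugar-fed female piRNA-dominant (0.65/0.60) and the other stages
  miRNA-dominant (0.30–0.40), reproducing the major/minor length-peak
  inversion between stages.
* **1U/10A** — planted by rejection-sampling locus positions until the
  genomic bases under positions 1 and 10 match independently drawn
  Bernoulli(0.76)/Bernoulli(0.41) targets; reads stay exact genome
  substrings.
* **Ping-pong** — a paired locus emits an opposite-strand partner with
  every read: 5′–5′ overlap exactly 10 with probability
  `ping_pong_rate` (bundle default 0.30), else uniform on 1–30 (the
  flat background). Because partner reads are exact substrings, the
  partner's position-10 base **is** the complement of the primary's
  first base: 1U and 10A cannot be planted independently on the two
  members of an exact-match pair — this coupling is real ping-pong
  geometry, not an implementation shortcut. Consequently the planted
  1U/10A marginals refer to primary loci; marginal-recovery checks use
  the dedicated per-read simulation with pairing off
  (`simulate_base_bias_reads`, i.i.d. per read, so the observed
  fraction is genuinely binomial), and ping-pong recovery uses the
  block-separated pair simulation (`simulate_ping_pong_reads`, one
  event per ≥ 160-bp intergenic block, so no incidental cross-event
  overlaps contaminate the histogram).
* **Categories and strand bias** — locus counts follow
  intergenic/repeat/gene = 0.5/0.3/0.2, with class-specific sense
  probabilities (antisense-dominant LINE/LTR/DNA, sense-dominant SINE)
  and subfeature-specific gene biases.
* **Clusters** — six intergenic loci of 20 member tags each, separated
  by more than the merge gap, one divergent (two opposite-strand
  halves); member abundances are rescaled so the planted cluster read
  share (intergenic fraction × 0.9 = 45% of piRNA reads) holds exactly
  in expectation, which also gives each member tag cluster-grade
  (≥ 200-read) support at bundle depth. Per-cluster stage profiles
  (embryo-high, larva-high, …) drive the expression patterns.
* **Expression effects** — planted differential groups (male-biased,
  female-biased, blood-induced, blood-specific, embryo-high) multiply
  per-library abundances by 4–6×; these loci are drawn abundant (6×
  base abundance), as differential analyses of tag counts concern
  well-sampled piRNAs.
* **Contaminants** — ncRNA-locus fragments (4%), homopolymer artifacts
  (1%), and the 3′ adapter appended to every read, truncated at the
  36-nt machine read length, so the trimmer is genuinely exercised.

Not emulated: base-call errors and quality-score structure (reads are
exact substrings apart from planted artifacts), isoform structure,
genome assembly artifacts, and realistic genome scale. Passing tests
therefore demonstrate correctness of the statistics and the planted-
signal recovery of the estimators — not robustness to sequencing error
or to mappability pathologies of a 2-Gb repeat-rich genome.

## Problem sizes and numerical choices

The default test/acceptance bundle uses 30,000 primary emission events
per library over a ~480-kb toy genome with ~1,100 loci — sizes chosen
so every planted signal is comfortably detectable while a full run
completes in seconds; the CLI default matches. The focused simulations
use 50,000 reads (1U/10A marginals), 800–1,500 pair events (ping-pong),
and a pool of 10,000 with two samples of 2,000 (capture–recapture).
Poisson-test simulations use 10,000 tags at mean count 25, where the
exact test's discreteness is mild (observed null rejection ≈ 0.04 at
nominal 0.05) and 4-fold effects are detected with essentially full
power.

Determinism: a single `numpy` Generator seeds each simulation; the
pipeline itself is deterministic, tables are written with a fixed float
format, and byte-identical reruns are asserted in the suite. Degenerate
inputs: empty libraries warn and propagate as empty tables; a missing
repeat annotation yields empty repeat categories with a warning rather
than an error; undefined ratios are flagged (inf for an empty antisense
side, NaN for an empty group).

## Known limitations

* Exact matching understates mappability on polymorphic or error-prone
  data; the SAM-ingest path is the escape hatch.
* The annotation precedence (repeat > gene) and the exon-keeping rule
  are conventions; both are localised and overridable in code.
* Chapman capture–recapture assumes homogeneous capture; heterogeneous
  tag abundances bias the pool estimate toward the abundant fraction
  of the pool.
* `mixed_overlapping` dual-strand cluster loci are reported as a
  residual state; no biological sub-classification is attempted.
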