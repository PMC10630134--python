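# Methods

## Model

Two genomes are modelled as a string \(G\) and a mutated copy \(G'\) in
which every base is independently substituted (to a different letter)
with probability θ; true ANI is defined as 1 − θ. Under this model a
k-mer survives mutation with probability (1 − θ)^k, which is what makes
ratios of matching k-mers to total k-mers invertible to an ANI: if a
fraction r of k-mers in a homologous region match exactly, then
ANI ≈ r^(1/k). The package's central idea is to restrict that ratio to
*orthologous regions found by chaining*, so that k-mers missing because
of assembly incompleteness, contamination or structural variation never
enter the denominator. For random sequence the spurious-match
background between unrelated length-n strings is ~n²/4^k pairs (about
9 matches for n = 100 kb at k = 15), far below any signal the chainer
accepts.

## Pipeline and parameters

All tunables live in one `SketchParams` record; the defaults are the
package's operating point and every comparison is stamped with a
parameter fingerprint so sketches made under different settings can
never be silently mixed.

| parameter | default | meaning |
|---|---|---|
| k | 15 | seed k-mer length (anchoring/chaining) |
| c | 125 | seed subsampling rate (expected density 1/c) |
| marker_k | 21 | marker length (screening only) |
| marker_c | 1000 | marker subsampling rate |
| chunk_size | 20 000 b | query fragmentation window |
| band_B | 2500 b | max query gap while chaining |
| band_A | B//c (≥1) | predecessors scanned per anchor |
| mask_threshold | B//c (≥1) | max occurrences before a seed is masked |
| marker_ani_threshold | 0.80 | screening gate on ANI_FMH |
| af_threshold | 0.15 | min AF (either genome) to report ANI |
| lr_ani_gate / lr_min_span | 0.950 / 4c b | truncated-chunk estimate gates |
| min_chain_anchors | 3 | orthologous-selection minimum |
| overlap_frac | 0.50 | max reference-span overlap for selection |
| bootstrap_iters / min_chunks | 100 / 10 | CI resamples; CI needs > 10 chunks |
| debias gates | ANI > 0.90, > 150 kb, c ≥ 70 | learned-correction applicability |

CLI presets map to c = 30 (slow: very fragmented/distant genomes),
70 (medium), 200 (fast: similar, contiguous genomes); an explicit `-c`
wins over a preset. Runtime and sketch size scale as 1/c.

### Hashing and selection

k-mers are 2-bit encoded; the canonical form is the numerically smaller
of the encoding and its reverse-complement encoding (A<C<G<T), passed
through the murmur3 `fmix64` finalizer — any fixed invertible 64-bit
mixer serves, since FracMinHash only needs a uniform, deterministic
hash. Selection keeps a window iff its hash < 2^64/rate (inclusive
arithmetic handles rate = 1 exactly). Windows covering any non-ACGT
character are voided outright; no IUPAC expansion is attempted, which
keeps the rule deterministic and unbiased. Coordinates are 0-based,
positions name the leftmost base of a window, and all intervals are
half-open.

Masking removes seed hashes occurring more than B//c times (integer
division, floor 1) *per genome*: at k = 15, repeats would otherwise
flood the chaining band. Per-genome (rather than per-contig) counting
was chosen because repetitive families span contigs.

### Chaining

Anchors are grouped by (reference contig, relative orientation) and
chained within a group only. Reverse-orientation groups are chained in
mirrored reference coordinates y′ = contig_length − k − y so that one
strictly-increasing DP serves both strands; spans are mapped back
before any overlap arithmetic. The score S(i,j) = 20 − |Δy − Δx|
rewards diagonal consistency and deliberately ignores k-mer overlap:
the chain must collect *every* homologous seed or the ANI ratio would
be biased. The DP scans at most band_A predecessors and stops early
when the query gap exceeds band_B; ties in the predecessor argmax go to
the earliest anchor, and union-find backtracking emits exactly one
chain per predecessor component (anchors of a component not on its best
path are dropped, not re-emitted). With the band disabled the DP is
exactly the O(N²) optimum — the suite asserts score *and* predecessor
equality against an exhaustive oracle.

### Chunk estimates and aggregation

Trailing partial chunks are kept and weighted by their seed counts;
discarding them would bias fragmented assemblies whose contigs rarely
hit 20-kb multiples. For a chunk, α is capped at M (multiple reference
occurrences of one chunk seed can otherwise inflate the count) and the
truncated estimate uses the seeds between the flanking anchors on
*query* coordinates (flank span + k bases), since M and M_LR count query
seeds. Orthologous-selection overlap is measured on reference
coordinates because paralogy duplicates reference loci. Per-chain
covered bases add 2c to the anchor span to compensate for the expected
c-base overhang of subsampled seeds at each chain end; AF sums these
per genome and is capped at 1. The AF gate passes if *either* genome
reaches 15%: a complete genome versus a small true fragment should
still be reported.

The bootstrap resamples chunks with replacement (100 iterations,
weighted mean, 5th/95th percentiles) and runs only with > 10 chunks; it
quantifies seeding variance only and never moves the point estimate.
The RNG is a single seedable generator; the CLI derives a per-pair seed
from the user seed and the two genome ids so output bytes are
independent of row evaluation order and thread count.

### Learned correction

Chains can slightly overestimate ANI because mutated k-mers near chain
edges fall outside the chain. The optional correction is a
gradient-boosted regression tree (absolute-deviation loss) over five
features: the raw ANI, the SD of per-chunk ANI estimates, the
90th-percentile contig length of each genome, and the mean reference
span of the selected chains. Training truth is the known 1 − θ of
synthetic pairs; validation holds out a random split (and, where base
genomes are reused, all pairs from unseen bases). The correction is
clamped to ±0.02 of the raw value and to [0, 1], fires only above 90%
ANI with > 150 kb aligned, and auto-enables only at c ≥ 70 — at denser
seeding the bias is negligible. "SD of the putative ANI distribution"
is read as the chunk-ANI SD (not the bootstrap SD); the two are close
in practice, the chunk SD being cheaper and seed-independent. No
pretrained weights ship with the package; `chainani.debias.train_debias`
builds a model from synthetic pairs in seconds.

## What the generator emulates — and what it does not

`chainani.simgen` produces i.i.d. uniform ACGT genomes, independent
per-base substitutions (no indels), fragmentation by uniform random
breakpoints calibrated so the realized N50 approximates a target
(length-weighted median of near-exponential fragments ≈ 1.678 × mean),
random contig dropout to a target completeness, and unrelated random
contigs as contamination. It does **not** emulate GC skew, repeat
families, horizontal transfer, chimeric bins, indels or real assembler
error profiles. Passing tests therefore demonstrate correctness of the
estimator under its own mutation model and robustness to the modelled
assembly artefacts — not calibration against alignment-based ANI on
real MAGs. Indel robustness is exercised only implicitly (fragmentation
breaks collinearity the way small rearrangements do); an indel mode is
an extension point.

## Numerical and design choices

- Banded-DP window: band_A is the *number of predecessors scanned*
  (j ∈ [i−A, i−1]), the natural reading that keeps A = 1 meaningful.
- Reference selection maximizes total_length × mean contig length,
  ties broken lexicographically on genome id, so results are symmetric
  to argument order bit-for-bit.
- The screen is strict (> 0.80), as is the truncated-estimate gate
  (> 0.950); the AF gate is ≥ 0.15.
- Marker/seed sets are sets: multiplicity is discarded before
  containment, which is defined on sets.
- A genome too short to carry markers cannot be screened; the pair
  proceeds with a warning rather than silently failing.
- Sketch files are a canonical (sorted) binary layout, so
  write → read → write is byte-identical; the marker section precedes
  the seed section so database search can stop reading early.
- Problem sizes in the suite (1-Mb genomes, 20–30 replicates per
  regime, 500 chaining-oracle instances) were chosen as the smallest
  scales at which the binomial/bootstrap statistics under test are
  stable; all tolerances were frozen from oracle runs before being
  enforced.

## Known limitations

- Accuracy degrades below ~82% ANI (the screen deliberately refuses
  such pairs): sparse seeds leave too few anchors per chunk.
- AF sums chain spans without merging overlaps on the same genome; the
  0.50 overlap bound keeps double-counting small, and AF is capped at 1.
- The per-chunk estimator assumes seeds are uniformly informative;
  low-complexity sequence that survives masking can still distort a
  chunk.
- The chaining heuristic is not the optimal sub-quadratic chainer; it
  is the banded heuristic by design, and only its band-disabled limit
  is exact.
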