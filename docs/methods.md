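# Methods

`redyeast` packages the bespoke computational stages of a small-fungal-genome
comparative analysis — reference-guided scaffolding, synteny-block
detection, orthogroup presence/absence analytics, k-mer-spectrum genome-size
and ploidy estimation, and 2^−ΔΔCt qPCR quantification — together with a
synthetic-data generator that provides ground truth for every stage.  This
note records the models, the parameters that matter, the numerical choices,
and what the synthetic benchmarks do and do not demonstrate.

## Reference-guided scaffolding

### Anchor discovery

Anchors are maximal exact matches (MEMs): shared substrings of at least
`min_match` bp (default 20) that cannot be extended by one base in either
direction.  Discovery seeds on fixed-length `min_match`-mers (2-bit-encoded,
located through a sorted-array index of the reference) and extends each seed
outwards to maximality; a per-diagonal cursor prevents re-extending seeds
that fall inside an already-emitted match.  `N` never matches anything,
including another `N`, so anchors are always N-free.  Both strands are
searched; a `−` anchor relates the reverse complement of the query interval
to the reference interval, and its conserved coordinate is the anti-diagonal
`q_start + r_end` (constant along a reverse-strand collinear run) rather
than the diagonal `r_start − q_start` used for `+` anchors.

The default `min_match` of 20 makes spurious seeds between unrelated
sequences negligible at ~20 Mb genome scale (a random 20-mer collision rate
of 4^−20 per position pair), while remaining short enough that ~3% diverged
genomes still produce dense anchor chains (the expected exact-match run
between 97%-identical sequences is ~33 bp).

### Chaining (maxgap / mincluster)

Anchors of one (query, reference, strand) combination are chained by
single-linkage closure: two anchors belong to the same cluster when,
transitively, their query gap, reference gap and diagonal offset difference
are all ≤ `maxgap` (default 500 bp).  Because the relation is a closure
rather than a greedy scan, the clustering is independent of input order.
Clusters whose summed anchor length is below `mincluster` (default 100 bp)
are discarded.  These two defaults are the classic anchor-chaining settings
for closely related genomes.

### Identity and filtering

Cluster identity is matching columns over alignment columns of a global
minimum-edit (unit cost) alignment of the clustered query span against the
clustered reference span (reverse-complemented for `−` clusters), computed
with edlib.  Identity by global alignment, rather than by anchor coverage,
avoids underestimating identity around indels.  The final filter keeps
clusters with aligned query span ≥ `min_align_len` (default 1,500 bp) and
identity **strictly greater than** `min_identity` (default 0.97): a span of
1,499 bp or an identity of exactly 0.970 is rejected.  The length cut-off is
interpreted as a minimum aligned span per cluster, not a minimum scaffold
length, and both thresholds are configurable.

### Placement and joining

Each query scaffold with at least one surviving cluster is assigned to the
reference scaffold carrying the largest total aligned length; orientation is
the strand holding the majority of that support; the anchor position is the
smallest reference start among supporting clusters.  A query is never split
across references — chimeric queries are out of scope.  Per reference
scaffold, placements are sorted by anchor position (ties: larger support,
then query id) and joined with runs of N whose length is the estimated
reference distance between consecutive placements, floored at `min_gap`
(default 100; a fixed gap size is available).  Reference-distance gaps
preserve the reference's geometry while the floor marks every joint
unambiguously, including overlapping placements (negative estimated gap).
Unplaced queries are dropped by default and appended verbatim only on
request, mirroring the observation that a scaffolded assembly with as many
records as its reference implies leftovers were not emitted.

Assembly statistics use the conventional N50: the length of the first
scaffold, in descending length order, at which the cumulative length reaches
half the total.  The length filter keeps scaffolds of exactly the threshold
length (default 2,000 bp — "removing scaffolds < 2,000 bp").

## Synteny blocks

Anchors here are orthologous gene pairs with ordinal positions along their
scaffolds.  Within one scaffold pair the chainer repeatedly extracts the
maximum-cardinality strictly monotone chain — co-monotone for `+` blocks,
anti-monotone for `−` — subject to an ordinal gap bound (`max_gene_gap`,
default 25 skipped genes) on both genomes, removing each extracted chain's
anchors before searching again, until no chain reaches `min_block_genes`
(default 5; a four-gene run is never reported).  Cardinality scoring keeps
the exhaustive-enumeration oracle exact; ties between candidate chains go to
the chain with the smaller starting ordinal on genome A, then to `+`, making
the output independent of input order.

A limitation of cardinality scoring: an inversion whose span exceeds roughly
twice the gap bound cannot be recovered as a separate block, because a
single anchor inside the inverted segment can serve as a monotone
stepping stone that joins the two flanks into one longer chain.  Truth
recovery on simulated inversions therefore requires `max_gene_gap` below
half the inversion span (the recovery tests use 2 with spans ≥ 5);
gap-penalized scoring, which would remove the artefact, is out of scope.

## Orthogroup presence/absence analytics

The presence matrix sets cell (genome, group) to 1 when the genome has at
least one member in the group (no minimum copy number).  Jaccard distance
between genomes is 1 − |intersection| / |union| of their presence sets,
defined as 0 when both sets are empty.  Genomes are clustered by
agglomerative hierarchical clustering (average linkage by default; complete
and single available) implemented as a small Lance–Williams agglomeration so
that ties in the merge queue can be broken deterministically toward the pair
containing the lexicographically smallest genome label; node heights are
half the merge distance (UPGMA convention), so the dendrogram is
ultrametric.  scipy's implementation is used as an independent cross-check
in the test suite, never as the implementation.

The Venn partition assigns each group to the exact subset of genomes
containing it (core = all-genomes subset, unique = singletons); the subset
counts partition the group set.  Single-copy groups have exactly one member
in every listed genome; every single-copy group necessarily lies in the
core.  Topology agreement between the presence/absence dendrogram and an
independently estimated species tree is measured by the unrooted
Robinson–Foulds distance (dendropy), 0 iff the topologies agree.

## K-mer spectrum

Canonical counting pools each k-mer with its reverse complement under the
lexicographically smaller 2-bit spelling; k must be odd so no k-mer is its
own reverse complement.  Windows containing N are skipped.  Counting is
vectorized: reads are joined with a single `N` separator (which also
invalidates cross-read windows) and window codes are assembled by recursive
doubling over power-of-two block widths, so a full read set is encoded in a
handful of whole-array operations.  k defaults to 31.

Spectrum fitting smooths the histogram with a centred moving average
(window 3; the empty multiplicity-0 bin is padded with h(1) so the smoother
cannot fabricate a local minimum at m = 1).  The error cutoff `m_err` is the
first multiplicity where the smoothed spectrum turns upward; a monotone
decreasing spectrum yields an `ambiguous` call with a warning.  The main
peak c is the modal multiplicity above `m_err`.  Ploidy: the spectrum is
called diploid when a smoothed local maximum with height ≥ 10% of the modal
bin lies within ±25% of c/2 — or of 2c, since at ~1% haplotype divergence
and k = 31 the heterozygous peak (at half coverage) is frequently *taller*
than the homozygous peak, in which case the modal multiplicity is the
heterozygous peak and the homozygous companion sits at twice it.  The two
cases are canonicalized so `main_peak` always reports the homozygous peak
and `secondary_peak` the heterozygous one.  Both thresholds (25% proximity,
10% height) are configurable.

Genome size is the number of k-mer instances above the error cutoff divided
by a sub-integer coverage estimate.  For a single-peak spectrum that
estimate is the count-weighted mean multiplicity of the whole signal region,
which is nearly unbiased (errors lie below `m_err`, so the mean runs over
genomic k-mers only); dividing by the integer modal bin instead would carry
a ±1-bin bias of up to several percent at moderate coverage.  For a
two-peak spectrum the mean is restricted to a re-centred ±25% window around
the homozygous peak so the heterozygous peak cannot deflate it; the
resulting size approximates the haploid genome length.  Multiplicities
above 10× the modal bin are excluded from peak search but included in the
size sum (they represent repeats, not noise).

## qPCR quantification

The Livak 2^−ΔΔCt method: per sample, ΔCt = mean Ct(target) − mean
Ct(housekeeping) over replicates (arithmetic mean of Ct, the standard
summary); ΔΔCt = ΔCt(treated) − ΔCt(control); fold = 2^−ΔΔCt.  Adding a
constant to every Ct leaves the fold unchanged, and swapping the sample
labels inverts it exactly.  Primer-efficiency correction is deliberately not
modelled — the pure formula assumes near-100% efficiency.  When a Ct table
carries an `experiment` column, per-experiment mode computes one fold per
experiment and averages the folds (appropriate for independent experiments
run in triplicate); the default pools all replicates.

## Synthetic data: what it does and does not emulate

The generators are pure functions of (parameters, seed).  One root seed is
combined with a stable per-generator label (BLAKE2 hash) so adding a
generator never perturbs another's stream.

- **Genomes** are i.i.d. bases at a chosen GC fraction — no repeats, no
  compositional heterogeneity.  Anchor uniqueness and k-mer spectrum
  results on such genomes are therefore best cases; real genomes add
  repeat-induced ambiguity that these benchmarks do not probe.
- **Fragmentation** tiles the source exactly (breakpoints uniform with a
  minimum fragment length via stick-breaking), inverts each fragment with
  probability `p_invert` and applies i.i.d. substitutions — no indels, no
  missing or duplicated sequence, so scaffolder recovery tests demonstrate
  ordering/orientation logic, not robustness to structural error.
- **Reads** are uniform single-end substrings with i.i.d. substitution
  errors and no quality model; coverage `c`, length `L_r` give
  ceil(c·L/L_r) reads.
- **Gene families** evolve by pure loss along a tree whose branch lengths
  are per-branch loss probabilities; a retained family contributes exactly
  one gene per surviving taxon (a duplication rate exists but defaults to
  off so single-copy extraction has controlled copy numbers).  Families
  lost everywhere are dropped (a group absent from every genome cannot be
  observed).
- **Gene orders** differ by non-overlapping segmental inversions; truth
  blocks are the maximal conserved runs.
- **Ct tables** shift the treated target by −log2(true fold), leave the
  housekeeping gene unshifted and add Gaussian replicate noise.

## Benchmark problem sizes

The test suite and the acceptance script use: a 2 Mb genome in three
reference scaffolds cut into 40 fragments (≥ 5 kb, 30% inverted, 1%
diverged) for the scaffolder round trip; 200 random anchor sets of ≤ 12
anchors for the synteny oracle; 100 replicates of a 5-taxon, 2,000-family
loss simulation for clustering recovery; 20 haploid read simulations over
300 kb genomes at coverage 30–60 (plus one 500 kb worked example and 10
two-haplotype simulations at 1% divergence over 200 kb) for the spectrum;
and noise-free plus σ = 0.2 Ct designs for ΔΔCt.  These sizes keep every
property measurable with comfortable statistical margins on a single CPU.

## Known limitations

- One placement per query: chimeric scaffolds spanning two references are
  placed on the better-supported one, never split.
- Identity scoring assumes N-free cluster spans (guaranteed for anchors,
  not enforced for the inter-anchor gaps of real data with N runs).
- The spectrum fitter models at most two peaks; higher ploidies and strong
  repeat structure fall back to `haploid`/`ambiguous` calls.
- Jaccard clustering treats group presence, not per-genome protein counts;
  gene-family expansions are invisible to it.
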