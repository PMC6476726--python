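# redyeast

Comparative-genomics building blocks for small fungal (red-yeast-sized)
genomes, written for analyses where one well-assembled genome serves as a
reference for a closely related, fragmented one:

- **Reference-guided scaffolding** — maximal-exact-match anchors chained
  with the classic `maxgap`/`mincluster` rules, identity-filtered clusters
  (aligned span ≥ 1,500 bp, identity > 97%), query scaffolds ordered and
  oriented along the reference and joined with N runs; AGP v2.1 output,
  assembly length filter and N50 statistics.
- **Synteny blocks** — maximum-cardinality collinear chains of orthologous
  gene anchors per scaffold pair, with the five-gene block cut-off.
- **Orthogroup analytics** — genomes × orthogroups presence/absence matrix,
  Jaccard distances d(X,Y) = 1 − |X∩Y|/|X∪Y|, average-linkage clustering
  with deterministic tie-breaking, core/unique Venn partition, single-copy
  orthologue extraction, Robinson–Foulds topology comparison.
- **K-mer spectrum** — canonical k-mer counting (k = 31), error-valley /
  coverage-peak detection, genome size G = Σ_{m>m_err} m·h(m) / c and a
  haploid/diploid/ambiguous ploidy call from companion-peak structure.
- **2^−ΔΔCt quantification** — Livak fold changes from replicated Ct tables
  with a housekeeping gene.
- **Synthetic data** — seeded generators for every input above with known
  ground truth: fragmented/inverted/diverged genomes, shotgun reads, gene
  families lost along a tree, gene orders with inversions, Ct designs.

See `docs/methods.md` for the models, parameter defaults and numerical
choices.

## Worked example

Simulate a reference, shatter it into diverged shuffled fragments, and
scaffold them back:

```bash
redyeast simulate genome --length 40000 --seed 3 --out ref.fa
redyeast simulate fragments --genome ref.fa --n-fragments 5 --p-invert 0.4 \
    --substitution-rate 0.005 --min-fragment-len 5000 --seed 3 --out-prefix frags
redyeast scaffold --query frags.fasta --ref ref.fa --out-prefix scaf
redyeast stats scaf.fasta
```

which prints

```
n_scaffolds	total_length	n50	largest
1	40400	40400	40400
```

— the five fragments were all placed on the single reference scaffold and
joined with four 100 bp N runs (40,000 bp of fragments + 400 bp of gaps);
`scaf.placements.tsv` lists each fragment's reference position, orientation
and supporting aligned length, and `scaf.agp` records the composition.

The same operations are a library:

```python
from redyeast import AlignParams, scaffold_assembly
from redyeast.synthetic import simulate_genome, fragment_and_shuffle

refs = [simulate_genome(667_000, 0.5, seed, f"ref{seed}") for seed in range(3)]
frags, truth = fragment_and_shuffle(refs, 40, 0.3, 0.01, seed=0, min_fragment_len=5000)
supers, placements, unplaced = scaffold_assembly(frags, refs, AlignParams())
```

Other subcommands: `align`, `filter`, `synteny`, `orthomat`, `orthoclust`,
`orthovenn`, `singlecopy`, `rfdist`, `kmerhist`, `kmerfit`, `ddct`, and
`simulate {genome,fragments,reads,families,orders,ct}`.

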