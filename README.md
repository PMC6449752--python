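# phatpack

Tools for **automatic reference trees and multilevel phylogenetic placement**.

Phylogenetic placement attaches anonymous environmental reads (query
sequences, QS) onto the branches of a fixed reference tree (RT), scoring
each branch with a likelihood weight ratio (LWR).  Doing this well at scale
raises three practical problems that `phatpack` addresses:

1. **Which reference sequences?**  Curating an RT by hand from databases
   with hundreds of thousands of taxonomically annotated sequences is
   impractical.  `phatpack` builds a *Phylogenetic Automatic (Reference)
   Tree* (PhAT) input set: it measures the diversity of each taxonomic
   clade *t* by the Shannon entropy of its aligned sequences,

       H_i = − Σ_c f_c,i · log₂ f_c,i ,   c ∈ {A, C, G, T, −}
       H(t) = Σ_i H_i   over all alignment sites i,

   and greedily expands the most diverse clades of the taxonomy until a
   user-chosen number of candidate clades is reached.  Each candidate is
   then represented by one per-site majority-rule consensus sequence,
   labelled with its taxonomic path, ready for ML tree inference (a
   taxonomy constraint tree is emitted alongside).
2. **How to place on huge trees?**  *Multilevel (Russian Doll) placement*:
   place first on a broad backbone tree (BT), route each query to the clade
   tree (CT) owning the BT branches it hit, and place again there.
   Splitting 10 000 taxa into a BT and CTs of 1 000 taxa each cuts compute
   by 5× and peak memory by 10× (`cost-model`).  Queries landing on inner
   BT branches are filtered — placement-based removal of spurious reads.
3. **How to place billions of reads?**  Exact cross-sample deduplication
   with per-sample abundance maps, chunking into equal-size FASTA chunks
   for the placement engine, and resolution of per-chunk jplace results
   back into per-sample jplace files with correct multiplicities.

An evaluation module scores placement quality: LWR-weighted topological and
branch-length distances to each query's *expected* edge, the expected
distance between placement locations (EDPL), clade-identification accuracy,
cumulative accuracy curves, and placement-based taxonomic assignment.

The package reads/writes aligned FASTA, Silva-style taxonomy tables
(`id<TAB>Rank1;Rank2;`), edge-numbered newick (`A:0.1{0}`) and jplace v3.
ML tree inference and the placement engines themselves (RAxML, EPA-ng,
pplacer, …) are external and out of scope; a fixtures module generates
synthetic stand-ins so the whole pipeline runs self-contained.

## Worked example

```sh
phatpack fixtures --preset small --seed 3 --out-dir demo
phatpack phat --taxonomy demo/taxonomy.tsv --alignment demo/alignment.fasta \
              --target-size 6 --out-prefix demo/ref
```

prints

```
candidates: 7 (target 6)
target_deviation_percent: 16.67
consensus_records: 7
```

i.e. the greedy expansion overshot the target by one clade — the second
expanded clade brought three sub-clades at once, and the target cannot
always be met exactly — yielding 7 labelled consensus sequences in
`demo/ref.fasta` with the constraint tree in `demo/ref.constraint.newick`.

```sh
phatpack route --jplace demo/mock.jplace --clades demo/clades.tsv --out-dir demo/routed
phatpack eval  --jplace demo/mock.jplace --expected demo/expected.tsv --out demo/report.tsv
```

prints (routing) `labels: 3` / `filtered_pqueries: 0` and (evaluation)

```
pqueries: 36 (unmapped 0)
mean_edge_distance: 0.0000
mean_bl_distance: 0.0000
fraction_exact: 1.0000
fraction_within_one: 1.0000
```

— on this noise-free mock placement every query sits exactly on its
expected branch, so the mean weighted distances are 0 and the fraction of
exactly placed queries is 1.  `phatpack cost-model --full 10000 --bt 1000
--ct 1000` prints `speedup: 5` and `memory_factor: 10`.

See `phatpack --help` for all subcommands (`entropy`, `phat`, `route`,
`chunkify`, `unchunkify`, `eval`, `fixtures`, `cost-model`) and
`docs/methods.md` for the model details and design choices.

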