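# Methods

## The problem and the model

Classical BGC miners assume the microbial situation: pathway genes that are
contiguous, co-oriented and colinear. In animal genomes, validated pathway
loci instead show *semiconserved neighbourhoods* — the same enzyme genes
recur near each other across species, but in species-specific order and
separated by variable runs of unrelated genes (observed separations between
co-bundled vertebrate pathway genes reach 19 intervening gene models).
`bundlemine` therefore models a candidate locus as a **bundle**: a set of
motif-flagged genes on one scaffold whose pairwise separations, counted in
intervening gene models, respect two gap tolerances. Everything downstream
(family formation, phenotype screening, co-occurrence) treats a bundle as
its **domain signature** — the set of motif identifiers on its flagged
genes — and ignores order, orientation and copy number.

## Pipeline stages, parameters, defaults

### Filtering

A gene is flagged iff it has ≥ 1 hit against the motif library with
`score ≥ score_threshold` and, when an e-value is present,
`evalue ≤ evalue_threshold` (default `1e-5`, the conventional
homology-search cutoff). Three interchangeable backends satisfy the same
contract:

* **table** — precomputed hit tables. Both a simple whitespace-delimited
  `gene motif score [evalue]` layout and full HMMER `domtblout` rows
  (target name, query name, full-sequence e-value and score at their
  standard columns) are accepted; `#` lines are comments. This is the
  intended production path: run hmmscan or DIAMOND yourself.
* **builtin_kmer** — score = number of distinct k-mers (k = 4) shared with
  the best-matching exemplar protein, divided by query length; default
  `score_threshold = 0.1`. Deterministic, dependency-free, and exact on
  the synthetic fixtures (see below); it is a real, if crude, similarity
  search, not a mock.
* **external** — an adapter point: any search whose output is fed back
  through the table backend.

The summary reports **both** the pooled percentage
(100 × Σ flagged / Σ total) and the unweighted per-genome mean, clearly
labelled, because the two differ whenever genome sizes differ; percentages
are rendered to one decimal.

### Two-stage bundling

Per scaffold, with flagged genes at ordinals `o_1 < o_2 < …`:

* **Stage 1** joins consecutive flagged genes when
  `o_{i+1} − o_i − 1 ≤ g1` (default **g1 = 5**, a tight neighbourhood);
  clusters with fewer than `min_core` (default **2**) flagged genes are
  discarded — a lone flagged gene is not a bundle.
* **Stage 2** merges neighbouring surviving clusters, transitively, when
  the count of gene models strictly between their spans is ≤ `g2`
  (default **g2 = 20**, chosen to span the 4–19 intervening-gene
  separations seen in validated vertebrate bundles). Stage 2 never crosses
  a scaffold and is idempotent.

Gaps are counted in gene models rather than bp because gene density, not
intergenic length, is what is comparable across assemblies. Both `g1` and
`g2` are prominent CLI flags; bp-based bundling was deliberately not made
the primary mode. Ordinals are assigned by sorting each scaffold's genes by
(start, end, gene_id) — the gene_id tie-break makes loading
permutation-invariant and deterministic.

One monotonicity subtlety: widening `g1`/`g2` always *coarsens* the result
(every tight-gap bundle is contained in exactly one wide-gap bundle, and
no gene loses membership), but the bundle **count** is only monotone when
`min_core = 1`. With `min_core ≥ 2`, widening can promote two previously
discarded singletons into a new bundle (flagged ordinals {0, 2}: g1 = 0
gives no bundles, g1 = 1 gives one). The tests assert the coarsening form.

### Families

Raw distance between bundles is `1 − Jaccard` on domain **sets**; edges
form at `raw_distance ≤ 0.5` (inclusive — the rule must pick a side, and
inclusive keeps the boundary case of exactly half-shared signatures
linked), and families are connected components (single linkage), matching
common practice in BGC family networks. An adjacency/synteny term was
deliberately left out of the metric: the bundling model explicitly
disclaims conserved order, so rewarding colinearity would contradict it. A
weighted multiset-Jaccard variant (min/max over per-gene domain counts) is
available via `metric="multiset_jaccard"` for users who want copy number
to matter; it is API-only because per-gene counts are not serialized in
the bundles TSV.

### Phenotype screen

Presence of a family in a genome means ≥ 1 member bundle from that genome;
copy number is ignored. *Exclusive* (≥ 1 producer, no non-producer) and
*universal* (every producer) are computed independently — a family can be
either, both, or neither — because conflating them would hide candidates
that are universal but leak into one non-producer (e.g. an unrecognised
producer). By default singleton families are excluded from the screened
set: a bundle observed in a single species carries no cross-species
signal; they are counted separately.

### Co-occurrence

For each unordered domain pair, `cooccurrence` = number of bundles whose
signature contains both (presence per bundle, not multiplicity) and
`probability = cooccurrence / total_clusters`. Edges are kept only when
probability is **strictly** greater than 0.025; with 40 bundles, a pair
seen once (probability exactly 0.025) is dropped, with 39 it is kept.
Sorting is by descending probability, then pair name, so `top_k` is
deterministic under ties.

## The synthetic-data generator

`bundlemine.synthetic` emulates a small comparative survey. Defaults: 5
producer + 3 non-producer genomes, 2 scaffolds × 120 gene models each, one
six-gene bundle planted in every producer plus two three/four-gene bundles
planted in producer subsets, gaps between planted members drawn uniformly
from [0, 4], and ~2% of remaining genes flagged as decoys — a flagged
fraction of the same order as real biosynthetic filters retain. Per
species, planted member order is shuffled and gaps are redrawn, giving the
semiconserved-order, variable-interspersion structure the bundler is built
for.

Design choices worth knowing:

* Exemplar and flagged proteins are built from one half of the amino-acid
  alphabet, neutral proteins from the disjoint other half, so the built-in
  k-mer matcher separates the classes perfectly. Recovery tests therefore
  probe bundling logic, not matcher noise — and, correspondingly, passing
  them says nothing about motif-detection sensitivity on real sequences.
* Decoys are *isolated*: placed at least `g2 + 1` gene models from any
  planted bundle and from each other. They can therefore never form or
  join a bundle (they test that scattered flagged singletons are
  discarded), and the manifest's planted bundles are exactly the ground
  truth bundle set. Real genomes will contain flagged genes that happen to
  co-locate by chance; the generator does not model that background rate.
* One global seed; per-genome substreams are derived by CRC-32 hashing of
  `"{seed}:{genome_id}"`, so outputs are byte-identical under a fixed seed
  and adding a genome leaves the others unchanged.
* Not modelled: sequence evolution, paralogy, isoforms, fragmented
  assemblies, bundles split across scaffolds.

## Numerical and degenerate-input choices

* All thresholds' boundary behaviour is fixed and tested: stage gaps and
  the family threshold are inclusive (`≤`), the co-occurrence display
  threshold is strict (`>`).
* Ties everywhere break lexicographically (ordinals by gene_id, family ids
  by smallest member bundle id, co-occurrence by pair name); repeated runs
  are byte-identical except the timestamp confined to `run_manifest.yaml`.
* Empty inputs: zero flagged genes → zero bundles (valid, empty outputs);
  an empty motif library or zero genes after the feature filter is a
  configuration/input error; co-occurrence over zero bundles is an error
  (the probability denominator would be undefined).
* Isoform-level annotations are collapsed (behind a flag) to one record
  per gene, longest protein winning, ties to the smallest feature id —
  preventing isoform-inflated bundles.

## Verification strategy and problem sizes

The bundler is checked against an independent oracle that enumerates all
2^(n−1) contiguous partitions of a scaffold's flagged ordinals and asserts
the gap-respecting partition is unique, for scaffolds of ≤ 15 flagged
genes over 200 randomized configurations; families are checked against a
hand-rolled union-find over the exhaustive pairwise distance matrix for
≤ 20 bundles. Planted-bundle recovery is measured on 20 independently
seeded five-genome fixtures; the default survey run uses the 8-genome,
1,920-gene configuration above. These sizes make every check exhaustive or
near-exhaustive at interactive speed while exercising all code paths; the
pipeline itself has no dimension limits beyond memory.

## Known limitations

* The filter is only as good as the motif library; the packaged exemplars
  are synthetic toys, and real use requires a user-supplied library (e.g.
  profile HMMs of characterized biosynthetic families).
* Bundles split across scaffolds are not detected; chromosome-scale
  assemblies are assumed.
* The screen is presence/absence with no statistical enrichment test; with
  few genomes, exclusivity can easily arise by chance and should be read
  as a ranking signal, not significance.
* Set-Jaccard on domain content cannot distinguish bundles that share
  vocabulary but differ in architecture (domain order/copy number); the
  multiset variant softens, but does not remove, this.
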