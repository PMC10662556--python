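# Methods

## Model

Each observed point mutation is a row: a gene identifier plus one
category per attribute. Two attributes are configured by default —
mutation type (6 categories: Missense, Nonsense, RNA, Silent,
Splice_Site, Nonstop) and nucleotide change (the 12 ordered single-base
substitutions) — but the core is attribute-agnostic and accepts any list
of categorical columns.

For gene *g* and attribute *A*, the conditional profile is the empirical
distribution P(v | g) over *A*'s categories among *g*'s rows. Duplicate
rows count: the probabilities are per-row frequencies, and sample
identity is ignored (mutations are pooled per gene across samples).
Categories a gene never exhibits get probability exactly 0 — no
smoothing or pseudocounts, which is required for the exact worked-example
values and for the "distance 0 iff identical profiles" characterization.

The per-attribute distance is max over category subsets *w* of
P_x(w) + P_y(~w) − 1. Since the optimum puts into *w* exactly the
categories where P_x ≥ P_y, this equals Σ_v max(P_x(v), P_y(v)) − 1 =
½ Σ_v |P_x(v) − P_y(v)|: the total-variation distance between the two
profiles. The gene distance is the unweighted mean over the configured
attributes — the divisor is the number of categorical attributes (the
gene column itself is not part of the comparison). Being an average of
total-variation distances, the gene distance is a pseudometric on genes:
range [0, 1], symmetric, zero diagonal, triangle inequality, and zero
exactly on profile-identical pairs.

## Numerical choices

* Conditional profiles store `fractions.Fraction` probabilities
  (count / support), so pairwise distances on small tables are exact
  rationals; the worked example yields literally 1/3, 2/3, 1/2.
* The all-pairs matrix uses a vectorized float64 path: per attribute, a
  gene × category count matrix (pandas crosstab) is row-normalized and
  all pairs evaluated as half the L1 distance between rows (scipy
  `pdist(..., "cityblock")`), then averaged over attributes, clipped to
  [0, 1] and mirrored with an exactly-zero diagonal. The test suite
  checks this path against the exact pairwise path to 1e-12.
* The brute-force subset enumerator exists solely as an independent
  oracle: it walks all 2^K subsets (refused above K = 20) and reports the
  maximizing subset ω. Ties between maximizing subsets are broken by
  smallest cardinality, then lexicographic category order, making ω
  deterministic; ω is reported for the profile pair in the given
  argument order (the complementary subset wins for the swapped order,
  at the same distance value). Enumeration at the default vocabularies
  would cost 2^12 = 4096 subset evaluations per gene pair per attribute,
  which is why the closed form is the production path.
* Threshold comparisons in network construction use `distance ≤
  threshold + 1e-9`, so "distance exactly 0" networks are robust to
  float rounding from the matrix path.
* Arrow notation in nucleotide-change strings ("→", "->", ">") is
  canonicalized to ">" with whitespace stripped; beyond that, categories
  are opaque strings compared case-sensitively after trimming. In
  particular, a dataset written in dinucleotide context ("GG>GT") is not
  collapsed to single-base notation ("G>T") — the measure treats
  categories as unordered labels, so only internal consistency within
  one dataset matters. MAF Variant_Classification values are matched
  case-insensitively because MAF dialects vary in casing, but gene
  symbols are never case-folded to avoid silently merging distinct
  symbols.

## Input handling

The minimal TSV dialect is header + one row per mutation, with a
role → column mapping. The MAF reader keeps single-nucleotide
substitutions only: both alleles must be single distinct bases in
{A, C, G, T}, and when a `Variant_Type` column is present it must read
`SNP`. Mutation types come from `Variant_Classification` through a
configurable map defaulting to the six classes above; unmapped classes
(e.g. Intron, Frame_Shift_Ins) are dropped and counted. The reader
returns the table together with a filter report satisfying
`records_out + dropped_non_snv + dropped_unmapped_class = rows_in`.
Strand is ignored and alleles are taken as reported. Rows with blank
genes or attribute values abort with the line number by default; a
lenient flag downgrades them to logged skips.

## Synthetic data

The generator emulates exactly the statistical structure the distance
consumes: per gene, per record, each attribute is an independent
categorical draw from a user-specified distribution. Cross-attribute
dependence is deliberately not modeled — the distance only reads
per-attribute marginals conditional on the gene, so independence is
sufficient for testing and anything richer would be untestable dead
weight here. Likewise the generator produces no genomic positions,
samples, or mutational signatures; passing tests therefore demonstrate
correctness of the measure and the network machinery on tables with the
right marginal structure, not robustness to the correlation patterns,
hypermutated samples, or coverage artifacts of real cohorts.

One integer seed drives everything; each gene's draws come from a
substream keyed on (seed, gene name), so adding or removing a gene never
perturbs the other genes' records. `true_distance` evaluates the
distance's closed form on the *true* distributions, providing the ground
truth that the empirical distance on a generated table must approach: at
10,000 mutations per gene over random 6-way × 12-way distributions,
every pairwise error stays below 0.02 (the multinomial fluctuation of a
total-variation estimate at that sample size).

## Problem sizes

Default test and acceptance runs use: the 4-row worked example; 500
random profile pairs for the fast-path/enumeration identity; 100 random
tables (≤ 15 genes, ≤ 30 records) for the metric-property battery; a
10-gene spec at 10,000 mutations/gene for recovery; and a 500-gene ×
50-mutation table for the at-scale run (full 500 × 500 matrix plus GEXF
export, a fraction of a second on one core). The vectorized matrix path
scales as O(G² · K) per attribute and handles cohort-scale gene counts
(thousands of genes) comfortably.

## Design choices

* Distance, not similarity, is the canonical internal quantity
  (δ(x, x) = 0); every edge output carries both `distance` and
  `similarity = 1 − distance` so either reading convention can be applied
  without ambiguity.
* The subset maximization is allowed to range over the empty set and the
  full vocabulary; both give P_x(∅) + P_y(full) − 1 = 0 and only tie for
  the maximum when the profiles are identical, so no restriction to
  proper subsets is needed.
* Global networks exclude isolated genes by default (a flag includes
  them): thresholded exploration is about connected neighborhoods.
* Ego networks always include seed-neighbor edges; neighbor-neighbor
  edges are opt-in, since the two views (star around a seed vs. the
  seed's full similarity neighborhood) answer different questions.
* GEXF and GraphML exports go through networkx with lexicographic node
  and edge order, so files are byte-stable across runs. GraphML carries
  the threshold as a graph-level key; GEXF notes it in the meta
  description and on each edge (the GEXF writer has no general
  graph-attribute slot).

## Limitations

* The measure sees only per-gene marginal distributions of categorical
  attributes; it cannot represent mutation order, co-mutation within a
  sample, genomic position, or any numeric covariate.
* Genes with few mutations have coarse, high-variance profiles (a
  single-mutation gene has a degenerate profile), and the distance does
  not discount for support; interpret near-zero distances between
  low-support genes cautiously.
* Attributes are equally weighted in the average; there is no weighting
  hook.
* No statistical significance is attached to distances, and no
  clustering of the matrix is provided.
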