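# Methods

## Pipeline overview

`gocollapse` consumes, per species: an OBO 1.2 ontology, gene→GO-term
annotations, and a DESeq2-style differential-expression (DE) table. The
stages are

1. annotation propagation up the `is_a` closure within one namespace;
2. directional gene-list selection by volcano thresholds;
3. one-sided hypergeometric over-representation analysis (ORA) with
   Benjamini–Hochberg (BH) correction, per direction;
4. gene-membership dissimilarity + complete-linkage collapsing of the
   enriched terms into GO clusters (per species, and jointly for two
   species);
5. representative selection and per-cluster summaries (ratio n, l2fc
   boxplots).

## Annotation propagation

A gene annotated to a term is counted for every `is_a` ancestor of that
term, restricted to one namespace (default `molecular_function`) and to a
declared gene universe. Only `is_a` edges are followed; `part_of` and
other relations are not modelled, which matches the minimal reading of
GO's subsumption semantics and keeps term gene sets a superset chain along
ancestry (`propagated[t] ⊆ propagated[a]` for every ancestor `a`).
Obsolete terms, annotations to unknown terms, and genes outside the
universe are dropped with logged warnings rather than errors, so partial
annotation files for non-model organisms remain usable. Terms whose
propagated set is empty are omitted. The gene universe is caller-supplied;
the CLI uses all genes present in the DE table — i.e. all genes actually
tested for differential expression — as the background, the conventional
choice when the true annotation background is unknown.

## Directional selection

A gene is *up* when `p < alpha` and `l2fc > lfc_min`, *down* when
`p < alpha` and `l2fc < −lfc_min`; defaults `alpha = 0.05`,
`lfc_min = 1`, applied as **strict** inequalities. The p-value column
defaults to the BH-adjusted `padj` (the stricter, standard choice); raw
`pvalue` is selectable. Genes with a missing value in the selected column
are never significant. Up and down sets are disjoint by construction, and
loosening either threshold can only grow them (tested as a monotonicity
property).

## Enrichment

For each direction, every propagated term with `min_term_size ≤ K ≤
max_term_size` (defaults 3 and 500 — conventional ORA guards against
uninformative tiny terms and uninterpretable giant ones) is scored by the
hypergeometric upper tail P[X ≥ k], computed through the survival function
in scipy (numerically stable; exact to enumeration at small N, verified to
1e-12). BH adjustment is applied within each direction over exactly the
tested terms of that direction — not over the whole ontology — because the
two directions are scientifically separate families reported separately.
Records with `padj < 0.05` are kept, sorted by (padj, p, term id) so ties
are deterministic. The statistic is one-sided by design: ORA asks only
about over-representation; depletion is out of scope.

## Term collapsing

**Dissimilarity.** The default metric is Jaccard distance
`1 − |A∩B|/|A∪B|`; the phrase "75 % or more shared genes" is read as
Jaccard similarity ≥ 0.75, hence the default cut height 0.25. Because
that phrase could also mean the overlap coefficient
(`1 − |A∩B|/min(|A|,|B|)`, which is 0 whenever one set contains the
other), that metric is available behind `--metric overlap_coefficient`
for sensitivity analysis. Both satisfy the endpoint semantics: 0 at total
overlap, 1 at no shared genes.

**Which gene sets.** Dissimilarities are computed on the *full propagated*
term gene sets within the species universe, not only on DE genes: ratio n
divides by "the total number of genes in that cluster", which only makes
sense if clusters carry their non-DE genes too.

**Which terms.** The clustered set is the union of up- and down-enriched
terms within a species, so terms enriched in opposite directions may
co-cluster; per-direction ratios are emitted alongside the pooled one.

**Agglomeration.** Complete linkage, D(U,V) = max pairwise d, implemented
directly (Lance–Williams max-update) with a deterministic tie-break: among
pairs attaining the minimal linkage value, the pair whose merged sorted
term-id tuple is lexicographically smallest merges first. Complete linkage
admits no inversions, so merge heights are nondecreasing and the flat cut
at height h (inclusive, so pairs at exactly 75 % shared genes merge)
guarantees max within-cluster pairwise dissimilarity ≤ h; this guarantee
is asserted on every run. The implementation is cross-checked in the test
suite against both a naive rescan-the-original-matrix oracle and scipy's
`linkage`/`fcluster` on tie-free matrices. The full merge tree is exported
as Newick (term ids single-quoted because they contain `:`; branch lengths
are height increments) for external dendrogram rendering.

**Representative and summaries.** The representative is the member term
with the highest proportion of significantly regulated genes
(|sig ∩ genes(t)| / |genes(t)|); ties break to the smaller term, then the
lexicographically smaller id. Cluster statistics: union of member gene
sets (no double counting), `ratio_n = |union ∩ (up ∪ down)| / |union|`,
per-direction variants, and the multiset of l2fc values of union genes
measured in the DE table (unmeasured genes are excluded and counted in a
warning).

## Two-species merging

The joint term set is the union of both species' enriched terms. For a
term pair with gene sets in both species the joint dissimilarity is the
arithmetic mean of the per-species values; a pair measurable in only one
species keeps that species' value; a pair of terms that no single species
annotates together is assigned d = 1 (conservative: never merged, logged).
The joint tree is cut at the same height. A cluster is **shared** when at
least one member term is enriched (padj < cutoff, either direction) in
each species — an intentionally direction-agnostic definition so that
opposite responses in the two species still surface as one comparable
cluster. Per-species l2fc multisets come from that species' cluster union
intersected with its own DE table, so genes unmeasured in one species
simply do not contribute to that species' box. The joint representative
scores each member by its best per-species significant-gene proportion
over the species that annotate it, with the same tie-breaks as the
single-species rule. More than two species are not merged jointly; the
method is pairwise.

## Boxplot convention

Quartiles use linear interpolation between order statistics (numpy's
default, the common plotting convention); IQR = Q3 − Q1; whiskers reach
the most extreme values within 1.5·IQR of the box; everything beyond is an
outlier, listed individually. A single value yields the degenerate box
median = Q1 = Q3 with no outliers.

## Synthetic studies

The generator emulates the *post-DE* inputs of a two-species co-culture
experiment, not the sequencing itself:

- **Ontology:** a rooted single-namespace `is_a` tree (default 60 terms,
  depth ≤ 4, branching ≤ 3), large enough to exercise propagation and to
  supply ≥ 20 leaves for planting while keeping runs sub-second.
- **Annotations:** planted term groups (default 5 groups × 4 leaf terms)
  are built from a 20-gene core per group plus at most
  `floor(core·(1−s)/(2s))` private genes per term, bounding within-group
  Jaccard similarity below by the target s = 0.8 (realized ≈ 0.83, i.e.
  distance ≈ 0.17 ≤ 0.2); groups draw disjoint gene pools, so
  between-group distance among planted terms is exactly 1. Non-planted
  leaves are annotated with 5–15 genes from the leftover background pool.
  Both species plant the *same* leaf-term groups but draw independent
  memberships, giving the joint clustering real cross-species structure.
- **DE tables:** genes of planted up/down groups draw
  l2fc ~ Normal(±3, 0.3) with padj ~ U(1e-8, 1e-4) — comfortably past the
  thresholds, as a genuinely regulated pathway would be — while null genes
  draw l2fc ~ Normal(0, 0.5) and near-uniform p-values (padj ≥ pvalue), so
  a realistic handful of null genes also pass the thresholds. The defaults
  (500-gene universes, ~140 significant genes per species) are sized like
  a small bacterial contrast. The adjusted p-values are generated
  directly rather than derived from a count model: the package tests the
  post-DE method, not the DE model itself.
- **Truth:** every generator records its planted structure and the
  *realized* quantities (pass counts re-filtered from the emitted rows,
  realized similarities recomputed from the emitted file), and all
  artifacts are byte-identical under a repeated seed.

What passing on these fixtures does **not** show: robustness to shallow
real GO DAGs with multiple parents per term (the generator emits trees;
propagation is tested on random DAGs separately), to annotation bias and
hypothetical-protein deserts in non-model genomes, to correlated genes
violating the hypergeometric independence assumption, or to DE tables
whose padj came from a misspecified model. Planted effects are strong by
design; power at marginal effect sizes is not characterised.

## Numerical and degenerate-input choices

- Hypergeometric p clipped into (0, 1]; k = 0 returns exactly 1.
- Impossible counts (k > min(K, n), K > N) are validation errors, not NaN.
- An empty significant gene list produces an empty enrichment with a
  warning, not an error; zero enriched terms skips clustering cleanly.
- Matrix validation tolerates 1e-12 asymmetry from float arithmetic.
- All output files use fixed `%.6g` float formatting and sorted orderings;
  the provenance manifest records input hashes, config and version but no
  timestamps, so identical reruns are byte-identical.
- Exit codes: 0 success (warnings allowed), 2 configuration/schema
  errors, 3 input validation errors.

## Known limitations

- Only `is_a` propagation; no evidence-code filtering beyond dropping
  GAF `NOT` qualifiers; no semantic-similarity (Resnik/Lin) measures.
- ORA only — no GSEA-style rank tests, no conditional (parent–child)
  enrichment, no two-sided Fisher variant.
- Complete linkage is the primary and only supported linkage for the
  method's guarantee; no multi-species (> 2) joint merging.
- The enrichment defaults (term-size bounds, cutoffs) are explicit,
  documented stand-ins where the field has no single convention; all are
  flags.
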