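# Methods

## Model

Over-representation of a gene list in an annotated gene set is modelled by
sampling without replacement: if the background (universe) holds `N` genes,
a term annotates `K` of them, and the query contains `n` background genes,
then under the null the overlap `k` follows a hypergeometric distribution
and the reported statistic is the upper tail `P(X ≥ k)`. The assumptions
are the usual ones for this test: the background is the set of genes that
*could* have appeared in the query (hence custom backgrounds for targeted
panels — the store is re-projected onto the background and both `N` and
every `K` are recomputed), genes are exchangeable under the null, and the
query is a set (duplicates collapse; genes outside the background are
dropped, counted, and excluded from `n`).

Tails are evaluated through the survival function of
`scipy.stats.hypergeom`, which works in log space and is stable for
genome-scale `N`; results are floored at the smallest positive double so
`-log10` transforms stay finite. The test suite checks the tail against
exhaustive enumeration of all `C(N, n)` draws for every parameter
combination with `N ≤ 12` (agreement to 1e-12) and against exact rational
arithmetic on random larger instances.

### Ordered queries

When the input list carries a meaningful ranking, each term is tested on
every prefix of the list (lengths 1..n, optional stride for very long
lists, always including the full list) and reported at the prefix length
minimizing the tail, ties broken toward the shortest prefix. Exact ties can
be mis-ordered by float rounding, so "tie" is interpreted with a 1e-9
relative tolerance; a brute-force rational-arithmetic scan over all
prefixes confirms both the minimum and the chosen prefix on 200 random
instances. The per-term minimum over prefixes is the test statistic; under
Bonferroni/BH the family size is the number of terms, which ignores the
prefix multiplicity and is therefore mildly anticonservative — the
empirical correction below simulates ordered null queries and absorbs the
multiplicity exactly.

### Multi-list queries

`>name` headers split the input into named lists; each is analysed
independently against the same store, background and correction, and the
joint table contains exactly the terms significant in at least one list
with one adjusted-p column per list.

## Multiple-testing correction

Three regimes, selected by tag:

* `bonferroni` — `min(1, p·m)` with `m` = number of terms tested;
* `fdr` — Benjamini–Hochberg step-up, implemented directly and
  cross-checked against the statsmodels reference on random vectors to
  1e-12;
* `gscs` (default) — an empirical min-p resampling family-wise correction.

For the empirical correction, `R` random queries of the observed size are
drawn uniformly from the background (random orderings in ordered mode); for
each, the minimum raw p over all terms (and prefixes) is recorded. An
observed p is adjusted to `(1 + #{null minima ≤ p}) / (R + 1)`, ties
counted inclusively (conservative). Rejecting when this quantity is ≤ α is
the classical min-p construction for family-wise error control under the
complete null, and because the null is simulated on the actual term
collection it automatically accounts for the correlation induced by term
overlap — under strong overlap it rejects more than Bonferroni, and in the
limit of independent non-overlapping terms it coincides with Bonferroni for
small p (verified in the tests to within Monte-Carlo error). The adjusted
value is additionally floored at the raw p itself: the min-p rank estimate
can undershoot `p` by Monte-Carlo noise at moderate p, and the floor keeps
`adjusted ≥ raw` exact without affecting the small-p regime where decisions
happen.

Defaults: `R = 1000` replicates, α = 0.05 on adjusted values, and a
mandatory seed (the CLI refuses `gscs` without one) so every run is exactly
reproducible. Measured over many seeds, the realized family-wise error of
the default configuration on a 500-gene, 40-term nested store is ≈ 0.040
at nominal 0.05 — valid but slightly conservative, for two reasons worth
knowing: hypergeometric p-values are discrete, so the min-p null has atoms
and the inclusive tie rule skips part of the rejection mass; and one null
of `R` replicates is shared across runs, adding threshold noise of order
`sqrt(α(1−α)/R)`. Larger `R` tightens both.

## Identifier and coordinate mapping

All aliases resolve case-insensitively through a user-supplied TSV
(`alias, namespace, reference_id`); resolution is deterministic and
independent of table row order. A token matching several reference ids is
reported `ambiguous` and excluded from enrichment by default — an explicit
flag takes the lexicographically smallest reference id instead, because a
silent tie-break would be untestable and invisible to the user. Namespace
conversion and two-step ortholog mapping (token → reference id →
target-species reference id) emit one row per mapping pair, with empty
fields rather than dropped rows for unresolved tokens and missing
orthologs, so output row counts are auditable.

Genomic coordinates are 0-based half-open internally; BED input is taken
as-is, GFF-like 1-based inclusive tables are normalized on load behind an
explicit flag, and `chrom:start-end` query tokens are treated as 1-based
inclusive. A gene is assigned to an interval iff they share at least one
base on the same chromosome; strand is ignored. The interval index is an
interval tree; a naive all-pairs scan is kept in the tests as the oracle.

## Outputs

Term positions in the Manhattan layout are a pure function of the store,
the parent edges and the configured source order: source blocks in fixed
sequence, and within a block a depth-first traversal of the parent graph
(children directly after parents, lexicographic tie-breaks) so that terms
of one annotation subtree are adjacent and enrichment of a subtree shows as
a peak. p-values never influence positions, which is what makes plots of
different queries comparable. Marker radius is `sqrt(K)` scaled into a
configured range, making marker *area* proportional to term size; rendered
`-log10` values are capped (default 16) for display only — tables always
carry exact values. CSV and GEM writers are pure functions of the records
(no clock or locale), and the GEM dialect follows the generic
EnrichmentMap format (`GO.ID, Description, p.Val, FDR, Phenotype, Genes`,
phenotype `+1`, genes comma-joined in universe order).

## Synthetic data

The fixture generator builds the entire test surface without downloads:
a universe of synthetic identifiers; a term hierarchy constructed top-down
with every child a random subset of its parent, giving GO-like nested
overlap with analytically known containment (depth 1 degenerates to
independent draws); alias tables in several namespaces including a
deliberately ambiguous alias and self-resolving reference ids; one-to-many
and missing orthologs; and intervals tiling a synthetic chromosome. Queries
are drawn with a planted signal fraction `f` (`⌈f·n⌉` genes from a chosen
term, the rest uniform from its complement; `f = 0` is the exact null of
the correction module — a two-sample Kolmogorov–Smirnov test in the suite
confirms the generator and the null builder sample the same min-p
distribution). What the generator does *not* emulate: realistic term-size
distributions, annotation bias toward well-studied genes, and correlated
gene behaviour within pathways — so passing tests demonstrate statistical
correctness of the machinery, not biological performance on real data.

Problem sizes used in the checked-in statistical tests (chosen to give
stable Monte-Carlo estimates at interactive runtimes): family-wise error on
a 500-gene, 40-term store with 2000 null runs against an `R = 1000` null;
strictness ordering over 100 planted 400-gene datasets; planted-term
recovery (`f = 0.8, n = 20, K = 40, N = 1000`) over 100 seeds;
independence limit on twenty disjoint 30-gene terms with `R = 2000`.

## Known limitations

* The empirical correction is a min-p analogue characterized by the
  properties stated above (overlap-aware, between BH and Bonferroni under
  dependence); it is not a bit-exact reproduction of any service's
  historical threshold tables.
* Ordered mode starts at prefix length 1; tools that enforce a minimum
  prefix may report different optima for terms peaking on very short
  prefixes.
* Classical corrections in ordered mode use the number of terms as family
  size (see above); only the empirical correction absorbs prefix
  multiplicity.
* Parent edges are used for layout adjacency only — no ontology reasoning,
  no propagation of annotations up the graph.
* Ambiguity across namespaces is reported, never resolved by precedence
  rules; analyses with heavily ambiguous identifier types should supply a
  disambiguated mapping table.
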