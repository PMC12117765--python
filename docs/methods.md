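# Methods

## Overrepresentation model

A background model is a map from functional categories to sets of protein
identifiers. Its universe size `N` is the number of *distinct* proteins
annotated to at least one category of the model, never the sum of
per-category counts: a protein carrying two KOG letters contributes once to
`N` and once to each letter's `K`. This keeps `k/n` and `K/N` on a common
denominator when proteins are multi-annotated, at every aggregation level
(the class-level KOG model unions the protein sets of its letters, so the
same protein never counts twice within a class).

Given a query list, ids are deduplicated, trimmed and intersected with the
model universe; ids outside the universe are reported as dropped, and
`n_input = n_mapped + n_dropped` always holds. For each category the
one-sided hypergeometric tail `P(X ≥ k)` is computed (via the
`scipy.stats.hypergeom` survival function; `P(X ≥ 0)` is returned as
exactly 1). Only overrepresentation is tested; depletion is out of scope.
The chi-squared alternative builds the 2×2 table
`[[k, n−k], [K−k, (N−K)−(n−k)]]` and applies the test of independence with
1 df and Yates continuity correction (switchable); it is inherently
two-sided, so direction must be read off the enrichment ratio. Degenerate
tables (a zero margin) return p = 1 with a warning rather than failing.

**Family size for correction.** Adjusted p-values are computed across all
model categories, not only those with query hits: the background model
defines the hypothesis family, and restricting the family to observed
categories would inflate significance. Implementation-wise every category
gets a raw p (k = 0 gives p = 1 under the hypergeometric test), the whole
vector is adjusted, and k = 0 rows are then omitted from the report.
Correction methods (BH, bonferroni, holm, BY, hochberg, hommel, none) are
delegated to `statsmodels.stats.multitest.multipletests`, whose semantics
match the classical definitions; the test suite cross-checks BH,
bonferroni and holm against direct implementations of their formulas.

## GO handling

The ontology is read from an OBO file into a DAG keeping non-obsolete
terms, `is_a` and `part_of` edges, and `alt_id` aliases; acyclicity is
verified at construction. Both relation types participate in propagation
by default (each is independently switchable), following standard
true-path practice. Queries never leave a term's namespace; term depth is
the shortest upward path to a namespace root (roots have depth 0) —
shortest rather than longest path because the latter is unstable under
ontology edits.

Annotation propagation closes the (protein, term) relation under ancestry
and collapses duplicates; it is idempotent, never shrinks a term's protein
set, and gives each namespace root the union of its namespace's annotated
proteins. Records whose term is missing from the DAG are dropped and
counted, not fatal.

**Redundancy reduction.** Two significant terms are considered redundant
when some ancestor lies within `depth_limit` upward hops of *each* of them
(a term is its own ancestor at distance 0). The "within a user-defined
depth" criterion could also be read as a cap on the ancestor's absolute
depth; the hop interpretation was chosen because it is local, monotone in
the limit, and independent of ontology-wide depth conventions. Groups are
the connected components of this relation (union–find), which makes the
result order-independent; from each group the row with the smallest
adjusted p survives (ties: smaller raw p, then lexicographic id). Namespace
roots present in the input are excluded from grouping and returned as
singletons, since a root is within any reasonable depth of everything near
the top of the graph. Adjusted p-values are intentionally not recomputed
after reduction — the reduction is a presentation filter, not a new test.
With `depth_limit = 0` only identical terms group, so all significant rows
survive.

## Input dialects

The paperless reality of annotation exports is that column layouts vary by
portal and version, so every tabular parser resolves column roles from a
default dialect map (`#`-prefixed header tolerated) that a per-file
`column_map` can override; a missing required column is a configuration
error naming the role. Identifiers are compared as exact strings after
whitespace trimming — no fuzzy matching — because enrichment is only valid
when query ids match the gene-model ids exactly. Malformed rows are
skipped with counted, logged warnings; parsers never abort on ragged input
and never fabricate identifiers. All readers accept gzip-compressed files
by suffix.

Specifics worth knowing:

* **KOG**: one record per distinct (protein, letter); the broad class is
  read from the file when present, else from the built-in canonical
  COG/KOG letter→class table (also used for letter labels and for eggNOG
  sources, which carry only letters; overridable).
* **GO**: numeric term ids are zero-padded into `GO:NNNNNNN` accessions;
  term types normalize onto the three OBO namespace strings; the skip
  count is returned alongside the records.
* **KEGG**: each row fans out into up to four records, one per aggregation
  axis; rows with an EC number but no pathway yield only the
  enzyme-definition record, and each axis model keeps its own background
  universe so the EC fallback does not deflate pathway enrichment.
* **KEGG link files**: database prefixes (`tre:`, `ko:`) are stripped up
  to the first colon; pairs are deduplicated.
* **eggNOG-mapper v2**: `##` comments, `#query` header; `-` cells become
  empty sets; multi-letter `COG_category` cells explode to single letters;
  `ko:`-prefixed KOs keep the `KNNNNN` token; `ko`/`map` pathway spellings
  unify onto `map#####`.
* **GTF/GFF3** (via `gffutils`, in-memory db): one conversion row per
  transcript; gene name falls back to gene id; GFF3 protein ids default to
  the JGI `proteinId` attribute and can be remapped; dialect
  auto-detection keys on `=` vs space-separated attributes. A regex
  rewrite utility covers eggNOG query ids whose FASTA-header decorations
  do not match gene-model ids. Cross-database id translation
  (Ensembl/RefSeq/UniProt) is explicitly not attempted.

## Synthetic fixtures

The generator emulates a small fungal-genome annotation release over one
protein universe (default 1000 proteins, ids `FGP_#####`): a KOG table
(18 of the 26 canonical letters; 80% annotation density; 15% of annotated
proteins carry a second letter), a GO table over three random single-rooted
namespace DAGs (40/20/20 terms; each non-root term has 1–2 earlier parents,
15% `part_of`) with the matching OBO file, a KEGG table (12 pathways with
class/type metadata, 15 synthetic enzymes, including EC-only fallback
rows), a KEGG link file, an eggNOG-mapper table consistent with all of the
above, a GTF with occasional two-isoform genes, and a query list.

Enrichment is planted deterministically: a planted category at fold `f`
contributes `round(min(1, f·K/N) · query_size)` of its members to the
query; the remainder is drawn uniformly from the rest of the universe, so
fold 1.0 is the exact null. All randomness flows from the mandatory seed
and identical configurations yield byte-identical files. The defaults were
chosen so a 4-fold planted category in a 1000-protein background with a
50-id query is comfortably but not trivially detectable (expected k ≈ 10
vs ≈ 2.5 under the null).

What the fixtures do **not** emulate: real category-size distributions
(they are roughly uniform here, while real KOG/GO sizes are heavy-tailed),
annotation biases correlated across sources, obsolete/alt-id churn in real
ontologies, and identifier noise. Passing the planted-recovery and null
calibration checks therefore demonstrates statistical correctness of the
machinery, not performance on any particular real genome.

## Numerical and rendering choices

* Hypergeometric tails use the scipy survival function with the result
  clamped to [0, 1]; agreement with exhaustive enumeration of all draws is
  verified to 1e-12 for all valid configurations with N ≤ 12.
* Ratios are only formed for k ≥ 1 rows and model categories always have
  K ≥ 1, so no division by zero can occur.
* Reports sort by (adjusted p, category id); all serialization sorts
  protein sets, making every output file deterministic.
* SVG plots pin matplotlib's `svg.hashsalt` and drop the date metadata so
  repeated renders are byte-identical. Stars annotate *adjusted*
  p-values: `*`, `**`, `***` below 0.05, 0.01, 0.001; the plotted value
  axis is the enrichment ratio by default, with −log10 adjusted p as the
  alternative.

## Verification problem sizes

The acceptance script and test suite use: the full (k, K, n, N) grid with
N ≤ 12 against enumeration; 1000 random p-vectors (length ≤ 60) for the
adjustment procedures; 200 random DAGs (≤ 50 nodes) for propagation; 100
random DAG fixtures for redundancy reduction; and 200 seeded replicates
each for planted recovery (fold 4, N = 1000, query 50) and the unplanted
null. These sizes give stable rates while keeping the whole verification
run in well under a minute per check on one CPU.

## Known limitations

* No GAF/GPAD association formats, no network access, no bundled species
  models (the documented model TSV format is the extension point for
  shipping precomputed models).
* No ranked gene-set (GSEA-style) testing and no depletion testing —
  strictly set-based overrepresentation.
* No semantic-similarity-based GO reduction; grouping is purely
  ancestry-based.
* The chi-squared option is approximate for the small counts typical of
  sparse categories; the hypergeometric default is exact and preferred.
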