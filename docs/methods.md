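# Methods

## Data model

The database distinguishes three data types. Binary features are gene
sets: a gene either belongs to the category (value 1) or not (0). Metric
features are sparse real-valued vectors over genes; absence of a value
means "no data" and such genes are ignored by every computation — missing
is never coerced to 0 or NaN. Pairwise features are undirected gene–gene
edge sets (physical or genetic interactions), stored once per unordered
pair with self-loops removed. Every binary/metric feature carries a theme
(GO Biological Process, Phenotypes, Transcript Features, ...) used only to
organize selection and reporting; a theme never changes how a statistic is
computed. Gene identifiers are opaque case-sensitive strings, so the
machinery is organism-agnostic.

Merging feature tables (`assemble_database`) requires globally unique
feature ids and sorts the merged gene universe, so identical inputs always
produce identical reports.

## Query validation and backgrounds

A query list is deduplicated (first occurrence wins) and restricted to the
active background; removed ids are kept with the reason. Lists that end up
below 10 genes trigger a warning — rank and count statistics are fragile
at that size. All statistics are computed within the background universe
*B*: gene sets are intersected with *B*, metric comparisons use *B∖A*, and
the permutation pool is *B∖A*. Choosing a background that matches how the
list was produced (e.g. non-essential genes for a deletion-screen hit
list) is the main lever for avoiding systematically biased enrichments.

## Tests

**Fisher (categorical).** The 2×2 table counts |A∩G|, |G∖A|, |A∖G| and the
remainder of *B*. The two-tailed p-value is the sum of hypergeometric
point probabilities over all tables with the observed margins whose
probability does not exceed that of the observed table (the classical
"minimum-likelihood" convention; `scipy.stats.fisher_exact` agrees and is
used as an independent cross-check in the tests, with an exact
rational-arithmetic enumeration oracle covering every table with |B| ≤ 12).
The implementation evaluates the whole overlap support at once and caches
the resulting p-array per (|B|, |A|, |G∩B|), which makes the
2000-feature × 500-replicate calibration runs cheap. Point probabilities
are compared with a 10⁻⁹ relative slack so exactly tied tables (symmetric
margins) are always included despite float rounding. Degenerate margins
(an empty row or column) cannot deviate from expectation and report p = 1
with a warning. Direction is "over" iff the observed overlap exceeds
|A||G∩B|/|B|.

**Wilcoxon rank-sum (metric).** Midranks handle ties. While the number of
rank assignments C(n+m, n) is at most 2500 the permutation distribution of
the query rank sum is enumerated exactly and the two-sided p is twice the
smaller tail, capped at 1; above that threshold a normal approximation
with ±0.5 continuity correction and tie-corrected variance takes over.
2500 is also the warning threshold, together with query sides below 10
values and p ≥ 0.25. An all-tied comparison yields p = 1. The exact path
is checked against full enumeration for n+m ≤ 10 and the approximate path
against a subset-sum dynamic-programming oracle (agreement within 0.01 at
20+20, tie-free) and scipy's asymptotic Mann–Whitney.

**Permutation (pairwise).** The statistic is the induced-subgraph edge
count: each interacting pair inside the query counts once. Each of the
n_perm permutations draws |A| genes uniformly without replacement from the
pool (vectorized via argsort of uniform variates). Exceedance is strict
(ties with the observed sum do not count) and the count is floored at 1
before doubling, so p = max(c, 1)/n_perm × 2 with a cap at 1 — at the
default 1000 permutations the smallest attainable p is 0.002, which cannot
survive correction among thousands of tests; raising n_perm is the
intended remedy. If the pool is smaller than twice the query, no p-value
is computed and the feature is skipped with a warning. Permutation testing
is disabled by default because of its cost.

**Corrections.** Bonferroni (p·t, capped), Holm step-down and
Benjamini–Hochberg step-up are delegated to
`statsmodels.stats.multitest.multipletests`; the test suite checks them
against hand-derived examples and an independently written step-down/
step-up implementation. `t` is defined as the number of p-values actually
submitted: untestable features (empty set within the background, a side
with no metric values, pool-guard skips) are excluded from `t` — counting
never-computed tests would only inflate the penalty. Reporting semantics
follow each method's standard usage: BH reports the step-up rejections at
α; Holm/Bonferroni report adjusted p ≤ α.

## Ontology handling

OBO parsing is delegated to `obonet`; only `is_a` and `part_of` edges are
traversed (the standard propagation relations — `regulates`-type edges are
deliberately excluded), alt_ids resolve to canonical ids, and obsolete
terms keep no edges and accept no annotations (annotating one warns and
skips). The edge graph must be acyclic; a cycle is reported by name.
Propagation assigns each gene to its annotated terms and all their
ancestors, memoizing ancestor closures; correctness is established against
a per-gene brute-force DFS oracle on random DAGs of up to 30 terms. The
at-least-two-genes filter is applied *after* propagation, on the
propagated sets and against the full database universe — backgrounds only
enter at test time. GAF qualifier `NOT` annotations are skipped.

## Computed gene and protein features

Coordinates are 1-based inclusive. Intron count is exons−1; average intron
length is the mean inter-exon gap (missing for single-exon genes);
transcript length is the exon-length sum. Chromosomal distances use the
gene-span midpoint: distance to the nearest centromere boundary (0 inside)
and to the nearer chromosome end, both also reported relative to
chromosome length. The midpoint/nearest-boundary conventions are choices
made here for reproducibility; neither is forced by the data. First-intron
GC is computed in transcript orientation (last genomic gap on the minus
strand); N bases leave the denominator. Protein molecular weight uses
Biopython's average residue masses; pI is solved by bisection of the
Henderson–Hasselbalch net charge on [0, 14] to 10⁻⁴, with the EMBOSS
pepstats default pKa set (overridable). The fold index is the whole-protein
value 2.785·⟨H⟩ − |⟨R⟩| − 1.151 with Kyte–Doolittle hydropathy rescaled to
[0, 1] and net charge counting K, R as +1 and D, E as −1; one value per
protein, no sliding window.

## Synthetic databases and calibration

The generator emulates every input dialect at toy scale: a random layered
DAG ontology with random GAF annotations, GMT-like gene-set files, tabular
metric files with metadata rows, interaction files and background lists,
plus a JSON manifest recording spec and seed; the same seed reproduces the
files byte for byte. Null binary features are uniform random gene sets
(sizes 10–50 by default); null metric features are i.i.d. standard normal
(the rank-sum test is distribution-free, so this is convenience, not an
assumption). Planted signal is defined against a query template *Q*:
a binary plant shares a stated fraction of *Q*; a metric plant shifts
*Q*'s values by a stated multiple of the null SD; a pairwise plant adds a
stated number of edges inside *Q*.

What the toys do *not* emulate: the size correlations, annotation-depth
structure and inter-feature dependence of a real curated database, or
realistic genome composition. Passing calibration here demonstrates the
statistics behave as designed under independence; it does not bound error
rates on strongly correlated real feature collections (BH is only
guaranteed under independence/PRDS).

FDR calibration regenerates, per replicate, a database of 2000 binary
features over 500 genes — 40 planted with overlap fraction 0.6 at set size
50, 1960 nulls — queries it with its 50-gene template, applies BH at
α = 0.01 and scores the fraction of reported features that are nulls (0
when nothing is reported). With 500 replicates the mean false-discovery
proportion sits well below 1% (discreteness of Fisher p-values makes the
procedure conservative); these problem sizes keep the whole calibration
around a minute on one CPU while leaving the Monte-Carlo error far smaller
than the 1% bound being verified.

## Numerical and design notes

* Feature iteration, merged gene order, report ordering (theme, then raw
  p, then feature id) and per-network permutation seeds derived from the
  run seed make byte-identical reports a tested invariant.
* Equal observed and expected values report direction "under" (a tie is
  not an enrichment); for pairwise rows the direction is always "over"
  since only enrichment is tested.
* Report numbers are rendered with 6 significant digits; the report
  re-parses to the same rows at that precision.
* The web-style "explain" action is the `explain(result, feature_id)`
  function, returning contingency cells or group means/sizes, the overlap
  gene list and both p-values for any tested feature.
* Known limitations: no evidence-code filtering or annotation extensions
  in GAF input; no odds-ratio confidence intervals or mid-p variants; BH
  independence caveat above; the permutation test's p-floor means its
  results are only informative when n_perm is raised accordingly.
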