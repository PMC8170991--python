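# Methods

## Coordinate model

All coordinates are 0-based half-open internally. GTF input (1-based
inclusive) is converted on read and back on write; BED is native. Exons
are merged across all transcripts of a gene into a disjoint sorted union;
introns are the gaps between consecutive merged exons, so a single-exon
gene has none. One internal convention removes off-by-one drift between
the formats; the conversion is covered by a round-trip property test.

## Neighborhood search

The window for ncRNA rᵢ is its full genomic span extended by
`upstream_bp` before the start and `downstream_bp` after the end (clamped
at 0). With `strand_aware` the two extensions swap on minus-strand ncRNAs
so "upstream" follows the direction of transcription; the default is
strand-blind genomic left/right, since an enhancer-like *cis* effect has
no preferred transcriptional side. A protein-coding gene joins Cᵢ when any
of its regions — full span, merged exons, or introns, per `region_mode` —
shares at least 1 bp with the window on the same chromosome. The ncRNA
side always uses its full span; the region mode restricts only the coding
side, which is where intron/exon-limited analyses are meaningful.
Defaults: ±10 kb, a conventional *cis*-regulatory scale; both window arms
are independently user-set, and 0/0 reduces the search to direct overlap.

Anchoring the window on the whole span (rather than TSS/TES points) is
this package's documented contract: it subsumes start- and end-anchored
searches for any symmetric window and avoids a strand lookup in the
default path. Overlap of ≥ 1 bp defines proximity; no minimum overlap
fraction is imposed. An input gene that is itself protein-coding is never
a member of its own Cᵢ (logged).

The implementation queries a per-chromosome interval tree; an all-pairs
O(n·m) scan written from first principles serves as the oracle in tests,
with exact set equality required across windows, strand modes and region
modes.

## Refinement filters

All filters are element-wise intersections on the Cᵢ, so each output is a
subset of its input, TAD and target filters commute, and the union pool
shrinks monotonically; these algebraic facts are asserted on random
fixtures rather than assumed.

**TAD filtering.** A gene belongs to every TAD its span overlaps by
≥ 1 bp — genes straddling a boundary belong to both sides, a deliberate
any-overlap choice because boundary calls are themselves uncertain and
full containment would silently drop long genes. Cᵢ keeps genes sharing at
least one TAD with rᵢ; an ncRNA overlapping no TAD keeps nothing
(conservative: with no domain evidence, no neighbor is "in the same TAD").

**Co-expression.** Preprocessing runs in a fixed order: optional
low-expression drop (expression below `low_expr_value` in more than
`low_expr_fraction` of samples), optional log2(x+1), variance filter
(default cutoff 0.0025), optional MAD filter. The order mirrors the usual
RNA-seq workflow (filter raw-scale counts, transform, then
dispersion-filter on the analysis scale). Pairwise correlation uses
Pearson (t-test, n−2 df), Spearman (t approximation on ranks) or Kendall
tau-b (normal approximation); p-values are two-sided, the cutoff rule on
the coefficient is `absolute` by default with signed `positive`/`negative`
variants, and Pearson edges carry a Fisher-z interval at confidence level
0.95. The interval is reported but does not gate retention — the p-value
cutoff already does, and double-gating would make the confidence level a
second significance knob. Filter mode intersects each Cᵢ with the
retained partners of rᵢ; expand mode leaves the Cᵢ untouched and adds any
coding gene correlated with any rᵢ to the union pool, recorded under a
dedicated pseudo-entry so the pool always equals the union of per-ncRNA
sets and the invariant stays machine-checkable.

**miRNA targets.** Cᵢ is intersected with the supplied target set of rᵢ,
matched case-insensitively; stripping the three-letter species prefix
(hsa-, mmu-, ...) is optional because target tables disagree on it. An
input miRNA absent from the table keeps no neighbors (warning).

**Biotype.** The input set is subset to (keep) or purged of (exclude) the
named biotypes before any neighborhood search; emptying the input is a
hard error.

## Enrichment

Background B defaults to the union of all genes in the collection;
query genes outside B are dropped from n with a log message (the test
universe must contain the query). Term size K is measured inside B, and
terms with K < `min_set_size` (default 5) are skipped before testing.
Terms with zero overlap are neither reported nor counted in the
multiple-testing family — the family is the set of terms actually tested
with k ≥ 1, and its size is logged. BH is the default adjustment; the
step-up is implemented directly (sort, p·m/rank, running minimum from the
largest rank, cap at 1) and cross-checked against statsmodels in tests.
The chi-square test refuses tables with a zero expected cell and points
the user to the exact tests instead of applying a continuity correction.

`ContingencyCounts` enforces 0 ∨ (n+K−N) ≤ k ≤ min(n, K), n, K ≤ N: the
lower bound is forced for any two subsets of a finite universe and keeps
every derived 2×2 cell non-negative.

## Reporting

Rows are ranked by p or adjusted p with a stable, fully deterministic
order (ties: larger overlap first, then term id). The network is built
gene-mediated: term—gene edges from the overlap sets and gene—ncRNA edges
from the neighbor map (a direct term—ncRNA edge would hide which gene
carried the signal). Clustering is greedy modularity maximisation with
sorted node insertion, so repeated builds and permuted inputs give
identical partitions; the partition's Newman modularity is checked against
the trivial one-cluster partition in tests. All writers emit
deterministic, sorted, plain-text TSV (optionally GraphML), so whole
output directories are byte-comparable across runs.

## Synthetic fixtures

The generator emulates exactly the structure the method consumes, not
genome realism. Defaults: 2 chromosomes × 2 Mb holding 300 protein-coding
and 30 ncRNA genes (lincRNA/antisense/miRNA rotation) placed uniformly
with ≥ 1 kb gaps — about one gene per 12 kb, compact enough that ±10 kb
windows yield a neighbor pool of ~40–55 genes from 30 input ncRNAs.
Coding genes get 1–4 exons; TADs tile each chromosome with boundaries
snapped to inter-gene gaps (a flag forces boundaries through genes to
exercise the straddling rule). Expression is generated on the log scale:
unit-variance Gaussian noise, with each planted pair (a, b, ρ) built as
b = ρ·standardize(a) + √(1−ρ²)·noise so the expected Pearson correlation
is ρ. The gene-set collection contains one planted term holding 16 pool
genes (roughly 40 % of the default pool — a strongly enriched pathway)
plus an equal number of off-pool fillers, and 40 decoy terms of matched
size drawn uniformly from all coding genes, so decoy–pool overlaps follow
the hypergeometric null.

What passing tests on these fixtures do not show: robustness to GC or
mappability artefacts, isoform-level structure, batch effects or heavy
tails in real expression data, or the reliability of any particular TAD
call set. They do show that the search, filters and statistics implement
their definitions exactly and that planted signal of realistic strength
survives the whole pipeline.

Problem sizes used by the test suite and acceptance script: the
neighborhood oracle comparison runs fixtures of ~1000 coding + 200 ncRNA
genes; recovery rates use 50–100 seeded replicates of the default
fixture; exhaustive hypergeometric verification covers every valid table
with N ≤ 30.

## Numerical choices

- Hypergeometric tail via the survival function in log space; values
  clamped to (0, 1].
- Fisher and hypergeometric are the same statistic computed by different
  routes and must agree to 1e-12 — kept as mutual cross-checks.
- Pearson CI undefined for n < 4 or |r| = 1: NaN sentinels, excluded from
  gating and from the edge invariant.
- Constant expression vectors yield an undefined correlation; after the
  variance prefilter they cannot occur, and any that slip through are
  dropped rather than scored.
- Missing or non-numeric expression cells are an error, never imputed.
- Unknown configuration keys are rejected outright; defaults are filled
  only for absent keys.

## Known limitations

- 1D proximity only: no Hi-C contact maps, loop calls or
  enhancer–promoter models beyond TAD co-membership.
- ID resolution is table-driven (gene_id, symbol, alias TSV); no remote
  lookup, and transcript-to-gene mapping must be provided via the alias
  table.
- The binomial and chi-square tests are approximations offered for
  comparability; the hypergeometric/Fisher route is exact and preferred.
- Expansion-mode co-expression genes carry no ncRNA attribution in the
  reported `ncGeneList` (they joined the pool through correlation, not
  through a neighborhood).
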