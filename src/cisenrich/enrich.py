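"""Over-representation testing of the curated coding-gene pool.

Given the neighbor pool C and a gene-set collection, each term is scored
with one of four tests on the counts (k, n, K, N):

    k = |query ∩ term|      n = |query|  (pool restricted to background)
    K = |term ∩ background| N = |background|

The hypergeometric upper tail P(X >= k) is the primary test; the one-sided
Fisher exact test is mathematically identical; binomial and chi-square are
asymptotic alternatives. Adjusted p-values default to Benjamini-Hochberg.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy import stats

from .errors import DataError, ValidationError
from .neighborhood import NeighborMap
from .types import GeneSetCollection

logger = logging.getLogger(__name__)

TESTS = ("hypergeometric", "fisher", "binomial", "chisq")
PADJ_METHODS = ("BH", "bonferroni", "none")


@dataclass(frozen=True)
class ContingencyCounts:
    """Overlap counts (k, n, K, N) behind one enrichment test."""

    k: int
    n: int
    K: int
    N: int

    def __post_init__(self) -> None:
        if min(self.k, self.n, self.K, self.N) < 0:
            raise ValidationError("counts must be non-negative")
        if self.k > min(self.n, self.K):
            raise ValidationError(f"k={self.k} exceeds min(n={self.n}, K={self.K})")
        if self.n > self.N or self.K > self.N:
            raise ValidationError("n and K must not exceed N")
        if self.k < self.n + self.K - self.N:
            # two subsets of size n and K inside N must share >= n+K-N genes
            raise ValidationError(
                f"k={self.k} below the forced overlap n+K-N="
                f"{self.n + self.K - self.N}"
            )

    def table(self) -> np.ndarray:
        """The 2x2 table (in-term/out-of-term x in-query/out-of-query)."""
        return np.array(
            [
                [self.k, self.n - self.k],
                [self.K - self.k, self.N - self.K - self.n + self.k],
            ]
        )

    @property
    def gene_ratio(self) -> str:
        return f"{self.k}/{self.n}"

    @property
    def bg_ratio(self) -> str:
        return f"{self.K}/{self.N}"


@dataclass
class EnrichmentRow:
    """One enriched term with its statistics and contributing ncRNAs."""

    term_id: str
    term_name: str
    p_value: float
    p_adjusted: float
    counts: ContingencyCounts
    overlap_genes: set[str]
    contributing_ncrnas: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if len(self.overlap_genes) != self.counts.k:
            raise ValidationError(
                f"term {self.term_id}: |overlap_genes| != k ({self.counts.k})"
            )


@dataclass(frozen=True)
class EnrichConfig:
    test: str = "hypergeometric"
    min_set_size: int = 5
    padj_method: str = "BH"
    background: Optional[frozenset[str]] = None

    def __post_init__(self) -> None:
        if self.test not in TESTS:
            raise ValidationError(f"unknown test {self.test!r}")
        if self.min_set_size < 1:
            raise ValidationError("min_set_size must be >= 1")
        if self.padj_method not in PADJ_METHODS:
            raise ValidationError(f"unknown adjustment {self.padj_method!r}")


def hypergeom_pvalue(c: ContingencyCounts) -> float:
    """Upper-tail P(X >= k), X ~ Hypergeom(N, K, n), computed in log space."""
    if c.k == 0:
        return 1.0
    # sf(k-1) = P(X >= k); scipy evaluates the tail via logpmf internally
    p = float(stats.hypergeom.sf(c.k - 1, c.N, c.K, c.n))
    return min(max(p, np.nextafter(0, 1)), 1.0)


def fisher_pvalue(c: ContingencyCounts) -> float:
    """One-sided (greater) Fisher exact p on the 2x2 table.

    Identical to the hypergeometric upper tail; both routes are exposed so
    each can cross-check the other.
    """
    table = c.table()
    if (table < 0).any():
        raise ValidationError("negative derived cell in contingency table")
    return float(stats.fisher_exact(table, alternative="greater")[1])


def binomial_pvalue(c: ContingencyCounts) -> float:
    """Upper-tail P(X >= k), X ~ Binomial(n, K/N)."""
    if c.N == 0:
        raise ValidationError("background size N must be positive")
    if c.k == 0:
        return 1.0
    res = stats.binomtest(c.k, c.n, c.K / c.N, alternative="greater")
    return float(res.pvalue)


def chisq_pvalue(c: ContingencyCounts) -> float:
    """Pearson chi-square (no continuity correction), df=1, upper tail.

    Requires all four expected counts positive; degenerate margins should
    use an exact test instead.
    """
    table = c.table()
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row * col / table.sum()
    if (expected <= 0).any():
        raise ValidationError(
            "a zero expected cell makes the chi-square approximation invalid; "
            "use the hypergeometric or Fisher exact test"
        )
    statistic = float(((table - expected) ** 2 / expected).sum())
    return float(stats.chi2.sf(statistic, df=1))


_TEST_FUNCS = {
    "hypergeometric": hypergeom_pvalue,
    "fisher": fisher_pvalue,
    "binomial": binomial_pvalue,
    "chisq": chisq_pvalue,
}


def adjust_pvalues(pvals: Sequence[float], method: str = "BH") -> list[float]:
    """Multiple-testing adjustment: BH step-up, Bonferroni, or none.

    BH: sort ascending, p_(i) * m / i, enforce monotonicity from the
    largest rank down, cap at 1, and return in the input order.
    """
    arr = np.asarray(pvals, dtype=float)
    if arr.size == 0:
        return []
    if ((arr < 0) | (arr > 1)).any() or np.isnan(arr).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = arr.size
    if method == "none":
        return arr.tolist()
    if method == "bonferroni":
        return np.minimum(arr * m, 1.0).tolist()
    if method != "BH":
        raise ValidationError(f"unknown adjustment {method!r}")
    order = np.argsort(arr, kind="stable")
    ranked = arr[order] * m / np.arange(1, m + 1)
    ranked = np.minimum.accumulate(ranked[::-1])[::-1]
    ranked = np.minimum(ranked, 1.0)
    out = np.empty(m)
    out[order] = ranked
    return out.tolist()


def enrich(
    pool: NeighborMap,
    collection: GeneSetCollection,
    cfg: EnrichConfig | None = None,
) -> list[EnrichmentRow]:
    """Test every sufficiently large term for over-representation in C.

    The background is the collection's gene universe unless an explicit
    background is configured. Query genes outside the background are
    dropped from n (and logged); terms are sized within the background,
    skipped below ``min_set_size``; only terms with k >= 1 are reported
    and adjusted.
    """
    if cfg is None:
        cfg = EnrichConfig()
    if not collection.terms:
        raise DataError("gene-set collection is empty")
    background = (
        set(cfg.background) if cfg.background is not None else collection.universe()
    )
    pool_genes = set(pool.union_pool)
    query = pool_genes & background
    if not query:
        raise DataError(
            f"no pool gene is present in the background: {len(pool_genes)} pool "
            f"genes, {len(background)} background genes, 0 shared"
        )
    dropped = len(pool_genes) - len(query)
    if dropped:
        logger.info(
            "%d of %d pool genes are absent from the background and were dropped",
            dropped,
            len(pool_genes),
        )
    n = len(query)
    N = len(background)
    test = _TEST_FUNCS[cfg.test]

    candidates: list[tuple[str, str, ContingencyCounts, set[str]]] = []
    skipped_small = 0
    for term_id in sorted(collection.terms):
        term_name, genes = collection.terms[term_id]
        in_bg = genes & background
        if len(in_bg) < cfg.min_set_size:
            skipped_small += 1
            continue
        overlap = query & in_bg
        if not overlap:
            continue
        counts = ContingencyCounts(k=len(overlap), n=n, K=len(in_bg), N=N)
        candidates.append((term_id, term_name, counts, overlap))
    if skipped_small:
        logger.info(
            "%d terms below min_set_size=%d were skipped", skipped_small, cfg.min_set_size
        )
    logger.info("multiple-testing family size: %d terms", len(candidates))
    if not candidates:
        logger.warning("no term passed the size filter with a non-empty overlap")
        return []

    pvals = [test(c) for _, _, c, _ in candidates]
    padj = adjust_pvalues(pvals, cfg.padj_method)

    rows = []
    ncrna_sets = {r: pool.per_ncrna[r] for r in pool.ncrna_ids}
    for (term_id, term_name, counts, overlap), p, pa in zip(candidates, pvals, padj):
        contributors = {r for r, ci in ncrna_sets.items() if ci & overlap}
        rows.append(
            EnrichmentRow(
                term_id=term_id,
                term_name=term_name,
                p_value=p,
                p_adjusted=max(pa, p),
                counts=counts,
                overlap_genes=overlap,
                contributing_ncrnas=contributors,
            )
        )
    return rows
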