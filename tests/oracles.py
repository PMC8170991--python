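"""Independent reference implementations used to cross-check the package.

Everything here is deliberately naive: exact rational arithmetic,
brute-force enumeration, and scalar textbook formulas. None of it calls
the code paths (or scipy routines) it is used to verify.
"""

from __future__ import annotations

import itertools
import math
from fractions import Fraction

from cisenrich.types import GeneAnnotation, GenomicInterval


def hypergeom_tail_exact(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) for X ~ Hypergeom(N, K, n), as an exact rational."""
    total = math.comb(N, n)
    acc = Fraction(0)
    for x in range(k, min(n, K) + 1):
        acc += Fraction(math.comb(K, x) * math.comb(N - K, n - x), total)
    return acc


def hypergeom_tail_enumerated(k: int, n: int, K: int, N: int) -> Fraction:
    """P(X >= k) by literally enumerating all C(N, n) draws.

    The background is items 0..N-1 with the first K marked as in-term.
    Feasible only for small N.
    """
    hits = 0
    total = 0
    for draw in itertools.combinations(range(N), n):
        total += 1
        if sum(1 for item in draw if item < K) >= k:
            hits += 1
    return Fraction(hits, total)


def binomial_tail_direct(k: int, n: int, p: float) -> float:
    """P(X >= k) by term-by-term summation of the binomial pmf."""
    return sum(
        math.comb(n, x) * p**x * (1 - p) ** (n - x) for x in range(k, n + 1)
    )


def chisq_statistic_direct(table: list[list[float]]) -> float:
    """Pearson chi-square statistic computed cell by cell, no correction."""
    rows = [sum(r) for r in table]
    cols = [sum(c) for c in zip(*table)]
    total = sum(rows)
    stat = 0.0
    for i in range(2):
        for j in range(2):
            expected = rows[i] * cols[j] / total
            stat += (table[i][j] - expected) ** 2 / expected
    return stat


def pearson_scalar(x: list[float], y: list[float]) -> float:
    """Textbook Pearson correlation from raw sums."""
    n = len(x)
    mx = sum(x) / n
    my = sum(y) / n
    num = sum((a - mx) * (b - my) for a, b in zip(x, y))
    den = math.sqrt(
        sum((a - mx) ** 2 for a in x) * sum((b - my) ** 2 for b in y)
    )
    return num / den


def bh_stepup(pvals: list[float]) -> list[float]:
    """Benjamini-Hochberg step-up, written directly from its definition."""
    m = len(pvals)
    order = sorted(range(m), key=lambda i: pvals[i])
    adjusted = [0.0] * m
    running_min = 1.0
    for rank_from_top in range(m, 0, -1):
        i = order[rank_from_top - 1]
        value = min(pvals[i] * m / rank_from_top, 1.0)
        running_min = min(running_min, value)
        adjusted[i] = running_min
    return adjusted


def interval_union_length(intervals: list[tuple[int, int]]) -> int:
    """Base-by-base size of the union of half-open intervals."""
    covered: set[int] = set()
    for start, end in intervals:
        covered.update(range(start, end))
    return len(covered)


def brute_force_neighbors(
    ncrna_ids: list[str],
    annotation: GeneAnnotation,
    upstream: int,
    downstream: int,
    strand_aware: bool,
    region_mode: str,
    coding_biotypes: set[str] = frozenset({"protein_coding"}),
) -> dict[str, set[str]]:
    """All-pairs O(n*m) neighbor search, no interval index.

    Re-states the window and region rules from first principles: extend
    the ncRNA span (swapping up/down on minus strand when strand-aware),
    then keep coding genes with any region sharing >= 1 bp on the same
    chromosome.
    """
    coding = [g for g in annotation if g.biotype in coding_biotypes]
    result: dict[str, set[str]] = {}
    for rid in ncrna_ids:
        span = annotation[rid].span
        up, down = upstream, downstream
        if strand_aware and span.strand == "-":
            up, down = down, up
        w_start = max(0, span.start - up)
        w_end = span.end + down
        hits: set[str] = set()
        for gene in coding:
            if gene.gene_id == rid or gene.span.chrom != span.chrom:
                continue
            if region_mode == "gene":
                regions: list[GenomicInterval] = [gene.span]
            elif region_mode == "exon":
                regions = gene.exons
            else:
                regions = gene.introns
            for reg in regions:
                if reg.start < w_end and w_start < reg.end:
                    hits.add(gene.gene_id)
                    break
        result[rid] = hits
    return result
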