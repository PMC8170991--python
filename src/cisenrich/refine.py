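"""Refinement of the neighbor pool: co-expression, TADs, miRNA targets, biotype.

Each filter intersects the per-ncRNA neighbor sets with independent
biological evidence; co-expression additionally offers an expansion mode
that grows the union pool with coding genes correlated to any input ncRNA.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Iterable, Optional

import numpy as np
from scipy import stats

from .errors import DataError, ValidationError
from .neighborhood import EXPANSION_KEY, NeighborMap
from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    NcrnaSet,
    TadSet,
    TargetTable,
)

logger = logging.getLogger(__name__)

CORRELATION_METHODS = ("pearson", "spearman", "kendall")
COEFFICIENT_RULES = ("absolute", "positive", "negative")


@dataclass(frozen=True)
class CoexpressionConfig:
    """Options for expression preprocessing and pairwise correlation.

    Defaults follow the tool's published configuration: variance cutoff
    0.0025, correlation coefficient cutoff 0.3, significance p-value 0.05,
    confidence level 0.95. The optional low-expression / log2 / MAD fields
    reproduce the RPKM-style preprocessing preset (drop genes below 0.05
    in >20% of samples, log2(x+1), MAD > 0.5).
    """

    method: str = "pearson"
    variance_cutoff: float = 0.0025
    coefficient_cutoff: float = 0.3
    coefficient_rule: str = "absolute"
    p_cutoff: float = 0.05
    confidence_level: float = 0.95
    low_expr_value: Optional[float] = None
    low_expr_fraction: Optional[float] = None
    log2_transform: bool = False
    mad_cutoff: Optional[float] = None

    def __post_init__(self) -> None:
        if self.method not in CORRELATION_METHODS:
            raise ValidationError(f"unknown correlation method {self.method!r}")
        if self.coefficient_rule not in COEFFICIENT_RULES:
            raise ValidationError(f"unknown coefficient rule {self.coefficient_rule!r}")
        if self.variance_cutoff < 0:
            raise ValidationError("variance_cutoff must be non-negative")
        if not 0 < self.confidence_level < 1:
            raise ValidationError("confidence_level must lie in (0, 1)")
        if (self.low_expr_value is None) != (self.low_expr_fraction is None):
            raise ValidationError(
                "low_expr_value and low_expr_fraction must be set together"
            )


@dataclass(frozen=True)
class CoexpressionEdge:
    """One retained gene-gene correlation with its test statistics."""

    gene_a: str
    gene_b: str
    coefficient: float
    p_value: float
    ci_low: float = float("nan")
    ci_high: float = float("nan")
    n_samples: int = 0

    def __post_init__(self) -> None:
        if self.gene_a == self.gene_b:
            raise ValidationError("self-correlation edge is not allowed")
        if abs(self.coefficient) > 1 + 1e-12:
            raise ValidationError(f"|coefficient| > 1: {self.coefficient}")


def prefilter_expression(
    matrix: ExpressionMatrix, cfg: CoexpressionConfig
) -> ExpressionMatrix:
    """Apply the preprocessing chain: low-expression, log2, variance, MAD.

    Steps run in that fixed order; a step is skipped when its option is
    unset. Removing every gene is a hard error.
    """
    if matrix.shape[0] == 0:
        raise DataError("expression matrix has no genes")
    values = matrix.values
    keep = np.ones(values.shape[0], dtype=bool)

    if cfg.low_expr_value is not None:
        low_frac = (values < cfg.low_expr_value).mean(axis=1)
        keep &= low_frac <= cfg.low_expr_fraction
    values = values[keep]
    ids = [g for g, k in zip(matrix.gene_ids, keep) if k]

    if cfg.log2_transform:
        values = np.log2(values + 1.0)

    var = values.var(axis=1, ddof=1) if values.shape[1] > 1 else np.zeros(len(ids))
    keep2 = var >= cfg.variance_cutoff

    if cfg.mad_cutoff is not None:
        med = np.median(values, axis=1, keepdims=True)
        mad = np.median(np.abs(values - med), axis=1)
        keep2 &= mad > cfg.mad_cutoff

    values = values[keep2]
    ids = [g for g, k in zip(ids, keep2) if k]
    dropped = matrix.shape[0] - len(ids)
    if dropped:
        logger.info("expression prefilter removed %d of %d genes", dropped, matrix.shape[0])
    if not ids:
        raise DataError("expression prefilter removed every gene")
    return ExpressionMatrix(ids, matrix.sample_ids, values)


def _pearson_ci(r: float, n: int, confidence: float) -> tuple[float, float]:
    """Fisher z-transform confidence interval for a Pearson coefficient."""
    if n < 4 or abs(r) >= 1.0:
        return float("nan"), float("nan")
    z = math.atanh(r)
    se = 1.0 / math.sqrt(n - 3)
    crit = stats.norm.ppf(0.5 + confidence / 2.0)
    return math.tanh(z - crit * se), math.tanh(z + crit * se)


def _correlate(x: np.ndarray, y: np.ndarray, method: str) -> tuple[float, float]:
    if method == "pearson":
        res = stats.pearsonr(x, y)
    elif method == "spearman":
        res = stats.spearmanr(x, y)
    else:  # kendall: tau-b with the normal approximation
        res = stats.kendalltau(x, y, variant="b", method="asymptotic")
    return float(res.statistic), float(res.pvalue)


def _passes(coef: float, cfg: CoexpressionConfig) -> bool:
    if cfg.coefficient_rule == "absolute":
        return abs(coef) >= cfg.coefficient_cutoff
    if cfg.coefficient_rule == "positive":
        return coef >= cfg.coefficient_cutoff
    return coef <= -cfg.coefficient_cutoff


def compute_coexpression(
    matrix: ExpressionMatrix,
    left_ids: Iterable[str],
    right_ids: Iterable[str],
    cfg: CoexpressionConfig | None = None,
) -> list[CoexpressionEdge]:
    """Correlate every (left, right) gene pair and keep significant edges.

    An edge survives when its coefficient passes the configured rule and
    cutoff and its two-sided p-value is at most ``p_cutoff``. Pearson edges
    carry a Fisher-z confidence interval at the configured level.
    """
    if cfg is None:
        cfg = CoexpressionConfig()
    n = matrix.shape[1]
    if n < 3:
        raise DataError(f"correlation needs >= 3 samples, got {n}")
    left = [g for g in left_ids if g in matrix]
    right = [g for g in right_ids if g in matrix]
    edges: list[CoexpressionEdge] = []
    for a in left:
        xa = matrix.row(a)
        for b in right:
            if a == b:
                continue
            coef, pval = _correlate(xa, matrix.row(b), cfg.method)
            if math.isnan(coef):
                continue  # constant vector slipped past the prefilter
            if not (_passes(coef, cfg) and pval <= cfg.p_cutoff):
                continue
            lo, hi = (
                _pearson_ci(coef, n, cfg.confidence_level)
                if cfg.method == "pearson"
                else (float("nan"), float("nan"))
            )
            edges.append(
                CoexpressionEdge(a, b, coef, pval, lo, hi, n_samples=n)
            )
    return edges


def apply_coexpression(
    nm: NeighborMap,
    edges: list[CoexpressionEdge],
    mode: str = "filter",
) -> NeighborMap:
    """Filter each C_i to co-expressed partners, or expand the union pool.

    filter: C_i keeps only genes with a retained edge to r_i.
    expand: per-ncRNA sets are unchanged; coding genes correlated with any
    r_i join the union pool, recorded under a dedicated pseudo-entry so the
    union invariant stays checkable.
    """
    if mode not in ("filter", "expand"):
        raise ValidationError(f"co-expression mode must be filter|expand, got {mode!r}")
    partners: dict[str, set[str]] = {}
    for e in edges:
        partners.setdefault(e.gene_a, set()).add(e.gene_b)
        partners.setdefault(e.gene_b, set()).add(e.gene_a)
    out = nm.copy()
    if mode == "filter":
        for rid in out.ncrna_ids:
            out.per_ncrna[rid] &= partners.get(rid, set())
    else:
        extra: set[str] = set()
        for rid in out.ncrna_ids:
            extra |= partners.get(rid, set())
        extra -= set(out.ncrna_ids)
        if extra:
            out.per_ncrna[EXPANSION_KEY] = (
                out.per_ncrna.get(EXPANSION_KEY, set()) | extra
            )
    out.union_pool = set().union(*out.per_ncrna.values()) if out.per_ncrna else set()
    return out


def assign_tads(
    gene_ids: Iterable[str], annotation: GeneAnnotation, tads: TadSet
) -> dict[str, set[str]]:
    """Map each gene to every TAD its span overlaps by >= 1 bp."""
    out: dict[str, set[str]] = {}
    for gid in gene_ids:
        span = annotation[gid].span
        hit = {
            name
            for name, region in tads.regions
            if span.overlaps(region)
        }
        out[gid] = hit
    return out


def filter_by_tad(
    nm: NeighborMap, annotation: GeneAnnotation, tads: TadSet
) -> NeighborMap:
    """Keep only neighbors sharing at least one TAD with their ncRNA.

    Membership is any-overlap: a gene straddling a boundary belongs to both
    TADs. An ncRNA assigned to no TAD loses its whole neighbor set.
    """
    if not tads.regions:
        raise ValidationError("TAD set is empty")
    all_ids = set(nm.union_pool) | set(nm.ncrna_ids)
    membership = assign_tads(all_ids, annotation, tads)
    out = nm.copy()
    for rid in out.ncrna_ids:
        r_tads = membership.get(rid, set())
        if not r_tads:
            logger.warning("ncRNA %s overlaps no TAD; neighbor set emptied", rid)
            out.per_ncrna[rid] = set()
            continue
        out.per_ncrna[rid] = {
            gid for gid in out.per_ncrna[rid] if membership[gid] & r_tads
        }
    out.union_pool = set().union(*out.per_ncrna.values()) if out.per_ncrna else set()
    return out


def _normalize_mirna(token: str, strip_species_prefix: bool = False) -> str:
    t = token.lower()
    if strip_species_prefix and "-" in t:
        head, rest = t.split("-", 1)
        if len(head) == 3 and rest.startswith(("mir", "let")):
            t = rest
    return t


def filter_by_targets(
    nm: NeighborMap,
    targets: TargetTable,
    strip_species_prefix: bool = False,
) -> NeighborMap:
    """Restrict each C_i to predicted targets of the miRNA r_i.

    miRNA keys match case-insensitively; optionally the three-letter
    species prefix (hsa-, mmu-, ...) is stripped on both sides. An input
    miRNA absent from the table loses its neighbors with a warning.
    """
    table = {
        _normalize_mirna(m, strip_species_prefix): genes
        for m, genes in targets.targets.items()
    }
    out = nm.copy()
    for rid in out.ncrna_ids:
        key = _normalize_mirna(rid, strip_species_prefix)
        if key not in table:
            logger.warning("miRNA %s has no entry in the target table", rid)
            out.per_ncrna[rid] = set()
            continue
        out.per_ncrna[rid] &= table[key]
    out.union_pool = set().union(*out.per_ncrna.values()) if out.per_ncrna else set()
    return out


def filter_biotype(
    ncrnas: NcrnaSet,
    annotation: GeneAnnotation,
    biotypes: Iterable[str],
    mode: str = "keep",
) -> NcrnaSet:
    """Subset the input ncRNAs by biotype, keeping or excluding the given set."""
    biotypes = set(biotypes)
    if not biotypes:
        raise ValidationError("biotype set must be non-empty")
    if mode not in ("keep", "exclude"):
        raise ValidationError(f"biotype mode must be keep|exclude, got {mode!r}")
    if mode == "keep":
        kept = [r for r in ncrnas.resolved if annotation.biotype_of(r) in biotypes]
    else:
        kept = [r for r in ncrnas.resolved if annotation.biotype_of(r) not in biotypes]
    if not kept:
        raise DataError(
            f"biotype filter ({mode} {sorted(biotypes)}) removed every input gene"
        )
    return NcrnaSet(resolved=kept, unresolved=list(ncrnas.unresolved))
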