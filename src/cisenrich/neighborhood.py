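"""Curation of per-ncRNA proximal protein-coding gene sets.

For every input ncRNA r_i, the neighborhood search extends the ncRNA's
genomic span by an upstream/downstream window and collects every coding
gene whose region (full span, merged exons, or introns, per the configured
region mode) overlaps that window by at least 1 bp on the same chromosome.
The union of all per-ncRNA sets, C, is the pool later tested for
enrichment.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

from intervaltree import IntervalTree

from .errors import ValidationError
from .types import GeneAnnotation, GeneRecord, GenomicInterval, NcrnaSet

logger = logging.getLogger(__name__)

REGION_MODES = ("gene", "exon", "intron")

#: pseudo-entry key under which co-expression expansion genes are recorded
#: so that union_pool always equals the union of per-ncRNA sets.
EXPANSION_KEY = "__coexpression_expansion__"


@dataclass(frozen=True)
class SearchConfig:
    """Window and region options for the cis-neighborhood search.

    upstream_bp / downstream_bp extend the ncRNA span before its start and
    after its end. With ``strand_aware`` the roles swap on minus-strand
    ncRNAs so "upstream" follows transcription; otherwise the extension is
    purely genomic left/right.
    """

    upstream_bp: int = 10_000
    downstream_bp: int = 10_000
    strand_aware: bool = False
    region_mode: str = "gene"
    coding_biotypes: frozenset[str] = frozenset({"protein_coding"})

    def __post_init__(self) -> None:
        if self.upstream_bp < 0 or self.downstream_bp < 0:
            raise ValidationError("window sizes must be non-negative")
        if self.region_mode not in REGION_MODES:
            raise ValidationError(
                f"region_mode must be one of {REGION_MODES}, got {self.region_mode!r}"
            )
        if not self.coding_biotypes:
            raise ValidationError("coding_biotypes must be non-empty")


@dataclass
class NeighborMap:
    """Per-ncRNA coding neighbor sets C_i and their union pool C."""

    per_ncrna: dict[str, set[str]]
    union_pool: set[str] = field(default_factory=set)
    parameters: SearchConfig | None = None

    def __post_init__(self) -> None:
        recomputed = set().union(*self.per_ncrna.values()) if self.per_ncrna else set()
        if not self.union_pool:
            self.union_pool = recomputed
        elif self.union_pool != recomputed:
            raise ValidationError("union_pool does not equal the union of C_i")

    @property
    def ncrna_ids(self) -> list[str]:
        return [r for r in self.per_ncrna if r != EXPANSION_KEY]

    def copy(self) -> "NeighborMap":
        return NeighborMap(
            per_ncrna={r: set(c) for r, c in self.per_ncrna.items()},
            union_pool=set(self.union_pool),
            parameters=self.parameters,
        )

    def counts(self) -> dict[str, int]:
        return {r: len(c) for r, c in self.per_ncrna.items()}


def derive_regions(gene: GeneRecord, mode: str) -> list[GenomicInterval]:
    """Gene regions under a region mode: span, merged exons, or introns.

    Intron mode on a single-exon gene yields an empty list (not an error).
    """
    if mode == "gene":
        return [gene.span]
    if mode == "exon":
        return list(gene.exons)
    if mode == "intron":
        return gene.introns
    raise ValidationError(f"unknown region mode {mode!r}")


def search_window(interval: GenomicInterval, cfg: SearchConfig) -> GenomicInterval:
    """Extend an ncRNA span by the configured window, clamped at 0.

    Strand-aware mode swaps upstream/downstream on the minus strand.
    """
    up, down = cfg.upstream_bp, cfg.downstream_bp
    if cfg.strand_aware and interval.strand == "-":
        up, down = down, up
    return GenomicInterval(
        interval.chrom,
        max(0, interval.start - up),
        interval.end + down,
        interval.strand,
    )


def _region_tree(
    annotation: GeneAnnotation, cfg: SearchConfig
) -> dict[str, IntervalTree]:
    """Per-chromosome interval index of coding-gene regions under cfg."""
    trees: dict[str, IntervalTree] = {}
    for gene in annotation:
        if gene.biotype not in cfg.coding_biotypes:
            continue
        for region in derive_regions(gene, cfg.region_mode):
            trees.setdefault(region.chrom, IntervalTree()).addi(
                region.start, region.end, gene.gene_id
            )
    return trees


def find_cis_neighbors(
    ncrnas: NcrnaSet,
    annotation: GeneAnnotation,
    cfg: SearchConfig | None = None,
) -> NeighborMap:
    """Build the NeighborMap: C_i per ncRNA and the union pool C.

    Overlap is strand-blind and requires >= 1 shared bp between the
    ncRNA's search window and a coding gene's region on the same
    chromosome. An ncRNA never appears in its own C_i.
    """
    if cfg is None:
        cfg = SearchConfig()
    if not ncrnas.resolved:
        raise ValidationError("no resolved ncRNA identifiers to search from")
    trees = _region_tree(annotation, cfg)
    per: dict[str, set[str]] = {}
    for rid in ncrnas.resolved:
        gene = annotation[rid]
        if gene.biotype in cfg.coding_biotypes:
            logger.warning(
                "input gene %s is annotated as coding (%s); it is excluded "
                "from its own neighbor set",
                rid,
                gene.biotype,
            )
        window = search_window(gene.span, cfg)
        tree = trees.get(window.chrom)
        hits: set[str] = set()
        if tree is not None:
            hits = {h.data for h in tree.overlap(window.start, window.end)}
        hits.discard(rid)
        per[rid] = hits
    nm = NeighborMap(per_ncrna=per, parameters=cfg)
    if not nm.union_pool:
        logger.warning("no coding neighbors found for any input ncRNA")
    return nm


def neighbor_distances(
    nm: NeighborMap, annotation: GeneAnnotation
) -> list[tuple[str, str, int]]:
    """(ncRNA, neighbor, gap bp) rows; 0 when the spans overlap."""
    rows = []
    for rid in nm.ncrna_ids:
        r_span = annotation[rid].span
        for gid in sorted(nm.per_ncrna[rid]):
            rows.append((rid, gid, r_span.distance_to(annotation[gid].span)))
    return rows
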