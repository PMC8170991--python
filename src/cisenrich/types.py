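"""Core domain containers.

All genomic coordinates are stored 0-based half-open, regardless of the
file format they came from (GTF is converted on read, BED is native).
Strand is "+", "-" or "." (unstranded).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping

import numpy as np
from intervaltree import IntervalTree

from .errors import ValidationError

STRANDS = {"+", "-", "."}


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """A half-open interval [start, end) on a named chromosome."""

    chrom: str
    start: int
    end: int
    strand: str = "."

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValidationError("interval chromosome name must be non-empty")
        if self.start < 0:
            raise ValidationError(f"interval start {self.start} < 0")
        if self.start >= self.end:
            raise ValidationError(
                f"interval start {self.start} >= end {self.end} on {self.chrom}"
            )
        if self.strand not in STRANDS:
            raise ValidationError(f"invalid strand {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True when the two intervals share >= 1 bp (strand-blind)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def distance_to(self, other: "GenomicInterval") -> int:
        """Gap in bp between the intervals; 0 when they overlap or touch."""
        if self.chrom != other.chrom:
            raise ValidationError("distance undefined across chromosomes")
        if self.start < other.end and other.start < self.end:
            return 0
        return max(self.start - other.end, other.start - self.end, 0)


def merge_intervals(intervals: Iterable[GenomicInterval]) -> list[GenomicInterval]:
    """Merge overlapping/adjacent intervals into a sorted disjoint union.

    All intervals must share one chromosome and strand.
    """
    ivs = sorted(intervals, key=lambda iv: (iv.start, iv.end))
    if not ivs:
        return []
    chroms = {iv.chrom for iv in ivs}
    strands = {iv.strand for iv in ivs}
    if len(chroms) > 1 or len(strands) > 1:
        raise ValidationError("cannot merge intervals across chromosomes/strands")
    merged: list[GenomicInterval] = [ivs[0]]
    for iv in ivs[1:]:
        last = merged[-1]
        if iv.start <= last.end:
            if iv.end > last.end:
                merged[-1] = GenomicInterval(last.chrom, last.start, iv.end, last.strand)
        else:
            merged.append(iv)
    return merged


@dataclass
class GeneRecord:
    """One gene: its span, merged exon union across transcripts, and identity."""

    gene_id: str
    symbol: str
    biotype: str
    span: GenomicInterval
    exons: list[GenomicInterval] = field(default_factory=list)
    aliases: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        if not self.biotype:
            raise ValidationError(f"gene {self.gene_id}: biotype must be non-empty")
        if not self.exons:
            self.exons = [self.span]
        for ex in self.exons:
            if ex.chrom != self.span.chrom or ex.strand != self.span.strand:
                raise ValidationError(
                    f"gene {self.gene_id}: exon on different chrom/strand than span"
                )
            if ex.start < self.span.start or ex.end > self.span.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exon {ex.start}-{ex.end} outside span"
                )
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start < a.end:
                raise ValidationError(
                    f"gene {self.gene_id}: exons not disjoint/sorted"
                )

    @property
    def introns(self) -> list[GenomicInterval]:
        """Gaps between consecutive merged exons; empty for single-exon genes."""
        out = []
        for a, b in zip(self.exons, self.exons[1:]):
            if b.start > a.end:
                out.append(
                    GenomicInterval(self.span.chrom, a.end, b.start, self.span.strand)
                )
        return out


class GeneAnnotation:
    """Indexed collection of gene records; the coordinate universe for queries."""

    def __init__(self, genes: Iterable[GeneRecord], assembly_label: str = "custom"):
        self.assembly_label = assembly_label
        self.genes: dict[str, GeneRecord] = {}
        for g in genes:
            if g.gene_id in self.genes:
                raise ValidationError(f"duplicate gene_id {g.gene_id}")
            self.genes[g.gene_id] = g
        self._trees: dict[str, IntervalTree] = {}
        for g in self.genes.values():
            tree = self._trees.setdefault(g.span.chrom, IntervalTree())
            tree.addi(g.span.start, g.span.end, g.gene_id)
        # symbol/alias lookup, case-insensitive
        self._by_symbol: dict[str, set[str]] = {}
        self._by_alias: dict[str, set[str]] = {}
        for g in self.genes.values():
            if g.symbol:
                self._by_symbol.setdefault(g.symbol.lower(), set()).add(g.gene_id)
            for al in g.aliases:
                self._by_alias.setdefault(al.lower(), set()).add(g.gene_id)

    def __len__(self) -> int:
        return len(self.genes)

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.genes

    def __getitem__(self, gene_id: str) -> GeneRecord:
        return self.genes[gene_id]

    def __iter__(self) -> Iterator[GeneRecord]:
        return iter(self.genes.values())

    def chromosomes(self) -> list[str]:
        return sorted(self._trees)

    def overlapping(self, interval: GenomicInterval) -> set[str]:
        """gene_ids whose span overlaps `interval` by >= 1 bp (strand-blind)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return set()
        return {hit.data for hit in tree.overlap(interval.start, interval.end)}

    def lookup_symbol(self, token: str) -> set[str]:
        return set(self._by_symbol.get(token.lower(), set()))

    def lookup_alias(self, token: str) -> set[str]:
        return set(self._by_alias.get(token.lower(), set()))

    def biotype_of(self, gene_id: str) -> str:
        return self.genes[gene_id].biotype


@dataclass
class NcrnaSet:
    """Resolved input gene set S = {r_1, ..., r_n} plus unmapped tokens."""

    resolved: list[str]
    unresolved: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen = set()
        deduped = []
        for g in self.resolved:
            if g not in seen:
                seen.add(g)
                deduped.append(g)
        self.resolved = deduped

    def __len__(self) -> int:
        return len(self.resolved)


@dataclass
class TadSet:
    """Named TAD regions; overlap and nesting between regions is allowed."""

    regions: list[tuple[str, GenomicInterval]]

    def __len__(self) -> int:
        return len(self.regions)


@dataclass
class GeneSetCollection:
    """term_id -> (term_name, member genes); doubles as default background."""

    terms: dict[str, tuple[str, set[str]]]
    source_label: str = "custom"

    def __post_init__(self) -> None:
        for tid, (_, genes) in self.terms.items():
            if not genes:
                raise ValidationError(f"term {tid} has an empty gene set")

    def __len__(self) -> int:
        return len(self.terms)

    def universe(self) -> set[str]:
        """Union of all member genes across terms (the default background)."""
        out: set[str] = set()
        for _, genes in self.terms.values():
            out |= genes
        return out


class ExpressionMatrix:
    """Genes x samples numeric matrix with unique, ordered axis labels."""

    def __init__(
        self,
        gene_ids: list[str],
        sample_ids: list[str],
        values: np.ndarray,
    ):
        values = np.asarray(values, dtype=float)
        if values.shape != (len(gene_ids), len(sample_ids)):
            raise ValidationError(
                f"matrix shape {values.shape} does not match "
                f"{len(gene_ids)} genes x {len(sample_ids)} samples"
            )
        if len(set(gene_ids)) != len(gene_ids):
            raise ValidationError("duplicate gene IDs in expression matrix")
        if len(set(sample_ids)) != len(sample_ids):
            raise ValidationError("duplicate sample IDs in expression matrix")
        self.gene_ids = list(gene_ids)
        self.sample_ids = list(sample_ids)
        self.values = values
        self._row = {g: i for i, g in enumerate(gene_ids)}

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self._row

    def row(self, gene_id: str) -> np.ndarray:
        return self.values[self._row[gene_id]]

    def subset(self, gene_ids: Iterable[str]) -> "ExpressionMatrix":
        keep = [g for g in self.gene_ids if g in set(gene_ids)]
        idx = [self._row[g] for g in keep]
        return ExpressionMatrix(keep, self.sample_ids, self.values[idx])


@dataclass
class TargetTable:
    """miRNA identifier -> set of target gene IDs."""

    targets: Mapping[str, set[str]]

    def __post_init__(self) -> None:
        for mirna, genes in self.targets.items():
            if not genes:
                raise ValidationError(f"miRNA {mirna} has an empty target set")

    def __len__(self) -> int:
        return len(self.targets)
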