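"""Readers for the standard input formats and gene-identifier resolution.

Every reader accepts a plain or gzip-compressed text file. GTF coordinates
(1-based inclusive) are converted to the internal 0-based half-open
convention on read; BED is already native.
"""

from __future__ import annotations

import gzip
import logging
import re
from pathlib import Path
from typing import IO, Iterable, Optional

import numpy as np
import pandas as pd

from .errors import DataError, FormatError, ValidationError
from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    GeneSetCollection,
    GenomicInterval,
    NcrnaSet,
    TadSet,
    TargetTable,
    merge_intervals,
)

logger = logging.getLogger(__name__)

_ATTR_RE = re.compile(r'(\w+)\s+"([^"]*)"')

DEFAULT_CODING_BIOTYPES = frozenset({"protein_coding"})


def _open_text(path: str | Path) -> IO[str]:
    path = Path(path)
    if path.suffix == ".gz":
        return gzip.open(path, "rt")
    return open(path, "rt")


def _parse_gtf_attributes(raw: str) -> dict[str, str]:
    return dict(_ATTR_RE.findall(raw))


def read_gtf(
    path: str | Path,
    coding_biotypes: Iterable[str] = DEFAULT_CODING_BIOTYPES,
) -> GeneAnnotation:
    """Parse a GENCODE-dialect GTF into a :class:`GeneAnnotation`.

    Gene spans come from ``gene`` features; exons are collected across all
    transcripts of a gene and merged into a disjoint union. Genes without
    any exon feature fall back to their span as the single exon. Both
    ``gene_type`` (GENCODE) and ``gene_biotype`` (Ensembl) attribute names
    are accepted.
    """
    spans: dict[str, GenomicInterval] = {}
    symbols: dict[str, str] = {}
    biotypes: dict[str, str] = {}
    exon_parts: dict[str, list[GenomicInterval]] = {}

    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 9:
                raise FormatError(
                    f"{path}: line {lineno}: expected 9 tab-separated fields, "
                    f"got {len(fields)}"
                )
            chrom, _source, feature, start_s, end_s, _score, strand, _frame, attrs_s = fields
            if feature not in ("gene", "exon"):
                continue
            try:
                start1 = int(start_s)
                end1 = int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start1 < 1 or end1 < start1:
                raise FormatError(
                    f"{path}: line {lineno}: invalid 1-based interval {start1}-{end1}"
                )
            attrs = _parse_gtf_attributes(attrs_s)
            gene_id = attrs.get("gene_id")
            if not gene_id:
                raise FormatError(f"{path}: line {lineno}: missing gene_id attribute")
            if strand not in ("+", "-"):
                strand = "."
            # 1-based inclusive -> 0-based half-open
            iv = GenomicInterval(chrom, start1 - 1, end1, strand)
            if feature == "gene":
                if gene_id in spans and spans[gene_id] != iv:
                    raise ValidationError(
                        f"{path}: line {lineno}: duplicate gene_id {gene_id} "
                        f"with conflicting coordinates"
                    )
                spans[gene_id] = iv
                symbols[gene_id] = attrs.get("gene_name", gene_id)
                biotypes[gene_id] = (
                    attrs.get("gene_type") or attrs.get("gene_biotype") or "unknown"
                )
            else:
                exon_parts.setdefault(gene_id, []).append(iv)

    records = []
    for gene_id, span in spans.items():
        parts = exon_parts.get(gene_id)
        exons = merge_intervals(parts) if parts else [span]
        records.append(
            GeneRecord(
                gene_id=gene_id,
                symbol=symbols[gene_id],
                biotype=biotypes[gene_id],
                span=span,
                exons=exons,
            )
        )
    if not records:
        logger.warning("GTF %s contained no gene features", path)
    ann = GeneAnnotation(records, assembly_label=str(path))
    ann.coding_biotypes = frozenset(coding_biotypes)  # type: ignore[attr-defined]
    return ann


def read_bed(path: str | Path) -> TadSet:
    """Read BED3/BED4 TAD regions; unnamed regions are auto-named by ordinal."""
    regions: list[tuple[str, GenomicInterval]] = []
    with _open_text(path) as fh:
        ordinal = 0
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: BED needs >= 3 columns"
                )
            chrom, start_s, end_s = fields[0], fields[1], fields[2]
            try:
                start, end = int(start_s), int(end_s)
            except ValueError as exc:
                raise FormatError(
                    f"{path}: line {lineno}: non-integer coordinates"
                ) from exc
            if start >= end:
                raise ValidationError(
                    f"{path}: line {lineno}: chromStart {start} >= chromEnd {end}"
                )
            ordinal += 1
            name = fields[3] if len(fields) >= 4 and fields[3] else f"region_{ordinal}"
            regions.append((name, GenomicInterval(chrom, start, end)))
    return TadSet(regions)


def read_gmt(path: str | Path) -> GeneSetCollection:
    """Read a GMT gene-set file: term, description, member genes."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise FormatError(
                    f"{path}: line {lineno}: GMT line needs term, description "
                    f"and >= 1 gene"
                )
            term_id, desc = fields[0], fields[1]
            genes = {g for g in fields[2:] if g}
            if not genes:
                raise FormatError(f"{path}: line {lineno}: no genes for {term_id}")
            if term_id in terms:
                raise FormatError(
                    f"{path}: line {lineno}: duplicate term {term_id}"
                )
            terms[term_id] = (desc, genes)
    return GeneSetCollection(terms, source_label=str(path))


def read_term_gene_table(path: str | Path) -> GeneSetCollection:
    """Read a 2/3-column TSV (term_id, gene_id[, term_name]) into gene sets."""
    terms: dict[str, tuple[str, set[str]]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: need term_id and gene_id columns"
                )
            term_id, gene_id = fields[0], fields[1]
            name = fields[2] if len(fields) >= 3 and fields[2] else term_id
            if term_id in terms:
                old_name, genes = terms[term_id]
                genes.add(gene_id)
                if name != term_id:
                    terms[term_id] = (name, genes)
            else:
                terms[term_id] = (name, {gene_id})
    return GeneSetCollection(terms, source_label=str(path))


def read_expression(path: str | Path) -> ExpressionMatrix:
    """Read a genes x samples TSV: first column gene IDs, header sample IDs.

    Non-numeric or missing cells are an error — missing-data handling is
    deliberately not silently imputed.
    """
    df = pd.read_csv(_open_text(path), sep="\t", index_col=0, dtype=str)
    if df.index.has_duplicates:
        dups = df.index[df.index.duplicated()].unique().tolist()
        raise ValidationError(f"{path}: duplicate gene ID rows: {dups[:5]}")
    numeric = df.apply(pd.to_numeric, errors="coerce")
    bad = numeric.isna()
    if bad.to_numpy().any():
        r, c = np.argwhere(bad.to_numpy())[0]
        raise FormatError(
            f"{path}: non-numeric cell at gene {df.index[r]!r}, "
            f"sample {df.columns[c]!r}: {df.iat[r, c]!r}"
        )
    return ExpressionMatrix(
        list(df.index.astype(str)),
        list(df.columns.astype(str)),
        numeric.to_numpy(dtype=float),
    )


def read_target_table(path: str | Path) -> TargetTable:
    """Read a two-column TSV (miRNA_id, target_gene_id) into a TargetTable."""
    targets: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: need miRNA_id and target columns"
                )
            targets.setdefault(fields[0], set()).add(fields[1])
    return TargetTable(targets)


def read_alias_table(path: str | Path) -> dict[str, set[str]]:
    """Read a two-column TSV (alias, gene_id), lower-cased alias keys."""
    mapping: dict[str, set[str]] = {}
    with _open_text(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise FormatError(
                    f"{path}: line {lineno}: need alias and gene_id columns"
                )
            mapping.setdefault(fields[0].lower(), set()).add(fields[1])
    return mapping


def read_gene_list(path: str | Path) -> list[str]:
    """Read a plain-text gene list, one token per line."""
    with _open_text(path) as fh:
        return [line.strip() for line in fh if line.strip()]


def resolve_ids(
    tokens: list[str],
    annotation: GeneAnnotation,
    mapping: Optional[dict[str, set[str]]] = None,
) -> NcrnaSet:
    """Map heterogeneous input identifiers onto annotation gene IDs.

    Each token is matched case-insensitively against gene_id, then symbol,
    then the optional alias table. An ambiguous symbol resolves to every
    matching gene with a warning. Duplicate tokens collapse.
    """
    if not tokens:
        raise DataError("input gene list is empty")
    by_id = {gid.lower(): gid for gid in annotation.genes}
    resolved: list[str] = []
    unresolved: list[str] = []
    seen: set[str] = set()
    for token in tokens:
        low = token.lower()
        hits: set[str] = set()
        if low in by_id:
            hits = {by_id[low]}
        else:
            hits = annotation.lookup_symbol(token)
            if not hits:
                hits = annotation.lookup_alias(token)
            if not hits and mapping:
                hits = {g for g in mapping.get(low, set()) if g in annotation}
        if not hits:
            unresolved.append(token)
            continue
        if len(hits) > 1:
            logger.warning(
                "token %r matched %d genes: %s", token, len(hits), sorted(hits)
            )
        for gid in sorted(hits):
            if gid not in seen:
                seen.add(gid)
                resolved.append(gid)
    if not resolved:
        raise DataError(
            f"none of the {len(tokens)} input tokens could be resolved "
            f"against the annotation (first unmapped: {unresolved[:5]})"
        )
    if unresolved:
        logger.warning("%d input tokens could not be resolved", len(unresolved))
    return NcrnaSet(resolved=resolved, unresolved=unresolved)
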