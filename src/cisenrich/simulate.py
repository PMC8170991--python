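"""Deterministic synthetic fixtures: genomes, TADs, expression, gene sets.

Every generator is a pure function of a :class:`FixtureSpec`, so identical
specs produce byte-identical files. The generators plant recoverable
signal — correlated ncRNA/coding expression pairs and a gene-set term
loaded with neighbor-pool genes — so the whole pipeline can be exercised
end-to-end without any external download.
"""

from __future__ import annotations

import gzip
import json
from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable

import numpy as np

from .errors import ValidationError
from .types import (
    ExpressionMatrix,
    GeneAnnotation,
    GeneRecord,
    GeneSetCollection,
    GenomicInterval,
    TadSet,
    TargetTable,
)

NCRNA_BIOTYPES = ("lincRNA", "antisense", "miRNA")

CODING_LEN = (1_000, 10_000)
NCRNA_LEN = (300, 3_000)
MIN_GAP = 1_000


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of one synthetic dataset.

    ``planted_pairs`` lists (ncRNA index, coding index, target Pearson rho)
    triples realised in the expression matrix; ``planted_term_overlap`` is
    the number of neighbor-pool genes loaded into the planted gene-set
    term. Defaults give a compact two-chromosome genome that a laptop
    processes in well under a second.
    """

    seed: int = 0
    n_chrom: int = 2
    chrom_length_bp: int = 2_000_000
    n_coding: int = 300
    n_ncrna: int = 30
    n_tads_per_chrom: int = 8
    n_samples: int = 100
    planted_pairs: tuple[tuple[int, int, float], ...] = ()
    planted_term_overlap: int = 16
    n_decoy_terms: int = 40

    def __post_init__(self) -> None:
        for name in ("n_chrom", "chrom_length_bp", "n_coding", "n_ncrna",
                     "n_tads_per_chrom", "n_samples", "n_decoy_terms"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if self.planted_term_overlap > self.n_coding:
            raise ValidationError("planted_term_overlap exceeds n_coding")
        for i, j, rho in self.planted_pairs:
            if not -1 < rho < 1:
                raise ValidationError(f"planted rho {rho} outside (-1, 1)")
            if not (0 <= i < self.n_ncrna and 0 <= j < self.n_coding):
                raise ValidationError(f"planted pair ({i}, {j}) out of range")


def coding_ids(spec: FixtureSpec) -> list[str]:
    return [f"CG{i:05d}" for i in range(spec.n_coding)]


def ncrna_ids(spec: FixtureSpec) -> list[str]:
    return [f"NC{i:05d}" for i in range(spec.n_ncrna)]


def _make_exons(
    rng: np.random.Generator, span: GenomicInterval
) -> list[GenomicInterval]:
    """Cut a span into 1-4 exons separated by introns of >= 1 bp."""
    n_exons = int(rng.integers(1, 5))
    if n_exons == 1 or len(span) < 2 * n_exons * 10:
        return [span]
    # 2*n_exons - 2 interior cut points -> exon/intron alternation
    cuts = np.sort(
        rng.choice(
            np.arange(span.start + 1, span.end), size=2 * n_exons - 2, replace=False
        )
    )
    bounds = [span.start, *cuts.tolist(), span.end]
    return [
        GenomicInterval(span.chrom, bounds[i], bounds[i + 1], span.strand)
        for i in range(0, len(bounds) - 1, 2)
    ]


def make_annotation(spec: FixtureSpec) -> GeneAnnotation:
    """Place non-overlapping genes uniformly with >= 1 kb inter-gene gaps.

    Coding genes get 1-4 exons; ncRNAs rotate through lincRNA, antisense
    and miRNA biotypes and keep a single exon.
    """
    rng = np.random.default_rng(spec.seed)
    entries = [("coding", i) for i in range(spec.n_coding)] + [
        ("ncrna", i) for i in range(spec.n_ncrna)
    ]
    chrom_of = rng.integers(0, spec.n_chrom, size=len(entries))
    records: list[GeneRecord] = []
    for c in range(spec.n_chrom):
        chrom = f"chr{c + 1}"
        members = [entries[i] for i in np.flatnonzero(chrom_of == c)]
        rng.shuffle(members)
        lengths = [
            int(rng.integers(*CODING_LEN)) if kind == "coding"
            else int(rng.integers(*NCRNA_LEN))
            for kind, _ in members
        ]
        needed = sum(lengths) + (len(members) + 1) * MIN_GAP
        if needed > spec.chrom_length_bp:
            raise ValidationError(
                f"{chrom}: {len(members)} genes need {needed} bp but the "
                f"chromosome is {spec.chrom_length_bp} bp; increase "
                f"chrom_length_bp or n_chrom"
            )
        slack = spec.chrom_length_bp - needed
        weights = rng.random(len(members) + 1)
        extra = np.floor(weights / weights.sum() * slack).astype(int)
        pos = 0
        for (kind, idx), length, pad in zip(members, lengths, extra):
            pos += MIN_GAP + int(pad)
            strand = "+" if rng.random() < 0.5 else "-"
            span = GenomicInterval(chrom, pos, pos + length, strand)
            pos += length
            if kind == "coding":
                records.append(
                    GeneRecord(
                        gene_id=f"CG{idx:05d}",
                        symbol=f"PCG{idx}",
                        biotype="protein_coding",
                        span=span,
                        exons=_make_exons(rng, span),
                        aliases={f"ALT:CG{idx:05d}"},
                    )
                )
            else:
                biotype = NCRNA_BIOTYPES[idx % len(NCRNA_BIOTYPES)]
                prefix = {"lincRNA": "LINC", "antisense": "AS", "miRNA": "MIR"}[biotype]
                records.append(
                    GeneRecord(
                        gene_id=f"NC{idx:05d}",
                        symbol=f"{prefix}{idx}",
                        biotype=biotype,
                        span=span,
                        aliases={f"ALT:NC{idx:05d}"},
                    )
                )
    records.sort(key=lambda r: r.gene_id)
    return GeneAnnotation(records, assembly_label=f"synthetic-seed{spec.seed}")


def make_tads(
    spec: FixtureSpec, annotation: GeneAnnotation, force_straddle: bool = False
) -> TadSet:
    """Tile each chromosome with contiguous TADs covering [0, length).

    Boundaries snap to the midpoint of the nearest inter-gene gap so genes
    rarely straddle them; ``force_straddle`` instead drops each boundary
    inside the nearest gene to exercise the any-overlap assignment rule.
    """
    regions: list[tuple[str, GenomicInterval]] = []
    for c in range(spec.n_chrom):
        chrom = f"chr{c + 1}"
        spans = sorted(
            (g.span for g in annotation if g.span.chrom == chrom),
            key=lambda s: s.start,
        )
        gaps = [
            (a.end + b.start) // 2
            for a, b in zip(spans, spans[1:])
            if b.start > a.end
        ]
        mids = [(s.start + s.end) // 2 for s in spans]
        step = spec.chrom_length_bp / spec.n_tads_per_chrom
        bounds = [0]
        for t in range(1, spec.n_tads_per_chrom):
            target = int(t * step)
            anchors = mids if force_straddle else gaps
            snapped = min(anchors, key=lambda g: abs(g - target)) if anchors else target
            if snapped <= bounds[-1]:
                snapped = target
            if snapped > bounds[-1]:
                bounds.append(snapped)
        bounds.append(spec.chrom_length_bp)
        for t in range(len(bounds) - 1):
            regions.append(
                (
                    f"{chrom}_TAD{t + 1}",
                    GenomicInterval(chrom, bounds[t], bounds[t + 1]),
                )
            )
    return TadSet(regions)


def make_expression(spec: FixtureSpec, annotation: GeneAnnotation) -> ExpressionMatrix:
    """Expression on the log scale: unit-variance noise plus planted pairs.

    For each planted (ncRNA a, coding b, rho), gene b's profile is
    rho * standardize(a) + sqrt(1 - rho^2) * fresh noise, so the expected
    Pearson correlation between a and b is rho.
    """
    rng = np.random.default_rng(spec.seed + 1)
    ids = ncrna_ids(spec) + coding_ids(spec)
    values = rng.standard_normal((len(ids), spec.n_samples))
    for i, j, rho in spec.planted_pairs:
        a = values[i]
        a_std = (a - a.mean()) / a.std()
        noise = rng.standard_normal(spec.n_samples)
        values[spec.n_ncrna + j] = rho * a_std + np.sqrt(1 - rho**2) * noise
    samples = [f"S{s:03d}" for s in range(spec.n_samples)]
    present = [g for g in ids if g in annotation]
    mat = ExpressionMatrix(ids, samples, values)
    return mat.subset(present) if len(present) != len(ids) else mat


def make_genesets(
    spec: FixtureSpec,
    annotation: GeneAnnotation,
    pool: Iterable[str],
) -> GeneSetCollection:
    """One planted term enriched for pool genes, plus matched-size decoys.

    The planted term holds ``planted_term_overlap`` genes sampled from the
    pool and an equal number of off-pool fillers. Decoys of the same size
    are sampled uniformly from all coding genes, so their pool overlap
    follows the hypergeometric null.
    """
    rng = np.random.default_rng(spec.seed + 2)
    pool = sorted(set(pool))
    coding = coding_ids(spec)
    if len(pool) < spec.planted_term_overlap:
        raise ValidationError(
            f"pool has {len(pool)} genes but planted_term_overlap is "
            f"{spec.planted_term_overlap}"
        )
    planted_members = list(
        rng.choice(pool, size=spec.planted_term_overlap, replace=False)
    )
    off_pool = sorted(set(coding) - set(pool))
    n_fillers = max(spec.planted_term_overlap, 5 - spec.planted_term_overlap)
    fillers = list(rng.choice(off_pool, size=min(n_fillers, len(off_pool)), replace=False))
    term_size = len(planted_members) + len(fillers)
    terms: dict[str, tuple[str, set[str]]] = {
        "T_PLANTED": ("planted pool-enriched term", set(planted_members) | set(fillers))
    }
    for d in range(spec.n_decoy_terms):
        members = rng.choice(coding, size=term_size, replace=False)
        terms[f"T_DECOY{d:03d}"] = (f"decoy term {d}", set(members))
    return GeneSetCollection(terms, source_label=f"synthetic-seed{spec.seed}")


def make_targets(
    spec: FixtureSpec,
    annotation: GeneAnnotation,
    neighbor_sets: dict[str, set[str]] | None = None,
    keep_fraction: float = 0.6,
) -> TargetTable:
    """Predicted target sets for each ncRNA treated as a miRNA.

    When neighbor sets are supplied, each ncRNA's targets retain roughly
    ``keep_fraction`` of its neighbors plus random off-neighbor coding
    genes; otherwise targets are uniform random coding subsets.
    """
    rng = np.random.default_rng(spec.seed + 3)
    coding = coding_ids(spec)
    targets: dict[str, set[str]] = {}
    for rid in ncrna_ids(spec):
        chosen: set[str] = set()
        if neighbor_sets and neighbor_sets.get(rid):
            for gid in sorted(neighbor_sets[rid]):
                if rng.random() < keep_fraction:
                    chosen.add(gid)
        n_random = int(rng.integers(5, 16))
        chosen |= set(rng.choice(coding, size=n_random, replace=False))
        targets[rid] = chosen
    return TargetTable(targets)


# ---------------------------------------------------------------------------
# plain-text writers (the CLI `simulate` surface)


def _open_w(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def write_gtf(annotation: GeneAnnotation, path: str | Path) -> None:
    """Serialise an annotation as GENCODE-dialect GTF (1-based inclusive)."""
    path = Path(path)
    with _open_w(path) as fh:
        for gene in sorted(annotation, key=lambda g: (g.span.chrom, g.span.start)):
            attrs = (
                f'gene_id "{gene.gene_id}"; gene_name "{gene.symbol}"; '
                f'gene_type "{gene.biotype}";'
            )
            s = gene.span
            fh.write(
                f"{s.chrom}\tcisenrich\tgene\t{s.start + 1}\t{s.end}\t.\t"
                f"{s.strand}\t.\t{attrs}\n"
            )
            for ex in gene.exons:
                fh.write(
                    f"{ex.chrom}\tcisenrich\texon\t{ex.start + 1}\t{ex.end}\t.\t"
                    f"{ex.strand}\t.\t{attrs}\n"
                )


def write_bed(tads: TadSet, path: str | Path) -> None:
    with _open_w(Path(path)) as fh:
        for name, iv in tads.regions:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{name}\n")


def write_gmt(collection: GeneSetCollection, path: str | Path) -> None:
    with _open_w(Path(path)) as fh:
        for term_id in sorted(collection.terms):
            name, genes = collection.terms[term_id]
            fh.write("\t".join([term_id, name, *sorted(genes)]) + "\n")


def write_expression(matrix: ExpressionMatrix, path: str | Path) -> None:
    with _open_w(Path(path)) as fh:
        fh.write("gene_id\t" + "\t".join(matrix.sample_ids) + "\n")
        for gid, row in zip(matrix.gene_ids, matrix.values):
            fh.write(gid + "\t" + "\t".join(f"{v:.6g}" for v in row) + "\n")


def write_targets(targets: TargetTable, path: str | Path) -> None:
    with _open_w(Path(path)) as fh:
        for mirna in sorted(targets.targets):
            for gene in sorted(targets.targets[mirna]):
                fh.write(f"{mirna}\t{gene}\n")


def write_fixture_dir(spec: FixtureSpec, out_dir: str | Path) -> dict[str, Path]:
    """Generate and write a complete fixture set plus a truth manifest."""
    from .neighborhood import SearchConfig, find_cis_neighbors
    from .types import NcrnaSet

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    annotation = make_annotation(spec)
    tads = make_tads(spec, annotation)
    expression = make_expression(spec, annotation)
    ncrnas = NcrnaSet(resolved=[g for g in ncrna_ids(spec) if g in annotation])
    nm = find_cis_neighbors(ncrnas, annotation, SearchConfig())
    genesets = make_genesets(spec, annotation, nm.union_pool)
    targets = make_targets(spec, annotation, nm.per_ncrna)

    paths = {
        "gtf": out / "genome.gtf",
        "tads": out / "tads.bed",
        "expression": out / "expression.tsv",
        "targets": out / "targets.tsv",
        "genesets": out / "genesets.gmt",
        "truth": out / "truth.json",
    }
    write_gtf(annotation, paths["gtf"])
    write_bed(tads, paths["tads"])
    write_expression(expression, paths["expression"])
    write_targets(targets, paths["targets"])
    write_gmt(genesets, paths["genesets"])
    truth = {
        "seed": spec.seed,
        "planted_term": "T_PLANTED",
        "planted_pairs": [list(p) for p in spec.planted_pairs],
        "ncrna_ids": ncrnas.resolved,
        "pool_size": len(nm.union_pool),
    }
    paths["truth"].write_text(json.dumps(truth, indent=2, sort_keys=True) + "\n")
    return paths
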