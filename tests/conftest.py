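import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("reproducible", derandomize=True, deadline=None)
settings.load_profile("reproducible")

from cisenrich.neighborhood import SearchConfig, find_cis_neighbors
from cisenrich.simulate import FixtureSpec, make_annotation, ncrna_ids
from cisenrich.types import (
    GeneAnnotation,
    GeneRecord,
    GenomicInterval,
    NcrnaSet,
)


def gene(gene_id, chrom, start, end, biotype="protein_coding", strand="+",
         symbol=None, exons=None, aliases=None):
    """Terse GeneRecord builder for hand-laid test genomes."""
    exons = [
        GenomicInterval(chrom, e.start, e.end, strand) for e in (exons or [])
    ]
    return GeneRecord(
        gene_id=gene_id,
        symbol=symbol or gene_id.lower(),
        biotype=biotype,
        span=GenomicInterval(chrom, start, end, strand),
        exons=exons,
        aliases=aliases or set(),
    )


@pytest.fixture
def tiny_annotation():
    """Two ncRNAs and four coding genes on two chromosomes.

    Layout (chr1): NC1 100k-101k, CGA 105k-106k (4 kb gap),
    CGB 120k-121k (19 kb gap), NC2 300k-301k, CGC 302k-310k.
    CGD sits alone on chr2.
    """
    return GeneAnnotation(
        [
            gene("NC1", "chr1", 100_000, 101_000, biotype="lincRNA", symbol="LINC1"),
            gene("CGA", "chr1", 105_000, 106_000),
            gene("CGB", "chr1", 120_000, 121_000),
            gene("NC2", "chr1", 300_000, 301_000, biotype="miRNA", symbol="MIR2",
                 strand="-"),
            gene(
                "CGC", "chr1", 302_000, 310_000,
                exons=[
                    GenomicInterval("chr1", 302_000, 303_000, "+"),
                    GenomicInterval("chr1", 308_000, 310_000, "+"),
                ],
            ),
            gene("CGD", "chr2", 100_000, 101_000),
        ]
    )


@pytest.fixture
def tiny_ncrnas():
    return NcrnaSet(resolved=["NC1", "NC2"])


@pytest.fixture
def tiny_neighbors(tiny_annotation, tiny_ncrnas):
    return find_cis_neighbors(tiny_ncrnas, tiny_annotation, SearchConfig())


def fixture_ncrna_set(spec: FixtureSpec, annotation) -> NcrnaSet:
    return NcrnaSet(resolved=[g for g in ncrna_ids(spec) if g in annotation])


@pytest.fixture
def default_fixture():
    spec = FixtureSpec(seed=11)
    annotation = make_annotation(spec)
    ncrnas = fixture_ncrna_set(spec, annotation)
    nm = find_cis_neighbors(ncrnas, annotation, SearchConfig())
    return spec, annotation, ncrnas, nm


@pytest.fixture
def rng():
    return np.random.default_rng(42)
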