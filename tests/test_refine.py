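"""Pool refinement: expression prefilter, correlation, TAD/target/biotype."""

import math

import numpy as np
import pytest

from cisenrich.errors import DataError, ValidationError
from cisenrich.neighborhood import EXPANSION_KEY, NeighborMap, SearchConfig, find_cis_neighbors
from cisenrich.refine import (
    CoexpressionConfig,
    apply_coexpression,
    assign_tads,
    compute_coexpression,
    filter_biotype,
    filter_by_tad,
    filter_by_targets,
    prefilter_expression,
)
from cisenrich.simulate import (
    FixtureSpec,
    make_annotation,
    make_expression,
    make_tads,
    make_targets,
    ncrna_ids,
)
from cisenrich.types import (
    ExpressionMatrix,
    GenomicInterval,
    NcrnaSet,
    TadSet,
    TargetTable,
)

from .conftest import fixture_ncrna_set
from .oracles import pearson_scalar


def matrix(genes, values):
    values = np.asarray(values, dtype=float)
    samples = [f"S{i}" for i in range(values.shape[1])]
    return ExpressionMatrix(genes, samples, values)


class TestPrefilterExpression:
    def test_constant_gene_dropped_by_default_variance_cutoff(self):
        mat = matrix(["flat", "varying"], [[5] * 6, [0, 1, 0, 1, 0, 1]])
        out = prefilter_expression(mat, CoexpressionConfig())
        assert out.gene_ids == ["varying"]

    def test_alternating_gene_survives_default_cutoff(self):
        mat = matrix(["g"], [[0, 1] * 5])
        assert prefilter_expression(mat, CoexpressionConfig()).gene_ids == ["g"]

    def test_low_expression_rule_drops_mostly_silent_gene(self):
        # below 0.05 in 9 of 10 samples, i.e. more than 20% of samples
        quiet = [0.01] * 9 + [1.0]
        loud = [1.0, 2.0] * 5
        mat = matrix(["quiet", "loud"], [quiet, loud])
        cfg = CoexpressionConfig(low_expr_value=0.05, low_expr_fraction=0.2)
        assert prefilter_expression(mat, cfg).gene_ids == ["loud"]

    def test_mad_cutoff_drops_low_dispersion_gene(self):
        tight = [10.0, 10.1, 9.9, 10.0, 10.05, 9.95]
        wide = [1.0, 5.0, 9.0, 2.0, 8.0, 3.0]
        mat = matrix(["tight", "wide"], [tight, wide])
        cfg = CoexpressionConfig(mad_cutoff=0.5)
        assert prefilter_expression(mat, cfg).gene_ids == ["wide"]

    def test_log2_transform_applied_before_variance(self):
        mat = matrix(["g"], [[0, 3, 0, 3, 0, 3]])
        out = prefilter_expression(mat, CoexpressionConfig(log2_transform=True))
        assert np.allclose(out.row("g"), np.log2(np.array([0, 3, 0, 3, 0, 3]) + 1))

    def test_removing_every_gene_is_hard_error(self):
        mat = matrix(["flat"], [[1] * 5])
        with pytest.raises(DataError):
            prefilter_expression(mat, CoexpressionConfig())


class TestComputeCoexpression:
    def test_identical_vectors_give_coefficient_one(self, rng):
        x = rng.normal(size=20)
        mat = matrix(["a", "b"], [x, x.copy()])
        edges = compute_coexpression(mat, {"a"}, {"b"})
        assert len(edges) == 1
        assert edges[0].coefficient == pytest.approx(1.0)

    def test_anticorrelated_pair_sign_rules(self, rng):
        x = rng.normal(size=20)
        mat = matrix(["a", "b"], [x, -x])
        kept_abs = compute_coexpression(
            mat, {"a"}, {"b"}, CoexpressionConfig(coefficient_rule="absolute")
        )
        kept_pos = compute_coexpression(
            mat, {"a"}, {"b"}, CoexpressionConfig(coefficient_rule="positive")
        )
        assert kept_abs[0].coefficient == pytest.approx(-1.0)
        assert kept_pos == []

    def test_pearson_matches_textbook_scalar_formula(self):
        x = [1.2, 3.4, 2.2, 5.6, 4.1, 0.3, 2.9, 7.7, 6.0, 1.1]
        y = [2.0, 3.1, 2.5, 6.0, 3.9, 1.0, 3.3, 7.2, 5.5, 2.2]
        mat = matrix(["a", "b"], [x, y])
        cfg = CoexpressionConfig(coefficient_cutoff=0.0, p_cutoff=1.0)
        edge = compute_coexpression(mat, {"a"}, {"b"}, cfg)[0]
        assert edge.coefficient == pytest.approx(pearson_scalar(x, y), abs=1e-12)

    def test_pearson_ci_brackets_coefficient(self, rng):
        x = rng.normal(size=30)
        y = 0.7 * x + rng.normal(size=30)
        mat = matrix(["a", "b"], [x, y])
        cfg = CoexpressionConfig(coefficient_cutoff=0.0, p_cutoff=1.0)
        edge = compute_coexpression(mat, {"a"}, {"b"}, cfg)[0]
        assert edge.ci_low <= edge.coefficient <= edge.ci_high

    @pytest.mark.parametrize("method", ["spearman", "kendall"])
    def test_rank_methods_detect_monotone_association(self, method, rng):
        x = rng.normal(size=40)
        y = np.exp(x)  # monotone, nonlinear
        mat = matrix(["a", "b"], [x, y])
        edges = compute_coexpression(
            mat, {"a"}, {"b"}, CoexpressionConfig(method=method)
        )
        assert len(edges) == 1
        assert edges[0].coefficient == pytest.approx(1.0)

    def test_too_few_samples_is_error(self):
        mat = matrix(["a", "b"], [[1, 2], [2, 1]])
        with pytest.raises(DataError):
            compute_coexpression(mat, {"a"}, {"b"})

    def test_fisher_ci_covers_generating_rho_at_nominal_rate(self):
        """Nominal 95% Fisher-z CI covers rho=0.6 within Monte-Carlo error."""
        rho, n, reps = 0.6, 50, 400
        rng = np.random.default_rng(7)
        cfg = CoexpressionConfig(coefficient_cutoff=0.0, p_cutoff=1.0)
        covered = 0
        for _ in range(reps):
            x = rng.standard_normal(n)
            y = rho * x + math.sqrt(1 - rho**2) * rng.standard_normal(n)
            edge = compute_coexpression(matrix(["a", "b"], [x, y]), {"a"}, {"b"}, cfg)[0]
            covered += edge.ci_low <= rho <= edge.ci_high
        # 3 sigma Monte-Carlo band around 0.95
        se = math.sqrt(0.95 * 0.05 / reps)
        assert abs(covered / reps - 0.95) < 3 * se + 1e-9


class TestApplyCoexpression:
    def make_nm(self):
        return NeighborMap(per_ncrna={"r1": {"G1", "G2"}, "r2": {"G3"}})

    def edge(self, a, b, coef=0.9):
        from cisenrich.refine import CoexpressionEdge

        return CoexpressionEdge(a, b, coef, 0.001, n_samples=10)

    def test_filter_with_no_edges_empties_every_set(self):
        out = apply_coexpression(self.make_nm(), [], mode="filter")
        assert all(not ci for ci in out.per_ncrna.values())

    def test_expand_adds_new_gene_to_union_pool(self):
        out = apply_coexpression(self.make_nm(), [self.edge("r1", "G_new")], "expand")
        assert "G_new" in out.union_pool
        assert out.per_ncrna["r1"] == {"G1", "G2"}  # per-ncRNA sets unchanged
        assert out.per_ncrna[EXPANSION_KEY] == {"G_new"}

    def test_filter_result_contained_in_expand_result(self):
        edges = [self.edge("r1", "G1"), self.edge("r2", "G_new")]
        filtered = apply_coexpression(self.make_nm(), edges, "filter")
        expanded = apply_coexpression(self.make_nm(), edges, "expand")
        assert filtered.union_pool <= expanded.union_pool

    def test_union_invariant_maintained(self):
        out = apply_coexpression(self.make_nm(), [self.edge("r1", "G_new")], "expand")
        assert out.union_pool == set().union(*out.per_ncrna.values())


class TestFilterByTad:
    def tad(self, name, chrom, start, end):
        return (name, GenomicInterval(chrom, start, end))

    def test_shared_tad_keeps_gene(self, tiny_annotation, tiny_neighbors):
        tads = TadSet([self.tad("TAD_A", "chr1", 90_000, 110_000)])
        out = filter_by_tad(tiny_neighbors, tiny_annotation, tads)
        assert "CGA" in out.per_ncrna["NC1"]

    def test_different_tad_removes_gene(self, tiny_annotation, tiny_neighbors):
        tads = TadSet(
            [
                self.tad("TAD_A", "chr1", 90_000, 104_000),
                self.tad("TAD_B", "chr1", 104_000, 130_000),
            ]
        )
        out = filter_by_tad(tiny_neighbors, tiny_annotation, tads)
        assert "CGA" not in out.per_ncrna["NC1"]

    def test_ncrna_outside_all_tads_loses_neighbors(
        self, tiny_annotation, tiny_neighbors
    ):
        tads = TadSet([self.tad("TAD_Z", "chr2", 0, 500_000)])
        out = filter_by_tad(tiny_neighbors, tiny_annotation, tads)
        assert out.per_ncrna["NC1"] == set()
        assert out.per_ncrna["NC2"] == set()

    def test_boundary_straddling_gene_kept_by_any_overlap(
        self, tiny_annotation, tiny_neighbors
    ):
        # boundary at 105,500 cuts CGA (105k-106k); NC1 sits in the left TAD
        tads = TadSet(
            [
                self.tad("TAD_A", "chr1", 90_000, 105_500),
                self.tad("TAD_B", "chr1", 105_500, 130_000),
            ]
        )
        out = filter_by_tad(tiny_neighbors, tiny_annotation, tads)
        assert "CGA" in out.per_ncrna["NC1"]
        # cross-check assignment against a direct enumeration
        membership = assign_tads(["NC1", "CGA"], tiny_annotation, tads)
        assert membership["CGA"] == {"TAD_A", "TAD_B"}
        assert membership["NC1"] == {"TAD_A"}


class TestFilterByTargets:
    def test_intersection_with_target_set(self):
        nm = NeighborMap(per_ncrna={"mir-9": {"G1", "G2"}})
        out = filter_by_targets(nm, TargetTable({"MIR-9": {"G2", "G3"}}))
        assert out.per_ncrna["mir-9"] == {"G2"}

    def test_missing_mirna_empties_its_set(self):
        nm = NeighborMap(per_ncrna={"mir-9": {"G1"}})
        out = filter_by_targets(nm, TargetTable({"mir-10": {"G1"}}))
        assert out.per_ncrna["mir-9"] == set()

    def test_species_prefix_stripping(self):
        nm = NeighborMap(per_ncrna={"MIR-21": {"G1", "G2"}})
        table = TargetTable({"hsa-miR-21": {"G1"}})
        assert filter_by_targets(nm, table).per_ncrna["MIR-21"] == set()
        out = filter_by_targets(nm, table, strip_species_prefix=True)
        assert out.per_ncrna["MIR-21"] == {"G1"}


class TestFilterBiotype:
    def test_keep_retains_only_named_biotypes(self, tiny_annotation):
        nc = NcrnaSet(resolved=["NC1", "NC2"])
        out = filter_biotype(nc, tiny_annotation, {"lincRNA"}, "keep")
        assert out.resolved == ["NC1"]

    def test_exclude_is_the_complement(self, tiny_annotation):
        nc = NcrnaSet(resolved=["NC1", "NC2"])
        out = filter_biotype(nc, tiny_annotation, {"lincRNA"}, "exclude")
        assert out.resolved == ["NC2"]

    def test_keep_then_exclude_same_biotypes_is_empty_error(self, tiny_annotation):
        nc = NcrnaSet(resolved=["NC1", "NC2"])
        kept = filter_biotype(nc, tiny_annotation, {"lincRNA"}, "keep")
        with pytest.raises(DataError):
            filter_biotype(kept, tiny_annotation, {"lincRNA"}, "exclude")


class TestFilterAlgebra:
    """Subset/superset and commutation laws on seeded random fixtures."""

    @pytest.mark.parametrize("seed", range(5))
    def test_every_filter_is_a_subset_map(self, seed):
        spec = FixtureSpec(seed=seed)
        ann = make_annotation(spec)
        ncrnas = fixture_ncrna_set(spec, ann)
        nm = find_cis_neighbors(
            ncrnas, ann, SearchConfig(upstream_bp=50_000, downstream_bp=50_000)
        )
        tads = make_tads(spec, ann)
        targets = make_targets(spec, ann, nm.per_ncrna)
        for out in (
            filter_by_tad(nm, ann, tads),
            filter_by_targets(nm, targets),
        ):
            for rid in nm.ncrna_ids:
                assert out.per_ncrna[rid] <= nm.per_ncrna[rid]
            assert out.union_pool <= nm.union_pool

    @pytest.mark.parametrize("seed", range(5))
    def test_tad_and_target_filters_commute(self, seed):
        spec = FixtureSpec(seed=seed)
        ann = make_annotation(spec)
        ncrnas = fixture_ncrna_set(spec, ann)
        nm = find_cis_neighbors(
            ncrnas, ann, SearchConfig(upstream_bp=50_000, downstream_bp=50_000)
        )
        tads = make_tads(spec, ann)
        targets = make_targets(spec, ann, nm.per_ncrna)
        ab = filter_by_targets(filter_by_tad(nm, ann, tads), targets)
        ba = filter_by_tad(filter_by_targets(nm, targets), ann, tads)
        assert ab.per_ncrna == ba.per_ncrna

    def test_expand_is_a_superset_map(self):
        spec = FixtureSpec(seed=9, planted_pairs=((0, 0, 0.9), (1, 1, 0.9)))
        ann = make_annotation(spec)
        ncrnas = fixture_ncrna_set(spec, ann)
        nm = find_cis_neighbors(ncrnas, ann, SearchConfig())
        mat = make_expression(spec, ann)
        edges = compute_coexpression(
            mat, set(ncrna_ids(spec)), set(mat.gene_ids) - set(ncrna_ids(spec))
        )
        out = apply_coexpression(nm, edges, "expand")
        assert out.union_pool >= nm.union_pool
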