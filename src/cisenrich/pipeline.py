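"""End-to-end pipeline composition with a reproducible run manifest.

Stage order: resolve -> biotype filter -> neighbors -> TAD filter ->
co-expression -> target filter -> enrich -> report. Optional stages are
true no-ops when disabled. All outputs are deterministic functions of the
configuration and seed; a failed run removes whatever it had written.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path

from . import __version__
from .config import PipelineConfig
from .enrich import enrich
from .errors import CisEnrichError
from .io import (
    read_alias_table,
    read_bed,
    read_expression,
    read_gene_list,
    read_gmt,
    read_gtf,
    read_target_table,
    resolve_ids,
)
from .neighborhood import find_cis_neighbors, neighbor_distances
from .refine import (
    apply_coexpression,
    compute_coexpression,
    filter_biotype,
    filter_by_tad,
    filter_by_targets,
    prefilter_expression,
)
from .report import build_term_network, rank_and_select, write_outputs

logger = logging.getLogger(__name__)


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute the configured pipeline; return the run manifest.

    The manifest records the configuration, seed, per-stage gene counts
    and package version, and is written as ``manifest.json`` next to the
    tabular outputs.
    """
    logging.getLogger("cisenrich").setLevel(cfg.log_level)
    stage_counts: dict[str, dict] = {}
    written: list[Path] = []
    try:
        annotation = read_gtf(cfg.gtf_path, coding_biotypes=cfg.search.coding_biotypes)
        tokens = read_gene_list(cfg.input_path)
        alias = read_alias_table(cfg.alias_table) if cfg.alias_table else None
        ncrnas = resolve_ids(tokens, annotation, alias)
        stage_counts["resolve"] = {
            "input_tokens": len(tokens),
            "resolved": len(ncrnas.resolved),
            "unresolved": len(ncrnas.unresolved),
        }

        if cfg.biotypes:
            ncrnas = filter_biotype(ncrnas, annotation, cfg.biotypes, cfg.biotype_mode)
            stage_counts["biotype"] = {"resolved": len(ncrnas.resolved)}

        nm = find_cis_neighbors(ncrnas, annotation, cfg.search)
        stage_counts["neighbors"] = {
            "pool": len(nm.union_pool),
            "per_ncrna": nm.counts(),
        }

        if cfg.tad_path:
            nm = filter_by_tad(nm, annotation, read_bed(cfg.tad_path))
            stage_counts["tad"] = {"pool": len(nm.union_pool), "per_ncrna": nm.counts()}

        if cfg.expression_path:
            matrix = prefilter_expression(
                read_expression(cfg.expression_path), cfg.coexpression
            )
            edges = compute_coexpression(
                matrix, set(nm.ncrna_ids),
                set(nm.union_pool) if cfg.coexpression_mode == "filter"
                else {g for g in matrix.gene_ids if g in annotation
                      and annotation.biotype_of(g) in cfg.search.coding_biotypes},
                cfg.coexpression,
            )
            nm = apply_coexpression(nm, edges, cfg.coexpression_mode)
            stage_counts["coexpression"] = {
                "edges": len(edges),
                "pool": len(nm.union_pool),
                "per_ncrna": nm.counts(),
            }

        if cfg.targets_path:
            nm = filter_by_targets(
                nm, read_target_table(cfg.targets_path), cfg.strip_species_prefix
            )
            stage_counts["targets"] = {
                "pool": len(nm.union_pool),
                "per_ncrna": nm.counts(),
            }

        collection = read_gmt(cfg.genesets_path)
        enr_cfg = cfg.enrich
        if cfg.background_path:
            from dataclasses import replace

            enr_cfg = replace(
                enr_cfg, background=frozenset(read_gene_list(cfg.background_path))
            )
        rows = enrich(nm, collection, enr_cfg)
        stage_counts["enrichment"] = {
            "terms_tested": len(rows),
            "terms_padj_lt_0.05": sum(r.p_adjusted < 0.05 for r in rows),
        }

        ranked = rank_and_select(rows, by=cfg.rank_by, top_n=cfg.top_n)
        network = build_term_network(ranked, nm) if ranked else None
        out = write_outputs(ranked, network, cfg.output_dir, graphml=cfg.graphml)
        written = list(out.values())

        nb_path = cfg.output_dir / "neighbors.tsv"
        with open(nb_path, "w") as fh:
            fh.write("ncRNA_id\tneighbor_gene_id\tdistance_bp\n")
            for rid, gid, dist in neighbor_distances(nm, annotation):
                fh.write(f"{rid}\t{gid}\t{dist}\n")
        written.append(nb_path)

        manifest = {
            "version": __version__,
            "seed": cfg.seed,
            "config": {
                "input": str(cfg.input_path),
                "gtf": str(cfg.gtf_path),
                "genesets": str(cfg.genesets_path),
                "tad": str(cfg.tad_path) if cfg.tad_path else None,
                "expression": str(cfg.expression_path) if cfg.expression_path else None,
                "coexpression_mode": cfg.coexpression_mode if cfg.expression_path else None,
                "targets": str(cfg.targets_path) if cfg.targets_path else None,
                "biotypes": sorted(cfg.biotypes) if cfg.biotypes else None,
                "test": cfg.enrich.test,
                "min_set_size": cfg.enrich.min_set_size,
                "padj_method": cfg.enrich.padj_method,
                "upstream_bp": cfg.search.upstream_bp,
                "downstream_bp": cfg.search.downstream_bp,
                "strand_aware": cfg.search.strand_aware,
                "region_mode": cfg.search.region_mode,
            },
            "stages": stage_counts,
        }
        manifest_path = cfg.output_dir / "manifest.json"
        manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
        written.append(manifest_path)
        return manifest
    except CisEnrichError:
        for path in written:
            try:
                path.unlink()
            except OSError:
                pass
        raise
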