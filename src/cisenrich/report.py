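"""Ranking, tabulation and network views of enrichment results.

The term-gene network is bipartite at its core (term <-> overlap gene),
extended with gene <-> ncRNA edges taken from the neighbor map, and
partitioned with greedy modularity maximisation.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import networkx as nx
import pandas as pd

from .enrich import EnrichmentRow
from .errors import ValidationError
from .neighborhood import NeighborMap

RANK_KEYS = ("pval", "padj")

ENRICHMENT_COLUMNS = [
    "term_id",
    "term_name",
    "p_value",
    "p_adjusted",
    "GeneRatio",
    "BGRatio",
    "EGNo",
    "overlap_genes",
    "ncGeneList",
]


@dataclass
class TermNetwork:
    """Graph of terms, genes and ncRNAs with a modularity partition."""

    graph: nx.Graph
    clusters: dict[str, int]

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def degree(self, node: str) -> int:
        return self.graph.degree(node)

    def node_type(self, node: str) -> str:
        return self.graph.nodes[node]["kind"]


def _rank_key(row: EnrichmentRow, by: str) -> tuple:
    p = row.p_value if by == "pval" else row.p_adjusted
    return (p, -row.counts.k, row.term_id)


def rank_and_select(
    rows: list[EnrichmentRow], by: str = "padj", top_n: Optional[int] = None
) -> list[EnrichmentRow]:
    """Stable ascending sort by p or adjusted p; ties break by k desc, term asc."""
    if by not in RANK_KEYS:
        raise ValidationError(f"rank key must be one of {RANK_KEYS}, got {by!r}")
    if top_n is not None and top_n < 1:
        raise ValidationError("top_n must be >= 1")
    ranked = sorted(rows, key=lambda r: _rank_key(r, by))
    return ranked if top_n is None else ranked[:top_n]


def dotplot_data(
    rows: list[EnrichmentRow], by: str = "padj", top_n: Optional[int] = None
) -> pd.DataFrame:
    """Table behind the dot plot: term, chosen p metric, overlap size."""
    ranked = rank_and_select(rows, by=by, top_n=top_n)
    metric = "p_value" if by == "pval" else "p_adjusted"
    return pd.DataFrame(
        [
            {
                "term_name": r.term_name,
                metric: r.p_value if by == "pval" else r.p_adjusted,
                "EGNo": r.counts.k,
            }
            for r in ranked
        ],
        columns=["term_name", metric, "EGNo"],
    )


def render_dotplot(rows: list[EnrichmentRow], path: str | Path, by: str = "padj",
                   top_n: Optional[int] = None) -> None:
    """Optional rendering of the dot-plot table to an image file."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = dotplot_data(rows, by=by, top_n=top_n)
    metric = df.columns[1]
    fig, ax = plt.subplots(figsize=(6, max(2, 0.4 * len(df))))
    y = range(len(df))[::-1]
    sizes = [30 + 20 * k for k in df["EGNo"]]
    colors = [-math.log10(max(p, 1e-300)) for p in df[metric]]
    sc = ax.scatter(df[metric], list(y), s=sizes, c=colors, cmap="viridis")
    ax.set_yticks(list(y))
    ax.set_yticklabels(df["term_name"])
    ax.set_xlabel(metric)
    fig.colorbar(sc, ax=ax, label=f"-log10({metric})")
    fig.tight_layout()
    fig.savefig(path)
    plt.close(fig)


def build_term_network(rows: list[EnrichmentRow], nm: NeighborMap) -> TermNetwork:
    """Bipartite term-gene edges plus gene-ncRNA edges, modularity-clustered.

    Clustering uses greedy modularity maximisation, which is deterministic
    for a fixed node insertion order; nodes are inserted sorted so repeated
    builds agree. Cluster labels are assigned in sorted-community order.
    """
    g = nx.Graph()
    for row in sorted(rows, key=lambda r: r.term_id):
        g.add_node(row.term_id, kind="term")
        for gene in sorted(row.overlap_genes):
            g.add_node(gene, kind="gene")
            g.add_edge(row.term_id, gene)
    overlap_union = set().union(*(r.overlap_genes for r in rows)) if rows else set()
    for rid in sorted(nm.ncrna_ids):
        linked = sorted(nm.per_ncrna[rid] & overlap_union)
        for gene in linked:
            g.add_node(rid, kind="ncrna")
            g.add_edge(gene, rid)
    if g.number_of_nodes() == 0:
        return TermNetwork(graph=g, clusters={})
    communities = nx.community.greedy_modularity_communities(g)
    clusters: dict[str, int] = {}
    for label, members in enumerate(sorted(communities, key=lambda s: sorted(s)[0])):
        for node in members:
            clusters[node] = label
    return TermNetwork(graph=g, clusters=clusters)


def enrichment_table(rows: list[EnrichmentRow]) -> pd.DataFrame:
    """Enrichment results as a DataFrame in the contracted column order."""
    records = []
    for r in rows:
        records.append(
            {
                "term_id": r.term_id,
                "term_name": r.term_name,
                "p_value": r.p_value,
                "p_adjusted": r.p_adjusted,
                "GeneRatio": r.counts.gene_ratio,
                "BGRatio": r.counts.bg_ratio,
                "EGNo": r.counts.k,
                "overlap_genes": ";".join(sorted(r.overlap_genes)),
                "ncGeneList": ";".join(sorted(r.contributing_ncrnas)),
            }
        )
    return pd.DataFrame(records, columns=ENRICHMENT_COLUMNS)


def read_enrichment_table(path: str | Path) -> pd.DataFrame:
    """Re-parse a written enrichment TSV (round-trip inverse of write)."""
    return pd.read_csv(path, sep="\t", dtype={"GeneRatio": str, "BGRatio": str})


def write_outputs(
    rows: list[EnrichmentRow],
    network: Optional[TermNetwork],
    out_dir: str | Path,
    graphml: bool = False,
) -> dict[str, Path]:
    """Write the enrichment TSV and network edge/node TSVs into ``out_dir``."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    written: dict[str, Path] = {}

    enr_path = out_dir / "enrichment.tsv"
    enrichment_table(rows).to_csv(enr_path, sep="\t", index=False, float_format="%.6g")
    written["enrichment"] = enr_path

    if network is not None:
        edge_path = out_dir / "network_edges.tsv"
        with open(edge_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["source", "target", "edge_type"])
            for a, b in sorted(network.graph.edges):
                kinds = {network.node_type(a), network.node_type(b)}
                etype = "term-gene" if "term" in kinds else "gene-ncrna"
                w.writerow([a, b, etype])
        written["edges"] = edge_path

        node_path = out_dir / "network_nodes.tsv"
        with open(node_path, "w", newline="") as fh:
            w = csv.writer(fh, delimiter="\t", lineterminator="\n")
            w.writerow(["node", "type", "degree", "cluster"])
            for node in sorted(network.nodes):
                w.writerow(
                    [node, network.node_type(node), network.degree(node),
                     network.clusters.get(node, -1)]
                )
        written["nodes"] = node_path

        if graphml:
            gm_path = out_dir / "network.graphml"
            g = network.graph.copy()
            for node, label in network.clusters.items():
                g.nodes[node]["cluster"] = label
            nx.write_graphml(g, gm_path)
            written["graphml"] = gm_path

    return written
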