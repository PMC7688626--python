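"""Tripartite miRNA-gene-pathway network and the count-score screen.

The tripartite network links DE miRNAs to their filtered overlap targets and
those targets to the selected pathways containing them.  The count-score of a
(miRNA, pathway) pair is the number of genes the two share through the
network; pairs with count-score >= 2 (inclusive) form the bipartite
miRNA-pathway network, whose nodes are ranked by connectivity degree (plain
edge count — the count-score stays on the edge as a weight attribute).
"""

from __future__ import annotations

from typing import NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .de import DETable
from .enrich import EnrichmentRecord
from .io import PathwayCatalog, TargetTable
from .targets import OverlapGeneSet

__all__ = [
    "NetworkCounts",
    "build_tripartite",
    "network_counts",
    "count_scores",
    "pairs_to_frame",
    "build_mirna_pathway_network",
    "rank_nodes",
]


class NetworkCounts(NamedTuple):
    n_genes: int
    n_mirnas: int
    n_pathways: int
    n_edges: int


def build_tripartite(
    de_mirnas: DETable,
    targets: TargetTable,
    overlap: OverlapGeneSet,
    selected: Sequence[EnrichmentRecord],
    catalog: PathwayCatalog,
) -> nx.DiGraph:
    """Directed typed graph: miRNA -> gene (target) -> pathway (membership).

    Gene -> pathway edges exist only for overlap genes inside selected
    pathways; gene nodes lacking either a miRNA edge or a pathway edge are
    pruned (and miRNA nodes left edgeless with them).  All selected pathways
    appear as nodes, even when no overlap gene reaches them.  ``targets``
    must already be binding-filtered.
    """
    g = nx.DiGraph()
    selected_ids = [r.pathway_id for r in selected]
    activity = {r.pathway_id: r.activity for r in selected}
    for pid in selected_ids:
        g.add_node(pid, type="pathway", regulation=activity[pid])

    de_mirna_ids = set(de_mirnas.de_ids)
    # gene -> pathway membership restricted to selected pathways
    for gene, rec in overlap.genes.items():
        member_of = [pid for pid in selected_ids if gene in catalog.sets[pid]]
        if not member_of:
            continue  # prune: no pathway edge
        targeting = rec.mirnas & de_mirna_ids
        # keep only target-table-supported miRNA edges (overlap annotations
        # are built from the same filtered table, so this is a consistency
        # guard rather than a second filter)
        targeting = {
            m for m in targeting if gene in targets.targets_of(m)
        }
        if not targeting:
            continue  # prune: no miRNA edge
        g.add_node(gene, type="gene", regulation="up" if rec.direction > 0 else "down")
        for m in sorted(targeting):
            if m not in g:
                call = de_mirnas.table.at[m, "call"]
                g.add_node(m, type="mirna", regulation=call)
            g.add_edge(m, gene)
        for pid in member_of:
            g.add_edge(gene, pid)
    return g


def network_counts(network: nx.DiGraph) -> NetworkCounts:
    """Node counts by type plus the edge count; total nodes = sum of types."""
    kinds = nx.get_node_attributes(network, "type")
    return NetworkCounts(
        n_genes=sum(1 for t in kinds.values() if t == "gene"),
        n_mirnas=sum(1 for t in kinds.values() if t == "mirna"),
        n_pathways=sum(1 for t in kinds.values() if t == "pathway"),
        n_edges=network.number_of_edges(),
    )


def count_scores(network: nx.DiGraph) -> pd.DataFrame:
    """Count-score per (miRNA, pathway) pair: shared genes through the network.

    count_score(m, P) = |{g : m -> g and g -> P}|; only pairs with score >= 1
    are emitted.  Sorted by miRNA then pathway id.
    """
    kinds = nx.get_node_attributes(network, "type")
    rows = []
    for m in sorted(n for n, t in kinds.items() if t == "mirna"):
        pathway_hits: dict[str, int] = {}
        for gene in network.successors(m):
            for pid in network.successors(gene):
                pathway_hits[pid] = pathway_hits.get(pid, 0) + 1
        for pid in sorted(pathway_hits):
            rows.append((m, pid, pathway_hits[pid]))
    return pd.DataFrame(rows, columns=["mirna_id", "pathway_id", "count_score"])


def pairs_to_frame(pairs) -> pd.DataFrame:
    """Coerce an iterable of (mirna, pathway[, count]) into a PairSet frame."""
    if isinstance(pairs, pd.DataFrame):
        return pairs
    rows = []
    for rec in pairs:
        if len(rec) == 2:
            rows.append((rec[0], rec[1], 1))
        else:
            rows.append(tuple(rec[:3]))
    return pd.DataFrame(rows, columns=["mirna_id", "pathway_id", "count_score"])


def build_mirna_pathway_network(
    pairs: pd.DataFrame,
    min_count: int = 2,
    mirna_regulation: dict[str, str] | None = None,
    pathway_activity: dict[str, str] | None = None,
) -> nx.Graph:
    """Bipartite miRNA-pathway network from pairs with count-score >= min_count.

    The threshold is inclusive.  Isolated nodes are absent; count-score is
    kept as the ``count_score`` edge attribute.  Optional regulation /
    activity maps annotate the surviving nodes.
    """
    pairs = pairs_to_frame(pairs)
    g = nx.Graph()
    kept = pairs[pairs["count_score"] >= min_count]
    for row in kept.itertuples(index=False):
        g.add_node(row.mirna_id, type="mirna", bipartite=0)
        g.add_node(row.pathway_id, type="pathway", bipartite=1)
        g.add_edge(row.mirna_id, row.pathway_id, count_score=int(row.count_score))
    if mirna_regulation:
        for n, d in g.nodes(data=True):
            if d["type"] == "mirna" and n in mirna_regulation:
                g.nodes[n]["regulation"] = mirna_regulation[n]
    if pathway_activity:
        for n, d in g.nodes(data=True):
            if d["type"] == "pathway" and n in pathway_activity:
                g.nodes[n]["regulation"] = pathway_activity[n]
    return g


def rank_nodes(
    network: nx.Graph, top_n: int = 10
) -> tuple[list[tuple[str, int]], list[tuple[str, int]]]:
    """Top miRNAs and pathways by connectivity degree.

    Each list is sorted by degree descending, ties broken by id; degree is
    the unweighted count of incident edges.
    """
    kinds = nx.get_node_attributes(network, "type")
    mirnas = [(n, network.degree(n)) for n, t in kinds.items() if t == "mirna"]
    pathways = [(n, network.degree(n)) for n, t in kinds.items() if t == "pathway"]
    key = lambda item: (-item[1], item[0])  # noqa: E731
    return sorted(mirnas, key=key)[:top_n], sorted(pathways, key=key)[:top_n]
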