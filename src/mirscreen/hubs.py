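"""Hub-miRNA screening across the two comparisons.

miRNA-pathway pairs surviving the count-score threshold in both the
disease-vs-control and treated-vs-disease networks are intersected by
(miRNA, pathway) identity; the intersected edges form the hub network, whose
nodes carry a two-comparison regulation pattern (e.g. ``down_up`` = down in
disease, up after treatment).  Hub miRNAs are selected by connectivity degree
(default >= 3) and, by default, a reversal pattern — the signature of a
feature suppressed by disease and restored by treatment or vice versa.
Degrees are recomputed from the intersected edge set itself.
"""

from __future__ import annotations

from typing import Mapping, NamedTuple, Sequence

import networkx as nx
import pandas as pd

from .de import DETable
from .exceptions import DataError
from .network import pairs_to_frame

__all__ = [
    "HubSelection",
    "intersect_pairs",
    "mirna_pattern",
    "pathway_pattern",
    "build_hub_network",
    "select_validation_mirnas",
]

REVERSAL_PATTERNS = ("down_up", "up_down")


class HubSelection(NamedTuple):
    mirna_id: str
    degree: int
    pattern: str


def intersect_pairs(pairs_a, pairs_b) -> list[tuple[str, str]]:
    """Exact (mirna, pathway) identity intersection of two pair sets.

    Count-scores are ignored; inputs may be PairSet frames, graphs, or plain
    iterables of pairs.  Result sorted by miRNA then pathway id.
    """
    set_a = _as_pair_set(pairs_a)
    set_b = _as_pair_set(pairs_b)
    return sorted(set_a & set_b)


def _as_pair_set(pairs) -> set[tuple[str, str]]:
    if isinstance(pairs, nx.Graph):
        kinds = nx.get_node_attributes(pairs, "type")
        out = set()
        for u, v in pairs.edges:
            if kinds.get(u) == "mirna":
                out.add((u, v))
            else:
                out.add((v, u))
        return out
    if isinstance(pairs, pd.DataFrame):
        return {(r.mirna_id, r.pathway_id) for r in pairs.itertuples(index=False)}
    return {(m, p) for m, p, *_ in (tuple(rec) for rec in pairs)}


def mirna_pattern(mirna_id: str, de_a: DETable, de_b: DETable) -> str:
    """Two-comparison pattern from DE calls, e.g. ``down_up``."""
    parts = []
    for de in (de_a, de_b):
        if mirna_id not in de.table.index:
            raise DataError(f"miRNA missing from {de.comparison}: {mirna_id!r}")
        call = de.table.at[mirna_id, "call"]
        parts.append(call if call in ("up", "down") else "ns")
    return "_".join(parts)


def pathway_pattern(
    pathway_id: str,
    activity_a: Mapping[str, str],
    activity_b: Mapping[str, str],
) -> str:
    """Two-comparison pattern from activity classes, e.g. ``up_down``;
    unknown/zero activities map to the ``unknown`` component."""
    parts = []
    for activity in (activity_a, activity_b):
        if pathway_id not in activity:
            raise DataError(f"pathway missing activity annotation: {pathway_id!r}")
        parts.append(
            {"increased": "up", "decreased": "down"}.get(activity[pathway_id], "unknown")
        )
    return "_".join(parts)


def build_hub_network(
    hub_pairs: Sequence[tuple[str, str]],
    de_a: DETable,
    de_b: DETable,
    activity_a: Mapping[str, str],
    activity_b: Mapping[str, str],
) -> nx.Graph:
    """Hub network over the intersected pairs, nodes annotated with patterns.

    ``de_a`` / ``de_b`` are the miRNA DE tables of the two comparisons;
    ``activity_a`` / ``activity_b`` map pathway id -> activity class.  Missing
    annotations raise a :class:`DataError` naming the node.  Degrees follow
    from the intersected edge set.
    """
    g = nx.Graph()
    for mirna, pathway in hub_pairs:
        if mirna not in g:
            g.add_node(mirna, type="mirna", pattern=mirna_pattern(mirna, de_a, de_b))
        if pathway not in g:
            g.add_node(
                pathway,
                type="pathway",
                pattern=pathway_pattern(pathway, activity_a, activity_b),
            )
        g.add_edge(mirna, pathway)
    return g


def select_validation_mirnas(
    network: nx.Graph,
    min_degree: int = 3,
    require_reversal: bool = True,
) -> list[HubSelection]:
    """Hub miRNAs with degree >= min_degree, optionally reversal-patterned.

    Reversal patterns are ``down_up`` and ``up_down``.  Sorted by degree
    descending, then miRNA id.
    """
    kinds = nx.get_node_attributes(network, "type")
    out = []
    for node, kind in kinds.items():
        if kind != "mirna":
            continue
        degree = network.degree(node)
        pattern = network.nodes[node].get("pattern", "ns_ns")
        if degree < min_degree:
            continue
        if require_reversal and pattern not in REVERSAL_PATTERNS:
            continue
        out.append(HubSelection(mirna_id=node, degree=degree, pattern=pattern))
    return sorted(out, key=lambda h: (-h.degree, h.mirna_id))
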