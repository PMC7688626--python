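"""Tripartite construction, count-scores and bipartite degree tests."""

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from mirscreen.io import PathwayCatalog
from mirscreen.network import (
    build_mirna_pathway_network,
    build_tripartite,
    count_scores,
    network_counts,
    rank_nodes,
)
from mirscreen.targets import OverlapGene, OverlapGeneSet

from _factories import make_de_table, make_record, make_targets


def _overlap(genes: dict[str, frozenset], comparison="WD_vs_ND") -> OverlapGeneSet:
    return OverlapGeneSet(
        comparison=comparison,
        genes={g: OverlapGene(direction=1, mirnas=m) for g, m in genes.items()},
    )


class TestBuildTripartite:
    def test_hand_countable_star(self):
        de_mi = make_de_table(down=["m1"])
        targets = make_targets([("m1", "g1", 0.99), ("m1", "g2", 0.99)])
        overlap = _overlap({"g1": frozenset({"m1"}), "g2": frozenset({"m1"})})
        selected = [make_record("P1", z=1.0)]
        catalog = PathwayCatalog(sets={"P1": frozenset({"g1", "g2", "gX"})})
        g = build_tripartite(de_mi, targets, overlap, selected, catalog)
        assert g.number_of_nodes() == 4 and g.number_of_edges() == 4
        assert g.nodes["m1"]["regulation"] == "down"
        assert g.nodes["P1"]["regulation"] == "increased"

    def test_gene_outside_selected_pathways_pruned(self):
        de_mi = make_de_table(down=["m1"])
        targets = make_targets([("m1", "g1", 0.99)])
        overlap = _overlap({"g1": frozenset({"m1"})})
        selected = [make_record("P1", z=1.0)]
        catalog = PathwayCatalog(
            sets={"P1": frozenset({"gZ"}), "P2": frozenset({"g1"})}
        )
        g = build_tripartite(de_mi, targets, overlap, selected, catalog)
        assert "g1" not in g
        counts = network_counts(g)
        assert (counts.n_genes, counts.n_mirnas, counts.n_pathways) == (0, 0, 1)

    def test_matches_brute_force_edge_construction(self):
        rng = np.random.default_rng(31)
        mirnas = [f"m{i}" for i in range(8)]
        genes = [f"g{i}" for i in range(30)]
        pathways = [f"P{i}" for i in range(6)]
        target_pairs = {
            (m, g) for m in mirnas for g in genes if rng.uniform() < 0.15
        }
        membership = {
            p: frozenset(g for g in genes if rng.uniform() < 0.25) or frozenset({genes[0]})
            for p in pathways
        }
        de_mi = make_de_table(up=mirnas[:5], ns=mirnas[5:])
        targets = make_targets([(m, g, 0.99) for m, g in sorted(target_pairs)])
        overlap_genes = {}
        for g in genes:
            hitters = frozenset(
                m for m in mirnas[:5] if (m, g) in target_pairs
            )
            if hitters and rng.uniform() < 0.8:
                overlap_genes[g] = hitters
        overlap = _overlap(overlap_genes)
        selected = [make_record(p, z=1.0) for p in pathways[:4]]
        catalog = PathwayCatalog(sets=membership)

        net = build_tripartite(de_mi, targets, overlap, selected, catalog)

        expected_edges = set()
        for g, hitters in overlap_genes.items():
            pws = [p for p in pathways[:4] if g in membership[p]]
            if not pws or not hitters:
                continue
            for m in hitters:
                expected_edges.add((m, g))
            for p in pws:
                expected_edges.add((g, p))
        assert set(net.edges) == expected_edges

    def test_pruning_is_idempotent(self):
        de_mi = make_de_table(down=["m1"])
        targets = make_targets([("m1", "g1", 0.99)])
        overlap = _overlap({"g1": frozenset({"m1"})})
        selected = [make_record("P1", z=1.0)]
        catalog = PathwayCatalog(sets={"P1": frozenset({"g1"})})
        g1 = build_tripartite(de_mi, targets, overlap, selected, catalog)
        g2 = build_tripartite(de_mi, targets, overlap, selected, catalog)
        assert nx.utils.graphs_equal(g1, g2)


class TestCountScores:
    def test_shared_gene_count(self):
        g = nx.DiGraph()
        g.add_node("m1", type="mirna")
        for gene in ("g1", "g2", "g3"):
            g.add_node(gene, type="gene")
            g.add_edge("m1", gene)
        g.add_node("P1", type="pathway")
        g.add_edge("g2", "P1")
        g.add_edge("g3", "P1")
        pairs = count_scores(g)
        assert pairs.iloc[0].tolist() == ["m1", "P1", 2]

    def test_matches_triple_loop_brute_force(self):
        rng = np.random.default_rng(32)
        for _ in range(100):
            g = nx.DiGraph()
            mirnas = [f"m{i}" for i in range(4)]
            genes = [f"g{i}" for i in range(10)]
            pathways = [f"P{i}" for i in range(4)]
            for n, t in [(m, "mirna") for m in mirnas] + [
                (x, "gene") for x in genes
            ] + [(p, "pathway") for p in pathways]:
                g.add_node(n, type=t)
            for m in mirnas:
                for x in genes:
                    if rng.uniform() < 0.3:
                        g.add_edge(m, x)
            for x in genes:
                for p in pathways:
                    if rng.uniform() < 0.3:
                        g.add_edge(x, p)
            pairs = count_scores(g)
            got = {
                (r.mirna_id, r.pathway_id): r.count_score
                for r in pairs.itertuples(index=False)
            }
            expected = {}
            for m in mirnas:
                for p in pathways:
                    c = sum(
                        1
                        for x in genes
                        if g.has_edge(m, x) and g.has_edge(x, p)
                    )
                    if c >= 1:
                        expected[(m, p)] = c
            assert got == expected
            # count-score bounded by both side degrees
            for (m, p), c in got.items():
                assert c <= min(g.out_degree(m), g.in_degree(p))


class TestBipartite:
    def test_threshold_inclusive_at_two(self):
        pairs = pd.DataFrame(
            [("m1", "P1", 1), ("m1", "P2", 2), ("m2", "P1", 3)],
            columns=["mirna_id", "pathway_id", "count_score"],
        )
        net = build_mirna_pathway_network(pairs, min_count=2)
        assert net.number_of_edges() == 2
        assert ("m1", "P1") not in net.edges

    def test_all_subthreshold_gives_empty_network(self):
        pairs = pd.DataFrame(
            [("m1", "P1", 1)], columns=["mirna_id", "pathway_id", "count_score"]
        )
        net = build_mirna_pathway_network(pairs, min_count=2)
        assert net.number_of_nodes() == 0

    def test_raising_threshold_never_adds_edges(self):
        rng = np.random.default_rng(33)
        pairs = pd.DataFrame(
            [
                (f"m{i}", f"P{j}", int(rng.integers(1, 6)))
                for i in range(6)
                for j in range(6)
                if rng.uniform() < 0.5
            ],
            columns=["mirna_id", "pathway_id", "count_score"],
        )
        previous = None
        for cut in (1, 2, 3, 4, 5):
            edges = {
                frozenset(e) for e in build_mirna_pathway_network(pairs, cut).edges
            }
            if previous is not None:
                assert edges <= previous
            previous = edges

    def test_handshake_identity_on_random_networks(self):
        rng = np.random.default_rng(34)
        for _ in range(100):
            pairs = pd.DataFrame(
                [
                    (f"m{i}", f"P{j}", int(rng.integers(1, 5)))
                    for i in range(rng.integers(1, 8))
                    for j in range(rng.integers(1, 8))
                    if rng.uniform() < 0.6
                ],
                columns=["mirna_id", "pathway_id", "count_score"],
            )
            net = build_mirna_pathway_network(pairs, 2)
            kinds = nx.get_node_attributes(net, "type")
            mirna_deg = sum(net.degree(n) for n, t in kinds.items() if t == "mirna")
            pw_deg = sum(net.degree(n) for n, t in kinds.items() if t == "pathway")
            assert mirna_deg == pw_deg == net.number_of_edges()


class TestRankNodes:
    def test_star_graph_degrees(self):
        pairs = pd.DataFrame(
            [("m1", f"P{i}", 2) for i in range(5)],
            columns=["mirna_id", "pathway_id", "count_score"],
        )
        net = build_mirna_pathway_network(pairs, 2)
        mirnas, pathways = rank_nodes(net)
        assert mirnas == [("m1", 5)]
        assert all(d == 1 for _, d in pathways)

    def test_empty_network_gives_empty_lists(self):
        assert rank_nodes(nx.Graph()) == ([], [])

    def test_ranks_agree_with_recount(self):
        rng = np.random.default_rng(35)
        pairs = pd.DataFrame(
            [
                (f"m{i}", f"P{j}", 2)
                for i in range(10)
                for j in range(10)
                if rng.uniform() < 0.3
            ],
            columns=["mirna_id", "pathway_id", "count_score"],
        )
        net = build_mirna_pathway_network(pairs, 2)
        mirnas, _ = rank_nodes(net, top_n=100)
        recount = {
            m: sum(1 for r in pairs.itertuples(index=False) if r.mirna_id == m)
            for m, _ in mirnas
        }
        for m, d in mirnas:
            assert d == recount[m]
        degrees = [d for _, d in mirnas]
        assert degrees == sorted(degrees, reverse=True)
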