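import math
import random

import pytest

from _oracles import (
    brute_aa,
    brute_cn,
    brute_dice,
    brute_jaccard,
    brute_l3,
    brute_ra,
    brute_shortest,
    random_er_graph,
)
from conftest import graph_from_edges
from fdinet.fixtures import TOY_GRAPH_NAMES, generate_toy_graph
from fdinet.graph_build import build_graph, from_toy, joinify
from fdinet.link_prediction import (
    Prediction,
    aa_score,
    cn_score,
    dice_score,
    jaccard_score,
    l3_score,
    neighborhood_scores,
    predict,
    ra_score,
    rank_predictions,
    read_predictions_tsv,
    shortest_path_scores,
    write_predictions_tsv,
)
from fdinet.similarity import SimilarityEdge

SCORERS = {
    "aa": (aa_score, brute_aa),
    "cn": (cn_score, brute_cn),
    "jaccard": (jaccard_score, brute_jaccard),
    "ra": (ra_score, brute_ra),
    "dice": (dice_score, brute_dice),
    "l3": (l3_score, brute_l3),
}


class TestNeighborhoodScorers:
    def test_no_common_neighbors_gives_zero_aa(self):
        g = graph_from_edges([("a", "b", 1.0), ("c", "d", 1.0)])
        assert aa_score(g, ("a", "c")) == 0.0

    def test_single_degree2_common_neighbor_identities(self):
        # z has degree 2: AA = 1/ln 2, RA = 1/2
        g = graph_from_edges([("a", "z", 1.0), ("z", "b", 1.0)])
        assert aa_score(g, ("a", "b")) == pytest.approx(1.0 / math.log(2), abs=1e-15)
        assert ra_score(g, ("a", "b")) == 0.5

    def test_aa_sums_over_neighbor_degrees(self):
        # common neighbors z1 (degree 2) and z2 (degree 4)
        edges = [("a", "z1", 1.0), ("z1", "b", 1.0),
                 ("a", "z2", 1.0), ("z2", "b", 1.0),
                 ("z2", "x", 1.0), ("z2", "y", 1.0)]
        g = graph_from_edges(edges)
        expected = 1.0 / math.log(2) + 1.0 / math.log(4)
        assert aa_score(g, ("a", "b")) == pytest.approx(expected, abs=1e-15)

    def test_ra_sums_inverse_degrees(self):
        edges = [("a", "z1", 1.0), ("z1", "b", 1.0),
                 ("a", "z2", 1.0), ("z2", "b", 1.0),
                 ("z2", "x", 1.0), ("z2", "y", 1.0), ("z2", "w", 1.0)]
        g = graph_from_edges(edges)
        assert ra_score(g, ("a", "b")) == pytest.approx(0.7, abs=1e-15)

    def test_cn_on_complete_graph_of_four(self):
        nodes = ["a", "b", "c", "d"]
        edges = [(u, v, 1.0) for i, u in enumerate(nodes) for v in nodes[i + 1:]]
        g = graph_from_edges(edges)
        for i, u in enumerate(nodes):
            for v in nodes[i + 1:]:
                assert cn_score(g, (u, v)) == 2.0

    def test_jaccard_and_dice_worked_examples(self):
        # Γ(a) = {z, c}, Γ(b) = {z, d}
        g = graph_from_edges([("a", "z", 1.0), ("b", "z", 1.0),
                              ("a", "c", 1.0), ("b", "d", 1.0)])
        assert jaccard_score(g, ("a", "b")) == pytest.approx(1.0 / 3.0)
        assert dice_score(g, ("a", "b")) == 0.5

    def test_identical_neighborhoods_score_one(self):
        g = graph_from_edges([("a", "z", 1.0), ("b", "z", 1.0),
                              ("a", "w", 1.0), ("b", "w", 1.0)])
        assert jaccard_score(g, ("a", "b")) == 1.0
        assert dice_score(g, ("a", "b")) == 1.0

    def test_l3_single_paths(self):
        g = from_toy(generate_toy_graph("l3_path"))
        assert l3_score(g, ("a", "b")) == 0.5
        half = graph_from_edges([("a", "u", 0.5), ("u", "v", 0.5), ("v", "b", 0.5)])
        assert l3_score(half, ("a", "b")) == pytest.approx(0.0625, abs=1e-15)
        no_path = graph_from_edges([("a", "u", 1.0), ("v", "b", 1.0)])
        assert l3_score(no_path, ("a", "b")) == 0.0


class TestScorerOracleEquivalence:
    @pytest.mark.parametrize("name", TOY_GRAPH_NAMES)
    @pytest.mark.parametrize("method", sorted(SCORERS))
    def test_toy_graphs_match_brute_force(self, name, method):
        toy = generate_toy_graph(name)
        g = from_toy(toy)
        ours, brute = SCORERS[method]
        edges = list(toy.edges)
        for i, a in enumerate(toy.nodes):
            for b in toy.nodes[i + 1:]:
                if g.graph.has_edge(a, b):
                    continue
                assert ours(g, (a, b)) == pytest.approx(
                    brute(edges, a, b), abs=1e-12
                ), (name, method, a, b)

    @pytest.mark.parametrize("seed", range(20))
    def test_random_graphs_match_brute_force(self, seed):
        rng = random.Random(seed)
        nodes, edges = random_er_graph(rng)
        g = graph_from_edges(edges, nodes=nodes)
        for method, (ours, brute) in SCORERS.items():
            for i, a in enumerate(nodes):
                for b in nodes[i + 1:]:
                    if g.graph.has_edge(a, b):
                        continue
                    assert ours(g, (a, b)) == pytest.approx(
                        brute(edges, a, b), abs=1e-12
                    ), (method, a, b)

    @pytest.mark.parametrize("seed", range(10))
    def test_scores_symmetric_and_nonnegative(self, seed):
        nodes, edges = random_er_graph(random.Random(seed + 100))
        g = graph_from_edges(edges, nodes=nodes)
        for method, (ours, _) in SCORERS.items():
            for i, a in enumerate(nodes):
                for b in nodes[i + 1:]:
                    s_ab, s_ba = ours(g, (a, b)), ours(g, (b, a))
                    assert s_ab == pytest.approx(s_ba, abs=1e-12)
                    assert s_ab >= 0.0
                    if method in ("jaccard", "dice"):
                        assert s_ab <= 1.0

    @pytest.mark.parametrize("seed", range(10))
    def test_dice_jaccard_identity(self, seed):
        nodes, edges = random_er_graph(random.Random(seed + 200))
        g = graph_from_edges(edges, nodes=nodes)
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                j = jaccard_score(g, (a, b))
                assert dice_score(g, (a, b)) == pytest.approx(2 * j / (1 + j), abs=1e-12)


class TestShortestPathScores:
    def test_chain_sum_of_weights(self):
        g = graph_from_edges([("D1", "F1", 0.9), ("F1", "F2", 0.8)])
        preds = shortest_path_scores(g, 2)
        assert len(preds) == 1
        assert preds[0].pair == ("D1", "F2")
        assert preds[0].score == pytest.approx(1.7)

    def test_dijkstra_takes_minimum_weight_route(self):
        # two 2-edge routes between a and b: sums 1.7 and 0.9
        g = graph_from_edges([("a", "x", 0.9), ("x", "b", 0.8),
                              ("a", "y", 0.4), ("y", "b", 0.5)])
        scores = {p.pair: p.score for p in shortest_path_scores(g, 2)}
        assert scores[("a", "b")] == pytest.approx(0.9)

    def test_adjacent_pairs_never_emitted(self):
        g = graph_from_edges([("a", "b", 0.9), ("b", "c", 0.8), ("a", "c", 0.7)])
        assert shortest_path_scores(g, 2) == []

    def test_descending_rank_prefers_larger_path_sum(self):
        preds = [
            Prediction("DrugA", "FoodX", "sp2", 1.12),
            Prediction("DrugB", "FoodY", "sp2", 2.0),
        ]
        ranked = rank_predictions(preds)
        assert ranked[0].pair == ("DrugB", "FoodY") and ranked[0].rank == 1

    @pytest.mark.parametrize("length", [2, 3])
    @pytest.mark.parametrize("seed", range(10))
    def test_scores_match_exhaustive_enumeration(self, length, seed):
        nodes, edges = random_er_graph(random.Random(seed + 300))
        g = graph_from_edges(edges, nodes=nodes)
        preds = {p.pair: p.score for p in shortest_path_scores(g, length)}
        for i, a in enumerate(nodes):
            for b in nodes[i + 1:]:
                pair = (a, b) if a < b else (b, a)
                if g.graph.has_edge(a, b):
                    assert pair not in preds
                    continue
                best, lengths = brute_shortest(edges, a, b)
                if best is None:
                    assert pair not in preds
                elif pair in preds:
                    assert preds[pair] == pytest.approx(best, abs=1e-12)
                    assert length in lengths
                else:
                    assert length not in lengths or len(lengths) > 1

    def test_sp2_equals_min_over_shared_neighbors(self):
        rng = random.Random(17)
        nodes, edges = random_er_graph(rng)
        g = graph_from_edges(edges, nodes=nodes)
        adj = {n: {} for n in nodes}
        for u, v, w in edges:
            adj[u][v] = w
            adj[v][u] = w
        for p in shortest_path_scores(g, 2):
            a, b = p.pair
            via = [adj[a][z] + adj[z][b] for z in set(adj[a]) & set(adj[b])]
            assert p.score == pytest.approx(min(via), abs=1e-12)

    def test_bridge_paths_flagged_and_filterable(self):
        hg = build_graph([SimilarityEdge("a", "b", 0.9, "DD"),
                          SimilarityEdge("c", "d", 0.8, "DD")])
        joint = joinify(hg, seed=0)
        preds = shortest_path_scores(joint, 2)
        assert any(p.uses_bridge for p in preds)
        assert shortest_path_scores(joint, 2, exclude_bridge_paths=True) == [
            p for p in preds if not p.uses_bridge
        ]


class TestRanking:
    def test_dense_ranks_descending(self):
        preds = [Prediction("x", "y", "cn", 3.0), Prediction("p", "q", "cn", 1.0),
                 Prediction("m", "n", "cn", 2.0)]
        ranked = rank_predictions(preds)
        assert [(p.score, p.rank) for p in ranked] == [(3.0, 1), (2.0, 2), (1.0, 3)]

    def test_ties_break_lexicographically(self):
        preds = [Prediction("A", "C", "cn", 1.0), Prediction("A", "B", "cn", 1.0)]
        ranked = rank_predictions(preds)
        assert [p.pair for p in ranked] == [("A", "B"), ("A", "C")]

    def test_rank_invariant_to_input_order(self):
        preds = [Prediction(f"n{i}", f"m{i}", "cn", float(i % 5)) for i in range(20)]
        shuffled = list(preds)
        random.Random(1).shuffle(shuffled)
        assert rank_predictions(preds) == rank_predictions(shuffled)

    def test_ascending_mode_inverts_preference(self):
        preds = [Prediction("a", "b", "sp2", 2.0), Prediction("c", "d", "sp2", 1.0)]
        assert rank_predictions(preds, ascending=True)[0].pair == ("c", "d")


class TestBatchPrediction:
    def test_neighborhood_batch_matches_pair_scorer(self):
        nodes, edges = random_er_graph(random.Random(5))
        g = graph_from_edges(edges, nodes=nodes)
        for method, (ours, _) in SCORERS.items():
            for p in neighborhood_scores(g, method):
                assert p.score == pytest.approx(ours(g, p.pair), abs=1e-12)
                assert not g.graph.has_edge(*p.pair)
                assert p.score > 0.0

    def test_fdi_only_restricts_to_drug_food_pairs(self):
        labels = {"D1": "drug", "D2": "drug", "F1": "food_compound", "z": "drug"}
        g = graph_from_edges(
            [("D1", "z", 1.0), ("D2", "z", 1.0), ("F1", "z", 1.0)], labels=labels
        )
        pairs = {p.pair for p in neighborhood_scores(g, "cn", fdi_only=True)}
        assert pairs == {("D1", "F1"), ("D2", "F1")}

    def test_unknown_method_raises(self):
        g = graph_from_edges([("a", "b", 1.0)])
        with pytest.raises(ValueError, match="unknown"):
            neighborhood_scores(g, "pagerank")

    def test_predict_returns_ranked_list(self):
        g = from_toy(generate_toy_graph("square"))
        ranked = predict(g, "cn")
        assert [p.rank for p in ranked] == list(range(1, len(ranked) + 1))


def test_predictions_tsv_round_trip(tmp_path):
    g = from_toy(generate_toy_graph("square"))
    preds = predict(g, "ra")
    write_predictions_tsv(preds, tmp_path / "p.tsv")
    assert read_predictions_tsv(tmp_path / "p.tsv") == preds
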