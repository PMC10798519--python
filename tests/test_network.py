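"""Graph construction, node taxonomy, composition shares, centralities."""

from __future__ import annotations

import math

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, strategies as st

from credflow.network import (
    NodeClass,
    build_graph,
    centrality_summary,
    classify_nodes,
    composition_from_counts,
    composition_summary,
    degree_centrality,
    eigenvector_centrality,
)

from conftest import make_record


def rt(rid, source, source_author, author, when="2021-03-05T13:00:00"):
    return make_record(tweet_id=rid, when=when, source=source,
                       source_author=source_author, author=author)


class TestBuildGraph:
    def test_broadcast_cascade_flattens_to_hub_and_spokes(self):
        recs = [
            make_record(tweet_id="t1", author="A"),
            rt("r1", "t1", "A", "B"),
            rt("r2", "t1", "A", "C"),
        ]
        G = build_graph(recs)
        assert set(G.edges) == {("A", "B"), ("A", "C")}
        assert G.nodes["A"]["w"] == 2

    def test_retweeter_of_absent_content_is_isolate(self):
        # The source tweet (posted before the window) is not in the set.
        recs = [rt("r1", "t0", "X", "B")]
        G = build_graph(recs)
        assert set(G.nodes) == {"B"} and G.number_of_edges() == 0
        assert classify_nodes(G)["B"] is NodeClass.ISOLATE

    def test_repeat_retweet_increments_multiplicity_not_degree(self):
        recs = [
            make_record(tweet_id="t1", author="A"),
            rt("r1", "t1", "A", "B"),
            rt("r2", "t1", "A", "B", when="2021-03-05T14:00:00"),
        ]
        G = build_graph(recs)
        assert G["A"]["B"]["multiplicity"] == 2
        assert G.out_degree("A") == 1
        assert G.nodes["A"]["w"] == 2

    def test_self_retweet_dropped_and_counted(self):
        recs = [make_record(tweet_id="t1", author="A"), rt("r1", "t1", "A", "A")]
        G = build_graph(recs)
        assert G.number_of_edges() == 0
        assert G.graph["n_self_retweets"] == 1

    @pytest.mark.parametrize("n_b,n_c", [(1, 1), (2, 1), (3, 2), (0, 2)])
    def test_edge_accounting_matches_brute_force(self, n_b, n_c):
        # Enumerated 3-user scenarios: B retweets n_b times, C n_c times.
        recs = [make_record(tweet_id="t1", author="A")]
        for i in range(n_b):
            recs.append(rt(f"rb{i}", "t1", "A", "B"))
        for i in range(n_c):
            recs.append(rt(f"rc{i}", "t1", "A", "C"))
        G = build_graph(recs)
        assert G.nodes["A"]["w"] == n_b + n_c
        assert G.out_degree("A") == int(n_b > 0) + int(n_c > 0)
        total_mult = sum(d["multiplicity"] for _, _, d in G.edges(data=True))
        assert total_mult == n_b + n_c  # weight conservation

    def test_tweets_only_graph_is_all_isolates(self):
        recs = [make_record(tweet_id=f"t{i}", author=f"u{i}") for i in range(5)]
        classes = classify_nodes(build_graph(recs))
        assert all(c is NodeClass.ISOLATE for c in classes.values())


class TestClassification:
    @pytest.mark.parametrize(
        "k_in,k_out,expected",
        [
            (0, 3, NodeClass.AUTHOR),
            (0, 0, NodeClass.ISOLATE),
            (2, 1, NodeClass.AUTHOR_SHARER),
            (5, 0, NodeClass.SHARER),
        ],
    )
    def test_degree_formula(self, k_in, k_out, expected):
        G = nx.DiGraph()
        G.add_node("x")
        for i in range(k_in):
            G.add_edge(f"in{i}", "x")
        for i in range(k_out):
            G.add_edge("x", f"out{i}")
        assert classify_nodes(G)["x"] is expected

    @given(st.integers(0, 2**32 - 1))
    def test_classification_partitions_random_graphs(self, seed):
        G = nx.gnp_random_graph(12, 0.25, seed=seed, directed=True)
        classes = classify_nodes(G)
        comp = composition_summary(classes)
        assert comp["count"].sum() == G.number_of_nodes()
        assert set(classes) == set(G.nodes)


class TestComposition:
    def test_reproduces_printed_vaccine_lowcred_peak_row(self):
        comp = composition_from_counts(
            {"Author": 138, "Sharer": 1002, "Author/Sharer": 2, "Isolate": 188}
        )
        printed = dict(zip(comp["class"], comp["pct_printed"]))
        assert printed == {
            "Author": 10.4, "Sharer": 75.3, "Author/Sharer": 0.2, "Isolate": 14.1,
        }
        assert comp.attrs["n_nodes"] == 1330

    def test_all_isolates(self):
        comp = composition_from_counts({"Isolate": 7})
        shares = dict(zip(comp["class"], comp["pct_printed"]))
        assert shares["Isolate"] == 100.0
        assert shares["Author"] == 0.0

    def test_three_sig_fig_shares_match_running_text(self):
        pre = composition_from_counts(
            {"Author": 2557, "Sharer": 26448, "Author/Sharer": 329, "Isolate": 3379}
        )
        assert pre.loc[pre["class"] == "Author", "pct_3sf"].item() == 7.82
        peak = composition_from_counts(
            {"Author": 2336, "Sharer": 19526, "Author/Sharer": 326, "Isolate": 3001}
        )
        assert peak.loc[peak["class"] == "Author", "pct_3sf"].item() == 9.27
        assert peak.loc[peak["class"] == "Sharer", "pct_3sf"].item() == 77.5


class TestDegreeCentrality:
    def test_star_hub_saturates(self):
        G = nx.DiGraph()
        for leaf in "bcde":
            G.add_edge("a", leaf)
        assert degree_centrality(G, "out")["a"] == 1.0

    def test_isolate_scores_zero(self):
        G = nx.DiGraph()
        G.add_edge("a", "b")
        G.add_node("z")
        assert degree_centrality(G, "in")["z"] == 0.0

    def test_normalization_includes_isolates(self):
        G = nx.DiGraph()
        for i in range(10):
            G.add_edge("hub", f"s{i}")
        for i in range(90):
            G.add_node(f"iso{i}")
        assert degree_centrality(G, "out")["hub"] == pytest.approx(0.1)

    def test_single_node_rejected(self):
        G = nx.DiGraph()
        G.add_node("a")
        with pytest.raises(ValueError):
            degree_centrality(G, "out")


def _oracle_check(G, scores, atol=1e-5):
    """Dense symmetric eigensolver oracle for the undirected projection."""
    U = nx.Graph(G)
    nodes = list(U.nodes)
    A = nx.to_numpy_array(U, nodelist=nodes, weight=None)
    w, V = np.linalg.eigh(A)
    lam1 = w[-1]
    v = np.array([scores[n] for n in nodes])
    assert np.all(v >= 0)
    assert np.linalg.norm(v) == pytest.approx(1.0, abs=1e-9)
    # v must lie in the dominant eigenspace: residual of the eigen-equation.
    assert np.max(np.abs(A @ v - lam1 * v)) <= atol * max(lam1, 1.0)
    if len(w) > 1 and lam1 - w[-2] > 1e-8:
        u = np.abs(V[:, -1])
        assert np.max(np.abs(v - u)) <= atol


class TestEigenvectorCentrality:
    @pytest.mark.parametrize("n", [1, 3, 10, 50])
    def test_star_hub_is_inverse_root_two(self, n):
        G = nx.star_graph(n)
        scores = eigenvector_centrality(G, tol=1e-10)
        assert scores[0] == pytest.approx(1 / math.sqrt(2), abs=1e-6)
        assert scores[1] == pytest.approx(1 / math.sqrt(2 * n), abs=1e-6)

    def test_triangle_is_uniform(self):
        scores = eigenvector_centrality(nx.cycle_graph(3), tol=1e-10)
        for v in scores.values():
            assert v == pytest.approx(1 / math.sqrt(3), abs=1e-8)

    def test_edgeless_graph_rejected(self):
        G = nx.Graph()
        G.add_nodes_from("ab")
        with pytest.raises(ValueError):
            eigenvector_centrality(G)

    def test_atlas_graphs_match_dense_oracle(self):
        # Exhaustive over all isomorphism classes up to 7 nodes.
        from networkx.generators.atlas import graph_atlas_g

        for G in graph_atlas_g():
            if G.number_of_edges() == 0:
                continue
            scores = eigenvector_centrality(G, tol=1e-10, max_iter=100_000)
            _oracle_check(G, scores)

    @pytest.mark.parametrize("seed", range(10))
    def test_random_graphs_match_dense_oracle(self, seed):
        G = nx.gnp_random_graph(12, 0.3, seed=seed)
        if G.number_of_edges() == 0:
            pytest.skip("empty draw")
        scores = eigenvector_centrality(G, tol=1e-10, max_iter=100_000)
        _oracle_check(G, scores)

    def test_isolates_score_numerically_zero(self):
        G = nx.star_graph(30)
        G.add_nodes_from(f"iso{i}" for i in range(5))
        scores = eigenvector_centrality(G, tol=1e-10)
        for i in range(5):
            assert scores[f"iso{i}"] <= 1e-8
        assert scores[0] == pytest.approx(1 / math.sqrt(2), abs=1e-6)

    def test_star_dominance_in_disconnected_graph(self):
        # Largest component a star: its hub attains the maximum score ~1/sqrt(2).
        G = nx.star_graph(40)
        G.add_edge("x", "y")  # small side component
        scores = eigenvector_centrality(G, tol=1e-10)
        med, mx = centrality_summary(scores)
        assert mx == pytest.approx(1 / math.sqrt(2), abs=1e-4)
        assert max(scores, key=scores.get) == 0


class TestCentralitySummary:
    def test_median_over_all_nodes_including_zeros(self):
        med, mx = centrality_summary({"a": 0, "b": 0, "c": 0, "d": 0.5})
        assert med == 0.0 and mx == 0.5

    def test_majority_zero_out_degree_gives_zero_median(self, default_stream):
        # Broadcast networks are sharer-dominated, so the published
        # out-degree medians are exactly 0; same here by construction.
        from credflow.corpus import CredClass, partition_credibility

        config, _, records, _ = default_stream
        part = partition_credibility(records, set(config.lowcred_pool), config.windows)
        G = build_graph(part.records(period="Peak", cls=CredClass.RESIDUAL))
        med, _ = centrality_summary(degree_centrality(G, "out"))
        assert med == 0.0

    def test_plain_median(self):
        med, mx = centrality_summary({"a": 0.1, "b": 0.2, "c": 0.3})
        assert med == pytest.approx(0.2) and mx == pytest.approx(0.3)

    def test_empty_map_rejected(self):
        with pytest.raises(ValueError):
            centrality_summary({})
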