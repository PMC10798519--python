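"""Flattened retweet networks: construction, node taxonomy, centrality.

The platform attributes every retweet directly to the original author, so a
cascade collapses to a hub-and-spoke (broadcast) graph: a directed edge runs
author -> retweeter for each retweet of in-window content, with multiplicity
for repeat retweets.  Node weight w(u) is the total number of retweets u's
in-window content received.  Degrees count distinct neighbours, not
multiplicities: in-degree is the number of different authors a user
retweeted, out-degree the number of different users who retweeted them.

Users split four ways by degree: Authors (k_out>0, k_in=0) only had their
content shared; Sharers (k_in>0, k_out=0) only passed content on;
Author/Sharers did both; Isolates did neither — authors nobody retweeted, or
sharers of content posted outside the window or corpus.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from enum import Enum
from typing import Iterable, Mapping

import networkx as nx
import numpy as np
import pandas as pd

from ._rounding import round_half_up, round_sig_half_up
from .records import TweetRecord


class NodeClass(str, Enum):
    AUTHOR = "Author"
    SHARER = "Sharer"
    AUTHOR_SHARER = "Author/Sharer"
    ISOLATE = "Isolate"


def build_graph(records: Iterable[TweetRecord]) -> nx.DiGraph:
    """Build the flattened retweet graph for one (period, class) record set.

    Nodes are every user appearing as an author or retweeter in the set.
    An edge u->v (multiplicity incremented) is added iff v retweeted a tweet
    of u's that is itself present in the set; retweeters of absent (out-of-
    window or out-of-corpus) content stay isolated.  Self-retweets are
    dropped and counted in ``G.graph["n_self_retweets"]``.
    """
    records = list(records)
    G = nx.DiGraph(n_self_retweets=0, n_external_sources=0)
    original_ids = {r.tweet_id for r in records if not r.is_retweet}

    def ensure_node(rec: TweetRecord, user: str) -> None:
        if user not in G:
            G.add_node(
                user,
                followers=rec.author_followers,
                verified=rec.author_verified,
                created_at=rec.author_created_at,
            )

    for rec in records:
        ensure_node(rec, rec.author_id)
    for rec in records:
        if not rec.is_retweet:
            continue
        if rec.source_tweet_id not in original_ids:
            G.graph["n_external_sources"] += 1
            continue
        src_author = rec.source_author_id
        if src_author == rec.author_id:
            G.graph["n_self_retweets"] += 1
            continue
        if G.has_edge(src_author, rec.author_id):
            G[src_author][rec.author_id]["multiplicity"] += 1
        else:
            G.add_edge(src_author, rec.author_id, multiplicity=1)

    for node in G.nodes:
        G.nodes[node]["w"] = sum(
            d["multiplicity"] for _, _, d in G.out_edges(node, data=True)
        )
    return G


def classify_nodes(G: nx.DiGraph) -> dict[str, NodeClass]:
    """Four-way degree taxonomy; distinct-neighbour degrees."""
    out: dict[str, NodeClass] = {}
    for node in G.nodes:
        k_in = G.in_degree(node)
        k_out = G.out_degree(node)
        if k_out > 0 and k_in == 0:
            out[node] = NodeClass.AUTHOR
        elif k_in > 0 and k_out == 0:
            out[node] = NodeClass.SHARER
        elif k_in > 0 and k_out > 0:
            out[node] = NodeClass.AUTHOR_SHARER
        else:
            out[node] = NodeClass.ISOLATE
    return out


def composition_from_counts(counts: Mapping[NodeClass | str, int]) -> pd.DataFrame:
    """Composition shares from raw class counts.

    Percentages of N are reported unrounded, half-up at one decimal (the
    table convention), and at three significant figures (the running-text
    convention).  N=0 yields NaN shares.
    """
    counts = {NodeClass(k): int(v) for k, v in counts.items()}
    n_total = sum(counts.get(c, 0) for c in NodeClass)
    rows = []
    for c in NodeClass:
        count = counts.get(c, 0)
        pct = 100.0 * count / n_total if n_total else math.nan
        rows.append(
            {
                "class": c.value,
                "count": count,
                "pct": pct,
                "pct_printed": round_half_up(pct, 1),
                "pct_3sf": round_sig_half_up(pct, 3),
            }
        )
    frame = pd.DataFrame(rows)
    frame.attrs["n_nodes"] = n_total
    return frame


def composition_summary(node_classes: Mapping[str, NodeClass]) -> pd.DataFrame:
    """Counts and percentage shares of the four node classes."""
    counts: dict[NodeClass, int] = {c: 0 for c in NodeClass}
    for cls in node_classes.values():
        counts[cls] += 1
    return composition_from_counts(counts)


def degree_centrality(G: nx.DiGraph, direction: str) -> dict[str, float]:
    """Distinct-neighbour degree centrality k/(N-1); isolates score 0.

    N counts every node in the graph, isolates included, matching the
    whole-network normalization behind the tiny published medians.
    """
    if G.number_of_nodes() < 2:
        raise ValueError("degree centrality requires at least 2 nodes")
    if direction == "in":
        return nx.in_degree_centrality(G)
    if direction == "out":
        return nx.out_degree_centrality(G)
    raise ValueError(f"direction must be 'in' or 'out', got {direction!r}")


def eigenvector_centrality(
    G: nx.Graph | nx.DiGraph, *, tol: float = 1e-6, max_iter: int = 1000
) -> dict[str, float]:
    """Eigenvector centrality on the undirected, unweighted projection.

    Power iteration on A + I (the identity shift keeps the dominant
    eigenvalue strictly largest in magnitude, so iteration converges on the
    bipartite hub-and-spoke graphs these networks actually are) from a
    uniform start, stopping when the max absolute change falls below
    ``tol``; the result is L2-normalized and nonnegative.  Isolates and
    nodes off the dominant component score (numerically) zero.
    """
    U = nx.Graph(G)  # undirected, multiplicity ignored
    if U.number_of_edges() == 0:
        raise ValueError("eigenvector centrality requires at least one edge")
    nodes = list(U.nodes)
    A = nx.to_scipy_sparse_array(U, nodelist=nodes, weight=None, format="csr")
    x = np.full(len(nodes), 1.0 / math.sqrt(len(nodes)))
    for _ in range(max_iter):
        y = A @ x + x
        y /= np.linalg.norm(y)
        if np.max(np.abs(y - x)) < tol:
            x = y
            break
        x = y
    else:
        raise RuntimeError(
            f"power iteration did not converge within {max_iter} iterations"
        )
    x = np.clip(x, 0.0, None)
    norm = np.linalg.norm(x)
    if norm > 0:
        x = x / norm
    return dict(zip(nodes, x.tolist()))


def centrality_summary(scores: Mapping[str, float]) -> tuple[float, float]:
    """(median, maximum) over all nodes, isolates included."""
    if not scores:
        raise ValueError("empty centrality map")
    values = np.asarray(list(scores.values()), dtype=float)
    return float(np.median(values)), float(values.max())


@dataclass
class GraphReport:
    """Per-graph node table and centrality medians/maxima."""

    node_table: pd.DataFrame
    composition: pd.DataFrame
    centrality_stats: pd.DataFrame


def analyze_graph(G: nx.DiGraph) -> GraphReport:
    """Classify nodes and compute the three centrality measures in one pass."""
    classes = classify_nodes(G)
    n = G.number_of_nodes()
    cin = degree_centrality(G, "in") if n >= 2 else {u: 0.0 for u in G}
    cout = degree_centrality(G, "out") if n >= 2 else {u: 0.0 for u in G}
    try:
        ceig = eigenvector_centrality(G)
    except ValueError:
        ceig = {u: 0.0 for u in G}
    rows = [
        {
            "user_id": u,
            "class": classes[u].value,
            "w": G.nodes[u].get("w", 0),
            "k_in": G.in_degree(u),
            "k_out": G.out_degree(u),
            "in_degree_centrality": cin[u],
            "out_degree_centrality": cout[u],
            "eigenvector_centrality": ceig[u],
            "followers": G.nodes[u].get("followers"),
            "verified": G.nodes[u].get("verified"),
            "created_at": G.nodes[u].get("created_at"),
        }
        for u in sorted(G.nodes)
    ]
    node_table = pd.DataFrame(rows)
    stat_rows = []
    for name, scores in (
        ("in_degree", cin),
        ("out_degree", cout),
        ("eigenvector", ceig),
    ):
        med, mx = centrality_summary(scores) if scores else (math.nan, math.nan)
        stat_rows.append({"measure": name, "median": med, "maximum": mx})
    return GraphReport(
        node_table=node_table,
        composition=composition_summary(classes),
        centrality_stats=pd.DataFrame(stat_rows),
    )


def export_edge_list(G: nx.DiGraph) -> pd.DataFrame:
    rows = [
        {"source": u, "target": v, "multiplicity": d["multiplicity"]}
        for u, v, d in sorted(G.edges(data=True))
    ]
    return pd.DataFrame(rows, columns=["source", "target", "multiplicity"])
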