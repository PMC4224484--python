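"""Residue correlation networks and betweenness-based core extraction.

An edge joins two residues when their maximum mDCC is at least a threshold
(default 0.5) AND the centers of the maximising modes are closer than a
distance cutoff (default 5.0 A) — i.e. the pair is both strongly
correlated and in contact.  An edge is flagged *transient* when the
conventional DCC of the pair stays below 0.5: the correlation lives in
only part of the trajectory (a side-chain flip, a backbone slide).

Node importance is measured with unnormalised betweenness centrality
g(i) = sum over unordered node pairs (s, t), s != i != t, of
sigma_st(i) / sigma_st, where sigma_st counts shortest paths.  Subnetworks
keep the top percentile of betweenness; the "core" adds every node and
edge on the shortest paths between top nodes.

Graphs are plain ``networkx.Graph`` objects so downstream tooling can use
the whole networkx ecosystem.
"""

from __future__ import annotations

import math
from typing import Optional

import networkx as nx
import numpy as np
import pandas as pd

from .residue_map import ResidueCorrelationMap

MDCC_MIN = 0.5
DIST_MAX = 5.0
TRANSIENT_DCC_MAX = 0.5


def build_network(rmap: ResidueCorrelationMap, mdcc_min: float = MDCC_MIN,
                  dist_max: float = DIST_MAX,
                  transient_dcc_max: float = TRANSIENT_DCC_MAX) -> nx.Graph:
    """Undirected residue graph from a residue correlation map.

    Edge rule: ``mdcc(a,b) >= mdcc_min`` and ``center_distance < dist_max``
    (and a != b).  A missing center distance (no argmax recorded) excludes
    the pair.  ``transient`` is set when the pair's DCC is below
    ``transient_dcc_max`` or undefined.
    """
    G = nx.Graph()
    for idx, label in enumerate(rmap.residues):
        chain, _, resid = label.partition(":")
        G.add_node(label, chain=chain, resid=resid, order=idx)
    for (a, b), info in rmap.argmax.items():
        val = rmap.mdcc[a, b]
        if not np.isfinite(val) or val < mdcc_min:
            continue
        if not info["center_distance"] < dist_max:
            continue
        dcc = float(rmap.dcc[a, b])
        G.add_edge(rmap.residues[a], rmap.residues[b],
                   mdcc=float(val), dcc=dcc,
                   transient=bool(not dcc >= transient_dcc_max),
                   distance=float(info["center_distance"]))
    return G


def betweenness(G: nx.Graph) -> dict:
    """Unnormalised betweenness over unordered pairs, endpoints excluded.

    Disconnected pairs contribute nothing.  Values are also stored on the
    nodes as the ``betweenness`` attribute.
    """
    vals = nx.betweenness_centrality(G, normalized=False)
    nx.set_node_attributes(G, vals, "betweenness")
    return vals


def _top_nodes(G: nx.Graph, percent: float) -> list:
    """Top-percent nodes by betweenness, boundary ties included."""
    if G.number_of_nodes() == 0:
        return []
    bt = nx.get_node_attributes(G, "betweenness") or betweenness(G)
    n_take = math.ceil(percent / 100.0 * G.number_of_nodes())
    n_take = min(max(n_take, 0), G.number_of_nodes())
    if n_take == 0:
        return []
    ranked = sorted(bt.items(), key=lambda kv: (-kv[1], kv[0]))
    boundary = ranked[n_take - 1][1]
    # all nodes tying with the boundary value are included
    return [node for node, v in ranked if v >= boundary - 1e-12]


def top_percent_subnetwork(G: nx.Graph, percent: float = 20.0) -> nx.Graph:
    """Induced subgraph on the top-percent betweenness nodes.

    Nodes tying with the boundary value are all included (deterministic,
    seed-free).  Nodes left without edges are kept out of the subgraph but
    listed in ``graph['isolated']`` metadata.
    """
    top = _top_nodes(G, percent)
    sub = G.subgraph(top).copy()
    isolated = [n for n in sub.nodes if sub.degree(n) == 0]
    sub.remove_nodes_from(isolated)
    sub.graph["isolated"] = isolated
    sub.graph["selected"] = list(top)
    return sub


def core_network(G: nx.Graph, percent: float = 5.0) -> nx.Graph:
    """Top-percent nodes plus all nodes/edges on shortest paths among them.

    For every unordered pair of top nodes in the same component, every
    shortest path contributes its nodes and edges.  Pairs in different
    components are skipped.
    """
    top = _top_nodes(G, percent)
    nodes = set(top)
    edges = set()
    for i, s in enumerate(top):
        for t in top[i + 1:]:
            if not nx.has_path(G, s, t):
                continue
            for path in nx.all_shortest_paths(G, s, t):
                nodes.update(path)
                edges.update(frozenset(e) for e in zip(path[:-1], path[1:]))
    core = nx.Graph()
    for n in nodes:
        core.add_node(n, **G.nodes[n])
    for e in edges:
        u, v = tuple(e)
        core.add_edge(u, v, **G.edges[u, v])
    core.graph["top_nodes"] = list(top)
    return core


def compare_networks(net_a: nx.Graph, net_b: nx.Graph) -> pd.DataFrame:
    """Edge difference table between two residue networks.

    One row per edge present in either network, with mDCC in each, the
    difference (b - a), and a presence flag ``both`` / ``a_only`` /
    ``b_only``.
    """
    shared_universe = set(net_a.nodes) & set(net_b.nodes)
    if not shared_universe:
        import warnings
        warnings.warn("compare_networks: node universes are disjoint")
    pairs = {frozenset(e) for e in net_a.edges} | \
            {frozenset(e) for e in net_b.edges}
    rows = []
    for e in sorted(pairs, key=lambda s: tuple(sorted(s))):
        u, v = tuple(sorted(e))
        in_a = net_a.has_edge(u, v)
        in_b = net_b.has_edge(u, v)
        ma = net_a.edges[u, v]["mdcc"] if in_a else float("nan")
        mb = net_b.edges[u, v]["mdcc"] if in_b else float("nan")
        rows.append((u, v, ma, mb, mb - ma,
                     "both" if in_a and in_b else ("a_only" if in_a
                                                   else "b_only")))
    return pd.DataFrame(rows, columns=["res_a", "res_b", "mdcc_a", "mdcc_b",
                                       "delta_mdcc", "presence"])


def export_graph(G: nx.Graph, path, fmt: str = "graphml") -> None:
    """GraphML (node: chain, resid, betweenness; edge: mdcc, dcc, transient,
    distance) or a flat edge TSV."""
    if fmt == "graphml":
        H = G.copy()
        H.graph.clear()  # graphml cannot serialise list-valued metadata
        nx.write_graphml(H, path)
    elif fmt == "edge-tsv":
        rows = [(u, v, d.get("mdcc"), d.get("dcc"), d.get("transient"),
                 d.get("distance")) for u, v, d in G.edges(data=True)]
        pd.DataFrame(rows, columns=["res_a", "res_b", "mdcc", "dcc",
                                    "transient", "distance"]).to_csv(
            path, sep="\t", index=False, na_rep="NA", float_format="%.12g")
    else:
        raise ValueError(f"unknown graph format: {fmt!r}")


def read_graph(path) -> nx.Graph:
    """Parse back a GraphML file written by :func:`export_graph`."""
    return nx.read_graphml(path)
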