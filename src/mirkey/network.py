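"""Interaction-network filtering, core extraction, twelve topological
centralities, and consensus hub voting.

The pipeline mirrors the classic STRING/cytoHubba workflow: drop edges
below a confidence score of 0.7, keep the largest connected component,
extract the nodes whose degree and (raw, unnormalized) betweenness both
exceed the network averages, score every node with twelve centrality
algorithms, and call "hub" any gene appearing in at least two of the
twelve top-20 lists.

Centrality definitions (the cytoHubba set)
------------------------------------------
Degree              number of incident edges.
Betweenness         sum over pairs of the fraction of shortest paths
                    through v (unnormalized).
Stress              count of shortest paths through v.
Closeness           (n-1) / sum of distances from v.
EcCentricity        1 / eccentricity(v).
Radiality           sum_w (diam + 1 - d(v, w)) / (n - 1).
ClusteringCoefficient  2 e(N(v)) / deg(v)(deg(v)-1); 0 when deg < 2.
MNC                 size of the largest connected component of the
                    subgraph induced by the neighbours of v.
DMNC                |E| / |V|^1.7 of that same component.
MCC                 sum over maximal cliques C containing v of (|C|-1)!.
EPC                 mean size of v's component over seeded random edge
                    subgraphs (each edge kept with probability 1/2).
BottleNeck          one point per BFS shortest-path tree (first-discovered
                    parent, neighbours in sorted order) in which more than
                    n/4 nodes route through v.

Graph container: ``networkx.Graph`` with a ``score`` edge attribute in
[0, 1]; the standard centralities are delegated to networkx, the
cytoHubba-specific ones are implemented here.
"""

from __future__ import annotations

import math
import warnings
from collections import deque
from dataclasses import dataclass

import networkx as nx
import numpy as np
import pandas as pd
from scipy.sparse import csr_matrix
from scipy.sparse.csgraph import connected_components

__all__ = [
    "ALGORITHMS",
    "filter_edges",
    "main_component",
    "degree_betweenness_core",
    "centralities",
    "consensus_hubs",
    "ConsensusHubs",
]

ALGORITHMS = (
    "Degree",
    "EPC",
    "MNC",
    "DMNC",
    "MCC",
    "BottleNeck",
    "EcCentricity",
    "Closeness",
    "Radiality",
    "Betweenness",
    "ClusteringCoefficient",
    "Stress",
)

DMNC_EPS = 1.7  # exponent of the DMNC denominator


def filter_edges(g: nx.Graph, min_score: float = 0.7) -> nx.Graph:
    """Remove edges with confidence score below ``min_score``; nodes stay."""
    out = nx.Graph()
    out.add_nodes_from(g.nodes(data=True))
    for u, v, data in g.edges(data=True):
        score = data.get("score", 1.0)
        if not 0.0 <= score <= 1.0:
            raise ValueError(f"edge score out of [0,1]: {score}")
        if score >= min_score:
            out.add_edge(u, v, **data)
    return out


def main_component(g: nx.Graph) -> nx.Graph:
    """Largest connected component (ties: more edges, then smallest node set)."""
    if g.number_of_nodes() == 0:
        return g.copy()
    comps = [set(c) for c in nx.connected_components(g)]
    comps.sort(key=lambda c: (-len(c), -g.subgraph(c).number_of_edges(), sorted(c)))
    return g.subgraph(comps[0]).copy()


def degree_betweenness_core(g: nx.Graph) -> tuple[nx.Graph, float, float]:
    """Induced subgraph on nodes with degree AND raw betweenness strictly
    above the input graph's averages. Returns (core, mean_degree,
    mean_betweenness)."""
    if not nx.is_connected(g):
        raise ValueError("core extraction expects a connected graph")
    deg = dict(g.degree())
    btw = nx.betweenness_centrality(g, normalized=False)
    mean_deg = float(np.mean(list(deg.values())))
    mean_btw = float(np.mean(list(btw.values())))
    keep = [v for v in g if deg[v] > mean_deg and btw[v] > mean_btw]
    if not keep:
        raise ValueError(
            "degree/betweenness core is empty (all nodes at or below the "
            "averages); relax the thresholds or inspect the graph"
        )
    return g.subgraph(keep).copy(), mean_deg, mean_btw


# ---------------------------------------------------------------------------
# cytoHubba-specific centralities


def _stress(g: nx.Graph, nodes: list) -> dict:
    """Shortest-path counts through each node, via distance and sigma
    matrices: sigma_st(v) = sigma_sv * sigma_vt when d(sv)+d(vt)=d(st)."""
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    D = np.full((n, n), np.inf)
    S = np.zeros((n, n))
    for s in nodes:
        si = idx[s]
        dist = {s: 0}
        sigma = {s: 1.0}
        q = deque([s])
        while q:
            u = q.popleft()
            for w in g[u]:
                if w not in dist:
                    dist[w] = dist[u] + 1
                    sigma[w] = sigma[u]
                    q.append(w)
                elif dist[w] == dist[u] + 1:
                    sigma[w] += sigma[u]
        for w, d in dist.items():
            D[si, idx[w]] = d
            S[si, idx[w]] = sigma[w]
    stress = {}
    for v in nodes:
        vi = idx[v]
        on_path = (D[:, vi][:, None] + D[vi, :][None, :]) == D
        cnt = S[:, vi][:, None] * S[vi, :][None, :] * on_path
        cnt[vi, :] = 0
        cnt[:, vi] = 0
        np.fill_diagonal(cnt, 0)
        stress[v] = float(cnt.sum() / 2.0)  # each unordered pair once
    return stress


def _mnc_dmnc(g: nx.Graph, nodes: list) -> tuple[dict, dict]:
    mnc, dmnc = {}, {}
    for v in nodes:
        nb = list(g[v])
        if not nb:
            mnc[v], dmnc[v] = 0, 0.0
            continue
        sub = g.subgraph(nb)
        comp = max(nx.connected_components(sub), key=lambda c: (len(c), sorted(c)))
        comp_g = sub.subgraph(comp)
        mnc[v] = comp_g.number_of_nodes()
        dmnc[v] = comp_g.number_of_edges() / comp_g.number_of_nodes() ** DMNC_EPS
    return mnc, dmnc


def _mcc(g: nx.Graph, nodes: list) -> dict:
    mcc = {v: 0.0 for v in nodes}
    for clique in nx.find_cliques(g):
        w = math.factorial(len(clique) - 1)
        for v in clique:
            mcc[v] += w
    return mcc


def _epc(g: nx.Graph, nodes: list, rng: np.random.Generator, n_samples: int) -> dict:
    n = len(nodes)
    idx = {v: i for i, v in enumerate(nodes)}
    edges = np.array([(idx[u], idx[v]) for u, v in g.edges()], dtype=np.int64)
    if len(edges) == 0:
        return {v: 1.0 for v in nodes}
    total = np.zeros(n)
    for _ in range(n_samples):
        keep = rng.random(len(edges)) < 0.5
        kept = edges[keep]
        data = np.ones(len(kept))
        m = csr_matrix((data, (kept[:, 0], kept[:, 1])), shape=(n, n))
        _, labels = connected_components(m, directed=False)
        sizes = np.bincount(labels)
        total += sizes[labels]
    return {v: float(total[idx[v]] / n_samples) for v in nodes}


def _bottleneck(g: nx.Graph, nodes: list) -> dict:
    n = len(nodes)
    score = {v: 0 for v in nodes}
    for s in nodes:
        parent = {s: None}
        order = [s]
        q = deque([s])
        while q:
            u = q.popleft()
            for w in sorted(g[u]):
                if w not in parent:
                    parent[w] = u
                    order.append(w)
                    q.append(w)
        desc = {v: 0 for v in parent}
        for w in reversed(order):
            p = parent[w]
            if p is not None:
                desc[p] += desc[w] + 1
        for v, d in desc.items():
            if d > n / 4.0:
                score[v] += 1
    return score


def centralities(
    g: nx.Graph,
    seed: int | np.random.Generator = 0,
    epc_samples: int = 1000,
) -> pd.DataFrame:
    """All twelve centrality scores per node (rows: nodes, columns:
    algorithms). Requires a connected graph with at least 3 nodes; the EPC
    resampling uses the given seed."""
    if g.number_of_nodes() < 3:
        raise ValueError("centralities need at least 3 nodes")
    if not nx.is_connected(g):
        raise ValueError("centralities require a connected graph")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    nodes = sorted(g.nodes())
    n = len(nodes)

    ecc = nx.eccentricity(g)
    diam = max(ecc.values())
    dist = dict(nx.all_pairs_shortest_path_length(g))
    radiality = {
        v: sum(diam + 1 - dist[v][w] for w in nodes if w != v) / (n - 1) for v in nodes
    }
    btw = nx.betweenness_centrality(g, normalized=False)
    mnc, dmnc = _mnc_dmnc(g, nodes)

    cols = {
        "Degree": {v: float(g.degree(v)) for v in nodes},
        "EPC": _epc(g, nodes, rng, epc_samples),
        "MNC": {v: float(mnc[v]) for v in nodes},
        "DMNC": dmnc,
        "MCC": _mcc(g, nodes),
        "BottleNeck": {v: float(s) for v, s in _bottleneck(g, nodes).items()},
        "EcCentricity": {v: 1.0 / ecc[v] for v in nodes},
        "Closeness": nx.closeness_centrality(g),
        "Radiality": radiality,
        "Betweenness": btw,
        "ClusteringCoefficient": nx.clustering(g),
        "Stress": _stress(g, nodes),
    }
    return pd.DataFrame({a: [cols[a][v] for v in nodes] for a in ALGORITHMS}, index=nodes)


@dataclass
class ConsensusHubs:
    """Per-gene count of top-k centrality lists containing it."""

    counts: pd.Series  # gene -> number of algorithms (0..12)
    min_count: int

    @property
    def hubs(self) -> list[str]:
        s = self.counts[self.counts >= self.min_count]
        return sorted(s.index, key=lambda v: (-s[v], str(v)))

    def table(self) -> pd.DataFrame:
        df = pd.DataFrame({"gene": self.counts.index, "count": self.counts.values})
        df = df.sort_values(["count", "gene"], ascending=[False, True])
        df["hub"] = df["count"] >= self.min_count
        return df.reset_index(drop=True)


def consensus_hubs(
    table: pd.DataFrame, top_k: int = 20, min_count: int = 2
) -> ConsensusHubs:
    """Vote hubs from per-algorithm top-k membership.

    For each algorithm the top-k nodes by score are taken, with every node
    tied at the k-th score included; a gene is a hub when it appears in at
    least ``min_count`` lists.
    """
    counts = pd.Series(0, index=table.index, dtype=int)
    for alg in table.columns:
        scores = table[alg].sort_values(ascending=False)
        if len(scores) <= top_k:
            members = scores.index
        else:
            cutoff = scores.iloc[top_k - 1]
            members = scores[scores >= cutoff].index
        counts[members] += 1
    return ConsensusHubs(counts, min_count)
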