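"""Pathway-crosstalk network construction, MCODE clustering, and the
hub-gene x pathway bipartite core.

Two enriched pathways are linked when they share genes; the edge carries
the Jaccard coefficient JC = |A∩B|/|A∪B|, the overlap (Szymkiewicz–Simpson)
coefficient OC = |A∩B|/min(|A|,|B|), and their mean as weight. Pathways
with fewer than three genes and pairs sharing fewer than two genes are
excluded. The resulting topology is clustered with the Bader–Hogue MCODE
procedure (vertex weighting by the density of the highest k-core of the
closed neighbourhood, seed-and-grow with a vertex-weight percentage
cutoff, optional haircut); clusters scoring above 4 (density x size) are
retained. Hub genes are then mapped into the retained pathways as a
bipartite network whose above-average-degree nodes form the gene/pathway
core.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .enrich import GeneSetCollection

__all__ = [
    "jaccard",
    "overlap_coef",
    "build_crosstalk",
    "Cluster",
    "mcode",
    "map_gene_pathway",
    "select_core",
]


def jaccard(A, B) -> float:
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("Jaccard coefficient undefined for an empty set")
    return len(A & B) / len(A | B)


def overlap_coef(A, B) -> float:
    A, B = set(A), set(B)
    if not A or not B:
        raise ValueError("overlap coefficient undefined for an empty set")
    return len(A & B) / min(len(A), len(B))


def build_crosstalk(
    pathways: GeneSetCollection,
    min_genes: int = 3,
    min_shared: int = 2,
) -> nx.Graph:
    """Crosstalk graph over pathways with >= ``min_genes`` genes; an edge
    joins pairs sharing >= ``min_shared`` genes, attributed with jc, oc,
    weight = (jc+oc)/2 and the shared gene list."""
    kept = {p: set(g) for p, g in pathways.sets.items() if len(g) >= min_genes}
    net = nx.Graph()
    for p, genes in kept.items():
        net.add_node(p, genes=frozenset(genes))
    names = sorted(kept)
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            shared = kept[a] & kept[b]
            if len(shared) < min_shared:
                continue
            jc = jaccard(kept[a], kept[b])
            oc = overlap_coef(kept[a], kept[b])
            net.add_edge(a, b, jc=jc, oc=oc, weight=(jc + oc) / 2.0,
                         shared_genes=frozenset(shared))
    if net.number_of_nodes() < 2:
        warnings.warn("crosstalk network has fewer than 2 pathways")
    return net


@dataclass(frozen=True)
class Cluster:
    members: tuple
    n_nodes: int
    n_edges: int
    density: float
    score: float
    retained: bool


def _vertex_weights(g: nx.Graph) -> dict:
    """MCODE weighting: density of the highest k-core of G[N[v]] times its
    core level; isolated vertices weigh 0."""
    w = {}
    for v in g:
        nbhd = set(g[v]) | {v}
        sub = g.subgraph(nbhd)
        if sub.number_of_edges() == 0:
            w[v] = 0.0
            continue
        core_num = nx.core_number(sub)
        kmax = max(core_num.values())
        core_nodes = [u for u, c in core_num.items() if c >= kmax]
        core = sub.subgraph(core_nodes)
        nn = core.number_of_nodes()
        dens = (
            2.0 * core.number_of_edges() / (nn * (nn - 1)) if nn > 1 else 0.0
        )
        w[v] = kmax * dens
    return w


def _graph_density(g: nx.Graph) -> float:
    n = g.number_of_nodes()
    return 2.0 * g.number_of_edges() / (n * (n - 1)) if n > 1 else 0.0


def mcode(
    net: nx.Graph,
    vwp: float = 0.2,
    haircut: bool = True,
    fluff: bool = False,
    min_score: float = 4.0,
    min_cluster_size: int = 3,
) -> list[Cluster]:
    """Bader–Hogue MCODE complex prediction on an unweighted topology.

    Seeds are taken in decreasing vertex weight; growth admits unseen
    neighbours whose weight is >= (1 - vwp) x seed weight. Haircut removes
    members of degree < 2 within the cluster (iteratively, i.e. the
    cluster 2-core). Cluster score = density x size; clusters are
    ``retained`` when score > ``min_score``. Fluff is accepted for
    interface parity but not applied.
    """
    if fluff:
        warnings.warn("fluff is not implemented; ignoring")
    weights = _vertex_weights(net)
    seen: set = set()
    clusters = []
    for seed in sorted(net.nodes, key=lambda v: (-weights[v], str(v))):
        if seed in seen or weights[seed] <= 0:
            continue
        threshold = weights[seed] * (1.0 - vwp)
        members = {seed}
        frontier = [seed]
        while frontier:
            u = frontier.pop()
            for w in net[u]:
                if w in seen or w in members:
                    continue
                if weights[w] >= threshold:
                    members.add(w)
                    frontier.append(w)
        seen |= members
        sub = net.subgraph(members).copy()
        if haircut:
            sub = nx.k_core(sub, 2)
        if sub.number_of_nodes() < min_cluster_size:
            continue
        dens = _graph_density(sub)
        score = dens * sub.number_of_nodes()
        clusters.append(
            Cluster(
                tuple(sorted(sub.nodes())),
                sub.number_of_nodes(),
                sub.number_of_edges(),
                dens,
                score,
                score > min_score,
            )
        )
    clusters.sort(key=lambda c: (-c.score, c.members))
    return clusters


def map_gene_pathway(
    hub_genes,
    cluster_pathways,
    membership: GeneSetCollection,
) -> nx.Graph:
    """Bipartite gene/pathway membership network.

    One edge per (hub gene, retained-cluster pathway) pair where the
    pathway contains the gene; genes without any membership are dropped,
    pathways are kept (possibly isolated) so the pathway side stays
    inspectable.
    """
    net = nx.Graph()
    pws = list(cluster_pathways)
    for p in pws:
        net.add_node(p, role="pathway")
    for gene in sorted(set(hub_genes)):
        edges = [p for p in pws if gene in membership[p]]
        if not edges:
            continue
        net.add_node(gene, role="gene")
        for p in edges:
            net.add_edge(gene, p)
    return net


def select_core(net: nx.Graph) -> tuple[list, list]:
    """Nodes with degree strictly above the pooled mean degree, split into
    (genes, pathways)."""
    if net.number_of_nodes() == 0:
        raise ValueError("empty gene-pathway network")
    degs = dict(net.degree())
    mean_deg = float(np.mean(list(degs.values())))
    genes = sorted(
        v for v, d in net.nodes(data=True)
        if d.get("role") == "gene" and degs[v] > mean_deg
    )
    pathways = sorted(
        v for v, d in net.nodes(data=True)
        if d.get("role") == "pathway" and degs[v] > mean_deg
    )
    return genes, pathways
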