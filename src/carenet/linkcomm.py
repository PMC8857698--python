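"""Overlapping community detection by link (edge) clustering.

Nodes in care-team networks genuinely belong to several teams at once, so
communities are detected on *edges*: adjacent edges are scored with the
weighted Tanimoto similarity of the inclusive neighborhoods of their
non-shared endpoints, the edges are clustered hierarchically with WPGMA
(McQuitty) linkage on distance 1 - S, and the dendrogram is cut at the
height that maximizes the partition density

    D = (2/M) * sum_c m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1)),

where M is the total edge count and m_c, n_c are the edge and node counts
of community c (communities spanning only two nodes contribute zero).  Each
node inherits the communities of its incident edges, with pie fractions
giving the proportion of its edges per community.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import squareform

from .errors import ContractError
from .network import CollabNetwork

Edge = tuple[str, str]


def _canonical_edges(graph) -> list[Edge]:
    return sorted(tuple(sorted(e)) for e in graph.edges())


def edge_similarity(network: CollabNetwork) -> dict[tuple[Edge, Edge], float]:
    """Weighted Tanimoto similarity for every pair of adjacent edges.

    For edges e = (i, k) and f = (j, k) sharing node k,

        S(e, f) = (a_i . a_j) / (|a_i|^2 + |a_j|^2 - a_i . a_j)

    where a_i is i's weight vector over its inclusive neighborhood, with the
    self-entry a_i(i) set to the mean weight of i's incident edges.  With
    uniform weights this reduces to the Jaccard index of the inclusive
    neighborhoods.  Non-adjacent edge pairs are absent (similarity 0).
    """
    g = network.graph
    # inclusive-neighborhood weight vectors and their squared norms
    vec: dict[str, dict[str, float]] = {}
    norm2: dict[str, float] = {}
    for i in g.nodes:
        if g.degree(i) == 0:
            continue
        weights = {nbr: d["weight"] for nbr, d in g[i].items()}
        weights[i] = sum(weights.values()) / len(weights)
        vec[i] = weights
        norm2[i] = sum(w * w for w in weights.values())

    sims: dict[tuple[Edge, Edge], float] = {}
    for k in g.nodes:
        nbrs = sorted(g[k])
        for x in range(len(nbrs)):
            for y in range(x + 1, len(nbrs)):
                i, j = nbrs[x], nbrs[y]
                e = tuple(sorted((i, k)))
                f = tuple(sorted((j, k)))
                if e == f:
                    raise ContractError(f"parallel edges detected at {e}")
                ai, aj = vec[i], vec[j]
                small, large = (ai, aj) if len(ai) <= len(aj) else (aj, ai)
                dot = sum(w * large[u] for u, w in small.items() if u in large)
                s = dot / (norm2[i] + norm2[j] - dot)
                key = (e, f) if e < f else (f, e)
                # two edges can share two different nodes only via parallel
                # edges, so each adjacent pair is scored exactly once
                sims[key] = s
    return sims


@dataclass
class EdgeDendrogram:
    """WPGMA merge tree over the edges of one network."""

    leaves: list[Edge]  # canonical (sorted) edge order
    merges: np.ndarray  # scipy linkage matrix, shape (n_leaves - 1, 4)

    @property
    def heights(self) -> np.ndarray:
        return self.merges[:, 2] if len(self.merges) else np.array([])


def cluster_edges_wpgma(
    similarity: dict[tuple[Edge, Edge], float], network: CollabNetwork
) -> EdgeDendrogram:
    """Agglomerate edges with WPGMA (McQuitty) linkage on d = 1 - S.

    Pairs without a similarity entry (non-adjacent edges) sit at distance 1,
    so disconnected parts of the edge-similarity graph join at height 1.
    Leaves are in canonical sorted-edge order, which fixes tie-breaking and
    makes the dendrogram independent of input edge order.
    """
    edges = _canonical_edges(network.graph)
    m = len(edges)
    if m == 0:
        raise ContractError("cannot cluster an empty edge set")
    if m == 1:
        return EdgeDendrogram(leaves=edges, merges=np.empty((0, 4)))
    index = {e: i for i, e in enumerate(edges)}
    dist = np.ones((m, m))
    np.fill_diagonal(dist, 0.0)
    for (e, f), s in similarity.items():
        i, j = index[e], index[f]
        dist[i, j] = dist[j, i] = 1.0 - s
    z = linkage(squareform(dist, checks=False), method="weighted")
    return EdgeDendrogram(leaves=edges, merges=z)


def partition_density(network: CollabNetwork, edge_partition: list[list[Edge]]):
    """Partition density D and each community's contribution term.

    The per-community term is m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1));
    communities with exactly two nodes (single edges, or multi-edges on two
    nodes) contribute zero.
    """
    M = network.graph.number_of_edges()
    covered = sum(len(c) for c in edge_partition)
    if covered != M:
        raise ContractError(
            f"edge partition covers {covered} edges but the network has {M}"
        )
    terms = []
    for community in edge_partition:
        m_c = len(community)
        nodes = {u for e in community for u in e}
        n_c = len(nodes)
        if m_c >= 1 and n_c < 2:
            raise ContractError("community with edges but fewer than 2 nodes")
        if n_c <= 2:
            terms.append(0.0)
        else:
            terms.append(m_c * (m_c - (n_c - 1)) / ((n_c - 2) * (n_c - 1)))
    d = (2.0 / M) * sum(terms) if M else 0.0
    return d, terms


@dataclass
class Community:
    community_id: int
    edges: list[Edge]
    nodes: tuple[str, ...]

    @property
    def m(self) -> int:
        return len(self.edges)

    @property
    def n(self) -> int:
        return len(self.nodes)


@dataclass
class LinkCommunityResult:
    """Communities, memberships and the density profile for one network."""

    cut_height: float
    partition_density_value: float
    communities: list[Community]
    background_edges: list[Edge]  # single-edge clusters at the chosen cut
    density_profile: list[tuple[float, float]]  # (height, D)
    node_memberships: dict[str, tuple[int, ...]]
    pie_fractions: dict[str, dict[str, float]]  # community id (str) or "background"
    n_edges: int

    def roles_in_all_communities(self) -> tuple[str, ...]:
        k = len(self.communities)
        if k == 0:
            return ()
        return tuple(
            sorted(n for n, mem in self.node_memberships.items() if len(mem) == k)
        )

    def to_dict(self) -> dict:
        return {
            "cut_height": self.cut_height,
            "partition_density": self.partition_density_value,
            "n_communities": len(self.communities),
            "communities": [
                {
                    "id": c.community_id,
                    "n_edges": c.m,
                    "nodes": list(c.nodes),
                    "edges": [list(e) for e in c.edges],
                }
                for c in self.communities
            ],
            "background_edges": [list(e) for e in self.background_edges],
            "density_profile": [[h, d] for h, d in self.density_profile],
            "node_memberships": {n: list(m) for n, m in sorted(self.node_memberships.items())},
            "pie_fractions": {
                n: dict(sorted(f.items())) for n, f in sorted(self.pie_fractions.items())
            },
        }


def _partitions_of(dendrogram: EdgeDendrogram):
    """All distinct flat partitions of the dendrogram: the all-singletons
    partition plus the partition after the merges at each distinct height."""
    m = len(dendrogram.leaves)
    yield 0.0, np.arange(1, m + 1)
    if not len(dendrogram.merges):
        return
    # evaluate just above each distinct merge height; heights closer than the
    # tolerance are treated as a single level
    for h in np.unique(dendrogram.heights):
        yield float(h), fcluster(
            dendrogram.merges, t=float(h) + 1e-9, criterion="distance"
        )


def cut_at_max_density(
    dendrogram: EdgeDendrogram, network: CollabNetwork
) -> LinkCommunityResult:
    """Cut the edge dendrogram at the height maximizing partition density.

    Ties prefer the cut with more communities (the finer partition).
    Clusters with at least two edges are reported as communities; single-edge
    clusters are background.  Node memberships and pie fractions are derived
    from the reported communities.
    """
    edges = dendrogram.leaves
    best = None  # (D, n_clusters, height, labels)
    profile = []
    for h, labels in _partitions_of(dendrogram):
        clusters: dict[int, list[Edge]] = {}
        for e, lab in zip(edges, labels):
            clusters.setdefault(int(lab), []).append(e)
        d, _ = partition_density(network, list(clusters.values()))
        profile.append((h, d))
        d_r = round(d, 12)
        cand = (d_r, len(clusters), -h, labels)
        if best is None or cand[:3] > best[:3]:
            best = cand
    assert best is not None
    _, _, neg_h, labels = best
    cut_height = -neg_h

    clusters: dict[int, list[Edge]] = {}
    for e, lab in zip(edges, labels):
        clusters.setdefault(int(lab), []).append(e)
    multi = sorted(
        (c for c in clusters.values() if len(c) >= 2),
        key=lambda c: (-len(c), c[0]),
    )
    background = sorted(e for c in clusters.values() if len(c) == 1 for e in c)
    communities = []
    for cid, cluster_edges in enumerate(multi):
        nodes = tuple(sorted({u for e in cluster_edges for u in e}))
        communities.append(Community(community_id=cid, edges=sorted(cluster_edges), nodes=nodes))

    d_value, _ = partition_density(network, [c.edges for c in communities] + [[e] for e in background])

    incident: dict[str, list[str]] = {}
    for cid, comm in enumerate(communities):
        for e in comm.edges:
            for u in e:
                incident.setdefault(u, []).append(str(cid))
    for e in background:
        for u in e:
            incident.setdefault(u, []).append("background")

    node_memberships = {
        n: tuple(sorted({int(c) for c in labs if c != "background"}))
        for n, labs in incident.items()
    }
    pie_fractions = {}
    for n, labs in incident.items():
        total = len(labs)
        fr: dict[str, float] = {}
        for lab in labs:
            fr[lab] = fr.get(lab, 0.0) + 1.0 / total
        pie_fractions[n] = fr

    return LinkCommunityResult(
        cut_height=cut_height,
        partition_density_value=d_value,
        communities=communities,
        background_edges=background,
        density_profile=profile,
        node_memberships=node_memberships,
        pie_fractions=pie_fractions,
        n_edges=len(edges),
    )


def detect_link_communities(network: CollabNetwork) -> LinkCommunityResult:
    """Similarity -> WPGMA -> max-density cut, in one call."""
    sims = edge_similarity(network)
    dend = cluster_edges_wpgma(sims, network)
    return cut_at_max_density(dend, network)
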