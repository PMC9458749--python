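"""Synthetic topologies, basic-motif census, and clustering rewiring.

Graphs are plain :class:`networkx.Graph` objects with contiguous integer
node ids 0..N-1 (``validate_network`` checks the convention).  Basic motifs
are convex n-gons: edges (n = 2), triangles (n = 3), squares (n = 4) and
pentagons (n = 5).  Squares and pentagons are counted as chordless
(induced) cycles so that a chorded 4-cycle is attributed to its triangles
rather than double-counted as a square.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import networkx as nx
import numpy as np

from .errors import FeasibilityError, ParameterError

__all__ = [
    "MotifCensus",
    "validate_network",
    "adjacency",
    "degrees",
    "generate_er",
    "generate_small_world",
    "local_star",
    "embedded_star",
    "chain_with_degrees",
    "random_degree_sequence",
    "motif_census",
    "independent_edges_wrt_source",
    "triangles_through_edge",
    "rewire_to_clustering",
]


def validate_network(G: nx.Graph) -> nx.Graph:
    """Check the package's graph convention: simple, undirected, 0..N-1 ids."""
    if G.is_directed() or G.is_multigraph():
        raise ParameterError("network must be a simple undirected graph")
    n = G.number_of_nodes()
    if set(G.nodes()) != set(range(n)):
        raise ParameterError("node ids must be the contiguous integers 0..N-1")
    if any(u == v for u, v in G.edges()):
        raise ParameterError("self-loops are not allowed")
    return G


def adjacency(G: nx.Graph):
    """CSR adjacency matrix in node-id order."""
    return nx.to_scipy_sparse_array(G, nodelist=sorted(G.nodes()), format="csr").astype(float)


def degrees(G: nx.Graph) -> np.ndarray:
    return np.array([G.degree(i) for i in sorted(G.nodes())], dtype=float)


# --- generators -----------------------------------------------------------

def generate_er(n: int, p: float, seed: int, largest_component: bool = False) -> nx.Graph:
    """Erdos-Renyi G(n, p), reproducible for a given seed."""
    if not 0 <= p <= 1:
        raise ParameterError(f"link probability must lie in [0, 1], got {p}")
    if n < 2:
        raise ParameterError("need at least two nodes")
    G = nx.fast_gnp_random_graph(n, p, seed=seed)
    if largest_component and G.number_of_edges() > 0:
        cc = max(nx.connected_components(G), key=len)
        G = nx.convert_node_labels_to_integers(G.subgraph(cc).copy(), ordering="sorted")
    return G


def generate_small_world(n: int, k: int, beta: float, seed: int) -> nx.Graph:
    """Watts-Strogatz ring lattice with per-edge rewiring probability beta."""
    if k % 2 != 0:
        raise ParameterError("neighbour count k must be even")
    if k >= n:
        raise ParameterError("k must be smaller than n")
    if not 0 <= beta <= 1:
        raise ParameterError("rewiring probability must lie in [0, 1]")
    return nx.watts_strogatz_graph(n, k, beta, seed=seed)


def local_star(d: int, kind: str = "edges") -> tuple[nx.Graph, int, int]:
    """Source-target pair with d local motifs at the target.

    ``kind='edges'``: source m - target i edge plus d leaves on i, so the
    target carries d independent edges (degree d + 1).
    ``kind='triangles'``: d triangles hang off the target, each a pair
    (u_k, v_k) with edges i-u_k, i-v_k, u_k-v_k.
    ``kind='source_triangles'``: d triangles through the source-target edge
    itself — d common neighbours of m and i, the configuration in which the
    triangle correction to the response time operates.

    Returns (graph, source, target).
    """
    if d < 1:
        raise ParameterError("need d >= 1")
    G = nx.Graph()
    m, i = 0, 1
    G.add_edge(m, i)
    nxt = 2
    for _ in range(d):
        if kind == "edges":
            G.add_edge(i, nxt)
            nxt += 1
        elif kind == "triangles":
            u, v = nxt, nxt + 1
            G.add_edges_from([(i, u), (i, v), (u, v)])
            nxt += 2
        elif kind == "source_triangles":
            G.add_edges_from([(i, nxt), (m, nxt)])
            nxt += 1
        else:
            raise ParameterError(f"unknown star kind {kind!r}")
    return G, m, i


def embedded_star(
    d: int,
    kind: str,
    bulk_n: int,
    bulk_degree: float,
    seed: int,
    source_in_bulk: bool = False,
) -> tuple[nx.Graph, int, int]:
    """A degree-d target embedded in an Erdos-Renyi bulk.

    The target i is a fresh node wired to d bulk nodes drawn without
    replacement (nested across d for a fixed seed, so sweeps over d share
    their random environment).  ``kind='edges'`` attaches the source m to i
    alone; ``kind='triangles'`` additionally links m to each of i's bulk
    neighbours, placing d triangles on the m-i edge.  With
    ``source_in_bulk`` the source is a random bulk node instead of a leaf.

    This is the fixture on which the mean-field premise of the local
    response theory holds: the target's neighbours sit in a bulk whose
    steady states do not depend on the target degree being swept.
    """
    if d < 1:
        raise ParameterError("need d >= 1")
    G = generate_er(bulk_n, bulk_degree / (bulk_n - 1), seed=seed, largest_component=True)
    n = G.number_of_nodes()
    if d > n:
        raise ParameterError(f"d={d} exceeds bulk size {n}")
    rng = np.random.default_rng(seed + 1)
    order = rng.permutation(n)
    targets = order[:d]
    i = n
    if source_in_bulk:
        m = int(order[-1])
    else:
        m = n + 1
    G.add_edge(m, i)
    for h in targets:
        G.add_edge(i, int(h))
        if kind == "triangles":
            G.add_edge(m, int(h))
    return G, m, i


def chain_with_degrees(degrees_seq: Sequence[int]) -> tuple[nx.Graph, int, list[int]]:
    """Backbone path whose node k is padded with leaves to degree degrees_seq[k].

    Returns (graph, source, backbone path); the source is the first
    backbone node.
    """
    degrees_seq = [int(d) for d in degrees_seq]
    k = len(degrees_seq)
    if k < 2:
        raise ParameterError("need at least two chain nodes")
    G = nx.path_graph(k)
    nxt = k
    for node, want in enumerate(degrees_seq):
        backbone = 1 if node in (0, k - 1) else 2
        extra = want - backbone
        if extra < 0:
            raise FeasibilityError(
                f"chain node {node} needs degree >= {backbone}, got {want}"
            )
        for _ in range(extra):
            G.add_edge(node, nxt)
            nxt += 1
    return G, 0, list(range(k))


def random_degree_sequence(
    length: int, mean: float, variance: float, seed: int, floor: int = 2
) -> list[int]:
    """Integer sequence with controlled sample mean and variance.

    Discretised sampling around the mean followed by pairwise +1/-1
    adjustments (which leave the sum unchanged) until the sample variance
    is within 10% of the target; the mean stays within 0.5 by construction.
    """
    if mean < floor:
        raise FeasibilityError(f"mean {mean} below the degree floor {floor}")
    rng = np.random.default_rng(seed)
    base = int(round(mean))
    seq = np.full(length, base, dtype=int)
    if variance == 0:
        return seq.tolist()
    # upper bound on the variance attainable with the floor and this mean
    total = base * length
    slack = total - floor * length
    max_var = (slack**2 * (length - 1) / length**2) if slack > 0 else 0.0
    if variance > max_var:
        raise FeasibilityError(
            f"variance {variance} unattainable for mean {mean} with floor {floor}"
            f" (max {max_var:.3g})"
        )

    def var(s: np.ndarray) -> float:
        return float(np.var(s))

    for _ in range(200_000):
        v = var(seq)
        if abs(v - variance) <= 0.1 * variance:
            return seq.tolist()
        if v < variance:
            # spread: move mass from a low node to a high node
            lo_ok = np.where(seq > floor)[0]
            if lo_ok.size == 0:
                raise FeasibilityError("variance target unreachable: all at floor")
            give = lo_ok[rng.integers(lo_ok.size)]
            take = int(rng.integers(length))
            if take == give:
                continue
            if seq[take] < seq[give]:
                give, take = take, give
                if seq[give] <= floor:
                    continue
            seq[give] -= 1
            seq[take] += 1
        else:
            # contract: move mass from a high node to a low node
            hi = int(np.argmax(seq))
            lo = int(np.argmin(seq))
            if hi == lo:
                return seq.tolist()
            seq[hi] -= 1
            seq[lo] += 1
    raise FeasibilityError("variance adjustment did not converge")


# --- motif census ---------------------------------------------------------

@dataclass(frozen=True)
class MotifCensus:
    """Counts and shares of basic motifs (n-gons, n = 2..5).

    ``counts[2]`` is the number of independent edges in the global sense:
    edges that belong to no triangle.  ``edge_share`` follows the literal
    per-network-size normalisation (edges in the motif divided by N, which
    can exceed 1); ``edge_fraction`` divides by the edge count instead.
    """

    counts: dict[int, int]
    edges_in_motif: dict[int, int]
    share_of_motifs: dict[int, float]
    edge_share: dict[int, float]
    edge_fraction: dict[int, float]


def motif_census(G: nx.Graph, max_n: int = 5) -> MotifCensus:
    """Census of basic motifs: independent edges, triangles, chordless squares
    and pentagons, with per-edge motif membership."""
    if max_n not in (2, 3, 4, 5):
        raise ParameterError("max_n must be between 2 and 5")
    validate_network(G)
    n_nodes = max(G.number_of_nodes(), 1)
    n_edges = G.number_of_edges()
    counts = {n: 0 for n in range(2, max_n + 1)}
    edge_sets: dict[int, set] = {n: set() for n in range(2, max_n + 1)}

    for cyc in nx.chordless_cycles(G, length_bound=max_n):
        size = len(cyc)
        if size < 3 or size > max_n:
            continue
        counts[size] += 1
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            edge_sets[size].add(frozenset((a, b)))

    tri_edges = edge_sets.get(3, set())
    indep = {frozenset(e) for e in G.edges()} - tri_edges
    counts[2] = len(indep)
    edge_sets[2] = indep

    total = sum(counts.values())
    share = {n: (counts[n] / total if total else 0.0) for n in counts}
    edge_share = {n: len(edge_sets[n]) / n_nodes for n in counts}
    edge_fraction = {n: (len(edge_sets[n]) / n_edges if n_edges else 0.0) for n in counts}
    return MotifCensus(
        counts=counts,
        edges_in_motif={n: len(edge_sets[n]) for n in counts},
        share_of_motifs=share,
        edge_share=edge_share,
        edge_fraction=edge_fraction,
    )


def independent_edges_wrt_source(G: nx.Graph, source: int) -> set[frozenset]:
    """Edges not directly connected to the source.

    An edge (i, j) counts as independent when neither endpoint is the
    source and the endpoints do not both neighbour the source (which would
    close a triangle with it).
    """
    if source not in G:
        raise KeyError(f"source {source} not in network")
    nbrs = set(G.neighbors(source))
    out = set()
    for u, v in G.edges():
        if u == source or v == source:
            continue
        if u in nbrs and v in nbrs:
            continue
        out.add(frozenset((u, v)))
    return out


def triangles_through_edge(G: nx.Graph, edge: tuple[int, int]) -> int:
    """Number of triangles containing the edge = common neighbours of its ends."""
    u, v = edge
    if not G.has_edge(u, v):
        raise KeyError(f"edge {edge} not in network")
    return len(set(G.neighbors(u)) & set(G.neighbors(v)))


# --- clustering rewiring --------------------------------------------------

def _local_clustering_sums(G: nx.Graph) -> tuple[np.ndarray, np.ndarray]:
    n = G.number_of_nodes()
    tri = np.zeros(n)
    for node, t in nx.triangles(G).items():
        tri[node] = t
    deg = np.array([G.degree(i) for i in range(n)], dtype=float)
    pairs = deg * (deg - 1) / 2.0
    return tri, pairs


def _mean_clustering(tri: np.ndarray, pairs: np.ndarray) -> float:
    with np.errstate(invalid="ignore", divide="ignore"):
        c = np.where(pairs > 0, tri / np.where(pairs > 0, pairs, 1.0), 0.0)
    return float(np.mean(c))


@dataclass
class RewireResult:
    graph: nx.Graph
    clustering: float
    accepted_swaps: int
    attempted_swaps: int
    reached_target: bool


def rewire_to_clustering(
    G: nx.Graph,
    target_C: float,
    seed: int,
    max_steps: int = 100_000,
    tol: float = 0.01,
) -> RewireResult:
    """Degree-preserving double-edge swaps toward a target mean clustering.

    A swap (a-b, c-d) -> (a-d, c-b) is accepted iff it moves the mean local
    clustering coefficient toward ``target_C`` and keeps the graph
    connected.  The degree sequence is exactly invariant (only endpoints
    are exchanged), so per-node triangle counts are updated incrementally
    and the pair denominators never change.  If the target is not reached
    within ``max_steps`` attempts the best-so-far graph is returned with
    ``reached_target=False``.
    """
    if not 0 <= target_C <= 1:
        raise ParameterError("target clustering must lie in [0, 1]")
    if not nx.is_connected(G):
        raise ParameterError("network must be connected")
    H = G.copy()
    rng = np.random.default_rng(seed)
    n = H.number_of_nodes()
    tri, pairs = _local_clustering_sums(H)
    inv_pairs = np.where(pairs > 0, 1.0 / np.where(pairs > 0, pairs, 1.0), 0.0)
    current = float(np.mean(tri * inv_pairs))

    def delta_edge(u: int, v: int, sign: float) -> float:
        """Change of mean clustering from adding (sign=+1) / removing (-1) edge u-v,
        applied to ``tri`` in place."""
        common = set(H.neighbors(u)) & set(H.neighbors(v))
        change = 0.0
        for w in common:
            tri[w] += sign
            change += sign * inv_pairs[w]
        tri[u] += sign * len(common)
        tri[v] += sign * len(common)
        change += sign * len(common) * (inv_pairs[u] + inv_pairs[v])
        return change / n

    accepted = 0
    attempts = 0
    edges = list(H.edges())
    while attempts < max_steps and abs(current - target_C) >= tol:
        attempts += 1
        a, b = edges[rng.integers(len(edges))]
        c, d = edges[rng.integers(len(edges))]
        if rng.random() < 0.5:
            c, d = d, c
        if len({a, b, c, d}) < 4 or H.has_edge(a, d) or H.has_edge(c, b):
            continue
        # common neighbours must be evaluated against the live graph, so
        # apply removals before additions and track the clustering change
        change = 0.0
        change += delta_edge(a, b, -1.0)
        H.remove_edge(a, b)
        change += delta_edge(c, d, -1.0)
        H.remove_edge(c, d)
        change += delta_edge(a, d, +1.0)
        H.add_edge(a, d)
        change += delta_edge(c, b, +1.0)
        H.add_edge(c, b)
        cand = current + change
        if abs(cand - target_C) < abs(current - target_C) and nx.is_connected(H):
            current = cand
            accepted += 1
            edges = list(H.edges())
        else:  # revert
            delta_edge(a, d, -1.0)
            H.remove_edge(a, d)
            delta_edge(c, b, -1.0)
            H.remove_edge(c, b)
            delta_edge(a, b, +1.0)
            H.add_edge(a, b)
            delta_edge(c, d, +1.0)
            H.add_edge(c, d)
    return RewireResult(
        graph=H,
        clustering=current,
        accepted_swaps=accepted,
        attempted_swaps=attempts,
        reached_target=abs(current - target_C) < tol,
    )
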