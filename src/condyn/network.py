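"""Correlation-weighted residue interaction networks and communities.

Residues (anchored at their Cα atoms) are nodes; an edge joins residues
that stay within a contact cutoff (default 4.5 Å) for at least a fraction
of frames (default 75%).  Retained edges carry the distance weight

    d_ij = -log(|C_ij|)

with C_ij the DCCM entry for the pair, so strongly coupled residues are
"close".  Optimal pathways are all-pairs shortest paths (Floyd–Warshall),
edge betweenness counts optimal paths per edge (ties split equally among
co-optimal paths, or an integer single-path mode), and communities come
from Girvan–Newman divisive clustering: iteratively remove the
highest-betweenness edge, recompute, and keep the dendrogram level with
maximal modularity.  Communities smaller than 3 residues are discarded
from the reported partition.

These graph algorithms are implemented here rather than delegated, since
they are the analysis itself; networkx serves only as an independent test
oracle.
"""

from __future__ import annotations

import heapq
import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import cdist

from .fluct import CorrelationMatrix
from .traj_io import Trajectory

log = logging.getLogger(__name__)

CORRELATION_FLOOR = 1e-6   # |C| floor before the log, keeps weights finite


# --------------------------------------------------------------------------
# Contacts and network construction
# --------------------------------------------------------------------------

def contact_occupancy(traj: Trajectory, residues: list[np.ndarray] | None = None,
                      cutoff: float = 4.5, mode: str = "heavy-atom-min",
                      exclude_neighbors: int = 1,
                      max_frames: int | None = None) -> np.ndarray:
    """Fraction of frames each residue pair spends within ``cutoff`` Å.

    ``residues`` lists, per node, the atom indices defining it; by default
    every residue of the topology becomes one node using all its non-hydrogen
    atoms.  ``mode`` is ``heavy-atom-min`` (minimum heavy-atom distance, the
    dynamical-network convention) or ``calpha`` (Cα–Cα distance).  Pairs
    closer in sequence than ``exclude_neighbors`` + 1 are fixed at occupancy
    0 so trivial backbone contacts never enter the network.  ``max_frames``
    subsamples frames evenly for large trajectories.
    """
    top = traj.topology
    if residues is None:
        order: list[tuple[str, int]] = []
        groups: dict[tuple[str, int], list[int]] = {}
        for a in range(top.n_atoms):
            key = (top.chains[a], int(top.resids[a]))
            if key not in groups:
                groups[key] = []
                order.append(key)
            if top.elements[a].upper() != "H":
                groups[key].append(a)
        residues = [np.asarray(groups[k], dtype=int) for k in order]
    if not residues:
        raise ValueError("no residues to build contacts from")
    n = len(residues)
    # sequence identity of each node, for the neighbor-exclusion rule
    node_keys = [(top.chains[r[0]], int(top.resids[r[0]])) for r in residues]
    if mode == "calpha":
        anchors = []
        for atoms in residues:
            ca = [a for a in atoms if top.names[a] == "CA"]
            anchors.append(ca[0] if ca else atoms[0])
        residues = [np.asarray([a]) for a in anchors]
    elif mode != "heavy-atom-min":
        raise ValueError(f"unknown contact mode {mode!r}")

    frames = np.arange(traj.n_frames)
    if max_frames is not None and traj.n_frames > max_frames:
        frames = np.linspace(0, traj.n_frames - 1, max_frames).round().astype(int)
    flat = np.concatenate(residues)
    bounds = np.cumsum([0] + [len(r) for r in residues])
    singletons = all(len(r) == 1 for r in residues)
    counts = np.zeros((n, n))
    for f in frames:
        xyz = traj.coordinates[f, flat, :]
        D = cdist(xyz, xyz)
        if singletons:
            M = np.triu(D, k=1) + np.tril(np.full((n, n), np.inf))
        else:
            # reduce atom-pair distances to residue-pair minima
            M = np.full((n, n), np.inf)
            for i in range(n):
                si = slice(bounds[i], bounds[i + 1])
                for j in range(i + 1, n):
                    sj = slice(bounds[j], bounds[j + 1])
                    M[i, j] = D[si, sj].min()
        counts += (M <= cutoff)
    occ = counts / len(frames)
    occ = occ + occ.T
    np.fill_diagonal(occ, 0.0)
    if exclude_neighbors > 0:
        for i in range(n):
            for j in range(i + 1, n):
                ci, ri = node_keys[i]
                cj, rj = node_keys[j]
                if ci == cj and abs(ri - rj) <= exclude_neighbors:
                    occ[i, j] = occ[j, i] = 0.0
    return occ


@dataclass
class Edge:
    occupancy: float
    correlation: float
    weight: float           # -log |C|, floored
    betweenness: float = 0.0


@dataclass
class ResidueNetwork:
    """Occupancy-filtered residue graph with -log|C| distance weights."""

    nodes: list[int]
    edges: dict[tuple[int, int], Edge] = field(default_factory=dict)

    def weight_dict(self) -> dict[tuple[int, int], float]:
        return {e: d.weight for e, d in self.edges.items()}

    def neighbors(self) -> dict[int, list[tuple[int, float]]]:
        adj: dict[int, list[tuple[int, float]]] = {u: [] for u in self.nodes}
        for (u, v), d in self.edges.items():
            adj[u].append((v, d.weight))
            adj[v].append((u, d.weight))
        return adj


def build_network(occupancy: np.ndarray, correlation: CorrelationMatrix | np.ndarray,
                  occupancy_threshold: float = 0.75,
                  node_ids: list[int] | None = None) -> ResidueNetwork:
    """Edges where occupancy >= threshold (inclusive), weighted -log|C_ij|.

    |C| is floored at 1e-6 so weights stay finite; an exactly zero
    correlation on a retained edge is floored with a warning.
    """
    C = correlation.values if isinstance(correlation, CorrelationMatrix) else np.asarray(correlation)
    occ = np.asarray(occupancy)
    if occ.shape != C.shape:
        raise ValueError(f"occupancy {occ.shape} and correlation {C.shape} shapes differ")
    n = occ.shape[0]
    nodes = list(range(n)) if node_ids is None else list(node_ids)
    net = ResidueNetwork(nodes=nodes)
    for i in range(n):
        for j in range(i + 1, n):
            if occ[i, j] >= occupancy_threshold:
                c = abs(float(C[i, j]))
                if c < CORRELATION_FLOOR:
                    log.warning("correlation %.2g on retained edge (%d, %d) floored at %g",
                                c, nodes[i], nodes[j], CORRELATION_FLOOR)
                    c = CORRELATION_FLOOR
                c = min(c, 1.0)
                net.edges[(nodes[i], nodes[j])] = Edge(
                    occupancy=float(occ[i, j]), correlation=float(C[i, j]),
                    weight=float(-np.log(c)))
    return net


def network_from_weights(nodes, weights: dict[tuple[int, int], float]) -> ResidueNetwork:
    """Wrap a plain weighted edge dict (e.g. a planted graph) as a network."""
    net = ResidueNetwork(nodes=list(nodes))
    for (u, v), w in weights.items():
        if w < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        e = (min(u, v), max(u, v))
        net.edges[e] = Edge(occupancy=1.0, correlation=float(np.exp(-w)), weight=float(w))
    return net


# --------------------------------------------------------------------------
# Shortest paths (Floyd-Warshall) and edge betweenness
# --------------------------------------------------------------------------

def optimal_paths(network: ResidueNetwork):
    """All-pairs shortest distances and predecessor matrix (Floyd-Warshall).

    Returns ``(dist, pred, index_of)``: ``dist[a, b]`` is the minimal total
    weight between nodes at positions a, b (inf when unreachable);
    ``pred[a, b]`` is the position of b's predecessor on one optimal a->b
    path (-1 when none).  Deterministic under ties: the first (lowest
    intermediate index) optimal path found is kept.
    """
    nodes = network.nodes
    n = len(nodes)
    index_of = {u: i for i, u in enumerate(nodes)}
    dist = np.full((n, n), np.inf)
    pred = np.full((n, n), -1, dtype=int)
    np.fill_diagonal(dist, 0.0)
    for (u, v), d in network.edges.items():
        if d.weight < 0:
            raise ValueError(f"negative edge weight on ({u}, {v})")
        a, b = index_of[u], index_of[v]
        if d.weight < dist[a, b]:
            dist[a, b] = dist[b, a] = d.weight
            pred[a, b] = a
            pred[b, a] = b
    for k in range(n):
        alt = dist[:, k, None] + dist[None, k, :]
        better = alt < dist - 1e-15
        dist = np.where(better, alt, dist)
        pred = np.where(better, np.broadcast_to(pred[k, :], (n, n)), pred)
    return dist, pred, index_of


def reconstruct_path(pred: np.ndarray, a: int, b: int) -> list[int]:
    """Node-position sequence of one optimal path a -> b (inclusive)."""
    if a == b:
        return [a]
    if pred[a, b] < 0:
        return []
    path = [b]
    while path[-1] != a:
        path.append(int(pred[a, path[-1]]))
    return path[::-1]


def edge_betweenness(network: ResidueNetwork, tie_mode: str = "split"
                     ) -> dict[tuple[int, int], float]:
    """Per-edge count of pairwise optimal paths traversing it.

    ``split`` (default): co-optimal paths share a pair's unit contribution
    equally (Brandes accumulation over the shortest-path DAG).  ``single``:
    exactly one deterministic optimal path per pair (Floyd-Warshall
    predecessors) contributes integer counts.
    """
    eb = {e: 0.0 for e in network.edges}
    if tie_mode == "single":
        dist, pred, index_of = optimal_paths(network)
        nodes = network.nodes
        n = len(nodes)
        for a in range(n):
            for b in range(a + 1, n):
                path = reconstruct_path(pred, a, b)
                for u, v in zip(path[:-1], path[1:]):
                    x, y = nodes[u], nodes[v]
                    eb[(min(x, y), max(x, y))] += 1.0
        return eb
    if tie_mode != "split":
        raise ValueError(f"unknown tie_mode {tie_mode!r}")
    adj = network.neighbors()
    for s in network.nodes:
        # Dijkstra with path counts
        dist = {u: np.inf for u in network.nodes}
        sigma = {u: 0.0 for u in network.nodes}
        preds: dict[int, list[int]] = {u: [] for u in network.nodes}
        dist[s] = 0.0
        sigma[s] = 1.0
        heap = [(0.0, s)]
        order = []
        done = set()
        while heap:
            d, u = heapq.heappop(heap)
            if u in done:
                continue
            done.add(u)
            order.append(u)
            for v, w in adj[u]:
                nd = d + w
                if nd < dist[v] - 1e-12:
                    dist[v] = nd
                    sigma[v] = sigma[u]
                    preds[v] = [u]
                    heapq.heappush(heap, (nd, v))
                elif abs(nd - dist[v]) <= 1e-12 and u not in preds[v]:
                    sigma[v] += sigma[u]
                    preds[v].append(u)
        delta = {u: 0.0 for u in network.nodes}
        for w in reversed(order):
            for v in preds[w]:
                c = sigma[v] / sigma[w] * (1.0 + delta[w])
                eb[(min(v, w), max(v, w))] += c
                delta[v] += c
    for e in eb:
        eb[e] /= 2.0   # each unordered pair was visited from both endpoints
    return eb


# --------------------------------------------------------------------------
# Communities
# --------------------------------------------------------------------------

@dataclass
class CommunityPartition:
    communities: list[list[int]]            # size >= 3, sorted by first node
    discarded: list[list[int]]              # communities below the size floor
    modularity: float
    intercommunity_connectivity: np.ndarray  # (m, m) symmetric betweenness totals
    sizes: list[int] = field(default_factory=list)

    def __post_init__(self):
        if not self.sizes:
            self.sizes = [len(c) for c in self.communities]


def _components(nodes: list[int], edges: set[tuple[int, int]]) -> list[list[int]]:
    adj: dict[int, list[int]] = {u: [] for u in nodes}
    for u, v in edges:
        adj[u].append(v)
        adj[v].append(u)
    seen: set[int] = set()
    comps = []
    for start in nodes:
        if start in seen:
            continue
        stack, comp = [start], []
        seen.add(start)
        while stack:
            u = stack.pop()
            comp.append(u)
            for v in adj[u]:
                if v not in seen:
                    seen.add(v)
                    stack.append(v)
        comps.append(sorted(comp))
    return comps


def modularity(network: ResidueNetwork, communities: list[list[int]],
               weighted: bool = True) -> float:
    """Newman-Girvan modularity of a partition.

    Edge affinity is exp(-weight) = |C| when ``weighted`` (distance weights
    would invert the meaning of a strong tie), or 1 per edge otherwise.
    """
    comm_of = {}
    for ci, comm in enumerate(communities):
        for u in comm:
            comm_of[u] = ci
    W = 0.0
    intra = 0.0
    degree: dict[int, float] = {u: 0.0 for u in network.nodes}
    for (u, v), d in network.edges.items():
        a = float(np.exp(-d.weight)) if weighted else 1.0
        W += a
        degree[u] += a
        degree[v] += a
        if comm_of.get(u) is not None and comm_of.get(u) == comm_of.get(v):
            intra += a
    if W == 0:
        return 0.0
    Q = intra / W
    for comm in communities:
        deg = sum(degree[u] for u in comm)
        Q -= (deg / (2.0 * W)) ** 2
    return Q


def girvan_newman(network: ResidueNetwork, min_community_size: int = 3,
                  weighted_modularity: bool = True,
                  tie_mode: str = "split") -> CommunityPartition:
    """Divisive community detection by iterative highest-betweenness edge
    removal with recomputation, selecting the max-modularity dendrogram level.

    Ties in maximum betweenness break deterministically on lexicographic
    edge order.  Communities below ``min_community_size`` are discarded from
    the reported partition (listed separately); the connectivity table sums
    the full network's edge betweenness over edges crossing community pairs.
    """
    if not network.nodes:
        raise ValueError("network is empty")
    work = ResidueNetwork(nodes=list(network.nodes),
                          edges={e: Edge(d.occupancy, d.correlation, d.weight)
                                 for e, d in network.edges.items()})
    best_comms = _components(work.nodes, set(work.edges))
    best_Q = modularity(network, best_comms, weighted_modularity)
    while work.edges:
        eb = edge_betweenness(work, tie_mode=tie_mode)
        top = max(eb.values())
        candidates = sorted(e for e, b in eb.items() if b >= top - 1e-9)
        if len(candidates) > 1:
            log.debug("betweenness tie among %d edges; removing %s", len(candidates),
                      candidates[0])
        del work.edges[candidates[0]]
        comms = _components(work.nodes, set(work.edges))
        Q = modularity(network, comms, weighted_modularity)
        if Q > best_Q + 1e-12:
            best_Q = Q
            best_comms = comms
    kept = sorted([c for c in best_comms if len(c) >= min_community_size],
                  key=lambda c: c[0])
    discarded = sorted([c for c in best_comms if len(c) < min_community_size],
                       key=lambda c: c[0])
    if discarded:
        log.info("discarded %d communities below %d residues", len(discarded),
                 min_community_size)
    conn = intercommunity_connectivity(kept, network, tie_mode=tie_mode)
    return CommunityPartition(communities=kept, discarded=discarded,
                              modularity=best_Q, intercommunity_connectivity=conn)


def intercommunity_connectivity(communities: list[list[int]],
                                network: ResidueNetwork,
                                tie_mode: str = "split") -> np.ndarray:
    """Symmetric table of total edge betweenness crossing each community pair."""
    m = len(communities)
    conn = np.zeros((m, m))
    if m == 0:
        return conn
    comm_of = {}
    for ci, comm in enumerate(communities):
        for u in comm:
            comm_of[u] = ci
    eb = edge_betweenness(network, tie_mode=tie_mode)
    for (u, v), b in eb.items():
        cu, cv = comm_of.get(u), comm_of.get(v)
        if cu is None or cv is None or cu == cv:
            continue
        conn[cu, cv] += b
        conn[cv, cu] += b
    return conn
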