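"""Community structure, topology, keystones and fragmentation.

All computations treat the consensus network as a simple unweighted
undirected graph (edge attributes are bookkeeping only). Fragmentation f is
the number of disconnected subgraphs divided by the number of nodes; the
stability analysis removes the keystone taxa (top-10 joint degree +
betweenness) one at a time and tracks f.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.stats import rankdata

from .datatypes import CooccurrenceNetwork


def _as_graph(net: CooccurrenceNetwork | nx.Graph) -> nx.Graph:
    return net.graph if isinstance(net, CooccurrenceNetwork) else net


@dataclass
class CommunityPartition:
    assignment: dict[str, int]
    modularity: float | None
    pruned_communities: list[int]
    pruned_nodes: list[str]
    resolution: float
    n_retained: int


def _relocation_refine(
    g: nx.Graph, comms: list[set], resolution: float, max_sweeps: int = 50
) -> list[set]:
    """Greedy single-node relocation hill climbing on modularity.

    Uses the O(deg) modularity-delta formula for moving node v from its
    community a to b: dQ = (k_vb - k_va)/m - gamma * k_v (d_b - d_a')/2m^2,
    with d_a' the degree sum of a without v.
    """
    m = g.number_of_edges()
    if m == 0:
        return [set(c) for c in comms if c]
    member = {}
    comms = [set(c) for c in comms if c]
    for i, c in enumerate(comms):
        for v in c:
            member[v] = i
    deg = dict(g.degree())
    comm_deg = [sum(deg[v] for v in c) for c in comms]
    nodes = sorted(g.nodes())
    for _ in range(max_sweeps):
        improved = False
        for v in nodes:
            a = member[v]
            kv = deg[v]
            k_to = {}
            for u in g[v]:
                k_to[member[u]] = k_to.get(member[u], 0) + 1
            k_va = k_to.get(a, 0)
            d_a_prime = comm_deg[a] - kv
            best_gain, best_b = 1e-12, None
            # existing communities
            for b in set(k_to) | {len(comms)}:
                if b == a:
                    continue
                if b == len(comms):  # fresh singleton
                    k_vb, d_b = 0, 0
                else:
                    k_vb, d_b = k_to.get(b, 0), comm_deg[b]
                gain = (k_vb - k_va) / m - resolution * kv * (
                    d_b - d_a_prime
                ) / (2.0 * m * m)
                if gain > best_gain:
                    best_gain, best_b = gain, b
            if best_b is not None:
                comms[a].discard(v)
                comm_deg[a] -= kv
                if best_b == len(comms):
                    comms.append({v})
                    comm_deg.append(kv)
                else:
                    comms[best_b].add(v)
                    comm_deg[best_b] += kv
                member[v] = best_b if best_b < len(comms) else len(comms) - 1
                improved = True
        if not improved:
            break
    return [c for c in comms if c]


def _candidate_partitions(g: nx.Graph, resolution: float, seed: int,
                          restarts: int = 4):
    """Louvain restarts over a small resolution sweep, plus Newman's
    leading-eigenvector split; all candidates are scored at the requested
    resolution, so the sweep only diversifies the search."""
    for gi, mult in enumerate((0.5, 0.7, 0.85, 1.0)):
        for r in range(restarts):
            yield nx.community.louvain_communities(
                g, resolution=resolution * mult, seed=seed + r + 100 * gi
            )
    try:
        import igraph as ig

        nodes = list(g.nodes())
        idx = {v: i for i, v in enumerate(nodes)}
        G = ig.Graph(n=len(nodes),
                     edges=[(idx[u], idx[v]) for u, v in g.edges()])
        part = G.community_leading_eigenvector()
        yield [set(nodes[i] for i in c) for c in part]
    except Exception:  # eigenvector split is a best-effort extra candidate
        pass


def louvain_communities(
    net: CooccurrenceNetwork | nx.Graph,
    resolution: float = 1.0,
    min_size: int = 5,
    seed: int = 0,
) -> CommunityPartition:
    """Louvain modularity optimisation; communities below min_size pruned.

    The greedy Louvain pass is restarted with shuffled node orders (and a
    leading-eigenvector candidate) and followed by single-node relocation
    refinement; the best-modularity partition wins. Modularity is reported
    for the full (unpruned) partition; pruned communities are recorded and
    their nodes flagged so they are excluded from cluster counts downstream.
    """
    g = _as_graph(net)
    if g.number_of_nodes() == 0:
        return CommunityPartition({}, None, [], [], resolution, 0)
    if g.number_of_edges() == 0:
        comms = [{v} for v in sorted(g.nodes())]
    else:
        best_q, comms = -np.inf, None
        for cand in _candidate_partitions(g, resolution, seed):
            cand = _relocation_refine(g, cand, resolution)
            q = nx.community.modularity(g, cand, resolution=resolution)
            if q > best_q:
                best_q, comms = q, cand
    comms = sorted(comms, key=lambda c: (-len(c), sorted(c)[0]))
    assignment = {v: i for i, c in enumerate(comms) for v in c}
    q = nx.community.modularity(g, comms, resolution=resolution) if g.number_of_edges() else None
    pruned = [i for i, c in enumerate(comms) if len(c) < min_size]
    pruned_nodes = [v for i in pruned for v in sorted(comms[i])]
    return CommunityPartition(
        assignment=assignment,
        modularity=q,
        pruned_communities=pruned,
        pruned_nodes=pruned_nodes,
        resolution=resolution,
        n_retained=len(comms) - len(pruned),
    )


@dataclass
class TopologyMetrics:
    n_nodes: int
    n_edges: int
    n_clusters: int
    diameter: int | None
    edge_density: float
    modularity: float | None
    assortativity: float | None
    transitivity: float

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def topology(
    net: CooccurrenceNetwork | nx.Graph,
    partition: CommunityPartition | None = None,
) -> TopologyMetrics:
    """Node/edge counts, cluster count, diameter, density, Q, assortativity,
    transitivity. Diameter is hop-based on the largest connected component."""
    g = _as_graph(net)
    n, e = g.number_of_nodes(), g.number_of_edges()
    diameter = None
    if n >= 2:
        comp = max(nx.connected_components(g), key=len)
        if len(comp) >= 2:
            diameter = nx.diameter(g.subgraph(comp))
        else:
            diameter = 0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            assort = nx.degree_pearson_correlation_coefficient(g) if e else None
        if assort is not None and np.isnan(assort):
            assort = None
    except (ZeroDivisionError, ValueError):
        assort = None
    return TopologyMetrics(
        n_nodes=n,
        n_edges=e,
        n_clusters=partition.n_retained if partition else 0,
        diameter=diameter,
        edge_density=nx.density(g) if n > 1 else 0.0,
        modularity=partition.modularity if partition else None,
        assortativity=assort,
        transitivity=nx.transitivity(g),
    )


@dataclass
class CentralityScores:
    degree: dict[str, int]
    betweenness: dict[str, float]
    degree_rank: dict[str, int]
    betweenness_rank: dict[str, int]


def centrality(net: CooccurrenceNetwork | nx.Graph) -> CentralityScores:
    """Degree and unnormalised shortest-path betweenness, with dense ranks
    (rank 1 = highest; ties share the better rank)."""
    g = _as_graph(net)
    nodes = sorted(g.nodes(), key=str)
    deg = {v: int(g.degree(v)) for v in nodes}
    btw = nx.betweenness_centrality(g, normalized=False)
    btw = {v: float(btw[v]) for v in nodes}
    dvals = np.array([deg[v] for v in nodes], dtype=float)
    bvals = np.array([btw[v] for v in nodes], dtype=float)
    drank = rankdata(-dvals, method="dense").astype(int)
    brank = rankdata(-bvals, method="dense").astype(int)
    return CentralityScores(
        degree=deg,
        betweenness=btw,
        degree_rank=dict(zip(nodes, drank)),
        betweenness_rank=dict(zip(nodes, brank)),
    )


@dataclass
class KeystoneReport:
    keystones: list[str]
    score: dict[str, int]
    degree: dict[str, int]
    betweenness: dict[str, float]
    relative_abundance: dict[str, float] = field(default_factory=dict)
    truncated: bool = False


def select_keystones(
    scores: CentralityScores,
    k: int = 10,
    relative_abundance: dict[str, float] | None = None,
) -> KeystoneReport:
    """Top-k nodes by joint degree + betweenness rank-sum.

    Ties are broken by higher betweenness, then lexical node id. When the
    graph has fewer than k nodes, all nodes are returned with a warning.
    """
    nodes = list(scores.degree)
    if not nodes:
        raise ValueError("empty centrality scores")
    ranksum = {
        v: scores.degree_rank[v] + scores.betweenness_rank[v] for v in nodes
    }
    ordered = sorted(
        nodes, key=lambda v: (ranksum[v], -scores.betweenness[v], str(v))
    )
    truncated = False
    if k > len(nodes):
        warnings.warn(f"requested top {k} keystones from a {len(nodes)}-node graph")
        truncated = True
        k = len(nodes)
    chosen = ordered[:k]
    return KeystoneReport(
        keystones=chosen,
        score={v: ranksum[v] for v in chosen},
        degree={v: scores.degree[v] for v in chosen},
        betweenness={v: scores.betweenness[v] for v in chosen},
        relative_abundance={
            v: (relative_abundance or {}).get(v, float("nan")) for v in chosen
        },
        truncated=truncated,
    )


def fragmentation(net: CooccurrenceNetwork | nx.Graph) -> float:
    """f = connected components / nodes (1/N for connected, 1 for edgeless)."""
    g = _as_graph(net)
    n = g.number_of_nodes()
    if n == 0:
        raise ValueError("fragmentation of an empty graph is undefined")
    return nx.number_connected_components(g) / n


@dataclass
class TrajectoryStep:
    removed_node: str
    n_nodes_remaining: int
    n_components: int
    f: float
    n_clusters: int


@dataclass
class FragmentationTrajectory:
    baseline_f: float
    steps: list[TrajectoryStep]

    @property
    def f_mean(self) -> float:
        return float(np.mean([s.f for s in self.steps])) if self.steps else float("nan")


def removal_trajectory(
    net: CooccurrenceNetwork | nx.Graph,
    keystones: KeystoneReport,
    recompute: bool = False,
    original_denominator: bool = False,
    min_cluster_size: int = 5,
    seed: int = 0,
) -> FragmentationTrajectory:
    """Remove keystones one at a time and track fragmentation.

    By default the static rank-ordered keystone list is removed; with
    ``recompute`` the centrality ranking is refreshed after each removal.
    ``original_denominator`` divides component counts by the pre-removal
    node count instead of the current one. The Louvain cluster count is
    recomputed after each removal.
    """
    g = _as_graph(net).copy()
    n0 = g.number_of_nodes()
    missing = [v for v in keystones.keystones if v not in g]
    if missing:
        raise ValueError(f"keystones not in graph: {missing}")
    baseline = fragmentation(g)
    steps: list[TrajectoryStep] = []
    queue = list(keystones.keystones)
    for step in range(len(queue)):
        if recompute:
            target = select_keystones(centrality(g), k=1).keystones[0]
        else:
            target = queue[step]
            if target not in g:
                continue
        g.remove_node(target)
        if g.number_of_nodes() == 0:
            break
        ncomp = nx.number_connected_components(g)
        denom = n0 if original_denominator else g.number_of_nodes()
        part = louvain_communities(g, min_size=min_cluster_size, seed=seed)
        steps.append(
            TrajectoryStep(
                removed_node=target,
                n_nodes_remaining=g.number_of_nodes(),
                n_components=ncomp,
                f=ncomp / denom,
                n_clusters=part.n_retained,
            )
        )
    return FragmentationTrajectory(baseline_f=baseline, steps=steps)
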