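"""Median-joining haplotype networks over binary haplotype strings.

The algorithm follows the classic median-joining scheme: iterate
(1) build the epsilon-relaxed minimum spanning network (MSN) over the current
node set, (2) for every triplet of mutually linked nodes propose the median
(position-wise majority) vector, (3) add the proposal that most reduces the
network cost (total minimum-spanning-tree weight), strictly; stop when no
median reduces the cost, then drop obsolete median vectors whose removal
leaves the cost unchanged.  Tie-breaks are lexicographic throughout, so the
construction is deterministic.

Only binary (ancestral/derived) states are supported; edge weights are
Hamming distances (mutational steps).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from .haplotypes import CoreMotif


@dataclass
class HapNode:
    """A haplotype in the network: observed chromosomes or an inferred median."""

    haplotype: str
    observed_count: int = 0
    population_composition: dict[str, int] = field(default_factory=dict)
    labels: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if set(self.haplotype) - {"0", "1"}:
            raise ValueError(
                f"non-binary haplotype state in {self.haplotype!r}; "
                "multistate characters are not supported"
            )
        comp_total = sum(self.population_composition.values())
        if self.population_composition and comp_total != self.observed_count:
            raise ValueError(
                f"population composition sums to {comp_total}, "
                f"observed_count is {self.observed_count}"
            )

    @property
    def is_median(self) -> bool:
        return self.observed_count == 0


@dataclass
class HapNetwork:
    """A built network: nodes keyed by haplotype string, weighted edges."""

    nodes: dict[str, HapNode]
    graph: nx.Graph
    epsilon: int
    total_cost: int

    def edge_list(self) -> list[tuple[str, str, int]]:
        return sorted(
            (min(u, v), max(u, v), d["weight"])
            for u, v, d in self.graph.edges(data=True)
        )

    def write_edges(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("hap1\thap2\tdistance\n")
            for u, v, w in self.edge_list():
                fh.write(f"{u}\t{v}\t{w}\n")

    def write_gml(self, path: str | Path) -> None:
        g = nx.Graph()
        for h, node in self.nodes.items():
            g.add_node(
                h,
                observed_count=node.observed_count,
                is_median=int(node.is_median),
                labels=";".join(node.labels),
            )
        for u, v, d in self.graph.edges(data=True):
            g.add_edge(u, v, weight=int(d["weight"]))
        nx.write_gml(g, str(path))


def hamming(h1: str, h2: str) -> int:
    """Number of differing positions between two equal-length allele strings."""
    if len(h1) != len(h2):
        raise ValueError(f"length mismatch: {len(h1)} vs {len(h2)}")
    return sum(1 for a, b in zip(h1, h2) if a != b)


def _distance_matrix(haps: list[str]) -> np.ndarray:
    arr = np.array([[c == "1" for c in h] for h in haps], dtype=np.uint8)
    return (arr[:, None, :] != arr[None, :, :]).sum(axis=2).astype(int)


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, x: int) -> int:
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _msn_edges(dist: np.ndarray, epsilon: int) -> list[tuple[int, int, int]]:
    """Edges of the epsilon-relaxed minimum spanning network.

    An edge (u,v) is included iff d(u,v) <= w_crit(u,v) + epsilon, where
    w_crit is the weight class at which u and v first join in a Kruskal pass
    (epsilon = 0 gives exactly the union of all minimum spanning trees for
    distinct weights, i.e. the standard MSN).
    """
    n = dist.shape[0]
    if n == 1:
        return []
    w_crit = np.zeros((n, n), dtype=int)
    uf = _UnionFind(n)
    weights = sorted(set(dist[np.triu_indices(n, 1)].tolist()))
    connected = np.eye(n, dtype=bool)
    for w in weights:
        for i in range(n):
            for j in range(i + 1, n):
                if dist[i, j] == w:
                    uf.union(i, j)
        roots = [uf.find(i) for i in range(n)]
        for i in range(n):
            for j in range(i + 1, n):
                if not connected[i, j] and roots[i] == roots[j]:
                    w_crit[i, j] = w_crit[j, i] = w
                    connected[i, j] = connected[j, i] = True
        if connected.all():
            break
    edges = []
    for i in range(n):
        for j in range(i + 1, n):
            if dist[i, j] <= w_crit[i, j] + epsilon:
                edges.append((i, j, int(dist[i, j])))
    return edges


def _mst_cost(dist: np.ndarray) -> int:
    from scipy.sparse.csgraph import minimum_spanning_tree

    if dist.shape[0] <= 1:
        return 0
    return int(round(minimum_spanning_tree(dist).sum()))


def _median(a: str, b: str, c: str) -> str:
    return "".join(
        "1" if (x == "1") + (y == "1") + (z == "1") >= 2 else "0"
        for x, y, z in zip(a, b, c)
    )


def median_joining(
    haplotypes: dict[str, HapNode] | dict[str, int],
    epsilon: int = 0,
    prune: bool = False,
) -> HapNetwork:
    """Build a median-joining network from observed haplotypes.

    ``haplotypes`` maps haplotype string -> HapNode (or -> observed count).
    ``prune=True`` applies a maximum-parsimony-style pass removing median
    vectors that lie on no shortest observed-to-observed network path.
    """
    if not haplotypes:
        raise ValueError("at least one haplotype is required")
    nodes: dict[str, HapNode] = {}
    for h, v in haplotypes.items():
        nodes[h] = v if isinstance(v, HapNode) else HapNode(h, observed_count=int(v))
    lengths = {len(h) for h in nodes}
    if len(lengths) != 1:
        raise ValueError("haplotypes differ in length")

    current = sorted(nodes)
    dist = _distance_matrix(current)
    cost = _mst_cost(dist)

    while True:
        edges = _msn_edges(dist, 0)
        adj: dict[int, set[int]] = {i: set() for i in range(len(current))}
        for i, j, _ in edges:
            adj[i].add(j)
            adj[j].add(i)
        candidates: set[str] = set()
        existing = set(current)
        for i in range(len(current)):
            for j in sorted(adj[i]):
                if j <= i:
                    continue
                for k in sorted(adj[i] & adj[j]):
                    if k <= j:
                        continue
                    med = _median(current[i], current[j], current[k])
                    if med not in existing:
                        candidates.add(med)
        best_med = None
        best_cost = cost
        # sorted iteration + strict improvement keeps the lexicographically
        # smallest median among cost ties
        for med in sorted(candidates):
            trial = sorted(existing | {med})
            c = _mst_cost(_distance_matrix(trial))
            if c < best_cost:
                best_cost = c
                best_med = med
        if best_med is None:
            break
        current = sorted(existing | {best_med})
        dist = _distance_matrix(current)
        cost = best_cost

    # drop obsolete medians: removal leaves the spanning cost unchanged
    changed = True
    while changed:
        changed = False
        for h in sorted(current):
            if h in nodes:  # observed
                continue
            trial = [x for x in current if x != h]
            if _mst_cost(_distance_matrix(trial)) == cost:
                current = trial
                dist = _distance_matrix(current)
                changed = True
                break

    graph = _build_graph(current, dist, epsilon)

    if prune:
        observed = [h for h in current if h in nodes]
        keep = set(observed)
        sp = dict(nx.all_pairs_dijkstra_path_length(graph, weight="weight"))
        for m in current:
            if m in keep:
                continue
            on_path = any(
                sp[a][m] + sp[m][b] == sp[a][b]
                for ai, a in enumerate(observed)
                for b in observed[ai + 1:]
                if m in sp[a] and b in sp[m]
            )
            if on_path:
                keep.add(m)
        current = sorted(keep)
        dist = _distance_matrix(current)
        cost = _mst_cost(dist)
        graph = _build_graph(current, dist, epsilon)

    out_nodes = {
        h: nodes.get(h, HapNode(h, observed_count=0)) for h in current
    }
    return HapNetwork(nodes=out_nodes, graph=graph, epsilon=epsilon,
                      total_cost=cost)


def _build_graph(current: list[str], dist: np.ndarray, epsilon: int) -> nx.Graph:
    graph = nx.Graph()
    graph.add_nodes_from(current)
    for i, j, w in _msn_edges(dist, epsilon):
        graph.add_edge(current[i], current[j], weight=w)
    return graph


def frequency_filter(counts: dict[str, int], min_frequency: int = 2) -> dict[str, int]:
    """Restrict to haplotypes with count >= min_frequency (e.g. frequency > 1)."""
    return {h: c for h, c in counts.items() if c >= min_frequency}


def cluster_partition(
    net: HapNetwork, motif: CoreMotif, locus_ids: list[str]
) -> dict:
    """Partition network nodes by core-motif carriage.

    Returns ``{"core": [...], "non_core": [...], "separation": int | nan}``
    where separation is the minimum Hamming distance between the two
    partitions (nan when one partition is empty).
    """
    idx = motif.indices(locus_ids)
    core, non_core = [], []
    for h in sorted(net.nodes):
        (core if all(h[i] == "1" for i in idx) else non_core).append(h)
    if not core or not non_core:
        sep: float = float("nan")
    else:
        sep = min(hamming(a, b) for a in core for b in non_core)
    return {"core": core, "non_core": non_core, "separation": sep}
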