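"""Hierarchical clustering with locus-bootstrap support, and minimum
spanning networks.

UPGMA is agglomerative average linkage with node height equal to half the
merge distance; ties are broken deterministically by merging the pair whose
(lexicographically smallest member id of each cluster) pair sorts first.
Branch support resamples the marker loci with replacement — the S-locus
counting as one unit among eleven — rebuilding the Nei matrix and tree per
replicate, and reports the percentage of replicates containing each clade.
Branches below a support threshold (default 40%) can be collapsed into
polytomies.

The minimum spanning network is a Kruskal MST under a deterministic
(weight, endpoint) edge ordering, optionally augmented with tied alternative
edges: any non-tree edge whose weight equals the heaviest edge on the tree
path between its endpoints could replace that edge in another valid MST.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import networkx as nx
import numpy as np

from .distance import DistanceMatrix, nei_from_components, nei_locus_components
from .genotypes import GenotypeTable

__all__ = [
    "TreeNode",
    "SupportTree",
    "Network",
    "upgma",
    "bootstrap_support",
    "minimum_spanning_network",
]

_TIE_TOL = 1e-12


@dataclass
class TreeNode:
    """Node of a rooted ultrametric tree. Leaves have a label and height 0."""

    height: float = 0.0
    label: Optional[str] = None
    children: list["TreeNode"] = field(default_factory=list)
    support: Optional[float] = None  # % of bootstrap replicates, internal only

    @property
    def is_leaf(self) -> bool:
        return not self.children

    def leaves(self) -> frozenset[str]:
        if self.is_leaf:
            return frozenset([self.label])
        out: set[str] = set()
        for c in self.children:
            out |= c.leaves()
        return frozenset(out)

    def walk(self):
        yield self
        for c in self.children:
            yield from c.walk()


@dataclass
class SupportTree:
    """Rooted ultrametric dendrogram over accession ids with optional
    per-clade bootstrap support (percent)."""

    root: TreeNode
    ids: tuple[str, ...]

    def clades(self) -> dict[frozenset[str], TreeNode]:
        """Internal non-root clades keyed by their leaf set."""
        out = {}
        all_leaves = self.root.leaves()
        for node in self.root.walk():
            if node.is_leaf or node is self.root:
                continue
            lv = node.leaves()
            if lv != all_leaves:
                out[lv] = node
        return out

    def cophenetic(self) -> DistanceMatrix:
        ids = self.ids
        n = len(ids)
        pos = {a: i for i, a in enumerate(ids)}
        M = np.zeros((n, n))

        def rec(node: TreeNode) -> list[str]:
            if node.is_leaf:
                return [node.label]
            groups = [rec(c) for c in node.children]
            for gi in range(len(groups)):
                for gj in range(gi + 1, len(groups)):
                    for a in groups[gi]:
                        for b in groups[gj]:
                            d = 2.0 * node.height
                            M[pos[a], pos[b]] = M[pos[b], pos[a]] = d
            return [x for g in groups for x in g]

        rec(self.root)
        return DistanceMatrix(ids=ids, values=M, metric_tag="cophenetic")

    def to_newick(self) -> str:
        """Newick with supports as internal node labels and branch lengths
        equal to the height drop along each edge."""

        def rec(node: TreeNode, parent_height: Optional[float]) -> str:
            if node.is_leaf:
                body = node.label
            else:
                inner = ",".join(rec(c, node.height) for c in node.children)
                lab = "" if node.support is None else f"{node.support:g}"
                body = f"({inner}){lab}"
            if parent_height is None:
                return body
            return f"{body}:{parent_height - node.height:.10g}"

        return rec(self.root, None) + ";"

    def write_newick(self, path) -> None:
        with open(path, "w") as fh:
            fh.write(self.to_newick() + "\n")


def upgma(D: DistanceMatrix) -> SupportTree:
    """Average-linkage agglomeration; deterministic lexicographic tie-break."""
    n = D.n
    if n < 2:
        raise ValueError("upgma needs at least 2 accessions")
    ids = D.ids
    # active clusters: key -> (min-id, node, size); distances on key pairs
    nodes = {i: TreeNode(height=0.0, label=ids[i]) for i in range(n)}
    key = {i: ids[i] for i in range(n)}
    size = {i: 1 for i in range(n)}
    dist = {(i, j): float(D.values[i, j]) for i in range(n) for j in range(i + 1, n)}
    active = list(range(n))
    next_id = n
    while len(active) > 1:
        best = None
        for ai in range(len(active)):
            for aj in range(ai + 1, len(active)):
                i, j = active[ai], active[aj]
                d = dist[(min(i, j), max(i, j))]
                tie_key = tuple(sorted((key[i], key[j])))
                cand = (d, tie_key, i, j)
                if best is None or cand[:2] < best[:2]:
                    best = cand
        d, _, i, j = best
        merged = TreeNode(height=d / 2.0, children=[nodes[i], nodes[j]])
        nodes[next_id] = merged
        key[next_id] = min(key[i], key[j])
        size[next_id] = size[i] + size[j]
        for k in active:
            if k in (i, j):
                continue
            dik = dist[(min(i, k), max(i, k))]
            djk = dist[(min(j, k), max(j, k))]
            dist[(min(next_id, k), max(next_id, k))] = (
                size[i] * dik + size[j] * djk
            ) / (size[i] + size[j])
        active = [k for k in active if k not in (i, j)] + [next_id]
        next_id += 1
    return SupportTree(root=nodes[active[0]], ids=ids)


def _upgma_clades(values: np.ndarray, ids: Sequence[str]) -> set[frozenset[str]]:
    """Clade sets of the UPGMA tree of a raw matrix (fast path for bootstrap)."""
    tree = upgma(DistanceMatrix(ids=tuple(ids), values=values))
    return set(tree.clades().keys())


def bootstrap_support(
    table: GenotypeTable,
    n_reps: int = 1000,
    seed: Optional[int] = None,
    threshold_pct: float = 40.0,
) -> SupportTree:
    """UPGMA tree of the Nei matrix with locus-bootstrap clade support.

    Loci (S-locus included, one unit each) are resampled with replacement
    ``n_reps`` times; support is the percentage of replicate trees containing
    each reference clade.  Clades below ``threshold_pct`` are collapsed into
    polytomies; ``threshold_pct=0`` keeps the tree fully binary.
    """
    if len(table) < 3:
        raise ValueError("bootstrap_support needs at least 3 accessions")
    if len(table.loci) < 2:
        raise ValueError("bootstrap_support needs at least 2 loci")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    loci, jxy, jx = nei_locus_components(table)
    L = len(loci)
    ids = table.accession_ids
    ref_values = nei_from_components(jxy, jx)
    ref = upgma(DistanceMatrix(ids=ids, values=ref_values, metric_tag="nei_standard"))
    ref_clades = ref.clades()
    counts = {lv: 0 for lv in ref_clades}
    rng = np.random.default_rng(seed)
    for _ in range(n_reps):
        draw = rng.integers(0, L, size=L)
        rep_values = nei_from_components(jxy, jx, locus_idx=draw)
        for lv in _upgma_clades(rep_values, ids):
            if lv in counts:
                counts[lv] += 1
    for lv, node in ref_clades.items():
        node.support = 100.0 * counts[lv] / n_reps
    if threshold_pct > 0:
        _collapse_low_support(ref.root, threshold_pct)
    return ref


def _collapse_low_support(root: TreeNode, threshold_pct: float) -> None:
    """Promote children of internal nodes whose support < threshold."""

    def rec(node: TreeNode) -> list[TreeNode]:
        # returns the list of nodes that should replace `node` in its parent
        if node.is_leaf:
            return [node]
        new_children: list[TreeNode] = []
        for c in node.children:
            new_children.extend(rec(c))
        node.children = new_children
        if node is not root and node.support is not None and node.support < threshold_pct:
            return node.children
        return [node]

    rec(root)


@dataclass
class Network:
    """Minimum spanning network: the MST plus tied alternative edges."""

    graph: nx.Graph
    metric_tag: str = ""

    @property
    def nodes(self) -> list[str]:
        return list(self.graph.nodes)

    def edges(self) -> list[tuple[str, str, float, bool, bool]]:
        out = []
        for u, v, d in self.graph.edges(data=True):
            a, b = sorted((u, v))
            out.append((a, b, d["weight"], d["in_mst"], d["tie_alternate"]))
        out.sort(key=lambda e: (e[2], e[0], e[1]))
        return out

    @property
    def mst_weight(self) -> float:
        return sum(d["weight"] for _, _, d in self.graph.edges(data=True) if d["in_mst"])

    def to_edge_csv(self, path) -> None:
        import csv

        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["from", "to", "weight", "in_mst", "tie_alternate"])
            for a, b, wt, mst, tie in self.edges():
                w.writerow([a, b, f"{wt:.10g}", int(mst), int(tie)])

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.graph, path)


class _UnionFind:
    def __init__(self, items):
        self.parent = {x: x for x in items}

    def find(self, x):
        while self.parent[x] != x:
            self.parent[x] = self.parent[self.parent[x]]
            x = self.parent[x]
        return x

    def union(self, a, b) -> bool:
        ra, rb = self.find(a), self.find(b)
        if ra == rb:
            return False
        self.parent[ra] = rb
        return True


def minimum_spanning_network(D: DistanceMatrix, include_ties: bool = True) -> Network:
    """Kruskal MST with deterministic (weight, endpoints) ordering; with
    ``include_ties``, every non-tree edge whose weight equals (within 1e-12)
    the heaviest edge on the tree path between its endpoints is added with
    the ``tie_alternate`` flag."""
    n = D.n
    if n < 2:
        raise ValueError("minimum_spanning_network needs at least 2 nodes")
    ids = D.ids
    edges = sorted(
        (float(D.values[i, j]), *sorted((ids[i], ids[j])))
        for i in range(n)
        for j in range(i + 1, n)
    )
    uf = _UnionFind(ids)
    G = nx.Graph()
    G.add_nodes_from(ids)
    mst_edges = []
    for w, u, v in edges:
        if uf.union(u, v):
            G.add_edge(u, v, weight=w, in_mst=True, tie_alternate=False)
            mst_edges.append((u, v, w))
    if include_ties:
        T = nx.Graph()
        T.add_weighted_edges_from(mst_edges)
        for w, u, v in edges:
            if G.has_edge(u, v):
                continue
            path = nx.shortest_path(T, u, v)
            wmax = max(
                T[a][b]["weight"] for a, b in zip(path[:-1], path[1:])
            )
            if abs(w - wmax) <= _TIE_TOL:
                G.add_edge(u, v, weight=w, in_mst=False, tie_alternate=True)
    return Network(graph=G, metric_tag=D.metric_tag)
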