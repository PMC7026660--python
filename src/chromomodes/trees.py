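"""Cell dendrograms from covariance distances.

Per-chromosome arc distances d_cov(A,B) are aggregated (default: maximum over
chromosomes) into a complete distance graph over cells, from which two
dendrograms are built: a minimum spanning tree (Prim's algorithm; cells may
sit at internal vertices) and a neighbor-joining tree (Saitou–Nei; all cells
are leaves). Neither construction implies a developmental or evolutionary
relation; they summarize covariance similarity.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np
import pandas as pd
from skbio import DistanceMatrix
from skbio.tree import nj as _skbio_nj

from .errors import ChromomodesError, DegenerateInputError


@dataclass
class DistanceGraph:
    """Complete weighted graph over cell labels (symmetric, zero diagonal)."""

    labels: list[str]
    matrix: np.ndarray
    aggregation: str = "max"

    def __post_init__(self):
        self.matrix = np.asarray(self.matrix, float)
        n = len(self.labels)
        if self.matrix.shape != (n, n):
            raise ChromomodesError("distance matrix shape mismatch")
        if np.abs(self.matrix - self.matrix.T).max() > 1e-9:
            raise ChromomodesError("distance matrix asymmetric")
        if np.abs(np.diag(self.matrix)).max() > 1e-9:
            raise ChromomodesError("distance matrix has nonzero diagonal")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.matrix, index=self.labels, columns=self.labels)


@dataclass
class CellTree:
    """A dendrogram over cells: MST (cells may be internal) or NJ (cells are
    leaves, internal nodes are anonymous)."""

    kind: str  # "mst" | "nj"
    labels: list[str]
    edges: list[tuple[str, str, float]]
    newick: str = ""

    @property
    def total_weight(self) -> float:
        return float(sum(w for _, _, w in self.edges))

    def bipartitions(self) -> list[frozenset]:
        """For every tree edge, the set of cell labels on one side (the side
        not containing the lexicographically smallest label)."""
        nodes = set()
        adj: dict[str, list[tuple[str, str, float]]] = {}
        for a, b, w in self.edges:
            nodes.update((a, b))
            adj.setdefault(a, []).append((a, b, w))
            adj.setdefault(b, []).append((b, a, w))
        anchor = min(self.labels)
        parts = []
        for a, b, _ in self.edges:
            # BFS from b with edge (a,b) removed
            seen = {b}
            queue = [b]
            while queue:
                x = queue.pop()
                for _, y, _ in adj[x]:
                    if (x, y) in ((a, b), (b, a)):
                        continue
                    if y not in seen:
                        seen.add(y)
                        queue.append(y)
            side = frozenset(l for l in self.labels if l in seen)
            if anchor in side:
                side = frozenset(self.labels) - side
            parts.append(side)
        return parts


def build_distance_graph(per_chromosome: dict[str, pd.DataFrame],
                         aggregate: str = "max") -> DistanceGraph:
    """Aggregate per-chromosome cell–cell distance matrices into one graph.

    ``per_chromosome`` maps chromosome → labeled square DataFrame. The default
    ``max`` keeps, for each cell pair, the largest distance observed on any
    chromosome; ``mean`` averages.
    """
    if not per_chromosome:
        raise DegenerateInputError("no per-chromosome distances")
    frames = list(per_chromosome.values())
    labels = list(frames[0].index)
    stack = []
    for f in frames:
        if list(f.index) != labels or list(f.columns) != labels:
            raise ChromomodesError("inconsistent cell sets across chromosomes")
        stack.append(f.to_numpy(dtype=float))
    arr = np.stack(stack)
    if aggregate == "max":
        agg = arr.max(axis=0)
    elif aggregate == "mean":
        agg = arr.mean(axis=0)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    return DistanceGraph(labels=labels, matrix=agg, aggregation=aggregate)


def minimum_spanning_tree(g: DistanceGraph) -> CellTree:
    """Prim's algorithm with deterministic lexicographic tie-breaking
    (weight, then sorted label pair)."""
    labels = sorted(g.labels)
    idx = {l: i for i, l in enumerate(g.labels)}
    start = labels[0]
    in_tree = {start}
    edges: list[tuple[str, str, float]] = []
    heap: list[tuple[float, str, str]] = []

    def push_from(u: str) -> None:
        for v in labels:
            if v not in in_tree:
                a, b = sorted((u, v))
                heapq.heappush(heap, (float(g.matrix[idx[u], idx[v]]), a, b))

    push_from(start)
    while len(in_tree) < len(labels):
        w, a, b = heapq.heappop(heap)
        new = b if a in in_tree else a
        if new in in_tree:
            continue
        edges.append((a, b, w))
        in_tree.add(new)
        push_from(new)
    tree = CellTree(kind="mst", labels=list(g.labels), edges=edges)
    tree.newick = _mst_newick(tree)
    return tree


def _mst_newick(tree: CellTree) -> str:
    """Serialize the MST as Newick rooted at the smallest label; cells at
    internal vertices appear as named internal nodes."""
    adj: dict[str, list[tuple[str, float]]] = {}
    for a, b, w in tree.edges:
        adj.setdefault(a, []).append((b, w))
        adj.setdefault(b, []).append((a, w))
    root = min(tree.labels)

    def render(node: str, parent: str | None) -> str:
        children = sorted((c, w) for c, w in adj.get(node, []) if c != parent)
        if not children:
            return node
        inner = ",".join(f"{render(c, node)}:{w:.10g}" for c, w in children)
        return f"({inner}){node}"

    return render(root, None) + ";"


def neighbor_joining(g: DistanceGraph) -> CellTree:
    """Saitou–Nei neighbor joining; negative intermediate branch lengths are
    clamped to zero with the deficit shifted to the sister branch."""
    if len(g.labels) < 3:
        raise DegenerateInputError("neighbor joining needs at least 3 cells")
    dm = DistanceMatrix(g.matrix, ids=list(g.labels))
    tree = _skbio_nj(dm, neg_as_zero=True)
    newick = str(tree).strip()
    edges: list[tuple[str, str, float]] = []
    counter = [0]

    def name_of(node) -> str:
        if node.name:
            return node.name
        counter[0] += 1
        node.name = f"_nj{counter[0]}"
        return node.name

    for node in tree.traverse(include_self=True):
        for child in node.children:
            edges.append((name_of(node), name_of(child),
                          float(child.length or 0.0)))
    return CellTree(kind="nj", labels=list(g.labels), edges=edges,
                    newick=newick)


def write_newick(tree: CellTree, path) -> None:
    with open(path, "w") as fh:
        fh.write(tree.newick + "\n")
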