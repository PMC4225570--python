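"""Hierarchical clustering flavors and the common dendrogram structures.

Three tree-building routes are provided:

* Ward's agglomeration on a correlation-distance matrix,
* Ward's agglomeration on the power-metric matrix (see :mod:`.simmap`),
* top-down *hierarchical two-means*: recursive bipartitioning with 2-means,
  keeping the best of several random restarts per split.

Ward on non-Euclidean dissimilarities applies the Lance-Williams update to
the supplied matrix — the convention in the infrared-imaging literature.
Merge heights need not be monotone under that abuse, so every operation
that needs a "topmost" ordering (truncation, horizontal cuts) ranks
vertices by merge order, not height.

Vertex numbering follows the standard linkage convention: leaves are
``0..N-1``, the i-th merge creates vertex ``N+i``, the root is ``2N-2``.
"""
from __future__ import annotations

import heapq
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.cluster import hierarchy as sch
from scipy.spatial.distance import pdist, squareform

from .simmap import DEFAULT_ALPHA, pairwise_power_distance

__all__ = [
    "Dendrogram",
    "TruncatedDendrogram",
    "distance_matrix",
    "ward_linkage",
    "bisecting_two_means",
    "horizontal_cut",
    "truncate_topmost",
    "cluster_spectra",
]


@dataclass
class Dendrogram:
    """A rooted binary merge tree over N items, wrapping a linkage matrix."""

    Z: np.ndarray  # (N-1, 4): child1, child2, height, count

    def __post_init__(self) -> None:
        self.Z = np.asarray(self.Z, dtype=float)
        if self.Z.ndim != 2 or self.Z.shape[1] != 4:
            raise ValueError("linkage matrix must be (N-1, 4)")

    @property
    def n_leaves(self) -> int:
        return self.Z.shape[0] + 1

    @property
    def n_vertices(self) -> int:
        return 2 * self.n_leaves - 1

    @property
    def root(self) -> int:
        return self.n_vertices - 1

    def children(self, v: int) -> tuple[int, int] | None:
        n = self.n_leaves
        if v < n:
            return None
        c1, c2 = self.Z[v - n, :2]
        return int(c1), int(c2)

    def merge_height(self, v: int) -> float:
        n = self.n_leaves
        if v < n:
            return 0.0
        return float(self.Z[v - n, 2])

    def leaves_under(self, v: int) -> np.ndarray:
        """Item indices in the subtree rooted at vertex v (iterative DFS)."""
        n = self.n_leaves
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u < n:
                out.append(u)
            else:
                stack.extend(self.children(u))  # type: ignore[arg-type]
        return np.array(sorted(out), dtype=int)

    # -- serialization -----------------------------------------------------

    def to_linkage_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("child1,child2,height,count\n")
            for c1, c2, h, cnt in self.Z:
                fh.write(f"{int(c1)},{int(c2)},{float(h)!r},{int(cnt)}\n")

    @classmethod
    def from_linkage_csv(cls, path: str | Path) -> "Dendrogram":
        rows = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
        return cls(rows)

    def to_newick(self) -> str:
        """Newick with item indices as taxa; branch lengths encode heights."""

        def rec(v: int) -> str:
            ch = self.children(v)
            if ch is None:
                return str(v)
            h = self.merge_height(v)
            parts = []
            for c in ch:
                bl = max(h - self.merge_height(c), 0.0)
                parts.append(f"{rec(c)}:{bl!r}")
            return "(" + ",".join(parts) + ")"

        import sys

        old = sys.getrecursionlimit()
        sys.setrecursionlimit(max(old, 4 * self.n_vertices + 100))
        try:
            return rec(self.root) + ";"
        finally:
            sys.setrecursionlimit(old)

    @classmethod
    def from_newick(cls, s: str) -> "Dendrogram":
        """Rebuild a Dendrogram from :meth:`to_newick` output.

        Internal vertices are ordered by height (root-path heights are
        reconstructed from branch lengths), so round-trips are faithful for
        monotone trees.
        """
        node, _ = _parse_newick(s.strip().rstrip(";"), 0)
        leaves: list[int] = []
        internals: list[dict] = []
        stack = [node]
        while stack:
            nd = stack.pop()
            if nd["children"]:
                internals.append(nd)
                stack.extend(c for c, _bl in nd["children"])
            else:
                leaves.append(int(nd["name"]))
        n = len(leaves)
        for nd in internals:
            nd["height"] = _height_from(nd)
        internals.sort(key=lambda nd: nd["height"])
        Z = np.zeros((n - 1, 4))
        for i, nd in enumerate(internals):
            nd["vid"] = n + i
            cs, cnt = [], 0
            for c, _bl in nd["children"]:
                cs.append(int(c["name"]) if not c["children"] else c["vid"])
                cnt += c.get("count", 1)
            nd["count"] = cnt
            Z[i] = [min(cs), max(cs), nd["height"], cnt]
        return cls(Z)


def _height_from(nd) -> float:
    best = 0.0
    for c, bl in nd["children"]:
        sub = _height_from(c) if c["children"] else 0.0
        best = max(best, sub + bl)
    return best


def _parse_newick(s: str, i: int):
    """Minimal parser for the restricted newick this package writes."""
    node = {"children": [], "name": None}
    if s[i] == "(":
        i += 1
        while True:
            child, i = _parse_newick(s, i)
            bl = 0.0
            if i < len(s) and s[i] == ":":
                j = i + 1
                while j < len(s) and s[j] not in ",()":
                    j += 1
                bl = float(s[i + 1 : j])
                i = j
            node["children"].append((child, bl))
            if s[i] == ",":
                i += 1
                continue
            if s[i] == ")":
                i += 1
                break
    j = i
    while j < len(s) and s[j] not in ",():;":
        j += 1
    name = s[i:j]
    if name:
        node["name"] = name
    return node, j


@dataclass
class TruncatedDendrogram:
    """A dendrogram restricted to its topmost vertices.

    ``children_map`` holds the retained internal structure; ``frontier_items``
    maps each frontier vertex (a retained vertex whose children were pruned,
    or a genuine leaf) to the multiset of item indices it carries.  The
    frontier jointly covers every item exactly once.
    """

    children_map: dict[int, tuple[int, int]]
    frontier_items: dict[int, np.ndarray]
    root: int
    n_items: int
    heights: dict[int, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        total = sum(len(v) for v in self.frontier_items.values())
        if total != self.n_items:
            raise ValueError(
                f"frontier covers {total} items, expected {self.n_items}"
            )

    @property
    def vertices(self) -> list[int]:
        return sorted(set(self.children_map) | set(self.frontier_items))

    @property
    def n_vertices(self) -> int:
        return len(self.children_map) + len(self.frontier_items)

    @property
    def frontier(self) -> list[int]:
        return sorted(self.frontier_items)

    def children(self, v: int) -> tuple[int, int] | None:
        return self.children_map.get(v)

    def postorder(self) -> list[int]:
        out, stack = [], [(self.root, False)]
        while stack:
            v, done = stack.pop()
            if done or v in self.frontier_items:
                out.append(v)
            else:
                stack.append((v, True))
                for c in self.children_map[v]:
                    stack.append((c, False))
        return out

    def items_under(self, v: int) -> np.ndarray:
        if v in self.frontier_items:
            return self.frontier_items[v]
        out, stack = [], [v]
        while stack:
            u = stack.pop()
            if u in self.frontier_items:
                out.append(self.frontier_items[u])
            else:
                stack.extend(self.children_map[u])
        return np.sort(np.concatenate(out))

    def parent_map(self) -> dict[int, int]:
        return {
            c: v for v, (a, b) in self.children_map.items() for c in (a, b)
        }


# ---------------------------------------------------------------------------
# Distances and agglomeration
# ---------------------------------------------------------------------------


def distance_matrix(
    spectra: np.ndarray,
    metric: str = "correlation",
    alpha: float = DEFAULT_ALPHA,
) -> np.ndarray:
    """Square distance matrix under the correlation or power metric.

    Correlation distance is 1 minus the Pearson correlation of the two
    spectra; the power distance is ``1 - sigma_alpha`` (requires spectra in
    [0, 1]).  The diagonal is exactly zero.
    """
    spectra = np.asarray(spectra, dtype=float)
    if spectra.ndim != 2 or spectra.shape[0] < 2:
        raise ValueError("need an (N>=2, B) spectra matrix")
    if metric == "correlation":
        sd = spectra.std(axis=1)
        scale = np.abs(spectra).max(axis=1)
        bad = np.flatnonzero(sd <= 1e-12 * np.maximum(scale, 1e-300))
        if bad.size:
            raise ValueError(
                f"zero-variance spectrum at row {bad[0]}: correlation undefined"
            )
        d = squareform(pdist(spectra, metric="correlation"))
        np.fill_diagonal(d, 0.0)
        return d
    if metric == "power":
        return pairwise_power_distance(spectra, alpha=alpha)
    raise ValueError(f"unknown metric {metric!r}")


def ward_linkage(dist: np.ndarray) -> Dendrogram:
    """Agglomerate under the Ward (Lance-Williams) update on given dissimilarities."""
    dist = np.asarray(dist, dtype=float)
    if not np.all(np.isfinite(dist)):
        raise ValueError("distance matrix contains non-finite entries")
    if dist.ndim == 2:
        if not np.allclose(dist, dist.T):
            raise ValueError("distance matrix is not symmetric")
        condensed = squareform(dist, checks=False)
    else:
        condensed = dist
    Z = sch.linkage(condensed, method="ward")
    return Dendrogram(Z)


def horizontal_cut(d: Dendrogram, k: int) -> np.ndarray:
    """Partition into k clusters by removing the k-1 topmost merges.

    Merges are ranked by merge order (identical to height for monotone
    trees, well defined under Ward inversions).  Returns a length-N array
    of dense cluster ids 0..k-1, numbered by smallest member item.
    """
    n = d.n_leaves
    if not 1 <= k <= n:
        raise ValueError(f"k={k} out of range 1..{n}")
    removed_floor = 2 * n - 1 - (k - 1)  # vertices with id >= floor are removed
    labels = np.empty(n, dtype=int)
    roots = [d.root] if k == 1 else []
    for v in range(removed_floor, 2 * n - 1):
        for c in d.children(v):  # type: ignore[union-attr]
            if c < removed_floor:
                roots.append(c)
    roots = sorted(roots, key=lambda v: int(d.leaves_under(v)[0]))
    for cid, v in enumerate(roots):
        labels[d.leaves_under(v)] = cid
    return labels


def truncate_topmost(d: Dendrogram, V: int = 255) -> TruncatedDendrogram:
    """Restrict a dendrogram to its topmost V vertices.

    Starting from the root, internal vertices are expanded in descending
    merge order; each expansion adds the vertex's two children, so the
    truncated tree holds ``1 + 2*floor((V-1)/2)`` vertices (capped at the
    full tree) and its frontier carries the pruned item multisets.  With
    the default V = 255 the frontier holds at most 128 segments.
    """
    if V < 1:
        raise ValueError("V must be >= 1")
    n = d.n_leaves
    n_exp = min((V - 1) // 2, n - 1)
    floor = 2 * n - 1 - n_exp  # internal ids >= floor are expanded
    children_map: dict[int, tuple[int, int]] = {}
    frontier: dict[int, np.ndarray] = {}
    heights: dict[int, float] = {}
    if n_exp == 0:
        frontier[d.root] = np.arange(n)
        heights[d.root] = d.merge_height(d.root)
        return TruncatedDendrogram({}, frontier, d.root, n, heights)
    for v in range(floor, 2 * n - 1):
        children_map[v] = d.children(v)  # type: ignore[assignment]
        heights[v] = d.merge_height(v)
    for v, (a, b) in list(children_map.items()):
        for c in (a, b):
            if c < floor:
                frontier[c] = d.leaves_under(c)
                heights[c] = d.merge_height(c)
    return TruncatedDendrogram(children_map, frontier, d.root, n, heights)


# ---------------------------------------------------------------------------
# Hierarchical two-means
# ---------------------------------------------------------------------------


def _two_means_split(
    X: np.ndarray, restarts: int, rng: np.random.Generator, max_iter: int = 100
):
    """Best-of-``restarts`` 2-means with random-partition initialization.

    Returns (labels, inertia) or None when every restart failed to produce
    two non-empty clusters (e.g. all points identical).
    """
    from sklearn.cluster import KMeans

    best = None
    for _ in range(restarts):
        lab0 = rng.integers(0, 2, size=len(X))
        if lab0.min() == lab0.max():  # force both sides non-empty
            lab0[rng.integers(len(X))] = 1 - lab0[0]
        centers = np.stack([X[lab0 == 0].mean(axis=0), X[lab0 == 1].mean(axis=0)])
        km = KMeans(n_clusters=2, init=centers, n_init=1, max_iter=max_iter)
        lab = km.fit_predict(X)
        if lab.min() == lab.max():
            continue
        if best is None or km.inertia_ < best[1]:
            best = (lab, float(km.inertia_))
    return best


def bisecting_two_means(
    spectra: np.ndarray,
    vertex_budget: int = 255,
    restarts: int = 5,
    seed: int | None = None,
) -> TruncatedDendrogram:
    """Top-down hierarchical two-means, built only down to ``vertex_budget``.

    The frontier node with the largest within-cluster sum of squares is
    split next (so the topmost vertices capture the dominant structure);
    each split keeps the lowest-inertia result of ``restarts`` random
    2-means initializations.  Splitting stops once the tree holds
    ``vertex_budget`` vertices or every frontier node is a singleton.
    Fully reproducible from ``seed``.
    """
    X = np.asarray(spectra, dtype=float)
    if X.ndim != 2 or len(X) < 2:
        raise ValueError("need an (N>=2, B) spectra matrix")
    if vertex_budget < 1:
        raise ValueError("vertex_budget must be >= 1")
    rng = np.random.default_rng(seed)
    n = len(X)

    def sse(idx: np.ndarray) -> float:
        sub = X[idx]
        return float(((sub - sub.mean(axis=0)) ** 2).sum())

    next_id = 0
    root = next_id
    next_id += 1
    frontier_items: dict[int, np.ndarray] = {root: np.arange(n)}
    children_map: dict[int, tuple[int, int]] = {}
    heights: dict[int, float] = {root: sse(np.arange(n))}
    # max-heap on SSE; counter breaks ties deterministically
    heap: list[tuple[float, int, int]] = [(-heights[root], root, root)]
    n_vertices = 1
    while heap and n_vertices + 2 <= vertex_budget:
        neg_sse, _, v = heapq.heappop(heap)
        idx = frontier_items.get(v)
        if idx is None or len(idx) < 2:
            continue
        split = _two_means_split(X[idx], restarts, rng)
        if split is None:
            continue  # unsplittable node stays on the frontier
        lab, _inertia = split
        a, b = next_id, next_id + 1
        next_id += 2
        ia, ib = idx[lab == 0], idx[lab == 1]
        del frontier_items[v]
        children_map[v] = (a, b)
        frontier_items[a], frontier_items[b] = ia, ib
        for u, iu in ((a, ia), (b, ib)):
            heights[u] = sse(iu)
            if len(iu) > 1:
                heapq.heappush(heap, (-heights[u], u, u))
        n_vertices += 2
    return TruncatedDendrogram(children_map, frontier_items, root, n, heights)


# ---------------------------------------------------------------------------
# One-call pipeline helper
# ---------------------------------------------------------------------------

FLAVORS = ("ward_correlation", "ward_power", "two_means")


def cluster_spectra(
    spectra: np.ndarray,
    flavor: str = "ward_power",
    V: int = 255,
    alpha: float = DEFAULT_ALPHA,
    restarts: int = 5,
    seed: int | None = None,
) -> TruncatedDendrogram:
    """Build a topmost-V truncated dendrogram under one of the three flavors."""
    if flavor == "ward_correlation":
        return truncate_topmost(ward_linkage(distance_matrix(spectra, "correlation")), V)
    if flavor == "ward_power":
        return truncate_topmost(
            ward_linkage(distance_matrix(spectra, "power", alpha=alpha)), V
        )
    if flavor == "two_means":
        return bisecting_two_means(spectra, vertex_budget=V, restarts=restarts, seed=seed)
    raise ValueError(f"unknown clustering flavor {flavor!r}; expected one of {FLAVORS}")
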