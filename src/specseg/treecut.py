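"""Optimal non-horizontal dendrogram cuts ("tree assignments").

Given a (truncated) dendrogram over n items and a reference partitioning
C' of those items, a *tree assignment* selects an antichain of Q vertices
whose subtrees partition the items — a non-horizontal cut of depth Q.  The
selection minimizes the data-dependent part of the Mirkin distance between
the implied partitioning C and the reference:

    M(C, C') = sum_i |C_i|^2 + sum_j |C'_j|^2 - 2 sum_ij m_ij^2,
    m_ij = |C_i ∩ C'_j|.

Since the reference term sum_j |C'_j|^2 is constant, it suffices to
minimize  M' = sum_{selected i} w_i  with per-vertex weights

    w_i = |C_i|^2 - 2 sum_j m_ij^2,

computable bottom-up in one pass.  Minimizing the Mirkin distance is
equivalent to maximizing the Rand index, R = 1 - M/(n(n-1)).

The selection problem is the integer program

    min  sum_i w_i X_i
    s.t. sum over each root-to-frontier path of X = 1   (exact cover)
         sum_i X_i = Q                                  (depth)
         X_i in {0, 1},

which is polynomial on trees: the default solver is an exact dynamic
program over the tree (min-cost exact-cover antichain of cardinality Q);
the MILP formulation is retained as an alternative backend and as a
cross-check.  A brute-force antichain enumerator serves as an independent
oracle for small instances.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .hclust import TruncatedDendrogram
from . import validate as _validate

__all__ = [
    "VertexWeights",
    "TreeAssignment",
    "InfeasibleQError",
    "compute_weights",
    "solve",
    "brute_force_oracle",
    "majority_vote",
    "depth_sweep",
]


class InfeasibleQError(ValueError):
    """Raised when no size-Q antichain covers the items; carries ``max_feasible``."""

    def __init__(self, Q: int, max_feasible: int):
        super().__init__(
            f"no antichain of size Q={Q}; feasible sizes are 1..{max_feasible}"
        )
        self.Q = Q
        self.max_feasible = max_feasible


@dataclass
class VertexWeights:
    """Per-vertex Mirkin weights w_i and class-overlap vectors."""

    w: dict[int, int]
    overlaps: dict[int, np.ndarray]  # vertex -> counts per reference class
    sizes: dict[int, int]
    class_ids: np.ndarray  # column order of the overlap vectors


def _ref_labels(ref) -> np.ndarray:
    labels = np.asarray(getattr(ref, "assignment", ref), dtype=int)
    if labels.ndim != 1:
        raise ValueError("reference labels must be a 1-D array")
    return labels


def compute_weights(t: TruncatedDendrogram, ref) -> VertexWeights:
    """Exact integer weights w_i = |C_i|^2 - 2 sum_j m_ij^2 for every vertex.

    Overlap vectors are accumulated bottom-up: a parent's vector is the sum
    of its children's.  ``ref`` labels every item (array of class ids or a
    :class:`~specseg.validate.Partitioning`).
    """
    labels = _ref_labels(ref)
    if labels.shape != (t.n_items,):
        raise ValueError(
            f"reference labels cover {labels.shape[0]} items, tree holds {t.n_items}"
        )
    class_ids, dense = np.unique(labels, return_inverse=True)
    k = len(class_ids)
    overlaps: dict[int, np.ndarray] = {}
    w: dict[int, int] = {}
    sizes: dict[int, int] = {}
    for v in t.postorder():
        if v in t.frontier_items:
            ov = np.bincount(dense[t.frontier_items[v]], minlength=k)
        else:
            a, b = t.children_map[v]
            ov = overlaps[a] + overlaps[b]
        overlaps[v] = ov
        size = int(ov.sum())
        sizes[v] = size
        w[v] = size * size - 2 * int((ov.astype(np.int64) ** 2).sum())
    return VertexWeights(w, overlaps, sizes, class_ids)


@dataclass
class TreeAssignment:
    """An antichain of selected vertices with its objective and partitioning."""

    selected: tuple[int, ...]
    Q: int
    objective: int
    partition: np.ndarray  # item -> dense cluster id (one per selected vertex)
    vertex_of_cluster: tuple[int, ...]
    labels: dict[int, int] = field(default_factory=dict)  # vertex -> class (majority vote)
    n_label_ties: int = 0

    def mirkin(self, ref) -> int:
        """Full Mirkin distance to the reference: M = M' + sum_j |C'_j|^2."""
        labels = _ref_labels(ref)
        _, counts = np.unique(labels, return_counts=True)
        return self.objective + int((counts.astype(np.int64) ** 2).sum())

    def rand_index(self, ref) -> float:
        """Rand index implied by the objective via R = 1 - M/(n(n-1))."""
        n = len(self.partition)
        return 1.0 - self.mirkin(ref) / (n * (n - 1))


def _assemble(t: TruncatedDendrogram, selected: list[int], vw: VertexWeights) -> TreeAssignment:
    selected = sorted(selected)
    part = np.full(t.n_items, -1, dtype=int)
    for cid, v in enumerate(selected):
        part[t.items_under(v)] = cid
    if (part < 0).any():
        raise AssertionError("selected vertices do not cover all items")
    obj = int(sum(vw.w[v] for v in selected))
    return TreeAssignment(tuple(selected), len(selected), obj, part, tuple(selected))


def _check_antichain(t: TruncatedDendrogram, selected: tuple[int, ...]) -> None:
    parent = t.parent_map()
    chosen = set(selected)
    for v in selected:
        u = parent.get(v)
        while u is not None:
            if u in chosen:
                raise AssertionError(f"vertices {v} and {u} violate the antichain property")
            u = parent.get(u)


def solve(
    t: TruncatedDendrogram,
    ref,
    Q: int,
    mode: str = "exact_Q",
    backend: str = "dp",
) -> TreeAssignment:
    """Minimum-M' antichain of size Q (``exact_Q``) or at most Q (``at_most_Q``).

    ``backend='dp'`` runs the exact tree dynamic program; ``backend='ilp'``
    solves the integer program with scipy's MILP (HiGHS).  Both are exact;
    the antichain and exact-cover structure of the result is verified
    before returning.
    """
    if mode not in ("exact_Q", "at_most_Q"):
        raise ValueError(f"unknown mode {mode!r}")
    max_Q = len(t.frontier_items)
    if not 1 <= Q <= max_Q:
        raise InfeasibleQError(Q, max_Q)
    vw = compute_weights(t, ref)
    if backend == "dp":
        selected = _solve_dp(t, vw, Q, mode)
    elif backend == "ilp":
        selected = _solve_ilp(t, vw, Q, mode)
    else:
        raise ValueError(f"unknown backend {backend!r}")
    ta = _assemble(t, selected, vw)
    _check_antichain(t, ta.selected)
    if mode == "exact_Q" and ta.Q != Q:
        raise AssertionError(f"solver returned {ta.Q} vertices, expected {Q}")
    return ta


def _solve_dp(
    t: TruncatedDendrogram, vw: VertexWeights, Q: int, mode: str
) -> list[int]:
    INF = np.inf
    dp: dict[int, np.ndarray] = {}
    choice: dict[int, np.ndarray] = {}
    for v in t.postorder():
        row = np.full(Q + 1, INF)
        row[1] = vw.w[v]  # select v itself
        ch = t.children_map.get(v)
        if ch is not None:
            a, b = ch
            ra, rb = dp[a], dp[b]
            ch_choice = np.zeros(Q + 1, dtype=int)
            for q in range(2, Q + 1):
                # split q between the two children (>=1 each)
                cand = ra[1:q] + rb[q - 1 : 0 : -1]
                j = int(np.argmin(cand))
                if cand[j] < row[q]:
                    row[q] = cand[j]
                    ch_choice[q] = j + 1  # budget sent to child a
            choice[v] = ch_choice
        dp[v] = row
    root_row = dp[t.root]
    if mode == "exact_Q":
        q_star = Q
        if not np.isfinite(root_row[Q]):
            raise InfeasibleQError(Q, len(t.frontier_items))
    else:
        q_star = int(np.nanargmin(np.where(np.isfinite(root_row), root_row, np.inf)))
    selected: list[int] = []
    stack = [(t.root, q_star)]
    while stack:
        v, q = stack.pop()
        if q == 1 or v not in choice or (q > 1 and choice[v][q] == 0):
            if q == 1:
                selected.append(v)
                continue
            raise AssertionError("inconsistent DP reconstruction")
        qa = int(choice[v][q])
        a, b = t.children_map[v]
        stack.append((a, qa))
        stack.append((b, q - qa))
    return selected


def _solve_ilp(
    t: TruncatedDendrogram, vw: VertexWeights, Q: int, mode: str
) -> list[int]:
    from scipy.optimize import LinearConstraint, milp

    verts = t.vertices
    pos = {v: i for i, v in enumerate(verts)}
    p = len(verts)
    parent = t.parent_map()
    rows = []
    for f in t.frontier:
        # one constraint per root-frontier path, aggregated per frontier vertex
        r = np.zeros(p)
        u: int | None = f
        while u is not None:
            r[pos[u]] = 1.0
            u = parent.get(u)
        rows.append(r)
    A = np.vstack(rows + [np.ones(p)])
    lb = np.ones(len(rows) + 1)
    ub = np.ones(len(rows) + 1)
    lb[-1] = 1.0 if mode == "at_most_Q" else Q
    ub[-1] = Q
    c = np.array([vw.w[v] for v in verts], dtype=float)
    res = milp(
        c=c,
        constraints=LinearConstraint(A, lb, ub),
        integrality=np.ones(p),
        bounds=(0, 1),
    )
    if not res.success:
        raise InfeasibleQError(Q, len(t.frontier_items))
    return [verts[i] for i in np.flatnonzero(np.round(res.x) > 0.5)]


def brute_force_oracle(t: TruncatedDendrogram, ref, Q: int) -> TreeAssignment:
    """Exhaustive minimum over all size-Q exact-cover antichains.

    Independent of the DP/ILP solvers: enumerates antichains recursively
    (each vertex is either selected or expanded into both children) and
    keeps the minimum objective, ties broken toward the lexicographically
    smallest sorted vertex-id set.  Refuses instances with more than 24
    selectable vertices.
    """
    if t.n_vertices > 24:
        raise ValueError(f"{t.n_vertices} selectable vertices exceed the oracle limit (24)")
    max_Q = len(t.frontier_items)
    if not 1 <= Q <= max_Q:
        raise InfeasibleQError(Q, max_Q)
    vw = compute_weights(t, ref)
    max_under = {
        v: (1 if v in t.frontier_items else None) for v in t.postorder()
    }
    for v in t.postorder():
        if max_under[v] is None:
            a, b = t.children_map[v]
            max_under[v] = max_under[a] + max_under[b]  # type: ignore[operator]

    def antichains(v: int, q: int):
        if q < 1 or q > max_under[v]:  # type: ignore[operator]
            return
        if q == 1:
            yield [v]
        ch = t.children_map.get(v)
        if ch is not None and q >= 2:
            a, b = ch
            for qa in range(1, q):
                for left in antichains(a, qa):
                    for right in antichains(b, q - qa):
                        yield left + right

    best: tuple[int, list[int]] | None = None
    for sel in antichains(t.root, Q):
        obj = sum(vw.w[v] for v in sel)
        key = (obj, sorted(sel))
        if best is None or key < (best[0], sorted(best[1])):
            best = (obj, sel)
    if best is None:
        raise InfeasibleQError(Q, max_Q)
    return _assemble(t, best[1], vw)


def majority_vote(
    a: TreeAssignment, t: TruncatedDendrogram, ref
) -> TreeAssignment:
    """Label each selected vertex with its modal reference class.

    Every item inherits the label of its selected ancestor; ties go to the
    smallest class id and are counted in ``n_label_ties``.  Returns a new
    assignment carrying ``labels`` and leaves the input untouched.  The
    per-item class labels are available as ``class_labels(a)``.
    """
    labels = _ref_labels(ref)
    class_ids = np.unique(labels)
    vertex_label: dict[int, int] = {}
    ties = 0
    for v in a.selected:
        items = t.items_under(v)
        counts = np.bincount(
            np.searchsorted(class_ids, labels[items]), minlength=len(class_ids)
        )
        top = counts.max()
        winners = class_ids[counts == top]
        if len(winners) > 1:
            ties += 1
        vertex_label[v] = int(winners.min())
    return TreeAssignment(
        a.selected, a.Q, a.objective, a.partition, a.vertex_of_cluster,
        labels=vertex_label, n_label_ties=ties,
    )


def class_labels(a: TreeAssignment) -> np.ndarray:
    """Per-item class labels implied by a majority-voted assignment."""
    if not a.labels:
        raise ValueError("assignment carries no class labels; run majority_vote first")
    lut = np.array([a.labels[v] for v in a.vertex_of_cluster])
    return lut[a.partition]


def depth_sweep(
    t: TruncatedDendrogram,
    ref,
    Q_values,
    mode: str = "exact_Q",
    backend: str = "dp",
) -> pd.DataFrame:
    """Solve + majority-vote + validate across a grid of depths Q.

    Returns a tidy table with one row per Q: feasibility, objective M',
    Rand index and accuracy of the majority-voted class labeling, plus the
    Rand index of the raw Q-cluster partitioning.  Infeasible depths are
    recorded and the sweep continues.
    """
    labels = _ref_labels(ref)
    rows = []
    for Q in Q_values:
        try:
            a = solve(t, labels, int(Q), mode=mode, backend=backend)
        except InfeasibleQError as exc:
            rows.append(
                {"Q": int(Q), "feasible": False, "objective": np.nan,
                 "rand_index": np.nan, "accuracy": np.nan,
                 "rand_partition": np.nan, "note": str(exc)}
            )
            continue
        voted = majority_vote(a, t, labels)
        pred = class_labels(voted)
        rows.append(
            {
                "Q": int(Q),
                "feasible": True,
                "objective": a.objective,
                "rand_index": _validate.rand_index(pred, labels),
                "accuracy": _validate.accuracy(pred, labels),
                "rand_partition": a.rand_index(labels),
                "note": "",
            }
        )
    return pd.DataFrame(rows)
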