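"""Partition-comparison measures and the Monte-Carlo validation driver.

Two partitionings C and C' of items {1..n} are compared through pair
counts: the Rand index is the fraction of ordered item pairs (i != j) on
which the two partitionings agree (both together or both apart),

    R(C, C') = 2 (n11 + n00) / (n (n - 1)),

and the Mirkin metric counts pairwise disagreements through cluster sizes
and overlaps m_ij = |C_i ∩ C'_j|:

    M(C, C') = sum_i |C_i|^2 + sum_j |C'_j|^2 - 2 sum_ij m_ij^2.

The two are linearly related, R = 1 - M / (n (n - 1)); the implementations
here deliberately use independent routes (explicit pair enumeration vs
overlap sums) so the identity doubles as a correctness check.
"""
from __future__ import annotations

from dataclasses import dataclass
import numpy as np
import pandas as pd

from .spectra_core import BACKGROUND, UNASSIGNED, LabeledSpectra

__all__ = [
    "Partitioning",
    "ValidationReport",
    "rand_index",
    "mirkin",
    "adjusted_rand",
    "accuracy",
    "confusion",
    "monte_carlo",
    "MonteCarloResult",
]


@dataclass
class Partitioning:
    """An assignment of n items to clusters, as a dense integer label array."""

    assignment: np.ndarray

    def __post_init__(self) -> None:
        self.assignment = np.asarray(self.assignment, dtype=int)
        if self.assignment.ndim != 1:
            raise ValueError("assignment must be 1-D (one cluster id per item)")

    @property
    def n(self) -> int:
        return len(self.assignment)

    @property
    def k(self) -> int:
        return len(np.unique(self.assignment))

    def sizes(self) -> np.ndarray:
        return np.unique(self.assignment, return_counts=True)[1]


def _labels(p) -> np.ndarray:
    a = np.asarray(getattr(p, "assignment", p), dtype=int)
    if a.ndim != 1:
        raise ValueError("partition labels must be 1-D")
    return a


def _pair_labels(C, Cp) -> tuple[np.ndarray, np.ndarray]:
    a, b = _labels(C), _labels(Cp)
    if a.shape != b.shape:
        raise ValueError("partitionings cover different item sets")
    if len(a) < 2:
        raise ValueError("pair-counting measures are undefined for n < 2")
    return a, b


def rand_index(C, Cp) -> float:
    """Rand index by explicit pair counting (boolean co-membership matrices)."""
    a, b = _pair_labels(C, Cp)
    same_a = a[:, None] == a[None, :]
    same_b = b[:, None] == b[None, :]
    n = len(a)
    agree = (same_a == same_b).sum() - n  # drop the diagonal (i == j)
    return float(agree) / (n * (n - 1))


def mirkin(C, Cp) -> int:
    """Mirkin metric via cluster sizes and the overlap (contingency) table."""
    a, b = _pair_labels(C, Cp)
    _, ai = np.unique(a, return_inverse=True)
    _, bi = np.unique(b, return_inverse=True)
    ka, kb = ai.max() + 1, bi.max() + 1
    m = np.bincount(ai * kb + bi, minlength=ka * kb).reshape(ka, kb).astype(np.int64)
    sa = m.sum(axis=1)
    sb = m.sum(axis=0)
    return int((sa**2).sum() + (sb**2).sum() - 2 * (m**2).sum())


def adjusted_rand(C, Cp) -> float:
    """Chance-corrected Rand index (extra output; approaches 0 under random labels).

    The raw Rand index tends toward 1 on datasets with many classes, which
    makes differences hard to read; the adjusted form corrects for that.
    """
    from sklearn.metrics import adjusted_rand_score

    a, b = _pair_labels(C, Cp)
    return float(adjusted_rand_score(a, b))


def accuracy(pred, ref) -> float:
    """Fraction of items whose predicted class equals the reference class.

    UNASSIGNED (and BACKGROUND) predictions count as incorrect; the
    denominator is the number of all items passed in.
    """
    p, r = _labels(pred), _labels(ref)
    if p.shape != r.shape:
        raise ValueError("prediction and reference cover different item sets")
    if len(p) == 0:
        raise ValueError("accuracy undefined for zero items")
    return float(((p == r) & (p != UNASSIGNED) & (p != BACKGROUND)).mean())


def confusion(pred, ref, class_names: dict[int, str] | None = None) -> pd.DataFrame:
    """Reference-class x predicted-class count table.

    Rows are reference classes sorted by class size descending (largest
    tissue class first), with sizes annotated in the row index; a trailing
    UNASSIGNED column collects rejected items when present.
    """
    p, r = _labels(pred), _labels(ref)
    if p.shape != r.shape:
        raise ValueError("prediction and reference cover different item sets")
    names = class_names or {}

    def name_of(c: int) -> str:
        if c == UNASSIGNED:
            return "UNASSIGNED"
        if c == BACKGROUND:
            return "BACKGROUND"
        return names.get(c, f"class_{c:02d}")

    ref_classes, ref_sizes = np.unique(r, return_counts=True)
    order = np.argsort(-ref_sizes, kind="stable")
    ref_classes, ref_sizes = ref_classes[order], ref_sizes[order]
    pred_classes = np.unique(p)
    # predicted columns in reference order first, extras (incl. UNASSIGNED) last
    cols = [c for c in ref_classes if c in pred_classes] + [
        c for c in pred_classes if c not in ref_classes
    ]
    table = np.zeros((len(ref_classes), len(cols)), dtype=int)
    for i, rc in enumerate(ref_classes):
        sel = p[r == rc]
        for j, pc in enumerate(cols):
            table[i, j] = int((sel == pc).sum())
    index = [f"{name_of(c)} ({s})" for c, s in zip(ref_classes, ref_sizes)]
    return pd.DataFrame(table, index=index, columns=[name_of(c) for c in cols])


def plot_confusion(table: pd.DataFrame, path) -> None:
    """Render a confusion table as a row-normalized heat map (PNG/PDF)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    frac = table.to_numpy(dtype=float)
    frac = frac / np.maximum(frac.sum(axis=1, keepdims=True), 1)
    fig, ax = plt.subplots(figsize=(1 + 0.45 * table.shape[1], 1 + 0.4 * table.shape[0]))
    im = ax.imshow(frac, cmap="viridis", vmin=0, vmax=1)
    ax.set_xticks(range(table.shape[1]), table.columns, rotation=90, fontsize=7)
    ax.set_yticks(range(table.shape[0]), table.index, fontsize=7)
    fig.colorbar(im, ax=ax, label="row fraction")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


@dataclass
class ValidationReport:
    """Bundle of the standard external-validation measures."""

    rand_index: float
    mirkin: int
    accuracy: float
    adjusted_rand: float
    confusion: pd.DataFrame

    @classmethod
    def from_labels(
        cls, pred, ref, class_names: dict[int, str] | None = None
    ) -> "ValidationReport":
        return cls(
            rand_index=rand_index(pred, ref),
            mirkin=mirkin(pred, ref),
            accuracy=accuracy(pred, ref),
            adjusted_rand=adjusted_rand(pred, ref),
            confusion=confusion(pred, ref, class_names),
        )

    def to_dict(self) -> dict:
        return {
            "rand_index": self.rand_index,
            "mirkin": self.mirkin,
            "accuracy": self.accuracy,
            "adjusted_rand": self.adjusted_rand,
        }


# ---------------------------------------------------------------------------
# Monte-Carlo cross validation
# ---------------------------------------------------------------------------


@dataclass
class MonteCarloResult:
    """Per-fold scores plus their mean and standard deviation."""

    folds: pd.DataFrame

    def summary(self) -> pd.DataFrame:
        g = self.folds.groupby(["flavor", "Q"])[["rand_index", "accuracy"]]
        return g.agg(["mean", "std"]).fillna(0.0)

    def mean(self, flavor: str, Q: int, measure: str = "rand_index") -> float:
        sel = self.folds[(self.folds["flavor"] == flavor) & (self.folds["Q"] == Q)]
        return float(sel[measure].mean())

    def sd(self, flavor: str, Q: int, measure: str = "rand_index") -> float:
        sel = self.folds[(self.folds["flavor"] == flavor) & (self.folds["Q"] == Q)]
        return float(sel[measure].std(ddof=1))


def _stratified_subsample(
    labels: np.ndarray, fraction: float, rng: np.random.Generator
) -> np.ndarray:
    idx = []
    for c in np.unique(labels):
        members = np.flatnonzero(labels == c)
        m = int(round(fraction * len(members)))
        if m < 1:
            raise ValueError(f"class {c} emptied by subsampling (fraction={fraction})")
        idx.append(rng.choice(members, size=m, replace=False))
    return np.sort(np.concatenate(idx))


def monte_carlo(
    train: LabeledSpectra,
    flavors=("ward_correlation", "ward_power", "two_means"),
    Q_values=(14,),
    folds: int = 10,
    subsample_fraction: float = 0.8,
    seed: int | None = None,
    alpha: float = 1.5,
    V: int = 255,
    mode: str = "exact_Q",
) -> MonteCarloResult:
    """Monte-Carlo cross validation of clustering + tree assignment.

    Each fold draws a stratified subsample (``subsample_fraction`` per
    class, without replacement), clusters it under each flavor, truncates
    to the topmost V vertices, solves the tree assignment at each Q,
    majority-votes class labels, and scores Rand index and accuracy
    against the subsample's own labels.  All folds share identical
    subsamples across flavors, and everything derives from ``seed``.
    """
    from . import treecut
    from .hclust import cluster_spectra

    if folds < 2:
        raise ValueError("folds must be >= 2")
    ss = np.random.SeedSequence(seed)
    fold_seeds = ss.spawn(folds)
    rows = []
    for fold, fs in enumerate(fold_seeds):
        rng = np.random.default_rng(fs)
        idx = _stratified_subsample(train.labels, subsample_fraction, rng)
        X = train.spectra[idx]
        y = train.labels[idx]
        cluster_seed = int(rng.integers(2**31))
        for flavor in flavors:
            t = cluster_spectra(X, flavor=flavor, V=V, alpha=alpha, seed=cluster_seed)
            for Q in Q_values:
                a = treecut.solve(t, y, int(Q), mode=mode)
                voted = treecut.majority_vote(a, t, y)
                pred = treecut.class_labels(voted)
                rows.append(
                    {
                        "fold": fold,
                        "flavor": flavor,
                        "Q": int(Q),
                        "n": len(idx),
                        "objective": a.objective,
                        "rand_index": rand_index(pred, y),
                        "accuracy": accuracy(pred, y),
                    }
                )
    return MonteCarloResult(pd.DataFrame(rows))
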