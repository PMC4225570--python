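"""Product-form spectral similarity, similarity maps, and threshold segmentation.

The similarity between two unit-interval spectra R and S is

    sigma_alpha(R, S) = prod_i (1 - |R_i - S_i|**alpha),

a product over channels that equals 1 iff the spectra coincide and is
driven toward 0 by any channel with a large absolute difference.  The
sensitivity exponent ``alpha > 0`` controls how quickly the product
vanishes: larger alpha damps the per-channel penalties (|d|**alpha shrinks
for |d| < 1), so the similarity is strictly increasing in alpha whenever
the spectra differ but no channel difference reaches 1.  Common choices
lie between 1 and 2; the package default is 1.5.

The complement ``d_P = 1 - sigma`` is used as a dissimilarity ("power
metric") for hierarchical clustering.  It is a genuine metric for
``alpha <= 1`` (each per-channel term is then a metric, and the
1-minus-product construction preserves the triangle inequality); for
``alpha > 1`` the triangle inequality can fail — e.g. spectra 0, 0.5, 1 in
a single channel at alpha = 2 — although violations become rare in high
dimension, where all distances crowd toward 1.
"""
from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .spectra_core import (
    BACKGROUND,
    UNASSIGNED,
    LabeledSpectra,
    LabelImage,
    SpectralImage,
)

__all__ = [
    "DEFAULT_ALPHA",
    "ReferenceEntry",
    "ReferenceSet",
    "SimilarityMap",
    "similarity",
    "power_distance",
    "pairwise_power_distance",
    "compute_map",
    "segment",
    "auto_pick_references",
]

DEFAULT_ALPHA = 1.5


def _check_unit(v: np.ndarray, name: str) -> np.ndarray:
    v = np.asarray(v, dtype=float)
    if v.min(initial=0.0) < 0.0 or v.max(initial=0.0) > 1.0:
        raise ValueError(f"{name} has components outside [0, 1]; rescale first")
    return v


def similarity(R: np.ndarray, S: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """sigma_alpha(R, S) = prod(1 - |R_i - S_i|**alpha); symmetric, in [0, 1]."""
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    R = _check_unit(R, "R")
    S = _check_unit(S, "S")
    if R.shape != S.shape:
        raise ValueError(f"length mismatch: {R.shape} vs {S.shape}")
    return float(np.prod(1.0 - np.abs(R - S) ** alpha))


def power_distance(X: np.ndarray, Y: np.ndarray, alpha: float = DEFAULT_ALPHA) -> float:
    """Dissimilarity 1 - sigma_alpha(X, Y); zero iff X == Y."""
    return 1.0 - similarity(X, Y, alpha)


def pairwise_power_distance(
    X: np.ndarray,
    alpha: float = DEFAULT_ALPHA,
    row_chunk: int = 64,
    channel_chunk: int = 64,
) -> np.ndarray:
    """Dense ``(N, N)`` matrix of power distances between the rows of X.

    Computed blockwise in float32 via log-similarity accumulation to bound
    peak memory at roughly ``row_chunk * N * channel_chunk`` floats.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    X = _check_unit(X, "X").astype(np.float32)
    n, b = X.shape
    out = np.empty((n, n), dtype=np.float64)
    with np.errstate(divide="ignore"):
        for i0 in range(0, n, row_chunk):
            i1 = min(i0 + row_chunk, n)
            acc = np.zeros((i1 - i0, n), dtype=np.float64)
            for j0 in range(0, b, channel_chunk):
                j1 = min(j0 + channel_chunk, b)
                d = np.abs(X[i0:i1, None, j0:j1] - X[None, :, j0:j1])
                acc += np.log1p(-(d**alpha)).sum(axis=-1, dtype=np.float64)
            out[i0:i1] = 1.0 - np.exp(acc)
    np.fill_diagonal(out, 0.0)
    # enforce exact symmetry against float round-off
    out = 0.5 * (out + out.T)
    return out


@dataclass
class ReferenceEntry:
    """One reference spectrum for one class, with its intensity threshold."""

    class_id: int
    spectrum: np.ndarray
    threshold: float = 0.5
    class_name: str = ""
    position: tuple[int, int] | None = None  # (row, col) if picked from an image

    def __post_init__(self) -> None:
        self.spectrum = _check_unit(self.spectrum, "reference spectrum")
        if not 0.0 <= self.threshold <= 1.0:
            raise ValueError("threshold must lie in [0, 1]")


@dataclass
class ReferenceSet:
    """Per-class reference spectra driving similarity-map segmentation.

    Mirroring the operator protocol, each class may carry one or two
    reference spectra; a pixel belongs to a class when any of that class's
    similarity maps reaches the entry's threshold, and conflicts between
    classes go to the map of highest intensity.
    """

    entries: list[ReferenceEntry] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA

    def __post_init__(self) -> None:
        if self.alpha <= 0:
            raise ValueError("alpha must be positive")
        counts: dict[int, int] = {}
        lengths = set()
        for e in self.entries:
            counts[e.class_id] = counts.get(e.class_id, 0) + 1
            lengths.add(e.spectrum.size)
        over = [c for c, k in counts.items() if k > 2]
        if over:
            raise ValueError(f"classes {over} have more than two reference spectra")
        if len(lengths) > 1:
            raise ValueError("reference spectra differ in channel count")

    @property
    def class_ids(self) -> list[int]:
        return sorted({e.class_id for e in self.entries})

    def class_names(self) -> dict[int, str]:
        return {
            e.class_id: (e.class_name or f"class_{e.class_id:02d}")
            for e in self.entries
        }

    def to_csv(self, path: str | Path) -> None:
        """Serialize as class_id, class_name, row, col, threshold rows.

        Only position-based entries serialize this way; the cube they were
        picked from must be supplied again on load.
        """
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["class_id", "class_name", "row", "col", "threshold"])
            for e in self.entries:
                if e.position is None:
                    raise ValueError(
                        f"entry for class {e.class_id} carries no (row, col) position"
                    )
                w.writerow([e.class_id, e.class_name, *e.position, e.threshold])

    @classmethod
    def from_csv(
        cls, path: str | Path, img: SpectralImage, alpha: float = DEFAULT_ALPHA
    ) -> "ReferenceSet":
        entries = []
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                r, c = int(row["row"]), int(row["col"])
                if not img.valid_mask[r, c]:
                    raise ValueError(f"reference position ({r}, {c}) is invalid")
                entries.append(
                    ReferenceEntry(
                        class_id=int(row["class_id"]),
                        spectrum=img.values[r, c],
                        threshold=float(row["threshold"]),
                        class_name=row.get("class_name", ""),
                        position=(r, c),
                    )
                )
        return cls(entries, alpha=alpha)


@dataclass
class SimilarityMap:
    """Per-pixel similarity to one reference spectrum; NaN at invalid pixels."""

    intensities: np.ndarray
    reference: np.ndarray
    alpha: float

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities, dtype=float)


def _map_values(
    img: SpectralImage, R: np.ndarray, alpha: float
) -> np.ndarray:
    vals = np.full(img.shape[:2], np.nan)
    S = img.valid_spectra()
    d = np.abs(S - R[None, :])
    vals[img.valid_mask] = np.prod(1.0 - d**alpha, axis=1)
    return vals


def compute_map(
    img: SpectralImage,
    ref: tuple[int, int] | np.ndarray,
    alpha: float = DEFAULT_ALPHA,
) -> SimilarityMap:
    """Similarity of every valid pixel to a reference spectrum.

    ``ref`` is either an explicit unit-interval spectrum or a ``(row, col)``
    position in the (already rescaled) image.  Invalid pixels carry NaN.
    """
    if alpha <= 0:
        raise ValueError("alpha must be positive")
    if isinstance(ref, tuple):
        r, c = ref
        if not img.valid_mask[r, c]:
            raise ValueError(f"reference position ({r}, {c}) is an invalid pixel")
        R = img.values[r, c]
    else:
        R = np.asarray(ref, dtype=float)
    R = _check_unit(R, "R")
    _check_unit(img.valid_spectra(), "image")
    if R.size != img.n_channels:
        raise ValueError("reference length does not match channel count")
    return SimilarityMap(_map_values(img, R, alpha), R, alpha)


def segment(img: SpectralImage, refs: ReferenceSet) -> LabelImage:
    """Multi-reference threshold segmentation with conflict resolution.

    A pixel is claimed by class ``c`` when some reference of ``c`` attains
    map intensity >= its threshold there; among qualifying classes the one
    whose qualifying map is most intense wins (ties to the lower class id).
    Valid pixels claimed by no class become UNASSIGNED; invalid pixels are
    BACKGROUND.
    """
    if not refs.entries:
        raise ValueError("reference set is empty")
    class_ids = refs.class_ids
    H, W = img.shape[:2]
    # per-class best qualifying intensity (-inf where nothing qualifies)
    best = np.full((len(class_ids), H, W), -np.inf)
    for e in refs.entries:
        m = _map_values(img, e.spectrum, refs.alpha)
        qual = np.where(m >= e.threshold, m, -np.inf)
        qual[np.isnan(qual)] = -np.inf  # invalid pixels never qualify
        k = class_ids.index(e.class_id)
        best[k] = np.maximum(best[k], qual)
    winner = best.argmax(axis=0)  # first max -> lowest class id on ties
    labels = np.asarray(class_ids)[winner]
    labels[~np.isfinite(best.max(axis=0))] = UNASSIGNED
    labels[~img.valid_mask] = BACKGROUND
    return LabelImage(labels, refs.class_names())


def auto_pick_references(
    train: LabeledSpectra,
    alpha: float = DEFAULT_ALPHA,
    threshold: float = 0.5,
) -> ReferenceSet:
    """Pick one reference per class from labeled training spectra.

    Convenience helper standing in for the interactive reference-picking
    workflow: per class, the training spectrum maximizing mean similarity
    to its own class is chosen.  Spectra must already lie in [0, 1].
    """
    entries = []
    for c in sorted(np.unique(train.labels).tolist()):
        members = _check_unit(train.spectra[train.labels == c], "training spectra")
        if len(members) > 400:  # cap the quadratic cost; a sample suffices
            rng = np.random.default_rng(len(members))
            members = members[rng.choice(len(members), 400, replace=False)]
        sims = np.empty(len(members))
        for i, R in enumerate(members):
            sims[i] = np.prod(1.0 - np.abs(members - R[None]) ** alpha, axis=1).mean()
        best = members[int(sims.argmax())]
        entries.append(
            ReferenceEntry(
                class_id=int(c),
                spectrum=best,
                threshold=threshold,
                class_name=train.class_names.get(int(c), ""),
            )
        )
    return ReferenceSet(entries, alpha=alpha)
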