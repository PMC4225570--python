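"""Synthetic spectral phantoms with labeled ground truth.

The generator emulates the statistical structure of FT-IR tissue images
that the rest of the package consumes, without claiming physical realism:

* ~10-14 tissue classes with unbalanced (geometrically decaying) sizes;
* class mean spectra built from Gaussian absorption bands on a common
  950-1800 cm^-1 axis, sharing the dominant protein bands so that
  between-class differences stay subtle on an absolute scale;
* within-class variability — smooth random spectral perturbations — small
  relative to the minimum between-class mean separation, controlled by a
  single *separability* knob ``c`` (within-class deviation scale =
  min between-class mean distance / c);
* a planted fraction of invalid pixels ("holes": near-zero rough spectra)
  for quality-control filtering to catch.

Everything is reproducible from the spec's seed.  The 14-class band table
is shipped as a versioned CSV fixture; other class counts synthesize band
tables deterministically from the seed.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d

from .spectra_core import BACKGROUND, LabeledSpectra, LabelImage, SpectralImage

__all__ = [
    "PhantomSpec",
    "geometric_proportions",
    "class_mean_spectra",
    "generate_image",
    "generate_training",
]

#: Tissue-component names for the 14-class colon-like preset, large to small.
COLON14_NAMES = [
    "crypts", "tumour", "submucosa", "muscle", "support_cells",
    "inflammatory", "connective_tissue", "mucosa_surface",
    "lamina_muscularis", "out", "fat_remainders", "follicles",
    "blood", "slime",
]


def geometric_proportions(K: int, ratio: float = 0.8) -> np.ndarray:
    """Unbalanced class proportions p_k ∝ ratio**k, normalized to sum 1."""
    p = ratio ** np.arange(K, dtype=float)
    return p / p.sum()


@dataclass
class PhantomSpec:
    """Full description of a phantom; defaults mirror a colon-like study.

    ``within_class_sd`` is the L2 norm scale of the smooth within-class
    perturbation; when left ``None`` it is derived from ``separability``
    as (min between-class mean distance) / separability.  ``noise_sd`` is
    per-channel white measurement noise (absorbance units).
    """

    K: int = 14
    class_proportions: np.ndarray | None = None
    B: int = 400
    wn_min: float = 950.0
    wn_max: float = 1800.0
    band_table: pd.DataFrame | None = None
    separability: float = 2.0
    within_class_sd: float | None = None
    hole_fraction: float = 0.10
    noise_sd: float = 0.004
    H: int = 64
    W: int = 64
    layout: str = "voronoi"
    seed: int = 0
    class_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            self.class_proportions = geometric_proportions(self.K)
        self.class_proportions = np.asarray(self.class_proportions, dtype=float)
        if self.class_proportions.shape != (self.K,):
            raise ValueError(
                f"{len(self.class_proportions)} proportions given for K={self.K} classes"
            )
        if not np.isclose(self.class_proportions.sum(), 1.0):
            raise ValueError("class proportions must sum to 1")
        if not 0.0 <= self.hole_fraction < 1.0:
            raise ValueError("hole_fraction must lie in [0, 1)")
        if self.layout not in ("blobs", "voronoi", "stripes"):
            raise ValueError(f"unknown layout {self.layout!r}")
        if self.separability <= 0:
            raise ValueError("separability must be positive")
        if not self.class_names:
            if self.K == len(COLON14_NAMES):
                self.class_names = list(COLON14_NAMES)
            else:
                self.class_names = [f"class_{k:02d}" for k in range(self.K)]

    @property
    def wavenumbers(self) -> np.ndarray:
        return np.linspace(self.wn_min, self.wn_max, self.B)

    def names_dict(self) -> dict[int, str]:
        return dict(enumerate(self.class_names))


def _load_colon14_bands() -> pd.DataFrame:
    with resources.files("specseg.data").joinpath("colon14_bands.csv").open() as fh:
        return pd.read_csv(fh)


# Shared protein/lipid bands every tissue class carries (center, width, amp).
_COMMON_BANDS = [
    (1655.0, 28.0, 0.80),  # amide I
    (1545.0, 26.0, 0.50),  # amide II
    (1455.0, 18.0, 0.22),  # CH2 bending
    (1400.0, 16.0, 0.16),  # COO- symmetric stretch
    (1240.0, 24.0, 0.18),  # amide III / phosphate
    (1080.0, 22.0, 0.16),  # phosphate / carbohydrate
]


def _synthesize_band_table(K: int, rng: np.random.Generator) -> pd.DataFrame:
    """Deterministic band table for non-preset class counts.

    All classes share the common bands with mildly perturbed amplitudes and
    get two class-specific fingerprint bands, keeping differences subtle.
    """
    rows = []
    for k in range(K):
        for c, w, a in _COMMON_BANDS:
            rows.append((k, c, w, a * (1 + 0.12 * rng.standard_normal())))
        for _ in range(2):
            rows.append(
                (
                    k,
                    float(rng.uniform(980, 1350)),
                    float(rng.uniform(12, 30)),
                    float(rng.uniform(0.08, 0.30)),
                )
            )
    return pd.DataFrame(rows, columns=["class_id", "center", "width", "amplitude"])


def class_mean_spectra(spec: PhantomSpec) -> np.ndarray:
    """(K, B) class mean spectra: baseline plus the class's Gaussian bands."""
    if spec.band_table is not None:
        bands = spec.band_table
    elif spec.K == 14:
        bands = _load_colon14_bands()
    else:
        bands = _synthesize_band_table(spec.K, np.random.default_rng(spec.seed + 977))
    wn = spec.wavenumbers
    means = np.full((spec.K, spec.B), 0.08)
    for _, row in bands.iterrows():
        k = int(row["class_id"])
        if k >= spec.K:
            raise ValueError(f"band table references class {k} but K={spec.K}")
        means[k] += row["amplitude"] * np.exp(
            -0.5 * ((wn - row["center"]) / row["width"]) ** 2
        )
    return means


def _min_mean_separation(means: np.ndarray) -> float:
    K = len(means)
    best = np.inf
    for i in range(K):
        d = np.linalg.norm(means[i + 1 :] - means[i], axis=1)
        if d.size:
            best = min(best, float(d.min()))
    return best


def _resolve_within_sd(spec: PhantomSpec, means: np.ndarray) -> float:
    if spec.within_class_sd is not None:
        return spec.within_class_sd
    return _min_mean_separation(means) / spec.separability


def _within_perturbation(
    n: int, B: int, sd: float, rng: np.random.Generator
) -> np.ndarray:
    """Smooth random curves with L2 norm sd * |t|, t ~ N(0, 1)."""
    if sd == 0 or n == 0:
        return np.zeros((n, B))
    z = gaussian_filter1d(rng.standard_normal((n, B)), sigma=max(B / 50, 2), axis=1)
    z /= np.linalg.norm(z, axis=1, keepdims=True)
    t = rng.standard_normal((n, 1))
    return sd * t * z


def _layout_labels(spec: PhantomSpec, rng: np.random.Generator) -> np.ndarray:
    H, W, K = spec.H, spec.W, spec.K
    p = spec.class_proportions
    if spec.layout == "stripes":
        # exact proportions, row-major: class boundaries at cumulative counts
        counts = _apportion(H * W, p)
        flat = np.repeat(np.arange(K), counts)
        return flat.reshape(H, W)
    if spec.layout == "voronoi":
        seeds = np.column_stack(
            [rng.uniform(0, H, size=K), rng.uniform(0, W, size=K)]
        )
        rr, cc = np.mgrid[0:H, 0:W]
        d2 = (rr[..., None] - seeds[:, 0]) ** 2 + (cc[..., None] - seeds[:, 1]) ** 2
        return np.argmin(d2 / p[None, None, :], axis=-1)
    # blobs: largest class as background, the rest as disks sized by proportion
    labels = np.zeros((H, W), dtype=int)
    rr, cc = np.mgrid[0:H, 0:W]
    for k in range(1, K):
        radius = np.sqrt(p[k] * H * W / np.pi)
        r0 = rng.uniform(radius, H - radius) if H > 2 * radius else H / 2
        c0 = rng.uniform(radius, W - radius) if W > 2 * radius else W / 2
        labels[(rr - r0) ** 2 + (cc - c0) ** 2 <= radius**2] = k
    return labels


def _apportion(N: int, p: np.ndarray) -> np.ndarray:
    """Largest-remainder apportionment of N items to proportions p (each >= 1)."""
    raw = N * p
    counts = np.floor(raw).astype(int)
    counts = np.maximum(counts, 1)
    while counts.sum() > N:
        counts[int(np.argmax(counts))] -= 1
    rem = raw - np.floor(raw)
    order = np.argsort(-rem)
    i = 0
    while counts.sum() < N:
        counts[order[i % len(p)]] += 1
        i += 1
    return counts


def generate_image(spec: PhantomSpec) -> tuple[SpectralImage, LabelImage]:
    """A phantom cube plus its ground-truth label image.

    Each pixel's spectrum is its class mean plus a smooth within-class
    perturbation plus white channel noise.  A ``hole_fraction`` of pixels
    is replaced by near-zero rough spectra — the ground truth marks those
    BACKGROUND, while the returned cube's ``valid_mask`` stays all-True:
    detecting the holes is :func:`specseg.spectra_core.qc_filter`'s job.
    """
    rng = np.random.default_rng(spec.seed)
    means = class_mean_spectra(spec)
    sd = _resolve_within_sd(spec, means)
    labels = _layout_labels(spec, rng)
    H, W, B = spec.H, spec.W, spec.B
    values = means[labels.ravel()].reshape(H, W, B).copy()
    values += _within_perturbation(H * W, B, sd, rng).reshape(H, W, B)
    values += rng.normal(0, spec.noise_sd, size=(H, W, B))
    np.clip(values, 0.0, None, out=values)
    gt = labels.copy()
    n_holes = int(round(spec.hole_fraction * H * W))
    if n_holes:
        holes = rng.choice(H * W, size=n_holes, replace=False)
        hr, hc = np.unravel_index(holes, (H, W))
        values[hr, hc] = np.abs(rng.normal(0, 0.008, size=(n_holes, B)))
        gt[hr, hc] = BACKGROUND
    img = SpectralImage(values, spec.wavenumbers)
    return img, LabelImage(gt, spec.names_dict())


def generate_training(spec: PhantomSpec, N: int) -> LabeledSpectra:
    """N labeled spectra drawn under the spec's proportions and noise model."""
    if N < spec.K:
        raise ValueError(f"N={N} smaller than number of classes K={spec.K}")
    rng = np.random.default_rng(spec.seed + 1)
    means = class_mean_spectra(spec)
    sd = _resolve_within_sd(spec, means)
    counts = _apportion(N, spec.class_proportions)
    labels = np.repeat(np.arange(spec.K), counts)
    spectra = means[labels] + _within_perturbation(N, spec.B, sd, rng)
    spectra += rng.normal(0, spec.noise_sd, size=spectra.shape)
    np.clip(spectra, 0.0, None, out=spectra)
    perm = rng.permutation(N)
    return LabeledSpectra(
        spectra[perm], labels[perm], spec.names_dict(), wavenumbers=spec.wavenumbers
    )
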