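"""Data model and I/O for spectral images and labeled training spectra.

A spectral image is a cube of non-negative absorbance values, ``H x W``
pixels by ``B`` spectral channels, with an ascending wavenumber axis
(cm^-1) and a per-pixel validity mask.  All spatial coordinates in this
package are ``(row, col)``, 0-based, row-major.

Two distinguished label ids are used throughout:

* :data:`BACKGROUND` marks pixels discarded by quality control (or known
  a priori to contain no tissue);
* :data:`UNASSIGNED` marks valid pixels that no segmentation rule claimed.
"""
from __future__ import annotations

import csv
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple

import numpy as np

__all__ = [
    "BACKGROUND",
    "UNASSIGNED",
    "SpectralImage",
    "LabeledSpectra",
    "LabelImage",
    "QCResult",
    "load_cube",
    "write_cube",
    "rescale_unit",
    "qc_filter",
    "write_label_image",
    "read_label_image",
]

#: Valid-but-unclaimed pixels (below every similarity threshold).
UNASSIGNED = -1
#: Pixels excluded from analysis (QC-discarded, holes, off-sample).
BACKGROUND = -2


@dataclass
class SpectralImage:
    """An ``H x W x B`` absorbance cube with wavenumber axis and validity mask.

    Parameters
    ----------
    values
        Absorbance cube, shape ``(H, W, B)``.
    wavenumbers
        Strictly increasing channel axis of length ``B`` (cm^-1).  When a
        file format carries no axis, channel indices ``0..B-1`` are used.
    valid_mask
        Boolean ``(H, W)`` array; ``False`` marks discarded pixels.
    """

    values: np.ndarray
    wavenumbers: np.ndarray
    valid_mask: np.ndarray = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3:
            raise ValueError(f"values must be (H, W, B), got shape {self.values.shape}")
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        if self.wavenumbers.shape != (self.values.shape[2],):
            raise ValueError(
                f"wavenumber axis length {self.wavenumbers.shape} does not match "
                f"B={self.values.shape[2]}"
            )
        if self.wavenumbers.size > 1 and not np.all(np.diff(self.wavenumbers) > 0):
            raise ValueError("wavenumbers must be strictly increasing")
        if self.valid_mask is None:
            self.valid_mask = np.ones(self.values.shape[:2], dtype=bool)
        else:
            self.valid_mask = np.asarray(self.valid_mask, dtype=bool)
            if self.valid_mask.shape != self.values.shape[:2]:
                raise ValueError("valid_mask shape does not match image")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape  # type: ignore[return-value]

    @property
    def n_channels(self) -> int:
        return self.values.shape[2]

    @property
    def n_valid(self) -> int:
        return int(self.valid_mask.sum())

    def valid_spectra(self) -> np.ndarray:
        """Spectra of valid pixels as an ``(n_valid, B)`` matrix (row-major order)."""
        return self.values[self.valid_mask]

    def copy(self) -> "SpectralImage":
        return SpectralImage(
            self.values.copy(), self.wavenumbers.copy(), self.valid_mask.copy()
        )


@dataclass
class LabeledSpectra:
    """A labeled training matrix: ``N`` spectra by ``B`` channels, one class id each."""

    spectra: np.ndarray
    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)
    wavenumbers: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.spectra = np.asarray(self.spectra, dtype=float)
        self.labels = np.asarray(self.labels, dtype=int)
        if self.spectra.ndim != 2:
            raise ValueError("spectra must be a 2-D (N, B) matrix")
        if self.labels.shape != (self.spectra.shape[0],):
            raise ValueError("labels length must match number of spectra")
        present = set(np.unique(self.labels).tolist())
        if not self.class_names:
            self.class_names = {c: f"class_{c:02d}" for c in sorted(present)}
        missing = present - set(self.class_names)
        if missing:
            raise ValueError(f"labels {sorted(missing)} missing from class_names")

    @property
    def n_classes(self) -> int:
        return len(np.unique(self.labels))

    def class_sizes(self) -> dict[int, int]:
        vals, counts = np.unique(self.labels, return_counts=True)
        return dict(zip(vals.tolist(), counts.tolist()))


@dataclass
class LabelImage:
    """An ``H x W`` class-id array; ids < 0 are the sentinels above."""

    labels: np.ndarray
    class_names: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=int)
        if self.labels.ndim != 2:
            raise ValueError("labels must be 2-D (H, W)")

    @property
    def shape(self) -> tuple[int, int]:
        return self.labels.shape  # type: ignore[return-value]

    def check_consistent(self, img: SpectralImage) -> None:
        """Raise unless every invalid pixel of ``img`` is BACKGROUND here."""
        if self.labels.shape != img.valid_mask.shape:
            raise ValueError("label image and spectral image shapes differ")
        if np.any(self.labels[~img.valid_mask] != BACKGROUND):
            raise ValueError("invalid pixels must carry the BACKGROUND id")


# ---------------------------------------------------------------------------
# Cube I/O
# ---------------------------------------------------------------------------

_FORMATS = ("delimited-matrix", "hdf5-container", "tiff-stack")

_SUFFIX_FORMAT = {
    ".csv": "delimited-matrix",
    ".txt": "delimited-matrix",
    ".tsv": "delimited-matrix",
    ".h5": "hdf5-container",
    ".hdf5": "hdf5-container",
    ".tif": "tiff-stack",
    ".tiff": "tiff-stack",
}


def _infer_format(path: Path, fmt: str | None) -> str:
    if fmt is not None:
        if fmt not in _FORMATS:
            raise ValueError(f"unknown format {fmt!r}; expected one of {_FORMATS}")
        return fmt
    try:
        return _SUFFIX_FORMAT[path.suffix.lower()]
    except KeyError:
        raise ValueError(f"cannot infer cube format from suffix {path.suffix!r}") from None


def load_cube(path: str | Path, format: str | None = None) -> SpectralImage:
    """Read a spectral cube from one of the supported dialects.

    ``delimited-matrix``: one pixel-spectrum per row, first two columns are
    ``row, col``, optional header line ``row,col,<wavenumbers...>``.  Without
    the header the channel axis falls back to indices ``0..B-1``.

    ``hdf5-container``: datasets ``/cube`` (H, W, B), ``/wavenumbers`` (B,)
    and ``/mask`` (H, W).

    ``tiff-stack``: one page per channel; the wavenumber axis is recovered
    from a JSON image description when present, else channel indices.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    fmt = _infer_format(path, format)
    if fmt == "delimited-matrix":
        return _load_delimited(path)
    if fmt == "hdf5-container":
        return _load_hdf5(path)
    return _load_tiff(path)


def _sniff_delimiter(line: str) -> str:
    return "," if line.count(",") >= line.count("\t") else "\t"


def _load_delimited(path: Path) -> SpectralImage:
    with open(path, "r") as fh:
        lines = [ln.strip() for ln in fh if ln.strip()]
    if not lines:
        raise ValueError(f"{path}: empty file")
    delim = _sniff_delimiter(lines[0])
    first = [f.strip() for f in lines[0].split(delim)]
    wavenumbers = None
    data_lines = lines
    if first and first[0].lower() in ("row", "y"):
        try:
            wavenumbers = np.array([float(v) for v in first[2:]])
        except ValueError as exc:
            raise ValueError(f"{path}: malformed wavenumber header: {exc}") from exc
        data_lines = lines[1:]
    rows = []
    width = None
    for lineno, ln in enumerate(data_lines, start=1 if wavenumbers is None else 2):
        fields = ln.split(delim)
        if width is None:
            width = len(fields)
        elif len(fields) != width:
            raise ValueError(
                f"{path}:{lineno}: expected {width} fields, found {len(fields)}"
            )
        try:
            rows.append([float(v) for v in fields])
        except ValueError as exc:
            raise ValueError(f"{path}:{lineno}: {exc}") from exc
    arr = np.array(rows)
    if arr.shape[1] < 3:
        raise ValueError(f"{path}: need row, col plus at least one channel")
    rc = arr[:, :2].astype(int)
    spectra = arr[:, 2:]
    B = spectra.shape[1]
    H, W = rc[:, 0].max() + 1, rc[:, 1].max() + 1
    values = np.zeros((H, W, B))
    mask = np.zeros((H, W), dtype=bool)
    values[rc[:, 0], rc[:, 1]] = spectra
    mask[rc[:, 0], rc[:, 1]] = True
    if wavenumbers is None:
        wavenumbers = np.arange(B, dtype=float)
    elif wavenumbers.size != B:
        raise ValueError(f"{path}: header lists {wavenumbers.size} wavenumbers for B={B}")
    return SpectralImage(values, wavenumbers, mask)


def _load_hdf5(path: Path) -> SpectralImage:
    import h5py

    with h5py.File(path, "r") as fh:
        for name in ("cube",):
            if name not in fh:
                raise ValueError(f"{path}: missing dataset /{name}")
        cube = fh["cube"][()]
        wn = fh["wavenumbers"][()] if "wavenumbers" in fh else np.arange(cube.shape[2])
        mask = fh["mask"][()].astype(bool) if "mask" in fh else None
    return SpectralImage(cube, wn, mask)


def _load_tiff(path: Path) -> SpectralImage:
    import tifffile

    with tifffile.TiffFile(path) as tf:
        pages = tf.asarray()  # (B, H, W)
        desc = tf.pages[0].description
    if pages.ndim == 2:
        pages = pages[None]
    cube = np.moveaxis(pages, 0, -1)
    wn = np.arange(cube.shape[2], dtype=float)
    mask = None
    if desc:
        try:
            meta = json.loads(desc)
            if "wavenumbers" in meta:
                wn = np.asarray(meta["wavenumbers"], dtype=float)
            if "mask_rle" in meta:
                mask = _rle_decode(meta["mask_rle"], cube.shape[:2])
        except (json.JSONDecodeError, KeyError, TypeError):
            pass
    return SpectralImage(cube, wn, mask)


def _rle_encode(mask: np.ndarray) -> list[int]:
    flat = mask.ravel().astype(np.int8)
    change = np.flatnonzero(np.diff(flat)) + 1
    bounds = np.concatenate(([0], change, [flat.size]))
    runs = np.diff(bounds).tolist()
    return [int(flat[0])] + runs


def _rle_decode(rle: list[int], shape: tuple[int, int]) -> np.ndarray:
    start, runs = rle[0], rle[1:]
    out = np.empty(int(np.prod(shape)), dtype=bool)
    pos, val = 0, bool(start)
    for r in runs:
        out[pos : pos + r] = val
        pos += r
        val = not val
    return out.reshape(shape)


def write_cube(img: SpectralImage, path: str | Path, format: str | None = None) -> None:
    """Write a cube in any of the dialects :func:`load_cube` reads."""
    path = Path(path)
    fmt = _infer_format(path, format)
    if fmt == "delimited-matrix":
        H, W, B = img.shape
        with open(path, "w") as fh:
            fh.write("row,col," + ",".join(f"{w:g}" for w in img.wavenumbers) + "\n")
            for r in range(H):
                for c in range(W):
                    if img.valid_mask[r, c]:
                        fh.write(
                            f"{r},{c},"
                            + ",".join(repr(float(v)) for v in img.values[r, c])
                            + "\n"
                        )
    elif fmt == "hdf5-container":
        import h5py

        with h5py.File(path, "w") as fh:
            # track_times=False keeps the file byte-identical across runs
            fh.create_dataset("cube", data=img.values, track_times=False)
            fh.create_dataset("wavenumbers", data=img.wavenumbers, track_times=False)
            fh.create_dataset(
                "mask", data=img.valid_mask.astype(np.uint8), track_times=False
            )
    else:
        import tifffile

        meta = {
            "wavenumbers": img.wavenumbers.tolist(),
            "mask_rle": _rle_encode(img.valid_mask),
        }
        tifffile.imwrite(
            path,
            np.moveaxis(img.values, -1, 0).astype(np.float32),
            photometric="minisblack",
            description=json.dumps(meta),
        )


# ---------------------------------------------------------------------------
# Rescaling and quality control
# ---------------------------------------------------------------------------


def rescale_unit(img: SpectralImage) -> SpectralImage:
    """Map the whole dataset onto [0, 1] with one global affine transform.

    The minimum absorbance occurring at any wavenumber in any *valid*
    spectrum becomes 0 and the corresponding maximum becomes 1; every valid
    pixel and channel is transformed with the same affine map, preserving
    relative band shapes.  Invalid pixels are left untouched.
    """
    if not img.valid_mask.any():
        raise ValueError("rescale_unit requires at least one valid pixel")
    valid = img.values[img.valid_mask]
    lo, hi = float(valid.min()), float(valid.max())
    if hi == lo:
        raise ValueError("degenerate range: all valid absorbances are equal")
    out = img.values.copy()
    out[img.valid_mask] = (valid - lo) / (hi - lo)
    return SpectralImage(out, img.wavenumbers.copy(), img.valid_mask.copy())


class QCResult(NamedTuple):
    image: SpectralImage
    n_discarded: int
    fraction_discarded: float


def integrated_absorbance(values: np.ndarray) -> np.ndarray:
    """Mean absorbance over channels — the weak-signal score (B-independent)."""
    return np.asarray(values).mean(axis=-1)


def noise_score(values: np.ndarray) -> np.ndarray:
    """RMS of first channel differences — a high-frequency noise score."""
    d = np.diff(np.asarray(values), axis=-1)
    return np.sqrt((d * d).mean(axis=-1))


def qc_filter(
    img: SpectralImage,
    min_integrated_absorbance: float = 0.05,
    max_noise: float = 0.25,
) -> QCResult:
    """Discard weak or noisy spectra, as is standard practice before analysis.

    A currently-valid pixel is discarded when its channel-averaged absorbance
    falls below ``min_integrated_absorbance`` *or* the RMS of its first
    channel differences exceeds ``max_noise``.  Defaults are calibrated on
    the synthetic phantom so that planted holes (near-zero, rough spectra)
    are caught while smooth tissue-like spectra are retained.

    Returns the filtered image together with the count and fraction of
    previously-valid pixels discarded.
    """
    if min_integrated_absorbance < 0 or max_noise < 0:
        raise ValueError("QC thresholds must be non-negative")
    weak = integrated_absorbance(img.values) < min_integrated_absorbance
    noisy = noise_score(img.values) > max_noise
    discard = (weak | noisy) & img.valid_mask
    n_before = img.n_valid
    new_mask = img.valid_mask & ~discard
    out = SpectralImage(img.values.copy(), img.wavenumbers.copy(), new_mask)
    n_disc = int(discard.sum())
    return QCResult(out, n_disc, n_disc / max(n_before, 1))


# ---------------------------------------------------------------------------
# Label-image I/O (indexed PNG + CSV legend)
# ---------------------------------------------------------------------------

# Reserved palette slots 0/1; classes start at slot 2.
_BACKGROUND_SLOT, _UNASSIGNED_SLOT = 0, 1
_BACKGROUND_RGB = (0, 0, 0)
_UNASSIGNED_RGB = (128, 128, 128)


def _class_palette(n: int) -> list[tuple[int, int, int]]:
    import matplotlib

    cmap = matplotlib.colormaps["tab20"]
    cols = []
    for i in range(n):
        r, g, b, _ = cmap(i % 20)
        # darken repeats beyond 20 so every slot stays distinct
        f = 1.0 - 0.35 * (i // 20)
        cols.append((int(255 * r * f), int(255 * g * f), int(255 * b * f)))
    return cols


def write_label_image(lab: LabelImage, path: str | Path) -> None:
    """Write a palette-indexed PNG plus a sidecar ``.legend.csv``.

    Slot 0 is reserved for BACKGROUND (black) and slot 1 for UNASSIGNED
    (gray); classes occupy slots 2 and up, so at most 254 classes fit.
    Output is bit-exact across runs.
    """
    from PIL import Image

    path = Path(path)
    classes = sorted(c for c in np.unique(lab.labels) if c >= 0)
    if len(classes) > 254:
        raise ValueError(f"{len(classes)} classes exceed the 254-slot palette capacity")
    slot_of = {BACKGROUND: _BACKGROUND_SLOT, UNASSIGNED: _UNASSIGNED_SLOT}
    slot_of.update({c: i + 2 for i, c in enumerate(classes)})
    idx = np.zeros(lab.labels.shape, dtype=np.uint8)
    for cid, slot in slot_of.items():
        idx[lab.labels == cid] = slot
    colors = [_BACKGROUND_RGB, _UNASSIGNED_RGB] + _class_palette(len(classes))
    pal = []
    for rgb in colors:
        pal.extend(rgb)
    pal.extend([0] * (768 - len(pal)))
    im = Image.fromarray(idx, mode="P")
    im.putpalette(pal)
    im.save(path, format="PNG")
    legend = path.with_suffix(path.suffix + ".legend.csv")
    with open(legend, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["class_id", "name", "palette_slot", "r", "g", "b"])
        w.writerow([BACKGROUND, "BACKGROUND", _BACKGROUND_SLOT, *_BACKGROUND_RGB])
        w.writerow([UNASSIGNED, "UNASSIGNED", _UNASSIGNED_SLOT, *_UNASSIGNED_RGB])
        for i, c in enumerate(classes):
            name = lab.class_names.get(c, f"class_{c:02d}")
            w.writerow([c, name, i + 2, *colors[i + 2]])


def read_label_image(path: str | Path) -> LabelImage:
    """Read back a label image written by :func:`write_label_image`."""
    from PIL import Image

    path = Path(path)
    idx = np.asarray(Image.open(path), dtype=int)
    legend = path.with_suffix(path.suffix + ".legend.csv")
    class_of_slot: dict[int, int] = {}
    names: dict[int, str] = {}
    with open(legend, newline="") as fh:
        for row in csv.DictReader(fh):
            cid, slot = int(row["class_id"]), int(row["palette_slot"])
            class_of_slot[slot] = cid
            if cid >= 0:
                names[cid] = row["name"]
    labels = np.full(idx.shape, BACKGROUND, dtype=int)
    for slot, cid in class_of_slot.items():
        labels[idx == slot] = cid
    return LabelImage(labels, names)
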