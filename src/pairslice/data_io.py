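"""Image input, synthetic glyph generation, deletion noise and archives.

The pipeline consumes 28x28 8-bit grayscale images with class labels 0-9.
Two sources are supported: the IDX binary format used by MNIST, and a
built-in procedural glyph generator that rasterizes a fixed stroke template
per class so the whole pipeline can run without any external dataset.

Spike records and per-class "expression" archives (ordered lists of
active-neuron sets, one per time slice) are serialized to NPZ/CSV and
versioned JSON respectively.
"""

from __future__ import annotations

import json
import struct
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

IMAGE_SHAPE = (28, 28)

IDX_IMAGES_MAGIC = 0x00000803
IDX_LABELS_MAGIC = 0x00000801

EXPRESSION_SCHEMA_VERSION = 1


class FormatError(ValueError):
    """Raised for malformed IDX files or expression archives."""


class ConsistencyError(ValueError):
    """Raised when paired files (images/labels) disagree."""


# ---------------------------------------------------------------------------
# Domain containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GrayImage:
    """A 28x28 8-bit grayscale image with an optional class label."""

    pixels: np.ndarray
    label: int | None = None

    def __post_init__(self) -> None:
        px = np.asarray(self.pixels)
        if px.shape != IMAGE_SHAPE:
            raise ValueError(f"image shape must be {IMAGE_SHAPE}, got {px.shape}")
        if px.min() < 0 or px.max() > 255:
            raise ValueError("intensities must lie in [0, 255]")
        object.__setattr__(self, "pixels", px.astype(np.uint8))

    @property
    def nonzero_count(self) -> int:
        return int(np.count_nonzero(self.pixels))


@dataclass
class LabeledImageSet:
    """An ordered collection of labeled images with per-class counts."""

    images: list[GrayImage] = field(default_factory=list)

    def __post_init__(self) -> None:
        for im in self.images:
            if im.label is None:
                raise ValueError("every image in a LabeledImageSet needs a label")

    @property
    def class_counts(self) -> dict[int, int]:
        counts: dict[int, int] = {}
        for im in self.images:
            counts[im.label] = counts.get(im.label, 0) + 1
        return counts

    @property
    def classes(self) -> list[int]:
        return sorted(self.class_counts)

    def by_class(self, label: int) -> list[GrayImage]:
        return [im for im in self.images if im.label == label]

    def __len__(self) -> int:
        return len(self.images)

    def __iter__(self):
        return iter(self.images)


# ---------------------------------------------------------------------------
# IDX (MNIST) reading / writing
# ---------------------------------------------------------------------------

def _read_idx_images(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < 16:
        raise FormatError(f"{path}: truncated IDX image header")
    magic, count, rows, cols = struct.unpack(">IIII", data[:16])
    if magic != IDX_IMAGES_MAGIC:
        raise FormatError(f"{path}: bad IDX image magic 0x{magic:08x}")
    expected = 16 + count * rows * cols
    if len(data) < expected:
        raise FormatError(f"{path}: truncated IDX image payload")
    arr = np.frombuffer(data[16:expected], dtype=np.uint8)
    return arr.reshape(count, rows, cols)


def _read_idx_labels(path: Path) -> np.ndarray:
    data = path.read_bytes()
    if len(data) < 8:
        raise FormatError(f"{path}: truncated IDX label header")
    magic, count = struct.unpack(">II", data[:8])
    if magic != IDX_LABELS_MAGIC:
        raise FormatError(f"{path}: bad IDX label magic 0x{magic:08x}")
    if len(data) < 8 + count:
        raise FormatError(f"{path}: truncated IDX label payload")
    return np.frombuffer(data[8 : 8 + count], dtype=np.uint8)


def _locate_idx_pair(path: Path) -> tuple[Path, Path]:
    if path.is_dir():
        images = sorted(path.glob("*idx3*")) or sorted(path.glob("*images*"))
        labels = sorted(path.glob("*idx1*")) or sorted(path.glob("*labels*"))
        if not images or not labels:
            raise FormatError(f"{path}: no IDX image/label pair found")
        return images[0], labels[0]
    # a single file path: look for the sibling label file by convention
    name = path.name
    for src, dst in (("idx3", "idx1"), ("images", "labels")):
        if src in name:
            sibling = path.with_name(name.replace(src, dst))
            if sibling.exists():
                return path, sibling
    raise FormatError(f"{path}: cannot locate the matching label file")


def read_idx(path: str | Path) -> LabeledImageSet:
    """Read an IDX image/label pair (MNIST layout) into a LabeledImageSet.

    ``path`` may be a directory containing the pair, or the image file
    itself (the label file is found by the idx3/idx1 naming convention).
    """
    img_path, lbl_path = _locate_idx_pair(Path(path))
    images = _read_idx_images(img_path)
    labels = _read_idx_labels(lbl_path)
    if images.shape[0] != labels.shape[0]:
        raise ConsistencyError(
            f"image count {images.shape[0]} != label count {labels.shape[0]}"
        )
    return LabeledImageSet(
        [GrayImage(img, int(lbl)) for img, lbl in zip(images, labels)]
    )


def write_idx(image_set: LabeledImageSet, directory: str | Path,
              prefix: str = "data") -> tuple[Path, Path]:
    """Write a LabeledImageSet as an IDX image/label file pair."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    img_path = directory / f"{prefix}-images-idx3-ubyte"
    lbl_path = directory / f"{prefix}-labels-idx1-ubyte"
    n = len(image_set)
    with open(img_path, "wb") as fh:
        fh.write(struct.pack(">IIII", IDX_IMAGES_MAGIC, n, *IMAGE_SHAPE))
        for im in image_set:
            fh.write(im.pixels.tobytes())
    with open(lbl_path, "wb") as fh:
        fh.write(struct.pack(">II", IDX_LABELS_MAGIC, n))
        fh.write(bytes(im.label for im in image_set))
    return img_path, lbl_path


# ---------------------------------------------------------------------------
# Synthetic glyph generation
# ---------------------------------------------------------------------------

def _blank() -> np.ndarray:
    return np.zeros(IMAGE_SHAPE, dtype=float)


def _stroke(grid: np.ndarray, r0: int, c0: int, r1: int, c1: int,
            thickness: int = 2, value: float = 255.0) -> None:
    """Rasterize a straight stroke of the given thickness onto ``grid``."""
    steps = max(abs(r1 - r0), abs(c1 - c0), 1)
    for t in np.linspace(0.0, 1.0, steps * 2 + 1):
        r = r0 + (r1 - r0) * t
        c = c0 + (c1 - c0) * t
        rlo, rhi = int(round(r)), int(round(r)) + thickness
        clo, chi = int(round(c)), int(round(c)) + thickness
        grid[max(rlo, 0):rhi, max(clo, 0):chi] = value


def _template_ring() -> np.ndarray:
    g = _blank()
    rr, cc = np.mgrid[0:28, 0:28]
    d = np.hypot(rr - 13.5, cc - 13.5)
    g[(d >= 6.0) & (d <= 8.5)] = 255.0
    return g


def _template_vbar() -> np.ndarray:
    g = _blank()
    _stroke(g, 5, 13, 22, 13, thickness=3)
    return g


def _template_cross() -> np.ndarray:
    g = _blank()
    _stroke(g, 13, 5, 13, 22, thickness=3)
    _stroke(g, 5, 13, 22, 13, thickness=3)
    return g


def _template_diagonal() -> np.ndarray:
    g = _blank()
    _stroke(g, 5, 5, 22, 22, thickness=3)
    return g


def _template_lshape() -> np.ndarray:
    g = _blank()
    _stroke(g, 5, 8, 21, 8, thickness=3)
    _stroke(g, 21, 8, 21, 21, thickness=3)
    return g


def _template_tshape() -> np.ndarray:
    g = _blank()
    _stroke(g, 6, 5, 6, 22, thickness=3)
    _stroke(g, 6, 13, 22, 13, thickness=3)
    return g


def _template_scurve() -> np.ndarray:
    g = _blank()
    _stroke(g, 6, 8, 6, 20, thickness=2)
    _stroke(g, 6, 8, 13, 8, thickness=2)
    _stroke(g, 13, 8, 13, 20, thickness=2)
    _stroke(g, 13, 19, 21, 19, thickness=2)
    _stroke(g, 21, 8, 21, 20, thickness=2)
    return g


def _template_dotgrid() -> np.ndarray:
    g = _blank()
    for r in (7, 14, 21):
        for c in (7, 14, 21):
            g[r - 1:r + 2, c - 1:c + 2] = 255.0
    return g


def _template_chevron() -> np.ndarray:
    g = _blank()
    _stroke(g, 20, 6, 8, 14, thickness=3)
    _stroke(g, 8, 14, 20, 22, thickness=3)
    return g


def _template_hshape() -> np.ndarray:
    g = _blank()
    _stroke(g, 5, 7, 22, 7, thickness=3)
    _stroke(g, 5, 19, 22, 19, thickness=3)
    _stroke(g, 13, 7, 13, 19, thickness=3)
    return g


GLYPH_TEMPLATES: tuple = (
    _template_ring,
    _template_vbar,
    _template_cross,
    _template_diagonal,
    _template_lshape,
    _template_tshape,
    _template_scurve,
    _template_dotgrid,
    _template_chevron,
    _template_hshape,
)


def glyph_template(label: int) -> np.ndarray:
    """The noiseless 28x28 stroke template for a class (float, 0/255)."""
    return GLYPH_TEMPLATES[label]()


def generate_glyphs(classes: int, n_per_class: int, seed: int,
                    jitter_px: int = 2, noise_sd: float = 8.0) -> LabeledImageSet:
    """Generate a synthetic labeled glyph dataset.

    Each class has a fixed stroke template (ring, bar, cross, ...). Every
    sample translates the template by an integer offset drawn uniformly
    from [-jitter_px, jitter_px] per axis and perturbs stroke intensities
    with Gaussian noise of sd ``noise_sd`` (clipped to [0, 255]). Noise is
    applied to stroke pixels only, so the background stays exactly zero and
    the nonzero-pixel fraction stays in the sparse regime typical of
    handwritten-digit images. Deterministic given ``seed``.
    """
    if not 2 <= classes <= 10:
        raise ValueError("classes must be in [2, 10]")
    if n_per_class < 1:
        raise ValueError("n_per_class must be positive")
    rng = np.random.default_rng(seed)
    templates = [glyph_template(k) for k in range(classes)]
    images: list[GrayImage] = []
    for label in range(classes):
        base = templates[label]
        for _ in range(n_per_class):
            dr = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            dc = int(rng.integers(-jitter_px, jitter_px + 1)) if jitter_px else 0
            shifted = np.roll(np.roll(base, dr, axis=0), dc, axis=1)
            noisy = shifted.copy()
            if noise_sd > 0:
                mask = shifted > 0
                noisy[mask] += rng.normal(0.0, noise_sd, size=int(mask.sum()))
            noisy = np.clip(np.round(noisy), 0, 255)
            images.append(GrayImage(noisy.astype(np.uint8), label))
    return LabeledImageSet(images)


def corrupt_deletion_noise(image: GrayImage, ratio: float, seed: int) -> GrayImage:
    """Set round(ratio * n_nonzero) nonzero pixels to zero, uniformly chosen.

    Surviving pixels keep their exact value; zero pixels are never touched.
    round() uses banker's rounding (ties to even). Deterministic given seed.
    """
    if not 0.0 <= ratio <= 1.0:
        raise ValueError("ratio must lie in [0, 1]")
    px = image.pixels.copy()
    nz_rows, nz_cols = np.nonzero(px)
    n_delete = int(np.round(ratio * len(nz_rows)))
    if n_delete > 0:
        rng = np.random.default_rng(seed)
        picked = rng.choice(len(nz_rows), size=n_delete, replace=False)
        px[nz_rows[picked], nz_cols[picked]] = 0
    return GrayImage(px, image.label)


# ---------------------------------------------------------------------------
# Expression archives (versioned JSON)
# ---------------------------------------------------------------------------

@dataclass
class ExpressionArchive:
    """Per-class expressions: for each class, n ordered active-neuron sets.

    ``slice_bounds`` are contiguous half-open [start, end) intervals in ms
    covering the whole simulation window. ``metadata`` records at least the
    firing-frequency threshold, sample count and monitored-layer namespace
    used when the expressions were built.
    """

    n_slices: int
    slice_bounds: list[tuple[float, float]]
    expressions: dict[int, list[set[int]]]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.n_slices < 1:
            raise ValueError("n_slices must be >= 1")
        if len(self.slice_bounds) != self.n_slices:
            raise ValueError("slice_bounds length must equal n_slices")
        for (a0, a1), (b0, b1) in zip(self.slice_bounds, self.slice_bounds[1:]):
            if not np.isclose(a1, b0):
                raise ValueError("slice bounds must be contiguous")
        for cls, maps in self.expressions.items():
            if len(maps) != self.n_slices:
                raise ValueError(f"class {cls} has {len(maps)} maps, "
                                 f"expected {self.n_slices}")

    @property
    def classes(self) -> list[int]:
        return sorted(self.expressions)


def save_expressions(archive: ExpressionArchive, path: str | Path) -> None:
    payload = {
        "schema_version": EXPRESSION_SCHEMA_VERSION,
        "n_slices": archive.n_slices,
        "slice_bounds": [[float(a), float(b)] for a, b in archive.slice_bounds],
        "expressions": {
            str(cls): [sorted(int(i) for i in s) for s in maps]
            for cls, maps in archive.expressions.items()
        },
        "metadata": archive.metadata,
    }
    Path(path).write_text(json.dumps(payload, indent=1, sort_keys=True))


def load_expressions(path: str | Path) -> ExpressionArchive:
    try:
        payload = json.loads(Path(path).read_text())
    except json.JSONDecodeError as exc:
        raise FormatError(f"{path}: not a valid expression archive") from exc
    version = payload.get("schema_version")
    if version != EXPRESSION_SCHEMA_VERSION:
        raise FormatError(
            f"{path}: schema version {version!r} unsupported "
            f"(expected {EXPRESSION_SCHEMA_VERSION})"
        )
    return ExpressionArchive(
        n_slices=payload["n_slices"],
        slice_bounds=[tuple(b) for b in payload["slice_bounds"]],
        expressions={
            int(cls): [set(s) for s in maps]
            for cls, maps in payload["expressions"].items()
        },
        metadata=payload.get("metadata", {}),
    )


# ---------------------------------------------------------------------------
# Spike-record serialization (CSV / NPZ)
# ---------------------------------------------------------------------------

def save_spike_events(events: Sequence[tuple[str, int, float]],
                      path: str | Path) -> None:
    """Write (layer, neuron_id, time_ms) events to CSV or NPZ by suffix."""
    path = Path(path)
    layers = np.array([e[0] for e in events])
    ids = np.array([e[1] for e in events], dtype=np.int64)
    times = np.array([e[2] for e in events], dtype=float)
    if path.suffix == ".npz":
        np.savez(path, layer=layers, neuron_id=ids, time_ms=times)
    else:
        with open(path, "w") as fh:
            fh.write("layer,neuron_id,time_ms\n")
            for layer, nid, t in zip(layers, ids, times):
                fh.write(f"{layer},{nid},{t:.6f}\n")


def load_spike_events(path: str | Path) -> list[tuple[str, int, float]]:
    path = Path(path)
    if path.suffix == ".npz":
        data = np.load(path, allow_pickle=False)
        return [
            (str(l), int(i), float(t))
            for l, i, t in zip(data["layer"], data["neuron_id"], data["time_ms"])
        ]
    events = []
    with open(path) as fh:
        next(fh)  # header
        for line in fh:
            layer, nid, t = line.rstrip("\n").split(",")
            events.append((layer, int(nid), float(t)))
    return events
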