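"""Image front-end: oriented filter bank, pooling, and latency encoding.

A 28x28 image is correlated with four zero-DC oriented line detectors
(0 deg, 45 deg, 90 deg, 135 deg; 5x5, valid mode, 28 -> 24 per axis),
rectified, 2x2 max-pooled (24 -> 12) and per-block max-normalized to
[0, 1], yielding four 12x12 feature blocks — 576 feature values in total.

Each feature value v is then turned into a single first-spike latency by an
exponential rank-order code: stronger features fire earlier, so the spike
*order* across the 576 input neurons carries the image content,

    T(v) = T_start + (2 * 0.5**v - 1) * (T_stop - T_start),    v in [0, 1]

which is strictly decreasing with T(1) = T_start and T(v -> 0) -> T_stop.
Features below ``v_min`` emit no spike at all.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.signal import correlate2d

from .data_io import GrayImage

N_BLOCKS = 4
BLOCK_SIDE = 12
N_INPUT_NEURONS = N_BLOCKS * BLOCK_SIDE * BLOCK_SIDE  # 576

#: Orientations of the shipped filter bank, in degrees. The angle is the
#: orientation of the line/edge the kernel responds to most strongly.
ORIENTATIONS = (0, 45, 90, 135)


@dataclass(frozen=True)
class FilterBank:
    """Four 5x5 zero-DC convolution kernels (oriented line detectors)."""

    kernels: np.ndarray  # shape (4, 5, 5)

    def __post_init__(self) -> None:
        k = np.asarray(self.kernels, dtype=float)
        if k.shape != (N_BLOCKS, 5, 5):
            raise ValueError(f"expected (4, 5, 5) kernels, got {k.shape}")
        sums = k.sum(axis=(1, 2))
        if not np.allclose(sums, 0.0, atol=1e-9):
            raise ValueError(f"kernels must each sum to 0, got sums {sums}")
        k.setflags(write=False)
        object.__setattr__(self, "kernels", k)

    def to_json(self) -> list[list[list[float]]]:
        return self.kernels.tolist()


def default_filter_bank() -> FilterBank:
    """The fixed bank of oriented line detectors shipped with the package.

    Each kernel has a positive ridge of weight 4 along its orientation and
    uniform -1 elsewhere, so every kernel sums to zero (constant images
    produce no response) and a thin line aligned with the ridge yields the
    maximal response while the orthogonal line yields zero.
    """
    kernels = np.full((N_BLOCKS, 5, 5), -1.0)
    rows, cols = np.mgrid[0:5, 0:5]
    kernels[0][rows == 2] = 4.0             # 0 deg: horizontal line
    kernels[1][rows + cols == 4] = 4.0      # 45 deg: anti-diagonal
    kernels[2][cols == 2] = 4.0             # 90 deg: vertical line
    kernels[3][rows == cols] = 4.0          # 135 deg: main diagonal
    return FilterBank(kernels)


@dataclass(frozen=True)
class FeatureBlocks:
    """Four 12x12 feature maps normalized to [0, 1], block-major order."""

    blocks: np.ndarray  # shape (4, 12, 12)

    def __post_init__(self) -> None:
        b = np.asarray(self.blocks, dtype=float)
        if b.shape != (N_BLOCKS, BLOCK_SIDE, BLOCK_SIDE):
            raise ValueError(f"expected (4, 12, 12) blocks, got {b.shape}")
        if b.min() < 0.0 or b.max() > 1.0 + 1e-12:
            raise ValueError("feature values must lie in [0, 1]")
        b.setflags(write=False)
        object.__setattr__(self, "blocks", b)

    def flatten(self) -> np.ndarray:
        """Feature vector in the fixed neuron-id order.

        Neuron id = block * 144 + row * 12 + col (row-major within block).
        """
        return self.blocks.reshape(-1)


def convolve_pool(image: GrayImage, bank: FilterBank | None = None) -> FeatureBlocks:
    """Correlate with each kernel, rectify, 2x2-max-pool and normalize.

    Valid-mode correlation of the 28x28 intensity grid with each 5x5 kernel
    gives 24x24 responses; negatives are clipped to 0, 2x2 max pooling with
    stride 2 reduces to 12x12, and each block is divided by its own maximum
    (an all-zero block stays all-zero).
    """
    if bank is None:
        bank = default_filter_bank()
    img = image.pixels.astype(float)
    blocks = np.empty((N_BLOCKS, BLOCK_SIDE, BLOCK_SIDE))
    for b, kernel in enumerate(bank.kernels):
        resp = correlate2d(img, kernel, mode="valid")
        resp = np.maximum(resp, 0.0)
        pooled = resp.reshape(BLOCK_SIDE, 2, BLOCK_SIDE, 2).max(axis=(1, 3))
        peak = pooled.max()
        blocks[b] = pooled / peak if peak > 0 else pooled
    return FeatureBlocks(blocks)


@dataclass(frozen=True)
class InputSpikePattern:
    """First-spike latency per input neuron; NaN means "no spike".

    ``times`` has one entry per input neuron (0..575, block-major
    flattening); every finite entry lies in [t_start, t_stop].
    """

    times: np.ndarray  # shape (576,), ms; NaN = silent
    t_start: float
    t_stop: float

    def __post_init__(self) -> None:
        t = np.asarray(self.times, dtype=float)
        if t.shape != (N_INPUT_NEURONS,):
            raise ValueError(f"expected {N_INPUT_NEURONS} latencies, got {t.shape}")
        finite = t[np.isfinite(t)]
        if finite.size and (finite.min() < self.t_start - 1e-9
                            or finite.max() > self.t_stop + 1e-9):
            raise ValueError("latencies must lie in [t_start, t_stop]")
        t.setflags(write=False)
        object.__setattr__(self, "times", t)

    @property
    def n_spikes(self) -> int:
        return int(np.isfinite(self.times).sum())

    def spike_list(self) -> list[tuple[int, float]]:
        """(neuron id, time) pairs for all spiking neurons, by id."""
        idx = np.flatnonzero(np.isfinite(self.times))
        return [(int(i), float(self.times[i])) for i in idx]


def latency(v: float | np.ndarray, t_start: float, t_stop: float,
            raw_formula: bool = False) -> float | np.ndarray:
    """The exponential rank-order latency map for feature value(s) v.

    With ``raw_formula=True`` the uncorrected variant
    ``(0.5**v - 1) * (t_stop - t_start) + t_start`` is returned instead; it
    has the same exponential shape but maps v > 0 to times before t_start,
    and exists for inspection only.
    """
    v = np.asarray(v, dtype=float)
    span = t_stop - t_start
    if raw_formula:
        out = (0.5 ** v - 1.0) * span + t_start
    else:
        out = t_start + (2.0 * 0.5 ** v - 1.0) * span
    return out if out.shape else float(out)


def encode_latencies(blocks: FeatureBlocks, t_start: float = 0.0,
                     t_stop: float = 100.0, v_min: float = 0.05) -> InputSpikePattern:
    """Map feature blocks to one first-spike latency per input neuron.

    Features with value below ``v_min`` stay silent; all others spike at
    ``latency(v)``, which decreases strictly with v, so the brightest
    feature of each block fires exactly at ``t_start``.
    """
    if t_stop <= t_start:
        raise ValueError("t_stop must exceed t_start")
    if not 0.0 < v_min <= 1.0:
        raise ValueError("v_min must lie in (0, 1]")
    v = blocks.flatten()
    times = np.where(v >= v_min, latency(v, t_start, t_stop), np.nan)
    return InputSpikePattern(times, t_start, t_stop)


def encode_image(image: GrayImage, bank: FilterBank | None = None,
                 t_start: float = 0.0, t_stop: float = 100.0,
                 v_min: float = 0.05) -> InputSpikePattern:
    """Full front-end: filter bank + pooling + latency code for one image."""
    return encode_latencies(convolve_pool(image, bank), t_start, t_stop, v_min)
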