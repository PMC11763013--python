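"""Time-sliced population decoding with Jaccard-distance matching.

The simulation window [0, T) is partitioned into n contiguous half-open
slices. Each spike record collapses, slice by slice, into the *set* of
neurons that fired at least once within the slice (a "spiking map").
Aggregating the maps of many samples of one class and keeping the neurons
active in at least a fraction ``freq_threshold`` of samples yields the
class's *expression* — its stored spatio-temporal memory.

A new sample is classified by the summed per-slice Jaccard distance

    delta(N_k, N') = sum_i [ 1 - |M_ki & M_i'| / |M_ki | M_i'| ]

against every class expression; the minimum-distance class wins. A slice
where both sets are empty contributes 0 (identical silence is perfect
agreement); a slice where exactly one side is empty contributes 1.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import ExpressionArchive
from .lif_network import SpikeRecord, Topology

#: Global-id offset per monitored layer, so that maps over several layers
#: (e.g. M1 and M2 of the 3-layer network) share one integer namespace.
LAYER_OFFSETS: dict[str, int] = {"M1": 0, "M2": 100_000}


@dataclass(frozen=True)
class SliceScheme:
    """n contiguous half-open time slices covering [0, duration)."""

    bounds: tuple[tuple[float, float], ...]

    def __post_init__(self) -> None:
        if not self.bounds:
            raise ValueError("a slice scheme needs at least one slice")
        for (a0, a1) in self.bounds:
            if a1 <= a0:
                raise ValueError("each slice must have positive width")
        for (_, a1), (b0, _) in zip(self.bounds, self.bounds[1:]):
            if not np.isclose(a1, b0):
                raise ValueError("slices must be contiguous")

    @classmethod
    def even(cls, n: int, duration: float) -> "SliceScheme":
        """n equal-width slices over [0, duration) — the default scheme."""
        if n < 1:
            raise ValueError("n must be >= 1")
        edges = np.linspace(0.0, duration, n + 1)
        return cls(tuple(zip(edges[:-1], edges[1:])))

    @property
    def n(self) -> int:
        return len(self.bounds)

    @property
    def duration(self) -> float:
        return self.bounds[-1][1] - self.bounds[0][0]

    def slice_of(self, t: float) -> int:
        """Index of the slice containing time t (half-open convention)."""
        for i, (a, b) in enumerate(self.bounds):
            if a <= t < b:
                return i
        raise ValueError(f"time {t} outside [0, {self.duration})")


@dataclass
class SliceMaps:
    """Ordered per-slice sets of active (global) neuron ids of one sample."""

    maps: list[set[int]]

    @property
    def n(self) -> int:
        return len(self.maps)


def global_ids(layer: str, ids: Iterable[int]) -> set[int]:
    off = LAYER_OFFSETS[layer]
    return {off + i for i in ids}


def slice_spikes(record: SpikeRecord, scheme: SliceScheme,
                 layers: Sequence[str] = ("M1",)) -> SliceMaps:
    """Collapse a spike record into per-slice active-neuron sets.

    A neuron belongs to slice i iff it has at least one spike with time in
    [T_i, T_{i+1}); multiple spikes in a slice collapse to one membership.
    Only the ``layers`` (the monitored layers) contribute, with ids mapped
    into the shared global namespace.
    """
    if not np.isclose(scheme.duration, record.duration):
        raise ValueError(
            f"scheme covers {scheme.duration} ms but the record lasts "
            f"{record.duration} ms"
        )
    maps: list[set[int]] = [set() for _ in range(scheme.n)]
    wanted = set(layers)
    for layer, nid, t in record.events:
        if layer not in wanted or t >= record.duration:
            continue
        maps[scheme.slice_of(t)].add(LAYER_OFFSETS[layer] + nid)
    return SliceMaps(maps)


def build_expression(samples: Sequence[SliceMaps], scheme: SliceScheme,
                     freq_threshold: float) -> list[set[int]]:
    """Aggregate one class's sample maps into its expression.

    Per slice and neuron, the activation frequency is the fraction of
    samples in which the neuron is active in that slice; the expression
    keeps neurons with frequency >= freq_threshold (inclusive).
    """
    if not samples:
        raise ValueError("need at least one sample to build an expression")
    if not 0.0 <= freq_threshold <= 1.0:
        raise ValueError("freq_threshold must lie in [0, 1]")
    n_samples = len(samples)
    expr: list[set[int]] = []
    for i in range(scheme.n):
        counts: dict[int, int] = {}
        for sm in samples:
            for nid in sm.maps[i]:
                counts[nid] = counts.get(nid, 0) + 1
        expr.append({nid for nid, c in counts.items()
                     if c / n_samples >= freq_threshold})
    return expr


def build_archive(records_by_class: Mapping[int, Sequence[SpikeRecord]],
                  scheme: SliceScheme, freq_threshold: float,
                  layers: Sequence[str] = ("M1",)) -> ExpressionArchive:
    """Build the full per-class expression archive from raw spike records."""
    expressions = {}
    n_samples = 0
    for cls, records in records_by_class.items():
        samples = [slice_spikes(r, scheme, layers) for r in records]
        expressions[cls] = build_expression(samples, scheme, freq_threshold)
        n_samples = max(n_samples, len(samples))
    return ExpressionArchive(
        n_slices=scheme.n,
        slice_bounds=list(scheme.bounds),
        expressions=expressions,
        metadata={
            "freq_threshold": freq_threshold,
            "n_samples": n_samples,
            "layers": list(layers),
            "layer_offsets": {l: LAYER_OFFSETS[l] for l in layers},
        },
    )


def jaccard_distance(expr_maps: Sequence[set[int]],
                     sample_maps: SliceMaps | Sequence[set[int]]) -> float:
    """Summed per-slice Jaccard distance between two ordered map lists.

    Symmetric, bounded by the slice count n, and 0 iff the lists agree
    slice-wise (under the empty/empty = identical-silence convention).
    """
    if isinstance(sample_maps, SliceMaps):
        sample_maps = sample_maps.maps
    if len(expr_maps) != len(sample_maps):
        raise ValueError(
            f"slice counts differ: {len(expr_maps)} vs {len(sample_maps)}"
        )
    total = 0.0
    for a, b in zip(expr_maps, sample_maps):
        union = len(a | b)
        if union == 0:
            continue  # both silent: perfect agreement
        total += 1.0 - len(a & b) / union
    return total


def classify(sample: SliceMaps, archive: ExpressionArchive,
             ) -> tuple[int, dict[int, float]]:
    """Minimum-Jaccard-distance class of a sample, plus all distances.

    Ties go to the lowest class id.
    """
    if sample.n != archive.n_slices:
        raise ValueError("sample and archive slice counts differ")
    if not archive.expressions:
        raise ValueError("archive holds no expressions")
    distances = {
        cls: jaccard_distance(maps, sample)
        for cls, maps in sorted(archive.expressions.items())
    }
    best = min(distances, key=lambda c: (distances[c], c))
    return best, distances


# ---------------------------------------------------------------------------
# Slice-map figures
# ---------------------------------------------------------------------------

def plot_slice_maps(maps: SliceMaps | Sequence[set[int]], scheme: SliceScheme,
                    path, grid_side: int = 12, n_blocks: int = 4,
                    title: str | None = None) -> None:
    """One panel per slice: active M1 neurons as dots on the feature grid.

    M2 neurons (offset namespace) are drawn below the grid as a strip.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if isinstance(maps, SliceMaps):
        maps = maps.maps
    n = len(maps)
    fig, axes = plt.subplots(1, n, figsize=(3 * n, 3.4), squeeze=False)
    per_block = grid_side * grid_side
    for i, (ax, s) in enumerate(zip(axes[0], maps)):
        for nid in s:
            if nid >= LAYER_OFFSETS["M2"]:
                k = nid - LAYER_OFFSETS["M2"]
                ax.plot(k % grid_side, -2 - k // grid_side, "rs", ms=3)
                continue
            block, rest = divmod(nid, per_block)
            row, col = divmod(rest, grid_side)
            ax.plot(block % 2 * (grid_side + 1) + col,
                    grid_side - row + (block // 2) * (grid_side + 1),
                    "ko", ms=3)
        a, b = scheme.bounds[i]
        ax.set_title(f"[{a:.0f}, {b:.0f}) ms")
        ax.set_xlim(-1, 2 * grid_side + 2)
        ax.set_ylim(-6, 2 * grid_side + 3)
        ax.set_xticks([])
        ax.set_yticks([])
    if title:
        fig.suptitle(title)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
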