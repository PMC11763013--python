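"""End-to-end experiment orchestration.

One config drives the whole pipeline: dataset -> feature encoding -> pair
formation -> STDP refinement -> topology construction -> expression
building -> Jaccard classification, plus the sweep experiments (slice
counts x frequency thresholds, pair-count caps, preset currents, deletion
noise). Every stage is deterministic given the config seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from importlib.metadata import version as _pkg_version
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from . import data_io
from .data_io import GrayImage, LabeledImageSet
from .expression_decoding import (
    SliceMaps,
    SliceScheme,
    build_archive,
    classify,
    plot_slice_maps,
    slice_spikes,
)
from .lif_network import (
    LIFParams,
    Network,
    STDPParams,
    SpikeRecord,
    Topology,
    attach_preset_current,
    base_topology,
    default_stdp_params,
    rheobase,
)
from .preprocess import encode_image
from .structural_learning import (
    PairFormationParams,
    RefinedPairSet,
    build_topology,
    form_pairs,
    pairs_to_json,
    refine_pairs,
    train_pair_weights,
)

logger = logging.getLogger("pairslice")

RESULT_COLUMNS = [
    "n_layers", "n_slices", "freq_threshold", "n_pairs",
    "preset_M1_pA", "preset_M2_pA", "noise_ratio",
    "accuracy", "per_class_accuracy", "mean_distance_margin",
    "m2_spike_count",
]


@dataclass
class ExperimentConfig:
    """All knobs of one experiment run.

    The simulation interval defaults to the encoding interval plus 20 ms
    of headroom so delayed spikes stay inside the window; configurations
    with less headroom are rejected.
    """

    dataset: str = "synthetic"          # "synthetic" or a path to IDX files
    classes: int = 10
    n_train_per_class: int = 200
    n_test_per_class: int = 50
    seed: int = 0
    jitter_px: int = 2
    noise_sd: float = 8.0

    t_encode: float = 100.0             # ms
    t_sim: float | None = None          # ms, default t_encode + 20
    dt: float = 0.1                     # ms
    delay: float = 1.0                  # ms
    v_min: float = 0.05

    n_layers: int = 2
    slice_counts: tuple[int, ...] = (2, 3, 4, 6)
    freq_thresholds: tuple[float, ...] = (0.2, 0.4, 0.5)
    pair_cap: int | None = None         # keep top-k refined pairs by weight

    T_thre: float = 10.0                # ms co-firing window
    S_thre: int = 1                     # Chebyshev neighborhood radius
    C_thre_fraction: float = 0.35       # of a digit's presentations
    dominance_ratio: float = 1.2

    preset_currents: dict = field(default_factory=dict)   # layer -> pA
    noise_ratios: tuple[float, ...] = (0.0, 0.2)
    outdir: str | None = None

    def __post_init__(self) -> None:
        if self.t_sim is None:
            self.t_sim = self.t_encode + 20.0
        if self.t_sim < self.t_encode + 20.0 - 1e-9:
            raise ValueError("t_sim must be at least t_encode + 20 ms")
        for name in ("slice_counts", "freq_thresholds", "noise_ratios"):
            if not getattr(self, name):
                raise ValueError(f"{name} must be non-empty")
        if self.n_layers not in (2, 3):
            raise ValueError("n_layers must be 2 or 3")


def load_dataset(config: ExperimentConfig) -> tuple[LabeledImageSet, LabeledImageSet]:
    """Train/test image sets per the config (synthetic glyphs or IDX)."""
    n_total = config.n_train_per_class + config.n_test_per_class
    if config.dataset == "synthetic":
        full = data_io.generate_glyphs(
            config.classes, n_total, seed=config.seed,
            jitter_px=config.jitter_px, noise_sd=config.noise_sd,
        )
    else:
        full = data_io.read_idx(config.dataset)
    train, test = [], []
    for cls in sorted(full.class_counts):
        imgs = full.by_class(cls)
        train.extend(imgs[: config.n_train_per_class])
        test.extend(imgs[config.n_train_per_class : n_total])
    return LabeledImageSet(train), LabeledImageSet(test)


class TrainedPipeline:
    """A fitted pipeline: refined pairs, built topology, cached records.

    Construction runs Algorithm steps 1-3 (pair formation, STDP
    refinement, topology building) and simulates the train and test sets
    once on the final static network; evaluation sweeps (slice counts,
    thresholds, noise, preset currents) reuse the cached records where the
    dynamics are unchanged.
    """

    def __init__(self, config: ExperimentConfig) -> None:
        self.config = config
        self.lif = LIFParams()
        self.stdp = default_stdp_params(self.lif)
        logger.info("fitting pipeline: %s (pairslice %s)",
                    asdict(config), _pkg_version("pairslice"))

        self.train_set, self.test_set = load_dataset(config)
        self.digits = sorted(self.train_set.class_counts)

        # --- Step 1: pair formation on the base (one-to-one) network ----
        base = base_topology(self.lif, delay=config.delay)
        base_net = Network(base, config.dt)
        records_by_digit: dict[int, list[SpikeRecord]] = {}
        for digit in self.digits:
            records_by_digit[digit] = [
                base_net.run(self._encode(im), config.t_sim)[0]
                for im in self.train_set.by_class(digit)
            ]
        c_thre = max(1, int(round(config.C_thre_fraction
                                  * config.n_train_per_class)))
        self.pair_params = PairFormationParams(config.T_thre, config.S_thre, c_thre)
        self.candidates = form_pairs(records_by_digit, self.pair_params)
        logger.info("step 1: %s candidate pairs per digit",
                    {d: len(v) for d, v in self.candidates.items()})

        # --- Step 2: unsupervised STDP refinement -----------------------
        matrix = train_pair_weights(
            self.candidates, self.train_set, lif=self.lif, stdp=self.stdp,
            dt=config.dt, delay=config.delay,
            t_encode=config.t_encode, t_sim=config.t_sim, v_min=config.v_min,
        )
        self.refined: RefinedPairSet = refine_pairs(
            matrix, config.dominance_ratio
        ).top_k(config.pair_cap)
        logger.info("step 2: %d refined pairs", len(self.refined))

        # --- Step 3: final static topology ------------------------------
        if self.refined.pairs:
            self.topology = build_topology(self.refined, config.n_layers,
                                           lif=self.lif, delay=config.delay)
        else:
            # degenerate (tiny) runs can refine away every candidate; fall
            # back to the bare one-to-one network so the run still completes
            logger.warning("no refined pairs survived; using the base network")
            self.topology = base_topology(self.lif, delay=config.delay)
        for layer, amp in config.preset_currents.items():
            self.topology = attach_preset_current(self.topology, layer, amp)
        self.monitored = self.topology.monitored

        # --- cache records on the final network -------------------------
        self.train_records = {
            digit: self._simulate_images(self.train_set.by_class(digit))
            for digit in self.digits
        }
        self.test_records = [
            (im.label, rec)
            for im, rec in zip(self.test_set,
                               self._simulate_images(list(self.test_set)))
        ]

    # -- helpers ---------------------------------------------------------

    def _encode(self, image: GrayImage):
        return encode_image(image, t_start=0.0, t_stop=self.config.t_encode,
                            v_min=self.config.v_min)

    def _simulate_images(self, images: Sequence[GrayImage],
                         topology: Topology | None = None) -> list[SpikeRecord]:
        net = Network(topology or self.topology, self.config.dt)
        return [net.run(self._encode(im), self.config.t_sim)[0] for im in images]

    def scheme(self, n_slices: int) -> SliceScheme:
        return SliceScheme.even(n_slices, self.config.t_sim)

    def archive(self, n_slices: int, freq_threshold: float,
                train_records: dict[int, list[SpikeRecord]] | None = None):
        return build_archive(train_records or self.train_records,
                             self.scheme(n_slices), freq_threshold,
                             layers=self.monitored)

    # -- evaluation ------------------------------------------------------

    def evaluate(self, n_slices: int, freq_threshold: float,
                 test_records: Sequence[tuple[int, SpikeRecord]] | None = None,
                 ) -> dict:
        """Accuracy (overall and per class) and the mean distance margin
        of the runner-up over the winner, for one slicing/threshold."""
        archive = self.archive(n_slices, freq_threshold)
        scheme = self.scheme(n_slices)
        records = self.test_records if test_records is None else test_records
        hits: dict[int, list[bool]] = {d: [] for d in self.digits}
        margins = []
        for label, rec in records:
            sample = slice_spikes(rec, scheme, self.monitored)
            pred, dists = classify(sample, archive)
            hits[label].append(pred == label)
            ranked = sorted(dists.values())
            margins.append(ranked[1] - ranked[0] if len(ranked) > 1 else 0.0)
        per_class = {d: float(np.mean(h)) if h else float("nan")
                     for d, h in hits.items()}
        accuracy = float(np.mean([ok for h in hits.values() for ok in h]))
        return {
            "n_slices": n_slices,
            "freq_threshold": freq_threshold,
            "accuracy": accuracy,
            "per_class_accuracy": per_class,
            "mean_distance_margin": float(np.mean(margins)),
        }

    def noisy_test_records(self, ratio: float) -> list[tuple[int, SpikeRecord]]:
        """Test records after deletion noise at the given ratio."""
        noisy = [
            data_io.corrupt_deletion_noise(im, ratio, seed=self.config.seed + 1 + i)
            for i, im in enumerate(self.test_set)
        ]
        return [(im.label, rec)
                for im, rec in zip(noisy, self._simulate_images(noisy))]

    def with_preset_currents(self, currents: dict[str, float]) -> Topology:
        topo = self.topology
        for layer in self.monitored:
            topo = attach_preset_current(topo, layer, currents.get(layer, 0.0))
        return topo

    def layer_spike_count(self, records: Sequence[tuple[int, SpikeRecord]],
                          layer: str) -> int:
        return int(sum(rec.count(layer) for _, rec in records))


def _result_row(pipeline: TrainedPipeline, metrics: dict, *,
                noise_ratio: float = 0.0,
                preset: tuple[float, float] = (0.0, 0.0),
                m2_spikes: int | None = None) -> dict:
    cfg = pipeline.config
    return {
        "n_layers": cfg.n_layers,
        "n_slices": metrics["n_slices"],
        "freq_threshold": metrics["freq_threshold"],
        "n_pairs": len(pipeline.refined),
        "preset_M1_pA": preset[0],
        "preset_M2_pA": preset[1],
        "noise_ratio": noise_ratio,
        "accuracy": metrics["accuracy"],
        "per_class_accuracy": json.dumps(metrics["per_class_accuracy"],
                                         sort_keys=True),
        "mean_distance_margin": metrics["mean_distance_margin"],
        "m2_spike_count": m2_spikes if m2_spikes is not None else 0,
    }


def _finish(rows: list[dict], config: ExperimentConfig,
            name: str) -> pd.DataFrame:
    table = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if config.outdir:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        path = outdir / f"{name}.csv"
        table.to_csv(path, index=False, float_format="%.6f")
        logger.info("wrote %s", path)
    return table


def run_pipeline(config: ExperimentConfig,
                 pipeline: TrainedPipeline | None = None,
                 figures: bool = False) -> pd.DataFrame:
    """Fit the pipeline and sweep slice counts x frequency thresholds.

    Writes the result CSV, the refined pair set and one expression archive
    per swept combination into ``config.outdir`` (when set).
    """
    pipeline = pipeline or TrainedPipeline(config)
    rows = []
    outdir = Path(config.outdir) if config.outdir else None
    if outdir:
        outdir.mkdir(parents=True, exist_ok=True)
        (outdir / "refined_pairs.json").write_text(
            json.dumps(pairs_to_json(pipeline.refined), indent=1)
        )
    preset = (pipeline.topology.preset_current("M1"),
              pipeline.topology.preset_current("M2")
              if "M2" in pipeline.topology.layer_sizes else 0.0)
    for n_slices in config.slice_counts:
        for theta in config.freq_thresholds:
            metrics = pipeline.evaluate(n_slices, theta)
            m2 = (pipeline.layer_spike_count(pipeline.test_records, "M2")
                  if "M2" in pipeline.monitored else None)
            rows.append(_result_row(pipeline, metrics, preset=preset,
                                    m2_spikes=m2))
            if outdir:
                data_io.save_expressions(
                    pipeline.archive(n_slices, theta),
                    outdir / f"expressions_n{n_slices}_t{theta:g}.json",
                )
            if figures and outdir:
                digit = pipeline.digits[0]
                sample = slice_spikes(pipeline.train_records[digit][0],
                                      pipeline.scheme(n_slices),
                                      pipeline.monitored)
                plot_slice_maps(sample, pipeline.scheme(n_slices),
                                outdir / f"slicemap_d{digit}_n{n_slices}.png",
                                title=f"digit {digit}, {n_slices} slices")
    return _finish(rows, config, "results")


def run_noise_experiment(config: ExperimentConfig,
                         ratios: Sequence[float] | None = None,
                         pipeline: TrainedPipeline | None = None) -> pd.DataFrame:
    """Classify deletion-noise-corrupted test sets at each noise ratio.

    Uses the first configured slice count and frequency threshold; the
    ratio-0 row classifies the clean cached test records.
    """
    pipeline = pipeline or TrainedPipeline(config)
    ratios = tuple(config.noise_ratios if ratios is None else ratios)
    n_slices, theta = config.slice_counts[0], config.freq_thresholds[0]
    rows = []
    for ratio in ratios:
        records = (pipeline.test_records if ratio == 0.0
                   else pipeline.noisy_test_records(ratio))
        metrics = pipeline.evaluate(n_slices, theta, test_records=records)
        rows.append(_result_row(pipeline, metrics, noise_ratio=ratio))
    return _finish(rows, config, "noise_results")


def run_preset_current_experiment(config: ExperimentConfig,
                                  currents: Sequence[tuple[float, float]],
                                  pipeline: TrainedPipeline | None = None,
                                  ) -> pd.DataFrame:
    """One row per (M1, M2) preset-current pair, incl. the (0,0) baseline.

    Currents are applied at test time only; sub-rheobase amplitudes
    depolarize neurons without making a silent network fire. Amplitudes at
    or above the rheobase are allowed but logged as a warning since those
    neurons fire on their own.
    """
    pipeline = pipeline or TrainedPipeline(config)
    currents = list(currents)
    if (0.0, 0.0) not in currents:
        currents.insert(0, (0.0, 0.0))
    i_rheo = rheobase(pipeline.lif)
    n_slices, theta = config.slice_counts[0], config.freq_thresholds[0]
    rows = []
    for a, b in currents:
        if max(a, b) >= i_rheo:
            logger.warning("preset current (%s, %s) pA reaches the rheobase "
                           "%s pA; neurons will self-fire", a, b, i_rheo)
        if (a, b) == (0.0, 0.0):
            records = pipeline.test_records
        else:
            topo = pipeline.with_preset_currents({"M1": a, "M2": b})
            records = [
                (im.label, rec)
                for im, rec in zip(
                    pipeline.test_set,
                    pipeline._simulate_images(list(pipeline.test_set), topo),
                )
            ]
        metrics = pipeline.evaluate(n_slices, theta, test_records=records)
        m2 = (pipeline.layer_spike_count(records, "M2")
              if "M2" in pipeline.monitored else None)
        rows.append(_result_row(pipeline, metrics, preset=(a, b),
                                m2_spikes=m2))
    return _finish(rows, config, "preset_current_results")
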