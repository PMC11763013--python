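"""Shared fixtures: parameter sets, small datasets, trained pipelines.

The two trained pipelines (2-layer and 3-layer) are session-scoped because
fitting one runs several hundred network simulations; every end-to-end
test shares them. Study conditions: 4 well-separated glyph classes, 50
training and 20 test images per class, fixed seed.
"""

from __future__ import annotations

import numpy as np
import pytest

from pairslice import ExperimentConfig, TrainedPipeline
from pairslice.lif_network import LIFParams, SpikeRecord
from pairslice.structural_learning import PairFormationParams, neighborhood


@pytest.fixture(scope="session")
def lif() -> LIFParams:
    return LIFParams()


def _pipeline_config(n_layers: int) -> ExperimentConfig:
    return ExperimentConfig(
        classes=4, n_train_per_class=50, n_test_per_class=20,
        n_layers=n_layers, slice_counts=(1, 4), freq_thresholds=(0.2,),
        noise_ratios=(0.0, 0.2, 1.0), seed=1,
    )


@pytest.fixture(scope="session")
def trained_pipeline() -> TrainedPipeline:
    """Fitted 2-layer pipeline on the 4-class glyph task."""
    return TrainedPipeline(_pipeline_config(n_layers=2))


@pytest.fixture(scope="session")
def trained_pipeline_3layer() -> TrainedPipeline:
    """Fitted 3-layer pipeline on the same task (dedicated M2 neurons)."""
    return TrainedPipeline(_pipeline_config(n_layers=3))


# ---------------------------------------------------------------------------
# Brute-force pair-formation oracle
# ---------------------------------------------------------------------------

def brute_force_pairs(records: list[SpikeRecord], params: PairFormationParams,
                      n_neurons: int, side: int) -> set[tuple[int, int]]:
    """Nested-loop reference for pair formation: all ordered neighbor pairs
    x all presentations, counting first-spike co-firings."""
    firsts = [r.first_spike_times("M1", n_neurons) for r in records]
    out = set()
    for i in range(n_neurons):
        for j in neighborhood(i, params.S_thre, side):
            count = 0
            for f in firsts:
                d = f[j] - f[i]
                if np.isfinite(d) and 0 < d <= params.T_thre:
                    count += 1
            if count >= params.C_thre:
                out.add((i, j))
    return out


def random_records(rng: np.random.Generator, n_neurons: int,
                   n_presentations: int, duration: float = 50.0,
                   p_active: float = 0.7) -> list[SpikeRecord]:
    """Random small first-spike records on an M1 grid, for oracle tests."""
    records = []
    for _ in range(n_presentations):
        events = []
        for n in range(n_neurons):
            if rng.random() < p_active:
                events.append(("M1", n, float(rng.uniform(0, duration))))
        events.sort(key=lambda e: e[2])
        records.append(SpikeRecord(events, duration, 0.1))
    return records


@pytest.fixture(scope="session")
def pair_oracle():
    return brute_force_pairs


@pytest.fixture(scope="session")
def random_record_factory():
    return random_records
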