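"""Structural learning: neuron pairs from co-firing, refined by STDP.

The memory layer M1 is a 4 x 12 x 12 grid (four orientation blocks of
12 x 12 neurons, one per input neuron). Structural learning proceeds in
three steps:

1. *Pair formation* ("fire together, wire together"): for every ordered
   pair (Ni, Nj) with Nj in the Chebyshev neighborhood of Ni within the
   same orientation block, count the presentations of a digit in which Nj
   fires within (0, T_thre] ms after Ni (first spikes per presentation).
   Pairs whose count reaches C_thre become candidates for that digit.

2. *Pair refinement*: all candidate pairs get plastic (STDP) synapses;
   each digit's images are presented in turn and the final weight of every
   pair is recorded per digit, with weights reset between rounds. The
   process is unsupervised — labels only group the presentation rounds. A
   pair is kept for the digit whose trained weight dominates the runner-up
   by ``dominance_ratio``; among survivors sharing a post neuron only the
   strongest is retained.

3. *Topology construction*: the refined pairs are wired with static
   synapses — inside M1 (2-layer network) or each onto a dedicated
   second-memory-layer neuron fed by both pair members (3-layer network).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np

from .data_io import LabeledImageSet
from .lif_network import (
    LIFParams,
    Network,
    SpikeRecord,
    STDPParams,
    Synapse,
    Topology,
    base_topology,
    default_stdp_params,
    suprathreshold_weight,
)
from .preprocess import BLOCK_SIDE, N_INPUT_NEURONS, encode_image

M1_GRID = BLOCK_SIDE  # neurons per block axis


@dataclass(frozen=True)
class PairFormationParams:
    """Thresholds of the pair-formation rule.

    T_thre: co-firing window in ms; S_thre: Chebyshev neighborhood radius
    on the 12x12 block grid; C_thre: minimum number of presentations in
    which the ordered co-firing must occur.
    """

    T_thre: float = 10.0
    S_thre: int = 1
    C_thre: int = 1

    def __post_init__(self) -> None:
        if self.T_thre <= 0:
            raise ValueError("T_thre must be positive")
        if self.S_thre < 1 or int(self.S_thre) != self.S_thre:
            raise ValueError("S_thre must be a positive integer")
        if self.C_thre < 1 or int(self.C_thre) != self.C_thre:
            raise ValueError("C_thre must be a positive integer")


@dataclass(frozen=True)
class NeuronPair:
    """An ordered pre -> post pair of M1 neurons assigned to a digit."""

    pre: int
    post: int
    digit: int
    weight: float = 0.0

    def __post_init__(self) -> None:
        if self.pre == self.post:
            raise ValueError("a pair needs two distinct neurons")


@dataclass
class RefinedPairSet:
    """Refined pairs (unique post neurons) plus the ratio that refined them."""

    pairs: list[NeuronPair]
    dominance_ratio: float

    def __post_init__(self) -> None:
        posts = [p.post for p in self.pairs]
        if len(posts) != len(set(posts)):
            raise ValueError("refined pairs must have unique post neurons")

    def top_k(self, k: int | None) -> "RefinedPairSet":
        """Keep the k pairs with the largest weights (stable by pre id)."""
        if k is None or k >= len(self.pairs):
            return self
        ranked = sorted(self.pairs, key=lambda p: (-p.weight, p.pre, p.post))
        return RefinedPairSet(ranked[:k], self.dominance_ratio)

    def __len__(self) -> int:
        return len(self.pairs)


def grid_position(neuron: int, side: int = M1_GRID) -> tuple[int, int, int]:
    """(block, row, col) of an M1 neuron id under block-major flattening."""
    per_block = side * side
    block, rest = divmod(neuron, per_block)
    row, col = divmod(rest, side)
    return block, row, col


def neighborhood(neuron: int, radius: int, side: int = M1_GRID) -> list[int]:
    """Same-block neighbors of a neuron within Chebyshev ``radius``."""
    block, row, col = grid_position(neuron, side)
    out = []
    for dr in range(-radius, radius + 1):
        for dc in range(-radius, radius + 1):
            if dr == 0 and dc == 0:
                continue
            r, c = row + dr, col + dc
            if 0 <= r < side and 0 <= c < side:
                out.append(block * side * side + r * side + c)
    return out


def form_pairs(records_by_digit: Mapping[int, Sequence[SpikeRecord]],
               params: PairFormationParams, layer: str = "M1",
               n_neurons: int = N_INPUT_NEURONS,
               side: int = M1_GRID) -> dict[int, list[tuple[int, int]]]:
    """Candidate ordered pairs per digit from first-spike co-firing counts.

    For each digit, each ordered neighbor pair (Ni, Nj) is emitted iff
    0 < T(Nj) - T(Ni) <= T_thre held (on first spikes) in at least C_thre
    of the digit's presentations.
    """
    nbr = [neighborhood(i, params.S_thre, side) for i in range(n_neurons)]
    pre_idx = np.array([i for i in range(n_neurons) for _ in nbr[i]], dtype=np.int64)
    post_idx = np.array([j for i in range(n_neurons) for j in nbr[i]], dtype=np.int64)

    out: dict[int, list[tuple[int, int]]] = {}
    for digit in sorted(records_by_digit):
        records = records_by_digit[digit]
        if not records:
            raise ValueError(f"no spike records supplied for digit {digit}")
        counts = np.zeros(len(pre_idx), dtype=np.int64)
        for rec in records:
            first = rec.first_spike_times(layer, n_neurons)
            dtv = first[post_idx] - first[pre_idx]
            counts += ((dtv > 0) & (dtv <= params.T_thre)).astype(np.int64)
        hits = counts >= params.C_thre
        out[digit] = [(int(a), int(b)) for a, b in
                      zip(pre_idx[hits], post_idx[hits])]
    return out


@dataclass
class PairWeightMatrix:
    """Trained weight of every candidate pair under every digit's round."""

    pairs: list[tuple[int, int]]       # union of candidates across digits
    digits: list[int]
    weights: np.ndarray                # shape (n_pairs, n_digits)

    def __post_init__(self) -> None:
        if self.weights.shape != (len(self.pairs), len(self.digits)):
            raise ValueError("weight matrix shape mismatch")


def train_pair_weights(candidates: Mapping[int, Sequence[tuple[int, int]]],
                       image_set: LabeledImageSet,
                       lif: LIFParams | None = None,
                       stdp: STDPParams | None = None,
                       w_init: float | None = None,
                       w_in: float | None = None,
                       dt: float = 0.1, delay: float = 1.0,
                       t_encode: float = 100.0, t_sim: float = 120.0,
                       v_min: float = 0.05,
                       union_network: bool = True) -> PairWeightMatrix:
    """Step-2 unsupervised STDP training of all candidate pairs.

    One network holds plastic synapses for the union of candidate pairs
    across digits (``union_network=True``, the default) or only the
    current digit's candidates in isolation. For each digit in turn, its
    images are presented with STDP enabled (weights carried across
    presentations within the round), final weights are recorded, and all
    plastic weights are reset before the next digit's round.
    """
    lif = lif or LIFParams()
    stdp = stdp or default_stdp_params(lif)
    if w_init is None:
        # start near the bottom of the range: refinement reads out
        # potentiation, so a low start maximizes the dominance contrast
        w_init = 0.1 * stdp.w_max

    union: list[tuple[int, int]] = sorted(
        {pair for pairs in candidates.values() for pair in pairs}
    )
    digits = sorted(candidates)
    if not union:
        return PairWeightMatrix([], digits, np.zeros((0, len(digits))))

    patterns = {
        digit: [encode_image(im, t_start=0.0, t_stop=t_encode, v_min=v_min)
                for im in image_set.by_class(digit)]
        for digit in digits
    }

    def round_weights(pairs: list[tuple[int, int]], digit: int) -> dict:
        base = base_topology(lif, w_in=w_in, delay=delay)
        plastic = tuple(
            Synapse("M1", a, "M1", b, w_init, delay, "stdp") for a, b in pairs
        )
        topo = Topology(layers=base.layers, synapses=base.synapses + plastic,
                        lif=lif, monitored=("M1",))
        net = Network(topo, dt)
        w = net.w0.copy()
        for pat in patterns[digit]:
            _, w = net.run(pat, t_sim, plastic=True, weights=w, stdp=stdp)
        n_static = len(base.synapses)
        return dict(zip(pairs, w[n_static:]))

    weights = np.zeros((len(union), len(digits)))
    for j, digit in enumerate(digits):
        pairs = union if union_network else sorted(set(candidates[digit]))
        trained = round_weights(pairs, digit)
        for i, pair in enumerate(union):
            weights[i, j] = trained.get(pair, w_init if union_network else 0.0)
    return PairWeightMatrix(union, digits, weights)


def refine_pairs(matrix: PairWeightMatrix,
                 dominance_ratio: float = 1.2) -> RefinedPairSet:
    """Keep pairs whose best digit's weight dominates, one per post neuron.

    Rule 1: pair p is assigned to d* = argmax_d W[p, d] iff
    W[p, d*] >= dominance_ratio * (second-highest weight); ties in the
    argmax go to the lowest digit id. A pair whose best weight is 0
    carries no evidence and is removed. Rule 2: among survivors sharing a
    post neuron only the largest-weight pair is retained (tie: lowest
    pre id).
    """
    if dominance_ratio <= 1.0:
        raise ValueError("dominance_ratio must exceed 1")
    survivors: list[NeuronPair] = []
    for i, (pre, post) in enumerate(matrix.pairs):
        row = matrix.weights[i]
        best = int(np.argmax(row))  # argmax -> lowest digit index on ties
        w_best = row[best]
        if w_best <= 0:
            continue
        if len(row) > 1:
            second = np.partition(row, -2)[-2]
            if w_best < dominance_ratio * second:
                continue
        survivors.append(NeuronPair(pre, post, matrix.digits[best], float(w_best)))

    by_post: dict[int, NeuronPair] = {}
    for pair in survivors:
        held = by_post.get(pair.post)
        if held is None or (pair.weight, -pair.pre) > (held.weight, -held.pre):
            by_post[pair.post] = pair
    kept = sorted(by_post.values(), key=lambda p: (p.post, p.pre))
    return RefinedPairSet(kept, dominance_ratio)


def build_topology(refined: RefinedPairSet, n_layers: int,
                   lif: LIFParams | None = None,
                   w_in: float | None = None, w_pair_max: float | None = None,
                   delay: float = 1.0) -> Topology:
    """Wire the refined pairs into a runnable 2- or 3-layer network.

    The base network is input (576) one-to-one onto M1 (576) with static
    suprathreshold weights. Learned pair weights are rescaled
    proportionally into [0, w_pair_max] (default: the suprathreshold
    weight). For ``n_layers=2`` each pair adds one static pre -> post
    synapse inside M1 (monitored: M1); for ``n_layers=3`` each pair gets a
    dedicated M2 neuron receiving static synapses from both pair members
    (monitored: M1 and M2).
    """
    if n_layers not in (2, 3):
        raise ValueError("n_layers must be 2 or 3")
    if not refined.pairs:
        raise ValueError("refined pair set is empty")
    lif = lif or LIFParams()
    if w_pair_max is None:
        w_pair_max = suprathreshold_weight(lif)
    base = base_topology(lif, w_in=w_in, delay=delay)

    w_learned = np.array([p.weight for p in refined.pairs])
    peak = w_learned.max()
    w_static = w_pair_max * w_learned / peak if peak > 0 else w_learned

    if n_layers == 2:
        extra = tuple(
            Synapse("M1", p.pre, "M1", p.post, float(w), delay, "static")
            for p, w in zip(refined.pairs, w_static)
        )
        return Topology(layers=base.layers, synapses=base.synapses + extra,
                        lif=lif, monitored=("M1",))

    m2_size = len(refined.pairs)
    extra = []
    for k, (p, w) in enumerate(zip(refined.pairs, w_static)):
        extra.append(Synapse("M1", p.pre, "M2", k, float(w), delay, "static"))
        extra.append(Synapse("M1", p.post, "M2", k, float(w), delay, "static"))
    return Topology(
        layers=base.layers + (("M2", m2_size),),
        synapses=base.synapses + tuple(extra),
        lif=lif, monitored=("M1", "M2"),
    )


# ---------------------------------------------------------------------------
# JSON round-trip for refined pair sets
# ---------------------------------------------------------------------------

def pairs_to_json(refined: RefinedPairSet) -> dict:
    return {
        "dominance_ratio": refined.dominance_ratio,
        "pairs": [
            {"pre": p.pre, "post": p.post, "digit": p.digit, "weight": p.weight}
            for p in refined.pairs
        ],
    }


def pairs_from_json(payload: dict) -> RefinedPairSet:
    return RefinedPairSet(
        [NeuronPair(d["pre"], d["post"], d["digit"], d["weight"])
         for d in payload["pairs"]],
        payload["dominance_ratio"],
    )
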