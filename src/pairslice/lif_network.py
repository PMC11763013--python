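"""Clock-driven simulation of layered LIF networks with alpha-shaped PSCs.

The neuron is the classic leaky integrate-and-fire model with current-based
alpha synapses (the ``iaf_psc_alpha`` dynamics): below threshold the
membrane potential V and the synaptic current state (y1, y2) obey the
linear system

    dy1/dt = -y1 / tau_syn
    dy2/dt =  y1 - y2 / tau_syn
    dV/dt  = -(V - E_L) / tau_m + (y2 + I_DC) / C_m

where an incoming spike of weight w (pA) adds ``w * e / tau_syn`` to y1 so
that the resulting post-synaptic current y2(t) = w * (e*t/tau_syn) *
exp(-t/tau_syn) peaks at exactly w after tau_syn. When V exceeds V_th
(strictly — see ``rheobase``) the neuron emits a spike, V is reset to
V_reset and clamped there for the refractory period t_ref.

Integration is clock-driven with an exact propagator for the linear
subsystem (matrix exponential of the (y1, y2, V) system per time step), so
sub-threshold trajectories are exact on the grid; only threshold crossings
are resolved at dt resolution.

Plastic synapses follow a nearest-neighbor pair-based STDP rule with soft
(multiplicative) bounds; see ``stdp_delta_w``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from functools import lru_cache
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .preprocess import InputSpikePattern, N_INPUT_NEURONS


# ---------------------------------------------------------------------------
# Parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LIFParams:
    """Membrane and synapse constants of the alpha-PSC LIF neuron.

    Defaults are the conventional values for this neuron model:
    C_m=250 pF, tau_m=10 ms, E_L=V_reset=-70 mV, V_th=-55 mV,
    tau_syn=2 ms, with a 1 ms refractory period.
    """

    C_m: float = 250.0      # pF
    tau_m: float = 10.0     # ms
    V_th: float = -55.0     # mV
    E_L: float = -70.0      # mV
    V_reset: float = -70.0  # mV
    t_ref: float = 1.0      # ms
    tau_syn: float = 2.0    # ms

    def __post_init__(self) -> None:
        if self.V_th <= self.V_reset or self.V_th <= self.E_L:
            raise ValueError("V_th must exceed both V_reset and E_L")
        if min(self.tau_m, self.tau_syn, self.C_m) <= 0 or self.t_ref < 0:
            raise ValueError("time constants and C_m must be positive")

    @property
    def R(self) -> float:
        """Membrane resistance tau_m / C_m in GOhm (mV per pA)."""
        return self.tau_m / self.C_m

    @property
    def theta(self) -> float:
        """Threshold depolarization V_th - E_L in mV."""
        return self.V_th - self.E_L


@dataclass(frozen=True)
class STDPParams:
    """Nearest-neighbor pair STDP with soft weight bounds."""

    tau_plus: float = 20.0    # ms
    tau_minus: float = 20.0   # ms
    A_plus: float = 0.01
    A_minus: float = 0.0105
    w_min: float = 0.0        # pA
    w_max: float = 1000.0     # pA

    def __post_init__(self) -> None:
        if self.tau_plus <= 0 or self.tau_minus <= 0:
            raise ValueError("STDP time constants must be positive")
        if self.A_plus < 0 or self.A_minus < 0:
            raise ValueError("STDP amplitudes must be non-negative")
        if not self.w_max > self.w_min >= 0:
            raise ValueError("need w_max > w_min >= 0")


def stdp_delta_w(delta_t: float, w: float, params: STDPParams) -> float:
    """Weight change for a pre/post spike pair separated by delta_t ms.

    delta_t = t_post - t_pre. Positive delta_t (pre before post)
    potentiates toward w_max, negative depresses toward w_min, zero does
    nothing; the soft-bound factors guarantee w stays in [w_min, w_max].
    """
    if delta_t > 0:
        return params.A_plus * math.exp(-delta_t / params.tau_plus) * (params.w_max - w)
    if delta_t < 0:
        return -params.A_minus * math.exp(delta_t / params.tau_minus) * (w - params.w_min)
    return 0.0


# ---------------------------------------------------------------------------
# Unit PSP amplitude and calibrated weights
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def unit_psp_peak(params: LIFParams, dt: float = 0.01, horizon: float = 50.0) -> float:
    """Peak membrane deflection (mV) caused by one spike of weight 1 pA.

    Evaluated by propagating the exact linear system at fine resolution;
    used to calibrate synaptic weights in threshold units.
    """
    P, dc_row = _propagator(params, dt)
    y1, y2, h = math.e / params.tau_syn, 0.0, 0.0
    peak = 0.0
    for _ in range(int(horizon / dt)):
        y1, y2, h = (
            P[0, 0] * y1,
            P[1, 0] * y1 + P[1, 1] * y2,
            P[2, 0] * y1 + P[2, 1] * y2 + P[2, 2] * h,
        )
        peak = max(peak, h)
    return peak


def suprathreshold_weight(params: LIFParams, margin: float = 1.3) -> float:
    """Synaptic weight (pA) whose single-spike PSP is margin x threshold.

    With the default margin one presynaptic spike from rest reliably
    drives the postsynaptic neuron over threshold exactly once.
    """
    return margin * params.theta / unit_psp_peak(params)


def default_stdp_params(lif: LIFParams) -> STDPParams:
    """STDP defaults with w_max tied to the suprathreshold static weight."""
    return STDPParams(w_max=suprathreshold_weight(lif))


# ---------------------------------------------------------------------------
# Topology
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Synapse:
    pre_layer: str
    pre: int
    post_layer: str
    post: int
    weight: float          # pA (peak PSC)
    delay: float = 1.0     # ms
    kind: str = "static"   # "static" | "stdp"


@dataclass(frozen=True)
class Topology:
    """Named layers, synapses and per-layer DC preset currents.

    The first layer ("input") is a spike source driven by an
    InputSpikePattern; all other layers are LIF populations. Standard
    constructors wire input -> M1 one-to-one.
    """

    layers: tuple[tuple[str, int], ...]     # ordered (name, size)
    synapses: tuple[Synapse, ...]
    lif: LIFParams = LIFParams()
    preset_currents: tuple[tuple[str, float], ...] = ()
    monitored: tuple[str, ...] = ("M1",)

    def __post_init__(self) -> None:
        sizes = dict(self.layers)
        for syn in self.synapses:
            for layer, idx in ((syn.pre_layer, syn.pre), (syn.post_layer, syn.post)):
                if layer not in sizes:
                    raise ValueError(f"synapse references unknown layer {layer!r}")
                if not 0 <= idx < sizes[layer]:
                    raise ValueError(f"neuron {layer}[{idx}] out of range")
        for layer, _ in self.preset_currents:
            if layer not in sizes:
                raise ValueError(f"preset current on unknown layer {layer!r}")

    @property
    def layer_sizes(self) -> dict[str, int]:
        return dict(self.layers)

    def preset_current(self, layer: str) -> float:
        return dict(self.preset_currents).get(layer, 0.0)


def base_topology(lif: LIFParams | None = None, w_in: float | None = None,
                  delay: float = 1.0, n_input: int = N_INPUT_NEURONS) -> Topology:
    """Input layer wired one-to-one to an equal-sized memory layer M1."""
    lif = lif or LIFParams()
    if w_in is None:
        w_in = suprathreshold_weight(lif)
    synapses = tuple(
        Synapse("input", i, "M1", i, w_in, delay, "static") for i in range(n_input)
    )
    return Topology(
        layers=(("input", n_input), ("M1", n_input)),
        synapses=synapses, lif=lif, monitored=("M1",),
    )


def attach_preset_current(topology: Topology, layer: str, amplitude: float) -> Topology:
    """Return a copy with a constant DC of ``amplitude`` pA on ``layer``."""
    if layer not in topology.layer_sizes:
        raise ValueError(f"unknown layer {layer!r}")
    currents = dict(topology.preset_currents)
    currents[layer] = amplitude
    return replace(topology, preset_currents=tuple(sorted(currents.items())))


# ---------------------------------------------------------------------------
# Spike records
# ---------------------------------------------------------------------------

@dataclass
class SpikeRecord:
    """Ordered (layer, neuron id, time ms) events from one simulation."""

    events: list[tuple[str, int, float]]
    duration: float
    dt: float

    def spikes_of(self, layer: str) -> list[tuple[int, float]]:
        return [(nid, t) for lay, nid, t in self.events if lay == layer]

    def count(self, layer: str | None = None) -> int:
        if layer is None:
            return len(self.events)
        return sum(1 for lay, _, _ in self.events if lay == layer)

    def first_spike_times(self, layer: str, n_neurons: int) -> np.ndarray:
        """First spike time per neuron of a layer; NaN where silent."""
        first = np.full(n_neurons, np.nan)
        for nid, t in self.spikes_of(layer):
            if np.isnan(first[nid]) or t < first[nid]:
                first[nid] = t
        return first


# ---------------------------------------------------------------------------
# Propagators (exact update of the linear subsystem per step)
# ---------------------------------------------------------------------------

@lru_cache(maxsize=None)
def _propagator(params: LIFParams, dt: float) -> tuple[np.ndarray, float]:
    """(P, q): state propagator over one step and the DC response factor.

    P = expm(A*dt) for state x = (y1, y2, V - E_L); for a constant drive
    b = (0, 0, I_DC/C_m) the exact update is x' = P x + A^-1 (P - I) b,
    whose only nonzero component is q * I_DC with q in mV/pA.
    """
    ts, tm, cm = params.tau_syn, params.tau_m, params.C_m
    A = np.array([
        [-1.0 / ts, 0.0, 0.0],
        [1.0, -1.0 / ts, 0.0],
        [0.0, 1.0 / cm, -1.0 / tm],
    ])
    P = expm(A * dt)
    C = np.linalg.solve(A, P - np.eye(3))
    q = C[2, 2] / cm  # mV per pA of constant current, per step
    return P, q


# ---------------------------------------------------------------------------
# The simulator
# ---------------------------------------------------------------------------

class Network:
    """A compiled, runnable network: propagators, adjacency, buffers.

    Construction is separated from running so that repeated presentations
    (training rounds, test sweeps) do not pay the setup cost again. The
    default dynamics are fully deterministic; ``seed`` is accepted for
    interface stability but unused unless a stochastic component is added.
    """

    def __init__(self, topology: Topology, dt: float = 0.1) -> None:
        if dt <= 0:
            raise ValueError("dt must be positive")
        min_delay = min((s.delay for s in topology.synapses), default=dt)
        if dt > min_delay + 1e-12:
            raise ValueError(f"dt={dt} exceeds the minimum synaptic delay {min_delay}")
        self.topology = topology
        self.dt = dt
        self.params = topology.lif

        layers = topology.layers
        if layers[0][0] != "input":
            raise ValueError("first layer must be the 'input' spike source")
        self.layer_names = [name for name, _ in layers]
        self.layer_sizes = dict(layers)
        self.n_input = layers[0][1]

        # global neuron indexing: input first, then LIF layers contiguously
        self.global_offset: dict[str, int] = {}
        off = 0
        for name, size in layers:
            self.global_offset[name] = off
            off += size
        self.n_global = off
        self.n_lif = off - self.n_input

        # reverse map: LIF index -> (layer, local id)
        self.lif_layer_of = np.empty(self.n_lif, dtype=object)
        self.lif_local_id = np.empty(self.n_lif, dtype=np.int64)
        for name, size in layers[1:]:
            base = self.global_offset[name] - self.n_input
            self.lif_layer_of[base:base + size] = name
            self.lif_local_id[base:base + size] = np.arange(size)

        # synapse arrays
        syns = topology.synapses
        self.n_syn = len(syns)
        self.syn_pre_global = np.array(
            [self.global_offset[s.pre_layer] + s.pre for s in syns], dtype=np.int64
        )
        self.syn_post_lif = np.array(
            [self.global_offset[s.post_layer] + s.post - self.n_input for s in syns],
            dtype=np.int64,
        )
        if self.n_syn and self.syn_post_lif.min() < 0:
            raise ValueError("input-layer neurons cannot be postsynaptic")
        self.syn_delay_steps = np.array(
            [max(1, int(round(s.delay / dt))) for s in syns], dtype=np.int64
        )
        self.syn_plastic = np.array([s.kind == "stdp" for s in syns], dtype=bool)
        self.w0 = np.array([s.weight for s in syns], dtype=float)

        # outgoing synapse lists per global neuron
        self.out_syn: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(self.n_global)
        ]
        order = np.argsort(self.syn_pre_global, kind="stable")
        for g, grp in _groupby_sorted(self.syn_pre_global, order):
            self.out_syn[g] = grp
        # incoming *plastic* synapses per LIF neuron (for STDP on post spikes)
        self.in_plastic: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(self.n_lif)
        ]
        plastic_idx = np.flatnonzero(self.syn_plastic)
        order = np.argsort(self.syn_post_lif[plastic_idx], kind="stable")
        for p, grp in _groupby_sorted(self.syn_post_lif[plastic_idx], order):
            self.in_plastic[p] = plastic_idx[grp]

        self.P, self.q_dc = _propagator(self.params, dt)
        self.ref_steps = int(round(self.params.t_ref / dt))
        self.i_dc = np.zeros(self.n_lif)
        for name, size in layers[1:]:
            amp = topology.preset_current(name)
            if amp:
                base = self.global_offset[name] - self.n_input
                self.i_dc[base:base + size] = amp
        self.kick = math.e / self.params.tau_syn  # y1 increment per unit weight

    def run(self, pattern: "InputSpikePattern | np.ndarray | None", duration: float,
            plastic: bool = False, weights: np.ndarray | None = None,
            stdp: STDPParams | None = None, seed: int | None = None,
            ) -> tuple[SpikeRecord, np.ndarray]:
        """Simulate for ``duration`` ms; return the spike record and weights.

        ``pattern`` may be an InputSpikePattern or a plain array of spike
        times (ms; NaN = silent), one entry per input neuron. ``weights``
        overrides the topology's synaptic weights (e.g. to carry plastic
        weights across presentations); the returned array holds the final
        weights (identical to the input when static).
        """
        dt = self.dt
        n_steps = int(round(duration / dt))
        if abs(n_steps * dt - duration) > 1e-9:
            raise ValueError("dt must divide duration")
        if plastic and stdp is None:
            stdp = default_stdp_params(self.params)

        w = self.w0.copy() if weights is None else np.asarray(weights, float).copy()
        if w.shape != (self.n_syn,):
            raise ValueError("weights length must match the synapse count")

        # input spike schedule: step -> array of spiking input neuron ids
        input_steps: dict[int, np.ndarray] = {}
        if pattern is not None:
            times = pattern if isinstance(pattern, np.ndarray) else pattern.times
            if times.shape[0] != self.n_input:
                raise ValueError("pattern size does not match the input layer")
            ids = np.flatnonzero(np.isfinite(times))
            steps = np.round(times[ids] / dt).astype(np.int64)
            for s in np.unique(steps):
                input_steps[int(s)] = ids[steps == s]

        max_delay = int(self.syn_delay_steps.max()) if self.n_syn else 1
        L = max_delay + 2
        buf = np.zeros((L, self.n_lif))

        y1 = np.zeros(self.n_lif)
        y2 = np.zeros(self.n_lif)
        h = np.zeros(self.n_lif)  # V - E_L
        ref = np.zeros(self.n_lif, dtype=np.int64)
        theta = self.params.theta
        h_reset = self.params.V_reset - self.params.E_L
        dc_step = self.q_dc * self.i_dc

        last_spike = np.full(self.n_global, -np.inf)  # emission times, ms
        p00, p10, p11 = self.P[0, 0], self.P[1, 0], self.P[1, 1]
        p20, p21, p22 = self.P[2, 0], self.P[2, 1], self.P[2, 2]

        events: list[tuple[str, int, float]] = []

        for step in range(n_steps):
            # deliveries scheduled for this step enter y1 before propagation
            row = step % L
            y1 += buf[row]
            buf[row] = 0.0

            y1_old = y1
            y1 = p00 * y1_old
            y2_new = p10 * y1_old + p11 * y2
            h = p20 * y1_old + p21 * y2 + p22 * h + dc_step
            y2 = y2_new

            refractory = ref > 0
            if refractory.any():
                h[refractory] = h_reset
                ref[refractory] -= 1

            crossed = (h > theta) & ~refractory
            t_now = (step + 1) * dt
            spiking_global: list[int] = []

            if crossed.any():
                idx = np.flatnonzero(crossed)
                h[idx] = h_reset
                ref[idx] = self.ref_steps
                for k in idx:
                    layer = self.lif_layer_of[k]
                    events.append((layer, int(self.lif_local_id[k]), t_now))
                    spiking_global.append(int(k) + self.n_input)

            if step in input_steps:
                t_in = step * dt  # the encoded (grid-aligned) emission time
                for nid in input_steps[step]:
                    events.append(("input", int(nid), float(t_in)))
                    spiking_global.append(int(nid))

            if not spiking_global:
                continue

            if plastic:
                # nearest-neighbor pair rule on emission times; all updates
                # in one step use the pre-step last-spike tables
                for g in spiking_global:
                    t_g = step * dt if g < self.n_input else t_now
                    for s in self.out_syn[g]:
                        if not self.syn_plastic[s]:
                            continue
                        t_post = last_spike[self.syn_post_lif[s] + self.n_input]
                        if np.isfinite(t_post):
                            w[s] += stdp_delta_w(t_post - t_g, w[s], stdp)
                    if g >= self.n_input:
                        for s in self.in_plastic[g - self.n_input]:
                            t_pre = last_spike[self.syn_pre_global[s]]
                            if np.isfinite(t_pre):
                                w[s] += stdp_delta_w(t_g - t_pre, w[s], stdp)
                np.clip(w, stdp.w_min, stdp.w_max, out=w)

            # schedule deliveries with post-update weights, then refresh
            # the last-spike tables
            for g in spiking_global:
                for s in self.out_syn[g]:
                    arrival = (step + self.syn_delay_steps[s] + 1) % L
                    buf[arrival, self.syn_post_lif[s]] += w[s] * self.kick
                last_spike[g] = step * dt if g < self.n_input else t_now

        events.sort(key=lambda e: (e[2], e[0], e[1]))
        return SpikeRecord(events, duration, dt), w


def _groupby_sorted(values: np.ndarray, order: np.ndarray):
    """Yield (value, indices) groups given a stable argsort of values."""
    if len(order) == 0:
        return
    sorted_vals = values[order]
    boundaries = np.flatnonzero(np.diff(sorted_vals)) + 1
    for grp in np.split(order, boundaries):
        yield int(values[grp[0]]), grp


def simulate(topology: Topology, pattern: "InputSpikePattern | np.ndarray | None",
             duration: float, dt: float = 0.1, plastic: bool = False,
             weights: np.ndarray | None = None, stdp: STDPParams | None = None,
             seed: int | None = None) -> tuple[SpikeRecord, np.ndarray]:
    """One-shot simulation of ``topology`` driven by ``pattern``.

    Returns the spike record of all layers and the final weight table
    (aligned with ``topology.synapses``). See ``Network.run``.
    """
    return Network(topology, dt).run(pattern, duration, plastic=plastic,
                                     weights=weights, stdp=stdp, seed=seed)


# ---------------------------------------------------------------------------
# Rheobase
# ---------------------------------------------------------------------------

def dc_first_spike_times(params: LIFParams, amplitudes: np.ndarray,
                         t_max: float = 1000.0, dt: float = 0.1) -> np.ndarray:
    """First spike time under constant DC for each amplitude; NaN if silent.

    Uses the same exact per-step propagator as the full simulator with no
    synaptic input (y1 = y2 = 0), so it is the simulator restricted to an
    isolated DC-driven neuron, vectorized over amplitudes.
    """
    amplitudes = np.asarray(amplitudes, dtype=float)
    P, q = _propagator(params, dt)
    p22 = P[2, 2]
    h = np.zeros_like(amplitudes)
    first = np.full_like(amplitudes, np.nan)
    theta = params.theta
    dc = q * amplitudes
    n_steps = int(round(t_max / dt))
    for step in range(n_steps):
        h = p22 * h + dc
        crossed = (h > theta) & np.isnan(first)
        if crossed.any():
            first[crossed] = (step + 1) * dt
            if not np.isnan(first).any():
                break
    return first


def rheobase(params: LIFParams | None = None, step_pA: float = 1.0,
             t_max: float = 1000.0, dt: float = 0.1) -> float:
    """Smallest DC amplitude on the step_pA grid that elicits a spike.

    A single isolated neuron is driven for ``t_max`` ms at each grid
    amplitude; the smallest amplitude with at least one spike is returned.
    The analytic steady state is V_inf = E_L + I * tau_m / C_m, so the
    exact bound is I = C_m * theta / tau_m (375 pA with defaults), reached
    only asymptotically — the returned value is the smallest grid point
    strictly above it (376 pA with defaults and a 1 pA grid).
    """
    if step_pA <= 0:
        raise ValueError("step_pA must be positive")
    params = params or LIFParams()
    bound = params.C_m * params.theta / params.tau_m
    hi = max(2.0 * bound, 10.0 * step_pA)
    while True:
        grid = np.arange(step_pA, hi + step_pA / 2, step_pA)
        spiked = np.isfinite(dc_first_spike_times(params, grid, t_max, dt))
        if spiked.any():
            return float(grid[np.argmax(spiked)])
        hi *= 2.0
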