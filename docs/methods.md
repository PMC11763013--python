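# Methods

This note documents the models, the numerical choices and the design
decisions behind `pairslice`, in the order the pipeline runs.

## Image front-end and latency code

Images are 28×28 8-bit grayscale grids. Four fixed 5×5 oriented line
detectors (0°, 45°, 90°, 135°; a +4 ridge along the orientation, −1
elsewhere, so every kernel sums to zero) are applied in valid mode
(28→24 per axis), responses are rectified and 2×2 max-pooled with stride
2 (24→12), and each 12×12 block is divided by its own maximum so every
orientation channel uses the full value range (an all-zero block stays
zero). The zero-DC kernels make the front-end exactly invariant to
constant intensity offsets. The kernels are shipped constants, not
learned: reproducibility is worth more here than a tuned front-end.

Feature values v ∈ [0, 1] become first-spike latencies through

    T(v) = T_start + (2·0.5^v − 1)·(T_stop − T_start).

This is the affinely rescaled form of an exponential latency map: it
preserves the exponential shape, maps v = 1 to T_start and v → 0 to
T_stop, and is strictly decreasing — the rank order of spikes is the
reverse rank order of feature values, which is the defining property of a
rank-order code (important information travels first). The unshifted
variant (0.5^v − 1)·ΔT + T_start, which places v > 0 before T_start, is
kept behind a `raw_formula` flag for inspection only. Features below
v_min = 0.05 emit no spike; zero regions of an image therefore stay
silent. The flattening convention is fixed: input-neuron id =
block·144 + row·12 + col.

Defaults: encoding window 100 ms, simulation window 120 ms (encoding plus
20 ms of headroom so delayed and slow-rising responses stay inside the
record).

## Neuron and synapse model

Neurons are leaky integrate-and-fire with current-based alpha synapses:

    dy1/dt = −y1/τ_syn
    dy2/dt = y1 − y2/τ_syn
    dV/dt  = −(V − E_L)/τ_m + (y2 + I_DC)/C_m

A presynaptic spike of weight w (pA) adds w·e/τ_syn to y1 after its
delay, so the post-synaptic current y2 peaks at exactly w one τ_syn
later. Defaults: C_m = 250 pF, τ_m = 10 ms, E_L = V_reset = −70 mV,
V_th = −55 mV, τ_syn = 2 ms, refractory period 1 ms, synaptic delay
1 ms, dt = 0.1 ms. These are the conventional defaults of this neuron
model; they are also the only parameter set consistent with the 376 pA
firing threshold the package reproduces (see below).

Integration is clock-driven with the exact matrix-exponential propagator
of the linear (y1, y2, V) subsystem per step, so sub-threshold
trajectories carry no discretization error on the grid; only threshold
crossings are resolved at dt. Crossing, reset and refractory clamping are
handled per step: V is clamped at V_reset for the refractory period while
synaptic state keeps evolving. Within one step all threshold crossings
are processed first, then all plasticity updates using the pre-step
last-spike tables (order-independent within a step), then deliveries are
scheduled with the post-update weights.

**Threshold convention.** A spike requires V strictly above V_th. At the
analytic rheobase I = C_m·(V_th−E_L)/τ_m = 375 pA the membrane converges
to V_th from below and, in float64, rounds to exactly V_th within a
1000 ms run; a ≥ test would therefore fire at 375 pA. With the strict
test the smallest spiking amplitude on a 1 pA grid is 376 pA, the value
the package treats as its reference point. `rheobase()` performs the grid
search with the same propagator the full simulator uses, vectorized over
amplitudes.

**Verification.** The simulator is checked against (a) the closed-form
DC inter-spike interval t_ref + τ_m·ln((IR − (V_reset−E_L))/(IR −
(V_th−E_L))) to 2 %, (b) spike-time stability under dt halving, and (c)
an independent forward-Euler integrator at 1 µs resolution on a
microcircuit, to 0.1 ms per spike.

## STDP

Plastic synapses follow a nearest-neighbor pair rule with soft bounds:

    Δw = +A₊ · exp(−Δt/τ₊) · (w_max − w)   for Δt = t_post − t_pre > 0
    Δw = −A₋ · exp(+Δt/τ₋) · (w − w_min)   for Δt < 0,   Δw = 0 at Δt = 0

with τ₊ = τ₋ = 20 ms, A₊ = 0.01, A₋ = 0.0105, w_min = 0. w_max is tied
to the calibrated static weight (next paragraph), so a fully potentiated
pair synapse is as strong as an input synapse. Updates use emission
times; the soft-bound factors keep every trajectory inside
[w_min, w_max] at all times.

**Weight calibration.** The peak membrane deflection per pA of synaptic
weight is computed numerically from the exact propagator
(`unit_psp_peak`). The standard static weight is 1.3× the weight whose
single-spike PSP just reaches threshold: one presynaptic spike from rest
then reliably produces exactly one postsynaptic spike (the refractory
period absorbs the PSP tail). The input→M1 one-to-one synapses use this
weight, so M1 mirrors the input timing — which pair formation relies on.

## Pair formation, refinement, topology

**Formation.** For each class, ordered pairs (Ni, Nj) with Nj in the
Chebyshev ball of radius S_thre around Ni *within the same orientation
block* (cross-block adjacency is undefined — the blocks are parallel
channels) are counted over presentations: a presentation contributes 1
when 0 < T(Nj) − T(Ni) ≤ T_thre on first spikes (the latency code emits
essentially one spike per neuron). Pairs reaching C_thre presentations
become candidates. The implementation is vectorized but exactly
equivalent to the nested-loop enumeration it is tested against.

Defaults: S_thre = 1, T_thre = 10 ms, C_thre = 35 % of a class's
presentations. The time window and consistency fraction were calibrated
on the glyph generator's conditions: ±2 px positional jitter caps the
co-firing consistency of any fixed spatial pair near 40–50 %, and a
10 ms window corresponds to a feature-value gap of roughly 0.1 —
neighboring cells along one stroke. Under these defaults a 4-class run
produces ~50–100 candidates, the regime in which the pair mechanism is
informative; tighter settings produce none at all.

**Refinement.** All candidate pairs (union across classes) receive
plastic synapses at w_init = 0.1·w_max in one network; each class's
images are presented in turn with STDP on (weights carried across
presentations within a round, reset between rounds), and the final
weight of every pair is recorded per class. The low w_init maximizes the
dynamic range of potentiation, which is what the selection rule reads
out. The process is unsupervised — labels only group the rounds; an
isolated-per-class variant is available via `union_network=False`.

Selection: a pair is kept for its argmax class iff that weight is at
least `dominance_ratio` (default 1.2) times the runner-up; a pair whose
best weight is 0 is removed as carrying no evidence (the formal
0 ≥ ratio·0 would admit it). Among survivors sharing a post neuron only
the largest-weight pair survives; ties go to the lowest pre id so builds
are deterministic.

**Topology.** Learned weights transfer to static testing weights by
proportional rescaling w_static = w_max·w/max(w) (keeps zero at zero,
deterministic). The 2-layer network adds one static pre→post synapse per
pair inside M1 and monitors M1. The 3-layer network adds one dedicated
M2 neuron per pair, fed by both pair members, and monitors M1 and M2;
M2 neurons act as coincidence detectors whose excitability the preset
currents modulate. When a degenerate (tiny) run refines away every
candidate, the experiment driver falls back to the bare one-to-one
network so the run still completes.

## Time slicing and classification

The [0, T_sim) window splits into n equal half-open slices
[T_i, T_{i+1}); a spike exactly on an internal boundary belongs to the
later slice. A sample's slice map is the set of neurons with ≥1 spike in
the slice (multiple spikes collapse). For the 3-layer network, maps are
taken over the union of M1 and M2 in a shared integer namespace (M2 ids
offset by 100 000); an M1-only or M2-only view is a parameter.

A class expression keeps, per slice, the neurons active in at least a
fraction θ of the class's training samples — the threshold is inclusive
(≥), which matters when sweeping the printed values 0.2/0.4/0.5. θ = 0
gives slice-wise unions; θ larger can only shrink the maps (monotonicity,
property-tested).

Classification minimizes the summed per-slice Jaccard distance. The 0/0
slice term (both sets empty) is defined as distance 0 — identical
silence is maximal agreement; if exactly one side is empty the term is
1. Per slice the distance is a true metric; across slices it is
additive, so refining a slicing scheme can only sharpen, never blur, the
dissimilarity between classes. Ties in the argmin go to the lowest class
id, which also pins the fully-deleted-input case to exact chance
accuracy.

## Synthetic glyph generator

Ten fixed stroke templates (ring, vertical bar, cross, diagonal,
L-shape, T-shape, S-curve, dot grid, chevron, H-shape) are rasterized at
intensity 255, translated by an integer offset uniform in ±jitter_px per
axis, and perturbed with Gaussian intensity noise (sd `noise_sd`) on
stroke pixels only, clipped to [0, 255]. Background pixels stay exactly
zero: that keeps the nonzero-pixel fraction in the sparse band typical
of handwritten digits (5–40 %) and gives the deletion-noise experiment
("set a fraction of the nonzero pixels to zero") a well-defined target.
Defaults: jitter_px = 2, noise_sd = 8 — positional uncertainty of the
order of a stroke width and ~3 % intensity noise, a plausible stand-in
for handwriting variability.

What the generator does *not* emulate: shape deformation (all variation
is rigid translation plus intensity noise), stroke-thickness variation,
class overlap (the templates are well separated by construction), and
class imbalance. Passing the end-to-end tests therefore shows the
pipeline recovers well-separated, rigidly-jittered classes — not that it
reaches any particular accuracy on handwritten digits.

Deletion noise zeroes exactly round(ratio·n_nonzero) nonzero pixels
(banker's rounding, documented so counts are exactly testable), chosen
uniformly without replacement, before pre-processing.

## Experiment driver and problem sizes

`ExperimentConfig` carries every knob; all randomness flows from its
single seed (the simulation itself is deterministic). Results are
written as CSV with fixed float formatting, so identical configs produce
byte-identical files. Preset currents are applied at test time only by
default (whether the original experiments applied them during memory
formation as well is not stated; the alternative is one config change).
Pair-count sweeps cap the refined set to the top-k pairs by weight.

The shipped test and example configuration uses 4 classes with 50
training and 20 test images per class — about 1 300 network simulations
per fitted pipeline, a deliberate desk-scale choice that keeps a full
pipeline fit around ten seconds on one core. Larger runs (10 classes ×
200 samples) use the same code paths and scale linearly.

## Known limitations

- Clock-driven integration resolves threshold crossings at dt; event
  timestamps are grid-aligned, not interpolated.
- The pair-formation thresholds are calibrated to the glyph generator's
  jitter regime; heavily different input statistics (e.g. uncentered
  data) need re-calibration of T_thre/C_thre.
- STDP constants are conventional values, not fitted; only their
  qualitative regime (potentiation-dominant readout, depression slightly
  stronger than potentiation) matters for refinement.
- The 3-layer network's accuracy depends on M2 excitability; without
  preset currents weak pairs may never lift their M2 neuron over
  threshold, which is precisely the effect the preset-current experiment
  measures.
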