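# pairslice

Structural learning and time-sliced decoding for spiking neural networks.

`pairslice` is a self-contained research pipeline for studying how a small
spiking neural network (SNN) can *store* the spatio-temporal structure of
images in its topology and how that stored structure can be *read back out*
in an interpretable way. It is aimed at computational-neuroscience and
neuromorphic-computing work where one wants full control over every stage:
encoding, simulation, plasticity and decoding are all plain, inspectable
Python.

The pipeline has four stages:

1. **Latency encoding.** A 28×28 grayscale image is filtered by four
   oriented 5×5 edge detectors and 2×2 max-pooled into four 12×12 feature
   blocks (576 values in [0, 1]). Each feature value *v* becomes one
   first-spike latency under an exponential rank-order code,

       T(v) = T_start + (2·0.5^v − 1)·(T_stop − T_start),

   so stronger features fire earlier and the *order* of spikes carries the
   image content. Sub-threshold features (v < 0.05) stay silent.

2. **LIF simulation.** Neurons are leaky integrate-and-fire units with
   alpha-shaped post-synaptic currents (C_m = 250 pF, τ_m = 10 ms,
   V_th − E_L = 15 mV, τ_syn = 2 ms, 1 ms refractory period). The input
   layer projects one-to-one onto a 576-neuron memory layer M1.
   Integration is clock-driven with an exact propagator for the linear
   subsystem; the firing threshold for constant current (rheobase) is
   376 pA on a 1 pA grid, matching the closed form C_m·(V_th−E_L)/τ_m =
   375 pA reached only asymptotically.

3. **Structural learning.** Ordered neuron pairs that reliably co-fire
   within a time window (Hebbian "fire together, wire together") become
   candidates; spike-timing-dependent plasticity (STDP) trains one plastic
   synapse per candidate, one class at a time, and a dominance rule keeps
   each pair for the class whose training potentiated it most. Refined
   pairs are wired in with static synapses — inside M1 (2-layer network)
   or each onto a dedicated coincidence-detector neuron in a second memory
   layer M2 (3-layer network).

4. **Time-sliced decoding.** The simulation window is split into *n* equal
   slices; each sample collapses into *n* active-neuron sets. Aggregating
   a class's training samples and keeping neurons active in at least a
   fraction θ of them yields the class *expression*. A test sample is
   classified by the summed per-slice Jaccard distance

       δ(N_k, N′) = Σᵢ [ 1 − |M_ki ∩ M_i′| / |M_ki ∪ M_i′| ],

   taking the minimum-distance class.

A built-in synthetic glyph generator (ten fixed stroke templates with
positional jitter and stroke noise) makes the whole pipeline runnable and
testable offline; the MNIST IDX format is supported as an optional input.

## Worked example

Four glyph classes, 50 training and 20 test images per class, comparing a
single time slice against four slices:

```python
from pairslice import ExperimentConfig, run_pipeline

cfg = ExperimentConfig(classes=4, n_train_per_class=50, n_test_per_class=20,
                       slice_counts=(1, 4), freq_thresholds=(0.2,), seed=1)
table = run_pipeline(cfg)
print(table[["n_layers", "n_slices", "freq_threshold", "n_pairs",
             "accuracy", "mean_distance_margin"]].to_string(index=False))
```

prints

```
 n_layers  n_slices  freq_threshold  n_pairs  accuracy  mean_distance_margin
        2         1             0.2       55       1.0              0.229319
        2         4             0.2       55       1.0              0.572593
```

Reading the numbers: structural learning kept 55 refined neuron pairs; both
slicing schemes classify the 80 test glyphs perfectly, but with four slices
the mean margin between the best and second-best class distance is 2.5×
larger — the time-sliced expression separates the classes far more
decisively, which is the property that carries over to harder, noisier
data.

The same sweeps are available from the shell:

```sh
pairslice rheobase                       # -> 376
pairslice run -c config.yaml --figures
pairslice sweep --slices 2,3,4,6 --thresholds 0.2,0.4,0.5
pairslice noise --ratios 0,0.2,0.5,1.0
pairslice currents --currents 0:0,100:0,0:300
```

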