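# gridcan

A continuous attractor network (CAN) laboratory for grid cells: how does
the hexagonal spatial code survive biological heterogeneity, and does
intrinsic neuronal resonance protect it?

Grid cells in medial entorhinal cortex fire on the vertices of a
triangular lattice tiling the environment.  The standard rate-based CAN
model explains this with a toroidal sheet of neurons coupled by
center-shifted Mexican-hat (difference-of-Gaussians) inhibition: the sheet
settles into a triangular pattern of activity bumps, velocity input
translates the pattern, and each neuron's time-averaged activity over the
arena becomes a hexagonal rate map.  That textbook model is perfectly
homogeneous.  `gridcan` makes it biological: per-neuron integration time
constants τ, per-neuron velocity gains α, and per-synapse weight jitter are
drawn from progressively wider distributions (degrees 1–5), and two
resonator neuron models replace the leaky integrator —

* a **phenomenological resonator**, S = R·u·|du/dt|^ε, the integrator
  composed with a fractional-order high-pass stage, resonating at
  f_R = √ε/(2πτ) ≈ 8.7 Hz for the defaults (τ = 10 ms, ε = 0.3);
* a **mechanistic resonator**, τ dS/dt = −S − g·m + f(·), where a slow
  sigmoidal negative-feedback variable m (time constant τ_m = 75 ms)
  suppresses low-frequency activity the way resonating conductances do.

The analysis suite quantifies the consequences: occupancy-normalized rate
maps, autocorrelogram grid scores, field size/count/spacing, Skaggs
information rate, sparsity, and the spectral fingerprint of heterogeneity
(normalized spectral differences between heterogeneous networks and their
homogeneous twins, their across-neuron variance, and octave-band AUCs).

Who it is for: computational neuroscientists studying attractor models,
robustness to parameter dispersion, or adaptation/resonance mechanisms —
anyone who wants a seedable, testable CAN sandbox rather than a one-off
script.

## Worked example

```python
import numpy as np
from gridcan import *
from gridcan.gridmetrics import metrics_for_neurons, percent_change

arena = Arena()                                   # 2 m circle
traj  = generate_virtual_trajectory(arena, duration=30.0, seed=11)
spec  = NetworkSpec(n=60)                         # 3600 neurons, lambda=13
W     = build_weight_matrix(spec)

homo = apply_heterogeneities(spec, W, HeterogeneitySpec(degree=0))
het  = apply_heterogeneities(spec, W, HeterogeneitySpec(degree=5, seed=101))

cfg = SimulationConfig(init_seed=7)
trace_h = simulate(spec, homo, traj, NeuronModel(), cfg)
trace_5 = simulate(spec, het,  traj, NeuronModel(), cfg)

idx = np.linspace(0, 3599, 24).astype(int)        # sampled neurons
m_h = metrics_for_neurons(trace_h, traj, idx, arena=arena)
m_5 = metrics_for_neurons(trace_5, traj, idx, arena=arena)
pc  = percent_change(m_5["grid_score"], m_h["grid_score"])
print(f"homogeneous median grid score : {np.median(m_h['grid_score']):+.2f}")
print(f"degree-5     median grid score: {np.median(m_5['grid_score']):+.2f}")
print(f"median percent change         : {np.nanmedian(pc):+.0f}%")
```

Output (one CPU, ~3 min):

```
homogeneous median grid score : +0.38
degree-5     median grid score: -0.07
median percent change         : -120%
```

A median grid score of +0.38 with most neurons above +0.3 is a healthy
hexagonal code; combined degree-5 heterogeneities drive the per-neuron
score change to −120% — the grid code collapses.  Running the same pair
with `NeuronModel(kind="mechanistic")` (slow negative feedback, g = 0.1)
softens the collapse to ≈ −98%, and the protection strengthens
monotonically as the feedback slows from τ_m = 15 ms to 75 ms.

Single neurons are probed with a 0–100 Hz chirp:

```bash
gridcan chirp --model phenomenological
# fR = 8.90 Hz (strength 1.35)
gridcan chirp --model mechanistic --g 0.8 --param-sweep tau_m=0.005,0.015,0.075,0.3
```

Other entry points: `gridcan trajectory|simulate|metrics|spectra|experiment`
(see `--help`); `gridcan experiment --list` names the preset experiment
families (heterogeneity sweeps per kind, resonator rescue, τ/ε/τ_m sweeps,
network-size sweep).

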