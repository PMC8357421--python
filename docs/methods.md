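# Model and methods

`gridcan` simulates a rate-based two-dimensional continuous attractor network
(CAN) of the kind used to model grid cells in medial entorhinal cortex, and
asks how the emergent spatial code survives biological heterogeneity — and
whether intrinsic neuronal resonance protects it.

## The network

Neurons sit on an `n x n` lattice with periodic boundaries (default
`n = 60`).  Each neuron has a preferred direction θ ∈ {0°, 90°, 180°, 270°},
tiled in 2×2 blocks so each direction owns a quarter of the sheet.  The
recurrent weight from neuron j to neuron i is a difference of Gaussians
evaluated at the toroidal displacement, shifted by `l = 2` lattice units
along j's preferred direction:

    W_ij = a·exp(−γ|x_i − x_j − l·ê_j|²) − exp(−β|x_i − x_j − l·ê_j|²)

with β = 3/λ², γ = 1.1β, lattice period λ = 13, and a = 1 so that every
weight is inhibitory.  Each neuron also receives a feed-forward drive

    B_i = 1 + α·(ê_i · v)

where v is the animal's displacement per integration step (meters/step) and
α = 45.  Euler integration of

    τ dS_i/dt = −S_i + f(Σ_j W_ij S_j + B_i),    f(x) = max(x, 0)

with τ = 10 ms and dt = 1 ms produces a triangular lattice of activity bumps
that translates with the animal's velocity; each neuron's time-averaged
activity over the arena is then a hexagonal grid map.

Velocity units: v must be per-step displacement.  With α = 45 and steps
≤ 4 mm the drive modulation |α ê·v| ≤ 0.18 stays perturbative; interpreting
v in m/s drives the network far outside its operating point and destroys the
pattern (verified numerically).  The measured pattern-flow gain is ≈ 20
lattice units per meter, giving a grid spacing of ≈ 0.75–0.95 m in a 2 m
arena.

Lattice size matters: the torus must accommodate a near-integer number of
bump periods (the natural period is ≈ 15 lattice units at λ = 13).  At
`n = 60` the pattern is commensurate and path integration is reliable; at
`n = 40` or 56 the frustrated pattern slips under drive and no neuron
develops a coherent grid.  Network-level analyses therefore run at the
60×60 size.  `n = 52 = 4·13` is commensurate but locks into a square
lattice, which scores at or below zero by construction.

## Virtual trajectory

The virtual animal starts at the arena center, and each 1 ms step draws a
step length d ~ U[0, 4 mm] and a heading deviation ~ U[−5°, +5°] added to a
persistent heading (x advances with sin, y with cos of the heading).  Within
2 cm of the wall the absolute heading is redrawn from U[0, 2π], producing
sharp wall turns.  Out-of-arena candidates are redrawn.  The persistent
heading is an interpretational choice: a literal absolute heading confined
to ±5° of north cannot cover the arena.  The resulting path moves at ~2 m/s
— roughly ten times faster than a real rat — and covers most of the arena
within tens of seconds, which is the point: rate maps of useful quality in
a fraction of the recording time.

## Heterogeneities

Three forms, at integer degrees 1–5, all sampled from uniform distributions
that widen with degree:

| degree | τ (ms)   | α        | weight jitter span (κ·raw) |
|--------|----------|----------|-----------------------------|
| 1      | 8–12     | 35–55    | ±0.0015                     |
| 3      | 4–16     | 15–75    | ±0.0045                     |
| 5      | 1–20     | 0–100    | ±0.0075                     |

τ and α are drawn per neuron; the weight jitter is drawn independently per
synapse, zero-mean, with the raw tabulated bounds (300…1500) scaled by
κ = 1e-5.  Two constraints pin this interpretation: a *positive-mean*
jitter accumulates over the N² synapses of a row and flips the net
recurrence excitatory (runaway activity even at degree 1 for n = 60), and a
span much larger than a few percent of the peak weight magnitude (≈ 0.035)
destroys grids already at degree 1, contradicting the graded disruption
that defines the degrees.  With κ = 1e-5 the synaptic-only disruption is
graded (median grid-score change ≈ −15%, −60%, −81% at degrees 1/3/5) and
synaptic remains the most disruptive form, ahead of afferent and intrinsic.

## Resonator neurons

**Phenomenological** — the integrator state u is passed through a
fractional-order high-pass stage; the activity the rest of the network sees
(and all analyses consume) is

    S = R · u · |du/dt|^ε,   ε = 0.3.

The chirp-response envelope is ∝ ω^ε (1 + ω²τ²)^−(1+ε)/2, maximized at
ωτ = √ε, i.e. f_R = √ε/(2πτ) ≈ 8.7 Hz at defaults — theta-band resonance.
The derivative is the per-step backward difference; its magnitude is used
because fractional powers of negative numbers are undefined (a rectified
variant is available).  The output scale R matters greatly in the network:
chirp-magnitude matching (R ≈ 0.36) or exact mean-rate matching (R ≈ 0.53)
both weaken the recurrence into a regime where the bump attractor degrades;
the default R = 0.7 preserves homogeneous grid patterns while keeping mean
rates within ~8% of the integrator network's.

**Mechanistic** — a slow activity-dependent negative feedback:

    τ dS/dt = −S − g·m + f(·),    τ_m dm/dt = m∞(S) − m,
    m∞(S) = 1 / (1 + exp((S_half − S)/k)),

with k = 0.1, S_half = 0.3, τ_m = 75 ms.  Resonance requires the feedback
to be slow (τ_m > τ) and *strong enough to matter*: the maximal
low-frequency suppression is g·max(m∞′) = g/(4k).  A feedback strength of
0.015 (2.5% suppression ceiling) produces no measurable resonance, no sag,
and no network-level protection; theta-band single-neuron resonance needs
g ≈ 0.8.  In the network, however, g ≥ 0.15 makes the adaptation strong
enough to set bumps traveling on their own, which decoheres path
integration.  The default is g = 0.1 — the strongest feedback that leaves
homogeneous grids intact — and single-neuron resonance characterization
(tuning curves) uses g ≈ 0.8 with a small probe amplitude, where the
band-pass peak is measurable.  Both regimes are documented because no
single value reproduces the full phenomenology at once.

Single-neuron frequency-response probes of the mechanistic model use a
chirp of amplitude 0.2 (below S_half): at unit amplitude the activity
sweeps across the entire sigmoid and the feedback acts as a comparator,
flattening or inverting the tuning trends in k and S_half.

## Resonance-frequency estimation

The general estimator (`resonance_frequency`) is the argmax of the smoothed
single-sided FFT magnitude, as is standard.  For chirp responses this
estimator carries two systematic errors: Fresnel edge ripple dents the
lowest ~1 Hz (so even a pure low-pass response shows a spurious interior
peak), and for the fractional-derivative output the harmonics of |du/dt|^ε
leak power upward, biasing the argmax by up to ~15%.  The chirp-specific
estimator (`chirp_resonance_frequency`) therefore averages |response| over
*exact* chirp half-cycles (boundaries t_k = √(kT/f_max) are analytic),
smooths lightly across neighboring half-cycles, and localizes the peak by a
log-log parabolic fit within an octave of the argmax.  This estimator
matches the closed-form envelope optimum within max(0.5 Hz, 10%) across
τ ∈ {5…20} ms × ε ∈ {0.1…0.5}, at both dt = 1 ms and dt = 0.1 ms.  A
profile whose peak exceeds the low-frequency magnitude by less than 10%
(`resonance_strength < 1.1`) is classified low-pass, f_R := 0.

## Grid metrics

Rate maps divide the arena into 100×100 pixels; the rate is mean activity
per visit, smoothed with a σ = 2 px Gaussian whose weights are renormalized
over visited pixels.  Runs shorter than full coverage leave unvisited
holes; the smoother interpolates those from their neighborhoods over the
whole in-arena support so that field detection and rotation comparisons see
contiguous maps (information rate, sparsity and occupancy always use raw
visited pixels only).

The grid score is min(SAC60, SAC120) − max(SAC30, SAC90, SAC150), where
SAC_φ correlates the map's masked spatial **autocorrelogram** with its
rotation by φ about the (centered) origin.  Correlating the raw map with
its own rotation about the arena center — the naive reading — is sensitive
to where the firing lattice happens to sit: a perfect hexagonal map scores
≈ +1 only if a field lies at the arena center and ≈ −0.4 otherwise
(verified on synthetic lattices), which would make population summaries
meaningless.  The autocorrelogram is translation-invariant, so the score
measures lattice geometry alone: synthetic triangular lattices score
+0.5…+1.2 regardless of phase, square lattices ≈ −0.9.

Firing fields are connected regions around local maxima of the smoothed
map holding ≥ 20% of the peak, with contested pixels assigned to the
nearest peak and maxima below 0.1 a.u. discarded.  Field spacing defaults
to the mean over all pairwise peak distances (a literal reading that grows
with field count; a nearest-neighbor mode is provided).  Information rate
is the Skaggs bits/s statistic; sparsity is μ²/⟨μ_m²⟩.

## Spectral analysis

Per-neuron magnitude spectra of the full activity trace, no taper, DC
retained (a window would redistribute exactly the low-frequency content
under study).  Heterogeneous runs are compared with homogeneous twins that
share the trajectory and the activity initialization:

    ΔS(f) = (S_het(f) − S_homo(f)) / (max S_het + max S_homo)

The across-neuron variance of ΔS per frequency bin summarizes the
perturbation; octave AUC shares (0–2, 2–4, 4–8, 8–16 Hz) summarize its
distribution.  In heterogeneous integrator networks the 0–2 Hz octave
dominates this variance at every degree and the total AUC grows with
degree; resonator networks (both kinds) show less total variance than
integrator twins, and the mechanistic network adds less 8–16 Hz power than
the phenomenological one, whose derivative stage is the source of the
spurious high-frequency content.

## What the simulations do and do not reproduce

Reproduced (numbers from the 60×60 test bank: 20 s metric runs, 24 sampled
neurons, heterogeneity seeds pooled where stated): grid emergence in
homogeneous networks for all three neuron models (79 / 58 / 71% of neurons
above 0.3 for integrator / phenomenological / mechanistic at 30 s);
monotone disruption across degrees 1–5 with the synaptic ≥ afferent ≥
intrinsic hierarchy at degree 3; near-total collapse at degree 5 (pooled
median grid-score change −107%); dominance of the 0–2 Hz octave in the
heterogeneity-induced spectral variance at every degree (68–75% of the
band total); strong mechanistic protection at degree 5 (median change −28%
vs −107% for the integrator, 3 seeds) with a monotone improvement as the
feedback slows (τ_m = 15/25/50/75 ms: −126/−120/−22/+2%); theta-band
resonance and all tuning-curve monotonicities of the phenomenological
resonator; the mechanistic tuning phenomenology at characterization
feedback strengths; and the smaller high-frequency (8–16 Hz) power
increase of the mechanistic network relative to the phenomenological one.

Not reproduced: a *phenomenological* rescue of heterogeneous grids — the
per-millisecond velocity noise of the fast virtual trajectory dominates
du/dt, so the derivative stage cannot separate static heterogeneity-induced
bias from genuine bump motion; the heterogeneous phenomenological network
scores somewhat worse than the integrator (−171% vs −107%), and its
derivative stage injects enough spectral variance of its own that its
total heterogeneity-induced variance exceeds the integrator's at mild
degrees (1–2).  The total variance AUC also saturates from degree 3 rather
than growing monotonically to degree 5: the normalized difference is
bounded and the grid code is fully decohered by degree 3 under this
heterogeneity calibration.  Finally, the commonly quoted feedback strength
of 0.015 cannot produce either a measurable single-neuron resonance or any
network rescue; the default strength was instead derived from the
phenomenology itself, and the two constraints (single-neuron resonance
wants g ≈ 0.8, network pattern survival wants g ≤ 0.1) cannot be satisfied
by one value in this implementation.

## Problem sizes and numerics

Tests run the 60×60 network with 20 s trajectories for metric-bearing
comparisons, 30 s for homogeneous pattern quality, and 6 s for
spectral-only twin comparisons, scoring an evenly spaced subsample of 24
neurons per network; the full-scale protocol (100 s, all 3600 neurons) is a
configuration change away.  Forward Euler is used throughout with
dt/τ ≤ 1 enforced.  Activities below 1e-12 are flushed to zero each step
(they are dynamically zero and would otherwise enter the subnormal range,
where the recurrent matvec incurs a large hardware penalty).  Unjittered
recurrence is evaluated by FFT convolution per direction block (exact to
float32 round-off, ~5× faster than the dense product); jittered weights use
the dense product in float32.  Divergence (|S| > 1e6 or non-finite) aborts
with a diagnostic.
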