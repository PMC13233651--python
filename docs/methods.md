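# Methods

## The neural field

Every mesh vertex carries a six-state Epileptor neural mass.  With per-node
excitability `x0`, bias currents `Iext = 3.1`, `Iext2 = 0.45`, time scales
`tau0 = 2857`, `tau1 = 1`, `tau2 = 10` and the global time-scale `tt = 0.17`
multiplying all derivatives, the uncoupled right-hand sides are

    dx1 = tt (y1 − f1(x1, x2, z) − z + Iext)
    dy1 = tt (1 − 5 x1² − y1) / tau1
    dz  = tt (s (x1 − x0) − z) / tau0
    dx2 = tt (−y2 + x2 − x2³ + Iext2 + 2 g − 0.3 (z − 3.5))
    dy2 = tt (−y2 + f2(x2)) / tau2
    dg  = tt (−0.01 (g − 0.1 x1))

with the fast nullcline `f1 = x1³ − 3x1²` for `x1 < 0` and
`f1 = (x2 − m − 0.6 (z − 4)²) x1` otherwise (`m` defaults to 0), and the SWE
recovery `f2 = 0` below `x2 = −0.25`, `6 (x2 + 0.25)` above.  `g` low-passes
past fast-discharge activity into the SWE subsystem ("integral coupling").

### Calibration of the permittivity drive

`s` (`z_slope`, default **7.5**) sets how strongly the fast state drives the
slow permittivity.  With the conventional value 4 the resting point of the
fast subsystem loses existence already at `x0 ≈ −2.06`, so a node at the
propagation-zone excitability `x0 = −1.9` would seize autonomously within
roughly two seconds — contradicting the intended dichotomy in which only the
epileptogenic zone (`x0 = −1.6`) seizes on its own.  With `s = 7.5` the
printed resting state becomes an exact equilibrium of the propagation zone
(`7.5 · (−1.5 + 1.9) = 3.0 = z_rest`), the autonomous-seizure threshold
moves to `x0 ≈ −1.72`, and an onset-initialized seizure of an `x0 = −1.6`
node terminates at ≈ 2 s with a recurrence period of ≈ 7.6 s that scales
approximately linearly in `tau0`.  The slope is config-exposed for users who
want the conventional variant.

### Coupling

Global coupling enters `x1` as delayed difference coupling
`k γ_glob Σ_j w_ij (x1_j(t − d_ij) − x1_i(t))` with `k = 0.636`,
`γ_glob = 1`, delays `d_ij = tract_length_ij / conduction_speed`
(default 3 mm/ms; delays rounded to the nearest integer step, ties up).
Difference coupling vanishes at consensus, so homogeneous equilibria of the
single node remain network equilibria.  Past `x1` values live in a ring
buffer whose depth covers the maximal delay; reading at delay 0 returns the
current state.

Local coupling uses a Laplace (exponential) kernel
`K_ij = exp(−d_ij/σ)` on edge-graph geodesic distances (Dijkstra on mesh
edges — a standard approximation to polyhedral geodesics, adequate at mesh
resolution), truncated at a cutoff (defaults σ = 2 mm, cutoff = 6 mm,
self-coupling excluded, row normalization off but available).  The three
Heaviside-gated channels are

    lc11 = γ11 Σ_j K_ij H(x1_j − θ11)   → x1 equation
    lc12 = γ12 Σ_j K_ij H(x1_j − θ12)   → g  equation
    lc22 = γ22 Σ_j K_ij H(x2_j − θ22)   → x2 equation

with `γ = (0.34, 0.064, 0.032)` and `θ = (−1, −1, −0.5)`; `H` is the strict
step (`H(0) = 0`).  Placing `lc12` in the `g` equation realizes the
bidirectional fast↔SWE link through neighboring tissue.

### Integration

Deterministic Heun (predictor–corrector) at `dt = 0.1` ms, no stochastic
forcing.  The delayed global coupling is evaluated once per step from the
history buffer and reused in the corrector; the cheap local coupling is
re-evaluated at the predictor.  The history buffer advances exactly once per
step.  The compiled (numba) production loop reproduces the plain-numpy
`heun_step` semantics; a dense full-history reference implementation in the
test suite agrees with it to < 1e-10 over 1000 steps on a 100-node random
connectome.  Divergence (non-finite state) aborts with a diagnostic.

Initialization: non-onset nodes at `(−1.5, −11, 3, −0.9, 0.3, −0.1)`, the
onset zone at `(0, −5, 3, 0, 0, 0)`.  The onset zone is a compact patch of
adjacent CA1 vertices (nearest the CA1 centroid by default).

## The spiking network

Neurons are conductance-based point models in the Hill–Tononi style: a
leaky membrane (`tau_m = 16` ms, Na/K leaks toward +30/−90 mV), an adaptive
threshold (`theta_eq = −51` mV, `tau_theta = 2` ms), and intrinsic currents
— persistent sodium `I_NaP` (sigmoidal activation at −55.7 mV, fast
positive feedback), a depolarization-activated potassium current `I_KNa`
whose slow activity variable `D` (influx above −10 mV, decay
`tau_D = 400` ms) terminates bursts, plus low-threshold `I_T` and
hyperpolarization-activated `I_h` with first-order gates.  The spike
mechanism is explicit: on crossing, the neuron emits, `V` and `theta` are
set to `E_Na`; during the 2 ms refractory window `V` repolarizes toward
`E_K` with `tau_spike = 1.75` ms.  The `I_NaP`/`I_KNa` pair yields the
characteristic burst–silence firing: under a sustained step current of
~12 (in `tau_m`-scaled units) a neuron fires bursts of ≥ 2 spikes separated
by > 150 ms of silence.  All constants are config-exposed.  The network is
purely excitatory (a downscaled CA1 pyramidal population); interneurons are
outside the present scope.

Synapses follow the Tsodyks–Markram model with per-connection resource `x`
and utilization `u` (defaults `U = 0.5`, `tau_rec = 800` ms, `tau_fac = 0`,
i.e. depressing): recovery between presynaptic spikes is applied in closed
form at event time, each release transfers `weight · u⁺ · x` to the target's
receptor conductance after the transmission delay (rounded to steps, ties
up).  Receptors are exponential-decay AMPA (E = 0 mV, τ = 2.4 ms) and
GABA-A (E = −70 mV, τ = 5 ms) conductances.

Per-vertex devices: an input device per CA1 vertex draws
`Poisson(λ)` spikes each step and relays them identically to every neuron
of the vertex's subpopulation through static synapses (default weight 4.0 —
suprathreshold for a resting neuron — and delay 1 ms); an output device
counts the subpopulation's emitted spikes per step.  Vector ordering always
follows the device-creation order (ascending CA1 vertex id).

Downscaling samples neurons uniformly without replacement and keeps exactly
the induced connections; ids are re-indexed by order-preserving compaction
and the old→new mapping is returned.  Integrity statistics (per-axis soma
density, in/outdegree and connection-length histograms with summary
moments) quantify what the reduction preserves.

## The bridge

The conversion uses offsets `o_x1 = 2`, `o_x2 = 0.5`, gains `g_x1 = 0.375`,
`g_x2 = 1.25` at `dt = 0.1` ms, each channel rectified separately, summed
into the per-step Poisson parameter.  At rest the x2 channel is exactly
zero; the x1 channel carries a small baseline (0.01875 per step) because
the resting `x1 = −1.5` sits above the rectification boundary −2 — the
boundary is reached only during the ictal wave.  λ is treated as a
dimensionless per-step expected count; reported rates are λ/dt.  A
Bernoulli mode (λ clipped at 1) is available as a config flag.

The exchange is lockstep at a shared `dt`: field step → rate message →
device draws → relay → network step → spike-count message.  Messages are
plain objects with a newline-delimited, versioned byte encoding; the
in-process and serialized transports are interchangeable and produce
byte-identical logs under a fixed seed.  The count channel is logged but
not fed back by default, making the co-simulation one-directional (the
field trajectory is bit-identical with and without the spiking side); a
feedback hook (gain on per-vertex counts into the `x1` equation) exists for
future bidirectional use.

## Geometry and assignment

The synthetic surface is a constant-curvature extrusion of a jittered
(AP, PD) grid — an exactly isometric embedding, so the generating
parameters are the ground-truth flat map.  PD bands are labeled
subiculum / CA1 / CA2 to exercise the relabeling rule at band boundaries.
Neuron somata are sampled area-uniformly on the assignable surface within a
shell of configurable thickness and inherit the AP–PD coordinates of their
generating surface point.

Assignment attaches every neuron to its nearest CA1/CA2/subiculum vertex in
AP–PD space (strict partition; ties to the lowest vertex id) so each device
drives a disjoint subpopulation.  Relabeling then reconciles anatomy with
the assignment: populated CA2/subiculum vertices become CA1; empty CA1
vertices inherit the label of the nearest CA2/subiculum vertex in AP–PD
space.  One application reaches the fixed point (CA1 ⇔ populated), making
the operation idempotent.

## Analyses

Phase is the angle of the analytic signal (Hilbert transform after mean
removal), wrapped to [−π, π); constant signals are rejected.  Phase-locked
histograms use 20 half-open, left-inclusive bins by default, exclude the
first and last 5 % of samples against edge artifacts, and come in
per-vertex, vertex-averaged and pooled variants together with the vector
strength (modulus of the count-weighted mean phasor).  The phase carrier is
`x2 − x1` by default; the transmitted-probability signal is available as an
alternative source.  The quantitative form of the locking claim used in the
acceptance tests is: (i) the realized vector strength exceeds the 95th
percentile of 200 per-vertex circular-shift nulls (which preserve both the
phase occupancy and each vertex's spike count), and (ii) the spike
histogram's modal bin lies within one bin (circularly) of the modal bin of
the transmitted-probability mass binned by the same phases — the
probability-mass histogram is the exact expectation of the spike histogram,
and the one-bin tolerance absorbs mode flips between near-tied adjacent
bins.

Seizure-onset latency is the first sample at which `x2 − x1` drops below a
threshold (default 0.3, half the resting value 0.6, with rest one
`hysteresis` above it).  The downward direction is deliberate: with the
calibrated local coupling the SWE channel pushes `x2` upward in recruited
tissue, so the signal need not cross zero; the departure from the resting
band is the robust marker.  Nodes that never cross are reported absent
(NaN).

## What the synthetic data do and do not show

The generator reproduces the structural features the pipeline depends on —
labeled subfield bands, a smooth two-axis parameterization, geodesic
neighborhoods, distance-dependent connectivity with realistic degree and
length distributions — under exact ground truth, which is what makes the
assignment, relabeling and flat-map contracts testable at all.  It does not
emulate subject anatomy, curvature-dependent registration error, laminar
soma distributions or cell-type diversity; passing tests therefore validate
the algorithms and their contracts, not anatomical fidelity on real data.

## Problem sizes and numerical choices

Default study sizes keep every stage comfortably on one CPU: meshes of
~100–200 vertices, clouds of 300–1000 neurons, 2–20 s of simulated time at
`dt = 0.1` ms.  The propagation analysis uses a 200-node mesh (4 s of
simulated time); the dichotomy and recurrence checks run single nodes for
20–45 s of simulated time; conversion maxima come from a 6 s single-node
trace containing one complete seizure.  Tolerances: fixed-point residuals
< 1e-10; sparse-vs-dense agreement < 1e-10; stochastic checks use 3-sigma
bands (binomial/hypergeometric/Poisson) and two-sample KS tests.
Degenerate inputs (empty node sets, non-positive durations, shape
mismatches, non-finite states) raise immediately rather than propagate.

## Known limitations

One process, shared address space — the transport abstraction is
message-faithful but not an MPI deployment.  The full-scale model
(435k mesh nodes, 5.28M neurons) is supported by the data structures
(sparse matrices, ring history, chunked connectivity generation) but not
exercised.  Feedback coupling is implemented but unvalidated scientifically
(disabled by default).  The Heun scheme is fixed-step; stiff excursions at
very large `dt` abort rather than adapt.
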