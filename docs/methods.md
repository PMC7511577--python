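# Methods

## Scientific question

Large cortical and hippocampal pyramidal neurons receive slow (theta-band)
and fast (gamma-band) input at different locations along their
soma-apical axis, and single-cell nonlinearities can couple them: the
slow-band membrane-potential phase modulates the fast-band amplitude
(phase-amplitude cross-frequency coupling, PAC). The hyperpolarization-
activated mixed cation current I_h is a prime suspect for shaping this
coupling because its density often rises steeply along the apical
dendrite, it is the only major subthreshold conductance that *activates*
on hyperpolarization, and it gates slowly enough to follow theta but not
gamma. This package implements a reduced multicompartment
conductance-based pyramidal-neuron model in three I_h configurations —
an exponential somato-apical gradient, a near-uniform distribution, and
none — together with the dual-sinusoid current-injection protocols and
the PAC quantification pipeline needed to compare them.

## Model

### Morphology

A soma with three attached unbranched cables: a 13-compartment apical
shaft (75 um cylinders, diameter tapering linearly from the somatic to
the distal value) continuing into a 3-compartment tuft, so the apical
axis spans 0-1200 um with apdend12 beginning 825 um from the soma; a
3-compartment basal chain; and a 2-compartment axonal stub. Each
compartment is an iso-potential cylinder mapped to one of 21
conductance-density "levels": axon = levels 0-1, soma = 2, basal = 3-5,
apical shaft = 6-18 (one level per compartment, matching the 13 shaft
compartments to the 13 apical levels), tuft = 19-20. The source model's
exact geometry is not published; dimensions live in one `MorphologySpec`
block, and four diameters (soma, basal, proximal apical, distal
apical/tuft) are part of the calibration vector (below). The calibrated
distal diameter comes out well above the classical 2 um thin-tuft
picture; a thinner distal cable makes the distal tip far too isolated
axially to reproduce the reported distal-to-somatic input-resistance
ratio.

### Membrane currents

Densities for nine active conductances are specified per level by the
packaged density table; the fast Na column is zero everywhere, so the
model is strictly subthreshold by construction. Table densities are
relative and are converted to mS/cm^2 by one global `density_scale`.
Kinetics are standard Hodgkin-Huxley first-order gates with Boltzmann
steady states and constant or bell-shaped time constants, all defined in
a versioned YAML config (`data/kinetics.yaml`) so the whole set can be
swapped. Choices that matter:

* **I_h (anomalous rectifier).** Single gate, opens on hyperpolarization.
  Half-activation and slope are calibration parameters (calibrated to
  about -81 mV and 11 mV). The time constant uses the classical HCN
  two-exponential form scaled to a ~110 ms peak near -75 mV. The scale is
  a mechanism-driven design choice: the gate must *partition the two
  injected bands*, following a 4 Hz voltage swing with sizable gain
  (~0.4-0.5, lag 60-80 degrees) while attenuating 40 Hz more than
  tenfold in absolute terms. A much slower profile (the ~900 ms peak of
  the thalamic-relay H-current formula) makes the gate effectively blind
  to both bands, and the h-current then cannot participate in coupling
  at all.
* **K(M).** Depolarization-activated, non-inactivating; time constant
  ~150 ms at subthreshold voltages (the literature M-current
  deactivation range). Its slow, lagged conductance modulation is the
  main depolarization-side modulator of fast-band amplitude.
* **K(DR), K(A), Na(P), Ca(H), Ca(L).** Conventional subthreshold
  parameterizations; fast gates, so they modulate impedance nearly
  instantaneously.
* **Ca-dependent K.** A first-order Ca pool per compartment (influx
  proportional to inward Ca current, 20 ms decay) drives K(C) through an
  instantaneous saturating factor and K2 through a slow Ca-activated
  gate (AHP-like). Both carry no current when the pool is empty.
* No temperature scaling (a single implicit temperature).

### Numerical integration

Staggered scheme: exponential Euler for all gates and the Ca pool at the
pre-step voltage, then a fully implicit (backward Euler) linear solve
for the coupled voltages with conductances frozen at the updated gates.
The implicit solve is unconditionally stable for the stiff cable system
and its fixed point is the exact steady state, so resting-potential and
input-resistance measurements carry no time-step bias. Default
dt = 0.025 ms (contract: dt <= 0.05 ms); halving dt changes trace
voltages by well under 0.1 mV. The inner loop is compiled with numba
(Gaussian elimination without pivoting — the system matrix is strictly
diagonally dominant); a pure-numpy loop with identical semantics is kept
as `engine="numpy"` and asserted equivalent to ~1e-13 mV in the tests.

Resting states are computed by a Newton solve of the full nonlinear
steady-state system and verified against the |dV/dt| < 1e-6 mV/ms
criterion, with a 10 s relaxation fallback. Input resistance defaults to
the measurement protocol: a -0.1 nA step from rest, steady-state
deflection over amplitude (mV/nA = MOhm); a two-Newton-solve variant
(`method="steady"`, the exact long-step limit) is used inside the
calibration loop for speed.

### Calibration

The source model's absolute densities, passive parameters, and geometry
are not published; what is published is a strong joint constraint: six
input resistances (soma and apdend13 in each I_h configuration,
54/34/25 and 76/52/30 MOhm) plus the range of resting potentials across
all compartments and models (-85 to -56 mV). `scripts/calibrate.py`
fits {density_scale, g_leak, E_leak, E_h, axial resistivity, h-gate
half-activation and slope, four diameters} to those eight observables by
least squares (residuals scaled by the per-quantity tolerance: 10%
relative on resistances, ~1.7 mV on the range endpoints; the endpoints
are targeted 0.25 mV inside the range so every compartment rests within
it). The calibrated set ships as `data/calibrated.yaml` and is loaded by
`build_model` by default; the fit residuals are recorded in that file.
The three models share every calibrated parameter and differ only in
which h-density column is active.

This reduced morphology cannot reproduce all six resistances exactly:
the fundamental tension is that the same activation curve must leave
enough distal I_h conductance to depolarize the tuft to -56 mV while not
collapsing the distal input resistance of the gradient model below its
reported value. The shipped calibration is the best joint compromise
found; residuals per target are in `calibrated.yaml` and the acceptance
tests report each target at its +-10% bar.

## Injection protocols and experiment grid

The core protocol injects two simultaneous sinusoids: a slow 4 Hz
"modulation" current (at apdend13, "distal", or the soma,
"perisomatic") and a fast 40 Hz current (at the apical base apdend1,
middle apdend7, or distal apdend12), both 1.5 nA by default. The full
grid crosses 2 modulation sites x 3 fast sites x 3 models = 18 runs.
Each run starts from the solved resting state, discards max(transient,
filter length) from the start, and analyzes an integer number of slow
cycles (default 8; tests use 4 to keep the grid tractable — the binning
is phase-folded, so any cycle count >= 2 measures the same quantity
with more or less averaging). With the reported input resistances, the
1.5 nA protocol drives local swings up to ~100 mV about rest at the
distal injection site of the no-I_h model; nothing in that model
rectifies hyperpolarizing excursions, so such excursions are intrinsic
to the printed protocol/resistance combination, not a numerical
artifact.

## Coupling quantification

1. Decimate the trace (anti-aliased, zero-phase) to ~1 kHz; subtract the
   mean; zero-phase FIR band-pass into theta (2-6 Hz) and low-gamma
   (30-50 Hz) bands (1 s filters, ~3 Hz transition); exclude one filter
   length at each record end from analysis.
2. Slow-band phase and fast-band envelope from the analytic (Hilbert)
   signals. The absolute phase reference is a convention: the default
   places 0 degrees at the slow component's upward zero-crossing (its
   sine phase, the natural reference for an injected sine; the peak is
   at 90 degrees). A "peak" convention (0 at the maximum) is available.
3. Mean envelope per phase bin (N = 72 five-degree bins by default),
   normalized to a distribution P(j). Empty bins raise an error rather
   than being imputed; a vanishing slow component raises (phase
   undefined).
4. Metrics: modulation index MI = (log N + sum P log P)/log N (natural
   logs, 0 log 0 = 0; the normalized entropy deficit, 0 = uniform, 1 =
   one-hot); height ratio (h_max - h_min)/h_max of P; amplitude ratio
   sqrt(2) x RMS(theta component) over sqrt(2) x RMS(gamma component);
   and the bin-center phases of the envelope maximum and minimum (ties
   break toward the earlier phase). MI and height ratio are invariant to
   uniform envelope rescaling because the normalization cancels.

## What the synthetic generator emulates

`generate_coupled` produces a slow sinusoid plus a fast sinusoid whose
envelope is cosine-modulated by the slow phase with depth chi_c in
[0, 1] (chi_c = 1: envelope touches zero, height ratio 1) at a
controllable coupling phase, plus optional white Gaussian noise. It
exercises the entire metric pipeline with known ground truth —
phase-reference bookkeeping, bin discretization, filter leakage, noise
robustness — but it is *not* membrane-like: no 1/f background, no
harmonics, no waveform asymmetry, and stationary coupling. Passing
recovery tests therefore validates the estimator, not the neuron model;
the simulator-side tests do that separately. `generate_passive_fixture`
produces exact closed-form RC-membrane responses to step/sine protocols
and serves as the independent oracle for the cable integrator.

## Mechanism, in brief

At a fixed operating point the fast-band envelope at a compartment is
set by its local 40 Hz impedance. Conductances that activate with
depolarization (chiefly K(M), with K(DR)/K(A)/Na(P) contributing
near-instantaneously) lower the impedance around the depolarized phase
of the slow cycle, so the envelope minimum falls shortly after the slow
peak (lagged by the M-current kinetics) and the maximum roughly half a
cycle later. The h-current opposes this modulation: depolarization
*deactivates* it, raising impedance with its own lag. Its net effect is
threefold: it depolarizes the resting point (bringing the
depolarization-activated modulators into range), it lowers input
resistance (shrinking the slow voltage swing), and its anti-phase
conductance modulation partially cancels the K-driven modulation —
which is why the gradient model, with the most distal I_h, couples more
weakly than the uniform model.

## Known limitations

* The reduced 22-compartment morphology and the hand-specified kinetics
  are calibrated surrogates, not a reconstruction of the source model;
  per-compartment metric values should be read as patterns, not
  point predictions.
* Two of the six input-resistance targets sit somewhat outside the +-10%
  calibration bar (see `calibrated.yaml` residuals); the no-I_h/uniform
  distal spread cannot be fully reconciled with the gradient model's
  distal resistance in this geometry.
* The no-I_h model's coupling strength relative to the I_h models is
  sensitive to the (unpublished) K-channel kinetics: with the defaults
  here it remains comparable to the uniform model rather than clearly
  weaker, and its envelope-extrema phases do not invert.
* Band filters assume the drive frequencies sit mid-band; analyzing
  drives near band edges requires retuning the bands.
* No synapses, no action potentials, single temperature.
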