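# dendrocfc

Theta–gamma phase–amplitude coupling in multicompartment model pyramidal
neurons, as a function of the spatial distribution of the
hyperpolarization-activated cation current I_h.

Large cortical and hippocampal pyramidal neurons receive slow
(theta-band) input distally and fast (gamma-band) input perisomatically,
and their intrinsic conductances can couple the two: the phase of the
slow membrane-potential oscillation modulates the amplitude of the fast
one (phase–amplitude cross-frequency coupling, CFC/PAC). This package is
for computational neuroscientists who want to dissect that single-cell
mechanism. It provides:

* a reduced 22-compartment conductance-based pyramidal neuron (soma,
  13-compartment apical shaft, 3-compartment tuft spanning 0–1200 µm,
  basal and axonal stubs) with nine Hodgkin–Huxley-style conductances
  whose densities are set per structural level by a packaged table, in
  three I_h configurations that differ *only* in the h-density column:
  `exp_gradient` (density rising exponentially along the apical axis),
  `uniform`, and `none`;
* a cable-equation integrator (implicit voltage step + exponential-Euler
  gates, numba-accelerated) for arbitrary sinusoidal/step current
  injections, with resting-state and input-resistance measurement
  operations and a passive parameterization calibrated against the six
  reported input resistances and the reported resting range;
* the CFC quantification pipeline: zero-phase band decomposition,
  Hilbert phase/envelope, phase-binned normalized amplitude distribution
  P(j), and the metrics

      MI = (log N + Σⱼ P(j) log P(j)) / log N          (modulation index)
      height ratio = (h_max − h_min) / h_max
      amplitude ratio = Vm(4 Hz) / Vm(40 Hz)

  plus the theta phases of the envelope extrema;
* a synthetic coupled-signal generator with ground-truth coupling depth
  and phase, and exact RC-membrane fixtures, used as independent oracles
  for the pipeline;
* an experiments layer that runs the 2 × 3 × 3 grid (distal/perisomatic
  4 Hz modulation × base/middle/distal 40 Hz site × three models),
  bin-count and injection-amplitude sensitivity sweeps, and cross-model
  comparison tables.

## Worked example

Distal 1.5 nA 4 Hz modulation with a perisomatic 1.5 nA 40 Hz injection
in the exponential-gradient model, analyzed at the 11th apical
compartment with N = 72 phase bins:

```python
from dendrocfc import build_model, compute_cfc
from dendrocfc.experiments import ScenarioSpec, SimWindow, simulate_scenario

spec = ScenarioSpec(modulation_site="distal", gamma_site="base",
                    ih_mode="exp_gradient")
window = SimWindow()                      # 1 s transient, 8 theta cycles
trace = simulate_scenario(spec, window)
start, stop, _ = window.spans(spec.theta_freq_hz)
res = compute_cfc(trace.t, trace.channel("apdend11"),
                  n_bins=72, start_ms=start, stop_ms=stop)
print(f"MI {res.mi:.3e}  height ratio {res.height_ratio:.3f}  "
      f"amplitude ratio {res.amplitude_ratio:.2f}  "
      f"envelope min/max at {res.phase_min_deg:.0f}/{res.phase_max_deg:.0f} deg")
```

prints

```
MI 1.121e-03  height ratio 0.248  amplitude ratio 3.22  envelope min/max at 48/208 deg
```

i.e. clear coupling at this mid-apical site (MI far above the ~4×10⁻⁵
no-coupling threshold), with the 40 Hz envelope minimal shortly after
the theta peak (90° in the sine phase convention) and maximal in the
opposite half-cycle — the signature of slow depolarization-activated
conductances opposed by I_h. The same pipeline applied along the whole
apical axis (`run_scenario`) shows coupling growing from soma to tuft
under distal modulation, and `run_grid` + `model_comparison` reproduce
the cross-model ordering (uniform I_h strongest, gradient weaker).

A command-line interface mirrors these calls:

```sh
dendrocfc run-scenario --ih-mode exp --modulation distal --gamma-site base --out profile.csv
dendrocfc run-grid --out grid.csv
dendrocfc analyze-trace --trace trace.csv --n-bins 72
dendrocfc measure --ih-mode none --site apdend13
dendrocfc calibrate --out calibrated.yaml
```

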