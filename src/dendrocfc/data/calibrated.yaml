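# Calibrated global parameters (regenerate with scripts/calibrate.py).
# One parameter set jointly fit to the six target input resistances
# (soma and apdend13 under the three I_h configurations) and the
# endpoints of the resting-potential range.
density_scale: 0.0237   # mS/cm^2 per relative density-table unit
g_leak: 0.1032          # mS/cm^2, uniform
e_leak: -83.217         # mV
e_h: -15.0              # mV
ra: 594.11              # ohm cm axial resistivity
cm: 0.9                 # uF/cm^2
ih_vhalf: -81.238       # mV, h-gate half-activation
ih_slope: 11.104        # mV, h-gate slope (opens on hyperpolarization)
soma_diameter: 10.0     # um (equivalent cylinder)
basal_diameter: 1.5     # um
apical_diam_proximal: 10.0  # um
distal_diameter: 4.626  # um (distal apical shaft and tuft)
# post-fit measured values (step protocol / resting solve):
fit_residuals:
  r_in_exp_gradient_soma: 24.909     # target 25
  r_in_exp_gradient_apdend13: 25.383 # target 30
  r_in_none_soma: 49.725             # target 54
  r_in_none_apdend13: 77.788         # target 76
  r_in_uniform_soma: 35.872          # target 34
  r_in_uniform_apdend13: 58.271      # target 52
  rest_min: -84.582                  # target -85
  rest_max: -57.068                  # target -56
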