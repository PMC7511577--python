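# Default channel-kinetics set, version 1.
#
# Every voltage gate has a Boltzmann steady state
#     x_inf(V) = 1 / (1 + exp((vhalf - V) / slope))
# (positive slope: opens with depolarization; negative slope: opens with
# hyperpolarization, as for the h-current / anomalous-rectifier gate) and a
# voltage-dependent time constant tau(V) in ms:
#     const : tau = value
#     bell  : tau = base + amp / (exp((V-vpeak)/sig1) + exp(-(V-vpeak)/sig2))
#     hcn   : tau = scale / (exp(-14.59 - 0.086 V) + exp(-1.87 + 0.0701 V))
# The hcn form gives the slow, bell-shaped time-constant profile of the
# anomalous rectifier (peak ~900 ms near -75 mV), so the gate cannot follow
# 40 Hz modulation but tracks 4 Hz modulation with a phase lag.
#
# K2 is modeled as a slow Ca-activated K current: its gate opens at a rate
# proportional to the Ca-pool activity chi (alpha = min(alpha_per_chi * chi,
# alpha_max)) and closes at a fixed rate beta, so it carries no current when
# chi = 0.  K(C) has a voltage gate scaled by the instantaneous saturating
# factor min(chi / kc_half, 1).
version: 1
reversals:
  E_Na: 50.0
  E_K: -95.0
  E_Ca: 125.0
  E_h: -40.0
ca_pool:
  influx_gain: 50.0   # chi per (uA/cm^2 x ms) of inward Ca current
  decay_tau: 20.0     # ms
  kc_half: 250.0      # chi giving a saturated K(C) Ca factor
channels:
  NaP:
    reversal: E_Na
    gates:
      - {name: m, exponent: 1, vhalf: -50.0, slope: 5.0, tau: {type: const, value: 2.0}}
  KDR:
    reversal: E_K
    gates:
      - {name: n, exponent: 2, vhalf: -20.0, slope: 6.0,
         tau: {type: bell, base: 1.0, amp: 12.0, vpeak: -40.0, sig1: 20.0, sig2: 20.0}}
  KA:
    reversal: E_K
    gates:
      - {name: a, exponent: 1, vhalf: -45.0, slope: 6.0, tau: {type: const, value: 5.0}}
      - {name: b, exponent: 1, vhalf: -70.0, slope: -6.0, tau: {type: const, value: 50.0}}
  KM:
    reversal: E_K
    gates:
      - {name: m, exponent: 1, vhalf: -35.0, slope: 9.0,
         tau: {type: bell, base: 40.0, amp: 360.0, vpeak: -45.0, sig1: 25.0, sig2: 25.0}}
  KC:
    reversal: E_K
    ca_factor: true
    gates:
      - {name: c, exponent: 1, vhalf: -30.0, slope: 8.0, tau: {type: const, value: 4.0}}
  K2:
    reversal: E_K
    ca_gated: true
    gates:
      - {name: q, exponent: 1, alpha_per_chi: 2.0e-5, alpha_max: 0.01, beta: 0.001}
  CaH:
    reversal: E_Ca
    ca_current: true
    gates:
      - {name: m, exponent: 2, vhalf: -20.0, slope: 7.0, tau: {type: const, value: 2.0}}
  CaL:
    reversal: E_Ca
    ca_current: true
    gates:
      - {name: m, exponent: 2, vhalf: -40.0, slope: 6.0, tau: {type: const, value: 5.0}}
      - {name: h, exponent: 1, vhalf: -65.0, slope: -6.0, tau: {type: const, value: 100.0}}
  h:
    reversal: E_h
    gates:
      - {name: q, exponent: 1, vhalf: -75.0, slope: -5.5, tau: {type: hcn, scale: 0.12}}
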