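"""Hodgkin-Huxley-style gating kinetics for all membrane conductances.

Each channel is a set of first-order gates ``dx/dt = (x_inf(V) - x)/tau(V)``
raised to integer exponents; the membrane current density is

    I = g_bar * prod_i x_i^p_i * (V - E_rev)        [uA/cm^2, outward > 0]

The centerpiece is the h-current (anomalous rectifier): a single gate
whose steady state falls sigmoidally with depolarization and whose time
constant is bell-shaped (peak ~110 ms near -75 mV with the default
scale).  The profile is chosen so the gate partitions the two injected
bands: it acts as a first-order low-pass that follows a 4 Hz voltage
swing with appreciable gain and a phase lag, while 40 Hz modulation is
attenuated more than tenfold.

Two K currents depend on the intracellular Ca pool ``chi`` (a dimensionless
first-order activity variable fed by the Ca currents): K(C) through an
instantaneous saturating factor min(chi/kc_half, 1) on its conductance, and
K2 through a gate whose opening rate is proportional to chi.  Both carry no
current when chi = 0 and their gates are shut.

Parameters live in a versioned YAML config (``data/kinetics.yaml``);
alternative kinetics sets can be loaded from any file with the same schema.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field
from typing import Callable

import numpy as np
import yaml

__all__ = [
    "GateSpec",
    "ChannelSpec",
    "CaPoolParams",
    "load_kinetics",
    "build_channels",
    "channel_spec",
    "channel_current",
    "ih_activation",
    "ih_time_constant",
    "boltzmann",
]


def boltzmann(v, vhalf: float, slope: float):
    """Sigmoid steady state; positive slope opens with depolarization."""
    return 1.0 / (1.0 + np.exp((vhalf - np.asarray(v, dtype=float)) / slope))


def _tau_fn(cfg: dict) -> Callable:
    kind = cfg["type"]
    if kind == "const":
        value = float(cfg["value"])
        return lambda v: np.full_like(np.asarray(v, dtype=float), value)
    if kind == "bell":
        base, amp = float(cfg["base"]), float(cfg["amp"])
        vpeak, s1, s2 = float(cfg["vpeak"]), float(cfg["sig1"]), float(cfg["sig2"])

        def tau(v):
            v = np.asarray(v, dtype=float)
            return base + amp / (np.exp((v - vpeak) / s1) + np.exp(-(v - vpeak) / s2))

        return tau
    if kind == "hcn":
        scale = float(cfg.get("scale", 1.0))

        def tau(v):
            v = np.asarray(v, dtype=float)
            return scale / (
                np.exp(-14.59 - 0.086 * v) + np.exp(-1.87 + 0.0701 * v)
            )

        return tau
    raise ValueError(f"unknown tau type {kind!r}")


@dataclass
class GateSpec:
    """One first-order gate: steady state and time constant over voltage.

    Ca-dependent gates (K2) expose rates over the Ca activity chi instead:
    ``steady_state`` and ``time_constant`` then take chi as argument.
    """

    name: str
    exponent: int
    steady_state: Callable
    time_constant: Callable
    ca_dependent: bool = False
    params: dict = field(default_factory=dict)


@dataclass
class ChannelSpec:
    name: str
    gates: list[GateSpec]
    reversal: float  # mV
    ca_factor: bool = False  # conductance scaled by min(chi/kc_half, 1)
    is_ca_current: bool = False  # current feeds the Ca pool


@dataclass
class CaPoolParams:
    """First-order Ca pool: dchi/dt = -gain * I_Ca - chi / tau."""

    influx_gain: float
    decay_tau: float  # ms
    kc_half: float


def load_kinetics(source=None) -> dict:
    """Load a kinetics config (the packaged default set by default)."""
    if source is None:
        ref = importlib.resources.files("dendrocfc.data") / "kinetics.yaml"
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(source) as fh:
        return yaml.safe_load(fh)


def _make_gate(gcfg: dict, ca_gated: bool) -> GateSpec:
    if ca_gated:
        a_per_chi = float(gcfg["alpha_per_chi"])
        a_max = float(gcfg["alpha_max"])
        beta = float(gcfg["beta"])

        def x_inf(chi):
            a = np.minimum(a_per_chi * np.asarray(chi, dtype=float), a_max)
            return a / (a + beta)

        def tau(chi):
            a = np.minimum(a_per_chi * np.asarray(chi, dtype=float), a_max)
            return 1.0 / (a + beta)

        return GateSpec(gcfg["name"], int(gcfg["exponent"]), x_inf, tau,
                        ca_dependent=True, params=dict(gcfg))

    vhalf, slope = float(gcfg["vhalf"]), float(gcfg["slope"])
    return GateSpec(
        gcfg["name"],
        int(gcfg["exponent"]),
        lambda v, vh=vhalf, k=slope: boltzmann(v, vh, k),
        _tau_fn(gcfg["tau"]),
        params=dict(gcfg),
    )


def build_channels(kinetics: dict | None = None) -> dict[str, ChannelSpec]:
    """Build ChannelSpec objects for every channel in a kinetics config."""
    kin = kinetics or load_kinetics()
    reversals = kin["reversals"]
    channels: dict[str, ChannelSpec] = {}
    for name, ccfg in kin["channels"].items():
        ca_gated = bool(ccfg.get("ca_gated", False))
        gates = [_make_gate(g, ca_gated) for g in ccfg["gates"]]
        channels[name] = ChannelSpec(
            name=name,
            gates=gates,
            reversal=float(reversals[ccfg["reversal"]]),
            ca_factor=bool(ccfg.get("ca_factor", False)),
            is_ca_current=bool(ccfg.get("ca_current", False)),
        )
    return channels


def ca_pool_params(kinetics: dict | None = None) -> CaPoolParams:
    kin = kinetics or load_kinetics()
    p = kin["ca_pool"]
    return CaPoolParams(float(p["influx_gain"]), float(p["decay_tau"]),
                        float(p["kc_half"]))


_DEFAULT_CHANNELS: dict[str, ChannelSpec] | None = None


def channel_spec(name: str) -> ChannelSpec:
    """Look up a channel of the default kinetics set by name."""
    global _DEFAULT_CHANNELS
    if _DEFAULT_CHANNELS is None:
        _DEFAULT_CHANNELS = build_channels()
    try:
        return _DEFAULT_CHANNELS[name]
    except KeyError:
        raise KeyError(
            f"unknown channel {name!r}; known: {sorted(_DEFAULT_CHANNELS)}"
        ) from None


def channel_current(spec: ChannelSpec, density, gate_states, v, chi=0.0,
                    kc_half: float = 250.0):
    """Membrane current density (uA/cm^2, outward positive).

    ``gate_states`` maps gate name -> open fraction (or a sequence in gate
    order).  Linear in ``density`` (mS/cm^2); zero at ``v == reversal``.
    """
    if isinstance(gate_states, dict):
        states = [gate_states[g.name] for g in spec.gates]
    else:
        states = list(gate_states)
    g_open = np.asarray(density, dtype=float)
    for gate, x in zip(spec.gates, states):
        x = np.asarray(x, dtype=float)
        if np.any((x < 0) | (x > 1)):
            raise ValueError(f"gate {gate.name} state outside [0, 1]")
        g_open = g_open * x**gate.exponent
    if spec.ca_factor:
        g_open = g_open * np.minimum(np.asarray(chi, dtype=float) / kc_half, 1.0)
    return g_open * (np.asarray(v, dtype=float) - spec.reversal)


def ih_activation(v, kinetics: dict | None = None):
    """Steady-state activation of the h-current gate (falls with V)."""
    gate = (build_channels(kinetics) if kinetics else _default())["h"].gates[0]
    return gate.steady_state(v)


def ih_time_constant(v, kinetics: dict | None = None):
    """Activation time constant of the h-current gate in ms."""
    gate = (build_channels(kinetics) if kinetics else _default())["h"].gates[0]
    return gate.time_constant(v)


def _default() -> dict[str, ChannelSpec]:
    global _DEFAULT_CHANNELS
    if _DEFAULT_CHANNELS is None:
        _DEFAULT_CHANNELS = build_channels()
    return _DEFAULT_CHANNELS
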