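"""Synthetic test signals with known ground truth.

Two generators:

* coupled theta-gamma signals with a controllable coupling depth, for
  exercising the phase-amplitude metrics without a neuron model:

      x(t) = A_th sin(2 pi f_th t)
           + A_ga [1 - chi_c + chi_c (1 + cos(ph(t) - phi_c)) / 2]
             sin(2 pi f_ga t) + noise

  where ph(t) is the slow component's sine phase (0 deg at its upward
  zero-crossing, the same convention the analysis uses), chi_c in [0, 1] is the
  coupling depth (0: constant envelope; 1: envelope touching zero, height
  ratio 1) and phi_c the slow phase of maximal fast envelope;

* exact RC-membrane responses to step/sine protocols (closed forms), as
  an independent oracle for the cable integrator.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass

import numpy as np

from .protocols import InjectionProtocol

__all__ = ["CoupledSignalSpec", "generate_coupled", "generate_passive_fixture"]


@dataclass(frozen=True)
class CoupledSignalSpec:
    theta_freq: float = 4.0  # Hz
    theta_amp: float = 5.0  # mV
    gamma_freq: float = 40.0  # Hz
    gamma_amp: float = 1.0  # mV (base, i.e. unmodulated, amplitude)
    coupling_depth: float = 0.5  # chi_c in [0, 1]
    coupling_phase_deg: float = 270.0  # slow phase of max fast envelope
    noise_sd: float = 0.0  # mV
    duration_ms: float = 4000.0
    fs_hz: float = 1000.0
    seed: int = 0

    def validate(self) -> None:
        if not 0.0 <= self.coupling_depth <= 1.0:
            raise ValueError("coupling_depth must lie in [0, 1]")
        if self.fs_hz < 20.0 * self.gamma_freq:
            raise ValueError("sampling rate must be >= 20x the gamma frequency")
        if self.noise_sd < 0 or self.duration_ms <= 0:
            raise ValueError("invalid noise_sd or duration")


def generate_coupled(spec: CoupledSignalSpec):
    """Return (t_ms, x, ground_truth_dict); deterministic given the seed."""
    spec.validate()
    n = int(round(spec.duration_ms * spec.fs_hz / 1000.0))
    t = np.arange(n) / spec.fs_hz * 1000.0  # ms
    ts = t * 1e-3
    # slow-carrier phase in the sine convention (0 deg at the upward
    # zero-crossing), matching the analysis default
    ph = 2.0 * np.pi * spec.theta_freq * ts
    envelope = spec.gamma_amp * (
        1.0
        - spec.coupling_depth
        + spec.coupling_depth
        * (1.0 + np.cos(ph - np.deg2rad(spec.coupling_phase_deg)))
        / 2.0
    )
    x = (
        spec.theta_amp * np.sin(2.0 * np.pi * spec.theta_freq * ts)
        + envelope * np.sin(2.0 * np.pi * spec.gamma_freq * ts)
    )
    if spec.noise_sd > 0:
        rng = np.random.default_rng(spec.seed)
        x = x + rng.normal(0.0, spec.noise_sd, size=n)
    truth = {
        "coupling_depth": spec.coupling_depth,
        "coupling_phase_deg": spec.coupling_phase_deg,
    }
    return t, x, truth


def write_trace(path, t_ms, x, spec: CoupledSignalSpec | None = None) -> None:
    """Two-column CSV trace plus a JSON sidecar with the ground truth."""
    import pandas as pd

    pd.DataFrame({"time_ms": t_ms, "v_mV": x}).to_csv(path, index=False)
    if spec is not None:
        with open(f"{path}.json", "w") as fh:
            json.dump(asdict(spec), fh, indent=1)


def generate_passive_fixture(
    r_mohm: float,
    c_nf: float,
    protocol: InjectionProtocol,
    duration_ms: float,
    dt_ms: float = 0.025,
    v_rest: float = 0.0,
):
    """Exact response of an isolated RC membrane to a protocol.

    R in MOhm and C in nF give the time constant R*C in ms directly; each
    source contributes its closed-form step or sinusoid response (including
    the onset transient), superposed by linearity.  Returns (t_ms, v_mV).
    """
    if r_mohm <= 0 or c_nf <= 0:
        raise ValueError("R and C must be positive")
    tau = r_mohm * c_nf  # ms
    t = np.arange(int(round(duration_ms / dt_ms)) + 1) * dt_ms
    v = np.full_like(t, float(v_rest))
    for s in protocol:
        t0 = s.onset
        tt = np.maximum(t - t0, 0.0)
        on = t >= t0
        if s.waveform == "step":
            resp = s.amplitude * r_mohm * (1.0 - np.exp(-tt / tau))
        else:
            w = 2.0 * np.pi * s.frequency * 1e-3  # rad/ms
            phi0 = np.deg2rad(s.phase_deg)
            gain = s.amplitude * r_mohm / np.sqrt(1.0 + (w * tau) ** 2)
            lag = np.arctan(w * tau)
            ss = gain * np.sin(w * tt + phi0 - lag)
            # transient restoring v(t0) continuity
            resp = ss - gain * np.sin(phi0 - lag) * np.exp(-tt / tau)
        if s.offset is not None:
            # switch-off: freeze drive and decay from the value at offset
            t_off = np.maximum(t - s.offset, 0.0)
            after = t >= s.offset
            v_off = np.interp(s.offset, t, np.where(on, resp, 0.0))
            resp = np.where(after, v_off * np.exp(-t_off / tau), resp)
        v = v + np.where(on, resp, 0.0)
    return t, v
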