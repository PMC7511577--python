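"""Current-injection protocols: sets of sinusoidal or step point sources."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["CurrentSource", "InjectionProtocol", "sine", "step"]


@dataclass(frozen=True)
class CurrentSource:
    """One point current source.

    amplitude in nA; frequency in Hz (ignored for steps); phase in degrees;
    onset/offset in ms (offset ``None`` = on until the end of the run).
    """

    compartment: str
    waveform: str  # "sine" | "step"
    amplitude: float
    frequency: float = 0.0
    phase_deg: float = 0.0
    onset: float = 0.0
    offset: float | None = None

    def __post_init__(self):
        if self.waveform not in ("sine", "step"):
            raise ValueError(f"unknown waveform {self.waveform!r}")
        if not np.isfinite(self.amplitude):
            raise ValueError("amplitude must be finite")

    def current(self, t_ms: np.ndarray) -> np.ndarray:
        """Injected current (nA) on a time base in ms."""
        t = np.asarray(t_ms, dtype=float)
        on = (t >= self.onset) & (
            np.ones_like(t, dtype=bool) if self.offset is None else (t < self.offset)
        )
        if self.waveform == "step":
            return np.where(on, self.amplitude, 0.0)
        phase = 2.0 * np.pi * self.frequency * (t - self.onset) * 1e-3
        return np.where(
            on, self.amplitude * np.sin(phase + np.deg2rad(self.phase_deg)), 0.0
        )


@dataclass(frozen=True)
class InjectionProtocol:
    sources: tuple[CurrentSource, ...] = field(default_factory=tuple)

    def __post_init__(self):
        object.__setattr__(self, "sources", tuple(self.sources))

    def __iter__(self):
        return iter(self.sources)


def sine(compartment: str, amplitude: float, frequency: float,
         phase_deg: float = 0.0, onset: float = 0.0) -> CurrentSource:
    return CurrentSource(compartment, "sine", amplitude, frequency, phase_deg, onset)


def step(compartment: str, amplitude: float, onset: float = 0.0,
         offset: float | None = None) -> CurrentSource:
    return CurrentSource(compartment, "step", amplitude, onset=onset, offset=offset)
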