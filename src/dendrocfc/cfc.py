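"""Phase-amplitude coupling quantification.

Pipeline (slow band defaults to theta 2-6 Hz around the 4 Hz drive, fast
band to low gamma 30-50 Hz around the 40 Hz drive):

1. ``decompose`` - zero-phase FIR band-pass of a single-compartment voltage
   trace into the two bands; slow-band phase and fast-band amplitude
   envelope from the analytic (Hilbert) signal.  Phase is mapped to
   [0, 360) degrees; by default 0 marks the slow component's upward
   zero-crossing (its sine phase; peak at 90), a configurable convention
   since the absolute reference is not identifiable from theory.
2. ``phase_amplitude_profile`` - mean envelope <A40>(j) in N phase bins
   (default N = 72, i.e. 5 degree bins), normalized to the distribution
   P(j) = <A40>(j) / sum_k <A40>(k).
3. Metrics on the profile:

   * modulation index  MI = (log N + sum_j P log P) / log N, the
     normalized entropy deficit relative to uniform (0 = no coupling,
     1 = all amplitude in one bin); natural logarithms, 0 log 0 = 0.
   * height ratio  (h_max - h_min) / h_max of the normalized profile.
   * amplitude ratio  Vm(slow) / Vm(fast): sqrt(2) x RMS of the slow
     component over that of the fast component (peak amplitude for pure
     sinusoids).
   * phase of extrema - bin-center phases of the profile maximum and
     minimum (ties break toward the earlier phase).

Traces sampled faster than ~1 kHz are decimated (anti-aliased, zero-phase)
before filtering so the slow-band FIR stays a manageable length; one filter
length at each end of the record is excluded from binning as
edge-contaminated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import signal

__all__ = [
    "BandDecomposition",
    "PhaseAmplitudeProfile",
    "CfcResult",
    "decompose",
    "phase_amplitude_profile",
    "modulation_index",
    "height_ratio",
    "amplitude_ratio",
    "phase_of_extrema",
    "compute_cfc",
    "read_trace_csv",
    "EmptyBinError",
]


class EmptyBinError(ValueError):
    pass


@dataclass
class BandDecomposition:
    t: np.ndarray  # ms (possibly decimated relative to the input)
    theta: np.ndarray  # slow-band component, mV
    gamma: np.ndarray  # fast-band component, mV
    phase_deg: np.ndarray  # slow-band phase, [0, 360)
    envelope: np.ndarray  # fast-band amplitude envelope, mV >= 0
    valid: np.ndarray  # edge-exclusion mask
    theta_band: tuple
    gamma_band: tuple
    fs_hz: float


@dataclass
class PhaseAmplitudeProfile:
    n_bins: int
    edges_deg: np.ndarray  # length n_bins + 1
    mean_amp: np.ndarray  # <A40>(j), mV
    p: np.ndarray  # normalized distribution, sums to 1

    @property
    def centers_deg(self) -> np.ndarray:
        return 0.5 * (self.edges_deg[:-1] + self.edges_deg[1:])


@dataclass
class CfcResult:
    mi: float
    height_ratio: float
    h_max: float
    h_min: float
    amplitude_ratio: float
    phase_max_deg: float
    phase_min_deg: float
    compartment: str | None = None
    meta: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        d = {
            "compartment": self.compartment,
            "mi": self.mi,
            "height_ratio": self.height_ratio,
            "h_max": self.h_max,
            "h_min": self.h_min,
            "amplitude_ratio": self.amplitude_ratio,
            "phase_max_deg": self.phase_max_deg,
            "phase_min_deg": self.phase_min_deg,
        }
        d.update(self.meta)
        return d


def _stage_factors(q: int) -> list[int]:
    """Split a decimation factor into stages of at most 10."""
    factors = []
    while q > 10:
        for d in (10, 8, 7, 6, 5, 4, 3, 2):
            if q % d == 0:
                factors.append(d)
                q //= d
                break
        else:  # prime > 10: fall back to a single large stage
            break
    factors.append(q)
    return [f for f in factors if f > 1]


def decompose(
    t_ms: np.ndarray,
    v: np.ndarray,
    theta_band: tuple = (2.0, 6.0),
    gamma_band: tuple = (30.0, 50.0),
    fs_target_hz: float = 1000.0,
    filter_len_ms: float = 1000.0,
    phase_convention: str = "sine",
) -> BandDecomposition:
    """Band decomposition of one voltage channel (zero-phase filtering).

    ``phase_convention`` fixes the slow-band phase reference, which is not
    identifiable from theory: ``"sine"`` (default) puts 0 deg at the upward
    zero-crossing (the phase of an injected sine; peak at 90 deg),
    ``"peak"`` puts 0 deg at the slow-component maximum.
    """
    t = np.asarray(t_ms, dtype=float)
    v = np.asarray(v, dtype=float)
    if t.size != v.size or t.size < 3:
        raise ValueError("time base and signal must be equal-length, >= 3 samples")
    fs = 1000.0 / (t[1] - t[0])

    q = int(fs // fs_target_hz)
    if q > 1:
        for f in _stage_factors(q):
            v = signal.decimate(v, f, ftype="fir", zero_phase=True)
        t = t[0] + np.arange(v.size) * (q / fs) * 1000.0
        fs = fs / q

    nyq = fs / 2.0
    if gamma_band[1] >= nyq or theta_band[1] >= nyq:
        raise ValueError(f"band edges exceed Nyquist ({nyq:.1f} Hz)")
    if fs < 20.0 * (gamma_band[0] + gamma_band[1]) / 2.0:
        raise ValueError("sampling rate below 20x the fast-band frequency")

    numtaps = int(filter_len_ms * fs / 1000.0) // 2 * 2 + 1
    min_len = 2000.0 / theta_band[0]  # two slow cycles, ms
    if (t[-1] - t[0]) < min_len + 2 * filter_len_ms:
        raise ValueError(
            "window too short: need two slow-band cycles plus filter edges"
        )

    v = v - v.mean()
    th_taps = signal.firwin(numtaps, theta_band, fs=fs, pass_zero=False)
    ga_taps = signal.firwin(numtaps, gamma_band, fs=fs, pass_zero=False)
    padlen = min(numtaps, v.size - 1)
    theta = signal.filtfilt(th_taps, 1.0, v, padlen=padlen)
    gamma = signal.filtfilt(ga_taps, 1.0, v, padlen=padlen)

    offset = {"sine": 90.0, "peak": 0.0}
    if phase_convention not in offset:
        raise ValueError(f"unknown phase convention {phase_convention!r}")
    phase = (
        np.rad2deg(np.angle(signal.hilbert(theta))) + offset[phase_convention]
    ) % 360.0
    env = np.abs(signal.hilbert(gamma))
    valid = np.zeros(v.size, dtype=bool)
    valid[numtaps:-numtaps] = True
    return BandDecomposition(
        t=t, theta=theta, gamma=gamma, phase_deg=phase, envelope=env,
        valid=valid, theta_band=tuple(theta_band), gamma_band=tuple(gamma_band),
        fs_hz=fs,
    )


def _window_mask(decomp: BandDecomposition, start_ms, stop_ms) -> np.ndarray:
    mask = decomp.valid.copy()
    if start_ms is not None:
        mask &= decomp.t >= start_ms
    if stop_ms is not None:
        mask &= decomp.t < stop_ms
    if not mask.any():
        raise ValueError("analysis window contains no valid samples")
    return mask


def phase_amplitude_profile(
    decomp: BandDecomposition,
    n_bins: int = 72,
    start_ms: float | None = None,
    stop_ms: float | None = None,
) -> PhaseAmplitudeProfile:
    """Mean fast-band envelope per slow-band phase bin, normalized."""
    if n_bins < 2:
        raise ValueError("need at least 2 phase bins")
    mask = _window_mask(decomp, start_ms, stop_ms)
    if float(np.sqrt(np.mean(decomp.theta[mask] ** 2))) < 1e-9:
        raise ValueError(
            "slow-band component is (near) zero; its phase is undefined"
        )
    phase = decomp.phase_deg[mask]
    env = decomp.envelope[mask]
    edges = np.linspace(0.0, 360.0, n_bins + 1)
    which = np.minimum((phase / (360.0 / n_bins)).astype(int), n_bins - 1)
    counts = np.bincount(which, minlength=n_bins)
    if (counts == 0).any():
        empty = int(np.argmax(counts == 0))
        raise EmptyBinError(
            f"phase bin {empty} received no samples; analyze a longer window "
            f"or use fewer bins"
        )
    sums = np.bincount(which, weights=env, minlength=n_bins)
    mean_amp = sums / counts
    total = mean_amp.sum()
    if total <= 0:
        raise ValueError("fast-band envelope is identically zero")
    return PhaseAmplitudeProfile(n_bins, edges, mean_amp, mean_amp / total)


def modulation_index(profile: PhaseAmplitudeProfile) -> float:
    """Normalized entropy deficit of P relative to uniform (0..1)."""
    p = profile.p
    plogp = np.where(p > 0, p * np.log(np.where(p > 0, p, 1.0)), 0.0)
    mi = (math.log(profile.n_bins) + plogp.sum()) / math.log(profile.n_bins)
    return float(min(max(mi, 0.0), 1.0))


def height_ratio(profile: PhaseAmplitudeProfile) -> float:
    """(h_max - h_min) / h_max of the normalized profile (0..1)."""
    h_max = float(profile.p.max())
    if h_max <= 0:
        raise ValueError("all-zero profile has no height ratio")
    return (h_max - float(profile.p.min())) / h_max


def amplitude_ratio(
    decomp: BandDecomposition,
    start_ms: float | None = None,
    stop_ms: float | None = None,
) -> float:
    """Slow-band over fast-band amplitude (sqrt(2) x RMS of each)."""
    mask = _window_mask(decomp, start_ms, stop_ms)
    a_slow = np.sqrt(2.0 * np.mean(decomp.theta[mask] ** 2))
    a_fast = np.sqrt(2.0 * np.mean(decomp.gamma[mask] ** 2))
    if a_fast == 0:
        raise ValueError("fast-band component is zero; amplitude ratio undefined")
    return float(a_slow / a_fast)


def phase_of_extrema(profile: PhaseAmplitudeProfile) -> dict:
    """Bin-center phases of the profile max and min (first = earlier wins)."""
    centers = profile.centers_deg
    return {
        "phase_max": float(centers[int(np.argmax(profile.p))]),
        "phase_min": float(centers[int(np.argmin(profile.p))]),
    }


def compute_cfc(
    t_ms: np.ndarray,
    v: np.ndarray,
    n_bins: int = 72,
    start_ms: float | None = None,
    stop_ms: float | None = None,
    compartment: str | None = None,
    **decompose_kwargs,
) -> CfcResult:
    """Full pipeline on one voltage channel."""
    dec = decompose(t_ms, v, **decompose_kwargs)
    prof = phase_amplitude_profile(dec, n_bins, start_ms, stop_ms)
    ext = phase_of_extrema(prof)
    return CfcResult(
        mi=modulation_index(prof),
        height_ratio=height_ratio(prof),
        h_max=float(prof.p.max()),
        h_min=float(prof.p.min()),
        amplitude_ratio=amplitude_ratio(dec, start_ms, stop_ms),
        phase_max_deg=ext["phase_max"],
        phase_min_deg=ext["phase_min"],
        compartment=compartment,
        meta={"n_bins": n_bins},
    )


def read_trace_csv(path) -> pd.DataFrame:
    """Read a trace CSV (time_ms column + one mV column per compartment)."""
    return pd.read_csv(path, comment="#")
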