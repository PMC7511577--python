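"""Shared fixtures: tiny hand-built models and synthetic decompositions."""

from __future__ import annotations

import math

import numpy as np
import pytest

from dendrocfc.cfc import BandDecomposition
from dendrocfc.conductances import load_conductance_table
from dendrocfc.model import ModelConfig, PassiveParams
from dendrocfc.kinetics import load_kinetics
from dendrocfc.morphology import Compartment


def passive_compartment(area_cm2: float, comp_id: str = "soma",
                        parent: str | None = None, level: int = 2,
                        diameter_um: float = 10.0,
                        start: float = 0.0) -> Compartment:
    """Cylinder with a prescribed membrane area."""
    length = area_cm2 / (math.pi * diameter_um * 1e-8)
    return Compartment(comp_id, level, length, diameter_um, start, parent)


def make_passive_model(
    r_mohm: float = 100.0,
    cm_uf: float = 1.0,
    e_leak: float = -70.0,
    area_cm2: float = 1e-5,
) -> ModelConfig:
    """Isolated passive compartment with input resistance ``r_mohm``.

    g_leak is chosen so 1/(g_leak * area) equals the requested resistance;
    all active densities are zero (density_scale = 0).
    """
    g_total_ms = 1e-3 / r_mohm  # mS
    passive = PassiveParams(cm=cm_uf, ra=100.0, g_leak=g_total_ms / area_cm2,
                            e_leak=e_leak, density_scale=0.0)
    comp = passive_compartment(area_cm2)
    return ModelConfig("none", [comp], load_conductance_table(), passive,
                       load_kinetics())


def make_passive_chain(n: int, area_cm2: float = 1e-5,
                       g_leak: float = 0.1, ra: float = 150.0,
                       e_leak: float = -70.0) -> ModelConfig:
    """Unbranched passive cable of ``n`` identical compartments."""
    comps = [passive_compartment(area_cm2, "c0")]
    for i in range(1, n):
        comps.append(
            passive_compartment(area_cm2, f"c{i}", parent=f"c{i-1}",
                                level=2, start=float(i))
        )
    passive = PassiveParams(cm=1.0, ra=ra, g_leak=g_leak, e_leak=e_leak,
                            density_scale=0.0)
    return ModelConfig("none", comps, load_conductance_table(), passive,
                       load_kinetics())


def synthetic_decomposition(envelope_of_phase, n_samples: int = 200_000,
                            theta_amp: float = 1.0) -> BandDecomposition:
    """Decomposition with a prescribed envelope as a function of phase.

    Phase sweeps [0, 360) uniformly and densely, bypassing any filtering,
    so profile tests can be checked against quadrature oracles.
    """
    phase = np.linspace(0.0, 360.0, n_samples, endpoint=False)
    env = np.asarray(envelope_of_phase(phase), dtype=float)
    t = np.arange(n_samples) * 1.0
    theta = theta_amp * np.cos(np.deg2rad(phase))
    return BandDecomposition(
        t=t, theta=theta, gamma=env, phase_deg=phase, envelope=env,
        valid=np.ones(n_samples, dtype=bool),
        theta_band=(2.0, 6.0), gamma_band=(30.0, 50.0), fs_hz=1000.0,
    )


@pytest.fixture(scope="session")
def conductance_table():
    return load_conductance_table()
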