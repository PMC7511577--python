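"""Assemble the three model neurons.

The three models share morphology, passive parameters, kinetics, and every
non-h conductance density; they differ only in which h-current column of
the density table is active:

* ``exp_gradient`` - density rising exponentially along the soma-apical
  axis (as in layer-5 and CA1 pyramidal neurons),
* ``uniform``      - near-uniform density,
* ``none``         - no h-current (pharmacological block).

Relative table densities are multiplied by a single global
``density_scale``; that scale, the uniform leak, the leak and h reversal
potentials, and the axial resistivity come from a calibration file fixed
once against the target input resistances and resting range
(``data/calibrated.yaml``, regenerated by ``scripts/calibrate.py``).
"""

from __future__ import annotations

import copy
import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from . import conductances as ctab
from . import kinetics as kin
from .morphology import (
    Compartment,
    MorphologySpec,
    build_morphology,
    resolve_compartment,
)

__all__ = ["PassiveParams", "ModelConfig", "build_model", "load_calibration",
           "IH_MODES"]

IH_MODES = ("exp_gradient", "uniform", "none")


@dataclass
class PassiveParams:
    cm: float = 0.9  # uF/cm^2
    ra: float = 250.0  # ohm cm
    g_leak: float = 0.10  # mS/cm^2, uniform across compartments
    e_leak: float = -85.0  # mV
    density_scale: float = 0.03  # mS/cm^2 per table unit


def load_calibration(source=None) -> dict:
    if source is None:
        ref = importlib.resources.files("dendrocfc.data") / "calibrated.yaml"
        with ref.open("r") as fh:
            return yaml.safe_load(fh)
    with open(source) as fh:
        return yaml.safe_load(fh)


@dataclass
class ModelConfig:
    """Full specification of one model neuron."""

    ih_mode: str
    morphology: list[Compartment]
    table: pd.DataFrame
    passive: PassiveParams
    kinetics: dict
    channels: dict[str, kin.ChannelSpec] = field(repr=False, default=None)

    def __post_init__(self):
        if self.channels is None:
            self.channels = kin.build_channels(self.kinetics)
        self._index = {c.id: i for i, c in enumerate(self.morphology)}

    @property
    def reversals(self) -> dict:
        rev = dict(self.kinetics["reversals"])
        rev["E_leak"] = self.passive.e_leak
        return rev

    @property
    def n_compartments(self) -> int:
        return len(self.morphology)

    def index(self, comp_id: str) -> int:
        comp_id = resolve_compartment(comp_id)
        try:
            return self._index[comp_id]
        except KeyError:
            raise KeyError(f"unknown compartment id: {comp_id!r}") from None

    def compartment(self, comp_id: str) -> Compartment:
        return self.morphology[self.index(comp_id)]

    def density(self, comp_id: str, channel: str) -> float:
        """Scaled conductance density (mS/cm^2) of ``channel`` at a site."""
        comp = self.compartment(comp_id)
        if channel == "leak":
            return self.passive.g_leak
        if channel == "h":
            col = ctab.ih_column_for_mode(self.ih_mode)
        else:
            cols = {v: k for k, v in ctab.CHANNEL_FOR_COLUMN.items()}
            try:
                col = cols[channel]
            except KeyError:
                raise KeyError(f"unknown channel {channel!r}") from None
        return float(self.table.loc[comp.level, col]) * self.passive.density_scale

    def density_matrix(self) -> pd.DataFrame:
        """Per-compartment scaled densities, one column per active channel."""
        rows = {}
        chans = list(ctab.CHANNEL_FOR_COLUMN.values()) + ["h"]
        for c in self.morphology:
            rows[c.id] = {ch: self.density(c.id, ch) for ch in chans}
        return pd.DataFrame.from_dict(rows, orient="index")[chans]

    def provenance(self) -> dict:
        p = self.passive
        return {
            "ih_mode": self.ih_mode,
            "kinetics_version": self.kinetics.get("version"),
            "density_scale": p.density_scale,
            "g_leak": p.g_leak,
            "e_leak": p.e_leak,
            "e_h": self.kinetics["reversals"]["E_h"],
            "ra": p.ra,
            "cm": p.cm,
        }


def build_model(
    ih_mode: str,
    passive_overrides: dict | None = None,
    morphology_spec: MorphologySpec | None = None,
    table: pd.DataFrame | None = None,
    kinetics: dict | None = None,
    calibration: dict | str | None = None,
) -> ModelConfig:
    """Build one of the three model neurons.

    ``calibration`` may be a dict, a path, or None for the packaged
    calibrated parameter set; ``passive_overrides`` (keys of
    :class:`PassiveParams` plus ``e_h``) take precedence over it.
    """
    if ih_mode not in IH_MODES:
        raise ValueError(f"unknown ih_mode {ih_mode!r}; expected one of {IH_MODES}")
    if calibration is None or isinstance(calibration, str):
        calibration = load_calibration(calibration)
    overrides = dict(passive_overrides or {})

    pp = PassiveParams(
        cm=float(calibration.get("cm", 0.9)),
        ra=float(calibration.get("ra", 250.0)),
        g_leak=float(calibration.get("g_leak", 0.10)),
        e_leak=float(calibration.get("e_leak", -85.0)),
        density_scale=float(calibration.get("density_scale", 0.03)),
    )
    e_h = float(overrides.pop("e_h", calibration.get("e_h", -40.0)))
    ih_vhalf = overrides.pop("ih_vhalf", calibration.get("ih_vhalf"))
    ih_slope = overrides.pop("ih_slope", calibration.get("ih_slope"))
    geo = {}
    for key, attrs in {
        "soma_diameter": ("soma_diameter",),
        "basal_diameter": ("basal_diameter",),
        "apical_diam_proximal": ("apical_diam_proximal",),
        "distal_diameter": ("apical_diam_distal", "tuft_diameter"),
    }.items():
        val = overrides.pop(key, calibration.get(key))
        if val is not None:
            for a in attrs:
                geo[a] = float(val)
    for k, v in overrides.items():
        if not hasattr(pp, k):
            raise ValueError(f"unknown passive parameter {k!r}")
        setattr(pp, k, float(v))
    if morphology_spec is None and geo:
        morphology_spec = MorphologySpec(**geo)

    kin_cfg = copy.deepcopy(kinetics or kin.load_kinetics())
    kin_cfg["reversals"]["E_h"] = e_h
    # calibrated position/steepness of the h-gate activation curve; the
    # negative sign keeps the gate hyperpolarization-activated
    if ih_vhalf is not None:
        kin_cfg["channels"]["h"]["gates"][0]["vhalf"] = float(ih_vhalf)
    if ih_slope is not None:
        kin_cfg["channels"]["h"]["gates"][0]["slope"] = -abs(float(ih_slope))

    morph = build_morphology(morphology_spec)
    tbl = table if table is not None else ctab.load_conductance_table()
    levels = {c.level for c in morph}
    missing = levels - set(tbl.index)
    if missing:
        raise ValueError(f"morphology uses levels absent from table: {missing}")
    return ModelConfig(ih_mode, morph, tbl, pp, kin_cfg)
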