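"""Reduced pyramidal-neuron morphology.

The neuron is a soma with three attached cables: a 13-compartment apical
shaft continuing into a 3-compartment tuft (soma to tuft end spans
0-1200 um), a short basal chain, and a two-compartment axonal stub.  Each
compartment is an iso-potential cylinder assigned to one of the 21
conductance levels of the density table (see :mod:`dendrocfc.conductances`).

The level assignment used throughout the package:

====================  ==========
compartment           level
====================  ==========
axon2, axon1          0, 1
soma                  2
basal1..basal3        3..5
apdend1..apdend13     6..18
tuft1, tuft2          19
tuft3                 20
====================  ==========

``start_distance`` is measured from the soma along the soma-apical axis
(the beginning of each compartment); basal and axonal compartments carry
negative values to mark the other side of the soma.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "Compartment",
    "MorphologySpec",
    "build_morphology",
    "level_for_compartment",
    "apical_axis_ids",
    "resolve_compartment",
]

#: Convenience aliases for commonly referenced sites.
ALIASES = {
    "tuft_last": "tuft3",
    "base_apical": "apdend1",
    "middle_apical": "apdend7",
    "distal_apical": "apdend12",
}


@dataclass(frozen=True)
class Compartment:
    """One iso-potential cylinder of the reduced morphology."""

    id: str
    level: int
    length: float  # um
    diameter: float  # um
    start_distance: float  # um from soma along the soma-apical axis
    parent: str | None  # id of the compartment this one attaches to

    @property
    def area_cm2(self) -> float:
        """Lateral membrane area in cm^2."""
        import math

        return math.pi * self.diameter * self.length * 1e-8

    @property
    def cross_section_cm2(self) -> float:
        """Axial cross-sectional area in cm^2."""
        import math

        return math.pi * (self.diameter / 2.0) ** 2 * 1e-8


@dataclass
class MorphologySpec:
    """Geometry block; every dimension in um, all overridable.

    The apical shaft is 13 cylinders of ``apical_length`` with diameter
    tapering linearly from ``apical_diam_proximal`` at the soma end to
    ``apical_diam_distal`` at the tuft end; the tuft continues at the
    distal diameter for three more cylinders, so the apical axis covers
    0-1200 um and apdend12 begins 825 um from the soma.
    """

    soma_length: float = 30.0
    soma_diameter: float = 20.0
    n_apical: int = 13
    apical_length: float = 75.0
    apical_diam_proximal: float = 6.0
    apical_diam_distal: float = 3.0
    n_tuft: int = 3
    tuft_length: float = 75.0
    tuft_diameter: float = 3.0
    n_basal: int = 3
    basal_length: float = 60.0
    basal_diameter: float = 4.0
    n_axon: int = 2
    axon_length: float = 50.0
    axon_diameter: float = 2.0


class UnknownCompartmentError(KeyError):
    pass


def build_morphology(spec: MorphologySpec | None = None) -> list[Compartment]:
    """Build the compartment list (apical axis first, then basal and axon)."""
    spec = spec or MorphologySpec()
    comps: list[Compartment] = []
    comps.append(
        Compartment("soma", 2, spec.soma_length, spec.soma_diameter, 0.0, None)
    )
    # apical shaft, levels 6..(5 + n_apical), linear diameter taper
    for k in range(1, spec.n_apical + 1):
        if spec.n_apical > 1:
            frac = (k - 1) / (spec.n_apical - 1)
        else:
            frac = 0.0
        diam = spec.apical_diam_proximal + frac * (
            spec.apical_diam_distal - spec.apical_diam_proximal
        )
        comps.append(
            Compartment(
                f"apdend{k}",
                5 + k,
                spec.apical_length,
                diam,
                (k - 1) * spec.apical_length,
                "soma" if k == 1 else f"apdend{k - 1}",
            )
        )
    # tuft: all but the last compartment at level 19, the last at level 20
    tuft_start = spec.n_apical * spec.apical_length
    for k in range(1, spec.n_tuft + 1):
        comps.append(
            Compartment(
                f"tuft{k}",
                20 if k == spec.n_tuft else 19,
                spec.tuft_length,
                spec.tuft_diameter,
                tuft_start + (k - 1) * spec.tuft_length,
                f"apdend{spec.n_apical}" if k == 1 else f"tuft{k - 1}",
            )
        )
    # basal chain, levels 3..5
    for k in range(1, spec.n_basal + 1):
        comps.append(
            Compartment(
                f"basal{k}",
                2 + k,
                spec.basal_length,
                spec.basal_diameter,
                -k * spec.basal_length,
                "soma" if k == 1 else f"basal{k - 1}",
            )
        )
    # axonal stub, axon1 (adjacent to soma) level 1, axon2 level 0
    for k in range(1, spec.n_axon + 1):
        comps.append(
            Compartment(
                f"axon{k}",
                spec.n_axon - k,
                spec.axon_length,
                spec.axon_diameter,
                -k * spec.axon_length,
                "soma" if k == 1 else f"axon{k - 1}",
            )
        )
    return comps


def resolve_compartment(comp_id: str) -> str:
    """Map site aliases (e.g. ``tuft_last``) to canonical compartment ids."""
    return ALIASES.get(comp_id, comp_id)


def level_for_compartment(
    morphology: list[Compartment], comp_id: str
) -> int:
    """Density-table level of a compartment (alias-aware)."""
    comp_id = resolve_compartment(comp_id)
    for c in morphology:
        if c.id == comp_id:
            return c.level
    raise UnknownCompartmentError(f"unknown compartment id: {comp_id!r}")


def apical_axis_ids(morphology: list[Compartment]) -> list[str]:
    """Soma + apical shaft + tuft ids ordered by distance from the soma."""
    axis = [c for c in morphology if c.start_distance >= 0.0]
    axis.sort(key=lambda c: (c.start_distance, c.id != "soma"))
    return [c.id for c in axis]
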