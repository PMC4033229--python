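"""Material specifications for kernel transport.

A :class:`MediumSpec` is an elemental mass-fraction composition plus a mass
density.  The stopping-power model needs only two derived quantities: the
mean ratio Z/A (electrons per dalton) and the mean excitation energy I,
combined from elemental I-values by the usual Bragg ln-additivity rule.

The default medium is a four-component soft-tissue analogue for liver with
density 1.04 g/mL; density is an explicit parameter because the conversion
factor K scales inversely with it.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict

from .errors import InvalidParameterError

#: element -> (Z, atomic mass A [g/mol], mean excitation energy I [eV])
ELEMENT_DATA = {
    "H": (1, 1.008, 19.2),
    "C": (6, 12.011, 78.0),
    "N": (7, 14.007, 82.0),
    "O": (8, 15.999, 95.0),
    "Na": (11, 22.990, 149.0),
    "P": (15, 30.974, 173.0),
    "S": (16, 32.06, 180.0),
    "Cl": (17, 35.45, 174.0),
    "K": (19, 39.098, 190.0),
}


@dataclass(frozen=True)
class MediumSpec:
    """Homogeneous medium: name, density and elemental composition.

    Parameters
    ----------
    name : str
    density_kg_per_ml : float
        Mass density in kg/mL (water = 1.0e-3).
    composition : dict
        Element symbol -> mass fraction; fractions must sum to 1 within 1e-6.
    """

    name: str
    density_kg_per_ml: float
    composition: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.density_kg_per_ml <= 0:
            raise InvalidParameterError("medium density must be positive")
        total = sum(self.composition.values())
        if abs(total - 1.0) > 1e-6:
            raise InvalidParameterError(
                f"mass fractions sum to {total!r}, expected 1 within 1e-6"
            )
        unknown = set(self.composition) - set(ELEMENT_DATA)
        if unknown:
            raise InvalidParameterError(f"unknown elements: {sorted(unknown)}")

    @property
    def density_g_per_ml(self) -> float:
        return self.density_kg_per_ml * 1e3

    def mean_z_over_a(self) -> float:
        """⟨Z/A⟩ in mol electrons per gram."""
        return sum(
            w * ELEMENT_DATA[el][0] / ELEMENT_DATA[el][1]
            for el, w in self.composition.items()
        )

    def mean_excitation_energy_ev(self) -> float:
        """Bragg-additivity mean excitation energy, eV."""
        za = self.mean_z_over_a()
        ln_i = (
            sum(
                w * ELEMENT_DATA[el][0] / ELEMENT_DATA[el][1] * math.log(ELEMENT_DATA[el][2])
                for el, w in self.composition.items()
            )
            / za
        )
        return math.exp(ln_i)

    def radiation_length_g_cm2(self) -> float:
        """Radiation length X₀ [g/cm²] by elemental additivity (Tsai-style
        approximation, adequate for the multiple-scattering term)."""
        inv = 0.0
        for el, w in self.composition.items():
            z, a, _ = ELEMENT_DATA[el]
            x0_el = 716.408 * a / (z * (z + 1.0) * math.log(287.0 / math.sqrt(z)))
            inv += w / x0_el
        return 1.0 / inv


#: four-component soft-tissue analogue used as the liver default (1.04 g/mL)
LIVER = MediumSpec(
    name="liver",
    density_kg_per_ml=1.04e-3,
    composition={"H": 0.101172, "C": 0.111000, "N": 0.026000, "O": 0.761828},
)

WATER = MediumSpec(
    name="water",
    density_kg_per_ml=1.0e-3,
    composition={"H": 0.111894, "O": 0.888106},
)
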