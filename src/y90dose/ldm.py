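"""Local Deposition Method (LDM) dosimetry.

Radioembolization is treated as a permanent implant: all activity decays in
place and every β particle deposits its energy within the voxel of decay.
The committed absorbed dose in a voxel with initial activity concentration
A₀ [Bq/mL] is then

    D [Gy] = A₀ · K_X · exp(λ_c · t)

where K_X = K_⁹⁰Y · β_X / β_⁹⁰Y converts for the surrogate radionuclide the
scanner was configured for (²²Na, ⁸⁶Y or ⁶⁸Ge when ⁹⁰Y is unavailable in
the console software), λ_c = λ_⁹⁰Y − λ_X corrects the scanner's surrogate
decay correction back to the true ⁹⁰Y decay over the infusion-to-scan delay
t [h], and

    K_⁹⁰Y = E_avg / (λ ρ_liver)  [Gy·mL/Bq].

The shipped registry carries the printed constants verbatim (canonical for
output); :func:`derive_nuclide_params` recomputes every row from first
principles for validation.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from typing import Dict, Optional, Union

import numpy as np

from . import constants as c
from .errors import DataQualityError, InvalidParameterError, UnknownNuclideError
from .grids import ActivityGrid, DoseGrid, require_activity


@dataclass(frozen=True)
class NuclideParams:
    """Conversion-table row for one imaging radionuclide."""

    name: str
    decay_constant_per_h: float       # lambda_X
    positron_branching: float         # beta_X
    adjusted_decay_constant_per_h: float  # lambda_c = lambda_90Y - lambda_X
    k_factor: float                   # K_X, Gy*mL/Bq

    def __post_init__(self) -> None:
        if self.decay_constant_per_h <= 0:
            raise InvalidParameterError("decay constant must be positive")
        if not 0 < self.positron_branching <= 1:
            raise InvalidParameterError("positron branching must be in (0, 1]")
        if self.k_factor <= 0:
            raise InvalidParameterError("K factor must be positive")


#: canonical conversion table (printed values, bit-exact)
NUCLIDE_REGISTRY: Dict[str, NuclideParams] = {
    "90Y": NuclideParams("90Y", c.Y90_DECAY_CONSTANT_PER_H, c.Y90_POSITRON_BRANCHING,
                         0.0, c.Y90_K_FACTOR),
    "22Na": NuclideParams("22Na", 3.038e-5, 0.905, 1.080e-2, 1.353),
    "86Y": NuclideParams("86Y", 4.702e-2, 0.319, -3.619e-2, 0.4767),
    # 68Ge is imaged through its daughter 68Ga (secular equilibrium);
    # the branching is that of 68Ga.
    "68Ge": NuclideParams("68Ge", 1.066e-4, 0.890, 1.072e-2, 1.330),
}


def get_nuclide(name: str) -> NuclideParams:
    try:
        return NUCLIDE_REGISTRY[name]
    except KeyError:
        raise UnknownNuclideError(
            f"unknown nuclide {name!r}; known: {sorted(NUCLIDE_REGISTRY)}"
        ) from None


@dataclass(frozen=True)
class LdmConstants:
    """⁹⁰Y constants behind the conversion factor.

    Defaults are the printed values; pass a spectrum-derived mean energy or
    a different liver density to re-derive the chain.
    """

    mean_energy_j: float = c.Y90_MEAN_ENERGY_J
    half_life_h: float = c.Y90_HALF_LIFE_H
    decay_constant_per_h: float = c.Y90_DECAY_CONSTANT_PER_H
    liver_density_kg_per_ml: float = 1.04e-3

    def __post_init__(self) -> None:
        if min(self.mean_energy_j, self.half_life_h, self.decay_constant_per_h,
               self.liver_density_kg_per_ml) <= 0:
            raise InvalidParameterError("all LDM constants must be positive")
        derived = math.log(2.0) / self.half_life_h
        if abs(derived - self.decay_constant_per_h) / derived > 0.005:
            raise InvalidParameterError(
                f"decay constant {self.decay_constant_per_h:.4e} inconsistent with "
                f"half-life {self.half_life_h} h (ln2/T = {derived:.4e}) beyond 0.5%"
            )


def committed_energy_coefficient(constants: LdmConstants = LdmConstants()) -> float:
    """E_avg / λ with λ per second: J·s, i.e. committed J/mL per (Bq/mL)."""
    lam_per_s = constants.decay_constant_per_h / c.SECONDS_PER_HOUR
    return constants.mean_energy_j / lam_per_s


def k_factor_y90(constants: LdmConstants = LdmConstants()) -> float:
    """K_⁹⁰Y = committed-energy coefficient / liver density [Gy·mL/Bq]."""
    return committed_energy_coefficient(constants) / constants.liver_density_kg_per_ml


def surrogate_k_factor(k_y90: float, branching_x: float,
                       branching_y90: float = c.Y90_POSITRON_BRANCHING) -> float:
    """K_X = K_⁹⁰Y · β_X / β_⁹⁰Y."""
    if branching_x <= 0 or branching_x > 1 or branching_y90 <= 0 or branching_y90 > 1:
        raise InvalidParameterError("branching fractions must be in (0, 1]")
    return k_y90 * branching_x / branching_y90


def adjusted_decay_constant(lambda_y90: float, lambda_x: float) -> float:
    """λ_c = λ_⁹⁰Y − λ_X [h⁻¹]; negative for shorter-lived surrogates."""
    if lambda_y90 <= 0 or lambda_x <= 0:
        raise InvalidParameterError("decay constants must be positive")
    return lambda_y90 - lambda_x


def derive_nuclide_params(name: str, constants: LdmConstants = LdmConstants()) -> NuclideParams:
    """Recompute a registry row from λ_X, β_X and the canonical K_⁹⁰Y.

    Used to validate the printed table; the registry itself is canonical.
    """
    printed = get_nuclide(name)
    k90 = get_nuclide("90Y").k_factor
    if name == "90Y":
        k_x = k_factor_y90(constants)
        lam_c = 0.0
    else:
        k_x = surrogate_k_factor(k90, printed.positron_branching)
        lam_c = adjusted_decay_constant(constants.decay_constant_per_h,
                                        printed.decay_constant_per_h)
    return NuclideParams(name, printed.decay_constant_per_h,
                         printed.positron_branching, lam_c, k_x)


def ldm_dose(
    activity: ActivityGrid,
    nuclide: Union[str, NuclideParams] = "90Y",
    delay_hours: Optional[float] = None,
    *,
    negative_tolerance: float = 1.0,
) -> DoseGrid:
    """Voxelwise D = A₀ · K_X · exp(λ_c · t).

    Parameters
    ----------
    activity : ActivityGrid
        Values in Bq/mL.  Small reconstruction negatives in
        [−negative_tolerance, 0) Bq/mL are clipped to zero; anything more
        negative raises :class:`DataQualityError`.
    nuclide : str or NuclideParams
        Registry name (e.g. "90Y", "22Na") or explicit parameters.
    delay_hours : float, optional
        Infusion-to-scan delay t; defaults to `activity.scan_delay_h`.
        Irrelevant for native ⁹⁰Y imaging (λ_c = 0).
    """
    activity = require_activity(activity)
    params = get_nuclide(nuclide) if isinstance(nuclide, str) else nuclide
    t = activity.scan_delay_h if delay_hours is None else float(delay_hours)
    if t < 0:
        raise InvalidParameterError("delay_hours must be non-negative")

    values = activity.values
    worst = values.min()
    if worst < -negative_tolerance:
        raise DataQualityError(
            f"activity has voxels down to {worst:.3g} Bq/mL, below the "
            f"-{negative_tolerance:g} Bq/mL tolerance"
        )
    clean = np.where(values < 0, 0.0, values)

    dose = clean * params.k_factor * math.exp(params.adjusted_decay_constant_per_h * t)
    return DoseGrid(values=dose, voxel_size=activity.voxel_size,
                    origin=activity.origin, method_label="LDM")


def registry_json() -> str:
    """The nuclide registry as a JSON document (printed values)."""
    rows = {
        name: {
            "decay_constant_per_h": p.decay_constant_per_h,
            "positron_branching": p.positron_branching,
            "adjusted_decay_constant_per_h": p.adjusted_decay_constant_per_h,
            "k_factor_gy_ml_per_bq": p.k_factor,
        }
        for name, p in NUCLIDE_REGISTRY.items()
    }
    return json.dumps(rows, indent=2)
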