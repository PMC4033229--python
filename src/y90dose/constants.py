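"""Physical constants and the canonical ⁹⁰Y decay data used throughout.

Two families of numbers live here and are deliberately kept apart:

* fundamental constants (CODATA) used by the spectrum/kernel physics, and
* the *printed* ⁹⁰Y dosimetry constants that the local-deposition conversion
  table ships with (half-life 64.24 h, E_avg 1.498e-13 J, K 4.782e-5
  Gy·mL/Bq).  The printed values are canonical for user-facing output; the
  physics modules re-derive them independently for validation.
"""

import math

# --- fundamental constants -------------------------------------------------
ELECTRON_REST_MEV = 0.51099895          # electron rest energy, MeV
FINE_STRUCTURE = 1.0 / 137.035999084    # fine-structure constant
MEV_TO_J = 1.602176634e-13              # MeV -> joule
REDUCED_COMPTON_FM = 386.15926796       # hbar / (m_e c), femtometre
NUCLEAR_RADIUS_FM = 1.2                 # r0 in R = r0 * A^(1/3)

SECONDS_PER_HOUR = 3600.0

# --- canonical Y-90 decay data --------------------------------------------
Y90_ENDPOINT_MEV = 2.280        # beta endpoint (Q value to 90Zr ground state)
Y90_DAUGHTER_Z = 40             # zirconium
Y90_MASS_NUMBER = 90
Y90_HALF_LIFE_H = 64.24
Y90_POSITRON_BRANCHING = 3.2e-5  # internal pair branch used for PET imaging

# Printed (canonical) values for the conversion-factor chain.
Y90_DECAY_CONSTANT_PER_H = 1.083e-2     # h^-1 (printed; ln2/64.24 = 1.079e-2)
Y90_MEAN_ENERGY_J = 1.498e-13           # J per decay (0.935 MeV)
Y90_COMMITTED_ENERGY_COEFF_JS = 4.986e-8  # J*s, E_avg / lambda(s^-1)
Y90_K_FACTOR = 4.782e-5                 # Gy*mL/Bq in liver


def decay_constant_from_half_life(half_life_h: float) -> float:
    """ln(2)/T½ in h⁻¹."""
    return math.log(2.0) / half_life_h
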