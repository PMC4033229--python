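"""Local-deposition conversion chain: constants, registry, dose operator."""

import math

import numpy as np
import pytest

from y90dose import (
    ActivityGrid,
    LdmConstants,
    NUCLIDE_REGISTRY,
    adjusted_decay_constant,
    committed_energy_coefficient,
    derive_nuclide_params,
    get_nuclide,
    k_factor_y90,
    ldm_dose,
    surrogate_k_factor,
)
from y90dose.errors import (
    DataQualityError,
    InvalidParameterError,
    UnknownNuclideError,
)
from y90dose.ldm import registry_json


class TestRegistry:
    """The shipped table carries the printed constants verbatim."""

    @pytest.mark.parametrize(
        "name,branching,lam,lam_c,k",
        [
            ("90Y", 0.000032, 1.083e-2, 0.0, 4.782e-5),
            ("22Na", 0.905, 3.038e-5, 1.080e-2, 1.353),
            ("86Y", 0.319, 4.702e-2, -3.619e-2, 0.4767),
            ("68Ge", 0.890, 1.066e-4, 1.072e-2, 1.330),
        ],
    )
    def test_printed_rows_are_bit_exact(self, name, branching, lam, lam_c, k):
        p = get_nuclide(name)
        assert p.positron_branching == branching
        assert p.decay_constant_per_h == lam
        assert p.adjusted_decay_constant_per_h == lam_c
        assert p.k_factor == k

    def test_unknown_nuclide(self):
        with pytest.raises(UnknownNuclideError):
            get_nuclide("18F")

    def test_registry_json_contains_all_rows(self):
        import json

        doc = json.loads(registry_json())
        assert set(doc) == set(NUCLIDE_REGISTRY)
        assert doc["22Na"]["k_factor_gy_ml_per_bq"] == 1.353


class TestDerivationChain:
    def test_committed_energy_coefficient(self):
        """E_avg/λ = 4.986e-8 J·s within 0.5%."""
        assert committed_energy_coefficient() == pytest.approx(4.986e-8, rel=0.005)

    def test_coefficient_linearity_in_mean_energy(self):
        base = LdmConstants()
        doubled = LdmConstants(mean_energy_j=base.mean_energy_j * 2)
        assert committed_energy_coefficient(doubled) == pytest.approx(
            2 * committed_energy_coefficient(base), rel=1e-12
        )

    def test_coefficient_inverse_in_decay_constant(self):
        base = LdmConstants()
        faster = LdmConstants(half_life_h=base.half_life_h / 2,
                              decay_constant_per_h=base.decay_constant_per_h * 2)
        assert committed_energy_coefficient(faster) == pytest.approx(
            committed_energy_coefficient(base) / 2, rel=1e-12
        )

    def test_k_factor_y90_against_printed(self):
        assert k_factor_y90() == pytest.approx(4.782e-5, rel=0.01)

    def test_k_at_unit_density_equals_coefficient(self):
        c = LdmConstants(liver_density_kg_per_ml=1.0)
        assert k_factor_y90(c) == committed_energy_coefficient(c)

    def test_k_inverse_in_density(self):
        base = LdmConstants()
        half = LdmConstants(liver_density_kg_per_ml=base.liver_density_kg_per_ml / 2)
        assert k_factor_y90(half) == pytest.approx(2 * k_factor_y90(base), rel=1e-12)

    def test_inconsistent_decay_constant_rejected(self):
        with pytest.raises(InvalidParameterError):
            LdmConstants(half_life_h=64.24, decay_constant_per_h=1.2e-2)

    @pytest.mark.parametrize("name", ["22Na", "86Y", "68Ge"])
    def test_ratio_derived_surrogate_k_matches_printed(self, name):
        """K_X = K_⁹⁰Y·β_X/β_⁹⁰Y reproduces the printed column to 0.1%."""
        derived = derive_nuclide_params(name)
        printed = get_nuclide(name)
        assert derived.k_factor == pytest.approx(printed.k_factor, rel=1e-3)

    @pytest.mark.parametrize("name", ["22Na", "86Y", "68Ge"])
    def test_derived_adjusted_decay_constant_matches_printed(self, name):
        derived = derive_nuclide_params(name)
        printed = get_nuclide(name)
        assert derived.adjusted_decay_constant_per_h == pytest.approx(
            printed.adjusted_decay_constant_per_h, rel=3e-3
        )

    def test_surrogate_k_examples(self):
        assert surrogate_k_factor(4.782e-5, 0.905) == pytest.approx(1.353, rel=1e-3)
        assert surrogate_k_factor(4.782e-5, 0.319) == pytest.approx(0.4767, rel=1e-3)
        assert surrogate_k_factor(4.782e-5, 0.000032) == 4.782e-5

    def test_surrogate_k_invalid_branching(self):
        with pytest.raises(InvalidParameterError):
            surrogate_k_factor(4.782e-5, 0.0)

    def test_adjusted_decay_constant_examples(self):
        assert adjusted_decay_constant(1.083e-2, 3.038e-5) == pytest.approx(
            1.080e-2, rel=3e-3
        )
        assert adjusted_decay_constant(1.083e-2, 4.702e-2) == pytest.approx(
            -3.619e-2, rel=1e-3
        )
        assert adjusted_decay_constant(1.083e-2, 1.083e-2) == 0.0


def _uniform(value, shape=(6, 6, 6), voxel=4.0, **kw):
    return ActivityGrid(values=np.full(shape, float(value)), voxel_size=voxel, **kw)


class TestLdmDose:
    def test_uniform_y90_phantom_concentration(self):
        """2.2 MBq/mL of ⁹⁰Y commits 105.2 Gy everywhere."""
        dose = ldm_dose(_uniform(2.2e6), "90Y", delay_hours=5.0)
        assert np.allclose(dose.values, 2.2e6 * 4.782e-5)
        assert dose.values.flat[0] == pytest.approx(105.2, rel=1e-3)

    def test_na22_configured_scanner(self):
        dose = ldm_dose(_uniform(1000.0), "22Na", delay_hours=0.0)
        assert np.allclose(dose.values, 1353.0)

    def test_zero_activity_gives_zero_dose(self):
        dose = ldm_dose(_uniform(0.0), "90Y")
        assert np.all(dose.values == 0.0)

    def test_linearity(self):
        a = ActivityGrid(values=np.random.default_rng(0).uniform(0, 1e6, (5, 5, 5)),
                         voxel_size=2.0)
        d1 = ldm_dose(a, "90Y")
        d3 = ldm_dose(a.with_values(3.0 * a.values), "90Y")
        assert np.allclose(d3.values, 3.0 * d1.values, rtol=1e-12)

    def test_delay_increases_dose_for_longer_lived_surrogate(self):
        d0 = ldm_dose(_uniform(1000.0), "22Na", delay_hours=0.0)
        d24 = ldm_dose(_uniform(1000.0), "22Na", delay_hours=24.0)
        assert np.all(d24.values > d0.values)
        factor = math.exp(1.080e-2 * 24.0)
        assert d24.values.flat[0] == pytest.approx(d0.values.flat[0] * factor, rel=1e-12)

    def test_native_y90_is_delay_invariant(self):
        d0 = ldm_dose(_uniform(1000.0), "90Y", delay_hours=0.0)
        d48 = ldm_dose(_uniform(1000.0), "90Y", delay_hours=48.0)
        assert np.array_equal(d0.values, d48.values)

    def test_shorter_lived_surrogate_decreases_with_delay(self):
        d0 = ldm_dose(_uniform(1000.0), "86Y", delay_hours=0.0)
        d10 = ldm_dose(_uniform(1000.0), "86Y", delay_hours=10.0)
        assert np.all(d10.values < d0.values)

    def test_small_negatives_clipped_large_rejected(self):
        vals = np.full((4, 4, 4), 100.0)
        vals[0, 0, 0] = -0.5
        dose = ldm_dose(ActivityGrid(values=vals, voxel_size=4.0), "90Y")
        assert dose.values[0, 0, 0] == 0.0
        vals[0, 0, 0] = -5.0
        with pytest.raises(DataQualityError):
            ldm_dose(ActivityGrid(values=vals, voxel_size=4.0), "90Y")

    def test_negative_delay_rejected(self):
        with pytest.raises(InvalidParameterError):
            ldm_dose(_uniform(1.0), "90Y", delay_hours=-1.0)

    def test_geometry_preserved(self):
        a = _uniform(10.0, shape=(3, 4, 5), voxel=2.0, origin=(1.0, 2.0, 3.0))
        dose = ldm_dose(a, "90Y")
        assert dose.shape == a.shape
        assert dose.voxel_size == a.voxel_size
        assert dose.origin == a.origin
        assert dose.method_label == "LDM"
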