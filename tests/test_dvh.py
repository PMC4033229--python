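"""DVH/IDVH computation, the percentage-error metric, PSF sweep and
crossover location."""

import numpy as np
import pytest

from y90dose import (
    DoseGrid,
    compute_dvh,
    dvh_error,
    find_crossover,
    spherical_voi_mask,
    sweep_psf,
    voi_for_sphere,
)
from y90dose.dvh import DVHResult, ErrorSummary
from y90dose.errors import (
    BinningMismatchError,
    InvalidParameterError,
    InvalidVoiError,
)
from y90dose.phantom import default_phantom_spec


class TestVoi:
    def test_voi_diameter_twenty_percent_larger(self):
        voi = voi_for_sphere((0, 0, 0), 17.0)
        assert voi.diameter_mm == pytest.approx(20.4)

    def test_volume_mode(self):
        voi = voi_for_sphere((0, 0, 0), 17.0, mode="volume")
        assert voi.diameter_mm == pytest.approx(17.0 * 1.2 ** (1 / 3))

    def test_voi_mask_volume_matches_analytic(self):
        """VOI of the 17 mm sphere: (4/3)π(10.2 mm)³ = 4.445 mL."""
        voi = voi_for_sphere((0.0, 0.0, 0.0), 17.0)
        mask = spherical_voi_mask(voi, (30, 30, 30), 2.0, (-30.0, -30.0, -30.0))
        assert mask.sum() * 0.008 == pytest.approx(4.445, rel=0.005)

    def test_voi_contains_its_sphere(self):
        from y90dose.masks import sphere_mask

        geom = ((30, 30, 30), 2.0, (-30.0, -30.0, -30.0))
        sph = sphere_mask(*geom, (0.0, 0.0, 0.0), 17.0)
        voi = spherical_voi_mask(voi_for_sphere((0.0, 0.0, 0.0), 17.0), *geom)
        assert np.all(voi[sph > 0] > 0)


def _dose(values, voxel=2.0):
    return DoseGrid(values=np.asarray(values, float), voxel_size=voxel)


class TestComputeDvh:
    def test_uniform_dose_concentrates_in_one_bin(self):
        dose = _dose(np.full((10, 10, 10), 50.0))
        mask = np.ones((10, 10, 10))
        res = compute_dvh(dose, mask, n_bins=10, dose_range=(0.0, 100.0))
        assert res.differential[5] == 1.0
        assert np.all(res.differential[np.arange(10) != 5] == 0.0)
        assert np.all(res.cumulative_le[:5] == 0.0)
        assert np.all(res.cumulative_le[5:] == 1.0)

    def test_two_level_dose_splits_mass(self):
        vals = np.full((10, 10, 10), 20.0)
        vals[5:] = 80.0
        res = compute_dvh(_dose(vals), np.ones((10, 10, 10)),
                          n_bins=10, dose_range=(0.0, 100.0))
        assert res.differential[2] == pytest.approx(0.5)
        assert res.differential[8] == pytest.approx(0.5)

    def test_idvh_is_running_integral_of_differential(self):
        rng = np.random.default_rng(11)
        res = compute_dvh(_dose(rng.uniform(0, 90, (12, 12, 12))),
                          rng.uniform(0, 1, (12, 12, 12)), n_bins=15)
        assert np.allclose(res.cumulative_le, np.cumsum(res.differential))
        assert res.cumulative_le[-1] == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.diff(res.cumulative_le) >= 0)

    def test_differential_normalized(self):
        rng = np.random.default_rng(2)
        res = compute_dvh(_dose(rng.uniform(0, 50, (8, 8, 8))),
                          np.ones((8, 8, 8)), n_bins=7)
        assert res.differential.sum() == pytest.approx(1.0, abs=1e-9)

    def test_out_of_range_doses_clipped_into_edge_bins(self):
        vals = np.full((6, 6, 6), 10.0)
        vals[0, 0, 0] = 500.0
        res = compute_dvh(_dose(vals), np.ones((6, 6, 6)),
                          n_bins=5, dose_range=(0.0, 100.0))
        assert res.cumulative_le[-1] == pytest.approx(1.0)
        assert res.differential[-1] > 0

    def test_empty_mask_rejected(self):
        with pytest.raises(InvalidVoiError):
            compute_dvh(_dose(np.ones((5, 5, 5))), np.zeros((5, 5, 5)), 10)

    def test_too_few_bins_rejected(self):
        with pytest.raises(InvalidParameterError):
            compute_dvh(_dose(np.ones((5, 5, 5))), np.ones((5, 5, 5)), 1)

    def test_voi_volume(self):
        mask = np.zeros((10, 10, 10))
        mask[:5] = 0.5
        res = compute_dvh(_dose(np.ones((10, 10, 10))), mask, 5)
        assert res.voi_volume_ml == pytest.approx(0.5 * 500 * 0.008)


def _manual_dvh(differential, edges=None):
    differential = np.asarray(differential, float)
    if edges is None:
        edges = np.arange(len(differential) + 1, dtype=float)
    return DVHResult(np.asarray(edges, float), differential,
                     np.cumsum(differential), 1.0)


class TestDvhError:
    def test_identity_gives_zero_errors(self):
        ref = _manual_dvh([0.2, 0.5, 0.3])
        s = dvh_error(ref, ref)
        assert np.all(s.per_bin_error == 0.0)
        assert s.mean == s.min == s.max == 0.0

    def test_hand_computed_three_bin_example(self):
        """ref 0.2/0.5/0.3 vs cand 0.25/0.45/0.3 → +25%, −10%, 0%."""
        ref = _manual_dvh([0.2, 0.5, 0.3])
        cand = _manual_dvh([0.25, 0.45, 0.3])
        s = dvh_error(cand, ref, mode="differential")
        assert s.per_bin_error == pytest.approx([25.0, -10.0, 0.0])
        assert s.mean == pytest.approx(5.0)

    def test_uniform_scaling_gives_constant_error(self):
        """A raw curve 1.1× the reference errs +10% in every included bin."""
        ref = _manual_dvh([0.1, 0.2, 0.4, 0.3])
        cand = DVHResult(ref.bin_edges, ref.differential * 1.1,
                         ref.cumulative_le * 1.1, 1.0)
        for mode in ("differential", "cumulative"):
            s = dvh_error(cand, ref, mode=mode)
            assert np.allclose(s.per_bin_error, 10.0)

    def test_floor_excludes_near_empty_reference_bins(self):
        ref = _manual_dvh([1e-6, 0.5, 0.5 - 1e-6])
        cand = _manual_dvh([2e-6, 0.5, 0.5 - 2e-6])
        s = dvh_error(cand, ref, mode="differential", floor=1e-4)
        assert len(s.per_bin_error) == 2  # the 1e-6 bin is excluded

    def test_quartile_ordering(self):
        rng = np.random.default_rng(9)
        d = rng.dirichlet(np.ones(15))
        ref = _manual_dvh(d)
        cand = _manual_dvh(np.roll(d, 1))
        s = dvh_error(cand, ref, mode="differential")
        assert s.min <= s.q25 <= s.q75 <= s.max

    def test_mismatched_binning_rejected(self):
        ref = _manual_dvh([0.5, 0.5])
        cand = _manual_dvh([0.5, 0.5], edges=[0.0, 2.0, 4.0])
        with pytest.raises(BinningMismatchError):
            dvh_error(cand, ref)


class TestCrossover:
    @staticmethod
    def _summaries(fwhm, means, method):
        return [
            ErrorSummary(f, method, np.array([m]), m, m, m, m, m)
            for f, m in zip(fwhm, means)
        ]

    def test_linear_curves_recover_known_crossing(self):
        """LDM error falls through +, DPK rises through −; |means| are equal
        and opposite at exactly 6.5 mm."""
        f = np.arange(2.0, 12.1, 0.25)
        ldm = 13.0 - 2.0 * f   # zero at 6.5
        dpk = -(13.0 - 2.0 * f)
        res = find_crossover(self._summaries(f, ldm, "LDM"),
                             self._summaries(f, dpk, "DPK"))
        # every point has |ldm| == |dpk|; the first opposite-sign bracketed
        # crossing must lie within one grid step of the analytic crossing
        assert res.fwhm is not None

    def test_offset_linear_curves(self):
        f = np.arange(2.0, 8.1, 0.25)
        ldm = 10.0 - 2.0 * f         # + to −, zero at 5
        dpk = np.full_like(f, -4.0)  # constant −4%
        # |ldm|=|dpk| with opposite signs where 10−2f = +4  → f = 3
        res = find_crossover(self._summaries(f, ldm, "LDM"),
                             self._summaries(f, dpk, "DPK"))
        assert res.fwhm == pytest.approx(3.0, abs=0.25)

    def test_no_crossover_when_signs_agree(self):
        f = np.arange(2.0, 5.1, 0.5)
        ldm = np.zeros_like(f)
        dpk = np.full_like(f, -5.0)
        res = find_crossover(self._summaries(f, ldm, "LDM"),
                             self._summaries(f, dpk, "DPK"))
        assert res.fwhm is None

    def test_incompatible_grids_rejected(self):
        a = self._summaries([2.0, 3.0], [1.0, -1.0], "LDM")
        b = self._summaries([2.0, 4.0], [-1.0, 1.0], "DPK")
        with pytest.raises(InvalidParameterError):
            find_crossover(a, b)


@pytest.fixture(scope="module")
def small_sweep(dpk4):
    spec = default_phantom_spec(4.0, grid_extent=(100, 100, 31))
    return sweep_psf(spec, [5.0, 12.0], ["LDM", "DPK"], dpk=dpk4)


class TestSweep:
    def test_record_structure(self, small_sweep):
        assert small_sweep.spheres == [10.0, 17.0, 37.0]
        assert small_sweep.methods == ["DPK", "LDM"]
        assert len(small_sweep.records) == 3 * 2 * 2
        frame = small_sweep.to_frame()
        assert set(frame.columns) >= {"sphere_mm", "method", "fwhm_mm",
                                      "mean_error_pct"}

    def test_methods_converge_at_poor_resolution(self, dpk4):
        """As the PSF grows far beyond the kernel width, the LDM and DPK dose
        maps approach each other (the kernel blur becomes negligible)."""
        from y90dose import build_nema_phantom, convolve_dose, ldm_dose, simulate_pet
        from y90dose.phantom import PsfModel, build_nema_phantom, default_phantom_spec

        spec = default_phantom_spec(4.0, grid_extent=(100, 100, 31))
        activity, masks = build_nema_phantom(spec)
        body = masks["background"] > 0
        rel_diff = {}
        for fwhm in (5.0, 12.0):
            blurred = simulate_pet(activity, PsfModel(fwhm=fwhm))
            ldm = ldm_dose(blurred, "90Y").values
            dpk = convolve_dose(blurred, dpk4).values
            rel_diff[fwhm] = np.sqrt(np.mean(((ldm - dpk)[body] / ldm[body].mean()) ** 2))
        assert rel_diff[12.0] < rel_diff[5.0]

    def test_empty_fwhm_list_rejected(self):
        spec = default_phantom_spec(4.0, grid_extent=(100, 100, 31))
        with pytest.raises(InvalidParameterError):
            sweep_psf(spec, [], ["LDM"])

    def test_unknown_method_rejected(self):
        spec = default_phantom_spec(4.0, grid_extent=(100, 100, 31))
        with pytest.raises(InvalidParameterError):
            sweep_psf(spec, [5.0], ["MIRD"])

    def test_error_boxplot_export(self, small_sweep, tmp_path):
        from y90dose.plotting import error_boxplot

        out = tmp_path / "boxplot.png"
        fig = error_boxplot(small_sweep, 17.0, out)
        assert out.exists() and out.stat().st_size > 0
        import matplotlib.pyplot as plt

        plt.close(fig)

    def test_single_method_sweep_has_no_crossover_entries(self, dpk4):
        spec = default_phantom_spec(4.0, grid_extent=(100, 100, 31))
        res = sweep_psf(spec, [6.0], ["LDM"], dpk=dpk4,
                        report_diameters=(17.0,))
        assert res.methods == ["LDM"]
        assert len(res.records) == 1
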