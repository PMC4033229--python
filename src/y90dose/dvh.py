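"""Dose-volume histograms, the DVH error metric, the PSF sweep and the
LDM/DPK accuracy crossover.

Each hot sphere is analysed over a spherical VOI centered on it but 20%
larger in diameter, so that edge voxels — where the dosimetry techniques
differ most — are fully included.  The differential DVH is the
mask-weighted histogram of voxel doses normalized to unit total; the
integrated DVH (IDVH) is its running integral, the fraction of the VOI
receiving ≤ D.  A candidate dose map is scored against the True
Dosimetric Solution bin-by-bin:

    Error(D) = (DVH_cand(D) − DVH_TDS(D)) / DVH_TDS(D) · 100  [%]

applied by default to the cumulative (IDVH) curve, with the differential
curve available as a mode; reference bins below a small floor are
excluded.  Sweeping the Gaussian PSF FWHM and summarizing these errors
per (sphere, method, FWHM) reproduces the resolution-dependence analysis,
including the FWHM at which the LDM and DPK mean errors are equal and
opposite.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import constants as c
from .convolve import convolve_dose
from .errors import (
    BinningMismatchError,
    GeometryError,
    InvalidParameterError,
    InvalidVoiError,
)
from .grids import DoseGrid, require_dose
from .kernels import VoxelDPK, build_radial_kernel, voxelize_kernel
from .ldm import ldm_dose
from .masks import sphere_mask
from .media import LIVER
from .phantom import (
    DEFAULT_REPORT_DIAMETERS,
    PhantomSpec,
    PsfModel,
    build_nema_phantom,
    simulate_pet,
    true_dose,
)
from .spectrum import build_beta_spectrum

VOI_ENLARGEMENT = 1.2  # VOI diameter = 1.2 x sphere diameter


@dataclass(frozen=True)
class VoiSpec:
    """Spherical volume of interest."""

    center_mm: Tuple[float, float, float]
    diameter_mm: float

    def __post_init__(self) -> None:
        if self.diameter_mm <= 0:
            raise InvalidParameterError("VOI diameter must be positive")


def voi_for_sphere(center_mm, sphere_diameter_mm: float,
                   enlargement: float = VOI_ENLARGEMENT,
                   mode: str = "diameter") -> VoiSpec:
    """VOI 20% larger than the hot sphere.

    `mode="diameter"` scales the diameter by `enlargement` (default
    reading); `mode="volume"` scales the volume instead.
    """
    if mode == "diameter":
        d = sphere_diameter_mm * enlargement
    elif mode == "volume":
        d = sphere_diameter_mm * enlargement ** (1.0 / 3.0)
    else:
        raise InvalidParameterError(f"unknown VOI mode {mode!r}")
    return VoiSpec(tuple(center_mm), d)


def spherical_voi_mask(voi: VoiSpec, shape, voxel_size: float, origin,
                       supersample: int = 5) -> np.ndarray:
    """Fractional-occupancy mask of the VOI (same policy as the phantom)."""
    return sphere_mask(shape, voxel_size, origin, voi.center_mm,
                       voi.diameter_mm, supersample)


@dataclass(frozen=True)
class DVHResult:
    """Differential and integrated dose-volume histograms over a VOI.

    ``differential[i]`` is the VOI volume fraction with dose in
    [bin_edges[i], bin_edges[i+1]); ``cumulative_le[i]`` is the fraction
    with dose ≤ bin_edges[i+1] (the IDVH sampled at upper edges).
    """

    bin_edges: np.ndarray
    differential: np.ndarray
    cumulative_le: np.ndarray
    voi_volume_ml: float

    def __post_init__(self) -> None:
        edges = np.asarray(self.bin_edges, float)
        diff = np.asarray(self.differential, float)
        cum = np.asarray(self.cumulative_le, float)
        if edges.ndim != 1 or len(edges) != len(diff) + 1 or len(cum) != len(diff):
            raise InvalidParameterError("inconsistent DVH array lengths")
        object.__setattr__(self, "bin_edges", edges)
        object.__setattr__(self, "differential", diff)
        object.__setattr__(self, "cumulative_le", cum)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "bin_lo_Gy": self.bin_edges[:-1],
                "bin_hi_Gy": self.bin_edges[1:],
                "differential": self.differential,
                "idvh": self.cumulative_le,
            }
        )


def compute_dvh(
    dose: DoseGrid,
    mask: np.ndarray,
    n_bins: int = 15,
    dose_range: Optional[Tuple[float, float]] = None,
) -> DVHResult:
    """Mask-weighted differential DVH and its running integral.

    `dose_range` defaults to [0, max dose inside the VOI].  Doses outside
    the range are clipped into the first/last bin so the histogram always
    integrates to 1 and the IDVH ends at 1.
    """
    dose = require_dose(dose)
    if n_bins < 2:
        raise InvalidParameterError("n_bins must be at least 2")
    mask = np.asarray(mask, float)
    if mask.shape != dose.shape:
        raise GeometryError("mask shape does not match dose grid")
    total = mask.sum()
    if total <= 0:
        raise InvalidVoiError("VOI mask selects no voxels")

    vals = dose.values[mask > 0]
    weights = mask[mask > 0]
    if dose_range is None:
        dose_range = (0.0, float(vals.max()) if vals.max() > 0 else 1.0)
    lo, hi = dose_range
    if not hi > lo:
        raise InvalidParameterError("dose_range upper bound must exceed lower bound")
    edges = np.linspace(lo, hi, n_bins + 1)
    clipped = np.clip(vals, lo, np.nextafter(hi, lo))
    hist, _ = np.histogram(clipped, bins=edges, weights=weights)
    differential = hist / total
    cumulative = np.cumsum(differential)
    voi_volume_ml = float(total) * dose.voxel_volume_ml
    return DVHResult(edges, differential, cumulative, voi_volume_ml)


@dataclass(frozen=True)
class ErrorSummary:
    """Boxplot statistics of the per-bin DVH error for one curve pair."""

    psf_fwhm: float
    method_label: str
    per_bin_error: np.ndarray   # percent, included bins only
    mean: float
    q25: float
    q75: float
    min: float
    max: float

    @property
    def mean_abs(self) -> float:
        return float(np.mean(np.abs(self.per_bin_error)))


def dvh_error(
    candidate: DVHResult,
    reference: DVHResult,
    *,
    mode: str = "cumulative",
    floor: float = 1e-4,
    psf_fwhm: float = float("nan"),
    method_label: str = "",
) -> ErrorSummary:
    """Per-bin percentage error of a candidate DVH against a reference.

    `mode` selects the cumulative (IDVH, default) or differential curve;
    reference bins at or below `floor` (fraction of total) are excluded
    from the statistics.
    """
    if candidate.bin_edges.shape != reference.bin_edges.shape or not np.allclose(
        candidate.bin_edges, reference.bin_edges
    ):
        raise BinningMismatchError("candidate and reference bin edges differ")
    if mode == "cumulative":
        cand, ref = candidate.cumulative_le, reference.cumulative_le
    elif mode == "differential":
        cand, ref = candidate.differential, reference.differential
    else:
        raise InvalidParameterError(f"unknown error mode {mode!r}")

    include = ref > floor
    if not include.any():
        raise InvalidVoiError("no reference bins above the floor")
    err = (cand[include] - ref[include]) / ref[include] * 100.0
    return ErrorSummary(
        psf_fwhm=psf_fwhm,
        method_label=method_label,
        per_bin_error=err,
        mean=float(err.mean()),
        q25=float(np.percentile(err, 25)),
        q75=float(np.percentile(err, 75)),
        min=float(err.min()),
        max=float(err.max()),
    )


@dataclass(frozen=True)
class SweepRecord:
    sphere_diameter: float
    method: str
    fwhm: float
    summary: ErrorSummary


@dataclass
class SweepResult:
    """All error summaries from a PSF sweep, plus enough context to find
    crossovers and export tables."""

    records: List[SweepRecord] = field(default_factory=list)
    voxel_size: float = 0.0

    def summaries(self, sphere: float, method: str) -> List[ErrorSummary]:
        recs = [r for r in self.records
                if r.sphere_diameter == sphere and r.method == method]
        return [r.summary for r in sorted(recs, key=lambda r: r.fwhm)]

    @property
    def spheres(self) -> List[float]:
        return sorted({r.sphere_diameter for r in self.records})

    @property
    def methods(self) -> List[str]:
        return sorted({r.method for r in self.records})

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "sphere_mm": r.sphere_diameter,
                "method": r.method,
                "fwhm_mm": r.fwhm,
                "mean_error_pct": r.summary.mean,
                "mean_abs_error_pct": r.summary.mean_abs,
                "q25_pct": r.summary.q25,
                "q75_pct": r.summary.q75,
                "min_pct": r.summary.min,
                "max_pct": r.summary.max,
            }
            for r in self.records
        ]
        return pd.DataFrame(rows).sort_values(
            ["sphere_mm", "method", "fwhm_mm"], ignore_index=True
        )


def default_kernel(voxel_size: float, medium=LIVER, samples_per_axis: int = 7) -> VoxelDPK:
    """⁹⁰Y liver voxel DPK at the requested voxel size (default pipeline)."""
    spec = build_beta_spectrum()
    radial = build_radial_kernel(spec, medium)
    return voxelize_kernel(radial, voxel_size, medium, samples_per_axis)


def sweep_psf(
    phantom_spec: PhantomSpec,
    fwhm_values: Sequence[float],
    methods: Sequence[str] = ("LDM", "DPK"),
    *,
    dpk: Optional[VoxelDPK] = None,
    report_diameters: Sequence[float] = DEFAULT_REPORT_DIAMETERS,
    n_bins: int = 15,
    error_mode: str = "cumulative",
    supersample: int = 5,
    decay_constant_per_h: float = c.Y90_DECAY_CONSTANT_PER_H,
) -> SweepResult:
    """Blur → dose → DVH-error analysis over a set of PSF widths.

    For each FWHM the phantom is blurred, dosimetry is run with each
    requested method, and each reported sphere's DVH (binned on the TDS
    range) is scored against the TDS of the unblurred phantom.
    """
    if not fwhm_values:
        raise InvalidParameterError("fwhm_values must be non-empty")
    unknown = set(m.upper() for m in methods) - {"LDM", "DPK"}
    if unknown:
        raise InvalidParameterError(f"unknown methods: {sorted(unknown)}")
    methods = [m.upper() for m in methods]

    activity, _ = build_nema_phantom(phantom_spec, supersample)
    if dpk is None:
        dpk = default_kernel(phantom_spec.voxel_size)
    tds = true_dose(activity, dpk, decay_constant_per_h)

    # per-sphere VOI masks and TDS reference DVHs (fix the bin edges)
    vois: Dict[float, np.ndarray] = {}
    refs: Dict[float, DVHResult] = {}
    for sph in phantom_spec.spheres:
        if sph.diameter_mm not in report_diameters:
            continue
        voi = voi_for_sphere(sph.center_mm, sph.diameter_mm)
        mask = spherical_voi_mask(voi, activity.shape, activity.voxel_size,
                                  activity.origin, supersample)
        vois[sph.diameter_mm] = mask
        refs[sph.diameter_mm] = compute_dvh(tds, mask, n_bins)

    result = SweepResult(voxel_size=phantom_spec.voxel_size)
    for fwhm in fwhm_values:
        blurred = simulate_pet(activity, PsfModel(fwhm=float(fwhm)))
        dose_maps: Dict[str, DoseGrid] = {}
        if "LDM" in methods:
            dose_maps["LDM"] = ldm_dose(blurred, "90Y")
        if "DPK" in methods:
            dose_maps["DPK"] = convolve_dose(blurred, dpk, decay_constant_per_h)
        for diam, mask in vois.items():
            ref = refs[diam]
            rng = (float(ref.bin_edges[0]), float(ref.bin_edges[-1]))
            for method, dose in dose_maps.items():
                cand = compute_dvh(dose, mask, n_bins, rng)
                summ = dvh_error(cand, ref, mode=error_mode,
                                 psf_fwhm=float(fwhm), method_label=method)
                result.records.append(
                    SweepRecord(diam, method, float(fwhm), summ)
                )
    return result


@dataclass(frozen=True)
class CrossoverResult:
    """FWHM [mm] where LDM and DPK mean errors are equal and opposite;
    `fwhm` is None when no sign-structured crossing exists in range."""

    fwhm: Optional[float]
    sphere: Optional[float] = None  # None = pooled over spheres


def _crossover_fwhm(fwhm: np.ndarray, err_ldm: np.ndarray,
                    err_dpk: np.ndarray) -> Optional[float]:
    """Root of |mean_LDM| − |mean_DPK| (linear interpolation) at which the
    two mean errors have opposite signs."""
    g = np.abs(err_ldm) - np.abs(err_dpk)
    opposite = err_ldm * err_dpk < 0
    for i in range(len(fwhm) - 1):
        if g[i] == 0.0 and opposite[i]:
            return float(fwhm[i])
        if g[i] * g[i + 1] < 0 and (opposite[i] or opposite[i + 1]):
            frac = g[i] / (g[i] - g[i + 1])
            return float(fwhm[i] + frac * (fwhm[i + 1] - fwhm[i]))
    if g[-1] == 0.0 and opposite[-1]:
        return float(fwhm[-1])
    return None


def find_crossover(
    summaries_ldm: Sequence[ErrorSummary],
    summaries_dpk: Sequence[ErrorSummary],
    sphere: Optional[float] = None,
) -> CrossoverResult:
    """Locate the equal-and-opposite mean-error crossover of two sweeps.

    Both summary lists must share one ascending FWHM grid.
    """
    f_l = np.array([s.psf_fwhm for s in summaries_ldm])
    f_d = np.array([s.psf_fwhm for s in summaries_dpk])
    if len(f_l) != len(f_d) or not np.allclose(f_l, f_d):
        raise InvalidParameterError("summary lists are not on a common FWHM grid")
    if np.any(np.diff(f_l) <= 0):
        raise InvalidParameterError("FWHM grid must be ascending")
    e_l = np.array([s.mean for s in summaries_ldm])
    e_d = np.array([s.mean for s in summaries_dpk])
    return CrossoverResult(fwhm=_crossover_fwhm(f_l, e_l, e_d), sphere=sphere)


def sweep_crossovers(result: SweepResult) -> Dict[str, CrossoverResult]:
    """Per-sphere and pooled crossovers from a sweep with both methods.

    The pooled curve averages the per-sphere mean errors at each FWHM.
    """
    out: Dict[str, CrossoverResult] = {}
    pooled_l = None
    pooled_d = None
    for sphere in result.spheres:
        s_l = result.summaries(sphere, "LDM")
        s_d = result.summaries(sphere, "DPK")
        out[f"sphere_{sphere:g}mm"] = find_crossover(s_l, s_d, sphere)
        e_l = np.array([s.mean for s in s_l])
        e_d = np.array([s.mean for s in s_d])
        pooled_l = e_l if pooled_l is None else pooled_l + e_l
        pooled_d = e_d if pooled_d is None else pooled_d + e_d
    if pooled_l is not None:
        n = len(result.spheres)
        fwhm = np.array([s.psf_fwhm for s in result.summaries(result.spheres[0], "LDM")])
        out["pooled"] = CrossoverResult(
            fwhm=_crossover_fwhm(fwhm, pooled_l / n, pooled_d / n)
        )
    return out
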