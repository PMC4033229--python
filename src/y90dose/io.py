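"""Reading quantitative PET volumes and writing dose maps.

Supported formats: NIfTI volumes (read/write) and DICOM PET series (read).
All activity values are converted to Bq/mL on read; downstream code only
ever sees isotropic grids (anisotropic input is rejected unless a
resampling flag is passed).  Dose maps are written as NIfTI in Gy with a
JSON sidecar recording method, nuclide, conversion factor, delay and
kernel provenance.
"""

from __future__ import annotations

import datetime as _dt
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Dict, Optional, Tuple, Union

import numpy as np

from .errors import GeometryError, MetadataError, UnitsError
from .grids import ActivityGrid, DoseGrid
from .ldm import NUCLIDE_REGISTRY

#: multiplicative factors into Bq/mL
UNIT_FACTORS = {
    "Bq/mL": 1.0,
    "BQML": 1.0,
    "kBq/mL": 1e3,
    "MBq/mL": 1e6,
}

ISOTROPY_TOL = 1e-3  # mm


@dataclass(frozen=True)
class ScanMetadata:
    nuclide_label: str
    units_label: str
    voxel_size: float
    infusion_time: Optional[str] = None
    scan_time: Optional[str] = None
    delay_hours: float = 0.0


def _units_factor(label: str) -> float:
    if label not in UNIT_FACTORS:
        raise UnitsError(
            f"unknown units {label!r}; expected one of {sorted(UNIT_FACTORS)}"
        )
    return UNIT_FACTORS[label]


def read_activity_volume(
    path: Union[str, Path],
    fmt: Optional[str] = None,
    metadata_overrides: Optional[Dict] = None,
    *,
    allow_resample: bool = False,
) -> Tuple[ActivityGrid, ScanMetadata]:
    """Read a quantitative PET volume into an ActivityGrid in Bq/mL.

    `fmt` is "nifti" or "dicom"; by default directories are treated as
    DICOM series and files as NIfTI.  `metadata_overrides` may set
    ``units``, ``nuclide``, ``delay_hours``.
    """
    path = Path(path)
    overrides = dict(metadata_overrides or {})
    if fmt is None:
        fmt = "dicom" if path.is_dir() else "nifti"
    if fmt == "nifti":
        return _read_nifti(path, overrides, allow_resample)
    if fmt == "dicom":
        return _read_dicom_series(path, overrides, allow_resample)
    raise MetadataError(f"unknown format {fmt!r}")


def _isotropic_voxel(zooms, allow_resample: bool) -> Tuple[float, Optional[np.ndarray]]:
    zooms = np.asarray(zooms[:3], float)
    if zooms.max() - zooms.min() <= ISOTROPY_TOL:
        return float(zooms.mean()), None
    if not allow_resample:
        raise GeometryError(
            f"anisotropic voxels {tuple(zooms)} mm; pass allow_resample=True "
            "to resample to the smallest spacing"
        )
    target = float(zooms.min())
    return target, zooms / target


def _read_nifti(path: Path, overrides: Dict, allow_resample: bool):
    import nibabel as nib

    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    voxel, zoom_factors = _isotropic_voxel(zooms, allow_resample)
    values = np.asarray(img.dataobj, dtype=float)
    if zoom_factors is not None:
        from scipy.ndimage import zoom

        values = zoom(values, zoom_factors, order=1)

    units = overrides.get("units", "Bq/mL")
    values = values * _units_factor(units)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    meta = ScanMetadata(
        nuclide_label=overrides.get("nuclide", "90Y"),
        units_label="Bq/mL",
        voxel_size=voxel,
        delay_hours=float(overrides.get("delay_hours", 0.0)),
    )
    grid = ActivityGrid(values=values, voxel_size=voxel, origin=origin,
                        nuclide_label=meta.nuclide_label,
                        scan_delay_h=meta.delay_hours)
    return grid, meta


def _parse_dicom_time(value: str) -> _dt.datetime:
    value = str(value).split(".")[0]
    return _dt.datetime.strptime(value.ljust(6, "0"), "%H%M%S")


def _read_dicom_series(path: Path, overrides: Dict, allow_resample: bool):
    import pydicom

    files = sorted(p for p in path.iterdir() if p.is_file())
    slices = []
    for f in files:
        try:
            ds = pydicom.dcmread(str(f))
        except Exception:
            continue
        if getattr(ds, "Modality", None) == "PT":
            slices.append(ds)
    if not slices:
        raise MetadataError(f"no DICOM PET slices found under {path}")
    slices.sort(key=lambda d: float(d.ImagePositionPatient[2]))

    first = slices[0]
    row_mm, col_mm = (float(x) for x in first.PixelSpacing)
    if len(slices) > 1:
        z_mm = float(slices[1].ImagePositionPatient[2]) - float(
            first.ImagePositionPatient[2]
        )
    else:
        z_mm = float(getattr(first, "SliceThickness", row_mm))
    voxel, zoom_factors = _isotropic_voxel((row_mm, col_mm, abs(z_mm)), allow_resample)

    planes = []
    for ds in slices:
        arr = ds.pixel_array.astype(float)
        slope = float(getattr(ds, "RescaleSlope", 1.0))
        intercept = float(getattr(ds, "RescaleIntercept", 0.0))
        planes.append(arr * slope + intercept)
    values = np.stack(planes, axis=-1)  # (row, col, slice)
    if zoom_factors is not None:
        from scipy.ndimage import zoom

        values = zoom(values, zoom_factors, order=1)

    units = overrides.get("units") or str(getattr(first, "Units", "") or "")
    if not units:
        raise UnitsError("DICOM series carries no Units tag; pass an override")
    values = values * _units_factor(units)

    delay = overrides.get("delay_hours")
    infusion_str = scan_str = None
    if delay is None:
        try:
            pharm = first.RadiopharmaceuticalInformationSequence[0]
            infusion_str = str(pharm.RadiopharmaceuticalStartTime)
            scan_str = str(first.SeriesTime)
            delta = _parse_dicom_time(scan_str) - _parse_dicom_time(infusion_str)
            delay = delta.total_seconds() / 3600.0
            if delay < 0:
                raise MetadataError("scan time precedes infusion time")
        except (AttributeError, IndexError) as exc:
            raise MetadataError(
                "missing infusion/scan timing in DICOM headers; pass "
                "delay_hours override"
            ) from exc

    nuclide = overrides.get("nuclide")
    if nuclide is None:
        try:
            pharm = first.RadiopharmaceuticalInformationSequence[0]
            nuclide = str(
                pharm.RadionuclideCodeSequence[0].CodeMeaning
            )
        except (AttributeError, IndexError):
            nuclide = "90Y"

    origin = tuple(float(x) for x in first.ImagePositionPatient)
    meta = ScanMetadata(
        nuclide_label=nuclide,
        units_label="Bq/mL",
        voxel_size=voxel,
        infusion_time=infusion_str,
        scan_time=scan_str,
        delay_hours=float(delay),
    )
    grid = ActivityGrid(values=values, voxel_size=voxel, origin=origin,
                        nuclide_label=nuclide, scan_delay_h=float(delay))
    return grid, meta


def write_activity_volume(grid: ActivityGrid, path: Union[str, Path]) -> Path:
    """Write an activity grid (Bq/mL) as NIfTI."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([grid.voxel_size] * 3 + [1.0])
    affine[:3, 3] = grid.origin
    nib.save(nib.Nifti1Image(grid.values.astype(np.float64), affine), str(path))
    return path


def write_dose_volume(
    dose: DoseGrid,
    path: Union[str, Path],
    sidecar_fields: Optional[Dict] = None,
) -> Tuple[Path, Path]:
    """Write a dose grid as NIfTI (Gy) plus a JSON sidecar."""
    import nibabel as nib

    path = Path(path)
    affine = np.diag([dose.voxel_size] * 3 + [1.0])
    affine[:3, 3] = dose.origin
    nib.save(nib.Nifti1Image(dose.values.astype(np.float64), affine), str(path))

    sidecar = {
        "units": "Gy",
        "method": dose.method_label,
        "voxel_size_mm": dose.voxel_size,
    }
    fields = dict(sidecar_fields or {})
    nuclide = fields.get("nuclide")
    if nuclide in NUCLIDE_REGISTRY and "k_factor" not in fields:
        fields["k_factor"] = NUCLIDE_REGISTRY[nuclide].k_factor
    sidecar.update(fields)
    sidecar_path = path.with_suffix("").with_suffix(".json")
    sidecar_path.write_text(json.dumps(sidecar, indent=2))
    return path, sidecar_path


def read_dose_volume(path: Union[str, Path]) -> DoseGrid:
    """Read back a dose NIfTI written by :func:`write_dose_volume`."""
    import nibabel as nib

    path = Path(path)
    img = nib.load(str(path))
    zooms = img.header.get_zooms()[:3]
    voxel, _ = _isotropic_voxel(zooms, allow_resample=False)
    method = "LDM"
    sidecar_path = path.with_suffix("").with_suffix(".json")
    if sidecar_path.exists():
        method = json.loads(sidecar_path.read_text()).get("method", method)
    origin = tuple(float(x) for x in img.affine[:3, 3])
    return DoseGrid(values=np.asarray(img.dataobj, dtype=float),
                    voxel_size=voxel, origin=origin, method_label=method)
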