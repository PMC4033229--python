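"""Grid containers: activity concentration (Bq/mL) and absorbed dose (Gy).

The two grid types are deliberately distinct classes so that unit mix-ups
(convolving a dose map, histogramming an activity map as dose) fail at the
type level before any computation runs.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Tuple

import numpy as np

from .errors import GeometryError, InvalidInputError


@dataclass(frozen=True)
class _Grid3D:
    values: np.ndarray
    voxel_size: float                      # mm, isotropic
    origin: Tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        v = np.asarray(self.values, dtype=float)
        if v.ndim != 3 or min(v.shape) < 1:
            raise InvalidInputError("grid values must be a 3-D array")
        if not self.voxel_size > 0:
            raise GeometryError("voxel_size must be positive")
        object.__setattr__(self, "values", v)
        object.__setattr__(self, "origin", tuple(float(x) for x in self.origin))

    @property
    def shape(self) -> Tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_ml(self) -> float:
        return self.voxel_size**3 / 1000.0

    def voxel_centers_mm(self, axis: int) -> np.ndarray:
        """World coordinates of voxel centers along one axis:
        origin + (index + 0.5) * voxel_size."""
        n = self.values.shape[axis]
        return self.origin[axis] + (np.arange(n) + 0.5) * self.voxel_size

    def same_geometry(self, other: "_Grid3D", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.voxel_size - other.voxel_size) <= tol
            and all(abs(a - b) <= tol for a, b in zip(self.origin, other.origin))
        )


@dataclass(frozen=True)
class ActivityGrid(_Grid3D):
    """3-D activity-concentration grid, values in Bq/mL."""

    nuclide_label: str = "90Y"
    scan_delay_h: float = 0.0

    def with_values(self, values: np.ndarray) -> "ActivityGrid":
        return replace(self, values=values)


@dataclass(frozen=True)
class DoseGrid(_Grid3D):
    """3-D committed absorbed-dose grid, values in Gy.

    `method_label` records how the map was produced: "LDM", "DPK" or "TDS".
    """

    method_label: str = "LDM"

    def __post_init__(self) -> None:
        super().__post_init__()
        if np.any(self.values < 0):
            raise InvalidInputError("dose values must be non-negative")


def require_activity(grid: object) -> ActivityGrid:
    if not isinstance(grid, ActivityGrid):
        raise InvalidInputError(
            f"expected an ActivityGrid (Bq/mL), got {type(grid).__name__}"
        )
    return grid


def require_dose(grid: object) -> DoseGrid:
    if not isinstance(grid, DoseGrid):
        raise InvalidInputError(f"expected a DoseGrid (Gy), got {type(grid).__name__}")
    return grid
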