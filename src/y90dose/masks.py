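"""Fractional-occupancy masks on voxel grids.

Region masks are float grids in [0, 1]: 1 for voxels fully inside the
region, 0 fully outside, and a subvoxel-supersampled fraction for boundary
voxels.  Voxel centers sit at origin + (index + 0.5) * voxel_size.

Boundary detection is geometric: for spheres, any voxel whose center lies
within half a voxel diagonal of the surface is supersampled (this also
catches tangent caps whose corners all fall outside); for the elliptical
body contour, corner disagreement suffices because its curvature radius is
much larger than a voxel.
"""

from __future__ import annotations

from typing import Tuple

import numpy as np

from .errors import GeometryError


def _axis_centers(n: int, voxel_size: float, origin: float) -> np.ndarray:
    return origin + (np.arange(n) + 0.5) * voxel_size


def sphere_mask(
    shape: Tuple[int, int, int],
    voxel_size: float,
    origin: Tuple[float, float, float],
    center_mm: Tuple[float, float, float],
    diameter_mm: float,
    supersample: int = 5,
) -> np.ndarray:
    """Fractional-occupancy mask of a sphere.

    With `supersample` = 1 the mask is binary on voxel centers.  Raises
    :class:`GeometryError` if the sphere extends outside the grid.
    """
    if diameter_mm <= 0:
        raise GeometryError("sphere diameter must be positive")
    radius = diameter_mm / 2.0
    for ax in range(3):
        lo = origin[ax]
        hi = origin[ax] + shape[ax] * voxel_size
        if center_mm[ax] - radius < lo or center_mm[ax] + radius > hi:
            raise GeometryError(
                f"sphere (center {center_mm}, d={diameter_mm} mm) exceeds grid "
                f"extent on axis {ax} [{lo}, {hi}] mm"
            )

    xs = _axis_centers(shape[0], voxel_size, origin[0]) - center_mm[0]
    ys = _axis_centers(shape[1], voxel_size, origin[1]) - center_mm[1]
    zs = _axis_centers(shape[2], voxel_size, origin[2]) - center_mm[2]
    dist = np.sqrt(xs[:, None, None] ** 2 + ys[None, :, None] ** 2 + zs[None, None, :] ** 2)

    half_diag = voxel_size * np.sqrt(3.0) / 2.0
    mask = (dist <= radius - half_diag).astype(float)
    if supersample <= 1:
        return np.where(dist <= radius, 1.0, 0.0)

    boundary = np.argwhere(np.abs(dist - radius) < half_diag)
    if boundary.size:
        sub = (np.arange(supersample) + 0.5) / supersample - 0.5  # voxel units
        off = sub * voxel_size
        ox, oy, oz = np.meshgrid(off, off, off, indexing="ij")
        h = voxel_size / supersample
        for i, j, k in boundary:
            px = xs[i] + ox
            py = ys[j] + oy
            pz = zs[k] + oz
            d = np.sqrt(px**2 + py**2 + pz**2)
            # antialiased subsample: each subvoxel contributes the clamped
            # signed-distance fraction of itself inside the surface (O(h²)
            # accurate vs O(h) for binary counting)
            frac = np.clip(0.5 + (radius - d) / h, 0.0, 1.0)
            mask[i, j, k] = frac.mean()
    return mask


def elliptical_cylinder_mask(
    shape: Tuple[int, int, int],
    voxel_size: float,
    origin: Tuple[float, float, float],
    center_mm: Tuple[float, float],
    semi_axes_mm: Tuple[float, float],
    supersample: int = 5,
) -> np.ndarray:
    """Fractional mask of an axially-extruded ellipse spanning the full
    z extent (2-D problem broadcast along z)."""
    a, b = semi_axes_mm
    if a <= 0 or b <= 0:
        raise GeometryError("ellipse semi-axes must be positive")
    xs = _axis_centers(shape[0], voxel_size, origin[0]) - center_mm[0]
    ys = _axis_centers(shape[1], voxel_size, origin[1]) - center_mm[1]

    # inside metric on voxel corners
    xc = np.concatenate([xs - voxel_size / 2, [xs[-1] + voxel_size / 2]])
    yc = np.concatenate([ys - voxel_size / 2, [ys[-1] + voxel_size / 2]])
    corner_inside = (xc[:, None] / a) ** 2 + (yc[None, :] / b) ** 2 <= 1.0
    n_in = (
        corner_inside[:-1, :-1].astype(int)
        + corner_inside[1:, :-1]
        + corner_inside[:-1, 1:]
        + corner_inside[1:, 1:]
    )
    plane = (n_in == 4).astype(float)
    boundary = np.argwhere((n_in > 0) & (n_in < 4))
    if supersample <= 1:
        plane = ((xs[:, None] / a) ** 2 + (ys[None, :] / b) ** 2 <= 1.0).astype(float)
    elif boundary.size:
        sub = ((np.arange(supersample) + 0.5) / supersample - 0.5) * voxel_size
        ox, oy = np.meshgrid(sub, sub, indexing="ij")
        for i, j in boundary:
            inside = ((xs[i] + ox) / a) ** 2 + ((ys[j] + oy) / b) ** 2 <= 1.0
            plane[i, j] = inside.mean()
    return np.repeat(plane[:, :, None], shape[2], axis=2)
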