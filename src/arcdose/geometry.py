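"""Structure geometry: rasterization, margin expansion and target-shape metrics.

The shape statistics quantify how far a target volume departs from a sphere.
True sphericity compares the surface area of the volume-equivalent sphere to
the actual surface area:

    Psi = pi^(1/3) (6V)^(2/3) / A,

which is 1 for a perfect sphere and falls towards 0 for concave, lobed
shapes.  Because planning systems report structure volumes but rarely surface
areas, a surrogate is available that uses only the CTV and PTV volumes and
the isotropic margin d that generated the PTV: the CTV/PTV shell is treated
as an onion layer of thickness d, giving an effective area
(V_PTV - V_CTV)/d and an effective mid-shell volume (V_CTV + V_PTV)/2, hence

    Psi~ = pi^(1/3) d (3 (V_CTV + V_PTV))^(2/3) / (V_PTV - V_CTV).

Psi~ behaves like sphericity but may exceed 1 slightly (for concentric
spheres the shell area surrogate underestimates the mid-sphere area).
"""

from __future__ import annotations

import numpy as np
from matplotlib.path import Path as MplPath
from scipy import ndimage
from skimage import measure

from .grids import ContourSet, DoseGrid, StructureMask

__all__ = [
    "rasterize",
    "expand_margin",
    "surface_and_volume",
    "sphericity",
    "sphericity_like",
    "min_distance",
    "isocentre_displacement",
    "overlap",
]


def rasterize(contours: ContourSet, geometry: DoseGrid | StructureMask,
              role: str = "other") -> StructureMask:
    """Rasterize per-slice contours onto a grid geometry.

    A voxel is included iff its centre lies inside any polygon of the contour
    slice nearest to the voxel's z plane (even-odd rule).  Each contour slice
    is assigned to its nearest grid plane; contours outside the grid extent
    raise an error naming the offending slice.
    """
    nz, ny, nx = geometry.values.shape
    mask = np.zeros((nz, ny, nx), dtype=bool)
    if contours.is_empty():
        return StructureMask(mask, spacing=geometry.spacing, origin=geometry.origin,
                             name=contours.name, role=role)

    zs = geometry.axis_coords(0)
    ys = geometry.axis_coords(1)
    xs = geometry.axis_coords(2)
    # voxel-centre lattice of one slice, as (x, y) points for polygon testing
    gx, gy = np.meshgrid(xs, ys)
    points = np.column_stack([gx.ravel(), gy.ravel()])

    dz = geometry.spacing[0]
    for sl in contours.slices:
        if sl.z < zs[0] - dz / 2 or sl.z > zs[-1] + dz / 2:
            raise ValueError(
                f"contour slice z={sl.z} mm of {contours.name!r} outside grid "
                f"extent [{zs[0] - dz / 2}, {zs[-1] + dz / 2}] mm"
            )
        iz = int(np.argmin(np.abs(zs - sl.z)))
        for poly in sl.polygons:
            lo_y, lo_x = poly.min(axis=0)
            hi_y, hi_x = poly.max(axis=0)
            if lo_x < xs[0] - geometry.spacing[2] or hi_x > xs[-1] + geometry.spacing[2] \
                    or lo_y < ys[0] - geometry.spacing[1] or hi_y > ys[-1] + geometry.spacing[1]:
                raise ValueError(
                    f"contour polygon at z={sl.z} mm of {contours.name!r} "
                    "extends outside the grid"
                )
            path = MplPath(poly[:, [1, 0]])  # (x, y) vertex order
            inside = path.contains_points(points).reshape(ny, nx)
            mask[iz] |= inside

    return StructureMask(mask, spacing=geometry.spacing, origin=geometry.origin,
                         name=contours.name, role=role)


def expand_margin(mask: StructureMask, margin: float | tuple[float, float, float]) -> StructureMask:
    """Euclidean dilation of a mask by a (possibly anisotropic) margin in mm.

    A voxel belongs to the output iff its centre lies within the margin
    ellipsoid of any input voxel centre; with an isotropic margin this is a
    dilation by a Euclidean ball.  Zero margin returns an identical mask.
    """
    margins = np.broadcast_to(np.asarray(margin, dtype=float), (3,)).copy()
    if np.any(margins < 0):
        raise ValueError("margin must be non-negative")
    if np.all(margins == 0) or mask.is_empty():
        return StructureMask(mask.values.copy(), spacing=mask.spacing,
                             origin=mask.origin, name=mask.name, role=mask.role)
    # distance in margin-normalised units: a zero margin component forbids
    # growth along that axis (effectively infinite normalised distance)
    margins_safe = np.where(margins > 0, margins, 1e-12)
    sampling = np.asarray(mask.spacing) / margins_safe
    dt = ndimage.distance_transform_edt(~mask.values, sampling=sampling)
    grown = dt <= 1.0 + 1e-9
    return StructureMask(grown, spacing=mask.spacing, origin=mask.origin,
                         name=mask.name, role=mask.role)


def surface_and_volume(mask: StructureMask) -> tuple[float, float]:
    """Surface area (cm^2) and volume (cm^3) of a binary mask.

    Volume is the voxel count times the voxel volume.  Area comes from a
    marching-cubes triangulation of the 0.5 level of the indicator field
    smoothed by a one-voxel Gaussian.  (Face counting overestimates a
    sphere's area by a constant factor, and triangulating the raw binary
    field leaves a staircase surface whose area does not converge under
    refinement; the smoothed level set does.)
    """
    if mask.is_empty():
        raise ValueError("surface_and_volume requires a nonempty mask")
    volume_cm3 = mask.volume_cm3
    padded = np.pad(mask.values.astype(np.float64), 4)
    padded = ndimage.gaussian_filter(padded, sigma=1.0)
    verts, faces, _, _ = measure.marching_cubes(padded, level=0.5, spacing=mask.spacing)
    area_cm2 = float(measure.mesh_surface_area(verts, faces)) / 100.0
    return area_cm2, volume_cm3


def sphericity(area_cm2: float, volume_cm3: float) -> float:
    """True sphericity Psi = pi^(1/3) (6V)^(2/3) / A; 1 for a perfect sphere."""
    if area_cm2 <= 0 or volume_cm3 <= 0:
        raise ValueError("sphericity requires positive area and volume")
    return float(np.pi ** (1 / 3) * (6.0 * volume_cm3) ** (2 / 3) / area_cm2)


def sphericity_like(v_ctv_cm3: float, v_ptv_cm3: float, margin_mm: float) -> float:
    """Shell-surrogate sphericity Psi~ from CTV/PTV volumes and the margin d.

    Volumes are given in cm^3 and converted to mm^3 internally so that the
    statistic is evaluated in consistent mm units with ``margin_mm``.
    """
    if v_ctv_cm3 <= 0:
        raise ValueError("CTV volume must be positive")
    if v_ptv_cm3 <= v_ctv_cm3:
        raise ValueError("PTV volume must exceed CTV volume (degenerate shell)")
    if margin_mm <= 0:
        raise ValueError("margin must be positive")
    v_ctv = v_ctv_cm3 * 1000.0
    v_ptv = v_ptv_cm3 * 1000.0
    return float(
        np.pi ** (1 / 3) * margin_mm * (3.0 * (v_ctv + v_ptv)) ** (2 / 3) / (v_ptv - v_ctv)
    )


def min_distance(mask_a: StructureMask, mask_b: StructureMask,
                 per_slice: bool = False) -> float:
    """Minimum Euclidean distance (mm) between voxel centres of two masks.

    Returns 0 when the masks intersect.  ``per_slice=True`` restricts the
    search to matching axial planes (a 2D scan of the slices), which can only
    increase the distance; the default is the full 3D minimum via a distance
    transform.
    """
    if mask_a.is_empty() or mask_b.is_empty():
        raise ValueError("min_distance requires nonempty masks")
    if not mask_a.same_geometry(mask_b):
        raise ValueError("masks must share geometry")
    if per_slice:
        best = np.inf
        for iz in range(mask_a.values.shape[0]):
            a, b = mask_a.values[iz], mask_b.values[iz]
            if not (a.any() and b.any()):
                continue
            dt = ndimage.distance_transform_edt(~b, sampling=mask_a.spacing[1:])
            best = min(best, float(dt[a].min()))
        return best
    dt = ndimage.distance_transform_edt(~mask_b.values, sampling=mask_a.spacing)
    return float(dt[mask_a.values].min())


def isocentre_displacement(x_ml: float, x_ap: float) -> float:
    """In-plane displacement R = sqrt(x_ml^2 + x_ap^2) of the field isocentre
    from the patient origin (mm); sign-invariant in both components."""
    return float(np.hypot(x_ml, x_ap))


def overlap(mask_a: StructureMask, mask_b: StructureMask) -> tuple[float, float]:
    """Intersection volume (cm^3) and its percentage of ``mask_a``'s volume."""
    if not mask_a.same_geometry(mask_b):
        raise ValueError("masks must share geometry")
    if mask_a.is_empty():
        raise ValueError("overlap percentage undefined for an empty first mask")
    inter = np.count_nonzero(mask_a.values & mask_b.values)
    inter_cm3 = inter * mask_a.voxel_volume_cm3
    pct = 100.0 * inter / np.count_nonzero(mask_a.values)
    return inter_cm3, pct
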