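"""Core spatial containers: dose grids, planar doses, structure masks and contours.

All geometry is expressed in patient-style millimetre coordinates.  Arrays are
indexed ``(z, y, x)`` ("zyx" axis order); ``spacing`` and ``origin`` follow the
same axis order.  Voxel values live at voxel centres: the centre of voxel
``(i, j, k)`` sits at ``origin + (i, j, k) * spacing``.  Doses are in Gy,
distances in mm, reported volumes in cm^3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

AXIS_ORDER = "zyx"

__all__ = [
    "AXIS_ORDER",
    "DoseGrid",
    "PlanarDose",
    "StructureMask",
    "ContourSet",
    "ContourSlice",
    "MediumLabelMap",
    "MEDIA",
]

#: canonical medium labels for the thorax phantom
MEDIA = ("outside", "lung", "soft tissue", "bone")


def _check_spacing(spacing: tuple[float, ...], ndim: int) -> tuple[float, ...]:
    spacing = tuple(float(s) for s in spacing)
    if len(spacing) != ndim:
        raise ValueError(f"spacing must have {ndim} entries, got {len(spacing)}")
    if any(s <= 0 for s in spacing):
        raise ValueError(f"spacing must be positive, got {spacing}")
    return spacing


@dataclass
class DoseGrid:
    """A 3D scalar dose field (Gy) on a regular grid.

    Parameters
    ----------
    values : ndarray, shape (nz, ny, nx)
        Absorbed dose per voxel in Gy; must be non-negative.
    spacing : tuple of float
        Voxel spacing in mm per axis, ``(dz, dy, dx)``.
    origin : tuple of float
        Position (mm) of the centre of voxel ``(0, 0, 0)``.
    axis_order : str
        Convention tag; always ``"zyx"``.
    flipped_z : bool
        True when the source file stored slices with descending z and the
        grid was re-sorted ascending on read.
    """

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    axis_order: str = AXIS_ORDER
    flipped_z: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 3:
            raise ValueError(f"DoseGrid expects 3D values, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("DoseGrid values must be non-empty")
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")
        self.spacing = _check_spacing(self.spacing, 3)
        self.origin = tuple(float(o) for o in self.origin)
        if self.axis_order != AXIS_ORDER:
            raise ValueError(f"unsupported axis order {self.axis_order!r}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        """Volume of one voxel in cm^3."""
        return float(np.prod(self.spacing)) / 1000.0

    def axis_coords(self, axis: int) -> np.ndarray:
        """Physical coordinates (mm) of voxel centres along one axis."""
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_geometry(self, other: "DoseGrid | StructureMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class PlanarDose:
    """A 2D dose plane (Gy), e.g. a film measurement or an exported TPS plane."""

    values: np.ndarray
    spacing: tuple[float, float]
    origin: tuple[float, float] = (0.0, 0.0)
    label: str = ""

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.ndim != 2:
            raise ValueError(f"PlanarDose expects 2D values, got ndim={self.values.ndim}")
        if self.values.size == 0:
            raise ValueError("PlanarDose values must be non-empty")
        if np.any(self.values < 0):
            raise ValueError("doses must be non-negative")
        self.spacing = _check_spacing(self.spacing, 2)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)


@dataclass
class StructureMask:
    """A binary voxel mask aligned to a :class:`DoseGrid` geometry."""

    values: np.ndarray
    spacing: tuple[float, float, float]
    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    name: str = ""
    role: str = "other"  # CTV|PTV|lung|cord|oesophagus|external|other

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values).astype(bool)
        if self.values.ndim != 3:
            raise ValueError("StructureMask expects a 3D array")
        if self.values.size == 0:
            raise ValueError("StructureMask values must be non-empty")
        self.spacing = _check_spacing(self.spacing, 3)
        self.origin = tuple(float(o) for o in self.origin)

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.values.shape

    @property
    def voxel_volume_cm3(self) -> float:
        return float(np.prod(self.spacing)) / 1000.0

    @property
    def volume_cm3(self) -> float:
        """Total mask volume in cm^3 (voxel count x voxel volume)."""
        return float(np.count_nonzero(self.values)) * self.voxel_volume_cm3

    def is_empty(self) -> bool:
        return not bool(self.values.any())

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def same_geometry(self, other: "DoseGrid | StructureMask") -> bool:
        return (
            self.values.shape == other.values.shape
            and np.allclose(self.spacing, other.spacing)
            and np.allclose(self.origin, other.origin)
        )


@dataclass
class ContourSlice:
    """All closed polygons of one structure on one axial slice."""

    z: float
    polygons: list[np.ndarray] = field(default_factory=list)  # each (n, 2) of (y, x) mm

    def __post_init__(self) -> None:
        self.z = float(self.z)
        checked = []
        for poly in self.polygons:
            poly = np.asarray(poly, dtype=np.float64)
            if poly.ndim != 2 or poly.shape[1] != 2 or poly.shape[0] < 3:
                raise ValueError("each polygon needs >= 3 (y, x) vertices")
            checked.append(poly)
        self.polygons = checked


@dataclass
class ContourSet:
    """Per-slice closed polygons of one ROI, ordered by increasing z."""

    name: str
    slices: list[ContourSlice] = field(default_factory=list)

    def __post_init__(self) -> None:
        zs = [s.z for s in self.slices]
        if any(b <= a for a, b in zip(zs, zs[1:])):
            raise ValueError("slice z positions must be strictly increasing")

    @property
    def z_positions(self) -> np.ndarray:
        return np.array([s.z for s in self.slices])

    def is_empty(self) -> bool:
        return not self.slices


@dataclass
class MediumLabelMap:
    """Per-voxel medium labels aligned to a dose geometry.

    ``values`` holds small integer codes indexing into ``labels``; every voxel
    belongs to exactly one medium ("outside" marks air beyond the body).
    """

    values: np.ndarray
    spacing: tuple[float, ...]
    origin: tuple[float, ...] = (0.0, 0.0, 0.0)
    labels: tuple[str, ...] = MEDIA

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int16)
        if self.values.ndim not in (2, 3):
            raise ValueError("MediumLabelMap expects a 2D or 3D array")
        self.spacing = _check_spacing(self.spacing, self.values.ndim)
        self.origin = tuple(float(o) for o in self.origin)
        if self.values.size and (
            self.values.min() < 0 or self.values.max() >= len(self.labels)
        ):
            raise ValueError("label codes out of range")

    def region(self, label: str) -> np.ndarray:
        """Boolean field selecting one medium."""
        return self.values == self.labels.index(label)

    def axis_coords(self, axis: int) -> np.ndarray:
        n = self.values.shape[axis]
        return self.origin[axis] + self.spacing[axis] * np.arange(n)

    def plane(self, index: int) -> "MediumLabelMap":
        """Extract one axial slice as a 2D label map."""
        if self.values.ndim != 3:
            raise ValueError("plane() requires a 3D label map")
        return MediumLabelMap(
            self.values[index],
            spacing=self.spacing[1:],
            origin=self.origin[1:],
            labels=self.labels,
        )
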