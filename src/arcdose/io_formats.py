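"""Reading and writing the formats the pipeline touches.

Supported formats:

* DICOM RT Dose (read, plus a minimal writer used to build test fixtures);
* DICOM RT Structure Set (read + minimal fixture writer);
* a portable grid format — a raw little-endian array next to a JSON sidecar
  carrying shape, spacing, origin and provenance — used for all intermediate
  artifacts so that no DICOM dependency leaks into downstream modules.

DICOM RT Dose stores integers with a grid scaling factor; doses returned here
are always in Gy with the scaling applied.  Frames with descending z are
re-sorted ascending on read and the flip is recorded on the grid.
"""

from __future__ import annotations

import datetime
import json
import warnings
from pathlib import Path

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileDataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid

from .grids import MEDIA, ContourSet, ContourSlice, DoseGrid, MediumLabelMap, PlanarDose, StructureMask

__all__ = [
    "FormatError",
    "read_rt_dose",
    "write_rt_dose",
    "read_rt_struct",
    "write_rt_struct",
    "write_portable",
    "read_portable",
]

RT_DOSE_STORAGE = "1.2.840.10008.5.1.4.1.1.481.2"
RT_STRUCT_STORAGE = "1.2.840.10008.5.1.4.1.1.481.3"

_SLICE_SPACING_TOL = 1e-3  # mm; non-uniform frame offsets beyond this are rejected


class FormatError(ValueError):
    """Raised when a file violates the format contract."""


# ---------------------------------------------------------------------------
# DICOM RT Dose


def read_rt_dose(path: str | Path) -> DoseGrid | PlanarDose:
    """Read a DICOM RT Dose file into a :class:`DoseGrid` (or a
    :class:`PlanarDose` for single-frame files).

    Doses are returned in Gy with ``DoseGridScaling`` applied.  Multi-frame
    files must carry a ``GridFrameOffsetVector`` with uniform spacing (within
    1e-3 mm); descending z is re-sorted ascending with ``flipped_z`` set.
    """
    ds = pydicom.dcmread(str(path))
    scaling = float(getattr(ds, "DoseGridScaling", 1.0))
    raw = ds.pixel_array  # (frames, rows, cols) or (rows, cols)
    values = raw.astype(np.float64) * scaling

    dy, dx = (float(v) for v in ds.PixelSpacing)  # row spacing, column spacing
    ipp = [float(v) for v in ds.ImagePositionPatient]  # (x, y, z)
    x0, y0, z0 = ipp

    if values.ndim == 2 or values.shape[0] == 1:
        plane = values if values.ndim == 2 else values[0]
        return PlanarDose(
            plane,
            spacing=(dy, dx),
            origin=(y0, x0),
            label=str(getattr(ds, "SeriesDescription", "")),
        )

    offsets = getattr(ds, "GridFrameOffsetVector", None)
    if offsets is None:
        raise FormatError(f"{path}: multi-frame RT Dose without GridFrameOffsetVector")
    offsets = np.asarray([float(v) for v in offsets])
    if len(offsets) != values.shape[0]:
        raise FormatError(
            f"{path}: {len(offsets)} frame offsets for {values.shape[0]} frames"
        )
    steps = np.diff(offsets)
    if len(steps) == 0:
        raise FormatError(f"{path}: degenerate single-offset multi-frame dose")
    if np.ptp(np.abs(steps)) > _SLICE_SPACING_TOL:
        raise FormatError(
            f"{path}: non-uniform slice spacing (range {np.ptp(np.abs(steps)):.4g} mm "
            f"exceeds {_SLICE_SPACING_TOL} mm tolerance)"
        )
    flipped = bool(steps[0] < 0)
    if flipped:
        values = values[::-1]
        offsets = offsets[::-1]
    dz = float(abs(steps[0]))
    return DoseGrid(
        values,
        spacing=(dz, dy, dx),
        origin=(z0 + offsets[0], y0, x0),
        flipped_z=flipped,
    )


def _file_meta(sop_class: str) -> FileMetaDataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    return meta


def _common_fields(ds: FileDataset, modality: str) -> None:
    now = datetime.datetime(2000, 1, 1)
    ds.PatientName = "Phantom^Synthetic"
    ds.PatientID = "SYN000"
    ds.Modality = modality
    ds.StudyInstanceUID = generate_uid()
    ds.SeriesInstanceUID = generate_uid()
    ds.SOPInstanceUID = ds.file_meta.MediaStorageSOPInstanceUID
    ds.SOPClassUID = ds.file_meta.MediaStorageSOPClassUID
    ds.ContentDate = now.strftime("%Y%m%d")
    ds.ContentTime = now.strftime("%H%M%S")


def write_rt_dose(
    grid: DoseGrid | PlanarDose,
    path: str | Path,
    scaling: float | None = None,
    descending_z: bool = False,
) -> None:
    """Write a grid as a DICOM RT Dose file (32-bit ints + grid scaling).

    Primarily a fixture generator for tests; ``descending_z`` stores frames
    with decreasing z offsets to exercise the read-time re-sort.
    """
    values = grid.values
    if scaling is None:
        vmax = float(values.max())
        scaling = vmax / (2**31 - 1) if vmax > 0 else 1.0
    stored = np.round(values / scaling).astype(np.uint32)

    ds = FileDataset(str(path), {}, file_meta=_file_meta(RT_DOSE_STORAGE), preamble=b"\0" * 128)
    _common_fields(ds, "RTDOSE")
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "PLAN"
    ds.DoseGridScaling = scaling
    ds.BitsAllocated = 32
    ds.BitsStored = 32
    ds.HighBit = 31
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"

    if isinstance(grid, PlanarDose):
        dy, dx = grid.spacing
        y0, x0 = grid.origin
        ds.Rows, ds.Columns = values.shape
        ds.PixelSpacing = [dy, dx]
        ds.ImagePositionPatient = [x0, y0, 0.0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.SeriesDescription = grid.label
        ds.PixelData = stored.tobytes()
    else:
        dz, dy, dx = grid.spacing
        z0, y0, x0 = grid.origin
        nz = values.shape[0]
        offsets = dz * np.arange(nz)
        if descending_z:
            stored = stored[::-1]
            offsets = offsets[::-1] - offsets[-1]
            z0 = z0 + dz * (nz - 1)
        ds.NumberOfFrames = nz
        ds.Rows, ds.Columns = values.shape[1:]
        ds.PixelSpacing = [dy, dx]
        ds.ImagePositionPatient = [x0, y0, z0]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.GridFrameOffsetVector = list(offsets)
        ds.PixelData = stored.tobytes()

    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# DICOM RT Structure Set


def read_rt_struct(path: str | Path) -> list[ContourSet]:
    """Read every ROI of an RT Structure Set as a list of :class:`ContourSet`.

    Vertices are returned in patient mm coordinates as (y, x) pairs per slice.
    An ROI without contour data yields an empty ContourSet with a warning
    rather than an exception, preserving file order.
    """
    ds = pydicom.dcmread(str(path))
    names = {}
    for roi in getattr(ds, "StructureSetROISequence", []):
        names[int(roi.ROINumber)] = str(roi.ROIName)

    out: list[ContourSet] = []
    for rc in getattr(ds, "ROIContourSequence", []):
        number = int(rc.ReferencedROINumber)
        name = names.get(number, f"ROI-{number}")
        contours = getattr(rc, "ContourSequence", None)
        if not contours:
            warnings.warn(f"{path}: ROI {name!r} has no contour data", stacklevel=2)
            out.append(ContourSet(name=name, slices=[]))
            continue
        by_z: dict[float, list[np.ndarray]] = {}
        for c in contours:
            data = np.asarray([float(v) for v in c.ContourData]).reshape(-1, 3)
            z = float(np.round(data[:, 2].mean(), 6))
            poly = data[:, [1, 0]]  # (y, x)
            by_z.setdefault(z, []).append(poly)
        slices = [ContourSlice(z=z, polygons=by_z[z]) for z in sorted(by_z)]
        out.append(ContourSet(name=name, slices=slices))
    return out


def write_rt_struct(contour_sets: list[ContourSet], path: str | Path) -> None:
    """Write ContourSets as a minimal DICOM RT Structure Set (test fixture)."""
    ds = FileDataset(str(path), {}, file_meta=_file_meta(RT_STRUCT_STORAGE), preamble=b"\0" * 128)
    _common_fields(ds, "RTSTRUCT")
    ds.StructureSetLabel = "synthetic"

    ds.StructureSetROISequence = []
    ds.ROIContourSequence = []
    for i, cs in enumerate(contour_sets, start=1):
        roi = Dataset()
        roi.ROINumber = i
        roi.ROIName = cs.name
        roi.ReferencedFrameOfReferenceUID = generate_uid()
        roi.ROIGenerationAlgorithm = "AUTOMATIC"
        ds.StructureSetROISequence.append(roi)

        rc = Dataset()
        rc.ReferencedROINumber = i
        seq = []
        for sl in cs.slices:
            for poly in sl.polygons:
                c = Dataset()
                c.ContourGeometricType = "CLOSED_PLANAR"
                c.NumberOfContourPoints = poly.shape[0]
                xyz = np.column_stack([poly[:, 1], poly[:, 0], np.full(len(poly), sl.z)])
                c.ContourData = [float(v) for v in xyz.ravel()]
                seq.append(c)
        if seq:
            rc.ContourSequence = seq
        ds.ROIContourSequence.append(rc)

    ds.save_as(str(path), enforce_file_format=True)


# ---------------------------------------------------------------------------
# Portable grid format (raw little-endian array + JSON sidecar)

_PORTABLE_TYPES = {
    "DoseGrid": DoseGrid,
    "PlanarDose": PlanarDose,
    "StructureMask": StructureMask,
    "MediumLabelMap": MediumLabelMap,
}


def _portable_paths(path: str | Path) -> tuple[Path, Path]:
    base = Path(path)
    if base.suffix in {".json", ".raw"}:
        base = base.with_suffix("")
    return base.with_suffix(".json"), base.with_suffix(".raw")


def write_portable(
    obj: DoseGrid | PlanarDose | StructureMask | MediumLabelMap,
    path: str | Path,
    provenance: dict | None = None,
) -> Path:
    """Write a grid-like object as ``<path>.raw`` + ``<path>.json``.

    The raw file holds the array in little-endian order (float64 for doses,
    uint8 for masks, int16 for label maps); the sidecar carries everything
    needed for a lossless round-trip plus optional provenance (e.g. the
    generator parameters that produced a synthetic grid).
    """
    if obj.values.size == 0:
        raise FormatError("refusing to write a 0-sized grid")
    sidecar_path, raw_path = _portable_paths(path)

    if isinstance(obj, StructureMask):
        arr = obj.values.astype("|u1")
    elif isinstance(obj, MediumLabelMap):
        arr = obj.values.astype("<i2")
    else:
        arr = obj.values.astype("<f8")

    meta: dict = {
        "format": "arcdose-portable-grid/1",
        "type": type(obj).__name__,
        "dtype": arr.dtype.str,
        "shape": list(arr.shape),
        "spacing_mm": list(obj.spacing),
        "origin_mm": list(obj.origin),
    }
    if isinstance(obj, DoseGrid):
        meta["flipped_z"] = obj.flipped_z
    if isinstance(obj, PlanarDose):
        meta["label"] = obj.label
    if isinstance(obj, StructureMask):
        meta["name"] = obj.name
        meta["role"] = obj.role
    if isinstance(obj, MediumLabelMap):
        meta["labels"] = list(obj.labels)
    if provenance:
        meta["provenance"] = provenance

    raw_path.write_bytes(arr.tobytes())
    sidecar_path.write_text(json.dumps(meta, indent=1))
    return sidecar_path


def read_portable(path: str | Path) -> DoseGrid | PlanarDose | StructureMask | MediumLabelMap:
    """Read a portable grid written by :func:`write_portable`."""
    sidecar_path, raw_path = _portable_paths(path)
    meta = json.loads(sidecar_path.read_text())
    if meta.get("format") != "arcdose-portable-grid/1":
        raise FormatError(f"{sidecar_path}: not a portable grid sidecar")
    shape = tuple(meta["shape"])
    arr = np.frombuffer(raw_path.read_bytes(), dtype=np.dtype(meta["dtype"]))
    if arr.size != int(np.prod(shape)):
        raise FormatError(
            f"{raw_path}: array size {arr.size} does not match sidecar shape {shape}"
        )
    arr = arr.reshape(shape)

    kind = meta["type"]
    spacing = tuple(meta["spacing_mm"])
    origin = tuple(meta["origin_mm"])
    if kind == "DoseGrid":
        return DoseGrid(arr, spacing=spacing, origin=origin, flipped_z=meta.get("flipped_z", False))
    if kind == "PlanarDose":
        return PlanarDose(arr, spacing=spacing, origin=origin, label=meta.get("label", ""))
    if kind == "StructureMask":
        return StructureMask(
            arr.astype(bool), spacing=spacing, origin=origin,
            name=meta.get("name", ""), role=meta.get("role", "other"),
        )
    if kind == "MediumLabelMap":
        return MediumLabelMap(arr, spacing=spacing, origin=origin, labels=tuple(meta.get("labels", MEDIA)))
    raise FormatError(f"{sidecar_path}: unknown portable type {kind!r}")


def read_portable_provenance(path: str | Path) -> dict:
    """Return the provenance dict recorded in a portable sidecar (may be empty)."""
    sidecar_path, _ = _portable_paths(path)
    return json.loads(sidecar_path.read_text()).get("provenance", {})
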