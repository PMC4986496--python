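"""DICOM-compatible image, contour, registration and dose I/O.

Fixed coordinate conventions used throughout the toolkit:

* patient coordinates are DICOM LPS-like: x increases toward the patient's
  left, y toward posterior, z toward superior; all lengths in mm;
* voxel indexing is 0-based ``[slice][row][col]`` with the stored value
  located at the voxel centre;
* contour vertices are absolute patient coordinates (not slice-relative);
* HU values are clamped at -1000 on ingest (-1000 is defined as zero
  density by the scan-circle masking semantics).

Setup corrections (couch shifts and roll) applied at each treatment
fraction travel in a private tag block of the MV CT headers; the private
creator and element layout are documented on :data:`REG_PRIVATE_CREATOR`.
"""

from __future__ import annotations

import datetime as _dt
import math
import os
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pydicom
from pydicom.dataset import Dataset, FileMetaDataset
from pydicom.uid import ExplicitVRLittleEndian, generate_uid
from shapely.geometry import Polygon as _ShapelyPolygon

__all__ = [
    "ImageVolume",
    "Registration",
    "ContourSet",
    "SliceContour",
    "DoseCube",
    "UnusableFractionError",
    "read_ct_series",
    "write_ct_series",
    "read_registration",
    "write_dose",
    "read_dose",
    "write_contours",
    "read_contours",
    "REG_PRIVATE_CREATOR",
    "REG_PRIVATE_GROUP",
]

HU_FLOOR = -1000

#: Private block carrying per-fraction setup corrections.  Elements within
#: the reserved block: 0x01 = dx (mm, DS), 0x02 = dy (mm, DS), 0x03 = dz
#: (mm, DS), 0x04 = roll (degrees, DS), 0x05 = usable flag (CS, "YES"/"NO").
REG_PRIVATE_CREATOR = "VOXCALC_REG"
REG_PRIVATE_GROUP = 0x7771

_CT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.2"
_RTSTRUCT_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.3"
_RTDOSE_SOP_CLASS = "1.2.840.10008.5.1.4.1.1.481.2"


class UnusableFractionError(RuntimeError):
    """Raised when a fraction flagged as unusable is asked to do work."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass
class ImageVolume:
    """A CT image stack in HU with geometry and acquisition metadata.

    ``voxels`` is indexed ``[slice][row][col]``; ``origin`` is the patient
    coordinate of the centre of voxel ``[0][0][0]``; ``pixel_spacing`` is
    the (row, col) in-plane spacing in mm; ``slice_positions`` the z
    coordinate of each slice (strictly increasing).
    """

    voxels: np.ndarray
    origin: tuple[float, float, float]
    pixel_spacing: tuple[float, float]
    slice_positions: np.ndarray
    modality: str = "kV"
    acquisition_date: _dt.date = _dt.date(2013, 1, 1)
    machine_id: str = "A"

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError("voxels must be a 3-D [slice][row][col] array")
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if len(self.slice_positions) != self.voxels.shape[0]:
            raise ValueError("one slice position per slice required")
        if len(self.slice_positions) > 1 and not np.all(
            np.diff(self.slice_positions) > 0
        ):
            raise ValueError("slice_positions must be strictly increasing")
        if self.modality not in ("kV", "MV"):
            raise ValueError(f"modality must be 'kV' or 'MV', got {self.modality!r}")
        if np.issubdtype(self.voxels.dtype, np.integer):
            self.voxels = np.maximum(self.voxels, HU_FLOOR)
        else:
            self.voxels = np.maximum(self.voxels, float(HU_FLOOR))
        self.origin = tuple(float(v) for v in self.origin)
        self.pixel_spacing = tuple(float(v) for v in self.pixel_spacing)

    # -- geometry helpers ---------------------------------------------------

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.voxels.shape

    @property
    def n_slices(self) -> int:
        return self.voxels.shape[0]

    @property
    def slice_spacing(self) -> float:
        if len(self.slice_positions) < 2:
            return 0.0
        return float(self.slice_positions[1] - self.slice_positions[0])

    def x_coords(self) -> np.ndarray:
        """Patient x of every column centre."""
        return self.origin[0] + np.arange(self.voxels.shape[2]) * self.pixel_spacing[1]

    def y_coords(self) -> np.ndarray:
        """Patient y of every row centre."""
        return self.origin[1] + np.arange(self.voxels.shape[1]) * self.pixel_spacing[0]

    def has_uniform_z(self, atol: float = 1e-6) -> bool:
        if len(self.slice_positions) < 2:
            return True
        d = np.diff(self.slice_positions)
        return bool(np.allclose(d, d[0], atol=atol))

    def copy(self) -> "ImageVolume":
        return replace(
            self, voxels=self.voxels.copy(), slice_positions=self.slice_positions.copy()
        )


@dataclass(frozen=True)
class Registration:
    """Per-fraction setup correction: couch shifts (mm) and roll (degrees).

    ``usable`` is False for images flagged as not immediately preceding
    treatment (machine breakdown, patient rescanned, ...), which must be
    excluded from recalculation.
    """

    dx: float
    dy: float
    dz: float
    roll: float
    usable: bool = True
    max_roll: float = 10.0

    def __post_init__(self) -> None:
        vals = (self.dx, self.dy, self.dz, self.roll)
        if not all(math.isfinite(v) for v in vals):
            raise ValueError("registration values must be finite")
        if abs(self.roll) >= self.max_roll:
            raise ValueError(
                f"|roll| = {abs(self.roll):.2f} deg exceeds the sanity bound "
                f"{self.max_roll} deg"
            )


@dataclass(frozen=True)
class SliceContour:
    """One closed planar polygon at slice position ``z`` (vertices in mm)."""

    z: float
    vertices: np.ndarray  # (n, 2) x/y patient coordinates, implicitly closed

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, dtype=float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ValueError("a contour needs >= 3 (x, y) vertices")
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
            if v.shape[0] < 3:
                raise ValueError("a contour needs >= 3 distinct vertices")
        poly = _ShapelyPolygon(v)
        if not poly.is_simple or poly.area <= 0:
            raise ValueError("contour must be a simple (non-self-intersecting) polygon")
        object.__setattr__(self, "vertices", v)

    @property
    def area(self) -> float:
        return _ShapelyPolygon(self.vertices).area


@dataclass
class ContourSet:
    """Per-slice closed polygons for one structure."""

    contours: list[SliceContour]
    frame_of_reference: str = ""
    name: str = "RECTUM"

    def __post_init__(self) -> None:
        self.contours = sorted(self.contours, key=lambda c: c.z)

    def slice_zs(self) -> np.ndarray:
        return np.array([c.z for c in self.contours])

    def at_z(self, z: float, atol: float = 1e-3) -> list[SliceContour]:
        return [c for c in self.contours if abs(c.z - z) <= atol]

    def z_extent(self) -> tuple[float, float]:
        zs = self.slice_zs()
        return float(zs.min()), float(zs.max())

    def __len__(self) -> int:
        return len(self.contours)


@dataclass
class DoseCube:
    """Dose in Gy on a grid derived from an MV image.

    In-plane spacing is the MV pixel spacing times ``downsample_factor``
    (a power of 2); the SI spacing follows the MV slice interval.
    """

    dose: np.ndarray
    origin: tuple[float, float, float]
    pixel_spacing: tuple[float, float]
    slice_positions: np.ndarray
    downsample_factor: int = 1

    def __post_init__(self) -> None:
        self.dose = np.asarray(self.dose, dtype=float)
        if self.dose.ndim != 3:
            raise ValueError("dose must be [slice][row][col]")
        if np.any(self.dose < 0):
            raise ValueError("dose values must be non-negative")
        f = self.downsample_factor
        if f < 1 or (f & (f - 1)) != 0:
            raise ValueError("downsample_factor must be a power of 2")
        self.slice_positions = np.asarray(self.slice_positions, dtype=float)
        if len(self.slice_positions) != self.dose.shape[0]:
            raise ValueError("one slice position per dose plane required")
        if len(self.slice_positions) > 1 and not np.all(
            np.diff(self.slice_positions) > 0
        ):
            raise ValueError("slice_positions must be strictly increasing")
        self.origin = tuple(float(v) for v in self.origin)
        self.pixel_spacing = tuple(float(v) for v in self.pixel_spacing)

    def x_coords(self) -> np.ndarray:
        return self.origin[0] + np.arange(self.dose.shape[2]) * self.pixel_spacing[1]

    def y_coords(self) -> np.ndarray:
        return self.origin[1] + np.arange(self.dose.shape[1]) * self.pixel_spacing[0]


# ---------------------------------------------------------------------------
# CT series I/O
# ---------------------------------------------------------------------------


def _base_dataset(sop_class: str) -> Dataset:
    meta = FileMetaDataset()
    meta.MediaStorageSOPClassUID = sop_class
    meta.MediaStorageSOPInstanceUID = generate_uid()
    meta.TransferSyntaxUID = ExplicitVRLittleEndian
    ds = Dataset()
    ds.file_meta = meta
    ds.SOPClassUID = sop_class
    ds.SOPInstanceUID = meta.MediaStorageSOPInstanceUID
    ds.PatientName = "ANON"
    ds.PatientID = "ANON"
    return ds


def _write_registration_tags(ds: Dataset, reg: Registration) -> None:
    block = ds.private_block(REG_PRIVATE_GROUP, REG_PRIVATE_CREATOR, create=True)
    block.add_new(0x01, "DS", f"{reg.dx:.6g}")
    block.add_new(0x02, "DS", f"{reg.dy:.6g}")
    block.add_new(0x03, "DS", f"{reg.dz:.6g}")
    block.add_new(0x04, "DS", f"{reg.roll:.6g}")
    if not reg.usable:
        # the skip flag is only ever written to mark exclusions
        block.add_new(0x05, "CS", "NO")


def write_ct_series(
    volume: ImageVolume,
    path: str | os.PathLike,
    registration: Registration | None = None,
) -> list[Path]:
    """Write a CT volume as one DICOM file per slice.

    When ``registration`` is given (MV series) the shifts/roll private tag
    block is added to every slice header.
    """
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    frame_uid = generate_uid()
    series_uid = generate_uid()
    vox = np.asarray(volume.voxels)
    vox_i = np.clip(np.rint(vox), -32768, 32767).astype(np.int16)
    files: list[Path] = []
    for k in range(volume.n_slices):
        ds = _base_dataset(_CT_SOP_CLASS)
        ds.Modality = "CT"
        ds.SeriesDescription = volume.modality
        ds.SeriesInstanceUID = series_uid
        ds.FrameOfReferenceUID = frame_uid
        ds.StationName = volume.machine_id
        ds.AcquisitionDate = volume.acquisition_date.strftime("%Y%m%d")
        ds.InstanceNumber = k + 1
        ds.ImagePositionPatient = [
            float(f"{volume.origin[0]:.6g}"),
            float(f"{volume.origin[1]:.6g}"),
            float(f"{volume.slice_positions[k]:.6g}"),
        ]
        ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
        ds.PixelSpacing = [volume.pixel_spacing[0], volume.pixel_spacing[1]]
        ds.SliceThickness = abs(volume.slice_spacing) or 1.0
        ds.Rows, ds.Columns = vox_i.shape[1], vox_i.shape[2]
        ds.BitsAllocated = 16
        ds.BitsStored = 16
        ds.HighBit = 15
        ds.PixelRepresentation = 1  # signed
        ds.SamplesPerPixel = 1
        ds.PhotometricInterpretation = "MONOCHROME2"
        ds.RescaleSlope = 1.0
        ds.RescaleIntercept = 0.0
        ds.PixelData = vox_i[k].tobytes()
        if registration is not None:
            _write_registration_tags(ds, registration)
        fn = path / f"ct_{k:04d}.dcm"
        ds.save_as(fn, enforce_file_format=True)
        files.append(fn)
    return files


def read_ct_series(path: str | os.PathLike) -> ImageVolume:
    """Read a directory of single-slice CT files into an :class:`ImageVolume`.

    Slices are sorted by ascending z regardless of on-disk order; rescale
    slope/intercept are applied to produce HU and values below -1000 are
    clamped.  Mixed frames of reference or non-uniform in-plane spacing
    are rejected.
    """
    path = Path(path)
    files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
    if not files:
        raise FileNotFoundError(f"no DICOM files in {path}")
    datasets = [pydicom.dcmread(f) for f in files]
    frames = {str(getattr(ds, "FrameOfReferenceUID", "")) for ds in datasets}
    if len(frames) != 1:
        raise ValueError(f"mixed frames of reference in {path}: {sorted(frames)}")
    spacings = {tuple(float(v) for v in ds.PixelSpacing) for ds in datasets}
    if len(spacings) != 1:
        raise ValueError(f"non-uniform in-plane spacing in {path}")
    for ds, f in zip(datasets, files):
        if "ImagePositionPatient" not in ds:
            raise ValueError(f"slice {f.name} is missing its position attribute")
    datasets.sort(key=lambda ds: float(ds.ImagePositionPatient[2]))
    first = datasets[0]
    slope = float(getattr(first, "RescaleSlope", 1.0))
    intercept = float(getattr(first, "RescaleIntercept", 0.0))
    vox = np.stack([ds.pixel_array for ds in datasets]).astype(np.float64)
    vox = vox * slope + intercept
    hu = np.maximum(np.rint(vox), HU_FLOOR).astype(np.int32)
    zs = np.array([float(ds.ImagePositionPatient[2]) for ds in datasets])
    date_str = str(getattr(first, "AcquisitionDate", "20130101"))
    date = _dt.datetime.strptime(date_str, "%Y%m%d").date()
    modality = str(getattr(first, "SeriesDescription", "kV"))
    if modality not in ("kV", "MV"):
        modality = "kV"
    return ImageVolume(
        voxels=hu,
        origin=(
            float(first.ImagePositionPatient[0]),
            float(first.ImagePositionPatient[1]),
            float(zs[0]),
        ),
        pixel_spacing=(float(first.PixelSpacing[0]), float(first.PixelSpacing[1])),
        slice_positions=zs,
        modality=modality,
        acquisition_date=date,
        machine_id=str(getattr(first, "StationName", "A")),
    )


# ---------------------------------------------------------------------------
# registration tags
# ---------------------------------------------------------------------------


def read_registration(meta: Dataset | str | os.PathLike) -> Registration:
    """Extract the per-fraction shift/roll record from MV series metadata.

    ``meta`` may be a pydicom dataset or a directory holding the MV
    series (the first slice header is used).  Missing shift tags raise;
    an absent roll tag defaults to 0 (the shifts-only case); an absent
    skip flag means the image is usable — the flag is only written to
    mark exclusions.
    """
    if not isinstance(meta, Dataset):
        path = Path(meta)
        files = sorted(p for p in path.iterdir() if p.suffix.lower() == ".dcm")
        if not files:
            raise FileNotFoundError(f"no DICOM files in {path}")
        meta = pydicom.dcmread(files[0], stop_before_pixels=True)
    try:
        block = meta.private_block(REG_PRIVATE_GROUP, REG_PRIVATE_CREATOR)
    except KeyError as exc:
        raise KeyError(
            "MV header carries no shift/roll private block "
            f"(creator {REG_PRIVATE_CREATOR!r})"
        ) from exc
    vals = {}
    for off, name in ((0x01, "dx"), (0x02, "dy"), (0x03, "dz")):
        try:
            vals[name] = float(block[off].value)
        except KeyError as exc:
            raise KeyError(
                f"missing shift tag {name!r} in MV registration block"
            ) from exc
    try:
        roll = float(block[0x04].value)
    except KeyError:
        import warnings

        warnings.warn("roll tag absent; assuming roll = 0", stacklevel=2)
        roll = 0.0
    try:
        usable = str(block[0x05].value).upper() != "NO"
    except KeyError:
        usable = True
    return Registration(vals["dx"], vals["dy"], vals["dz"], roll, usable)


# ---------------------------------------------------------------------------
# RTDOSE
# ---------------------------------------------------------------------------


def write_dose(cube: DoseCube, path: str | os.PathLike) -> Path:
    """Save a dose cube as a 16-bit GRID-type RTDOSE object."""
    if np.any(cube.dose < 0):
        raise ValueError("negative dose cannot be encoded")
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = _base_dataset(_RTDOSE_SOP_CLASS)
    ds.Modality = "RTDOSE"
    ds.SeriesInstanceUID = generate_uid()
    ds.FrameOfReferenceUID = generate_uid()
    ds.DoseUnits = "GY"
    ds.DoseType = "PHYSICAL"
    ds.DoseSummationType = "FRACTION"
    dmax = float(cube.dose.max())
    scaling = dmax / 65535.0 if dmax > 0 else 1.0
    scaling = float(f"{scaling:.10g}")
    ds.DoseGridScaling = scaling
    pix = np.rint(cube.dose / scaling).astype(np.uint32)
    pix = np.minimum(pix, 65535).astype(np.uint16)
    ds.ImagePositionPatient = [float(f"{v:.6g}") for v in cube.origin]
    ds.ImageOrientationPatient = [1, 0, 0, 0, 1, 0]
    ds.PixelSpacing = [cube.pixel_spacing[0], cube.pixel_spacing[1]]
    ds.NumberOfFrames = cube.dose.shape[0]
    ds.GridFrameOffsetVector = [
        float(f"{z - cube.slice_positions[0]:.6g}") for z in cube.slice_positions
    ]
    ds.Rows, ds.Columns = cube.dose.shape[1], cube.dose.shape[2]
    ds.BitsAllocated = 16
    ds.BitsStored = 16
    ds.HighBit = 15
    ds.PixelRepresentation = 0
    ds.SamplesPerPixel = 1
    ds.PhotometricInterpretation = "MONOCHROME2"
    ds.PixelData = pix.tobytes()
    block = ds.private_block(REG_PRIVATE_GROUP, REG_PRIVATE_CREATOR, create=True)
    block.add_new(0x10, "IS", str(cube.downsample_factor))
    ds.save_as(path, enforce_file_format=True)
    return path


def read_dose(path: str | os.PathLike) -> DoseCube:
    ds = pydicom.dcmread(path)
    scaling = float(ds.DoseGridScaling)
    dose = ds.pixel_array.astype(np.float64) * scaling
    if dose.ndim == 2:
        dose = dose[None]
    offsets = np.array([float(v) for v in ds.GridFrameOffsetVector])
    z0 = float(ds.ImagePositionPatient[2])
    factor = 1
    try:
        block = ds.private_block(REG_PRIVATE_GROUP, REG_PRIVATE_CREATOR)
        factor = int(block[0x10].value)
    except KeyError:
        pass
    return DoseCube(
        dose=dose,
        origin=(
            float(ds.ImagePositionPatient[0]),
            float(ds.ImagePositionPatient[1]),
            z0,
        ),
        pixel_spacing=(float(ds.PixelSpacing[0]), float(ds.PixelSpacing[1])),
        slice_positions=z0 + offsets,
        downsample_factor=factor,
    )


# ---------------------------------------------------------------------------
# RTSTRUCT
# ---------------------------------------------------------------------------


def write_contours(cset: ContourSet, path: str | os.PathLike) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    ds = _base_dataset(_RTSTRUCT_SOP_CLASS)
    ds.Modality = "RTSTRUCT"
    ds.SeriesInstanceUID = generate_uid()
    ds.StructureSetLabel = cset.name
    frame_uid = cset.frame_of_reference or generate_uid()

    roi = Dataset()
    roi.ROINumber = 1
    roi.ROIName = cset.name
    roi.ReferencedFrameOfReferenceUID = frame_uid
    ds.StructureSetROISequence = [roi]

    rc = Dataset()
    rc.ReferencedROINumber = 1
    items = []
    for c in cset.contours:
        item = Dataset()
        item.ContourGeometricType = "CLOSED_PLANAR"
        item.NumberOfContourPoints = c.vertices.shape[0]
        data: list[float] = []
        for x, y in c.vertices:
            data.extend([round(float(x), 4), round(float(y), 4), round(float(c.z), 4)])
        item.ContourData = data
        items.append(item)
    rc.ContourSequence = items
    ds.ROIContourSequence = [rc]
    ds.save_as(path, enforce_file_format=True)
    return path


def read_contours(path: str | os.PathLike, name: str | None = None) -> ContourSet:
    """Read the (single) structure from an RTSTRUCT file.

    Open polylines are rejected; all vertices must share their slice's z.
    """
    ds = pydicom.dcmread(path)
    roi = ds.StructureSetROISequence[0]
    contours: list[SliceContour] = []
    for item in ds.ROIContourSequence[0].ContourSequence:
        if str(item.ContourGeometricType) != "CLOSED_PLANAR":
            raise ValueError(
                f"unsupported contour type {item.ContourGeometricType!r}: "
                "only closed planar polygons are supported"
            )
        data = np.array([float(v) for v in item.ContourData]).reshape(-1, 3)
        zs = data[:, 2]
        if not np.allclose(zs, zs[0], atol=1e-3):
            raise ValueError("contour vertices must be coplanar in z")
        contours.append(SliceContour(z=float(zs[0]), vertices=data[:, :2]))
    return ContourSet(
        contours=contours,
        frame_of_reference=str(getattr(roi, "ReferencedFrameOfReferenceUID", "")),
        name=str(getattr(roi, "ROIName", name or "RECTUM")),
    )
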