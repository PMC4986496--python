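"""Composite kV/MV radiological path lengths.

The MV CT scan circle (38.6 cm diameter) is frequently too small to cover
the patient's lateral extent, so the planning kV image supplies the
anatomy outside the circle: the kV image is aligned to the delivery (MV)
frame using the fraction's couch shifts and roll, every kV voxel inside
the scan circle is set to -1000 (zero density), and the water-equivalent
path length (WEPL) to any point is the sum of a ray trace through the MV
image and one through the masked kV image.  No composite image is ever
built — tracing twice through the separate grids is cheaper and avoids
resampling either image.

Roll sign convention: positive roll rotates the patient's left side
anteriorly, i.e. the +x axis toward -y (viewed from superior this is a
clockwise in-plane rotation).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

from ._tracing import trace_batch
from .hu_calibration import CalibrationLine, hu_to_density
from .imaging_io import HU_FLOOR, ImageVolume, Registration, UnusableFractionError

__all__ = [
    "ScanCircle",
    "RaySegmentResult",
    "DoseGrid",
    "roll_matrix",
    "registration_transform",
    "mask_scan_circle",
    "align_kv",
    "trace_wepl",
    "wepl_batch",
    "dual_wepl",
    "dual_wepl_batch",
    "make_dose_grid",
]


@dataclass(frozen=True)
class ScanCircle:
    """The MV CT field-of-view circle; ``center`` is isocentre-referenced mm."""

    center: tuple[float, float] = (0.0, 0.0)
    diameter: float = 386.0

    def __post_init__(self) -> None:
        if self.diameter < 0:
            raise ValueError("scan circle diameter must be >= 0")


@dataclass(frozen=True)
class RaySegmentResult:
    """Geometric length and water-equivalent path length of one segment."""

    geometric_length: float  # mm
    wepl: float  # mm


@dataclass(frozen=True)
class DoseGrid:
    """Dose-calculation points: one plane of (x, y) per MV slice."""

    xs: np.ndarray
    ys: np.ndarray
    zs: np.ndarray
    spacing: tuple[float, float]
    downsample_factor: int

    @property
    def shape(self) -> tuple[int, int, int]:
        return (len(self.zs), len(self.ys), len(self.xs))


def roll_matrix(roll_deg: float) -> np.ndarray:
    """In-plane rotation by ``roll_deg`` (positive = left rotates anteriorly)."""
    th = np.deg2rad(roll_deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, s], [-s, c]])


def registration_transform(
    reg: Registration, isocentre: tuple[float, float] = (0.0, 0.0)
):
    """Planning-frame -> delivery-frame map ``T(q) = R(q - c) + c + (dx, dy)``.

    Returns (forward, inverse) callables acting on (n, 2) in-plane mm
    arrays; z is handled separately as ``z + dz``.
    """
    R = roll_matrix(reg.roll)
    c = np.asarray(isocentre, dtype=float)
    s = np.array([reg.dx, reg.dy])

    def forward(q: np.ndarray) -> np.ndarray:
        q = np.atleast_2d(np.asarray(q, dtype=float))
        return (q - c) @ R.T + c + s

    def inverse(p: np.ndarray) -> np.ndarray:
        p = np.atleast_2d(np.asarray(p, dtype=float))
        return (p - c - s) @ R + c

    return forward, inverse


# ---------------------------------------------------------------------------
# masking and alignment
# ---------------------------------------------------------------------------


def mask_scan_circle(
    kv_image: ImageVolume,
    circle: ScanCircle,
    isocentre: tuple[float, float] = (0.0, 0.0),
) -> ImageVolume:
    """Set every voxel whose in-plane centre lies strictly inside the scan
    circle to -1000 (zero density).

    Boundary voxels (centre exactly on the circle) are left unmasked;
    masking is idempotent.
    """
    cx = isocentre[0] + circle.center[0]
    cy = isocentre[1] + circle.center[1]
    r = circle.diameter / 2.0
    xs = kv_image.x_coords() - cx
    ys = kv_image.y_coords() - cy
    inside = (xs[None, :] ** 2 + ys[:, None] ** 2) < r * r
    out = kv_image.copy()
    out.voxels[:, inside] = HU_FLOOR
    return out


def align_kv(
    kv_image: ImageVolume,
    registration: Registration,
    isocentre: tuple[float, float] = (0.0, 0.0),
) -> ImageVolume:
    """Resample the kV volume into the delivery (MV) frame.

    In-plane, each output voxel at patient position ``p`` takes the
    (bilinearly interpolated) kV value at ``T^-1(p)`` where ``T`` applies
    the roll about the isocentre axis then the (dx, dy) shift.  Along z
    the slice coordinates are simply shifted by dz — kV slices are finer
    than the 6-mm MV planes, so no z resampling is performed.  Voxels
    mapping outside the original field get -1000.
    """
    if not registration.usable:
        raise UnusableFractionError(
            "registration is flagged unusable; this fraction must be skipped"
        )
    _, inverse = registration_transform(registration, isocentre)
    sy, sx = kv_image.pixel_spacing
    ox, oy = kv_image.origin[0], kv_image.origin[1]

    # Compose the index-space affine for scipy: input_index = M @ out_index + off
    # patient p = origin + idx * spacing (x uses col spacing, y row spacing)
    R = roll_matrix(registration.roll)
    c = np.array([isocentre[0], isocentre[1]])
    s = np.array([registration.dx, registration.dy])
    # inverse map on (x, y): q = R^T ... careful: inverse(p) = (p - c - s) @ R + c
    # equivalently q = Rinv @ (p - c - s) + c with Rinv = R^T applied on column vecs
    Rinv = R.T  # (p - c - s) @ R == R.T @ (p - c - s) for column vectors
    # index order for a slice array is (row=y, col=x)
    S = np.diag([sy, sx])  # idx(row, col) -> (y, x)
    Sinv = np.diag([1.0 / sy, 1.0 / sx])
    P = np.array([[0.0, 1.0], [1.0, 0.0]])  # swap (y,x) <-> (x,y)
    A = Sinv @ P @ Rinv @ P @ S
    o = np.array([oy, ox])
    b = Sinv @ (P @ (Rinv @ (P @ o - c - s) + c) - o)

    out = np.empty_like(kv_image.voxels, dtype=float)
    src = kv_image.voxels.astype(float)
    for k in range(kv_image.n_slices):
        out[k] = ndimage.affine_transform(
            src[k], A, offset=b, order=1, mode="constant", cval=float(HU_FLOOR)
        )
    out = np.maximum(np.rint(out), HU_FLOOR)
    return replace(
        kv_image,
        voxels=out.astype(kv_image.voxels.dtype)
        if np.issubdtype(kv_image.voxels.dtype, np.integer)
        else out,
        slice_positions=kv_image.slice_positions + registration.dz,
        origin=(
            kv_image.origin[0],
            kv_image.origin[1],
            kv_image.origin[2] + registration.dz,
        ),
    )


# ---------------------------------------------------------------------------
# ray tracing
# ---------------------------------------------------------------------------


def density_volume(volume: ImageVolume, line: CalibrationLine) -> np.ndarray:
    """Relative-electron-density array for a volume under a calibration."""
    return hu_to_density(volume.voxels.astype(float), line)


def _bounds(volume: ImageVolume) -> tuple[float, float, float, float, float, float]:
    sy, sx = volume.pixel_spacing
    if volume.n_slices > 1:
        if not volume.has_uniform_z(atol=1e-6):
            raise ValueError("ray tracing requires uniform slice spacing")
        sz = float(volume.slice_positions[1] - volume.slice_positions[0])
    else:
        sz = 1.0
    bx = volume.origin[0] - sx / 2.0
    by = volume.origin[1] - sy / 2.0
    bz = float(volume.slice_positions[0]) - sz / 2.0
    return bx, by, bz, sx, sy, sz


def wepl_batch(
    sources: np.ndarray,
    targets: np.ndarray,
    volume: ImageVolume,
    line: CalibrationLine,
    density: np.ndarray | None = None,
) -> np.ndarray:
    """WEPL (mm) of many segments through one volume.

    ``density`` may be passed to reuse a precomputed density array.
    """
    p0 = np.ascontiguousarray(np.atleast_2d(sources), dtype=np.float64)
    p1 = np.ascontiguousarray(np.atleast_2d(targets), dtype=np.float64)
    dens = density if density is not None else density_volume(volume, line)
    dens = np.ascontiguousarray(dens, dtype=np.float64)
    bx, by, bz, sx, sy, sz = _bounds(volume)
    return trace_batch(p0, p1, dens, bx, by, bz, sx, sy, sz)


def trace_wepl(
    source_point,
    target_point,
    volume: ImageVolume,
    line: CalibrationLine,
) -> RaySegmentResult:
    """Exact voxel-boundary WEPL of the segment source -> target (mm)."""
    p0 = np.asarray(source_point, dtype=float)
    p1 = np.asarray(target_point, dtype=float)
    length = float(np.linalg.norm(p1 - p0))
    if length == 0.0:
        return RaySegmentResult(0.0, 0.0)
    w = wepl_batch(p0[None], p1[None], volume, line)
    return RaySegmentResult(length, float(w[0]))


def dual_wepl(
    source,
    target,
    mv_image: ImageVolume,
    masked_kv: ImageVolume,
    cal_mv: CalibrationLine,
    cal_kv: CalibrationLine,
) -> float:
    """WEPL = trace through MV image + trace through masked, aligned kV."""
    w_mv = trace_wepl(source, target, mv_image, cal_mv).wepl
    w_kv = trace_wepl(source, target, masked_kv, cal_kv).wepl
    return w_mv + w_kv


def dual_wepl_batch(
    sources: np.ndarray,
    targets: np.ndarray,
    mv_image: ImageVolume,
    masked_kv: ImageVolume | None,
    cal_mv: CalibrationLine,
    cal_kv: CalibrationLine | None,
    dens_mv: np.ndarray | None = None,
    dens_kv: np.ndarray | None = None,
) -> np.ndarray:
    w = wepl_batch(sources, targets, mv_image, cal_mv, density=dens_mv)
    if masked_kv is not None:
        w = w + wepl_batch(sources, targets, masked_kv, cal_kv, density=dens_kv)
    return w


# ---------------------------------------------------------------------------
# dose grid
# ---------------------------------------------------------------------------


def make_dose_grid(mv_image: ImageVolume, downsample_factor: int = 2) -> DoseGrid:
    """Dose-calculation points on the MV geometry.

    In-plane spacing is the MV pixel spacing times the (power-of-2)
    downsampling factor, starting at the first voxel centre; one plane
    per MV slice (the SI spacing follows the 6-mm MV interval).
    """
    f = int(downsample_factor)
    if f < 1 or (f & (f - 1)) != 0:
        raise ValueError(f"downsample factor must be a power of 2, got {downsample_factor}")
    sy, sx = mv_image.pixel_spacing
    nz, ny, nx = mv_image.shape
    xs = mv_image.origin[0] + np.arange(0, nx, f) * sx
    ys = mv_image.origin[1] + np.arange(0, ny, f) * sy
    return DoseGrid(
        xs=xs,
        ys=ys,
        zs=mv_image.slice_positions.copy(),
        spacing=(sy * f, sx * f),
        downsample_factor=f,
    )
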