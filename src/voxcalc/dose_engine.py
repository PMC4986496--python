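"""Per-fraction dose reconstruction from a helical plan sinogram.

The plan is a sinogram of per-leaf open-time fractions for each of the
projections of a continuously rotating helical delivery.  Each
projection is expanded into seven control points (subprojections)
uniformly subdividing its gantry arc and couch travel; a fraction's roll
correction is applied by offsetting every control-point gantry angle by
the roll, exactly mimicking delivery (this rotates the dose distribution
relative to the MV image).

The beamlet dose model here is a deliberately simple, interface-complete
stand-in for a commissioned engine: exponential attenuation in
water-equivalent depth, inverse-square fall-off, and a Gaussian lateral
leaf profile.  It is adequate for geometric and algorithmic studies
(linearity, roll handling, composite ray tracing, density-change
sensitivity), not for absolute clinical dosimetry.

Gantry angle 0 has the source anterior of the isocentre (source at
``(iso_x, iso_y - SAD)``), increasing toward the patient's left.
"""

from __future__ import annotations

import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
from scipy import ndimage

from .composite_raytrace import (
    DoseGrid,
    dual_wepl_batch,
    density_volume,
    make_dose_grid,
)
from .hu_calibration import CalibrationLine
from .imaging_io import DoseCube, ImageVolume, Registration, UnusableFractionError

__all__ = [
    "HelicalPlan",
    "ControlPoint",
    "expand_control_points",
    "beamlet_dose",
    "compute_fraction_dose",
    "box_index",
    "load_plan",
    "save_plan",
]


@dataclass
class HelicalPlan:
    """A simplified helical delivery: sinogram plus machine geometry.

    ``leaf_open`` is ``[projection][leaf]`` in [0, 1]; projections run
    over all rotations (``projections_per_rotation * n_rotations`` rows).
    ``pitch`` is couch travel in mm per rotation, ``couch_start`` the
    couch z at the start of the first projection.  ``field_width`` is the
    longitudinal aperture at the isocentre: a control point only
    irradiates grid points within half a field width of its couch z.
    """

    leaf_open: np.ndarray
    projections_per_rotation: int = 51
    n_rotations: int = 1
    pitch: float = 15.0
    gantry_start: float = 0.0
    couch_start: float = 0.0
    n_leaves: int = 64
    leaf_width_at_iso: float = 6.25
    fan_extent: float = 400.0
    field_width: float = 25.0
    source_axis_distance: float = 850.0
    output_factor: float = 2.0
    dose_scale: float = 1.0
    mu_eff: float = 0.05  # effective attenuation, 1/cm of water-equivalent depth

    def __post_init__(self) -> None:
        self.leaf_open = np.asarray(self.leaf_open, dtype=float)
        n_proj = self.projections_per_rotation * self.n_rotations
        if self.leaf_open.shape != (n_proj, self.n_leaves):
            raise ValueError(
                f"leaf_open must be ({n_proj}, {self.n_leaves}), "
                f"got {self.leaf_open.shape}"
            )
        if np.any(self.leaf_open < 0) or np.any(self.leaf_open > 1):
            raise ValueError("leaf open fractions must lie in [0, 1]")
        if self.pitch < 0:
            raise ValueError("pitch must be >= 0")
        if self.projections_per_rotation < 1:
            raise ValueError("projections_per_rotation must be >= 1")

    @property
    def n_projections(self) -> int:
        return self.leaf_open.shape[0]

    def leaf_centers(self) -> np.ndarray:
        """Lateral leaf-centre positions at the isocentre (mm)."""
        i = np.arange(self.n_leaves)
        return (i - (self.n_leaves - 1) / 2.0) * self.leaf_width_at_iso

    @property
    def lateral_sigma(self) -> float:
        # Gaussian leaf profile with FWHM equal to the leaf width
        return self.leaf_width_at_iso / 2.355


@dataclass(frozen=True)
class ControlPoint:
    """One subprojection: gantry angle (roll already applied), couch z, weight."""

    gantry_angle: float  # degrees
    couch_z: float  # mm
    weight: float  # fraction of the projection's open time
    projection: int  # index into the sinogram


def expand_control_points(
    plan: HelicalPlan, roll: float = 0.0, n_sub: int = 7
) -> list[ControlPoint]:
    """Expand every projection into ``n_sub`` control points.

    The control points uniformly subdivide both the projection's gantry
    arc and its couch travel (midpoint rule), each with weight
    ``1/n_sub``; every gantry angle is incremented by the fraction's roll.
    """
    if n_sub < 1:
        raise ValueError("n_sub must be >= 1")
    arc = 360.0 / plan.projections_per_rotation
    travel = plan.pitch / plan.projections_per_rotation
    cps: list[ControlPoint] = []
    for p in range(plan.n_projections):
        for k in range(n_sub):
            frac = (k + 0.5) / n_sub
            cps.append(
                ControlPoint(
                    gantry_angle=plan.gantry_start + (p + frac) * arc + roll,
                    couch_z=plan.couch_start + (p + frac) * travel,
                    weight=1.0 / n_sub,
                    projection=p,
                )
            )
    return cps


def beamlet_dose(
    open_fraction: float,
    wepl_mm: float,
    source_distance_mm: float,
    lateral_offset_mm: float,
    plan: HelicalPlan,
) -> float:
    """Dose (Gy) from one beamlet at one point.

    Normalised so that a fully open leaf at zero water-equivalent depth,
    at the source-axis distance and on the beamlet axis delivers
    ``plan.output_factor``.
    """
    if open_fraction == 0.0:
        return 0.0
    sad = plan.source_axis_distance
    atten = math.exp(-plan.mu_eff * wepl_mm / 10.0)
    inv_sq = (sad / source_distance_mm) ** 2
    sigma = plan.lateral_sigma
    profile = math.exp(-0.5 * (lateral_offset_mm / sigma) ** 2)
    return plan.output_factor * open_fraction * atten * inv_sq * profile


def _source_position(plan: HelicalPlan, angle_deg: float, couch_z: float,
                     isocentre: tuple[float, float]) -> np.ndarray:
    th = math.radians(angle_deg)
    sad = plan.source_axis_distance
    return np.array(
        [isocentre[0] + sad * math.sin(th), isocentre[1] - sad * math.cos(th), couch_z]
    )


def compute_fraction_dose(
    plan: HelicalPlan,
    mv_image: ImageVolume,
    masked_kv: ImageVolume | None,
    registration: Registration,
    cal_mv: CalibrationLine,
    cal_kv: CalibrationLine | None = None,
    downsample: int = 2,
    isocentre: tuple[float, float] = (0.0, 0.0),
    n_sub: int = 7,
) -> DoseCube:
    """Dose cube for one fraction on the MV-derived grid.

    For every grid point the beamlet doses of all control points whose
    fan reaches it are summed; water-equivalent depth comes from the dual
    (MV + masked kV) ray trace from the source position to the point.
    """
    if not registration.usable:
        raise UnusableFractionError(
            "fraction flagged unusable (image did not immediately precede "
            "treatment); dose is not recalculated"
        )
    grid = make_dose_grid(mv_image, downsample)
    cps = expand_control_points(plan, roll=registration.roll, n_sub=n_sub)

    dens_mv = np.ascontiguousarray(density_volume(mv_image, cal_mv))
    dens_kv = None
    if masked_kv is not None:
        if cal_kv is None:
            raise ValueError("cal_kv required when a masked kV image is supplied")
        dens_kv = np.ascontiguousarray(density_volume(masked_kv, cal_kv))

    X, Y = np.meshgrid(grid.xs, grid.ys)  # (ny, nx)
    npts_plane = X.size
    nz = len(grid.zs)
    dose = np.zeros((nz, X.shape[0], X.shape[1]))
    leaf_u = plan.leaf_centers()
    sigma = plan.lateral_sigma
    half_fw = plan.field_width / 2.0
    half_fan = plan.fan_extent / 2.0
    sad = plan.source_axis_distance
    flatX = X.ravel()
    flatY = Y.ravel()

    for cp in cps:
        zmask = np.abs(grid.zs - cp.couch_z) <= half_fw
        if not zmask.any():
            continue
        open_row = plan.leaf_open[cp.projection]
        if not open_row.any():
            continue
        S = _source_position(plan, cp.gantry_angle, cp.couch_z, isocentre)
        th = math.radians(cp.gantry_angle)
        ax, ay = -math.sin(th), math.cos(th)  # beam axis (unit, in-plane)
        tx, ty = math.cos(th), math.sin(th)  # transverse direction
        relx = flatX - S[0]
        rely = flatY - S[1]
        along = relx * ax + rely * ay
        valid = along > 1e-6
        u = np.zeros_like(along)
        u[valid] = (relx[valid] * tx + rely[valid] * ty) * sad / along[valid]
        fan = valid & (np.abs(u) <= half_fan)
        if not fan.any():
            continue
        # effective open fraction seen at each lateral position
        du = u[fan, None] - leaf_u[None, :]
        eff_open = (np.exp(-0.5 * (du / sigma) ** 2) * open_row[None, :]).sum(axis=1)
        keep = eff_open > 1e-9
        if not keep.any():
            continue
        fan_idx = np.flatnonzero(fan)[keep]
        eff_open = eff_open[keep]
        px = flatX[fan_idx]
        py = flatY[fan_idx]
        al = along[fan_idx]
        for iz in np.flatnonzero(zmask):
            z = grid.zs[iz]
            tgt = np.column_stack([px, py, np.full(px.shape, z)])
            src = np.tile(S, (len(fan_idx), 1))
            src[:, 2] = cp.couch_z
            wepl = dual_wepl_batch(
                src, tgt, mv_image, masked_kv, cal_mv, cal_kv, dens_mv, dens_kv
            )
            dist = np.sqrt((px - S[0]) ** 2 + (py - S[1]) ** 2 + (z - cp.couch_z) ** 2)
            contrib = (
                plan.output_factor
                * plan.dose_scale
                * cp.weight
                * eff_open
                * np.exp(-plan.mu_eff * wepl / 10.0)
                * (sad / dist) ** 2
            )
            np.add.at(dose[iz].ravel(), fan_idx, contrib)
    return DoseCube(
        dose=dose,
        origin=(float(grid.xs[0]), float(grid.ys[0]), float(grid.zs[0])),
        pixel_spacing=grid.spacing,
        slice_positions=grid.zs,
        downsample_factor=grid.downsample_factor,
    )


# ---------------------------------------------------------------------------
# dose comparison
# ---------------------------------------------------------------------------


def box_index(
    reference_cube: DoseCube,
    eval_cube: DoseCube,
    dose_tol: float = 0.03,
    dist_tol: float = 3.0,
    min_depth: float = 5.0,
    body_mask: np.ndarray | None = None,
) -> float:
    """Fraction of points passing a 3%/3 mm box comparison.

    A point passes when *any* reference point within the ``dist_tol`` box
    around it has dose within ``dose_tol`` of the global reference
    maximum of the evaluated dose.  Points shallower than ``min_depth``
    inside ``body_mask`` (and points outside the body) are excluded.
    """
    ref = reference_cube.dose
    ev = eval_cube.dose
    if ref.shape != ev.shape:
        raise ValueError("box_index requires commensurable (equal-shape) grids")
    sy, sx = eval_cube.pixel_spacing
    sz = (
        float(eval_cube.slice_positions[1] - eval_cube.slice_positions[0])
        if len(eval_cube.slice_positions) > 1
        else float("inf")
    )
    tol = dose_tol * float(ref.max())

    evaluable = np.ones(ev.shape, dtype=bool)
    if body_mask is not None:
        body_mask = np.asarray(body_mask, dtype=bool)
        depth = ndimage.distance_transform_edt(
            body_mask, sampling=(sz if np.isfinite(sz) else 1e6, sy, sx)
        )
        evaluable = body_mask & (depth >= min_depth)
    if not evaluable.any():
        raise ValueError("no evaluable points (body mask / depth excluded all)")

    nzo = int(dist_tol // sz) if np.isfinite(sz) else 0
    nyo = int(dist_tol // sy)
    nxo = int(dist_tol // sx)
    passed = np.zeros(ev.shape, dtype=bool)
    padded = np.pad(
        ref,
        ((nzo, nzo), (nyo, nyo), (nxo, nxo)),
        mode="constant",
        constant_values=np.inf,
    )
    nz, ny, nx = ev.shape
    for oz in range(-nzo, nzo + 1):
        for oy in range(-nyo, nyo + 1):
            for ox in range(-nxo, nxo + 1):
                shifted = padded[
                    nzo + oz : nzo + oz + nz,
                    nyo + oy : nyo + oy + ny,
                    nxo + ox : nxo + ox + nx,
                ]
                passed |= np.abs(shifted - ev) <= tol
    return float(passed[evaluable].mean())


# ---------------------------------------------------------------------------
# plan serialization
# ---------------------------------------------------------------------------


def save_plan(plan: HelicalPlan, path) -> Path:
    """Serialize a plan as structured text (JSON, keys = field names)."""
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    d = asdict(plan)
    d["leaf_open"] = plan.leaf_open.tolist()
    path.write_text(json.dumps(d, indent=1))
    return path


def load_plan(path) -> HelicalPlan:
    d = json.loads(Path(path).read_text())
    d["leaf_open"] = np.asarray(d["leaf_open"], dtype=float)
    return HelicalPlan(**d)
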