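"""Synthetic inputs: cheese phantom, pelvis phantom series, helical plans.

Everything the reconstruction pipeline consumes can be generated here,
so no external data is ever required:

* :func:`make_cheese_phantom` builds the cylindrical density-insert
  calibration phantom, including the plug-removal configurations used to
  probe sensitivity to large density changes;
* :func:`make_pelvis_series` builds a planning kV scan with ground-truth
  rectum contours plus a series of daily MV scans — coarse 6-mm slices,
  cropped to the 38.6-cm scan circle, with per-fraction couch
  shifts/roll, per-slice rectal deformation, gas pockets, and occasional
  low-contrast confusions that exercise the segmentation corrections;
* :func:`make_prostate_plan` builds a helical plan whose sinogram opens
  the leaves that geometrically cover a spherical target.

All generators are deterministic functions of their spec's ``seed``.
The pelvis body is a 400 x 300 mm ellipse, so its lateral edges fall
outside the scan circle and the composite kV/MV ray-trace path is
genuinely exercised.
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np

from .composite_raytrace import registration_transform
from .dose_engine import HelicalPlan, save_plan
from .hu_calibration import (
    INSERT_DENSITIES,
    CalibrationLine,
    KV_STANDARD_LINE,
    builtin_mv_calibration_table,
    density_to_hu,
    select_calibration,
    write_calibration_table,
)
from .imaging_io import (
    ContourSet,
    ImageVolume,
    Registration,
    SliceContour,
    write_contours,
    write_ct_series,
)

__all__ = [
    "PhantomSpec",
    "PelvisSpec",
    "PelvisSeries",
    "FractionData",
    "make_cheese_phantom",
    "make_pelvis_series",
    "make_prostate_plan",
    "make_dataset",
]


# ---------------------------------------------------------------------------
# cheese phantom
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PhantomSpec:
    """Cylindrical density-insert ("cheese") phantom.

    A 300-mm diameter water cylinder with 20 insert holes in two rings.
    ``configuration`` selects what the holes contain: the density-insert
    set (calibration measurements), unit-density plugs in every hole, the
    inner ring removed (air), or all plugs removed.
    """

    body_radius: float = 150.0
    inner_ring_radius: float = 50.0
    outer_ring_radius: float = 105.0
    n_inner: int = 8
    n_outer: int = 12
    hole_radius: float = 12.5
    configuration: str = "density_inserts"
    pixel_spacing: float = 2.0
    n_pixels: int = 170
    n_slices: int = 3
    slice_spacing: float = 6.0

    def __post_init__(self) -> None:
        if self.configuration not in (
            "density_inserts",
            "all_plugs",
            "inner_removed",
            "all_removed",
        ):
            raise ValueError(f"unknown configuration {self.configuration!r}")

    def hole_centers(self) -> np.ndarray:
        centers = []
        for n, r in ((self.n_inner, self.inner_ring_radius),
                     (self.n_outer, self.outer_ring_radius)):
            th = 2 * np.pi * np.arange(n) / n
            centers.extend(np.column_stack([r * np.cos(th), r * np.sin(th)]))
        return np.asarray(centers)

    def hole_densities(self) -> np.ndarray:
        n_holes = self.n_inner + self.n_outer
        if self.configuration == "density_inserts":
            pool = list(INSERT_DENSITIES) + [0.0, 1.0]  # inserts + air + water
            dens = [pool[i % len(pool)] for i in range(n_holes)]
            return np.asarray(dens)
        if self.configuration == "all_plugs":
            return np.ones(n_holes)
        if self.configuration == "inner_removed":
            return np.concatenate([np.zeros(self.n_inner), np.ones(self.n_outer)])
        return np.zeros(n_holes)  # all_removed


def make_cheese_phantom(
    spec: PhantomSpec, calibration: CalibrationLine
) -> tuple[ImageVolume, np.ndarray]:
    """Synthesize the phantom image and its ground-truth density map.

    HU values follow the forward calibration model
    ``HU = offset + slope * (rho - 1)``; air (density 0) maps to -1000
    regardless of calibration, matching the zero-density convention.
    """
    centers = spec.hole_centers()
    dists = np.linalg.norm(centers[:, None] - centers[None, :], axis=2)
    np.fill_diagonal(dists, np.inf)
    if dists.min() < 2 * spec.hole_radius:
        raise ValueError("insert holes overlap")
    if np.any(np.linalg.norm(centers, axis=1) + spec.hole_radius > spec.body_radius):
        raise ValueError("insert holes extend outside the phantom body")

    n = spec.n_pixels
    half = (n - 1) / 2.0 * spec.pixel_spacing
    xs = np.linspace(-half, half, n)
    X, Y = np.meshgrid(xs, xs)
    density = np.zeros((n, n))
    body = X**2 + Y**2 <= spec.body_radius**2
    density[body] = 1.0  # water
    for (cx, cy), rho in zip(centers, spec.hole_densities()):
        hole = (X - cx) ** 2 + (Y - cy) ** 2 <= spec.hole_radius**2
        density[hole] = rho

    hu = np.full((n, n), -1000.0)
    inside = density > 0
    hu[inside] = density_to_hu(density[inside], calibration)
    hu[body & ~inside] = -1000.0

    zs = spec.slice_spacing * (np.arange(spec.n_slices) - (spec.n_slices - 1) / 2.0)
    vol = ImageVolume(
        voxels=np.rint(np.repeat(hu[None], spec.n_slices, axis=0)).astype(np.int32),
        origin=(-half, -half, float(zs[0])),
        pixel_spacing=(spec.pixel_spacing, spec.pixel_spacing),
        slice_positions=zs,
        modality="MV",
        acquisition_date=_dt.date(2013, 6, 1),
        machine_id=calibration.machine_id,
    )
    density3d = np.repeat(density[None], spec.n_slices, axis=0)
    return vol, density3d


# ---------------------------------------------------------------------------
# pelvis phantom series
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class PelvisSpec:
    """Pelvis phantom with a deformable rectum, imaged over many fractions.

    Default geometry follows the clinical setting: MV images on 6-mm
    coarse slices with 0.76-mm pixels limited to the 38.6-cm scan
    circle, and a finer, wider planning kV scan.  Per-fraction setup
    errors are normal with the stated scales; per-slice rectal radius
    jitter deforms the organ between fractions.  ``lobe_prob`` controls
    occasional low-contrast material adjacent to the rectum (not part of
    the organ) emulating indistinct boundaries, and the most inferior
    portion of each MV scan loses rectum/muscle contrast entirely — the
    two failure modes the segmentation corrections exist for.
    """

    seed: int = 0
    n_fractions: int = 4
    # body and anatomy (planning frame, isocentre at the prostate centre)
    body_semi_axes: tuple[float, float] = (200.0, 150.0)
    body_hu_density: float = 1.03  # soft tissue
    fat_hu_density: float = 0.92
    rectum_center_y: float = 40.0  # posterior of the prostate (+y = posterior)
    rectum_radius: float = 14.0
    rectum_density: float = 1.02
    rectum_z_extent: tuple[float, float] = (-54.0, 54.0)
    wobble_amplitude: float = 5.0  # mm lateral centreline wobble
    wobble_period: float = 120.0  # mm
    prostate_radius: float = 20.0
    prostate_density: float = 1.04
    femoral_density: float = 1.7
    # per-fraction perturbations
    shift_sigma: float = 3.0  # mm, each axis
    roll_sigma: float = 1.0  # degrees
    radius_wave_amp: float = 0.06  # s.d. of the per-fraction smooth radius wave
    radius_wave_period: float = 80.0  # mm wavelength of the radius wave
    radius_jitter: float = 0.02  # small independent per-slice radius s.d.
    gas_prob: float = 0.3  # per-slice gas pocket probability
    lobe_prob: float = 0.1  # per-slice adjacent low-contrast lobe probability
    halo_prob: float = 0.12  # per-slice partial-ring low-contrast halo probability
    halo_depth: float = 5.0  # mm of rectum-like material beyond the wall
    halo_arc_deg: float = 240.0  # angular extent of the halo
    blur_inferior_slices: int = 2  # MV slices with no rectum/muscle contrast
    flagged_fractions: tuple[int, ...] = ()
    # imaging
    mv_pixels: int = 512
    mv_pixel_spacing: float = 0.76
    mv_n_slices: int = 12
    mv_slice_spacing: float = 6.0
    mv_noise_hu: float = 30.0
    kv_pixels: int = 384
    kv_pixel_spacing: float = 1.37
    kv_n_slices: int = 40
    kv_slice_spacing: float = 3.0
    kv_noise_hu: float = 10.0
    scan_circle_diameter: float = 386.0
    machine_id: str = "A"
    acquisition_date: _dt.date = _dt.date(2013, 6, 1)

    def small(self) -> "PelvisSpec":
        """A coarse variant for fast end-to-end runs."""
        return replace(
            self,
            mv_pixels=128,
            mv_pixel_spacing=3.04,
            mv_n_slices=6,
            kv_pixels=128,
            kv_pixel_spacing=4.11,
            kv_n_slices=20,
            kv_slice_spacing=6.0,
        )


@dataclass
class FractionData:
    """One treatment fraction: MV image, setup record, ground truth."""

    mv: ImageVolume
    registration: Registration
    gt_masks: np.ndarray  # (nz, ny, nx) bool rectum mask on the MV grid


@dataclass
class PelvisSeries:
    planning_kv: ImageVolume
    planning_contours: ContourSet
    planning_gt_masks: np.ndarray  # rectum mask on the kV grid
    rectum_si_extent: tuple[float, float]
    fractions: list[FractionData]
    spec: PelvisSpec


def _rectum_center(spec: PelvisSpec, z: np.ndarray | float) -> np.ndarray:
    cx = spec.wobble_amplitude * np.sin(2 * np.pi * np.asarray(z) / spec.wobble_period)
    return cx


def _anatomy_density(
    spec: PelvisSpec,
    X: np.ndarray,
    Y: np.ndarray,
    z_plan: float,
    rectum_radius: float,
) -> tuple[np.ndarray, np.ndarray]:
    """Planning-frame density slice and rectum mask at planning z."""
    a, b = spec.body_semi_axes
    density = np.zeros_like(X)
    body = (X / a) ** 2 + (Y / b) ** 2 <= 1.0
    density[body] = spec.body_hu_density
    # perirectal fat
    cz = _rectum_center(spec, z_plan)
    fat = ((X - cz) / 50.0) ** 2 + ((Y - (spec.rectum_center_y + 2)) / 45.0) ** 2 <= 1.0
    density[fat & body] = spec.fat_hu_density
    # femoral heads
    for sx in (-85.0, 85.0):
        fem = (X - sx) ** 2 + (Y - 5.0) ** 2 <= 22.0**2
        density[fem & body] = spec.femoral_density
    # prostate (sphere about the isocentre)
    pr2 = spec.prostate_radius**2 - z_plan**2
    if pr2 > 0:
        prost = X**2 + Y**2 <= pr2
        density[prost & body] = spec.prostate_density
    # rectum
    lo, hi = spec.rectum_z_extent
    rectum = np.zeros_like(body)
    if lo <= z_plan <= hi:
        rectum = (X - cz) ** 2 + (Y - spec.rectum_center_y) ** 2 <= rectum_radius**2
        rectum &= body
        density[rectum] = spec.rectum_density
    return density, rectum


def make_pelvis_series(
    spec: PelvisSpec,
    registrations: list[Registration] | None = None,
    calibration_table: list[CalibrationLine] | None = None,
) -> PelvisSeries:
    """Generate the planning scan, its rectum contours, and all fractions.

    The MV anatomy of fraction f is the planning anatomy mapped through
    the fraction's rigid setup transform (roll about the isocentre, then
    the couch shifts), with per-fraction/per-slice rectal deformation on
    top; the registration record stores exactly that transform, and the
    ground-truth masks are transformed consistently.  MV images are
    cropped to the scan circle and carry Gaussian HU noise.
    """
    rng = np.random.default_rng(spec.seed)
    table = calibration_table or builtin_mv_calibration_table()
    cal_mv = select_calibration(spec.acquisition_date, spec.machine_id, table)
    cal_kv = KV_STANDARD_LINE

    # ---- planning kV scan -------------------------------------------------
    nkv = spec.kv_pixels
    half_kv = (nkv - 1) / 2.0 * spec.kv_pixel_spacing
    xs_kv = np.linspace(-half_kv, half_kv, nkv)
    Xk, Yk = np.meshgrid(xs_kv, xs_kv)
    zs_kv = spec.kv_slice_spacing * (
        np.arange(spec.kv_n_slices) - (spec.kv_n_slices - 1) / 2.0
    )
    kv_vox = np.empty((spec.kv_n_slices, nkv, nkv))
    kv_masks = np.zeros((spec.kv_n_slices, nkv, nkv), dtype=bool)
    contours = []
    for k, z in enumerate(zs_kv):
        density, rectum = _anatomy_density(spec, Xk, Yk, float(z), spec.rectum_radius)
        hu = np.full(density.shape, -1000.0)
        inside = density > 0
        hu[inside] = density_to_hu(density[inside], cal_kv)
        kv_vox[k] = hu
        kv_masks[k] = rectum
        lo, hi = spec.rectum_z_extent
        if lo <= z <= hi:
            th = 2 * np.pi * np.arange(64) / 64
            cz = float(_rectum_center(spec, float(z)))
            contours.append(
                SliceContour(
                    z=float(z),
                    vertices=np.column_stack(
                        [
                            cz + spec.rectum_radius * np.cos(th),
                            spec.rectum_center_y + spec.rectum_radius * np.sin(th),
                        ]
                    ),
                )
            )
    if spec.kv_noise_hu > 0:
        kv_vox += rng.normal(0.0, spec.kv_noise_hu, kv_vox.shape)
    planning_kv = ImageVolume(
        voxels=np.rint(np.maximum(kv_vox, -1000)).astype(np.int32),
        origin=(-half_kv, -half_kv, float(zs_kv[0])),
        pixel_spacing=(spec.kv_pixel_spacing, spec.kv_pixel_spacing),
        slice_positions=zs_kv,
        modality="kV",
        acquisition_date=spec.acquisition_date,
        machine_id=spec.machine_id,
    )

    # ---- fractions --------------------------------------------------------
    nmv = spec.mv_pixels
    half_mv = (nmv - 1) / 2.0 * spec.mv_pixel_spacing
    xs_mv = np.linspace(-half_mv, half_mv, nmv)
    Xm, Ym = np.meshgrid(xs_mv, xs_mv)
    zs_mv = spec.mv_slice_spacing * (
        np.arange(spec.mv_n_slices) - (spec.mv_n_slices - 1) / 2.0
    )
    circle = Xm**2 + Ym**2 <= (spec.scan_circle_diameter / 2.0) ** 2

    fractions = []
    for f in range(spec.n_fractions):
        if registrations is not None:
            reg = registrations[f]
        else:
            dx, dy, dz = rng.normal(0.0, spec.shift_sigma, 3)
            roll = float(np.clip(rng.normal(0.0, spec.roll_sigma), -9.5, 9.5))
            reg = Registration(
                float(dx), float(dy), float(dz), roll,
                usable=f not in spec.flagged_fractions,
            )
        _, inverse = registration_transform(reg, isocentre=(0.0, 0.0))
        q = inverse(np.column_stack([Xm.ravel(), Ym.ravel()]))
        Xq = q[:, 0].reshape(Xm.shape)
        Yq = q[:, 1].reshape(Ym.shape)

        vox = np.empty((spec.mv_n_slices, nmv, nmv))
        masks = np.zeros((spec.mv_n_slices, nmv, nmv), dtype=bool)
        # smooth per-fraction deformation: the rectal radius varies slowly
        # along z (organs are smooth), plus a small independent jitter
        wave_amp = rng.normal(0.0, spec.radius_wave_amp)
        wave_phase = rng.uniform(0.0, 2 * np.pi)
        for k, z in enumerate(zs_mv):
            z_plan = float(z - reg.dz)
            shape_factor = 1.0 + wave_amp * np.sin(
                2 * np.pi * z_plan / spec.radius_wave_period + wave_phase
            )
            r_k = spec.rectum_radius * float(
                np.clip(
                    shape_factor * (1.0 + rng.normal(0.0, spec.radius_jitter)),
                    0.6,
                    1.5,
                )
            )
            density, rectum = _anatomy_density(spec, Xq, Yq, z_plan, r_k)
            cz = float(_rectum_center(spec, z_plan))
            lo, hi = spec.rectum_z_extent
            in_rectum_z = lo <= z_plan <= hi
            # low-contrast lobe adjacent to the rectum (not part of the organ)
            if in_rectum_z and rng.random() < spec.lobe_prob:
                ang = rng.uniform(0, 2 * np.pi)
                lx = cz + (r_k + 6.0) * np.cos(ang)
                ly = spec.rectum_center_y + (r_k + 6.0) * np.sin(ang)
                lobe = (Xq - lx) ** 2 + (Yq - ly) ** 2 <= 8.0**2
                density[lobe & (density > 0) & ~rectum] = spec.rectum_density
            # partial-ring halo of rectum-like material (indistinct wall)
            if in_rectum_z and rng.random() < spec.halo_prob:
                start = rng.uniform(0, 2 * np.pi)
                halo = (Xq - cz) ** 2 + (Yq - spec.rectum_center_y) ** 2 <= (
                    r_k + spec.halo_depth
                ) ** 2
                ang = np.arctan2(Yq - spec.rectum_center_y, Xq - cz)
                in_arc = np.mod(ang - start, 2 * np.pi) <= np.deg2rad(
                    spec.halo_arc_deg
                )
                density[halo & in_arc & (density > 0) & ~rectum] = spec.rectum_density
            # gas pocket inside the rectum
            if in_rectum_z and rng.random() < spec.gas_prob:
                ang = rng.uniform(0, 2 * np.pi)
                gx = cz + 0.35 * r_k * np.cos(ang)
                gy = spec.rectum_center_y + 0.35 * r_k * np.sin(ang)
                gas = (Xq - gx) ** 2 + (Yq - gy) ** 2 <= (0.45 * r_k) ** 2
                density[gas & rectum] = 0.0
            # the most inferior MV slices lose all rectum/muscle contrast
            if in_rectum_z and k < spec.blur_inferior_slices:
                ring = (Xq - cz) ** 2 + (Yq - spec.rectum_center_y) ** 2 <= (
                    r_k + 14.0
                ) ** 2
                density[ring & (density > 0)] = spec.rectum_density
            hu = np.full(density.shape, -1000.0)
            inside = density > 0
            hu[inside] = density_to_hu(density[inside], cal_mv)
            vox[k] = hu
            masks[k] = rectum
        if spec.mv_noise_hu > 0:
            vox += rng.normal(0.0, spec.mv_noise_hu, vox.shape)
        vox[:, ~circle] = -1000.0
        masks[:, ~circle] = False
        mv = ImageVolume(
            voxels=np.rint(np.maximum(vox, -1000)).astype(np.int32),
            origin=(-half_mv, -half_mv, float(zs_mv[0])),
            pixel_spacing=(spec.mv_pixel_spacing, spec.mv_pixel_spacing),
            slice_positions=zs_mv,
            modality="MV",
            acquisition_date=spec.acquisition_date,
            machine_id=spec.machine_id,
        )
        fractions.append(FractionData(mv=mv, registration=reg, gt_masks=masks))

    return PelvisSeries(
        planning_kv=planning_kv,
        planning_contours=ContourSet(contours, name="RECTUM"),
        planning_gt_masks=kv_masks,
        rectum_si_extent=spec.rectum_z_extent,
        fractions=fractions,
        spec=spec,
    )


# ---------------------------------------------------------------------------
# plans
# ---------------------------------------------------------------------------


def make_prostate_plan(
    target_center: tuple[float, float, float] = (0.0, 0.0, 0.0),
    target_radius: float = 25.0,
    n_rotations: int = 2,
    pitch: float = 20.0,
    couch_start: float | None = None,
    **plan_kwargs,
) -> HelicalPlan:
    """A helical plan whose leaves open where they cover a spherical target.

    Open-times are the geometric coverage of the target by each leaf from
    each projection's central axis, with linearly smoothed edges both
    laterally (over one leaf width) and longitudinally (over one field
    width).
    """
    defaults = dict(
        projections_per_rotation=51,
        n_leaves=64,
        leaf_width_at_iso=6.25,
        fan_extent=400.0,
        field_width=25.0,
        source_axis_distance=850.0,
        output_factor=2.0,
        pitch=pitch,
        n_rotations=n_rotations,
    )
    defaults.update(plan_kwargs)
    ppr = defaults["projections_per_rotation"]
    n_proj = ppr * n_rotations
    travel = pitch * n_rotations
    if couch_start is None:
        couch_start = target_center[2] - travel / 2.0  # centre on the target
    sad = defaults["source_axis_distance"]
    lw = defaults["leaf_width_at_iso"]
    fw = defaults["field_width"]
    n_leaves = defaults["n_leaves"]
    leaf_u = (np.arange(n_leaves) - (n_leaves - 1) / 2.0) * lw

    cx, cy, czt = target_center
    arc = 360.0 / ppr
    leaf_open = np.zeros((n_proj, n_leaves))
    for p in range(n_proj):
        angle = (p + 0.5) * arc
        th = np.deg2rad(angle)
        sx, sy = sad * np.sin(th), -sad * np.cos(th)
        ax, ay = -np.sin(th), np.cos(th)
        tx, ty = np.cos(th), np.sin(th)
        along = (cx - sx) * ax + (cy - sy) * ay
        if along <= 0:
            continue
        u_t = ((cx - sx) * tx + (cy - sy) * ty) * sad / along
        r_proj = target_radius * sad / along
        lateral = np.clip((r_proj + lw / 2.0 - np.abs(leaf_u - u_t)) / lw, 0.0, 1.0)
        zc = couch_start + (p + 0.5) * pitch / ppr
        zfac = float(
            np.clip((target_radius + fw / 2.0 - abs(zc - czt)) / fw, 0.0, 1.0)
        )
        leaf_open[p] = lateral * zfac
    return HelicalPlan(leaf_open=leaf_open, couch_start=couch_start, **defaults)


# ---------------------------------------------------------------------------
# on-disk dataset for the batch pipeline
# ---------------------------------------------------------------------------


def make_dataset(
    root,
    n_patients: int = 3,
    n_fractions: int = 4,
    spec: PelvisSpec | None = None,
    seed: int = 0,
    flagged: dict[str, tuple[int, ...]] | None = None,
    plan: HelicalPlan | None = None,
    downsample: int = 4,
    n_theta: int = 21,
    geud_a: float = 8.0,
) -> Path:
    """Write a complete hierarchical dataset the batch pipeline can run.

    Layout: ``root/<patient>/planning/{ct/, struct.dcm, plan.json}`` and
    ``root/<patient>/fractions/NNN/mv/``; calibration CSV and a pipeline
    config at the root.
    """
    root = Path(root)
    root.mkdir(parents=True, exist_ok=True)
    flagged = flagged or {}
    base = spec or PelvisSpec().small()
    write_calibration_table(builtin_mv_calibration_table(), root / "calibration.csv")
    if plan is None:
        plan = make_prostate_plan(
            target_center=(0.0, 0.0, 0.0), target_radius=25.0, n_rotations=2,
            pitch=20.0,
        )
    for i in range(n_patients):
        pid = f"pat{i:03d}"
        pspec = replace(
            base,
            seed=seed + 1000 * i,
            n_fractions=n_fractions,
            flagged_fractions=tuple(flagged.get(pid, ())),
        )
        series = make_pelvis_series(pspec)
        pdir = root / pid
        write_ct_series(series.planning_kv, pdir / "planning" / "ct")
        write_contours(series.planning_contours, pdir / "planning" / "struct.dcm")
        save_plan(plan, pdir / "planning" / "plan.json")
        for f, frac in enumerate(series.fractions):
            write_ct_series(
                frac.mv, pdir / "fractions" / f"{f:03d}" / "mv", frac.registration
            )
    config = {
        "downsample": downsample,
        "n_theta": n_theta,
        "geud_a": geud_a,
        "n_patients": n_patients,
        "n_fractions": n_fractions,
    }
    import json

    (root / "config.json").write_text(json.dumps(config, indent=1))
    return root
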