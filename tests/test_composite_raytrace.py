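"""Scan-circle masking, kV alignment, and the dual (MV + masked kV) ray trace."""

import numpy as np
import pytest
from scipy.interpolate import RegularGridInterpolator

from voxcalc.composite_raytrace import (
    ScanCircle,
    align_kv,
    density_volume,
    dual_wepl,
    make_dose_grid,
    mask_scan_circle,
    trace_wepl,
    wepl_batch,
)
from voxcalc.imaging_io import HU_FLOOR, ImageVolume, Registration, UnusableFractionError


def _uniform_volume(hu, n=50, spacing=2.0, nz=8, z_spacing=4.0):
    half = (n - 1) / 2 * spacing
    return ImageVolume(
        voxels=np.full((nz, n, n), hu, dtype=np.int32),
        origin=(-half, -half, -(nz - 1) / 2 * z_spacing),
        pixel_spacing=(spacing, spacing),
        slice_positions=np.arange(nz) * z_spacing - (nz - 1) / 2 * z_spacing,
    )


def _quadrature_wepl(p0, p1, volume, line, step=0.01):
    """Independent fine-step midpoint integration of density along the ray."""
    dens = density_volume(volume, line)
    p0, p1 = np.asarray(p0, float), np.asarray(p1, float)
    L = np.linalg.norm(p1 - p0)
    n = max(int(L / step), 1)
    t = (np.arange(n) + 0.5) / n
    pts = p0[None] + t[:, None] * (p1 - p0)[None]
    sy, sx = volume.pixel_spacing
    sz = volume.slice_positions[1] - volume.slice_positions[0]
    ix = np.floor((pts[:, 0] - (volume.origin[0] - sx / 2)) / sx).astype(int)
    iy = np.floor((pts[:, 1] - (volume.origin[1] - sy / 2)) / sy).astype(int)
    iz = np.floor((pts[:, 2] - (volume.slice_positions[0] - sz / 2)) / sz).astype(int)
    nzv, nyv, nxv = volume.shape
    ok = (ix >= 0) & (ix < nxv) & (iy >= 0) & (iy < nyv) & (iz >= 0) & (iz < nzv)
    vals = np.zeros(n)
    vals[ok] = dens[iz[ok], iy[ok], ix[ok]]
    return vals.sum() * L / n


class TestMaskScanCircle:
    def test_center_voxel_masked(self, kv_line):
        vol = _uniform_volume(0)
        out = mask_scan_circle(vol, ScanCircle(diameter=60.0))
        iy = ix = vol.shape[1] // 2
        assert out.voxels[0, iy, ix] == HU_FLOOR

    def test_zero_diameter_leaves_image_unchanged(self):
        vol = _uniform_volume(100)
        out = mask_scan_circle(vol, ScanCircle(diameter=0.0))
        assert np.array_equal(out.voxels, vol.voxels)

    def test_masked_count_matches_per_voxel_oracle(self):
        # full-size scan circle on a kV-like 1.37-mm grid
        vol = _uniform_volume(100, n=300, spacing=1.37, nz=1, z_spacing=6.0)
        out = mask_scan_circle(vol, ScanCircle(diameter=386.0))
        masked = int((out.voxels[0] == HU_FLOOR).sum())
        xs, ys = vol.x_coords(), vol.y_coords()
        count = 0
        for y in ys:
            for x in xs:
                if x * x + y * y < 193.0**2:
                    count += 1
        assert masked == count

    def test_idempotent(self):
        vol = _uniform_volume(100, n=40)
        circle = ScanCircle(diameter=50.0)
        once = mask_scan_circle(vol, circle)
        twice = mask_scan_circle(once, circle)
        assert np.array_equal(once.voxels, twice.voxels)

    def test_boundary_voxel_unmasked(self):
        # voxel centre exactly on the circle is "not strictly inside"
        vol = _uniform_volume(100, n=21, spacing=1.0)
        out = mask_scan_circle(vol, ScanCircle(diameter=20.0))
        # (10, 0) lies exactly on a radius-10 circle
        iy = 10
        ix = 20
        assert abs(vol.x_coords()[ix] - 10.0) < 1e-9
        assert out.voxels[0, iy, ix] == 100


class TestAlignKv:
    def _asym(self):
        img = np.full((2, 25, 25), -1000, dtype=np.int32)
        img[:, 4:9, 14:20] = 500
        img[:, 15:19, 3:8] = -200
        return ImageVolume(img, origin=(-24, -24, 0), pixel_spacing=(2, 2),
                           slice_positions=[0.0, 6.0])

    def test_identity_for_zero_registration(self):
        vol = self._asym()
        out = align_kv(vol, Registration(0, 0, 0, 0, True))
        assert np.abs(out.voxels - vol.voxels).max() <= 0.5

    def test_rotation_matches_dense_bilinear_oracle(self):
        vol = self._asym()
        reg = Registration(3.0, -2.0, 0.0, 9.0, True)
        out = align_kv(vol, reg)
        from voxcalc.composite_raytrace import registration_transform

        _, inverse = registration_transform(reg)
        xs, ys = vol.x_coords(), vol.y_coords()
        X, Y = np.meshgrid(xs, ys)
        q = inverse(np.column_stack([X.ravel(), Y.ravel()]))
        interp = RegularGridInterpolator(
            (ys, xs), vol.voxels[0].astype(float),
            bounds_error=False, fill_value=float(HU_FLOOR),
        )
        brute = interp(np.column_stack([q[:, 1], q[:, 0]])).reshape(X.shape)
        brute = np.maximum(np.rint(brute), HU_FLOOR)
        assert np.abs(out.voxels[0] - brute).max() <= 1

    def test_pure_dz_shifts_slice_positions_only(self):
        vol = self._asym()
        out = align_kv(vol, Registration(0, 0, 12.0, 0, True))
        assert np.abs(out.voxels - vol.voxels).max() <= 0.5
        assert np.allclose(out.slice_positions, vol.slice_positions + 12.0)

    def test_unusable_registration_rejected(self):
        with pytest.raises(UnusableFractionError):
            align_kv(self._asym(), Registration(0, 0, 0, 0, usable=False))


class TestTraceWepl:
    def test_uniform_water_segment(self, kv_line):
        vol = _uniform_volume(0, n=101, spacing=2.0)  # water on the kV line
        res = trace_wepl((-50.0, 1.0, 0.5), (50.0, 1.0, 0.5), vol, kv_line)
        assert res.geometric_length == pytest.approx(100.0)
        assert res.wepl == pytest.approx(100.0, abs=1e-6)

    def test_all_air_volume(self, kv_line):
        vol = _uniform_volume(-1000)
        assert trace_wepl((-40, 0, 0), (60, 0, 0), vol, kv_line).wepl == 0.0

    def test_zero_length_ray(self, kv_line):
        vol = _uniform_volume(0)
        assert trace_wepl((1, 2, 3), (1, 2, 3), vol, kv_line).wepl == 0.0

    def test_random_rays_match_quadrature_oracle(self, kv_line, rng):
        hu = rng.integers(-1000, 1500, (8, 20, 24)).astype(np.int32)
        vol = ImageVolume(hu, origin=(-23, -19, -14), pixel_spacing=(2.0, 2.0),
                          slice_positions=np.arange(8) * 4.0 - 14)
        for _ in range(50):
            p0 = rng.uniform(-60, 60, 3)
            p1 = rng.uniform(-60, 60, 3)
            w = trace_wepl(p0, p1, vol, kv_line).wepl
            q = _quadrature_wepl(p0, p1, vol, kv_line)
            assert w == pytest.approx(q, abs=0.1)

    def test_direction_reversal_invariance(self, kv_line, rng):
        hu = rng.integers(-1000, 1200, (6, 16, 16)).astype(np.int32)
        vol = ImageVolume(hu, origin=(-15, -15, -10), pixel_spacing=(2, 2),
                          slice_positions=np.arange(6) * 4.0 - 10)
        for _ in range(20):
            p0, p1 = rng.uniform(-40, 40, 3), rng.uniform(-40, 40, 3)
            assert trace_wepl(p0, p1, vol, kv_line).wepl == pytest.approx(
                trace_wepl(p1, p0, vol, kv_line).wepl, abs=1e-8
            )

    def test_additive_over_subdivision(self, kv_line, rng):
        hu = rng.integers(-1000, 1200, (6, 16, 16)).astype(np.int32)
        vol = ImageVolume(hu, origin=(-15, -15, -10), pixel_spacing=(2, 2),
                          slice_positions=np.arange(6) * 4.0 - 10)
        for _ in range(20):
            p0, p1 = rng.uniform(-40, 40, 3), rng.uniform(-40, 40, 3)
            t = rng.uniform(0.2, 0.8)
            mid = p0 + t * (p1 - p0)
            whole = trace_wepl(p0, p1, vol, kv_line).wepl
            parts = (
                trace_wepl(p0, mid, vol, kv_line).wepl
                + trace_wepl(mid, p1, vol, kv_line).wepl
            )
            assert whole == pytest.approx(parts, abs=1e-6)

    def test_monotone_in_voxel_density(self, kv_line):
        vol = _uniform_volume(0, n=21, spacing=2.0, nz=3, z_spacing=4.0)
        p0, p1 = (-30, 0.3, 0.0), (30, -0.2, 0.0)
        base = trace_wepl(p0, p1, vol, kv_line).wepl
        bumped = vol.copy()
        bumped.voxels[1, 10, 10] += 500
        assert trace_wepl(p0, p1, bumped, kv_line).wepl > base


class TestDualWepl:
    def _phantoms(self, mv_line, kv_line, rng, circle_diameter=150.0):
        """Nested-grid phantoms: the kV grid refines the MV grid 2x, so a
        single merged-density volume is an exact composite oracle."""
        n_mv, s_mv = 48, 5.0
        n_kv, s_kv = 96, 2.5
        half_mv = (n_mv - 1) / 2 * s_mv
        base = rng.integers(-200, 600, (6, n_mv, n_mv)).astype(np.int32)
        xs = np.linspace(-half_mv, half_mv, n_mv)
        X, Y = np.meshgrid(xs, xs)
        body = (X / 110.0) ** 2 + (Y / 70.0) ** 2 <= 1.0  # wider than the circle
        base[:, ~body] = -1000
        zs = np.arange(6) * 6.0 - 15.0
        inside = X**2 + Y**2 < (circle_diameter / 2) ** 2
        mv_vox = np.where(inside[None], base, -1000)
        mv = ImageVolume(mv_vox.astype(np.int32), origin=(-half_mv, -half_mv, zs[0]),
                         pixel_spacing=(s_mv, s_mv), slice_positions=zs, modality="MV")
        kv_vox = np.repeat(np.repeat(base, 2, axis=1), 2, axis=2)
        kv = ImageVolume(kv_vox.astype(np.int32),
                         origin=(-half_mv - s_kv / 2, -half_mv - s_kv / 2, zs[0]),
                         pixel_spacing=(s_kv, s_kv), slice_positions=zs, modality="kV")
        masked = mask_scan_circle(kv, ScanCircle(diameter=circle_diameter))
        # merged oracle: MV density where the parent MV voxel centre is in
        # the circle, kV density where the kV voxel centre is outside
        dens_mv_fine = np.repeat(
            np.repeat(density_volume(mv, mv_line), 2, axis=1), 2, axis=2
        )
        dens_kv = density_volume(masked, kv_line)
        merged_dens = dens_mv_fine + dens_kv
        merged_hu = 1000.0 * (merged_dens - 1.0)  # exact under the kV line
        merged = ImageVolume(merged_hu, origin=kv.origin,
                             pixel_spacing=kv.pixel_spacing, slice_positions=zs)
        return mv, masked, merged

    def test_dual_equals_merged_image_trace(self, mv_line, kv_line, rng):
        mv, masked, merged = self._phantoms(mv_line, kv_line, rng)
        for _ in range(60):
            p0 = rng.uniform(-140, 140, 3) * [1, 1, 0.2]
            p1 = rng.uniform(-140, 140, 3) * [1, 1, 0.2]
            dual = dual_wepl(p0, p1, mv, masked, mv_line, kv_line)
            single = trace_wepl(p0, p1, merged, kv_line).wepl
            assert dual == pytest.approx(single, abs=0.2)

    def test_body_inside_circle_reduces_to_mv_only(self, mv_line, kv_line, rng):
        mv, masked, _ = self._phantoms(mv_line, kv_line, rng, circle_diameter=400.0)
        p0, p1 = (-120.0, 5.0, 0.0), (120.0, -5.0, 0.0)
        dual = dual_wepl(p0, p1, mv, masked, mv_line, kv_line)
        assert dual == pytest.approx(trace_wepl(p0, p1, mv, mv_line).wepl, abs=1e-6)

    def test_ray_missing_both_volumes_is_zero(self, mv_line, kv_line, rng):
        mv, masked, _ = self._phantoms(mv_line, kv_line, rng)
        assert dual_wepl((500, 500, 0), (600, 500, 0), mv, masked,
                         mv_line, kv_line) == 0.0


class TestMakeDoseGrid:
    def _mv(self, n=256, spacing=0.76):
        half = (n - 1) / 2 * spacing
        return ImageVolume(np.zeros((3, n, n), dtype=np.int32),
                           origin=(-half, -half, 0.0), pixel_spacing=(spacing, spacing),
                           slice_positions=[0.0, 6.0, 12.0], modality="MV")

    def test_factor_two_spacing(self):
        grid = make_dose_grid(self._mv(), 2)
        assert grid.spacing == (pytest.approx(1.52), pytest.approx(1.52))

    def test_factor_one_congruent_with_voxel_centers(self):
        mv = self._mv(n=32)
        grid = make_dose_grid(mv, 1)
        assert np.allclose(grid.xs, mv.x_coords())
        assert np.allclose(grid.ys, mv.y_coords())
        assert np.allclose(grid.zs, mv.slice_positions)

    def test_factor_four_point_count(self):
        grid = make_dose_grid(self._mv(n=256), 4)
        assert (len(grid.ys), len(grid.xs)) == (64, 64)

    def test_si_spacing_follows_mv_slices(self):
        grid = make_dose_grid(self._mv(), 2)
        assert np.allclose(np.diff(grid.zs), 6.0)

    @pytest.mark.parametrize("bad", [3, 5, 6, 0, -2])
    def test_non_power_of_two_rejected(self, bad):
        with pytest.raises(ValueError, match="power of 2"):
            make_dose_grid(self._mv(n=32), bad)
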