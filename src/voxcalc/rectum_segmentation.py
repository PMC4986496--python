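"""Automatic rectum delineation on daily MV CT slices.

Each MV slice overlapping the planning rectum is segmented with a
two-phase Chan–Vese level set seeded from the planning contour (mapped
into the delivery frame by the fraction's shifts and roll).  Three
corrections follow, addressing the known failure modes of the raw level
set on noisy MV images:

1. *air remapping* — gas pockets in the rectum are far darker than
   rectal material and would split the region, so connected areas below
   an air threshold are reassigned the rectal-material HU before the
   intensity window is applied;
2. *inferior replacement* — at the inferior end the rectum/muscle
   contrast is too poor even for an expert, and the level set
   over-contours; the most superior slice with an unexpectedly large
   contour is found and all slices from the inferior end up to it are
   replaced by the planning contours;
3. *smoothed-surface outlier replacement* — occasional single-slice
   failures are detected by comparing every contour with a smoothed 3-D
   surface built from all contours of the scan (radial resampling from
   the slice centroids, per-ray smoothing across slices); slices
   deviating too far are replaced by the smoothed contour.

Contour/mask conversion conventions: a mask contains the pixels whose
centres are inside the polygon; polygons are recovered from masks by
marching squares at the 0.5 level.  The conformity index used throughout
is the Jaccard overlap |A∩B|/|A∪B| (not Dice).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage
from scipy.signal import savgol_filter
from shapely.geometry import LineString, Point, Polygon
from skimage import measure
from skimage.draw import polygon2mask
from skimage.segmentation import chan_vese as _sk_chan_vese

from .composite_raytrace import registration_transform
from .imaging_io import (
    ContourSet,
    ImageVolume,
    Registration,
    SliceContour,
    UnusableFractionError,
)

__all__ = [
    "SegmentationParams",
    "SegmentationResult",
    "preprocess_slice",
    "chan_vese_slice",
    "fix_inferior",
    "surface_smooth_replace",
    "conformity_index",
    "segment_scan",
    "mask_to_polygon",
    "polygon_to_mask",
]


@dataclass(frozen=True)
class SegmentationParams:
    """Tunable parameters of the autocontouring pipeline.

    Defaults were tuned on the synthetic pelvis phantom; on real data
    they would be retuned against manually drawn training contours.
    """

    window: tuple[float, float] = (-250.0, 250.0)  # HU rescale window
    air_threshold: float = -300.0  # HU below which a region counts as gas
    rectal_hu: float = 20.0  # HU that remapped gas is assigned
    lambda1: float = 1.0  # Chan-Vese inside-region weight
    lambda2: float = 1.0  # Chan-Vese outside-region weight
    mu: float = 0.1  # Chan-Vese boundary-length weight
    max_iter: int = 500
    tol: float = 1e-4  # level-set variation stopping tolerance
    cv_dt: float = 2.0  # level-set time step
    inferior_area_ratio: float = 1.5  # "unexpectedly large" vs planning area
    surface_dev_mm: float = 2.0  # mean radial deviation triggering replacement
    smooth_span: int = 5  # slices in the moving polynomial fit
    n_rays: int = 64  # radial resampling rays for the smoothed surface
    crop_margin_mm: float = 25.0  # segmentation window around the seed contour

    def __post_init__(self) -> None:
        if self.window[0] >= self.window[1]:
            raise ValueError("window low must be < high")
        if self.max_iter < 1:
            raise ValueError("max_iter must be >= 1")
        if self.inferior_area_ratio <= 0 or self.surface_dev_mm <= 0:
            raise ValueError("thresholds must be positive")


# ---------------------------------------------------------------------------
# mask <-> polygon
# ---------------------------------------------------------------------------


def polygon_to_mask(
    vertices_mm: np.ndarray,
    shape: tuple[int, int],
    origin_xy: tuple[float, float],
    spacing_rc: tuple[float, float],
) -> np.ndarray:
    """Pixels whose centres are inside the polygon (vertices in mm)."""
    v = np.asarray(vertices_mm, dtype=float)
    rows = (v[:, 1] - origin_xy[1]) / spacing_rc[0]
    cols = (v[:, 0] - origin_xy[0]) / spacing_rc[1]
    return polygon2mask(shape, np.column_stack([rows, cols]))


def mask_to_polygon(
    mask: np.ndarray,
    origin_xy: tuple[float, float],
    spacing_rc: tuple[float, float],
) -> np.ndarray | None:
    """Longest marching-squares contour of a mask, in mm (x, y) vertices."""
    padded = np.pad(mask.astype(float), 1)
    contours = measure.find_contours(padded, 0.5)
    if not contours:
        return None
    rc = max(contours, key=len) - 1.0  # undo the pad
    x = origin_xy[0] + rc[:, 1] * spacing_rc[1]
    y = origin_xy[1] + rc[:, 0] * spacing_rc[0]
    xy = np.column_stack([x, y])
    if np.allclose(xy[0], xy[-1]):
        xy = xy[:-1]
    return xy


# ---------------------------------------------------------------------------
# pipeline steps
# ---------------------------------------------------------------------------


def preprocess_slice(mv_slice: np.ndarray, params: SegmentationParams) -> np.ndarray:
    """Air remapping followed by window rescale to [0, 1].

    Connected regions darker than the air threshold are reassigned the
    rectal-material HU, then intensities are clipped to the window and
    mapped linearly (and monotonically) to [0, 1].
    """
    img = np.asarray(mv_slice, dtype=float).copy()
    img[img < params.air_threshold] = params.rectal_hu
    lo, hi = params.window
    img = np.clip(img, lo, hi)
    return (img - lo) / (hi - lo)


def chan_vese_slice(
    image: np.ndarray, init_mask: np.ndarray, params: SegmentationParams
) -> np.ndarray:
    """Two-phase piecewise-constant Chan–Vese segmentation of one slice.

    The level set is initialised from the signed distance of
    ``init_mask``.  Returns the converged foreground mask (guaranteed
    non-empty) or the init mask when the descent yields nothing.
    """
    init_mask = np.asarray(init_mask, dtype=bool)
    if not init_mask.any():
        raise ValueError("initial mask is empty")
    image = np.asarray(image, dtype=float)
    if np.ptp(image) < 1e-12:
        # a constant image gives the energy no gradient to descend
        return init_mask.copy()
    phi = ndimage.distance_transform_edt(init_mask) - ndimage.distance_transform_edt(
        ~init_mask
    )
    seg = _sk_chan_vese(
        np.asarray(image, dtype=float),
        mu=params.mu,
        lambda1=params.lambda1,
        lambda2=params.lambda2,
        tol=params.tol,
        max_num_iter=params.max_iter,
        dt=params.cv_dt,
        init_level_set=phi,
    )
    seg = np.asarray(seg, dtype=bool)
    if not seg.any():
        return init_mask.copy()
    # the level set may converge with phases swapped on inverted contrast
    if (seg & init_mask).sum() < (~seg & init_mask).sum():
        seg = ~seg
    return seg


def _select_component(mask: np.ndarray, init_mask: np.ndarray) -> np.ndarray:
    """Keep the connected component overlapping the seed the most."""
    labels, n = ndimage.label(mask)
    if n <= 1:
        return mask
    overlaps = ndimage.sum_labels(init_mask.astype(int), labels, index=np.arange(1, n + 1))
    if overlaps.max() == 0:
        sizes = ndimage.sum_labels(np.ones_like(mask, dtype=int), labels,
                                   index=np.arange(1, n + 1))
        best = int(np.argmax(sizes)) + 1
    else:
        best = int(np.argmax(overlaps)) + 1
    return labels == best


def fix_inferior(
    contour_areas: np.ndarray,
    contours: list,
    planning_contours: list,
    params: SegmentationParams,
    planning_areas: np.ndarray | None = None,
) -> tuple[list, np.ndarray]:
    """Replace over-contoured inferior slices with the planning contours.

    Slices are ordered inferior -> superior.  A slice is "unexpectedly
    large" when its area exceeds ``inferior_area_ratio`` times the
    matching planning area; every slice from the inferior end up to the
    most superior flagged slice is replaced.  Returns the corrected list
    and the boolean replacement flags.
    """
    areas = np.asarray(contour_areas, dtype=float)
    if planning_areas is None:
        planning_areas = np.array(
            [np.count_nonzero(p) if isinstance(p, np.ndarray) else p
             for p in planning_contours],
            dtype=float,
        )
    if len(areas) != len(contours) or len(areas) != len(planning_areas):
        raise ValueError("areas, contours and planning contours must align per slice")
    flagged = areas > params.inferior_area_ratio * planning_areas
    replaced = np.zeros(len(contours), dtype=bool)
    if flagged.any():
        top = int(np.max(np.flatnonzero(flagged)))
        replaced[: top + 1] = True
    out = [
        (planning_contours[i] if replaced[i] else contours[i])
        for i in range(len(contours))
    ]
    return out, replaced


def _radial_profile(
    polygon_xy: np.ndarray, center: np.ndarray, angles: np.ndarray
) -> np.ndarray:
    """Distance from ``center`` to the contour's outer boundary per ray."""
    poly = Polygon(polygon_xy)
    boundary = poly.exterior
    reach = 2.0 * max(poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1]) + 1.0
    radii = np.empty(len(angles))
    for i, th in enumerate(angles):
        ray = LineString(
            [center, (center[0] + reach * np.cos(th), center[1] + reach * np.sin(th))]
        )
        inter = ray.intersection(boundary)
        if inter.is_empty:
            radii[i] = 0.0
            continue
        pts = (
            [inter]
            if isinstance(inter, Point)
            else [g for g in getattr(inter, "geoms", [inter]) if isinstance(g, Point)]
        )
        if not pts:
            # grazing/linear intersection; fall back to boundary distance
            radii[i] = float(Point(center).distance(boundary))
            continue
        radii[i] = max(float(Point(center).distance(p)) for p in pts)
    return radii


def _smooth_along_slices(values: np.ndarray, span: int) -> np.ndarray:
    """Robust smoothing along the slice axis: moving median then a moving
    quadratic (Savitzky-Golay) fit.

    The median prefilter makes the smoothed surface insensitive to a
    single bad slice, so an outlier's deviation is measured against its
    neighbours rather than against a surface it has dragged toward
    itself, and its replacement lands on the neighbours' radius.
    """
    n = values.shape[0]
    if n < 3:
        return values.copy()
    window = min(span, n)
    if window % 2 == 0:
        window -= 1
    if window < 3:
        window = 3
    med = ndimage.median_filter(
        values, size=(window,) + (1,) * (values.ndim - 1), mode="nearest"
    )
    order = min(2, window - 1)
    return savgol_filter(med, window_length=window, polyorder=order, axis=0,
                         mode="interp")


def surface_smooth_replace(
    contours: list[np.ndarray],
    params: SegmentationParams,
) -> tuple[list[np.ndarray], np.ndarray]:
    """Replace single-slice outliers with the smoothed 3-D surface.

    Every contour (an (n, 2) mm polygon; slices ordered in SI) is
    resampled to ``n_rays`` fixed angular rays from its centroid; the
    centroid track and the per-ray radii are smoothed across slices with
    a moving quadratic fit over ``smooth_span`` slices.  A slice whose
    mean radial deviation from the smoothed surface exceeds
    ``surface_dev_mm`` is replaced by the smoothed contour.  Returns the
    corrected contours and replacement flags.
    """
    n = len(contours)
    if n < 3:
        raise ValueError("surface smoothing needs >= 3 slices")
    angles = np.arange(params.n_rays) * (2 * np.pi / params.n_rays)
    centroids = np.array(
        [np.asarray(Polygon(c).centroid.coords[0]) for c in contours]
    )
    smooth_centroids = _smooth_along_slices(centroids, params.smooth_span)
    radii = np.array(
        [
            _radial_profile(contours[i], smooth_centroids[i], angles)
            for i in range(n)
        ]
    )
    smooth_radii = _smooth_along_slices(radii, params.smooth_span)
    deviation = np.abs(radii - smooth_radii).mean(axis=1)
    replaced = deviation > params.surface_dev_mm
    out = []
    for i in range(n):
        if replaced[i]:
            r = np.maximum(smooth_radii[i], 0.5)
            xy = np.column_stack(
                [
                    smooth_centroids[i, 0] + r * np.cos(angles),
                    smooth_centroids[i, 1] + r * np.sin(angles),
                ]
            )
            out.append(xy)
        else:
            out.append(np.asarray(contours[i], dtype=float))
    return out, replaced


def conformity_index(mask_a: np.ndarray, mask_b: np.ndarray) -> float:
    """Jaccard overlap |A∩B| / |A∪B| of two same-grid masks."""
    a = np.asarray(mask_a, dtype=bool)
    b = np.asarray(mask_b, dtype=bool)
    if a.shape != b.shape:
        raise ValueError("masks must share a grid")
    union = np.count_nonzero(a | b)
    if union == 0:
        raise ValueError("both masks are empty")
    return float(np.count_nonzero(a & b) / union)


# ---------------------------------------------------------------------------
# full-scan pipeline
# ---------------------------------------------------------------------------


@dataclass
class SegmentationResult:
    """Per-scan segmentation output with diagnostics."""

    contours: ContourSet
    masks: list[np.ndarray]  # final per-slice masks on the MV grid
    masks_pre_smooth: list[np.ndarray]  # after Chan-Vese + inferior fix
    slice_zs: np.ndarray
    inferior_replaced: np.ndarray
    smooth_replaced: np.ndarray


def _transform_planning_contours(
    planning: ContourSet,
    registration: Registration | None,
    isocentre: tuple[float, float],
) -> ContourSet:
    if registration is None:
        return planning
    forward, _ = registration_transform(registration, isocentre)
    moved = [
        SliceContour(z=c.z + registration.dz, vertices=forward(c.vertices))
        for c in planning.contours
    ]
    return ContourSet(moved, planning.frame_of_reference, planning.name)


def segment_scan(
    mv_volume: ImageVolume,
    planning_contours: ContourSet,
    params: SegmentationParams = SegmentationParams(),
    registration: Registration | None = None,
    isocentre: tuple[float, float] = (0.0, 0.0),
) -> SegmentationResult:
    """Segment the rectum on every MV slice overlapping the planning contour.

    Pipeline per slice: map the planning contour into the delivery frame,
    rasterise it as the level-set seed, preprocess (air remap + window),
    run Chan–Vese on a window cropped around the seed, keep the component
    covering the seed; then apply the inferior replacement and the
    smoothed-surface outlier replacement across slices and convert the
    final masks back to polygons.
    """
    if registration is not None and not registration.usable:
        raise UnusableFractionError("fraction flagged unusable; skipping segmentation")
    seeds = _transform_planning_contours(planning_contours, registration, isocentre)
    seed_zs = seeds.slice_zs()
    sy, sx = mv_volume.pixel_spacing
    origin_xy = (mv_volume.origin[0], mv_volume.origin[1])
    ny, nx = mv_volume.shape[1:]
    seed_spacing = float(np.median(np.diff(seed_zs))) if len(seed_zs) > 1 else 0.0
    z_tol = max(abs(mv_volume.slice_spacing), seed_spacing) / 2.0 + 1e-6

    slice_idx: list[int] = []
    seed_masks: list[np.ndarray] = []
    for k, z in enumerate(mv_volume.slice_positions):
        j = int(np.argmin(np.abs(seed_zs - z)))
        if abs(seed_zs[j] - z) > z_tol:
            continue
        mask = polygon_to_mask(
            seeds.contours[j].vertices, (ny, nx), origin_xy, (sy, sx)
        )
        if mask.any():
            slice_idx.append(k)
            seed_masks.append(mask)
    if not slice_idx:
        raise ValueError("planning rectum does not overlap the MV scan's SI extent")

    margin_px = int(np.ceil(params.crop_margin_mm / min(sy, sx)))
    masks: list[np.ndarray] = []
    for k, seed in zip(slice_idx, seed_masks):
        rows, cols = np.nonzero(seed)
        r0 = max(rows.min() - margin_px, 0)
        r1 = min(rows.max() + margin_px + 1, ny)
        c0 = max(cols.min() - margin_px, 0)
        c1 = min(cols.max() + margin_px + 1, nx)
        crop = preprocess_slice(mv_volume.voxels[k, r0:r1, c0:c1], params)
        seg = chan_vese_slice(crop, seed[r0:r1, c0:c1], params)
        seg = _select_component(seg, seed[r0:r1, c0:c1])
        seg = ndimage.binary_fill_holes(seg)
        full = np.zeros((ny, nx), dtype=bool)
        full[r0:r1, c0:c1] = seg
        masks.append(full)

    pixel_area = sy * sx
    areas = np.array([m.sum() * pixel_area for m in masks])
    seed_areas = np.array([m.sum() * pixel_area for m in seed_masks])
    masks, inf_replaced = fix_inferior(
        areas, masks, seed_masks, params, planning_areas=seed_areas
    )
    masks_pre_smooth = [m.copy() for m in masks]

    polys = []
    poly_ok = []
    for m in masks:
        p = mask_to_polygon(m, origin_xy, (sy, sx))
        polys.append(p)
        poly_ok.append(p is not None and len(p) >= 3)
    smooth_replaced = np.zeros(len(masks), dtype=bool)
    if sum(poly_ok) >= 3 and all(poly_ok):
        smoothed, smooth_replaced = surface_smooth_replace(polys, params)
        for i, rep in enumerate(smooth_replaced):
            if rep:
                masks[i] = polygon_to_mask(smoothed[i], (ny, nx), origin_xy, (sy, sx))
                polys[i] = smoothed[i]

    zs = mv_volume.slice_positions[np.array(slice_idx)]
    contours = []
    for p, z in zip(polys, zs):
        if p is not None and len(p) >= 3:
            try:
                contours.append(SliceContour(z=float(z), vertices=p))
            except ValueError:
                continue
    return SegmentationResult(
        contours=ContourSet(contours, name=planning_contours.name),
        masks=masks,
        masks_pre_smooth=masks_pre_smooth,
        slice_zs=zs,
        inferior_replaced=inf_replaced,
        smooth_replaced=smooth_replaced,
    )
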