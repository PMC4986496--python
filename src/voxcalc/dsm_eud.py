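"""Rectal dose-surface maps (DSMs) and generalized EUD.

The rectum is treated as a cylinder: each slice contour is "cut" at the
point where a vertical line from its centroid crosses the posterior
edge, unfolded, and the dose sampled at ``n_theta`` points equally
spaced by arc length around the boundary.  Resampling every slice to a
fixed number of points normalizes away day-to-day circumference changes,
and cutting posterior of the centroid (rather than at the most posterior
boundary point, which jitters from slice to slice) keeps the central DSM
column on the middle of the anterior rectal wall — the surface that is
stable relative to the prostate.

Per-fraction maps are summed on a fixed 6-mm SI lattice, with each
fraction's rows placed at its image slice positions corrected by the dz
couch shift.  Because the MV scan is shorter than the rectum, lattice
rows a fraction does not cover are filled from the planning DSM divided
by the planned number of fractions.

gEUD follows the Niemierko power-mean form ``(mean(d^a))^(1/a)``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.interpolate import RegularGridInterpolator
from scipy.special import logsumexp
from shapely.geometry import LineString, Point, Polygon

from .imaging_io import ContourSet, DoseCube, SliceContour

__all__ = [
    "DoseSurfaceMap",
    "cut_point",
    "unfold_slice",
    "build_fraction_dsm",
    "accumulate_dsms",
    "geud",
    "relative_eud",
    "write_dsm",
    "read_dsm",
    "plot_dsm",
]

DSM_ROW_SPACING = 6.0  # mm, the MV slice interval that sets the SI lattice


@dataclass
class DoseSurfaceMap:
    """Unfolded rectal-surface dose: rows = SI positions, columns = the
    ``n_theta`` equally spaced boundary points, values in Gy."""

    values: np.ndarray  # (n_rows, n_theta)
    row_si: np.ndarray  # mm, strictly increasing
    circumference: np.ndarray  # mm per row
    provenance: str = "fraction"  # fraction | planning | accumulated

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        self.row_si = np.asarray(self.row_si, dtype=float)
        self.circumference = np.asarray(self.circumference, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("DSM values must be 2-D [row][column]")
        if len(self.row_si) != self.values.shape[0]:
            raise ValueError("one SI position per row required")
        if len(self.row_si) > 1 and not np.all(np.diff(self.row_si) > 0):
            raise ValueError("row_si must be strictly increasing")
        if np.any(self.values < 0):
            raise ValueError("DSM doses must be non-negative")
        if self.provenance not in ("fraction", "planning", "accumulated"):
            raise ValueError(f"unknown provenance {self.provenance!r}")

    @property
    def n_theta(self) -> int:
        return self.values.shape[1]


# ---------------------------------------------------------------------------
# cut and unfold
# ---------------------------------------------------------------------------


def cut_point(
    contour: np.ndarray, posterior: tuple[float, float] = (0.0, -1.0)
) -> np.ndarray:
    """Where the posterior vertical ray from the centroid crosses the boundary.

    ``posterior`` is the in-plane direction of "posterior"; the default
    (0, -1) suits contours expressed with posterior downward, while the
    patient-frame pipeline passes (0, +1) for LPS coordinates.  With
    several crossings the one nearest the centroid is used.
    """
    v = np.asarray(contour, dtype=float)
    poly = Polygon(v)
    if poly.area <= 0:
        raise ValueError("degenerate contour")
    c = np.asarray(poly.centroid.coords[0])
    d = np.asarray(posterior, dtype=float)
    d = d / np.linalg.norm(d)
    reach = 4.0 * max(
        poly.bounds[2] - poly.bounds[0], poly.bounds[3] - poly.bounds[1]
    ) + 1.0
    ray = LineString([c, c + reach * d])
    inter = ray.intersection(poly.exterior)
    pts: list[Point] = []
    if inter.is_empty:
        pts = []
    elif isinstance(inter, Point):
        pts = [inter]
    else:
        for g in getattr(inter, "geoms", [inter]):
            if isinstance(g, Point):
                pts.append(g)
            elif isinstance(g, LineString):
                pts.extend(Point(xy) for xy in g.coords)
    # keep genuinely posterior crossings (exclude the centroid itself)
    pts = [p for p in pts if (np.asarray(p.coords[0]) - c) @ d > 1e-9]
    if not pts:
        raise ValueError(
            "no posterior boundary crossing from the centroid (centroid may "
            "lie outside the polygon)"
        )
    best = min(pts, key=lambda p: Point(c).distance(p))
    return np.asarray(best.coords[0])


def _boundary_samples(
    contour: np.ndarray, n_theta: int, posterior: tuple[float, float]
) -> tuple[np.ndarray, float]:
    """``n_theta`` boundary points equally spaced by arc length starting at
    the cut point and proceeding patient-left (+x) first."""
    v = np.asarray(contour, dtype=float)
    poly = Polygon(v)
    ring = poly.exterior
    length = float(ring.length)
    if length <= 0:
        raise ValueError("zero-perimeter contour")
    cp = cut_point(v, posterior)
    s0 = float(ring.project(Point(cp)))
    step = length / n_theta
    # direction probe: a short way along the ring from the cut point
    probe = np.asarray(ring.interpolate((s0 + 0.02 * length) % length).coords[0])
    direction = 1.0 if probe[0] >= cp[0] else -1.0
    ss = (s0 + direction * step * np.arange(n_theta)) % length
    pts = np.array([ring.interpolate(float(s)).coords[0] for s in ss])
    return pts, length


def unfold_slice(
    contour: np.ndarray,
    dose_plane: np.ndarray,
    xs: np.ndarray,
    ys: np.ndarray,
    n_theta: int = 21,
    posterior: tuple[float, float] = (0.0, -1.0),
) -> tuple[np.ndarray, float]:
    """One DSM row: dose bilinearly interpolated at ``n_theta`` equally
    spaced boundary points, plus the slice circumference (mm).

    ``dose_plane`` is a (ny, nx) dose array on the grid ``ys`` x ``xs``,
    which must cover the contour's bounding box.
    """
    pts, length = _boundary_samples(contour, n_theta, posterior)
    if (
        pts[:, 0].min() < xs[0]
        or pts[:, 0].max() > xs[-1]
        or pts[:, 1].min() < ys[0]
        or pts[:, 1].max() > ys[-1]
    ):
        raise ValueError("dose plane does not cover the contour bounding box")
    interp = RegularGridInterpolator((ys, xs), dose_plane, method="linear")
    row = interp(np.column_stack([pts[:, 1], pts[:, 0]]))
    return np.asarray(row, dtype=float), length


def build_fraction_dsm(
    contour_set: ContourSet,
    dose_cube: DoseCube,
    n_theta: int = 21,
    dz: float = 0.0,
    posterior: tuple[float, float] = (0.0, 1.0),
    provenance: str = "fraction",
) -> DoseSurfaceMap:
    """DSM of one fraction: one row per contoured slice.

    Each contour is matched to the nearest dose plane; ``dz`` (the
    fraction's SI couch shift) corrects the stored row positions so that
    maps from different fractions align anatomically.  The default
    ``posterior`` direction is +y (patient-frame LPS).
    """
    if len(contour_set) == 0:
        raise ValueError("empty contour set")
    xs = dose_cube.x_coords()
    ys = dose_cube.y_coords()
    half = (
        abs(dose_cube.slice_positions[1] - dose_cube.slice_positions[0]) / 2.0
        if len(dose_cube.slice_positions) > 1
        else np.inf
    )
    rows = []
    zs = []
    circs = []
    for c in contour_set.contours:
        j = int(np.argmin(np.abs(dose_cube.slice_positions - c.z)))
        if abs(dose_cube.slice_positions[j] - c.z) > half + 1e-6:
            raise ValueError(f"no dose plane covers contour slice z = {c.z:.1f} mm")
        try:
            row, circ = unfold_slice(
                c.vertices, dose_cube.dose[j], xs, ys, n_theta, posterior
            )
        except ValueError as exc:
            raise ValueError(f"slice z = {c.z:.1f} mm: {exc}") from exc
        rows.append(row)
        zs.append(c.z + dz)
        circs.append(circ)
    order = np.argsort(zs)
    return DoseSurfaceMap(
        values=np.asarray(rows)[order],
        row_si=np.asarray(zs)[order],
        circumference=np.asarray(circs)[order],
        provenance=provenance,
    )


# ---------------------------------------------------------------------------
# accumulation
# ---------------------------------------------------------------------------


def accumulate_dsms(
    fraction_dsms: list[DoseSurfaceMap],
    planning_dsm: DoseSurfaceMap,
    rectum_si_extent: tuple[float, float],
    n_planned_fractions: int | None = None,
    row_spacing: float = DSM_ROW_SPACING,
) -> DoseSurfaceMap:
    """Sum per-fraction DSMs on a fixed SI lattice across the rectum.

    The lattice spans ``rectum_si_extent`` at ``row_spacing`` (6 mm).
    Where a fraction covers a lattice row (its nearest row lies within
    half a lattice step), its values are used; elsewhere the planning
    DSM's nearest row divided by ``n_planned_fractions`` substitutes, so
    the top and bottom of the rectum are padded with planning data.
    """
    if not fraction_dsms:
        raise ValueError("no fraction DSMs to accumulate")
    n_theta = planning_dsm.n_theta
    for d in fraction_dsms:
        if d.n_theta != n_theta:
            raise ValueError(
                f"n_theta mismatch: fraction has {d.n_theta}, planning {n_theta}"
            )
    if n_planned_fractions is None:
        n_planned_fractions = len(fraction_dsms)
    lo, hi = rectum_si_extent
    lattice = lo + row_spacing * np.arange(int(np.floor((hi - lo) / row_spacing)) + 1)
    total = np.zeros((len(lattice), n_theta))
    circ = np.zeros(len(lattice))
    half = row_spacing / 2.0
    for d in fraction_dsms:
        for i, z in enumerate(lattice):
            j = int(np.argmin(np.abs(d.row_si - z)))
            if abs(d.row_si[j] - z) <= half + 1e-9:
                total[i] += d.values[j]
                circ[i] += d.circumference[j]
            else:
                jp = int(np.argmin(np.abs(planning_dsm.row_si - z)))
                total[i] += planning_dsm.values[jp] / n_planned_fractions
                circ[i] += planning_dsm.circumference[jp]
    return DoseSurfaceMap(
        values=total,
        row_si=lattice,
        circumference=circ / len(fraction_dsms),
        provenance="accumulated",
    )


# ---------------------------------------------------------------------------
# gEUD
# ---------------------------------------------------------------------------


def geud(dsm_or_values, a: float) -> float:
    """Generalized equivalent uniform dose ``(mean(d^a))^(1/a)`` in Gy.

    ``a`` must be non-zero.  For negative ``a`` any zero dose drives the
    power mean to its limit 0, which is what is returned.  Computation is
    done in log space so large ``a`` (max-dose limit) stays stable.
    """
    if a == 0:
        raise ValueError("gEUD exponent a must be non-zero")
    if isinstance(dsm_or_values, DoseSurfaceMap):
        values = dsm_or_values.values
    else:
        values = np.asarray(dsm_or_values, dtype=float)
    v = values.ravel()
    if v.size == 0:
        raise ValueError("empty dose sample")
    if np.any(v < 0):
        raise ValueError("doses must be non-negative")
    if a < 0 and np.any(v == 0):
        return 0.0
    if np.all(v == 0):
        return 0.0
    with np.errstate(divide="ignore"):
        logs = np.log(v)
    if a > 0:
        # zeros contribute exp(-inf) = 0 to the mean of d^a
        lse = logsumexp(a * logs)
    else:
        lse = logsumexp(a * logs)
    return float(np.exp((lse - np.log(v.size)) / a))


def relative_eud(
    delivered_dsm: DoseSurfaceMap, planned_dsm: DoseSurfaceMap, a: float
) -> float:
    """Delivered gEUD relative to planned gEUD."""
    planned = geud(planned_dsm, a)
    if planned <= 0:
        raise ValueError("planned EUD is zero; ratio undefined")
    return geud(delivered_dsm, a) / planned


# ---------------------------------------------------------------------------
# serialization and plotting
# ---------------------------------------------------------------------------


def write_dsm(dsm: DoseSurfaceMap, path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    payload = {
        "values": dsm.values.tolist(),
        "row_si": dsm.row_si.tolist(),
        "circumference": dsm.circumference.tolist(),
        "provenance": dsm.provenance,
    }
    path.write_text(json.dumps(payload))
    return path


def read_dsm(path) -> DoseSurfaceMap:
    d = json.loads(Path(path).read_text())
    return DoseSurfaceMap(
        values=np.asarray(d["values"]),
        row_si=np.asarray(d["row_si"]),
        circumference=np.asarray(d["circumference"]),
        provenance=d.get("provenance", "fraction"),
    )


def dsm_to_csv(dsm: DoseSurfaceMap, path) -> Path:
    """CSV export: first column SI position, remaining columns dose (Gy)."""
    import pandas as pd

    path = Path(path)
    df = pd.DataFrame(
        dsm.values, columns=[f"theta_{k}" for k in range(dsm.n_theta)]
    )
    df.insert(0, "si_mm", dsm.row_si)
    df["circumference_mm"] = dsm.circumference
    df.to_csv(path, index=False)
    return path


def plot_dsm(dsm: DoseSurfaceMap, ax=None, cmap: str = "viridis"):
    """Quick-look pcolormesh of a DSM (columns = unfolded angle)."""
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots()
    theta = np.linspace(0, 1, dsm.n_theta)
    m = ax.pcolormesh(theta, dsm.row_si, dsm.values, cmap=cmap, shading="nearest")
    ax.set_xlabel("normalized circumference (cut at posterior midline)")
    ax.set_ylabel("SI position (mm)")
    plt.colorbar(m, ax=ax, label="dose (Gy)")
    return ax
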