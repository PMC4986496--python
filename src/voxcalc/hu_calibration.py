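"""HU <-> relative electron density calibration for kV and MV CT.

MV CT Hounsfield calibration drifts over time (target changes, weekly
recalibration procedures), so the conversion used for dose reconstruction
must be selected by machine and image date.  The calibration model is a
water-anchored line::

    HU = offset + slope * (rho_e - 1)

so ``offset`` is the HU of water (rho_e = 1) and ``slope`` the HU change
per unit relative electron density.  A standard diagnostic kV scanner has
offset 0 and slope 1000 on this scale.

Calibration lines are fitted from cheese-phantom density-insert
measurements (mean HU in a circular ROI per insert) and monitored with a
water-HU QA check (pass while the deviation is below 30 HU, the TG-148
criterion).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .imaging_io import ImageVolume

__all__ = [
    "CalibrationLine",
    "InsertMeasurement",
    "RoiSpec",
    "INSERT_DENSITIES",
    "KV_STANDARD_LINE",
    "hu_to_density",
    "density_to_hu",
    "select_calibration",
    "fit_calibration",
    "qa_check",
    "measure_inserts",
    "load_calibration_table",
    "write_calibration_table",
    "builtin_mv_calibration_table",
]

#: Relative electron densities of the Gammex insert set used for MV HU
#: calibration, plus air (0.0) and distilled water (1.0).
INSERT_DENSITIES: tuple[float, ...] = (
    0.30,
    0.49,
    0.942,
    0.979,
    1.018,
    1.053,
    1.080,
    1.104,
    1.112,
    1.274,
    1.472,
    1.694,
)


@dataclass(frozen=True)
class CalibrationLine:
    """One HU-vs-electron-density line valid from a given date on a machine."""

    offset: float  # HU at unit relative electron density
    slope: float  # HU per unit relative electron density
    valid_from: _dt.date
    machine_id: str
    offset_sd: float | None = None  # stored for users, not propagated to dose
    slope_sd: float | None = None

    def __post_init__(self) -> None:
        if self.slope <= 0:
            raise ValueError(f"slope must be positive, got {self.slope}")
        if abs(self.offset) > 100:
            raise ValueError(
                f"offset {self.offset} HU outside the +/-100 HU sanity range"
            )


@dataclass(frozen=True)
class RoiSpec:
    """Circular in-plane ROI: centre (x, y) mm, radius mm, slice index."""

    center: tuple[float, float]
    radius: float
    slice_index: int = 0
    density: float | None = None  # nominal insert density, if known


@dataclass(frozen=True)
class InsertMeasurement:
    """Mean HU measured over one density insert's ROI."""

    density: float
    mean_hu: float
    roi: RoiSpec | None = None

    def __post_init__(self) -> None:
        if self.density < 0:
            raise ValueError("relative electron density must be >= 0")


#: The standard diagnostic kV relation (offset 0, slope 1000).
KV_STANDARD_LINE = CalibrationLine(
    offset=0.0, slope=1000.0, valid_from=_dt.date(2000, 1, 1), machine_id="kV"
)


def builtin_mv_calibration_table() -> list[CalibrationLine]:
    """The toolkit's bundled MV calibration history for machines "A"
    (installed 2007) and "B" (installed 2009)."""
    rows = [
        ("A", _dt.date(2007, 10, 31), 25.0, 1000.0, 15.0, 55.0),
        ("A", _dt.date(2011, 7, 29), 12.0, 992.0, 15.0, 41.0),
        ("A", _dt.date(2012, 7, 1), 8.0, 970.0, 4.0, 12.0),
        ("B", _dt.date(2010, 1, 14), 35.0, 982.0, 9.0, 27.0),
        ("B", _dt.date(2011, 4, 1), 15.0, 962.0, 14.0, 33.0),
        ("B", _dt.date(2012, 7, 1), 10.0, 940.0, 5.0, 10.0),
    ]
    return [
        CalibrationLine(offset=o, slope=s, valid_from=d, machine_id=m,
                        offset_sd=osd, slope_sd=ssd)
        for m, d, o, s, osd, ssd in rows
    ]


# ---------------------------------------------------------------------------
# conversion
# ---------------------------------------------------------------------------


def hu_to_density(hu, line: CalibrationLine):
    """Relative electron density from HU; clamped so density >= 0."""
    rho = 1.0 + (np.asarray(hu, dtype=float) - line.offset) / line.slope
    rho = np.maximum(rho, 0.0)
    if np.isscalar(hu) or np.ndim(hu) == 0:
        return float(rho)
    return rho


def density_to_hu(density, line: CalibrationLine):
    """Forward model: HU = offset + slope * (rho_e - 1)."""
    hu = line.offset + line.slope * (np.asarray(density, dtype=float) - 1.0)
    if np.isscalar(density) or np.ndim(density) == 0:
        return float(hu)
    return hu


def select_calibration(
    date: _dt.date, machine_id: str, table: Sequence[CalibrationLine]
) -> CalibrationLine:
    """The line valid on ``date`` for ``machine_id``.

    A line is valid from its ``valid_from`` date (inclusive) until the
    next line's date; selection is piecewise constant and
    right-continuous in date.
    """
    rows = sorted(
        (r for r in table if r.machine_id == machine_id),
        key=lambda r: r.valid_from,
    )
    applicable = [r for r in rows if r.valid_from <= date]
    if not applicable:
        raise LookupError(
            f"no calibration for machine {machine_id!r} on or before {date}"
        )
    return applicable[-1]


# ---------------------------------------------------------------------------
# fitting and QA
# ---------------------------------------------------------------------------


def fit_calibration(
    measurements: Iterable[InsertMeasurement],
    machine_id: str = "A",
    valid_from: _dt.date | None = None,
) -> tuple[CalibrationLine, float]:
    """Ordinary least squares of measured HU on (rho_e - 1).

    HU is the response (the measurement noise lives in HU).  Returns the
    fitted line and the residual standard deviation (0 for a 2-point fit).
    """
    ms = list(measurements)
    if len(ms) < 2:
        raise ValueError("need at least 2 insert measurements to fit a line")
    x = np.array([m.density - 1.0 for m in ms])
    y = np.array([m.mean_hu for m in ms])
    if np.ptp(x) == 0:
        raise ValueError("all insert densities are equal; line is undetermined")
    slope, offset = np.polyfit(x, y, 1)
    resid = y - (offset + slope * x)
    dof = max(len(ms) - 2, 1)
    resid_sd = float(np.sqrt(np.sum(resid**2) / dof))
    line = CalibrationLine(
        offset=float(offset),
        slope=float(slope),
        valid_from=valid_from or _dt.date.today(),
        machine_id=machine_id,
    )
    return line, resid_sd


def qa_check(
    water_hu: float, line: CalibrationLine, tolerance: float = 30.0
) -> tuple[bool, float]:
    """Water-HU stability check: fail iff |water_hu - offset| >= tolerance.

    The 30 HU default is the monthly QA criterion keeping dosimetric
    uncertainty at or below 2%.  Returns (passed, deviation).
    """
    deviation = float(water_hu - line.offset)
    return abs(deviation) < tolerance, deviation


def measure_inserts(
    phantom_image: ImageVolume, roi_specs: Sequence[RoiSpec]
) -> list[InsertMeasurement]:
    """Mean HU over the voxels whose centres fall inside each circular ROI."""
    out = []
    xs = phantom_image.x_coords()
    ys = phantom_image.y_coords()
    for roi in roi_specs:
        if not (0 <= roi.slice_index < phantom_image.n_slices):
            raise ValueError(f"ROI slice index {roi.slice_index} outside image")
        cx, cy = roi.center
        if (
            cx - roi.radius < xs[0]
            or cx + roi.radius > xs[-1]
            or cy - roi.radius < ys[0]
            or cy + roi.radius > ys[-1]
        ):
            raise ValueError(f"ROI at ({cx}, {cy}) r={roi.radius} extends outside image")
        dx = xs[None, :] - cx
        dy = ys[:, None] - cy
        inside = dx * dx + dy * dy <= roi.radius**2
        if not inside.any():
            raise ValueError(f"ROI at ({cx}, {cy}) r={roi.radius} contains no voxel centres")
        mean_hu = float(phantom_image.voxels[roi.slice_index][inside].mean())
        out.append(
            InsertMeasurement(
                density=roi.density if roi.density is not None else 1.0,
                mean_hu=mean_hu,
                roi=roi,
            )
        )
    return out


# ---------------------------------------------------------------------------
# calibration table CSV
# ---------------------------------------------------------------------------


def load_calibration_table(path) -> list[CalibrationLine]:
    """Read a calibration CSV: machine_id, valid_from (ISO), offset, slope
    and optional offset_sd/slope_sd columns."""
    df = pd.read_csv(path)
    required = {"machine_id", "valid_from", "offset", "slope"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"calibration CSV missing columns: {sorted(missing)}")
    lines = []
    for _, row in df.iterrows():
        lines.append(
            CalibrationLine(
                offset=float(row["offset"]),
                slope=float(row["slope"]),
                valid_from=_dt.date.fromisoformat(str(row["valid_from"])),
                machine_id=str(row["machine_id"]),
                offset_sd=float(row["offset_sd"]) if "offset_sd" in df.columns else None,
                slope_sd=float(row["slope_sd"]) if "slope_sd" in df.columns else None,
            )
        )
    return lines


def write_calibration_table(lines: Sequence[CalibrationLine], path) -> Path:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    df = pd.DataFrame(
        {
            "machine_id": [l.machine_id for l in lines],
            "valid_from": [l.valid_from.isoformat() for l in lines],
            "offset": [l.offset for l in lines],
            "slope": [l.slope for l in lines],
            "offset_sd": [l.offset_sd for l in lines],
            "slope_sd": [l.slope_sd for l in lines],
        }
    )
    df.to_csv(path, index=False)
    return path
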