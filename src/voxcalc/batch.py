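"""Non-interactive batch orchestration of the per-fraction pipeline.

Work is split into independent jobs — one per (patient, fraction, stage)
— which can be executed sequentially or on a local worker pool, with
per-job failure isolation and atomic output writes (temp file + rename).
Fractions whose MV image is flagged unusable are planned as *skipped*
and never executed.  Merging accumulates each patient's per-fraction
dose-surface maps (with planning padding) and writes a per-patient gEUD
summary table.

Dataset layout::

    root/config.json                 pipeline parameters
    root/calibration.csv             HU calibration history
    root/<patient>/planning/ct/      planning kV CT series
    root/<patient>/planning/struct.dcm
    root/<patient>/planning/plan.json
    root/<patient>/fractions/NNN/mv/ per-fraction MV CT series
    root/<patient>/fractions/NNN/out/  per-fraction outputs
"""

from __future__ import annotations

import json
import os
import time
import traceback
from concurrent.futures import ProcessPoolExecutor
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .composite_raytrace import ScanCircle, align_kv, mask_scan_circle
from .dose_engine import compute_fraction_dose, load_plan
from .dsm_eud import (
    accumulate_dsms,
    build_fraction_dsm,
    geud,
    read_dsm,
    relative_eud,
    write_dsm,
)
from .hu_calibration import (
    KV_STANDARD_LINE,
    load_calibration_table,
    select_calibration,
)
from .imaging_io import (
    read_contours,
    read_ct_series,
    read_dose,
    read_registration,
    write_contours,
    write_dose,
)
from .rectum_segmentation import SegmentationParams, segment_scan

__all__ = ["JobSpec", "RunReport", "plan_jobs", "run_jobs", "merge_outputs",
           "merge_all", "STAGES"]

STAGES = ("dose", "segment", "dsm")

_STAGE_OUTPUT = {"dose": "dose.dcm", "segment": "struct.dcm", "dsm": "dsm.json"}


@dataclass
class JobSpec:
    """One unit of work: a stage applied to one patient's fraction."""

    patient: str
    fraction: int
    stage: str
    root: str
    output: str
    status: str = "pending"  # pending | done | failed | skipped
    error: str = ""
    seconds: float = 0.0

    def __post_init__(self) -> None:
        if self.stage not in STAGES:
            raise ValueError(f"unknown stage {self.stage!r}")


@dataclass
class RunReport:
    jobs: list[JobSpec]

    @property
    def counts(self) -> dict[str, int]:
        c: dict[str, int] = {}
        for j in self.jobs:
            c[j.status] = c.get(j.status, 0) + 1
        return c


def _patients(root: Path) -> list[str]:
    return sorted(
        p.name for p in root.iterdir() if p.is_dir() and (p / "planning").is_dir()
    )


def _fraction_dirs(root: Path, patient: str) -> list[Path]:
    fdir = root / patient / "fractions"
    if not fdir.is_dir():
        return []
    return sorted(p for p in fdir.iterdir() if p.is_dir())


def plan_jobs(dataset_root, stages=STAGES) -> list[JobSpec]:
    """One job per usable fraction per stage; flagged fractions -> skipped,
    fractions with existing outputs -> done (idempotent re-planning)."""
    root = Path(dataset_root)
    jobs: list[JobSpec] = []
    if not root.is_dir():
        return jobs
    for patient in _patients(root):
        for fdir in _fraction_dirs(root, patient):
            fraction = int(fdir.name)
            try:
                reg = read_registration(fdir / "mv")
                usable = reg.usable
            except (FileNotFoundError, KeyError):
                usable = False
            for stage in stages:
                out = fdir / "out" / _STAGE_OUTPUT[stage]
                job = JobSpec(
                    patient=patient,
                    fraction=fraction,
                    stage=stage,
                    root=str(root),
                    output=str(out),
                )
                if not usable:
                    job.status = "skipped"
                elif out.exists():
                    job.status = "done"
                jobs.append(job)
    return jobs


# ---------------------------------------------------------------------------
# stage implementations
# ---------------------------------------------------------------------------


def _load_config(root: Path) -> dict:
    cfg_path = root / "config.json"
    if cfg_path.exists():
        return json.loads(cfg_path.read_text())
    return {"downsample": 4, "n_theta": 21, "geud_a": 8.0}


def _fraction_paths(root: Path, job: JobSpec) -> Path:
    return root / job.patient / "fractions" / f"{job.fraction:03d}"


def _run_dose(job: JobSpec) -> None:
    root = Path(job.root)
    cfg = _load_config(root)
    fdir = _fraction_paths(root, job)
    mv = read_ct_series(fdir / "mv")
    reg = read_registration(fdir / "mv")
    kv = read_ct_series(root / job.patient / "planning" / "ct")
    plan = load_plan(root / job.patient / "planning" / "plan.json")
    table = load_calibration_table(root / "calibration.csv")
    cal_mv = select_calibration(mv.acquisition_date, mv.machine_id, table)
    aligned = align_kv(kv, reg)
    masked = mask_scan_circle(aligned, ScanCircle())
    cube = compute_fraction_dose(
        plan, mv, masked, reg, cal_mv, KV_STANDARD_LINE,
        downsample=int(cfg.get("downsample", 4)),
    )
    tmp = Path(job.output).with_suffix(".tmp")
    tmp.parent.mkdir(parents=True, exist_ok=True)
    write_dose(cube, tmp)
    os.replace(tmp, job.output)


def _run_segment(job: JobSpec) -> None:
    root = Path(job.root)
    fdir = _fraction_paths(root, job)
    mv = read_ct_series(fdir / "mv")
    reg = read_registration(fdir / "mv")
    planning = read_contours(root / job.patient / "planning" / "struct.dcm")
    result = segment_scan(mv, planning, SegmentationParams(), registration=reg)
    tmp = Path(job.output).with_suffix(".tmp")
    tmp.parent.mkdir(parents=True, exist_ok=True)
    write_contours(result.contours, tmp)
    os.replace(tmp, job.output)


def _run_dsm(job: JobSpec) -> None:
    root = Path(job.root)
    cfg = _load_config(root)
    fdir = _fraction_paths(root, job)
    out_dir = fdir / "out"
    dose = read_dose(out_dir / "dose.dcm")
    contours = read_contours(out_dir / "struct.dcm")
    reg = read_registration(fdir / "mv")
    dsm = build_fraction_dsm(
        contours, dose, n_theta=int(cfg.get("n_theta", 21)), dz=reg.dz
    )
    tmp = Path(job.output).with_suffix(".tmp")
    tmp.parent.mkdir(parents=True, exist_ok=True)
    write_dsm(dsm, tmp)
    os.replace(tmp, job.output)


_RUNNERS = {"dose": _run_dose, "segment": _run_segment, "dsm": _run_dsm}

# dsm consumes dose + segment outputs, so stages execute in this order
_STAGE_ORDER = {"dose": 0, "segment": 1, "dsm": 2}


def _execute(job: JobSpec) -> JobSpec:
    t0 = time.perf_counter()
    try:
        _RUNNERS[job.stage](job)
        job.status = "done"
    except Exception:
        job.status = "failed"
        job.error = traceback.format_exc(limit=3)
    job.seconds = time.perf_counter() - t0
    return job


def run_jobs(jobs: list[JobSpec], n_workers: int = 1) -> RunReport:
    """Execute pending jobs; failures are isolated per job.

    Jobs share no mutable state and write their outputs atomically, so
    the result is independent of worker count and execution order
    (stages are ordered so dsm jobs see their fraction's dose/segment
    outputs).
    """
    pending = sorted(
        (j for j in jobs if j.status == "pending"),
        key=lambda j: (_STAGE_ORDER[j.stage], j.patient, j.fraction),
    )
    done_jobs: list[JobSpec] = [j for j in jobs if j.status != "pending"]
    if n_workers <= 1:
        for j in pending:
            done_jobs.append(_execute(j))
    else:
        # dsm depends on dose+segment of the same fraction: run in stage waves
        for stage in STAGES:
            wave = [j for j in pending if j.stage == stage]
            if not wave:
                continue
            with ProcessPoolExecutor(max_workers=n_workers) as ex:
                done_jobs.extend(ex.map(_execute, wave))
    return RunReport(jobs=done_jobs)


# ---------------------------------------------------------------------------
# merging
# ---------------------------------------------------------------------------


def _planning_dsm(root: Path, patient: str, cfg: dict):
    """Planning dose cube + DSM (per-fraction dose) on the planning scan."""
    from .imaging_io import Registration

    kv = read_ct_series(root / patient / "planning" / "ct")
    plan = load_plan(root / patient / "planning" / "plan.json")
    contours = read_contours(root / patient / "planning" / "struct.dcm")
    cube = compute_fraction_dose(
        plan, kv, None, Registration(0, 0, 0, 0, True), KV_STANDARD_LINE,
        downsample=int(cfg.get("downsample", 4)),
    )
    dsm = build_fraction_dsm(
        contours, cube, n_theta=int(cfg.get("n_theta", 21)), dz=0.0,
        provenance="planning",
    )
    return dsm, contours


def merge_outputs(dataset_root, patient: str, stage: str = "dsm") -> dict:
    """Accumulate a patient's fraction DSMs and compute delivered vs
    planned gEUD.  Refuses (naming the fraction) if a usable fraction's
    output is missing."""
    root = Path(dataset_root)
    cfg = _load_config(root)
    a = float(cfg.get("geud_a", 8.0))
    fraction_dsms = []
    n_planned = 0
    for fdir in _fraction_dirs(root, patient):
        try:
            reg = read_registration(fdir / "mv")
        except (FileNotFoundError, KeyError):
            continue
        n_planned += 1
        if not reg.usable:
            continue
        out = fdir / "out" / _STAGE_OUTPUT[stage]
        if not out.exists():
            raise FileNotFoundError(
                f"fraction {fdir.name} of {patient} has no {stage} output; "
                "run its jobs before merging"
            )
        fraction_dsms.append(read_dsm(out))
    if not fraction_dsms:
        raise ValueError(f"no usable fraction outputs for {patient}")
    planning_dsm, contours = _planning_dsm(root, patient, cfg)
    extent = contours.z_extent()
    accumulated = accumulate_dsms(
        fraction_dsms, planning_dsm, extent, n_planned_fractions=n_planned
    )
    write_dsm(accumulated, root / patient / "accumulated_dsm.json")
    planned_course = replace(
        planning_dsm, values=planning_dsm.values * n_planned, provenance="planning"
    )
    eud_delivered = geud(accumulated, a)
    eud_planned = geud(planned_course, a)
    return {
        "patient": patient,
        "n_fractions_planned": n_planned,
        "n_fractions_used": len(fraction_dsms),
        "geud_a": a,
        "eud_delivered_gy": eud_delivered,
        "eud_planned_gy": eud_planned,
        "relative_eud": eud_delivered / eud_planned,
    }


def merge_all(dataset_root) -> pd.DataFrame:
    """Merge every patient and write the per-patient EUD summary CSV."""
    root = Path(dataset_root)
    rows = [merge_outputs(root, p) for p in _patients(root)]
    df = pd.DataFrame(rows)
    df.to_csv(root / "eud_summary.csv", index=False)
    return df
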