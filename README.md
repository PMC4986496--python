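# voxcalc

Reconstruction of the radiotherapy dose actually delivered, fraction by
fraction, on helical tomotherapy — for researchers linking *delivered*
(rather than planned) dose to outcomes, and for physicists who need
batch, non-interactive recalculation that does not tie up a clinical
planning terminal.

A patient's anatomy changes from day to day, so the dose delivered in
each of the 20–37 daily fractions differs from the planned one.  Each
fraction comes with a megavoltage (MV) CT taken for image guidance — a
coarse scan (6-mm slices) limited to a 38.6-cm circle — plus the couch
shifts and roll applied after matching.  `voxcalc` turns those inputs
into per-fraction dose, daily rectum contours, and course-accumulated
dose-surface maps:

* **HU calibration** (`hu_calibration`) — date- and machine-dependent
  conversion HU = offset + slope·(ρe − 1) to relative electron density,
  with insert-phantom fitting and TG-148-style water-HU QA.
* **Composite ray tracing** (`composite_raytrace`) — anatomy outside the
  MV scan circle comes from the planning kV CT, aligned with the
  fraction's shifts/roll and masked to zero density inside the circle;
  the water-equivalent path length to any point is the sum of exact
  Siddon-style traces through the two images, ∫ρe dl, with no composite
  image ever built.
* **Dose engine** (`dose_engine`) — a helical plan sinogram expanded
  into 7 control points per projection, roll applied as a gantry-angle
  offset, and a documented simplified beamlet model (exponential
  attenuation in WEPL, inverse square, Gaussian leaf profile); includes
  a 3%/3 mm box-index dose comparator.
* **Rectum segmentation** (`rectum_segmentation`) — per-slice Chan–Vese
  level set seeded from the planning contour, with gas remapping,
  inferior-overcontour replacement and smoothed-surface outlier
  replacement; conformity scored as Jaccard |A∩B|/|A∪B|.
* **DSM + gEUD** (`dsm_eud`) — each contour cut at the posterior
  crossing of the vertical through its centroid, unfolded to a fixed
  number of arc-length-equal samples; fractions summed on a 6-mm SI
  lattice with planning padding; Niemierko gEUD (mean dᵃ)^(1/a).
* **Synthetic data** (`synthetic_data`) — cheese (density-insert)
  phantom with plug-removal configurations, and a seeded pelvis phantom
  series with ground-truth rectum masks emulating every pipeline input.
* **Batch orchestration** (`batch`, `cli`) — per-(patient, fraction,
  stage) jobs, skip-flag handling, atomic outputs, worker-count-
  independent results, per-patient EUD summaries.

Everything is DICOM-compatible on disk: CT series, RTSTRUCT contours,
16-bit RTDOSE cubes, with shifts/roll in a documented private tag block
of the MV headers.

## Worked example

Generate a small synthetic cohort and run the whole pipeline:

```sh
$ voxcalc simulate --root demo --patients 1 --fractions 2 --seed 7
dataset written to demo
$ voxcalc run --root demo
pat000 fraction 000 dose     done         2.2s
pat000 fraction 001 dose     done         2.1s
pat000 fraction 000 segment  done         1.1s
pat000 fraction 001 segment  done         1.1s
pat000 fraction 000 dsm      done         0.0s
pat000 fraction 001 dsm      done         0.0s
{"done": 6}
$ voxcalc merge --root demo
patient  n_fractions_planned  n_fractions_used  geud_a  eud_delivered_gy  eud_planned_gy  relative_eud
 pat000                    2                 2     8.0         61.741393       57.640615      1.071144
```

Per fraction this reconstructed the dose on the MV grid (written as
RTDOSE under `demo/pat000/fractions/NNN/out/`), auto-contoured the
rectum (RTSTRUCT), and unfolded the contoured dose into a DSM; `merge`
summed the DSMs on the 6-mm lattice (padding the rectum's ends from the
planning scan) and reports the generalized EUD of the accumulated map
against the planned one — here the delivered surface dose came out 7%
above plan for this two-fraction toy course, the kind of per-patient
deviation the accumulated-vs-planned comparison is designed to surface.
The gEUD exponent a = 8 is a rectum convention, passed explicitly.

The same steps are available as library calls (`make_dataset`,
`plan_jobs`, `run_jobs`, `merge_all`) and as single-shot commands
(`voxcalc dose|segment|dsm|eud ...`) for one fraction at a time.

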