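# Methods

`voxcalc` reconstructs the radiotherapy dose actually delivered in each
treatment fraction of a helical-tomotherapy course from the daily
megavoltage (MV) CT image and the recorded setup corrections, delineates
the rectum on those images, and accumulates rectal dose-surface maps
(DSMs) and generalized EUD across the course.  This note records the
models, the conventions, the parameters that matter, and the design
choices made where the design was genuinely open.

## Coordinate and setup conventions

Patient coordinates are DICOM LPS-like: x toward the patient's left, y
posterior, z superior, everything in mm.  Voxels are indexed
`[slice][row][col]`, values at voxel centres.  Per-fraction setup
corrections are a couch shift (dx, dy, dz) and a roll about the SI axis.
Positive roll rotates the patient's left side anteriorly (the +x axis
toward −y); the map from planning frame to delivery frame is
`T(q) = R(q − c) + c + s` with `c` the in-plane isocentre and `s` the
shift.  The orientation of roll is not externally constrained, so the
toolkit fixes this convention and uses it consistently in image
alignment, in the ground-truth transforms of the synthetic generator and
in the dose engine's gantry-angle offset; the roll-rotation equivalence
test pins all three to each other.

## HU calibration

MV CT Hounsfield calibration varies by machine and drifts over time, so
conversion to relative electron density ρe uses a date- and
machine-selected line

    HU = offset + slope · (ρe − 1),

a water-anchored form under which a standard diagnostic kV scanner is
(offset 0, slope 1000).  A bundled table carries the measured history of
two machines (2007–2015); selection takes the row with the latest
`valid_from` at or before the image date (piecewise constant,
right-continuous).  Fits from density-insert phantom measurements use
ordinary least squares with HU as the response, since the measurement
noise lives in HU.  ρe is clamped at 0, and −1000 HU is zero density by
convention.  The tabulated 1-σ uncertainties are stored but not
propagated into dose — dose-level uncertainty from calibration drift
(up to ~2% before 2011, <1% after) is reported to users as a caveat
instead.  The water-HU QA check fails at a deviation of 30 HU or more
(the TG-148 monthly criterion, boundary exclusive).

## Composite kV/MV ray tracing

The MV scan circle is 38.6 cm across and often cuts off the patient's
lateral edges, so radiological depth is computed from two images: the MV
image, and the planning kV image aligned to the delivery frame with
every voxel strictly inside the scan circle set to −1000 (zero density).
The water-equivalent path length (WEPL) to a point is the sum of one
exact voxel-boundary (Siddon-style) trace through each image; no
composite image is ever built, which avoids both the resampling cost and
an interpolation choice.  Voxel values are treated as piecewise
constant; segments outside a volume contribute nothing.  The traversal
kernel is compiled with numba and verified against fine-step (0.01 mm)
numerical integration, and the dual trace is verified against a single
trace through an exactly merged composite built on a nested test grid.

Alignment resamples the kV image in-plane only (bilinear, fill −1000),
rotating by the roll about the isocentre and translating by (dx, dy);
the dz shift moves the slice coordinates without resampling, and the kV
volume keeps its own (finer) z grid — the ray tracer handles differing
grids natively, so collapsing kV slices onto the 6-mm MV planes would
only lose information.  Circle membership is strict inequality on voxel
centres; boundary voxels stay unmasked; masking is idempotent.

Dose points lie on the MV geometry: in-plane spacing is the MV pixel
pitch times a power-of-2 downsampling factor (0.76 mm × 2 ≈ 1.5 mm is
the working default), one plane per 6-mm MV slice.

## Dose engine

A helical plan is a sinogram of leaf open-time fractions (51 projections
per rotation, 64 leaves of 6.25 mm at the isocentre, SAD 850 mm by
default).  Each projection expands into 7 control points that uniformly
subdivide both its gantry arc and its couch travel (midpoint rule,
weight 1/7 each) — the subdivision is applied to both axes because the
delivery is continuous in both.  A fraction's roll is applied by adding
it to every control-point gantry angle, which rotates the dose
distribution relative to the MV image exactly as delivery does.

The beamlet model is deliberately simple and documented as such: dose =
output_factor × open_fraction × exp(−μ_eff · WEPL) × (SAD/d)² × Gaussian
lateral leaf profile (FWHM = leaf width), with μ_eff = 0.05 cm⁻¹ and a
box longitudinal aperture (`field_width`, default 25 mm) that gates
which dose planes a control point irradiates.  It is linear in the
sinogram, exact in its geometric transformations, and sensitive to
density changes through the WEPL — the properties the surrounding
machinery needs — but it models no scatter kernels, leaf latency,
leakage or couch attenuation and is not a commissioned clinical engine.
On the cheese phantom the plug-removal study nevertheless lands close to
physical reality: removing the inner plug ring raises the chamber doses
by ~8–9% and removing all plugs by ~14%, the same direction and similar
magnitude as measured ionization-chamber data for that experiment.

Dose comparisons use a 3%/3 mm *box* index: a point passes if any
reference point within the 3-mm axis-aligned box holds dose within 3% of
the global reference maximum, with points shallower than 5 mm inside the
body (and points outside it) excluded.  The implementation is verified
against an exhaustive per-point search.

## Rectum segmentation

Each MV slice overlapping the planning rectum is segmented with the
classical two-phase piecewise-constant Chan–Vese level set
(scikit-image's implementation), seeded with the planning contour mapped
through the fraction's setup transform.  Preprocessing remaps connected
regions below −300 HU (rectal gas) to +20 HU (rectal material) and then
windows [−250, 250] HU to [0, 1]; segmentation runs on a window cropped
25 mm around the seed; the connected component covering the seed is
kept and holes are filled.

Two corrections follow:

* **Inferior replacement.**  Slices whose area exceeds 1.5× the matching
  planning area are flagged; all slices from the inferior end up to the
  most superior flagged slice are replaced by the planning contours.
  This targets the inferior rectum, where rectum/muscle contrast is too
  poor to segment (or even to contour manually with confidence).
* **Smoothed-surface outlier replacement.**  Contours are resampled to
  64 fixed angular rays from their (smoothed) centroids; per-ray radii
  are smoothed across slices with a moving median followed by a moving
  quadratic fit over 5 slices, and a slice whose mean radial deviation
  from this surface exceeds 2 mm is replaced by the smoothed contour.
  The median prefilter is essential: it keeps a single bad slice from
  dragging the reference surface toward itself, so the outlier is
  measured against its neighbours and its replacement lands on their
  radius.  The construction of the smoothed 3-D surface is an open
  design point; radial resampling plus robust across-slice smoothing is
  one reasonable realization and is flagged as an interpretation.

Level-set weights (λ1 = λ2 = 1, μ = 0.1), time step 2.0, 500 iterations
with a 10⁻⁴ level-set-variation tolerance, and both correction
thresholds were tuned on a training set of synthetic phantom scans with
known ground truth — the same procedure a clinical deployment would
follow against manually drawn contours, with the tuned values then
verified on independently seeded test scans.  On the phantom training
data, healthy slices deviate ≤ 1.4 mm from the smoothed surface while
genuine failures deviate ≥ 2.6 mm, so the 2-mm threshold separates the
populations with margin on both sides.

The conformity index is Jaccard, |A∩B|/|A∪B|.  This is stated
prominently because "conformity index" is sometimes read as Dice, which
would change every number (Dice = 2J/(1+J)).

Contour↔mask conversions: a mask holds the pixels whose centres are
inside the polygon; polygons come from masks by marching squares at the
0.5 level.

## Dose-surface maps and gEUD

The rectum is treated as a cylinder.  Each slice contour is cut where
the vertical ray from its centroid crosses the posterior boundary
(nearest crossing if several) and unfolded into a row of `n_theta`
points equally spaced by arc length, proceeding patient-left first, with
dose bilinearly interpolated at each point.  Cutting posterior of the
centroid — not at the most posterior boundary point, which jitters from
slice to slice — keeps the central DSM column on the anterior rectal
wall, the surface that is stable relative to the prostate.  Fixed
`n_theta` (default 21; the count is a convention, configurable)
normalizes away day-to-day circumference changes; rows store physical
dose at normalized angular coordinate.  In patient-frame (LPS)
coordinates posterior is +y; the low-level geometry helpers default to a
display-style frame with posterior at −y, and the pipeline passes the
LPS direction explicitly.

Fraction DSM rows sit at the image slice positions corrected by the
fraction's dz, and accumulation sums fractions on a fixed 6-mm SI
lattice spanning the rectum: where a fraction has a row within half a
lattice step it contributes that row; elsewhere the planning DSM's
nearest row divided by the planned number of fractions substitutes
(the MV scan is shorter than the rectum, so its top and bottom always
come from planning data).

gEUD is the Niemierko power mean `(mean dᵃ)^(1/a)`, computed in log
space so large exponents stay stable.  `a` is a required user choice;
the CLI default of 8 for rectum is a convention, not a measured value.
For a < 0 a zero dose sends the power mean to its limit 0, which is what
is returned.  Delivered EUD is reported relative to the planned EUD.

## Synthetic data

The generator is the package's test bed and defines its study
conditions; everything is a deterministic function of the spec's seed.

The **cheese phantom** is a 300-mm water cylinder with 20 holes in two
rings (8 at r = 50 mm, 12 at r = 105 mm, 12.5-mm radius), carrying
either the 12-insert relative-electron-density set {0.30 … 1.694} plus
air and water, or the plug-study configurations (all unit-density
plugs, inner ring removed, all removed).  HU values follow the forward
calibration model exactly, so insert measurement + refit recovers the
generating line.

The **pelvis phantom** is a 400 × 300 mm soft-tissue ellipse — wider
than the 38.6-cm scan circle, so the composite ray-trace path is
genuinely exercised — containing femoral heads, a prostate sphere at the
isocentre, perirectal fat, and a rectum tube (radius 14 mm, posterior
of the prostate, with a slowly wandering centreline) spanning 108 mm of
SI extent, longer than the 72-mm MV scan.  Per fraction: couch shifts
N(0, 3 mm) per axis and roll N(0, 1°) applied rigidly (the registration
record stores exactly this transform, and ground-truth masks are
transformed consistently); a smooth radius wave (σ 6%, 80-mm period)
plus 2% per-slice jitter deforms the organ; gas pockets appear in 30% of
slices.  Two confusers emulate the documented failure modes: the two
most inferior MV slices lose all rectum/muscle contrast (a ring of
rectum-like material), and with probability 0.12 per slice a partial-arc
halo (240°, 5 mm) of rectum-like material abuts the wall.  MV images are
cropped to the scan circle and carry 30-HU Gaussian noise (kV: 10 HU).
Default MV geometry matches the clinical setting (0.76-mm pixels, 6-mm
coarse slices); a coarse preset (`PelvisSpec().small()`) exists for fast
end-to-end runs.

What the phantom does *not* emulate: MV scatter/ring artifacts,
beam hardening, genuinely deformable (non-radial) anatomy, and
observer-style contouring ambiguity.  Passing tests therefore show that
the pipeline is geometrically and algorithmically correct under
realistic noise and the designed failure modes — not that clinical
conformity on real patients would be 0.94.  The clinical expectation
remains the published-range 0.7–0.8 regime; on this phantom the
pre-smoothing mean is ≈ 0.94 and the smoothed-surface step adds a small
strict improvement, preserving the direction (not the absolute values)
of that comparison.

**Problem sizes.**  The bundled acceptance evaluation uses 20
single-fraction scans at full MV resolution (~6 min on one core); the
dose-engine checks use an 80-pixel, 3-slice phantom with a single
rotation; the end-to-end cohort test uses the coarse preset with 3
patients × 4 fractions.  These sizes were chosen to make the whole
verification suite a desk-scale computation while leaving every
algorithmic path exercised at clinical resolution somewhere in the
suite.

## Batch orchestration

Work splits into one job per (patient, fraction, stage ∈ {dose, segment,
dsm}); fractions flagged unusable are planned as skipped and never run;
existing outputs are detected and not re-queued.  Jobs share no mutable
state, write outputs atomically (temp file + rename), and can run
sequentially or on a local process pool — results are identical for any
worker count, which the tests assert byte-for-byte on the merged
outputs.  Merging accumulates each patient's fraction DSMs (computing
the planning dose and DSM on the planning scan for the padding and the
planned-EUD reference) and writes a per-patient EUD summary CSV.
Cluster/grid backends are out of scope; the job model is the interface a
distributed backend would adapt.

## Known limitations

* The beamlet model is a stand-in: absolute doses are internally
  consistent, not clinically commissioned.
* Rigid alignment only; deformable registration and voxel-level dose
  accumulation are explicitly out of scope (DSM summation is the chosen
  alternative).
* Chan–Vese stopping uses scikit-image's level-set-variation tolerance
  rather than a boundary-pixel-change criterion; with the 10⁻⁴
  tolerance the difference is below the marching-squares resampling
  noise.
* Calibration uncertainties are stored, not propagated.
* RTSTRUCT/RTDOSE I/O covers the conventions this pipeline produces
  (axial, single structure, uniform grids), not the full DICOM-RT
  standard.
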