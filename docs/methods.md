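# Methods

`strokequant` quantifies the acute pathology of the porcine permanent
middle-cerebral-artery-occlusion (MCAO) stroke model from MRI-derived
inputs and pressure-mat gait recordings, and compares two pig breeds with
unpaired statistics. This note records the measurement models, the
defaults that matter, the design choices that were genuinely open, and
what the synthetic validation does and does not demonstrate.

## Imaging conventions

All volumes are 3-D grids in canonical right-anterior-superior (RAS)
order with per-axis voxel spacing in mm; a "coronal slice" is a fixed
index along the anterior-posterior axis. Voxel indices are 0-based, world
coordinates are mm. The artifact consumes ADC maps (10^-3 mm^2/s), FA
maps (dimensionless, [0, 1]) and integer label volumes; it does not fit
tensors or segment tissue from raw diffusion data. The occlusion in this
model is right-sided, so ipsilateral defaults to the right hemisphere and
is configurable. Region volumes are voxel counts times voxel volume,
reported in cm^3 (1 decimal in reports, full precision internally).

## Edema-corrected lesion volume

Acute infarcts swell, so the lesion measured on the ipsilateral
hemisphere overstates the tissue actually infarcted. With HVc and HVi the
contralateral/ipsilateral hemisphere volumes and LVu the uncorrected
lesion volume,

    LVc = (HVc + HVi) − (HVc + HVi − LVu) · (HVc + HVi) / (2·HVc).

Two properties pin this form down: LVc = LVu exactly when HVc = HVi, and
LVc decreases as HVi grows with HVc and LVu fixed (swelling shrinks the
corrected lesion). It also tracks the classical indirect estimate
HVc − (HVi − LVu) closely (e.g. 2.125 vs 2.0 cm^3 at HVc = 80, HVi = 90,
LVu = 12). Note the formula can return negative values when the
measured swelling exceeds the lesion volume — that is the formula's
behavior, not an implementation artifact, and it is reported unclamped.

Lesion masks are produced by thresholding the ADC map inside the
ipsilateral hemisphere at a fraction (default 0.80) of the
contralateral-hemisphere mean ADC, keeping the largest 26-connected
component. The default sits between the diffusivity drop of acute
infarct in this model (roughly 35–45% below contralateral) and normal
tissue; it is configurable. Swelling and ventricle compression are plain
percent changes, 100·(ipsi − contra)/contra.

## Diffusivity and white-matter metrics

Hemisphere ADC change is computed per coronal slice containing at least
one voxel of each hemisphere — 100·(mean ipsi − mean contra)/mean contra
— and summarized as the unweighted mean across included slices
(voxel-count weighting is available behind a flag). Slices missing a
hemisphere are excluded and logged. Whether the original protocol
restricted to lesion-bearing slices is not stated; a lesion-slices-only
mode exists but is off by default. Internal-capsule FA change is the
percent change of the ipsilateral ROI mean relative to the contralateral
one. Hemisphere masks exclude CSF only insofar as the label volume
encodes it; no intensity-based stripping is applied.

## Midline shift and herniation indices

All geometry is planar and landmark-based. MLS is the perpendicular
distance from the septum pellucidum to the ideal midline through the
anterior/posterior midline anchors — perpendicular rather than
horizontal, so the measure is invariant to in-plane head rotation. The
magnitude is reported unsigned with a separate direction flag, since the
sign convention is not standardized.

On the midsagittal plane, the skull length line SLL runs from the dorsal
cribriform plate to the dorsal foramen magnum margin; the transtentorial
line TTL from the dorsal sella to the rostral tentorium; the foramen
magnum line FML across the foramen. TTX and FMX are the maximal
perpendicular extents of the ventral cerebellar contour beyond TTL/FML
along a caudal unit normal, clamped at zero; CTH = TTX/SLL and
FMH = FMX/SLL are dimensionless, invariant to rigid motion and uniform
scale. Because a human rater selects the relevant part of the cerebellar
margin by eye, the landmark file may carry two measurement-specific arcs
(tentorial and caudal) in addition to, or instead of, a single ventral
contour; the caudal normal per line is either stored in the file or
derived as the perpendicular oriented toward the measured arc's centroid.
Ties between equally protruding contour points are resolved by the
maximum, which is tie-independent.

## Gait analysis

A run is one pass over the pressure mat. The good-run rule requires at
least 12 footfalls and at least three complete contact-to-contact cycles
per limb. Per limb: cycle time is the mean interval between successive
contacts of that hoof, stride length the mean forward distance between
those placements, stance the contact-to-lift interval, swing percent
100·(cycle − mean stance)/cycle, and pressure the mean of the hoof's
event pressures (arbitrary units; the vendor's exact definitions are
proprietary, these are documented substitutes). Run velocity is
first-to-last contact displacement over elapsed time, since the mat
records no continuous trajectory. Cadence is 60/mean limb cycle time
(strides/min): this reproduces the published magnitudes (cycle ≈ 0.45 s
↔ cadence ≈ 133), whereas counting all four hooves' footfalls would give
≈ 4× the printed values. The forward axis is x and runs in either
direction are normalized to positive displacement.

Pre-stroke aggregation is the mean of per-day means over three
collection days (equal day weights; a pooled-run mean is available by
flag); post-stroke performance is the mean over exactly five good runs.
Post values are normalized per animal: 100·(post − pre)/pre. Swing
values above 50% are reproduced as the definitional arithmetic gives
them; their physiological interpretation is left open.

## Statistics

Each metric is screened per group with Shapiro-Wilk (p ≥ 0.05 treated as
consistent with normality; delegated to scipy and cross-checked against
an independent R oracle in the tests). Breeds are compared with Welch's
unequal-variance t-test and Satterthwaite degrees of freedom, two-tailed,
significance at p ≤ 0.05. A failed normality screen is recorded with a
warning but does not change the test, and no multiple-comparison
correction is applied by default (a Holm option exists behind a flag) —
both choices reproduce the source workflow rather than improve on it.
Simulated group sizes default to 6 vs 12, the study's post-exclusion
sizes.

## Synthetic validation

The phantom generator builds both hemispheres, lateral ventricles,
internal capsules, corpus callosum and cerebellum as ellipsoids, plus a
spherical lesion of reduced ADC, on a configurable grid (default 0.5 mm
isotropic). Surfaces are selected by ranking voxels on the squared-radius
field and keeping exactly the number matching the requested volume, so
voxel-counted ground truth equals the specification to within half a
voxel plus ties. Intensities are uniform per compartment (ADC 1.0
contralateral, CSF at 3×, lesion and ipsilateral ratios configurable; FA
0.25 parenchyma, 0.45 corpus callosum, internal capsules as specified).
The contralateral internal-capsule FA baseline of 0.500 is a package
choice: only the percent change is published. Landmark geometry is
generated in closed form (a canonical skull skeleton scaled to the
requested SLL, arcs offset by exactly TTX/FMX), not extracted from the
image, mirroring the manual rater. Optional Gaussian intensity noise is
seeded and off by default.

Gait cohorts draw per-pig parameters from the breed presets (normal,
printed means/SDs); post-stroke values apply drawn percent changes to
each pig's own pre values. Footfall times/positions are constructed as a
two-beat pace such that the extractor recovers every drawn parameter
exactly at zero noise; in particular the trailing hind hoof's start
position is solved so that first-to-last displacement over elapsed time
equals the drawn velocity. Cadence is derived from the drawn cycle times
(the published cadence and cycle-time changes are mutually inconsistent
with cadence ≡ 60/cycle, so cycle times are primary). Within-pig
run-to-run noise defaults to 20% of the between-pig SD. Parameters are
drawn independently; between-parameter correlations are not published
and are not modeled.

What passing validation shows: the measurement path (I/O, voxel
counting, thresholding, slice averaging, planar geometry, footfall
parsing, aggregation, normalization) is internally correct to the stated
tolerances — volumes 2%, percent changes 1 point absolute, MLS one
voxel, indices 0.005, gait exact at zero noise. What it does not show:
robustness to registration error, partial-volume and bias-field effects,
rater variability in landmark placement, non-ellipsoidal anatomy, or
correlated gait deficits — none of which the simple solids emulate.

## Problem sizes

Validation and the test suite run phantoms at 1–2 mm spacing; the
reproduction script uses 0.5 mm (about 5.3 million voxels per phantom).
Monte-Carlo checks use 10,000 null pairs for the type-I error of the
Welch test and 1,000 random fixtures for the geometry oracle.

## Known limitations

- The published "lesion volume normalized to hemispheric volume"
  (≈ 59%) is arithmetically inconsistent with ~10 cm^3 lesions in
  ~80 cm^3 hemispheres; the package computes 100·LVc/HVi and reports it
  without attempting to reproduce the published normalization, whose
  denominator is unknown.
- ADC map units are standardized to 10^-3 mm^2/s, but only unit-free
  percent changes are ever reported, so the choice is inert.
- The a-priori power analysis of the source study is under-specified and
  not reproduced.
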