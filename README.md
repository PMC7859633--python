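# strokequant

Quantification battery for the porcine ischemic-stroke (permanent MCAO)
model: edema-corrected lesion volumetry, hemispheric swelling and
lateral-ventricle compression, midline-shift and cerebellar-herniation
indices, ADC/FA diffusion-map statistics, quadruped spatiotemporal gait
analysis with pre/post normalization, and Welch-Satterthwaite breed
comparison. It is written for groups running pig stroke studies who need
the published measurement battery as tested, scriptable code rather than
manual ROI work — and it validates itself end to end on synthetic brain
phantoms and simulated gait cohorts with exactly known ground truth.

## What it computes

Volumes are voxel counts × voxel volume on label images (NIfTI-1, RAS).
With HVc/HVi the contralateral/ipsilateral hemisphere volumes and LVu
the ADC-derived uncorrected lesion volume, the edema-corrected lesion
volume is

    LVc = (HVc + HVi) − (HVc + HVi − LVu) · (HVc + HVi) / (2·HVc)

which reduces to LVu when the hemispheres are equal and shrinks the
lesion under ipsilateral swelling. Swelling and ventricle compression
are 100·(ipsi − contra)/contra. Diffusivity change is the per-coronal-
slice ADC percent change between hemispheres, averaged across slices;
white-matter change is the internal-capsule FA percent change. Midline
shift is the perpendicular deviation of the septum pellucidum from the
ideal midline; the herniation indices are CTH = TTX/SLL and
FMH = FMX/SLL, cerebellar protrusion extents normalized by skull length.
Gait runs passing the good-run rule (≥ 12 footfalls, ≥ 3 cycles per
limb) yield velocity, cadence, and per-limb cycle time, swing percent,
stride length and mean pressure; post-stroke values are normalized per
animal to its pre-stroke average. Breeds are compared metric-by-metric
with Welch's unequal-variance t-test (Satterthwaite df, α = 0.05, no
multiplicity correction), after a Shapiro-Wilk normality screen.

See `docs/methods.md` for the measurement models, defaults and
limitations.

## Worked example

Generate a phantom parameterized at the Yucatan group means and measure
it:

```python
import strokequant as sq

spec = sq.phantom_spec_for_breed("yc", spacing=1.0)
b = sq.generate_phantom(spec)
vol = sq.volumetry_report(b.labels, adc=b.adc)
diff = sq.diffusion_report(b.adc, b.fa, b.labels)
geo = sq.herniation_indices(b.landmarks_sagittal, b.landmarks_axial)
print(f"hemispheres (contra/ipsi): {vol.hv_contra:.1f} / {vol.hv_ipsi:.1f} cm^3")
print(f"swelling: {vol.swelling_percent:.1f} %")
print(f"ventricle compression: {vol.ventricle_compression_percent:.1f} %")
print(f"lesion (uncorrected/corrected): {vol.lesion_uncorrected:.1f} / {vol.lesion_corrected:.1f} cm^3")
print(f"IC FA change: {diff.fa_change_percent:.1f} %")
print(f"MLS: {geo.mls_mm:.1f} mm   CTH: {geo.cth:.2f}   FMH: {geo.fmh:.2f}")
```

prints

```
hemispheres (contra/ipsi): 79.8 / 90.5 cm^3
swelling: 13.4 %
ventricle compression: -53.1 %
lesion (uncorrected/corrected): 10.0 / -0.7 cm^3
IC FA change: -11.4 %
MLS: 1.6 mm   CTH: 0.12   FMH: 0.11
```

The pipeline recovers every generator parameter: 13.4% swelling from
79.8 vs 90.5 cm³ hemispheres, −53.1% compression of the 1.40 cm³
ventricle to 0.657 cm³, the 10.0 cm³ lesion, the −11.4% FA drop, and the
landmark geometry (1.6 mm shift, indices 0.12/0.11). The corrected
lesion volume is near zero here because at these group means the
measured swelling (≈ 10.7 cm³) is as large as the lesion itself — the
correction attributes the whole lesion to edema.

Command-line equivalents:

```
strokequant simulate phantom --preset yc-post --seed 7 --out phantom/
strokequant simulate gait --preset lr --pigs 12 --seed 7 --out gait/
strokequant compare --config study.json   # per-pig metrics + breed comparison
strokequant validate --seed 0             # closure checks vs ground truth
```

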