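# voxreflect

Voxel-wise T1-weighted MRI contrast quantification for tube phantoms.

When a candidate MRI contrast agent (for example a gadolinium-loaded,
cancer-targeted nanoparticle) is evaluated in vitro, the treated ("test")
and untreated ("control") cell samples sit in separate microcentrifuge
tubes, scanned separately.  The traditional readout is the percent
enhancement of manually drawn 2D ROI means,

    R = (Test_avg − Control_avg) / Control_avg × 100 ,

which discards the 3D structure of the data and is sensitive to where the
analyst draws the ROI.  `voxreflect` implements the automated, local
alternative: it extracts each tube as a 3D Volume of Interest, brings the
test tube into dense voxel-on-voxel correspondence with the control tube by
a two-step registration, and computes the reflectivity as a ratio of sums
over the matched voxels,

    R = Σᵢ (Iᵢ − gᵢ) / Σᵢ gᵢ × 100 ,

where Iᵢ and gᵢ are the water-normalized test and control signals at
matched voxel *i* and *N* voxels contribute.  On a fixed common mask the two
formulas agree algebraically; the value of the voxel-wise route is the
automation (no hand-drawn ROI), the registration (which makes the
comparison local), and the per-voxel map (Iᵢ−gᵢ)/gᵢ×100 rendered as a
diverging color map.

The analysis chain:

1. **VOI extraction** — Otsu background removal (between-class-variance
   threshold on a 256-bin histogram) and 26-connected 3D region growing
   isolate each tube; every scan is divided by the mean signal of its
   water tube so scans share a unit.
2. **Distance maps** — the interior Euclidean distance of every tube voxel
   to the tube boundary, computed by a fast-marching min-heap front, is
   used as a shape feature image that is independent of tube signal.
3. **Registration** — a 12-degree-of-freedom affine transform maximizing
   the mutual information of the distance maps, refined by a four-stage
   multiresolution cubic B-spline free-form deformation optimized with
   L-BFGS-B.
4. **Reflectivity** — the global R, the per-voxel percent map, and the
   color rendering.

The supporting quantitative chain is included: per-voxel T1 fitting from an
arrayed-TR spin-echo series (S(TR) = S₀(1 − e^(−TR/T1))), relaxivity
regression (r1 = slope of 1/T1 versus Gd concentration, mM⁻¹s⁻¹),
xylenol-orange Gd(III) quantification from A573/A433 absorbance ratios, and
exact paired two-tailed t-tests for comparing measurement sets.  A
synthetic phantom generator with Rician noise and known applied
misalignments provides ground truth for every stage.

## Worked example

`examples/04_reflectivity_pipeline.py` builds a control scan and a test
scan whose sample tube is 20% brighter, misaligns the test scan by a
3-voxel shift, a 5° rotation and a mild smooth warp, and runs the full
chain:

```
global reflectivity R = 19.84% over 1105 tube voxels (ground truth 20%)
water means: test 60.05, control 59.98 (scans rescaled to a common unit)
elastic stage max displacement 0.36 mm
color map rendered: (21, 21, 29) voxels, diverging scale over [-100.0, 100.0]%
without registration the same pair reads R = -7.43% - the misalignment destroys the measurement
```

The recovered R is within the noise of the constructed 20% truth; the final
line is the ablation that shows why registration is the heart of the
method.  The other examples cover phantom simulation, VOI extraction,
registration accuracy, T1/relaxivity fitting and the Gd assay; each prints
the numbers it computes and what they mean.

A thin CLI mirrors the library (`voxreflect simulate | convert | normalize |
extract | register | analyze | t1map | relaxivity | gd-assay`).

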