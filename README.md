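# retmorph

Micro-densitometry of retinal arteries on OCT cross-sections, with the
downstream morphometry, reliability and cohort statistics needed to study
vascular remodeling alongside retinal neurodegeneration.

## The problem

On a spectral-domain OCT B-scan, a retinal artery crossed by the scan shows
up as two wall reflections on either side of the blood column. Sampling the
image intensity along a line through the vessel gives a profile with two
wall lobes; the edge of each wall can be localized at **full-width
half-maximum (FWHM)** — the sub-pixel position where the profile crosses the
midpoint between the lobe's local background and its peak. From the outer
and inner crossings of the two lobes, calibrated by the pixel length of the
scan's 200 µm scale bar, one obtains the retinal artery outer diameter
(RAOD) and lumen diameter (RALD), and from them the standard wall
morphometry:

    AWT  = (RAOD − RALD) / 2            arterial wall thickness, µm
    WLR  = (RAOD − RALD) / RALD         wall-to-lumen ratio
    WCSA = (π/4) (RAOD² − RALD²)        wall cross-sectional area, µm²

These markers of arteriolar remodeling are studied in type 2 diabetes,
where inner-retinal neurodegeneration (ganglion cell layer and nerve fiber
layer thinning) may precede visible vascular lesions. The package targets
researchers who want a tested, scriptable version of this measurement chain:

* `retmorph.densitometry` — profile extraction, scale calibration, wall-lobe
  detection, sub-pixel half-max crossings, diameter measurement;
* `retmorph.morphometry` — AWT/WLR/WCSA, duplicate averaging, aggregation of
  the four largest arteries into one value set per eye;
* `retmorph.reliability` — two-way absolute-agreement ICC (single/average)
  with F-based CIs, Bland–Altman limits of agreement with a trend line,
  within-subject coefficient of variation;
* `retmorph.cohort_stats` — normality-gated group comparisons with Tukey
  post-hoc tests, chi-square for categorical covariates, per-group Pearson
  correlation grids, univariate and covariate-adjusted regressions with
  standardized coefficients;
* `retmorph.synthetic` — vessel phantoms with exact geometric ground truth
  and three-group cohorts with specified means/SDs/correlations, so the
  whole chain runs without clinical data.

## Worked example

Measure a synthetic artery whose true geometry is known (outer 130.71 µm,
lumen 97.21 µm), blurred by a 4 µm point-spread function with additive
noise:

```python
import retmorph as rm

spec = rm.VesselPhantomSpec(raod_um=130.71, rald_um=97.21,
                            psf_sigma_um=4.0, noise_sd=3.0)
profile, truth = rm.generate_vessel_profile(spec, seed=1)
calib = rm.calibrate_scale(200.0)          # 200 px per 200 µm scale bar
pair, bounds = rm.measure_vessel(profile, calib,
                                 rm.DensitometryConfig(polarity="walls-bright"))
print(f"true RAOD {truth.raod_um:.2f} µm   measured {pair.raod_um:.2f} µm")
print(f"true RALD {truth.rald_um:.2f} µm   measured {pair.rald_um:.2f} µm")
print(f"AWT  {rm.compute_awt(pair.raod_um, pair.rald_um):.2f} µm")
print(f"WLR  {rm.compute_wlr(pair.raod_um, pair.rald_um):.2f}")
print(f"WCSA {rm.compute_wcsa(pair.raod_um, pair.rald_um):.2f} µm²")
```

prints

```
true RAOD 130.71 µm   measured 131.41 µm
true RALD 97.21 µm   measured 96.52 µm
AWT  17.45 µm
WLR  0.36
WCSA 6247.32 µm²
```

Both diameters are recovered to well under a micrometre of bias on average
(this single noisy draw is off by ~0.7 µm), and the derived parameters land
in the physiological range reported for large retinal arteries.

The same chain is available from the shell:

```sh
retmorph run-all --outdir out --seed 7     # phantoms → measurement →
                                           # morphometry → reliability →
                                           # cohort reports + hash manifest
retmorph measure --profile profile.csv --scale-px 200
```

`run-all` writes per-eye morphometry, a reliability report (ICC ≈ 0.998 and
sub-percent CV for duplicate phantom measurements, i.e. the "good
agreement" regime), cohort comparison/correlation/regression tables, and a
`manifest.json` of SHA-256 hashes — two runs with the same seed produce
identical manifests.

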