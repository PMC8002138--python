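# Methods

## The measurement model

A retinal artery crossed perpendicularly by the OCT scan appears, along a
sampling line through the vessel, as two wall lobes separated by the lumen.
We model the ideal cross-section as piecewise constant — background, wall
annulus, lumen, wall annulus, background — convolved with a Gaussian
point-spread function of scale σ (µm) and sampled on a uniform grid with
additive i.i.d. Gaussian noise. The observed "parabola-like" wall lobes of
real profiles are exactly what this blurred-boxcar model produces, while
keeping the pre-blur edge positions available as ground truth; this is why
the phantom generator uses a boxcar rather than a literal parabola.

Boundaries are localized at **half maximum**: for each wall lobe, the
reference baseline is the median of the `baseline_fraction` (default 10%)
of samples on that lobe's *outer* side, the half level is
`baseline + (peak − baseline)/2`, and the crossing on each side is found by
walking outward/inward from the peak to the first sample interval
straddling the half level, then linearly interpolating between the two
straddling samples. The outer diameter is the distance between the outer
crossings of the two lobes, the lumen diameter between the inner crossings,
both scaled by `200 / pixels_per_200um` µm per pixel.

Because the half level is defined relative to the local baseline, the
measurement is exactly invariant under affine intensity maps `I → aI + b`
(a > 0), equivariant under profile translation, and exactly linear in the
scale calibration.

### Bias of half-maximum localization

The half-maximum crossing of a Gaussian-blurred step sits exactly at the
step **when the intensity levels on both sides of the wall are equal and
the wall plateau is resolved**. Two deviations matter in practice:

1. *Unequal flanking levels.* With a single per-lobe baseline, a lumen
   whose intensity differs from the background shifts the inner crossing by
   about σ·Φ⁻¹-scale amounts. The phantom default therefore places lumen
   and background at one level (walls bright above both), which is also the
   realistic OCT configuration of a hyperreflective wall over a
   hyporeflective blood column and vitreous. Measurements on media where
   the lumen level differs substantially from the background will carry a
   corresponding lumen-diameter bias.
2. *Unresolved plateau.* When σ approaches half the wall thickness, the
   blur from the wall's two edges interacts: the lobe no longer reaches
   full wall intensity, its lobe-relative half level falls below the step
   midpoint, and the outer diameter is overestimated (lumen
   underestimated). For a 16.75 µm wall, the bias is ≲ 0.4 µm at σ = 4 µm
   but grows to several µm by σ = 8 µm. The sub-sampling-step bias
   guarantee therefore holds for σ up to roughly a quarter of the wall
   thickness; a regression test documents the outward bias beyond that.

### Polarity

Display conventions differ on whether vessel walls are bright or dark.
`DensitometryConfig.polarity` accepts `walls-bright`, `walls-dark`, or
`auto`, which compares the median of the central 50% of samples against the
median of the two profile ends; when those medians tie (lumen at background
level), it falls back to asking on which side of the end-level the larger
excursion lies. Auto mode assumes the lumen intensity does not sit on the
opposite side of the background from the walls.

### Parameters that matter

| parameter | default | role |
|---|---|---|
| `smoothing_window_px` | 1 (off) | centred moving average before detection; crossings use the smoothed signal |
| `baseline_fraction` | 0.10 | outer-tail fraction per lobe used as local background |
| `min_lumen_px` | 5 | minimum peak separation, rejects double-detection of one lobe |
| phantom σ | 4 µm | axial/lateral blur scale typical of SD-OCT at this magnification |
| phantom noise SD | contrast/33 | keeps single-profile diameter errors below ~1 µm, matching sub-percent duplicate CVs |
| sampling | 1 µm/px | profile grid; window extends 50 µm beyond each outer edge |

When more than two candidate lobes exist, the two with the highest
prominences are kept; equal-prominence ties resolve to the pair whose
midpoint is closest to the profile centre. Sub-pixel refinement of the peak
position itself is deliberately omitted — only the crossings need sub-pixel
accuracy, and first-crossing linear interpolation matches their semantics.

## Morphometry

AWT = (RAOD − RALD)/2, WLR = (RAOD − RALD)/RALD, WCSA = (π/4)(RAOD² −
RALD²). Every vessel is measured twice and the diameters averaged before
anything else; each eye's value set averages its four largest arteries
(largest by duplicate-averaged RAOD, ties by input order). Derived
parameters are computed per vessel from averaged diameters and then
averaged across vessels; because WLR and WCSA are nonlinear in the
diameters, this differs from recomputing them from per-eye mean diameters —
the alternative is available via `aggregate_eye(..., from_eye_means=True)`,
and a test pins the counterexample. AWT commutes with aggregation exactly.

## Reliability battery

The intra-rater statistics treat vessels as rows and sessions as columns of
a complete n × k matrix (k = 2 here).

* **ICC**: two-way random-effects absolute-agreement forms — single measure
  `(MSR − MSE) / (MSR + (k−1)MSE + (k/n)(MSC − MSE))` and average measure
  `(MSR − MSE) / (MSR + (MSC − MSE)/n)` — with 95% CIs from the standard
  F-based construction (Satterthwaite degrees of freedom for the session
  term); the average-measure interval is the Spearman–Brown transform of
  the single-measure one. A zero-variance matrix is reported as an explicit
  degenerate result rather than a number. Tests verify equality (≤ 1e-9)
  with a definitional sums-of-squares oracle and with pingouin's
  ICC(A,1)/ICC(A,k).
* **Bland–Altman**: bias = mean(first − second), limits of agreement
  bias ± 1.96·SD(differences) (SD with n−1), plus the ordinary
  least-squares line of difference on pairwise mean.
* **Within-subject CV**: root-mean-square form
  `cv = 100·sqrt(mean_i[(d_i²/2)/m_i²])`. The 95% interval scales cv by
  chi-square quantile bounds on the pooled within-subject variance with n
  degrees of freedom — a documented choice, since the estimator's interval
  construction is not standardized across software. A per-subject SD/mean
  variant is available via `method="sd_mean"`.

## Cohort statistics

Group comparisons are gated on a one-sample Kolmogorov–Smirnov test against
a normal with the sample mean/SD, applied per variable pooled across groups
at α = 0.05: parametric path (one-way ANOVA with Tukey-adjusted pairwise
p-values for three groups, Student's t for two) when not rejected,
Kruskal–Wallis otherwise. Categorical covariates use Pearson chi-square
without continuity correction, refusing tables with expected counts below
1. Regressions are ordinary least squares; the reported standardized
coefficient is `slope · SD(predictor)/SD(dependent)` (equal to Pearson r in
the univariate case — asserted to 1e-9 in tests), while the CI refers to
the unstandardized slope. The adjusted model adds age, gender (male = 1),
diabetes duration and HbA1c as covariates, uses complete cases, and rejects
rank-deficient designs naming the collinear columns.

## Synthetic cohorts

`generate_cohort` draws each group from a latent Gaussian copula:
continuous variables are affine transforms of correlated standard normals
(so targeted pairwise Pearson correlations are hit asymptotically), binary
variables threshold their latent at the requested prevalence. Correlation
targets that do not assemble into a positive semi-definite matrix are
rejected naming the offending pairs. The packaged default spec emulates a
three-group study — 32 healthy control, 32 diabetic-without-retinopathy and
21 mild-retinopathy eyes — with group means/SDs for demographics,
morphometry and layer thicknesses in the ranges reported for such cohorts,
a strong central GCL–macular-RNFL correlation per group (0.81/0.68/0.78)
and a moderate WCSA–central-GCL association (0.353) in the diabetic groups.

What the generator does **not** emulate: within-subject correlation between
an eye's morphometry and the phantom pipeline's measurements (cohort
columns are drawn, not measured), speckle or multiplicative OCT noise,
segmentation failures, non-Gaussian marginals (all continuous variables are
normal), and missingness beyond structurally absent variables (diabetes
duration/HbA1c in controls). Passing cohort tests therefore demonstrates
the statistical machinery's correctness and calibration, not robustness to
real-data pathologies.

## Problem sizes and numerics

Monte-Carlo checks use 100 phantom seeds for diameter recovery, 1000
replicate null cohorts (n = 50/group) for type-I calibration, n = 2000 and
n = 5000 cohorts for effect-size recovery, and 10⁴ pairs for algebraic
identities — sizes at which binomial/standard-error bands comfortably
separate pass from fail while the full suite stays quick. All randomness
flows through `numpy.random.default_rng` with explicit seeds; equal specs
and seeds reproduce byte-identical artifacts, which the pipeline verifies
by hashing every output into a manifest. Report tables round to 2 decimals;
all machine-readable outputs keep full precision.

## Known limitations

* The FWHM estimator needs both wall lobes inside the profile window; a
  lobe truncated by the window is an error ("open lobe"), not a guess.
* Vessel localization is out of scope: the sampling line is supplied by the
  user (or by the phantom generator), mirroring manual practice.
* Artery/vein discrimination is a label in the data model, not an
  algorithm; it is done on infrared fundus images in practice.
* Eyes are treated as independent sampling units, as in the emulated
  design (one eye per subject).
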