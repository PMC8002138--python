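"""Synthetic vessel phantoms and cohorts with known ground truth.

Two generators make the whole pipeline testable without clinical data:

* **Vessel phantoms** — an idealized artery cross-section along the sampling
  line is piecewise constant (background | wall | lumen | wall | background),
  blurred by a Gaussian point-spread function and sampled with additive
  Gaussian noise.  The pre-blur edge positions are exact ground truth for
  the outer and lumen diameters, and the blurred boxcar reproduces the
  two-lobe appearance of real OCT wall profiles.

* **Cohorts** — a three-group, eye-level table (healthy controls, diabetics
  without retinopathy, diabetics with mild non-proliferative retinopathy)
  with per-group means/SDs, targeted Pearson correlations realized through
  a latent-Gaussian copula, and binary covariates thresholded from the same
  latents.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .densitometry import IntensityProfile

GROUP_LABELS = ("control", "NDR", "NPDR")


@dataclass(frozen=True)
class GroundTruth:
    """True morphometry implied by a phantom's pre-blur geometry."""

    raod_um: float
    rald_um: float
    awt_um: float
    wlr: float
    wcsa_um2: float

    @classmethod
    def from_diameters(cls, raod_um: float, rald_um: float) -> "GroundTruth":
        awt = (raod_um - rald_um) / 2.0
        return cls(
            raod_um=raod_um,
            rald_um=rald_um,
            awt_um=awt,
            wlr=2.0 * awt / rald_um,
            wcsa_um2=math.pi * awt * (rald_um + awt),
        )


@dataclass(frozen=True)
class VesselPhantomSpec:
    """Geometry, optics and noise of one synthetic artery cross-section.

    Default diameters are a typical large retinal artery (outer 130.71 µm,
    lumen 97.21 µm); the lumen and background share one intensity level with
    bright walls, the configuration under which half-maximum edges of the
    blurred profile coincide with the true edges.
    """

    raod_um: float = 130.71
    rald_um: float = 97.21
    wall_intensity: float = 120.0
    lumen_intensity: float = 20.0
    background_intensity: float = 20.0
    psf_sigma_um: float = 4.0
    noise_sd: float = 0.0
    um_per_px: float = 1.0
    profile_halfwidth_um: float = 50.0
    polarity: str = "walls-bright"

    def __post_init__(self) -> None:
        if not (self.raod_um > self.rald_um > 0):
            raise ValueError("require raod_um > rald_um > 0")
        if self.psf_sigma_um < 0 or self.noise_sd < 0:
            raise ValueError("psf_sigma_um and noise_sd must be >= 0")
        if self.um_per_px <= 0:
            raise ValueError("um_per_px must be positive")
        if self.polarity not in ("walls-bright", "walls-dark"):
            raise ValueError("polarity must be 'walls-bright' or 'walls-dark'")
        w, l, b = self.wall_intensity, self.lumen_intensity, self.background_intensity
        if w == l or w == b:
            raise ValueError("wall_intensity must differ from lumen and background")
        if self.polarity == "walls-bright" and not (w > l and w > b):
            raise ValueError("walls-bright requires wall_intensity above lumen and background")
        if self.polarity == "walls-dark" and not (w < l and w < b):
            raise ValueError("walls-dark requires wall_intensity below lumen and background")
        if self.profile_halfwidth_um < 3.0 * self.psf_sigma_um:
            raise ValueError(
                "profile window too small: profile_halfwidth_um must extend at "
                f"least 3*psf_sigma_um = {3.0 * self.psf_sigma_um:g} µm beyond "
                "each outer boundary"
            )

    @property
    def ground_truth(self) -> GroundTruth:
        return GroundTruth.from_diameters(self.raod_um, self.rald_um)

    @classmethod
    def walls_dark(cls, **kwargs) -> "VesselPhantomSpec":
        """Convenience constructor with inverted default intensities."""
        defaults = dict(
            wall_intensity=20.0, lumen_intensity=120.0,
            background_intensity=120.0, polarity="walls-dark",
        )
        defaults.update(kwargs)
        return cls(**defaults)


def _blurred_box(x: np.ndarray, a: float, b: float, sigma: float) -> np.ndarray:
    """Indicator of [a, b] convolved with a Gaussian of scale sigma."""
    if sigma == 0:
        return ((x >= a) & (x <= b)).astype(float)
    return ndtr((x - a) / sigma) - ndtr((x - b) / sigma)


def generate_vessel_profile(
    spec: VesselPhantomSpec, seed: int
) -> Tuple[IntensityProfile, GroundTruth]:
    """Render one phantom profile and its ground truth.

    The profile is centred on the vessel: the outer edges sit at
    (n-1)/2 ± raod/(2·um_per_px) in pixel coordinates, the inner edges at
    (n-1)/2 ± rald/(2·um_per_px).  Identical (spec, seed) pairs reproduce
    identical samples.
    """
    r_out = spec.raod_um / 2.0
    r_in = spec.rald_um / 2.0
    half_extent = r_out + spec.profile_halfwidth_um
    n_half = int(np.floor(half_extent / spec.um_per_px))
    n = 2 * n_half + 1
    if n < 7:
        raise ValueError("profile window too small for a valid profile")
    x_um = (np.arange(n) - n_half) * spec.um_per_px

    bg, wall, lumen = (
        spec.background_intensity, spec.wall_intensity, spec.lumen_intensity,
    )
    ideal = (
        bg
        + (wall - bg) * _blurred_box(x_um, -r_out, r_out, spec.psf_sigma_um)
        + (lumen - wall) * _blurred_box(x_um, -r_in, r_in, spec.psf_sigma_um)
    )
    rng = np.random.default_rng(seed)
    noisy = ideal + rng.normal(0.0, spec.noise_sd, n) if spec.noise_sd > 0 else ideal
    profile = IntensityProfile(positions=np.arange(n, dtype=float), intensities=noisy)
    return profile, spec.ground_truth


def generate_repeat_measurements(
    truth_table: Sequence[GroundTruth],
    error_sd: float,
    n_repeats: int = 2,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate repeated diameter readings of each vessel by one grader.

    Each repeat adds independent N(0, error_sd²) µm measurement error to the
    true outer and lumen diameters.  Returns a long table with columns
    vessel_id, repeat (1-based), raod_um, rald_um.
    """
    if len(truth_table) == 0:
        raise ValueError("truth_table must not be empty")
    if n_repeats < 2:
        raise ValueError("n_repeats must be >= 2")
    if error_sd < 0:
        raise ValueError("error_sd must be >= 0")
    rng = np.random.default_rng(seed)
    rows = []
    for i, truth in enumerate(truth_table):
        for rep in range(1, n_repeats + 1):
            rows.append(
                {
                    "vessel_id": f"v{i:04d}",
                    "repeat": rep,
                    "raod_um": truth.raod_um + rng.normal(0.0, error_sd),
                    "rald_um": truth.rald_um + rng.normal(0.0, error_sd),
                }
            )
    return pd.DataFrame(rows)


def repeats_matrix(repeats: pd.DataFrame, value: str = "raod_um") -> np.ndarray:
    """Pivot a long repeated-measures table to an n x k matrix."""
    wide = repeats.pivot(index="vessel_id", columns="repeat", values=value)
    if wide.isna().any().any():
        raise ValueError("unbalanced repeats: missing cells after pivot")
    return wide.to_numpy()


@dataclass(frozen=True)
class CohortSpec:
    """Per-group distributional targets for a synthetic eye-level cohort."""

    groups: Tuple[Tuple[str, int], ...]
    variable_means: Mapping[str, Mapping[str, float]]
    variable_sds: Mapping[str, Mapping[str, float]]
    correlations: Tuple[Tuple[str, str, str, float], ...] = ()
    binary_rates: Mapping[str, Mapping[str, float]] = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("at least one group required")
        for label, n in self.groups:
            if n < 3:
                raise ValueError(f"group {label!r} needs n >= 3")
            if label not in self.variable_means or label not in self.variable_sds:
                raise ValueError(f"means/SDs missing for group {label!r}")
            for var, sd in self.variable_sds[label].items():
                if sd < 0:
                    raise ValueError(f"negative SD for {var!r} in group {label!r}")
        labels = {g for g, _ in self.groups}
        for a, b, grp, r in self.correlations:
            if grp not in labels:
                raise ValueError(f"correlation target names unknown group {grp!r}")
            if not (-1 < r < 1):
                raise ValueError(f"correlation target r({a}, {b}) must lie in (-1, 1)")
            if a == b:
                raise ValueError("correlation target must involve two distinct variables")
        for grp, rates in self.binary_rates.items():
            for var, p in rates.items():
                if not (0 <= p <= 1):
                    raise ValueError(f"binary rate for {var!r} must lie in [0, 1]")


class CorrelationNotRepresentableError(ValueError):
    """The requested pairwise correlations do not form a valid joint matrix."""


def _group_correlation_matrix(
    spec: CohortSpec, label: str, variables: List[str]
) -> np.ndarray:
    idx = {v: i for i, v in enumerate(variables)}
    c = np.eye(len(variables))
    pairs = []
    for a, b, grp, r in spec.correlations:
        if grp != label:
            continue
        if a not in idx or b not in idx:
            raise ValueError(
                f"correlation target ({a}, {b}) names a variable absent from group {label!r}"
            )
        c[idx[a], idx[b]] = c[idx[b], idx[a]] = r
        pairs.append((a, b, r))
    if pairs and np.linalg.eigvalsh(c).min() < -1e-8:
        raise CorrelationNotRepresentableError(
            f"correlation targets for group {label!r} are not jointly "
            f"representable (matrix not positive semi-definite); offending "
            f"pairs: {pairs}"
        )
    return c


def generate_cohort(spec: CohortSpec) -> pd.DataFrame:
    """Draw an eye-level cohort table from a latent-Gaussian copula.

    Continuous variables are affine transforms of correlated standard
    normals, so their means, SDs and pairwise Pearson correlations converge
    to the targets as n grows.  Binary variables threshold the same latents
    at the requested rates.  Deterministic under the spec's seed.
    """
    frames = []
    for g_idx, (label, n) in enumerate(spec.groups):
        cont = list(spec.variable_means[label].keys())
        binary = list(spec.binary_rates.get(label, {}).keys())
        variables = cont + binary
        c = _group_correlation_matrix(spec, label, variables)
        # PSD square root; tolerates semi-definite matrices.
        w, v = np.linalg.eigh(c)
        root = v @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
        rng = np.random.default_rng([spec.seed, g_idx])
        z = rng.standard_normal((n, len(variables))) @ root.T
        data: Dict[str, np.ndarray] = {
            "eye_id": np.array([f"{label}-{i:04d}" for i in range(n)]),
            "group": np.repeat(label, n),
        }
        for j, var in enumerate(cont):
            mean = spec.variable_means[label][var]
            sd = spec.variable_sds[label].get(var, 0.0)
            data[var] = mean + sd * z[:, j]
        for j, var in enumerate(binary, start=len(cont)):
            p = spec.binary_rates[label][var]
            data[var] = (ndtr(z[:, j]) < p).astype(float)
        frames.append(pd.DataFrame(data))
    table = pd.concat(frames, ignore_index=True, sort=False)
    return table


def default_cohort_spec(seed: int = 0, scale: float = 1.0) -> CohortSpec:
    """Three-group cohort spec emulating the study sample.

    Group sizes 32/32/21 eyes (control / diabetic without retinopathy /
    mild non-proliferative retinopathy) with per-group means and SDs for
    demographics, arterial morphometry and retinal layer thicknesses, the
    strong central GCL–macular-RNFL correlation in each group and the
    moderate WCSA–central-GCL association in the diabetic groups.
    ``scale`` multiplies group sizes (for convergence studies).
    """
    m = {
        "control": {
            "age": 55.34, "bmi": 27.16,
            "raod_um": 130.71, "rald_um": 97.21, "awt_um": 16.75,
            "wlr": 0.35, "wcsa_um2": 6065.36,
            "gcl_central": 16.16, "gcl_average": 40.65,
            "mrnfl_central": 12.50, "mrnfl_average": 27.22,
            "prnfl_average": 103.19,
            "retina_central": 280.19, "retina_average": 315.88,
        },
        "NDR": {
            "age": 60.50, "bmi": 32.12, "diabetes_duration": 9.24, "hba1c": 9.25,
            "raod_um": 133.73, "rald_um": 98.78, "awt_um": 17.47,
            "wlr": 0.36, "wcsa_um2": 6391.15,
            "gcl_central": 15.06, "gcl_average": 38.05,
            "mrnfl_central": 12.44, "mrnfl_average": 26.48,
            "prnfl_average": 99.19,
            "retina_central": 264.44, "retina_average": 302.66,
        },
        "NPDR": {
            "age": 60.48, "bmi": 29.44, "diabetes_duration": 14.67, "hba1c": 9.28,
            "raod_um": 135.76, "rald_um": 100.38, "awt_um": 17.69,
            "wlr": 0.35, "wcsa_um2": 6646.89,
            "gcl_central": 17.81, "gcl_average": 38.80,
            "mrnfl_central": 13.57, "mrnfl_average": 27.98,
            "prnfl_average": 98.48,
            "retina_central": 286.19, "retina_average": 315.32,
        },
    }
    s = {
        "control": {
            "age": 12.37, "bmi": 5.03,
            "raod_um": 10.08, "rald_um": 8.10, "awt_um": 2.19,
            "wlr": 0.05, "wcsa_um2": 1162.26,
            "gcl_central": 4.68, "gcl_average": 3.29,
            "mrnfl_central": 1.97, "mrnfl_average": 1.97,
            "prnfl_average": 17.47,
            "retina_central": 21.38, "retina_average": 12.48,
        },
        "NDR": {
            "age": 9.95, "bmi": 7.23, "diabetes_duration": 8.10, "hba1c": 2.30,
            "raod_um": 8.44, "rald_um": 6.87, "awt_um": 1.90,
            "wlr": 0.04, "wcsa_um2": 977.05,
            "gcl_central": 4.11, "gcl_average": 3.95,
            "mrnfl_central": 2.18, "mrnfl_average": 2.58,
            "prnfl_average": 10.28,
            "retina_central": 22.20, "retina_average": 14.07,
        },
        "NPDR": {
            "age": 9.53, "bmi": 4.84, "diabetes_duration": 6.03, "hba1c": 1.79,
            "raod_um": 10.04, "rald_um": 8.12, "awt_um": 2.13,
            "wlr": 0.05, "wcsa_um2": 1085.16,
            "gcl_central": 7.70, "gcl_average": 4.19,
            "mrnfl_central": 2.98, "mrnfl_average": 5.19,
            "prnfl_average": 11.61,
            "retina_central": 24.07, "retina_average": 16.79,
        },
    }
    correlations = (
        ("gcl_central", "mrnfl_central", "control", 0.81),
        ("gcl_central", "mrnfl_central", "NDR", 0.68),
        ("gcl_central", "mrnfl_central", "NPDR", 0.78),
        ("wcsa_um2", "gcl_central", "NDR", 0.353),
        ("wcsa_um2", "gcl_central", "NPDR", 0.353),
    )
    binary = {
        "control": {
            "gender_male": 17 / 32, "smoking": 8 / 32, "hbp": 17 / 32,
            "cardiovascular": 3 / 32, "dyslipidemia": 6 / 32,
        },
        "NDR": {
            "gender_male": 18 / 32, "smoking": 10 / 32, "insulin": 21 / 32,
            "hbp": 24 / 32, "cardiovascular": 14 / 32, "dyslipidemia": 18 / 32,
        },
        "NPDR": {
            "gender_male": 15 / 21, "smoking": 8 / 21, "insulin": 17 / 21,
            "hbp": 13 / 21, "cardiovascular": 12 / 21, "dyslipidemia": 16 / 21,
        },
    }
    groups = tuple(
        (label, max(3, int(round(n * scale))))
        for label, n in (("control", 32), ("NDR", 32), ("NPDR", 21))
    )
    return CohortSpec(
        groups=groups,
        variable_means=m,
        variable_sds=s,
        correlations=correlations,
        binary_rates=binary,
        seed=seed,
    )
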