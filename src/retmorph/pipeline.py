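"""End-to-end synthetic reproduction of the analysis, stage by stage.

Stages (in dependency order): ``simulate-vessels`` renders phantom profiles
with known geometry; ``measure`` runs the FWHM densitometry on every
profile; ``morphometry`` aggregates duplicate measurements into per-eye
parameter sets; ``reliability`` runs the intra-rater battery on the
duplicates; ``simulate-cohort`` draws an eye-level cohort; ``cohort``
produces the group-comparison / correlation / regression reports.  Every
run ends with a JSON manifest of produced files and their SHA-256 hashes,
so identical configurations and seeds are verifiably reproducible.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from . import io as rio
from .cohort_stats import (
    DEFAULT_COVARIATES,
    adjusted_regression,
    chi_square_counts,
    compare_groups,
    pearson_grid,
    univariate_regression,
)
from .densitometry import DensitometryConfig, ScaleCalibration, measure_vessel
from .morphometry import EYE_PARAMETERS, morphometry_table
from .reliability import bland_altman, coefficient_of_variation, icc_absolute_agreement
from .synthetic import (
    VesselPhantomSpec,
    default_cohort_spec,
    generate_cohort,
    generate_vessel_profile,
)

log = logging.getLogger("retmorph")

ALL_STAGES = (
    "simulate-vessels",
    "measure",
    "morphometry",
    "reliability",
    "simulate-cohort",
    "cohort",
)


class MissingArtifactError(FileNotFoundError):
    """A stage's required input artifact was not produced or supplied."""


@dataclass(frozen=True)
class RunConfig:
    """Configuration of a pipeline run."""

    outdir: Path
    seed: int = 0
    stages: Tuple[str, ...] = ALL_STAGES
    n_eyes: int = 8
    vessels_per_eye: int = 4
    psf_sigma_um: float = 4.0
    snr: float = 33.0
    densitometry: DensitometryConfig = field(
        default_factory=lambda: DensitometryConfig(polarity="walls-bright")
    )
    pixels_per_200um: float = 200.0
    cohort_spec_path: Optional[Path] = None
    alpha: float = 0.05

    def __post_init__(self) -> None:
        unknown = set(self.stages) - set(ALL_STAGES)
        if unknown:
            raise ValueError(f"unknown stages: {sorted(unknown)}")


def _require(path: Path, producer: str) -> Path:
    if not path.exists():
        raise MissingArtifactError(
            f"missing artifact {path.name!r}: run the {producer!r} stage first"
        )
    return path


def simulate_vessels_stage(cfg: RunConfig) -> List[Path]:
    """Render duplicate phantom profiles for every vessel of every eye."""
    rng = np.random.default_rng(cfg.seed)
    profiles_dir = cfg.outdir / "profiles"
    profiles_dir.mkdir(parents=True, exist_ok=True)
    written = []
    truth_rows = []
    contrast = 100.0
    for e in range(cfg.n_eyes):
        eye_id = f"eye{e:03d}"
        for v in range(cfg.vessels_per_eye):
            raod = float(np.clip(rng.normal(130.71, 10.08), 100.0, 165.0))
            awt = float(np.clip(rng.normal(16.75, 2.19), 10.0, 25.0))
            spec = VesselPhantomSpec(
                raod_um=raod,
                rald_um=raod - 2 * awt,
                psf_sigma_um=cfg.psf_sigma_um,
                noise_sd=contrast / cfg.snr,
            )
            for rep in (1, 2):
                pseed = int(rng.integers(2**31))
                profile, truth = generate_vessel_profile(spec, pseed)
                path = profiles_dir / f"{eye_id}_v{v}_rep{rep}.csv"
                rio.write_profile_csv(profile, path)
                written.append(path)
            truth_rows.append(
                {
                    "eye_id": eye_id,
                    "vessel_id": f"v{v}",
                    "raod_um": truth.raod_um,
                    "rald_um": truth.rald_um,
                }
            )
    truth_path = cfg.outdir / "vessel_truth.csv"
    pd.DataFrame(truth_rows).to_csv(truth_path, index=False)
    written.append(truth_path)
    return written


def measure_stage(cfg: RunConfig) -> List[Path]:
    """Measure every simulated profile with the FWHM method."""
    profiles_dir = _require(cfg.outdir / "profiles", "simulate-vessels")
    calib = ScaleCalibration(pixels_per_200um=cfg.pixels_per_200um)
    rows = []
    for path in sorted(profiles_dir.glob("*.csv")):
        eye_id, vessel_id, rep = path.stem.rsplit("_", 2)
        profile = rio.read_profile_csv(path)
        pair, bounds = measure_vessel(profile, calib, cfg.densitometry)
        rows.append(
            {
                "eye_id": eye_id,
                "vessel_id": vessel_id,
                "repeat": int(rep.removeprefix("rep")),
                "raod_um": pair.raod_um,
                "rald_um": pair.rald_um,
                "outer_left_px": bounds.outer_left,
                "inner_left_px": bounds.inner_left,
                "inner_right_px": bounds.inner_right,
                "outer_right_px": bounds.outer_right,
            }
        )
    if not rows:
        raise MissingArtifactError("missing artifact 'profiles/*.csv': nothing to measure")
    out = cfg.outdir / "measurements.csv"
    pd.DataFrame(rows).to_csv(out, index=False)
    return [out]


def morphometry_stage(cfg: RunConfig) -> List[Path]:
    """Aggregate duplicate measurements into per-eye morphometry."""
    meas_path = _require(cfg.outdir / "measurements.csv", "measure")
    meas = pd.read_csv(meas_path)
    eyes = morphometry_table(meas)
    out = cfg.outdir / "eye_morphometry.csv"
    eyes.to_csv(out, index=False)
    summary = (
        eyes[list(EYE_PARAMETERS)]
        .agg(["mean", "std"])
        .T.round(2)
        .rename_axis("parameter")
        .reset_index()
    )
    summary_path = cfg.outdir / "morphometry_summary.csv"
    summary.to_csv(summary_path, index=False)
    return [out, summary_path]


def reliability_stage(cfg: RunConfig) -> List[Path]:
    """Intra-rater ICC, Bland–Altman and CV on the duplicate measurements."""
    meas_path = _require(cfg.outdir / "measurements.csv", "measure")
    meas = pd.read_csv(meas_path)
    meas["uid"] = meas["eye_id"] + "_" + meas["vessel_id"]
    report = {}
    for var in ("raod_um", "rald_um"):
        wide = meas.pivot(index="uid", columns="repeat", values=var)
        matrix = wide.to_numpy()
        first, second = matrix[:, 0], matrix[:, 1]
        icc1 = icc_absolute_agreement(matrix, form="single", alpha=cfg.alpha)
        icc2 = icc_absolute_agreement(matrix, form="average", alpha=cfg.alpha)
        ba = bland_altman(first, second)
        cv = coefficient_of_variation(first, second, alpha=cfg.alpha)
        report[var] = {
            "icc_single": {"icc": icc1.icc, "ci": [icc1.ci_low, icc1.ci_high]},
            "icc_average": {"icc": icc2.icc, "ci": [icc2.ci_low, icc2.ci_high]},
            "bland_altman": dataclasses.asdict(ba),
            "cv_percent": {"cv": cv.cv_percent, "ci": [cv.ci_low, cv.ci_high]},
            "n_vessels": int(matrix.shape[0]),
        }
    out = cfg.outdir / "reliability.json"
    out.write_text(json.dumps(report, indent=2, sort_keys=True))
    return [out]


def simulate_cohort_stage(cfg: RunConfig) -> List[Path]:
    """Draw the synthetic three-group cohort table."""
    if cfg.cohort_spec_path is not None:
        spec = rio.read_cohort_spec(cfg.cohort_spec_path)
        spec = dataclasses.replace(spec, seed=cfg.seed)
    else:
        spec = default_cohort_spec(seed=cfg.seed)
    table = generate_cohort(spec)
    out = cfg.outdir / "cohort.csv"
    rio.write_cohort_csv(table, out)
    return [out]


_COMPARISON_VARIABLES = (
    "age", "bmi", "diabetes_duration", "hba1c",
    "raod_um", "rald_um", "awt_um", "wlr", "wcsa_um2",
    "gcl_central", "gcl_average", "mrnfl_central", "mrnfl_average",
    "prnfl_average", "retina_central", "retina_average",
)
_BINARY_VARIABLES = (
    "gender_male", "smoking", "insulin", "hbp", "cardiovascular", "dyslipidemia",
)


def cohort_stage(cfg: RunConfig) -> List[Path]:
    """Group comparisons, categorical tests, correlations and regressions."""
    cohort_path = _require(cfg.outdir / "cohort.csv", "simulate-cohort")
    table = rio.read_cohort_csv(cohort_path)
    written = []

    comp_rows = []
    for var in _COMPARISON_VARIABLES:
        if var not in table.columns:
            continue
        res = compare_groups(table, var, alpha=cfg.alpha)
        row = {
            "variable": var,
            "test_used": res.test_used,
            "statistic": res.statistic,
            "p_value": res.p_value,
        }
        if res.posthoc:
            for (a, b), p in res.posthoc.items():
                row[f"tukey_{a}_vs_{b}"] = p
        comp_rows.append(row)
    comp_path = cfg.outdir / "group_comparisons.csv"
    pd.DataFrame(comp_rows).to_csv(comp_path, index=False)
    written.append(comp_path)

    cat_rows = []
    for var in _BINARY_VARIABLES:
        if var not in table.columns:
            continue
        sub = table[["group", var]].dropna()
        counts = pd.crosstab(sub["group"], sub[var])
        if counts.shape[1] < 2 or (counts.sum(axis=1) == 0).any():
            continue
        stat, p = chi_square_counts(counts.to_numpy())
        cat_rows.append({"variable": var, "test_used": "chi-square",
                         "statistic": stat, "p_value": p})
    cat_path = cfg.outdir / "categorical_comparisons.csv"
    pd.DataFrame(cat_rows).to_csv(cat_path, index=False)
    written.append(cat_path)

    corr = pearson_grid(table, "gcl", "mrnfl", ("central", "average"))
    corr_path = cfg.outdir / "gcl_mrnfl_correlations.csv"
    corr.to_csv(corr_path, index=False)
    written.append(corr_path)

    reg_rows = []
    for dep in EYE_PARAMETERS:
        for predictor in ("gcl_central", "gcl_average", "mrnfl_average"):
            uni = univariate_regression(table, dep, predictor)
            adj = adjusted_regression(table, dep, predictor, DEFAULT_COVARIATES)
            for res in (uni, adj):
                reg_rows.append(
                    {
                        "dependent": res.dependent,
                        "predictor": res.predictor,
                        "model": res.model,
                        "standardized_coefficient": res.standardized_coefficient,
                        "coefficient": res.coefficient,
                        "ci_low": res.ci_low,
                        "ci_high": res.ci_high,
                        "p_value": res.p_value,
                        "n": res.n,
                    }
                )
    reg_path = cfg.outdir / "regressions.csv"
    pd.DataFrame(reg_rows).to_csv(reg_path, index=False)
    written.append(reg_path)
    return written


_STAGE_FUNCS = {
    "simulate-vessels": simulate_vessels_stage,
    "measure": measure_stage,
    "morphometry": morphometry_stage,
    "reliability": reliability_stage,
    "simulate-cohort": simulate_cohort_stage,
    "cohort": cohort_stage,
}


def run_pipeline(cfg: RunConfig) -> Dict[str, str]:
    """Execute the requested stages in dependency order; return the manifest."""
    cfg.outdir.mkdir(parents=True, exist_ok=True)
    produced: List[Path] = []
    for stage in ALL_STAGES:
        if stage not in cfg.stages:
            continue
        t0 = time.perf_counter()
        produced.extend(_STAGE_FUNCS[stage](cfg))
        log.info("stage %s finished in %.2fs", stage, time.perf_counter() - t0)
    manifest_path = cfg.outdir / "manifest.json"
    manifest = rio.write_manifest(produced, manifest_path, cfg.outdir)
    return manifest
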