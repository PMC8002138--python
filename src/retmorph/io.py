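"""File formats: profile CSV, cohort CSV, spec JSON, image reading, manifests.

All tables are comma-separated UTF-8 with a mandatory header row and ``.``
decimals.  Profiles are two-column CSVs (position_px, intensity); cohort
tables carry one row per eye with a mandatory ``group`` column; phantom and
cohort specs round-trip through JSON.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from pathlib import Path
from typing import Dict, Iterable, Union

import numpy as np
import pandas as pd

from .densitometry import IntensityProfile
from .synthetic import CohortSpec, VesselPhantomSpec

PathLike = Union[str, Path]

PROFILE_COLUMNS = ("position_px", "intensity")


def write_profile_csv(profile: IntensityProfile, path: PathLike) -> None:
    df = pd.DataFrame(
        {"position_px": profile.positions, "intensity": profile.intensities}
    )
    df.to_csv(path, index=False)


def read_profile_csv(path: PathLike) -> IntensityProfile:
    df = pd.read_csv(path)
    missing = set(PROFILE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"profile CSV {path} missing columns: {sorted(missing)}")
    return IntensityProfile(
        positions=df["position_px"].to_numpy(dtype=float),
        intensities=df["intensity"].to_numpy(dtype=float),
    )


def read_image(path: PathLike) -> np.ndarray:
    """Read a PNG/TIFF as a 2-D grayscale float array (RGB averaged)."""
    import imageio.v3 as iio

    img = np.asarray(iio.imread(path), dtype=float)
    if img.ndim == 3:
        img = img[..., :3].mean(axis=2)
    if img.ndim != 2:
        raise ValueError(f"image {path} is not 2-D grayscale")
    return img


_STRING_COLUMNS = {"group", "eye_id", "vessel_id"}


def read_cohort_csv(path: PathLike) -> pd.DataFrame:
    """Read an eye-level cohort table; unknown columns are preserved.

    The ``group`` column is required; every other column is parsed as a
    number, and rows that fail to parse are reported with their line numbers
    (1-based, counting the header as line 1).
    """
    df = pd.read_csv(path, dtype=str, keep_default_na=True)
    if "group" not in df.columns:
        raise ValueError("cohort CSV schema error: missing required column 'group'")
    out = {}
    bad: Dict[str, list] = {}
    for col in df.columns:
        if col in _STRING_COLUMNS:
            out[col] = df[col]
            continue
        raw = df[col]
        parsed = pd.to_numeric(raw, errors="coerce")
        failed = raw.notna() & parsed.isna()
        if failed.any():
            bad[col] = [int(i) + 2 for i in df.index[failed]]
        out[col] = parsed
    if bad:
        detail = "; ".join(f"column {c!r} at lines {lines}" for c, lines in bad.items())
        raise ValueError(f"malformed rows in cohort CSV: {detail}")
    return pd.DataFrame(out)


def write_cohort_csv(table: pd.DataFrame, path: PathLike) -> None:
    if "group" not in table.columns:
        raise ValueError("cohort table must carry a 'group' column")
    table.to_csv(path, index=False)


def _spec_to_jsonable(spec) -> dict:
    d = dataclasses.asdict(spec)

    def convert(obj):
        if isinstance(obj, dict):
            return {k: convert(v) for k, v in obj.items()}
        if isinstance(obj, (list, tuple)):
            return [convert(v) for v in obj]
        if isinstance(obj, (np.floating, np.integer)):
            return obj.item()
        return obj

    return convert(d)


def write_phantom_spec(spec: VesselPhantomSpec, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_spec_to_jsonable(spec), indent=2))


def read_phantom_spec(path: PathLike) -> VesselPhantomSpec:
    return VesselPhantomSpec(**json.loads(Path(path).read_text()))


def write_cohort_spec(spec: CohortSpec, path: PathLike) -> None:
    Path(path).write_text(json.dumps(_spec_to_jsonable(spec), indent=2))


def read_cohort_spec(path: PathLike) -> CohortSpec:
    d = json.loads(Path(path).read_text())
    d["groups"] = tuple((g, int(n)) for g, n in d["groups"])
    d["correlations"] = tuple(
        (a, b, g, float(r)) for a, b, g, r in d.get("correlations", [])
    )
    return CohortSpec(**d)


def file_sha256(path: PathLike) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def write_manifest(paths: Iterable[PathLike], out: PathLike, root: PathLike) -> dict:
    """Write a JSON manifest of produced files with content hashes."""
    root = Path(root)
    manifest = {
        str(Path(p).relative_to(root)): file_sha256(p)
        for p in sorted(Path(p) for p in paths)
    }
    Path(out).write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
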