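"""Derived arterial wall parameters and per-eye aggregation.

From the outer diameter (RAOD) and lumen diameter (RALD) of an artery:

    AWT  = (RAOD - RALD) / 2          arterial wall thickness, µm
    WLR  = (RAOD - RALD) / RALD       wall-to-lumen ratio, dimensionless
    WCSA = (π/4) (RAOD² - RALD²)      wall cross-sectional area, µm²

Each vessel is measured twice and the duplicate diameters averaged; the
four largest arteries of an eye are then averaged into a single value set
per eye for RAOD, RALD, AWT, WLR and WCSA.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from .densitometry import DiameterPair

EYE_PARAMETERS = ("raod_um", "rald_um", "awt_um", "wlr", "wcsa_um2")


def _check_pair(raod_um: float, rald_um: float) -> None:
    if not (raod_um > rald_um > 0):
        raise ValueError(
            f"require raod_um > rald_um > 0, got ({raod_um}, {rald_um})"
        )


def compute_awt(raod_um: float, rald_um: float) -> float:
    """Arterial wall thickness (RAOD - RALD)/2 in µm."""
    _check_pair(raod_um, rald_um)
    return (raod_um - rald_um) / 2.0


def compute_wlr(raod_um: float, rald_um: float) -> float:
    """Wall-to-lumen ratio (RAOD - RALD)/RALD."""
    _check_pair(raod_um, rald_um)
    return (raod_um - rald_um) / rald_um


def compute_wcsa(raod_um: float, rald_um: float) -> float:
    """Wall cross-sectional area (π/4)(RAOD² - RALD²) in µm²."""
    _check_pair(raod_um, rald_um)
    return math.pi / 4.0 * (raod_um**2 - rald_um**2)


def average_repeats(repeat_a: DiameterPair, repeat_b: DiameterPair) -> DiameterPair:
    """Component-wise mean of two duplicate diameter measurements."""
    return DiameterPair(
        raod_um=(repeat_a.raod_um + repeat_b.raod_um) / 2.0,
        rald_um=(repeat_a.rald_um + repeat_b.rald_um) / 2.0,
    )


@dataclass(frozen=True)
class VesselMeasurement:
    """One vessel's duplicate measurements and their average."""

    vessel_id: str
    repeat_a: DiameterPair
    repeat_b: DiameterPair

    @property
    def averaged(self) -> DiameterPair:
        return average_repeats(self.repeat_a, self.repeat_b)


@dataclass(frozen=True)
class EyeMorphometry:
    """Per-eye averages of the five arterial morphometry parameters."""

    eye_id: str
    raod_um: float
    rald_um: float
    awt_um: float
    wlr: float
    wcsa_um2: float

    def __post_init__(self) -> None:
        if not (self.awt_um > 0 and self.wlr > 0 and self.wcsa_um2 > 0):
            raise ValueError("derived parameters must be positive")


def aggregate_eye(
    vessels: Sequence[VesselMeasurement],
    n_largest: int = 4,
    eye_id: str = "",
    from_eye_means: bool = False,
) -> EyeMorphometry:
    """Aggregate a list of vessels into one morphometry value set per eye.

    The ``n_largest`` vessels by duplicate-averaged RAOD are selected (all if
    fewer; ties broken by input order).  By default AWT/WLR/WCSA are computed
    per vessel from the averaged diameters and then averaged across the
    selected vessels; with ``from_eye_means`` they are instead recomputed
    from the per-eye mean diameters (equivalent for AWT, not for WLR/WCSA).
    """
    if len(vessels) == 0:
        raise ValueError("aggregate_eye requires at least one vessel")
    if n_largest < 1:
        raise ValueError("n_largest must be >= 1")
    ranked = sorted(
        range(len(vessels)),
        key=lambda i: (-vessels[i].averaged.raod_um, i),
    )
    chosen = [vessels[i] for i in sorted(ranked[:n_largest])]
    pairs = [v.averaged for v in chosen]
    raod = sum(p.raod_um for p in pairs) / len(pairs)
    rald = sum(p.rald_um for p in pairs) / len(pairs)
    if from_eye_means:
        awt = compute_awt(raod, rald)
        wlr = compute_wlr(raod, rald)
        wcsa = compute_wcsa(raod, rald)
    else:
        awt = sum(compute_awt(p.raod_um, p.rald_um) for p in pairs) / len(pairs)
        wlr = sum(compute_wlr(p.raod_um, p.rald_um) for p in pairs) / len(pairs)
        wcsa = sum(compute_wcsa(p.raod_um, p.rald_um) for p in pairs) / len(pairs)
    return EyeMorphometry(
        eye_id=eye_id, raod_um=raod, rald_um=rald, awt_um=awt, wlr=wlr, wcsa_um2=wcsa
    )


def morphometry_table(
    repeats: pd.DataFrame,
    n_largest: int = 4,
    from_eye_means: bool = False,
) -> pd.DataFrame:
    """Per-eye morphometry from a long table of repeated vessel measurements.

    ``repeats`` needs columns eye_id, vessel_id, repeat, raod_um, rald_um
    with exactly two repeats per vessel.  Returns one row per eye with the
    five parameters of :data:`EYE_PARAMETERS`.
    """
    required = {"eye_id", "vessel_id", "repeat", "raod_um", "rald_um"}
    missing = required - set(repeats.columns)
    if missing:
        raise ValueError(f"missing columns: {sorted(missing)}")
    rows = []
    for eye_id, eye_df in repeats.groupby("eye_id", sort=True):
        vessels = []
        for vessel_id, v_df in eye_df.groupby("vessel_id", sort=True):
            v_df = v_df.sort_values("repeat")
            if len(v_df) != 2:
                raise ValueError(
                    f"vessel {vessel_id!r} of eye {eye_id!r} has "
                    f"{len(v_df)} repeats, expected 2"
                )
            a, b = (
                DiameterPair(raod_um=r.raod_um, rald_um=r.rald_um)
                for r in v_df.itertuples()
            )
            vessels.append(VesselMeasurement(str(vessel_id), a, b))
        eye = aggregate_eye(
            vessels, n_largest=n_largest, eye_id=str(eye_id),
            from_eye_means=from_eye_means,
        )
        rows.append(
            {"eye_id": eye.eye_id, **{p: getattr(eye, p) for p in EYE_PARAMETERS}}
        )
    return pd.DataFrame(rows)
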