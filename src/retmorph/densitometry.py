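"""FWHM micro-densitometry of vessel cross-section intensity profiles.

A retinal artery crossed perpendicularly by a sampling line produces an
intensity profile with two wall lobes (the near and far vessel wall) on
either side of the lumen.  Each wall boundary is localized at half-maximum:
the sub-pixel position where the profile crosses the midpoint between the
lobe's local background and its extremum.  The outer diameter (RAOD) is the
distance between the outer half-max crossings of the two lobes, the lumen
diameter (RALD) the distance between the inner crossings; both are converted
to micrometres with a scale-bar calibration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Tuple

import numpy as np
from scipy import ndimage, signal


class DensitometryError(ValueError):
    """Base class for measurement failures on a profile."""


class NoVesselError(DensitometryError):
    """Fewer than two qualifying wall lobes were found."""


class NoContrastError(DensitometryError):
    """The profile is flat (saturated or constant)."""


class OpenLobeError(DensitometryError):
    """A lobe's half level is never crossed before the profile ends."""


class InconsistentBoundariesError(DensitometryError):
    """The four boundary positions are not strictly ordered."""


@dataclass(frozen=True)
class IntensityProfile:
    """1-D intensity samples along a line, in pixel coordinates.

    ``positions`` must be strictly increasing with uniform spacing; sample i
    of a profile extracted from an image sits at position i along the line
    (0-based, continuous pixel units).
    """

    positions: np.ndarray
    intensities: np.ndarray

    def __post_init__(self) -> None:
        pos = np.asarray(self.positions, dtype=float)
        inten = np.asarray(self.intensities, dtype=float)
        object.__setattr__(self, "positions", pos)
        object.__setattr__(self, "intensities", inten)
        if pos.ndim != 1 or inten.ndim != 1 or pos.size != inten.size:
            raise ValueError("positions and intensities must be 1-D and equally long")
        if pos.size < 7:
            raise ValueError("profile needs at least 7 samples")
        if not (np.all(np.isfinite(pos)) and np.all(np.isfinite(inten))):
            raise ValueError("profile contains non-finite values")
        steps = np.diff(pos)
        if np.any(steps <= 0):
            raise ValueError("positions must be strictly increasing")
        step = steps[0]
        if np.any(np.abs(steps - step) > 1e-9 * max(abs(step), 1.0)):
            raise ValueError("positions must be uniformly spaced")

    @property
    def step(self) -> float:
        return float(self.positions[1] - self.positions[0])

    def __len__(self) -> int:
        return int(self.positions.size)


@dataclass(frozen=True)
class ScaleCalibration:
    """Pixel length of the 200 µm scale bar printed on the OCT scan."""

    pixels_per_200um: float

    def __post_init__(self) -> None:
        if not (self.pixels_per_200um > 0):
            raise ValueError("pixels_per_200um must be positive")

    @property
    def um_per_px(self) -> float:
        return 200.0 / self.pixels_per_200um


def calibrate_scale(pixel_length_of_200um: float) -> ScaleCalibration:
    """Build a calibration from the measured pixel length of the 200 µm bar."""
    return ScaleCalibration(pixels_per_200um=float(pixel_length_of_200um))


@dataclass(frozen=True)
class DensitometryConfig:
    """Tunable parameters of the FWHM measurement.

    polarity
        'walls-bright' if the walls are local intensity maxima,
        'walls-dark' if minima, 'auto' to decide from the profile itself.
    smoothing_window_px
        Odd width of an optional centred moving average applied before lobe
        detection; 1 disables smoothing. Crossings are computed on the
        smoothed signal.
    baseline_fraction
        Fraction of samples at each profile end used to estimate the local
        background of the adjacent lobe.
    min_lumen_px
        Minimum separation (px) between the two lobe extrema.
    """

    polarity: str = "auto"
    smoothing_window_px: int = 1
    baseline_fraction: float = 0.10
    min_lumen_px: float = 5.0

    def __post_init__(self) -> None:
        if self.polarity not in ("auto", "walls-bright", "walls-dark"):
            raise ValueError(f"unknown polarity {self.polarity!r}")
        if self.smoothing_window_px < 1 or self.smoothing_window_px % 2 == 0:
            raise ValueError("smoothing_window_px must be an odd integer >= 1")
        if not (0 < self.baseline_fraction <= 0.25):
            raise ValueError("baseline_fraction must lie in (0, 0.25]")
        if self.min_lumen_px <= 0:
            raise ValueError("min_lumen_px must be positive")


@dataclass
class WallLobe:
    """One vessel-wall lobe on the polarity-normalized profile.

    ``orientation`` is +1 when the lobe is a maximum of the raw intensities
    and -1 when the raw profile had dark walls and was negated; crossings
    and levels always refer to the normalized (walls-up) signal.
    """

    extremum_position: float
    extremum_value: float
    baseline_value: float
    half_level: float
    left_crossing: Optional[float] = None
    right_crossing: Optional[float] = None
    orientation: int = 1

    def __post_init__(self) -> None:
        if not (self.baseline_value < self.half_level < self.extremum_value):
            raise ValueError("half_level must lie strictly between baseline and extremum")
        if self.left_crossing is not None and self.right_crossing is not None:
            if not (self.left_crossing < self.extremum_position < self.right_crossing):
                raise ValueError("crossings must bracket the extremum")


@dataclass(frozen=True)
class VesselBoundaryEstimate:
    """Four ordered sub-pixel boundary positions along the profile (px)."""

    outer_left: float
    inner_left: float
    inner_right: float
    outer_right: float

    def __post_init__(self) -> None:
        b = (self.outer_left, self.inner_left, self.inner_right, self.outer_right)
        if not all(x < y for x, y in zip(b, b[1:])):
            raise InconsistentBoundariesError(
                f"inconsistent boundaries: expected outer_left < inner_left < "
                f"inner_right < outer_right, got {b}"
            )


@dataclass(frozen=True)
class DiameterPair:
    """Calibrated outer and lumen diameters of one vessel (µm)."""

    raod_um: float
    rald_um: float

    def __post_init__(self) -> None:
        if not (self.raod_um > self.rald_um > 0):
            raise ValueError(
                f"require raod_um > rald_um > 0, got ({self.raod_um}, {self.rald_um})"
            )


def extract_profile(
    image: np.ndarray,
    line_start: Tuple[float, float],
    line_end: Tuple[float, float],
    samples_per_px: float = 1.0,
) -> IntensityProfile:
    """Sample a grayscale image along a line segment by bilinear interpolation.

    ``line_start``/``line_end`` are (row, col) coordinates; positions of the
    returned profile are distances along the line in pixels.
    """
    img = np.asarray(image, dtype=float)
    if img.ndim != 2:
        raise ValueError("image must be a 2-D grayscale array")
    if samples_per_px <= 0:
        raise ValueError("samples_per_px must be positive")
    r0, c0 = map(float, line_start)
    r1, c1 = map(float, line_end)
    for r, c in ((r0, c0), (r1, c1)):
        if not (0 <= r <= img.shape[0] - 1 and 0 <= c <= img.shape[1] - 1):
            raise ValueError(f"line endpoint ({r}, {c}) outside image bounds")
    length = float(np.hypot(r1 - r0, c1 - c0))
    if length == 0:
        raise ValueError("zero-length sampling line")
    n = int(np.floor(length * samples_per_px)) + 1
    if n < 7:
        n = 7
    positions = np.linspace(0.0, length, n)
    t = positions / length
    rows = r0 + t * (r1 - r0)
    cols = c0 + t * (c1 - c0)
    values = ndimage.map_coordinates(img, [rows, cols], order=1, mode="nearest")
    return IntensityProfile(positions=positions, intensities=values)


def _smooth(intensities: np.ndarray, window: int) -> np.ndarray:
    if window <= 1:
        return intensities
    half = window // 2
    padded = np.pad(intensities, half, mode="reflect")
    kernel = np.full(window, 1.0 / window)
    return np.convolve(padded, kernel, mode="valid")


def _normalized_signal(
    profile: IntensityProfile, config: DensitometryConfig
) -> Tuple[np.ndarray, int]:
    """Smooth and flip the profile so that walls are maxima.

    Returns the walls-up signal and the orientation sign applied (+1/-1).
    """
    s = _smooth(profile.intensities, config.smoothing_window_px)
    if np.ptp(s) == 0:
        raise NoContrastError("no contrast: profile is flat")
    if config.polarity == "walls-bright":
        sign = 1
    elif config.polarity == "walls-dark":
        sign = -1
    else:
        n = s.size
        n_end = max(1, int(round(config.baseline_fraction * n)))
        ends = np.concatenate([s[:n_end], s[-n_end:]])
        lo, hi = int(round(0.25 * n)), int(round(0.75 * n))
        central = s[lo:hi]
        med_c, med_e = float(np.median(central)), float(np.median(ends))
        if med_c > med_e:
            sign = 1
        elif med_c < med_e:
            sign = -1
        else:
            # Equal medians (e.g. lumen at background level): decide by which
            # side of the background the larger excursion lies on.
            sign = 1 if (s.max() - med_e) >= (med_e - s.min()) else -1
    return sign * s, sign


def detect_wall_lobes(
    profile: IntensityProfile, config: DensitometryConfig = DensitometryConfig()
) -> Tuple[WallLobe, WallLobe]:
    """Locate the two vessel-wall lobes of a cross-section profile.

    The two most prominent peaks of the walls-up signal whose extrema are at
    least ``min_lumen_px`` apart are returned, left lobe first, with their
    half-max crossings already computed.  Ties in prominence are broken in
    favour of the pair whose midpoint is closest to the profile centre.
    """
    s, sign = _normalized_signal(profile, config)
    pos = profile.positions
    step = profile.step

    prom_floor = 0.05 * np.ptp(s)
    peaks, props = signal.find_peaks(s, prominence=prom_floor)
    if peaks.size < 2:
        raise NoVesselError("no vessel found: fewer than two wall lobes")
    prominences = props["prominences"]

    # Keep the best-separated pair by total prominence; midpoint-to-centre
    # distance breaks ties.
    order = np.argsort(prominences)[::-1][: min(peaks.size, 8)]
    center = 0.5 * (pos[0] + pos[-1])
    best = None
    for ii in range(order.size):
        for jj in range(ii + 1, order.size):
            i, j = order[ii], order[jj]
            if abs(pos[peaks[i]] - pos[peaks[j]]) < config.min_lumen_px:
                continue
            score = prominences[i] + prominences[j]
            mid_dist = abs(0.5 * (pos[peaks[i]] + pos[peaks[j]]) - center)
            key = (-score, mid_dist)
            if best is None or key < best[0]:
                best = (key, (min(peaks[i], peaks[j]), max(peaks[i], peaks[j])))
    if best is None:
        raise NoVesselError("no vessel found: lobes closer than min_lumen_px")
    left_idx, right_idx = best[1]

    n = s.size
    n_base = max(1, int(round(config.baseline_fraction * n)))
    lobes = []
    for idx, tail in ((left_idx, s[:n_base]), (right_idx, s[-n_base:])):
        baseline = float(np.median(tail))
        extremum = float(s[idx])
        if extremum <= baseline:
            raise NoVesselError("no vessel found: lobe does not rise above baseline")
        lobe = WallLobe(
            extremum_position=float(pos[idx]),
            extremum_value=extremum,
            baseline_value=baseline,
            half_level=baseline + 0.5 * (extremum - baseline),
            orientation=sign,
        )
        left_c, right_c = half_max_crossings(profile, lobe, config)
        lobe.left_crossing = left_c
        lobe.right_crossing = right_c
        lobes.append(lobe)
    return lobes[0], lobes[1]


def half_max_crossings(
    profile: IntensityProfile,
    lobe: WallLobe,
    config: DensitometryConfig = DensitometryConfig(),
) -> Tuple[float, float]:
    """Sub-pixel positions where the profile crosses the lobe's half level.

    Walking outward from the extremum on each side, the first sample interval
    straddling ``half_level`` is located and the crossing found by linear
    interpolation between the two straddling samples.
    """
    s = lobe.orientation * _smooth(profile.intensities, config.smoothing_window_px)
    pos = profile.positions
    step = profile.step
    idx = int(round((lobe.extremum_position - pos[0]) / step))
    idx = min(max(idx, 0), s.size - 1)
    half = lobe.half_level

    def walk(direction: int) -> float:
        j = idx
        while 0 <= j + direction < s.size and s[j + direction] >= half:
            j += direction
        nxt = j + direction
        if nxt < 0 or nxt >= s.size:
            raise OpenLobeError(
                "open lobe: half level never crossed before the profile ends"
            )
        # s[j] >= half > s[nxt]
        frac = (s[j] - half) / (s[j] - s[nxt])
        return float(pos[j] + frac * direction * step)

    return walk(-1), walk(+1)


def measure_vessel(
    profile: IntensityProfile,
    calib: ScaleCalibration,
    config: DensitometryConfig = DensitometryConfig(),
) -> Tuple[DiameterPair, VesselBoundaryEstimate]:
    """Measure calibrated outer and lumen diameters from one profile.

    Outer diameter spans the outer half-max crossings of the two wall lobes;
    lumen diameter spans the inner crossings.
    """
    left, right = detect_wall_lobes(profile, config)
    boundaries = VesselBoundaryEstimate(
        outer_left=left.left_crossing,
        inner_left=left.right_crossing,
        inner_right=right.left_crossing,
        outer_right=right.right_crossing,
    )
    um = calib.um_per_px
    pair = DiameterPair(
        raod_um=(boundaries.outer_right - boundaries.outer_left) * um,
        rald_um=(boundaries.inner_right - boundaries.inner_left) * um,
    )
    return pair, boundaries
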