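"""FWHM measurement: profile extraction, lobe detection, sub-pixel crossings."""

import numpy as np
import pytest

import retmorph as rm
from retmorph.densitometry import (
    NoVesselError,
    OpenLobeError,
    detect_wall_lobes,
    half_max_crossings,
)


class TestExtractProfile:
    def test_constant_image_gives_constant_profile(self):
        img = np.full((40, 60), 7.5)
        p = rm.extract_profile(img, (5, 5), (30, 50))
        np.testing.assert_allclose(p.intensities, 7.5, rtol=1e-12)

    def test_vertical_line_reproduces_image_column(self):
        rng = np.random.default_rng(0)
        img = rng.uniform(0, 255, (50, 20))
        p = rm.extract_profile(img, (0, 7), (49, 7))
        np.testing.assert_allclose(p.intensities, img[:, 7], atol=1e-12)

    def test_diagonal_line_on_ramp_has_directional_derivative_slope(self):
        """On I(r,c) = 3r + 5c, the profile along direction (dr,dc)/L is
        linear with slope (3*dr + 5*dc)/L per pixel of arc length."""
        rows, cols = np.mgrid[0:40, 0:40]
        img = 3.0 * rows + 5.0 * cols
        start, end = (2.0, 3.0), (32.0, 23.0)
        dr, dc = end[0] - start[0], end[1] - start[1]
        length = np.hypot(dr, dc)
        p = rm.extract_profile(img, start, end)
        slopes = np.diff(p.intensities) / np.diff(p.positions)
        np.testing.assert_allclose(slopes, (3 * dr + 5 * dc) / length, rtol=1e-9)

    def test_bad_lines_rejected(self):
        img = np.zeros((10, 10))
        with pytest.raises(ValueError):
            rm.extract_profile(img, (2, 2), (2, 2))
        with pytest.raises(ValueError):
            rm.extract_profile(img, (0, 0), (20, 5))


class TestCalibrateScale:
    @pytest.mark.parametrize("px,expected", [(100.0, 2.0), (80.0, 2.5), (200.0, 1.0)])
    def test_um_per_px(self, px, expected):
        assert rm.calibrate_scale(px).um_per_px == pytest.approx(expected)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            rm.calibrate_scale(0.0)


class TestDetectWallLobes:
    def test_lobe_extrema_near_wall_annulus_centers(self, control_phantom_spec):
        spec = control_phantom_spec
        profile, _ = rm.generate_vessel_profile(spec, seed=4)
        left, right = detect_wall_lobes(
            profile, rm.DensitometryConfig(polarity="walls-bright")
        )
        center = (len(profile) - 1) / 2
        annulus_center_um = (spec.raod_um + spec.rald_um) / 4
        assert left.extremum_position == pytest.approx(
            center - annulus_center_um, abs=2.0
        )
        assert right.extremum_position == pytest.approx(
            center + annulus_center_um, abs=2.0
        )

    def test_inverted_profile_with_auto_polarity_gives_identical_lobes(
        self, control_phantom_spec
    ):
        profile, _ = rm.generate_vessel_profile(control_phantom_spec, seed=4)
        inverted = rm.IntensityProfile(
            positions=profile.positions, intensities=255.0 - profile.intensities
        )
        auto = rm.DensitometryConfig(polarity="auto")
        l1, r1 = detect_wall_lobes(profile, auto)
        l2, r2 = detect_wall_lobes(inverted, auto)
        assert l1.left_crossing == pytest.approx(l2.left_crossing, abs=1e-9)
        assert r1.right_crossing == pytest.approx(r2.right_crossing, abs=1e-9)
        assert l2.orientation == -1

    def test_monotone_ramp_has_no_vessel(self):
        ramp = rm.IntensityProfile(
            positions=np.arange(100.0), intensities=np.linspace(0, 50, 100)
        )
        with pytest.raises(NoVesselError):
            detect_wall_lobes(ramp)

    def test_flat_profile_has_no_contrast(self):
        flat = rm.IntensityProfile(
            positions=np.arange(50.0), intensities=np.full(50, 9.0)
        )
        with pytest.raises(rm.DensitometryError, match="contrast"):
            detect_wall_lobes(flat)


class TestHalfMaxCrossings:
    def test_triangle_lobe_crossings_by_linear_interpolation(self):
        intens = np.zeros(9)
        intens[4] = 1.0
        intens[3] = intens[5] = 0.0
        profile = rm.IntensityProfile(positions=np.arange(9.0), intensities=intens)
        lobe = rm.WallLobe(
            extremum_position=4.0, extremum_value=1.0, baseline_value=0.0,
            half_level=0.5,
        )
        left, right = half_max_crossings(profile, lobe)
        assert left == pytest.approx(3.5)
        assert right == pytest.approx(4.5)

    def test_gaussian_lobe_crossings_at_fwhm(self):
        """A Gaussian lobe of scale σ crosses half maximum at ±σ√(2 ln 2)."""
        sigma = 8.0
        x = np.arange(201.0)
        intens = np.exp(-0.5 * ((x - 100.0) / sigma) ** 2)
        profile = rm.IntensityProfile(positions=x, intensities=intens)
        lobe = rm.WallLobe(
            extremum_position=100.0, extremum_value=1.0, baseline_value=0.0,
            half_level=0.5,
        )
        left, right = half_max_crossings(profile, lobe)
        hwhm = sigma * np.sqrt(2 * np.log(2))
        assert left == pytest.approx(100.0 - hwhm, abs=1.0)
        assert right == pytest.approx(100.0 + hwhm, abs=1.0)

    def test_truncated_lobe_is_open(self):
        x = np.arange(10.0)
        intens = np.linspace(1.0, 0.0, 10)  # lobe peak at the profile edge
        profile = rm.IntensityProfile(positions=x, intensities=intens)
        lobe = rm.WallLobe(
            extremum_position=0.0, extremum_value=1.0, baseline_value=0.0,
            half_level=0.5,
        )
        with pytest.raises(OpenLobeError):
            half_max_crossings(profile, lobe)


class TestMeasureVessel:
    def test_clean_phantom_measured_within_one_step(
        self, clean_phantom, unit_calibration, walls_bright_config
    ):
        _, profile, truth = clean_phantom
        pair, bounds = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
        assert pair.raod_um == pytest.approx(truth.raod_um, abs=1.0)
        assert pair.rald_um == pytest.approx(truth.rald_um, abs=1.0)
        assert bounds.outer_left < bounds.inner_left < bounds.inner_right < bounds.outer_right

    def test_blurred_noisy_recovery_mean_abs_error_below_1um(
        self, control_phantom_spec, unit_calibration, walls_bright_config
    ):
        """Monte-Carlo recovery: 100 noise seeds, PSF σ = 4 µm, SNR 33."""
        errs_raod, errs_rald = [], []
        for seed in range(100):
            profile, truth = rm.generate_vessel_profile(control_phantom_spec, seed)
            pair, _ = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
            errs_raod.append(abs(pair.raod_um - truth.raod_um))
            errs_rald.append(abs(pair.rald_um - truth.rald_um))
        assert np.mean(errs_raod) <= 1.0
        assert np.mean(errs_rald) <= 1.0

    def test_ramp_error_propagates(self, unit_calibration):
        ramp = rm.IntensityProfile(
            positions=np.arange(100.0), intensities=np.linspace(0, 50, 100)
        )
        with pytest.raises(rm.DensitometryError):
            rm.measure_vessel(ramp, unit_calibration)

    def test_affine_intensity_invariance(
        self, control_phantom_spec, unit_calibration, walls_bright_config
    ):
        """Boundary positions are unchanged under I -> aI + b (a > 0)."""
        profile, _ = rm.generate_vessel_profile(control_phantom_spec, seed=5)
        _, ref = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
        rng = np.random.default_rng(0)
        for _ in range(50):
            a = rng.uniform(0.05, 20.0)
            b = rng.uniform(-100.0, 100.0)
            mapped = rm.IntensityProfile(
                positions=profile.positions, intensities=a * profile.intensities + b
            )
            _, got = rm.measure_vessel(mapped, unit_calibration, walls_bright_config)
            for attr in ("outer_left", "inner_left", "inner_right", "outer_right"):
                assert getattr(got, attr) == pytest.approx(
                    getattr(ref, attr), abs=1e-9
                )

    def test_translation_equivariance(
        self, control_phantom_spec, unit_calibration, walls_bright_config
    ):
        profile, _ = rm.generate_vessel_profile(control_phantom_spec, seed=6)
        shift = 17.0
        shifted = rm.IntensityProfile(
            positions=profile.positions + shift, intensities=profile.intensities
        )
        p1, b1 = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
        p2, b2 = rm.measure_vessel(shifted, unit_calibration, walls_bright_config)
        assert p2.raod_um == pytest.approx(p1.raod_um, abs=1e-9)
        assert p2.rald_um == pytest.approx(p1.rald_um, abs=1e-9)
        assert b2.outer_left == pytest.approx(b1.outer_left + shift, abs=1e-9)

    def test_scale_linearity(self, control_phantom_spec, walls_bright_config):
        """Halving pixels_per_200um doubles the reported µm diameters."""
        profile, _ = rm.generate_vessel_profile(control_phantom_spec, seed=7)
        p1, _ = rm.measure_vessel(
            profile, rm.calibrate_scale(200.0), walls_bright_config
        )
        p2, _ = rm.measure_vessel(
            profile, rm.calibrate_scale(100.0), walls_bright_config
        )
        assert p2.raod_um == pytest.approx(2 * p1.raod_um, rel=1e-12)
        assert p2.rald_um == pytest.approx(2 * p1.rald_um, rel=1e-12)

    @pytest.mark.parametrize("psf", [0.0, 2.0, 4.0])
    def test_psf_bias_bounded_by_one_step_without_noise(
        self, psf, unit_calibration, walls_bright_config
    ):
        """Half-max of a symmetric blurred step stays at the step while the
        two wall edges' blur does not interact (psf up to about a quarter of
        the wall thickness)."""
        spec = rm.VesselPhantomSpec(psf_sigma_um=psf, noise_sd=0.0)
        profile, truth = rm.generate_vessel_profile(spec, seed=0)
        pair, _ = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
        assert abs(pair.raod_um - truth.raod_um) <= spec.um_per_px
        assert abs(pair.rald_um - truth.rald_um) <= spec.um_per_px

    def test_heavy_blur_biases_diameters_outward(
        self, unit_calibration, walls_bright_config
    ):
        """When psf approaches half the wall thickness the lobe no longer
        reaches full wall intensity, so its half level drops below the step
        midpoint and the outer diameter is overestimated — a documented
        limitation of lobe-relative half-maximum localization."""
        spec = rm.VesselPhantomSpec(psf_sigma_um=8.0, noise_sd=0.0)
        profile, truth = rm.generate_vessel_profile(spec, seed=0)
        pair, _ = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
        assert pair.raod_um > truth.raod_um + 1.0
        assert pair.rald_um < truth.rald_um - 1.0

    def test_raod_exceeds_rald_on_success(
        self, unit_calibration, walls_bright_config
    ):
        rng = np.random.default_rng(1)
        for seed in range(20):
            raod = rng.uniform(110, 150)
            rald = raod - rng.uniform(20, 45)
            spec = rm.VesselPhantomSpec(
                raod_um=raod, rald_um=rald, psf_sigma_um=3.0, noise_sd=3.0
            )
            profile, _ = rm.generate_vessel_profile(spec, seed)
            pair, _ = rm.measure_vessel(profile, unit_calibration, walls_bright_config)
            assert pair.raod_um > pair.rald_um
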