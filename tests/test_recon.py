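"""Delays, weights, GB-BP summation, B-mode baseline, envelope, scan conversion."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gbbp import (
    CartesianGrid,
    GaussianBeamParams,
    InvalidParameterError,
    PolarGrid,
    PositionLimits,
    ReconImage,
    ScanGeometry,
    Sinogram,
    delay_pa,
    delay_us,
    envelope,
    gaussian_weight,
    reconstruct_bmode,
    reconstruct_gbbp,
    scan_convert,
)

V = 1.5  # mm/us


def _single_angle_geom(n_samples=2000, fs=200.0):
    return ScanGeometry(
        angles_rad=np.array([0.0]), virtual_radius_mm=0.0,
        imaging_radius_mm=12.5, speed_of_sound_mm_us=V,
        sampling_rate_mhz=fs, n_samples=n_samples,
    )


class TestDelays:
    def test_on_axis_beyond_focus(self, beam):
        assert delay_pa(3.0, 0.0, beam, V) == pytest.approx(10.0 / 1.5)

    def test_on_axis_before_focus_arrives_earlier(self, beam):
        assert delay_pa(-2.0, 0.0, beam, V) == pytest.approx(5.0 / 1.5)

    def test_a_zero_collapses_to_focal_time(self, beam):
        # the radial term enters multiplied by a, so at a=0 any b gives F/v
        assert delay_pa(0.0, 5.0, beam, V) == pytest.approx(7.0 / 1.5)
        assert delay_us(0.0, 3.0, beam, V) == pytest.approx(2 * 7.0 / 1.5)

    @settings(max_examples=100, deadline=None, derandomize=True)
    @given(a=st.floats(-6, 5), b=st.floats(0, 12))
    def test_two_way_is_exactly_twice_one_way(self, beam, a, b):
        assert delay_us(a, b, beam, V) == 2.0 * delay_pa(a, b, beam, V)


class TestGaussianWeight:
    def test_unity_at_focus(self, beam):
        lim = PositionLimits(-7.0, 5.5, -12.5, 12.5)
        assert gaussian_weight(0.0, 0.0, beam, lim) == 1.0

    def test_half_at_one_semi_focal_depth_on_axis(self, beam):
        z0 = beam.semi_focal_depth_mm
        assert gaussian_weight(z0, 0.0, beam) == pytest.approx(0.5)

    def test_zero_outside_position_limits(self, beam):
        lim = PositionLimits(-7.0, 5.5, -12.5, 12.5)
        assert gaussian_weight(5.6, 0.0, beam, lim) == 0.0
        assert gaussian_weight(-7.1, 0.0, beam, lim) == 0.0
        assert gaussian_weight(0.0, 12.6, beam, lim) == 0.0

    def test_lateral_profile_is_beam_intensity(self, beam):
        """At the focal plane the weight falls to 1/e at b = w0/sqrt(2),
        the Gaussian-beam intensity profile exp(-2 b^2/w0^2)."""
        b = beam.waist_mm / np.sqrt(2.0)
        assert gaussian_weight(0.0, b, beam) == pytest.approx(np.exp(-1.0))

    def test_alternative_exponent_convention(self, beam):
        b = beam.waist_mm
        full = gaussian_weight(0.0, b, beam, exponent="intensity")
        half = gaussian_weight(0.0, b, beam, exponent="half")
        assert full == pytest.approx(np.exp(-2.0))
        assert half == pytest.approx(np.exp(-0.5))

    def test_bounded_and_maximal_at_focus(self, beam):
        rng = np.random.default_rng(7)
        a = rng.uniform(-7, 5.5, 500)
        b = rng.uniform(0, 12.5, 500)
        w = gaussian_weight(a, b, beam)
        assert np.all((w >= 0) & (w <= 1))


class TestReconstructGBBP:
    def test_zero_sinogram_gives_zero_image(self, beam):
        geom = _single_angle_geom()
        sino = Sinogram(np.zeros((1, 2000)), "pa", geom)
        grid = PolarGrid(np.array([0.0]), np.arange(1.0, 10.0, 0.01))
        img = reconstruct_gbbp(sino, beam, grid)
        assert img.stage == "rf"
        assert np.all(img.values == 0)

    def test_linearity_in_the_signal(self, beam, small_geometry):
        rng = np.random.default_rng(3)
        rf = rng.normal(size=(small_geometry.n_angles, small_geometry.n_samples))
        grid = PolarGrid(small_geometry.angles_rad[::4].copy(),
                         np.arange(2.0, 12.0, 0.05))
        s1 = Sinogram(rf, "pa", small_geometry)
        s2 = Sinogram(3.5 * rf, "pa", small_geometry)
        i1 = reconstruct_gbbp(s1, beam, grid)
        i2 = reconstruct_gbbp(s2, beam, grid)
        np.testing.assert_allclose(
            i2.values, 3.5 * i1.values, rtol=1e-12,
            atol=1e-12 * np.abs(i1.values).max(),
        )

    def test_single_angle_pulse_peaks_at_source_depth(self, beam):
        """A delta-like pulse at the arrival time of an on-axis point makes
        that point the per-angle maximum along the axis (brute-force check
        of the delay-and-sum at a line of on-axis pixels)."""
        geom = _single_angle_geom()
        a_star = 2.0  # mm beyond the focus
        t_star = float(delay_pa(a_star, 0.0, beam, V))
        rf = np.zeros((1, geom.n_samples))
        idx = int(round(t_star * geom.sampling_rate_mhz))
        rf[0, idx] = 1.0
        sino = Sinogram(rf, "pa", geom)
        radii = np.arange(5.0, 12.0, 0.001)
        img = reconstruct_gbbp(sino, beam, PolarGrid(np.array([0.0]), radii))
        r_peak = radii[np.argmax(img.values[0])]
        assert r_peak == pytest.approx(7.0 + a_star, abs=0.01)

    def test_modality_consistency_under_time_compression(self, beam, small_geometry):
        """A US reconstruction equals the PA reconstruction of the same RF
        matrix read at twice the sampling rate (time axis compressed by 2)."""
        import dataclasses

        rng = np.random.default_rng(11)
        rf = rng.normal(size=(small_geometry.n_angles, small_geometry.n_samples))
        geom_2fs = dataclasses.replace(
            small_geometry, sampling_rate_mhz=2 * small_geometry.sampling_rate_mhz
        )
        grid = PolarGrid(small_geometry.angles_rad[::8].copy(),
                         np.arange(2.0, 8.0, 0.05))
        us = reconstruct_gbbp(Sinogram(rf, "us", small_geometry), beam, grid)
        pa = reconstruct_gbbp(Sinogram(rf, "pa", geom_2fs), beam, grid)
        np.testing.assert_allclose(us.values, pa.values, rtol=1e-9, atol=1e-12)

    def test_unfocused_limit_matches_bmode_single_angle(self, pulse):
        """With z0 and w0 pushed to the unfocused limit, single-angle GB-BP
        degenerates to range mapping along the axis and its envelope matches
        the B-mode baseline within interpolation tolerance."""
        geom = _single_angle_geom()
        t = np.arange(geom.n_samples) / geom.sampling_rate_mhz
        rf = pulse(t - 4.0)[None, :]  # burst at 6 mm (PA)
        sino = Sinogram(rf, "pa", geom)
        unfocused = GaussianBeamParams(7.0, 1e3, 1e6)
        radii = np.arange(2.0, 11.0, 0.005)
        gb = envelope(reconstruct_gbbp(sino, unfocused, radii_grid := PolarGrid(
            np.array([0.0]), radii)))
        bm = reconstruct_bmode(sino, radii)
        scale = bm.values.max()
        # linear time interpolation of a 10 MHz carrier at 200 MHz carries a
        # worst-case second-order error of (pi f/fs)^2 / 2 ~ 1.25%
        np.testing.assert_allclose(gb.values / scale, bm.values / scale, atol=0.015)

    def test_missing_modality_rejected(self, small_geometry):
        with pytest.raises(InvalidParameterError):
            Sinogram(np.zeros((small_geometry.n_angles, 10)), "xx", small_geometry)


class TestBmode:
    def test_pulse_maps_to_one_way_range_pa_and_half_range_us(self, small_geometry, pulse):
        t = np.arange(small_geometry.n_samples) / small_geometry.sampling_rate_mhz
        rf = np.zeros((small_geometry.n_angles, small_geometry.n_samples))
        i = 7
        rf[i] = pulse(t - 6.0)
        radii = np.arange(1.0, 12.0, 0.01)
        pa = reconstruct_bmode(Sinogram(rf, "pa", small_geometry), radii)
        us = reconstruct_bmode(Sinogram(rf, "us", small_geometry), radii)
        ia, ir = np.unravel_index(np.argmax(pa.values), pa.values.shape)
        assert ia == i
        assert radii[ir] == pytest.approx(6.0 * 1.5, abs=0.02)
        ia, ir = np.unravel_index(np.argmax(us.values), us.values.shape)
        assert radii[ir] == pytest.approx(6.0 * 1.5 / 2, abs=0.02)

    def test_zero_in_zero_out(self, small_geometry):
        sino = Sinogram(np.zeros((small_geometry.n_angles, 100)), "pa",
                        ScanGeometry(
                            angles_rad=small_geometry.angles_rad,
                            virtual_radius_mm=0.0, imaging_radius_mm=12.5,
                            speed_of_sound_mm_us=V, sampling_rate_mhz=200.0,
                            n_samples=100))
        img = reconstruct_bmode(sino, np.arange(0.5, 0.7, 0.01))
        assert img.stage == "envelope"
        assert np.all(img.values == 0)


class TestEnvelope:
    def test_envelope_bounds_rf_and_is_sign_invariant(self, small_geometry, pulse):
        t = np.arange(small_geometry.n_samples) / small_geometry.sampling_rate_mhz
        rf = np.tile(pulse(t - 5.0), (small_geometry.n_angles, 1))
        grid = PolarGrid(small_geometry.angles_rad.copy(),
                         np.arange(0, small_geometry.n_samples) * 0.0075)
        img = ReconImage(rf, grid, "rf", "pa")
        env = envelope(img)
        assert env.stage == "envelope"
        assert np.all(env.values >= np.abs(rf) - 1e-9)
        neg = envelope(ReconImage(-rf, grid, "rf", "pa"))
        np.testing.assert_allclose(neg.values, env.values, rtol=1e-12)

    def test_wrong_stage_rejected(self, small_geometry):
        grid = PolarGrid(small_geometry.angles_rad.copy(), np.arange(100) * 0.01)
        env = ReconImage(np.ones((small_geometry.n_angles, 100)), grid,
                         "envelope", "pa")
        with pytest.raises(InvalidParameterError):
            envelope(env)


class TestScanConvert:
    def test_constant_ring_maps_to_constant_disc(self):
        grid = PolarGrid(np.linspace(-np.pi, np.pi, 361), np.linspace(1, 10, 200))
        img = ReconImage(np.ones(grid.shape), grid, "envelope", "pa")
        cart = CartesianGrid(-6, 6, -6, 6, 0.05)
        out = scan_convert(img, cart)
        xx, yy = np.meshgrid(cart.x_centers, cart.y_centers)
        rr = np.hypot(xx, yy)
        inside = (rr > 1.1) & (rr < 9.9)
        np.testing.assert_allclose(out.values[inside], 1.0, atol=1e-9)
        assert np.all(out.values[rr > 10.1] == 0)

    def test_round_trip_on_smooth_image(self):
        """Polar -> Cartesian -> polar round trip reproduces a band-limited
        image within bilinear interpolation tolerance."""
        from scipy.interpolate import RegularGridInterpolator

        angles = np.linspace(-0.3, 0.3, 121)
        radii = np.linspace(3, 10, 400)
        th, rr = np.meshgrid(angles, radii, indexing="ij")
        vals = 1 + 0.5 * np.sin(2 * np.pi * rr / 3) * np.cos(5 * th)
        img = ReconImage(vals, PolarGrid(angles, radii), "rf", "pa")
        cart = CartesianGrid(2.5, 10.5, -3.5, 3.5, 0.01)
        out = scan_convert(img, cart)
        interp = RegularGridInterpolator(
            (cart.y_centers, cart.x_centers), out.values)
        # probe strictly interior polar points
        th_p, rr_p = np.meshgrid(angles[10:-10:5], radii[20:-20:10], indexing="ij")
        back = interp(np.stack([(rr_p * np.sin(th_p)).ravel(),
                                (rr_p * np.cos(th_p)).ravel()], axis=1))
        truth = 1 + 0.5 * np.sin(2 * np.pi * rr_p / 3) * np.cos(5 * th_p)
        assert np.max(np.abs(back - truth.ravel())) < 0.01
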