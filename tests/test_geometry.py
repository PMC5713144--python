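"""Angle/Q maps and the geometry-dependent correction maps, each checked
against an independent scalar or numerical oracle."""

import numpy as np
import pytest
from scipy.integrate import quad

from saxsred import (
    ConfigurationError,
    Geometry,
    angle_maps,
    angular_efficiency_map,
    polarization_map,
    self_absorption_map,
    solid_angle_map,
)


@pytest.fixture()
def geo():
    return Geometry(
        distance_m=1.0,
        pixel_pitch_m=(172e-6, 172e-6),
        beam_center=(10.0, 12.0),
        wavelength_nm=0.1,
        sensor_optical_depth=1.0,
        polarization_fraction=0.5,
    )


class TestAngleMaps:
    def test_beam_center_pixel(self, geo):
        am = angle_maps(geo, (32, 32))
        assert am.two_theta[12, 10] == 0.0
        assert am.q[12, 10] == 0.0

    def test_hand_trigonometry(self):
        # pixel 100 pitches (0.0172 m) from center, L = 1 m, lambda = 0.1 nm
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1)
        am = angle_maps(geo, (1, 128))
        tt = np.arctan2(0.0172, 1.0)
        assert am.two_theta[0, 100] == pytest.approx(0.0171983, abs=1e-7)
        assert am.two_theta[0, 100] == pytest.approx(tt, rel=1e-15)
        # independent scalar implementation of q = 4 pi / lambda sin(theta)
        q = 4 * np.pi / 0.1 * np.sin(tt / 2)
        assert am.q[0, 100] == pytest.approx(q, rel=1e-15)
        assert am.q[0, 100] == pytest.approx(1.0805880, abs=1e-6)

    def test_chi_axis_convention(self, geo):
        am = angle_maps(geo, (32, 32))
        assert am.chi[20, 10] == pytest.approx(np.pi / 2)   # +vertical axis
        assert am.chi[12, 20] == pytest.approx(0.0)          # +horizontal axis
        assert am.chi.min() > -np.pi
        assert am.chi.max() <= np.pi

    def test_q_invariant_under_point_reflection(self):
        geo = Geometry(1.0, (172e-6, 172e-6), (15.5, 15.5), 0.1)
        am = angle_maps(geo, (32, 32))
        np.testing.assert_allclose(am.q, am.q[::-1, ::-1], rtol=1e-12)

    def test_q_consistent_with_two_theta(self, geo):
        am = angle_maps(geo, (16, 16))
        np.testing.assert_allclose(
            am.q, 4 * np.pi / geo.wavelength_nm * np.sin(am.two_theta / 2),
            rtol=1e-15,
        )


class TestSolidAngle:
    def test_on_axis_value(self):
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1)
        sp = solid_angle_map(geo, (4, 4))
        assert sp.values[0, 0] == pytest.approx(2.95840e-8, rel=1e-5)
        assert sp.apply == "divide"

    def test_cos_cubed_at_60_degrees(self):
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1)
        am = angle_maps(geo, (2, 2))
        omega0 = solid_angle_map(geo, (2, 2)).values[0, 0]
        # analytic: at psi = 60 deg the factor is cos^3 = 0.125
        psi = np.deg2rad(60.0)
        omega = (172e-6**2 / 1.0**2) * np.cos(psi) ** 3
        assert omega == pytest.approx(0.125 * omega0, rel=1e-12)

    def test_inverse_square_with_distance(self):
        near = solid_angle_map(Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1), (2, 2))
        far = solid_angle_map(Geometry(2.0, (172e-6, 172e-6), (0.0, 0.0), 0.1), (2, 2))
        assert far.values[0, 0] == pytest.approx(near.values[0, 0] / 4, rel=1e-12)

    def test_against_subpixel_integration(self):
        """Brute-force oracle: integrate dA cos^3(psi)/L^2 over each pixel
        with a 64x64 midpoint rule and compare to the center-value map."""
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1)
        shape = (16, 16)
        sp = solid_angle_map(geo, shape).values
        n = 64
        off = (np.arange(n) + 0.5) / n - 0.5
        px, py = geo.pixel_pitch_m
        for i, j in [(0, 0), (3, 5), (9, 2), (15, 15)]:
            xs = (j + off) * px
            ys = (i + off) * py
            X, Y = np.meshgrid(xs, ys)
            r2 = X**2 + Y**2
            cos3 = (1 + r2 / geo.distance_m**2) ** -1.5
            omega = cos3.mean() * px * py / geo.distance_m**2
            assert sp[i, j] == pytest.approx(omega, rel=1e-6)


class TestPolarization:
    def test_forward_scattering_is_unity(self, geo):
        am = angle_maps(geo, (32, 32))
        po = polarization_map(geo, am)
        assert po.values[12, 10] == 1.0

    def test_unpolarized_is_azimuthally_uniform(self):
        # nu = 1/2 reduces to 1 - sin^2(2theta)/2, independent of chi
        geo = Geometry(0.05, (172e-6, 172e-6), (31.5, 31.5), 0.1,
                       polarization_fraction=0.5)
        am = angle_maps(geo, (64, 64))
        po = polarization_map(geo, am).values
        expected = 1 - np.sin(am.two_theta) ** 2 / 2
        np.testing.assert_allclose(po, expected, rtol=1e-12)
        # pixels at (almost) equal two_theta must agree regardless of chi
        tt = am.two_theta
        ring = np.isclose(tt, tt[31, 50], atol=1e-6)
        assert po[ring].std() < 1e-6 * po[ring].mean()

    def test_horizontal_scattering_of_horizontal_polarization_suppressed(self):
        geo = Geometry(1e-6, (1.0, 1.0), (0.0, 0.0), 0.1,
                       polarization_fraction=1.0)
        am = angle_maps(geo, (1, 2))  # pixel at chi=0, two_theta ~ 90 deg
        po = polarization_map(geo, am)
        assert po.values[0, 1] == pytest.approx(0.0, abs=1e-10)
        assert po.invalid[0, 1]  # singular pixel auto-masked


class TestAngularEfficiency:
    def test_on_axis_factor_is_one(self, geo):
        am = angle_maps(geo, (32, 32))
        ae = angular_efficiency_map(geo, am)
        assert ae.values[12, 10] == 1.0

    def test_closed_form_at_60_degrees(self):
        # mu d = 1, psi = 60 deg: (1 - e^-1) / (1 - e^-2) = 0.73106
        geo = Geometry(1.0, (np.sqrt(3.0), 1.0), (0.0, 0.0), 0.1,
                       sensor_optical_depth=1.0)
        am = angle_maps(geo, (1, 2))  # pixel (0, 1) sits at two_theta = 60 deg
        np.testing.assert_allclose(am.two_theta[0, 1], np.deg2rad(60), rtol=1e-12)
        ae = angular_efficiency_map(geo, am)
        assert ae.values[0, 1] == pytest.approx(0.73106, abs=1e-5)
        oracle = -np.expm1(-1.0) / -np.expm1(-2.0)
        assert ae.values[0, 1] == pytest.approx(oracle, rel=1e-12)

    def test_thick_sensor_limit(self):
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1,
                       sensor_optical_depth=500.0)
        am = angle_maps(geo, (8, 8))
        ae = angular_efficiency_map(geo, am)
        np.testing.assert_allclose(ae.values, 1.0, atol=1e-12)

    def test_zero_depth_is_configuration_error(self):
        geo = Geometry(1.0, (172e-6, 172e-6), (0.0, 0.0), 0.1,
                       sensor_optical_depth=0.0)
        am = angle_maps(geo, (4, 4))
        with pytest.raises(ConfigurationError):
            angular_efficiency_map(geo, am)


def _self_absorption_oracle(two_theta: float, transmission: float) -> float:
    """Numerical path-length integration over a unit-thickness plate."""
    mu = -np.log(transmission)
    sec = 1.0 / np.cos(two_theta)
    integrand = lambda x: np.exp(-mu * x) * np.exp(-mu * (1 - x) * sec)
    val, _ = quad(integrand, 0.0, 1.0, epsabs=1e-14, epsrel=1e-14)
    return val / transmission


class TestSelfAbsorption:
    def test_forward_limit(self, geo):
        am = angle_maps(geo, (32, 32))
        sa = self_absorption_map(am, 0.5)
        assert sa.values[12, 10] == 1.0

    def test_against_path_length_integration(self):
        geo = Geometry(1.0, (1.0, 1.0), (0.0, 0.0), 0.1)
        am = angle_maps(geo, (1, 2))  # two_theta = 45 deg at pixel (0, 1)
        sa = self_absorption_map(am, 0.5)
        oracle = _self_absorption_oracle(np.pi / 4, 0.5)
        assert sa.values[0, 1] == pytest.approx(oracle, abs=1e-10)
        assert sa.values[0, 1] == pytest.approx(0.8692512, abs=1e-7)

    def test_strictly_decreasing_in_angle(self):
        geo = Geometry(1.0, (0.02, 0.02), (0.0, 0.0), 0.1)
        am = angle_maps(geo, (1, 40))
        f = self_absorption_map(am, 0.3).values[0]
        assert np.all(np.diff(f) < 0)

    def test_full_transmission_warns(self, geo):
        am = angle_maps(geo, (4, 4))
        with pytest.warns(UserWarning):
            sa = self_absorption_map(am, 1.0)
        assert np.all(sa.values == 1.0)

    def test_invalid_transmission(self, geo):
        am = angle_maps(geo, (4, 4))
        with pytest.raises(ValueError):
            self_absorption_map(am, 0.0)


def test_all_maps_unity_at_beam_center():
    geo = Geometry(1.0, (172e-6, 172e-6), (8.0, 8.0), 0.1,
                   sensor_optical_depth=0.7, polarization_fraction=0.9)
    shape = (17, 17)
    am = angle_maps(geo, shape)
    c = (8, 8)
    assert polarization_map(geo, am).values[c] == 1.0
    assert angular_efficiency_map(geo, am).values[c] == 1.0
    assert self_absorption_map(am, 0.4).values[c] == 1.0
    # solid angle keeps absolute steradians; at center it is px*py/L^2
    sp = solid_angle_map(geo, shape, am)
    assert sp.values[c] == pytest.approx(172e-6**2, rel=1e-12)
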