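"""Instrument geometry: per-pixel scattering-angle/Q maps and the
geometry-dependent correction maps (solid angle, polarization, angular
detection efficiency, sample self-absorption).

Conventions
-----------
The detector is assumed flat and normal to the beam, so the photon
incidence angle onto the sensor equals the scattering angle 2-theta.
Pixel coordinates are 0-based with the *center* of pixel ``(0, 0)`` at
coordinate ``(0.0, 0.0)``; the beam center is given in these fractional
pixel units as ``(center_col, center_row)``.  The azimuth chi is zero
along the +horizontal (column) axis, increases counterclockwise as seen
from the sample, and lies in ``(-pi, pi]``; the +vertical (row) axis is
at ``chi = +pi/2``.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import ConfigurationError
from .frames import CorrectionMap


@dataclass(frozen=True)
class Geometry:
    """Instrument description.

    Parameters
    ----------
    distance_m : sample-detector distance L, meters.
    pixel_pitch_m : (horizontal, vertical) pixel pitch, meters.
    beam_center : beam center (column, row) in fractional pixel units.
    wavelength_nm : X-ray wavelength, nanometers.
    sensor_optical_depth : mu_s * d_s, dimensionless optical depth of
        the sensor layer at the working energy (normal incidence).
    polarization_fraction : fraction nu of the beam polarized along the
        horizontal axis; 0.5 for an unpolarized beam.
    """

    distance_m: float
    pixel_pitch_m: tuple[float, float]
    beam_center: tuple[float, float]
    wavelength_nm: float
    sensor_optical_depth: float = 0.0
    polarization_fraction: float = 0.5

    def __post_init__(self) -> None:
        px, py = self.pixel_pitch_m
        if not (self.distance_m > 0 and px > 0 and py > 0 and self.wavelength_nm > 0):
            raise ConfigurationError(
                "distance, pixel pitch and wavelength must all be positive"
            )
        if self.sensor_optical_depth < 0:
            raise ConfigurationError("sensor_optical_depth must be >= 0")
        if not 0 <= self.polarization_fraction <= 1:
            raise ConfigurationError("polarization_fraction must lie in [0, 1]")


@dataclass(frozen=True)
class AngleMaps:
    """Per-pixel scattering angle 2-theta (rad), azimuth chi (rad) and
    momentum transfer q (nm^-1)."""

    two_theta: np.ndarray
    chi: np.ndarray
    q: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.two_theta.shape


def angle_maps(geometry: Geometry, shape: tuple[int, int]) -> AngleMaps:
    """Compute 2-theta, chi and q for every pixel center.

    ``two_theta = atan(r / L)`` with r the in-plane distance of the
    pixel center from the beam center, and
    ``q = (4 pi / lambda) sin(two_theta / 2)``.
    """
    rows, cols = shape
    px, py = geometry.pixel_pitch_m
    cx, cy = geometry.beam_center
    x = (np.arange(cols) - cx) * px          # horizontal, meters
    y = (np.arange(rows) - cy) * py          # vertical, meters
    X, Y = np.meshgrid(x, y)
    r = np.hypot(X, Y)
    two_theta = np.arctan2(r, geometry.distance_m)
    chi = np.arctan2(Y, X)
    chi = np.where(chi == -np.pi, np.pi, chi)
    q = (4 * np.pi / geometry.wavelength_nm) * np.sin(two_theta / 2)
    return AngleMaps(two_theta=two_theta, chi=chi, q=q)


def solid_angle_map(geometry: Geometry, shape: tuple[int, int],
                    maps: AngleMaps | None = None) -> CorrectionMap:
    """SP: solid angle subtended by each pixel, in steradians.

    For a flat detector normal to the beam the pixel at scattering angle
    psi = 2-theta subtends ``Omega = (px * py / L**2) * cos(psi)**3``
    (one cosine for the projected area, two for the increased distance).
    Applying the map divides the signal by Omega, putting it on an
    absolute per-steradian footing rather than normalizing to the
    on-axis pixel.
    """
    if maps is None:
        maps = angle_maps(geometry, shape)
    px, py = geometry.pixel_pitch_m
    omega = (px * py / geometry.distance_m**2) * np.cos(maps.two_theta) ** 3
    return CorrectionMap(values=omega, name="SP", apply="divide")


#: Polarization factors below this are treated as singular and auto-masked.
POLARIZATION_FLOOR = 1e-6


def polarization_map(geometry: Geometry, maps: AngleMaps) -> CorrectionMap:
    """PO: probability factor for Thomson scattering into each pixel.

    With nu the horizontally polarized fraction,
    ``P = nu * (1 - (cos chi * sin 2theta)**2)
        + (1 - nu) * (1 - (sin chi * sin 2theta)**2)``.
    For an unpolarized beam (nu = 1/2) this reduces to the azimuthally
    uniform ``1 - sin(2theta)**2 / 2``.  The correction divides the
    signal by P; pixels where P vanishes (full suppression of the
    scattered polarization) are auto-masked instead of producing huge
    corrected values.
    """
    nu = geometry.polarization_fraction
    s = np.sin(maps.two_theta)
    p = nu * (1 - (np.cos(maps.chi) * s) ** 2) + (1 - nu) * (
        1 - (np.sin(maps.chi) * s) ** 2
    )
    singular = p < POLARIZATION_FLOOR
    return CorrectionMap(values=p, name="PO", apply="divide", invalid=singular)


def angular_efficiency_map(geometry: Geometry, maps: AngleMaps) -> CorrectionMap:
    """AE: relative detection efficiency vs photon incidence angle.

    The sensor layer of optical depth ``mu_s d_s`` absorbs a fraction
    ``eps(psi) = 1 - exp(-mu_s d_s / cos psi)`` of the photons crossing
    it at incidence angle psi, so oblique pixels are *more* efficient
    (longer path through the sensor).  The correction multiplies the
    signal by ``eps(0) / eps(psi)``, referencing everything to the
    on-axis pixel; the absolute quantum efficiency is left to the
    absolute-units calibration.
    """
    mud = geometry.sensor_optical_depth
    if mud == 0:
        raise ConfigurationError(
            "angular efficiency undefined for sensor_optical_depth = 0"
        )
    eps = -np.expm1(-mud / np.cos(maps.two_theta))
    eps0 = -np.expm1(-mud)
    return CorrectionMap(values=eps0 / eps, name="AE", apply="multiply")


def self_absorption_map(maps: AngleMaps, transmission: float) -> CorrectionMap:
    """SA: direction-dependent extra absorption for plate samples.

    Valid for plate-like samples with the surface normal to the beam
    only.  Rays scattered at depth x through angle 2-theta traverse
    ``(d - x) sec(2theta)`` of sample on the way out; averaging the
    Beer-Lambert attenuation over x and normalizing by the
    straight-through transmission gives, with ``s = sec(2theta)`` and
    ``u = (s - 1) ln T``, the relative factor ``F = expm1(u) / u``
    (F -> 1 as 2theta -> 0).  F modifies, and does not replace, the
    transmission correction; applying the map divides the signal by F.
    """
    if transmission <= 0 or transmission > 1:
        raise ValueError(f"transmission must lie in (0, 1], got {transmission}")
    if transmission == 1:
        warnings.warn("transmission = 1: self-absorption factor is identically 1")
        return CorrectionMap(values=np.ones(maps.shape), name="SA", apply="divide")
    sec = 1.0 / np.cos(maps.two_theta)
    u = (sec - 1.0) * np.log(transmission)
    with np.errstate(invalid="ignore"):
        f = np.where(u == 0, 1.0, np.expm1(u) / np.where(u == 0, 1.0, u))
    return CorrectionMap(values=f, name="SA", apply="divide")
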