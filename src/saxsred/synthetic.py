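"""Forward instrument simulator.

Generates raw photon-count frames with fully known ground truth — a
dilute-sphere analyte in a flat-scattering dispersant inside a
container, imaged by a photon-counting detector with dark counts,
per-pixel sensitivity variations, angle-dependent sensor efficiency and
deadtime — so the whole correction chain can be validated closed-loop
without any external data.

The forward model is the inverse of the correction sequence: the
expected detected rate at pixel (i, j) for a measurement of
cross-section field ``Sigma(q)`` and thickness d is ::

    rate = Phi_i * T * [Sigma(q) * d + c] * Omega * P * (eps/eps0) * S + dark

with c the container's equivalent scattering (sr^-1), Omega the pixel
solid angle, P the polarization factor, eps/eps0 the relative angular
detection efficiency, and S the per-pixel sensitivity (the reciprocal
of the flatfield correction matrix).  Counts are drawn Poisson per
frame and then distorted by the deadtime model, which the DT correction
inverts exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigurationError
from .frames import CorrectionMap, DetectorFrame, MeasurementMeta
from .geometry import Geometry, angle_maps
from .pipeline import InstrumentMaps, build_maps

#: Planck constant times c in keV nm: photon energy = HC_KEV_NM / wavelength.
HC_KEV_NM = 1.2398419843320026

#: First zero of the sphere form factor amplitude (root of tan x = x).
SPHERE_FIRST_MINIMUM_QR = 4.493409457909064


def sphere_form_factor_cross_section(q, radius_nm: float, contrast_m2: float,
                                     volume_fraction: float):
    """Differential cross section of dilute homogeneous spheres, (m sr)^-1.

    ``dSigma/dOmega(q) = phi * V * drho^2 * [3 (sin qR - qR cos qR)/(qR)^3]^2``
    with q in nm^-1, R in nm, the scattering-length-density contrast in
    m^-2 and V the sphere volume in m^3.  The q -> 0 limit is
    ``phi * V * drho^2``.
    """
    if radius_nm <= 0:
        raise ValueError("sphere radius must be positive")
    q = np.asarray(q, dtype=float)
    if np.any(q < 0):
        raise ValueError("q must be non-negative")
    x = q * radius_nm
    small = x < 1e-4
    xs = np.where(small, 1.0, x)
    amp = np.where(small, 1.0 - x**2 / 10.0,
                   3.0 * (np.sin(xs) - xs * np.cos(xs)) / xs**3)
    volume = (4.0 / 3.0) * np.pi * (radius_nm * 1e-9) ** 3
    return volume_fraction * volume * contrast_m2**2 * amp**2


def make_flatfield(shape, seed: int, rel_spread: float = 0.01) -> np.ndarray:
    """A per-pixel sensitivity-correction matrix, normalized to mean 1."""
    rng = np.random.default_rng(seed)
    ff = 1.0 + rel_spread * rng.standard_normal(shape)
    ff = np.clip(ff, 0.5, 1.5)
    return ff / ff.mean()


@dataclass(frozen=True)
class GroundTruth:
    """Complete description of the simulated instrument and samples.

    Defaults model a small laboratory/beamline setup: a 256x256
    photon-counting detector with 172 um pixels one meter behind a 1 mm
    sample, 0.1 nm photons, R = 5 nm spheres at 1% volume fraction in a
    flat-scattering solvent, measured as 10 frames of 1 s each.
    """

    geometry: Geometry = field(default_factory=lambda: Geometry(
        distance_m=1.0,
        pixel_pitch_m=(172e-6, 172e-6),
        beam_center=(127.5, 127.5),
        wavelength_nm=0.1,
        sensor_optical_depth=1.0,
        polarization_fraction=0.95,
    ))
    shape: tuple[int, int] = (256, 256)
    n_frames: int = 10
    time_s: float = 1.0
    flux_incident: float = 2e12            # photons/s
    transmission: dict = field(default_factory=lambda: {
        "A": 0.92, "B": 0.34, "C": 0.34,
    })
    thickness_m: float = 1e-3
    deadtime_s: float = 1e-6
    deadtime_model: str = "nonparalyzable"  # or "paralyzable"
    dark_rate_cps: float = 0.05
    dispersant_level: float = 40.0          # (m sr)^-1, flat in q
    container_sr: float = 0.02              # container equivalent, sr^-1
    sphere_radius_nm: float = 5.0
    contrast_m2: float = 3e14
    volume_fraction: float = 0.01
    flatfield: np.ndarray | None = None     # correction matrix, mean 1
    cal_factor: float = 1.0
    container_id: str = "cap1"
    metadata_bias: dict = field(default_factory=dict)  # key -> relative bias

    def __post_init__(self) -> None:
        if not 0 <= self.volume_fraction < 1:
            raise ConfigurationError("volume_fraction must lie in [0, 1)")
        if self.dispersant_level < 0 or self.container_sr < 0:
            raise ConfigurationError("cross sections must be non-negative")
        if self.deadtime_model not in ("nonparalyzable", "paralyzable"):
            raise ConfigurationError(
                f"unknown deadtime model {self.deadtime_model!r}"
            )

    @property
    def energy_kev(self) -> float:
        return HC_KEV_NM / self.geometry.wavelength_nm

    def sensitivity(self) -> np.ndarray:
        """Per-pixel sensitivity = reciprocal of the flatfield matrix."""
        if self.flatfield is None:
            return np.ones(self.shape)
        return 1.0 / self.flatfield

    def flatfield_map(self) -> CorrectionMap:
        ff = np.ones(self.shape) if self.flatfield is None else self.flatfield
        return CorrectionMap(values=ff, name="FF", apply="multiply")

    def maps(self) -> InstrumentMaps:
        return build_maps(self.geometry, self.shape)


def make_default_truth(seed: int = 0, shape=(256, 256), n_frames: int = 10,
                       **overrides) -> GroundTruth:
    """The standard test fixture, with a seeded 1% rms flatfield."""
    cx = (shape[1] - 1) / 2.0
    cy = (shape[0] - 1) / 2.0
    base = GroundTruth()
    geometry = replace(base.geometry, beam_center=(cx, cy))
    return replace(
        base,
        geometry=overrides.pop("geometry", geometry),
        shape=shape,
        n_frames=n_frames,
        flatfield=make_flatfield(shape, seed=int(seed) % (2**31 - 1) ^ 0x5AF5),
        **overrides,
    )


def sample_cross_section(truth: GroundTruth, role: str, q) -> np.ndarray:
    """The in-beam sample cross section Sigma(q) for a role, (m sr)^-1."""
    q = np.asarray(q, dtype=float)
    if role == "A":
        return np.zeros_like(q)
    if role == "B":
        return np.full_like(q, truth.dispersant_level)
    if role == "C":
        analyte = sphere_form_factor_cross_section(
            q, truth.sphere_radius_nm, truth.contrast_m2, truth.volume_fraction
        )
        return analyte + (1.0 - truth.volume_fraction) * truth.dispersant_level
    raise ConfigurationError(f"unknown role {role!r}")


def expected_rate(truth: GroundTruth, role: str) -> np.ndarray:
    """Expected detected count rate per pixel (before deadtime), cps."""
    maps = truth.maps()
    am = maps.angles
    omega = maps.solid_angle.values
    pol = maps.polarization.values
    eff = (1.0 / maps.angular_efficiency.values
           if maps.angular_efficiency is not None else 1.0)
    sigma = sample_cross_section(truth, role, am.q)
    per_photon = (sigma * truth.thickness_m + truth.container_sr) * omega * pol
    rate = (truth.flux_incident * truth.transmission[role]
            * per_photon * eff * truth.sensitivity())
    return rate + truth.dark_rate_cps


def _apply_deadtime(counts: np.ndarray, time_s: float, tau: float,
                    model: str) -> np.ndarray:
    if tau == 0:
        return counts
    rate = counts / time_s
    if model == "nonparalyzable":
        return counts / (1.0 + rate * tau)
    return counts * np.exp(-rate * tau)


def _biased(truth: GroundTruth, key: str, value: float) -> float:
    return value * (1.0 + truth.metadata_bias.get(key, 0.0))


def measurement_meta(truth: GroundTruth, role: str) -> MeasurementMeta:
    """The nominal sidecar metadata the pipeline sees (bias included)."""
    t_true = truth.transmission[role]
    flux = _biased(truth, "flux_incident", truth.flux_incident)
    trans = _biased(truth, "transmission", t_true)
    return MeasurementMeta(
        time_s=_biased(truth, "time_s", truth.time_s),
        flux_incident=flux,
        flux_emergent=flux * trans,
        transmission=trans,
        deadtime_s=truth.deadtime_s,
        thickness_m=_biased(truth, "thickness_m", truth.thickness_m),
        volume_fraction=(truth.volume_fraction if role == "C" else 0.0),
        role=role,
        container_id=truth.container_id,
    )


def simulate_measurement(truth: GroundTruth, role: str,
                         seed: int) -> list[DetectorFrame]:
    """Draw the raw frames for one measurement.

    Returns ``n_frames`` frames of Poisson counts (deadtime-distorted),
    each carrying the nominal sidecar metadata and a DS provenance mark,
    exactly as if they had been read from disk.  Output is a pure
    function of ``(truth, role, seed)``.
    """
    role_ix = {"A": 1, "B": 2, "C": 3}[role]
    rng = np.random.default_rng([int(seed), role_ix])
    rate = expected_rate(truth, role)
    if np.any(rate * truth.deadtime_s >= 1.0):
        raise ConfigurationError(
            "expected rate * deadtime >= 1: detector would saturate"
        )
    meta = measurement_meta(truth, role)
    frames = []
    for _ in range(truth.n_frames):
        n = rng.poisson(rate * truth.time_s).astype(float)
        m = _apply_deadtime(n, truth.time_s, truth.deadtime_s,
                            truth.deadtime_model)
        frames.append(DetectorFrame(
            signal=m, uncertainty=np.zeros_like(m), meta=meta,
            units_state="raw_counts", provenance=("DS",),
        ))
    return frames


def dark_frame(truth: GroundTruth) -> DetectorFrame:
    """The calibrated dark-current rate map (cps) fed to the DC step."""
    rate = np.full(truth.shape, truth.dark_rate_cps)
    return DetectorFrame(
        signal=rate, uncertainty=np.zeros_like(rate),
        meta=MeasurementMeta(), units_state="raw_counts", provenance=("DS",),
    )


def analyte_counts_per_pixel(truth: GroundTruth) -> np.ndarray:
    """Expected counts per pixel attributable to the analyte, summed
    over all frames of the role-C measurement.  Used to decide where
    the recovered curve carries enough statistics to be compared
    against the ground truth."""
    maps = truth.maps()
    analyte = sphere_form_factor_cross_section(
        maps.angles.q, truth.sphere_radius_nm, truth.contrast_m2,
        truth.volume_fraction,
    )
    eff = (1.0 / maps.angular_efficiency.values
           if maps.angular_efficiency is not None else 1.0)
    rate = (truth.flux_incident * truth.transmission["C"]
            * analyte * truth.thickness_m * maps.solid_angle.values
            * maps.polarization.values * eff * truth.sensitivity())
    return rate * truth.time_s * truth.n_frames


def anisotropic_flare_rate(geometry: Geometry, shape, level_cps: float,
                           flare_cps: float, flare_width: float = 0.35,
                           flare_chi: float = 0.0) -> np.ndarray:
    """An azimuthally localized background flare on top of a flat level.

    Models parasitic streaks (slit scatter) whose intensity depends on
    the azimuth chi: a Gaussian lobe of angular width *flare_width*
    (rad) centered at *flare_chi* and at its mirror across the beam.
    Returns the expected rate field in cps.
    """
    am = angle_maps(geometry, shape)
    d1 = np.angle(np.exp(1j * (am.chi - flare_chi)))
    d2 = np.angle(np.exp(1j * (am.chi - flare_chi - np.pi)))
    lobe = np.exp(-0.5 * (d1 / flare_width) ** 2) + np.exp(
        -0.5 * (d2 / flare_width) ** 2
    )
    return level_cps + flare_cps * lobe
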