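"""Measurement-dependent elementary correction steps.

Each function is a pure transform ``DetectorFrame -> DetectorFrame``
that reads its scalar parameters from the frame's
:class:`~saxsred.frames.MeasurementMeta`, propagates uncertainty through
the shared :func:`~saxsred.frames.scale_frame` engine, and records its
two-letter step code in the provenance.  The scalar steps (TI, FL, TR,
TH, AU, DV) are plain multiplications and therefore mutually commute.
"""

from __future__ import annotations

import warnings

import numpy as np

from .errors import SaturationError, SequenceError
from .frames import CorrectionMap, DetectorFrame, scale_frame, subtract_frames


def poisson_uncertainty(frame: DetectorFrame) -> DetectorFrame:
    """PU: set the counting uncertainty from the detected photon counts.

    ``sigma = sqrt(max(counts, 1))``; the floor of one count on empty
    pixels keeps them from acquiring infinite weight in inverse-variance
    averaging.  Must run on raw counts, before the deadtime, dark
    current or flatfield corrections rescale them.
    """
    late = [c for c in ("DT", "DC", "FF") if frame.has_step(c)]
    if late:
        raise SequenceError(
            f"Poisson uncertainty must precede {late}; provenance {frame.provenance}"
        )
    if frame.units_state != "raw_counts":
        raise SequenceError(
            f"Poisson uncertainty requires raw counts, got {frame.units_state}"
        )
    unc = np.sqrt(np.maximum(frame.signal, 1.0))
    return frame.evolve(uncertainty=unc).with_step("PU")


#: Deadtime correction refuses rates beyond this fraction of saturation.
DEADTIME_RATE_LIMIT = 0.9


def deadtime_correct(frame: DetectorFrame) -> DetectorFrame:
    """DT: non-paralyzable deadtime correction.

    With measured per-pixel rate ``r = counts / t`` and deadtime tau,
    the estimated number of arriving photons is
    ``counts / (1 - r * tau)``; the uncertainty is scaled by the same
    factor.  Pixels with ``r * tau`` at or beyond 90% of saturation
    cannot be corrected reliably and raise :class:`SaturationError`.
    """
    frame.meta.require("deadtime_s", "time_s")
    tau = frame.meta.deadtime_s
    if tau == 0:
        return frame.with_step("DT")
    rate = frame.signal / frame.meta.time_s
    occupancy = rate * tau
    saturated = (occupancy >= DEADTIME_RATE_LIMIT) & ~frame.mask
    if np.any(saturated):
        i, j = np.argwhere(saturated)[0]
        raise SaturationError(
            f"count rate at pixel ({i}, {j}) reaches {occupancy[i, j]:.3f} "
            f"of the deadtime limit (>= {DEADTIME_RATE_LIMIT})"
        )
    factor = 1.0 / (1.0 - np.clip(occupancy, None, DEADTIME_RATE_LIMIT))
    return frame.evolve(
        signal=frame.signal * factor, uncertainty=frame.uncertainty * factor
    ).with_step("DT")


def darkcurrent_subtract(frame: DetectorFrame, dark: DetectorFrame) -> DetectorFrame:
    """DC: subtract the exposure-scaled dark-current rate.

    The dark measurement is stored as a count *rate* (counts/s per
    pixel) so a single long dark acquisition serves any exposure time;
    since DC precedes time normalization the subtracted counts are
    ``dark_rate * t`` with uncertainty ``t * sigma_dark``, combined in
    quadrature.
    """
    frame.meta.require("time_s")
    t = frame.meta.time_s
    scaled = dark.evolve(
        signal=dark.signal * t,
        uncertainty=dark.uncertainty * t,
        units_state=frame.units_state,
        provenance=(),
    )
    return subtract_frames(frame, scaled, step_code="DC")


def time_normalize(frame: DetectorFrame) -> DetectorFrame:
    """TI: divide by the exposure time; counts become counts/s."""
    frame.meta.require("time_s")
    t, st = frame.meta.time_s, frame.meta.time_sigma
    return scale_frame(frame, 1.0 / t, st / t**2, step_code="TI")


def flux_normalize(frame: DetectorFrame) -> DetectorFrame:
    """FL: divide by the incident flux; the signal becomes dimensionless."""
    frame.meta.require("flux_incident")
    phi, sp = frame.meta.flux_incident, frame.meta.flux_incident_sigma
    return scale_frame(frame, 1.0 / phi, sp / phi**2, step_code="FL")


#: Relative transmission uncertainty above which a warning is emitted
#: (the quality of the result depends strongly on T; better than 1%
#: accuracy should be aimed for).
TRANSMISSION_ACCURACY = 0.01


def transmission_correct(frame: DetectorFrame) -> DetectorFrame:
    """TR: divide by the sample transmission factor T in (0, 1]."""
    frame.meta.require("transmission")
    t, st = frame.meta.transmission, frame.meta.transmission_sigma
    if st / t > TRANSMISSION_ACCURACY:
        warnings.warn(
            f"transmission known only to {100 * st / t:.2f}% — the corrected "
            "cross section depends strongly on T; aim for better than "
            f"{100 * TRANSMISSION_ACCURACY:.0f}%"
        )
    return scale_frame(frame, 1.0 / t, st / t**2, step_code="TR")


def combined_flux_transmission(frame: DetectorFrame) -> DetectorFrame:
    """FL+TR in one step: divide by the emergent flux.

    Since ``T = flux_emergent / flux_incident``, dividing the signal by
    the emergent flux equals the sequential flux normalization and
    transmission correction, without needing an upstream flux monitor.
    Provenance gains both FL and TR.
    """
    frame.meta.require("flux_emergent")
    phi, sp = frame.meta.flux_emergent, frame.meta.flux_emergent_sigma
    out = scale_frame(frame, 1.0 / phi, sp / phi**2, step_code=None)
    return out.with_step("FL").with_step("TR")


def flatfield_correct(frame: DetectorFrame, flatfield: CorrectionMap) -> DetectorFrame:
    """FF: multiply by the inter-pixel sensitivity correction matrix.

    The flatfield is normalized to mean 1 over unmasked pixels; a map
    off by more than 1e-6 is renormalized with a warning.  Non-positive
    factors on unmasked pixels are invalid.
    """
    if flatfield.shape != frame.shape:
        raise ValueError(f"flatfield shape {flatfield.shape} != frame {frame.shape}")
    values = flatfield.values
    sigma = flatfield.sigma
    unmasked = ~frame.mask
    if flatfield.invalid is not None:
        unmasked = unmasked & ~flatfield.invalid
    if np.any((values <= 0) & unmasked):
        i, j = np.argwhere((values <= 0) & unmasked)[0]
        raise ValueError(f"non-positive flatfield factor at unmasked pixel ({i}, {j})")
    mean = values[unmasked].mean()
    if abs(mean - 1.0) > 1e-6:
        warnings.warn(
            f"flatfield mean over unmasked pixels is {mean:.6g}; renormalizing to 1"
        )
        values = values / mean
        sigma = None if sigma is None else sigma / mean
    ff = CorrectionMap(values=values, sigma=sigma, name="FF", apply="multiply",
                       invalid=flatfield.invalid)
    return scale_frame(frame, ff, step_code="FF")


def thickness_normalize(frame: DetectorFrame) -> DetectorFrame:
    """TH: divide by the sample thickness in meters.

    For dispersions the thickness of the liquid phase only is used.
    Moves the units toward reciprocal length (m^-1 sr^-1).
    """
    frame.meta.require("thickness_m")
    d, sd = frame.meta.thickness_m, frame.meta.thickness_sigma
    return scale_frame(frame, 1.0 / d, sd / d**2, step_code="TH")


def absolute_scale(frame: DetectorFrame, cal_factor: float,
                   cal_sigma: float = 0.0) -> DetectorFrame:
    """AU: apply the externally determined absolute-intensity factor.

    The calibration factor (from e.g. a glassy carbon or water
    calibrant reduction, outside this package's scope) scales the data
    to differential scattering cross section in (m sr)^-1.
    """
    if not cal_factor > 0:
        raise ValueError(f"calibration factor must be positive, got {cal_factor}")
    return scale_frame(frame, cal_factor, cal_sigma, step_code="AU")


def displaced_volume_scale(frame: DetectorFrame, volume_fraction: float,
                           volume_fraction_sigma: float = 0.0) -> DetectorFrame:
    """DV: scale a dispersant signal by (1 - phi).

    An analyte occupying volume fraction phi of the beam path displaces
    that share of dispersant, so the dispersant's contribution to the
    dispersion measurement shrinks proportionally.  Applies to the
    stored dispersant (Output-B-class) signal only — never to the
    dispersion (role C) measurement itself.
    """
    if not 0 <= volume_fraction < 1:
        raise ValueError(f"volume fraction must lie in [0, 1), got {volume_fraction}")
    if frame.meta.role == "C":
        raise SequenceError(
            "displaced-volume scaling applies to the dispersant signal, "
            "not to the dispersion (role C) measurement"
        )
    return scale_frame(frame, 1.0 - volume_fraction, volume_fraction_sigma,
                       step_code="DV")
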