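"""Orchestration of the three correction processes.

Process A reduces the instrumental background (empty container),
Process B a non-dispersed material or pure dispersant, and Process C the
dispersion (dispersant + analyte).  B and C subtract the Process-A
output at the first merging point; C additionally subtracts the fully
corrected dispersant signal — scaled by (1 - phi) for the volume the
analyte displaces — at the second merging point, leaving the absolute
scattering cross section of the analyte alone.

Steps that commute (the scalar multiplications TI/FL/TR/TH/AU and the
per-pixel maps FF/AE/SP/PO) may be listed in any order in a
:class:`ProcessConfig`; the engine applies each exactly once at its
canonical site, so any permutation of a commuting group produces
bit-identical output.  Corrections deferred past a merging point (FF,
AE, SP, PO, TH, AU) run once per process, which keeps the duplicate
contribution of their uncertainties to the propagated error as small as
the schema allows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from . import corrections as corr
from .averaging import Curve1D, radial_average
from .errors import ConfigurationError, RangeError, SequenceError, UnitsStateError
from .frames import (
    CorrectionMap,
    DetectorFrame,
    MeasurementMeta,
    apply_mask,
    average_frames,
    scale_frame,
    subtract_frames,
)
from .geometry import (
    AngleMaps,
    Geometry,
    angle_maps,
    angular_efficiency_map,
    polarization_map,
    self_absorption_map,
    solid_angle_map,
)

# Canonical order of the correction sequence; enabled steps must form a
# subsequence of this, up to permutations within the commuting groups.
CANONICAL_ORDER = (
    "DS", "MK", "PU", "DT", "DC", "TI", "FL", "TR", "SA", "FA",
    "BG", "FF", "AE", "SP", "PO", "TH", "AU", "DV", "RM", "SB", "AV",
)

#: Scalar multiplicative steps: mutually commuting.
SCALAR_GROUP = frozenset({"TI", "FL", "TR", "TH", "AU"})
#: Per-pixel multiplicative maps applied after the first merging point:
#: mutually commuting.
MAP_GROUP = frozenset({"FF", "AE", "SP", "PO"})

_ROLE_STEPS = {
    "A": ("DS", "MK", "PU", "DT", "DC", "TI", "FL", "TR", "SA", "FA"),
    "B": ("DS", "MK", "PU", "DT", "DC", "TI", "FL", "TR", "SA", "FA",
          "BG", "FF", "AE", "SP", "PO", "TH", "AU"),
    "C": ("DS", "MK", "PU", "DT", "DC", "TI", "FL", "TR", "SA", "FA",
          "BG", "FF", "AE", "SP", "PO", "TH", "AU", "DV", "RM", "SB"),
}

#: Library entries may be reused at a relative energy difference up to
#: this; beyond it reuse is refused (or warned about in non-strict mode).
ENERGY_RTOL = 1e-3


def _token(code: str) -> str:
    if code in SCALAR_GROUP:
        return "<scalar>"
    if code in MAP_GROUP:
        return "<map>"
    return code


def normalize_steps(steps, role: str, strict: bool = False) -> tuple[str, ...]:
    """Validate a step list and return it in canonical order.

    Commuting steps may appear in any order among the slots their group
    occupies; any other deviation from the canonical sequence is a
    :class:`SequenceError` in strict mode and a warning otherwise.
    """
    steps = tuple(steps)
    allowed = set(_ROLE_STEPS[role])
    unknown = [s for s in steps if s not in CANONICAL_ORDER]
    if unknown:
        raise ConfigurationError(f"unknown step codes {unknown}")
    extraneous = [s for s in steps if s not in allowed]
    if extraneous:
        raise ConfigurationError(
            f"steps {extraneous} are not part of Process {role}"
        )
    if len(set(steps)) != len(steps):
        raise ConfigurationError(f"duplicate steps in {steps}")
    canonical = tuple(s for s in CANONICAL_ORDER if s in set(steps))
    if [_token(s) for s in steps] != [_token(s) for s in canonical]:
        msg = (
            f"step order {steps} deviates from the canonical sequence beyond "
            "commuting-group permutations; applying canonical order "
            f"{canonical}"
        )
        if strict:
            raise SequenceError(msg)
        warnings.warn(msg, stacklevel=2)
    return canonical


@dataclass(frozen=True)
class ProcessConfig:
    """Which steps to run, with their shared resources.

    The default step list for a role enables everything except SA
    (plate-geometry samples only) and the optional dark/flatfield steps,
    which are switched on automatically when the corresponding resource
    is supplied.
    """

    role: str
    steps: tuple[str, ...] | None = None
    strict: bool = False
    mask: np.ndarray | None = None
    dark: DetectorFrame | None = None
    flatfield: CorrectionMap | None = None
    cal_factor: float = 1.0
    cal_sigma: float = 0.0
    use_emergent_flux: bool = False
    weighted_average: bool = True
    enable_self_absorption: bool = False
    energy_kev: float | None = None

    def resolved_steps(self) -> tuple[str, ...]:
        if self.steps is not None:
            return normalize_steps(self.steps, self.role, self.strict)
        steps = [s for s in _ROLE_STEPS[self.role] if s != "SA"]
        if self.dark is None:
            steps.remove("DC")
        if self.flatfield is None and "FF" in steps:
            steps.remove("FF")
        if self.enable_self_absorption:
            steps.append("SA")
        return normalize_steps(steps, self.role, self.strict)


@dataclass(frozen=True)
class InstrumentMaps:
    """Bundle of the per-pixel angle and geometry-correction maps."""

    angles: AngleMaps
    solid_angle: CorrectionMap | None = None
    polarization: CorrectionMap | None = None
    angular_efficiency: CorrectionMap | None = None


def build_maps(geometry: Geometry, shape: tuple[int, int]) -> InstrumentMaps:
    """Derive all geometry-dependent maps for a detector of *shape*."""
    am = angle_maps(geometry, shape)
    ae = None
    if geometry.sensor_optical_depth > 0:
        ae = angular_efficiency_map(geometry, am)
    return InstrumentMaps(
        angles=am,
        solid_angle=solid_angle_map(geometry, shape, am),
        polarization=polarization_map(geometry, am),
        angular_efficiency=ae,
    )


@dataclass(frozen=True)
class BackgroundEntry:
    """A fully corrected dispersant/background signal for the library.

    Stored in absolute units together with the beam energy it was
    measured at and the container it was measured in, so it can be
    reused for later samples at the same energy in the same container.
    """

    payload: DetectorFrame | Curve1D
    energy_kev: float
    container_id: str = ""
    provenance: tuple[str, ...] = field(default=())

    def __post_init__(self) -> None:
        if isinstance(self.payload, DetectorFrame):
            if self.payload.units_state != "absolute":
                raise UnitsStateError(
                    "library entries must be in absolute units, got "
                    f"{self.payload.units_state}"
                )
            if not self.provenance:
                object.__setattr__(self, "provenance", self.payload.provenance)
        if not self.energy_kev > 0:
            raise ConfigurationError("energy_kev must be positive")


# -- shared per-measurement chain (steps i-x) -----------------------------


def _measurement_chain(frames, config: ProcessConfig, maps: InstrumentMaps | None):
    """Apply the measurement-dependent steps MK..SA to each frame, then FA."""
    steps = config.resolved_steps()
    out = []
    for f in frames:
        if "MK" in steps and config.mask is not None:
            f = apply_mask(f, config.mask)
        if "PU" in steps:
            f = corr.poisson_uncertainty(f)
        if "DT" in steps:
            f = corr.deadtime_correct(f)
        if "DC" in steps:
            if config.dark is None:
                raise ConfigurationError("DC enabled but no dark frame supplied")
            f = corr.darkcurrent_subtract(f, config.dark)
        if "TI" in steps:
            f = corr.time_normalize(f)
        if config.use_emergent_flux and {"FL", "TR"} <= set(steps):
            f = corr.combined_flux_transmission(f)
        else:
            if "FL" in steps:
                f = corr.flux_normalize(f)
            if "TR" in steps:
                f = corr.transmission_correct(f)
        if "SA" in steps:
            if maps is None:
                raise ConfigurationError("SA enabled but no instrument maps supplied")
            f.meta.require("transmission")
            sa = self_absorption_map(maps.angles, f.meta.transmission)
            f = scale_frame(f, sa, step_code="SA")
        out.append(f)
    if "FA" in steps:
        return average_frames(out, weighted=config.weighted_average,
                              strict=config.strict)
    if len(out) != 1:
        raise ConfigurationError("multiple frames require the FA step")
    return out[0]


def _post_merge_chain(frame: DetectorFrame, config: ProcessConfig,
                      maps: InstrumentMaps) -> DetectorFrame:
    """Apply the once-per-process steps FF/AE/SP/PO then TH/AU."""
    steps = config.resolved_steps()
    if "FF" in steps:
        if config.flatfield is None:
            raise ConfigurationError("FF enabled but no flatfield supplied")
        frame = corr.flatfield_correct(frame, config.flatfield)
    if "AE" in steps:
        if maps.angular_efficiency is None:
            raise ConfigurationError(
                "AE enabled but geometry has no sensor optical depth"
            )
        frame = scale_frame(frame, maps.angular_efficiency)
    if "SP" in steps:
        frame = scale_frame(frame, maps.solid_angle)
    if "PO" in steps:
        frame = scale_frame(frame, maps.polarization)
    if "TH" in steps:
        frame = corr.thickness_normalize(frame)
    if "AU" in steps:
        frame = corr.absolute_scale(frame, config.cal_factor, config.cal_sigma)
    return frame


def _check_container(sample_meta: MeasurementMeta, background: DetectorFrame,
                     what: str) -> None:
    a = sample_meta.container_id
    b = background.meta.container_id
    if a and b and a != b:
        warnings.warn(
            f"container mismatch between sample ({a}) and {what} ({b}); the "
            "same container should be used so its scattering cancels",
            stacklevel=3,
        )


# -- the three processes --------------------------------------------------


def run_process_a(measurements, config: ProcessConfig,
                  maps: InstrumentMaps | None = None) -> DetectorFrame:
    """Reduce the instrumental-background measurement (empty container).

    Applies the measurement-dependent steps (masking through the
    transmission correction, using the container's own transmission)
    and frame averaging.  The result stays an in-memory intermediate
    consumed by Processes B and C at their first merging point.
    """
    if config.role != "A":
        raise ConfigurationError(f"expected a role-A config, got {config.role}")
    if len(measurements) == 0:
        raise ValueError("Process A requires at least one measurement frame")
    return _measurement_chain(measurements, config, maps)


def run_process_b(measurements, background_a: DetectorFrame,
                  config: ProcessConfig, maps: InstrumentMaps) -> DetectorFrame:
    """Reduce a solid sample or pure dispersant to absolute units.

    Runs the per-measurement chain, subtracts the Process-A background,
    then applies the deferred detector/geometry maps and the thickness
    and absolute-intensity scalings.  Output B is the material's (or
    dispersant's) differential scattering cross section in (m sr)^-1.
    """
    if config.role != "B":
        raise ConfigurationError(f"expected a role-B config, got {config.role}")
    steps = config.resolved_steps()
    sample = _measurement_chain(measurements, config, maps)
    if "BG" in steps:
        _check_container(sample.meta, background_a, "Process-A background")
        require = tuple(c for c in ("TI", "FL", "TR") if c in steps)
        sample = subtract_frames(sample, background_a, step_code="BG",
                                 require_steps=require, strict=config.strict)
    return _post_merge_chain(sample, config, maps)


def run_process_c(measurements, background_a: DetectorFrame,
                  dispersant, config: ProcessConfig,
                  maps: InstrumentMaps) -> DetectorFrame:
    """Reduce a dispersion and isolate the analyte's scattering.

    The dispersion measurement goes through the identical chain as
    Process B up to absolute units.  The stored dispersant signal
    (Output B or a library entry; remapped from 1D if necessary) is
    scaled by ``1 - phi`` for the volume displaced by the analyte and
    subtracted, leaving Output C: the absolute scattering cross section
    of the analyte alone.
    """
    if config.role != "C":
        raise ConfigurationError(f"expected a role-C config, got {config.role}")
    steps = config.resolved_steps()
    b_config = ProcessConfig(
        role="B",
        steps=tuple(s for s in steps if s in set(_ROLE_STEPS["B"])),
        strict=config.strict, mask=config.mask, dark=config.dark,
        flatfield=config.flatfield, cal_factor=config.cal_factor,
        cal_sigma=config.cal_sigma, use_emergent_flux=config.use_emergent_flux,
        weighted_average=config.weighted_average,
        enable_self_absorption=config.enable_self_absorption,
    )
    sample = run_process_b(measurements, background_a, b_config, maps)
    sample = sample.evolve(meta=measurements[0].meta)

    # Resolve the dispersant signal.
    if isinstance(dispersant, BackgroundEntry):
        if config.energy_kev is not None:
            rel = abs(dispersant.energy_kev - config.energy_kev) / config.energy_kev
            if rel > ENERGY_RTOL:
                msg = (
                    f"library entry energy {dispersant.energy_kev} keV differs "
                    f"from run energy {config.energy_kev} keV by {rel:.2e} "
                    f"(tolerance {ENERGY_RTOL:.0e})"
                )
                if config.strict:
                    raise ConfigurationError(msg)
                warnings.warn(msg, stacklevel=2)
        payload = dispersant.payload
    else:
        payload = dispersant

    if isinstance(payload, Curve1D):
        if "RM" not in steps:
            raise SequenceError("1D dispersant requires the RM remapping step")
        disp = remap_1d_to_2d(payload, maps.angles)
    else:
        disp = payload
    if disp.units_state != "absolute":
        raise UnitsStateError(
            f"dispersant must be in absolute units, got {disp.units_state}"
        )
    _check_container(sample.meta, disp, "dispersant") if isinstance(
        payload, DetectorFrame) else None

    if "DV" in steps:
        phi = sample.meta.volume_fraction or 0.0
        disp = corr.displaced_volume_scale(
            disp, phi, sample.meta.volume_fraction_sigma
        )
    if "SB" in steps:
        sample = subtract_frames(sample, disp, step_code="SB",
                                 strict=config.strict)
    return sample


def remap_1d_to_2d(curve: Curve1D, maps: AngleMaps) -> DetectorFrame:
    """RM: interpolate a stored isotropic 1D curve back onto the detector.

    Linear interpolation of intensity and uncertainty in Q at every
    pixel's q value.  Pixels outside the curve's populated Q range are
    masked (with a warning); no overlap at all is an error.  Only valid
    for isotropic stored backgrounds.
    """
    if curve.mode != "azimuthal":
        raise RangeError("only azimuthal (I vs Q) curves can be remapped")
    good = (curve.n_pix > 0) & np.isfinite(curve.intensity)
    if good.sum() < 2:
        raise RangeError("curve has fewer than two populated bins")
    qs = curve.abscissa[good]
    iv = curve.intensity[good]
    sv = curve.sigma_prop[good]
    qmap = maps.q
    outside = (qmap < qs[0]) | (qmap > qs[-1])
    if outside.all():
        raise RangeError(
            f"no overlap between curve Q range [{qs[0]:.4g}, {qs[-1]:.4g}] "
            "and the detector q map"
        )
    if outside.any():
        warnings.warn(
            f"{int(outside.sum())} pixels fall outside the stored curve's "
            "Q range and are masked",
            stacklevel=2,
        )
    signal = np.interp(qmap, qs, iv)
    sigma = np.interp(qmap, qs, sv)
    return DetectorFrame(
        signal=signal, uncertainty=sigma, mask=outside,
        meta=MeasurementMeta(role="B"), units_state="absolute",
        provenance=("RM",),
    )


def check_isotropy(frame: DetectorFrame, maps: AngleMaps,
                   nbins: int = 36, nsigma: float = 3.0) -> tuple[bool, float]:
    """Chi-bin dispersion test used before storing a background as 1D.

    Returns ``(isotropic, score)`` where score is the spread of the
    azimuthal profile, ``(max - min) / median sigma``; a frame passes
    when the score is below *nsigma*.
    """
    prof = radial_average(frame, maps, nbins=nbins)
    ok = prof.n_pix > 1
    if ok.sum() < 2:
        return True, 0.0
    spread = float(np.nanmax(prof.intensity[ok]) - np.nanmin(prof.intensity[ok]))
    scale = float(np.nanmedian(prof.sigma[ok]))
    score = spread / scale if scale > 0 else np.inf
    return score < nsigma * 2, score
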