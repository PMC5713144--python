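"""Core data model: detector frames, measurement metadata and the
elementary frame arithmetic every correction step is built from.

A :class:`DetectorFrame` bundles the 2D signal with a same-shaped
uncertainty map, a validity mask (``True`` = invalid pixel), the scalar
measurement metadata and a provenance list of applied step codes.  All
operations are pure: they return a new frame and never mutate their
inputs.  Uncertainties propagate under the assumption that successive
correction steps are statistically independent, so products combine in
relative quadrature and differences in absolute quadrature.

Masked pixels keep their numeric values through every arithmetic step
(they are only excluded from averages and binned statistics); this keeps
each correction an invertible elementwise transform.
"""

from __future__ import annotations

import hashlib
import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

logger = logging.getLogger("saxsred")

from .errors import (
    MetadataError,
    SequenceError,
    ShapeError,
    UnitsStateError,
)

# Canonical order of the twenty elementary steps (data read-in through
# azimuthal averaging), plus SB for the final solvent subtraction merging
# point of Process C, which sits between RM and AV.
STEP_ORDER: tuple[str, ...] = (
    "DS", "MK", "PU", "DT", "DC", "TI", "FL", "TR", "SA", "FA",
    "BG", "FF", "AE", "SP", "PO", "TH", "AU", "DV", "RM", "SB", "AV",
)

#: Units bookkeeping: raw photon counts -> count rate (after TI) ->
#: flux-normalized dimensionless signal (after FL) -> absolute
#: differential scattering cross section in (m sr)^-1 (after AU).
UNITS_STATES: tuple[str, ...] = ("raw_counts", "rate", "normalized", "absolute")

# Steps whose application advances the units state.
_UNITS_TRANSITION = {"TI": "rate", "FL": "normalized", "AU": "absolute"}

_ROLES = ("A", "B", "C")


def _as_2d(a, name: str) -> np.ndarray:
    arr = np.asarray(a)
    if arr.ndim != 2:
        raise ShapeError(f"{name} must be 2D, got ndim={arr.ndim}")
    return arr


@dataclass(frozen=True)
class MeasurementMeta:
    """Scalar per-measurement metadata with optional 1-sigma uncertainties.

    Parameters
    ----------
    time_s : exposure time of one frame, seconds.
    flux_incident : incident flux upstream of the sample, photons/s.
    flux_emergent : emergent flux (transmitted + scattered + diffracted),
        photons/s; used by the combined flux/transmission correction.
    transmission : sample transmission factor T in (0, 1].
    deadtime_s : per-event detector deadtime tau, seconds.
    thickness_m : sample thickness (liquid-phase thickness for
        dispersions), meters.
    volume_fraction : analyte volume fraction phi in [0, 1).
    role : which correction process the measurement feeds ("A", "B", "C").
    container_id : identifier of the sample container, used to enforce
        the same-container rule between processes.
    """

    time_s: float | None = None
    flux_incident: float | None = None
    flux_emergent: float | None = None
    transmission: float | None = None
    deadtime_s: float | None = None
    thickness_m: float | None = None
    volume_fraction: float | None = None
    role: str | None = None
    container_id: str | None = None
    time_sigma: float = 0.0
    flux_incident_sigma: float = 0.0
    flux_emergent_sigma: float = 0.0
    transmission_sigma: float = 0.0
    thickness_sigma: float = 0.0
    volume_fraction_sigma: float = 0.0

    def __post_init__(self) -> None:
        strictly_positive = {
            "time_s": self.time_s,
            "flux_incident": self.flux_incident,
            "flux_emergent": self.flux_emergent,
            "transmission": self.transmission,
            "thickness_m": self.thickness_m,
        }
        for key, value in strictly_positive.items():
            if value is not None and not value > 0:
                raise MetadataError(f"{key} must be strictly positive, got {value}")
        if self.deadtime_s is not None and self.deadtime_s < 0:
            raise MetadataError(f"deadtime_s must be >= 0, got {self.deadtime_s}")
        if self.transmission is not None and self.transmission > 1:
            raise MetadataError(
                f"transmission must be in (0, 1], got {self.transmission}"
            )
        if self.volume_fraction is not None and not (0 <= self.volume_fraction < 1):
            raise MetadataError(
                f"volume_fraction must be in [0, 1), got {self.volume_fraction}"
            )
        if self.role is not None and self.role not in _ROLES:
            raise MetadataError(f"role must be one of {_ROLES}, got {self.role!r}")
        # T = flux_emergent / flux_incident must hold when all three are set.
        if (
            self.transmission is not None
            and self.flux_incident is not None
            and self.flux_emergent is not None
        ):
            implied = self.flux_emergent / self.flux_incident
            if abs(implied - self.transmission) > 1e-9 * self.transmission:
                raise MetadataError(
                    "inconsistent metadata: transmission="
                    f"{self.transmission} but flux_emergent/flux_incident="
                    f"{implied}"
                )

    def require(self, *names: str) -> None:
        """Raise :class:`MetadataError` listing any of *names* that are unset."""
        missing = [n for n in names if getattr(self, n) is None]
        if missing:
            raise MetadataError(f"missing required metadata: {', '.join(missing)}")


@dataclass(frozen=True)
class CorrectionMap:
    """A per-pixel correction factor field.

    ``values`` holds the physical quantity (solid angle in sr,
    polarization factor, efficiency ratio, ...); ``apply`` says whether
    the correction multiplies or divides the signal by it.  ``invalid``
    optionally flags pixels where the correction is singular (for
    example a vanishing polarization factor); those are merged into the
    frame mask when the map is applied.
    """

    values: np.ndarray
    sigma: np.ndarray | None = None
    name: str = ""
    apply: str = "multiply"  # or "divide"
    invalid: np.ndarray | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "values", np.asarray(self.values, dtype=float))
        if self.apply not in ("multiply", "divide"):
            raise ValueError(f"apply must be 'multiply' or 'divide', got {self.apply!r}")
        if self.sigma is not None:
            sig = np.asarray(self.sigma, dtype=float)
            if sig.shape != self.values.shape:
                raise ShapeError("sigma shape does not match values")
            object.__setattr__(self, "sigma", sig)
        if self.invalid is not None:
            inv = np.asarray(self.invalid, dtype=bool)
            if inv.shape != self.values.shape:
                raise ShapeError("invalid shape does not match values")
            object.__setattr__(self, "invalid", inv)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.values.shape

    def factor_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        """Return the multiplicative factor and its sigma, as arrays."""
        v = self.values
        s = self.sigma if self.sigma is not None else np.zeros_like(v)
        if self.apply == "divide":
            safe = np.where(v != 0, v, 1.0)
            return 1.0 / safe, s / safe**2
        return v, s


@dataclass(frozen=True)
class DetectorFrame:
    """A 2D detector signal with uncertainty, mask and provenance."""

    signal: np.ndarray
    uncertainty: np.ndarray
    mask: np.ndarray | None = None
    meta: MeasurementMeta = field(default_factory=MeasurementMeta)
    units_state: str = "raw_counts"
    provenance: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        sig = np.asarray(self.signal, dtype=float)
        _as_2d(sig, "signal")
        unc = np.asarray(self.uncertainty, dtype=float)
        if unc.shape != sig.shape:
            raise ShapeError(
                f"uncertainty shape {unc.shape} != signal shape {sig.shape}"
            )
        if np.any(unc < 0):
            raise ValueError("uncertainty must be non-negative everywhere")
        mask = self.mask
        if mask is None:
            mask = np.zeros(sig.shape, dtype=bool)
        else:
            mask = np.asarray(mask, dtype=bool)
            if mask.shape != sig.shape:
                raise ShapeError(f"mask shape {mask.shape} != signal shape {sig.shape}")
        if self.units_state not in UNITS_STATES:
            raise UnitsStateError(f"unknown units_state {self.units_state!r}")
        prov = tuple(self.provenance)
        if len(set(prov)) != len(prov):
            raise SequenceError(f"duplicate step code in provenance {prov}")
        object.__setattr__(self, "signal", sig)
        object.__setattr__(self, "uncertainty", unc)
        object.__setattr__(self, "mask", mask)
        object.__setattr__(self, "provenance", prov)

    # -- helpers ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, int]:
        return self.signal.shape

    def has_step(self, code: str) -> bool:
        return code in self.provenance

    def evolve(self, **changes) -> "DetectorFrame":
        return replace(self, **changes)

    def with_step(self, code: str, units_state: str | None = None) -> "DetectorFrame":
        """Return a copy whose provenance records *code*.

        The units state advances when *code* triggers a transition (TI,
        FL, AU) or when *units_state* is given explicitly; transitions
        may only move forward along the raw_counts -> rate -> normalized
        -> absolute ladder.
        """
        if code in self.provenance:
            raise SequenceError(f"step {code} already applied (provenance {self.provenance})")
        if units_state is not None:
            if UNITS_STATES.index(units_state) < UNITS_STATES.index(self.units_state):
                raise UnitsStateError(
                    f"units_state may not move backwards "
                    f"({self.units_state} -> {units_state})"
                )
            new_state = units_state
        else:
            target = _UNITS_TRANSITION.get(code)
            # advance monotonically: a commuted scalar step never regresses
            # a state already reached
            new_state = self.units_state
            if target and UNITS_STATES.index(target) > UNITS_STATES.index(new_state):
                new_state = target
        return replace(self, units_state=new_state, provenance=self.provenance + (code,))


def zeros_like(frame: DetectorFrame) -> DetectorFrame:
    """An all-zero frame (zero uncertainty) matching *frame*'s shape and state."""
    z = np.zeros(frame.shape)
    return DetectorFrame(
        z, z.copy(), frame.mask.copy(),
        meta=frame.meta, units_state=frame.units_state, provenance=frame.provenance,
    )


# -- elementary operations ------------------------------------------------


def apply_mask(frame: DetectorFrame, mask) -> DetectorFrame:
    """MK: union the given invalid-pixel mask into the frame.

    Signal values under the mask are preserved but flagged; no operation
    downstream ever unmasks a pixel.
    """
    new = np.asarray(mask, dtype=bool)
    if new.shape != frame.shape:
        raise ShapeError(f"mask shape {new.shape} != frame shape {frame.shape}")
    out = frame.evolve(mask=frame.mask | new)
    return out.with_step("MK") if not out.has_step("MK") else out


def subtract_frames(
    a: DetectorFrame,
    b: DetectorFrame,
    step_code: str = "BG",
    require_steps: Sequence[str] = (),
    strict: bool = False,
) -> DetectorFrame:
    """Subtract frame *b* from *a*, combining uncertainties in quadrature.

    The two frames must be in the same units state.  ``require_steps``
    lists step codes the subtrahend's provenance must contain (the
    measurement-dependent corrections that must precede a background
    subtraction); a violation raises :class:`SequenceError` in strict
    mode and warns otherwise.
    """
    if a.shape != b.shape:
        raise ShapeError(f"frame shapes differ: {a.shape} vs {b.shape}")
    if a.units_state != b.units_state:
        raise UnitsStateError(
            f"units_state mismatch: {a.units_state} vs {b.units_state}"
        )
    missing = [c for c in require_steps if not b.has_step(c)]
    if missing:
        msg = f"subtrahend lacks required correction steps {missing}"
        if strict:
            raise SequenceError(msg)
        warnings.warn(msg, stacklevel=2)
    digest = hashlib.sha256(np.ascontiguousarray(b.signal).tobytes()).hexdigest()
    logger.info("step %s: subtrahend sha256 %s", step_code, digest[:12])
    out = a.evolve(
        signal=a.signal - b.signal,
        uncertainty=np.hypot(a.uncertainty, b.uncertainty),
        mask=a.mask | b.mask,
    )
    return out.with_step(step_code)


def scale_frame(
    frame: DetectorFrame,
    factor,
    sigma=0.0,
    step_code: str | None = None,
) -> DetectorFrame:
    """Multiply the frame by a scalar or per-pixel correction factor.

    This is the shared engine behind every multiplicative step.  The
    propagated uncertainty is the first-order quadrature
    ``sigma_out = sqrt((factor * sigma_I)**2 + (I * sigma_factor)**2)``.

    ``factor`` may be a scalar, a 2D array, or a :class:`CorrectionMap`
    (whose ``apply`` attribute decides multiply vs divide and whose
    ``invalid`` pixels are merged into the mask).
    """
    mask = frame.mask
    if isinstance(factor, CorrectionMap):
        if factor.shape != frame.shape:
            raise ShapeError(f"map shape {factor.shape} != frame shape {frame.shape}")
        if factor.invalid is not None:
            mask = mask | factor.invalid
        fac, sig = factor.factor_arrays()
        if not step_code and factor.name:
            step_code = factor.name
    else:
        fac = np.asarray(factor, dtype=float)
        sig = np.asarray(sigma, dtype=float)
        if fac.ndim not in (0, 2):
            raise ShapeError("factor must be scalar or 2D")
        if fac.ndim == 2 and fac.shape != frame.shape:
            raise ShapeError(f"factor shape {fac.shape} != frame shape {frame.shape}")

    bad = ~np.isfinite(fac) | (fac == 0)
    if fac.ndim == 0:
        if bad:
            raise ValueError(f"scale factor is zero or non-finite: {fac}")
    else:
        bad_unmasked = bad & ~mask
        if np.any(bad_unmasked):
            i, j = np.argwhere(bad_unmasked)[0]
            raise ValueError(
                f"zero or non-finite correction factor at unmasked pixel ({i}, {j})"
            )
        # Masked singular pixels: apply a neutral factor so values survive.
        fac = np.where(bad, 1.0, fac)
        sig = np.where(bad, 0.0, sig) if sig.ndim else sig

    if fac.ndim == 0:
        logger.info("step %s: scalar factor %.9g (sigma %.3g)",
                    step_code or "scale", float(fac), float(sig))
    else:
        digest = hashlib.sha256(np.ascontiguousarray(fac).tobytes()).hexdigest()
        logger.info("step %s: map factor sha256 %s", step_code or "scale",
                    digest[:12])

    out = frame.evolve(
        signal=frame.signal * fac,
        uncertainty=np.hypot(fac * frame.uncertainty, frame.signal * sig),
        mask=mask,
    )
    if step_code:
        out = out.with_step(step_code)
    return out


def average_frames(frames: Sequence[DetectorFrame], weighted: bool = True,
                   strict: bool = False) -> DetectorFrame:
    """FA: merge repeated exposures into one frame.

    With ``weighted=True`` (default) each pixel is the inverse-variance
    weighted mean over the frames in which it is unmasked, giving a high
    dynamic range merge of frames with different exposure times; the
    combined uncertainty is ``(sum of weights)**-1/2``.  Pixels masked in
    every frame stay masked (their plain mean value is carried).  All
    frames must share provenance, so that mixed-exposure merging happens
    only after time normalization.
    """
    if len(frames) == 0:
        raise ValueError("average_frames requires at least one frame")
    first = frames[0]
    if len(frames) == 1:
        return first.with_step("FA")
    for f in frames[1:]:
        if f.shape != first.shape:
            raise ShapeError("frames to average must share dimensions")
        if f.provenance != first.provenance:
            msg = (
                f"provenance mismatch in frame averaging: {f.provenance} "
                f"vs {first.provenance}"
            )
            if strict:
                raise SequenceError(msg)
            warnings.warn(msg, stacklevel=2)
        if f.units_state != first.units_state:
            raise UnitsStateError("frames to average must share units_state")

    sig = np.stack([f.signal for f in frames])
    unc = np.stack([f.uncertainty for f in frames])
    msk = np.stack([f.mask for f in frames])
    valid = ~msk
    n_valid = valid.sum(axis=0)
    all_masked = n_valid == 0
    plain_mean = sig.mean(axis=0)

    if weighted:
        with np.errstate(divide="ignore"):
            w = np.where(valid & (unc > 0), 1.0 / np.where(unc > 0, unc, 1.0) ** 2, 0.0)
        # A zero-uncertainty contribution is exact: it dominates the pixel.
        exact = valid & (unc == 0)
        has_exact = exact.any(axis=0)
        wsum = w.sum(axis=0)
        ok = wsum > 0
        mean = np.where(ok, (w * sig).sum(axis=0) / np.where(ok, wsum, 1.0), plain_mean)
        with np.errstate(divide="ignore"):
            err = np.where(ok, 1.0 / np.sqrt(np.where(ok, wsum, 1.0)), 0.0)
        if has_exact.any():
            n_exact = exact.sum(axis=0)
            exact_mean = np.where(
                has_exact, (np.where(exact, sig, 0.0)).sum(axis=0) / np.where(has_exact, n_exact, 1), 0.0
            )
            mean = np.where(has_exact, exact_mean, mean)
            err = np.where(has_exact, 0.0, err)
        if all_masked.any():
            err = np.where(all_masked, np.sqrt((unc**2).mean(axis=0)), err)
    else:
        cnt = np.where(all_masked, len(frames), n_valid)
        use = np.where(all_masked[None], True, valid)
        mean = np.where(use, sig, 0.0).sum(axis=0) / cnt
        err = np.sqrt(np.where(use, unc**2, 0.0).sum(axis=0)) / cnt

    out = first.evolve(signal=mean, uncertainty=err, mask=all_masked)
    return out.with_step("FA")
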