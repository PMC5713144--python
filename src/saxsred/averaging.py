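"""Dimensionality reduction: azimuthal (I vs Q) and radial (I vs chi)
binned averages of corrected 2D frames, with two uncertainty estimators
per bin.

Each bin reports the unweighted mean of its unmasked pixels together
with

* ``sigma_prop`` — the propagated uncertainty of the mean,
  ``sqrt(sum sigma_i**2) / n``, carried forward from the per-pixel
  uncertainty chain, and
* ``sigma_sem`` — the standard error of the mean estimated from the
  in-bin scatter, ``std(values, ddof=1) / sqrt(n)``.

The in-bin mean is unweighted (not inverse-variance) so that
``sigma_sem`` remains an honest scatter estimate; the user is free to
choose the estimator they trust for their instrument, and exports
default to the larger of the two per bin.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .errors import RangeError, SequenceError
from .frames import DetectorFrame
from .geometry import AngleMaps

DEFAULT_NBINS = 100


@dataclass(frozen=True)
class Curve1D:
    """A reduced 1D curve: I vs Q (nm^-1) or I vs chi (rad)."""

    abscissa: np.ndarray          # bin centers
    edges: np.ndarray             # bin edges, len = nbins + 1
    intensity: np.ndarray         # unweighted in-bin mean
    sigma_prop: np.ndarray        # propagated uncertainty of the mean
    sigma_sem: np.ndarray         # standard error from in-bin scatter
    n_pix: np.ndarray             # contributing unmasked pixels per bin
    mode: str = "azimuthal"       # "azimuthal" (vs Q) or "radial" (vs chi)
    units: str = ""               # intensity units label

    def __post_init__(self) -> None:
        if not np.all(np.diff(self.abscissa) > 0):
            raise ValueError("abscissa must be strictly increasing")
        if np.any(self.sigma_prop[self.n_pix > 0] < 0):
            raise ValueError("sigma_prop must be non-negative")

    @property
    def empty(self) -> np.ndarray:
        """Boolean flag per bin: no contributing pixels."""
        return self.n_pix == 0

    @property
    def sigma(self) -> np.ndarray:
        """Default reported uncertainty: the larger estimator per bin
        (sigma_sem is ignored where undefined)."""
        sem = np.where(np.isnan(self.sigma_sem), 0.0, self.sigma_sem)
        return np.maximum(self.sigma_prop, sem)


def _binned_stats(values, sigmas, bin_index, nbins):
    """Per-bin count, unweighted mean, propagated sigma and SEM."""
    n = np.bincount(bin_index, minlength=nbins).astype(float)
    s1 = np.bincount(bin_index, weights=values, minlength=nbins)
    s2 = np.bincount(bin_index, weights=values**2, minlength=nbins)
    sv = np.bincount(bin_index, weights=sigmas**2, minlength=nbins)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.where(n > 0, n, 1), np.nan)
        prop = np.where(n > 0, np.sqrt(sv) / np.where(n > 0, n, 1), np.nan)
        # sample variance via the two-pass-equivalent sum formula
        var = np.where(n > 1, (s2 - n * mean**2) / np.where(n > 1, n - 1, 1), np.nan)
        var = np.clip(var, 0.0, None)  # guard tiny negative round-off
        sem = np.where(n > 1, np.sqrt(var / np.where(n > 0, n, 1)), np.nan)
    return n.astype(int), mean, prop, sem


def _check_past_background(frame: DetectorFrame, strict: bool) -> None:
    if not frame.has_step("BG"):
        msg = (
            "averaging before background subtraction: anisotropic background "
            "components inflate the in-bin scatter estimate"
        )
        if strict:
            raise SequenceError(msg)
        warnings.warn(msg, stacklevel=3)


def default_q_edges(frame: DetectorFrame, maps: AngleMaps,
                    nbins: int = DEFAULT_NBINS, log: bool = False) -> np.ndarray:
    """Linear (default) or log-spaced bin edges spanning the unmasked q range."""
    q = maps.q[~frame.mask]
    if q.size == 0:
        raise RangeError("no unmasked pixels to derive a q range from")
    lo, hi = float(q.min()), float(q.max())
    if log:
        lo = max(lo, hi * 1e-6)
        return np.geomspace(lo, hi, nbins + 1)
    return np.linspace(lo, hi, nbins + 1)


def azimuthal_average(frame: DetectorFrame, maps: AngleMaps,
                      q_edges: np.ndarray | None = None,
                      nbins: int = DEFAULT_NBINS,
                      strict: bool = False) -> Curve1D:
    """Reduce a frame to I(Q) by averaging over azimuth in Q bins.

    Suitable for isotropic scattering.  Pixels are assigned to bins by
    their center q value; masked pixels never contribute.  Performed
    after the background subtraction so anisotropic background features
    (flares) are removed in 2D first.
    """
    _check_past_background(frame, strict)
    if q_edges is None:
        q_edges = default_q_edges(frame, maps, nbins)
    q_edges = np.asarray(q_edges, dtype=float)
    nb = len(q_edges) - 1
    sel = ~frame.mask
    if not sel.any():
        raise RangeError("all pixels are masked; nothing to average")
    q = maps.q[sel]
    idx = np.searchsorted(q_edges, q, side="right") - 1
    idx = np.where(q == q_edges[-1], nb - 1, idx)  # top edge inclusive
    keep = (idx >= 0) & (idx < nb)
    n, mean, prop, sem = _binned_stats(
        frame.signal[sel][keep], frame.uncertainty[sel][keep], idx[keep], nb
    )
    centers = 0.5 * (q_edges[:-1] + q_edges[1:])
    units = "(m sr)^-1" if frame.units_state == "absolute" else frame.units_state
    return Curve1D(centers, q_edges, mean, prop, sem, n, mode="azimuthal",
                   units=units)


def radial_average(frame: DetectorFrame, maps: AngleMaps,
                   chi_edges: np.ndarray | None = None,
                   q_range: tuple[float, float] = (0.0, np.inf),
                   nbins: int = 36,
                   strict: bool = False) -> Curve1D:
    """Reduce a frame to I(chi) over a restricted q annulus.

    Typically applied to anisotropic data over a limited radial range
    to extract a degree of orientation (e.g. fibre patterns).
    """
    _check_past_background(frame, strict)
    qlo, qhi = q_range
    if not qhi > qlo:
        raise RangeError(f"empty q range {q_range}")
    if chi_edges is None:
        chi_edges = np.linspace(-np.pi, np.pi, nbins + 1)
    chi_edges = np.asarray(chi_edges, dtype=float)
    nb = len(chi_edges) - 1
    sel = ~frame.mask & (maps.q >= qlo) & (maps.q <= qhi)
    if not sel.any():
        raise RangeError(f"no unmasked pixels with q in {q_range}")
    chi = maps.chi[sel]
    idx = np.searchsorted(chi_edges, chi, side="right") - 1
    idx = np.where(chi == chi_edges[-1], nb - 1, idx)
    keep = (idx >= 0) & (idx < nb)
    n, mean, prop, sem = _binned_stats(
        frame.signal[sel][keep], frame.uncertainty[sel][keep], idx[keep], nb
    )
    centers = 0.5 * (chi_edges[:-1] + chi_edges[1:])
    units = "(m sr)^-1" if frame.units_state == "absolute" else frame.units_state
    return Curve1D(centers, chi_edges, mean, prop, sem, n, mode="radial",
                   units=units)
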