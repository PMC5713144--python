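import numpy as np
import pytest

from saxsred import (
    DetectorFrame,
    Geometry,
    MeasurementMeta,
    make_default_truth,
)
from saxsred.synthetic import dark_frame


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture()
def geometry():
    """Small-detector instrument: 1 m, 172 um pixels, 0.1 nm photons."""
    return Geometry(
        distance_m=1.0,
        pixel_pitch_m=(172e-6, 172e-6),
        beam_center=(31.5, 31.5),
        wavelength_nm=0.1,
        sensor_optical_depth=1.0,
        polarization_fraction=0.95,
    )


def make_frame(signal, sigma=None, mask=None, units_state="raw_counts",
               provenance=("DS",), **meta):
    signal = np.asarray(signal, dtype=float)
    if sigma is None:
        sigma = np.zeros_like(signal)
    elif np.ndim(sigma) == 0:
        sigma = np.full_like(signal, float(sigma))
    return DetectorFrame(
        signal=signal, uncertainty=np.asarray(sigma, dtype=float), mask=mask,
        meta=MeasurementMeta(**meta), units_state=units_state,
        provenance=tuple(provenance),
    )


@pytest.fixture()
def frame_factory():
    return make_frame


@pytest.fixture(scope="session")
def small_truth():
    """A 64x64, 3-frame instance of the standard synthetic instrument."""
    return make_default_truth(7, shape=(64, 64), n_frames=3)


@pytest.fixture(scope="session")
def small_maps(small_truth):
    return small_truth.maps()


@pytest.fixture(scope="session")
def small_dark(small_truth):
    return dark_frame(small_truth)
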