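"""Measurement-dependent correction steps: counting statistics,
deadtime, dark current, normalizations and the multiplicative algebra
connecting them."""

import itertools

import numpy as np
import pytest

from saxsred import (
    SaturationError,
    SequenceError,
    absolute_scale,
    combined_flux_transmission,
    darkcurrent_subtract,
    deadtime_correct,
    displaced_volume_scale,
    flatfield_correct,
    flux_normalize,
    poisson_uncertainty,
    thickness_normalize,
    time_normalize,
    transmission_correct,
)
from saxsred.frames import CorrectionMap

from conftest import make_frame


class TestPoissonUncertainty:
    def test_sqrt_counts(self):
        f = poisson_uncertainty(make_frame([[100.0, 1e6]]))
        assert f.uncertainty[0, 0] == 10.0
        # 1e6 counts -> 0.1% relative uncertainty
        assert f.uncertainty[0, 1] / f.signal[0, 1] == pytest.approx(1e-3)

    def test_zero_count_floor(self):
        f = poisson_uncertainty(make_frame([[0.0]]))
        assert f.uncertainty[0, 0] == 1.0

    def test_must_precede_rescaling_steps(self):
        f = make_frame([[10.0]], provenance=("DS", "DT"))
        with pytest.raises(SequenceError):
            poisson_uncertainty(f)
        f = make_frame([[10.0]], units_state="rate", provenance=("DS", "TI"))
        with pytest.raises(SequenceError):
            poisson_uncertainty(f)


class TestDeadtime:
    def test_zero_tau_identity(self):
        f = make_frame([[123.0]], sigma=11.0, deadtime_s=0.0, time_s=1.0)
        out = deadtime_correct(f)
        assert out.signal[0, 0] == 123.0
        assert out.uncertainty[0, 0] == 11.0
        assert out.has_step("DT")

    def test_closed_form(self):
        # 1e5 counts in 1 s with tau = 1 us: occupancy 0.1
        f = make_frame([[1e5]], sigma=np.sqrt(1e5), deadtime_s=1e-6, time_s=1.0)
        out = deadtime_correct(f)
        assert out.signal[0, 0] == pytest.approx(111111.111111, rel=1e-10)
        # uncertainty scaled by the same factor
        assert out.uncertainty[0, 0] == pytest.approx(np.sqrt(1e5) / 0.9, rel=1e-12)

    def test_factor_monotone_in_rate(self):
        rates = np.linspace(1e3, 5e5, 20).reshape(1, -1)
        f = make_frame(rates, deadtime_s=1e-6, time_s=1.0)
        out = deadtime_correct(f)
        factors = out.signal / f.signal
        assert np.all(np.diff(factors[0]) > 0)

    def test_saturation_error(self):
        f = make_frame([[9.5e5]], deadtime_s=1e-6, time_s=1.0)
        with pytest.raises(SaturationError, match=r"\(0, 0\)"):
            deadtime_correct(f)


class TestDarkCurrent:
    def test_zero_dark_identity(self):
        f = make_frame([[50.0]], sigma=5.0, time_s=100.0)
        dark = make_frame([[0.0]])
        out = darkcurrent_subtract(f, dark)
        assert out.signal[0, 0] == 50.0
        assert out.uncertainty[0, 0] == 5.0

    def test_rate_times_exposure(self):
        # 0.01 cps dark over 100 s removes exactly one count
        f = make_frame([[50.0]], time_s=100.0)
        dark = make_frame([[0.01]])
        out = darkcurrent_subtract(f, dark)
        assert out.signal[0, 0] == pytest.approx(49.0)

    def test_uncertainty_quadrature(self):
        f = make_frame([[50.0]], sigma=5.0, time_s=100.0)
        dark = make_frame([[0.01]], sigma=0.002)
        out = darkcurrent_subtract(f, dark)
        assert out.uncertainty[0, 0] == pytest.approx(
            np.hypot(5.0, 100.0 * 0.002), rel=1e-12
        )


class TestScalarNormalizations:
    def test_time(self):
        f = make_frame([[200.0]], units_state="raw_counts", time_s=2.0)
        out = time_normalize(f)
        assert out.signal[0, 0] == 100.0
        assert out.units_state == "rate"

    def test_time_uncertainty(self):
        f = make_frame([[200.0]], sigma=0.0, time_s=2.0, time_sigma=0.02)
        out = time_normalize(f)
        # 1% relative clock uncertainty in quadrature with nothing
        assert out.uncertainty[0, 0] / out.signal[0, 0] == pytest.approx(0.01)

    def test_flux(self):
        f = make_frame([[3.0]], units_state="rate", provenance=("DS", "TI"),
                       flux_incident=1e8)
        out = flux_normalize(f)
        assert out.signal[0, 0] == pytest.approx(3e-8, rel=1e-12)
        assert out.units_state == "normalized"

    def test_transmission(self):
        f = make_frame([[1.0]], units_state="normalized",
                       provenance=("DS", "TI", "FL"), transmission=0.3699)
        out = transmission_correct(f)
        assert out.signal[0, 0] == pytest.approx(2.70343, abs=2e-5)

    def test_transmission_accuracy_warning(self):
        f = make_frame([[1.0]], transmission=0.5, transmission_sigma=0.02)
        with pytest.warns(UserWarning, match="strongly"):
            transmission_correct(f)

    def test_thickness(self):
        f = make_frame([[1.0]], thickness_m=1e-3)
        out = thickness_normalize(f)
        assert out.signal[0, 0] == 1000.0

    def test_absolute(self):
        f = make_frame([[2.0]], sigma=0.1, units_state="normalized",
                       provenance=("DS", "TI", "FL"))
        out = absolute_scale(f, 0.37, 0.37 * 0.02)
        assert out.signal[0, 0] == pytest.approx(0.74)
        assert out.units_state == "absolute"
        rel = out.uncertainty[0, 0] / out.signal[0, 0]
        assert rel == pytest.approx(np.hypot(0.05, 0.02), rel=1e-12)


class TestCombinedFluxTransmission:
    def test_equals_sequential(self, rng):
        sig = rng.uniform(10, 1e4, (16, 16))
        meta = dict(flux_incident=1e8, transmission=0.5, flux_emergent=5e7)
        f1 = make_frame(sig, sigma=np.sqrt(sig), units_state="rate",
                        provenance=("DS", "TI"), **meta)
        seq = transmission_correct(flux_normalize(f1))
        comb = combined_flux_transmission(f1)
        np.testing.assert_allclose(comb.signal, seq.signal, rtol=1e-12)
        np.testing.assert_allclose(comb.uncertainty, seq.uncertainty, rtol=1e-12)
        assert comb.has_step("FL") and comb.has_step("TR")
        assert comb.units_state == "normalized"

    def test_identity_and_arithmetic(self):
        f = make_frame([[100.0]], flux_emergent=5e7, flux_incident=1e8,
                       transmission=0.5)
        out = combined_flux_transmission(f)
        assert out.signal[0, 0] == pytest.approx(2e-6, rel=1e-12)


class TestFlatfield:
    def test_unit_flatfield_identity(self):
        f = make_frame(np.full((3, 3), 7.0), sigma=1.0)
        ff = CorrectionMap(values=np.ones((3, 3)), name="FF")
        out = flatfield_correct(f, ff)
        np.testing.assert_array_equal(out.signal, f.signal)

    def test_pixel_sensitivity(self):
        values = np.ones((2, 2))
        values[0, 1] = 1.05
        values = values / values.mean()
        f = make_frame(np.full((2, 2), 100.0))
        out = flatfield_correct(f, CorrectionMap(values=values, name="FF"))
        assert out.signal[0, 1] / out.signal[0, 0] == pytest.approx(1.05)

    def test_renormalization_warning(self):
        f = make_frame(np.ones((2, 2)))
        ff = CorrectionMap(values=np.full((2, 2), 1.5), name="FF")
        with pytest.warns(UserWarning, match="renormaliz"):
            out = flatfield_correct(f, ff)
        np.testing.assert_allclose(out.signal, 1.0)

    def test_nonpositive_rejected(self):
        f = make_frame(np.ones((2, 2)))
        values = np.ones((2, 2))
        values[1, 1] = -0.5
        with pytest.raises(ValueError, match=r"\(1, 1\)"):
            flatfield_correct(f, CorrectionMap(values=values, name="FF"))

    def test_flatfield_uncertainty_adds_in_quadrature(self):
        f = make_frame(np.full((2, 2), 100.0), sigma=0.0)
        ff = CorrectionMap(values=np.ones((2, 2)), sigma=np.full((2, 2), 0.01),
                           name="FF")
        out = flatfield_correct(f, ff)
        assert np.all(out.uncertainty / out.signal >= 0.01 - 1e-15)


class TestDisplacedVolume:
    def test_identity_at_zero(self):
        f = make_frame([[40.0]], role="B")
        out = displaced_volume_scale(f, 0.0)
        assert out.signal[0, 0] == 40.0

    def test_proportional_reduction(self):
        f = make_frame([[40.0]], role="B")
        out = displaced_volume_scale(f, 0.3)
        assert out.signal[0, 0] == pytest.approx(28.0)

    def test_uncertainty_contribution(self):
        f = make_frame([[40.0]], sigma=0.0, role="B")
        out = displaced_volume_scale(f, 0.3, 0.03)
        assert out.uncertainty[0, 0] / out.signal[0, 0] == pytest.approx(
            0.03 / 0.7, rel=1e-12
        )

    def test_rejected_on_dispersion_frame(self):
        f = make_frame([[40.0]], role="C")
        with pytest.raises(SequenceError):
            displaced_volume_scale(f, 0.1)


def test_scalar_steps_commute():
    """TI, FL, TR, TH, AU applied in any order agree to float precision."""
    meta = dict(time_s=2.0, flux_incident=1e8, transmission=0.5,
                thickness_m=1e-3)
    ops = {
        "TI": time_normalize,
        "FL": flux_normalize,
        "TR": transmission_correct,
        "TH": thickness_normalize,
        "AU": lambda fr: absolute_scale(fr, 0.37),
    }
    results = []
    for order in itertools.permutations(ops):
        f = make_frame([[1000.0]], sigma=10.0, **meta)
        for code in order:
            f = ops[code](f)
        results.append((f.signal[0, 0], f.uncertainty[0, 0]))
    base = results[0]
    for r in results[1:]:
        assert r[0] == pytest.approx(base[0], rel=5e-15)
        assert r[1] == pytest.approx(base[1], rel=5e-15)
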