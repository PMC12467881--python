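"""Response estimation, grid alignment, and the H-to-L transfer correction."""

import numpy as np
import pytest

from libsbridge.correction import (
    CorrectionError,
    ResponseFunction,
    apply_correction,
    build_transfer,
    estimate_response,
    interp_align,
)
from libsbridge.simulate import (
    high_res_instrument,
    lamp_reference,
    low_res_instrument,
    simulate_lamp,
)
from libsbridge.spectra import Spectrum


def brute_force_interp(x, y, q):
    """Independent two-point interpolation oracle, interval by interval."""
    out = np.empty(len(q))
    for i, qi in enumerate(q):
        j = np.searchsorted(x, qi)
        if x[min(j, len(x) - 1)] == qi:
            out[i] = y[min(j, len(x) - 1)]
            continue
        j = max(j, 1)
        t = (qi - x[j - 1]) / (x[j] - x[j - 1])
        out[i] = (1 - t) * y[j - 1] + t * y[j]
    return out


class TestInterpAlign:
    def test_exact_on_linear_signal(self, rng):
        x = np.sort(rng.uniform(300, 800, 40))
        s = Spectrum(x, 3.0 * x + 1.0)
        q = np.sort(rng.uniform(x[0], x[-1], 100))
        out = interp_align(s, q)
        np.testing.assert_allclose(out.intensities, 3.0 * q + 1.0, atol=1e-10)

    def test_identity_on_same_grid(self, simple_spectrum):
        out = interp_align(simple_spectrum, simple_spectrum.wavelengths)
        np.testing.assert_array_equal(out.intensities, simple_spectrum.intensities)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(20):
            x = np.sort(rng.uniform(0, 100, rng.integers(5, 40)))
            x = np.unique(x)
            if x.size < 3:
                continue
            y = rng.normal(size=x.size)
            q = np.sort(rng.uniform(x[0], x[-1], 50))
            out = interp_align(Spectrum(x, y), q)
            np.testing.assert_allclose(
                out.intensities, brute_force_interp(x, y, q), atol=1e-12
            )

    def test_extrapolation_refused(self, simple_spectrum):
        with pytest.raises(CorrectionError, match="outside source support"):
            interp_align(simple_spectrum, [250.0, 350.0])


class TestEstimateResponse:
    def test_identity_when_measured_equals_reference(self):
        ref = lamp_reference()
        r = estimate_response(ref, ref)
        np.testing.assert_allclose(r.values, 1.0, atol=1e-12)

    def test_ratio_half_for_doubled_measurement(self):
        ref = lamp_reference()
        meas = ref.copy()
        meas.intensities = 2.0 * ref.intensities
        r = estimate_response(ref, meas)
        np.testing.assert_allclose(r.values, 0.5, atol=1e-12)

    @pytest.mark.parametrize("model_fn", [low_res_instrument, high_res_instrument])
    def test_recovers_inverse_response_no_noise(self, model_fn):
        model = model_fn().with_(sigma_add=0.0, sigma_prop=0.0)
        ref = lamp_reference()
        r = estimate_response(ref, simulate_lamp(model, ref))
        truth = 1.0 / model.response(r.wavelengths)
        scale = np.median(r.values / truth)
        np.testing.assert_allclose(r.values, scale * truth, rtol=1e-6)

    def test_masked_floor_points_filled(self):
        lam = np.linspace(400.0, 500.0, 101)
        ref = Spectrum(lam, np.full(101, 2.0))
        meas_vals = np.full(101, 4.0)
        meas_vals[50] = 0.0  # dead pixel
        r = estimate_response(ref, Spectrum(lam, meas_vals))
        np.testing.assert_allclose(r.values, 0.5, atol=1e-9)

    def test_too_many_masked_errors(self):
        lam = np.linspace(400.0, 500.0, 11)
        ref = Spectrum(lam, np.ones(11))
        meas = Spectrum(lam, np.r_[np.zeros(5), np.ones(6)])
        with pytest.raises(CorrectionError, match="floor"):
            estimate_response(ref, meas)

    def test_smoothing_preserves_monotone_response(self):
        model = low_res_instrument().with_(sigma_add=0.0, sigma_prop=0.0)
        ref = lamp_reference()
        r = estimate_response(ref, simulate_lamp(model, ref), smooth=True)
        truth = 1.0 / model.response(r.wavelengths)
        scale = np.median(r.values / truth)
        np.testing.assert_allclose(r.values, scale * truth, rtol=1e-4)


class TestBuildTransfer:
    def test_equal_responses_give_unity(self):
        lam = np.linspace(350.0, 850.0, 200)
        r = ResponseFunction(lam, 1.0 + lam / 1000.0, (350.0, 850.0))
        t = build_transfer(r, r)
        np.testing.assert_allclose(t.values, 1.0, atol=1e-12)

    def test_ratio_algebra(self):
        lam = np.linspace(350.0, 850.0, 200)
        rl = ResponseFunction(lam, np.ones(200), (350.0, 850.0))
        eta = 0.5 + lam / 2000.0
        rh = ResponseFunction(lam, 1.0 / eta, (350.0, 850.0))
        t = build_transfer(rl, rh)
        np.testing.assert_allclose(t.values, 1.0 / eta, rtol=1e-9)

    def test_clipped_to_range(self):
        ref = lamp_reference()
        low = low_res_instrument().with_(sigma_add=0.0, sigma_prop=0.0)
        high = high_res_instrument().with_(sigma_add=0.0, sigma_prop=0.0)
        rl = estimate_response(ref, simulate_lamp(low, ref))
        rh = estimate_response(ref, simulate_lamp(high, ref))
        t = build_transfer(rl, rh, (350.0, 850.0))
        assert t.valid_range[0] >= 350.0 - 1e-9 and t.valid_range[1] <= 850.0 + 1e-9

    def test_empty_intersection_errors(self):
        a = ResponseFunction([350.0, 400.0], [1.0, 1.0], (350.0, 400.0))
        b = ResponseFunction([500.0, 600.0], [1.0, 1.0], (500.0, 600.0))
        with pytest.raises(CorrectionError, match="intersect"):
            build_transfer(a, b)


class TestApplyCorrection:
    def test_unity_response_restricts_but_preserves(self):
        lam = np.linspace(300.0, 900.0, 601)
        s = Spectrum(lam, np.sin(lam / 30.0) + 2.0)
        r = ResponseFunction(
            np.linspace(350.0, 850.0, 100), np.ones(100), (350.0, 850.0)
        )
        out = apply_correction(s, r)
        assert out.wavelengths[0] >= 350.0 and out.wavelengths[-1] <= 850.0
        mask = (lam >= out.wavelengths[0]) & (lam <= out.wavelengths[-1])
        np.testing.assert_allclose(out.intensities, s.intensities[mask], rtol=1e-12)

    def test_linear_in_intensity(self):
        lam = np.linspace(400.0, 800.0, 301)
        r = ResponseFunction(lam, 2.0 * np.ones(301), (400.0, 800.0))
        s = Spectrum(lam, np.cos(lam / 50.0) + 3.0)
        out = apply_correction(s, r)
        np.testing.assert_allclose(out.intensities, 2.0 * s.intensities, rtol=1e-12)

    def test_no_overlap_errors(self):
        s = Spectrum([100.0, 200.0], [1.0, 1.0])
        r = ResponseFunction([300.0, 400.0], [1.0, 1.0], (300.0, 400.0))
        with pytest.raises(CorrectionError, match="overlap"):
            apply_correction(s, r)


class TestRoundTrip:
    """Flat-source consistency: corrected high-res equals low-res measurement."""

    def _flat_source(self):
        lam = np.linspace(340.0, 1010.0, 700)
        return Spectrum(lam, np.full(700, 5.0))

    def test_corrected_flat_source_matches_low_res(self):
        ref = lamp_reference()
        low = low_res_instrument().with_(sigma_add=0.0, sigma_prop=0.0)
        high = high_res_instrument().with_(sigma_add=0.0, sigma_prop=0.0)
        rl = estimate_response(ref, simulate_lamp(low, ref))
        rh = estimate_response(ref, simulate_lamp(high, ref))
        transfer = build_transfer(rl, rh, (350.0, 850.0))

        flat = self._flat_source()
        meas_h = simulate_lamp(high, flat)  # a flat broadband source
        meas_l = simulate_lamp(low, flat)
        corrected = apply_correction(meas_h, transfer)
        target = interp_align(meas_l, corrected.wavelengths)
        scale = np.median(corrected.intensities / target.intensities)
        resid = corrected.intensities / (scale * target.intensities) - 1.0
        assert np.sqrt(np.mean(resid**2)) < 0.02

    def test_normalization_invariant_to_global_response_scale(self):
        from libsbridge.spectra import minmax_normalize

        lam = np.linspace(400.0, 800.0, 301)
        s = Spectrum(lam, np.cos(lam / 40.0) ** 2 + 0.5)
        r1 = ResponseFunction(lam, 1.0 + lam / 1000.0, (400.0, 800.0))
        r7 = ResponseFunction(lam, 7.0 * (1.0 + lam / 1000.0), (400.0, 800.0))
        a = minmax_normalize(apply_correction(s, r1))
        b = minmax_normalize(apply_correction(s, r7))
        np.testing.assert_allclose(a.intensities, b.intensities, atol=1e-12)
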