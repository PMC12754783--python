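"""CD conversion and melting-curve processing against the two-state
generator's ground truth."""

import numpy as np
import pytest

from g4screen.constants import CD_CONVERSION
from g4screen.optical import (
    Baselines,
    CDSpectrum,
    MeltingCurve,
    delta_tm,
    fit_baselines,
    folded_fraction,
    hysteresis,
    melting_temperature,
    molar_ellipticity,
)
from g4screen.synthetic import SimConfig, simulate_cd, simulate_melting


class TestMolarEllipticity:
    def test_unit_case(self):
        c, l = 1e-5, 0.2
        spec = CDSpectrum(
            wavelength_nm=np.array([260.0, 265.0]),
            ellipticity_mdeg=np.array([CD_CONVERSION * c * l, 0.0]),
            c_molar=c, path_cm=l,
        )
        d_eps = molar_ellipticity(spec)
        assert d_eps[0] == pytest.approx(1.0)
        assert d_eps[1] == 0.0

    def test_direct_evaluation(self):
        # theta = 10 mdeg, c = 10 uM, l = 0.2 cm
        spec = CDSpectrum(
            wavelength_nm=np.array([264.0]),
            ellipticity_mdeg=np.array([10.0]),
            c_molar=10e-6, path_cm=0.2,
        )
        assert molar_ellipticity(spec)[0] == pytest.approx(
            10.0 / (32980.0 * 1e-5 * 0.2)
        )

    def test_invalid_concentration_rejected(self):
        with pytest.raises(ValueError):
            CDSpectrum(np.array([260.0]), np.array([1.0]), c_molar=0.0,
                       path_cm=1.0)

    def test_linearity_in_theta_and_inverse_in_c_l(self, rng):
        wl = np.linspace(220, 320, 50)
        theta = rng.normal(0, 5, 50)
        for c, l, k in [(1e-5, 0.2, 3.0), (2e-5, 1.0, 0.5)]:
            base = molar_ellipticity(
                CDSpectrum(wl, theta, c_molar=c, path_cm=l)
            )
            scaled = molar_ellipticity(
                CDSpectrum(wl, k * theta, c_molar=c, path_cm=l)
            )
            np.testing.assert_allclose(scaled, k * base)
            halved_c = molar_ellipticity(
                CDSpectrum(wl, theta, c_molar=c / 2, path_cm=l)
            )
            np.testing.assert_allclose(halved_c, 2 * base)


class TestBaselinesAndFoldedFraction:
    def test_perfect_linear_flanks_exact(self):
        curve, ledger = simulate_melting(t_m_C=55.0, enthalpy_kJ=300.0)
        bl = fit_baselines(curve)
        truth = ledger["baselines"]
        assert bl.L0[0] == pytest.approx(truth.L0[0], rel=0.01, abs=1e-3)
        assert bl.L1[0] == pytest.approx(truth.L1[0], rel=0.01, abs=1e-3)

    def test_windows_inside_transition_warn(self):
        curve, _ = simulate_melting(t_m_C=55.0, enthalpy_kJ=300.0)
        with pytest.warns(UserWarning, match="baseline fit"):
            fit_baselines(curve, low_window=(30.0, 54.0),
                          high_window=(56.0, 80.0))

    def test_overlapping_windows_rejected(self):
        curve, _ = simulate_melting()
        with pytest.raises(ValueError, match="overlap"):
            fit_baselines(curve, low_window=(4.0, 50.0),
                          high_window=(40.0, 90.0))

    @pytest.mark.parametrize("which,expected", [("L0", 0.0), ("L1", 1.0)])
    def test_absorbance_on_baseline(self, which, expected):
        T = np.linspace(10, 80, 100)
        bl = Baselines(L0=(0.3, 0.001), L1=(0.6, -0.001))
        A = bl.l0_at(T) if which == "L0" else bl.l1_at(T)
        curve = MeltingCurve(temperature_C=T, absorbance=A)
        ffc = folded_fraction(curve, bl)
        np.testing.assert_allclose(ffc.theta, expected, atol=1e-12)

    def test_midpoint_gives_half(self):
        T = np.linspace(10, 80, 100)
        bl = Baselines(L0=(0.3, 0.001), L1=(0.6, -0.001))
        A = 0.5 * (bl.l0_at(T) + bl.l1_at(T))
        ffc = folded_fraction(MeltingCurve(T, A), bl)
        np.testing.assert_allclose(ffc.theta, 0.5, atol=1e-12)

    def test_identical_baselines_rejected(self):
        T = np.linspace(10, 80, 100)
        bl = Baselines(L0=(0.3, 0.0), L1=(0.3, 0.0))
        with pytest.raises(ValueError, match="intersect"):
            folded_fraction(MeltingCurve(T, np.full(100, 0.3)), bl)

    def test_generator_theta_recovered_exactly_with_true_baselines(self):
        curve, ledger = simulate_melting(t_m_C=50.0, enthalpy_kJ=250.0)
        ffc = folded_fraction(curve, ledger["baselines"])
        np.testing.assert_allclose(ffc.theta, ledger["theta"], atol=1e-12)


class TestMeltingTemperature:
    def test_tm_55_recovered_within_0p2C(self):
        curve, _ = simulate_melting(t_m_C=55.0, enthalpy_kJ=200.0)
        res = melting_temperature(folded_fraction(curve, fit_baselines(curve)))
        assert res.t_m == pytest.approx(55.0, abs=0.2)

    def test_no_crossing_undetermined(self):
        T = np.linspace(10, 80, 100)
        bl = Baselines(L0=(0.3, 0.0), L1=(0.6, 0.0))
        A = bl.l1_at(T) - 0.03  # theta stays near 1, never 0.5
        res = melting_temperature(folded_fraction(MeltingCurve(T, A), bl))
        assert res.t_m is None
        assert res.theta_range[0] > 0.5

    def test_affine_absorbance_invariance(self):
        curve, _ = simulate_melting(t_m_C=60.0, enthalpy_kJ=220.0)
        res_a = melting_temperature(
            folded_fraction(curve, fit_baselines(curve))
        )
        scaled = MeltingCurve(
            temperature_C=curve.temperature_C,
            absorbance=3.0 * curve.absorbance + 0.7,
            wavelength_nm=curve.wavelength_nm,
        )
        res_b = melting_temperature(
            folded_fraction(scaled, fit_baselines(scaled))
        )
        assert res_b.t_m == pytest.approx(res_a.t_m, abs=1e-9)

    def test_reversible_curves_zero_hysteresis(self):
        heat, _ = simulate_melting(t_m_C=55.0, direction="heating")
        cool, _ = simulate_melting(t_m_C=55.0, direction="cooling")
        res_h = melting_temperature(folded_fraction(heat, fit_baselines(heat)))
        res_c = melting_temperature(folded_fraction(cool, fit_baselines(cool)))
        assert hysteresis(res_h, res_c) == pytest.approx(0.0, abs=0.05)

    def test_biphasic_curve_flags_multimodal(self):
        c1, _ = simulate_melting(t_m_C=40.0, enthalpy_kJ=400.0)
        c2, _ = simulate_melting(t_m_C=70.0, enthalpy_kJ=400.0)
        T = c1.temperature_C
        mixed = MeltingCurve(T, 0.5 * (c1.absorbance + c2.absorbance))
        bl = fit_baselines(mixed)
        ffc = folded_fraction(mixed, bl)
        # the mixture crosses 0.5 once but its derivative is bimodal; force
        # a doubly-crossing curve by adding a ripple around theta ~ 0.5
        ripple = 0.04 * np.exp(-0.5 * ((T - 55.0) / 1.5) ** 2)
        wavy = MeltingCurve(T, mixed.absorbance + ripple)
        res = melting_temperature(folded_fraction(wavy, bl))
        if res.multimodal:
            assert res.t_m is not None


class TestDeltaTm:
    def test_identical_curves_zero(self):
        curve, _ = simulate_melting(t_m_C=55.0)
        res = melting_temperature(folded_fraction(curve, fit_baselines(curve)))
        assert delta_tm(res, res) == 0.0

    def test_injected_plus_10C_within_0p3(self):
        ref, _ = simulate_melting(t_m_C=50.0, enthalpy_kJ=250.0)
        shifted, _ = simulate_melting(t_m_C=60.0, enthalpy_kJ=250.0)
        res_ref = melting_temperature(folded_fraction(ref, fit_baselines(ref)))
        res_shift = melting_temperature(
            folded_fraction(shifted, fit_baselines(shifted))
        )
        assert delta_tm(res_shift, res_ref) == pytest.approx(10.0, abs=0.3)

    def test_undetermined_reference_propagates(self):
        curve, _ = simulate_melting(t_m_C=55.0)
        res = melting_temperature(folded_fraction(curve, fit_baselines(curve)))
        from g4screen.optical import MeltingResult

        assert delta_tm(res, MeltingResult(t_m=None)) is None


class TestSimulateCd:
    def test_parallel_signature_single_positive_max(self):
        spec, ledger = simulate_cd("parallel")
        d_eps = molar_ellipticity(spec)
        i = np.argmax(d_eps)
        assert 255 <= spec.wavelength_nm[i] <= 275
        assert d_eps.min() < 0  # negative band near 245 nm

    def test_conversion_independent_of_c_and_l(self):
        a = molar_ellipticity(simulate_cd("antiparallel", 1e-5, 0.2)[0])
        b = molar_ellipticity(simulate_cd("antiparallel", 4e-5, 1.0)[0])
        np.testing.assert_allclose(a, b, atol=1e-9)

    def test_seeded_noise_reproducible(self):
        cfg = SimConfig(seed=11, noise_sigma=0.5)
        a, _ = simulate_cd("hybrid", cfg=cfg)
        b, _ = simulate_cd("hybrid", cfg=SimConfig(seed=11, noise_sigma=0.5))
        np.testing.assert_array_equal(a.ellipticity_mdeg, b.ellipticity_mdeg)
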