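import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from memion.electrostatics import (
    AdsorptionParams,
    BoundaryPotentialCurve,
    ElectrolyteConditions,
    IFCScan,
    adsorption_curve,
    debye_huckel_psi,
    estimate_phi_in,
    fit_adsorption,
    grahame_psi,
    grahame_sigma,
    nonactin_delta_phi,
)
from memion.errors import FitError, RangeError

COND = ElectrolyteConditions()  # 20 mM, 295 K, eps_r 80


class TestGrahame:
    def test_neutral_surface_zero_potential(self):
        assert grahame_psi(0.0, COND) == 0.0

    def test_odd_and_increasing(self):
        sigmas = np.linspace(-0.5, 0.5, 21)
        psis = np.array([grahame_psi(s, COND) for s in sigmas])
        np.testing.assert_allclose(psis, -psis[::-1], atol=1e-12)
        assert np.all(np.diff(psis) > 0)

    def test_debye_huckel_limit_within_one_percent(self):
        # linear regime: |psi| < 10 mV
        for sigma in (0.001, 0.005, 0.02, -0.02):
            full = grahame_psi(sigma, COND)
            lin = debye_huckel_psi(sigma, COND)
            assert abs(full) < 10.0
            assert abs(full - lin) / abs(lin) < 0.01

    def test_small_sigma_slope_is_diffuse_layer_capacitance(self):
        eps = 1e-8
        slope = grahame_psi(eps, COND) / eps
        lin = debye_huckel_psi(1.0, COND)
        assert slope == pytest.approx(lin, rel=1e-6)

    @given(st.floats(-1.0, 1.0))
    @settings(deadline=None, max_examples=50)
    def test_round_trip_inverse(self, sigma):
        back = grahame_sigma(grahame_psi(sigma, COND), COND)
        assert back == pytest.approx(sigma, rel=1e-10, abs=1e-12)

    def test_non_finite_sigma_rejected(self):
        with pytest.raises(ValueError):
            grahame_psi(float("nan"), COND)


CATION = AdsorptionParams(binding_constant=1e5, max_site_density=0.05,
                          surfactant_valence=1)
ANION = AdsorptionParams(binding_constant=1e5, max_site_density=0.05,
                         surfactant_valence=-1)
CONC = np.geomspace(1.0, 100.0, 8)


class TestAdsorptionCurve:
    def test_vanishing_concentration_vanishing_potential(self):
        phi = adsorption_curve(CATION, COND, [1e-6]).delta_phi_mV[0]
        assert abs(phi) < 1e-3

    def test_monotone_in_concentration(self):
        curve = adsorption_curve(CATION, COND, CONC)
        assert np.all(np.diff(curve.delta_phi_mV) > 0)
        assert np.all(curve.delta_phi_mV > 0)

    def test_anionic_curve_is_sign_mirror(self):
        up = adsorption_curve(CATION, COND, CONC).delta_phi_mV
        dn = adsorption_curve(ANION, COND, CONC).delta_phi_mV
        np.testing.assert_allclose(dn, -up, atol=1e-9)

    def test_strong_binding_saturates_at_full_coverage(self):
        strong = AdsorptionParams(binding_constant=1e12, max_site_density=0.05,
                                  surfactant_valence=1)
        phi = adsorption_curve(strong, COND, [10.0]).delta_phi_mV[0]
        assert phi == pytest.approx(grahame_psi(0.05, COND), rel=1e-4)

    def test_feedback_lowers_cationic_adsorption(self):
        with_fb = adsorption_curve(CATION, COND, CONC).delta_phi_mV
        without = adsorption_curve(CATION, COND, CONC, feedback=False).delta_phi_mV
        # electrostatic repulsion depletes the subsurface concentration
        assert np.all(with_fb < without)


class TestFitAdsorption:
    def test_noise_free_self_consistency(self):
        curve = adsorption_curve(CATION, COND, CONC)
        fit = fit_adsorption(curve, COND, valence=1)
        assert fit.identifiable and fit.converged
        assert fit.params.binding_constant == pytest.approx(1e5, rel=1e-4)
        assert fit.params.max_site_density == pytest.approx(0.05, rel=1e-4)

    def test_noisy_recovery_median_error(self):
        truth = adsorption_curve(CATION, COND, CONC).delta_phi_mV
        rng = np.random.default_rng(77)
        errs = []
        for _ in range(200):
            noisy = BoundaryPotentialCurve(
                CONC, truth * (1 + rng.normal(0, 0.05, len(CONC))), "IFC"
            )
            f = fit_adsorption(noisy, COND, valence=1)
            errs.append(abs(f.params.binding_constant / 1e5 - 1))
        assert np.median(errs) < 0.10

    def test_flat_curve_unidentifiable(self):
        curve = BoundaryPotentialCurve(CONC, np.zeros(len(CONC)), "IFC")
        fit = fit_adsorption(curve, COND, valence=1)
        assert not fit.identifiable
        assert fit.params is None

    def test_too_few_points_rejected(self):
        curve = BoundaryPotentialCurve([1.0, 2.0, 4.0], [1.0, 2.0, 3.0], "IFC")
        with pytest.raises(FitError):
            fit_adsorption(curve, COND, valence=1)


class TestEstimatePhiIn:
    @given(
        st.floats(-80.0, 80.0),
        st.floats(0.1, 10.0),
        st.floats(1e-6, 1e-3),
    )
    @settings(deadline=None, max_examples=60)
    def test_exact_on_noise_free_parabola(self, phi_in, c0, alpha):
        u = np.linspace(phi_in - 100.0, phi_in + 100.0, 21)
        scan = IFCScan(u, c0 * (1 + alpha * (u - phi_in) ** 2))
        est = estimate_phi_in(scan)
        assert est.phi_in_mV == pytest.approx(phi_in, abs=1e-6)
        assert est.c0 == pytest.approx(c0, rel=1e-6)
        assert est.alpha == pytest.approx(alpha, rel=1e-6)

    def test_symmetric_parabola_vertex_zero(self):
        u = np.linspace(-50, 50, 11)
        est = estimate_phi_in(IFCScan(u, 1.0 + 1e-4 * u ** 2))
        assert est.phi_in_mV == pytest.approx(0.0, abs=1e-9)

    def test_noisy_recovery_within_three_standard_errors(self):
        rng = np.random.default_rng(13)
        u = np.linspace(-60, 130, 33)
        hits = 0
        for _ in range(200):
            c = 1.0 * (1 + 2e-5 * (u - 37.0) ** 2)
            c = c * (1 + rng.normal(0, 0.01, len(u)))
            est = estimate_phi_in(IFCScan(u, c))
            hits += abs(est.phi_in_mV - 37.0) < 3 * est.stderr_mV
        assert hits / 200 >= 0.95

    def test_monotone_scan_raises_range_error(self):
        u = np.linspace(0, 100, 11)
        with pytest.raises(RangeError):
            estimate_phi_in(IFCScan(u, 1.0 + 0.01 * u))

    def test_minimum_outside_range_raises(self):
        u = np.linspace(50, 100, 11)
        with pytest.raises(RangeError):
            estimate_phi_in(IFCScan(u, 1.0 + 1e-4 * (u - 0.0) ** 2))

    def test_too_few_points_raises(self):
        with pytest.raises(RangeError):
            estimate_phi_in(IFCScan(np.array([-1.0, 0.0, 1.0]),
                                    np.array([2.0, 1.0, 2.0])))


class TestNonactin:
    def test_equal_conductance_zero_shift(self):
        assert nonactin_delta_phi(3.0, 3.0) == 0.0

    def test_thermal_voltage_at_295K(self):
        # G0/G = e -> RT/F = 8.314 * 295 / 96485 = 25.42 mV
        assert nonactin_delta_phi(1.0, np.e, T=295.0) == pytest.approx(
            25.42, abs=0.005
        )

    @given(st.floats(-200.0, 200.0))
    @settings(deadline=None, max_examples=50)
    def test_inverse_consistency(self, dphi):
        g0 = 5.0
        g = g0 * np.exp(-dphi / 25.421133)
        assert nonactin_delta_phi(g, g0, T=295.0) == pytest.approx(dphi, abs=1e-6)

    def test_nonpositive_conductance_rejected(self):
        with pytest.raises(ValueError):
            nonactin_delta_phi(0.0, 1.0)


class TestEndToEndClosure:
    def test_measurement_model_closure(self):
        """Simulated IFC scans re-analysed end to end recover the parameters."""
        from memion.synthetic import IFCSettings, generate_measurements

        curve, scans, true_curve = generate_measurements(
            CATION, COND, CONC, noise_sd_mV=2.0,
            ifc=IFCSettings(noise_sd=0.01), seed=42,
        )
        ests = [estimate_phi_in(s) for s in scans]
        re_phi = np.array([e.phi_in_mV for e in ests])
        # scan vertices sit at the noisy potentials by construction;
        # capacitance noise leaves an uncertainty the fit itself reports
        for e, phi in zip(ests, curve.delta_phi_mV):
            assert abs(e.phi_in_mV - phi) < 3 * e.stderr_mV
        refit = fit_adsorption(
            BoundaryPotentialCurve(CONC, re_phi, "IFC"), COND, valence=1
        )
        assert refit.identifiable
        assert abs(refit.params.binding_constant / 1e5 - 1) < 0.5
        assert abs(refit.params.max_site_density / 0.05 - 1) < 0.25
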