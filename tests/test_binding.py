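"""Stern-Volmer, isotherm, quenching classification, and thermodynamics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from tmzbind import (
    QuenchTitration,
    bimolecular_rate_constant,
    classify_quenching,
    dissociation_constant,
    fit_binding_isotherm,
    fit_stern_volmer,
    gibbs_free_energy,
    vant_hoff_regression,
    vant_hoff_two_point,
)
from tmzbind.binding import R_GAS
from tmzbind.errors import InsufficientDataError, InvalidParameterError
from tmzbind.simulate import NoiseSpec, gen_quench_titration

CONC_55UM = np.arange(0.0, 56e-6, 5e-6)


class TestSternVolmer:
    def test_recovers_buffer_phase_constant_exactly(self):
        """Noiseless forward data refit to the HSA/buffer K_SV of 4837."""
        t = gen_quench_titration("stern_volmer", {"K_SV": 4837.0}, CONC_55UM)
        fit = fit_stern_volmer(t)
        assert fit.K_SV == pytest.approx(4837.0, rel=1e-6)
        assert fit.intercept == pytest.approx(1.0, rel=1e-9)
        assert not fit.non_quenching

    def test_equal_intensities_give_zero_slope(self):
        t = QuenchTitration(CONC_55UM, np.full(CONC_55UM.size, 500.0))
        assert fit_stern_volmer(t).K_SV == pytest.approx(0.0, abs=1e-9)

    def test_monte_carlo_recovery_within_two_percent(self):
        """200 noisy replicates, sigma = 1% of I0, mean slope near truth."""
        truth = 4837.0
        conc = np.linspace(0.0, 55e-6, 12)
        slopes = [
            fit_stern_volmer(gen_quench_titration(
                "stern_volmer", {"K_SV": truth}, conc,
                noise=NoiseSpec("gaussian_additive", 0.01, seed))).K_SV
            for seed in range(200)
        ]
        assert np.mean(slopes) == pytest.approx(truth, rel=0.02)

    def test_too_few_points_rejected(self):
        t = QuenchTitration(np.array([0.0, 1e-5]), np.array([100.0, 90.0]))
        with pytest.raises(InsufficientDataError):
            fit_stern_volmer(t)

    @given(ksv=st.floats(1e2, 1e5))
    @settings(max_examples=25, deadline=None, derandomize=True)
    def test_noiseless_recovery_across_ksv_range(self, ksv):
        t = gen_quench_titration("stern_volmer", {"K_SV": ksv},
                                 np.linspace(0, 2e-3, 8))
        assert fit_stern_volmer(t).K_SV == pytest.approx(ksv, rel=1e-6)


class TestQuenchingMechanism:
    def test_rate_constant_from_hsa_water_ksv(self):
        """K_SV = 5248 over tau0 = 6.4 ns gives the printed 8.2e11."""
        assert bimolecular_rate_constant(5248.0, 6.4e-9) == pytest.approx(
            8.2e11, rel=0.01)

    def test_zero_ksv_gives_zero_rate(self):
        assert bimolecular_rate_constant(0.0, 6.4e-9) == 0.0

    def test_agp_rate_constant_is_positive_4_83e11(self):
        """Division gives +4.83e11 for K_SV = 3093 at tau0 = 6.4 ns."""
        assert bimolecular_rate_constant(3093.0, 6.4e-9) == pytest.approx(
            4.83e11, rel=0.01)

    def test_bad_tau0_rejected(self):
        with pytest.raises(InvalidParameterError):
            bimolecular_rate_constant(1000.0, 0.0)

    @pytest.mark.parametrize(
        "kq,expected",
        [
            (8.2e11, "static"),
            (1e9, "dynamic-compatible"),
            (2.0e10, "dynamic-compatible"),  # boundary is strict
        ],
    )
    def test_classification(self, kq, expected):
        assert classify_quenching(kq) == expected


class TestBindingIsotherm:
    def test_recovers_water_phase_hsa_constant(self):
        """Noiseless data at the water-phase K_a = 5103 invert exactly."""
        conc = np.linspace(0.0, 2 / 5103.0, 12)
        t = gen_quench_titration("isotherm",
                                 {"K_a": 5103.0, "Ic": 0.0, "I0": 1.0}, conc)
        fit = fit_binding_isotherm(t)
        assert fit.K_a == pytest.approx(5103.0, rel=1e-6)
        assert fit.Ic == pytest.approx(0.0, abs=1e-6)
        assert fit.K_d == pytest.approx(1.96e-4, rel=1e-3)

    def test_half_saturation_at_inverse_ka(self):
        ka, i0, ic = 3000.0, 800.0, 100.0
        conc = np.array([0.0] + list(np.geomspace(1e-5, 3e-3, 11)))
        t = gen_quench_titration("isotherm",
                                 {"K_a": ka, "Ic": ic, "I0": i0}, conc)
        # forward model at [Q] = 1/Ka drops intensity by half the amplitude
        di = (i0 - ic) * (1 / ka) / (1 / ka + 1 / ka)
        assert di == pytest.approx((i0 - ic) / 2)

    def test_residual_fluorescence_recovered(self):
        """Partial-quenching case (Ic ~30% of I0, as seen for AGP)."""
        conc = np.linspace(0.0, 4e-4, 12)
        t = gen_quench_titration("isotherm",
                                 {"K_a": 8184.0, "Ic": 300.0, "I0": 1000.0},
                                 conc)
        fit = fit_binding_isotherm(t)
        assert fit.K_a == pytest.approx(8184.0, rel=1e-5)
        assert fit.Ic == pytest.approx(300.0, rel=1e-5)

    def test_median_bias_under_noise_below_two_percent(self):
        truth = 5103.0
        conc = np.linspace(0.0, 2 / truth, 12)
        kas = [
            fit_binding_isotherm(gen_quench_titration(
                "isotherm", {"K_a": truth, "Ic": 0.0, "I0": 1.0}, conc,
                noise=NoiseSpec("gaussian_additive", 0.01, seed))).K_a
            for seed in range(200)
        ]
        assert abs(np.median(kas) - truth) / truth < 0.02

    def test_narrow_concentration_span_rejected(self):
        conc = np.array([0.0, 1e-4, 1.5e-4, 2e-4, 3e-4])
        t = gen_quench_titration("isotherm", {"K_a": 5000.0}, conc)
        with pytest.raises(InsufficientDataError, match="factor"):
            fit_binding_isotherm(t)

    @given(
        ka=st.floats(1e2, 1e5),
        ic_frac=st.floats(0.0, 0.5),
    )
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_noiseless_recovery_across_parameter_space(self, ka, ic_frac):
        i0 = 1000.0
        conc = np.array([0.0] + list(np.geomspace(0.05 / ka, 5 / ka, 11)))
        t = gen_quench_titration(
            "isotherm", {"K_a": ka, "Ic": ic_frac * i0, "I0": i0}, conc)
        fit = fit_binding_isotherm(t)
        assert fit.K_a == pytest.approx(ka, rel=1e-5)
        assert fit.Ic == pytest.approx(ic_frac * i0, abs=i0 * 1e-5)


class TestThermodynamics:
    @pytest.mark.parametrize(
        "ka,expected_kd",
        [
            (5103.0, 1.96e-4),  # rounds to the quoted 0.2 mM
            (4016.0, 2.49e-4),  # rounds to the quoted 0.25 mM
            (1000.0, 1e-3),
        ],
    )
    def test_dissociation_constant(self, ka, expected_kd):
        assert dissociation_constant(ka) == pytest.approx(expected_kd, rel=1e-2)

    @pytest.mark.parametrize(
        "ka,expected_dg",
        [
            (4016.0, -2.06e4),  # HSA in buffer, 25 C
            (8184.0, -2.23e4),  # AGP, 25 C
        ],
    )
    def test_gibbs_matches_printed_values(self, ka, expected_dg):
        assert gibbs_free_energy(ka, 298.15) == pytest.approx(
            expected_dg, rel=0.005)

    def test_gibbs_of_unit_ka_is_zero(self):
        assert gibbs_free_energy(1.0, 298.15) == 0.0

    def test_gibbs_strictly_decreasing_in_ka(self):
        kas = np.geomspace(10, 1e6, 30)
        dgs = [gibbs_free_energy(k, 298.15) for k in kas]
        assert np.all(np.diff(dgs) < 0)

    def test_two_point_vant_hoff_closed_form(self):
        p = vant_hoff_two_point(2000.0, 288.15, 4000.0, 298.15)
        assert p.dH == pytest.approx(4.95e4, rel=0.01)
        assert p.dG == pytest.approx(p.dH - p.T * p.dS, rel=1e-9)

    def test_temperature_independent_ka_gives_zero_enthalpy(self):
        p = vant_hoff_two_point(3000.0, 288.15, 3000.0, 298.15)
        assert p.dH == 0.0
        assert p.dS == pytest.approx(R_GAS * np.log(3000.0), rel=1e-9)

    def test_equal_temperatures_rejected(self):
        with pytest.raises(InvalidParameterError):
            vant_hoff_two_point(1000.0, 298.15, 2000.0, 298.15)

    def test_regression_route_matches_closed_form_on_exact_line(self):
        dH, dS = 4.0e4, 80.0
        T = np.array([283.15, 293.15, 303.15])
        ka = np.exp(-dH / (R_GAS * T) + dS / R_GAS)
        p = vant_hoff_regression(ka, T)
        assert p.dH == pytest.approx(dH, rel=1e-9)
        assert p.dS == pytest.approx(dS, rel=1e-9)
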