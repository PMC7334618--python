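"""Dose-response curves, equilibrium intersections and uncertainty ensembles."""

import numpy as np
import pytest

from narloop import (CircuitVariant, char_density, closed_loop_steady_state,
                     controller_dose_response, feedback_curve, find_equilibrium,
                     metabolic_dose_response, molecules_to_gl, production_curve,
                     tf_dose_response, uncertainty_ensemble)
from narloop.dose_response import DoseResponseCurve, open_loop_equivalent_chs
from narloop.uncertainty import perturbed_params
from narloop import model

NAR_GRID = np.array([0.05, 0.1, 0.25, 0.5, 0.75, 1.0, 1.5, 2.0])


@pytest.fixture(scope="module")
def metabolic(calibrated):
    return metabolic_dose_response(NAR_GRID, calibrated)


class TestMetabolic:
    def test_anchor_and_linear_regime(self, metabolic):
        assert np.interp(1.0, metabolic.grid, metabolic.response) == \
            pytest.approx(5e-6, rel=1e-2)
        assert np.interp(0.5, metabolic.grid, metabolic.response) == \
            pytest.approx(2.5e-6, rel=2e-2)

    def test_zero_input_zero_output(self, calibrated):
        curve = metabolic_dose_response([1e-12, 1.0], calibrated)
        assert curve.response[0] == pytest.approx(0.0, abs=1e-12)

    def test_monotone_increasing(self, metabolic):
        assert np.all(np.diff(metabolic.response) > 0)
        assert not metabolic.flags.any()


class TestTf:
    def test_floor_ceiling_and_monotonicity(self, calibrated):
        curve = tf_dose_response(NAR_GRID, calibrated)
        _, mu = char_density(calibrated)
        q_tot = calibrated.k_E * calibrated.C_Ns / (calibrated.d_E + mu)
        floor = calibrated.k_A * calibrated.C_Ns * \
            model.pqdoI_activity(q_tot, calibrated) / (calibrated.d_A + mu)
        ceiling = calibrated.k_A * calibrated.C_Ns / (calibrated.d_A + mu)
        assert curve.response[0] >= floor - 1e-9
        assert np.all(np.diff(curve.response) >= -1e-12)
        assert curve.response[-1] <= ceiling * (1 + 1e-9)
        # the detuned sensor fully de-represses well inside the g/L range
        assert curve.response[-1] == pytest.approx(ceiling, rel=0.05)

    def test_zero_input_at_repressed_floor(self, calibrated):
        _, mu = char_density(calibrated)
        curve = tf_dose_response([1e-12, 0.5], calibrated)
        q_tot = calibrated.k_E * calibrated.C_Ns / (calibrated.d_E + mu)
        floor = calibrated.k_A * calibrated.C_Ns * \
            model.pqdoI_activity(q_tot, calibrated) / (calibrated.d_A + mu)
        assert curve.response[0] == pytest.approx(floor, rel=1e-9)


class TestController:
    def test_limits_and_monotonicity(self, calibrated):
        _, mu = char_density(calibrated)
        grid = np.geomspace(1e-3, 1e4, 40)
        curve = controller_dose_response(grid, calibrated)
        assert np.all(np.diff(curve.response) < 0)
        basal_floor = calibrated.k_b * calibrated.C_Nh / (calibrated.d_CHS + mu)
        assert curve.response[-1] == pytest.approx(basal_floor, rel=1e-2)
        no_antisigma = controller_dose_response([1e-12], calibrated).response[0]
        assert curve.response[0] <= no_antisigma
        sig_free = model.sigma_production(calibrated) / (calibrated.d_S + mu)
        chs_max = (calibrated.k_b + calibrated.k_c *
                   model.sigma_activation(sig_free, calibrated)) * \
            calibrated.C_Nh / (calibrated.d_CHS + mu)
        assert no_antisigma == pytest.approx(chs_max, rel=1e-9)


class TestProduction:
    def test_zero_chs_or_malonyl_gives_zero(self, calibrated):
        curve = production_curve([1.0, 10.0], 0.0, calibrated)
        assert np.all(curve.response == 0.0)
        assert production_curve([1e-300, 1.0], 1.0, calibrated).response[0] == \
            pytest.approx(0.0, abs=1e-12)

    def test_open_loop_equivalent_level_reproduces_nominal(self, calibrated):
        chs = open_loop_equivalent_chs(calibrated, 1.0)
        curve = production_curve([chs], 1.0, calibrated)
        assert curve.response[0] == pytest.approx(1.0, rel=1e-6)
        # and the full open-loop simulation agrees within 1%
        from narloop import Scenario, run_scenario
        tr = run_scenario(Scenario(variant=CircuitVariant.OPEN_LOOP, p=0.0), calibrated)
        assert tr.final_titer == pytest.approx(1.0, rel=1e-2)

    def test_monotone_and_capped_above_nominal(self, calibrated):
        grid = np.geomspace(1e3, 1e9, 60)
        curve = production_curve(grid, 1.0, calibrated)
        assert np.all(np.diff(curve.response) >= 0)
        cap = calibrated.supply_cap_ratio * calibrated.supply_knee * \
            calibrated.rho_cells * calibrated.MW_nar / calibrated.N_A * \
            __import__("narloop").od_integral(calibrated)
        assert curve.response[-1] <= cap * (1 + 1e-9)
        assert curve.response[-1] > 1.05  # flattens above the 1 g/L nominal


class TestEquilibrium:
    def test_open_loop_line_intersects_at_nominal(self, calibrated):
        chs = open_loop_equivalent_chs(calibrated, 1.0)
        grid = np.linspace(0.05, 2.0, 80)
        fb = DoseResponseCurve("naringenin", "g/L", "CHS", "molecules/cell",
                               grid, np.full_like(grid, chs))
        prod = production_curve(np.geomspace(1e3, 1e8, 200), 1.0, calibrated)
        eq = find_equilibrium(fb, prod)
        assert eq.found
        assert eq.N_star == pytest.approx(1.0, rel=1e-2)

    def test_closed_loop_intersection_matches_ode_oracle(self, calibrated):
        _, mu = char_density(calibrated)
        od_ref, _ = char_density(calibrated)
        fb = feedback_curve(np.geomspace(0.01, 3.0, 120), calibrated)
        prod = production_curve(np.geomspace(1e3, 1e8, 200), 1.0, calibrated)
        eq = find_equilibrium(fb, prod)
        assert eq.found
        oracle = closed_loop_steady_state(calibrated, CircuitVariant.ANTITHETIC, mu=mu)
        n_oracle = molecules_to_gl(oracle["N"], calibrated.MW_nar, od_ref, calibrated)
        assert eq.N_star == pytest.approx(n_oracle, rel=2e-2)

    def test_oracle_equivalence_under_random_parameter_draws(self, calibrated, rng):
        _, mu = char_density(calibrated)
        od_ref, _ = char_density(calibrated)
        for _ in range(20):
            p_i = perturbed_params(calibrated, 0.15, rng)
            fb = feedback_curve(np.geomspace(0.01, 3.0, 120), p_i)
            prod = production_curve(np.geomspace(1e3, 1e8, 200), 1.0, p_i)
            eq = find_equilibrium(fb, prod)
            oracle = closed_loop_steady_state(p_i, CircuitVariant.ANTITHETIC, mu=mu)
            n_oracle = molecules_to_gl(oracle["N"], p_i.MW_nar, od_ref, p_i)
            assert eq.found and eq.N_star == pytest.approx(n_oracle, rel=2e-2)

    def test_no_crossing_without_production(self, calibrated):
        fb = feedback_curve(np.linspace(0.05, 2.0, 20), calibrated)
        prod = production_curve(np.geomspace(1e3, 1e8, 50), 0.0, calibrated)
        eq = find_equilibrium(fb, prod)
        assert not eq.found
        with pytest.raises(ValueError):
            eq.N_star


class TestEnsemble:
    def test_same_seed_bitwise_identical(self, calibrated):
        a = uncertainty_ensemble(metabolic_dose_response, 0.15, 5, 7, calibrated,
                                 nar_grid=[0.5, 1.0])
        b = uncertainty_ensemble(metabolic_dose_response, 0.15, 5, 7, calibrated,
                                 nar_grid=[0.5, 1.0])
        assert np.array_equal(a.ensemble, b.ensemble)

    def test_vanishing_uncertainty_collapses_to_mean(self, calibrated):
        curve = uncertainty_ensemble(metabolic_dose_response, 1e-9, 4, 3, calibrated,
                                     nar_grid=[1.0])
        assert np.allclose(curve.ensemble, curve.response, rtol=1e-6)

    def test_ensemble_mean_near_anchor_at_fifteen_percent(self, calibrated):
        curve = uncertainty_ensemble(metabolic_dose_response, 0.15, 200, 11,
                                     calibrated, nar_grid=[1.0])
        assert curve.ensemble.shape == (200, 1)
        assert curve.ensemble.mean() == pytest.approx(5e-6, rel=0.10)

    def test_copy_number_forced_to_ten(self, calibrated):
        p = calibrated.copy(C_Ns=3, C_Nh=17)
        curve = uncertainty_ensemble(metabolic_dose_response, 0.15, 3, 1, p,
                                     nar_grid=[1.0])
        ten = metabolic_dose_response([1.0], calibrated.copy(C_Ns=10, C_Nh=10))
        assert curve.response[0] == pytest.approx(ten.response[0], rel=1e-12)
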