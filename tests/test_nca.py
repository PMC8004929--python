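import math

import numpy as np
import pytest
from scipy.integrate import trapezoid

from mmae_pbpk.nca import (
    NCAError,
    adjust_kp,
    auc_linlog,
    ivive,
    kp,
    lambda_z,
    moment_analysis,
    percent_pe,
    scale_ps,
)
from mmae_pbpk.simulator import DoseEvent, simulate

from conftest import STUDY_TIMES


class TestAucLinLog:
    def test_constant_segment_is_linear(self):
        assert auc_linlog([0.0, 1.0], [10.0, 10.0]) == 10.0

    def test_monoexponential_closed_form(self):
        c0, k = 100.0, 0.28
        t_half = math.log(2) / k
        t = np.linspace(0.0, 5 * t_half, 50)
        c = c0 * np.exp(-k * t)
        expected = c0 / k * (1.0 - math.exp(-k * t[-1]))
        assert abs(auc_linlog(t, c) / expected - 1.0) < 5e-3

    def test_log_trapezoid_below_linear_on_decline(self):
        t, c = [0.0, 2.0], [10.0, 1.0]
        log_auc = auc_linlog(t, c)
        linear_auc = 0.5 * (10.0 + 1.0) * 2.0
        assert log_auc < linear_auc

    def test_extrapolated_tail_added(self):
        c0, k = 50.0, 0.5
        t = np.linspace(0, 10, 30)
        c = c0 * np.exp(-k * t)
        auc_inf = auc_linlog(t, c, extrapolate=True)
        assert abs(auc_inf / (c0 / k) - 1.0) < 5e-3

    def test_too_few_points_rejected(self):
        with pytest.raises(NCAError, match="at least 2"):
            auc_linlog([1.0], [5.0])

    def test_rising_terminal_phase_rejects_extrapolation(self):
        with pytest.raises(NCAError, match="non-declining"):
            auc_linlog([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0], extrapolate=True)

    def test_agrees_with_dense_quadrature_on_model_output(self, phys, drug, tum):
        # lin/log rule on study + dense times vs an independent oracle:
        # plain trapezoid on a much finer log-spaced grid that resolves the
        # fast initial distribution phase
        grid = np.unique(
            np.concatenate([np.array(STUDY_TIMES), np.geomspace(0.02, 168.0, 400)])
        )
        res = simulate(DoseEvent(0.1, 28.0), phys, drug, tum, grid)
        c = res.observable("plasma")
        oracle_grid = np.unique(np.concatenate([grid, np.geomspace(1e-3, 168.0, 8000)]))
        oc = simulate(DoseEvent(0.1, 28.0), phys, drug, tum, oracle_grid).observable("plasma")
        mask = oracle_grid >= grid[0]
        oracle = trapezoid(oc[mask], oracle_grid[mask])
        assert abs(auc_linlog(grid, c) / oracle - 1.0) < 5e-3


class TestKp:
    def test_muscle_row(self):
        assert round(kp(94.6, 75.4), 2) == 1.25

    def test_kidney_row_within_rounding(self):
        assert abs(kp(2396.0, 75.4) / 31.6 - 1.0) < 0.01

    def test_equal_aucs_give_unity(self):
        assert kp(75.4, 75.4) == 1.0

    def test_zero_plasma_auc_rejected(self):
        with pytest.raises(NCAError):
            kp(10.0, 0.0)


class TestAdjustKp:
    def test_lung_pair(self):
        assert round(adjust_kp(35.3, 0.5439), 1) == 64.9

    def test_identity_at_full_cellularity(self):
        assert adjust_kp(2.0, 1.0) == 2.0

    def test_never_decreases(self):
        for f in (0.2, 0.5, 0.99, 1.0):
            assert adjust_kp(3.0, f) >= 3.0

    def test_out_of_range_fraction_rejected(self):
        with pytest.raises(NCAError):
            adjust_kp(2.0, 0.0)
        with pytest.raises(NCAError):
            adjust_kp(2.0, 1.2)


class TestMomentAnalysis:
    @pytest.fixture(scope="class")
    def monoexp(self):
        V, k, dose = 40.0, 0.28, 3900.0
        t = np.linspace(0.01, 5 * math.log(2) / k, 60)
        c = dose / V * np.exp(-k * t)
        return t, c, V, k, dose

    def test_clearance_recovered(self, monoexp):
        t, c, V, k, dose = monoexp
        s = moment_analysis(t, c, dose)
        assert abs(s.CL / (V * k) - 1.0) < 0.01

    def test_half_life_recovered(self, monoexp):
        t, c, V, k, dose = monoexp
        s = moment_analysis(t, c, dose)
        assert abs(s.t_half / (math.log(2) / k) - 1.0) < 0.01

    def test_vss_equals_v_for_one_compartment(self, monoexp):
        t, c, V, k, dose = monoexp
        s = moment_analysis(t, c, dose)
        assert abs(s.Vss / V - 1.0) < 0.02

    def test_dose_scales_auc_not_cl(self, monoexp):
        t, c, V, k, dose = monoexp
        s1 = moment_analysis(t, c, dose)
        s2 = moment_analysis(t, 2 * c, 2 * dose)
        assert math.isclose(s2.AUC_0_inf, 2 * s1.AUC_0_inf, rel_tol=1e-9)
        assert math.isclose(s2.CL, s1.CL, rel_tol=1e-9)

    def test_no_terminal_slope_flags_partial_result(self):
        s = moment_analysis([0, 1, 2, 3], [1.0, 2.0, 3.0, 4.0], 100.0)
        assert s.flagged and math.isnan(s.CL) and s.AUC_0_t > 0


class TestLambdaZ:
    def test_exact_on_monoexponential(self):
        t = np.array([1.0, 2.0, 4.0, 8.0])
        c = 10 * np.exp(-0.3 * t)
        assert math.isclose(lambda_z(t, c), 0.3, rel_tol=1e-9)

    def test_requires_enough_positive_points(self):
        with pytest.raises(NCAError, match="positive points"):
            lambda_z([1.0, 2.0, 3.0], [5.0, 0.0, 0.0])


class TestPercentPE:
    def test_perfect_prediction_is_zero(self):
        assert percent_pe(75.4, 75.4) == 0.0

    def test_plasma_reference_value(self):
        assert round(percent_pe(81.59, 75.4), 2) == 8.21

    def test_absolute_value_convention(self):
        assert percent_pe(50.0, 100.0) == percent_pe(150.0, 100.0)
        assert percent_pe(50.0, 100.0, signed=True) == -50.0

    def test_zero_observed_rejected(self):
        with pytest.raises(NCAError):
            percent_pe(10.0, 0.0)


class TestIvive:
    def test_hepatocyte_scaling(self):
        out = ivive(3.0, 135.0, 1.0, clint_basis="hepatocyte")
        assert round(out["CL_metabolic"], 1) == 24.3

    def test_microsome_scaling(self):
        out = ivive(24.0, 41.9, 1.0, clint_basis="microsome")
        assert round(out["CL_metabolic"], 1) == 60.3

    def test_total_equals_metabolic_when_fully_metabolic(self):
        out = ivive(3.0, 135.0, 1.0, f_metabolic=1.0)
        assert out["CL_int_total"] == out["CL_metabolic"]

    def test_forty_percent_split_scales_total(self):
        out = ivive(3.0, 135.0, 1.0, f_metabolic=0.4)
        assert math.isclose(out["CL_int_total"], out["CL_metabolic"] / 0.4)

    def test_basis_mismatch_rejected(self):
        with pytest.raises(NCAError, match="does not match"):
            ivive(3.0, 135.0, 1.0, clint_basis="hepatocyte", sf_basis="mg_per_g")


class TestScalePs:
    def test_identity_at_equal_weights(self):
        assert scale_ps(1.0, 28.0, 28.0) == 1.0

    def test_mouse_to_human_factor(self):
        assert round(scale_ps(1.0, 28.0, 28000.0), 1) == round(1000.0**0.67, 1)

    def test_monotone_in_target_weight(self):
        assert scale_ps(1.0, 28.0, 70000.0) > scale_ps(1.0, 28.0, 28000.0)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(NCAError):
            scale_ps(1.0, 0.0, 70.0)
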