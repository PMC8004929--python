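import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from mmae_pbpk.estimation import (
    DEFAULT_ESTIMATED,
    EstimationError,
    FitResult,
    FitSpec,
    _Objective,
    _current_value,
    aic,
    fit,
    neg2ll,
)
from mmae_pbpk.synthetic_data import StudyDataset, StudyDesign, generate_study


@pytest.fixture(scope="module")
def noisy_dataset(phys, drug, tum):
    # additive-only noise so the sigma1 MLE has a clean closed form
    design = StudyDesign(sigma1=0.5, sigma2=0.0, seed=11)
    return generate_study(design, phys, drug, tum)


class TestNeg2LL:
    def test_zero_residuals_give_n_log_2pi(self, phys, drug, tum, noise_free_dataset):
        n = len(noise_free_dataset.non_blq())
        val = neg2ll({}, noise_free_dataset, phys, drug, tum, sigma1=1.0, sigma2=0.0)
        assert abs(val - n * math.log(2 * math.pi)) < 1e-4 * n

    def test_doubling_sigma1_adds_n_log4(self, phys, drug, tum, noise_free_dataset):
        n = len(noise_free_dataset.non_blq())
        v1 = neg2ll({}, noise_free_dataset, phys, drug, tum, sigma1=1.0, sigma2=0.0)
        v2 = neg2ll({}, noise_free_dataset, phys, drug, tum, sigma1=2.0, sigma2=0.0)
        assert abs((v2 - v1) - n * math.log(4.0)) < 1e-4 * n

    def test_sigma1_mle_is_rms_residual(self, phys, drug, tum, noisy_dataset, noise_free_dataset):
        # residuals = noisy records - noise-free predictions at the truth
        obs = noisy_dataset.non_blq().sort_values(["time_h", "matrix", "replicate"])
        spec = FitSpec(sigma1=0.5, sigma2=0.0, estimate_sigma2=False)
        obj = _Objective(noisy_dataset, spec, phys, drug, tum, solver_rtol=1e-8, solver_atol=1e-10)
        pred = obj.predict({})
        msr = float(np.mean((obs["conc_nM"].to_numpy() - pred) ** 2))
        res = minimize_scalar(
            lambda s: obj.neg2ll({}, s, 0.0), bounds=(0.05, 5.0), method="bounded"
        )
        assert abs(res.x / math.sqrt(msr) - 1.0) < 1e-3

    def test_record_order_invariance(self, phys, drug, tum, noisy_dataset):
        shuffled = StudyDataset(
            records=noisy_dataset.records.sample(frac=1.0, random_state=3).reset_index(drop=True),
            design=noisy_dataset.design,
            MW=noisy_dataset.MW,
        )
        a = neg2ll({}, noisy_dataset, phys, drug, tum, sigma1=0.5, sigma2=0.0)
        b = neg2ll({}, shuffled, phys, drug, tum, sigma1=0.5, sigma2=0.0)
        assert math.isclose(a, b, rel_tol=1e-12)


class TestFit:
    def test_noise_free_recovery_from_doubled_start(self, phys, drug, tum, noise_free_dataset):
        names = ("CL_int", "PS_kidney", "PS_lung")
        truth = {n: _current_value(drug, tum, n) for n in names}
        spec = FitSpec(
            estimated=names,
            initial={n: 2.0 * v for n, v in truth.items()},
            estimate_sigma2=False,
            sigma1=0.01,
            sigma2=0.05,
        )
        res = fit(noise_free_dataset, spec, phys, drug, tum, compute_cv=False)
        for n in names:
            assert abs(res.estimates[n] / truth[n] - 1.0) < 0.01, n
        # accepted optimizer steps never increase the objective
        start_obj = neg2ll(
            dict(spec.initial), noise_free_dataset, phys, drug, tum,
            sigma1=0.01, sigma2=0.05,
        )
        assert res.neg2ll <= start_obj

    def test_uninfluential_parameter_is_poorly_identified(self, phys, drug, tum, noise_free_dataset):
        # thymus is never sampled; its PS touches the observed matrices only
        # through whole-body feedback, so its curvature is near-singular and
        # the reported CV% must be unusable (NaN) or enormous
        spec = FitSpec(
            estimated=("PS_thymus",),
            estimate_sigma2=False,
            sigma1=0.01,
            sigma2=0.05,
        )
        res = fit(noise_free_dataset, spec, phys, drug, tum, maxiter=5)
        cv = res.cv_percent["PS_thymus"]
        assert math.isnan(cv) or cv > 100.0

    def test_blq_records_are_excluded(self, phys, drug, tum, noise_free_dataset):
        spec = FitSpec(estimated=("CL_int",), estimate_sigma2=False, sigma2=0.05)
        obj = _Objective(noise_free_dataset, spec, phys, drug, tum)
        flagged = int(noise_free_dataset.records["blq"].sum())
        assert flagged > 0
        assert obj.n_excluded == flagged
        assert len(obj.obs) == noise_free_dataset.n_records - flagged


class TestAic:
    def _result(self, n2ll, k):
        return FitResult(
            estimates={}, cv_percent={}, neg2ll=n2ll, aic=n2ll + 2 * k,
            n_params=k, converged=True, n_obs=10, n_excluded_blq=0,
            sigma1=0.01, sigma2=0.1, n_objective_evals=1, message="",
        )

    def test_zero_parameters(self):
        assert aic(self._result(10.0, 0)) == 10.0

    def test_useless_parameter_costs_two(self):
        assert aic(self._result(10.0, 3)) - aic(self._result(10.0, 2)) == 2.0

    def test_matches_stored_value(self):
        r = self._result(123.4, 5)
        assert aic(r) == r.aic


class TestFitSpecValidation:
    def test_duplicate_names_rejected(self):
        with pytest.raises(EstimationError, match="duplicate"):
            FitSpec(estimated=("CL_int", "CL_int"))

    def test_unknown_name_rejected(self):
        with pytest.raises(EstimationError, match="unknown parameter"):
            FitSpec(estimated=("CL_hepatic",))

    def test_degenerate_variance_rejected(self):
        with pytest.raises(EstimationError, match="cannot both be zero"):
            FitSpec(sigma1=0.0, sigma2=0.0, estimate_sigma2=False)

    def test_default_set_covers_published_parameters(self):
        assert "CL_int" in DEFAULT_ESTIMATED
        assert "k_in" in DEFAULT_ESTIMATED
        assert len([n for n in DEFAULT_ESTIMATED if n.startswith("PS_")]) == 12
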