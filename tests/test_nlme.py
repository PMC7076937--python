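"""Mixed-effects estimator tests: likelihood arithmetic, degenerate-setting
oracles, quadrature cross-check of the marginal likelihood, and SAEM
behaviour on small synthetic cohorts."""

import math

import numpy as np
import pytest
from scipy import stats

from tumornlme.errors import ConfigurationError
from tumornlme.models import DoseRegimen
from tumornlme.nlme import (FitResult, SaemSettings, estimate_minus2LL,
                            fit_population, individual_fits, individual_loglik)
from tumornlme.population import ErrorParams, PopulationSpec
from tumornlme.simulate import Cohort, StudyDesign, Subject, generate_cohort
from tumornlme.structural import get_model


class ToyLinearModel:
    """f(t; phi) = phi * t — analytic stand-in for quadrature cross-checks."""

    id = "toy-linear"
    param_names = ("slope",)

    def predict(self, times, phi, regimen=None):
        return np.asarray(phi, dtype=float)[0] * np.asarray(times, dtype=float)


def _subject(times, volumes, group="control"):
    return Subject(id="S1", group=group, regimen=DoseRegimen.control(),
                   times=np.asarray(times, float), volumes=np.asarray(volumes, float))


class TestIndividualLoglik:
    def test_zero_residual_closed_form(self):
        model = ToyLinearModel()
        err = ErrorParams(a=5.0, b=0.02)
        s = _subject([2.0], [20.0])  # slope 10 -> exact fit
        g = 5.0 + 0.02 * 20.0
        expected = -0.5 * math.log(2 * math.pi * g * g)
        assert individual_loglik(s, [10.0], model, err) == pytest.approx(expected)

    def test_doubling_scale_costs_log2_per_observation(self):
        model = ToyLinearModel()
        s = _subject([1.0, 2.0, 3.0], [10.0, 20.0, 30.0])
        ll1 = individual_loglik(s, [10.0], model, ErrorParams(a=8.0, b=0.0))
        ll2 = individual_loglik(s, [10.0], model, ErrorParams(a=16.0, b=0.0))
        assert ll1 - ll2 == pytest.approx(3 * math.log(2.0))

    def test_three_point_fixture_against_direct_density(self):
        """Matches the product of normal densities evaluated independently."""
        model = ToyLinearModel()
        err = ErrorParams(a=10.0, b=0.05)
        times = [1.0, 3.0, 5.0]
        y = [12.0, 28.0, 55.0]
        phi = [9.5]
        f = 9.5 * np.asarray(times)
        expected = stats.norm.logpdf(y, loc=f, scale=10.0 + 0.05 * f).sum()
        assert individual_loglik(_subject(times, y), phi, model, err) == \
            pytest.approx(expected, rel=1e-12)


class TestMarginalLikelihood:
    ERR = ErrorParams(a=10.0, b=0.0)

    def _toy_cohort_and_fit(self, mu=math.log(10.0), omega=0.25):
        s = _subject([1.0, 2.0, 4.0], [11.0, 19.0, 42.0])
        cohort = Cohort(subjects=[s])
        fit = FitResult(
            model_id="toy-linear", param_names=("slope",),
            mu=np.array([mu]), omega=np.array([omega]), error=self.ERR,
            minus2LL=np.nan, minus2LL_method="", minus2LL_se=np.nan,
            individual_eta=np.array([[mu]]), n_obs=3, n_subjects=1, k=3,
            converged=True, data_hash=cohort.data_hash())
        return cohort, fit

    def _gauss_hermite_minus2ll(self, cohort, mu, omega):
        x, w = np.polynomial.hermite.hermgauss(120)
        s = cohort.subjects[0]
        etas = mu + math.sqrt(2.0) * omega * x
        lik = np.array([
            np.exp(stats.norm.logpdf(s.volumes, loc=math.exp(e) * s.times,
                                     scale=10.0).sum()) for e in etas])
        return -2.0 * math.log(float((w * lik).sum() / math.sqrt(math.pi)))

    def test_importance_sampling_matches_quadrature(self):
        cohort, fit = self._toy_cohort_and_fit()
        oracle = self._gauss_hermite_minus2ll(cohort, float(fit.mu[0]), float(fit.omega[0]))
        est = estimate_minus2LL(fit, cohort, ToyLinearModel(),
                                n_is_samples=40_000, seed=7)
        assert fit.minus2LL_se < 5e-3
        assert est == pytest.approx(oracle, abs=4 * fit.minus2LL_se)

    def test_monte_carlo_error_shrinks_with_sample_size(self):
        cohort, fit = self._toy_cohort_and_fit()
        reps = {n: [estimate_minus2LL(fit, cohort, ToyLinearModel(),
                                      n_is_samples=n, seed=100 + r)
                    for r in range(25)] for n in (50, 200)}
        ratio = np.var(reps[200]) / np.var(reps[50])
        assert ratio < 0.8  # expected ~0.25 with 4x the samples

    def test_omega_zero_collapses_to_plain_likelihood(self):
        cohort, fit = self._toy_cohort_and_fit(omega=0.0)
        model = ToyLinearModel()
        est = estimate_minus2LL(fit, cohort, model, n_is_samples=10, seed=0)
        direct = -2.0 * individual_loglik(cohort.subjects[0],
                                          np.exp(fit.mu), model, self.ERR)
        assert est == pytest.approx(direct, rel=1e-12)
        assert fit.minus2LL_method == "exact"

    def test_mismatched_cohort_rejected(self):
        cohort, fit = self._toy_cohort_and_fit()
        other = Cohort(subjects=[_subject([1.0], [5.0])])
        with pytest.raises(ConfigurationError):
            estimate_minus2LL(fit, other, ToyLinearModel(), 10, 0)


def _tiny_tgf_cohort(seed=3, n=8, noise=ErrorParams(a=5.0, b=0.02)):
    spec = PopulationSpec.from_typical(
        "tgf", {"lambda0": 0.25, "lambda1": 120.0, "V0": 200.0},
        omega={"lambda0": 0.2, "lambda1": 0.2, "V0": 0.3}, error=noise)
    design = StudyDesign(n_control=n, n_treated=0, horizon_days=28)
    return spec, generate_cohort(spec, design, seed)


class TestFitPopulation:
    def test_omega_zero_single_subject_is_plain_nonlinear_ml(self):
        """With no random effects and one subject the fit reduces to ordinary
        ML regression: a noiseless Gompertz series is recovered ~exactly."""
        from tumornlme.models import ClassicParams, classic_volume

        times = np.arange(0.0, 30.0, 2.0)
        truth = ClassicParams("gompertz", V0=200.0, a=0.05, beta=1 / 50.0)
        vols = classic_volume(times, truth)
        s = Subject(id="g1", group="control", regimen=DoseRegimen.control(),
                    times=times, volumes=vols)
        settings = SaemSettings(
            omega_zero=True, error_model="additive", init_error=(1.0, 0.0),
            init_typical={"a": 0.04, "beta": 1 / 80.0, "V0": 250.0})
        fit = fit_population(Cohort(subjects=[s]), get_model("gompertz"),
                             settings, seed=0)
        assert fit.typical["a"] == pytest.approx(0.05, rel=1e-2)
        assert fit.typical["beta"] == pytest.approx(1 / 50.0, rel=1e-2)
        assert fit.typical["V0"] == pytest.approx(200.0, rel=1e-2)
        assert np.all(fit.omega == 0.0)

    def test_seed_determinism(self):
        spec, cohort = _tiny_tgf_cohort()
        settings = SaemSettings(n_burn=15, n_smooth=10,
                                init_typical=spec.typical)
        fits = [fit_population(cohort, get_model("tgf"), settings, seed=42)
                for _ in range(2)]
        np.testing.assert_array_equal(fits[0].mu, fits[1].mu)
        np.testing.assert_array_equal(fits[0].omega, fits[1].omega)
        np.testing.assert_array_equal(fits[0].individual_eta, fits[1].individual_eta)

    def test_low_noise_cohort_recovers_typical_values(self):
        spec, cohort = _tiny_tgf_cohort(noise=ErrorParams(a=2.0, b=0.005))
        settings = SaemSettings.profile("fast", init_typical={
            "lambda0": 0.2, "lambda1": 100.0, "V0": 250.0})
        fit = fit_population(cohort, get_model("tgf"), settings, seed=11)
        sample_mean = {p: np.mean([np.log(s.phi_true[p]) for s in cohort.subjects])
                       for p in spec.param_names}
        for j, p in enumerate(spec.param_names):
            # against the cohort's own realized parameter draws
            assert fit.mu[j] == pytest.approx(sample_mean[p], abs=0.1)

    def test_saem_objective_improves_after_burn_in(self):
        """Smoothed complete-data -2LL does not get worse over the smoothing
        phase (monotone trend of the stochastic approximation)."""
        spec, cohort = _tiny_tgf_cohort()
        settings = SaemSettings(n_burn=40, n_smooth=40, init_typical=spec.typical)
        fit = fit_population(cohort, get_model("tgf"), settings, seed=2)
        obj = fit.diagnostics["obj_trace"][40:]
        first, last = obj[:10].mean(), obj[-10:].mean()
        assert last <= first + 5.0

    def test_parameter_count_for_information_criteria(self):
        spec, cohort = _tiny_tgf_cohort()
        settings = SaemSettings(n_burn=5, n_smooth=5, init_typical=spec.typical)
        fit = fit_population(cohort, get_model("tgf"), settings, seed=1)
        # 3 fixed effects + 3 RE variances + 2 error scales
        assert fit.k == 8

    def test_missing_starting_values_rejected(self):
        _, cohort = _tiny_tgf_cohort()
        with pytest.raises(ConfigurationError):
            fit_population(cohort, get_model("tgf"), SaemSettings(), seed=0)


class TestIndividualFits:
    def test_noiseless_subject_reproduced_and_order_invariant(self):
        spec = PopulationSpec.from_typical(
            "tgf", {"lambda0": 0.25, "lambda1": 120.0, "V0": 200.0},
            omega={"lambda0": 0.25, "V0": 0.3}, error=ErrorParams(a=1e-6, b=0.0))
        design = StudyDesign(n_control=4, n_treated=0, horizon_days=21)
        cohort = generate_cohort(spec, design, seed=8)
        settings = SaemSettings(n_burn=30, n_smooth=20, error_model="additive",
                                init_error=(1.0, 0.0), init_typical=spec.typical)
        fit = fit_population(cohort, get_model("tgf"), settings, seed=5)
        frame, modes = individual_fits(fit, cohort, "tgf")
        rel = np.abs(frame.predicted_mm3 / frame.observed_mm3 - 1.0)
        assert float(rel.max()) < 1e-3

        # reversing subject order leaves each subject's fit unchanged
        rev = Cohort(subjects=list(reversed(cohort.subjects)))
        fit.data_hash = rev.data_hash()
        fit.individual_eta = fit.individual_eta[::-1]
        frame_rev, _ = individual_fits(fit, rev, "tgf")
        merged = frame.merge(frame_rev, on=["subject_id", "time_day"], suffixes=("", "_r"))
        np.testing.assert_allclose(merged.predicted_mm3, merged.predicted_mm3_r,
                                   rtol=1e-6)
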