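"""Tests of the synthetic-cohort generator: distributions, design rules,
censoring and reproducibility."""

import numpy as np
import pytest

from tumornlme.errors import ConfigurationError, DomainError
from tumornlme.population import ErrorParams, PopulationSpec
from tumornlme.simulate import (StudyDesign, caliper_volume, control_population,
                                default_population, generate_cohort, observe,
                                read_cohort_csv, sample_individual_params)


class TestSampleIndividualParams:
    def test_degenerate_population_collapses_to_typical(self):
        spec = control_population()
        spec.omega = {}
        phi = sample_individual_params(spec, 5, seed=0)
        expected = [spec.typical[p] for p in spec.param_names]
        np.testing.assert_allclose(phi, np.tile(expected, (5, 1)))

    def test_seed_determinism(self):
        spec = default_population()
        a = sample_individual_params(spec, 10, seed=42)
        b = sample_individual_params(spec, 10, seed=42)
        np.testing.assert_array_equal(a, b)

    def test_large_sample_moments_recover_mu_and_omega(self):
        """Law of large numbers: log phi has mean mu and sd omega."""
        spec = default_population()
        n = 100_000
        logphi = np.log(sample_individual_params(spec, n, seed=7))
        mu, om = spec.mu_vector, spec.omega_vector
        se = om / np.sqrt(n)
        assert np.all(np.abs(logphi.mean(axis=0) - mu) < 3 * se + 1e-12)
        np.testing.assert_allclose(logphi.std(axis=0), om, rtol=0.02)

    def test_lognormal_cv_identity(self):
        """Sample CV of each phi component matches sqrt(exp(omega^2)-1)."""
        spec = default_population()
        phi = sample_individual_params(spec, 100_000, seed=3)
        cv = phi.std(axis=0) / phi.mean(axis=0)
        expected = np.sqrt(np.exp(spec.omega_vector ** 2) - 1.0)
        np.testing.assert_allclose(cv, expected, rtol=0.03)

    def test_positivity(self):
        phi = sample_individual_params(default_population(), 1000, seed=0)
        assert np.all(phi > 0)


class TestObserve:
    def test_combined_error_sd(self, rng):
        """Empirical sd at f=500, a=20, b=0.1 is a + b f = 70."""
        err = ErrorParams(a=20.0, b=0.1)
        ys = np.array([observe(500.0, err, rng) for _ in range(100_000)])
        assert ys.std() == pytest.approx(70.0, abs=1.0)
        assert np.all(ys > 0)

    def test_additive_only_at_zero_prediction(self, rng):
        err = ErrorParams(a=15.0, b=0.2)
        ys = np.array([observe(0.0, err, rng) for _ in range(20_000)])
        # truncated-at-zero half-normal with scale a
        assert ys.max() < 15.0 * 5
        assert np.all(ys > 0)

    def test_proportional_only_scaling(self, rng):
        err = ErrorParams(a=0.0, b=0.05)
        ys = np.array([observe(1000.0, err, rng) for _ in range(50_000)])
        assert ys.std() == pytest.approx(50.0, rel=0.03)

    def test_error_params_validation(self):
        with pytest.raises(ConfigurationError):
            ErrorParams(a=0.0, b=0.0)
        with pytest.raises(ConfigurationError):
            ErrorParams(a=-1.0, b=0.1)


class TestCaliperVolume:
    @pytest.mark.parametrize("l, w, expected", [(10.0, 5.0, 125.0),
                                                (2.0, 1.0, 1.0),
                                                (3.0, 3.0, 13.5)])
    def test_formula(self, l, w, expected):
        assert caliper_volume(l, w) == pytest.approx(expected)

    def test_width_exceeding_length_rejected(self):
        with pytest.raises(DomainError):
            caliper_volume(4.0, 5.0)
        with pytest.raises(DomainError):
            caliper_volume(4.0, 0.0)


class TestGenerateCohort:
    def test_default_design_matches_study_arms(self):
        cohort = generate_cohort(default_population(), StudyDesign(), seed=5,
                                 control_spec=control_population())
        assert len(cohort) == 40
        groups = [s.group for s in cohort.subjects]
        assert groups.count("control") == 21 and groups.count("treated") == 19
        assert all(s.n_obs > 0 for s in cohort.subjects)
        assert all(s.volumes[0] < 700.0 + 5 * 70 for s in cohort.subjects)
        assert all(s.phi_true["V0"] < 700.0 for s in cohort.subjects)

    def test_weekend_gaps_in_schedule(self):
        days = StudyDesign(horizon_days=14).observation_days()
        assert 5.0 not in days and 6.0 not in days and 7.0 in days

    def test_csv_roundtrip_is_byte_identical(self, tmp_path):
        spec, design = default_population(), StudyDesign(n_control=3, n_treated=3)
        for run in ("a", "b"):
            c = generate_cohort(spec, design, seed=99)
            c.to_csv(tmp_path / f"{run}.csv", tmp_path / f"{run}_dose.csv")
        assert (tmp_path / "a.csv").read_bytes() == (tmp_path / "b.csv").read_bytes()
        assert (tmp_path / "a_dose.csv").read_bytes() == (tmp_path / "b_dose.csv").read_bytes()
        back = read_cohort_csv(tmp_path / "a.csv", tmp_path / "a_dose.csv")
        assert len(back) == 6 and back.n_obs == c.n_obs
        np.testing.assert_allclose(back.subjects[0].volumes,
                                   c.subjects[0].volumes, rtol=1e-5)

    def test_censoring_monotone_in_threshold(self):
        spec = default_population()
        counts = []
        for thresh in (1200.0, 2500.0, np.inf):
            design = StudyDesign(n_control=6, n_treated=0, censor_volume=thresh)
            c = generate_cohort(spec, design, seed=17, control_spec=control_population())
            counts.append([s.n_obs for s in c.subjects])
        for lo, hi in zip(counts[:-1], counts[1:]):
            assert all(a <= b for a, b in zip(lo, hi))
        # infinite threshold: everyone observed over the full horizon
        full = len(StudyDesign(n_control=6, n_treated=0).observation_days())
        assert all(n == full for n in counts[-1])

    def test_noise_free_cohort_reproduces_population_curves(self):
        spec = PopulationSpec.from_typical(
            "tgf", {"lambda0": 0.25, "lambda1": 120.0, "V0": 200.0},
            omega={}, error=ErrorParams(a=1e-9, b=0.0))
        design = StudyDesign(n_control=3, n_treated=0, censor_volume=np.inf)
        c = generate_cohort(spec, design, seed=1)
        model = spec.model
        phi = [spec.typical[p] for p in spec.param_names]
        for s in c.subjects:
            np.testing.assert_allclose(
                s.volumes, model.predict(s.times, phi, s.regimen), rtol=1e-6)

    def test_treatment_separates_arms_at_day_seven(self):
        """Same seed, dosed vs zero-dose: the bolus lowers day-7 volumes."""
        spec = default_population()
        treated = generate_cohort(spec, StudyDesign(n_control=0, n_treated=12), seed=31)
        sham = generate_cohort(spec, StudyDesign(n_control=0, n_treated=12,
                                                 dose_amount=0.0), seed=31)
        def day7(c):
            return np.mean([s.volumes[s.times == 7.0][0] for s in c.subjects
                            if np.any(s.times == 7.0)])
        assert day7(treated) < day7(sham)

    def test_invalid_design_rejected(self):
        with pytest.raises(ConfigurationError):
            StudyDesign(horizon_days=0)
        with pytest.raises(ConfigurationError):
            StudyDesign(n_control=0, n_treated=0)
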