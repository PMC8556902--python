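"""Parametric fitting, Cox/PH diagnostics, selection and transition probabilities."""

import numpy as np
import pytest
from scipy.integrate import quad

import ros1ce as r
from ros1ce.distributions import FAMILIES, get_family
from ros1ce.errors import AbsorbingStateError, NonIdentifiableError, ValidationError
from ros1ce.survfit import SurvivalFit
from ros1ce.synth import theta_from_median

from conftest import RECOVERY_SHAPES, two_arm_sample


def make_records(times, events, arm="crizotinib"):
    return [
        r.IPDRecord(float(t), bool(e), arm, "s") for t, e in zip(times, events)
    ]


class TestFitParametric:
    def test_exponential_mle_closed_form_uncensored(self):
        fit = r.fit_parametric(make_records([1, 2, 3], [1, 1, 1]), "exponential")
        assert fit.params_natural()["rate"] == pytest.approx(0.5, rel=1e-4)

    def test_exponential_mle_equals_events_over_exposure_with_censoring(self):
        rng = np.random.default_rng(8)
        t = rng.exponential(9.0, 200)
        e = rng.uniform(size=200) < 0.6
        fit = r.fit_parametric(make_records(t, e), "exponential")
        assert fit.params_natural()["rate"] == pytest.approx(e.sum() / t.sum(), rel=1e-4)

    def test_all_censored_is_non_identifiable(self):
        with pytest.raises(NonIdentifiableError):
            r.fit_parametric(make_records([1, 2, 3], [0, 0, 0]), "exponential")

    def test_shared_fit_requires_events_in_both_arms(self):
        recs = make_records([1, 2], [1, 1], "crizotinib") + make_records(
            [3, 4], [0, 0], "chemotherapy"
        )
        with pytest.raises(NonIdentifiableError):
            r.fit_parametric(recs, "weibull", shared_treatment=True)

    def test_information_criteria_identities(self, best_fit):
        assert best_fit.aic == pytest.approx(2 * best_fit.k - 2 * best_fit.loglik)
        assert best_fit.bic == pytest.approx(
            best_fit.k * np.log(best_fit.n) - 2 * best_fit.loglik
        )

    def test_aft_time_ratio_recovered_on_loglogistic_data(self):
        rng = np.random.default_rng(12)
        recs = two_arm_sample("log_logistic", rng, n_per_arm=500)
        fit = r.fit_parametric(recs, "log_logistic", shared_treatment=True, seed=0)
        te = fit.treatment_effect()
        assert te["type"] == "acceleration_factor"
        assert te["value"] == pytest.approx(16.2 / 7.8, rel=0.12)
        assert fit.median("chemotherapy") == pytest.approx(7.8, rel=0.10)
        assert fit.median("crizotinib") == pytest.approx(16.2, rel=0.10)

    def test_weibull_fit_matches_lifelines(self):
        from lifelines import WeibullFitter

        rng = np.random.default_rng(21)
        t = 10.0 * rng.weibull(1.4, 300)
        e = rng.uniform(size=300) < 0.75
        fit = r.fit_parametric(make_records(t, e), "weibull")
        wf = WeibullFitter().fit(t, e)
        assert fit.loglik == pytest.approx(wf.log_likelihood_, rel=1e-5)
        assert fit.params_natural()["scale"] == pytest.approx(wf.lambda_, rel=1e-3)
        assert fit.params_natural()["shape"] == pytest.approx(wf.rho_, rel=1e-3)


class TestFamilyInternals:
    @pytest.mark.parametrize("name", sorted(FAMILIES))
    def test_hazard_integrates_to_cumulative_hazard(self, name):
        """Internal consistency: integral of h equals -ln S on a grid."""
        fam = get_family(name)
        theta = theta_from_median(name, 9.0, RECOVERY_SHAPES[name] or None)
        haz = lambda t: np.exp(fam.logpdf(t, theta) - fam.logsf(t, theta))
        for t_hi in (2.0, 7.5, 15.0):
            H_quad, _ = quad(haz, 0.0, t_hi, limit=200)
            assert H_quad == pytest.approx(float(fam.cumhaz(t_hi, theta)), abs=1e-6)

    @pytest.mark.parametrize("name", sorted(FAMILIES))
    def test_median_parameterization_round_trip(self, name):
        fam = get_family(name)
        theta = theta_from_median(name, 9.0, RECOVERY_SHAPES[name] or None)
        assert fam.median(theta) == pytest.approx(9.0, rel=1e-6)
        assert float(fam.sf(9.0, theta)) == pytest.approx(0.5, abs=1e-6)

    def test_negative_gompertz_shape_is_improper_and_flagged(self):
        fam = get_family("gompertz")
        theta = np.array([-0.3, np.log(0.4)])
        assert not fam.is_proper(theta)
        assert float(fam.sf(1e6, theta)) > 0  # plateau of never-progressors
        rng = np.random.default_rng(0)
        t = fam.rvs(np.array([0.08, np.log(0.05)]), 300, rng)
        t = np.minimum(t, 60.0)
        fit = r.fit_parametric(
            make_records(t, t < 60.0), "gompertz"
        )
        assert isinstance(fit.flags, list)


class TestCoxAndPHTest:
    def test_two_arm_hr_recovered(self):
        rng = np.random.default_rng(5)
        recs = make_records(
            rng.exponential(16.2 / np.log(2), 400), np.ones(400), "crizotinib"
        ) + make_records(
            rng.exponential(7.8 / np.log(2), 400), np.ones(400), "chemotherapy"
        )
        hr = r.cox_hr_and_ph_test(recs)
        assert hr.value == pytest.approx(7.8 / 16.2, rel=0.15)
        assert hr.ci_lower < hr.value < hr.ci_upper
        assert hr.p_ph_test > 0.05  # exponential arms are proportional

    def test_null_relabeling_gives_hr_near_one(self):
        rng = np.random.default_rng(6)
        t = rng.exponential(10.0, 200)
        arms = np.where(rng.permutation(200) < 100, "crizotinib", "chemotherapy")
        recs = [
            r.IPDRecord(float(ti), True, str(a), "s") for ti, a in zip(t, arms)
        ]
        hr = r.cox_hr_and_ph_test(recs)
        assert 0.7 < hr.value < 1.4
        assert hr.ci_lower < 1.0 < hr.ci_upper

    def test_single_arm_rejected(self):
        with pytest.raises(ValidationError):
            r.cox_hr_and_ph_test(make_records([1, 2, 3], [1, 1, 1]))

    def test_zero_event_arm_rejected(self):
        recs = make_records([1, 2], [1, 1], "crizotinib") + make_records(
            [3, 4], [0, 0], "chemotherapy"
        )
        with pytest.raises(NonIdentifiableError):
            r.cox_hr_and_ph_test(recs)


class TestSelectDistribution:
    def test_minimum_aic_wins(self, all_fits):
        best, report = r.select_distribution(all_fits)
        assert best.aic == min(f.aic for f in all_fits)
        assert list(report["aic"]) == sorted(report["aic"])
        assert set(report["family"]) == set(FAMILIES)

    def test_two_fit_ordering(self):
        def stub(name, loglik, k=2):
            return SurvivalFit(
                family_name=name, theta=np.zeros(k), covariance=np.eye(k),
                loglik=loglik, n=100, n_events=80, shared_treatment=False,
            )

        best, _ = r.select_distribution([stub("weibull", -48.0), stub("log_logistic", -49.0)])
        assert best.family_name == "weibull"  # AIC 100 beats 102

    def test_single_fit_rejected(self, best_fit):
        with pytest.raises(ValidationError):
            r.select_distribution([best_fit])

    def test_differing_data_rejected(self, best_fit):
        other = SurvivalFit(
            family_name="weibull", theta=np.zeros(2), covariance=np.eye(2),
            loglik=-10.0, n=best_fit.n + 5, n_events=3, shared_treatment=False,
        )
        with pytest.raises(ValidationError):
            r.select_distribution([best_fit, other])

    def test_selection_consistency_under_known_truth(self):
        """AIC picks the generating family in most pooled-size replicates."""
        wins = 0
        reps = 40
        for rep in range(reps):
            suite = r.generate_benchmark_suite(seed=1000 + rep, shape=2.0)
            fits = r.fit_all_families(suite.true_ipd, shared_treatment=True, seed=rep)
            best, _ = r.select_distribution(fits)
            wins += best.family_name == "log_logistic"
        assert wins / reps >= 0.70


class TestTransitionProbabilities:
    def test_exponential_memoryless_value(self):
        sf = lambda t: np.exp(-0.15069 * t)
        for t0 in (0.0, 3.0, 24.0):
            tp = r.conditional_transition_probability(sf, t0, 1.0)
            assert tp == pytest.approx(1.0 - np.exp(-0.15069), abs=1e-9)
            assert tp == pytest.approx(0.13988, abs=1e-5)

    def test_loglogistic_closed_form(self):
        sf = lambda t: 1.0 / (1.0 + (t / 16.2) ** 2)
        tp = r.conditional_transition_probability(sf, 0.0, 1.0)
        assert tp == pytest.approx(1.0 - 1.0 / (1.0 + (1.0 / 16.2) ** 2), abs=1e-12)
        assert tp == pytest.approx(0.00380, abs=5e-5)

    def test_vanishing_interval_limit(self):
        sf = lambda t: np.exp(-0.2 * t)
        tps = [
            r.conditional_transition_probability(sf, 5.0, d)
            for d in (1.0, 0.1, 0.01, 1e-6)
        ]
        assert tps == sorted(tps, reverse=True)
        assert tps[-1] < 1e-6

    def test_exhausted_state_rejected(self):
        sf = lambda t: max(1.0 - t / 10.0, 0.0)
        with pytest.raises(AbsorbingStateError):
            r.conditional_transition_probability(sf, 10.0, 1.0)


class TestHazardRatioOnProbabilities:
    def test_worked_value(self):
        assert r.apply_hazard_ratio(0.2, 0.62) == pytest.approx(0.12921, abs=1e-5)

    def test_identity_and_zero(self):
        assert r.apply_hazard_ratio(0.37, 1.0) == pytest.approx(0.37)
        assert r.apply_hazard_ratio(0.0, 0.5) == 0.0

    def test_monotone_increasing_in_hr(self):
        # a protective hazard ratio (< 1) lowers the per-cycle probability
        vals = [r.apply_hazard_ratio(0.3, h) for h in (0.4, 0.62, 1.0, 1.5)]
        assert vals == sorted(vals)
        assert vals[0] < 0.3 < vals[-1]

    def test_agrees_with_powered_survival_curve(self):
        # PH on S: S^hr gives the same per-cycle probability transform
        sf = lambda t: np.exp(-0.1 * t**1.3)
        hr = 0.62
        sf_hr = lambda t: sf(t) ** hr
        for t0 in (0.0, 2.0, 9.0):
            tp = r.conditional_transition_probability(sf, t0, 1.0)
            tp_hr = r.conditional_transition_probability(sf_hr, t0, 1.0)
            assert tp_hr == pytest.approx(r.apply_hazard_ratio(tp, hr), abs=1e-12)

    def test_absorbed_probability_rejected(self):
        with pytest.raises(ValidationError):
            r.apply_hazard_ratio(1.0, 0.62)


class TestRateFromMedian:
    @pytest.mark.parametrize(
        "median, rate",
        [(4.60, 0.15069), (3.26, 0.21263), (float(np.log(2.0)), 1.0)],
    )
    def test_values(self, median, rate):
        assert r.rate_from_median(median) == pytest.approx(rate, abs=1e-5)

    def test_round_trip(self):
        assert np.log(2.0) / r.rate_from_median(7.79) == pytest.approx(7.79)

    def test_non_positive_rejected(self):
        with pytest.raises(ValidationError):
            r.rate_from_median(0.0)
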