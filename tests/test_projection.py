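import numpy as np
import pytest

from hivbia import (CohortSpec, ComorbidityEpi, PopulationParams,
                    ValidationError, incidence_at, person_years,
                    project_cohort_population, project_comorbidity_counts)


def _pop(mortality):
    return PopulationParams(national_population=1e6, hiv_prevalence=0.003,
                            diagnosed_fraction=0.9, recent_fraction=0.4,
                            annual_mortality=mortality)


def _epi(young=0.0, old=None, reduction=0.0, threshold=50.0):
    return ComorbidityEpi(comorbidity="renal", cohort="recent",
                          baseline_prevalence=0.1, incidence_young=young,
                          incidence_old=young if old is None else old,
                          age_threshold=threshold,
                          annual_incidence_reduction=reduction)


class TestPopulationProjection:
    def test_geometric_decay_closed_form(self):
        cohort = CohortSpec(label="recent", size_2024=1000,
                            mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.5), (2024, 2026))
        assert traj.alive == pytest.approx([1000, 500, 250])

    def test_no_deaths_constant(self):
        cohort = CohortSpec(label="recent", size_2024=123.4,
                            mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0), (2024, 2034))
        assert np.all(traj.alive == 123.4)

    def test_mean_age_advances_one_per_year(self):
        cohort = CohortSpec(label="longstanding", size_2024=10,
                            mean_age_2024=48)
        traj = project_cohort_population(cohort, _pop(0.02), (2024, 2034))
        assert list(traj.mean_age) == list(range(48, 59))
        assert np.all(np.diff(traj.alive) <= 0)

    def test_published_survivor_counts(self):
        cohort = CohortSpec(label="recent", size_2024=139_390,
                            mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0207), (2024, 2034))
        assert traj.alive[-1] == pytest.approx(113_081, rel=1e-3)


class TestIncidence:
    def test_decay_hand_value(self):
        epi = _epi(young=0.02, reduction=0.01)
        assert incidence_at(epi, 40, 2) == pytest.approx(0.019602)

    def test_no_decay_constant_within_band(self):
        epi = _epi(young=0.03, reduction=0.0)
        assert incidence_at(epi, 40, 0) == incidence_at(epi, 45, 7) == 0.03

    def test_band_switch_at_threshold_inclusive(self):
        # a cohort entering at mean age 48 must switch bands in its third
        # model year, when the mean age reaches exactly 50
        epi = _epi(young=0.01, old=0.04, reduction=0.0)
        ages = [48, 49, 50, 51]
        rates = [incidence_at(epi, a, k) for k, a in enumerate(ages)]
        assert rates == [0.01, 0.01, 0.04, 0.04]

    def test_negative_offset_rejected(self):
        with pytest.raises(ValidationError):
            incidence_at(_epi(0.01), 40, -1)


class TestComorbidityCounts:
    def test_single_cycle_at_risk_pool(self):
        cohort = CohortSpec(label="recent", size_2024=1000, mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0), (2024, 2025))
        counts = project_comorbidity_counts(traj, _epi(young=0.1), 100, 0.0)
        assert counts.prevalent[1] == pytest.approx(190.0)

    def test_static_pool_without_flows(self):
        cohort = CohortSpec(label="recent", size_2024=500, mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0), (2024, 2034))
        counts = project_comorbidity_counts(traj, _epi(young=0.0), 77, 0.0)
        assert np.all(counts.prevalent == 77.0)

    def test_zero_incidence_matches_survival_closed_form(self):
        m = 0.0207
        cohort = CohortSpec(label="recent", size_2024=9000, mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(m), (2024, 2034))
        counts = project_comorbidity_counts(traj, _epi(young=0.0), 800, m)
        expected = 800 * (1 - m) ** np.arange(11)
        np.testing.assert_allclose(counts.prevalent, expected, rtol=1e-12)

    def test_whole_cohort_rule_linear_growth_closed_form(self):
        cohort = CohortSpec(label="recent", size_2024=1000, mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0), (2024, 2034))
        counts = project_comorbidity_counts(traj, _epi(young=0.01), 50, 0.0,
                                            rule="whole-cohort")
        expected = 50 + 0.01 * 1000 * np.arange(11)
        np.testing.assert_allclose(counts.prevalent, expected, rtol=1e-12)

    def test_baseline_exceeding_cohort_rejected(self):
        cohort = CohortSpec(label="recent", size_2024=100, mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0), (2024, 2025))
        with pytest.raises(ValidationError):
            project_comorbidity_counts(traj, _epi(), 101, 0.0)

    def test_engine_matches_independent_loop(self, loop_oracle):
        rng = np.random.default_rng(7)
        for _ in range(100):
            size = rng.uniform(10, 1e5)
            m = rng.uniform(0, 0.3)
            young, old = rng.uniform(0, 0.2, size=2)
            red = rng.uniform(0, 0.05)
            age = rng.uniform(30, 60)
            p0 = rng.uniform(0, size)
            rule = rng.choice(["at-risk", "whole-cohort"])
            cohort = CohortSpec(label="recent", size_2024=size,
                                mean_age_2024=age)
            traj = project_cohort_population(cohort, _pop(m), (2024, 2034))
            epi = _epi(young=young, old=old, reduction=red)
            got = project_comorbidity_counts(traj, epi, p0, m, rule=rule)
            want = loop_oracle(size, age, m, p0, young, old, 50.0, red, 11,
                               rule=rule)
            np.testing.assert_allclose(got.prevalent, want, rtol=1e-9)


class TestPersonYears:
    def test_hand_sum(self):
        assert person_years([100, 50, 25]) == 175

    def test_empty_horizon(self):
        assert person_years([]) == 0

    def test_published_total_person_years(self):
        cohort = CohortSpec(label="recent", size_2024=139_390,
                            mean_age_2024=40)
        traj = project_cohort_population(cohort, _pop(0.0207), (2024, 2034))
        assert person_years(traj) == pytest.approx(1_384_058, rel=1e-3)

    def test_additive_across_cohorts(self, paper_result):
        labels = paper_result.bundle.cohort_labels
        parts = sum(person_years(paper_result.population[c]) for c in labels)
        assert parts == pytest.approx(paper_result.total_person_years())
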