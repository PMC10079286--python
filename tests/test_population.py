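"""Synthetic cohort generation: demographics, behaviour, HPV history."""

import numpy as np
import pytest

from screensim._time import ym
from screensim.population import (
    AdherenceProfile,
    CohortSpec,
    InvalidSpecError,
    assign_hpv_history,
    assign_screening_behaviour,
    generate_cohort,
)
from screensim.programmes import cervix_config, due_date


def _bowel_spec(n=71_000):
    return CohortSpec(programme="bowel", size=n, sex_split_male=3.5 / 7.1)


class TestGenerateCohort:
    def test_size_and_sex_split(self):
        cohort = generate_cohort(_bowel_spec(), seed=1)
        assert len(cohort) == 71_000
        n_male = int(cohort.sex.sum())
        p = 3.5 / 7.1
        sd = np.sqrt(71_000 * p * (1 - p))
        assert abs(n_male - 71_000 * p) < 3 * sd

    def test_single_individual_in_age_range(self):
        spec = CohortSpec(programme="breast", size=1)
        cohort = generate_cohort(spec, seed=3)
        age = cohort.age_years(spec.reference_month)[0]
        assert 50 <= age < 75

    def test_deterministic_given_seed(self):
        a = generate_cohort(_bowel_spec(5000), seed=11)
        b = generate_cohort(_bowel_spec(5000), seed=11)
        assert np.array_equal(a.birth_month, b.birth_month)
        assert np.array_equal(a.sex, b.sex)

    def test_no_individual_outside_age_range(self):
        spec = CohortSpec(programme="cervix", size=20_000, age_min=25, age_max=74)
        cohort = generate_cohort(spec, seed=5)
        ages = cohort.age_years(spec.reference_month)
        assert ages.min() >= 25 and ages.max() < 75

    def test_age_pyramid_table(self):
        spec = CohortSpec(
            programme="breast", size=10_000,
            age_pyramid=((50, 3.0), (60, 1.0)),
        )
        cohort = generate_cohort(spec, seed=2)
        ages = np.floor(cohort.age_years(spec.reference_month)).astype(int)
        assert set(np.unique(ages)) <= {50, 60}
        assert (ages == 50).mean() > 0.6

    def test_invalid_specs_rejected(self):
        with pytest.raises(InvalidSpecError):
            CohortSpec(programme="bowel", size=0)
        with pytest.raises(InvalidSpecError):
            CohortSpec(programme="bowel", size=10, sex_split_male=1.5)
        with pytest.raises(InvalidSpecError):
            CohortSpec(programme="bowel", size=10, age_min=10, age_max=74)


class TestScreeningBehaviour:
    def test_participation_binomial(self):
        cohort = generate_cohort(_bowel_spec(100_000), seed=4)
        assign_screening_behaviour(cohort, 0.435, AdherenceProfile(), seed=4)
        count = int(cohort.participant.sum())
        sd = np.sqrt(100_000 * 0.435 * 0.565)
        assert abs(count - 43_500) < 3 * sd

    def test_zero_participation_means_no_screeners(self):
        cohort = generate_cohort(_bowel_spec(1000), seed=4)
        assign_screening_behaviour(cohort, 0.0, seed=4)
        assert not cohort.participant.any()

    def test_participation_converges_large_n(self):
        # law of large numbers at n=1e6: within 0.3 percentage points
        cohort = generate_cohort(_bowel_spec(1_000_000), seed=9)
        assign_screening_behaviour(cohort, 0.55, seed=9)
        assert abs(cohort.participant.mean() - 0.55) < 0.003

    def test_adherence_profile_bounds(self):
        profile = AdherenceProfile(on_time=(0.60, 0.84))
        assert profile.on_time_for(0) == 0.60
        assert profile.on_time_for(1) == 0.84
        assert profile.on_time_for(7) == 0.84  # clamps to last round

    def test_invalid_participation(self):
        cohort = generate_cohort(_bowel_spec(10), seed=1)
        with pytest.raises(InvalidSpecError):
            assign_screening_behaviour(cohort, 1.2)


class TestHPVHistory:
    def _cohort(self, n=100_000, seed=6):
        spec = CohortSpec(programme="cervix", size=n, age_min=25, age_max=74)
        cohort = generate_cohort(spec, seed)
        assign_screening_behaviour(cohort, 0.46, seed=seed)
        return cohort

    def test_transition_fraction_and_no_2020_dues(self):
        cohort = self._cohort()
        assign_hpv_history(cohort, 0.536, 0.80, seed=6)
        count = int(cohort.hpv_transitioned.sum())
        sd = np.sqrt(100_000 * 0.536 * 0.464)
        assert abs(count - 53_600) < 3 * sd
        # transitioned women are not due for routine screening before Dec 2022
        cfg = cervix_config()
        idx = np.flatnonzero(cohort.hpv_transitioned)[:200]
        for i in idx:
            due = due_date(cohort.individual(i), cfg, ym(2020, 3))
            assert due >= ym(2022, 12)

    def test_all_transitioned_means_no_routine_screens_due_2020(self):
        cohort = self._cohort(5000)
        assign_hpv_history(cohort, 1.0, 0.80, seed=6)
        cfg = cervix_config()
        for i in range(0, 5000, 50):
            due = due_date(cohort.individual(i), cfg, ym(2020, 1))
            assert due > ym(2020, 12)

    def test_due_2020_fraction_matches_schedule_oracle(self):
        # half transitioned; non-transitioned due last_cytology + 24 months,
        # cytology uniform over 2018-2019, so dues land uniformly in 2020-2021
        cohort = self._cohort()
        assign_hpv_history(cohort, 0.5, 0.0, seed=6)
        non_trans = ~cohort.hpv_transitioned
        due = cohort.last_cytology_month[non_trans] + 24
        in_2020 = ((due >= ym(2020, 1)) & (due <= ym(2020, 12))).mean()
        # analytic oracle from the due-date rule: last cytology uniform over
        # 24 months of 2018-2019 -> exactly the 2018 half is due in 2020
        assert abs(in_2020 - 0.5) < 0.01

    def test_requires_cervical_cohort(self):
        cohort = generate_cohort(_bowel_spec(100), seed=1)
        with pytest.raises(InvalidSpecError):
            assign_hpv_history(cohort, 0.5, 0.8)

    def test_vaccination_by_birth_cohort(self):
        cohort = self._cohort(50_000)
        assign_hpv_history(cohort, 0.536, 0.80, seed=6)
        young = cohort.birth_month >= ym(1980, 1)
        assert not cohort.hpv_vaccinated[~young].any()
        if young.sum() > 100:
            assert abs(cohort.hpv_vaccinated[young].mean() - 0.80) < 0.05
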