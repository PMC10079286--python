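import pytest

from screensim.natural_history import NaturalHistoryParams
from screensim.population import (
    AdherenceProfile,
    CohortSpec,
    assign_hpv_history,
    assign_screening_behaviour,
    generate_cohort,
)


@pytest.fixture(scope="session")
def nh_params():
    return NaturalHistoryParams()


@pytest.fixture()
def small_bowel_cohort():
    spec = CohortSpec(programme="bowel", size=2000, sex_split_male=3.5 / 7.1)
    cohort = generate_cohort(spec, seed=7)
    assign_screening_behaviour(cohort, 0.435, AdherenceProfile(), seed=7)
    return cohort


@pytest.fixture()
def small_cervix_cohort():
    spec = CohortSpec(programme="cervix", size=3000, age_min=25, age_max=74)
    cohort = generate_cohort(spec, seed=7)
    assign_screening_behaviour(cohort, 0.46, AdherenceProfile(), seed=7)
    assign_hpv_history(cohort, 0.536, 0.80, seed=7)
    return cohort


def frames_equal(a, b) -> bool:
    """Bitwise comparison of two event-log DataFrames."""
    import pandas as pd

    try:
        pd.testing.assert_frame_equal(a, b, check_exact=True)
        return True
    except AssertionError:
        return False
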