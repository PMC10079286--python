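"""Screening logic: due dates, test outcomes, follow-up pathways."""

import numpy as np
import pytest

from screensim._rng import substream
from screensim._time import ym
from screensim.natural_history import BowelParams, BreastParams, DiseaseArrays, bowel_model, breast_model
from screensim.population import Individual, InvalidSpecError
from screensim.programmes import (
    FollowupPlan,
    ProgrammeConfig,
    ScreenResult,
    bowel_config,
    breast_config,
    cervix_config,
    due_date,
    perform_screen,
    resolve_followup,
    screen_outcome_codes,
    DETECTED_CANCER,
    NEGATIVE,
)


def _woman(birth=ym(1960, 6), **kw):
    return Individual(id=0, sex="female", birth_month=birth, participant=True, **kw)


class TestDueDate:
    def test_breast_biennial_interval(self):
        w = _woman(last_screen_month=0)
        assert due_date(w, breast_config(), 6) == 24

    def test_cervical_first_hpv_two_years_after_cytology(self):
        w = _woman(last_cytology_month=-12)
        assert due_date(w, cervix_config(), 0) == 12

    def test_transitioned_not_due_before_dec_2022(self):
        w = _woman(first_hpv_month=ym(2017, 12))
        assert due_date(w, cervix_config(), ym(2020, 3)) >= ym(2022, 12)

    def test_never_screened_invited_at_invitation_age(self):
        w = _woman(birth=ym(1972, 1))
        assert due_date(w, breast_config(), ym(2020, 1)) == ym(2022, 1)

    def test_ineligible_sex_rejected(self):
        man = Individual(id=1, sex="male", birth_month=ym(1960, 1), participant=True)
        with pytest.raises(InvalidSpecError):
            due_date(man, breast_config(), ym(2020, 1))


class TestPerformScreen:
    def test_healthy_perfect_specificity_always_negative(self):
        cfg = breast_config(specificity=1.0)
        model = breast_model(BreastParams())
        state = DiseaseArrays(model, 100)
        rng = substream(0, "scr")
        for i in range(100):
            res = perform_screen(state, i, cfg, 10, rng)
            assert res.outcome == "negative"

    def test_detected_cancer_carries_stage(self):
        cfg = breast_config()
        model = breast_model(BreastParams())
        state = DiseaseArrays(model, 1)
        state.comp[0] = model.index("preclinical_large")
        rng = substream(1, "scr")
        for _ in range(50):
            res = perform_screen(state, 0, cfg, 5, rng)
            if res.outcome == "detected_cancer":
                assert res.stage == ">15mm"
                break
        else:
            pytest.fail("perfectly sensitive test never detected a large tumour")

    def test_screen_result_invariant(self):
        with pytest.raises(InvalidSpecError):
            ScreenResult(month=0, modality="mammogram", outcome="detected_cancer", stage=None)

    def test_outcome_codes_sensitivity_by_state(self):
        cfg = bowel_config(sensitivity={"adenoma": 0.0, "crc_early": 1.0, "crc_late": 1.0},
                           specificity=1.0)
        model = bowel_model(BowelParams())
        comp = np.array([model.index("adenoma")] * 500 + [model.index("crc_early")] * 500)
        u = substream(2, "u").random(1000)
        codes = screen_outcome_codes(comp, model, cfg, u=u)
        assert (codes[:500] == NEGATIVE).all()
        assert (codes[500:] == DETECTED_CANCER).all()


class TestFollowup:
    def test_positive_ifobt_completion_rate(self):
        # ~70% of positive iFOBTs are followed by a diagnostic colonoscopy
        cfg = bowel_config()
        rng = substream(3, "fu")
        result = ScreenResult(month=0, modality="iFOBT", outcome="recalled_positive")
        n = 100_000
        done = sum(
            resolve_followup(result, cfg, rng).pathway != "lost-to-follow-up"
            for _ in range(n)
        )
        sd = np.sqrt(n * 0.7 * 0.3)
        assert abs(done - 70_000) < 3 * sd

    def test_certain_completion_clear_colonoscopy_returns_in_4y(self):
        cfg = bowel_config(followup_completion=1.0)
        rng = substream(4, "fu")
        result = ScreenResult(month=100, modality="iFOBT", outcome="recalled_positive")
        plan = resolve_followup(result, cfg, rng)
        assert plan.pathway == "return-to-iFOBT-4y"
        assert plan.next_routine_month == 148

    def test_precursor_finding_enters_surveillance(self):
        cfg = bowel_config(followup_completion=1.0)
        rng = substream(5, "fu")
        result = ScreenResult(
            month=0, modality="iFOBT", outcome="detected_precursor", true_state="adenoma"
        )
        plan = resolve_followup(result, cfg, rng)
        assert plan.pathway == "surveillance"
        assert 12 <= plan.surveillance_months <= 60

    def test_breast_recall_resolves_by_assessment(self):
        plan = resolve_followup(
            ScreenResult(month=0, modality="mammogram", outcome="recalled_positive"),
            breast_config(),
            substream(6, "fu"),
        )
        assert plan.pathway == "assessment"

    def test_cervical_positive_goes_to_colposcopy(self):
        plan = resolve_followup(
            ScreenResult(month=0, modality="HPV test", outcome="detected_precursor"),
            cervix_config(),
            substream(7, "fu"),
        )
        assert plan.pathway == "triage-colposcopy"

    def test_negative_result_rejected(self):
        with pytest.raises(InvalidSpecError):
            resolve_followup(
                ScreenResult(month=0, modality="iFOBT", outcome="negative"),
                bowel_config(),
                substream(8, "fu"),
            )

    def test_followup_plan_invariants(self):
        with pytest.raises(InvalidSpecError):
            FollowupPlan(pathway="holiday")
        with pytest.raises(InvalidSpecError):
            FollowupPlan(pathway="surveillance", surveillance_months=6)


def test_config_invariants():
    with pytest.raises(InvalidSpecError):
        breast_config(participation=1.5)
    with pytest.raises(InvalidSpecError):
        ProgrammeConfig(
            programme="bowel", eligible_sex="both", age_min=50, age_max=74,
            interval_months=0, invitation_age=50, participation=0.4,
            sensitivity={}, specificity=0.9,
        )
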