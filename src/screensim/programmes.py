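"""Status quo screening logic for the three national programmes.

Encodes routine intervals, invitation ages, test characteristics and
follow-up pathways: biennial mammography for women 50-74 (all abnormal
screens assessed within the programme), biennial iFOBT for persons
50-74 (positive tests referred to follow-up colonoscopy, completed by
~70%; findings route people back to iFOBT screening after 4 years or
into 1-5-yearly surveillance colonoscopy), and 5-yearly primary HPV
screening for women 25-74 with a collapsed positive->colposcopy triage
pathway.

Test sensitivities are expressed per detectable disease compartment and
are calibration parameters, not literature constants.  Colonoscopy and
colposcopy are perfectly sensitive for invasive cancer; precursor
sensitivity is configurable.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .natural_history import DiseaseArrays, DiseaseModel
from .population import Individual, InvalidSpecError

# screen outcome codes (vectorised form)
NEGATIVE = 0
FALSE_POSITIVE = 1  # recalled/positive with no disease behind it
DETECTED_PRECURSOR = 2
DETECTED_CANCER = 3

OUTCOME_NAMES = {
    NEGATIVE: "negative",
    FALSE_POSITIVE: "recalled_positive",
    DETECTED_PRECURSOR: "detected_precursor",
    DETECTED_CANCER: "detected_cancer",
}

MODALITY = {"breast": "mammogram", "bowel": "iFOBT", "cervix": "HPV test"}
ASSESSMENT = {"breast": "assessment", "bowel": "colonoscopy", "cervix": "colposcopy"}


@dataclass(frozen=True)
class ProgrammeConfig:
    """Parameters of one screening programme."""

    programme: str
    eligible_sex: str  # "female" | "both"
    age_min: int
    age_max: int
    interval_months: int
    invitation_age: int
    participation: float
    sensitivity: dict[str, float]  # by compartment name
    specificity: float
    followup_completion: float = 1.0
    precursor_colonoscopy_sensitivity: float = 0.95
    surveillance_months: tuple[int, ...] = (36,)
    return_months: int = 48  # bowel: back to iFOBT after clear colonoscopy

    def __post_init__(self) -> None:
        if self.interval_months <= 0:
            raise InvalidSpecError("routine interval must be positive")
        probs = [self.participation, self.specificity, self.followup_completion]
        probs += list(self.sensitivity.values())
        if any(not 0.0 <= p <= 1.0 for p in probs):
            raise InvalidSpecError("probabilities must lie in [0, 1]")
        if any(not 12 <= m <= 60 for m in self.surveillance_months):
            raise InvalidSpecError("surveillance intervals must lie in 12..60 months")


def breast_config(**overrides) -> ProgrammeConfig:
    base = ProgrammeConfig(
        programme="breast",
        eligible_sex="female",
        age_min=50,
        age_max=74,
        interval_months=24,
        invitation_age=50,
        participation=0.55,
        sensitivity={"preclinical_small": 0.88, "preclinical_large": 0.95},
        specificity=0.9535,
    )
    return replace(base, **overrides) if overrides else base


def bowel_config(**overrides) -> ProgrammeConfig:
    base = ProgrammeConfig(
        programme="bowel",
        eligible_sex="both",
        age_min=50,
        age_max=74,
        interval_months=24,
        invitation_age=50,
        participation=0.435,
        sensitivity={"adenoma": 0.215, "crc_early": 0.946, "crc_late": 1.0},
        specificity=0.905,
        followup_completion=0.70,
        surveillance_months=(12, 36, 60),
    )
    return replace(base, **overrides) if overrides else base


def cervix_config(**overrides) -> ProgrammeConfig:
    base = ProgrammeConfig(
        programme="cervix",
        eligible_sex="female",
        age_min=25,
        age_max=74,
        interval_months=60,
        invitation_age=25,
        participation=0.46,
        sensitivity={
            "hpv": 0.90,
            "cin": 0.92,
            "localised": 0.95,
            "regional": 0.98,
            "distant": 0.99,
        },
        specificity=0.93,
        followup_completion=0.90,  # colposcopy referral/attendance after a positive test
        surveillance_months=(12,),
    )
    return replace(base, **overrides) if overrides else base


DEFAULT_CONFIGS = {
    "breast": breast_config,
    "bowel": bowel_config,
    "cervix": cervix_config,
}


@dataclass(frozen=True)
class ScreenResult:
    """Outcome of one screening episode."""

    month: int
    modality: str
    outcome: str
    stage: str | None = None
    true_state: str = "healthy"

    def __post_init__(self) -> None:
        if self.outcome == "detected_cancer" and self.stage is None:
            raise InvalidSpecError("detected cancers must carry a stage label")


@dataclass(frozen=True)
class FollowupPlan:
    """What happens after a positive/recalled screen."""

    pathway: str  # return-to-iFOBT-4y | surveillance | triage-colposcopy | assessment
    next_routine_month: int | None = None
    surveillance_months: int | None = None

    def __post_init__(self) -> None:
        # "lost-to-follow-up" is the explicit loss record for positives whose
        # diagnostic follow-up is never completed
        valid = {"return-to-iFOBT-4y", "surveillance", "triage-colposcopy",
                 "assessment", "lost-to-follow-up"}
        if self.pathway not in valid:
            raise InvalidSpecError(f"unknown pathway {self.pathway!r}")
        if self.surveillance_months is not None and not 12 <= self.surveillance_months <= 60:
            raise InvalidSpecError("surveillance interval must lie in 12..60 months")


# ---------------------------------------------------------------------------
# operations


def due_date(individual: Individual, config: ProgrammeConfig, current_month: int) -> int:
    """Scheduled month of the next routine screen.

    Never-screened people are invited at the invitation age.  Cervical
    transition rules: women who have attended their first primary HPV
    test are due five years after it; women still on the cytology
    pathway are due their first HPV test two years after their last
    cytology test.
    """
    age = individual.age_years(current_month)
    if config.eligible_sex == "female" and individual.sex != "female":
        raise InvalidSpecError("individual not eligible for this programme (sex)")
    if age > config.age_max + 1:
        raise InvalidSpecError("individual beyond the eligible age range")

    invitation_month = individual.birth_month + config.invitation_age * 12
    if config.programme == "cervix":
        if individual.first_hpv_month is not None:
            return individual.first_hpv_month + config.interval_months
        if individual.last_cytology_month is not None:
            return individual.last_cytology_month + 24
        return max(invitation_month, current_month)
    if individual.last_screen_month is not None:
        return individual.last_screen_month + config.interval_months
    return max(invitation_month, current_month)


def screen_outcome_codes(
    comp: np.ndarray,
    model: DiseaseModel,
    config: ProgrammeConfig,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
    sensitivity_factor: float = 1.0,
) -> np.ndarray:
    """Vectorised primary-test outcomes for true compartments ``comp``.

    ``u`` lets callers supply pre-drawn uniforms (common-random-number
    pairing); ``sensitivity_factor`` scales all sensitivities (used for
    the pre-renewal cytology test).
    """
    n = len(comp)
    out = np.full(n, NEGATIVE, dtype=np.int8)
    if u is None:
        u = rng.random(n)
    sens = np.zeros(n)
    detectable = np.zeros(n, dtype=bool)
    for name, s in config.sensitivity.items():
        c = model.index(name)
        mask = comp == c
        sens[mask] = min(s * sensitivity_factor, 1.0)
        detectable[mask] = True
    hit = detectable & (u < sens)
    is_cancer = np.isin(comp, list(model.cancer_comps))
    out[hit & is_cancer] = DETECTED_CANCER
    out[hit & ~is_cancer] = DETECTED_PRECURSOR
    fp = ~detectable & (u < 1.0 - config.specificity)
    out[fp] = FALSE_POSITIVE
    return out


def perform_screen(
    state: DiseaseArrays,
    i: int,
    config: ProgrammeConfig,
    month: int,
    rng: np.random.Generator,
) -> ScreenResult:
    """Screen person ``i`` at ``month`` and return the episode result."""
    comp = np.array([state.comp[i]])
    code = int(screen_outcome_codes(comp, state.model, config, rng)[0])
    true_state = state.model.compartments[int(state.comp[i])]
    stage = None
    if code == DETECTED_CANCER:
        stage = state.stage_label(i)
    return ScreenResult(
        month=month,
        modality=MODALITY[config.programme],
        outcome=OUTCOME_NAMES[code],
        stage=stage,
        true_state=true_state,
    )


def resolve_followup(
    result: ScreenResult,
    config: ProgrammeConfig,
    rng: np.random.Generator,
) -> FollowupPlan:
    """Route a positive/recalled screen down its programme's pathway.

    Bowel: follow-up colonoscopy completed with probability
    ``followup_completion`` (~0.70); adenoma findings enter 1-5-yearly
    surveillance, otherwise return to iFOBT screening after 4 years.
    Breast: recall resolves by assessment within the programme.
    Cervix: positives referred to colposcopy.
    """
    if result.outcome == "negative":
        raise InvalidSpecError("follow-up applies to positive/recalled screens only")
    if config.programme == "breast":
        return FollowupPlan(pathway="assessment")
    if config.programme == "cervix":
        return FollowupPlan(pathway="triage-colposcopy")
    # bowel
    if rng.random() >= config.followup_completion:
        # colonoscopy never completed; person stays on the routine biennial schedule
        return FollowupPlan(pathway="lost-to-follow-up",
                            next_routine_month=result.month + config.interval_months)
    if result.outcome == "detected_precursor":
        months = int(rng.choice(config.surveillance_months))
        return FollowupPlan(pathway="surveillance", surveillance_months=months)
    return FollowupPlan(
        pathway="return-to-iFOBT-4y",
        next_routine_month=result.month + config.return_months,
    )
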