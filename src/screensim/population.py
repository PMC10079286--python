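"""Synthetic screening-eligible cohorts.

Generates scalable stand-ins for the Australian populations targeted by
the three national cancer screening programmes: persons 50-74 for bowel
screening (7.1 M nationally; 3.5 M men, 3.6 M women), women 50-74 for
breast screening, and women 25-74 for cervical screening.  Cohorts are
columnar (numpy arrays) for speed; :class:`Individual` offers a
row-level view for inspection and unit testing.

Ages are uniform within the eligible range by default (an optional
age-pyramid table is accepted); cohorts are closed over the short
reporting horizon.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._rng import substream
from ._time import ym

FEMALE = 0
MALE = 1

#: sentinel for "no such event"
NEVER = -(10**6)


class InvalidSpecError(ValueError):
    """Raised when a cohort specification violates its invariants."""


@dataclass(frozen=True)
class CohortSpec:
    """Demographic specification of a screening-eligible cohort.

    Parameters
    ----------
    programme:
        ``"breast"``, ``"bowel"`` or ``"cervix"``.
    size:
        Number of simulated persons (after scaling).
    age_min, age_max:
        Inclusive eligible age range in years at ``reference_month``.
    sex_split_male:
        Fraction male (0 for the female-only programmes).
    scale:
        Scale factor relative to the national cohort (1/100 for
        desk-scale runs); count outputs are multiplied back by
        ``1/scale`` on report.
    reference_month:
        Calendar month (index) at which ages are evaluated.
    age_pyramid:
        Optional ``(age_years, weight)`` table; defaults to uniform.
    """

    programme: str
    size: int
    age_min: int = 50
    age_max: int = 74
    sex_split_male: float = 0.0
    scale: float = 0.01
    reference_month: int = ym(2020, 1)
    age_pyramid: tuple[tuple[int, float], ...] | None = None

    def __post_init__(self) -> None:
        if self.size <= 0:
            raise InvalidSpecError(f"cohort size must be positive, got {self.size}")
        if not 0.0 <= self.sex_split_male <= 1.0:
            raise InvalidSpecError("sex split must lie in [0, 1]")
        if not (18 <= self.age_min <= self.age_max <= 85):
            raise InvalidSpecError("age range must lie within [18, 85]")
        if self.scale <= 0:
            raise InvalidSpecError("scale factor must be positive")
        if self.programme not in ("breast", "bowel", "cervix"):
            raise InvalidSpecError(f"unknown programme {self.programme!r}")


@dataclass(frozen=True)
class AdherenceProfile:
    """Attendance-delay behaviour of screeners.

    ``on_time`` is the probability of attending in the scheduled month,
    configurable per screening round (observed round-specific on-schedule
    attendance spans roughly 0.60-0.84); late attenders delay by
    ``1 + Geometric`` months with the given mean.
    """

    on_time: float | Sequence[float] = 0.72
    late_mean_months: float = 6.0

    def on_time_for(self, round_index: int) -> float:
        if np.isscalar(self.on_time):
            return float(self.on_time)  # type: ignore[arg-type]
        seq = list(self.on_time)  # type: ignore[arg-type]
        return float(seq[min(round_index, len(seq) - 1)])


@dataclass
class Individual:
    """Row-level view of one simulated person."""

    id: int
    sex: str
    birth_month: int
    participant: bool
    hpv_transitioned: bool | None = None
    hpv_vaccinated: bool | None = None
    last_cytology_month: int | None = None
    first_hpv_month: int | None = None
    last_screen_month: int | None = None
    events: list = field(default_factory=list)

    def age_years(self, month: int) -> float:
        return (month - self.birth_month) / 12.0


class Cohort:
    """Columnar collection of simulated persons for one programme."""

    def __init__(self, spec: CohortSpec, birth_month: np.ndarray, sex: np.ndarray):
        n = spec.size
        assert len(birth_month) == n and len(sex) == n
        self.spec = spec
        self.ids = np.arange(n, dtype=np.int64)
        self.birth_month = birth_month.astype(np.int64)
        self.sex = sex.astype(np.int8)
        self.participant = np.zeros(n, dtype=bool)
        self.on_time_prob = np.zeros(n, dtype=float)
        self.late_mean = np.zeros(n, dtype=float)
        self.adherence: AdherenceProfile | None = None
        # cervical-programme fields (meaningful only when programme == "cervix")
        self.hpv_transitioned = np.zeros(n, dtype=bool)
        self.hpv_vaccinated = np.zeros(n, dtype=bool)
        self.last_cytology_month = np.full(n, NEVER, dtype=np.int64)
        self.first_hpv_month = np.full(n, NEVER, dtype=np.int64)

    def __len__(self) -> int:
        return self.spec.size

    @property
    def n(self) -> int:
        return self.spec.size

    def age_years(self, month: int) -> np.ndarray:
        return (month - self.birth_month) / 12.0

    def individual(self, i: int) -> Individual:
        cervical = self.spec.programme == "cervix"
        return Individual(
            id=int(self.ids[i]),
            sex="male" if self.sex[i] == MALE else "female",
            birth_month=int(self.birth_month[i]),
            participant=bool(self.participant[i]),
            hpv_transitioned=bool(self.hpv_transitioned[i]) if cervical else None,
            hpv_vaccinated=bool(self.hpv_vaccinated[i]) if cervical else None,
            last_cytology_month=(
                int(self.last_cytology_month[i])
                if cervical and self.last_cytology_month[i] != NEVER
                else None
            ),
            first_hpv_month=(
                int(self.first_hpv_month[i])
                if cervical and self.first_hpv_month[i] != NEVER
                else None
            ),
        )

    def to_frame(self) -> pd.DataFrame:
        """Columnar text-friendly view (one row per person)."""
        df = pd.DataFrame(
            {
                "id": self.ids,
                "sex": np.where(self.sex == MALE, "male", "female"),
                "birth_month": self.birth_month,
                "participant": self.participant.astype(int),
            }
        )
        if self.spec.programme == "cervix":
            df["hpv_transitioned"] = self.hpv_transitioned.astype(int)
            df["hpv_vaccinated"] = self.hpv_vaccinated.astype(int)
        return df

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def generate_cohort(spec: CohortSpec, seed: int) -> Cohort:
    """Draw a cohort matching ``spec``; deterministic given ``seed``.

    Ages at the reference month are uniform over the eligible range
    unless ``spec.age_pyramid`` supplies integer-age weights.
    """
    rng = substream(seed, f"population/{spec.programme}")
    n = spec.size
    if spec.age_pyramid is None:
        age_months = rng.integers(spec.age_min * 12, (spec.age_max + 1) * 12, size=n)
    else:
        ages = np.array([a for a, _ in spec.age_pyramid])
        weights = np.array([w for _, w in spec.age_pyramid], dtype=float)
        if (weights < 0).any() or weights.sum() <= 0:
            raise InvalidSpecError("age pyramid weights must be non-negative, not all zero")
        years = rng.choice(ages, size=n, p=weights / weights.sum())
        age_months = years * 12 + rng.integers(0, 12, size=n)
    birth_month = spec.reference_month - age_months
    sex = (rng.random(n) < spec.sex_split_male).astype(np.int8)
    return Cohort(spec, birth_month, sex)


def assign_screening_behaviour(
    cohort: Cohort,
    participation: float,
    adherence_profile: AdherenceProfile | None = None,
    seed: int = 0,
) -> Cohort:
    """Mark ever-screeners and draw attendance-delay behaviour in place.

    A fraction ``participation`` of the cohort are ever-screeners
    (binomial draw); each screener receives an on-schedule attendance
    probability and a mean lateness from ``adherence_profile``.
    """
    if not 0.0 <= participation <= 1.0:
        raise InvalidSpecError(f"participation must lie in [0, 1], got {participation}")
    profile = adherence_profile or AdherenceProfile()
    rng = substream(seed, f"behaviour/{cohort.spec.programme}")
    cohort.participant = rng.random(cohort.n) < participation
    cohort.adherence = profile
    cohort.on_time_prob = np.full(cohort.n, profile.on_time_for(0))
    # per-person lateness propensity: mean lateness jittered +-25% around profile
    cohort.late_mean = profile.late_mean_months * rng.uniform(0.75, 1.25, cohort.n)
    return cohort


def assign_hpv_history(
    cohort: Cohort,
    transitioned_fraction: float,
    vaccination_coverage: float,
    seed: int = 0,
    first_hpv_window: tuple[int, int] = (ym(2017, 12), ym(2020, 2)),
    last_cytology_window: tuple[int, int] = (ym(2018, 1), ym(2019, 12)),
    vaccinated_born_after: int = ym(1980, 1),
) -> Cohort:
    """Assign HPV-era screening history to a cervical cohort in place.

    ``transitioned_fraction`` of screeners have already attended their
    first 5-yearly primary HPV test (drawn uniformly over
    ``first_hpv_window``) and are not due again for at least five years
    (i.e. not before December 2022 for a pre-2018 first test); the rest
    are due two years after their last cytology test, drawn uniformly
    over ``last_cytology_window``.  Vaccination flags are set by birth
    cohort: coverage applies to women born after ``vaccinated_born_after``
    (school-programme cohorts).
    """
    if cohort.spec.programme != "cervix":
        raise InvalidSpecError("HPV history applies only to cervical cohorts")
    if not 0.0 <= transitioned_fraction <= 1.0:
        raise InvalidSpecError("transitioned fraction must lie in [0, 1]")
    if not 0.0 <= vaccination_coverage <= 1.0:
        raise InvalidSpecError("vaccination coverage must lie in [0, 1]")
    rng = substream(seed, "hpv_history")
    n = cohort.n
    transitioned = rng.random(n) < transitioned_fraction
    cohort.hpv_transitioned = transitioned
    lo, hi = first_hpv_window
    cohort.first_hpv_month = np.where(
        transitioned, rng.integers(lo, hi + 1, size=n), NEVER
    )
    clo, chi = last_cytology_window
    cohort.last_cytology_month = np.where(
        ~transitioned, rng.integers(clo, chi + 1, size=n), NEVER
    )
    eligible = cohort.birth_month >= vaccinated_born_after
    cohort.hpv_vaccinated = eligible & (rng.random(n) < vaccination_coverage)
    return cohort
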