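"""Disruption scenarios: time-varying capacity, attendance modifiers and
rescheduling rules.

A scenario is a single continuous national disruption to one programme:
either a complete pause of throughput (breast, bowel) or a reduction in
routine-screening attendance (cervix), followed by a recovery.  Breast
recovery ramps linearly over six months, reaching the target capacity
(100% or 150% of status quo) in the seventh month after resumption;
bowel resumption is instantaneous; cervical recovery is expressed as
rescheduling of missed screens over 2021 or 2021-2022.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from ._time import APRIL_2020, ym
from .population import InvalidSpecError

PAUSE = "pause"
ATTENDANCE_REDUCTION = "attendance_reduction"

# rescheduling policy tags
NEXT_ROUND = "next-round"  # bowel: screened at the next round, 2 y later
ALL_2021 = "all-2021"  # cervix 9-mo: all missed screens attended in 2021
SPREAD_2021_2022 = "spread-2021-2022"  # cervix 6-/12-mo
QUEUE = "queue"  # breast: enqueue into the prioritisation queue
NONE = "none"


@dataclass(frozen=True)
class DisruptionScenario:
    """One programme disruption relative to status quo."""

    programme: str
    duration_months: int
    pause_start: int = APRIL_2020
    mode: str = PAUSE
    reduction_degree: float = 0.0
    recovery_target: float = 1.0
    ramp_months: int = 6  # target reached in the (ramp_months+1)-th month
    ramp_start_fraction: float = 0.45
    instant_resumption: bool = False
    opportunistic_multiplier: float = 0.5
    reschedule_policy: str = NONE

    def __post_init__(self) -> None:
        if self.duration_months < 0:
            raise InvalidSpecError("pause duration must be >= 0")
        if not 0.0 <= self.reduction_degree <= 1.0:
            raise InvalidSpecError("attendance-reduction degree must lie in [0, 1]")
        if self.recovery_target < 1.0:
            raise InvalidSpecError("recovery target multiplier must be >= 1")
        if self.mode not in (PAUSE, ATTENDANCE_REDUCTION):
            raise InvalidSpecError(f"unknown disruption mode {self.mode!r}")

    @property
    def pause_end(self) -> int:
        """First month after the disruption window."""
        return self.pause_start + self.duration_months

    def in_window(self, month: int) -> bool:
        return self.pause_start <= month < self.pause_end


def breast_scenario(duration_months: int, **overrides) -> DisruptionScenario:
    """Breast pause starting 1 April 2020; 150% recovery for a 12-mo pause."""
    target = 1.5 if duration_months >= 12 else 1.0
    sc = DisruptionScenario(
        programme="breast",
        duration_months=duration_months,
        recovery_target=target,
        reschedule_policy=QUEUE if duration_months > 0 else NONE,
    )
    return replace(sc, **overrides) if overrides else sc


def bowel_scenario(duration_months: int, **overrides) -> DisruptionScenario:
    """Bowel pause: instant resumption; the 12-mo pause spans calendar 2020."""
    start = ym(2020, 1) if duration_months >= 12 else APRIL_2020
    sc = DisruptionScenario(
        programme="bowel",
        duration_months=duration_months,
        pause_start=start,
        instant_resumption=True,
        ramp_start_fraction=1.0,
        reschedule_policy=NEXT_ROUND if duration_months > 0 else NONE,
    )
    return replace(sc, **overrides) if overrides else sc


#: attendance-reduction degree by cervical disruption duration (months)
CERVIX_DEGREE = {6: 0.50, 9: 0.75, 12: 0.95}


def cervix_scenario(duration_months: int, **overrides) -> DisruptionScenario:
    """Cervical attendance reduction over 2020 with catch-up in 2021(-22).

    The 12-month disruption covers calendar 2020; shorter ones start in
    April 2020.  Reduction degrees are 50/75/95% for 6/9/12 months.
    """
    degree = CERVIX_DEGREE.get(duration_months, 0.0)
    policy = NONE
    if duration_months == 9:
        policy = ALL_2021
    elif duration_months in (6, 12):
        policy = SPREAD_2021_2022
    start = ym(2020, 1) if duration_months >= 12 else APRIL_2020
    sc = DisruptionScenario(
        programme="cervix",
        duration_months=duration_months,
        pause_start=start,
        mode=ATTENDANCE_REDUCTION,
        reduction_degree=degree,
        reschedule_policy=policy,
    )
    return replace(sc, **overrides) if overrides else sc


STATUS_QUO = {
    "breast": lambda: breast_scenario(0),
    "bowel": lambda: bowel_scenario(0),
    "cervix": lambda: cervix_scenario(0),
}


class CapacitySchedule:
    """Calendar-anchored per-month throughput multipliers."""

    def __init__(self, start_month: int, multipliers: np.ndarray):
        if (np.asarray(multipliers) < 0).any():
            raise InvalidSpecError("capacity multipliers must be >= 0")
        self.start_month = start_month
        self.multipliers = np.asarray(multipliers, dtype=float)

    def multiplier(self, month: int) -> float:
        i = month - self.start_month
        if i < 0:
            return 1.0
        if i >= len(self.multipliers):
            return float(self.multipliers[-1]) if len(self.multipliers) else 1.0
        return float(self.multipliers[i])

    def window(self, first: int, last: int) -> np.ndarray:
        return np.array([self.multiplier(m) for m in range(first, last + 1)])


def build_capacity_schedule(
    scenario: DisruptionScenario, horizon_months: int
) -> CapacitySchedule:
    """Throughput multipliers from the pause start over ``horizon_months``.

    Complete pauses zero out throughput for the pause duration, then
    either resume instantly at the recovery target or ramp linearly from
    ``ramp_start_fraction`` so the target is reached in the seventh
    month after resumption.  Attendance-reduction scenarios leave
    throughput at 1.0 (the disruption acts on attendance instead).
    """
    if horizon_months < scenario.duration_months:
        raise InvalidSpecError("horizon shorter than the pause")
    mult = np.ones(horizon_months)
    if scenario.mode == ATTENDANCE_REDUCTION or scenario.duration_months == 0:
        return CapacitySchedule(scenario.pause_start, mult)
    d = scenario.duration_months
    mult[:d] = 0.0
    if scenario.instant_resumption:
        mult[d:] = scenario.recovery_target
        return CapacitySchedule(scenario.pause_start, mult)
    s = scenario.ramp_start_fraction
    t = scenario.recovery_target
    r = scenario.ramp_months
    for k in range(horizon_months - d):
        mult[d + k] = s + (t - s) * min(k, r) / r if r > 0 else t
    return CapacitySchedule(scenario.pause_start, mult)


def attendance_modifier(
    scenario: DisruptionScenario, month: int, stream: str = "routine"
) -> float:
    """Multiplier on attendance probability for one visit stream.

    Cervical scenarios reduce *routine* primary-screening attendance only
    (surveillance and follow-up visits are unaffected); the breast
    opportunistic stream (screening outside the programme) is halved
    during the pause and back to normal on resumption.
    """
    if not scenario.in_window(month):
        return 1.0
    if stream == "opportunistic":
        return scenario.opportunistic_multiplier
    if scenario.mode == ATTENDANCE_REDUCTION and stream == "routine":
        return 1.0 - scenario.reduction_degree
    return 1.0


def reschedule_missed(
    scenario: DisruptionScenario,
    missed_month: int,
    rng: np.random.Generator | None = None,
) -> int | None:
    """New due month for a screen missed in the disruption window.

    Bowel screens move to the next round two years later; missed
    cervical screens are re-attended uniformly over 2021 (9-mo policy)
    or over 2021-2022 (6-/12-mo policy); breast screens return ``None``
    and must be enqueued into the prioritisation queue.
    """
    policy = scenario.reschedule_policy
    if policy == NEXT_ROUND:
        return missed_month + 24
    if policy == ALL_2021:
        rng = np.random.default_rng() if rng is None else rng
        return int(rng.integers(ym(2021, 1), ym(2021, 12) + 1))
    if policy == SPREAD_2021_2022:
        rng = np.random.default_rng() if rng is None else rng
        return int(rng.integers(ym(2021, 1), ym(2022, 12) + 1))
    if policy == QUEUE:
        return None
    raise InvalidSpecError(f"unknown rescheduling policy {policy!r}")
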