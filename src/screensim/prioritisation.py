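"""Capacity-constrained allocation of breast-screening appointments
during recovery.

When BreastScreen resumes after a pause, available appointments are
rationed by a four-factor priority: (i) whether the client is in the
50-74 target age range, (ii) whether her appointment fell during the
pause or during the recovery period, (iii) whether she is an existing
client or newly invited, and (iv) how long she is overdue (most overdue
first).  The factor ordering is configurable; the default places target
age first and overdue time last-but-decisive, with ties broken by id so
allocation is fully deterministic given queue contents and capacity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._time import WEEKS_PER_MONTH
from .population import InvalidSpecError
from .scenario import CapacitySchedule

DEFAULT_FACTOR_ORDER = ("target_age", "period", "client", "overdue")


@dataclass(frozen=True)
class BookingRequest:
    """One woman waiting for a screening appointment."""

    individual_id: int
    age_years: float
    newly_invited: bool
    scheduled_month: int
    period_class: str  # "pause" | "recovery"

    def __post_init__(self) -> None:
        if self.period_class not in ("pause", "recovery"):
            raise InvalidSpecError(f"unknown period class {self.period_class!r}")

    def weeks_overdue(self, now_month: int) -> float:
        return max(0.0, (now_month - self.scheduled_month) * WEEKS_PER_MONTH)


@dataclass(frozen=True)
class PriorityKey:
    """Total order over booking requests (smaller sorts first)."""

    key: tuple

    def __lt__(self, other: "PriorityKey") -> bool:
        return self.key < other.key


def priority_key(
    request: BookingRequest,
    now_month: int,
    factor_order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
) -> PriorityKey:
    """Deterministic priority of ``request`` at allocation time.

    Women aged 50-74 strictly precede others; appointments that fell
    during the pause precede recovery-period ones; existing clients
    precede the newly invited; within equal leading factors, the most
    overdue comes first.  Ties break by individual id.
    """
    factors = {
        "target_age": 0 if 50 <= request.age_years <= 74 else 1,
        "period": 0 if request.period_class == "pause" else 1,
        "client": 1 if request.newly_invited else 0,
        "overdue": -request.weeks_overdue(now_month),
    }
    key = tuple(factors[f] for f in factor_order) + (request.individual_id,)
    return PriorityKey(key)


def allocate(
    queue: list[BookingRequest],
    schedule: CapacitySchedule,
    month: int,
    base_capacity: float,
    factor_order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
) -> tuple[list[BookingRequest], list[BookingRequest]]:
    """Book the top requests within this month's capacity.

    Capacity is ``floor(base_capacity * multiplier(month))`` screens;
    unbooked requests are carried (their overdue time keeps growing).
    """
    if base_capacity < 0:
        raise InvalidSpecError("base capacity must be >= 0")
    cap = math.floor(base_capacity * schedule.multiplier(month))
    ranked = sorted(queue, key=lambda r: priority_key(r, month, factor_order))
    return ranked[:cap], ranked[cap:]


def queue_frame(
    queue: list[BookingRequest],
    now_month: int,
    factor_order: tuple[str, ...] = DEFAULT_FACTOR_ORDER,
) -> pd.DataFrame:
    """Audit view of a booking queue, in allocation order.

    One row per request with its key fields and computed overdue time;
    write with ``.to_csv(path, sep="\\t", index=False)`` for a TSV dump.
    """
    ranked = sorted(queue, key=lambda r: priority_key(r, now_month, factor_order))
    return pd.DataFrame(
        {
            "rank": range(len(ranked)),
            "id": [r.individual_id for r in ranked],
            "age_years": [round(r.age_years, 2) for r in ranked],
            "newly_invited": [r.newly_invited for r in ranked],
            "scheduled_month": [r.scheduled_month for r in ranked],
            "period_class": [r.period_class for r in ranked],
            "weeks_overdue": [round(r.weeks_overdue(now_month), 1) for r in ranked],
        }
    )


def median_screening_interval(
    screens: pd.DataFrame,
    subgroup_ids: np.ndarray | list | None = None,
    window: tuple[int, int] | None = None,
) -> float | None:
    """Median screen-to-screen interval in weeks.

    ``screens`` must have ``id`` and ``month`` columns, one row per
    attended screen.  Intervals are between consecutive attended screens
    of the same woman, restricted to intervals *ending* inside
    ``window`` (inclusive month indices) when given; ``subgroup_ids``
    restricts to those women.  Returns ``None`` when no completed
    interval exists in the subgroup.
    """
    df = screens[["id", "month"]].sort_values(["id", "month"])
    if subgroup_ids is not None:
        df = df[df["id"].isin(np.asarray(subgroup_ids))]
    prev = df.groupby("id")["month"].shift()
    gaps = (df["month"] - prev).dropna()
    ends = df.loc[gaps.index, "month"]
    if window is not None:
        keep = (ends >= window[0]) & (ends <= window[1])
        gaps = gaps[keep]
    if len(gaps) == 0:
        return None
    return float(np.median(gaps) * WEEKS_PER_MONTH)
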