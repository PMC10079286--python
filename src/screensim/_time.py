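"""Calendar helpers.

Simulation time is an integer month index anchored at January 2000
(month 0).  All programme rules in this package are calendar-anchored
(pauses start on specific months, reporting windows are calendar years),
so a single global epoch keeps arithmetic trivial and unambiguous.
"""

from __future__ import annotations

EPOCH_YEAR = 2000

MONTHS_PER_YEAR = 12
WEEKS_PER_MONTH = 365.25 / 12 / 7  # 4.348

# Widely used calendar anchors.
APRIL_2020 = (2020 - EPOCH_YEAR) * 12 + 3
JAN_2020 = (2020 - EPOCH_YEAR) * 12
DEC_2022 = (2022 - EPOCH_YEAR) * 12 + 11


def ym(year: int, month: int) -> int:
    """Month index for calendar ``year``/``month`` (month is 1-based)."""
    if not 1 <= month <= 12:
        raise ValueError(f"month must be in 1..12, got {month}")
    return (year - EPOCH_YEAR) * 12 + (month - 1)


def year_of(month_index: int) -> int:
    return EPOCH_YEAR + month_index // 12


def months_to_weeks(months: float) -> float:
    return months * WEEKS_PER_MONTH


def year_window(first_year: int, last_year: int) -> tuple[int, int]:
    """Inclusive month-index window covering whole calendar years."""
    return ym(first_year, 1), ym(last_year, 12)
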