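"""Brute-force oracle for the four-factor booking priority order."""

from screensim.prioritisation import BookingRequest


def random_requests(rng, n):
    return [
        BookingRequest(
            individual_id=int(i),
            age_years=float(rng.uniform(40, 80)),
            newly_invited=bool(rng.random() < 0.3),
            scheduled_month=int(rng.integers(230, 250)),
            period_class="pause" if rng.random() < 0.5 else "recovery",
        )
        for i in range(int(n))
    ]


def _less(a: BookingRequest, b: BookingRequest, now: int) -> bool:
    """Literal pairwise application of the four factors plus id tie-break."""
    ka = (
        0 if 50 <= a.age_years <= 74 else 1,
        0 if a.period_class == "pause" else 1,
        1 if a.newly_invited else 0,
        -a.weeks_overdue(now),
        a.individual_id,
    )
    kb = (
        0 if 50 <= b.age_years <= 74 else 1,
        0 if b.period_class == "pause" else 1,
        1 if b.newly_invited else 0,
        -b.weeks_overdue(now),
        b.individual_id,
    )
    return ka < kb


def oracle_sorted(reqs, now):
    """Selection sort using only pairwise comparisons (exhaustive oracle)."""
    remaining = list(reqs)
    out = []
    while remaining:
        best = remaining[0]
        for r in remaining[1:]:
            if _less(r, best, now):
                best = r
        remaining.remove(best)
        out.append(best)
    return out
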