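"""Reported programme metrics.

Computes, from paired (scenario vs status quo) simulation runs sharing
a seed and cohort: screens provided and missed, cancer diagnoses and
rates per 100,000 (full population denominator, including people who do
not participate in screening), interval cancer rates at 12 and 27
months, programme sensitivity, recall rates, stage/size/nodal/grade
distributions, upstaging attribution, and diagnostic service demand.

Upstaging attribution follows excess-flow bookkeeping over an ordered
stage ladder: the net excess of diagnoses in the catch-up years is
assigned to the earliest stage; any increase in the most advanced stage
is attributed to upstaging from the stage below; residual changes in
the intermediate stages are attributed to upstaging from the stage
above them in the ladder.  Defined for the cervical three-stage ladder
(localised/regional/distant) and generalised to the colorectal
two-stage ladder (1-2 / 3-4).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ._time import ym, year_of
from .population import InvalidSpecError

SCREEN_DETECTED = "screen-detected"
INTERVAL_12 = "interval-12"
INTERVAL_27 = "interval-27"
OTHER = "other"


@dataclass(frozen=True)
class DetectionRecord:
    """One cancer diagnosis with its detection mode."""

    individual_id: int
    cancer: str
    month: int
    mode: str
    stage: str


@dataclass(frozen=True)
class StageShiftRecord:
    """Cancers attributed as upstaged due to a disruption."""

    window: tuple[int, int]  # first and last calendar year
    shifts: dict[str, float]  # e.g. {"localised->regional": 18, "regional->distant": 9}
    additional: float  # net excess diagnoses assigned to the earliest stage
    status_quo_cases: float

    @property
    def total_upstaged(self) -> float:
        return float(sum(self.shifts.values()))

    @property
    def pct_upstaged(self) -> float:
        """Upstaged cancers as a percentage of status quo cases."""
        return 100.0 * self.total_upstaged / self.status_quo_cases

    @property
    def affected(self) -> float:
        """Women affected by delays: additional plus upstaged cancers."""
        return self.additional + self.total_upstaged


# ---------------------------------------------------------------------------
# detection-mode classification


def classify_detection_mode(
    diagnosis_month: int,
    diagnosed_by_screen: bool,
    negative_screen_months: np.ndarray | list[int],
) -> str:
    """Detection mode of one diagnosis given the person's screen history.

    Screen-detected if the diagnosis results from a screening episode;
    otherwise interval-12/interval-27 if a negative screen occurred
    within 12 (respectively 27) months before diagnosis; otherwise
    ``other``.  The 12-month class is nested inside the 27-month class;
    the finest applicable label is returned.
    """
    if diagnosed_by_screen:
        return SCREEN_DETECTED
    negs = np.asarray(negative_screen_months)
    prior = negs[(negs < diagnosis_month)]
    if len(prior) == 0:
        return OTHER
    gap = diagnosis_month - prior.max()
    if gap <= 12:
        return INTERVAL_12
    if gap <= 27:
        return INTERVAL_27
    return OTHER


def classify_modes(diagnoses: pd.DataFrame, screens: pd.DataFrame) -> pd.DataFrame:
    """Vectorised detection-mode classification.

    ``diagnoses`` needs columns ``id``, ``month``, ``by_screen``;
    ``screens`` needs ``id``, ``month``, ``outcome`` (negative episodes
    are those with outcome ``"negative"``).  Returns a copy of
    ``diagnoses`` with ``mode`` and ``months_since_negative`` columns.
    """
    out = diagnoses.reset_index(drop=True).copy()
    negs = screens[screens["outcome"] == "negative"][["id", "month"]]
    merged = out[["id", "month"]].reset_index().merge(
        negs, on="id", how="left", suffixes=("", "_neg")
    )
    merged = merged[merged["month_neg"] < merged["month"]]
    last_neg = merged.groupby("index")["month_neg"].max()
    gap = np.full(len(out), np.nan)
    pos = last_neg.index.to_numpy()
    gap[pos] = out["month"].to_numpy()[pos] - last_neg.to_numpy()
    out["months_since_negative"] = gap
    mode = np.where(
        out["by_screen"].to_numpy(),
        SCREEN_DETECTED,
        np.where(
            gap <= 12, INTERVAL_12, np.where(gap <= 27, INTERVAL_27, OTHER)
        ),
    )
    out["mode"] = mode
    return out


def programme_sensitivity(screen_detected: float, interval_27: float) -> float | None:
    """Screen-detected cancers as a % of screen-detected + interval (27 mo).

    Returns ``None`` when both counts are zero (undefined).
    """
    if screen_detected < 0 or interval_27 < 0:
        raise InvalidSpecError("counts must be non-negative")
    total = screen_detected + interval_27
    if total == 0:
        return None
    return 100.0 * screen_detected / total


# ---------------------------------------------------------------------------
# upstaging attribution

CERVIX_STAGES = ("localised", "regional", "distant")
BOWEL_STAGES = ("1-2", "3-4")


def upstaging_attribution(
    status_quo: pd.DataFrame,
    scenario: pd.DataFrame,
    window: tuple[int, int],
    stages: tuple[str, ...] = CERVIX_STAGES,
) -> StageShiftRecord:
    """Attribute stage shifts between paired stage-by-year count tables.

    Both tables are indexed by calendar year with one column per stage
    (ordered least to most advanced).  Over the window: (1) the net
    excess of total diagnoses is assigned to the earliest stage;
    (2) any increase in the most advanced stage is attributed to
    upstaging from the stage below; (3) residual changes in intermediate
    stages are attributed to upstaging from the stage above them in the
    ladder (i.e. the next-lower stage), worked from the most advanced
    stage downwards.
    """
    for tbl in (status_quo, scenario):
        if set(stages) - set(tbl.columns):
            raise InvalidSpecError("stage tables must cover the configured stages")
    y0, y1 = window
    years = range(y0, y1 + 1)
    sq = status_quo.reindex(years).fillna(0.0)[list(stages)]
    sc = scenario.reindex(years).fillna(0.0)[list(stages)]
    delta = (sc - sq).sum(axis=0)  # per-stage change over the window
    additional = float(delta.sum())
    shifts: dict[str, float] = {}
    # work down the ladder: excess at the top is upstaging from below
    carried = 0.0  # flow already attributed onward out of the upper stage
    for j in range(len(stages) - 1, 0, -1):
        upper, lower = stages[j], stages[j - 1]
        shift = max(float(delta[upper]) + carried, 0.0)
        shifts[f"{lower}->{upper}"] = shift
        carried = shift
    sq_total = float(sq.to_numpy().sum())
    return StageShiftRecord(
        window=window, shifts=shifts, additional=additional, status_quo_cases=sq_total
    )


# ---------------------------------------------------------------------------
# tabulation


def _count_window(df: pd.DataFrame, first: int, last: int) -> int:
    return int(((df["month"] >= first) & (df["month"] <= last)).sum())


def screens_in_window(result, first: int, last: int, stream: str | None = "routine") -> int:
    s = result.screens
    if stream is not None:
        s = s[s["stream"] == stream]
    return _count_window(s, first, last)


def demand_summary(diagnostics: pd.DataFrame, window: tuple[int, int]) -> dict[str, int]:
    """Diagnostic service volumes over an inclusive month window.

    ``diagnostics`` has columns ``id``, ``month``, ``procedure``.
    NBCSP-related colonoscopies are the sum of follow-up and
    surveillance colonoscopies.
    """
    d = diagnostics[(diagnostics["month"] >= window[0]) & (diagnostics["month"] <= window[1])]
    counts = d["procedure"].value_counts()
    followup = int(counts.get("colonoscopy_followup", 0))
    surveillance = int(counts.get("colonoscopy_surveillance", 0))
    return {
        "followup_colonoscopies": followup,
        "surveillance_colonoscopies": surveillance,
        "nbcsp_colonoscopies": followup + surveillance,
        "colposcopies": int(counts.get("colposcopy", 0)),
        "assessments": int(counts.get("assessment", 0)),
    }


def stage_by_year(diagnoses: pd.DataFrame, stages: tuple[str, ...]) -> pd.DataFrame:
    """Count table of cancer diagnoses by calendar year and stage."""
    d = diagnoses.copy()
    d["year"] = d["month"].apply(year_of)
    tbl = d.pivot_table(index="year", columns="stage", aggfunc="size", fill_value=0)
    for s in stages:
        if s not in tbl.columns:
            tbl[s] = 0
    return tbl[list(stages)].astype(float)


@dataclass
class OutcomeTable:
    """Per-programme metrics for a scenario against its paired status quo."""

    programme: str
    rows: pd.DataFrame  # columns: metric, status_quo, scenario, change, pct_change

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    def to_json(self) -> dict:
        return {
            "programme": self.programme,
            "metrics": self.rows.set_index("metric").to_dict(orient="index"),
        }

    def value(self, metric: str, column: str = "scenario") -> float:
        row = self.rows[self.rows["metric"] == metric]
        if row.empty:
            raise KeyError(metric)
        return float(row.iloc[0][column])


def _rate_per_100k_per_year(count: float, population: int, years: float) -> float:
    return 1e5 * count / population / years


def breast_summary(result, window_years: tuple[int, int] = (2020, 2021)) -> dict[str, float]:
    """Status-quo-style breast metrics for one run (no pairing needed)."""
    y0, y1 = window_years
    w = (ym(y0, 1), ym(y1, 12))
    years = y1 - y0 + 1
    n = result.cohort_n
    diag = classify_modes(result.diagnoses, result.screens)
    in_w = diag[(diag["month"] >= w[0]) & (diag["month"] <= w[1])]
    # programme screen-detected only; opportunistic detections count towards
    # population diagnoses but not programme metrics
    sd = in_w[(in_w["mode"] == SCREEN_DETECTED) & (in_w["source"] == "programme")]
    total = len(in_w)
    # interval cancers: 12-mo window counts diagnoses in the first year only,
    # 27-mo window counts diagnoses over both years (reporting convention)
    ic12 = int(
        (
            (diag["mode"] == INTERVAL_12)
            & (diag["month"] >= ym(y0, 1))
            & (diag["month"] <= ym(y0, 12))
        ).sum()
    )
    ic27 = int(
        (
            diag["mode"].isin([INTERVAL_12, INTERVAL_27])
            & (diag["month"] >= w[0])
            & (diag["month"] <= w[1])
        ).sum()
    )
    screens = result.screens
    episodes = screens[
        (screens["stream"].isin(["routine", "queued"]))
        & (screens["month"] >= w[0])
        & (screens["month"] <= w[1])
    ]
    n_episodes = len(episodes)
    recalled = int((episodes["outcome"] != "negative").sum())
    fp = int((episodes["outcome"] == "recalled_positive").sum())
    sens = programme_sensitivity(len(sd), ic27)
    out = {
        "diagnoses_per_100k": _rate_per_100k_per_year(total, n, years),
        "screen_detected_per_100k": _rate_per_100k_per_year(len(sd), n, years),
        "interval_12_per_100k": _rate_per_100k_per_year(ic12, n, 1),
        "interval_27_per_100k": _rate_per_100k_per_year(ic27, n, years),
        "programme_sensitivity_pct": float("nan") if sens is None else sens,
        "pct_small": 100.0 * (sd["stage"] == "<=15mm").mean() if len(sd) else float("nan"),
        "pct_nodal": 100.0 * sd["nodal"].mean() if len(sd) else float("nan"),
        "pct_grade3": 100.0 * sd["grade3"].mean() if len(sd) else float("nan"),
        "recall_rate_pct": 100.0 * recalled / n_episodes if n_episodes else float("nan"),
        "fp_recall_rate_pct": 100.0 * fp / n_episodes if n_episodes else float("nan"),
        "screens_apr20_mar21": _count_window(
            result.screens[result.screens["stream"] != "opportunistic"],
            ym(2020, 4),
            ym(2021, 3),
        ),
        "diagnoses": float(total),
    }
    return out


def bowel_summary(result, window_years: tuple[int, int] = (2020, 2021)) -> dict[str, float]:
    y0, y1 = window_years
    w = (ym(y0, 1), ym(y1, 12))
    diag = result.diagnoses
    in_w = diag[(diag["month"] >= w[0]) & (diag["month"] <= w[1])]
    cancers = in_w[in_w["stage"].isin(BOWEL_STAGES)]
    late = int((cancers["stage"] == "3-4").sum())
    dem = demand_summary(result.diagnostics, w)
    return {
        "kits_apr20_mar21": _count_window(result.screens, ym(2020, 4), ym(2021, 3)),
        "crc_diagnoses": float(len(cancers)),
        "pct_stage_34": 100.0 * late / len(cancers) if len(cancers) else float("nan"),
        "nbcsp_colonoscopies": float(dem["nbcsp_colonoscopies"]),
    }


def cervix_summary(result, window_years: tuple[int, int] = (2020, 2022)) -> dict[str, float]:
    y0, y1 = window_years
    w = (ym(y0, 1), ym(y1, 12))
    diag = result.diagnoses
    cancers = diag[diag["stage"].isin(CERVIX_STAGES)]
    in_w = cancers[(cancers["month"] >= w[0]) & (cancers["month"] <= w[1])]
    dem = demand_summary(result.diagnostics, w)
    return {
        "cervical_diagnoses": float(len(in_w)),
        "colposcopies": float(dem["colposcopies"]),
        "screens_apr20_mar21": _count_window(result.screens, ym(2020, 4), ym(2021, 3)),
    }


SUMMARIES = {"breast": breast_summary, "bowel": bowel_summary, "cervix": cervix_summary}


def tabulate(scenario_result, status_quo_result, window_years=None) -> OutcomeTable:
    """Paired scenario-vs-status-quo outcome table for one programme.

    Runs must share programme, seed and cohort size; count metrics are
    rescaled to national scale by ``1/scale``.
    """
    sc, sq = scenario_result, status_quo_result
    if sc.programme != sq.programme or sc.seed != sq.seed or sc.cohort_n != sq.cohort_n:
        raise InvalidSpecError("tabulate requires paired runs (same programme/seed/cohort)")
    prog = sc.programme
    kwargs = {} if window_years is None else {"window_years": window_years}
    m_sc = SUMMARIES[prog](sc, **kwargs)
    m_sq = SUMMARIES[prog](sq, **kwargs)
    count_metrics = {
        "screens_apr20_mar21", "kits_apr20_mar21", "diagnoses", "crc_diagnoses",
        "nbcsp_colonoscopies", "cervical_diagnoses", "colposcopies",
    }
    rows = []
    for metric in m_sq:
        a, b = m_sq[metric], m_sc[metric]
        if metric in count_metrics:
            a, b = a / sc.scale, b / sc.scale
        change = b - a
        pct = 100.0 * change / a if a else float("nan")
        rows.append(
            {"metric": metric, "status_quo": a, "scenario": b, "change": change,
             "pct_change": pct}
        )
    return OutcomeTable(programme=prog, rows=pd.DataFrame(rows))
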