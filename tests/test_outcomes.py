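"""Outcome metrics: detection-mode classification, programme
sensitivity, upstaging attribution, demand summaries, tabulation."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from screensim._time import ym
from screensim.engine import run_pair
from screensim.outcomes import (
    BOWEL_STAGES,
    CERVIX_STAGES,
    INTERVAL_12,
    INTERVAL_27,
    OTHER,
    SCREEN_DETECTED,
    classify_detection_mode,
    classify_modes,
    demand_summary,
    programme_sensitivity,
    stage_by_year,
    tabulate,
    upstaging_attribution,
)
from screensim.population import InvalidSpecError
from screensim.scenario import bowel_scenario, breast_scenario


class TestClassifyDetectionMode:
    def test_symptomatic_10mo_after_negative_is_interval12(self):
        assert classify_detection_mode(110, False, [100]) == INTERVAL_12

    def test_symptomatic_20mo_after_negative_is_interval27(self):
        assert classify_detection_mode(120, False, [100]) == INTERVAL_27

    def test_no_prior_screen_is_other(self):
        assert classify_detection_mode(110, False, []) == OTHER

    def test_screen_detected(self):
        assert classify_detection_mode(110, True, [100]) == SCREEN_DETECTED

    @settings(derandomize=True, max_examples=200)
    @given(
        diag=st.integers(100, 160),
        by_screen=st.booleans(),
        negs=st.lists(st.integers(80, 159), max_size=5),
    )
    def test_vectorised_matches_rule_oracle(self, diag, by_screen, negs):
        diagnoses = pd.DataFrame({"id": [1], "month": [diag], "by_screen": [by_screen]})
        screens = pd.DataFrame(
            {"id": [1] * len(negs), "month": negs, "outcome": ["negative"] * len(negs)}
        )
        got = classify_modes(diagnoses, screens)["mode"].iloc[0]
        assert got == classify_detection_mode(diag, by_screen, negs)


class TestProgrammeSensitivity:
    def test_reported_three_month_column(self):
        assert programme_sensitivity(117, 35) == pytest.approx(77.0, abs=0.05)

    def test_boundaries(self):
        assert programme_sensitivity(10, 0) == 100.0
        assert programme_sensitivity(0, 10) == 0.0
        assert programme_sensitivity(0, 0) is None

    def test_negative_counts_rejected(self):
        with pytest.raises(InvalidSpecError):
            programme_sensitivity(-1, 5)


def _table(years, stages, counts):
    return pd.DataFrame(counts, index=years, columns=list(stages), dtype=float)


def _flow_oracle(sq, sc, stages):
    """Hand-coded sequential bookkeeping of the attribution rules."""
    delta = (sc - sq).sum(axis=0)
    shifts = {}
    carried = 0.0
    for j in range(len(stages) - 1, 0, -1):
        s = max(float(delta[stages[j]]) + carried, 0.0)
        shifts[f"{stages[j-1]}->{stages[j]}"] = s
        carried = s
    return shifts, float(delta.sum())


class TestUpstagingAttribution:
    def test_reported_cervical_example(self):
        # 12-mo scenario: L->R 18, R->D 9 against 1878 status quo cases
        years = [2020, 2021, 2022]
        sq = _table(years, CERVIX_STAGES, [[400, 150, 76], [400, 150, 76], [400, 150, 76]])
        sc_counts = np.array(sq)
        sc = _table(years, CERVIX_STAGES, sc_counts)
        sc.loc[2021, "localised"] += 69 - 18 + 18  # additional cases (net of shifts)
        sc.loc[2021, "localised"] -= 18
        sc.loc[2021, "regional"] += 18 - 9
        sc.loc[2021, "distant"] += 9
        rec = upstaging_attribution(sq, sc, (2020, 2022))
        assert rec.shifts["regional->distant"] == 9
        assert rec.shifts["localised->regional"] == 18
        assert rec.additional == pytest.approx(69)
        assert rec.pct_upstaged == pytest.approx(100 * 27 / 1878, abs=0.01)
        assert rec.affected == pytest.approx(69 + 27)

    def test_identical_tables_zero_record(self):
        sq = _table([2020, 2021], CERVIX_STAGES, [[5, 3, 1], [5, 3, 1]])
        rec = upstaging_attribution(sq, sq.copy(), (2020, 2021))
        assert rec.total_upstaged == 0 and rec.additional == 0

    def test_mismatched_stage_sets_rejected(self):
        sq = _table([2020], CERVIX_STAGES, [[5, 3, 1]])
        bad = _table([2020], ("a", "b", "c"), [[5, 3, 1]])
        with pytest.raises(InvalidSpecError):
            upstaging_attribution(sq, bad, (2020, 2020))

    @settings(derandomize=True, max_examples=200)
    @given(data=st.data())
    def test_matches_flow_oracle_on_small_tables(self, data):
        years = [2020, 2021]
        cell = st.integers(0, 20)
        sq = _table(years, CERVIX_STAGES,
                    [[data.draw(cell) for _ in range(3)] for _ in years])
        sc = _table(years, CERVIX_STAGES,
                    [[data.draw(cell) for _ in range(3)] for _ in years])
        rec = upstaging_attribution(sq, sc, (2020, 2021))
        oracle_shifts, oracle_additional = _flow_oracle(sq, sc, CERVIX_STAGES)
        assert rec.shifts == oracle_shifts
        assert rec.additional == pytest.approx(oracle_additional)

    def test_conservation_bound(self):
        # attribution never creates or destroys cancers
        sq = _table([2020, 2021], BOWEL_STAGES, [[60, 30], [60, 30]])
        sc = _table([2020, 2021], BOWEL_STAGES, [[55, 36], [58, 31]])
        rec = upstaging_attribution(sq, sc, (2020, 2021), stages=BOWEL_STAGES)
        delta_total = float((sc - sq).to_numpy().sum())
        assert rec.additional == pytest.approx(delta_total)
        assert rec.shifts["1-2->3-4"] == pytest.approx(7)


class TestDemandSummary:
    def test_counting_oracle(self):
        diag = pd.DataFrame(
            {
                "id": range(5),
                "month": [240] * 5,
                "procedure": ["colonoscopy_followup"] * 3
                + ["colonoscopy_surveillance"] * 2,
            }
        )
        out = demand_summary(diag, (230, 250))
        assert out["followup_colonoscopies"] == 3
        assert out["surveillance_colonoscopies"] == 2
        assert out["nbcsp_colonoscopies"] == 5

    def test_empty_period_zero_demand(self):
        diag = pd.DataFrame({"id": [1], "month": [240], "procedure": ["colposcopy"]})
        out = demand_summary(diag, (0, 100))
        assert sum(out.values()) == 0


class TestTabulate:
    def test_status_quo_against_itself_all_changes_zero(self):
        sq, sc = run_pair("bowel", bowel_scenario(0), seed=2, scale=0.002)
        table = tabulate(sc, sq)
        assert (table.rows["change"].abs() < 1e-9).all()

    def test_unpaired_runs_rejected(self):
        sq1, _ = run_pair("bowel", bowel_scenario(0), seed=2, scale=0.002)
        sq2, _ = run_pair("bowel", bowel_scenario(0), seed=3, scale=0.002)
        with pytest.raises(InvalidSpecError):
            tabulate(sq1, sq2)

    def test_counts_rescaled_to_national(self):
        sq, sc = run_pair("bowel", bowel_scenario(0), seed=2, scale=0.002)
        table = tabulate(sc, sq)
        kits_raw = int(
            ((sq.screens.month >= ym(2020, 4)) & (sq.screens.month <= ym(2021, 3))).sum()
        )
        assert table.value("kits_apr20_mar21", "status_quo") == pytest.approx(
            kits_raw / 0.002
        )


def test_interval_nesting_in_simulation():
    # every interval-12 cancer is also an interval-27 cancer
    sq, _ = run_pair("breast", breast_scenario(0), seed=4, scale=0.003)
    modes = classify_modes(sq.diagnoses, sq.screens)
    gap = modes["months_since_negative"]
    sym = ~modes["by_screen"]
    assert ((gap[sym & (gap <= 12)] <= 27)).all()
    n12 = int((sym & (gap <= 12)).sum())
    n27 = int((sym & (gap <= 27)).sum())
    assert n12 <= n27


def test_stage_by_year_shapes():
    diag = pd.DataFrame(
        {"id": [1, 2], "month": [ym(2020, 5), ym(2021, 7)],
         "stage": ["localised", "distant"]}
    )
    tbl = stage_by_year(diag, CERVIX_STAGES)
    assert tbl.loc[2020, "localised"] == 1
    assert tbl.loc[2021, "distant"] == 1
    assert tbl.loc[2020, "regional"] == 0
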