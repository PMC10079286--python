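"""Per-programme microsimulation drivers.

Each driver advances a cohort month-by-month from a pre-2020 burn-in
through the reporting horizon, combining the disease chain
(:mod:`natural_history`), programme screening logic
(:mod:`programmes`), disruption rules (:mod:`scenario`) and, for
breast recovery, the capacity-constrained booking queue
(:mod:`prioritisation`).

Common random numbers: every month draws fixed-size uniform vectors
from a month-keyed substream of the master seed, so a scenario run and
its paired status quo run see identical disease progression and test
randomness for every person-month.  Scenario effects are then estimated
as low-variance paired differences.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._rng import substream
from ._time import ym
from .natural_history import (
    HEALTHY,
    DiseaseArrays,
    NaturalHistoryParams,
    bowel_model,
    breast_model,
    cervix_model,
    initialize_states,
)
from .population import (
    NEVER,
    AdherenceProfile,
    Cohort,
    CohortSpec,
    InvalidSpecError,
    assign_hpv_history,
    assign_screening_behaviour,
    generate_cohort,
)
from .prioritisation import BookingRequest, allocate
from .programmes import (
    DEFAULT_CONFIGS,
    DETECTED_CANCER,
    FALSE_POSITIVE,
    NEGATIVE,
    OUTCOME_NAMES,
    ProgrammeConfig,
    screen_outcome_codes,
)
from .scenario import (
    DisruptionScenario,
    attendance_modifier,
    bowel_scenario,
    breast_scenario,
    build_capacity_schedule,
    cervix_scenario,
    reschedule_missed,
)

RENEWAL_START = ym(2017, 12)  # cervical programme transition to primary HPV


@dataclass(frozen=True)
class EngineOptions:
    """Run-level switches shared by the three drivers."""

    sim_start: int = ym(2014, 1)
    sim_end: int = ym(2022, 12)
    opportunistic_monthly: float = 0.004  # breast screening outside the programme
    mortality: bool = False  # background mortality (long-horizon runs)


@dataclass
class RunResult:
    """Event logs and metadata from one simulation run."""

    programme: str
    scenario: DisruptionScenario
    seed: int
    scale: float
    cohort_n: int
    screens: pd.DataFrame
    diagnoses: pd.DataFrame
    diagnostics: pd.DataFrame
    base_monthly_capacity: float | None = None
    extras: dict = field(default_factory=dict)


class _Recorder:
    def __init__(self) -> None:
        self.screens: list[tuple] = []
        self.diagnoses: list[tuple] = []
        self.diagnostics: list[tuple] = []

    def screen(self, ids, month, outcome_codes, stream, true_state) -> None:
        for i, c, t in zip(ids, outcome_codes, true_state):
            self.screens.append((int(i), month, OUTCOME_NAMES[int(c)], stream, t))

    def diagnosis(self, i, month, source, stage, nodal=False, grade3=False) -> None:
        self.diagnoses.append(
            (int(i), month, source != "symptomatic", source, stage, bool(nodal), bool(grade3))
        )

    def procedure(self, ids, month, name) -> None:
        for i in np.atleast_1d(ids):
            self.diagnostics.append((int(i), month, name))

    def frames(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        screens = pd.DataFrame(
            self.screens, columns=["id", "month", "outcome", "stream", "true_state"]
        )
        diagnoses = pd.DataFrame(
            self.diagnoses,
            columns=["id", "month", "by_screen", "source", "stage", "nodal", "grade3"],
        )
        diagnostics = pd.DataFrame(self.diagnostics, columns=["id", "month", "procedure"])
        return screens, diagnoses, diagnostics


LATENESS_CAP = 11  # months; keeps a late attendance within its own round


def _lateness(
    idx: np.ndarray,
    u_onsched: np.ndarray,
    geom: np.ndarray,
    on_time: np.ndarray,
) -> np.ndarray:
    """Months of lateness for screens scheduled this month.

    Geometric with the profile's mean, capped below half a biennial
    round: beyond that a register re-anchors the person to the next
    round rather than mailing two kits in quick succession.
    """
    late = u_onsched[idx] >= on_time[idx]
    return np.where(late, np.minimum(geom[idx], LATENESS_CAP), 0)


def _monthly_mortality(age_years: np.ndarray) -> np.ndarray:
    # Gompertz-like all-cause hazard: ~0.3%/y at 50 doubling every ~9 y
    return 2.6e-4 * np.exp2((age_years - 50.0) / 9.0)


# ---------------------------------------------------------------------------
# breast


def run_breast(
    cohort: Cohort,
    config: ProgrammeConfig,
    nh: NaturalHistoryParams,
    scenario: DisruptionScenario,
    seed: int,
    options: EngineOptions | None = None,
    base_capacity: float | None = None,
) -> RunResult:
    """Simulate the breast programme for one cohort under one scenario."""
    opt = options or EngineOptions()
    pb = nh.breast
    model = breast_model(pb)
    n = cohort.n
    state = DiseaseArrays(model, n)
    init_rng = substream(seed, "breast/init")
    initialize_states(
        state,
        opt.sim_start - cohort.birth_month,
        opt.sim_start,
        init_rng,
        disease_start_age=20,
        breast_params=pb,
    )
    diagnosed = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    last_screen = np.full(n, NEVER, dtype=np.int64)
    round_count = np.zeros(n, dtype=np.int32)
    profile = cohort.adherence or AdherenceProfile()
    on_time_table = np.array([profile.on_time_for(r) for r in range(40)])
    late_mean = np.maximum(cohort.late_mean, 1.0)

    # initial schedule: people already past the invitation age stagger
    # uniformly over one interval; younger people start at their invitation
    # month (uniform by birthday, so monthly volumes stay level)
    attend = np.full(n, NEVER, dtype=np.int64)
    invite = cohort.birth_month + config.invitation_age * 12
    stagger = opt.sim_start + init_rng.integers(0, config.interval_months, size=n)
    s0 = np.where(invite <= opt.sim_start, stagger, invite)
    part = cohort.participant
    # first screens attend at the staggered month exactly: adding lateness at
    # the window boundary would dent the first months and send a spurious
    # 2-yearly volume wave through the whole simulation
    attend[part] = s0[part]

    disrupted = scenario.duration_months > 0
    if disrupted:
        if base_capacity is None:
            raise InvalidSpecError("scenario breast runs need base_capacity from a paired status quo run")
        horizon = opt.sim_end - scenario.pause_start + 1
        schedule = build_capacity_schedule(scenario, horizon)
    queue: list[BookingRequest] = []
    pause_missed: set[int] = set()
    monthly_attended: dict[int, int] = {}
    rec = _Recorder()

    age_max_m = (config.age_max + 1) * 12

    def _schedule_next(idx: np.ndarray, m: int, u_onsched, geom) -> None:
        if len(idx) == 0:
            return
        s = m + config.interval_months
        ok = (s - cohort.birth_month[idx]) < age_max_m
        idx = idx[ok]
        ot = on_time_table[np.minimum(round_count[idx], 39)]
        late = np.where(u_onsched[idx] >= ot, geom[idx], 0)
        attend[idx] = s + late

    for m in range(opt.sim_start, opt.sim_end + 1):
        rng = substream(seed, f"breast/m{m}")
        newly = state.step_month(m, rng, active=alive & ~diagnosed, breast_params=pb)
        u_screen = rng.random(n)
        u_opp = rng.random(n)
        u_onsched = rng.random(n)
        geom = rng.geometric(1.0 / late_mean)
        u_death = rng.random(n) if opt.mortality else None

        # symptomatic presentations
        for i in np.flatnonzero(newly):
            stage = model.stage_labels[int(state.presented_stage[i])]
            rec.diagnosis(i, m, "symptomatic", stage, state.nodal[i], state.grade3[i])
        diagnosed |= newly

        due = np.flatnonzero((attend == m) & ~diagnosed & alive)
        if disrupted and m >= scenario.pause_start:
            in_pause = scenario.in_window(m)
            for i in due:
                queue.append(
                    BookingRequest(
                        individual_id=int(i),
                        age_years=float((m - cohort.birth_month[i]) / 12.0),
                        newly_invited=last_screen[i] == NEVER,
                        scheduled_month=m,
                        period_class="pause" if in_pause else "recovery",
                    )
                )
                if in_pause:
                    pause_missed.add(int(i))
            attend[due] = NEVER
            queue = [r for r in queue if not diagnosed[r.individual_id] and alive[r.individual_id]]
            booked, queue = allocate(queue, schedule, m, base_capacity)
            attendees = np.array([r.individual_id for r in booked], dtype=np.int64)
            stream = "queued"
        else:
            attendees = due
            stream = "routine"

        if len(attendees):
            codes = screen_outcome_codes(
                state.comp[attendees], model, config, u=u_screen[attendees]
            )
            rec.screen(
                attendees,
                m,
                codes,
                stream,
                [model.compartments[c] for c in state.comp[attendees]],
            )
            det = attendees[codes == DETECTED_CANCER]
            for i in det:
                rec.diagnosis(
                    i, m, "programme", state.stage_label(i), state.nodal[i], state.grade3[i]
                )
            rec.procedure(det, m, "assessment")
            fp = attendees[codes == FALSE_POSITIVE]
            rec.procedure(fp, m, "assessment")
            diagnosed[det] = True
            last_screen[attendees] = m
            round_count[attendees] += 1
            cont = attendees[codes != DETECTED_CANCER]
            _schedule_next(cont, m, u_onsched, geom)
            if not disrupted:
                monthly_attended[m] = len(attendees)

        # opportunistic screening outside the programme (non-participants)
        p_opp = opt.opportunistic_monthly * attendance_modifier(scenario, m, "opportunistic")
        in_age = (m - cohort.birth_month >= config.age_min * 12) & (
            m - cohort.birth_month < age_max_m
        )
        opp = np.flatnonzero(
            ~cohort.participant & alive & ~diagnosed & in_age & (u_opp < p_opp)
        )
        if len(opp):
            codes = screen_outcome_codes(state.comp[opp], model, config, u=u_screen[opp])
            rec.screen(
                opp, m, codes, "opportunistic",
                [model.compartments[c] for c in state.comp[opp]],
            )
            det = opp[codes == DETECTED_CANCER]
            for i in det:
                rec.diagnosis(
                    i, m, "opportunistic", state.stage_label(i), state.nodal[i], state.grade3[i]
                )
            diagnosed[det] = True

        if opt.mortality:
            h = _monthly_mortality((m - cohort.birth_month) / 12.0)
            alive &= ~(u_death < h)

    screens, diagnoses, diagnostics = rec.frames()
    pre = [monthly_attended.get(mm, 0) for mm in range(scenario.pause_start - 12, scenario.pause_start)]
    base = float(np.mean(pre)) if not disrupted else base_capacity
    return RunResult(
        programme="breast",
        scenario=scenario,
        seed=seed,
        scale=cohort.spec.scale,
        cohort_n=n,
        screens=screens,
        diagnoses=diagnoses,
        diagnostics=diagnostics,
        base_monthly_capacity=base,
        extras={
            "pause_missed_ids": np.array(sorted(pause_missed), dtype=np.int64),
            "carried_queue": len(queue) if disrupted else 0,
        },
    )


# ---------------------------------------------------------------------------
# bowel


def run_bowel(
    cohort: Cohort,
    config: ProgrammeConfig,
    nh: NaturalHistoryParams,
    scenario: DisruptionScenario,
    seed: int,
    options: EngineOptions | None = None,
) -> RunResult:
    """Simulate the bowel programme (iFOBT + colonoscopy pathways)."""
    opt = options or EngineOptions()
    pbw = nh.bowel
    model = bowel_model(pbw)
    n = cohort.n
    state = DiseaseArrays(model, n)
    init_rng = substream(seed, "bowel/init")
    initialize_states(
        state, opt.sim_start - cohort.birth_month, opt.sim_start, init_rng,
        disease_start_age=30,
    )
    diagnosed = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    last_screen = np.full(n, NEVER, dtype=np.int64)
    profile = cohort.adherence or AdherenceProfile()
    on_time = np.full(n, profile.on_time_for(0))
    late_mean = np.maximum(cohort.late_mean, 1.0)

    # kits are mailed on an anchored biennial schedule: the next round is due
    # two years after the previous *scheduled* round, and lateness is one-off
    # jitter around the anchor rather than cumulative drift.  This keeps
    # monthly kit volumes level (no beat between a drifting cycle and the
    # calendar), matching the postal programme's fixed mailing cadence.
    attend = np.full(n, NEVER, dtype=np.int64)
    sched = np.full(n, NEVER, dtype=np.int64)
    invite = cohort.birth_month + config.invitation_age * 12
    stagger = opt.sim_start + init_rng.integers(0, config.interval_months, size=n)
    s0 = np.where(invite <= opt.sim_start, stagger, invite)
    part = cohort.participant
    sched[part] = s0[part]
    attend[part] = s0[part]

    colono_month = np.full(n, NEVER, dtype=np.int64)
    colono_surv = np.zeros(n, dtype=bool)
    surv_menu = np.array(config.surveillance_months)

    disrupted = scenario.duration_months > 0
    rec = _Recorder()
    age_max_m = (config.age_max + 1) * 12

    for m in range(opt.sim_start, opt.sim_end + 1):
        rng = substream(seed, f"bowel/m{m}")
        newly = state.step_month(m, rng, active=alive & ~diagnosed)
        u_screen = rng.random(n)
        u_follow = rng.random(n)
        u_colo = rng.random(n)
        u_surv = rng.random(n)
        u_onsched = rng.random(n)
        geom = rng.geometric(1.0 / late_mean)
        u_death = rng.random(n) if opt.mortality else None

        for i in np.flatnonzero(newly):
            rec.diagnosis(i, m, "symptomatic", model.stage_labels[int(state.presented_stage[i])])
        diagnosed |= newly

        if disrupted and scenario.in_window(m):
            # no kits sent or processed; missed screens move to the next round
            pushed = np.flatnonzero((attend == m) & alive & ~diagnosed)
            attend[pushed] = reschedule_missed(scenario, m)
            sched[pushed] += 24
            # all NBCSP-related colonoscopies halted; affected people return
            # to routine screening at the next round
            cancelled = np.flatnonzero((colono_month == m) & alive & ~diagnosed)
            colono_month[cancelled] = NEVER
            colono_surv[cancelled] = False
            ok = (m + 24 - cohort.birth_month[cancelled]) < age_max_m
            attend[cancelled[ok]] = m + 24
            sched[cancelled[ok]] = m + 24
        else:
            due = np.flatnonzero(
                (attend == m)
                & alive
                & ~diagnosed
                & (m - cohort.birth_month < age_max_m)
            )
            if len(due):
                codes = screen_outcome_codes(
                    state.comp[due], model, config, u=u_screen[due]
                )
                rec.screen(
                    due, m, codes, "routine",
                    [model.compartments[c] for c in state.comp[due]],
                )
                last_screen[due] = m
                attend[due] = NEVER
                anchor = sched[due]
                positive = codes != NEGATIVE

                def _next_round(ids, anchors):
                    nxt = anchors + config.interval_months
                    ok = (nxt - cohort.birth_month[ids]) < age_max_m
                    late = _lateness(ids[ok], u_onsched, geom, on_time)
                    sched[ids[ok]] = nxt[ok]
                    attend[ids[ok]] = np.maximum(nxt[ok] + late, m + 1)

                # negatives: next routine round (anchored two years on)
                _next_round(due[~positive], anchor[~positive])
                # positives: ~70% complete a follow-up colonoscopy
                comp_mask = u_follow[due[positive]] < config.followup_completion
                completers = due[positive][comp_mask]
                colono_month[completers] = m + 2
                colono_surv[completers] = False
                _next_round(due[positive][~comp_mask], anchor[positive][~comp_mask])

            colo = np.flatnonzero((colono_month == m) & alive & ~diagnosed)
            if len(colo):
                kind = np.where(colono_surv[colo], "colonoscopy_surveillance", "colonoscopy_followup")
                for i, k in zip(colo, kind):
                    rec.diagnostics.append((int(i), m, k))
                colono_month[colo] = NEVER
                has_crc = np.isin(state.comp[colo], [model.index("crc_early"), model.index("crc_late")])
                for i in colo[has_crc]:
                    rec.diagnosis(i, m, "programme", state.stage_label(i))
                diagnosed[colo[has_crc]] = True
                adeno = (state.comp[colo] == model.index("adenoma")) & (
                    u_colo[colo] < config.precursor_colonoscopy_sensitivity
                ) & ~has_crc
                found = colo[adeno]
                # adenoma removal, then surveillance colonoscopy in 1-5 y
                state.comp[found] = HEALTHY
                state.entry[found, HEALTHY] = m
                pick = (u_surv[found] * len(surv_menu)).astype(int)
                colono_month[found] = m + surv_menu[np.minimum(pick, len(surv_menu) - 1)]
                colono_surv[found] = True
                clear = colo[~adeno & ~has_crc]
                # clear colonoscopy: return to iFOBT screening after 4 y
                late = _lateness(clear, u_onsched, geom, on_time)
                nxt = m + config.return_months
                ok = (nxt - cohort.birth_month[clear]) < age_max_m
                sched[clear[ok]] = nxt
                attend[clear[ok]] = nxt + late[ok]

        if opt.mortality:
            h = _monthly_mortality((m - cohort.birth_month) / 12.0)
            alive &= ~(u_death < h)

    screens, diagnoses, diagnostics = rec.frames()
    return RunResult(
        programme="bowel",
        scenario=scenario,
        seed=seed,
        scale=cohort.spec.scale,
        cohort_n=n,
        screens=screens,
        diagnoses=diagnoses,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# cervix


def run_cervix(
    cohort: Cohort,
    config: ProgrammeConfig,
    nh: NaturalHistoryParams,
    scenario: DisruptionScenario,
    seed: int,
    options: EngineOptions | None = None,
) -> RunResult:
    """Simulate the cervical programme through the HPV transition."""
    opt = options or EngineOptions()
    pc = nh.cervix
    model = cervix_model(pc, vaccinated=False)
    model_vacc = cervix_model(pc, vaccinated=True)
    n = cohort.n
    state = DiseaseArrays(model, n)
    init_rng = substream(seed, "cervix/init")
    initialize_states(
        state,
        opt.sim_start - cohort.birth_month,
        opt.sim_start,
        init_rng,
        disease_start_age=15,
        P_alt=model_vacc.P,
        alt_group=cohort.hpv_vaccinated,
    )
    diagnosed = np.zeros(n, dtype=bool)
    alive = np.ones(n, dtype=bool)
    profile = cohort.adherence or AdherenceProfile()
    on_time = np.full(n, profile.on_time_for(0))
    late_mean = np.maximum(cohort.late_mean, 1.0)

    # anchor: last cytology test (transitioned women: 2 y before first HPV test)
    anchor = np.where(
        cohort.hpv_transitioned, cohort.first_hpv_month - 24, cohort.last_cytology_month
    )
    attend = np.full(n, NEVER, dtype=np.int64)
    part = cohort.participant
    base = np.maximum(anchor, opt.sim_start)
    c0 = opt.sim_start + (base - opt.sim_start) % 24
    attend[part] = c0[part]
    surv_next = np.zeros(n, dtype=bool)  # next visit is surveillance, not routine
    had_hpv_test = np.zeros(n, dtype=bool)
    colpo_month = np.full(n, NEVER, dtype=np.int64)

    disrupted = scenario.duration_months > 0
    rec = _Recorder()
    age_max_m = (config.age_max + 1) * 12
    cancer_comps = [model.index(s) for s in ("localised", "regional", "distant")]

    for m in range(opt.sim_start, opt.sim_end + 1):
        rng = substream(seed, f"cervix/m{m}")
        newly = state.step_month(
            m, rng, active=alive & ~diagnosed,
            P_alt=model_vacc.P, alt_group=cohort.hpv_vaccinated,
        )
        u_screen = rng.random(n)
        u_att = rng.random(n)
        u_follow = rng.random(n)
        u_treat = rng.random(n)
        u_resched = rng.random(n)
        u_onsched = rng.random(n)
        geom = rng.geometric(1.0 / late_mean)

        for i in np.flatnonzero(newly):
            rec.diagnosis(i, m, "symptomatic", model.stage_labels[int(state.presented_stage[i])])
        diagnosed |= newly

        hpv_era = m >= RENEWAL_START
        # a woman's first HPV test is her first attendance after her last
        # cytology test (the renewal rule: first HPV test due 2 y after it);
        # earlier attendances are pre-renewal cytology
        is_hpv = had_hpv_test | (hpv_era & (m > anchor))
        min_age = np.where(is_hpv, 25, 20) * 12
        due = (attend == m) & alive & ~diagnosed
        too_young = due & (m - cohort.birth_month < min_age)
        attend[too_young] = m + 12
        due &= ~too_young
        due &= m - cohort.birth_month < age_max_m

        # disruption suppresses routine attendance only
        routine_due = due & ~surv_next
        if disrupted and scenario.in_window(m):
            degree = 1.0 - attendance_modifier(scenario, m, "routine")
            missed = routine_due & (u_att < degree)
            for i in np.flatnonzero(missed):
                attend[i] = reschedule_missed(
                    scenario, m, np.random.default_rng(int(u_resched[i] * 2**31))
                )
            due &= ~missed

        attendees = np.flatnonzero(due)
        if len(attendees):
            is_surv = surv_next[attendees]
            hpv_now = is_hpv[attendees]
            # cytology is less sensitive than the primary HPV test
            codes = np.empty(len(attendees), dtype=np.int8)
            for grp, factor in ((hpv_now, 1.0), (~hpv_now, 0.8)):
                if grp.any():
                    codes[grp] = screen_outcome_codes(
                        state.comp[attendees[grp]], model, config,
                        u=u_screen[attendees[grp]], sensitivity_factor=factor,
                    )
            streams = np.where(is_surv, "surveillance", "routine")
            for i, c, s in zip(attendees, codes, streams):
                rec.screens.append(
                    (int(i), m, OUTCOME_NAMES[int(c)], s,
                     model.compartments[int(state.comp[i])])
                )
            had_hpv_test[attendees[hpv_now]] = True
            surv_next[attendees] = False
            attend[attendees] = NEVER
            # 5-yearly once on the HPV pathway, 2-yearly cytology before it
            interval = np.where(hpv_now, config.interval_months, 24)
            negative = codes == NEGATIVE
            neg_ids = attendees[negative]
            late = _lateness(neg_ids, u_onsched, geom, on_time)
            attend[neg_ids] = m + interval[negative] + late
            # positives referred to colposcopy (collapsed triage pathway)
            positive = attendees[~negative]
            ref_mask = u_follow[positive] < config.followup_completion
            colpo_month[positive[ref_mask]] = m + 1
            attend[positive[~ref_mask]] = m + interval[~negative][~ref_mask]

        colpo = np.flatnonzero((colpo_month == m) & alive & ~diagnosed)
        if len(colpo):
            rec.procedure(colpo, m, "colposcopy")
            colpo_month[colpo] = NEVER
            has_cancer = np.isin(state.comp[colpo], cancer_comps)
            for i in colpo[has_cancer]:
                rec.diagnosis(i, m, "programme", state.stage_label(i))
            diagnosed[colpo[has_cancer]] = True
            cin = (state.comp[colpo] == model.index("cin")) & ~has_cancer
            treated = colpo[cin & (u_treat[colpo] < config.precursor_colonoscopy_sensitivity)]
            # CIN treated and cleared; test-of-cure surveillance in 12 months
            state.comp[treated] = HEALTHY
            state.entry[treated, HEALTHY] = m
            hpv_only = colpo[(state.comp[colpo] == model.index("hpv")) & ~has_cancer]
            watch = np.concatenate([treated, hpv_only])
            attend[watch] = m + 12
            surv_next[watch] = True
            rest = np.setdiff1d(colpo[~has_cancer], watch)
            # benign colposcopy: back to the routine interval of the woman's
            # current pathway (biennial cytology until her first HPV test)
            attend[rest] = m + np.where(had_hpv_test[rest], config.interval_months, 24)
            surv_next[rest] = False

    screens, diagnoses, diagnostics = rec.frames()
    return RunResult(
        programme="cervix",
        scenario=scenario,
        seed=seed,
        scale=cohort.spec.scale,
        cohort_n=n,
        screens=screens,
        diagnoses=diagnoses,
        diagnostics=diagnostics,
    )


# ---------------------------------------------------------------------------
# standard cohorts and paired runs

#: national cohort sizes the synthetic populations emulate.  The bowel
#: cohort covers everyone age-eligible in 2020 or 2021 (born 1945-1971,
#: so 48-74 at the January 2020 reference): people ageing into
#: eligibility balance those ageing out, keeping kit volumes level.
NATIONAL = {
    "breast": dict(size=3_600_000, sex_split_male=0.0, age_min=50, age_max=74),
    "bowel": dict(size=7_100_000, sex_split_male=3.5 / 7.1, age_min=48, age_max=74),
    "cervix": dict(size=8_000_000, sex_split_male=0.0, age_min=25, age_max=74),
}

RUNNERS = {"breast": run_breast, "bowel": run_bowel, "cervix": run_cervix}

SCENARIO_FACTORIES = {
    "breast": breast_scenario,
    "bowel": bowel_scenario,
    "cervix": cervix_scenario,
}


def standard_cohort_spec(programme: str, scale: float = 0.01) -> CohortSpec:
    nat = NATIONAL[programme]
    return CohortSpec(
        programme=programme,
        size=max(1, int(round(nat["size"] * scale))),
        age_min=nat["age_min"],
        age_max=nat["age_max"],
        sex_split_male=nat["sex_split_male"],
        scale=scale,
    )


def build_standard_cohort(
    programme: str,
    seed: int,
    scale: float = 0.01,
    config: ProgrammeConfig | None = None,
) -> Cohort:
    """Cohort with the participation/behaviour structure of the programme."""
    cfg = config or DEFAULT_CONFIGS[programme]()
    cohort = generate_cohort(standard_cohort_spec(programme, scale), seed)
    assign_screening_behaviour(cohort, cfg.participation, AdherenceProfile(), seed)
    if programme == "cervix":
        assign_hpv_history(cohort, 0.536, 0.80, seed)
    return cohort


def run_pair(
    programme: str,
    scenario: DisruptionScenario,
    seed: int,
    scale: float = 0.01,
    config: ProgrammeConfig | None = None,
    nh: NaturalHistoryParams | None = None,
    options: EngineOptions | None = None,
) -> tuple[RunResult, RunResult]:
    """Run status quo and a scenario on the same cohort and seed.

    Returns ``(status_quo, scenario)`` results; paired differences are
    low-variance because all random streams are shared.
    """
    cfg = config or DEFAULT_CONFIGS[programme]()
    nh = nh or NaturalHistoryParams()
    cohort = build_standard_cohort(programme, seed, scale, cfg)
    null = SCENARIO_FACTORIES[programme](0)
    runner = RUNNERS[programme]
    if programme == "breast":
        sq = run_breast(cohort, cfg, nh, null, seed, options)
        sc = run_breast(
            cohort, cfg, nh, scenario, seed, options,
            base_capacity=sq.base_monthly_capacity,
        )
    else:
        sq = runner(cohort, cfg, nh, null, seed, options)
        sc = runner(cohort, cfg, nh, scenario, seed, options)
    return sq, sc
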