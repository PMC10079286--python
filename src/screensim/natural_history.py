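"""Simplified stochastic natural histories for breast, colorectal, and
cervical cancer.

Each cancer is a continuous-time Markov chain over a small set of
compartments (healthy, precursor, preclinical cancer stages, clinical
presentation), advanced on a monthly grid by sampling from the *exact*
one-month transition matrix ``expm(Q)``.  Compartment occupancy therefore
matches the matrix-exponential solution of the chain up to Monte Carlo
error, with no time-discretisation bias.  Dwell times are exponential
(memoryless); free parameters are set by :mod:`screensim.calibration`
against status quo programme outcomes, since absolute incidence levels
are not derivable from first principles here.

Stage conventions
-----------------
breast
    tumour size class (``<=15mm`` / ``>15mm``) carried by the chain;
    nodal involvement accrues by hazard once the tumour is large; grade
    (1-2 vs 3) is fixed at onset.  Clinical presentation hazard depends
    on size.
bowel
    adenoma -> CRC stage 1-2 -> CRC stage 3-4; presentation hazard rises
    with stage.
cervix
    HPV infection -> CIN -> invasive cancer localised -> regional ->
    distant.  HPV may clear and CIN may regress (the only permitted
    regressions); invasive stages only progress.  HPV vaccination
    multiplies the acquisition hazard.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
from scipy.linalg import expm

from .population import NEVER


class ParameterError(ValueError):
    """Raised for invalid natural-history parameters."""


# ---------------------------------------------------------------------------
# parameter containers


def _check_nonneg(**kwargs: float) -> None:
    for name, value in kwargs.items():
        if value < 0:
            raise ParameterError(f"hazard {name!r} must be >= 0, got {value}")


@dataclass(frozen=True)
class BreastParams:
    """Monthly hazards of the breast model (all per person-month)."""

    onset: float = 2.505e-4
    small_to_large: float = 1 / 19.9
    symptomatic_small: float = 1 / 84.2
    symptomatic_large: float = 1 / 30.5
    nodal_rate: float = 0.1072
    grade3_frac: float = 0.466

    def __post_init__(self) -> None:
        _check_nonneg(
            onset=self.onset,
            small_to_large=self.small_to_large,
            symptomatic_small=self.symptomatic_small,
            symptomatic_large=self.symptomatic_large,
            nodal_rate=self.nodal_rate,
        )
        if not 0.0 <= self.grade3_frac <= 1.0:
            raise ParameterError("grade3_frac must lie in [0, 1]")


@dataclass(frozen=True)
class BowelParams:
    """Monthly hazards of the colorectal model."""

    adenoma_onset: float = 1.583e-4
    adenoma_to_crc: float = 1 / 150.0
    early_to_late: float = 1 / 44.0
    symptomatic_early: float = 1 / 30.0
    symptomatic_late: float = 1 / 9.2

    def __post_init__(self) -> None:
        _check_nonneg(**self.__dict__)


@dataclass(frozen=True)
class CervixParams:
    """Monthly hazards of the HPV/cervical model."""

    hpv_onset: float = 3.5e-3
    hpv_clearance: float = 1 / 18.0
    hpv_to_cin: float = 1 / 60.0
    cin_regression: float = 1 / 48.0
    cin_to_cancer: float = 1 / 3500.0
    loc_to_reg: float = 1 / 30.0
    reg_to_dist: float = 1 / 30.0
    symptomatic_loc: float = 1 / 36.0
    symptomatic_reg: float = 1 / 12.0
    symptomatic_dist: float = 1 / 4.0
    vaccination_multiplier: float = 0.1

    def __post_init__(self) -> None:
        d = {k: v for k, v in self.__dict__.items() if k != "vaccination_multiplier"}
        _check_nonneg(**d)
        if not 0.0 <= self.vaccination_multiplier <= 1.0:
            raise ParameterError("vaccination multiplier must lie in [0, 1]")


@dataclass(frozen=True)
class NaturalHistoryParams:
    """Per-cancer parameter bundle used by the engine and calibration."""

    breast: BreastParams = field(default_factory=BreastParams)
    bowel: BowelParams = field(default_factory=BowelParams)
    cervix: CervixParams = field(default_factory=CervixParams)


# ---------------------------------------------------------------------------
# chain definitions

HEALTHY = 0
CLINICAL_LABEL = "clinical"


def _rate_matrix(n: int, edges: dict[tuple[int, int], float]) -> np.ndarray:
    Q = np.zeros((n, n))
    for (i, j), rate in edges.items():
        if rate < 0:
            raise ParameterError("negative transition rate")
        Q[i, j] = rate
    np.fill_diagonal(Q, -Q.sum(axis=1))
    return Q


def monthly_transition_matrix(Q: np.ndarray) -> np.ndarray:
    """Exact one-month transition probabilities for rate matrix ``Q``."""
    P = expm(Q)
    P = np.clip(P, 0.0, None)
    return P / P.sum(axis=1, keepdims=True)


def markov_step(
    comp: np.ndarray,
    P: np.ndarray,
    rng: np.random.Generator | None = None,
    u: np.ndarray | None = None,
) -> np.ndarray:
    """Advance compartment indices one month under transition matrix ``P``.

    Accepts pre-drawn uniforms ``u`` so callers can keep random-number
    consumption fixed-size per month (common-random-number pairing).
    """
    cum = np.cumsum(P, axis=1)
    if u is None:
        u = rng.random(len(comp))
    return (u[:, None] > cum[comp]).sum(axis=1).astype(comp.dtype)


class DiseaseModel:
    """A compartment chain plus stage semantics for one cancer type."""

    def __init__(
        self,
        cancer: str,
        compartments: Sequence[str],
        edges: dict[tuple[int, int], float],
        detectable: Sequence[int],
        cancer_comps: Sequence[int],
        stage_labels: dict[int, str],
    ):
        self.cancer = cancer
        self.compartments = list(compartments)
        self.clinical = self.compartments.index(CLINICAL_LABEL)
        self.Q = _rate_matrix(len(compartments), edges)
        self.P = monthly_transition_matrix(self.Q)
        self.detectable = np.array(detectable)
        self.cancer_comps = frozenset(cancer_comps)
        self.stage_labels = dict(stage_labels)

    def index(self, name: str) -> int:
        return self.compartments.index(name)


def breast_model(p: BreastParams) -> DiseaseModel:
    comps = ["healthy", "preclinical_small", "preclinical_large", CLINICAL_LABEL]
    edges = {
        (0, 1): p.onset,
        (1, 2): p.small_to_large,
        (1, 3): p.symptomatic_small,
        (2, 3): p.symptomatic_large,
    }
    return DiseaseModel(
        "breast",
        comps,
        edges,
        detectable=[1, 2],
        cancer_comps=[1, 2],
        stage_labels={1: "<=15mm", 2: ">15mm"},
    )


def bowel_model(p: BowelParams) -> DiseaseModel:
    comps = ["healthy", "adenoma", "crc_early", "crc_late", CLINICAL_LABEL]
    edges = {
        (0, 1): p.adenoma_onset,
        (1, 2): p.adenoma_to_crc,
        (2, 3): p.early_to_late,
        (2, 4): p.symptomatic_early,
        (3, 4): p.symptomatic_late,
    }
    return DiseaseModel(
        "bowel",
        comps,
        edges,
        detectable=[1, 2, 3],
        cancer_comps=[2, 3],
        stage_labels={1: "adenoma", 2: "1-2", 3: "3-4"},
    )


def cervix_model(p: CervixParams, vaccinated: bool = False) -> DiseaseModel:
    comps = ["healthy", "hpv", "cin", "localised", "regional", "distant", CLINICAL_LABEL]
    onset = p.hpv_onset * (p.vaccination_multiplier if vaccinated else 1.0)
    edges = {
        (0, 1): onset,
        (1, 0): p.hpv_clearance,
        (1, 2): p.hpv_to_cin,
        (2, 0): p.cin_regression,
        (2, 3): p.cin_to_cancer,
        (3, 4): p.loc_to_reg,
        (3, 6): p.symptomatic_loc,
        (4, 5): p.reg_to_dist,
        (4, 6): p.symptomatic_reg,
        (5, 6): p.symptomatic_dist,
    }
    return DiseaseModel(
        "cervix",
        comps,
        edges,
        detectable=[1, 2, 3, 4, 5],
        cancer_comps=[3, 4, 5],
        stage_labels={1: "hpv", 2: "cin", 3: "localised", 4: "regional", 5: "distant"},
    )


def apply_vaccination_effect(params: CervixParams, vaccinated: bool) -> float:
    """Effective HPV-acquisition hazard for one individual.

    Vaccinated women acquire HPV at ``hpv_onset * vaccination_multiplier``.
    """
    if not 0.0 <= params.vaccination_multiplier <= 1.0:
        raise ParameterError("vaccination multiplier must lie in [0, 1]")
    return params.hpv_onset * (params.vaccination_multiplier if vaccinated else 1.0)


# ---------------------------------------------------------------------------
# cohort-level disease state


class DiseaseArrays:
    """Columnar disease state for a cohort under one cancer model.

    ``comp`` is the current compartment; ``entry[:, c]`` the month each
    person most recently entered compartment ``c`` (``NEVER`` if never).
    ``presented_stage`` records the cancer compartment occupied when a
    person jumped to clinical presentation.
    """

    def __init__(self, model: DiseaseModel, n: int):
        self.model = model
        k = len(model.compartments)
        self.comp = np.zeros(n, dtype=np.int8)
        self.entry = np.full((n, k), NEVER, dtype=np.int32)
        self.entry[:, HEALTHY] = -(10**5)
        self.presented_stage = np.full(n, -1, dtype=np.int8)
        self.presented_month = np.full(n, NEVER, dtype=np.int32)
        # breast marks
        self.nodal = np.zeros(n, dtype=bool)
        self.nodal_month = np.full(n, NEVER, dtype=np.int32)
        self.grade3 = np.zeros(n, dtype=bool)

    def step_month(
        self,
        month: int,
        rng: np.random.Generator,
        active: np.ndarray,
        P: np.ndarray | None = None,
        P_alt: np.ndarray | None = None,
        alt_group: np.ndarray | None = None,
        breast_params: BreastParams | None = None,
    ) -> np.ndarray:
        """Advance ``active`` individuals by one month ending at ``month``.

        Returns a boolean mask of individuals newly presenting clinically
        this month.  ``P_alt``/``alt_group`` let a subgroup (e.g. HPV-
        vaccinated women) evolve under a different transition matrix.
        For the breast model, also accrues nodal involvement and assigns
        grade at onset.

        Random-number consumption is fixed (full cohort length each
        draw) regardless of state, so paired scenario/status quo runs
        sharing a seed see identical disease randomness.
        """
        model = self.model
        P = model.P if P is None else P
        n = len(self.comp)
        u = rng.random(n)
        u_grade = rng.random(n) if breast_params is not None else None
        u_nodal = rng.random(n) if breast_params is not None else None
        idx = np.flatnonzero(active & (self.comp != model.clinical))
        newly_clinical = np.zeros(n, dtype=bool)
        if len(idx) == 0:
            return newly_clinical
        old = self.comp[idx]
        new = markov_step(old, P, u=u[idx])
        if alt_group is not None and P_alt is not None:
            alt = alt_group[idx]
            if alt.any():
                new[alt] = markov_step(old[alt], P_alt, u=u[idx][alt])
        moved = new != old
        midx = idx[moved]
        self.comp[midx] = new[moved]
        self.entry[midx, new[moved]] = month
        clin = midx[new[moved] == model.clinical]
        # multi-jump months can skip from a pre-cancer compartment straight to
        # clinical; the presented stage is then the earliest cancer stage
        min_cancer = min(model.cancer_comps)
        self.presented_stage[clin] = np.maximum(
            old[moved][new[moved] == model.clinical], min_cancer
        )
        self.presented_month[clin] = month
        newly_clinical[clin] = True
        if breast_params is not None:
            onset = midx[(old[moved] == HEALTHY) & (new[moved] != HEALTHY)]
            self.grade3[onset] = u_grade[onset] < breast_params.grade3_frac
            large = np.flatnonzero(active & (self.comp == 2) & ~self.nodal)
            p_nodal = 1.0 - np.exp(-breast_params.nodal_rate)
            hit = large[u_nodal[large] < p_nodal]
            self.nodal[hit] = True
            self.nodal_month[hit] = month
        return newly_clinical

    def compartment_at(self, i: int, month: int) -> int:
        entries = self.entry[i]
        valid = np.flatnonzero(entries != NEVER)
        valid = valid[entries[valid] <= month]
        if len(valid) == 0:
            return HEALTHY
        # latest entry wins; ties broken towards the later compartment
        latest = entries[valid].max()
        return int(valid[entries[valid] == latest].max())

    def stage_label(self, i: int, comp: int | None = None) -> str:
        """Stage label for person ``i`` in ``comp`` (default: current)."""
        c = self.comp[i] if comp is None else comp
        if c not in self.model.stage_labels:
            raise ParameterError(
                f"compartment {self.model.compartments[int(c)]!r} has no stage label"
            )
        return self.model.stage_labels[int(c)]


def stage_at_event(state: DiseaseArrays, i: int, event_month: int) -> str:
    """Stage occupied by person ``i`` at ``event_month``.

    Raises if the person was not in a cancer compartment then.
    """
    comp = state.compartment_at(i, event_month)
    if comp not in state.model.cancer_comps:
        raise ParameterError(
            f"person {i} not in a cancer compartment at month {event_month}"
        )
    return state.stage_label(i, comp)


def initialize_states(
    state: DiseaseArrays,
    age_months: np.ndarray,
    start_month: int,
    rng: np.random.Generator,
    disease_start_age: int = 20,
    P_alt: np.ndarray | None = None,
    alt_group: np.ndarray | None = None,
    breast_params: BreastParams | None = None,
) -> None:
    """Seed compartments from the chain's own occupancy at each age.

    For a person aged ``a`` at the simulation start, the compartment is
    drawn from ``expm(Q * t)`` applied to the healthy state, with
    ``t = a - disease_start_age`` years of exposure, conditioned on not
    having presented clinically yet (previously diagnosed people are not
    part of a screening-naive at-risk cohort).  This avoids decades of
    burn-in for slow precursors while matching the model's own
    age-prevalence profile.
    """
    model = state.model
    n = len(age_months)
    years = np.clip(age_months // 12 - disease_start_age, 0, None).astype(int)
    comp = np.zeros(n, dtype=np.int8)
    u = rng.random(n)
    u_alt = rng.random(n)
    for grp, P in (("base", model.P), ("alt", P_alt)):
        if P is None:
            continue
        mask = np.ones(n, dtype=bool) if alt_group is None else (
            ~alt_group if grp == "base" else alt_group
        )
        if not mask.any():
            continue
        for t in np.unique(years[mask]):
            occ = np.linalg.matrix_power(P, int(t) * 12)[HEALTHY].copy()
            occ[model.clinical] = 0.0  # condition on no prior clinical diagnosis
            occ /= occ.sum()
            sel = mask & (years == t)
            uu = u if grp == "base" else u_alt
            comp[sel] = np.searchsorted(np.cumsum(occ), uu[sel], side="right")
    state.comp = comp
    state.entry[np.arange(n), comp] = start_month
    if breast_params is not None:
        # marks for pre-existing preclinical disease
        state.grade3 = rng.random(n) < breast_params.grade3_frac
        large = comp == 2
        # nodal status of prevalent large tumours: equilibrium guess of ~half
        dwell = 1.0 / max(breast_params.symptomatic_large, 1e-9)
        p_nodal = 1.0 - np.exp(-breast_params.nodal_rate * dwell / 2)
        state.nodal = large & (rng.random(n) < p_nodal)


def advance_state(
    state: DiseaseArrays,
    i: int,
    from_month: int,
    to_month: int,
    rng: np.random.Generator,
    breast_params: BreastParams | None = None,
) -> list[tuple[int, str]]:
    """Advance one individual month-by-month, returning dated events.

    Events are ``(month, description)`` pairs for compartment entries
    and clinical presentation.  Thin per-individual wrapper over the
    vectorised :meth:`DiseaseArrays.step_month`.
    """
    if to_month <= from_month:
        raise ParameterError("to_month must exceed from_month")
    events: list[tuple[int, str]] = []
    active = np.zeros(len(state.comp), dtype=bool)
    active[i] = True
    for month in range(from_month + 1, to_month + 1):
        before = state.comp[i]
        newly = state.step_month(month, rng, active, breast_params=breast_params)
        after = state.comp[i]
        if after != before:
            events.append((month, f"enter:{state.model.compartments[int(after)]}"))
        if newly[i]:
            events.append((month, "symptomatic_presentation"))
    return events
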