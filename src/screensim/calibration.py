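"""Fitting the simplified natural histories to status quo programme
outcomes.

The stand-in disease models have no literature-derived rates; their
free parameters are chosen so that a status quo run reproduces the
status quo column of the reported outcome tables (diagnosis rates,
screen-detected fractions, interval cancer rates, recall rates, stage
distributions).  Scenario columns are never fitted — they are
predictions.

The objective is a weighted sum of squared relative errors over the
targets, evaluated on common-random-number runs (fixed seed inside the
simulator) so the search sees a deterministic surface.  The optimiser
is a multiplicative coordinate search (robust, derivative-free, and
insensitive to parameter scale) with an optional Nelder-Mead polish.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Callable, Mapping, Sequence

import numpy as np
import yaml

from .natural_history import BreastParams, NaturalHistoryParams
from .population import InvalidSpecError


@dataclass(frozen=True)
class CalibrationTarget:
    """One status quo metric the model should reproduce."""

    metric: str
    value: float
    weight: float = 1.0
    tolerance: float = 0.1  # relative, used for reporting convergence

    def __post_init__(self) -> None:
        if self.weight < 0:
            raise InvalidSpecError("target weight must be >= 0")
        if self.tolerance <= 0:
            raise InvalidSpecError("target tolerance must be > 0")


def discrepancy(
    simulated: Mapping[str, float], targets: Sequence[CalibrationTarget]
) -> float:
    """Weighted sum of squared relative errors; zero iff all targets hit."""
    total = 0.0
    for t in targets:
        if t.metric not in simulated:
            raise InvalidSpecError(f"simulated metrics missing target {t.metric!r}")
        err = (float(simulated[t.metric]) - t.value) / t.value
        total += t.weight * err * err
    return total


def calibrate(
    simulator: Callable[[Mapping[str, float]], Mapping[str, float]],
    initial: Mapping[str, float],
    targets: Sequence[CalibrationTarget],
    budget: int,
    seed: int = 0,
    step: float = 0.2,
    free: Sequence[str] | None = None,
) -> tuple[dict[str, float], float]:
    """Derivative-free search minimising :func:`discrepancy`.

    ``simulator`` maps a parameter dict to a metric dict (it must fix
    its own random seed so the objective is deterministic).  ``budget``
    counts simulator evaluations; 0 returns the initial parameters
    unchanged.  Returns ``(fitted_params, achieved_discrepancy)`` with
    discrepancy never above the initial value.
    """
    if budget < 0:
        raise InvalidSpecError("budget must be >= 0")
    params = dict(initial)
    names = list(free) if free is not None else list(params)
    best = discrepancy(simulator(params), targets)
    if not np.isfinite(best):
        raise InvalidSpecError(f"non-finite objective at initial parameters {params}")
    evals = 1
    rng = np.random.default_rng(seed & 0x7FFFFFFF)
    cur_step = step
    while evals < budget:
        improved = False
        for name in names:
            if evals >= budget:
                break
            for factor in (1.0 + cur_step, 1.0 / (1.0 + cur_step)):
                if evals >= budget:
                    break
                trial = dict(params)
                trial[name] = params[name] * factor
                val = discrepancy(simulator(trial), targets)
                evals += 1
                if np.isfinite(val) and val < best:
                    best, params = val, trial
                    improved = True
                    break
        if not improved:
            cur_step /= 2.0
            if cur_step < 0.01:
                # random restart direction jitter within remaining budget
                if evals >= budget:
                    break
                jitter = {
                    k: v * float(np.exp(rng.normal(0, 0.05))) for k, v in params.items()
                }
                val = discrepancy(simulator(jitter), targets)
                evals += 1
                if np.isfinite(val) and val < best:
                    best, params = val, jitter
                cur_step = step / 2.0
    return params, best


# ---------------------------------------------------------------------------
# breast status quo calibration (used by the scenario evaluations)

#: status quo targets for the breast programme (per 100,000 women rates
#: annualised over 2020-2021, percentages as printed)
BREAST_SQ_TARGETS = (
    CalibrationTarget("diagnoses_per_100k", 298.0, weight=3.0),
    CalibrationTarget("screen_detected_per_100k", 127.0, weight=3.0),
    CalibrationTarget("interval_12_per_100k", 15.0),
    CalibrationTarget("interval_27_per_100k", 38.0),
    CalibrationTarget("programme_sensitivity_pct", 77.0, weight=2.0),
    CalibrationTarget("pct_small", 59.7),
    CalibrationTarget("pct_nodal", 24.9),
    CalibrationTarget("recall_rate_pct", 5.2),
    CalibrationTarget("fp_recall_rate_pct", 4.6),
)

#: parameters the breast calibration may move (monthly hazards / probabilities)
BREAST_FREE_PARAMS = (
    "onset",
    "small_to_large",
    "symptomatic_small",
    "symptomatic_large",
    "nodal_rate",
    "sens_small",
    "sens_large",
)


def breast_params_from_dict(d: Mapping[str, float]) -> tuple[BreastParams, dict]:
    """Split a flat parameter dict into BreastParams and config overrides."""
    bp = BreastParams(
        onset=d["onset"],
        small_to_large=d["small_to_large"],
        symptomatic_small=d["symptomatic_small"],
        symptomatic_large=d["symptomatic_large"],
        nodal_rate=d["nodal_rate"],
        grade3_frac=d.get("grade3_frac", 0.466),
    )
    cfg = {
        "sensitivity": {
            "preclinical_small": min(d["sens_small"], 1.0),
            "preclinical_large": min(d["sens_large"], 1.0),
        }
    }
    if "specificity" in d:
        cfg["specificity"] = min(d["specificity"], 1.0)
    return bp, cfg


def breast_initial_params(nh: NaturalHistoryParams | None = None) -> dict[str, float]:
    bp = (nh or NaturalHistoryParams()).breast
    from .programmes import breast_config

    cfg = breast_config()
    return {
        "onset": bp.onset,
        "small_to_large": bp.small_to_large,
        "symptomatic_small": bp.symptomatic_small,
        "symptomatic_large": bp.symptomatic_large,
        "nodal_rate": bp.nodal_rate,
        "sens_small": cfg.sensitivity["preclinical_small"],
        "sens_large": cfg.sensitivity["preclinical_large"],
    }


def breast_simulator(scale: float = 0.01, seed: int = 12345) -> Callable:
    """Simulator closure: breast status quo metrics for a parameter dict."""

    def simulate(d: Mapping[str, float]) -> Mapping[str, float]:
        from .engine import build_standard_cohort, run_breast
        from .outcomes import breast_summary
        from .programmes import breast_config
        from .scenario import breast_scenario

        bp, cfg_over = breast_params_from_dict(d)
        cfg = breast_config(**cfg_over)
        nh = NaturalHistoryParams(breast=bp)
        cohort = build_standard_cohort("breast", seed, scale, cfg)
        res = run_breast(cohort, cfg, nh, breast_scenario(0), seed)
        return breast_summary(res)

    return simulate


def calibrate_breast(
    budget: int = 0,
    seed: int = 12345,
    scale: float = 0.01,
    targets: Sequence[CalibrationTarget] = BREAST_SQ_TARGETS,
    initial: Mapping[str, float] | None = None,
) -> tuple[NaturalHistoryParams, dict, float]:
    """Fit the breast model to the status quo column.

    Returns ``(natural_history_params, config_overrides, discrepancy)``.
    The shipped defaults are already fitted, so small budgets act as a
    verification/polish pass.
    """
    init = dict(initial or breast_initial_params())
    sim = breast_simulator(scale, seed)
    if budget == 0:
        return (*_pack(init), discrepancy(sim(init), targets))
    fitted, val = calibrate(sim, init, targets, budget, seed, free=BREAST_FREE_PARAMS)
    return (*_pack(fitted), val)


def _pack(d: Mapping[str, float]) -> tuple[NaturalHistoryParams, dict]:
    bp, cfg_over = breast_params_from_dict(d)
    return NaturalHistoryParams(breast=bp), cfg_over


# ---------------------------------------------------------------------------
# bowel and cervical status quo calibration

#: status quo targets for the bowel programme at 1:100 scale (kits counted
#: over Apr 2020-Mar 2021, the other quantities over 2020-2021)
BOWEL_SQ_TARGETS = (
    CalibrationTarget("kits_apr20_mar21", 13539.0, weight=2.0),
    CalibrationTarget("crc_diagnoses", 210.7, weight=3.0),
    CalibrationTarget("pct_stage_34", 33.9, weight=2.0),
    CalibrationTarget("nbcsp_colonoscopies", 1949.5),
)

BOWEL_FREE_PARAMS = (
    "adenoma_onset",
    "adenoma_to_crc",
    "early_to_late",
    "symptomatic_early",
    "symptomatic_late",
    "sens_adenoma",
    "sens_early",
    "sens_late",
    "specificity",
)


def bowel_params_from_dict(d: Mapping[str, float]) -> tuple["BowelParams", dict]:
    from .natural_history import BowelParams

    bp = BowelParams(
        adenoma_onset=d["adenoma_onset"],
        adenoma_to_crc=d["adenoma_to_crc"],
        early_to_late=d["early_to_late"],
        symptomatic_early=d["symptomatic_early"],
        symptomatic_late=d["symptomatic_late"],
    )
    cfg = {
        "sensitivity": {
            "adenoma": min(d["sens_adenoma"], 1.0),
            "crc_early": min(d["sens_early"], 1.0),
            "crc_late": min(d["sens_late"], 1.0),
        },
        "specificity": min(d["specificity"], 1.0),
    }
    return bp, cfg


def bowel_initial_params() -> dict[str, float]:
    from .natural_history import BowelParams
    from .programmes import bowel_config

    bp = BowelParams()
    cfg = bowel_config()
    return {
        "adenoma_onset": bp.adenoma_onset,
        "adenoma_to_crc": bp.adenoma_to_crc,
        "early_to_late": bp.early_to_late,
        "symptomatic_early": bp.symptomatic_early,
        "symptomatic_late": bp.symptomatic_late,
        "sens_adenoma": cfg.sensitivity["adenoma"],
        "sens_early": cfg.sensitivity["crc_early"],
        "sens_late": cfg.sensitivity["crc_late"],
        "specificity": cfg.specificity,
    }


def bowel_simulator(scale: float = 0.01, seed: int = 12345) -> Callable:
    def simulate(d: Mapping[str, float]) -> Mapping[str, float]:
        from .engine import build_standard_cohort, run_bowel
        from .outcomes import bowel_summary
        from .programmes import bowel_config
        from .scenario import bowel_scenario

        bp, cfg_over = bowel_params_from_dict(d)
        cfg = bowel_config(**cfg_over)
        nh = NaturalHistoryParams(bowel=bp)
        cohort = build_standard_cohort("bowel", seed, scale, cfg)
        res = run_bowel(cohort, cfg, nh, bowel_scenario(0), seed)
        return bowel_summary(res)

    return simulate


#: cervical status quo targets at 1:100 scale (2020-2022 window counts)
CERVIX_SQ_TARGETS = (
    CalibrationTarget("cervical_diagnoses", 18.78, weight=3.0, tolerance=0.3),
    CalibrationTarget("colposcopies", 2456.2),
)

CERVIX_FREE_PARAMS = (
    "hpv_onset",
    "hpv_to_cin",
    "cin_to_cancer",
    "symptomatic_loc",
    "followup_completion",
)


def cervix_simulator(scale: float = 0.01, seed: int = 12345) -> Callable:
    def simulate(d: Mapping[str, float]) -> Mapping[str, float]:
        from .engine import build_standard_cohort, run_cervix
        from .natural_history import CervixParams
        from .outcomes import cervix_summary
        from .programmes import cervix_config
        from .scenario import cervix_scenario

        base = CervixParams()
        cp = replace(
            base,
            hpv_onset=d.get("hpv_onset", base.hpv_onset),
            hpv_to_cin=d.get("hpv_to_cin", base.hpv_to_cin),
            cin_to_cancer=d.get("cin_to_cancer", base.cin_to_cancer),
            symptomatic_loc=d.get("symptomatic_loc", base.symptomatic_loc),
        )
        cfg = cervix_config(
            followup_completion=min(d.get("followup_completion", 0.85), 1.0)
        )
        nh = NaturalHistoryParams(cervix=cp)
        cohort = build_standard_cohort("cervix", seed, scale, cfg)
        res = run_cervix(cohort, cfg, nh, cervix_scenario(0), seed)
        return cervix_summary(res)

    return simulate


def save_params(path, params: Mapping[str, float], *, seed: int, targets, achieved: float) -> None:
    """Serialise a fitted parameter set with provenance."""
    doc = {
        "params": {k: float(v) for k, v in params.items()},
        "provenance": {
            "seed": int(seed),
            "targets": [
                {"metric": t.metric, "value": t.value, "weight": t.weight}
                for t in targets
            ],
            "discrepancy": float(achieved),
        },
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_params(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)
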