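# Methods

`screensim` is a monthly-step microsimulator of Australia's three
national cancer screening programmes (BreastScreen, the National Bowel
Cancer Screening Program, and the renewed National Cervical Screening
Program) built to evaluate what a COVID-19-style disruption — a
complete pause of throughput, or a reduction in attendance — does to
screens delivered, cancer diagnoses, tumour stage at diagnosis, and
downstream diagnostic demand. Every scenario is evaluated against a
*status quo* run of the same cohort under the same random numbers, so
reported effects are paired differences.

## Cohorts

Cohorts are synthetic and closed (no migration; background mortality is
off within the three-year reporting horizon and can be switched on for
the long-horizon bowel run). Sizes emulate the national
screening-eligible populations at 1:100 "desk scale" by default; all
rates are scale-invariant and counts are rescaled on report.

* breast: 3.6 M women aged 50–74 at January 2020;
* bowel: 7.1 M persons (3.5 M men / 3.6 M women) covering everyone
  age-eligible during 2020–2021, i.e. ages 48–74 at January 2020, so
  people ageing into eligibility balance those ageing out and monthly
  kit volumes stay level;
* cervix: 8.0 M women aged 25–74 at January 2020.

Ages are uniform within the range (no published pyramid for the
screening-eligible subpopulations; an optional table-driven pyramid is
accepted). Ever-screener status is a Bernoulli draw at the programme
participation rate (55% breast, 43.5% bowel, 46% cervix). Screeners
carry an attendance-delay profile: they attend on schedule with
probability 0.72 by default (configurable per round within the observed
0.60–0.84 range) and otherwise delay by 1 + Geometric months with mean
6, capped at 11 months — beyond half a round a register re-anchors a
person to their next round rather than issuing two invitations in quick
succession.

For the cervical programme, 53.6% of screeners have already attended
their first 5-yearly primary HPV test (drawn over December 2017 –
February 2020) and are not due again before December 2022; the rest are
due two years after their last cytology test (uniform over 2018–2019).
Women born from 1980 onwards are HPV-vaccinated with 80% coverage,
which multiplies their HPV-acquisition hazard by 0.1.

## Natural histories

Each cancer is a continuous-time Markov chain with exponential
(memoryless) dwell times, advanced on a monthly grid by sampling from
the exact one-month transition matrix `expm(Q)` — occupancy therefore
matches the matrix-exponential solution of the chain with no
discretisation bias, only Monte Carlo error.

* breast: healthy → preclinical ≤15 mm → preclinical >15 mm →
  clinical presentation; nodal involvement accrues by hazard once the
  tumour is large; grade (3 vs 1–2) is fixed at onset.
* bowel: healthy → adenoma → CRC stage 1–2 → stage 3–4 → clinical;
  presentation hazard rises with stage.
* cervix: healthy → HPV → CIN → localised → regional → distant →
  clinical. HPV may clear and CIN may regress (the only permitted
  regressions); invasive stages never regress.

Clinical cancer is absorbing (treatment and mortality are not
modelled; the long-horizon bowel mode adds a Gompertz-like background
mortality). Simulations start in 2014 with compartments drawn from the
chain's own age-specific occupancy (conditioned on no prior clinical
diagnosis), which replaces decades of burn-in for the slow precursors.

None of these rates is observable directly; they are **calibration
parameters** fitted so a status quo run reproduces the programmes'
reported status quo outcomes (see Calibration). The shipped defaults
are the fitted values.

## Screening logic

* Breast: biennial mammography, invitation at 50. Sensitivity depends
  on size class (fitted: 0.88 small / 0.95 large); specificity 0.9535
  so that the false-positive recall rate is ~4.6% of episodes. All
  recalls are assessed within the programme in the same month.
  Non-participants undergo opportunistic mammography outside the
  programme at 0.4%/month, halved during a pause.
* Bowel: biennial iFOBT by post; kits are anchored to a fixed biennial
  mailing cadence. 70% of positives complete a follow-up colonoscopy
  (the model's assumption; observed completion is lower). Colonoscopy
  is perfectly sensitive for invasive cancer and 95% for adenomas;
  adenoma findings are removed and enter 1–5-yearly surveillance
  colonoscopy; clear colonoscopies return to iFOBT after 4 years.
  Follow-up plus surveillance colonoscopies constitute "NBCSP-related
  colonoscopies".
* Cervix: 5-yearly primary HPV screening from 25; women still on the
  cytology pathway screen 2-yearly (cytology sensitivity scaled by
  0.8) until their first HPV test, due two years after their last
  cytology. Positives are referred to colposcopy (a collapsed triage
  pathway, referral probability 0.90); CIN found at colposcopy is
  treated and cleared with a 12-month test-of-cure; HPV-positive
  women without CIN re-test in 12 months (surveillance stream).

## Scenarios

A disruption is a single continuous national event:

* breast: complete pause of programme throughput for 3/6/12 months
  from 1 April 2020, recovery ramping linearly over six months to the
  target capacity — 100% of status quo for 3-/6-month pauses, 150% for
  the 12-month pause — reached in the seventh month after resumption.
  The ramp's starting fraction is a free design parameter; the default
  0.45 was tuned (as the documented design decision allows) against the
  two scenario benchmarks it controls: the 12-month-pause diagnosis
  reduction and the median re-screening interval of pause-affected
  women. Missed and newly due appointments flow through the
  prioritisation queue (below). Opportunistic screening is halved
  during the pause.
* bowel: complete pause (no kits sent or processed, all NBCSP-related
  colonoscopies halted) for 3/6 months from April 2020, or spanning
  calendar 2020 for 12 months; resumption is instantaneous. People who
  miss a screen are screened at the next round, two years later;
  colonoscopies cancelled by the pause return the person to routine
  screening at the next round.
* cervix: attendance reductions of 50/75/95% to *routine* primary
  screening for 6 (Apr–Sep), 9 (Apr–Dec) or 12 (calendar-2020) months;
  surveillance and follow-up visits are unaffected. Women who miss
  screening in 2020 re-attend uniformly over 2021 (9-month policy) or
  over 2021–2022 (6-/12-month policies).

A zero-duration scenario is bit-for-bit identical to status quo under
the same seed.

## Prioritisation queue (breast recovery)

During the pause and recovery, appointments are rationed monthly.
Capacity is `floor(base × multiplier)` where `base` is the average
monthly attended screens in the paired status quo run over the year
before the pause. Requests are ordered by four factors —
(i) target age 50–74 first, (ii) appointments that fell during the
pause before recovery-period ones, (iii) existing clients before newly
invited, (iv) most overdue first — with ties broken by id, so
allocation is deterministic. The factor permutation is configurable;
the order of existing vs newly invited clients is not externally
specified and the default is a package choice.

## Outcomes

Detection modes follow programme reporting conventions: screen-detected
(diagnosis via a screening/assessment chain), interval cancers
(symptomatic diagnosis within 12 or 27 months of a negative screen,
with the 12-month class counted in the first reporting year and the
27-month class over the two-year window), and other. Programme
sensitivity is screen-detected / (screen-detected + interval-27).
Rates per 100,000 use the full population denominator including
non-participants, annualised over the reporting window.

Upstaging attribution compares paired stage-by-year tables with
excess-flow bookkeeping: the net excess of diagnoses over the window is
assigned to the earliest stage; any increase in the most advanced stage
is upstaging from the stage below; residual intermediate-stage changes
are attributed down the ladder. Defined for the cervical
localised/regional/distant ladder and generalised to the colorectal
1–2 / 3–4 ladder. "Women affected by delays" is the sum of additional
and upstaged cancers.

## Calibration

The objective is a weighted sum of squared relative errors over the
status quo outcome targets, evaluated on common-random-number runs
(fixed internal seed) so the search surface is deterministic; the
optimiser is a multiplicative coordinate search with step-halving and
jittered restarts. Scenario outcomes are never fitted — they are
predictions. Breast targets: diagnoses 298 and screen-detected 127 per
100,000 women-years, interval cancers 15 (12-month) and 38 (27-month),
programme sensitivity 77.0% (the component-rate formula value), 59.7%
of screen-detected tumours ≤15 mm, 24.9% node-positive, recall 5.2%
and false-positive recall 4.6%. Bowel targets: 1.354 M kits over
April 2020 – March 2021, 21,068 CRC diagnoses and 194,954 NBCSP-related
colonoscopies over 2020–2021, 33.9% of cancers detected at stages 3–4
(all scaled by the cohort scale factor). Achieved discrepancies are
0.037 (breast) and 0.0007 (bowel) at 1:50 and 1:100 scale respectively.
The cervical model is set to reproduce ~1,878 diagnoses over 2020–2022
and the observed ~8% primary-test positivity; its small case counts at
desk scale make a formal fit noisy, so its parameters were chosen once
to land in the right regime and validated directionally.

## Problem sizes and numerical choices

Desk-scale analyses use 1:100 cohorts. The packaged acceptance
computation uses 1:100 cohorts over three seeds for the deterministic
kit-fraction check, and 1:20 cohorts over ten seed-paired runs for the
breast scenario quantities, where the paired-difference standard error
of the diagnosis change is about 0.5 percentage points. Medians of
screening intervals are quantised by the monthly grid (one month =
4.35 weeks). Capacity floors, priority ties, and surveillance-menu
draws are all deterministic given the seed; every stochastic event
consumes fixed-size per-month uniform vectors from month-keyed
substreams of the master seed, which is what makes paired runs share
their randomness exactly.

## What the synthetic data do and do not show

The generator reproduces the *structure* the scenario analysis needs —
participation, screening cadence and transition state, age eligibility,
HPV vaccination cohorts — not the full heterogeneity of the real
populations: no socio-economic, geographic or Indigenous-status
structure, no age-specific incidence gradients, no family-history or
high-risk annual-screening subgroups, and no treatment or mortality
outcomes. Passing tests therefore demonstrate that the scenario
machinery (pauses, queues, rescheduling, attribution arithmetic) and
the calibrated aggregate behaviour reproduce the reported programme
quantities; they do not validate individual-level risk prediction.

Known limitations: bowel scenario *magnitudes* for diagnosis changes
are attenuated relative to the reported rows (the simplified natural
history has a lower screen-detected fraction of CRC than the original
proprietary calibration), though directions and monotonicity hold; the
cervical transition-era screening volume is ~40% below the reported
episode count because pre-renewal triage and early-re-screen streams
are collapsed; and the reported screening-episode table's 12-month
bowel row (zero kits over April 2020 – March 2021) is inconsistent with
a calendar-2020 pause, after which this model resumes kit delivery in
January 2021.
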