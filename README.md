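# screensim

Microsimulation of disruptions to population breast, bowel, and
cervical cancer screening programmes, modelled on Australia's three
national programmes. It answers the question health services faced in
2020: if screening pauses for 3, 6, 9 or 12 months — or attendance
drops by 50–95% — how many screens are missed, how do cancer diagnoses
and tumour stage at diagnosis shift over the following years, and what
happens to demand for assessments, colonoscopies and colposcopies?

It is written for epidemiologists and health-services modellers who
need a transparent, seed-reproducible scenario engine rather than a
clinical prediction tool.

## Model

Synthetic cohorts (women 50–74 for biennial mammography at 55%
participation; persons 48–74 for biennial iFOBT at 43.5%; women 25–74
for 5-yearly primary HPV screening at 46%, mid-transition from
cytology) carry simplified stochastic natural histories: each cancer is
a continuous-time Markov chain (healthy → precursor → preclinical
stages → clinical presentation) advanced monthly by sampling the exact
one-month transition matrix `expm(Q)`. Screening tests intercept
preclinical disease with state-dependent sensitivity; positives follow
each programme's pathway (assessment; follow-up and surveillance
colonoscopy; colposcopy with precursor treatment).

Free natural-history and test parameters are calibrated so a
no-disruption run reproduces the programmes' reported status quo
outcomes (e.g. 298 invasive breast cancers and 127 screen-detected per
100,000 women-years, programme sensitivity SD/(SD+IC₂₇) = 77%, 33.9%
of screen-era CRC detected at stages 3–4). Disruption scenarios are
then *predictions*, evaluated as paired differences against a status
quo run sharing every random number (common random numbers via
month-keyed substreams).

The breast recovery is capacity-constrained: a booking queue rations
monthly appointments by a four-factor priority (target age 50–74;
pause-period before recovery-period appointments; existing before
newly invited clients; most overdue first) while throughput ramps
linearly to 100% or 150% of status quo by the seventh month after
resumption.

## Worked example

Run the breast scenario grid at 1:100 scale and render the outcome
tables:

```bash
screensim run --seed 1 --scale 0.01 --scenario breast --out results/demo
screensim report --out results/demo
```

```
== breast_12mo (breast) ==
  diagnoses_per_100k           sq=       295.8 scenario=       258.3 change=     -37.5 (-12.7%)
  screen_detected_per_100k     sq=       122.2 scenario=        80.6 change=     -41.7 (-34.1%)
  ...
  screens_apr20_mar21          sq=    860900.0 scenario=         0.0 change= -860900.0 (-100.0%)
  diagnoses                    sq=     21300.0 scenario=     18600.0 change=   -2700.0 (-12.7%)
```

Reading this: under a 12-month pause starting April 2020 no programme
screens are delivered in the 12-month window (count rescaled to
national scale), and invasive diagnoses among women 50–74 over
2020–2021 fall from 295.8 to 258.3 per 100,000 per year — cancers that
would have been screen-detected remain hidden until later years. A
single 1:100 run is deliberately small; headline numbers firm up when
averaged over seeds (see below). The same command with
`--scenario bowel` or `--scenario cervix` produces the kit/colonoscopy
and diagnosis/colposcopy tables, where bowel diagnoses fall and
cervical diagnoses over 2020–2022 *rise* (missed precursor treatment
converts to additional invasive cancers).

`screensim fixtures` prints an arithmetic consistency report for the
embedded reference tables, and `screensim calibrate` re-runs the
status quo fit.

## Layout

| module | contents |
| --- | --- |
| `screensim.population` | synthetic cohorts, participation, HPV history |
| `screensim.natural_history` | disease chains, stages, vaccination effect |
| `screensim.programmes` | screening rules, test characteristics, follow-up |
| `screensim.scenario` | pauses, attendance reductions, capacity ramps, rescheduling |
| `screensim.prioritisation` | breast booking queue and interval statistics |
| `screensim.outcomes` | detection modes, sensitivity, upstaging attribution, tables |
| `screensim.calibration` | status quo fitting (coordinate search, CRN objective) |
| `screensim.engine` | monthly per-programme drivers, paired runs |
| `screensim.reporting` / `screensim.cli` | end-to-end runner and `screensim` CLI |
| `screensim.fixtures` | embedded reference tables + consistency report |

See `docs/methods.md` for model assumptions, parameter meanings and
defaults, calibration details, and known limitations.
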