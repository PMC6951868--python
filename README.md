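# sepscreen

Simulated sepsis surveillance over hospital encounter event streams: a
temporal rules engine for severe-sepsis screen-in, exercised end to end on
a synthetic electronic-health-record cohort with known ground truth, and
an evaluation layer for the central design question of such systems — the
trade-off between **alert reliability** (positive predictive value on
suspected infection) and **condition sensitivity** as screening parameters
are removed or constrained.

It is written for informaticists and biostatisticians who want to study
how rule configuration changes which patients a surveillance system
identifies, what parameter "substitution effects" that induces, and how
mortality risk differs across the parameter classes that fire.

## The model

An encounter's clinical data is a stream of timestamped observations
(vitals and labs), each possibly re-issued as a corrected result.  Version
resolution keeps, for every clinical event `(concept, event_time)`, only
the highest update-counter version.  The screen then runs at every
observation time `t` from admission to discharge.  A criterion is met at
`t` iff some value of its concept inside the half-open lookback window
`(t − L, t]` crosses its threshold, with `L` = 12 h for lactate, 72 h for
creatinine and 30 h otherwise.

Severe-sepsis screen-in at `t` requires **≥ 2 SIRS criteria** —
temperature > 38.3 °C or < 36 °C; heart rate > 90 /min; respiratory
rate > 20 /min; WBC > 12 000 /mm³, < 4 000 /mm³ or > 10 % band forms — and
**≥ 1 organ-dysfunction parameter**:

| class | rule (reference scenario) |
|---|---|
| `sbp_drop` | SBP decrease > 40 mm Hg from baseline (first SBP in window) |
| `sbp_or_map` | SBP < 90 mm Hg or MAP < 65 mm Hg |
| `lactate` | serum lactate > 2.0 mmol/L |
| `bilirubin` | total bilirubin ≥ 2.0 mg/dL |
| `creatinine` | serum creatinine ≥ 2.0 mg/dL |
| `platelets` / `inr` | platelets < 100 000 /µL, INR > 1.5 |

Three shipped scenario presets nest by construction: `sep2_based` (all
parameters; closest to the CMS severe-sepsis definition), `near_sep2`
(drops the hyperactive SBP-decrease parameter) and `conservative`
(additionally requires a creatinine rise ≥ 0.5 mg/dL, caps qualifying
bilirubin at 10 mg/dL and eliminates the hematologic parameters).  Each
flagged encounter is attributed to exactly one class — `mods` when
parameters span ≥ 2 organ systems — so per-class counts always partition
the flagged count.

Around the screen: suspected-infection labeling (qualifying microbiology
culture drawn **and** IV anti-infective administered), admission acuity
(six-component NEWS and the apparent strong ion difference
SIDa = Na⁺ + K⁺ + 1.85 − Cl⁻, flagged outside (34, 48) mmol/L), and the
evaluation layer: per-scenario PPV and sensitivity against the
all-parameters reference, substitution analyses with Woolf crude odds
ratios, and adjusted logistic mortality models (covariates age, sex, NEWS
category).

## Worked example

The bundled 12-encounter worked example has one encounter per parameter
class, one multi-system case, near-miss controls (SIRS alone, one organ
value alone) and healthy controls:

```python
from sepscreen import worked_example_cohort, preset, screen_cohort

cohort, truth = worked_example_cohort()
alerts = screen_cohort(cohort, preset("near_sep2"))
print(alerts.loc[alerts.flagged, ["encounter_id", "first_alert_time", "attributed_class"]])
```

```
encounter_id    first_alert_time attributed_class
         W02 2016-03-01 19:00:00       sbp_or_map
         W03 2016-03-01 19:00:00          lactate
         W04 2016-03-01 19:00:00        bilirubin
         W05 2016-03-01 19:00:00       creatinine
         W06 2016-03-01 19:00:00        platelets
         W07 2016-03-01 19:00:00              inr
         W08 2016-03-01 19:00:00             mods
```

W01, the encounter whose only abnormality is an SBP fall from 152 to
106 mm Hg, is flagged by `sep2_based` but absent here — the `near_sep2`
preset exists precisely to remove that parameter.  The controls W09–W12
are flagged by no scenario.

## The analysis pipeline

Numbered drivers under `analysis/` run the full study on a generated
5000-encounter cohort and write tables under `results/`:

```
python analysis/01_generate_cohort.py      # cohort tables + ground truth
python analysis/02_screen_scenarios.py     # alerts per scenario, nesting check
python analysis/03_label_acuity.py         # infection labels, NEWS/SIDa
python analysis/04_evaluate.py             # metrics, substitution, mortality, forest plot
```

A typical run prints a reliability/sensitivity trade-off of the expected
shape — PPV 65 % → 69 % → 72 % while sensitivity falls 100 % → 76 % → 56 %
across `sep2_based` → `near_sep2` → `conservative` — and reports the
mortality odds ratios of reclassified versus same-class patients.  The
same stages are available as CLI subcommands (`sepscreen synth`,
`screen`, `acuity`, `label`, `evaluate`).

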