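# Methods

## The screening model

The engine treats an encounter as a set of per-concept time series at
minute resolution.  Hospital source systems re-issue results (preliminary
lab values later corrected), so the atom of the store is a *versioned*
observation: `(encounter, concept, event_time, update_seq, value)`.
Version resolution keeps the highest `update_seq` per clinical event,
where event identity is keyed by `(concept, event_time)`; two versions of
one event with equal counters are rejected as a data error, because the
counter exists precisely to disambiguate.  Resolution is idempotent and
invariant to input order (both are property-tested).

Evaluation runs at every observation event time between admission and
discharge, not on a clock grid: an alert can only change state when data
arrives.  At evaluation time `t`, a criterion consults the half-open
window `(t − L, t]` — the reading at the evaluation instant counts, a
reading exactly `L` hours old does not.  Lookbacks are 12 h for lactate,
72 h for creatinine, 30 h for everything else.  The first instant at which
≥ 2 SIRS criteria and ≥ 1 organ-dysfunction parameter hold jointly is the
alert time; criteria sets and attribution are recorded as of that instant
(the alert is a point-in-time notification, so multiple-organ-dysfunction
status is not accumulated over the stay).

Threshold conventions follow the rule text exactly: SIRS bounds and the
lactate/platelet/INR/SBP/MAP thresholds are strict inequalities;
bilirubin ≥ 2.0 and creatinine ≥ 2.0 are inclusive.  Boundary values are
unit-tested on both sides.

Interpretations that the rule text leaves open, decided here once:

* **SBP decrease > 40 mm Hg.**  Baseline is the *first* SBP reading in the
  30-h window; the criterion compares that baseline against the window
  minimum and requires a strictly greater than 40 mm Hg fall.  Among the
  many possible readings of "decrease from baseline" this one maximizes
  detections, consistent with the parameter's known hyperactivity.
* **Conservative creatinine rule.**  Read conjunctively: the 2.0 mg/dL
  threshold must still be reached *and* the window must contain a rise
  ≥ 0.5 mg/dL ending at a qualifying high value (an earlier in-window
  reading at least 0.5 below some reading ≥ 2.0).  The conservative
  scenario is described as a restriction and its totals shrink; a
  disjunctive reading would enlarge it.
* **Attribution precedence.**  When a single organ system contributes
  several parameters, attribution follows the listing order of the
  criteria: `sbp_drop > sbp_or_map > lactate` (cardiovascular) and
  `platelets > inr` (hematologic).  This affects how flagged counts split
  across rows, never their total; the partition identity (class counts sum
  to the flagged count) is enforced structurally and tested.
* **Joint satisfaction.**  SIRS and organ criteria must hold at one
  evaluation instant, each through its own lookback — not merely within
  overlapping windows at different instants.

Because `near_sep2` only disables a parameter and `conservative` only
restricts further, flagged sets nest
(`conservative ⊆ near_sep2 ⊆ sep2_based`) on every cohort; this is tested
over 20 generated cohorts.

## Labels and acuity

Suspected infection requires at least one culture from a closed specimen
list *and* at least one administration from a closed anti-infective list
with route IV, anywhere in the encounter — no temporal coupling between
the two, since the definition states none.  The list is kept exactly as
specified, including fluticasone-salmeterol (an inhaled respiratory
agent); fidelity was preferred over plausibility.  Mortality is
death in hospital or hospice referral at discharge.

NEWS is computed in a six-component variant (respiratory rate, SpO₂,
temperature, SBP, heart rate, level of consciousness) from the earliest
post-admission value per component independently; there is no
supplemental-oxygen item, so the maximum is 18 points, still inside the
top "9–25" reporting band.  A missing component scores 0 with a logged
warning rather than excluding the encounter.  SIDa = Na + K + 1.85 − Cl
(the 1.85 constant is taken as given), flagged inclusively at ≤ 34.0 or
≥ 48.0 mmol/L, absent unless all three analytes were measured.

## Evaluation layer

Alert reliability is PPV on suspected infection among flagged encounters.
There is no gold-standard sepsis adjudication, so condition sensitivity
is defined against the all-parameters reference scenario: among
suspected-infection patients flagged by `sep2_based`, the fraction also
flagged by the comparison scenario (the reference scores 1 by
construction).  Substitution analyses restrict to suspected-infection
patients flagged by both scenarios of a pair and contrast death among
reclassified versus same-class patients; crude odds ratios carry Woolf
(log-OR Wald) 95 % intervals, `exp(log OR ± 1.96·SE)` with
`SE = √(1/a + 1/b + 1/c + 1/d)`, and a 0.5 continuity correction on any
zero cell (with a warning).  Mortality models are binary logistic
regressions fit by IRLS (log-likelihood tolerance 1e-8), one parameter
class per model with absence of that class as reference, adjusted for age
in years (continuous, untransformed), sex, and NEWS category as an
ordered factor with "0–4" as reference.  Non-convergence, perfect or
quasi-separation, and absent contrast are reported as failed fits with a
diagnostic, never silently.  Without covariates the fitted OR equals the
closed-form crude OR of the 2×2 table, which is used as an oracle test.

Display rounding follows the conventional presentation: proportions to
whole percent, odds ratios and intervals to 2 decimals.

## The synthetic-data generator

The generator emulates the *statistical structure* the analysis needs,
not physiology.  Vitals are baseline bands plus a transient deterioration
episode, because the screen only cares about threshold crossings within
windows:

* **Septic profiles** (default 26 % of encounters) get ≥ 2 SIRS-crossing
  vitals followed 45 min later by the planted organ-dysfunction values,
  all at one instant so the first alert carries exactly the planted
  parameter set.  Planted classes are drawn from a weighted mix (defaults
  proportional to the attribution mix of an all-parameters screen); 10 %
  of septic encounters get two classes from distinct organ systems and
  hence a multiple-organ-dysfunction attribution.
* **Non-septic encounters** stay strictly inside safe bands chosen so no
  criterion can fire spuriously (e.g. background SBP jitter is bounded so
  a 40 mm Hg window drop is impossible).  A configurable fraction are
  deliberate near-misses — SIRS alone, or one organ value alone — that
  exercise the conjunction logic without ever screening in.

This construction makes the reference screen recover the planted septic
labels with sensitivity = specificity = 1, which is the generator's
acceptance oracle, and makes planted-class attribution exact.  Suspected
infection is planted with probability `frac_infected_given_flagged`
(default 0.64) among septic encounters — optionally per attributed class,
to reproduce the reliability gradient in which the SBP-drop class is
least reliable and lactate most — and at a background rate (default 0.15)
otherwise, alongside near-miss records (culture without antibiotic, oral
route) for the labeler.  Death/hospice is drawn from a logistic model:
base odds from `mortality_base_rate` multiplied by one odds ratio per
planted class, which makes crude and adjusted ORs recoverable at cohort
scale.  Corrected-re-result noise replaces a chosen fraction of lab
values with an out-of-category decoy at `update_seq` 0 and appends the
true value at `update_seq` 1, so only update-resolved pipelines see
truth-consistent data; alerts on noised and clean tables agree exactly
after resolution.

Ages are drawn from a normal (mean 64, SD 17) truncated to 18–100, giving
median ≈ 66 and IQR ≈ 52–76; length of stay is log-normal around a 4-day
median.  Admission-acuity spread uses channels that no screening rule
consults (SpO₂, level of consciousness, a mildly low but safe SBP band),
plus deranged arrival vitals for half the septic encounters.  One seeded
generator drives all draws through named child streams, so tables are
byte-identical across runs and toggling the update-noise rate perturbs
nothing else.

What the generator does **not** model — and hence what passing tests do
not show about real data: informed-presence and missing-not-at-random
observation patterns, physiologic autocorrelation and treatment response,
culture positivity, pharmacokinetics, and any coupling between acuity
covariates and mortality beyond the planted class effects.  In
particular, the generator's substitution effects arise only from
multi-class encounters, so reclassification shares are smaller than a
real deployment would show; the substitution machinery itself is
additionally verified on constructed tables reproducing published
summary counts.

## Problem sizes and numerics

Cohort-scale checks use 5000 encounters (partition, nesting sensitivity,
label-recovery fidelity, PPV convergence within 3 binomial SEs, planted-OR
recovery with a single non-null class so the marginal and conditional OR
coincide); nesting is additionally checked on 20 cohorts of 150 and
update-noise equivalence on 10 cohorts of 120.  Timestamps are
timezone-naive at minute resolution; all window arithmetic is integer
nanoseconds.  Logistic fits use statsmodels GLM/binomial with
`tol = 1e-8`, `maxiter = 200`; a fitted |coefficient| > 15 or SE > 50 is
reported as quasi-separation.  The forest plot is rendered with a fixed
SVG hash salt and no date metadata so report bundles are reproducible.
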