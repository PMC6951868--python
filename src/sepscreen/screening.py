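"""SIRS / organ-dysfunction rules engine over resolved timelines.

The screen runs at every observation event time between admission and
discharge (alert state can only change when data arrives).  At an
evaluation instant ``t`` a criterion is met iff some value of its concept
inside the criterion's own half-open lookback window ``(t - L, t]``
crosses the threshold.  Severe-sepsis screen-in requires >=2 SIRS criteria
and >=1 organ-dysfunction parameter jointly at a single evaluation instant;
the first such instant is the alert time and the criteria recorded are
those met then.

Attribution collapses the organ parameters met at alert time to exactly
one class: parameters spanning >=2 organ systems mean multiple organ
dysfunction (``mods``); within one system a fixed precedence (SBP drop >
SBP-or-MAP > lactate; platelets > INR) picks the single class, so the
per-class counts always partition the flagged count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .concepts import ORGAN_SYSTEM_OF
from .events import EncounterRecord, ResolvedTimeline, resolve_timeline, window_values
from .io import Cohort
from .scenarios import ScenarioConfig

__all__ = [
    "AlertResult",
    "eval_sirs",
    "baseline_sbp",
    "eval_organ_dysfunction",
    "attribute_class",
    "screen_encounter",
    "resolve_cohort",
    "screen_cohort",
]

# within-system precedence for single-system attribution
_ATTRIBUTION_PRECEDENCE = (
    "sbp_drop", "sbp_or_map", "lactate", "bilirubin", "creatinine", "platelets", "inr",
)


@dataclass(frozen=True)
class AlertResult:
    """Per-encounter screening outcome under one scenario."""

    encounter_id: str
    flagged: bool
    first_alert_time: pd.Timestamp | None = None
    sirs_criteria_met: frozenset = frozenset()
    organ_parameters_met: frozenset = frozenset()
    attributed_class: str | None = None

    def __post_init__(self):
        present = (self.first_alert_time is not None, self.attributed_class is not None)
        if self.flagged != present[0] or self.flagged != present[1]:
            raise ValueError("flagged must coincide with alert time and attribution")


def eval_sirs(timeline: ResolvedTimeline, at, config: ScenarioConfig) -> set[str]:
    """SIRS criteria met at ``at``: subset of {temperature, heart_rate, resp_rate, wbc}.

    Absent data never meets a criterion.  All thresholds are strict.
    """
    L = config.default_lookback_h
    met: set[str] = set()
    temps = [v for _, v in window_values(timeline, "temperature_C", at, L)]
    if any(v > config.temp_high_C or v < config.temp_low_C for v in temps):
        met.add("temperature")
    if any(v > config.hr_high_bpm for _, v in window_values(timeline, "heart_rate_bpm", at, L)):
        met.add("heart_rate")
    if any(v > config.rr_high_bpm for _, v in window_values(timeline, "resp_rate_bpm", at, L)):
        met.add("resp_rate")
    wbcs = [v for _, v in window_values(timeline, "wbc_per_mm3", at, L)]
    bands = [v for _, v in window_values(timeline, "band_pct", at, L)]
    if any(v > config.wbc_high_per_mm3 or v < config.wbc_low_per_mm3 for v in wbcs) or any(
        v > config.band_high_pct for v in bands
    ):
        met.add("wbc")
    return met


def baseline_sbp(timeline: ResolvedTimeline, at, lookback_h: float = 30.0) -> float | None:
    """First SBP reading within the lookback window; None when none exists."""
    w = window_values(timeline, "sbp_mmHg", at, lookback_h)
    return w[0][1] if w else None


def eval_organ_dysfunction(
    timeline: ResolvedTimeline, at, config: ScenarioConfig
) -> set[str]:
    """Organ-dysfunction parameters met at ``at`` under ``config``."""
    L = config.default_lookback_h
    met: set[str] = set()

    sbps = [v for _, v in window_values(timeline, "sbp_mmHg", at, L)]
    maps_ = [v for _, v in window_values(timeline, "map_mmHg", at, L)]
    if any(v < config.sbp_low_mmHg for v in sbps) or any(v < config.map_low_mmHg for v in maps_):
        met.add("sbp_or_map")
    if config.sbp_drop_enabled and sbps:
        if sbps[0] - min(sbps) > config.sbp_drop_mmHg:
            met.add("sbp_drop")

    if any(
        v > config.lactate_high_mmol_L
        for _, v in window_values(timeline, "lactate_mmol_L", at, config.lactate_lookback_h)
    ):
        met.add("lactate")

    bili = [v for _, v in window_values(timeline, "bilirubin_mg_dL", at, L)]
    cap = config.bilirubin_cap_mg_dL
    if any(v >= config.bilirubin_low_mg_dL and (cap is None or v <= cap) for v in bili):
        met.add("bilirubin")

    crea = [v for _, v in window_values(timeline, "creatinine_mg_dL", at, config.creatinine_lookback_h)]
    if crea:
        if config.creatinine_delta_required:
            # rise must end at the qualifying high value: an earlier in-window
            # reading at least delta below some reading >= threshold
            prefmin = np.minimum.accumulate(np.asarray(crea))
            vals = np.asarray(crea)
            if np.any((vals >= config.creatinine_high_mg_dL)
                      & (vals - prefmin >= config.creatinine_delta_mg_dL)):
                met.add("creatinine")
        elif any(v >= config.creatinine_high_mg_dL for v in crea):
            met.add("creatinine")

    if config.platelets_inr_enabled:
        if any(v < config.platelets_low_per_uL
               for _, v in window_values(timeline, "platelets_per_uL", at, L)):
            met.add("platelets")
        if any(v > config.inr_high for _, v in window_values(timeline, "inr", at, L)):
            met.add("inr")
    return met


def attribute_class(organ_parameters_met) -> str:
    """Collapse the organ parameters met at alert time to one class.

    >=2 distinct organ systems -> ``mods``; within a single system the
    precedence sbp_drop > sbp_or_map > lactate (cardiovascular) and
    platelets > inr (hematologic) applies; hepatic and renal are singletons.
    """
    params = set(organ_parameters_met)
    if not params:
        raise ValueError("attribution requires a nonempty set of parameters met")
    unknown = params - set(ORGAN_SYSTEM_OF)
    if unknown:
        raise ValueError(f"unknown organ parameters: {sorted(unknown)}")
    systems = {ORGAN_SYSTEM_OF[p] for p in params}
    if len(systems) >= 2:
        return "mods"
    for p in _ATTRIBUTION_PRECEDENCE:
        if p in params:
            return p
    raise AssertionError("unreachable")


# ---------------------------------------------------------------------------
# vectorized evaluation over all observation times of one encounter

_NS_PER_H = 3_600_000_000_000


def _met_mask(qual_ns: np.ndarray, eval_ns: np.ndarray, lookback_h: float) -> np.ndarray:
    """For each eval time t, is there a qualifying event in (t - L, t]?"""
    if qual_ns.size == 0:
        return np.zeros(eval_ns.shape, dtype=bool)
    lb = int(round(lookback_h * _NS_PER_H))
    lo = np.searchsorted(qual_ns, eval_ns - lb, side="right")
    hi = np.searchsorted(qual_ns, eval_ns, side="right")
    return hi > lo


def _series_ns(timeline: ResolvedTimeline, concept: str) -> tuple[np.ndarray, np.ndarray]:
    t, v = timeline.get(concept)
    return t.astype("datetime64[ns]").astype(np.int64), v


def _screen_masks(timeline: ResolvedTimeline, eval_ns: np.ndarray, config: ScenarioConfig):
    """(sirs_count, organ_any) boolean machinery across all eval times."""
    L = config.default_lookback_h

    def mask(concept, predicate, lookback):
        t, v = _series_ns(timeline, concept)
        return _met_mask(t[predicate(v)], eval_ns, lookback)

    sirs = {
        "temperature": mask(
            "temperature_C", lambda v: (v > config.temp_high_C) | (v < config.temp_low_C), L
        ),
        "heart_rate": mask("heart_rate_bpm", lambda v: v > config.hr_high_bpm, L),
        "resp_rate": mask("resp_rate_bpm", lambda v: v > config.rr_high_bpm, L),
        "wbc": mask(
            "wbc_per_mm3",
            lambda v: (v > config.wbc_high_per_mm3) | (v < config.wbc_low_per_mm3),
            L,
        )
        | mask("band_pct", lambda v: v > config.band_high_pct, L),
    }

    organ: dict[str, np.ndarray] = {}
    organ["sbp_or_map"] = mask("sbp_mmHg", lambda v: v < config.sbp_low_mmHg, L) | mask(
        "map_mmHg", lambda v: v < config.map_low_mmHg, L
    )
    organ["lactate"] = mask(
        "lactate_mmol_L", lambda v: v > config.lactate_high_mmol_L, config.lactate_lookback_h
    )
    cap = config.bilirubin_cap_mg_dL
    organ["bilirubin"] = mask(
        "bilirubin_mg_dL",
        lambda v: (v >= config.bilirubin_low_mg_dL) & ((cap is None) | (v <= (cap or np.inf))),
        L,
    )

    ct_ns, cv = _series_ns(timeline, "creatinine_mg_dL")
    if config.creatinine_delta_required:
        organ["creatinine"] = _creatinine_delta_mask(ct_ns, cv, eval_ns, config)
    else:
        organ["creatinine"] = _met_mask(
            ct_ns[cv >= config.creatinine_high_mg_dL], eval_ns, config.creatinine_lookback_h
        )

    if config.platelets_inr_enabled:
        organ["platelets"] = mask(
            "platelets_per_uL", lambda v: v < config.platelets_low_per_uL, L
        )
        organ["inr"] = mask("inr", lambda v: v > config.inr_high, L)

    if config.sbp_drop_enabled:
        organ["sbp_drop"] = _sbp_drop_mask(timeline, eval_ns, config)

    return sirs, organ


def _creatinine_delta_mask(ct_ns, cv, eval_ns, config: ScenarioConfig) -> np.ndarray:
    out = np.zeros(eval_ns.shape, dtype=bool)
    if ct_ns.size == 0:
        return out
    lb = int(round(config.creatinine_lookback_h * _NS_PER_H))
    lo = np.searchsorted(ct_ns, eval_ns - lb, side="right")
    hi = np.searchsorted(ct_ns, eval_ns, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b <= a:
            continue
        w = cv[a:b]
        prefmin = np.minimum.accumulate(w)
        out[i] = bool(
            np.any(
                (w >= config.creatinine_high_mg_dL)
                & (w - prefmin >= config.creatinine_delta_mg_dL)
            )
        )
    return out


def _sbp_drop_mask(timeline: ResolvedTimeline, eval_ns, config: ScenarioConfig) -> np.ndarray:
    st_ns, sv = _series_ns(timeline, "sbp_mmHg")
    out = np.zeros(eval_ns.shape, dtype=bool)
    if st_ns.size == 0:
        return out
    lb = int(round(config.default_lookback_h * _NS_PER_H))
    lo = np.searchsorted(st_ns, eval_ns - lb, side="right")
    hi = np.searchsorted(st_ns, eval_ns, side="right")
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b > a:
            out[i] = sv[a] - sv[a:b].min() > config.sbp_drop_mmHg
    return out


def screen_encounter(
    encounter: EncounterRecord, timeline: ResolvedTimeline, config: ScenarioConfig
) -> AlertResult:
    """Run the screen over one encounter; alert at the first instant where
    >=2 SIRS criteria and >=1 organ-dysfunction parameter are jointly met."""
    if not encounter.discharge_time > encounter.admit_time:
        raise ValueError("discharge before admit")
    all_times = timeline.event_times
    admit = np.datetime64(encounter.admit_time)
    disch = np.datetime64(encounter.discharge_time)
    eval_times = all_times[(all_times >= admit) & (all_times <= disch)]
    if eval_times.size == 0:
        return AlertResult(encounter.encounter_id, flagged=False)

    eval_ns = eval_times.astype("datetime64[ns]").astype(np.int64)
    sirs, organ = _screen_masks(timeline, eval_ns, config)
    sirs_count = sum(m.astype(np.int8) for m in sirs.values())
    organ_any = np.zeros(eval_ns.shape, dtype=bool)
    for m in organ.values():
        organ_any |= m
    fire = (sirs_count >= 2) & organ_any
    if not fire.any():
        return AlertResult(encounter.encounter_id, flagged=False)

    i = int(np.argmax(fire))
    at = pd.Timestamp(eval_times[i])
    sirs_met = frozenset(k for k, m in sirs.items() if m[i])
    organ_met = frozenset(k for k, m in organ.items() if m[i])
    return AlertResult(
        encounter_id=encounter.encounter_id,
        flagged=True,
        first_alert_time=at,
        sirs_criteria_met=sirs_met,
        organ_parameters_met=organ_met,
        attributed_class=attribute_class(organ_met),
    )


# ---------------------------------------------------------------------------
# cohort-level driver

def resolve_cohort(cohort: Cohort) -> dict[str, ResolvedTimeline]:
    """Apply update resolution to every encounter's event stream at once."""
    obs = cohort.observations
    if obs.empty:
        return {eid: ResolvedTimeline(eid) for eid in cohort.encounter_ids}
    key = ["encounter_id", "concept", "event_time", "update_seq"]
    df = obs.sort_values(key, kind="mergesort")
    if df.duplicated(key).any():
        raise ValueError("tied update_seq for one clinical event during resolution")
    df = df.drop_duplicates(["encounter_id", "concept", "event_time"], keep="last")

    enc = df["encounter_id"].to_numpy()
    con = df["concept"].to_numpy()
    times = df["event_time"].to_numpy(dtype="datetime64[ns]")
    vals = df["value"].to_numpy(dtype=float)

    timelines: dict[str, ResolvedTimeline] = {
        eid: ResolvedTimeline(eid) for eid in cohort.encounter_ids
    }
    # group boundaries over the (encounter, concept) sorted arrays
    n = len(df)
    change = np.flatnonzero((enc[1:] != enc[:-1]) | (con[1:] != con[:-1])) + 1
    starts = np.concatenate(([0], change))
    stops = np.concatenate((change, [n]))
    for a, b in zip(starts, stops):
        tl = timelines.get(enc[a])
        if tl is not None:
            tl.series[con[a]] = (times[a:b], vals[a:b])
    return timelines


def screen_cohort(
    cohort: Cohort,
    config: ScenarioConfig,
    timelines: dict[str, ResolvedTimeline] | None = None,
) -> pd.DataFrame:
    """Screen every encounter; one row per encounter.

    Columns: encounter_id, flagged, first_alert_time, sirs_met, organ_met
    (pipe-joined, sorted), attributed_class.  Pass ``timelines`` (from
    :func:`resolve_cohort`) to amortize resolution across scenarios.
    """
    if timelines is None:
        timelines = resolve_cohort(cohort)
    rows = []
    for rec in cohort.encounters.itertuples(index=False):
        enc = EncounterRecord(
            encounter_id=rec.encounter_id,
            age_years=int(rec.age_years),
            sex=rec.sex,
            admit_time=rec.admit_time,
            discharge_time=rec.discharge_time,
            disposition=rec.disposition,
            icu_within_48h=bool(rec.icu_within_48h),
        )
        tl = timelines.get(rec.encounter_id, ResolvedTimeline(rec.encounter_id))
        r = screen_encounter(enc, tl, config)
        rows.append(
            {
                "encounter_id": r.encounter_id,
                "flagged": r.flagged,
                "first_alert_time": r.first_alert_time,
                "sirs_met": "|".join(sorted(r.sirs_criteria_met)),
                "organ_met": "|".join(sorted(r.organ_parameters_met)),
                "attributed_class": r.attributed_class,
            }
        )
    out = pd.DataFrame(rows)
    out.attrs["scenario"] = config.name
    return out
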