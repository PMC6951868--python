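"""Admission-time acuity covariates.

Two severity measures computed from the first documented values after
admission:

* the National Early Warning Score (NEWS) in a six-component variant —
  respiratory rate, oxygen saturation, temperature, systolic blood
  pressure, heart rate and level of consciousness; there is no
  supplemental-oxygen item, so the maximum is 18 points (each component
  contributes at most 3).  Points are banded into the categories
  0–4, 5–6, 7–8 and 9–25 used as an ordered covariate downstream.
* the apparent Strong Ion Difference, SIDa = (Na + K + 1.85) − Cl in
  mmol/L, flagged as a severe electrolyte/metabolic disturbance when
  ≤34.0 or ≥48.0 (both boundaries inclusive).

A missing NEWS component contributes 0 points with a logged warning; the
SIDa value is absent (and the flag false) unless all three analytes were
measured.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .events import EncounterRecord, ResolvedTimeline
from .io import Cohort
from .screening import resolve_cohort

log = logging.getLogger(__name__)

__all__ = [
    "AcuityProfile",
    "news_score",
    "news_category",
    "sida",
    "first_values_after",
    "acuity_profile",
    "acuity_cohort",
]

NEWS_COMPONENTS = (
    "resp_rate_bpm",
    "spo2_pct",
    "temperature_C",
    "sbp_mmHg",
    "heart_rate_bpm",
    "loc_avpu",
)

NEWS_CATEGORIES = ("0-4", "5-6", "7-8", "9-25")


@dataclass(frozen=True)
class AcuityProfile:
    encounter_id: str
    news_points: int
    news_category: str
    sida_mmol_L: float | None
    sida_flag: bool


def _rr_points(v: float) -> int:
    if v <= 8:
        return 3
    if v < 12:
        return 1
    if v <= 20:
        return 0
    if v <= 24:
        return 2
    return 3


def _spo2_points(v: float) -> int:
    if v <= 91:
        return 3
    if v <= 93:
        return 2
    if v <= 95:
        return 1
    return 0


def _temp_points(v: float) -> int:
    if v <= 35.0:
        return 3
    if v <= 36.0:
        return 1
    if v <= 38.0:
        return 0
    if v <= 39.0:
        return 1
    return 2


def _sbp_points(v: float) -> int:
    if v <= 90:
        return 3
    if v <= 100:
        return 2
    if v <= 110:
        return 1
    if v < 220:
        return 0
    return 3


def _hr_points(v: float) -> int:
    if v <= 40:
        return 3
    if v <= 50:
        return 1
    if v <= 90:
        return 0
    if v <= 110:
        return 1
    if v <= 130:
        return 2
    return 3


def _loc_points(v: float) -> int:
    # AVPU: alert scores 0; any response below alert (V/P/U) scores 3
    return 0 if v == 0 else 3


_SCORERS = {
    "resp_rate_bpm": _rr_points,
    "spo2_pct": _spo2_points,
    "temperature_C": _temp_points,
    "sbp_mmHg": _sbp_points,
    "heart_rate_bpm": _hr_points,
    "loc_avpu": _loc_points,
}


def news_category(points: int) -> str:
    if points < 0:
        raise ValueError("NEWS points cannot be negative")
    if points <= 4:
        return "0-4"
    if points <= 6:
        return "5-6"
    if points <= 8:
        return "7-8"
    if points <= 25:
        return "9-25"
    raise ValueError(f"NEWS points out of range: {points}")


def news_score(first_vitals: dict[str, float]) -> tuple[int, str]:
    """Six-component NEWS points and category from first documented vitals.

    ``first_vitals`` maps component concept -> value; missing components
    score 0 with a warning.
    """
    points = 0
    for comp in NEWS_COMPONENTS:
        if comp in first_vitals and first_vitals[comp] is not None:
            points += _SCORERS[comp](float(first_vitals[comp]))
        else:
            log.warning("NEWS component %s missing; scored 0", comp)
    return points, news_category(points)


def sida(sodium: float, potassium: float, chloride: float) -> tuple[float, bool]:
    """Apparent Strong Ion Difference (Na + K + 1.85) − Cl, with severity flag."""
    for v in (sodium, potassium, chloride):
        if not math.isfinite(v):
            raise ValueError("SIDa requires finite analyte values")
    value = sodium + potassium + 1.85 - chloride
    return value, bool(value <= 34.0 or value >= 48.0)


def first_values_after(
    timeline: ResolvedTimeline, concepts, at
) -> dict[str, float]:
    """Earliest value at/after ``at`` per concept, independently per concept."""
    at64 = np.datetime64(pd.Timestamp(at).floor("min"))
    out: dict[str, float] = {}
    for concept in concepts:
        times, values = timeline.get(concept)
        idx = np.searchsorted(times, at64, side="left")
        if idx < len(times):
            out[concept] = float(values[idx])
    return out


def acuity_profile(encounter: EncounterRecord, timeline: ResolvedTimeline) -> AcuityProfile:
    vitals = first_values_after(timeline, NEWS_COMPONENTS, encounter.admit_time)
    points, category = news_score(vitals)
    analytes = first_values_after(
        timeline,
        ("sodium_mmol_L", "potassium_mmol_L", "chloride_mmol_L"),
        encounter.admit_time,
    )
    if len(analytes) == 3:
        value, flag = sida(
            analytes["sodium_mmol_L"], analytes["potassium_mmol_L"], analytes["chloride_mmol_L"]
        )
    else:
        value, flag = None, False
    return AcuityProfile(encounter.encounter_id, points, category, value, flag)


def acuity_cohort(
    cohort: Cohort, timelines: dict[str, ResolvedTimeline] | None = None
) -> pd.DataFrame:
    """Acuity profiles for every encounter as a DataFrame."""
    if timelines is None:
        timelines = resolve_cohort(cohort)
    rows = []
    for rec in cohort.encounters.itertuples(index=False):
        enc = EncounterRecord(
            rec.encounter_id, int(rec.age_years), rec.sex, rec.admit_time,
            rec.discharge_time, rec.disposition, bool(rec.icu_within_48h),
        )
        tl = timelines.get(rec.encounter_id, ResolvedTimeline(rec.encounter_id))
        p = acuity_profile(enc, tl)
        rows.append(
            {
                "encounter_id": p.encounter_id,
                "news_points": p.news_points,
                "news_category": p.news_category,
                "sida": p.sida_mmol_L,
                "sida_flag": p.sida_flag,
            }
        )
    return pd.DataFrame(rows)
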