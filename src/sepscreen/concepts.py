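"""Clinical concept registry shared by every stage of the pipeline.

Each observation carries one of a closed set of concept codes with a fixed
unit; there is deliberately no unit conversion anywhere downstream.  The
plausibility bounds are ingest-time sanity gates (a temperature of 98.6
almost certainly arrived in Fahrenheit), not clinical alert thresholds.
"""

from __future__ import annotations

# concept -> (lower, upper) inclusive physiologic plausibility bounds, in the
# fixed unit encoded in the concept name. Violations are rejected at ingest
# with a logged reason, never clamped.
PLAUSIBILITY_BOUNDS: dict[str, tuple[float, float]] = {
    "temperature_C": (25.0, 45.0),
    "heart_rate_bpm": (0.0, 350.0),
    "resp_rate_bpm": (0.0, 90.0),
    "wbc_per_mm3": (0.0, 500_000.0),
    "band_pct": (0.0, 100.0),
    "sbp_mmHg": (20.0, 320.0),
    "map_mmHg": (10.0, 250.0),
    "lactate_mmol_L": (0.0, 35.0),
    "bilirubin_mg_dL": (0.0, 60.0),
    "creatinine_mg_dL": (0.0, 35.0),
    "platelets_per_uL": (0.0, 2_500_000.0),
    "inr": (0.1, 25.0),
    "sodium_mmol_L": (90.0, 200.0),
    "potassium_mmol_L": (0.5, 12.0),
    "chloride_mmol_L": (50.0, 160.0),
    "spo2_pct": (0.0, 100.0),
    # level of consciousness on the AVPU scale, ordinal A=0, V=1, P=2, U=3
    "loc_avpu": (0.0, 3.0),
}

CONCEPTS: frozenset[str] = frozenset(PLAUSIBILITY_BOUNDS)

#: concepts that arrive from the laboratory (eligible for corrected re-results)
LAB_CONCEPTS: frozenset[str] = frozenset(
    {
        "wbc_per_mm3",
        "band_pct",
        "lactate_mmol_L",
        "bilirubin_mg_dL",
        "creatinine_mg_dL",
        "platelets_per_uL",
        "inr",
        "sodium_mmol_L",
        "potassium_mmol_L",
        "chloride_mmol_L",
    }
)

#: organ-dysfunction parameter classes and the organ system each belongs to.
#: Multiple parameters met across >=2 distinct systems at alert time means
#: multiple organ dysfunction (MODS).
ORGAN_SYSTEM_OF: dict[str, str] = {
    "sbp_drop": "cardiovascular",
    "sbp_or_map": "cardiovascular",
    "lactate": "cardiovascular",
    "bilirubin": "hepatic",
    "creatinine": "renal",
    "platelets": "hematologic",
    "inr": "hematologic",
}

PARAMETER_CLASSES: tuple[str, ...] = tuple(ORGAN_SYSTEM_OF)

#: attribution classes: the seven single-parameter classes plus MODS
ATTRIBUTION_CLASSES: tuple[str, ...] = PARAMETER_CLASSES + ("mods",)

SIRS_CRITERIA: tuple[str, ...] = ("temperature", "heart_rate", "resp_rate", "wbc")

#: microbiology specimen types that qualify toward suspected infection
#: (matched case-insensitively against the source string)
QUALIFYING_SPECIMENS: frozenset[str] = frozenset(
    {
        "blood",
        "body fluid",
        "bronchial",
        "catheter tip",
        "cerebrospinal fluid",
        "fungal",
        "ova and parasites",
        "sputum",
        "stool",
        "tissue",
        "urine",
        "wound",
    }
)

#: anti-infective agents that qualify toward suspected infection when given IV.
#: fluticasone-salmeterol is an inhaled respiratory agent but is retained in
#: the qualifying list of the surveillance definition this package implements.
QUALIFYING_ANTIBIOTICS: frozenset[str] = frozenset(
    {
        "ampicillin-sulbactam",
        "azithromycin",
        "cefepime",
        "ceftriaxone",
        "ciprofloxacin",
        "clindamycin",
        "fluconazole",
        "fluticasone-salmeterol",
        "levofloxacin",
        "meropenem",
        "piperacillin-tazobactam",
        "vancomycin",
    }
)

DISPOSITIONS: tuple[str, ...] = ("home_or_other", "expired", "hospice")
SEXES: tuple[str, ...] = ("female", "male")
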