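"""Synthetic hospital-cohort generator with per-encounter ground truth.

The generator emulates the statistical *structure* the surveillance
analysis assumes — not physiology.  Each encounter gets a stream of
timestamped vitals and labs; a chosen fraction receives a "deterioration
episode": two or more SIRS-crossing vitals followed by the planted
organ-dysfunction values, all inside their respective lookback windows, so
that the all-parameters (SEP-2-based) screen is guaranteed to flag exactly
the planted-septic encounters.  Non-septic encounters include deliberate
near-misses — SIRS alone, or a single organ abnormality alone, never both
in temporal conjunction — to exercise the conjunction logic.

Suspected infection (culture draws plus IV antibiotics) is planted with a
configurable probability among flagged encounters, so empirical PPV is a
direct handle; death/hospice is drawn from a logistic model whose odds
multiply per planted parameter class, so crude and adjusted odds ratios
are recoverable.

All randomness flows from one seed through named child streams, so the
same spec yields byte-identical tables, and toggling ``update_rate`` (the
corrected-re-result noise) leaves every other draw untouched.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .concepts import PARAMETER_CLASSES, ORGAN_SYSTEM_OF
from .io import Cohort, IngestReport

__all__ = [
    "CohortSpec",
    "GroundTruth",
    "TABLE2_INFECTION_RATES",
    "generate_cohort",
    "plant_update_noise",
    "worked_example_cohort",
]

#: per-class suspected-infection rates with the reliability gradient of the
#: reference all-parameters scenario (SBP-drop least reliable, lactate most);
#: pass as ``infected_rate_by_class`` to emulate that structure.
TABLE2_INFECTION_RATES: dict[str, float] = {
    "sbp_drop": 0.53,
    "sbp_or_map": 0.61,
    "lactate": 0.85,
    "bilirubin": 0.57,
    "creatinine": 0.50,
    "platelets": 0.67,
    "inr": 0.56,
    "mods": 0.72,
}

# planting mix across the seven singleton classes, proportional to the
# attribution mix observed under an all-parameters screen
_DEFAULT_CLASS_WEIGHTS: dict[str, float] = {
    "sbp_drop": 1083.0,
    "sbp_or_map": 719.0,
    "lactate": 759.0,
    "bilirubin": 121.0,
    "creatinine": 88.0,
    "platelets": 278.0,
    "inr": 420.0,
}

_DEFAULT_MORTALITY_OR: dict[str, float] = {
    "sbp_drop": 1.2,
    "sbp_or_map": 1.5,
    "lactate": 1.8,
    "bilirubin": 1.4,
    "creatinine": 2.0,
    "platelets": 1.3,
    "inr": 1.3,
}

_SPECIMENS = ("Blood", "Urine", "Sputum", "Wound", "Stool", "Tissue")
_IV_ABX = (
    "vancomycin",
    "piperacillin-tazobactam",
    "ceftriaxone",
    "cefepime",
    "levofloxacin",
    "meropenem",
    "azithromycin",
)

_EPOCH = pd.Timestamp("2016-01-01 00:00")


@dataclass(frozen=True)
class CohortSpec:
    """Parameters of one synthetic cohort.

    Proportions are in [0, 1]; odds multipliers are positive.  Defaults
    describe a cohort with roughly one flagged encounter in four, the
    reference-scenario alert reliability of about two thirds, and a
    class-planting mix matching the attribution mix of an all-parameters
    screen.
    """

    n_encounters: int
    seed: int = 0
    frac_septic_physiology: float = 0.26
    frac_infected_given_flagged: float = 0.64
    infected_rate_by_class: dict | None = None
    frac_infected_nonseptic: float = 0.15
    mortality_base_rate: float = 0.12
    mortality_or_per_parameter: dict = field(
        default_factory=lambda: dict(_DEFAULT_MORTALITY_OR)
    )
    obs_interval_h: float = 4.0
    update_rate: float = 0.2
    los_days_median: float = 4.0
    frac_multi_organ: float = 0.10
    class_weights: dict = field(default_factory=lambda: dict(_DEFAULT_CLASS_WEIGHTS))
    lactate_measured_rate: float = 0.75
    near_miss_frac: float = 0.30
    frac_hospice_given_died: float = 0.25

    def __post_init__(self):
        if self.n_encounters < 1:
            raise ValueError("n_encounters must be >= 1")
        for name in (
            "frac_septic_physiology",
            "frac_infected_given_flagged",
            "frac_infected_nonseptic",
            "mortality_base_rate",
            "update_rate",
            "frac_multi_organ",
            "lactate_measured_rate",
            "near_miss_frac",
            "frac_hospice_given_died",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.obs_interval_h <= 0 or self.los_days_median <= 0:
            raise ValueError("obs_interval_h and los_days_median must be positive")
        for cls, m in self.mortality_or_per_parameter.items():
            if cls not in PARAMETER_CLASSES:
                raise ValueError(f"unknown parameter class in mortality ORs: {cls!r}")
            if m <= 0:
                raise ValueError("odds multipliers must be > 0")
        for cls in self.class_weights:
            if cls not in PARAMETER_CLASSES:
                raise ValueError(f"unknown parameter class in class_weights: {cls!r}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass(frozen=True)
class GroundTruth:
    """What the generator planted for one encounter."""

    encounter_id: str
    septic_profile: bool
    planted_parameters: frozenset
    infected: bool
    died_or_hospice: bool

    def __post_init__(self):
        if bool(self.planted_parameters) != self.septic_profile:
            raise ValueError("planted_parameters nonempty iff septic_profile")


def _truth_attribution(planted: frozenset) -> str:
    systems = {ORGAN_SYSTEM_OF[p] for p in planted}
    if len(systems) >= 2:
        return "mods"
    return next(iter(planted))


def _draw_age(rng: np.random.Generator) -> int:
    # roughly median 66, IQR ~52-76, truncated to adults
    while True:
        a = rng.normal(64.0, 17.0)
        if 18.0 <= a <= 100.0:
            return int(round(a))


class _Rows:
    """Column-wise row accumulator for one output table."""

    def __init__(self, columns):
        self.columns = columns
        self.rows: list[tuple] = []

    def add(self, *row):
        self.rows.append(row)

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows, columns=self.columns)


def generate_cohort(spec: CohortSpec) -> tuple[Cohort, pd.DataFrame]:
    """Generate cohort tables and the ground-truth table.

    Returns ``(cohort, ground_truth)`` where ground_truth has columns
    encounter_id, septic_profile, planted_parameters (pipe-joined),
    truth_class (single-class or ``mods``), infected, died_or_hospice.
    Deterministic given ``spec`` (including its seed).
    """
    ss = np.random.SeedSequence(spec.seed)
    child_main, child_noise = ss.spawn(2)
    rng = np.random.default_rng(child_main)

    classes = [c for c in PARAMETER_CLASSES if spec.class_weights.get(c, 0) > 0]
    weights = np.array([spec.class_weights[c] for c in classes], dtype=float)
    weights /= weights.sum()

    enc = _Rows(["encounter_id", "age_years", "sex", "admit_time", "discharge_time",
                 "disposition", "icu_within_48h"])
    obs = _Rows(["encounter_id", "concept", "value", "event_time", "update_seq"])
    cul = _Rows(["encounter_id", "specimen", "collect_time"])
    med = _Rows(["encounter_id", "drug", "route", "admin_time"])
    truth_rows = []

    def t_at(base: pd.Timestamp, hours: float) -> pd.Timestamp:
        return (base + pd.Timedelta(hours=float(hours))).floor("min")

    for i in range(spec.n_encounters):
        eid = f"E{i:05d}"
        age = _draw_age(rng)
        sex = "female" if rng.random() < 0.48 else "male"
        admit = t_at(_EPOCH, rng.uniform(0.0, 90 * 24.0))
        los_d = float(np.clip(np.exp(np.log(spec.los_days_median) + 0.65 * rng.normal()), 1.0, 30.0))
        discharge = t_at(admit, los_d * 24.0)

        septic = rng.random() < spec.frac_septic_physiology
        planted: frozenset = frozenset()
        if septic:
            first = rng.choice(len(classes), p=weights)
            chosen = {classes[first]}
            if rng.random() < spec.frac_multi_organ:
                sys0 = ORGAN_SYSTEM_OF[classes[first]]
                other = [k for k, c in enumerate(classes) if ORGAN_SYSTEM_OF[c] != sys0]
                if other:
                    w2 = weights[other] / weights[other].sum()
                    chosen.add(classes[other[int(rng.choice(len(other), p=w2))]])
            planted = frozenset(chosen)

        near_miss = None
        if not septic and rng.random() < spec.near_miss_frac:
            near_miss = "sirs_only" if rng.random() < 0.5 else "organ_only"

        # minute flooring can land a planted value on the same instant as a
        # background reading of the same concept; keyed writes let the
        # plants (added last) win instead of creating a tied update_seq
        local: dict[tuple, float] = {}

        def add_obs(concept: str, value: float, at: pd.Timestamp):
            local[(concept, at)] = value

        high_sbp_band = "sbp_drop" in planted
        if high_sbp_band:
            sbp_base = rng.uniform(150.0, 162.0)
        elif rng.random() < 0.12:
            # mildly hypotensive band for admission acuity: NEWS SBP points
            # without ever crossing the organ thresholds (>=94 with jitter)
            sbp_base = rng.uniform(98.0, 106.0)
        else:
            sbp_base = rng.uniform(112.0, 128.0)

        # --- background vitals stream ------------------------------------
        n_vit = max(2, int(los_d * 24.0 / spec.obs_interval_h))
        steps = rng.uniform(0.7, 1.3, size=n_vit) * spec.obs_interval_h
        vit_h = np.concatenate(([0.25], 0.25 + np.cumsum(steps)))
        vit_h = vit_h[vit_h < los_d * 24.0 - 0.1]
        k = len(vit_h)
        temp = rng.uniform(36.2, 38.0, size=k)
        hr = rng.uniform(62.0, 88.0, size=k)
        rr = rng.uniform(12.0, 19.0, size=k)
        sbp_jit = 5.0 if high_sbp_band else (4.0 if sbp_base < 110.0 else 8.0)
        sbp = sbp_base + rng.uniform(-sbp_jit, sbp_jit, size=k)
        map_ = rng.uniform(72.0, 95.0, size=k)
        # SpO2 and LOC feed NEWS but no screening rule, so they are free
        # channels for admission-acuity spread
        spo2 = (
            rng.uniform(89.0, 95.0, size=k)
            if rng.random() < 0.20
            else rng.uniform(95.0, 99.0, size=k)
        )
        for j in range(k):
            tt = t_at(admit, vit_h[j])
            add_obs("temperature_C", round(float(temp[j]), 1), tt)
            add_obs("heart_rate_bpm", round(float(hr[j])), tt)
            add_obs("resp_rate_bpm", round(float(rr[j])), tt)
            add_obs("sbp_mmHg", round(float(sbp[j])), tt)
            add_obs("map_mmHg", round(float(map_[j])), tt)
            add_obs("spo2_pct", round(float(spo2[j])), tt)
        if rng.random() < 0.06:
            loc0 = float(rng.choice([1.0, 2.0, 3.0], p=[0.7, 0.2, 0.1]))
        else:
            loc0 = 0.0
        add_obs("loc_avpu", loc0, t_at(admit, 0.25))
        if septic and rng.random() < 0.5:
            # deranged vitals already at arrival for half the septic
            # encounters (they alert at the episode regardless)
            t0 = t_at(admit, 0.25)
            add_obs("heart_rate_bpm", round(float(rng.uniform(95, 120))), t0)
            add_obs("resp_rate_bpm", round(float(rng.uniform(21, 28))), t0)
            add_obs("temperature_C", round(float(rng.uniform(38.4, 39.4)), 1), t0)

        # --- background labs ---------------------------------------------
        lab_t = t_at(admit, rng.uniform(1.0, 3.0))
        add_obs("wbc_per_mm3", round(float(rng.uniform(5000, 11000))), lab_t)
        add_obs("band_pct", round(float(rng.uniform(0.0, 8.0)), 1), lab_t)
        add_obs("sodium_mmol_L", round(float(rng.uniform(134, 144)), 1), lab_t)
        add_obs("potassium_mmol_L", round(float(rng.uniform(3.6, 4.8)), 2), lab_t)
        add_obs("chloride_mmol_L", round(float(rng.uniform(99, 107)), 1), lab_t)
        add_obs("bilirubin_mg_dL", round(float(rng.uniform(0.3, 1.2)), 1), lab_t)
        add_obs("platelets_per_uL", round(float(rng.uniform(160_000, 320_000))), lab_t)
        add_obs("inr", round(float(rng.uniform(0.9, 1.3)), 2), lab_t)
        for d in range(int(los_d) + 1):
            add_obs("creatinine_mg_dL", round(float(rng.uniform(0.7, 1.3)), 2),
                    t_at(admit, 2.0 + 24.0 * d))
        lactate_measured = rng.random() < spec.lactate_measured_rate
        if lactate_measured and "lactate" not in planted and near_miss != "organ_only":
            add_obs("lactate_mmol_L", round(float(rng.uniform(0.6, 1.8)), 1), lab_t)

        # --- deterioration episode / near-miss ---------------------------
        episode_h = float(rng.uniform(0.25, 0.75)) * (los_d * 24.0 - 3.0) + 1.0
        t_sirs1 = t_at(admit, episode_h)
        t_sirs2 = t_at(admit, episode_h + 1 / 3)
        t_org = t_at(admit, episode_h + 0.75)

        def plant_sirs():
            add_obs("heart_rate_bpm", round(float(rng.uniform(105, 130))), t_sirs1)
            add_obs("temperature_C", round(float(rng.uniform(38.8, 39.6)), 1), t_sirs2)

        def plant_organ(cls: str, at: pd.Timestamp):
            if cls == "sbp_drop":
                # background band starts at 145+, so 96-102 guarantees a
                # drop >40 while staying at or above the SBP-low threshold
                add_obs("sbp_mmHg", round(float(rng.uniform(96, 102))), at)
            elif cls == "sbp_or_map":
                add_obs("map_mmHg", round(float(rng.uniform(52, 62))), at)
            elif cls == "lactate":
                add_obs("lactate_mmol_L", round(float(rng.uniform(2.6, 6.0)), 1), at)
            elif cls == "bilirubin":
                add_obs("bilirubin_mg_dL", round(float(rng.uniform(2.5, 6.0)), 1), at)
            elif cls == "creatinine":
                add_obs("creatinine_mg_dL", round(float(rng.uniform(2.4, 4.0)), 2), at)
            elif cls == "platelets":
                add_obs("platelets_per_uL", round(float(rng.uniform(40_000, 85_000))), at)
            elif cls == "inr":
                add_obs("inr", round(float(rng.uniform(1.8, 3.2)), 2), at)

        if septic:
            plant_sirs()
            for cls in sorted(planted):
                plant_organ(cls, t_org)
        elif near_miss == "sirs_only":
            plant_sirs()
        elif near_miss == "organ_only":
            plant_organ(str(rng.choice(["lactate", "bilirubin", "platelets"])), t_org)

        # --- infection ----------------------------------------------------
        if septic:
            if spec.infected_rate_by_class is not None:
                p_inf = float(spec.infected_rate_by_class[_truth_attribution(planted)])
            else:
                p_inf = spec.frac_infected_given_flagged
        else:
            p_inf = spec.frac_infected_nonseptic
        infected = rng.random() < p_inf
        if infected:
            cul.add(eid, str(rng.choice(_SPECIMENS)), t_at(admit, rng.uniform(0.5, los_d * 20.0)))
            for _ in range(int(rng.integers(1, 3))):
                med.add(eid, str(rng.choice(_IV_ABX)), "IV",
                        t_at(admit, rng.uniform(0.5, los_d * 20.0)))
        else:
            u = rng.random()
            if u < 0.20:  # culture without IV antibiotics
                cul.add(eid, str(rng.choice(_SPECIMENS)), t_at(admit, rng.uniform(0.5, los_d * 20.0)))
            elif u < 0.35:  # oral antibiotic only: route fails to qualify
                med.add(eid, str(rng.choice(_IV_ABX)), "PO",
                        t_at(admit, rng.uniform(0.5, los_d * 20.0)))

        # --- mortality ------------------------------------------------
        odds = spec.mortality_base_rate / (1.0 - spec.mortality_base_rate)
        for cls in planted:
            odds *= spec.mortality_or_per_parameter.get(cls, 1.0)
        died = rng.random() < odds / (1.0 + odds)
        if died:
            disposition = "hospice" if rng.random() < spec.frac_hospice_given_died else "expired"
        else:
            disposition = "home_or_other"
        icu = rng.random() < (0.45 if septic else 0.10)

        for (concept, at), value in local.items():
            obs.add(eid, concept, value, at, 0)

        enc.add(eid, age, sex, admit, discharge, disposition, icu)
        truth_rows.append(
            {
                "encounter_id": eid,
                "septic_profile": septic,
                "planted_parameters": "|".join(sorted(planted)),
                "truth_class": _truth_attribution(planted) if septic else "",
                "infected": infected,
                "died_or_hospice": died,
            }
        )

    observations = obs.frame()
    observations = plant_update_noise(observations, spec, np.random.default_rng(child_noise))
    cohort = Cohort(
        encounters=enc.frame(),
        observations=observations,
        cultures=cul.frame(),
        med_admins=med.frame(),
        report=IngestReport(),
    )
    return cohort, pd.DataFrame(truth_rows)


# decoy ranges for the superseded (update_seq 0) version of a corrected lab
_NORMAL_RANGE = {
    "wbc_per_mm3": (5000, 11000),
    "band_pct": (0.0, 8.0),
    "lactate_mmol_L": (0.6, 1.8),
    "bilirubin_mg_dL": (0.3, 1.2),
    "creatinine_mg_dL": (0.7, 1.3),
    "platelets_per_uL": (160_000, 320_000),
    "inr": (0.9, 1.3),
    "sodium_mmol_L": (134, 144),
    "potassium_mmol_L": (3.6, 4.8),
    "chloride_mmol_L": (99, 107),
}
_ABNORMAL_RANGE = {
    "wbc_per_mm3": (14_000, 22_000),
    "band_pct": (12.0, 25.0),
    "lactate_mmol_L": (2.6, 6.0),
    "bilirubin_mg_dL": (2.5, 6.0),
    "creatinine_mg_dL": (2.4, 4.0),
    "platelets_per_uL": (40_000, 85_000),
    "inr": (1.8, 3.2),
    "sodium_mmol_L": (124, 131),
    "potassium_mmol_L": (5.5, 6.5),
    "chloride_mmol_L": (88, 95),
}


def _is_abnormal(concept: str, v: float) -> bool:
    lo, hi = _NORMAL_RANGE[concept]
    return not (lo <= v <= hi)


def plant_update_noise(
    observations: pd.DataFrame, spec: CohortSpec, rng: np.random.Generator | None = None
) -> pd.DataFrame:
    """Simulate corrected lab re-results.

    For a ``spec.update_rate`` fraction of lab events, the original
    (update_seq 0) value is replaced by a decoy drawn from the opposite
    normal/abnormal range and the true value is appended as the corrected
    version (update_seq 1) — so only update-resolved pipelines see data
    consistent with the ground truth.  ``update_rate = 0`` returns the
    input unchanged.
    """
    if spec.update_rate == 0:
        return observations
    if rng is None:
        rng = np.random.default_rng(np.random.SeedSequence(spec.seed).spawn(2)[1])
    df = observations.copy()
    is_lab = df["concept"].isin(_NORMAL_RANGE).to_numpy()
    pick = is_lab & (rng.random(len(df)) < spec.update_rate)
    idx = np.flatnonzero(pick)
    corrected = []
    values = df["value"].to_numpy(dtype=float).copy()
    for j in idx:
        concept = df.iat[j, df.columns.get_loc("concept")]
        true_v = values[j]
        lo, hi = (_NORMAL_RANGE if _is_abnormal(concept, true_v) else _ABNORMAL_RANGE)[concept]
        values[j] = round(float(rng.uniform(lo, hi)), 2)
        corrected.append(
            (
                df.iat[j, df.columns.get_loc("encounter_id")],
                concept,
                true_v,
                df.iat[j, df.columns.get_loc("event_time")],
                int(df.iat[j, df.columns.get_loc("update_seq")]) + 1,
            )
        )
    df["value"] = values
    add = pd.DataFrame(corrected, columns=df.columns.tolist())
    return pd.concat([df, add], ignore_index=True)


# ---------------------------------------------------------------------------
# hand-authored worked example

def worked_example_cohort() -> tuple[Cohort, pd.DataFrame]:
    """A fixed 12-encounter cohort exercising every rule once.

    One encounter per singleton parameter class (W01..W07), one multi-system
    (MODS) case (W08), a SIRS-only near-miss (W09), an organ-only near-miss
    (W10) and two fully normal controls (W11, W12).  Constants are
    hand-authored and stable; no randomness.
    """
    admit = pd.Timestamp("2016-03-01 08:00")
    disch = admit + pd.Timedelta(days=4)

    enc = _Rows(["encounter_id", "age_years", "sex", "admit_time", "discharge_time",
                 "disposition", "icu_within_48h"])
    obs = _Rows(["encounter_id", "concept", "value", "event_time", "update_seq"])
    cul = _Rows(["encounter_id", "specimen", "collect_time"])
    med = _Rows(["encounter_id", "drug", "route", "admin_time"])

    def t(h: float) -> pd.Timestamp:
        return (admit + pd.Timedelta(hours=h)).floor("min")

    def base_obs(eid: str, sbp0: float = 120.0):
        # admission vitals (NEWS inputs) and safe background values
        obs.add(eid, "resp_rate_bpm", 15, t(0.5), 0)
        obs.add(eid, "spo2_pct", 97, t(0.5), 0)
        obs.add(eid, "temperature_C", 37.0, t(0.5), 0)
        obs.add(eid, "sbp_mmHg", sbp0, t(0.5), 0)
        obs.add(eid, "heart_rate_bpm", 74, t(0.5), 0)
        obs.add(eid, "loc_avpu", 0, t(0.5), 0)
        obs.add(eid, "map_mmHg", 85, t(0.5), 0)
        obs.add(eid, "wbc_per_mm3", 8000, t(2), 0)
        obs.add(eid, "band_pct", 3.0, t(2), 0)
        obs.add(eid, "creatinine_mg_dL", 1.0, t(2), 0)
        obs.add(eid, "bilirubin_mg_dL", 0.8, t(2), 0)
        obs.add(eid, "platelets_per_uL", 240_000, t(2), 0)
        obs.add(eid, "inr", 1.1, t(2), 0)
        obs.add(eid, "sodium_mmol_L", 139.0, t(2), 0)
        obs.add(eid, "potassium_mmol_L", 4.2, t(2), 0)
        obs.add(eid, "chloride_mmol_L", 103.0, t(2), 0)
        obs.add(eid, "sbp_mmHg", sbp0 - 2, t(6), 0)

    def sirs(eid: str):
        obs.add(eid, "heart_rate_bpm", 114, t(10), 0)
        obs.add(eid, "temperature_C", 39.0, t(10.3), 0)

    septic_cases = {
        "W01": ("sbp_drop", 152.0),
        "W02": ("sbp_or_map", 120.0),
        "W03": ("lactate", 120.0),
        "W04": ("bilirubin", 120.0),
        "W05": ("creatinine", 120.0),
        "W06": ("platelets", 120.0),
        "W07": ("inr", 120.0),
    }
    plants = {
        "sbp_drop": ("sbp_mmHg", 106),
        "sbp_or_map": ("map_mmHg", 58),
        "lactate": ("lactate_mmol_L", 3.5),
        "bilirubin": ("bilirubin_mg_dL", 3.2),
        "creatinine": ("creatinine_mg_dL", 2.6),
        "platelets": ("platelets_per_uL", 62_000),
        "inr": ("inr", 2.4),
    }
    ages = {"W01": 71, "W02": 64, "W03": 58, "W04": 66, "W05": 80, "W06": 55,
            "W07": 62, "W08": 77, "W09": 45, "W10": 52, "W11": 39, "W12": 68}
    sexes = {"W01": "male", "W02": "female", "W03": "female", "W04": "male",
             "W05": "female", "W06": "male", "W07": "male", "W08": "female",
             "W09": "male", "W10": "female", "W11": "female", "W12": "male"}
    dispositions = {e: "home_or_other" for e in ages}
    dispositions["W08"] = "expired"
    dispositions["W05"] = "hospice"

    truth_rows = []
    for eid, (cls, sbp0) in septic_cases.items():
        base_obs(eid, sbp0)
        sirs(eid)
        concept, value = plants[cls]
        obs.add(eid, concept, value, t(11), 0)

    # W08: lactate + bilirubin at the same instant -> cardiovascular +
    # hepatic -> MODS under every scenario (both parameters always enabled)
    base_obs("W08")
    sirs("W08")
    obs.add("W08", "lactate_mmol_L", 3.0, t(11), 0)
    obs.add("W08", "bilirubin_mg_dL", 3.0, t(11), 0)

    base_obs("W09")  # SIRS alone, every organ value safe
    sirs("W09")
    base_obs("W10")  # one organ abnormality, vitals never septic
    obs.add("W10", "lactate_mmol_L", 3.1, t(11), 0)
    base_obs("W11")
    base_obs("W12")

    infections = {
        "W01": ("Blood", "vancomycin", "IV"),
        "W02": ("Urine", "ceftriaxone", "IV"),
        "W03": ("Sputum", "levofloxacin", "IV"),
        "W05": ("Blood", "meropenem", "IV"),
        "W08": ("Blood", "piperacillin-tazobactam", "IV"),
        "W10": ("Urine", "azithromycin", "IV"),
    }
    for eid, (spec_, drug, route) in infections.items():
        cul.add(eid, spec_, t(9))
        med.add(eid, drug, route, t(12))
    cul.add("W06", "Blood", t(9))               # culture but no antibiotic
    cul.add("W07", "Blood", t(9))
    med.add("W07", "ciprofloxacin", "PO", t(12))  # oral route: not qualifying

    for eid in ages:
        enc.add(eid, ages[eid], sexes[eid], admit, disch, dispositions[eid],
                eid in ("W05", "W08"))
        septic = eid in septic_cases or eid == "W08"
        planted = ""
        truth_class = ""
        if eid in septic_cases:
            planted = septic_cases[eid][0]
            truth_class = planted
        elif eid == "W08":
            planted = "bilirubin|lactate"
            truth_class = "mods"
        truth_rows.append(
            {
                "encounter_id": eid,
                "septic_profile": septic,
                "planted_parameters": planted,
                "truth_class": truth_class,
                "infected": eid in infections,
                "died_or_hospice": dispositions[eid] != "home_or_other",
            }
        )

    cohort = Cohort(enc.frame(), obs.frame(), cul.frame(), med.frame(), IngestReport())
    return cohort, pd.DataFrame(truth_rows)
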