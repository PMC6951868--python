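"""Suspected-infection labeling and the mortality outcome.

Suspected infection requires both elements during the encounter, with no
temporal-ordering constraint between them: at least one microbiology
culture drawn from a qualifying specimen type AND at least one qualifying
anti-infective administered intravenously.  Specimen and drug strings are
matched case-insensitively against closed lists; anything else does not
qualify and is logged.

Mortality is in-hospital death or referral to hospice at discharge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .concepts import QUALIFYING_ANTIBIOTICS, QUALIFYING_SPECIMENS
from .events import EncounterRecord
from .io import Cohort

log = logging.getLogger(__name__)

__all__ = [
    "InfectionLabel",
    "label_suspected_infection",
    "mortality_outcome",
    "label_cohort",
]


@dataclass(frozen=True)
class InfectionLabel:
    encounter_id: str
    suspected_infection: bool
    first_culture_time: pd.Timestamp | None = None
    first_abx_time: pd.Timestamp | None = None
    lactate_measured: bool = False

    def __post_init__(self):
        if self.suspected_infection and (
            self.first_culture_time is None or self.first_abx_time is None
        ):
            raise ValueError("suspected infection requires both culture and antibiotic times")


def _norm(s) -> str:
    return str(s).strip().lower()


def label_suspected_infection(
    cultures: pd.DataFrame,
    med_admins: pd.DataFrame,
    encounter: EncounterRecord,
    lactate_measured: bool = False,
) -> InfectionLabel:
    """Label one encounter from its culture draws and medication administrations.

    ``cultures``/``med_admins`` are that encounter's rows of the cohort
    tables (columns specimen/collect_time and drug/route/admin_time).
    """
    qual_cult = []
    for row in cultures.itertuples(index=False):
        if _norm(row.specimen) in QUALIFYING_SPECIMENS:
            qual_cult.append(pd.Timestamp(row.collect_time))
        else:
            log.info("non-qualifying specimen %r (%s)", row.specimen, encounter.encounter_id)

    qual_abx = []
    for row in med_admins.itertuples(index=False):
        if _norm(row.route) != "iv":
            continue
        if _norm(row.drug) in QUALIFYING_ANTIBIOTICS:
            qual_abx.append(pd.Timestamp(row.admin_time))
        else:
            log.info("non-qualifying IV drug %r (%s)", row.drug, encounter.encounter_id)

    suspected = bool(qual_cult) and bool(qual_abx)
    return InfectionLabel(
        encounter_id=encounter.encounter_id,
        suspected_infection=suspected,
        first_culture_time=min(qual_cult) if qual_cult else None,
        first_abx_time=min(qual_abx) if qual_abx else None,
        lactate_measured=bool(lactate_measured),
    )


def mortality_outcome(encounter: EncounterRecord) -> bool:
    """True iff the encounter ended in in-hospital death or hospice referral."""
    return encounter.disposition in ("expired", "hospice")


def label_cohort(cohort: Cohort) -> pd.DataFrame:
    """Infection and mortality labels for every encounter.

    Columns: encounter_id, suspected_infection, first_culture_time,
    first_abx_time, lactate_measured, died_or_hospice.
    """
    cult_by = dict(tuple(cohort.cultures.groupby("encounter_id", sort=False)))
    med_by = dict(tuple(cohort.med_admins.groupby("encounter_id", sort=False)))
    obs = cohort.observations
    lact_ids = set(obs.loc[obs["concept"] == "lactate_mmol_L", "encounter_id"])

    empty_c = cohort.cultures.iloc[0:0]
    empty_m = cohort.med_admins.iloc[0:0]
    rows = []
    for rec in cohort.encounters.itertuples(index=False):
        enc = EncounterRecord(
            rec.encounter_id, int(rec.age_years), rec.sex, rec.admit_time,
            rec.discharge_time, rec.disposition, bool(rec.icu_within_48h),
        )
        lab = label_suspected_infection(
            cult_by.get(rec.encounter_id, empty_c),
            med_by.get(rec.encounter_id, empty_m),
            enc,
            lactate_measured=rec.encounter_id in lact_ids,
        )
        rows.append(
            {
                "encounter_id": lab.encounter_id,
                "suspected_infection": lab.suspected_infection,
                "first_culture_time": lab.first_culture_time,
                "first_abx_time": lab.first_abx_time,
                "lactate_measured": lab.lactate_measured,
                "died_or_hospice": mortality_outcome(enc),
            }
        )
    return pd.DataFrame(rows)
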