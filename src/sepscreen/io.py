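"""Cohort ingest and egress.

A cohort is four tables sharing the encounter identifier as primary key:

* ``encounters``: encounter_id, age_years, sex, admit_time, discharge_time,
  disposition, icu_within_48h
* ``observations``: encounter_id, concept, value, event_time, update_seq
* ``cultures``: encounter_id, specimen, collect_time
* ``med_admins``: encounter_id, drug, route, admin_time

Ingest is strict about structure (a missing column is a hard error naming
the column) and forgiving about rows: a row with an unparseable timestamp,
an implausible value or an unknown enum is rejected, counted and logged,
never silently repaired.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

from .concepts import CONCEPTS, DISPOSITIONS, PLAUSIBILITY_BOUNDS, SEXES

log = logging.getLogger(__name__)

TABLE_COLUMNS: dict[str, list[str]] = {
    "encounters": [
        "encounter_id",
        "age_years",
        "sex",
        "admit_time",
        "discharge_time",
        "disposition",
        "icu_within_48h",
    ],
    "observations": ["encounter_id", "concept", "value", "event_time", "update_seq"],
    "cultures": ["encounter_id", "specimen", "collect_time"],
    "med_admins": ["encounter_id", "drug", "route", "admin_time"],
}

_TIME_COLS = {
    "encounters": ["admit_time", "discharge_time"],
    "observations": ["event_time"],
    "cultures": ["collect_time"],
    "med_admins": ["admin_time"],
}


@dataclass
class IngestReport:
    """Per-table accounting of what ingest accepted and why rows fell out."""

    rows_read: dict[str, int] = field(default_factory=dict)
    rows_rejected: dict[str, int] = field(default_factory=dict)
    reasons: dict[str, dict[str, int]] = field(default_factory=dict)

    def reject(self, table: str, reason: str, n: int) -> None:
        if n == 0:
            return
        self.rows_rejected[table] = self.rows_rejected.get(table, 0) + int(n)
        self.reasons.setdefault(table, {})
        self.reasons[table][reason] = self.reasons[table].get(reason, 0) + int(n)
        log.warning("ingest %s: rejected %d row(s): %s", table, n, reason)


@dataclass
class Cohort:
    """In-memory cohort: the four validated tables plus the ingest report."""

    encounters: pd.DataFrame
    observations: pd.DataFrame
    cultures: pd.DataFrame
    med_admins: pd.DataFrame
    report: IngestReport = field(default_factory=IngestReport)

    @property
    def encounter_ids(self) -> list[str]:
        return self.encounters["encounter_id"].tolist()

    def __len__(self) -> int:
        return len(self.encounters)


def _drop(df: pd.DataFrame, bad: pd.Series, table: str, reason: str, report: IngestReport):
    n = int(bad.sum())
    if n:
        report.reject(table, reason, n)
    return df.loc[~bad]


def _read_table(path: Path, table: str, dialect: str) -> pd.DataFrame:
    if dialect == "csv":
        df = pd.read_csv(path, dtype={"encounter_id": str})
    elif dialect == "parquet":
        df = pd.read_parquet(path)
        df["encounter_id"] = df["encounter_id"].astype(str)
    else:
        raise ValueError(f"unknown dialect: {dialect!r} (expected 'csv' or 'parquet')")
    for col in TABLE_COLUMNS[table]:
        if col not in df.columns:
            raise ValueError(f"table {table!r} is missing required column {col!r}")
    return df.loc[:, TABLE_COLUMNS[table]]


def _parse_times(df, table, report):
    for col in _TIME_COLS[table]:
        parsed = pd.to_datetime(df[col], errors="coerce")
        df = df.assign(**{col: parsed.dt.floor("min")})
        df = _drop(df, df[col].isna(), table, f"unparseable timestamp in {col}", report)
    return df


def _validate_encounters(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    t = "encounters"
    df = _parse_times(df, t, report)
    age = pd.to_numeric(df["age_years"], errors="coerce")
    df = df.assign(age_years=age)
    df = _drop(df, df["age_years"].isna() | (df["age_years"] < 18), t, "age missing or < 18", report)
    df = df.assign(age_years=df["age_years"].astype(int))
    df = _drop(df, ~df["sex"].isin(SEXES), t, "unknown sex", report)
    df = _drop(df, ~df["disposition"].isin(DISPOSITIONS), t, "unknown disposition", report)
    df = _drop(df, ~(df["discharge_time"] > df["admit_time"]), t, "discharge not after admit", report)
    df = _drop(df, df["encounter_id"].duplicated(keep=False), t, "duplicate encounter_id", report)
    icu = df["icu_within_48h"]
    if icu.dtype != bool:
        df = df.assign(
            icu_within_48h=icu.astype(str).str.strip().str.lower().isin(("true", "1", "yes"))
        )
    return df.reset_index(drop=True)


def _validate_observations(df: pd.DataFrame, report: IngestReport) -> pd.DataFrame:
    t = "observations"
    df = _parse_times(df, t, report)
    df = _drop(df, ~df["concept"].isin(CONCEPTS), t, "unknown concept", report)
    val = pd.to_numeric(df["value"], errors="coerce")
    df = df.assign(value=val)
    df = _drop(df, ~np.isfinite(df["value"].to_numpy(dtype=float, na_value=np.nan)), t,
               "non-finite value", report)
    lo = df["concept"].map({c: b[0] for c, b in PLAUSIBILITY_BOUNDS.items()})
    hi = df["concept"].map({c: b[1] for c, b in PLAUSIBILITY_BOUNDS.items()})
    df = _drop(df, (df["value"] < lo) | (df["value"] > hi), t,
               "value outside plausibility bounds", report)
    seq = pd.to_numeric(df["update_seq"], errors="coerce")
    df = df.assign(update_seq=seq)
    df = _drop(df, df["update_seq"].isna() | (df["update_seq"] < 0), t,
               "invalid update_seq", report)
    df = df.assign(update_seq=df["update_seq"].astype(int))
    dup = df.duplicated(["encounter_id", "concept", "event_time", "update_seq"], keep=False)
    df = _drop(df, dup, t, "tied update_seq for one clinical event", report)
    return df.reset_index(drop=True)


def read_cohort(source, dialect: str = "csv") -> Cohort:
    """Read and validate the four cohort tables.

    Parameters
    ----------
    source
        Directory containing ``encounters.<ext>`` etc., or a mapping
        table-name -> path.
    dialect
        ``"csv"`` (delimited text) or ``"parquet"`` (columnar binary).
    """
    ext = {"csv": "csv", "parquet": "parquet"}.get(dialect)
    if ext is None:
        raise ValueError(f"unknown dialect: {dialect!r}")
    if isinstance(source, Mapping):
        paths = {t: Path(source[t]) for t in TABLE_COLUMNS}
    else:
        root = Path(source)
        paths = {t: root / f"{t}.{ext}" for t in TABLE_COLUMNS}

    report = IngestReport()
    raw = {}
    for table, path in paths.items():
        raw[table] = _read_table(path, table, dialect)
        report.rows_read[table] = len(raw[table])

    enc = _validate_encounters(raw["encounters"], report)
    obs = _validate_observations(raw["observations"], report)
    cul = _parse_times(raw["cultures"], "cultures", report).reset_index(drop=True)
    med = _parse_times(raw["med_admins"], "med_admins", report).reset_index(drop=True)

    known = set(enc["encounter_id"])
    for name, df in (("observations", obs), ("cultures", cul), ("med_admins", med)):
        orphan = ~df["encounter_id"].astype(str).isin(known)
        df.drop(index=df.index[orphan], inplace=True)
        if orphan.any():
            report.reject(name, "encounter_id not in encounters table", int(orphan.sum()))

    for table in TABLE_COLUMNS:
        log.info(
            "ingest %s: %d read, %d rejected",
            table, report.rows_read.get(table, 0), report.rows_rejected.get(table, 0),
        )
    return Cohort(enc, obs.reset_index(drop=True), cul.reset_index(drop=True),
                  med.reset_index(drop=True), report)


def write_cohort(cohort: Cohort, out_dir, dialect: str = "csv") -> dict[str, Path]:
    """Write the four tables under ``out_dir``; returns table -> path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tables = {
        "encounters": cohort.encounters,
        "observations": cohort.observations,
        "cultures": cohort.cultures,
        "med_admins": cohort.med_admins,
    }
    written: dict[str, Path] = {}
    for name, df in tables.items():
        if dialect == "csv":
            path = out / f"{name}.csv"
            df.to_csv(path, index=False)
        elif dialect == "parquet":
            path = out / f"{name}.parquet"
            df.to_parquet(path, index=False)
        else:
            raise ValueError(f"unknown dialect: {dialect!r}")
        written[name] = path
    return written
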