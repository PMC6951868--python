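"""Domain types and the temporally ordered event store.

Hospital data warehouses deliver several versions of the same clinical
result (a preliminary lab value, then one or more corrections).  Every
version shares the clinical event's identity — here keyed by
``(concept, event_time)`` — and carries a monotone ``update_seq`` counter;
only the highest-counter version is clinically current.  All screening
logic consumes :class:`ResolvedTimeline`, in which each clinical event
appears exactly once, after :func:`resolve_timeline` has applied that rule.

Timestamps are timezone-naive and normalized to minute resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .concepts import CONCEPTS, PLAUSIBILITY_BOUNDS

__all__ = [
    "ObservationEvent",
    "EncounterRecord",
    "ResolvedTimeline",
    "resolve_timeline",
    "window_values",
]


def _norm_time(t) -> pd.Timestamp:
    ts = pd.Timestamp(t)
    if ts.tzinfo is not None:
        raise ValueError("timestamps must be timezone-naive")
    return ts.floor("min")


@dataclass(frozen=True)
class ObservationEvent:
    """One timestamped clinical measurement, the atom of the event store.

    ``update_seq`` disambiguates corrected re-results of the same clinical
    event: among events sharing ``(encounter_id, concept, event_time)`` the
    highest ``update_seq`` is the current value.
    """

    encounter_id: str
    concept: str
    value: float
    event_time: pd.Timestamp
    update_seq: int = 0

    def __post_init__(self):
        if self.concept not in CONCEPTS:
            raise ValueError(f"unknown concept: {self.concept!r}")
        if not np.isfinite(self.value):
            raise ValueError(f"non-finite value for {self.concept}")
        lo, hi = PLAUSIBILITY_BOUNDS[self.concept]
        if not (lo <= self.value <= hi):
            raise ValueError(
                f"{self.concept}={self.value} outside plausibility bounds [{lo}, {hi}]"
            )
        if self.update_seq < 0:
            raise ValueError("update_seq must be non-negative")
        object.__setattr__(self, "event_time", _norm_time(self.event_time))


@dataclass(frozen=True)
class EncounterRecord:
    """One adult hospitalization with demographics and disposition."""

    encounter_id: str
    age_years: int
    sex: str
    admit_time: pd.Timestamp
    discharge_time: pd.Timestamp
    disposition: str
    icu_within_48h: bool = False

    def __post_init__(self):
        object.__setattr__(self, "admit_time", _norm_time(self.admit_time))
        object.__setattr__(self, "discharge_time", _norm_time(self.discharge_time))
        if self.age_years < 18:
            raise ValueError("study population is adults (age_years >= 18)")
        if self.sex not in ("female", "male"):
            raise ValueError(f"unknown sex: {self.sex!r}")
        if self.disposition not in ("home_or_other", "expired", "hospice"):
            raise ValueError(f"unknown disposition: {self.disposition!r}")
        if not self.discharge_time > self.admit_time:
            raise ValueError("discharge_time must be after admit_time")


@dataclass
class ResolvedTimeline:
    """Per-concept time series with each clinical event represented once.

    ``series`` maps concept -> (times, values) where ``times`` is an
    ascending ``datetime64[ns]`` array and each ``(concept, event_time)``
    pair carries the value of its highest-``update_seq`` version.
    """

    encounter_id: str
    series: dict[str, tuple[np.ndarray, np.ndarray]] = field(default_factory=dict)

    def get(self, concept: str) -> tuple[np.ndarray, np.ndarray]:
        """(times, values) for ``concept``; empty arrays when never observed."""
        if concept not in CONCEPTS:
            raise KeyError(f"unknown concept: {concept!r}")
        if concept in self.series:
            return self.series[concept]
        return (np.array([], dtype="datetime64[ns]"), np.array([], dtype=float))

    @property
    def concepts(self) -> frozenset[str]:
        return frozenset(self.series)

    @property
    def event_times(self) -> np.ndarray:
        """Sorted unique times across all concepts (screening cadence)."""
        if not self.series:
            return np.array([], dtype="datetime64[ns]")
        return np.unique(np.concatenate([t for t, _ in self.series.values()]))

    def to_events(self) -> list[ObservationEvent]:
        """Re-wrap as update_seq=0 events (resolution is idempotent)."""
        out = []
        for concept, (times, values) in sorted(self.series.items()):
            for t, v in zip(times, values):
                out.append(
                    ObservationEvent(self.encounter_id, concept, float(v), pd.Timestamp(t), 0)
                )
        return out


def resolve_timeline(events) -> ResolvedTimeline:
    """Collapse versioned events of one encounter into a resolved timeline.

    For every ``(concept, event_time)`` group only the version with the
    maximal ``update_seq`` survives; output is sorted ascending by time
    within each concept and is invariant to input order.

    Parameters
    ----------
    events
        Iterable of :class:`ObservationEvent`, or a DataFrame with columns
        ``encounter_id, concept, value, event_time, update_seq``; all rows
        must share one encounter_id.

    Raises
    ------
    ValueError
        On mixed encounter_ids, or on two versions of one clinical event
        carrying the same ``update_seq`` (the counter exists precisely to
        disambiguate, so a tie is a data error).
    """
    if isinstance(events, pd.DataFrame):
        df = events.loc[:, ["encounter_id", "concept", "value", "event_time", "update_seq"]].copy()
        df["event_time"] = pd.to_datetime(df["event_time"]).dt.floor("min")
    else:
        events = list(events)
        df = pd.DataFrame(
            {
                "encounter_id": [e.encounter_id for e in events],
                "concept": [e.concept for e in events],
                "value": [e.value for e in events],
                "event_time": [e.event_time for e in events],
                "update_seq": [e.update_seq for e in events],
            }
        )
    if df.empty:
        return ResolvedTimeline(encounter_id="")

    ids = df["encounter_id"].unique()
    if len(ids) > 1:
        raise ValueError(f"events from multiple encounters: {sorted(map(str, ids))}")

    if df.duplicated(["concept", "event_time", "update_seq"]).any():
        dup = df[df.duplicated(["concept", "event_time", "update_seq"], keep=False)]
        key = dup.iloc[0]
        raise ValueError(
            "tied update_seq for one clinical event: "
            f"({key['concept']}, {key['event_time']}, seq {key['update_seq']})"
        )

    resolved = (
        df.sort_values(["concept", "event_time", "update_seq"])
        .groupby(["concept", "event_time"], as_index=False, sort=True)
        .last()
    )
    series: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for concept, grp in resolved.groupby("concept", sort=True):
        series[str(concept)] = (
            grp["event_time"].to_numpy(dtype="datetime64[ns]"),
            grp["value"].to_numpy(dtype=float),
        )
    return ResolvedTimeline(encounter_id=str(ids[0]), series=series)


def window_values(
    timeline: ResolvedTimeline,
    concept: str,
    at,
    lookback_h: float,
) -> list[tuple[pd.Timestamp, float]]:
    """Values of ``concept`` in the half-open window ``(at - lookback_h, at]``.

    The reading at the evaluation instant counts; a reading exactly
    ``lookback_h`` hours old does not.  Ascending by time; empty when none.
    """
    if lookback_h <= 0:
        raise ValueError("lookback_h must be positive")
    times, values = timeline.get(concept)  # raises KeyError on unknown concept
    at = _norm_time(at)
    lo = np.searchsorted(times, np.datetime64(at - pd.Timedelta(hours=lookback_h)), side="right")
    hi = np.searchsorted(times, np.datetime64(at), side="right")
    return [(pd.Timestamp(t), float(v)) for t, v in zip(times[lo:hi], values[lo:hi])]
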