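"""Stay-level data model, interchange IO, cohort filters and ventilation states.

A :class:`PatientStay` carries the timestamped dynamic measurements, the
static demographics and the invasive-mechanical-ventilation (IMV) on/off
intervals of one ICU stay.  Cohort inclusion mirrors the hypoxemic-ICU
setting: adults (age > 15), length of stay between 12 h and 10 days, and at
least one hypoxemic measurement (PaO2 < 60 mmHg or SpO2 < 90 %) at any time
during the stay.

Hours are half-open bins ``[h, h+1)``, 0-based from admission.  The per-hour
ventilation state takes one of four values: ONSET (off -> on transition),
STAY_ON, WEAN (on -> off), STAY_OFF.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .registry import FeatureRegistry, default_registry

logger = logging.getLogger(__name__)

EVENT_COLUMNS = ["feature_id", "time", "value"]


class SchemaError(ValueError):
    """An interchange file does not conform to the documented schema."""


class RegistryError(ValueError):
    """Events reference feature ids absent from the feature registry."""


class VentState(enum.IntEnum):
    STAY_OFF = 0
    ONSET = 1
    STAY_ON = 2
    WEAN = 3


def normalize_intervals(intervals: Iterable[tuple[float, float]]) -> np.ndarray:
    """Sort and merge overlapping or touching ``[start, end)`` intervals."""
    ivs = sorted((float(s), float(e)) for s, e in intervals)
    for s, e in ivs:
        if not s < e:
            raise ValueError(f"degenerate ventilation interval [{s}, {e})")
    merged: list[list[float]] = []
    for s, e in ivs:
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return np.asarray(merged, dtype=float).reshape(-1, 2)


@dataclass
class PatientStay:
    """One ICU stay: events, statics and IMV intervals.

    ``events`` is a DataFrame with columns (feature_id, time, value), time in
    hours since admission; ``vent`` an (n, 2) array of normalized half-open
    IMV intervals.
    """

    stay_id: int
    los_hours: float
    age: float | None = None
    sex: str | None = None  # 'male' | 'female'
    weight: float | None = None
    height: float | None = None
    events: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=EVENT_COLUMNS)
    )
    vent: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    def __post_init__(self) -> None:
        self.vent = normalize_intervals(map(tuple, np.asarray(self.vent).reshape(-1, 2)))
        ev = self.events
        if list(ev.columns[:3]) != EVENT_COLUMNS:
            missing = [c for c in EVENT_COLUMNS if c not in ev.columns]
            if missing:
                raise SchemaError(f"events missing required column(s): {missing}")
            ev = ev[EVENT_COLUMNS]
        ev = ev.sort_values(["time", "feature_id"], kind="stable").reset_index(drop=True)
        self.events = ev

    @property
    def n_hours(self) -> int:
        return int(math.floor(self.los_hours))

    def validate(self, registry: FeatureRegistry | None = None) -> None:
        ev = self.events
        if len(ev):
            t = ev["time"].to_numpy(float)
            v = ev["value"].to_numpy(float)
            if (t < 0).any():
                raise ValueError(f"stay {self.stay_id}: negative event time")
            if (t > self.los_hours).any():
                raise ValueError(f"stay {self.stay_id}: event after discharge")
            if not np.isfinite(v).all():
                raise ValueError(f"stay {self.stay_id}: non-finite event value")
        if len(self.vent):
            if self.vent[0, 0] < 0 or self.vent[-1, 1] > self.los_hours + 1e-9:
                raise ValueError(
                    f"stay {self.stay_id}: ventilation interval outside [0, LOS]"
                )
        if registry is not None and len(ev):
            unknown = sorted(set(ev["feature_id"]) - set(registry))
            if unknown:
                raise RegistryError(
                    f"stay {self.stay_id}: unknown feature id(s) {unknown}"
                )


@dataclass(frozen=True)
class CohortSpec:
    """Inclusion criteria for the hypoxemic cohort."""

    age_min: float = 15.0  # exclusive
    los_min: float = 12.0  # inclusive
    los_max: float = 240.0  # inclusive (10 days)
    pao2_hypox_mmHg: float = 60.0  # hypoxemic strictly below
    spo2_hypox_pct: float = 90.0  # hypoxemic strictly below

    def __post_init__(self) -> None:
        if not self.los_min < self.los_max:
            raise ValueError("los_min must be < los_max")
        if min(self.pao2_hypox_mmHg, self.spo2_hypox_pct) <= 0:
            raise ValueError("hypoxemia thresholds must be positive")


# --------------------------------------------------------------------- IO

def _require_columns(df: pd.DataFrame, cols: Sequence[str], fname: str) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise SchemaError(f"{fname}: missing required column(s) {missing}")


def load_stays(
    path: str | Path,
    format: str = "csv-bundle",
    registry: FeatureRegistry | None = None,
) -> list[PatientStay]:
    """Read a cohort from ``csv-bundle`` (stays/events/vent CSVs) or
    ``hourly-hdf5``.  Every event row is attached to its stay; unknown
    feature ids raise a :class:`RegistryError` listing the offenders."""
    path = Path(path)
    if format == "csv-bundle":
        stays_df = pd.read_csv(path / "stays.csv")
        events_df = pd.read_csv(path / "events.csv")
        vent_df = pd.read_csv(path / "vent.csv")
    elif format == "hourly-hdf5":
        with pd.HDFStore(path, mode="r") as store:
            stays_df = store["stays"]
            events_df = store["events"]
            vent_df = store["vent"]
    else:
        raise ValueError(f"unknown format {format!r}")

    _require_columns(stays_df, ["stay_id", "los_hours"], "stays.csv")
    _require_columns(events_df, ["stay_id", "feature_id", "time_hours", "value"], "events.csv")
    _require_columns(vent_df, ["stay_id", "start_hours", "end_hours"], "vent.csv")

    if registry is not None:
        unknown = sorted(set(events_df["feature_id"].unique()) - set(registry))
        if unknown:
            raise RegistryError(f"unknown feature id(s) in events: {unknown}")

    ev_groups = dict(iter(events_df.groupby("stay_id", sort=False)))
    vent_groups = dict(iter(vent_df.groupby("stay_id", sort=False)))

    def _opt(row: pd.Series, col: str) -> float | None:
        if col not in row or pd.isna(row[col]):
            return None
        return float(row[col])

    stays = []
    for _, row in stays_df.iterrows():
        sid = int(row["stay_id"])
        ev = ev_groups.get(sid)
        if ev is None:
            ev = pd.DataFrame(columns=EVENT_COLUMNS)
        else:
            ev = ev.rename(columns={"time_hours": "time"})[EVENT_COLUMNS]
        vt = vent_groups.get(sid)
        vent = (
            vt[["start_hours", "end_hours"]].to_numpy(float)
            if vt is not None
            else np.empty((0, 2))
        )
        sex = row.get("sex")
        stays.append(
            PatientStay(
                stay_id=sid,
                los_hours=float(row["los_hours"]),
                age=_opt(row, "age"),
                sex=None if pd.isna(sex) else str(sex),
                weight=_opt(row, "weight"),
                height=_opt(row, "height"),
                events=ev,
                vent=vent,
            )
        )
    return stays


def write_stays(
    stays: Sequence[PatientStay], path: str | Path, format: str = "csv-bundle"
) -> None:
    """Write a cohort in the interchange layout read by :func:`load_stays`."""
    path = Path(path)
    stays_df = pd.DataFrame(
        {
            "stay_id": [s.stay_id for s in stays],
            "los_hours": [s.los_hours for s in stays],
            "age": [s.age for s in stays],
            "sex": [s.sex for s in stays],
            "weight": [s.weight for s in stays],
            "height": [s.height for s in stays],
        }
    )
    ev_parts = []
    for s in stays:
        if len(s.events):
            part = s.events.copy()
            part.insert(0, "stay_id", s.stay_id)
            ev_parts.append(part)
    events_df = (
        pd.concat(ev_parts, ignore_index=True)
        if ev_parts
        else pd.DataFrame(columns=["stay_id", *EVENT_COLUMNS])
    ).rename(columns={"time": "time_hours"})
    vent_df = pd.DataFrame(
        [
            {"stay_id": s.stay_id, "start_hours": a, "end_hours": b}
            for s in stays
            for a, b in s.vent
        ],
        columns=["stay_id", "start_hours", "end_hours"],
    )
    if format == "csv-bundle":
        path.mkdir(parents=True, exist_ok=True)
        stays_df.to_csv(path / "stays.csv", index=False)
        events_df.to_csv(path / "events.csv", index=False)
        vent_df.to_csv(path / "vent.csv", index=False)
    elif format == "hourly-hdf5":
        vent_df = vent_df.astype(
            {"stay_id": "int64", "start_hours": "float64", "end_hours": "float64"}
        )
        events_df = events_df.astype(
            {"stay_id": "int64", "feature_id": "object",
             "time_hours": "float64", "value": "float64"}
        )
        with pd.HDFStore(path, mode="w") as store:
            store.put("stays", stays_df, format="fixed")
            store.put("events", events_df, format="fixed")
            store.put("vent", vent_df, format="fixed")
    else:
        raise ValueError(f"unknown format {format!r}")


# ----------------------------------------------------------------- filters

def apply_outlier_thresholds(
    stays: Sequence[PatientStay],
    thresholds: Mapping[str, tuple[float, float]] | FeatureRegistry | None = None,
) -> list[PatientStay]:
    """Remove (never clip) event values outside their feature's open
    plausibility interval; removal counts are logged per feature."""
    if thresholds is None:
        thresholds = default_registry()
    if isinstance(thresholds, FeatureRegistry):
        thresholds = thresholds.thresholds()
    removed: dict[str, int] = {}
    out = []
    for s in stays:
        ev = s.events
        if not len(ev):
            out.append(s)
            continue
        lows = ev["feature_id"].map(lambda f: thresholds.get(f, (-np.inf, np.inf))[0])
        highs = ev["feature_id"].map(lambda f: thresholds.get(f, (-np.inf, np.inf))[1])
        keep = (ev["value"] > lows.to_numpy(float)) & (ev["value"] < highs.to_numpy(float))
        if keep.all():
            out.append(s)
            continue
        dropped = ev.loc[~keep, "feature_id"].value_counts()
        for fid, n in dropped.items():
            removed[fid] = removed.get(fid, 0) + int(n)
        out.append(replace(s, events=ev.loc[keep].reset_index(drop=True)))
    for fid, n in sorted(removed.items()):
        logger.info("outlier removal: feature %s: %d value(s) removed", fid, n)
    return out


def is_hypoxemic(stay: PatientStay, spec: CohortSpec = CohortSpec()) -> bool:
    """At least one PaO2 < 60 mmHg or SpO2 < 90 % at any time in the stay."""
    ev = stay.events
    if not len(ev):
        return False
    fid = ev["feature_id"]
    val = ev["value"].to_numpy(float)
    pao2 = (fid == "pao2").to_numpy() & (val < spec.pao2_hypox_mmHg)
    spo2 = (fid == "spo2").to_numpy() & (val < spec.spo2_hypox_pct)
    return bool(pao2.any() or spo2.any())


def filter_cohort(
    stays: Sequence[PatientStay], spec: CohortSpec = CohortSpec()
) -> list[PatientStay]:
    """Retain stays with age > age_min, LOS within bounds and at least one
    qualifying hypoxemic measurement.  Stays without a recorded age are
    excluded and logged."""
    kept = []
    for s in stays:
        if s.age is None:
            logger.info("cohort filter: stay %d has no age; excluded", s.stay_id)
            continue
        if not (
            s.age > spec.age_min
            and spec.los_min <= s.los_hours <= spec.los_max
            and is_hypoxemic(s, spec)
        ):
            continue
        kept.append(s)
    return kept


# --------------------------------------------------------- vent states

def imv_active_hours(stay: PatientStay) -> np.ndarray:
    """Boolean per hour: does ``[h, h+1)`` overlap any IMV interval?"""
    H = stay.n_hours
    active = np.zeros(H, dtype=bool)
    for start, end in stay.vent:
        lo = max(0, int(math.floor(start)))
        hi = min(H, int(math.ceil(end)))
        if hi > lo:
            active[lo:hi] = True
    return active


def derive_vent_states(stay: PatientStay) -> np.ndarray:
    """Per-hour ventilation state sequence of length ``floor(LOS)``.

    ONSET at h iff IMV active in h and not in h-1 (or h is the first hour);
    WEAN iff inactive in h and active in h-1; otherwise STAY_ON / STAY_OFF.
    """
    active = imv_active_hours(stay)
    H = len(active)
    states = np.full(H, VentState.STAY_OFF, dtype=np.int8)
    prev = np.concatenate(([False], active[:-1]))
    states[active & ~prev] = VentState.ONSET
    states[active & prev] = VentState.STAY_ON
    states[~active & prev] = VentState.WEAN
    return states
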