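"""Hourly triplet featurization and sliding-window sample construction.

Each dynamic feature is encoded per hour as a triplet: the hourly mean value
(later standardized and forward-fill imputed), a 0/1 presence mask and the
time since the last measured hour (tsl).  Derived respiratory indices (ROX,
SpO2/FiO2, PaO2/FiO2) are computed from the raw hourly means before
standardization.  A labeled sample takes the 6 preceding hours of triplets
plus statics; the label says whether an IMV onset occurs inside a 4-h target
window separated from the features by a gap of 6–24 h, and any candidate
whose feature or gap hours touch active IMV is excluded.

The sklearn-style entry point is :class:`WindowFeaturizer` (``fit`` learns
the retained feature list and standardization parameters on training stays
only; ``make_samples`` builds design matrices for any stays).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Iterable, Sequence

import h5py
import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator

from .cohort import PatientStay, VentState, derive_vent_states
from .registry import DERIVED_INDICES, FeatureRegistry, default_registry

logger = logging.getLogger(__name__)

TRIPLET_CHANNELS = ("value", "mask", "tsl")
STATIC_FEATURES = ("age", "sex", "weight", "height")


@dataclass(frozen=True)
class WindowConfig:
    feature_window: int = 6
    gap: int = 6
    target_window: int = 4
    stride: int = 1

    def __post_init__(self) -> None:
        for f in dc_fields(self):
            v = getattr(self, f.name)
            if not (isinstance(v, (int, np.integer)) and v > 0):
                raise ValueError(f"{f.name} must be a positive integer, got {v!r}")


@dataclass
class HourlyMatrix:
    """Rectangular per-stay grid over hours 0..floor(LOS)-1.

    ``value`` holds raw hourly means (NaN where unmeasured) until
    standardization/imputation, after which ``standardized`` is set and
    ``value`` holds imputed z-scores.  ``mask`` and ``tsl`` are never
    altered by imputation.
    """

    stay_id: int
    feature_ids: list[str]
    value: np.ndarray  # (H, F)
    mask: np.ndarray  # (H, F) uint8
    tsl: np.ndarray  # (H, F)
    statics: dict[str, float]
    standardized: bool = False

    @property
    def n_hours(self) -> int:
        return self.value.shape[0]

    def restrict(self, feature_ids: Sequence[str]) -> "HourlyMatrix":
        idx = [self.feature_ids.index(f) for f in feature_ids]
        return HourlyMatrix(
            self.stay_id,
            list(feature_ids),
            self.value[:, idx],
            self.mask[:, idx],
            self.tsl[:, idx],
            dict(self.statics),
            self.standardized,
        )


def _tsl_from_mask(mask: np.ndarray) -> np.ndarray:
    """tsl[h] = h - (last measured hour <= h); h + 1 before any measurement."""
    H = mask.shape[0]
    hh = np.arange(H)[:, None]
    last = np.where(mask.astype(bool), hh, -1)
    last = np.maximum.accumulate(last, axis=0)
    return (hh - last).astype(float)


def aggregate_hourly(stay: PatientStay, feature_ids: Sequence[str]) -> HourlyMatrix:
    """Arithmetic mean of each hour's raw measurements per feature, with the
    presence mask and time-since-last channel."""
    H = stay.n_hours
    F = len(feature_ids)
    sums = np.zeros((max(H, 0), F))
    counts = np.zeros((max(H, 0), F))
    ev = stay.events
    if len(ev) and H > 0:
        col_of = {f: j for j, f in enumerate(feature_ids)}
        cols = ev["feature_id"].map(col_of)
        ok = cols.notna().to_numpy()
        t = ev["time"].to_numpy(float)[ok]
        hrs = np.floor(t).astype(int)
        in_grid = hrs < H
        hrs = hrs[in_grid]
        cidx = cols.to_numpy()[ok][in_grid].astype(int)
        vals = ev["value"].to_numpy(float)[ok][in_grid]
        np.add.at(sums, (hrs, cidx), vals)
        np.add.at(counts, (hrs, cidx), 1.0)
    mask = (counts > 0).astype(np.uint8)
    with np.errstate(invalid="ignore"):
        value = np.where(mask, sums / np.where(counts, counts, 1.0), np.nan)
    statics = {
        "age": np.nan if stay.age is None else float(stay.age),
        "sex": np.nan if stay.sex is None else float(stay.sex == "male"),
        "weight": np.nan if stay.weight is None else float(stay.weight),
        "height": np.nan if stay.height is None else float(stay.height),
    }
    return HourlyMatrix(stay.stay_id, list(feature_ids), value, mask,
                        _tsl_from_mask(mask), statics)


def add_derived_indices(hm: HourlyMatrix) -> HourlyMatrix:
    """Append ROX, SpO2/FiO2 and PaO2/FiO2 computed from raw hourly means.

    A derived hour is measured only when every constituent is measured that
    hour and strictly positive (guarding the divisions)."""
    if hm.standardized:
        raise ValueError("derived indices must be computed on raw hourly means")
    cols = {f: j for j, f in enumerate(hm.feature_ids)}
    new_ids = list(hm.feature_ids)
    vals = [hm.value]
    masks = [hm.mask]
    tsls = [hm.tsl]
    for name, parts in DERIVED_INDICES.items():
        if name in cols or any(p not in cols for p in parts):
            continue
        pm = np.stack([hm.mask[:, cols[p]].astype(bool) for p in parts], axis=1)
        pv = np.stack([hm.value[:, cols[p]] for p in parts], axis=1)
        with np.errstate(invalid="ignore"):
            ok = pm.all(axis=1) & (pv > 0).all(axis=1)
        v = np.full(hm.n_hours, np.nan)
        if ok.any():
            if name == "spo2_fio2_ratio":
                v[ok] = pv[ok, 0] / pv[ok, 1]
            elif name == "pao2_fio2_ratio":
                v[ok] = pv[ok, 0] / pv[ok, 1]
            elif name == "rox_index":
                v[ok] = pv[ok, 0] / pv[ok, 1] / pv[ok, 2]
        n_degenerate = int((pm.all(axis=1) & ~ok).sum())
        if n_degenerate:
            logger.info(
                "derived index %s: %d hour(s) with non-positive constituents "
                "treated as unmeasured (stay %d)", name, n_degenerate, hm.stay_id,
            )
        m = ok.astype(np.uint8)[:, None]
        new_ids.append(name)
        vals.append(v[:, None])
        masks.append(m)
        tsls.append(_tsl_from_mask(m))
    return HourlyMatrix(
        hm.stay_id,
        new_ids,
        np.concatenate(vals, axis=1),
        np.concatenate(masks, axis=1),
        np.concatenate(tsls, axis=1),
        dict(hm.statics),
        False,
    )


@dataclass
class StandardizationParams:
    """Per-feature mean/sd over measured hours of the training split."""

    feature_ids: list[str]
    mean: np.ndarray
    sd: np.ndarray
    constant: np.ndarray  # bool: sd undefined or 0; standardized value is 0

    def to_dict(self) -> dict:
        return {
            "feature_ids": self.feature_ids,
            "mean": [None if not np.isfinite(m) else float(m) for m in self.mean],
            "sd": [None if not np.isfinite(s) else float(s) for s in self.sd],
            "constant": [bool(c) for c in self.constant],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "StandardizationParams":
        return cls(
            list(d["feature_ids"]),
            np.array([np.nan if m is None else m for m in d["mean"]], float),
            np.array([np.nan if s is None else s for s in d["sd"]], float),
            np.array(d["constant"], bool),
        )


def fit_standardization(
    matrices: Iterable[HourlyMatrix], feature_ids: Sequence[str] | None = None
) -> StandardizationParams:
    """Mean and sd per feature over measured (mask = 1) hours only."""
    matrices = list(matrices)
    if not matrices:
        raise ValueError("no training matrices")
    if feature_ids is None:
        feature_ids = matrices[0].feature_ids
    F = len(feature_ids)
    n = np.zeros(F)
    s1 = np.zeros(F)
    s2 = np.zeros(F)
    for hm in matrices:
        sub = hm if hm.feature_ids == list(feature_ids) else hm.restrict(feature_ids)
        m = sub.mask.astype(bool)
        v = np.where(m, sub.value, 0.0)
        n += m.sum(axis=0)
        s1 += v.sum(axis=0)
        s2 += (v**2).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = np.where(n > 0, s1 / np.where(n, n, 1), np.nan)
        var = np.where(n > 1, (s2 - n * mean**2) / np.maximum(n - 1, 1), np.nan)
    var = np.where(var < 0, 0.0, var)  # numerical guard
    sd = np.sqrt(var)
    constant = ~(sd > 1e-12)
    for j in np.flatnonzero(constant):
        logger.info("feature %s is constant/unmeasured in training; "
                    "standardized value fixed at 0", feature_ids[j])
    return StandardizationParams(list(feature_ids), mean, sd, constant)


def impute(hm: HourlyMatrix, params: StandardizationParams) -> HourlyMatrix:
    """Standardize measured hours, carry the last standardized observation
    forward, fill hours before any observation with 0 (the standardized
    training mean).  Idempotent; mask and tsl are untouched."""
    sub = hm if hm.feature_ids == params.feature_ids else hm.restrict(params.feature_ids)
    m = sub.mask.astype(bool)
    if sub.standardized:
        z = sub.value
    else:
        with np.errstate(invalid="ignore"):
            z = (sub.value - params.mean) / np.where(params.constant, 1.0, params.sd)
        z = np.where(params.constant, 0.0, z)
    H, F = z.shape
    hh = np.arange(H)[:, None]
    last = np.maximum.accumulate(np.where(m, hh, -1), axis=0)
    cols = np.broadcast_to(np.arange(F), (H, F))
    filled = np.where(last >= 0, z[np.clip(last, 0, None), cols], 0.0)
    return HourlyMatrix(sub.stay_id, list(params.feature_ids), filled,
                        sub.mask.copy(), sub.tsl.copy(), dict(sub.statics), True)


def enumerate_windows(
    states: np.ndarray, cfg: WindowConfig
) -> tuple[np.ndarray, np.ndarray]:
    """Candidate reference hours and labels for one stay.

    A candidate at reference hour t (end of the feature window, exclusive)
    is emitted iff no hour of ``[t - feature_window, t + gap)`` is IMV
    active; its label is 1 iff an ONSET hour lies in
    ``[t + gap, t + gap + target_window)``.  Candidates stop early enough
    that the target window fits inside the stay.
    """
    H = len(states)
    W, G, T, stride = cfg.feature_window, cfg.gap, cfg.target_window, cfg.stride
    t_hi = H - G - T
    if t_hi < W:
        logger.info("stay shorter than feature+gap+target windows; no samples")
        return np.empty(0, int), np.empty(0, np.int8)
    active = (states == VentState.ONSET) | (states == VentState.STAY_ON)
    onset = states == VentState.ONSET
    cact = np.concatenate(([0], np.cumsum(active)))
    cons = np.concatenate(([0], np.cumsum(onset)))
    ts = np.arange(W, t_hi + 1, stride)
    ok = (cact[ts + G] - cact[ts - W]) == 0
    ts = ts[ok]
    labels = ((cons[ts + G + T] - cons[ts + G]) > 0).astype(np.int8)
    return ts, labels


def measured_hour_counts(matrices: Iterable[HourlyMatrix]) -> pd.Series:
    """Measured-hour count per feature, summed over stays."""
    total: pd.Series | None = None
    for hm in matrices:
        c = pd.Series(hm.mask.sum(axis=0).astype(int), index=hm.feature_ids)
        total = c if total is None else total.add(c, fill_value=0)
    if total is None:
        raise ValueError("no matrices")
    return total.astype(int)


def exclude_rare_features(counts: pd.Series, min_count: int) -> list[str]:
    """Features with at least ``min_count`` measured training hours, in the
    original order; the complement is dropped from the model feature list."""
    kept = [f for f in counts.index if counts[f] >= min_count]
    dropped = [f for f in counts.index if counts[f] < min_count]
    if dropped:
        logger.info("rare-feature exclusion (min_count=%d): dropped %s",
                    min_count, dropped)
    return kept


def split_patients(
    stays: Sequence[PatientStay], fractions: Sequence[float], seed: int
) -> list[list[int]]:
    """Reproducible patient-level partition of stay ids."""
    if not stays:
        raise ValueError("empty cohort")
    if not math.isclose(sum(fractions), 1.0, abs_tol=1e-9):
        raise ValueError("fractions must sum to 1")
    ids = np.array([s.stay_id for s in stays])
    rng = np.random.default_rng(seed)
    perm = rng.permutation(len(ids))
    bounds = np.round(np.cumsum(fractions) * len(ids)).astype(int)
    out, lo = [], 0
    for hi in bounds:
        out.append([int(x) for x in ids[perm[lo:hi]]])
        lo = hi
    return out


@dataclass
class WindowDataset:
    """Flattened labeled window samples for a set of stays."""

    X: np.ndarray  # (n, d) float32
    y: np.ndarray  # (n,) int8
    stay_ids: np.ndarray
    ts: np.ndarray  # reference hours
    columns: list[str]
    window: WindowConfig = field(default_factory=WindowConfig)

    def __len__(self) -> int:
        return len(self.y)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        with h5py.File(path, "w") as f:
            f.create_dataset("X", data=self.X, compression="gzip")
            f.create_dataset("y", data=self.y)
            f.create_dataset("stay_ids", data=self.stay_ids)
            f.create_dataset("ts", data=self.ts)
            f.attrs["columns"] = json.dumps(self.columns)
            f.attrs["window"] = json.dumps(vars(self.window))

    @classmethod
    def load(cls, path: str | Path) -> "WindowDataset":
        with h5py.File(path, "r") as f:
            return cls(
                f["X"][...],
                f["y"][...],
                f["stay_ids"][...],
                f["ts"][...],
                json.loads(f.attrs["columns"]),
                WindowConfig(**json.loads(f.attrs["window"])),
            )


def triplet_columns(feature_ids: Sequence[str], window: int) -> list[str]:
    cols = [
        f"{fid}|{chan}|h{k}"
        for fid in feature_ids
        for chan in TRIPLET_CHANNELS
        for k in range(window)
    ]
    cols.extend(f"{s}|static" for s in STATIC_FEATURES)
    return cols


def parse_column(name: str) -> tuple[str, str, int | None]:
    """Column name -> (feature_id, channel, within-window hour or None)."""
    parts = name.split("|")
    if parts[-1] == "static":
        return parts[0], "static", None
    fid, chan, h = parts
    return fid, chan, int(h.removeprefix("h"))


class WindowFeaturizer(BaseEstimator):
    """Stays -> labeled sliding-window design matrices.

    ``fit`` (training stays only) aggregates hourly triplets, appends the
    derived respiratory indices, drops rarely measured features and learns
    standardization parameters.  ``make_samples`` featurizes any stays with
    the fitted manifest — target-domain stays are deliberately featurized
    with the source featurizer so a source model and its adaptation see the
    same coordinates.

    Parameters
    ----------
    registry : feature registry (default: the standard one).
    window : WindowConfig (6-h features, 6-h gap, 4-h target, 1-h stride).
    include_operational : include the clinician-set ventilator features.
    derived_indices : append ROX / SpO2:FiO2 / PaO2:FiO2.
    min_count : rare-feature exclusion threshold on measured training hours.
    """

    def __init__(
        self,
        registry: FeatureRegistry | None = None,
        window: WindowConfig | None = None,
        include_operational: bool = True,
        derived_indices: bool = True,
        min_count: int = 1000,
    ):
        self.registry = registry
        self.window = window
        self.include_operational = include_operational
        self.derived_indices = derived_indices
        self.min_count = min_count

    # ------------------------------------------------------------ internals
    def _window_cfg(self) -> WindowConfig:
        return self.window if self.window is not None else WindowConfig()

    def _base_ids(self) -> list[str]:
        reg = self.registry if self.registry is not None else default_registry()
        return [
            f
            for f in reg.dynamic_ids(self.include_operational)
            if reg[f].kind != "derived"
        ]

    def _raw_matrix(self, stay: PatientStay) -> HourlyMatrix:
        hm = aggregate_hourly(stay, self._base_ids())
        if self.derived_indices:
            hm = add_derived_indices(hm)
        return hm

    # -------------------------------------------------------------- persist
    def to_json(self, path: str | Path) -> None:
        """Persist the fitted manifest, standardization and window config."""
        reg = self.registry if self.registry is not None else default_registry()
        payload = {
            "window": vars(self._window_cfg()),
            "include_operational": self.include_operational,
            "derived_indices": self.derived_indices,
            "min_count": self.min_count,
            "feature_list": self.feature_list_,
            "dropped_features": self.dropped_features_,
            "standardization": self.standardization_.to_dict(),
            "columns": self.columns_,
            "registry": {
                fid: {
                    "name": d.name, "unit": d.unit, "outlier_low": d.outlier_low,
                    "outlier_high": d.outlier_high, "kind": d.kind,
                }
                for fid, d in reg.items()
            },
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "WindowFeaturizer":
        from .registry import FeatureDef

        payload = json.loads(Path(path).read_text())
        reg = FeatureRegistry(
            {fid: FeatureDef(**d) for fid, d in payload["registry"].items()}
        )
        obj = cls(
            registry=reg,
            window=WindowConfig(**payload["window"]),
            include_operational=payload["include_operational"],
            derived_indices=payload["derived_indices"],
            min_count=payload["min_count"],
        )
        obj.feature_list_ = payload["feature_list"]
        obj.dropped_features_ = payload["dropped_features"]
        obj.standardization_ = StandardizationParams.from_dict(payload["standardization"])
        obj.columns_ = payload["columns"]
        return obj

    # ------------------------------------------------------------------ api
    def fit(self, stays: Sequence[PatientStay], y=None) -> "WindowFeaturizer":
        if not stays:
            raise ValueError("cannot fit featurizer on an empty cohort")
        matrices = [self._raw_matrix(s) for s in stays]
        counts = measured_hour_counts(matrices)
        self.measured_counts_ = counts
        self.feature_list_ = exclude_rare_features(counts, self.min_count)
        self.dropped_features_ = [f for f in counts.index if f not in self.feature_list_]
        if not self.feature_list_:
            raise ValueError("every feature fell below min_count; nothing to model")
        self.standardization_ = fit_standardization(matrices, self.feature_list_)
        self.columns_ = triplet_columns(self.feature_list_, self._window_cfg().feature_window)
        return self

    def transform_stay(self, stay: PatientStay) -> HourlyMatrix:
        """Imputed, standardized hourly matrix over the fitted feature list."""
        return impute(self._raw_matrix(stay), self.standardization_)

    def make_samples(
        self, stays: Sequence[PatientStay], window: WindowConfig | None = None
    ) -> WindowDataset:
        cfg = window if window is not None else self._window_cfg()
        if cfg.feature_window != self._window_cfg().feature_window:
            raise ValueError("feature_window is fixed by the fitted column manifest")
        W = cfg.feature_window
        n_stat = len(STATIC_FEATURES)
        Xs, ys, sids, tss = [], [], [], []
        for stay in stays:
            hm = self.transform_stay(stay)
            states = derive_vent_states(stay)
            ts, labels = enumerate_windows(states, cfg)
            if not len(ts):
                continue
            # (H, 3F) channel stack in manifest order: (feature, channel)
            arr = np.empty((hm.n_hours, 3 * len(hm.feature_ids)), dtype=np.float32)
            arr[:, 0::3] = hm.value
            arr[:, 1::3] = hm.mask
            arr[:, 2::3] = hm.tsl
            view = np.lib.stride_tricks.sliding_window_view(arr, W, axis=0)
            # view[s] has shape (3F, W); row s corresponds to t = s + W
            block = view[ts - W]  # (n, 3F, W) -> flatten feature-major
            flat = block.reshape(len(ts), -1)
            stat = np.array(
                [hm.statics[s] for s in STATIC_FEATURES], dtype=np.float32
            )
            Xs.append(np.hstack([flat, np.broadcast_to(stat, (len(ts), n_stat))]))
            ys.append(labels)
            sids.append(np.full(len(ts), stay.stay_id))
            tss.append(ts)
        d = 3 * len(self.feature_list_) * W + n_stat
        if not Xs:
            return WindowDataset(
                np.empty((0, d), np.float32), np.empty(0, np.int8),
                np.empty(0, int), np.empty(0, int), list(self.columns_), cfg,
            )
        return WindowDataset(
            np.vstack(Xs).astype(np.float32),
            np.concatenate(ys),
            np.concatenate(sids),
            np.concatenate(tss),
            list(self.columns_),
            cfg,
        )
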