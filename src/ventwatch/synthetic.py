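"""Seeded synthetic ICU cohort generator.

Stands in for credentialed bedside data.  Each simulated stay carries a
latent severity process (AR(1) around a patient-specific trend) that drives
both the observable vitals/labs (through per-feature loadings) and a
per-hour logistic hazard of invasive-mechanical-ventilation onset.
Measurements arrive at feature-specific Poisson rates, giving the irregular
sampling and missingness structure of real charts.  A configurable domain
shift (feature means, severity loadings, hazard coefficients) turns a source
cohort into a distinct target cohort for transfer-learning experiments.

Units are clinical: SpO2 in %, FiO2 as a fraction, pressures in mmHg/cmH2O.
SpO2 and PaO2 load negatively on severity so deteriorating patients become
hypoxemic and qualify for the cohort filter; a ``healthy_frac`` of stays is
generated non-deteriorating to exercise the filter.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import numpy as np
import yaml

from .cohort import PatientStay, write_stays
from .registry import FeatureRegistry, default_registry

import pandas as pd


@dataclass(frozen=True)
class FeatureSpec:
    """Generation law of one dynamic feature.

    value(hour) = patient_baseline + loading * severity(hour) + AR(1) noise,
    observed at Poisson(``rate``) measurements per hour, clipped to ``clip``.
    """

    baseline: float
    baseline_sd: float
    noise_sd: float
    rate: float  # measurements per hour
    loading: float = 0.0
    ar1: float = 0.5
    clip: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ValueError("measurement rate must be >= 0")
        if not 0 <= self.ar1 < 1:
            raise ValueError("AR(1) coefficient must be in [0, 1)")


@dataclass(frozen=True)
class SeverityProcess:
    """Latent severity: random walk with a per-patient drift.

    A ``p_deteriorate`` fraction of patients drifts upward toward the
    hazard's operating range; the rest drift flat or slowly recover.
    Healthy-fraction stays start lower and never deteriorate."""

    p_deteriorate: float = 0.15
    drift_mean: float = 0.12  # per hour, deteriorating patients
    drift_sd: float = 0.03
    stable_drift_mean: float = -0.02
    stable_drift_sd: float = 0.03
    sigma: float = 0.10  # random-walk innovation sd per hour
    init_mean: float = -1.5
    init_sd: float = 0.8
    clip: tuple[float, float] = (-4.0, 5.0)


@dataclass(frozen=True)
class OnsetHazard:
    """Per-hour onset probability: sigmoid(intercept + slope * severity).

    The steep default slope makes onset close to a threshold crossing at
    severity ~ -intercept/slope, so deterioration visible hours earlier is
    genuinely predictive."""

    intercept: float = -15.0
    slope: float = 6.0


@dataclass(frozen=True)
class DomainShift:
    """Source -> target changes: additive feature-mean shifts, additive
    severity-loading deltas and hazard-coefficient deltas."""

    mean_shift: Mapping[str, float] = field(default_factory=dict)
    loading_shift: Mapping[str, float] = field(default_factory=dict)
    hazard_intercept_delta: float = 0.0
    hazard_slope_delta: float = 0.0


def default_feature_specs() -> dict[str, FeatureSpec]:
    """Study-condition defaults.  paco2 is the dominant planted predictor;
    fio2_set and peep_set are informative operational features (clinicians
    escalate support as severity rises); misc_lab_* are pure noise."""
    return {
        "paco2": FeatureSpec(42.0, 2.5, 1.5, 0.6, loading=8.0, clip=(15.0, 140.0)),
        "spo2": FeatureSpec(92.5, 1.5, 3.0, 1.0, loading=-2.0, clip=(55.0, 100.0)),
        "resp_rate": FeatureSpec(18.0, 2.0, 2.5, 1.0, loading=3.0, clip=(4.0, 70.0)),
        "heart_rate": FeatureSpec(84.0, 8.0, 7.0, 1.0, loading=6.0, clip=(25.0, 250.0)),
        "fio2": FeatureSpec(0.35, 0.04, 0.05, 0.6, loading=0.08, clip=(0.21, 1.0)),
        "pao2": FeatureSpec(85.0, 8.0, 10.0, 0.35, loading=-10.0, clip=(25.0, 600.0)),
        "mean_bp": FeatureSpec(78.0, 6.0, 6.0, 1.0, loading=-4.0, clip=(25.0, 190.0)),
        "temperature": FeatureSpec(37.0, 0.3, 0.4, 0.4, loading=0.3, clip=(31.0, 42.5)),
        "wbc": FeatureSpec(10.0, 2.0, 2.5, 0.12, loading=1.5, clip=(0.5, 150.0)),
        "creatinine": FeatureSpec(1.2, 0.3, 0.3, 0.12, loading=0.2, clip=(0.1, 25.0)),
        "fio2_set": FeatureSpec(0.30, 0.03, 0.05, 0.5, loading=0.08, clip=(0.21, 1.0)),
        "peep_set": FeatureSpec(5.0, 0.8, 1.0, 0.35, loading=1.2, clip=(0.0, 24.0)),
        "misc_lab_1": FeatureSpec(100.0, 5.0, 8.0, 0.3),
        "misc_lab_2": FeatureSpec(50.0, 3.0, 5.0, 0.3),
        "misc_lab_3": FeatureSpec(10.0, 1.0, 2.0, 0.3),
    }


#: The feature whose severity loading dominates (largest signal-to-noise).
DOMINANT_FEATURE = "paco2"


@dataclass(frozen=True)
class SimulationConfig:
    n_patients: int = 500
    los_bounds: tuple[float, float] = (24.0, 96.0)
    short_stay_frac: float = 0.04  # LOS < 12 h, excluded by the cohort filter
    underage_frac: float = 0.02  # age <= 15, excluded by the cohort filter
    healthy_frac: float = 0.15  # non-deteriorating, rarely hypoxemic
    feature_specs: Mapping[str, FeatureSpec] = field(
        default_factory=default_feature_specs
    )
    severity: SeverityProcess = SeverityProcess()
    hazard: OnsetHazard = OnsetHazard()
    vent_duration_lognorm: tuple[float, float] = (3.4, 0.8)  # mean ~41 h
    seed: int = 0

    def with_seed(self, seed: int) -> "SimulationConfig":
        return dataclasses.replace(self, seed=int(seed))

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["feature_specs"] = {k: dataclasses.asdict(v) for k, v in self.feature_specs.items()}
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SimulationConfig":
        d = yaml.safe_load(Path(path).read_text())
        d["feature_specs"] = {
            k: FeatureSpec(**{**v, "clip": tuple(v["clip"]) if v.get("clip") else None})
            for k, v in d["feature_specs"].items()
        }
        d["severity"] = SeverityProcess(
            **{**d["severity"], "clip": tuple(d["severity"]["clip"])}
        )
        d["hazard"] = OnsetHazard(**d["hazard"])
        d["los_bounds"] = tuple(d["los_bounds"])
        d["vent_duration_lognorm"] = tuple(d["vent_duration_lognorm"])
        return cls(**d)


@dataclass
class SyntheticCohort:
    stays: list[PatientStay]
    truth: dict
    registry: FeatureRegistry
    config: SimulationConfig

    def to_csv_bundle(self, path: str | Path) -> None:
        path = Path(path)
        write_stays(self.stays, path, format="csv-bundle")
        Path(path, "truth.json").write_text(json.dumps(self.truth, indent=1))


def shift_domain(config: SimulationConfig, shift: DomainShift) -> SimulationConfig:
    """Apply a domain shift to a configuration; zero shift returns an equal
    config.  Unknown feature names raise a ``KeyError``."""
    specs = dict(config.feature_specs)
    for name in set(shift.mean_shift) | set(shift.loading_shift):
        if name not in specs:
            raise KeyError(f"domain shift names unknown feature {name!r}")
    for fid, delta in shift.mean_shift.items():
        specs[fid] = dataclasses.replace(specs[fid], baseline=specs[fid].baseline + delta)
    for fid, delta in shift.loading_shift.items():
        specs[fid] = dataclasses.replace(specs[fid], loading=specs[fid].loading + delta)
    hazard = OnsetHazard(
        intercept=config.hazard.intercept + shift.hazard_intercept_delta,
        slope=config.hazard.slope + shift.hazard_slope_delta,
    )
    return dataclasses.replace(config, feature_specs=specs, hazard=hazard)


def covid_like_shift() -> DomainShift:
    """Default target-domain shift used in the transfer experiments.

    Emulates a population whose route to respiratory failure differs from
    the source ICU's: deterioration with much less CO2 retention ("silent
    hypoxemia" — the dominant source predictor loses most of its loading),
    more pronounced desaturation, a sign-flipped heart-rate loading and
    shifted vital baselines."""
    return DomainShift(
        mean_shift={
            "heart_rate": -8.0,
            "mean_bp": 8.0,
            "wbc": -4.0,
            "temperature": 0.6,
            "fio2": 0.06,
        },
        loading_shift={
            "paco2": -7.5,  # +8 -> +0.5: severity no longer drives CO2 up
            "spo2": -1.0,  # -2 -> -3: desaturation somewhat more prominent
            "heart_rate": -12.0,  # +6 -> -6: tachycardia no longer tracks severity
            "resp_rate": 2.0,
            "mean_bp": 6.0,  # -4 -> +2
        },
        hazard_intercept_delta=0.3,
        hazard_slope_delta=-0.2,
    )


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def simulate_cohort(config: SimulationConfig) -> SyntheticCohort:
    """Generate a seeded cohort; identical seeds give identical cohorts."""
    rng = np.random.default_rng(config.seed)
    sev = config.severity
    fids = list(config.feature_specs)
    stays: list[PatientStay] = []
    truth_stays: dict[str, dict] = {}

    for i in range(config.n_patients):
        sid = i + 1
        # --- demographics / stay shape (fixed draw order for determinism)
        u_short, u_young, u_healthy = rng.uniform(size=3)
        if u_short < config.short_stay_frac:
            los = rng.uniform(6.0, 11.9)
        else:
            los = rng.uniform(*config.los_bounds)
        if u_young < config.underage_frac:
            age = rng.uniform(8.0, 15.0)
        else:
            age = float(np.clip(rng.normal(66.0, 16.0), 18.0, 95.0))
        sex = "male" if rng.uniform() < 0.56 else "female"
        weight = float(np.clip(rng.normal(81.0, 20.0), 40.0, 200.0))
        height = float(np.clip(rng.normal(168.0, 10.0), 145.0, 205.0))
        healthy = u_healthy < config.healthy_frac
        H = int(math.floor(los))

        # --- latent severity (random walk with per-patient drift)
        u_det = rng.uniform()
        deteriorating = (not healthy) and u_det < sev.p_deteriorate
        if deteriorating:
            drift = rng.normal(sev.drift_mean, sev.drift_sd)
        else:
            drift = rng.normal(sev.stable_drift_mean, sev.stable_drift_sd)
        init = rng.normal(sev.init_mean - (1.0 if healthy else 0.0), sev.init_sd)
        eps = rng.normal(size=max(H, 1))
        s = np.empty(max(H, 1))
        s[0] = init
        for h in range(1, len(s)):
            s[h] = s[h - 1] + drift + sev.sigma * eps[h]
        s = np.clip(s, sev.clip[0], sev.clip[1])

        # --- onset hazard (uniforms drawn for every hour to keep the
        # stream aligned across shifted configurations)
        u_hours = rng.uniform(size=max(H, 1))
        p = _sigmoid(config.hazard.intercept + config.hazard.slope * s)
        fired = u_hours < p
        onset_hour: int | None = None
        if H > 0 and fired[:H].any():
            onset_hour = int(np.argmax(fired[:H]))
        mu_d, sd_d = config.vent_duration_lognorm
        duration = float(rng.lognormal(mu_d, sd_d))  # drawn unconditionally
        vent = np.empty((0, 2))
        if onset_hour is not None:
            vent = np.array([[onset_hour, min(onset_hour + duration, los)]])

        # --- observed features
        rows_f, rows_t, rows_v = [], [], []
        for fid in fids:
            spec = config.feature_specs[fid]
            base = spec.baseline + spec.baseline_sd * rng.normal()
            if healthy and fid == "spo2":
                base += 2.0
            # hourly AR(1) measurement-process noise
            e = rng.normal(size=max(H, 1))
            noise = np.empty(max(H, 1))
            innov_sd = spec.noise_sd * math.sqrt(1.0 - spec.ar1**2)
            noise[0] = spec.noise_sd * e[0]
            for h in range(1, len(noise)):
                noise[h] = spec.ar1 * noise[h - 1] + innov_sd * e[h]
            underlying = base + spec.loading * s + noise

            n_meas = rng.poisson(spec.rate * los)
            if n_meas == 0:
                continue
            times = np.sort(rng.uniform(0.0, los, size=n_meas))
            hour_idx = np.minimum(np.floor(times).astype(int), max(H, 1) - 1)
            values = underlying[hour_idx] + 0.1 * spec.noise_sd * rng.normal(size=n_meas)
            if spec.clip is not None:
                values = np.clip(values, spec.clip[0], spec.clip[1])
            rows_f.extend([fid] * n_meas)
            rows_t.append(times)
            rows_v.append(values)

        events = pd.DataFrame(
            {
                "feature_id": rows_f,
                "time": np.concatenate(rows_t) if rows_t else np.empty(0),
                "value": np.concatenate(rows_v) if rows_v else np.empty(0),
            }
        )
        stays.append(
            PatientStay(
                stay_id=sid,
                los_hours=los,
                age=age,
                sex=sex,
                weight=weight,
                height=height,
                events=events,
                vent=vent,
            )
        )
        truth_stays[str(sid)] = {
            "severity": [round(float(x), 4) for x in s[:H]],
            "onset_hour": onset_hour,
            "healthy": bool(healthy),
            "deteriorating": bool(deteriorating),
        }

    informative = [f for f, sp in config.feature_specs.items() if sp.loading != 0.0]
    noise_features = [f for f, sp in config.feature_specs.items() if sp.loading == 0.0]
    truth = {
        "stays": truth_stays,
        "informative_features": informative,
        "noise_features": noise_features,
        "dominant_feature": DOMINANT_FEATURE if DOMINANT_FEATURE in informative else None,
        "seed": config.seed,
    }
    return SyntheticCohort(stays, truth, default_registry(), config)
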