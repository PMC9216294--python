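"""Shared fixtures and independent oracles.

The window-enumeration oracle here recomputes candidate emission and labels
directly from the raw ventilation intervals with explicit loops — it never
touches ``derive_vent_states`` or ``enumerate_windows`` — so agreement is a
genuine two-route check.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
import pytest

from ventwatch.cohort import PatientStay, apply_outlier_thresholds, filter_cohort
from ventwatch.featurize import WindowConfig
from ventwatch.synthetic import SimulationConfig, simulate_cohort


# ------------------------------------------------------------------ oracles

def brute_force_windows(stay: PatientStay, cfg: WindowConfig):
    """Exhaustive (reference hour, label) enumeration from raw intervals."""

    def active(h: int) -> bool:
        return any(start < h + 1 and end > h for start, end in stay.vent)

    def onset(h: int) -> bool:
        return active(h) and (h == 0 or not active(h - 1))

    H = int(math.floor(stay.los_hours))
    W, G, T = cfg.feature_window, cfg.gap, cfg.target_window
    out = []
    for t in range(W, H - G - T + 1, cfg.stride):
        if any(active(h) for h in range(t - W, t + G)):
            continue
        label = int(any(onset(h) for h in range(t + G, t + G + T)))
        out.append((t, label))
    return out


def pairwise_auc(labels, scores) -> float:
    """O(n^2) concordant-pair AUC with half credit for ties."""
    labels = np.asarray(labels)
    scores = np.asarray(scores, float)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = 0.0
    for p in pos:
        for q in neg:
            if p > q:
                total += 1.0
            elif p == q:
                total += 0.5
    return total / (len(pos) * len(neg))


def random_vent_stay(rng: np.random.Generator, stay_id: int) -> PatientStay:
    """A stay with random LOS and 0-3 random IMV intervals, no events."""
    los = float(rng.uniform(8.0, 60.0))
    n_iv = int(rng.integers(0, 4))
    ivs = []
    for _ in range(n_iv):
        a = rng.uniform(0.0, los - 0.5)
        b = rng.uniform(a + 0.25, min(los, a + rng.uniform(0.5, 30.0)))
        ivs.append((a, b))
    return PatientStay(stay_id=stay_id, los_hours=los, age=50.0, sex="female",
                       vent=np.array(ivs).reshape(-1, 2))


# ----------------------------------------------------------------- fixtures

@pytest.fixture(scope="session")
def small_cohort():
    """Filtered synthetic cohort of ~150 stays used across module tests."""
    cohort = simulate_cohort(SimulationConfig(n_patients=300, seed=42))
    stays = apply_outlier_thresholds(cohort.stays, cohort.registry)
    return filter_cohort(stays), cohort.truth


@pytest.fixture(scope="session")
def small_dataset(small_cohort):
    """Fitted featurizer + window samples over the small cohort."""
    from ventwatch.featurize import WindowFeaturizer

    stays, _ = small_cohort
    ftz = WindowFeaturizer(min_count=100).fit(stays)
    return ftz, ftz.make_samples(stays)


def make_events(rows):
    return pd.DataFrame(rows, columns=["feature_id", "time", "value"])
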