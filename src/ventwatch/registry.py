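"""Feature registry: the catalogue of measurable variables.

Every dynamic measurement, static demographic and derived index handled by
the pipeline is declared here with its unit, physiologic plausibility bounds
(used for outlier removal) and a kind tag.  Operational features are the
clinician-set ventilator parameters; they can be toggled out of a model to
emulate deployment before any ventilator data exist.
"""

from __future__ import annotations

from dataclasses import dataclass, asdict
from pathlib import Path

import yaml

DYNAMIC = "dynamic"
STATIC = "static"
OPERATIONAL = "operational"
DERIVED = "derived"

_KINDS = {DYNAMIC, STATIC, OPERATIONAL, DERIVED}


@dataclass(frozen=True)
class FeatureDef:
    """Declaration of one feature.

    ``outlier_low``/``outlier_high`` are open-interval plausibility bounds:
    raw values outside ``(low, high)`` are discarded, never clipped.
    """

    name: str
    unit: str
    outlier_low: float
    outlier_high: float
    kind: str = DYNAMIC

    def __post_init__(self) -> None:
        if self.kind not in _KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.outlier_low < self.outlier_high:
            raise ValueError(
                f"{self.name}: outlier_low must be < outlier_high "
                f"({self.outlier_low} >= {self.outlier_high})"
            )


class FeatureRegistry(dict):
    """Mapping feature_id -> :class:`FeatureDef` with convenience views."""

    def dynamic_ids(self, include_operational: bool = True) -> list[str]:
        kinds = {DYNAMIC, DERIVED} | ({OPERATIONAL} if include_operational else set())
        return [fid for fid, d in self.items() if d.kind in kinds]

    def operational_ids(self) -> list[str]:
        return [fid for fid, d in self.items() if d.kind == OPERATIONAL]

    def static_ids(self) -> list[str]:
        return [fid for fid, d in self.items() if d.kind == STATIC]

    def thresholds(self) -> dict[str, tuple[float, float]]:
        return {fid: (d.outlier_low, d.outlier_high) for fid, d in self.items()}

    # ------------------------------------------------------------------ io
    def to_yaml(self, path: str | Path) -> None:
        payload = {fid: asdict(d) for fid, d in self.items()}
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=True))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "FeatureRegistry":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        return cls({fid: FeatureDef(**d) for fid, d in payload.items()})


#: The nine clinician-set ventilator parameters treated as operational.
OPERATIONAL_FEATURES = (
    "peep_set",
    "tidal_volume_set",
    "resp_rate_set",
    "plateau_pressure",
    "peep",
    "tidal_volume_observed",
    "fio2_set",
    "tidal_volume_spontaneous",
    "peak_insp_pressure",
)


def default_registry() -> FeatureRegistry:
    """Registry with the standard vitals/labs, the nine operational
    ventilator-setting features and the static demographics."""
    r = FeatureRegistry()
    dyn = {
        "heart_rate": ("heart rate", "bpm", 20, 300),
        "resp_rate": ("respiratory rate", "breaths/min", 2, 80),
        "spo2": ("oxygen saturation (pulse oximetry)", "%", 50, 100.5),
        "fio2": ("fraction of inspired oxygen", "fraction", 0.15, 1.01),
        "pao2": ("arterial oxygen partial pressure", "mmHg", 20, 700),
        "paco2": ("arterial CO2 partial pressure", "mmHg", 10, 150),
        "mean_bp": ("mean arterial blood pressure", "mmHg", 20, 200),
        "temperature": ("body temperature", "degC", 30, 43),
        "wbc": ("white blood cell count", "1e3/uL", 0.1, 200),
        "creatinine": ("serum creatinine", "mg/dL", 0.05, 30),
        "misc_lab_1": ("auxiliary laboratory assay 1", "AU", -1e6, 1e6),
        "misc_lab_2": ("auxiliary laboratory assay 2", "AU", -1e6, 1e6),
        "misc_lab_3": ("auxiliary laboratory assay 3", "AU", -1e6, 1e6),
    }
    for fid, (name, unit, lo, hi) in dyn.items():
        r[fid] = FeatureDef(name, unit, lo, hi, DYNAMIC)
    op = {
        "peep_set": ("PEEP set", "cmH2O", -0.5, 30),
        "tidal_volume_set": ("tidal volume set", "mL", 50, 1200),
        "resp_rate_set": ("respiratory rate set", "breaths/min", 2, 60),
        "plateau_pressure": ("plateau pressure", "cmH2O", 0, 80),
        "peep": ("PEEP observed", "cmH2O", -0.5, 35),
        "tidal_volume_observed": ("tidal volume observed", "mL", 20, 1500),
        "fio2_set": ("FiO2 set", "fraction", 0.15, 1.01),
        "tidal_volume_spontaneous": ("tidal volume spontaneous", "mL", 0, 1500),
        "peak_insp_pressure": ("peak inspiratory pressure", "cmH2O", 0, 100),
    }
    for fid, (name, unit, lo, hi) in op.items():
        r[fid] = FeatureDef(name, unit, lo, hi, OPERATIONAL)
    stat = {
        "age": ("age", "years", 0, 130),
        "sex": ("sex", "binary (1=male)", -0.5, 1.5),
        "weight": ("weight", "kg", 20, 400),
        "height": ("height", "cm", 100, 250),
    }
    for fid, (name, unit, lo, hi) in stat.items():
        r[fid] = FeatureDef(name, unit, lo, hi, STATIC)
    return r


#: Derived respiratory indices appended by the featurizer, with the raw
#: features each one is computed from.
DERIVED_INDICES: dict[str, tuple[str, ...]] = {
    "spo2_fio2_ratio": ("spo2", "fio2"),
    "pao2_fio2_ratio": ("pao2", "fio2"),
    "rox_index": ("spo2", "fio2", "resp_rate"),
}


def derived_defs() -> dict[str, FeatureDef]:
    return {
        "spo2_fio2_ratio": FeatureDef("SpO2/FiO2 ratio", "ratio", 0, 1e9, DERIVED),
        "pao2_fio2_ratio": FeatureDef("PaO2/FiO2 ratio", "ratio", 0, 1e9, DERIVED),
        "rox_index": FeatureDef("ROX index", "ratio", 0, 1e9, DERIVED),
    }
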