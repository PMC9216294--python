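"""End-to-end experiment harness: simulate, featurize, train, adapt, score.

These functions wire the pipeline together under the study conditions used
throughout the package: a source cohort of 2000 simulated stays and a
target cohort of 300 stays whose feature means, severity loadings and
onset hazard are shifted.  Training uses patient-level splits (80/20
train/test on the source with a validation carve-out for the random
search; 70/30 fit/eval on the target, with a further carve-out for the
adaptation search).
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from .cohort import CohortSpec, PatientStay, apply_outlier_thresholds, filter_cohort
from .evaluate import CIResult, roc_auc, sensitivity_auc_ci
from .featurize import WindowConfig, WindowFeaturizer, split_patients
from .model import AdaptationConfig, HyperparamSpace, OnsetBoostedClassifier
from .registry import default_registry
from .synthetic import (
    DomainShift,
    SimulationConfig,
    covid_like_shift,
    shift_domain,
    simulate_cohort,
)


def _subset(stays: Sequence[PatientStay], ids: Sequence[int]) -> list[PatientStay]:
    wanted = set(ids)
    return [s for s in stays if s.stay_id in wanted]


def prepare_cohort(
    config: SimulationConfig, spec: CohortSpec = CohortSpec()
) -> list[PatientStay]:
    """Simulate, outlier-filter and cohort-filter one cohort."""
    cohort = simulate_cohort(config)
    stays = apply_outlier_thresholds(cohort.stays, cohort.registry)
    return filter_cohort(stays, spec)


@dataclass(frozen=True)
class ExperimentConfig:
    """Sizes and knobs of the source/target transfer experiment."""

    n_source: int = 2000
    n_target: int = 300
    gap: int = 6
    include_operational: bool = True
    source_test_fraction: float = 0.2
    valid_fraction: float = 0.15  # of source training stays, for the search
    target_fit_fraction: float = 0.7
    adapt_valid_fraction: float = 0.25  # of the target fit stays
    min_count_source: int = 1000
    min_count_target: int = 200
    space: HyperparamSpace = field(default_factory=HyperparamSpace)
    adaptation: AdaptationConfig = field(default_factory=AdaptationConfig)
    shift: DomainShift = field(default_factory=covid_like_shift)


def train_source_model(
    stays: Sequence[PatientStay],
    seed: int,
    cfg: ExperimentConfig = ExperimentConfig(),
):
    """Patient-level 80/20 split, search-fit a model on the training side.

    Returns (featurizer, model, test_auc, test_dataset)."""
    test_frac = cfg.source_test_fraction
    train_ids, test_ids = split_patients(
        stays, (1 - test_frac, test_frac), seed=seed
    )
    train_stays = _subset(stays, train_ids)
    fit_ids, valid_ids = split_patients(
        train_stays, (1 - cfg.valid_fraction, cfg.valid_fraction), seed=seed + 1
    )
    window = WindowConfig(gap=cfg.gap)
    ftz = WindowFeaturizer(
        registry=default_registry(),
        window=window,
        include_operational=cfg.include_operational,
        min_count=cfg.min_count_source,
    ).fit(train_stays)
    ds_fit = ftz.make_samples(_subset(train_stays, fit_ids))
    ds_valid = ftz.make_samples(_subset(train_stays, valid_ids))
    ds_test = ftz.make_samples(_subset(stays, test_ids))
    model = OnsetBoostedClassifier(space=cfg.space, seed=seed).fit(
        ds_fit, valid=(ds_valid.X, ds_valid.y)
    )
    test_auc = roc_auc(ds_test.y, model.score_samples(ds_test.X))
    return ftz, model, test_auc, ds_test


@dataclass
class TransferResult:
    seed: int
    source_test_auc: float
    target_as_is_auc: float
    target_adapted_auc: float
    target_only_auc: float
    n_source_stays: int
    n_target_stays: int
    source_model: OnsetBoostedClassifier | None = None
    featurizer: WindowFeaturizer | None = None
    eval_labels: np.ndarray | None = None
    eval_probs: dict[str, np.ndarray] | None = None


def run_transfer_experiment(
    seed: int,
    cfg: ExperimentConfig = ExperimentConfig(),
    shifted: bool = True,
    keep_models: bool = False,
    keep_predictions: bool = False,
) -> TransferResult:
    """One seed of the two-step experiment.

    Trains the source model, applies it to the held-out target eval split
    as-is, adapts it on the target fit split, and trains a target-only
    model on the same fit split for comparison.
    """
    seed = int(seed)
    src_cfg = SimulationConfig(n_patients=cfg.n_source, seed=seed * 1000 + 1)
    tgt_cfg = SimulationConfig(n_patients=cfg.n_target, seed=seed * 1000 + 2)
    if shifted:
        tgt_cfg = shift_domain(tgt_cfg, cfg.shift)
    source = prepare_cohort(src_cfg)
    target = prepare_cohort(tgt_cfg)

    ftz, model, source_test_auc, _ = train_source_model(source, seed, cfg)

    fit_ids, eval_ids = split_patients(
        target, (cfg.target_fit_fraction, 1 - cfg.target_fit_fraction), seed=seed + 2
    )
    fit_stays = _subset(target, fit_ids)
    afit_ids, avalid_ids = split_patients(
        fit_stays,
        (1 - cfg.adapt_valid_fraction, cfg.adapt_valid_fraction),
        seed=seed + 3,
    )
    # target stays are featurized with the SOURCE manifest and scaling
    ds_afit = ftz.make_samples(_subset(fit_stays, afit_ids))
    ds_avalid = ftz.make_samples(_subset(fit_stays, avalid_ids))
    ds_eval = ftz.make_samples(_subset(target, eval_ids))

    as_is_auc = roc_auc(ds_eval.y, model.score_samples(ds_eval.X))
    adapted = model.adapt(
        ds_afit.X, ds_afit.y, ds_avalid.X, ds_avalid.y,
        cfg=cfg.adaptation, seed=seed,
    )
    adapted_auc = roc_auc(ds_eval.y, adapted.score_samples(ds_eval.X))

    # target-only model: featurizer and classifier see only the fit split
    tftz = WindowFeaturizer(
        registry=default_registry(),
        window=WindowConfig(gap=cfg.gap),
        include_operational=cfg.include_operational,
        min_count=cfg.min_count_target,
    ).fit(fit_stays)
    tds_fit = tftz.make_samples(_subset(fit_stays, afit_ids))
    tds_valid = tftz.make_samples(_subset(fit_stays, avalid_ids))
    tds_eval = tftz.make_samples(_subset(target, eval_ids))
    tmodel = OnsetBoostedClassifier(space=cfg.space, seed=seed).fit(
        tds_fit, valid=(tds_valid.X, tds_valid.y)
    )
    target_only_auc = roc_auc(tds_eval.y, tmodel.score_samples(tds_eval.X))

    return TransferResult(
        seed=seed,
        source_test_auc=float(source_test_auc),
        target_as_is_auc=float(as_is_auc),
        target_adapted_auc=float(adapted_auc),
        target_only_auc=float(target_only_auc),
        n_source_stays=len(source),
        n_target_stays=len(target),
        source_model=model if keep_models else None,
        featurizer=ftz if keep_models else None,
        eval_labels=ds_eval.y if keep_predictions else None,
        eval_probs=(
            {
                "as_is": model.score_samples(ds_eval.X),
                "adapted": adapted.score_samples(ds_eval.X),
                "target_only": tmodel.score_samples(tds_eval.X),
            }
            if keep_predictions
            else None
        ),
    )


def run_sensitivity_ci(
    seed: int,
    n_source: int = 2000,
    n_splits: int = 10,
    gap: int = 6,
    include_operational: bool = True,
    level: float = 0.95,
) -> CIResult:
    """Repeated-random-split AUC CI on one simulated source cohort.

    The hyperparameter configuration is tuned once (random search on the
    first split) and then held fixed while the patient split is redrawn,
    so the interval reflects split-to-split variability of one configured
    model.
    """
    cfg = ExperimentConfig(n_source=n_source, gap=gap,
                           include_operational=include_operational)
    stays = prepare_cohort(SimulationConfig(n_patients=n_source, seed=seed * 1000 + 1))
    ftz, model, _, _ = train_source_model(stays, seed, cfg)
    tuned = model.best_params_
    fixed_space = HyperparamSpace(
        max_depth=(tuned["max_depth"], tuned["max_depth"]),
        learning_rate=(tuned["learning_rate"], tuned["learning_rate"]),
        n_rounds=(tuned["n_rounds"], tuned["n_rounds"]),
        subsample=(tuned["subsample"], tuned["subsample"]),
        colsample_bytree=(tuned["colsample_bytree"], tuned["colsample_bytree"]),
        min_child_weight=(tuned["min_child_weight"], tuned["min_child_weight"]),
        n_draws=1,
    )
    split_cfg = dataclasses.replace(cfg, space=fixed_space)

    def procedure(cohort, split_seed: int) -> float:
        _, _, auc, _ = train_source_model(cohort, split_seed, split_cfg)
        return auc

    return sensitivity_auc_ci(procedure, stays, n_splits=n_splits,
                              seed=seed + 10, level=level)
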