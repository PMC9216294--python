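"""Evaluation battery for imbalanced onset prediction.

ROC/AUC, a decision threshold anchored at a target false-positive rate
(default 0.2, "predict positive iff probability >= mu"), the resulting
confusion matrix, F-beta (default beta = 0.5) and the Matthews correlation
coefficient, precision-recall curves, precision inside probability bins
above the threshold, repeated-split AUC confidence intervals, and
cohort-characteristics summary tables.  Counts are window-level (number of
sliding-window samples), not patient-level.
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.metrics import precision_recall_curve, roc_auc_score, roc_curve

from .cohort import PatientStay
from .model import SingleClassError

logger = logging.getLogger(__name__)

DEFAULT_BIN_EDGES = (0.1, 0.2, 0.3, 0.4, 0.5, 0.6, 0.7, 0.8, 0.9, 1.0)


@dataclass(frozen=True)
class EvaluationConfig:
    target_fpr: float = 0.2
    beta: float = 0.5
    bin_edges: tuple[float, ...] = DEFAULT_BIN_EDGES
    n_splits: int = 30
    ci_level: float = 0.95

    def __post_init__(self) -> None:
        if not 0 < self.target_fpr < 1:
            raise ValueError("target_fpr must be in (0, 1)")
        if self.beta <= 0:
            raise ValueError("beta must be positive")
        e = self.bin_edges
        if any(b <= a for a, b in zip(e, e[1:])) or e[-1] != 1.0:
            raise ValueError("bin edges must be strictly increasing and end at 1.0")


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    tn: int
    fn: int
    threshold: float

    @property
    def precision(self) -> float:
        return self.tp / (self.tp + self.fp) if self.tp + self.fp else float("nan")

    @property
    def recall(self) -> float:
        return self.tp / (self.tp + self.fn) if self.tp + self.fn else float("nan")


def _check_binary(labels: np.ndarray, need_pos=True, need_neg=True) -> None:
    pos, neg = int((labels == 1).sum()), int((labels == 0).sum())
    if (need_pos and pos == 0) or (need_neg and neg == 0):
        raise SingleClassError(f"labels have {pos} positives and {neg} negatives")


def roc_auc(labels, probabilities) -> float:
    """Tie-corrected AUC (probability a random positive outscores a random
    negative, ties counted half)."""
    labels = np.asarray(labels)
    _check_binary(labels)
    return float(roc_auc_score(labels, probabilities))


def roc_points(labels, probabilities) -> pd.DataFrame:
    fpr, tpr, thr = roc_curve(labels, probabilities)
    return pd.DataFrame({"fpr": fpr, "tpr": tpr, "threshold": thr})


def threshold_at_fpr(labels, probabilities, target_fpr: float = 0.2):
    """Smallest observed score mu with FPR(mu) <= target; returns
    (mu, achieved_fpr).  Positives are scores >= mu."""
    labels = np.asarray(labels)
    probabilities = np.asarray(probabilities, float)
    _check_binary(labels, need_pos=False)
    neg = np.sort(probabilities[labels == 0])
    n_neg = len(neg)
    cands = np.unique(probabilities)
    fprs = (n_neg - np.searchsorted(neg, cands, side="left")) / n_neg
    ok = np.flatnonzero(fprs <= target_fpr)
    if len(ok):
        return float(cands[ok[0]]), float(fprs[ok[0]])
    # no observed score qualifies: step just above the largest score
    return float(np.max(probabilities)) + np.finfo(float).eps, 0.0


def confusion(labels, probabilities, mu: float) -> ConfusionMatrix:
    """Counts with the rule: predicted positive iff probability >= mu."""
    labels = np.asarray(labels).astype(int)
    pred = np.asarray(probabilities, float) >= mu
    return ConfusionMatrix(
        tp=int((pred & (labels == 1)).sum()),
        fp=int((pred & (labels == 0)).sum()),
        tn=int((~pred & (labels == 0)).sum()),
        fn=int((~pred & (labels == 1)).sum()),
        threshold=float(mu),
    )


def f_beta(cm: ConfusionMatrix, beta: float = 0.5) -> float:
    """(1 + b^2) P R / (b^2 P + R); 0 when precision = recall = 0."""
    p, r = cm.precision, cm.recall
    if not (p > 0 or r > 0):
        return 0.0
    p = 0.0 if math.isnan(p) else p
    r = 0.0 if math.isnan(r) else r
    denom = beta**2 * p + r
    return (1 + beta**2) * p * r / denom if denom else 0.0


def mcc(cm: ConfusionMatrix) -> float:
    """Matthews correlation; 0 when any marginal is empty."""
    tp, fp, tn, fn = cm.tp, cm.fp, cm.tn, cm.fn
    denom = (tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    if denom == 0:
        return 0.0
    return (tp * tn - fp * fn) / math.sqrt(denom)


def pr_curve(labels, probabilities) -> pd.DataFrame:
    """One (recall, precision) point per distinct score threshold."""
    labels = np.asarray(labels)
    _check_binary(labels, need_neg=False)
    precision, recall, thr = precision_recall_curve(labels, probabilities)
    # drop the artificial (recall 0, precision 1) endpoint
    return pd.DataFrame(
        {"recall": recall[:-1], "precision": precision[:-1], "threshold": thr}
    )


def precision_by_bin(
    labels, probabilities, mu: float, bin_edges: Sequence[float] = DEFAULT_BIN_EDGES
) -> pd.DataFrame:
    """Precision inside probability bins partitioning [mu, 1].

    Fixed edges at or below mu are discarded; the first bin starts at mu and
    the last bin is closed at 1.  Empty bins report count 0 and NaN
    precision.  The count-weighted mean of bin precisions equals the
    overall precision above mu.
    """
    if mu >= 1:
        raise ValueError("mu must be < 1")
    labels = np.asarray(labels).astype(int)
    probabilities = np.asarray(probabilities, float)
    edges = [mu] + [e for e in bin_edges if e > mu]
    rows = []
    for i, (lo, hi) in enumerate(zip(edges, edges[1:])):
        last = i == len(edges) - 2
        sel = (probabilities >= lo) & (
            (probabilities <= hi) if last else (probabilities < hi)
        )
        n = int(sel.sum())
        rows.append(
            {
                "lo": lo,
                "hi": hi,
                "count": n,
                "positives": int(labels[sel].sum()),
                "precision": float(labels[sel].mean()) if n else float("nan"),
            }
        )
    return pd.DataFrame(rows)


@dataclass
class EvalReport:
    """Full evaluation of one set of window-level predictions."""

    auc: float
    mu: float
    achieved_fpr: float
    cm: ConfusionMatrix
    precision: float
    recall: float
    f_beta: float
    beta: float
    mcc: float
    roc: pd.DataFrame
    pr: pd.DataFrame
    bins: pd.DataFrame
    n_samples: int
    n_positives: int
    ci: tuple[float, float] | None = None

    def to_dict(self) -> dict:
        d = {
            "auc": self.auc,
            "mu": self.mu,
            "achieved_fpr": self.achieved_fpr,
            "confusion": asdict(self.cm),
            "precision": self.precision,
            "recall": self.recall,
            "f_beta": self.f_beta,
            "beta": self.beta,
            "mcc": self.mcc,
            "n_samples": self.n_samples,
            "n_positives": self.n_positives,
            "ci": list(self.ci) if self.ci else None,
            "roc": self.roc.to_dict("list"),
            "pr": self.pr.to_dict("list"),
            "bins": self.bins.to_dict("records"),
        }
        return d

    def to_json(self, path: str | Path) -> None:
        def _default(o):
            if isinstance(o, (np.floating, np.integer)):
                return o.item()
            raise TypeError(type(o))

        Path(path).write_text(json.dumps(self.to_dict(), default=_default, indent=1))


def evaluate_predictions(
    labels, probabilities, cfg: EvaluationConfig = EvaluationConfig()
) -> EvalReport:
    """Compute the whole battery at the FPR-anchored threshold."""
    labels = np.asarray(labels).astype(int)
    probabilities = np.asarray(probabilities, float)
    auc = roc_auc(labels, probabilities)
    mu, achieved = threshold_at_fpr(labels, probabilities, cfg.target_fpr)
    cm = confusion(labels, probabilities, mu)
    return EvalReport(
        auc=auc,
        mu=mu,
        achieved_fpr=achieved,
        cm=cm,
        precision=cm.precision,
        recall=cm.recall,
        f_beta=f_beta(cm, cfg.beta),
        beta=cfg.beta,
        mcc=mcc(cm),
        roc=roc_points(labels, probabilities),
        pr=pr_curve(labels, probabilities),
        bins=precision_by_bin(labels, probabilities, mu, cfg.bin_edges)
        if mu < 1
        else pd.DataFrame(),
        n_samples=int(len(labels)),
        n_positives=int(labels.sum()),
    )


@dataclass
class CIResult:
    mean: float
    low: float
    high: float
    aucs: list[float] = field(default_factory=list)

    @property
    def width(self) -> float:
        return self.high - self.low


def sensitivity_auc_ci(
    procedure: Callable[[Sequence[PatientStay], int], float],
    stays: Sequence[PatientStay],
    n_splits: int = 30,
    seed: int = 0,
    level: float = 0.95,
) -> CIResult:
    """Repeated-random-split AUC confidence interval.

    ``procedure(stays, split_seed)`` must re-run the full split/train/test
    pipeline and return the test AUC.  A split producing a single-class
    test set is resampled with a logged new seed.  The CI is
    mean +- t(level, n-1) * sd / sqrt(n) over split AUCs.
    """
    if n_splits < 2:
        raise ValueError("n_splits must be >= 2")
    aucs: list[float] = []
    split_seed = int(seed)
    attempts = 0
    while len(aucs) < n_splits:
        try:
            aucs.append(float(procedure(stays, split_seed)))
        except SingleClassError:
            logger.info("split seed %d yielded a single-class set; resampling",
                        split_seed)
        split_seed += 1
        attempts += 1
        if attempts > 10 * n_splits:
            raise RuntimeError("too many single-class splits; cohort too small")
    arr = np.asarray(aucs)
    mean = float(arr.mean())
    sd = float(arr.std(ddof=1))
    half = float(stats.t.ppf(0.5 + level / 2, len(arr) - 1) * sd / math.sqrt(len(arr)))
    return CIResult(mean, mean - half, mean + half, aucs)


# ----------------------------------------------------------- cohort summary

def percent(count: int, total: int, decimals: int = 0) -> float:
    """Percentage rounded as configured (e.g. 6281 of 11816 -> 53.2)."""
    if total == 0:
        return float("nan")
    return round(100.0 * count / total, decimals)


def _mean_sd(values: Sequence[float]) -> tuple[float, float]:
    arr = np.asarray([v for v in values if v is not None and np.isfinite(v)], float)
    if not len(arr):
        return float("nan"), float("nan")
    return float(arr.mean()), float(arr.std(ddof=1)) if len(arr) > 1 else 0.0


def cohort_summary(
    stays: Sequence[PatientStay],
    first24_features: Sequence[str] = ("heart_rate", "mean_bp", "spo2", "resp_rate"),
    pct_decimals: int = 1,
) -> pd.DataFrame:
    """Baseline-characteristics table: counts with percentages for binary
    traits, mean (SD) for continuous ones, first-24-h means for selected
    dynamic features and respiratory-support exposure flags."""
    rows: list[dict] = []
    n = len(stays)
    if n == 0:
        return pd.DataFrame(columns=["characteristic", "n", "pct", "mean", "sd"])

    def add_count(name, count):
        rows.append({"characteristic": name, "n": count,
                     "pct": percent(count, n, pct_decimals),
                     "mean": None, "sd": None})

    def add_cont(name, values):
        m, s = _mean_sd(values)
        rows.append({"characteristic": name, "n": None, "pct": None,
                     "mean": m, "sd": s})

    rows.append({"characteristic": "total", "n": n, "pct": 100.0,
                 "mean": None, "sd": None})
    add_count("male sex", sum(1 for s in stays if s.sex == "male"))
    add_cont("age (years)", [s.age for s in stays])
    add_cont("weight (kg)", [s.weight for s in stays])
    add_cont("height (cm)", [s.height for s in stays])
    add_cont(
        "BMI (kg/m2)",
        [
            s.weight / (s.height / 100.0) ** 2
            for s in stays
            if s.weight and s.height
        ],
    )
    for fid in first24_features:
        vals = []
        for s in stays:
            ev = s.events
            sel = (ev["feature_id"] == fid) & (ev["time"] < 24.0)
            if sel.any():
                vals.append(float(ev.loc[sel, "value"].mean()))
        add_cont(f"{fid} (first 24 h)", vals)
    add_count(
        "any oxygen/ventilator setting recorded",
        sum(
            1
            for s in stays
            if len(s.events)
            and s.events["feature_id"].isin(["fio2_set", "peep_set"]).any()
        ),
    )
    add_count("invasive mechanical ventilation",
              sum(1 for s in stays if len(s.vent)))
    add_cont("length of stay (days)", [s.los_hours / 24.0 for s in stays])
    return pd.DataFrame(rows)
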