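"""Gradient-boosted tree classifier for IMV-onset prediction.

:class:`OnsetBoostedClassifier` wraps XGBoost with a random hyperparameter
search (validation-AUC selection), class-imbalance weighting through
``scale_pos_weight`` (defaulting to the training negative:positive ratio),
and a transfer-learning ``adapt`` step: the source model's trees are frozen
and additional rounds are boosted on a target-domain fit split starting
from the source margin, with the number of added rounds and their learning
rate chosen by random search on a target validation split.  The null model
(zero added rounds, i.e. the source applied as-is) is always among the
adaptation candidates, so adapting on an unshifted target cannot be forced
to change the model.
"""

from __future__ import annotations

import json
import tempfile
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.metrics import roc_auc_score

from .featurize import WindowDataset

FORMAT_VERSION = 1


class ManifestMismatchError(ValueError):
    """Sample feature manifest differs from the model's manifest."""


class SingleClassError(ValueError):
    """A training or validation set contains a single class."""


@dataclass(frozen=True)
class HyperparamSpace:
    """Random-search ranges.  Integer ranges are inclusive; continuous
    ranges uniform (``learning_rate`` log-uniform).  ``scale_pos_weight``
    of ``None`` uses the training set's negative:positive ratio."""

    max_depth: tuple[int, int] = (3, 7)
    learning_rate: tuple[float, float] = (0.05, 0.3)
    n_rounds: tuple[int, int] = (40, 120)
    subsample: tuple[float, float] = (0.7, 1.0)
    colsample_bytree: tuple[float, float] = (0.6, 1.0)
    min_child_weight: tuple[float, float] = (1.0, 8.0)
    scale_pos_weight: tuple[float, float] | None = None
    n_draws: int = 4

    def __post_init__(self) -> None:
        if self.n_draws < 1:
            raise ValueError("n_draws must be >= 1")

    def sample(self, rng: np.random.Generator, neg_pos_ratio: float) -> dict:
        lo, hi = self.learning_rate
        return {
            "max_depth": int(rng.integers(self.max_depth[0], self.max_depth[1] + 1)),
            "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
            "n_rounds": int(rng.integers(self.n_rounds[0], self.n_rounds[1] + 1)),
            "subsample": float(rng.uniform(*self.subsample)),
            "colsample_bytree": float(rng.uniform(*self.colsample_bytree)),
            "min_child_weight": float(rng.uniform(*self.min_child_weight)),
            "scale_pos_weight": (
                float(neg_pos_ratio)
                if self.scale_pos_weight is None
                else float(rng.uniform(*self.scale_pos_weight))
            ),
        }


@dataclass(frozen=True)
class AdaptationConfig:
    """Transfer-learning search: extra rounds and their learning rate."""

    fit_fraction: float = 0.7
    n_rounds_range: tuple[int, int] = (50, 300)
    learning_rate_range: tuple[float, float] = (0.02, 0.1)
    max_depth_range: tuple[int, int] = (2, 3)  # shallow: small target cohorts
    min_child_weight_range: tuple[float, float] = (2.0, 6.0)
    n_draws: int = 6
    freeze_source_trees: bool = True
    include_null: bool = True  # always consider 0 added rounds
    refit_on_full: bool = True  # refit the chosen continuation on fit+valid

    def __post_init__(self) -> None:
        if not 0 < self.fit_fraction < 1:
            raise ValueError("fit_fraction must be in (0, 1)")


def _as_xy(data, y=None):
    if isinstance(data, WindowDataset):
        return data.X, data.y, list(data.columns)
    if isinstance(data, pd.DataFrame):
        return data.to_numpy(np.float32), y, [str(c) for c in data.columns]
    return np.asarray(data, np.float32), y, None


def _check_classes(y: np.ndarray, what: str) -> None:
    pos, neg = int((y == 1).sum()), int((y == 0).sum())
    if pos == 0 or neg == 0:
        raise SingleClassError(
            f"{what} has a single class ({pos} positive, {neg} negative)"
        )


class OnsetBoostedClassifier(BaseEstimator, ClassifierMixin):
    """XGBoost onset classifier with seeded random hyperparameter search.

    Parameters
    ----------
    space : HyperparamSpace, search ranges and number of draws.
    seed : controls the search draws and the booster's RNG.
    n_jobs : threads handed to XGBoost (1 keeps runs bit-reproducible).
    valid_fraction : rows carved out for search validation when ``fit``
        receives no explicit validation set.
    """

    def __init__(
        self,
        space: HyperparamSpace | None = None,
        seed: int = 0,
        n_jobs: int = 1,
        valid_fraction: float = 0.25,
    ):
        self.space = space
        self.seed = seed
        self.n_jobs = n_jobs
        self.valid_fraction = valid_fraction

    # --------------------------------------------------------------- helpers
    def _base_params(self, hp: Mapping) -> dict:
        return {
            "objective": "binary:logistic",
            "eval_metric": "auc",
            "tree_method": "hist",
            "nthread": self.n_jobs,
            "seed": int(self.seed),
            "max_depth": hp["max_depth"],
            "eta": hp["learning_rate"],
            "subsample": hp["subsample"],
            "colsample_bytree": hp["colsample_bytree"],
            "min_child_weight": hp["min_child_weight"],
            "scale_pos_weight": hp["scale_pos_weight"],
        }

    def _dmatrix(self, X: np.ndarray, y: np.ndarray | None = None) -> xgb.DMatrix:
        return xgb.DMatrix(
            X, label=y, feature_names=getattr(self, "feature_names_", None)
        )

    def _validate_manifest(self, columns: Sequence[str] | None) -> None:
        manifest = getattr(self, "feature_names_", None)
        if columns is None or manifest is None:
            return
        if list(columns) != list(manifest):
            missing = [c for c in manifest if c not in columns]
            extra = [c for c in columns if c not in manifest]
            raise ManifestMismatchError(
                f"feature manifest mismatch: missing={missing}, extra={extra}"
            )

    # ------------------------------------------------------------------- fit
    def fit(self, X, y=None, *, valid=None, feature_names=None):
        X, y, cols = _as_xy(X, y)
        y = np.asarray(y).astype(int)
        if feature_names is None:
            feature_names = cols
        self.feature_names_ = (
            [str(c) for c in feature_names] if feature_names is not None else None
        )
        if valid is None:
            rng = np.random.default_rng(self.seed)
            n_valid = max(1, int(round(self.valid_fraction * len(y))))
            perm = rng.permutation(len(y))
            vi, ti = perm[:n_valid], perm[n_valid:]
            X_tr, y_tr, X_va, y_va = X[ti], y[ti], X[vi], y[vi]
        else:
            Xv, yv = valid
            Xv, yv, vcols = _as_xy(Xv, yv)
            self._validate_manifest(vcols)
            X_tr, y_tr, X_va, y_va = X, y, Xv, np.asarray(yv).astype(int)
        _check_classes(y_tr, "training set")
        _check_classes(y_va, "validation set")
        npr = float((y_tr == 0).sum()) / float((y_tr == 1).sum())
        space = self.space if self.space is not None else HyperparamSpace()
        rng = np.random.default_rng(self.seed)
        dtrain = self._dmatrix(X_tr, y_tr)
        dvalid = self._dmatrix(X_va)
        best = None
        log = []
        for i in range(space.n_draws):
            hp = space.sample(rng, npr)
            bst = xgb.train(self._base_params(hp), dtrain,
                            num_boost_round=hp["n_rounds"])
            if hp["n_rounds"] > 0:
                auc = float(roc_auc_score(y_va, bst.predict(dvalid)))
            else:
                auc = 0.5
            log.append({"draw": i, "params": hp, "valid_auc": auc})
            if best is None or auc > best[0]:
                best = (auc, hp, bst)
        self.best_valid_auc_, self.best_params_, self.booster_ = best
        self.search_log_ = log
        self.classes_ = np.array([0, 1])
        self.n_features_in_ = X.shape[1]
        self.metadata_ = {
            "seed": int(self.seed),
            "hyperparams": self.best_params_,
            "adapted": False,
            "n_train": int(len(y_tr)),
            "neg_pos_ratio": npr,
        }
        return self

    # --------------------------------------------------------------- predict
    def _predict_margin(self, X) -> np.ndarray:
        Xa, _, cols = _as_xy(X)
        self._validate_manifest(cols)
        return self.booster_.predict(self._dmatrix(Xa), output_margin=True)

    def predict_proba(self, X) -> np.ndarray:
        Xa, _, cols = _as_xy(X)
        self._validate_manifest(cols)
        p = self.booster_.predict(self._dmatrix(Xa))
        return np.column_stack([1.0 - p, p])

    def predict(self, X) -> np.ndarray:
        return (self.predict_proba(X)[:, 1] >= 0.5).astype(int)

    def score_samples(self, X) -> np.ndarray:
        """Positive-class probability (convenience)."""
        return self.predict_proba(X)[:, 1]

    # ----------------------------------------------------------------- adapt
    def adapt(
        self,
        X_fit,
        y_fit=None,
        X_valid=None,
        y_valid=None,
        cfg: AdaptationConfig | None = None,
        seed: int = 0,
    ) -> "OnsetBoostedClassifier":
        """Continue boosting on target-domain data from the source margin.

        Source trees are preserved verbatim (``freeze_source_trees``); the
        number of added rounds and their learning rate are chosen by random
        search on ``(X_valid, y_valid)``, and the chosen continuation is
        then refitted on fit+valid together (``refit_on_full``) so the final
        trees see the whole target fit portion.  Returns a new fitted
        classifier; ``self`` is unchanged.
        """
        cfg = cfg if cfg is not None else AdaptationConfig()
        Xf, yf, fcols = _as_xy(X_fit, y_fit)
        self._validate_manifest(fcols)
        yf = np.asarray(yf).astype(int)
        Xv, yv, vcols = _as_xy(X_valid, y_valid)
        self._validate_manifest(vcols)
        yv = np.asarray(yv).astype(int)
        _check_classes(yf, "target fit split")
        _check_classes(yv, "target validation split")
        npr = float((yf == 0).sum()) / float((yf == 1).sum())
        rng = np.random.default_rng(seed)
        dfit = self._dmatrix(Xf, yf)
        dvalid = self._dmatrix(Xv)
        source_trees = self.booster_.num_boosted_rounds()

        start = self.booster_
        if not cfg.freeze_source_trees and source_trees > 0:
            # refresh the source trees' leaf weights on the target fit split
            refresh_params = dict(self._base_params(self.best_params_))
            refresh_params.update(
                process_type="update", updater="refresh", refresh_leaf=1
            )
            refresh_params.pop("tree_method", None)
            start = xgb.train(refresh_params, dfit,
                              num_boost_round=source_trees,
                              xgb_model=self._booster_copy())

        candidates = []
        if cfg.include_null:
            candidates.append({"n_rounds": 0, "learning_rate": 0.0,
                               "scale_pos_weight": npr})
        lo, hi = cfg.learning_rate_range
        for _ in range(cfg.n_draws):
            candidates.append(
                {
                    "n_rounds": int(
                        rng.integers(cfg.n_rounds_range[0], cfg.n_rounds_range[1] + 1)
                    ),
                    "learning_rate": float(np.exp(rng.uniform(np.log(lo), np.log(hi)))),
                    "max_depth": int(
                        rng.integers(cfg.max_depth_range[0], cfg.max_depth_range[1] + 1)
                    ),
                    "min_child_weight": float(
                        rng.uniform(*cfg.min_child_weight_range)
                    ),
                    "scale_pos_weight": npr,
                }
            )
        best = None
        log = []
        for i, hp in enumerate(candidates):
            if hp["n_rounds"] == 0:
                bst = self._booster_copy(start)
            else:
                params = dict(self._base_params(self.best_params_))
                params.update(
                    eta=hp["learning_rate"],
                    max_depth=hp["max_depth"],
                    min_child_weight=hp["min_child_weight"],
                    scale_pos_weight=hp["scale_pos_weight"],
                    seed=int(seed),
                    process_type="default",
                )
                params.pop("updater", None)
                bst = xgb.train(params, dfit, num_boost_round=hp["n_rounds"],
                                xgb_model=self._booster_copy(start))
            auc = float(roc_auc_score(yv, bst.predict(dvalid)))
            log.append({"draw": i, "params": hp, "valid_auc": auc})
            if best is None or auc > best[0]:
                best = (auc, hp, bst)

        if cfg.refit_on_full and best[1]["n_rounds"] > 0:
            hp = best[1]
            X_all = np.vstack([Xf, Xv])
            y_all = np.concatenate([yf, yv])
            npr_all = float((y_all == 0).sum()) / float((y_all == 1).sum())
            dall = self._dmatrix(X_all, y_all)
            params = dict(self._base_params(self.best_params_))
            params.update(eta=hp["learning_rate"], max_depth=hp["max_depth"],
                          min_child_weight=hp["min_child_weight"],
                          scale_pos_weight=npr_all, seed=int(seed),
                          process_type="default")
            bst = xgb.train(params, dall, num_boost_round=hp["n_rounds"],
                            xgb_model=self._booster_copy(start))
            best = (best[0], hp, bst)

        adapted = OnsetBoostedClassifier(
            space=self.space, seed=seed, n_jobs=self.n_jobs
        )
        adapted.booster_ = best[2]
        adapted.feature_names_ = self.feature_names_
        adapted.best_params_ = dict(self.best_params_, adaptation=best[1])
        adapted.best_valid_auc_ = best[0]
        adapted.search_log_ = log
        adapted.classes_ = np.array([0, 1])
        adapted.n_features_in_ = Xf.shape[1]
        adapted.metadata_ = {
            "seed": int(seed),
            "hyperparams": adapted.best_params_,
            "adapted": True,
            "source_trees": int(source_trees),
            "added_rounds": int(best[1]["n_rounds"]),
            "freeze_source_trees": bool(cfg.freeze_source_trees),
        }
        return adapted

    def _booster_copy(self, booster: xgb.Booster | None = None) -> xgb.Booster:
        src = booster if booster is not None else self.booster_
        return src.copy()

    # ------------------------------------------------------------ importance
    def feature_importance(self) -> pd.Series:
        """Split-count-weighted squared-gain importance from the tree dump.

        Sum over splits of squared gain per feature, normalized to 1,
        descending; ties broken by manifest order.  Empty for a 0-tree
        model.
        """
        if self.booster_.num_boosted_rounds() == 0:
            return pd.Series(dtype=float)
        df = self.booster_.trees_to_dataframe()
        splits = df[df["Feature"] != "Leaf"]
        if not len(splits):
            return pd.Series(dtype=float)
        raw = (splits["Gain"].astype(float) ** 2).groupby(splits["Feature"]).sum()
        imp = raw / raw.sum()
        manifest = self.feature_names_ or list(imp.index)
        order = {f: i for i, f in enumerate(manifest)}
        idx = sorted(imp.index, key=lambda f: (-imp[f], order.get(f, len(order))))
        return imp.loc[idx]

    # ------------------------------------------------------------------- io
    def save(self, path: str | Path) -> None:
        raw = self.booster_.save_raw("json").decode()
        payload = {
            "format_version": FORMAT_VERSION,
            "booster": json.loads(raw),
            "manifest": self.feature_names_,
            "metadata": self.metadata_,
            "best_params": self.best_params_,
            "search_log": self.search_log_,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path: str | Path) -> "OnsetBoostedClassifier":
        try:
            payload = json.loads(Path(path).read_text())
        except json.JSONDecodeError as e:
            raise ValueError(f"corrupt model file {path}: {e}") from e
        version = payload.get("format_version")
        if version != FORMAT_VERSION:
            raise ValueError(
                f"model format version mismatch: file has {version!r}, "
                f"expected {FORMAT_VERSION}"
            )
        obj = cls()
        bst = xgb.Booster()
        bst.load_model(bytearray(json.dumps(payload["booster"]).encode()))
        obj.booster_ = bst
        obj.feature_names_ = payload["manifest"]
        obj.metadata_ = payload["metadata"]
        obj.best_params_ = payload["best_params"]
        obj.search_log_ = payload["search_log"]
        obj.classes_ = np.array([0, 1])
        return obj


def aggregate_importance(importance: pd.Series) -> pd.Series:
    """Sum per-column importance over triplet channels and window hours to a
    per-feature ranking (statics keep their own name)."""
    if not len(importance):
        return pd.Series(dtype=float)
    base = importance.index.map(lambda c: str(c).split("|")[0])
    agg = importance.groupby(base).sum()
    return agg.sort_values(ascending=False)
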