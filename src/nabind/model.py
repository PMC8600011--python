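"""Regression models, group-aware validation and the evaluation suite.

The predictor is an extremely-randomized-trees regressor (alternative
algorithms are available behind one registry) trained on the feature
schema of :mod:`nabind.features`.  Validation is always group-aware: all
records of a complex — including hypothetical reverse mutations, which
share the forward record's group id — stay in the same fold, under
group-based k-fold (k in 5/10/20) or leave-one-complex-out schemes.

Metrics: Pearson/Spearman/Kendall(tau-b)/RMSE for regression; accuracy,
F1, MCC and AUC for direction-of-change classification-by-regression
after excluding the neutral band; sensitivity/specificity/precision/
accuracy/F1/MCC for the alanine-scanning hot-spot benchmark; and
outlier-trimmed variants that drop the worst-predicted fraction.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field
from typing import Sequence

import joblib
import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import (ExtraTreesRegressor, GradientBoostingRegressor,
                              RandomForestRegressor)
from sklearn.gaussian_process import GaussianProcessRegressor
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import GroupKFold, LeaveOneGroupOut
from sklearn.neighbors import KNeighborsRegressor
from sklearn.neural_network import MLPRegressor
from sklearn.svm import SVR

from .dataset import NEUTRAL_BAND, label_direction
from .errors import SchemaMismatchError

ALGORITHMS = {
    "extra_trees": ExtraTreesRegressor,
    "random_forest": RandomForestRegressor,
    "gradient_boosting": GradientBoostingRegressor,
    "knn": KNeighborsRegressor,
    "svr": SVR,
    "gaussian_process": GaussianProcessRegressor,
    "mlp": MLPRegressor,
}

SEEDED = {"extra_trees", "random_forest", "gradient_boosting", "mlp",
          "gaussian_process"}


@dataclass
class ModelConfig:
    """Algorithm choice, hyperparameters and selection settings."""

    algorithm: str = "extra_trees"
    hyperparameters: dict = field(default_factory=lambda: {"n_estimators": 300})
    random_seed: int = 42
    max_selected_features: int = 13
    selection_min_improvement: float = 1e-3

    def build(self):
        cls = ALGORITHMS[self.algorithm]
        kwargs = dict(self.hyperparameters)
        if self.algorithm in SEEDED:
            kwargs.setdefault("random_state", self.random_seed)
        return cls(**kwargs)


@dataclass
class CVScheme:
    """Group-based k-fold or leave-one-complex-out splitting."""

    kind: str = "group-k-fold"           # or "leave-one-complex-out"
    k: int = 5

    def splitter(self):
        if self.kind == "leave-one-complex-out":
            return LeaveOneGroupOut()
        if self.kind == "group-k-fold":
            return GroupKFold(n_splits=self.k)
        raise ValueError(f"unknown CV scheme {self.kind!r}")


# ---------------------------------------------------------------------------
# metrics

def evaluate_regression(y_true: Sequence[float],
                        y_pred: Sequence[float]) -> dict[str, float]:
    """Pearson, Spearman, Kendall (tau-b) correlations and RMSE."""
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    if len(yt) != len(yp) or len(yt) < 3:
        raise ValueError("need equal-length vectors of length >= 3")
    if np.std(yt) == 0 or np.std(yp) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    return {
        "pearson": float(stats.pearsonr(yt, yp)[0]),
        "spearman": float(stats.spearmanr(yt, yp)[0]),
        "kendall": float(stats.kendalltau(yt, yp)[0]),
        "rmse": float(np.sqrt(np.mean((yt - yp) ** 2))),
    }


def confusion_metrics(tp: int, fp: int, tn: int, fn: int) -> dict[str, float]:
    """SEN/SPE/PRE/ACC/F1/MCC from a 2x2 table (0 where undefined)."""
    def _safe(num: float, den: float) -> float:
        return num / den if den else 0.0

    sen = _safe(tp, tp + fn)
    spe = _safe(tn, tn + fp)
    pre = _safe(tp, tp + fp)
    acc = _safe(tp + tn, tp + fp + tn + fn)
    f1 = _safe(2 * pre * sen, pre + sen)
    mcc_den = np.sqrt(float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn))
    mcc = _safe(tp * tn - fp * fn, mcc_den)
    return {"sen": sen, "spe": spe, "pre": pre, "acc": acc, "f1": f1,
            "mcc": float(mcc)}


def classification_by_regression(y_true: Sequence[float],
                                 y_pred: Sequence[float],
                                 neutral_band: tuple[float, float] = NEUTRAL_BAND,
                                 ) -> dict[str, float]:
    """Direction-of-change metrics after excluding experimentally neutral records.

    True class is the sign of the experimental ddG outside the neutral
    band; the predicted class is the sign of the prediction (threshold
    0), with the raw prediction as the continuous score for AUC (higher
    = more likely increasing).
    """
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    keep = np.array([label_direction(v, neutral_band) != "neutral" for v in yt])
    yt, yp = yt[keep], yp[keep]
    if len(np.unique(yt > 0)) < 2:
        raise ValueError("only one direction class present after filtering")
    true_pos = yt > 0      # increasing affinity
    pred_pos = yp > 0
    tp = int(np.sum(true_pos & pred_pos))
    fp = int(np.sum(~true_pos & pred_pos))
    tn = int(np.sum(~true_pos & ~pred_pos))
    fn = int(np.sum(true_pos & ~pred_pos))
    m = confusion_metrics(tp, fp, tn, fn)
    return {"accuracy": m["acc"], "f1": m["f1"], "mcc": m["mcc"],
            "auc": float(roc_auc_score(true_pos, yp)),
            "n_used": int(len(yt))}


def outlier_trimmed_metrics(y_true: Sequence[float], y_pred: Sequence[float],
                            fraction: float = 0.10) -> dict[str, float]:
    """Regression metrics after dropping the worst-predicted fraction.

    ceil(fraction * n) records with the largest absolute residual are
    removed (ties broken by record order) before recomputing.
    """
    if not 0 <= fraction < 1:
        raise ValueError("fraction must be in [0, 1)")
    yt = np.asarray(y_true, dtype=float)
    yp = np.asarray(y_pred, dtype=float)
    n_drop = int(np.ceil(fraction * len(yt)))
    if n_drop:
        resid = np.abs(yt - yp)
        # stable sort keeps record order among ties
        order = np.argsort(-resid, kind="stable")
        drop = set(order[:n_drop].tolist())
        keep = np.array([i not in drop for i in range(len(yt))])
        yt, yp = yt[keep], yp[keep]
    out = evaluate_regression(yt, yp)
    out["n_used"] = int(len(yt))
    out["trim_fraction"] = fraction
    return out


def evaluate_hotspot(pred_ddg: Sequence[float], true_ddg: Sequence[float],
                     cutoff: float) -> dict[str, float]:
    """Hot-spot benchmark metrics: both vectors binarized at the cutoff."""
    yp = np.asarray(pred_ddg, dtype=float)
    yt = np.asarray(true_ddg, dtype=float)
    if len(yt) == 0:
        raise ValueError("no records to evaluate")
    true_hot = yt <= cutoff
    pred_hot = yp <= cutoff
    tp = int(np.sum(true_hot & pred_hot))
    fp = int(np.sum(~true_hot & pred_hot))
    tn = int(np.sum(~true_hot & ~pred_hot))
    fn = int(np.sum(true_hot & ~pred_hot))
    return confusion_metrics(tp, fp, tn, fn)


# ---------------------------------------------------------------------------
# feature selection and validation

def _group_cv_pearson(features: pd.DataFrame, targets: np.ndarray,
                      groups: np.ndarray, config: ModelConfig,
                      k: int = 5) -> float:
    preds = _pooled_oof_predictions(features, targets, groups,
                                    CVScheme("group-k-fold", k), config)
    if np.std(preds) == 0:
        return 0.0
    return float(stats.pearsonr(targets, preds)[0])


def greedy_forward_selection(features: pd.DataFrame, targets: Sequence[float],
                             groups: Sequence[str],
                             config: ModelConfig = ModelConfig(),
                             k: int = 5) -> list[str]:
    """Bottom-up greedy feature selection by group-CV Pearson correlation.

    Starts empty; each round adds the candidate that maximizes the pooled
    group-k-fold CV Pearson of the configured model; stops when the
    improvement falls below the configured threshold or the cap (default
    13 features) is reached.  Ties break by schema order.
    """
    y = np.asarray(targets, dtype=float)
    g = np.asarray(groups)
    if np.std(y) == 0:
        raise ValueError("degenerate target: zero variance")
    if features.shape[1] == 0:
        raise ValueError("no candidate features")
    selected: list[str] = []
    best_score = -np.inf
    candidates = list(features.columns)
    while len(selected) < config.max_selected_features and candidates:
        round_best, round_feat = -np.inf, None
        for name in candidates:
            score = _group_cv_pearson(features[selected + [name]], y, g,
                                      config, k)
            if score > round_best:
                round_best, round_feat = score, name
        if round_feat is None:
            break
        if best_score > -np.inf and \
                round_best - best_score < config.selection_min_improvement:
            break
        selected.append(round_feat)
        candidates.remove(round_feat)
        best_score = round_best
    return selected


def _pooled_oof_predictions(features: pd.DataFrame, targets: np.ndarray,
                            groups: np.ndarray, scheme: CVScheme,
                            config: ModelConfig) -> np.ndarray:
    x = features.to_numpy(dtype=float)
    splitter = scheme.splitter()
    n_groups = len(np.unique(groups))
    if scheme.kind == "group-k-fold" and n_groups < scheme.k:
        raise ValueError(
            f"{n_groups} groups cannot be split into {scheme.k} folds")
    preds = np.full(len(targets), np.nan)
    for train_idx, test_idx in splitter.split(x, targets, groups):
        est = config.build()
        est.fit(x[train_idx], targets[train_idx])
        preds[test_idx] = est.predict(x[test_idx])
    assert not np.isnan(preds).any(), "incomplete out-of-fold coverage"
    return preds


@dataclass
class EvalReport:
    """Bundled metrics for one validation run."""

    regression: dict[str, float]
    regression_trimmed: dict[str, float]
    classification: dict[str, float] | None
    n_used: int
    scheme: str
    per_fold: list[dict[str, float]] = field(default_factory=list)


def cross_validate(features: pd.DataFrame, targets: Sequence[float],
                   groups: Sequence[str],
                   scheme: CVScheme = CVScheme(),
                   config: ModelConfig = ModelConfig(),
                   trim_fraction: float = 0.10,
                   ) -> tuple[EvalReport, np.ndarray]:
    """Group-aware cross-validation with pooled out-of-fold predictions.

    Every record is predicted exactly once while its whole group is held
    out.  Returns the metric bundle and the pooled predictions.
    """
    y = np.asarray(targets, dtype=float)
    g = np.asarray(groups)
    preds = _pooled_oof_predictions(features, y, g, scheme, config)
    per_fold = []
    for train_idx, test_idx in scheme.splitter().split(features, y, g):
        if len(test_idx) >= 3 and np.std(y[test_idx]) > 0 \
                and np.std(preds[test_idx]) > 0:
            per_fold.append(evaluate_regression(y[test_idx], preds[test_idx]))
    try:
        classification = classification_by_regression(y, preds)
    except ValueError:
        classification = None
    report = EvalReport(
        regression=evaluate_regression(y, preds),
        regression_trimmed=outlier_trimmed_metrics(y, preds, trim_fraction),
        classification=classification,
        n_used=len(y),
        scheme=f"{scheme.kind}(k={scheme.k})",
        per_fold=per_fold,
    )
    return report, preds


# ---------------------------------------------------------------------------
# trained model bundle

def schema_hash(feature_names: Sequence[str]) -> str:
    return hashlib.sha256("\n".join(feature_names).encode()).hexdigest()[:16]


@dataclass
class TrainedModel:
    """A fitted estimator plus the feature schema it expects."""

    estimator: object
    feature_names: list[str]
    config: ModelConfig
    schema_hash: str

    def predict(self, features: pd.DataFrame) -> np.ndarray:
        missing = [c for c in self.feature_names if c not in features.columns]
        if missing:
            raise SchemaMismatchError(
                f"feature table lacks columns {missing[:5]}...")
        if schema_hash(self.feature_names) != self.schema_hash:
            raise SchemaMismatchError("model bundle schema hash mismatch")
        x = features[self.feature_names].to_numpy(dtype=float)
        return np.asarray(self.estimator.predict(x), dtype=float)

    def save(self, path: str) -> None:
        joblib.dump({"estimator": self.estimator,
                     "feature_names": self.feature_names,
                     "config": self.config,
                     "schema_hash": self.schema_hash}, path)

    @classmethod
    def load(cls, path: str) -> "TrainedModel":
        blob = joblib.load(path)
        return cls(estimator=blob["estimator"],
                   feature_names=blob["feature_names"],
                   config=blob["config"],
                   schema_hash=blob["schema_hash"])


def train(features: pd.DataFrame, targets: Sequence[float],
          config: ModelConfig = ModelConfig(),
          feature_names: Sequence[str] | None = None) -> TrainedModel:
    """Fit the configured estimator on (optionally selected) features."""
    names = list(feature_names) if feature_names is not None \
        else list(features.columns)
    est = config.build()
    est.fit(features[names].to_numpy(dtype=float),
            np.asarray(targets, dtype=float))
    return TrainedModel(estimator=est, feature_names=names, config=config,
                        schema_hash=schema_hash(names))
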