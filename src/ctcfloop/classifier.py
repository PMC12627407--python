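"""Gradient-boosted loop classifier: training, scoring, evaluation,
feature importance, and single-file model persistence.

The model is a binary XGBoost classifier over the loop feature matrix
(logistic objective). Defaults — 300 trees, depth 4, learning rate 0.1 —
are deliberately plain and fully exposed; single-threaded histogram
training makes runs bit-reproducible for a given seed.

The feature schema (column names, in order) is frozen at training time and
serialized with the model; any predict-time mismatch is a hard error that
names the differing columns. Training requires complete rows; at predict
time an absent anchor-motif score is imputed with a sentinel one unit
below the minimum score seen in training, pushing such loops toward the
unbound regime rather than the middle of the score range.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.metrics import average_precision_score, roc_auc_score
from sklearn.model_selection import train_test_split

__all__ = [
    "DEFAULT_HYPERPARAMS",
    "TrainedLoopModel",
    "EvalReport",
    "split_train_test",
    "train",
    "predict_scores",
    "evaluate",
    "feature_importance",
    "save_model",
    "load_model",
]

DEFAULT_HYPERPARAMS: dict = {
    "n_estimators": 300,
    "max_depth": 4,
    "learning_rate": 0.1,
    "objective": "binary:logistic",
    # allow pure leaves to keep refining on separable data so probabilities
    # can saturate toward 0/1 — the regime the discordance thresholds
    # (0.0005 / 0.999) presume
    "min_child_weight": 0,
}

# Columns eligible for sentinel imputation of missing values at predict
# time (anchors without an assigned motif).
_IMPUTABLE = ("start_motif_score", "end_motif_score")


@dataclass
class TrainedLoopModel:
    """A fitted booster plus everything needed to reuse it safely."""

    booster: xgb.Booster
    feature_names: list[str]
    hyperparams: dict
    seed: int
    impute: dict[str, float]
    importances: dict[str, float] = field(default_factory=dict)


def split_train_test(
    labels: Sequence, fraction: float = 2 / 3, seed: int = 0
) -> tuple[np.ndarray, np.ndarray]:
    """Stratified train/test index split.

    Returns disjoint, exhaustive index arrays with ``fraction`` of the
    examples (rounded) in the training part and class proportions
    preserved. Reproducible for a given seed. A single-class input is
    fatal — nothing could be learned or evaluated from it.
    """
    y = np.asarray(labels)
    if len(y) < 3:
        raise ValueError("need at least 3 examples to split")
    if len(np.unique(y)) < 2:
        raise ValueError("cannot split a single-class dataset")
    idx = np.arange(len(y))
    train_idx, test_idx = train_test_split(
        idx, train_size=fraction, stratify=y, random_state=seed, shuffle=True
    )
    return np.sort(train_idx), np.sort(test_idx)


def _check_schema(feature_names: Sequence[str]) -> None:
    leaked = [c for c in feature_names if "rad21" in c.lower()]
    if leaked:
        raise ValueError(
            f"RAD21-derived columns in the feature schema would leak the "
            f"label into the model: {leaked}"
        )


def _booster_params(hyperparams: Mapping, seed: int) -> tuple[dict, int]:
    hp = dict(DEFAULT_HYPERPARAMS)
    hp.update(hyperparams or {})
    rounds = int(hp.pop("n_estimators"))
    params = {
        "objective": hp.pop("objective"),
        "max_depth": int(hp.pop("max_depth")),
        "eta": float(hp.pop("learning_rate")),
        "tree_method": "hist",
        "nthread": 1,
        "seed": int(seed) % (2**31),
    }
    params.update(hp)  # anything else passes straight through to xgboost
    return params, rounds


def train(
    matrix: pd.DataFrame,
    labels: Sequence,
    hyperparams: Mapping | None = None,
    seed: int = 0,
) -> TrainedLoopModel:
    """Fit the loop classifier on a complete feature matrix.

    ``labels`` are 0/1 (or booleans). Deterministic for a given seed.
    """
    y = np.asarray(labels, dtype=float)
    if len(matrix) != len(y):
        raise ValueError("matrix and labels lengths differ")
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both classes")
    _check_schema(matrix.columns)
    if matrix.isna().any().any():
        bad = list(matrix.columns[matrix.isna().any()])
        raise ValueError(f"training matrix has missing values in {bad}")
    params, rounds = _booster_params(hyperparams or {}, seed)
    dtrain = xgb.DMatrix(
        matrix.to_numpy(dtype=float), label=y, feature_names=list(matrix.columns)
    )
    booster = xgb.train(params, dtrain, num_boost_round=rounds)
    impute = {
        col: float(matrix[col].min()) - 1.0
        for col in _IMPUTABLE
        if col in matrix.columns
    }
    model = TrainedLoopModel(
        booster=booster,
        feature_names=list(matrix.columns),
        hyperparams={**DEFAULT_HYPERPARAMS, **(dict(hyperparams) if hyperparams else {})},
        seed=int(seed),
        impute=impute,
    )
    model.importances = dict(feature_importance(model))
    return model


def predict_scores(model: TrainedLoopModel, matrix: pd.DataFrame) -> np.ndarray:
    """Per-loop positive-class probability, row order preserved.

    The matrix schema must equal the training schema exactly; missing
    anchor-motif scores are filled with the training sentinel.
    """
    got, want = list(matrix.columns), list(model.feature_names)
    if got != want:
        missing = [c for c in want if c not in got]
        extra = [c for c in got if c not in want]
        raise ValueError(
            f"feature schema mismatch: missing {missing}, unexpected {extra}, "
            f"expected order {want}"
        )
    if len(matrix) == 0:
        return np.empty(0, dtype=float)
    filled = matrix.copy()
    for col, sentinel in model.impute.items():
        filled[col] = filled[col].fillna(sentinel)
    if filled.isna().any().any():
        bad = list(filled.columns[filled.isna().any()])
        raise ValueError(f"missing values in non-imputable columns {bad}")
    dmat = xgb.DMatrix(filled.to_numpy(dtype=float), feature_names=want)
    return model.booster.predict(dmat)


@dataclass(frozen=True)
class EvalReport:
    """Threshold metrics plus ranking metrics for one evaluation.

    ``roc_auc`` / ``pr_auc`` are None (undefined) when only one class is
    present in the labels.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    precision: float
    recall: float
    f_score: float
    roc_auc: float | None
    pr_auc: float | None

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.tn + self.fn


def evaluate(
    scores: Sequence[float], labels: Sequence, threshold: float = 0.5
) -> EvalReport:
    """Precision / recall / F at ``threshold``, plus ROC-AUC (trapezoid
    over the ROC curve) and PR-AUC (average precision)."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels, dtype=int)
    if len(s) != len(y):
        raise ValueError("scores and labels lengths differ")
    if len(s) and (np.any(~np.isfinite(s)) or s.min() < 0 or s.max() > 1):
        raise ValueError("scores must be finite and in [0, 1]")
    pred = s >= threshold
    tp = int(np.sum(pred & (y == 1)))
    fp = int(np.sum(pred & (y == 0)))
    fn = int(np.sum(~pred & (y == 1)))
    tn = int(np.sum(~pred & (y == 0)))
    precision = tp / (tp + fp) if tp + fp else 0.0
    recall = tp / (tp + fn) if tp + fn else 0.0
    f_score = (
        2 * precision * recall / (precision + recall) if precision + recall else 0.0
    )
    if len(np.unique(y)) < 2:
        roc = pr = None
    else:
        roc = float(roc_auc_score(y, s))
        pr = float(average_precision_score(y, s))
    return EvalReport(
        tp=tp, fp=fp, tn=tn, fn=fn,
        precision=precision, recall=recall, f_score=f_score,
        roc_auc=roc, pr_auc=pr,
    )


def feature_importance(model: TrainedLoopModel) -> list[tuple[str, float]]:
    """(feature, importance) pairs, total-gain importances normalized to
    sum 1, descending; ties break by schema order. Features the booster
    never split on get importance 0."""
    raw = model.booster.get_score(importance_type="total_gain")
    gains = np.array([raw.get(name, 0.0) for name in model.feature_names])
    total = gains.sum()
    if total > 0:
        gains = gains / total
    else:  # a constant model: no splits anywhere
        gains = np.full(len(gains), 1.0 / max(len(gains), 1))
    order = sorted(
        range(len(gains)), key=lambda i: (-gains[i], i)
    )
    return [(model.feature_names[i], float(gains[i])) for i in order]


def save_model(model: TrainedLoopModel, path: str | Path) -> None:
    """Serialize the model to a single JSON file: booster, schema,
    hyperparameters, seed, imputation sentinels, importances."""
    payload = {
        "format": "ctcfloop-model",
        "kind": "loop",
        "feature_names": model.feature_names,
        "hyperparams": model.hyperparams,
        "seed": model.seed,
        "impute": model.impute,
        "importances": model.importances,
        "booster": json.loads(bytes(model.booster.save_raw(raw_format="json"))),
    }
    Path(path).write_text(json.dumps(payload))


def load_model(path: str | Path) -> TrainedLoopModel:
    payload = json.loads(Path(path).read_text())
    if payload.get("format") != "ctcfloop-model" or payload.get("kind") != "loop":
        raise ValueError(f"{path} is not a serialized loop model")
    booster = xgb.Booster()
    booster.load_model(bytearray(json.dumps(payload["booster"]), "utf-8"))
    return TrainedLoopModel(
        booster=booster,
        feature_names=list(payload["feature_names"]),
        hyperparams=dict(payload["hyperparams"]),
        seed=int(payload["seed"]),
        impute={k: float(v) for k, v in payload["impute"].items()},
        importances={k: float(v) for k, v in payload["importances"].items()},
    )
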