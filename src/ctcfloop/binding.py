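"""Windowed CTCF-binding prediction with a Random Forest.

Each candidate CTCF binding site (a FIMO motif hit) is described by a
fixed 500-bp span centred on the motif midpoint, tiled into twenty 25-bp
bins. For every configured epigenomic track each bin carries a 0/1 flag —
whether any track interval overlaps that bin — and the motif's FIMO score
is appended, giving a ``20 * n_tracks + 1`` column matrix. Sites are
labeled *bound* when the motif overlaps a CTCF ChIP-seq peak by >= 1 bp.

A Random Forest (500 trees, sqrt features per split) maps these matrices
to binding probabilities, which can in turn replace CTCF ChIP presence in
the loop feature matrix when ChIP data for a condition is unavailable
(see :func:`ctcfloop.features.substitute_binding_predictions`).

Three evaluation regimes mirror a multi-sample study design: a 2/3–1/3
self-split within one sample, leave-one-sample-out across controls, and
all-controls → case.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .classifier import EvalReport, evaluate, split_train_test
from .io import GenomicInterval, MotifHit
from .windows import IntervalIndex

__all__ = [
    "BINDING_PRESETS",
    "DEFAULT_SPAN",
    "DEFAULT_BIN",
    "binding_columns",
    "build_site_matrix",
    "build_binding_matrix",
    "label_sites",
    "TrainedBindingModel",
    "train_binding_model",
    "predict_binding",
    "self_split_eval",
    "leave_one_out_eval",
    "controls_to_case_eval",
]

DEFAULT_SPAN = 500
DEFAULT_BIN = 25

BINDING_PRESETS: dict[str, tuple[str, ...]] = {
    # cell-line design: accessibility, four histone marks, methylation
    "cellline": ("dnase", "h3k4me1", "h3k9me3", "h3k27me3", "h3k27ac", "methylation"),
    # brain-tissue design: accessibility plus three histone marks
    "ad": ("dnase", "h3k4me3", "h3k27me3", "h3k27ac"),
}


def binding_columns(
    tracks: Sequence[str], span: int = DEFAULT_SPAN, bin_size: int = DEFAULT_BIN
) -> list[str]:
    n_bins = span // bin_size
    cols = [f"{t}_bin{b:02d}" for t in tracks for b in range(n_bins)]
    cols.append("fimo_score")
    return cols


def build_site_matrix(
    site: MotifHit,
    tracks: Mapping[str, IntervalIndex],
    span: int = DEFAULT_SPAN,
    bin_size: int = DEFAULT_BIN,
) -> dict[str, float]:
    """Per-bin overlap flags around one site, plus its FIMO score.

    Bin ``b`` covers ``[mid - span/2 + b*bin, mid - span/2 + (b+1)*bin)``.
    Bins falling left of the chromosome start are clamped away and read 0.
    """
    if span % bin_size != 0:
        raise ValueError(f"span {span} not divisible by bin size {bin_size}")
    n_bins = span // bin_size
    mid = site.interval.midpoint
    left = mid - span // 2
    vec: dict[str, float] = {}
    for track, index in tracks.items():
        for b in range(n_bins):
            s = left + b * bin_size
            e = s + bin_size
            if e <= 0:
                flag = 0.0
            else:
                iv = GenomicInterval(site.chrom, max(0, s), e)
                flag = float(index.any_overlap(iv))
            vec[f"{track}_bin{b:02d}"] = flag
    vec["fimo_score"] = site.fimo_score
    return vec


def build_binding_matrix(
    sites: Sequence[MotifHit],
    tracks: Mapping[str, IntervalIndex],
    track_order: Sequence[str] | None = None,
    span: int = DEFAULT_SPAN,
    bin_size: int = DEFAULT_BIN,
) -> pd.DataFrame:
    """Stack per-site matrices into one DataFrame in fixed column order."""
    order = list(track_order) if track_order is not None else sorted(tracks)
    missing = [t for t in order if t not in tracks]
    if missing:
        raise KeyError(f"configured tracks missing: {missing}")
    cols = binding_columns(order, span, bin_size)
    sub = {t: tracks[t] for t in order}
    rows = [build_site_matrix(s, sub, span, bin_size) for s in sites]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def label_sites(sites: Sequence[MotifHit], ctcf_peaks: IntervalIndex) -> np.ndarray:
    """1 where the motif interval overlaps a CTCF peak by >= 1 bp."""
    return np.array(
        [int(ctcf_peaks.any_overlap(s.interval)) for s in sites], dtype=int
    )


@dataclass
class TrainedBindingModel:
    forest: RandomForestClassifier
    feature_names: list[str]
    seed: int


def train_binding_model(
    matrix: pd.DataFrame,
    labels: Sequence,
    seed: int = 0,
    n_estimators: int = 500,
) -> TrainedBindingModel:
    """Fit the Random Forest binding predictor (sqrt features per split)."""
    y = np.asarray(labels, dtype=int)
    if len(np.unique(y)) < 2:
        raise ValueError("training requires both bound and unbound sites")
    forest = RandomForestClassifier(
        n_estimators=n_estimators,
        max_features="sqrt",
        random_state=int(seed) % (2**31),
        n_jobs=1,
    )
    forest.fit(matrix.to_numpy(dtype=float), y)
    return TrainedBindingModel(
        forest=forest, feature_names=list(matrix.columns), seed=int(seed)
    )


def predict_binding(
    model: TrainedBindingModel, matrix: pd.DataFrame
) -> np.ndarray:
    """Per-site bound probability; schema must match training exactly."""
    if list(matrix.columns) != model.feature_names:
        raise ValueError(
            f"binding feature schema mismatch: got {list(matrix.columns)}, "
            f"expected {model.feature_names}"
        )
    if len(matrix) == 0:
        return np.empty(0, dtype=float)
    return model.forest.predict_proba(matrix.to_numpy(dtype=float))[:, 1]


def self_split_eval(
    matrix: pd.DataFrame,
    labels: Sequence,
    fraction: float = 2 / 3,
    seed: int = 0,
) -> EvalReport:
    """Train on a stratified ``fraction`` of one sample's sites, evaluate
    on the remainder."""
    y = np.asarray(labels, dtype=int)
    tr, te = split_train_test(y, fraction=fraction, seed=seed)
    model = train_binding_model(matrix.iloc[tr], y[tr], seed=seed)
    return evaluate(predict_binding(model, matrix.iloc[te]), y[te])


def leave_one_out_eval(
    matrices: Mapping[str, pd.DataFrame],
    labels: Mapping[str, Sequence],
    seed: int = 0,
) -> dict[str, EvalReport]:
    """For each sample, train on all the others and evaluate on it."""
    names = sorted(matrices)
    if set(names) != set(labels):
        raise ValueError("matrices and labels must cover the same samples")
    out: dict[str, EvalReport] = {}
    for held_out in names:
        rest = [n for n in names if n != held_out]
        x_train = pd.concat([matrices[n] for n in rest], ignore_index=True)
        y_train = np.concatenate([np.asarray(labels[n], dtype=int) for n in rest])
        model = train_binding_model(x_train, y_train, seed=seed)
        scores = predict_binding(model, matrices[held_out])
        out[held_out] = evaluate(scores, np.asarray(labels[held_out], dtype=int))
    return out


def controls_to_case_eval(
    control_matrices: Mapping[str, pd.DataFrame],
    control_labels: Mapping[str, Sequence],
    case_matrix: pd.DataFrame,
    case_labels: Sequence,
    seed: int = 0,
) -> tuple[EvalReport, np.ndarray]:
    """Pool every control sample as training, evaluate on the case.

    Returns the report and the per-site case probabilities (reusable as
    substitute CTCF features downstream).
    """
    names = sorted(control_matrices)
    x_train = pd.concat([control_matrices[n] for n in names], ignore_index=True)
    y_train = np.concatenate(
        [np.asarray(control_labels[n], dtype=int) for n in names]
    )
    model = train_binding_model(x_train, y_train, seed=seed)
    scores = predict_binding(model, case_matrix)
    return evaluate(scores, np.asarray(case_labels, dtype=int)), scores
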