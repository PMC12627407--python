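"""Turn candidate loops into named numeric feature vectors.

The feature vector of a loop holds the FIMO scores of its two anchor
motifs, the loop span in bp, and one binary presence flag per configured
epigenomic mark per evaluation window (start anchor, end anchor,
interloop). Presence means >= 1 track interval overlaps the window; a
degenerate (empty) interloop yields 0 for every interloop flag. Presence
stays binary no matter how many peaks overlap.

Two named presets cover the two study designs:

* ``cellline`` — CTCF plus h3k4me1 / h3k9me3 / h3k27me3 / h3k27ac, for
  ChIA-PET loops with 1000-bp anchor windows;
* ``ad`` — CTCF plus DNase / h3k4me3 / h3k27me3 / h3k27ac, for Hi-C loops
  with 500-bp anchor windows.

When a windowed CTCF-binding predictor is available, its per-motif
probabilities can replace (or sit alongside) the ChIP-derived CTCF anchor
flags via :func:`substitute_binding_predictions`, turning those columns
continuous in [0, 1].

RAD21 is a labeling signal, never a feature; a schema containing it is
rejected outright.
"""

from __future__ import annotations

from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .labeling import CandidateLoop
from .windows import IntervalIndex

__all__ = [
    "PRESETS",
    "WINDOW_NAMES",
    "feature_columns",
    "extract_features",
    "build_feature_matrix",
    "substitute_binding_predictions",
    "motif_key",
]

PRESETS: dict[str, tuple[str, ...]] = {
    "cellline": ("ctcf", "h3k4me1", "h3k9me3", "h3k27me3", "h3k27ac"),
    "ad": ("ctcf", "dnase", "h3k4me3", "h3k27me3", "h3k27ac"),
}

WINDOW_NAMES = ("start", "end", "interloop")

_BASE_COLUMNS = ("start_motif_score", "end_motif_score", "loop_span")


def _check_marks(marks: Sequence[str]) -> None:
    for mark in marks:
        if "rad21" in mark.lower():
            raise ValueError(
                "RAD21 defines labels and must never appear among features"
            )


def feature_columns(marks: Sequence[str]) -> list[str]:
    """The fixed column order for a mark set: motif scores, span, then
    ``presence_{mark}_{window}`` in mark-major order."""
    _check_marks(marks)
    cols = list(_BASE_COLUMNS)
    for mark in marks:
        for window in WINDOW_NAMES:
            cols.append(f"presence_{mark}_{window}")
    return cols


def extract_features(
    cand: CandidateLoop,
    tracks: Mapping[str, IntervalIndex],
    marks: Sequence[str],
) -> dict[str, float]:
    """The named feature vector of one candidate loop.

    Pure and deterministic: identical inputs give a bit-identical vector.
    A configured mark missing from ``tracks`` is fatal.
    """
    _check_marks(marks)
    for mark in marks:
        if mark not in tracks:
            raise KeyError(f"configured mark {mark!r} missing from tracks")
    wl = cand.windowed
    vec: dict[str, float] = {
        "start_motif_score": (
            cand.start_motif.fimo_score if cand.start_motif is not None else np.nan
        ),
        "end_motif_score": (
            cand.end_motif.fimo_score if cand.end_motif is not None else np.nan
        ),
        "loop_span": float(wl.span),
    }
    window_ivs = {
        "start": wl.start_window,
        "end": wl.end_window,
        "interloop": wl.interloop,  # None when degenerate -> flag 0
    }
    for mark in marks:
        index = tracks[mark]
        for wname, iv in window_ivs.items():
            vec[f"presence_{mark}_{wname}"] = float(index.any_overlap(iv))
    return vec


def build_feature_matrix(
    cands: Sequence[CandidateLoop],
    tracks: Mapping[str, IntervalIndex],
    marks: Sequence[str] | str = "cellline",
) -> pd.DataFrame:
    """Feature matrix for a collection of candidates, one row per loop,
    columns in the fixed schema order. ``marks`` may be a preset name."""
    if isinstance(marks, str):
        marks = PRESETS[marks]
    cols = feature_columns(marks)
    rows = [extract_features(c, tracks, marks) for c in cands]
    if not rows:
        return pd.DataFrame(columns=cols)
    return pd.DataFrame(rows, columns=cols)


def motif_key(cand_motif) -> tuple[str, int, int]:
    """Stable identity of an anchor motif: (chrom, start, end)."""
    iv = cand_motif.interval
    return (iv.chrom, iv.start, iv.end)


def substitute_binding_predictions(
    matrix: pd.DataFrame,
    cands: Sequence[CandidateLoop],
    site_scores: Mapping[tuple[str, int, int], float],
    mode: Literal["replace", "augment"] = "replace",
) -> pd.DataFrame:
    """Inject predicted CTCF-binding probabilities for the anchor motifs.

    ``site_scores`` maps a motif's (chrom, start, end) to a probability in
    [0, 1]. With ``mode="replace"`` the binary ``presence_ctcf_start/end``
    flags become those probabilities (idempotent); with ``mode="augment"``
    two new columns ``pred_ctcf_start`` / ``pred_ctcf_end`` are appended.
    A missing probability for any anchor motif is fatal.
    """
    if len(matrix) != len(cands):
        raise ValueError("matrix and candidate list lengths differ")
    probs = np.empty((len(cands), 2))
    missing: list[tuple] = []
    for i, cand in enumerate(cands):
        for j, motif in enumerate((cand.start_motif, cand.end_motif)):
            if motif is None:
                missing.append((i, "start" if j == 0 else "end"))
                continue
            key = motif_key(motif)
            if key not in site_scores:
                missing.append(key)
                continue
            p = float(site_scores[key])
            if not (0.0 <= p <= 1.0):
                raise ValueError(f"predicted probability out of [0,1] for {key}: {p}")
            probs[i, j] = p
    if missing:
        raise KeyError(f"no predicted binding probability for motifs: {missing[:5]}")
    out = matrix.copy()
    if mode == "replace":
        out["presence_ctcf_start"] = probs[:, 0]
        out["presence_ctcf_end"] = probs[:, 1]
    elif mode == "augment":
        out["pred_ctcf_start"] = probs[:, 0]
        out["pred_ctcf_end"] = probs[:, 1]
    else:
        raise ValueError(f"mode must be 'replace' or 'augment', got {mode!r}")
    return out
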