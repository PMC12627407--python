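"""High-confidence loop labeling and negative-example sampling.

A candidate loop is called *positive* when

a. the best CTCF motifs in its two anchor windows are convergently
   oriented (``+`` at the upstream anchor, ``-`` at the downstream one —
   the loop-extrusion geometry),
b. both anchor motifs are occupied by CTCF (overlap a CTCF ChIP-seq peak
   by >= 1 bp), and
c. cohesin is present: a RAD21 peak overlaps at least one of the loop
   windows (by default any of start / end / interloop; an anchors-only
   mode is available).

RAD21 enters *only* here — it is never a classifier feature, otherwise the
label would leak into the model.

Negative examples are sampled pairs of unbound CTCF motifs (no CTCF peak
on either motif, no RAD21 in any loop window), with spans drawn to match
the positive span distribution by quantile-bin matching.
"""

from __future__ import annotations

import bisect
import warnings
from dataclasses import dataclass, replace
from typing import Iterable, Literal, Sequence

import numpy as np

from .io import GenomicInterval, LoopCall, MotifHit
from .windows import IntervalIndex, WindowedLoop, make_windowed_loop

__all__ = [
    "CandidateLoop",
    "assign_anchor_motif",
    "build_candidates",
    "is_convergent",
    "label_loop",
    "sample_negatives",
]

Label = Literal["positive", "negative", "unlabeled"]


@dataclass(frozen=True, slots=True)
class CandidateLoop:
    """A windowed loop with its assigned anchor motifs and label."""

    windowed: WindowedLoop
    start_motif: MotifHit | None
    end_motif: MotifHit | None
    label: Label = "unlabeled"
    label_reason: str = ""

    @property
    def has_both_motifs(self) -> bool:
        return self.start_motif is not None and self.end_motif is not None


def assign_anchor_motif(
    window: GenomicInterval, motifs: IntervalIndex
) -> MotifHit | None:
    """The motif hit overlapping ``window`` with the highest FIMO score.

    Ties break to the leftmost start. Returns None when no hit overlaps.
    """
    hits: list[MotifHit] = motifs.query(window)
    if not hits:
        return None
    return min(hits, key=lambda h: (-h.fimo_score, h.interval.start))


def build_candidates(
    windowed: Iterable[WindowedLoop],
    motifs: IntervalIndex,
    require_both: bool = True,
) -> list[CandidateLoop]:
    """Assign anchor motifs to each windowed loop.

    With ``require_both`` (the default), loops lacking a motif in either
    anchor window are dropped — they cannot be CTCF loops under the model.
    """
    out: list[CandidateLoop] = []
    for wl in windowed:
        sm = assign_anchor_motif(wl.start_window, motifs)
        em = assign_anchor_motif(wl.end_window, motifs)
        if require_both and (sm is None or em is None):
            continue
        out.append(CandidateLoop(windowed=wl, start_motif=sm, end_motif=em))
    return out


def is_convergent(start_motif: MotifHit, end_motif: MotifHit) -> bool:
    """Convergent orientation: forward strand upstream, reverse downstream."""
    return start_motif.interval.strand == "+" and end_motif.interval.strand == "-"


def label_loop(
    cand: CandidateLoop,
    ctcf_peaks: IntervalIndex,
    rad21_peaks: IntervalIndex,
    rad21_windows: Literal["anchors", "all3"] = "all3",
    require_convergent: bool = True,
) -> CandidateLoop:
    """Label one candidate positive/negative by the high-confidence rule.

    ``rad21_windows`` selects whether cohesin may sit in any of the three
    loop windows or only the two anchor windows. A candidate missing an
    anchor motif stays unlabeled, with the reason recorded.
    """
    if cand.start_motif is None or cand.end_motif is None:
        return replace(cand, label="unlabeled", label_reason="missing anchor motif")
    convergent = is_convergent(cand.start_motif, cand.end_motif)
    if require_convergent and not convergent:
        return replace(cand, label="negative", label_reason="not convergent")
    bound = ctcf_peaks.any_overlap(cand.start_motif.interval) and ctcf_peaks.any_overlap(
        cand.end_motif.interval
    )
    if not bound:
        return replace(cand, label="negative", label_reason="anchor motif unbound")
    wl = cand.windowed
    rad_windows = [wl.start_window, wl.end_window]
    if rad21_windows == "all3":
        rad_windows.append(wl.interloop)
    elif rad21_windows != "anchors":
        raise ValueError(f"rad21_windows must be 'anchors' or 'all3', got {rad21_windows!r}")
    if not any(rad21_peaks.any_overlap(w) for w in rad_windows):
        return replace(cand, label="negative", label_reason="no RAD21")
    return replace(cand, label="positive", label_reason="")


def _quantile_bin_targets(
    positive_spans: Sequence[int], n: int, n_bins: int
) -> tuple[np.ndarray, np.ndarray]:
    """Bin edges over the positive span distribution and per-bin target
    counts summing to ``n``."""
    spans = np.sort(np.asarray(positive_spans, dtype=float))
    qs = np.linspace(0, 1, n_bins + 1)
    edges = np.quantile(spans, qs)
    edges[0] -= 1.0  # make the first bin left-inclusive under searchsorted
    counts = np.full(n_bins, n // n_bins)
    counts[: n % n_bins] += 1
    return edges, counts


def sample_negatives(
    motifs: Sequence[MotifHit],
    ctcf_peaks: IntervalIndex,
    rad21_peaks: IntervalIndex,
    n: int,
    span_range: tuple[int, int],
    rng_seed: int,
    half_width: int = 500,
    positive_spans: Sequence[int] | None = None,
    n_bins: int = 10,
    max_tries_factor: int = 200,
) -> list[CandidateLoop]:
    """Sample ``n`` negative candidates from unbound motif pairs.

    Pairs are same-chromosome, with midpoint span inside ``span_range``,
    neither motif overlapping a CTCF peak, and no RAD21 peak in any of the
    three loop windows. When ``positive_spans`` is given, sampled spans are
    matched to the positive span distribution by quantile bins. If fewer
    than ``n`` eligible pairs can be found within the try budget, all found
    pairs are returned with a warning.
    """
    rng = np.random.default_rng(rng_seed)
    lo, hi = span_range
    unbound = [m for m in motifs if not ctcf_peaks.any_overlap(m.interval)]
    by_chrom: dict[str, list[MotifHit]] = {}
    for m in unbound:
        by_chrom.setdefault(m.chrom, []).append(m)
    for hits in by_chrom.values():
        hits.sort(key=lambda m: m.interval.midpoint)
    chroms = sorted(by_chrom)
    if not chroms:
        warnings.warn("no unbound motifs available; returning empty sample")
        return []
    mids = {c: [m.interval.midpoint for m in by_chrom[c]] for c in chroms}

    if positive_spans is not None and len(positive_spans) > 0:
        edges, targets = _quantile_bin_targets(positive_spans, n, n_bins)
        filled = np.zeros(n_bins, dtype=int)
    else:
        edges = targets = filled = None

    out: list[CandidateLoop] = []
    seen: set[tuple] = set()
    tries = 0
    budget = max_tries_factor * max(n, 1)
    while len(out) < n and tries < budget:
        tries += 1
        chrom = chroms[rng.integers(len(chroms))]
        hits = by_chrom[chrom]
        if len(hits) < 2:
            continue
        i = int(rng.integers(len(hits)))
        a = hits[i]
        # candidate partners within the span window of a's midpoint
        lo_pos = bisect.bisect_left(mids[chrom], a.interval.midpoint + lo)
        hi_pos = bisect.bisect_right(mids[chrom], a.interval.midpoint + hi)
        if hi_pos <= lo_pos:
            continue
        b = hits[lo_pos + int(rng.integers(hi_pos - lo_pos))]
        key = (chrom, a.interval.start, b.interval.start)
        if key in seen:
            continue
        span = b.interval.midpoint - a.interval.midpoint
        if not (lo <= span <= hi):
            continue
        if edges is not None:
            bin_idx = min(
                max(int(np.searchsorted(edges, span, side="right")) - 1, 0),
                len(targets) - 1,
            )
            if filled[bin_idx] >= targets[bin_idx]:
                continue
        loop = LoopCall.normalized(
            chrom,
            (a.interval.start, a.interval.end),
            (b.interval.start, b.interval.end),
            pet_count=0,
            fdr=0.0,
        )
        wl = make_windowed_loop(loop, half_width)
        rad_windows = [wl.start_window, wl.end_window, wl.interloop]
        if any(rad21_peaks.any_overlap(w) for w in rad_windows):
            continue
        seen.add(key)
        if edges is not None:
            filled[bin_idx] += 1
        out.append(
            CandidateLoop(
                windowed=wl, start_motif=a, end_motif=b,
                label="negative", label_reason="sampled",
            )
        )
    if len(out) < n:
        warnings.warn(
            f"only {len(out)} of {n} requested negative pairs were eligible"
        )
    return out
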