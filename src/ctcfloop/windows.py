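"""Loop filtering and the three per-loop evaluation windows.

Each retained loop call is expanded into a :class:`WindowedLoop` with a
start-anchor window, an end-anchor window (both of width ``2 * half_width``
centred on the anchor midpoints) and the interloop interval between them.
Loop span is measured midpoint-to-midpoint, the only choice invariant to
anchor width. Overlap queries use half-open semantics: one shared base pair
counts.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .io import GenomicInterval, LoopCall

__all__ = [
    "WindowedLoop",
    "IntervalIndex",
    "filter_loop_calls",
    "filter_by_span",
    "make_windowed_loop",
    "build_index",
    "query_overlaps",
    "DEFAULT_MIN_SPAN",
    "DEFAULT_MAX_SPAN",
]

# Human chromatin loops are reported essentially entirely within this span
# range; both bounds are inclusive.
DEFAULT_MIN_SPAN = 2_000
DEFAULT_MAX_SPAN = 2_000_000


@dataclass(frozen=True, slots=True)
class WindowedLoop:
    """A loop call plus its three evaluation windows.

    For loops so short that the two anchor windows touch or overlap, the
    interloop interval is empty: ``interloop`` is None and ``degenerate``
    is set. Otherwise the three windows tile the region without gaps.
    """

    source: LoopCall
    start_window: GenomicInterval
    end_window: GenomicInterval
    interloop: GenomicInterval | None
    span: int

    @property
    def chrom(self) -> str:
        return self.source.chrom

    @property
    def degenerate(self) -> bool:
        return self.interloop is None


def filter_loop_calls(
    loops: Iterable[LoopCall], min_pet: int = 2, max_fdr: float = 0.05
) -> list[LoopCall]:
    """Keep loops with ``pet_count >= min_pet`` and ``fdr <= max_fdr``.

    The removal rules are read strictly: a loop with exactly ``min_pet``
    PETs or exactly ``max_fdr`` FDR survives. Input order is preserved.
    """
    if min_pet < 0:
        raise ValueError("min_pet must be >= 0")
    if not (0.0 <= max_fdr <= 1.0):
        raise ValueError("max_fdr must be in [0, 1]")
    return [lp for lp in loops if lp.pet_count >= min_pet and lp.fdr <= max_fdr]


def filter_by_span(
    windowed: Iterable[WindowedLoop],
    min_span: int = DEFAULT_MIN_SPAN,
    max_span: int = DEFAULT_MAX_SPAN,
) -> list[WindowedLoop]:
    """Keep loops with span in ``[min_span, max_span]`` (both inclusive)."""
    if min_span >= max_span:
        raise ValueError("min_span must be < max_span")
    return [wl for wl in windowed if min_span <= wl.span <= max_span]


def make_windowed_loop(loop: LoopCall, half_width: int) -> WindowedLoop:
    """Centre windows of width ``2 * half_width`` on the anchor midpoints.

    Windows are clamped at position 0. If the two anchor windows touch or
    overlap the interloop interval is empty and the loop is flagged
    degenerate.
    """
    if half_width < 1:
        raise ValueError("half_width must be >= 1")
    m1 = sum(loop.anchor1) // 2
    m2 = sum(loop.anchor2) // 2
    start_window = GenomicInterval(
        loop.chrom, max(0, m1 - half_width), m1 + half_width
    )
    end_window = GenomicInterval(
        loop.chrom, max(0, m2 - half_width), m2 + half_width
    )
    if end_window.start > start_window.end:
        interloop = GenomicInterval(loop.chrom, start_window.end, end_window.start)
    else:
        interloop = None
    return WindowedLoop(
        source=loop,
        start_window=start_window,
        end_window=end_window,
        interloop=interloop,
        span=m2 - m1,
    )


class IntervalIndex:
    """Per-chromosome interval tree over a fixed collection of items.

    Items may be bare :class:`GenomicInterval` objects or any object with
    an ``interval`` attribute (motif hits, gene records). Queries return
    exactly the stored items overlapping the query by >= 1 bp, matching a
    brute-force scan of the collection.
    """

    def __init__(self, items: Iterable) -> None:
        self._trees: dict[str, IntervalTree] = {}
        self._n = 0
        for item in items:
            iv = item if isinstance(item, GenomicInterval) else item.interval
            tree = self._trees.setdefault(iv.chrom, IntervalTree())
            tree.addi(iv.start, iv.end, item)
            self._n += 1

    def __len__(self) -> int:
        return self._n

    def query(self, interval: GenomicInterval) -> list:
        """Stored items overlapping ``interval`` by >= 1 bp, in positional
        order (start, then end)."""
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return []
        hits = tree.overlap(interval.start, interval.end)
        return [h.data for h in sorted(hits, key=lambda h: (h.begin, h.end))]

    def any_overlap(self, interval: GenomicInterval | None) -> bool:
        """True iff at least one stored item overlaps ``interval``."""
        if interval is None:
            return False
        tree = self._trees.get(interval.chrom)
        if tree is None:
            return False
        return tree.overlaps(interval.start, interval.end)


def build_index(items: Iterable) -> IntervalIndex:
    return IntervalIndex(items)


def query_overlaps(index: IntervalIndex, interval: GenomicInterval) -> list:
    return index.query(interval)
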