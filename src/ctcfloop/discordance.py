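"""Cross-condition loop comparison: discordant scores, lost/gained
classes, gene annotation and gene ranking.

Each loop scored in a control condition (s_control, averaged over control
samples) and a case condition (s_case) receives the discordant loop score

    D = (s_control - s_case)^2,

a symmetric quantity in [0, 1]. A loop is *lost* when the control score is
essentially 1 (>= tau_high) while the case score collapses below tau_lost;
*gained* when the control score is essentially 0 (<= tau_low) and the case
score exceeds tau_gained; otherwise *concordant*. The near-one/near-zero
operationalization (0.9995 / 0.0005) exists because exact 0 and 1 are
measure-zero events for a probabilistic classifier; all four thresholds
are arguments.

Loops are annotated with the single overlapping gene whose body shares the
most base pairs with the inter-anchor span (midpoint to midpoint); genes
are then ranked, separately for lost and gained loops, by the sum of D
over the discordant loops assigned to them.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io import GeneRecord, GenomicInterval
from .windows import IntervalIndex, WindowedLoop

__all__ = [
    "TAU_LOST",
    "TAU_GAINED",
    "TAU_HIGH",
    "TAU_LOW",
    "DiscordanceRecord",
    "discordant_score",
    "classify_loop",
    "annotate_loop_gene",
    "aggregate_control_scores",
    "build_discordance_records",
    "records_to_frame",
    "rank_genes",
]

TAU_LOST = 0.0005    # case score below this: looping lost
TAU_GAINED = 0.999   # case score above this: looping gained
TAU_HIGH = 0.9995    # control score "essentially 1"
TAU_LOW = 0.0005     # control score "essentially 0"

Klass = Literal["lost", "gained", "concordant"]


@dataclass(frozen=True, slots=True)
class DiscordanceRecord:
    loop: WindowedLoop
    s_control: float
    s_case: float
    d_score: float
    klass: Klass
    gene: GeneRecord | None
    overlap_bp: int


def discordant_score(s_control: float, s_case: float) -> float:
    """Squared difference of the two loop scores; symmetric, in [0, 1]."""
    for name, v in (("s_control", s_control), ("s_case", s_case)):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    return (s_control - s_case) ** 2


def classify_loop(
    s_control: float,
    s_case: float,
    tau_lost: float = TAU_LOST,
    tau_gained: float = TAU_GAINED,
    tau_high: float = TAU_HIGH,
    tau_low: float = TAU_LOW,
) -> Klass:
    """Assign exactly one of lost / gained / concordant to a score pair."""
    for name, v in (
        ("tau_lost", tau_lost), ("tau_gained", tau_gained),
        ("tau_high", tau_high), ("tau_low", tau_low),
    ):
        if not (0.0 <= v <= 1.0):
            raise ValueError(f"{name} must be in [0, 1], got {v}")
    if s_control >= tau_high and s_case < tau_lost:
        return "lost"
    if s_control <= tau_low and s_case > tau_gained:
        return "gained"
    return "concordant"


def _span_interval(loop: WindowedLoop) -> GenomicInterval:
    m1 = sum(loop.source.anchor1) // 2
    m2 = sum(loop.source.anchor2) // 2
    return GenomicInterval(loop.chrom, m1, m2)


def annotate_loop_gene(
    loop: WindowedLoop, genes: IntervalIndex, k: int = 1
) -> list[tuple[GeneRecord, int]]:
    """Top-``k`` genes by bp overlap with the loop's inter-anchor span.

    Overlap is the intersection length between the midpoint-to-midpoint
    span and the gene body; ties break to the leftmost gene start. An
    empty list means no gene overlaps the span.
    """
    span = _span_interval(loop)
    scored: list[tuple[GeneRecord, int]] = []
    for gene in genes.query(span):
        ov = min(span.end, gene.interval.end) - max(span.start, gene.interval.start)
        if ov > 0:
            scored.append((gene, ov))
    scored.sort(key=lambda t: (-t[1], t[0].interval.start, t[0].gene_id))
    return scored[:k]


def aggregate_control_scores(score_sets: Sequence[Sequence[float]]) -> np.ndarray:
    """Combine per-control-sample score vectors into one s_control per
    loop by the mean across samples. All samples must score every loop."""
    if not score_sets:
        raise ValueError("need at least one control score set")
    arrays = [np.asarray(s, dtype=float) for s in score_sets]
    n = len(arrays[0])
    for i, a in enumerate(arrays):
        if len(a) != n:
            raise ValueError(
                f"control sample {i} scored {len(a)} loops, expected {n}"
            )
        if np.any(np.isnan(a)):
            missing = list(np.flatnonzero(np.isnan(a))[:5])
            raise ValueError(f"control sample {i} missing scores at loops {missing}")
    return np.mean(arrays, axis=0)


def build_discordance_records(
    loops: Sequence[WindowedLoop],
    s_control: Sequence[float],
    s_case: Sequence[float],
    genes: IntervalIndex | None = None,
    tau_lost: float = TAU_LOST,
    tau_gained: float = TAU_GAINED,
    tau_high: float = TAU_HIGH,
    tau_low: float = TAU_LOW,
) -> list[DiscordanceRecord]:
    """Score, classify and (optionally) gene-annotate every loop."""
    sc = np.asarray(s_control, dtype=float)
    sa = np.asarray(s_case, dtype=float)
    if not (len(loops) == len(sc) == len(sa)):
        raise ValueError("loops and score vectors must have equal length")
    out: list[DiscordanceRecord] = []
    for loop, c, a in zip(loops, sc, sa):
        gene, overlap = None, 0
        if genes is not None:
            top = annotate_loop_gene(loop, genes, k=1)
            if top:
                gene, overlap = top[0]
        out.append(
            DiscordanceRecord(
                loop=loop,
                s_control=float(c),
                s_case=float(a),
                d_score=discordant_score(float(c), float(a)),
                klass=classify_loop(c, a, tau_lost, tau_gained, tau_high, tau_low),
                gene=gene,
                overlap_bp=overlap,
            )
        )
    return out


def records_to_frame(records: Iterable[DiscordanceRecord]) -> pd.DataFrame:
    """Flatten records into the on-disk discordance table layout."""
    rows = []
    for r in records:
        m1 = sum(r.loop.source.anchor1) // 2
        m2 = sum(r.loop.source.anchor2) // 2
        rows.append(
            {
                "chrom": r.loop.chrom,
                "startloop": m1,
                "endloop": m2,
                "s_control": r.s_control,
                "s_case": r.s_case,
                "d_score": r.d_score,
                "klass": r.klass,
                "gene_name": r.gene.gene_name if r.gene is not None else ".",
            }
        )
    cols = ["chrom", "startloop", "endloop", "s_control", "s_case",
            "d_score", "klass", "gene_name"]
    return pd.DataFrame(rows, columns=cols)


def rank_genes(
    records: Iterable[DiscordanceRecord], top_n: int | None = 5
) -> pd.DataFrame:
    """Rank genes by the summed discordant score of their discordant
    loops, separately for lost and gained classes.

    Genes with only concordant loops (or loops with no gene) are excluded.
    Returns columns gene_name / klass / d_score_sum / n_loops, descending
    by summed score within each class (lost first), ties by gene name.
    ``top_n=None`` returns the full ranking per class.
    """
    sums: dict[tuple[str, str], list] = {}
    for r in records:
        if r.klass == "concordant" or r.gene is None:
            continue
        key = (r.klass, r.gene.gene_name)
        entry = sums.setdefault(key, [0.0, 0])
        entry[0] += r.d_score
        entry[1] += 1
    rows = [
        {"gene_name": gene, "klass": klass, "d_score_sum": total, "n_loops": count}
        for (klass, gene), (total, count) in sums.items()
    ]
    frame = pd.DataFrame(
        rows, columns=["gene_name", "klass", "d_score_sum", "n_loops"]
    )
    if frame.empty:
        return frame
    parts = []
    for klass in ("lost", "gained"):
        part = frame[frame["klass"] == klass].sort_values(
            ["d_score_sum", "gene_name"], ascending=[False, True]
        )
        if top_n is not None:
            part = part.head(top_n)
        parts.append(part)
    return pd.concat(parts, ignore_index=True)
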