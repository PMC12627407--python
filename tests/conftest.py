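"""Shared fixtures and brute-force reference implementations.

The brute-force helpers here deliberately re-derive results by direct
O(n*m) scans and first-principles formulas, independent of the package's
indexed/vectorized code paths, so tests can compare the two routes.
"""

from __future__ import annotations

import numpy as np
import pytest

from ctcfloop.io import GenomicInterval, LoopCall, MotifHit


# ---------------------------------------------------------------------------
# brute-force oracles


def iv_of(item):
    return item if isinstance(item, GenomicInterval) else item.interval


def brute_overlaps(items, query: GenomicInterval):
    """Direct scan: every stored item sharing >= 1 bp with the query."""
    out = []
    for item in items:
        iv = iv_of(item)
        if iv.chrom == query.chrom and iv.start < query.end and query.start < iv.end:
            out.append(item)
    return out


def brute_roc_auc(scores, labels) -> float:
    """ROC-AUC as the pairwise concordance probability with 0.5 for ties."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    total = conc = 0.0
    for p in pos:
        for q in neg:
            total += 1
            if p > q:
                conc += 1
            elif p == q:
                conc += 0.5
    return conc / total


# ---------------------------------------------------------------------------
# random-instance builders


def random_intervals(rng, n, chroms=("chrA", "chrB"), max_pos=10_000, max_len=400):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            GenomicInterval(
                str(rng.choice(chroms)), start, start + int(rng.integers(1, max_len))
            )
        )
    return out


def random_motifs(rng, n, chroms=("chrA", "chrB"), max_pos=100_000, width=19):
    out = []
    for _ in range(n):
        start = int(rng.integers(0, max_pos))
        out.append(
            MotifHit(
                GenomicInterval(
                    str(rng.choice(chroms)), start, start + width,
                    str(rng.choice(["+", "-"])),
                ),
                fimo_score=float(rng.normal(15, 4)),
                p_value=float(10.0 ** -rng.uniform(3, 8)),
            )
        )
    return out


def random_loops(rng, n, chrom="chrA"):
    out = []
    for _ in range(n):
        m1 = int(rng.integers(1_000, 500_000))
        span = int(rng.integers(500, 3_000_000))
        out.append(
            LoopCall(
                chrom, (m1 - 100, m1 + 100), (m1 + span - 100, m1 + span + 100),
                pet_count=int(rng.integers(0, 10)),
                fdr=float(rng.uniform(0, 0.2)),
            )
        )
    return out


@pytest.fixture()
def rng():
    # function-scoped so every test sees the same deterministic stream
    # regardless of execution order
    return np.random.default_rng(20240917)
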