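"""Readers and writers for the genomic file formats the pipeline touches.

Supported on-disk dialects:

* ENCODE narrowPeak (BED6+4) for ChIP-seq / DNase peak calls,
* bedpe for chromatin-loop calls carrying a PET count and an FDR,
* FIMO 5.x tab-separated motif-hit tables,
* GTF2.2 gene annotation (``gene`` features only),
* the pipeline's own tab-separated result tables.

All coordinates are held internally as 0-based half-open intervals.
BED-family inputs are already in that convention; FIMO and GTF use 1-based
inclusive coordinates and are shifted on read (``start - 1``) and shifted
back on write, so every conversion is an exact inverse.

Readers are tolerant of malformed *data* lines (skipped, with a counted
warning naming the line) but strict about *structural* problems such as a
wrong column count or a missing header, which raise :class:`FormatError`.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

__all__ = [
    "FormatError",
    "GenomicInterval",
    "MotifHit",
    "LoopCall",
    "GeneRecord",
    "ReadResult",
    "read_narrowpeak",
    "read_bedpe_loops",
    "read_fimo_tsv",
    "read_gtf_genes",
    "write_tables",
    "read_table",
    "TABLE_KINDS",
]


class FormatError(ValueError):
    """A structural problem in an input file (wrong columns, bad header)."""


@dataclass(frozen=True, slots=True)
class GenomicInterval:
    """A located genomic feature, 0-based half-open.

    ``strand`` is one of ``+``, ``-`` or ``.`` (unstranded); ``score`` is
    optional and carries the narrowPeak signalValue for peak intervals.
    """

    chrom: str
    start: int
    end: int
    strand: str = "."
    score: float | None = None

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("chrom must be non-empty")
        if self.start < 0:
            raise ValueError(f"start must be >= 0, got {self.start}")
        if self.end <= self.start:
            raise ValueError(f"end must exceed start: [{self.start}, {self.end})")
        if self.strand not in ("+", "-", "."):
            raise ValueError(f"strand must be one of + - . , got {self.strand!r}")

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def midpoint(self) -> int:
        return (self.start + self.end) // 2

    def overlaps(self, other: "GenomicInterval") -> bool:
        """True iff the two intervals share >= 1 bp (half-open semantics)."""
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass(frozen=True, slots=True)
class MotifHit:
    """A FIMO-predicted CTCF binding site: a stranded interval with a
    log-odds score and a p-value."""

    interval: GenomicInterval
    fimo_score: float
    p_value: float

    def __post_init__(self) -> None:
        if self.interval.strand not in ("+", "-"):
            raise ValueError("motif hits must be stranded (+ or -)")
        if not math.isfinite(self.fimo_score):
            raise ValueError("fimo_score must be finite")
        if not (0.0 < self.p_value <= 1.0):
            raise ValueError(f"p_value must be in (0, 1], got {self.p_value}")

    @property
    def chrom(self) -> str:
        return self.interval.chrom


@dataclass(frozen=True, slots=True)
class LoopCall:
    """A raw loop record: two same-chromosome anchors plus the PET count
    and FDR reported by the upstream loop caller.

    Anchors are normalized so ``anchor1``'s midpoint does not exceed
    ``anchor2``'s.
    """

    chrom: str
    anchor1: tuple[int, int]
    anchor2: tuple[int, int]
    pet_count: int
    fdr: float

    def __post_init__(self) -> None:
        for s, e in (self.anchor1, self.anchor2):
            if s < 0 or e <= s:
                raise ValueError(f"bad anchor interval [{s}, {e})")
        if self.pet_count < 0:
            raise ValueError("pet_count must be non-negative")
        if not (0.0 <= self.fdr <= 1.0):
            raise ValueError(f"fdr must be in [0, 1], got {self.fdr}")
        m1 = sum(self.anchor1) // 2
        m2 = sum(self.anchor2) // 2
        if m1 > m2:
            raise ValueError("anchor1 midpoint must not exceed anchor2 midpoint")

    @staticmethod
    def normalized(
        chrom: str, anchor1: tuple[int, int], anchor2: tuple[int, int],
        pet_count: int, fdr: float,
    ) -> "LoopCall":
        """Build a LoopCall, swapping anchors into genomic order if needed."""
        if sum(anchor1) // 2 > sum(anchor2) // 2:
            anchor1, anchor2 = anchor2, anchor1
        return LoopCall(chrom, anchor1, anchor2, pet_count, fdr)


@dataclass(frozen=True, slots=True)
class GeneRecord:
    """One annotated gene body."""

    gene_id: str
    gene_name: str
    interval: GenomicInterval


@dataclass(slots=True)
class ReadResult:
    """Records parsed from one file plus per-line diagnostics.

    ``warnings`` holds one human-readable message (with its 1-based line
    number) per skipped data line; ``n_dropped`` counts rows removed by a
    stated rule (e.g. inter-chromosomal loops) rather than malformation.
    Row conservation: ``n_rows == len(records) + len(warnings) + n_dropped``.
    """

    records: list
    warnings: list[str] = field(default_factory=list)
    n_dropped: int = 0
    n_rows: int = 0

    def __iter__(self):
        return iter(self.records)

    def __len__(self) -> int:
        return len(self.records)


def _data_lines(path: str | Path):
    p = Path(path)
    if not p.exists():
        raise FileNotFoundError(f"input file not found: {p}")
    with open(p) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.rstrip("\n")
            if not line.strip():
                continue
            yield lineno, line


def read_narrowpeak(path: str | Path) -> ReadResult:
    """Read an ENCODE narrowPeak (BED6+4) file into intervals.

    Column 7 (signalValue) is stored as the interval score. Lines with
    inverted coordinates are skipped with a counted warning.
    """
    res = ReadResult(records=[])
    for lineno, line in _data_lines(path):
        if line.startswith(("track", "browser", "#")):
            continue
        fields = line.split("\t")
        if len(fields) < 10:
            raise FormatError(
                f"{path}:{lineno}: narrowPeak needs >= 10 columns, got {len(fields)}"
            )
        res.n_rows += 1
        chrom, start, end = fields[0], int(fields[1]), int(fields[2])
        strand = fields[5] if fields[5] in ("+", "-") else "."
        if end <= start:
            res.warnings.append(f"line {lineno}: end <= start ({start}, {end}); skipped")
            continue
        res.records.append(
            GenomicInterval(chrom, start, end, strand, score=float(fields[6]))
        )
    return res


def read_bedpe_loops(
    path: str | Path, pet_col: int = 6, fdr_col: int = 7
) -> ReadResult:
    """Read loop calls from a bedpe file.

    ``pet_col`` and ``fdr_col`` are 0-based column indices; the defaults
    match a caller that appends PET count then FDR right after the six
    coordinate columns. Anchors are normalized into genomic order;
    inter-chromosomal rows are dropped and counted in ``n_dropped``.
    """
    res = ReadResult(records=[])
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 6:
            raise FormatError(
                f"{path}:{lineno}: bedpe needs >= 6 columns, got {len(fields)}"
            )
        res.n_rows += 1
        c1, s1, e1 = fields[0], int(fields[1]), int(fields[2])
        c2, s2, e2 = fields[3], int(fields[4]), int(fields[5])
        if c1 != c2:
            res.n_dropped += 1
            continue
        try:
            pet = int(float(fields[pet_col]))
            fdr = float(fields[fdr_col])
            loop = LoopCall.normalized(c1, (s1, e1), (s2, e2), pet, fdr)
        except (ValueError, IndexError) as exc:
            res.warnings.append(f"line {lineno}: {exc}; skipped")
            continue
        res.records.append(loop)
    return res


_FIMO_REQUIRED = ("sequence_name", "start", "stop", "strand", "score", "p-value")


def read_fimo_tsv(path: str | Path) -> ReadResult:
    """Read a FIMO 5.x TSV into motif hits.

    FIMO reports 1-based inclusive coordinates; these become 0-based
    half-open as ``[start - 1, stop)``. Unstranded rows are rejected with
    a counted warning (a motif hit is stranded by construction).
    """
    lines = list(_data_lines(path))
    if not lines:
        raise FormatError(f"{path}: empty FIMO file (header expected)")
    header = lines[0][1].split("\t")
    col = {name: i for i, name in enumerate(header)}
    for required in _FIMO_REQUIRED:
        if required not in col:
            raise FormatError(f"{path}: FIMO header lacks column {required!r}")
    res = ReadResult(records=[])
    for lineno, line in lines[1:]:
        if line.startswith("#"):  # FIMO appends a comment block
            continue
        fields = line.split("\t")
        res.n_rows += 1
        strand = fields[col["strand"]]
        if strand not in ("+", "-"):
            res.warnings.append(f"line {lineno}: unstranded motif hit; skipped")
            continue
        try:
            hit = MotifHit(
                GenomicInterval(
                    fields[col["sequence_name"]],
                    int(fields[col["start"]]) - 1,
                    int(fields[col["stop"]]),
                    strand,
                ),
                fimo_score=float(fields[col["score"]]),
                p_value=float(fields[col["p-value"]]),
            )
        except ValueError as exc:
            res.warnings.append(f"line {lineno}: {exc}; skipped")
            continue
        res.records.append(hit)
    return res


def _gtf_attributes(attr: str) -> dict[str, str]:
    out: dict[str, str] = {}
    for part in attr.strip().split(";"):
        part = part.strip()
        if not part:
            continue
        key, _, value = part.partition(" ")
        out[key] = value.strip().strip('"')
    return out


def read_gtf_genes(path: str | Path) -> ReadResult:
    """Read ``gene`` features from a GTF2.2 file.

    GTF 1-based inclusive coordinates convert to ``[start - 1, end)``.
    A gene line without a ``gene_id`` attribute, or a duplicated
    ``gene_id``, is a fatal error.
    """
    res = ReadResult(records=[])
    seen: set[str] = set()
    for lineno, line in _data_lines(path):
        if line.startswith("#"):
            continue
        fields = line.split("\t")
        if len(fields) < 9:
            raise FormatError(f"{path}:{lineno}: GTF needs 9 columns, got {len(fields)}")
        if fields[2] != "gene":
            continue
        res.n_rows += 1
        attrs = _gtf_attributes(fields[8])
        if "gene_id" not in attrs:
            raise FormatError(f"{path}:{lineno}: gene feature lacks gene_id")
        gene_id = attrs["gene_id"]
        if gene_id in seen:
            raise FormatError(f"{path}:{lineno}: duplicate gene_id {gene_id!r}")
        seen.add(gene_id)
        strand = fields[6] if fields[6] in ("+", "-") else "."
        res.records.append(
            GeneRecord(
                gene_id=gene_id,
                gene_name=attrs.get("gene_name", gene_id),
                interval=GenomicInterval(
                    fields[0], int(fields[3]) - 1, int(fields[4]), strand
                ),
            )
        )
    return res


# Fixed column orders of the pipeline's own tab-separated result tables.
TABLE_KINDS: dict[str, tuple[str, ...]] = {
    "candidates": (
        "chrom", "a1_start", "a1_end", "a2_start", "a2_end",
        "pet_count", "fdr", "span", "start_motif_score", "end_motif_score",
        "label",
    ),
    "scores": ("chrom", "a1_start", "a1_end", "a2_start", "a2_end", "score"),
    "discordance": (
        "chrom", "startloop", "endloop", "s_control", "s_case",
        "d_score", "klass", "gene_name",
    ),
    "gene_ranking": ("gene_name", "klass", "d_score_sum", "n_loops"),
}


def write_tables(records, path: str | Path, kind: str) -> None:
    """Write a result table with the fixed column order for ``kind``.

    ``records`` may be a DataFrame or an iterable of mappings; floats are
    printed with 6 decimals. An empty collection yields a header-only file.
    """
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}; one of {sorted(TABLE_KINDS)}")
    columns = list(TABLE_KINDS[kind])
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame(list(records))
    if frame.empty:
        frame = pd.DataFrame(columns=columns)
    missing = [c for c in columns if c not in frame.columns]
    if missing:
        raise ValueError(f"records for kind {kind!r} lack columns {missing}")
    frame[columns].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_table(path: str | Path, kind: str) -> pd.DataFrame:
    """Read back a table written by :func:`write_tables`."""
    if kind not in TABLE_KINDS:
        raise ValueError(f"unknown table kind {kind!r}")
    frame = pd.read_csv(path, sep="\t")
    expected = list(TABLE_KINDS[kind])
    if list(frame.columns) != expected:
        raise FormatError(
            f"{path}: columns {list(frame.columns)} != expected {expected}"
        )
    return frame
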