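"""Synthetic multi-sample epigenome fixtures with a planted
feature -> loop dependency.

The generator writes the exact file dialects the pipeline reads — FIMO
TSV motif hits, per-sample narrowPeak tracks, a bedpe loop file with PET
counts and FDRs, a GTF gene annotation — plus a ground-truth table, so
every downstream module can be exercised end to end without real data.

Generative model (loop fixture)
-------------------------------
Candidate loops are laid out on synthetic chromosomes in exclusive,
non-overlapping territories so window queries never pick up a neighbour's
signal. Each *true* loop gets a convergent CTCF motif pair at its anchor
midpoints (bound-level FIMO scores), CTCF peaks over both anchor motifs,
RAD21 at its anchors, and per-mark peaks emitted per evaluation window
with probability ``P(peak | positive)``. *Negative* units are motif pairs
with random orientation, unbound-level scores, and peaks emitted with
``P(peak | negative)``. A few *filter decoys* straddle the PET/FDR
thresholds to exercise the loop filters. Spans are log-uniform over the
configured range, mimicking the broad span spectrum of real loop calls.

Case samples replay the same generative model except that a configured
fraction of true loops is *disrupted*: their CTCF and RAD21 occupancy is
deleted, while their motifs and other marks remain — the signature of a
lost loop. One gene body is planted inside each true loop's span; when
disruption is on, one gene is deliberately shared by two adjacent
disrupted loops so the gene ranking has a unique known winner (recorded
in ``meta.json``).

All randomness flows from a single integer seed through per-purpose
``numpy`` generator streams, making the emitted file set byte-identical
across runs with the same configuration.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .features import PRESETS
from .binding import BINDING_PRESETS

__all__ = [
    "SyntheticConfig",
    "BindingConfig",
    "generate_fixture",
    "generate_binding_fixture",
    "load_fixture",
    "load_binding_fixture",
    "loop_key",
]

GROUND_TRUTH_COLUMNS = (
    "loop_id", "chrom", "a1_start", "a1_end", "a2_start", "a2_end",
    "span", "status", "disrupted", "gene_id", "gene_name",
)


def _default_emission() -> dict[str, tuple[float, float]]:
    return {mark: (0.9, 0.1) for mark in PRESETS["cellline"]}


@dataclass
class SyntheticConfig:
    """Study conditions for the loop fixture.

    ``peak_emission`` maps each feature mark to ``(P(peak | positive),
    P(peak | negative))`` per evaluation window; ``rad21_emission`` is the
    same pair for the cohesin labeling track (per anchor). Loop spans are
    log-uniform over ``[min_span, max_span]``.
    """

    n_chroms: int = 4
    chrom_length: int = 250_000_000
    motif_width: int = 19
    anchor_width: int = 200
    n_true_loops: int = 200
    n_negative_pairs: int = 200
    n_filter_decoys: int = 10
    min_span: int = 2_000
    max_span: int = 2_000_000
    half_width: int = 500
    peak_emission: dict = field(default_factory=_default_emission)
    rad21_emission: tuple[float, float] = (1.0, 0.0)
    motif_score_bound: tuple[float, float] = (18.0, 3.0)
    motif_score_unbound: tuple[float, float] = (12.0, 3.0)
    n_background_genes: int = 10
    n_control_samples: int = 3
    n_case_samples: int = 1
    case_disruption: float = 0.0
    seed: int = 0

    @property
    def marks(self) -> tuple[str, ...]:
        return tuple(self.peak_emission)

    @property
    def sample_names(self) -> list[str]:
        return [f"control{i + 1}" for i in range(self.n_control_samples)] + [
            f"case{i + 1}" for i in range(self.n_case_samples)
        ]

    def is_case(self, sample: str) -> bool:
        return sample.startswith("case")


@dataclass
class _Unit:
    uid: str
    status: str              # positive | negative | filtered
    chrom: str
    m1: int                  # anchor midpoints
    m2: int
    strand1: str
    strand2: str
    score1: float
    score2: float
    p1: float
    p2: float
    pet: int
    fdr: float
    disrupted: bool = False
    gene: tuple[str, str, int, int] | None = None  # id, name, start, end


def _motif_iv(cfg: SyntheticConfig, mid: int) -> tuple[int, int]:
    s = mid - cfg.motif_width // 2
    return s, s + cfg.motif_width


def _anchor_iv(cfg: SyntheticConfig, mid: int) -> tuple[int, int]:
    h = cfg.anchor_width // 2
    return mid - h, mid + h


def _place_units(cfg: SyntheticConfig, rng: np.random.Generator) -> list[_Unit]:
    statuses = (
        ["positive"] * cfg.n_true_loops
        + ["negative"] * cfg.n_negative_pairs
        + ["filtered"] * cfg.n_filter_decoys
    )
    order = rng.permutation(len(statuses))
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    # exclusive-territory margin so no window reaches a neighbour
    margin = 4 * cfg.half_width + cfg.anchor_width
    cursors = {c: 10_000 for c in chrom_names}
    units: list[_Unit] = []
    log_lo, log_hi = math.log(cfg.min_span), math.log(cfg.max_span)
    for k, idx in enumerate(order):
        status = statuses[idx]
        chrom = chrom_names[k % cfg.n_chroms]
        span = int(round(math.exp(rng.uniform(log_lo, log_hi))))
        span = min(max(span, cfg.min_span), cfg.max_span)
        m1 = cursors[chrom] + cfg.half_width + cfg.anchor_width
        m2 = m1 + span
        end_of_territory = m2 + margin + int(rng.integers(0, 2_000))
        if end_of_territory >= cfg.chrom_length:
            raise ValueError(
                f"chromosome {chrom} overflow at unit {k}: increase "
                f"chrom_length or n_chroms"
            )
        cursors[chrom] = end_of_territory
        if status == "positive":
            strand1, strand2 = "+", "-"
            mu, sd = cfg.motif_score_bound
        else:
            if status == "negative":
                strand1, strand2 = rng.choice(["+", "-"], size=2)
            else:
                strand1, strand2 = "+", "-"
            mu, sd = cfg.motif_score_unbound
        score1, score2 = rng.normal(mu, sd, size=2)
        p1, p2 = 10.0 ** (-rng.uniform(4, 8, size=2))
        if status == "filtered":
            # straddle the PET / FDR removal thresholds
            if rng.random() < 0.5:
                pet, fdr = 1, float(rng.uniform(0.0, 0.05))
            else:
                pet, fdr = int(2 + rng.poisson(6)), float(rng.uniform(0.051, 0.5))
        else:
            pet, fdr = int(2 + rng.poisson(6)), float(rng.uniform(0.0, 0.05))
        units.append(
            _Unit(
                uid=f"L{idx:05d}", status=status, chrom=chrom, m1=m1, m2=m2,
                strand1=str(strand1), strand2=str(strand2),
                score1=float(score1), score2=float(score2),
                p1=float(p1), p2=float(p2), pet=pet, fdr=fdr,
            )
        )
    return units


def _choose_disrupted(
    cfg: SyntheticConfig, units: list[_Unit], rng: np.random.Generator
) -> None:
    positives = [u for u in units if u.status == "positive"]
    n_dis = int(round(cfg.case_disruption * len(positives)))
    if n_dis == 0:
        return
    chosen = set(
        rng.choice(len(positives), size=n_dis, replace=False).tolist()
    )
    for i in chosen:
        positives[i].disrupted = True
    if n_dis < 2:
        return
    # guarantee one adjacent same-chromosome disrupted pair to host the
    # shared gene (the known top-ranked gene)
    by_chrom: dict[str, list[_Unit]] = {}
    for u in positives:
        by_chrom.setdefault(u.chrom, []).append(u)
    for neigh in by_chrom.values():
        neigh.sort(key=lambda u: u.m1)
    def find_pair():
        for neigh in by_chrom.values():
            for a, b in zip(neigh, neigh[1:]):
                if a.disrupted and b.disrupted:
                    return a, b
        return None
    if find_pair() is None:
        # flip one disrupted loop's neighbour on, another's flag off
        for neigh in by_chrom.values():
            for a, b in zip(neigh, neigh[1:]):
                if a.disrupted and not b.disrupted:
                    donors = [u for u in positives if u.disrupted and u is not a]
                    if donors:
                        donors[-1].disrupted = False
                        b.disrupted = True
                        return
    return


def _assign_genes(cfg: SyntheticConfig, units: list[_Unit]) -> str | None:
    """Plant one gene per true loop; a shared gene over one disrupted
    pair when disruption is configured. Returns the expected top gene."""
    gene_counter = 0
    shared_gene_name: str | None = None
    by_chrom: dict[str, list[_Unit]] = {}
    for u in units:
        if u.status == "positive":
            by_chrom.setdefault(u.chrom, []).append(u)
    for neigh in by_chrom.values():
        neigh.sort(key=lambda u: u.m1)
    pair: tuple[_Unit, _Unit] | None = None
    for neigh in by_chrom.values():
        for a, b in zip(neigh, neigh[1:]):
            if a.disrupted and b.disrupted:
                pair = (a, b)
                break
        if pair:
            break
    for u in units:
        if u.status != "positive":
            continue
        if pair is not None and u in pair:
            continue
        pad = max(u.m2 - u.m1, 10) // 10
        gene_counter += 1
        u.gene = (
            f"SYNG{gene_counter:05d}", f"g{gene_counter:05d}",
            u.m1 + pad, u.m2 - pad,
        )
    if pair is not None:
        a, b = pair
        gene_counter += 1
        pad_a = max(a.m2 - a.m1, 10) // 10
        pad_b = max(b.m2 - b.m1, 10) // 10
        gid, gname = f"SYNG{gene_counter:05d}", f"g{gene_counter:05d}"
        a.gene = (gid, gname, a.m1 + pad_a, b.m2 - pad_b)
        b.gene = a.gene
        shared_gene_name = gname
    return shared_gene_name


def _narrowpeak_line(
    chrom: str, start: int, end: int, name: str, signal: float
) -> str:
    return (
        f"{chrom}\t{start}\t{end}\t{name}\t0\t.\t{signal:.2f}\t-1\t-1\t"
        f"{(end - start) // 2}"
    )


def _emit_sample_tracks(
    cfg: SyntheticConfig,
    units: Sequence[_Unit],
    is_case: bool,
    rng: np.random.Generator,
) -> dict[str, list[str]]:
    """narrowPeak lines per track for one sample."""
    tracks: dict[str, list[str]] = {m: [] for m in cfg.marks}
    tracks["rad21"] = []
    counter = 0

    def window_peak(chrom: str, lo: int, hi: int) -> tuple[int, int]:
        width = int(rng.integers(80, 180))
        width = min(width, hi - lo)
        s = int(rng.integers(lo, max(lo + 1, hi - width + 1)))
        return s, s + max(width, 1)

    for u in units:
        if u.status == "filtered":
            continue
        positive = u.status == "positive"
        disrupted_here = is_case and u.disrupted
        sw = (max(0, u.m1 - cfg.half_width), u.m1 + cfg.half_width)
        ew = (max(0, u.m2 - cfg.half_width), u.m2 + cfg.half_width)
        il = (sw[1], ew[0]) if ew[0] > sw[1] else None
        for mark in cfg.marks:
            p_pos, p_neg = cfg.peak_emission[mark]
            if mark == "ctcf":
                # anchor occupancy: peaks over the motifs themselves
                p = 0.0 if disrupted_here else (p_pos if positive else p_neg)
                for mid in (u.m1, u.m2):
                    if rng.random() < p:
                        ms, me = _motif_iv(cfg, mid)
                        counter += 1
                        tracks[mark].append(
                            _narrowpeak_line(
                                u.chrom, ms - 30, me + 30,
                                f"ctcf_{counter}", float(rng.uniform(2, 20)),
                            )
                        )
                if il is not None and rng.random() < p:
                    s, e = window_peak(u.chrom, il[0], il[1])
                    counter += 1
                    tracks[mark].append(
                        _narrowpeak_line(
                            u.chrom, s, e, f"ctcf_{counter}",
                            float(rng.uniform(2, 20)),
                        )
                    )
            else:
                p = p_pos if positive else p_neg
                for lo, hi in (sw, ew) + ((il,) if il is not None else ()):
                    if rng.random() < p:
                        s, e = window_peak(u.chrom, lo, hi)
                        counter += 1
                        tracks[mark].append(
                            _narrowpeak_line(
                                u.chrom, s, e, f"{mark}_{counter}",
                                float(rng.uniform(2, 20)),
                            )
                        )
        # cohesin: labeling-only track, per anchor
        r_pos, r_neg = cfg.rad21_emission
        p = 0.0 if disrupted_here else (r_pos if positive else r_neg)
        for mid in (u.m1, u.m2):
            if rng.random() < p:
                s, e = window_peak(u.chrom, max(0, mid - cfg.half_width),
                                   mid + cfg.half_width)
                counter += 1
                tracks["rad21"].append(
                    _narrowpeak_line(u.chrom, s, e, f"rad21_{counter}",
                                     float(rng.uniform(2, 20)))
                )
    return tracks


_FIMO_HEADER = (
    "motif_id\tmotif_alt_id\tsequence_name\tstart\tstop\tstrand\tscore\t"
    "p-value\tq-value\tmatched_sequence"
)


def _fimo_line(
    chrom: str, start0: int, end0: int, strand: str, score: float, p: float
) -> str:
    # internal half-open -> FIMO 1-based inclusive
    return (
        f"MA0139.1\tCTCF\t{chrom}\t{start0 + 1}\t{end0}\t{strand}\t"
        f"{score:.4f}\t{p:.3e}\t1.0e-02\tN"
    )


def generate_fixture(cfg: SyntheticConfig, outdir: str | Path) -> Path:
    """Write the complete loop fixture under ``outdir`` and return it.

    Layout: ``motifs.tsv``, ``loops.bedpe``, ``genes.gtf`` and
    ``ground_truth.tsv`` at the top level (shared across samples), one
    narrowPeak file per track under ``samples/<name>/``, and ``meta.json``
    recording the configuration, the disrupted loop ids and the expected
    top-ranked gene.
    """
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    placement_rng = np.random.default_rng(ss.spawn(1)[0])
    units = _place_units(cfg, placement_rng)
    _choose_disrupted(cfg, units, placement_rng)
    top_gene = _assign_genes(cfg, units)

    # --- motifs (sorted by position for readability) ---
    fimo_lines = [_FIMO_HEADER]
    for u in sorted(units, key=lambda u: (u.chrom, u.m1)):
        for mid, strand, score, p in (
            (u.m1, u.strand1, u.score1, u.p1),
            (u.m2, u.strand2, u.score2, u.p2),
        ):
            s, e = _motif_iv(cfg, mid)
            fimo_lines.append(_fimo_line(u.chrom, s, e, strand, score, p))
    (out / "motifs.tsv").write_text("\n".join(fimo_lines) + "\n")

    # --- loop calls ---
    bedpe_lines = []
    for u in units:
        a1s, a1e = _anchor_iv(cfg, u.m1)
        a2s, a2e = _anchor_iv(cfg, u.m2)
        bedpe_lines.append(
            f"{u.chrom}\t{a1s}\t{a1e}\t{u.chrom}\t{a2s}\t{a2e}\t{u.pet}\t"
            f"{u.fdr:.6f}\t{u.uid}"
        )
    (out / "loops.bedpe").write_text("\n".join(bedpe_lines) + "\n")

    # --- genes ---
    gtf_lines = []
    seen_gene_ids: set[str] = set()
    for u in units:
        if u.gene is None or u.gene[0] in seen_gene_ids:
            continue
        gid, gname, gs, ge = u.gene
        seen_gene_ids.add(gid)
        gtf_lines.append(
            f"{u.chrom}\tsynth\tgene\t{gs + 1}\t{ge}\t.\t+\t.\t"
            f'gene_id "{gid}"; gene_name "{gname}";'
        )
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    max_m2 = {c: 0 for c in chrom_names}
    for u in units:
        max_m2[u.chrom] = max(max_m2[u.chrom], u.m2)
    for i in range(cfg.n_background_genes):
        chrom = chrom_names[i % cfg.n_chroms]
        gs = max_m2[chrom] + 50_000 + 30_000 * (i // cfg.n_chroms)
        gid = f"SYNBG{i + 1:04d}"
        gtf_lines.append(
            f"{chrom}\tsynth\tgene\t{gs + 1}\t{gs + 20_000}\t.\t-\t.\t"
            f'gene_id "{gid}"; gene_name "bg{i + 1:04d}";'
        )
    (out / "genes.gtf").write_text("\n".join(gtf_lines) + "\n")

    # --- ground truth ---
    rows = []
    for u in units:
        a1s, a1e = _anchor_iv(cfg, u.m1)
        a2s, a2e = _anchor_iv(cfg, u.m2)
        rows.append(
            {
                "loop_id": u.uid, "chrom": u.chrom,
                "a1_start": a1s, "a1_end": a1e,
                "a2_start": a2s, "a2_end": a2e,
                "span": u.m2 - u.m1, "status": u.status,
                "disrupted": int(u.disrupted),
                "gene_id": u.gene[0] if u.gene else ".",
                "gene_name": u.gene[1] if u.gene else ".",
            }
        )
    truth = pd.DataFrame(rows, columns=list(GROUND_TRUTH_COLUMNS))
    truth.to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    # --- per-sample tracks ---
    sample_seeds = ss.spawn(1 + len(cfg.sample_names))[1:]
    for name, child in zip(cfg.sample_names, sample_seeds):
        rng = np.random.default_rng(child)
        tracks = _emit_sample_tracks(cfg, units, cfg.is_case(name), rng)
        sdir = out / "samples" / name
        sdir.mkdir(parents=True, exist_ok=True)
        for mark, lines in tracks.items():
            (sdir / f"{mark}.narrowPeak").write_text(
                "\n".join(lines) + ("\n" if lines else "")
            )

    meta = {
        "config": {
            **{k: v for k, v in asdict(cfg).items() if k != "peak_emission"},
            "peak_emission": {m: list(v) for m, v in cfg.peak_emission.items()},
        },
        "samples": cfg.sample_names,
        "disrupted_loops": sorted(u.uid for u in units if u.disrupted),
        "expected_top_gene": top_gene,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


def loop_key(chrom: str, a1: tuple[int, int], a2: tuple[int, int]) -> tuple:
    """Join key between a LoopCall and a ground-truth row."""
    return (chrom, a1[0], a1[1], a2[0], a2[1])


@dataclass
class LoadedFixture:
    root: Path
    meta: dict
    truth: pd.DataFrame
    sample_names: list[str]

    def track_path(self, sample: str, mark: str) -> Path:
        return self.root / "samples" / sample / f"{mark}.narrowPeak"

    @property
    def motifs_path(self) -> Path:
        return self.root / "motifs.tsv"

    @property
    def loops_path(self) -> Path:
        return self.root / "loops.bedpe"

    @property
    def genes_path(self) -> Path:
        return self.root / "genes.gtf"

    def status_by_key(self) -> dict[tuple, str]:
        return {
            loop_key(r.chrom, (r.a1_start, r.a1_end), (r.a2_start, r.a2_end)): r.status
            for r in self.truth.itertuples()
        }

    def row_by_key(self) -> dict[tuple, pd.Series]:
        return {
            loop_key(
                r["chrom"], (r["a1_start"], r["a1_end"]),
                (r["a2_start"], r["a2_end"]),
            ): r
            for _, r in self.truth.iterrows()
        }


def load_fixture(outdir: str | Path) -> LoadedFixture:
    root = Path(outdir)
    meta = json.loads((root / "meta.json").read_text())
    truth = pd.read_csv(root / "ground_truth.tsv", sep="\t")
    return LoadedFixture(
        root=root, meta=meta, truth=truth, sample_names=list(meta["samples"])
    )


# ---------------------------------------------------------------------------
# binding-site fixture


@dataclass
class BindingConfig:
    """Study conditions for the windowed binding-predictor fixture.

    ``track_emission = (P(peak | bound), P(peak | unbound))`` governs, per
    track and sample, whether a peak is emitted somewhere in the 500-bp
    span of a site.
    """

    n_chroms: int = 2
    n_sites: int = 1_000
    motif_width: int = 19
    frac_bound: float = 0.5
    span: int = 500
    bin_size: int = 25
    tracks: tuple[str, ...] = BINDING_PRESETS["ad"]
    track_emission: tuple[float, float] = (0.85, 0.15)
    fimo_bound: tuple[float, float] = (18.0, 3.0)
    fimo_unbound: tuple[float, float] = (13.0, 3.0)
    n_control_samples: int = 3
    n_case_samples: int = 1
    seed: int = 0

    @property
    def sample_names(self) -> list[str]:
        return [f"control{i + 1}" for i in range(self.n_control_samples)] + [
            f"case{i + 1}" for i in range(self.n_case_samples)
        ]


def generate_binding_fixture(cfg: BindingConfig, outdir: str | Path) -> Path:
    """Write the binding fixture: shared motifs + per-sample CTCF and
    epigenomic tracks, with bound sites carrying elevated track emission."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    ss = np.random.SeedSequence(cfg.seed)
    rng = np.random.default_rng(ss.spawn(1)[0])
    gap = cfg.span * 3
    chrom_names = [f"chr{i + 1}" for i in range(cfg.n_chroms)]
    sites = []  # (chrom, mid, strand, score, p, bound)
    cursors = {c: 5_000 for c in chrom_names}
    for i in range(cfg.n_sites):
        chrom = chrom_names[i % cfg.n_chroms]
        mid = cursors[chrom] + cfg.span
        cursors[chrom] = mid + gap
        bound = bool(rng.random() < cfg.frac_bound)
        mu, sd = cfg.fimo_bound if bound else cfg.fimo_unbound
        sites.append(
            (
                chrom, mid, "+" if rng.random() < 0.5 else "-",
                float(rng.normal(mu, sd)), 10.0 ** (-float(rng.uniform(4, 8))),
                bound,
            )
        )

    fimo_lines = [_FIMO_HEADER]
    truth_rows = []
    for i, (chrom, mid, strand, score, p, bound) in enumerate(sites):
        s = mid - cfg.motif_width // 2
        e = s + cfg.motif_width
        fimo_lines.append(_fimo_line(chrom, s, e, strand, score, p))
        truth_rows.append(
            {
                "site_id": f"S{i:05d}", "chrom": chrom,
                "start": s, "end": e, "bound": int(bound),
            }
        )
    (out / "motifs.tsv").write_text("\n".join(fimo_lines) + "\n")
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth.tsv", sep="\t", index=False)

    p_bound, p_unbound = cfg.track_emission
    sample_seeds = ss.spawn(1 + len(cfg.sample_names))[1:]
    for name, child in zip(cfg.sample_names, sample_seeds):
        srng = np.random.default_rng(child)
        sdir = out / "samples" / name
        sdir.mkdir(parents=True, exist_ok=True)
        lines: dict[str, list[str]] = {t: [] for t in cfg.tracks}
        lines["ctcf"] = []
        counter = 0
        for chrom, mid, strand, score, p, bound in sites:
            left = mid - cfg.span // 2
            if bound:
                s = mid - cfg.motif_width // 2
                counter += 1
                lines["ctcf"].append(
                    _narrowpeak_line(chrom, s - 30, s + cfg.motif_width + 30,
                                     f"ctcf_{counter}", float(srng.uniform(2, 20)))
                )
            for track in cfg.tracks:
                pe = p_bound if bound else p_unbound
                if srng.random() < pe:
                    width = int(srng.integers(100, 400))
                    s = left + int(srng.integers(0, cfg.span - width))
                    counter += 1
                    lines[track].append(
                        _narrowpeak_line(chrom, s, s + width,
                                         f"{track}_{counter}",
                                         float(srng.uniform(2, 20)))
                    )
        for track, content in lines.items():
            (sdir / f"{track}.narrowPeak").write_text(
                "\n".join(content) + ("\n" if content else "")
            )

    meta = {
        "config": asdict(cfg),
        "samples": cfg.sample_names,
    }
    (out / "meta.json").write_text(json.dumps(meta, indent=1))
    return out


@dataclass
class LoadedBindingFixture:
    root: Path
    meta: dict
    truth: pd.DataFrame
    sample_names: list[str]

    def track_path(self, sample: str, track: str) -> Path:
        return self.root / "samples" / sample / f"{track}.narrowPeak"

    @property
    def motifs_path(self) -> Path:
        return self.root / "motifs.tsv"


def load_binding_fixture(outdir: str | Path) -> LoadedBindingFixture:
    root = Path(outdir)
    meta = json.loads((root / "meta.json").read_text())
    truth = pd.read_csv(root / "ground_truth.tsv", sep="\t")
    return LoadedBindingFixture(
        root=root, meta=meta, truth=truth, sample_names=list(meta["samples"])
    )
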