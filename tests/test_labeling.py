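"""Anchor-motif assignment, convergence, the high-confidence labeling
rule (checked against a direct predicate oracle), and negative sampling."""

import numpy as np
import pytest

from ctcfloop.io import GenomicInterval, LoopCall, MotifHit
from ctcfloop import labeling as gl
from ctcfloop import windows as gw
from conftest import brute_overlaps, random_motifs


def motif(chrom, start, strand="+", score=10.0, width=19):
    return MotifHit(
        GenomicInterval(chrom, start, start + width, strand),
        fimo_score=score, p_value=1e-5,
    )


class TestAssignAnchorMotif:
    def test_highest_score_wins(self):
        idx = gw.build_index([motif("chr1", 100, score=12.1), motif("chr1", 150, score=18.4)])
        best = gl.assign_anchor_motif(GenomicInterval("chr1", 50, 300), idx)
        assert best.fimo_score == 18.4

    def test_no_hit_is_absent(self):
        idx = gw.build_index([motif("chr1", 5_000)])
        assert gl.assign_anchor_motif(GenomicInterval("chr1", 50, 300), idx) is None

    def test_score_tie_breaks_leftmost(self):
        idx = gw.build_index([motif("chr1", 200, score=9.0), motif("chr1", 120, score=9.0)])
        best = gl.assign_anchor_motif(GenomicInterval("chr1", 50, 400), idx)
        assert best.interval.start == 120


@pytest.mark.parametrize(
    "s1,s2,expected",
    [("+", "-", True), ("-", "+", False), ("+", "+", False), ("-", "-", False)],
)
def test_convergence_definition(s1, s2, expected):
    assert gl.is_convergent(motif("chr1", 0, s1), motif("chr1", 5_000, s2)) is expected


def _candidate(chrom="chr1", m1=10_000, span=40_000, s1="+", s2="-", half=500):
    loop = LoopCall(chrom, (m1 - 100, m1 + 100), (m1 + span - 100, m1 + span + 100), 5, 0.0)
    wl = gw.make_windowed_loop(loop, half)
    return gl.CandidateLoop(
        windowed=wl,
        start_motif=motif(chrom, m1 - 9, s1),
        end_motif=motif(chrom, m1 + span - 9, s2),
    )


class TestLabelLoop:
    def peaks(self, *intervals):
        return gw.build_index(list(intervals))

    def test_full_rule_positive(self):
        cand = _candidate()
        ctcf = self.peaks(GenomicInterval("chr1", 9_900, 10_100),
                          GenomicInterval("chr1", 49_900, 50_100))
        rad21 = self.peaks(GenomicInterval("chr1", 9_800, 10_000))
        assert gl.label_loop(cand, ctcf, rad21).label == "positive"

    def test_no_rad21_is_negative(self):
        cand = _candidate()
        ctcf = self.peaks(GenomicInterval("chr1", 9_900, 10_100),
                          GenomicInterval("chr1", 49_900, 50_100))
        out = gl.label_loop(cand, ctcf, self.peaks())
        assert out.label == "negative" and "RAD21" in out.label_reason

    def test_missing_motif_unlabeled(self):
        cand = _candidate()
        cand = gl.CandidateLoop(windowed=cand.windowed, start_motif=None,
                                end_motif=cand.end_motif)
        out = gl.label_loop(cand, self.peaks(), self.peaks())
        assert out.label == "unlabeled" and "motif" in out.label_reason

    def test_rad21_anchors_only_mode(self):
        cand = _candidate()
        ctcf = self.peaks(GenomicInterval("chr1", 9_900, 10_100),
                          GenomicInterval("chr1", 49_900, 50_100))
        rad21_inside = self.peaks(GenomicInterval("chr1", 25_000, 25_200))
        assert gl.label_loop(cand, ctcf, rad21_inside).label == "positive"
        assert (
            gl.label_loop(cand, ctcf, rad21_inside, rad21_windows="anchors").label
            == "negative"
        )

    def test_matches_direct_predicate_oracle(self, rng):
        """Random candidates + random peak sets: labels equal a from-scratch
        evaluation of (convergent AND both-bound AND rad21-in-a-window)."""
        for trial in range(100):
            span = int(rng.integers(3_000, 80_000))
            cand = _candidate(
                m1=int(rng.integers(2_000, 50_000)), span=span,
                s1=str(rng.choice(["+", "-"])), s2=str(rng.choice(["+", "-"])),
            )
            chrom = cand.windowed.chrom
            ctcf_peaks = [
                GenomicInterval(
                    chrom, s := int(rng.integers(0, 140_000)), s + int(rng.integers(50, 400))
                )
                for _ in range(rng.integers(0, 12))
            ]
            rad21_peaks = [
                GenomicInterval(
                    chrom, s := int(rng.integers(0, 140_000)), s + int(rng.integers(50, 400))
                )
                for _ in range(rng.integers(0, 6))
            ]
            got = gl.label_loop(
                cand, gw.build_index(ctcf_peaks), gw.build_index(rad21_peaks)
            ).label
            conv = (
                cand.start_motif.interval.strand == "+"
                and cand.end_motif.interval.strand == "-"
            )
            bound = brute_overlaps(ctcf_peaks, cand.start_motif.interval) and \
                brute_overlaps(ctcf_peaks, cand.end_motif.interval)
            wl = cand.windowed
            wins = [wl.start_window, wl.end_window] + (
                [] if wl.interloop is None else [wl.interloop]
            )
            rad = any(brute_overlaps(rad21_peaks, w) for w in wins)
            want = "positive" if (conv and bound and rad) else "negative"
            assert got == want, f"trial {trial}"


class TestSampleNegatives:
    def _setup(self, rng, n_motifs=400, n_bound=40):
        motifs = random_motifs(rng, n_motifs, chroms=("chrA",), max_pos=3_000_000)
        bound = motifs[:n_bound]
        ctcf = gw.build_index(
            [GenomicInterval(m.chrom, m.interval.start - 10, m.interval.end + 10)
             for m in bound]
        )
        rad21 = gw.build_index([])
        return motifs, ctcf, rad21

    def test_no_unbound_motifs_warns_and_returns_empty(self, rng):
        motifs, _, rad21 = self._setup(rng, n_motifs=20, n_bound=20)
        ctcf = gw.build_index(
            [GenomicInterval(m.chrom, m.interval.start, m.interval.end) for m in motifs]
        )
        with pytest.warns(UserWarning):
            out = gl.sample_negatives(motifs, ctcf, rad21, n=5,
                                      span_range=(2_000, 2_000_000), rng_seed=1)
        assert out == []

    def test_same_seed_reproduces_sample(self, rng):
        motifs, ctcf, rad21 = self._setup(rng)
        kw = dict(n=30, span_range=(2_000, 2_000_000), rng_seed=7)
        a = gl.sample_negatives(motifs, ctcf, rad21, **kw)
        b = gl.sample_negatives(motifs, ctcf, rad21, **kw)
        assert [(c.start_motif.interval.start, c.end_motif.interval.start) for c in a] \
            == [(c.start_motif.interval.start, c.end_motif.interval.start) for c in b]

    def test_every_pair_satisfies_predicates(self, rng):
        motifs, ctcf, rad21 = self._setup(rng)
        out = gl.sample_negatives(motifs, ctcf, rad21, n=50,
                                  span_range=(2_000, 2_000_000), rng_seed=3)
        assert len(out) > 0
        for c in out:
            assert c.label == "negative"
            assert not ctcf.any_overlap(c.start_motif.interval)
            assert not ctcf.any_overlap(c.end_motif.interval)
            assert 2_000 <= c.windowed.span <= 2_000_000
            assert c.start_motif.chrom == c.end_motif.chrom

    def test_span_matching_tracks_positive_distribution(self, rng):
        """Quantile-bin matched sampling: per-bin proportions within a few
        percent of the positive span histogram."""
        motifs, ctcf, rad21 = self._setup(rng, n_motifs=2_000)
        pos_spans = np.exp(rng.uniform(np.log(3_000), np.log(1_000_000), 300)).astype(int)
        out = gl.sample_negatives(
            motifs, ctcf, rad21, n=200, span_range=(2_000, 2_000_000),
            rng_seed=11, positive_spans=pos_spans, n_bins=5,
        )
        assert len(out) >= 150  # near-full sample must be feasible
        edges = np.quantile(np.sort(pos_spans), np.linspace(0, 1, 6))
        edges[0] -= 1
        got = np.array([c.windowed.span for c in out], dtype=float)
        counts, _ = np.histogram(got, bins=edges)
        frac = counts / counts.sum()
        assert np.all(np.abs(frac - 0.2) < 0.08)
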