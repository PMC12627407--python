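"""Discordant-score algebra, lost/gained classification, gene annotation
(vs brute-force intersections) and gene ranking (vs brute-force sums)."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ctcfloop.io import GeneRecord, GenomicInterval, LoopCall
from ctcfloop import discordance as gd
from ctcfloop import windows as gw


def wloop(m1, m2, chrom="chr1", half=500):
    loop = LoopCall(chrom, (m1 - 100, m1 + 100), (m2 - 100, m2 + 100), 5, 0.0)
    return gw.make_windowed_loop(loop, half)


def gene(gid, start, end, chrom="chr1"):
    return GeneRecord(gid, gid.lower(), GenomicInterval(chrom, start, end))


unit = st.floats(0.0, 1.0, allow_nan=False)


class TestScore:
    @given(x=unit)
    @settings(max_examples=50, deadline=None)
    def test_equal_scores_give_zero(self, x):
        assert gd.discordant_score(x, x) == 0.0

    @given(a=unit, b=unit)
    @settings(max_examples=100, deadline=None)
    def test_symmetric_bounded_nonnegative(self, a, b):
        d = gd.discordant_score(a, b)
        assert d == gd.discordant_score(b, a)
        assert 0.0 <= d <= 1.0
        if a == b:
            assert d == 0.0
        else:
            # zero only when the gap is so small its square underflows
            assert d > 0.0 or abs(a - b) < 1e-150

    def test_out_of_range_fatal(self):
        with pytest.raises(ValueError):
            gd.discordant_score(1.2, 0.0)


class TestClassify:
    def test_lost_and_gained_conditions(self):
        assert gd.classify_loop(1.0, 1e-4) == "lost"
        assert gd.classify_loop(0.0, 0.9995) == "gained"
        assert gd.classify_loop(0.7, 0.7) == "concordant"

    @given(a=unit, b=unit)
    @settings(max_examples=200, deadline=None)
    def test_partitions_unit_square(self, a, b):
        assert gd.classify_loop(a, b) in ("lost", "gained", "concordant")

    def test_threshold_edges(self):
        # case score exactly at tau_lost is NOT lost (< is strict)
        assert gd.classify_loop(1.0, 0.0005) == "concordant"
        # case score exactly at tau_gained is NOT gained (> is strict)
        assert gd.classify_loop(0.0, 0.999) == "concordant"


class TestAnnotate:
    def test_longest_overlap_wins(self):
        loops = wloop(10_000, 60_000)
        genes = gw.build_index(
            [gene("G5KB", 20_000, 25_000), gene("G30KB", 25_000, 55_000)]
        )
        (top,) = gd.annotate_loop_gene(loops, genes, k=1)
        assert top[0].gene_id == "G30KB" and top[1] == 30_000

    def test_no_overlap_absent(self):
        genes = gw.build_index([gene("G", 500_000, 520_000)])
        assert gd.annotate_loop_gene(wloop(10_000, 60_000), genes) == []

    def test_top_k_ordering(self):
        genes = gw.build_index(
            [gene("A", 12_000, 20_000), gene("B", 20_000, 50_000), gene("C", 59_000, 59_500)]
        )
        top2 = gd.annotate_loop_gene(wloop(10_000, 60_000), genes, k=2)
        assert [g.gene_id for g, _ in top2] == ["B", "A"]

    def test_matches_brute_force_intersections(self, rng):
        for _ in range(100):
            m1 = int(rng.integers(1_000, 200_000))
            m2 = m1 + int(rng.integers(5_000, 150_000))
            loop = wloop(m1, m2)
            genes = [
                gene(f"G{j}", s := int(rng.integers(0, 400_000)),
                     s + int(rng.integers(1_000, 80_000)))
                for j in range(int(rng.integers(1, 10)))
            ]
            got = gd.annotate_loop_gene(loop, gw.build_index(genes), k=1)
            overlaps = [
                (g, min(m2, g.interval.end) - max(m1, g.interval.start))
                for g in genes
            ]
            overlaps = [(g, ov) for g, ov in overlaps if ov > 0]
            if not overlaps:
                assert got == []
            else:
                best = sorted(overlaps, key=lambda t: (-t[1], t[0].interval.start))[0]
                assert got[0][0].gene_id == best[0].gene_id
                assert got[0][1] == best[1]


class TestAggregate:
    def test_mean_identity_and_single_sample(self):
        assert gd.aggregate_control_scores([[1.0, 0.9], [1.0, 1.0], [1.0, 0.8]]).tolist() \
            == [1.0, pytest.approx(0.9)]
        assert gd.aggregate_control_scores([[0.3, 0.7]]).tolist() == [0.3, 0.7]

    def test_missing_loop_fatal(self):
        with pytest.raises(ValueError, match="missing"):
            gd.aggregate_control_scores([[1.0, np.nan], [1.0, 1.0]])
        with pytest.raises(ValueError):
            gd.aggregate_control_scores([[1.0], [1.0, 1.0]])


class TestRankGenes:
    def _records(self, spec):
        """spec: list of (gene_id or None, s_control, s_case)."""
        out = []
        for i, (gid, sc, sa) in enumerate(spec):
            g = gene(gid, 0, 1_000) if gid else None
            loop = wloop(10_000 + i * 100_000, 60_000 + i * 100_000)
            out.append(
                gd.DiscordanceRecord(
                    loop=loop, s_control=sc, s_case=sa,
                    d_score=gd.discordant_score(sc, sa),
                    klass=gd.classify_loop(sc, sa),
                    gene=g, overlap_bp=100 if g else 0,
                )
            )
        return out

    def test_gene_scores_sum_over_loops(self):
        recs = self._records(
            [("GA", 1.0, 0.0), ("GA", 1.0, 0.0002), ("GB", 1.0, 0.0001)]
        )
        frame = gd.rank_genes(recs)
        ga = frame[frame.gene_name == "ga"].iloc[0]
        assert ga["n_loops"] == 2 and ga["d_score_sum"] == pytest.approx(
            1.0 + (1 - 0.0002) ** 2
        )
        assert frame.iloc[0]["gene_name"] == "ga"  # larger sum ranks first

    def test_concordant_loops_excluded(self):
        recs = self._records([("GA", 0.7, 0.7), ("GB", 0.5, 0.4)])
        assert gd.rank_genes(recs).empty

    def test_lost_and_gained_ranked_separately(self):
        recs = self._records([("GA", 1.0, 0.0), ("GB", 0.0, 1.0)])
        frame = gd.rank_genes(recs)
        assert frame[frame.klass == "lost"].iloc[0]["gene_name"] == "ga"
        assert frame[frame.klass == "gained"].iloc[0]["gene_name"] == "gb"

    def test_matches_brute_force_group_sum(self, rng):
        spec = []
        for _ in range(200):
            gid = f"G{int(rng.integers(0, 12))}"
            if rng.random() < 0.4:
                sc, sa = 1.0, float(rng.uniform(0, 4e-4))
            elif rng.random() < 0.5:
                sc, sa = 0.0, float(rng.uniform(0.9995, 1.0))
            else:
                sc, sa = float(rng.uniform(0.2, 0.8)), float(rng.uniform(0.2, 0.8))
            spec.append((gid, sc, sa))
        recs = self._records(spec)
        frame = gd.rank_genes(recs, top_n=None)
        want: dict = {}
        for r in recs:
            if r.klass == "concordant":
                continue
            key = (r.klass, r.gene.gene_name)
            want[key] = want.get(key, 0.0) + r.d_score
        for _, row in frame.iterrows():
            assert row["d_score_sum"] == pytest.approx(
                want[(row["klass"], row["gene_name"])]
            )
        for klass in ("lost", "gained"):
            part = frame[frame.klass == klass]["d_score_sum"].to_numpy()
            assert np.all(np.diff(part) <= 1e-12)


class TestRecords:
    def test_build_and_frame_round_trip(self):
        loops = [wloop(10_000, 60_000), wloop(100_000, 180_000)]
        genes = gw.build_index([gene("GA", 15_000, 55_000)])
        recs = gd.build_discordance_records(
            loops, [1.0, 0.5], [0.0001, 0.5], genes
        )
        assert [r.klass for r in recs] == ["lost", "concordant"]
        assert recs[0].gene.gene_id == "GA" and recs[1].gene is None
        frame = gd.records_to_frame(recs)
        assert frame.iloc[0]["startloop"] == 10_000
        assert frame.iloc[0]["gene_name"] == "ga"
        assert frame.iloc[1]["gene_name"] == "."
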