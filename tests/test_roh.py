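"""ROH detection, length classes, incidence, islands, shared islands."""

import numpy as np
import pandas as pd
import pytest

from snpdiv.datamodel import MISSING
from snpdiv.roh import (
    ROHParams,
    classify_and_summarize,
    detect_islands,
    detect_roh,
    length_class,
    roh_incidence,
    shared_islands,
)

from conftest import make_gm
from oracles import grid_intersection, roh_scan_loop


def _het_background(rng, m):
    """Dense heterozygote-rich background genotypes (het prob 0.6)."""
    return np.where(rng.random(m) < 0.6, 1, rng.integers(0, 2, size=m) * 2).astype(np.int8)


class TestDetectRoh:
    def test_planted_run_exact_bounds(self, rng):
        # 60 homozygous SNPs spanning ~900 kb flanked by dense heterozygous SNPs
        m = 200
        pos = np.cumsum(rng.integers(10_000, 20_000, size=m)) + 1
        dos = np.ones(m, dtype=np.int8)
        a, b = 70, 130
        dos[a:b] = rng.integers(0, 2, size=b - a) * 2
        gm = make_gm(dos[None, :], positions=pos)
        segs = detect_roh(gm)
        assert len(segs) == 1
        # the hit-fraction rule excludes the outermost run SNP (covered by
        # only 2 of 50 qualifying windows, below the 5% threshold), so the
        # recovered bounds sit within one SNP of the planted ones
        assert segs.loc[0, "start_bp"] in (pos[a], pos[a + 1])
        assert segs.loc[0, "end_bp"] in (pos[b - 2], pos[b - 1])
        assert segs.loc[0, "n_snps"] >= b - a - 2
        oracle = roh_scan_loop(dos, pos, ROHParams())
        assert [(segs.loc[0, "start_bp"], segs.loc[0, "end_bp"])] == oracle

    def test_short_run_rejected(self, rng):
        # 30 homozygous SNPs spanning ~400 kb: below the length minimum
        m = 120
        pos = np.cumsum(np.full(m, 13_500)) + 1
        dos = _het_background(rng, m)
        dos[40:70] = 0
        gm = make_gm(dos[None, :], positions=pos)
        assert len(detect_roh(gm)) == 0

    def test_gap_split_matches_oracle(self, rng):
        # a 1.4-Mb homozygous run broken by a 600-kb inter-SNP gap
        params = ROHParams()
        pos = np.concatenate([
            np.arange(1, 41) * 20_000,
            np.arange(41, 81) * 20_000 + 600_000,
        ]).astype(np.int64)
        dos = np.zeros(80, dtype=np.int8)
        gm = make_gm(dos[None, :], positions=pos)
        segs = detect_roh(gm, params)
        oracle = roh_scan_loop(dos, pos, params)
        assert [(s, e) for s, e in zip(segs["start_bp"], segs["end_bp"])] == oracle

    def test_fully_het_individual_has_no_runs(self):
        gm = make_gm(np.ones((1, 300), dtype=np.int8), spacing_bp=20_000)
        assert len(detect_roh(gm)) == 0

    def test_fully_hom_individual_covers_genome(self):
        gm = make_gm(np.zeros((1, 300), dtype=np.int8), spacing_bp=20_000)
        segs = detect_roh(gm)
        covered = (segs["end_bp"] - segs["start_bp"] + 1).sum()
        span = 300 * 20_000 - 20_000 + 1
        assert covered >= 0.95 * span

    def test_every_segment_satisfies_params(self, rng):
        params = ROHParams()
        for _ in range(20):
            m = int(rng.integers(60, 300))
            pos = np.cumsum(rng.integers(5_000, 80_000, size=m)) + 1
            hom_block = rng.random() < 0.7
            dos = _het_background(rng, m)
            if hom_block:
                a = int(rng.integers(0, m // 2))
                b = int(rng.integers(a + 20, m))
                dos[a:b] = rng.integers(0, 2, size=b - a) * 2
            gm = make_gm(dos[None, :], positions=pos)
            for _, s in detect_roh(gm, params).iterrows():
                assert s["length_bp"] >= params.min_length_kb * 1000
                assert s["n_snps"] >= params.min_snps
                assert s["length_bp"] / s["n_snps"] <= params.max_kb_per_snp * 1000
                assert s["length_bp"] == s["end_bp"] - s["start_bp"] + 1

    def test_matches_brute_force_oracle_random_genomes(self, rng):
        params = ROHParams()
        for _ in range(60):
            m = int(rng.integers(40, 300))
            pos = np.cumsum(rng.integers(2_000, 120_000, size=m)) + 1
            p_het = rng.uniform(0.0, 0.4)
            p_mis = rng.uniform(0.0, 0.1)
            u = rng.random(m)
            dos = np.where(u < p_het, 1,
                           np.where(u < p_het + p_mis, MISSING,
                                    rng.integers(0, 2, size=m) * 2)).astype(np.int8)
            gm = make_gm(dos[None, :], positions=pos)
            segs = detect_roh(gm, params)
            got = [(s, e) for s, e in zip(segs["start_bp"], segs["end_bp"])]
            assert got == roh_scan_loop(dos, pos, params)

    def test_unsorted_positions_rejected(self):
        gm = make_gm(np.zeros((1, 3), dtype=np.int8), positions=[10, 20, 30])
        gm.variants.loc[1, "position_bp"] = 40  # corrupt after validation
        with pytest.raises(ValueError):
            detect_roh(gm)

    def test_bad_params_rejected(self):
        with pytest.raises(ValueError):
            ROHParams(window_hit_threshold=0.0)
        with pytest.raises(ValueError):
            ROHParams(min_snps=-1)


class TestClassification:
    @pytest.mark.parametrize(
        "length_mb,expected",
        [(1.9, "lt2"), (2.0, "2to4"), (16.0, "gt16"), (7.999, "4to8"), (8.0, "8to16")],
    )
    def test_boundary_convention_lower_inclusive(self, length_mb, expected):
        assert length_class(int(length_mb * 1e6)) == expected

    def test_single_segment_summary(self):
        segs = pd.DataFrame(
            [{"length_class": "2to4", "length_bp": 3_000_000}]
        )
        summ = classify_and_summarize(segs).set_index("length_class")
        assert summ.loc["2to4", "mean_mb"] == pytest.approx(3.0)
        assert summ.loc["2to4", "sd_mb"] == 0.0
        assert summ.loc["2to4", "count"] == 1

    def test_summary_matches_loop(self, rng):
        lengths = rng.integers(500_000, 30_000_000, size=100)
        segs = pd.DataFrame(
            {"length_bp": lengths, "length_class": [length_class(x) for x in lengths]}
        )
        summ = classify_and_summarize(segs).set_index("length_class")
        for cls in summ.index:
            sub = [x / 1e6 for x in lengths if length_class(x) == cls]
            assert summ.loc[cls, "count"] == len(sub)
            if sub:
                assert summ.loc[cls, "mean_mb"] == pytest.approx(np.mean(sub))
                assert summ.loc[cls, "max_mb"] == pytest.approx(np.max(sub))


class TestIncidence:
    def test_half_population_covered(self):
        gm = make_gm(np.zeros((10, 5), dtype=np.int8), spacing_bp=100_000)
        segs = pd.DataFrame(
            [
                {"sample_id": f"i{i}", "chromosome": "1",
                 "start_bp": 150_000, "end_bp": 350_000}
                for i in range(5)
            ]
        )
        inc = roh_incidence(segs, gm)
        np.testing.assert_allclose(inc, [0.0, 0.5, 0.5, 0.0, 0.0])

    def test_matches_containment_loop(self, rng):
        gm = make_gm(np.zeros((8, 50), dtype=np.int8), spacing_bp=40_000)
        rows = []
        for _ in range(30):
            i = int(rng.integers(0, 8))
            a = int(rng.integers(1, 2_000_000))
            rows.append({"sample_id": f"i{i}", "chromosome": "1",
                         "start_bp": a, "end_bp": a + int(rng.integers(0, 500_000))})
        segs = pd.DataFrame(rows)
        inc = roh_incidence(segs, gm)
        pos = gm.positions
        expect = np.zeros(50)
        for j, p in enumerate(pos):
            who = {r["sample_id"] for r in rows if r["start_bp"] <= p <= r["end_bp"]}
            expect[j] = len(who) / 8
        np.testing.assert_allclose(inc, expect)


class TestIslands:
    def test_low_incidence_everywhere_gives_none(self):
        gm = make_gm(np.zeros((4, 100), dtype=np.int8), spacing_bp=10_000)
        isl = detect_islands(np.full(100, 0.10), gm)
        assert len(isl) == 0

    def test_single_island_from_hot_block(self, rng):
        gm = make_gm(np.zeros((4, 1000), dtype=np.int8), spacing_bp=10_000)
        inc = np.full(1000, 0.05)
        inc[500:508] = 0.6
        isl = detect_islands(inc, gm)
        assert len(isl) == 1
        assert isl.loc[0, "start_bp"] == gm.positions[500]
        assert isl.loc[0, "end_bp"] == gm.positions[507]
        assert isl.loc[0, "n_snps"] == 8
        assert isl.loc[0, "peak_incidence"] == pytest.approx(0.6)

    def test_candidates_far_apart_not_merged(self):
        gm = make_gm(np.zeros((4, 3), dtype=np.int8),
                     positions=[100_000, 250_000, 1_000_000])
        inc = np.array([0.9, 0.9, 0.0])
        isl = detect_islands(inc, gm, quantile=0.0)
        assert len(isl) == 2  # 150 kb apart: merge rule is "< 100 kb"


class TestSharedIslands:
    def test_pairwise_intersection(self):
        a = pd.DataFrame([{"chromosome": "1", "start_bp": 1_000_000, "end_bp": 2_000_000}])
        b = pd.DataFrame([{"chromosome": "1", "start_bp": 1_500_000, "end_bp": 2_500_000}])
        out = shared_islands({"a": a, "b": b})
        assert out.iloc[0].tolist() == ["1", 1_500_000, 2_000_000]

    def test_disjoint_is_empty(self):
        a = pd.DataFrame([{"chromosome": "1", "start_bp": 1, "end_bp": 10}])
        b = pd.DataFrame([{"chromosome": "1", "start_bp": 20, "end_bp": 30}])
        assert len(shared_islands({"a": a, "b": b})) == 0

    def test_three_populations_match_grid_oracle(self, rng):
        positions = np.arange(1, 2001) * 1_000  # 1-kb grid
        sets = []
        frames = {}
        for p in range(3):
            ivs = []
            for _ in range(6):
                a = int(rng.integers(1, 1_900_000))
                ivs.append((a, a + int(rng.integers(10_000, 300_000))))
            sets.append(ivs)
            frames[f"p{p}"] = pd.DataFrame(
                [{"chromosome": "1", "start_bp": a, "end_bp": b} for a, b in ivs]
            )
        out = shared_islands(frames)
        covered = np.zeros(len(positions), dtype=bool)
        for _, r in out.iterrows():
            covered |= (positions >= r["start_bp"]) & (positions <= r["end_bp"])
        np.testing.assert_array_equal(covered, grid_intersection(sets, positions))

    def test_empty_group_rejected(self):
        with pytest.raises(ValueError):
            shared_islands({})
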