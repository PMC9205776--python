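"""APA, extended loops, differential maps, top-site selection, stripes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from loopscreen import aggregates as ag
from loopscreen import matrixcore as mc
from loopscreen.aggregates import AnchorSet, Loop
from loopscreen.matrixcore import ContactMatrix

from conftest import make_genome


def constant_matrix(n_bins, value=2.0, resolution=100_000, stage="scaled"):
    g = make_genome(n_bins, resolution)
    iu, ju = np.triu_indices(n_bins)
    return ContactMatrix(g, "chrS", iu, ju, np.full(iu.size, value), stage=stage)


def brute_force_extended(loops, window, longer_than_seed=False):
    """O(n^2) reference enumerator, written independently of the library."""
    out = set()
    primary = {(l.chrom, l.anchor5, l.anchor3) for l in loops}
    for seed in loops:
        for other in loops:
            if other.chrom != seed.chrom:
                continue
            a5, a3 = seed.anchor5, other.anchor3
            if a5 < a3 and a3 - a5 <= window \
                    and (seed.chrom, a5, a3) not in primary \
                    and (not longer_than_seed or a3 - a5 > seed.span):
                out.add((seed.chrom, a5, a3))
    return sorted(out)


class TestLoopIO:
    def test_midpoint_rule(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t1000\t2000\tchr1\t5000\t6000\n")
        loops = ag.read_loops(p)
        assert loops == [Loop("chr1", 1500, 5500)]

    def test_interchromosomal_dropped(self, tmp_path, caplog):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t10\tchr2\t100\t110\n"
                     "chr1\t0\t10\tchr1\t100\t110\n")
        with caplog.at_level("INFO"):
            loops = ag.read_loops(p)
        assert len(loops) == 1
        assert "1 inter-chromosomal" in caplog.text

    def test_roundtrip(self, tmp_path):
        loops = [Loop("chr1", 100, 900), Loop("chr1", 500, 5000)]
        p = tmp_path / "out.bedpe"
        ag.write_loops(loops, p)
        assert ag.read_loops(p) == loops

    def test_malformed_row_names_row(self, tmp_path):
        p = tmp_path / "loops.bedpe"
        p.write_text("chr1\t0\t10\tchr1\t100\t110\nchr1\tnope\t10\tchr1\t1\t2\n")
        with pytest.raises(ValueError, match="row 2"):
            ag.read_loops(p)

    def test_anchor_bed_roundtrip(self, tmp_path):
        sites = AnchorSet(pd.DataFrame({
            "chrom": ["chr1", "chr1"], "pos": [150, 700], "score": [3.5, 1.0]}))
        p = tmp_path / "sites.bed"
        ag.write_anchors(sites, p)
        back = ag.read_anchors(p)
        assert list(back.table["pos"]) == [150, 700]
        assert list(back.table["score"]) == [3.5, 1.0]


class TestExtendedLoops:
    def test_three_loop_example(self):
        mb = 1_000_000
        loops = [Loop("c", 0 * mb + 1, 1 * mb), Loop("c", 1 * mb, 2 * mb),
                 Loop("c", 2 * mb, 4 * mb)]
        # shift first anchor5 by 1 bp so anchor5 < anchor3 holds at 0
        ext = ag.enumerate_extended_loops(loops, window=3 * mb)
        assert ext == [Loop("c", 1, 2 * mb), Loop("c", 1 * mb, 4 * mb)]

    def test_window_boundary_inclusive(self):
        loops = [Loop("c", 0 + 1, 1_000_000), Loop("c", 1_000_000, 3_000_001)]
        ext = ag.enumerate_extended_loops(loops, window=3_000_000)
        # 3000001 - 1 = 3000000 exactly at the boundary -> included
        assert Loop("c", 1, 3_000_001) in ext

    def test_single_loop_yields_nothing(self):
        assert ag.enumerate_extended_loops([Loop("c", 5, 10)], 100) == []

    def test_invalid_window(self):
        with pytest.raises(ValueError):
            ag.enumerate_extended_loops([Loop("c", 5, 10)], 0)

    @settings(max_examples=200, deadline=None, derandomize=True)
    @given(st.lists(st.tuples(st.integers(0, 48), st.integers(1, 50)),
                    min_size=1, max_size=50),
           st.integers(5, 40), st.booleans())
    def test_matches_brute_force(self, pairs, window, longer):
        loops = sorted({Loop("c", min(a, b), max(a, b) + (a == b))
                        for a, b in ((a, b) for a, b in pairs)})
        ext = ag.enumerate_extended_loops(loops, window=window,
                                          longer_than_seed=longer)
        assert [(l.chrom, l.anchor5, l.anchor3) for l in ext] == \
            brute_force_extended(loops, window, longer)


class TestApa:
    def test_constant_map(self):
        cm = constant_matrix(30, value=7.0)
        loops = [Loop("chrS", 500_000, 1_500_000), Loop("chrS", 700_000, 2_500_000)]
        m = ag.apa(cm, loops, flank=200_000)
        assert np.allclose(m.grid, 7.0)
        assert m.n_used == 2

    def test_side_length(self):
        cm = constant_matrix(60, resolution=20_000)
        loops = [Loop("chrS", 300_000, 700_000)]
        m = ag.apa(cm, loops, flank=100_000)
        assert m.side == 11
        assert m.center == 5

    def test_slicing_oracle(self):
        rng = np.random.default_rng(5)
        n = 200
        g = make_genome(n, 20_000)
        iu, ju = np.triu_indices(n)
        cm = ContactMatrix(g, "chrS", iu, ju,
                           rng.uniform(0.1, 3.0, iu.size), stage="scaled")
        dense = cm.to_dense()
        loops = []
        while len(loops) < 50:
            b5, b3 = sorted(rng.integers(6, n - 6, 2))
            if b5 != b3:
                loops.append(Loop("chrS", int(b5) * 20_000 + 10_000,
                                  int(b3) * 20_000 + 10_000))
        m = ag.apa(cm, loops, flank=100_000)
        acc = np.zeros((11, 11))
        for lp in loops:
            b5, b3 = lp.anchor5 // 20_000, lp.anchor3 // 20_000
            acc += dense[b5 - 5:b5 + 6, b3 - 5:b3 + 6]
        np.testing.assert_allclose(m.grid, acc / 50, rtol=1e-12)

    def test_out_of_bounds_skipped_and_empty_errors(self):
        cm = constant_matrix(30)
        edge = [Loop("chrS", 10_000, 200_000)]  # window crosses the start
        with pytest.raises(ValueError):
            ag.apa(cm, edge, flank=300_000)
        mixed = edge + [Loop("chrS", 900_000, 1_900_000)]
        m = ag.apa(cm, mixed, flank=300_000)
        assert m.n_used == 1

    def test_linearity_in_matrix(self):
        rng = np.random.default_rng(0)
        n = 40
        g = make_genome(n)
        iu, ju = np.triu_indices(n)
        v1 = rng.uniform(0, 2, iu.size)
        v2 = rng.uniform(0, 2, iu.size)
        a = ContactMatrix(g, "chrS", iu, ju, v1, stage="scaled")
        b = ContactMatrix(g, "chrS", iu, ju, v2, stage="scaled")
        s = ContactMatrix(g, "chrS", iu, ju, v1 + v2, stage="scaled")
        loops = [Loop("chrS", 500_000, 2_500_000), Loop("chrS", 1_500_000, 3_100_000)]
        np.testing.assert_allclose(
            ag.apa(s, loops, 200_000).grid,
            ag.apa(a, loops, 200_000).grid + ag.apa(b, loops, 200_000).grid)

    def test_feature_order_invariance(self):
        cm = constant_matrix(40)
        rng = np.random.default_rng(1)
        loops = [Loop("chrS", int(a) * 100_000 + 50_000, int(b) * 100_000 + 50_000)
                 for a, b in [sorted(rng.integers(5, 35, 2)) for _ in range(8)]
                 if a != b]
        m1 = ag.apa(cm, loops, 200_000)
        m2 = ag.apa(cm, loops[::-1], 200_000)
        np.testing.assert_allclose(m1.grid, m2.grid)


class TestApaScore:
    def test_central_block(self):
        grid = np.ones((11, 11))
        grid[4:7, 4:7] = 2.0
        m = ag.AggregateMap(grid, flank=500_000, resolution=100_000, n_used=1)
        assert ag.apa_score(m, 3) == pytest.approx(2.0)
        assert ag.apa_score(ag.AggregateMap(np.full((5, 5), 3.3), 200_000,
                                            100_000, 1), 3) == pytest.approx(3.3)

    def test_random_map_oracle(self):
        rng = np.random.default_rng(7)
        grid = rng.normal(size=(11, 11))
        m = ag.AggregateMap(grid, flank=500_000, resolution=100_000, n_used=1)
        assert ag.apa_score(m, 3) == pytest.approx(grid[4:7, 4:7].mean())
        assert ag.apa_score(m, 11) == pytest.approx(grid.mean())

    def test_even_size_rejected(self):
        m = ag.AggregateMap(np.ones((5, 5)), 200_000, 100_000, 1)
        with pytest.raises(ValueError):
            ag.apa_score(m, 2)
        with pytest.raises(ValueError):
            ag.apa_score(m, 7)


class TestDifferentialMap:
    def test_self_difference_and_antisymmetry(self):
        rng = np.random.default_rng(2)
        a = ag.AggregateMap(rng.uniform(size=(5, 5)), 200_000, 100_000, 3)
        b = ag.AggregateMap(rng.uniform(size=(5, 5)), 200_000, 100_000, 4)
        assert np.allclose(ag.differential_map(a, a).grid, 0)
        assert np.allclose(ag.differential_map(a, b).grid
                           + ag.differential_map(b, a).grid, 0)

    def test_shape_mismatch(self):
        a = ag.AggregateMap(np.ones((5, 5)), 200_000, 100_000, 1)
        b = ag.AggregateMap(np.ones((3, 3)), 100_000, 100_000, 1)
        with pytest.raises(ValueError):
            ag.differential_map(a, b)


class TestTopSites:
    def test_selection_and_ties(self):
        sites = AnchorSet(pd.DataFrame({
            "chrom": ["c2", "c1", "c1", "c1", "c1"],
            "pos": [10, 30, 20, 40, 50],
            "score": [5.0, 5.0, 1.0, 9.0, 2.0]}))
        top = ag.select_top_sites(sites, 3)
        assert list(top.table["score"]) == [9.0, 5.0, 5.0]
        # tie between (c2,10) and (c1,30): chromosome order breaks it
        assert list(top.table["chrom"]) == ["c1", "c1", "c2"]

    def test_short_set_returned_whole(self, caplog):
        sites = AnchorSet(pd.DataFrame({
            "chrom": ["c"], "pos": [1], "score": [1.0]}))
        with caplog.at_level("WARNING"):
            top = ag.select_top_sites(sites, 10)
        assert len(top) == 1
        assert "only 1 sites" in caplog.text


class TestAggregateStripes:
    def test_unit_oe_gives_unit_profiles(self):
        cm = constant_matrix(100, value=4.0)
        sites = AnchorSet(pd.DataFrame({
            "chrom": "chrS", "pos": [4_000_000, 5_000_000], "score": [1.0, 2.0]}))
        agg, p5, p3 = ag.aggregate_stripes(cm, sites, flank=3_000_000)
        np.testing.assert_allclose(agg.grid, 1.0)
        np.testing.assert_allclose(p5.values, 1.0)
        np.testing.assert_allclose(p3.values, 1.0)

    def test_shapes_at_100kb_3mb(self):
        cm = constant_matrix(100)
        sites = AnchorSet(pd.DataFrame({
            "chrom": "chrS", "pos": [5_000_000], "score": [1.0]}))
        agg, p5, p3 = ag.aggregate_stripes(cm, sites, flank=3_000_000)
        assert agg.side == 61
        assert len(p3.values) == 31 and len(p5.values) == 31
        assert p3.distances[0] == 0 and p3.distances[-1] == 3_000_000

    def test_out_of_bounds_sites_skipped(self):
        cm = constant_matrix(100)
        sites = AnchorSet(pd.DataFrame({
            "chrom": "chrS", "pos": [100_000, 5_000_000], "score": [1.0, 1.0]}))
        agg, p5, p3 = ag.aggregate_stripes(cm, sites, flank=3_000_000)
        assert p3.n_used == 1
        only_bad = AnchorSet(sites.table.iloc[[0]])
        with pytest.raises(ValueError):
            ag.aggregate_stripes(cm, only_bad, flank=3_000_000)

    def test_profile_extraction_matches_grid(self):
        rng = np.random.default_rng(9)
        n = 100
        g = make_genome(n)
        iu, ju = np.triu_indices(n)
        cm = ContactMatrix(g, "chrS", iu, ju, rng.uniform(0.5, 2, iu.size),
                           stage="scaled")
        sites = AnchorSet(pd.DataFrame({
            "chrom": "chrS", "pos": [5_000_000], "score": [1.0]}))
        agg, p5, p3 = ag.aggregate_stripes(cm, sites, flank=2_000_000)
        f = agg.center
        np.testing.assert_allclose(p3.values, agg.grid[f, f:])
        np.testing.assert_allclose(p5.values, agg.grid[:f + 1, f][::-1])
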