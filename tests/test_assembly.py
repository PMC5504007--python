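"""Tile graph, maximum spanning tree, position composition and blending."""

import itertools
import math

import numpy as np
import pytest

from gridstitch import assembly, pcm, synthetic
from gridstitch.assembly import (build_tile_graph, compose_positions,
                                 linear_blend_weights, maximum_spanning_tree,
                                 render_mosaic, apply_layout)
from gridstitch.grid import StageModel, TileGrid, TranslationTable, TranslationTables

from conftest import source_for_grid


def model(r=2.0, overlap=10.0):
    return StageModel(overlap_h=overlap, overlap_v=overlap, alpha=0.0, r=r)


def tables_2x2(h_entries, v_entries, w=64):
    """Hand-built 2x2-grid tables; entries are (dx, dy, ncc)."""
    h = TranslationTable((2, 1))
    v = TranslationTable((1, 2))
    for r, (dx, dy, ncc) in enumerate(h_entries):
        h.dx[r, 0], h.dy[r, 0], h.ncc[r, 0] = dx, dy, ncc
    for c, (dx, dy, ncc) in enumerate(v_entries):
        v.dx[0, c], v.dy[0, c], v.ncc[0, c] = dx, dy, ncc
    return TranslationTables(h, v)


def brute_force_mst_weight(graph):
    """Maximum spanning-tree weight by exhaustive edge-subset enumeration."""
    edges = list(graph.edges(data=True))
    n = graph.number_of_nodes()
    best = -math.inf
    for combo in itertools.combinations(range(len(edges)), n - 1):
        parent = {node: node for node in graph.nodes}

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        ok = True
        total = 0.0
        for k in combo:
            u, v, d = edges[k]
            ru, rv = find(u), find(v)
            if ru == rv:
                ok = False
                break
            parent[ru] = rv
            total += d["weight"]
        if ok and total > best:
            best = total
    return best


class TestTileGraph:
    def test_2x2_grid_counts(self):
        tables = tables_2x2([(58, 0, 0.9), (58, 0, 0.9)],
                            [(0, 58, 0.9), (0, 58, 0.9)])
        g = build_tile_graph(tables, model(overlap=10), 64, 64)
        assert g.number_of_nodes() == 4
        assert g.number_of_edges() == 4

    def test_plausible_edge_outweighs_implausible(self):
        # plausible displacement with low ncc vs junk displacement with high ncc
        tables = tables_2x2([(58, 0, 0.3), (10, 40, 0.9)],
                            [(0, 58, 0.9), (0, 58, 0.9)])
        g = build_tile_graph(tables, model(r=2, overlap=10), 64, 64)
        w_plausible = g.edges[(0, 0), (0, 1)]["weight"]
        w_implausible = g.edges[(1, 0), (1, 1)]["weight"]
        assert w_plausible == pytest.approx(1.3)
        assert w_implausible == pytest.approx(0.9)
        assert w_plausible > w_implausible

    def test_invalid_edges_get_sentinel_weight_but_tree_spans(self):
        tables = tables_2x2([(0, 0, math.nan)] * 2, [(0, 0, math.nan)] * 2)
        g = build_tile_graph(tables, model(), 64, 64)
        tree = maximum_spanning_tree(g)
        assert len(tree) == 3
        assert all(d["weight"] <= assembly.INVALID_WEIGHT for _, _, d in tree)


class TestMaximumSpanningTree:
    def test_2x2_cycle_drops_lowest_edge(self):
        tables = tables_2x2([(58, 0, 0.9), (58, 0, 0.6)],
                            [(0, 58, 0.8), (0, 58, 0.7)])
        # kill the boost so raw ncc ordering decides
        g = build_tile_graph(tables, model(overlap=50), 64, 64)
        tree = maximum_spanning_tree(g)
        kept = {frozenset(e[:2]) for e in tree}
        assert frozenset({(1, 0), (1, 1)}) not in kept  # the 0.6 edge

    def test_equal_weights_deterministic_and_total(self):
        tables = tables_2x2([(58, 0, 0.5)] * 2, [(0, 58, 0.5)] * 2)
        g = build_tile_graph(tables, model(overlap=50), 64, 64)
        t1 = maximum_spanning_tree(g)
        t2 = maximum_spanning_tree(g)
        assert [e[:2] for e in t1] == [e[:2] for e in t2]
        assert sum(d["weight"] for _, _, d in t1) == pytest.approx(3 * 0.5)

    def test_matches_brute_force_on_random_3x3_graphs(self):
        rng = np.random.default_rng(50)
        for _ in range(25):
            h = TranslationTable((3, 2))
            v = TranslationTable((2, 3))
            h.ncc[:] = rng.uniform(-1, 1, size=(3, 2))
            v.ncc[:] = rng.uniform(-1, 1, size=(2, 3))
            h.dx[:] = 58
            v.dy[:] = 58
            tables = TranslationTables(h, v)
            g = build_tile_graph(tables, model(overlap=50), 64, 64)
            tree = maximum_spanning_tree(g)
            got = sum(d["weight"] for _, _, d in tree)
            assert got == pytest.approx(brute_force_mst_weight(g))


class TestComposePositions:
    def test_single_edge_pair(self):
        src, _ = synthetic.generate_source(51, 300, 100, "texture")
        acq = synthetic.simulate_acquisition(src, 1, 2, 64, 64, overlap_pct=10,
                                             alpha_deg=0, r_px=0, seed=51)
        tables = pcm.compute_translation_tables(acq.grid)
        g = build_tile_graph(tables, model(overlap=10), 64, 64)
        layout = compose_positions(maximum_spanning_tree(g), tables, acq.grid)
        assert layout.position(0, 0) == (0, 0)
        assert layout.position(0, 1) == (58, 0)   # 64·0.9 rounded
        assert layout.mosaic_width == 58 + 64

    def test_noiseless_grid_recovers_truth_exactly(self, noiseless_acq):
        tables = pcm.compute_translation_tables(noiseless_acq.grid)
        g = build_tile_graph(tables, model(overlap=20), 64, 64)
        layout = compose_positions(maximum_spanning_tree(g), tables, noiseless_acq.grid)
        assert np.array_equal(layout.x, noiseless_acq.truth_layout.x)
        assert np.array_equal(layout.y, noiseless_acq.truth_layout.y)
        layout.validate()

    def test_min_normalization_is_traversal_invariant(self):
        # negative displacements (east->west acquisition) normalize away
        h = TranslationTable((1, 1))
        h.dx[0, 0], h.dy[0, 0], h.ncc[0, 0] = -58, 0, 0.9
        tables = TranslationTables(h, TranslationTable((0, 2)))
        imgs = [[np.zeros((64, 64), dtype=np.uint8) for _ in range(2)]]
        grid = TileGrid.from_images(imgs)
        g = build_tile_graph(tables, model(overlap=10), 64, 64)
        layout = compose_positions(maximum_spanning_tree(g), tables, grid)
        assert layout.x.min() == 0 and layout.y.min() == 0
        assert layout.position(0, 0) == (58, 0)
        assert layout.position(0, 1) == (0, 0)

    def test_tree_shape_invariants_random_grids(self):
        rng = np.random.default_rng(52)
        for rows, cols in ((2, 2), (3, 4), (5, 5), (6, 6)):
            h = TranslationTable((rows, cols - 1))
            v = TranslationTable((rows - 1, cols))
            h.ncc[:] = rng.uniform(0, 1, size=h.shape)
            v.ncc[:] = rng.uniform(0, 1, size=v.shape)
            h.dx[:] = 58
            v.dy[:] = 58
            g = build_tile_graph(TranslationTables(h, v), model(overlap=50), 64, 64)
            tree = maximum_spanning_tree(g)
            assert len(tree) == rows * cols - 1
            nodes = set()
            for u, v_, _ in tree:
                nodes.update((u, v_))
            assert len(nodes) == rows * cols


class TestRendering:
    def test_single_tile_identity_all_modes(self):
        src, _ = synthetic.generate_source(53, 120, 120, "texture")
        acq = synthetic.simulate_acquisition(src, 1, 1, 64, 64, overlap_pct=10,
                                             alpha_deg=0, r_px=0, seed=53)
        for mode in ("overlay", "average", "linear"):
            out = render_mosaic(acq.truth_layout, acq.grid, mode)
            assert np.array_equal(out, acq.grid.tile(0, 0).image)

    def test_identical_overlap_content_average_equals_tile(self, noiseless_acq):
        out = render_mosaic(noiseless_acq.truth_layout, noiseless_acq.grid, "average")
        h, w = 64, 64
        lay = noiseless_acq.truth_layout
        sub = noiseless_acq.source
        for r in range(3):
            for c in range(3):
                px, py = lay.position(r, c)
                assert np.array_equal(out[py:py + h, px:px + w],
                                      noiseless_acq.grid.tile(r, c).image)
        assert np.array_equal(out[:lay.mosaic_height, :lay.mosaic_width],
                              sub[:lay.mosaic_height, :lay.mosaic_width])

    def test_overlay_round_trip_equals_source(self, noiseless_acq):
        out = render_mosaic(noiseless_acq.truth_layout, noiseless_acq.grid, "overlay")
        lay = noiseless_acq.truth_layout
        assert np.array_equal(out, noiseless_acq.source[:lay.mosaic_height,
                                                        :lay.mosaic_width])

    def test_linear_blend_weights_properties(self):
        for h, w in ((8, 8), (7, 9), (64, 48)):
            wts = linear_blend_weights(h, w)
            assert wts.shape == (h, w)
            assert np.all(wts > 0)
            assert np.allclose(wts, wts[::-1, :])
            assert np.allclose(wts, wts[:, ::-1])
            assert wts.max() <= 1.0 + 1e-12

    def test_apply_layout_same_grid_matches_render(self, noiseless_acq):
        a = render_mosaic(noiseless_acq.truth_layout, noiseless_acq.grid, "overlay")
        b = apply_layout(noiseless_acq.truth_layout, noiseless_acq.grid, "overlay")
        assert np.array_equal(a, b)

    def test_apply_layout_pointwise_transform_commutes(self, noiseless_acq):
        inv_tiles = [[np.asarray(60000 - noiseless_acq.grid.tile(r, c).image,
                                 dtype=np.uint16)
                      for c in range(3)] for r in range(3)]
        inv_grid = TileGrid.from_images(inv_tiles)
        ref = render_mosaic(noiseless_acq.truth_layout, noiseless_acq.grid, "overlay")
        out = apply_layout(noiseless_acq.truth_layout, inv_grid, "overlay")
        lay = noiseless_acq.truth_layout
        covered = np.zeros(ref.shape, dtype=bool)
        for r in range(3):
            for c in range(3):
                px, py = lay.position(r, c)
                covered[py:py + 64, px:px + 64] = True
        assert np.array_equal(out[covered], 60000 - ref[covered].astype(np.int64))

    def test_apply_layout_shape_mismatch_rejected(self, noiseless_acq):
        imgs = [[np.zeros((64, 64), dtype=np.uint16) for _ in range(2)]]
        with pytest.raises(Exception):
            apply_layout(noiseless_acq.truth_layout, TileGrid.from_images(imgs))
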