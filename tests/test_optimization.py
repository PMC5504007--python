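"""Median filtering and constrained hill climbing of the translation tables."""

import itertools
import math

import numpy as np
import pytest

from gridstitch import optimization, pcm, synthetic
from gridstitch.grid import StageModel, TranslationTable, TranslationTables
from gridstitch.optimization import (_ascend, filter_translations, hill_climb,
                                     optimize_all)

from conftest import source_for_grid


def model(r=2.0, overlap=10.0, alpha=0.0):
    return StageModel(overlap_h=overlap, overlap_v=overlap, alpha=alpha, r=r)


def h_table(dx_list, dy=0, ncc=0.9, w=1040):
    """Single-column H table from a list of dx values."""
    t = TranslationTable((len(dx_list), 1))
    for i, dx in enumerate(dx_list):
        t.dx[i, 0] = dx
        t.dy[i, 0] = dy
        t.ncc[i, 0] = ncc
    return t


class TestFilterTranslations:
    def test_outlier_replaced_by_column_median(self):
        tables = TranslationTables(h_table([936, 937, 935, 400]),
                                   TranslationTable((0, 2)))
        out = filter_translations(tables, model(r=2), tile_w=1040, tile_h=1040)
        assert out.h.dx[3, 0] == 936
        assert out.h.dy[3, 0] == 0
        assert out.h.repaired[3, 0]
        assert math.isnan(out.h.ncc[3, 0])
        assert not out.h.repaired[:3].any()

    def test_within_band_table_unchanged(self):
        tables = TranslationTables(h_table([936, 937, 935, 938]),
                                   TranslationTable((0, 2)))
        out = filter_translations(tables, model(r=2), tile_w=1040, tile_h=1040)
        assert np.array_equal(out.h.dx, tables.h.dx)
        assert not out.h.repaired.any()

    def test_idempotence(self):
        tables = TranslationTables(h_table([936, 937, 935, 400, 910]),
                                   TranslationTable((0, 2)))
        once = filter_translations(tables, model(r=2), tile_w=1040, tile_h=1040)
        twice = filter_translations(once, model(r=2), tile_w=1040, tile_h=1040)
        assert once.h == twice.h and once.v == twice.v

    def test_v_filtered_row_wise(self):
        # row 0 good, one junk entry in row 1
        t = TranslationTable((2, 3))
        t.dy[:] = [[936, 935, 937], [940, 30, 941]]
        t.dx[:] = 0
        t.ncc[:] = 0.9
        t.ncc[1, 1] = 0.1
        tables = TranslationTables(TranslationTable((2, 0)), t)
        out = filter_translations(tables, model(r=2), tile_w=1040, tile_h=1040)
        assert out.v.dy[1, 1] == 940  # row-1 median, not row-0's
        assert out.v.repaired[1, 1]

    def test_line_without_valid_entries_uses_table_median(self):
        t = TranslationTable((2, 2))
        t.dx[:] = [[936, 12], [937, 40]]
        t.dy[:] = 0
        t.ncc[:] = [[0.9, 0.1], [0.9, 0.2]]  # column 1 has no trusted entry
        tables = TranslationTables(t, TranslationTable((1, 3)))
        out = filter_translations(tables, model(r=2), tile_w=1040, tile_h=1040)
        assert out.h.dx[0, 1] == 936 and out.h.dx[1, 1] == 936

    def test_no_valid_entries_anywhere_uses_nominal(self):
        t = TranslationTable((2, 2))
        t.dx[:] = 5
        t.ncc[:] = 0.1
        tables = TranslationTables(t, TranslationTable((1, 3)))
        out = filter_translations(tables, model(r=2, overlap=10), tile_w=1040,
                                  tile_h=1040)
        assert np.all(out.h.dx == 936)
        assert out.h.repaired.all()

    def test_corrupted_entries_land_within_4r_of_line_median(self):
        src, _ = source_for_grid(40, 5, 5, 64, 20)
        acq = synthetic.simulate_acquisition(src, 5, 5, 64, 64, overlap_pct=20,
                                             alpha_deg=0, r_px=2, seed=40)
        tables = pcm.compute_translation_tables(acq.grid)
        corrupted, masks = synthetic.corrupt_translations(tables, 0.3, 200, 41)
        m = model(r=2, overlap=20)
        out = filter_translations(corrupted, m, tile_w=64, tile_h=64)
        for table, axis in ((out.h, 0), (out.v, 1)):
            n_lines = table.shape[1] if axis == 0 else table.shape[0]
            for i in range(n_lines):
                sel = (slice(None), i) if axis == 0 else (i, slice(None))
                keep = np.isfinite(table.ncc[sel]) & ~table.repaired[sel]
                if not keep.any():
                    continue
                med_dx = np.median(table.dx[sel][keep])
                med_dy = np.median(table.dy[sel][keep])
                assert np.all(np.abs(table.dx[sel] - med_dx) <= 4 * m.r + 1)
                assert np.all(np.abs(table.dy[sel] - med_dy) <= 4 * m.r + 1)


class TestHillClimb:
    def test_matches_exhaustive_argmax_on_unimodal_windows(self, texture_512):
        rng = np.random.default_rng(42)
        size, r = 64, 2
        half = 2 * r
        for _ in range(20):
            dx = int(rng.integers(20, 40))
            dy = int(rng.integers(-5, 6))
            y0, x0 = int(rng.integers(80, 300)), int(rng.integers(80, 300))
            a = texture_512[y0:y0 + size, x0:x0 + size].astype(float)
            b = texture_512[y0 + dy:y0 + dy + size,
                            x0 + dx:x0 + dx + size].astype(float)
            start = (dx + int(rng.integers(-2, 3)), dy + int(rng.integers(-2, 3)))
            got = hill_climb(a, b, start, r, 25)
            best = max(((sx, sy, pcm.ncc(a, b, sx, sy, 25))
                        for sx in range(start[0] - half, start[0] + half + 1)
                        for sy in range(start[1] - half, start[1] + half + 1)
                        if not math.isnan(pcm.ncc(a, b, sx, sy, 25))),
                       key=lambda t: t[2])
            # equality on unimodal surfaces; never better than the oracle
            assert got.ncc <= best[2] + 1e-12
            if (got.dx, got.dy) != best[:2]:
                pytest.fail(f"hill climb stopped at {(got.dx, got.dy)} "
                            f"instead of {best[:2]}")

    def test_start_at_maximum_is_fixed_point(self, texture_512):
        a = texture_512[100:164, 100:164].astype(float)
        b = texture_512[102:166, 130:194].astype(float)
        t = hill_climb(a, b, (30, 2), 2, 25)
        assert (t.dx, t.dy) == (30, 2)
        assert t.ncc == pytest.approx(1.0)

    def test_confinement_never_violated(self, texture_512):
        rng = np.random.default_rng(43)
        a = texture_512[50:114, 50:114].astype(float)
        b = texture_512[53:117, 90:154].astype(float)
        for r in (1, 2, 3):
            start = (int(rng.integers(30, 50)), int(rng.integers(-4, 4)))
            t = hill_climb(a, b, start, r, 25)
            assert abs(t.dx - start[0]) <= 2 * r
            assert abs(t.dy - start[1]) <= 2 * r

    def test_invalid_start_with_no_valid_neighbors(self):
        flat = np.full((32, 32), 3.0)
        t = hill_climb(flat, flat, (10, 0), 2, 25)
        assert (t.dx, t.dy) == (10, 0)
        assert not t.valid

    def test_monotone_path_on_hand_built_surface(self):
        # center lowest, NE corner highest, strictly increasing toward NE
        surf = {(dx, dy): dx - dy for dx in range(-2, 3) for dy in range(-2, 3)}
        end, val = _ascend(lambda dx, dy: surf.get((dx, dy), math.nan), (0, 0), 2)
        assert end == (2, -2)
        assert val == 4

    def test_ascent_stops_at_local_maximum(self):
        # two bumps; the near one is lower but blocks the path
        def score(dx, dy):
            if (dx, dy) == (1, 0):
                return 5.0
            if (dx, dy) == (4, 0):
                return 9.0
            return -abs(dx) - abs(dy)
        end, val = _ascend(score, (0, 0), 4)
        assert end == (1, 0)  # greedy: cannot cross the valley
        assert val == 5.0


class TestOptimizeAll:
    def test_noiseless_grid_is_fixed_point(self, noiseless_acq):
        tables = pcm.compute_translation_tables(noiseless_acq.grid)
        m = model(r=1, overlap=20)
        filtered = filter_translations(tables, m, tile_w=64, tile_h=64)
        out = optimize_all(filtered, m, noiseless_acq.grid)
        assert np.array_equal(out.h.dx, tables.h.dx)
        assert np.array_equal(out.h.dy, tables.h.dy)
        assert np.array_equal(out.v.dx, tables.v.dx)
        assert np.array_equal(out.v.dy, tables.v.dy)

    def test_repaired_entry_recovers_true_offset(self, jittered_acq):
        tables = pcm.compute_translation_tables(jittered_acq.grid)
        corrupted, masks = synthetic.corrupt_translations(tables, 0.3, 150, 44)
        m = model(r=2, overlap=20, alpha=1.0)
        filtered = filter_translations(corrupted, m, tile_w=64, tile_h=64)
        out = optimize_all(filtered, m, jittered_acq.grid)
        lay = jittered_acq.truth_layout
        total = hits = 0
        for r in range(5):
            for c in range(4):
                true = (lay.x[r, c + 1] - lay.x[r, c], lay.y[r, c + 1] - lay.y[r, c])
                total += 1
                hits += (abs(out.h.dx[r, c] - true[0]) <= 1
                         and abs(out.h.dy[r, c] - true[1]) <= 1)
        for r in range(4):
            for c in range(5):
                true = (lay.x[r + 1, c] - lay.x[r, c], lay.y[r + 1, c] - lay.y[r, c])
                total += 1
                hits += (abs(out.v.dx[r, c] - true[0]) <= 1
                         and abs(out.v.dy[r, c] - true[1]) <= 1)
        assert hits / total >= 0.95

    def test_ascent_and_confinement_invariants(self, jittered_acq):
        tables = pcm.compute_translation_tables(jittered_acq.grid)
        m = model(r=2, overlap=20, alpha=1.0)
        filtered = filter_translations(tables, m, tile_w=64, tile_h=64)
        out = optimize_all(filtered, m, jittered_acq.grid)
        for before, after in ((filtered.h, out.h), (filtered.v, out.v)):
            assert np.all(np.abs(after.dx - before.dx) <= 2 * m.r)
            assert np.all(np.abs(after.dy - before.dy) <= 2 * m.r)
            had = np.isfinite(before.ncc)
            assert np.all(after.ncc[had] >= before.ncc[had] - 1e-12)
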