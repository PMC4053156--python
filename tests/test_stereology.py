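"""Counting-frame geometry, forbidden-line rules, CE and agreement."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import ki67calib as k
from ki67calib.errors import (InvalidGridError, UndefinedLIError,
                              UndefinedSegmentsError, AlignmentError)
from ki67calib.stereology import (CEParams, GridCountResult, build_grid,
                                  ci_agreement, coefficient_error,
                                  confidence_interval, count_frame_profiles,
                                  external_segments, frames_in_tumour,
                                  grid_count)
from ki67calib.synthetic import CellProfile, TUMOUR_NEGATIVE, TUMOUR_POSITIVE

from conftest import truth_only_spot


def _disc(cid, x, y, r, cls=TUMOUR_NEGATIVE):
    return CellProfile(cid, x, y, r, cls, 200.0)


class TestBuildGrid:
    @pytest.mark.parametrize("extent,b,a,off,expected", [
        ((2000, 2000), 125, 250, (0, 0), 64),   # 8 frames per axis
        ((125, 125), 125, 125, (0, 0), 1),
        ((2000, 2000), 125, 250, (249, 249), 49),
    ])
    def test_frame_counts(self, extent, b, a, off, expected):
        assert build_grid(extent, b, a, off).n_frames == expected

    def test_spacing_smaller_than_frame_rejected(self):
        with pytest.raises(InvalidGridError):
            build_grid((1000, 1000), 250, 125)

    def test_all_frames_inside_extent(self):
        g = build_grid((700, 500), 100, 150, (30, 70))
        for cell in g.lattice_cells:
            x, y = g.frame_origin(cell)
            assert 0 <= x and x + 100 <= 700
            assert 0 <= y and y + 100 <= 500


def _boundary_edges_bruteforce(cells):
    """Oracle: unit edges of the cell union adjacent to exactly one cell."""
    cells = set(cells)
    m = 0
    for (i, j) in cells:
        for di, dj in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            if (i + di, j + dj) not in cells:
                m += 1
    return m


class TestExternalSegments:
    def test_single_frame(self):
        assert external_segments({(0, 0)}) == 4

    def test_six_frame_line_matches_worked_value(self):
        line = {(i, 0) for i in range(6)}
        assert external_segments(line) == 14

    def test_two_by_three_block(self):
        block = {(i, j) for i in range(2) for j in range(3)}
        assert external_segments(block) == _boundary_edges_bruteforce(block) == 10

    def test_empty_set_undefined(self):
        with pytest.raises(UndefinedSegmentsError):
            external_segments(set())

    @given(st.sets(st.tuples(st.integers(0, 6), st.integers(0, 6)),
                   min_size=1, max_size=20))
    def test_formula_equals_boundary_enumeration(self, cells):
        assert external_segments(cells) == _boundary_edges_bruteforce(cells)

    @given(st.sets(st.tuples(st.integers(0, 6), st.integers(0, 6)),
                   min_size=1, max_size=20))
    def test_m_bounds(self, cells):
        m = external_segments(cells)
        n = len(cells)
        assert 4 <= m <= 4 * n
        adjacency_free = all(
            (i + 1, j) not in cells and (i, j + 1) not in cells
            for (i, j) in cells)
        assert (m == 4 * n) == adjacency_free


class TestCountingRules:
    FRAME = (100, 100, 50)   # left, top, size

    @pytest.mark.parametrize("rule", ["simple", "gundersen"])
    def test_interior_profile_counted(self, rule):
        truth = [_disc(0, 125, 125, 5)]
        assert count_frame_profiles(truth, self.FRAME, rule) == (0, 1)

    @pytest.mark.parametrize("rule", ["simple", "gundersen"])
    def test_profile_crossing_left_edge_excluded(self, rule):
        truth = [_disc(0, 100, 125, 5)]   # straddles x = 100
        assert count_frame_profiles(truth, self.FRAME, rule) == (0, 0)

    @pytest.mark.parametrize("rule", ["simple", "gundersen"])
    def test_profile_crossing_bottom_edge_excluded(self, rule):
        truth = [_disc(0, 125, 150, 5)]   # straddles y = 150
        assert count_frame_profiles(truth, self.FRAME, rule) == (0, 0)

    @pytest.mark.parametrize("rule", ["simple", "gundersen"])
    def test_profile_crossing_top_edge_counted(self, rule):
        truth = [_disc(0, 125, 100, 5)]   # acceptance edge
        assert count_frame_profiles(truth, self.FRAME, rule) == (0, 1)

    @pytest.mark.parametrize("rule", ["simple", "gundersen"])
    def test_profile_crossing_right_edge_counted(self, rule):
        truth = [_disc(0, 150, 125, 5, TUMOUR_POSITIVE)]
        assert count_frame_profiles(truth, self.FRAME, rule) == (1, 0)

    def test_gundersen_extension_excludes_above_left_line(self):
        # pokes into the frame across the top-left corner but straddles the
        # left line only *above* the frame: the simple rule accepts it, the
        # gundersen upward extension rejects it
        truth = [_disc(0, 103, 97, 4)]
        assert count_frame_profiles(truth, self.FRAME, "simple") == (0, 1)
        assert count_frame_profiles(truth, self.FRAME, "gundersen") == (0, 0)

    def test_non_tumour_never_counted(self):
        truth = [CellProfile(0, 125, 125, 5, "lymphocyte", 200.0),
                 CellProfile(1, 130, 130, 5, "stroma", 200.0)]
        assert count_frame_profiles(truth, self.FRAME, "simple") == (0, 0)


class TestTilingExactness:
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_gundersen_tiling_counts_each_profile_once(self, seed):
        spec = k.SpotSpec(spot_diameter_um=250.0, cell_density_per_mm2=4000.0,
                          true_li_percent=35.0, seed=seed)
        spot = truth_only_spot(spec)
        size = spec.image_size_px
        grid = build_grid((size, size), 125, 125, (0, 0))
        res = grid_count(spot, grid, "gundersen")
        n_tumour = sum(1 for c in spot.truth if c.is_tumour)
        n_pos = sum(1 for c in spot.truth
                    if c.cell_class == TUMOUR_POSITIVE)
        assert res.total_profiles == n_tumour
        assert res.pos_count == n_pos


class TestFramesInTumour:
    def test_full_and_empty_masks(self):
        g = build_grid((500, 500), 100, 100)
        assert frames_in_tumour(g, np.ones((500, 500), bool)) == \
            frozenset(g.lattice_cells)
        assert frames_in_tumour(g, np.zeros((500, 500), bool)) == frozenset()

    def test_mask_covering_single_frame(self):
        g = build_grid((500, 500), 100, 100)
        mask = np.zeros((500, 500), bool)
        mask[210:290, 110:190] = True      # strictly inside frame (1, 2)
        assert frames_in_tumour(g, mask) == frozenset({(1, 2)})

    def test_min_overlap_fraction(self):
        g = build_grid((200, 200), 100, 100)
        mask = np.zeros((200, 200), bool)
        mask[:100, :30] = True             # 30% of frame (0, 0)
        assert (0, 0) in frames_in_tumour(g, mask, 0.2)
        assert (0, 0) not in frames_in_tumour(g, mask, 0.5)


class TestCoefficientError:
    def test_worked_value_six_frames(self):
        assert coefficient_error(6, 14) == pytest.approx(0.2761, abs=1e-4)

    def test_zero_external_segments(self):
        assert coefficient_error(10, 0) == 0.0

    def test_four_by_six_block(self):
        cells = {(i, j) for i in range(4) for j in range(6)}
        assert external_segments(cells) == 20
        assert coefficient_error(24, 20) == pytest.approx(0.0825, abs=1e-4)

    def test_undefined_for_no_frames(self):
        with pytest.raises(UndefinedLIError):
            coefficient_error(0, 4)

    def test_decreases_with_growing_blocks(self):
        ces = []
        for kk in range(1, 7):
            cells = {(i, j) for i in range(kk) for j in range(kk)}
            ces.append(coefficient_error(len(cells),
                                         external_segments(cells)))
        assert all(a > b for a, b in zip(ces, ces[1:]))


class TestConfidenceInterval:
    @pytest.mark.parametrize("li,ce,expected", [
        (50.0, 0.0, (50.0, 50.0)),
        (30.0, 0.2761, (21.717, 38.283)),
        (90.0, 0.2, (72.0, 100.0)),       # clamped at 100
    ])
    def test_relative_interval(self, li, ce, expected):
        lo, hi = confidence_interval(li, ce)
        assert lo == pytest.approx(expected[0], abs=0.01)
        assert hi == pytest.approx(expected[1], abs=0.01)


class TestGridCount:
    def test_all_positive_spot_has_li_100(self):
        spec = k.SpotSpec(spot_diameter_um=250, true_li_percent=100.0, seed=1)
        spot = truth_only_spot(spec)
        g = build_grid((spec.image_size_px,) * 2, 125, 250)
        assert grid_count(spot, g).li_percent == 100.0

    def test_deterministic(self):
        spec = k.SpotSpec(spot_diameter_um=250, seed=5)
        spot = truth_only_spot(spec)
        g = build_grid((spec.image_size_px,) * 2, 125, 250)
        assert grid_count(spot, g) == grid_count(spot, g)

    def test_li_identity_and_ci_bracketing(self):
        spec = k.SpotSpec(spot_diameter_um=400, seed=8)
        spot = truth_only_spot(spec)
        g = build_grid((spec.image_size_px,) * 2, 125, 250)
        res = grid_count(spot, g)
        assert res.total_profiles == res.pos_count + res.neg_count
        assert res.li_percent == 100.0 * res.pos_count / res.total_profiles
        assert res.ci_low_percent <= res.li_percent <= res.ci_high_percent
        assert res.m_external_segments <= 4 * res.n_frames_in_tumour


def _result(lo, hi):
    li = (lo + hi) / 2
    return GridCountResult(1, 1, li, 4, 8, 0.1, lo, hi, 2)


class TestCIAgreement:
    def test_identical_results_agree_fully(self):
        rep = ci_agreement([[_result(10, 20)] * 3] * 5)
        assert rep.all_way == 1.0
        assert all(v == 1.0 for v in rep.pairwise.values())

    def test_disjoint_intervals_never_agree(self):
        rep = ci_agreement([[_result(10, 20), _result(30, 40)]])
        assert rep.all_way == 0.0
        assert rep.pairwise[(0, 1)] == 0.0

    def test_chained_overlap_pairwise_but_not_all_way(self):
        rep = ci_agreement([[_result(0, 10), _result(8, 18), _result(16, 26)]])
        assert rep.pairwise[(0, 1)] == 1.0
        assert rep.pairwise[(1, 2)] == 1.0
        assert rep.pairwise[(0, 2)] == 0.0
        assert rep.all_way == 0.0

    def test_mismatched_lists_rejected(self):
        with pytest.raises(AlignmentError):
            ci_agreement([[_result(0, 1)]])
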