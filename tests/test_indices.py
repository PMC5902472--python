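"""Tests for the DLG spatial indices against closed forms and a brute oracle."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from dlgrowth.indices import (
    ColonyPointSet,
    angular_index,
    bias_index,
    compute_index,
    repulsion_index,
)
from dlgrowth import synthetic

BOUNDS = (0.0, 10.0, 0.0, 10.0)


def brute_indices(points, bounds, seeds, n_bins):
    """Independent loop-based computation of all three indices."""
    pts = list(map(tuple, points))
    cx = sum(p[0] for p in pts) / len(pts)
    cy = sum(p[1] for p in pts) / len(pts)
    counts = [0] * n_bins
    for x, y in pts:
        ang = math.atan2(y - cy, x - cx) % (2 * math.pi)
        counts[min(int(ang / (2 * math.pi / n_bins)), n_bins - 1)] += 1
    scaled = [c / (len(pts) / n_bins) for c in counts]
    mean = sum(scaled) / n_bins
    itheta = math.sqrt(sum((v - mean) ** 2 for v in scaled) / n_bins)
    lo, hi = sorted(s[0] for s in seeds)
    ic = sum(1 for x, _ in pts if lo < x < hi) / len(pts)
    mid = 0.5 * (bounds[0] + bounds[1])
    ib = sum(1.0 if x > mid else 0.5 if x == mid else 0.0 for x, _ in pts) / len(pts)
    return itheta, ic, ib


class TestAngularIndex:
    def test_zero_for_equal_bin_counts(self):
        # 4 points per quadrant bin, exactly symmetric about the centroid
        ang = np.arange(16) * (2 * np.pi / 16) + 0.1
        pts = np.column_stack([5 + np.cos(ang), 5 + np.sin(ang)])
        res = angular_index(ColonyPointSet(pts, BOUNDS), n_bins=4)
        assert res.value == pytest.approx(0.0, abs=1e-12)

    def test_single_occupied_bin_approaches_sqrt_b_minus_1(self):
        # Angle offsets about the centroid sum to zero, so a finite set can
        # never occupy one bin exactly; sqrt(B - 1) is the supremum.  A tight
        # cluster balanced by one remote point approaches it at rate O(B/n).
        n = 100_000
        pts = np.vstack([np.tile([[9.0, 5.0]], (n, 1)), [[1.0, 5.0]]])
        res = angular_index(ColonyPointSet(pts, BOUNDS), n_bins=16)
        assert res.value == pytest.approx(np.sqrt(15.0), abs=1e-3)
        # and the closed form itself: scaled counts {B, 0, ...} have
        # population variance B - 1 about their mean of 1
        B = 16
        scaled = np.zeros(B)
        scaled[0] = B
        assert scaled.std() == pytest.approx(np.sqrt(B - 1), abs=1e-12)

    def test_matches_brute_oracle_on_hand_points(self):
        rng = np.random.default_rng(42)
        pts = rng.uniform(1, 9, size=(20, 2))
        got = angular_index(ColonyPointSet(pts, BOUNDS), n_bins=8).value
        expect = brute_indices(pts, BOUNDS, [(2.0, 5.0), (8.0, 5.0)], 8)[0]
        assert got == pytest.approx(expect, abs=1e-12)

    def test_invariant_under_translation_and_bin_rotation(self):
        rng = np.random.default_rng(7)
        pts = rng.uniform(2, 8, size=(50, 2))
        base = angular_index(ColonyPointSet(pts, BOUNDS), n_bins=8).value
        shifted = angular_index(
            ColonyPointSet(pts + 100.0, (100, 110, 100, 110)), n_bins=8
        ).value
        assert shifted == pytest.approx(base, abs=1e-9)
        # rotating every point by one bin width permutes the bins only
        c = pts.mean(axis=0)
        th = 2 * np.pi / 8
        rot = np.array([[np.cos(th), -np.sin(th)], [np.sin(th), np.cos(th)]])
        rotated = (pts - c) @ rot.T + c
        rot_val = angular_index(
            ColonyPointSet(rotated, (-20, 20, -20, 20)), n_bins=8
        ).value
        assert rot_val == pytest.approx(base, abs=1e-9)

    @pytest.mark.parametrize("n,bound", [(1_000, 0.35), (100_000, 0.05)])
    def test_uniform_disc_decay(self, n, bound):
        # multinomial std of scaled counts ~ sqrt(n_bins / n)
        pts = synthetic.uniform_disc(n, seed=123)
        assert angular_index(pts, n_bins=16).value < bound

    def test_rejects_empty_and_degenerate_sets(self):
        with pytest.raises(ValueError):
            angular_index(ColonyPointSet(np.empty((0, 2)), BOUNDS))
        pts = np.full((5, 2), 3.0)
        with pytest.raises(ValueError):
            angular_index(ColonyPointSet(pts, BOUNDS))


class TestRepulsionIndex:
    def test_all_cells_in_strip_gives_one(self):
        pts = np.column_stack([np.full(10, 5.0), np.linspace(1, 9, 10)])
        cps = ColonyPointSet(pts, BOUNDS, seeds=[(2.0, 5.0), (8.0, 5.0)])
        assert repulsion_index(cps).value == 1.0

    def test_empty_strip_gives_zero(self):
        # twin colonies that grew entirely away from each other
        pts = np.array([[1.0, 5.0], [1.5, 4.0], [9.0, 5.0], [8.5, 6.0]])
        cps = ColonyPointSet(pts, BOUNDS, seeds=[(2.0, 5.0), (8.0, 5.0)])
        assert repulsion_index(cps).value == 0.0

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(3)
        pts = rng.uniform(0.5, 9.5, size=(20, 2))
        seeds = [(3.0, 5.0), (7.0, 5.0)]
        got = repulsion_index(ColonyPointSet(pts, BOUNDS, seeds=seeds)).value
        assert got == pytest.approx(brute_indices(pts, BOUNDS, seeds, 8)[1])

    def test_uniform_twin_discs_score_near_half(self):
        # uniformly grown twin colonies leave no gap: I_c ~ 0.5
        pts = synthetic.twin_discs(n=20_000, radius=30.0, seed=11)
        assert repulsion_index(pts).value == pytest.approx(0.5, abs=0.03)

    def test_requires_two_distinct_seeds(self):
        pts = np.array([[1.0, 1.0]])
        with pytest.raises(ValueError):
            repulsion_index(ColonyPointSet(pts, BOUNDS, seeds=[(1.0, 1.0)]))
        with pytest.raises(ValueError):
            repulsion_index(
                ColonyPointSet(pts, BOUNDS, seeds=[(2.0, 1.0), (2.0, 9.0)])
            )


class TestBiasIndex:
    def test_all_right_gives_one(self):
        pts = np.column_stack([np.linspace(6, 9, 12), np.linspace(1, 9, 12)])
        assert bias_index(ColonyPointSet(pts, BOUNDS)).value == 1.0

    def test_mirror_symmetric_set_gives_exactly_half(self):
        rng = np.random.default_rng(5)
        right = rng.uniform(5, 10, size=(30, 2))
        left = np.column_stack([10.0 - right[:, 0], right[:, 1]])
        on_mid = np.array([[5.0, 2.0], [5.0, 8.0]])  # midline ties: half each
        pts = np.vstack([right, left, on_mid])
        assert bias_index(ColonyPointSet(pts, BOUNDS)).value == 0.5

    def test_matches_brute_oracle(self):
        rng = np.random.default_rng(8)
        pts = rng.uniform(0, 10, size=(20, 2))
        got = bias_index(ColonyPointSet(pts, BOUNDS)).value
        assert got == pytest.approx(
            brute_indices(pts, BOUNDS, [(2.0, 5.0), (8.0, 5.0)], 8)[2]
        )

    @given(dy=st.floats(-50, 50))
    @settings(max_examples=25, deadline=None)
    def test_invariant_under_vertical_translation(self, dy):
        pts = np.array([[1.0, 2.0], [6.0, 3.0], [9.0, 9.0]])
        base = bias_index(ColonyPointSet(pts, BOUNDS)).value
        shifted = ColonyPointSet(
            pts + [0.0, dy], (0.0, 10.0, pts[:, 1].min() + dy - 1, pts[:, 1].max() + dy + 1)
        )
        assert bias_index(shifted).value == base

    def test_rejects_empty_set(self):
        with pytest.raises(ValueError):
            bias_index(ColonyPointSet(np.empty((0, 2)), BOUNDS))


def test_compute_index_dispatch_and_unknown_kind():
    pts = ColonyPointSet(np.array([[6.0, 5.0]]), BOUNDS)
    assert compute_index(pts, "b").value == 1.0
    with pytest.raises(ValueError):
        compute_index(pts, "nope")
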