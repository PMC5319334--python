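"""Unit tests for the sequential reconstruction analyses."""

import math
from itertools import combinations

import numpy as np
import pytest

from bowercourt import (
    CourtGeometry,
    CourtObject,
    InsufficientDataError,
    PermutationPlan,
    PlacementSequence,
    compare_residual_sets,
    first_k_summary,
    fit_gradient,
    relative_position,
    residual_sets,
    rms_trajectory,
    sequential_bonferroni,
    sign_test,
    time_binned_trajectory,
)
from bowercourt.reconstruction import ResidualSets, first_k_objects

from conftest import make_court, on_axis_objects


def footprint_court(geom, length=80.0, width=60.0):
    """Four corner-ish objects spanning an exact L x W footprint."""
    a = geom.avenue_offset
    coords = [(a + length, 0.0), (a + 1.0, width / 2), (a + 1.0, -width / 2),
              (a + length / 2, 10.0)]
    return [
        CourtObject(id=f"f{i}", x=x, y=y, visible_width=1.0, visible_depth=1.0)
        for i, (x, y) in enumerate(coords)
    ]


def seq_from(court_before, placed, geom):
    events = [
        CourtObject(
            id=o.id, x=o.x, y=o.y,
            visible_width=o.visible_width, visible_depth=o.visible_depth,
            placed_at=10.0 * (i + 1), placement_rank=i + 1,
        )
        for i, o in enumerate(placed)
    ]
    return PlacementSequence(court_before, events, geom)


class TestRelativePosition:
    def test_footprint_centre_maps_to_half_half(self, geom):
        court = footprint_court(geom)
        centre = CourtObject(id="c", x=geom.avenue_offset + 40.0, y=0.0,
                             visible_width=1, visible_depth=1)
        rel = relative_position(centre, court, geom)
        assert rel.x_rel == pytest.approx(0.5)
        assert rel.y_rel == pytest.approx(0.5)

    def test_entrance_on_axis(self, geom):
        court = footprint_court(geom)
        at_entrance = CourtObject(id="e", x=geom.avenue_offset, y=0.0,
                                  visible_width=1, visible_depth=1)
        rel = relative_position(at_entrance, court, geom)
        assert rel.x_rel == pytest.approx(0.0)
        assert rel.y_rel == pytest.approx(0.5)

    def test_hand_arithmetic_case(self, geom):
        # L = 80, W = 60; axial 20 from entrance, y = -15 -> (0.25, 0.25)
        court = footprint_court(geom, length=80.0, width=60.0)
        o = CourtObject(id="h", x=geom.avenue_offset + 20.0, y=-15.0,
                        visible_width=1, visible_depth=1)
        rel = relative_position(o, court, geom)
        assert rel.x_rel == pytest.approx(0.25)
        assert rel.y_rel == pytest.approx(0.25)
        assert rel.inside_footprint

    def test_outside_footprint_flagged_not_error(self, geom):
        court = footprint_court(geom)
        o = CourtObject(id="o", x=geom.avenue_offset + 100.0, y=40.0,
                        visible_width=1, visible_depth=1)
        rel = relative_position(o, court, geom)
        assert rel.x_rel > 1.0 and rel.y_rel > 1.0
        assert not rel.inside_footprint

    def test_empty_original_court_is_error(self, geom):
        o = CourtObject(id="o", x=30.0, y=0.0, visible_width=1, visible_depth=1)
        with pytest.raises(InsufficientDataError):
            relative_position(o, [], geom)


class TestFirstKSummary:
    def test_constant_placement_position(self, geom):
        court = footprint_court(geom)
        a = geom.avenue_offset
        placed = [
            CourtObject(id=f"p{i}", x=a + 20.0, y=0.0,
                        visible_width=1, visible_depth=1)
            for i in range(10)
        ]
        s = first_k_summary(seq_from(court, placed, geom), k=10)
        assert s.mean_x_rel == pytest.approx(0.25)
        assert s.se_x_rel == pytest.approx(0.0, abs=1e-12)
        assert s.frac_closest_third == 1.0
        assert s.frac_middle_lateral_third == 1.0

    def test_alternating_near_far(self, geom):
        court = footprint_court(geom)
        a = geom.avenue_offset
        placed = [
            CourtObject(id=f"p{i}", x=a + (8.0 if i % 2 == 0 else 72.0), y=0.0,
                        visible_width=1, visible_depth=1)
            for i in range(10)
        ]
        s = first_k_summary(seq_from(court, placed, geom), k=10)
        assert s.mean_x_rel == pytest.approx(0.5)
        assert s.frac_closest_third == pytest.approx(0.5)

    def test_matches_second_pass_recomputation(self, geom):
        court = make_court(20, seed=8, geom=geom)
        seq = seq_from(court, court[:10], geom)
        s = first_k_summary(seq, k=10)
        # spreadsheet-style second pass from the raw table
        a = geom.avenue_offset
        L = max(o.x - a for o in court)
        W = 2 * max(abs(o.y) for o in court)
        xr = [(o.x - a) / L for o in court[:10]]
        yr = [0.5 + o.y / W for o in court[:10]]
        assert s.mean_x_rel == pytest.approx(np.mean(xr), rel=1e-12)
        assert s.mean_y_rel == pytest.approx(np.mean(yr), rel=1e-12)
        assert s.se_x_rel == pytest.approx(
            np.std(xr, ddof=1) / math.sqrt(10), rel=1e-12
        )

    def test_too_few_placements(self, geom):
        court = footprint_court(geom)
        with pytest.raises(InsufficientDataError):
            first_k_summary(seq_from(court, court[:3], geom), k=10)


class TestRmsTrajectory:
    def test_objects_on_original_line_give_zero_rms(self, geom):
        xs = geom.avenue_offset + np.linspace(5, 75, 12)
        widths = 0.5 + 0.02 * xs
        court = on_axis_objects(xs, widths)
        fit = fit_gradient(court, geom, "width")
        seq = seq_from(court, court[:10], geom)
        traj = rms_trajectory(seq, fit, geom, "width")
        assert traj.shape == (7,)
        assert np.allclose(traj, 0.0, atol=1e-10)

    def test_hand_listed_residuals_at_step_four(self, geom):
        xs = geom.avenue_offset + np.linspace(10, 70, 4)
        widths = 1.0 + 0.02 * xs + np.array([1.0, -1.0, 2.0, -2.0])
        court_line = on_axis_objects(xs, 1.0 + 0.02 * xs)
        fit = fit_gradient(court_line + on_axis_objects(
            [geom.avenue_offset + 5.0], [1.0 + 0.02 * (geom.avenue_offset + 5)]
        ), geom, "width")
        placed = on_axis_objects(xs, widths)
        seq = seq_from(court_line, placed, geom)
        traj = rms_trajectory(seq, fit, geom, "width")
        # residuals {1, -1, 2, -2} -> RMS sqrt(10/4)
        assert traj[0] == pytest.approx(math.sqrt(10.0 / 4.0), abs=1e-9)

    def test_needs_enough_placements(self, geom):
        court = make_court(12, seed=1, geom=geom)
        fit = fit_gradient(court, geom, "width")
        seq = seq_from(court, court[:3], geom)
        with pytest.raises(InsufficientDataError):
            rms_trajectory(seq, fit, geom, "width")


class TestResidualSets:
    def test_first10_on_original_line_gives_zero_r3(self, geom):
        xs = geom.avenue_offset + np.linspace(5, 75, 20)
        widths = 0.5 + 0.02 * xs
        court = on_axis_objects(xs, widths)
        first10 = on_axis_objects(
            geom.avenue_offset + np.linspace(7, 60, 10),
            0.5 + 0.02 * (geom.avenue_offset + np.linspace(7, 60, 10)),
        )
        rs = residual_sets(court, first10, geom, "width", "gradient")
        assert np.allclose(rs.R3, 0.0, atol=1e-9)

    def test_subset_consistency(self, geom):
        # first 10 = untouched subset of the original court: R3 entries are
        # exactly the corresponding entries of R1
        court = make_court(20, seed=13, geom=geom)
        first10 = court[:10]
        for metric in ("gradient", "angle"):
            rs = residual_sets(court, first10, geom, "width", metric)
            assert np.allclose(rs.R3, rs.R1[:10], atol=1e-12)

    def test_sizes_match_contract(self, geom):
        court = make_court(25, seed=2, geom=geom)
        rs = residual_sets(court, court[:10], geom, "depth", "angle")
        assert rs.R2.shape == rs.R3.shape == (10,)
        assert rs.R1.shape == (25,)

    def test_r1_rms_recovers_generative_noise(self, geom):
        # over replicates the original-fit RMS estimates the noise s.d.
        sigma = 0.3
        rms = [
            fit_gradient(make_court(200, seed=s, geom=geom, noise=sigma),
                         geom, "width").rms
            for s in range(100)
        ]
        se = np.std(rms, ddof=1) / math.sqrt(len(rms))
        assert abs(np.mean(rms) - sigma) < 3 * se + 0.01


class TestCompareResidualSets:
    def make_sets(self, r1, r2):
        return ResidualSets(
            bower_id="b", dimension="width", metric="gradient",
            R1=np.asarray(r1, float), R2=np.asarray(r2, float),
            R3=np.asarray(r2, float),
        )

    def test_identical_multisets_give_zero_statistic_p_one(self):
        r = [0.5, -0.3, 0.2, -0.4]
        cmp_ = compare_residual_sets(self.make_sets(r, r), "R1R2")
        assert cmp_.statistic == pytest.approx(0.0, abs=1e-12)
        assert cmp_.p_value == 1.0

    def test_tiny_exhaustive_matches_manual_enumeration(self):
        r1, r2 = [1.0, -2.0], [0.5, 3.0]
        cmp_ = compare_residual_sets(self.make_sets(r1, r2), "R1R2")
        assert cmp_.exhaustive and cmp_.n_permutations == 6  # C(4, 2)
        pool = np.array(r1 + r2)
        obs = math.sqrt(np.mean(np.square(r2))) - math.sqrt(np.mean(np.square(r1)))
        stats = []
        for idx in combinations(range(4), 2):
            a = pool[list(idx)]
            b = pool[[i for i in range(4) if i not in idx]]
            stats.append(
                math.sqrt(np.mean(b**2)) - math.sqrt(np.mean(a**2))
            )
        n_ge = sum(abs(s) >= abs(obs) - 1e-12 for s in stats)
        assert cmp_.p_value == pytest.approx((1 + n_ge) / 7.0, abs=1e-12)

    def test_sampled_agrees_with_exhaustive(self):
        rng = np.random.default_rng(3)
        r1 = rng.normal(0, 1.0, 5)
        r2 = rng.normal(0, 2.0, 5)
        sets = self.make_sets(r1, r2)
        exh = compare_residual_sets(sets, "R1R2")
        assert exh.exhaustive
        q = exh.p_value
        samp = compare_residual_sets(
            sets, "R1R2",
            PermutationPlan(n_permutations=20_000, seed=5),
            exhaustive_total=0,
        )
        assert not samp.exhaustive
        se = math.sqrt(q * (1 - q) / 20_000)
        assert abs(samp.p_value - q) < 3 * se + 1e-3

    def test_type_one_error_calibrated(self):
        # both groups from one noise law: rejection rate ~ alpha
        rng = np.random.default_rng(99)
        alpha, n_rep = 0.05, 400
        rej = 0
        for _ in range(n_rep):
            sets = self.make_sets(rng.normal(0, 1, 6), rng.normal(0, 1, 6))
            rej += compare_residual_sets(sets, "R1R2").p_value <= alpha
        rate = rej / n_rep
        assert abs(rate - alpha) < 3 * math.sqrt(alpha * (1 - alpha) / n_rep)


class TestSequentialBonferroni:
    def test_all_ones_reject_nothing(self):
        assert not sequential_bonferroni([1.0, 1.0, 1.0]).any()

    def test_hand_checked_holm_sequence(self):
        # 0.001 <= 0.05/3 rejected; 0.2 > 0.05/2 stops the sequence
        flags = sequential_bonferroni([0.001, 0.2, 0.9])
        assert flags.tolist() == [True, False, False]

    def test_single_test_reduces_to_plain_alpha(self):
        assert sequential_bonferroni([0.049]).tolist() == [True]
        assert sequential_bonferroni([0.051]).tolist() == [False]

    def test_between_bonferroni_and_unadjusted(self):
        rng = np.random.default_rng(21)
        for _ in range(50):
            p = rng.uniform(0, 0.3, 12)
            holm = sequential_bonferroni(p)
            plain = p <= 0.05
            bonf = p <= 0.05 / p.size
            assert np.all(holm <= plain)  # subset of unadjusted
            assert np.all(bonf <= holm)   # superset of Bonferroni

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            sequential_bonferroni([0.2, 1.5])


class TestSignTest:
    def test_balanced_signs_give_p_one(self):
        assert sign_test([1] * 5 + [-1] * 5) == pytest.approx(1.0)

    def test_two_of_ten_positive(self):
        # 2 * sum_{k<=2} C(10,k) / 2^10 = 0.109375
        assert sign_test([1, 1] + [-1] * 8) == pytest.approx(0.109375)

    def test_all_negative(self):
        assert sign_test([-1.0] * 10) == pytest.approx(2.0 / 1024.0)

    def test_zeros_dropped(self):
        assert sign_test([0.0, 0.0, 1.0, 1.0, -1.0, -1.0]) == pytest.approx(1.0)

    def test_all_zero_undefined(self):
        with pytest.raises(InsufficientDataError):
            sign_test([0.0, 0.0])


class TestTimeBinnedTrajectory:
    def test_single_object_reported_every_bin(self, geom):
        court = footprint_court(geom)
        placed = [CourtObject(id="p0", x=geom.avenue_offset + 20.0, y=0.0,
                              visible_width=1, visible_depth=1,
                              placed_at=0.0, placement_rank=1)]
        seq = PlacementSequence(court, placed, geom)
        pts = time_binned_trajectory(seq, geom)
        assert len(pts) == 21  # 7 daylight bins x 3 days (05:30-18:00, 2 h)
        for pt in pts:
            assert pt.n_objects == 1
            assert pt.mean_x_rel == pytest.approx(0.25)
            assert pt.se_x_rel == 0.0
            assert math.isnan(pt.slope_width)

    def test_object_count_steps_at_bin_boundary(self, geom):
        court = footprint_court(geom)
        a = geom.avenue_offset
        placed = [
            CourtObject(id="p0", x=a + 20.0, y=0.0, visible_width=1,
                        visible_depth=1, placed_at=30.0, placement_rank=1),
            CourtObject(id="p1", x=a + 40.0, y=5.0, visible_width=1,
                        visible_depth=1, placed_at=200.0, placement_rank=2),
        ]
        seq = PlacementSequence(court, placed, geom)
        pts = time_binned_trajectory(seq, geom)
        counts = [pt.n_objects for pt in pts[:3]]
        assert counts == [1, 2, 2]  # second object lands in bin 2 (120-240)

    def test_moved_object_uses_latest_position(self, geom):
        court = footprint_court(geom)
        a = geom.avenue_offset
        placed = [
            CourtObject(id="p0", x=a + 60.0, y=0.0, visible_width=1,
                        visible_depth=1, placed_at=10.0, placement_rank=1),
            CourtObject(id="p0", x=a + 20.0, y=0.0, visible_width=1,
                        visible_depth=1, placed_at=500.0, placement_rank=2),
        ]
        seq = PlacementSequence(court, placed, geom)
        pts = time_binned_trajectory(seq, geom)
        assert pts[0].mean_x_rel == pytest.approx(0.75)
        assert pts[-1].mean_x_rel == pytest.approx(0.25)
        assert pts[-1].n_objects == 1

    def test_no_placements_warns_empty(self, geom):
        court = footprint_court(geom)
        placed = [CourtObject(id="p0", x=geom.avenue_offset + 20.0, y=0.0,
                              visible_width=1, visible_depth=1,
                              placed_at=1e6, placement_rank=1)]
        seq = PlacementSequence(court, placed, geom)
        with pytest.warns(UserWarning):
            assert time_binned_trajectory(seq, geom) == []


class TestPlacementSequenceValidation:
    def test_noncontiguous_ranks_rejected(self, geom):
        court = footprint_court(geom)
        bad = [CourtObject(id="p0", x=30.0, y=0.0, visible_width=1,
                           visible_depth=1, placed_at=5.0, placement_rank=2)]
        with pytest.raises(ValueError):
            PlacementSequence(court, bad, geom)

    def test_time_must_be_monotone_with_rank(self, geom):
        court = footprint_court(geom)
        bad = [
            CourtObject(id="p0", x=30.0, y=0.0, visible_width=1,
                        visible_depth=1, placed_at=50.0, placement_rank=1),
            CourtObject(id="p1", x=35.0, y=0.0, visible_width=1,
                        visible_depth=1, placed_at=20.0, placement_rank=2),
        ]
        with pytest.raises(ValueError):
            PlacementSequence(court, bad, geom)
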