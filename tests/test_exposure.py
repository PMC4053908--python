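import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from commute_exposure.exposure import (
    cell_path_lengths,
    compute_exposures,
    leg_concentration,
    leg_dose,
    subject_concentration,
    subject_exposure,
    subject_record,
)
from commute_exposure.models import (
    ConcentrationGrid,
    GridExtentError,
    Leg,
    RatioTable,
    Subject,
    Trip,
    Wait,
    polyline_length,
)


def dense_sample_cell_lengths(points, grid, pts_per_m=10_000):
    """Oracle: attribute length by dense midpoint sampling along the line."""
    acc = {}
    for (x0, y0), (x1, y1) in zip(points[:-1], points[1:]):
        seg_len = math.hypot(x1 - x0, y1 - y0)
        if seg_len == 0:
            continue
        n = max(int(seg_len * pts_per_m), 1)
        t = (np.arange(n) + 0.5) / n
        xs = x0 + t * (x1 - x0)
        ys = y0 + t * (y1 - y0)
        i = np.minimum(((xs - grid.x0) // grid.cell_size).astype(int), grid.ncols - 1)
        j = np.minimum(((ys - grid.y0) // grid.cell_size).astype(int), grid.nrows - 1)
        w = seg_len / n
        for ci, cj in zip(i, j):
            acc[(int(ci), int(cj))] = acc.get((int(ci), int(cj)), 0.0) + w
    return acc


def _leg(points, mode="walking", road_class="side", start_min=480, duration=10.0):
    return Leg(id=0, subject_id=0, trip_id=0, mode=mode, origin_node=0, dest_node=1,
               points=points, start_min=start_min, duration_min=duration,
               road_class=road_class)


def _grid(values, cell=1.0):
    return ConcentrationGrid(x0=0.0, y0=0.0, cell_size=cell, values=np.asarray(values, float))


class TestCellPathLengths:
    def test_segment_inside_one_cell(self, uniform_grid):
        pieces = cell_path_lengths([(5.0, 5.0), (10.0, 5.0)], uniform_grid)
        assert pieces == [((0, 0), pytest.approx(5.0))]

    def test_diagonal_symmetry(self):
        grid = _grid(np.zeros((2, 2)))
        pieces = dict(cell_path_lengths([(0.0, 0.0), (2.0, 2.0)], grid))
        assert set(pieces) == {(0, 0), (1, 1)}
        assert pieces[(0, 0)] == pytest.approx(math.sqrt(2))
        assert pieces[(1, 1)] == pytest.approx(math.sqrt(2))

    def test_vertex_outside_extent_raises(self, uniform_grid):
        with pytest.raises(GridExtentError, match="outside grid"):
            cell_path_lengths([(5.0, 5.0), (500.0, 5.0)], uniform_grid)

    def test_top_right_boundary_belongs_to_last_cell(self):
        grid = _grid(np.zeros((2, 2)))
        pieces = dict(cell_path_lengths([(2.0, 1.5), (2.0, 2.0)], grid))
        assert set(pieces) == {(1, 1)}

    def test_lengths_sum_to_polyline_length_random(self):
        rng = np.random.default_rng(3)
        grid = _grid(np.zeros((10, 10)))
        for _ in range(50):
            pts = [tuple(p) for p in rng.uniform(0, 10, size=(4, 2))]
            pieces = cell_path_lengths(pts, grid)
            assert sum(l for _, l in pieces) == pytest.approx(
                polyline_length(pts), rel=1e-9
            )

    def test_matches_dense_sampling_oracle(self):
        rng = np.random.default_rng(8)
        grid = _grid(np.zeros((10, 10)))
        for _ in range(25):
            pts = [tuple(p) for p in rng.uniform(0.0, 10.0, size=(3, 2))]
            exact = dict(cell_path_lengths(pts, grid))
            approx = dense_sample_cell_lengths(pts, grid, pts_per_m=10_000)
            total = polyline_length(pts)
            for cell in set(exact) | set(approx):
                assert abs(exact.get(cell, 0.0) - approx.get(cell, 0.0)) <= 0.005 * total

    @settings(max_examples=50, deadline=None)
    @given(
        st.lists(
            st.tuples(
                st.floats(0.0, 10.0, allow_nan=False),
                st.floats(0.0, 10.0, allow_nan=False),
            ),
            min_size=2,
            max_size=6,
        )
    )
    def test_property_lengths_partition_arc_length(self, pts):
        grid = _grid(np.zeros((10, 10)))
        pieces = cell_path_lengths(pts, grid)
        assert sum(l for _, l in pieces) == pytest.approx(polyline_length(pts), abs=1e-9)
        assert all(l >= 0 for _, l in pieces)


class TestLegConcentration:
    def test_uniform_grid_any_leg(self, uniform_grid):
        leg = _leg([(3.0, 7.0), (150.0, 150.0), (60.0, 12.0)])
        assert leg_concentration(leg, uniform_grid) == pytest.approx(40.0)

    def test_half_in_each_of_two_cells(self):
        grid = _grid([[20.0, 60.0]], cell=10.0)
        leg = _leg([(5.0, 5.0), (15.0, 5.0)])
        assert leg_concentration(leg, grid) == pytest.approx(40.0)

    def test_zero_length_leg_point_lookup(self):
        grid = _grid([[20.0, 60.0]], cell=10.0)
        leg = _leg([(12.0, 5.0), (12.0, 5.0)])
        assert leg_concentration(leg, grid) == pytest.approx(60.0)

    def test_matches_dense_sampling_mean(self):
        rng = np.random.default_rng(21)
        for _ in range(20):
            vals = rng.uniform(10.0, 80.0, size=(10, 10))
            grid = _grid(vals)
            pts = [tuple(p) for p in rng.uniform(0.0, 10.0, size=(3, 2))]
            leg = _leg(pts)
            exact = leg_concentration(leg, grid)
            dense = dense_sample_cell_lengths(pts, grid, pts_per_m=10_000)
            total = sum(dense.values())
            oracle = sum(vals[j, i] * l for (i, j), l in dense.items()) / total
            assert exact == pytest.approx(oracle, rel=0.005)


class TestSubjectAggregation:
    def test_single_leg_ratio_one(self, uniform_grid):
        leg = _leg([(5.0, 5.0), (50.0, 5.0)], duration=12.0)
        c = subject_concentration([leg], [], RatioTable.identity(), uniform_grid)
        assert c == pytest.approx(40.0)

    def test_hand_arithmetic_three_components(self):
        """legs (40,r1.2,t10) and (30,r1,t5), wait (25,r1,t3) -> 705/18."""
        grid = _grid([[40.0, 30.0, 25.0]], cell=10.0)
        table = RatioTable(ratio_m=np.full(24, 1.2), ratio_s=np.ones(24))
        legs = [
            _leg([(2.0, 5.0), (8.0, 5.0)], road_class="main", duration=10.0),   # C=40, r=1.2
            _leg([(12.0, 5.0), (18.0, 5.0)], road_class="side", duration=5.0),  # C=30, r=1.0
        ]
        wait = Wait(location=(25.0, 5.0), start_min=480, duration_min=3.0, road_class="side")
        c = subject_concentration(legs, [wait], table, grid)
        e, tw = subject_exposure(legs, [wait], table, grid)
        assert c == pytest.approx((480 + 150 + 75) / 18)
        assert e == pytest.approx(705.0)
        assert tw == pytest.approx(705.0 / 18.0)

    def test_equal_durations_simple_mean(self):
        grid = _grid([[10.0, 30.0]], cell=10.0)
        legs = [
            _leg([(2.0, 5.0), (8.0, 5.0)], duration=7.0),
            _leg([(12.0, 5.0), (18.0, 5.0)], duration=7.0),
        ]
        c = subject_concentration(legs, [], RatioTable.identity(), grid)
        assert c == pytest.approx(20.0)

    def test_doubling_durations_doubles_exposure_not_tw(self, uniform_grid):
        legs = [_leg([(5.0, 5.0), (50.0, 5.0)], duration=10.0)]
        e1, tw1 = subject_exposure(legs, [], RatioTable.identity(), uniform_grid)
        legs2 = [_leg([(5.0, 5.0), (50.0, 5.0)], duration=20.0)]
        e2, tw2 = subject_exposure(legs2, [], RatioTable.identity(), uniform_grid)
        assert e2 == pytest.approx(2 * e1)
        assert tw2 == pytest.approx(tw1)

    def test_exposure_e_400(self, uniform_grid):
        legs = [_leg([(5.0, 5.0), (50.0, 5.0)], duration=10.0)]
        e, _ = subject_exposure(legs, [], RatioTable.identity(), uniform_grid)
        assert e == pytest.approx(400.0)

    def test_zero_total_duration_errors(self, uniform_grid):
        legs = [_leg([(5.0, 5.0), (50.0, 5.0)], duration=0.0)]
        with pytest.raises(ValueError, match="duration"):
            subject_concentration(legs, [], RatioTable.identity(), uniform_grid)

    def test_negative_duration_errors(self, uniform_grid):
        leg = _leg([(5.0, 5.0), (50.0, 5.0)])
        leg.duration_min = -1.0
        with pytest.raises(ValueError, match="negative"):
            subject_exposure([leg], [], RatioTable.identity(), uniform_grid)

    def test_zero_duration_wait_changes_nothing(self, uniform_grid):
        legs = [_leg([(5.0, 5.0), (50.0, 5.0)], duration=10.0)]
        w = Wait(location=(5.0, 5.0), start_min=480, duration_min=0.0, road_class="side")
        e0, tw0 = subject_exposure(legs, [], RatioTable.identity(), uniform_grid)
        e1, tw1 = subject_exposure(legs, [w], RatioTable.identity(), uniform_grid)
        assert (e0, tw0) == (e1, tw1)

    def test_time_weighted_equals_c_subject(self):
        rng = np.random.default_rng(4)
        grid = _grid(rng.uniform(10, 60, size=(10, 10)))
        table = RatioTable(rng.uniform(0.7, 1.4, 24), rng.uniform(0.7, 1.4, 24))
        legs = [
            _leg([tuple(p) for p in rng.uniform(0, 10, (3, 2))],
                 road_class=rng.choice(["main", "side"]), duration=float(rng.uniform(2, 30)),
                 start_min=int(rng.integers(0, 1440)))
            for _ in range(4)
        ]
        c = subject_concentration(legs, [], table, grid)
        _, tw = subject_exposure(legs, [], table, grid)
        assert c == pytest.approx(tw, abs=1e-12)


class TestLegDose:
    def test_motorized_ratio_one(self):
        assert leg_dose(468.0, "motorized") == pytest.approx(468.0)

    def test_walking_scaling(self):
        assert leg_dose(100.0, "walking") == pytest.approx(170.0)

    def test_bicycle_exact_factor_two(self):
        assert leg_dose(414.5, "bicycle") / 414.5 == pytest.approx(2.0)

    def test_unknown_mode_errors(self):
        with pytest.raises(ValueError, match="mode"):
            leg_dose(100.0, "teleport")


def _make_subject(sid, legs, waits=()):
    trip = Trip(id=0, origin_node=0, dest_node=1, start_min=450,
                legs=list(legs), waits=list(waits))
    return Subject(id=sid, home_node=0, work_node=1, home_xy=(0.0, 0.0),
                   work_xy=(1.0, 1.0), trips=[trip])


class TestRecordsAndInvariants:
    def test_record_identity_e_equals_sum(self, uniform_grid):
        legs = [
            _leg([(5.0, 5.0), (60.0, 5.0)], mode="bicycle", duration=8.0),
            _leg([(60.0, 5.0), (60.0, 80.0)], mode="walking", duration=15.0),
        ]
        subj = _make_subject(0, legs)
        rec = subject_record(subj, RatioTable.identity(), uniform_grid)
        total = sum(c["c_adjusted"] * c["duration_min"] for c in rec.legs)
        assert rec.e_subject == pytest.approx(total, abs=1e-9)
        assert rec.time_weighted == pytest.approx(rec.e_subject / rec.total_duration_min)

    def test_median_dose_over_median_exposure_per_mode(self, uniform_grid):
        """Constant-multiple property: the ratio of medians is the ventilation ratio."""
        rng = np.random.default_rng(13)
        ratios = {"walking": 1.7, "bicycle": 2.0, "motorized": 1.0, "public": 1.0}
        for mode, vr in ratios.items():
            exposures, doses = [], []
            for k in range(11):
                leg = _leg([(5.0, 5.0), (float(rng.uniform(20, 190)), 5.0)],
                           mode=mode, duration=float(rng.uniform(5, 40)))
                subj = _make_subject(k, [leg])
                rec = subject_record(subj, RatioTable.identity(), uniform_grid)
                exposures.append(rec.e_subject)
                doses.append(rec.dose)
            assert np.median(doses) / np.median(exposures) == pytest.approx(vr, abs=1e-12)

    def test_resolution_consistency_on_uniform_field(self):
        """Uniform latent field: C_subject identical across 25/50/100 m grids."""
        grids = [
            ConcentrationGrid(0.0, 0.0, c, np.full((int(200 // c), int(200 // c)), 37.0),
                              model_name=f"m{c:g}")
            for c in (25.0, 50.0, 100.0)
        ]
        rng = np.random.default_rng(2)
        legs = [
            _leg([tuple(p) for p in rng.uniform(0, 200, (4, 2))], duration=10.0)
            for _ in range(5)
        ]
        subj = _make_subject(0, legs)
        recs = compute_exposures([subj], RatioTable.identity(), grids)
        vals = [r.c_subject for r in recs]
        assert max(vals) - min(vals) < 1e-9
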