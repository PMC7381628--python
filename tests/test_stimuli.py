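"""Stimulus geometry, placement constraints, polarity and schedules."""

import math

import numpy as np
import pytest

from shapenum import stimuli
from shapenum.stimuli import (
    AREA_RADIUS_DEG, MIN_DISTANCE_DEG, VERTEX_EXCLUSION_DEG,
    Condition, ShapeSpec, InfeasibleGeometryError,
)


class TestPolygonVertices:
    def test_triangle_at_stated_convention(self):
        v = stimuli.polygon_vertices(ShapeSpec("triangle", 4.0))
        angles = np.degrees(np.arctan2(v[:, 1], v[:, 0])) % 360
        assert np.allclose(sorted(angles), [90, 210, 330])
        assert np.allclose(np.linalg.norm(v, axis=1), 4.0)

    @pytest.mark.parametrize("kind,expected_side", [
        ("square", math.sqrt(2) * 4.0),
        ("hexagon", 4.0),
    ])
    def test_side_lengths(self, kind, expected_side):
        v = stimuli.polygon_vertices(ShapeSpec(kind, 4.0))
        sides = np.linalg.norm(np.roll(v, -1, axis=0) - v, axis=1)
        assert np.allclose(sides, expected_side)

    def test_orientation_rotates_vertices(self):
        a = stimuli.polygon_vertices(ShapeSpec("square", 4.0, 0.0))
        b = stimuli.polygon_vertices(ShapeSpec("square", 4.0, math.pi / 2))
        # quarter turn maps the square onto itself
        assert np.allclose(sorted(map(tuple, np.round(a, 9))),
                           sorted(map(tuple, np.round(b, 9))))


class TestPlacement:
    def test_exp1_shape_elements_are_vertices(self):
        cond = Condition(1, "shape", 3)
        shape = ShapeSpec("triangle", 4.0, 0.3)
        layout = stimuli.place_on_vertices(cond, shape)
        assert np.array_equal(layout.centres,
                              stimuli.polygon_vertices(shape))

    def test_exp2_six_elements_three_on_vertices(self):
        cond = Condition(2, "shape", 6)
        shape = ShapeSpec("triangle", 4.0, 0.1)
        layout = stimuli.place_on_vertices(cond, shape, seed=5)
        verts = stimuli.polygon_vertices(shape)
        on_vertex = sum(
            any(np.allclose(c, v) for v in verts) for c in layout.centres)
        assert on_vertex == 3
        for c in layout.centres:
            assert stimuli.point_in_polygon(c, shape, tol=1e-9)

    def test_exp2_three_elements_degenerates_to_vertices(self):
        shape = ShapeSpec("triangle", 4.0, 0.2)
        a = stimuli.place_on_vertices(Condition(1, "shape", 3), shape)
        b = stimuli.place_on_vertices(Condition(2, "shape", 3), shape, seed=1)
        assert np.array_equal(a.centres, b.centres)

    def test_contour_placement_on_boundary_off_vertices(self):
        shape = ShapeSpec("triangle", 4.0, 0.0)
        layout = stimuli.place_random_on_contour(shape, 3, seed=11)
        verts = stimuli.polygon_vertices(shape)
        for c in layout.centres:
            assert stimuli.distance_to_contour(c, shape) < 1e-9
            assert min(np.linalg.norm(c - v) for v in verts) \
                >= VERTEX_EXCLUSION_DEG

    def test_contour_placement_deterministic(self):
        shape = ShapeSpec("hexagon", 4.0, 0.5)
        a = stimuli.place_random_on_contour(shape, 6, seed=7)
        b = stimuli.place_random_on_contour(shape, 6, seed=7)
        assert np.array_equal(a.centres, b.centres)

    def test_infeasible_contour_packing_raises(self):
        # tiny triangle: the perimeter cannot hold 6 separated elements
        shape = ShapeSpec("triangle", 0.9, 0.0)
        with pytest.raises(InfeasibleGeometryError):
            stimuli.place_random_on_contour(shape, 6, seed=0)

    def test_within_placement_stays_in_closed_triangle(self):
        shape = ShapeSpec("triangle", 4.0, 0.8)
        for seed in range(200):
            layout = stimuli.place_random_within(shape, 3, seed)
            for c in layout.centres:
                assert stimuli.point_in_polygon(c, shape, tol=1e-9)

    def test_within_placement_empty(self):
        layout = stimuli.place_random_within(ShapeSpec("triangle", 4.0), 0, 1)
        assert layout.n == 0

    def test_within_sampling_is_area_uniform(self):
        # compare two equal-area halves of the triangle (split by a median)
        shape = ShapeSpec("triangle", 4.0, 0.0)
        verts = stimuli.polygon_vertices(shape)
        a, b, c = verts
        mid_bc = (b + c) / 2
        rng_counts = [0, 0]
        n_draws = 4000
        for seed in range(n_draws):
            layout = stimuli.place_random_within(shape, 1, seed)
            p = layout.centres[0]
            u, w = mid_bc - a, p - a
            side = u[0] * w[1] - u[1] * w[0]
            rng_counts[0 if side > 0 else 1] += 1
        n = sum(rng_counts)
        se = math.sqrt(n * 0.25)
        assert abs(rng_counts[0] - n / 2) < 3 * se


class TestLayoutInvariants:
    @pytest.mark.parametrize("experiment", [1, 2, 3])
    def test_min_distance_and_area_over_many_layouts(self, experiment):
        count = 0
        for cond in stimuli.conditions_for_experiment(experiment):
            for seed in range(150):
                layout = stimuli.generate_layout(cond, seed * 0.01, seed)
                assert layout.min_pairwise_distance() >= MIN_DISTANCE_DEG - 1e-9
                assert np.linalg.norm(layout.centres, axis=1).max() \
                    <= AREA_RADIUS_DEG + 1e-9
                count += 1
        assert count == 8 * 150


class TestPolarity:
    def test_uniform_schemes(self):
        shape = ShapeSpec("triangle", 4.0)
        layout = stimuli.place_random_within(shape, 3, 1)
        assert stimuli.assign_polarity(layout, "all_white", 0).polarities \
            == ["white"] * 3
        assert stimuli.assign_polarity(layout, "all_black", 0).polarities \
            == ["black"] * 3

    def test_mixed_always_contains_both(self):
        shape = ShapeSpec("triangle", 4.0)
        layout = stimuli.place_random_within(shape, 3, 2)
        for seed in range(500):
            pol = stimuli.assign_polarity(layout, "mixed", seed).polarities
            assert "white" in pol and "black" in pol

    def test_mixed_white_count_matches_conditional_binomial(self):
        # conditioning Binomial(6, 1/2) on {1..5} leaves mean 3
        shape = ShapeSpec("triangle", 4.0)
        layout = stimuli.place_on_vertices(Condition(2, "shape", 6), shape, 3)
        counts = []
        for seed in range(4000):
            pol = stimuli.assign_polarity(layout, "mixed", seed).polarities
            counts.append(pol.count("white"))
        # variance of the conditional distribution: E[X^2|1..5] - 9
        p = np.array([math.comb(6, k) for k in range(1, 6)], dtype=float)
        p /= p.sum()
        var = float(sum(pk * k * k for pk, k in zip(p, range(1, 6))) - 9.0)
        se = math.sqrt(var / len(counts))
        assert abs(np.mean(counts) - 3.0) < 3 * se


class TestRender:
    def test_background_and_peaks(self):
        display = stimuli.DisplayGeometry()
        empty = stimuli.StimulusLayout(np.empty((0, 2)), [],
                                       Condition(1, "shape", 3))
        img = stimuli.render(empty, display)
        assert np.allclose(img, 65.5)

        one = stimuli.StimulusLayout(np.array([[0.0, 0.0]]), ["white"],
                                     Condition(1, "shape", 3))
        img = stimuli.render(one, display)
        # centre pixel sits within half a pixel of the exact centre
        assert img.max() == pytest.approx(65.5 * 1.9, rel=0.02)

        one.polarities = ["black"]
        img = stimuli.render(one, display)
        # trough within the sub-pixel sampling error of 65.5 * (1 - 0.90)
        assert 65.5 * 0.1 - 1e-9 <= img.min() <= 65.5 * 0.125
        assert img.min() >= 0

    def test_too_small_display_raises(self):
        tiny = stimuli.DisplayGeometry(height_px=300)
        empty = stimuli.StimulusLayout(np.empty((0, 2)), [],
                                       Condition(1, "shape", 3))
        with pytest.raises(stimuli.OutOfDisplayError):
            stimuli.render(empty, tiny)


class TestSchedule:
    def test_experiment1_design_counts(self):
        sched = stimuli.build_schedule(1, reps=100, seed=9)
        assert len(sched) == 800
        counts = sched.rows["condition"].value_counts()
        assert len(counts) == 8
        assert (counts == 100).all()

    def test_single_rep_all_distinct(self):
        sched = stimuli.build_schedule(2, reps=1, seed=0)
        assert len(sched) == 8
        assert sched.rows["condition"].nunique() == 8

    def test_schedule_deterministic(self):
        a = stimuli.build_schedule(3, reps=5, seed=42)
        b = stimuli.build_schedule(3, reps=5, seed=42)
        assert a.rows.equals(b.rows)

    def test_orientations_uniform_range(self):
        sched = stimuli.build_schedule(1, reps=50, seed=4)
        ori = sched.rows["orientation_rad"]
        assert (ori >= 0).all() and (ori < 2 * math.pi).all()
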