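"""Geometry of derived measurements: distances, deformation, line
intersections, fascicle length and pennation angle."""

import numpy as np
import pytest
from hypothesis import given, strategies as st

import sonopoint as sp
from sonopoint.measures import (
    DegenerateGeometry,
    MeasurementSpec,
    deformation_series,
    fascicle_metrics,
    line_intersection,
    pair_distance_series,
)


def traj(label_id, points, fps=50.0):
    return sp.Trajectory(label_id, np.asarray(points, dtype=float), fps=fps)


# -- pair distances --------------------------------------------------------

def test_pair_distance_345_triangle():
    a = traj(0, [[0.0, 0.0]] * 3)
    b = traj(1, [[3.0, 4.0]] * 3)
    series = pair_distance_series(a, b)
    np.testing.assert_allclose(series.values, 5.0)
    assert series.units == "px"


def test_pair_distance_pixel_pitch_converts_to_micrometres():
    a = traj(0, [[0.0, 0.0]])
    b = traj(1, [[3.0, 4.0]])
    series = pair_distance_series(a, b, pitch=75.0)
    np.testing.assert_allclose(series.values, 375.0)
    assert series.units == "um"


def test_coincident_points_have_zero_distance():
    a = traj(0, [[7.0, 7.0]])
    series = pair_distance_series(a, traj(1, [[7.0, 7.0]]))
    assert series.values[0] == 0.0


def test_mismatched_ranges_rejected():
    with pytest.raises(ValueError, match="frame range"):
        pair_distance_series(traj(0, [[0, 0]] * 3), traj(1, [[0, 0]] * 4))


rigid = st.tuples(
    st.floats(-np.pi, np.pi),
    st.floats(-50, 50),
    st.floats(-50, 50),
)


@given(transform=rigid)
def test_distance_invariant_under_rigid_transforms(transform):
    theta, tx, ty = transform
    rot = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
    pts_a = np.array([[1.0, 2.0], [3.0, 1.0]])
    pts_b = np.array([[4.0, 6.0], [0.0, 0.0]])
    base = pair_distance_series(traj(0, pts_a), traj(1, pts_b)).values
    moved = pair_distance_series(
        traj(0, pts_a @ rot.T + [tx, ty]), traj(1, pts_b @ rot.T + [tx, ty])
    ).values
    np.testing.assert_allclose(moved, base, atol=1e-9)


# -- deformation -----------------------------------------------------------

def test_deformation_formula():
    d0 = 10.0
    dist = sp.ScalarSeries("d", [d0, 1.1 * d0, 0.5 * d0], units="px")
    deform = deformation_series(dist, reference_frame=0)
    np.testing.assert_allclose(deform.values, [0.0, 0.1, -0.5])
    assert deform.units == "dimensionless"


def test_deformation_zero_reference_rejected():
    with pytest.raises(ValueError, match="positive"):
        deformation_series(sp.ScalarSeries("d", [0.0, 1.0]), 0)


def test_uniform_scaling_gives_deformation_s_minus_one():
    s = 1.3
    pts_a = np.array([[0.0, 0.0], [0.0, 0.0]])
    pts_b = np.array([[6.0, 8.0], [6.0 * s, 8.0 * s]])
    dist = pair_distance_series(traj(0, pts_a), traj(1, pts_b))
    deform = deformation_series(dist, reference_frame=0)
    np.testing.assert_allclose(deform.values[1], s - 1.0)


# -- line intersection -----------------------------------------------------

def test_axes_intersect_at_origin():
    p = line_intersection([0, 0], [1, 0], [0, 0], [0, 1])
    np.testing.assert_allclose(p, [0.0, 0.0], atol=1e-12)


def test_oblique_lines_algebraic_solution():
    # y = 2x + 1 and y = -x + 4 meet at (1, 3)
    p = line_intersection([0, 1], [1, 3], [0, 4], [4, 0])
    np.testing.assert_allclose(p, [1.0, 3.0], atol=1e-12)


def test_parallel_and_degenerate_lines_signal():
    with pytest.raises(DegenerateGeometry, match="parallel"):
        line_intersection([0, 0], [1, 0], [0, 5], [1, 5])
    with pytest.raises(DegenerateGeometry, match="coincident"):
        line_intersection([2, 2], [2, 2], [0, 0], [1, 1])


# -- fascicle metrics ------------------------------------------------------

def fascicle_setup(angle_deg, sep=60.0, n=1):
    """Horizontal aponeuroses ``sep`` px apart, fascicle at ``angle_deg`` to
    the deep (lower) aponeurosis; closed-form length is sep / sin(angle)."""
    theta = np.radians(angle_deg)
    d1 = [100.0, 100.0]
    fd = [100.0 + 10.0 * np.cos(theta), 100.0 - 10.0 * np.sin(theta)]
    pts = {
        0: [50.0, 40.0], 1: [150.0, 40.0],  # superficial
        2: d1, 3: [150.0, 100.0],           # deep
        4: fd,                               # along the fascicle
    }
    trajs = {i: traj(i, [p] * n) for i, p in pts.items()}
    spec = MeasurementSpec(
        kind="fascicle",
        roles={"sup_apo_1": 0, "sup_apo_2": 1, "deep_apo_1": 2, "deep_apo_2": 3,
               "fascicle_dir": 4},
    )
    return trajs, spec


def test_vertical_fascicle_length_equals_separation():
    trajs, spec = fascicle_setup(90.0)
    length, penn = fascicle_metrics(trajs, spec)
    np.testing.assert_allclose(length.values, 60.0, rtol=1e-9)
    np.testing.assert_allclose(penn.values, 90.0, rtol=1e-9)


def test_oblique_fascicle_matches_h_over_sin_theta():
    trajs, spec = fascicle_setup(20.0)
    length, penn = fascicle_metrics(trajs, spec)
    np.testing.assert_allclose(length.values, 60.0 / np.sin(np.radians(20.0)), rtol=1e-9)
    np.testing.assert_allclose(penn.values, 20.0, rtol=1e-9)


def test_fascicle_parallel_to_deep_aponeurosis_flags_frame():
    trajs, spec = fascicle_setup(20.0, n=2)
    # second frame: fascicle_dir moved onto the deep aponeurosis direction
    trajs[4].positions[1] = [110.0, 100.0]
    length, penn = fascicle_metrics(trajs, spec)
    assert np.isfinite(length.values[0]) and np.isnan(length.values[1])
    assert np.isfinite(penn.values[0]) and np.isnan(penn.values[1])


def test_fascicle_length_bounded_below_by_perpendicular_distance():
    for angle in (20.0, 45.0, 70.0, 90.0):
        trajs, spec = fascicle_setup(angle)
        length, _ = fascicle_metrics(trajs, spec)
        assert length.values[0] >= 60.0 - 1e-9
    trajs, spec = fascicle_setup(90.0)
    length, _ = fascicle_metrics(trajs, spec)
    np.testing.assert_allclose(length.values[0], 60.0)  # equality iff 90 deg


def test_metrics_invariant_to_superficial_point_swap():
    trajs, spec = fascicle_setup(33.0)
    length_a, penn_a = fascicle_metrics(trajs, spec)
    spec_swapped = MeasurementSpec(
        kind="fascicle",
        roles={"sup_apo_1": 1, "sup_apo_2": 0, "deep_apo_1": 2, "deep_apo_2": 3,
               "fascicle_dir": 4},
    )
    length_b, penn_b = fascicle_metrics(trajs, spec_swapped)
    np.testing.assert_allclose(length_b.values, length_a.values, atol=1e-9)
    np.testing.assert_allclose(penn_b.values, penn_a.values, atol=1e-9)


def test_pennation_invariant_to_deep_line_direction():
    """The acute angle does not depend on which way along the deep
    aponeurosis its second point lies."""
    trajs, spec = fascicle_setup(33.0)
    _, penn_a = fascicle_metrics(trajs, spec)
    flipped = dict(trajs)
    flipped[3] = traj(3, [[50.0, 100.0]])  # other side of deep_apo_1
    _, penn_b = fascicle_metrics(flipped, spec)
    np.testing.assert_allclose(penn_b.values, penn_a.values, atol=1e-9)


def test_spec_validation():
    with pytest.raises(ValueError, match="missing roles"):
        MeasurementSpec(kind="fascicle", roles={"a": 0, "b": 1})
    with pytest.raises(ValueError, match="distinct"):
        MeasurementSpec(kind="pair_distance", roles={"a": 0, "b": 0})
    with pytest.raises(ValueError, match="unknown"):
        MeasurementSpec(kind="area", roles={"a": 0, "b": 1})
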