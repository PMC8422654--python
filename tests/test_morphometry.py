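"""Geometric-morphometric primitives: curves, areas, GPA, disparity,
RRPP regression and trajectory analysis."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from charrdev.morphometry import (
    LandmarkConfig,
    centroid_size,
    disparity_test,
    dummy_code,
    gpa,
    polygon_area,
    procrustes_variance,
    resample_curve,
    rrpp_regression,
    standard_length,
    trajectory_analysis,
)


def _random_similarity(rng):
    a = rng.uniform(0, 2 * np.pi)
    rot = np.array([[np.cos(a), -np.sin(a)], [np.sin(a), np.cos(a)]])
    return rot, rng.uniform(0.5, 2.0), rng.uniform(-10, 10, 2)


# ---------------------------------------------------------------- curves

def test_resample_segment_and_endpoints():
    seg = np.array([[0.0, 0.0], [1.0, 0.0]])
    np.testing.assert_allclose(
        resample_curve(seg, 3), [[0, 0], [0.5, 0], [1, 0]], atol=1e-12
    )
    np.testing.assert_allclose(resample_curve(seg, 2), seg, atol=1e-12)


def test_resample_half_circle_equal_arc_spacing():
    # dense polyline along the unit half-circle: arc length pi, so 5
    # semilandmarks sit at arc positions k * pi / 4
    th = np.linspace(0, np.pi, 1001)
    curve = np.column_stack([np.cos(th), np.sin(th)])
    pts = resample_curve(curve, 5)
    angles = np.arctan2(pts[:, 1], pts[:, 0])
    arc = np.pi - np.unwrap(angles)[::-1] if angles[0] > angles[-1] else angles
    arc_pos = np.abs(np.arccos(np.clip(pts[:, 0], -1, 1)))
    np.testing.assert_allclose(arc_pos, np.arange(5) * np.pi / 4, atol=1e-3)


def test_resample_degenerate_curve_errors():
    with pytest.raises(ValueError, match="degenerate"):
        resample_curve(np.array([[1.0, 1.0], [1.0, 1.0]]), 4)
    with pytest.raises(ValueError):
        resample_curve(np.array([[0.0, 0.0], [1.0, 0.0]]), 1)


# ---------------------------------------------------------------- areas

@pytest.mark.parametrize(
    "pts,expected",
    [
        ([[0, 0], [1, 0], [1, 1], [0, 1]], 1.0),
        ([[0, 0], [4, 0], [0, 3]], 6.0),
    ],
)
def test_polygon_area_examples(pts, expected):
    assert polygon_area(np.array(pts, float)) == pytest.approx(expected)
    # orientation independence
    assert polygon_area(np.array(pts, float)[::-1]) == pytest.approx(expected)


def test_polygon_area_circle():
    ang = np.linspace(0, 2 * np.pi, 200, endpoint=False)
    circle = np.column_stack([np.cos(ang), np.sin(ang)])
    assert polygon_area(circle) == pytest.approx(np.pi, abs=1e-3)


def test_polygon_area_needs_three_points():
    with pytest.raises(ValueError):
        polygon_area(np.array([[0.0, 0.0], [1.0, 1.0]]))


@given(st.integers(min_value=0, max_value=10_000))
@settings(max_examples=50, deadline=None)
def test_polygon_area_matches_fan_triangulation(seed):
    """Shoelace area equals the sum of signed fan-triangle areas on random
    convex polygons."""
    rng = np.random.default_rng(seed)
    k = rng.integers(3, 40)
    ang = np.sort(rng.uniform(0, 2 * np.pi, k))
    r = rng.uniform(0.5, 3.0)
    pts = np.column_stack([r * np.cos(ang), r * np.sin(ang)]) + rng.uniform(-5, 5, 2)
    fan = 0.0
    for i in range(1, k - 1):
        a, b, c = pts[0], pts[i], pts[i + 1]
        fan += 0.5 * ((b[0] - a[0]) * (c[1] - a[1]) - (b[1] - a[1]) * (c[0] - a[0]))
    assert polygon_area(pts) == pytest.approx(abs(fan), rel=1e-10)


# ---------------------------------------------------------------- lengths

def _config_with_head(coords, head, tip, sid="s1"):
    return LandmarkConfig(
        specimen_id=sid, stage=None, coords=coords,
        curves={"head": head}, aux_points={"notochord": np.asarray(tip, float)},
    )


def test_standard_length_examples():
    coords = np.array([[0.0, 0.0], [1.0, 0.0], [0.0, 1.0]])
    cfg = _config_with_head(coords, np.array([[0.0, 0.0], [1.0, 0.0]]), (10.0, 0.0))
    assert standard_length(cfg) == pytest.approx(10.0)
    th = np.linspace(-np.pi, np.pi, 401)  # endpoints at (-1, 0), preserved
    circle = np.column_stack([np.cos(th), np.sin(th)])
    cfg2 = _config_with_head(coords, circle, (5.0, 0.0))
    assert standard_length(cfg2) == pytest.approx(6.0, abs=1e-3)


def test_standard_length_matches_bruteforce(rng):
    pts = rng.normal(size=(50, 2)).cumsum(axis=0)
    tip = rng.normal(size=2) * 5
    cfg = _config_with_head(np.array([[0, 0], [1, 0], [0, 1]], float), pts, tip)
    semis = resample_curve(pts, 50)
    brute = max(np.hypot(p[0] - tip[0], p[1] - tip[1]) for p in semis)
    assert standard_length(cfg) == pytest.approx(brute, rel=1e-12)


def test_standard_length_missing_parts_error():
    cfg = LandmarkConfig("s", None, np.array([[0, 0], [1, 0], [0, 1]], float))
    with pytest.raises(KeyError):
        standard_length(cfg)


# ---------------------------------------------------------------- GPA

def test_gpa_similarity_transforms_collapse(rng):
    base = rng.normal(size=(12, 2))
    configs = []
    for _ in range(10):
        rot, s, t = _random_similarity(rng)
        configs.append(s * (base @ rot.T) + t)
    res = gpa(np.stack(configs))
    for i in range(10):
        assert np.abs(res.aligned[i] - res.aligned[0]).max() < 1e-8


def test_gpa_identical_shapes_zero_distance(rng):
    base = rng.normal(size=(8, 2))
    res = gpa(np.stack([base, base.copy()]))
    assert np.abs(res.aligned[0] - res.aligned[1]).max() < 1e-12


def test_gpa_invariant_to_input_similarity_transform(rng):
    shapes = rng.normal(size=(6, 10, 2))
    res0 = gpa(shapes)
    transformed = np.empty_like(shapes)
    scales = np.empty(6)
    for i in range(6):
        rot, s, t = _random_similarity(rng)
        transformed[i] = s * (shapes[i] @ rot.T) + t
        scales[i] = s
    res1 = gpa(transformed)
    # aligned shapes agree up to a common rotation of the consensus frame
    h = res1.aligned.reshape(-1, 2).T @ res0.aligned.reshape(-1, 2)
    u, _, vt = np.linalg.svd(h)
    rot = u @ np.diag([1, np.sign(np.linalg.det(u @ vt))]) @ vt
    back = res1.aligned @ rot
    assert np.abs(back - res0.aligned).max() < 1e-8
    # centroid sizes multiply by the applied scale factor
    np.testing.assert_allclose(res1.centroid_sizes, res0.centroid_sizes * scales, rtol=1e-10)


def test_gpa_consensus_is_mean_of_aligned(rng):
    shapes = rng.normal(size=(7, 9, 2))
    res = gpa(shapes)
    mean = res.aligned.mean(axis=0)
    mean -= mean.mean(axis=0)
    mean /= np.sqrt((mean**2).sum())
    assert np.abs(mean - res.consensus).max() < 1e-8


def test_gpa_mismatched_landmark_counts_error(rng):
    a = LandmarkConfig("a", None, rng.normal(size=(5, 2)))
    b = LandmarkConfig("b", None, rng.normal(size=(6, 2)))
    with pytest.raises(ValueError, match="mismatched"):
        gpa([a, b])


def test_landmark_config_validation(rng):
    with pytest.raises(ValueError, match="at least 3"):
        LandmarkConfig("a", None, np.array([[0, 0], [1, 1]], float))
    with pytest.raises(ValueError, match="duplicated"):
        LandmarkConfig("a", None, np.array([[0, 0], [0, 0], [1, 1]], float))
    with pytest.raises(ValueError, match="non-finite"):
        LandmarkConfig("a", None, np.array([[0, 0], [np.nan, 1], [1, 1]]))


# ---------------------------------------------------------------- disparity

def test_disparity_identical_specimens_zero():
    y = np.tile(np.arange(8.0), (10, 1))
    groups = np.repeat(["a", "b"], 5)
    disp = procrustes_variance(y, groups)
    assert disp["a"] == 0.0 and disp["b"] == 0.0


def test_disparity_group_of_one_errors(rng):
    y = rng.normal(size=(3, 4))
    with pytest.raises(ValueError, match="fewer than 2"):
        procrustes_variance(y, ["a", "a", "b"])


def test_disparity_variance_scaling(rng):
    """Doubling the noise SD in one group quadruples its disparity."""
    n = 200
    y = np.vstack([rng.normal(0, 1, (n, 6)), rng.normal(0, 2, (n, 6))])
    groups = np.repeat(["a", "b"], n)
    disp = procrustes_variance(y, groups)
    assert 3.5 < disp["b"] / disp["a"] < 4.5
    tab = disparity_test(y, groups, n_perm=199, seed=1)
    assert tab.loc[0, "p"] <= 0.01


def test_disparity_test_seeded_reproducible(rng):
    y = rng.normal(size=(30, 6))
    groups = np.repeat(["a", "b", "c"], 10)
    t1 = disparity_test(y, groups, n_perm=99, seed=7)
    t2 = disparity_test(y, groups, n_perm=99, seed=7)
    pd.testing.assert_frame_equal(t1, t2)


# ---------------------------------------------------------------- RRPP

def test_rrpp_r2_sums_to_one(rng):
    n = 40
    y = rng.normal(size=(n, 10))
    terms = [
        ("cov", rng.normal(size=n)),
        ("grp", dummy_code(np.repeat(["a", "b"], n // 2))),
    ]
    tab = rrpp_regression(y, terms, n_perm=99, seed=0).set_index("term")
    total_r2 = tab.loc[["cov", "grp", "Residuals"], "R2"].sum()
    assert total_r2 == pytest.approx(1.0, abs=1e-10)
    assert tab.loc["cov", "SS"] + tab.loc["grp", "SS"] + tab.loc["Residuals", "SS"] == pytest.approx(
        tab.loc["Total", "SS"]
    )
    assert ((tab["p"].dropna() > 0) & (tab["p"].dropna() <= 1)).all()


def test_rrpp_power_and_specificity():
    """Strong size allometry with no group effect: the size term is detected
    and the group term stays null in nearly all replicates."""
    n = 60
    hits_size, hits_group = 0, 0
    reps = 60
    for rep in range(reps):
        rng = np.random.default_rng(1000 + rep)
        size = rng.normal(size=n)
        direction = rng.normal(size=8)
        y = np.outer(size, direction) + rng.normal(0, 0.5, (n, 8))
        groups = np.repeat(["a", "b", "c"], n // 3)
        tab = rrpp_regression(
            y, [("size", size), ("group", dummy_code(groups))],
            n_perm=199, seed=rep,
        ).set_index("term")
        hits_size += tab.loc["size", "p"] <= 0.01
        hits_group += tab.loc["group", "p"] > 0.05
    assert hits_size >= 0.95 * reps
    assert hits_group >= 0.85 * reps


def test_rrpp_aliased_term_named():
    n = 20
    rng = np.random.default_rng(0)
    y = rng.normal(size=(n, 4))
    g = np.repeat(["a", "b"], n // 2)
    with pytest.raises(ValueError, match="dup"):
        rrpp_regression(
            y, [("grp", dummy_code(g)), ("dup", dummy_code(g))], n_perm=99, seed=0
        )


def test_rrpp_effect_monotone_in_signal():
    """Larger injected effects give stochastically larger Z."""
    zs = []
    for strength in (0.0, 0.5, 2.0):
        vals = []
        for rep in range(10):
            rng = np.random.default_rng(rep)
            n = 40
            x = rng.normal(size=n)
            y = strength * np.outer(x, np.ones(6)) + rng.normal(size=(n, 6))
            tab = rrpp_regression(y, [("x", x)], n_perm=199, seed=rep)
            vals.append(tab.loc[0, "Z"])
        zs.append(np.mean(vals))
    assert zs[0] < zs[1] < zs[2]


# ---------------------------------------------------------------- trajectories

def _traj_data(rng, shift=0.0, scale_b=1.0):
    n_per = 12
    stages = np.tile(np.repeat([1, 2, 3, 4], n_per), 2)
    groups = np.repeat(["a", "b"], 4 * n_per)
    direction = np.zeros(6)
    direction[0] = 1.0
    y = np.zeros((len(groups), 6))
    for i, (g, s) in enumerate(zip(groups, stages)):
        scale = scale_b if g == "b" else 1.0
        y[i] = direction * (s - 1) * scale
        y[i, 1] = shift if g == "b" else 0.0
    return y, groups, stages


def test_trajectory_identical_means_null():
    rng = np.random.default_rng(3)
    y, groups, stages = _traj_data(rng)
    tab = trajectory_analysis(y, groups, stages, n_perm=99, seed=0)
    assert tab.loc[0, "path_length_diff"] == pytest.approx(0.0, abs=1e-12)
    assert tab.loc[0, "p_length"] > 0.99
    assert tab.loc[0, "shape_distance"] == pytest.approx(0.0, abs=1e-8)


def test_trajectory_constructed_path_length():
    """Scaling one group's stage means 2x along the shared direction
    doubles its path length."""
    rng = np.random.default_rng(4)
    y, groups, stages = _traj_data(rng, scale_b=2.0)
    tab = trajectory_analysis(y, groups, stages, n_perm=99, seed=0)
    # group a path = 3, group b path = 6
    assert tab.loc[0, "path_length_diff"] == pytest.approx(3.0, abs=1e-6)


def test_trajectory_missing_cell_errors(rng):
    y = rng.normal(size=(6, 4))
    groups = ["a", "a", "a", "b", "b", "b"]
    stages = [1, 2, 3, 1, 2, 2]
    with pytest.raises(ValueError, match="missing group x stage"):
        trajectory_analysis(y, groups, stages, n_perm=99, seed=0)
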