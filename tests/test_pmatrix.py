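"""P-matrix summaries, resampling nulls and Krzanowski common subspaces."""

import dataclasses

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import ortho_group

from charrdev import simulate as sim
from charrdev.mixed_models import ChainSettings
from charrdev.pmatrix import (
    PMatrixDraws,
    angle,
    angle_draws,
    assemble_P,
    eccentricity,
    fit_pmatrix,
    krzanowski_H,
    mean_standardize,
    project_ellipsoids,
    random_angle_null,
    subspace_null,
    variance_table,
    vtot,
    _clip_psd,
)


def _rand_psd(rng, p=7, scale=1.0):
    a = rng.normal(size=(p, p))
    return scale * (a @ a.T) / p


# ---------------------------------------------------------------- summaries

def test_vtot_examples():
    assert vtot(np.eye(7)) == pytest.approx(7.0)
    assert vtot(np.diag([1.0, 2, 3, 0, 0, 0, 0])) == pytest.approx(6.0)


def test_vtot_asymmetric_rejected(rng):
    m = rng.normal(size=(4, 4))
    with pytest.raises(ValueError, match="symmetric"):
        vtot(m)


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_vtot_equals_trace(seed):
    rng = np.random.default_rng(seed)
    m = _rand_psd(rng)
    assert abs(vtot(m) - np.trace(m)) < 1e-10


def test_eccentricity_examples():
    assert eccentricity(np.eye(7)) == pytest.approx(1.0)
    assert eccentricity(np.diag([4.0, 2, 1, 1, 1, 1, 1])) == pytest.approx(2.0)
    with pytest.raises(ValueError, match="degenerate"):
        eccentricity(np.diag([1.0, 0, 0]))


@given(st.integers(0, 10_000))
@settings(max_examples=30, deadline=None)
def test_eccentricity_rotation_invariant(seed):
    rng = np.random.default_rng(seed)
    m = _rand_psd(rng, p=5)
    q = ortho_group.rvs(5, random_state=rng)
    assert eccentricity(q @ m @ q.T) == pytest.approx(eccentricity(m), rel=1e-8)


def test_angle_examples():
    p = np.diag([5.0, 2, 1, 1, 1, 1, 1])
    assert angle(p, p) == pytest.approx(0.0)
    p2 = np.diag([1.0, 5, 1, 1, 1, 1, 1])
    assert angle(p, p2) == pytest.approx(90.0)
    v = np.zeros(7)
    v[:2] = 1 / np.sqrt(2)
    p3 = 4 * np.outer(v, v) + 0.5 * np.eye(7)
    assert angle(p3, p) == pytest.approx(45.0)


def test_angle_symmetric_in_arguments(rng):
    a, b = _rand_psd(rng), _rand_psd(rng)
    assert angle(a, b) == pytest.approx(angle(b, a))


def test_angle_degenerate_leading_space_warns():
    with pytest.warns(UserWarning, match="degenerate"):
        angle(np.eye(3), np.diag([2.0, 1.0, 0.5]))


def test_clip_psd():
    m = np.diag([1.0, -1e-12])
    clipped, was = _clip_psd(m)
    assert was
    assert np.linalg.eigvalsh(clipped).min() >= 0


# ---------------------------------------------------------------- assembly

def test_mean_standardization_scale_invariance(rng):
    df = pd.DataFrame({"a": rng.uniform(1, 2, 100), "b": rng.uniform(3, 4, 100)})
    v1 = mean_standardize(df, ["a", "b"])["a"].var()
    df2 = df.copy()
    df2["a"] *= 2.0  # doubling the raw scale
    v2 = mean_standardize(df2, ["a", "b"])["a"].var()
    assert v1 == pytest.approx(v2, rel=1e-12)


def test_assemble_requires_trait_count(rng):
    from charrdev.mixed_models import PosteriorSamples

    s = PosteriorSamples(
        fixed=np.zeros((10, 1)), fixed_names=["b"],
        G={"individual": np.stack([np.eye(3)] * 10)},
        R=np.stack([np.eye(3)] * 10), response_names=list("abc"),
    )
    with pytest.raises(ValueError, match="7 traits"):
        assemble_P(s, [f"t{i}" for i in range(7)])


def test_pmatrix_recovery_diagonal():
    """Known ind_cov = diag(1..7)/10: the posterior-mean P diagonal is
    recovered within 20% elementwise at n = 360."""
    rng = np.random.default_rng(0)
    n = 360
    truth = np.diag(np.arange(1, 8) / 10.0)
    ids = np.array([f"i{j}" for j in range(n)])
    fams = np.array([f"f{j % 9}" for j in range(n)])
    y = rng.multivariate_normal(np.zeros(7), truth, size=n)
    wide = pd.DataFrame(y, columns=[f"t{i}" for i in range(7)])
    wide["id"] = ids
    wide["family"] = fams
    draws = fit_pmatrix(
        wide, [f"t{i}" for i in range(7)], cross="x",
        chain=ChainSettings(1500, 300, 3, seed=1), standardize=False,
    )
    est = np.diag(draws.posterior_mean)
    assert np.all(np.abs(est - np.diag(truth)) / np.diag(truth) < 0.20)


# ---------------------------------------------------------------- angle null

def test_random_angle_null_seeded_and_power(rng):
    p = 7
    # focal cross: strong first axis; other cross: weaker orthogonal axis
    cov1 = np.diag([5.0] + [0.2] * (p - 1))
    cov2 = np.diag([0.2, 1.5] + [0.2] * (p - 2))
    x1 = rng.multivariate_normal(np.zeros(p), cov1, 120)
    x2 = rng.multivariate_normal(np.zeros(p), cov2, 120)
    null = random_angle_null(x1, x2, n_rep=300, seed=3)
    null_b = random_angle_null(x1, x2, n_rep=300, seed=3)
    np.testing.assert_array_equal(null["angles"], null_b["angles"])
    assert not null["with_replacement"]
    # observed angle between the two generating structures is 90 degrees,
    # far above the null upper bound
    obs = angle(np.cov(x1, rowvar=False), np.cov(x2, rowvar=False))
    assert obs > np.percentile(null["angles"], 97.5)


def test_random_angle_null_small_pool_flags_replacement(rng):
    x = rng.normal(size=(40, 7))
    null = random_angle_null(x[:20], x[20:], n_draw=150, n_rep=50, seed=0)
    assert null["with_replacement"]


# ---------------------------------------------------------------- subspaces

def test_krzanowski_identical_matrices():
    p = np.diag([5.0, 4, 3, 2, 1, 0.5, 0.25])
    res = krzanowski_H({"a": p, "b": p, "c": p}, k=3)
    np.testing.assert_allclose(res.eigenvalues[:3], 3.0, atol=1e-9)
    assert res.eigenvalues.max() <= 3 + 1e-9


def test_krzanowski_orthogonal_subspaces():
    a = np.diag([5.0, 1e-3, 1e-3, 1e-4])
    b = np.diag([1e-3, 5.0, 1e-3, 1e-4])
    res = krzanowski_H({"a": a, "b": b}, k=1)
    np.testing.assert_allclose(res.eigenvalues[:2], 1.0, atol=1e-9)


def test_krzanowski_matches_projector_oracle(rng):
    mats = {g: _rand_psd(rng, p=6) for g in "abc"}
    k = 2
    res = krzanowski_H(mats, k=k)
    h = np.zeros((6, 6))
    for m in mats.values():
        w, v = np.linalg.eigh(m)
        a = v[:, ::-1][:, :k]
        h += a @ a.T
    np.testing.assert_allclose(np.sort(res.eigenvalues), np.sort(np.linalg.eigvalsh(h)), atol=1e-10)
    assert res.eigenvalues.min() >= -1e-12 and res.eigenvalues.max() <= 3 + 1e-9


def test_krzanowski_k_bound():
    p = np.eye(7)
    with pytest.raises(ValueError, match="k must be"):
        krzanowski_H({"a": p, "b": p}, k=4)


def test_subspace_null_shapes_and_bounds(rng):
    data = {g: rng.normal(size=(40, 6)) for g in "abc"}
    null = subspace_null(data, k=2, n_rep=25, seed=1)
    assert null.shape == (25, 6)
    assert null.max() <= 3 + 1e-9 and null.min() >= -1e-12


# ---------------------------------------------------------------- ellipsoids

def _draws_from(m, n=5):
    return PMatrixDraws("x", np.stack([m] * n), [f"t{i}" for i in range(m.shape[0])])


def test_project_ellipsoids_reference_fraction():
    m = np.diag([5.0, 4, 3, 2, 1, 0.5, 0.25])
    out = project_ellipsoids({"a": _draws_from(m)}, reference="a")
    expected = (5 + 4 + 3) / vtot(m)
    assert out["a"]["captured_fraction"] == pytest.approx(expected)


def test_project_ellipsoids_isotropic():
    out = project_ellipsoids({"a": _draws_from(np.eye(7))}, reference="a")
    assert out["a"]["captured_fraction"] == pytest.approx(3.0 / 7.0)


def test_project_ellipsoids_trait_order_invariance(rng):
    m = _rand_psd(rng)
    perm = rng.permutation(7)
    m2 = m[np.ix_(perm, perm)]
    f1 = project_ellipsoids({"a": _draws_from(m)}, "a")["a"]["captured_fraction"]
    f2 = project_ellipsoids({"a": _draws_from(m2)}, "a")["a"]["captured_fraction"]
    assert f1 == pytest.approx(f2, rel=1e-10)


def test_variance_table_shape():
    m = np.diag(np.arange(1.0, 8.0))
    groups = {g: _draws_from(m, n=150) for g in ("PL", "SB", "F1")}
    tab = variance_table(groups)
    assert len(tab) == 21  # 7 traits x 3 crosses
    assert {"lo80", "hi80", "lo90", "hi90", "lo95", "hi95"} <= set(tab.columns)


def test_angle_draws_pairing(rng):
    a = PMatrixDraws("a", np.stack([_rand_psd(rng) for _ in range(120)]), list("abcdefg"))
    b = PMatrixDraws("b", np.stack([_rand_psd(rng) for _ in range(150)]), list("abcdefg"))
    th = angle_draws(a, b)
    assert th.shape == (120,)
    assert np.all((th >= 0) & (th <= 90))
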