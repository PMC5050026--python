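"""Reference paths and the (S, Z) path collective variables."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from confex.pathcv import (
    DegeneratePathError,
    ReferencePath,
    build_reference_path,
    choose_lambda,
    path_cv_values,
    path_cv_values_batch,
    path_cv_with_grad,
)


def test_two_node_path_is_endpoints():
    A, B = np.array([0.0]), np.array([1.0])
    path = build_reference_path(A, B, n_nodes=2)
    assert np.allclose(path.nodes.reshape(-1), [0.0, 1.0])


def test_linear_path_nodes_uniform():
    path = build_reference_path(np.array([0.0]), np.array([1.0]), n_nodes=31)
    assert np.allclose(path.nodes.reshape(-1), np.arange(31) / 30.0, atol=1e-3)


def test_degenerate_endpoints_rejected():
    with pytest.raises(DegeneratePathError):
        build_reference_path(np.array([1.0, 2.0]), np.array([1.0, 2.0]))


def test_curved_interpolant_reparameterized_equidistant(beads):
    """A curved A->B interpolant still yields near-equidistant nodes."""
    _, A, B = beads
    bump = np.sin(np.linspace(0, np.pi, A.size)).reshape(A.shape)

    def interp(t):
        return A + t * (B - A) + 0.8 * np.sin(np.pi * t) * bump

    path = build_reference_path(A, B, n_nodes=31, interpolant=interp)
    # recompute adjacent metric distances by brute force
    d = np.array(
        [
            float(np.sum((path.nodes[i + 1] - path.nodes[i]) ** 2)) / A.shape[0]
            for i in range(30)
        ]
    )
    assert np.all(np.abs(d - d.mean()) <= 0.05 * d.mean() + 1e-12)


def test_node_distance_matrix_gullwing(beads):
    """Distances grow monotonically away from the diagonal along rows."""
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=15)
    D = np.array([path.distances(n) for n in path.nodes])
    for i in range(15):
        row = D[i]
        assert np.all(np.diff(row[i:]) >= -1e-12)
        assert np.all(np.diff(row[: i + 1]) <= 1e-12)


def test_cv_at_node_limit():
    """With lambda*(adjacent distance) >> 1, x at node k gives S=k/(N-1), Z=0."""
    path = build_reference_path(np.array([0.0]), np.array([1.0]), n_nodes=11, lam=2000.0)
    for k in (0, 3, 7, 10):
        v = path_cv_values(path.nodes[k], path)
        assert np.isclose(v.S, k / 10.0, atol=1e-3)
        assert np.isclose(v.Z, 0.0, atol=1e-6)


def test_cv_hand_computed_three_node():
    """3-node path with hand-set distances checked against direct summation."""
    # single particle in 3D placed so the metric distances to the nodes
    # are exactly (0.5, 0.1, 0.9)
    d = np.array([0.5, 0.1, 0.9])
    nodes = np.array(
        [
            [np.sqrt(0.5), 0.0, 0.0],
            [0.0, np.sqrt(0.1), 0.0],
            [0.0, 0.0, np.sqrt(0.9)],
        ]
    ).reshape(3, 1, 3)
    path = ReferencePath(nodes=nodes, lam=2.0)
    x = np.zeros(3)
    assert np.allclose(path.distances(x), d)
    w = np.exp(-2.0 * d)
    S_expect = float(np.array([0.0, 0.5, 1.0]) @ w / w.sum())
    Z_expect = float(-np.log(w.sum()) / 2.0)
    v = path_cv_values(x, path)
    assert np.isclose(v.S, S_expect, atol=1e-12)
    assert np.isclose(v.Z, Z_expect, atol=1e-12)


def test_cv_symmetric_point_is_half():
    path = build_reference_path(np.array([-1.0, 0.0]), np.array([1.0, 0.0]), n_nodes=11)
    v = path_cv_values(np.array([0.0, 0.7]), path)
    assert np.isclose(v.S, 0.5, atol=1e-12)


def test_choose_lambda_formula():
    # adjacent metric distance 0.1 -> lambda 23; 1.0 -> 2.3
    nodes = np.cumsum(np.concatenate([[0.0], np.full(10, np.sqrt(0.1))]))
    path = ReferencePath(nodes=nodes.reshape(-1, 1), lam=1.0)
    assert np.isclose(choose_lambda(path), 23.0, rtol=1e-6)
    nodes = np.arange(11.0)
    path = ReferencePath(nodes=nodes.reshape(-1, 1), lam=1.0)
    assert np.isclose(choose_lambda(path), 2.3, rtol=1e-6)


def test_lambda_scales_with_refinement():
    """Refining the path shrinks the adjacent metric distance and raises
    lambda by the same factor (the metric is squared, so doubling the node
    count quarters the adjacent distance)."""
    A, B = np.array([0.0]), np.array([1.0])
    p31 = build_reference_path(A, B, n_nodes=31)
    p61 = build_reference_path(A, B, n_nodes=61)
    d31 = p31.adjacent_distances().mean()
    d61 = p61.adjacent_distances().mean()
    assert np.isclose(d61, d31 / 4.0, rtol=0.01)
    assert np.isclose(p61.lam / p31.lam, d31 / d61, rtol=1e-9)


def test_s_increases_along_path_and_z_softmin(beads):
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=21)
    S_vals = [path_cv_values(n, path).S for n in path.nodes]
    assert np.all(np.diff(S_vals) > 0)
    # Z lower bound -(ln N)/lambda and the softmin property
    x = A + 0.3 * (B - A)
    v = path_cv_values(x, path)
    d = path.distances(x)
    assert v.Z >= -np.log(path.n_nodes) / path.lam - 1e-12
    assert v.Z <= d.min() + 1e-12


def test_z_approaches_min_distance_at_large_lambda(beads):
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=21)
    span = path.adjacent_distances().mean()
    path.lam = 60.0 / span  # lambda * span >= 40
    x = A.reshape(-1) + 0.25 * (B - A).reshape(-1) + 0.05
    v = path_cv_values(x, path)
    assert np.isclose(v.Z, path.distances(x).min(), atol=1e-6)


def test_kabsch_metric_rototranslation_invariance(beads, rng):
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=11, metric_id="msd_kabsch")
    x = A + 0.4 * (B - A) + 0.1 * rng.standard_normal(A.shape)
    v0 = path_cv_values(x, path)
    # random rotation + translation of the query conformation
    q = rng.standard_normal((3, 3))
    R = np.linalg.qr(q)[0]
    if np.linalg.det(R) < 0:
        R[:, 0] *= -1
    moved = x @ R.T + rng.standard_normal(3)
    v1 = path_cv_values(moved, path)
    assert np.isclose(v0.S, v1.S, atol=1e-8)
    assert np.isclose(v0.Z, v1.Z, atol=1e-8)


def test_gradients_match_finite_differences(beads, rng):
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=15)
    h = 1e-6
    for _ in range(10):
        x = (A + rng.uniform(0, 1) * (B - A)).reshape(-1) + 0.2 * rng.standard_normal(A.size)
        S, Z, dS, dZ = path_cv_with_grad(x, path)
        for d in rng.choice(A.size, size=3, replace=False):
            e = np.zeros(A.size)
            e[d] = h
            vp, vm = path_cv_values(x + e, path), path_cv_values(x - e, path)
            assert np.isclose(dS[d], (vp.S - vm.S) / (2 * h), rtol=1e-4, atol=1e-8)
            assert np.isclose(dZ[d], (vp.Z - vm.Z) / (2 * h), rtol=1e-4, atol=1e-8)


def test_batch_agrees_with_scalar(beads, rng):
    _, A, B = beads
    path = build_reference_path(A, B, n_nodes=15)
    X = A.reshape(-1) + 0.5 * rng.standard_normal((8, A.size))
    S, Z = path_cv_values_batch(X, path)
    for i, row in enumerate(X):
        v = path_cv_values(row, path)
        assert np.isclose(S[i], v.S, atol=1e-12)
        assert np.isclose(Z[i], v.Z, atol=1e-12)


@settings(derandomize=True, max_examples=50)
@given(x=st.floats(-3.0, 3.0), lam=st.floats(0.5, 200.0))
def test_cv_bounds_property(x, lam):
    """S stays in [0,1] and Z above its softmin bound for any query point."""
    path = build_reference_path(np.array([0.0]), np.array([1.0]), n_nodes=11, lam=lam)
    v = path_cv_values(np.array([x]), path)
    assert -1e-12 <= v.S <= 1.0 + 1e-12
    assert v.Z >= -np.log(path.n_nodes) / lam - 1e-9
    assert np.isfinite(v.Z)
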