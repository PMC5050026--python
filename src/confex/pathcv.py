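"""Path collective variables: reference paths and the (S, Z) pair.

Given a discretized reference path {x_i, i=0..N-1} between two end
conformations and a metric distance d_i(x) from a configuration to node i,

    S(x) = sum_i (i/(N-1)) w_i / sum_i w_i,      w_i = exp(-lambda d_i)
    Z(x) = -(1/lambda) ln sum_i w_i

S is the dimensionless progress of the transition along the path (0 at the
first node, 1 at the last); Z is a soft-min distance to the path in metric
units.  The metric is the mean-squared deviation per particle, optionally
after optimal rigid-body superposition (Kabsch), so Z carries units of
length squared.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

__all__ = [
    "ReferencePath",
    "PathCVValue",
    "build_reference_path",
    "path_cv_values",
    "path_cv_values_batch",
    "path_cv_with_grad",
    "choose_lambda",
    "DegeneratePathError",
]


class DegeneratePathError(ValueError):
    """Raised when the two path endpoints coincide."""


def _msd(x: np.ndarray, ref: np.ndarray) -> float:
    d = x.reshape(-1) - ref.reshape(-1)
    return float(d @ d) / _n_particles(ref)


def _n_particles(conf: np.ndarray) -> int:
    return conf.shape[0] if conf.ndim > 1 else 1


def _kabsch_superpose(x: np.ndarray, ref: np.ndarray) -> np.ndarray:
    """Rotate+translate ``ref`` onto ``x`` (both (n, 3)); returns moved ref."""
    xc = x - x.mean(axis=0)
    rc = ref - ref.mean(axis=0)
    H = rc.T @ xc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(U @ Vt))
    D = np.diag([1.0] * (H.shape[0] - 1) + [d])
    R = (U @ D @ Vt).T
    return rc @ R.T + x.mean(axis=0)


@dataclass
class ReferencePath:
    """Ordered, approximately equidistant nodes between conformations A and B.

    ``nodes`` has shape (N, n_particles, ndim) (or (N, 1) for scalar toys);
    ``lam`` is the softmin smoothing parameter in 1/metric units;
    ``metric_id`` is ``"sq_euclid"`` (plain per-particle MSD) or
    ``"msd_kabsch"`` (MSD after optimal superposition).
    """

    nodes: np.ndarray
    lam: float
    metric_id: str = "sq_euclid"

    def __post_init__(self):
        self.nodes = np.asarray(self.nodes, dtype=float)
        if self.nodes.ndim == 1:
            self.nodes = self.nodes.reshape(-1, 1)
        if self.lam <= 0:
            raise ValueError("lambda must be positive")
        if self.metric_id not in ("sq_euclid", "msd_kabsch"):
            raise ValueError(f"unknown metric {self.metric_id!r}")

    @property
    def n_nodes(self) -> int:
        return self.nodes.shape[0]

    def distances(self, x: np.ndarray) -> np.ndarray:
        """Metric distance (length^2) from configuration x to every node."""
        x = np.asarray(x, dtype=float)
        if self.metric_id == "msd_kabsch":
            x3 = x.reshape(self.nodes.shape[1:])
            return np.array(
                [_msd(x3, _kabsch_superpose(x3, node)) for node in self.nodes]
            )
        flat = self.nodes.reshape(self.n_nodes, -1)
        d = flat - x.reshape(-1)
        return np.einsum("ij,ij->i", d, d) / _n_particles(self.nodes[0])

    def adjacent_distances(self) -> np.ndarray:
        return np.array(
            [self.distances(self.nodes[i])[i + 1] for i in range(self.n_nodes - 1)]
        )


@dataclass
class PathCVValue:
    S: float
    Z: float


def build_reference_path(
    A: np.ndarray,
    B: np.ndarray,
    n_nodes: int = 31,
    interpolant: Callable[[float], np.ndarray] | None = None,
    lam: float | None = None,
    metric_id: str = "sq_euclid",
    n_dense: int = 2001,
) -> ReferencePath:
    """Discretize an A->B path into ``n_nodes`` approximately equidistant nodes.

    By default the path is the straight-line interpolation in conformation
    space; a custom ``interpolant(t) -> conformation`` for t in [0, 1] may be
    supplied (it must hit A at 0 and B at 1).  The dense interpolant is
    reparameterized by accumulated root-metric arc length so that adjacent
    nodes are equidistant in the metric.  ``lam`` defaults to
    :func:`choose_lambda` on the finished path.
    """
    A = np.asarray(A, dtype=float)
    B = np.asarray(B, dtype=float)
    if A.shape != B.shape:
        raise ValueError("endpoint shapes differ")
    if not np.any(A != B):
        raise DegeneratePathError("path endpoints coincide")
    if n_nodes < 2:
        raise ValueError("n_nodes must be >= 2")
    if interpolant is None:
        def interpolant(t):
            return A + t * (B - A)
    ts = np.linspace(0.0, 1.0, n_dense)
    dense = np.array([interpolant(t) for t in ts], dtype=float)
    seg = (dense[1:] - dense[:-1]).reshape(n_dense - 1, -1)
    step = np.sqrt(
        np.einsum("ij,ij->i", seg, seg) / _n_particles(A)
    )  # root-metric length of each dense segment
    arclen = np.concatenate([[0.0], np.cumsum(step)])
    targets = np.linspace(0.0, arclen[-1], n_nodes)
    flat = dense.reshape(n_dense, -1)
    nodes = np.stack(
        [np.interp(targets, arclen, flat[:, d]) for d in range(flat.shape[1])],
        axis=1,
    ).reshape((n_nodes,) + A.shape)
    nodes[0], nodes[-1] = A, B
    path = ReferencePath(nodes=nodes, lam=1.0, metric_id=metric_id)
    path.lam = lam if lam is not None else choose_lambda(path)
    return path


def choose_lambda(path: ReferencePath) -> float:
    """Default softmin smoothing: lambda = 2.3 / mean adjacent-node distance.

    Makes exp(-lambda*d) drop by about an order of magnitude per node, the
    customary choice for path CVs; override freely.
    """
    return 2.3 / float(path.adjacent_distances().mean())


def path_cv_values(x: np.ndarray, path: ReferencePath) -> PathCVValue:
    """Evaluate (S, Z) for one configuration (overflow-guarded softmin)."""
    d = path.distances(x)
    m = d.min()
    w = np.exp(-path.lam * (d - m))
    wsum = w.sum()
    f = np.arange(path.n_nodes) / (path.n_nodes - 1)
    S = float(f @ w / wsum)
    Z = float(m - np.log(wsum) / path.lam)
    return PathCVValue(S=S, Z=Z)


def path_cv_values_batch(X: np.ndarray, path: ReferencePath):
    """(S, Z) for many configurations at once (sq_euclid metric only).

    ``X`` is (n, dof); returns ``(S, Z)`` arrays of length n.  Used by
    vectorised basin predicates in rate calculations.
    """
    if path.metric_id != "sq_euclid":
        raise NotImplementedError("batch evaluation supports sq_euclid only")
    X = np.atleast_2d(np.asarray(X, dtype=float))
    flat = path.nodes.reshape(path.n_nodes, -1)
    n_at = _n_particles(path.nodes[0])
    diff = X[:, None, :] - flat[None, :, :]  # (n, N, dof)
    d = np.einsum("inj,inj->in", diff, diff) / n_at
    m = d.min(axis=1, keepdims=True)
    w = np.exp(-path.lam * (d - m))
    wsum = w.sum(axis=1)
    f = np.arange(path.n_nodes) / (path.n_nodes - 1)
    S = (w @ f) / wsum
    Z = m[:, 0] - np.log(wsum) / path.lam
    return S, Z


def path_cv_with_grad(x: np.ndarray, path: ReferencePath):
    """(S, Z) and their gradients w.r.t. the flattened configuration.

    Only the plain squared-deviation metric has an implemented gradient
    (biased sampling on the toys never needs the Kabsch metric).
    """
    if path.metric_id != "sq_euclid":
        raise NotImplementedError("gradients implemented for sq_euclid only")
    xf = np.asarray(x, dtype=float).reshape(-1)
    n_at = _n_particles(path.nodes[0])
    flat = path.nodes.reshape(path.n_nodes, -1)
    if flat.shape[1] == 1:  # hot path for scalar toys
        diff1 = xf[0] - flat[:, 0]
        d = diff1 * diff1
        dd_dx = (2.0 * diff1)[:, None]
    else:
        diff = xf - flat  # (N, dof)
        d = np.einsum("ij,ij->i", diff, diff) / n_at
        dd_dx = 2.0 * diff / n_at  # (N, dof)
    m = d.min()
    w = np.exp(-path.lam * (d - m))
    wsum = w.sum()
    p = w / wsum
    f = np.arange(path.n_nodes) / (path.n_nodes - 1)
    S = float(f @ p)
    Z = float(m - np.log(wsum) / path.lam)
    # dS/dx = -lambda * sum_i (f_i - S) p_i dd_i/dx ; dZ/dx = sum_i p_i dd_i/dx
    dS = -path.lam * ((f - S) * p) @ dd_dx
    dZ = p @ dd_dx
    return S, Z, dS, dZ
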