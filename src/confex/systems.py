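"""Synthetic two-state energy models, Langevin sampling and brute-force oracles.

The models here stand in for a molecular force field: analytic potentials
with a sparsely populated minor basin, tunable free-energy asymmetry and
barrier height, plus a toy multi-particle "bead" model with two reference
conformations for path-CV and restrained-ensemble work.  Everything is in
reduced units (kBT = 1 by default).

Conventions
-----------
The deeper basin plays the role of the ground (G) state, the shallower one
the excited (E) state; ``delta_G_true`` = E(E-minimum) - E(G-minimum) is
positive when E is the minor state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

__all__ = [
    "EnergyModel",
    "DoubleWell1D",
    "ThreeHole2D",
    "TwoStateBeads",
    "SimulationParams",
    "Trajectory",
    "SimulationDivergence",
    "run_langevin",
    "run_langevin_batch",
    "quadrature_free_energy",
    "brute_force_rates",
    "make_two_state_beads",
]

_DIVERGENCE_ENERGY = 1e8


class SimulationDivergence(RuntimeError):
    """Raised when the integrator leaves the finite-energy domain."""


class EnergyModel:
    """Base class for analytic potential-energy models.

    Subclasses provide ``potential`` and ``gradient`` acting on a single
    configuration (1-D array of length :attr:`dimensionality`) and, where
    useful, vectorised ``potential_batch``/``gradient_batch`` acting on an
    ``(n, dof)`` array of configurations.
    """

    form_id: str = "base"
    dimensionality: int = 1

    def potential(self, x: np.ndarray) -> float:
        raise NotImplementedError

    def gradient(self, x: np.ndarray) -> np.ndarray:
        raise NotImplementedError

    # Batched defaults loop over rows; subclasses override with vector code.
    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.potential(row) for row in np.atleast_2d(X)])

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        return np.array([self.gradient(row) for row in np.atleast_2d(X)])

    def parameters(self) -> dict:
        return {}


@dataclass
class DoubleWell1D(EnergyModel):
    """Quartic double well with an exactly controlled minimum-to-minimum gap.

    ``V(x) = barrier * ((x/a)^2 - 1)^2 + (delta/2) * s(x/a)`` where ``s`` is
    ``sin(pi*u/2)`` clipped to +-1 outside ``|u| <= 1``.  The tilt has zero
    slope at ``u = +-1``, so the minima stay exactly at ``x = -a`` (G state)
    and ``x = +a`` (E state) and their energy difference is exactly
    ``delta_G_true``.  The barrier seen from the G minimum is
    ``barrier + delta/2`` to leading order.
    """

    barrier: float = 7.0
    delta_G_true: float = 1.5
    well_separation: float = 2.0  # distance between the two minima

    form_id: str = "double_well_1d"
    dimensionality: int = 1

    @property
    def a(self) -> float:
        return self.well_separation / 2.0

    def _tilt(self, u: np.ndarray) -> np.ndarray:
        return np.where(np.abs(u) < 1.0, np.sin(0.5 * np.pi * u), np.sign(u))

    def _tilt_deriv(self, u: np.ndarray) -> np.ndarray:
        return np.where(
            np.abs(u) < 1.0, 0.5 * np.pi * np.cos(0.5 * np.pi * u), 0.0
        )

    def potential(self, x: np.ndarray) -> float:
        return float(self.potential_batch(np.atleast_2d(x))[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        # scalar hot path used by the step loops
        u = float(x[0]) / self.a
        tilt_d = 0.5 * np.pi * np.cos(0.5 * np.pi * u) if abs(u) < 1.0 else 0.0
        g = (
            4.0 * self.barrier * u * (u * u - 1.0)
            + 0.5 * self.delta_G_true * tilt_d
        ) / self.a
        return np.array([g])

    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        u = np.asarray(X).reshape(-1) / self.a
        return self.barrier * (u**2 - 1.0) ** 2 + 0.5 * self.delta_G_true * self._tilt(u)

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        u = np.asarray(X).reshape(-1) / self.a
        g = (
            4.0 * self.barrier * u * (u**2 - 1.0)
            + 0.5 * self.delta_G_true * self._tilt_deriv(u)
        ) / self.a
        return g.reshape(-1, 1)

    @property
    def minima(self) -> tuple[float, float]:
        """(G minimum, E minimum) positions."""
        return (-self.a, self.a)

    def parameters(self) -> dict:
        return {
            "barrier": self.barrier,
            "delta_G_true": self.delta_G_true,
            "well_separation": self.well_separation,
        }


@dataclass
class ThreeHole2D(EnergyModel):
    """The classic three-hole 2-D model potential (two deep wells, one shallow
    upper channel); used for 2-D free-energy-surface exercises."""

    form_id: str = "three_hole_2d"
    dimensionality: int = 2

    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        x, y = X[:, 0], X[:, 1]
        return (
            3.0 * np.exp(-(x**2) - (y - 1.0 / 3.0) ** 2)
            - 3.0 * np.exp(-(x**2) - (y - 5.0 / 3.0) ** 2)
            - 5.0 * np.exp(-((x - 1.0) ** 2) - y**2)
            - 5.0 * np.exp(-((x + 1.0) ** 2) - y**2)
            + 0.2 * x**4
            + 0.2 * (y - 1.0 / 3.0) ** 4
        )

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        x, y = X[:, 0], X[:, 1]
        e1 = np.exp(-(x**2) - (y - 1.0 / 3.0) ** 2)
        e2 = np.exp(-(x**2) - (y - 5.0 / 3.0) ** 2)
        e3 = np.exp(-((x - 1.0) ** 2) - y**2)
        e4 = np.exp(-((x + 1.0) ** 2) - y**2)
        gx = (
            -6.0 * x * e1
            + 6.0 * x * e2
            + 10.0 * (x - 1.0) * e3
            + 10.0 * (x + 1.0) * e4
            + 0.8 * x**3
        )
        gy = (
            -6.0 * (y - 1.0 / 3.0) * e1
            + 6.0 * (y - 5.0 / 3.0) * e2
            + 10.0 * y * e3
            + 10.0 * y * e4
            + 0.8 * (y - 1.0 / 3.0) ** 3
        )
        return np.stack([gx, gy], axis=1)

    def potential(self, x: np.ndarray) -> float:
        return float(self.potential_batch(np.atleast_2d(x))[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.gradient_batch(np.atleast_2d(x))[0]


@dataclass
class TwoStateBeads(EnergyModel):
    """Multi-particle toy with two reference conformations A and B.

    The energy is a double well along the normalised A->B interpolation
    coordinate ``s`` (minima at s=0 and s=1, asymmetry ``delta_G_true``,
    barrier ``barrier``) plus a harmonic restraint of stiffness
    ``orthogonal_stiffness`` on the component of the configuration
    orthogonal to the A->B direction.  With stiff orthogonal modes the
    system is effectively one slow coordinate, which keeps quadrature
    oracles exact up to an additive constant.
    """

    A: np.ndarray = None  # (n_beads, ndim)
    B: np.ndarray = None
    barrier: float = 7.0
    delta_G_true: float = 1.5
    orthogonal_stiffness: float = 50.0

    form_id: str = "two_state_beads"

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.B = np.asarray(self.B, dtype=float)
        if self.A.shape != self.B.shape:
            raise ValueError("A and B must have the same shape")
        if not np.any(self.A != self.B):
            raise ValueError("reference conformations A and B must differ")
        self._a_flat = self.A.reshape(-1)
        self._u = self.B.reshape(-1) - self._a_flat
        self._L2 = float(self._u @ self._u)
        self.dimensionality = self._a_flat.size

    @property
    def n_beads(self) -> int:
        return self.A.shape[0]

    def progress(self, x: np.ndarray) -> float:
        """Normalised A->B interpolation coordinate s (0 at A, 1 at B)."""
        return float((np.asarray(x).reshape(-1) - self._a_flat) @ self._u / self._L2)

    def _dw(self, s: np.ndarray):
        # double well in q = 2s-1 with the same clipped-sine tilt as DoubleWell1D
        q = 2.0 * np.asarray(s) - 1.0
        tilt = np.where(np.abs(q) < 1.0, np.sin(0.5 * np.pi * q), np.sign(q))
        dtilt = np.where(np.abs(q) < 1.0, 0.5 * np.pi * np.cos(0.5 * np.pi * q), 0.0)
        v = self.barrier * (q**2 - 1.0) ** 2 + 0.5 * self.delta_G_true * tilt
        dv_dq = 4.0 * self.barrier * q * (q**2 - 1.0) + 0.5 * self.delta_G_true * dtilt
        return v, 2.0 * dv_dq  # dV/ds

    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        rel = X - self._a_flat
        s = rel @ self._u / self._L2
        y = rel - np.outer(s, self._u)
        v, _ = self._dw(s)
        return v + 0.5 * self.orthogonal_stiffness * np.einsum("ij,ij->i", y, y)

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        rel = X - self._a_flat
        s = rel @ self._u / self._L2
        y = rel - np.outer(s, self._u)
        _, dv_ds = self._dw(s)
        return np.outer(dv_ds / self._L2, self._u) + self.orthogonal_stiffness * y

    def potential(self, x: np.ndarray) -> float:
        return float(self.potential_batch(np.asarray(x).reshape(1, -1))[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.gradient_batch(np.asarray(x).reshape(1, -1))[0]

    def line_configuration(self, s) -> np.ndarray:
        """Flattened configuration A + s*(B - A); the zero-Z ridge line."""
        s = np.asarray(s)
        return self._a_flat + np.multiply.outer(s, self._u)

    def parameters(self) -> dict:
        return {
            "n_beads": self.n_beads,
            "barrier": self.barrier,
            "delta_G_true": self.delta_G_true,
            "orthogonal_stiffness": self.orthogonal_stiffness,
        }


def make_two_state_beads(
    n_beads: int,
    displacement: float,
    delta_G_true: float,
    barrier: float,
    seed: int,
    ndim: int = 3,
    orthogonal_stiffness: float = 50.0,
):
    """Build a seeded two-state bead model.

    Returns ``(model, A, B)`` where A and B are ``(n_beads, ndim)`` reference
    conformations separated by a configuration-space distance
    ``displacement``.
    """
    if n_beads < 3:
        raise ValueError("n_beads must be >= 3")
    if displacement <= 0:
        raise ValueError("displacement must be positive (degenerate path)")
    rng = np.random.default_rng(seed)
    A = rng.normal(scale=1.0, size=(n_beads, ndim))
    direction = rng.normal(size=(n_beads, ndim))
    direction /= np.linalg.norm(direction)
    B = A + displacement * direction
    model = TwoStateBeads(
        A=A,
        B=B,
        barrier=barrier,
        delta_G_true=delta_G_true,
        orthogonal_stiffness=orthogonal_stiffness,
    )
    return model, A, B


@dataclass
class SimulationParams:
    """Langevin integration parameters in reduced units."""

    n_steps: int
    dt: float = 0.005
    kBT: float = 1.0
    friction: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.kBT <= 0:
            raise ValueError("kBT must be positive")
        if self.dt * self.friction >= 1.0:
            raise ValueError("stability bound dt*friction < 1 violated")


@dataclass
class Trajectory:
    """Uniformly spaced trajectory with optional CV and bias records."""

    times: np.ndarray
    frames: np.ndarray  # (n_frames, dof)
    energies: np.ndarray | None = None
    cv_series: np.ndarray | None = None  # (n_frames, n_cv)
    bias_series: np.ndarray | None = None  # instantaneous bias at each frame

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        self.frames = np.asarray(self.frames, dtype=float)
        if not np.all(np.isfinite(self.frames)):
            raise ValueError("non-finite coordinates in trajectory")
        if len(self.times) > 2:
            dts = np.diff(self.times)
            if not np.allclose(dts, dts[0], rtol=1e-8, atol=1e-12):
                raise ValueError("trajectory times must be uniformly spaced")


def _baoab_coeffs(params: SimulationParams):
    c1 = np.exp(-params.friction * params.dt)
    c2 = np.sqrt(params.kBT * (1.0 - c1 * c1))
    return c1, c2


def run_langevin(
    model: EnergyModel,
    params: SimulationParams,
    x0: np.ndarray,
    bias_force: Callable[[np.ndarray], np.ndarray] | None = None,
    stride: int = 1,
    callback: Callable[[int, np.ndarray], bool] | None = None,
) -> Trajectory:
    """Integrate underdamped Langevin dynamics with the BAOAB splitting.

    ``bias_force(x)`` (if given) returns an extra force added to the model
    force each step.  ``callback(step, x)`` (if given) is called every step
    and may return True to stop early (used for first-passage sampling).
    Identical seeds reproduce trajectories bit-for-bit.
    """
    rng = np.random.default_rng(params.seed)
    x = np.array(x0, dtype=float).reshape(-1)
    v = np.zeros_like(x)
    c1, c2 = _baoab_coeffs(params)
    half_dt = 0.5 * params.dt

    def force(x):
        f = -model.gradient(x)
        if bias_force is not None:
            f = f + bias_force(x)
        return f

    f = force(x)
    n_out = params.n_steps // stride + 1
    frames = np.empty((n_out, x.size))
    energies = np.empty(n_out)
    times = np.empty(n_out)
    frames[0], energies[0], times[0] = x, model.potential(x), 0.0
    k = 1
    for step in range(1, params.n_steps + 1):
        v += half_dt * f
        x += half_dt * v
        v = c1 * v + c2 * rng.standard_normal(x.size)
        x += half_dt * v
        f = force(x)
        v += half_dt * f
        if step % stride == 0 and k < n_out:
            e = model.potential(x)
            if not np.isfinite(e) or e > _DIVERGENCE_ENERGY:
                raise SimulationDivergence(
                    f"energy {e!r} at step {step}; reduce dt or check the model"
                )
            frames[k], energies[k], times[k] = x, e, step * params.dt
            k += 1
        if callback is not None and callback(step, x):
            frames, energies, times = frames[:k], energies[:k], times[:k]
            break
    return Trajectory(times=times, frames=frames, energies=energies)


def run_langevin_batch(
    model: EnergyModel,
    params: SimulationParams,
    X0: np.ndarray,
    stop_predicate: Callable[[np.ndarray], np.ndarray],
    max_steps: int | None = None,
) -> np.ndarray:
    """Run independent walkers in parallel until each satisfies
    ``stop_predicate`` (vectorised over configurations); returns the
    first-passage time of each walker (NaN for walkers that never stop).

    This is the engine behind the brute-force rate oracle: all walkers are
    stepped together so the per-step cost is one vectorised force call.
    """
    rng = np.random.default_rng(params.seed)
    X = np.array(np.atleast_2d(X0), dtype=float)
    n, dof = X.shape
    V = np.zeros_like(X)
    c1, c2 = _baoab_coeffs(params)
    half_dt = 0.5 * params.dt
    F = -model.gradient_batch(X)
    fpt = np.full(n, np.nan)
    active = np.ones(n, dtype=bool)
    max_steps = max_steps or params.n_steps
    for step in range(1, max_steps + 1):
        V += half_dt * F
        X += half_dt * V
        V = c1 * V + c2 * rng.standard_normal((n, dof))
        X += half_dt * V
        F = -model.gradient_batch(X)
        V += half_dt * F
        hit = stop_predicate(X) & active
        if np.any(hit):
            fpt[hit] = step * params.dt
            active &= ~hit
            if not active.any():
                break
            # freeze finished walkers so they stop consuming dynamics
            V[~active] = 0.0
            F[~active] = 0.0
    return fpt


def quadrature_free_energy(
    model: EnergyModel,
    cv_func: Callable[[np.ndarray], np.ndarray],
    grid: np.ndarray,
    kBT: float,
    domain: Sequence[tuple[float, float]],
    n_points: int = 4001,
):
    """Ground-truth free energy on a CV grid by direct Boltzmann quadrature.

    Integrates ``exp(-V/kBT)`` over the model coordinates (1-D or 2-D dense
    mesh over ``domain``), bins the weight by the CV value, and returns
    ``F = -kBT ln(weight / binwidth)`` normalised to ``min F = 0``.
    ``cv_func`` maps an ``(n, dof)`` coordinate array to ``n`` CV values.
    Bins never visited carry ``+inf``.
    """
    domain = list(domain)
    if len(domain) == 1:
        xs = np.linspace(domain[0][0], domain[0][1], n_points)
        pts = xs.reshape(-1, 1)
        dvol = xs[1] - xs[0]
    elif len(domain) == 2:
        m = int(np.sqrt(n_points))
        xs = np.linspace(domain[0][0], domain[0][1], m)
        ys = np.linspace(domain[1][0], domain[1][1], m)
        XX, YY = np.meshgrid(xs, ys, indexing="ij")
        pts = np.stack([XX.ravel(), YY.ravel()], axis=1)
        dvol = (xs[1] - xs[0]) * (ys[1] - ys[0])
    else:
        raise ValueError("quadrature supports 1-D or 2-D coordinate domains")
    V = model.potential_batch(pts)
    if not np.all(np.isfinite(V)):
        raise ValueError("non-finite energy in quadrature domain")
    w = np.exp(-(V - V.min()) / kBT) * dvol
    c = np.asarray(cv_func(pts)).reshape(-1)
    grid = np.asarray(grid, dtype=float)
    edges = np.concatenate(
        [
            [grid[0] - 0.5 * (grid[1] - grid[0])],
            0.5 * (grid[1:] + grid[:-1]),
            [grid[-1] + 0.5 * (grid[-1] - grid[-2])],
        ]
    )
    weight, _ = np.histogram(c, bins=edges, weights=w)
    widths = np.diff(edges)
    with np.errstate(divide="ignore"):
        F = -kBT * np.log(weight / widths)
    F = F - F.min()
    from .metad import FreeEnergySurface  # local import avoids a cycle

    return FreeEnergySurface(grid=(grid,), F=F, kBT=kBT, checkpoint_time=0.0)


def brute_force_rates(
    model: EnergyModel,
    params: SimulationParams,
    state_defs: tuple[Callable, Callable],
    n_events: int,
    start_points: tuple[np.ndarray, np.ndarray] | None = None,
    max_steps: int | None = None,
    n_boot: int = 1000,
):
    """Unbiased mean first-passage times between two basins.

    ``state_defs = (in_G, in_E)`` are vectorised committed-basin predicates
    over ``(n, dof)`` coordinate arrays.  ``n_events`` walkers are launched
    from each basin minimum and run until committed arrival in the other
    basin.  Returns ``(tau_G_to_E, tau_E_to_G)`` as dicts with the mean
    lifetime, bootstrap standard error and the raw first-passage samples.

    Raises ``TimeoutError`` if fewer than ``n_events`` transitions complete
    within the step budget.
    """
    in_G, in_E = state_defs
    if start_points is None:
        if not isinstance(model, DoubleWell1D):
            raise ValueError("start_points required for non-1D models")
        start_points = (
            np.array([model.minima[0]]),
            np.array([model.minima[1]]),
        )
    out = []
    for direction, (x0, target) in enumerate(
        [(start_points[0], in_E), (start_points[1], in_G)]
    ):
        X0 = np.tile(np.asarray(x0, dtype=float).reshape(1, -1), (n_events, 1))
        p = SimulationParams(
            n_steps=params.n_steps,
            dt=params.dt,
            kBT=params.kBT,
            friction=params.friction,
            seed=params.seed + direction,
        )
        fpt = run_langevin_batch(model, p, X0, target, max_steps=max_steps)
        if np.isnan(fpt).any():
            raise TimeoutError(
                f"only {np.sum(np.isfinite(fpt))}/{n_events} transitions "
                "within the step budget"
            )
        rng = np.random.default_rng(params.seed + 100 + direction)
        boots = rng.choice(fpt, size=(n_boot, len(fpt))).mean(axis=1)
        out.append(
            {
                "mean_tau": float(fpt.mean()),
                "se": float(boots.std(ddof=1)),
                "samples": fpt,
            }
        )
    return tuple(out)
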