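"""Adiabatic-biased (ratchet-and-pawl) dynamics for cavity escape.

A ratcheting potential selects spontaneous fluctuations of a reaction
coordinate rho (here the Euclidean deviation of a tracer particle from its
bound pose) toward the unbound state: the bias is zero whenever rho reaches
a new maximum, and a harmonic penalty (k/2)(rho - rho_best)^2 opposes
regression below the best progress so far.  The ratchet never performs
work along forward displacements, so the escape pathway is chosen by the
system's own fluctuations; robustness is checked by repeating runs at two
force constants (defaults 20 and 50).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .systems import EnergyModel, SimulationParams, _baoab_coeffs

__all__ = [
    "RatchetState",
    "ShellWithGaps3D",
    "ratchet_bias",
    "run_abmd_escape",
    "EscapeResult",
]


@dataclass
class RatchetState:
    """Best-progress bookkeeping for the ratchet potential."""

    rho_best: float
    k: float = 20.0

    def __post_init__(self):
        if self.k < 0:
            raise ValueError("force constant must be non-negative")


def ratchet_bias(rho_t: float, state: RatchetState) -> tuple[float, RatchetState]:
    """Ratchet energy at coordinate value ``rho_t``; updates best progress.

    Returns ``(energy, state)`` with energy 0 (and ``rho_best`` advanced)
    when ``rho_t >= rho_best``, else ``(k/2)(rho_t - rho_best)^2``.
    """
    if rho_t >= state.rho_best:
        state.rho_best = rho_t
        return 0.0, state
    return 0.5 * state.k * (rho_t - state.rho_best) ** 2, state


@dataclass
class ShellWithGaps3D(EnergyModel):
    """Spherical soft-wall cavity with angular gaps of different widths.

    The wall is a Gaussian ridge of height ``wall_height`` at radius
    ``radius`` (width ``sigma``), multiplied for each gap by
    ``1 - depth*exp(-(1 - cos psi)/w^2)`` where psi is the angle to the
    gap axis, w its angular half-width (radians) and ``depth`` in (0, 1]
    the gap's openness (1 = fully open; smaller leaves a residual wall,
    emulating a sterically hindered opening).  Near the axis the factor
    reduces to the Gaussian cap ``1 - depth*exp(-psi^2/2w^2)``, so the
    wall opens smoothly inside each gap.  Gaps are ``(axis, w)`` or
    ``(axis, w, depth)`` tuples.  The cavity interior and far field are
    flat.
    """

    radius: float = 3.0
    sigma: float = 0.3
    wall_height: float = 8.0
    gaps: tuple = ((np.array([0.0, 0.0, 1.0]), 0.55),)  # (axis, half-width[, depth])

    form_id: str = "shell_with_gaps_3d"
    dimensionality: int = 3

    def _wall_factors(self, xhat: np.ndarray):
        """Per-gap transmission factors and their d/dt coefficients."""
        facs, coefs, axes = [], [], []
        for gap in self.gaps:
            axis, w = gap[0], gap[1]
            depth = gap[2] if len(gap) > 2 else 1.0
            axis = np.asarray(axis, dtype=float)
            axis = axis / np.linalg.norm(axis)
            t = xhat @ axis
            g = depth * np.exp(-(1.0 - t) / (w * w))
            facs.append(1.0 - g)
            coefs.append(-g / (w * w))  # d(1-g)/dt
            axes.append(axis)
        return facs, coefs, axes

    def potential_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        r = np.linalg.norm(X, axis=1)
        safe_r = np.where(r > 1e-12, r, 1.0)
        xhat = X / safe_r[:, None]
        radial = self.wall_height * np.exp(
            -((r - self.radius) ** 2) / (2.0 * self.sigma**2)
        )
        facs, _, _ = self._wall_factors(xhat)
        angular = np.prod(np.stack(facs, axis=0), axis=0)
        return radial * angular

    def gradient_batch(self, X: np.ndarray) -> np.ndarray:
        X = np.atleast_2d(X)
        r = np.linalg.norm(X, axis=1)
        safe_r = np.where(r > 1e-12, r, 1.0)
        xhat = X / safe_r[:, None]
        radial = self.wall_height * np.exp(
            -((r - self.radius) ** 2) / (2.0 * self.sigma**2)
        )
        dradial = radial * (-(r - self.radius) / self.sigma**2)
        facs, coefs, axes = self._wall_factors(xhat)
        facs = np.stack(facs, axis=0)  # (n_gaps, n)
        angular = np.prod(facs, axis=0)
        grad = dradial[:, None] * angular[:, None] * xhat
        for g in range(len(axes)):
            others = angular / np.where(facs[g] != 0.0, facs[g], 1.0)
            others = np.where(facs[g] != 0.0, others, 0.0)
            # dt/dx = (axis - t*xhat)/r
            t = xhat @ axes[g]
            dt_dx = (axes[g][None, :] - t[:, None] * xhat) / safe_r[:, None]
            grad += (radial * others * coefs[g])[:, None] * dt_dx
        return grad

    def potential(self, x: np.ndarray) -> float:
        return float(self.potential_batch(np.atleast_2d(x))[0])

    def gradient(self, x: np.ndarray) -> np.ndarray:
        return self.gradient_batch(np.atleast_2d(x))[0]


@dataclass
class EscapeResult:
    seed: int
    k: float
    escape_time: float
    exit_label: int
    exit_direction: np.ndarray
    max_bias: float
    escaped: bool


def run_abmd_escape(
    model: EnergyModel,
    k: float,
    sim: SimulationParams,
    x0: np.ndarray | None = None,
    bound_pose: np.ndarray | None = None,
    escape_radius: float | None = None,
    exit_directions: np.ndarray | None = None,
) -> EscapeResult:
    """Ratchet-driven escape of a tracer from a cavity model.

    The reaction coordinate is rho = |x - bound_pose|.  The run ends when
    rho exceeds ``escape_radius`` (default: shell radius + 3 sigma for
    shell models) or the step budget runs out.  ``exit_directions``
    (rows of unit vectors, e.g. the tunnel exits found by the tunnels
    module on the matching sphere model) assign ``exit_label`` as the
    nearest direction to the escape point; -1 when none are given.
    """
    dof = model.dimensionality
    bound = (
        np.zeros(dof) if bound_pose is None else np.asarray(bound_pose, float).reshape(-1)
    )
    x = bound.copy() if x0 is None else np.asarray(x0, float).reshape(-1).copy()
    if escape_radius is None:
        if isinstance(model, ShellWithGaps3D):
            escape_radius = model.radius + 3.0 * model.sigma
        else:
            raise ValueError("escape_radius required for this model")
    rng = np.random.default_rng(sim.seed)
    v = np.zeros_like(x)
    c1, c2 = _baoab_coeffs(sim)
    half_dt = 0.5 * sim.dt
    state = RatchetState(rho_best=float(np.linalg.norm(x - bound)), k=k)
    max_bias = 0.0
    escaped = False
    escape_time = sim.n_steps * sim.dt

    def force(x):
        nonlocal max_bias
        rel = x - bound
        rho = float(np.linalg.norm(rel))
        e, _ = ratchet_bias(rho, state)
        max_bias = max(max_bias, e)
        f = -model.gradient(x)
        if e > 0.0 and rho > 1e-12:
            # dE/drho = k (rho - rho_best) < 0, force pushes rho back up
            f = f - state.k * (rho - state.rho_best) * (rel / rho)
        return f, rho

    f, rho = force(x)
    for step in range(1, sim.n_steps + 1):
        v += half_dt * f
        x += half_dt * v
        v = c1 * v + c2 * rng.standard_normal(dof)
        x += half_dt * v
        f, rho = force(x)
        v += half_dt * f
        if rho >= escape_radius:
            escaped = True
            escape_time = step * sim.dt
            break
    direction = (x - bound) / max(np.linalg.norm(x - bound), 1e-12)
    label = -1
    if exit_directions is not None and len(exit_directions) > 0:
        dirs = np.atleast_2d(np.asarray(exit_directions, dtype=float))
        dirs = dirs / np.linalg.norm(dirs, axis=1, keepdims=True)
        label = int(np.argmax(dirs @ direction))
    return EscapeResult(
        seed=sim.seed,
        k=k,
        escape_time=escape_time,
        exit_label=label,
        exit_direction=direction,
        max_bias=max_bias,
        escaped=escaped,
    )
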