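"""Well-tempered metadynamics with adaptive hill widths over 1-2 CVs.

A history-dependent bias V(s,t) = sum_k h_k exp(-|s - c_k|^2 / 2w_k^2) is
deposited during Langevin sampling.  In the well-tempered variant the hill
height decays with the bias already present,

    h_k = h0 * exp(-V(c_k, t_k) / (kB * dT)),    dT = (gamma - 1) T,

which makes the bias converge to -(dT/(T+dT)) F(s), so the free-energy
surface is recovered as F(s) = -((T+dT)/dT) V(s) = -(gamma/(gamma-1)) V(s)
up to a constant.  Hill widths follow the local CV fluctuation over a
trailing window (adaptive hills), floored to avoid needle-shaped kernels.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .systems import (
    EnergyModel,
    SimulationParams,
    SimulationDivergence,
    Trajectory,
    _DIVERGENCE_ENERGY,
    _baoab_coeffs,
)

__all__ = [
    "Hill",
    "BiasParams",
    "BiasPotential",
    "FreeEnergySurface",
    "evaluate_bias",
    "deposit_and_sample",
    "reconstruct_fes",
    "reweighted_fes",
    "project_fes",
]


@dataclass
class Hill:
    center: tuple
    widths: tuple
    height: float
    time: float


@dataclass
class BiasParams:
    """Metadynamics configuration.

    h0: initial hill height (energy); pace: steps between depositions;
    gamma: well-tempered bias factor (> 1; use ``np.inf`` for the standard
    non-tempered limit); adaptive_window: trailing steps used to estimate
    hill widths; width_floor: hard minimum width per CV; fixed_widths: skip
    the adaptive estimate entirely.
    """

    h0: float = 0.5
    pace: int = 500
    gamma: float = 10.0
    adaptive_window: int = 500
    width_floor: float | Sequence[float] = 0.02
    fixed_widths: Sequence[float] | None = None

    def __post_init__(self):
        if self.gamma <= 1.0:
            raise ValueError("well-tempered bias factor gamma must exceed 1")
        if self.pace < 1:
            raise ValueError("pace must be >= 1")


class BiasPotential:
    """Deposited-hill history with fast evaluation on points and grids."""

    def __init__(self, n_cv: int, params: BiasParams):
        self.n_cv = n_cv
        self.params = params
        self.centers = np.empty((0, n_cv))
        self.widths = np.empty((0, n_cv))
        self.heights = np.empty(0)
        self.times = np.empty(0)

    @property
    def hills(self) -> list[Hill]:
        return [
            Hill(tuple(c), tuple(w), float(h), float(t))
            for c, w, h, t in zip(self.centers, self.widths, self.heights, self.times)
        ]

    def add_hill(self, center, widths, height, time):
        widths = np.asarray(widths, dtype=float)
        if np.any(widths <= 0) or height < 0:
            raise ValueError("hill widths must be positive and height >= 0")
        self.centers = np.vstack([self.centers, np.asarray(center, float)])
        self.widths = np.vstack([self.widths, widths])
        self.heights = np.append(self.heights, height)
        self.times = np.append(self.times, time)

    def value(self, s, t_max: float | None = None) -> float:
        return float(self.value_many(np.atleast_2d(s), t_max)[0])

    def value_many(self, S: np.ndarray, t_max: float | None = None) -> np.ndarray:
        """Bias at each row of ``S`` using hills deposited up to ``t_max``."""
        S = np.atleast_2d(np.asarray(S, dtype=float))
        sel = slice(None) if t_max is None else self.times <= t_max
        c, w, h = self.centers[sel], self.widths[sel], self.heights[sel]
        if len(h) == 0:
            return np.zeros(S.shape[0])
        # (points, hills, cv)
        z = (S[:, None, :] - c[None, :, :]) / w[None, :, :]
        return np.exp(-0.5 * (z * z).sum(axis=2)) @ h

    def gradient(self, s: np.ndarray) -> np.ndarray:
        """dV/ds at a single CV point."""
        if len(self.heights) == 0:
            return np.zeros(self.n_cv)
        s = np.asarray(s, dtype=float).reshape(1, -1)
        z = (s - self.centers) / self.widths
        g = np.exp(-0.5 * (z * z).sum(axis=1)) * self.heights
        return -(g[:, None] * z / self.widths).sum(axis=0)


def evaluate_bias(bias: BiasPotential, s) -> float:
    """Total bias energy at CV point ``s``."""
    return bias.value(np.asarray(s, dtype=float).reshape(1, -1))


@dataclass
class FreeEnergySurface:
    """Free energy on a regular 1-D or 2-D CV grid (min normalised to 0).

    ``grid`` is a tuple of axis arrays; unsampled cells carry +inf and are
    excluded from normalisation.
    """

    grid: tuple
    F: np.ndarray
    kBT: float
    checkpoint_time: float = 0.0

    def __post_init__(self):
        self.F = np.asarray(self.F, dtype=float)
        finite = np.isfinite(self.F)
        if finite.any():
            self.F = self.F - self.F[finite].min()

    @property
    def ndim(self) -> int:
        return len(self.grid)


def deposit_and_sample(
    model: EnergyModel,
    cv: Callable[[np.ndarray], tuple],
    bias_params: BiasParams,
    sim: SimulationParams,
    x0: np.ndarray,
    stride: int = 10,
    stop_predicate: Callable[[np.ndarray], bool] | None = None,
    track_alpha: bool = False,
):
    """Run Langevin dynamics while depositing well-tempered adaptive hills.

    ``cv(x)`` returns ``(values, grads)`` with ``values`` a length-n_cv
    array and ``grads`` an ``(n_cv, dof)`` array.  Every ``pace`` steps a
    hill is placed at the current CV point with height
    ``h0*exp(-V_bias/(kB*dT))`` and widths from the sample standard
    deviation of each CV over the trailing ``adaptive_window`` steps.

    Returns ``(trajectory, bias)`` — or ``(trajectory, bias, alpha, n_run)``
    when ``track_alpha`` is set, where ``alpha`` is the running average of
    ``exp(V_bias(s_t)/kBT)`` needed for infrequent-metadynamics time
    rescaling (accumulated in log space) and ``n_run`` the steps executed.
    ``stop_predicate(x)`` halts the run early (first-passage mode).
    """
    rng = np.random.default_rng(sim.seed)
    x = np.array(x0, dtype=float).reshape(-1)
    v = np.zeros_like(x)
    c1, c2 = _baoab_coeffs(sim)
    half_dt = 0.5 * sim.dt
    vals, grads = cv(x)
    n_cv = len(vals)
    bias = BiasPotential(n_cv, bias_params)
    kb_dT = (bias_params.gamma - 1.0) * sim.kBT  # kB*dT; inf gamma -> no decay
    floor = np.broadcast_to(
        np.asarray(bias_params.width_floor, dtype=float), (n_cv,)
    )

    window = np.empty((bias_params.adaptive_window, n_cv))
    window[0] = vals
    n_win = 1

    n_out = sim.n_steps // stride + 1
    frames = np.empty((n_out, x.size))
    cv_series = np.empty((n_out, n_cv))
    bias_series = np.empty(n_out)
    times = np.empty(n_out)
    frames[0], cv_series[0], bias_series[0], times[0] = x, vals, 0.0, 0.0
    k_out = 1

    log_alpha_sum = 0.0  # log sum exp(V/kBT); starts with step-0 term V=0
    n_alpha = 1
    n_run = sim.n_steps

    f = -model.gradient(x) - bias.gradient(np.asarray(vals)) @ grads
    for step in range(1, sim.n_steps + 1):
        v += half_dt * f
        x += half_dt * v
        v = c1 * v + c2 * rng.standard_normal(x.size)
        x += half_dt * v
        vals, grads = cv(x)
        vals = np.asarray(vals, dtype=float)

        window[n_win % bias_params.adaptive_window] = vals
        n_win += 1

        if track_alpha:
            vb = bias.value(vals)
            log_alpha_sum = np.logaddexp(log_alpha_sum, vb / sim.kBT)
            n_alpha += 1

        if step % bias_params.pace == 0:
            if not track_alpha:
                vb = bias.value(vals)
            if bias_params.fixed_widths is not None:
                widths = np.asarray(bias_params.fixed_widths, dtype=float)
            else:
                m = min(n_win, bias_params.adaptive_window)
                widths = window[:m].std(axis=0)
            widths = np.maximum(widths, floor)
            height = (
                bias_params.h0
                if not np.isfinite(kb_dT)
                else bias_params.h0 * np.exp(-vb / kb_dT)
            )
            bias.add_hill(vals, widths, height, step * sim.dt)

        f = -model.gradient(x) - bias.gradient(vals) @ grads
        v += half_dt * f
        if step % stride == 0 and k_out < n_out:
            e = model.potential(x)
            if not np.isfinite(e) or e > _DIVERGENCE_ENERGY:
                raise SimulationDivergence(f"energy {e!r} at step {step}")
            frames[k_out], cv_series[k_out], times[k_out] = x, vals, step * sim.dt
            bias_series[k_out] = vb if track_alpha else bias.value(vals)
            k_out += 1
        if stop_predicate is not None and stop_predicate(x):
            n_run = step
            break

    traj = Trajectory(
        times=times[:k_out],
        frames=frames[:k_out],
        cv_series=cv_series[:k_out],
        bias_series=bias_series[:k_out],
    )
    if track_alpha:
        alpha = float(np.exp(log_alpha_sum - np.log(n_alpha)))
        return traj, bias, alpha, n_run
    return traj, bias


def reconstruct_fes(
    bias: BiasPotential,
    grid,
    checkpoints: Sequence[float] | None = None,
    kBT: float = 1.0,
) -> list[FreeEnergySurface]:
    """Free-energy surfaces from the deposited bias at each checkpoint time.

    Well-tempered estimator: F(s) = -(gamma/(gamma-1)) V_bias(s, t<=cp),
    normalised to min 0.  ``grid`` is an axis array (1-D) or a tuple of two
    axis arrays (2-D).
    """
    gamma = bias.params.gamma
    if not np.isfinite(gamma):
        raise ValueError("free-energy reconstruction requires finite gamma > 1")
    scale = gamma / (gamma - 1.0)
    if isinstance(grid, tuple):
        axes = tuple(np.asarray(g, dtype=float) for g in grid)
    else:
        axes = (np.asarray(grid, dtype=float),)
    if len(axes) == 1:
        pts = axes[0].reshape(-1, 1)
        shape = (len(axes[0]),)
    else:
        XX, YY = np.meshgrid(axes[0], axes[1], indexing="ij")
        pts = np.stack([XX.ravel(), YY.ravel()], axis=1)
        shape = XX.shape
    if checkpoints is None:
        checkpoints = [bias.times[-1] if len(bias.times) else 0.0]
    out = []
    for cp in checkpoints:
        F = (-scale * bias.value_many(pts, t_max=cp)).reshape(shape)
        out.append(FreeEnergySurface(grid=axes, F=F, kBT=kBT, checkpoint_time=cp))
    return out


def reweighted_fes(
    traj: Trajectory,
    bias: BiasPotential,
    grid: np.ndarray,
    kBT: float = 1.0,
    t_window: tuple | None = None,
) -> FreeEnergySurface:
    """Bias-reweighted histogram estimate of a 1-D free-energy profile.

    The biased density at time t obeys
    rho(s, t) ~ exp(-(F(s) + V(s, t) - c(t))/kBT); each sample is weighted
    by exp((V(s_t, t) - c(t))/kBT) with the instantaneous bias recorded
    along the trajectory and the well-tempered offset

        c(t) = kBT ln( sum_s e^{(g/(g-1)) V(s,t)/kBT}
                       / sum_s e^{(1/(g-1)) V(s,t)/kBT} ),

    which keeps the weights O(1) as the bias grows so no single time slice
    dominates.  This estimator self-corrects the frozen deposition ripple
    of the pure bias inversion: where the bias overshot, the occupancy is
    depressed by the exact compensating factor.  ``t_window`` restricts
    the samples (default: the second half of the trajectory).  Unvisited
    bins carry +inf.
    """
    if traj.cv_series is None or traj.bias_series is None:
        raise ValueError("trajectory carries no CV/bias series")
    gamma = bias.params.gamma
    if not np.isfinite(gamma):
        raise ValueError("reweighting requires the well-tempered gamma")
    s = traj.cv_series[:, 0]
    t = traj.times
    if t_window is None:
        t_window = (t[-1] / 2.0, t[-1])
    sel = (t > t_window[0]) & (t <= t_window[1])
    grid = np.asarray(grid, dtype=float)
    # c(t) on a coarse time mesh, interpolated to the sample times
    from scipy.special import logsumexp

    t_mesh = np.linspace(t_window[0], t_window[1], 33)
    pts = grid.reshape(-1, 1)
    c_mesh = np.empty_like(t_mesh)
    for i, tm in enumerate(t_mesh):
        v = bias.value_many(pts, t_max=tm) / kBT
        c_mesh[i] = kBT * (
            logsumexp(gamma / (gamma - 1.0) * v) - logsumexp(v / (gamma - 1.0))
        )
    c_t = np.interp(t[sel], t_mesh, c_mesh)
    edges = np.concatenate(
        [
            [grid[0] - 0.5 * (grid[1] - grid[0])],
            0.5 * (grid[1:] + grid[:-1]),
            [grid[-1] + 0.5 * (grid[-1] - grid[-2])],
        ]
    )
    logw = (traj.bias_series[sel] - c_t) / kBT
    logw -= logw.max()  # overflow guard; constants cancel
    weight, _ = np.histogram(s[sel], bins=edges, weights=np.exp(logw))
    counts, _ = np.histogram(s[sel], bins=edges)
    with np.errstate(divide="ignore"):
        F = -kBT * np.log(weight / np.diff(edges))
    F[counts == 0] = np.inf
    return FreeEnergySurface(grid=(grid,), F=F, kBT=kBT, checkpoint_time=t_window[1])


def project_fes(F2d: FreeEnergySurface) -> FreeEnergySurface:
    """Boltzmann projection of a 2-D F(S, Z) onto the first axis:
    F(S) = -kBT ln sum_Z exp(-F(S,Z)/kBT), renormalised to min 0."""
    if F2d.ndim != 2:
        raise ValueError("projection expects a 2-D surface")
    with np.errstate(over="ignore"):
        w = np.exp(-np.where(np.isfinite(F2d.F), F2d.F, np.inf) / F2d.kBT)
    mass = w.sum(axis=1)
    with np.errstate(divide="ignore"):
        F1 = -F2d.kBT * np.log(mass)
    return FreeEnergySurface(
        grid=(F2d.grid[0],), F=F1, kBT=F2d.kBT, checkpoint_time=F2d.checkpoint_time
    )
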