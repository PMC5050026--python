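"""Synthetic systems: gradients, Langevin sampling, quadrature and rate oracles."""

import numpy as np
import pytest

from confex.systems import (
    DoubleWell1D,
    EnergyModel,
    SimulationParams,
    ThreeHole2D,
    TwoStateBeads,
    brute_force_rates,
    make_two_state_beads,
    quadrature_free_energy,
    run_langevin,
    run_langevin_batch,
)
from confex.thermo import DeltaG, population_from_delta_g
from confex.units import RT_KCAL


class Harmonic1D(EnergyModel):
    """V = k/2 x^2; closed-form reference for equipartition checks."""

    dimensionality = 1

    def __init__(self, k=4.0):
        self.k = k

    def potential(self, x):
        return 0.5 * self.k * float(x[0] ** 2)

    def gradient(self, x):
        return self.k * np.asarray(x)

    def potential_batch(self, X):
        return 0.5 * self.k * np.atleast_2d(X)[:, 0] ** 2

    def gradient_batch(self, X):
        return self.k * np.atleast_2d(X)


@pytest.mark.parametrize(
    "model,domain",
    [
        (DoubleWell1D(barrier=7.0, delta_G_true=1.5), [(-1.8, 1.8)]),
        (ThreeHole2D(), [(-1.8, 1.8), (-0.8, 2.2)]),
    ],
)
def test_gradient_matches_finite_differences(model, domain, rng):
    h = 1e-6
    for _ in range(100):
        x = np.array([rng.uniform(lo, hi) for lo, hi in domain])
        g = model.gradient(x)
        for d in range(len(x)):
            e = np.zeros_like(x)
            e[d] = h
            fd = (model.potential(x + e) - model.potential(x - e)) / (2 * h)
            assert np.isclose(g[d], fd, rtol=1e-5, atol=1e-7)


def test_beads_gradient_and_endpoints(beads, rng):
    model, A, B = beads
    # gradient vs central differences at random configurations
    h = 1e-6
    for _ in range(20):
        x = A.reshape(-1) + 0.3 * rng.standard_normal(A.size)
        g = model.gradient(x)
        for d in rng.choice(A.size, size=4, replace=False):
            e = np.zeros(A.size)
            e[d] = h
            fd = (model.potential(x + e) - model.potential(x - e)) / (2 * h)
            assert np.isclose(g[d], fd, rtol=1e-5, atol=1e-7)
    # reference conformations are distinct minima with the exact energy gap
    assert np.linalg.norm(A - B) > 0
    dE = model.potential(B.reshape(-1)) - model.potential(A.reshape(-1))
    assert np.isclose(dE, model.delta_G_true, atol=1e-12)
    # barrier at the midpoint
    mid = model.line_configuration(0.5)
    assert model.potential(mid) >= max(
        model.potential(A.reshape(-1)), model.potential(B.reshape(-1))
    )


def test_beads_minor_population_three_percent():
    """A 2.1 kcal/mol gap at 298.15 K puts the minor state near 3%."""
    model, _, _ = make_two_state_beads(
        n_beads=4, displacement=1.5, delta_G_true=2.1, barrier=8.0, seed=0
    )
    p = population_from_delta_g(DeltaG(value=model.delta_G_true))
    assert round(100 * p) == 3


def test_beads_degenerate_inputs():
    with pytest.raises(ValueError):
        make_two_state_beads(n_beads=2, displacement=1.0, delta_G_true=1.0, barrier=5.0, seed=0)
    with pytest.raises(ValueError):
        make_two_state_beads(n_beads=4, displacement=0.0, delta_G_true=1.0, barrier=5.0, seed=0)


def test_simulation_params_validation():
    with pytest.raises(ValueError):
        SimulationParams(n_steps=10, dt=-0.1)
    with pytest.raises(ValueError):
        SimulationParams(n_steps=10, kBT=0.0)
    with pytest.raises(ValueError):
        SimulationParams(n_steps=10, dt=0.5, friction=3.0)


def test_langevin_equipartition():
    """Long-run positional variance in a harmonic well approaches kBT/k."""
    model = Harmonic1D(k=4.0)
    p = SimulationParams(n_steps=1_000_000, dt=0.005, kBT=1.0, friction=1.0, seed=7)
    traj = run_langevin(model, p, np.array([0.0]), stride=5)
    assert np.isclose(traj.frames.var(), 1.0 / 4.0, rtol=0.05)


def test_langevin_deterministic_and_cold_relaxation(double_well):
    p = SimulationParams(n_steps=5_000, dt=0.005, seed=11)
    t1 = run_langevin(double_well, p, np.array([0.5]))
    t2 = run_langevin(double_well, p, np.array([0.5]))
    assert np.array_equal(t1.frames, t2.frames)
    cold = SimulationParams(n_steps=20_000, dt=0.005, kBT=1e-6, seed=3)
    tc = run_langevin(double_well, cold, np.array([0.6]))
    assert np.isclose(tc.frames[-1, 0], 1.0, atol=1e-3)  # E-basin local minimum


def test_occupancy_ratio_matches_quadrature():
    """Unbiased basin occupancies reproduce the quadrature free-energy gap."""
    model = DoubleWell1D(barrier=2.5, delta_G_true=1.0)
    grid = np.linspace(-1.6, 1.6, 161)
    F = quadrature_free_energy(
        model, lambda X: np.atleast_2d(X)[:, 0], grid, 1.0, domain=[(-2.2, 2.2)]
    )
    w = np.exp(-F.F[np.isfinite(F.F)] / 1.0)
    g = grid[np.isfinite(F.F)]
    dg_quad = -np.log(w[g > 0].sum() / w[g < 0].sum())
    p = SimulationParams(n_steps=2_000_000, dt=0.005, seed=5)
    traj = run_langevin(model, p, np.array([-1.0]), stride=10)
    x = traj.frames[:, 0]
    dg_run = -np.log(np.mean(x > 0) / np.mean(x < 0))
    assert abs(dg_run - dg_quad) < 0.1
    assert abs(dg_quad - 1.0) < 0.15  # the low barrier shifts it slightly off delta


def test_quadrature_symmetric_and_high_barrier_limit():
    sym = DoubleWell1D(barrier=10.0, delta_G_true=0.0)
    grid = np.linspace(-1.5, 1.5, 301)
    F = quadrature_free_energy(
        sym, lambda X: np.atleast_2d(X)[:, 0], grid, 1.0, domain=[(-2.2, 2.2)]
    )
    w = np.exp(-F.F[np.isfinite(F.F)])
    g = grid[np.isfinite(F.F)]
    assert abs(np.log(w[g > 0].sum() / w[g < 0].sum())) < 1e-10
    for barrier in (10.0, 14.0):
        model = DoubleWell1D(barrier=barrier, delta_G_true=1.0)
        Fq = quadrature_free_energy(
            model, lambda X: np.atleast_2d(X)[:, 0], grid, 1.0,
            domain=[(-2.2, 2.2)], n_points=20001,
        )
        w = np.exp(-Fq.F[np.isfinite(Fq.F)])
        g = grid[np.isfinite(Fq.F)]
        dg = -np.log(w[g > 0].sum() / w[g < 0].sum())
        assert np.isclose(dg, 1.0, rtol=0.02)


def test_quadrature_harmonic_curvature():
    model = Harmonic1D(k=4.0)
    grid = np.linspace(-0.8, 0.8, 161)
    F = quadrature_free_energy(
        model, lambda X: np.atleast_2d(X)[:, 0], grid, 1.0, domain=[(-2.0, 2.0)],
        n_points=40001,
    )
    coeff = np.polyfit(grid, F.F, 2)
    assert np.isclose(2 * coeff[0], 4.0, rtol=0.01)


def test_brute_force_rates_symmetric_and_kramers():
    model = DoubleWell1D(barrier=6.0, delta_G_true=0.0)
    margin = 0.1
    in_G = lambda X: np.atleast_2d(X)[:, 0] < -2 * margin
    in_E = lambda X: np.atleast_2d(X)[:, 0] > 2 * margin
    p = SimulationParams(n_steps=10_000_000, dt=0.005, friction=5.0, seed=2)
    fwd, bwd = brute_force_rates(model, p, (in_G, in_E), n_events=20)
    # symmetry: equal lifetimes within 2 combined standard errors
    se = np.hypot(fwd["se"], bwd["se"])
    assert abs(fwd["mean_tau"] - bwd["mean_tau"]) < 2 * se
    # high-friction Kramers estimate from the model curvatures
    w_min = np.sqrt(8.0 * model.barrier)
    w_bar = np.sqrt(4.0 * model.barrier)
    tau_kramers = 2 * np.pi * 5.0 / (w_min * w_bar) * np.exp(6.0)
    mean = 0.5 * (fwd["mean_tau"] + bwd["mean_tau"])
    assert tau_kramers / 2 < mean < tau_kramers * 2


def test_brute_force_detailed_balance():
    """Forward/backward lifetime ratio reproduces the Boltzmann gap."""
    model = DoubleWell1D(barrier=4.0, delta_G_true=1.0)
    grid = np.linspace(-1.6, 1.6, 161)
    F = quadrature_free_energy(
        model, lambda X: np.atleast_2d(X)[:, 0], grid, 1.0, domain=[(-2.2, 2.2)]
    )
    w = np.exp(-F.F[np.isfinite(F.F)])
    g = grid[np.isfinite(F.F)]
    dg_quad = -np.log(w[g > 0].sum() / w[g < 0].sum())
    in_G = lambda X: np.atleast_2d(X)[:, 0] < -0.2
    in_E = lambda X: np.atleast_2d(X)[:, 0] > 0.2
    p = SimulationParams(n_steps=5_000_000, dt=0.005, seed=8)
    fwd, bwd = brute_force_rates(model, p, (in_G, in_E), n_events=100)
    ratio = fwd["mean_tau"] / bwd["mean_tau"]
    assert np.isclose(ratio, np.exp(dg_quad), rtol=0.2)


def test_brute_force_timeout():
    model = DoubleWell1D(barrier=12.0, delta_G_true=0.0)
    in_G = lambda X: np.atleast_2d(X)[:, 0] < -0.2
    in_E = lambda X: np.atleast_2d(X)[:, 0] > 0.2
    p = SimulationParams(n_steps=2_000, dt=0.005, seed=0)
    with pytest.raises(TimeoutError):
        brute_force_rates(model, p, (in_G, in_E), n_events=5, max_steps=2_000)


def test_trajectory_validation():
    from confex.systems import Trajectory

    with pytest.raises(ValueError):
        Trajectory(times=[0.0, 1.0], frames=np.array([[0.0], [np.nan]]))
    with pytest.raises(ValueError):
        Trajectory(times=[0.0, 1.0, 3.0], frames=np.zeros((3, 1)))
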