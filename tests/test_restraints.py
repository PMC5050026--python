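"""Replica-averaged restraints: energies, forces, maximum-entropy behaviour."""

import numpy as np
import pytest
from scipy import stats

from confex.pathcv import build_reference_path
from confex.restraints import (
    ObservableModel,
    ReplicaSet,
    make_linear_observable_model,
    observable_rmsd,
    project_ensemble,
    restraint_energy,
    run_restrained_sampling,
    synthetic_targets,
)
from confex.systems import DoubleWell1D, SimulationParams, run_langevin


def test_restraint_energy_closed_forms():
    obs = ObservableModel(
        M=np.array([[1.0]]), b=np.zeros(1), scales=np.ones(1), groups=np.array(["Ha"])
    )
    # replica mean equals the target: zero energy
    rep = ReplicaSet(states=np.array([[2.0], [4.0]]), epsilon=5.0, targets=np.array([3.0]))
    e, f = restraint_energy(rep, obs)
    assert np.isclose(e, 0.0) and np.allclose(f, 0.0)
    # N=1, delta=3, target=1, eps=2 -> E = 2*(3-1)^2 = 8
    rep = ReplicaSet(states=np.array([[3.0]]), epsilon=2.0, targets=np.array([1.0]))
    e, _ = restraint_energy(rep, obs)
    assert np.isclose(e, 8.0)


def test_restraint_forces_match_finite_differences(rng):
    obs = make_linear_observable_model(dof=6, n_obs=5, seed=3)
    X = rng.standard_normal((4, 6))
    targets = rng.standard_normal(5)
    rep = ReplicaSet(states=X.copy(), epsilon=7.0, targets=targets)
    e0, forces = restraint_energy(rep, obs)
    h = 1e-6
    for r in range(4):
        for d in range(6):
            Xp, Xm = X.copy(), X.copy()
            Xp[r, d] += h
            Xm[r, d] -= h
            ep, _ = restraint_energy(ReplicaSet(states=Xp, epsilon=7.0, targets=targets), obs)
            em, _ = restraint_energy(ReplicaSet(states=Xm, epsilon=7.0, targets=targets), obs)
            assert np.isclose(-forces[r, d], (ep - em) / (2 * h), rtol=1e-5, atol=1e-7)


def test_restraint_permutation_invariance_and_replica_scaling(rng):
    obs = make_linear_observable_model(dof=4, n_obs=6, seed=5)
    X = rng.standard_normal((5, 4))
    targets = rng.standard_normal(6)
    e1, _ = restraint_energy(ReplicaSet(states=X, epsilon=3.0, targets=targets), obs)
    e2, _ = restraint_energy(
        ReplicaSet(states=X[::-1].copy(), epsilon=3.0, targets=targets), obs
    )
    assert np.isclose(e1, e2)
    # per-replica force scales as 1/N at a fixed replica-mean residual:
    # the restraint perturbs each copy less as the ensemble grows
    norms = []
    for N in (1, 2, 4, 8):
        Xn = np.tile(X[:1], (N, 1))
        _, f = restraint_energy(ReplicaSet(states=Xn, epsilon=3.0, targets=targets), obs)
        norms.append(np.linalg.norm(f[0]))
    assert np.allclose(norms, norms[0] / np.array([1, 2, 4, 8]), rtol=1e-9)


def test_restraint_dimension_mismatch():
    obs = make_linear_observable_model(dof=3, n_obs=4, seed=0)
    rep = ReplicaSet(states=np.zeros((2, 3)), epsilon=1.0, targets=np.zeros(5))
    with pytest.raises(ValueError):
        restraint_energy(rep, obs)


def test_observable_rmsd_identities(rng):
    obs = make_linear_observable_model(dof=2, n_obs=10, seed=9)
    frames = rng.standard_normal((50, 2))
    mean_obs = obs.observe_batch(frames).mean(axis=0)
    # ensemble average equal to targets: all zero
    out = observable_rmsd(frames, obs, mean_obs)
    assert all(np.isclose(v, 0.0) for v in out.values())
    # single frame, hand numbers
    single = ObservableModel(
        M=np.eye(2), b=np.zeros(2), scales=np.ones(2), groups=np.array(["Ha", "HN"])
    )
    out = observable_rmsd(np.array([[3.0, 1.0]]), single, np.array([1.0, 1.0]))
    assert np.isclose(out["all"], np.sqrt(2.0))
    assert np.isclose(out["Ha"], 2.0) and np.isclose(out["HN"], 0.0)
    # pooled^2 equals the count-weighted mean of the group RMSD^2
    targets = mean_obs + rng.standard_normal(10)
    out = observable_rmsd(frames, obs, targets)
    groups = np.unique(obs.groups)
    weighted = sum(
        np.sum(obs.groups == g) * out[str(g)] ** 2 for g in groups
    ) / obs.n_obs
    assert np.isclose(out["all"] ** 2, weighted, rtol=1e-12)


def test_project_ensemble_nodes_and_empty():
    path = build_reference_path(np.array([-2.0]), np.array([2.0]), n_nodes=11)
    S, hist, edges, mass = project_ensemble(path.nodes.reshape(11, 1), path)
    # node frames land at their own S values (soft-min rounds the endpoints)
    assert np.allclose(sorted(S), np.linspace(0, 1, 11), atol=0.05)
    assert np.all(np.diff(sorted(S)) > 0)
    with pytest.raises(ValueError):
        project_ensemble(np.empty((0, 1)), path)


def test_epsilon_zero_matches_unrestrained_sampling():
    """With no restraint the replica ensemble is plain Langevin sampling."""
    model = DoubleWell1D(barrier=3.0, delta_G_true=1.5)
    obs = make_linear_observable_model(dof=1, n_obs=5, seed=1)
    targets = np.zeros(5)
    sim = SimulationParams(n_steps=150_000, dt=0.005, seed=21)
    ens = run_restrained_sampling(
        model, obs, targets, sim, np.array([1.0]), n_replicas=4, epsilon=0.0,
        stride=20, equilibration=15_000,
    )
    ref_sim = SimulationParams(n_steps=600_000, dt=0.005, seed=500)
    ref = run_langevin(model, ref_sim, np.array([1.0]), stride=20)
    # thin to roughly independent samples (the basin-hopping time is the
    # slowest correlation) so the two-sample KS assumptions hold
    a = ens.frames[::50, 0]
    b = ref.frames[15_000 // 20 :: 50, 0]
    ks = stats.ks_2samp(a, b)
    assert ks.pvalue > 0.01


def test_large_epsilon_pins_observables_to_targets():
    model = DoubleWell1D(barrier=3.0, delta_G_true=1.5)
    obs = make_linear_observable_model(dof=1, n_obs=5, seed=2)
    rng = np.random.default_rng(3)
    ref = model.minima[1] + 0.2 * rng.standard_normal((200, 1))
    targets = synthetic_targets(ref, obs, seed=4, noise_fraction=0.05)
    sim = SimulationParams(n_steps=30_000, dt=0.005, seed=5)
    ens = run_restrained_sampling(
        model, obs, targets, sim, np.array([model.minima[1]]),
        n_replicas=4, epsilon=400.0, stride=10, equilibration=3_000,
    )
    mean_obs = obs.observe_batch(ens.frames).mean(axis=0)
    assert np.all(np.abs(mean_obs - targets) < obs.scales)


def test_minimal_perturbation_shifts_mean_not_variance():
    """Targets from a shifted basin move the ensemble mean toward them while
    per-replica fluctuations stay comparable to unrestrained sampling."""
    model = DoubleWell1D(barrier=3.0, delta_G_true=1.5)
    obs = make_linear_observable_model(dof=1, n_obs=5, seed=6)
    rng = np.random.default_rng(7)
    # reference basin shifted 0.3 beyond the E minimum
    ref = (model.minima[1] + 0.3) + 0.15 * rng.standard_normal((200, 1))
    targets = synthetic_targets(ref, obs, seed=8, noise_fraction=0.05)
    sim = SimulationParams(n_steps=40_000, dt=0.005, seed=9)
    kw = dict(stride=10, equilibration=4_000, n_replicas=4)
    restrained = run_restrained_sampling(
        model, obs, targets, sim, np.array([model.minima[1]]), epsilon=24.0, **kw
    )
    free = run_restrained_sampling(
        model, obs, targets, sim, np.array([model.minima[1]]), epsilon=0.0, **kw
    )
    # E-basin frames only (the unrestrained run also leaks to G)
    rx = restrained.frames[restrained.frames[:, 0] > 0.3, 0]
    fx = free.frames[free.frames[:, 0] > 0.3, 0]
    assert rx.mean() > fx.mean()  # mean moves toward the shifted target basin
    assert rx.var() < 2.0 * fx.var()  # fluctuations not crushed
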