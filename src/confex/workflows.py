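"""End-to-end study workflows on the standard synthetic two-state system.

These functions wire the modules together the way the full-scale analysis
chains them on a protein: build the reference path, run path-CV
well-tempered metadynamics, extract dG from the converged profile, collect
infrequent-metadynamics first-passage samples, cross-validate the two dG
routes, run the restrained-ensemble and escape/tunnel stages.  They are
the single source of the toy study conditions used by the CLI, the test
suite and the acceptance script.

Standard toy conditions
-----------------------
1-D double well with minima at x = +-1, barrier 7 kBT and asymmetry
(delta_G_true) 1.5 kBT — a two-state system whose minor basin holds ~18%
of the population, exchanged over a barrier high enough that unbiased
crossings are rare on the sampling timescale.  The reference path spans
x in [-2, 2] with 31 nodes, which puts the G basin near S = 0.25, the E
basin near S = 0.75 and the separatrix near S = 0.5.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import kinetics as kin
from .abmd import EscapeResult, ShellWithGaps3D, run_abmd_escape
from .metad import BiasParams, deposit_and_sample, reconstruct_fes
from .pathcv import (
    ReferencePath,
    build_reference_path,
    path_cv_values_batch,
    path_cv_with_grad,
)
from .systems import (
    DoubleWell1D,
    SimulationParams,
    brute_force_rates,
    quadrature_free_energy,
)
from .thermo import (
    StatePartition,
    delta_g_from_fes,
    delta_g_timeseries,
    find_separatrix,
)
from .tunnels import detect_tunnels, make_shell_sphere_model

__all__ = [
    "TwoStateStudy",
    "make_two_state_study",
    "pathmetad_study",
    "inmetad_study",
    "brute_force_study",
    "aggressive_ks_study",
    "restrained_study",
    "two_gap_shell_study",
    "abmd_escape_ensemble",
]

S_GRID = np.linspace(0.01, 0.99, 197)


@dataclass
class TwoStateStudy:
    """The standard 1-D two-state system with its path CV and ground truth."""

    model: DoubleWell1D
    path: ReferencePath
    partition: StatePartition
    dg_true_kbt: float  # quadrature ground truth, units kBT
    kBT: float = 1.0

    def cv(self, x):
        S, _, dS, _ = path_cv_with_grad(x, self.path)
        return np.array([S]), dS.reshape(1, -1)

    def s_of_x(self, X):
        return path_cv_values_batch(np.atleast_2d(X), self.path)[0]

    def committed_E(self, x, margin: float = 0.1):
        return self.s_of_x(np.atleast_2d(x)) > self.partition.separatrix + margin

    def committed_G(self, x, margin: float = 0.1):
        return self.s_of_x(np.atleast_2d(x)) < self.partition.separatrix - margin

    def quadrature_fes(self, grid=None):
        return quadrature_free_energy(
            self.model,
            self.s_of_x,
            grid if grid is not None else S_GRID,
            kBT=self.kBT,
            domain=[(-2.5, 2.5)],
            n_points=8001,
        )


def make_two_state_study(
    barrier: float = 7.0,
    delta: float = 1.5,
    n_nodes: int = 31,
    kBT: float = 1.0,
) -> TwoStateStudy:
    """Build the standard study: model, 31-node path, separatrix, exact dG."""
    model = DoubleWell1D(barrier=barrier, delta_G_true=delta)
    path = build_reference_path(np.array([-2.0]), np.array([2.0]), n_nodes=n_nodes)
    # ground-truth profile and separatrix from direct quadrature
    tmp = TwoStateStudy(
        model=model,
        path=path,
        partition=StatePartition(separatrix=0.5),
        dg_true_kbt=np.nan,
        kBT=kBT,
    )
    F_true = tmp.quadrature_fes()
    part = find_separatrix(F_true)
    dg_true = delta_g_from_fes(F_true, part, kBT=kBT).value
    return TwoStateStudy(
        model=model, path=path, partition=part, dg_true_kbt=dg_true, kBT=kBT
    )


def _pathmetad_single(
    study: TwoStateStudy,
    n_steps: int,
    seed: int,
    bp: BiasParams,
    n_checkpoints: int,
    dt: float,
    friction: float,
):
    """One metadynamics walker; returns its tail-averaged dG(t) series.

    At each checkpoint t the instantaneous well-tempered dG estimates from
    the window (t/2, t] are averaged, which suppresses the hill-height
    noise of any single bias snapshot (the converged bias fluctuates
    around the tempered free energy).
    """
    sim = SimulationParams(
        n_steps=n_steps, dt=dt, kBT=study.kBT, friction=friction, seed=seed
    )
    x0 = np.array([study.model.minima[0]])
    traj, bias = deposit_and_sample(study.model, study.cv, bp, sim, x0, stride=20)
    checkpoints = np.linspace(
        bias.times[-1] / n_checkpoints, bias.times[-1], n_checkpoints
    )
    fes_list = reconstruct_fes(bias, S_GRID, checkpoints=checkpoints, kBT=study.kBT)
    # mask CV bins the trajectory never visited
    visited, _ = np.histogram(
        traj.cv_series[:, 0],
        bins=np.concatenate([[S_GRID[0] - 0.0025], S_GRID + 0.0025]),
    )
    for F in fes_list:
        F.F = np.where(visited > 0, F.F, np.inf)
        F.__post_init__()
    times, raw_series, _ = delta_g_timeseries(
        fes_list, study.partition, kBT=study.kBT, tol=0.1
    )
    series = np.array(
        [raw_series[(i + 1) // 2 : i + 1].mean() for i in range(len(raw_series))]
    )
    return {
        "trajectory": traj,
        "bias": bias,
        "fes_checkpoints": fes_list,
        "dg_times": times,
        "dg_series_raw": raw_series,
        "dg_series": series,
    }


def pathmetad_study(
    study: TwoStateStudy,
    n_steps: int = 500_000,
    n_walkers: int = 4,
    seed: int = 0,
    bias_params: BiasParams | None = None,
    n_checkpoints: int = 40,
    dt: float = 0.005,
    friction: float = 1.0,
):
    """Well-tempered path-CV metadynamics on the standard system.

    Runs ``n_walkers`` independent walkers of ``n_steps`` each and averages
    their tail-averaged dG(t) series (the multiple-walker route to a
    converged free-energy difference).  ``converged`` reports whether the
    combined series drifts by less than 0.1 kBT over its last quarter.
    Returns a dict with per-walker results, the combined dG series, the
    final estimate and the quadrature ground truth (all in kBT).
    """
    bp = bias_params or BiasParams(h0=0.5, pace=500, gamma=10.0, width_floor=0.02)
    walkers = [
        _pathmetad_single(
            study, n_steps, seed + 17 * w, bp, n_checkpoints, dt, friction
        )
        for w in range(n_walkers)
    ]
    series = np.mean([w["dg_series"] for w in walkers], axis=0)
    times = walkers[0]["dg_times"]
    q = max(1, len(series) // 4)
    drift = float(series[-q:].max() - series[-q:].min())
    return {
        "walkers": walkers,
        "bias": walkers[0]["bias"],
        "fes_checkpoints": walkers[0]["fes_checkpoints"],
        "dg_times": times,
        "dg_series": series,
        "converged": bool(drift < 0.1),
        "dg_estimate_kbt": float(series[-1]),
        "dg_true_kbt": study.dg_true_kbt,
        "last_quarter_drift_kbt": drift,
    }


def inmetad_study(
    study: TwoStateStudy,
    n_events: int = 20,
    seed: int = 0,
    pace: int = 5000,
    h0: float = 0.25,
    max_steps: int = 2_000_000,
    dt: float = 0.005,
    friction: float = 1.0,
    enforce_protocol: bool = True,
):
    """Infrequent-metadynamics first-passage sampling in both directions.

    Collects ``n_events`` rescaled first-passage times G->E (launched from
    the G minimum) and E->G, estimates the mean lifetimes with bootstrap
    CIs and the KS/Poisson diagnostic, and returns dG from the rate ratio
    in kBT for direct comparison with the free-energy route.
    """
    bp = BiasParams(
        h0=h0, pace=pace, gamma=10.0, adaptive_window=500, width_floor=0.02
    )
    results = {}
    for direction, x_start, committed in [
        ("G->E", study.model.minima[0], study.committed_E),
        ("E->G", study.model.minima[1], study.committed_G),
    ]:
        samples = []
        for i in range(n_events):
            sim = SimulationParams(
                n_steps=max_steps,
                dt=dt,
                kBT=study.kBT,
                friction=friction,
                seed=seed + 1000 * (direction == "E->G") + i,
            )
            samples.append(
                kin.sample_first_passage(
                    study.model,
                    study.cv,
                    bp,
                    lambda x: committed(x)[0],
                    sim,
                    np.array([x_start]),
                    enforce_protocol=enforce_protocol,
                    direction=direction,
                )
            )
        results[direction] = {
            "samples": samples,
            "estimate": kin.estimate_rates(samples, boot_seed=seed),
        }
    tau_fwd = results["G->E"]["estimate"].mean_tau
    tau_bwd = results["E->G"]["estimate"].mean_tau
    results["dg_rates_kbt"] = float(study.kBT * np.log(tau_fwd / tau_bwd))
    return results


def brute_force_study(
    study: TwoStateStudy,
    n_events: int = 20,
    seed: int = 0,
    dt: float = 0.005,
    friction: float = 1.0,
    max_steps: int = 5_000_000,
):
    """Unbiased mean lifetimes for the standard system (oracle route)."""
    sim = SimulationParams(
        n_steps=max_steps, dt=dt, kBT=study.kBT, friction=friction, seed=seed
    )
    fwd, bwd = brute_force_rates(
        study.model,
        sim,
        (lambda X: study.committed_G(X), lambda X: study.committed_E(X)),
        n_events=n_events,
        max_steps=max_steps,
    )
    return {"G->E": fwd, "E->G": bwd}


def aggressive_ks_study(
    study: TwoStateStudy,
    n_runs: int = 20,
    n_events: int = 9,
    seed: int = 0,
    pace: int = 350,
    h0: float = 0.75,
    hill_width: float = 0.3,
    max_steps: int = 2_000_000,
    dt: float = 0.005,
):
    """KS/Poisson p-values under a deliberately over-aggressive protocol.

    The protocol violates the infrequent-deposition conditions the way that
    actually corrupts rate recovery: hills broad enough (width ~ the
    basin-to-barrier distance in S) to bias the transition-state region,
    deposited at the free-energy-run cadence.  In this system narrow hills
    at a fast pace alone are *not* enough to break exponentiality, because
    intra-basin relaxation is orders of magnitude faster than any
    deposition pace — the corruption comes from the transition state
    feeling the bias.  Returns the per-run KS p-values (G->E direction).
    """
    bp = BiasParams(h0=h0, pace=pace, gamma=10.0, fixed_widths=[hill_width])
    ps = []
    for rep in range(n_runs):
        samples = []
        for i in range(n_events):
            sim = SimulationParams(
                n_steps=max_steps,
                dt=dt,
                kBT=study.kBT,
                friction=1.0,
                seed=seed + 100 * rep + i,
            )
            samples.append(
                kin.sample_first_passage(
                    study.model,
                    study.cv,
                    bp,
                    lambda x: study.committed_E(x)[0],
                    sim,
                    np.array([study.model.minima[0]]),
                    enforce_protocol=False,
                )
            )
        ps.append(kin.ks_poisson_test(samples)[1])
    return np.array(ps)


def restrained_study(
    barrier: float = 3.0,
    delta: float = 1.5,
    n_replicas: int = 4,
    epsilon: float = 24.0,
    n_obs: int = 10,
    n_steps: int = 40_000,
    seed: int = 0,
    noise_fraction: float = 0.1,
):
    """Replica-averaged restrained sampling of the minor (E) basin.

    The system is the standard double well with a reduced barrier (3 kBT)
    so that, unrestrained, an E-started ensemble leaks back into the
    deeper G basin within the run length.  Synthetic "experimental"
    targets are the observables of a harmonic reference ensemble in the E
    basin plus noise; the restrained run starts at the E minimum.  Returns
    the ensemble, its E-band mass on the path CV, the observable RMSDs
    and the matching unrestrained (epsilon = 0) control.
    """
    from .restraints import (
        make_linear_observable_model,
        observable_rmsd,
        project_ensemble,
        run_restrained_sampling,
        synthetic_targets,
    )

    model = DoubleWell1D(barrier=barrier, delta_G_true=delta)
    path = build_reference_path(np.array([-2.0]), np.array([2.0]), n_nodes=31)
    obs = make_linear_observable_model(dof=1, n_obs=n_obs, seed=seed + 7)
    # harmonic reference ensemble around the E minimum
    rng = np.random.default_rng(seed + 13)
    curv = 8.0 * barrier - 0.5 * delta * (np.pi / 2.0) ** 2
    ref = model.minima[1] + np.sqrt(1.0 / curv) * rng.standard_normal((400, 1))
    targets = synthetic_targets(ref, obs, seed=seed + 29, noise_fraction=noise_fraction)
    sim = SimulationParams(n_steps=n_steps, dt=0.005, kBT=1.0, friction=1.0, seed=seed)
    x0 = np.array([model.minima[1]])
    ens = run_restrained_sampling(
        model, obs, targets, sim, x0,
        n_replicas=n_replicas, epsilon=epsilon, stride=10,
        equilibration=n_steps // 10,
    )
    control = run_restrained_sampling(
        model, obs, targets, sim, x0,
        n_replicas=n_replicas, epsilon=0.0, stride=10,
        equilibration=n_steps // 10,
    )
    _, _, _, mass = project_ensemble(ens.frames, path)
    _, _, _, mass_control = project_ensemble(control.frames, path)
    return {
        "model": model,
        "path": path,
        "obs": obs,
        "targets": targets,
        "ensemble": ens,
        "control": control,
        "e_band_mass": mass,
        "e_band_mass_unrestrained": mass_control,
        "rmsd": observable_rmsd(ens.frames, obs, targets),
        "rmsd_unrestrained": observable_rmsd(control.frames, obs, targets),
    }


def two_gap_shell_study(
    wide_half_angle: float = 0.80,
    narrow_half_angle: float = 0.28,
    narrow_openness: float = 0.72,
    shell_radius: float = 3.0,
):
    """Cavity with one wide (+z) and one narrow (-z) opening.

    Returns the smooth potential used for escape dynamics, the matching
    sphere model for tunnel detection (scaled to protein-like Angstrom
    dimensions), and the two gap axes.  The wide gap is fully open; the
    narrow one is both angularly smaller and sterically hindered (a
    residual wall of (1 - openness)*wall_height at its core), so escape
    flux strongly favours the wide opening while both register as tunnels
    in the sphere model.
    """
    wide_axis = np.array([0.0, 0.0, 1.0])
    narrow_axis = np.array([0.0, 0.0, -1.0])
    potential = ShellWithGaps3D(
        radius=shell_radius,
        sigma=0.3,
        wall_height=8.0,
        gaps=(
            (wide_axis, wide_half_angle, 1.0),
            (narrow_axis, narrow_half_angle, narrow_openness),
        ),
    )
    spheres = make_shell_sphere_model(
        radius=shell_radius * 2.5,  # sphere model scaled so vdW spheres seal the wall
        n_spheres=800,
        sphere_radius=1.0,
        gaps=((wide_axis, wide_half_angle), (narrow_axis, narrow_half_angle)),
    )
    # the bound pose sits off-center on the hindered side, as a buried
    # binding cavity does relative to its dominant escape tunnel
    bound_pose = -0.8 * wide_axis
    return potential, spheres, (wide_axis, narrow_axis), bound_pose


def abmd_escape_ensemble(
    potential: ShellWithGaps3D,
    exit_directions: np.ndarray,
    k: float,
    n_runs: int = 20,
    seed: int = 0,
    bound_pose: np.ndarray | None = None,
    n_steps: int = 400_000,
    dt: float = 0.005,
) -> list[EscapeResult]:
    """Seeded ratchet escape runs with exits labelled by tunnel direction."""
    out = []
    for i in range(n_runs):
        sim = SimulationParams(n_steps=n_steps, dt=dt, kBT=1.0, friction=1.0, seed=seed + i)
        out.append(
            run_abmd_escape(
                potential, k, sim,
                bound_pose=bound_pose, exit_directions=exit_directions,
            )
        )
    return out
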