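"""Two-state thermodynamics from a free-energy profile.

Separatrix location, basin populations by Boltzmann summation, the G->E
free-energy difference dG = G_E - G_G (positive when E is the minor
state), mutational ddG, and population <-> dG conversions at room
temperature (RT = 0.5925 kcal/mol at 298.15 K).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.signal import find_peaks

from .metad import FreeEnergySurface
from .units import R_KCAL, T_ROOM

__all__ = [
    "StatePartition",
    "DeltaG",
    "NoBarrierError",
    "find_separatrix",
    "delta_g_from_fes",
    "population_from_delta_g",
    "delta_g_from_population",
    "delta_delta_g",
    "delta_g_timeseries",
]


class NoBarrierError(ValueError):
    """The profile has no barrier splitting two basins."""


@dataclass
class StatePartition:
    """Dividing CV value s*: G is S < s*, E is S > s*."""

    separatrix: float

    def label_G(self, s) -> np.ndarray:
        return np.asarray(s) < self.separatrix

    def label_E(self, s) -> np.ndarray:
        return np.asarray(s) > self.separatrix


@dataclass
class DeltaG:
    """A free-energy difference with its temperature and provenance."""

    value: float  # kcal/mol unless noted otherwise by the caller
    temperature: float = T_ROOM
    provenance: str = "external"  # fes | rates | external

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise ValueError("dG must be finite")


def find_separatrix(F: FreeEnergySurface, min_barrier_kbt: float = 0.5) -> StatePartition:
    """Place the separatrix at the maximum of F between its two deepest minima.

    Basins are local minima with prominence of at least ``min_barrier_kbt``
    (in kBT), which makes the search robust to the softmin ripple that path
    CVs imprint on a profile.  Raises :class:`NoBarrierError` for
    monotone/single-basin profiles or when the barrier above the shallower
    minimum is below ``min_barrier_kbt``.
    """
    if F.ndim != 1:
        raise ValueError("separatrix search expects a 1-D profile")
    grid, f = F.grid[0], F.F
    finite = np.isfinite(f)
    grid, f = grid[finite], f[finite]
    minima, _ = find_peaks(-f, prominence=min_barrier_kbt * F.kBT)
    if len(minima) < 2:
        raise NoBarrierError("fewer than two prominent minima in the profile")
    minima = sorted(minima, key=lambda i: f[i])[:2]
    lo, hi = sorted(minima)
    barrier_idx = lo + int(np.argmax(f[lo : hi + 1]))
    barrier = f[barrier_idx] - max(f[lo], f[hi])
    if barrier < min_barrier_kbt * F.kBT:
        raise NoBarrierError(
            f"barrier {barrier / F.kBT:.2f} kBT below threshold {min_barrier_kbt}"
        )
    return StatePartition(separatrix=float(grid[barrier_idx]))


def delta_g_from_fes(
    F: FreeEnergySurface,
    part: StatePartition,
    kBT: float | None = None,
    temperature: float = T_ROOM,
    in_kcal: bool = False,
) -> DeltaG:
    """dG = -kBT ln(P_E/P_G) with P_X the Boltzmann mass of F on side X.

    The value is in the energy units of F (reduced kBT) unless ``in_kcal``
    is set, in which case the kBT value is converted through RT at
    ``temperature``.  Invariant to adding a constant to F.
    """
    if F.ndim != 1:
        raise ValueError("dG summation expects a 1-D profile")
    kBT = kBT if kBT is not None else F.kBT
    grid, f = F.grid[0], F.F
    finite = np.isfinite(f)
    w = np.zeros_like(f)
    w[finite] = np.exp(-(f[finite] - f[finite].min()) / kBT)
    dx = np.gradient(grid)
    pG = float(np.sum(w * dx * part.label_G(grid)))
    pE = float(np.sum(w * dx * part.label_E(grid)))
    if pG <= 0 or pE <= 0:
        raise ValueError("one side of the separatrix carries no population")
    dg_kbt = -np.log(pE / pG)
    if in_kcal:
        return DeltaG(
            value=dg_kbt * R_KCAL * temperature,
            temperature=temperature,
            provenance="fes",
        )
    return DeltaG(value=float(dg_kbt * kBT), temperature=temperature, provenance="fes")


def population_from_delta_g(dg: DeltaG) -> float:
    """E-state fraction of a two-state system: p_E = 1/(1 + exp(dG/RT)).

    For dG > 0 this is the minor-state population (e.g. 2.1 kcal/mol ->
    about 3%); for dG < 0 it is the now-major E fraction (e.g. -1.9 ->
    about 96%).
    """
    rt = R_KCAL * dg.temperature
    return float(1.0 / (1.0 + np.exp(dg.value / rt)))


def delta_g_from_population(p_e: float, temperature: float = T_ROOM) -> DeltaG:
    """Inverse of :func:`population_from_delta_g`: dG = -RT ln(p/(1-p))."""
    if not 0.0 < p_e < 1.0:
        raise ValueError("population must be in (0, 1)")
    rt = R_KCAL * temperature
    return DeltaG(value=float(-rt * np.log(p_e / (1.0 - p_e))), temperature=temperature)


def delta_delta_g(dg_a: DeltaG, dg_b: DeltaG) -> float:
    """ddG = dG_a - dG_b; both must share a temperature."""
    if abs(dg_a.temperature - dg_b.temperature) > 1e-9:
        raise ValueError("cannot subtract dG values at different temperatures")
    return dg_a.value - dg_b.value


def delta_g_timeseries(
    checkpoints: Sequence[FreeEnergySurface],
    part: StatePartition,
    kBT: float | None = None,
    tol: float = 0.1,
):
    """dG at each FES checkpoint plus a convergence flag.

    ``converged`` is True when the range of the last quarter of the series
    is below ``tol`` (in the same units as the dG values); None when fewer
    than two checkpoints make convergence undefined.
    """
    if len(checkpoints) < 1:
        raise ValueError("need at least one checkpoint")
    series = np.array(
        [delta_g_from_fes(F, part, kBT=kBT).value for F in checkpoints]
    )
    times = np.array([F.checkpoint_time for F in checkpoints])
    if len(series) < 2:
        converged = None
    else:
        tail = series[-max(1, len(series) // 4) :]
        converged = bool(tail.max() - tail.min() < tol)
    return times, series, converged
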