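"""Cavity-to-surface tunnel detection on sphere models.

A protein (or synthetic shell) is modelled as a set of van der Waals
spheres.  The clearance field on a regular grid is the distance from each
grid point to the nearest sphere surface; a tunnel is a widest
(maximum-bottleneck) path from a cavity seed point to the exterior,
found with a priority-first (Dijkstra-style) search that maximises the
minimum clearance along the path.  Each distinct surface exit yields one
tunnel with its centerline, clearance profile, bottleneck radius and arc
length.  Tunnels from an ensemble of models are grouped by average-link
hierarchical clustering of pairwise centerline distances.
"""

from __future__ import annotations

import heapq
import io
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial import cKDTree
from scipy.spatial.distance import squareform

__all__ = [
    "VDW_RADII",
    "SphereModel",
    "Tunnel",
    "TunnelCluster",
    "read_structure",
    "make_shell_sphere_model",
    "shell_gap_clearance",
    "detect_tunnels",
    "bottleneck_by_threshold",
    "cluster_tunnels",
    "ensemble_tunnel_stats",
]

#: Bondi-style van der Waals radii (Angstrom) keyed by element symbol.
VDW_RADII = {
    "H": 1.20,
    "C": 1.70,
    "N": 1.55,
    "O": 1.52,
    "F": 1.47,
    "P": 1.80,
    "S": 1.80,
    "CL": 1.75,
    "BR": 1.85,
    "I": 1.98,
    "SE": 1.90,
}
_DEFAULT_RADIUS = 1.70
_WATER_RESNAMES = {"HOH", "WAT", "DOD", "H2O"}


@dataclass
class SphereModel:
    """Van der Waals sphere set with an optional cavity seed point."""

    centers: np.ndarray  # (n, 3) Angstrom
    radii: np.ndarray  # (n,)
    seed_point: np.ndarray | None = None

    def __post_init__(self):
        self.centers = np.atleast_2d(np.asarray(self.centers, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).reshape(-1)
        if np.any(self.radii <= 0):
            raise ValueError("all sphere radii must be positive")
        if self.seed_point is not None:
            self.seed_point = np.asarray(self.seed_point, dtype=float).reshape(3)
            if self.clearance(self.seed_point[None, :])[0] <= 0:
                raise ValueError("seed point lies inside a sphere")

    def clearance(self, points: np.ndarray, k: int = 24) -> np.ndarray:
        """Distance from each point to the nearest sphere surface.

        Uses the k nearest centers from a KD-tree; exact whenever the
        radius spread is smaller than the center-distance slack, which
        holds for vdW radii (spread < 0.8 A) at k = 24.
        """
        pts = np.atleast_2d(points)
        k = min(k, len(self.radii))
        dist, idx = cKDTree(self.centers).query(pts, k=k)
        dist = np.atleast_2d(dist.reshape(len(pts), k))
        idx = np.atleast_2d(idx.reshape(len(pts), k))
        return np.min(dist - self.radii[idx], axis=1)


@dataclass
class Tunnel:
    """Cavity-to-surface centerline with its clearance profile."""

    centerline: np.ndarray  # (m, 3) ordered seed -> exit
    clearance: np.ndarray  # (m,) radius profile along the centerline

    def __post_init__(self):
        self.centerline = np.atleast_2d(np.asarray(self.centerline, dtype=float))
        self.clearance = np.asarray(self.clearance, dtype=float).reshape(-1)
        if np.any(self.clearance <= 0):
            raise ValueError("clearance must stay positive along a tunnel")

    @property
    def bottleneck(self) -> float:
        return float(self.clearance.min())

    @property
    def length(self) -> float:
        return float(
            np.sum(np.linalg.norm(np.diff(self.centerline, axis=0), axis=1))
        )

    @property
    def exit_point(self) -> np.ndarray:
        return self.centerline[-1]

    def direction_at_radius(self, origin: np.ndarray, r: float) -> np.ndarray:
        """Unit direction of the first centerline point beyond radius ``r``
        from ``origin`` — the direction in which the tunnel pierces the
        surface (more robust than the grid-boundary endpoint)."""
        origin = np.asarray(origin, dtype=float)
        dist = np.linalg.norm(self.centerline - origin, axis=1)
        beyond = np.nonzero(dist >= r)[0]
        idx = beyond[0] if len(beyond) else len(dist) - 1
        v = self.centerline[idx] - origin
        return v / max(np.linalg.norm(v), 1e-12)

    def resample(self, m: int = 20) -> np.ndarray:
        """Centerline resampled to ``m`` arc-length-equidistant points."""
        seg = np.linalg.norm(np.diff(self.centerline, axis=0), axis=1)
        arc = np.concatenate([[0.0], np.cumsum(seg)])
        if arc[-1] == 0.0:
            return np.tile(self.centerline[0], (m, 1))
        t = np.linspace(0.0, arc[-1], m)
        return np.stack(
            [np.interp(t, arc, self.centerline[:, d]) for d in range(3)], axis=1
        )


@dataclass
class TunnelCluster:
    members: list
    representative: Tunnel
    fraction: float


def read_structure(
    pdb_text: str, strip_ligands: bool = True, keep_hydrogens: bool = False
) -> SphereModel:
    """Parse PDB text into a sphere model.

    Keeps heavy protein atoms (ATOM records); waters are always dropped;
    HETATM ligands are dropped unless ``strip_ligands`` is False; of
    alternate locations only blank or 'A' are kept.  Radii come from the
    element-keyed vdW table, falling back to 1.7 A with a warning for
    unknown elements.
    """
    from Bio.PDB import PDBParser

    parser = PDBParser(QUIET=True)
    structure = parser.get_structure("model", io.StringIO(pdb_text))
    centers, radii = [], []
    for atom in structure.get_atoms():
        res = atom.get_parent()
        resname = res.get_resname().strip().upper()
        if resname in _WATER_RESNAMES:
            continue
        hetflag = res.id[0].strip()
        if hetflag and strip_ligands:
            continue
        if atom.get_altloc() not in (" ", "A"):
            continue
        element = (atom.element or "").strip().upper()
        if element == "H" and not keep_hydrogens:
            continue
        if element not in VDW_RADII:
            warnings.warn(
                f"unknown element {element!r}; using {_DEFAULT_RADIUS} A",
                stacklevel=2,
            )
            r = _DEFAULT_RADIUS
        else:
            r = VDW_RADII[element]
        centers.append(atom.get_coord())
        radii.append(r)
    if not centers:
        raise ValueError("no usable atoms in PDB text")
    return SphereModel(centers=np.array(centers, dtype=float), radii=np.array(radii))


def make_shell_sphere_model(
    radius: float = 8.0,
    n_spheres: int = 600,
    sphere_radius: float = 1.7,
    gaps: tuple = (),
    seed: int = 0,
) -> SphereModel:
    """Synthetic spherical shell of spheres with circular gaps.

    Sphere centers sit on a Fibonacci lattice of the shell; centers within
    a gap's angular half-width of its axis are removed, opening a circular
    aperture.  ``gaps`` is a tuple of ``(axis, half_angle_rad)`` pairs.
    The cavity seed is the shell center.
    """
    i = np.arange(n_spheres)
    phi = np.pi * (3.0 - np.sqrt(5.0)) * i
    z = 1.0 - 2.0 * (i + 0.5) / n_spheres
    rho = np.sqrt(np.maximum(0.0, 1.0 - z * z))
    pts = np.stack([rho * np.cos(phi), rho * np.sin(phi), z], axis=1)
    keep = np.ones(n_spheres, dtype=bool)
    for axis, half_angle in gaps:
        axis = np.asarray(axis, dtype=float)
        axis = axis / np.linalg.norm(axis)
        keep &= pts @ axis < np.cos(half_angle)
    centers = radius * pts[keep]
    return SphereModel(
        centers=centers,
        radii=np.full(keep.sum(), sphere_radius),
        seed_point=np.zeros(3),
    )


def shell_gap_clearance(
    model: SphereModel, gap_axis: np.ndarray, r_max: float, n_scan: int = 2000
) -> float:
    """Analytic-geometry oracle for a shell gap's bottleneck.

    Scans the gap axis from the cavity center outward and returns the
    maximum over the axis of the minimum clearance — the widest probe that
    can pass through the aperture center, computed directly from the sphere
    set without any grid or path search.
    """
    axis = np.asarray(gap_axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    ts = np.linspace(0.0, r_max, n_scan)
    pts = np.outer(ts, axis)
    c = model.clearance(pts, k=min(64, len(model.radii)))
    # bottleneck of the axial path: the widest path through the gap must
    # pass the aperture, where the axial clearance is smallest beyond the
    # cavity; take min over the wall region then max cannot exceed it
    return float(np.min(c))


_NEIGHBOR_OFFSETS = np.array(
    [[1, 0, 0], [-1, 0, 0], [0, 1, 0], [0, -1, 0], [0, 0, 1], [0, 0, -1]]
)


def _build_grid(model: SphereModel, grid_spacing: float, padding: float):
    lo = model.centers.min(axis=0) - model.radii.max() - padding
    hi = model.centers.max(axis=0) + model.radii.max() + padding
    axes = [np.arange(lo[d], hi[d] + grid_spacing, grid_spacing) for d in range(3)]
    shape = tuple(len(a) for a in axes)
    XX, YY, ZZ = np.meshgrid(*axes, indexing="ij")
    pts = np.stack([XX.ravel(), YY.ravel(), ZZ.ravel()], axis=1)
    clearance = model.clearance(pts).reshape(shape)
    return axes, clearance


def _widest_path(clearance, seed_idx, open_mask):
    """Priority-first search maximising the path's minimum clearance.

    Returns ``(best, pred)``: the best achievable bottleneck per cell and
    the predecessor array for backtracking.
    """
    shape = clearance.shape
    best = np.full(shape, -np.inf)
    pred = np.full(shape + (3,), -1, dtype=np.int32)
    best[seed_idx] = clearance[seed_idx]
    heap = [(-best[seed_idx], seed_idx)]
    while heap:
        negb, idx = heapq.heappop(heap)
        b = -negb
        if b < best[idx]:
            continue
        for off in _NEIGHBOR_OFFSETS:
            nb = (idx[0] + off[0], idx[1] + off[1], idx[2] + off[2])
            if not (
                0 <= nb[0] < shape[0]
                and 0 <= nb[1] < shape[1]
                and 0 <= nb[2] < shape[2]
            ):
                continue
            if not open_mask[nb]:
                continue
            cand = min(b, clearance[nb])
            if cand > best[nb]:
                best[nb] = cand
                pred[nb] = idx
                heapq.heappush(heap, (-cand, nb))
    return best, pred


def detect_tunnels(
    model: SphereModel,
    grid_spacing: float = 0.4,
    min_clearance: float = 0.9,
    padding: float = 2.0,
    max_tunnels: int = 8,
) -> list[Tunnel]:
    """Widest cavity-to-surface paths on a clearance grid.

    A priority-first search from the seed cell propagates the best
    achievable bottleneck (max over paths of min clearance) through
    6-connected cells whose clearance exceeds ``min_clearance``.  The path
    to the best-reachable grid-boundary cell is backtracked into tunnel
    #1; its corridor through the sphere-occupied wall region is then
    blocked and the search repeated, so each further tunnel must thread a
    distinct opening.  Extraction stops when the exterior becomes
    unreachable or ``max_tunnels`` is hit.  Returns an empty list for a
    sealed cavity; raises if the seed point is missing or blocked.
    """
    if model.seed_point is None:
        raise ValueError("sphere model has no cavity seed point")
    axes, clearance = _build_grid(model, grid_spacing, padding)
    shape = clearance.shape
    seed_idx = tuple(
        int(np.clip(np.searchsorted(axes[d], model.seed_point[d]) - 1, 0, shape[d] - 1))
        for d in range(3)
    )
    if clearance[seed_idx] <= min_clearance:
        raise ValueError("seed point is not inside an open cavity")

    boundary = np.zeros(shape, dtype=bool)
    for d in range(3):
        sl = [slice(None)] * 3
        for edge in (0, shape[d] - 1):
            sl[d] = edge
            boundary[tuple(sl)] = True

    # wall region: radial band (from the seed) actually occupied by spheres
    radial = np.linalg.norm(model.centers - model.seed_point, axis=1)
    wall_lo = float(radial.min() - model.radii.max())
    wall_hi = float(radial.max() + model.radii.max())
    grids = np.meshgrid(*axes, indexing="ij")
    r_seed = np.sqrt(
        sum((g - s) ** 2 for g, s in zip(grids, model.seed_point))
    )
    in_wall = (r_seed >= wall_lo) & (r_seed <= wall_hi)
    cell_pts = np.stack([g.ravel() for g in grids], axis=1)

    open_mask = clearance > min_clearance
    tunnels = []
    for _ in range(max_tunnels):
        best, pred = _widest_path(clearance, seed_idx, open_mask)
        reached = boundary & (best > -np.inf)
        if not reached.any():
            break
        cells = np.argwhere(reached)
        target = tuple(cells[int(np.argmax([best[tuple(c)] for c in cells]))])
        chain = [target]
        while chain[-1] != seed_idx:
            p = tuple(pred[chain[-1]])
            if p == (-1, -1, -1):
                break
            chain.append(p)
        chain.reverse()
        pts = np.array([[axes[d][c[d]] for d in range(3)] for c in chain])
        prof = np.array([clearance[c] for c in chain])
        tunnel = Tunnel(centerline=pts, clearance=prof)
        tunnels.append(tunnel)
        # block a corridor around this tunnel's wall passage
        wall_pts = pts[
            (np.linalg.norm(pts - model.seed_point, axis=1) >= wall_lo)
            & (np.linalg.norm(pts - model.seed_point, axis=1) <= wall_hi)
        ]
        if len(wall_pts) == 0:
            break
        block_radius = 2.0 * tunnel.bottleneck + grid_spacing
        near = cKDTree(wall_pts).query(cell_pts, k=1)[0].reshape(shape)
        open_mask = open_mask & ~(in_wall & (near <= block_radius))
    tunnels.sort(key=lambda t: -t.bottleneck)
    return tunnels


def bottleneck_by_threshold(
    model: SphereModel,
    grid_spacing: float = 0.4,
    min_clearance: float = 0.9,
    padding: float = 2.0,
    tol: float = 1e-3,
) -> float:
    """Independent widest-path oracle by threshold bisection.

    The true maximum-bottleneck value equals the largest threshold t at
    which the seed cell is still connected to the grid boundary through
    cells of clearance >= t; found by bisection over connected-component
    labelling, with no path search involved.
    """
    if model.seed_point is None:
        raise ValueError("sphere model has no cavity seed point")
    axes, clearance = _build_grid(model, grid_spacing, padding)
    shape = clearance.shape
    seed_idx = tuple(
        int(np.clip(np.searchsorted(axes[d], model.seed_point[d]) - 1, 0, shape[d] - 1))
        for d in range(3)
    )

    def connected(t: float) -> bool:
        mask = clearance >= t
        if not mask[seed_idx]:
            return False
        labels, _ = ndimage.label(mask)
        seed_label = labels[seed_idx]
        boundary_labels = np.concatenate(
            [
                labels[0].ravel(), labels[-1].ravel(),
                labels[:, 0].ravel(), labels[:, -1].ravel(),
                labels[:, :, 0].ravel(), labels[:, :, -1].ravel(),
            ]
        )
        return seed_label in boundary_labels

    lo, hi = min_clearance, float(clearance[seed_idx])
    if not connected(lo):
        return np.nan
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if connected(mid):
            lo = mid
        else:
            hi = mid
    return lo


def cluster_tunnels(
    tunnels: list[Tunnel], threshold: float = 3.0, n_points: int = 20
) -> list[TunnelCluster]:
    """Average-link clustering of tunnels by mean centerline distance.

    The pairwise tunnel distance is the mean Euclidean distance between
    arc-length-matched centerline points; the average-link dendrogram is
    cut at ``threshold`` (Angstrom).  Clusters are ranked by population
    fraction; the representative is the member with the widest bottleneck.
    """
    if len(tunnels) == 0:
        raise ValueError("need at least one tunnel")
    if len(tunnels) == 1:
        return [TunnelCluster(members=list(tunnels), representative=tunnels[0], fraction=1.0)]
    P = np.stack([t.resample(n_points) for t in tunnels])  # (n, m, 3)
    D = np.linalg.norm(P[:, None, :, :] - P[None, :, :, :], axis=3).mean(axis=2)
    Z = linkage(squareform(D, checks=False), method="average")
    assignment = fcluster(Z, t=threshold, criterion="distance")
    clusters = []
    for cid in np.unique(assignment):
        members = [t for t, a in zip(tunnels, assignment) if a == cid]
        rep = max(members, key=lambda t: t.bottleneck)
        clusters.append(
            TunnelCluster(
                members=members,
                representative=rep,
                fraction=len(members) / len(tunnels),
            )
        )
    clusters.sort(key=lambda c: -c.fraction)
    return clusters


def ensemble_tunnel_stats(clusters: list[TunnelCluster]):
    """Per-cluster summary: population, max/mean bottleneck, mean length."""
    import pandas as pd

    if not clusters:
        raise ValueError("no clusters to summarise")
    rows = []
    for i, c in enumerate(clusters):
        b = np.array([t.bottleneck for t in c.members])
        ln = np.array([t.length for t in c.members])
        rows.append(
            {
                "cluster": i + 1,
                "n_tunnels": len(c.members),
                "fraction": c.fraction,
                "max_bottleneck": float(b.max()),
                "mean_bottleneck": float(b.mean()),
                "mean_length": float(ln.mean()),
            }
        )
    return pd.DataFrame(rows)
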