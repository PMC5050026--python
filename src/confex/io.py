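"""Plain-text serialization: XYZ trajectories/paths, TSV tables, YAML configs."""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "write_xyz",
    "read_xyz",
    "write_hills_tsv",
    "write_fes_tsv",
    "write_trajectory_tsv",
    "write_yaml",
    "read_yaml",
    "write_json",
]


def write_xyz(path, frames: np.ndarray, comment: str = "", names=None):
    """Write frames (n_frames, n_particles, ndim<=3) as multi-frame XYZ.

    Coordinates with fewer than 3 dimensions are zero-padded; particles are
    labelled 'X' unless ``names`` is given.
    """
    frames = np.asarray(frames, dtype=float)
    if frames.ndim == 2:
        frames = frames[:, :, None] if frames.shape[1] == 1 else frames[:, None, :]
    n_particles = frames.shape[1]
    names = names or ["X"] * n_particles
    with open(path, "w") as fh:
        for i, frame in enumerate(frames):
            fh.write(f"{n_particles}\n{comment} frame {i}\n")
            for name, coords in zip(names, frame):
                xyz = np.zeros(3)
                xyz[: len(coords)] = coords
                fh.write(f"{name} {xyz[0]:.8f} {xyz[1]:.8f} {xyz[2]:.8f}\n")


def read_xyz(path) -> np.ndarray:
    """Read multi-frame XYZ back into an (n_frames, n_particles, 3) array."""
    frames = []
    with open(path) as fh:
        lines = fh.read().splitlines()
    i = 0
    while i < len(lines):
        n = int(lines[i].strip())
        block = lines[i + 2 : i + 2 + n]
        frames.append([[float(v) for v in ln.split()[1:4]] for ln in block])
        i += 2 + n
    return np.array(frames, dtype=float)


def write_hills_tsv(path, bias):
    """Hill history as TSV: time, center_*, width_*, height (stable order)."""
    n_cv = bias.n_cv
    cols = (
        ["time"]
        + [f"center_{i}" for i in range(n_cv)]
        + [f"width_{i}" for i in range(n_cv)]
        + ["height"]
    )
    data = np.column_stack(
        [bias.times, bias.centers, bias.widths, bias.heights]
    ) if len(bias.heights) else np.empty((0, len(cols)))
    pd.DataFrame(data, columns=cols).to_csv(path, sep="\t", index=False)


def write_fes_tsv(path, fes):
    """1-D or 2-D free-energy surface as a TSV grid table."""
    if fes.ndim == 1:
        df = pd.DataFrame({"cv": fes.grid[0], "F": fes.F})
    else:
        XX, YY = np.meshgrid(fes.grid[0], fes.grid[1], indexing="ij")
        df = pd.DataFrame(
            {"cv0": XX.ravel(), "cv1": YY.ravel(), "F": fes.F.ravel()}
        )
    df.to_csv(path, sep="\t", index=False)


def write_trajectory_tsv(path, traj):
    """Time/energy/CV sidecar for a trajectory."""
    data = {"time": traj.times}
    if traj.energies is not None:
        data["energy"] = traj.energies
    if traj.cv_series is not None:
        for i in range(traj.cv_series.shape[1]):
            data[f"cv_{i}"] = traj.cv_series[:, i]
    pd.DataFrame(data).to_csv(path, sep="\t", index=False)


def write_yaml(path, obj: dict):
    with open(path, "w") as fh:
        yaml.safe_dump(obj, fh, sort_keys=False)


def read_yaml(path) -> dict:
    with open(path) as fh:
        return yaml.safe_load(fh)


def write_json(path, obj: dict):
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True) + "\n")
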