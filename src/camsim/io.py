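"""Trajectory container and HDF5 round trip.

Layout of the HDF5 file::

    /config            (attrs: yaml = run-config snapshot, seed)
    /frames/000000/    positions (n,2), polarizations (n,2),
                       velocities (n,2), ids (n,)   [attr: time]
    /frames/000001/    ...

Per-frame cell counts may differ (division).  CSV export flattens all
frames into tidy rows.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

__all__ = ["Trajectory", "write_trajectory", "read_trajectory",
           "trajectory_to_csv", "voronoi_to_csv"]


@dataclass
class Trajectory:
    """Recorded frames of one simulation run."""

    times: list[float] = field(default_factory=list)
    positions: list[np.ndarray] = field(default_factory=list)
    polarizations: list[np.ndarray] = field(default_factory=list)
    velocities: list[np.ndarray] = field(default_factory=list)
    ids: list[np.ndarray] = field(default_factory=list)
    config_yaml: str = ""
    seed: int = 0

    def __len__(self) -> int:
        return len(self.times)

    def append(self, time, positions, polarizations, velocities, ids) -> None:
        if self.times and time <= self.times[-1]:
            raise ValueError("frame times must be strictly increasing")
        self.times.append(float(time))
        self.positions.append(np.array(positions))
        self.polarizations.append(np.array(polarizations))
        self.velocities.append(np.array(velocities))
        self.ids.append(np.array(ids))


def write_trajectory(traj: Trajectory, path) -> None:
    """Write all frames plus the config snapshot to an HDF5 file."""
    with h5py.File(path, "w") as f:
        f.attrs["config_yaml"] = traj.config_yaml
        f.attrs["seed"] = traj.seed
        f.attrs["n_frames"] = len(traj)
        frames = f.create_group("frames")
        for k in range(len(traj)):
            g = frames.create_group(f"{k:06d}")
            g.attrs["time"] = traj.times[k]
            g.create_dataset("positions", data=traj.positions[k])
            g.create_dataset("polarizations", data=traj.polarizations[k])
            g.create_dataset("velocities", data=traj.velocities[k])
            g.create_dataset("ids", data=traj.ids[k])


def read_trajectory(path) -> Trajectory:
    """Lossless inverse of :func:`write_trajectory` (raises on truncation)."""
    traj = Trajectory()
    with h5py.File(path, "r") as f:
        try:
            traj.config_yaml = str(f.attrs["config_yaml"])
            traj.seed = int(f.attrs["seed"])
            n_frames = int(f.attrs["n_frames"])
            frames = f["frames"]
            keys = sorted(frames.keys())
            if len(keys) != n_frames:
                raise KeyError(
                    f"/frames holds {len(keys)} groups, header says {n_frames}"
                )
            for k in keys:
                g = frames[k]
                traj.append(
                    float(g.attrs["time"]),
                    g["positions"][...],
                    g["polarizations"][...],
                    g["velocities"][...],
                    g["ids"][...],
                )
        except KeyError as exc:
            raise IOError(f"malformed trajectory file {path}: {exc}") from exc
    return traj


def voronoi_to_csv(voronoi, ids, path) -> None:
    """Dump clipped Voronoi polygons as (cell_id, vertex order, x, y) rows."""
    rows = []
    for i, verts in enumerate(voronoi.polygons):
        for order, (x, y) in enumerate(verts):
            rows.append({"cell_id": int(ids[i]), "ring_order": order,
                         "vertex_x": x, "vertex_y": y})
    pd.DataFrame(rows).to_csv(path, index=False)


def trajectory_to_csv(traj: Trajectory, path) -> None:
    """Tidy per-cell export: one row per (frame, cell)."""
    rows = []
    for k in range(len(traj)):
        t = traj.times[k]
        for c in range(len(traj.ids[k])):
            rows.append({
                "time": t,
                "cell_id": int(traj.ids[k][c]),
                "x": traj.positions[k][c, 0],
                "y": traj.positions[k][c, 1],
                "px": traj.polarizations[k][c, 0],
                "py": traj.polarizations[k][c, 1],
                "vx": traj.velocities[k][c, 0],
                "vy": traj.velocities[k][c, 1],
            })
    pd.DataFrame(rows).to_csv(path, index=False)
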